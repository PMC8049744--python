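"""Readers and writers for the plain-text formats used throughout the pipeline.

Coordinate convention: all genomic intervals are 0-based, half-open
(``width == end - start``), in memory and on disk (BED/narrowPeak dialect).
Count matrices are tab-separated with features in rows and a header row of
sample ids; the companion sample sheet is a TSV keyed by sample id.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "CountExperiment",
    "MotifModel",
    "read_counts",
    "write_counts",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_bed6",
    "write_bed6",
    "read_pwm",
    "write_pwm",
    "read_fasta",
    "write_fasta",
]

DESIGN_COLUMNS = ("structure", "timepoint", "treatment", "replicate")


class FormatError(ValueError):
    """Raised when an on-disk file violates its format contract."""


@dataclass(frozen=True)
class GenomicInterval:
    """A scored genomic interval (0-based, half-open).

    ``summit_offset`` is the narrowPeak column-10 point-source offset relative
    to ``start``; -1 means "no summit recorded" (plain BED6 input).
    """

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."
    summit_offset: int = -1

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.summit_offset != -1 and not (0 <= self.summit_offset < self.width):
            raise FormatError(
                f"summit offset {self.summit_offset} outside interval of width {self.width}"
            )
        if self.strand not in ("+", "-", "."):
            raise FormatError(f"bad strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return self.start + self.width // 2

    @property
    def summit(self) -> int:
        """Absolute summit coordinate; interval midpoint when no summit is set."""
        if self.summit_offset == -1:
            return self.midpoint
        return self.start + self.summit_offset

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def reciprocal_overlap(self, other: "GenomicInterval", frac: float = 0.5) -> bool:
        ov = self.overlap(other)
        return ov >= frac * self.width and ov >= frac * other.width


class PeakSet:
    """An ordered collection of :class:`GenomicInterval`."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self.intervals: list[GenomicInterval] = list(intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, PeakSet) and self.intervals == other.intervals

    def sorted(self) -> "PeakSet":
        return PeakSet(sorted(self.intervals, key=lambda p: (p.chrom, p.start, p.end)))

    def names(self) -> list[str]:
        return [p.name for p in self.intervals]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [p.chrom for p in self.intervals],
                "start": [p.start for p in self.intervals],
                "end": [p.end for p in self.intervals],
                "name": [p.name for p in self.intervals],
                "score": [p.score for p in self.intervals],
                "strand": [p.strand for p in self.intervals],
                "summit_offset": [p.summit_offset for p in self.intervals],
            }
        )


@dataclass
class CountExperiment:
    """Feature x sample integer counts plus the per-sample design.

    ``design`` is indexed by sample id with columns
    (structure, timepoint, treatment, replicate).
    """

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.columns.duplicated().any():
            raise FormatError("duplicate sample ids in count matrix")
        if self.counts.index.duplicated().any():
            raise FormatError("duplicate feature ids in count matrix")
        missing = set(self.counts.columns) - set(self.design.index)
        if missing:
            raise FormatError(f"samples missing from design sheet: {sorted(missing)}")
        for col in DESIGN_COLUMNS:
            if col not in self.design.columns:
                raise FormatError(f"design sheet missing column {col!r}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                bad = np.argwhere(~np.isclose(vals, np.round(vals)))[0]
                raise FormatError(
                    f"non-integer count at feature {self.counts.index[bad[0]]!r}, "
                    f"sample {self.counts.columns[bad[1]]!r}"
                )
            self.counts = self.counts.round().astype(np.int64)
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            bad = np.argwhere(vals < 0)[0]
            raise FormatError(
                f"negative count at feature {self.counts.index[bad[0]]!r}, "
                f"sample {self.counts.columns[bad[1]]!r}"
            )
        # align design rows to count columns
        self.design = self.design.loc[list(self.counts.columns)]

    @property
    def features(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_features(self, features: Sequence[str]) -> "CountExperiment":
        return CountExperiment(self.counts.loc[list(features)], self.design.copy())

    def subset_samples(self, samples: Sequence[str]) -> "CountExperiment":
        return CountExperiment(
            self.counts[list(samples)], self.design.loc[list(samples)].copy()
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CountExperiment)
            and self.counts.equals(other.counts)
            and self.design.equals(other.design)
        )


@dataclass
class MotifModel:
    """A base-probability PWM over A, C, G, T.

    ``matrix`` has shape (4, L) with columns summing to 1; ``background`` is
    the base composition used for log-odds scoring.
    """

    id: str
    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 0.008

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4:
            raise FormatError(f"PWM {self.id}: matrix must be 4 x L")
        if self.matrix.shape[1] < 4:
            raise FormatError(f"PWM {self.id}: motif length must be >= 4")
        colsums = self.matrix.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-6):
            raise FormatError(f"PWM {self.id}: probability columns must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=0))

    def reverse_complement(self) -> "MotifModel":
        return replace(self, matrix=self.matrix[::-1, ::-1])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, MotifModel)
            and self.id == other.id
            and np.allclose(self.matrix, other.matrix)
            and np.allclose(self.background, other.background)
        )


# ---------------------------------------------------------------------------
# count matrix + sample sheet


def write_counts(exp: CountExperiment, counts_path, sheet_path) -> None:
    counts = exp.counts.copy()
    counts.index.name = "feature"
    counts.to_csv(counts_path, sep="\t")
    design = exp.design.copy()
    design.index.name = "sample"
    design.to_csv(sheet_path, sep="\t")


def read_counts(counts_path, sheet_path) -> CountExperiment:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0, comment="#")
    try:
        counts = counts.astype(np.int64)
    except (ValueError, TypeError):
        # let CountExperiment produce the precise error message
        counts = counts.apply(pd.to_numeric, errors="raise")
    design = pd.read_csv(sheet_path, sep="\t", index_col=0, comment="#")
    return CountExperiment(counts, design)


# ---------------------------------------------------------------------------
# narrowPeak / BED6


def _parse_bed_line(line: str, lineno: int, path) -> GenomicInterval:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 6:
        raise FormatError(f"{path}:{lineno}: expected >= 6 tab-separated columns")
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: non-numeric coordinates") from exc
    score = float(fields[4]) if fields[4] != "." else 0.0
    summit = -1
    if len(fields) >= 10:
        score = float(fields[6])  # signalValue preferred for scored peak lists
        summit = int(fields[9])
    try:
        return GenomicInterval(
            chrom=fields[0],
            start=start,
            end=end,
            name=fields[3],
            score=score,
            strand=fields[5],
            summit_offset=summit,
        )
    except FormatError as exc:
        raise FormatError(f"{path}:{lineno}: {exc}") from exc


def read_narrowpeak(path) -> PeakSet:
    """Read a narrowPeak (BED6+4) or plain BED6 file.

    For 10-column lines the score reported on the interval is the signalValue
    (column 7) — the column used downstream for IDR ranking — and the summit
    offset is preserved.  BED6 lines get ``summit_offset = -1``.
    """
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            peaks.append(_parse_bed_line(line, lineno, path))
    return PeakSet(peaks)


def write_narrowpeak(peaks: PeakSet, path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t"
                f"{min(1000, int(round(p.score)))}\t{p.strand}\t"
                f"{p.score:g}\t-1\t-1\t{p.summit_offset}\n"
            )


read_bed6 = read_narrowpeak


def write_bed6(peaks: PeakSet, path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.score:g}\t{p.strand}\n"
            )


# ---------------------------------------------------------------------------
# JASPAR-like PWM text
#
#   >motif_id optional description
#   A [ 10  0  3 ... ]
#   C [  0 10  2 ... ]
#   G ...
#   T ...
#
# Rows may also be bare whitespace-separated numbers in ACGT order. Count
# matrices are converted to probabilities with the model pseudocount.

_BASE_ORDER = "ACGT"


def _rows_to_motif(motif_id: str, rows: list[list[float]], pseudocount: float) -> MotifModel:
    if len(rows) != 4:
        raise FormatError(f"PWM {motif_id}: expected 4 base rows, got {len(rows)}")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise FormatError(f"PWM {motif_id}: ragged matrix (row lengths {sorted(lengths)})")
    mat = np.array(rows, dtype=float)
    colsums = mat.sum(axis=0)
    if np.any(colsums <= 0):
        raise FormatError(f"PWM {motif_id}: column with sum 0")
    if np.allclose(colsums, 1.0, atol=1e-6):
        probs = mat / colsums
    else:
        # counts: add pseudocount then normalize
        mat = mat + pseudocount
        probs = mat / mat.sum(axis=0)
    return MotifModel(id=motif_id, matrix=probs, pseudocount=pseudocount)


def read_pwm(path, pseudocount: float = 0.008) -> list[MotifModel]:
    motifs: list[MotifModel] = []
    motif_id: str | None = None
    rows: list[list[float]] = []

    def flush() -> None:
        nonlocal rows, motif_id
        if motif_id is not None:
            motifs.append(_rows_to_motif(motif_id, rows, pseudocount))
        rows = []

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush()
                motif_id = line[1:].split()[0]
                continue
            if motif_id is None:
                raise FormatError(f"{path}: matrix row before any >header")
            tokens = line.replace("[", " ").replace("]", " ").split()
            if tokens and tokens[0].upper() in _BASE_ORDER and len(tokens) > 1:
                base = tokens[0].upper()
                expected = _BASE_ORDER[len(rows)]
                if base != expected:
                    raise FormatError(
                        f"PWM {motif_id}: row order must be A,C,G,T (got {base})"
                    )
                tokens = tokens[1:]
            try:
                rows.append([float(t) for t in tokens])
            except ValueError as exc:
                raise FormatError(f"PWM {motif_id}: malformed numeric row") from exc
    flush()
    return motifs


def write_pwm(motifs: Sequence[MotifModel], path) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f">{m.id}\n")
            for b, row in zip(_BASE_ORDER, m.matrix):
                fh.write(f"{b} [ " + " ".join(f"{v:.6f}" for v in row) + " ]\n")


# ---------------------------------------------------------------------------
# FASTA (peak sequences for motif scanning)


def read_fasta(path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line.upper())
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(seqs: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# JSON / YAML helpers


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def write_yaml(obj, path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def read_yaml(path):
    return yaml.safe_load(Path(path).read_text())
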