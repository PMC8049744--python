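"""PWM scanning, peak annotation, and bias-corrected motif deviation scores.

Deviation scoring follows the published accessibility-deviation definition:
per motif and sample, the observed aggregate count in motif-bearing peaks is
compared with the expectation under proportional sampling, and the resulting
fractional deviation is z-scored against background peak sets matched on GC
content and mean accessibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial import cKDTree

from .formats import GenomicInterval, MotifModel, PeakSet

__all__ = [
    "MotifHit",
    "MotifAnnotation",
    "DeviationMatrix",
    "scan_pwm",
    "scan_peak_sequences",
    "fix_peak_width",
    "make_annotation",
    "annotation_from_placements",
    "deviation_scores",
    "significant_motifs",
    "motif_similarity",
    "cluster_motifs",
]

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass(frozen=True)
class MotifHit:
    position: int     # 0-based offset of the match on the forward sequence
    strand: str
    score: float


def _logodds(motif: MotifModel) -> np.ndarray:
    """5 x L log-odds matrix (last row: N scores 0)."""
    m = motif.matrix + motif.pseudocount
    m = m / m.sum(axis=0)
    ll = np.log(m / motif.background[:, None])
    return np.vstack([ll, np.zeros(motif.length)])


def scan_pwm(
    sequence: str,
    motif: MotifModel,
    threshold: float = 0.8,
    both_strands: bool = True,
) -> list[MotifHit]:
    """Log-odds scan of a sequence; hit iff score >= threshold * max score.

    The maximum achievable score is the sum of per-column maxima of the
    log-odds matrix; if it is not positive (e.g. an uninformative PWM) there
    are no hits.  N bases contribute the background log-odds of 0.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    L = motif.length
    if L > len(sequence):
        raise ValueError(f"motif length {L} exceeds sequence length {len(sequence)}")
    try:
        idx = np.array([_BASE_IDX[b] for b in sequence.upper()], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"sequence contains non-ACGTN base {exc}") from None

    hits: list[MotifHit] = []
    strands = ("+", "-") if both_strands else ("+",)
    for strand in strands:
        m = motif if strand == "+" else motif.reverse_complement()
        ll = _logodds(m)
        max_score = ll[:4].max(axis=0).sum()
        if max_score <= 0:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(idx, L)
        scores = ll[windows, np.arange(L)].sum(axis=1)
        for pos in np.flatnonzero(scores >= threshold * max_score - 1e-12):
            hits.append(MotifHit(int(pos), strand, float(scores[pos])))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def scan_peak_sequences(
    sequences: Mapping[str, str],
    motifs: Sequence[MotifModel],
    threshold: float = 0.8,
) -> pd.DataFrame:
    """Boolean peak x motif presence matrix from sequence scanning."""
    data = {
        m.id: [bool(scan_pwm(seq, m, threshold)) for seq in sequences.values()]
        for m in motifs
    }
    return pd.DataFrame(data, index=list(sequences.keys()))


# ---------------------------------------------------------------------------
# fixed-width peaks


def fix_peak_width(
    peaks: PeakSet, width: int = 250, chrom_sizes: Mapping[str, int] | None = None
) -> PeakSet:
    """Re-centre each peak on its summit (midpoint if unset) at fixed width.

    Peaks running off a chromosome end are clipped and a warning is issued.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    out = []
    clipped = 0
    for p in peaks:
        center = p.summit
        start = center - width // 2
        end = start + width
        if start < 0:
            start, clipped = 0, clipped + 1
        limit = chrom_sizes.get(p.chrom) if chrom_sizes else None
        if limit is not None and end > limit:
            end, clipped = limit, clipped + 1
        summit = center - start if start <= center < end else -1
        out.append(
            GenomicInterval(p.chrom, start, end, p.name, p.score, p.strand, summit)
        )
    if clipped:
        warnings.warn(f"{clipped} peaks clipped at chromosome bounds", stacklevel=2)
    return PeakSet(out)


# ---------------------------------------------------------------------------
# annotation


@dataclass
class MotifAnnotation:
    """Peak x motif membership plus the peak covariates used for background
    matching (GC fraction and mean normalized accessibility)."""

    matrix: pd.DataFrame      # bool, peaks x motifs
    peak_gc: pd.Series
    peak_mean_count: pd.Series

    def __post_init__(self) -> None:
        empty = [m for m in self.matrix.columns if not self.matrix[m].any()]
        if empty:
            raise ValueError(f"motifs with zero annotated peaks: {empty}")
        if not self.matrix.index.equals(self.peak_gc.index) or not self.matrix.index.equals(
            self.peak_mean_count.index
        ):
            raise ValueError("annotation components must share the peak index")


def make_annotation(
    matrix: pd.DataFrame, peak_gc: pd.Series, counts: pd.DataFrame
) -> MotifAnnotation:
    cpm = counts / counts.sum(axis=0) * 1e6
    return MotifAnnotation(
        matrix=matrix.astype(bool),
        peak_gc=peak_gc.loc[matrix.index].astype(float),
        peak_mean_count=cpm.loc[matrix.index].mean(axis=1),
    )


def annotation_from_placements(
    placements: Mapping[str, Sequence[str]],
    peak_ids: Sequence[str],
    peak_gc: pd.Series,
    counts: pd.DataFrame,
) -> MotifAnnotation:
    matrix = pd.DataFrame(
        {m: pd.Index(peak_ids).isin(set(p)) for m, p in placements.items()},
        index=list(peak_ids),
    )
    return make_annotation(matrix, peak_gc, counts)


# ---------------------------------------------------------------------------
# deviation scores


@dataclass
class DeviationMatrix:
    z: pd.DataFrame            # motif x sample
    raw: pd.DataFrame
    variability: pd.Series     # per-motif SD of z across samples


def _motif_deviation(X, rowsums, T, total, M):
    """Fractional deviations for annotation M (peaks x motifs, bool)."""
    observed = M.T @ X                                    # motifs x samples
    expected = np.outer((M.T @ rowsums) / total, T)
    return observed / expected - 1.0, expected


def deviation_scores(
    counts: pd.DataFrame,
    annotation: MotifAnnotation,
    n_background: int = 50,
    k_neighbors: int = 50,
    seed: int = 0,
) -> DeviationMatrix:
    """Bias-corrected motif deviation z-scores.

    For each background iteration every peak is substituted by one of its
    ``k_neighbors`` nearest neighbors in standardized (GC, log mean count)
    space, and the deviation statistic is recomputed; z-scores are the raw
    deviations centered and scaled by the background distribution.
    """
    if not counts.index.equals(annotation.matrix.index):
        raise ValueError("count matrix and annotation must share the peak index")
    X = counts.to_numpy(dtype=float)
    T = X.sum(axis=0)
    if (T == 0).any():
        bad = counts.columns[int(np.argmax(T == 0))]
        raise ValueError(f"sample {bad!r} has zero total counts")
    rowsums = X.sum(axis=1)
    total = rowsums.sum()
    M = annotation.matrix.to_numpy(dtype=float)

    raw, _ = _motif_deviation(X, rowsums, T, total, M)

    covar = np.column_stack(
        [
            annotation.peak_gc.to_numpy(dtype=float),
            np.log1p(annotation.peak_mean_count.to_numpy(dtype=float)),
        ]
    )
    covar = (covar - covar.mean(axis=0)) / np.maximum(covar.std(axis=0), 1e-12)
    k = min(k_neighbors, X.shape[0])
    _, neighbors = cKDTree(covar).query(covar, k=k)
    neighbors = np.atleast_2d(neighbors)
    if neighbors.shape[1] < k:  # degenerate single-peak case
        neighbors = np.tile(neighbors, (1, k))

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    # balanced sampling: every peak cycles through its k matched neighbors in
    # a random order, so background means are exact neighbor averages when
    # n_background is a multiple of k (removes Monte-Carlo drift between seeds)
    perms = np.argsort(rng.random((X.shape[0], k)), axis=1)
    bg = np.empty((n_background, M.shape[1], X.shape[1]))
    for b in range(n_background):
        pick = neighbors[np.arange(X.shape[0]), perms[:, b % k]]
        Xb = X[pick]
        rb = rowsums[pick]
        observed = M.T @ Xb
        expected = np.outer((M.T @ rb) / total, T)
        bg[b] = observed / expected - 1.0

    mean_bg = bg.mean(axis=0)
    sd_bg = bg.std(axis=0, ddof=1)
    z = np.where(sd_bg > 1e-12, (raw - mean_bg) / np.maximum(sd_bg, 1e-12), 0.0)

    z_df = pd.DataFrame(z, index=annotation.matrix.columns, columns=counts.columns)
    raw_df = pd.DataFrame(raw, index=annotation.matrix.columns, columns=counts.columns)
    return DeviationMatrix(
        z=z_df, raw=raw_df, variability=z_df.std(axis=1, ddof=1)
    )


# ---------------------------------------------------------------------------
# per-timepoint significance of deviation changes


def significant_motifs(
    dev: DeviationMatrix,
    design: pd.DataFrame,
    timepoint: int,
    alpha: float = 0.05,
    treatment: str = "untreated",
) -> pd.DataFrame:
    """Motifs whose mean deviation z changes from 0 hpa at ``timepoint``.

    Two-sided t-test of replicate z-scores (t vs 0 hpa) per motif and
    structure; BH adjustment across all tests; direction is the sign of the
    mean difference.  Rows with ``fdr <= alpha`` are the significant calls.
    """
    design = design.loc[dev.z.columns]
    rows = []
    for structure in sorted(design["structure"].unique()):
        sel_t = design[
            (design["structure"] == structure)
            & (design["timepoint"] == timepoint)
            & (design["treatment"] == treatment)
        ].index
        sel_0 = design[
            (design["structure"] == structure)
            & (design["timepoint"] == 0)
            & (design["treatment"] == treatment)
        ].index
        if len(sel_t) < 2 or len(sel_0) < 2:
            raise ValueError(
                f"need >= 2 replicates per cell (structure {structure})"
            )
        for motif in dev.z.index:
            zt = dev.z.loc[motif, sel_t].to_numpy(dtype=float)
            z0 = dev.z.loc[motif, sel_0].to_numpy(dtype=float)
            if np.allclose(np.var(zt), 0) and np.allclose(np.var(z0), 0):
                p = 1.0 if np.isclose(zt.mean(), z0.mean()) else 0.0
            else:
                p = float(stats.ttest_ind(zt, z0).pvalue)
            diff = float(zt.mean() - z0.mean())
            rows.append((motif, structure, diff, p))
    out = pd.DataFrame(rows, columns=["motif", "structure", "mean_diff", "p"])
    out["fdr"] = bh_adjust_safe(out["p"].to_numpy())
    out["direction"] = np.where(out["mean_diff"] > 0, "increased", "decreased")
    out["significant"] = out["fdr"] <= alpha
    return out


def bh_adjust_safe(p: np.ndarray) -> np.ndarray:
    from .diffexpr import bh_adjust

    return bh_adjust(np.clip(p, 0.0, 1.0))


# ---------------------------------------------------------------------------
# motif redundancy clustering


def _column_corr(a: np.ndarray, b: np.ndarray) -> float:
    x, y = a.ravel(), b.ravel()
    if x.std() < 1e-12 or y.std() < 1e-12:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def motif_similarity(m1: MotifModel, m2: MotifModel, min_overlap: int = 4) -> float:
    """Max Pearson correlation over ungapped alignments, both orientations."""
    best = -1.0
    for m2o in (m2, m2.reverse_complement()):
        a, b = m1.matrix, m2o.matrix
        la, lb = a.shape[1], b.shape[1]
        for off in range(-(lb - min_overlap), la - min_overlap + 1):
            a_lo, a_hi = max(0, off), min(la, off + lb)
            if a_hi - a_lo < min_overlap:
                continue
            b_lo = a_lo - off
            best = max(best, _column_corr(a[:, a_lo:a_hi], b[:, b_lo : b_lo + (a_hi - a_lo)]))
    return best


def cluster_motifs(
    motifs: Sequence[MotifModel],
    dev: DeviationMatrix,
    similarity_cut: float = 0.9,
    design: pd.DataFrame | None = None,
) -> list[dict]:
    """Group redundant motifs and pick one representative per cluster.

    Average-linkage hierarchical clustering on (1 - pairwise similarity),
    cut at distance ``1 - similarity_cut``.  The representative is the member
    with the greatest range of mean deviation z across treatment groups
    (per-sample z when no design is supplied).
    """
    if not 0.0 < similarity_cut < 1.0:
        raise ValueError("similarity_cut must lie in (0, 1)")
    if len(motifs) < 2:
        raise ValueError("need >= 2 motifs")
    ids = [m.id for m in motifs]
    n = len(motifs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sim = motif_similarity(motifs[i], motifs[j])
            dist[i, j] = dist[j, i] = 1.0 - sim
    condensed = dist[np.triu_indices(n, k=1)]
    linkage = hierarchy.average(condensed)
    labels = hierarchy.fcluster(linkage, t=1.0 - similarity_cut, criterion="distance")

    if design is not None:
        design = design.loc[dev.z.columns]
        groups = design.apply(
            lambda r: f"{r['structure']}:{r['timepoint']}:{r['treatment']}", axis=1
        )
        means = dev.z.T.groupby(groups).mean().T  # motif x group
    else:
        means = dev.z
    zrange = (means.max(axis=1) - means.min(axis=1)).reindex(ids).fillna(0.0)

    clusters = []
    for lab in sorted(set(labels)):
        members = [ids[i] for i in range(n) if labels[i] == lab]
        rep = max(members, key=lambda m: (zrange[m], m))
        clusters.append({"members": members, "representative": rep})
    return clusters
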