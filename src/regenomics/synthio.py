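"""Synthetic multi-omic experiment generator.

Emulates a 2 structure x 4 timepoint x 2 treatment bisection-injury design:
negative-binomial RNA and chromatin-accessibility counts on a toy genome,
with a generic injury program planted at 3 hpa, structure-specific programs
appearing at 8/12 hpa, a TCF-inhibitor arm that delays the divergence, motif
placements tied to the planted programs, and a two-cluster single-cell
matrix.  Every generator is a pure function of (config, seed).

RNG stream order (children of ``SeedSequence(config.seed)``):
0 gene baselines, 1 gene dispersions, 2 peak baselines, 3 peak dispersions,
4 library factors, 5 effect sizes, 6 RNA counts, 7 ATAC counts,
8 sequences and motif placements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .formats import (
    CountExperiment,
    GenomicInterval,
    MotifModel,
    PeakSet,
)
from .consensus import ScoredPeakReplicates

__all__ = [
    "DesignConfig",
    "EffectModel",
    "SyntheticTruth",
    "make_effect_model",
    "make_motif_library",
    "generate_experiment",
    "generate_scored_replicates",
    "generate_tss_profiles",
    "generate_single_cell",
]

UNTREATED = "untreated"
ICRT = "iCRT14"
_TREAT_SHORT = {UNTREATED: "unt", ICRT: "icrt"}


@dataclass(frozen=True)
class DesignConfig:
    """Parameters of the synthetic experimental design."""

    n_genes: int = 2000
    n_peaks: int = 5000
    structures: tuple[str, ...] = ("H", "F")
    timepoints: tuple[int, ...] = (0, 3, 8, 12)
    replicates_per_cell: int = 3
    treatments: tuple[str, ...] = (UNTREATED, ICRT)
    library_size_cv: float = 0.15
    baseline_log2_range: tuple[float, float] = (2.0, 10.0)
    dispersion_log_mean: float = -3.0   # median NB dispersion ~ exp(-3) = 0.05
    dispersion_log_sd: float = 0.5
    peak_width: int = 500
    gene_length: int = 800
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_peaks < 1:
            raise ValueError("n_genes and n_peaks must be >= 1")
        if self.n_peaks < self.n_genes:
            raise ValueError("need at least one peak per gene (promoter peaks)")
        if 0 not in self.timepoints:
            raise ValueError("timepoints must include the 0 hpa control")
        if self.replicates_per_cell < 1:
            raise ValueError("replicates_per_cell must be >= 1")

    @property
    def genome_size(self) -> int:
        return max(10_000_000, (self.n_peaks + 1) * 1500)


@dataclass(frozen=True)
class EffectModel:
    """Planted effect sets and their magnitudes.

    Injury and apoptosis effects apply at 3 hpa in both structures;
    structure-specific (context) effects apply at 8 and 12 hpa in one
    structure only.  Under the TCF-inhibitor arm the context effect is scaled
    by ``icrt_delay`` per timepoint, and the injury program of
    ``prolonged_fraction`` of injury features persists into 8/12 hpa.
    """

    injury_set: tuple[str, ...] = ()
    head_set: tuple[str, ...] = ()
    foot_set: tuple[str, ...] = ()
    apoptosis_set: tuple[str, ...] = ()
    mu_inj: float = 2.0
    sd_inj: float = 0.4
    mu_ctx: float = 2.5
    sd_ctx: float = 0.4
    icrt_delay: tuple[tuple[int, float], ...] = ((8, 0.0), (12, 0.5))
    prolong_injury_under_icrt: bool = True
    prolonged_fraction: float = 0.5

    def __post_init__(self) -> None:
        if set(self.head_set) & set(self.foot_set):
            raise ValueError("head_set and foot_set must be disjoint")

    @property
    def delay(self) -> dict[int, float]:
        return dict(self.icrt_delay)


def make_effect_model(
    features: Sequence[str],
    n_injury: int = 200,
    n_head: int = 100,
    n_foot: int = 100,
    n_apoptosis: int = 0,
    seed: int = 0,
    **kwargs,
) -> EffectModel:
    """Draw disjoint effect sets from ``features`` (deterministic in seed)."""
    total = n_injury + n_head + n_foot + n_apoptosis
    if total > len(features):
        raise ValueError("effect sets larger than feature universe")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    chosen = rng.choice(len(features), size=total, replace=False)
    ids = [features[i] for i in chosen]
    return EffectModel(
        injury_set=tuple(ids[:n_injury]),
        head_set=tuple(ids[n_injury : n_injury + n_head]),
        foot_set=tuple(ids[n_injury + n_head : n_injury + n_head + n_foot]),
        apoptosis_set=tuple(ids[n_injury + n_head + n_foot :]),
        **kwargs,
    )


@dataclass
class SyntheticTruth:
    """Machine-readable ground truth for a generated experiment."""

    config: dict
    gene_effects: dict          # gene -> {"injury": lfc, "context": lfc, ...}
    peak_effects: dict          # peak -> same structure
    injury_genes: list[str]
    head_genes: list[str]
    foot_genes: list[str]
    apoptosis_genes: list[str]
    prolonged_genes: list[str]
    injury_peaks: list[str]
    head_peaks: list[str]
    foot_peaks: list[str]
    peak_to_gene: dict          # promoter peak -> gene
    gene_tss: dict              # gene -> TSS coordinate
    motif_placements: dict      # motif id -> sorted list of peak ids
    injury_tf_motif: str
    decoy_motifs: list[str]
    motif_tf_map: dict          # motif id -> list of TF gene ids
    wnt_like_genes: list[str]
    icrt_delay: dict            # timepoint(str) -> retained fraction
    baseline_genes: dict = field(default_factory=dict)
    baseline_peaks: dict = field(default_factory=dict)
    sc_markers: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        return cls(**d)

    def __eq__(self, other) -> bool:
        return isinstance(other, SyntheticTruth) and self.to_dict() == other.to_dict()


# ---------------------------------------------------------------------------
# core NB sampler


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: np.ndarray):
    """Gamma-Poisson draw: Var = mean + dispersion * mean^2."""
    mean = np.asarray(mean, dtype=float)
    dispersion = np.broadcast_to(np.asarray(dispersion, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    tiny = dispersion < 1e-8
    if tiny.any():
        out[tiny] = rng.poisson(mean[tiny])
    if (~tiny).any():
        shape = 1.0 / dispersion[~tiny]
        lam = rng.gamma(shape, mean[~tiny] / shape)
        out[~tiny] = rng.poisson(lam)
    return out


# ---------------------------------------------------------------------------
# toy genome geometry


def _toy_genome(config: DesignConfig):
    """Evenly spaced peaks; every gene anchored at a promoter peak's center."""
    spacing = config.genome_size // (config.n_peaks + 1)
    half = config.peak_width // 2
    centers = [(k + 1) * spacing for k in range(config.n_peaks)]
    peak_ids = [f"p{k:05d}" for k in range(config.n_peaks)]
    peaks = PeakSet(
        GenomicInterval("chr1", c - half, c + half, pid, 0.0, ".", half)
        for c, pid in zip(centers, peak_ids)
    )
    stride = config.n_peaks // config.n_genes
    gene_ids = [f"g{i:04d}" for i in range(config.n_genes)]
    promoter_idx = [i * stride for i in range(config.n_genes)]
    genes = PeakSet(
        GenomicInterval(
            "chr1",
            centers[pi],
            centers[pi] + config.gene_length,
            gid,
            0.0,
            "+",
        )
        for gid, pi in zip(gene_ids, promoter_idx)
    )
    peak_to_gene = {peak_ids[pi]: gid for gid, pi in zip(gene_ids, promoter_idx)}
    return peaks, genes, peak_to_gene


# ---------------------------------------------------------------------------
# motif library


def _motif_from_consensus(motif_id: str, consensus: str, info: float = 0.94) -> MotifModel:
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    L = len(consensus)
    mat = np.full((4, L), (1 - info) / 3)
    for j, b in enumerate(consensus):
        mat[:, j] = (1 - info) / 3
        mat[idx[b], j] = info
    return MotifModel(id=motif_id, matrix=mat)


def make_motif_library(n_decoys: int = 5, seed: int = 0) -> list[MotifModel]:
    """One sharp injury-TF motif plus random decoy motifs of length 8."""
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    motifs = [_motif_from_consensus("bzip_inj", "TGACGTCA")]
    bases = "ACGT"
    seen = {"TGACGTCA"}
    for d in range(n_decoys):
        while True:
            cons = "".join(bases[i] for i in rng.integers(0, 4, size=8))
            if cons not in seen:
                seen.add(cons)
                break
        motifs.append(_motif_from_consensus(f"decoy{d:02d}", cons))
    return motifs


# ---------------------------------------------------------------------------
# planted log2FC assembly


def _design_frame(config: DesignConfig, assay: str) -> pd.DataFrame:
    rows = []
    for treat in config.treatments:
        for struct in config.structures:
            for t in config.timepoints:
                for r in range(1, config.replicates_per_cell + 1):
                    sid = f"{assay}_{struct}{t}_{_TREAT_SHORT.get(treat, treat)}_r{r}"
                    rows.append((sid, struct, t, treat, r))
    df = pd.DataFrame(
        rows, columns=["sample", "structure", "timepoint", "treatment", "replicate"]
    )
    return df.set_index("sample")


def _effect_lfc_matrix(
    features: Sequence[str],
    design: pd.DataFrame,
    effects: EffectModel,
    sizes: dict[str, dict[str, float]],
    prolonged: set[str],
) -> np.ndarray:
    """Per-feature, per-sample planted log2 fold change (0 at 0 hpa)."""
    fidx = {f: i for i, f in enumerate(features)}
    lfc = np.zeros((len(features), len(design)))
    delay = effects.delay
    for j, (_, row) in enumerate(design.iterrows()):
        t, struct, treat = row["timepoint"], row["structure"], row["treatment"]
        if t == 0:
            continue
        for g in effects.injury_set:
            e = sizes[g]["injury"]
            if t == 3:
                lfc[fidx[g], j] += e
            elif treat == ICRT and g in prolonged:
                lfc[fidx[g], j] += e
        for g in effects.apoptosis_set:
            if t == 3:
                lfc[fidx[g], j] += sizes[g]["apoptosis"]
        if t in (8, 12):
            scale = delay.get(t, 1.0) if treat == ICRT else 1.0
            for g in effects.head_set:
                if struct == "H":
                    lfc[fidx[g], j] += sizes[g]["context"] * scale
            for g in effects.foot_set:
                if struct == "F":
                    lfc[fidx[g], j] += sizes[g]["context"] * scale
    return lfc


def _draw_effect_sizes(
    effects: EffectModel, rng: np.random.Generator
) -> tuple[dict[str, dict[str, float]], set[str]]:
    sizes: dict[str, dict[str, float]] = {}
    for g in effects.injury_set:
        sizes.setdefault(g, {})["injury"] = float(
            rng.normal(effects.mu_inj, effects.sd_inj)
        )
    for g in effects.apoptosis_set:
        sizes.setdefault(g, {})["apoptosis"] = float(
            rng.normal(effects.mu_inj, effects.sd_inj)
        )
    for g in effects.head_set:
        sizes.setdefault(g, {})["context"] = float(
            rng.normal(effects.mu_ctx, effects.sd_ctx)
        )
    for g in effects.foot_set:
        sizes.setdefault(g, {})["context"] = float(
            rng.normal(effects.mu_ctx, effects.sd_ctx)
        )
    prolonged: set[str] = set()
    if effects.prolong_injury_under_icrt and effects.injury_set:
        n_pro = int(round(effects.prolonged_fraction * len(effects.injury_set)))
        if n_pro:
            idx = rng.choice(len(effects.injury_set), size=n_pro, replace=False)
            prolonged = {effects.injury_set[i] for i in sorted(idx)}
    return sizes, prolonged


# ---------------------------------------------------------------------------
# main generator


def generate_experiment(
    config: DesignConfig,
    effects: EffectModel | None = None,
    motifs: list[MotifModel] | None = None,
    n_wnt_like: int = 4,
):
    """Generate matched RNA and ATAC count experiments plus ground truth.

    Returns ``(rna, atac, truth, extras)`` where ``extras`` holds the toy
    genome annotation needed by downstream stages: ``peaks`` (PeakSet),
    ``genes`` (PeakSet of gene models), ``sequences`` (peak id -> str),
    ``peak_gc`` (Series), and ``motifs`` (the library used).
    """
    effects = effects if effects is not None else EffectModel()
    gene_ids = [f"g{i:04d}" for i in range(config.n_genes)]
    unknown = (
        set(effects.injury_set)
        | set(effects.head_set)
        | set(effects.foot_set)
        | set(effects.apoptosis_set)
    ) - set(gene_ids)
    if unknown:
        raise ValueError(f"effect sets contain unknown feature ids: {sorted(unknown)[:5]}")

    streams = np.random.SeedSequence(config.seed).spawn(9)
    rng_gb, rng_gd, rng_pb, rng_pd, rng_lib, rng_eff, rng_rna, rng_atac, rng_seq = (
        np.random.default_rng(s) for s in streams
    )

    peaks, genes, peak_to_gene = _toy_genome(config)
    peak_ids = peaks.names()
    gene_of_promoter = peak_to_gene
    promoter_of_gene = {g: p for p, g in gene_of_promoter.items()}

    lo, hi = config.baseline_log2_range
    base_genes = 2.0 ** rng_gb.uniform(lo, hi, size=config.n_genes)
    disp_genes = np.exp(
        rng_gd.normal(config.dispersion_log_mean, config.dispersion_log_sd, config.n_genes)
    )
    base_peaks = 2.0 ** rng_pb.uniform(lo, hi, size=config.n_peaks)
    disp_peaks = np.exp(
        rng_pd.normal(config.dispersion_log_mean, config.dispersion_log_sd, config.n_peaks)
    )

    rna_design = _design_frame(config, "rna")
    atac_design = _design_frame(config, "atac")
    n_samples = len(rna_design)
    lib_rna = np.exp(rng_lib.normal(0.0, config.library_size_cv, n_samples))
    lib_atac = np.exp(rng_lib.normal(0.0, config.library_size_cv, n_samples))

    sizes, prolonged = _draw_effect_sizes(effects, rng_eff)
    lfc_genes = _effect_lfc_matrix(gene_ids, rna_design, effects, sizes, prolonged)

    # peak-level effects mirror the gene-level program at promoter peaks
    def _gene_set_to_peaks(gene_set):
        return tuple(
            promoter_of_gene[g] for g in gene_set if g in promoter_of_gene
        )

    peak_effects_model = EffectModel(
        injury_set=_gene_set_to_peaks(effects.injury_set),
        head_set=_gene_set_to_peaks(effects.head_set),
        foot_set=_gene_set_to_peaks(effects.foot_set),
        apoptosis_set=_gene_set_to_peaks(effects.apoptosis_set),
        icrt_delay=effects.icrt_delay,
        prolong_injury_under_icrt=effects.prolong_injury_under_icrt,
        prolonged_fraction=effects.prolonged_fraction,
    )
    peak_sizes = {
        promoter_of_gene[g]: v for g, v in sizes.items() if g in promoter_of_gene
    }
    prolonged_peaks = {promoter_of_gene[g] for g in prolonged if g in promoter_of_gene}
    lfc_peaks = _effect_lfc_matrix(
        peak_ids, atac_design, peak_effects_model, peak_sizes, prolonged_peaks
    )

    mu_rna = base_genes[:, None] * (2.0 ** lfc_genes) * lib_rna[None, :]
    mu_atac = base_peaks[:, None] * (2.0 ** lfc_peaks) * lib_atac[None, :]
    counts_rna = _nb_sample(rng_rna, mu_rna, disp_genes[:, None])
    counts_atac = _nb_sample(rng_atac, mu_atac, disp_peaks[:, None])

    rna = CountExperiment(
        pd.DataFrame(counts_rna, index=gene_ids, columns=rna_design.index),
        rna_design.copy(),
    )
    atac = CountExperiment(
        pd.DataFrame(counts_atac, index=peak_ids, columns=atac_design.index),
        atac_design.copy(),
    )

    # --- sequences and motif placements -----------------------------------
    motifs = motifs if motifs is not None else make_motif_library(seed=config.seed)
    injury_motif = motifs[0].id
    decoys = [m.id for m in motifs[1:]]
    placements: dict[str, set[str]] = {m.id: set() for m in motifs}
    injury_peak_set = set(peak_effects_model.injury_set)
    for pid in peak_ids:
        for m in motifs:
            if m.id == injury_motif:
                p_place = 0.9 if pid in injury_peak_set else 0.03
            else:
                p_place = 0.10
            if rng_seq.random() < p_place:
                placements[m.id].add(pid)
    for m in motifs:  # guarantee every motif annotates >= 1 peak
        if not placements[m.id]:
            placements[m.id].add(peak_ids[int(rng_seq.integers(config.n_peaks))])

    peak_gc = pd.Series(
        rng_seq.uniform(0.30, 0.60, size=config.n_peaks), index=peak_ids
    )
    sequences = _peak_sequences(
        peaks, peak_gc, motifs, placements, rng_seq, config.peak_width
    )

    # wnt-like injury genes: ensure their promoter peaks carry the injury motif
    wnt_candidates = [g for g in effects.injury_set if g in promoter_of_gene]
    wnt_like = wnt_candidates[:n_wnt_like]
    for g in wnt_like:
        pid = promoter_of_gene[g]
        if pid not in placements[injury_motif]:
            placements[injury_motif].add(pid)
            sequences[pid] = _implant(sequences[pid], motifs[0].consensus(), rng_seq)

    motif_tf_map = {injury_motif: wnt_candidates[-1:] if wnt_candidates else []}
    non_injury = [g for g in gene_ids if g not in set(effects.injury_set)]
    for i, d in enumerate(decoys):
        motif_tf_map[d] = [non_injury[i % len(non_injury)]] if non_injury else []

    truth = SyntheticTruth(
        config=asdict(config),
        gene_effects={g: sizes[g] for g in sorted(sizes)},
        peak_effects={p: peak_sizes[p] for p in sorted(peak_sizes)},
        injury_genes=sorted(effects.injury_set),
        head_genes=sorted(effects.head_set),
        foot_genes=sorted(effects.foot_set),
        apoptosis_genes=sorted(effects.apoptosis_set),
        prolonged_genes=sorted(prolonged),
        injury_peaks=sorted(peak_effects_model.injury_set),
        head_peaks=sorted(peak_effects_model.head_set),
        foot_peaks=sorted(peak_effects_model.foot_set),
        peak_to_gene=dict(sorted(gene_of_promoter.items())),
        gene_tss={g.name: g.start for g in genes},
        motif_placements={m: sorted(v) for m, v in placements.items()},
        injury_tf_motif=injury_motif,
        decoy_motifs=decoys,
        motif_tf_map=motif_tf_map,
        wnt_like_genes=list(wnt_like),
        icrt_delay={str(t): v for t, v in effects.delay.items()},
        baseline_genes={g: float(b) for g, b in zip(gene_ids, base_genes)},
        baseline_peaks={p: float(b) for p, b in zip(peak_ids, base_peaks)},
    )
    extras = {
        "peaks": peaks,
        "genes": genes,
        "sequences": sequences,
        "peak_gc": peak_gc,
        "motifs": motifs,
    }
    return rna, atac, truth, extras


_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def _implant(seq: str, site: str, rng: np.random.Generator) -> str:
    pos = int(rng.integers(0, len(seq) - len(site) + 1))
    return seq[:pos] + site + seq[pos + len(site):]


def _peak_sequences(peaks, peak_gc, motifs, placements, rng, width):
    by_id = {m.id: m for m in motifs}
    seqs: dict[str, str] = {}
    # implant in reverse library order so the first (planted injury) motif's
    # site is written last and cannot be clobbered by decoy implants
    order = [m.id for m in reversed(motifs)]
    for p in peaks:
        seq = _random_seq(rng, width, float(peak_gc[p.name]))
        for mid in order:
            if p.name in placements[mid]:
                seq = _implant(seq, by_id[mid].consensus(), rng)
        seqs[p.name] = seq
    return seqs


# ---------------------------------------------------------------------------
# scored peak replicates (IDR exercise)


def generate_scored_replicates(
    truth_or_npeaks,
    n_replicates: int,
    reproducible_fraction: float,
    noise_sd: float,
    seed: int = 0,
    signal_mean: float = 3.0,
) -> ScoredPeakReplicates:
    """Replicate score lists with a planted reproducible subset.

    A ``reproducible_fraction`` of peaks share a latent signal (correlated
    scores across replicates, elevated mean); the rest receive independent
    noise scores.  Accepts either a :class:`SyntheticTruth` (uses its peak
    universe) or an integer peak count (builds a fresh toy peak set).
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    if not 0.0 <= reproducible_fraction <= 1.0:
        raise ValueError("reproducible_fraction must lie in [0, 1]")
    if isinstance(truth_or_npeaks, SyntheticTruth):
        n_peaks = int(truth_or_npeaks.config["n_peaks"])
        cfg = DesignConfig(
            n_genes=int(truth_or_npeaks.config["n_genes"]), n_peaks=n_peaks
        )
        peaks, _, _ = _toy_genome(cfg)
    else:
        n_peaks = int(truth_or_npeaks)
        if n_peaks < 1:
            raise ValueError("n_peaks must be >= 1")
        cfg = DesignConfig(n_genes=1, n_peaks=n_peaks)
        peaks, _, _ = _toy_genome(cfg)

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    n_rep_peaks = int(round(reproducible_fraction * n_peaks))
    is_rep = np.zeros(n_peaks, dtype=bool)
    if n_rep_peaks:
        is_rep[rng.choice(n_peaks, size=n_rep_peaks, replace=False)] = True

    scores = np.empty((n_peaks, n_replicates))
    latent = rng.normal(signal_mean, 1.0, size=n_peaks)
    for r in range(n_replicates):
        noise = rng.normal(0.0, 1.0, size=n_peaks)
        rep_scores = latent + (
            rng.normal(0.0, noise_sd, size=n_peaks) if noise_sd > 0 else 0.0
        )
        scores[:, r] = np.where(is_rep, rep_scores, noise)

    return ScoredPeakReplicates(
        peaks=peaks,
        scores=scores,
        replicate_ids=[f"rep{r + 1}" for r in range(n_replicates)],
        reproducible_mask=is_rep,
    )


# ---------------------------------------------------------------------------
# TSS profiles


def generate_tss_profiles(
    n_genes: int = 2000,
    enrichment: float = 7.0,
    flank: int = 1000,
    seed: int = 0,
    base_rate: float = 1.0,
    bump_sd: float = 150.0,
) -> np.ndarray:
    """Poisson coverage profiles (genes x positions -flank..+flank).

    Expected signal at the center is ``enrichment`` times the expected flank
    signal; the elevation decays as a Gaussian bump of width ``bump_sd``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if enrichment < 1:
        raise ValueError("enrichment must be >= 1")
    if flank <= 0:
        raise ValueError("flank must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    pos = np.arange(-flank, flank + 1)
    rate = base_rate * (1.0 + (enrichment - 1.0) * np.exp(-(pos**2) / (2 * bump_sd**2)))
    return rng.poisson(np.broadcast_to(rate, (n_genes, pos.size))).astype(np.int64)


# ---------------------------------------------------------------------------
# single-cell matrix


def generate_single_cell(
    n_cells_per_cluster: int,
    markers_head: Sequence[str],
    markers_foot: Sequence[str],
    effect_log2fc: float,
    seed: int = 0,
    n_genes: int = 500,
    base_log2_mean: float = 1.0,
    dispersion: float = 0.4,
) -> tuple[pd.DataFrame, pd.Series]:
    """Two-cluster (head/foot epithelial) NB count matrix with planted markers."""
    markers_head = list(markers_head)
    markers_foot = list(markers_foot)
    if set(markers_head) & set(markers_foot):
        raise ValueError("marker sets must be disjoint")
    if n_cells_per_cluster < 2:
        raise ValueError("need >= 2 cells per cluster")
    named = markers_head + markers_foot
    filler = [f"gf{i:04d}" for i in range(max(0, n_genes - len(named)))]
    genes = named + filler
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    base = 2.0 ** rng.normal(base_log2_mean, 0.5, size=len(genes))
    lfc = np.zeros(len(genes))
    gidx = {g: i for i, g in enumerate(genes)}
    for g in markers_head:
        lfc[gidx[g]] = effect_log2fc
    for g in markers_foot:
        lfc[gidx[g]] = -effect_log2fc
    n = n_cells_per_cluster
    # head cluster gets +lfc/2, foot cluster -lfc/2 (symmetric planting)
    mu_head = base[:, None] * 2.0 ** (lfc[:, None] / 2.0) * np.ones((1, n))
    mu_foot = base[:, None] * 2.0 ** (-lfc[:, None] / 2.0) * np.ones((1, n))
    counts_head = _nb_sample(rng, mu_head, dispersion)
    counts_foot = _nb_sample(rng, mu_foot, dispersion)
    cells = [f"head_c{i:04d}" for i in range(n)] + [f"foot_c{i:04d}" for i in range(n)]
    counts = pd.DataFrame(
        np.hstack([counts_head, counts_foot]), index=genes, columns=cells
    )
    labels = pd.Series(["head"] * n + ["foot"] * n, index=cells, name="cluster")
    return counts, labels
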