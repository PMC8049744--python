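"""Enrichment statistics, peak-gene assignment, and the candidate-TF screen."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .diffexpr import bh_adjust
from .formats import PeakSet

__all__ = [
    "EnrichmentResult",
    "hypergeom_enrichment",
    "assign_peaks_to_genes",
    "peak_gene_concordance",
    "motif_enrichment_in_peaks",
    "run_screen",
]


@dataclass(frozen=True)
class EnrichmentResult:
    k: int          # overlap
    n: int          # |set_a|
    K: int          # |set_b|
    N: int          # |universe|
    fold: float     # k / (n*K/N)
    p: float        # upper-tail P(X >= k)


def _hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """Exact P(X >= k) for X ~ Hypergeom(N, K, n), via log-gamma summation."""
    if k <= max(0, n + K - N):
        return 1.0
    hi = min(n, K)
    xs = np.arange(k, hi + 1)
    if xs.size == 0:
        return 0.0
    logp = (
        _log_choose(K, xs)
        + _log_choose(N - K, n - xs)
        - _log_choose(N, n)
    )
    m = logp.max()
    return float(min(1.0, np.exp(m) * np.exp(logp - m).sum()))


def _log_choose(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1)


def hypergeom_enrichment(
    set_a: Sequence, set_b: Sequence, universe: Sequence
) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment of ``set_a`` overlap with ``set_b``
    within ``universe``; fold = observed / expected overlap."""
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    a, b = set(set_a), set(set_b)
    if not a <= uni or not b <= uni:
        raise ValueError("set_a and set_b must be subsets of the universe")
    N, n, K = len(uni), len(a), len(b)
    k = len(a & b)
    expected = n * K / N
    fold = k / expected if expected > 0 else 0.0
    return EnrichmentResult(
        k=k, n=n, K=K, N=N, fold=float(fold), p=_hypergeom_upper_tail(k, N, K, n)
    )


# ---------------------------------------------------------------------------
# peak -> gene assignment


def assign_peaks_to_genes(
    peaks: PeakSet, genes: PeakSet, max_distance: int = 20_000
) -> dict[str, str]:
    """Assign each peak to the gene whose body it overlaps, else to the
    nearest gene start within ``max_distance``.  Ties go to the gene with the
    lower start coordinate; unmatched peaks are absent from the mapping."""
    by_chrom: dict[str, list] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for lst in by_chrom.values():
        lst.sort(key=lambda g: (g.start, g.name))

    mapping: dict[str, str] = {}
    for p in peaks:
        candidates = by_chrom.get(p.chrom, [])
        best = None  # (priority, distance, gene_start, gene_name)
        for g in candidates:
            ov = p.overlap(g)
            if ov > 0:
                key = (0, -ov, g.start, g.name)
            else:
                dist = min(abs(g.start - p.start), abs(g.start - (p.end - 1)))
                if p.start <= g.start < p.end:
                    dist = 0
                if dist > max_distance:
                    continue
                key = (1, dist, g.start, g.name)
            if best is None or key < best:
                best = key
        if best is not None:
            mapping[p.name] = best[3]
    return mapping


def peak_gene_concordance(
    structure_specific_peaks: Sequence[str],
    structure_specific_genes: Sequence[str],
    mapping: Mapping[str, str],
    universe: Sequence[str],
) -> EnrichmentResult:
    """Enrichment of structure-specific peaks among peaks assigned to
    structure-specific genes (universe = all tested peaks)."""
    if not structure_specific_peaks or not structure_specific_genes:
        raise ValueError("structure-specific sets must be non-empty")
    gene_set = set(structure_specific_genes)
    peaks_near = {p for p in universe if mapping.get(p) in gene_set}
    return hypergeom_enrichment(structure_specific_peaks, peaks_near, universe)


# ---------------------------------------------------------------------------
# motif enrichment (Fisher)


def motif_enrichment_in_peaks(
    target_peaks: Sequence[str],
    background_peaks: Sequence[str],
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """One-sided Fisher exact test of motif presence in target vs background
    peaks; fold = ratio of presence fractions; BH across motifs."""
    target = list(dict.fromkeys(target_peaks))
    background = list(dict.fromkeys(background_peaks))
    if set(target) & set(background):
        raise ValueError("target and background peak sets must be disjoint")
    ann_t = annotation.loc[target]
    ann_b = annotation.loc[background]
    rows = []
    for motif in annotation.columns:
        a = int(ann_t[motif].sum())          # target, motif present
        b = len(target) - a
        c = int(ann_b[motif].sum())          # background, motif present
        d = len(background) - c
        if a + c == 0:
            raise ValueError(f"motif {motif!r} absent from all peaks")
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        frac_t = a / len(target)
        frac_b = c / len(background)
        fold = frac_t / frac_b if frac_b > 0 else np.inf
        rows.append((motif, a, c, fold, p))
    out = pd.DataFrame(
        rows, columns=["motif", "n_target", "n_background", "fold", "p"]
    ).set_index("motif")
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# four-criteria candidate screen


def run_screen(
    sig_motifs_3hpa: pd.DataFrame,
    tf_de_3hpa: Mapping[str, pd.DataFrame],
    motif_enrichment: pd.DataFrame,
    promoter_hits: Mapping[str, Sequence[str]],
    wnt_gene_list: Sequence[str],
    motif_tf_map: Mapping[str, Sequence[str]],
    peak_to_gene: Mapping[str, str],
    tf_fdr: float = 1e-3,
    enrich_fdr: float = 0.05,
) -> pd.DataFrame:
    """Candidate injury-TF screen.

    Criteria per motif: (1) significant accessibility increase at 3 hpa in
    both structures (``sig_motifs_3hpa`` from
    :func:`regenomics.motifs.significant_motifs`), (2) at least one mapped TF
    transcript significantly up at 3 hpa in both structures
    (``tf_de_3hpa``: structure -> injury-contrast result frame), (3) motif
    enriched in injury-responsive peaks (``motif_enrichment`` with fdr), and
    (4) a scan hit in a peak assigned to at least one listed gene
    (``promoter_hits``: motif -> peak ids with hits).  A candidate satisfies
    all of (1)-(3) and (4).
    """
    if not wnt_gene_list:
        raise ValueError("wnt_gene_list must be non-empty")
    motif_ids = list(motif_enrichment.index)
    unmapped = [m for m in motif_ids if m not in motif_tf_map]
    if unmapped:
        raise ValueError(f"motifs missing from motif_tf_map: {unmapped}")

    structures = sorted(sig_motifs_3hpa["structure"].unique())
    rows = []
    for motif in motif_ids:
        sub = sig_motifs_3hpa[sig_motifs_3hpa["motif"] == motif]
        acc_up = all(
            (
                (sub["structure"] == s)
                & sub["significant"]
                & (sub["direction"] == "increased")
            ).any()
            for s in structures
        )
        tf_up = False
        for tf in motif_tf_map.get(motif, []):
            ok = True
            for s, res in tf_de_3hpa.items():
                if tf not in res.index:
                    ok = False
                    break
                row = res.loc[tf]
                if not (row["fdr"] <= tf_fdr and row["log2FC"] > 0):
                    ok = False
                    break
            if ok and tf_de_3hpa:
                tf_up = True
                break
        enriched = bool(motif_enrichment.loc[motif, "fdr"] <= enrich_fdr)
        hit_genes = {
            peak_to_gene[p]
            for p in promoter_hits.get(motif, [])
            if p in peak_to_gene
        }
        presence = {g: (g in hit_genes) for g in wnt_gene_list}
        candidate = acc_up and tf_up and enriched and any(presence.values())
        rows.append(
            {
                "motif": motif,
                "accessibility_up": acc_up,
                "tf_up": tf_up,
                "enriched": enriched,
                **{f"near_{g}": v for g, v in presence.items()},
                "candidate": candidate,
            }
        )
    return pd.DataFrame(rows).set_index("motif")
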