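"""Reproducible-peak consensus: IDR copula mixture, pseudo-replicates, QC.

The irreproducible discovery rate model is the rank-based two-component
Gaussian copula mixture: scores are rank-transformed to Gaussian
pseudo-values; the irreproducible ("noise") component is a standard
uncorrelated bivariate normal, the reproducible component has common mean
``mu``, variance ``sigma^2`` and correlation ``rho``.  The model is fitted
by EM from several grid starts.  Because only ranks enter, the fit is
invariant under strictly monotone transforms of either score vector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

from .formats import GenomicInterval, PeakSet

__all__ = [
    "ScoredPeakReplicates",
    "IdrFit",
    "QcReport",
    "idr_fit",
    "consensus_peaks",
    "match_scored_peaks",
    "pseudo_replicates",
    "qc_ratios",
    "tss_enrichment",
]

MIN_IDR_PEAKS = 50


@dataclass
class ScoredPeakReplicates:
    """Replicate score lists on a matched peak universe.

    ``scores`` has shape (n_peaks, n_replicates); NaN marks a peak absent
    from a replicate.  ``reproducible_mask`` is optional generator truth.
    """

    peaks: PeakSet
    scores: np.ndarray
    replicate_ids: list[str] = field(default_factory=list)
    reproducible_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[0] != len(self.peaks):
            raise ValueError("scores must be (n_peaks, n_replicates)")
        if not self.replicate_ids:
            self.replicate_ids = [f"rep{r + 1}" for r in range(self.scores.shape[1])]

    @property
    def n_replicates(self) -> int:
        return self.scores.shape[1]

    def replicate_peakset(self, r: int) -> PeakSet:
        """The r-th replicate as a scored PeakSet (NaN-score peaks dropped)."""
        out = []
        for p, s in zip(self.peaks, self.scores[:, r]):
            if np.isfinite(s):
                out.append(
                    GenomicInterval(
                        p.chrom, p.start, p.end, p.name, float(s), p.strand,
                        p.summit_offset,
                    )
                )
        return PeakSet(out)


@dataclass
class IdrFit:
    pi_noise: float
    rho: float
    mu: float
    sigma: float
    local_idr: np.ndarray
    global_idr: np.ndarray
    loglik: float
    n_iter: int


def _shifted_ecdf(scores: np.ndarray) -> np.ndarray:
    """Rank / (n + 1): the shifted empirical CDF (avoids 0 and 1)."""
    n = scores.size
    ranks = stats.rankdata(scores, method="average")
    return ranks / (n + 1.0)


def _mixture_quantile(u: np.ndarray, pi_rep, mu, sigma2, rho) -> np.ndarray:
    """Invert the mixture marginal CDF G(z) = (1-pi)Phi(z) + pi Phi((z-mu)/s).

    Pseudo-values are the model-consistent quantiles of the shifted ECDF;
    under the fitted model the noise component is then marginally N(0, 1).
    """
    s = math.sqrt(sigma2)
    lo = min(-8.0, mu - 8.0 * s)
    hi = max(8.0, mu + 8.0 * s)
    grid = np.linspace(lo, hi, 4000)
    cdf = (1.0 - pi_rep) * stats.norm.cdf(grid) + pi_rep * stats.norm.cdf(
        (grid - mu) / s
    )
    return np.interp(u, cdf, grid)


def _bvn_logpdf(z1, z2, mu, sigma2, rho):
    a = (z1 - mu) / math.sqrt(sigma2)
    b = (z2 - mu) / math.sqrt(sigma2)
    om = 1.0 - rho * rho
    return (
        -math.log(2 * math.pi)
        - math.log(sigma2)
        - 0.5 * math.log(om)
        - (a * a - 2 * rho * a * b + b * b) / (2 * om)
    )


def _em_once(u1, u2, pi_rep, mu, sigma2, rho, max_iter=200, tol=1e-5):
    prev_ll = -np.inf
    it = 0
    z1 = _mixture_quantile(u1, pi_rep, mu, sigma2, rho)
    z2 = _mixture_quantile(u2, pi_rep, mu, sigma2, rho)
    for it in range(1, max_iter + 1):
        log_noise = _bvn_logpdf(z1, z2, 0.0, 1.0, 0.0)  # fixed component
        log_rep = _bvn_logpdf(z1, z2, mu, sigma2, rho)
        lw_rep = math.log(max(pi_rep, 1e-12)) + log_rep
        lw_noise = math.log(max(1.0 - pi_rep, 1e-12)) + log_noise
        m = np.maximum(lw_rep, lw_noise)
        denom = m + np.log(np.exp(lw_rep - m) + np.exp(lw_noise - m))
        resp = np.exp(lw_rep - denom)  # P(reproducible | z)
        ll = float(denom.sum())
        if abs(ll - prev_ll) < tol:
            prev_ll = ll
            break
        prev_ll = ll
        w = resp.sum()
        if w < 1e-8:
            break
        pi_rep = float(w / resp.size)
        mu = float((resp * (z1 + z2)).sum() / (2 * w))
        mu = max(mu, 0.0)
        d1, d2 = z1 - mu, z2 - mu
        sigma2 = float((resp * (d1 * d1 + d2 * d2)).sum() / (2 * w))
        sigma2 = max(sigma2, 1e-4)
        rho = float((resp * d1 * d2).sum() / (w * sigma2))
        rho = min(max(rho, 0.0), 0.999)
        # model-consistent pseudo-values for the updated parameters
        z1 = _mixture_quantile(u1, pi_rep, mu, sigma2, rho)
        z2 = _mixture_quantile(u2, pi_rep, mu, sigma2, rho)
    log_noise = _bvn_logpdf(z1, z2, 0.0, 1.0, 0.0)
    log_rep = _bvn_logpdf(z1, z2, mu, sigma2, rho)
    lw_rep = math.log(max(pi_rep, 1e-12)) + log_rep
    lw_noise = math.log(max(1.0 - pi_rep, 1e-12)) + log_noise
    m = np.maximum(lw_rep, lw_noise)
    denom = m + np.log(np.exp(lw_rep - m) + np.exp(lw_noise - m))
    local_idr = np.exp(lw_noise - denom)
    return pi_rep, mu, sigma2, rho, local_idr, prev_ll, it


def idr_fit(scores_a: Sequence[float], scores_b: Sequence[float]) -> IdrFit:
    """Fit the two-component copula mixture to paired replicate scores."""
    za_raw = np.asarray(scores_a, dtype=float)
    zb_raw = np.asarray(scores_b, dtype=float)
    if za_raw.shape != zb_raw.shape or za_raw.ndim != 1:
        raise ValueError("score vectors must be 1-D and of equal length")
    if za_raw.size < MIN_IDR_PEAKS:
        raise ValueError(f"need >= {MIN_IDR_PEAKS} shared peaks, got {za_raw.size}")
    if not (np.isfinite(za_raw).all() and np.isfinite(zb_raw).all()):
        raise ValueError("scores must be finite")
    if np.ptp(za_raw) == 0 or np.ptp(zb_raw) == 0:
        raise ValueError("constant score vector")

    u1 = _shifted_ecdf(za_raw)
    u2 = _shifted_ecdf(zb_raw)

    best = None
    for pi0 in (0.1, 0.3, 0.5, 0.7, 0.9):
        fit = _em_once(u1, u2, pi_rep=pi0, mu=1.5, sigma2=1.0, rho=0.8)
        if best is None or fit[5] > best[5]:
            best = fit
    pi_rep, mu, sigma2, rho, local_idr, ll, it = best

    # degenerate fit: the "reproducible" component is indistinguishable from
    # the noise component (no correlation, no location shift) — e.g. on pure
    # noise input the mixture is unidentifiable. Report everything as noise.
    if rho < 0.1 and abs(mu) < 0.1:
        pi_rep = 0.0
        local_idr = np.ones_like(local_idr)

    order = np.argsort(local_idr, kind="stable")
    csum = np.cumsum(local_idr[order])
    global_sorted = csum / np.arange(1, local_idr.size + 1)
    global_idr = np.empty_like(local_idr)
    global_idr[order] = global_sorted
    return IdrFit(
        pi_noise=float(1.0 - pi_rep),
        rho=float(rho),
        mu=float(mu),
        sigma=float(math.sqrt(sigma2)),
        local_idr=local_idr,
        global_idr=global_idr,
        loglik=float(ll),
        n_iter=it,
    )


# ---------------------------------------------------------------------------
# peak matching across replicates


def _best_cluster(clusters_tail, iv: GenomicInterval):
    best_j, best_ov, best_start = -1, -1, None
    for j, (rep, _members) in clusters_tail:
        ov = rep.overlap(iv)
        if ov >= 0.5 * rep.width and ov >= 0.5 * iv.width:
            if ov > best_ov or (ov == best_ov and rep.start < best_start):
                best_j, best_ov, best_start = j, ov, rep.start
    return best_j


def match_scored_peaks(replicate_sets: Sequence[PeakSet]) -> ScoredPeakReplicates:
    """Match peaks across replicates by >= 50% reciprocal overlap.

    Cluster representative = first interval in (chrom, start, end) order;
    ties broken by larger overlap then lower start.  Merged coordinates are
    the union span of the matched members.  Deterministic and invariant to
    the order in which replicates are supplied (up to replicate column
    order, which follows the input order).
    """
    tagged = []
    for r, ps in enumerate(replicate_sets):
        for p in ps:
            tagged.append((p.chrom, p.start, p.end, r, p))
    tagged.sort(key=lambda t: (t[0], t[1], t[2]))

    clusters: list[tuple[GenomicInterval, dict[int, tuple[GenomicInterval, int]]]] = []
    active_from = 0
    for chrom, start, _end, r, p in tagged:
        # drop clusters that can no longer overlap (sorted by start)
        while active_from < len(clusters) and (
            clusters[active_from][0].chrom != chrom
            or clusters[active_from][0].end <= start
        ):
            active_from += 1
        tail = list(enumerate(clusters))[active_from:]
        j = _best_cluster(tail, p)
        if j < 0:
            clusters.append((p, {r: (p, p.width)}))
        else:
            rep, members = clusters[j]
            ov = rep.overlap(p)
            if r not in members or ov > members[r][1] or (
                ov == members[r][1] and p.start < members[r][0].start
            ):
                members[r] = (p, ov)

    n_rep = len(replicate_sets)
    merged, scores = [], []
    for rep, members in clusters:
        starts = [iv.start for iv, _ in members.values()]
        ends = [iv.end for iv, _ in members.values()]
        merged.append(
            GenomicInterval(rep.chrom, min(starts), max(ends), rep.name, rep.score,
                            rep.strand, rep.summit_offset)
        )
        row = np.full(n_rep, np.nan)
        for r, (iv, _) in members.items():
            row[r] = iv.score
        scores.append(row)
    return ScoredPeakReplicates(PeakSet(merged), np.array(scores))


# ---------------------------------------------------------------------------
# consensus rule


def _pair_global_idr(sa: np.ndarray, sb: np.ndarray) -> np.ndarray:
    return idr_fit(sa, sb).global_idr


def consensus_peaks(
    groups: Mapping[str, ScoredPeakReplicates | Sequence[PeakSet]],
    idr_cut: float = 0.1,
    min_pairs: int = 3,
    idr_fn: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
):
    """Consensus = peaks reproducible (global IDR <= ``idr_cut``) in at least
    ``min_pairs`` pairwise replicate comparisons within >= 1 group.

    Returns ``(per_group, union)``: per-group consensus PeakSets and their
    union across groups.  ``idr_fn`` overrides the IDR engine (maps two score
    vectors to per-peak global IDR values); the default is :func:`idr_fit`.
    """
    idr_fn = idr_fn or _pair_global_idr
    per_group: dict[str, PeakSet] = {}
    union_names: set[str] = set()
    union_peaks: list[GenomicInterval] = []
    for gname, reps in groups.items():
        if not isinstance(reps, ScoredPeakReplicates):
            reps = match_scored_peaks(list(reps))
        if reps.n_replicates < 3:
            raise ValueError(
                f"group {gname!r} has {reps.n_replicates} replicates; need >= 3"
            )
        n = len(reps.peaks)
        passes = np.zeros(n, dtype=int)
        for i, j in combinations(range(reps.n_replicates), 2):
            mask = np.isfinite(reps.scores[:, i]) & np.isfinite(reps.scores[:, j])
            if mask.sum() == 0:
                continue
            gidr = np.asarray(idr_fn(reps.scores[mask, i], reps.scores[mask, j]))
            hit = np.zeros(n, dtype=bool)
            hit[np.flatnonzero(mask)] = gidr <= idr_cut
            passes += hit
        keep = passes >= min_pairs
        kept = PeakSet(p for p, k in zip(reps.peaks, keep) if k)
        per_group[gname] = kept
        for p in kept:
            key = f"{p.chrom}:{p.start}-{p.end}"
            if key not in union_names:
                union_names.add(key)
                union_peaks.append(p)
    union = PeakSet(sorted(union_peaks, key=lambda p: (p.chrom, p.start, p.end)))
    return per_group, union


# ---------------------------------------------------------------------------
# pseudo-replicates


def pseudo_replicates(
    peaks: PeakSet, weights: Sequence[int], seed: int = 0
) -> ScoredPeakReplicates:
    """Split pooled per-peak read weights binomially into two pseudo-replicates.

    Scores are the assigned weights (proportionality is all that matters for
    the rank-based IDR downstream).
    """
    if len(peaks) == 0:
        raise ValueError("empty peak set")
    w = np.asarray(weights)
    if w.shape != (len(peaks),):
        raise ValueError("weights must align with peaks")
    if not np.issubdtype(w.dtype, np.integer):
        if not np.allclose(w, np.round(w)):
            raise ValueError("weights must be integers")
        w = w.astype(np.int64)
    if (w < 1).any():
        raise ValueError("weights must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    a = rng.binomial(w, 0.5)
    b = w - a
    return ScoredPeakReplicates(
        peaks=peaks,
        scores=np.column_stack([a, b]).astype(float),
        replicate_ids=["pseudo1", "pseudo2"],
    )


# ---------------------------------------------------------------------------
# QC metrics


@dataclass
class QcReport:
    tss_score: float
    n_reproducible: int
    self_consistency_ratio: float
    rescue_ratio: float

    @property
    def passed(self) -> bool:
        return self.self_consistency_ratio < 2.0 and self.rescue_ratio < 2.0


def qc_ratios(
    pseudo_rep_counts: Sequence[int], n_true: int, n_pooled: int
) -> tuple[float, float, bool]:
    """Self-consistency and rescue ratios (max/min; < 2 passes).

    ``pseudo_rep_counts``: reproducible-peak counts from each biological
    replicate's within-replicate pseudo-split (>= 2 entries); the
    self-consistency ratio is the largest pairwise max/min fold difference.
    ``n_true`` vs ``n_pooled``: true-replicate vs pooled-pseudo-replicate
    reproducible counts.
    """
    counts = [int(c) for c in pseudo_rep_counts]
    if len(counts) < 2:
        raise ValueError("need >= 2 pseudo-replicate counts")
    if any(c <= 0 for c in counts) or n_true <= 0 or n_pooled <= 0:
        raise ValueError("all reproducible-peak counts must be > 0")
    scr = max(max(a, b) / min(a, b) for a, b in combinations(counts, 2))
    rescue = max(n_true, n_pooled) / min(n_true, n_pooled)
    return float(scr), float(rescue), (scr < 2.0 and rescue < 2.0)


def tss_enrichment(
    profiles: np.ndarray, flank_window: int = 100, smooth: int = 21
) -> float:
    """Aggregate TSS enrichment score of a genes x positions coverage matrix.

    The mean profile is normalized by the average of the two outermost
    ``flank_window`` segments, smoothed with a ``smooth``-bp moving average,
    and scored as the maximum within +/- 50 bp of the center position.
    """
    profiles = np.atleast_2d(np.asarray(profiles, dtype=float))
    width = profiles.shape[1]
    if width < 2 * 1000 + 1:
        raise ValueError(f"profile width {width} < {2 * 1000 + 1}")
    if width % 2 == 0:
        raise ValueError("profile width must be odd (center position required)")
    agg = profiles.mean(axis=0)
    flank = 0.5 * (agg[:flank_window].mean() + agg[-flank_window:].mean())
    if flank <= 0:
        raise ValueError("zero flank signal; cannot normalize")
    norm = agg / flank
    kernel = np.ones(smooth) / smooth
    sm = np.convolve(norm, kernel, mode="same")
    center = width // 2
    lo, hi = center - 50, center + 51
    return float(sm[lo:hi].max())
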