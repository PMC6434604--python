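"""Dual outlier scans.

1. An F_ST-vs-heterozygosity outlier scan against a parametric null: per
   simulated locus, an ancestral frequency is drawn from the empirical
   frequency distribution, per-population frequencies from a
   Balding-Nichols Beta(p(1-F)/F, q(1-F)/F), and genotype counts
   binomially at the observed sample sizes.  Per-He-bin empirical quantiles
   of theta form the confidence envelope; per-locus empirical p-values are
   Benjamini-Hochberg corrected.

2. An environmental-correlation scan: per-locus scores are absolute rank
   correlations between covariance-whitened population allele frequencies
   and a gradient (e.g. ocean distance from the origin), selected by the
   empirical within-frequency-bin ranking procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core_data import MISSING, GenotypeMatrix, PopulationMap
from .expansion_geo import DistanceTable
from .structure_analysis import wc_components

__all__ = [
    "NullEnvelope",
    "AssocScore",
    "build_null_envelope",
    "fst_outliers",
    "env_assoc_scores",
    "empirical_rank_bins",
]


# ---------------------------------------------------------------------------
# helpers shared by both scans


def _pop_freq_counts(gm: GenotypeMatrix, pm: PopulationMap):
    """(pops, n_genotyped, alt-allele freq, het fraction) arrays, (K, L)."""
    idx = pm.sample_indices_by_pop(gm)
    pops = pm.populations
    n = np.zeros((len(pops), gm.n_loci))
    p = np.zeros_like(n)
    h = np.zeros_like(n)
    for k, pop in enumerate(pops):
        sub = gm.calls[idx[pop], :]
        mask = sub != MISSING
        n[k] = mask.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[k] = np.where(n[k] > 0, np.where(mask, sub, 0).sum(axis=0) / np.maximum(2 * n[k], 1), 0.0)
        h[k] = np.where(n[k] > 0, (sub == 1).sum(axis=0) / np.maximum(n[k], 1), 0.0)
    return pops, n, p, h


def _theta_he(n: np.ndarray, p: np.ndarray, h: np.ndarray):
    """Per-locus WC theta and pooled expected heterozygosity."""
    a, b, c = wc_components(n, p, h)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(denom != 0, a / np.where(denom == 0, 1.0, denom), 0.0)
    pbar = (n * p).sum(axis=0) / np.maximum(n.sum(axis=0), 1)
    he = 2.0 * pbar * (1.0 - pbar)
    return theta, he


# ---------------------------------------------------------------------------
# F_ST outlier scan


@dataclass
class NullEnvelope:
    """Per-He-bin F_ST null distribution summaries."""

    bin_edges: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    null_theta_by_bin: list[np.ndarray]
    target_fst: float
    n_sims: int
    conf: float
    seed: int

    def bin_of(self, he: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.bin_edges, he, side="right") - 1
        return np.clip(idx, 0, len(self.bin_edges) - 2)


def _simulate_null_loci(
    rng: np.random.Generator,
    ancestral: np.ndarray,
    sample_sizes: np.ndarray,
    target_fst: float,
    n_sims: int,
):
    """Vectorized Balding-Nichols null: returns (theta, he) of n_sims loci."""
    p0 = rng.choice(ancestral, size=n_sims, replace=True)
    f = target_fst
    if f <= 0:
        pk = np.broadcast_to(p0, (len(sample_sizes), n_sims)).copy()
    else:
        shape1 = p0 * (1.0 - f) / f
        shape2 = (1.0 - p0) * (1.0 - f) / f
        pk = rng.beta(
            np.broadcast_to(shape1, (len(sample_sizes), n_sims)),
            np.broadcast_to(shape2, (len(sample_sizes), n_sims)),
        )
    n = np.broadcast_to(sample_sizes[:, None].astype(float), pk.shape)
    # genotype counts under HWE within each population
    p2 = pk * pk
    p1 = 2.0 * pk * (1.0 - pk)
    counts_hom = rng.binomial(n.astype(int), np.clip(p2, 0, 1))
    rem = n.astype(int) - counts_hom
    with np.errstate(invalid="ignore", divide="ignore"):
        cond = np.where(p2 < 1.0, p1 / np.maximum(1.0 - p2, 1e-12), 0.0)
    counts_het = rng.binomial(rem, np.clip(cond, 0, 1))
    p_hat = (2 * counts_hom + counts_het) / (2.0 * n)
    h_hat = counts_het / n
    return _theta_he(np.asarray(n), p_hat, h_hat)


def build_null_envelope(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    target_fst: float | None = None,
    n_sims: int = 100_000,
    conf: float = 0.95,
    n_he_bins: int = 20,
    seed: int = 0,
) -> NullEnvelope:
    """Simulate the neutral F_ST-vs-He envelope at the data's dimensions.

    ``target_fst`` defaults to the data-wide multilocus theta (floored at a
    small positive value).  Bins with fewer than 100 simulated loci are
    merged with their neighbor, with a warning.
    """
    if not (0 < (target_fst if target_fst is not None else 0.5) < 1):
        raise ValueError("target_fst must be in (0, 1)")
    pops, n, p, h = _pop_freq_counts(gm, pm)
    copies = 2 * n
    pbar = (n * p).sum(axis=0) / np.maximum(n.sum(axis=0), 1)
    poly = (pbar > 0) & (pbar < 1)
    ancestral = pbar[poly]
    if ancestral.size == 0:
        raise ValueError("no polymorphic loci to build a null from")
    if target_fst is None:
        a, b, c = wc_components(n, p, h)
        denom = float((a + b + c).sum())
        target_fst = max(float(a.sum()) / denom if denom else 0.0, 1e-4)
    sample_sizes = np.round(n.mean(axis=1)).astype(int)
    sample_sizes = np.maximum(sample_sizes, 2)

    rng = np.random.default_rng(seed)
    theta_sim, he_sim = _simulate_null_loci(rng, ancestral, sample_sizes, target_fst, n_sims)

    edges = np.linspace(0.0, 0.5, n_he_bins + 1)
    # merge sparse bins right-to-left
    while n_he_bins > 1:
        idx = np.clip(np.searchsorted(edges, he_sim, side="right") - 1, 0, n_he_bins - 1)
        counts = np.bincount(idx, minlength=n_he_bins)
        if counts.min() >= 100:
            break
        warnings.warn("widening He bins: fewer than 100 simulations in a bin")
        n_he_bins //= 2
        edges = np.linspace(0.0, 0.5, n_he_bins + 1)
    idx = np.clip(np.searchsorted(edges, he_sim, side="right") - 1, 0, n_he_bins - 1)

    lo_q, hi_q = (1.0 - conf) / 2.0, 1.0 - (1.0 - conf) / 2.0
    lower = np.full(n_he_bins, -1.0)
    upper = np.full(n_he_bins, 1.0)
    by_bin: list[np.ndarray] = []
    for k in range(n_he_bins):
        vals = np.sort(theta_sim[idx == k])
        by_bin.append(vals)
        if vals.size:
            lower[k] = float(np.quantile(vals, lo_q))
            upper[k] = float(np.quantile(vals, hi_q))
    return NullEnvelope(edges, lower, upper, by_bin, float(target_fst), n_sims, conf, seed)


def fst_outliers(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    envelope: NullEnvelope,
    fdr: float = 0.01,
):
    """Flag loci whose theta exceeds the upper envelope bound of their He bin
    AND survives Benjamini-Hochberg correction of per-locus empirical
    p-values at the requested rate.

    Returns a list of dicts (locus_id, theta, he, p_value, above_envelope,
    flagged); monomorphic loci are skipped.
    """
    pops, n, p, h = _pop_freq_counts(gm, pm)
    theta, he = _theta_he(n, p, h)
    poly = he > 0
    bins = envelope.bin_of(he)

    records = []
    pvals = []
    keep_idx = []
    for j in np.flatnonzero(poly):
        vals = envelope.null_theta_by_bin[bins[j]]
        if vals.size == 0:
            pv = 1.0
        else:
            # raw empirical tail proportion (0 when theta exceeds every
            # simulated value) so that clear outliers can survive BH at
            # stringent rates despite the finite simulation resolution
            ge = vals.size - np.searchsorted(vals, theta[j], side="left")
            pv = ge / vals.size
        pvals.append(pv)
        keep_idx.append(j)
    pvals = np.asarray(pvals)
    reject = _benjamini_hochberg(pvals, fdr)
    for row, j in enumerate(keep_idx):
        above = theta[j] > envelope.upper[bins[j]]
        records.append(
            {
                "locus_id": gm.loci[j].locus_id,
                "theta": float(theta[j]),
                "he": float(he[j]),
                "p_value": float(pvals[row]),
                "above_envelope": bool(above),
                "flagged": bool(above and reject[row]),
            }
        )
    return records


def _benjamini_hochberg(pvals: np.ndarray, fdr: float) -> np.ndarray:
    m = len(pvals)
    if m == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(pvals)
    ranked = pvals[order]
    thresh = fdr * (np.arange(1, m + 1) / m)
    below = ranked <= thresh
    reject = np.zeros(m, dtype=bool)
    if below.any():
        k = int(np.max(np.flatnonzero(below)))
        reject[order[: k + 1]] = True
    return reject


# ---------------------------------------------------------------------------
# Environmental-correlation scan


@dataclass(frozen=True)
class AssocScore:
    locus_id: str
    score: float
    major_freq: float  # dataset-wide major-allele frequency (p)
    bin_index: int | None = None
    rank: int | None = None
    quantile: float | None = None


def env_assoc_scores(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    gradient: DistanceTable | dict[str, float],
    covariance: np.ndarray | str = "estimate",
    shrinkage: float = 0.5,
) -> list[AssocScore]:
    """Population-structure-adjusted association of each locus with a gradient.

    Per-locus population frequencies are standardized, whitened by the
    inverse square root of a population covariance estimate (covariance of
    standardized frequencies across loci, shrunk toward its diagonal by
    ``shrinkage``), and scored as the absolute Spearman correlation between
    the whitened frequencies and the identically whitened gradient.
    Constant loci score 0.
    """
    pops, n, p, h = _pop_freq_counts(gm, pm)
    grad_map = gradient.distances if isinstance(gradient, DistanceTable) else gradient
    g = np.asarray([grad_map[pop] for pop in pops], dtype=float)

    pbar = (n * p).sum(axis=0) / np.maximum(n.sum(axis=0), 1)
    sd = np.sqrt(np.clip(pbar * (1.0 - pbar), 0.0, None))
    variable = sd > 0
    x = np.zeros_like(p)
    x[:, variable] = (p[:, variable] - pbar[variable]) / sd[variable]

    if isinstance(covariance, str):
        if covariance != "estimate":
            raise ValueError("covariance must be a matrix or 'estimate'")
        cov = np.cov(x[:, variable]) if variable.sum() >= 2 else np.eye(len(pops))
        cov = (1.0 - shrinkage) * cov + shrinkage * np.diag(np.diag(cov))
    else:
        cov = np.asarray(covariance, dtype=float)
    vals, vecs = np.linalg.eigh(cov)
    vals = np.clip(vals, 1e-10, None)
    whiten = vecs @ np.diag(vals**-0.5) @ vecs.T

    xw = whiten @ x
    gw = whiten @ g

    major_ref = pbar >= 0.5
    major_freq = np.where(major_ref, pbar, 1.0 - pbar)

    out = []
    for j, locus in enumerate(gm.loci):
        if not variable[j] or np.allclose(xw[:, j], xw[0, j]):
            score = 0.0
        else:
            rho = stats.spearmanr(xw[:, j], gw).statistic
            score = float(abs(rho)) if np.isfinite(rho) else 0.0
        out.append(AssocScore(locus.locus_id, score, float(major_freq[j])))
    return out


def empirical_rank_bins(
    scores: list[AssocScore],
    top_frac: float = 0.05,
    seed: int = 0,
) -> list[str]:
    """Select top-scoring loci within decimal allele-frequency bins.

    Each locus is assigned to a decimal-interval bin using its major- or
    minor-allele frequency, chosen uniformly at random (seeded).  Within a
    bin, loci are ranked by descending score; rank/bin_size quantiles
    <= ``top_frac`` are selected.  Frequency exactly 1.0 falls in the last
    bin.
    """
    if not scores:
        return []
    rng = np.random.default_rng(seed)
    use_p = rng.random(len(scores)) < 0.5
    freqs = np.asarray(
        [s.major_freq if use_p[i] else 1.0 - s.major_freq for i, s in enumerate(scores)]
    )
    bins = np.clip((freqs * 10).astype(int), 0, 9)

    selected: list[str] = []
    for b in range(10):
        members = [i for i in range(len(scores)) if bins[i] == b]
        if not members:
            continue
        members.sort(key=lambda i: (-scores[i].score, scores[i].locus_id))
        size = len(members)
        for rank, i in enumerate(members, start=1):
            if rank / size <= top_frac:
                selected.append(scores[i].locus_id)
    return selected
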