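"""Pairwise differentiation (Weir & Cockerham 1984 theta) with permutation
significance and Bonferroni correction, plus smartpca-style PCA with
iterative outlier removal."""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .core_data import MISSING, GenotypeMatrix, PopulationMap

__all__ = [
    "FstResult",
    "PcaResult",
    "wc_components",
    "pairwise_fst",
    "fst_matrix",
    "pca",
]


@dataclass(frozen=True)
class FstResult:
    pop_a: str
    pop_b: str
    theta: float
    sum_a: float
    sum_b: float
    sum_c: float
    p_value: float | None = None
    significant: bool | None = None


@dataclass
class PcaResult:
    samples: list[str]
    coordinates: np.ndarray  # (n_retained, k)
    percent_variance: np.ndarray
    removed_per_iteration: list[list[str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Weir-Cockerham variance components


def wc_components(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus WC84 variance components a, b, c.

    Parameters are (n_pops, n_loci) arrays of genotyped-individual counts,
    allele frequencies and observed-heterozygote fractions.  Loci where
    fewer than two populations have data, or where mean sample size is <= 1,
    yield zero components (they contribute nothing to the ratio).
    """
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    h = np.asarray(h, dtype=float)
    valid = n > 0
    r = valid.sum(axis=0).astype(float)
    n_sum = n.sum(axis=0)
    ok = r >= 2
    r_safe = np.where(ok, r, 2.0)
    nbar = n_sum / r_safe
    nc = np.where(
        ok,
        (n_sum - (n * n).sum(axis=0) / np.maximum(n_sum, 1)) / (r_safe - 1.0),
        1.0,
    )
    ok &= (nbar > 1.0) & (nc > 0.0)
    pw = np.where(valid, n * p, 0.0)
    pbar = pw.sum(axis=0) / np.maximum(n_sum, 1)
    s2 = np.where(valid, n * (p - pbar) ** 2, 0.0).sum(axis=0) / (
        (r_safe - 1.0) * np.maximum(nbar, 1e-300)
    )
    hbar = np.where(valid, n * h, 0.0).sum(axis=0) / np.maximum(n_sum, 1)

    nbar_s = np.where(ok, nbar, 2.0)
    nc_s = np.where(ok, nc, 1.0)
    pq = pbar * (1.0 - pbar)
    frac = (r_safe - 1.0) / r_safe
    a = (nbar_s / nc_s) * (
        s2 - (1.0 / (nbar_s - 1.0)) * (pq - frac * s2 - hbar / 4.0)
    )
    b = (nbar_s / (nbar_s - 1.0)) * (
        pq - frac * s2 - ((2.0 * nbar_s - 1.0) / (4.0 * nbar_s)) * hbar
    )
    c = hbar / 2.0
    zero = ~ok
    for arr in (a, b, c):
        arr[zero] = 0.0
    return a, b, c


def _pop_nph(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """n, p (alt-allele), h per locus for one population's call block."""
    mask = calls != MISSING
    n = mask.sum(axis=0).astype(float)
    alt = np.where(mask, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(2 * n, 1), 0.0)
    h = np.where(n > 0, (calls == 1).sum(axis=0) / np.maximum(n, 1), 0.0)
    return n, p, h


def _multilocus_theta(blocks: list[np.ndarray]) -> tuple[float, float, float, float]:
    nph = [_pop_nph(blk) for blk in blocks]
    n = np.stack([t[0] for t in nph])
    p = np.stack([t[1] for t in nph])
    h = np.stack([t[2] for t in nph])
    a, b, c = wc_components(n, p, h)
    sa, sb, sc = float(a.sum()), float(b.sum()), float(c.sum())
    denom = sa + sb + sc
    theta = sa / denom if denom != 0.0 else 0.0
    return theta, sa, sb, sc


def pairwise_fst(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    pop_a: str,
    pop_b: str,
    n_perm: int = 999,
    seed: int = 0,
) -> FstResult:
    """Multilocus WC84 theta between two populations with a permutation test.

    The p-value is the add-one-corrected proportion of individual-label
    permutations with theta* >= theta.
    """
    idx = pm.sample_indices_by_pop(gm)
    ia, ib = idx[pop_a], idx[pop_b]
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError("each population needs >= 2 genotyped individuals")
    block_a, block_b = gm.calls[ia, :], gm.calls[ib, :]
    theta, sa, sb, sc = _multilocus_theta([block_a, block_b])
    if sa + sb + sc == 0.0:
        import warnings

        warnings.warn(f"no shared polymorphic loci for {pop_a}/{pop_b}; theta set to 0")
        return FstResult(pop_a, pop_b, 0.0, sa, sb, sc, p_value=1.0)

    p_value = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        pooled = np.concatenate([block_a, block_b], axis=0)
        na = len(ia)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled.shape[0])
            t_star, *_ = _multilocus_theta([pooled[perm[:na]], pooled[perm[na:]]])
            if t_star >= theta:
                hits += 1
        p_value = (hits + 1) / (n_perm + 1)
    return FstResult(pop_a, pop_b, theta, sa, sb, sc, p_value=p_value)


def fst_matrix(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[tuple[str, str], FstResult]:
    """All pairwise theta values with Bonferroni-corrected significance.

    Significance flag: p <= alpha / n_pairs.  Both (a, b) and (b, a) keys are
    present with identical theta.
    """
    pops = pm.populations
    pairs = list(itertools.combinations(pops, 2))
    divisor = len(pairs)
    out: dict[tuple[str, str], FstResult] = {}
    for k, (a, b) in enumerate(pairs):
        res = pairwise_fst(gm, pm, a, b, n_perm=n_perm, seed=seed + k)
        sig = None if res.p_value is None else res.p_value <= alpha / divisor
        res = FstResult(a, b, res.theta, res.sum_a, res.sum_b, res.sum_c, res.p_value, sig)
        out[(a, b)] = res
        out[(b, a)] = FstResult(b, a, res.theta, res.sum_a, res.sum_b, res.sum_c, res.p_value, sig)
    return out


# ---------------------------------------------------------------------------
# PCA


def _scaled_dosage(calls: np.ndarray) -> np.ndarray:
    """Mean-center and scale columns by sqrt(p(1-p)); missing -> column mean."""
    x = calls.astype(float)
    x[calls == MISSING] = np.nan
    col_mean = np.nanmean(x, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    inds = np.where(np.isnan(x))
    x[inds] = np.take(col_mean, inds[1])
    p_hat = col_mean / 2.0
    scale = np.sqrt(np.clip(p_hat * (1.0 - p_hat), 0.0, None))
    keep = scale > 0
    return (x[:, keep] - col_mean[keep]) / scale[keep]


def pca(
    gm: GenotypeMatrix,
    n_axes: int = 10,
    n_outlier_iters: int = 4,
    sd_threshold: float = 6.0,
) -> PcaResult:
    """Eigen-decomposition of the scaled-dosage sample covariance with
    smartpca-style iterative outlier removal.

    Per iteration, any sample farther than ``sd_threshold`` standard
    deviations from the mean along any of the top ``n_axes`` axes is removed
    and the decomposition recomputed.
    """
    if gm.n_samples < 3:
        raise ValueError("PCA needs at least 3 samples")
    retained = list(gm.samples)
    removed_log: list[list[str]] = []

    def decompose(samples: list[str]):
        sub = gm.subset_samples(samples)
        x = _scaled_dosage(sub.calls)
        if x.shape[1] == 0 or np.allclose(x, 0.0):
            raise ValueError("degenerate input: no variable loci for PCA")
        cov = x @ x.T / x.shape[1]
        vals, vecs = np.linalg.eigh(cov)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        vals = np.clip(vals, 0.0, None)
        coords = vecs * np.sqrt(vals)
        pct = 100.0 * vals / vals.sum()
        return coords, pct

    coords, pct = decompose(retained)
    for _ in range(n_outlier_iters):
        k = min(n_axes, coords.shape[1])
        top = coords[:, :k]
        sd = top.std(axis=0, ddof=0)
        sd[sd == 0] = np.inf
        z = np.abs((top - top.mean(axis=0)) / sd)
        bad = np.flatnonzero((z > sd_threshold).any(axis=1))
        removed = [retained[i] for i in bad]
        removed_log.append(removed)
        if not removed:
            continue
        retained = [s for s in retained if s not in removed]
        if len(retained) < 3:
            raise ValueError("outlier removal left fewer than 3 samples")
        coords, pct = decompose(retained)

    k = min(n_axes, coords.shape[1])
    return PcaResult(
        samples=retained,
        coordinates=coords[:, :k],
        percent_variance=pct,
        removed_per_iteration=removed_log,
    )
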