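"""Per-locus and per-population diversity statistics.

Conventions (pinned by tests):

* ``p`` is the reference-oriented allele frequency at a (pop, locus) cell;
  population summaries report the mean frequency of the *globally* major
  allele by default (per-population polarization available by flag).
* pi is the unbiased gene diversity ``(n/(n-1)) * (1 - p^2 - q^2)`` with
  ``n`` counted in gene copies.
* F_IS = (H_S - H_I)/H_S and is *undefined* (None), not zero, when H_S = 0;
  population means average defined values only.
* Binned distributions use left-closed bins with the final bin closed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln

from .core_data import MISSING, GenotypeMatrix, PopulationMap

__all__ = [
    "LocusPopStats",
    "PopulationSummary",
    "BinnedDistribution",
    "locus_pop_stats",
    "population_summary",
    "rarefied_richness",
    "fis_distribution",
    "folded_sfs",
    "pop_frequency_table",
]


@dataclass(frozen=True)
class LocusPopStats:
    locus_id: str
    population: str
    n_gene_copies: int
    p: float
    q: float
    h_obs: float
    h_exp: float
    pi: float
    f_is: float | None


@dataclass(frozen=True)
class PopulationSummary:
    population: str
    n_individuals: int
    mean_n_genotyped: float
    private_alleles: int
    mean_major_freq: float
    mean_h_obs: float
    mean_h_exp: float
    mean_pi: float
    mean_f_is: float
    allelic_richness: float


@dataclass(frozen=True)
class BinnedDistribution:
    bin_edges: np.ndarray
    proportions: np.ndarray

    @property
    def is_empty(self) -> bool:
        return bool(np.all(self.proportions == 0))


# ---------------------------------------------------------------------------


def _pop_calls(gm: GenotypeMatrix, pm: PopulationMap, pop: str) -> np.ndarray:
    idx = pm.sample_indices_by_pop(gm).get(pop)
    if idx is None or len(idx) == 0:
        raise ValueError(f"population {pop!r} has no samples in the matrix")
    return gm.calls[idx, :]


def locus_pop_stats(
    gm: GenotypeMatrix, pm: PopulationMap, pop: str, locus_id: str
) -> LocusPopStats | None:
    """Single-cell statistics; None when no individuals are genotyped."""
    j = gm.locus_ids.index(locus_id)
    col = _pop_calls(gm, pm, pop)[:, j]
    geno = col[col != MISSING]
    n_ind = len(geno)
    if n_ind == 0:
        return None
    n = 2 * n_ind
    p = 1.0 - geno.sum() / n  # reference-allele frequency
    q = 1.0 - p
    h_obs = float(np.mean(geno == 1))
    h_exp = 2.0 * p * q
    pi = (n / (n - 1)) * (1.0 - p * p - q * q) if n > 1 else 0.0
    f_is = None if h_exp == 0.0 else (h_exp - h_obs) / h_exp
    return LocusPopStats(locus_id, pop, n, p, q, h_obs, h_exp, pi, f_is)


def _lchoose(n: np.ndarray, k: float) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefied_richness(allele_counts: Sequence[int], g: int) -> float:
    """Expected number of distinct alleles in a subsample of ``g`` gene copies.

    Hypergeometric rarefaction: sum over alleles of
    ``1 - C(N - N_a, g) / C(N, g)``.
    """
    counts = np.asarray([c for c in allele_counts if c > 0], dtype=float)
    n_total = counts.sum()
    if g < 1 or g > n_total:
        raise ValueError(f"g={g} outside [1, {int(n_total)}]")
    rest = n_total - counts
    prob_absent = np.where(
        rest < g, 0.0, np.exp(_lchoose(rest, g) - _lchoose(np.asarray(n_total), g))
    )
    return float(np.sum(1.0 - prob_absent))


def _per_pop_arrays(gm: GenotypeMatrix, pm: PopulationMap):
    """Vectorized per-pop arrays: n_genotyped, ref-allele count, het count."""
    idx = pm.sample_indices_by_pop(gm)
    pops = pm.populations
    n_geno = np.zeros((len(pops), gm.n_loci), dtype=float)
    ref_count = np.zeros_like(n_geno)
    het_count = np.zeros_like(n_geno)
    for k, pop in enumerate(pops):
        sub = gm.calls[idx[pop], :]
        mask = sub != MISSING
        n_geno[k] = mask.sum(axis=0)
        ref_count[k] = (2 * mask.sum(axis=0)) - np.where(mask, sub, 0).sum(axis=0)
        het_count[k] = (sub == 1).sum(axis=0)
    return pops, n_geno, ref_count, het_count


def pop_frequency_table(gm: GenotypeMatrix, pm: PopulationMap) -> tuple[list[str], np.ndarray, np.ndarray]:
    """(pops, ref-allele frequency matrix (n_pops, n_loci), gene-copy counts).

    Cells with no genotyped individual are NaN.
    """
    pops, n_geno, ref_count, _ = _per_pop_arrays(gm, pm)
    copies = 2 * n_geno
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(copies > 0, ref_count / np.maximum(copies, 1), np.nan)
    return pops, freq, copies


def global_major_is_ref(gm: GenotypeMatrix) -> np.ndarray:
    """Per-locus bool: the dataset-wide major allele is the reference allele.

    Ties at exactly 0.5 break toward the reference allele.
    """
    mask = gm.calls != MISSING
    copies = 2 * mask.sum(axis=0)
    alt = np.where(mask, gm.calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ref_freq = np.where(copies > 0, (copies - alt) / np.maximum(copies, 1), 1.0)
    return ref_freq >= 0.5


def population_summary(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    pop: str,
    rarefaction_g: int | None = None,
    major_allele: str = "global",
) -> PopulationSummary:
    """Table-1-shaped summary for one population, averaged over loci with data.

    ``major_allele``: "global" reports the mean per-population frequency of
    the dataset-wide major allele; "local" reports mean max(p, q) per cell.
    ``rarefaction_g`` defaults to the smallest per-population gene-copy count
    observed at any locus (>= 2).
    """
    pops, n_geno, ref_count, het_count = _per_pop_arrays(gm, pm)
    k = pops.index(pop)
    copies = 2 * n_geno
    has_data = n_geno[k] > 0
    if not has_data.any():
        raise ValueError(f"population {pop!r} has no genotyped loci")

    n = copies[k][has_data]
    p_ref = ref_count[k][has_data] / n
    q_ref = 1.0 - p_ref
    h_obs = het_count[k][has_data] / n_geno[k][has_data]
    h_exp = 2.0 * p_ref * q_ref
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(n > 1, (n / np.maximum(n - 1, 1)) * h_exp, 0.0)
    defined = h_exp > 0
    mean_f_is = (
        float(np.mean((h_exp[defined] - h_obs[defined]) / h_exp[defined]))
        if defined.any()
        else float("nan")
    )

    if major_allele == "global":
        major_ref = global_major_is_ref(gm)[has_data]
        major_freq = np.where(major_ref, p_ref, q_ref)
    elif major_allele == "local":
        major_freq = np.maximum(p_ref, q_ref)
    else:
        raise ValueError("major_allele must be 'global' or 'local'")

    # private alleles: allele present (count > 0) here and in no other pop
    alt_count = copies - ref_count
    private = 0
    for allele_counts in (ref_count, alt_count):
        here = allele_counts[k] > 0
        elsewhere = (np.delete(allele_counts, k, axis=0) > 0).any(axis=0)
        private += int(np.sum(here & ~elsewhere))

    if rarefaction_g is None:
        observed = copies[n_geno > 0]
        rarefaction_g = max(2, int(observed.min())) if observed.size else 2
    rich = []
    for j in np.flatnonzero(has_data):
        total = copies[k, j]
        g = min(rarefaction_g, int(total))
        rich.append(
            rarefied_richness([int(ref_count[k, j]), int(total - ref_count[k, j])], g)
        )

    members = pm.samples_in(pop)
    return PopulationSummary(
        population=pop,
        n_individuals=len([s for s in members if s in gm.samples]),
        mean_n_genotyped=float(np.mean(n_geno[k][has_data])),
        private_alleles=private,
        mean_major_freq=float(np.mean(major_freq)),
        mean_h_obs=float(np.mean(h_obs)),
        mean_h_exp=float(np.mean(h_exp)),
        mean_pi=float(np.mean(pi)),
        mean_f_is=mean_f_is,
        allelic_richness=float(np.mean(rich)),
    )


# ---------------------------------------------------------------------------
# Binned distributions


def _bin_proportions(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Left-closed bins, last bin closed on the right."""
    props = np.zeros(len(edges) - 1)
    if values.size == 0:
        return props
    idx = np.searchsorted(edges, values, side="right") - 1
    idx = np.clip(idx, 0, len(edges) - 2)
    for i in idx:
        props[i] += 1
    return props / values.size


def fis_distribution(
    stats: Iterable[LocusPopStats], n_bins: int = 10
) -> BinnedDistribution:
    """Proportion of loci per F_IS bin on [-1, 1]; undefined F_IS dropped."""
    vals = np.asarray([s.f_is for s in stats if s is not None and s.f_is is not None])
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    return BinnedDistribution(edges, _bin_proportions(vals, edges))


def folded_sfs(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    pop: str,
    n_bins: int = 10,
    fold: bool = False,
) -> BinnedDistribution:
    """Per-locus allele-frequency spectrum for one population.

    Default bins the major-allele frequency on [0, 1]; with ``fold=True``
    bins the minor-allele frequency on [0, 0.5].
    """
    pops, freq, copies = pop_frequency_table(gm, pm)
    k = pops.index(pop)
    f = freq[k][copies[k] > 0]
    major_ref = global_major_is_ref(gm)[copies[k] > 0]
    major = np.where(major_ref, f, 1.0 - f)
    if fold:
        vals = np.minimum(major, 1.0 - major)
        edges = np.linspace(0.0, 0.5, n_bins + 1)
    else:
        vals = major
        edges = np.linspace(0.0, 1.0, n_bins + 1)
    return BinnedDistribution(edges, _bin_proportions(vals, edges))
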