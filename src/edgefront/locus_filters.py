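"""Locus classifiers based on per-population frequencies of the global
major allele, and set-overlap accounting between classifier outputs.

All classifiers are deterministic functions of the genotype matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_data import GenotypeMatrix, PopulationMap
from .sumstats import global_major_is_ref, pop_frequency_table

__all__ = [
    "LocusFrequencyProfile",
    "frequency_profiles",
    "flip_flop_loci",
    "minmax_diff_loci",
    "center_edge_excess",
    "overlap_table",
]


@dataclass(frozen=True)
class LocusFrequencyProfile:
    """Per-population frequency of one locus's dataset-wide major allele.

    The major allele is the allele most frequent across all samples pooled;
    a tie at exactly 0.5 breaks toward the reference allele.
    """

    locus_id: str
    major_is_ref: bool
    freqs: dict[str, float]  # population -> major-allele frequency (NaN if no data)

    @property
    def min_freq(self) -> float:
        return float(np.nanmin(list(self.freqs.values())))

    @property
    def max_freq(self) -> float:
        return float(np.nanmax(list(self.freqs.values())))

    @property
    def minmax_diff(self) -> float:
        return self.max_freq - self.min_freq


def frequency_profiles(
    gm: GenotypeMatrix, pm: PopulationMap
) -> list[LocusFrequencyProfile]:
    """One profile per locus, globally polarized, missing-aware."""
    pops, ref_freq, copies = pop_frequency_table(gm, pm)
    major_ref = global_major_is_ref(gm)
    out = []
    for j, locus in enumerate(gm.loci):
        f = ref_freq[:, j] if major_ref[j] else 1.0 - ref_freq[:, j]
        out.append(
            LocusFrequencyProfile(
                locus_id=locus.locus_id,
                major_is_ref=bool(major_ref[j]),
                freqs=dict(zip(pops, f.tolist())),
            )
        )
    return out


def flip_flop_loci(profiles: list[LocusFrequencyProfile]) -> set[str]:
    """Loci where the global major allele is locally the minor allele in at
    least one population (per-pop frequency strictly below 0.5)."""
    return {p.locus_id for p in profiles if p.min_freq < 0.5}


def minmax_diff_loci(
    profiles: list[LocusFrequencyProfile],
    threshold: float,
    inclusive: bool = True,
) -> set[str]:
    """Loci whose max-min spread of major-allele frequency reaches ``threshold``.

    ``inclusive`` selects >= (default, "at least"); False selects strict >.
    """
    if inclusive:
        return {p.locus_id for p in profiles if p.minmax_diff >= threshold}
    return {p.locus_id for p in profiles if p.minmax_diff > threshold}


def center_edge_excess(
    profiles: list[LocusFrequencyProfile],
    center_pop: str,
    edge_pop: str,
    locus_set: set[str] | None = None,
) -> tuple[int, list[str]]:
    """Loci (within ``locus_set``) with strictly greater major-allele
    frequency in the center population than the edge population."""
    hits = []
    for p in profiles:
        if locus_set is not None and p.locus_id not in locus_set:
            continue
        fc, fe = p.freqs[center_pop], p.freqs[edge_pop]
        if np.isnan(fc) or np.isnan(fe):
            continue
        if fc > fe:
            hits.append(p.locus_id)
    return len(hits), hits


def overlap_table(named_sets: dict[str, set[str]]) -> dict:
    """Pairwise intersection and difference counts between named locus sets.

    Returns ``{"sizes": {name: |A|}, "intersection": {(a, b): |A∩B|},
    "difference": {(a, b): |A\\B|}}`` over all ordered pairs.
    """
    names = list(named_sets)
    inter: dict[tuple[str, str], int] = {}
    diff: dict[tuple[str, str], int] = {}
    for a in names:
        for b in names:
            if a == b:
                continue
            common = len(named_sets[a] & named_sets[b])
            inter[(a, b)] = common
            diff[(a, b)] = len(named_sets[a]) - common
    return {
        "sizes": {n: len(named_sets[n]) for n in names},
        "intersection": inter,
        "difference": diff,
    }
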