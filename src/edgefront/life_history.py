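"""Age estimation from fish length and genome-size arithmetic.

Growth-curve and length-conversion coefficients are configuration, not
constants; the shipped defaults are documented plausibility values for a
lionfish-like reef fish and can be overridden from a TOML/JSON config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "GrowthParams",
    "GenomeModelParams",
    "standard_length_from_total",
    "total_length_from_standard",
    "age_from_length",
    "length_from_age",
    "recruitment_year",
    "predict_genome_size",
    "invert_genome_size",
    "genome_fraction",
    "round_percent",
]


@dataclass(frozen=True)
class GrowthParams:
    """von Bertalanffy parameters plus a linear total->standard length map."""

    l_inf: float = 425.0  # asymptotic standard length, mm
    k: float = 0.47  # growth coefficient, 1/yr
    t0: float = -0.5  # theoretical age at length zero, yr
    tl_to_sl_slope: float = 0.78
    tl_to_sl_intercept: float = 0.9

    def __post_init__(self) -> None:
        if self.l_inf <= 0 or self.k <= 0:
            raise ValueError("l_inf and k must be positive")


def standard_length_from_total(total_length_mm: float, params: GrowthParams) -> float:
    sl = params.tl_to_sl_slope * total_length_mm + params.tl_to_sl_intercept
    if sl < 0:
        raise ValueError(f"conversion yields negative standard length ({sl:.2f} mm)")
    return sl


def total_length_from_standard(standard_length_mm: float, params: GrowthParams) -> float:
    if params.tl_to_sl_slope == 0:
        raise ValueError("conversion slope is zero; not invertible")
    return (standard_length_mm - params.tl_to_sl_intercept) / params.tl_to_sl_slope


def length_from_age(age_yr: float, params: GrowthParams) -> float:
    """Forward von Bertalanffy curve L(t) = L_inf (1 - e^{-K (t - t0)})."""
    return params.l_inf * (1.0 - math.exp(-params.k * (age_yr - params.t0)))


def age_from_length(standard_length_mm: float, params: GrowthParams) -> float:
    """Inverse von Bertalanffy: age = t0 - ln(1 - SL/L_inf) / K."""
    if standard_length_mm >= params.l_inf:
        raise ValueError(
            f"length {standard_length_mm} mm >= asymptotic length {params.l_inf} mm; "
            "age undefined"
        )
    if standard_length_mm < 0:
        raise ValueError("length must be non-negative")
    return params.t0 - math.log(1.0 - standard_length_mm / params.l_inf) / params.k


def recruitment_year(collection_date: float, age_yr: float) -> int:
    """Calendar year of recruitment from a fractional collection date."""
    if age_yr < 0:
        raise ValueError("age must be non-negative")
    return math.floor(collection_date - age_yr)


# ---------------------------------------------------------------------------
# Genome size


def _default_genome_coefficients() -> tuple[float, float]:
    # log10(genome bp) = intercept + slope * log10(cut sites); anchored to the
    # published mapping endpoints (15,000 sites -> 370,725,631 bp and
    # 25,000 sites -> 680,784,288 bp) for an SbfI digest.
    x1, y1 = math.log10(15_000), math.log10(370_725_631)
    x2, y2 = math.log10(25_000), math.log10(680_784_288)
    slope = (y2 - y1) / (x2 - x1)
    return y1 - slope * x1, slope


@dataclass(frozen=True)
class GenomeModelParams:
    """Log-log linear model mapping restriction cut-site count to genome size."""

    log10_intercept: float = _default_genome_coefficients()[0]
    log10_slope: float = _default_genome_coefficients()[1]

    def __post_init__(self) -> None:
        if self.log10_slope <= 0:
            raise ValueError("genome-size model must be monotone increasing")


def predict_genome_size(
    n_cut_sites: float, params: GenomeModelParams | None = None
) -> float:
    """Predicted genome size (bp) for an observed cut-site count."""
    if n_cut_sites <= 0:
        raise ValueError("cut-site count must be positive")
    params = params or GenomeModelParams()
    return 10.0 ** (params.log10_intercept + params.log10_slope * math.log10(n_cut_sites))


def invert_genome_size(genome_bp: float, params: GenomeModelParams | None = None) -> float:
    """Cut-site count implied by a genome size; inverse of the forward map."""
    if genome_bp <= 0:
        raise ValueError("genome size must be positive")
    params = params or GenomeModelParams()
    return 10.0 ** ((math.log10(genome_bp) - params.log10_intercept) / params.log10_slope)


def genome_fraction(
    n_loci: int, locus_len_bp: float, genome_size_bp: float, ndigits: int = 2
) -> float:
    """Percent of the genome covered by ``n_loci`` loci of fixed length."""
    if genome_size_bp <= 0:
        raise ValueError("genome size must be positive")
    if n_loci < 0 or locus_len_bp < 0:
        raise ValueError("counts and lengths must be non-negative")
    return round(100.0 * n_loci * locus_len_bp / genome_size_bp, ndigits)


def round_percent(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Rounded percentage ``100 * numerator / denominator``."""
    if denominator == 0:
        raise ValueError("denominator must be nonzero")
    return round(100.0 * numerator / denominator, ndigits)
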