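"""Synthetic datasets: serial-founder range expansions, island-model nulls,
toy ocean grids, and fish length tables.

The expansion simulator runs forward-time Wright-Fisher drift on per-locus
allele frequencies (loci independent, matching the unlinked-SNP assumption
of the downstream analyses).  Demes along a colonization path are founded
serially by small binomial founder draws from their source deme, grow
logistically to carrying capacity, and exchange symmetric migrants with
adjacent colonized demes each generation.  Final diploid samples are drawn
from a mixture of the local deme and its neighbors (a recent-migrant
Wahlund component), which produces the heterozygote deficits that
accumulate toward the expanding edge.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .core_data import MISSING, GenotypeMatrix, LocusInfo, PopulationMap
from .expansion_geo import OceanGrid
from .life_history import GrowthParams, length_from_age, total_length_from_standard

__all__ = [
    "ExpansionConfig",
    "SimTruth",
    "simulate_expansion",
    "simulate_null",
    "make_toy_ocean_grid",
    "simulate_lengths",
]


@dataclass
class ExpansionConfig:
    """Parameters of the serial-founder expansion simulator."""

    n_demes: int = 9
    deme_positions: list[tuple[float, float]] | None = None  # (lat, lon) per deme
    colonization_order: list[int] | None = None  # permutation; default 0..n-1
    generations_between: int = 5
    post_generations: int = 5
    founder_size: int = 10
    carrying_capacity: int = 500
    growth_rate: float = 0.5
    migration_rate: float = 0.01
    migrant_sampling_fraction: float = 0.15
    n_loci: int = 12_000
    ancestral_dist: str = "one_over_x"  # or "beta"
    beta_params: tuple[float, float] = (0.5, 0.5)
    samples_per_deme: Sequence[int] | int = (11, 9, 11, 14, 16, 7, 20, 15, 16)
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.founder_size > self.carrying_capacity:
            raise ValueError("founder size must not exceed carrying capacity")
        if not (0.0 <= self.migration_rate <= 1.0):
            raise ValueError("migration rate must be in [0, 1]")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError("missing rate must be in [0, 1]")
        if self.colonization_order is None:
            self.colonization_order = list(range(self.n_demes))
        if sorted(self.colonization_order) != list(range(self.n_demes)):
            raise ValueError("colonization_order must be a permutation of demes")
        if isinstance(self.samples_per_deme, int):
            self.samples_per_deme = [self.samples_per_deme] * self.n_demes
        else:
            self.samples_per_deme = list(self.samples_per_deme)
        if len(self.samples_per_deme) != self.n_demes:
            raise ValueError("samples_per_deme length must equal n_demes")
        if self.deme_positions is None:
            self.deme_positions = [(0.0, float(i)) for i in range(self.n_demes)]


@dataclass
class SimTruth:
    """Ground truth sufficient to reproduce a simulated dataset bit-for-bit."""

    origin_deme: str
    colonization_times: dict[str, int]
    config: dict
    seed: int
    kind: str = "expansion"

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


def _ancestral_frequencies(rng: np.random.Generator, cfg: ExpansionConfig) -> np.ndarray:
    n = 2 * cfg.carrying_capacity
    lo, hi = 1.0 / n, 1.0 - 1.0 / n
    if cfg.ancestral_dist == "one_over_x":
        # density proportional to 1/x on [lo, hi]; inverse-CDF sampling
        u = rng.random(cfg.n_loci)
        return lo * (hi / lo) ** u
    if cfg.ancestral_dist == "beta":
        return np.clip(rng.beta(*cfg.beta_params, size=cfg.n_loci), lo, hi)
    raise ValueError(f"unknown ancestral_dist {cfg.ancestral_dist!r}")


def _deme_labels(n: int) -> list[str]:
    return [f"D{i:02d}" for i in range(n)]


def simulate_expansion(
    cfg: ExpansionConfig,
) -> tuple[GenotypeMatrix, PopulationMap, SimTruth]:
    """Forward-time serial-founder expansion; see module docstring.

    Returns the sampled genotype matrix, a population map with deme
    coordinates, and the ground truth (origin, colonization times, config).
    """
    rng = np.random.default_rng(cfg.seed)
    order = list(cfg.colonization_order)
    labels = _deme_labels(cfg.n_demes)

    freq = np.zeros((cfg.n_demes, cfg.n_loci))
    size = np.zeros(cfg.n_demes, dtype=int)
    colonized = np.zeros(cfg.n_demes, dtype=bool)

    origin = order[0]
    freq[origin] = _ancestral_frequencies(rng, cfg)
    size[origin] = cfg.carrying_capacity
    colonized[origin] = True
    colonization_times = {labels[origin]: 0}

    def step_generation() -> None:
        """One generation: migration along the path, growth, drift."""
        active = np.flatnonzero(colonized)
        if cfg.migration_rate > 0 and len(active) > 1:
            # adjacency along the colonization path among colonized demes
            new = freq.copy()
            rank = {d: k for k, d in enumerate(order)}
            for d in active:
                nbrs = [
                    e
                    for e in active
                    if abs(rank[e] - rank[d]) == 1
                ]
                if nbrs:
                    inflow = np.mean([freq[e] for e in nbrs], axis=0)
                    m = cfg.migration_rate * len(nbrs)
                    new[d] = (1.0 - m) * freq[d] + m * inflow
            freq[active] = new[active]
        for d in active:
            if size[d] < cfg.carrying_capacity:
                grown = size[d] + cfg.growth_rate * size[d] * (
                    1.0 - size[d] / cfg.carrying_capacity
                )
                size[d] = min(cfg.carrying_capacity, int(round(grown)) or 1)
            copies = 2 * size[d]
            freq[d] = rng.binomial(copies, freq[d]) / copies

    generation = 0
    for nxt in order[1:]:
        for _ in range(cfg.generations_between):
            step_generation()
            generation += 1
        # founder draw from the previous deme on the path: 2F gene copies
        # sampled without replacement, so F equal to the source size copies
        # the source exactly (no drift opportunity)
        src = order[order.index(nxt) - 1]
        copies = 2 * cfg.founder_size
        src_copies = 2 * int(size[src])
        derived = np.rint(freq[src] * src_copies).astype(int)
        if copies >= src_copies:
            freq[nxt] = derived / src_copies
        else:
            freq[nxt] = rng.hypergeometric(derived, src_copies - derived, copies) / copies
        size[nxt] = cfg.founder_size
        colonized[nxt] = True
        colonization_times[labels[nxt]] = generation
    for _ in range(cfg.post_generations):
        step_generation()
        generation += 1

    # sampling: per individual, pick a source component (resident or recent
    # neighbor migrant), then draw a diploid genotype from that component
    rank = {d: k for k, d in enumerate(order)}
    samples: list[str] = []
    sample_to_pop: dict[str, str] = {}
    rows: list[np.ndarray] = []
    for d in range(cfg.n_demes):
        nbrs = [e for e in range(cfg.n_demes) if abs(rank[e] - rank[d]) == 1]
        comp_freqs = [freq[d]] + [freq[e] for e in nbrs]
        weights = np.asarray(
            [1.0 - cfg.migrant_sampling_fraction]
            + [cfg.migrant_sampling_fraction / len(nbrs)] * len(nbrs)
            if nbrs
            else [1.0]
        )
        for i in range(cfg.samples_per_deme[d]):
            name = f"{labels[d]}_{i:03d}"
            samples.append(name)
            sample_to_pop[name] = labels[d]
            comp = rng.choice(len(comp_freqs), p=weights)
            dose = rng.binomial(2, comp_freqs[comp]).astype(np.int8)
            rows.append(dose)
    calls = np.stack(rows, axis=0)
    if cfg.missing_rate > 0:
        mask = rng.random(calls.shape) < cfg.missing_rate
        calls = np.where(mask, np.int8(MISSING), calls)

    loci = [
        LocusInfo(locus_id=f"L{j:06d}", tag_id=f"tag{j:06d}", pos=1, ref="A", alt="C")
        for j in range(cfg.n_loci)
    ]
    gm = GenotypeMatrix(samples=samples, loci=loci, calls=calls)
    coords = {labels[d]: cfg.deme_positions[d] for d in range(cfg.n_demes)}
    pm = PopulationMap(sample_to_pop=sample_to_pop, coordinates=coords)
    truth = SimTruth(
        origin_deme=labels[origin],
        colonization_times=colonization_times,
        config=asdict(cfg),
        seed=cfg.seed,
    )
    return gm, pm, truth


def simulate_null(
    n_pops: int = 9,
    n_loci: int = 1000,
    samples_per_pop: Sequence[int] | int = 12,
    target_fst: float = 0.01,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> tuple[GenotypeMatrix, PopulationMap, SimTruth]:
    """Island-model null: Balding-Nichols frequencies at a target F_ST.

    With ``target_fst == 0`` every population shares the ancestral
    frequencies exactly.
    """
    if not (0.0 <= target_fst < 1.0):
        raise ValueError("target_fst must be in [0, 1)")
    rng = np.random.default_rng(seed)
    if isinstance(samples_per_pop, int):
        samples_per_pop = [samples_per_pop] * n_pops
    labels = _deme_labels(n_pops)

    lo, hi = 0.05, 0.95
    u = rng.random(n_loci)
    p0 = lo * (hi / lo) ** u
    if target_fst == 0.0:
        pk = np.broadcast_to(p0, (n_pops, n_loci)).copy()
    else:
        f = target_fst
        pk = rng.beta(
            np.broadcast_to(p0 * (1 - f) / f, (n_pops, n_loci)),
            np.broadcast_to((1 - p0) * (1 - f) / f, (n_pops, n_loci)),
        )

    samples: list[str] = []
    sample_to_pop: dict[str, str] = {}
    rows = []
    for k in range(n_pops):
        for i in range(samples_per_pop[k]):
            name = f"{labels[k]}_{i:03d}"
            samples.append(name)
            sample_to_pop[name] = labels[k]
            rows.append(rng.binomial(2, pk[k]).astype(np.int8))
    calls = np.stack(rows, axis=0)
    if missing_rate > 0:
        mask = rng.random(calls.shape) < missing_rate
        calls = np.where(mask, np.int8(MISSING), calls)
    loci = [
        LocusInfo(locus_id=f"L{j:06d}", tag_id=f"tag{j:06d}", pos=1, ref="A", alt="C")
        for j in range(n_loci)
    ]
    gm = GenotypeMatrix(samples=samples, loci=loci, calls=calls)
    pm = PopulationMap(
        sample_to_pop=sample_to_pop,
        coordinates={labels[k]: (0.0, float(k)) for k in range(n_pops)},
    )
    truth = SimTruth(
        origin_deme="",
        colonization_times={},
        config={
            "n_pops": n_pops,
            "n_loci": n_loci,
            "samples_per_pop": list(samples_per_pop),
            "target_fst": target_fst,
            "missing_rate": missing_rate,
        },
        seed=seed,
        kind="island_null",
    )
    return gm, pm, truth


def make_toy_ocean_grid(
    rows: int,
    cols: int,
    land_cells: Sequence[tuple[int, int]] = (),
    cell_size_km: float = 1.0,
) -> OceanGrid:
    """Planar rectangular grid with designated land cells (for tests/demos)."""
    water = np.ones((rows, cols), dtype=bool)
    for r, c in land_cells:
        water[r, c] = False
    y = np.arange(rows)[:, None] * cell_size_km * np.ones((1, cols))
    x = np.ones((rows, 1)) * np.arange(cols)[None, :] * cell_size_km
    return OceanGrid(water=water, lat=y, lon=x, planar=True)


def simulate_lengths(
    n: int,
    params: GrowthParams,
    age_range: tuple[float, float] = (0.5, 6.0),
    noise_sd_mm: float = 5.0,
    collection_date: float = 2013.5,
    seed: int = 0,
):
    """Fish length table: ages ~ Uniform(age_range), forward growth curve plus
    Gaussian noise on standard length, total length via the inverse of the
    TL->SL conversion.

    Returns a list of dicts with true_age, standard/total lengths and the
    collection date.
    """
    rng = np.random.default_rng(seed)
    ages = rng.uniform(*age_range, size=n)
    out = []
    for i, age in enumerate(ages):
        sl = length_from_age(float(age), params) + rng.normal(0.0, noise_sd_mm)
        sl = float(np.clip(sl, 0.0, params.l_inf * 0.999))
        out.append(
            {
                "fish_id": f"F{i:04d}",
                "true_age_yr": float(age),
                "standard_length_mm": sl,
                "total_length_mm": total_length_from_standard(sl, params),
                "collection_date": collection_date,
            }
        )
    return out
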