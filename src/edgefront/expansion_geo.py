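"""Least-cost ocean distances, diversity-vs-distance regressions, and the
directionality index (psi) with origin ranking.

The ocean grid is a raster of water/land cells with 8-neighborhood
adjacency.  Edge weights are great-circle lengths between cell centers for
geographic grids, or Euclidean lengths for planar toy grids.  Waypoint
constraints (e.g. routing around a landmass) are realized by concatenating
shortest legs through an ordered list of waypoint sites.

The directionality index psi_ij is the mean, over included loci, of the
difference in derived-allele frequency between two populations after both
are downsampled to a common number of gene copies.  With alleles polarized
so that the dataset-wide minor allele is "derived", populations nearer an
expansion origin carry lower derived frequencies at surfed alleles, so
ranking sites by ascending row mean puts the origin first.
"""

from __future__ import annotations

import itertools
import warnings
import zlib
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .core_data import MISSING, GenotypeMatrix, PopulationMap

__all__ = [
    "OceanGrid",
    "DistanceTable",
    "RegressionResult",
    "PsiMatrix",
    "UnreachableError",
    "least_cost_distance",
    "distance_table",
    "diversity_distance_regression",
    "psi_from_frequencies",
    "psi_pair",
    "psi_matrix_and_ranking",
]

EARTH_RADIUS_KM = 6371.0088


class UnreachableError(RuntimeError):
    """No water path exists between the requested cells."""


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance between two (lat, lon) points in km."""
    la1, lo1, la2, lo2 = map(np.radians, (lat1, lon1, lat2, lon2))
    s = (
        np.sin((la2 - la1) / 2.0) ** 2
        + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2.0) ** 2
    )
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(s)))


@dataclass
class OceanGrid:
    """Water/land raster with cell geometry.

    ``water`` is a (rows, cols) boolean mask.  ``lat``/``lon`` give cell
    center coordinates; for ``planar`` grids they are y/x in km and edges use
    Euclidean lengths instead of great-circle lengths.
    """

    water: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    planar: bool = False
    _graph: nx.Graph | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.water = np.asarray(self.water, dtype=bool)
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        if not (self.water.shape == self.lat.shape == self.lon.shape):
            raise ValueError("water, lat and lon must share a shape")
        if not self.water.any():
            raise ValueError("grid contains no water cells")

    @classmethod
    def from_elevation(
        cls,
        elevation: np.ndarray,
        lat: np.ndarray,
        lon: np.ndarray,
        sea_threshold: float = 0.0,
    ) -> "OceanGrid":
        """Build from a single-band elevation raster: sea where value <= threshold."""
        return cls(np.asarray(elevation) <= sea_threshold, lat, lon, planar=False)

    def _edge_length(self, a: tuple[int, int], b: tuple[int, int]) -> float:
        if self.planar:
            dy = self.lat[a] - self.lat[b]
            dx = self.lon[a] - self.lon[b]
            return float(np.hypot(dx, dy))
        return haversine_km(self.lat[a], self.lon[a], self.lat[b], self.lon[b])

    def graph(self) -> nx.Graph:
        """8-neighborhood graph over water cells; cached."""
        if self._graph is not None:
            return self._graph
        g = nx.Graph()
        rows, cols = self.water.shape
        wr, wc = np.nonzero(self.water)
        g.add_nodes_from(zip(wr.tolist(), wc.tolist()))
        for r, c in zip(wr.tolist(), wc.tolist()):
            for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < rows and 0 <= c2 < cols and self.water[r2, c2]:
                    w = self._edge_length((r, c), (r2, c2))
                    if w <= 0:
                        raise ValueError("non-positive edge length in grid")
                    g.add_edge((r, c), (r2, c2), weight=w)
        self._graph = g
        return g

    def snap(self, lat: float, lon: float) -> tuple[int, int]:
        """Nearest water cell; ties broken by row-major order."""
        wr, wc = np.nonzero(self.water)
        if self.planar:
            d = np.hypot(self.lat[wr, wc] - lat, self.lon[wr, wc] - lon)
        else:
            d = np.asarray(
                [
                    haversine_km(lat, lon, self.lat[r, c], self.lon[r, c])
                    for r, c in zip(wr, wc)
                ]
            )
        best = int(np.argmin(d))  # nonzero() order is row-major, argmin takes first
        return int(wr[best]), int(wc[best])


def _leg(grid: OceanGrid, a: tuple[int, int], b: tuple[int, int]) -> float:
    g = grid.graph()
    try:
        return float(nx.dijkstra_path_length(g, a, b, weight="weight"))
    except (nx.NetworkXNoPath, nx.NodeNotFound) as exc:
        raise UnreachableError(f"no water path between {a} and {b}") from exc


def least_cost_distance(
    grid: OceanGrid,
    src: tuple[float, float],
    dst: tuple[float, float],
    waypoints: list[tuple[float, float]] | None = None,
) -> float:
    """Shortest over-water path length from src to dst ((lat, lon) pairs).

    With waypoints, the path is the concatenation of shortest legs
    src -> w1 -> ... -> dst, so the result is >= the unconstrained distance.
    """
    pts = [grid.snap(*src)] + [grid.snap(*w) for w in (waypoints or [])] + [grid.snap(*dst)]
    return sum(_leg(grid, a, b) for a, b in zip(pts[:-1], pts[1:]))


@dataclass
class DistanceTable:
    """Per-site distances (km) from a designated origin site."""

    origin: str
    distances: dict[str, float]
    method: str = "least-cost"

    def __post_init__(self) -> None:
        for site, d in self.distances.items():
            if d < 0:
                raise ValueError(f"negative distance for {site}")
        if self.origin in self.distances and self.distances[self.origin] != 0.0:
            raise ValueError("origin distance must be 0")

    def aligned(self, sites: list[str]) -> np.ndarray:
        return np.asarray([self.distances[s] for s in sites], dtype=float)


def distance_table(
    grid: OceanGrid,
    sites: dict[str, tuple[float, float]],
    origin: str,
    waypoints_for: dict[str, list[tuple[float, float]]] | None = None,
    method: str = "least-cost",
) -> DistanceTable:
    """Distances from ``origin`` to every site.

    ``waypoints_for`` maps site labels to ordered waypoint coordinates
    (e.g. sites west of a landmass constrained to route around it).
    ``method`` may be "least-cost" or "great-circle".
    """
    if origin not in sites:
        raise ValueError(f"origin {origin!r} not among sites")
    src = sites[origin]
    out: dict[str, float] = {}
    for label, coord in sites.items():
        if label == origin:
            out[label] = 0.0
        elif method == "great-circle":
            out[label] = haversine_km(*src, *coord)
        else:
            wps = (waypoints_for or {}).get(label)
            out[label] = least_cost_distance(grid, src, coord, waypoints=wps)
    return DistanceTable(origin=origin, distances=out, method=method)


# ---------------------------------------------------------------------------
# Regression


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def diversity_distance_regression(
    values: dict[str, float], distances: DistanceTable
) -> RegressionResult:
    """OLS of a per-site statistic against distance from the origin.

    Two-sided p-value from the t statistic with n-2 degrees of freedom.
    """
    sites = [s for s in values if s in distances.distances]
    if len(sites) < 3:
        raise ValueError("need at least 3 sites with both value and distance")
    x = distances.aligned(sites)
    y = np.asarray([values[s] for s in sites], dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in distances")
    res = stats.linregress(x, y)
    if not np.isfinite(res.rvalue):  # constant y: slope 0, no fit to speak of
        return RegressionResult(0.0, float(np.mean(y)), 0.0, 1.0, len(sites))
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(sites),
    )


# ---------------------------------------------------------------------------
# Directionality index


def _derived_counts(gm: GenotypeMatrix, pm: PopulationMap, polarization: str = "minor"):
    """Per-pop derived-allele counts and gene-copy totals, (n_pops, n_loci).

    ``polarization="minor"`` treats the dataset-wide minor allele as derived
    (ties at 0.5 resolve the REF allele as ancestral); ``"alt"`` trusts the
    VCF ALT allele as derived (use when REF is a true ancestral state).
    """
    idx = pm.sample_indices_by_pop(gm)
    pops = pm.populations
    alt = np.zeros((len(pops), gm.n_loci))
    tot = np.zeros_like(alt)
    for k, pop in enumerate(pops):
        sub = gm.calls[idx[pop], :]
        mask = sub != MISSING
        tot[k] = 2 * mask.sum(axis=0)
        alt[k] = np.where(mask, sub, 0).sum(axis=0)
    if polarization == "alt":
        return pops, alt, tot
    if polarization != "minor":
        raise ValueError("polarization must be 'minor' or 'alt'")
    alt_freq_global = alt.sum(axis=0) / np.maximum(tot.sum(axis=0), 1)
    derived_is_alt = alt_freq_global < 0.5
    derived = np.where(derived_is_alt, alt, tot - alt)
    return pops, derived, tot


def _hypergeom_downsample(
    rng: np.random.Generator, derived: np.ndarray, total: np.ndarray, m: int
) -> np.ndarray:
    """Draw without replacement m gene copies per locus; returns derived counts."""
    good = total - derived
    return rng.hypergeometric(derived.astype(int), good.astype(int), m)


def psi_from_frequencies(f_i: np.ndarray, f_j: np.ndarray) -> float:
    """psi for a pair given already-included per-locus derived frequencies."""
    f_i = np.asarray(f_i, dtype=float)
    f_j = np.asarray(f_j, dtype=float)
    if f_i.shape != f_j.shape or f_i.size == 0:
        raise ValueError("frequency vectors must be non-empty and equal-length")
    return float(np.mean(f_i - f_j))


def psi_pair(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    pop_i: str,
    pop_j: str,
    subsample_n: int = 10,
    polarization: str = "minor",
    seed: int = 0,
) -> tuple[float, int]:
    """Directionality index for one ordered pair; returns (psi, n_loci_used).

    Both populations are downsampled without replacement to ``subsample_n``
    gene copies per locus.  A locus is included iff the derived allele is
    present in both downsampled populations and not fixed in their union.
    psi_ij = mean over included loci of (f_i - f_j).

    The random stream is keyed on the unordered pair so that swapping the
    populations flips the sign exactly.
    """
    pops, derived, tot = _derived_counts(gm, pm, polarization=polarization)
    ki, kj = pops.index(pop_i), pops.index(pop_j)
    lo, hi = (ki, kj) if pop_i <= pop_j else (kj, ki)
    pair_key = zlib.crc32(f"{pops[lo]}|{pops[hi]}".encode())

    usable = (tot[ki] >= subsample_n) & (tot[kj] >= subsample_n)
    if not usable.any():
        warnings.warn("no loci with enough gene copies in both populations")
        return float("nan"), 0
    # common random numbers: both populations are downsampled with the same
    # pair-keyed stream, so identical populations yield identical draws
    # (psi exactly 0) and pair noise partially cancels
    rng_lo = np.random.default_rng(np.random.SeedSequence([seed, pair_key]))
    rng_hi = np.random.default_rng(np.random.SeedSequence([seed, pair_key]))
    d_lo = _hypergeom_downsample(rng_lo, derived[lo][usable], tot[lo][usable], subsample_n)
    d_hi = _hypergeom_downsample(rng_hi, derived[hi][usable], tot[hi][usable], subsample_n)
    d_i, d_j = (d_lo, d_hi) if lo == ki else (d_hi, d_lo)

    include = (d_i > 0) & (d_j > 0) & (d_i + d_j < 2 * subsample_n)
    if not include.any():
        warnings.warn(f"no loci pass the psi inclusion rule for {pop_i}/{pop_j}")
        return float("nan"), 0
    f_i = d_i[include] / subsample_n
    f_j = d_j[include] / subsample_n
    return float(np.mean(f_i - f_j)), int(include.sum())


@dataclass
class PsiMatrix:
    """Antisymmetric matrix of pairwise psi values plus an origin ranking."""

    populations: list[str]
    values: np.ndarray  # (n, n), values[i, j] = psi_ij
    n_loci: np.ndarray  # loci included per pair
    subsample_n: int
    ranking: list[str] = field(default_factory=list)

    def row_means(self) -> np.ndarray:
        n = len(self.populations)
        off = ~np.eye(n, dtype=bool)
        return np.array(
            [np.nanmean(self.values[i][off[i]]) for i in range(n)]
        )


def psi_matrix_and_ranking(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    subsample_n: int = 10,
    polarization: str = "minor",
    seed: int = 0,
) -> PsiMatrix:
    """Full psi matrix and origin ranking.

    Ranking statistic is each site's row mean, ordered so the inferred
    expansion origin comes first (ties broken by label).  Orientation is
    calibrated against the serial-founder simulator: with ancestral
    ("alt") polarization, surfing inflates derived frequencies away from
    the origin, so the origin has the *lowest* row mean; with the default
    dataset-minor polarization, loci whose surfed allele overtakes the
    dataset-wide majority are re-polarized, which reverses the asymmetry,
    so the origin has the *highest* row mean.
    """
    pops = pm.populations
    n = len(pops)
    vals = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    for i, j in itertools.combinations(range(n), 2):
        psi, used = psi_pair(
            gm, pm, pops[i], pops[j],
            subsample_n=subsample_n, polarization=polarization, seed=seed,
        )
        vals[i, j] = psi
        vals[j, i] = -psi
        counts[i, j] = counts[j, i] = used
    mat = PsiMatrix(list(pops), vals, counts, subsample_n)
    means = mat.row_means()
    sign = 1.0 if polarization == "alt" else -1.0
    order = sorted(range(n), key=lambda k: (sign * means[k], pops[k]))
    mat.ranking = [pops[k] for k in order]
    return mat
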