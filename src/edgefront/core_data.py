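"""Domain types, VCF/popmap I/O, and locus-retention filtering.

Genotypes are stored as alt-allele dosage (0, 1, 2) with ``-1`` marking a
missing call.  All allele-level statistics downstream assume diploidy and are
computed from these dosages.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MISSING",
    "LocusInfo",
    "GenotypeMatrix",
    "PopulationMap",
    "FilterConfig",
    "EmptyResultError",
    "read_vcf",
    "write_vcf",
    "read_popmap",
    "write_popmap",
    "write_structure",
    "apply_locus_filters",
]

logger = logging.getLogger(__name__)

#: Sentinel dosage for a missing genotype call.
MISSING: int = -1


@dataclass(frozen=True)
class LocusInfo:
    """Metadata for one biallelic SNP.

    ``tag_id`` identifies the RAD tag (or contig) the SNP came from and
    ``pos`` its position within that tag; the pair is unique per locus.
    """

    locus_id: str
    tag_id: str
    pos: int
    ref: str
    alt: str


@dataclass
class GenotypeMatrix:
    """Individuals-by-loci table of biallelic genotype dosages.

    ``calls`` has shape ``(n_samples, n_loci)`` with entries in
    ``{0, 1, 2, MISSING}``.
    """

    samples: list[str]
    loci: list[LocusInfo]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be 0, 1, 2 or missing (-1)")
        keys = {(l.tag_id, l.pos) for l in self.loci}
        if len(keys) != len(self.loci):
            raise ValueError("(tag_id, pos) pairs must be unique")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)

    def subset_loci(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = list(keep)
        return GenotypeMatrix(
            samples=list(self.samples),
            loci=[self.loci[i] for i in keep],
            calls=self.calls[:, keep].copy(),
        )

    def subset_samples(self, keep: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.samples.index(s) for s in keep]
        return GenotypeMatrix(
            samples=list(keep),
            loci=list(self.loci),
            calls=self.calls[idx, :].copy(),
        )


@dataclass
class PopulationMap:
    """Sample-to-population assignment plus optional site coordinates."""

    sample_to_pop: dict[str, str]
    coordinates: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.sample_to_pop.values():
            seen.setdefault(p, None)
        return list(seen)

    def samples_in(self, pop: str) -> list[str]:
        return [s for s, p in self.sample_to_pop.items() if p == pop]

    def validate_against(self, gm: GenotypeMatrix, strict: bool = True) -> None:
        """Check every genotyped sample is mapped (and, if *strict*, vice versa)."""
        unmapped = [s for s in gm.samples if s not in self.sample_to_pop]
        if unmapped:
            raise ValueError(f"samples missing from population map: {unmapped}")
        if strict:
            extra = [s for s in self.sample_to_pop if s not in gm.samples]
            if extra:
                raise ValueError(f"popmap samples absent from genotype data: {extra}")

    def sample_indices_by_pop(self, gm: GenotypeMatrix) -> dict[str, np.ndarray]:
        pos = {s: i for i, s in enumerate(gm.samples)}
        out: dict[str, list[int]] = {p: [] for p in self.populations}
        for s, p in self.sample_to_pop.items():
            if s in pos:
                out[p].append(pos[s])
        return {p: np.asarray(v, dtype=int) for p, v in out.items() if v}


@dataclass(frozen=True)
class FilterConfig:
    """Locus-retention rules.

    ``min_populations`` is the "present in at least this many populations"
    rule; ``min_fraction_individuals`` is the per-population genotyping-rate
    rule; a population only counts as "present" when that rate is met
    (inclusive ``>=`` at both thresholds).
    """

    min_populations: int = 8
    min_fraction_individuals: float = 0.8
    one_snp_per_tag: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.min_fraction_individuals <= 1.0):
            raise ValueError("min_fraction_individuals must be in (0, 1]")
        if self.min_populations < 1:
            raise ValueError("min_populations must be >= 1")


class EmptyResultError(RuntimeError):
    """Raised when a filter leaves zero loci."""


# ---------------------------------------------------------------------------
# VCF I/O


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Load biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Multiallelic and non-SNP records are skipped; the skip count is logged.
    ``./.`` genotypes become :data:`MISSING`.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    loci: list[LocusInfo] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    for var in vcf:
        alts = var.ALT
        if len(alts) != 1 or len(var.REF) != 1 or len(alts[0]) != 1:
            n_skipped += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(var.gt_types)
        dose = np.where(gt == 0, 0, np.where(gt == 1, 1, np.where(gt == 3, 2, MISSING)))
        locus_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        loci.append(
            LocusInfo(
                locus_id=locus_id,
                tag_id=var.CHROM,
                pos=var.POS,
                ref=var.REF,
                alt=alts[0],
            )
        )
        rows.append(dose.astype(np.int8))
    vcf.close()
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)
    if not loci:
        raise ValueError(f"no biallelic SNP records in {path}")
    calls = np.stack(rows, axis=1) if rows else np.empty((len(samples), 0), np.int8)
    return GenotypeMatrix(samples=samples, loci=loci, calls=calls)


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | Path, meta: Mapping[str, str] | None = None) -> None:
    """Write the matrix as an uncompressed VCF v4.2 file."""
    path = Path(path)
    tags: dict[str, None] = {}
    for l in gm.loci:
        tags.setdefault(l.tag_id, None)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=edgefront\n")
        for k, v in (meta or {}).items():
            fh.write(f"##edgefront_{k}={v}\n")
        for t in tags:
            fh.write(f"##contig=<ID={t}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for j, l in enumerate(gm.loci):
            gts = "\t".join(_GT_STR[int(d)] for d in gm.calls[:, j])
            fh.write(f"{l.tag_id}\t{l.pos}\t{l.locus_id}\t{l.ref}\t{l.alt}\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Population map I/O


def read_popmap(path: str | Path) -> PopulationMap:
    """Read a sample<TAB>population[<TAB>lat<TAB>lon] TSV."""
    path = Path(path)
    sample_to_pop: dict[str, str] = {}
    coords: dict[str, tuple[float, float]] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed popmap line: {line!r}")
            sample, pop = parts[0], parts[1]
            if sample in sample_to_pop:
                raise ValueError(f"duplicate sample in popmap: {sample}")
            sample_to_pop[sample] = pop
            if len(parts) >= 4:
                coords[pop] = (float(parts[2]), float(parts[3]))
    if not sample_to_pop:
        raise ValueError(f"empty popmap: {path}")
    return PopulationMap(sample_to_pop=sample_to_pop, coordinates=coords)


def write_popmap(pm: PopulationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s, p in pm.sample_to_pop.items():
            if p in pm.coordinates:
                lat, lon = pm.coordinates[p]
                fh.write(f"{s}\t{p}\t{lat}\t{lon}\n")
            else:
                fh.write(f"{s}\t{p}\n")


def write_structure(gm: GenotypeMatrix, pm: PopulationMap, path: str | Path) -> None:
    """STRUCTURE-format export: two rows per individual, -9 for missing.

    Alleles are coded 0 (ref) / 1 (alt).
    """
    pops = {p: i + 1 for i, p in enumerate(pm.populations)}
    with open(path, "w") as fh:
        for i, s in enumerate(gm.samples):
            popnum = pops[pm.sample_to_pop[s]]
            row = gm.calls[i]
            first = ["-9" if d == MISSING else ("1" if d == 2 else "0") for d in row]
            second = ["-9" if d == MISSING else ("1" if d >= 1 else "0") for d in row]
            fh.write("\t".join([s, str(popnum)] + first) + "\n")
            fh.write("\t".join([s, str(popnum)] + second) + "\n")


# ---------------------------------------------------------------------------
# Locus filters


def _presence_by_pop(
    gm: GenotypeMatrix, pm: PopulationMap, min_fraction: float
) -> np.ndarray:
    """Boolean (n_pops, n_loci) array: genotyping rate >= min_fraction."""
    idx = pm.sample_indices_by_pop(gm)
    rows = []
    for pop in pm.populations:
        members = idx.get(pop)
        if members is None or len(members) == 0:
            rows.append(np.zeros(gm.n_loci, dtype=bool))
            continue
        genotyped = (gm.calls[members, :] != MISSING).sum(axis=0)
        frac = genotyped / len(members)
        # nudge for float representation of e.g. 0.8 at exact boundaries
        rows.append(frac >= min_fraction - 1e-12)
    return np.stack(rows, axis=0)


def apply_locus_filters(
    gm: GenotypeMatrix, pm: PopulationMap, cfg: FilterConfig
) -> GenotypeMatrix:
    """Retain loci meeting the population-presence and genotyping-rate rules.

    A locus is kept iff the number of populations where the fraction of
    genotyped individuals is >= ``min_fraction_individuals`` is at least
    ``min_populations``.  With ``one_snp_per_tag``, one SNP per tag is then
    chosen uniformly at random from a single seeded stream iterating tags in
    sorted order (platform-stable).
    """
    pm.validate_against(gm, strict=False)
    if cfg.min_populations > len(pm.populations):
        raise ValueError(
            f"min_populations={cfg.min_populations} exceeds the "
            f"{len(pm.populations)} populations in the map"
        )
    present = _presence_by_pop(gm, pm, cfg.min_fraction_individuals)
    n_present = present.sum(axis=0)
    keep_mask = n_present >= cfg.min_populations
    keep = np.flatnonzero(keep_mask)

    if cfg.one_snp_per_tag and len(keep) > 0:
        by_tag: dict[str, list[int]] = {}
        for i in keep:
            by_tag.setdefault(gm.loci[i].tag_id, []).append(int(i))
        rng = random.Random(cfg.seed)
        chosen = [rng.choice(by_tag[t]) for t in sorted(by_tag)]
        keep = np.asarray(sorted(chosen), dtype=int)

    if len(keep) == 0:
        raise EmptyResultError("no loci survive the configured filters")
    logger.info("apply_locus_filters: %d of %d loci retained", len(keep), gm.n_loci)
    return gm.subset_loci(keep)
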