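"""End-to-end orchestration: filter -> summary statistics -> structure ->
distances/regressions -> psi -> locus classifiers -> outlier scans, written
as a directory of TSV/JSON outputs with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .core_data import FilterConfig, GenotypeMatrix, PopulationMap, apply_locus_filters, read_popmap, read_vcf
from .expansion_geo import DistanceTable, OceanGrid, distance_table, diversity_distance_regression, psi_matrix_and_ranking
from .locus_filters import flip_flop_loci, frequency_profiles, minmax_diff_loci, overlap_table
from .outlier_scan import build_null_envelope, empirical_rank_bins, env_assoc_scores, fst_outliers
from .structure_analysis import fst_matrix, pca
from .sumstats import population_summary

__all__ = ["PipelineConfig", "StageError", "run_pipeline"]

EXIT_OK, EXIT_CONFIG_ERROR, EXIT_DATA_ERROR = 0, 2, 3


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    vcf: str
    popmap: str
    out_dir: str
    filter: FilterConfig = field(default_factory=FilterConfig)
    origin_site: str | None = None
    grid: OceanGrid | None = None
    waypoints_for: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    psi_subsample_n: int = 10
    fst_permutations: int = 199
    outlier_n_sims: int = 100_000
    outlier_fdr: float = 0.01
    env_top_frac: float = 0.05
    minmax_thresholds: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8, 0.9)
    seed: int = 0


def _write_tsv(path: Path, header: list[str], rows, comments: list[str] = ()) -> None:
    with open(path, "w") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis; returns a manifest dict (also written to
    ``manifest.json`` in the output directory)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "edgefront_version": __version__,
        "python": sys.version.split()[0],
        "seed": cfg.seed,
        "stages": [],
    }

    def stage(name: str):
        manifest["stages"].append(name)
        return name

    try:
        stage("load")
        gm = read_vcf(cfg.vcf)
        pm = read_popmap(cfg.popmap)
        pm.validate_against(gm, strict=False)
    except Exception as exc:  # noqa: BLE001
        raise StageError("load", exc) from exc

    try:
        stage("filter")
        gm = apply_locus_filters(gm, pm, cfg.filter)
    except Exception as exc:
        raise StageError("filter", exc) from exc

    seed_note = f"seed={cfg.seed}"
    try:
        stage("sumstats")
        summaries = [population_summary(gm, pm, p) for p in pm.populations]
        _write_tsv(
            out / "population_summary.tsv",
            ["pop", "n", "mean_n_genotyped", "private", "major_freq", "obs_het",
             "exp_het", "pi", "f_is", "allelic_richness"],
            [
                (s.population, s.n_individuals, f"{s.mean_n_genotyped:.4f}",
                 s.private_alleles, f"{s.mean_major_freq:.4f}", f"{s.mean_h_obs:.4f}",
                 f"{s.mean_h_exp:.4f}", f"{s.mean_pi:.4f}", f"{s.mean_f_is:.4f}",
                 f"{s.allelic_richness:.4f}")
                for s in summaries
            ],
            comments=[seed_note],
        )
    except Exception as exc:
        raise StageError("sumstats", exc) from exc

    try:
        stage("fst")
        fsts = fst_matrix(gm, pm, n_perm=cfg.fst_permutations, seed=cfg.seed)
        pops = pm.populations
        rows = []
        for a in pops:
            row = [a]
            for b in pops:
                if a == b:
                    row.append("0")
                else:
                    r = fsts[(a, b)]
                    star = "*" if r.significant else ""
                    row.append(f"{r.theta:.6f}{star}")
            rows.append(row)
        _write_tsv(out / "fst_matrix.tsv", ["pop"] + pops, rows, comments=[seed_note])

        stage("pca")
        pr = pca(gm)
        _write_tsv(
            out / "pca_coordinates.tsv",
            ["sample"] + [f"pc{i+1}" for i in range(pr.coordinates.shape[1])],
            [
                [s] + [f"{v:.6f}" for v in pr.coordinates[i]]
                for i, s in enumerate(pr.samples)
            ],
        )
        _write_tsv(
            out / "pca_eigen.tsv",
            ["axis", "percent_variance"],
            [(i + 1, f"{v:.4f}") for i, v in enumerate(pr.percent_variance[:10])],
        )
    except Exception as exc:
        raise StageError("structure", exc) from exc

    distances: DistanceTable | None = None
    if cfg.origin_site is not None and cfg.grid is not None:
        try:
            stage("distances")
            distances = distance_table(
                cfg.grid, pm.coordinates, cfg.origin_site, waypoints_for=cfg.waypoints_for
            )
            _write_tsv(
                out / "distances.tsv",
                ["site", "distance_km"],
                [(s, f"{d:.3f}") for s, d in distances.distances.items()],
                comments=[f"origin={cfg.origin_site}", f"method={distances.method}"],
            )

            stage("regressions")
            reg_rows = []
            for stat_name, getter in (
                ("obs_het", lambda s: s.mean_h_obs),
                ("exp_het", lambda s: s.mean_h_exp),
                ("allelic_richness", lambda s: s.allelic_richness),
                ("major_freq", lambda s: s.mean_major_freq),
            ):
                vals = {s.population: getter(s) for s in summaries}
                r = diversity_distance_regression(vals, distances)
                reg_rows.append(
                    (stat_name, f"{r.slope:.6g}", f"{r.intercept:.6g}",
                     f"{r.r_squared:.4f}", f"{r.p_value:.4g}", r.n)
                )
            _write_tsv(
                out / "regressions.tsv",
                ["statistic", "slope", "intercept", "r_squared", "p_value", "n"],
                reg_rows,
            )
        except Exception as exc:
            raise StageError("distances", exc) from exc
    else:
        manifest["skipped"] = manifest.get("skipped", []) + ["distances", "regressions"]

    try:
        stage("psi")
        psi = psi_matrix_and_ranking(gm, pm, subsample_n=cfg.psi_subsample_n, seed=cfg.seed)
        _write_tsv(
            out / "psi_matrix.tsv",
            ["pop"] + psi.populations,
            [
                [p] + [f"{psi.values[i, j]:.6f}" for j in range(len(psi.populations))]
                for i, p in enumerate(psi.populations)
            ],
            comments=[seed_note, f"subsample_n={psi.subsample_n}",
                      "ranking=" + ",".join(psi.ranking)],
        )
    except Exception as exc:
        raise StageError("psi", exc) from exc

    try:
        stage("locus_filters")
        profiles = frequency_profiles(gm, pm)
        sets: dict[str, set[str]] = {"flip_flop": flip_flop_loci(profiles)}
        for t in cfg.minmax_thresholds:
            sets[f"diff_{t}"] = minmax_diff_loci(profiles, t)
        for name, ids in sets.items():
            _write_tsv(out / f"loci_{name}.tsv", ["locus_id"], [(x,) for x in sorted(ids)])
    except Exception as exc:
        raise StageError("locus_filters", exc) from exc

    try:
        stage("outliers_fst")
        env = build_null_envelope(gm, pm, n_sims=cfg.outlier_n_sims, seed=cfg.seed)
        recs = fst_outliers(gm, pm, env, fdr=cfg.outlier_fdr)
        _write_tsv(
            out / "fst_outliers.tsv",
            ["locus_id", "theta", "he", "p_value", "above_envelope", "flagged"],
            [
                (r["locus_id"], f"{r['theta']:.6f}", f"{r['he']:.6f}",
                 f"{r['p_value']:.6g}", r["above_envelope"], r["flagged"])
                for r in recs
            ],
            comments=[seed_note, f"target_fst={env.target_fst:.6g}", f"n_sims={env.n_sims}"],
        )
        sets["fst_outliers"] = {r["locus_id"] for r in recs if r["flagged"]}

        if distances is not None:
            stage("outliers_env")
            scores = env_assoc_scores(gm, pm, distances)
            selected = empirical_rank_bins(scores, top_frac=cfg.env_top_frac, seed=cfg.seed)
            _write_tsv(
                out / "env_scores.tsv",
                ["locus_id", "score", "major_freq"],
                [(s.locus_id, f"{s.score:.6f}", f"{s.major_freq:.6f}") for s in scores],
                comments=[seed_note, f"top_frac={cfg.env_top_frac}"],
            )
            sets["env_selected"] = set(selected)
        else:
            manifest["skipped"] = manifest.get("skipped", []) + ["outliers_env"]

        stage("overlap")
        table = overlap_table(sets)
        names = list(table["sizes"])
        _write_tsv(
            out / "overlap_table.tsv",
            ["set"] + names,
            [
                [a] + [
                    str(table["sizes"][a]) if a == b else str(table["intersection"][(a, b)])
                    for b in names
                ]
                for a in names
            ],
        )
    except Exception as exc:
        raise StageError("outliers", exc) from exc

    cfg_repr = json.dumps(
        {k: v for k, v in asdict(cfg).items() if k != "grid"}, sort_keys=True, default=str
    )
    manifest["config"] = json.loads(cfg_repr)
    manifest["config_hash"] = hashlib.sha256(cfg_repr.encode()).hexdigest()[:16]
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
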