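import numpy as np
import pytest

from edgefront.outlier_scan import (
    AssocScore,
    _simulate_null_loci,
    build_null_envelope,
    empirical_rank_bins,
    env_assoc_scores,
    fst_outliers,
)
from edgefront.simdata import simulate_null

from conftest import make_gm, make_pm


class TestNullSimulation:
    def test_f_to_zero_limit(self):
        rng = np.random.default_rng(0)
        anc = np.full(200, 0.3)
        theta, he = _simulate_null_loci(rng, anc, np.array([50, 50, 50]), 1e-6, 200)
        assert np.abs(theta).mean() < 0.02

    def test_balding_nichols_moments(self):
        rng = np.random.default_rng(1)
        p0, f = 0.3, 0.1
        draws = rng.beta(p0 * (1 - f) / f, (1 - p0) * (1 - f) / f, size=200_000)
        assert draws.mean() == pytest.approx(p0, abs=0.005)
        assert draws.var() == pytest.approx(p0 * (1 - p0) * f, rel=0.05)

    def test_envelope_excludes_about_five_percent(self):
        # calibration: envelope from one null run, fresh null loci scored
        gm, pm, _ = simulate_null(n_pops=6, n_loci=400, samples_per_pop=12,
                                  target_fst=0.05, seed=10)
        env = build_null_envelope(gm, pm, target_fst=0.05, n_sims=30_000,
                                  conf=0.95, seed=11)
        rng = np.random.default_rng(12)
        anc = np.random.default_rng(13).uniform(0.05, 0.95, 10_000)
        theta, he = _simulate_null_loci(rng, anc, np.full(6, 12), 0.05, 10_000)
        bins = env.bin_of(he)
        outside = (theta > env.upper[bins]) | (theta < env.lower[bins])
        assert 0.02 < outside.mean() < 0.09


class TestFstOutliers:
    def test_monomorphic_never_flagged(self):
        gm, pm, _ = simulate_null(n_pops=4, n_loci=50, samples_per_pop=10,
                                  target_fst=0.02, seed=3)
        gm.calls[:, 0] = 0  # force monomorphic
        env = build_null_envelope(gm, pm, target_fst=0.02, n_sims=5_000, seed=4)
        recs = fst_outliers(gm, pm, env)
        assert all(r["locus_id"] != "L000000" for r in recs)

    def test_null_calibration_small(self):
        # reduced-scale version of the acceptance criterion
        rates = []
        for rep in range(5):
            gm, pm, _ = simulate_null(n_pops=9, n_loci=2_000, samples_per_pop=12,
                                      target_fst=0.01, seed=rep + 20)
            env = build_null_envelope(gm, pm, n_sims=10_000, seed=rep)
            recs = fst_outliers(gm, pm, env, fdr=0.01)
            rates.append(np.mean([r["flagged"] for r in recs]))
        assert np.mean(rates) <= 0.02

    def test_planted_outlier_flagged(self):
        gm, pm, _ = simulate_null(n_pops=6, n_loci=500, samples_per_pop=15,
                                  target_fst=0.01, seed=30)
        # plant a locus fixed for alternate alleles in alternating pops
        idx = pm.sample_indices_by_pop(gm)
        for k, pop in enumerate(pm.populations):
            gm.calls[idx[pop], 0] = 2 if k % 2 else 0
        env = build_null_envelope(gm, pm, target_fst=0.01, n_sims=20_000, seed=31)
        recs = {r["locus_id"]: r for r in fst_outliers(gm, pm, env, fdr=0.01)}
        assert recs["L000000"]["flagged"]

    def test_target_fst_validation(self):
        gm, pm, _ = simulate_null(n_pops=3, n_loci=20, samples_per_pop=5, seed=1)
        with pytest.raises(ValueError):
            build_null_envelope(gm, pm, target_fst=1.5, n_sims=100)


class TestEnvAssoc:
    def _pops_gm(self, freq_by_pop, n_per_pop=20, seed=0):
        """Deterministic genotypes realizing exact per-pop alt frequencies."""
        blocks = []
        assignments = {}
        s = 0
        for freqs in freq_by_pop:
            block = np.zeros((n_per_pop, len(freqs)), dtype=np.int8)
            for j, f in enumerate(freqs):
                n_alt = round(f * 2 * n_per_pop)
                col = []
                for _ in range(n_per_pop):
                    take = min(2, n_alt)
                    col.append(take)
                    n_alt -= take
                block[:, j] = col
            blocks.append(block)
        for k in range(len(freq_by_pop)):
            for i in range(n_per_pop):
                assignments[f"s{s}"] = f"P{k}"
                s += 1
        return make_gm(np.vstack(blocks).tolist()), make_pm(assignments)

    def test_monotone_identity_covariance_scores_one(self):
        freqs = [[0.1], [0.2], [0.3], [0.4], [0.5]]
        gm, pm = self._pops_gm(freqs)
        grad = {f"P{k}": float(k) for k in range(5)}
        scores = env_assoc_scores(gm, pm, grad, covariance=np.eye(5))
        assert scores[0].score == pytest.approx(1.0)

    def test_constant_frequencies_score_zero(self):
        gm, pm = self._pops_gm([[0.3], [0.3], [0.3], [0.3]])
        grad = {f"P{k}": float(k) for k in range(4)}
        scores = env_assoc_scores(gm, pm, grad, covariance=np.eye(4))
        assert scores[0].score == 0.0

    def test_gradient_permutation_exchangeability(self):
        rng = np.random.default_rng(7)
        gm, pm, _ = simulate_null(n_pops=6, n_loci=150, samples_per_pop=12,
                                  target_fst=0.05, seed=70)
        grad0 = {p: float(i) for i, p in enumerate(pm.populations)}
        base = np.mean([s.score for s in env_assoc_scores(gm, pm, grad0)])
        perms = []
        for rep in range(20):
            vals = rng.permutation(6).astype(float)
            grad = {p: vals[i] for i, p in enumerate(pm.populations)}
            perms.append(np.mean([s.score for s in env_assoc_scores(gm, pm, grad)]))
        perms = np.asarray(perms)
        # observed mean score is not an outlier among permuted gradients
        z = (base - perms.mean()) / perms.std(ddof=1)
        assert abs(z) < 3


class TestEmpiricalRankBins:
    def _scores(self, n, freq, seed=0):
        rng = np.random.default_rng(seed)
        return [
            AssocScore(f"L{i}", float(rng.random()), freq) for i in range(n)
        ]

    def test_bin_of_100_top5(self):
        scores = self._scores(100, 0.55)
        # every locus lands in a 0.5/0.4 decimal bin depending on the coin
        chosen = empirical_rank_bins(scores, top_frac=0.05, seed=1)
        rng = np.random.default_rng(1)
        use_p = rng.random(100) < 0.5
        by_bin = {}
        for i, s in enumerate(scores):
            b = int((s.major_freq if use_p[i] else 1 - s.major_freq) * 10)
            by_bin.setdefault(b, []).append(s)
        expect = []
        for b, members in by_bin.items():
            members.sort(key=lambda s: (-s.score, s.locus_id))
            k = int(0.05 * len(members))
            expect += [m.locus_id for m in members[:k]]
        assert sorted(chosen) == sorted(expect)

    def test_single_bin_exact_count(self):
        scores = self._scores(100, 1.0)  # p=1 and q=0 share the outer bins
        rng = np.random.default_rng(3)
        use_p = rng.random(100) < 0.5
        chosen = empirical_rank_bins(scores, top_frac=0.05, seed=3)
        n_p = int(use_p.sum())
        # each of the two bins contributes floor(5% of its size)
        assert len(chosen) == int(0.05 * n_p) + int(0.05 * (100 - n_p))

    def test_small_bin_yields_nothing(self):
        scores = self._scores(10, 1.0, seed=4)
        rng = np.random.default_rng(5)
        # minimum quantile in any bin of <= 10 is >= 0.1 > 0.05
        assert empirical_rank_bins(scores, top_frac=0.05, seed=5) == []

    def test_seed_reproducibility(self):
        scores = self._scores(200, 0.72, seed=6)
        a = empirical_rank_bins(scores, top_frac=0.1, seed=9)
        b = empirical_rank_bins(scores, top_frac=0.1, seed=9)
        assert a == b

    def test_monotone_transform_invariance(self):
        scores = self._scores(150, 0.65, seed=8)
        transformed = [
            AssocScore(s.locus_id, np.exp(3 * s.score), s.major_freq) for s in scores
        ]
        a = empirical_rank_bins(scores, top_frac=0.1, seed=2)
        b = empirical_rank_bins(transformed, top_frac=0.1, seed=2)
        assert a == b

    def test_dual_scan_overlap_on_expansion_data(self):
        # loci picked by both scans co-occur more than independent random
        # selection of equal-size sets would predict (hypergeometric test)
        from scipy.stats import hypergeom

        from edgefront.expansion_geo import DistanceTable
        from edgefront.simdata import ExpansionConfig, simulate_expansion

        overlaps, expected = [], []
        for seed in range(3):
            gm, pm, _ = simulate_expansion(ExpansionConfig(n_loci=3000, seed=seed + 60))
            env = build_null_envelope(gm, pm, n_sims=10_000, seed=seed)
            fst_flagged = {
                r["locus_id"]
                for r in fst_outliers(gm, pm, env, fdr=0.2)
                if r["above_envelope"]
            }
            grad = DistanceTable(
                origin="D00",
                distances={p: float(i) for i, p in enumerate(pm.populations)},
            )
            scores = env_assoc_scores(gm, pm, grad)
            env_sel = set(empirical_rank_bins(scores, top_frac=0.1, seed=seed))
            overlaps.append(len(fst_flagged & env_sel))
            expected.append(len(fst_flagged) * len(env_sel) / gm.n_loci)
        assert sum(overlaps) > sum(expected)
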