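"""Unfit fractions, G-test, robustness assay, PCA clustering, smoothing."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

import heteropatry as hp
from heteropatry.simulate import Population

SUIT = np.array([True, False, True, False])


class TestUnfitFraction:
    def test_preferring_an_unsuitable_niche_is_unfit(self):
        assert hp.unfit_fraction(np.array([[1, 1, 0, 0]]), SUIT) == 1.0

    def test_suitable_only_preferences_are_fit(self):
        assert hp.unfit_fraction(np.array([[1, 0, 1, 0]]), SUIT) == 0.0

    def test_direct_count(self):
        classes = np.array([[1, 0, 0, 0], [0, 1, 0, 0]])
        assert hp.unfit_fraction(classes, SUIT) == 0.5

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            hp.unfit_fraction(np.empty((0, 4)), SUIT)


class TestMlChi2:
    def test_independence_gives_zero(self):
        g, p = hp.ml_chi2(np.array([[50, 50], [50, 50]]))
        assert g == 0.0
        assert p == pytest.approx(1.0)

    def test_unfit_contrast_table(self):
        """Counts reconstructed from 14.0% of 2226 vs 11.6% of 2246."""
        g, p = hp.ml_chi2(np.array([[312, 2226 - 312], [261, 2246 - 261]]))
        assert g == pytest.approx(5.9, abs=0.4)
        assert p < 0.05

    def test_matches_scipy_likelihood_ratio(self, rng):
        for _ in range(25):
            table = rng.integers(1, 500, size=(2, 2))
            g, p = hp.ml_chi2(table)
            ref = chi2_contingency(table, correction=False, lambda_="log-likelihood")
            assert g == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_g_scales_linearly_with_total(self):
        table = np.array([[30, 70], [50, 50]])
        g1, _ = hp.ml_chi2(table)
        g2, _ = hp.ml_chi2(2 * table)
        assert g2 == pytest.approx(2 * g1)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            hp.ml_chi2(np.array([[0, 0], [10, 20]]))


class TestRobustnessTest:
    def test_sample_size_is_p_times_p_minus_1(self, env, rng):
        pool = Population.from_genomes(hp.fixture_genomes("specialist1", 5))
        res = hp.robustness_test(pool, env, hp.MutationRates(), rng)
        assert res.pool_size == 5
        assert res.n_mutants == 20

    def test_minimum_pool(self, env, rng):
        pool = Population.from_genomes(hp.fixture_genomes("specialist1", 2))
        assert hp.robustness_test(pool, env, hp.MutationRates(), rng).n_mutants == 2
        single = Population.from_genomes(hp.fixture_genomes("specialist1", 1))
        with pytest.raises(ValueError):
            hp.robustness_test(single, env, hp.MutationRates(), rng)

    def test_all_niches_suitable_means_no_unfit(self, rng):
        """When every niche is suitable no mutant can become unfit, and the
        increase is 0% (0 -> 0)."""
        benign = hp.Environment(resource_values=np.array([250.0] * 4))
        pool = Population.from_genomes(hp.fixture_genomes("generalist", 10))
        res = hp.robustness_test(pool, benign, hp.MutationRates(), rng)
        assert res.baseline_unfit_count == 0
        assert res.mutant_unfit_pct == 0.0
        assert res.increase_pct == 0.0

    def test_matches_exhaustive_scan(self, env, rng):
        """The resampled mutant unfit rate agrees with an exhaustive scan
        over (individual, haplotype, locus) with many perturbation draws."""
        genomes = hp.fixture_genomes("specialist1", 12, rng=rng, jitter=0.4)
        pool = Population.from_genomes(genomes)
        rates = hp.MutationRates()
        res = hp.robustness_test(pool, env, rates, rng)

        oracle_rng = np.random.default_rng(999)
        sig = env.signal_set.signals
        hits = trials = 0
        for g in genomes:
            for hap in range(2):
                for locus in range(13):
                    for delta in oracle_rng.uniform(-10, 10, 40):
                        pref = g.pref.copy()
                        pref[hap, locus] = np.clip(pref[hap, locus] + delta, -20, 20)
                        psi = hp.response_array(hp.Genome(pref), hp.SignalSet(sig))
                        cls = hp.classify_phenotype(psi)
                        hits += bool((cls[~env.suitability] == 1).any())
                        trials += 1
        oracle_pct = 100.0 * hits / trials
        # K = 132 resamples: allow a few Monte-Carlo standard errors
        se = 100.0 * np.sqrt(oracle_pct / 100 * (1 - oracle_pct / 100) / res.n_mutants)
        assert res.mutant_unfit_pct == pytest.approx(oracle_pct, abs=4 * se + 1.0)


class TestPcaCluster:
    def test_recovers_two_synthetic_clouds(self, rng):
        a = rng.normal(0, 0.3, (40, 13)) + 5
        b = rng.normal(0, 0.3, (40, 13)) - 5
        scores, labels = hp.pca_cluster(np.vstack([a, b]), n_clusters=2)
        assert scores.shape == (80, 2)
        assert len(set(labels[:40])) == 1 and len(set(labels[40:])) == 1
        assert labels[0] != labels[-1]

    def test_identical_rows_collapse_to_one_cluster(self):
        X = np.tile(np.arange(13.0), (10, 1))
        scores, labels = hp.pca_cluster(X, n_clusters=3)
        assert len(set(labels)) == 1

    def test_genotype_rows_split_ab_and_ba(self, rng):
        """Genotype rows in haplotype storage order produce four clusters:
        AA, BB and the mirror pair AB / BA."""
        hap_a = np.full(13, 6.0)
        hap_b = np.full(13, -6.0)
        hap_b[::2] *= -1  # make B not a mirror image of A
        rows, truth = [], []
        for name, (h1, h2) in {
            "AA": (hap_a, hap_a),
            "BB": (hap_b, hap_b),
            "AB": (hap_a, hap_b),
            "BA": (hap_b, hap_a),
        }.items():
            for _ in range(15):
                noise = rng.normal(0, 0.15, 26)
                rows.append(np.concatenate([h1, h2]) + noise)
                truth.append(name)
        scores, labels = hp.pca_cluster(np.asarray(rows), n_clusters=4, n_components=3)
        truth = np.asarray(truth)
        assert len(set(labels)) == 4
        for name in ("AA", "BB", "AB", "BA"):
            group = labels[truth == name]
            assert len(set(group)) == 1  # each genotype in its own cluster
        assert len({labels[truth == n][0] for n in ("AA", "BB", "AB", "BA")}) == 4

    def test_silhouette_selection_finds_two(self, rng):
        a = rng.normal(0, 0.2, (30, 13)) + 4
        b = rng.normal(0, 0.2, (30, 13)) - 4
        _, labels = hp.pca_cluster(np.vstack([a, b]))
        assert len(set(labels)) == 2

    def test_more_clusters_than_rows_rejected(self):
        with pytest.raises(ValueError):
            hp.pca_cluster(np.zeros((3, 13)), n_clusters=5)


class TestSmoothCounts:
    def test_constant_series_is_unchanged(self):
        s = pd.Series(np.full(400, 100.0))
        out = hp.smooth_counts(s, window=80, stride=20, threshold=80)
        assert np.allclose(out.iloc[:, 0].dropna(), 100.0)

    def test_series_below_threshold_dropped(self):
        df = pd.DataFrame({"low": np.full(200, 79.0), "high": np.full(200, 81.0)})
        out = hp.smooth_counts(df, window=10, stride=5, threshold=80)
        assert list(out.columns) == ["high"]

    def test_linear_ramp_gives_midpoint(self):
        s = pd.Series(np.arange(101, dtype=float))
        out = hp.smooth_counts(s, window=5, stride=1, threshold=0)
        # centred odd window on a ramp returns the centre value
        for idx, val in out.iloc[:, 0].dropna().items():
            assert val == pytest.approx(float(idx))

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError):
            hp.smooth_counts(pd.Series(np.ones(10)), window=20)


class TestPolymorphismSummary:
    @staticmethod
    def _population(n_aa, n_ab, n_bb, hap_a, hap_b, rng, noise=0.05):
        prefs = []
        for _ in range(n_aa):
            prefs.append(np.stack([hap_a, hap_a]))
        for _ in range(n_ab):
            prefs.append(np.stack([hap_a, hap_b]))
        for _ in range(n_bb):
            prefs.append(np.stack([hap_b, hap_b]))
        pref = np.asarray(prefs) + rng.normal(0, noise, (len(prefs), 2, 13))
        return Population(pref, np.zeros((len(prefs), 2), dtype=np.int8))

    def test_type_polymorphism_detected(self, env, rng):
        """A saturated specialist haplotype over a null haplotype expresses
        the specialist phenotype, so AB matches AA and differs from BB."""
        hap_a = hp.fixture_genomes("specialist1", 1)[0].pref[0]
        hap_b = np.zeros(13)  # null haplotype: BB responds 0.5 -> [1,1,1,1]
        pop = self._population(35, 40, 25, hap_a, hap_b, rng, noise=0.0)
        summ = hp.polymorphism_summary(pop, env)
        assert summ.outcome == "type_polymorphism"
        assert summ.modal_classes["AA"] == summ.modal_classes["AB"] == (1, 0, 0, 0)
        assert summ.modal_classes["BB"] == (1, 1, 1, 1)

    def test_genotype_counts_recovered(self, env, rng):
        hap_a = hp.fixture_genomes("specialist1", 1)[0].pref[0]
        hap_b = hp.fixture_genomes("specialist3", 1)[0].pref[0]
        pop = self._population(25, 35, 20, hap_a, hap_b, rng)
        labels, sil = hp.assign_genotypes(pop)
        assert sil > 0.8
        counts = {g: int((labels == g).sum()) for g in ("AA", "AB", "BB")}
        # cluster identity of A vs B is arbitrary; compare as multisets
        assert counts["AB"] == 35
        assert sorted([counts["AA"], counts["BB"]]) == [20, 25]

    def test_monomorphic_population(self, env, rng):
        hap = hp.fixture_genomes("specialist1", 1)[0].pref[0]
        pop = self._population(50, 0, 0, hap, hap, rng)
        summ = hp.polymorphism_summary(pop, env)
        assert summ.outcome == "monomorphic"
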