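import itertools

import numpy as np
import pandas as pd
import pytest

from funorg.daa import (
    NullEnsemble,
    delta_histogram,
    delta_histogram_statistic,
    flag_anomalies,
    log_differential,
    permutation_null,
)
from funorg.discriminant import ma_direction

from conftest import make_composition


@pytest.fixture
def four_samples():
    table = make_composition(
        [[0.1, 0.2, 0.35, 0.4],
         [0.5, 0.45, 0.2, 0.3],
         [0.4, 0.35, 0.45, 0.3]]
    )
    labels = pd.Series(["H", "H", "U", "U"], index=table.sample_ids)
    return table, labels


class TestLogDifferential:
    def test_identical_groups_give_zero(self):
        table = make_composition([[0.3, 0.3], [0.7, 0.7]])
        labels = pd.Series(["H", "U"], index=table.sample_ids)
        profile = log_differential(table, labels)
        assert (profile.delta == 0).all()

    def test_decade_ratio_gives_delta_one(self):
        table = make_composition([[0.01, 0.1], [0.99, 0.9]])
        labels = pd.Series(["H", "U"], index=table.sample_ids)
        profile = log_differential(table, labels)
        assert profile.delta["c0"] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(50))
    def test_label_swap_negates_delta(self, seed):
        rng = np.random.default_rng(seed)
        table = make_composition(rng.random((8, 6)) + 0.01)
        labels = pd.Series(["H"] * 3 + ["U"] * 3, index=table.sample_ids)
        swapped = labels.map({"H": "U", "U": "H"})
        d1 = log_differential(table, labels).delta
        d2 = log_differential(table, swapped).delta
        np.testing.assert_allclose(d1, -d2, atol=1e-12)

    def test_zero_ma_components_excluded(self):
        table = make_composition([[0.0, 0.4], [1.0, 0.6]])
        labels = pd.Series(["H", "U"], index=table.sample_ids)
        profile = log_differential(table, labels)
        assert profile.excluded_ids == ["c0"]
        assert list(profile.delta.index) == ["c1"]


class TestDeltaHistogram:
    def test_all_zero_deltas_single_window(self):
        table = make_composition([[0.3, 0.3], [0.7, 0.7]])
        labels = pd.Series(["H", "U"], index=table.sample_ids)
        hist = delta_histogram(log_differential(table, labels))
        assert hist.window_centers.size == 1
        assert hist.counts[0] == 2

    def test_histogram_conserves_component_count(self, four_samples):
        table, labels = four_samples
        profile = log_differential(table, labels)
        hist = delta_histogram(profile, width=10.0, step=10.0)
        assert hist.counts.sum() == profile.delta.size


class TestPermutationNull:
    def test_single_realization_band_is_the_replicate(self, four_samples):
        table, labels = four_samples
        stat = lambda t, l: ma_direction(t, l).to_numpy()
        null = permutation_null(table, labels, stat, n_realizations=1, seed=3)
        np.testing.assert_array_equal(null.mean, null.replicates[0])
        assert (null.sigma_plus == 0).all()
        assert (null.sigma_minus == 0).all()

    def test_reproducible_under_fixed_seed(self, four_samples):
        table, labels = four_samples
        stat = lambda t, l: ma_direction(t, l).to_numpy()
        a = permutation_null(table, labels, stat, n_realizations=20, seed=9)
        b = permutation_null(table, labels, stat, n_realizations=20, seed=9)
        np.testing.assert_array_equal(a.replicates, b.replicates)

    def test_label_free_statistic_has_degenerate_band(self, four_samples):
        table, labels = four_samples
        stat = lambda t, l: t.values.mean(axis=1).to_numpy()
        null = permutation_null(table, labels, stat, n_realizations=25, seed=0)
        np.testing.assert_allclose(null.mean, stat(table, labels), atol=1e-15)
        np.testing.assert_allclose(null.sigma_plus, 0, atol=1e-12)

    def test_sampled_band_matches_exhaustive_enumeration(self, four_samples):
        """2H/2U has six label assignments; the sampled band must agree
        with the exact enumeration within Monte-Carlo error."""
        table, labels = four_samples
        stat = lambda t, l: ma_direction(t, l).to_numpy()
        values = []
        for h_pair in itertools.combinations(range(4), 2):
            lab = np.array(["U"] * 4)
            lab[list(h_pair)] = "H"
            values.append(stat(table, pd.Series(lab, index=labels.index)))
        values = np.array(values)
        exact_mean = values.mean(axis=0)
        exact_sd = values.std(axis=0)
        null = permutation_null(table, labels, stat, n_realizations=600, seed=11)
        mc_err = exact_sd / np.sqrt(600)
        assert (np.abs(null.mean - exact_mean) <= 3 * mc_err + 1e-15).all()


class TestFlags:
    def _null(self, mean, sp, sm):
        reps = np.tile(mean, (3, 1))
        return NullEnsemble(reps, np.asarray(mean, float), np.asarray(sp, float),
                            np.asarray(sm, float), 3)

    def test_observed_at_mean_is_inside(self):
        null = self._null([1.0, 2.0], [0.1, 0.1], [0.1, 0.1])
        assert list(flag_anomalies([1.0, 2.0], null)) == ["inside", "inside"]

    def test_two_sigma_point_flagged_above(self):
        null = self._null([0.0, 0.0], [0.5, 0.5], [0.5, 0.5])
        assert list(flag_anomalies([1.0, 0.0], null)) == ["above", "inside"]

    def test_below_band(self):
        null = self._null([0.0], [0.5], [0.2])
        assert list(flag_anomalies([-0.5], null)) == ["below"]

    def test_support_mismatch_rejected(self):
        null = self._null([0.0, 0.0], [1, 1], [1, 1])
        with pytest.raises(ValueError):
            flag_anomalies([0.0], null)


class TestSyntheticBehaviour:
    def test_planted_enrichment_inflates_right_tail(self):
        """Boosting signature taxa in U pushes enriched functions' delta
        right of the permutation band."""
        import funorg as f
        from funorg.synthetic import generate_study
        from conftest import tiny_params
        hits = 0
        n_seeds = 5
        for s in range(n_seeds):
            p = tiny_params(enriched_categories=frozenset("GP"),
                            depleted_categories=frozenset("DJO"),
                            effect_size=5.0, seed=s,
                            n_samples_H=12, n_samples_U=12)
            counts, gcn, ann, labels, _ = generate_study(p)
            td, _ = f.build_taxonomic_table(counts)
            fd = f.project(gcn, td)
            profile = log_differential(fd, labels)
            hist = delta_histogram(profile)
            stat = delta_histogram_statistic(hist.window_centers)
            null = permutation_null(fd, labels, stat, n_realizations=60,
                                    seed=100 + s)
            flags = flag_anomalies(hist.density, null)
            right = hist.window_centers > 0.2
            hits += (flags[right] == "above").any()
        assert hits >= n_seeds - 1

    def test_null_configuration_coverage(self):
        """Without a planted effect the observed histogram behaves like a
        null replicate: at least ~60% of windows inside the 1-sigma band."""
        import funorg as f
        from funorg.synthetic import generate_study, null_params
        fracs = []
        for s in range(4):
            p = null_params(n_taxa=60, n_functions=160, n_samples_H=10,
                            n_samples_U=10, reads_per_sample=30_000, seed=s)
            counts, gcn, ann, labels, _ = generate_study(p)
            td, _ = f.build_taxonomic_table(counts)
            fd = f.project(gcn, td)
            profile = log_differential(fd, labels)
            hist = delta_histogram(profile)
            stat = delta_histogram_statistic(hist.window_centers)
            null = permutation_null(fd, labels, stat, n_realizations=100,
                                    seed=200 + s)
            flags = flag_anomalies(hist.density, null)
            fracs.append((flags == "inside").mean())
        assert np.mean(fracs) >= 0.60
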