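import numpy as np
import pandas as pd
import pytest

from funorg.correlation import (
    CorrelationSummary,
    aggregate_categories,
    correlation_matrix,
    correlation_profile,
    eigenvalue_decay,
    hist2d_corr_abundance,
)
from funorg.gcn import CategoryAnnotation

from conftest import make_composition


def brute_force_pearson(values):
    """Textbook double-loop Pearson, independent of numpy.corrcoef."""
    p, n = values.shape
    out = np.empty((p, p))
    for i in range(p):
        for j in range(p):
            xi, xj = values[i], values[j]
            num = ((xi - xi.mean()) * (xj - xj.mean())).sum()
            den = np.sqrt(((xi - xi.mean()) ** 2).sum()
                          * ((xj - xj.mean()) ** 2).sum())
            out[i, j] = num / den
    return out


def frame(values, components=None):
    values = np.asarray(values, dtype=float)
    comp = components or [f"c{i}" for i in range(values.shape[0])]
    return pd.DataFrame(values, index=comp,
                        columns=[f"s{j}" for j in range(values.shape[1])])


class TestCorrelationMatrix:
    def test_matches_brute_force_oracle(self, rng):
        values = rng.random((6, 9))
        summary = correlation_matrix(frame(values), None)
        np.testing.assert_allclose(summary.corr, brute_force_pearson(values),
                                   atol=1e-12)

    def test_unit_diagonal_and_linearity_limits(self):
        base = np.array([1.0, 2.0, 4.0, 3.0])
        values = np.vstack([base, 2 * base, 10 - base])
        summary = correlation_matrix(frame(values), None)
        C = summary.corr.to_numpy()
        assert np.allclose(np.diag(C), 1.0)
        assert C[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert C[0, 2] == pytest.approx(-1.0, abs=1e-12)

    def test_zero_variance_components_dropped(self):
        values = np.array([[1.0, 2.0, 3.0], [0.5, 0.5, 0.5]])
        summary = correlation_matrix(frame(values), None)
        assert summary.dropped_ids == ["c1"]

    def test_group_selection(self, rng):
        table = make_composition(rng.random((5, 8)) + 0.01)
        labels = pd.Series(["H"] * 4 + ["U"] * 4, index=table.sample_ids)
        s_h = correlation_matrix(table, labels, "H")
        direct = brute_force_pearson(table.values.iloc[:, :4].to_numpy())
        keep = [table.component_ids.get_loc(i) for i in s_h.included_ids]
        np.testing.assert_allclose(s_h.corr, direct[np.ix_(keep, keep)],
                                   atol=1e-12)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            correlation_matrix(frame(rng.random((4, 2))), None)


class TestHist2D:
    def test_two_components_make_one_couple(self, rng):
        values = rng.random((2, 5))
        H, *_ , nexcl = hist2d_corr_abundance(correlation_matrix(frame(values), None))
        assert H.sum() + nexcl == 1

    def test_couple_count_conservation(self, rng):
        values = rng.random((7, 6))
        summary = correlation_matrix(frame(values), None)
        H, *_ , nexcl = hist2d_corr_abundance(summary)
        p = len(summary.included_ids)
        assert H.sum() + nexcl == p * (p - 1) // 2

    def test_planted_high_abundance_couples_more_correlated(self, rng):
        """High-mean components share a latent factor; their couples sit
        in the top couple-abundance decades with high |C|."""
        n = 40
        factor = rng.lognormal(0, 1, n)
        loud = 5.0 * (0.2 * rng.random((5, n)) + 0.8 * factor)
        quiet = 0.05 * rng.lognormal(0, 1, size=(20, n))
        summary = correlation_matrix(frame(np.vstack([loud, quiet])), None)
        C = summary.corr.to_numpy()
        A = summary.couple_abundance.to_numpy()
        iu = np.triu_indices(C.shape[0], 1)
        c, a = np.abs(C[iu]), np.log10(A[iu])
        top = c[a > np.quantile(a, 0.9)]
        bottom = c[a < np.quantile(a, 0.1)]
        assert top.mean() > bottom.mean()


class TestProfiles:
    def test_uniform_weights_match_even_profile(self):
        base = np.array([1.0, 2.0, 4.0, 3.0, 5.0])
        values = np.vstack([base + 0.1 * np.random.default_rng(0).random(5)
                            for _ in range(4)])
        summary = correlation_matrix(frame(values), None)
        summary.couple_abundance.iloc[:, :] = 1.0
        centers, even = correlation_profile(summary, "even")
        _, weighted = correlation_profile(summary, "weighted")
        np.testing.assert_allclose(even, weighted, atol=1e-12)

    def test_weighted_mass_ratio(self):
        C = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        A = np.array([[0.0, 10.0, 1.0], [10.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        summary = CorrelationSummary(
            corr=pd.DataFrame(C), couple_abundance=pd.DataFrame(A),
            included_ids=[0, 1, 2], dropped_ids=[], group="all",
            representation="custom",
        )
        centers, weighted = correlation_profile(summary, "weighted", bins=20)
        pos = weighted[centers > 0].sum()
        neg = weighted[centers < 0].sum()
        assert pos / neg == pytest.approx(10.0, rel=1e-9)

    def test_single_correlation_value_occupies_one_bin(self):
        base = np.array([1.0, 2.0, 3.0])
        values = np.vstack([base, 2 * base])
        summary = correlation_matrix(frame(values), None)
        centers, even = correlation_profile(summary, "even", bins=10)
        assert (even > 0).sum() == 1


class TestEigenDecay:
    def test_block_closed_form(self, rng):
        base = rng.random(6)
        indep = rng.random(6)
        values = np.vstack([base, 2 * base, indep])
        spec = eigenvalue_decay(frame(values), None, matrix_kind="correlation")
        lam = spec.eigenvalues
        # eigenvalues of [[1,1,r],[1,1,r],[r,r,1]] are {0, ...}; with the
        # independent row nearly orthogonal the top two are close to 2, 1
        assert lam[2] == pytest.approx(0.0, abs=1e-9)
        assert lam.sum() == pytest.approx(3.0, abs=1e-6)

    def test_exact_closed_form_with_orthogonal_third(self):
        # construct exact sample correlations: c2 = 2*c1, c3 uncorrelated
        c1 = np.array([1.0, -1.0, 1.0, -1.0])
        c3 = np.array([1.0, 1.0, -1.0, -1.0])
        values = np.vstack([c1, 2 * c1, c3])
        spec = eigenvalue_decay(frame(values), None, matrix_kind="correlation")
        np.testing.assert_allclose(spec.eigenvalues, [2.0, 1.0, 0.0], atol=1e-9)

    def test_trace_identity(self, rng):
        values = rng.random((8, 10))
        spec = eigenvalue_decay(frame(values), None, matrix_kind="correlation")
        assert spec.eigenvalues.sum() == pytest.approx(8.0, abs=1e-6)

    def test_covariance_matches_numpy(self, rng):
        values = rng.random((5, 7))
        spec = eigenvalue_decay(frame(values), None, matrix_kind="covariance")
        direct = np.sort(np.linalg.eigvalsh(np.cov(values)))[::-1]
        np.testing.assert_allclose(spec.eigenvalues, np.clip(direct, 0, None),
                                   atol=1e-9)

    def test_rank_bounded_by_samples(self, rng):
        values = rng.random((20, 5))
        spec = eigenvalue_decay(frame(values), None, matrix_kind="correlation")
        assert (spec.eigenvalues > 1e-8).sum() <= 4


def test_category_aggregation_preserves_closure(tiny_study):
    import funorg as f
    counts, gcn, ann, labels, _ = tiny_study
    td, _ = f.build_taxonomic_table(counts)
    fd = f.project(gcn, td)
    agg = aggregate_categories(fd, ann)
    np.testing.assert_allclose(agg.values.sum(axis=0), 1.0, atol=1e-9)
    assert agg.values.shape[0] == len(ann.alphabet)
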