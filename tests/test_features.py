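import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ssclvoice import (
    EmptySelectionError,
    RunConfig,
    UndefinedCorrelationError,
    build_and_select,
    family_correlations,
    fit_pca,
    mww_test,
    pearson,
    project,
    retained_components,
)
from ssclvoice.datamodel import FeatureTable

from conftest import null_spec, separated_spec
from ssclvoice import generate


# ---------------------------------------------------------------- pearson


class TestPearson:
    def test_identity_and_anticorrelation(self):
        assert pearson([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert pearson([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # cov((1,2,3),(1,2,4)) / (SD*SD) = 1.5 / (1 * sqrt(7/3)) = 0.981980...
        assert pearson([1, 2, 3], [1, 2, 4]) == pytest.approx(0.9819805060619659)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson([1, 1, 1], [1, 2, 3])

    @settings(derandomize=True, max_examples=50)
    @given(
        data=st.lists(st.floats(-50, 50), min_size=3, max_size=12),
        slope=st.floats(-5, 5).filter(lambda a: abs(a) > 1e-3),
        offset=st.floats(-10, 10),
    )
    def test_affine_equivariance(self, data, slope, offset):
        a = np.asarray(data)
        if np.std(a) < 1e-6:
            return
        rho = pearson(a, slope * a + offset)
        assert rho == pytest.approx(np.sign(slope), abs=1e-8)


class TestFamilyCorrelations:
    def test_jitter_strong_nonlinear_weak(self, default_table):
        by_family = {c.family: c for c in family_correlations(default_table)}
        assert by_family["jitter"].strong_flag
        assert not by_family["nonlinear"].strong_flag
        for c in by_family.values():
            np.testing.assert_allclose(c.matrix, c.matrix.T, atol=1e-12)
            np.testing.assert_allclose(np.diag(c.matrix), 1.0)
            assert np.all(np.abs(c.matrix) <= 1 + 1e-12)

    def test_single_parameter_family(self):
        t = FeatureTable(
            values=np.array([[1.0], [2.0], [3.0]]),
            parameter_names=["PPE"],
            family_of={"PPE": "nonlinear"},
            subject_id=np.array(["a", "b", "c"]),
            record_index=np.array([1, 1, 1]),
            label=np.array([0, 0, 1]),
            gender=np.array(["male"] * 3, dtype=object),
        )
        (corr,) = family_correlations(t)
        assert corr.matrix.shape == (1, 1)
        assert not corr.strong_flag

    def test_constant_column_named_in_error(self, default_table):
        t = default_table.subset(np.arange(10))
        t.values[:, 2] = 7.0
        with pytest.raises(UndefinedCorrelationError, match=t.parameter_names[2]):
            family_correlations(t)


# ---------------------------------------------------------------- PCA


class TestRetentionRule:
    def test_spot_values(self):
        assert retained_components(np.array([9.0, 0.5, 0.5]), 0.90) == 1
        assert retained_components(np.ones(10), 0.90) == 9

    def test_minimal_h_matches_exhaustive_search(self, rng):
        for _ in range(200):
            q = rng.integers(1, 12)
            lam = np.sort(rng.exponential(size=q))[::-1]
            thr = rng.uniform(0.05, 1.0)
            h = retained_components(lam, thr)
            feasible = [
                k for k in range(1, q + 1) if lam[:k].sum() / lam.sum() >= thr - 1e-12
            ]
            assert h == min(feasible)

    def test_monotone_in_threshold(self, rng):
        lam = np.sort(rng.exponential(size=8))[::-1]
        hs = [retained_components(lam, t) for t in np.linspace(0.1, 1.0, 19)]
        assert hs == sorted(hs)


class TestFitProject:
    def test_training_projection_variance_equals_eigenvalues(self, default_table):
        model = fit_pca(default_table, "mfcc", threshold=0.90)
        z = project(model, default_table)
        assert z.shape == (240, model.h)
        np.testing.assert_allclose(
            z.var(axis=0, ddof=1), model.eigenvalues[: model.h], rtol=1e-8
        )
        # retained variance satisfies the rule, h minimal
        frac = model.eigenvalues[: model.h].sum() / model.eigenvalues.sum()
        assert frac >= 0.90
        if model.h > 1:
            assert model.eigenvalues[: model.h - 1].sum() / model.eigenvalues.sum() < 0.90

    def test_components_orthonormal_and_full_reconstruction(self, default_table):
        model = fit_pca(default_table, "shimmer", threshold=0.90)
        v = model.components
        np.testing.assert_allclose(v.T @ v, np.eye(v.shape[1]), atol=1e-10)
        z = (default_table.family_values("shimmer") - model.mean) / model.scale
        np.testing.assert_allclose((z @ v) @ v.T, z, atol=1e-10)

    def test_dominant_family_retains_one_component(self, default_table):
        # rho ~ 0.95 equicorrelation: the first eigenvalue carries > 90%
        for fam in ("jitter", "shimmer", "hnr"):
            assert fit_pca(default_table, fam, 0.90).h == 1

    def test_projection_uses_frozen_training_statistics(self, default_table):
        model = fit_pca(default_table, "jitter", 0.90)
        mean_only = default_table.subset([0])
        mean_only.values[:, default_table.family_columns("jitter")] = model.mean
        np.testing.assert_allclose(project(model, mean_only), 0.0, atol=1e-12)

    def test_single_record_projection_shape(self, default_table):
        model = fit_pca(default_table, "hnr", 0.90)
        row = project(model, default_table.subset([5]))
        assert row.shape == (1, model.h)

    def test_parameter_mismatch_rejected(self, default_table):
        model = fit_pca(default_table, "jitter", 0.90)
        other = generate(null_spec(seed=1))
        other.parameter_names[0] = "Jitter-X"
        other.family_of["Jitter-X"] = "jitter"
        del other.family_of["Jitter-Rel"]
        with pytest.raises(ValueError, match="do not match"):
            project(model, other)


# ---------------------------------------------------------------- MWW


def mww_exact_oracle(x, y):
    """Two-sided p by enumerating every split of the pooled ranks."""
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    u_big = max(u_obs, n * m - u_obs)
    count = total = 0
    for combo in itertools.combinations(range(n + m), n):
        xs = pooled[list(combo)]
        ys = np.delete(pooled, list(combo))
        u = sum(1 for xi in xs for yj in ys if xi > yj)
        count += int(u >= u_big)
        total += 1
    return min(1.0, 2 * count / total)


class TestMww:
    def test_identical_samples(self):
        assert mww_test(np.arange(20.0), np.arange(20.0)) == pytest.approx(1.0)

    def test_exact_spot_values(self):
        assert mww_test([1, 2], [3, 4]) == pytest.approx(1 / 3)
        assert mww_test(np.arange(1, 6), np.arange(6, 11)) == pytest.approx(2 / 252)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mww_test([], [1.0])

    def test_exact_branch_matches_enumeration(self, rng):
        for _ in range(40):
            n = int(rng.integers(2, 6))
            m = int(rng.integers(2, 11 - n))
            pooled = rng.permutation(rng.standard_normal(n + m))
            x, y = pooled[:n], pooled[n:]
            assert mww_test(x, y) == pytest.approx(mww_exact_oracle(x, y))

    @settings(derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_invariant_under_monotone_transform(self, seed):
        r = np.random.default_rng(seed)
        x = r.standard_normal(15)
        y = r.standard_normal(12) + 0.5
        p1 = mww_test(x, y)
        p2 = mww_test(np.exp(x), np.exp(y))  # strictly increasing transform
        assert p1 == pytest.approx(p2)


# ---------------------------------------------------------------- selection


class TestBuildAndSelect:
    def test_selected_equals_significant_candidates(self, default_table, config):
        reduced, report, pipeline = build_and_select(default_table, config)
        expected = [f for f, p in zip(report.feature_names, report.p_values)
                    if p < config.alpha]
        assert report.selected == expected
        assert reduced.feature_names == expected
        assert reduced.values.shape == (240, len(expected))
        assert np.all((report.p_values >= 0) & (report.p_values <= 1))

    def test_candidate_order_is_stable_family_order(self, default_table, config):
        _, report, _ = build_and_select(default_table, config)
        names = report.feature_names
        assert names[0] == "Jitter-PCA"
        assert names[1] == "Shimmer-PCA"
        assert names[2] == "HNR-PCA"
        assert names[3:7] == ["RPDE", "DFA", "PPE", "GNE"]
        assert names[7].startswith("MFCC-PCA")

    def test_selection_monotone_in_alpha(self, default_table):
        _, strict, _ = build_and_select(default_table, RunConfig(alpha=0.01))
        _, loose, _ = build_and_select(default_table, RunConfig(alpha=0.10))
        assert set(strict.selected) <= set(loose.selected)

    def test_jitter_shift_selects_jitter_pca(self):
        table = generate(separated_spec(seed=7))
        _, report, _ = build_and_select(table, RunConfig())
        assert "Jitter-PCA" in report.selected
        assert "Shimmer-PCA" in report.selected

    def test_empty_selection_raises_with_report(self):
        table = generate(null_spec(seed=42))
        with pytest.raises(EmptySelectionError) as exc:
            build_and_select(table, RunConfig(alpha=1e-9))
        assert exc.value.report is not None
        assert len(exc.value.report.p_values) > 0

    def test_pin_components_overrides_retention(self, default_table, config):
        _, report, pipeline = build_and_select(
            default_table, config, pin_components={"mfcc": 6, "delta": 5}
        )
        assert pipeline.pca_models["mfcc"].h == 6
        assert pipeline.pca_models["delta"].h == 5
        assert "MFCC-PCA6" in report.feature_names
        assert "Delta-PCA6" not in report.feature_names

    def test_transform_is_frozen(self, default_table, config):
        reduced, _, pipeline = build_and_select(default_table, config)
        half = default_table.subset(np.arange(120))
        again = pipeline.transform(half)
        np.testing.assert_allclose(again.values, reduced.values[:120])
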