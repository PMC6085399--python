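"""Paired regression, Bray–Curtis and the three dissimilarity levels."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from domfrag.stats import (
    bray_curtis,
    dissimilarity_levels,
    paired_regression,
    replicate_variability,
)

from oracles import oracle_bray_curtis


def _keys(n):
    return [f"frag{i:03d}" for i in range(n)]


class TestPairedRegression:
    def test_identity_gives_slope_one(self):
        rng = np.random.default_rng(0)
        rel = dict(zip(_keys(20), rng.uniform(0, 0.3, 20)))
        res = paired_regression(rel, rel)
        assert res.slope == pytest.approx(1.0, abs=1e-12)
        assert res.delta_sl == pytest.approx(0.0, abs=1e-12)
        assert res.r == pytest.approx(1.0, abs=1e-12)

    def test_scaled_input_gives_scaled_slope(self):
        rng = np.random.default_rng(1)
        a = dict(zip(_keys(15), rng.uniform(0.01, 0.3, 15)))
        b = {k: 0.8 * v for k, v in a.items()}
        res = paired_regression(a, b)
        assert res.slope == pytest.approx(0.8, abs=1e-12)
        assert res.delta_sl == pytest.approx(0.2, abs=1e-12)
        assert res.r == pytest.approx(1.0, abs=1e-10)

    def test_noisy_shared_profiles(self):
        """Shared profiles + 5% multiplicative noise, n = 324 pairs."""
        rng = np.random.default_rng(2)
        base = rng.uniform(0.005, 0.2, 324)
        a = dict(zip(_keys(324), base * rng.lognormal(0, 0.05, 324)))
        b = dict(zip(_keys(324), base * rng.lognormal(0, 0.05, 324)))
        res = paired_regression(a, b)
        assert res.delta_sl < 0.05
        assert res.r > 0.95
        assert res.p_value < 1e-4

    def test_single_outlier_excluded(self):
        rng = np.random.default_rng(3)
        a = dict(zip(_keys(30), rng.uniform(0.01, 0.3, 30)))
        b = dict(a)
        b["frag000"] = a["frag000"] + 0.5  # gross outlier
        res = paired_regression(a, b)
        assert res.excluded_outliers == ["frag000"]
        assert res.delta_sl == pytest.approx(0.0, abs=1e-9)
        assert res.raw_delta_sl > res.delta_sl

    def test_mismatched_keys_error(self):
        with pytest.raises(ValueError, match="keys"):
            paired_regression({"a": 1.0, "b": 2.0, "c": 3.0}, {"a": 1.0, "b": 2.0, "d": 3.0})

    def test_degenerate_abscissa_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            paired_regression(
                {k: 0.1 for k in _keys(5)}, dict(zip(_keys(5), [1, 2, 3, 4, 5]))
            )


class TestBrayCurtis:
    def test_identical_is_zero(self):
        x = [1.0, 2.0, 3.0]
        assert bray_curtis(x, x) == 0.0

    def test_disjoint_is_one(self):
        assert bray_curtis([1.0, 0.0], [0.0, 2.0]) == 1.0

    def test_hand_value(self):
        assert bray_curtis([2.0, 0.0], [1.0, 1.0]) == pytest.approx(0.5)

    def test_both_zero_errors(self):
        with pytest.raises(ValueError):
            bray_curtis([0.0, 0.0], [0.0, 0.0])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(0, 100, allow_nan=False), st.floats(0, 100, allow_nan=False)
            ),
            min_size=1,
            max_size=30,
        )
    )
    def test_matches_bruteforce_oracle_and_bounds(self, pairs):
        x = np.array([p[0] for p in pairs])
        y = np.array([p[1] for p in pairs])
        if x.sum() + y.sum() == 0:
            return
        bc = bray_curtis(x, y)
        assert bc == pytest.approx(oracle_bray_curtis(x, y), abs=1e-12)
        assert 0.0 <= bc <= 1.0
        assert bc == pytest.approx(bray_curtis(y, x), abs=1e-12)

    def test_matches_skbio_reference(self):
        # independent ecology-library route as cross-check
        from skbio.diversity import beta_diversity

        rng = np.random.default_rng(9)
        for _ in range(20):
            x, y = rng.uniform(0, 5, 12), rng.uniform(0, 5, 12)
            dm = beta_diversity("braycurtis", np.vstack([x, y]), ids=["x", "y"])
            assert bray_curtis(x, y) == pytest.approx(dm["x", "y"], abs=1e-12)


class TestDissimilarityLevels:
    def test_identical_samples_all_zero(self):
        form = {"a": {"F1": 3.0, "F2": 7.0}, "b": {"F1": 3.0, "F2": 7.0}}
        frag = {"a": {("F1", "CO2"): 0.2}, "b": {("F1", "CO2"): 0.2}}
        out = dissimilarity_levels(form, frag)
        for level in ("all_formulae", "common_formulae", "fragments"):
            assert out[level].value("a", "b") == pytest.approx(0.0)

    def test_abundance_shift_with_shared_fragments(self):
        """Different formula abundances but identical fragment profiles:
        levels 1-2 elevated, level 3 zero."""
        form = {"a": {"F1": 9.0, "F2": 1.0}, "b": {"F1": 1.0, "F2": 9.0}}
        frag = {"a": {("F1", "CO2"): 0.2, ("F2", "H2O"): 0.1},
                "b": {("F1", "CO2"): 0.2, ("F2", "H2O"): 0.1}}
        out = dissimilarity_levels(form, frag)
        assert out["common_formulae"].value("a", "b") > 0.5
        assert out["fragments"].value("a", "b") == pytest.approx(0.0)

    def test_disjoint_sets_error(self):
        form = {"a": {"F1": 1.0}, "b": {"F2": 1.0}}
        with pytest.raises(ValueError, match="common"):
            dissimilarity_levels(form)

    def test_missing_fragmentation_omits_level3(self):
        form = {"a": {"F1": 1.0}, "b": {"F1": 2.0}}
        out = dissimilarity_levels(form, None)
        assert set(out) == {"all_formulae", "common_formulae"}

    def test_matrix_invariants(self):
        rng = np.random.default_rng(4)
        form = {
            s: {f"F{i}": float(v) for i, v in enumerate(rng.uniform(0.1, 5, 8))}
            for s in ("a", "b", "c")
        }
        out = dissimilarity_levels(form)
        for m in out.values():
            vals = m.data.values
            assert np.allclose(vals, vals.T)
            assert np.allclose(np.diag(vals), 0)
            assert ((vals >= 0) & (vals <= 1)).all()


class TestReplicateVariability:
    def test_identical_replicates_zero(self):
        rep = {("F1", "CO2"): 0.2, ("F1", "H2O"): 0.1}
        assert replicate_variability(rep, rep) == 0.0

    def test_five_pct_noise_in_two_to_eight_pct_band(self):
        rng = np.random.default_rng(6)
        base = rng.uniform(0.005, 0.2, 200)
        keys = _keys(200)
        a = dict(zip(keys, base * rng.lognormal(0, 0.05, 200)))
        b = dict(zip(keys, base * rng.lognormal(0, 0.05, 200)))
        bc = replicate_variability(a, b)
        assert 0.02 <= bc <= 0.08

    def test_censoring_increases_dissimilarity_monotonically(self):
        rng = np.random.default_rng(7)
        base = dict(zip(_keys(50), rng.uniform(0.01, 0.2, 50)))
        prev = 0.0
        for n_censored in (1, 5, 10, 20):
            censored = dict(base)
            for k in _keys(n_censored):
                censored[k] = 0.0
            bc = replicate_variability(base, censored)
            assert bc > prev
            prev = bc
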