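"""Descriptive, rank and correlation statistics against enumeration oracles."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from retorient.image import axial_distance
from retorient.stats import (
    axial_mean,
    axial_std,
    describe,
    mann_whitney_u,
    pearson_r,
    sector_descriptives,
)


def enumerated_mw_p(a, b, alternative="two-sided"):
    """Independent oracle: two-sided Mann–Whitney p by full enumeration.

    U is computed by direct pair counting (wins + half-ties), enumerating
    every assignment of the pooled values to group A.
    """
    pooled = np.concatenate([a, b])
    na = len(a)
    idx = range(len(pooled))

    def u_of(group_idx):
        ga = pooled[list(group_idx)]
        gb = np.delete(pooled, list(group_idx))
        wins = (ga[:, None] > gb[None, :]).sum()
        ties = (ga[:, None] == gb[None, :]).sum()
        return wins + 0.5 * ties

    u_obs = u_of(range(na))
    us = np.array([u_of(c) for c in combinations(idx, na)])
    eps = 1e-12
    p_ge = np.mean(us >= u_obs - eps)
    p_le = np.mean(us <= u_obs + eps)
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2.0 * min(p_ge, p_le))


class TestDescriptives:
    def test_head_tail_wrap_example(self):
        d = describe([10.0, 170.0], circular=True)
        assert d["mean"] == 90.0
        assert d["axial_mean"] == pytest.approx(0.0, abs=1e-9)

    def test_single_value_degenerate(self):
        d = describe([42.0])
        assert d["mean"] == d["min"] == d["max"] == 42.0
        assert d["sd"] == 0.0 and d["n"] == 1

    def test_axial_mean_identity_and_shift_invariance(self, rng):
        assert axial_mean([30.0, 30.0, 30.0]) == pytest.approx(30.0)
        theta = rng.uniform(0, 180, 25)
        shifted = theta + 180.0 * (rng.random(25) < 0.5)
        assert axial_mean(shifted) == pytest.approx(axial_mean(theta), abs=1e-9)
        assert axial_std(shifted) == pytest.approx(axial_std(theta), abs=1e-9)

    def test_axial_std_zero_for_aligned_sample(self):
        assert axial_std([77.0, 77.0, 257.0]) == pytest.approx(0.0, abs=1e-6)

    def test_sector_table_layout(self):
        table = pd.DataFrame({
            "metric": ["preferred_orientation"] * 4 + ["vessel_area"] * 4,
            "sector": ["NS", "NS", "SN", "SN"] * 2,
            "value": [10.0, 170.0, 30.0, 40.0, 100.0, 200.0, 300.0, 500.0],
        })
        out = sector_descriptives(table)
        assert len(out) == 4
        row = out[(out.metric == "preferred_orientation") & (out.sector == "NS")].iloc[0]
        assert row["mean"] == 90.0 and row["axial_mean"] == pytest.approx(0.0, abs=1e-9)
        area = out[(out.metric == "vessel_area") & (out.sector == "SN")].iloc[0]
        assert area["min"] == 300.0 and area["max"] == 500.0
        assert "axial_mean" not in area or np.isnan(area["axial_mean"])


class TestAxialProperties:
    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.floats(0.0, 179.99), min_size=1, max_size=20),
           st.integers(min_value=0, max_value=2**20 - 1))
    def test_axial_mean_invariant_to_head_tail_flips(self, angles, bits):
        """Adding 180° to any subset of axial observations changes nothing."""
        t = np.radians(2.0 * np.asarray(angles))
        resultant = np.hypot(np.sin(t).mean(), np.cos(t).mean())
        assume(resultant > 0.05)  # the mean direction is ill-defined near isotropy
        flipped = [a + 180.0 * ((bits >> i) & 1) for i, a in enumerate(angles)]
        assert axial_distance(axial_mean(flipped), axial_mean(angles)) <= 1e-6

    @settings(derandomize=True, max_examples=60)
    @given(st.floats(-720.0, 720.0), st.floats(-720.0, 720.0))
    def test_axial_distance_is_a_bounded_metric(self, a, b):
        d = axial_distance(a, b)
        assert 0.0 <= d <= 90.0 + 1e-9
        assert d == pytest.approx(axial_distance(b, a), abs=1e-9)
        assert axial_distance(a + 180.0, b) == pytest.approx(d, abs=1e-6)


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.u == 0.0
        assert res.p_value == pytest.approx(0.1, abs=1e-12)
        assert res.method == "exact"

    def test_identical_groups_p_one(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_exact_p_matches_full_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 6, size=rng.integers(3, 7)).astype(float)
        b = rng.integers(0, 6, size=rng.integers(3, 7)).astype(float)
        res = mann_whitney_u(a, b)
        assert res.p_value == pytest.approx(enumerated_mw_p(a, b), abs=1e-12)

    def test_u_statistics_sum_to_product(self, rng):
        a = rng.normal(size=6)
        b = rng.normal(size=5)
        ua = mann_whitney_u(a, b).u
        ub = mann_whitney_u(b, a).u
        assert ua + ub == pytest.approx(len(a) * len(b))

    def test_invariant_under_monotone_transform(self, rng):
        a = rng.normal(size=5)
        b = rng.normal(size=7) + 0.5
        p1 = mann_whitney_u(a, b).p_value
        p2 = mann_whitney_u(np.exp(a), np.exp(b)).p_value
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_large_samples_use_normal_approximation(self, rng):
        a = rng.normal(size=20)
        b = rng.normal(size=20)
        res = mann_whitney_u(a, b)
        assert res.method == "asymptotic"
        assert 0.0 <= res.p_value <= 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestPearson:
    def test_affine_relations(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1).r == pytest.approx(1.0)
        assert pearson_r(x, -x).r == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        x = rng.normal(size=40)
        y = 0.3 * x + rng.normal(size=40)
        want = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        assert pearson_r(x, y).r == pytest.approx(want, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            pearson_r([1.0, 2.0], [3.0, 4.0])
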