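"""Food shares, weighted quantiles, the poverty line and capacity-to-pay."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cheimp import (
    compute_ctp_nf,
    compute_ctp_wb,
    compute_ctp_who,
    derive_households,
    food_share,
    poverty_line,
    select_band,
    subsistence,
    weighted_quantile,
)
from conftest import brute_force_weighted_quantile


class TestFoodShare:
    @pytest.mark.parametrize("f, x, expected", [(50, 100, 0.5), (0, 100, 0.0), (100, 100, 1.0)])
    def test_values(self, f, x, expected):
        assert food_share(f, x) == expected

    def test_zero_expenditure_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            food_share(10, 0)


class TestWeightedQuantile:
    @pytest.mark.parametrize(
        "values, weights, q, expected",
        [
            ([1, 2, 3], [1, 1, 1], 0.5, 2),
            ([7], [3.2], 0.0, 7),
            ([7], [3.2], 1.0, 7),
            ([1, 2], [3, 1], 0.9, 2),  # cum normalised weights 0.75, 1.0
            ([1, 2], [3, 1], 0.75, 1),  # boundary hit is inclusive
        ],
    )
    def test_examples(self, values, weights, q, expected):
        assert weighted_quantile(values, weights, q) == expected

    def test_input_validation(self):
        with pytest.raises(ValueError):
            weighted_quantile([], [], 0.5)
        with pytest.raises(ValueError):
            weighted_quantile([1, 2], [1, -1], 0.5)
        with pytest.raises(ValueError):
            weighted_quantile([1, 2], [1, 1], 1.5)

    @settings(derandomize=True, max_examples=1000)
    @given(
        data=st.lists(
            st.tuples(
                st.floats(-1e6, 1e6, allow_nan=False),
                st.floats(1e-3, 1e3, allow_nan=False),
            ),
            min_size=1,
            max_size=50,
        ),
        q=st.sampled_from([0.05 * k for k in range(1, 20)]),
    )
    def test_matches_brute_force_oracle(self, data, q):
        """Exact agreement with a sequential sort-and-accumulate oracle."""
        values = [v for v, _ in data]
        weights = [w for _, w in data]
        assert weighted_quantile(values, weights, q) == brute_force_weighted_quantile(
            values, weights, q
        )


class TestBandAndPovertyLine:
    def test_middle_household_only(self):
        shares = [0.2, 0.5, 0.8]
        ind, lo, hi = select_band(shares, [1, 1, 1], 0.45, 0.55)
        assert lo == hi == 0.5
        assert list(ind) == [False, True, False]

    def test_degenerate_distribution_selects_all(self):
        ind, _, _ = select_band([0.3] * 5, [1] * 5, 0.45, 0.55)
        assert ind.all()

    def test_full_band_selects_all(self):
        ind, _, _ = select_band([0.1, 0.4, 0.9], [1, 2, 3], 0.0, 1.0)
        assert ind.all()

    def test_toy_poverty_line_is_50(self, toy_three_households):
        derived, pl = derive_households(toy_three_households)
        assert pl.ell == 50.0
        assert pl.n_band == 1
        assert list(derived["in_band"]) == [False, True, False]

    def test_reweighting_single_band_member_leaves_line(self, toy_three_households):
        frame = toy_three_households.copy()
        frame.loc[frame["household_id"] == "h2", "weight"] = 2.0
        _, pl = derive_households(frame)
        assert pl.ell == 50.0

    def test_identical_households_average_to_their_fe(self):
        fe = [30.0] * 4
        pl = poverty_line(fe, [1, 2, 3, 4], [True] * 4)
        assert pl.ell == 30.0
        assert pl.total_band_weight == 10.0

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError, match="empty band"):
            poverty_line([1.0, 2.0], [1, 1], [False, False])

    def test_unweighted_mean_special_case(self, random_frame_factory):
        """Equal weights + he = 1 everywhere: the line is the plain mean of f in band."""
        frame = random_frame_factory(n=150, seed=3)
        frame["adults"] = 1
        frame["kids"] = 0
        frame["weight"] = 1.0
        derived, pl = derive_households(frame)
        in_band = derived["in_band"]
        assert pl.ell == pytest.approx(derived.loc[in_band, "food_who"].mean(), rel=1e-12)

    def test_weight_rescaling_invariance(self, random_frame_factory):
        frame = random_frame_factory(n=300, seed=11)
        _, pl1 = derive_households(frame)
        scaled = frame.copy()
        scaled["weight"] = scaled["weight"] * 17.3
        _, pl2 = derive_households(scaled)
        assert pl2.ell == pytest.approx(pl1.ell, rel=1e-12)


class TestCapacityToPay:
    @pytest.mark.parametrize(
        "x, f, s, expected",
        [
            (100, 30, 20, 80),  # subsistence affordable: x - s
            (100, 30, 40, 70),  # food below subsistence: x - f
            (100, 100, 100, 0),  # boundary, both branches agree
        ],
    )
    def test_who_branches(self, x, f, s, expected):
        assert compute_ctp_who(x, f, s) == expected

    def test_wb_and_nf(self):
        assert compute_ctp_wb(100, 1) == 100
        assert compute_ctp_wb(100, 2) == 50
        assert compute_ctp_wb(3021.61, 3.19) == pytest.approx(947.21, abs=0.01)
        assert compute_ctp_nf(100, 40, 1) == 60
        assert compute_ctp_nf(100, 100, 1) == 0
        assert compute_ctp_nf(100, 40, 2) == 30

    def test_subsistence(self):
        assert subsistence(50, 1) == 50
        assert subsistence(50, 2.68788) == pytest.approx(134.394, abs=1e-9)
        assert subsistence(0, 3.7) == 0

    def test_nf_never_exceeds_wb(self, random_frame_factory):
        derived, _ = derive_households(random_frame_factory(n=400, seed=5))
        assert (derived["ctp_nf"] <= derived["ctp_wb"] + 1e-12).all()

    def test_who_ctp_nonnegative(self, random_frame_factory):
        derived, _ = derive_households(random_frame_factory(n=400, seed=6))
        assert (derived["ctp_who"] >= -1e-9).all()

    def test_currency_rescaling_equivariance(self, random_frame_factory):
        """Scaling all expenditures by c scales ell, s and every ctp by c."""
        frame = random_frame_factory(n=250, seed=9)
        d1, pl1 = derive_households(frame)
        scaled = frame.copy()
        for col in ("food_who", "food_wb", "total", "oop"):
            scaled[col] = scaled[col] * 100.0
        d2, pl2 = derive_households(scaled)
        assert pl2.ell == pytest.approx(100 * pl1.ell, rel=1e-9)
        for col in ("s", "ctp_who", "ctp_wb", "ctp_nf"):
            assert np.allclose(d2[col], 100 * d1[col], rtol=1e-9)
        assert (d1["in_band"] == d2["in_band"]).all()
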