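"""Ring Measure instrument geometry and SVO scoring."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svocortex.ring import (
    CATEGORIES,
    CONSISTENCY_THRESHOLD,
    InvalidInstrumentError,
    MalformedResponseError,
    build_ring,
    classify,
    filter_consistent,
    score_choices,
    score_table,
    utility_choices,
    weights_from_totals,
)


def brute_force_score(choices, ring):
    """Independent oracle: enumerate chosen points one by one and accumulate
    totals and the resultant directly from the displayed payoff table."""
    total_self = total_other = rx = ry = 0.0
    for k, c in enumerate(choices):
        i, j = k, (k + 1) % ring.n_points
        point = [i, j][c]
        s, o = ring.points[point]
        total_self += s
        total_other += o
        rx += s - ring.origin_self
        ry += o - ring.origin_other
    length = math.sqrt(rx * rx + ry * ry) / ring.n_points
    angle = math.degrees(math.atan2(ry, rx)) % 360.0 if (rx, ry) != (0, 0) else None
    return total_self, total_other, length, angle


class TestInstrument:
    def test_printed_payoffs(self, ring):
        # the two options of the worked choice: points at 30 and 15 degrees
        assert tuple(ring.points[2]) == (28.0, 22.5)
        assert tuple(ring.points[1]) == (29.5, 18.9)
        assert tuple(ring.points[0]) == (30.0, 15.0)

    def test_points_on_circle_within_rounding(self, ring):
        r = np.hypot(ring.points[:, 0] - 15.0, ring.points[:, 1] - 15.0)
        assert np.all(np.abs(r - 15.0) <= 0.08)

    def test_pair_structure(self, ring):
        assert ring.n_points == 24
        assert len(ring.points) == 24 and len(ring.pairs) == 24
        counts = np.zeros(24, dtype=int)
        for i, j in ring.pairs:
            counts[i] += 1
            counts[j] += 1
        assert np.all(counts == 2)  # each point appears in exactly 2 pairs

    @pytest.mark.parametrize("radius,n", [(-1.0, 24), (0.0, 24), (15.0, 2)])
    def test_invalid_instrument(self, radius, n):
        with pytest.raises(InvalidInstrumentError):
            build_ring(radius=radius, n_points=n)


class TestScoring:
    def test_worked_example_weights(self, ring):
        # printed to two decimals: 20.40/60 = 0.34 exactly, 10.90/60 = 0.18167
        w_self, w_other = weights_from_totals(380.40, 370.90, ring)
        assert round(w_self, 2) == 0.34
        assert round(w_other, 2) == 0.18
        assert w_self == pytest.approx(20.40 / 60.0, abs=1e-12)
        assert w_other == pytest.approx(10.90 / 60.0, abs=1e-12)

    def test_perfectly_consistent_grid_aligned(self, ring):
        prof = score_choices(utility_choices(ring, 0.0), ring)
        assert prof.vector_length == pytest.approx(1.25, abs=1e-12)
        assert prof.w_self == pytest.approx(0.5, abs=1e-12)
        assert prof.w_other == pytest.approx(0.0, abs=1e-12)
        assert prof.included

    @pytest.mark.parametrize("k", range(24))
    def test_consistent_responder_any_grid_direction(self, ring, k):
        # maximum attained (up to display rounding) for every grid direction,
        # and cross-checked against the brute-force oracle
        theta = 15.0 * k
        choices = utility_choices(ring, theta)
        prof = score_choices(choices, ring)
        *_, length, angle = brute_force_score(choices, ring)
        assert prof.vector_length == pytest.approx(length, abs=1e-12)
        assert prof.vector_length == pytest.approx(1.25, abs=0.01)

    def test_random_responder_resultant_near_zero(self, ring):
        # Monte Carlo over >= 1e4 random response vectors: expected resultant
        # ~ 0 and typical vector length far below the exclusion threshold
        rng = np.random.default_rng(42)
        draws = rng.integers(0, 2, size=(10_000, 24))
        pairs = np.asarray(ring.pairs)
        chosen = pairs[np.arange(24)[None, :], draws]
        offsets = ring.offsets[chosen]  # (draws, 24, 2)
        resultants = offsets.sum(axis=1)
        lengths = np.hypot(resultants[:, 0], resultants[:, 1]) / 24
        assert np.abs(resultants.mean(axis=0)).max() < 0.5
        assert lengths.mean() < CONSISTENCY_THRESHOLD - 0.2
        assert np.median(lengths) < CONSISTENCY_THRESHOLD - 0.25
        # a minority of random responders clear the cut-off by chance
        # (Rayleigh tail: exp(-15^2 / (2 * 46)) ~ 0.09)
        assert (lengths >= CONSISTENCY_THRESHOLD).mean() < 0.15

    def test_scoring_matches_brute_force_oracle(self, ring):
        rng = np.random.default_rng(7)
        for _ in range(100):
            choices = rng.integers(0, 2, size=24)
            prof = score_choices(choices, ring)
            ts, to, length, angle = brute_force_score(choices, ring)
            assert prof.total_self == pytest.approx(ts, abs=1e-9)
            assert prof.total_other == pytest.approx(to, abs=1e-9)
            assert prof.vector_length == pytest.approx(length, abs=1e-12)
            if angle is not None:
                assert prof.raw_angle_deg == pytest.approx(angle, abs=1e-9)
                assert prof.angle_deg == pytest.approx((angle + 135.0) % 360.0, abs=1e-9)

    def test_angle_recovery_within_half_grid_spacing(self, ring):
        # zero-lapse responder with preferred direction theta: recovered raw
        # angle within 7.5 degrees (half the 15-degree grid spacing)
        for theta in np.arange(0.0, 360.0, 1.0):
            prof = score_choices(utility_choices(ring, theta), ring)
            diff = (prof.raw_angle_deg - theta + 180.0) % 360.0 - 180.0
            assert abs(diff) <= 7.5 + 1e-9, f"theta={theta}: off by {diff}"

    @given(st.lists(st.integers(0, 1), min_size=24, max_size=24))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_weight_and_length_bounds(self, choices):
        prof = score_choices(choices)
        assert -0.5 - 1e-9 <= prof.w_self <= 0.5 + 1e-9
        assert -0.5 - 1e-9 <= prof.w_other <= 0.5 + 1e-9
        assert 0.0 <= prof.vector_length <= 1.25 + 1e-9

    def test_pair_order_invariance(self, ring, rng):
        choices = rng.integers(0, 2, size=24)
        df = pd.DataFrame(
            {"participant_id": "a", "pair_index": np.arange(24), "chosen": choices}
        )
        shuffled = df.sample(frac=1.0, random_state=3)
        a = score_choices(df, ring)
        b = score_choices(shuffled, ring)
        assert a.angle_deg == b.angle_deg
        assert a.vector_length == b.vector_length

    def test_zero_resultant_flagged(self, ring):
        # choosing every pair's first option selects each circle point exactly
        # once, so the resultant vanishes and the angle is undefined
        prof = score_choices(np.zeros(24, dtype=int), ring)
        assert prof.degenerate
        assert math.isnan(prof.angle_deg)
        assert prof.vector_length == 0.0
        assert not prof.included
        assert prof.category == "undefined"

    def test_malformed_responses(self, ring):
        with pytest.raises(MalformedResponseError):
            score_choices([0, 1, 0], ring)
        df = pd.DataFrame(
            {"participant_id": "a", "pair_index": [0] + list(range(23)), "chosen": 0}
        )
        with pytest.raises(MalformedResponseError):
            score_choices(df, ring)
        with pytest.raises(MalformedResponseError):
            score_choices([2] * 24, ring)


class TestClassify:
    def test_poles_and_antipodes(self):
        assert classify(0.0) == "sadistic"
        assert classify(180.0) == "prosocial/cooperative"
        assert classify(135.0) == "individualistic"

    def test_boundary_belongs_to_lower_sector(self):
        assert classify(22.5) == "sadistic"
        assert classify(22.5 + 1e-6) == "aggressive"
        assert classify(337.5) == "masochistic"
        assert classify(360.0 - 1e-6) == "sadistic"

    def test_eight_equal_sectors(self):
        # exhaustive sweep: each category covers the same share of the circle
        sweep = np.arange(0.0, 360.0, 0.1)
        counts = pd.Series([classify(a) for a in sweep]).value_counts()
        assert set(counts.index) == set(CATEGORIES)
        assert counts.max() == counts.min() == 450


class TestFilter:
    def test_boundary_is_included(self):
        profiles = pd.DataFrame(
            {
                "participant_id": ["a", "b", "c"],
                "vector_length": [0.625, 0.6249, 1.25],
                "degenerate": [False, False, False],
            }
        )
        kept, report = filter_consistent(profiles)
        assert list(kept["participant_id"]) == ["a", "c"]
        assert list(report["participant_id"]) == ["b"]
        assert (report["reason"] == "inconsistent").all()

    def test_noise_subgroup_mostly_excluded(self, ring):
        from svocortex.simulate import PopulationSpec, simulate_choices

        spec = PopulationSpec(n_subjects=214)
        choices, truth = simulate_choices(spec, ring, seed=11)
        profiles = score_table(choices, ring)
        kept, report = filter_consistent(profiles)
        n_noise = int(truth["noise_subgroup"].sum())
        # the large majority of random responders fall below the threshold
        # (each clears it with probability ~0.09 by chance)
        assert abs(len(report) - n_noise) <= 4
        assert len(report) >= 0.7 * n_noise
        excluded = set(report["participant_id"])
        noisy = set(truth.loc[truth["noise_subgroup"], "participant_id"])
        assert excluded <= noisy  # no consistent responder is excluded here
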