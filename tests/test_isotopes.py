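"""Label-fraction arithmetic, the MRM channel logic, and the mixture estimator."""

import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rubiscoflux.isotopes import (
    FluxFractionEstimate,
    IsotopologueDistribution,
    LabelingExperiment,
    MixtureParams,
    MrmPair,
    carboxyl_12c_from_m2,
    compare_to_fba,
    estimate_rubisco_fraction,
    experiments_to_frames,
    mrm_carboxyl_13c,
    read_isotopologue_csv,
    total_12c_fraction,
    total_13c_fraction,
)


def dist(*fractions, compound="serine"):
    return IsotopologueDistribution(compound, tuple(fractions))


class TestLabelFractions:
    @pytest.mark.parametrize(
        "fractions, expected",
        [
            ((1, 0, 0, 0), 0.0),  # all M+0
            ((0, 0, 0, 1), 1.0),  # fully labeled
            ((0.2, 0.3, 0.5), 0.65),  # (0.3*1 + 0.5*2)/2
        ],
    )
    def test_weighted_average(self, fractions, expected):
        assert total_13c_fraction(dist(*fractions)) == pytest.approx(expected)

    def test_complement(self):
        assert total_12c_fraction(dist(0.2, 0.3, 0.5)) == pytest.approx(0.35)
        assert total_12c_fraction(dist(1, 0)) == pytest.approx(1.0)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=7)
        .filter(lambda f: sum(f) > 1e-6)
    )
    def test_reversal_symmetry(self, weights):
        """Swapping i <-> N-i maps f12C to 1 - f12C."""
        f = np.array(weights) / sum(weights)
        forward = total_12c_fraction(dist(*f))
        reverse = total_12c_fraction(dist(*f[::-1]))
        assert forward + reverse == pytest.approx(1.0, abs=1e-9)

    def test_invalid_distributions_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            dist(0.5, 0.1)
        with pytest.raises(ValueError):
            dist(1.2, -0.2)
        with pytest.raises(ValueError, match="M\\+0 and M\\+1"):
            dist(1.0)


class TestMrm:
    @pytest.mark.parametrize(
        "a, b, expected", [(0, 5, 0.0), (2, 2, 0.5), (3, 1, 0.75)]
    )
    def test_channel_ratio(self, a, b, expected):
        assert mrm_carboxyl_13c(MrmPair(a, b)) == pytest.approx(expected)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        a=st.floats(min_value=0, max_value=1e6),
        b=st.floats(min_value=1e-6, max_value=1e6),
        scale=st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_scale_invariance(self, a, b, scale):
        assert mrm_carboxyl_13c(MrmPair(a * scale, b * scale)) == pytest.approx(
            mrm_carboxyl_13c(MrmPair(a, b)), rel=1e-9
        )

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            MrmPair(0.0, 0.0)

    def test_m2_deconditioning_round_trip(self):
        """q12 = p(1-b)/(p(1-b)+2b(1-p)) inverts back to p exactly."""
        for b in (0.01, 0.02, 0.1):
            for p in (b, 0.05, 0.3, 0.9):
                q12 = p * (1 - b) / (p * (1 - b) + 2 * b * (1 - p))
                assert carboxyl_12c_from_m2(q12, b) == pytest.approx(p, rel=1e-12)

    def test_control_m2_channels_split_one_third_two_thirds(self):
        """With all positions at background b, the M+2 12C sits at the
        carboxyl exactly 1/3 of the time, independent of b."""
        for b in (0.005, 0.02, 0.2):
            q12 = b * (1 - b) / (b * (1 - b) + 2 * b * (1 - b))
            assert q12 == pytest.approx(1.0 / 3.0)
            assert carboxyl_12c_from_m2(q12, b) == pytest.approx(b)


def analytic_replicates(x, b, c, d, role, n=1):
    """Noise-free labeling replicates under the forward mixture model."""
    x_eff = x if role == "experiment" else 0.0
    p = b + x_eff * d * (c - b)
    p12 = [p, b, b]
    probs = np.array([1.0])
    for q in p12:
        probs = np.convolve(probs, [q, 1 - q])
    a = (1 - p) * 2 * b * (1 - b)  # M+2, carboxyl 13C
    bb = p * (1 - b) ** 2  # M+2, carboxyl 12C
    prefix = "exp" if role == "experiment" else "ctrl"
    return [
        LabelingExperiment(
            role,
            f"{prefix}_{i}",
            (IsotopologueDistribution("serine", tuple(probs)),),
            MrmPair(a, bb),
        )
        for i in range(1, n + 1)
    ]


class TestEstimator:
    B, C, D, X = 0.02, 0.989, 0.5, 0.14

    def exp_ctrl(self, x=None, mode_n=2):
        x = self.X if x is None else x
        exp = analytic_replicates(x, self.B, self.C, self.D, "experiment", mode_n)
        ctrl = analytic_replicates(x, self.B, self.C, self.D, "control", mode_n)
        return exp, ctrl

    @pytest.mark.parametrize("mode", ["total_serine", "carboxyl_mrm"])
    def test_identical_labeling_gives_zero(self, mode):
        exp, ctrl = self.exp_ctrl(x=0.0)
        est = estimate_rubisco_fraction(exp, ctrl, MixtureParams(mode=mode))
        assert est.mean == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("mode", ["total_serine", "carboxyl_mrm"])
    def test_noise_free_round_trip(self, mode):
        """Forward-simulated labeling at x=0.14 inverts to exactly 0.14."""
        exp, ctrl = self.exp_ctrl()
        est = estimate_rubisco_fraction(exp, ctrl, MixtureParams(mode=mode))
        assert est.mean == pytest.approx(self.X, abs=1e-9)
        assert not est.any_clipped

    def test_forward_value_matches_hand_mixture(self):
        # b=0.02, c=0.989, d=0.5, x=0.14 -> p = 0.02 + 0.07*0.969 = 0.08783
        p = self.B + self.X * self.D * (self.C - self.B)
        assert p == pytest.approx(0.08783)

    def test_saturated_mixture_gives_one(self):
        exp, ctrl = self.exp_ctrl(x=1.0)
        est = estimate_rubisco_fraction(
            exp, ctrl, MixtureParams(mode="carboxyl_mrm")
        )
        assert est.mean == pytest.approx(1.0, abs=1e-9)

    def test_clipping_is_flagged_never_silent(self):
        # control background above the experiment signal drives x below 0
        exp = analytic_replicates(0.0, 0.02, self.C, self.D, "experiment")
        ctrl = analytic_replicates(0.0, 0.05, self.C, self.D, "control")
        est = estimate_rubisco_fraction(
            exp, ctrl, MixtureParams(mode="total_serine")
        )
        assert est.per_replicate[0] == 0.0
        assert est.clipped[0]
        assert est.any_clipped

    def test_no_contrast_errors(self):
        exp, ctrl = self.exp_ctrl()
        with pytest.raises(ValueError, match="contrast"):
            estimate_rubisco_fraction(exp, ctrl, MixtureParams(c=0.01))

    def test_missing_mrm_errors_in_carboxyl_mode(self):
        exp, ctrl = self.exp_ctrl()
        exp = [
            LabelingExperiment(r.role, r.replicate, r.distributions, None)
            for r in exp
        ]
        with pytest.raises(ValueError, match="MRM"):
            estimate_rubisco_fraction(exp, ctrl, MixtureParams(mode="carboxyl_mrm"))

    def test_per_replicate_and_min_reported(self):
        exp, ctrl = self.exp_ctrl(mode_n=3)
        est = estimate_rubisco_fraction(exp, ctrl, MixtureParams())
        assert len(est.per_replicate) == 3
        assert est.min == min(est.per_replicate)
        assert est.mean == pytest.approx(np.mean(est.per_replicate))


class TestCompareToFba:
    def make_estimate(self, mean):
        return FluxFractionEstimate(
            x=mean, per_replicate=(mean,), mean=mean, min=mean,
            clipped=(False,), background_b=0.02, params=MixtureParams(),
        )

    def test_outside_range_gap(self):
        rec = compare_to_fba(self.make_estimate(0.14), (0.20, (0.16, 0.24)))
        assert not rec["inside_range"]
        assert rec["absolute_gap"] == pytest.approx(0.02)

    def test_inside_range_gap_zero(self):
        rec = compare_to_fba(self.make_estimate(0.18), (0.20, (0.16, 0.24)))
        assert rec["inside_range"]
        assert rec["absolute_gap"] == 0.0

    def test_degenerate_range(self):
        rec = compare_to_fba(self.make_estimate(0.14), (0.20, (0.20, 0.20)))
        assert rec["absolute_gap"] == pytest.approx(0.06)


class TestTabularIO:
    def test_round_trip_through_csv(self):
        exp = analytic_replicates(0.14, 0.02, 0.989, 0.5, "experiment", 2)
        ctrl = analytic_replicates(0.14, 0.02, 0.989, 0.5, "control", 2)
        iso, mrm = experiments_to_frames(exp + ctrl)
        iso_buf, mrm_buf = io.StringIO(), io.StringIO()
        iso.to_csv(iso_buf, index=False)
        mrm.to_csv(mrm_buf, index=False)
        iso_buf.seek(0), mrm_buf.seek(0)
        reps = read_isotopologue_csv(iso_buf, mrm_buf)
        assert len(reps) == 4
        by_key = {(r.role, r.replicate): r for r in reps}
        orig = exp[0]
        back = by_key[("experiment", orig.replicate)]
        assert back.distribution("serine").fractions == pytest.approx(
            orig.distribution("serine").fractions
        )
        assert back.mrm.peak_61_1 == pytest.approx(orig.mrm.peak_61_1)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            read_isotopologue_csv(io.StringIO("compound,fraction\nserine,1\n"))
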