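"""EC-coupling metrics on synthetic ground-truth waveforms."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crucell.fixtures import (APSpec, CaTransientSpec, gen_ap,
                              gen_ca_transient)
from crucell.metrics import (ForceParams, apd, detect_eads, ecc_gain,
                             fractional_release, inverse_force_um,
                             notch_depth, predicted_force, predicted_force_um,
                             staircase_potentiation, stats_compare,
                             time_to_peak)


class TestPredictedForce:
    def test_half_maximal_at_pca50(self):
        for nh in (3.0, 3.5, 4.0):
            fp = ForceParams(nH=nh, pCa50=6.0)
            assert predicted_force(1e-6, fp) == pytest.approx(0.5)

    def test_closed_form_value(self):
        # pCa 6.5 with nH=3, pCa50=6 -> 1/(1+10^1.5)
        fp = ForceParams(nH=3.0, pCa50=6.0)
        assert predicted_force(10 ** -6.5, fp) == pytest.approx(
            1.0 / (1.0 + 10 ** 1.5), rel=1e-12)

    def test_limits_and_monotonicity(self):
        fp = ForceParams()
        assert predicted_force(1e-2) > 0.999
        assert predicted_force(1e-12) < 1e-6
        cas = np.logspace(-8, -4, 60)
        forces = [predicted_force(c, fp) for c in cas]
        assert all(b > a for a, b in zip(forces, forces[1:]))

    def test_micromolar_conversion(self):
        # 1 µM -> pCa 6 -> force 0.5 at pCa50 = 6
        assert predicted_force_um(1.0) == pytest.approx(0.5)

    def test_inverse_round_trip(self):
        for f in (0.1, 0.5, 0.9):
            ca = inverse_force_um(f)
            assert predicted_force_um(ca) == pytest.approx(f, rel=1e-10)

    def test_parameter_ranges_validated(self):
        with pytest.raises(ValueError):
            ForceParams(nH=5.0)
        assert ForceParams(nH=5.0, validate=False).nH == 5.0
        with pytest.raises(ValueError):
            predicted_force(0.0)


class TestFractionalRelease:
    @pytest.mark.parametrize("dia, sys, expected",
                             [(1000.0, 1000.0, 0.0),
                              (1000.0, 0.0, 1.0),
                              (1000.0, 600.0, 0.4)])
    def test_arithmetic(self, dia, sys, expected):
        assert fractional_release(dia, sys) == pytest.approx(expected)

    def test_scale_invariance(self):
        assert fractional_release(800.0, 300.0) == pytest.approx(
            fractional_release(8.0, 3.0))

    def test_guards(self):
        with pytest.raises(ValueError):
            fractional_release(0.0, 0.0)
        assert fractional_release(100.0, 120.0) == 0.0   # clamp rule


class TestAPD:
    def test_triangular_ap_analytic(self):
        # peak 40 mV at t=2 ms, linear return to -80 at 302 ms: the 90%
        # level (-68 mV) is crossed 270 ms after the peak -> APD90 = 272 ms
        t = np.arange(0.0, 320.0, 0.5)
        v = np.where(t <= 2.0, -80.0 + 60.0 * t,
                     np.maximum(40.0 - 0.4 * (t - 2.0), -80.0))
        assert apd(t, v) == pytest.approx(272.0, abs=1.0)

    def test_flat_trace_yields_none(self):
        t = np.arange(0.0, 100.0, 0.5)
        assert apd(t, np.full_like(t, -80.0)) is None

    def test_fixture_round_trip(self):
        spec = APSpec(notch_depth=12.0)
        t, v, truth = gen_ap(spec)
        assert apd(t, v) == pytest.approx(truth["apd90"], abs=2.0)


class TestTimeToPeak:
    def test_planted_peak(self):
        t, ca, truth = gen_ca_transient(CaTransientSpec(time_to_peak=37.0))
        assert time_to_peak(t, ca, 0.0) == pytest.approx(0.037, abs=0.001)

    def test_monotone_decay_peaks_at_stimulus(self):
        t = np.arange(0.0, 200.0, 0.5)
        ca = 1.0 * np.exp(-t / 50.0)
        assert time_to_peak(t, ca, 0.0) == 0.0

    def test_empty_segment_rejected(self):
        with pytest.raises(ValueError):
            time_to_peak(np.array([]), np.array([]), 0.0)


class TestNotchDepth:
    def test_planted_notch(self):
        t, v, truth = gen_ap(APSpec(notch_depth=12.0))
        assert notch_depth(t, v) == pytest.approx(12.0, abs=1.5)

    def test_monotone_plateau_gives_zero(self):
        t, v, _ = gen_ap(APSpec(notch_depth=0.0))
        assert notch_depth(t, v) == 0.0

    def test_noise_robustness(self):
        t, v, _ = gen_ap(APSpec(notch_depth=12.0, noise_sd=1.0, seed=5))
        assert notch_depth(t, v, smooth_window=9) == pytest.approx(12.0, abs=4.0)


class TestDetectEADs:
    def test_monotone_repolarization_clean(self):
        t, v, _ = gen_ap(APSpec())
        assert detect_eads(t, v) == []

    def test_two_planted_humps(self):
        spec = APSpec(ead_times=(180.0, 240.0), ead_amplitude=5.0,
                      t_end_repol=320.0, duration=400.0)
        t, v, truth = gen_ap(spec)
        events = detect_eads(t, v, smooth_window=1)
        assert len(events) == 2
        for ev, t_true in zip(events, truth["ead_times"]):
            assert abs(ev["t_peak"] - t_true) < 10.0


class TestEccGain:
    class _FakeTrace:
        def __init__(self, t, j_rel, j_lcc):
            self.data = {"t": t, "J_rel": j_rel, "J_lcc": j_lcc}
            self.meta = {}
            self.t = t

        def __getitem__(self, k):
            return self.data[k]

    def test_ratio_of_planted_peaks(self):
        t = np.arange(0, 100.0, 0.5)
        tr = self._FakeTrace(t, np.full_like(t, 10.0), np.full_like(t, 2.0))
        out = ecc_gain({0.0: tr})
        assert out.gain.iloc[0] == pytest.approx(5.0)

    def test_zero_trigger_reported_missing(self):
        t = np.arange(0, 100.0, 0.5)
        tr = self._FakeTrace(t, np.full_like(t, 10.0), np.zeros_like(t))
        out = ecc_gain({0.0: tr})
        assert np.isnan(out.gain.iloc[0])


class TestStaircase:
    def test_constant_force_ratio_one(self):
        force = np.ones(20)
        labels = np.array([0] * 8 + [1] * 8 + [2] * 4)
        assert staircase_potentiation(force, labels) == pytest.approx(1.0)

    def test_linear_ramp_fixture(self):
        # slow beats at 0.2, rapid beats ramp 0.3..0.7 -> last-5 mean 0.5/0.2
        force = np.array([0.2] * 6 + list(np.linspace(0.3, 0.7, 5)))
        labels = np.array([0] * 6 + [1] * 5)
        assert staircase_potentiation(force, labels) == pytest.approx(
            np.mean(np.linspace(0.3, 0.7, 5)) / 0.2)

    def test_too_few_beats_rejected(self):
        with pytest.raises(ValueError):
            staircase_potentiation(np.ones(6), np.array([0, 0, 0, 1, 1, 1]))


class TestStatsCompare:
    def test_identical_groups_not_significant(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        out = stats_compare({"a": g, "b": g.copy()})
        assert out["paired_t_p"][("a", "b")] == pytest.approx(1.0)
        assert out["anova_p"] > 0.9

    def test_three_group_anova_matches_manual_sums_of_squares(self):
        groups = {"a": np.array([4.0, 5.0, 6.0]),
                  "b": np.array([6.0, 7.0, 8.0]),
                  "c": np.array([9.0, 10.0, 11.0])}
        out = stats_compare(groups)
        # manual one-way ANOVA
        all_vals = np.concatenate(list(groups.values()))
        grand = all_vals.mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2
                         for g in groups.values())
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups.values())
        f_manual = (ss_between / 2) / (ss_within / 6)
        assert out["anova_F"] == pytest.approx(f_manual, rel=1e-10)

    def test_shifted_groups_detected(self):
        """Groups offset by 3 sigma are flagged in >= 95% of replicates."""
        rng = np.random.default_rng(77)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            a = rng.normal(0.0, 1.0, 20)
            b = rng.normal(3.0, 1.0, 20)
            out = stats_compare({"a": a, "b": b})
            if out["anova_p"] < 0.05:
                hits += 1
        assert hits / n_rep >= 0.95

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            stats_compare({"a": np.array([1.0])})
        with pytest.raises(ValueError):
            stats_compare({"a": np.array([1.0, 2.0])})
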