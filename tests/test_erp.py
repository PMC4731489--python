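import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from multierp.erp import (ERPWaveform, amplitude_measure, average_erp,
                          builtin_contrasts, cohens_d_vs_baseline,
                          complexity_comparison, compute_contrast, lrp,
                          matched_amplitude, n2pc)
from multierp.errors import DomainError, ParameterError, SelectionError
from tests.conftest import make_epochs


def _vector_with(mean, sd, n=18, seed=0):
    """n values whose sample mean and SD (ddof=1) are exactly as given."""
    z = np.random.default_rng(seed).standard_normal(n)
    z = (z - z.mean()) / z.std(ddof=1)
    return mean + sd * z


class TestRegistry:
    def test_ten_contrasts(self):
        assert len(builtin_contrasts()) == 10
        assert set(builtin_contrasts()) == {
            "C1", "P50", "MMN", "N1", "P2", "N170", "N2pc", "LRP", "P300",
            "ERN"}

    def test_p300_spec(self):
        spec = builtin_contrasts()["P300"]
        assert spec.channels == ("Pz",)
        assert spec.lock == "stimulus"
        df = pd.DataFrame({"category": ["rare", "frequent"]})
        assert list(spec.condition_a(df)) == [True, False]
        assert list(spec.condition_b(df)) == [False, True]

    def test_ern_is_response_locked(self):
        assert builtin_contrasts()["ERN"].lock == "response"

    def test_n170_is_four_level_factor(self):
        spec = builtin_contrasts()["N170"]
        df = pd.DataFrame({"image": ["MooneyFace", "MooneyDistorted",
                                     "Kanizsa", "KanizsaDistorted"]})
        assert list(spec.factor(df)) == ["FacePresent", "FaceAbsent",
                                         "ShapePresent", "ShapeAbsent"]

    def test_predicates_disjoint(self):
        df = pd.DataFrame({
            "category": ["rare", "frequent"], "distractor": ["top", "bottom"],
            "accuracy": ["correct", "incorrect"],
            "event_type": ["tone_s1", "tone_s2"],
            "tone_is_deviant": [True, False],
            "cd_tone": ["random_delay", "on_response"],
            "tone_pair_type": ["none", "none"]})
        for spec in builtin_contrasts().values():
            if spec.condition_a is None:
                continue
            both = spec.condition_a(df) & spec.condition_b(df)
            assert not both.any()


class TestAverage:
    def test_identical_epochs(self):
        data = np.tile(np.arange(50.0), (2, 1, 1)).reshape(2, 1, 50)
        es = make_epochs(data)
        w = average_erp(es, np.array([True, True]), "ch0")
        assert np.allclose(w.mean_uv, data[0, 0])
        assert w.n == 2

    def test_empty_selection_raises(self):
        es = make_epochs(np.zeros((2, 1, 10)))
        with pytest.raises(SelectionError):
            average_erp(es, np.array([False, False]), "ch0")


class TestLRP:
    def _epochs(self, c3_traces, c4_traces, buttons):
        n = len(buttons)
        t = len(c3_traces[0])
        data = np.zeros((n, 2, t))
        data[:, 0] = c3_traces
        data[:, 1] = c4_traces
        labels = pd.DataFrame({"button": buttons})
        return make_epochs(data, labels, channels=("C3", "C4"),
                           lock="response")

    def test_symmetric_null(self):
        trace = np.ones(40)
        es = self._epochs([trace] * 4, [trace] * 4,
                          ["left", "left", "right", "right"])
        assert np.allclose(lrp(es).mean_uv, 0)

    def test_recovers_contralateral_negativity(self):
        t = np.zeros(40)
        contra = t - 2.0        # flat -2 uV on the contralateral channel
        es = self._epochs(
            c3_traces=[t, contra], c4_traces=[contra, t],
            buttons=["left", "right"])
        assert np.allclose(lrp(es).mean_uv, -2.0)

    def test_label_swap_flips_sign(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((6, 2, 40))
        labels = pd.DataFrame({"button": ["left", "right"] * 3})
        es = make_epochs(data, labels, channels=("C3", "C4"))
        assert np.allclose(lrp(es, "C3", "C4").mean_uv,
                           -lrp(es, "C4", "C3").mean_uv)

    def test_single_hand_rejected(self):
        es = self._epochs([np.zeros(10)], [np.zeros(10)], ["left"])
        with pytest.raises(SelectionError):
            lrp(es)


class TestN2pc:
    def _epochs(self, po7, po8, sides):
        n = len(sides)
        data = np.zeros((n, 2, 30))
        data[:, 0] = po7
        data[:, 1] = po8
        labels = pd.DataFrame({"side": sides})
        return make_epochs(data, labels, channels=("PO7", "PO8"))

    def test_balanced_null(self):
        z = np.ones(30)
        es = self._epochs([z] * 4, [z] * 4, ["left", "right"] * 2)
        assert np.allclose(n2pc(es).mean_uv, 0)

    def test_recovers_contralateral_negativity(self):
        flat = np.zeros(30)
        dip = flat - 1.5
        # target left -> contra channel is PO8; target right -> PO7
        es = self._epochs(po7=[flat, dip], po8=[dip, flat],
                          sides=["left", "right"])
        assert np.allclose(n2pc(es).mean_uv, -1.5)

    def test_label_swap_flips_sign(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((6, 2, 30))
        labels = pd.DataFrame({"side": ["left", "right"] * 3})
        es = make_epochs(data, labels, channels=("PO7", "PO8"))
        assert np.allclose(n2pc(es, "PO7", "PO8").mean_uv,
                           -n2pc(es, "PO8", "PO7").mean_uv)

    def test_one_sided_rejected(self):
        es = self._epochs([np.zeros(30)], [np.zeros(30)], ["left"])
        with pytest.raises(SelectionError):
            n2pc(es)


class TestAmplitude:
    def _wave(self, values, t0=-100.0, srate=250.0):
        values = np.asarray(values, float)
        times = t0 + np.arange(len(values)) * 1000.0 / srate
        return ERPWaveform("Pz", times, values, n=1)

    def test_constant_mean(self):
        w = self._wave(np.full(100, 3.0))
        assert amplitude_measure(w, (0, 200), "mean") == pytest.approx(3.0)

    def test_off_window_spike_ignored(self):
        v = np.zeros(100)
        v[0] = 50.0  # at -100 ms, outside the window
        w = self._wave(v)
        assert amplitude_measure(w, (0, 200), "peak") == 0.0

    def test_peak_is_signed_extremum(self):
        v = np.zeros(100)
        v[50] = -4.0
        w = self._wave(v)
        assert amplitude_measure(w, (-100, 290), "peak") == -4.0

    def test_empty_window_rejected(self):
        w = self._wave(np.zeros(10))
        with pytest.raises(ParameterError):
            amplitude_measure(w, (5000, 6000), "mean")

    def test_matched_amplitude_recovers_gaussian(self):
        times = np.arange(-100, 400, 4.0)
        env = 3.5 * np.exp(-0.5 * ((times - 120) / 30) ** 2)
        w = ERPWaveform("Cz", times, env, n=1)
        assert matched_amplitude(w, 120, 30) == pytest.approx(3.5, abs=1e-6)


class TestCohensD:
    def test_table_value_c1(self):
        x = _vector_with(-1.0, 0.44)
        assert round(abs(cohens_d_vs_baseline(x)), 2) == 2.27

    def test_table_value_p300(self):
        x = _vector_with(3.23, 1.49)
        assert round(cohens_d_vs_baseline(x), 2) == 2.17

    def test_zero_variance_rejected(self):
        with pytest.raises(DomainError):
            cohens_d_vs_baseline([2.0, 2.0, 2.0])

    def test_single_value_rejected(self):
        with pytest.raises(DomainError):
            cohens_d_vs_baseline([1.0])

    @given(k=st.floats(0.1, 50), mean=st.floats(-5, 5),
           sd=st.floats(0.2, 4))
    def test_scale_invariance(self, k, mean, sd):
        x = _vector_with(mean, sd, seed=3)
        d0 = cohens_d_vs_baseline(x)
        dk = cohens_d_vs_baseline(k * x)
        assert dk == pytest.approx(d0, rel=1e-9)


class TestComplexity:
    def _level_epochs(self, scale, n=20):
        rng = np.random.default_rng(42)
        times_n = 250
        data = np.zeros((n, 1, times_n))
        t = -200 + np.arange(times_n) * 4.0
        bump = np.exp(-0.5 * ((t - 220) / 35) ** 2)
        for i in range(n):
            data[i, 0] = -3.0 * scale * bump + 0.1 * rng.standard_normal(
                times_n)
        labels = pd.DataFrame({"image": ["MooneyFace"] * n,
                               "side": ["left", "right"] * (n // 2)})
        return make_epochs(data, labels, channels=("PO8",))

    def test_recovers_injected_ordering(self):
        sets = {"Learn": self._level_epochs(0.5),
                "Who": self._level_epochs(0.8),
                "Discern": self._level_epochs(1.0)}
        out = complexity_comparison("N170", sets, condition="FacePresent")
        amps = out["amplitudes"]
        assert abs(amps["Learn"]) < abs(amps["Who"]) < abs(amps["Discern"])
        assert out["monotone_increasing_magnitude"]

    def test_identical_injections_flat(self):
        sets = {lv: self._level_epochs(1.0) for lv in ("Learn", "Who")}
        out = complexity_comparison("N170", sets, condition="FacePresent")
        a = list(out["amplitudes"].values())
        assert abs(a[0] - a[1]) < 0.2

    def test_single_level(self):
        sets = {"Who": self._level_epochs(1.0)}
        out = complexity_comparison("N170", sets, condition="FacePresent")
        assert len(out["waveforms"]) == 1
        assert not out["monotone_increasing_magnitude"]


class TestComputeContrast:
    def test_difference_wave(self):
        data = np.zeros((4, 1, 50))
        data[:2] = 5.0  # rare
        data[2:] = 1.0  # frequent
        labels = pd.DataFrame({"category": ["rare", "rare", "frequent",
                                            "frequent"]})
        es = make_epochs(data, labels, channels=("Pz",))
        res = compute_contrast(builtin_contrasts()["P300"], es)
        assert np.allclose(res.difference.mean_uv, 4.0)
        assert res.waveforms["A"].n == 2
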