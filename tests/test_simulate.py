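import numpy as np
import pandas as pd
import pytest
from scipy import stats

from multierp import (Level, Montage, ParadigmConfig, SubjectProfile,
                      default_templates, generate_level, pink_noise,
                      simulate_behavior, simulate_recording)
from multierp.errors import ParameterError
from multierp.simulate import (CD_ATTENUATION, build_event_table,
                               render_component)


class TestMontage:
    def test_default_has_19_channels(self):
        assert len(Montage().channels) == 19

    def test_duplicate_names_rejected(self):
        with pytest.raises(ParameterError):
            Montage(channels=("Cz", "Cz", "Pz", "POz", "PO7", "PO8", "FCz",
                              "C3", "C4"))

    def test_missing_contrast_channel_rejected(self):
        with pytest.raises(ParameterError):
            Montage(channels=("Cz", "Pz"))


class TestBehavior:
    def test_passive_blocks_have_no_responses(self, learn_schedule):
        beh = simulate_behavior(learn_schedule, SubjectProfile(), seed=0)
        merged = learn_schedule.trials.merge(beh[["trial", "button"]],
                                             on="trial")
        passive = merged[merged["block_mode"] == "passive"]
        assert set(passive["button"]) == {"none"}

    def test_degenerate_profile_all_correct(self, who_schedule):
        prof = SubjectProfile(rt_median_ms=300, rt_sigma=0.01,
                              accuracy={lv.value: 1.0 for lv in Level})
        beh = simulate_behavior(who_schedule, prof, seed=0)
        stim = beh[beh["kind"] == "stimulus"]
        assert set(stim["accuracy"]) == {"correct"}

    def test_discern_more_errors_than_who(self, default_config):
        who_err, dis_err = 0, 0
        n_who, n_dis = 0, 0
        for seed in range(3):  # ~1200 active trials per level
            who = generate_level(Level.WHO, default_config, seed)
            dis = generate_level(Level.DISCERN, default_config, seed)
            bw = simulate_behavior(who, SubjectProfile(), seed)
            bd = simulate_behavior(dis, SubjectProfile(), seed)
            who_err += (bw["accuracy"] == "incorrect").sum()
            n_who += (bw["accuracy"].isin(["correct", "incorrect"])).sum()
            dis_err += (bd["accuracy"] == "incorrect").sum()
            n_dis += (bd["accuracy"].isin(["correct", "incorrect"])).sum()
        # one-sided two-proportion comparison at p < 0.01
        res = stats.binomtest(int(dis_err), int(n_dis), who_err / n_who,
                              alternative="greater")
        assert res.pvalue < 0.01

    def test_post_reversal_block_has_elevated_errors(self, default_config):
        errs_first_b, errs_rest_b = [], []
        for seed in range(5):
            dis = generate_level(Level.DISCERN, default_config, seed)
            beh = simulate_behavior(dis, SubjectProfile(), seed)
            merged = dis.trials.merge(beh[["trial", "accuracy"]], on="trial")
            active = merged[merged["accuracy"].isin(["correct", "incorrect"])]
            first_b = active[active["block"] == 9]
            rest_b = active[active["block"] > 9]
            errs_first_b.append((first_b["accuracy"] == "incorrect").mean())
            errs_rest_b.append((rest_b["accuracy"] == "incorrect").mean())
        assert np.mean(errs_first_b) > np.mean(errs_rest_b)

    def test_rt_truncated_at_response_window(self, who_schedule):
        beh = simulate_behavior(who_schedule, SubjectProfile(), seed=2)
        assert beh["rt_ms"].max() <= 700


class TestPinkNoise:
    def test_spectral_slope_near_minus_one(self):
        sig = pink_noise(2, 250 * 60, 250.0, 5.0, seed=0)
        f, p = __import__("scipy.signal", fromlist=["welch"]).welch(
            sig[0], fs=250, nperseg=2048)
        band = (f >= 1) & (f <= 40)
        slope = np.polyfit(np.log10(f[band]), np.log10(p[band]), 1)[0]
        assert -1.3 <= slope <= -0.7

    def test_zero_amplitude_gives_zeros(self):
        assert not pink_noise(1, 1000, 250.0, 0.0, seed=1).any()

    def test_seeded_determinism(self):
        a = pink_noise(2, 1000, 250.0, 3.0, seed=5)
        b = pink_noise(2, 1000, 250.0, 3.0, seed=5)
        assert np.array_equal(a, b)

    def test_channels_independent(self):
        sig = pink_noise(2, 250 * 30, 250.0, 5.0, seed=2)
        r = np.corrcoef(sig)[0, 1]
        assert abs(r) < 0.2

    def test_rms_matches_amplitude(self):
        sig = pink_noise(1, 250 * 30, 250.0, 7.5, seed=3)
        assert abs(sig.std() - 7.5) / 7.5 < 0.01

    def test_too_short_rejected(self):
        with pytest.raises(ParameterError):
            pink_noise(1, 100, 250.0, 1.0)


class TestRenderComponent:
    def _events(self, sample, **fields):
        base = {"sample": sample, "event_type": "stimulus",
                "distractor": "top", "category": "frequent",
                "side": "left", "image": "MooneyFace", "level": "Who",
                "button": "none", "accuracy": "na", "cd_tone": "none",
                "tone_is_deviant": False}
        base.update(fields)
        return pd.DataFrame([base])

    def test_zero_amplitude_yields_zero_signal(self):
        tpl = [t for t in default_templates() if t.name == "C1"][0]
        ev = self._events(500, distractor="none")  # C1 rule gives 0
        sig = render_component(tpl, ev, Montage(), 2000, 250.0)
        assert not sig.any()

    def test_c1_polarity_rule(self):
        tpl = [t for t in default_templates() if t.name == "C1"][0]
        mont = Montage()
        top = render_component(tpl, self._events(500, distractor="top"),
                               mont, 2000, 250.0)
        bottom = render_component(tpl, self._events(500, distractor="bottom"),
                                  mont, 2000, 250.0)
        poz = mont.index("POz")
        peak = 500 + int(round(tpl.peak_latency_ms * 0.25))
        assert top[poz, peak] < 0 < bottom[poz, peak]
        assert np.allclose(top, -bottom)

    def test_event_beyond_end_skipped(self):
        tpl = [t for t in default_templates() if t.name == "P300"][0]
        ev = self._events(1990, category="rare")
        sig = render_component(tpl, ev, Montage(), 2000, 250.0)
        assert not sig.any()

    def test_superposition_linearity(self):
        tpl = [t for t in default_templates() if t.name == "P300"][0]
        mont = Montage()
        e1 = self._events(400, category="rare")
        e2 = self._events(900, category="rare")
        both = pd.concat([e1, e2], ignore_index=True)
        sig = render_component(tpl, both, mont, 2000, 250.0)
        expected = (render_component(tpl, e1, mont, 2000, 250.0)
                    + render_component(tpl, e2, mont, 2000, 250.0))
        assert np.allclose(sig, expected)


class TestRecording:
    def test_duration_covers_schedule(self, small_who_schedule,
                                      small_who_recording):
        rec = small_who_recording
        expect_s = (small_who_schedule.total_duration_ms + 4000) / 1000.0
        assert abs(rec.duration_s - expect_s) < 0.01

    def test_events_sorted_and_sample_accurate(self, small_who_recording):
        ev = small_who_recording.events
        assert ev["sample"].is_monotonic_increasing
        assert (np.abs(ev["sample"] - ev["onset_ms"] * 0.25) <= 0.5).all()

    def test_deterministic(self, small_who_schedule):
        a = simulate_recording(small_who_schedule, seed=42)
        b = simulate_recording(small_who_schedule, seed=42)
        assert np.array_equal(a.signal, b.signal)
        pd.testing.assert_frame_equal(a.events, b.events)

    def test_noiseless_epoch_average_equals_template(self, small_config):
        # P300-only simulation with zero noise: the rare-trial average at
        # Pz must reproduce the injected deflection exactly
        sched = generate_level(Level.WHO, small_config, seed=2)
        tpl = [t for t in default_templates() if t.name == "P300"]
        rec = simulate_recording(sched, profile=SubjectProfile(noise_uv=0),
                                 templates=tpl, seed=2)
        mont = rec.montage
        stim = rec.events.query("event_type == 'stimulus' and "
                                "category == 'rare'")
        pz = mont.index("Pz")
        peak_amp = []
        for s in stim["sample"]:
            peak_amp.append(rec.signal[pz, int(s + round(400 * 0.25))])
        assert np.allclose(peak_amp, 5.0, atol=1e-9)

    def test_cd_attenuation_in_who(self, small_who_recording):
        ev = small_who_recording.events
        cd = ev.query("event_type == 'tone_cd'")
        assert set(cd["cd_tone"]) == {"on_response", "random_delay"}
        tpl = [t for t in default_templates() if t.name == "N1"][0]
        a_imm = tpl.amplitude(
            {"event_type": "tone_cd", "cd_tone": "on_response"})
        a_ext = tpl.amplitude(
            {"event_type": "tone_cd", "cd_tone": "random_delay"})
        assert a_imm == pytest.approx(CD_ATTENUATION * a_ext)

    def test_srate_too_low_rejected(self, small_who_schedule):
        with pytest.raises(ParameterError):
            simulate_recording(small_who_schedule, srate_hz=50.0)


class TestEventTable:
    def test_baseline_trials_have_only_trial_start(self, small_who_schedule):
        ev = build_event_table(small_who_schedule, None, 250.0)
        base = ev[ev["kind"] == "baseline"]
        assert set(base["event_type"]) == {"trial_start"}

    def test_silent_slots_emit_no_tone_events(self, small_who_schedule):
        ev = build_event_table(small_who_schedule, None, 250.0)
        silent = ev[ev["tone_pair_type"] == "silent"]
        assert not silent["event_type"].isin(["tone_s1", "tone_s2"]).any()

    def test_tone_pair_gap_500ms(self, small_who_schedule):
        ev = build_event_table(small_who_schedule, None, 250.0)
        s1 = ev.query("event_type == 'tone_s1'").set_index("trial")["onset_ms"]
        s2 = ev.query("event_type == 'tone_s2'").set_index("trial")["onset_ms"]
        assert ((s2 - s1) == 500).all()
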