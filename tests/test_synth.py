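"""Generator statistics: planted effects must be present and recoverable."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import tempocontext as tc
from tempocontext import context, synth


def _sides(angles, plane="task_related"):
    return np.asarray(context.side_of_plane(angles, plane, "left_right"))


class TestGenLocations:
    def test_biased_repeat_fraction(self):
        cfg = tc.SimConfig(n_blocks=10, trials_per_block=1000)
        bias = tc.BiasSpec(plane="task_related", p_repeat=0.75,
                           second_plane_p_repeat=0.5)
        rng = np.random.default_rng(0)
        a = synth.gen_locations(cfg, bias, rng)
        s = _sides(a)
        within = np.arange(1, a.size) % cfg.trials_per_block != 0
        frac = (s[1:][within] == s[:-1][within]).mean()
        # 99% binomial interval around 0.75
        half = 2.576 * np.sqrt(0.75 * 0.25 / within.sum())
        assert abs(frac - 0.75) < half

    def test_degenerate_probability_one(self):
        cfg = tc.SimConfig(n_blocks=2, trials_per_block=50)
        bias = tc.BiasSpec(p_repeat=1.0, second_plane_p_repeat=1.0)
        a = synth.gen_locations(cfg, bias, np.random.default_rng(1))
        s = _sides(a)
        u = _sides(a, "task_unrelated")
        for b in range(2):
            blk = slice(b * 50, (b + 1) * 50)
            assert np.all(s[blk] == s[blk][0])
            assert np.all(u[blk] == u[blk][0])

    def test_unbiased_marginal_uniform(self):
        cfg = tc.SimConfig(n_blocks=1, trials_per_block=50_000)
        a = synth.gen_locations(cfg, tc.BiasSpec.experiment1(),
                                np.random.default_rng(2))
        p = stats.kstest(a / 360.0, "uniform").pvalue
        assert p > 0.01

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            tc.BiasSpec(p_repeat=1.2)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = tc.SimConfig(n_blocks=2, trials_per_block=50, n_sensors=6,
                           sample_rate=64.0)
        truth = tc.GroundTruth(drift_sd=1.0)
        a = tc.simulate_experiment("2", cfg, truth, seed=5)
        b = tc.simulate_experiment("2", cfg, truth, seed=5)
        pd.testing.assert_frame_equal(a["trials"], b["trials"])
        np.testing.assert_array_equal(a["pupil"][0], b["pupil"][0])

    def test_different_seeds_differ(self):
        cfg = tc.SimConfig(n_blocks=1, trials_per_block=50)
        a = tc.simulate_experiment("1", cfg, seed=1)["trials"]
        b = tc.simulate_experiment("1", cfg, seed=2)["trials"]
        assert not np.allclose(a["angle_deg"], b["angle_deg"])


class TestBinaryResponses:
    def _labeled(self, n, rng, p=0.75):
        cfg = tc.SimConfig(n_blocks=1, trials_per_block=n, repro_fraction=0.0)
        bias = tc.BiasSpec(p_repeat=p, second_plane_p_repeat=p)
        angles = synth.gen_locations(cfg, bias, rng)
        df = context.label_trials(pd.DataFrame({"angle_deg": angles}),
                                  p_repeat_task=p, p_repeat_unrelated=p)
        return angles, df

    def test_null_context_effect(self):
        rng = np.random.default_rng(0)
        angles, df = self._labeled(10_000, rng)
        truth = tc.GroundTruth(rt_context_effect=0.0)
        resp = synth.gen_binary_responses(angles, df, truth, rng)
        m = df["macro_task_related"].to_numpy()
        diff = (np.median(resp.loc[m == "unexpected", "rt_s"])
                - np.median(resp.loc[m == "expected", "rt_s"]))
        assert abs(diff) < 0.01

    def test_planted_rt_effect_recovered(self):
        rng = np.random.default_rng(1)
        angles, df = self._labeled(10_000, rng)
        truth = tc.GroundTruth(rt_context_effect=0.03)
        resp = synth.gen_binary_responses(angles, df, truth, rng)
        m = df["macro_task_related"].to_numpy()
        diff = (np.median(resp.loc[m == "unexpected", "rt_s"])
                - np.median(resp.loc[m == "expected", "rt_s"]))
        # the additive shift moves the median by exactly its own size
        assert diff == pytest.approx(0.03, abs=0.012)

    def test_perfect_accuracy(self):
        rng = np.random.default_rng(2)
        angles, df = self._labeled(500, rng)
        truth = tc.GroundTruth(acc_expected=1.0, acc_unexpected=1.0)
        resp = synth.gen_binary_responses(angles, df, truth, rng)
        assert resp["correct"].all()
        sides = _sides(angles)
        np.testing.assert_array_equal(resp["response"].to_numpy(), sides)

    def test_all_rts_exceed_shift(self):
        rng = np.random.default_rng(3)
        angles, df = self._labeled(1000, rng)
        truth = tc.GroundTruth()
        resp = synth.gen_binary_responses(angles, df, truth, rng)
        assert (resp["rt_s"] > truth.rt_t0).all()

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            synth.gen_binary_responses(
                np.zeros(5), pd.DataFrame({"x": [1, 2]}), tc.GroundTruth(),
                np.random.default_rng(0))


class TestReproductions:
    def test_flag_fraction(self):
        cfg = tc.SimConfig(n_blocks=1, trials_per_block=20_000,
                           repro_fraction=0.10)
        rng = np.random.default_rng(0)
        flags, _, _ = synth.gen_reproductions(np.zeros(20_000), None,
                                              tc.GroundTruth(), cfg, rng)
        half = 2.576 * np.sqrt(0.1 * 0.9 / 20_000)
        assert abs(flags.mean() - 0.10) < half

    def test_pure_guessing_uniform(self):
        cfg = tc.SimConfig(n_blocks=1, trials_per_block=5000,
                           repro_fraction=1.0)
        rng = np.random.default_rng(1)
        truth = tc.GroundTruth(guess_rate=1.0)
        _, _, err = synth.gen_reproductions(np.zeros(5000), None, truth, cfg,
                                            rng)
        p = stats.kstest((err + 180) / 360.0, "uniform").pvalue
        assert p > 0.01

    def test_serial_bias_curve_shape(self):
        d = np.array([-90.0, -45.0, 0.0, 45.0, 90.0])
        mu = synth.serial_bias_curve(d, amplitude=2.0, width=45.0)
        assert mu[2] == 0.0
        assert mu[3] == pytest.approx(2.0)     # peak at delta = width
        assert mu[1] == pytest.approx(-2.0)
        assert abs(mu[0]) < 2.0 and abs(mu[4]) < 2.0


class TestPupilGen:
    def test_blinks_all_detected(self):
        from tempocontext.pupil import detect_blinks

        cfg = tc.SimConfig(n_blocks=1, trials_per_block=30, repro_fraction=0.0)
        truth = tc.GroundTruth(blink_rate_hz=0.2)
        rng = np.random.default_rng(0)
        labels = pd.DataFrame({"macro_task_related": ["expected"] * 30})
        trace, events, episodes = synth.gen_pupil(labels, truth, cfg, rng)
        mask = detect_blinks(trace, cfg.pupil_rate)
        for s, e in episodes:
            i0, i1 = int(s * cfg.pupil_rate), int(e * cfg.pupil_rate)
            assert mask[i0:i1].all()
        assert len(episodes) >= 1

    def test_event_count_and_spacing(self):
        cfg = tc.SimConfig(n_blocks=1, trials_per_block=20, repro_fraction=0.0)
        rng = np.random.default_rng(1)
        labels = pd.DataFrame({"macro_task_related": [None] * 20})
        trace, events, _ = synth.gen_pupil(labels, tc.GroundTruth(), rng=rng,
                                           config=cfg)
        assert events.size == 20
        np.testing.assert_allclose(np.diff(events), cfg.iti_s)


class TestEpochGen:
    def test_no_signal_before_onset(self, signal_epochs):
        pre = signal_epochs.times < 0.05
        truth_free = signal_epochs.data[:, :, pre]
        # pre-onset samples contain only noise: no angle information
        from tempocontext.iem import make_basis

        basis = make_basis()
        C = basis(signal_epochs.angles)
        corr = np.corrcoef(C[0], truth_free.mean(axis=(1, 2)))[0, 1]
        assert abs(corr) < 0.2

    def test_noiseless_decodes_accurately(self):
        cfg = tc.SimConfig(n_blocks=1, trials_per_block=120, n_sensors=10,
                           sample_rate=64.0)
        truth = tc.GroundTruth(noise_sd=0.0)
        rng = np.random.default_rng(5)
        angles = rng.uniform(0, 360, 120)
        ep = synth.gen_epochs(angles, None, truth, cfg, rng)
        from tempocontext.iem import crossval_iem

        res = crossval_iem(ep, n_folds=5, random_state=0)
        peak = np.nanmax(res.accuracy)
        # high but not exactly 1: the rectified fifth-power basis carries a
        # deterministic aliasing bias through the phasor decoder
        assert peak > 0.95

    def test_gain_modulates_pattern_energy(self):
        cfg = tc.SimConfig(n_blocks=1, trials_per_block=200, n_sensors=8,
                           sample_rate=64.0)
        truth = tc.GroundTruth(gain_expected=0.5, gain_unexpected=2.0,
                               noise_sd=0.0)
        rng = np.random.default_rng(6)
        labels = pd.DataFrame({"macro_task_related":
                               ["expected", "unexpected"] * 100})
        ep = synth.gen_epochs(rng.uniform(0, 360, 200), labels, truth, cfg, rng)
        energy = (ep.data ** 2).sum(axis=(1, 2))
        assert energy[1::2].mean() > 4 * energy[::2].mean()


class TestCounterbalance:
    def test_eight_distinct_conditions(self):
        conds = synth.counterbalance_conditions()
        assert len(conds) == 8
        assert len(set(conds)) == 8
        axes = {c[0] for c in conds}
        assert axes == {"left_right", "above_below"}
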