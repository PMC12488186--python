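"""Synthetic behavioral, pupil, and sensor-epoch data generator.

Emulates the three psychophysics experiments and the re-analyzed EEG
paradigm so that every downstream stage can be verified by parameter
recovery:

* Experiment 1 — angles uniform on the circle, blocks of 100 trials, 10%
  reproduction trials, repeat/alternate equiprobable on both task planes.
* Experiments 2/3 — quadrant-biased sampling: the side of each task plane
  repeats with probability 0.75 (or 0.25) relative to the previous trial
  under a 2 (task plane) x 2 (left/right bias) x 2 (above/below bias)
  counterbalanced design; the angle is then uniform within the selected
  quadrant, so the bias affects transition statistics, not marginal
  location.
* EEG-like epochs — -0.125..0.5 s at 512 Hz, sensor patterns driven by
  five angle-tuned channels, with expectation-dependent response gain and
  latency, spatially correlated noise, and a slow AR(1) across-trial drift
  shared over sensors. The drift is the mechanism that biases a
  side-of-plane classifier toward repeat classifications and is what the
  shuffle-label baseline correction removes.

All randomness flows through an explicit ``numpy.random.Generator``.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .context import label_trials
from .iem import make_basis


@dataclass
class BiasSpec:
    """Repeat-probability bias of the quadrant sampler.

    ``p_repeat`` applies to ``plane`` and ``second_plane_p_repeat`` to the
    orthogonal plane. Experiment 1 is ``p_repeat = 0.5`` on both planes.
    """

    plane: str = "task_related"
    p_repeat: float = 0.5
    second_plane_p_repeat: float = 0.5

    def __post_init__(self):
        if self.plane not in ("task_related", "task_unrelated"):
            raise ValueError(f"unknown plane {self.plane!r}")
        for p in (self.p_repeat, self.second_plane_p_repeat):
            if not 0.0 <= p <= 1.0:
                raise ValueError("repeat probabilities must be in [0, 1]")

    def p_for(self, plane):
        if plane == self.plane:
            return self.p_repeat
        return self.second_plane_p_repeat

    @classmethod
    def experiment1(cls):
        return cls(p_repeat=0.5, second_plane_p_repeat=0.5)

    @classmethod
    def experiment2(cls, plane="task_related", repeat_biased=True):
        p = 0.75 if repeat_biased else 0.25
        return cls(plane=plane, p_repeat=p, second_plane_p_repeat=0.75)


def counterbalance_conditions():
    """The eight bias conditions of the 2 x 2 x 2 counterbalanced design.

    Returns a list of ``(task_axis, p_repeat_leftright, p_repeat_abovebelow)``
    tuples: task reference plane (which axis the judgement uses) crossed
    with a 0.75/0.25 repeat bias on each of the two meridians.
    """
    conds = []
    for axis, p_lr, p_ab in itertools.product(
        ("left_right", "above_below"), (0.75, 0.25), (0.75, 0.25)
    ):
        conds.append((axis, p_lr, p_ab))
    return conds


@dataclass
class SimConfig:
    """Structural parameters of a simulated session."""

    n_blocks: int = 15
    trials_per_block: int = 100
    repro_fraction: float = 0.10
    task_axis: str = "left_right"
    n_sensors: int = 16
    sample_rate: float = 512.0
    epoch_window: tuple = (-0.125, 0.5)
    pupil_rate: float = 1000.0
    iti_s: float = 2.5          # event spacing for the pupil trace
    soa_s: float = 0.3          # stimulus onset asynchrony of the EEG stream

    def __post_init__(self):
        if not 0.0 <= self.repro_fraction <= 1.0:
            raise ValueError("repro_fraction must be in [0, 1]")
        if self.sample_rate <= 0 or self.pupil_rate <= 0:
            raise ValueError("rates must be positive")
        if self.epoch_window[0] >= self.epoch_window[1]:
            raise ValueError("epoch_window start must precede end")

    @property
    def n_trials(self):
        return self.n_blocks * self.trials_per_block


@dataclass
class GroundTruth:
    """Planted effect sizes and noise parameters; the recovery test surface.

    kappa / kappa_by_condition : von Mises concentration of reproduction
        errors (optionally per macro condition).
    guess_rate : uniform-mixture weight g in [0, 1].
    serial_bias_amplitude / width : derivative-of-Gaussian bias of
        reproduction errors as a function of delta location (deg); positive
        amplitude = repulsion away from the previous stimulus.
    rt_* : shifted log-normal response times; ``rt_context_effect`` is added
        to unexpected trials (expected faster).
    acc_expected / acc_unexpected : probability of a correct speeded choice.
    gain_expected / gain_unexpected : evoked-response scaling per macro (or
        micro, when no macro labels exist) condition.
    latency_shift : extra evoked latency of expected stimuli (s); encodes
        the "unexpected classified earlier" effect.
    drift_sd : stationary sd of the AR(1) across-trial drift.
    pupil_surprise_gain : fractional dilation increase per unit surprise
        (macro: unexpected = 1; meso: (rank-1)/7).
    """

    kappa: float = 8.0
    kappa_by_condition: dict | None = None
    guess_rate: float = 0.1
    serial_bias_amplitude: float = 2.0
    serial_bias_width: float = 45.0
    rt_t0: float = 0.25
    rt_logmean: float = -1.1
    rt_logsd: float = 0.35
    rt_context_effect: float = 0.03
    acc_expected: float = 0.97
    acc_unexpected: float = 0.93
    gain_expected: float = 1.0
    gain_unexpected: float = 1.0
    latency_shift: float = 0.02
    drift_sd: float = 0.0
    noise_sd: float = 1.0
    signal_amplitude: float = 1.0
    pupil_amp: float = 1.0
    pupil_surprise_gain: float = 0.5
    pupil_noise_sd: float = 0.1
    blink_rate_hz: float = 0.05
    blink_duration_s: float = 0.15

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if not 0.0 <= self.guess_rate <= 1.0:
            raise ValueError("guess_rate must be in [0, 1]")
        if self.gain_expected <= 0 or self.gain_unexpected <= 0:
            raise ValueError("gains must be positive")

    def kappa_for(self, condition):
        if self.kappa_by_condition and condition in self.kappa_by_condition:
            return self.kappa_by_condition[condition]
        return self.kappa


_QUADRANT_BASE = {(1, 1): 0.0, (-1, 1): 90.0, (-1, -1): 180.0, (1, -1): 270.0}


def gen_locations(config, bias, rng):
    """Sample per-trial stimulus angles under the quadrant-biased design.

    The first trial of each block is uniform on [0, 360). Each later
    trial's side on each task plane repeats the previous trial's side with
    that plane's repeat probability; the angle is then uniform within the
    selected quadrant. With 0.5 on both planes, angles are marginally
    uniform.
    """
    n = config.n_trials
    angles = np.empty(n)
    p_x, p_y = _plane_probs(config.task_axis, bias)
    u = rng.random((n, 3))
    for j in range(n):
        if j % config.trials_per_block == 0:
            angles[j] = u[j, 2] * 360.0
            continue
        prev = np.radians(angles[j - 1])
        sx = 1 if np.cos(prev) >= 0 else -1
        sy = 1 if np.sin(prev) >= 0 else -1
        sx *= 1 if u[j, 0] < p_x else -1
        sy *= 1 if u[j, 1] < p_y else -1
        angles[j] = _QUADRANT_BASE[(sx, sy)] + u[j, 2] * 90.0
    return angles


def _plane_probs(task_axis, bias):
    """Repeat probabilities for the x (left/right) and y (above/below) sides."""
    p_task = bias.p_for("task_related")
    p_unrel = bias.p_for("task_unrelated")
    if task_axis == "left_right":
        return p_task, p_unrel
    return p_unrel, p_task


def _macro_indicator(labels, plane="task_related"):
    """1 where unexpected, 0 where expected, 0 where undefined."""
    col = f"macro_{plane}"
    if labels is None or col not in labels:
        return None
    lab = labels[col].to_numpy()
    return np.array([1.0 if v == "unexpected" else 0.0 for v in lab]), np.array(
        [v in ("expected", "unexpected") for v in lab]
    )


def gen_binary_responses(angles, labels, truth, rng, task_axis="left_right"):
    """Speeded binary judgement: choice correctness and response time.

    RT is a shifted log-normal (all RTs > t0) plus an additive context
    effect on unexpected trials; choices are correct with a
    context-dependent probability.
    """
    angles = np.asarray(angles, dtype=float)
    n = angles.size
    if labels is not None and len(labels) != n:
        raise ValueError("labels must align with angles")
    macro = _macro_indicator(labels)
    if macro is None:
        unexpected = np.zeros(n)
    else:
        unexpected = macro[0]
    rt = truth.rt_t0 + rng.lognormal(truth.rt_logmean, truth.rt_logsd, n)
    rt = rt + truth.rt_context_effect * unexpected
    p_correct = np.where(unexpected > 0, truth.acc_unexpected, truth.acc_expected)
    correct = rng.random(n) < p_correct
    from .context import side_of_plane

    true_side = np.asarray(side_of_plane(angles, "task_related", task_axis))
    response = np.where(correct, true_side, -true_side)
    return pd.DataFrame({"response": response, "correct": correct, "rt_s": rt})


def serial_bias_curve(delta, amplitude, width=45.0):
    """Derivative-of-Gaussian bias (deg) at delta location (deg).

    Peaks at ``delta == width`` with value ``amplitude``; positive amplitude
    means errors directed away from the previous stimulus (repulsion).
    """
    d = np.asarray(delta, dtype=float) / float(width)
    return amplitude * d * np.exp(0.5 * (1.0 - d * d))


def gen_reproductions(angles, labels, truth, config, rng, flags=None):
    """Reproduction flags and reported angles.

    Flags are independent Bernoulli(repro_fraction) unless supplied.
    Reported angle = target + error with error ~ (1-g) vonMises(mu(delta),
    kappa) + g uniform, where mu(delta) is the planted
    derivative-of-Gaussian serial-bias curve. Returns
    (flags, reported_deg, error_deg); non-flagged entries are NaN.
    """
    angles = np.asarray(angles, dtype=float)
    n = angles.size
    if flags is None:
        flags = rng.random(n) < config.repro_fraction
    else:
        flags = np.asarray(flags, dtype=bool)
    delta = np.zeros(n)
    if labels is not None and "delta_deg" in labels:
        d = labels["delta_deg"].to_numpy(dtype=float)
        delta = np.where(np.isfinite(d), d, 0.0)
    mu = serial_bias_curve(delta, truth.serial_bias_amplitude, truth.serial_bias_width)

    macro = _macro_indicator(labels)
    kappa = np.full(n, truth.kappa)
    if macro is not None and truth.kappa_by_condition:
        unexpected, defined = macro
        kappa = np.where(
            defined & (unexpected > 0),
            truth.kappa_for("unexpected"),
            np.where(defined, truth.kappa_for("expected"), truth.kappa),
        )

    err = np.degrees(rng.vonmises(np.radians(mu), kappa))
    guess = rng.random(n) < truth.guess_rate
    uni = rng.uniform(-180.0, 180.0, n)
    err = np.where(guess, uni, err)
    reported = (angles + err) % 360.0
    error = np.where(flags, err, np.nan)
    reported = np.where(flags, reported, np.nan)
    return flags, reported, error


def _surprise(labels, scale):
    """Per-trial surprise in [0, 1] from macro or meso labels."""
    n = len(labels) if labels is not None else 0
    if labels is None:
        return np.zeros(0)
    if scale == "macro":
        macro = _macro_indicator(labels)
        return macro[0] if macro is not None else np.zeros(n)
    if scale == "meso":
        col = labels.get("meso_task_related")
        if col is None:
            return np.zeros(n)
        r = col.to_numpy(dtype=float)
        return np.where(np.isfinite(r), (r - 1.0) / 7.0, 0.0)
    raise ValueError(f"unknown surprise scale {scale!r}")


def pupil_response_kernel(t, peak_s=1.0):
    """Unit-peak dilation kernel: gamma-shaped, peaking ``peak_s`` after onset."""
    tau = peak_s / 2.0
    x = np.maximum(np.asarray(t, dtype=float), 0.0) / tau
    return (x ** 2) * np.exp(2.0 - x)  # peak 1 at x = 2


def gen_pupil(labels, truth, config, rng, surprise_scale="macro"):
    """Continuous pupil trace with surprise-scaled dilations and blinks.

    The trace is slow baseline drift + one dilation kernel per event whose
    amplitude is ``pupil_amp * (1 + pupil_surprise_gain * surprise)`` +
    white noise, with blink episodes zeroed out (sentinel 0). Returns
    ``(trace, event_times_s, blink_episodes)`` where episodes are
    (start_s, end_s) pairs.
    """
    n_events = len(labels)
    rate = config.pupil_rate
    t_end = (n_events + 1) * config.iti_s + 2.0
    n_samp = int(round(t_end * rate))
    t = np.arange(n_samp) / rate
    events = config.iti_s * (1.0 + np.arange(n_events))

    # slow baseline drift (~5 s correlation length): smoothed low-rate noise,
    # interpolated up to the full sampling rate
    from scipy.ndimage import gaussian_filter1d

    slow_rate = 2.0  # Hz
    t_slow = np.arange(int(np.ceil(t_end * slow_rate)) + 2) / slow_rate
    slow = gaussian_filter1d(rng.normal(size=t_slow.size), sigma=5.0 * slow_rate,
                             mode="nearest")
    slow *= 0.3 / max(slow.std(), 1e-12)
    drift = np.interp(t, t_slow, slow)

    surprise = _surprise(labels, surprise_scale)
    amp = truth.pupil_amp * (1.0 + truth.pupil_surprise_gain * surprise)
    trace = drift + rng.normal(0.0, truth.pupil_noise_sd, n_samp)
    kernel_len = int(round(3.0 * rate))
    kt = pupil_response_kernel(np.arange(kernel_len) / rate)
    for ev, a in zip(events, amp):
        i0 = int(round(ev * rate))
        seg = slice(i0, min(i0 + kernel_len, n_samp))
        trace[seg] += a * kt[: seg.stop - seg.start]

    episodes = []
    n_blinks = rng.poisson(truth.blink_rate_hz * t_end)
    starts = np.sort(rng.uniform(0.5, t_end - 1.0, n_blinks))
    for s in starts:
        e = s + truth.blink_duration_s
        i0, i1 = int(s * rate), min(int(e * rate), n_samp)
        trace[i0:i1] = 0.0
        episodes.append((s, e))
    return trace, events, episodes


def evoked_kernel(t, onset_s=0.05, peak_s=0.12):
    """Unit-peak evoked waveform rising after ``onset_s``, peaking at ``peak_s``."""
    tau = (peak_s - onset_s) / 2.0
    x = np.maximum(np.asarray(t, dtype=float) - onset_s, 0.0) / tau
    return (x ** 2) * np.exp(2.0 - x)


def gen_epochs(angles, labels, truth, config, rng, basis=None, surprise_scale="macro"):
    """Sensor epochs with angle-tuned signal, correlated noise, and drift.

    Per trial: ``signal_amplitude * gain(context) * W @ c(theta)`` outer the
    evoked kernel (latency-shifted for expected stimuli), plus spatially
    correlated Gaussian noise and an AR(1) across-trial drift (coefficient
    0.99, stationary sd ``drift_sd``) projected onto a fixed sensor pattern
    and constant within each epoch.
    """
    from .containers import SensorEpochs

    angles = np.asarray(angles, dtype=float)
    n = angles.size
    m = config.n_sensors
    basis = make_basis() if basis is None else basis
    if m < basis.n_channels:
        raise ValueError("n_sensors must be >= n_channels")
    t0, t1 = config.epoch_window
    nt = int(round((t1 - t0) * config.sample_rate))
    times = t0 + np.arange(nt) / config.sample_rate

    W = rng.normal(size=(m, basis.n_channels))
    C = basis(angles)  # (k, n)

    if labels is not None and len(labels) == n:
        surprise = _surprise(labels, surprise_scale)
    else:
        surprise = np.zeros(n)
    gain = np.where(surprise > 0, truth.gain_unexpected, truth.gain_expected)
    latency = np.where(surprise > 0, 0.0, truth.latency_shift)

    patterns = truth.signal_amplitude * (W @ C) * gain  # (m, n)
    data = np.empty((n, m, nt))
    # evoked kernel per distinct latency
    for lat in np.unique(latency):
        idx = latency == lat
        h = evoked_kernel(times - lat)
        data[idx] = patterns[:, idx].T[:, :, None] * h[None, None, :]

    if truth.noise_sd > 0:
        mix = rng.normal(size=(m, m)) / np.sqrt(m)
        noise = rng.normal(size=(n, m, nt))
        data += truth.noise_sd * np.einsum("ij,njt->nit", mix, noise)

    if truth.drift_sd > 0:
        rho = 0.99
        innov = rng.normal(0.0, truth.drift_sd * np.sqrt(1 - rho ** 2), n)
        d = np.empty(n)
        d[0] = rng.normal(0.0, truth.drift_sd)
        for j in range(1, n):
            d[j] = rho * d[j - 1] + innov[j]
        u = rng.normal(size=m)
        data += d[:, None, None] * u[None, :, None]

    return SensorEpochs(data=data, times=times, rate=config.sample_rate,
                        angles=angles, labels=labels)


def make_trial_table(config, bias, truth, rng):
    """Full labeled trial table for one simulated session."""
    angles = gen_locations(config, bias, rng)
    blocks = np.repeat(np.arange(config.n_blocks), config.trials_per_block)
    base = pd.DataFrame({
        "trial": np.arange(config.n_trials),
        "block": blocks,
        "angle_deg": angles,
    })
    p_x, p_y = _plane_probs(config.task_axis, bias)
    p_task = p_x if config.task_axis == "left_right" else p_y
    p_unrel = p_y if config.task_axis == "left_right" else p_x
    # flags must precede labeling (sequence validity depends on them)
    flags = rng.random(config.n_trials) < config.repro_fraction
    base["is_repro"] = flags
    df = label_trials(base, config.task_axis, p_task, p_unrel)
    resp = gen_binary_responses(angles, df, truth, rng, config.task_axis)
    for c in resp.columns:
        df[c] = resp[c].to_numpy()
    _, reported, error = gen_reproductions(angles, df, truth, config, rng, flags=flags)
    df["repro_deg"] = reported
    df["repro_error_deg"] = error
    return df


def simulate_experiment(experiment, config=None, truth=None, bias=None, seed=0):
    """Convenience driver: one synthetic session of a named experiment.

    ``experiment`` in {'1','2','3','eeg'}. Returns a dict with the labeled
    trial table and, for 'eeg', sensor epochs; pupil traces are included for
    the behavioral experiments.
    """
    experiment = str(experiment)
    rng = np.random.default_rng(seed)
    config = config or SimConfig()
    truth = truth or GroundTruth()
    if bias is None:
        bias = BiasSpec.experiment1() if experiment == "1" else BiasSpec.experiment2()
        if experiment == "eeg":
            bias = BiasSpec.experiment1()
    out = {"config": config, "truth": truth, "bias": bias}
    trials = make_trial_table(config, bias, truth, rng)
    out["trials"] = trials
    if experiment == "eeg":
        out["epochs"] = gen_epochs(
            trials["angle_deg"].to_numpy(), trials, truth, config, rng
        )
    else:
        scale = "macro" if experiment in ("2", "3") else "meso"
        out["pupil"] = gen_pupil(trials, truth, config, rng, surprise_scale=scale)
    return out


def ground_truth_dict(truth):
    """JSON-serializable view of a GroundTruth (for provenance files)."""
    return asdict(truth)
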