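"""File formats, provenance, and the pipeline driver.

Trial tables travel as CSV (human-diffable), arrays as HDF5, results as
JSON. Every writer embeds a provenance attribute (package version and a
hash of the generating configuration) so a results directory can be
reproduced bit-identically from its config and seed.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import SensorEpochs

TRIAL_COLUMNS = ["trial", "block", "angle_deg", "response", "rt_s", "correct",
                 "is_repro", "repro_deg"]


def config_hash(config):
    """Stable short hash of a JSON-serializable configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_trials(table, path):
    """Write a trial table to CSV (lossless round trip for label columns)."""
    table.to_csv(path, index=False)


def read_trials(path, require_all=True):
    """Read and validate a trial CSV.

    Angles are validated into [0, 360) (exactly 360 normalizes to 0);
    response times must be positive. Errors name the offending row.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if require_all and missing:
        raise ValueError(f"missing column(s): {', '.join(missing)}")
    if "angle_deg" in df:
        ang = df["angle_deg"].to_numpy(dtype=float)
        bad = np.flatnonzero((ang < 0) | (ang > 360) | ~np.isfinite(ang))
        if bad.size:
            raise ValueError(f"angle out of range [0, 360] at row {bad[0]}")
        df["angle_deg"] = ang % 360.0
    if "rt_s" in df:
        rt = df["rt_s"].to_numpy(dtype=float)
        bad = np.flatnonzero(np.isfinite(rt) & (rt <= 0))
        if bad.size:
            raise ValueError(f"non-positive response time at row {bad[0]}")
    return df


def write_epochs(epochs, path, provenance=None):
    """Write sensor epochs to HDF5 (/data, /times, /angles, /labels/*)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("times", data=epochs.times)
        f.create_dataset("angles", data=epochs.angles)
        f.attrs["rate"] = epochs.rate
        if provenance:
            f.attrs["provenance"] = json.dumps(provenance)
        if epochs.labels is not None:
            g = f.create_group("labels")
            for col in epochs.labels.columns:
                vals = epochs.labels[col].to_numpy()
                if vals.dtype == object:
                    vals = np.array(["" if v is None or v != v else str(v)
                                     for v in vals], dtype="S32")
                elif vals.dtype == bool:
                    vals = vals.astype("i1")
                g.create_dataset(col, data=vals)


def read_epochs(path):
    """Read sensor epochs from HDF5, validating shapes."""
    with h5py.File(path, "r") as f:
        for key in ("data", "times", "angles"):
            if key not in f:
                raise ValueError(f"missing dataset /{key}")
        data = f["data"][...]
        times = f["times"][...]
        angles = f["angles"][...]
        if data.ndim != 3 or data.shape[2] != times.size:
            raise ValueError("/data shape inconsistent with /times")
        if data.shape[0] != angles.size:
            raise ValueError("/data shape inconsistent with /angles")
        labels = None
        if "labels" in f:
            cols = {}
            for col in f["labels"]:
                v = f["labels"][col][...]
                if v.dtype.kind == "S":
                    v = np.array([s.decode() or None for s in v], dtype=object)
                cols[col] = v
            labels = pd.DataFrame(cols)
        rate = float(f.attrs.get("rate", 1.0 / np.median(np.diff(times))))
    return SensorEpochs(data=data, times=times, rate=rate, angles=angles,
                        labels=labels)


def write_pupil(trace, times, events, path, episodes=None, provenance=None):
    """Write a continuous pupil recording (/pupil, /times, /events)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("pupil", data=np.asarray(trace, dtype=float))
        f.create_dataset("times", data=np.asarray(times, dtype=float))
        f.create_dataset("events", data=np.asarray(events, dtype=float))
        if episodes is not None and len(episodes):
            f.create_dataset("blinks", data=np.asarray(episodes, dtype=float))
        if provenance:
            f.attrs["provenance"] = json.dumps(provenance)


def read_pupil(path):
    with h5py.File(path, "r") as f:
        for key in ("pupil", "times", "events"):
            if key not in f:
                raise ValueError(f"missing dataset /{key}")
        trace = f["pupil"][...]
        times = f["times"][...]
        events = f["events"][...]
        episodes = f["blinks"][...] if "blinks" in f else None
    return trace, times, events, episodes


def run_pipeline(config=None, out_dir=".", seed=0):
    """End-to-end synthetic run: simulate, label, analyze, report.

    Generates one session of each stage's input under ``config`` (a dict of
    overrides for the generator and analyses), runs the behavioral, pupil,
    LDA and IEM analyses with cluster inference where applicable, and
    writes a machine-readable ``summary.json`` plus the intermediate
    artifacts. Deterministic given ``seed``.
    """
    from . import behavior, cluster, lda, iem
    from .synth import BiasSpec, GroundTruth, SimConfig, simulate_experiment
    from .pupil import preprocess_pupil, condition_difference

    config = dict(config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = {"config": config, "seed": seed, "hash": config_hash(config)}

    sim_cfg = SimConfig(**config.get("sim", {"n_blocks": 4,
                                             "trials_per_block": 100,
                                             "n_sensors": 12,
                                             "sample_rate": 64.0}))
    truth = GroundTruth(**config.get("truth", {}))
    bias = BiasSpec(**config.get("bias", {"p_repeat": 0.75,
                                          "second_plane_p_repeat": 0.75}))

    sim = simulate_experiment("2", sim_cfg, truth, bias, seed=seed)
    trials = sim["trials"]
    write_trials(trials, out / "trials.csv")

    summary = {"provenance": prov, "n_trials": int(len(trials))}
    cond = behavior.condition_summary(trials, "macro_task_related")
    summary["behavior"] = cond.to_dict(orient="records")
    err = trials.loc[trials["is_repro"], "repro_error_deg"].dropna().to_numpy()
    if err.size >= 30:
        fit = behavior.fit_mixture(err)
        summary["mixture"] = {"kappa": fit.kappa, "g": fit.g, "mu": fit.mu,
                              "converged": fit.converged}

    rng = np.random.default_rng(seed + 1)
    from .synth import gen_pupil, gen_epochs
    trace, events, episodes = gen_pupil(trials, truth, sim_cfg, rng)
    write_pupil(trace, np.arange(trace.size) / sim_cfg.pupil_rate, events,
                out / "pupil.h5", episodes, prov)
    pe = preprocess_pupil(trace, events, sim_cfg.pupil_rate, labels=trials)
    diff = condition_difference(pe, pe.labels["macro_task_related"].to_numpy())
    summary["pupil"] = {"n_epochs": int(pe.n_epochs),
                        "peak_difference": float(np.nanmax(np.abs(diff)))}

    epochs = gen_epochs(trials["angle_deg"].to_numpy(), trials, truth,
                        sim_cfg, rng)
    write_epochs(epochs, out / "epochs.h5", prov)
    side = trials["side_task_related"].to_numpy()
    curves = lda.shuffle_baseline(epochs, side, n_shuffles=20,
                                  random_state=seed)
    summary["lda"] = {"peak_corrected_accuracy":
                      float(np.max(curves["all"].corrected))}
    res = iem.crossval_iem(epochs, n_folds=5, random_state=seed)
    summary["iem"] = {"peak_accuracy": float(np.nanmax(res.accuracy))}

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
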