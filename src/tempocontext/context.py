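"""Trial-context labeling at micro, meso, and macro temporal scales.

Each trial in a sequence of stimulus angles is labeled relative to its
predecessor on three reference planes:

* ``task_related`` — the plane defining the speeded judgement (the vertical
  meridian for a left/right task, the horizontal meridian for an above/below
  task);
* ``task_unrelated`` — the plane orthogonal to the task-related one;
* ``stimulus`` — the plane orthogonal to the previous stimulus direction, so
  a trial is a repeat when it moved by less than 90 deg.

Micro labels are repeat/alternate codes per plane. Meso labels classify the
pattern of the last four transitions (a five-event window) into eight
symmetric sequence classes ranked by the expectedness of the final event.
Macro labels mark a trial as expected or unexpected given the long-run
repeat probability of the session.

Tie conventions (measure-zero events): |Δ| exactly 90 deg is an alternate;
an angle exactly on a reference plane yields side 0 and the trial is treated
as invalid on that plane.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

MICRO_REPEAT = "R"
MICRO_ALTERNATE = "A"

#: Reference planes carrying repeat/alternate codes.
PLANES = ("task_related", "task_unrelated", "stimulus")

#: Expectancy ranking of the eight symmetric transition-pattern classes.
#: Keys are the canonical (R-initial) member of each {pattern, complement}
#: pair, read oldest transition first; rank 1 is the sequence whose final
#: event is most expected (RRRR/AAAA), rank 8 the maximal final violation
#: (RRRA/AAAR). Generated by a recency-weighted consistency score (see
#: docs/methods.md); override via the ``rank_table`` arguments to customize.
MESO_RANK_TABLE = {
    "RRRR": 1,
    "RAAA": 2,
    "RARR": 3,
    "RRAA": 4,
    "RRAR": 5,
    "RARA": 6,
    "RAAR": 7,
    "RRRA": 8,
}

_WINDOW = 5  # events per meso window (four transitions)


def wrap_angle(angle):
    """Wrap angle(s) in degrees to (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    wrapped = -((-a + 180.0) % 360.0 - 180.0)
    return wrapped if wrapped.ndim else float(wrapped)


def delta_location(prev_angle, cur_angle):
    """Signed angular distance current - previous, wrapped to (-180, 180].

    The 180 deg boundary maps to +180, never -180.
    """
    return wrap_angle(np.asarray(cur_angle, dtype=float) - np.asarray(prev_angle, dtype=float))


def side_of_plane(angle, plane, task_axis="left_right"):
    """Side of a task reference plane: +1 / -1, or 0 exactly on the plane.

    For a left/right task the task-related plane is the vertical meridian
    (+1 = right) and the task-unrelated plane the horizontal meridian
    (+1 = above); for an above/below task the roles swap.
    """
    if plane not in ("task_related", "task_unrelated"):
        raise ValueError(f"unknown plane {plane!r}")
    if task_axis not in ("left_right", "above_below"):
        raise ValueError(f"unknown task_axis {task_axis!r}")
    rad = np.radians(np.asarray(angle, dtype=float))
    use_x = (plane == "task_related") == (task_axis == "left_right")
    coord = np.cos(rad) if use_x else np.sin(rad)
    # snap numerical noise at the plane itself to an exact tie
    coord = np.where(np.abs(coord) < 1e-12, 0.0, coord)
    out = np.sign(coord)
    return out if out.ndim else float(out)


def label_micro(angles, blocks=None, task_axis="left_right"):
    """Repeat/alternate codes per plane for each trial.

    Returns a DataFrame with columns ``side_task_related``,
    ``side_task_unrelated``, ``delta_deg`` and ``micro_<plane>`` for the
    three planes. The first trial of each block (and any trial following a
    block boundary) has NaN delta and missing micro codes. Stimulus-plane
    repeats are |Δ| < 90; |Δ| = 90 exactly is an alternate.
    """
    angles = np.asarray(angles, dtype=float)
    n = angles.size
    if n < 2:
        raise ValueError("need at least 2 trials")
    blocks = np.zeros(n, dtype=int) if blocks is None else np.asarray(blocks)

    side_t = np.asarray(side_of_plane(angles, "task_related", task_axis))
    side_u = np.asarray(side_of_plane(angles, "task_unrelated", task_axis))

    delta = np.full(n, np.nan)
    delta[1:] = delta_location(angles[:-1], angles[1:])
    new_block = np.ones(n, dtype=bool)
    new_block[1:] = blocks[1:] != blocks[:-1]
    delta[new_block] = np.nan

    def codes(same):
        out = np.array([None] * n, dtype=object)
        out[1:] = np.where(same, MICRO_REPEAT, MICRO_ALTERNATE)
        out[new_block] = None
        return out

    same_t = side_t[1:] == side_t[:-1]
    same_u = side_u[1:] == side_u[:-1]
    same_s = np.abs(delta[1:]) < 90.0
    micro = pd.DataFrame(
        {
            "side_task_related": side_t,
            "side_task_unrelated": side_u,
            "delta_deg": delta,
            "micro_task_related": codes(same_t),
            "micro_task_unrelated": codes(same_u),
            "micro_stimulus": codes(same_s),
        }
    )
    # ties on a plane invalidate the trial on that plane
    for col, side in (("micro_task_related", side_t), ("micro_task_unrelated", side_u)):
        bad = (side == 0) | np.concatenate([[False], side[:-1] == 0])
        micro.loc[bad, col] = None
    return micro


def enumerate_histories(series_length):
    """All repeat/alternate transition patterns for a series of binary events.

    A series of ``series_length`` events has ``series_length - 1``
    transitions, hence ``2**(series_length-1)`` patterns, returned in
    lexicographic order (A < R).
    """
    series_length = int(series_length)
    if series_length < 2:
        raise ValueError("series_length must be >= 2")
    k = series_length - 1
    return ["".join("AR"[(i >> (k - 1 - j)) & 1] for j in range(k)) for i in range(2 ** k)]


def _complement(pattern):
    return pattern.translate(str.maketrans("RA", "AR"))


def combine_symmetric(patterns, rank_table=None):
    """Collapse transition patterns into symmetric pairs with expectancy ranks.

    Each class pairs a pattern with its R/A complement, so that the two
    members end in one repeat and one alternate and micro-scale identity is
    balanced within a class. Returns a dict ``pattern -> rank`` covering
    every input pattern.
    """
    patterns = list(patterns)
    table = dict(MESO_RANK_TABLE if rank_table is None else rank_table)
    out = {}
    for p in patterns:
        canon = p if p.startswith("R") else _complement(p)
        if canon not in table:
            raise ValueError(f"no rank for pattern class {canon!r}")
        out[p] = table[canon]
    ranks = set(out.values())
    if len(patterns) == 16 and ranks != set(range(1, 9)):
        raise ValueError("rank table does not produce 8 classes for 16 patterns")
    return out


def expectancy_score(pattern):
    """Recency-weighted consistency of the final transition with its history.

    Evidence for a repeat is the recency-weighted sum (+1 per R, -1 per A;
    weights 1..len-1 over the preceding transitions); the score is that
    evidence signed by the final transition, with a half-point tiebreak for
    agreement with the immediately preceding transition. Higher scores mean
    a more expected final event. Used once to generate MESO_RANK_TABLE.
    """
    *hist, final = pattern
    s = sum((i + 1) * (1 if c == MICRO_REPEAT else -1) for i, c in enumerate(hist))
    sgn = 1 if final == MICRO_REPEAT else -1
    tie = 0.5 if hist and hist[-1] == final else -0.5
    return s * sgn + tie


def label_meso(micro_codes, transition_valid, rank_table=None):
    """Meso sequence class (1..8) per trial from a plane's micro codes.

    ``micro_codes`` are the per-trial transition codes ('R'/'A' or None) of a
    single plane; ``transition_valid`` flags whether each trial's incoming
    transition may participate in a sequence (same block, not disrupted by a
    reproduction task). A trial's class is defined by the four transitions
    ending at it; any missing or invalid transition leaves it unclassed.
    """
    codes = np.asarray(micro_codes, dtype=object)
    valid = np.asarray(transition_valid, dtype=bool)
    n = codes.size
    table = combine_symmetric(enumerate_histories(_WINDOW), rank_table)
    out = np.full(n, np.nan)
    ok = valid & np.array([c in (MICRO_REPEAT, MICRO_ALTERNATE) for c in codes])
    for t in range(_WINDOW - 2, n):
        w = slice(t - (_WINDOW - 2), t + 1)
        if ok[w].all():
            out[t] = table["".join(codes[w])]
    return out


def label_macro(micro_codes, p_repeat):
    """Expected/unexpected macro labels for one plane.

    A trial is expected when its micro code matches the majority transition
    type under the session's bias (p_repeat > 0.5 favors repeats). An
    unbiased session (p_repeat == 0.5) has no defined macro labels.
    """
    if not 0.0 <= p_repeat <= 1.0:
        raise ValueError("p_repeat must be in [0, 1]")
    codes = np.asarray(micro_codes, dtype=object)
    if p_repeat == 0.5:
        return np.array([None] * codes.size, dtype=object)
    majority = MICRO_REPEAT if p_repeat > 0.5 else MICRO_ALTERNATE
    out = np.array([None] * codes.size, dtype=object)
    known = np.array([c in (MICRO_REPEAT, MICRO_ALTERNATE) for c in codes])
    out[known] = np.where(codes[known] == majority, "expected", "unexpected")
    return out


def valid_sequence_mask(blocks, is_repro, repro_rule="window_plus_next"):
    """Per-trial validity of the incoming transition.

    A transition into trial t is invalid when t starts a block (or the
    session) or, under the default rule, when trial t-1 carried a
    reproduction task (the reproduction interrupts the sequence after the
    response). ``repro_rule='none'`` keeps transitions after reproduction
    trials valid; meso windows containing a reproduction trial are always
    dropped by :func:`label_trials`.
    """
    if repro_rule not in ("window_plus_next", "none"):
        raise ValueError(f"unknown repro_rule {repro_rule!r}")
    blocks = np.asarray(blocks)
    is_repro = np.asarray(is_repro, dtype=bool)
    n = blocks.size
    valid = np.zeros(n, dtype=bool)
    valid[1:] = blocks[1:] == blocks[:-1]
    if repro_rule == "window_plus_next":
        valid[1:] &= ~is_repro[:-1]
    return valid


def label_trials(trials, task_axis="left_right", p_repeat_task=0.5,
                 p_repeat_unrelated=0.5, repro_rule="window_plus_next",
                 rank_table=None):
    """Attach micro/meso/macro context labels to a trial table.

    Parameters
    ----------
    trials : DataFrame with at least ``angle_deg``; optional ``block`` and
        ``is_repro`` columns (defaults: one block, no reproductions).
    task_axis : 'left_right' or 'above_below'.
    p_repeat_task, p_repeat_unrelated : session repeat probability per task
        plane; 0.5 leaves macro labels undefined.

    Returns a copy of ``trials`` with the label columns of
    :class:`ContextLabels` semantics: sides, delta, micro per plane, meso
    class per task plane, macro per task plane, and ``valid_micro`` /
    ``valid_meso_<plane>`` masks.
    """
    df = trials.copy().reset_index(drop=True)
    angles = df["angle_deg"].to_numpy(dtype=float)
    blocks = df["block"].to_numpy() if "block" in df else np.zeros(len(df), dtype=int)
    is_repro = (
        df["is_repro"].to_numpy(dtype=bool) if "is_repro" in df
        else np.zeros(len(df), dtype=bool)
    )

    micro = label_micro(angles, blocks, task_axis)
    for col in micro.columns:
        df[col] = micro[col].to_numpy()

    trans_valid = valid_sequence_mask(blocks, is_repro, repro_rule)
    df["valid_micro"] = trans_valid
    for plane in ("task_related", "task_unrelated"):
        codes = micro[f"micro_{plane}"].to_numpy()
        # meso windows must not contain any reproduction event
        win_ok = trans_valid.copy()
        win_ok[1:] &= ~is_repro[1:] & ~is_repro[:-1]
        meso = label_meso(codes, win_ok, rank_table)
        df[f"meso_{plane}"] = meso
        df[f"valid_meso_{plane}"] = ~np.isnan(meso)
        p = p_repeat_task if plane == "task_related" else p_repeat_unrelated
        macro = label_macro(codes, p)
        macro[~trans_valid] = None
        df[f"macro_{plane}"] = macro
    return df
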