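"""Behavioral readout of network output trajectories.

Accuracy is scored on the window from 100 ms after motion onset to trial
end; the reaction time is the first moment the two output probabilities
separate by more than a threshold for three consecutive steps, with a
600 ms fallback for trials that never commit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

RT_FALLBACK_MS = 600.0


def _window_mask(record, batch):
    scored = record.times >= batch.timing.scoring_onset
    if not scored.any():
        raise ValueError("scoring window lies outside the record")
    return scored


def choices(record, batch, mode: str = "window_mean") -> np.ndarray:
    """Per-trial chosen response unit.

    ``window_mean``: argmax of the output probability averaged over the
    scoring window (default).  ``majority``: per-step argmax followed by a
    majority vote over the window.
    """
    scored = _window_mask(record, batch)
    p = record.outputs[scored]
    if mode == "window_mean":
        return p.mean(axis=0).argmax(axis=1)
    if mode == "majority":
        votes = p.argmax(axis=2)
        return (votes.mean(axis=0) > 0.5).astype(int)
    raise ValueError(f"unknown mode {mode!r}")


def accuracy(record, batch, mode: str = "window_mean") -> float:
    """Fraction of trials whose choice matches the rewarded response."""
    return float(np.mean(choices(record, batch, mode)
                         == batch.correct_output))


def reaction_time(record, batch=None, threshold: float = 0.8, k: int = 3,
                  fallback: float = RT_FALLBACK_MS,
                  motion_onset: float | None = None) -> np.ndarray:
    """Per-trial RT in ms after motion onset.

    RT is the time of the first step of the first run of >= k consecutive
    post-onset steps where |p_left - p_right| > threshold; trials without
    such a run get ``fallback``.
    """
    if motion_onset is None:
        motion_onset = batch.timing.motion_onset
    diff = np.abs(record.outputs[..., 0] - record.outputs[..., 1])
    post = record.times >= motion_onset
    d = diff[post] > threshold                      # (steps, trials)
    t_post = record.times[post] - motion_onset
    n_steps, n_trials = d.shape
    rts = np.full(n_trials, fallback)
    if n_steps >= k:
        runs = np.all(np.stack([d[i:n_steps - k + 1 + i]
                                for i in range(k)]), axis=0)
        for j in range(n_trials):
            idx = np.argmax(runs[:, j])
            if runs[idx, j]:
                rts[j] = t_post[idx]
    return rts


def behavior_table(record, batch, threshold: float = 0.8,
                   mode: str = "window_mean") -> pd.DataFrame:
    """Per-trial behavior: choice, correctness, RT and labels."""
    ch = choices(record, batch, mode)
    rt = reaction_time(record, batch, threshold)
    return pd.DataFrame({
        "trial": np.arange(batch.n_trials),
        "direction": batch.direction,
        "coherence": batch.coherence,
        "config": batch.target_config,
        "choice": ch,
        "correct": (ch == batch.correct_output).astype(int),
        "rt_ms": rt,
    })


def psychometric_chronometric(tables) -> pd.DataFrame:
    """Empirical per-coherence summary over one or more behavior tables.

    Returns accuracy mean +/- SE, mean RT, and the proportion of trials on
    which the 315-degree-associated (red) target was chosen, per signed
    coherence.  Cells with no trials are flagged via n = 0 rows omitted.
    """
    if isinstance(tables, pd.DataFrame):
        tables = [tables]
    df = pd.concat(tables, ignore_index=True)
    from .task import RED_DIRECTION, RED_RIGHT, RIGHT

    red_loc = np.where(df["config"] == RED_RIGHT, RIGHT, 1 - RIGHT)
    df = df.assign(chose_315=(df["choice"] == red_loc).astype(float))
    rows = []
    for coh, g in df.groupby("coherence"):
        n = len(g)
        acc = g["correct"].mean()
        rows.append({
            "coherence": coh, "n": n,
            "accuracy": acc,
            "accuracy_se": np.sqrt(max(acc * (1 - acc), 0) / n),
            "rt_mean": g["rt_ms"].mean(),
            "rt_se": g["rt_ms"].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
            "p315_pref_dir": g.loc[g["direction"] == RED_DIRECTION,
                                   "chose_315"].mean(),
            "p315_null_dir": g.loc[g["direction"] != RED_DIRECTION,
                                   "chose_315"].mean(),
        })
    return pd.DataFrame(rows).sort_values("coherence", ignore_index=True)
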