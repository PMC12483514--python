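"""Trial-based selectivity statistics for neurons and network units.

The same machinery is applied to synthetic electrophysiology sessions and
to RNN hidden units: sliding-window ROC direction selectivity, choice
probability on ambiguous trials, partial correlations separating
stimulus- from decision-linked activity, the contralateral/ipsilateral
modulation index, unit screening, and response-field (RF) localization.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import task as task_mod

PREF_WINDOW = (50.0, 250.0)  # ms after motion onset, reference window


@dataclass
class RateTable:
    """Trial-resolved rates with labels.

    rates: (units, trials, time); times in ms relative to motion onset.
    labels: per-trial DataFrame with columns direction, coherence, choice
    (response side), correct, rt_ms, target_config.
    hemisphere: per-unit 0 (left) / 1 (right).
    """

    rates: np.ndarray
    times: np.ndarray
    labels: pd.DataFrame
    hemisphere: np.ndarray

    @property
    def n_units(self):
        return self.rates.shape[0]

    @property
    def n_trials(self):
        return self.rates.shape[1]

    def window_mean(self, window) -> np.ndarray:
        """(units, trials) mean rate inside [window[0], window[1]] ms."""
        sel = (self.times >= window[0]) & (self.times <= window[1])
        if not sel.any():
            raise ValueError(f"window {window} outside the time axis")
        return self.rates[:, :, sel].mean(axis=2)

    def subset_units(self, idx) -> "RateTable":
        return RateTable(self.rates[idx], self.times,
                         self.labels, self.hemisphere[idx])

    def subset_trials(self, sel) -> "RateTable":
        sel = np.asarray(sel)
        return RateTable(self.rates[:, sel], self.times,
                         self.labels.iloc[sel].reset_index(drop=True),
                         self.hemisphere)

    def save(self, path):
        with h5py.File(path, "w") as f:
            f.create_dataset("rates", data=self.rates)
            f.create_dataset("times", data=self.times)
            f.create_dataset("hemisphere", data=self.hemisphere)
            lab = f.create_group("labels")
            for col in self.labels.columns:
                lab.create_dataset(col, data=self.labels[col].to_numpy())

    @classmethod
    def load(cls, path):
        with h5py.File(path, "r") as f:
            labels = pd.DataFrame({k: f["labels"][k][...]
                                   for k in f["labels"]})
            return cls(f["rates"][...], f["times"][...], labels,
                       f["hemisphere"][...])

    def to_long_frame(self) -> pd.DataFrame:
        u, tr, t = np.meshgrid(np.arange(self.n_units),
                               np.arange(self.n_trials),
                               self.times, indexing="ij")
        return pd.DataFrame({"unit": u.ravel(), "trial": tr.ravel(),
                             "time_ms": t.ravel(),
                             "rate": self.rates.ravel()})


def rate_table_from_rnn(record, batch, params, choice=None) -> RateTable:
    """Build a RateTable from an RNN activity record.

    Times are re-referenced to motion onset; choices default to the
    window-mean readout.
    """
    from .behavior import choices as _choices, reaction_time
    if choice is None:
        choice = _choices(record, batch)
    rates = np.transpose(record.rates, (2, 1, 0))  # (units, trials, steps)
    times = record.times - batch.timing.motion_onset
    correct = batch.correct_output
    labels = pd.DataFrame({
        "direction": batch.direction,
        "coherence": batch.coherence,
        "choice": choice,
        "correct": (choice == correct).astype(int),
        "rt_ms": reaction_time(record, batch),
        "target_config": batch.target_config,
    })
    return RateTable(rates, times, labels, params.layout.hemisphere.copy())


# ---------------------------------------------------------------------------
# ROC machinery


def roc_auc(a, b) -> float:
    """P(random draw from a > random draw from b), ties counted 1/2.

    Equals the Mann-Whitney U statistic of a vs b divided by n_a * n_b.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    u = stats.mannwhitneyu(a, b, alternative="two-sided").statistic
    return float(u / (a.size * b.size))


def preferred_direction(table: RateTable, window=PREF_WINDOW,
                        correct_only=True) -> np.ndarray:
    """Per-unit preferred direction (135 or 315) from a reference window."""
    sel = np.ones(table.n_trials, dtype=bool)
    if correct_only:
        corr = table.labels["correct"].to_numpy() == 1
        if corr.sum() >= 4:
            sel = corr
    wm = table.window_mean(window)[:, sel]
    direc = table.labels["direction"].to_numpy()[sel]
    m315 = wm[:, direc == 315].mean(axis=1)
    m135 = wm[:, direc == 135].mean(axis=1)
    return np.where(m315 >= m135, 315.0, 135.0)


def _window_centers(times, width, step):
    lo, hi = times.min(), times.max()
    centers = np.arange(lo + width / 2, hi - width / 2 + 1e-9, step)
    if centers.size == 0:
        raise ValueError("time axis shorter than the sliding window")
    return centers


def chosen_direction(labels: pd.DataFrame) -> np.ndarray:
    """Direction corresponding to each trial's chosen target color."""
    red_loc = np.where(labels["target_config"].to_numpy()
                       == task_mod.RED_RIGHT, task_mod.RIGHT, task_mod.LEFT)
    chose_red = labels["choice"].to_numpy() == red_loc
    return np.where(chose_red, task_mod.RED_DIRECTION,
                    task_mod.GREEN_DIRECTION)


def _split_direction_labels(table, split):
    if split == "direction":
        return table.labels["direction"].to_numpy().astype(float)
    if split == "choice":
        return chosen_direction(table.labels).astype(float)
    raise ValueError(f"unknown split {split!r}")


def sliding_roc(table: RateTable, window: float = 100.0, step: float = 5.0,
                split: str = "direction", prefs=None,
                trial_sel=None) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window ROC per unit.

    split='direction' uses the stimulus direction; split='choice' uses the
    chosen direction (choice mapped to direction via the target
    configuration), which is also the convention for zero-coherence
    trials.  The ROC is oriented by each unit's preferred direction, so
    values above 0.5 mean selectivity in the preferred orientation.
    Windows with fewer than 2 trials per class yield NaN.

    Returns (centers_ms, roc[units, centers]).
    """
    if prefs is None:
        prefs = preferred_direction(table)
    prefs = np.asarray(prefs, dtype=float)
    if trial_sel is not None:
        table = table.subset_trials(trial_sel)
    lab = _split_direction_labels(table, split)
    centers = _window_centers(table.times, window, step)
    out = np.full((table.n_units, centers.size), np.nan)
    for j, c in enumerate(centers):
        wm = table.window_mean((c - window / 2, c + window / 2))
        # units sharing a preferred direction share the trial split, so the
        # rank statistic vectorizes across them
        for p in np.unique(prefs):
            rows = np.where(prefs == p)[0]
            a = wm[np.ix_(rows, lab == p)]
            b = wm[np.ix_(rows, lab != p)]
            if a.shape[1] >= 2 and b.shape[1] >= 2:
                u = stats.mannwhitneyu(a, b, alternative="two-sided",
                                       axis=1).statistic
                out[rows, j] = u / (a.shape[1] * b.shape[1])
    return centers, out


# ---------------------------------------------------------------------------
# screening


def screen_units(table: RateTable, alpha: float = 0.01,
                 window=PREF_WINDOW, min_rate: float = 2.0,
                 mode: str = "ephys") -> pd.DataFrame:
    """Unit inclusion flags.

    ephys mode: one-way ANOVA across motion directions in the reference
    window at p < alpha, plus a peak-rate floor (mean rate to the better
    direction >= min_rate spikes/s).  rnn mode: keep units with motion- or
    saccade-direction modulation at p < alpha; no rate floor (unit
    activities are dimensionless).
    """
    wm = table.window_mean(window)
    direc = table.labels["direction"].to_numpy()
    rows = []
    for i in range(table.n_units):
        groups = [wm[i, direc == d] for d in np.unique(direc)]
        reason = ""
        if any(g.size < 2 for g in groups):
            rows.append({"unit": i, "keep": False, "reason": "too_few_trials"})
            continue
        if np.ptp(np.concatenate(groups)) == 0:
            rows.append({"unit": i, "keep": False,
                         "reason": "degenerate_variance"})
            continue
        p_dir = stats.f_oneway(*groups).pvalue
        if mode == "ephys":
            peak = max(g.mean() for g in groups)
            keep = p_dir < alpha and peak >= min_rate
            if not keep:
                reason = "low_rate" if peak < min_rate else "no_direction_ds"
        elif mode == "rnn":
            side = table.labels["choice"].to_numpy()
            sgroups = [wm[i, side == s] for s in np.unique(side)]
            if len(sgroups) == 2 and all(g.size >= 2 for g in sgroups) and \
                    np.ptp(np.concatenate(sgroups)) > 0:
                p_sacc = stats.f_oneway(*sgroups).pvalue
            else:
                p_sacc = 1.0
            keep = (p_dir < alpha) or (p_sacc < alpha)
            reason = "" if keep else "no_task_modulation"
        else:
            raise ValueError(f"unknown mode {mode!r}")
        rows.append({"unit": i, "keep": bool(keep), "reason": reason})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CT / IT labelling


def target_side(labels: pd.DataFrame, use: str = "correct") -> np.ndarray:
    """Per-trial side (LEFT/RIGHT) of the relevant target."""
    if use == "choice":
        return labels["choice"].to_numpy().astype(int)
    direction = labels["direction"].to_numpy()
    conf = labels["target_config"].to_numpy()
    return np.array([task_mod.correct_side(d, c)
                     for d, c in zip(direction, conf)])


def label_ct_it(table: RateTable, use: str = "correct") -> np.ndarray:
    """(units, trials) boolean: True where the trial is CT for the unit.

    CT = the relevant (correct, or chosen) target lies contralateral to
    the unit's hemisphere.  Zero-coherence trials always use the chosen
    target (no deterministic correct target exists there).
    """
    if table.hemisphere is None:
        raise ValueError("unit hemisphere labels are required")
    side = target_side(table.labels, use)
    if use == "correct":
        zero = table.labels["coherence"].to_numpy() == 0
        side = np.where(zero, table.labels["choice"].to_numpy(), side)
    contra = 1 - np.asarray(table.hemisphere)[:, None]   # (units, 1)
    return side[None, :] == contra


# ---------------------------------------------------------------------------
# partial correlations


def partial_corr(x, y, z) -> float:
    """First-order partial correlation r_xy.z."""
    x, y, z = (np.asarray(v, dtype=float) for v in (x, y, z))
    if x.std() == 0 or y.std() == 0 or z.std() == 0:
        return np.nan
    rxy = np.corrcoef(x, y)[0, 1]
    rxz = np.corrcoef(x, z)[0, 1]
    ryz = np.corrcoef(y, z)[0, 1]
    denom = np.sqrt((1 - rxz ** 2) * (1 - ryz ** 2))
    if denom == 0:
        return np.nan
    return float((rxy - rxz * ryz) / denom)


def stimulus_choice_codes(table: RateTable, prefs):
    """Per-unit signed trial codes for the partial-correlation analysis.

    Stimulus: +/- {4, 2, 1, 0} (positive toward the unit's preferred
    direction; 4/2/1/0 for high/medium/low/zero coherence).  Choice: -2
    for choosing the preferred direction, +2 for the nonpreferred.
    Returns (stim_code[units, trials], choice_code[units, trials]).
    """
    coh = table.labels["coherence"].to_numpy()
    nz = np.sort(np.unique(coh[coh > 0]))[::-1]      # high -> low
    mag_map = {0.0: 0.0}
    codes = (4.0, 2.0, 1.0)
    for k, lev in enumerate(nz):
        mag_map[lev] = codes[k] if k < len(codes) else 1.0
    mag = np.array([mag_map[c] for c in coh])
    direc = table.labels["direction"].to_numpy()
    chosen = chosen_direction(table.labels)
    prefs = np.asarray(prefs, dtype=float)
    stim = np.where(direc[None, :] == prefs[:, None], 1.0, -1.0) * mag[None, :]
    choice_code = np.where(chosen[None, :] == prefs[:, None], -2.0, 2.0)
    return stim, choice_code


def partial_corr_series(table: RateTable, window: float = 100.0,
                        step: float = 5.0, prefs=None):
    """Sliding r_stimulus and r_decision per unit.

    r_stimulus = r(activity, stimulus | choice);
    r_decision = r(activity, choice | stimulus).
    Returns (centers_ms, r_stimulus[units, centers], r_decision[...]).
    """
    if prefs is None:
        prefs = preferred_direction(table)
    stim, dec = stimulus_choice_codes(table, prefs)
    centers = _window_centers(table.times, window, step)
    r_stim = np.full((table.n_units, centers.size), np.nan)
    r_dec = np.full_like(r_stim, np.nan)
    for j, c in enumerate(centers):
        wm = table.window_mean((c - window / 2, c + window / 2))
        for i in range(table.n_units):
            r_stim[i, j] = partial_corr(wm[i], stim[i], dec[i])
            r_dec[i, j] = partial_corr(wm[i], dec[i], stim[i])
    return centers, r_stim, r_dec


# ---------------------------------------------------------------------------
# modulation index


def modulation_index(table: RateTable, window=PREF_WINDOW,
                     prefs=None) -> pd.DataFrame:
    """MI = (d_contra - d_ipsi) / (d_contra + d_ipsi) per unit, where
    d = mean rate (preferred) - mean rate (nonpreferred) in the window,
    separately for contralateral- and ipsilateral-saccade trials."""
    if prefs is None:
        prefs = preferred_direction(table)
    wm = table.window_mean(window)
    direc = table.labels["direction"].to_numpy()
    choice_side = table.labels["choice"].to_numpy()
    rows = []
    for i in range(table.n_units):
        contra_side = 1 - table.hemisphere[i]
        is_contra = choice_side == contra_side
        is_pref = direc == prefs[i]
        deltas = {}
        for name, sel in (("contra", is_contra), ("ipsi", ~is_contra)):
            a = wm[i, sel & is_pref]
            b = wm[i, sel & ~is_pref]
            deltas[name] = np.nan if (a.size == 0 or b.size == 0) \
                else a.mean() - b.mean()
        dc, di = deltas["contra"], deltas["ipsi"]
        denom = (dc + di) if np.isfinite(dc) and np.isfinite(di) else np.nan
        mi = np.nan if (not np.isfinite(denom) or denom == 0) else \
            (dc - di) / denom
        rows.append({"unit": i, "delta_contra": dc, "delta_ipsi": di,
                     "mi": mi, "defined": bool(np.isfinite(mi))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# correct/error (choice vs stimulus) ROC


def correct_error_roc(table: RateTable, coherence: float,
                      window: float = 100.0, step: float = 5.0,
                      min_trials: int = 4, prefs=None):
    """Choice-locked vs stimulus-locked sliding ROC on correct+error trials.

    Only units with more than ``min_trials`` correct AND error trials for
    each direction at the given coherence are included.  Returns
    (centers, roc_by_stimulus, roc_by_choice, included_units).
    """
    if prefs is None:
        prefs = preferred_direction(table)
    sel = table.labels["coherence"].to_numpy() == coherence
    sub = table.subset_trials(sel)
    direc = sub.labels["direction"].to_numpy()
    corr = sub.labels["correct"].to_numpy()
    included = []
    for i in range(table.n_units):
        ok = all(np.sum((direc == d) & (corr == c)) > min_trials
                 for d in np.unique(direc) for c in (0, 1))
        if ok:
            included.append(i)
    included = np.array(included, dtype=int)
    if included.size == 0:
        return None, None, None, included
    sub_u = sub.subset_units(included)
    prefs_u = np.asarray(prefs)[included]
    centers, roc_stim = sliding_roc(sub_u, window, step, "direction", prefs_u)
    _, roc_choice = sliding_roc(sub_u, window, step, "choice", prefs_u)
    return centers, roc_stim, roc_choice, included


# ---------------------------------------------------------------------------
# RT-split selectivity


def rt_split_ds(table: RateTable, coherence: float = 0.0,
                window: float = 100.0, step: float = 5.0,
                epoch=(100.0, 300.0), n_boot: int = 1000, rng=None,
                prefs=None):
    """Choice selectivity on fast vs slow (median-RT-split) trials.

    Returns dict with the two sliding-ROC matrices, centers, and a
    bootstrap (label-permutation) p-value for mean ROC(fast) > ROC(slow)
    within ``epoch``.
    """
    rng = rng if rng is not None else np.random.default_rng()
    if prefs is None:
        prefs = preferred_direction(table)
    sel = table.labels["coherence"].to_numpy() == coherence
    sub = table.subset_trials(sel)
    rt = sub.labels["rt_ms"].to_numpy()
    if np.ptp(rt) == 0:
        raise ValueError("all RTs equal; cannot median-split")
    order = np.argsort(rt, kind="stable")
    half = len(rt) // 2
    fast_idx, slow_idx = order[:half], order[half:]

    def _roc(idx):
        return sliding_roc(sub.subset_trials(idx), window, step,
                           "choice", prefs)

    centers, roc_fast = _roc(fast_idx)
    _, roc_slow = _roc(slow_idx)
    ep = (centers >= epoch[0]) & (centers <= epoch[1])
    observed = np.nanmean(roc_fast[:, ep]) - np.nanmean(roc_slow[:, ep])

    boots = np.empty(n_boot)
    n = len(rt)
    for b in range(n_boot):
        perm = rng.permutation(n)
        _, rf = _roc(perm[:half])
        _, rs = _roc(perm[half:])
        boots[b] = np.nanmean(rf[:, ep]) - np.nanmean(rs[:, ep])
    p = float((np.sum(boots >= observed) + 1) / (n_boot + 1))
    return {"centers": centers, "roc_fast": roc_fast, "roc_slow": roc_slow,
            "difference": float(observed), "p": p,
            "n_fast": half, "n_slow": n - half}


# ---------------------------------------------------------------------------
# response-field center


def rf_center(responses, baseline, angles=None, alpha: float = 0.01):
    """RF center from a memory-guided-saccade style 8-location screen.

    ``responses``: sequence of 8 per-trial response arrays, one per target
    location; ``baseline``: fixation-period activity samples.  Returns
    (center_deg, reason): center is None unless (1) responses differ
    across locations (one-way ANOVA p < alpha) and (2) mean activity
    exceeds baseline (one-sided t-test p < alpha); the center is the mean
    of a circular-Gaussian fit to the 8 location means.
    """
    responses = [np.asarray(r, dtype=float) for r in responses]
    if angles is None:
        angles = np.arange(0.0, 360.0, 45.0)
    angles = np.asarray(angles, dtype=float)
    pooled = np.concatenate(responses)
    if np.ptp(pooled) == 0:
        return None, "no_location_difference"
    p_loc = stats.f_oneway(*responses).pvalue
    if not p_loc < alpha:
        return None, "no_location_difference"
    p_base = stats.ttest_ind(pooled, np.asarray(baseline, dtype=float),
                             alternative="greater").pvalue
    if not p_base < alpha:
        return None, "not_above_baseline"

    means = np.array([r.mean() for r in responses])

    def model(theta, base, amp, mu, sigma):
        d = np.angle(np.exp(1j * np.deg2rad(theta - mu)))
        return base + amp * np.exp(-0.5 * (np.rad2deg(d) / sigma) ** 2)

    mu0 = angles[np.argmax(means)]
    try:
        popt, _ = optimize.curve_fit(
            model, angles, means,
            p0=[means.min(), np.ptp(means), mu0, 60.0],
            bounds=([-np.inf, 0, mu0 - 180, 5],
                    [np.inf, np.inf, mu0 + 180, 360]),
            maxfev=5000)
    except RuntimeError:
        return None, "fit_failed"
    return float(popt[2]) % 360.0, "ok"
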