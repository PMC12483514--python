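"""End-to-end analysis helpers: train cohorts, test batteries, and the
figure-level statistics (coherence-linked direction selectivity, CT/IT
modulation, connectivity structure, ablation effects, landscape metrics).

These are the building blocks the recipes, the test suite and the
acceptance script share.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import behavior, connectivity, landscape, network, selectivity
from . import task as task_mod
from . import training

TEST_COHERENCES = (0.75, 0.55, 0.35, 0.0)
DS_EPOCH = (50.0, 450.0)   # ms after motion onset, DS evaluation epoch


def train_cohort(n_nets: int, seed: int = 0, train_cfg=None, dyn=None,
                 feedback: bool = True, density_matched: bool = False,
                 verbose: bool = False):
    """Train ``n_nets`` independently initialized networks.

    Seeds are derived deterministically from ``seed``.  Returns a list of
    (params, history) pairs.
    """
    out = []
    for i in range(n_nets):
        net_seed = seed * 1000 + i
        if feedback:
            params = network.build_network(seed=net_seed)
        else:
            from .perturbation import no_feedback_network
            params = no_feedback_network(seed=net_seed,
                                         density_matched=density_matched)
        trained, hist = training.train(params, train_cfg, dyn,
                                       seed=net_seed, verbose=verbose)
        out.append((trained, hist))
    return out


def test_battery(params, seed: int = 0, coherences=TEST_COHERENCES,
                 trials_per_condition: int = 40, dyn=None):
    """Run a test block at untrained coherences.

    Returns (batch, record, behavior_table, rate_table).
    """
    rng = np.random.default_rng(seed)
    n_cells = len(coherences) * 4
    batch = task_mod.generate_batch(trials_per_condition * n_cells,
                                    coherences, None, rng)
    rec = network.forward(params, batch, dyn, rng, dtype=np.float32)
    btab = behavior.behavior_table(rec, batch)
    rtab = selectivity.rate_table_from_rnn(rec, batch, params)
    return batch, rec, btab, rtab


def motion_units(table, params, alpha: float = 0.01):
    """Screened motion-module unit indices (task-modulated, rnn mode)."""
    keep = selectivity.screen_units(table, alpha, mode="rnn")["keep"]
    in_motion = np.isin(params.layout.module, network.MOTION_MODULES)
    return np.where(keep.to_numpy() & in_motion)[0]


def ds_by_coherence(table, params, epoch=DS_EPOCH, units=None):
    """Epoch-mean direction selectivity per motion unit and coherence.

    Direction labels are used at nonzero coherence; choice labels at zero
    coherence.  Returns DataFrame (unit, coherence, roc).
    """
    if units is None:
        units = motion_units(table, params)
    prefs = selectivity.preferred_direction(table)
    coh = table.labels["coherence"].to_numpy()
    rows = []
    for c in np.unique(coh):
        sub = table.subset_trials(coh == c)
        lab = (sub.labels["direction"].to_numpy() if c > 0
               else selectivity.chosen_direction(sub.labels))
        wm = sub.window_mean(epoch)
        for i in units:
            a = wm[i, lab == prefs[i]]
            b = wm[i, lab != prefs[i]]
            if a.size >= 2 and b.size >= 2:
                rows.append({"unit": i, "coherence": c,
                             "roc": selectivity.roc_auc(a, b)})
    return pd.DataFrame(rows)


def ds_coherence_correlation(table, params, window: float = 100.0,
                             step: float = 20.0) -> float:
    """Per-network mean (over motion units) Spearman correlation between
    sliding-window DS and motion coherence.

    For each screened motion unit, the sliding ROC time course (direction
    labels; choice labels at zero coherence) is computed per coherence
    over the whole trial, and the unit's r is the Spearman correlation of
    ROC with coherence across all (coherence, window) points.  Windows
    before motion onset carry no direction information and anchor the
    chance end of the correlation, as in time-resolved DS analyses.
    """
    units = motion_units(table, params)
    prefs = selectivity.preferred_direction(table)
    coh = table.labels["coherence"].to_numpy()
    series = {}
    for c in np.unique(coh):
        sub = table.subset_trials(coh == c)
        split = "direction" if c > 0 else "choice"
        _, roc = selectivity.sliding_roc(sub, window, step, split, prefs)
        series[c] = roc
    rs = []
    for u in units:
        xs, ys = [], []
        for c, roc in series.items():
            ok = np.isfinite(roc[u])
            xs.extend([c] * int(ok.sum()))
            ys.extend(roc[u][ok])
        if len(set(xs)) >= 3:
            r = stats.spearmanr(xs, ys).statistic
            if np.isfinite(r):
                rs.append(r)
    return float(np.mean(rs)) if rs else np.nan


def ct_it_ds_difference(table, params, epoch=DS_EPOCH, units=None):
    """Mean CT - IT direction selectivity over motion units.

    For each screened motion unit, DS (epoch-mean ROC, direction labels;
    choice labels at zero coherence) is computed separately on CT and IT
    trials.  Returns (mean difference, per-unit differences).
    """
    if units is None:
        units = motion_units(table, params)
    prefs = selectivity.preferred_direction(table)
    ct = selectivity.label_ct_it(table, use="correct")
    coh = table.labels["coherence"].to_numpy()
    direc = table.labels["direction"].to_numpy().astype(float)
    chosen = selectivity.chosen_direction(table.labels)
    lab = np.where(coh > 0, direc, chosen)
    wm = table.window_mean(epoch)
    diffs = []
    for i in units:
        vals = {}
        for name, sel in (("ct", ct[i]), ("it", ~ct[i])):
            a = wm[i, sel & (lab == prefs[i])]
            b = wm[i, sel & (lab != prefs[i])]
            vals[name] = selectivity.roc_auc(a, b) \
                if a.size >= 2 and b.size >= 2 else np.nan
        d = vals["ct"] - vals["it"]
        if np.isfinite(d):
            diffs.append(d)
    diffs = np.asarray(diffs)
    return (float(diffs.mean()) if diffs.size else np.nan), diffs


def connectivity_summary(table, params):
    """Preference table, group means, and match-weight correlation."""
    prefs = connectivity.unit_preferences(table, params)
    groups = connectivity.group_weights(params, prefs)
    r = connectivity.match_weight_correlation(params, prefs)
    return prefs, groups, r


def rt_coherence_anova(btab: pd.DataFrame):
    """One-way ANOVA of RT over nonzero coherence levels; returns p."""
    groups = [g["rt_ms"].to_numpy()
              for c, g in btab.groupby("coherence") if c > 0]
    if len(groups) < 2:
        return np.nan
    return float(stats.f_oneway(*groups).pvalue)


def landscape_summary(table, params, seed=0, coherence_conditions=True,
                      n_bins: int = 40, t_eval: float = 300.0,
                      time_pool_ms: float = 100.0, axis=None):
    """Choice-axis fit, per-choice and per-coherence potentials, and basin
    metrics at ``t_eval`` ms after motion onset.

    Pass a fitted ``axis`` (e.g. from the intact network) to project this
    table through the same axis and unit selection, so that basin depths
    are comparable across intact and perturbed networks.
    """
    if axis is not None:
        X = landscape.project_table(table, axis)
    else:
        axis, X = landscape.fit_choice_axis(
            table, params, rng=np.random.default_rng(seed))
    times = table.times
    choice = table.labels["choice"].to_numpy()
    land_choice = landscape.estimate_potential(X, times, choice,
                                               n_bins=n_bins,
                                               time_pool_ms=time_pool_ms)
    combined = landscape.combine_choice_potentials(land_choice)
    metrics = landscape.basin_metrics(combined, land_choice.positions,
                                      land_choice.times, t_eval)
    out = {"axis": axis, "positions": X, "landscape_choice": land_choice,
           "combined": combined, "metrics": metrics}
    if coherence_conditions:
        coh = table.labels["coherence"].to_numpy()
        land_coh = landscape.estimate_potential(X, times, coh, n_bins=n_bins,
                                                time_pool_ms=time_pool_ms)
        depth, by_coh = {}, {}
        for c in np.unique(coh):
            m = landscape.basin_metrics(land_coh.potential[c],
                                        land_coh.positions, land_coh.times,
                                        t_eval)
            depth[float(c)] = m["depth_mean"]
            by_coh[float(c)] = m
        out["landscape_coherence"] = land_coh
        out["depth_by_coherence"] = depth
        out["metrics_by_coherence"] = by_coh
    return out
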