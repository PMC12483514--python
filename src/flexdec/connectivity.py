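"""Selectivity-aligned structure of trained cross-module weights.

"Feedforward" weights run from the motion module to the target module
within a hemisphere; "feedback" weights run from the target module back to
the motion module.  Each cross-module unit pair is labelled matched
(motion unit prefers 315 and target unit prefers red, or 135/green) or
nonmatched, based on signed selectivity strengths, and the feedback edges
are partitioned into a selectivity-specific and a nonspecific group.

Weights are signed by the presynaptic Dale sign (excitatory positive,
inhibitory negative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .network import NetworkParams, feedback_block, feedforward_block
from .selectivity import RateTable

MOTION_SEL_WINDOW = (50.0, 250.0)     # ms after motion onset
TARGET_SEL_WINDOW = (-400.0, -200.0)  # rel. motion onset = 0-200 post-target


def unit_preferences(table: RateTable, params: NetworkParams,
                     motion_window=MOTION_SEL_WINDOW,
                     target_window=TARGET_SEL_WINDOW) -> pd.DataFrame:
    """Signed selectivity strength per unit.

    Motion-module units: mean differential activity to 315 vs 135 motion
    (positive = prefers 315).  Target-module units: mean differential
    activity to red vs green in the unit's response field (positive =
    prefers red), from the post-target window.
    """
    from .network import MOTION_MODULES
    direc = table.labels["direction"].to_numpy()
    wm_motion = table.window_mean(motion_window)
    sel_motion = (wm_motion[:, direc == 315].mean(axis=1)
                  - wm_motion[:, direc == 135].mean(axis=1))

    # color seen by each unit's hemisphere: left hemisphere sees the right
    # location's color, and vice versa
    from .task import RED_RIGHT, RIGHT
    red_loc = np.where(table.labels["target_config"].to_numpy() == RED_RIGHT,
                       RIGHT, 1 - RIGHT)
    wm_target = table.window_mean(target_window)
    hemi = np.asarray(table.hemisphere)
    seen_loc = 1 - hemi                      # contralateral location
    sees_red = red_loc[None, :] == seen_loc[:, None]
    sel_target = np.array([
        wm_target[i, sees_red[i]].mean() - wm_target[i, ~sees_red[i]].mean()
        for i in range(table.n_units)])

    is_motion = np.isin(params.layout.module, MOTION_MODULES)
    strength = np.where(is_motion, sel_motion, sel_target)
    return pd.DataFrame({
        "unit": np.arange(table.n_units),
        "kind": np.where(is_motion, "motion", "target"),
        "strength": strength,
        "preference": np.where(
            is_motion, np.where(sel_motion >= 0, "315", "135"),
            np.where(sel_target >= 0, "red", "green")),
    })


@dataclass
class CrossModuleEdges:
    """Edge list of one cross-module block with match labels."""

    src: np.ndarray
    dst: np.ndarray
    weight: np.ndarray       # signed (Dale) weight
    matched: np.ndarray      # bool
    direction: str           # "feedforward" or "feedback"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"src": self.src, "dst": self.dst,
                             "weight": self.weight, "matched": self.matched,
                             "direction": self.direction})


def _edges(params: NetworkParams, prefs: pd.DataFrame,
           direction: str) -> CrossModuleEdges:
    block = feedback_block(params.layout) if direction == "feedback" \
        else feedforward_block(params.layout)
    w = params.effective_recurrent()
    post, pre = np.where(block & (params.masks.recurrent > 0))
    strength = prefs["strength"].to_numpy()
    if direction == "feedback":
        s_target, s_motion = strength[pre], strength[post]
    else:
        s_motion, s_target = strength[pre], strength[post]
    # matched: (315, red) or (135, green) <=> same selectivity sign
    matched = (s_motion * s_target) > 0
    return CrossModuleEdges(pre, post, w[post, pre], matched, direction)


def group_weights(params: NetworkParams, prefs: pd.DataFrame) -> pd.DataFrame:
    """Mean signed weight for {matched, nonmatched} x {ff, fb} groups."""
    rows = []
    for direction in ("feedforward", "feedback"):
        e = _edges(params, prefs, direction)
        for label, sel in (("matched", e.matched),
                           ("nonmatched", ~e.matched)):
            rows.append({"direction": direction, "group": label,
                         "mean_weight": float(e.weight[sel].mean())
                         if sel.any() else np.nan,
                         "n_edges": int(sel.sum())})
    return pd.DataFrame(rows)


def match_weight_correlation(params: NetworkParams, prefs: pd.DataFrame,
                             direction: str = "feedback",
                             use_rank: bool = True) -> float:
    """Correlation between weight (rank) and selectivity-match similarity.

    Both unit populations are ranked by signed selectivity; a pair's
    similarity is the negated absolute rank difference (ranks rescaled to
    a common [0, 1] range), so well-matched pairs score high.  The sign
    convention is fixed so that a positive correlation means
    stronger-matched pairs carry larger weights.
    """
    e = _edges(params, prefs, direction)
    if e.weight.size < 10:
        raise ValueError("need at least 10 cross-module pairs")
    strength = prefs["strength"].to_numpy()
    kind = prefs["kind"].to_numpy()
    rank = np.empty(len(strength))
    for k in ("motion", "target"):
        sel = kind == k
        r = stats.rankdata(strength[sel])
        rank[sel] = (r - 1) / max(len(r) - 1, 1)   # rescale to [0, 1]
    similarity = -np.abs(rank[e.src] - rank[e.dst])
    if np.ptp(similarity) == 0:
        raise ValueError("similarity is constant; correlation undefined")
    x = stats.rankdata(e.weight) if use_rank else e.weight
    return float(stats.pearsonr(x, similarity).statistic)


def partition_feedback(params: NetworkParams, prefs: pd.DataFrame):
    """Split feedback edges into specific and nonspecific groups.

    Specific: positive weight on a matched pair, or negative weight on a
    nonmatched pair.  Zero-weight edges fall in the nonspecific group.
    Returns (specific_sel, nonspecific_sel, edges): boolean selectors over
    the edge list.
    """
    e = _edges(params, prefs, "feedback")
    specific = (e.matched & (e.weight > 0)) | (~e.matched & (e.weight < 0))
    return specific, ~specific, e


def edge_table(params: NetworkParams, prefs: pd.DataFrame) -> pd.DataFrame:
    """Full cross-module edge list with module and group annotations."""
    frames = []
    for direction in ("feedforward", "feedback"):
        e = _edges(params, prefs, direction)
        df = e.to_frame()
        df["src_module"] = params.layout.module[e.src]
        df["dst_module"] = params.layout.module[e.dst]
        if direction == "feedback":
            spec, _, _ = partition_feedback(params, prefs)
            df["group"] = np.where(spec, "specific", "nonspecific")
        else:
            df["group"] = ""
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
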