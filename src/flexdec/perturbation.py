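"""Projection-specific inactivation experiments in silico.

Three families of manipulation of the within-hemisphere target->motion
("feedback") projection of a trained network:

* ablation — zero all feedback weights, or only the selectivity-specific /
  nonspecific subgroup;
* shuffling — permute the feedback weight values over the existing
  feedback edge positions (topology and total strength preserved);
* no-feedback retraining — build networks whose masks never contain
  feedback edges, optionally raising the remaining recurrent connection
  probabilities by 1.176 to match the full model's connection count.

All perturbations touch only the targeted weight block; everything else is
bitwise unchanged.
"""

from __future__ import annotations

import warnings

import numpy as np

from .network import (ConnectionProbs, NetworkParams, build_layout,
                      feedback_block, init_params, sample_masks)

DENSITY_MATCH_FACTOR = 1.176


def ablate_feedback(params: NetworkParams) -> NetworkParams:
    """Zero all within-hemisphere target->motion weights."""
    out = params.copy()
    block = feedback_block(out.layout)
    out.w_rec[block] = 0.0
    out.masks.recurrent[block] = 0
    return out


def shuffle_feedback(params: NetworkParams, rng=None,
                     per_hemisphere: bool = True) -> NetworkParams:
    """Permute feedback weights over the existing feedback edges.

    The multiset of nonzero feedback weights (and hence any weight-sum
    statistic of the block) is preserved exactly; only the assignment of
    weights to edges changes.  By default the permutation is performed
    within each hemisphere, preserving hemispheric totals.
    """
    rng = rng if rng is not None else np.random.default_rng()
    out = params.copy()
    block = feedback_block(out.layout)
    edges = block & (out.masks.recurrent > 0)
    if per_hemisphere:
        for h in (0, 1):
            hemi_units = out.layout.hemisphere == h
            sub = edges & hemi_units[:, None] & hemi_units[None, :]
            vals = out.w_rec[sub]
            out.w_rec[sub] = rng.permutation(vals)
    else:
        vals = out.w_rec[edges]
        out.w_rec[edges] = rng.permutation(vals)
    return out


def ablate_group(params: NetworkParams, group: str, prefs) -> NetworkParams:
    """Zero only the specific or nonspecific feedback edges.

    ``prefs`` is the unit-preference table from
    :func:`flexdec.connectivity.unit_preferences`.
    """
    from .connectivity import partition_feedback
    if group not in ("specific", "nonspecific"):
        raise ValueError(f"unknown group {group!r}")
    specific, nonspecific, edges = partition_feedback(params, prefs)
    sel = specific if group == "specific" else nonspecific
    if not sel.any():
        warnings.warn(f"{group} feedback group is empty; returning an "
                      "unmodified copy")
        return params.copy()
    out = params.copy()
    out.w_rec[edges.dst[sel], edges.src[sel]] = 0.0
    out.masks.recurrent[edges.dst[sel], edges.src[sel]] = 0
    return out


def no_feedback_network(seed=None, n_units: int = 200,
                        probs: ConnectionProbs | None = None,
                        density_matched: bool = False,
                        stp=None) -> NetworkParams:
    """Build a network whose masks exclude feedback edges from the start.

    With ``density_matched=True`` the remaining recurrent connection
    probabilities are multiplied by 1.176 (capped at 1) so the expected
    connection count matches the full model's.
    """
    probs = probs or ConnectionProbs()
    if density_matched:
        probs = probs.scaled_recurrent(DENSITY_MATCH_FACTOR)
        if max(probs.local, probs.across_rf, probs.cross_hemisphere) >= 1.0:
            warnings.warn("a scaled connection probability was capped at 1")
    rng = np.random.default_rng(seed)
    layout = build_layout(n_units)
    masks = sample_masks(layout, probs, rng, feedback=False)
    return init_params(masks, layout, rng, stp)
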