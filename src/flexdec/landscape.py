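"""Attractor-landscape reconstruction of target-module population activity.

The population state of saccade-selective target-module units is reduced
to five principal components (fitted on condition-averaged activity), a
choice axis is taken as the unit normal of the best cross-validated linear
SVM hyperplane on late-trial activity, single-trial trajectories are
projected to one dimension (decision boundary at 0), and a potential

    V(x, t) = -dx * sum over bins p between 0 and x of E[dX/dt | X_t = p]

is accumulated outward from the boundary, separately per condition
(choice, or stimulus coherence).  Basin depth and separation are then read
off the reconstructed potential.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC


class ChoiceAxis(BaseEstimator, TransformerMixin):
    """PCA + linear-SVM choice axis for population activity.

    Parameters
    ----------
    n_components : PCA components retained (fitted on condition means).
    C : SVM regularization strength.
    n_folds : cross-validation folds for the linear classifier.
    readout_window_ms : length of the end-of-trial window whose mean
        activity feeds the classifier.

    Attributes (after fit)
    ----------------------
    pca_ : fitted PCA on condition-averaged activity.
    axis_ : unit normal of the best fold's separating hyperplane (5-d).
    offset_ : scalar such that position = pc @ axis_ + offset_ is 0 on
        the hyperplane.
    cv_accuracy_ : mean held-out accuracy over folds.
    variance_explained_ : total PCA variance ratio captured.
    reliable_ : False when the classifier performs at chance.
    """

    def __init__(self, n_components=5, C=1.0, n_folds=10,
                 readout_window_ms=100.0, random_state=None):
        self.n_components = n_components
        self.C = C
        self.n_folds = n_folds
        self.readout_window_ms = readout_window_ms
        self.random_state = random_state

    def fit(self, X, y, conditions=None, times=None):
        """Fit the axis.

        X: (trials, units, timepoints) activity; y: binary choice labels;
        conditions: per-trial condition ids used for the PCA condition
        averages (defaults to the choice labels); times: ms axis of the
        third dimension (defaults to uniform, readout = last window).
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        n_trials, n_units, n_t = X.shape
        if conditions is None:
            conditions = y
        conditions = np.asarray(conditions)

        cond_means = []
        for c in np.unique(conditions):
            cond_means.append(X[conditions == c].mean(axis=0).T)  # (t, units)
        cm = np.concatenate(cond_means, axis=0)
        self.pca_ = PCA(n_components=self.n_components).fit(cm)
        self.variance_explained_ = float(
            self.pca_.explained_variance_ratio_.sum())
        if self.variance_explained_ < 0.90:
            import warnings
            warnings.warn(
                f"top {self.n_components} components explain only "
                f"{self.variance_explained_:.1%} of condition-averaged "
                "variance")

        if times is None:
            times = np.arange(n_t, dtype=float)
        late = times >= times.max() - self.readout_window_ms
        feat = self.pca_.transform(X[:, :, late].mean(axis=2))

        best = None
        skf = StratifiedKFold(self.n_folds, shuffle=True,
                              random_state=self.random_state)
        accs = []
        for tr_idx, te_idx in skf.split(feat, y):
            clf = SVC(kernel="linear", C=self.C).fit(feat[tr_idx], y[tr_idx])
            acc = float(np.mean(clf.predict(feat[te_idx]) == y[te_idx]))
            accs.append(acc)
            margin = 1.0 / np.linalg.norm(clf.coef_)
            key = (acc, margin)
            if best is None or key > best[0]:
                best = (key, clf)
        self.cv_accuracy_ = float(np.mean(accs))
        clf = best[1]
        w = clf.coef_.ravel()
        norm = np.linalg.norm(w)
        self.axis_ = w / norm
        self.offset_ = float(clf.intercept_[0]) / norm
        self.reliable_ = self.cv_accuracy_ > 0.5 + 1.0 / np.sqrt(len(y))
        return self

    def transform(self, X):
        """Project (trials, units, timepoints) activity to 1-d positions.

        Returns (trials, timepoints); 0 is the decision boundary, positive
        values lie on the side the classifier labels 1.
        """
        X = np.asarray(X, dtype=float)
        n_trials, n_units, n_t = X.shape
        flat = np.transpose(X, (0, 2, 1)).reshape(-1, n_units)
        pc = self.pca_.transform(flat)
        pos = pc @ self.axis_ + self.offset_
        return pos.reshape(n_trials, n_t)

    def project_points(self, pc_points):
        """Project already-reduced (n, n_components) points to positions."""
        return np.asarray(pc_points) @ self.axis_ + self.offset_


def fit_choice_axis(table, params=None, rng=None, alpha=0.01, units=None,
                    **axis_kwargs) -> tuple[ChoiceAxis, np.ndarray]:
    """Fit the choice axis on saccade-selective target-module units.

    ``table`` is a RateTable (RNN units or neurons).  When ``params`` is
    given, units are restricted to the target modules; units must show
    saccade (choice) modulation at p < alpha (or pass ``units`` to fix
    the selection).  Returns (axis, X_t), where X_t is the
    (trials, time) 1-d projection of the selected population; the unit
    selection is stored on the axis as ``units_`` so other recordings can
    be projected through the same axis via :func:`project_table`.
    """
    from scipy import stats as sstats
    choice = table.labels["choice"].to_numpy()
    if units is None:
        sel = np.ones(table.n_units, dtype=bool)
        if params is not None:
            from .network import TARGET_MODULES
            sel &= np.isin(params.layout.module, TARGET_MODULES)
        wm = table.window_mean((0, table.times.max()))
        keep = []
        for i in np.where(sel)[0]:
            g = [wm[i, choice == s] for s in np.unique(choice)]
            if len(g) == 2 and all(x.size >= 2 for x in g) and \
                    np.ptp(np.concatenate(g)) > 0:
                if sstats.f_oneway(*g).pvalue < alpha:
                    keep.append(i)
        keep = np.array(keep, dtype=int)
    else:
        keep = np.asarray(units, dtype=int)
    if keep.size < 2:
        raise ValueError("fewer than 2 saccade-selective units")
    sub = table.subset_units(keep)
    X = np.transpose(sub.rates, (1, 0, 2))        # (trials, units, time)
    if rng is None:
        seed = None
    elif np.isscalar(rng):
        seed = int(np.random.default_rng(rng).integers(2 ** 31))
    else:
        seed = int(rng.integers(2 ** 31))
    axis = ChoiceAxis(random_state=seed, **axis_kwargs)
    conds = pd.MultiIndex.from_frame(
        table.labels[["direction", "coherence", "choice"]]).factorize()[0]
    axis.fit(X, choice, conditions=conds, times=sub.times)
    axis.units_ = keep
    return axis, axis.transform(X)


def project_table(table, axis: ChoiceAxis) -> np.ndarray:
    """Project a RateTable through a previously fitted choice axis.

    Uses the axis's stored unit selection, so positions from different
    recordings (e.g. intact vs perturbed networks) share one scale.
    """
    sub = table.subset_units(axis.units_)
    return axis.transform(np.transpose(sub.rates, (1, 0, 2)))


@dataclass
class EnergyLandscape:
    """Potential on a (position x time) grid for one or more conditions."""

    positions: np.ndarray                 # bin centers; 0 = boundary
    times: np.ndarray                     # ms
    dx: float
    potential: dict = field(default_factory=dict)   # cond -> (bins, times)
    visits: dict = field(default_factory=dict)      # cond -> counts

    def save(self, path):
        with h5py.File(path, "w") as f:
            f.create_dataset("positions", data=self.positions)
            f.create_dataset("times", data=self.times)
            f.attrs["dx"] = self.dx
            for cond in self.potential:
                g = f.create_group(f"condition_{cond}")
                g.create_dataset("potential", data=self.potential[cond])
                g.create_dataset("visits", data=self.visits[cond])


def make_grid(positions, n_bins: int = 40, coverage: float = 0.99):
    """Uniform grid over the central ``coverage`` mass of visited
    positions, with a bin edge exactly at 0.  Returns (edges, centers)."""
    pos = np.asarray(positions).ravel()
    pos = pos[np.isfinite(pos)]
    tail = (1 - coverage) / 2
    lo, hi = np.quantile(pos, [tail, 1 - tail])
    lo, hi = min(lo, 0), max(hi, 0)
    dx = (hi - lo) / n_bins
    n_neg = int(np.ceil(-lo / dx))
    n_pos = int(np.ceil(hi / dx))
    edges = np.arange(-n_neg, n_pos + 1) * dx
    centers = (edges[:-1] + edges[1:]) / 2
    return edges, centers


def _binned_drift(x_now, x_next, dt, edges, min_count=1):
    """Mean drift (per ms) and visit count per position bin."""
    drift = (x_next - x_now) / dt
    idx = np.digitize(x_now, edges) - 1
    n_bins = len(edges) - 1
    mean = np.full(n_bins, np.nan)
    count = np.zeros(n_bins, dtype=int)
    ok = (idx >= 0) & (idx < n_bins)
    for b in range(n_bins):
        sel = ok & (idx == b)
        count[b] = sel.sum()
        if count[b] >= min_count:
            mean[b] = drift[sel].mean()
    return mean, count


def _integrate(drift, centers, dx):
    """Potential from binned drift, anchored V = 0 at the boundary.

    Midpoint rule: a bin's own drift contributes half a bin width at its
    center, so constant drift g yields V(x) = -g x exactly.  Accumulation
    stops at unvisited bins (gaps stay blank).
    """
    v = np.full(len(centers), np.nan)
    pos_side = np.where(centers > 0)[0]
    neg_side = np.where(centers < 0)[0][::-1]
    for side, sign in ((pos_side, 1.0), (neg_side, -1.0)):
        acc = 0.0
        for j in side:
            if not np.isfinite(drift[j]):
                break
            v[j] = -(acc + 0.5 * drift[j] * dx) * sign
            acc += drift[j] * dx
    return v


def estimate_potential(positions, times, condition_labels, dt=None,
                       n_bins: int = 40, min_count: int = 1,
                       time_pool_ms: float | None = None) -> EnergyLandscape:
    """Reconstruct V(x, t) per condition from 1-d trajectories.

    positions: (trials, timepoints) projections on the choice axis;
    times: ms axis; condition_labels: per-trial labels (e.g. choice or
    coherence); dt defaults to the time-axis spacing.  Drift at time t is
    conditioned on the position bin occupied at t.  With ``time_pool_ms``
    set, drift samples are pooled over time bins of that width, which
    densifies the position coverage late in the trial when most
    trajectories have already settled at the attractors.
    """
    positions = np.asarray(positions, dtype=float)
    times = np.asarray(times, dtype=float)
    if dt is None:
        dt = float(np.median(np.diff(times)))
    edges, centers = make_grid(positions, n_bins)
    dx = float(edges[1] - edges[0])
    step_times = times[:-1]
    if time_pool_ms is None:
        groups = [np.array([k]) for k in range(len(step_times))]
        t_out = step_times
    else:
        lo = step_times.min()
        bin_idx = ((step_times - lo) // time_pool_ms).astype(int)
        groups = [np.where(bin_idx == b)[0] for b in np.unique(bin_idx)]
        t_out = np.array([step_times[g].mean() for g in groups])
    cond_labels = np.asarray(condition_labels)
    land = EnergyLandscape(centers, t_out, dx)
    for cond in np.unique(cond_labels):
        rows = np.where(cond_labels == cond)[0]
        V = np.full((len(centers), len(groups)), np.nan)
        counts = np.zeros((len(centers), len(groups)), dtype=int)
        for col, g in enumerate(groups):
            x_now = positions[np.ix_(rows, g)].ravel()
            x_next = positions[np.ix_(rows, g + 1)].ravel()
            drift, cnt = _binned_drift(x_now, x_next, dt, edges, min_count)
            V[:, col] = _integrate(drift, centers, dx)
            counts[:, col] = cnt
        land.potential[cond] = V
        land.visits[cond] = counts
    return land


def combine_choice_potentials(land: EnergyLandscape,
                              side_of: dict | None = None) -> np.ndarray:
    """Join the two per-choice potentials at position 0.

    Each choice contributes the branch on its own side of the boundary
    (determined by the sign of its mean visited position).  Returns a
    (bins, times) array.
    """
    conds = sorted(land.potential)
    if len(conds) != 2:
        raise ValueError("expected exactly two choice conditions")
    if side_of is None:
        # each choice owns the side its trajectories occupy late in the
        # trial (early columns sit at the pre-decision baseline and are
        # uninformative about the attractor side)
        late = max(1, land.visits[conds[0]].shape[1] // 3)
        side_of = {}
        for c in conds:
            w = land.visits[c][:, -late:].sum(axis=1).astype(float)
            side_of[c] = np.sign(np.average(land.positions, weights=w)
                                 if w.sum() else 1.0)
        if side_of[conds[0]] == side_of[conds[1]]:
            # degenerate: assign by relative mean position
            m = [np.average(land.positions,
                            weights=land.visits[c][:, -late:].sum(axis=1)
                            + 1e-9) for c in conds]
            order = np.argsort(m)
            side_of[conds[order[0]]] = -1.0
            side_of[conds[order[1]]] = 1.0
    combined = np.full_like(land.potential[conds[0]], np.nan)
    for c in conds:
        sel = (land.positions * side_of[c]) > 0
        combined[sel] = land.potential[c][sel]
    return combined


def basin_metrics(potential, positions, times, t_eval: float = 300.0,
                  t_window: float = 0.0) -> dict:
    """Attractor-basin depth and separation at evaluation time.

    depth = V(boundary) - min V within each side's visited range (>= 0
    when a basin exists); separation = distance between the two minima.
    Sides without an interior minimum are flagged.
    """
    potential = np.asarray(potential)
    times = np.asarray(times)
    if t_window > 0:
        cols = np.abs(times - t_eval) <= t_window / 2
    else:
        cols = [int(np.argmin(np.abs(times - t_eval)))]
    block = potential[:, cols]
    if block.size:
        finite_rows = np.isfinite(block).any(axis=1)
        v = np.full(len(positions), np.nan)
        v[finite_rows] = np.nanmean(block[finite_rows], axis=1)
    else:
        v = np.full(len(positions), np.nan)
    out = {"t_eval": t_eval}
    minima = {}
    for name, sel in (("left", positions < 0), ("right", positions > 0)):
        vv = v[sel]
        pp = positions[sel]
        if not np.isfinite(vv).any():
            out[f"depth_{name}"] = 0.0
            out[f"flag_{name}"] = "unvisited"
            continue
        j = np.nanargmin(vv)
        depth = max(0.0, -float(vv[j]))
        out[f"depth_{name}"] = depth
        out[f"flag_{name}"] = "" if depth > 0 else "no_basin"
        minima[name] = float(pp[j])
    if len(minima) == 2 and out["depth_left"] > 0 and out["depth_right"] > 0:
        out["separation"] = minima["right"] - minima["left"]
    else:
        out["separation"] = np.nan
    out["depth_mean"] = float(np.mean([out.get("depth_left", 0.0),
                                       out.get("depth_right", 0.0)]))
    return out


def aggregate_models(landscapes, min_models: int = 4):
    """Positionwise mean and SE of per-model potentials on a common grid.

    ``landscapes``: list of (positions, values) 1-d profiles on the SAME
    grid.  Positions are retained only where they fall inside the
    contiguous visited span (around the boundary) of at least
    ``min_models`` models.  Returns (mean, se, count) arrays.
    """
    values = np.asarray([v for _, v in landscapes], dtype=float)
    positions = np.asarray(landscapes[0][0])
    n_models, n_bins = values.shape
    in_span = np.zeros_like(values, dtype=bool)
    b0 = int(np.argmin(np.abs(positions)))
    for m in range(n_models):
        fin = np.isfinite(values[m])
        # walk outward from the boundary until the first gap on each side
        for j in range(b0, n_bins):
            if not fin[j]:
                break
            in_span[m, j] = True
        for j in range(b0 - 1, -1, -1):
            if not fin[j]:
                break
            in_span[m, j] = True
    count = in_span.sum(axis=0)
    keep = count >= min_models
    mean = np.full(n_bins, np.nan)
    se = np.full(n_bins, np.nan)
    for j in np.where(keep)[0]:
        vals = values[in_span[:, j], j]
        mean[j] = vals.mean()
        se[j] = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
    return mean, se, count
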