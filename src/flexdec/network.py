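"""Multi-module excitatory/inhibitory rate RNN.

200 hidden units split into two "hemispheres", each containing a motion
module and a target module (40 excitatory + 10 inhibitory units per nominal
module).  Recurrent connectivity is sparse with class-specific densities
(local 50%, across-RF 25%, cross-hemisphere 10%, the latter excitatory-only
and restricted to corresponding modules).  Input and output weights are
fixed and non-negative; outputs are read from excitatory target-module
units with a dense contralateral (0.32) and sparse ipsilateral (0.08)
projection and passed through a softmax.  Synapses carry short-term
plasticity (facilitation/depression, assigned per presynaptic unit).

Dale's law is enforced by parameterizing the trainable recurrent matrix as
``W_eff = |W| * mask * sign(presynaptic unit)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
from scipy.stats import truncnorm

MOTION_L, TARGET_L, MOTION_R, TARGET_R = 0, 1, 2, 3
MOTION_MODULES = (MOTION_L, MOTION_R)
TARGET_MODULES = (TARGET_L, TARGET_R)

N_MOTION_IN, N_TARGET_IN = 9, 8
N_IN = N_MOTION_IN + N_TARGET_IN
N_OUT = 2


@dataclass
class ModuleLayout:
    """Unit-to-module assignment and Dale signs."""

    n_units: int
    module: np.ndarray     # nominal module id per unit (0..3)
    dale_sign: np.ndarray  # +1 excitatory, -1 inhibitory
    hemisphere: np.ndarray  # 0 = left, 1 = right

    @property
    def excitatory(self) -> np.ndarray:
        return self.dale_sign > 0

    def units_of(self, module_id, excitatory_only=False) -> np.ndarray:
        sel = self.module == module_id
        if excitatory_only:
            sel &= self.excitatory
        return np.where(sel)[0]


def build_layout(n_units: int = 200, frac_exc: float = 0.8) -> ModuleLayout:
    """Deterministic layout: 4 nominal modules, each with frac_exc excitatory.

    Units are ordered [motion-L, target-L, motion-R, target-R]; within each
    module, excitatory units first.
    """
    if n_units % 4:
        raise ValueError("n_units must be divisible by 4")
    per_mod = n_units // 4
    n_exc = frac_exc * per_mod
    if abs(n_exc - round(n_exc)) > 1e-9:
        raise ValueError(
            f"frac_exc={frac_exc} gives a non-integer count of excitatory "
            f"units per module")
    n_exc = int(round(n_exc))
    module = np.repeat(np.arange(4), per_mod)
    sign = np.ones(n_units, dtype=int)
    for m in range(4):
        sign[m * per_mod + n_exc:(m + 1) * per_mod] = -1
    hemi = (module >= 2).astype(int)
    return ModuleLayout(n_units, module, sign, hemi)


@dataclass
class ConnectionProbs:
    local: float = 0.5
    across_rf: float = 0.25
    cross_hemisphere: float = 0.10
    input_p: float = 0.32
    output_contra: float = 0.32
    output_ipsi: float = 0.08

    def scaled_recurrent(self, factor: float) -> "ConnectionProbs":
        """Scale all recurrent probabilities (capped at 1)."""
        return replace(self,
                       local=min(1.0, self.local * factor),
                       across_rf=min(1.0, self.across_rf * factor),
                       cross_hemisphere=min(1.0, self.cross_hemisphere * factor))


@dataclass
class ConnectivityMasks:
    """Binary masks; recurrent is (post, pre), input (post, channel),
    output (response_unit, post)."""

    recurrent: np.ndarray
    input: np.ndarray
    output: np.ndarray

    @property
    def n_connections(self) -> int:
        return int(self.recurrent.sum())


def recurrent_probability_matrix(layout: ModuleLayout,
                                 probs: ConnectionProbs,
                                 feedback: bool = True) -> np.ndarray:
    """Per-ordered-pair connection probability (post, pre)."""
    n = layout.n_units
    mod = layout.module
    same_mod = mod[None, :] == mod[:, None]
    same_hemi = layout.hemisphere[None, :] == layout.hemisphere[:, None]
    p = np.zeros((n, n))
    p[same_mod] = probs.local
    p[same_hemi & ~same_mod] = probs.across_rf
    # cross-hemisphere: corresponding module only, excitatory sources only
    corresponding = (mod[:, None] % 2) == (mod[None, :] % 2)
    exc_pre = layout.excitatory[None, :]
    p[~same_hemi & corresponding & exc_pre] = probs.cross_hemisphere
    np.fill_diagonal(p, 0.0)
    if not feedback:
        p[feedback_block(layout)] = 0.0
    return p


def feedback_block(layout: ModuleLayout) -> np.ndarray:
    """Boolean (post, pre) selector of within-hemisphere target->motion
    ("feedback") connections."""
    mod = layout.module
    post_motion = np.isin(mod, MOTION_MODULES)[:, None]
    pre_target = np.isin(mod, TARGET_MODULES)[None, :]
    same_hemi = layout.hemisphere[:, None] == layout.hemisphere[None, :]
    return post_motion & pre_target & same_hemi


def feedforward_block(layout: ModuleLayout) -> np.ndarray:
    """Within-hemisphere motion->target connections (post, pre)."""
    mod = layout.module
    post_target = np.isin(mod, TARGET_MODULES)[:, None]
    pre_motion = np.isin(mod, MOTION_MODULES)[None, :]
    same_hemi = layout.hemisphere[:, None] == layout.hemisphere[None, :]
    return post_target & pre_motion & same_hemi


def expected_n_connections(layout: ModuleLayout, probs: ConnectionProbs,
                           feedback: bool = True) -> float:
    return float(recurrent_probability_matrix(layout, probs, feedback).sum())


def sample_masks(layout: ModuleLayout, probs: ConnectionProbs | None = None,
                 rng=None, feedback: bool = True) -> ConnectivityMasks:
    """Bernoulli-sample the three connectivity masks."""
    probs = probs or ConnectionProbs()
    rng = rng if rng is not None else np.random.default_rng()
    n = layout.n_units
    p_rec = recurrent_probability_matrix(layout, probs, feedback)
    rec = (rng.random((n, n)) < p_rec).astype(np.int8)

    p_in = np.zeros((n, N_IN))
    motion_units = np.isin(layout.module, MOTION_MODULES)
    p_in[np.ix_(motion_units, range(N_MOTION_IN))] = probs.input_p
    # target channels 0-3 -> left-hemisphere target module, 4-7 -> right
    for hemi, mod_id in ((0, TARGET_L), (1, TARGET_R)):
        cols = N_MOTION_IN + 4 * hemi + np.arange(4)
        p_in[np.ix_(layout.module == mod_id, cols)] = probs.input_p
    inp = (rng.random(p_in.shape) < p_in).astype(np.int8)

    p_out = np.zeros((N_OUT, n))
    for mod_id, hemi in ((TARGET_L, 0), (TARGET_R, 1)):
        src = layout.units_of(mod_id, excitatory_only=True)
        contra, ipsi = 1 - hemi, hemi
        p_out[contra, src] = probs.output_contra
        p_out[ipsi, src] = probs.output_ipsi
    out = (rng.random(p_out.shape) < p_out).astype(np.int8)
    return ConnectivityMasks(rec, inp, out)


@dataclass
class STPConfig:
    """Short-term plasticity: half the units facilitating, half depressing."""

    enabled: bool = True
    tau_f_fac: float = 1500.0
    tau_d_fac: float = 200.0
    u_fac: float = 0.15
    tau_f_dep: float = 200.0
    tau_d_dep: float = 1500.0
    u_dep: float = 0.45

    def per_unit(self, n_units):
        """(tau_f, tau_d, U) arrays; even-indexed units facilitate."""
        fac = np.arange(n_units) % 2 == 0
        tau_f = np.where(fac, self.tau_f_fac, self.tau_f_dep)
        tau_d = np.where(fac, self.tau_d_fac, self.tau_d_dep)
        u = np.where(fac, self.u_fac, self.u_dep)
        return tau_f, tau_d, u


@dataclass
class DynamicsConfig:
    tau_mem: float = 100.0
    sigma_rec: float = 0.3
    stp: STPConfig = field(default_factory=STPConfig)

    def alpha(self, dt: float) -> float:
        return dt / self.tau_mem


def _redraw_extremes(values, rng, mean=0.2, sd=0.05, ratio=0.75):
    """Redraw entries below ratio*max from the acceptable band so that
    min >= ratio * max holds exactly (extreme-value re-initialization)."""
    m = values.max()
    lo = ratio * m
    bad = values < lo
    if bad.any():
        a, b = (lo - mean) / sd, (m - mean) / sd
        values[bad] = truncnorm.rvs(a, b, loc=mean, scale=sd,
                                    size=bad.sum(), random_state=rng)
    return values


@dataclass
class NetworkParams:
    """Trainable and fixed parameters together with structure."""

    layout: ModuleLayout
    masks: ConnectivityMasks
    w_in: np.ndarray     # fixed, (n, 17), non-negative
    w_rec: np.ndarray    # trainable magnitude-bearing matrix, (n, n)
    bias: np.ndarray     # trainable, (n,)
    h0: np.ndarray       # trainable initial rates, (n,)
    w_out: np.ndarray    # fixed, (2, n), non-negative
    stp_tau_f: np.ndarray
    stp_tau_d: np.ndarray
    stp_u: np.ndarray
    stp_enabled: bool = True

    def effective_recurrent(self) -> np.ndarray:
        """|W| * mask * Dale sign of the presynaptic (column) unit."""
        return (np.abs(self.w_rec) * self.masks.recurrent
                * self.layout.dale_sign[None, :])

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            self.layout,
            ConnectivityMasks(self.masks.recurrent.copy(),
                              self.masks.input.copy(),
                              self.masks.output.copy()),
            self.w_in.copy(), self.w_rec.copy(), self.bias.copy(),
            self.h0.copy(), self.w_out.copy(),
            self.stp_tau_f.copy(), self.stp_tau_d.copy(), self.stp_u.copy(),
            self.stp_enabled)

    def save(self, path):
        with h5py.File(path, "w") as f:
            for name, arr in (("w_in", self.w_in), ("w_rec", self.w_rec),
                              ("bias", self.bias), ("h0", self.h0),
                              ("w_out", self.w_out),
                              ("mask_rec", self.masks.recurrent),
                              ("mask_in", self.masks.input),
                              ("mask_out", self.masks.output),
                              ("module", self.layout.module),
                              ("dale_sign", self.layout.dale_sign),
                              ("stp_tau_f", self.stp_tau_f),
                              ("stp_tau_d", self.stp_tau_d),
                              ("stp_u", self.stp_u)):
                f.create_dataset(name, data=arr)
            f.attrs["stp_enabled"] = self.stp_enabled

    @classmethod
    def load(cls, path):
        with h5py.File(path, "r") as f:
            module = f["module"][...]
            sign = f["dale_sign"][...]
            layout = ModuleLayout(len(module), module, sign,
                                  (module >= 2).astype(int))
            return cls(layout,
                       ConnectivityMasks(f["mask_rec"][...], f["mask_in"][...],
                                         f["mask_out"][...]),
                       f["w_in"][...], f["w_rec"][...], f["bias"][...],
                       f["h0"][...], f["w_out"][...],
                       f["stp_tau_f"][...], f["stp_tau_d"][...],
                       f["stp_u"][...], bool(f.attrs["stp_enabled"]))


def init_params(masks: ConnectivityMasks, layout: ModuleLayout, rng=None,
                stp: STPConfig | None = None, weight_mean: float = 0.2,
                weight_sd: float = 0.05, gamma_shape: float = 0.1,
                gamma_scale: float = 0.02) -> NetworkParams:
    """Initialize parameters.

    Input/output weights are drawn N(0.2, 0.05) on masked entries; extreme
    (low) values per input channel / output unit are re-drawn from the
    acceptable band so that min >= 3/4 * max over the nonzero fan-out.
    Recurrent magnitudes are gamma-distributed (long-tailed, mostly small).
    """
    rng = rng if rng is not None else np.random.default_rng()
    stp = stp or STPConfig()
    n = layout.n_units

    w_in = np.zeros((n, N_IN))
    for ch in range(N_IN):
        sel = masks.input[:, ch] > 0
        if sel.any():
            vals = rng.normal(weight_mean, weight_sd, size=sel.sum())
            np.abs(vals, out=vals)  # excitatory input projections
            w_in[sel, ch] = _redraw_extremes(vals, rng, weight_mean, weight_sd)

    w_out = np.zeros((N_OUT, n))
    for o in range(N_OUT):
        sel = masks.output[o] > 0
        if sel.any():
            vals = rng.normal(weight_mean, weight_sd, size=sel.sum())
            np.abs(vals, out=vals)
            w_out[o, sel] = _redraw_extremes(vals, rng, weight_mean, weight_sd)

    w_rec = np.zeros((n, n))
    nz = masks.recurrent > 0
    w_rec[nz] = rng.gamma(gamma_shape, gamma_scale, size=int(nz.sum()))
    bias = np.zeros(n)
    h0 = 0.1 * rng.random(n)
    tau_f, tau_d, u = stp.per_unit(n)
    return NetworkParams(layout, masks, w_in, w_rec, bias, h0, w_out,
                         tau_f, tau_d, u, stp.enabled)


def build_network(seed=None, n_units: int = 200,
                  probs: ConnectionProbs | None = None,
                  stp: STPConfig | None = None,
                  feedback: bool = True) -> NetworkParams:
    """Convenience constructor: layout -> masks -> params."""
    rng = np.random.default_rng(seed)
    layout = build_layout(n_units)
    masks = sample_masks(layout, probs, rng, feedback=feedback)
    return init_params(masks, layout, rng, stp)


@dataclass
class NetworkState:
    h: np.ndarray
    stp_u: np.ndarray
    stp_x: np.ndarray
    output_prob: np.ndarray


@dataclass
class ActivityRecord:
    """Hidden rates and output probabilities over a batch.

    ``rates[k]`` is the state after integrating input step k; its time is
    ``times[k] = (k+1)*dt`` ms from trial start.
    """

    rates: np.ndarray     # (steps, trials, n)
    outputs: np.ndarray   # (steps, trials, 2)
    times: np.ndarray     # ms from trial start

    def save(self, path):
        with h5py.File(path, "w") as f:
            f.create_dataset("rates", data=self.rates)
            f.create_dataset("outputs", data=self.outputs)
            f.create_dataset("times", data=self.times)


def softmax2(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def initial_state(params: NetworkParams, n_trials: int,
                  dtype=np.float64) -> NetworkState:
    n = params.layout.n_units
    h = np.broadcast_to(np.maximum(params.h0, 0.0),
                        (n_trials, n)).astype(dtype).copy()
    u = np.broadcast_to(params.stp_u, (n_trials, n)).astype(dtype).copy()
    x = np.ones((n_trials, n), dtype=dtype)
    out = softmax2(h @ params.w_out.T.astype(dtype))
    return NetworkState(h, u, x, out)


def step(state: NetworkState, input_t, params: NetworkParams,
         cfg: DynamicsConfig, dt: float, rng=None) -> NetworkState:
    """One Euler step of the rate + STP dynamics.

    h <- (1 - a) h + a relu(W_eff (u*x*h) + W_in x_t + b + noise),
    with a = dt/tau_mem and recurrent noise sqrt(2/a) N(0, sigma_rec)
    inside the rectifier.  STP variables follow the standard
    facilitation/depression pair, clipped to [0, 1].
    """
    if not np.all(np.isfinite(state.h)):
        raise FloatingPointError("non-finite network state")
    a = cfg.alpha(dt)
    w_eff = params.effective_recurrent()
    if params.stp_enabled:
        s = state.stp_u * state.stp_x * state.h
    else:
        s = state.h
    z = s @ w_eff.T + np.atleast_2d(input_t) @ params.w_in.T + params.bias
    if rng is not None and cfg.sigma_rec > 0:
        z = z + np.sqrt(2.0 / a) * rng.normal(0.0, cfg.sigma_rec, size=z.shape)
    h = (1 - a) * state.h + a * np.maximum(z, 0.0)

    if params.stp_enabled:
        dt_s = dt / 1000.0
        ad = dt_s * 1000.0 / params.stp_tau_d
        af = dt_s * 1000.0 / params.stp_tau_f
        x = state.stp_x + ad * (1 - state.stp_x) \
            - dt_s * state.stp_u * state.stp_x * state.h
        u = state.stp_u + af * (params.stp_u - state.stp_u) \
            + dt_s * params.stp_u * (1 - state.stp_u) * state.h
        x = np.clip(x, 0.0, 1.0)
        u = np.clip(u, 0.0, 1.0)
    else:
        x, u = state.stp_x, state.stp_u
    out = softmax2(h @ params.w_out.T)
    return NetworkState(h, u, x, out)


def forward(params: NetworkParams, batch, cfg: DynamicsConfig | None = None,
            rng=None, dtype=np.float64) -> ActivityRecord:
    """Run a batch of trials through the network.

    Deterministic given the rng seed.  Raises on NaN with the step index.
    """
    cfg = cfg or DynamicsConfig()
    inputs = np.asarray(batch.inputs, dtype=dtype)
    n_steps, n_trials, n_in = inputs.shape
    if n_in != params.w_in.shape[1]:
        raise ValueError("batch input dimension does not match network")
    dt = batch.timing.dt
    state = initial_state(params, n_trials, dtype)
    n = params.layout.n_units
    rates = np.empty((n_steps, n_trials, n), dtype=dtype)
    outputs = np.empty((n_steps, n_trials, N_OUT), dtype=dtype)
    for k in range(n_steps):
        state = step(state, inputs[k], params, cfg, dt, rng)
        if not np.all(np.isfinite(state.h)):
            raise FloatingPointError(f"NaN in trajectory at step {k}")
        rates[k] = state.h
        outputs[k] = state.output_prob
    times = (np.arange(n_steps) + 1) * dt
    return ActivityRecord(rates, outputs, times)
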