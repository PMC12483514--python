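"""Backpropagation-through-time training of the decision network.

Gradients are computed by an explicit adjoint (reverse) recursion through
the discretized rate dynamics and the short-term-plasticity state
variables; they are checked against finite differences in the test suite.
Only the hidden-layer parameters (recurrent weights, bias, initial rates)
are optimized, with Adam and a global L2 gradient clip.

The loss has three parts: a cross-entropy performance loss on the softmax
outputs restricted to the scoring window (from 100 ms after motion onset to
the trial end), a metabolic cost on mean squared rates, and a metabolic
cost on mean squared recurrent weights.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from . import task as task_mod
from .behavior import accuracy
from .network import (ActivityRecord, DynamicsConfig, NetworkParams, N_OUT,
                      forward, softmax2)


@dataclass
class TrainConfig:
    lr: float = 0.01
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    grad_clip_l2: float = 0.1
    max_iters: int = 2000
    stop_acc: float = 0.99
    batch_size: int = 256
    train_coherences: tuple = (0.60, 0.90)
    c_perf: float = 1.0
    c_act: float = 1e-3
    c_wt: float = 1e-4
    eval_every: int = 25
    eval_trials: int = 512
    dtype: type = np.float32

    def __post_init__(self):
        if not 0 < self.stop_acc <= 1:
            raise ValueError("stop_acc must lie in (0, 1]")
        if self.grad_clip_l2 <= 0:
            raise ValueError("grad_clip_l2 must be positive")


@dataclass
class TrainHistory:
    iters: list = field(default_factory=list)
    loss_total: list = field(default_factory=list)
    loss_perf: list = field(default_factory=list)
    loss_act: list = field(default_factory=list)
    loss_wt: list = field(default_factory=list)
    grad_norm: list = field(default_factory=list)
    eval_iters: list = field(default_factory=list)
    eval_acc: list = field(default_factory=list)
    stop_reason: str = ""
    wall_time_s: float = 0.0

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "iter": self.iters, "loss": self.loss_total,
            "perf": self.loss_perf, "act": self.loss_act,
            "wt": self.loss_wt, "grad_norm": self.grad_norm})


def _scored_steps(batch):
    """Output-step selector for the scoring window (output step k has time
    (k+1)*dt)."""
    timing = batch.timing
    times = (np.arange(timing.n_steps) + 1) * timing.dt
    return times >= timing.scoring_onset


def loss(record: ActivityRecord, batch, params: NetworkParams,
         cfg: TrainConfig | None = None):
    """Three-part loss; returns (total, perf, act_cost, wt_cost)."""
    cfg = cfg or TrainConfig()
    if record.outputs.shape[1] != batch.n_trials:
        raise ValueError("record does not match batch")
    scored = _scored_steps(batch)
    p = record.outputs[scored]                          # (S, B, 2)
    y = batch.correct_output.astype(int)
    p_correct = np.take_along_axis(p, np.broadcast_to(
        y[None, :, None], (p.shape[0], len(y), 1)), axis=2)[..., 0]
    perf = cfg.c_perf * float(np.mean(-np.log(np.maximum(p_correct, 1e-12))))
    act = cfg.c_act * float(np.mean(record.rates ** 2))
    w_eff = params.effective_recurrent()
    wt = cfg.c_wt * float(np.mean(w_eff ** 2))
    return perf + act + wt, perf, act, wt


def _forward_cached(params, inputs, dt, dyn: DynamicsConfig, rng, dtype):
    """Forward pass storing everything the adjoint recursion needs."""
    n_steps, n_trials, _ = inputs.shape
    n = params.layout.n_units
    a = dyn.alpha(dt)
    w_eff = params.effective_recurrent().astype(dtype)
    w_in = params.w_in.astype(dtype)
    w_out = params.w_out.astype(dtype)
    bias = params.bias.astype(dtype)
    in_proj = inputs.reshape(-1, inputs.shape[2]) @ w_in.T
    in_proj = in_proj.reshape(n_steps, n_trials, n)

    h = np.empty((n_steps + 1, n_trials, n), dtype=dtype)
    u = np.empty_like(h)
    x = np.empty_like(h)
    relu_mask = np.empty((n_steps, n_trials, n), dtype=bool)
    mx = np.empty_like(relu_mask)
    mu = np.empty_like(relu_mask)
    h[0] = np.maximum(params.h0, 0.0).astype(dtype)
    u[0] = params.stp_u.astype(dtype)
    x[0] = 1.0
    dt_s = dt / 1000.0
    ad = (dt / params.stp_tau_d).astype(dtype)
    af = (dt / params.stp_tau_f).astype(dtype)
    ustar = params.stp_u.astype(dtype)
    noise_scale = np.sqrt(2.0 / a) * dyn.sigma_rec
    for k in range(n_steps):
        if params.stp_enabled:
            s = u[k] * x[k] * h[k]
        else:
            s = h[k]
        z = s @ w_eff.T + in_proj[k] + bias
        if rng is not None and dyn.sigma_rec > 0:
            z += noise_scale * rng.normal(0.0, 1.0, size=z.shape).astype(dtype)
        relu_mask[k] = z > 0
        h[k + 1] = (1 - a) * h[k] + a * np.where(relu_mask[k], z, 0.0)
        if params.stp_enabled:
            xn = x[k] + ad * (1 - x[k]) - dt_s * u[k] * x[k] * h[k]
            un = u[k] + af * (ustar - u[k]) + dt_s * ustar * (1 - u[k]) * h[k]
            mx[k] = (xn > 0) & (xn < 1)
            mu[k] = (un > 0) & (un < 1)
            x[k + 1] = np.clip(xn, 0.0, 1.0)
            u[k + 1] = np.clip(un, 0.0, 1.0)
        else:
            x[k + 1] = x[k]
            u[k + 1] = u[k]
    out = softmax2(h[1:] @ w_out.T)
    return dict(h=h, u=u, x=x, relu=relu_mask, mx=mx, mu=mu, out=out,
                w_eff=w_eff, a=a, dt_s=dt_s, ad=ad, af=af, ustar=ustar)


def loss_and_grads(params: NetworkParams, batch, cfg: TrainConfig,
                   dyn: DynamicsConfig, rng):
    """Loss components and gradients wrt (w_rec, bias, h0)."""
    dtype = cfg.dtype
    inputs = np.asarray(batch.inputs, dtype=dtype)
    n_steps, n_trials, _ = inputs.shape
    n = params.layout.n_units
    cache = _forward_cached(params, inputs, batch.timing.dt, dyn, rng, dtype)
    h, u, x = cache["h"], cache["u"], cache["x"]
    out = cache["out"]
    a, dt_s = cache["a"], cache["dt_s"]
    ad, af, ustar = cache["ad"], cache["af"], cache["ustar"]
    w_eff = cache["w_eff"]
    w_out = params.w_out.astype(dtype)

    scored = _scored_steps(batch)
    n_scored = int(scored.sum())
    y = batch.correct_output.astype(int)
    y_onehot = np.zeros((n_trials, N_OUT), dtype=dtype)
    y_onehot[np.arange(n_trials), y] = 1.0

    p_correct = out[scored][:, np.arange(n_trials), y]
    perf = cfg.c_perf * float(np.mean(-np.log(np.maximum(p_correct, 1e-12))))
    act = cfg.c_act * float(np.mean(h[1:] ** 2))
    w_masked = params.w_rec * params.masks.recurrent
    wt = cfg.c_wt * float(np.mean(w_masked ** 2))
    total = perf + act + wt

    # adjoint recursion
    gW = np.zeros((n, n), dtype=dtype)
    gb = np.zeros(n, dtype=dtype)
    gh = np.zeros((n_trials, n), dtype=dtype)
    gu = np.zeros_like(gh)
    gx = np.zeros_like(gh)
    act_coef = 2.0 * cfg.c_act / h[1:].size
    perf_coef = cfg.c_perf / (n_scored * n_trials)
    stp = params.stp_enabled
    for k in range(n_steps - 1, -1, -1):
        gh1 = gh + act_coef * h[k + 1]
        if scored[k]:
            gh1 = gh1 + perf_coef * ((out[k] - y_onehot) @ w_out)
        gz = (a * gh1) * cache["relu"][k]
        if stp:
            s = u[k] * x[k] * h[k]
        else:
            s = h[k]
        gW += gz.T @ s
        gb += gz.sum(axis=0)
        gs = gz @ w_eff
        if stp:
            cx = gx * cache["mx"][k]
            cu = gu * cache["mu"][k]
            uxh = u[k] * x[k]
            gh = ((1 - a) * gh1 + gs * uxh
                  - cx * (dt_s * uxh)
                  + cu * (dt_s * ustar * (1 - u[k])))
            gx_new = gs * (u[k] * h[k]) + cx * (1 - ad - dt_s * u[k] * h[k])
            gu_new = (gs * (x[k] * h[k]) - cx * (dt_s * x[k] * h[k])
                      + cu * (1 - af - dt_s * ustar * h[k]))
            gx, gu = gx_new, gu_new
        else:
            gh = (1 - a) * gh1 + gs
    gh0 = gh.sum(axis=0) * (params.h0 > 0)

    dale = params.layout.dale_sign[None, :]
    sgn = np.where(params.w_rec >= 0, 1.0, -1.0)
    g_wrec = (gW * params.masks.recurrent * dale * sgn
              + (2.0 * cfg.c_wt / params.w_rec.size) * w_masked)
    grads = {"w_rec": g_wrec.astype(np.float64),
             "bias": gb.astype(np.float64),
             "h0": gh0.astype(np.float64)}
    return (total, perf, act, wt), grads


def clip_gradients(grads, max_l2):
    """Scale gradients so their joint L2 norm is at most max_l2."""
    norm = np.sqrt(sum(float((g ** 2).sum()) for g in grads.values()))
    if norm > max_l2:
        scale = max_l2 / norm
        grads = {k: g * scale for k, g in grads.items()}
    return grads, norm


class Adam:
    def __init__(self, shapes, lr, b1, b2, eps):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}
        self.t = 0

    def step(self, grads):
        self.t += 1
        updates = {}
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            updates[k] = -self.lr * mhat / (np.sqrt(vhat) + self.eps)
        return updates


def evaluate_accuracy(params, cfg: TrainConfig, dyn, timing, motion_cfg,
                      target_cfg, rng, n_trials=None):
    batch = task_mod.generate_batch(
        n_trials or cfg.eval_trials, cfg.train_coherences, timing, rng,
        motion_cfg, target_cfg)
    rec = forward(params, batch, dyn, rng, dtype=cfg.dtype)
    return accuracy(rec, batch)


def train(params: NetworkParams, cfg: TrainConfig | None = None,
          dyn: DynamicsConfig | None = None, timing=None, motion_cfg=None,
          target_cfg=None, seed=None, verbose=False):
    """Train hidden-layer parameters with BPTT + Adam.

    Returns (trained_params, TrainHistory).  Input/output weights, masks
    and Dale signs are untouched.  Stops when held-out accuracy on the
    training coherences reaches ``stop_acc`` or at ``max_iters``.
    """
    cfg = cfg or TrainConfig()
    dyn = dyn or DynamicsConfig()
    timing = timing or task_mod.TaskTiming()
    rng = np.random.default_rng(seed)
    params = params.copy()
    hist = TrainHistory()
    opt = Adam({"w_rec": params.w_rec.shape, "bias": params.bias.shape,
                "h0": params.h0.shape},
               cfg.lr, cfg.adam_beta1, cfg.adam_beta2, cfg.adam_eps)
    t0 = time.time()
    stop = "max_iters"
    for it in range(cfg.max_iters):
        batch = task_mod.generate_batch(cfg.batch_size, cfg.train_coherences,
                                        timing, rng, motion_cfg, target_cfg)
        (total, perf, act, wt), grads = loss_and_grads(
            params, batch, cfg, dyn, rng)
        if not np.isfinite(total):
            hist.stop_reason = "diverged"
            raise FloatingPointError(
                f"training loss diverged at iteration {it}")
        grads, gnorm = clip_gradients(grads, cfg.grad_clip_l2)
        upd = opt.step(grads)
        params.w_rec += upd["w_rec"] * params.masks.recurrent
        params.bias += upd["bias"]
        params.h0 += upd["h0"]
        hist.iters.append(it)
        hist.loss_total.append(total)
        hist.loss_perf.append(perf)
        hist.loss_act.append(act)
        hist.loss_wt.append(wt)
        hist.grad_norm.append(min(gnorm, cfg.grad_clip_l2))
        if (it + 1) % cfg.eval_every == 0 or it == cfg.max_iters - 1:
            acc = evaluate_accuracy(params, cfg, dyn, timing, motion_cfg,
                                    target_cfg, rng)
            hist.eval_iters.append(it)
            hist.eval_acc.append(acc)
            if verbose:
                print(f"iter {it + 1}: loss {total:.4f} acc {acc:.3f}")
            if acc >= cfg.stop_acc:
                stop = "accuracy"
                break
    hist.stop_reason = stop
    hist.wall_time_s = time.time() - t0
    return params, hist
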