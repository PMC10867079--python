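"""First-passage simulation of the combined evidence process.

A single Wiener process with time-varying drift v(t) runs between two
absorbing boundaries at 0 and ``a``, starting unbiased at a/2; the upper
boundary encodes the correct response.  Integration is Euler–Maruyama
with Gaussian increments:

    X <- X + v(t) dt + sigma * sqrt(dt) * N(0, 1).

Trials are simulated in a vectorized sweep: the drift at each step is
shared by all still-active trials, so one normal draw per active trial
per step is the only per-trial work.  Each trial adds a non-decision
sample drawn uniformly from [Ter - st/2, Ter + st/2] (ms).

This module doubles as the synthetic-data generator: its defaults
(dt = 0.5 ms, midpoint start, 5 s censoring horizon) define the study
conditions for every simulation experiment and test in the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model_core import Congruency, DMCParameters, RDMCParameters, dmc_drift

__all__ = [
    "TrialTable",
    "CensoredTrialsWarning",
    "simulate_decision",
    "simulate_condition",
    "simulate_dataset",
    "simulate_dmc_dataset",
    "deterministic_crossing_time",
]

#: Default Euler step (s).  The fastest fitted attention dynamic
#: (k ~ 93/s) has a time constant of ~11 ms, so 0.5 ms resolves it.
DT_DEFAULT = 0.0005

#: Censoring horizon (s); non-terminating walks are cut off here and
#: flagged, never silently dropped.
MAX_TIME_DEFAULT = 5.0

CONDITIONS = (Congruency.CONGRUENT, Congruency.INCONGRUENT)


class CensoredTrialsWarning(UserWarning):
    """Some simulated walks hit the censoring horizon before a boundary."""


@dataclass
class TrialTable:
    """Trial-level choice/RT records with their generating metadata.

    ``data`` columns: subject, task, congruency ('congruent' /
    'incongruent'), rt_ms, accuracy (0/1), decision_ms, censored (bool).
    ``meta`` records generating parameters, seed, step size and n per
    condition so any table is reproducible from its metadata.
    """

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.data)

    def condition(self, cond: "Congruency | str") -> pd.DataFrame:
        cond = Congruency.from_label(cond)
        return self.data[self.data["congruency"] == cond.value]

    @property
    def n_censored(self) -> int:
        return int(self.data["censored"].sum())


def _drift_profile(params: RDMCParameters, cond: Congruency,
                   dt: float, n_steps: int) -> np.ndarray:
    """Drift evaluated at the start of each Euler step (evidence/s)."""
    t = np.arange(n_steps) * dt
    s_da = cond.drift_sign * params.d_a
    w_a = params.A0 * np.exp(-params.k(cond) * t)
    return w_a * s_da + (1.0 - w_a) * params.d_c


def _first_passage(drift_per_step: np.ndarray, a: float, sigma: float,
                   dt: float, n: int, rng: np.random.Generator):
    """Vectorized Euler–Maruyama walk for ``n`` trials.

    Returns (hit_upper bool array, decision_time s array, censored bool
    array).  Censored trials carry the horizon as their decision time.
    """
    n_steps = drift_per_step.shape[0]
    sq = sigma * np.sqrt(dt)
    # continuity correction for discretely monitored barriers: shifting
    # each boundary inward by 0.5826*sigma*sqrt(dt) cancels the leading
    # O(sqrt(dt)) first-passage bias of the Euler scheme
    shift = min(0.5826 * sq, 0.25 * a)
    hi = a - shift
    lo = shift
    x = np.full(n, a / 2.0)
    hit_upper = np.zeros(n, dtype=bool)
    dtime = np.full(n, n_steps * dt)
    censored = np.ones(n, dtype=bool)
    idx = np.arange(n)
    for j in range(n_steps):
        if idx.size == 0:
            break
        x_act = x[idx] + drift_per_step[j] * dt + sq * rng.standard_normal(idx.size)
        up = x_act >= hi
        done = up | (x_act <= lo)
        if done.any():
            fin = idx[done]
            hit_upper[fin] = up[done]
            dtime[fin] = (j + 1) * dt
            censored[fin] = False
            idx = idx[~done]
            x[idx] = x_act[~done]
        else:
            x[idx] = x_act
    return hit_upper, dtime, censored


def simulate_decision(params: RDMCParameters, cond: "Congruency | str",
                      dt: float = DT_DEFAULT,
                      rng: "np.random.Generator | int | None" = None,
                      max_time: float = MAX_TIME_DEFAULT,
                      sigma: "float | None" = None):
    """Simulate a single decision; returns (boundary, decision_time_s).

    ``boundary`` is the string 'upper' (correct) or 'lower' (error), or
    'censored' if the walk outlives ``max_time``.  ``sigma`` overrides
    the diffusion scale (e.g. 0 for the noise-free limit used to check
    the integrator against the deterministic crossing time).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    cond = Congruency.from_label(cond)
    rng = np.random.default_rng(rng)
    sig = params.sigma if sigma is None else sigma
    n_steps = int(round(max_time / dt))
    drift = _drift_profile(params, cond, dt, n_steps)
    if sig == 0.0:
        # deterministic walk: cumulative displacement crossing
        path = params.a / 2.0 + np.cumsum(drift * dt)
        crossed = np.nonzero((path >= params.a) | (path <= 0.0))[0]
        if crossed.size == 0:
            return "censored", n_steps * dt
        j = int(crossed[0])
        return ("upper" if path[j] >= params.a else "lower"), (j + 1) * dt
    hit_upper, dtime, censored = _first_passage(drift, params.a, sig, dt, 1, rng)
    if censored[0]:
        return "censored", float(dtime[0])
    return ("upper" if hit_upper[0] else "lower"), float(dtime[0])


def simulate_condition(params: RDMCParameters, cond: "Congruency | str",
                       n: int, dt: float = DT_DEFAULT,
                       rng: "np.random.Generator | int | None" = None,
                       max_time: float = MAX_TIME_DEFAULT) -> pd.DataFrame:
    """Simulate ``n`` trials of one congruency condition.

    Returns a DataFrame with columns congruency, accuracy, decision_ms,
    rt_ms, censored.  Correct responses are upper-boundary absorptions.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    cond = Congruency.from_label(cond)
    rng = np.random.default_rng(rng)
    n_steps = int(round(max_time / dt))
    drift = _drift_profile(params, cond, dt, n_steps)
    hit_upper, dtime, censored = _first_passage(
        drift, params.a, params.sigma, dt, n, rng)
    ndt = rng.uniform(params.Ter - params.st / 2.0,
                      params.Ter + params.st / 2.0, size=n)
    if params.st == 0.0:
        ndt = np.full(n, params.Ter)
    decision_ms = dtime * 1000.0
    return pd.DataFrame({
        "congruency": cond.value,
        "accuracy": hit_upper.astype(int),
        "decision_ms": decision_ms,
        "rt_ms": decision_ms + ndt,
        "censored": censored,
    })


def simulate_dataset(params: RDMCParameters, n_per_condition: int,
                     dt: float = DT_DEFAULT, seed: "int | None" = None,
                     max_time: float = MAX_TIME_DEFAULT,
                     subject: str = "sim", task: str = "rdmc") -> TrialTable:
    """Simulate a two-condition dataset; fully reproducible from ``seed``."""
    rng = np.random.default_rng(seed)
    frames = []
    for cond in CONDITIONS:
        df = simulate_condition(params, cond, n_per_condition, dt, rng, max_time)
        frames.append(df)
    data = pd.concat(frames, ignore_index=True)
    data.insert(0, "task", task)
    data.insert(0, "subject", subject)
    n_cens = int(data["censored"].sum())
    if n_cens:
        warnings.warn(
            f"{n_cens} of {len(data)} trials censored at {max_time} s",
            CensoredTrialsWarning, stacklevel=2)
    meta = {"params": params.to_dict(), "n_per_condition": n_per_condition,
            "dt": dt, "seed": seed, "max_time": max_time,
            "n_censored": n_cens, "model": "rdmc"}
    return TrialTable(data, meta)


def simulate_dmc_dataset(params: DMCParameters, n_per_condition: int,
                         dt_ms: float = 0.5, seed: "int | None" = None,
                         max_time_ms: float = 2000.0,
                         subject: str = "sim", task: str = "dmc") -> TrialTable:
    """Simulate the reference pulse-function model (millisecond time base)."""
    rng = np.random.default_rng(seed)
    n_steps = int(round(max_time_ms / dt_ms))
    # drift at step starts; t=0 uses the right-limit convention
    t = np.arange(n_steps) * dt_ms
    frames = []
    for cond in CONDITIONS:
        drift = np.asarray(dmc_drift(t, params, cond))
        hit_upper, dtime, censored = _first_passage(
            drift, params.a, params.sigma, dt_ms, n_per_condition, rng)
        ndt = rng.uniform(params.Ter - params.st / 2.0,
                          params.Ter + params.st / 2.0, size=n_per_condition)
        if params.st == 0.0:
            ndt = np.full(n_per_condition, params.Ter)
        frames.append(pd.DataFrame({
            "congruency": cond.value,
            "accuracy": hit_upper.astype(int),
            "decision_ms": dtime,
            "rt_ms": dtime + ndt,
            "censored": censored,
        }))
    data = pd.concat(frames, ignore_index=True)
    data.insert(0, "task", task)
    data.insert(0, "subject", subject)
    n_cens = int(data["censored"].sum())
    if n_cens:
        warnings.warn(
            f"{n_cens} of {len(data)} DMC trials censored at {max_time_ms} ms",
            CensoredTrialsWarning, stacklevel=2)
    meta = {"params": params.to_dict(), "n_per_condition": n_per_condition,
            "dt_ms": dt_ms, "seed": seed, "max_time_ms": max_time_ms,
            "n_censored": n_cens, "model": "dmc"}
    return TrialTable(data, meta)


def net_displacement(params: RDMCParameters, cond: Congruency, t):
    """Closed-form integral of the drift, ∫0..t v(s) ds (evidence units)."""
    t = np.asarray(t, dtype=float)
    k = params.k(cond)
    s_da = cond.drift_sign * params.d_a
    if k == 0.0:
        extra = (s_da - params.d_c) * params.A0 * t
    else:
        extra = (s_da - params.d_c) * params.A0 * (1.0 - np.exp(-k * t)) / k
    out = params.d_c * t + extra
    return float(out) if out.ndim == 0 else out


def deterministic_crossing_time(params: RDMCParameters,
                                cond: "Congruency | str",
                                t_max: float = 60.0) -> float:
    """First time the noise-free drift path reaches either boundary (s).

    Finds the first root of |net displacement| = a/2 by bracketed root
    finding on a fine grid.  A testing oracle for the integrator, not
    part of the stochastic model.
    """
    cond = Congruency.from_label(cond)
    h = params.a / 2.0
    grid = np.linspace(0.0, t_max, 200_001)
    s = net_displacement(params, cond, grid)
    crossed = np.nonzero((s >= h) | (s <= -h))[0]
    if crossed.size == 0:
        raise ValueError(
            "noise-free path reaches neither boundary within "
            f"{t_max} s; drift asymptote too small for a={params.a}")
    j = int(crossed[0])
    target = h if s[j] >= h else -h
    f = lambda t: net_displacement(params, cond, t) - target
    return brentq(f, grid[j - 1], grid[j], xtol=1e-12) if j > 0 else 0.0
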