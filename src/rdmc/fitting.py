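"""Quantile chi-square fitting by multistart Nelder–Mead simplex.

Observed data for each congruency condition are reduced to six correct
RT bins, delimited by the .1/.3/.5/.7/.9 quantiles of the correct RTs,
plus one bin holding all error responses (errors are rare in conflict
tasks, typically < 10%).  Model predictions have no closed form, so the
expected proportion P_i of each bin is estimated by simulating the
model; the expected frequency is E_i = P_i * N with N the condition
trial count, and the objective is

    chi2 = sum over conditions, sum over the 7 bins of (O_i - E_i)^2 / E_i.

Both conditions are fitted jointly, sharing all eight parameters.  The
simulation seed is fixed per fit (common random numbers), making the
objective a deterministic function of the parameters so the simplex
search is well behaved.  Expected counts are floored at one observation
to keep the statistic finite when the model predicts (near-)zero errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .model_core import Congruency, RDMCParameters
from .simulator import TrialTable, simulate_condition
from .summaries import PROBS_DEFAULT, rt_quantiles

__all__ = [
    "ObservedBins",
    "FitConfig",
    "FitResult",
    "bin_observed",
    "bin_observed_from_summary",
    "predicted_proportions",
    "chi_square",
    "fit",
    "PARAM_ORDER",
    "DEFAULT_BOUNDS",
]

log = logging.getLogger(__name__)

PARAM_ORDER = ("A0", "k_c", "k_i", "d_a", "d_c", "a", "Ter", "st")

#: Default box bounds for the free parameters, wide enough to contain
#: the plausible ranges used in the recovery study with head-room.
DEFAULT_BOUNDS = {
    "A0": (0.0, 1.0),
    "k_c": (0.0, 150.0),
    "k_i": (0.0, 150.0),
    "d_a": (0.05, 1.5),
    "d_c": (0.05, 1.5),
    "a": (0.03, 0.3),
    "Ter": (150.0, 600.0),
    "st": (0.0, 250.0),
}

#: Expected-count floor (observation equivalents).
E_FLOOR = 1.0


@dataclass(frozen=True)
class ObservedBins:
    """Quantile bin edges and counts for one condition.

    ``correct_counts`` holds the observed frequencies O in the six
    half-open intervals (-inf, q1], (q1, q2], ..., (q5, inf) over
    correct trials; ``error_count`` holds all error trials.
    """

    edges: tuple              # 5 RT values (ms), non-decreasing
    correct_counts: tuple     # 6 observed frequencies
    error_count: int
    n: int                    # total trials in the condition

    def __post_init__(self):
        if len(self.edges) + 1 != len(self.correct_counts):
            raise ValueError("need one more correct bin than edges")
        if np.any(np.diff(self.edges) < 0):
            raise ValueError("edges must be non-decreasing")
        if sum(self.correct_counts) + self.error_count != self.n:
            raise ValueError("bin counts must sum to the trial count")

    @property
    def counts(self) -> np.ndarray:
        """All 7 observed frequencies: six correct bins then errors."""
        return np.array(list(self.correct_counts) + [self.error_count], float)


@dataclass
class FitConfig:
    """Settings of the chi-square fit.

    n_sim simulated trials per condition per objective evaluation
    approximate the model's predicted bin proportions; 10 restarts of
    the simplex, each from a start perturbed within +/-10% per
    parameter, guard against local minima.
    """

    n_sim: int = 8000
    dt: float = 0.001
    restarts: int = 10
    perturbation: float = 0.10
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    seed: int = 0
    max_evals: int = 1500
    xatol: float = 1e-4
    fatol: float = 1e-4
    probs: tuple = PROBS_DEFAULT

    def __post_init__(self):
        if self.n_sim < 1000:
            raise ValueError("n_sim must be >= 1000 for fitting")


@dataclass
class FitResult:
    """Best-fit parameters, objective value, and per-restart trace."""

    params: RDMCParameters
    chi2: float
    restarts: pd.DataFrame    # columns: start_*, end_*, chi2, n_evals, ok
    seed: int
    config: FitConfig

    def to_dict(self) -> dict:
        return {**self.params.to_dict(), "chi2": self.chi2,
                "n_sim": self.config.n_sim, "dt": self.config.dt,
                "seed": self.seed, "restarts": int(len(self.restarts))}


def bin_observed(cond_trials: pd.DataFrame,
                 probs=PROBS_DEFAULT) -> ObservedBins:
    """Reduce one condition's trials to quantile bins and counts."""
    correct = cond_trials.loc[cond_trials["accuracy"] == 1, "rt_ms"].to_numpy()
    if correct.size < 10:
        raise ValueError(
            f"need at least 10 correct trials per condition, got {correct.size}")
    edges = rt_quantiles(correct, probs)
    counts = _interval_counts(correct, edges)
    n_err = int((cond_trials["accuracy"] == 0).sum())
    return ObservedBins(edges=tuple(edges.tolist()),
                        correct_counts=tuple(int(c) for c in counts),
                        error_count=n_err, n=len(cond_trials))


def bin_observed_from_summary(quantiles, n: int, accuracy: float,
                              probs=PROBS_DEFAULT) -> ObservedBins:
    """ObservedBins from group-averaged quantiles and an accuracy rate.

    Used when only quantile-averaged summaries exist (no raw trials):
    correct mass is split across the six bins in the canonical
    .1/.2/.2/.2/.2/.1 proportions implied by the quantile construction.
    """
    shares = np.array([probs[0]] + list(np.diff(probs)) + [1 - probs[-1]])
    n_corr = accuracy * n
    counts = np.rint(shares * n_corr).astype(int)
    n_err = int(round(n - counts.sum()))
    return ObservedBins(edges=tuple(np.asarray(quantiles, float).tolist()),
                        correct_counts=tuple(int(c) for c in counts),
                        error_count=n_err, n=int(counts.sum()) + n_err)


def _interval_counts(rts: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Counts in (-inf, e1], (e1, e2], ..., (e_last, inf)."""
    idx = np.searchsorted(edges, rts, side="left")
    return np.bincount(idx, minlength=len(edges) + 1)


def predicted_proportions(params: RDMCParameters, edges, cond,
                          n_sim: int, seed: int,
                          dt: float = 0.001) -> np.ndarray:
    """Model-predicted proportions of the 7 bins for one condition.

    Simulates ``n_sim`` trials and returns the fractions of simulated
    trials that are correct and fall in each of the six RT intervals,
    followed by the simulated error fraction.  Censored trials reduce
    the total mass; a warning is logged if they exceed 0.1%.
    """
    cond = Congruency.from_label(cond)
    # per-condition seed offset keeps the two conditions' noise independent
    rng = np.random.default_rng(seed + (0 if cond is Congruency.CONGRUENT else 1))
    df = simulate_condition(params, cond, n_sim, dt, rng)
    live = df[~df["censored"]]
    n_cens = len(df) - len(live)
    if n_cens > 0.001 * n_sim:
        log.warning("%.2f%% of simulated trials censored at params %s",
                    100.0 * n_cens / n_sim, params)
    corr = live.loc[live["accuracy"] == 1, "rt_ms"].to_numpy()
    p = _interval_counts(corr, np.asarray(edges, float)) / n_sim
    p_err = (live["accuracy"] == 0).sum() / n_sim
    return np.append(p, p_err)


def chi_square(observed, proportions) -> float:
    """Pearson chi-square over all conditions and bins.

    ``observed`` maps condition label -> ObservedBins; ``proportions``
    maps condition label -> 7 predicted proportions.  Expected counts
    E = P * N are floored at one observation.
    """
    total = 0.0
    for label, obs in observed.items():
        p = np.asarray(proportions[label], float)
        if np.all(p == 0.0):
            raise ValueError(f"all-zero expected proportions for {label!r}")
        e = p * obs.n
        o = obs.counts
        # floor only the denominator: a bin with O = E = 0 contributes 0,
        # and near-zero expected counts cannot blow up the statistic
        total += float(np.sum((o - e) ** 2 / np.maximum(e, E_FLOOR)))
    return total


def _objective(theta: np.ndarray, observed: dict, config: FitConfig) -> float:
    kw = dict(zip(PARAM_ORDER, theta))
    # clamp the simplex's exploratory points into the valid region
    kw["A0"] = min(max(kw["A0"], 0.0), 1.0)
    for key in ("k_c", "k_i", "st"):
        kw[key] = max(kw[key], 0.0)
    for key in ("d_a", "d_c", "a"):
        kw[key] = max(kw[key], 1e-4)
    kw["Ter"] = max(kw["Ter"], kw["st"] / 2.0)
    params = RDMCParameters(**kw)
    props = {
        label: predicted_proportions(
            params, observed[label].edges, label,
            config.n_sim, config.seed, config.dt)
        for label in observed
    }
    return chi_square(observed, props)


def fit(data: "TrialTable | dict", config: FitConfig,
        start: RDMCParameters) -> FitResult:
    """Joint chi-square fit over both congruency conditions.

    ``data`` is either a TrialTable (binned here) or a prebuilt mapping
    of condition label -> ObservedBins.  The simplex is restarted from
    ``config.restarts`` points, each drawn within +/- ``perturbation``
    of ``start`` per parameter; the best restart wins.  The objective
    uses one fixed simulation seed throughout the fit, so it is a
    deterministic function of the parameters.
    """
    if isinstance(data, TrialTable):
        if len(data) == 0:
            raise ValueError("empty trial table")
        observed = {c: bin_observed(data.condition(c), config.probs)
                    for c in ("congruent", "incongruent")}
    else:
        observed = dict(data)
        if not observed:
            raise ValueError("no observed bins supplied")

    rng = np.random.default_rng(config.seed)
    x0 = np.array([getattr(start, k) for k in PARAM_ORDER], float)
    lb = np.array([config.bounds[k][0] for k in PARAM_ORDER])
    ub = np.array([config.bounds[k][1] for k in PARAM_ORDER])
    if np.any(x0 < lb) or np.any(x0 > ub):
        raise ValueError("start point outside the parameter bounds")

    rows = []
    best = None
    for r in range(config.restarts):
        jitter = rng.uniform(1.0 - config.perturbation,
                             1.0 + config.perturbation, size=x0.size)
        s = np.clip(x0 * jitter, lb, ub)
        try:
            res = optimize.minimize(
                _objective, s, args=(observed, config),
                method="Nelder-Mead",
                bounds=optimize.Bounds(lb, ub),
                options={"maxfev": config.max_evals,
                         "xatol": config.xatol, "fatol": config.fatol})
            ok = True
        except Exception as exc:        # noqa: BLE001 - logged, not fatal
            log.warning("restart %d failed: %s", r, exc)
            rows.append({"restart": r, "chi2": np.inf, "n_evals": 0,
                         "ok": False,
                         **{f"start_{k}": v for k, v in zip(PARAM_ORDER, s)}})
            continue
        row = {"restart": r, "chi2": float(res.fun),
               "n_evals": int(res.nfev), "ok": ok}
        row.update({f"start_{k}": v for k, v in zip(PARAM_ORDER, s)})
        row.update({f"end_{k}": v for k, v in zip(PARAM_ORDER, res.x)})
        rows.append(row)
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError("all simplex restarts failed")
    kw = dict(zip(PARAM_ORDER, np.clip(best.x, lb, ub)))
    kw["Ter"] = max(kw["Ter"], kw["st"] / 2.0)
    return FitResult(params=RDMCParameters(**kw), chi2=float(best.fun),
                     restarts=pd.DataFrame(rows), seed=config.seed,
                     config=config)
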