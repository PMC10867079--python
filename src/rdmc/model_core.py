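"""Parameter containers and the deterministic mathematical core.

The revised diffusion model for conflict tasks (RDMC) drives a single
Wiener process with a time-varying drift rate built from two evidence
channels: an *automatic* channel carrying task-irrelevant (distractor)
information and a *controlled* channel carrying task-relevant (target)
information.  Attention is reallocated between the channels over the
course of a trial by complementary weights

    w_a(t) = A0 * exp(-k * t),      w_c(t) = 1 - w_a(t),

so the combined drift is

    v(t) = w_a(t) * (s * d_a) + w_c(t) * d_c,

where ``s`` is +1 on congruent and -1 on incongruent trials.  Because
the weights are non-negative, the automatic contribution never changes
sign within a trial — the property that distinguishes RDMC from the
original pulse-function model (DMC), in which the expected automatic
evidence rises and is later withdrawn.

The original DMC pulse function and its drift are provided as a
reference model for comparison simulations.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

__all__ = [
    "Congruency",
    "RDMCParameters",
    "DMCParameters",
    "automatic_weight",
    "controlled_weight",
    "rdmc_drift",
    "dmc_pulse_expectation",
    "dmc_automatic_drift",
    "dmc_drift",
]

#: Fixed square root of the diffusion coefficient (evidence / sqrt(s)).
#: A scaling constant of the model, not a free parameter.
SIGMA_DEFAULT = 0.1


class Congruency(enum.Enum):
    """Trial congruency condition.

    The sign applied to the automatic base drift ``d_a`` is +1 on
    congruent trials (distractor supports the correct response) and -1
    on incongruent trials (distractor supports the error response).
    """

    CONGRUENT = "congruent"
    INCONGRUENT = "incongruent"

    @property
    def drift_sign(self) -> int:
        return 1 if self is Congruency.CONGRUENT else -1

    @classmethod
    def from_label(cls, label: "str | Congruency") -> "Congruency":
        if isinstance(label, Congruency):
            return label
        try:
            return cls(str(label).strip().lower())
        except ValueError:
            raise ValueError(
                f"unknown congruency label {label!r}; "
                f"expected 'congruent' or 'incongruent'"
            ) from None


@dataclass(frozen=True)
class RDMCParameters:
    """The eight free parameters of RDMC plus the fixed diffusion scale.

    Attributes
    ----------
    A0 : float
        Initial activation weight of the automatic channel, in [0, 1].
    k_c, k_i : float
        Attention shift rates (1/s) on congruent / incongruent trials.
    d_a : float
        Automatic base drift magnitude (evidence/s).  Stored positive;
        the congruency sign is applied at drift evaluation.
    d_c : float
        Controlled base drift (evidence/s), always positive.
    a : float
        Boundary separation (evidence units); the process starts at a/2.
    Ter : float
        Mean non-decision time (ms).
    st : float
        Range of the uniform non-decision time distribution (ms).
    sigma : float
        Square root of the diffusion coefficient (evidence/sqrt(s));
        fixed scaling constant 0.1 unless explicitly overridden.
    """

    A0: float
    k_c: float
    k_i: float
    d_a: float
    d_c: float
    a: float
    Ter: float
    st: float = 0.0
    sigma: float = SIGMA_DEFAULT

    def __post_init__(self) -> None:
        if not 0.0 <= self.A0 <= 1.0:
            raise ValueError(f"A0 must lie in [0, 1], got {self.A0}")
        if self.k_c < 0 or self.k_i < 0:
            raise ValueError("attention shift rates k_c, k_i must be >= 0")
        if self.d_a <= 0 or self.d_c <= 0:
            raise ValueError("base drifts d_a, d_c must be > 0 "
                             "(d_a is a magnitude; sign comes from congruency)")
        if self.a <= 0:
            raise ValueError("boundary separation a must be > 0")
        if self.st < 0:
            raise ValueError("non-decision range st must be >= 0")
        if self.Ter < self.st / 2:
            raise ValueError("Ter must be >= st/2 so non-decision time "
                             "is never negative")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")

    def k(self, cond: Congruency) -> float:
        """Attention shift rate for the given condition."""
        return self.k_c if cond is Congruency.CONGRUENT else self.k_i

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RDMCParameters":
        known = {f for f in cls.__dataclass_fields__}
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown parameter keys: {sorted(extra)}")
        return cls(**d)

    def to_json(self, path: "str | Path") -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: "str | Path") -> "RDMCParameters":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def replace(self, **kw) -> "RDMCParameters":
        return replace(self, **kw)


@dataclass(frozen=True)
class DMCParameters:
    """Parameters of the original pulse-function diffusion model (DMC).

    This reference model runs on a millisecond time base (a=100, sigma=3
    conventions).  The expected automatic evidence is a rescaled gamma
    density: A * exp(-t/tau) * (t*e / ((alpha-1)*tau))**(alpha-1).
    """

    A: float          # pulse amplitude (evidence units)
    tau: float        # pulse scale (ms)
    alpha: float      # gamma shape, > 1
    v_c: float        # controlled drift (evidence/ms)
    a: float          # boundary separation
    sigma: float      # diffusion scale (evidence/sqrt(ms))
    Ter: float        # mean non-decision time (ms)
    st: float = 0.0   # non-decision range (ms)

    def __post_init__(self) -> None:
        if self.alpha <= 1:
            raise ValueError(f"gamma shape alpha must be > 1, got {self.alpha}")
        if self.tau <= 0:
            raise ValueError("pulse scale tau must be > 0")
        if self.a <= 0:
            raise ValueError("boundary separation a must be > 0")
        if self.st < 0 or self.Ter < self.st / 2:
            raise ValueError("need st >= 0 and Ter >= st/2")

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------
# RDMC attention weights and drift


def _check_time(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time t must be >= 0")
    return t


def automatic_weight(t, A0: float, k: float):
    """Automatic channel activation weight ``A0 * exp(-k t)``.

    Parameters are unitless (A0), 1/s (k), seconds (t).  Monotone
    non-increasing in t, with range [0, A0].
    """
    t = _check_time(t)
    if not 0.0 <= A0 <= 1.0:
        raise ValueError("A0 must lie in [0, 1]")
    if k < 0:
        raise ValueError("k must be >= 0")
    out = A0 * np.exp(-k * t)
    return float(out) if out.ndim == 0 else out


def controlled_weight(t, A0: float, k: float):
    """Controlled channel weight ``1 - automatic_weight(t)``.

    The two weights sum to exactly 1 for every t.
    """
    w = automatic_weight(t, A0, k)
    return 1.0 - w


def rdmc_drift(t, params: RDMCParameters, cond: Congruency):
    """Combined time-varying drift ``w_a(t)*(s*d_a) + w_c(t)*d_c`` (evidence/s).

    ``s`` is the condition drift sign.  Converges to d_c as t grows;
    the automatic contribution keeps a constant sign over the trial.
    """
    cond = Congruency.from_label(cond)
    k = params.k(cond)
    w_a = automatic_weight(t, params.A0, k)
    s_da = cond.drift_sign * params.d_a
    out = np.asarray(w_a) * s_da + (1.0 - np.asarray(w_a)) * params.d_c
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------
# DMC reference: pulse function and its drift (millisecond time base)


def dmc_pulse_expectation(t, p: DMCParameters):
    """Expected automatic evidence of DMC at time t (ms).

    A rescaled gamma density: zero at t=0, a single interior maximum of
    exactly ``A`` at t = (alpha-1)*tau, then decay back toward zero.
    """
    t = _check_time(t)
    scale = (p.alpha - 1.0) * p.tau
    with np.errstate(divide="ignore", invalid="ignore"):
        out = p.A * np.exp(-t / p.tau) * (t * math.e / scale) ** (p.alpha - 1.0)
    out = np.where(t == 0.0, 0.0, out)
    return float(out) if out.ndim == 0 else out


def dmc_automatic_drift(t, p: DMCParameters):
    """Automatic drift of DMC: d/dt of the pulse expectation (evidence/ms).

    Equals ``dmc_pulse_expectation(t) * ((alpha-1)/t - 1/tau)``: positive
    before the pulse peak at t=(alpha-1)*tau, zero at the peak, negative
    after — exactly one sign change.  At t=0 the right limit is used:
    ``A*e/tau`` for alpha == 2 and 0 for alpha > 2 (for alpha < 2 the
    derivative diverges at the origin and t=0 is rejected).
    """
    t = _check_time(t)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    if np.any(t == 0.0) and p.alpha < 2.0:
        raise ValueError("automatic drift diverges at t=0 for alpha < 2")
    out = np.empty_like(t)
    zero = t == 0.0
    # right limit at the origin: E(t) ~ t**(alpha-1), so E(t)*(alpha-1)/t
    # tends to A*e/tau when alpha == 2 and to 0 when alpha > 2
    out[zero] = p.A * math.e / p.tau if p.alpha == 2.0 else 0.0
    tz = t[~zero]
    out[~zero] = dmc_pulse_expectation(tz, p) * ((p.alpha - 1.0) / tz - 1.0 / p.tau)
    return float(out[0]) if scalar else out


def dmc_drift(t, p: DMCParameters, cond: Congruency):
    """Combined DMC drift ``s * v_a(t) + v_c`` (evidence/ms)."""
    cond = Congruency.from_label(cond)
    va = dmc_automatic_drift(t, p)
    out = cond.drift_sign * np.asarray(va) + p.v_c
    return float(out) if out.ndim == 0 else out
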