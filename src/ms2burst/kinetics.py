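"""Closed-form steady-state statistics of the two-state (telegraph) promoter.

The promoter toggles between OFF and ON with rates ``k_on`` (OFF -> ON) and
``k_off`` (ON -> OFF) and, while ON, initiates polymerases at rate ``r``.
Each polymerase resides on the gene for the elongation time ``T``, so the
observable tracked by an MS2/MCP reporter is the number of nascent
transcripts ``m(t)``: a Poisson initiation stream gated by the promoter
state and filtered by a boxcar window of width ``T``.

In steady state,

    <m>     = r * T * k_on / kappa,            kappa = k_on + k_off
    Var(m)  = <m> * Fano
    Fano    = 1 + (2 r k_off / kappa^2) * g(kappa * T)

with ``g(x) = 1 + (exp(-x) - 1)/x``, an increasing map of [0, inf) onto
[0, 1).  The Fano factor is therefore always >= 1 (super-Poissonian), and
the product ``kappa * T`` — switching rate relative to the polymerase
residence time — controls which limit applies:

* ``kappa*T >> 1`` (fast switching): Fano ~= 1 + 2 r k_off / kappa^2.
* ``kappa*T -> 0`` at fixed rates (T -> 0): Fano -> 1, the Poisson limit.
  Note the limit requires the retained first-order term
  ``r * k_off * T / kappa`` to be small, not merely ``kappa*T``.

All rates are in 1/s and times in s.  Unit conversions (minutes, frames)
belong at the I/O boundary, not here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

from scipy.optimize import brentq

__all__ = [
    "KineticParams",
    "ParameterComparison",
    "SensitivitySignature",
    "InvalidParametersError",
    "UndefinedFanoError",
    "InfeasibleTargetError",
    "steady_state_mean",
    "steady_state_variance",
    "fano_factor",
    "mean_partial",
    "fano_partial",
    "classify_regime",
    "sensitivity_signs",
    "solve_matched_mean",
]

# kappa*T brackets for declaring the limit expansions applicable; between the
# two the regime is reported as ambiguous.
SMALL_KAPPA_T = 0.1
LARGE_KAPPA_T = 10.0

VariedParameter = Literal["r", "k_on", "k_off"]


class InvalidParametersError(ValueError):
    """Kinetic parameters violate their invariants (e.g. kappa == 0)."""


class UndefinedFanoError(ValueError):
    """Fano factor requested where the steady-state mean is zero."""


class InfeasibleTargetError(ValueError):
    """No non-negative parameter value reaches the requested mean."""


@dataclass(frozen=True)
class KineticParams:
    """Rates of the two-state promoter plus the elongation time.

    Parameters
    ----------
    r
        Initiation rate while ON (events/s).
    k_on
        OFF -> ON switching rate (1/s).
    k_off
        ON -> OFF switching rate (1/s).
    T
        Residence (elongation) time of one polymerase on the gene (s).
    """

    r: float
    k_on: float
    k_off: float
    T: float

    def __post_init__(self) -> None:
        if self.r < 0 or self.k_on < 0 or self.k_off < 0:
            raise InvalidParametersError("rates must be non-negative")
        if self.T <= 0:
            raise InvalidParametersError("elongation time T must be positive")

    @property
    def kappa(self) -> float:
        """Total switching rate k_on + k_off (1/s)."""
        return self.k_on + self.k_off

    @property
    def occupancy(self) -> float:
        """Stationary probability of the ON state, k_on / kappa."""
        if self.kappa == 0:
            raise InvalidParametersError(
                "occupancy undefined for kappa = k_on + k_off = 0"
            )
        return self.k_on / self.kappa


@dataclass(frozen=True)
class ParameterComparison:
    """Two parameter sets whose steady-state means differ by a factor alpha."""

    params_1: KineticParams
    params_2: KineticParams
    alpha: float
    varied_parameter: VariedParameter

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


@dataclass(frozen=True)
class SensitivitySignature:
    """Sign of the response of mean and Fano to one parameter, per regime."""

    parameter: VariedParameter
    regime: str  # small_kappaT | large_kappaT | ambiguous
    sign_mean: str  # + | - | 0
    sign_fano: str  # + | - | 0 | indeterminate


def _g(x: float) -> float:
    """g(x) = 1 + (exp(-x) - 1)/x, increasing from 0 to 1 on [0, inf)."""
    if x == 0:
        return 0.0
    return 1.0 + math.expm1(-x) / x


def _g_prime(x: float) -> float:
    """Derivative of g: (1 - e^-x - x e^-x) / x^2, with a series for tiny x."""
    if x < 1e-6:
        return 0.5 - x / 3.0 + x * x / 8.0
    return (-math.expm1(-x) - x * math.exp(-x)) / (x * x)


def steady_state_mean(params: KineticParams) -> float:
    """Expected nascent-mRNA count in steady state, r*T*k_on/kappa."""
    if params.kappa == 0:
        raise InvalidParametersError("mean undefined: kappa = 0 (occupancy undefined)")
    return params.r * params.T * params.occupancy


def fano_factor(params: KineticParams) -> float:
    """Variance/mean of the stationary nascent count; always >= 1."""
    if params.kappa == 0:
        raise InvalidParametersError("Fano undefined: kappa = 0")
    if steady_state_mean(params) == 0:
        raise UndefinedFanoError("Fano undefined: steady-state mean is zero")
    k = params.kappa
    return 1.0 + (2.0 * params.r * params.k_off / k**2) * _g(k * params.T)


def steady_state_variance(params: KineticParams) -> float:
    """Stationary variance of the nascent count, <m> * Fano.

    Zero when the mean is zero (the count is degenerate at 0).
    """
    mean = steady_state_mean(params)
    if mean == 0:
        return 0.0
    return mean * fano_factor(params)


def mean_partial(params: KineticParams, parameter: VariedParameter) -> float:
    """Exact partial derivative of the steady-state mean."""
    k = params.kappa
    if k == 0:
        raise InvalidParametersError("kappa = 0")
    if parameter == "r":
        return params.T * params.k_on / k
    if parameter == "k_on":
        return params.r * params.T * params.k_off / k**2
    if parameter == "k_off":
        return -params.r * params.T * params.k_on / k**2
    raise ValueError(f"unknown parameter {parameter!r}")


def fano_partial(params: KineticParams, parameter: VariedParameter) -> float:
    """Exact partial derivative of the Fano factor.

    Writing Fano = 1 + 2 r k_off * phi(kappa) with phi(k) = g(kT)/k^2,
    the switching-rate derivatives share
    dphi/dkappa = (T g'(kT) - 2 g(kT)/k) / k^2.
    """
    k = params.kappa
    if k == 0:
        raise InvalidParametersError("kappa = 0")
    x = k * params.T
    g = _g(x)
    dphi = (params.T * _g_prime(x) - 2.0 * g / k) / k**2
    if parameter == "r":
        return 2.0 * params.k_off * g / k**2
    if parameter == "k_on":
        return 2.0 * params.r * params.k_off * dphi
    if parameter == "k_off":
        return 2.0 * params.r * (g / k**2 + params.k_off * dphi)
    raise ValueError(f"unknown parameter {parameter!r}")


def classify_regime(
    params: KineticParams,
    small: float = SMALL_KAPPA_T,
    large: float = LARGE_KAPPA_T,
) -> str:
    """Classify kappa*T as small_kappaT, large_kappaT or ambiguous."""
    x = params.kappa * params.T
    if x < small:
        return "small_kappaT"
    if x > large:
        return "large_kappaT"
    return "ambiguous"


def sensitivity_signs(params: KineticParams) -> list[SensitivitySignature]:
    """Sign table of mean/Fano responses to each kinetic parameter.

    In the small-kappa*T regime the Fano factor is (to first order)
    insensitive to the switching rates; in the large regime an increase in
    k_on lowers it while the k_off response changes sign at k_off = kappa/2
    (factor 1 - 2*k_off/kappa) and is therefore reported indeterminate.
    For parameters in the ambiguous band the signs fall back to the exact
    derivatives.
    """
    regime = classify_regime(params)
    if regime == "ambiguous":
        out = []
        for p in ("r", "k_on", "k_off"):
            out.append(
                SensitivitySignature(
                    parameter=p,
                    regime=regime,
                    sign_mean=_sign(mean_partial(params, p)),
                    sign_fano=_sign(fano_partial(params, p)),
                )
            )
        return out
    small = regime == "small_kappaT"
    return [
        SensitivitySignature("r", regime, "+", "+"),
        SensitivitySignature("k_on", regime, "+", "0" if small else "-"),
        SensitivitySignature("k_off", regime, "-", "0" if small else "indeterminate"),
    ]


def _sign(value: float, tol: float = 1e-12) -> str:
    if value > tol:
        return "+"
    if value < -tol:
        return "-"
    return "0"


def solve_matched_mean(
    params_1: KineticParams,
    varied_parameter: VariedParameter,
    alpha: float,
    rtol: float = 1e-9,
) -> KineticParams:
    """Find params_2, differing only in one parameter, with <m2> = alpha*<m1>.

    ``r`` and ``k_on`` invert analytically; ``k_off`` is solved by bracketed
    root-finding on the closed-form mean (it is monotone decreasing in
    k_off).  Raises :class:`InfeasibleTargetError` when no non-negative
    solution exists (the ON-state occupancy cannot exceed 1).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    mean_1 = steady_state_mean(params_1)
    if mean_1 == 0:
        raise InfeasibleTargetError("base parameters have zero mean; no alpha scaling")
    if alpha == 1.0:
        return params_1

    if varied_parameter == "r":
        params_2 = replace(params_1, r=alpha * params_1.r)
    elif varied_parameter == "k_on":
        target_occ = alpha * params_1.occupancy
        if target_occ >= 1.0:
            raise InfeasibleTargetError(
                f"required occupancy {target_occ:.4g} >= 1 unreachable by k_on"
            )
        if params_1.k_off == 0:
            # occupancy pinned at 1; only alpha == 1 is reachable
            raise InfeasibleTargetError("k_off = 0: occupancy fixed at 1")
        k_on_2 = target_occ * params_1.k_off / (1.0 - target_occ)
        params_2 = replace(params_1, k_on=k_on_2)
    elif varied_parameter == "k_off":
        target_occ = alpha * params_1.occupancy
        if target_occ > 1.0:
            raise InfeasibleTargetError(
                f"required occupancy {target_occ:.4g} > 1 unreachable by k_off"
            )
        if params_1.k_on == 0:
            raise InfeasibleTargetError("k_on = 0: mean is zero for any k_off")
        if target_occ == 1.0:
            return replace(params_1, k_off=0.0)
        target = alpha * mean_1

        def gap(k_off: float) -> float:
            return steady_state_mean(replace(params_1, k_off=k_off)) - target

        hi = max(params_1.k_off, params_1.k_on, 1e-12)
        while gap(hi) > 0:
            hi *= 2.0
            if hi > 1e12:  # pragma: no cover - occupancy>0 always brackets
                raise InfeasibleTargetError("failed to bracket k_off solution")
        k_off_2 = brentq(gap, 0.0, hi, xtol=1e-300, rtol=1e-15)
        params_2 = replace(params_1, k_off=float(k_off_2))
    else:
        raise ValueError(f"unknown parameter {varied_parameter!r}")

    achieved = steady_state_mean(params_2) / mean_1
    if not math.isclose(achieved, alpha, rel_tol=rtol):
        raise InfeasibleTargetError(
            f"matched-mean solve missed target: achieved alpha {achieved!r}"
        )
    return params_2
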