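"""Closed-form sample-size calculators for net and gross change.

All calculators share the critical factor ``(Z_{1-alpha(/2)} - Z_beta)^2``
and return a :class:`SizeSolution` carrying both the raw real-valued
formula output and the ceiled integer sample size, plus the intermediate
quantities used (variance term, critical factor) for reporting.

Conventions
-----------
* The ceiling is applied once, at the end of each calculator; intermediate
  algebra stays real-valued.
* The minimum returned ``n`` is 1: a degenerate ``n_raw <= 0`` (extreme
  parameters, e.g. rho -> 1 in the gross formula) yields ``n = 1`` with a
  warning flag rather than a meaningless zero-size sample.
* ``deff`` multiplies the simple-random-sampling requirement.
* One-sided tests use Z_{1-alpha} in place of Z_{1-alpha/2}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .specs import (
    GrossChangeSpecMeans,
    GrossChangeSpecProps,
    NetChangeSpecMeans,
    NetChangeSpecProps,
    Sided,
    SpecError,
    TestParams,
    z_quantile,
)

__all__ = [
    "SizeSolution",
    "InfeasibleDesignError",
    "critical_factor",
    "n_gross_means",
    "n_gross_props",
    "n_net_means",
    "n_net_props",
    "n_next_wave_means",
    "n_next_wave_props",
]


class InfeasibleDesignError(SpecError):
    """The requested design cannot be met by any sample size."""


@dataclass(frozen=True)
class SizeSolution:
    """One solved sample size.

    Attributes
    ----------
    n_raw
        The real-valued formula output, before ceiling.
    n
        ``max(1, ceil(n_raw))``.
    components
        Intermediate quantities (critical factor, variance term, ...) for
        reporting; contents vary by calculator.
    warnings
        Human-readable flags (degenerate inputs, clamps applied).
    """

    n_raw: float
    n: int
    components: Mapping[str, float] = field(default_factory=dict)
    warnings: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "n_raw": self.n_raw,
            "n": self.n,
            "components": dict(self.components),
            "warnings": list(self.warnings),
        }


def _finish(n_raw: float, components: dict, warnings: tuple[str, ...] = ()) -> SizeSolution:
    if n_raw <= 0:
        warnings = warnings + (
            "formula value is non-positive under these parameters; "
            "returning the minimum sample size 1",
        )
        n = 1
    else:
        n = max(1, math.ceil(n_raw))
    return SizeSolution(n_raw=n_raw, n=n, components=components, warnings=warnings)


def critical_factor(test: TestParams) -> float:
    """Squared sum of the significance and power quantiles.

    ``(Z_{1-alpha/2} + Z_{power})**2`` for a two-sided test and
    ``(Z_{1-alpha} + Z_{power})**2`` for a one-sided test -- equivalently
    ``(Z_{1-alpha(/2)} - Z_beta)**2`` with Z_beta the beta-quantile, which
    is negative whenever the target power exceeds one half.
    """
    a = test.alpha / 2 if test.sided is Sided.two else test.alpha
    return (z_quantile(1.0 - a) + z_quantile(test.power)) ** 2


def n_gross_means(spec: GrossChangeSpecMeans, deff: float = 1.0) -> SizeSolution:
    """Overlap-panel size ``n_11`` to detect a gross change in means.

    n_11 = deff * (2*sigma_o2 / Delta^2) * (1 - rho) * critical_factor.
    """
    c = critical_factor(spec.test)
    var_term = 2.0 * spec.sigma_o2 * (1.0 - spec.rho)
    n_raw = deff * var_term / spec.delta_gross**2 * c
    return _finish(n_raw, {"critical_factor": c, "variance_term": var_term, "deff": deff})


def n_gross_props(spec: GrossChangeSpecProps, deff: float = 1.0) -> SizeSolution:
    """Overlap-panel size ``n_11`` to detect a gross change in proportions.

    The variance term is the paired-difference variance
    ``p_t(1-p_t) + p_t1(1-p_t1) - 2(p_xy - p_t*p_t1)``.
    """
    c = critical_factor(spec.test)
    var_term = (
        spec.p_t * (1.0 - spec.p_t)
        + spec.p_t1 * (1.0 - spec.p_t1)
        - 2.0 * (spec.p_xy - spec.p_t * spec.p_t1)
    )
    n_raw = deff * var_term / spec.delta_gross**2 * c
    return _finish(n_raw, {"critical_factor": c, "variance_term": var_term, "deff": deff})


def n_net_means(
    spec: NetChangeSpecMeans, gamma: float, deff: float = 1.0
) -> SizeSolution:
    """Wave-t size ``n_t`` to detect a net change in means at overlap ``gamma``.

    n_t = deff * (sigma_x2 + r*sigma_y2 - 2*gamma*r*rho*sigma_x*sigma_y)
          / delta^2 * critical_factor,

    with ``n_{t+1} = ceil(n_t / r)`` reported in the components.
    """
    if not 0.0 <= gamma <= 1.0:
        raise SpecError(f"gamma must lie in [0, 1], got {gamma}")
    c = critical_factor(spec.test)
    sxsy = math.sqrt(spec.sigma_x2 * spec.sigma_y2)
    var_term = spec.sigma_x2 + spec.r * spec.sigma_y2 - 2.0 * gamma * spec.r * spec.rho * sxsy
    if var_term <= 0:
        raise InfeasibleDesignError(
            f"variance term {var_term:.6g} is non-positive "
            f"(gamma*r*rho too large for these variances)"
        )
    n_raw = deff * var_term / spec.delta**2 * c
    sol = _finish(n_raw, {"critical_factor": c, "variance_term": var_term, "deff": deff})
    return SizeSolution(
        n_raw=sol.n_raw,
        n=sol.n,
        components={**sol.components, "n_t1": math.ceil(sol.n / spec.r)},
        warnings=sol.warnings,
    )


def n_net_props(
    spec: NetChangeSpecProps, gamma: float, deff: float = 1.0
) -> SizeSolution:
    """Wave-t size ``n_t`` to detect a net change in proportions at overlap ``gamma``."""
    if not 0.0 <= gamma <= 1.0:
        raise SpecError(f"gamma must lie in [0, 1], got {gamma}")
    c = critical_factor(spec.test)
    var_term = (
        spec.p_t * (1.0 - spec.p_t)
        + spec.r * spec.p_t1 * (1.0 - spec.p_t1)
        - 2.0 * gamma * spec.r * (spec.p_xy - spec.p_t * spec.p_t1)
    )
    if var_term <= 0:
        raise InfeasibleDesignError(
            f"variance term {var_term:.6g} is non-positive"
        )
    n_raw = deff * var_term / spec.delta**2 * c
    sol = _finish(n_raw, {"critical_factor": c, "variance_term": var_term, "deff": deff})
    return SizeSolution(
        n_raw=sol.n_raw,
        n=sol.n,
        components={**sol.components, "n_t1": math.ceil(sol.n / spec.r)},
        warnings=sol.warnings,
    )


def _next_wave(
    n_t: int,
    n_11: int,
    c: float,
    var_t: float,
    var_t1: float,
    cov: float,
    delta: float,
) -> SizeSolution:
    # n_{t+1} = C*(n_t*var_t1 - 2*n_11*cov) / (n_t*delta^2 - var_t*C)
    if n_11 > n_t:
        raise SpecError(f"n_11 ({n_11}) cannot exceed n_t ({n_t})")
    denom = n_t * delta**2 - var_t * c
    components = {
        "critical_factor": c,
        "numerator": c * (n_t * var_t1 - 2.0 * n_11 * cov),
        "denominator": denom,
    }
    if denom <= 0:
        raise InfeasibleDesignError(
            f"first-wave sample too small: n_t must exceed {var_t * c / delta**2:.4f} "
            "before any second wave can reach the target power"
        )
    numer = components["numerator"]
    if numer < 0:
        return SizeSolution(
            n_raw=float(n_11),
            n=n_11,
            components=components,
            warnings=(
                "overlap already sufficient: the paired covariance alone exceeds "
                "the remaining variance budget; returning the minimum n_t1 = n_11",
            ),
        )
    return _finish(numer / denom, components)


def n_next_wave_means(
    n_t: int, n_11: int, spec: NetChangeSpecMeans
) -> SizeSolution:
    """Second-wave size ``n_{t+1}`` given a fixed first wave ``n_t`` and overlap ``n_11``.

    Solves the net-change variance for ``n_{t+1}`` so that back-substituting
    the raw solution reproduces variance ``delta^2 / critical_factor``
    exactly.  Infeasible when ``n_t`` alone falls short of the single-sample
    requirement ``sigma_x2 * C / delta^2``.
    """
    c = critical_factor(spec.test)
    sxsy = math.sqrt(spec.sigma_x2 * spec.sigma_y2)
    return _next_wave(
        n_t, n_11, c, spec.sigma_x2, spec.sigma_y2, spec.rho * sxsy, spec.delta
    )


def n_next_wave_props(
    n_t: int, n_11: int, spec: NetChangeSpecProps
) -> SizeSolution:
    """Proportions analogue of :func:`n_next_wave_means` with binomial moments."""
    c = critical_factor(spec.test)
    return _next_wave(
        n_t,
        n_11,
        c,
        spec.p_t * (1.0 - spec.p_t),
        spec.p_t1 * (1.0 - spec.p_t1),
        spec.p_xy - spec.p_t * spec.p_t1,
        spec.delta,
    )
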