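"""Sequential search for the dual net/gross sample-size problem.

No closed form solves for ``n_t``, ``n_11`` and ``n_{t+1}`` jointly when
all three are free, so the search proceeds in two stages: the overlap
panel ``n_11`` is fixed by the gross-change requirement, and ``n_t`` is
then walked upward from a theta-controlled lower bound, one unit per
iteration, until the normal-approximation power for the net change
reaches its target.  Field sizes are finally inflated for nonresponse.

Stop rule
---------
The default rule stops at the first candidate whose approximate power,
rounded to two decimals, reaches the target (power >= target - 0.005).
A strict first-crossing rule (power >= target exactly) is available via
``stop_rule="strict"``; it stops one or a few candidates later whenever
the rounded rule accepts a power a hair under target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Union

import pandas as pd

from scipy.stats import norm

from .closed_form import (
    InfeasibleDesignError,
    critical_factor,
    n_gross_means,
    n_gross_props,
)
from .specs import (
    DesignOptions,
    GrossChangeSpecMeans,
    GrossChangeSpecProps,
    NetChangeSpecMeans,
    NetChangeSpecProps,
    Sided,
    SpecError,
    z_quantile,
)

__all__ = [
    "IterationRecord",
    "SampleSizeResult",
    "overlap_lower_bound",
    "power_approx_means",
    "power_approx_props",
    "sequential_search",
    "inflate_for_nonresponse",
]

NetSpec = Union[NetChangeSpecMeans, NetChangeSpecProps]
GrossSpec = Union[GrossChangeSpecMeans, GrossChangeSpecProps]


@dataclass(frozen=True)
class IterationRecord:
    """One row of the sequential-search trace."""

    i: int
    n_i: int
    gamma_i: float
    z_i: float
    power_i: float


@dataclass(frozen=True)
class SampleSizeResult:
    """A solved two-wave design.

    ``n10 = n_t - n11`` and ``n01 = n_t1 - n11`` are the fresh shares of
    each wave; ``gamma = n11 / n_t`` is the overlap fraction.  The
    ``*_inflated`` sizes are the fielded counts after dividing by the
    expected completion rates.
    """

    n11: int
    n_t: int
    n_t1: int
    n10: int
    n01: int
    gamma: float
    iterations: int
    achieved_power_net: float
    achieved_power_gross: float
    n11_inflated: int
    n10_inflated: int
    trace: tuple[IterationRecord, ...] = ()

    def to_dict(self, include_trace: bool = False) -> dict:
        out = {
            "n11": self.n11,
            "n_t": self.n_t,
            "n_t1": self.n_t1,
            "n10": self.n10,
            "n01": self.n01,
            "gamma": self.gamma,
            "iterations": self.iterations,
            "achieved_power_net": self.achieved_power_net,
            "achieved_power_gross": self.achieved_power_gross,
            "n11_inflated": self.n11_inflated,
            "n10_inflated": self.n10_inflated,
        }
        if include_trace:
            out["trace"] = [vars(rec) | {} for rec in self.trace]
        return out

    def trace_frame(self) -> pd.DataFrame:
        """Iteration trace as a DataFrame (columns i, n_i, gamma_i, z_i, power_i)."""
        return pd.DataFrame(
            [(r.i, r.n_i, r.gamma_i, r.z_i, r.power_i) for r in self.trace],
            columns=["i", "n_i", "gamma_i", "z_i", "power_i"],
        )


def overlap_lower_bound(theta: float, n11: int) -> int:
    """Exclusive lower bound ``j`` on the fresh share ``n_10``.

    ``j = round(theta * n11 / (1 - theta))``; candidates then have
    ``n_10 = j + i`` for i >= 1.  theta = 0 lets n_10 start at zero;
    theta = 0.5 makes the bound equal n_11 (the search starts with the
    fresh share already above the panel share).
    """
    if not 0.0 <= theta < 1.0:
        raise SpecError(f"theta must lie in [0, 1), got {theta}")
    if n11 < 1:
        raise SpecError(f"n11 must be a positive integer, got {n11}")
    return int(math.floor(theta * n11 / (1.0 - theta) + 0.5))


def _zcrit(test) -> float:
    a = test.alpha / 2 if test.sided is Sided.two else test.alpha
    return z_quantile(1.0 - a)


def power_approx_means(
    n: int, n11: int, spec: NetChangeSpecMeans, deff: float = 1.0
) -> tuple[float, float]:
    """Normal-approximation power for the net-change test in means.

    With ``n_t = n``, ``n_{t+1} = ceil(n / r)``, the estimator variance is

        V = deff * (sigma_x2/n_t + sigma_y2/n_t1 - 2*n11*rho*sx*sy/(n_t*n_t1))

    and ``z = Z_crit - delta / sqrt(V)``; the approximate power is
    ``Phi(-z)``.  For r = 1 this reduces to
    ``Z_crit - sqrt(n * delta^2 / (sigma_x2 + sigma_y2 - 2*gamma*rho*sx*sy))``.
    """
    if not 1 <= n11 <= n:
        raise SpecError(f"need 1 <= n11 <= n, got n11={n11}, n={n}")
    n_t1 = math.ceil(n / spec.r)
    if n11 > n_t1:
        raise SpecError(
            f"overlap panel n11={n11} cannot exceed the second wave n_t1={n_t1}"
        )
    sxsy = math.sqrt(spec.sigma_x2 * spec.sigma_y2)
    var = deff * (
        spec.sigma_x2 / n
        + spec.sigma_y2 / n_t1
        - 2.0 * n11 * spec.rho * sxsy / (n * n_t1)
    )
    if var <= 0:
        raise InfeasibleDesignError(f"net-change variance {var:.6g} is non-positive")
    z = _zcrit(spec.test) - spec.delta / math.sqrt(var)
    return z, float(norm.cdf(-z))


def power_approx_props(
    n: int, n11: int, spec: NetChangeSpecProps, deff: float = 1.0
) -> tuple[float, float]:
    """Proportions analogue of :func:`power_approx_means` with binomial moments."""
    if not 1 <= n11 <= n:
        raise SpecError(f"need 1 <= n11 <= n, got n11={n11}, n={n}")
    n_t1 = math.ceil(n / spec.r)
    if n11 > n_t1:
        raise SpecError(
            f"overlap panel n11={n11} cannot exceed the second wave n_t1={n_t1}"
        )
    var = deff * (
        spec.p_t * (1.0 - spec.p_t) / n
        + spec.p_t1 * (1.0 - spec.p_t1) / n_t1
        - 2.0 * n11 * (spec.p_xy - spec.p_t * spec.p_t1) / (n * n_t1)
    )
    if var <= 0:
        raise InfeasibleDesignError(f"net-change variance {var:.6g} is non-positive")
    z = _zcrit(spec.test) - spec.delta / math.sqrt(var)
    return z, float(norm.cdf(-z))


def _gross_power(gross: GrossSpec, n11: int, deff: float) -> float:
    if isinstance(gross, GrossChangeSpecMeans):
        var_term = 2.0 * gross.sigma_o2 * (1.0 - gross.rho)
        delta = gross.delta_gross
    else:
        var_term = (
            gross.p_t * (1.0 - gross.p_t)
            + gross.p_t1 * (1.0 - gross.p_t1)
            - 2.0 * (gross.p_xy - gross.p_t * gross.p_t1)
        )
        delta = gross.delta_gross
    se = math.sqrt(deff * var_term / n11)
    return float(norm.cdf(delta / se - _zcrit(gross.test)))


def sequential_search(
    gross: GrossSpec,
    net: NetSpec,
    options: DesignOptions = DesignOptions(),
    stop_rule: str = "rounded",
) -> SampleSizeResult:
    """Solve the dual design: n_11 from the gross target, then walk n_t.

    Step 1 sizes the overlap panel from the gross-change requirement
    (ceiling applied, so the walk uses the integer n_11).  Step 2 sets the
    exclusive lower bound ``j`` on n_10 from ``options.theta`` and
    evaluates candidates ``n_i = n11 + i + j`` for i = 1, 2, ...; the walk
    stops at the first candidate whose approximate net power satisfies the
    stop rule.  Step 3 inflates the fielded sizes by the completion rates.

    Raises
    ------
    SpecError
        If the two specs are not on the same outcome scale, or the cap
        ``options.max_iter`` is exhausted (the message names the last
        achieved power).
    InfeasibleDesignError
        If the net-change variance is non-positive at some candidate.
    """
    if stop_rule not in ("rounded", "strict"):
        raise SpecError(f"stop_rule must be 'rounded' or 'strict', got {stop_rule!r}")

    if isinstance(gross, GrossChangeSpecMeans) and isinstance(net, NetChangeSpecMeans):
        gross_solver, power_fn = n_gross_means, power_approx_means
    elif isinstance(gross, GrossChangeSpecProps) and isinstance(net, NetChangeSpecProps):
        gross_solver, power_fn = n_gross_props, power_approx_props
    else:
        raise SpecError(
            "gross and net specs must be on the same outcome scale "
            f"(got {type(gross).__name__} and {type(net).__name__})"
        )

    n11 = gross_solver(gross, deff=options.deff).n
    j = overlap_lower_bound(options.theta, n11)
    target = net.test.power
    # candidate floor: both waves must be able to contain the overlap panel;
    # for r = 1 this is just n11, so n_i = n11 + i + j as in the base algorithm
    base = max(n11, math.ceil(n11 * net.r))

    trace: list[IterationRecord] = []
    stopped = None
    for i in range(1, options.max_iter + 1):
        n_i = base + i + j
        z_i, power_i = power_fn(n_i, n11, net, options.deff)
        trace.append(IterationRecord(i=i, n_i=n_i, gamma_i=n11 / n_i, z_i=z_i, power_i=power_i))
        if stop_rule == "rounded":
            hit = round(power_i, 2) >= target - 1e-9
        else:
            hit = power_i >= target
        if hit:
            stopped = trace[-1]
            break
    if stopped is None:
        raise SpecError(
            f"sequential search did not reach target power {target} within "
            f"{options.max_iter} iterations (last approximate power "
            f"{trace[-1].power_i:.4f} at n_t={trace[-1].n_i})"
        )

    n_t = stopped.n_i
    n_t1 = math.ceil(n_t / net.r)
    result = SampleSizeResult(
        n11=n11,
        n_t=n_t,
        n_t1=n_t1,
        n10=n_t - n11,
        n01=n_t1 - n11,
        gamma=n11 / n_t,
        iterations=stopped.i,
        achieved_power_net=stopped.power_i,
        achieved_power_gross=_gross_power(gross, n11, options.deff),
        n11_inflated=n11,
        n10_inflated=n_t - n11,
        trace=tuple(trace),
    )
    return inflate_for_nonresponse(result, options.rr11, options.rr10)


def inflate_for_nonresponse(
    result: SampleSizeResult, rr11: float, rr10: float
) -> SampleSizeResult:
    """Inflate fielded sizes for panel attrition and fresh-sample nonresponse.

    ``n11_inflated = ceil(n11 / rr11)`` and
    ``n10_inflated = ceil((n_t - n11) / rr10)``; all completed-interview
    sizes (and the powers, which refer to completed interviews) are left
    unchanged.
    """
    if not 0.0 < rr11 <= 1.0 or not 0.0 < rr10 <= 1.0:
        raise SpecError("completion rates must lie in (0, 1]")
    return replace(
        result,
        n11_inflated=math.ceil(result.n11 / rr11),
        n10_inflated=math.ceil((result.n_t - result.n11) / rr10),
    )
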