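"""Design parameters for two-wave panel sample-size problems.

A longitudinal (rotating- or split-panel) survey observes a wave-*t* sample
``s_t`` of size ``n_t`` and a wave-*t+1* sample ``s_{t+1}`` of size
``n_{t+1}`` that share an overlap panel ``s_11`` of size ``n_11``.  Two
estimands drive the design:

* **net change** -- the difference between the aggregate means (or
  proportions) of the two waves, estimated from the full, partially
  overlapping samples; and
* **gross change** -- the individual-level change, estimable only from the
  paired measurements in the overlap panel.

The classes here hold the detectable effect sizes and population moments
for each estimand, on either the means or the proportions scale, and
validate every statistical constraint (positivity, correlation bounds,
Frechet bounds on joint proportions) before any calculator runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from enum import Enum

from scipy.stats import norm

__all__ = [
    "Sided",
    "TestParams",
    "NetChangeSpecMeans",
    "NetChangeSpecProps",
    "GrossChangeSpecMeans",
    "GrossChangeSpecProps",
    "DesignOptions",
    "SpecError",
    "FrechetError",
    "validate",
    "z_quantile",
]


class SpecError(ValueError):
    """A design-parameter bundle violates one of its statistical constraints."""


class FrechetError(SpecError):
    """A joint proportion lies outside the Frechet bounds of its margins.

    Unlike an ordinary parameter error this signals an *impossible joint
    distribution*: no bivariate binary population has the requested margins
    and joint probability.
    """


class Sided(str, Enum):
    """Sidedness of the hypothesis test a design targets."""

    one = "one"
    two = "two"

    @classmethod
    def coerce(cls, value: "Sided | str") -> "Sided":
        if isinstance(value, cls):
            return value
        key = str(value).lower().replace("-", ".").replace("_", ".")
        if key in ("one", "one.sided", "1"):
            return cls.one
        if key in ("two", "two.sided", "2"):
            return cls.two
        raise SpecError(f"sided must be 'one' or 'two', got {value!r}")


def z_quantile(p: float) -> float:
    """Standard-normal quantile Phi^{-1}(p).

    Raises :class:`SpecError` outside the open unit interval.
    """
    if not 0.0 < p < 1.0:
        raise SpecError(f"quantile argument must lie in (0, 1), got {p}")
    return float(norm.ppf(p))


def _frechet_check(p_t: float, p_t1: float, p_xy: float, label: str = "p_xy") -> None:
    lo = max(0.0, p_t + p_t1 - 1.0)
    hi = min(p_t, p_t1)
    if not lo <= p_xy <= hi:
        raise FrechetError(
            f"{label}={p_xy} violates the Frechet bounds [{lo:.6g}, {hi:.6g}] "
            f"implied by margins ({p_t}, {p_t1}); no joint distribution exists"
        )


@dataclass(frozen=True)
class TestParams:
    """Significance level, target power and sidedness of one test.

    Parameters
    ----------
    alpha
        Significance level, in (0, 1).
    power
        Target power 1 - beta, in (0, 1).  Must exceed ``alpha`` for the
        sizing problem to be non-degenerate.
    sided
        ``Sided.one`` or ``Sided.two`` (strings ``"one"``/``"two"``/
        ``"one.sided"``/``"two.sided"`` are accepted).
    """

    alpha: float
    power: float
    sided: Sided = Sided.two

    __test__ = False  # not a test class despite the Test* name

    def __post_init__(self) -> None:
        object.__setattr__(self, "sided", Sided.coerce(self.sided))
        self.validate()

    def validate(self) -> "TestParams":
        if not 0.0 < self.alpha < 1.0:
            raise SpecError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not 0.0 < self.power < 1.0:
            raise SpecError(f"power must lie in (0, 1), got {self.power}")
        if self.power <= self.alpha:
            raise SpecError(
                f"power ({self.power}) must exceed alpha ({self.alpha}); "
                "otherwise the required sample size degenerates"
            )
        return self


@dataclass(frozen=True)
class NetChangeSpecMeans:
    """Detectable net change in means with its population moments.

    ``sigma_x2`` is the variance paired with the wave-*t* sample and
    ``sigma_y2`` with wave *t+1* in the variance of the net-change
    estimator; for the usual equal-wave design (r = 1) the labelling is
    immaterial.  The paired covariance is always parameterised as
    ``rho * sigma_x * sigma_y``.

    ``delta`` is stored as a magnitude: the sizing formulas use delta**2
    only, so its sign carries no information (test direction belongs to
    the analysis stage, not the design stage).
    """

    delta: float
    sigma_x2: float
    sigma_y2: float
    rho: float
    test: TestParams
    r: float = 1.0  # wave-size ratio n_t / n_{t+1}

    scale = "means"

    def __post_init__(self) -> None:
        object.__setattr__(self, "delta", abs(self.delta))
        self.validate()

    def validate(self) -> "NetChangeSpecMeans":
        if self.delta == 0:
            raise SpecError("delta must be nonzero")
        if self.sigma_x2 <= 0 or self.sigma_y2 <= 0:
            raise SpecError("variances sigma_x2, sigma_y2 must be positive")
        if not -1.0 < self.rho < 1.0:
            raise SpecError(f"rho must lie in (-1, 1), got {self.rho}")
        if self.r <= 0:
            raise SpecError(f"wave-size ratio r must be positive, got {self.r}")
        return self


@dataclass(frozen=True)
class NetChangeSpecProps:
    """Detectable net change in proportions.

    The detectable change is derived, never supplied: ``delta`` is
    ``|p_t1 - p_t|``.  ``p_xy`` is the joint proportion of overlap-panel
    units carrying the study characteristic at both waves and must satisfy
    the Frechet bounds of its margins.
    """

    p_t: float
    p_t1: float
    p_xy: float
    test: TestParams
    r: float = 1.0

    scale = "props"

    def __post_init__(self) -> None:
        self.validate()

    @property
    def delta(self) -> float:
        return abs(self.p_t1 - self.p_t)

    def validate(self) -> "NetChangeSpecProps":
        for name in ("p_t", "p_t1"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise SpecError(f"{name} must lie in (0, 1), got {v}")
        if self.p_t == self.p_t1:
            raise SpecError("p_t and p_t1 must differ (delta would be zero)")
        if self.r <= 0:
            raise SpecError(f"wave-size ratio r must be positive, got {self.r}")
        _frechet_check(self.p_t, self.p_t1, self.p_xy)
        return self


@dataclass(frozen=True)
class GrossChangeSpecMeans:
    """Detectable gross (within-panel) change in means.

    The overlap panel's paired measurements are assumed to share a common
    variance ``sigma_o2`` at both waves, with paired correlation ``rho``,
    so the difference y - x has variance 2*sigma_o2*(1 - rho).
    """

    delta_gross: float
    sigma_o2: float
    rho: float
    test: TestParams

    scale = "means"

    def __post_init__(self) -> None:
        object.__setattr__(self, "delta_gross", abs(self.delta_gross))
        self.validate()

    def validate(self) -> "GrossChangeSpecMeans":
        if self.delta_gross == 0:
            raise SpecError("delta_gross must be nonzero")
        if self.sigma_o2 <= 0:
            raise SpecError("sigma_o2 must be positive")
        if not -1.0 < self.rho < 1.0:
            raise SpecError(f"rho must lie in (-1, 1), got {self.rho}")
        return self


@dataclass(frozen=True)
class GrossChangeSpecProps:
    """Detectable gross change in proportions, over the overlap panel only."""

    p_t: float
    p_t1: float
    p_xy: float
    test: TestParams

    scale = "props"

    def __post_init__(self) -> None:
        self.validate()

    @property
    def delta_gross(self) -> float:
        return abs(self.p_t1 - self.p_t)

    def validate(self) -> "GrossChangeSpecProps":
        for name in ("p_t", "p_t1"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise SpecError(f"{name} must lie in (0, 1), got {v}")
        if self.p_t == self.p_t1:
            raise SpecError("p_t and p_t1 must differ (delta_gross would be zero)")
        _frechet_check(self.p_t, self.p_t1, self.p_xy)
        return self


@dataclass(frozen=True)
class DesignOptions:
    """Knobs shared by the sequential search and the field-size inflation.

    Parameters
    ----------
    theta
        Overlap lower-bound parameter in [0, 1).  theta = 0 lets the fresh
        share ``n_10`` start at zero; theta = 0.5 forces the search to start
        with ``n_10`` above ``n_11``.
    deff
        Design effect: scalar inflation of the simple-random-sampling
        requirement for a complex design.  Must be positive; >= 1 in
        practice.
    rr11, rr10
        Expected completion rates among panel and fresh units; their
        reciprocals inflate the fielded sample sizes.
    max_iter
        Safety cap on sequential-search iterations.
    """

    theta: float = 0.5
    deff: float = 1.0
    rr11: float = 1.0
    rr10: float = 1.0
    max_iter: int = 1_000_000

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> "DesignOptions":
        if not 0.0 <= self.theta < 1.0:
            raise SpecError(f"theta must lie in [0, 1), got {self.theta}")
        if self.deff <= 0:
            raise SpecError(f"deff must be positive, got {self.deff}")
        for name in ("rr11", "rr10"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise SpecError(f"{name} must lie in (0, 1], got {v}")
        if self.max_iter < 1:
            raise SpecError("max_iter must be a positive integer")
        return self


def validate(spec):
    """Re-validate any spec object and return it unchanged.

    Validation also runs at construction; this entry point exists so that
    callers holding a spec of unknown provenance can assert its invariants
    (the operation is idempotent).
    """
    return spec.validate()
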