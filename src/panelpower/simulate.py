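"""Monte-Carlo verification of designed power and size.

Generates synthetic two-wave panel data with the exact overlap structure
``s10 / s11 / s01``, applies the net- and gross-change estimators with
plug-in z-tests, and estimates empirical power (or type-I error, when the
true change is zero) for any design emitted by the calculators.

The design-stage formulas use population moments; the analysis-stage
tests here use the standard unbiased sample moments (ddof = 1), with the
net-change variance assembled from the full-wave sample variances and the
sample covariance of the paired subset.

Seeding: one master seed spawns independent per-replicate substreams
(``numpy.random.SeedSequence.spawn``), so replicate k draws the same data
regardless of how many replicates run or in what order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
from scipy.stats import norm

from .specs import SpecError, Sided, z_quantile

__all__ = [
    "PanelDataset",
    "PowerEstimate",
    "MeansTruth",
    "PropsTruth",
    "TestResult",
    "joint_bernoulli_cells",
    "gen_panel_means",
    "gen_panel_props",
    "net_change_test",
    "gross_change_test",
    "empirical_power",
]


@dataclass(frozen=True)
class PanelDataset:
    """Two-wave data partitioned by overlap status.

    ``pairs11`` is an (n11, 2) array: column 0 the wave-t measurement,
    column 1 the wave-t+1 measurement for the same unit.  ``y10`` holds
    wave-t-only units and ``x01`` wave-t+1-only units, so the full waves
    are ``s_t = s_10 U s_11`` and ``s_{t+1} = s_01 U s_11``.
    """

    y10: np.ndarray
    pairs11: np.ndarray
    x01: np.ndarray

    @property
    def n11(self) -> int:
        return self.pairs11.shape[0]

    @property
    def n_t(self) -> int:
        return self.y10.size + self.n11

    @property
    def n_t1(self) -> int:
        return self.x01.size + self.n11

    @property
    def wave_t(self) -> np.ndarray:
        return np.concatenate([self.y10, self.pairs11[:, 0]])

    @property
    def wave_t1(self) -> np.ndarray:
        return np.concatenate([self.pairs11[:, 1], self.x01])


@dataclass(frozen=True)
class PowerEstimate:
    """Empirical rejection rate over seeded replicates."""

    reps: int
    rejections: int
    power_hat: float
    mc_se: float
    seed: int

    @classmethod
    def from_counts(cls, rejections: int, reps: int, seed: int) -> "PowerEstimate":
        p = rejections / reps
        return cls(
            reps=reps,
            rejections=rejections,
            power_hat=p,
            mc_se=math.sqrt(p * (1.0 - p) / reps),
            seed=seed,
        )


@dataclass(frozen=True)
class MeansTruth:
    """True data-generating parameters for a continuous outcome."""

    mu_t: float
    mu_t1: float
    sigma_x2: float
    sigma_y2: float
    rho: float


@dataclass(frozen=True)
class PropsTruth:
    """True data-generating parameters for a binary outcome."""

    p_t: float
    p_t1: float
    p_xy: float


class TestResult(NamedTuple):
    estimate: float
    variance_hat: float
    z: float
    reject: bool


def joint_bernoulli_cells(
    p_t: float, p_t1: float, p_xy: float
) -> tuple[float, float, float, float]:
    """Cell probabilities (p11, p10, p01, p00) of the paired binary outcome.

    p11 is the probability of carrying the characteristic at both waves;
    raises :class:`~panelpower.specs.FrechetError` (via the bound check)
    when no joint distribution matches the margins.
    """
    from .specs import _frechet_check

    _frechet_check(p_t, p_t1, p_xy)
    p11 = p_xy
    p10 = p_t - p_xy
    p01 = p_t1 - p_xy
    p00 = 1.0 - p_t - p_t1 + p_xy
    return p11, p10, p01, p00


def gen_panel_means(
    n10: int,
    n11: int,
    n01: int,
    mu_t: float,
    mu_t1: float,
    sigma_x2: float,
    sigma_y2: float,
    rho: float,
    seed=None,
) -> PanelDataset:
    """Draw a continuous two-wave panel.

    Paired units come from a bivariate normal with wave-t variance
    ``sigma_x2``, wave-t+1 variance ``sigma_y2`` and correlation ``rho``;
    the single-wave subsets are independent normals with the matching
    marginals.  ``seed`` may be an int, a SeedSequence or a Generator.
    """
    if min(n10, n11, n01) < 0:
        raise SpecError("sample sizes must be non-negative")
    if sigma_x2 <= 0 or sigma_y2 <= 0 or not -1.0 <= rho <= 1.0:
        raise SpecError("need positive variances and rho in [-1, 1]")
    rng = np.random.default_rng(seed)
    sx, sy = math.sqrt(sigma_x2), math.sqrt(sigma_y2)
    cov = np.array(
        [[sigma_x2, rho * sx * sy], [rho * sx * sy, sigma_y2]]
    )
    pairs = rng.multivariate_normal([mu_t, mu_t1], cov, size=n11, method="cholesky")
    y10 = rng.normal(mu_t, sx, size=n10)
    x01 = rng.normal(mu_t1, sy, size=n01)
    return PanelDataset(y10=y10, pairs11=pairs, x01=x01)


def gen_panel_props(
    n10: int,
    n11: int,
    n01: int,
    p_t: float,
    p_t1: float,
    p_xy: float,
    seed=None,
) -> PanelDataset:
    """Draw a binary two-wave panel from the four-cell joint distribution."""
    if min(n10, n11, n01) < 0:
        raise SpecError("sample sizes must be non-negative")
    cells = joint_bernoulli_cells(p_t, p_t1, p_xy)
    rng = np.random.default_rng(seed)
    # cells map to (y, x): 11, 10, 01, 00
    outcomes = np.array([[1, 1], [1, 0], [0, 1], [0, 0]], dtype=float)
    idx = rng.choice(4, size=n11, p=np.asarray(cells))
    pairs = outcomes[idx]
    y10 = (rng.random(n10) < p_t).astype(float)
    x01 = (rng.random(n01) < p_t1).astype(float)
    return PanelDataset(y10=y10, pairs11=pairs, x01=x01)


def _decide(z: float, sided, alpha: float, direction: int) -> bool:
    sided = Sided.coerce(sided)
    if sided is Sided.two:
        return abs(z) >= z_quantile(1.0 - alpha / 2)
    return direction * z >= z_quantile(1.0 - alpha)


def net_change_test(
    data: PanelDataset,
    sided="two",
    alpha: float = 0.05,
    direction: int = 1,
) -> TestResult:
    """Net-change z-test: wave-t mean minus wave-t+1 mean.

    The plug-in variance is
    ``s2_t/n_t + s2_t1/n_t1 - 2*cov11*n11/(n_t*n_t1)`` with full-wave
    sample variances and the sample covariance of the paired subset.  For
    a one-sided test, ``direction`` is the hypothesized sign of the
    estimate (+1: wave-t mean larger).
    """
    if data.n_t < 2 or data.n_t1 < 2:
        raise SpecError("need at least 2 units in each wave")
    wt, wt1 = data.wave_t, data.wave_t1
    est = float(wt.mean() - wt1.mean())
    s2_t = float(wt.var(ddof=1))
    s2_t1 = float(wt1.var(ddof=1))
    cov11 = (
        float(np.cov(data.pairs11[:, 0], data.pairs11[:, 1], ddof=1)[0, 1])
        if data.n11 >= 2
        else 0.0
    )
    var = s2_t / data.n_t + s2_t1 / data.n_t1 - 2.0 * cov11 * data.n11 / (data.n_t * data.n_t1)
    if var <= 0:
        raise SpecError(f"estimated net-change variance {var:.6g} is not positive")
    z = est / math.sqrt(var)
    return TestResult(est, var, z, _decide(z, sided, alpha, direction))


def gross_change_test(
    data: PanelDataset,
    sided="two",
    alpha: float = 0.05,
    direction: int = 1,
) -> TestResult:
    """Paired-difference z-test over the overlap panel only.

    Uses the y - x differences of ``pairs11``; the single-wave subsets
    never enter.  ``direction`` as in :func:`net_change_test`.
    """
    if data.n11 < 2:
        raise SpecError("gross change needs at least 2 paired units")
    d = data.pairs11[:, 0] - data.pairs11[:, 1]
    est = float(d.mean())
    var = float(d.var(ddof=1)) / data.n11
    if var <= 0:
        raise SpecError("estimated gross-change variance is zero (constant differences)")
    z = est / math.sqrt(var)
    return TestResult(est, var, z, _decide(z, sided, alpha, direction))


def empirical_power(
    n10: int,
    n11: int,
    n01: int,
    net_truth: Optional[MeansTruth | PropsTruth] = None,
    gross_truth: Optional[MeansTruth | PropsTruth] = None,
    sided="one",
    alpha: float = 0.05,
    direction: int = 1,
    reps: int = 1000,
    seed: int = 0,
    sided_gross=None,
    alpha_gross: Optional[float] = None,
    return_flags: bool = False,
):
    """Estimate rejection rates by seeded replication.

    Runs ``reps`` independent replicates.  When ``net_truth`` is given,
    each replicate draws a full panel at sizes (n10, n11, n01) under it
    and applies the net-change test; when ``gross_truth`` is given, each
    replicate draws ``n11`` pairs under it and applies the gross test.
    The two truths are deliberately separate inputs: the net and gross
    requirements of a design are generally stated with incompatible
    moments, so each test is verified under its own data-generating
    process.

    Returns a dict with keys ``"net"`` and/or ``"gross"`` mapping to
    :class:`PowerEstimate`; with ``return_flags=True`` each value is a
    ``(PowerEstimate, ndarray-of-bool)`` pair of per-replicate rejections.
    """
    if reps < 100:
        raise SpecError("use at least 100 replicates for a meaningful estimate")
    if net_truth is None and gross_truth is None:
        raise SpecError("supply net_truth and/or gross_truth")
    sided_gross = sided if sided_gross is None else sided_gross
    alpha_gross = alpha if alpha_gross is None else alpha_gross

    streams = np.random.SeedSequence(seed).spawn(reps)
    net_flags = np.zeros(reps, dtype=bool)
    gross_flags = np.zeros(reps, dtype=bool)
    for k, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        if net_truth is not None:
            data = _gen(net_truth, n10, n11, n01, rng)
            net_flags[k] = net_change_test(data, sided, alpha, direction).reject
        if gross_truth is not None:
            data = _gen(gross_truth, 0, n11, 0, rng)
            gross_flags[k] = gross_change_test(
                data, sided_gross, alpha_gross, direction
            ).reject
    out = {}
    if net_truth is not None:
        est = PowerEstimate.from_counts(int(net_flags.sum()), reps, seed)
        out["net"] = (est, net_flags) if return_flags else est
    if gross_truth is not None:
        est = PowerEstimate.from_counts(int(gross_flags.sum()), reps, seed)
        out["gross"] = (est, gross_flags) if return_flags else est
    return out


def _gen(truth, n10: int, n11: int, n01: int, rng) -> PanelDataset:
    if isinstance(truth, MeansTruth):
        return gen_panel_means(
            n10, n11, n01,
            truth.mu_t, truth.mu_t1,
            truth.sigma_x2, truth.sigma_y2, truth.rho,
            seed=rng,
        )
    if isinstance(truth, PropsTruth):
        return gen_panel_props(n10, n11, n01, truth.p_t, truth.p_t1, truth.p_xy, seed=rng)
    raise SpecError(f"unknown truth type {type(truth).__name__}")
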