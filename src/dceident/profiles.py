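"""Profile likelihoods, confidence intervals, and identifiability verdicts.

For a target parameter :math:`\\theta_i` the profile likelihood is

.. math::

    PL(\\theta_i) = \\min_{\\theta_{j \\ne i}} \\mathrm{MLE}(\\theta),

i.e. the objective re-minimized over the remaining active parameters with
the target fixed at each grid value.  The pointwise confidence interval at
level :math:`\\alpha` collects the targets with
:math:`PL(\\theta_i) \\le \\mathrm{MLE}(\\hat\\theta) + \\Delta_\\alpha`,
where :math:`\\Delta_\\alpha` is the :math:`\\alpha` quantile of the
chi-squared distribution with one degree of freedom.  A parameter is
practically identifiable at that level when both interval ends are finite;
a flat profile is the signature of structural-style non-identifiability.

Compensating profiles trace how the re-optimized co-parameters move as the
target is perturbed around its optimum, exposing which parameters absorb
the change.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import chi2

from .fitting import FitConfig, FitResult
from .signals import SampledSignal
from .transport import ModelKind, ct_curves_batch

__all__ = [
    "LikelihoodProfile",
    "ConfidenceInterval",
    "IdentifiabilityVerdict",
    "CompensatingProfiles",
    "chi2_threshold",
    "profile_likelihood",
    "confidence_interval",
    "classify",
    "compensating_profiles",
]

#: Fraction of the chi-squared threshold below which the total variation of
#: a profile is reported as flat.  An artifact convention, recorded in the
#: profile metadata.
FLATNESS_FRACTION = 0.05


def chi2_threshold(level: float) -> float:
    """Quantile ``Delta_alpha`` of the chi-squared distribution, 1 df."""
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must lie in (0, 1)")
    return float(chi2.ppf(level, df=1))


@dataclass(frozen=True)
class LikelihoodProfile:
    """Profile of the objective along one parameter.

    ``co_params`` holds, per grid point, the re-optimized values of the
    remaining active parameters.
    """

    target: str
    kind: ModelKind
    grid: np.ndarray
    pl_values: np.ndarray
    co_params: tuple[dict[str, float], ...]
    theta_hat: dict[str, float]
    mle_hat: float
    sigma: float
    meta: dict = field(default_factory=dict)

    @property
    def target_hat(self) -> float:
        return self.theta_hat[self.target]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({self.target: self.grid, "pl": self.pl_values})
        for name in self.co_params[0]:
            df[name] = [cp[name] for cp in self.co_params]
        return df


@dataclass(frozen=True)
class ConfidenceInterval:
    """Profile-likelihood confidence interval; open sides carry the grid
    edge as the bound value with ``finite`` set to False."""

    level: float
    lower: float
    upper: float
    lower_finite: bool
    upper_finite: bool

    @property
    def finite(self) -> bool:
        return self.lower_finite and self.upper_finite

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "lower": self.lower,
            "upper": self.upper,
            "lower_finite": self.lower_finite,
            "upper_finite": self.upper_finite,
        }


@dataclass(frozen=True)
class IdentifiabilityVerdict:
    """Classification of one parameter at a stated confidence level."""

    status: str  # identifiable | practically_non_identifiable | flat
    level: float
    open_sides: tuple[str, ...]

    def to_json(self) -> str:
        return json.dumps(
            {"status": self.status, "level": self.level, "open_sides": list(self.open_sides)}
        )


@dataclass(frozen=True)
class CompensatingProfiles:
    """Traces of re-optimized co-parameters versus the perturbed target."""

    target: str
    kind: ModelKind
    target_values: np.ndarray
    traces: dict[str, np.ndarray]
    theta_hat: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({self.target: self.target_values})
        for name, tr in self.traces.items():
            df[name] = tr
        return df


# -- re-optimization core ---------------------------------------------------


def _reoptimize(
    kind: ModelKind,
    times: np.ndarray,
    u: np.ndarray,
    y: np.ndarray,
    sigma: float,
    target: str,
    target_value: float,
    free_names: tuple[str, ...],
    lb: np.ndarray,
    ub: np.ndarray,
    starts: list[np.ndarray],
):
    """Minimize the objective over the free parameters at a fixed target."""
    names = kind.active_params
    t_idx = names.index(target)
    f_idx = [names.index(n) for n in free_names]

    def assemble(free_vec):
        full = np.empty(len(names))
        full[t_idx] = target_value
        full[f_idx] = free_vec
        return full

    if not free_names:
        curve = ct_curves_batch(kind, times, u, assemble(np.empty(0))[None, :])[0]
        r = (curve - y) / sigma
        return float(np.dot(r, r)), {}

    def residuals(free_vec):
        curve = ct_curves_batch(kind, times, u, assemble(free_vec)[None, :])[0]
        return (curve - y) / sigma

    best_f, best_x = np.inf, None
    for x0 in starts:
        sol = least_squares(
            residuals, np.clip(x0, lb, ub), bounds=(lb, ub), method="trf",
            xtol=1e-12, ftol=1e-12, gtol=1e-12,
        )
        fval = float(2 * sol.cost)
        if fval < best_f:
            best_f, best_x = fval, sol.x
    co = dict(zip(free_names, (float(v) for v in best_x)))
    return best_f, co


def _default_grid(th: float, lo: float, hi: float, n_points: int, span_decades: float):
    """Log-spaced grid over ``[th/10^s, th*10^s]`` clipped to the bounds."""
    if th > 0:
        gmin = max(th / 10**span_decades, lo if lo > 0 else th / 10**span_decades)
        gmax = min(th * 10**span_decades, hi)
        grid = np.geomspace(gmin, gmax, n_points)
    else:  # optimum at (or below) zero: fall back to a linear sweep
        grid = np.linspace(max(lo, 0.0), hi, n_points)
    return np.unique(np.concatenate([grid, [th]])) if lo <= th <= hi else grid


def _as_theta_dict(theta_hat, kind: ModelKind) -> tuple[dict[str, float], float | None, float | None]:
    if isinstance(theta_hat, FitResult):
        return dict(theta_hat.theta), theta_hat.objective, theta_hat.sigma
    return dict(theta_hat), None, None


def profile_likelihood(
    data: SampledSignal,
    vif: SampledSignal,
    kind: ModelKind,
    theta_hat,
    target: str,
    grid: np.ndarray | None = None,
    config: FitConfig | None = None,
    n_points: int = 41,
    span_decades: float = 1.0,
    n_restarts: int = 2,
) -> LikelihoodProfile:
    """Profile the objective along ``target`` around the fit optimum.

    ``theta_hat`` is a :class:`FitResult` (preferred) or a dict of active
    parameters.  At each grid value the remaining active parameters are
    re-optimized from the neighboring grid point's solution plus
    ``n_restarts`` random restarts.  The sweep starts at the grid point
    nearest the optimum and moves outward in both directions.
    """
    config = config or FitConfig()
    data.require_same_grid(vif)
    if target not in kind.active_params:
        raise ValueError(f"{target!r} is not an active parameter of {kind.value}")
    theta, obj_hat, sigma_hat = _as_theta_dict(theta_hat, kind)
    sigma = sigma_hat if sigma_hat is not None else config.sigma
    lo, hi = config.bounds[target]
    th = theta[target]
    if grid is None:
        grid = _default_grid(th, lo, hi, n_points, span_decades)
    else:
        grid = np.sort(np.asarray(grid, dtype=float))
    meta: dict = {"flatness_fraction": FLATNESS_FRACTION, "warnings": []}
    if not (grid[0] <= th <= grid[-1]):
        msg = (
            f"profile grid [{grid[0]:g}, {grid[-1]:g}] does not contain the "
            f"optimum {target}={th:g}"
        )
        warnings.warn(msg, stacklevel=2)
        meta["warnings"].append(msg)

    free_names = tuple(n for n in kind.active_params if n != target)
    lb = np.array([config.bounds[n][0] for n in free_names])
    ub = np.array([config.bounds[n][1] for n in free_names])
    times, u, y = vif.times, vif.values, data.values
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x9E37)))

    center = int(np.argmin(np.abs(grid - th)))
    pl = np.empty(grid.size)
    co: list[dict[str, float] | None] = [None] * grid.size
    x_hat = np.array([theta[n] for n in free_names])

    def random_starts(k):
        return [lb + (ub - lb) * rng.random(lb.size) for _ in range(k)]

    for direction in (+1, -1):
        warm = x_hat.copy()
        idx_range = range(center, grid.size) if direction > 0 else range(center - 1, -1, -1)
        for i in idx_range:
            starts = [warm] + random_starts(n_restarts) if free_names else []
            fval, co_i = _reoptimize(
                kind, times, u, y, sigma, target, float(grid[i]),
                free_names, lb, ub, starts,
            )
            pl[i], co[i] = fval, co_i
            if free_names:
                warm = np.array([co_i[n] for n in free_names])

    mle_hat = obj_hat if obj_hat is not None else float(np.min(pl))
    # re-optimization at the grid can only improve on the global fit
    mle_hat = min(mle_hat, float(np.min(pl)))
    return LikelihoodProfile(
        target=target,
        kind=kind,
        grid=grid,
        pl_values=pl,
        co_params=tuple(co),
        theta_hat=theta,
        mle_hat=mle_hat,
        sigma=sigma,
        meta=meta,
    )


def confidence_interval(profile: LikelihoodProfile, level: float) -> ConfidenceInterval:
    """Threshold crossing of the profile at ``MLE + Delta_level``.

    Crossings are located by linear interpolation between grid points,
    scanning outward from the grid point nearest the optimum; a side that
    never exceeds the threshold inside the profiled range is flagged open
    (the reported bound is then the grid edge).
    """
    thr = profile.mle_hat + chi2_threshold(level)
    g, pl = profile.grid, profile.pl_values
    center = int(np.argmin(np.abs(g - profile.target_hat)))

    def scan(direction: int):
        i = center
        while 0 <= i + direction < g.size:
            j = i + direction
            if pl[j] >= thr:
                p0, p1 = pl[i], pl[j]
                if p1 == p0:
                    return float(g[j]), True
                frac = (thr - p0) / (p1 - p0)
                return float(g[i] + frac * (g[j] - g[i])), True
            i = j
        return float(g[-1] if direction > 0 else g[0]), False

    upper, upper_finite = scan(+1)
    lower, lower_finite = scan(-1)
    return ConfidenceInterval(
        level=level,
        lower=lower,
        upper=upper,
        lower_finite=lower_finite,
        upper_finite=upper_finite,
    )


def classify(profile: LikelihoodProfile, level: float) -> IdentifiabilityVerdict:
    """Identifiability verdict at a confidence level.

    ``flat`` when the total variation of the profile is below
    ``FLATNESS_FRACTION`` of the chi-squared threshold; ``identifiable``
    when both interval ends are finite; ``practically_non_identifiable``
    otherwise.
    """
    delta = chi2_threshold(level)
    variation = float(np.max(profile.pl_values) - np.min(profile.pl_values))
    ci = confidence_interval(profile, level)
    open_sides = tuple(
        s for s, fin in (("lower", ci.lower_finite), ("upper", ci.upper_finite)) if not fin
    )
    if variation < FLATNESS_FRACTION * delta:
        status = "flat"
    elif ci.finite:
        status = "identifiable"
    else:
        status = "practically_non_identifiable"
    return IdentifiabilityVerdict(status=status, level=level, open_sides=open_sides)


def compensating_profiles(
    data: SampledSignal,
    vif: SampledSignal,
    kind: ModelKind,
    theta_hat,
    target: str,
    span: float = 0.5,
    n_points: int = 21,
    config: FitConfig | None = None,
    n_restarts: int = 0,
) -> CompensatingProfiles:
    """Trace re-optimized co-parameters while perturbing ``target`` by
    ``+/- span`` (fraction of its optimum) around the fit optimum.

    Re-optimization is a warm-started continuation from the optimum by
    default (``n_restarts=0``): the traces are a local sensitivity
    analysis, and random restarts could hop to distant quasi-degenerate
    solutions and destroy their interpretation.
    """
    config = config or FitConfig()
    theta, _, _ = _as_theta_dict(theta_hat, kind)
    th = theta[target]
    lo, hi = config.bounds[target]
    grid = np.clip(np.linspace(th * (1 - span), th * (1 + span), n_points), lo, hi)
    grid = np.unique(grid)
    profile = profile_likelihood(
        data, vif, kind, theta_hat, target, grid=grid, config=config,
        n_restarts=n_restarts,
    )
    free_names = tuple(n for n in kind.active_params if n != target)
    traces = {
        name: np.array([cp[name] for cp in profile.co_params]) for name in free_names
    }
    return CompensatingProfiles(
        target=target,
        kind=kind,
        target_values=profile.grid,
        traces=traces,
        theta_hat=theta,
    )
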