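"""Structural identifiability of the LTK model via differential algebra.

Eliminating the compartment states from the LTK system reduces it to a
single ODE in the observable :math:`y = C_t(t)` driven by the input
:math:`u = C_p(t)` and its running integral :math:`v = \\int_0^t u`:

.. math::

    \\dot y + a_1 y + a_2 u + a_3 \\dot u + a_4 v = 0.

The coefficient map used in the DCE identifiability literature is

.. math::

    a_1 = K^{trans}/v_e^2, \\quad
    a_2 = -K^{trans} - K^{trans}/v_e^2 - \\lambda, \\quad
    a_3 = -v_p, \\quad
    a_4 = -(K^{trans}/v_e^2)\\,\\lambda,

and it inverts in closed form (:func:`params_from_coefficients`), which is
the structural-identifiability result: the coefficient vector, and hence
the noise-free input/output behaviour, determines the four kinetic
parameters uniquely.

A caveat for users who wish to check the observable ODE against simulated
curves: that literature map descends from a nonstandard writing of the
EES dynamics and drops :math:`v_p` from the :math:`a_2` cross-term.  Carrying
the elimination through the same dynamics that generate the convolution
solutions gives

.. math::

    a_1 = K_{ep}, \\quad
    a_2 = -(K^{trans} + \\lambda + K_{ep} v_p), \\quad
    a_3 = -v_p, \\quad
    a_4 = -K_{ep}\\lambda,

exposed as :func:`model_coefficients_from_params` (with its own inverse).
Both maps are closed-form invertible, so the identifiability conclusion is
the same; only the model-consistent map annihilates simulated LTK curves
in :func:`observable_residual`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .signals import SampledSignal
from .transport import PKParams

__all__ = [
    "ObservableCoefficients",
    "coefficients_from_params",
    "params_from_coefficients",
    "model_coefficients_from_params",
    "params_from_model_coefficients",
    "observable_residual",
]


@dataclass(frozen=True)
class ObservableCoefficients:
    """Coefficients ``a1..a4`` of the observable ODE (mixed units)."""

    a1: float
    a2: float
    a3: float
    a4: float

    def __post_init__(self) -> None:
        if not all(np.isfinite(v) for v in asdict(self).values()):
            raise ValueError("coefficients must be finite")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "ObservableCoefficients":
        return cls(**json.loads(text))


def coefficients_from_params(p: PKParams) -> ObservableCoefficients:
    """Map kinetic parameters to observable-ODE coefficients (literature map).

    For parameters within their invariants and ``ktrans > 0``: ``a1 > 0``,
    ``a2 < 0``, ``a3 <= 0`` and ``a4 <= 0`` with ``a4 = 0`` iff ``lam = 0``.
    """
    if p.ve <= 0:
        raise ValueError("coefficient map requires ve > 0")
    a1 = p.ktrans / p.ve**2
    a2 = -p.ktrans - p.ktrans / p.ve**2 - p.lam
    a3 = -p.vp
    a4 = -(p.ktrans / p.ve**2) * p.lam
    return ObservableCoefficients(a1, a2, a3, a4)


def params_from_coefficients(a: ObservableCoefficients) -> PKParams:
    """Closed-form inverse of :func:`coefficients_from_params`.

    Requires ``a1 > 0`` and the feasibility condition
    ``a2 <= a4/a1 - a1`` (equivalently ``ktrans >= 0`` and a real ``ve``);
    both hold automatically for coefficients produced from valid kinetic
    parameters.
    """
    if a.a1 <= 0:
        raise ValueError(f"infeasible coefficients: a1 = {a.a1:g} must be > 0")
    ktrans = a.a4 / a.a1 - a.a1 - a.a2
    if ktrans < 0:
        raise ValueError(
            "infeasible coefficients: a2 <= a4/a1 - a1 violated "
            f"(a2 = {a.a2:g}, a4/a1 - a1 = {a.a4 / a.a1 - a.a1:g})"
        )
    ve_sq = a.a4 / a.a1**2 - 1.0 - a.a2 / a.a1
    # ve_sq == ktrans/a1 algebraically; guard tiny negative round-off
    if ve_sq < -1e-15:
        raise ValueError("infeasible coefficients: negative ve^2")
    ve = float(np.sqrt(max(ve_sq, 0.0)))
    vp = -a.a3
    lam = -a.a4 / a.a1
    return PKParams(ktrans=ktrans, ve=ve, vp=vp, lam=lam)


def model_coefficients_from_params(p: PKParams) -> ObservableCoefficients:
    """Coefficient map consistent with the convolution forward solutions."""
    if p.ve <= 0:
        raise ValueError("coefficient map requires ve > 0")
    kep = p.kep
    return ObservableCoefficients(
        a1=kep,
        a2=-(p.ktrans + p.lam + kep * p.vp),
        a3=-p.vp,
        a4=-kep * p.lam,
    )


def params_from_model_coefficients(a: ObservableCoefficients) -> PKParams:
    """Closed-form inverse of :func:`model_coefficients_from_params`."""
    if a.a1 <= 0:
        raise ValueError(f"infeasible coefficients: a1 = {a.a1:g} must be > 0")
    vp = -a.a3
    lam = -a.a4 / a.a1
    ktrans = -a.a2 - lam - a.a1 * vp
    if ktrans < 0:
        raise ValueError("infeasible coefficients: implied ktrans < 0")
    ve = ktrans / a.a1
    return PKParams(ktrans=ktrans, ve=ve, vp=vp, lam=lam)


def observable_residual(
    y: SampledSignal,
    u: SampledSignal,
    a: ObservableCoefficients,
) -> float:
    """Discrete L2 norm of the observable-ODE residual.

    Derivatives are taken by central differences (one-sided at the ends)
    and ``v`` by cumulative trapezoid, so the result is discretization
    limited: for a tissue curve simulated from matching parameters it
    decays towards zero under grid refinement but is not exactly zero.
    """
    y.require_same_grid(u)
    t = y.times
    if len(t) < 3:
        raise ValueError("need at least 3 samples for central differences")
    ydot = np.gradient(y.values, t)
    udot = np.gradient(u.values, t)
    v = cumulative_trapezoid(u.values, t, initial=0.0)
    r = ydot + a.a1 * y.values + a.a2 * u.values + a.a3 * udot + a.a4 * v
    return float(np.sqrt(np.trapezoid(r**2, t)))
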