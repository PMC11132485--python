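"""Nested contrast-transport models for DCE-MRI tissue curves.

Four nested compartment models predict the tissue contrast-agent
concentration :math:`C_t(t)` from the plasma input :math:`C_p(t)`:

* Patlak (PM):   :math:`C_t = v_p C_p + K^{trans} \\int_0^t C_p`
* Tofts–Kety (TK): :math:`C_t = K^{trans} \\int_0^t C_p(\\tau)
  e^{-K_{ep}(t-\\tau)} d\\tau`, with reflux rate
  :math:`K_{ep} = K^{trans}/v_e`
* extended TK (eTK): TK plus the vascular term :math:`v_p C_p`
* Leaky TK (LTK): eTK plus a unidirectional leakage compartment
  :math:`C_L` with :math:`\\dot C_L = \\lambda C_p`, adding
  :math:`\\lambda \\int_0^t C_p`

All solutions are evaluated on the sampling grid of the input VIF.  The
default convolution treats the VIF as piecewise linear between samples and
integrates the exponential kernel exactly on each panel, which stays
accurate even when :math:`K_{ep}\\,\\Delta t \\gg 1`; a plain trapezoid
quadrature of the sampled integrand is available as ``method="trapezoid"``.
An independent ODE-integration oracle (:func:`ct_ode_oracle`) solves the
compartment equations with the same piecewise-linear input.
"""

from __future__ import annotations

import enum
import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid, solve_ivp

from .signals import SampledSignal

__all__ = [
    "PKParams",
    "ModelKind",
    "ct_patlak",
    "ct_tk",
    "ct_etk",
    "ct_ltk",
    "ct_model",
    "ct_ode_oracle",
    "exp_conv",
]


@dataclass(frozen=True)
class PKParams:
    """Kinetic parameter vector of the nested model family.

    Attributes
    ----------
    ktrans : float
        Forward volume-transfer constant plasma -> EES (1/s).
    ve : float
        Fractional extravascular extracellular space volume (dimensionless).
    vp : float
        Fractional plasma volume (dimensionless).
    lam : float
        Unidirectional plasma -> leakage-compartment transfer rate (1/s).

    Note that ``ve + vp <= 1`` is deliberately not enforced: the standard
    synthetic parameter sets include rows that violate it.
    """

    ktrans: float
    ve: float = 1.0
    vp: float = 0.0
    lam: float = 0.0

    def __post_init__(self) -> None:
        vals = asdict(self)
        if not all(np.isfinite(v) for v in vals.values()):
            raise ValueError("kinetic parameters must be finite")
        if self.ktrans < 0:
            raise ValueError("ktrans must be >= 0")
        if not (0.0 <= self.ve <= 1.0):
            raise ValueError("ve must lie in [0, 1]")
        if not (0.0 <= self.vp <= 1.0):
            raise ValueError("vp must lie in [0, 1]")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")

    @property
    def kep(self) -> float:
        """Reflux rate constant ``ktrans / ve`` (1/s)."""
        if self.ve <= 0:
            raise ZeroDivisionError("kep undefined for ve = 0")
        return self.ktrans / self.ve

    def replace(self, **kwargs) -> "PKParams":
        d = asdict(self)
        d.update(kwargs)
        return PKParams(**d)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "PKParams":
        return cls(**json.loads(text))


class ModelKind(enum.Enum):
    """Model family member, with its active-parameter subset."""

    PM = "PM"
    TK = "TK"
    ETK = "eTK"
    LTK = "LTK"

    @property
    def active_params(self) -> tuple[str, ...]:
        return {
            ModelKind.PM: ("ktrans", "vp"),
            ModelKind.TK: ("ktrans", "ve"),
            ModelKind.ETK: ("ktrans", "ve", "vp"),
            ModelKind.LTK: ("ktrans", "ve", "vp", "lam"),
        }[self]

    @classmethod
    def parse(cls, name: str) -> "ModelKind":
        for kind in cls:
            if kind.value.lower() == str(name).lower():
                return kind
        raise ValueError(f"unknown model kind {name!r}; expected PM/TK/eTK/LTK")


# -- quadrature kernels -----------------------------------------------------


def _cumtrapz(times: np.ndarray, u: np.ndarray) -> np.ndarray:
    return cumulative_trapezoid(u, times, initial=0.0)


def exp_conv(times: np.ndarray, u: np.ndarray, kep, method: str = "exact") -> np.ndarray:
    """Causal exponential-kernel convolution
    :math:`I(t_i) = \\int_0^{t_i} u(\\tau) e^{-k_{ep}(t_i-\\tau)} d\\tau`.

    ``kep`` may be a scalar or a 1-D array (batched evaluation; output shape
    ``(len(kep), len(times))``).  ``method="exact"`` integrates the kernel
    exactly against a piecewise-linear ``u`` via the stable recursion
    ``I_i = e^{-k h} I_{i-1} + panel``; ``method="trapezoid"`` applies the
    trapezoid rule to the sampled integrand.
    """
    kep_arr = np.asarray(kep, dtype=float)
    scalar = kep_arr.ndim == 0
    k = np.atleast_1d(kep_arr)[:, None]  # (K, 1)
    if np.any(k < 0):
        raise ValueError("kep must be >= 0")
    n = len(times)
    h = np.diff(times)[None, :]  # (1, N-1)
    x = k * h  # (K, N-1)
    e = np.exp(-x)
    a = u[:-1][None, :]
    b = u[1:][None, :]
    if method == "exact":
        # panel = [a (1 - e^-x) + (b - a) (1 - (1 - e^-x)/x)] / k, k > 0
        one_m_e = -np.expm1(-x)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = 1.0 - one_m_e / x  # -> x/2 - x^2/6 + ... for small x
            panel = (a * one_m_e + (b - a) * r) / k
        small = x < 1e-4
        if np.any(small):
            # series expansion of the exact panel in powers of x = kep*h
            # (also covers kep == 0, where it reduces to the trapezoid rule)
            panel_small = h * (
                a * (1 - x / 2 + x**2 / 6) + (b - a) * (0.5 - x / 6 + x**2 / 24)
            )
            panel = np.where(small, panel_small, panel)
    elif method == "trapezoid":
        panel = 0.5 * h * (b + a * e)
    else:
        raise ValueError(f"unknown quadrature method {method!r}")
    out = np.zeros((k.shape[0], n))
    for i in range(1, n):
        out[:, i] = out[:, i - 1] * e[:, i - 1] + panel[:, i - 1]
    return out[0] if scalar else out


# -- forward solutions ------------------------------------------------------


def ct_patlak(vif: SampledSignal, p: PKParams) -> SampledSignal:
    """Patlak tissue curve ``vp*Cp + ktrans * cumint(Cp)``."""
    values = p.vp * vif.values + p.ktrans * _cumtrapz(vif.times, vif.values)
    return vif.with_values(values, label="ct_PM")


def ct_tk(vif: SampledSignal, p: PKParams, method: str = "exact") -> SampledSignal:
    """Tofts–Kety tissue curve (exponential-kernel convolution)."""
    if p.ve <= 0:
        raise ValueError("TK model requires ve > 0 (kep singular at ve = 0)")
    values = p.ktrans * exp_conv(vif.times, vif.values, p.kep, method=method)
    return vif.with_values(values, label="ct_TK")


def ct_etk(vif: SampledSignal, p: PKParams, method: str = "exact") -> SampledSignal:
    """Extended Tofts–Kety tissue curve (TK plus the vascular term)."""
    tk = ct_tk(vif, p, method=method)
    return vif.with_values(p.vp * vif.values + tk.values, label="ct_eTK")


def ct_ltk(vif: SampledSignal, p: PKParams, method: str = "exact") -> SampledSignal:
    """Leaky Tofts–Kety tissue curve (eTK plus the leakage integral)."""
    etk = ct_etk(vif, p, method=method)
    values = etk.values + p.lam * _cumtrapz(vif.times, vif.values)
    return vif.with_values(values, label="ct_LTK")


_FORWARD = {
    ModelKind.TK: ct_tk,
    ModelKind.ETK: ct_etk,
    ModelKind.LTK: ct_ltk,
}


def ct_model(kind: ModelKind, vif: SampledSignal, p: PKParams, method: str = "exact") -> SampledSignal:
    """Dispatch to the forward solution for ``kind``."""
    if kind is ModelKind.PM:
        return ct_patlak(vif, p)
    return _FORWARD[kind](vif, p, method)


def ct_curves_batch(
    kind: ModelKind,
    times: np.ndarray,
    u: np.ndarray,
    theta: np.ndarray,
) -> np.ndarray:
    """Vectorized forward curves for a batch of active-parameter rows.

    ``theta`` has shape ``(S, len(kind.active_params))`` with columns in
    ``kind.active_params`` order; returns an ``(S, N)`` array of tissue
    curves.  Used by the swarm optimizer.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    cols = dict(zip(kind.active_params, theta.T))
    ktrans = cols.get("ktrans", np.zeros(theta.shape[0]))
    ve = cols.get("ve", np.ones(theta.shape[0]))
    vp = cols.get("vp", np.zeros(theta.shape[0]))
    lam = cols.get("lam", np.zeros(theta.shape[0]))
    v_int = _cumtrapz(times, u)[None, :]
    if kind is ModelKind.PM:
        return vp[:, None] * u[None, :] + ktrans[:, None] * v_int
    ve_safe = np.maximum(ve, 1e-300)
    conv = exp_conv(times, u, ktrans / ve_safe)
    out = ktrans[:, None] * conv
    if kind in (ModelKind.ETK, ModelKind.LTK):
        out = out + vp[:, None] * u[None, :]
    if kind is ModelKind.LTK:
        out = out + lam[:, None] * v_int
    return out


# -- ODE oracle -------------------------------------------------------------


def ct_ode_oracle(
    kind: ModelKind,
    vif: SampledSignal,
    p: PKParams,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> SampledSignal:
    """Tissue curve by direct numerical integration of the compartment ODEs.

    States start at zero (no contrast pre-bolus); the VIF is linearly
    interpolated between its samples.  Serves as an independent cross-check
    of the convolution solutions.
    """
    times, u = vif.times, vif.values

    def u_of_t(t):
        return np.interp(t, times, u)

    if kind is ModelKind.PM:
        # single state: the uptake integral
        def rhs(t, y):
            return [u_of_t(t)]

        sol = _solve(rhs, times, 1, rtol, atol)
        values = p.vp * u + p.ktrans * sol[0]
    elif kind is ModelKind.TK:
        kep = p.kep

        def rhs(t, y):
            return [kep * (u_of_t(t) - y[0])]

        sol = _solve(rhs, times, 1, rtol, atol)
        values = p.ve * sol[0]
    elif kind is ModelKind.ETK:
        kep = p.kep

        def rhs(t, y):
            return [kep * (u_of_t(t) - y[0])]

        sol = _solve(rhs, times, 1, rtol, atol)
        values = p.vp * u + p.ve * sol[0]
    elif kind is ModelKind.LTK:
        kep = p.kep

        def rhs(t, y):
            ut = u_of_t(t)
            return [kep * (ut - y[0]), p.lam * ut]

        sol = _solve(rhs, times, 2, rtol, atol)
        values = p.vp * u + p.ve * sol[0] + sol[1]
    else:  # pragma: no cover
        raise ValueError(kind)
    return vif.with_values(values, label=f"ct_{kind.value}_ode")


def _solve(rhs, times, n_states, rtol, atol):
    res = solve_ivp(
        rhs,
        (times[0], times[-1]),
        np.zeros(n_states),
        t_eval=times,
        method="LSODA",
        rtol=rtol,
        atol=atol,
        max_step=float(np.min(np.diff(times))) if len(times) > 1 else np.inf,
    )
    if not res.success:
        raise RuntimeError(f"ODE integration failed: {res.message}")
    return res.y
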