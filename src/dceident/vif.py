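"""Vascular input function (VIF) models and perturbations.

The population VIF of Parker et al. is a mixture of two Gaussians plus an
exponential washout gated by a sigmoid,

.. math::

    C_p(t) = \\sum_{n=1}^{2} \\frac{A_n}{\\sigma_n\\sqrt{2\\pi}}
             e^{-(t-T_n)^2 / 2\\sigma_n^2}
           + \\frac{\\alpha e^{-\\beta t}}{1 + e^{-l(t-\\tau)}},

with amplitudes :math:`A_n` (mM s), centers :math:`T_n` (s), widths
:math:`\\sigma_n` (s), exponential amplitude :math:`\\alpha` (mM) and decay
:math:`\\beta` (1/s), sigmoid width :math:`l` (1/s) and center
:math:`\\tau` (s).  The default constants are the population values
expressed in seconds/mM units.

This module also provides the graded VIF-noise injection used in the
practical-identifiability noise study: independent standard-normal noise
scaled per element to a fixed fraction of the noise-free VIF.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .signals import SampledSignal

__all__ = [
    "ParkerVIFParams",
    "parker_vif",
    "parker_vif_signal",
    "default_time_grid",
    "load_vif_csv",
    "add_vif_noise",
]

#: Brain-acquisition defaults: 3 zero pre-contrast baseline frames followed
#: by 32 dynamic frames at 6.03 s temporal resolution.
DEFAULT_DT = 6.03
DEFAULT_N_BASELINE = 3
DEFAULT_N_DYNAMIC = 32


@dataclass(frozen=True)
class ParkerVIFParams:
    """Constants of the population VIF (seconds / mM units)."""

    A1: float = 48.54  # mM s
    A2: float = 18.64  # mM s
    T1: float = 10.2276  # s
    T2: float = 21.9  # s
    sigma1: float = 3.378  # s
    sigma2: float = 7.92  # s
    alpha: float = 1.05  # mM
    beta: float = 0.0028  # 1/s
    l: float = 0.6346  # 1/s
    tau: float = 28.98  # s

    def __post_init__(self) -> None:
        if not all(np.isfinite(v) for v in asdict(self).values()):
            raise ValueError("VIF parameters must be finite")
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("Gaussian widths sigma1, sigma2 must be > 0")
        for name in ("A1", "A2", "alpha", "beta", "l"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "ParkerVIFParams":
        return cls(**json.loads(text))


def parker_vif(t, params: ParkerVIFParams | None = None) -> np.ndarray:
    """Evaluate the population VIF at time(s) ``t`` (seconds).

    Returns concentration in mM; vectorizes over ``t``.  Negative or
    non-finite times are rejected.
    """
    p = params or ParkerVIFParams()
    t_arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t_arr)):
        raise ValueError("t must be finite")
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    g1 = p.A1 / (p.sigma1 * np.sqrt(2 * np.pi)) * np.exp(
        -((t_arr - p.T1) ** 2) / (2 * p.sigma1**2)
    )
    g2 = p.A2 / (p.sigma2 * np.sqrt(2 * np.pi)) * np.exp(
        -((t_arr - p.T2) ** 2) / (2 * p.sigma2**2)
    )
    washout = p.alpha * np.exp(-p.beta * t_arr) / (1.0 + np.exp(-p.l * (t_arr - p.tau)))
    out = g1 + g2 + washout
    return out if out.ndim else float(out)


def default_time_grid(
    n_baseline: int = DEFAULT_N_BASELINE,
    n_dynamic: int = DEFAULT_N_DYNAMIC,
    dt: float = DEFAULT_DT,
) -> np.ndarray:
    """Acquisition time grid: ``n_baseline`` pre-contrast frames followed by
    ``n_dynamic`` post-contrast frames at spacing ``dt`` seconds."""
    return np.arange(n_baseline + n_dynamic) * float(dt)


def parker_vif_signal(
    times: np.ndarray | None = None,
    params: ParkerVIFParams | None = None,
    t_arrival: float | None = None,
) -> SampledSignal:
    """Population VIF sampled on a time grid as a :class:`SampledSignal`.

    Baseline frames before bolus arrival are zero; the VIF clock starts at
    ``t_arrival`` (default: the first post-baseline frame of the default
    grid).
    """
    if times is None:
        times = default_time_grid()
        if t_arrival is None:
            t_arrival = DEFAULT_N_BASELINE * DEFAULT_DT
    times = np.asarray(times, dtype=float)
    if t_arrival is None:
        t_arrival = 0.0
    values = np.zeros_like(times)
    post = times >= t_arrival
    values[post] = parker_vif(times[post] - t_arrival, params)
    return SampledSignal(times, values, label="parker_vif")


def load_vif_csv(path) -> SampledSignal:
    """Load a measured VIF from a two-column delimited file (s, mM)."""
    return SampledSignal.from_csv(path, label=str(path))


def add_vif_noise(
    vif: SampledSignal,
    level: float,
    seed: int,
    clip_negative: bool = False,
) -> SampledSignal:
    """Add graded multiplicative-amplitude Gaussian noise to a VIF.

    Each element becomes ``vif(t_i) + level * vif(t_i) * z_i`` with
    ``z_i ~ N(0, 1)`` independent: the noise-only signal is standard normal
    with per-element amplitude equal to a fixed fraction (``level``) of the
    noise-free VIF.  Deterministic for a fixed ``seed``.  Values are not
    clipped at zero unless ``clip_negative`` is set.
    """
    if level < 0:
        raise ValueError("noise level must be >= 0")
    if level == 0:
        return vif
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(len(vif))
    values = vif.values * (1.0 + level * z)
    if clip_negative:
        values = np.maximum(values, 0.0)
    return SampledSignal(
        vif.times, values, label=f"{vif.label}+noise{level:g}"
    )
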