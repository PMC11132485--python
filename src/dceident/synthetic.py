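"""Synthetic study scenarios: enhancement curves, noise, and smoothing.

All experiment inputs are generated here, so no MRI download is required.
Three canonical contrast-enhancement morphologies are simulated by forward
runs of the LTK model:

* Type I  (persistent): progressive signal increase,
* Type II (plateau): early peak followed by near-constant enhancement,
* Type III (wash-out): sharp uptake followed by decline,

using the standard parameter rows for the fully artificial (AA) case and
the real-VIF-like (RA) case.  Three study cases are emulated:

* ``AA``      - analytic population VIF, noise-free tissue curve;
* ``RA_like`` - a noisy VIF standing in for a vessel-ROI measurement
  (VIF noise is the operative difference between the AA and RA cases),
  with a noise-free tissue curve;
* ``RR_like`` - noisy VIF and additive Gaussian noise on the tissue curve,
  a stand-in for fully measured data.

In the noisy-VIF cases the tissue curve is always simulated with the
*true* (noise-free) population VIF: the tissue physically responds to the
true plasma input, and measurement noise corrupts only the VIF estimate
handed to the fitter.  This input-measurement mismatch is what degrades
practical identifiability; simulating the curve with the same noisy VIF
that is used for fitting would leave the inverse problem exactly
consistent and identifiability unimpaired.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .signals import SampledSignal
from .transport import PKParams, ct_ltk
from .vif import add_vif_noise, default_time_grid, parker_vif_signal

__all__ = [
    "TABLE_AA",
    "TABLE_RA",
    "ScenarioSpec",
    "generate_scenario",
    "add_ca_noise",
    "smooth_moving_average",
]

#: LTK parameter rows generating the three curve types, fully artificial case.
TABLE_AA: dict[str, PKParams] = {
    "I": PKParams(ktrans=0.0025, ve=0.9, vp=0.05, lam=0.01),
    "II": PKParams(ktrans=0.009, ve=0.5, vp=0.1, lam=0.001),
    "III": PKParams(ktrans=0.03, ve=0.5, vp=0.1, lam=0.001),
}

#: Parameter rows for the real-VIF case.  The Type III row sits at the
#: ``ve`` search bound (ve = 1e-3, a near-singular reflux rate) and is kept
#: deliberately: it stresses the fitter.
TABLE_RA: dict[str, PKParams] = {
    "I": PKParams(ktrans=0.0025, ve=0.9, vp=0.05, lam=0.001),
    "II": PKParams(ktrans=0.009, ve=0.5, vp=0.1, lam=0.001),
    "III": PKParams(ktrans=0.008, ve=0.001, vp=0.9, lam=0.0),
}

_CASES = ("AA", "RA_like", "RR_like")


@dataclass(frozen=True)
class ScenarioSpec:
    """Selects one synthetic study condition.

    ``AA`` uses a noise-free VIF and noise-free curve; ``RA_like`` a noisy
    VIF (default 10% amplitude) with a noise-free curve; ``RR_like``
    additionally perturbs the tissue curve (default SNR 20).
    """

    curve_type: str = "I"
    case: str = "AA"
    seed: int = 0
    vif_noise_level: float = 0.10
    ca_snr: float = 20.0
    n_baseline: int = 3
    n_dynamic: int = 32
    dt: float = 6.03

    def __post_init__(self) -> None:
        if self.curve_type not in ("I", "II", "III"):
            raise ValueError("curve_type must be one of I, II, III")
        if self.case not in _CASES:
            raise ValueError(f"case must be one of {_CASES}")
        if self.vif_noise_level < 0 or self.ca_snr <= 0:
            raise ValueError("vif_noise_level >= 0 and ca_snr > 0 required")

    @property
    def truth(self) -> PKParams:
        # RR_like surrogates the same tissue as the AA baseline through the
        # measurement-degradation chain, so it shares the AA parameter rows;
        # RA_like has its own dedicated rows.
        table = TABLE_RA if self.case == "RA_like" else TABLE_AA
        return table[self.curve_type]

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "ScenarioSpec":
        return cls(**json.loads(text))


def generate_scenario(spec: ScenarioSpec) -> tuple[SampledSignal, SampledSignal, PKParams]:
    """Materialize ``(vif, ca, truth)`` for a scenario.

    The returned VIF is the one a fitter should use (the "measured" input
    function: noisy for RA/RR-like cases); the tissue curve is always the
    forward simulation driven by the true noise-free VIF, plus measurement
    noise for RR_like.  Deterministic for a fixed ``spec.seed``; the VIF-
    and CA-noise streams are derived independently from it.
    """
    times = default_time_grid(spec.n_baseline, spec.n_dynamic, spec.dt)
    clean_vif = parker_vif_signal(times, t_arrival=spec.n_baseline * spec.dt)
    truth = spec.truth
    vif_seed, ca_seed = (
        int(s) for s in np.random.SeedSequence(spec.seed).generate_state(2)
    )
    if spec.case == "AA":
        vif = clean_vif
    else:
        vif = add_vif_noise(clean_vif, spec.vif_noise_level, seed=vif_seed)
    ca = ct_ltk(clean_vif, truth)
    if spec.case == "RR_like":
        ca = add_ca_noise(ca, spec.ca_snr, seed=ca_seed)
    label = f"{spec.case} Type {spec.curve_type}"
    return vif, ca.with_values(ca.values, label=label), truth


def add_ca_noise(ca: SampledSignal, snr: float, seed: int) -> SampledSignal:
    """Add i.i.d. Gaussian noise with SD ``peak(ca)/snr`` to a tissue curve."""
    if snr <= 0:
        raise ValueError("snr must be > 0")
    sd = float(np.max(ca.values)) / snr
    rng = np.random.default_rng(seed)
    values = ca.values + sd * rng.standard_normal(len(ca))
    return SampledSignal(ca.times, values, label=f"{ca.label}+snr{snr:g}")


def moving_average_window(gamma: float, n: int) -> int:
    """Window size (samples) used by :func:`smooth_moving_average`:
    ``max(3, nearest odd integer to gamma*n)`` for ``gamma > 0``, else 1."""
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    if gamma == 0.0:
        return 1
    w = int(2 * round((gamma * n - 1) / 2) + 1)
    return max(3, w)


def smooth_moving_average(signal: SampledSignal, gamma: float) -> SampledSignal:
    """Centered moving average with window scaled by ``gamma`` in [0, 1].

    The window is ``max(3, nearest odd integer to gamma*N)`` samples for
    ``gamma > 0`` and 1 (identity) for ``gamma = 0``.  Near the ends the
    window shrinks symmetrically so the average stays centered.
    """
    n = len(signal)
    w = moving_average_window(gamma, n)
    if w == 1:
        return signal
    half = w // 2
    vals = signal.values
    out = np.empty(n)
    for i in range(n):
        k = min(half, i, n - 1 - i)
        out[i] = vals[i - k : i + k + 1].mean()
    return SampledSignal(signal.times, out, label=f"{signal.label}+ma{gamma:g}")
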