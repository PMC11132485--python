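"""Time-stamped concentration series.

:class:`SampledSignal` is the universal exchange type of the package: it
carries a vascular input function (VIF) or a tissue contrast-agent curve as
a pair of arrays (time in seconds, concentration in mM) plus a free-text
label.  Signals are immutable; operations return new instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SampledSignal"]


@dataclass(frozen=True)
class SampledSignal:
    """A concentration time series sampled on a strictly increasing grid.

    Parameters
    ----------
    times : array-like
        Sample times in seconds, strictly increasing, ``times[0] >= 0``.
    values : array-like
        Concentrations in mM, finite, same length as ``times``.
    label : str, optional
        Free-text description (e.g. ``"parker_vif"`` or ``"AA Type I"``).
    """

    times: np.ndarray
    values: np.ndarray
    label: str = ""
    _skip_validation: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if self._skip_validation:
            return
        if times.ndim != 1 or values.ndim != 1:
            raise ValueError("times and values must be one-dimensional")
        if times.shape != values.shape:
            raise ValueError(
                f"times (n={times.size}) and values (n={values.size}) "
                "must have the same length"
            )
        if times.size == 0:
            raise ValueError("signal must contain at least one sample")
        if times[0] < 0:
            raise ValueError("times must start at or after t=0")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(times)) or not np.all(np.isfinite(values)):
            raise ValueError("times and values must be finite (no NaN/Inf)")

    def __len__(self) -> int:
        return int(self.times.size)

    def with_values(self, values: np.ndarray, label: str | None = None) -> "SampledSignal":
        """Return a new signal on the same grid with different values."""
        return SampledSignal(self.times, values, self.label if label is None else label)

    def same_grid(self, other: "SampledSignal", rtol: float = 1e-12) -> bool:
        """True if ``other`` is sampled on (numerically) the same time grid."""
        return self.times.shape == other.times.shape and np.allclose(
            self.times, other.times, rtol=rtol, atol=1e-12
        )

    def require_same_grid(self, other: "SampledSignal") -> None:
        if not self.same_grid(other):
            raise ValueError(
                f"signals {self.label!r} and {other.label!r} are not sampled "
                "on the same time grid"
            )

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path) -> None:
        """Write as a two-column CSV with header ``time_s, conc_mM``."""
        pd.DataFrame({"time_s": self.times, "conc_mM": self.values}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, label: str = "") -> "SampledSignal":
        """Load a two-column delimited file (header optional).

        The first column is taken as time in seconds, the second as
        concentration in mM.  Raises :class:`ValueError` on parse failure or
        non-monotone times.
        """
        try:
            df = pd.read_csv(path, sep=None, engine="python", comment="#")
        except Exception as exc:  # pragma: no cover - pandas message varies
            raise ValueError(f"could not parse {path!s}: {exc}") from exc
        # a header-less file parses with the first data row as column names;
        # detect that by trying to coerce the column names to numbers
        try:
            first = [float(c) for c in df.columns[:2]]
            df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#")
            _ = first
        except (TypeError, ValueError):
            pass
        if df.shape[1] < 2:
            raise ValueError(f"{path!s}: expected two columns (time_s, conc_mM)")
        times = pd.to_numeric(df.iloc[:, 0], errors="raise").to_numpy(float)
        values = pd.to_numeric(df.iloc[:, 1], errors="raise").to_numpy(float)
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError(f"{path!s}: time column is not strictly increasing")
        return cls(times, values, label=label or str(path))
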