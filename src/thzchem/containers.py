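"""Shared in-memory containers for THz time-domain spectroscopy data.

Conventions used throughout the package:

* delays in picoseconds, frequencies in THz;
* field amplitudes in arbitrary (but consistent) units;
* the Fourier kernel is ``exp(-i 2 pi f t)`` (numpy ``rfft``), so a pure
  time delay ``dt`` multiplies each bin by ``exp(-i 2 pi f dt)``;
* absorption coefficients in cm^-1 (intensity attenuation);
* pellet thickness declared in mm by default (``SampleGeometry``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "TimeDomainTrace",
    "FrequencySpectrum",
    "TransferFunction",
    "OpticalProperties",
    "SampleGeometry",
    "SpectraMatrix",
]

#: relative tolerance for "uniformly spaced" delay grids
_GRID_RTOL = 1e-9

_LENGTH_TO_M = {"mm": 1e-3, "um": 1e-6, "m": 1.0, "cm": 1e-2}


def _as_1d_float(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be 1-D, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class TimeDomainTrace:
    """A sampled THz field: delay axis (ps) and field amplitude (a.u.)."""

    delays: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "delays", _as_1d_float(self.delays, "delays"))
        object.__setattr__(
            self, "amplitudes", _as_1d_float(self.amplitudes, "amplitudes")
        )
        if self.delays.size < 64:
            raise ValueError(f"trace needs >=64 points, got {self.delays.size}")
        if self.delays.size != self.amplitudes.size:
            raise ValueError("delays and amplitudes differ in length")
        steps = np.diff(self.delays)
        dt = steps[0]
        if dt <= 0 or not np.allclose(steps, dt, rtol=_GRID_RTOL, atol=0.0):
            raise ValueError("delay grid must be uniform and increasing")

    @property
    def time_step(self) -> float:
        """Sampling interval in ps."""
        return float(self.delays[1] - self.delays[0])

    @property
    def n_points(self) -> int:
        return int(self.delays.size)

    def same_grid(self, other: "TimeDomainTrace") -> bool:
        return self.delays.size == other.delays.size and np.allclose(
            self.delays, other.delays, rtol=_GRID_RTOL, atol=0.0
        )


@dataclass(frozen=True)
class FrequencySpectrum:
    """One-sided complex spectrum on a strictly increasing grid in THz."""

    frequencies: np.ndarray
    complex_amplitudes: np.ndarray

    def __post_init__(self) -> None:
        f = _as_1d_float(self.frequencies, "frequencies")
        a = np.asarray(self.complex_amplitudes, dtype=complex)
        if a.ndim != 1 or a.size != f.size:
            raise ValueError("complex_amplitudes must match frequencies")
        if f.size and (np.any(np.diff(f) <= 0) or f[0] < 0):
            raise ValueError("frequencies must be strictly increasing and >= 0")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "complex_amplitudes", a)

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.complex_amplitudes)


@dataclass(frozen=True)
class TransferFunction:
    """Amplitude ratio rho(f) and unwrapped phase lag phi(f) of sample vs
    reference, restricted to the usable band.

    ``phi`` is the *positive* phase delay accumulated in the sample
    (``-arg(E_sam/E_ref)`` after unwrapping), so an optically thicker
    sample has larger phi.
    """

    frequencies: np.ndarray
    rho: np.ndarray
    phi: np.ndarray

    def __post_init__(self) -> None:
        f = _as_1d_float(self.frequencies, "frequencies")
        rho = _as_1d_float(self.rho, "rho")
        phi = _as_1d_float(self.phi, "phi")
        if not (f.size == rho.size == phi.size):
            raise ValueError("frequencies, rho, phi must share length")
        if np.any(rho < 0):
            raise ValueError("rho must be >= 0")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "rho", rho)
        object.__setattr__(self, "phi", phi)


@dataclass(frozen=True)
class OpticalProperties:
    """Per-frequency optical constants of one sample.

    ``n`` dimensionless refractive index, ``k`` dimensionless extinction
    coefficient (field convention, ``k = alpha*c/(2*omega)`` with alpha in
    1/m), ``alpha`` intensity absorption coefficient in cm^-1.
    """

    frequencies: np.ndarray
    n: np.ndarray
    k: np.ndarray
    alpha: np.ndarray

    def __post_init__(self) -> None:
        f = _as_1d_float(self.frequencies, "frequencies")
        n = _as_1d_float(self.n, "n")
        k = _as_1d_float(self.k, "k")
        alpha = _as_1d_float(self.alpha, "alpha")
        if not (f.size == n.size == k.size == alpha.size):
            raise ValueError("all arrays must share length")
        if np.any(n <= 0):
            raise ValueError("refractive index must be positive")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "k", k)
        object.__setattr__(self, "alpha", alpha)

    def feature(self, which: str) -> np.ndarray:
        if which == "absorption":
            return self.alpha
        if which == "refractive_index":
            return self.n
        raise ValueError(f"unknown feature {which!r}")


@dataclass(frozen=True)
class SampleGeometry:
    """Pellet geometry; ``thickness_d`` in ``thickness_unit`` (default mm)."""

    thickness_d: float = 1.0
    diameter: float = 13.0
    thickness_unit: str = "mm"

    def __post_init__(self) -> None:
        if self.thickness_d <= 0:
            raise ValueError("thickness must be positive")
        if self.thickness_unit not in _LENGTH_TO_M:
            raise ValueError(
                f"thickness_unit must be one of {sorted(_LENGTH_TO_M)}"
            )

    @property
    def thickness_m(self) -> float:
        """Thickness in metres, whatever the declared unit."""
        return self.thickness_d * _LENGTH_TO_M[self.thickness_unit]


@dataclass(frozen=True)
class SpectraMatrix:
    """Samples x frequency-variables feature matrix with class labels.

    Rows are samples; columns are a fixed frequency grid (THz). ``y`` holds
    integer class codes 1..K used directly as the regression response.
    """

    X: np.ndarray
    variable_frequencies: np.ndarray
    y: np.ndarray
    sample_ids: tuple = field(default=())

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        f = _as_1d_float(self.variable_frequencies, "variable_frequencies")
        y = np.asarray(self.y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if X.shape[1] != f.size:
            raise ValueError("variable_frequencies must match X columns")
        if y.ndim != 1 or y.size != X.shape[0]:
            raise ValueError("y must have one entry per row of X")
        if not np.allclose(y, np.round(y)):
            raise ValueError("class codes must be integers")
        y = np.round(y).astype(int)
        if y.size and (y.min() < 1):
            raise ValueError("class codes must be >= 1")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        ids = tuple(self.sample_ids) if self.sample_ids else tuple(
            f"S{i + 1:04d}" for i in range(X.shape[0])
        )
        if len(ids) != X.shape[0]:
            raise ValueError("sample_ids must match number of rows")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "variable_frequencies", f)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "sample_ids", ids)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_variables(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        return int(self.y.max()) if self.y.size else 0

    def select_variables(self, start: int, end: int) -> "SpectraMatrix":
        """Column slice by 1-based inclusive variable indices."""
        if not (1 <= start <= end <= self.n_variables):
            raise ValueError(
                f"variable range {start}-{end} outside 1-{self.n_variables}"
            )
        sl = slice(start - 1, end)
        return SpectraMatrix(
            self.X[:, sl],
            self.variable_frequencies[sl],
            self.y,
            self.sample_ids,
        )

    def select_samples(self, indices: Sequence[int]) -> "SpectraMatrix":
        idx = np.asarray(indices, dtype=int)
        return SpectraMatrix(
            self.X[idx],
            self.variable_frequencies,
            self.y[idx],
            tuple(self.sample_ids[i] for i in idx),
        )
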