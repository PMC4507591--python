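"""Optical-constant extraction from sample/reference time-domain traces.

Given a reference scan E_ref(t) (empty beam path) and a sample scan
E_sam(t) through a pellet of known thickness d, the complex transmission

    H(omega) = E_sam(omega) / E_ref(omega) = rho(omega) exp(-i phi(omega))

yields, under the single-pass thick-slab model,

    n(omega)     = 1 + phi(omega) * c / (omega * d)
    alpha(omega) = (2/d) * ln( 4 n / (rho * (n + 1)^2) )

with phi the unwrapped phase *lag* of the sample (positive for n > 1 under
the exp(-i*2*pi*f*t) Fourier kernel used here) and alpha the intensity
absorption coefficient, reported in cm^-1.

Phase unwrapping is anchored at low frequency: after unwrapping along the
band, the integer multiple of 2*pi that minimises the intercept of a
linear fit of phi(f) over the anchor band (default 0.2-0.5 THz) is
subtracted, removing the branch ambiguity the arctangent leaves.
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.constants import c as C_M_PER_S

from .containers import (
    FrequencySpectrum,
    OpticalProperties,
    SampleGeometry,
    SpectraMatrix,
    TimeDomainTrace,
    TransferFunction,
)
from .simulate import SimulatedDataset, alpha_to_k

__all__ = [
    "average_scans",
    "to_frequency",
    "transfer_function",
    "refractive_index",
    "absorption_coefficient",
    "extract_optical_properties",
    "extract_dataset",
    "build_matrix",
]


def average_scans(traces: Sequence[TimeDomainTrace]) -> TimeDomainTrace:
    """Pointwise mean of repeated scans sharing one delay grid."""
    if not traces:
        raise ValueError("no traces to average")
    first = traces[0]
    for i, tr in enumerate(traces[1:], start=2):
        if not first.same_grid(tr):
            raise ValueError(f"scan {i} is not on the delay grid of scan 1")
    mean = np.mean([tr.amplitudes for tr in traces], axis=0)
    return TimeDomainTrace(first.delays, mean)


def to_frequency(
    trace: TimeDomainTrace, zero_pad_to: Optional[int] = None
) -> FrequencySpectrum:
    """One-sided DFT of a trace; frequencies in THz (1/ps).

    ``zero_pad_to`` extends the record before transforming, refining the
    frequency grid to 1/(zero_pad_to * time_step).
    """
    n = trace.n_points if zero_pad_to is None else int(zero_pad_to)
    if n < trace.n_points:
        raise ValueError(
            f"zero_pad_to={n} shorter than the trace ({trace.n_points} points)"
        )
    freqs = np.fft.rfftfreq(n, d=trace.time_step)
    amps = np.fft.rfft(trace.amplitudes, n=n)
    return FrequencySpectrum(freqs, amps)


def transfer_function(
    sample: FrequencySpectrum,
    reference: FrequencySpectrum,
    band: Tuple[float, float],
    reference_floor: float = 1e-4,
    anchor_band: Tuple[float, float] = (0.2, 0.5),
) -> TransferFunction:
    """Amplitude ratio and anchored, unwrapped phase lag over ``band``.

    Bins where the reference amplitude falls below ``reference_floor`` times
    its in-band maximum are rejected (deconvolution there would amplify
    noise without bound) with an error listing the dead bins.
    """
    if sample.frequencies.size != reference.frequencies.size or not np.allclose(
        sample.frequencies, reference.frequencies, rtol=1e-9, atol=1e-12
    ):
        raise ValueError("sample and reference must share the frequency grid")
    f = reference.frequencies
    lo, hi = band
    if lo >= hi:
        raise ValueError("band must satisfy f_min < f_max")
    mask = (f >= lo) & (f <= hi)
    if not np.any(mask):
        raise ValueError(f"band {band} contains no frequency bins")
    fb = f[mask]
    ref = reference.complex_amplitudes[mask]
    sam = sample.complex_amplitudes[mask]

    floor = reference_floor * np.max(np.abs(ref))
    dead = np.abs(ref) < floor
    if np.any(dead):
        raise ValueError(
            "reference amplitude below floor at "
            f"{fb[dead].round(4).tolist()} THz"
        )

    ratio = sam / ref
    rho = np.abs(ratio)
    phi = -np.unwrap(np.angle(ratio))

    # anchor: phi(f) extrapolated to f=0 should pass through 0 (pure delay)
    a_lo, a_hi = anchor_band
    amask = (fb >= a_lo) & (fb <= a_hi)
    if np.sum(amask) < 2:
        amask = fb <= fb[0] + 0.25 * (fb[-1] - fb[0])
    if np.sum(amask) >= 2:
        slope, intercept = np.polyfit(fb[amask], phi[amask], 1)
        phi = phi - 2.0 * np.pi * np.round(intercept / (2.0 * np.pi))
    return TransferFunction(fb, rho, phi)


def refractive_index(tf: TransferFunction, geometry: SampleGeometry) -> np.ndarray:
    """n(f) = 1 + phi*c/(omega*d), per bin. The DC bin is not defined."""
    if np.any(tf.frequencies <= 0):
        raise ValueError("transfer function must exclude the f=0 bin")
    omega = 2.0 * np.pi * tf.frequencies * 1e12
    return 1.0 + tf.phi * C_M_PER_S / (omega * geometry.thickness_m)


def absorption_coefficient(
    tf: TransferFunction, n: np.ndarray, geometry: SampleGeometry
) -> np.ndarray:
    """alpha(f) = (2/d) ln(4n / (rho (n+1)^2)), in cm^-1.

    Noise can make individual bins slightly negative; values are flagged
    with a warning but deliberately not clipped.
    """
    n = np.asarray(n, dtype=float)
    if np.any(tf.rho <= 0):
        raise ValueError("rho must be strictly positive (log divergence)")
    if np.any(n <= 0):
        raise ValueError("refractive index must be positive")
    d_m = geometry.thickness_m
    alpha_m = (2.0 / d_m) * np.log(4.0 * n / (tf.rho * (n + 1.0) ** 2))
    alpha_cm = alpha_m / 100.0
    n_neg = int(np.sum(alpha_cm < 0))
    if n_neg:
        warnings.warn(
            f"{n_neg} absorption bins are negative (noise); not clipped",
            stacklevel=2,
        )
    return alpha_cm


def extract_optical_properties(
    sample_trace: TimeDomainTrace,
    reference_trace: TimeDomainTrace,
    geometry: SampleGeometry,
    band: Tuple[float, float] = (0.2, 1.5),
    zero_pad_to: Optional[int] = None,
    pad_bins: int = 2,
) -> OpticalProperties:
    """Full per-sample extraction: FFT, deconvolve, invert to n and alpha.

    The band is widened by ``pad_bins`` FFT bins on each side so that the
    returned grid always covers the requested band endpoints (the discrete
    grid rarely contains them exactly), which later resampling needs.
    """
    sam = to_frequency(sample_trace, zero_pad_to)
    ref = to_frequency(reference_trace, zero_pad_to)
    df = sam.frequencies[1] - sam.frequencies[0]
    wide = (max(band[0] - pad_bins * df, 0.5 * df), band[1] + pad_bins * df)
    tf = transfer_function(sam, ref, wide)
    n = refractive_index(tf, geometry)
    alpha = absorption_coefficient(tf, n, geometry)
    return OpticalProperties(tf.frequencies, n, alpha_to_k(alpha, tf.frequencies), alpha)


def extract_dataset(
    dataset: SimulatedDataset,
    band: Tuple[float, float] = (0.2, 1.5),
    zero_pad_to: Optional[int] = None,
) -> Dict[str, OpticalProperties]:
    """Extract every sample of a session: average its repeated scans, then
    deconvolve against the reference scan of its acquisition block."""
    out: Dict[str, OpticalProperties] = {}
    for sid in dataset.sample_ids:
        avg = average_scans(dataset.scans_of(sid))
        out[sid] = extract_optical_properties(
            avg, dataset.reference_of(sid), dataset.geometry, band, zero_pad_to
        )
    return out


def build_matrix(
    samples: Sequence[OpticalProperties],
    labels: Sequence[int],
    band: Tuple[float, float] = (0.2, 1.5),
    n_variables: int = 128,
    feature: str = "absorption",
    sample_ids: Optional[Sequence[str]] = None,
) -> SpectraMatrix:
    """Resample each sample's chosen feature onto a common linear grid.

    The grid is ``n_variables`` points spanning ``band`` inclusive; values
    are linearly interpolated from each sample's native grid. Samples not
    covering the band are rejected.
    """
    if len(samples) != len(labels):
        raise ValueError("labels must match samples")
    grid = np.linspace(band[0], band[1], n_variables)
    rows = []
    for i, props in enumerate(samples):
        f = props.frequencies
        if f[0] > band[0] + 1e-12 or f[-1] < band[1] - 1e-12:
            raise ValueError(
                f"sample {i} covers {f[0]:.4f}-{f[-1]:.4f} THz, not {band}"
            )
        rows.append(np.interp(grid, f, props.feature(feature)))
    ids = tuple(sample_ids) if sample_ids is not None else ()
    return SpectraMatrix(np.vstack(rows), grid, np.asarray(labels), ids)
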