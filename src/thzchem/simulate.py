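"""Forward model: synthetic THz time-domain traces for labelled classes.

The generator emulates a transmission THz-TDS measurement of pressed
pellets: a single-cycle (Gaussian-derivative) reference pulse, single-pass
propagation through a weakly absorbing, nearly dispersionless slab, and an
instrument noise model with a flat spectral noise floor so that SNR
degrades where the pulse spectrum rolls off (above ~1.5 THz by default).

Class structure of the material model: the absorption coefficient is a
featureless affine rise with frequency plus a smooth, band-limited
"composition" bump whose amplitude varies across classes, plus a smooth
per-sample deviation. This mirrors amorphous organic powders, whose THz
absorption increases monotonically with frequency and differs between
compositions without sharp resonances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.constants import c as C_M_PER_S

from .containers import (
    FrequencySpectrum,
    OpticalProperties,
    SampleGeometry,
    SpectraMatrix,
    TimeDomainTrace,
)

__all__ = [
    "InstrumentModel",
    "ClassProfile",
    "SimulatedDataset",
    "make_reference_pulse",
    "material_properties",
    "propagate",
    "generate_dataset",
    "generate_matrix",
    "default_wheat_profiles",
    "uniform_profiles",
    "WHEAT_CLASS_MEAN_ALPHA",
]

#: Published per-class band-average absorption coefficients (cm^-1) for the
#: eight wheat varieties, used as the default simulation targets.
WHEAT_CLASS_MEAN_ALPHA: Tuple[float, ...] = (
    37.1492,  # Zhengmai 9023
    39.4354,  # Zhouyuan 9369
    35.3358,  # Aobiao
    42.1133,  # DNS
    37.5468,  # Jiamai
    42.2520,  # Jinan 17
    39.8226,  # Zhoumai 27
    39.9409,  # Yunong 416
)


@dataclass(frozen=True)
class InstrumentModel:
    """Spectrometer model: sampling, pulse shape, and noise.

    Parameters
    ----------
    time_step : sampling interval of the delay line, ps.
    n_points : samples per scan (power of two preferred for the FFT).
    pulse_center : arrival time of the reference pulse, ps.
    pulse_width : Gaussian width tau of the single-cycle pulse, ps; the
        power spectrum of the Gaussian derivative peaks at 1/(2*pi*tau).
    amplitude_noise_sd : relative multiplicative noise per frequency bin.
    additive_noise_sd : additive white time-domain noise, field units;
        its flat spectral floor sets the dynamic range.
    dynamic_range_rolloff_freq : THz; descriptive marker of where the noise
        floor overtakes the rolling-off signal spectrum (default 1.5).
    """

    time_step: float = 0.02
    n_points: int = 2048
    pulse_center: float = 8.0
    pulse_width: float = 0.3
    amplitude_noise_sd: float = 0.005
    additive_noise_sd: float = 0.001
    dynamic_range_rolloff_freq: float = 1.5

    def __post_init__(self) -> None:
        if self.time_step <= 0:
            raise ValueError("time_step must be positive")
        if self.n_points < 64:
            raise ValueError("n_points must be >= 64")
        if self.pulse_width <= 0:
            raise ValueError("pulse_width must be positive")
        if self.amplitude_noise_sd < 0 or self.additive_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")

    @property
    def delays(self) -> np.ndarray:
        return np.arange(self.n_points) * self.time_step

    @property
    def frequencies(self) -> np.ndarray:
        """Native one-sided FFT grid in THz (includes the DC bin)."""
        return np.fft.rfftfreq(self.n_points, d=self.time_step)


@dataclass(frozen=True)
class ClassProfile:
    """Material model of one sample class.

    alpha(f) = alpha_offset + alpha_slope*f
               + signal_amplitude * bump(f; signal_band)
               + per-sample constant offset deviation
               + smooth per-sample deviation      [cm^-1, f in THz]
    n(f)     = n_baseline + smooth per-sample deviation

    The bump is a raised cosine confined to ``signal_band`` (peak 1 at the
    band centre); it carries the class-discriminative signal. The constant
    offset deviation models pellet-to-pellet thickness/packing-density
    scatter, which rescales the apparent absorption level of a whole
    spectrum — the dominant nuisance in pressed-pellet transmission work
    and the reason band-local contrasts beat global levels.
    """

    class_id: int
    alpha_offset: float
    alpha_slope: float = 10.0
    n_baseline: float = 1.5
    signal_band: Tuple[float, float] = (0.773, 0.845)
    signal_amplitude: float = 0.0
    alpha_offset_deviation_sd: float = 2.0
    alpha_deviation_sd: float = 0.5
    n_deviation_sd: float = 0.005

    def __post_init__(self) -> None:
        if self.class_id < 1:
            raise ValueError("class_id must be >= 1")
        if self.alpha_offset <= 0:
            raise ValueError("alpha_offset must be positive")
        if self.signal_band[0] >= self.signal_band[1]:
            raise ValueError("signal_band must satisfy f_lo < f_hi")
        if self.n_baseline <= 1:
            raise ValueError("n_baseline must exceed 1")
        if (
            self.alpha_deviation_sd < 0
            or self.n_deviation_sd < 0
            or self.alpha_offset_deviation_sd < 0
        ):
            raise ValueError("deviation SDs must be >= 0")


@dataclass(frozen=True)
class SimulatedDataset:
    """All traces and ground truth of one simulated measurement session."""

    traces: List[Tuple[str, int, TimeDomainTrace]]
    reference_traces: List[TimeDomainTrace]
    reference_index: Dict[str, int]
    labels: Dict[str, int]
    geometry: SampleGeometry
    rng_seed: int
    instrument: InstrumentModel
    planted: Dict[str, OpticalProperties] = field(default_factory=dict)
    scans_per_sample: int = 3

    def __post_init__(self) -> None:
        counts: Dict[str, int] = {}
        for sid, _scan, _tr in self.traces:
            counts[sid] = counts.get(sid, 0) + 1
        if set(counts) != set(self.labels):
            raise ValueError("labels must cover exactly the sampled ids")
        bad = {s: c for s, c in counts.items() if c != self.scans_per_sample}
        if bad:
            raise ValueError(f"samples without {self.scans_per_sample} scans: {bad}")

    @property
    def sample_ids(self) -> List[str]:
        return sorted(self.labels)

    def scans_of(self, sample_id: str) -> List[TimeDomainTrace]:
        return [tr for sid, _i, tr in self.traces if sid == sample_id]

    def reference_of(self, sample_id: str) -> TimeDomainTrace:
        return self.reference_traces[self.reference_index[sample_id]]


def _analytic_pulse(instrument: InstrumentModel) -> np.ndarray:
    """Noiseless Gaussian-derivative single-cycle pulse on the delay grid."""
    t = instrument.delays
    tau = instrument.pulse_width
    u = (t - instrument.pulse_center) / tau
    return -u * np.exp(-0.5 * u**2)


def _apply_instrument_noise(
    amplitudes: np.ndarray, instrument: InstrumentModel, rng: np.random.Generator
) -> np.ndarray:
    """Multiplicative per-bin spectral noise plus additive time-domain noise."""
    out = amplitudes
    if instrument.amplitude_noise_sd > 0:
        spec = np.fft.rfft(out)
        spec = spec * (
            1.0 + rng.normal(0.0, instrument.amplitude_noise_sd, spec.size)
        )
        out = np.fft.irfft(spec, n=amplitudes.size)
    if instrument.additive_noise_sd > 0:
        out = out + rng.normal(0.0, instrument.additive_noise_sd, out.size)
    return out


def make_reference_pulse(instrument: InstrumentModel, seed: int) -> TimeDomainTrace:
    """One reference scan: the analytic pulse plus instrument noise.

    Deterministic given ``seed``; with both noise SDs zero the trace equals
    the analytic pulse exactly (no FFT round trip is applied).
    """
    amp = _analytic_pulse(instrument)
    if instrument.amplitude_noise_sd > 0 or instrument.additive_noise_sd > 0:
        rng = np.random.default_rng(seed)
        amp = _apply_instrument_noise(amp, instrument, rng)
    return TimeDomainTrace(instrument.delays, amp)


def _bump(f: np.ndarray, band: Tuple[float, float]) -> np.ndarray:
    """Raised cosine confined to ``band``: 0 at the edges, 1 at the centre."""
    lo, hi = band
    centre = 0.5 * (lo + hi)
    width = hi - lo
    inside = (f >= lo) & (f <= hi)
    out = np.zeros_like(f)
    out[inside] = 0.5 * (1.0 + np.cos(2.0 * np.pi * (f[inside] - centre) / width))
    return out


def _smooth_deviation(
    f: np.ndarray,
    sd: float,
    rng: np.random.Generator,
    n_modes: int = 6,
    rising: bool = False,
) -> np.ndarray:
    """Smooth zero-mean random curve: low-order cosine series, pointwise SD
    ``sd`` (averaged over phase and position).

    With ``rising`` the envelope grows linearly from 0.5x at the low end to
    1.5x at the high end of the grid, mimicking scattering/etalon residue
    structure that worsens with frequency in pellet spectra.
    """
    if sd == 0:
        # still consume the draws so noisy/noiseless runs stay aligned
        rng.normal(size=n_modes)
        return np.zeros_like(f)
    span = f[-1] - f[0] if f[-1] > f[0] else 1.0
    u = (f - f[0]) / span
    coeff = rng.normal(0.0, sd * np.sqrt(2.0 / n_modes), n_modes)
    out = np.zeros_like(f)
    for m, a in enumerate(coeff, start=1):
        out += a * np.cos(m * np.pi * u)
    if rising:
        out *= 0.5 + u
    return out


def alpha_to_k(alpha_cm: np.ndarray, f_thz: np.ndarray) -> np.ndarray:
    """Extinction coefficient from absorption: k = alpha*c/(2*omega).

    ``alpha`` in cm^-1 (intensity), f in THz; k is dimensionless. The DC
    bin, where the conversion diverges, is returned as 0.
    """
    alpha_m = np.asarray(alpha_cm, float) * 100.0
    omega = 2.0 * np.pi * np.asarray(f_thz, float) * 1e12
    with np.errstate(divide="ignore", invalid="ignore"):
        k = alpha_m * C_M_PER_S / (2.0 * omega)
    return np.where(omega > 0, k, 0.0)


def material_properties(
    profile: ClassProfile,
    grid: np.ndarray,
    seed_or_rng,
) -> OpticalProperties:
    """Draw one sample's optical constants on ``grid`` (THz, increasing)."""
    f = np.asarray(grid, dtype=float)
    if f.ndim != 1 or np.any(np.diff(f) <= 0) or f[0] < 0:
        raise ValueError("grid must be 1-D, strictly increasing, >= 0")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    alpha = (
        profile.alpha_offset
        + profile.alpha_slope * f
        + profile.signal_amplitude * _bump(f, profile.signal_band)
        + rng.normal(0.0, profile.alpha_offset_deviation_sd)
        + _smooth_deviation(f, profile.alpha_deviation_sd, rng, rising=True)
    )
    if np.any(alpha < 0):
        warnings.warn(
            f"class {profile.class_id}: {int(np.sum(alpha < 0))} negative "
            "alpha values clipped to 0",
            stacklevel=2,
        )
        alpha = np.clip(alpha, 0.0, None)
    n = profile.n_baseline + _smooth_deviation(f, profile.n_deviation_sd, rng)
    return OpticalProperties(f, n, alpha_to_k(alpha, f), alpha)


def propagate(
    reference_spectrum: FrequencySpectrum,
    props: OpticalProperties,
    geometry: SampleGeometry,
    fresnel: str = "real",
) -> FrequencySpectrum:
    """Single-pass slab transmission: sample spectrum = reference * H.

    H combines the air/slab interface losses 4N/(N+1)^2 with the
    propagation factor exp(-i*omega*(N-1)*d/c), N = n - i*k. Etalon echoes
    are deliberately omitted (single-pass model). With ``fresnel="real"``
    (default) the interface factor is evaluated with the real index only,
    making the forward model the exact inverse of the standard
    amplitude/phase extraction formulas; ``"complex"`` uses the full
    complex-N factor (the loss correction at the interfaces is second
    order for weak absorbers).
    """
    f = props.frequencies
    if reference_spectrum.frequencies.size != f.size or not np.allclose(
        reference_spectrum.frequencies, f, rtol=1e-9, atol=1e-12
    ):
        raise ValueError("reference and properties must share the frequency grid")
    d = geometry.thickness_m
    omega = 2.0 * np.pi * f * 1e12
    n = props.n
    if fresnel == "real":
        fres = 4.0 * n / (n + 1.0) ** 2
    elif fresnel == "complex":
        N = n - 1j * props.k
        fres = 4.0 * N / (N + 1.0) ** 2
    else:
        raise ValueError("fresnel must be 'real' or 'complex'")
    # exp(-i*omega*(N-1)*d/c) = delay by (n-1)d/c and field attenuation
    # exp(-alpha*d/2); written without dividing by omega so the DC bin is
    # finite.
    alpha_m = props.alpha * 100.0
    attenuation = np.exp(-0.5 * alpha_m * d)
    phase = np.exp(-1j * omega * (n - 1.0) * d / C_M_PER_S)
    H = fres * attenuation * phase
    return FrequencySpectrum(f, reference_spectrum.complex_amplitudes * H)


def generate_dataset(
    profiles: Sequence[ClassProfile],
    n_per_class: int,
    instrument: InstrumentModel,
    geometry: SampleGeometry,
    seed: int,
    scans_per_sample: int = 3,
    samples_per_reference: int = 3,
) -> SimulatedDataset:
    """Simulate a full measurement session.

    ``K * n_per_class`` samples, ``scans_per_sample`` noisy scans each, and
    one noisy reference scan per block of ``samples_per_reference`` samples
    (references interleaved with the sample queue, as in practice). Fully
    reproducible from ``seed``.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 class profiles")
    if n_per_class < 2:
        raise ValueError("need at least 2 samples per class")
    rng = np.random.default_rng(seed)
    freqs = instrument.frequencies
    clean_pulse = _analytic_pulse(instrument)
    ref_spectrum = FrequencySpectrum(freqs, np.fft.rfft(clean_pulse))

    sample_order: List[Tuple[str, ClassProfile]] = []
    labels: Dict[str, int] = {}
    i = 0
    for prof in profiles:
        for _ in range(n_per_class):
            sid = f"S{i + 1:04d}"
            sample_order.append((sid, prof))
            labels[sid] = prof.class_id
            i += 1

    n_samples = len(sample_order)
    n_ref = -(-n_samples // samples_per_reference)  # ceil
    reference_traces = [
        TimeDomainTrace(
            instrument.delays,
            _apply_instrument_noise(clean_pulse, instrument, rng),
        )
        for _ in range(n_ref)
    ]

    traces: List[Tuple[str, int, TimeDomainTrace]] = []
    reference_index: Dict[str, int] = {}
    planted: Dict[str, OpticalProperties] = {}
    for idx, (sid, prof) in enumerate(sample_order):
        reference_index[sid] = idx // samples_per_reference
        props = material_properties(prof, freqs, rng)
        planted[sid] = props
        sample_spec = propagate(ref_spectrum, props, geometry)
        clean_sample = np.fft.irfft(
            sample_spec.complex_amplitudes, n=instrument.n_points
        )
        for scan in range(1, scans_per_sample + 1):
            noisy = _apply_instrument_noise(clean_sample, instrument, rng)
            traces.append((sid, scan, TimeDomainTrace(instrument.delays, noisy)))

    return SimulatedDataset(
        traces=traces,
        reference_traces=reference_traces,
        reference_index=reference_index,
        labels=labels,
        geometry=geometry,
        rng_seed=seed,
        instrument=instrument,
        planted=planted,
        scans_per_sample=scans_per_sample,
    )


def generate_matrix(
    profiles: Sequence[ClassProfile],
    n_per_class: int,
    seed: int,
    band: Tuple[float, float] = (0.2, 1.5),
    n_variables: int = 128,
    measurement_noise_sd: float = 0.5,
) -> SpectraMatrix:
    """Draw an absorption-feature matrix directly, skipping the time domain.

    Each row is one sample's alpha(f) on a linear ``n_variables``-point grid
    over ``band`` plus iid measurement noise (cm^-1). Statistically matches
    what the extraction stage produces, at a fraction of the cost; used for
    Monte-Carlo studies of the chemometric stages.
    """
    rng = np.random.default_rng(seed)
    grid = np.linspace(band[0], band[1], n_variables)
    rows, labels, ids = [], [], []
    i = 0
    for prof in profiles:
        for _ in range(n_per_class):
            props = material_properties(prof, grid, rng)
            rows.append(props.alpha + rng.normal(0, measurement_noise_sd, grid.size))
            labels.append(prof.class_id)
            ids.append(f"S{i + 1:04d}")
            i += 1
    return SpectraMatrix(np.vstack(rows), grid, np.array(labels), tuple(ids))


def _mean_bump_over_band(
    signal_band: Tuple[float, float], band: Tuple[float, float]
) -> float:
    """Band-average of the raised-cosine bump (analytic: 1/2 over its own
    support, scaled by the support fraction inside ``band``)."""
    lo = max(signal_band[0], band[0])
    hi = min(signal_band[1], band[1])
    if hi <= lo:
        return 0.0
    # exact only when the full bump lies inside band; good enough otherwise
    frac = (hi - lo) / (band[1] - band[0])
    return 0.5 * frac


def default_wheat_profiles(
    class_means: Sequence[float] = WHEAT_CLASS_MEAN_ALPHA,
    alpha_slope: float = 10.0,
    signal_band: Tuple[float, float] = (0.773, 0.845),
    signal_base: float = 1.0,
    signal_step: float = 1.5,
    n_baseline: float = 1.5,
    n_step: float = 0.003,
    band: Tuple[float, float] = (0.2, 1.5),
    alpha_offset_deviation_sd: float = 2.0,
    alpha_deviation_sd: float = 0.5,
    n_deviation_sd: float = 0.005,
) -> List[ClassProfile]:
    """Eight wheat-variety class profiles calibrated so that each class's
    band-average absorption equals the published per-variety mean.

    The class-discriminative bump amplitude grows linearly with the class
    code (``signal_base + signal_step*(c-1)``), matching the numeric-code
    response the regression uses; ``alpha_offset`` absorbs the slope and
    bump contributions so the configured band means are preserved.
    """
    f_mean = 0.5 * (band[0] + band[1])
    bump_mean = _mean_bump_over_band(signal_band, band)
    profiles = []
    for c, target in enumerate(class_means, start=1):
        amp = signal_base + signal_step * (c - 1)
        offset = target - alpha_slope * f_mean - amp * bump_mean
        if offset <= 0:
            raise ValueError(
                f"class {c}: target mean {target} too small for slope/signal"
            )
        profiles.append(
            ClassProfile(
                class_id=c,
                alpha_offset=offset,
                alpha_slope=alpha_slope,
                n_baseline=n_baseline + n_step * (c - 1),
                signal_band=signal_band,
                signal_amplitude=amp,
                alpha_offset_deviation_sd=alpha_offset_deviation_sd,
                alpha_deviation_sd=alpha_deviation_sd,
                n_deviation_sd=n_deviation_sd,
            )
        )
    return profiles


def uniform_profiles(
    n_classes: int = 8,
    alpha_mean: float = 39.0,
    band: Tuple[float, float] = (0.2, 1.5),
    **kwargs,
) -> List[ClassProfile]:
    """Identical profiles for every class: zero class separation.

    Used as the null condition — any classifier should score at chance.
    """
    base = default_wheat_profiles(
        class_means=[alpha_mean] * n_classes,
        signal_base=0.0,
        signal_step=0.0,
        n_step=0.0,
        band=band,
        **kwargs,
    )
    return [replace(p, signal_amplitude=0.0) for p in base]
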