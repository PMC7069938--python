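"""Pulse synthesis, RF channel-data simulation, envelopes, FWHM and SNR.

The simulated acquisition follows the single-scattering / linear-propagation
picture: every point source contributes the *same* transmit pulse to every
element, delayed by the time of flight.  In photoacoustic (PA) mode the path
is one-way (source to element); in plane-wave ultrasound (US) mode the plane
wave first travels from the array to the scatterer (delay ``z / c``) and the
echo then returns along the geometric path.

All sub-sample delays are applied as frequency-domain phase ramps on
zero-padded traces, never by nearest-sample rounding: at 62.5 MHz a one-sample
rounding error (16 ns, ~24 µm of path) would be larger than the 12.5 µm
reconstruction grid step.  RF synthesis and forward-model assembly share the
same shift operator, so delay composition is exact to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import gausspulse, hilbert

from .exceptions import MetricError, SamplingError, TruncationError
from .geometry import ElementSubset, ProbeGeometry, ReconGrid

__all__ = [
    "PA",
    "US_PLANEWAVE",
    "Pulse",
    "RFData",
    "SourceSet",
    "make_pulse",
    "synthesize_rf",
    "add_noise",
    "measure_snr",
    "envelope",
    "lateral_fwhm",
    "delay_traces",
    "delay_bank",
]

PA = "PA"
US_PLANEWAVE = "US_planewave"
_MODALITIES = (PA, US_PLANEWAVE)


def _planewave_flag(modality: str) -> float:
    """δ_US of the delay law: 1 for plane-wave US (emission travel time
    counts), 0 for PA (one-way only)."""
    if modality not in _MODALITIES:
        raise ValueError(f"unknown modality {modality!r}")
    return 1.0 if modality == US_PLANEWAVE else 0.0


# ---------------------------------------------------------------------------
# fractional (sub-sample) delays
# ---------------------------------------------------------------------------

def _shift_kernel(n_t: int, fs: float, dt: np.ndarray) -> tuple[int, np.ndarray]:
    # circular (unpadded) shift: delays then compose exactly —
    # shift(a)∘shift(b) == shift(a+b) to machine precision, which the
    # forward-model/synthesis equivalence relies on.  Callers must keep
    # waveforms away from the window edges (shifted content wraps around).
    nfft = n_t
    f = np.fft.rfftfreq(nfft, d=1.0 / fs)
    kernel = np.exp(-2j * np.pi * np.outer(f, dt))
    if nfft % 2 == 0:
        kernel[-1] = 0.0  # band-limit at Nyquist: keeps the shift compositional
    return nfft, kernel


def delay_traces(x: np.ndarray, dt: np.ndarray | float, fs: float) -> np.ndarray:
    """Delay each column of ``x`` (time × trace) by its own ``dt`` seconds.

    Positive ``dt`` moves the waveform towards later times. The shift is
    circular on the window; keep waveforms clear of the edges.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float).T).T  # (n_t, K)
    dt = np.broadcast_to(np.asarray(dt, dtype=float), (x.shape[1],))
    nfft, phase = _shift_kernel(x.shape[0], fs, dt)
    X = np.fft.rfft(x, n=nfft, axis=0)
    return np.fft.irfft(X * phase, n=nfft, axis=0)[: x.shape[0]]


def delay_bank(trace: np.ndarray, dts: np.ndarray, fs: float) -> np.ndarray:
    """Shift one trace by many delays at once; returns (n_t, len(dts))."""
    trace = np.asarray(trace, dtype=float).ravel()
    dts = np.asarray(dts, dtype=float).ravel()
    nfft, phase = _shift_kernel(trace.size, fs, dts)
    X = np.fft.rfft(trace, n=nfft)
    return np.fft.irfft(X[:, None] * phase, n=nfft, axis=0)[: trace.size]


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Pulse:
    """A Gaussian-modulated sinusoid transmit/receive pulse.

    ``fractional_bandwidth`` is the −6 dB spectral full width divided by the
    centre frequency. The envelope peaks (value 1) at the reference time 0.
    """

    center_frequency: float
    fractional_bandwidth: float
    sampling_rate: float
    waveform: np.ndarray = field(repr=False)
    time_axis: np.ndarray = field(repr=False)

    @property
    def sigma_t(self) -> float:
        """Envelope standard deviation in seconds (−6 dB definition)."""
        bw_hz = self.fractional_bandwidth * self.center_frequency
        return np.sqrt(2.0 * np.log(2.0)) / (np.pi * bw_hz)

    @property
    def half_duration(self) -> float:
        """Half support used when checking window containment (7 σ_t:
        envelope tail ~2e-11, numerically negligible)."""
        return 7.0 * self.sigma_t

    def sample(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the analytic pulse model at arbitrary times."""
        return gausspulse(
            np.asarray(t, dtype=float),
            fc=self.center_frequency,
            bw=self.fractional_bandwidth,
            bwr=-6,
        )


@dataclass(frozen=True)
class SourceSet:
    """Point sources in the imaging plane with nonnegative amplitudes."""

    positions: np.ndarray  # (n_sources, 2): columns x, z in metres
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        amp = np.asarray(self.amplitudes, dtype=float).ravel()
        if pos.shape[1] != 2:
            raise ValueError("positions must be (n, 2) [x, z]")
        if amp.size != pos.shape[0]:
            raise ValueError("one amplitude per source required")
        if np.any(amp < 0):
            raise ValueError("amplitudes must be nonnegative")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "amplitudes", amp)

    @property
    def n_sources(self) -> int:
        return int(self.positions.shape[0])


def five_channel_scene(
    spacing: float = 125e-6,
    depth: float = 15e-3,
    n_sources: int = 5,
    amplitude: float = 1.0,
) -> SourceSet:
    """The canonical test object: ``n_sources`` point sources in a lateral
    row at the elevational-focus depth, centre-to-centre ``spacing`` apart
    (defaults: five sources, 125 µm, 15 mm)."""
    x = (np.arange(n_sources) - (n_sources - 1) / 2.0) * spacing
    pos = np.column_stack([x, np.full(n_sources, depth)])
    return SourceSet(positions=pos, amplitudes=np.full(n_sources, amplitude))


@dataclass(frozen=True)
class RFData:
    """Radio-frequency channel data: time × active-element sample matrix.

    Absolute sample times are ``t0 + i / sampling_rate``.
    """

    samples: np.ndarray
    sampling_rate: float
    t0: float
    modality: str
    probe: ProbeGeometry
    subset: ElementSubset

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", s)
        if s.ndim != 2:
            raise ValueError("samples must be 2D (time × element)")
        if not np.all(np.isfinite(s)):
            raise ValueError("samples must be finite")
        if s.shape[1] != self.subset.n_elements:
            raise ValueError("column count must equal number of active elements")
        if self.modality not in _MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def n_samples(self) -> int:
        return int(self.samples.shape[0])

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sampling_rate

    @property
    def element_positions(self) -> np.ndarray:
        """(K, 2) positions of the active elements."""
        idx = self.subset.indices
        return np.column_stack([self.probe.element_x[idx], self.probe.element_z[idx]])


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def make_pulse(
    center_frequency: float,
    fractional_bandwidth: float = 0.6,
    sampling_rate: float = 62.5e6,
) -> Pulse:
    """Gaussian-modulated sinusoid with the stated −6 dB fractional
    bandwidth, envelope peak 1 at the reference time 0."""
    if center_frequency <= 0 or fractional_bandwidth <= 0 or sampling_rate <= 0:
        raise SamplingError("pulse parameters must be positive")
    if sampling_rate <= 2.0 * center_frequency * (1.0 + fractional_bandwidth):
        raise SamplingError(
            f"sampling rate {sampling_rate:g} Hz violates the Nyquist guard "
            f"2·fc·(1 + bw) = "
            f"{2 * center_frequency * (1 + fractional_bandwidth):g} Hz"
        )
    sigma_t = np.sqrt(2.0 * np.log(2.0)) / (
        np.pi * fractional_bandwidth * center_frequency
    )
    half_n = int(np.ceil(7.0 * sigma_t * sampling_rate))
    t = np.arange(-half_n, half_n + 1) / sampling_rate
    w = gausspulse(t, fc=center_frequency, bw=fractional_bandwidth, bwr=-6)
    return Pulse(
        center_frequency=float(center_frequency),
        fractional_bandwidth=float(fractional_bandwidth),
        sampling_rate=float(sampling_rate),
        waveform=w,
        time_axis=t,
    )


def arrival_times(
    positions: np.ndarray,
    element_pos: np.ndarray,
    c: float,
    modality: str,
) -> np.ndarray:
    """Absolute arrival times (n_points, K): plane-wave emission delay
    (US only) plus geometric time of flight."""
    positions = np.atleast_2d(positions)
    d = np.hypot(
        positions[:, 0:1] - element_pos[None, :, 0],
        positions[:, 1:2] - element_pos[None, :, 1],
    )
    return (_planewave_flag(modality) * positions[:, 1:2] + d) / c


def synthesize_rf(
    sources: SourceSet,
    probe: ProbeGeometry,
    subset: ElementSubset,
    pulse: Pulse,
    modality: str,
    c: float = 1500.0,
    t_start: float | None = None,
    n_samples: int | None = None,
) -> RFData:
    """Simulate single-shot RF channel data for point sources.

    Each element receives the superposition over sources of the transmit
    pulse delayed by the modality-appropriate time of flight, applied with
    sub-sample accuracy. With ``t_start``/``n_samples`` unset, a window
    covering every arrival plus the pulse support is chosen automatically.

    Raises :class:`TruncationError` if any arrival-time peak falls outside
    an explicitly requested window.
    """
    fs = pulse.sampling_rate
    idx = subset.indices
    elem = np.column_stack([probe.element_x[idx], probe.element_z[idx]])
    tau = arrival_times(sources.positions, elem, c, modality)  # (J, K)

    if t_start is None or n_samples is None:
        lo = tau.min() - pulse.half_duration
        hi = tau.max() + pulse.half_duration
        t_start = np.floor(lo * fs) / fs
        n_samples = int(np.ceil((hi - t_start) * fs)) + 1
    else:
        t_end = t_start + (n_samples - 1) / fs
        if tau.min() < t_start or tau.max() > t_end:
            raise TruncationError(
                "source arrival times fall outside the requested window "
                f"[{t_start:g}, {t_end:g}] s; widen the window instead of "
                "silently clipping"
            )

    # synthesize in the frequency domain: one phase ramp per (source, element)
    t_ref = t_start + (n_samples // 2) / fs  # window-centre reference sample
    base = pulse.sample(
        t_start + np.arange(n_samples) / fs - t_ref
    )  # pulse peaking at t_ref
    nfft = n_samples  # circular, matching the delay operators exactly
    f = np.fft.rfftfreq(nfft, d=1.0 / fs)
    B = np.fft.rfft(base, n=nfft)
    if nfft % 2 == 0:
        B[-1] = 0.0  # band-limit at Nyquist, matching the delay operators
    # per-element combined spectrum: B(f) · Σ_j a_j e^{-2πi f (τ_jk - t_ref)}
    phases = np.einsum(
        "j,fjk->fk",
        sources.amplitudes,
        np.exp(-2j * np.pi * f[:, None, None] * (tau[None, :, :] - t_ref)),
    )
    samples = np.fft.irfft(B[:, None] * phases, n=nfft, axis=0)[:n_samples]
    return RFData(
        samples=samples,
        sampling_rate=fs,
        t0=float(t_start),
        modality=modality,
        probe=probe,
        subset=subset,
    )


def add_noise(rf: RFData, sigma_n: float, seed=None) -> RFData:
    """Add i.i.d. zero-mean Gaussian noise of rms ``sigma_n`` to every
    sample; reproducible from ``seed`` (int or numpy Generator)."""
    if sigma_n < 0:
        raise ValueError("sigma_n must be nonnegative")
    if sigma_n == 0:
        return rf
    rng = np.random.default_rng(seed)
    noisy = rf.samples + rng.normal(0.0, sigma_n, size=rf.samples.shape)
    return replace(rf, samples=noisy)


def measure_snr(rf: RFData, signal_free_region: slice | tuple) -> float:
    """Peak |RF| divided by the noise standard deviation over a signal-free
    time-sample range (all elements pooled)."""
    if isinstance(signal_free_region, tuple):
        signal_free_region = slice(*signal_free_region)
    quiet = rf.samples[signal_free_region]
    if quiet.size == 0:
        raise ValueError("signal-free region is empty")
    noise_std = float(np.std(quiet))
    peak = float(np.max(np.abs(rf.samples)))
    if noise_std == 0.0:
        return np.inf
    return peak / noise_std


def envelope(trace: np.ndarray, axis: int = 0) -> np.ndarray:
    """Magnitude of the analytic signal along ``axis``."""
    trace = np.asarray(trace, dtype=float)
    if trace.shape[axis] < 4:
        raise ValueError("trace too short for envelope detection")
    return np.abs(hilbert(trace, axis=axis))


def lateral_fwhm(image: np.ndarray, grid: ReconGrid) -> float:
    """Lateral full width at half maximum of the profile through the global
    maximum of a (nz × nx) amplitude map, with linear interpolation between
    grid samples. This is the conventional diffraction-limited resolution
    measure of the point spread function."""
    image = np.asarray(image, dtype=float)
    if image.shape != (grid.nz, grid.nx):
        raise ValueError("image shape does not match grid")
    iz, ix = np.unravel_index(np.argmax(image), image.shape)
    profile = image[iz]
    half = profile[ix] / 2.0

    def _cross(direction: int) -> float:
        i = ix
        while 0 <= i + direction < grid.nx and profile[i + direction] >= half:
            i += direction
        j = i + direction
        if j < 0 or j >= grid.nx:
            raise MetricError(
                "lateral profile never falls below half maximum inside the grid"
            )
        # linear interpolation of the half-max crossing between i and j
        frac = (profile[i] - half) / (profile[i] - profile[j])
        return grid.x_coords[ix] + direction * grid.step * (abs(i - ix) + frac)

    return float(_cross(+1) - _cross(-1))
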