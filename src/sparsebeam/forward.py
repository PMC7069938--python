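"""Forward-model matrix assembly from a single point-source (PSF) record.

The linear acquisition model is ``S = A T0``: ``S`` is the vectorized RF
data, ``T0`` the discretized object on the reconstruction grid and each of
the n columns of ``A`` is the vectorized RF response of a unit point source
at one grid point.  Rather than measuring or simulating every column, all
columns are derived from a *single* PSF record by assuming the signals from
two distinct point sources differ only by their arrival times: column ``i``
is the PSF record with every element trace shifted by the delay law

    Δt(i, j, k) = δ_US · (z_i − z_j) / c
                + (‖r_i − r_k‖ − ‖r_j − r_k‖) / c ,

where ``j`` is the PSF source, ``k`` the element, δ_US = 1 for plane-wave
ultrasound (the emitted plane wave reaches deeper points later) and 0 for
photoacoustics.  Positive Δt means the response of point ``i`` arrives later
than the PSF source's response on that element.

Vectorization order: rows are grouped per element (element-major), each
group holding that element's ``n_window_samples`` consecutive time samples;
columns follow the grid's depth-major raster order.  Each element's window
is centred on its own arrival time from the PSF source, so a short window
(the replica configuration uses 36 samples per element) can follow the
arrival-time curvature across a wide aperture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import TruncationError
from .geometry import ElementSubset, ProbeGeometry, ReconGrid
from .signals import RFData, _planewave_flag, arrival_times, delay_bank, envelope

__all__ = ["PSFRecord", "ForwardModel", "delay_law", "build_matrix",
           "vectorize_rf", "model_diagnostics"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PSFRecord:
    """RF record of a single point source placed at ``source_position``."""

    rf: RFData
    source_position: tuple[float, float]  # (x_j, z_j) in metres

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "source_position",
            (float(self.source_position[0]), float(self.source_position[1])),
        )

    def validate_single_peak(self) -> bool:
        """True when every element trace has one dominant envelope lobe
        (the samples above half the trace maximum form a single run)."""
        env = envelope(self.rf.samples, axis=0)
        for k in range(env.shape[1]):
            above = env[:, k] >= 0.5 * env[:, k].max()
            runs = np.diff(above.astype(int))
            if np.count_nonzero(runs == 1) > 1:
                return False
        return True


@dataclass
class ForwardModel:
    """Dense forward-model matrix ``A`` plus the metadata defining its rows
    and columns.

    ``matrix`` has shape (n_window_samples × n_active_elements, grid
    n_points).  ``window_starts[k]`` is the first time-sample index (into the
    source PSF record) of element k's window; the absolute time of row
    ``k·n_window_samples + i`` is ``t0 + (window_starts[k] + i) / fs``.
    """

    matrix: np.ndarray
    grid: ReconGrid
    probe: ProbeGeometry
    subset: ElementSubset
    window_starts: np.ndarray
    n_window_samples: int
    sampling_rate: float
    t0: float
    source_position: tuple[float, float]
    modality: str
    c: float
    _gram: np.ndarray | None = field(default=None, repr=False)

    @property
    def m(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def n(self) -> int:
        return int(self.matrix.shape[1])

    def gram(self) -> np.ndarray:
        """Cached ``AᵀA`` (n × n): the solver iterates on it so each FISTA
        step costs O(n²) instead of O(mn)."""
        if self._gram is None:
            self._gram = self.matrix.T @ self.matrix
        return self._gram


def delay_law(
    point_i, source_j, element_k, c: float, modality: str
) -> float:
    """Arrival-time difference of grid point ``i`` relative to PSF source
    ``j`` on element ``k`` (seconds); positive means later arrival.

    US plane-wave mode adds the one-way emission term (z_i − z_j)/c on top
    of the geometric return-path difference; PA mode has the geometric term
    only.
    """
    if c <= 0:
        raise ValueError("speed of sound must be positive")
    xi, zi = float(point_i[0]), float(point_i[1])
    xj, zj = float(source_j[0]), float(source_j[1])
    xk, zk = float(element_k[0]), float(element_k[1])
    delta = _planewave_flag(modality)
    geo = np.hypot(xk - xi, zk - zi) - np.hypot(xk - xj, zk - zj)
    return float(delta * (zi - zj) / c + geo / c)


def build_matrix(
    psf: PSFRecord,
    grid: ReconGrid,
    subset: ElementSubset,
    c: float = 1500.0,
    n_window_samples: int | None = None,
    truncation_warn_fraction: float = 0.005,
) -> ForwardModel:
    """Assemble ``A`` by fractional-delay shifting the PSF record to every
    grid point.

    ``subset`` may be any subset of the elements present in the PSF record.
    ``n_window_samples`` selects a per-element window of that many samples
    centred on the element's arrival time from the PSF source (None: the
    full record).  Columns whose shifted energy leaves the window by more
    than ``truncation_warn_fraction`` are logged.
    """
    rf = psf.rf
    fs = rf.sampling_rate
    modality = rf.modality

    # map the requested subset onto the PSF record's columns
    rec_idx = psf.rf.subset.indices
    pos_in_record = {int(e): i for i, e in enumerate(rec_idx)}
    try:
        cols = np.array([pos_in_record[int(e)] for e in subset.indices])
    except KeyError as exc:
        raise ValueError(
            f"element {exc} not present in the PSF record"
        ) from None
    elem = np.column_stack(
        [psf.rf.probe.element_x[subset.indices],
         psf.rf.probe.element_z[subset.indices]]
    )

    src = np.array([psf.source_position])
    tau_j = arrival_times(src, elem, c, modality)[0]  # (K,)

    if n_window_samples is None:
        n_window_samples = rf.n_samples
        starts = np.zeros(len(cols), dtype=int)
    else:
        centre = np.round((tau_j - rf.t0) * fs).astype(int)
        starts = centre - n_window_samples // 2
        if np.any(starts < 0) or np.any(starts + n_window_samples > rf.n_samples):
            raise TruncationError(
                "per-element windows fall outside the PSF record; record a "
                "longer PSF or shorten the window"
            )

    gx, gz = grid.points()
    tau_i = arrival_times(np.column_stack([gx, gz]), elem, c, modality)  # (n, K)
    dt = tau_i - tau_j[None, :]  # Δt(i, k), the delay law for every column

    K = len(cols)
    A = np.empty((n_window_samples * K, grid.n_points))
    for a, (k, s) in enumerate(zip(cols, starts)):
        shifted = delay_bank(rf.samples[:, k], dt[:, a], fs)  # (n_t, n_points)
        A[a * n_window_samples:(a + 1) * n_window_samples] = (
            shifted[s:s + n_window_samples]
        )

    # column-energy audit: delayed copies spilling out of the window
    col_norm = np.linalg.norm(A, axis=0)
    full_norm = np.sqrt(
        sum(np.linalg.norm(rf.samples[:, k]) ** 2 for k in cols)
    )
    lossy = col_norm < (1.0 - truncation_warn_fraction) * full_norm
    if np.any(lossy):
        worst = 1.0 - col_norm.min() / full_norm
        log.info(
            "%d/%d forward-model columns lose > %.1f%% energy to window "
            "truncation (worst %.1f%%)",
            int(lossy.sum()), grid.n_points,
            100 * truncation_warn_fraction, 100 * worst,
        )

    return ForwardModel(
        matrix=A,
        grid=grid,
        probe=psf.rf.probe,
        subset=subset,
        window_starts=starts,
        n_window_samples=int(n_window_samples),
        sampling_rate=fs,
        t0=rf.t0,
        source_position=psf.source_position,
        modality=modality,
        c=float(c),
    )


def vectorize_rf(model: ForwardModel, rf: RFData) -> np.ndarray:
    """Extract and stack the model's per-element windows from an RF record,
    producing the data vector ``S`` conformable with ``model.matrix``."""
    if rf.sampling_rate != model.sampling_rate:
        raise ValueError("sampling rate mismatch between RF data and model")
    if abs(rf.t0 - model.t0) * model.sampling_rate > 1e-6:
        raise ValueError("time origin mismatch between RF data and model")
    pos_in_record = {int(e): i for i, e in enumerate(rf.subset.indices)}
    try:
        cols = [pos_in_record[int(e)] for e in model.subset.indices]
    except KeyError as exc:
        raise ValueError(f"element {exc} missing from RF data") from None
    n = model.n_window_samples
    parts = [
        rf.samples[s:s + n, k] for k, s in zip(cols, model.window_starts)
    ]
    return np.concatenate(parts)


def model_diagnostics(model: ForwardModel, rank_tol: float | None = None) -> dict:
    """Numerical rank, mutual coherence and conditioning of ``A``.

    Rank uses the conventional tolerance max(m, n)·eps·σ_max unless given.
    ``underdetermined`` is flagged when rank < n (more grid unknowns than
    independent data directions — the regime in which the l1 prior is doing
    the work).
    """
    A = model.matrix
    s = np.linalg.svd(A, compute_uv=False)
    if rank_tol is None:
        rank_tol = max(A.shape) * np.finfo(A.dtype).eps * s[0]
    rank = int(np.sum(s > rank_tol))
    norms = np.linalg.norm(A, axis=0)
    norms = np.where(norms == 0, 1.0, norms)
    G = (A / norms).T @ (A / norms)
    np.fill_diagonal(G, 0.0)
    coherence = float(np.max(np.abs(G)))
    return {
        "m": model.m,
        "n": model.n,
        "rank": rank,
        "rank_tol": float(rank_tol),
        "mutual_coherence": coherence,
        "sigma_max": float(s[0]),
        "sigma_min": float(s[-1]),
        "condition_number": float(s[0] / s[-1]) if s[-1] > 0 else np.inf,
        "underdetermined": rank < model.n,
    }
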