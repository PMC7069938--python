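"""Delay-and-sum (DAS) beamforming — the conventional, diffraction-limited
baseline the sparse reconstruction is compared against.

For each grid point the modality-appropriate time of flight to every active
element is computed (one-way for PA; plane-wave emission delay z/c plus the
return path for US), the RF trace is sampled there with linear
interpolation, and the contributions are summed.  No apodization and no
f-number gating: this is the plain delay-and-sum the comparison calls for.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geometry import ElementSubset, ProbeGeometry, ReconGrid
from .signals import RFData, arrival_times, envelope

__all__ = ["DASImage", "das_reconstruct"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DASImage:
    """Beamformed image on a reconstruction grid.

    ``amplitude`` is the signed RF summation; ``envelope`` its analytic-
    signal magnitude taken along the depth axis per lateral line (the
    standard B-mode detection convention). Both have shape (nz, nx).
    """

    amplitude: np.ndarray
    envelope: np.ndarray
    grid: ReconGrid

    def __post_init__(self) -> None:
        if self.amplitude.shape != (self.grid.nz, self.grid.nx):
            raise ValueError("amplitude shape does not match grid")
        if self.envelope.shape != self.amplitude.shape:
            raise ValueError("envelope shape does not match amplitude")


def das_reconstruct(
    rf: RFData,
    probe: ProbeGeometry,
    subset: ElementSubset,
    grid: ReconGrid,
    c: float = 1500.0,
) -> DASImage:
    """Delay-and-sum image of ``rf`` on ``grid`` using the elements of
    ``subset``.  Grid points whose time of flight leaves the RF window
    receive zero contribution from the affected elements (logged once)."""
    pos_in_record = {int(e): i for i, e in enumerate(rf.subset.indices)}
    try:
        cols = np.array([pos_in_record[int(e)] for e in subset.indices])
    except KeyError as exc:
        raise ValueError(f"element {exc} missing from RF data") from None
    elem = np.column_stack(
        [probe.element_x[subset.indices], probe.element_z[subset.indices]]
    )
    gx, gz = grid.points()
    tof = arrival_times(np.column_stack([gx, gz]), elem, c, rf.modality)

    t = rf.times
    out_of_window = (tof < t[0]) | (tof > t[-1])
    if np.any(out_of_window):
        log.warning(
            "DAS: %d grid-point/element pairs outside the RF window "
            "contribute zero", int(out_of_window.sum()),
        )
    acc = np.zeros(grid.n_points)
    for a, k in enumerate(cols):
        acc += np.interp(tof[:, a], t, rf.samples[:, k], left=0.0, right=0.0)
    amp = grid.vector_to_image(acc)
    env = envelope(amp, axis=0) if grid.nz >= 4 else np.abs(amp)
    return DASImage(amplitude=amp, envelope=env, grid=grid)
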