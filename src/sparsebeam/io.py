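"""HDF5 container I/O and run manifests.

One container format holds every array artifact (RF records, forward
models, images); geometry and acquisition metadata are embedded as
attributes so any file is self-describing and a run can be re-executed from
its outputs alone.  Metric tables are written as delimited text and run
manifests as JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np

from .forward import ForwardModel, PSFRecord
from .geometry import ElementSubset, ProbeGeometry, ReconGrid
from .signals import RFData

__all__ = [
    "save_rfdata", "load_rfdata", "save_model", "load_model",
    "save_image", "rf_to_text", "write_manifest", "array_hash",
]


def array_hash(a: np.ndarray) -> str:
    """Stable content hash of an array (used in provenance manifests)."""
    return hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()[:16]


def _write_probe(g: h5py.Group, probe: ProbeGeometry, subset: ElementSubset):
    g.create_dataset("element_x", data=probe.element_x)
    g.create_dataset("element_z", data=probe.element_z)
    g.attrs["pitch_m"] = probe.pitch
    g.create_dataset("subset_indices", data=subset.indices)
    g.attrs["subset_scheme"] = subset.scheme


def _read_probe(g: h5py.Group) -> tuple[ProbeGeometry, ElementSubset]:
    probe = ProbeGeometry(
        element_x=g["element_x"][()],
        element_z=g["element_z"][()],
        pitch=float(g.attrs["pitch_m"]),
    )
    subset = ElementSubset(
        indices=g["subset_indices"][()],
        scheme=str(g.attrs["subset_scheme"]),
        n_elements_total=probe.n_elements_total,
    )
    return probe, subset


def save_rfdata(path, rf: RFData) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("rf", data=rf.samples)
        f.attrs["sampling_rate_hz"] = rf.sampling_rate
        f.attrs["t0_s"] = rf.t0
        f.attrs["modality"] = rf.modality
        _write_probe(f.create_group("probe"), rf.probe, rf.subset)


def load_rfdata(path) -> RFData:
    with h5py.File(path, "r") as f:
        probe, subset = _read_probe(f["probe"])
        return RFData(
            samples=f["rf"][()],
            sampling_rate=float(f.attrs["sampling_rate_hz"]),
            t0=float(f.attrs["t0_s"]),
            modality=str(f.attrs["modality"]),
            probe=probe,
            subset=subset,
        )


def save_psf(path, psf: PSFRecord) -> None:
    save_rfdata(path, psf.rf)
    with h5py.File(path, "a") as f:
        f.attrs["psf_source_x_m"] = psf.source_position[0]
        f.attrs["psf_source_z_m"] = psf.source_position[1]


def load_psf(path) -> PSFRecord:
    rf = load_rfdata(path)
    with h5py.File(path, "r") as f:
        pos = (float(f.attrs["psf_source_x_m"]), float(f.attrs["psf_source_z_m"]))
    return PSFRecord(rf=rf, source_position=pos)


def save_model(path, model: ForwardModel) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("A", data=model.matrix)
        f.create_dataset("window_starts", data=model.window_starts)
        f.attrs["n_window_samples"] = model.n_window_samples
        f.attrs["sampling_rate_hz"] = model.sampling_rate
        f.attrs["t0_s"] = model.t0
        f.attrs["psf_source_x_m"] = model.source_position[0]
        f.attrs["psf_source_z_m"] = model.source_position[1]
        f.attrs["modality"] = model.modality
        f.attrs["c_m_per_s"] = model.c
        _write_probe(f.create_group("probe"), model.probe, model.subset)
        g = f.create_group("grid")
        g.create_dataset("x_coords", data=model.grid.x_coords)
        g.create_dataset("z_coords", data=model.grid.z_coords)
        g.attrs["step_m"] = model.grid.step


def load_model(path) -> ForwardModel:
    with h5py.File(path, "r") as f:
        probe, subset = _read_probe(f["probe"])
        grid = ReconGrid(
            x_coords=f["grid/x_coords"][()],
            z_coords=f["grid/z_coords"][()],
            step=float(f["grid"].attrs["step_m"]),
        )
        return ForwardModel(
            matrix=f["A"][()],
            grid=grid,
            probe=probe,
            subset=subset,
            window_starts=f["window_starts"][()],
            n_window_samples=int(f.attrs["n_window_samples"]),
            sampling_rate=float(f.attrs["sampling_rate_hz"]),
            t0=float(f.attrs["t0_s"]),
            source_position=(float(f.attrs["psf_source_x_m"]),
                             float(f.attrs["psf_source_z_m"])),
            modality=str(f.attrs["modality"]),
            c=float(f.attrs["c_m_per_s"]),
        )


def save_image(path, pixels: np.ndarray, x_coords: np.ndarray,
               z_coords: np.ndarray, **attrs) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("image", data=pixels)
        f.create_dataset("x_coords", data=x_coords)
        f.create_dataset("z_coords", data=z_coords)
        for k, v in attrs.items():
            f.attrs[k] = v


def rf_to_text(path, rf: RFData) -> None:
    """Plain-text export (one row per time sample) for interoperability."""
    header = (
        f"sampling_rate_hz={rf.sampling_rate} t0_s={rf.t0} "
        f"modality={rf.modality} n_elements={rf.subset.n_elements}"
    )
    np.savetxt(path, rf.samples, header=header)


def write_manifest(path, **entries) -> None:
    """JSON run manifest; numpy scalars/arrays are converted to plain types."""
    def default(o):
        if isinstance(o, np.generic):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(entries, indent=2, default=default, sort_keys=True))
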