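"""Linear transducer arrays, reconstruction grids and element-subset schemes.

Coordinates are physical metres. The origin sits at the array centre, ``x``
runs along the array and ``z`` points away from the probe into the medium.

The reconstruction grid is vectorized depth-major (``z`` fastest): grid point
``p`` corresponds to lateral index ``ix = p // nz`` and depth index
``iz = p % nz``.  This raster order is the column order of the forward-model
matrix and must never change silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import GeometryError, GridError, SubsetError

__all__ = [
    "ProbeGeometry",
    "ElementSubset",
    "ReconGrid",
    "make_linear_probe",
    "select_elements",
    "make_grid",
]


@dataclass(frozen=True)
class ProbeGeometry:
    """A 1D linear array of point-like transducer elements.

    Attributes
    ----------
    element_x : ndarray
        Lateral element coordinates (m), strictly increasing.
    element_z : ndarray
        Depth element coordinates (m); all zero for a flat linear array.
    pitch : float
        Inter-element spacing (m).
    """

    element_x: np.ndarray
    element_z: np.ndarray
    pitch: float

    def __post_init__(self) -> None:
        x = np.asarray(self.element_x, dtype=float)
        z = np.asarray(self.element_z, dtype=float)
        object.__setattr__(self, "element_x", x)
        object.__setattr__(self, "element_z", z)
        if x.ndim != 1 or x.size < 2:
            raise GeometryError("probe needs at least 2 elements")
        if z.shape != x.shape:
            raise GeometryError("element_x and element_z shapes differ")
        if self.pitch <= 0:
            raise GeometryError(f"pitch must be positive, got {self.pitch}")
        if np.any(np.diff(x) <= 0):
            raise GeometryError("element_x must be strictly increasing")

    @property
    def n_elements_total(self) -> int:
        return int(self.element_x.size)

    @property
    def aperture(self) -> float:
        """Full aperture, first-to-last element (m)."""
        return float(self.element_x[-1] - self.element_x[0])


@dataclass(frozen=True)
class ElementSubset:
    """An ordered subset of a probe's elements.

    ``scheme`` is one of ``{"all", "regular_with_endpoints",
    "random_with_endpoints"}``. For both the regular and random schemes the
    first and last elements of the full array are always included so the
    subset spans the full aperture (constant diffraction limit).
    """

    indices: np.ndarray
    scheme: str
    n_elements_total: int

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        object.__setattr__(self, "indices", idx)
        if idx.ndim != 1 or idx.size < 1:
            raise SubsetError("subset must contain at least one index")
        if np.unique(idx).size != idx.size:
            raise SubsetError("subset indices must be unique")
        if np.any(np.diff(idx) <= 0):
            raise SubsetError("subset indices must be sorted ascending")
        if idx[0] < 0 or idx[-1] >= self.n_elements_total:
            raise SubsetError("subset indices out of range")

    @property
    def n_elements(self) -> int:
        return int(self.indices.size)


@dataclass(frozen=True)
class ReconGrid:
    """Uniform cartesian 2D imaging grid (lateral x × depth z).

    Grid points are indexed depth-major: ``p = ix * nz + iz``.
    """

    x_coords: np.ndarray
    z_coords: np.ndarray
    step: float

    def __post_init__(self) -> None:
        x = np.asarray(self.x_coords, dtype=float)
        z = np.asarray(self.z_coords, dtype=float)
        object.__setattr__(self, "x_coords", x)
        object.__setattr__(self, "z_coords", z)
        if self.step <= 0:
            raise GridError(f"grid step must be positive, got {self.step}")
        for name, c in (("x_coords", x), ("z_coords", z)):
            if c.ndim != 1 or c.size < 1:
                raise GridError(f"{name} must be a non-empty 1D array")
            if c.size > 1:
                d = np.diff(c)
                if not np.allclose(d, self.step, rtol=1e-9, atol=1e-15):
                    raise GridError(f"{name} spacing is not uniform = step")

    @property
    def nx(self) -> int:
        return int(self.x_coords.size)

    @property
    def nz(self) -> int:
        return int(self.z_coords.size)

    @property
    def n_points(self) -> int:
        return self.nx * self.nz

    def point_index(self, ix: int, iz: int) -> int:
        """Raster index of lateral/depth indices (depth-major)."""
        if not (0 <= ix < self.nx and 0 <= iz < self.nz):
            raise GridError(f"grid index ({ix}, {iz}) out of range")
        return ix * self.nz + iz

    def index_to_ij(self, p: int) -> tuple[int, int]:
        """Inverse of :meth:`point_index`."""
        if not (0 <= p < self.n_points):
            raise GridError(f"raster index {p} out of range")
        return p // self.nz, p % self.nz

    def point_xz(self, p: int) -> tuple[float, float]:
        ix, iz = self.index_to_ij(p)
        return float(self.x_coords[ix]), float(self.z_coords[iz])

    def points(self) -> tuple[np.ndarray, np.ndarray]:
        """All grid-point coordinates in raster order, as (x, z) arrays."""
        x = np.repeat(self.x_coords, self.nz)
        z = np.tile(self.z_coords, self.nx)
        return x, z

    def nearest_cell(self, x: float, z: float) -> tuple[int, int]:
        """Nearest (ix, iz) to a physical position; ties break to the
        lower index (documented tie rule)."""
        dx = np.abs(self.x_coords - x)
        dz = np.abs(self.z_coords - z)
        # argmin returns first occurrence -> lower index on exact ties
        return int(np.argmin(dx)), int(np.argmin(dz))

    def vector_to_image(self, v: np.ndarray) -> np.ndarray:
        """Reshape a raster-ordered vector to an image array of shape
        (nz, nx) — depth down rows, lateral across columns."""
        v = np.asarray(v)
        if v.shape[-1] != self.n_points:
            raise GridError("vector length does not match grid size")
        return v.reshape(v.shape[:-1] + (self.nx, self.nz)).swapaxes(-1, -2)

    def image_to_vector(self, img: np.ndarray) -> np.ndarray:
        if img.shape[-2:] != (self.nz, self.nx):
            raise GridError("image shape does not match grid")
        return img.swapaxes(-1, -2).reshape(img.shape[:-2] + (self.n_points,))


def make_linear_probe(
    n_elements: int, pitch: float, center_x: float = 0.0
) -> ProbeGeometry:
    """Create a flat linear array of ``n_elements`` with uniform ``pitch``,
    centred on ``center_x`` at depth z = 0."""
    if n_elements < 2:
        raise GeometryError(f"need at least 2 elements, got {n_elements}")
    if pitch <= 0:
        raise GeometryError(f"pitch must be positive, got {pitch}")
    offsets = (np.arange(n_elements) - (n_elements - 1) / 2.0) * pitch
    return ProbeGeometry(
        element_x=center_x + offsets,
        element_z=np.zeros(n_elements),
        pitch=float(pitch),
    )


def select_elements(
    probe: ProbeGeometry,
    N: int,
    scheme: str = "regular_with_endpoints",
    seed: int | None = None,
) -> ElementSubset:
    """Select ``N`` elements of ``probe`` under one of the subset schemes.

    ``regular_with_endpoints``: first and last elements fixed, interior
    elements at the rounded positions of an even partition of the index
    range (round half up).  ``random_with_endpoints``: first and last fixed,
    interior drawn uniformly without replacement (reproducible from
    ``seed``).  ``all``: every element (requires N == n_elements_total).
    """
    M = probe.n_elements_total
    if not 2 <= N <= M:
        raise SubsetError(f"N must be in [2, {M}], got {N}")
    if scheme == "all":
        if N != M:
            raise SubsetError("scheme 'all' requires N == n_elements_total")
        idx = np.arange(M)
    elif scheme == "regular_with_endpoints":
        # even partition of [0, M-1]; round half up so placement is stable
        frac = np.arange(N) * (M - 1) / (N - 1)
        idx = np.floor(frac + 0.5).astype(int)
        idx = np.unique(idx)
        if idx.size != N:  # collisions only possible when N ~ M
            raise SubsetError("regular partition collapsed indices")
    elif scheme == "random_with_endpoints":
        rng = np.random.default_rng(seed)
        interior = rng.choice(np.arange(1, M - 1), size=N - 2, replace=False)
        idx = np.sort(np.concatenate(([0], interior, [M - 1])))
    else:
        raise SubsetError(f"unknown subset scheme {scheme!r}")
    return ElementSubset(indices=idx, scheme=scheme, n_elements_total=M)


def make_grid(
    x_min: float, x_max: float, z_min: float, z_max: float, step: float
) -> ReconGrid:
    """Inclusive uniform grid covering the window ``[x_min, x_max] ×
    [z_min, z_max]`` with spacing ``step``."""
    if step <= 0:
        raise GridError(f"grid step must be positive, got {step}")
    if x_max < x_min or z_max < z_min:
        raise GridError("empty grid window")
    nx = int(round((x_max - x_min) / step)) + 1
    nz = int(round((z_max - z_min) / step)) + 1
    return ReconGrid(
        x_coords=x_min + np.arange(nx) * step,
        z_coords=z_min + np.arange(nz) * step,
        step=float(step),
    )
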