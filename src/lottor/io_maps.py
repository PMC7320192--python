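"""On-disk I/O and grid conventions.

All other modules rely on the conventions fixed here:

* In memory a 3D map is a ``numpy`` array indexed ``(x, y, z)``; on disk the
  MRC column/row/section axes map to ``(x, y, z)`` in that order.
* The box/rotation center is at integer index ``n // 2`` on each axis, the
  same voxel the centered Fourier layout places DC in.
* The tilt axis is the in-memory Y axis; the beam runs along Z.
* Maps are written as CCP4/MRC 2014 mode-2 (4-byte float) with the voxel
  size carried in the cell fields and the header origin left at zero.
* Tilt angles travel in IMOD-style ``.tlt`` sidecar files: one angle in
  degrees per line, section order.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

TILT_AXIS = "Y"

#: CODATA standard atomic weights (Da) for the elements that occur in
#: ordinary macromolecular models.  Anything else falls back to carbon with
#: a logged warning (see :func:`read_atom_model`).
ATOMIC_MASS_DA = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "SE": 78.971, "FE": 55.845, "ZN": 65.38, "MG": 24.305,
    "MN": 54.938, "CA": 40.078, "NA": 22.990, "K": 39.098, "CL": 35.45,
    "CU": 63.546, "NI": 58.693, "CO": 58.933, "MO": 95.95, "F": 18.998,
    "BR": 79.904, "I": 126.904, "AU": 196.967, "B": 10.81, "W": 183.84,
}


class MapFormatError(ValueError):
    """Raised for unreadable or unsupported map/stack files."""


@dataclass
class DensityMap:
    """Real scalar field on an ``nx × ny × nz`` voxel grid.

    Parameters
    ----------
    values : ndarray
        The voxel values, indexed ``(x, y, z)``.
    voxel_size : float
        Å per voxel, isotropic.
    label : str
        Free-text provenance.
    """

    values: np.ndarray
    voxel_size: float
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("map contains non-finite values")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def box(self) -> int:
        """Edge length for cubic maps."""
        nx, ny, nz = self.values.shape
        if not (nx == ny == nz):
            raise ValueError(f"map is not cubic: {self.values.shape}")
        return nx

    def copy(self) -> "DensityMap":
        return DensityMap(self.values.copy(), self.voxel_size, self.label)


@dataclass
class TiltSeries:
    """Ordered stack of 2D projections about a fixed Y tilt axis.

    ``images`` has shape ``(n_tilt, px, py)``; frame axes are the in-plane
    (x, y) of the untilted map.  Angles are degrees, strictly increasing,
    each in (−90°, +90°].
    """

    images: np.ndarray
    angles: np.ndarray
    voxel_size: float
    axis: str = TILT_AXIS

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.images.ndim != 3:
            raise ValueError("images must be a stacked (n_tilt, px, py) array")
        if self.images.shape[0] != self.angles.size:
            raise ValueError(
                f"frame/angle count mismatch: {self.images.shape[0]} frames "
                f"vs {self.angles.size} angles"
            )
        if self.angles.size >= 2 and not np.all(np.diff(self.angles) > 0):
            raise ValueError("tilt angles must be strictly increasing")
        if self.angles.size and (
            self.angles[0] <= -90.0 or self.angles[-1] > 90.0
        ):
            raise ValueError("tilt angles must lie in (-90, 90] degrees")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be > 0")

    @property
    def n_tilt(self) -> int:
        return self.images.shape[0]


@dataclass
class AtomModel:
    """Point-atom model: (element, x, y, z in Å, mass in Da) per atom."""

    elements: list[str]
    coords: np.ndarray          # (n_atoms, 3) Å
    masses: np.ndarray          # (n_atoms,) Da

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("atom coordinates must be finite")
        if self.total_mass_da <= 0:
            raise ValueError("total mass must be positive")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def total_mass_da(self) -> float:
        return float(self.masses.sum())


@dataclass
class FSCTable:
    """Serialized FSC curve: (spatial frequency 1/Å, correlation) rows."""

    freq: np.ndarray
    fsc: np.ndarray

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.fsc = np.asarray(self.fsc, dtype=float)
        if self.freq.shape != self.fsc.shape:
            raise ValueError("freq and fsc must have the same length")
        if self.freq.size >= 2 and not np.all(np.diff(self.freq) > 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(np.abs(self.fsc) > 1 + 1e-6):
            raise ValueError("correlations must lie in [-1, 1]")


# ---------------------------------------------------------------------------
# maps

def _grid_from_array(values: np.ndarray, voxel_size: float) -> gemmi.FloatGrid:
    arr = np.ascontiguousarray(values, dtype=np.float32)
    grid = gemmi.FloatGrid(arr)
    nx, ny, nz = arr.shape
    grid.unit_cell = gemmi.UnitCell(
        nx * voxel_size, ny * voxel_size, nz * voxel_size, 90.0, 90.0, 90.0
    )
    grid.spacegroup = gemmi.SpaceGroup("P1")
    return grid


def write_map(density_map: DensityMap, path: str | os.PathLike) -> None:
    """Write a map as CCP4/MRC 2014 mode 2 (float32)."""
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = _grid_from_array(density_map.values, density_map.voxel_size)
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(os.fspath(path))


def read_map(path: str | os.PathLike) -> DensityMap:
    """Read a CCP4/MRC map; only mode-2 (float) data is supported."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"map file not found: {path}")
    try:
        ccp4 = gemmi.read_ccp4_map(path)
    except (RuntimeError, ValueError) as exc:
        raise MapFormatError(f"cannot read MRC map {path!r}: {exc}") from exc
    mode = ccp4.header_i32(4)
    if mode != 2:
        raise MapFormatError(
            f"unsupported MRC mode {mode} in {path!r}; only mode 2 "
            "(32-bit float) is supported"
        )
    values = np.array(ccp4.grid, copy=True)
    nx = values.shape[0]
    voxel_size = float(ccp4.grid.unit_cell.a) / nx
    return DensityMap(values, voxel_size, label=os.path.basename(path))


# ---------------------------------------------------------------------------
# tilt series

def write_tilt_series(ts: TiltSeries, stack_path: str | os.PathLike,
                      angles_path: str | os.PathLike) -> None:
    """Write a tilt stack as a multi-section mode-2 MRC plus a ``.tlt`` file.

    Sections run along the slowest file axis; each section is one frame.
    """
    # store frames as sections: in-memory (n_tilt, px, py) -> grid (px, py, n_tilt)
    vol = np.moveaxis(ts.images, 0, -1)
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = _grid_from_array(vol, ts.voxel_size)
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(os.fspath(stack_path))
    with open(angles_path, "w") as fh:
        for a in ts.angles:
            fh.write(f"{a:.2f}\n")


def read_tilt_angles(path: str | os.PathLike) -> np.ndarray:
    """Parse an IMOD-style ``.tlt`` file (degrees, one per line)."""
    with open(path) as fh:
        tokens = fh.read().split()
    if not tokens:
        raise ValueError(f"no angles found in {os.fspath(path)!r}")
    return np.array([float(t) for t in tokens])


def read_tilt_series(stack_path: str | os.PathLike,
                     angles_path: str | os.PathLike) -> TiltSeries:
    """Read a multi-section MRC stack paired with its ``.tlt`` angles."""
    as_map = read_map(stack_path)
    images = np.moveaxis(as_map.values, -1, 0)
    angles = read_tilt_angles(angles_path)
    if images.shape[0] != angles.size:
        raise ValueError(
            f"tilt stack has {images.shape[0]} sections but angle file has "
            f"{angles.size} angles"
        )
    return TiltSeries(images, angles, as_map.voxel_size)


# ---------------------------------------------------------------------------
# atom models

def read_atom_model(path: str | os.PathLike) -> AtomModel:
    """Read ATOM/HETATM records from a PDB file.

    The element is taken from the element column when present (gemmi also
    falls back to the atom name); elements missing from the mass table get
    the mass of carbon with a logged warning so that real-world PDB files
    with exotic records still produce phantoms.
    """
    structure = gemmi.read_structure(os.fspath(path))
    elements: list[str] = []
    coords: list[tuple[float, float, float]] = []
    masses: list[float] = []
    for model in structure:
        for chain in model:
            for residue in chain:
                for atom in residue:
                    symbol = atom.element.name.upper()
                    mass = ATOMIC_MASS_DA.get(symbol)
                    if mass is None:
                        logger.warning(
                            "unknown element %r in %s; using carbon mass",
                            symbol, path,
                        )
                        symbol, mass = "C", ATOMIC_MASS_DA["C"]
                    elements.append(symbol)
                    coords.append((atom.pos.x, atom.pos.y, atom.pos.z))
                    masses.append(mass)
        break  # first model only
    if not coords:
        raise ValueError(f"no ATOM/HETATM records in {os.fspath(path)!r}")
    return AtomModel(elements, np.array(coords), np.array(masses))


# ---------------------------------------------------------------------------
# FSC tables

def write_fsc_table(table: FSCTable, path: str | os.PathLike) -> None:
    """Write an FSC curve as a two-column TSV with a one-line header."""
    with open(path, "w") as fh:
        fh.write("freq_inv_angstrom\tfsc\n")
        for f, c in zip(table.freq, table.fsc):
            fh.write(f"{f:.6g}\t{c:.6g}\n")


def read_fsc_table(path: str | os.PathLike) -> FSCTable:
    data = np.loadtxt(path, skiprows=1, ndmin=2)
    return FSCTable(data[:, 0], data[:, 1])
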