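"""Electron-density maps and the >1-sigma reliability rule.

Reads CCP4/MRC binary maps (mode 2), resolves axis order and start offsets
to one world-coordinate convention, sigma-normalizes, interpolates point
density at atom centers (trilinear), and classifies atoms/residues as
reliable when their interpolated density exceeds the sigma cutoff.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, AnalysisConfig
from .structure_model import Atom, Residue, StructureModel, first_conformer

_HEADER_BYTES = 1024
_MODE_FLOAT32 = 2


class MapFormatError(ValueError):
    """Corrupt or unsupported CCP4/MRC header; message names the field."""


class OutOfBoundsError(ValueError):
    """Point lies outside a non-periodic map's sampled extent."""


def _cell_matrices(cell: tuple[float, ...]) -> tuple[np.ndarray, np.ndarray]:
    a, b, c, alpha, beta, gamma = cell
    al, be, ga = np.radians([alpha, beta, gamma])
    cx = c * np.cos(be)
    cy = c * (np.cos(al) - np.cos(be) * np.cos(ga)) / np.sin(ga)
    cz = np.sqrt(max(c * c - cx * cx - cy * cy, 0.0))
    frac_to_cart = np.array([
        [a, b * np.cos(ga), cx],
        [0.0, b * np.sin(ga), cy],
        [0.0, 0.0, cz],
    ])
    return frac_to_cart, np.linalg.inv(frac_to_cart)


@dataclass
class DensityMap:
    """Sigma-normalizable 3-D density grid on a crystal cell.

    ``grid[i, j, k]`` samples the point at fractional coordinate
    ``((origin_voxel + (i, j, k)) / sampling)`` along the crystal x, y, z
    axes (axis permutation from the file header is already resolved).
    """

    grid: np.ndarray
    cell: tuple[float, float, float, float, float, float]
    sampling: tuple[int, int, int]
    origin_voxel: tuple[int, int, int] = (0, 0, 0)
    normalized: bool = False
    raw_mean: float | None = None
    raw_sigma: float | None = None
    axis_order: tuple[int, int, int] = (1, 2, 3)  # as read from the file

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 3 or self.grid.size == 0:
            raise MapFormatError("grid must be a non-empty 3-D array")
        self._f2c, self._c2f = _cell_matrices(self.cell)

    @property
    def periodic(self) -> tuple[bool, bool, bool]:
        """True along axes whose extent covers a full cell period."""
        return tuple(n >= s for n, s in zip(self.grid.shape, self.sampling))

    def frac_to_cart(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, dtype=float) @ self._f2c.T

    def cart_to_frac(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz, dtype=float) @ self._c2f.T

    def node_coord(self, i: int, j: int, k: int) -> np.ndarray:
        """Cartesian position of grid node (i, j, k)."""
        frac = (np.array([i, j, k], dtype=float) + self.origin_voxel) / self.sampling
        return self.frac_to_cart(frac)


def read_map(path: str | Path) -> DensityMap:
    """Read a CCP4/MRC map file (mode 2 float32)."""
    raw = Path(path).read_bytes()
    if len(raw) < _HEADER_BYTES:
        raise MapFormatError("file shorter than the 1024-byte header")
    ints = struct.unpack("<10i", raw[0:40])
    nc, nr, ns, mode, ncstart, nrstart, nsstart, nx, ny, nz = ints
    if mode != _MODE_FLOAT32:
        raise MapFormatError(f"unsupported MODE {mode} (only 2 = float32)")
    cell = struct.unpack("<6f", raw[40:64])
    mapc, mapr, maps_ = struct.unpack("<3i", raw[64:76])
    if sorted((mapc, mapr, maps_)) != [1, 2, 3]:
        raise MapFormatError(f"bad axis order MAPC/MAPR/MAPS = {(mapc, mapr, maps_)}")
    nsymbt = struct.unpack("<i", raw[92:96])[0]
    if any(n <= 0 for n in (nc, nr, ns)) or any(n <= 0 for n in (nx, ny, nz)):
        raise MapFormatError("non-positive grid dimension NC/NR/NS or NX/NY/NZ")
    n_values = nc * nr * ns
    data_start = _HEADER_BYTES + nsymbt
    data = np.frombuffer(raw, dtype="<f4", count=-1, offset=data_start)
    if data.size < n_values:
        raise MapFormatError(
            f"truncated data section: expected {n_values} values, got {data.size}")
    data = data[:n_values].reshape(ns, nr, nc).astype(float)

    # data dims are (section, row, column) = crystal axes (maps_, mapr, mapc)
    dim_of_axis = {maps_: 0, mapr: 1, mapc: 2}
    grid = np.transpose(data, axes=[dim_of_axis[ax] for ax in (1, 2, 3)])
    start_of_axis = {mapc: ncstart, mapr: nrstart, maps_: nsstart}
    origin = tuple(start_of_axis[ax] for ax in (1, 2, 3))
    return DensityMap(grid=grid, cell=tuple(float(v) for v in cell),
                      sampling=(nx, ny, nz), origin_voxel=origin,
                      axis_order=(mapc, mapr, maps_))


def write_map(dmap: DensityMap, path: str | Path,
              axis_order: tuple[int, int, int] = (1, 2, 3)) -> None:
    """Write a CCP4 mode-2 map; ``axis_order`` sets MAPC/MAPR/MAPS."""
    mapc, mapr, maps_ = axis_order
    if sorted(axis_order) != [1, 2, 3]:
        raise ValueError("axis_order must be a permutation of (1, 2, 3)")
    # place crystal axes into (section, row, column) data layout
    grid_dim_of_axis = {1: 0, 2: 1, 3: 2}
    data = np.transpose(dmap.grid, axes=[grid_dim_of_axis[ax] for ax in (maps_, mapr, mapc)])
    ns, nr, nc = data.shape
    start_of = dict(zip((1, 2, 3), dmap.origin_voxel))
    header = bytearray(_HEADER_BYTES)
    struct.pack_into("<10i", header, 0, nc, nr, ns, _MODE_FLOAT32,
                     start_of[mapc], start_of[mapr], start_of[maps_],
                     *dmap.sampling)
    struct.pack_into("<6f", header, 40, *dmap.cell)
    struct.pack_into("<3i", header, 64, mapc, mapr, maps_)
    struct.pack_into("<3f", header, 76, float(dmap.grid.min()),
                     float(dmap.grid.max()), float(dmap.grid.mean()))
    struct.pack_into("<2i", header, 88, 1, 0)  # ISPG = P1, NSYMBT = 0
    header[208:212] = b"MAP "
    struct.pack_into("<4B", header, 212, 0x44, 0x44, 0, 0)  # little-endian stamp
    struct.pack_into("<f", header, 216, float(dmap.grid.std()))
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(data.astype("<f4").tobytes())


def normalize_map(dmap: DensityMap) -> DensityMap:
    """Return the sigma-normalized map: value' = (value - mean) / sigma."""
    mean = float(dmap.grid.mean())
    sigma = float(dmap.grid.std())
    if sigma < 1e-30:
        raise MapFormatError("degenerate map: constant density cannot be normalized")
    return DensityMap(
        grid=(dmap.grid - mean) / sigma,
        cell=dmap.cell,
        sampling=dmap.sampling,
        origin_voxel=dmap.origin_voxel,
        normalized=True,
        raw_mean=dmap.raw_mean if dmap.normalized else mean,
        raw_sigma=dmap.raw_sigma if dmap.normalized else sigma,
        axis_order=dmap.axis_order,
    )


def point_density(dmap: DensityMap, xyz) -> float:
    """Trilinear interpolation of the map at a Cartesian point (sigma units
    for a normalized map); exact at grid nodes, periodic along axes that
    cover a full cell.
    """
    frac = dmap.cart_to_frac(np.asarray(xyz, dtype=float))
    g = frac * np.array(dmap.sampling) - np.array(dmap.origin_voxel)
    shape = dmap.grid.shape
    periodic = dmap.periodic
    idx0 = np.floor(g).astype(int)
    t = g - idx0
    corners = np.zeros((2, 3), dtype=int)
    for ax in range(3):
        i0, i1 = idx0[ax], idx0[ax] + 1
        if periodic[ax]:
            i0 %= dmap.sampling[ax]
            i1 %= dmap.sampling[ax]
        else:
            if g[ax] < -1e-9 or g[ax] > shape[ax] - 1 + 1e-9:
                raise OutOfBoundsError(
                    f"point {np.asarray(xyz)} outside non-periodic map extent (axis {ax})")
            i0 = min(max(i0, 0), shape[ax] - 1)
            i1 = min(i1, shape[ax] - 1)
        corners[0, ax], corners[1, ax] = i0, i1
    value = 0.0
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = ((t[0] if dx else 1 - t[0])
                     * (t[1] if dy else 1 - t[1])
                     * (t[2] if dz else 1 - t[2]))
                if w:
                    value += w * dmap.grid[corners[dx, 0], corners[dy, 1], corners[dz, 2]]
    return float(value)


@dataclass
class ReliabilityRecord:
    residue_key: tuple[str, int, str]
    res_name: str
    atom_density: dict[str, float] = field(default_factory=dict)
    atom_reliable: dict[str, bool] = field(default_factory=dict)
    residue_reliable_all: bool = False
    residue_reliable_sidechain: bool = False

    @property
    def min_sigma(self) -> float:
        return min(self.atom_density.values()) if self.atom_density else float("nan")


def atom_reliable(dmap: DensityMap, atom: Atom,
                  config: AnalysisConfig = DEFAULT_CONFIG) -> bool:
    """Strict rule: reliable iff point density > sigma cutoff (1.0 sigma)."""
    if not dmap.normalized:
        raise ValueError("map must be normalized before reliability classification")
    return point_density(dmap, atom.coord) > config.density_sigma_cutoff


def residue_reliability(dmap: DensityMap, residue: Residue,
                        config: AnalysisConfig = DEFAULT_CONFIG) -> ReliabilityRecord:
    """Classify one residue from its first conformer's heavy atoms.

    ``residue_reliable_all`` requires every heavy atom above the cutoff;
    ``residue_reliable_sidechain`` only the side-chain heavy atoms.  Atoms
    outside a non-periodic map count as unreliable (with a warning).
    """
    state = first_conformer(residue) if config.reliability_first_conformer_only else None
    atoms = state.atoms if state is not None else residue.atoms
    rec = ReliabilityRecord(residue_key=residue.key, res_name=residue.res_name)
    for atom in atoms:
        if atom.is_hydrogen:
            continue
        try:
            dens = point_density(dmap, atom.coord)
        except OutOfBoundsError:
            warnings.warn(f"atom {atom.name} of {residue} outside map; counted unreliable",
                          stacklevel=2)
            dens = float("-inf")
        rec.atom_density[atom.name] = dens
        rec.atom_reliable[atom.name] = dens > config.density_sigma_cutoff
    heavy = [n for n in rec.atom_reliable]
    side = [n for n, a in _heavy_atoms(atoms) if a.is_sidechain]
    rec.residue_reliable_all = bool(heavy) and all(rec.atom_reliable[n] for n in heavy)
    rec.residue_reliable_sidechain = all(rec.atom_reliable[n] for n in side)
    return rec


def _heavy_atoms(atoms: list[Atom]):
    return [(a.name, a) for a in atoms if not a.is_hydrogen]


def reliability_table(model: StructureModel, dmap: DensityMap,
                      config: AnalysisConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Per-residue reliability CSV-ready table over all chains."""
    rows = []
    for chain_id, chain in model.chains.items():
        for residue in chain:
            if not residue.is_amino_acid:
                continue
            rec = residue_reliability(dmap, residue, config)
            rows.append({
                "pdb_id": model.pdb_id,
                "chain": chain_id,
                "resnum": residue.seq_id[0],
                "icode": residue.seq_id[1],
                "resname": residue.res_name,
                "n_atoms": len(rec.atom_density),
                "min_sigma": rec.min_sigma,
                "reliable_all": rec.residue_reliable_all,
                "reliable_sidechain": rec.residue_reliable_sidechain,
            })
    return pd.DataFrame(rows)
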