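"""Solvent-accessible surface area (Shrake-Rupley) and exposure classes.

ASA is computed on the whole structure (all chains jointly, first
conformer, heavy atoms) and then attributed per residue/chain; a residue
is exposed at >= 1.0 A^2 absolute ASA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import DEFAULT_CONFIG, AnalysisConfig
from .structure_model import Residue, StructureModel, first_conformer
from .tables import reference_asa, vdw_radii

log = logging.getLogger(__name__)


@dataclass
class ExposureRecord:
    residue_key: tuple[str, int, str]
    res_name: str
    absolute_asa: float
    relative_asa: float | None
    exposed: bool


def sphere_points(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (golden-spiral construction)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def _collect_atoms(model: StructureModel, config: AnalysisConfig):
    """Heavy first-conformer atoms of all chains (+ optional het occluders)."""
    owners: list[tuple[Residue | None, str]] = []
    coords: list[np.ndarray] = []
    radii: list[float] = []
    table = vdw_radii(config.radii_table)
    default_r = table["*"]
    for residue in model.residues():
        for atom in first_conformer(residue).atoms:
            if atom.is_hydrogen:
                continue
            r = table.get(atom.element.upper())
            if r is None:
                log.warning("unknown element %r on %s; default radius %.2f",
                            atom.element, residue, default_r)
                r = default_r
            owners.append((residue, atom.name))
            coords.append(atom.coord)
            radii.append(r)
    if config.include_het_in_occlusion:
        for residue in model.het:
            for atom in first_conformer(residue).atoms:
                if atom.is_hydrogen:
                    continue
                owners.append((None, atom.name))
                coords.append(atom.coord)
                radii.append(table.get(atom.element.upper(), default_r))
    return owners, np.asarray(coords, dtype=float), np.asarray(radii, dtype=float)


def shrake_rupley(
    model: StructureModel,
    probe_radius: float | None = None,
    n_points: int | None = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> dict[tuple[tuple[str, int, str], str], float]:
    """Per-atom accessible surface area (A^2) keyed by (residue key, atom name).

    Test points on each solvent-extended sphere are counted accessible when
    outside every neighbor's solvent-extended sphere:
    ``area = 4 pi (r + p)^2 * accessible / total``.
    """
    probe = config.sasa_probe_radius_A if probe_radius is None else probe_radius
    n = config.sasa_n_points if n_points is None else n_points
    owners, coords, radii = _collect_atoms(model, config)
    if len(coords) == 0:
        raise ValueError("empty model: no heavy atoms for ASA")
    unit = sphere_points(n)
    extended = radii + probe
    tree = cKDTree(coords)
    max_reach = 2.0 * extended.max()
    areas: dict[tuple[tuple[str, int, str], str], float] = {}
    for i, (residue, atom_name) in enumerate(owners):
        pts = coords[i] + extended[i] * unit
        neighbor_idx = [j for j in tree.query_ball_point(coords[i], max_reach)
                        if j != i]
        accessible = np.ones(n, dtype=bool)
        for j in neighbor_idx:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > extended[j] ** 2
            if not accessible.any():
                break
        area = 4.0 * np.pi * extended[i] ** 2 * accessible.sum() / n
        if residue is not None:
            areas[(residue.key, atom_name)] = float(area)
    return areas


def residue_asa(model: StructureModel,
                config: AnalysisConfig = DEFAULT_CONFIG,
                atom_areas: dict | None = None) -> list[ExposureRecord]:
    """Sum heavy-atom areas per residue; relative ASA against the
    Gly-X-Gly reference table (None for non-standard types)."""
    if atom_areas is None:
        atom_areas = shrake_rupley(model, config=config)
    records = []
    refs = reference_asa()
    by_residue: dict[tuple, float] = {}
    for (rkey, _), v in atom_areas.items():
        by_residue[rkey] = by_residue.get(rkey, 0.0) + v
    for residue in model.residues():
        total = by_residue.get(residue.key, 0.0)
        ref = refs.get(residue.standard_parent or "")
        records.append(ExposureRecord(
            residue_key=residue.key,
            res_name=residue.res_name,
            absolute_asa=total,
            relative_asa=(total / ref) if ref else None,
            exposed=total >= config.exposure_asa_cutoff_A2,
        ))
    return records


def classify_exposure(record: ExposureRecord,
                      config: AnalysisConfig = DEFAULT_CONFIG) -> str:
    """'exposed' iff absolute ASA >= cutoff (1.0 A^2 by default)."""
    return "exposed" if record.absolute_asa >= config.exposure_asa_cutoff_A2 else "buried"


def asa_table(model: StructureModel,
              config: AnalysisConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    records = residue_asa(model, config)
    return pd.DataFrame([{
        "chain": r.residue_key[0],
        "resnum": r.residue_key[1],
        "icode": r.residue_key[2],
        "resname": r.res_name,
        "absolute_asa": r.absolute_asa,
        "relative_asa": r.relative_asa,
        "exposed": r.exposed,
    } for r in records])
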