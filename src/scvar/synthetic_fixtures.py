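"""Synthetic structures and maps with known ground truth.

Ideal-geometry chains (helical backbone), template-built side chains whose
chi torsions are set exactly, altloc injection with chosen occupancies,
variant-pair generation with labelled chi changes, and Gaussian-atom
density rendering.  Everything is deterministic given (parameters, seed).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .density_reliability import DensityMap, normalize_map
from .structure_model import Atom, ConformerState, Residue, StructureModel

HELIX_PHI = -57.0
HELIX_PSI = -47.0

# backbone internal coordinates (lengths A, angles deg)
_BB = {
    "N_CA": 1.458, "CA_C": 1.525, "C_N": 1.329, "C_O": 1.231,
    "N_CA_C": 111.2, "CA_C_N": 116.2, "C_N_CA": 121.7, "CA_C_O": 120.8,
    "OMEGA": 180.0,
    "CB": (1.530, 110.5, 122.6),  # length, angle N-CA-CB, torsion C-N-CA-CB
}

# side-chain templates: atom -> (parents (a,b,c), length, angle b-c-d, torsion rule)
# torsion rule: ("chi", k, offset_deg); the placed torsion is chi_k + offset.
SIDECHAIN_TEMPLATES: dict[str, list[tuple[str, tuple[str, str, str], float, float, tuple]]] = {
    "SER": [
        ("OG", ("N", "CA", "CB"), 1.417, 110.8, ("chi", 1, 0.0)),
    ],
    "ASP": [
        ("CG", ("N", "CA", "CB"), 1.516, 112.6, ("chi", 1, 0.0)),
        ("OD1", ("CA", "CB", "CG"), 1.249, 118.4, ("chi", 2, 0.0)),
        ("OD2", ("CA", "CB", "CG"), 1.249, 118.4, ("chi", 2, 180.0)),
    ],
    "LEU": [
        ("CG", ("N", "CA", "CB"), 1.530, 116.3, ("chi", 1, 0.0)),
        ("CD1", ("CA", "CB", "CG"), 1.521, 110.7, ("chi", 2, 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.521, 110.7, ("chi", 2, 122.6)),
    ],
    # ring as a perfect hexagon so the chi2 <-> chi2+180 flip symmetry is exact
    "PHE": [
        ("CG", ("N", "CA", "CB"), 1.502, 113.8, ("chi", 1, 0.0)),
        ("CD1", ("CA", "CB", "CG"), 1.390, 120.0, ("chi", 2, 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.390, 120.0, ("chi", 2, 180.0)),
        ("CE1", ("CB", "CG", "CD1"), 1.390, 120.0, ("fixed", 180.0)),
        ("CE2", ("CB", "CG", "CD2"), 1.390, 120.0, ("fixed", 180.0)),
        ("CZ", ("CG", "CD1", "CE1"), 1.390, 120.0, ("fixed", 0.0)),
    ],
    "LYS": [
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 1, 0.0)),
        ("CD", ("CA", "CB", "CG"), 1.520, 111.3, ("chi", 2, 0.0)),
        ("CE", ("CB", "CG", "CD"), 1.508, 111.9, ("chi", 3, 0.0)),
        ("NZ", ("CG", "CD", "CE"), 1.486, 111.7, ("chi", 4, 0.0)),
    ],
    "ARG": [
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 1, 0.0)),
        ("CD", ("CA", "CB", "CG"), 1.520, 111.3, ("chi", 2, 0.0)),
        ("NE", ("CB", "CG", "CD"), 1.461, 112.0, ("chi", 3, 0.0)),
        ("CZ", ("CG", "CD", "NE"), 1.329, 124.2, ("chi", 4, 0.0)),
        ("NH1", ("CD", "NE", "CZ"), 1.326, 120.0, ("fixed", 0.0)),
        ("NH2", ("CD", "NE", "CZ"), 1.326, 120.0, ("fixed", 180.0)),
    ],
    "MET": [
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 1, 0.0)),
        ("SD", ("CA", "CB", "CG"), 1.803, 112.7, ("chi", 2, 0.0)),
        ("CE", ("CB", "CG", "SD"), 1.791, 100.9, ("chi", 3, 0.0)),
    ],
}

TEMPLATED_TYPES = tuple(sorted(SIDECHAIN_TEMPLATES))

_ELEMENT_OF = {"C": "C", "N": "N", "O": "O", "S": "S"}


def _element(atom_name: str) -> str:
    return _ELEMENT_OF.get(atom_name[0], atom_name[0])


class NotTemplatedError(ValueError):
    """Residue type has no shipped internal-coordinate template."""


@dataclass
class GroundTruth:
    """What the generator actually built, for use as a test oracle."""

    chis: dict[tuple[str, int, str], list[list[float]]] = field(default_factory=dict)
    changed: dict[tuple[str, int, str], bool] = field(default_factory=dict)
    occupancies: dict[tuple[str, int, str], list[float]] = field(default_factory=dict)
    render_params: dict = field(default_factory=dict)


def place_atom(a, b, c, length: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension (NeRF) placement: point d with |cd| = length,
    angle(b,c,d) = angle and dihedral(a,b,c,d) = torsion."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = np.radians(angle_deg)
    chi = np.radians(torsion_deg)
    bc = c - b
    bc_hat = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc_hat)
    n_hat = n / np.linalg.norm(n)
    m_hat = np.cross(n_hat, bc_hat)
    d_local = np.array([
        -length * np.cos(theta),
        length * np.sin(theta) * np.cos(chi),
        length * np.sin(theta) * np.sin(chi),
    ])
    M = np.column_stack([bc_hat, m_hat, n_hat])
    return c + M @ d_local


def build_sidechain(
    res_type: str,
    chis,
    backbone_frame: dict[str, np.ndarray],
) -> ConformerState:
    """Place side-chain heavy atoms so measured chis equal the requested
    values exactly (to construction precision).

    ``backbone_frame`` must contain N, CA, C and CB coordinates (CB is part
    of the frame, not chi-controlled).  Fewer chis than template slots
    leave the remaining torsions at 180.
    """
    template = SIDECHAIN_TEMPLATES.get(res_type)
    if template is None:
        raise NotTemplatedError(
            f"{res_type!r} is not templated; available: {TEMPLATED_TYPES}")
    chis = list(chis)
    coords = {k: np.asarray(v, dtype=float) for k, v in backbone_frame.items()}
    for name in ("N", "CA", "CB"):
        if name not in coords:
            raise ValueError(f"backbone frame missing {name}")
    atoms = []
    for name, (pa, pb, pc), length, angle, rule in template:
        if rule[0] == "chi":
            k, offset = rule[1], rule[2]
            base = chis[k - 1] if k <= len(chis) else 180.0
            torsion = base + offset
        else:
            torsion = rule[1]
        coords[name] = place_atom(coords[pa], coords[pb], coords[pc],
                                  length, angle, torsion)
        atoms.append(Atom(name=name, element=_element(name), coord=coords[name]))
    return ConformerState(state_id="", atoms=atoms)


def _default_chis(res_type: str, rng: np.random.Generator) -> list[float]:
    n = max(rule[1] for _, _, _, _, rule in SIDECHAIN_TEMPLATES[res_type]
            if rule[0] == "chi")
    rotamer = rng.choice([-60.0, 60.0, 180.0], size=n)
    jitter = rng.normal(0.0, 5.0, size=n)
    return [float(((r + j + 180.0) % 360.0) - 180.0) for r, j in zip(rotamer, jitter)]


def make_synthetic_chain(
    n_res: int,
    residue_types: list[str] | None = None,
    chi_assignments: dict[int, list[float]] | None = None,
    seed: int = 0,
    chain_id: str = "A",
    pdb_id: str = "synt",
    resolution: float = 1.0,
    phi: float = HELIX_PHI,
    psi: float = HELIX_PSI,
) -> tuple[StructureModel, GroundTruth]:
    """Ideal helical chain with side chains at assigned or sampled chis.

    ``residue_types`` cycles over the templated set by default;
    ``chi_assignments`` maps 0-based residue index to a chi list.
    """
    if n_res < 1:
        raise ValueError("n_res must be >= 1")
    rng = np.random.default_rng(seed)
    if residue_types is None:
        residue_types = [TEMPLATED_TYPES[i % len(TEMPLATED_TYPES)] for i in range(n_res)]
    if len(residue_types) != n_res:
        raise ValueError("residue_types length must equal n_res")
    chi_assignments = chi_assignments or {}

    # backbone by natural extension
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_BB["N_CA"], 0.0, 0.0])
    th = np.radians(180.0 - _BB["N_CA_C"])
    c0 = ca0 + _BB["CA_C"] * np.array([np.cos(th), np.sin(th), 0.0])
    backbone = [{"N": n0, "CA": ca0, "C": c0}]
    for i in range(1, n_res):
        prev = backbone[-1]
        n_i = place_atom(prev["N"], prev["CA"], prev["C"], _BB["C_N"], _BB["CA_C_N"], psi)
        ca_i = place_atom(prev["CA"], prev["C"], n_i, _BB["N_CA"], _BB["C_N_CA"], _BB["OMEGA"])
        c_i = place_atom(prev["C"], n_i, ca_i, _BB["CA_C"], _BB["N_CA_C"], phi)
        backbone.append({"N": n_i, "CA": ca_i, "C": c_i})

    chain: list[Residue] = []
    truth = GroundTruth()
    for i, frame in enumerate(backbone):
        res_type = residue_types[i]
        if res_type not in SIDECHAIN_TEMPLATES and res_type not in ("GLY", "ALA"):
            raise NotTemplatedError(f"{res_type!r} is not templated")
        # carbonyl O anti to the next N: torsion N-CA-C-O = psi + 180
        o_i = place_atom(frame["N"], frame["CA"], frame["C"], _BB["C_O"],
                         _BB["CA_C_O"], psi + 180.0)
        residue = Residue(res_name=res_type, seq_id=(i + 1, ""), chain_id=chain_id)
        residue.atoms.append(Atom("N", "N", frame["N"]))
        residue.atoms.append(Atom("CA", "C", frame["CA"]))
        residue.atoms.append(Atom("C", "C", frame["C"]))
        residue.atoms.append(Atom("O", "O", o_i))
        if res_type != "GLY":
            cb_len, cb_ang, cb_tor = _BB["CB"]
            cb = place_atom(frame["C"], frame["N"], frame["CA"], cb_len, cb_ang, cb_tor)
            residue.atoms.append(Atom("CB", "C", cb))
            if res_type in SIDECHAIN_TEMPLATES:
                chis = chi_assignments.get(i) or _default_chis(res_type, rng)
                state = build_sidechain(res_type, chis,
                                        {"N": frame["N"], "CA": frame["CA"],
                                         "C": frame["C"], "CB": cb})
                residue.atoms.extend(state.atoms)
                truth.chis[(chain_id, i + 1, "")] = [list(chis)]
        chain.append(residue)

    model = StructureModel(pdb_id=pdb_id, resolution=resolution,
                           chains={chain_id: chain})
    return model, truth


def _eligible(residue: Residue) -> bool:
    return residue.res_name in SIDECHAIN_TEMPLATES


def make_variant_pair(
    model: StructureModel,
    change_fraction: float,
    seed: int = 0,
    truth: GroundTruth | None = None,
) -> tuple[StructureModel, GroundTruth]:
    """Copy of ``model`` with exactly round(f * n_eligible) residues rebuilt
    at a chi1 rotated by 120 degrees (changed under the 30-degree rule even
    after symmetric flips); all other coordinates are untouched.  Returns
    the variant model and the change labels."""
    if not 0.0 <= change_fraction <= 1.0:
        raise ValueError("change_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    variant = copy.deepcopy(model)
    out = GroundTruth(render_params={"change_fraction": change_fraction, "seed": seed})
    eligible = [r for r in variant.residues() if _eligible(r)]
    n_change = round(change_fraction * len(eligible))
    chosen = set(rng.choice(len(eligible), size=n_change, replace=False).tolist()) \
        if n_change else set()
    from .chi_geometry import measure_chis  # local import avoids a cycle

    for idx, residue in enumerate(eligible):
        key = residue.key
        state = ConformerState(state_id="", atoms=residue.atoms)
        chis = measure_chis(state, residue.res_name).chis
        chis = [c if c is not None else 180.0 for c in chis]
        out.changed[key] = idx in chosen
        if idx not in chosen:
            continue
        new_chis = list(chis)
        new_chis[0] = ((chis[0] + 120.0 + 180.0) % 360.0) - 180.0
        frame = {n: state.coord(n) for n in ("N", "CA", "C", "CB")}
        rebuilt = build_sidechain(residue.res_name, new_chis, frame)
        new_coords = {a.name: a.coord for a in rebuilt.atoms}
        for atom in residue.atoms:
            if atom.name in new_coords:
                atom.coord = new_coords[atom.name]
        out.chis[key] = [new_chis]
    return variant, out


def inject_altlocs(
    model: StructureModel,
    residue_keys: list[tuple[str, int, str]],
    chi_deltas: dict[tuple[str, int, str], list[list[float]]],
    occupancies: dict[tuple[str, int, str], list[float]],
) -> StructureModel:
    """Give named residues extra conformer states with chi shifts.

    For each key, ``chi_deltas[key]`` lists the per-state chi offset
    vectors for states 2..k (state 1 keeps the original chis) and
    ``occupancies[key]`` gives all k state occupancies (sum <= 1).  The
    original side-chain atoms become altloc 'A'; new states get 'B', 'C'...
    """
    variant = copy.deepcopy(model)
    from .chi_geometry import measure_chis

    by_key = {r.key: r for r in variant.residues()}
    for key in residue_keys:
        residue = by_key.get(key)
        if residue is None:
            raise KeyError(f"residue {key} not in model")
        if not _eligible(residue):
            raise NotTemplatedError(f"{residue.res_name} is not templated")
        deltas = chi_deltas[key]
        occs = occupancies[key]
        if len(occs) != len(deltas) + 1:
            raise ValueError(f"{key}: need one occupancy per state "
                             f"({len(deltas) + 1}), got {len(occs)}")
        if sum(occs) > 1.0 + 1e-9:
            raise ValueError(f"{key}: occupancies sum to {sum(occs):.3f} > 1")
        state = ConformerState(state_id="", atoms=residue.atoms)
        base_chis = [c if c is not None else 180.0
                     for c in measure_chis(state, residue.res_name).chis]
        frame = {n: state.coord(n) for n in ("N", "CA", "C", "CB")}
        sidechain_names = {a[0] for a in SIDECHAIN_TEMPLATES[residue.res_name]}
        letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
        for atom in residue.atoms:
            if atom.name in sidechain_names:
                atom.altloc = "A"
                atom.occupancy = occs[0]
        for s, delta in enumerate(deltas, start=1):
            new_chis = [((c + d + 180.0) % 360.0) - 180.0
                        for c, d in zip(base_chis, list(delta) + [0.0] * len(base_chis))]
            rebuilt = build_sidechain(residue.res_name, new_chis, frame)
            for atom in rebuilt.atoms:
                atom.altloc = letters[s]
                atom.occupancy = occs[s]
                atom.element = _element(atom.name)
            residue.atoms.extend(rebuilt.atoms)
    return variant


def render_density(
    model: StructureModel,
    grid_spacing: float = 0.5,
    atom_sigma: float = 0.8,
    noise_sigma: float = 0.0,
    seed: int = 0,
    padding: float | None = None,
) -> DensityMap:
    """Occupancy-weighted Gaussian-atom density, sigma-normalized.

    rho(x) = sum_atoms occupancy * exp(-|x - r|^2 / (2 sigma^2)) + noise.
    The grid covers the bounding box plus padding (>= 3 atom sigmas) and is
    treated as one full periodic cell.
    """
    atoms = [a for a in model.all_atoms() if not a.is_hydrogen]
    if not atoms:
        raise ValueError("cannot render density for an empty model")
    pad = max(3.0 * atom_sigma, padding or 0.0)
    coords = np.array([a.coord for a in atoms])
    occ = np.array([a.occupancy for a in atoms])
    # snap the grid origin to an integer voxel so CCP4 start offsets are exact
    lo = np.floor((coords.min(axis=0) - pad) / grid_spacing) * grid_spacing
    hi = coords.max(axis=0) + pad
    n = np.maximum(np.ceil((hi - lo) / grid_spacing).astype(int), 2)
    if np.any(n <= 0):
        raise ValueError("zero-size grid")
    cell = (*(n * grid_spacing), 90.0, 90.0, 90.0)
    axes = [lo[ax] + np.arange(n[ax]) * grid_spacing for ax in range(3)]
    grid = np.zeros(tuple(n))
    cut = 4.0 * atom_sigma
    inv2s2 = 1.0 / (2.0 * atom_sigma**2)
    for pos, w in zip(coords, occ):
        sub = []
        dists = []
        for ax in range(3):
            mask = np.abs(axes[ax] - pos[ax]) <= cut
            idx = np.nonzero(mask)[0]
            sub.append(idx)
            dists.append(axes[ax][idx] - pos[ax])
        if any(len(s) == 0 for s in sub):
            continue
        dx2 = dists[0][:, None, None] ** 2 + dists[1][None, :, None] ** 2 \
            + dists[2][None, None, :] ** 2
        grid[np.ix_(*sub)] += w * np.exp(-dx2 * inv2s2)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        grid = grid + rng.normal(0.0, noise_sigma, size=grid.shape)
    # origin voxel such that node (0,0,0) sits at `lo`
    origin = np.round(lo / grid_spacing).astype(int)
    raw = DensityMap(grid=grid, cell=cell, sampling=tuple(int(x) for x in n),
                     origin_voxel=tuple(int(x) for x in origin))
    return normalize_map(raw)
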