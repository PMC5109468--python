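"""Side-chain and backbone dihedral measurement and comparison.

Implements the survey's geometric core: signed torsions, the strict
more-than-30-degrees change rule with 180-degree flips for residues whose
terminal group is chemically symmetric (Asp, Glu, Phe, Tyr and, following
the survey convention, Arg), Kabsch superposition and a sequence-paired
TM-score used for pair curation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import DEFAULT_CONFIG, AnalysisConfig
from .structure_model import ConformerState, Residue, first_conformer
from .tables import chi_quadruples, terminal_flip_index

PEPTIDE_BOND_MAX_A = 2.5  # C(i)-N(i+1) distance beyond which the chain is broken


class DihedralUndefinedError(ValueError):
    """Raised when four points do not define a torsion (collinear segment)."""


@dataclass
class DihedralSet:
    """Measured torsions of one conformer: chi list plus backbone phi/psi.

    Undefined angles (missing atoms, chain termini) are ``None``.
    """

    chis: list[float | None] = field(default_factory=list)
    phi: float | None = None
    psi: float | None = None

    @property
    def n_defined(self) -> int:
        return sum(1 for c in self.chis if c is not None)


@dataclass
class ChiComparison:
    """Outcome of comparing two conformers of the same residue type."""

    res_name: str
    diffs: list[float | None]
    same_chi1: bool
    same_chi12: bool
    same_all: bool
    changed: bool
    incomparable: bool

    @property
    def n_shared(self) -> int:
        return sum(1 for d in self.diffs if d is not None)


@dataclass
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    tm_score: float | None = None
    d0: float | None = None

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle in degrees, range (-180, 180].

    Sign convention: ``atan2((n1 x n2) . b2_hat, n1 . n2)`` with
    ``n1 = b1 x b2``, ``n2 = b2 x b3``.  Invariant under rigid transforms.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2_norm = np.linalg.norm(b2)
    if b2_norm < 1e-10:
        raise DihedralUndefinedError("central bond has zero length")
    scale = max(np.linalg.norm(b1), 1e-300) * max(np.linalg.norm(b3), 1e-300) * b2_norm**2
    if np.linalg.norm(n1) < 1e-9 * np.sqrt(scale) or np.linalg.norm(n2) < 1e-9 * np.sqrt(scale):
        raise DihedralUndefinedError("collinear points do not define a torsion")
    angle = np.degrees(np.arctan2(np.dot(np.cross(n1, n2), b2 / b2_norm), np.dot(n1, n2)))
    if angle <= -180.0:
        angle += 360.0
    return float(angle)


def angle_diff(a: float, b: float) -> float:
    """Circular distance between two angles, in [0, 180] degrees."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def chi_diff(
    res_name: str,
    chi_index: int,
    a: float,
    b: float,
    config: AnalysisConfig = DEFAULT_CONFIG,
    terminal_index: int | None = None,
) -> float:
    """Flip-aware chi difference for 1-based ``chi_index`` of ``res_name``.

    For the terminal chi of a symmetric residue the closer of ``b`` and
    ``b + 180`` is used.  ``terminal_index`` overrides the shipped table's
    flip position (used for Arg when its nominal terminal chi is missing).
    """
    if not 1 <= chi_index <= len(chi_quadruples().get(res_name, [])):
        raise ValueError(f"chi index {chi_index} invalid for {res_name}")
    plain = angle_diff(a, b)
    if res_name not in config.symmetric_residues:
        return plain
    if res_name == "ARG" and not config.flip_arg_terminal_chi:
        return plain
    flip_at = terminal_index if terminal_index is not None else terminal_flip_index().get(res_name)
    if flip_at != chi_index:
        return plain
    return min(plain, angle_diff(a, b + 180.0))


def measure_chis(state: ConformerState, res_name: str) -> DihedralSet:
    """Measure the standard chi torsions of one conformer.

    Quadruples with any missing atom yield ``None`` for that chi (and all
    chis are attempted independently, so a missing mid-chain atom knocks
    out every torsion that references it).  Gly/Ala yield an empty list.
    """
    quads = chi_quadruples().get(res_name)
    if quads is None:
        raise ValueError(f"non-standard residue type {res_name!r}")
    chis: list[float | None] = []
    for quad in quads:
        coords = [state.coord(name) for name in quad]
        if any(c is None for c in coords):
            chis.append(None)
            continue
        try:
            chis.append(dihedral(*coords))
        except DihedralUndefinedError:
            chis.append(None)
    return DihedralSet(chis=chis)


def measure_phi_psi(chain: list[Residue]) -> list[tuple[float | None, float | None]]:
    """Backbone (phi, psi) per residue, first-conformer coordinates.

    Phi is undefined for the first residue and after a chain break
    (C(i-1)-N(i) farther than 2.5 A); psi symmetrically at the end / before
    a break.
    """
    frames = []
    for residue in chain:
        state = first_conformer(residue)
        frames.append({name: state.coord(name) for name in ("N", "CA", "C")})
    bonded = []
    for i in range(len(chain) - 1):
        c_prev, n_next = frames[i]["C"], frames[i + 1]["N"]
        bonded.append(
            c_prev is not None
            and n_next is not None
            and float(np.linalg.norm(n_next - c_prev)) <= PEPTIDE_BOND_MAX_A
        )
    out: list[tuple[float | None, float | None]] = []
    for i, frame in enumerate(frames):
        phi = psi = None
        n, ca, c = frame["N"], frame["CA"], frame["C"]
        if i > 0 and bonded[i - 1] and all(
                v is not None for v in (frames[i - 1]["C"], n, ca, c)):
            try:
                phi = dihedral(frames[i - 1]["C"], n, ca, c)
            except DihedralUndefinedError:
                phi = None
        if i < len(frames) - 1 and bonded[i] and all(
                v is not None for v in (n, ca, c, frames[i + 1]["N"])):
            try:
                psi = dihedral(n, ca, c, frames[i + 1]["N"])
            except DihedralUndefinedError:
                psi = None
        out.append((phi, psi))
    return out


def compare_conformers(
    a: DihedralSet,
    b: DihedralSet,
    res_name: str,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> ChiComparison:
    """Apply the strict >30-degree change rule over the chis defined in both.

    A residue pair with chi1 undefined on either side is marked
    incomparable and excluded from all percentages downstream.  The flags
    are monotone: same_all implies same_chi12 implies same_chi1.
    """
    n = len(chi_quadruples().get(res_name, []))
    if len(a.chis) != n or len(b.chis) != n:
        raise ValueError(f"chi sets do not match residue type {res_name}")
    shared = [i for i in range(n) if a.chis[i] is not None and b.chis[i] is not None]
    # Arg's flip lands on its last chi measured on both sides
    term_override = (max(shared) + 1) if (res_name == "ARG" and shared) else None
    diffs: list[float | None] = [None] * n
    for i in shared:
        diffs[i] = chi_diff(res_name, i + 1, a.chis[i], b.chis[i], config,
                            terminal_index=term_override)
    cutoff = config.chi_change_cutoff_deg
    if n == 0 or 0 not in shared:
        incomparable = n > 0  # Gly/Ala trivially identical, not incomparable
        same = not incomparable
        return ChiComparison(res_name, diffs, same, same, same, False, incomparable)
    same_chi1 = diffs[0] <= cutoff
    same_chi12 = same_chi1 and (1 not in shared or diffs[1] <= cutoff)
    same_all = same_chi1 and all(diffs[i] <= cutoff for i in shared)
    return ChiComparison(res_name, diffs, same_chi1, same_chi12, same_all,
                         changed=not same_all, incomparable=False)


def kabsch_superpose(P: np.ndarray, Q: np.ndarray) -> SuperpositionResult:
    """Least-squares superposition of point set P onto Q (Kabsch).

    Returns the proper rotation R and translation t minimizing
    ``|| (P @ R.T + t) - Q ||`` and the post-fit RMSD.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must be matched N x 3 arrays")
    if len(P) < 3:
        raise ValueError("need at least 3 matched points")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def tm_d0(l_target: int) -> float:
    """TM-score normalization length with a 0.5 A floor for short chains."""
    if l_target > 15:
        d0 = 1.24 * (l_target - 15) ** (1.0 / 3.0) - 1.8
    else:
        d0 = 0.5
    return max(d0, 0.5)


def tm_score(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    l_target: int | None = None,
    max_iter: int = 20,
) -> SuperpositionResult:
    """TM-score of pre-paired CA coordinates, normalized by ``l_target``.

    ``coords_a``/``coords_b`` are the matched CA positions (pairing comes
    from sequence alignment upstream).  The superposition is refined
    iteratively: fit on the currently included pairs, re-include pairs with
    distance < max(d0, 3 A), stop when the included set repeats.  The final
    score sums over every pair; ``l_target`` defaults to the number of
    residues of the first (reference) chain, i.e. ``len(coords_a)`` when
    all its residues are paired.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2:
        raise ValueError("coordinate arrays must be matched N x 3")
    if len(A) < 3:
        raise ValueError("pairing shorter than 3 residues")
    if l_target is None:
        l_target = len(A)
    d0 = tm_d0(l_target)
    include_cut = max(d0, 3.0)

    included = np.ones(len(A), dtype=bool)
    best = kabsch_superpose(A, B)
    for _ in range(max_iter):
        sup = kabsch_superpose(A[included], B[included])
        dists = np.linalg.norm(A @ sup.rotation.T + sup.translation - B, axis=1)
        new = dists < include_cut
        if new.sum() < 3:
            best = sup
            break
        best = sup
        if np.array_equal(new, included):
            break
        # ties toward the larger included set
        if new.sum() == included.sum() and not np.array_equal(new, included):
            included = new | included if (new | included).sum() >= 3 else new
        else:
            included = new
    dists = np.linalg.norm(A @ best.rotation.T + best.translation - B, axis=1)
    tm = float(np.sum(1.0 / (1.0 + (dists / d0) ** 2)) / l_target)
    rmsd = float(np.sqrt(np.mean(dists**2)))
    return SuperpositionResult(rotation=best.rotation, translation=best.translation,
                               rmsd=rmsd, tm_score=tm, d0=d0)
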