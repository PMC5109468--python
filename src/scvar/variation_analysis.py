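"""Survey engine: pair residues across altloc states, chains and crystals,
classify side-chain conformational variation, attribute backbone effects,
and aggregate per-structure statistics into resolution/type/exposure tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .chi_geometry import (
    ChiComparison,
    angle_diff,
    compare_conformers,
    kabsch_superpose,
    measure_chis,
    measure_phi_psi,
    tm_score,
    SuperpositionResult,
)
from .config import DEFAULT_CONFIG, AnalysisConfig
from .structure_model import (
    Residue,
    StructureModel,
    chain_sequence,
    first_conformer,
    group_conformers,
)
from .tables import n_chi

log = logging.getLogger(__name__)

RESOLUTION_BINS = ((0.0, 1.0), (1.0, 2.0), (2.0, 3.0), (3.0, 3.5))


@dataclass
class AlignmentResult:
    """Global alignment as matched index columns plus percent identity."""

    columns: list[tuple[int | None, int | None]]
    identity_pct: float
    score: float


def align_sequences(s1: str, s2: str) -> AlignmentResult:
    """Needleman-Wunsch global alignment (BLOSUM62, gap open 10, extend 0.5).

    Identity = identical residues / aligned columns, excluding terminal
    gap columns from the denominator.
    """
    if not s1 or not s2:
        raise ValueError("cannot align an empty sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    alignment = aligner.align(s1, s2)[0]
    columns: list[tuple[int | None, int | None]] = []
    for (a_idx, b_idx) in zip(*alignment.indices):
        columns.append((None if a_idx < 0 else int(a_idx),
                        None if b_idx < 0 else int(b_idx)))
    # trim terminal gap columns from the identity denominator
    first = 0
    last = len(columns)
    while first < last and (columns[first][0] is None or columns[first][1] is None):
        first += 1
    while last > first and (columns[last - 1][0] is None or columns[last - 1][1] is None):
        last -= 1
    core = columns[first:last]
    n_ident = sum(1 for i, j in core
                  if i is not None and j is not None and s1[i] == s2[j])
    identity = 100.0 * n_ident / len(core) if core else 0.0
    return AlignmentResult(columns=columns, identity_pct=identity,
                           score=float(alignment.score))


def pair_residues(
    chain_a: list[Residue],
    chain_b: list[Residue],
    alignment: AlignmentResult,
) -> list[tuple[Residue, Residue, bool]]:
    """Matched residue pairs from alignment columns with residues on both
    sides; the flag marks residue-type agreement (mutation columns are kept
    but flagged, for the sequence-difference analysis)."""
    res_a, res_b = list(chain_a), list(chain_b)  # one letter per residue
    pairs = []
    for i, j in alignment.columns:
        if i is None or j is None:
            continue
        ra, rb = res_a[i], res_b[j]
        pairs.append((ra, rb, ra.standard_parent == rb.standard_parent))
    return pairs


@dataclass
class CurationResult:
    accepted: bool
    reason: str | None
    identity_pct: float | None = None
    superposition: SuperpositionResult | None = None
    pairing: list[tuple[Residue, Residue, bool]] = field(default_factory=list)


def pdb_id_distance(id_a: str, id_b: str) -> int:
    """Hamming distance over the 4-character PDB ids (case-insensitive)."""
    a, b = id_a.lower().strip(), id_b.lower().strip()
    if len(a) != len(b):
        return max(len(a), len(b))
    return sum(1 for x, y in zip(a, b) if x != y)


def curate_pair(
    model_a: StructureModel,
    model_b: StructureModel,
    chain_a: str,
    chain_b: str,
    config: AnalysisConfig = DEFAULT_CONFIG,
    same_crystal: bool = False,
) -> CurationResult:
    """Accept a chain pair for comparison per the survey criteria.

    Checks, in order: resolution present and within cutoff, chain length,
    pdb-id rule (same id for same-crystal mode, more than two letters
    different for cross-crystal), sequence identity, TM-score and RMSD.
    """
    for model in (model_a, model_b):
        if model.resolution is None:
            return CurationResult(False, "resolution missing")
        if model.resolution > config.resolution_max_A:
            return CurationResult(False, "resolution")
    ca, cb = model_a.chains.get(chain_a), model_b.chains.get(chain_b)
    if ca is None or cb is None:
        return CurationResult(False, "chain missing")
    seq_a, seq_b = chain_sequence(ca), chain_sequence(cb)
    if len(seq_a) <= config.min_length_aa or len(seq_b) <= config.min_length_aa:
        return CurationResult(False, "length")
    if same_crystal:
        if model_a.pdb_id and model_b.pdb_id and model_a.pdb_id != model_b.pdb_id:
            return CurationResult(False, "pdb id (expected same crystal)")
    else:
        # "different PDB structures": ids must differ in at least two
        # positions (the canonical cross-crystal exemplars, e.g. 2pa8/2pmz,
        # differ in exactly two)
        if pdb_id_distance(model_a.pdb_id, model_b.pdb_id) < 2:
            return CurationResult(False, "pdb id (fewer than two letters differ)")
    alignment = align_sequences(seq_a, seq_b)
    if alignment.identity_pct < config.pair_identity_min_pct:
        return CurationResult(False, "identity", identity_pct=alignment.identity_pct)
    pairing = pair_residues(ca, cb, alignment)
    coords = [(first_conformer(ra).coord("CA"), first_conformer(rb).coord("CA"))
              for ra, rb, _ in pairing]
    coords = [(p, q) for p, q in coords if p is not None and q is not None]
    if len(coords) < 3:
        return CurationResult(False, "too few matched CA atoms",
                              identity_pct=alignment.identity_pct)
    P = np.array([p for p, _ in coords])
    Q = np.array([q for _, q in coords])
    sup = tm_score(P, Q, l_target=len(seq_a) if config.tm_normalize_by == "first"
                   else (min(len(seq_a), len(seq_b)) if config.tm_normalize_by == "shorter"
                         else max(len(seq_a), len(seq_b))))
    if sup.tm_score <= config.tm_cutoff:
        return CurationResult(False, "tm", identity_pct=alignment.identity_pct,
                              superposition=sup, pairing=pairing)
    if sup.rmsd >= config.rmsd_cutoff_A:
        return CurationResult(False, "rmsd", identity_pct=alignment.identity_pct,
                              superposition=sup, pairing=pairing)
    return CurationResult(True, None, identity_pct=alignment.identity_pct,
                          superposition=sup, pairing=pairing)


@dataclass
class ComparisonRecord:
    """One residue-level comparison (altloc pair, chain pair or crystal pair)."""

    kind: str  # "altloc" | "same-crystal" | "cross-crystal"
    structure_id: str
    res_key_a: tuple[str, int, str]
    res_key_b: tuple[str, int, str] | None
    res_name: str
    chi: ChiComparison
    backbone_changed: bool | None = None
    exposed_a: bool | None = None
    exposed_b: bool | None = None
    reliable_a: bool | None = None
    reliable_b: bool | None = None
    resolution: float | None = None
    type_match: bool = True

    @property
    def comparable(self) -> bool:
        return not self.chi.incomparable and self.type_match and n_chi(self.res_name) > 0


def altloc_variation(
    residue: Residue,
    config: AnalysisConfig = DEFAULT_CONFIG,
    structure_id: str = "",
    resolution: float | None = None,
) -> ComparisonRecord | None:
    """Residue-level variation across its alternate-location states.

    All unordered state pairs are compared; the residue keeps chi1 (or
    chi1+2, or all chis) only when every pair agrees, and is changed when
    any pair is changed.  Returns None when fewer than two states have a
    measurable chi1.
    """
    parent = residue.standard_parent
    if parent is None or n_chi(parent) == 0:
        return None
    states = group_conformers(residue)
    dihedrals = []
    for state in states:
        ds = measure_chis(state, parent)
        if ds.chis and ds.chis[0] is not None:
            dihedrals.append(ds)
    if len(dihedrals) < 2:
        return None
    comparisons = [
        compare_conformers(dihedrals[i], dihedrals[j], parent, config)
        for i in range(len(dihedrals)) for j in range(i + 1, len(dihedrals))
    ]
    merged = ChiComparison(
        res_name=parent,
        diffs=[max((c.diffs[k] for c in comparisons if c.diffs[k] is not None),
                   default=None)
               for k in range(n_chi(parent))],
        same_chi1=all(c.same_chi1 for c in comparisons),
        same_chi12=all(c.same_chi12 for c in comparisons),
        same_all=all(c.same_all for c in comparisons),
        changed=any(c.changed for c in comparisons),
        incomparable=all(c.incomparable for c in comparisons),
    )
    return ComparisonRecord(kind="altloc", structure_id=structure_id,
                            res_key_a=residue.key, res_key_b=None,
                            res_name=parent, chi=merged, resolution=resolution)


def _has_sidechain_altloc(residue: Residue) -> bool:
    return any(a.altloc for a in residue.atoms)


def pair_variation(
    chain_a: list[Residue],
    chain_b: list[Residue],
    pairing: list[tuple[Residue, Residue, bool]],
    config: AnalysisConfig = DEFAULT_CONFIG,
    kind: str = "same-crystal",
    structure_id: str = "",
    resolution: float | None = None,
    reliability: dict[tuple[str, int, str], bool] | None = None,
    exposure: dict[tuple[str, int, str], bool] | None = None,
) -> list[ComparisonRecord]:
    """Per-residue comparison records for a curated chain pair.

    Residues carrying alternate locations on either side, or known to be
    density-unreliable, are excluded (the survey convention); Gly/Ala are
    skipped (no chi).  ``reliability``/``exposure`` are optional lookups by
    residue key.
    """
    phi_psi_a = dict(zip((r.key for r in chain_a), measure_phi_psi(chain_a)))
    phi_psi_b = dict(zip((r.key for r in chain_b), measure_phi_psi(chain_b)))
    reliability = reliability or {}
    exposure = exposure or {}
    records = []
    for ra, rb, type_match in pairing:
        parent = ra.standard_parent
        if parent is None or n_chi(parent) == 0:
            continue
        if _has_sidechain_altloc(ra) or _has_sidechain_altloc(rb):
            continue
        rel_a = reliability.get(ra.key)
        rel_b = reliability.get(rb.key)
        if rel_a is False or rel_b is False:
            continue
        if not type_match:
            records.append(ComparisonRecord(
                kind=kind, structure_id=structure_id, res_key_a=ra.key,
                res_key_b=rb.key, res_name=parent,
                chi=ChiComparison(parent, [None] * n_chi(parent),
                                  False, False, False, False, True),
                type_match=False, resolution=resolution,
                reliable_a=rel_a, reliable_b=rel_b,
                exposed_a=exposure.get(ra.key), exposed_b=exposure.get(rb.key)))
            continue
        chi = compare_conformers(
            measure_chis(first_conformer(ra), parent),
            measure_chis(first_conformer(rb), parent),
            parent, config)
        backbone_changed = None
        pa, pb = phi_psi_a.get(ra.key), phi_psi_b.get(rb.key)
        if pa and pb:
            deltas = [angle_diff(x, y) for x, y in zip(pa, pb)
                      if x is not None and y is not None]
            if len(deltas) == 2:
                backbone_changed = any(d > config.backbone_change_cutoff_deg
                                       for d in deltas)
        records.append(ComparisonRecord(
            kind=kind, structure_id=structure_id, res_key_a=ra.key,
            res_key_b=rb.key, res_name=parent, chi=chi,
            backbone_changed=backbone_changed,
            exposed_a=exposure.get(ra.key), exposed_b=exposure.get(rb.key),
            reliable_a=rel_a, reliable_b=rel_b, resolution=resolution))
    return records


def resolution_bin(resolution: float | None) -> str | None:
    if resolution is None:
        return None
    for lo, hi in RESOLUTION_BINS:
        if lo <= resolution < hi or (hi == RESOLUTION_BINS[-1][1] and resolution == hi):
            return f"{lo:.1f}-{hi:.1f}"
    return None


def records_frame(records: list[ComparisonRecord]) -> pd.DataFrame:
    """Flat per-record table (TSV-ready)."""
    rows = []
    for r in records:
        rows.append({
            "kind": r.kind,
            "structure_id": r.structure_id,
            "chain_a": r.res_key_a[0], "resnum_a": r.res_key_a[1],
            "chain_b": r.res_key_b[0] if r.res_key_b else "",
            "resnum_b": r.res_key_b[1] if r.res_key_b else "",
            "res_name": r.res_name,
            "comparable": r.comparable,
            "same_chi1": r.chi.same_chi1,
            "same_chi12": r.chi.same_chi12,
            "same_all": r.chi.same_all,
            "changed": r.chi.changed,
            "backbone_changed": r.backbone_changed,
            "exposed_a": r.exposed_a, "exposed_b": r.exposed_b,
            "resolution": r.resolution,
            "type_match": r.type_match,
        })
    return pd.DataFrame(rows)


def aggregate_survey(
    records: list[ComparisonRecord],
    grouping: str = "resolution",
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Mean +/- SD of per-structure percentages within each group.

    Percentages (same chi1 / chi1+2 / all, changed, backbone-changed) are
    computed per structure first, then averaged within the group; the SD is
    across structures (population SD unless ``config.sample_sd``).
    Grouping: "resolution" (survey bins), "residue_type" or "exposure".
    """
    usable = [r for r in records if r.comparable]
    if not usable:
        return pd.DataFrame()

    def group_key(r: ComparisonRecord) -> str | None:
        if grouping == "resolution":
            return resolution_bin(r.resolution)
        if grouping == "residue_type":
            return r.res_name
        if grouping == "exposure":
            if r.exposed_a is None:
                return None
            return "exposed" if r.exposed_a else "buried"
        raise ValueError(f"unknown grouping {grouping!r}")

    per_structure: dict[tuple[str, str], dict[str, int]] = {}
    for r in usable:
        g = group_key(r)
        if g is None:
            continue
        cell = per_structure.setdefault((g, r.structure_id), {
            "n": 0, "same_chi1": 0, "same_chi12": 0, "same_all": 0,
            "changed": 0, "backbone_n": 0, "backbone_changed": 0})
        cell["n"] += 1
        cell["same_chi1"] += r.chi.same_chi1
        cell["same_chi12"] += r.chi.same_chi12
        cell["same_all"] += r.chi.same_all
        cell["changed"] += r.chi.changed
        if r.backbone_changed is not None:
            cell["backbone_n"] += 1
            cell["backbone_changed"] += r.backbone_changed

    groups: dict[str, list[dict]] = {}
    for (g, sid), cell in per_structure.items():
        pct = {
            "structure_id": sid,
            "n": cell["n"],
            "pct_same_chi1": 100.0 * cell["same_chi1"] / cell["n"],
            "pct_same_chi12": 100.0 * cell["same_chi12"] / cell["n"],
            "pct_same_all": 100.0 * cell["same_all"] / cell["n"],
            "pct_changed": 100.0 * cell["changed"] / cell["n"],
            "pct_backbone_changed": (100.0 * cell["backbone_changed"] / cell["backbone_n"]
                                     if cell["backbone_n"] else np.nan),
        }
        groups.setdefault(g, []).append(pct)

    ddof = 1 if config.sample_sd else 0
    rows = []
    for g in sorted(groups):
        cells = groups[g]
        row: dict = {"group": g, "n_structures": len(cells),
                     "n_records": sum(c["n"] for c in cells)}
        for stat in ("pct_same_chi1", "pct_same_chi12", "pct_same_all",
                     "pct_changed", "pct_backbone_changed"):
            vals = np.array([c[stat] for c in cells], dtype=float)
            vals = vals[~np.isnan(vals)]
            if len(vals) == 0:
                row[f"mean_{stat}"] = np.nan
                row[f"sd_{stat}"] = np.nan
            else:
                row[f"mean_{stat}"] = float(vals.mean())
                row[f"sd_{stat}"] = float(vals.std(ddof=ddof)) if len(vals) > ddof else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def altloc_occurrence_table(models: list[StructureModel]) -> pd.DataFrame:
    """Residue-type occurrence for all residues vs altloc-bearing residues."""
    total: dict[str, int] = {}
    with_alt: dict[str, int] = {}
    for model in models:
        for residue in model.residues():
            parent = residue.standard_parent
            if parent is None:
                continue
            total[parent] = total.get(parent, 0) + 1
            if _has_sidechain_altloc(residue):
                with_alt[parent] = with_alt.get(parent, 0) + 1
    n_total = sum(total.values())
    n_alt = sum(with_alt.values())
    rows = []
    for res in sorted(total):
        rows.append({
            "res_name": res,
            "count_all": total[res],
            "count_altloc": with_alt.get(res, 0),
            "pct_of_all": 100.0 * total[res] / n_total if n_total else np.nan,
            "pct_of_altloc": (100.0 * with_alt.get(res, 0) / n_alt) if n_alt else np.nan,
        })
    return pd.DataFrame(rows)


def flexibility_estimate(
    pct_altloc: float,
    pct_certain_residues: float,
    pct_cross_structure_changed: float | None = None,
) -> float:
    """Headline flexibility arithmetic: altloc% + (100 - certain%)
    [+ cross-structure-changed% when provided]."""
    values = [pct_altloc, pct_certain_residues]
    if pct_cross_structure_changed is not None:
        values.append(pct_cross_structure_changed)
    for v in values:
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"percentage {v} outside [0, 100]")
    estimate = pct_altloc + (100.0 - pct_certain_residues)
    if pct_cross_structure_changed is not None:
        estimate += pct_cross_structure_changed
    return estimate
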