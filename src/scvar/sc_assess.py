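"""Multi-conformer, density-aware assessment of side-chain predictions.

Three ideas: (1) drop residues whose native density is unreliable,
(2) score each predicted residue against the *closest* native conformer
drawn from all altloc states of all supplied native structures (never just
state 'A'), (3) an orthogonal map-based score summing interpolated point
density over the predicted side-chain atoms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .chi_geometry import DihedralSet, chi_diff, measure_chis
from .config import DEFAULT_CONFIG, AnalysisConfig
from .density_reliability import DensityMap, OutOfBoundsError, point_density, residue_reliability
from .structure_model import (
    Residue,
    StructureModel,
    chain_sequence,
    first_conformer,
    group_conformers,
)
from .tables import n_chi
from .variation_analysis import align_sequences


@dataclass
class EnsembleConformer:
    dihedrals: DihedralSet
    provenance: str  # e.g. "4mv2:A:6:B"
    reliable: bool | None = None


@dataclass
class EnsembleEntry:
    res_name: str
    conformers: list[EnsembleConformer] = field(default_factory=list)


@dataclass
class NativeEnsemble:
    """Per-position native conformer sets keyed by reference-chain index."""

    reference_sequence: str
    entries: dict[int, EnsembleEntry] = field(default_factory=dict)


@dataclass
class AccuracyReport:
    n_assessed: int
    n_excluded: int
    n_missing: int
    chi1_pct: float
    chi12_pct: float
    chi_all_pct: float
    density_sum: float | None = None
    detail: pd.DataFrame | None = None


def _iter_native_chains(native_models, default_chain=None):
    for item in native_models:
        if isinstance(item, tuple):
            model, chain_id = item
        else:
            model, chain_id = item, None
        if chain_id is None:
            chain_id = next(iter(model.chains))
        yield model, chain_id


def build_ensemble(
    native_models: list,
    dmap: DensityMap | list[DensityMap | None] | None = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> NativeEnsemble:
    """Collect every altloc state of every native source per residue.

    ``native_models`` is a list of :class:`StructureModel` or
    ``(model, chain_id)`` tuples; the first is the reference and the others
    are paired to it by global sequence alignment.  When density maps are
    supplied (one per native, or a single map for the first), residues
    unreliable in *all* sources are dropped; individually unreliable
    conformers stay but carry ``reliable=False``.
    """
    natives = list(_iter_native_chains(native_models))
    if not natives:
        raise ValueError("at least one native structure is required")
    if dmap is None:
        maps: list[DensityMap | None] = [None] * len(natives)
    elif isinstance(dmap, DensityMap):
        maps = [dmap] + [None] * (len(natives) - 1)
    else:
        maps = list(dmap) + [None] * (len(natives) - len(dmap))

    ref_model, ref_chain_id = natives[0]
    ref_chain = ref_model.chains[ref_chain_id]
    ref_seq = chain_sequence(ref_chain)
    ensemble = NativeEnsemble(reference_sequence=ref_seq)
    any_reliable: dict[int, bool] = {}
    saw_map: dict[int, bool] = {}

    for source_idx, (model, chain_id) in enumerate(natives):
        chain = model.chains[chain_id]
        if source_idx == 0:
            mapping = {i: i for i in range(len(chain))}
        else:
            aln = align_sequences(ref_seq, chain_sequence(chain))
            mapping = {j: i for i, j in aln.columns if i is not None and j is not None}
        source_map = maps[source_idx]
        for pos, residue in enumerate(chain):
            ref_idx = mapping.get(pos)
            if ref_idx is None:
                continue
            parent = residue.standard_parent
            if parent is None or n_chi(parent) == 0:
                continue
            ref_parent = ref_chain[ref_idx].standard_parent
            if parent != ref_parent:
                continue  # mutated position: not a native conformer of the reference
            rel: bool | None = None
            if source_map is not None:
                rel = residue_reliability(source_map, residue, config).residue_reliable_sidechain
                saw_map[ref_idx] = True
                any_reliable[ref_idx] = any_reliable.get(ref_idx, False) or rel
            entry = ensemble.entries.setdefault(ref_idx, EnsembleEntry(res_name=parent))
            for state in group_conformers(residue):
                ds = measure_chis(state, parent)
                if ds.chis and ds.chis[0] is None:
                    continue
                tag = f"{model.pdb_id or source_idx}:{chain_id}:{residue.seq_id[0]}:{state.state_id or '-'}"
                entry.conformers.append(EnsembleConformer(ds, tag, rel))

    # drop residues unreliable in every mapped source
    for ref_idx, saw in saw_map.items():
        if saw and not any_reliable.get(ref_idx, False):
            ensemble.entries.pop(ref_idx, None)
    return ensemble


def closest_conformer(
    predicted: DihedralSet,
    entry: EnsembleEntry,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> tuple[EnsembleConformer, list[float | None]]:
    """Nearest native conformer: minimax over flip-aware per-chi diffs.

    Ties break toward the smaller chi1 difference, then provenance order.
    ``config.closest_metric = "chi1_lex"`` switches to lexicographic
    (chi1, chi2, ...) comparison.
    """
    if not entry.conformers:
        raise ValueError("empty ensemble entry")
    if predicted.chis and predicted.chis[0] is None:
        raise ValueError("predicted chi1 undefined")
    best = None
    for order, conformer in enumerate(entry.conformers):
        diffs: list[float | None] = []
        for k, (p, q) in enumerate(zip(predicted.chis, conformer.dihedrals.chis)):
            if p is None or q is None:
                diffs.append(None)
            else:
                diffs.append(chi_diff(entry.res_name, k + 1, p, q, config))
        defined = [d for d in diffs if d is not None]
        if not defined:
            continue
        if config.closest_metric == "chi1_lex":
            rank = tuple(d if d is not None else 999.0 for d in diffs)
        else:
            rank = (max(defined), diffs[0] if diffs[0] is not None else 999.0)
        key = (*rank, order)
        if best is None or key < best[0]:
            best = (key, conformer, diffs)
    if best is None:
        raise ValueError("no comparable conformer in entry")
    return best[1], best[2]


def chi_accuracy(
    prediction: StructureModel | list[Residue],
    ensemble: NativeEnsemble,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> AccuracyReport:
    """Closest-conformer chi accuracy of a predicted model.

    A residue is chi1-correct when its chi1 is within the change cutoff
    (30 degrees) of the closest native conformer; chi1+2 requires chi2 as
    well, chi_all every chi defined on both sides.  Gly/Ala are skipped;
    residues with no native conformers are excluded (``n_excluded``);
    residues present in the ensemble but absent from the prediction count
    as incorrect (``n_missing``).
    """
    if isinstance(prediction, StructureModel):
        pred_chain = prediction.chains[next(iter(prediction.chains))]
    else:
        pred_chain = prediction
    aln = align_sequences(ensemble.reference_sequence, chain_sequence(pred_chain))
    pred_of_ref = {i: j for i, j in aln.columns if i is not None}
    cutoff = config.chi_change_cutoff_deg
    rows = []
    n_excluded = n_missing = 0
    for ref_idx, entry in sorted(ensemble.entries.items()):
        if not entry.conformers:
            n_excluded += 1
            continue
        pred_idx = pred_of_ref.get(ref_idx)
        pred_res = pred_chain[pred_idx] if pred_idx is not None else None
        if pred_res is None or pred_res.standard_parent != entry.res_name:
            n_missing += 1
            rows.append({"ref_idx": ref_idx, "res_name": entry.res_name,
                         "status": "missing", "chi1_ok": False,
                         "chi12_ok": False, "chi_all_ok": False})
            continue
        ds = measure_chis(first_conformer(pred_res), entry.res_name)
        if not ds.chis or ds.chis[0] is None:
            n_missing += 1
            rows.append({"ref_idx": ref_idx, "res_name": entry.res_name,
                         "status": "chi1_unmeasurable", "chi1_ok": False,
                         "chi12_ok": False, "chi_all_ok": False})
            continue
        conformer, diffs = closest_conformer(ds, entry, config)
        shared = [d for d in diffs if d is not None]
        chi1_ok = diffs[0] is not None and diffs[0] <= cutoff
        chi12_ok = chi1_ok and (len(diffs) < 2 or diffs[1] is None or diffs[1] <= cutoff)
        chi_all_ok = chi1_ok and all(d <= cutoff for d in shared)
        rows.append({"ref_idx": ref_idx, "res_name": entry.res_name,
                     "status": "assessed", "closest": conformer.provenance,
                     "max_diff": max(shared), "chi1_ok": chi1_ok,
                     "chi12_ok": chi12_ok, "chi_all_ok": chi_all_ok})
    detail = pd.DataFrame(rows)
    scored = [r for r in rows if r["status"] != "excluded"]
    n_assessed = len(scored)
    if n_assessed == 0:
        return AccuracyReport(0, n_excluded, n_missing, 0.0, 0.0, 0.0, detail=detail)
    pct = lambda key: 100.0 * sum(r[key] for r in scored) / n_assessed  # noqa: E731
    return AccuracyReport(
        n_assessed=n_assessed, n_excluded=n_excluded, n_missing=n_missing,
        chi1_pct=pct("chi1_ok"), chi12_pct=pct("chi12_ok"),
        chi_all_pct=pct("chi_all_ok"), detail=detail)


@dataclass
class DensityScore:
    total: float
    per_residue: dict[tuple[str, int, str], float]


def density_sum_score(
    prediction: StructureModel,
    dmap: DensityMap,
    config: AnalysisConfig = DEFAULT_CONFIG,
    sidechain_only: bool = True,
) -> DensityScore:
    """Sum of interpolated point density over predicted side-chain heavy
    atoms (first predicted conformer); out-of-map atoms contribute 0."""
    if not dmap.normalized:
        raise ValueError("map must be normalized")
    per_residue: dict[tuple[str, int, str], float] = {}
    total = 0.0
    n_atoms = 0
    for residue in prediction.residues():
        subtotal = 0.0
        for atom in first_conformer(residue).atoms:
            if atom.is_hydrogen or (sidechain_only and not atom.is_sidechain):
                continue
            n_atoms += 1
            try:
                subtotal += point_density(dmap, atom.coord)
            except OutOfBoundsError:
                warnings.warn(f"atom {atom.name} of {residue} outside map; scored 0",
                              stacklevel=2)
        per_residue[residue.key] = subtotal
        total += subtotal
    if n_atoms == 0:
        warnings.warn("no side-chain heavy atoms in prediction; score 0", stacklevel=2)
    return DensityScore(total=total, per_residue=per_residue)
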