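import numpy as np
import pytest

from scvar.config import AnalysisConfig
from scvar.structure_model import read_pdb, write_pdb
from scvar.synthetic_fixtures import (
    inject_altlocs,
    make_synthetic_chain,
    make_variant_pair,
)
from scvar.variation_analysis import (
    ComparisonRecord,
    aggregate_survey,
    align_sequences,
    altloc_occurrence_table,
    altloc_variation,
    curate_pair,
    flexibility_estimate,
    pair_residues,
    pair_variation,
    pdb_id_distance,
    resolution_bin,
)
from conftest import make_chain_pair


class TestAlignSequences:
    def test_identical(self):
        assert align_sequences("ACDEFGHIKL", "ACDEFGHIKL").identity_pct == 100.0

    def test_five_of_six(self):
        assert align_sequences("ACDEFG", "ACDEFN").identity_pct == pytest.approx(100 * 5 / 6)

    def test_internal_deletion_hand_oracle(self):
        # "ACDEFGHIKL" vs the same with G deleted: 9 identities / 10 columns
        aln = align_sequences("ACDEFGHIKL", "ACDEFHIKL")
        assert aln.identity_pct == pytest.approx(90.0)
        assert sum(1 for i, j in aln.columns if i is not None and j is None) == 1

    def test_terminal_gaps_excluded_from_denominator(self):
        # terminal overhang should not dilute identity
        aln = align_sequences("ACDEFGHIKL", "CDEFGHIKL")
        assert aln.identity_pct == pytest.approx(100.0)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            align_sequences("", "ACD")


class TestPairResidues:
    def test_identical_chains_all_paired(self, chain40):
        model, _ = chain40
        chain = model.chains["A"]
        aln = align_sequences("".join(r.one_letter for r in chain),
                              "".join(r.one_letter for r in chain))
        pairs = pair_residues(chain, chain, aln)
        assert len(pairs) == len(chain)
        assert all(match for _, _, match in pairs)

    def test_gap_column_unpaired(self):
        model, _ = make_synthetic_chain(6, seed=0)
        chain = model.chains["A"]
        shorter = chain[:3] + chain[4:]
        aln = align_sequences("".join(r.one_letter for r in chain),
                              "".join(r.one_letter for r in shorter))
        pairs = pair_residues(chain, shorter, aln)
        assert len(pairs) == 5

    def test_point_mutation_flagged(self):
        model, _ = make_synthetic_chain(6, seed=0)
        chain = model.chains["A"]
        mutated, _ = make_synthetic_chain(6, seed=0)
        chain_b = mutated.chains["A"]
        chain_b[2].res_name = "SER" if chain_b[2].res_name != "SER" else "LEU"
        aln = align_sequences("".join(r.one_letter for r in chain),
                              "".join(r.one_letter for r in chain_b))
        pairs = pair_residues(chain, chain_b, aln)
        flags = [match for _, _, match in pairs]
        assert flags.count(False) == 1


class TestCuratePair:
    def test_same_crystal_accept(self, short_config):
        model, variant, _ = make_chain_pair(40, 0.1, seed=2)
        cur = curate_pair(model, variant, "A", "B", short_config, same_crystal=True)
        assert cur.accepted
        assert cur.superposition.tm_score > 0.8

    def test_low_tm_rejected(self, short_config):
        model, variant, _ = make_chain_pair(40, 0.0, seed=3)
        rng = np.random.default_rng(0)
        for residue in variant.chains["B"]:
            shift = rng.normal(0, 8.0, 3)
            for atom in residue.atoms:
                atom.coord = atom.coord + shift
        cur = curate_pair(model, variant, "A", "B", short_config, same_crystal=True)
        assert not cur.accepted
        assert cur.reason in ("tm", "rmsd")

    def test_missing_resolution_rejected(self, short_config):
        model, variant, _ = make_chain_pair(20, 0.0, seed=4)
        model.resolution = None
        cur = curate_pair(model, variant, "A", "B", short_config, same_crystal=True)
        assert not cur.accepted
        assert "resolution" in cur.reason

    def test_resolution_cutoff(self, short_config):
        model, variant, _ = make_chain_pair(20, 0.0, seed=5)
        model.resolution = 3.9
        cur = curate_pair(model, variant, "A", "B", short_config, same_crystal=True)
        assert not cur.accepted

    def test_short_chain_rejected(self, short_config):
        model, variant, _ = make_chain_pair(8, 0.0, seed=6)
        cur = curate_pair(model, variant, "A", "B", short_config, same_crystal=True)
        assert not cur.accepted
        assert cur.reason == "length"

    def test_pdb_id_rule_cross_crystal(self, short_config):
        model, variant, _ = make_chain_pair(20, 0.0, seed=7)
        model.pdb_id, variant.pdb_id = "2pa8", "2pmz"  # 2 letters differ: eligible
        cur = curate_pair(model, variant, "A", "B", short_config, same_crystal=False)
        assert cur.accepted
        variant.pdb_id = "2pa9"  # only 1 letter differs
        cur = curate_pair(model, variant, "A", "B", short_config, same_crystal=False)
        assert not cur.accepted

    def test_pdb_id_distance(self):
        assert pdb_id_distance("2pa8", "2pmz") == 2
        assert pdb_id_distance("2pa8", "2PA8") == 0
        assert pdb_id_distance("2pa8", "2pa9") == 1


class TestAltlocVariation:
    def _inject(self, deltas, occs=None, seed=0):
        model, _ = make_synthetic_chain(5, seed=seed)
        key = ("A", 3, "")
        occs = occs or [0.45, 0.55]
        v = inject_altlocs(model, [key], {key: deltas}, {key: occs})
        residue = [r for r in v.residues() if r.key == key][0]
        return residue

    def test_small_shift_same_all(self):
        rec = altloc_variation(self._inject([[2.0]]))
        assert rec.chi.same_all and not rec.chi.changed

    def test_large_chi1_shift_changed(self):
        rec = altloc_variation(self._inject([[120.0]]))
        assert rec.chi.changed and not rec.chi.same_chi1

    def test_three_states_one_deviant(self):
        # pairwise rule: one deviant state makes the residue changed
        rec = altloc_variation(self._inject([[1.0], [120.0]], occs=[0.4, 0.3, 0.3]))
        assert rec.chi.changed
        assert not rec.chi.same_chi1

    def test_single_state_none(self):
        model, _ = make_synthetic_chain(4, seed=1)
        assert altloc_variation(model.chains["A"][1]) is None

    def test_survives_pdb_round_trip(self):
        residue = self._inject([[120.0]])
        from scvar.structure_model import Residue, StructureModel
        model = StructureModel(pdb_id="test", chains={"A": [residue]})
        back = read_pdb(write_pdb(model)).residues()[0]
        rec = altloc_variation(back)
        assert rec.chi.changed


class TestPairVariation:
    def test_identical_chains_all_same(self, short_config):
        model, variant, _ = make_chain_pair(30, 0.0, seed=8)
        cur = curate_pair(model, variant, "A", "B", short_config, same_crystal=True)
        recs = pair_variation(model.chains["A"], variant.chains["B"], cur.pairing,
                              short_config, structure_id="synt", resolution=1.0)
        comp = [r for r in recs if r.comparable]
        assert comp and all(r.chi.same_all for r in comp)

    def test_injected_changes_recovered(self, short_config):
        model, variant, labels = make_chain_pair(50, 0.2, seed=9)
        cur = curate_pair(model, variant, "A", "B", short_config, same_crystal=True)
        recs = pair_variation(model.chains["A"], variant.chains["B"], cur.pairing,
                              short_config, structure_id="synt", resolution=1.0)
        got = {r.res_key_a: r.chi.changed for r in recs if r.comparable}
        assert got
        for key, changed in got.items():
            assert changed == labels[key]
        assert sum(got.values()) == 10

    def test_backbone_change_flag(self, short_config):
        model, variant, _ = make_chain_pair(20, 0.0, seed=10)
        # twist one residue's backbone by moving its N: phi changes, chis untouched
        chain_b = variant.chains["B"]
        from scvar.chi_geometry import measure_phi_psi
        before = measure_phi_psi(chain_b)
        cur = curate_pair(model, variant, "A", "B", short_config, same_crystal=True)
        recs = pair_variation(model.chains["A"], chain_b, cur.pairing, short_config)
        mid = [r for r in recs if r.backbone_changed is not None]
        assert mid and all(r.backbone_changed is False for r in mid)

    def test_altloc_residues_excluded(self, short_config):
        model, variant, _ = make_chain_pair(20, 0.0, seed=11)
        key = ("A", 5, "")
        model2 = inject_altlocs(model, [key], {key: [[120.0]]}, {key: [0.5, 0.5]})
        cur = curate_pair(model2, variant, "A", "B", short_config, same_crystal=True)
        recs = pair_variation(model2.chains["A"], variant.chains["B"], cur.pairing,
                              short_config)
        assert all(r.res_key_a != key for r in recs)

    def test_unreliable_residues_excluded(self, short_config):
        model, variant, _ = make_chain_pair(20, 0.0, seed=12)
        cur = curate_pair(model, variant, "A", "B", short_config, same_crystal=True)
        bad_key = ("A", 7, "")
        recs = pair_variation(model.chains["A"], variant.chains["B"], cur.pairing,
                              short_config, reliability={bad_key: False})
        assert all(r.res_key_a != bad_key for r in recs)

    def test_exclusion_never_raises_changed_pct(self, short_config):
        # injected changes confined to excluded residues: filtered set is clean
        model, variant, labels = make_chain_pair(30, 0.2, seed=13)
        cur = curate_pair(model, variant, "A", "B", short_config, same_crystal=True)
        changed_keys = {k for k, v in labels.items() if v}
        recs_all = pair_variation(model.chains["A"], variant.chains["B"], cur.pairing,
                                  short_config)
        recs_filt = pair_variation(model.chains["A"], variant.chains["B"], cur.pairing,
                                   short_config,
                                   reliability={k: False for k in changed_keys})
        pct = lambda rs: 100 * np.mean([r.chi.changed for r in rs if r.comparable])  # noqa: E731
        assert pct(recs_filt) <= pct(recs_all)
        assert pct(recs_filt) == 0.0


class TestAggregateSurvey:
    def _record(self, sid, res, changed, same1=True, same12=True, resolution=1.5):
        from scvar.chi_geometry import ChiComparison
        same_all = not changed
        chi = ChiComparison(res, [0.0, 0.0], same1, same12, same_all, changed, False)
        return ComparisonRecord(kind="same-crystal", structure_id=sid,
                                res_key_a=("A", 1, ""), res_key_b=("B", 1, ""),
                                res_name=res, chi=chi, resolution=resolution)

    def test_single_structure_100pct(self):
        recs = [self._record("s1", "SER", False) for _ in range(5)]
        table = aggregate_survey(recs, "resolution")
        assert table.iloc[0]["mean_pct_same_all"] == 100.0

    def test_two_structures_mean_sd(self):
        # 80% and 90% -> mean 85, population SD 5
        recs = ([self._record("s1", "SER", i < 2) for i in range(10)]
                + [self._record("s2", "SER", i < 1) for i in range(10)])
        table = aggregate_survey(recs, "resolution")
        assert table.iloc[0]["mean_pct_same_all"] == pytest.approx(85.0)
        assert table.iloc[0]["sd_pct_same_all"] == pytest.approx(5.0)

    def test_sample_sd_switch(self):
        recs = ([self._record("s1", "SER", i < 2) for i in range(10)]
                + [self._record("s2", "SER", i < 1) for i in range(10)])
        table = aggregate_survey(recs, "resolution", AnalysisConfig(sample_sd=True))
        assert table.iloc[0]["sd_pct_same_all"] == pytest.approx(5.0 * np.sqrt(2))

    def test_permutation_invariant(self, rng):
        recs = [self._record(f"s{i % 3}", "LYS", bool(i % 4 == 0)) for i in range(24)]
        t1 = aggregate_survey(recs, "resolution")
        shuffled = list(recs)
        rng.shuffle(shuffled)
        t2 = aggregate_survey(shuffled, "resolution")
        assert t1.equals(t2)

    def test_per_structure_vs_pooled_differ_on_unbalanced(self):
        # s1: 100 records 0% changed; s2: 10 records 100% changed
        recs = ([self._record("s1", "SER", False) for _ in range(100)]
                + [self._record("s2", "SER", True) for _ in range(10)])
        table = aggregate_survey(recs, "resolution")
        pooled = 100.0 * 10 / 110
        assert table.iloc[0]["mean_pct_changed"] == pytest.approx(50.0)
        assert abs(table.iloc[0]["mean_pct_changed"] - pooled) > 5

    def test_chi_category_monotone_in_rows(self):
        recs = [self._record("s1", "LYS", changed=bool(i % 2), same1=True,
                             same12=bool(i % 3)) for i in range(12)]
        # enforce flag consistency: same12 implies same1, same_all implies same12
        table = aggregate_survey(recs, "resolution")
        row = table.iloc[0]
        assert row["mean_pct_same_all"] <= row["mean_pct_same_chi12"] + 1e-9
        assert row["mean_pct_same_chi12"] <= row["mean_pct_same_chi1"] + 1e-9

    def test_resolution_bins(self):
        assert resolution_bin(0.8) == "0.0-1.0"
        assert resolution_bin(1.0) == "1.0-2.0"
        assert resolution_bin(2.5) == "2.0-3.0"
        assert resolution_bin(3.5) == "3.0-3.5"
        assert resolution_bin(4.2) is None

    def test_residue_type_grouping(self):
        recs = [self._record("s1", res, False) for res in ("SER", "SER", "LYS")]
        table = aggregate_survey(recs, "residue_type")
        assert set(table["group"]) == {"SER", "LYS"}


class TestOccurrence:
    def test_altloc_enrichment(self):
        model, _ = make_synthetic_chain(21, seed=14)
        keys = [("A", i, "") for i in (1, 8, 15)]  # ARG positions in the cycle
        v = inject_altlocs(model, keys, {k: [[120.0]] for k in keys},
                           {k: [0.5, 0.5] for k in keys})
        table = altloc_occurrence_table([v])
        arg = table[table["res_name"] == "ARG"].iloc[0]
        assert arg["count_altloc"] == 3
        assert arg["pct_of_altloc"] == 100.0
        assert arg["pct_of_altloc"] > arg["pct_of_all"]


class TestFlexibilityEstimate:
    def test_seventeen(self):
        assert flexibility_estimate(12, 95) == pytest.approx(17.0)

    def test_sixteen(self):
        assert flexibility_estimate(3, 87) == pytest.approx(16.0)

    def test_twenty_with_cross(self):
        assert flexibility_estimate(12, 95, 3) == pytest.approx(20.0)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            flexibility_estimate(120, 95)
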