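# scvar

Quantify protein side-chain conformational variability from crystal
structures: alternate-location (altloc) conformer analysis, χ-dihedral
comparison under the strict more-than-30° change rule (with 180° flips for
Asp/Glu/Phe/Tyr/Arg terminal χ), electron-density reliability at the >1σ
level, solvent exposure at the 1.0 Å² absolute-ASA cutoff, cross-chain and
cross-crystal variation surveys, and a multi-conformer, density-aware
assessment scheme for side-chain prediction.

## Layout

| module | what it does |
| --- | --- |
| `scvar.structure_model` | fixed-column PDB I/O with full altloc/occupancy/B-factor fidelity; conformer grouping; sequences; side-chain B averages |
| `scvar.chi_geometry` | torsions (χ/φ/ψ), flip-aware χ differences, conformer comparison flags, Kabsch superposition, sequence-paired TM-score |
| `scvar.density_reliability` | CCP4/MRC map I/O, σ-normalization, trilinear point density, atom/residue reliability |
| `scvar.accessibility` | Shrake–Rupley ASA on the whole structure, per-residue exposure classification |
| `scvar.variation_analysis` | pair curation (identity/TM/RMSD/resolution/length), altloc & chain-pair variation records, per-structure survey tables, flexibility estimate |
| `scvar.sc_assess` | native conformer ensembles, closest-conformer χ accuracy, density-sum model score |
| `scvar.synthetic_fixtures` | ideal-geometry chain/side-chain builders (NeRF), altloc injection, labelled variant pairs, Gaussian-atom map rendering |

Shipped data: `scvar/data/chi_atoms.json` (IUPAC χ quadruples + symmetric
terminal-flip indices) and `scvar/data/sasa_tables.json` (van der Waals
radii sets, reference ASA for relative accessibility).

## CLI

```bash
# synthetic fixture bundle: PDB pair + CCP4 map + ground-truth labels
scvar simulate --n-res 50 --change-fraction 0.2 --seed 7 --out sim/

# altloc-state variation survey of one or more structures
scvar compare --mode altloc --pdb model.pdb --out report/

# chain pair within one crystal (or across crystals with two --pdb files)
scvar compare --mode same-crystal --pdb crystal.pdb --chains A,B \
    [--map map.ccp4] --out report/

# closest-conformer assessment of a predicted model
scvar assess --pred model.pdb --native n1.pdb --native n2.pdb \
    [--map map.ccp4] --out report.csv
```

`compare` writes per-residue records (`records.tsv`) plus survey tables
grouped by resolution bin, residue type and exposure (`survey_*.csv`).
All cutoffs live in `AnalysisConfig` and can be overridden with a flat
`key=value` file passed via `--config`.

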