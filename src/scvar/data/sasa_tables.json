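{
  "_comment": "Van der Waals radii (Angstrom) per element for solvent-accessible surface area. 'default' is the Bondi set; 'naccess' is the Chothia-style set used by classic ASA programs. 'reference_asa' holds per-residue-type total accessible areas (A^2) of the extended Gly-X-Gly reference state used for relative ASA: for the types the synthetic builder templates (plus GLY/ALA) the values are computed with this package's own extended Gly-X-Gly construction, default radii, probe 1.4, 960 points; the remaining types use Tien et al. 2013 theoretical values as placeholders.",
  "radii": {
    "default": {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "SE": 1.90, "H": 1.20, "*": 1.70},
    "naccess": {"C": 1.87, "N": 1.65, "O": 1.40, "S": 1.85, "P": 1.90, "SE": 1.90, "H": 1.00, "*": 1.80}
  },
  "reference_asa": {
    "ALA": 113.9, "ARG": 240.1, "ASN": 195.0, "ASP": 154.3, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 85.8, "HIS": 224.0, "ILE": 197.0,
    "LEU": 178.4, "LYS": 205.0, "MET": 193.9, "PHE": 203.7, "PRO": 159.0,
    "SER": 126.6, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0
  }
}
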