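"""Analysis-wide cutoffs and switches.

All thresholds used by the comparison, reliability, exposure and curation
code live in one dataclass so a run is reproducible from a flat
``key=value`` config file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class AnalysisConfig:
    """Cutoffs governing every classification step.

    Defaults encode the survey conventions: a chi or backbone dihedral is
    "changed" only when it moves by strictly more than 30 degrees, an atom
    is density-reliable only above 1 sigma, and a residue is exposed at
    >= 1.0 A^2 absolute accessible surface area.
    """

    chi_change_cutoff_deg: float = 30.0
    backbone_change_cutoff_deg: float = 30.0
    density_sigma_cutoff: float = 1.0
    exposure_asa_cutoff_A2: float = 1.0
    tm_cutoff: float = 0.8
    rmsd_cutoff_A: float = 3.0
    pair_identity_min_pct: float = 90.0
    nonredundancy_identity_max_pct: float = 25.0
    resolution_max_A: float = 3.5
    min_length_aa: int = 100
    symmetric_residues: frozenset[str] = frozenset({"ARG", "GLU", "ASP", "PHE", "TYR"})

    # switches (not part of the headline contract)
    interpolation: str = "trilinear"  # or "cubic"
    reliability_first_conformer_only: bool = True
    flip_arg_terminal_chi: bool = True
    sample_sd: bool = False  # population SD across structures by default
    tm_normalize_by: str = "first"  # or "shorter" / "longer"
    closest_metric: str = "minimax"  # or "chi1_lex"
    radii_table: str = "default"  # or "naccess"
    include_het_in_occlusion: bool = False
    sasa_n_points: int = 960
    sasa_probe_radius_A: float = 1.4

    def __post_init__(self) -> None:
        for name in (
            "chi_change_cutoff_deg",
            "backbone_change_cutoff_deg",
            "density_sigma_cutoff",
            "exposure_asa_cutoff_A2",
            "tm_cutoff",
            "rmsd_cutoff_A",
            "resolution_max_A",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not isinstance(self.symmetric_residues, frozenset):
            object.__setattr__(self, "symmetric_residues", frozenset(self.symmetric_residues))

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load a flat ``key=value`` file; unknown keys raise."""
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            ftype = fields[key].type
            if key == "symmetric_residues":
                kwargs[key] = frozenset(v.strip().upper() for v in value.split(","))
            elif ftype in ("bool", bool):
                kwargs[key] = value.lower() in ("1", "true", "yes", "on")
            elif ftype in ("int", int):
                kwargs[key] = int(value)
            elif ftype in ("float", float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


DEFAULT_CONFIG = AnalysisConfig()
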