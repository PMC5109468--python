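"""Loaders for the shipped data tables (chi quadruples, SASA radii)."""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources


@lru_cache(maxsize=None)
def _load(name: str) -> dict:
    with resources.files("scvar.data").joinpath(name).open() as fh:
        return json.load(fh)


@lru_cache(maxsize=None)
def chi_quadruples() -> dict[str, list[tuple[str, str, str, str]]]:
    """Ordered chi-defining atom quadruples per residue type."""
    raw = _load("chi_atoms.json")["chi"]
    return {res: [tuple(q) for q in quads] for res, quads in raw.items()}


@lru_cache(maxsize=None)
def terminal_flip_index() -> dict[str, int]:
    """1-based chi index compared under a 180-degree flip, per residue type."""
    return dict(_load("chi_atoms.json")["terminal_flip"])


def n_chi(res_name: str) -> int:
    return len(chi_quadruples().get(res_name, []))


@lru_cache(maxsize=None)
def vdw_radii(table: str = "default") -> dict[str, float]:
    radii = _load("sasa_tables.json")["radii"]
    if table not in radii:
        raise KeyError(f"unknown radii table {table!r}; have {sorted(radii)}")
    return dict(radii[table])


@lru_cache(maxsize=None)
def reference_asa() -> dict[str, float]:
    """Extended Gly-X-Gly reference areas (A^2) for relative ASA."""
    return dict(_load("sasa_tables.json")["reference_asa"])
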