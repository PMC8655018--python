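"""Distance screening of residue pairs for state-locking disulfide design.

A cysteine pair can lock a conformation when the two residues sit within
disulfide range in that state; a pair that is far apart in the other
state then reports on which conformation the complex occupies.  The
screen measures Cβ–Cβ distances (the standard disulfide proxy; Cα
fallback for glycine) in each supplied state and classifies each pair as
compatible, marginal or incompatible per state.

The mutant panels from the BAM conformational-locking experiments ship
as data: inward-open locks S502C/V706C + G431C/G807C, outward-open locks
D503C/N681C + S425C/K808C, POTRA5–turn-4 locks E396C/R583C + G393C/G584C,
and the BamA×EspP hybrid-barrel sites (806/807 × 1226–1234 even).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import LookupResidueError, ParameterError
from .structio import StructureModel

__all__ = [
    "ResidueRef",
    "CrosslinkPair",
    "pair_distance",
    "screen_pairs",
    "bundled_mutant_panels",
    "pairs_to_dataframe",
]


@dataclass(frozen=True)
class ResidueRef:
    """(chain, residue number); chain None matches any chain if unambiguous."""

    chain_id: str | None
    residue_number: int

    def __str__(self) -> str:
        return f"{self.chain_id or '*'}/{self.residue_number}"


@dataclass
class CrosslinkPair:
    residue_a: ResidueRef
    residue_b: ResidueRef
    atom_class: str = "CB"
    intended_state: str = ""
    distance_in_state: dict[str, float] = field(default_factory=dict)
    classification: dict[str, str] = field(default_factory=dict)
    fallback_atoms: dict[str, str] = field(default_factory=dict)  # residue → atom used


def _find_atom(model: StructureModel, ref: ResidueRef, atom_class: str):
    """Locate the proxy atom; Gly (or missing Cβ) falls back to Cα."""
    if atom_class not in ("CA", "CB"):
        raise ParameterError(f"atom_class must be CA or CB, got {atom_class!r}")
    hits = {}
    for atom in model.atoms:
        if atom.residue_number != ref.residue_number:
            continue
        if ref.chain_id is not None and atom.chain_id != ref.chain_id:
            continue
        hits.setdefault(atom.chain_id, {})[atom.name] = atom
    if not hits:
        raise LookupResidueError(f"residue {ref} absent from {model.identifier or 'model'}")
    if ref.chain_id is None and len(hits) > 1:
        raise LookupResidueError(
            f"residue number {ref.residue_number} is ambiguous across chains "
            f"{sorted(hits)}; give a chain id")
    atoms = next(iter(hits.values()))
    if atom_class == "CB" and "CB" not in atoms:
        if "CA" in atoms:
            return atoms["CA"], "CA"   # glycine fallback
        raise LookupResidueError(f"residue {ref}: no CB or CA atom")
    if atom_class not in atoms:
        raise LookupResidueError(f"residue {ref}: no {atom_class} atom")
    return atoms[atom_class], atom_class


def pair_distance(model: StructureModel, a: ResidueRef | tuple, b: ResidueRef | tuple,
                  atom_class: str = "CB") -> tuple[float, dict[str, str]]:
    """Euclidean proxy-atom distance (Å) plus the atom names actually used."""
    a = a if isinstance(a, ResidueRef) else ResidueRef(*a)
    b = b if isinstance(b, ResidueRef) else ResidueRef(*b)
    atom_a, used_a = _find_atom(model, a, atom_class)
    atom_b, used_b = _find_atom(model, b, atom_class)
    dist = float(np.linalg.norm(atom_a.position - atom_b.position))
    return dist, {str(a): used_a, str(b): used_b}


def classify_distance(distance: float, compatible_max: float = 7.0,
                      incompatible_min: float = 12.0) -> str:
    if compatible_max > incompatible_min:
        raise ParameterError("compatible_max must be <= incompatible_min")
    if distance <= compatible_max:
        return "compatible"
    if distance >= incompatible_min:
        return "incompatible"
    return "marginal"


def screen_pairs(models: dict[str, StructureModel], pairs,
                 compatible_max: float = 7.0, incompatible_min: float = 12.0,
                 atom_class: str = "CB") -> list[CrosslinkPair]:
    """Measure and classify every pair in every supplied state.

    ``pairs`` is a list of (residue_a, residue_b) or (residue_a,
    residue_b, intended_state) tuples, residues as ResidueRef or
    (chain, number).
    """
    results = []
    for pair in pairs:
        a, b = pair[0], pair[1]
        intended = pair[2] if len(pair) > 2 else ""
        a = a if isinstance(a, ResidueRef) else ResidueRef(*a)
        b = b if isinstance(b, ResidueRef) else ResidueRef(*b)
        cp = CrosslinkPair(a, b, atom_class=atom_class, intended_state=intended)
        for state, model in models.items():
            d, used = pair_distance(model, a, b, atom_class)
            cp.distance_in_state[state] = d
            cp.classification[state] = classify_distance(d, compatible_max,
                                                         incompatible_min)
            for res, name in used.items():
                if name != atom_class:
                    cp.fallback_atoms[res] = name
        results.append(cp)
    return results


def pairs_to_dataframe(pairs: list[CrosslinkPair]) -> pd.DataFrame:
    """Long-format report table: one row per pair per state."""
    rows = []
    for cp in pairs:
        for state in cp.distance_in_state:
            rows.append({
                "residue_a": str(cp.residue_a),
                "residue_b": str(cp.residue_b),
                "atom_class": cp.atom_class,
                "intended_state": cp.intended_state,
                "state": state,
                "distance_A": cp.distance_in_state[state],
                "classification": cp.classification[state],
                "fallback": ";".join(f"{r}:{n}" for r, n in cp.fallback_atoms.items()),
            })
    return pd.DataFrame(rows)


def bundled_mutant_panels(bama_chain: str = "A",
                          espp_chain: str | None = None) -> dict[str, list]:
    """The designed crosslink panels, as (residue_a, residue_b, intended_state).

    BamA×EspP pairs span both tested β16 sites (806 and 807) against the
    five β9 sites of EspP, 10 pairs total.
    """
    A = bama_chain

    def ba(n):
        return ResidueRef(A, n)

    def ep(n):
        return ResidueRef(espp_chain, n)

    panels = {
        "inward_open_locks": [
            (ba(502), ba(706), "inward-open"),
            (ba(431), ba(807), "inward-open"),
        ],
        "outward_open_locks": [
            (ba(503), ba(681), "outward-open"),
            (ba(425), ba(808), "outward-open"),
        ],
        "potra5_t4_locks": [
            (ba(393), ba(584), "outward-open"),
            (ba(396), ba(583), "outward-open"),
        ],
        "bama_espp": [
            (ba(site), ep(target), "hybrid-barrel")
            for site in (806, 807)
            for target in (1226, 1228, 1230, 1232, 1234)
        ],
    }
    return panels
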