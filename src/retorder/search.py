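"""m/z-filtered database search ranked by retention-order match score.

Candidate annotation of an LC/MS feature proceeds in two independent stages:

1. *Mass filter* — keep database structures whose adduct m/z (default
   [M+H]+, i.e. neutral monoisotopic mass + proton mass) lies within a
   tolerance window (default ±0.5) of the observed precursor m/z.
2. *Order ranking* — for each surviving candidate, predict its order
   relations against the reference panel and compute the match score S′
   against the feature's *measured* order relations; candidates with
   S′ ≥ threshold (default 0.9) form the shortlist.

The stages commute: the mass filter never looks at the model, and the
ranking never looks at the masses.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from rdkit import Chem

from .chemio import neutral_monoisotopic_mass
from .fingerprints import prepare_mol
from .scoring import OrderRelationVector, accuracy_S, predicted_relations

__all__ = [
    "PROTON_MASS",
    "CandidateHit",
    "adduct_mz",
    "mz_filter",
    "rank_candidates",
]

PROTON_MASS = 1.007276466812  # Da

_ADDUCTS = {
    "[M+H]+": PROTON_MASS,
    "[M-H]-": -PROTON_MASS,
    "neutral": 0.0,
}


@dataclass(frozen=True)
class CandidateHit:
    """One database structure surviving the m/z filter."""

    db_id: str
    name: str
    smiles: str
    neutral_mass: float
    adduct_mz: float
    match_score: float | None = None
    passes_threshold: bool | None = None


def adduct_mz(neutral_mass: float, adduct: str = "[M+H]+") -> float:
    """m/z of a singly charged adduct (or the neutral mass itself)."""
    if adduct not in _ADDUCTS:
        raise ValueError(f"unknown adduct {adduct!r}; expected one of {sorted(_ADDUCTS)}")
    return neutral_mass + _ADDUCTS[adduct]


def mz_filter(
    db: Sequence[tuple[str, str, str]],
    observed_mz: float,
    tolerance: float = 0.5,
    adduct: str = "[M+H]+",
) -> tuple[list[CandidateHit], int]:
    """Filter (db_id, name, smiles) rows by |observed_mz − adduct_mz| ≤ tol.

    Unparseable structures are skipped and counted (second return value).
    Duplicate structures (same stereo-stripped canonical SMILES) are collapsed
    into one hit with ids merged as ``id1;id2;...``.
    """
    if not db:
        raise ValueError("empty candidate database")
    if tolerance <= 0:
        raise ValueError(f"tolerance must be positive, got {tolerance}")
    if adduct not in _ADDUCTS:
        raise ValueError(f"unknown adduct {adduct!r}; expected one of {sorted(_ADDUCTS)}")
    n_unparseable = 0
    by_canonical: dict[str, CandidateHit] = {}
    for db_id, name, smiles in db:
        try:
            mol = prepare_mol(smiles)
        except ValueError:
            n_unparseable += 1
            continue
        canonical = Chem.MolToSmiles(mol)
        mass = neutral_monoisotopic_mass(canonical)
        if abs(observed_mz - adduct_mz(mass, adduct)) > tolerance:
            continue
        if canonical in by_canonical:
            prev = by_canonical[canonical]
            by_canonical[canonical] = replace(
                prev, db_id=f"{prev.db_id};{db_id}"
            )
        else:
            by_canonical[canonical] = CandidateHit(
                db_id=str(db_id),
                name=str(name),
                smiles=canonical,
                neutral_mass=mass,
                adduct_mz=adduct_mz(mass, adduct),
            )
    return list(by_canonical.values()), n_unparseable


def rank_candidates(
    model,
    candidates: Sequence[CandidateHit],
    candidate_pcfs: np.ndarray,
    measured: OrderRelationVector,
    panel_pcfs: np.ndarray,
    threshold: float = 0.9,
) -> list[CandidateHit]:
    """Score candidates by S′ against the measured order relations.

    ``candidate_pcfs`` row i must correspond to ``candidates[i]``. Returns
    hits with ``match_score`` and ``passes_threshold`` filled, sorted by
    score descending (stable; ties by db_id).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    candidates = list(candidates)
    if not candidates:
        return []
    candidate_pcfs = np.atleast_2d(np.asarray(candidate_pcfs, dtype=float))
    if candidate_pcfs.shape[0] != len(candidates):
        raise ValueError(
            f"{candidate_pcfs.shape[0]} PCF rows for {len(candidates)} candidates"
        )
    scored = []
    for hit, pcf_vec in zip(candidates, candidate_pcfs):
        p = predicted_relations(model, pcf_vec, panel_pcfs, query_id=hit.db_id)
        s_prime = accuracy_S(measured, p)
        scored.append(
            replace(hit, match_score=s_prime, passes_threshold=s_prime >= threshold)
        )
    return sorted(scored, key=lambda h: (-h.match_score, h.db_id))
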