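"""Binary and counting molecular fingerprints and their MIX concatenation.

Four substructure-profile families are supported:

``maccs``
    The 166 predefined MACCS substructure keys (SMARTS patterns as shipped
    with RDKit). Counting mode records the number of distinct substructure
    matches per key; binary mode is the indicator ``count > 0``.
``extended``
    Hashed linear-path features: all simple bond paths up to a maximum depth
    (default 6 bonds), atoms typed by element/aromaticity/ring membership and
    bonds by bond order, folded into a power-of-two-length vector.
``graph``
    The same path enumeration with bond order ignored, so e.g. ethane and
    ethene give identical depth-1 features.
``circular``
    Hashed circular atom environments (Morgan/ECFP-style, default radius 3,
    i.e. ECFP6-like), computed with RDKit's Morgan generator.

The MIX fingerprint is the concatenation ``[maccs | extended | graph |
circular]`` (default length 166 + 3*1024 = 3238). All families are computed
on the largest covalent fragment with stereochemistry stripped, so
enantiomers map to identical vectors, and counting mode accumulates feature
multiplicities (hash collisions add).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.MACCSkeys import smartsPatts as _MACCS_SMARTS

__all__ = [
    "FingerprintVector",
    "MACCS_LENGTH",
    "maccs_fingerprint",
    "hashed_fingerprint",
    "mix_fingerprint",
    "fingerprint",
    "fingerprint_matrix",
    "feature_labels",
    "mix_slices",
    "prepare_mol",
]

MACCS_LENGTH = 166
HASHED_FAMILIES = ("extended", "graph", "circular")
DEFAULT_HASHED_LENGTH = 1024
DEFAULT_PATH_DEPTH = 6
DEFAULT_RADIUS = 3


@dataclass(frozen=True)
class FingerprintVector:
    """Fixed-length nonnegative integer substructure profile."""

    values: np.ndarray
    family: str
    mode: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.int64))
        if self.mode not in ("binary", "counting"):
            raise ValueError(f"mode must be 'binary' or 'counting', got {self.mode!r}")
        if self.mode == "binary" and not np.isin(self.values, (0, 1)).all():
            raise ValueError("binary fingerprint contains values outside {0, 1}")
        if (self.values < 0).any():
            raise ValueError("fingerprint counts must be nonnegative")

    @property
    def length(self) -> int:
        return int(self.values.shape[0])


# --- MACCS key table, compiled once at import ------------------------------
# RDKit stores a few placeholder keys as '?' (features outside SMARTS, e.g.
# isotopes); those positions are always 0 here.
def _compile_maccs() -> list[Chem.Mol | None]:
    patterns: list[Chem.Mol | None] = []
    for key_index in range(1, MACCS_LENGTH + 1):
        smarts, _count_threshold = _MACCS_SMARTS[key_index]
        if smarts == "?":
            patterns.append(None)
            continue
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise RuntimeError(f"MACCS key {key_index} has invalid SMARTS {smarts!r}")
        patterns.append(patt)
    return patterns


_MACCS_PATTERNS = _compile_maccs()


def prepare_mol(smiles: str) -> Chem.Mol:
    """Parse SMILES, keep the largest covalent fragment, strip stereo."""
    if not isinstance(smiles, str) or not smiles.strip():
        raise ValueError("empty structure")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid structure: {smiles!r}")
    frags = Chem.GetMolFrags(mol, asMols=True)
    if len(frags) > 1:
        mol = max(frags, key=lambda f: f.GetNumHeavyAtoms())
    Chem.RemoveStereochemistry(mol)
    return mol


def _check_mode(mode: str) -> None:
    if mode not in ("binary", "counting"):
        raise ValueError(f"mode must be 'binary' or 'counting', got {mode!r}")


def _check_length(length: int) -> None:
    if length <= 0 or (length & (length - 1)) != 0:
        raise ValueError(f"hashed fingerprint length must be a power of two, got {length}")


def maccs_counts(mol: Chem.Mol) -> np.ndarray:
    """Distinct substructure-match counts for each of the 166 MACCS keys."""
    counts = np.zeros(MACCS_LENGTH, dtype=np.int64)
    for j, patt in enumerate(_MACCS_PATTERNS):
        if patt is None:
            continue
        counts[j] = len(mol.GetSubstructMatches(patt, uniquify=True))
    return counts


def maccs_fingerprint(smiles: str, mode: str = "counting") -> FingerprintVector:
    """166-key MACCS fingerprint (counting = distinct SMARTS match count)."""
    _check_mode(mode)
    counts = maccs_counts(prepare_mol(smiles))
    values = (counts > 0).astype(np.int64) if mode == "binary" else counts
    return FingerprintVector(values=values, family="maccs", mode=mode)


# --- hashed path families --------------------------------------------------

def _atom_invariant(atom: Chem.Atom) -> str:
    ring = "R" if atom.IsInRing() else ""
    arom = "a" if atom.GetIsAromatic() else ""
    return f"{atom.GetSymbol()}{arom}{ring}"


_BOND_SYMBOL = {
    Chem.BondType.SINGLE: "-",
    Chem.BondType.DOUBLE: "=",
    Chem.BondType.TRIPLE: "#",
    Chem.BondType.AROMATIC: ":",
}


def _slot(feature: str, length: int) -> int:
    digest = hashlib.blake2b(feature.encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") % length


def _path_atom_sequence(mol: Chem.Mol, bond_ids: Sequence[int]) -> list[int]:
    bonds = [mol.GetBondWithIdx(b) for b in bond_ids]
    if len(bonds) == 1:
        return [bonds[0].GetBeginAtomIdx(), bonds[0].GetEndAtomIdx()]
    first = {bonds[0].GetBeginAtomIdx(), bonds[0].GetEndAtomIdx()}
    second = {bonds[1].GetBeginAtomIdx(), bonds[1].GetEndAtomIdx()}
    start = (first - second).pop()
    atoms = [start]
    for bond in bonds:
        atoms.append(bond.GetOtherAtomIdx(atoms[-1]))
    return atoms


def _path_features(mol: Chem.Mol, depth: int, use_bond_order: bool) -> list[str]:
    """Canonical strings for all simple paths of 0..depth bonds."""
    features = [_atom_invariant(atom) for atom in mol.GetAtoms()]
    for n_bonds in range(1, depth + 1):
        for bond_ids in Chem.FindAllPathsOfLengthN(mol, n_bonds, useBonds=True):
            atom_ids = _path_atom_sequence(mol, list(bond_ids))
            invs = [_atom_invariant(mol.GetAtomWithIdx(a)) for a in atom_ids]
            if use_bond_order:
                syms = [
                    _BOND_SYMBOL.get(mol.GetBondWithIdx(b).GetBondType(), "?")
                    for b in bond_ids
                ]
            else:
                syms = ["~"] * len(bond_ids)
            parts = [invs[0]]
            for sym, inv in zip(syms, invs[1:]):
                parts.extend([sym, inv])
            forward = "".join(parts)
            reverse = "".join(
                [invs[-1]]
                + [x for sym, inv in zip(syms[::-1], invs[-2::-1]) for x in (sym, inv)]
            )
            features.append(min(forward, reverse))
    return features


def _circular_counts(mol: Chem.Mol, radius: int, length: int) -> np.ndarray:
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=length)
    counts = np.zeros(length, dtype=np.int64)
    for slot, count in gen.GetCountFingerprint(mol).GetNonzeroElements().items():
        counts[slot] = count
    return counts


def hashed_fingerprint(
    smiles: str,
    family: str,
    mode: str = "counting",
    length: int = DEFAULT_HASHED_LENGTH,
    depth_or_radius: int | None = None,
) -> FingerprintVector:
    """Hashed path ('extended'/'graph') or circular (Morgan) fingerprint.

    ``depth_or_radius`` is the maximum path depth in bonds for the path
    families (default 6) and the maximum environment radius for ``circular``
    (default 3). ``length`` must be a power of two.
    """
    _check_mode(mode)
    _check_length(length)
    if family not in HASHED_FAMILIES:
        raise ValueError(f"family must be one of {HASHED_FAMILIES}, got {family!r}")
    mol = prepare_mol(smiles)
    if family == "circular":
        radius = DEFAULT_RADIUS if depth_or_radius is None else depth_or_radius
        counts = _circular_counts(mol, radius, length)
    else:
        depth = DEFAULT_PATH_DEPTH if depth_or_radius is None else depth_or_radius
        counts = np.zeros(length, dtype=np.int64)
        for feature in _path_features(mol, depth, use_bond_order=(family == "extended")):
            counts[_slot(feature, length)] += 1
    values = (counts > 0).astype(np.int64) if mode == "binary" else counts
    return FingerprintVector(values=values, family=family, mode=mode)


def mix_slices(hashed_length: int = DEFAULT_HASHED_LENGTH) -> dict[str, slice]:
    """Family offsets inside a MIX vector: [maccs | extended | graph | circular]."""
    offsets = {}
    start = 0
    for family, flen in (
        ("maccs", MACCS_LENGTH),
        ("extended", hashed_length),
        ("graph", hashed_length),
        ("circular", hashed_length),
    ):
        offsets[family] = slice(start, start + flen)
        start += flen
    return offsets


def mix_fingerprint(
    smiles: str,
    mode: str = "counting",
    hashed_length: int = DEFAULT_HASHED_LENGTH,
    depth: int = DEFAULT_PATH_DEPTH,
    radius: int = DEFAULT_RADIUS,
) -> FingerprintVector:
    """MIX fingerprint: concatenation of the four families in fixed order."""
    parts = [
        maccs_fingerprint(smiles, mode).values,
        hashed_fingerprint(smiles, "extended", mode, hashed_length, depth).values,
        hashed_fingerprint(smiles, "graph", mode, hashed_length, depth).values,
        hashed_fingerprint(smiles, "circular", mode, hashed_length, radius).values,
    ]
    return FingerprintVector(values=np.concatenate(parts), family="mix", mode=mode)


def fingerprint(
    smiles: str,
    family: str = "mix",
    mode: str = "counting",
    hashed_length: int = DEFAULT_HASHED_LENGTH,
    depth: int = DEFAULT_PATH_DEPTH,
    radius: int = DEFAULT_RADIUS,
) -> FingerprintVector:
    """Compute any fingerprint family by name."""
    if family == "maccs":
        return maccs_fingerprint(smiles, mode)
    if family == "mix":
        return mix_fingerprint(smiles, mode, hashed_length, depth, radius)
    if family in HASHED_FAMILIES:
        d = radius if family == "circular" else depth
        return hashed_fingerprint(smiles, family, mode, hashed_length, d)
    raise ValueError(f"unknown fingerprint family {family!r}")


def fingerprint_matrix(
    smiles_list: Sequence[str],
    family: str = "mix",
    mode: str = "counting",
    hashed_length: int = DEFAULT_HASHED_LENGTH,
    depth: int = DEFAULT_PATH_DEPTH,
    radius: int = DEFAULT_RADIUS,
) -> np.ndarray:
    """Stack fingerprints for a list of SMILES into an (n, length) matrix."""
    rows = [
        fingerprint(s, family, mode, hashed_length, depth, radius).values
        for s in smiles_list
    ]
    return np.vstack(rows)


def feature_labels(
    family: str = "mix", hashed_length: int = DEFAULT_HASHED_LENGTH
) -> list[str]:
    """Human-readable label per fingerprint slot (MACCS slots carry SMARTS)."""
    maccs = [
        f"MACCS_{k}:{_MACCS_SMARTS[k][0]}" for k in range(1, MACCS_LENGTH + 1)
    ]
    if family == "maccs":
        return maccs
    if family in HASHED_FAMILIES:
        return [f"{family}_{i}" for i in range(hashed_length)]
    if family == "mix":
        labels = list(maccs)
        for fam in HASHED_FAMILIES:
            labels.extend(f"{fam}_{i}" for i in range(hashed_length))
        return labels
    raise ValueError(f"unknown fingerprint family {family!r}")
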