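"""Synthetic molecule libraries with controllable retention behavior.

Real retention-order corpora (public RT collections of small molecules,
peptide RTs from proteomics runs) cannot ship with the package, so every
pipeline stage is exercised on libraries drawn from a small fragment grammar:

* *small molecules* — linear/branched assemblies of alkyl units, aromatic
  rings, hydroxyl/ether, carboxyl, amine, amide, halogenated and N-methylated
  fragments;
* *peptide-like* molecules — 5–12 residues drawn from 8 residue types,
  including two "non-proteinogenic" decorated residues (an N-methylated and a
  halogenated one) to mimic PNPAs.

Retention times follow a reversed-phase-flavored linear model: hydrophobic
substructure counts (aliphatic carbons, aromatic rings, methyl groups) raise
RT, hydrogen-bonding capacity lowers it, plus independent Gaussian noise:

    rt = a0 + a1·#aliphatic_C + a2·#aromatic_rings + a3·#CH3
            − a4·(#HBD + #HBA) + N(0, noise_sd),  clipped at 0.

Everything is deterministic given the seed. Because the RT-generating counts
are themselves substructure features, a noise-free library is a ground-truth
case where retention order is exactly learnable from fingerprints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import Lipinski, rdMolDescriptors

from .chemio import MoleculeRecord

__all__ = [
    "GeneratorConfig",
    "generate_library",
    "assign_rt",
    "synthetic_dataset",
    "sample_fragments",
    "rt_range",
    "rt_features",
]

# Chain-safe fragments: concatenating any sequence of these (after a leading
# carbon) yields a valid SMILES because each fragment starts and ends on an
# atom with a free valence and closes all its own rings/branches.
DEFAULT_FRAGMENTS: tuple[tuple[str, float], ...] = (
    ("C", 3.0),          # methylene extension
    ("CC", 2.0),         # ethylene
    ("C(C)", 1.5),       # branch methyl
    ("c1ccccc1", 1.0),   # aromatic ring
    ("O", 0.8),          # hydroxyl / ether
    ("C(=O)O", 0.6),     # carboxyl / ester linkage
    ("N", 0.6),          # amine
    ("C(=O)N", 0.6),     # amide
    ("C(Cl)", 0.3),      # halogen
    ("N(C)", 0.4),       # N-methyl
)

# Residue bodies "N–Cα(side chain)–C(=O)" that chain into peptides; the last
# two are the non-proteinogenic decorations (N-methylated, halogenated).
RESIDUES: tuple[str, ...] = (
    "NCC(=O)",                      # glycine-like
    "NC(C)C(=O)",                   # alanine-like
    "NC(CC(C)C)C(=O)",              # leucine-like
    "NC(Cc1ccccc1)C(=O)",           # phenylalanine-like
    "NC(CO)C(=O)",                  # serine-like
    "NC(CC(=O)O)C(=O)",             # aspartate-like
    "N(C)C(C)C(=O)",                # N-methyl-alanine-like
    "NC(Cc1ccc(Cl)cc1)C(=O)",       # p-chloro-phenylalanine-like
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic corpus.

    Defaults emulate a combined small-molecule + peptide training corpus at a
    desk scale: 300 molecules, half peptide-like, five round-robin subsets,
    RTs spanning roughly 1–15 min with 0.5 min measurement noise.
    """

    n_molecules: int = 300
    seed: int = 1
    peptide_fraction: float = 0.5
    fragment_grammar: tuple[tuple[str, float], ...] = DEFAULT_FRAGMENTS
    rt_coefficients: tuple[float, float, float, float, float] = (
        1.0,   # a0: column dead time offset, minutes
        0.12,  # a1: per aliphatic carbon
        0.6,   # a2: per aromatic ring
        0.4,   # a3: per methyl group
        0.1,   # a4: per H-bond donor+acceptor (subtracted)
    )
    noise_sd: float = 0.5
    n_subsets: int = 5
    min_fragments: int = 2
    max_fragments: int = 8
    min_residues: int = 5
    max_residues: int = 12

    def __post_init__(self) -> None:
        if self.n_subsets < 2 or self.n_molecules < self.n_subsets:
            raise ValueError("need n_molecules >= n_subsets >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not all(np.isfinite(w) for _, w in self.fragment_grammar):
            raise ValueError("fragment weights must be finite")
        if not all(np.isfinite(a) for a in self.rt_coefficients):
            raise ValueError("rt coefficients must be finite")


def sample_fragments(rng: np.random.Generator, config: GeneratorConfig) -> list[str]:
    """Draw one molecule's fragment sequence from the weighted grammar."""
    fragments, weights = zip(*config.fragment_grammar)
    prob = np.asarray(weights, float) / np.sum(weights)
    k = int(rng.integers(config.min_fragments, config.max_fragments + 1))
    picks = rng.choice(len(fragments), size=k, p=prob)
    return [fragments[i] for i in picks]


def _assemble_small_molecule(rng: np.random.Generator, config: GeneratorConfig) -> str:
    return "C" + "".join(sample_fragments(rng, config))


def _assemble_peptide(rng: np.random.Generator, config: GeneratorConfig) -> str:
    k = int(rng.integers(config.min_residues, config.max_residues + 1))
    picks = rng.integers(0, len(RESIDUES), size=k)
    return "".join(RESIDUES[i] for i in picks) + "O"  # C-terminal acid


def generate_library(config: GeneratorConfig) -> list[MoleculeRecord]:
    """Draw a deterministic library of valid molecules from the grammar."""
    rng = np.random.default_rng(config.seed)
    records = []
    n_peptides = round(config.n_molecules * config.peptide_fraction)
    for i in range(config.n_molecules):
        if i < n_peptides:
            smiles, dataset = _assemble_peptide(rng, config), "peptide"
        else:
            smiles, dataset = _assemble_small_molecule(rng, config), "smallmol"
        mol = Chem.MolFromSmiles(smiles)
        assert mol is not None, f"grammar bug: invalid SMILES {smiles!r}"
        records.append(
            MoleculeRecord(id=f"SYN{i:04d}", smiles=smiles, dataset=dataset)
        )
    return records


_ALIPHATIC_C = Chem.MolFromSmarts("[C;!c]")
_METHYL = Chem.MolFromSmarts("[CH3]")


def rt_features(smiles: str) -> tuple[int, int, int, int]:
    """(aliphatic C, aromatic rings, methyl groups, HBD+HBA) counts."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid structure: {smiles!r}")
    aliphatic = len(mol.GetSubstructMatches(_ALIPHATIC_C))
    rings = rdMolDescriptors.CalcNumAromaticRings(mol)
    methyls = len(mol.GetSubstructMatches(_METHYL))
    hbonds = Lipinski.NumHDonors(mol) + Lipinski.NumHAcceptors(mol)
    return aliphatic, rings, methyls, hbonds


def assign_rt(
    records: list[MoleculeRecord], config: GeneratorConfig
) -> list[MoleculeRecord]:
    """Attach retention times from the linear hydrophobicity model + noise."""
    rng = np.random.default_rng(config.seed + 1)  # independent of assembly draws
    a0, a1, a2, a3, a4 = config.rt_coefficients
    out = []
    for rec in records:
        aliphatic, rings, methyls, hbonds = rt_features(rec.smiles)
        rt = a0 + a1 * aliphatic + a2 * rings + a3 * methyls - a4 * hbonds
        rt += rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0
        out.append(rec.with_rt(max(rt, 0.0)))
    return out


def synthetic_dataset(config: GeneratorConfig) -> list[MoleculeRecord]:
    """Generate a library and assign RTs in one call."""
    return assign_rt(generate_library(config), config)


def rt_range(records: list[MoleculeRecord]) -> float:
    """Spread (max − min) of retention times, minutes."""
    rts = [r.rt for r in records if r.rt is not None]
    if not rts:
        raise ValueError("no retention times present")
    return max(rts) - min(rts)
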