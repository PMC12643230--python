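"""Structure + retention-time tables and retention-time-stratified splitting.

The central container is :class:`MoleculeRecord` — one compound with an
identifier, a SMILES structure, an optional retention time (RT, minutes) and
dataset/subset labels. Tables are read from CSV (schema
``id,smiles,rt,dataset,subset``; only ``id`` and ``smiles`` required) or SDF.

Cross-validation subsets are built by *round-robin* assignment: records are
sorted by RT and dealt cyclically into ``k`` subsets so that every subset
spans the full RT range with a near-uniform RT distribution. This mirrors the
standard practice for retention-order training corpora, where each fold must
cover early-, mid- and late-eluting chemistry.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem.Descriptors import ExactMolWt

__all__ = [
    "MoleculeRecord",
    "ReferencePanel",
    "ReadResult",
    "read_rt_table",
    "load_reference_panel",
    "neutral_monoisotopic_mass",
    "round_robin_split",
]


@dataclass(frozen=True)
class MoleculeRecord:
    """One compound: identifier, SMILES, optional RT (minutes), labels."""

    id: str
    smiles: str
    rt: float | None = None
    dataset: str = ""
    subset: str | None = None

    def __post_init__(self) -> None:
        if self.rt is not None and self.rt < 0:
            raise ValueError(f"record {self.id!r}: rt must be >= 0, got {self.rt}")

    def with_rt(self, rt: float) -> "MoleculeRecord":
        return replace(self, rt=float(rt))

    def with_subset(self, subset: str) -> "MoleculeRecord":
        return replace(self, subset=subset)


@dataclass(frozen=True)
class ReferencePanel:
    """Reference compounds with measured RTs, sorted ascending by RT.

    RT ties are resolved by input order (stable sort), so the stored order is
    deterministic. ``n`` is the panel size used by the order-agreement
    statistic S.
    """

    records: tuple[MoleculeRecord, ...]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError("a reference panel needs at least 2 compounds")
        for rec in self.records:
            if rec.rt is None:
                raise ValueError(f"reference {rec.id!r} has no retention time")

    @classmethod
    def from_records(cls, records: Iterable[MoleculeRecord]) -> "ReferencePanel":
        recs = sorted(records, key=lambda r: r.rt if r.rt is not None else -1.0)
        return cls(records=tuple(recs))

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def rts(self) -> tuple[float, ...]:
        return tuple(r.rt for r in self.records)  # type: ignore[misc]

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.records)

    @property
    def smiles(self) -> tuple[str, ...]:
        return tuple(r.smiles for r in self.records)


@dataclass
class ReadResult:
    """Records read from a table plus per-row rejections (index, reason)."""

    records: list[MoleculeRecord]
    rejected: list[tuple[int, str]] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _parse_or_none(smiles: str) -> Chem.Mol | None:
    if not isinstance(smiles, str) or not smiles.strip():
        return None
    return Chem.MolFromSmiles(smiles)


def read_rt_table(
    source: str | Path,
    fmt: str = "csv",
    rt_property: str = "RETENTION_TIME",
) -> ReadResult:
    """Read a structure+RT table from CSV or SDF.

    CSV columns: ``id`` and ``smiles`` are required; ``rt``, ``dataset`` and
    ``subset`` are optional. SDF records take the identifier from the molecule
    name (or an ``id`` property) and the RT from ``rt_property``.

    Rows whose structure does not parse are collected in
    :attr:`ReadResult.rejected` with their 0-based row index; a missing
    required column raises :class:`ValueError` naming the column. Row order is
    preserved.
    """
    if fmt == "csv":
        return _read_csv(source)
    if fmt == "sdf":
        return _read_sdf(source, rt_property)
    raise ValueError(f"unknown table format {fmt!r} (expected 'csv' or 'sdf')")


def _read_csv(source: str | Path) -> ReadResult:
    df = pd.read_csv(
        source, dtype={"id": str, "smiles": str, "dataset": str, "subset": str}
    )
    for col in ("id", "smiles"):
        if col not in df.columns:
            raise ValueError(f"required column {col!r} missing from {source}")
    result = ReadResult(records=[])
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        rid = str(row.id)
        mol = _parse_or_none(row.smiles)
        if mol is None:
            result.rejected.append((i, f"unparsable SMILES {row.smiles!r}"))
            continue
        if rid in seen:
            result.rejected.append((i, f"duplicate id {rid!r}"))
            continue
        seen.add(rid)
        rt = getattr(row, "rt", None)
        rt = None if rt is None or pd.isna(rt) else float(rt)
        dataset = getattr(row, "dataset", "")
        dataset = "" if dataset is None or pd.isna(dataset) else str(dataset)
        subset = getattr(row, "subset", None)
        subset = None if subset is None or pd.isna(subset) else str(subset)
        result.records.append(
            MoleculeRecord(id=rid, smiles=str(row.smiles), rt=rt, dataset=dataset, subset=subset)
        )
    return result


def _read_sdf(source: str | Path, rt_property: str) -> ReadResult:
    supplier = Chem.SDMolSupplier(str(source))
    result = ReadResult(records=[])
    seen: set[str] = set()
    for i, mol in enumerate(supplier):
        if mol is None:
            result.rejected.append((i, "unparsable SDF record"))
            continue
        rid = mol.GetProp("id") if mol.HasProp("id") else mol.GetProp("_Name")
        if not rid:
            result.rejected.append((i, "record has no name/id"))
            continue
        if rid in seen:
            result.rejected.append((i, f"duplicate id {rid!r}"))
            continue
        seen.add(rid)
        rt = float(mol.GetProp(rt_property)) if mol.HasProp(rt_property) else None
        dataset = mol.GetProp("dataset") if mol.HasProp("dataset") else ""
        result.records.append(
            MoleculeRecord(id=rid, smiles=Chem.MolToSmiles(mol), rt=rt, dataset=dataset)
        )
    return result


def write_rt_table(records: Sequence[MoleculeRecord], path: str | Path) -> None:
    """Write records to the CSV schema ``id,smiles,rt,dataset,subset``."""
    pd.DataFrame(
        {
            "id": [r.id for r in records],
            "smiles": [r.smiles for r in records],
            "rt": [r.rt for r in records],
            "dataset": [r.dataset for r in records],
            "subset": [r.subset for r in records],
        }
    ).to_csv(path, index=False)


def load_reference_panel() -> ReferencePanel:
    """Load the packaged 22-compound reference panel (RT 1.74–9.95 min).

    Retention times are the panel's measured values on a C18 reversed-phase
    gradient; the SMILES are curated by hand from compound names and are
    best-effort structure renderings, not authoritative registry records.
    """
    path = importlib.resources.files("retorder.data") / "reference_panel.csv"
    with importlib.resources.as_file(path) as p:
        result = read_rt_table(p, fmt="csv")
    if result.rejected:
        raise RuntimeError(f"packaged panel has bad rows: {result.rejected}")
    return ReferencePanel.from_records(result.records)


def neutral_monoisotopic_mass(smiles: str) -> float:
    """Monoisotopic neutral mass in Da (most-abundant isotope of each element)."""
    mol = _parse_or_none(smiles)
    if mol is None:
        raise ValueError(f"invalid structure: {smiles!r}")
    return ExactMolWt(mol)


def round_robin_split(records: Sequence[MoleculeRecord], k: int) -> list[list[MoleculeRecord]]:
    """Deal RT-sorted records cyclically into ``k`` subsets.

    Records are stable-sorted ascending by RT (ties keep input order) and
    record ``i`` of the sorted list goes to subset ``i mod k``, so every
    subset spans the global RT range and sizes differ by at most one.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2 for cross-validation splitting, got {k}")
    if k > len(records):
        raise ValueError(f"k={k} exceeds the number of records ({len(records)})")
    for rec in records:
        if rec.rt is None:
            raise ValueError(f"record {rec.id!r} has no retention time")
    ordered = sorted(records, key=lambda r: r.rt)  # stable: ties by input order
    subsets: list[list[MoleculeRecord]] = [[] for _ in range(k)]
    for i, rec in enumerate(ordered):
        subsets[i % k].append(rec)
    return subsets
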