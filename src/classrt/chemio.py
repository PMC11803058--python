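"""Dataset I/O, SMILES canonicalization, deterministic splitting, persistence.

The molecule table is the package's central container: an ordered collection
of :class:`MoleculeRecord` plus a provenance tag per record distinguishing
measured compounds from augmentation products. Canonical SMILES (RDKit
canonical form, stereochemistry preserved but not used for identity) is the
identity key for all deduplication and leakage logic.

Retention times are seconds throughout; readers accept minutes and convert
at ingest.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Literal, Optional

import numpy as np
from rdkit import Chem, RDLogger

from .errors import (
    ConfigurationError,
    DatasetTooSmallError,
    EmptyInputError,
    InvalidMoleculeError,
)

RDLogger.DisableLog("rdApp.*")

PROVENANCE_ORIGINAL = "original"
PROVENANCE_SE = "se_augmented"
PROVENANCE_TOPO = "topo_al_added"


def canonicalize(smiles: str) -> str:
    """Return the RDKit canonical SMILES for ``smiles``.

    Deterministic and idempotent: ``canonicalize(canonicalize(s)) ==
    canonicalize(s)``. Raises :class:`InvalidMoleculeError` on parse failure.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidMoleculeError(smiles)
    return Chem.MolToSmiles(mol)


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse a SMILES, raising :class:`InvalidMoleculeError` on failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidMoleculeError(smiles)
    return mol


@dataclass(frozen=True)
class MoleculeRecord:
    """One compound: identifier, SMILES forms, retention time in seconds."""

    id: str
    smiles_raw: str
    smiles_canonical: str
    rt: Optional[float] = None  # seconds; None only for query records
    class_path: Optional[tuple[str, str]] = None  # (superclass, subclass)

    def __post_init__(self):
        if self.rt is not None and not (self.rt > 0 and math.isfinite(self.rt)):
            raise ConfigurationError(
                f"record {self.id!r}: rt must be a finite positive number of "
                f"seconds, got {self.rt!r}"
            )

    @classmethod
    def from_smiles(
        cls, id: str, smiles: str, rt: Optional[float] = None
    ) -> "MoleculeRecord":
        return cls(id=id, smiles_raw=smiles, smiles_canonical=canonicalize(smiles), rt=rt)


@dataclass
class DatasetTable:
    """Ordered molecule records with per-record provenance tags."""

    records: list[MoleculeRecord] = field(default_factory=list)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            seen, dup = set(), None
            for i in ids:
                if i in seen:
                    dup = i
                    break
                seen.add(i)
            raise ConfigurationError(f"duplicate record id {dup!r} in table")
        for r in self.records:
            self.provenance.setdefault(r.id, PROVENANCE_ORIGINAL)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[MoleculeRecord]:
        return iter(self.records)

    def canonical_set(self) -> set[str]:
        return {r.smiles_canonical for r in self.records}

    def rts(self) -> np.ndarray:
        return np.asarray([r.rt for r in self.records], dtype=float)

    def subset(self, ids: Iterable[str]) -> "DatasetTable":
        keep = set(ids)
        recs = [r for r in self.records if r.id in keep]
        return DatasetTable(recs, {r.id: self.provenance[r.id] for r in recs})

    def extend(self, records: Iterable[MoleculeRecord], provenance: str) -> None:
        for r in records:
            if r.id in self.provenance:
                raise ConfigurationError(f"duplicate record id {r.id!r} on extend")
            self.records.append(r)
            self.provenance[r.id] = provenance

    def counts(self) -> dict[str, int]:
        out = {PROVENANCE_ORIGINAL: 0, PROVENANCE_SE: 0, PROVENANCE_TOPO: 0}
        for r in self.records:
            out[self.provenance[r.id]] = out.get(self.provenance[r.id], 0) + 1
        return out

    def copy(self) -> "DatasetTable":
        return DatasetTable(list(self.records), dict(self.provenance))


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test ratios (default 8:1:1) and the shuffle seed."""

    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self):
        if any(r < 0 for r in self.ratios):
            raise ConfigurationError("split ratios must be non-negative")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ConfigurationError(
                f"split ratios must sum to 1, got {sum(self.ratios)!r}"
            )


def read_dataset(
    path: str | Path,
    format: Literal["csv", "smi"] = "csv",
    rt_unit: Literal["s", "min"] = "s",
    require_rt: bool = True,
) -> tuple[DatasetTable, int]:
    """Read a molecule table, canonicalizing every SMILES.

    CSV files need header columns ``id,smiles,rt`` (``rt`` optional for query
    files when ``require_rt=False``); SMI files hold one ``SMILES<TAB>id`` per
    line. Unparseable rows are dropped and counted; the rejection count is
    returned alongside the table.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file not found: {path}")
    rows: list[tuple[str, str, Optional[float]]] = []
    if format == "csv":
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh)
            cols = [c.strip().lower() for c in (reader.fieldnames or [])]
            if "id" not in cols or "smiles" not in cols:
                raise ConfigurationError(
                    f"{path}: CSV must have 'id' and 'smiles' columns, got {cols}"
                )
            has_rt = "rt" in cols
            if require_rt and not has_rt:
                raise ConfigurationError(f"{path}: CSV is missing the 'rt' column")
            for raw in reader:
                raw = {k.strip().lower(): v for k, v in raw.items() if k}
                rt_val: Optional[float] = None
                if has_rt and raw.get("rt") not in (None, ""):
                    try:
                        rt_val = float(raw["rt"])
                    except ValueError:
                        rt_val = float("nan")
                rows.append((str(raw["id"]).strip(), str(raw["smiles"]).strip(), rt_val))
    elif format == "smi":
        for lineno, line in enumerate(path.read_text().splitlines(), 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            smiles = parts[0]
            rid = parts[1] if len(parts) > 1 else f"line{lineno}"
            rows.append((rid, smiles, None))
    else:
        raise ConfigurationError(f"unknown format {format!r}")

    records: list[MoleculeRecord] = []
    rejected = 0
    seen_ids: set[str] = set()
    for rid, smiles, rt in rows:
        if rt is not None:
            if not math.isfinite(rt) or rt <= 0:
                rejected += 1
                continue
            if rt_unit == "min":
                rt = rt * 60.0
        try:
            rec = MoleculeRecord.from_smiles(rid, smiles, rt)
        except InvalidMoleculeError:
            rejected += 1
            continue
        if rid in seen_ids:
            rejected += 1
            continue
        seen_ids.add(rid)
        records.append(rec)
    if not records:
        raise EmptyInputError(f"{path}: no parseable records")
    return DatasetTable(records), rejected


def write_dataset(table: DatasetTable, path: str | Path) -> None:
    """Write ``id,smiles,rt,provenance`` CSV (rt in seconds, blank if absent)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "smiles", "rt", "provenance"])
        for r in table.records:
            w.writerow(
                [
                    r.id,
                    r.smiles_canonical,
                    "" if r.rt is None else repr(float(r.rt)),
                    table.provenance[r.id],
                ]
            )


def split_dataset(
    table: DatasetTable, spec: SplitSpec = SplitSpec()
) -> tuple[DatasetTable, DatasetTable, DatasetTable]:
    """Deterministic train/val/test split, disjoint by canonical SMILES.

    Records sharing a canonical SMILES travel together (they are the same
    molecule, and letting copies straddle the split would leak labels).
    Subset sizes are the floors of the ratios with the remainder assigned to
    train. Splitting precedes augmentation: only ``original`` records are
    accepted.
    """
    if any(table.provenance[r.id] != PROVENANCE_ORIGINAL for r in table.records):
        raise ConfigurationError("split_dataset requires an unaugmented table")
    if len(table) < 3:
        raise DatasetTooSmallError(f"need >= 3 records to split, got {len(table)}")

    groups: dict[str, list[MoleculeRecord]] = {}
    order: list[str] = []
    for r in table.records:
        if r.smiles_canonical not in groups:
            groups[r.smiles_canonical] = []
            order.append(r.smiles_canonical)
        groups[r.smiles_canonical].append(r)

    n = len(order)
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    n_val = int(math.floor(n * spec.ratios[1]))
    n_test = int(math.floor(n * spec.ratios[2]))
    n_train = n - n_val - n_test  # floor of train ratio plus all remainders

    shuffled = [order[i] for i in perm]
    buckets = (
        shuffled[:n_train],
        shuffled[n_train : n_train + n_val],
        shuffled[n_train + n_val :],
    )

    def build(keys: list[str]) -> DatasetTable:
        keyset = set(keys)
        recs = [r for r in table.records if r.smiles_canonical in keyset]
        return DatasetTable(recs, {r.id: PROVENANCE_ORIGINAL for r in recs})

    return build(buckets[0]), build(buckets[1]), build(buckets[2])


def with_rt(record: MoleculeRecord, rt: float) -> MoleculeRecord:
    return replace(record, rt=rt)


def save_model(model, dir: str | Path) -> dict:
    """Persist a trained ensemble to ``dir``; returns the written manifest."""
    from .persist import save_ensemble

    return save_ensemble(model, dir)


def load_model(dir: str | Path):
    """Load an ensemble saved by :func:`save_model`."""
    from .persist import load_ensemble

    return load_ensemble(dir)
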