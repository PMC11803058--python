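"""Local 3-tier compound classification by weighted SMARTS rules.

Each rule pairs a SMARTS functional-group pattern with a priority weight and
a (superclass, subclass) label. A molecule is assigned the class of its
highest-weight matching rule — more specific groups carry larger weights, so
a sulfonamide outranks the amine pattern its nitrogen might also hit. Ties
break on lexicographic rule id; molecules matching nothing fall back to a
configurable catch-all class. The shipped default rule file spans 13
superclasses of food-contaminant chemistry (organoheterocyclics, benzenoids,
organic acids, organosulfur compounds, ...).
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

from rdkit import Chem

from .chemio import DatasetTable, MoleculeRecord, mol_from_smiles
from .errors import ConfigurationError, RuleError

FALLBACK_CLASS = ("unclassified", "unclassified")
RESIDUAL_CLASS_ID = "residual"


@dataclass(frozen=True)
class FunctionalGroupRule:
    """One weighted SMARTS rule mapping a functional group to a class."""

    rule_id: str
    smarts: str
    weight: float
    superclass: str
    subclass: str
    pattern: Chem.Mol = field(compare=False, repr=False, default=None)

    def __post_init__(self):
        if self.weight <= 0:
            raise RuleError(f"rule {self.rule_id!r}: weight must be > 0")
        if not self.superclass or not self.subclass:
            raise RuleError(f"rule {self.rule_id!r}: empty class label")
        if self.pattern is None:
            pat = Chem.MolFromSmarts(self.smarts)
            if pat is None:
                raise RuleError(
                    f"rule {self.rule_id!r}: SMARTS does not compile: {self.smarts!r}"
                )
            object.__setattr__(self, "pattern", pat)


@dataclass
class RuleSet:
    """Ordered rules plus the fallback class for unmatched molecules."""

    rules: list[FunctionalGroupRule]
    fallback: tuple[str, str] = FALLBACK_CLASS

    def __post_init__(self):
        if not self.rules:
            raise RuleError("a RuleSet needs at least one rule")
        ids = [r.rule_id for r in self.rules]
        if len(ids) != len(set(ids)):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise RuleError(f"duplicate rule_id {dup!r}")

    def superclasses(self) -> set[str]:
        return {r.superclass for r in self.rules}

    def content_hash(self) -> str:
        """Stable hash of rule content; stored in model manifests."""
        h = hashlib.sha256()
        for r in self.rules:
            h.update(
                f"{r.rule_id}\t{r.smarts}\t{r.weight!r}\t{r.superclass}\t{r.subclass}\n".encode()
            )
        h.update(f"{self.fallback}".encode())
        return h.hexdigest()[:16]


@dataclass(frozen=True)
class ClassAssignment:
    superclass: str
    subclass: str
    winning_weight: float
    matched_rule_ids: tuple[str, ...]


def compile_rules(rule_file: str | Path) -> RuleSet:
    """Compile a TSV rule file: ``rule_id  smarts  weight  superclass  subclass``."""
    path = Path(rule_file)
    if not path.exists():
        raise ConfigurationError(f"rule file not found: {path}")
    rules: list[FunctionalGroupRule] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, 1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) != 5:
                raise RuleError(f"{path}:{lineno}: expected 5 tab-separated fields")
            rule_id, smarts, weight, sup, sub = (c.strip() for c in row)
            try:
                w = float(weight)
            except ValueError:
                raise RuleError(f"{path}:{lineno}: bad weight {weight!r}") from None
            rules.append(FunctionalGroupRule(rule_id, smarts, w, sup, sub))
    return RuleSet(rules)


def default_ruleset() -> RuleSet:
    """The rule set shipped with the package (13 superclasses)."""
    with resources.as_file(
        resources.files("classrt.data").joinpath("default_rules.tsv")
    ) as p:
        return compile_rules(p)


def assign_class(
    mol: MoleculeRecord | str, rules: RuleSet
) -> ClassAssignment:
    """Classify a molecule: highest-weight matching rule wins.

    Total and deterministic — ties break on lexicographic rule id, and a
    molecule matching no rule receives the fallback class with weight 0.
    """
    smiles = mol.smiles_canonical if isinstance(mol, MoleculeRecord) else mol
    rdmol = mol_from_smiles(smiles)
    matched = [r for r in rules.rules if rdmol.HasSubstructMatch(r.pattern)]
    if not matched:
        return ClassAssignment(*rules.fallback, winning_weight=0.0, matched_rule_ids=())
    winner = min(matched, key=lambda r: (-r.weight, r.rule_id))
    return ClassAssignment(
        superclass=winner.superclass,
        subclass=winner.subclass,
        winning_weight=winner.weight,
        matched_rule_ids=tuple(sorted(r.rule_id for r in matched)),
    )


def partition_by_class(
    table: DatasetTable, rules: RuleSet, min_size: int = 15
) -> tuple[dict[str, DatasetTable], DatasetTable]:
    """Partition records into per-subclass tables plus a residual pool.

    Subclasses with fewer than ``min_size`` records merge into the residual
    pool (which later trains a single fallback submodel), so every record
    lands in exactly one output table.
    """
    if min_size < 3:
        raise ConfigurationError("min_size must be >= 3")
    by_class: dict[str, list[MoleculeRecord]] = {}
    for rec in table.records:
        sub = assign_class(rec, rules).subclass
        by_class.setdefault(sub, []).append(rec)

    out: dict[str, DatasetTable] = {}
    residual: list[MoleculeRecord] = []
    for sub in sorted(by_class):
        recs = by_class[sub]
        if len(recs) >= min_size and sub != RESIDUAL_CLASS_ID:
            out[sub] = DatasetTable(
                recs, {r.id: table.provenance[r.id] for r in recs}
            )
        else:
            residual.extend(recs)
    residual_table = DatasetTable(
        residual, {r.id: table.provenance[r.id] for r in residual}
    )
    return out, residual_table


def classify_table(
    table: DatasetTable, rules: Optional[RuleSet] = None
) -> list[tuple[str, ClassAssignment]]:
    """Assign every record; returns (record id, assignment) pairs in order."""
    rules = rules or default_ruleset()
    return [(rec.id, assign_class(rec, rules)) for rec in table.records]
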