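"""Training-set augmentation: SMILES enumeration and topology-guided
active learning, with leakage exclusion and an over-augmentation guard.

Two strategies grow the training table:

* **SMILES enumeration (SE)** — re-render each training molecule as up to
  *k* distinct non-canonical SMILES strings (random atom-traversal order).
  The molecular graph is unchanged, so for descriptor-based regressors this
  acts as sample re-weighting; enumerated rows keep the parent's retention
  time and canonical form and are tagged ``se_augmented``.
* **Topo-AL** — recruit labeled compounds from a wider pool whose maximum
  fingerprint similarity to the training set reaches a threshold (default
  0.5), after excluding anything whose canonical SMILES already appears in
  the validation or test sets. Recruits keep their own measured retention
  times and are tagged ``topo_al_added``.

Over-augmentation is caught by a validation guard: a cheap probe model is
refit after each enumeration step, and the loop stops once validation MAE
rises past a tolerance above the best value seen, returning the best set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional

from rdkit import Chem

from .chemio import (
    PROVENANCE_SE,
    PROVENANCE_TOPO,
    DatasetTable,
    MoleculeRecord,
    mol_from_smiles,
)
from .errors import ConfigurationError
from .simfp import bulk_max_similarity, ecfp


@dataclass(frozen=True)
class AugmentConfig:
    """Knobs for the combined SE + Topo-AL augmentation."""

    k: int = 5  # enumeration multiple
    sim_threshold: float = 0.5  # Topo-AL inclusion threshold (>=)
    topo_enabled: bool = True
    guard_enabled: bool = True
    guard_tolerance: float = 0.01  # relative val-MAE rise that stops the loop
    seed: int = 0
    fp_radius: int = 2
    fp_nbits: int = 2048
    similarity_metric: str = "tanimoto"

    def __post_init__(self):
        if self.k < 0:
            raise ConfigurationError("enumeration multiple k must be >= 0")
        if not (0.0 < self.sim_threshold <= 1.0):
            raise ConfigurationError("sim_threshold must be in (0, 1]")


@dataclass
class AugmentedSet:
    """Augmented training table with provenance counts and the guard log."""

    table: DatasetTable
    counts: dict[str, int]
    log: list[dict] = field(default_factory=list)


def enumerate_smiles(
    mol: MoleculeRecord | str, k: int, seed: int = 0
) -> list[str]:
    """Up to ``k`` distinct non-canonical renderings of one molecule.

    Every returned string parses and canonicalizes back to the molecule's
    canonical form, differs from that canonical form, and is distinct from
    the other variants. Small graphs admit few renderings, so fewer than
    ``k`` strings may come back; generation retries within a 10·k budget.
    """
    if k == 0:
        return []
    smiles = mol.smiles_canonical if isinstance(mol, MoleculeRecord) else mol
    rdmol = mol_from_smiles(smiles)
    canonical = Chem.MolToSmiles(rdmol)
    variants: list[str] = []
    seen: set[str] = {canonical}
    budget = 10 * k
    drawn = 0
    batch_seed = seed % (2**31 - 1) or 1
    while len(variants) < k and drawn < budget:
        n = min(budget - drawn, max(k, 4))
        for s in Chem.MolToRandomSmilesVect(rdmol, n, randomSeed=batch_seed):
            drawn += 1
            if s in seen:
                continue
            check = Chem.MolFromSmiles(s)
            if check is None or Chem.MolToSmiles(check) != canonical:
                continue  # defensive; RDKit renderings round-trip in practice
            seen.add(s)
            variants.append(s)
            if len(variants) == k:
                break
        batch_seed = (batch_seed * 48271) % (2**31 - 1)
    return variants


def _se_expand(table: DatasetTable, m: int, seed: int) -> DatasetTable:
    """Table plus up to m enumerated variants of every record."""
    out = table.copy()
    for idx, rec in enumerate(table.records):
        rec_seed = (seed * 1_000_003 + idx) % (2**31 - 1)
        for j, var in enumerate(enumerate_smiles(rec, m, rec_seed)):
            out.extend(
                [
                    MoleculeRecord(
                        id=f"{rec.id}#se{j}",
                        smiles_raw=var,
                        smiles_canonical=rec.smiles_canonical,
                        rt=rec.rt,
                        class_path=rec.class_path,
                    )
                ],
                PROVENANCE_SE,
            )
    return out


def topo_al_expand(
    train: DatasetTable,
    pool: DatasetTable,
    test_like: DatasetTable,
    tau: float = 0.5,
    fp_radius: int = 2,
    fp_nbits: int = 2048,
    metric: str = "tanimoto",
) -> DatasetTable:
    """Recruit pool compounds structurally similar to the training set.

    A pool record joins the training table when its maximum fingerprint
    similarity to any training molecule is ≥ ``tau`` — after first dropping
    every pool record whose canonical SMILES occurs in ``test_like`` (the
    validation + test material) or already in train. Recruits keep their own
    measured retention times.
    """
    if not (0.0 < tau <= 1.0):
        raise ConfigurationError("tau must be in (0, 1]")
    for rec in pool.records:
        if rec.rt is None:
            raise ConfigurationError(
                f"pool record {rec.id!r} has no measured rt; Topo-AL requires labels"
            )
    excluded = test_like.canonical_set() | train.canonical_set()
    candidates = [r for r in pool.records if r.smiles_canonical not in excluded]
    out = train.copy()
    if not candidates or not train.records:
        return out
    train_fps = [ecfp(s, fp_radius, fp_nbits) for s in sorted(train.canonical_set())]
    cand_fps = [ecfp(r, fp_radius, fp_nbits) for r in candidates]
    max_sim = bulk_max_similarity(cand_fps, train_fps, metric)
    used_ids = set(out.provenance)
    seen_canonical = out.canonical_set()
    for rec, sim in zip(candidates, max_sim):
        if sim < tau or rec.smiles_canonical in seen_canonical:
            continue
        rid = rec.id if rec.id not in used_ids else f"{rec.id}#al"
        out.extend([replace(rec, id=rid)], PROVENANCE_TOPO)
        used_ids.add(rid)
        seen_canonical.add(rec.smiles_canonical)
    return out


def assert_no_leakage(train: DatasetTable, test_like: DatasetTable) -> None:
    overlap = train.canonical_set() & test_like.canonical_set()
    if overlap:
        raise ConfigurationError(
            f"leakage: {len(overlap)} canonical SMILES shared with val/test"
        )


def guarded_augment(
    train: DatasetTable,
    val: DatasetTable,
    pool: Optional[DatasetTable],
    test_like: DatasetTable,
    config: AugmentConfig = AugmentConfig(),
    fit_probe: Optional[Callable[[DatasetTable, DatasetTable], float]] = None,
) -> AugmentedSet:
    """SE + Topo-AL augmentation under a validation-MAE guard.

    Iterates the enumeration multiple m = 1..k (Topo-AL applied once, before
    the first enumeration step). After each step the probe is refit and
    scored on ``val``; the loop stops early when validation MAE exceeds the
    best seen by more than ``guard_tolerance`` (relative), and the
    best-scoring set is returned. With the guard disabled the loop runs to
    m = k unconditionally and returns the final set.
    """
    base = train.copy()
    if config.topo_enabled and pool is not None and len(pool):
        base = topo_al_expand(
            base,
            pool,
            test_like,
            tau=config.sim_threshold,
            fp_radius=config.fp_radius,
            fp_nbits=config.fp_nbits,
            metric=config.similarity_metric,
        )
    assert_no_leakage(base, test_like)

    def finish(table: DatasetTable, log: list[dict]) -> AugmentedSet:
        c = table.counts()
        return AugmentedSet(
            table=table,
            counts={
                "n_original": c.get("original", 0),
                "n_se": c.get(PROVENANCE_SE, 0),
                "n_topo_al": c.get(PROVENANCE_TOPO, 0),
            },
            log=log,
        )

    if config.k == 0:
        return finish(base, [])

    log: list[dict] = []
    guard = config.guard_enabled and fit_probe is not None
    best_mae = float("inf")
    best_table = base
    last_table = base
    for m in range(1, config.k + 1):
        candidate = _se_expand(base, m, config.seed)
        assert_no_leakage(candidate, test_like)
        last_table = candidate
        if guard:
            mae = float(fit_probe(candidate, val))
            log.append({"m": m, "n_rows": len(candidate), "val_mae": mae})
            if mae < best_mae:
                best_mae = mae
                best_table = candidate
            elif mae > best_mae * (1.0 + config.guard_tolerance):
                break
        else:
            log.append({"m": m, "n_rows": len(candidate), "val_mae": None})
    return finish(best_table if guard else last_table, log)
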