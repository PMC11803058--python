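"""Circular fingerprints, Tanimoto similarity, and class-similarity summaries.

Fingerprints are extended-connectivity (Morgan) bit vectors, represented as
sets of on-bit indices. Similarity defaults to Tanimoto |A∩B|/|A∪B| in
[0, 1]; binary cosine is available behind ``metric="cosine"``. The
class-similarity summary reproduces the usual "how alike are my compound
classes" heatmap inputs: a symmetric mean cross-class similarity matrix, an
average-linkage clustering order, and quartile statistics of the
off-diagonal entries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from rdkit.Chem import rdFingerprintGenerator
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .chemio import DatasetTable, MoleculeRecord, mol_from_smiles
from .errors import ConfigurationError


@dataclass(frozen=True)
class BitFingerprint:
    """Fixed-width binary fingerprint as a set of on-bit indices."""

    on_bits: frozenset[int]
    nbits: int = 2048
    radius: int = 2

    def __post_init__(self):
        if self.nbits <= 0 or (self.nbits & (self.nbits - 1)) != 0:
            raise ConfigurationError(f"nbits must be a power of two, got {self.nbits}")
        if self.on_bits and not all(0 <= b < self.nbits for b in self.on_bits):
            raise ConfigurationError("fingerprint bit index out of range")

    def __len__(self) -> int:
        return len(self.on_bits)


@lru_cache(maxsize=8)
def _generator(radius: int, nbits: int):
    return rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)


def ecfp(
    mol: MoleculeRecord | str, radius: int = 2, nbits: int = 2048
) -> BitFingerprint:
    """ECFP-style circular fingerprint of a molecule.

    Deterministic for a given canonical SMILES, radius and width; identical
    for any SMILES rendering of the same molecular graph.
    """
    smiles = mol.smiles_canonical if isinstance(mol, MoleculeRecord) else mol
    rdmol = mol_from_smiles(smiles)
    fp = _generator(radius, nbits).GetFingerprint(rdmol)
    return BitFingerprint(frozenset(fp.GetOnBits()), nbits=nbits, radius=radius)


def tanimoto(a: BitFingerprint, b: BitFingerprint) -> float:
    """Tanimoto similarity |A∩B| / |A∪B|; two empty sets give 0.0."""
    if a.nbits != b.nbits:
        raise ConfigurationError(
            f"fingerprint width mismatch: {a.nbits} vs {b.nbits}"
        )
    inter = len(a.on_bits & b.on_bits)
    union = len(a.on_bits) + len(b.on_bits) - inter
    return inter / union if union else 0.0


def cosine_binary(a: BitFingerprint, b: BitFingerprint) -> float:
    """Cosine similarity on binary vectors: |A∩B| / sqrt(|A|·|B|)."""
    if a.nbits != b.nbits:
        raise ConfigurationError(
            f"fingerprint width mismatch: {a.nbits} vs {b.nbits}"
        )
    if not a.on_bits or not b.on_bits:
        return 0.0
    return len(a.on_bits & b.on_bits) / math.sqrt(len(a.on_bits) * len(b.on_bits))


_METRICS = {"tanimoto": tanimoto, "cosine": cosine_binary}


def similarity(a: BitFingerprint, b: BitFingerprint, metric: str = "tanimoto") -> float:
    try:
        return _METRICS[metric](a, b)
    except KeyError:
        raise ConfigurationError(f"unknown similarity metric {metric!r}") from None


def bulk_max_similarity(
    queries: list[BitFingerprint],
    reference: list[BitFingerprint],
    metric: str = "tanimoto",
) -> np.ndarray:
    """Max similarity of each query against a reference fingerprint list."""
    fn = _METRICS[metric]
    out = np.zeros(len(queries))
    for i, q in enumerate(queries):
        out[i] = max((fn(q, r) for r in reference), default=0.0)
    return out


@dataclass
class ClassSimilaritySummary:
    """Mean cross-class similarity matrix plus clustering order and quartiles."""

    labels: list[str]
    matrix: np.ndarray  # symmetric, diagonal 1
    order: list[int]  # permutation from average-linkage clustering
    quartiles: tuple[float, float, float]
    frac_below_half: float


def class_similarity_summary(
    class_tables: dict[str, DatasetTable],
    radius: int = 2,
    nbits: int = 2048,
    metric: str = "tanimoto",
    max_per_class: int = 200,
    seed: int = 0,
) -> ClassSimilaritySummary:
    """Mean pairwise similarity between every pair of compound classes.

    Entry (i, j) is the mean similarity over the full cross-product of class
    fingerprints (a seeded subsample of at most ``max_per_class`` per class
    keeps this desk-scale); the diagonal is 1 by convention. Classes are
    ordered by average-linkage hierarchical clustering on 1 − similarity, and
    the quartiles / below-0.5 fraction summarize the off-diagonal entries.
    """
    labels = sorted(class_tables)
    if len(labels) < 2:
        raise ConfigurationError("need at least 2 classes for a similarity summary")
    rng = np.random.default_rng(seed)
    fps: dict[str, list[BitFingerprint]] = {}
    for lab in labels:
        recs = class_tables[lab].records
        if not recs:
            raise ConfigurationError(f"class {lab!r} is empty")
        # unique molecules only: augmentation duplicates would bias the mean
        uniq = sorted({r.smiles_canonical for r in recs})
        if len(uniq) > max_per_class:
            idx = rng.choice(len(uniq), size=max_per_class, replace=False)
            uniq = [uniq[i] for i in sorted(idx)]
        fps[lab] = [ecfp(s, radius, nbits) for s in uniq]

    k = len(labels)
    mat = np.eye(k)
    fn = _METRICS[metric]
    for i in range(k):
        for j in range(i + 1, k):
            vals = [fn(a, b) for a in fps[labels[i]] for b in fps[labels[j]]]
            mat[i, j] = mat[j, i] = float(np.mean(vals))

    if k == 2:
        order = [0, 1]
    else:
        dist = squareform(1.0 - mat, checks=False)
        order = [int(i) for i in leaves_list(linkage(dist, method="average"))]

    off = mat[np.triu_indices(k, k=1)]
    q1, q2, q3 = (float(np.percentile(off, p)) for p in (25, 50, 75))
    return ClassSimilaritySummary(
        labels=labels,
        matrix=mat,
        order=order,
        quartiles=(q1, q2, q3),
        frac_below_half=float(np.mean(off < 0.5)),
    )
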