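"""Per-class expert regressors, routing, prediction, metrics, ablation.

For every compound class a suite of seven candidate regressors (RBF-kernel
SVR, random forest, gradient-boosted trees, extremely randomized trees,
k-nearest neighbors, L2-regularized linear, and a single-hidden-layer
feed-forward net) undergoes a seeded random hyperparameter search; the
configuration with the lowest validation MAE becomes that class's expert
submodel (ties break on registry order). Queries are routed taxonomy-first:
the weighted-SMARTS class assignment picks the submodel when one exists,
otherwise the query falls back to the submodel whose training fingerprints
are most similar (mean of the top-m Tanimoto similarities).
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesRegressor, RandomForestRegressor
from sklearn.linear_model import Ridge
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR
from xgboost import XGBRegressor

from .augment import AugmentConfig, guarded_augment
from .chemio import (
    DatasetTable,
    MoleculeRecord,
    SplitSpec,
    split_dataset,
)
from .errors import (
    ClassRTError,
    ConfigurationError,
    DatasetTooSmallError,
    InvalidMoleculeError,
    MetricError,
)
from .features import (
    Scaler,
    SelectionConfig,
    compute_descriptors,
    feature_block,
    select_features,
)
from .simfp import BitFingerprint, ecfp, similarity
from .taxonomy import RESIDUAL_CLASS_ID, RuleSet, assign_class, default_ruleset, partition_by_class

ALGORITHM_ORDER = (
    "svr_rbf",
    "random_forest",
    "gradient_boosting",
    "extra_trees",
    "knn",
    "ridge",
    "mlp",
)


def _stage_seed(seed: int, tag: str) -> int:
    return (int(seed) + zlib.crc32(tag.encode())) % (2**31 - 1)


# --- algorithm registry -----------------------------------------------------
# Each entry: default config (search draw 0) and a sampler for further draws.


def _registry_spec() -> dict[str, dict]:
    return {
        "svr_rbf": {
            "default": {"C": 10.0, "gamma": "scale", "epsilon": 0.1},
            "sample": lambda rng: {
                "C": float(10 ** rng.uniform(-1, 2)),
                "gamma": float(10 ** rng.uniform(-4, 0)),
                "epsilon": float(10 ** rng.uniform(-3, 1)),
            },
        },
        "random_forest": {
            "default": {"n_estimators": 200, "min_samples_leaf": 1, "max_features": 0.6},
            "sample": lambda rng: {
                "n_estimators": int(rng.choice([100, 200, 300])),
                "min_samples_leaf": int(rng.choice([1, 2, 4])),
                "max_features": float(rng.choice([0.3, 0.6, 1.0])),
            },
        },
        "gradient_boosting": {
            "default": {"n_estimators": 200, "learning_rate": 0.1, "max_depth": 5},
            "sample": lambda rng: {
                "n_estimators": int(rng.choice([100, 200, 400])),
                "learning_rate": float(10 ** rng.uniform(-1.5, -0.5)),
                "max_depth": int(rng.integers(3, 9)),
                "subsample": float(rng.choice([0.7, 1.0])),
            },
        },
        "extra_trees": {
            "default": {"n_estimators": 200, "min_samples_leaf": 1, "max_features": 0.6},
            "sample": lambda rng: {
                "n_estimators": int(rng.choice([100, 200, 300])),
                "min_samples_leaf": int(rng.choice([1, 2, 4])),
                "max_features": float(rng.choice([0.3, 0.6, 1.0])),
            },
        },
        "knn": {
            "default": {"n_neighbors": 5, "weights": "distance", "p": 2},
            "sample": lambda rng: {
                "n_neighbors": int(rng.integers(1, 16)),
                "weights": str(rng.choice(["uniform", "distance"])),
                "p": int(rng.choice([1, 2])),
            },
        },
        "ridge": {
            # near-zero penalty by default: exact on noiseless linear targets
            "default": {"alpha": 1e-10},
            "sample": lambda rng: {"alpha": float(10 ** rng.uniform(-8, 2))},
        },
        "mlp": {
            "default": {"hidden_layer_sizes": (100,), "alpha": 1e-4, "max_iter": 500},
            "sample": lambda rng: {
                "hidden_layer_sizes": (int(rng.choice([50, 100, 200])),),
                "alpha": float(10 ** rng.uniform(-6, -2)),
                "learning_rate_init": float(10 ** rng.uniform(-3.5, -2)),
                "max_iter": 500,
            },
        },
    }


def build_estimator(algorithm: str, params: dict, seed: int = 0):
    """Instantiate a registered regressor with the given hyperparameters."""
    p = dict(params)
    if algorithm == "svr_rbf":
        return SVR(kernel="rbf", **p)
    if algorithm == "random_forest":
        return RandomForestRegressor(random_state=seed, n_jobs=1, **p)
    if algorithm == "gradient_boosting":
        return XGBRegressor(
            random_state=seed, n_jobs=1, tree_method="hist", verbosity=0, **p
        )
    if algorithm == "extra_trees":
        return ExtraTreesRegressor(random_state=seed, n_jobs=1, **p)
    if algorithm == "knn":
        return KNeighborsRegressor(**p)
    if algorithm == "ridge":
        # the cholesky path loses precision at near-zero penalties
        solver = "svd" if p.get("alpha", 1.0) < 1e-6 else "auto"
        return Ridge(solver=solver, **p)
    if algorithm == "mlp":
        if "hidden_layer_sizes" in p:
            p["hidden_layer_sizes"] = tuple(p["hidden_layer_sizes"])
        return MLPRegressor(random_state=seed, **p)
    raise ConfigurationError(f"unknown algorithm {algorithm!r}")


# --- domain types -----------------------------------------------------------


@dataclass
class SubmodelRecord:
    """One class's trained expert regressor and everything needed to reuse it."""

    class_id: str
    algorithm: str
    hyperparams: dict
    selected_features: list[str]
    scaler: Scaler
    val_mae: float
    val_r2: float
    train_fingerprints: list[BitFingerprint]
    estimator: object
    n_train: int
    search_log: list[dict] = field(default_factory=list)
    augment_log: list[dict] = field(default_factory=list)
    augment_counts: dict = field(default_factory=dict)


@dataclass(frozen=True)
class RoutingConfig:
    mode: str = "taxonomy_first"
    sim_fallback_top_m: int = 5
    min_route_sim: float = 0.0


@dataclass
class EnsembleModel:
    submodels: dict[str, SubmodelRecord]
    ruleset: RuleSet
    routing: RoutingConfig = RoutingConfig()
    fp_radius: int = 2
    fp_nbits: int = 2048
    feature_set: str = "standard_2d"

    def __post_init__(self):
        if not self.submodels:
            raise ConfigurationError("an ensemble needs at least one submodel")


@dataclass
class MetricReport:
    mae: float
    medae: float
    mape: float  # fraction, not percent
    r2: float

    def as_dict(self) -> dict:
        return {"mae": self.mae, "medae": self.medae, "mape": self.mape, "r2": self.r2}


@dataclass
class TrainReport:
    """Bookkeeping from a full ensemble fit (splits, logs, winner tally)."""

    train: DatasetTable
    val: DatasetTable
    test: DatasetTable
    pool: DatasetTable
    class_sizes: dict[str, int]
    skipped_classes: list[str]
    winner_tally: dict[str, int]


# --- metrics ----------------------------------------------------------------


def metrics(y_true: Sequence[float], y_pred: Sequence[float]) -> MetricReport:
    """MAE, MedAE (seconds), MAPE (fraction), and R² of predictions."""
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if yt.shape != yp.shape:
        raise MetricError(f"length mismatch: {yt.shape} vs {yp.shape}")
    if yt.size < 2:
        raise MetricError("need at least 2 points")
    if np.any(yt <= 0):
        raise MetricError("MAPE requires strictly positive true values")
    err = np.abs(yt - yp)
    ss_tot = float(np.sum((yt - yt.mean()) ** 2))
    if ss_tot == 0:
        raise MetricError("R² undefined: zero-variance true values")
    return MetricReport(
        mae=float(err.mean()),
        medae=float(np.median(err)),
        mape=float(np.mean(err / yt)),
        r2=1.0 - float(np.sum((yt - yp) ** 2)) / ss_tot,
    )


# --- submodel training ------------------------------------------------------


def _relaxed_selection(frame: pd.DataFrame, y: np.ndarray, cap: int = 10) -> list[str]:
    """Tiny-table fallback: rank retained columns by |corr to rt|."""
    cols = [c for c in frame.columns if frame[c].std() > 0]
    def key(c):
        sd = frame[c].std()
        r = abs(float(np.corrcoef(frame[c], y)[0, 1])) if sd > 0 and y.std() > 0 else 0.0
        return (-r, c)
    return sorted(cols, key=key)[:cap]


def train_submodel(
    class_id: str,
    class_train: DatasetTable,
    class_val: DatasetTable,
    registry: Optional[Sequence[str]] = None,
    budget: int = 20,
    seed: int = 0,
    selection: SelectionConfig = SelectionConfig(),
    fp_radius: int = 2,
    fp_nbits: int = 2048,
    feature_set: str = "standard_2d",
) -> SubmodelRecord:
    """Fit all candidate regressors for one class and keep the best (OPSRT).

    Every registered algorithm gets a seeded random search of at most
    ``budget`` configurations (draw 0 is the algorithm's default config),
    each scored by MAE on the class validation split. The global argmin
    becomes the expert; ties break on registry order, then draw index. The
    full search log is retained so the argmin property is auditable.
    """
    registry = tuple(registry) if registry else ALGORITHM_ORDER
    spec = _registry_spec()
    unknown = [a for a in registry if a not in spec]
    if unknown:
        raise ConfigurationError(f"unknown algorithms {unknown}")
    if len(class_train) < 3 or len(class_val) < 1:
        raise DatasetTooSmallError(
            f"class {class_id!r}: need >= 3 train and >= 1 val records"
        )
    if budget < 1:
        raise ConfigurationError("budget must be >= 1")

    fm = compute_descriptors(class_train, feature_set)
    if fm.failed_rows:
        keep = [r.id for r in class_train.records if r.id not in set(fm.failed_rows)]
        class_train = class_train.subset(keep)
    y_train = class_train.rts()
    try:
        report = select_features(
            fm, y_train, selection, effective_rows=len(class_train.canonical_set())
        )
        selected = report.selected_names
    except DatasetTooSmallError:
        selected = _relaxed_selection(fm.retained, y_train)
    if not selected:
        raise ConfigurationError(f"class {class_id!r}: no usable features")

    X_train = fm.frame[selected].to_numpy(dtype=float)
    scaler = Scaler.fit(X_train)
    Xs = scaler.transform(X_train)
    X_val = scaler.transform(feature_block(class_val, selected, feature_set))
    y_val = class_val.rts()

    best = None  # (mae, reg_idx, draw, algorithm, params, estimator, r2)
    search_log: list[dict] = []
    for reg_idx, algo in enumerate(registry):
        rng = np.random.default_rng(_stage_seed(seed, f"search:{class_id}:{algo}"))
        for draw in range(budget):
            params = spec[algo]["default"] if draw == 0 else spec[algo]["sample"](rng)
            est = build_estimator(algo, params, seed=_stage_seed(seed, f"est:{algo}"))
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # e.g. MLP non-convergence
                    est.fit(Xs, y_train)
                    pred = np.asarray(est.predict(X_val), dtype=float)
            except Exception as exc:  # an unstable config is logged, not fatal
                search_log.append(
                    {"algorithm": algo, "params": params, "val_mae": None,
                     "error": str(exc)[:200]}
                )
                continue
            mae = float(np.mean(np.abs(pred - y_val)))
            search_log.append({"algorithm": algo, "params": params, "val_mae": mae})
            if best is None or mae < best[0]:
                ss = float(np.sum((y_val - y_val.mean()) ** 2))
                r2 = 1.0 - float(np.sum((y_val - pred) ** 2)) / ss if ss > 0 else float("nan")
                best = (mae, reg_idx, draw, algo, params, est, r2)
    if best is None:
        raise ClassRTError(f"class {class_id!r}: every candidate fit failed")

    fps = [ecfp(s, fp_radius, fp_nbits) for s in sorted(class_train.canonical_set())]
    return SubmodelRecord(
        class_id=class_id,
        algorithm=best[3],
        hyperparams=best[4],
        selected_features=list(selected),
        scaler=scaler,
        val_mae=best[0],
        val_r2=best[6],
        train_fingerprints=fps,
        estimator=best[5],
        n_train=len(class_train),
        search_log=search_log,
    )


# --- full training pipeline -------------------------------------------------

PROBE_FEATURES = [
    "MolLogP", "MolWt", "TPSA", "HeavyAtomCount", "NumRotatableBonds",
    "NumHAcceptors", "NumHDonors", "RingCount", "FractionCSP3", "BertzCT",
]


def ridge_probe(train: DatasetTable, val: DatasetTable) -> float:
    """Cheap deterministic probe for the augmentation guard: ridge fit on a
    fixed small descriptor panel, returning validation MAE in seconds."""
    X = feature_block(train, PROBE_FEATURES)
    scaler = Scaler.fit(X)
    est = Ridge(alpha=1.0)
    est.fit(scaler.transform(X), train.rts())
    pred = est.predict(scaler.transform(feature_block(val, PROBE_FEATURES)))
    return float(np.mean(np.abs(pred - val.rts())))


def _assign_to_tables(
    table: DatasetTable, rules: RuleSet, class_ids: set[str]
) -> dict[str, DatasetTable]:
    """Group records by assigned subclass; unknown subclasses -> residual."""
    groups: dict[str, list[MoleculeRecord]] = {}
    for rec in table.records:
        sub = assign_class(rec, rules).subclass
        if sub not in class_ids:
            sub = RESIDUAL_CLASS_ID
        groups.setdefault(sub, []).append(rec)
    return {
        k: DatasetTable(v, {r.id: table.provenance[r.id] for r in v})
        for k, v in groups.items()
    }


def train_ensemble(
    dataset: DatasetTable,
    rules: Optional[RuleSet] = None,
    aug_config: AugmentConfig = AugmentConfig(),
    split_spec: SplitSpec = SplitSpec(),
    min_size: int = 15,
    registry: Optional[Sequence[str]] = None,
    budget: int = 20,
    seed: int = 0,
    train_per_class: Optional[int] = None,
    routing: RoutingConfig = RoutingConfig(),
    fit_probe: Callable[[DatasetTable, DatasetTable], float] = ridge_probe,
    selection: SelectionConfig = SelectionConfig(),
) -> tuple[EnsembleModel, TrainReport]:
    """Full pipeline: split 8:1:1, partition by class, augment each class's
    training records, fit per-class experts, assemble the routed ensemble.

    ``train_per_class`` caps the per-class training subset (seeded); capped-out
    records become the Topo-AL pool — the data-sparse regime the augmentation
    strategies exist for. Without a cap the pool is empty and only SMILES
    enumeration applies.
    """
    if len(dataset) < 30:
        raise DatasetTooSmallError("train_ensemble needs >= 30 records")
    rules = rules or default_ruleset()
    train, val, test = split_dataset(dataset, split_spec)

    pool = DatasetTable([])
    if train_per_class is not None:
        rng = np.random.default_rng(_stage_seed(split_spec.seed, "train-cap"))
        by_class: dict[str, list[MoleculeRecord]] = {}
        for rec in train.records:
            by_class.setdefault(assign_class(rec, rules).subclass, []).append(rec)
        kept, spilled = [], []
        for sub in sorted(by_class):
            recs = by_class[sub]
            if len(recs) > train_per_class:
                idx = rng.choice(len(recs), size=train_per_class, replace=False)
                idx = set(int(i) for i in idx)
                kept.extend(r for i, r in enumerate(recs) if i in idx)
                spilled.extend(r for i, r in enumerate(recs) if i not in idx)
            else:
                kept.extend(recs)
        keep_ids = {r.id for r in kept}
        pool = train.subset([r.id for r in spilled])
        train = train.subset([r.id for r in train.records if r.id in keep_ids])

    class_tables, residual = partition_by_class(train, rules, min_size)
    tables = dict(class_tables)
    if len(residual):
        tables[RESIDUAL_CLASS_ID] = residual

    test_like = DatasetTable(
        list(val.records) + list(test.records),
        {r.id: "original" for r in list(val.records) + list(test.records)},
    )
    val_by_class = _assign_to_tables(val, rules, set(class_tables))

    submodels: dict[str, SubmodelRecord] = {}
    skipped: list[str] = []
    tally: dict[str, int] = {}
    for class_id in sorted(tables):
        ctrain = tables[class_id]
        if len(ctrain) < 3:
            skipped.append(class_id)
            continue
        cval = val_by_class.get(class_id, DatasetTable([]))
        if not len(cval):
            # no validation material for this class: carve a seeded holdout
            rng = np.random.default_rng(_stage_seed(seed, f"holdout:{class_id}"))
            n_hold = max(1, len(ctrain) // 10)
            hold_idx = set(
                int(i) for i in rng.choice(len(ctrain), size=n_hold, replace=False)
            )
            cval = ctrain.subset(
                [r.id for i, r in enumerate(ctrain.records) if i in hold_idx]
            )
            ctrain = ctrain.subset(
                [r.id for i, r in enumerate(ctrain.records) if i not in hold_idx]
            )
            if len(ctrain) < 3:
                skipped.append(class_id)
                continue
        cfg = AugmentConfig(
            k=aug_config.k,
            sim_threshold=aug_config.sim_threshold,
            topo_enabled=aug_config.topo_enabled,
            guard_enabled=aug_config.guard_enabled,
            guard_tolerance=aug_config.guard_tolerance,
            seed=_stage_seed(aug_config.seed, f"augment:{class_id}"),
            fp_radius=aug_config.fp_radius,
            fp_nbits=aug_config.fp_nbits,
            similarity_metric=aug_config.similarity_metric,
        )
        aug = guarded_augment(ctrain, cval, pool, test_like, cfg, fit_probe)
        sub = train_submodel(
            class_id,
            aug.table,
            cval,
            registry=registry,
            budget=budget,
            seed=_stage_seed(seed, f"class:{class_id}"),
            selection=selection,
            fp_radius=aug_config.fp_radius,
            fp_nbits=aug_config.fp_nbits,
        )
        sub.augment_log = aug.log
        sub.augment_counts = aug.counts
        submodels[class_id] = sub
        tally[sub.algorithm] = tally.get(sub.algorithm, 0) + 1

    if not submodels:
        raise ClassRTError("no class produced a trainable submodel")
    model = EnsembleModel(
        submodels=submodels,
        ruleset=rules,
        routing=routing,
        fp_radius=aug_config.fp_radius,
        fp_nbits=aug_config.fp_nbits,
    )
    report = TrainReport(
        train=train,
        val=val,
        test=test,
        pool=pool,
        class_sizes={k: len(v) for k, v in tables.items()},
        skipped_classes=skipped,
        winner_tally=tally,
    )
    return model, report


# --- routing and prediction -------------------------------------------------


def route(
    query: MoleculeRecord | str, model: EnsembleModel
) -> tuple[str, str]:
    """Assign a query to a submodel: taxonomy first, similarity fallback.

    Returns ``(class_id, mode)`` with mode ``"taxonomy"`` when the assigned
    subclass has a submodel and the query clears the similarity floor, else
    ``"similarity_fallback"`` to the submodel with the highest mean top-m
    similarity (ties: larger training class, then lexicographic class id).
    """
    smiles = query.smiles_canonical if isinstance(query, MoleculeRecord) else query
    fp = ecfp(smiles, model.fp_radius, model.fp_nbits)
    assigned = assign_class(smiles, model.ruleset).subclass
    sub = model.submodels.get(assigned)
    if sub is not None:
        max_sim = max(
            (similarity(fp, t) for t in sub.train_fingerprints), default=0.0
        )
        if max_sim >= model.routing.min_route_sim:
            return assigned, "taxonomy"

    m = model.routing.sim_fallback_top_m
    best_key, best_id = None, None
    for class_id in sorted(model.submodels):
        cand = model.submodels[class_id]
        sims = sorted(
            (similarity(fp, t) for t in cand.train_fingerprints), reverse=True
        )[:m]
        score = float(np.mean(sims)) if sims else 0.0
        key = (-score, -cand.n_train, class_id)
        if best_key is None or key < best_key:
            best_key, best_id = key, class_id
    return best_id, "similarity_fallback"


def predict(
    queries: DatasetTable | Sequence[tuple[str, str]], model: EnsembleModel
) -> pd.DataFrame:
    """Predict retention times for a batch of queries.

    Accepts a molecule table or raw ``(id, smiles)`` pairs; an unparseable
    SMILES yields an error row (NaN prediction) and the run continues. Output
    rows are in input order, one per query, with the routed class, the
    submodel's algorithm, and the route mode.
    """
    items: list[tuple[str, str, Optional[MoleculeRecord]]] = []
    if isinstance(queries, DatasetTable):
        for r in queries.records:
            items.append((r.id, r.smiles_raw, r))
    else:
        for rid, smi in queries:
            try:
                items.append((rid, smi, MoleculeRecord.from_smiles(rid, smi)))
            except InvalidMoleculeError:
                items.append((rid, smi, None))

    rows = []
    routed: dict[str, list[int]] = {}
    for i, (rid, smi, rec) in enumerate(items):
        if rec is None:
            rows.append(
                {"id": rid, "smiles": smi, "predicted_rt": np.nan,
                 "class_super": "", "class_sub": "", "submodel_algorithm": "",
                 "route_mode": "error", "error": "unparseable SMILES"}
            )
            continue
        class_id, mode = route(rec, model)
        assignment = assign_class(rec, model.ruleset)
        rows.append(
            {"id": rid, "smiles": rec.smiles_canonical, "predicted_rt": np.nan,
             "class_super": assignment.superclass, "class_sub": class_id,
             "submodel_algorithm": model.submodels[class_id].algorithm,
             "route_mode": mode, "error": ""}
        )
        routed.setdefault(class_id, []).append(i)

    for class_id, idxs in routed.items():
        sub = model.submodels[class_id]
        batch = DatasetTable(
            [
                MoleculeRecord(
                    id=f"q{i}",
                    smiles_raw=items[i][1],
                    smiles_canonical=items[i][2].smiles_canonical,
                )
                for i in idxs
            ]
        )
        X = sub.scaler.transform(
            feature_block(batch, sub.selected_features, model.feature_set)
        )
        pred = np.asarray(sub.estimator.predict(X), dtype=float)
        for i, p in zip(idxs, pred):
            rows[i]["predicted_rt"] = float(p)
    return pd.DataFrame(rows)


def evaluate(model: EnsembleModel, labeled: DatasetTable) -> MetricReport:
    """Route + predict a labeled table and score against its measured RTs."""
    preds = predict(labeled, model)
    ok = preds["error"] == ""
    y_true = np.asarray([r.rt for r, k in zip(labeled.records, ok) if k], dtype=float)
    return metrics(y_true, preds.loc[ok, "predicted_rt"].to_numpy())


# --- ablation harness -------------------------------------------------------

ABLATION_ARMS = ("none", "se", "topo_al", "both")


def _arm_config(arm: str, base: AugmentConfig) -> AugmentConfig:
    if arm == "none":
        return AugmentConfig(k=0, topo_enabled=False, guard_enabled=False,
                             seed=base.seed, sim_threshold=base.sim_threshold)
    if arm == "se":
        return AugmentConfig(k=base.k, topo_enabled=False, guard_enabled=False,
                             seed=base.seed, sim_threshold=base.sim_threshold)
    if arm == "topo_al":
        return AugmentConfig(k=0, topo_enabled=True, guard_enabled=False,
                             seed=base.seed, sim_threshold=base.sim_threshold)
    if arm == "both":
        return AugmentConfig(k=base.k, topo_enabled=True, guard_enabled=False,
                             seed=base.seed, sim_threshold=base.sim_threshold)
    raise ConfigurationError(f"unknown ablation arm {arm!r}")


def ablate(
    dataset: DatasetTable,
    arms: Sequence[str] = ABLATION_ARMS,
    seeds: Sequence[int] = (0, 1),
    rules: Optional[RuleSet] = None,
    base_config: AugmentConfig = AugmentConfig(),
    registry: Optional[Sequence[str]] = None,
    budget: int = 20,
    min_size: int = 15,
    train_per_class: Optional[int] = None,
) -> pd.DataFrame:
    """Paired four-arm augmentation ablation.

    Within each seed all arms share the identical 8:1:1 split (the split is a
    pure function of the seed) and the test metrics are therefore paired;
    only the augmentation configuration differs by arm. Returns one row per
    (arm, seed) with test-set MAE/MedAE/MAPE/R².
    """
    if len(seeds) < 2:
        raise ConfigurationError("ablation needs >= 2 seeds")
    rules = rules or default_ruleset()
    rows = []
    for s in seeds:
        for arm in arms:
            cfg = _arm_config(arm, base_config)
            model, report = train_ensemble(
                dataset,
                rules=rules,
                aug_config=cfg,
                split_spec=SplitSpec(seed=int(s)),
                min_size=min_size,
                registry=registry,
                budget=budget,
                seed=int(s),
                train_per_class=train_per_class,
            )
            rep = evaluate(model, report.test)
            n_aug = sum(
                sub.augment_counts.get("n_se", 0) + sub.augment_counts.get("n_topo_al", 0)
                for sub in model.submodels.values()
            )
            rows.append(
                {"arm": arm, "seed": int(s), "n_added": n_aug, **rep.as_dict()}
            )
    return pd.DataFrame(rows)


def ablation_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Per-arm mean ± sd of the paired test metrics."""
    return results.groupby("arm")[["mae", "medae", "mape", "r2"]].agg(["mean", "std"])
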