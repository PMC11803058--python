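"""Versioned on-disk persistence of trained ensembles.

A model directory holds a JSON manifest (the compatibility contract: schema
version, taxonomy rule hash, routing config, per-class feature lists, scaler
statistics and training fingerprints), the taxonomy rule file itself, and one
serialized estimator per class. Loading a directory with a different schema
version raises, never silently reinterprets.
"""

from __future__ import annotations

import json
from pathlib import Path

import joblib
import numpy as np

from .errors import ModelPersistenceError
from .features import Scaler
from .simfp import BitFingerprint
from .taxonomy import RuleSet, compile_rules

SCHEMA_VERSION = 1
MANIFEST_NAME = "manifest.json"
RULES_NAME = "rules.tsv"


def _write_rules(rules: RuleSet, path: Path) -> None:
    with path.open("w") as fh:
        for r in rules.rules:
            fh.write(f"{r.rule_id}\t{r.smarts}\t{r.weight!r}\t{r.superclass}\t{r.subclass}\n")


def save_ensemble(model, dir: str | Path) -> dict:
    from .ensemble import EnsembleModel  # local import: avoids a cycle

    assert isinstance(model, EnsembleModel)
    dir = Path(dir)
    dir.mkdir(parents=True, exist_ok=True)
    _write_rules(model.ruleset, dir / RULES_NAME)

    classes = []
    for idx, class_id in enumerate(sorted(model.submodels)):
        sub = model.submodels[class_id]
        est_file = f"estimator_{idx:03d}.joblib"
        joblib.dump(sub.estimator, dir / est_file)
        classes.append(
            {
                "class_id": class_id,
                "algorithm": sub.algorithm,
                "hyperparams": sub.hyperparams,
                "selected_features": sub.selected_features,
                "scaler_mean": [float(v) for v in sub.scaler.mean],
                "scaler_scale": [float(v) for v in sub.scaler.scale],
                "val_mae": sub.val_mae,
                "val_r2": sub.val_r2,
                "n_train": sub.n_train,
                "estimator_file": est_file,
                "train_fingerprints": [sorted(f.on_bits) for f in sub.train_fingerprints],
                "augment_counts": sub.augment_counts,
            }
        )
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "ruleset_hash": model.ruleset.content_hash(),
        "rules_file": RULES_NAME,
        "routing": {
            "mode": model.routing.mode,
            "sim_fallback_top_m": model.routing.sim_fallback_top_m,
            "min_route_sim": model.routing.min_route_sim,
        },
        "fp_radius": model.fp_radius,
        "fp_nbits": model.fp_nbits,
        "feature_set": model.feature_set,
        "classes": classes,
    }
    (dir / MANIFEST_NAME).write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def load_ensemble(dir: str | Path):
    from .ensemble import EnsembleModel, RoutingConfig, SubmodelRecord

    dir = Path(dir)
    manifest_path = dir / MANIFEST_NAME
    if not manifest_path.exists():
        raise ModelPersistenceError(f"no {MANIFEST_NAME} in {dir}")
    manifest = json.loads(manifest_path.read_text())
    version = manifest.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ModelPersistenceError(
            f"model schema version {version!r} incompatible with {SCHEMA_VERSION}"
        )
    rules = compile_rules(dir / manifest["rules_file"])
    if rules.content_hash() != manifest["ruleset_hash"]:
        raise ModelPersistenceError("taxonomy rule file does not match manifest hash")

    fp_radius = manifest["fp_radius"]
    fp_nbits = manifest["fp_nbits"]
    submodels = {}
    for entry in manifest["classes"]:
        est = joblib.load(dir / entry["estimator_file"])
        submodels[entry["class_id"]] = SubmodelRecord(
            class_id=entry["class_id"],
            algorithm=entry["algorithm"],
            hyperparams=entry["hyperparams"],
            selected_features=list(entry["selected_features"]),
            scaler=Scaler(
                mean=np.asarray(entry["scaler_mean"], dtype=float),
                scale=np.asarray(entry["scaler_scale"], dtype=float),
            ),
            val_mae=entry["val_mae"],
            val_r2=entry["val_r2"],
            train_fingerprints=[
                BitFingerprint(frozenset(bits), nbits=fp_nbits, radius=fp_radius)
                for bits in entry["train_fingerprints"]
            ],
            estimator=est,
            n_train=entry["n_train"],
            augment_counts=entry.get("augment_counts", {}),
        )
    routing = RoutingConfig(**manifest["routing"])
    return EnsembleModel(
        submodels=submodels,
        ruleset=rules,
        routing=routing,
        fp_radius=fp_radius,
        fp_nbits=fp_nbits,
        feature_set=manifest["feature_set"],
    )
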