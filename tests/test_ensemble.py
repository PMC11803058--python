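"""Expert-model selection, routing, prediction, metrics, persistence."""

import numpy as np
import pytest

from classrt.augment import AugmentConfig
from classrt.chemio import (
    DatasetTable,
    MoleculeRecord,
    SplitSpec,
    load_model,
    save_model,
)
from classrt.ensemble import (
    ALGORITHM_ORDER,
    EnsembleModel,
    RoutingConfig,
    metrics,
    predict,
    route,
    train_ensemble,
    train_submodel,
)
from classrt.errors import MetricError, ModelPersistenceError
from classrt.synthkit import SynthConfig, generate_library


class TestMetrics:
    def test_hand_computed_triple(self):
        # errors are (10, 10, 30): MAE 50/3, MedAE 10, SS_res 1100, SS_tot 20000
        rep = metrics([100, 200, 300], [110, 190, 330])
        assert rep.mae == pytest.approx(50 / 3)
        assert rep.medae == pytest.approx(10.0)
        assert rep.mape == pytest.approx((0.1 + 0.05 + 0.1) / 3)
        assert rep.r2 == pytest.approx(1 - 1100 / 20000)  # 0.945

    def test_perfect_prediction(self):
        rep = metrics([100, 200, 300], [100, 200, 300])
        assert (rep.mae, rep.medae, rep.mape, rep.r2) == (0, 0, 0, 1)

    def test_constant_shift(self):
        rep = metrics([100, 200, 300], [107, 207, 307])
        assert rep.mae == pytest.approx(7.0)
        assert rep.medae == pytest.approx(7.0)

    def test_length_mismatch_raises(self):
        with pytest.raises(MetricError):
            metrics([1, 2], [1, 2, 3])

    def test_zero_variance_truth_raises(self):
        with pytest.raises(MetricError):
            metrics([100, 100, 100], [90, 100, 110])


def _linear_tables(n_train=40, n_val=10, noise=0.0, seed=0):
    """Alkanol series: rt exactly linear in heavy-atom count (zero noise)."""
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n_train + n_val):
        length = 1 + i % 30
        branch = "O" if i % 2 else ""
        smi = "C" * length + branch
        heavy = length + (1 if branch else 0)
        rt = 100.0 + 37.0 * heavy + (rng.normal(0, noise) if noise else 0.0)
        recs.append(MoleculeRecord.from_smiles(f"lin{i}", smi, rt))
    uniq, seen = [], set()
    for r in recs:
        if r.smiles_canonical not in seen:
            seen.add(r.smiles_canonical)
            uniq.append(r)
    train = DatasetTable(uniq[:-5])
    val = DatasetTable(uniq[-5:])
    return train, val


class TestTrainSubmodel:
    def test_single_algorithm_registry_selected(self):
        train, val = _linear_tables()
        sub = train_submodel("c", train, val, registry=("knn",), budget=2, seed=0)
        assert sub.algorithm == "knn"

    def test_zero_noise_linear_target_is_solved_exactly(self):
        train, val = _linear_tables(noise=0.0)
        sub = train_submodel("c", train, val, registry=("ridge",), budget=1, seed=0)
        assert sub.val_mae < 1e-6

    def test_selected_mae_is_argmin_of_search_log(self):
        train, val = _linear_tables(noise=5.0)
        sub = train_submodel(
            "c", train, val, registry=("ridge", "knn", "random_forest"), budget=3, seed=1
        )
        evaluated = [e["val_mae"] for e in sub.search_log if e["val_mae"] is not None]
        assert sub.val_mae == pytest.approx(min(evaluated))
        assert sub.val_mae <= min(evaluated) + 1e-12


@pytest.fixture(scope="module")
def trained():
    """Small full ensemble on the 6-class synthetic library."""
    table, truth = generate_library(SynthConfig(per_class=40, noise_sd=10.0, seed=3))
    model, report = train_ensemble(
        table,
        aug_config=AugmentConfig(k=2, seed=3),
        split_spec=SplitSpec(seed=3),
        registry=("ridge", "random_forest"),
        budget=2,
        seed=3,
    )
    return table, truth, model, report


class TestTrainEnsemble:
    def test_one_submodel_per_class(self, trained):
        table, truth, model, report = trained
        assert set(model.submodels) == set(truth.class_offsets)

    def test_opsrt_optimality_per_class(self, trained):
        _, _, model, _ = trained
        for sub in model.submodels.values():
            evaluated = [e["val_mae"] for e in sub.search_log if e["val_mae"] is not None]
            assert sub.val_mae == pytest.approx(min(evaluated))

    def test_retrain_same_seed_identical_predictions(self, trained):
        table, truth, model, report = trained
        model2, _ = train_ensemble(
            table,
            aug_config=AugmentConfig(k=2, seed=3),
            split_spec=SplitSpec(seed=3),
            registry=("ridge", "random_forest"),
            budget=2,
            seed=3,
        )
        q = report.test.subset([report.test.records[i].id for i in range(5)])
        a = predict(q, model)["predicted_rt"].to_numpy()
        b = predict(q, model2)["predicted_rt"].to_numpy()
        assert np.array_equal(a, b)


class TestRouting:
    def test_taxonomy_route_when_submodel_exists(self, trained):
        _, truth, model, report = trained
        rec = report.test.records[0]
        class_id, mode = route(rec, model)
        assert mode == "taxonomy"
        assert class_id == truth.class_of[rec.id]

    def test_similarity_fallback_for_unruled_query(self, trained):
        _, _, model, _ = trained
        # plain alkane matches no taxonomy rule -> similarity fallback
        class_id, mode = route("CCCCCC", model)
        assert mode == "similarity_fallback"
        assert class_id in model.submodels

    def test_fallback_picks_most_similar_class_brute_force(self, trained):
        from classrt.simfp import ecfp, similarity

        _, _, model, _ = trained
        query = "CCCCCC"
        fp = ecfp(query, model.fp_radius, model.fp_nbits)
        m = model.routing.sim_fallback_top_m
        scores = {}
        for cid, sub in model.submodels.items():
            sims = sorted(
                (similarity(fp, t) for t in sub.train_fingerprints), reverse=True
            )[:m]
            scores[cid] = float(np.mean(sims))
        best = min(scores, key=lambda c: (-scores[c], -model.submodels[c].n_train, c))
        assert route(query, model)[0] == best

    def test_route_deterministic(self, trained):
        _, _, model, report = trained
        for rec in report.test.records[:10]:
            assert route(rec, model) == route(rec, model)


class TestPredict:
    def test_row_order_and_conservation(self, trained):
        _, _, model, report = trained
        queries = [(r.id, r.smiles_canonical) for r in report.test.records[:8]]
        queries.insert(3, ("bad", "xx_not_smiles"))
        out = predict(queries, model)
        assert len(out) == 9
        assert list(out["id"]) == [q[0] for q in queries]
        assert out.loc[3, "route_mode"] == "error"
        assert np.isnan(out.loc[3, "predicted_rt"])
        ok = out["route_mode"] != "error"
        assert np.isfinite(out.loc[ok, "predicted_rt"]).all()

    def test_prediction_invariant_to_smiles_rendering(self, trained):
        from classrt.augment import enumerate_smiles

        _, _, model, report = trained
        rec = report.test.records[0]
        variants = enumerate_smiles(rec.smiles_canonical, 3, seed=5)
        preds = predict(
            [("orig", rec.smiles_canonical)] + [(f"v{i}", v) for i, v in enumerate(variants)],
            model,
        )["predicted_rt"].to_numpy()
        assert np.all(preds == preds[0])

    def test_training_molecule_of_noiseless_class_interpolated(self):
        from classrt.features import SelectionConfig

        table, truth = generate_library(SynthConfig(per_class=30, noise_sd=0.0, seed=9))
        model, report = train_ensemble(
            table,
            aug_config=AugmentConfig(k=0, topo_enabled=False),
            split_spec=SplitSpec(seed=9),
            registry=("ridge",),
            budget=1,
            seed=9,
            # keep a wide, weakly-collapsed feature panel: the noiseless
            # signal is exactly linear in descriptors, so interpolation
            # should be limited only by numerical precision
            selection=SelectionConfig(corr_threshold=0.999, min_keep=30),
        )
        sample = report.train.subset([r.id for r in report.train.records[:20]])
        out = predict(sample, model)
        errs = np.abs(out["predicted_rt"].to_numpy() - sample.rts())
        assert np.max(errs) < 1e-3


class TestPersistence:
    def test_roundtrip_identical_predictions(self, trained, tmp_path):
        _, _, model, report = trained
        save_model(model, tmp_path / "m")
        loaded = load_model(tmp_path / "m")
        q = report.test.subset([r.id for r in report.test.records[:20]])
        a = predict(q, model)["predicted_rt"].to_numpy()
        b = predict(q, loaded)["predicted_rt"].to_numpy()
        assert np.array_equal(a, b)

    def test_missing_manifest_raises(self, tmp_path):
        (tmp_path / "empty").mkdir()
        with pytest.raises(ModelPersistenceError):
            load_model(tmp_path / "empty")

    def test_schema_version_bump_raises(self, trained, tmp_path):
        import json

        _, _, model, _ = trained
        save_model(model, tmp_path / "m2")
        mf = tmp_path / "m2" / "manifest.json"
        data = json.loads(mf.read_text())
        data["schema_version"] = 999
        mf.write_text(json.dumps(data))
        with pytest.raises(ModelPersistenceError, match="999"):
            load_model(tmp_path / "m2")
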