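"""End-to-end orchestration: phantoms -> preprocess -> split -> CNN -> hybrid heads.

All artifacts land in a single run directory; each JSON artifact embeds the
config hash and seed so provenance is reconstructible from outputs alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import cnn, dhl, phantom, transfer
from .config import ExperimentConfig
from .errors import StageError
from .preprocess import PreprocConfig, SplitSpec, holdout_split, preprocess_stack

log = logging.getLogger("oagrade")


def _provenance(config: ExperimentConfig) -> dict:
    return {"config_hash": config.config_hash(), "seed": config.seed}


def prepare_data(config: ExperimentConfig, run_dir: Path) -> dict:
    """Stages 1-3: generate phantoms, preprocess, split; returns arrays by split."""
    data_dir = run_dir / "data"
    dataset = phantom.generate_dataset(
        config.phantom.n_per_grade,
        seed=config.seed,
        out_dir=data_dir,
        noise_sd=config.phantom.noise_sd,
        image_size=config.phantom.image_size,
    )
    log.info("generated %d phantoms -> %s", len(dataset), data_dir)

    split = holdout_split(
        dataset,
        SplitSpec(
            test_fraction=config.split.test_fraction,
            valid_fraction_of_train=config.split.valid_fraction_of_train,
            stratified=config.split.stratified,
            seed=config.seed,
        ),
    )
    split.to_manifest(run_dir / "split_manifest.csv")

    raw = phantom.load_images(split, data_dir)
    pp = PreprocConfig(
        target_size=config.preprocess.target_size,
        clahe_clip_limit=config.preprocess.clahe_clip_limit,
        clahe_tile_grid=config.preprocess.clahe_tile_grid,
    )
    x = preprocess_stack(raw, pp)
    grades = split.grades
    tags = np.array([r.split for r in split.records])
    log.info("preprocessed stack %s", x.shape)

    out = {}
    for tag in ("train", "valid", "test"):
        mask = tags == tag
        out[f"x_{tag}"] = x[mask]
        out[f"y_{tag}"] = grades[mask]
    out["split"] = split
    np.savez_compressed(
        run_dir / "processed.npz",
        x=x.astype(np.float32),
        grades=grades,
        tags=tags,
    )
    return out


def run_experiment(config: ExperimentConfig, out_dir: str | Path) -> dict:
    """Run the full pipeline; returns a summary dict (also written as JSON)."""
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    prov = _provenance(config)
    (run_dir / "provenance.json").write_text(json.dumps(prov, indent=2))

    summary = {"provenance": prov, "stages": {}}

    def stage(name, fn):
        try:
            log.info("stage %s ...", name)
            return fn()
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            (run_dir / "failed_stage.txt").write_text(f"{name}: {exc}\n")
            raise StageError(name, str(exc)) from exc

    data = stage("prepare-data", lambda: prepare_data(config, run_dir))
    summary["stages"]["prepare-data"] = {
        tag: int(len(data[f"y_{tag}"])) for tag in ("train", "valid", "test")
    }

    model = stage("build-base", lambda: cnn.build_base_cnn(5, seed=config.seed))
    train_cfg = cnn.TrainConfig(
        learning_rate=config.train.learning_rate,
        beta1=config.train.beta1,
        beta2=config.train.beta2,
        batch_size=config.train.batch_size,
        epochs=config.train.epochs,
        seed=config.seed,
        chunk_size=config.train.chunk_size,
    )
    history = stage(
        "train-base",
        lambda: cnn.train(
            model, data["x_train"], data["y_train"], train_cfg,
            x_valid=data["x_valid"], y_valid=data["y_valid"],
        ),
    )
    cnn.write_history_csv(history, run_dir / "base_history.csv")
    model.save_weights(run_dir / "base_weights.npz")

    from . import metrics as M

    probs = cnn.predict_proba(model, data["x_test"])
    cnn_report = M.full_report(
        data["y_test"], probs.argmax(axis=1), 5, scores=probs
    )
    cnn_report.save_json(run_dir / "cnn_metrics.json", extra={"provenance": prov})
    summary["stages"]["cnn"] = {"test_accuracy": cnn_report.accuracy}

    dhl1 = stage(
        "fit-dhl",
        lambda: dhl.run_dhl(
            model,
            data["x_train"], data["y_train"],
            data["x_test"], data["y_test"],
            variance_target=config.dhl.variance_target,
            svm_params=dhl.SVMParams(C=config.dhl.C, gamma=config.dhl.gamma),
        ),
    )
    dhl1.report.save_json(
        run_dir / "dhl1_metrics.json",
        extra={"provenance": prov, "n_components": dhl1.n_components},
    )
    summary["stages"]["dhl1"] = {
        "test_accuracy": dhl1.report.accuracy,
        "n_components": dhl1.n_components,
    }

    for scheme in config.schemes:
        spec = transfer.FineTuneSpec(
            scheme=scheme,
            epochs=config.train.tl_epochs,
            learning_rate=config.train.learning_rate,
            beta1=config.train.beta1,
            beta2=config.train.beta2,
            batch_size=config.train.batch_size,
            seed=config.seed,
        )
        result, ft = stage(
            f"train-tl-{scheme.lower()}",
            lambda spec=spec, scheme=scheme: transfer.run_dhl2(
                model,
                data["x_train"], data["y_train"],
                data["x_test"], data["y_test"],
                scheme=scheme,
                spec=spec,
                x_valid=data["x_valid"], grades_valid=data["y_valid"],
                variance_target=config.dhl.variance_target,
                svm_params=dhl.SVMParams(C=config.dhl.C, gamma=config.dhl.gamma),
            ),
        )
        tag = scheme.lower()
        result.report.save_json(
            run_dir / f"dhl2_{tag}_metrics.json",
            extra={"provenance": prov, "n_components": result.n_components},
        )
        cnn.write_history_csv(ft.history, run_dir / f"tl_{tag}_history.csv")
        summary["stages"][f"dhl2_{tag}"] = {
            "test_accuracy": result.report.accuracy,
            "n_components": result.n_components,
        }

    (run_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
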