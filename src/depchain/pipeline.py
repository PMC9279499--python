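"""Pipeline orchestration: simulate -> (segment) -> extract -> rank -> train
-> evaluate, with YAML config, seeded stages and a checksummed manifest.

Each stage reads and writes plain files inside a run directory, so stages can
be re-run individually from the CLI; `run_pipeline` executes them in
dependency order and records a manifest (seed, parameters, per-artifact
SHA-256) that makes reruns verifiable: an identical config yields identical
artifact checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import chains, relieff, synthetic
from .detect import Template
from .regress import evaluate, impute_median, split_train_test, train_mlp

log = logging.getLogger("depchain")


@dataclass
class RunConfig:
    """Parameters for a full pipeline run (YAML-loadable)."""

    out_dir: str = "run"
    seed: int = 42
    voltages: list[int] = field(default_factory=lambda: list(range(1, 11)))
    images_per_voltage: int = 50
    image_size: int = 512
    particle_radius: int = 10
    noise_sd: float = 8.0
    detection_threshold: float = 0.9
    write_images: bool = False
    relieff_k: int = 10
    train_fraction: float = 0.8
    hidden: int = 32
    optimizer: str = "adam"
    alpha: float = 1e-4
    batch_size: int = 10
    epochs: int = 100

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def simulate_dataset(cfg: RunConfig) -> tuple[list[np.ndarray], list[dict]]:
    """Generate the voltage-conditioned image set with ground truth records."""
    images, records = [], []
    for v in cfg.voltages:
        for i in range(cfg.images_per_voltage):
            seed = cfg.seed * 100_000 + v * 1_000 + i
            spec = synthetic.make_scene(
                v,
                seed=seed,
                image_height=cfg.image_size,
                image_width=cfg.image_size,
                particle_radius=cfg.particle_radius,
                noise_sd=cfg.noise_sd,
            )
            img, truth = synthetic.generate_micrograph(spec)
            images.append(img)
            records.append(
                {"voltage": v, "index": i, "truth": truth, "spec": spec}
            )
    return images, records


def extract_stage(
    cfg: RunConfig, images: list[np.ndarray], records: list[dict]
) -> pd.DataFrame:
    template = Template.from_patch(
        synthetic.render_template(cfg.particle_radius)
    )
    feats = []
    ids = []
    for img, rec in zip(images, records):
        fv = chains.extract_features(
            img, template, cfg.detection_threshold, voltage=rec["voltage"]
        )
        feats.append(fv)
        ids.append(f"v{rec['voltage']:02d}_{rec['index']:04d}")
    return chains.features_to_frame(feats, ids)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    log.info("simulate: %d voltages x %d images", len(cfg.voltages), cfg.images_per_voltage)
    images, records = simulate_dataset(cfg)
    if cfg.write_images:
        img_dir = out / "images"
        img_dir.mkdir(exist_ok=True)
        for img, rec in zip(images, records):
            iio.imwrite(
                img_dir / f"v{rec['voltage']:02d}_{rec['index']:04d}.png", img
            )
    truth_rows = []
    for rec in records:
        truth = rec["truth"]
        image_id = f"v{rec['voltage']:02d}_{rec['index']:04d}"
        for chain_id, members in enumerate(truth.chain_membership):
            for pid in members:
                r, c = truth.particle_centers[pid]
                truth_rows.append(
                    {"image_id": image_id, "particle_id": pid,
                     "row": int(r), "col": int(c), "chain_id": chain_id}
                )
    truth_path = out / "ground_truth.csv"
    pd.DataFrame(truth_rows).to_csv(truth_path, index=False)
    artifacts["ground_truth.csv"] = _sha256(truth_path)

    log.info("extract: template matching + chain assembly")
    frame = extract_stage(cfg, images, records)
    features_path = out / "features.csv"
    frame.to_csv(features_path, index=False)
    artifacts["features.csv"] = _sha256(features_path)

    X, y = chains.predictor_matrix(frame)
    X = impute_median(X)

    log.info("rank: RReliefF feature importance")
    imp = relieff.rrelieff(
        X, y, k=cfg.relieff_k, seed=cfg.seed,
        feature_names=list(chains.PREDICTOR_NAMES),
    )
    weights_path = out / "weights.csv"
    pd.DataFrame(
        {"feature": imp.feature_names, "weight": imp.weights}
    ).to_csv(weights_path, index=False)
    artifacts["weights.csv"] = _sha256(weights_path)

    log.info("train: %s MLP (hidden=%d)", cfg.optimizer, cfg.hidden)
    (Xtr, ytr), (Xte, yte) = split_train_test(
        X, y, cfg.train_fraction, seed=cfg.seed
    )
    model = train_mlp(
        Xtr, ytr, hidden=cfg.hidden, optimizer=cfg.optimizer,
        alpha=cfg.alpha, batch_size=cfg.batch_size, epochs=cfg.epochs,
        seed=cfg.seed,
    )
    model_path = out / "model.json"
    model_path.write_text(json.dumps(
        {
            "w1": model.w1.tolist(), "b1": model.b1.tolist(),
            "w2": model.w2.tolist(), "b2": model.b2.tolist(),
            "hidden": cfg.hidden, "optimizer": cfg.optimizer,
        }
    ))
    artifacts["model.json"] = _sha256(model_path)

    report = evaluate(yte, model.predict(Xte))
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report.as_dict(), indent=2))
    artifacts["report.json"] = _sha256(report_path)

    manifest = {
        "config": asdict(cfg),
        "n_images": len(images),
        "artifacts": artifacts,
        "test_report": report.as_dict(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("done: test RMSE %.3f V, accuracy %.2f", report.rmse, report.accuracy)
    return manifest
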