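"""End-to-end runs: configuration, seed fan-out, manifests.

A single :class:`PipelineConfig` (one YAML file) fully determines a run:
simulate a corpus, partition records into train and eval pools, build the
weak-labeled balanced training set and the gold dev/test sets, train the
CNN on weak labels and on a small gold set, evaluate both on the held-out
test set, and compute occlusion maps for a few true-positive clips.

The global seed fans out to per-stage seeds through
``numpy.random.SeedSequence(seed).spawn`` in a fixed stage order
(scenario, partition, clips, weak training, gold training, occlusion), so
any stage can be rerun in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from weakeeg.clips import (
    ClipDatasetSpec,
    build_eval_sets,
    build_training_set,
    clips_to_arrays,
    extract_positive_clips,
    partition_records,
)
from weakeeg.errors import PipelineStageError
from weakeeg.metrics import evaluate_probs
from weakeeg.nn.inception import build_model, desk_preset, published_preset, predict_proba, save_checkpoint
from weakeeg.occlusion import occlusion_map
from weakeeg.synth.corpus import ScenarioConfig, generate_corpus
from weakeeg.train import TrainConfig, _subsample_balanced, desk_train_config, train

logger = logging.getLogger("weakeeg.pipeline")

_STAGES = ("scenario", "partition", "clips", "train_weak", "train_gold", "occlusion")


@dataclass
class PipelineConfig:
    """Everything an end-to-end run needs; defaults give a desk-scale run."""

    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    clip_dataset: ClipDatasetSpec = field(default_factory=ClipDatasetSpec)
    model_preset: str = "desk"
    train: TrainConfig = field(default_factory=desk_train_config)
    eval_fraction: float = 0.35
    #: the gold training set is the weak set's size divided by this
    gold_train_divisor: int = 100
    threshold: float = 0.5
    n_occlusion_clips: int = 2
    seed: int = 0


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {name: int(c.generate_state(1)[0] % 2**31) for name, c in zip(_STAGES, children)}


def validate_config(raw: dict | None) -> tuple[PipelineConfig | None, list[str]]:
    """Fill defaults and report every violation with a path into the config.

    Returns ``(config, [])`` on success or ``(None, errors)`` otherwise;
    nothing is raised.
    """
    raw = dict(raw or {})
    errors: list[str] = []

    def _build(section: str, cls, payload):
        try:
            return cls(**payload)
        except Exception as exc:  # noqa: BLE001 - reported, not raised
            errors.append(f"{section}: {exc}")
            return None

    noise_raw = dict(raw.get("scenario", {}).pop("noise", {}) or {})
    scenario_raw = dict(raw.get("scenario", {}) or {})
    from weakeeg.synth.annotate import NoiseModelConfig

    noise = _build("scenario.noise", NoiseModelConfig, noise_raw)
    if noise is not None:
        scenario_raw["noise"] = noise
    scenario = _build("scenario", ScenarioConfig, scenario_raw)
    clip_spec = _build("clip_dataset", ClipDatasetSpec, dict(raw.get("clip_dataset", {}) or {}))
    train_raw = dict(raw.get("train", {}) or {})
    train_cfg = (_build("train", TrainConfig, train_raw) if train_raw
                 else desk_train_config())

    preset = raw.get("model_preset", "desk")
    if preset not in ("desk", "published"):
        errors.append(f"model_preset: must be 'desk' or 'published', got {preset!r}")

    top = {k: raw[k] for k in ("eval_fraction", "gold_train_divisor", "threshold",
                               "n_occlusion_clips", "seed") if k in raw}
    if "eval_fraction" in top and not 0 < top["eval_fraction"] < 1:
        errors.append(f"eval_fraction: must be in (0, 1), got {top['eval_fraction']}")

    if errors:
        return None, errors
    return PipelineConfig(scenario=scenario, clip_dataset=clip_spec,
                          model_preset=preset, train=train_cfg, **top), errors


def load_config(path: str | Path) -> tuple[PipelineConfig | None, list[str]]:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh) or {})


def _sha256(arrays: list[np.ndarray]) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()


def hash_clips(clips) -> str:
    """Stable content hash of a clip dataset (signals + labels)."""
    X, y = clips_to_arrays(clips)
    return _sha256([X, y])


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the full run; returns (and writes) the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {"seed": config.seed, "stage_seeds": seeds, "stages": {}}
    t_all = time.perf_counter()

    def _run(stage: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001
            err = PipelineStageError(stage, exc)
            manifest["stages"][stage] = {"status": "failed", **err.status}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
            raise err from exc
        wall = time.perf_counter() - t0
        manifest["stages"][stage] = {"status": "ok"}
        logger.info("stage=%s seed=%s wall_s=%.2f", stage, seeds.get(stage), wall)
        return result

    # --- simulate -------------------------------------------------------
    scenario = dataclasses.replace(config.scenario, seed=seeds["scenario"])
    records = _run("scenario", lambda: generate_corpus(scenario))

    # --- partition + clips ---------------------------------------------
    train_records, eval_records = _run(
        "partition",
        lambda: partition_records(records, config.eval_fraction, seeds["partition"]),
    )

    def _clips():
        spec = dataclasses.replace(config.clip_dataset,
                                   negative_sampling_seed=seeds["clips"])
        weak_train = build_training_set(train_records, spec)
        dev, test = build_eval_sets(eval_records, spec)
        return spec, weak_train, dev, test

    spec, weak_train, dev, test = _run("clips", _clips)
    manifest["datasets"] = {
        "n_weak_train": len(weak_train), "n_dev": len(dev), "n_test": len(test),
        "weak_train_sha256": hash_clips(weak_train),
        "dev_sha256": hash_clips(dev),
        "test_sha256": hash_clips(test),
    }

    # --- training -------------------------------------------------------
    preset = desk_preset if config.model_preset == "desk" else published_preset
    model_cfg = preset(spec.clip_len_s)
    test_X, test_y = clips_to_arrays(test)

    def _train_weak():
        cfg = dataclasses.replace(config.train, seed=seeds["train_weak"])
        model = build_model(model_cfg, seed=seeds["train_weak"])
        return train(model, weak_train, dev, cfg)

    weak_result = _run("train_weak", _train_weak)

    def _train_gold():
        n_gold = max(4, len(weak_train) // config.gold_train_divisor)
        rng = np.random.default_rng(seeds["train_gold"])
        gold_train = _subsample_balanced(dev, n_gold, rng)
        cfg = dataclasses.replace(config.train, seed=seeds["train_gold"])
        model = build_model(model_cfg, seed=seeds["train_gold"])
        return train(model, gold_train, dev, cfg), len(gold_train)

    gold_result, n_gold = _run("train_gold", _train_gold)

    rows = []
    for name, result in (("weak", weak_result), ("gold_small", gold_result)):
        report = evaluate_probs(test_y, predict_proba(result.model, test_X), config.threshold)
        rows.append({"model": name, "auroc": report.auroc, "f1": report.f1,
                     "precision": report.precision, "recall": report.recall,
                     "fpr": report.fpr, "threshold": config.threshold})
        save_checkpoint(result.model, out / f"model_{name}.npz")
        result.history.to_csv(out / f"history_{name}.csv", index=False)
    metrics = pd.DataFrame(rows)
    metrics.to_csv(out / "metrics.csv", index=False)
    manifest["metrics"] = {r["model"]: {"auroc": r["auroc"], "f1": r["f1"]} for r in rows}
    manifest["datasets"]["n_gold_train"] = n_gold

    # --- occlusion on a few true positives ------------------------------
    def _occlude():
        gold_pos, _ = extract_positive_clips(eval_records, spec.clip_len_s, "gold")
        maps = [
            occlusion_map(weak_result.model, clip, normalize=True)
            for clip in gold_pos[: config.n_occlusion_clips]
        ]
        if maps:
            np.savez(out / "occlusion_maps.npz",
                     **{f"map{i}": m.values for i, m in enumerate(maps)})
        return len(maps)

    manifest["n_occlusion_maps"] = _run("occlusion", _occlude)
    manifest["wall_s"] = round(time.perf_counter() - t_all, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
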