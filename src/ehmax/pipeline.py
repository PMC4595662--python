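"""End-to-end orchestration: learn a cluster bank, encode C2 features, train
and evaluate the softmax head; every run writes a manifest with a config
snapshot, stage timings and content hashes of its artifacts."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import sklearn
import scipy
import skimage

from . import __version__
from .classify import evaluate, predict, save_model, train_softmax
from .config import PipelineConfig, config_to_dict, save_config
from .encoding import (ablate_position_features, compute_c2, compute_c2_ohmax,
                       compute_s2_ehmax, compute_s2_ohmax,
                       sample_prototypes_random)
from .exceptions import EHMaxError
from .features import full_gabor_bank, prepare_encoding_c1
from .io import load_dataset, split_datasets
from .learning import ClusterBank, run_learning, save_bank

LIBRARY_VERSIONS = {
    "ehmax": __version__,
    "numpy": np.__version__,
    "scipy": scipy.__version__,
    "scikit-learn": sklearn.__version__,
    "scikit-image": skimage.__version__,
}


@dataclass
class RunManifest:
    """Provenance of one pipeline run."""

    command: str
    seed: int
    config: dict
    stage_seconds: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)   # path -> sha256
    versions: dict = field(default_factory=lambda: dict(LIBRARY_VERSIONS))

    def add_artifact(self, path: str | Path) -> None:
        p = Path(path)
        digest = hashlib.sha256(p.read_bytes()).hexdigest()
        self.artifacts[p.name] = digest

    def write(self, path: str | Path) -> None:
        data = {"command": self.command, "seed": self.seed, "config": self.config,
                "stage_seconds": self.stage_seconds, "artifacts": self.artifacts,
                "versions": self.versions}
        Path(path).write_text(json.dumps(data, indent=1, sort_keys=True))


class _Timer:
    def __init__(self, manifest: RunManifest, stage: str):
        self.manifest, self.stage = manifest, stage

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, *exc):
        self.manifest.stage_seconds[self.stage] = round(
            time.perf_counter() - self.t0, 3)


def run_learn(dataset_dir: str | Path, config: PipelineConfig,
              out_dir: str | Path):
    """Load a dataset, learn the cluster bank, and persist bank + manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(command="learn", seed=config.seed,
                           config=config_to_dict(config))
    try:
        with _Timer(manifest, "load"):
            D, N = load_dataset(dataset_dir, max_side=config.max_side)
            splits = split_datasets(D, N, config.seed)
        with _Timer(manifest, "learning"):
            bank = run_learning(splits, config)
        with _Timer(manifest, "save"):
            save_bank(bank, out / "bank")
            save_config(config, out / "config.yaml")
    except EHMaxError as err:
        raise type(err)(f"[stage {list(manifest.stage_seconds) or ['load']}] {err}") \
            from err
    for p in sorted((out / "bank").iterdir()):
        manifest.add_artifact(p)
    manifest.add_artifact(out / "config.yaml")
    manifest.write(out / "manifest.json")
    return bank, manifest


def encode_c2_features(records: list, bank: ClusterBank, config: PipelineConfig,
                       ablate_position: bool = False) -> np.ndarray:
    """Enhanced-model C2 feature matrix for a list of ImageRecords (rows in
    record order, 3*Gamma columns, or Gamma when position is ablated)."""
    gbank = full_gabor_bank(config)
    rows = []
    for rec in records:
        c1 = prepare_encoding_c1(rec, config, bank=gbank)
        s2 = compute_s2_ehmax(c1, bank, encoder=config.encoder, rgb=rec.pixels)
        rows.append(compute_c2(s2).vector)
    X = np.vstack(rows)
    if ablate_position:
        X = ablate_position_features(X)
    return X


def encode_c2_ohmax(records: list, train_records: list, config: PipelineConfig,
                    M: int | None = None, sizes=None) -> np.ndarray:
    """Baseline C2 features: random prototypes sampled from the training
    records' band-1 C1 maps, Gaussian-like S2, max-only C2 (M columns)."""
    ocfg = config.ohmax
    M = M if M is not None else ocfg.n_prototypes
    sizes = tuple(sizes) if sizes is not None else tuple(ocfg.prototype_sizes)
    gbank = full_gabor_bank(config, n_orientations=ocfg.n_orientations)
    c1_cache = {rec.id: prepare_encoding_c1(rec, config, bank=gbank)
                for rec in {r.id: r for r in list(train_records) + list(records)}.values()}
    stacks = {rec.id: c1_cache[rec.id].band_stack(1) for rec in train_records}
    protos = sample_prototypes_random(stacks, M=M, sizes=sizes,
                                      seed=config.seed, beta=ocfg.tuning_sharpness)
    rows = []
    for rec in records:
        s2 = compute_s2_ohmax(c1_cache[rec.id], protos)
        rows.append(compute_c2_ohmax(s2).vector)
    return np.vstack(rows)


def split_train_test(records: list, seed: int, test_fraction: float = 1.0 / 3.0):
    """Per-class deterministic train/test split of labeled records."""
    rng = np.random.default_rng(seed)
    by_class: dict = {}
    for rec in records:
        by_class.setdefault(rec.label, []).append(rec)
    train, test = [], []
    for label in sorted(by_class):
        group = by_class[label]
        order = rng.permutation(len(group))
        n_test = max(1, round(len(group) * test_fraction))
        test.extend(group[i] for i in order[:n_test])
        train.extend(group[i] for i in order[n_test:])
    return train, test


def run_encode_train_eval(train_records: list, test_records: list,
                          bank: ClusterBank | None, config: PipelineConfig,
                          out_dir: str | Path | None = None,
                          ablate_position: bool = False,
                          baseline: str | None = None,
                          M: int | None = None) -> dict:
    """Encode C2 features, fit the softmax head on the training records, and
    evaluate on the held-out records.

    ``baseline="ohmax"`` switches to random prototypes with Gaussian-like S2
    (matched prototype count M); otherwise the learned ``bank`` is required.
    Returns a metrics dict with accuracy and the confusion table.
    """
    manifest = RunManifest(command="encode-train-eval", seed=config.seed,
                           config=config_to_dict(config))
    with _Timer(manifest, "encode"):
        if baseline == "ohmax":
            X_train = encode_c2_ohmax(train_records, train_records, config, M=M)
            X_test = encode_c2_ohmax(test_records, train_records, config, M=M)
        elif baseline is None:
            X_train = encode_c2_features(train_records, bank, config, ablate_position)
            X_test = encode_c2_features(test_records, bank, config, ablate_position)
        else:
            raise EHMaxError(f"unknown baseline {baseline!r}")
    with _Timer(manifest, "train"):
        model = train_softmax(X_train, [r.label for r in train_records],
                              seed=config.seed)
    with _Timer(manifest, "eval"):
        preds = predict(model, X_test)
        accuracy, confusion = evaluate(preds, [r.label for r in test_records])
    metrics = {
        "accuracy": accuracy,
        "n_train": len(train_records),
        "n_test": len(test_records),
        "feature_length": int(X_train.shape[1]),
        "ablate_position": ablate_position,
        "baseline": baseline,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_model(model, out / "softmax.json")
        confusion.to_csv(out / "confusion.tsv", sep="\t")
        (out / "metrics.json").write_text(json.dumps(metrics, indent=1))
        for name in ("softmax.json", "confusion.tsv", "metrics.json"):
            manifest.add_artifact(out / name)
        manifest.write(out / "manifest.json")
    metrics["confusion"] = confusion
    metrics["model"] = model
    return metrics
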