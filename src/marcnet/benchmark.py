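"""The package's standard scaled-down end-to-end study.

A fixed synthetic benchmark shared by the test suite and the acceptance
script: 12 subjects x 10 slices of 128x128 pelvis-like phantoms with
randomized applicators and per-subject acquisition conditions; a depth-8
residual network trained on 2,000 patches of 50x50 for 20 epochs with
batch 64; evaluation on the held-out test subject against the uncorrected
artifact-insert baseline, the ordinary-learning ablation and the LI
sinogram baseline.  Problem sizes are chosen so the whole study runs in
minutes on one CPU core; docs/methods.md discusses what this scale does
and does not demonstrate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .artifact_sim import DatasetConfig, build_dataset
from .evaluation import evaluate_model, psnr
from .mar import li_mar
from .training import TrainConfig, TrainResult, train

__all__ = ["BenchmarkConfig", "run_benchmark"]


@dataclass
class BenchmarkConfig:
    n_subjects: int = 12
    slices_per_subject: int = 10
    dataset: DatasetConfig = field(default_factory=DatasetConfig)
    depth: int = 8
    n_filters: int = 8
    n_patches: int = 2000
    epochs: int = 20
    batch_size: int = 64
    patch_size: int = 50
    learning_rate: float = 0.01

    def train_config(self, mode: str, seed: int) -> TrainConfig:
        return TrainConfig(
            patch_size=self.patch_size,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            epochs=self.epochs,
            n_patches=self.n_patches,
            mode=mode,
            seed=seed,
            depth=self.depth,
            n_filters=self.n_filters,
        )


def run_benchmark(
    seed: int = 1,
    config: BenchmarkConfig | None = None,
    train_ordinary: bool = True,
    run_li: bool = True,
) -> dict:
    """Run the full scaled-down study and return its measured quantities.

    Returns a dict with mean test-set PSNR for the uncorrected insert
    images, the residual-learning network, and (optionally) the
    ordinary-learning network and the LI baseline, plus the training
    histories.  Deterministic given (seed, config).
    """
    config = config or BenchmarkConfig()
    ss = np.random.SeedSequence(seed)
    dataset_seed, res_seed, ord_seed = (
        int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in ss.spawn(3)
    )
    dataset = build_dataset(
        config.n_subjects, config.slices_per_subject, dataset_seed, config.dataset
    )
    test = dataset.split("test")

    out: dict = {
        "seed": seed,
        "n_test_slices": len(test),
        "manifest_hash": dataset.manifest["manifest_hash"],
    }

    res: TrainResult = train(config.train_config("residual", res_seed), dataset)
    report = evaluate_model(res.state, test, label="residual")
    out["psnr_insert"] = report.mean["insert"]
    out["psnr_residual"] = report.mean["residual"]
    out["residual_history"] = res.history

    if train_ordinary:
        ordn = train(config.train_config("ordinary", ord_seed), dataset)
        out["psnr_ordinary"] = evaluate_model(ordn.state, test, label="ordinary").mean[
            "ordinary"
        ]
        out["ordinary_history"] = ordn.history

    if run_li:
        li_scores = [
            psnr(li_mar(t.artifact_insert, t.metal_mask).reduced, t.artifact_free)
            for t in test
        ]
        out["psnr_li"] = float(np.mean(li_scores))

    return out
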