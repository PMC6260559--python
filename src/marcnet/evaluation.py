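"""PSNR metric and the benchmark/experiment runner.

PSNR follows the standard 8-bit convention,

    MSE = 1/(H W) sum (X - Y)^2,   PSNR = 10 log10((2^n - 1)^2 / MSE),

with CT images first mapped linearly from the HU display window
[-1000, 3000] onto [0, 255] (metal saturates at the top of the window;
metal pixels are included in the metric unless a mask is passed).

The experiment runner reproduces the study designs on synthetic data:
patch-size sweep (25/50/100), residual-vs-ordinary learning, and a
training-set-size sweep, each as arms over one dataset manifest with
arm-specific seeds, reporting whether the expected qualitative orderings
hold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .artifact_sim import Dataset, DatasetConfig, TripletSample, build_dataset
from .mar import li_mar, remove_artifact
from .network import DEFAULT_WINDOW, TrainState, hu_to_unit
from .phantom import ImageGrid
from .training import TrainConfig, train

__all__ = [
    "EvalReport",
    "psnr",
    "evaluate_model",
    "run_experiment",
    "ExperimentConfig",
    "ExperimentResult",
]


def psnr(
    x: ImageGrid | np.ndarray,
    y: ImageGrid | np.ndarray,
    n_bits: int = 8,
    window: tuple[float, float] | None = DEFAULT_WINDOW,
    mask: np.ndarray | None = None,
) -> float:
    """Peak signal-to-noise ratio in dB (``inf`` for identical images).

    With ``window`` set, both inputs are HU images mapped (with clipping)
    onto the n-bit scale first; ``window=None`` treats the inputs as already
    being on that scale.  ``mask`` (optional) excludes pixels where True.
    """
    xv = x.values if isinstance(x, ImageGrid) else np.asarray(x, dtype=np.float64)
    yv = y.values if isinstance(y, ImageGrid) else np.asarray(y, dtype=np.float64)
    if xv.shape != yv.shape:
        raise ValueError("PSNR inputs must share a shape")
    peak = 2.0**n_bits - 1.0
    if window is not None:
        xv = hu_to_unit(xv, window) * peak
        yv = hu_to_unit(yv, window) * peak
    diff = xv - yv
    if mask is not None:
        diff = diff[~mask]
    mse = float(np.mean(diff**2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(peak**2 / mse))


@dataclass
class EvalReport:
    """Per-image PSNR per method plus means and provenance metadata."""

    per_image: dict[str, list[float]]
    metadata: dict = field(default_factory=dict)

    @property
    def mean(self) -> dict[str, float]:
        return {k: float(np.mean(v)) for k, v in self.per_image.items()}

    def to_dict(self) -> dict:
        return {"per_image": self.per_image, "mean": self.mean, "metadata": self.metadata}


def _apply(method, triplet: TripletSample) -> ImageGrid:
    if isinstance(method, TrainState):
        return remove_artifact(method, triplet.artifact_insert).reduced
    if method == "li":
        return li_mar(triplet.artifact_insert, triplet.metal_mask).reduced
    if callable(method):
        return method(triplet)
    raise TypeError(f"unsupported method {method!r}")


def evaluate_model(
    method,
    test_split: list[TripletSample],
    label: str = "method",
    window: tuple[float, float] = DEFAULT_WINDOW,
    metadata: dict | None = None,
) -> EvalReport:
    """Apply a method to every test slice and score PSNR vs artifact-free.

    ``method`` may be a trained :class:`TrainState`, the string ``"li"``,
    or a callable ``triplet -> ImageGrid``.  The report also carries the
    uncorrected insert-vs-free PSNR as the no-correction baseline.
    """
    if not test_split:
        raise ValueError("empty test split")
    scores: list[float] = []
    baseline: list[float] = []
    for t in test_split:
        if t.artifact_free is None:
            raise ValueError("missing ground truth for a test slice")
        reduced = _apply(method, t)
        scores.append(psnr(reduced, t.artifact_free, window=window))
        baseline.append(psnr(t.artifact_insert, t.artifact_free, window=window))
    return EvalReport(
        per_image={label: scores, "insert": baseline},
        metadata=metadata or {},
    )


# ---------------------------------------------------------------------------
# Experiment designs
# ---------------------------------------------------------------------------

DESIGNS = ("patch_size_sweep", "residual_vs_ordinary", "train_size_sweep")


@dataclass
class ExperimentConfig:
    """One dataset + one base training recipe, shared across arms."""

    n_subjects: int = 12
    slices_per_subject: int = 10
    dataset_seed: int = 0
    dataset: DatasetConfig = field(default_factory=DatasetConfig)
    base_train: TrainConfig = field(default_factory=TrainConfig)
    patch_sizes: tuple[int, ...] = (25, 50, 100)
    train_subject_counts: tuple[int, ...] | None = None  # default: 1/3, 2/3, all


@dataclass
class ExperimentResult:
    design: str
    table: dict  # arm -> mean PSNR (plus the insert baseline column)
    reports: dict[str, EvalReport]
    orderings: dict[str, bool]
    errors: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "design": self.design,
                "table": self.table,
                "orderings": self.orderings,
                "errors": self.errors,
                "reports": {k: r.to_dict() for k, r in self.reports.items()},
            },
            indent=2,
        )


def _arm_config(base: TrainConfig, seed: int, **overrides) -> TrainConfig:
    d = asdict(base)
    d.update(overrides, seed=seed)
    d["adam_betas"] = tuple(d["adam_betas"])
    return TrainConfig(**d)


def _subset_dataset(dataset: Dataset, n_train_subjects: int) -> Dataset:
    keep = set(dataset.manifest["subject_splits"]["train"][:n_train_subjects])
    splits = dict(dataset.splits)
    splits["train"] = [i for i in dataset.splits["train"] if dataset.subject_of[i] in keep]
    return Dataset(dataset.triplets, dataset.subject_of, splits, dataset.manifest)


def run_experiment(design: str, config: ExperimentConfig | None = None) -> ExperimentResult:
    """Run one experimental design end to end on a fresh synthetic dataset.

    Arms share the dataset manifest and differ only in the swept setting
    and an arm-specific training seed; a failed arm is recorded and the
    experiment continues.
    """
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}; expected one of {DESIGNS}")
    config = config or ExperimentConfig()
    dataset = build_dataset(
        config.n_subjects, config.slices_per_subject, config.dataset_seed, config.dataset
    )
    test = dataset.split("test")
    ss = np.random.SeedSequence(config.base_train.seed)

    if design == "patch_size_sweep":
        arms = {f"patch{s}": {"patch_size": s} for s in config.patch_sizes}
    elif design == "residual_vs_ordinary":
        arms = {"ordinary": {"mode": "ordinary"}, "residual": {"mode": "residual"}}
    else:
        n_train = len(dataset.manifest["subject_splits"]["train"])
        counts = config.train_subject_counts or tuple(
            sorted({max(1, n_train // 3), max(2, (2 * n_train) // 3), n_train})
        )
        arms = {f"subjects{c}": {"_n_train_subjects": c} for c in counts}

    reports: dict[str, EvalReport] = {}
    errors: dict[str, str] = {}
    table: dict[str, float] = {}
    for (name, overrides), child in zip(arms.items(), ss.spawn(len(arms))):
        seed = int(child.generate_state(1)[0] & 0x7FFFFFFF)
        try:
            ds = dataset
            ov = dict(overrides)
            n_sub = ov.pop("_n_train_subjects", None)
            if n_sub is not None:
                ds = _subset_dataset(dataset, n_sub)
            result = train(_arm_config(config.base_train, seed, **ov), ds)
            report = evaluate_model(
                result.state,
                test,
                label=name,
                metadata={
                    "manifest_hash": dataset.manifest["manifest_hash"],
                    "config_hash": dataset.manifest["config_hash"],
                    "train_seed": seed,
                },
            )
            reports[name] = report
            table[name] = report.mean[name]
            table.setdefault("insert", report.mean["insert"])
        except Exception as exc:  # arm failure must not kill the experiment
            errors[name] = f"{type(exc).__name__}: {exc}"

    orderings: dict[str, bool] = {}
    if design == "patch_size_sweep" and all(f"patch{s}" in table for s in config.patch_sizes):
        best = max(config.patch_sizes, key=lambda s: table[f"patch{s}"])
        orderings["patch50_best"] = best == 50
    if design == "residual_vs_ordinary" and {"residual", "ordinary"} <= table.keys():
        orderings["residual_ge_ordinary"] = table["residual"] >= table["ordinary"]
    if design == "train_size_sweep":
        vals = [v for k, v in sorted(table.items()) if k.startswith("subjects")]
        if len(vals) >= 2:
            orderings["psnr_nondecreasing_with_size"] = bool(
                np.all(np.diff(vals) >= -1e-9)
            )
    return ExperimentResult(design, table, reports, orderings, errors)
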