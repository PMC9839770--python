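"""Teacher-student self-training orchestration.

The workflow mirrors the standard self-training recipe for
semi-supervised segmentation:

1. split the labelled data into a small teacher set, a pool treated as
   unlabelled (its labels are hidden and used only to audit pseudo-label
   quality), and a held-out test set of real labels;
2. train the teacher supervised by minimising binary cross-entropy;
3. run the teacher over the pool to produce binarised pseudo labels;
4. (CCS mode) crop every pseudo-labelled lesion around its component
   centroid and expand each crop with the fixed 5-way augmentation;
5. train the student on the pseudo pairs (plus the real labelled pairs by
   default) and evaluate both models on the held-out real test labels.

Test images never contribute to any training stage, and pseudo labels are
produced only by the teacher.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Callable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .augment import AugmentationSpec, augment_dataset
from .ccs import ccs_sample_dataset, ccs_sample_pair
from .core import (
    PipelineError,
    Radiograph,
    SegmentationMask,
    TrainingDivergedError,
    check_aligned,
)
from .metrics import MetricReport, evaluate_dataset, evaluate_pair
from .model import FilterBankSegmenter, SegmentationModel, extract_features

__all__ = [
    "TrainConfig",
    "SplitSpec",
    "DatasetSplit",
    "PseudoPair",
    "RunReport",
    "default_backbone",
    "bce_loss",
    "split_dataset",
    "train_segmentation_model",
    "generate_pseudo_labels",
    "pseudo_label_fidelity",
    "run_supervised_baseline",
    "run_self_training",
    "run_sweeps",
]

logger = logging.getLogger(__name__)

LabelledPair = tuple[Radiograph, SegmentationMask]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings for one model fit.

    Batches are groups of ``batch_size`` images; within a batch, pixels are
    processed in chunks of ``pixel_chunk`` with one optimiser step each.
    Training stops early when the monitored loss fails to improve by
    ``min_delta`` for ``early_stop_patience`` consecutive epochs; the best
    checkpoint is restored.
    """

    batch_size: int = 8
    learning_rate: float = 1e-3
    max_epochs: int = 100
    early_stop_patience: int = 5
    validation_fraction: float = 0.1
    min_delta: float = 1e-4
    pixel_chunk: int = 2048
    seed: int = 0
    deterministic: bool = True

    def __post_init__(self) -> None:
        if min(self.batch_size, self.max_epochs, self.early_stop_patience,
               self.pixel_chunk) < 1:
            raise ValueError("batch_size, max_epochs, patience, pixel_chunk must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0.0 <= self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must be in [0, 1)")
        if self.early_stop_patience > self.max_epochs:
            raise ValueError("patience must be <= max_epochs")


@dataclass(frozen=True)
class SplitSpec:
    """How labelled data is partitioned for a self-training run."""

    test_fraction: float = 0.10
    n_teacher_labelled: int = 20
    n_pseudo: Optional[int] = None  # None = whole pool
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.test_fraction < 1.0):
            raise ValueError("test_fraction must be in (0, 1)")
        if self.n_teacher_labelled < 1:
            raise ValueError("n_teacher_labelled must be >= 1")
        if self.n_pseudo is not None and self.n_pseudo < 0:
            raise ValueError("n_pseudo must be >= 0")


@dataclass(eq=False)
class DatasetSplit:
    """Disjoint teacher/pool/test partition of a labelled dataset.

    Pool items keep their ground-truth masks, but the pipeline treats them
    as unlabelled: the hidden truth is used only to audit pseudo-label
    fidelity, never for training.
    """

    teacher: list[LabelledPair]
    pool: list[LabelledPair]
    test: list[LabelledPair]

    def manifests(self) -> dict[str, list[str]]:
        return {
            name: [img.id for img, _ in part]
            for name, part in (("teacher", self.teacher), ("pool", self.pool),
                               ("test", self.test))
        }


@dataclass(eq=False)
class PseudoPair:
    """An unlabelled image with its teacher-predicted binary mask."""

    image: Radiograph
    mask: SegmentationMask
    teacher_id: str
    threshold: float

    @property
    def is_empty(self) -> bool:
        return self.mask.is_empty()


@dataclass(eq=False)
class RunReport:
    """Everything one pipeline run produced, for reporting and auditing."""

    mode: str
    seed: int
    config: dict
    manifests: dict[str, list[str]]
    teacher_metrics: Optional[MetricReport]
    student_metrics: MetricReport
    teacher_curves: Optional[dict]
    student_curves: dict
    pseudo_fidelity: Optional[float] = None
    n_pseudo_used: int = 0
    n_student_examples: int = 0

    def as_dict(self) -> dict:
        return {
            "mode": self.mode,
            "seed": self.seed,
            "config": self.config,
            "manifests": self.manifests,
            "teacher_metrics": None if self.teacher_metrics is None
            else self.teacher_metrics.as_dict(),
            "student_metrics": self.student_metrics.as_dict(),
            "teacher_curves": self.teacher_curves,
            "student_curves": self.student_curves,
            "pseudo_fidelity": self.pseudo_fidelity,
            "n_pseudo_used": self.n_pseudo_used,
            "n_student_examples": self.n_student_examples,
        }


def default_backbone(seed: int = 0) -> FilterBankSegmenter:
    """The built-in CPU-friendly backbone with a fresh seeded init."""
    return FilterBankSegmenter(hidden_units=32, seed=seed)


def bce_loss(pred: np.ndarray, target: np.ndarray, eps: float = 1e-7) -> float:
    """Mean binary cross-entropy with predictions clipped to [eps, 1-eps]."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    check_aligned(pred, target, "predictions and targets")
    p = np.clip(pred, eps, 1.0 - eps)
    return float(-np.mean(target * np.log(p) + (1.0 - target) * np.log(1.0 - p)))


def split_dataset(pairs: Sequence[LabelledPair], spec: SplitSpec) -> DatasetSplit:
    """Deterministically partition labelled pairs into teacher/pool/test.

    The test size is ``round(test_fraction * N)``; of the remainder, the
    first ``n_teacher_labelled`` (after a seeded shuffle) form the teacher
    set and the rest the unlabelled pool.
    """
    n = len(pairs)
    n_test = int(round(spec.test_fraction * n))
    n_train = n - n_test
    if spec.n_teacher_labelled > n_train:
        raise PipelineError(
            f"need {spec.n_teacher_labelled} teacher images but only "
            f"{n_train} are available after the test split"
        )
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n)
    test_idx = order[:n_test]
    teacher_idx = order[n_test : n_test + spec.n_teacher_labelled]
    pool_idx = order[n_test + spec.n_teacher_labelled :]
    pick = lambda idx: [pairs[i] for i in idx]
    return DatasetSplit(teacher=pick(teacher_idx), pool=pick(pool_idx),
                        test=pick(test_idx))


def _as_xy(pair) -> tuple[np.ndarray, np.ndarray]:
    """Coerce any supported pair type to (image_array, mask_array)."""
    if isinstance(pair, tuple):
        image, mask = pair
    else:
        image, mask = pair.image, pair.mask
    x = image.pixels if isinstance(image, Radiograph) else np.asarray(image)
    y = mask.pixels if isinstance(mask, SegmentationMask) else np.asarray(mask)
    check_aligned(x, y, "training image and mask")
    return np.asarray(x, dtype=np.float64), np.asarray(y, dtype=np.float64)


class _Adam:
    """Adam with a fixed learning rate (the trainer's only optimiser state)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k in params:
            self.m[k] = b1 * self.m[k] + (1 - b1) * grads[k]
            self.v[k] = b2 * self.v[k] + (1 - b2) * grads[k] ** 2
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)


def train_segmentation_model(
    model: FilterBankSegmenter,
    pairs: Sequence,
    config: TrainConfig = TrainConfig(),
) -> tuple[FilterBankSegmenter, dict]:
    """Fit the backbone on image/mask pairs by minibatch BCE descent.

    Pairs may be full frames, CCS crops or augmented crops (anything with
    aligned image/mask grids; shapes may differ between pairs). A seeded
    fraction of the images is held out to monitor validation loss for
    early stopping; when the training set is too small to spare an image,
    the training loss is monitored instead. Returns the model (best
    checkpoint restored) and per-epoch curves.
    """
    if len(pairs) == 0:
        raise ValueError("cannot train on an empty dataset")
    rng = np.random.default_rng(config.seed)

    data = [_as_xy(p) for p in pairs]
    feats = [extract_features(x) for x, _ in data]
    labels = [y.reshape(-1) for _, y in data]

    all_feats = np.concatenate(feats, axis=0)
    model.set_normalisation(all_feats.mean(axis=0), all_feats.std(axis=0))
    feats = [model.normalise(f) for f in feats]
    del all_feats

    n = len(data)
    n_val = int(round(config.validation_fraction * n))
    if n_val >= n:
        n_val = n - 1
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    val_x = (np.concatenate([feats[i] for i in val_idx], axis=0)
             if n_val else None)
    val_y = (np.concatenate([labels[i] for i in val_idx], axis=0)
             if n_val else None)

    optimiser = _Adam(model.params, config.learning_rate)
    curves: dict[str, list] = {"train_loss": [], "val_loss": [], "val_accuracy": []}
    best_loss = np.inf
    best_params = model.copy_params()
    stall = 0

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(train_idx))
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            batch = [train_idx[i] for i in order[start : start + config.batch_size]]
            bx = np.concatenate([feats[i] for i in batch], axis=0)
            by = np.concatenate([labels[i] for i in batch], axis=0)
            for c0 in range(0, len(by), config.pixel_chunk):
                cx = bx[c0 : c0 + config.pixel_chunk]
                cy = by[c0 : c0 + config.pixel_chunk]
                p, cache = model.forward(cx)
                loss = bce_loss(p, cy)
                if not np.isfinite(loss):
                    raise TrainingDivergedError(f"non-finite loss at epoch {epoch}")
                grads = model.backward(cache, p, cy)
                optimiser.step(model.params, grads)
                epoch_losses.append(loss)
        train_loss = float(np.mean(epoch_losses))
        curves["train_loss"].append(train_loss)

        if val_x is not None:
            pv, _ = model.forward(val_x)
            monitored = bce_loss(pv, val_y)
            curves["val_loss"].append(monitored)
            curves["val_accuracy"].append(float(np.mean((pv >= 0.5) == (val_y >= 0.5))))
        else:
            monitored = train_loss
            curves["val_loss"].append(None)
            curves["val_accuracy"].append(None)
        if not np.isfinite(monitored):
            raise TrainingDivergedError(f"non-finite monitored loss at epoch {epoch}")

        if monitored < best_loss - config.min_delta:
            best_loss = monitored
            best_params = model.copy_params()
            stall = 0
        else:
            stall += 1
            if stall >= config.early_stop_patience:
                break

    model.set_params(best_params)
    return model, curves


def generate_pseudo_labels(
    teacher: SegmentationModel,
    images: Sequence[Radiograph],
    threshold: float = 0.5,
    teacher_id: str = "teacher",
) -> list[PseudoPair]:
    """Binarise teacher predictions into one pseudo pair per input image."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    out = []
    for image in images:
        mask = teacher.predict_mask(image, threshold=threshold)
        out.append(PseudoPair(image=image, mask=mask, teacher_id=teacher_id,
                              threshold=threshold))
    return out


def pseudo_label_fidelity(
    pseudo: Sequence[PseudoPair], hidden_truth: Sequence[SegmentationMask]
) -> float:
    """Mean foreground IoU of pseudo masks against the withheld truth.

    Audit-only: this quantity never feeds back into training.
    """
    if len(pseudo) != len(hidden_truth) or len(pseudo) == 0:
        raise ValueError("need matched, non-empty pseudo and truth sequences")
    ious = [evaluate_pair(p.mask, t)["fg_iou"] for p, t in zip(pseudo, hidden_truth)]
    return float(np.mean(ious))


def _evaluate_model(
    model: SegmentationModel,
    test: Sequence[LabelledPair],
    eval_crops: bool = False,
    crop_size: int = 32,
) -> MetricReport:
    """Full-frame evaluation by default; optional crop-centred protocol.

    In crop mode, windows come from the ground-truth component centroids
    of each test mask and metrics are computed inside the windows only.
    """
    if not eval_crops:
        preds = [model.predict_mask(img) for img, _ in test]
        truths = [msk for _, msk in test]
        ids = [img.id for img, _ in test]
        return evaluate_dataset(preds, truths, mode="micro", ids=ids)
    preds, truths, ids = [], [], []
    for img, msk in test:
        for crop in ccs_sample_pair(img, msk, crop_size=crop_size):
            prob = model.predict(crop.image)
            preds.append(SegmentationMask((prob >= 0.5).astype(np.uint8)))
            truths.append(SegmentationMask(crop.mask))
            ids.append(f"{img.id}:c{crop.component_index}")
    if not preds:
        raise PipelineError("no test crops: every test mask is empty")
    return evaluate_dataset(preds, truths, mode="micro", ids=ids)


def run_supervised_baseline(
    dataset: Sequence[LabelledPair],
    spec: SplitSpec = SplitSpec(),
    train_config: TrainConfig = TrainConfig(),
    model_factory: Callable[[int], FilterBankSegmenter] = default_backbone,
    n_train: Optional[int] = None,
    model_seed: Optional[int] = None,
) -> RunReport:
    """Fully supervised reference run on the same split geometry.

    Trains on the non-test labelled images (or only the first ``n_train``
    of them, e.g. the teacher subset) and evaluates on the held-out test
    set, so results are directly comparable with self-training runs that
    share the split seed.
    """
    split = split_dataset(dataset, spec)
    train_pairs = split.teacher + split.pool
    if n_train is not None:
        if n_train > len(train_pairs):
            raise PipelineError(f"n_train={n_train} exceeds {len(train_pairs)} available")
        train_pairs = train_pairs[:n_train]
    seed = spec.seed + 1 if model_seed is None else model_seed
    model = model_factory(seed)
    model, curves = train_segmentation_model(model, train_pairs, train_config)
    metrics = _evaluate_model(model, split.test)
    return RunReport(
        mode="supervised",
        seed=spec.seed,
        config={"split": asdict(spec), "train": asdict(train_config),
                "n_train": len(train_pairs)},
        manifests=split.manifests(),
        teacher_metrics=None,
        student_metrics=metrics,
        teacher_curves=None,
        student_curves=curves,
        n_student_examples=len(train_pairs),
    )


def run_self_training(
    dataset: Sequence[LabelledPair],
    spec: SplitSpec = SplitSpec(),
    mode: Literal["standard", "ccs"] = "ccs",
    crop_size: int = 32,
    aug_spec: AugmentationSpec = AugmentationSpec(),
    teacher_config: TrainConfig = TrainConfig(),
    student_config: Optional[TrainConfig] = None,
    model_factory: Callable[[int], FilterBankSegmenter] = default_backbone,
    include_real: bool = True,
    student_full_frames: bool = True,
    pseudo_threshold: float = 0.5,
    eval_crops: bool = False,
) -> RunReport:
    """One full teacher-student run; see the module docstring for the stages.

    ``standard`` mode trains both models on full frames. ``ccs`` mode
    trains the teacher on full frames plus their centroid crops, and the
    student on 5-way-augmented centroid crops of the pseudo pairs (plus
    the real labelled crops when ``include_real``). By default the
    student also sees the full frames behind those crops
    (``student_full_frames``): a pixel classifier trained on
    lesion-centred crops alone never observes most of the background
    distribution and misfires on it at full-frame inference.
    """
    if mode not in ("standard", "ccs"):
        raise ValueError(f"unknown mode {mode!r}")
    if student_config is None:
        student_config = teacher_config
    split = split_dataset(dataset, spec)
    test_ids = {img.id for img, _ in split.test}
    train_ids = {img.id for img, _ in split.teacher} | {img.id for img, _ in split.pool}
    assert not (test_ids & train_ids), "test images leaked into training pools"

    # --- teacher ---------------------------------------------------------
    teacher_pairs: list = list(split.teacher)
    if mode == "ccs":
        teacher_pairs = teacher_pairs + ccs_sample_dataset(split.teacher, crop_size)
    teacher = model_factory(spec.seed)
    teacher, teacher_curves = train_segmentation_model(
        teacher, teacher_pairs, teacher_config
    )

    # --- pseudo labels ---------------------------------------------------
    n_pseudo = len(split.pool) if spec.n_pseudo is None else spec.n_pseudo
    if n_pseudo > len(split.pool):
        raise PipelineError(
            f"requested {n_pseudo} pseudo images but the pool has {len(split.pool)}"
        )
    pool_used = split.pool[:n_pseudo]
    pseudo = generate_pseudo_labels(
        teacher, [img for img, _ in pool_used], threshold=pseudo_threshold
    )
    fidelity = (
        pseudo_label_fidelity(pseudo, [msk for _, msk in pool_used])
        if pool_used else None
    )
    n_empty = sum(p.is_empty for p in pseudo)
    if n_empty:
        logger.info("%d of %d pseudo masks are empty; CCS will skip them",
                    n_empty, len(pseudo))

    # --- student training set -------------------------------------------
    student_pairs: list = []
    if mode == "standard":
        student_pairs.extend((p.image, p.mask) for p in pseudo)
        if include_real:
            student_pairs.extend(split.teacher)
    else:
        pseudo_crops = ccs_sample_dataset(
            [(p.image, p.mask) for p in pseudo if not p.is_empty], crop_size
        )
        real_crops = ccs_sample_dataset(split.teacher, crop_size) if include_real else []
        if pseudo and not pseudo_crops and not real_crops:
            raise PipelineError(
                "every pseudo mask is empty and no real crops are included; "
                "check teacher quality before training a student"
            )
        student_pairs.extend(augment_dataset(pseudo_crops + real_crops, aug_spec))
        if student_full_frames:
            student_pairs.extend((p.image, p.mask) for p in pseudo if not p.is_empty)
            if include_real:
                student_pairs.extend(split.teacher)
    if not student_pairs:
        raise PipelineError("student training set is empty")

    student = model_factory(spec.seed + 1)
    student, student_curves = train_segmentation_model(
        student, student_pairs, student_config
    )

    # --- evaluation on real held-out labels ------------------------------
    teacher_metrics = _evaluate_model(teacher, split.test, eval_crops, crop_size)
    student_metrics = _evaluate_model(student, split.test, eval_crops, crop_size)

    return RunReport(
        mode=f"{mode}_self_training",
        seed=spec.seed,
        config={
            "split": asdict(spec),
            "teacher_train": asdict(teacher_config),
            "student_train": asdict(student_config),
            "crop_size": crop_size,
            "augmentation": asdict(aug_spec),
            "include_real": include_real,
            "student_full_frames": student_full_frames,
            "pseudo_threshold": pseudo_threshold,
            "eval_crops": eval_crops,
        },
        manifests=split.manifests(),
        teacher_metrics=teacher_metrics,
        student_metrics=student_metrics,
        teacher_curves=teacher_curves,
        student_curves=student_curves,
        pseudo_fidelity=fidelity,
        n_pseudo_used=len(pseudo),
        n_student_examples=len(student_pairs),
    )


def run_sweeps(
    dataset: Sequence[LabelledPair],
    labelled_counts: Sequence[int] = (20, 40, 60, 80, 120),
    pseudo_counts: Sequence[Optional[int]] = (None,),
    seeds: Sequence[int] = (0,),
    mode: Literal["standard", "ccs"] = "ccs",
    **run_kwargs,
) -> pd.DataFrame:
    """Grid of self-training runs over labelled/pseudo budgets and seeds.

    Every run with the same seed shares its test set (the split seed fixes
    the partition). Infeasible cells are skipped with a log entry. Returns
    one row per completed run with teacher/student summary metrics.
    """
    rows = []
    for n_labelled in labelled_counts:
        for n_pseudo in pseudo_counts:
            for seed in seeds:
                spec = SplitSpec(n_teacher_labelled=n_labelled, n_pseudo=n_pseudo,
                                 seed=seed)
                try:
                    report = run_self_training(dataset, spec, mode=mode, **run_kwargs)
                except PipelineError as exc:
                    logger.warning(
                        "skipping cell (labelled=%s, pseudo=%s, seed=%s): %s",
                        n_labelled, n_pseudo, seed, exc,
                    )
                    continue
                rows.append(
                    {
                        "n_labelled": n_labelled,
                        "n_pseudo": report.n_pseudo_used,
                        "seed": seed,
                        "mode": report.mode,
                        "teacher_miou": report.teacher_metrics.miou,
                        "teacher_fg_iou": report.teacher_metrics.fg_iou,
                        "student_miou": report.student_metrics.miou,
                        "student_fg_iou": report.student_metrics.fg_iou,
                        "student_mpa": report.student_metrics.mpa,
                        "student_dice": report.student_metrics.dice,
                        "pseudo_fidelity": report.pseudo_fidelity,
                    }
                )
    return pd.DataFrame(rows)
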