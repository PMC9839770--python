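"""Reduced-scale study: self-training variants compared on synthetic data.

The study conditions are a desk-scale analogue of a small bitewing
dataset: 120 synthetic 96x96 frames with ~8 px lesions, a 20-image teacher
set, 60 pseudo-labelled pool images and a ~12-image held-out test set.
For each of ``n_seeds`` replicate seeds it runs

* CCS-mode self-training (teacher on frames + centroid crops; student on
  5-way-augmented centroid crops of the pseudo pairs plus real crops),
* standard self-training (both models on full frames), and
* a supervised baseline trained only on the teacher subset,

all sharing the split (hence the test set) within a seed, and evaluated on
the held-out real labels only.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .pipeline import (
    RunReport,
    SplitSpec,
    TrainConfig,
    run_self_training,
    run_supervised_baseline,
)
from .synthetic import SyntheticConfig, generate_dataset

__all__ = ["study_config", "scaled_selftrain_study", "summarise_study"]


def study_config() -> SyntheticConfig:
    """Synthetic conditions of the reduced-scale study (96x96, ~8 px lesions)."""
    return SyntheticConfig(
        height=96, width=96, n_teeth=3, lesion_side_mean=8.0, lesion_side_sd=1.5
    )


def scaled_selftrain_study(
    seed: int = 0,
    n_seeds: int = 3,
    n_images: int = 120,
    n_teacher: int = 20,
    n_pseudo: int = 60,
) -> dict[str, list[RunReport]]:
    """Run the three-arm comparison over ``n_seeds`` replicate seeds.

    Replicate ``i`` uses seed ``seed + i`` for every stochastic component
    — the synthetic dataset realisation, the split and the optimisation —
    so the replicates probe the method rather than one fixed dataset.
    Returns the full reports per arm under keys ``"ccs"``, ``"standard"``
    and ``"baseline"``.
    """
    results: dict[str, list[RunReport]] = {"ccs": [], "standard": [], "baseline": []}
    for i in range(n_seeds):
        s = seed + i
        data = generate_dataset(n_images, study_config(), seed=s)
        spec = SplitSpec(n_teacher_labelled=n_teacher, n_pseudo=n_pseudo, seed=s)
        config = TrainConfig(seed=s)
        results["ccs"].append(
            run_self_training(data, spec, mode="ccs", teacher_config=config)
        )
        results["standard"].append(
            run_self_training(data, spec, mode="standard", teacher_config=config)
        )
        results["baseline"].append(
            run_supervised_baseline(data, spec, config, n_train=n_teacher)
        )
    return results


def summarise_study(results: dict[str, list[RunReport]]) -> dict[str, float]:
    """Seed-mean summary numbers of a study produced by the function above."""

    def mean(arm: str, getter) -> float:
        return float(np.mean([getter(r) for r in results[arm]]))

    return {
        "ccs_student_fg_iou": mean("ccs", lambda r: r.student_metrics.fg_iou),
        "ccs_student_miou": mean("ccs", lambda r: r.student_metrics.miou),
        "ccs_student_mpa": mean("ccs", lambda r: r.student_metrics.mpa),
        "ccs_student_dice": mean("ccs", lambda r: r.student_metrics.dice),
        "standard_student_fg_iou": mean("standard", lambda r: r.student_metrics.fg_iou),
        "standard_student_miou": mean("standard", lambda r: r.student_metrics.miou),
        "baseline_fg_iou": mean("baseline", lambda r: r.student_metrics.fg_iou),
        "baseline_miou": mean("baseline", lambda r: r.student_metrics.miou),
        "pseudo_fidelity": mean("ccs", lambda r: r.pseudo_fidelity),
    }
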