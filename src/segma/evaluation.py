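"""Evaluation harness: Dice overlap, leave-one-out cross-validation,
method comparison, parameter sweeps, and the drop-one-feature-group ablation.

Dice is reported as a percentage, DC(A, M) = 2|A∩M| / (|A| + |M|) × 100,
per non-background class; the mean over classes weights classes equally.
A class absent from both the automatic and reference segmentation yields an
undefined (0/0) Dice and is reported as missing, never as 0 or 100.

Every driver follows the same protocol: each subject in turn is the test
target, intensity standardization is fitted on the remaining pool, k
atlases are picked from the pool by the sparsity-based selection, and the
segmentation is scored against the held-out ground truth.  Splits and seeds
are shared across methods and ablation rows so comparisons are paired.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .atlas_selection import EmbeddingConfig, embed_pool, select_atlases
from .baselines import GlobalRFConfig, global_rf_segment, majority_vote
from .features import FEATURE_GROUPS, FEATURE_NAMES
from .segmentation import ForestParams, derive_seed, segment
from .standardize import (DEFAULT_PERCENTILES, apply_standardization,
                          fit_standard_scale)
from .volumes import AtlasSet, LabelVolume, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "DiceReport",
    "dice",
    "dice_report",
    "mean_dice",
    "loocv",
    "compare_methods",
    "ablate_features",
    "sweep_training_size",
    "sweep_trees",
]


@dataclass
class PipelineConfig:
    """End-to-end settings for one evaluation run."""

    k: int = 5
    w_side: int = 5
    forest: ForestParams = field(default_factory=ForestParams)
    percentiles: tuple = DEFAULT_PERCENTILES
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    feature_indices: Optional[tuple] = None
    stride: Optional[int] = None
    samples_per_atlas: int = 100_000
    seed: int = 0

    def subject_forest(self, subject_index: int) -> ForestParams:
        """Forest params with the per-fold seed for one held-out subject."""
        return replace(self.forest, seed=derive_seed(self.seed, subject_index))


def dice(A: LabelVolume, M: LabelVolume, label: int) -> float:
    """Dice overlap of one class between two label maps, in percent.

    Returns NaN (with a warning) when the class is absent from both maps —
    the 0/0 case is undefined, not perfect and not zero.
    """
    if tuple(A.shape) != tuple(M.shape):
        raise ValidationError("label maps must share one grid")
    a = A.data == label
    m = M.data == label
    na, nm = int(a.sum()), int(m.sum())
    if na == 0 and nm == 0:
        logger.warning("label %d absent from both maps; Dice undefined", label)
        return float("nan")
    return 2.0 * int((a & m).sum()) / (na + nm) * 100.0


@dataclass
class DiceReport:
    """Per-class Dice for one subject, with the underlying voxel counts."""

    subject: object
    per_class: Dict[int, float]
    counts: Dict[int, tuple]  # label -> (|A|, |M|, |A∩M|)

    @property
    def mean_dice(self) -> float:
        vals = [v for v in self.per_class.values() if not np.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")

    def rows(self) -> List[dict]:
        return [
            {"subject": self.subject, "label": lab, "dice": d,
             "n_auto": self.counts[lab][0], "n_ref": self.counts[lab][1],
             "n_overlap": self.counts[lab][2]}
            for lab, d in self.per_class.items()
        ]


def dice_report(pred: LabelVolume, truth: LabelVolume, subject=None,
                labels: Optional[Sequence[int]] = None) -> DiceReport:
    """Score a prediction against ground truth over non-background classes."""
    if labels is None:
        labels = sorted(set(pred.vocabulary) | set(truth.vocabulary))
    per_class, counts = {}, {}
    for lab in labels:
        a = pred.data == lab
        m = truth.data == lab
        counts[lab] = (int(a.sum()), int(m.sum()), int((a & m).sum()))
        na, nm, ni = counts[lab]
        per_class[lab] = float("nan") if (na == 0 and nm == 0) \
            else 2.0 * ni / (na + nm) * 100.0
    return DiceReport(subject=subject, per_class=per_class, counts=counts)


def mean_dice(table: pd.DataFrame) -> float:
    """Mean Dice over subjects of the per-subject class-mean."""
    return float(table.groupby("subject")["dice"].mean().mean())


def _prepare_fold(population: AtlasSet, test_index: int, config: PipelineConfig):
    """Standardize, select k atlases from the pool, return fold inputs."""
    pool_idx = [i for i in range(len(population)) if i != test_index]
    pool = population.subset(pool_idx)
    model = fit_standard_scale(pool.images, pool.masks, config.percentiles)
    pool_std = AtlasSet(
        images=[apply_standardization(img, m, model) for img, _, m in pool],
        labels=list(pool.labels),
        masks=list(pool.masks),
    )
    target_std = apply_standardization(
        population.images[test_index], population.masks[test_index], model
    )
    coords = embed_pool(pool_std.images, pool_std.masks, config.embedding)
    sel = select_atlases(coords, config.k)
    return target_std, population.masks[test_index], pool_std.subset(sel.indices)


def _check_k(population: AtlasSet, k: int) -> None:
    if k >= len(population):
        raise ValidationError(
            f"k={k} requires a population larger than k (got {len(population)})"
        )
    if k < 1:
        raise ValidationError("k must be >= 1")


def loocv(population: AtlasSet, k: Optional[int] = None,
          config: PipelineConfig = None) -> pd.DataFrame:
    """Leave-one-out cross-validation of the window-local method.

    Returns a tidy table with one row per (subject, class): columns
    ``subject``, ``label``, ``dice`` and the voxel counts behind them.
    """
    config = config or PipelineConfig()
    if k is not None:
        config = replace(config, k=k)
    _check_k(population, config.k)
    rows = []
    for t in range(len(population)):
        target_std, target_mask, selected = _prepare_fold(population, t, config)
        result = segment(target_std, target_mask, selected,
                         w_side=config.w_side,
                         params=config.subject_forest(t),
                         feature_indices=config.feature_indices,
                         stride=config.stride)
        rep = dice_report(result.labels, population.labels[t], subject=t)
        rows.extend(rep.rows())
    return pd.DataFrame(rows)


METHODS = ("segma", "majority_vote", "global_rf_full", "global_rf_intensity")


def compare_methods(population: AtlasSet, config: PipelineConfig = None,
                    methods: Sequence[str] = METHODS) -> pd.DataFrame:
    """Run several methods over identical LOOCV folds, atlases and seeds.

    Returns a tidy table with one row per (method, subject, class).  The
    paired per-subject summary can be derived by grouping on
    ``["method", "subject"]``.
    """
    config = config or PipelineConfig()
    _check_k(population, config.k)
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValidationError(f"unknown methods: {sorted(unknown)}")
    rows = []
    for t in range(len(population)):
        target_std, target_mask, selected = _prepare_fold(population, t, config)
        fold_forest = config.subject_forest(t)
        for method in methods:
            if method == "segma":
                pred = segment(target_std, target_mask, selected,
                               w_side=config.w_side, params=fold_forest,
                               feature_indices=config.feature_indices,
                               stride=config.stride).labels
            elif method == "majority_vote":
                pred = majority_vote(list(selected.labels))
            else:
                feats = "full" if method == "global_rf_full" else "intensity"
                grf = GlobalRFConfig(samples_per_atlas=config.samples_per_atlas,
                                     feature_set=feats, forest=fold_forest)
                pred = global_rf_segment(target_std, target_mask, selected, grf)
            rep = dice_report(pred, population.labels[t], subject=t)
            for row in rep.rows():
                row["method"] = method
                rows.append(row)
    return pd.DataFrame(rows)


def method_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-method mean Dice with per-subject support and paired differences
    against the first method in the table."""
    per_subject = table.groupby(["method", "subject"])["dice"].mean().reset_index()
    summary = per_subject.groupby("method")["dice"].agg(["mean", "std", "count"])
    summary = summary.rename(columns={"mean": "mean_dice", "std": "sd", "count": "n_subjects"})
    ref = table["method"].iloc[0]
    ref_vals = per_subject[per_subject["method"] == ref].set_index("subject")["dice"]
    diffs = {}
    for m in summary.index:
        vals = per_subject[per_subject["method"] == m].set_index("subject")["dice"]
        d = (ref_vals - vals).dropna()
        diffs[m] = {"mean_diff_vs_" + ref: float(d.mean()),
                    "n_subjects_better": int((d > 0).sum()),
                    "n_subjects_worse": int((d < 0).sum())}
    return summary.join(pd.DataFrame(diffs).T)


def ablate_features(population: AtlasSet, config: PipelineConfig = None,
                    groups: Dict[str, tuple] = None,
                    baseline: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Drop-one-feature-group ablation over identical LOOCV folds.

    Returns one row per configuration: the all-features baseline plus one
    run per dropped group, each with the resulting feature count and mean
    Dice.  ``baseline`` may supply a precomputed all-features LOOCV table
    (same population/config) to avoid recomputing it.
    """
    config = config or PipelineConfig()
    groups = groups or FEATURE_GROUPS
    covered = sorted(i for idx in groups.values() for i in idx)
    if covered != list(range(len(FEATURE_NAMES))):
        raise ValidationError("feature groups must partition the ten features")
    records = []
    base_table = baseline if baseline is not None else loocv(population, config=config)
    records.append({"dropped": "none", "n_features": len(FEATURE_NAMES),
                    "mean_dice": mean_dice(base_table)})
    for name, idx in groups.items():
        keep = tuple(i for i in range(len(FEATURE_NAMES)) if i not in idx)
        table = loocv(population, config=replace(config, feature_indices=keep))
        records.append({"dropped": name, "n_features": len(keep),
                        "mean_dice": mean_dice(table)})
    return pd.DataFrame(records)


def sweep_training_size(population: AtlasSet, ks: Sequence[int],
                        config: PipelineConfig = None) -> pd.DataFrame:
    """Mean LOOCV Dice as a function of the number of selected atlases k."""
    config = config or PipelineConfig()
    records = []
    for k in ks:
        table = loocv(population, k=k, config=config)
        records.append({"k": int(k), "mean_dice": mean_dice(table)})
    return pd.DataFrame(records)


def sweep_trees(population: AtlasSet, tree_counts: Sequence[int],
                config: PipelineConfig = None) -> pd.DataFrame:
    """Mean LOOCV Dice as a function of forest size."""
    config = config or PipelineConfig()
    records = []
    for n in tree_counts:
        cfg = replace(config, forest=replace(config.forest, n_trees=int(n)))
        table = loocv(population, config=cfg)
        records.append({"n_trees": int(n), "mean_dice": mean_dice(table)})
    return pd.DataFrame(records)
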