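"""Evaluation protocols: repeated k-fold CV, independent test, whole proteins.

Cross-validation re-randomizes the fold assignment on every repeat (seed +
repeat index), trains the full PSDP/norm pipeline on k-1 folds, predicts the
held-out fold, pools the k folds' predictions into one confusion table per
repeat, and averages the metric values across repeats.  Folds are stratified
by class by default so each fold keeps the global class ratio within one
sample.

The independent test guards against train/test leakage by exact window
identity; whole-protein evaluation scores every cysteine of every protein,
treating unannotated cysteines as true non-SNO sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .classifier import TrainedModel, decide_codes, fit
from .errors import ConfigError, InfeasibleFoldError, LeakageError
from .metrics import ConfusionCounts, MetricsReport, compute_metrics, confusion
from .windows import (
    DEFAULT_CONFIG,
    NON_SNO,
    SNO,
    PeptideWindow,
    ProteinRecord,
    SiteAnnotation,
    WindowConfig,
    enumerate_cysteine_windows,
    windows_to_codes,
)

_METRIC_KEYS = ("sn", "sp", "acc", "mcc")


@dataclass(frozen=True)
class CVConfig:
    """Repeated k-fold cross-validation settings."""

    k: int = 10
    repeats: int = 50
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ConfigError(f"k must be >= 2, got {self.k}")
        if self.repeats < 1:
            raise ConfigError(f"repeats must be >= 1, got {self.repeats}")


@dataclass
class CVResult:
    """Mean metrics over repeats, the per-repeat reports, and dispersions."""

    mean: dict  # metric name -> mean over repeats (None if undefined)
    dispersion: dict  # metric name -> sample std over repeats
    per_repeat: list[MetricsReport]
    config: CVConfig
    repeat_seeds: list[int]

    def to_dict(self) -> dict:
        return {
            "k": self.config.k,
            "repeats": self.config.repeats,
            "seed": self.config.seed,
            "stratified": self.config.stratified,
            "repeat_seeds": self.repeat_seeds,
            "mean": self.mean,
            "dispersion": self.dispersion,
            "per_repeat": [r.to_dict() for r in self.per_repeat],
        }

    def summary_tsv(self) -> str:
        """One line per metric: mean and standard deviation across repeats."""
        lines = ["metric\tmean\tsd"]
        for k in _METRIC_KEYS:
            m, s = self.mean[k], self.dispersion[k]
            fmt = lambda v: "NA" if v is None else repr(float(v))
            lines.append(f"{k}\t{fmt(m)}\t{fmt(s)}")
        return "\n".join(lines) + "\n"


def _fold_assignment(
    n_pos: int, n_neg: int, k: int, stratified: bool, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Fold id per positive and per negative sample."""
    if stratified:
        fp = np.arange(n_pos) % k
        fn_ = np.arange(n_neg) % k
        rng.shuffle(fp)
        rng.shuffle(fn_)
        return fp, fn_
    both = np.arange(n_pos + n_neg) % k
    rng.shuffle(both)
    return both[:n_pos], both[n_pos:]


def kfold_cv(
    positives: Sequence[PeptideWindow],
    negatives: Sequence[PeptideWindow],
    config: CVConfig = CVConfig(),
    window_config: WindowConfig = DEFAULT_CONFIG,
    rule: str = "nearest",
) -> CVResult:
    """Repeated stratified k-fold cross-validation of the full pipeline.

    Each held-out fold is predicted by a model trained from scratch on the
    other k-1 folds; the k folds of one repeat pool into a single confusion
    table.  Per-repeat seeds are ``config.seed + repeat`` and are recorded in
    the result.
    """
    if len(positives) < config.k or len(negatives) < config.k:
        raise InfeasibleFoldError(
            f"each class needs >= k={config.k} members "
            f"(got {len(positives)} positive, {len(negatives)} negative)"
        )
    pos_codes = windows_to_codes(positives)
    neg_codes = windows_to_codes(negatives)
    per_repeat: list[MetricsReport] = []
    repeat_seeds = [config.seed + r for r in range(config.repeats)]
    for rep_seed in repeat_seeds:
        rng = np.random.default_rng(rep_seed)
        fold_pos, fold_neg = _fold_assignment(
            len(positives), len(negatives), config.k, config.stratified, rng
        )
        counts = ConfusionCounts()
        for fold in range(config.k):
            train_p = pos_codes[fold_pos != fold]
            train_n = neg_codes[fold_neg != fold]
            test_p = pos_codes[fold_pos == fold]
            test_n = neg_codes[fold_neg == fold]
            model = fit(train_p, train_n, config=window_config, rule=rule)
            if len(test_p):
                _, _, is_sno, _ = decide_codes(model, test_p, rng)
                tp = int(is_sno.sum())
                counts = counts + ConfusionCounts(tp=tp, fn=len(test_p) - tp)
            if len(test_n):
                _, _, is_sno, _ = decide_codes(model, test_n, rng)
                fp = int(is_sno.sum())
                counts = counts + ConfusionCounts(fp=fp, tn=len(test_n) - fp)
        per_repeat.append(compute_metrics(counts))
    mean: dict = {}
    dispersion: dict = {}
    for key in _METRIC_KEYS:
        vals = [getattr(r, key) for r in per_repeat]
        if any(v is None for v in vals):
            mean[key] = None
            dispersion[key] = None
        else:
            arr = np.asarray(vals, dtype=float)
            mean[key] = float(arr.mean())
            dispersion[key] = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return CVResult(
        mean=mean,
        dispersion=dispersion,
        per_repeat=per_repeat,
        config=config,
        repeat_seeds=repeat_seeds,
    )


def assert_disjoint(
    train: Sequence[PeptideWindow], test: Sequence[PeptideWindow]
) -> None:
    """Raise :class:`LeakageError` if any test window occurs verbatim in training."""
    seen = {w.residues for w in train}
    overlap = sorted({w.residues for w in test} & seen)
    if overlap:
        raise LeakageError(
            f"{len(overlap)} test window(s) occur in the training set, "
            f"e.g. {overlap[0]!r}"
        )


def independent_test(
    model: TrainedModel,
    positives: Sequence[PeptideWindow],
    negatives: Sequence[PeptideWindow],
    seed: int = 0,
    train_windows: Sequence[PeptideWindow] | None = None,
) -> MetricsReport:
    """Score a trained model on held-out windows.

    If ``train_windows`` is given, exact 21-mer disjointness from the test set
    is verified first (memory-bias guard).
    """
    if train_windows is not None:
        assert_disjoint(train_windows, list(positives) + list(negatives))
    rng = np.random.default_rng(seed)
    counts = ConfusionCounts()
    if len(positives):
        _, _, is_sno, _ = decide_codes(model, windows_to_codes(positives), rng)
        tp = int(is_sno.sum())
        counts = counts + ConfusionCounts(tp=tp, fn=len(positives) - tp)
    if len(negatives):
        _, _, is_sno, _ = decide_codes(model, windows_to_codes(negatives), rng)
        fp = int(is_sno.sum())
        counts = counts + ConfusionCounts(fp=fp, tn=len(negatives) - fp)
    return compute_metrics(counts)


def evaluate_proteins(
    model: TrainedModel,
    proteins: Sequence[ProteinRecord],
    annotations: Sequence[SiteAnnotation],
    seed: int = 0,
) -> MetricsReport:
    """Whole-protein evaluation: predict every cysteine, pool one confusion table.

    Truth comes from the annotations; any cysteine without a SNO annotation
    counts as a true non-SNO site.
    """
    truth: list[str] = []
    predicted: list[str] = []
    rng = np.random.default_rng(seed)
    for protein in proteins:
        labeled = enumerate_cysteine_windows(protein, annotations, model.config)
        if not labeled:
            continue
        codes = windows_to_codes(labeled)
        _, _, is_sno, _ = decide_codes(model, codes, rng)
        truth.extend(w.label for w in labeled)
        predicted.extend(SNO if s else NON_SNO for s in is_sno)
    return compute_metrics(confusion(truth, predicted))
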