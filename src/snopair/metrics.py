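"""Confusion counting and the four-metric evaluation suite.

Sensitivity, specificity, overall accuracy and the Matthews correlation
coefficient, computable in two equivalent forms: the conventional
TP/TN/FP/FN ratios, and the intuitive form written in terms of the number
of positives missed (N+_ = FN) and negatives over-called (N-+ = FP) out of
the class totals N+ and N-.  Both are implemented and agree to floating
tolerance; the TP/TN form is the reference.

Degenerate cases follow common conventions the ratio formulas leave open:
MCC with an empty marginal is reported as 0.0 with a flag, and Sn (Sp) is
reported as missing — not 0 — when no positives (negatives) were evaluated.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

from .errors import ConfigError, UndefinedMetricsError
from .windows import LABELS, NON_SNO, SNO


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN with SNO as the positive class."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ConfigError("confusion counts must be nonnegative")

    # missed/over-called parameterization
    @property
    def n_pos(self) -> int:
        """N+: total positives evaluated."""
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        """N-: total negatives evaluated."""
        return self.tn + self.fp

    @property
    def n_pos_missed(self) -> int:
        """N+_: positives predicted negative (= FN)."""
        return self.fn

    @property
    def n_neg_overcalled(self) -> int:
        """N-+: negatives predicted positive (= FP)."""
        return self.fp

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            tp=self.tp + other.tp,
            tn=self.tn + other.tn,
            fp=self.fp + other.fp,
            fn=self.fn + other.fn,
        )


@dataclass
class MetricsReport:
    """Sn/Sp/Acc in [0,1], MCC in [-1,1], plus the underlying counts.

    ``sn``/``sp`` are None when their class total is zero;
    ``mcc_degenerate`` marks an MCC reported as 0.0 because a marginal was
    empty.
    """

    sn: float | None
    sp: float | None
    acc: float
    mcc: float
    counts: ConfusionCounts
    mcc_degenerate: bool = False

    def to_dict(self) -> dict:
        c = self.counts
        return {
            "sn": self.sn,
            "sp": self.sp,
            "acc": self.acc,
            "mcc": self.mcc,
            "mcc_degenerate": self.mcc_degenerate,
            "tp": c.tp,
            "tn": c.tn,
            "fp": c.fp,
            "fn": c.fn,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_tsv(self) -> str:
        d = self.to_dict()
        keys = ["sn", "sp", "acc", "mcc", "tp", "tn", "fp", "fn"]
        fmt = lambda v: "NA" if v is None else (repr(v) if isinstance(v, float) else str(v))
        return (
            "\t".join(keys) + "\n" + "\t".join(fmt(d[k]) for k in keys) + "\n"
        )


def confusion(truth: Sequence[str], predicted: Sequence[str]) -> ConfusionCounts:
    """Tally a confusion table from parallel label lists (SNO = positive)."""
    if len(truth) != len(predicted):
        raise ConfigError(
            f"length mismatch: {len(truth)} truth vs {len(predicted)} predicted labels"
        )
    tp = tn = fp = fn = 0
    for t, p in zip(truth, predicted):
        if t not in LABELS or p not in LABELS:
            bad = t if t not in LABELS else p
            raise ConfigError(f"unknown label {bad!r}: expected one of {LABELS}")
        if t == SNO:
            if p == SNO:
                tp += 1
            else:
                fn += 1
        else:
            if p == SNO:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Sn, Sp, Acc and MCC from a confusion table (conventional ratio form)."""
    if counts.total == 0:
        raise UndefinedMetricsError("metrics are undefined on an empty confusion table")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    sn = tp / (tp + fn) if (tp + fn) else None
    sp = tn / (tn + fp) if (tn + fp) else None
    acc = (tp + tn) / counts.total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    degenerate = denom == 0
    mcc = 0.0 if degenerate else (tp * tn - fp * fn) / math.sqrt(denom)
    return MetricsReport(
        sn=sn, sp=sp, acc=acc, mcc=mcc, counts=counts, mcc_degenerate=degenerate
    )


def intuitive_metrics(counts: ConfusionCounts) -> MetricsReport:
    """The same four metrics in the intuitive missed/over-called form.

    Sn = 1 - N+_/N+, Sp = 1 - N-+/N-, Acc = 1 - (N+_ + N-+)/(N+ + N-), and
    MCC = (1 - (N+_/N+ + N-+/N-)) / sqrt((1 + (N-+ - N+_)/N+)(1 + (N+_ - N-+)/N-)).
    Equivalent to :func:`compute_metrics`; kept as an independent formulation
    for cross-checking.
    """
    if counts.total == 0:
        raise UndefinedMetricsError("metrics are undefined on an empty confusion table")
    npos, nneg = counts.n_pos, counts.n_neg
    miss, over = counts.n_pos_missed, counts.n_neg_overcalled
    sn = 1 - miss / npos if npos else None
    sp = 1 - over / nneg if nneg else None
    acc = 1 - (miss + over) / (npos + nneg)
    degenerate = npos == 0 or nneg == 0
    if not degenerate:
        f1 = 1 + (over - miss) / npos
        f2 = 1 + (miss - over) / nneg
        degenerate = f1 <= 0 or f2 <= 0 or (f1 * f2) == 0
    if degenerate:
        # f1 or f2 hits 0 exactly when a *predicted* marginal is empty
        mcc = 0.0
    else:
        mcc = (1 - (miss / npos + over / nneg)) / math.sqrt(f1 * f2)
    return MetricsReport(
        sn=sn, sp=sp, acc=acc, mcc=mcc, counts=counts, mcc_degenerate=degenerate
    )
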