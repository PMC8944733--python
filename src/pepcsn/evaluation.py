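"""Classifier evaluation: confusion-matrix statistics and Friedman ranking.

Eight statistics summarize a binary confusion matrix: accuracy, Cohen's
kappa, sensitivity, specificity, positive and negative precision, the
Matthews correlation coefficient, and the false accept rate (FAR%).
Competing models evaluated on common blocks (dataset × metric cells) are
compared with the Friedman rank test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion matrix must count at least one case")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """The eight confusion-matrix statistics.

    Ratios with zero denominators are reported as None ("NA"); an MCC with
    a zero denominator is 0 by the standard convention. ``po`` equals
    accuracy and ``pc`` is the chance agreement used by kappa.
    """

    ac: float
    po: float
    pc: float
    kappa: float
    sn: float | None
    sp: float | None
    p_pos: float | None
    p_neg: float | None
    mcc: float
    far_percent: float | None

    def rounded(self) -> dict:
        """Display rounding: 3 decimals for proportions, 2 for percentages."""
        def r3(x):
            return None if x is None else round(x, 3)

        return {
            "ac": r3(self.ac),
            "kappa": r3(self.kappa),
            "sn": r3(self.sn),
            "sp": r3(self.sp),
            "p_pos": r3(self.p_pos),
            "p_neg": r3(self.p_neg),
            "mcc": r3(self.mcc),
            "far_percent": None
            if self.far_percent is None
            else round(self.far_percent, 2),
        }


def confusion(
    predicted: list[str], true: list[str], positive_label: str = "positive"
) -> ConfusionMatrix:
    """Count TP/TN/FP/FN from parallel predicted and true label lists."""
    if len(predicted) != len(true):
        raise ValueError("label lists differ in length")
    tp = tn = fp = fn = 0
    for p, t in zip(predicted, true):
        if t == positive_label:
            if p == positive_label:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive_label:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(tp, tn, fp, fn)


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Compute the eight statistics from a confusion matrix."""
    tp, tn, fp, fn = cm.tp, cm.tn, cm.fp, cm.fn
    total = cm.total
    ac = (tp + tn) / total
    po = ac
    pc = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / total**2
    kappa = 0.0 if pc == 1.0 else (po - pc) / (1 - pc)
    mcc_den = math.sqrt(
        float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    mcc = 0.0 if mcc_den == 0 else (tp * tn - fp * fn) / mcc_den
    far = _ratio(fp, fp + tn)
    return MetricsReport(
        ac=ac,
        po=po,
        pc=pc,
        kappa=kappa,
        sn=_ratio(tp, tp + fn),
        sp=_ratio(tn, tn + fp),
        p_pos=_ratio(tp, tp + fp),
        p_neg=_ratio(tn, tn + fn),
        mcc=mcc,
        far_percent=None if far is None else 100.0 * far,
    )


@dataclass(frozen=True)
class FriedmanResult:
    average_ranks: dict[str, float]
    rank_sums: dict[str, float]
    chi_square: float
    df: int
    p_value: float


def friedman_rank(
    performance: pd.DataFrame, higher_is_better: bool = True
) -> FriedmanResult:
    """Friedman rank test over a blocks × methods performance table.

    Rows are blocks (e.g. dataset/metric combinations), columns are
    methods. Within each block methods receive ranks 1..k (average ranks on
    ties; rank 1 is best). χ² = 12/(n·k·(k+1))·Σ R_j² − 3·n·(k+1), compared
    to a chi-square distribution with k−1 degrees of freedom.
    """
    if performance.isna().any().any():
        raise ValueError("performance table contains missing cells")
    n, k = performance.shape
    if k < 2 or n < 2:
        raise ValueError("need at least 2 methods and 2 blocks")
    vals = performance.to_numpy(float)
    ranked = np.vstack(
        [stats.rankdata(-row if higher_is_better else row) for row in vals]
    )
    rank_sums = ranked.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * float((rank_sums**2).sum()) - 3.0 * n * (k + 1)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    methods = list(performance.columns)
    return FriedmanResult(
        average_ranks=dict(zip(methods, (rank_sums / n).tolist())),
        rank_sums=dict(zip(methods, rank_sums.tolist())),
        chi_square=chi2,
        df=df,
        p_value=p,
    )
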