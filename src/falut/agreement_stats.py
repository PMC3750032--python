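"""Validation statistics: scheme agreement and screening performance.

Two sets of summaries validate a normative LUT. First, agreement between FA
measured with 12 and 30 diffusion-encoding directions is assessed in the
Bland-Altman framework: the mean paired difference with a 95% prediction
interval mean +/- z * sd(d), plus the Pearson correlation of the paired
values. Second, rater screening of MSA (multiple system atrophy) versus
non-MSA subjects is summarised as sensitivity/specificity with MSA as the
positive class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PairedMeasurements",
    "AgreementResult",
    "ConfusionResult",
    "bland_altman",
    "screening_confusion",
    "rater_summary",
]


class ConstantInputError(ValueError):
    """Correlation is undefined because one side of the pairs is constant."""


@dataclass(frozen=True)
class PairedMeasurements:
    """Complete FA pairs for one ROI group: 12-direction vs 30-direction."""

    fa_12: tuple[float, ...]
    fa_30: tuple[float, ...]
    roi_group: str = "custom"

    def __post_init__(self) -> None:
        if len(self.fa_12) != len(self.fa_30):
            raise ValueError(
                f"incomplete pairs: {len(self.fa_12)} vs {len(self.fa_30)} values"
            )

    def __len__(self) -> int:
        return len(self.fa_12)


@dataclass(frozen=True)
class AgreementResult:
    """Bland-Altman summary of paired differences (fa_12 - fa_30)."""

    mean_diff: float
    pi_diff_low: float
    pi_diff_high: float
    pearson_r: float
    r_pvalue: float
    n_pairs: int


@dataclass(frozen=True)
class ConfusionResult:
    """2x2 screening confusion summary; MSA is the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    @property
    def sensitivity_reported(self) -> int:
        return round_half_up(self.sensitivity)

    @property
    def specificity_reported(self) -> int:
        return round_half_up(self.specificity)


def round_half_up(x: float) -> int:
    """Round to the nearest integer with halves going up (0.5 -> 1)."""
    return int(math.floor(x + 0.5))


def bland_altman(pairs: PairedMeasurements, level: float = 0.95) -> AgreementResult:
    """Bland-Altman agreement of the paired FA measurements.

    Differences d = fa_12 - fa_30; the interval is mean(d) +/- z * sd(d)
    with the sample SD (denominator n - 1). Pearson correlation between the
    two sides is reported with its two-sided p-value. Raises
    :class:`ConstantInputError` when either side is constant (correlation
    undefined) rather than fabricating a value.
    """
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 pairs, got {len(pairs)}")
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must be in (0, 1), got {level}")
    a = np.asarray(pairs.fa_12, dtype=float)
    b = np.asarray(pairs.fa_30, dtype=float)
    d = a - b
    mean_diff = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    z = float(stats.norm.ppf((1.0 + level) / 2.0))
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        raise ConstantInputError(
            f"constant measurements on one side (group {pairs.roi_group!r}); "
            "Pearson correlation is undefined"
        )
    r, p = stats.pearsonr(a, b)
    return AgreementResult(
        mean_diff=mean_diff,
        pi_diff_low=mean_diff - z * sd,
        pi_diff_high=mean_diff + z * sd,
        pearson_r=float(r),
        r_pvalue=float(p),
        n_pairs=len(pairs),
    )


def screening_confusion(
    truth: Mapping[str, str], calls: Mapping[str, str], positive: str = "MSA"
) -> ConfusionResult:
    """Tally one rater's MSA/non-MSA calls against ground truth.

    Exact rational sensitivity/specificity are kept on the result; the
    ``*_reported`` properties round half-up to integer percent.
    """
    unknown = set(calls) - set(truth)
    if unknown:
        raise KeyError(f"call(s) for subject(s) missing from truth: {sorted(unknown)}")
    missing = set(truth) - set(calls)
    if missing:
        raise KeyError(f"no call for subject(s): {sorted(missing)}")
    tp = fp = tn = fn = 0
    for subj, t in truth.items():
        c = calls[subj]
        if t == positive:
            tp, fn = (tp + 1, fn) if c == positive else (tp, fn + 1)
        else:
            tn, fp = (tn + 1, fp) if c != positive else (tn, fp + 1)
    return ConfusionResult(tp=tp, fp=fp, tn=tn, fn=fn)


def rater_summary(
    results: Sequence[ConfusionResult] | Sequence[tuple[float, float]],
) -> tuple[int, int]:
    """Average per-rater sensitivity/specificity, reported as integers.

    Accepts either confusion results or (sensitivity, specificity) percentage
    pairs as printed per rater; the mean of printed-precision per-rater values
    is rounded half-up (e.g. (77+100+76+65)/4 = 79.5 reports as 80).
    """
    if not results:
        raise ValueError("need at least one rater result")
    sens: list[float] = []
    spec: list[float] = []
    for res in results:
        if isinstance(res, ConfusionResult):
            sens.append(float(res.sensitivity_reported))
            spec.append(float(res.specificity_reported))
        else:
            s, p = res
            sens.append(float(s))
            spec.append(float(p))
    return round_half_up(float(np.mean(sens))), round_half_up(float(np.mean(spec)))
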