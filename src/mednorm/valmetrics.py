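"""Diagnostic-accuracy mathematics for expert validation of a matcher.

A matcher's decisions (match found / no match) judged against an expert
consensus reference form a 2x2 confusion matrix; this module computes
the standard derived statistics — precision, recall (sensitivity),
specificity, balanced accuracy, Matthews correlation coefficient —
with Wilson score 95% intervals for the three proportions, plus
Cohen's kappa for inter-rater agreement.

It also provides the inverse problem: given a validation design
(total pairs, predicted-positive and predicted-negative counts) and the
*rounded* published point estimates, exhaustively enumerate all integer
confusion matrices consistent with them.  When the solution is unique,
the full matrix — and hence every derived statistic and interval — is
recovered exactly from four printed decimals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from scipy.stats import norm as _norm

__all__ = [
    "ConfusionMatrix",
    "ValidationMetrics",
    "metrics",
    "wilson_interval",
    "cohen_kappa",
    "recover_matrix",
    "RecoveryError",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 4) -> float:
    """Decimal half-up rounding (0.00005 -> 0.0001), unlike banker's."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix cells must be non-negative")

    @property
    def n_total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def predicted_positive(self) -> int:
        return self.tp + self.fp

    @property
    def predicted_negative(self) -> int:
        return self.fn + self.tn


@dataclass(frozen=True)
class ValidationMetrics:
    precision: float | None
    recall: float | None
    specificity: float | None
    balanced_accuracy: float | None
    mcc: float | None
    precision_ci: tuple[float, float] | None
    recall_ci: tuple[float, float] | None
    specificity_ci: tuple[float, float] | None


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


_Z_CACHE: dict[float, float] = {}


def _z_value(confidence: float) -> float:
    if confidence not in _Z_CACHE:
        _Z_CACHE[confidence] = float(_norm.ppf(0.5 + confidence / 2.0))
    return _Z_CACHE[confidence]


def wilson_interval(
    successes: int, n: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    Inverts the score test: center (p + z^2/2n) / (1 + z^2/n) with the
    usual half-width.  Well-behaved at the 0 and 1 boundaries, unlike
    the Wald interval.  Raises ``ValueError`` for n = 0 or an
    out-of-range success count.
    """
    if n <= 0:
        raise ValueError("wilson interval undefined for n = 0")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    z = _z_value(confidence)
    p = successes / n
    z2n = z * z / n
    center = (p + z2n / 2.0) / (1.0 + z2n)
    half = (z / (1.0 + z2n)) * math.sqrt(p * (1.0 - p) / n + z2n / (4.0 * n))
    # exact boundaries: p=0 (p=1) pins the lower (upper) limit
    low = 0.0 if successes == 0 else max(0.0, center - half)
    high = 1.0 if successes == n else min(1.0, center + half)
    return low, high


def metrics(cm: ConfusionMatrix, confidence: float = 0.95) -> ValidationMetrics:
    """All derived accuracy statistics; a zero denominator yields
    ``None`` for the affected metric rather than an error."""
    precision = _ratio(cm.tp, cm.tp + cm.fp)
    recall = _ratio(cm.tp, cm.tp + cm.fn)
    specificity = _ratio(cm.tn, cm.tn + cm.fp)
    balanced = (
        (recall + specificity) / 2.0
        if recall is not None and specificity is not None
        else None
    )
    denom = (
        (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    mcc = (
        (cm.tp * cm.tn - cm.fp * cm.fn) / math.sqrt(denom)
        if denom > 0
        else None
    )
    return ValidationMetrics(
        precision=precision,
        recall=recall,
        specificity=specificity,
        balanced_accuracy=balanced,
        mcc=mcc,
        precision_ci=(
            wilson_interval(cm.tp, cm.tp + cm.fp, confidence)
            if cm.tp + cm.fp > 0
            else None
        ),
        recall_ci=(
            wilson_interval(cm.tp, cm.tp + cm.fn, confidence)
            if cm.tp + cm.fn > 0
            else None
        ),
        specificity_ci=(
            wilson_interval(cm.tn, cm.tn + cm.fp, confidence)
            if cm.tn + cm.fp > 0
            else None
        ),
    )


def cohen_kappa(table: tuple[tuple[int, int], tuple[int, int]]) -> float | None:
    """Cohen's kappa for a 2x2 inter-rater agreement table
    ((both yes, rater1 yes/rater2 no), (rater1 no/rater2 yes, both no)).

    Returns ``None`` when expected agreement is 1 (kappa undefined).
    """
    (a, b), (c, d) = table
    n = a + b + c + d
    if n == 0:
        raise ValueError("agreement table must have positive total")
    p_o = (a + d) / n
    p_e = ((a + b) * (a + c) + (c + d) * (b + d)) / (n * n)
    if p_e == 1.0:
        return None
    return (p_o - p_e) / (1.0 - p_e)


class RecoveryError(ValueError):
    """Matrix recovery failed; carries the candidate list found."""

    def __init__(self, message: str, candidates: list[ConfusionMatrix]):
        super().__init__(message)
        self.candidates = candidates


def recover_matrix(
    n_total: int,
    n_pred_pos: int,
    n_pred_neg: int,
    printed: dict[str, float],
    ndigits: int = 4,
) -> ConfusionMatrix:
    """Recover the unique integer confusion matrix behind rounded
    published point estimates.

    Enumerates every (tp, fn) with tp <= n_pred_pos, fn <= n_pred_neg
    (fp and tn follow from the design) and keeps the matrices whose
    recomputed precision, recall and specificity all round (half-up, to
    *ndigits* places) to the printed values.  Raises
    :class:`RecoveryError` listing candidates unless exactly one
    matrix survives.
    """
    if n_pred_pos + n_pred_neg != n_total:
        raise ValueError("predicted-positive + predicted-negative != total")
    wanted = {k: round_half_up(v, ndigits) for k, v in printed.items()}
    candidates: list[ConfusionMatrix] = []
    for tp in range(n_pred_pos + 1):
        fp = n_pred_pos - tp
        for fn in range(n_pred_neg + 1):
            tn = n_pred_neg - fn
            point = {
                "precision": _ratio(tp, tp + fp),
                "recall": _ratio(tp, tp + fn),
                "specificity": _ratio(tn, tn + fp),
            }
            ok = True
            for key, target in wanted.items():
                value = point.get(key)
                if value is None or round_half_up(value, ndigits) != target:
                    ok = False
                    break
            if ok:
                candidates.append(ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn))
    if len(candidates) != 1:
        raise RecoveryError(
            f"expected a unique confusion matrix, found {len(candidates)}: "
            f"{candidates}",
            candidates,
        )
    return candidates[0]
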