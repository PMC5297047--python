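"""Allele-fraction classification of validation readcounts and ROC analysis.

Classification applies fixed allele-fraction cutoffs to deep tumor/normal
readcounts at each candidate locus:

* ``SOMATIC``  — tumor AF >= ``tumor_af_min`` and normal AF < ``normal_af_max``
* ``GERMLINE`` — tumor AF >= ``tumor_af_min`` and normal AF >= ``normal_af_max``
* ``FAIL``     — tumor AF < ``tumor_af_min``

Allele fractions use ref+alt counts only as the denominator. Observations
with zero depth in either sample are indeterminate and excluded from rates
with a logged count.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint, proportions_ztest

from .errors import DomainError

logger = logging.getLogger(__name__)

DEFAULT_TUMOR_AF_MIN = 0.05
DEFAULT_NORMAL_AF_MAX = 0.02


class Verdict(str, enum.Enum):
    SOMATIC = "SOMATIC"
    GERMLINE = "GERMLINE"
    FAIL = "FAIL"


@dataclass(frozen=True)
class ValidationObservation:
    """Deep-readcount evidence at one candidate locus."""

    chrom: str
    pos: int
    ref: str
    alt: str
    t_ref: int
    t_alt: int
    n_ref: int
    n_alt: int

    def __post_init__(self) -> None:
        if min(self.t_ref, self.t_alt, self.n_ref, self.n_alt) < 0:
            raise DomainError(f"negative readcount at {self.chrom}:{self.pos}")

    @property
    def tumor_depth(self) -> int:
        return self.t_ref + self.t_alt

    @property
    def normal_depth(self) -> int:
        return self.n_ref + self.n_alt

    @property
    def tumor_af(self) -> float:
        if self.tumor_depth == 0:
            raise DomainError(f"tumor depth 0 at {self.chrom}:{self.pos}; AF undefined")
        return self.t_alt / self.tumor_depth

    @property
    def normal_af(self) -> float:
        if self.normal_depth == 0:
            raise DomainError(f"normal depth 0 at {self.chrom}:{self.pos}; AF undefined")
        return self.n_alt / self.normal_depth


def classify(obs: ValidationObservation,
             tumor_af_min: float = DEFAULT_TUMOR_AF_MIN,
             normal_af_max: float = DEFAULT_NORMAL_AF_MAX) -> Verdict:
    """Classify one observation. Requires positive depth in both samples."""
    t_af, n_af = obs.tumor_af, obs.normal_af  # raises DomainError on zero depth
    if t_af < tumor_af_min:
        return Verdict.FAIL
    return Verdict.SOMATIC if n_af < normal_af_max else Verdict.GERMLINE


def classify_table(table: pd.DataFrame,
                   tumor_af_min: float = DEFAULT_TUMOR_AF_MIN,
                   normal_af_max: float = DEFAULT_NORMAL_AF_MAX) -> pd.DataFrame:
    """Classify a readcount table; zero-depth rows get verdict ``None``.

    Returns a copy with ``tumor_af``, ``normal_af`` and ``verdict`` columns.
    Indeterminate (zero-depth) rows are counted and logged; their verdict is
    left missing so rate computations can exclude them.
    """
    out = table.copy()
    t_depth = out["t_ref"] + out["t_alt"]
    n_depth = out["n_ref"] + out["n_alt"]
    with np.errstate(invalid="ignore", divide="ignore"):
        out["tumor_af"] = np.where(t_depth > 0, out["t_alt"] / t_depth, np.nan)
        out["normal_af"] = np.where(n_depth > 0, out["n_alt"] / n_depth, np.nan)
    verdict = np.where(
        out["tumor_af"] < tumor_af_min, Verdict.FAIL.value,
        np.where(out["normal_af"] < normal_af_max,
                 Verdict.SOMATIC.value, Verdict.GERMLINE.value))
    indeterminate = (t_depth == 0) | (n_depth == 0)
    out["verdict"] = np.where(indeterminate, None, verdict)
    n_bad = int(indeterminate.sum())
    if n_bad:
        logger.info("excluded %d zero-depth observation(s) from classification", n_bad)
    return out


def wilson_interval(k: int, n: int, confidence: float = 0.95) -> Tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n < 1:
        raise DomainError("Wilson interval requires n >= 1")
    lo, hi = proportion_confint(k, n, alpha=1 - confidence, method="wilson")
    return float(lo), float(hi)


def percent_display(k: int, n: int) -> float:
    """Percent as the paper-style display value.

    Nearest-integer percent for groups of 50+ loci, one decimal for smaller
    panels (e.g. 3/27 -> 11.1).
    """
    pct = 100.0 * k / n
    return float(round(pct)) if n >= 50 else float(round(pct, 1))


def validation_rate(verdicts: Sequence[Optional[str | Verdict]],
                    groups: Sequence[str] | None = None,
                    confidence: float = 0.95) -> pd.DataFrame:
    """Per-group validation rate: SOMATIC fraction with Wilson interval.

    ``verdicts`` may contain ``None`` entries (indeterminate observations);
    they are excluded. Empty groups are omitted with a warning.
    """
    verdicts = [v.value if isinstance(v, Verdict) else v for v in verdicts]
    if groups is None:
        groups = ["all"] * len(verdicts)
    if len(groups) != len(verdicts):
        raise DomainError("groups and verdicts must have equal length")
    df = pd.DataFrame({"verdict": verdicts, "group": list(groups)})
    df = df[df["verdict"].notna()]
    rows = []
    for group in dict.fromkeys(groups):  # preserve first-seen order
        sub = df[df["group"] == group]
        n_total = len(sub)
        if n_total == 0:
            logger.warning("group %r has no classifiable observations; omitted", group)
            continue
        n_somatic = int((sub["verdict"] == Verdict.SOMATIC.value).sum())
        rate = n_somatic / n_total
        lo, hi = wilson_interval(n_somatic, n_total, confidence)
        rows.append({
            "group": group, "n_somatic": n_somatic, "n_total": n_total,
            "rate": rate, "percent": percent_display(n_somatic, n_total),
            "wilson_low": lo, "wilson_high": hi,
        })
    return pd.DataFrame(rows)


def two_proportion_test(k1: int, n1: int, k2: int, n2: int,
                        alternative: str = "two-sided") -> float:
    """z-test p-value comparing two validation rates (supplementary)."""
    _, p = proportions_ztest([k1, k2], [n1, n2], alternative=alternative)
    return float(p)


@dataclass
class RocCurve:
    """ROC points ordered from (0,0) to (1,1) plus trapezoidal AUC."""

    thresholds: np.ndarray  # descending; leading +inf for the (0,0) point
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds,
                             "fpr": self.fpr, "tpr": self.tpr})


def roc(scores: Sequence[float], outcomes: Sequence[int | bool]) -> RocCurve:
    """ROC curve of a continuous score against binary validation outcomes.

    The trapezoidal AUC equals the rank statistic (probability a random
    positive outscores a random negative, ties counted half).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    if s.shape != y.shape or s.ndim != 1 or len(s) == 0:
        raise DomainError("scores and outcomes must be equal-length 1-D sequences")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise DomainError("ROC requires both classes present; AUC undefined")
    order = np.argsort(-s, kind="mergesort")
    s_sorted, y_sorted = s[order], y[order]
    # collapse ties: one curve point per distinct threshold
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), len(s_sorted) - 1]
    tp = np.cumsum(y_sorted)[distinct]
    fp = np.cumsum(~y_sorted)[distinct]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)
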