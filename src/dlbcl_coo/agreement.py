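"""Diagnostic agreement statistics between two subtype call sets.

When no ground truth exists, two assays are compared by overall percent
agreement (OPA, the confusion-matrix diagonal fraction), and — with one assay
designated the reference and GCB taken as the positive class — positive and
negative percent agreement (PPA/NPA), the sensitivity/specificity analogues.
Confidence intervals use the Wilson score method; two assays measured against
the same reference are compared by an exact McNemar test on the discordant
pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from statsmodels.stats.proportion import proportion_confint


def round_half_up_pct(proportion: float, digits: int = 1) -> float:
    """Display rounding: proportion → percent, half-up at ``digits`` decimals."""
    q = Decimal(10) ** -digits
    return float(Decimal(proportion * 100).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """Cross-tabulation of two call sets over their shared samples."""

    table: pd.DataFrame  # rows = assay A, columns = reference
    dropped: list[str] = field(default_factory=list)  # ids missing in either set

    @property
    def total(self) -> int:
        return int(self.table.to_numpy().sum())

    def with_subtotals(self) -> pd.DataFrame:
        out = self.table.copy()
        out["Subtotal"] = out.sum(axis=1)
        out.loc["Subtotal"] = out.sum(axis=0)
        return out

    @classmethod
    def from_counts(
        cls, counts: dict[tuple[str, str], int], row_order=None, col_order=None
    ) -> "ConfusionMatrix":
        """Build directly from (assay_label, reference_label) → count."""
        rows = row_order or sorted({k[0] for k in counts})
        cols = col_order or sorted({k[1] for k in counts})
        table = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
        for (r, c), n in counts.items():
            table.loc[r, c] += n
        return cls(table)


def confusion(calls_a: pd.Series, calls_b: pd.Series) -> ConfusionMatrix:
    """Confusion matrix of assay A (rows) versus assay B / reference (columns).

    Only samples callable by both assays enter the table; ids present in one
    set but not the other are excluded and recorded in ``dropped``.
    """
    calls_a, calls_b = pd.Series(calls_a), pd.Series(calls_b)
    shared = calls_a.index.intersection(calls_b.index)
    if len(shared) == 0:
        raise ValueError("the two call sets share no sample ids")
    dropped = sorted(
        set(calls_a.index.symmetric_difference(calls_b.index)).union(
            shared[calls_a[shared].isna() | calls_b[shared].isna()]
        )
    )
    keep = [s for s in shared if s not in set(dropped)]
    labels_a = sorted(calls_a[keep].unique())
    labels_b = sorted(calls_b[keep].unique())
    table = pd.crosstab(calls_a[keep], calls_b[keep]).reindex(
        index=labels_a, columns=labels_b, fill_value=0
    )
    table.index.name = "assay"
    table.columns.name = "reference"
    return ConfusionMatrix(table=table, dropped=dropped)


@dataclass
class ProportionEstimate:
    numerator: int
    denominator: int
    ci_level: float = 0.95
    undefined: bool = False

    @property
    def proportion(self) -> float:
        if self.undefined:
            raise ValueError("statistic undefined: empty reference class")
        return self.numerator / self.denominator

    @property
    def ci(self) -> tuple[float, float]:
        return wilson_ci(self.numerator, self.denominator, self.ci_level)

    @property
    def percent(self) -> float:
        """Half-up display rounding to one decimal, in percent."""
        return round_half_up_pct(self.proportion)

    def __str__(self) -> str:
        if self.undefined:
            return "undefined (empty reference class)"
        lo, hi = self.ci
        return (
            f"{self.percent}% ({self.numerator}/{self.denominator}, "
            f"{int(self.ci_level * 100)}% CI: {lo:.2f}-{hi:.2f})"
        )


def wilson_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    lo, hi = proportion_confint(successes, n, alpha=1 - level, method="wilson")
    return float(lo), float(hi)


def overall_agreement(m: ConfusionMatrix, ci_level: float = 0.95) -> ProportionEstimate:
    """Overall percent agreement: diagonal / total, with Wilson CI.

    Requires a square matrix whose row and column label sets coincide
    (order-insensitive; the diagonal is matched by label).
    """
    if m.total == 0:
        raise ValueError("empty confusion matrix")
    rows, cols = set(m.table.index), set(m.table.columns)
    if rows != cols:
        raise ValueError(
            f"row and column label sets differ: {sorted(rows)} vs {sorted(cols)}"
        )
    agree = int(sum(m.table.loc[l, l] for l in m.table.index))
    return ProportionEstimate(agree, m.total, ci_level)


def ppa_npa(
    m: ConfusionMatrix, positive: str = "GCB", ci_level: float = 0.95
) -> tuple[ProportionEstimate, ProportionEstimate]:
    """Positive/negative percent agreement of a 2×2 table, reference in columns.

    PPA is the fraction of reference-positive samples the assay also calls
    positive; NPA the analogue among reference-negatives. An empty reference
    class yields an estimate flagged ``undefined`` rather than NaN.
    """
    if m.table.shape != (2, 2):
        raise ValueError(f"need a 2x2 matrix, got {m.table.shape}")
    if positive not in m.table.columns or positive not in m.table.index:
        raise ValueError(f"positive label {positive!r} absent from the matrix")
    negative = [l for l in m.table.columns if l != positive][0]
    n_pos = int(m.table[positive].sum())
    n_neg = int(m.table[negative].sum())
    ppa = ProportionEstimate(
        int(m.table.loc[positive, positive]), max(n_pos, 1), ci_level,
        undefined=n_pos == 0,
    )
    npa = ProportionEstimate(
        int(m.table.loc[negative, negative]), max(n_neg, 1), ci_level,
        undefined=n_neg == 0,
    )
    return ppa, npa


@dataclass
class PairedAgreementTest:
    """Exact McNemar comparison of two assays against one shared reference."""

    b: int  # A correct, B wrong
    c: int  # A wrong, B correct
    p_value: float

    @property
    def statistic(self) -> int:
        return min(self.b, self.c)


def compare_paired_agreement(
    agree_a: pd.Series, agree_b: pd.Series
) -> PairedAgreementTest:
    """Exact McNemar test on per-sample correctness indicators.

    ``agree_a``/``agree_b`` are booleans marking whether each assay matched the
    shared reference on each sample. Only discordant pairs inform the test:
    the two-sided p-value is the exact binomial tail of min(b, c) out of
    b + c at p = one half.
    """
    agree_a, agree_b = pd.Series(agree_a), pd.Series(agree_b)
    if len(agree_a) != len(agree_b) or not agree_a.index.equals(agree_b.index):
        raise ValueError("the two agreement vectors must cover the same samples")
    a = agree_a.astype(bool).to_numpy()
    b_vec = agree_b.astype(bool).to_numpy()
    b = int((a & ~b_vec).sum())
    c = int((~a & b_vec).sum())
    if b + c == 0:
        return PairedAgreementTest(b=0, c=0, p_value=1.0)
    p = binomtest(min(b, c), b + c, 0.5, alternative="two-sided").pvalue
    return PairedAgreementTest(b=b, c=c, p_value=float(min(1.0, p)))
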