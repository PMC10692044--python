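"""Agreement statistics: intraclass correlation and observer DSC matrices.

The headline statistic is the two-way mixed-effects, single-measurement,
absolute-agreement intraclass correlation, ICC(A,1) in McGraw & Wong's
taxonomy.  With n subjects (scans) rated by k raters (e.g. the reference
workflow and the automatic model), the two-way ANOVA decomposition gives
mean squares for rows (MSR), columns (MSC) and error (MSE), and

    ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))

Absolute agreement penalises systematic offsets between raters (through
the MSC term); the consistency form ICC(C,1) = (MSR − MSE)/(MSR + (k−1)MSE)
does not, and is provided for comparison.  The 95% confidence interval uses
the McGraw–Wong F-distribution method with Satterthwaite degrees of
freedom.

Estimates are categorised with the conventional thresholds: poor (< 0.40),
fair (0.40–0.59), good (0.60–0.74), excellent (0.75–1.0); the boundary
values 0.40, 0.60 and 0.75 belong to the upper category.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ct_io import MaskVolume
from .metrics import confusion_counts, dice_from_counts, per_case_dice

__all__ = [
    "RatingsTable",
    "ICCResult",
    "ObserverDSCMatrix",
    "icc_absolute_agreement",
    "icc_consistency",
    "categorize_icc",
    "pairwise_observer_dsc",
]


@dataclass
class RatingsTable:
    """Complete n×k matrix of continuous ratings (subjects × raters)."""

    subjects: list[str]
    raters: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, k = len(self.subjects), len(self.raters)
        if self.values.shape != (n, k):
            raise ValueError(
                f"ratings matrix shape {self.values.shape} does not match "
                f"{n} subjects × {k} raters"
            )
        if np.isnan(self.values).any():
            raise ValueError("ratings table has missing cells; complete data required")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "RatingsTable":
        """Build from wide (index=scan, columns=raters) or long format.

        Long format needs columns ``scan_id``, ``rater``, ``value``.
        """
        if {"scan_id", "rater", "value"}.issubset(df.columns):
            wide = df.pivot(index="scan_id", columns="rater", values="value")
        else:
            wide = df
        if wide.isna().any().any():
            raise ValueError("ratings table has missing cells; complete data required")
        return cls(
            subjects=[str(s) for s in wide.index],
            raters=[str(r) for r in wide.columns],
            values=wide.to_numpy(dtype=float),
        )

    @property
    def n(self) -> int:
        return len(self.subjects)

    @property
    def k(self) -> int:
        return len(self.raters)


@dataclass
class ICCResult:
    estimate: float
    ci95: tuple[float, float]
    category: str
    n_subjects: int
    n_raters: int
    form: str = "ICC(A,1)"

    def to_dict(self) -> dict:
        return {
            "icc": self.estimate,
            "ci95_lower": self.ci95[0],
            "ci95_upper": self.ci95[1],
            "category": self.category,
            "n_subjects": self.n_subjects,
            "n_raters": self.n_raters,
            "form": self.form,
        }

    def summary(self) -> str:
        lo, hi = self.ci95
        return (
            f"{self.form} = {self.estimate:.3f} (95% CI {lo:.3f}–{hi:.3f}), "
            f"{self.category} agreement; n={self.n_subjects} subjects, "
            f"k={self.n_raters} raters"
        )


def _anova_mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """Two-way (subjects × raters) ANOVA mean squares (MSR, MSC, MSE)."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def _validate_table(table: RatingsTable) -> np.ndarray:
    if table.n < 3:
        raise ValueError(f"ICC needs at least 3 subjects, got {table.n}")
    if table.k < 2:
        raise ValueError(f"ICC needs at least 2 raters, got {table.k}")
    return table.values


def icc_absolute_agreement(table: RatingsTable, alpha: float = 0.05) -> ICCResult:
    """ICC(A,1): two-way model, single measurement, absolute agreement."""
    x = _validate_table(table)
    n, k = x.shape
    msr, msc, mse = _anova_mean_squares(x)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0:
        raise ValueError("no subject variance: ICC undefined for constant ratings")
    icc = (msr - mse) / denom

    # McGraw–Wong F-based CI with Satterthwaite df for ICC(A,1)
    if mse == 0 or icc >= 1:
        ci = (icc, icc)  # degenerate perfect-agreement table
    else:
        fj = msc / mse
        vn = (k - 1) * (n - 1) * (
            (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
        )
        vd = (n - 1) * (k * icc * fj) ** 2 + (
            n * (1 + (k - 1) * icc) - k * icc
        ) ** 2
        v = vn / vd
        f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lower = (
            n * (msr - f1 * mse)
            / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
        )
        upper = (
            n * (f2 * msr - mse)
            / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
        )
        ci = (float(min(lower, icc)), float(max(upper, icc)))

    return ICCResult(
        estimate=float(icc),
        ci95=ci,
        category=categorize_icc(float(icc)) if -1 <= icc <= 1 else "undefined",
        n_subjects=n,
        n_raters=k,
        form="ICC(A,1)",
    )


def icc_consistency(table: RatingsTable) -> ICCResult:
    """ICC(C,1): two-way model, single measurement, consistency."""
    x = _validate_table(table)
    n, k = x.shape
    msr, _, mse = _anova_mean_squares(x)
    denom = msr + (k - 1) * mse
    if denom == 0:
        raise ValueError("no subject variance: ICC undefined")
    icc = float((msr - mse) / denom)
    return ICCResult(
        estimate=icc,
        ci95=(float("nan"), float("nan")),
        category=categorize_icc(icc) if -1 <= icc <= 1 else "undefined",
        n_subjects=n,
        n_raters=k,
        form="ICC(C,1)",
    )


def categorize_icc(estimate: float) -> str:
    """Qualitative agreement category for an ICC estimate."""
    if not np.isfinite(estimate) or estimate > 1 or estimate < -1:
        raise ValueError(f"ICC estimate must be in [-1, 1], got {estimate}")
    if estimate < 0.40:
        return "poor"
    if estimate < 0.60:
        return "fair"
    if estimate < 0.75:
        return "good"
    return "excellent"


@dataclass
class ObserverDSCMatrix:
    """Symmetric m×m summary of pairwise observer agreement.

    Entries hold the per-case DSC median, IQR and the pooled (global) DSC
    for each observer pair; the diagonal is NaN.
    """

    observers: list[str]
    per_case_median: np.ndarray
    per_case_q1: np.ndarray
    per_case_q3: np.ndarray
    global_dsc: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        m = len(self.observers)
        cells = []
        for i in range(m):
            row = {}
            for j in range(m):
                if i == j:
                    row[self.observers[j]] = "-"
                else:
                    row[self.observers[j]] = (
                        f"{self.per_case_median[i, j]:.2f} "
                        f"({self.per_case_q1[i, j]:.2f}-{self.per_case_q3[i, j]:.2f})"
                        f"/{self.global_dsc[i, j]:.2f}"
                    )
            cells.append(row)
        return pd.DataFrame(cells, index=self.observers)


def pairwise_observer_dsc(
    observer_masks: dict[str, dict[str, MaskVolume]],
) -> ObserverDSCMatrix:
    """Pairwise DSC summaries between observers over a common scan set.

    `observer_masks` maps observer → {scan_id → mask}; every observer must
    cover every scan.
    """
    observers = sorted(observer_masks)
    if len(observers) < 2:
        raise ValueError("need at least two observers")
    scan_sets = {o: set(masks) for o, masks in observer_masks.items()}
    all_scans = sorted(set().union(*scan_sets.values()))
    for o in observers:
        missing = set(all_scans) - scan_sets[o]
        if missing:
            raise ValueError(
                f"observer {o!r} is missing masks for scans: {sorted(missing)}"
            )
    m = len(observers)
    med = np.full((m, m), np.nan)
    q1m = np.full((m, m), np.nan)
    q3m = np.full((m, m), np.nan)
    gd = np.full((m, m), np.nan)
    for i in range(m):
        for j in range(i + 1, m):
            pairs = [
                (observer_masks[observers[i]][s], observer_masks[observers[j]][s])
                for s in all_scans
            ]
            median, (q1, q3), _, _ = per_case_dice(pairs)
            pooled = None
            for p, r in pairs:
                c = confusion_counts(p, r)
                pooled = c if pooled is None else pooled + c
            g = dice_from_counts(pooled)
            med[i, j] = med[j, i] = median
            q1m[i, j] = q1m[j, i] = q1
            q3m[i, j] = q3m[j, i] = q3
            gd[i, j] = gd[j, i] = g
    return ObserverDSCMatrix(observers, med, q1m, q3m, gd)
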