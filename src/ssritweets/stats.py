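"""Intrasubject paired comparisons and agreement statistics.

Each feature is compared between the in-treatment and unknown-treatment
periods with a paired t test on the per-user differences
(in − unknown): t = mean(d) / (sd(d)/√n) with sd on the n−1 denominator,
two-sided p from Student's t with df = n − 1.  The Benjamini–Hochberg
step-up adjustment controls the false discovery rate across the feature
family of one comparison run; both raw and adjusted p values are reported.

Inter-rater utilities (percent agreement, Cohen's kappa) support the manual
mention-curation step of the study design.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .features import FEATURE_COLUMNS

__all__ = [
    "DegenerateVarianceError",
    "InsufficientDataError",
    "paired_t",
    "paired_t_from_summary",
    "bh_adjust",
    "percent_agreement",
    "cohen_kappa",
    "PairedPeriodComparison",
    "compare_periods",
]


class DegenerateVarianceError(ValueError):
    """All paired differences identical: the t statistic is undefined."""


class InsufficientDataError(ValueError):
    """Fewer than two complete pairs."""


def paired_t(differences) -> tuple[float, int, float]:
    """Paired t test from per-subject differences.

    Returns ``(t, df, p_two_sided)``.
    """
    d = np.asarray(differences, dtype=float)
    n = d.size
    if n < 2:
        raise InsufficientDataError(f"need >= 2 differences, got {n}")
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateVarianceError("all differences equal; sd of differences is 0")
    t = d.mean() / (sd / math.sqrt(n))
    df = n - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), df, float(p)


def paired_t_from_summary(mean_diff: float, sd_diff: float, n: int) -> float:
    """t statistic from the summary triple (mean difference, SD, n).

    Reports round this to two decimals; the raw value is returned.
    """
    if n < 2:
        raise InsufficientDataError(f"need n >= 2, got {n}")
    if sd_diff <= 0:
        raise DegenerateVarianceError("sd_diff must be positive")
    return float(mean_diff / (sd_diff / math.sqrt(n)))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def percent_agreement(labels_a, labels_b) -> float:
    """Percent of positions where two annotation vectors agree."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    if a.size == 0:
        raise ValueError("empty label vectors")
    return 100.0 * float(np.mean(a == b))


def cohen_kappa(labels_a, labels_b) -> float:
    """Chance-corrected agreement κ = (Po − Pe)/(1 − Pe).

    Pe is the expected agreement under independent raters with the observed
    marginals.  When both raters are constant and identical Pe = 1 and κ is
    undefined (NaN is returned to signal the degenerate case).
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("label vectors must be 1-D, nonempty and of equal length")
    cats = np.unique(np.concatenate([a, b]))
    n = a.size
    po = float(np.mean(a == b))
    pe = sum(
        float(np.mean(a == c)) * float(np.mean(b == c)) for c in cats
    )
    if pe >= 1.0:
        return float("nan")
    return (po - pe) / (1.0 - pe)


class PairedPeriodComparison(BaseEstimator):
    """Paired t tests across the feature battery with BH correction.

    ``fit`` takes the feature matrix indexed by ``(user_id, period)`` and
    produces ``results_``: one row per feature with n, the period means, the
    mean and SD of per-user differences, t, df, raw and BH-adjusted p, and a
    status column.  Users missing a feature in either period are dropped for
    that feature only (complete-case per feature); features with fewer than
    two complete pairs or zero difference variance are flagged in ``status``
    and excluded from the BH family rather than silently skipped.
    """

    def __init__(self, features: Sequence[str] | None = None, fdr_method: str = "bh"):
        self.features = features
        self.fdr_method = fdr_method

    def fit(self, feature_matrix: pd.DataFrame, y=None):
        if self.fdr_method != "bh":
            raise ValueError("only the Benjamini–Hochberg adjustment is supported")
        cols = list(self.features) if self.features is not None else [
            c for c in FEATURE_COLUMNS if c in feature_matrix.columns
        ]
        wide_in = feature_matrix.xs("in_treatment", level="period")
        wide_unk = feature_matrix.xs("unknown_treatment", level="period")
        users = wide_in.index.intersection(wide_unk.index)
        rows = []
        for col in cols:
            x = wide_in.loc[users, col].to_numpy(dtype=float)
            y_ = wide_unk.loc[users, col].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y_)
            n = int(ok.sum())
            d = x[ok] - y_[ok]
            rec = {
                "feature": col,
                "n": n,
                "mean_in": float(x[ok].mean()) if n else float("nan"),
                "mean_unk": float(y_[ok].mean()) if n else float("nan"),
                "mean_diff": float(d.mean()) if n else float("nan"),
                "sd_diff": float(d.std(ddof=1)) if n >= 2 else float("nan"),
                "t": float("nan"),
                "df": n - 1 if n else 0,
                "p_raw": float("nan"),
                "status": "ok",
            }
            if n < 2:
                rec["status"] = "insufficient_n"
            else:
                try:
                    t, df, p = paired_t(d)
                    rec.update(t=t, df=df, p_raw=p)
                except DegenerateVarianceError:
                    rec["status"] = "degenerate_variance"
            rows.append(rec)
        res = pd.DataFrame(rows)
        if res.empty or not (res["status"] == "ok").any():
            raise InsufficientDataError("no feature with at least two complete pairs")
        res["p_adj"] = np.nan
        ok_mask = res["status"] == "ok"
        res.loc[ok_mask, "p_adj"] = bh_adjust(res.loc[ok_mask, "p_raw"].to_numpy())
        self.results_ = res
        self.n_users_ = len(users)
        return self

    def transform(self, feature_matrix: pd.DataFrame) -> pd.DataFrame:
        return self.fit(feature_matrix).results_


def compare_periods(
    feature_matrix: pd.DataFrame, features: Sequence[str] | None = None
) -> pd.DataFrame:
    """One paired-comparison row per feature (see PairedPeriodComparison)."""
    return PairedPeriodComparison(features=features).fit(feature_matrix).results_
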