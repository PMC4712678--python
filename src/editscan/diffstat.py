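"""Differential-editing statistics: per-site t-tests, BH correction, and the
global mean-editing comparison between disease and control groups.

The per-site family within one tissue is corrected with Benjamini–Hochberg
at FDR 0.1; sites with fewer than two measurable values in a group are
marked untestable and excluded from the family before correction.  The
global signal is each sample's mean editing level over the retained sites,
compared between groups with a two-sample t-test.

Welch's unequal-variance t-test is the default (cohort sizes differ);
Student's pooled-variance variant is available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .editquant import EditingMatrix

__all__ = [
    "site_t_test",
    "bh_adjust",
    "differential_editing",
    "global_editing_test",
]

FDR = 0.1


def site_t_test(
    levels_a: np.ndarray, levels_b: np.ndarray, variant: str = "welch"
) -> tuple[float, float]:
    """Two-sided two-sample t-test after dropping missing values.

    Returns (t, p); (nan, nan) when either group has fewer than two values.
    """
    if variant not in ("welch", "student"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    a = np.asarray(levels_a, dtype=float)
    b = np.asarray(levels_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        return float("nan"), float("nan")
    t, p = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(t), float(p)


def bh_adjust(p_values, fdr: float = FDR) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: (monotone q-values, rejection flags)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    sig, q, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    return q, sig


def differential_editing(
    matrix: EditingMatrix,
    fdr: float = FDR,
    variant: str = "welch",
) -> pd.DataFrame:
    """Per-site AD-vs-NDC table with BH-corrected significance.

    Columns mirror the usual reporting layout: group means/SDs/SEMs, t, p,
    q, a significance flag at the configured FDR, and the direction of the
    change (``hypo`` when the disease mean is lower).
    """
    rows = []
    for site_id in matrix.site_ids:
        ad = matrix.group_values(site_id, "AD")
        ndc = matrix.group_values(site_id, "NDC")
        t, p = site_t_test(ad, ndc, variant=variant)
        rows.append(
            {
                "site_id": site_id,
                "tissue": matrix.tissue,
                "n_AD": len(ad),
                "n_NDC": len(ndc),
                "mean_AD": float(np.mean(ad)) if len(ad) else np.nan,
                "mean_NDC": float(np.mean(ndc)) if len(ndc) else np.nan,
                "sd_AD": float(np.std(ad, ddof=1)) if len(ad) > 1 else np.nan,
                "sd_NDC": float(np.std(ndc, ddof=1)) if len(ndc) > 1 else np.nan,
                "sem_AD": float(stats.sem(ad)) if len(ad) > 1 else np.nan,
                "sem_NDC": float(stats.sem(ndc)) if len(ndc) > 1 else np.nan,
                "t_stat": t,
                "p_value": p,
            }
        )
    df = pd.DataFrame(rows)
    df["testable"] = ~df["p_value"].isna()
    df["q_value"] = np.nan
    df["significant"] = False
    testable = df[df["testable"]]
    if len(testable):
        q, sig = bh_adjust(testable["p_value"].to_numpy(), fdr=fdr)
        df.loc[testable.index, "q_value"] = q
        df.loc[testable.index, "significant"] = sig
    df["direction"] = np.where(df["mean_AD"] < df["mean_NDC"], "hypo", "hyper")
    return df


@dataclass
class GlobalTestResult:
    tissue: str
    n_sites: int
    mean_AD: float
    sd_AD: float
    mean_NDC: float
    sd_NDC: float
    t_stat: float
    p_value: float

    @property
    def direction(self) -> str:
        return "hypo" if self.mean_AD < self.mean_NDC else "hyper"


def global_editing_test(
    matrix: EditingMatrix, variant: str = "welch"
) -> GlobalTestResult:
    """Mean editing level across retained sites, per sample, compared
    between groups (missing cells are skipped in the per-sample mean)."""
    sample_means = matrix.levels.mean(axis=1, skipna=True)
    ad = sample_means[matrix.groups == "AD"].dropna().to_numpy()
    ndc = sample_means[matrix.groups == "NDC"].dropna().to_numpy()
    t, p = site_t_test(ad, ndc, variant=variant)
    return GlobalTestResult(
        tissue=matrix.tissue,
        n_sites=len(matrix.site_ids),
        mean_AD=float(np.mean(ad)) if len(ad) else float("nan"),
        sd_AD=float(np.std(ad, ddof=1)) if len(ad) > 1 else float("nan"),
        mean_NDC=float(np.mean(ndc)) if len(ndc) else float("nan"),
        sd_NDC=float(np.std(ndc, ddof=1)) if len(ndc) > 1 else float("nan"),
        t_stat=t,
        p_value=p,
    )
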