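"""Relative transcript quantification by the ΔΔCT method.

Target-gene CT triplicates are averaged, normalized against the SDHA
housekeeping gene (ΔCT), calibrated against the mean ΔCT of the control
(NDC) samples of the same tissue (ΔΔCT), and expressed as fold change
2^(−ΔΔCT) assuming a doubling per cycle.  Group differences are assessed
with a Mann–Whitney U test (exact for small groups without ties, normal
approximation with tie correction otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import PanelError, SampleSheet

__all__ = [
    "load_ct_table",
    "aggregate_ct",
    "relative_expression",
    "mw_test",
    "expression_summary",
]

REFERENCE_GENE = "SDHA"


def load_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"sample_id", "gene", "ct1", "ct2", "ct3"}
    if not required <= set(df.columns):
        raise PanelError(
            f"CT table missing columns: {sorted(required - set(df.columns))}"
        )
    return df


def aggregate_ct(
    ct: pd.DataFrame, drop_outlier_range: float | None = None
) -> pd.DataFrame:
    """Mean CT per (sample, gene) from replicate columns.

    Replicates may be missing (NaN); at least two are required.  With
    ``drop_outlier_range`` set, triplicates whose range exceeds that many
    cycles drop the replicate farthest from the median first.
    """
    reps = ct[["ct1", "ct2", "ct3"]].to_numpy(dtype=float)
    means = []
    for row in reps:
        vals = row[~np.isnan(row)]
        if len(vals) < 2:
            means.append(np.nan)
            continue
        if (
            drop_outlier_range is not None
            and len(vals) == 3
            and vals.max() - vals.min() > drop_outlier_range
        ):
            med = np.median(vals)
            vals = np.delete(vals, np.argmax(np.abs(vals - med)))
        means.append(float(vals.mean()))
    out = ct[["sample_id", "gene"]].copy()
    out["ct_mean"] = means
    return out


def relative_expression(
    ct: pd.DataFrame,
    samples: SampleSheet,
    target: str,
    reference: str = REFERENCE_GENE,
    drop_outlier_range: float | None = None,
) -> pd.DataFrame:
    """Per-sample relative expression of ``target`` by ΔΔCT.

    ΔCT = mean CT(target) − mean CT(reference); ΔΔCT subtracts the mean ΔCT
    over the NDC samples of the sample's tissue; relative expression is
    2^(−ΔΔCT), so NDC samples average a fold change of 1 by construction.
    Samples missing the reference (or target) measurement are excluded.
    """
    agg = aggregate_ct(ct, drop_outlier_range)
    wide = agg.pivot_table(index="sample_id", columns="gene", values="ct_mean")
    if target not in wide.columns:
        raise PanelError(f"target gene {target!r} absent from CT table")
    if reference not in wide.columns:
        raise PanelError(f"reference gene {reference!r} absent from CT table")
    groups = samples.groups
    tissues = samples.tissues
    df = pd.DataFrame(
        {
            "sample_id": wide.index,
            "dct": (wide[target] - wide[reference]).to_numpy(),
        }
    )
    df["group"] = df["sample_id"].map(groups)
    df["tissue"] = df["sample_id"].map(tissues)
    df = df.dropna(subset=["dct", "group", "tissue"])
    calib = (
        df[df["group"] == "NDC"].groupby("tissue")["dct"].mean().rename("ndc_dct")
    )
    df = df.join(calib, on="tissue")
    df["ddct"] = df["dct"] - df["ndc_dct"]
    df["rel_expr"] = 2.0 ** (-df["ddct"])
    df.insert(1, "gene", target)
    return df.drop(columns=["ndc_dct"]).reset_index(drop=True)


def mw_test(values_a, values_b) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    Exact null distribution when both groups have ≤ 8 values and no ties
    across groups; otherwise the normal approximation with tie correction
    and continuity correction.  Returns (U of the first group, p).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups need at least one value")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class ExpressionSummary:
    gene: str
    tissue: str
    n_AD: int
    n_NDC: int
    mean_AD: float
    sem_AD: float
    mean_NDC: float
    sem_NDC: float
    fold_change: float  # mean AD / mean NDC relative expression
    u_stat: float
    p_value: float


def expression_summary(rel: pd.DataFrame) -> list[ExpressionSummary]:
    """Per-tissue group comparison of relative expression (MW test)."""
    out = []
    for tissue, sub in rel.groupby("tissue", sort=True):
        ad = sub[sub["group"] == "AD"]["rel_expr"].to_numpy()
        ndc = sub[sub["group"] == "NDC"]["rel_expr"].to_numpy()
        if len(ad) == 0 or len(ndc) == 0:
            continue
        u, p = mw_test(ad, ndc)
        out.append(
            ExpressionSummary(
                gene=str(sub["gene"].iloc[0]),
                tissue=str(tissue),
                n_AD=len(ad),
                n_NDC=len(ndc),
                mean_AD=float(ad.mean()),
                sem_AD=float(stats.sem(ad)) if len(ad) > 1 else float("nan"),
                mean_NDC=float(ndc.mean()),
                sem_NDC=float(stats.sem(ndc)) if len(ndc) > 1 else float("nan"),
                fold_change=float(ad.mean() / ndc.mean()),
                u_stat=u,
                p_value=p,
            )
        )
    return out
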