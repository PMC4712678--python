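"""Editing-level computation and the coverage / retention filters.

The editing level of a site in a sample is the A→G conversion fraction
nG / (nG + nA) over quality-filtered read bases; C and T bases (sequencing
noise) are excluded from the ratio.  Cells with no A or G evidence are
missing, never zero.  The analysis matrix keeps, per brain tissue, only
measurements with read coverage ≥ 500 and only sites with at least five
passing samples in each of the disease and control groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aligncount import PileupCounts
from .panel import SampleSheet

__all__ = [
    "editing_level",
    "measurements_from_pileup",
    "EditingMatrix",
    "apply_filters",
]

MIN_DEPTH = 500
N_MIN_PER_GROUP = 5


def editing_level(counts) -> float:
    """nG / (nG + nA) from a 4-vector (nA, nC, nG, nT); NaN when nG+nA == 0."""
    nA, _, nG, _ = (int(x) for x in counts)
    denom = nA + nG
    if denom == 0:
        return float("nan")
    return nG / denom


def measurements_from_pileup(
    counts: PileupCounts, min_depth: int = MIN_DEPTH
) -> pd.DataFrame:
    """Long-format per-(sample, site) editing measurements.

    ``depth`` is the total quality-filtered coverage (nA+nC+nG+nT);
    ``passed_coverage`` applies the ≥ ``min_depth`` rule.  Cells with no A/G
    evidence are dropped (missing, not zero).
    """
    rows = []
    for (sample_id, site_id), c in sorted(counts.counts.items()):
        level = editing_level(c)
        if np.isnan(level):
            continue
        depth = int(c.sum())
        rows.append((sample_id, site_id, level, depth, depth >= min_depth))
    return pd.DataFrame(
        rows,
        columns=["sample_id", "site_id", "level", "depth", "passed_coverage"],
    )


@dataclass
class EditingMatrix:
    """Samples × sites editing-level matrix for one tissue after filtering."""

    tissue: str
    levels: pd.DataFrame  # index samples, columns sites, NaN = missing
    depths: pd.DataFrame
    groups: pd.Series  # sample_id → AD | NDC

    @property
    def site_ids(self) -> list[str]:
        return list(self.levels.columns)

    def group_values(self, site_id: str, group: str) -> np.ndarray:
        samples = self.groups[self.groups == group].index
        vals = self.levels.loc[self.levels.index.intersection(samples), site_id]
        return vals.dropna().to_numpy()

    def to_tsv(self, path) -> None:
        self.levels.to_csv(path, sep="\t", na_rep="NA")


def apply_filters(
    measurements: pd.DataFrame,
    samples: SampleSheet,
    min_depth: int = MIN_DEPTH,
    n_min_per_group: int = N_MIN_PER_GROUP,
) -> dict[str, EditingMatrix]:
    """Coverage and per-group retention filters, applied per tissue.

    A measurement survives iff ``depth >= min_depth``; a site is retained in
    a tissue iff at least ``n_min_per_group`` passing samples exist in each
    of AD and NDC there.  Idempotent: re-filtering a filtered matrix changes
    nothing.
    """
    tissues = samples.tissues
    groups = samples.groups
    df = measurements.copy()
    df = df[df["depth"] >= min_depth]
    df["tissue"] = df["sample_id"].map(tissues)
    df["group"] = df["sample_id"].map(groups)
    out: dict[str, EditingMatrix] = {}
    for tissue, sub in df.groupby("tissue", sort=True):
        per_site = sub.groupby(["site_id", "group"])["sample_id"].nunique().unstack(
            fill_value=0
        )
        for g in ("AD", "NDC"):
            if g not in per_site.columns:
                per_site[g] = 0
        keep = per_site[
            (per_site["AD"] >= n_min_per_group)
            & (per_site["NDC"] >= n_min_per_group)
        ].index
        sub = sub[sub["site_id"].isin(keep)]
        if sub.empty:
            continue
        levels = sub.pivot(index="sample_id", columns="site_id", values="level")
        depths = sub.pivot(index="sample_id", columns="site_id", values="depth")
        grp = pd.Series(
            {s: groups[s] for s in levels.index}, name="group"
        )
        out[tissue] = EditingMatrix(
            tissue=str(tissue),
            levels=levels.sort_index(),
            depths=depths.sort_index(),
            groups=grp.sort_index(),
        )
    return out
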