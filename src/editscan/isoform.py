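"""Per-read phasing of clustered editing sites into isoform abundances.

When several editing sites sit within one amplicon, the per-site A/G ratios
hide which *combinations* of edits co-occur on single transcripts.  Each
aligned read that covers every site of a cluster with confident A/G bases is
phased into a binary editing state; state counts per sample give the mRNA
variant spectrum, and a codon model translates states into protein isoforms.

The shipped codon model covers the serotonin-2C receptor (HTR2C) cluster:
five sites (A, B, C', C, D) within the codons for amino acids 157/159/161
(unedited ATA-AAT-ATA → INI; fully edited GTG-GGT-GTA → VGV).  Enumerating
the 2^5 = 32 editing-state combinations yields 24 distinct protein isoforms.

Group comparison of variant abundances uses a two-way fixed-effects ANOVA
(disease group × variant, type-II sums of squares for the unbalanced cohort
sizes) with per-variant post-hoc contrasts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .aligncount import AlignedRead
from .panel import Panel, SiteCluster

__all__ = [
    "CodonModel",
    "htr2c_codon_model",
    "single_codon_model",
    "enumerate_variants",
    "phase_read",
    "variant_abundance",
    "compare_abundance",
]


@dataclass(frozen=True)
class CodonModel:
    """Maps a cluster's editing sites into codon positions.

    ``codons`` are the unedited affected codons (DNA alphabet, transcript
    orientation); ``aa_positions`` their amino-acid numbers in the protein;
    ``site_codon_pos`` maps each site to (codon index, position in codon),
    both 0-based.
    """

    cluster_id: str
    codons: tuple[str, ...]
    aa_positions: tuple[int, ...]
    site_codon_pos: Mapping[str, tuple[int, int]]

    def __post_init__(self):
        for sid, (ci, pos) in self.site_codon_pos.items():
            if not (0 <= ci < len(self.codons) and 0 <= pos < 3):
                raise ValueError(f"site {sid}: codon position out of range")
            if self.codons[ci][pos] != "A":
                raise ValueError(
                    f"site {sid}: codon {self.codons[ci]} position {pos + 1} "
                    "is not 'A'"
                )

    def edited_codons(
        self, cluster: SiteCluster, state: str
    ) -> tuple[str, ...]:
        codons = [list(c) for c in self.codons]
        for sid, bit in zip(cluster.site_ids, state):
            if bit == "1":
                ci, pos = self.site_codon_pos[sid]
                codons[ci][pos] = "G"
        return tuple("".join(c) for c in codons)

    def translate(self, cluster: SiteCluster, state: str) -> str:
        return str(Seq("".join(self.edited_codons(cluster, state))).translate())


def htr2c_codon_model(cluster: SiteCluster) -> CodonModel:
    """The HTR2C exon-5 model: sites A/B in the codon of amino acid 157,
    C'/C in 159, D in 161.

    The site→codon-position map is the unique assignment consistent with the
    known single-edit amino-acid changes (I157→V/M, N159→S/D/G, I161→V).
    """
    a, b, cp, c, d = cluster.site_ids
    return CodonModel(
        cluster_id=cluster.cluster_id,
        codons=("ATA", "AAT", "ATA"),
        aa_positions=(157, 159, 161),
        site_codon_pos={a: (0, 0), b: (0, 2), cp: (1, 0), c: (1, 1), d: (2, 0)},
    )


def single_codon_model(
    cluster: SiteCluster, codon: str = "ATA", position: int = 0
) -> CodonModel:
    """A one-site model for synthetic clusters."""
    (sid,) = cluster.site_ids
    return CodonModel(
        cluster_id=cluster.cluster_id,
        codons=(codon,),
        aa_positions=(1,),
        site_codon_pos={sid: (0, position)},
    )


def codon_model_for(cluster: SiteCluster) -> CodonModel | None:
    if cluster.codon_model_id == "HTR2C" and len(cluster) == 5:
        return htr2c_codon_model(cluster)
    return None


def enumerate_variants(
    cluster: SiteCluster, model: CodonModel | None = None
) -> pd.DataFrame:
    """All 2^k editing-state combinations of a cluster.

    Columns: state bitstring (ordered as the cluster's sites, 1 = edited),
    an mRNA label naming the edited sites, and — when a codon model is
    given — the edited codons and the protein isoform string.
    """
    model = model or codon_model_for(cluster)
    k = len(cluster)
    rows = []
    for bits in itertools.product("01", repeat=k):
        state = "".join(bits)
        edited = [
            sid for sid, bit in zip(cluster.site_ids, state) if bit == "1"
        ]
        row = {
            "cluster_id": cluster.cluster_id,
            "state": state,
            "n_edited": len(edited),
            "mrna_label": "+".join(edited) if edited else "unedited",
        }
        if model is not None:
            row["codons"] = "-".join(model.edited_codons(cluster, state))
            row["protein"] = model.translate(cluster, state)
        rows.append(row)
    return pd.DataFrame(rows)


def phase_read(
    aligned: AlignedRead, cluster: SiteCluster, q_min: int = 20
) -> str | None:
    """Joint editing state of one read over a cluster, or None.

    The read contributes iff it covers every cluster site with an aligned,
    non-deleted base of quality ≥ ``q_min`` and each base is A or G; any C/T
    base, low-quality base or deleted column rejects the read from phasing
    (its individually qualifying bases still count in the per-site pileup).
    """
    bits = []
    for sid in cluster.site_ids:
        rpos = aligned.site_read_pos.get(sid, -1)
        if rpos < 0:
            return None
        if ord(aligned.qual[rpos]) - 33 < q_min:
            return None
        base = aligned.seq[rpos].upper()
        if base == "A":
            bits.append("0")
        elif base == "G":
            bits.append("1")
        else:
            return None
    return "".join(bits)


def variant_abundance(
    states: Iterable[str] | Mapping[str, int],
    cluster: SiteCluster,
    model: CodonModel | None = None,
) -> pd.DataFrame:
    """Relative abundance of every 2^k variant from phased read states.

    ``states`` is either an iterable of per-read bitstrings or a
    state → count mapping.  Unobserved states are retained at abundance 0;
    abundances sum to 1 exactly.  Raises on zero phased reads.
    """
    if isinstance(states, Mapping):
        counts = dict(states)
    else:
        counts = {}
        for s in states:
            counts[s] = counts.get(s, 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no phased reads for this cluster")
    table = enumerate_variants(cluster, model)
    table["count"] = table["state"].map(counts).fillna(0).astype(int)
    table["abundance"] = table["count"] / total
    return table


@dataclass
class AbundanceComparison:
    anova: pd.DataFrame  # two-way ANOVA table (group, variant, interaction)
    per_variant: pd.DataFrame  # post-hoc group contrast per variant
    n_AD: int
    n_NDC: int

    @property
    def interaction_p(self) -> float:
        return float(self.anova.loc["C(group):C(state)", "PR(>F)"])


def compare_abundance(
    profiles: pd.DataFrame,
    min_abundance: float = 0.0,
) -> AbundanceComparison:
    """Two-way ANOVA of variant abundance (factors: disease group × variant).

    ``profiles`` is long-format with columns sample_id, group, state,
    abundance (one row per sample per variant).  Variants whose overall mean
    abundance is below ``min_abundance`` are excluded from the model.
    Per-variant post-hoc contrasts are Welch t-tests between groups.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from scipy import stats

    df = profiles.copy()
    keep = df.groupby("state")["abundance"].mean()
    df = df[df["state"].isin(keep[keep >= min_abundance].index)]
    n_ad = df[df["group"] == "AD"]["sample_id"].nunique()
    n_ndc = df[df["group"] == "NDC"]["sample_id"].nunique()
    if n_ad < 2 or n_ndc < 2:
        raise ValueError("need at least two samples per group")
    if df["abundance"].nunique() <= 1:
        raise ValueError("degenerate (constant) abundance data")
    fit = smf.ols("abundance ~ C(group) * C(state)", data=df).fit()
    anova = sm.stats.anova_lm(fit, typ=2)
    rows = []
    for state, sub in df.groupby("state", sort=True):
        ad = sub[sub["group"] == "AD"]["abundance"].to_numpy()
        ndc = sub[sub["group"] == "NDC"]["abundance"].to_numpy()
        if len(ad) >= 2 and len(ndc) >= 2 and (ad.std() + ndc.std()) > 0:
            t, p = stats.ttest_ind(ad, ndc, equal_var=False)
        else:
            t, p = np.nan, np.nan
        rows.append(
            {
                "state": state,
                "mean_AD": float(np.mean(ad)) if len(ad) else np.nan,
                "mean_NDC": float(np.mean(ndc)) if len(ndc) else np.nan,
                "diff": float(np.mean(ad) - np.mean(ndc))
                if len(ad) and len(ndc)
                else np.nan,
                "t_stat": float(t),
                "p_value": float(p),
            }
        )
    return AbundanceComparison(
        anova=anova, per_variant=pd.DataFrame(rows), n_AD=n_ad, n_NDC=n_ndc
    )
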