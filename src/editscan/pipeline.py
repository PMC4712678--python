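"""End-to-end orchestration: simulate → demux → align → quantify → test →
phase → qpcr → report.

The engine streams the pooled FASTQ once: each read is demultiplexed,
adapter-trimmed, aligned to its amplicon, added to the pileup and — when it
covers a full site cluster — phased.  Every stage's outputs land under the
run directory; the manifest records the seed, thresholds and per-stage
counts so a run can be reproduced byte-identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aligncount import (
    AmpliconIndex,
    PileupCounts,
    Rejection,
    Scoring,
    align_to_amplicons,
    pileup,
)
from .diffstat import differential_editing, global_editing_test
from .editquant import apply_filters, measurements_from_pileup
from .isoform import codon_model_for, phase_read, variant_abundance, compare_abundance
from .panel import Panel, SampleSheet, load_panel
from .preprocess import BarcodeAssigner, DemuxReport, read_fastq, trim_read
from .qpcr import expression_summary, load_ct_table, relative_expression
from .simgen import SimulationConfig, simulate_qpcr, simulate_run

__all__ = ["RunConfig", "StreamResult", "process_fastq", "run_all"]


@dataclass
class RunConfig:
    panel: str
    samples: str
    outdir: str
    fastq: str | None = None
    ct_table: str | None = None
    seed: int = 0
    q_min: int = 20
    min_depth: int = 500
    n_min_per_group: int = 5
    fdr: float = 0.1
    max_mismatch: int = 0
    min_len: int = 20
    band: int = 16
    t_variant: str = "welch"
    simulate: bool = False
    sim: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self):
        if min(self.q_min, self.min_depth, self.n_min_per_group, self.min_len) < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0 <= self.fdr <= 1:
            raise ValueError("fdr must lie in [0, 1]")


@dataclass
class StreamResult:
    counts: PileupCounts
    phase_counts: dict[tuple[str, str, str], int]  # (sample, cluster, state)
    demux: DemuxReport
    n_aligned: int = 0
    n_multimap: int = 0
    n_low_score: int = 0


def process_fastq(
    fastq_path,
    panel: Panel,
    samples: SampleSheet,
    q_min: int = 20,
    max_mismatch: int = 0,
    min_len: int = 20,
    band: int = 16,
    scoring: Scoring = Scoring(),
) -> StreamResult:
    """One streaming pass: demux, trim, align, pileup and phase every read."""
    assigner = BarcodeAssigner(samples, max_mismatch)
    index = AmpliconIndex(panel)
    clusters_by_amp: dict[str, list] = {}
    for cl in panel.clusters.values():
        amp_id = panel.sites[cl.site_ids[0]].amplicon_id
        clusters_by_amp.setdefault(amp_id, []).append(cl)
    res = StreamResult(
        counts=PileupCounts(),
        phase_counts={},
        demux=DemuxReport(assigned={r.sample_id: 0 for r in samples}),
    )
    for read in read_fastq(fastq_path):
        sid, read = assigner.assign(read)
        if sid is None:
            res.demux.unassigned += 1
            continue
        res.demux.assigned[sid] += 1
        read, found = trim_read(read)
        if found:
            res.demux.trimmed += 1
        else:
            res.demux.untrimmed += 1
        if len(read.seq) < min_len:
            res.demux.removed_short += 1
            continue
        ar = align_to_amplicons(read, index, scoring=scoring, band=band)
        if isinstance(ar, Rejection):
            if ar.reason == "multimap":
                res.n_multimap += 1
            else:
                res.n_low_score += 1
            continue
        res.n_aligned += 1
        pileup([(sid, ar)], panel, q_min=q_min, counts=res.counts)
        for cl in clusters_by_amp.get(ar.amplicon_id, ()):
            state = phase_read(ar, cl, q_min=q_min)
            if state is not None:
                key = (sid, cl.cluster_id, state)
                res.phase_counts[key] = res.phase_counts.get(key, 0) + 1
    return res


def _phase_profiles(
    res: StreamResult, panel: Panel, samples: SampleSheet
) -> pd.DataFrame:
    """Long-format per-sample variant abundances for every cluster."""
    groups = samples.groups
    tissues = samples.tissues
    frames = []
    by_sample_cluster: dict[tuple[str, str], dict[str, int]] = {}
    for (sid, cid, state), n in res.phase_counts.items():
        by_sample_cluster.setdefault((sid, cid), {})[state] = n
    for (sid, cid), counts in sorted(by_sample_cluster.items()):
        cl = panel.clusters[cid]
        tab = variant_abundance(counts, cl, codon_model_for(cl))
        tab.insert(0, "sample_id", sid)
        tab.insert(1, "group", groups.get(sid))
        tab.insert(2, "tissue", tissues.get(sid))
        frames.append(tab)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def run_all(cfg: RunConfig) -> dict:
    """Run every stage and write the report bundle; returns the manifest."""
    out = Path(cfg.outdir)
    for sub in ("demux", "align", "quant", "test", "phase", "qpcr", "report"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    panel, samples = load_panel(cfg.panel, cfg.samples)
    manifest: dict = {
        "editscan_version": __version__,
        "seed": cfg.seed,
        "config": {
            k: v for k, v in asdict(cfg).items() if not isinstance(v, dict)
        },
        "stages": {},
    }

    fastq = cfg.fastq
    if cfg.simulate or fastq is None:
        fastq = str(out / "simulated.fastq")
        sim = cfg.sim
        sim.seed = cfg.seed
        truth, report = simulate_run(
            panel, samples, sim, fastq, truth_prefix=out / "truth"
        )
        manifest["stages"]["simulate"] = {
            "n_cells": report.n_cells,
            "n_reads": report.n_reads,
        }
        if cfg.ct_table is None:
            ct, ct_truth = simulate_qpcr(samples, sim)
            ct_path = out / "qpcr" / "ct_table.csv"
            ct.to_csv(ct_path, index=False)
            ct_truth.to_csv(out / "truth.expression.tsv", sep="\t", index=False)
            cfg.ct_table = str(ct_path)

    res = process_fastq(
        fastq, panel, samples,
        q_min=cfg.q_min, max_mismatch=cfg.max_mismatch,
        min_len=cfg.min_len, band=cfg.band,
    )
    manifest["stages"]["demux"] = {
        "assigned": res.demux.total_assigned,
        "unassigned": res.demux.unassigned,
        "trimmed": res.demux.trimmed,
        "untrimmed": res.demux.untrimmed,
        "removed_short": res.demux.removed_short,
    }
    manifest["stages"]["align"] = {
        "aligned": res.n_aligned,
        "multimap": res.n_multimap,
        "low_score": res.n_low_score,
    }
    res.counts.to_frame().to_csv(out / "align" / "pileup.tsv", sep="\t", index=False)

    measurements = measurements_from_pileup(res.counts, min_depth=cfg.min_depth)
    measurements.to_csv(out / "quant" / "measurements.tsv", sep="\t", index=False)
    matrices = apply_filters(
        measurements, samples,
        min_depth=cfg.min_depth, n_min_per_group=cfg.n_min_per_group,
    )
    manifest["stages"]["quant"] = {
        t: {"n_sites": len(m.site_ids), "n_samples": len(m.levels)}
        for t, m in matrices.items()
    }

    global_results = {}
    for tissue, matrix in matrices.items():
        matrix.to_tsv(out / "quant" / f"editing_matrix.{tissue}.tsv")
        diff = differential_editing(matrix, fdr=cfg.fdr, variant=cfg.t_variant)
        diff.to_csv(out / "test" / f"differential.{tissue}.tsv", sep="\t",
                    index=False)
        g = global_editing_test(matrix, variant=cfg.t_variant)
        global_results[tissue] = {
            "n_sites": g.n_sites,
            "mean_AD": g.mean_AD,
            "sd_AD": g.sd_AD,
            "mean_NDC": g.mean_NDC,
            "sd_NDC": g.sd_NDC,
            "t_stat": g.t_stat,
            "p_value": g.p_value,
            "direction": g.direction,
            "n_significant_sites": int(diff["significant"].sum()),
        }
    manifest["stages"]["test"] = global_results

    profiles = _phase_profiles(res, panel, samples)
    if len(profiles):
        profiles.to_csv(out / "phase" / "variant_abundance.tsv", sep="\t",
                        index=False)
        phase_stats = {}
        for (tissue, cid), sub in profiles.groupby(["tissue", "cluster_id"]):
            try:
                cmp_res = compare_abundance(sub)
            except ValueError:
                continue
            cmp_res.per_variant.to_csv(
                out / "phase" / f"contrasts.{tissue}.{cid}.tsv",
                sep="\t", index=False,
            )
            phase_stats[f"{tissue}/{cid}"] = {
                "interaction_p": cmp_res.interaction_p,
                "n_AD": cmp_res.n_AD,
                "n_NDC": cmp_res.n_NDC,
            }
        manifest["stages"]["phase"] = phase_stats

    if cfg.ct_table:
        ct = load_ct_table(cfg.ct_table)
        targets = sorted(set(ct["gene"]) - {"SDHA"})
        qpcr_stats = {}
        for gene in targets:
            rel = relative_expression(ct, samples, gene)
            rel.to_csv(out / "qpcr" / f"rel_expr.{gene}.tsv", sep="\t",
                       index=False)
            for summ in expression_summary(rel):
                qpcr_stats[f"{gene}/{summ.tissue}"] = {
                    "fold_change": summ.fold_change,
                    "p_value": summ.p_value,
                    "n_AD": summ.n_AD,
                    "n_NDC": summ.n_NDC,
                }
        manifest["stages"]["qpcr"] = qpcr_stats

    with open(out / "report" / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
    return manifest
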