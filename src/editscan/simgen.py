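"""Synthetic barcoded-amplicon read generator with ground truth.

Emulates the statistical structure of a microfluidic multiplex-PCR targeted
resequencing experiment: every (sample, amplicon) pair is one PCR reaction
cell; each cell yields barcoded single-end reads of the amplicon insert, with
per-read editing states, Ion-Torrent-like homopolymer indels, uniform
substitution errors and Phred+33 qualities.

Statistical model
-----------------
* Between-sample variability of the editing level at a site is
  Beta(mu*kappa, (1-mu)*kappa); disease samples get an additive shift
  ``delta`` on ``mu`` (clipped to [0, 1]).  Per-read editing is Bernoulli
  given the sample level, i.e. read counts are beta-binomial across samples.
* Sites grouped in a cluster may instead draw a *joint* editing state per
  read from an explicit distribution over the 2^k on/off combinations,
  allowing isoform-level effects that per-site marginals cannot express.
* Reads are BARCODE + CS1 + insert + revcomp(CS2) in transcript orientation.

All randomness flows from one ``numpy`` Generator seeded by ``config.seed``:
identical configs produce byte-identical FASTQ output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .panel import CS1, CS2, Amplicon, Panel, SampleSheet, revcomp

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "draw_sample_levels",
    "synthesize_read",
    "simulate_run",
    "simulate_qpcr",
    "homopolymer_runs",
    "htr2c_cluster_probs",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Study-level knobs for the generator.

    Defaults reproduce the hippocampal arm of the study design this package
    targets: 28 disease vs 20 control samples, a mean editing level of 26.8%
    in controls with a -5 percentage-point disease shift, between-sample
    concentration ``kappa`` = 200 (SD ~3%), and ~1000 reads per reaction
    cell.
    """

    seed: int = 0
    reads_per_cell: float = 1000.0
    depth_dispersion: float = 0.0  # 0 → Poisson; >0 → gamma-Poisson excess CV
    mu: float | Mapping[str, float] = 0.268
    kappa: float = 200.0
    delta: float | Mapping[str, float] = -0.05
    # cluster_id -> {"AD": {bitstring: p}, "NDC": {...}} (or one dict for both)
    cluster_probs: Mapping[str, Mapping] | None = None
    cluster_kappa: float = 200.0  # Dirichlet concentration for per-sample jitter
    sub_rate: float = 0.001
    indel_rate: float = 0.0005  # per homopolymer run (>=2 nt) per read
    q_mean: float = 32.0
    q_sd: float = 4.0
    frac_below_q20: float = 0.05

    def site_mu(self, site_id: str) -> float:
        mu = self.mu[site_id] if isinstance(self.mu, Mapping) else self.mu
        if not 0.0 <= mu <= 1.0:
            raise ValueError(f"mu for {site_id} outside [0,1]")
        return float(mu)

    def site_delta(self, site_id: str) -> float:
        return float(
            self.delta[site_id] if isinstance(self.delta, Mapping) else self.delta
        )


@dataclass
class TruthTable:
    """Planted ground truth of one simulated run."""

    levels: pd.DataFrame  # sample_id, site_id, true_level
    cluster_states: pd.DataFrame  # sample_id, cluster_id, state, probability
    expression: pd.DataFrame | None = None  # sample_id, gene, true_rel_expr

    def level_map(self) -> dict[tuple[str, str], float]:
        return {
            (r.sample_id, r.site_id): r.true_level
            for r in self.levels.itertuples(index=False)
        }

    def write(self, prefix) -> None:
        prefix = Path(prefix)
        self.levels.to_csv(f"{prefix}.levels.tsv", sep="\t", index=False)
        self.cluster_states.to_csv(
            f"{prefix}.cluster_states.tsv", sep="\t", index=False
        )
        if self.expression is not None:
            self.expression.to_csv(
                f"{prefix}.expression.tsv", sep="\t", index=False
            )


def htr2c_cluster_probs() -> dict[str, dict[str, float]]:
    """Default joint editing-state distributions for the HTR2C cluster.

    States are bitstrings over the ordered sites (A, B, C', C, D).  Controls
    carry 45% unedited INI transcripts; disease samples carry 58% (a +13
    percentage-point shift) with a compensating depletion of the edited VDV
    (10101) and fully edited VGV (11111) forms — the hippocampal isoform
    pattern this package's cluster analysis is built to detect.
    """
    return {
        "NDC": {
            "00000": 0.45,  # INI
            "10101": 0.20,  # VDV
            "11111": 0.13,  # VGV
            "10100": 0.10,
            "10000": 0.07,
            "11101": 0.05,
        },
        "AD": {
            "00000": 0.58,
            "10101": 0.075,
            "11111": 0.075,
            "10100": 0.10,
            "10000": 0.07,
            "11101": 0.10,
        },
    }


def _group_params(cfg: SimulationConfig, site_id: str, group: str) -> float:
    mu = cfg.site_mu(site_id)
    if group == "AD":
        mu = min(1.0, max(0.0, mu + cfg.site_delta(site_id)))
    return mu


def _beta_level(rng: np.random.Generator, mu: float, kappa: float) -> float:
    if mu <= 0.0:
        return 0.0
    if mu >= 1.0:
        return 1.0
    return float(rng.beta(mu * kappa, (1.0 - mu) * kappa))


def _normalize_cluster_probs(
    probs: Mapping, k: int
) -> dict[str, dict[str, float]]:
    """Accept either one state→p dict for both groups or per-group dicts."""
    if probs and all(isinstance(v, (int, float)) for v in probs.values()):
        probs = {"AD": probs, "NDC": probs}
    out: dict[str, dict[str, float]] = {}
    for group, dist in probs.items():
        total = float(sum(dist.values()))
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"cluster state probabilities for {group} sum to {total}")
        for state in dist:
            if len(state) != k or set(state) - {"0", "1"}:
                raise ValueError(f"bad cluster state {state!r} for k={k}")
        out[group] = {s: float(p) / total for s, p in dist.items()}
    return out


def draw_sample_levels(
    panel: Panel,
    samples: SampleSheet,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> TruthTable:
    """Draw every sample's true per-site editing level (and, for clusters
    with an explicit joint model, its per-sample variant distribution)."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    level_rows = []
    cluster_rows = []
    joint_clusters: dict[str, dict[str, dict[str, float]]] = {}
    if config.cluster_probs:
        for cid, probs in config.cluster_probs.items():
            joint_clusters[cid] = _normalize_cluster_probs(
                probs, len(panel.clusters[cid])
            )

    for sample in samples:
        sample_cluster_dist: dict[str, dict[str, float]] = {}
        for cid, by_group in joint_clusters.items():
            base = by_group[sample.group]
            states = sorted(base)
            p = np.array([base[s] for s in states])
            if config.cluster_kappa and np.all(p > 0):
                p = rng.dirichlet(p * config.cluster_kappa)
            dist = {s: float(pi) for s, pi in zip(states, p)}
            sample_cluster_dist[cid] = dist
            for s, pi in dist.items():
                cluster_rows.append((sample.sample_id, cid, s, pi))
        for site in panel.sites.values():
            cid = site.cluster_id
            if cid in sample_cluster_dist:
                # marginal of the sample's joint distribution
                idx = panel.clusters[cid].site_ids.index(site.site_id)
                level = sum(
                    p for s, p in sample_cluster_dist[cid].items() if s[idx] == "1"
                )
            else:
                mu = _group_params(config, site.site_id, sample.group)
                level = _beta_level(rng, mu, config.kappa)
            level_rows.append((sample.sample_id, site.site_id, float(level)))

    return TruthTable(
        levels=pd.DataFrame(
            level_rows, columns=["sample_id", "site_id", "true_level"]
        ),
        cluster_states=pd.DataFrame(
            cluster_rows,
            columns=["sample_id", "cluster_id", "state", "probability"],
        ),
    )


# ---------------------------------------------------------------------------
# Read synthesis
# ---------------------------------------------------------------------------

def homopolymer_runs(seq: str, min_len: int = 2) -> list[tuple[int, int]]:
    """(start, length) of homopolymer runs of ``min_len`` or more."""
    runs = []
    i = 0
    n = len(seq)
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            runs.append((i, j - i))
        i = j
    return runs


def _qualities(rng: np.random.Generator, n: int, cfg: SimulationConfig) -> np.ndarray:
    q = np.clip(np.rint(rng.normal(cfg.q_mean, cfg.q_sd, size=n)), 20, 41)
    low = rng.random(n) < cfg.frac_below_q20
    if low.any():
        q[low] = rng.integers(2, 20, size=int(low.sum()))
    return q.astype(np.uint8)


def synthesize_read(
    amplicon: Amplicon,
    barcode: str,
    editing_state: Mapping[str, bool],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[str, str]:
    """One read (sequence, Phred+33 quality) for a reaction cell.

    Editing is applied first (A→G at edited site offsets), then uniform
    substitutions, then homopolymer ±1 indels, then qualities.
    """
    unknown = set(editing_state) - set(amplicon.site_offsets)
    if unknown:
        raise ValueError(f"editing state for unregistered sites: {sorted(unknown)}")
    insert = list(amplicon.insert)
    for sid, edited in editing_state.items():
        if edited:
            insert[amplicon.site_offsets[sid]] = "G"
    construct = barcode + CS1 + "".join(insert) + revcomp(CS2)
    seq = bytearray(construct, "ascii")

    n = len(seq)
    n_sub = rng.binomial(n, config.sub_rate)
    if n_sub:
        for pos in rng.choice(n, size=n_sub, replace=False):
            alts = [b for b in b"ACGT" if b != seq[pos]]
            seq[pos] = alts[rng.integers(0, 3)]

    if config.indel_rate > 0:
        runs = homopolymer_runs(construct)
        hit = rng.random(len(runs)) < config.indel_rate
        # apply right-to-left so earlier coordinates stay valid
        for (start, length), h in sorted(zip(runs, hit), reverse=True):
            if not h:
                continue
            if rng.random() < 0.5:
                seq.insert(start, seq[start])  # extend by one
            else:
                del seq[start]  # contract by one
    qual = _qualities(rng, len(seq), config)
    return seq.decode("ascii"), (qual + 33).tobytes().decode("ascii")


@dataclass
class RunReport:
    n_cells: int
    n_reads: int
    reads_per_cell: dict[tuple[str, str], int] = field(default_factory=dict)


def _cell_states(
    rng: np.random.Generator,
    panel: Panel,
    amplicon: Amplicon,
    n_reads: int,
    site_levels: Mapping[str, float],
    cluster_dist: Mapping[str, Mapping[str, float]],
) -> list[dict[str, bool]]:
    """Per-read editing states for one reaction cell."""
    site_ids = list(amplicon.site_offsets)
    states: list[dict[str, bool]] = [dict() for _ in range(n_reads)]
    clustered: set[str] = set()
    for cid, dist in cluster_dist.items():
        members = panel.clusters[cid].site_ids
        if not set(members) <= set(site_ids):
            continue
        clustered |= set(members)
        labels = sorted(dist)
        draws = rng.choice(len(labels), size=n_reads, p=[dist[s] for s in labels])
        for r, d in enumerate(draws):
            bits = labels[d]
            for sid, bit in zip(members, bits):
                states[r][sid] = bit == "1"
    for sid in site_ids:
        if sid in clustered:
            continue
        edited = rng.random(n_reads) < site_levels[sid]
        for r in range(n_reads):
            states[r][sid] = bool(edited[r])
    return states


def simulate_run(
    panel: Panel,
    samples: SampleSheet,
    config: SimulationConfig,
    fastq_path,
    truth_prefix=None,
) -> tuple[TruthTable, RunReport]:
    """Simulate the full pooled run: every (sample, amplicon) reaction cell.

    Writes one pooled FASTQ; read names carry ``sample|amplicon`` provenance
    so that demultiplexing and alignment can be audited against truth.
    Returns the truth table and a per-cell read-count report.
    """
    rng = np.random.default_rng(config.seed)
    truth = draw_sample_levels(panel, samples, config, rng)
    levels = truth.level_map()
    cluster_dist: dict[str, dict[str, dict[str, float]]] = {}
    for r in truth.cluster_states.itertuples(index=False):
        cluster_dist.setdefault(r.sample_id, {}).setdefault(r.cluster_id, {})[
            r.state
        ] = r.probability

    report = RunReport(n_cells=0, n_reads=0)
    counter = 0
    with open(fastq_path, "w") as fq:
        for sample in samples:
            for aid, amplicon in panel.amplicons.items():
                report.n_cells += 1
                if config.depth_dispersion > 0:
                    lam = rng.gamma(
                        1.0 / config.depth_dispersion,
                        config.reads_per_cell * config.depth_dispersion,
                    )
                    n_reads = int(rng.poisson(lam))
                elif config.reads_per_cell == int(config.reads_per_cell):
                    n_reads = int(config.reads_per_cell)
                else:
                    n_reads = int(rng.poisson(config.reads_per_cell))
                report.reads_per_cell[(sample.sample_id, aid)] = n_reads
                site_levels = {
                    sid: levels[(sample.sample_id, sid)]
                    for sid in amplicon.site_offsets
                }
                states = _cell_states(
                    rng, panel, amplicon, n_reads, site_levels,
                    cluster_dist.get(sample.sample_id, {}),
                )
                for state in states:
                    seq, qual = synthesize_read(
                        amplicon, sample.barcode, state, config, rng
                    )
                    name = f"sim{counter:08d}|{sample.sample_id}|{aid}"
                    fq.write(f"@{name}\n{seq}\n+\n{qual}\n")
                    counter += 1
                report.n_reads += n_reads
    if truth_prefix is not None:
        truth.write(truth_prefix)
    return truth, report


# ---------------------------------------------------------------------------
# qPCR simulator
# ---------------------------------------------------------------------------

def simulate_qpcr(
    samples: SampleSheet,
    config: SimulationConfig,
    genes: tuple[str, ...] = ("ADAR_p110", "ADAR_p150", "ADARB1"),
    fold_change: Mapping[str, float] | float = 1.0,
    reference: str = "SDHA",
    base_ct: float = 26.0,
    reference_ct: float = 22.0,
    ct_noise_sd: float = 0.2,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """CT triplicates for target genes plus the reference housekeeping gene.

    ``fold_change`` is the planted AD/NDC expression ratio per target gene
    (scalar applies to all); a 2-fold overexpression lowers the target CT by
    one cycle in AD samples.  Returns (ct_table, truth_expression).
    """
    rng = np.random.default_rng(config.seed + 7_000_003) if rng is None else rng
    rows = []
    truth_rows = []
    for sample in samples:
        for gene in (*genes, reference):
            if gene == reference:
                true_rel = 1.0
                mean_ct = reference_ct
            else:
                fc = (
                    fold_change.get(gene, 1.0)
                    if isinstance(fold_change, Mapping)
                    else float(fold_change)
                )
                true_rel = fc if sample.group == "AD" else 1.0
                mean_ct = base_ct - np.log2(true_rel)
            cts = rng.normal(mean_ct, ct_noise_sd, size=3)
            rows.append(
                (sample.sample_id, gene, *np.round(cts, 3))
            )
            if gene != reference:
                truth_rows.append((sample.sample_id, gene, true_rel))
    ct = pd.DataFrame(rows, columns=["sample_id", "gene", "ct1", "ct2", "ct3"])
    truth = pd.DataFrame(
        truth_rows, columns=["sample_id", "gene", "true_rel_expr"]
    )
    return ct, truth
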