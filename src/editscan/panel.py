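"""Target-site panel model and I/O.

A panel describes everything the pipeline knows about its targets before any
read is seen: the editing sites (genomic coordinates, gene, region class,
conservation), the PCR amplicons that carry them (insert sequence in
transcript orientation, primer pair, per-site offsets), groupings of sites
that sit close enough on one amplicon to be phased jointly, and the sample
sheet mapping 10-nt barcodes to cohort metadata.

Conventions
-----------
* Genomic positions are 1-based (matching ``Chr1:160302244``-style labels);
  amplicon offsets are 0-based indices into the insert.
* Inserts and offsets are stored in transcript orientation, so the editable
  base is always ``A`` and an edited read base is always ``G``.  Genome-strand
  bookkeeping is metadata only.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "EditingSite",
    "Amplicon",
    "SiteCluster",
    "SampleRow",
    "SampleSheet",
    "Panel",
    "PanelError",
    "load_panel",
    "write_panel",
    "load_sample_sheet",
    "write_sample_sheet",
    "panel_summary",
    "example_panel",
    "random_panel",
    "make_sample_sheet",
    "revcomp",
]

REGIONS = ("CDS", "UTR3", "ncRNA")
CONSERVATION_SPECIES = ("chimpanzee", "rhesus", "mouse")
GROUPS = ("AD", "NDC")
TISSUES = ("HpC", "TL", "FL")
BARCODE_LEN = 10

# Fluidigm universal "common sequences" fused to the target-specific primers.
CS1 = "ACACTGACGACATGGTTCTACA"
CS2 = "TACGGTAGCAGAGACTTGGTCT"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


class PanelError(ValueError):
    """Raised for malformed panel/sample-sheet files or invariant violations."""


@dataclass(frozen=True)
class EditingSite:
    site_id: str
    gene: str
    chrom: str
    position: int  # 1-based genomic coordinate
    strand: str
    region: str  # CDS | UTR3 | ncRNA
    recoding: bool
    conserved_in: frozenset[str] = frozenset()
    amplicon_id: str = ""
    offset: int = 0  # 0-based offset into the amplicon insert
    cluster_id: str | None = None

    def __post_init__(self):
        if self.position <= 0:
            raise PanelError(f"site {self.site_id}: position must be > 0")
        if self.strand not in ("+", "-"):
            raise PanelError(f"site {self.site_id}: bad strand {self.strand!r}")
        if self.region not in REGIONS:
            raise PanelError(f"site {self.site_id}: bad region {self.region!r}")
        bad = set(self.conserved_in) - set(CONSERVATION_SPECIES)
        if bad:
            raise PanelError(f"site {self.site_id}: unknown species {sorted(bad)}")

    @property
    def label(self) -> str:
        """The paper-style site label, e.g. ``Chr1:160302244``."""
        return f"{self.chrom}:{self.position}"


@dataclass(frozen=True)
class Amplicon:
    amplicon_id: str
    fwd_primer: str
    rev_primer: str
    insert: str  # transcript orientation, primers included at the ends
    site_offsets: Mapping[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        ins = self.insert.upper()
        if not ins or set(ins) - set("ACGTN"):
            raise PanelError(f"amplicon {self.amplicon_id}: non-DNA insert")
        if not ins.startswith(self.fwd_primer.upper()):
            raise PanelError(
                f"amplicon {self.amplicon_id}: fwd primer is not an insert prefix"
            )
        if not ins.endswith(revcomp(self.rev_primer.upper())):
            raise PanelError(
                f"amplicon {self.amplicon_id}: rev primer is not the reverse "
                "complement of the insert suffix"
            )
        for sid, off in self.site_offsets.items():
            if not 0 <= off < len(ins):
                raise PanelError(
                    f"amplicon {self.amplicon_id}: offset {off} of site {sid} "
                    f"outside insert of length {len(ins)}"
                )
            if ins[off] != "A":
                raise PanelError(
                    f"amplicon {self.amplicon_id}: site {sid} expects 'A' at "
                    f"offset {off}, found {ins[off]!r}"
                )


@dataclass(frozen=True)
class SiteCluster:
    cluster_id: str
    site_ids: tuple[str, ...]  # 5' to 3' on the transcript
    codon_model_id: str | None = None

    def __len__(self) -> int:
        return len(self.site_ids)


@dataclass(frozen=True)
class SampleRow:
    sample_id: str
    barcode: str
    group: str  # AD | NDC
    tissue: str  # HpC | TL | FL
    age: int
    sex: str

    def __post_init__(self):
        if len(self.barcode) != BARCODE_LEN or set(self.barcode) - set("ACGT"):
            raise PanelError(
                f"sample {self.sample_id}: barcode must be {BARCODE_LEN} nt of ACGT"
            )
        if self.group not in GROUPS:
            raise PanelError(f"sample {self.sample_id}: bad group {self.group!r}")
        if self.tissue not in TISSUES:
            raise PanelError(f"sample {self.sample_id}: bad tissue {self.tissue!r}")


@dataclass
class SampleSheet:
    rows: list[SampleRow]

    def __post_init__(self):
        barcodes = [r.barcode for r in self.rows]
        if len(set(barcodes)) != len(barcodes):
            raise PanelError("duplicate barcodes in sample sheet")
        ids = [r.sample_id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise PanelError("duplicate sample ids in sample sheet")

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def barcode_map(self) -> dict[str, str]:
        return {r.barcode: r.sample_id for r in self.rows}

    @property
    def groups(self) -> dict[str, str]:
        return {r.sample_id: r.group for r in self.rows}

    @property
    def tissues(self) -> dict[str, str]:
        return {r.sample_id: r.tissue for r in self.rows}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.sample_id, r.barcode, r.group, r.tissue, r.age, r.sex)
                for r in self.rows
            ],
            columns=["sample_id", "barcode", "group", "tissue", "age", "sex"],
        )


@dataclass
class Panel:
    """A validated bundle of sites, amplicons and clusters."""

    sites: dict[str, EditingSite]
    amplicons: dict[str, Amplicon]
    clusters: dict[str, SiteCluster]

    def validate(self) -> None:
        for amp in self.amplicons.values():
            amp.validate()
        for site in self.sites.values():
            if site.amplicon_id not in self.amplicons:
                raise PanelError(
                    f"site {site.site_id} references missing amplicon "
                    f"{site.amplicon_id!r}"
                )
            amp = self.amplicons[site.amplicon_id]
            if amp.site_offsets.get(site.site_id) != site.offset:
                raise PanelError(
                    f"site {site.site_id}: offset disagrees with amplicon "
                    f"{site.amplicon_id}"
                )
            if site.cluster_id is not None and site.cluster_id not in self.clusters:
                raise PanelError(
                    f"site {site.site_id} references missing cluster "
                    f"{site.cluster_id!r}"
                )
        for cl in self.clusters.values():
            amps = set()
            for sid in cl.site_ids:
                if sid not in self.sites:
                    raise PanelError(
                        f"cluster {cl.cluster_id} references missing site {sid!r}"
                    )
                amps.add(self.sites[sid].amplicon_id)
            if len(amps) != 1:
                raise PanelError(
                    f"cluster {cl.cluster_id}: member sites span several amplicons"
                )

    def sites_of(self, amplicon_id: str) -> list[EditingSite]:
        return [s for s in self.sites.values() if s.amplicon_id == amplicon_id]

    def cluster_offsets(self, cluster_id: str) -> list[int]:
        cl = self.clusters[cluster_id]
        return [self.sites[sid].offset for sid in cl.site_ids]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

PANEL_COLUMNS = [
    "site_id",
    "gene",
    "chrom",
    "position",
    "strand",
    "region",
    "recoding",
    "conserved_in",
    "amplicon_id",
    "offset",
    "cluster_id",
    "codon_model",
    "fwd_primer",
    "rev_primer",
    "insert",
]


def load_panel(panel_path, samples_path=None) -> tuple[Panel, SampleSheet | None]:
    """Read a panel TSV (and optionally a sample-sheet CSV) and validate it.

    One TSV row per site; amplicon columns (primers, insert) are repeated on
    every row of the amplicon and must agree.  Returns ``(panel, sheet)`` with
    ``sheet`` ``None`` when no sample sheet is given.
    """
    df = pd.read_csv(panel_path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise PanelError(f"panel file missing columns: {sorted(missing)}")
    sites: dict[str, EditingSite] = {}
    amp_rows: dict[str, tuple[str, str, str]] = {}
    amp_offsets: dict[str, dict[str, int]] = {}
    cluster_members: dict[str, list[tuple[int, str]]] = {}
    cluster_models: dict[str, str | None] = {}
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            site = EditingSite(
                site_id=row.site_id,
                gene=row.gene,
                chrom=row.chrom,
                position=int(row.position),
                strand=row.strand,
                region=row.region,
                recoding=row.recoding.lower() in ("1", "true", "yes"),
                conserved_in=frozenset(
                    s for s in row.conserved_in.split(";") if s
                ),
                amplicon_id=row.amplicon_id,
                offset=int(row.offset),
                cluster_id=row.cluster_id or None,
            )
        except (ValueError, PanelError) as exc:
            raise PanelError(f"{panel_path}: line {line_no}: {exc}") from exc
        if site.site_id in sites:
            raise PanelError(f"{panel_path}: line {line_no}: duplicate site id "
                             f"{site.site_id!r}")
        sites[site.site_id] = site
        key = (row.fwd_primer, row.rev_primer, row.insert)
        if site.amplicon_id in amp_rows and amp_rows[site.amplicon_id] != key:
            raise PanelError(
                f"{panel_path}: line {line_no}: amplicon {site.amplicon_id} "
                "has inconsistent sequence columns"
            )
        amp_rows[site.amplicon_id] = key
        amp_offsets.setdefault(site.amplicon_id, {})[site.site_id] = site.offset
        if site.cluster_id:
            cluster_members.setdefault(site.cluster_id, []).append(
                (site.offset, site.site_id)
            )
            model = row.codon_model or None
            if cluster_models.setdefault(site.cluster_id, model) != model:
                raise PanelError(
                    f"{panel_path}: line {line_no}: cluster {site.cluster_id} "
                    "has inconsistent codon_model values"
                )
    amplicons = {
        aid: Amplicon(aid, fwd, rev, ins, amp_offsets[aid])
        for aid, (fwd, rev, ins) in amp_rows.items()
    }
    clusters = {
        cid: SiteCluster(
            cid,
            tuple(sid for _, sid in sorted(members)),
            codon_model_id=cluster_models.get(cid),
        )
        for cid, members in cluster_members.items()
    }
    panel = Panel(sites, amplicons, clusters)
    panel.validate()
    sheet = load_sample_sheet(samples_path) if samples_path is not None else None
    return panel, sheet


def write_panel(panel: Panel, path) -> None:
    rows = []
    for site in panel.sites.values():
        amp = panel.amplicons[site.amplicon_id]
        rows.append(
            {
                "site_id": site.site_id,
                "gene": site.gene,
                "chrom": site.chrom,
                "position": site.position,
                "strand": site.strand,
                "region": site.region,
                "recoding": str(site.recoding).lower(),
                "conserved_in": ";".join(sorted(site.conserved_in)),
                "amplicon_id": site.amplicon_id,
                "offset": site.offset,
                "cluster_id": site.cluster_id or "",
                "codon_model": (
                    panel.clusters[site.cluster_id].codon_model_id or ""
                    if site.cluster_id in panel.clusters
                    else ""
                ),
                "fwd_primer": amp.fwd_primer,
                "rev_primer": amp.rev_primer,
                "insert": amp.insert,
            }
        )
    pd.DataFrame(rows, columns=PANEL_COLUMNS).to_csv(path, sep="\t", index=False)


def load_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"sample_id", "barcode", "group", "tissue", "age", "sex"}
    if not required <= set(df.columns):
        raise PanelError(f"sample sheet missing columns: {sorted(required - set(df.columns))}")
    rows = []
    for line_no, r in enumerate(df.itertuples(index=False), start=2):
        try:
            rows.append(
                SampleRow(r.sample_id, r.barcode, r.group, r.tissue, int(r.age), r.sex)
            )
        except (ValueError, PanelError) as exc:
            raise PanelError(f"{path}: line {line_no}: {exc}") from exc
    return SampleSheet(rows)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def panel_summary(sites: Iterable[EditingSite]) -> dict[str, tuple[int, int]]:
    """Per region class: (number of sites, number of distinct genes).

    A gene appearing in several region classes is counted once per class;
    site totals partition the panel.
    """
    by_region: dict[str, list[EditingSite]] = {}
    for s in sites:
        by_region.setdefault(s.region, []).append(s)
    return {
        region: (len(ss), len({s.gene for s in ss}))
        for region, ss in sorted(by_region.items())
    }


# ---------------------------------------------------------------------------
# Shipped fixture panel and generators
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _make_amplicon(
    amplicon_id: str,
    rng: np.random.Generator,
    length: int,
    offsets: list[int],
    primer_len: int = 20,
    region_seq: str | None = None,
    region_at: int | None = None,
) -> Amplicon:
    seq = list(_random_dna(rng, length))
    if region_seq is not None:
        seq[region_at : region_at + len(region_seq)] = list(region_seq)
    for off in offsets:
        seq[off] = "A"
    ins = "".join(seq)
    return Amplicon(
        amplicon_id,
        fwd_primer=ins[:primer_len],
        rev_primer=revcomp(ins[-primer_len:]),
        insert=ins,
        site_offsets={},
    )


# The serotonin-2C receptor carries five editing sites (A, B, C', C, D) within
# a 14-bp span of exon 5, recoding amino acids 157/159/161.  Unedited codons:
# ATA(I157) / AAT(N159) / ATA(I161); intervening codons 158/160 are untouched.
# Offsets below are relative to the region start.
_HTR2C_REGION = "ATA" + "CGG" + "AAT" + "GAG" + "ATA"  # codons 157..161
_HTR2C_SITE_REL = {"A": 0, "B": 2, "Cp": 6, "C": 7, "D": 12}
_HTR2C_ORDER = ("A", "B", "Cp", "C", "D")


def example_panel() -> tuple[Panel, SampleSheet]:
    """The shipped fixture panel: the HTR2C 5-site cluster plus eight
    single-site amplicons, with a 48-sample HpC cohort sheet (28 AD, 20 NDC).

    Sequences are deterministic pseudo-random stand-ins (synthetic); genomic
    labels follow hg19-style coordinates for recognizability only.
    """
    rng = np.random.default_rng(20160201)
    sites: dict[str, EditingSite] = {}
    amplicons: dict[str, Amplicon] = {}

    region_at = 61  # keeps the cluster mid-insert, clear of the primers
    amp = _make_amplicon(
        "amp_HTR2C",
        rng,
        length=150,
        offsets=[region_at + r for r in _HTR2C_SITE_REL.values()],
        region_seq=_HTR2C_REGION,
        region_at=region_at,
    )
    offsets = {}
    for letter in _HTR2C_ORDER:
        sid = f"HTR2C_{letter}"
        off = region_at + _HTR2C_SITE_REL[letter]
        offsets[sid] = off
        sites[sid] = EditingSite(
            site_id=sid,
            gene="HTR2C",
            chrom="chrX",
            position=113818520 + _HTR2C_SITE_REL[letter],
            strand="+",
            region="CDS",
            recoding=True,
            conserved_in=frozenset(CONSERVATION_SPECIES),
            amplicon_id="amp_HTR2C",
            offset=off,
            cluster_id="HTR2C_ABCD",
        )
    amplicons["amp_HTR2C"] = Amplicon(
        amp.amplicon_id, amp.fwd_primer, amp.rev_primer, amp.insert, offsets
    )

    singles = [
        ("GRIA2_QR", "GRIA2", "chr4", 158257875, "+", "CDS", True,
         frozenset(CONSERVATION_SPECIES)),
        ("GRIA3_RG", "GRIA3", "chrX", 122598962, "+", "CDS", True,
         frozenset(("chimpanzee", "rhesus"))),
        ("GRIA4_RG", "GRIA4", "chr11", 105804694, "+", "CDS", True,
         frozenset(("mouse",))),
        ("CYFIP2_KE", "CYFIP2", "chr5", 156736808, "+", "CDS", True,
         frozenset(CONSERVATION_SPECIES)),
        ("UNC80_SG", "UNC80", "chr2", 210712536, "+", "CDS", True,
         frozenset(("chimpanzee",))),
        ("COPA_IV", "COPA", "chr1", 160302244, "-", "CDS", True,
         frozenset(("rhesus",))),
        ("NARF_1", "NARF", "chr17", 80441088, "-", "CDS", True, frozenset()),
        ("MEG3_1", "MEG3", "chr14", 101304553, "+", "ncRNA", False,
         frozenset(("chimpanzee",))),
    ]
    for sid, gene, chrom, pos, strand, region, recoding, cons in singles:
        aid = f"amp_{gene}"
        off = int(rng.integers(45, 100))
        amp = _make_amplicon(aid, rng, length=int(rng.integers(130, 170)),
                             offsets=[off])
        amplicons[aid] = Amplicon(
            amp.amplicon_id, amp.fwd_primer, amp.rev_primer, amp.insert,
            {sid: off},
        )
        sites[sid] = EditingSite(
            site_id=sid, gene=gene, chrom=chrom, position=pos, strand=strand,
            region=region, recoding=recoding, conserved_in=cons,
            amplicon_id=aid, offset=off,
        )

    clusters = {
        "HTR2C_ABCD": SiteCluster(
            "HTR2C_ABCD",
            tuple(f"HTR2C_{l}" for l in _HTR2C_ORDER),
            codon_model_id="HTR2C",
        )
    }
    panel = Panel(sites, amplicons, clusters)
    panel.validate()
    sheet = make_sample_sheet(n_ad=28, n_ndc=20, tissue="HpC", seed=20160202)
    return panel, sheet


def random_panel(
    n_amplicons: int,
    sites_per_amplicon: int = 1,
    seed: int = 0,
    insert_len: int = 150,
) -> Panel:
    """Generate an arbitrary single-site-per-amplicon panel for simulations."""
    rng = np.random.default_rng(seed)
    sites: dict[str, EditingSite] = {}
    amplicons: dict[str, Amplicon] = {}
    for a in range(n_amplicons):
        aid = f"amp{a:03d}"
        offs = sorted(
            int(o)
            for o in rng.choice(
                np.arange(40, insert_len - 40), size=sites_per_amplicon,
                replace=False,
            )
        )
        amp = _make_amplicon(aid, rng, insert_len, offs)
        offsets = {}
        for k, off in enumerate(offs):
            sid = f"site{a:03d}_{k}"
            offsets[sid] = off
            sites[sid] = EditingSite(
                site_id=sid, gene=f"GENE{a:03d}", chrom=f"chr{a % 22 + 1}",
                position=1_000_000 + 1000 * a + off, strand="+", region="CDS",
                recoding=True, amplicon_id=aid, offset=off,
            )
        amplicons[aid] = Amplicon(
            amp.amplicon_id, amp.fwd_primer, amp.rev_primer, amp.insert, offsets
        )
    panel = Panel(sites, amplicons, {})
    panel.validate()
    return panel


def make_sample_sheet(
    n_ad: int,
    n_ndc: int,
    tissue: str = "HpC",
    seed: int = 1,
    start_index: int = 1,
) -> SampleSheet:
    """Deterministic cohort sheet with barcodes at pairwise Hamming
    distance ≥ 3 (supports unambiguous demultiplexing at ≤1 mismatch)."""
    rng = np.random.default_rng(seed)
    barcodes: list[str] = []
    while len(barcodes) < n_ad + n_ndc:
        cand = _random_dna(rng, BARCODE_LEN)
        if all(
            sum(a != b for a, b in zip(cand, bc)) >= 3 for bc in barcodes
        ):
            barcodes.append(cand)
    rows = []
    for i in range(n_ad + n_ndc):
        group = "AD" if i < n_ad else "NDC"
        rows.append(
            SampleRow(
                sample_id=f"{tissue}_{group}{(i if i < n_ad else i - n_ad) + start_index:02d}",
                barcode=barcodes[i],
                group=group,
                tissue=tissue,
                age=int(rng.integers(65, 95)),
                sex="F" if rng.random() < 0.5 else "M",
            )
        )
    return SampleSheet(rows)
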