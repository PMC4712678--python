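"""Demultiplexing by sample barcode and universal-sequence trimming.

Pooled reads start with a 10-nt sample barcode followed by the universal CS1
sequence, the amplicon insert, and the reverse complement of CS2.
Demultiplexing matches the leading barcode against the sample sheet within a
configurable Hamming radius; trimming removes the CS sequences from the read
ends (mismatch-tolerant, no indels in the adapter match) and drops reads
shorter than 20 nt afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple

import pysam

from .panel import BARCODE_LEN, CS1, CS2, PanelError, SampleSheet, revcomp

__all__ = [
    "Read",
    "DemuxReport",
    "read_fastq",
    "write_fastq",
    "hamming",
    "BarcodeAssigner",
    "demultiplex",
    "trim_read",
    "trim_and_filter",
]


class Read(NamedTuple):
    name: str
    seq: str
    qual: str  # Phred+33, same length as seq


def read_fastq(path) -> Iterator[Read]:
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            yield Read(rec.name, rec.sequence, rec.quality or "")


def write_fastq(reads: Iterable[Read], path) -> int:
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.seq}\n+\n{r.qual}\n")
            n += 1
    return n


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


@dataclass
class DemuxReport:
    assigned: dict[str, int] = field(default_factory=dict)
    unassigned: int = 0
    trimmed: int = 0
    untrimmed: int = 0
    removed_short: int = 0

    @property
    def total_assigned(self) -> int:
        return sum(self.assigned.values())


class BarcodeAssigner:
    """Assign reads to samples by their leading barcode.

    With ``max_mismatch`` = 0 assignment is an exact dictionary lookup;
    otherwise the nearest barcode within the radius wins, provided it is
    unique.  Construction fails if any two sample barcodes are close enough
    (pairwise Hamming distance ≤ 2·max_mismatch) to make a read ambiguous.
    """

    def __init__(self, samples: SampleSheet, max_mismatch: int = 0):
        self.max_mismatch = int(max_mismatch)
        self.barcodes = [(r.barcode, r.sample_id) for r in samples]
        self._exact = {bc: sid for bc, sid in self.barcodes}
        for i, (b1, s1) in enumerate(self.barcodes):
            for b2, s2 in self.barcodes[i + 1 :]:
                if hamming(b1, b2) <= 2 * self.max_mismatch:
                    raise PanelError(
                        f"barcodes of {s1} and {s2} collide at "
                        f"max_mismatch={self.max_mismatch}"
                    )

    def assign(self, read: Read) -> tuple[str | None, Read]:
        """Returns (sample_id or None, read with the barcode region removed
        when assigned)."""
        bc = read.seq[:BARCODE_LEN]
        sid = self._exact.get(bc)
        if sid is None and self.max_mismatch > 0 and len(bc) == BARCODE_LEN:
            for cand, cand_sid in self.barcodes:
                if hamming(bc, cand) <= self.max_mismatch:
                    sid = cand_sid
                    break  # uniqueness guaranteed by the collision check
        if sid is None:
            return None, read
        return sid, Read(read.name, read.seq[BARCODE_LEN:], read.qual[BARCODE_LEN:])


def demultiplex(
    reads: Iterable[Read],
    samples: SampleSheet,
    max_mismatch: int = 0,
) -> tuple[dict[str, list[Read]], list[Read], DemuxReport]:
    """De-index a pooled read stream into per-sample bins.

    Every read is either assigned to the unique sample whose barcode matches
    its leading 10 nt within ``max_mismatch``, or lands in the unassigned
    bin; assigned + unassigned equals the input count.
    """
    assigner = BarcodeAssigner(samples, max_mismatch)
    out: dict[str, list[Read]] = {r.sample_id: [] for r in samples}
    unassigned: list[Read] = []
    report = DemuxReport(assigned={r.sample_id: 0 for r in samples})
    for read in reads:
        sid, trimmed = assigner.assign(read)
        if sid is None:
            unassigned.append(read)
            report.unassigned += 1
        else:
            out[sid].append(trimmed)
            report.assigned[sid] += 1
    return out, unassigned, report


def _prefix_matches(seq: str, adapter: str, max_frac: float) -> bool:
    if len(seq) < len(adapter):
        return False
    return hamming(seq[: len(adapter)], adapter) <= int(max_frac * len(adapter))


def _suffix_matches(seq: str, adapter: str, max_frac: float) -> bool:
    if len(seq) < len(adapter):
        return False
    return hamming(seq[-len(adapter) :], adapter) <= int(max_frac * len(adapter))


def trim_read(
    read: Read,
    cs1: str = CS1,
    cs2: str = CS2,
    max_mismatch_frac: float = 0.1,
) -> tuple[Read, bool]:
    """Remove the CS1 prefix and the revcomp(CS2) suffix from a read.

    Qualities are trimmed in register with bases.  Returns the trimmed read
    and a flag: True when at least one adapter was found.  Reads with no
    adapter match pass through untouched (flagged False).
    """
    seq, qual = read.seq, read.qual
    found = False
    if cs1 and _prefix_matches(seq, cs1, max_mismatch_frac):
        seq, qual = seq[len(cs1) :], qual[len(cs1) :]
        found = True
    cs2_rc = revcomp(cs2) if cs2 else ""
    if cs2_rc and _suffix_matches(seq, cs2_rc, max_mismatch_frac):
        seq, qual = seq[: -len(cs2_rc)], qual[: -len(cs2_rc)]
        found = True
    return Read(read.name, seq, qual), found


def trim_and_filter(
    reads: Iterable[Read],
    cs1: str = CS1,
    cs2: str = CS2,
    min_len: int = 20,
    max_mismatch_frac: float = 0.1,
    report: DemuxReport | None = None,
) -> list[Read]:
    """Adapter-trim a read collection and drop reads shorter than ``min_len``."""
    out = []
    for read in reads:
        trimmed, found = trim_read(read, cs1, cs2, max_mismatch_frac)
        if report is not None:
            if found:
                report.trimmed += 1
            else:
                report.untrimmed += 1
        if len(trimmed.seq) < min_len:
            if report is not None:
                report.removed_short += 1
            continue
        out.append(trimmed)
    return out
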