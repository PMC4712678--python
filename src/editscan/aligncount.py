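"""Amplicon assignment, banded semi-global alignment, and quality pileup.

Reads are aligned only against the panel's amplicon inserts (the targets are
known), with a banded Needleman–Wunsch variant: the read must be consumed in
full, leading/trailing amplicon bases are free (free end-gaps on the
reference), and gaps are affine-scored.  Defaults (match +1, mismatch -3,
gap open -3, gap extend -1, score floor at half the read length) are chosen
to tolerate the small homopolymer indels typical of Ion-Torrent chemistry
while rejecting foreign sequence.

A read is assigned to the best-scoring amplicon; a score tie between the top
two amplicons marks the read multi-mapping and it is omitted, as is any read
whose best score falls below the floor.  Candidate amplicons are preselected
by exact 20-mer seeds (falling back to exhaustive scoring when no seed
hits), so a read is normally scored against one or two inserts only.

The pileup tallies, per (sample, site), the read bases aligned to the site's
insert offset with base quality ≥ 20; site columns deleted in a read
contribute nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
from numba import njit

from .panel import Amplicon, Panel

__all__ = [
    "Scoring",
    "AlignedRead",
    "Rejection",
    "AmpliconIndex",
    "align_to_amplicons",
    "PileupCounts",
    "pileup",
    "write_sam",
    "encode_seq",
]

_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i
    _LUT[_b + 32] = _i  # lower case

BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
NEG = -(1 << 28)


def encode_seq(seq: str) -> np.ndarray:
    """DNA string → uint8 codes (A0 C1 G2 T3, other 4)."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class Scoring:
    match: int = 1
    mismatch: int = -3
    gap_open: int = -3
    gap_extend: int = -1


@njit(cache=True)
def _sg_score(read, ref, match, mismatch, go, ge, w):  # pragma: no cover - jit
    """Banded affine semi-global score (free end-gaps on ``ref``).

    Band: for read row i, reference columns j = i + d - w + shift with
    d in [0, 2w] and shift = (m - n) // 2.
    """
    n = read.shape[0]
    m = ref.shape[0]
    shift = (m - n) // 2
    width = 2 * w + 1
    Mp = np.empty(width, np.int32)
    Xp = np.empty(width, np.int32)
    Yp = np.empty(width, np.int32)
    Mc = np.empty(width, np.int32)
    Xc = np.empty(width, np.int32)
    Yc = np.empty(width, np.int32)
    for d in range(width):
        j = d - w + shift
        Mp[d] = 0 if (0 <= j <= m) else NEG
        Xp[d] = NEG
        Yp[d] = NEG
    for i in range(1, n + 1):
        for d in range(width):
            j = i + d - w + shift
            if j < 0 or j > m:
                Mc[d] = NEG
                Xc[d] = NEG
                Yc[d] = NEG
                continue
            x = NEG
            if d + 1 < width:
                a = Mp[d + 1] + go
                b = Xp[d + 1] + ge
                x = a if a > b else b
            Xc[d] = x
            y = NEG
            if d >= 1:
                a = Mc[d - 1] + go
                b = Yc[d - 1] + ge
                y = a if a > b else b
            Yc[d] = y
            mm = NEG
            if j >= 1:
                diag = Mp[d]
                if Xp[d] > diag:
                    diag = Xp[d]
                if Yp[d] > diag:
                    diag = Yp[d]
                if diag > NEG // 2:
                    s = match if read[i - 1] == ref[j - 1] else mismatch
                    mm = diag + s
            Mc[d] = mm
        for d in range(width):
            Mp[d] = Mc[d]
            Xp[d] = Xc[d]
            Yp[d] = Yc[d]
    best = NEG
    for d in range(width):
        if Mp[d] > best:
            best = Mp[d]
        if Xp[d] > best:
            best = Xp[d]
    return best


@njit(cache=True)
def _sg_traceback(read, ref, match, mismatch, go, ge, w):  # pragma: no cover
    """As ``_sg_score`` but with full band matrices and traceback.

    Returns (score, ref_start, ops, n_ops); ops codes: 0 = aligned pair,
    1 = insertion (read base, gap in ref), 2 = deletion (ref base, gap in
    read), listed 5'→3'.  Score ties prefer aligned pairs, then insertions,
    placing gaps toward the read 5' end deterministically.
    """
    n = read.shape[0]
    m = ref.shape[0]
    shift = (m - n) // 2
    width = 2 * w + 1
    M = np.full((n + 1, width), NEG, np.int32)
    X = np.full((n + 1, width), NEG, np.int32)
    Y = np.full((n + 1, width), NEG, np.int32)
    PM = np.zeros((n + 1, width), np.int8)  # predecessor layer of the diag step
    PX = np.zeros((n + 1, width), np.int8)  # 0 open-from-M, 1 extend
    PY = np.zeros((n + 1, width), np.int8)
    for d in range(width):
        j = d - w + shift
        if 0 <= j <= m:
            M[0, d] = 0
    for i in range(1, n + 1):
        for d in range(width):
            j = i + d - w + shift
            if j < 0 or j > m:
                continue
            if d + 1 < width:
                a = M[i - 1, d + 1] + go
                b = X[i - 1, d + 1] + ge
                if a >= b:
                    X[i, d] = a
                    PX[i, d] = 0
                else:
                    X[i, d] = b
                    PX[i, d] = 1
            if d >= 1:
                a = M[i, d - 1] + go
                b = Y[i, d - 1] + ge
                if a >= b:
                    Y[i, d] = a
                    PY[i, d] = 0
                else:
                    Y[i, d] = b
                    PY[i, d] = 1
            if j >= 1:
                diag = M[i - 1, d]
                lay = 0
                if X[i - 1, d] > diag:
                    diag = X[i - 1, d]
                    lay = 1
                if Y[i - 1, d] > diag:
                    diag = Y[i - 1, d]
                    lay = 2
                if diag > NEG // 2:
                    s = match if read[i - 1] == ref[j - 1] else mismatch
                    M[i, d] = diag + s
                    PM[i, d] = lay
    best = NEG
    bd = 0
    blay = 0
    for d in range(width):
        j = n + d - w + shift
        if j < 0 or j > m:
            continue
        if M[n, d] >= best:
            if M[n, d] > best or blay != 0:
                best = M[n, d]
                bd = d
                blay = 0
        if X[n, d] > best:
            best = X[n, d]
            bd = d
            blay = 1
    ops = np.empty(n + m + 1, np.int8)
    k = 0
    i = n
    d = bd
    lay = blay
    while i > 0 or lay != 0:
        if lay == 0:
            ops[k] = 0
            k += 1
            nl = PM[i, d]
            i -= 1
            lay = nl
        elif lay == 1:
            ops[k] = 1
            k += 1
            nl = 0 if PX[i, d] == 0 else 1
            i -= 1
            d += 1
            lay = nl
        else:
            ops[k] = 2
            k += 1
            nl = 0 if PY[i, d] == 0 else 2
            d -= 1
            lay = nl
    ref_start = d - w + shift  # i == 0 here
    ops[:k] = ops[:k][::-1]
    return best, ref_start, ops, k


@dataclass
class AlignedRead:
    read_id: str
    amplicon_id: str
    seq: str
    qual: str
    score: int
    ref_start: int
    cigar: list[tuple[str, int]]  # M/I/D run-length ops, read 5'→3'
    site_read_pos: dict[str, int]  # site_id → read index, -1 if deleted/uncovered
    unique: bool = True

    def aligned_pairs(self) -> Iterator[tuple[int, int]]:
        """(read_pos, ref_pos) for every aligned (M) column."""
        i, j = 0, self.ref_start
        for op, length in self.cigar:
            if op == "M":
                for k in range(length):
                    yield i + k, j + k
                i += length
                j += length
            elif op == "I":
                i += length
            else:
                j += length


@dataclass(frozen=True)
class Rejection:
    read_id: str
    reason: str  # "multimap" | "low_score" | "no_candidate"


class AmpliconIndex:
    """Encoded amplicon inserts plus an exact k-mer lookup for candidate
    preselection (k mirrors a typical primer/seed length)."""

    def __init__(self, panel: Panel, k: int = 20, stride: int = 10):
        self.panel = panel
        self.k = k
        self.stride = stride
        self.ids: list[str] = list(panel.amplicons)
        self.encoded: list[np.ndarray] = [
            encode_seq(panel.amplicons[a].insert) for a in self.ids
        ]
        self.site_offsets: list[dict[str, int]] = [
            dict(panel.amplicons[a].site_offsets) for a in self.ids
        ]
        self._kmers: dict[str, set[int]] = {}
        for idx, aid in enumerate(self.ids):
            ins = panel.amplicons[aid].insert.upper()
            for p in range(0, max(1, len(ins) - k + 1)):
                self._kmers.setdefault(ins[p : p + k], set()).add(idx)

    def candidates(self, seq: str) -> list[int]:
        hits: set[int] = set()
        up = seq.upper()
        for p in range(0, max(1, len(up) - self.k + 1), self.stride):
            got = self._kmers.get(up[p : p + self.k])
            if got:
                hits |= got
        return sorted(hits) if hits else list(range(len(self.ids)))


def _site_positions(
    ops: np.ndarray, n_ops: int, ref_start: int, offsets: dict[str, int]
) -> dict[str, int]:
    """Read index aligned to each site offset; -1 when deleted or uncovered."""
    out = {sid: -1 for sid in offsets}
    wanted = sorted((off, sid) for sid, off in offsets.items())
    if not wanted:
        return out
    i, j = 0, ref_start
    widx = 0
    # skip sites before the alignment start
    while widx < len(wanted) and wanted[widx][0] < ref_start:
        widx += 1
    for t in range(n_ops):
        if widx >= len(wanted):
            break
        op = ops[t]
        if op == 0:
            while widx < len(wanted) and wanted[widx][0] == j:
                out[wanted[widx][1]] = i
                widx += 1
            i += 1
            j += 1
        elif op == 1:
            i += 1
        else:
            while widx < len(wanted) and wanted[widx][0] == j:
                widx += 1  # site column deleted in this read
            j += 1
    return out


def _ops_to_cigar(ops: np.ndarray, n_ops: int) -> list[tuple[str, int]]:
    names = ("M", "I", "D")
    cigar: list[tuple[str, int]] = []
    for t in range(n_ops):
        op = names[ops[t]]
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + 1)
        else:
            cigar.append((op, 1))
    return cigar


def align_to_amplicons(
    read,
    index: AmpliconIndex,
    scoring: Scoring = Scoring(),
    band: int = 16,
    min_score_frac: float = 0.5,
    exhaustive: bool = False,
) -> AlignedRead | Rejection:
    """Score a read against candidate amplicons and align it to the winner.

    Rejects the read when the top two amplicon scores tie (multi-mapping, as
    the study omitted multiply-aligned reads) or when the best score is
    below ``min_score_frac`` of the read length.
    """
    if not index.ids:
        raise ValueError("empty amplicon set")
    enc = encode_seq(read.seq)
    n = enc.shape[0]
    cand = (
        list(range(len(index.ids))) if exhaustive else index.candidates(read.seq)
    )
    scores = []
    for idx in cand:
        ref = index.encoded[idx]
        w = band + abs(ref.shape[0] - n) // 2 + 1
        scores.append(
            int(
                _sg_score(
                    enc, ref, scoring.match, scoring.mismatch,
                    scoring.gap_open, scoring.gap_extend, w,
                )
            )
        )
    order = sorted(range(len(cand)), key=lambda q: (-scores[q], cand[q]))
    best = order[0]
    if scores[best] < min_score_frac * n:
        return Rejection(read.name, "low_score")
    if len(order) > 1 and scores[order[1]] == scores[best]:
        return Rejection(read.name, "multimap")
    idx = cand[best]
    ref = index.encoded[idx]
    w = band + abs(ref.shape[0] - n) // 2 + 1
    score, ref_start, ops, n_ops = _sg_traceback(
        enc, ref, scoring.match, scoring.mismatch,
        scoring.gap_open, scoring.gap_extend, w,
    )
    return AlignedRead(
        read_id=read.name,
        amplicon_id=index.ids[idx],
        seq=read.seq,
        qual=read.qual,
        score=int(score),
        ref_start=int(ref_start),
        cigar=_ops_to_cigar(ops, n_ops),
        site_read_pos=_site_positions(ops, n_ops, int(ref_start),
                                      index.site_offsets[idx]),
    )


class PileupCounts:
    """Per-(sample, site) quality-filtered base counts (A, C, G, T)."""

    def __init__(self):
        self.counts: dict[tuple[str, str], np.ndarray] = {}

    def add(self, sample_id: str, site_id: str, base: str, q: int, q_min: int):
        if q < q_min:
            return
        idx = BASE_INDEX.get(base.upper())
        if idx is None:
            return
        key = (sample_id, site_id)
        arr = self.counts.get(key)
        if arr is None:
            arr = np.zeros(4, dtype=np.int64)
            self.counts[key] = arr
        arr[idx] += 1

    def cell(self, sample_id: str, site_id: str) -> np.ndarray:
        return self.counts.get((sample_id, site_id), np.zeros(4, dtype=np.int64))

    def to_frame(self):
        import pandas as pd

        rows = [
            (s, t, int(c[0]), int(c[1]), int(c[2]), int(c[3]), int(c.sum()))
            for (s, t), c in sorted(self.counts.items())
        ]
        return pd.DataFrame(
            rows,
            columns=["sample_id", "site_id", "nA", "nC", "nG", "nT", "depth"],
        )


def pileup(
    aligned: Iterable[tuple[str, AlignedRead]],
    panel: Panel,
    q_min: int = 20,
    counts: PileupCounts | None = None,
) -> PileupCounts:
    """Accumulate quality-filtered base counts at every panel site.

    ``aligned`` yields (sample_id, AlignedRead); a read contributes at a
    site iff the site column is aligned (not deleted) and the base quality
    is at least ``q_min``.
    """
    counts = PileupCounts() if counts is None else counts
    for sample_id, ar in aligned:
        for sid, rpos in ar.site_read_pos.items():
            if rpos < 0:
                continue
            counts.add(
                sample_id, sid, ar.seq[rpos], ord(ar.qual[rpos]) - 33, q_min
            )
    return counts


def write_sam(
    aligned: Iterable[AlignedRead], panel: Panel, path, sample_id: str | None = None
) -> None:
    """Export alignments as SAM with amplicon inserts as reference sequences."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [
            {"SN": aid, "LN": len(amp.insert)}
            for aid, amp in panel.amplicons.items()
        ],
    }
    ref_ids = {aid: i for i, aid in enumerate(panel.amplicons)}
    opmap = {"M": 0, "I": 1, "D": 2}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for ar in aligned:
            a = pysam.AlignedSegment(out.header)
            a.query_name = ar.read_id
            a.query_sequence = ar.seq
            a.query_qualities = pysam.qualitystring_to_array(ar.qual)
            a.reference_id = ref_ids[ar.amplicon_id]
            a.reference_start = ar.ref_start
            a.cigartuples = [(opmap[op], ln) for op, ln in ar.cigar]
            a.mapping_quality = 60
            if sample_id:
                a.set_tag("RG", sample_id)
            out.write(a)
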