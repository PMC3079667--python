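"""Semi-global read-to-amplicon alignment and strand-aware pileup.

Each demultiplexed insert is aligned to its amplicon's reference insert by
affine-gap dynamic programming (Gotoh) with free end-gaps on the read only,
so a truncated read simply starts or ends inside the insert without
penalty. The tie-break order (match/mismatch over deletion over insertion)
is fixed, and indel events are left-normalized against the reference before
entering the pileup, so identical events from different reads aggregate at
one canonical anchor.

Scoring defaults: match +1, mismatch -1, gap open -2, gap extend -1 (a
length-k gap costs 2 + (k-1)). Reads whose alignment identity falls below
70% are excluded from the pileup and tallied in a QC ledger.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from numba import njit

from .core_model import AmpliconDef, DesignError, PanelDef, ReferenceSequence
from .demultiplex import DemuxedRead
from .synthetic_data import left_normalize

_NEG = -(2**28)

# op codes in traceback output
_OP_MATCH, _OP_MISMATCH, _OP_DEL, _OP_INS = 0, 1, 2, 3

_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i


@dataclass(frozen=True)
class Scoring:
    match: int = 1
    mismatch: int = -1
    gap_open: int = -2
    gap_extend: int = -1
    min_identity: float = 0.70
    max_length_ratio: float = 2.0


DEFAULT_SCORING = Scoring()


def encode(seq: str) -> np.ndarray:
    arr = _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr < 0).any():
        raise DesignError("sequence contains non-ACGT characters")
    return arr


@njit(cache=False)
def _gotoh_fill(read, ref, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    m, n = read.shape[0], ref.shape[0]
    C = np.empty((m + 1, n + 1), dtype=np.int32)
    E = np.empty((m + 1, n + 1), dtype=np.int32)
    F = np.empty((m + 1, n + 1), dtype=np.int32)
    for j in range(n + 1):
        C[0, j] = 0  # free leading gap in the read (ref prefix skipped)
        E[0, j] = _NEG
        F[0, j] = _NEG
    for i in range(1, m + 1):
        E[i, 0] = _NEG
        F[i, 0] = gap_open + (i - 1) * gap_extend
        C[i, 0] = F[i, 0]
    for i in range(1, m + 1):
        ri = read[i - 1]
        for j in range(1, n + 1):
            s = match if ri == ref[j - 1] else mismatch
            diag = C[i - 1, j - 1] + s
            e = C[i, j - 1] + gap_open
            e2 = E[i, j - 1] + gap_extend
            if e2 > e:
                e = e2
            E[i, j] = e
            f = C[i - 1, j] + gap_open
            f2 = F[i - 1, j] + gap_extend
            if f2 > f:
                f = f2
            F[i, j] = f
            best = diag
            if e > best:
                best = e
            if f > best:
                best = f
            C[i, j] = best
    return C, E, F


@njit(cache=False)
def _gotoh_traceback(read, ref, C, E, F, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    m, n = read.shape[0], ref.shape[0]
    # rightmost column maximising the final row (free trailing gap in read)
    jstar = n
    best = C[m, n]
    for j in range(n, -1, -1):
        if C[m, j] > best:
            best = C[m, j]
            jstar = j
    ops = np.empty((m + n + 2, 3), dtype=np.int64)  # (op, ref_pos 1-based, read_pos 1-based)
    k = 0
    i, j = m, jstar
    state = 0  # 0=C, 1=E, 2=F
    while i > 0:
        if state == 0:
            if j > 0:
                s = match if read[i - 1] == ref[j - 1] else mismatch
                if C[i, j] == C[i - 1, j - 1] + s:
                    op = _OP_MATCH if read[i - 1] == ref[j - 1] else _OP_MISMATCH
                    ops[k, 0] = op
                    ops[k, 1] = j
                    ops[k, 2] = i
                    k += 1
                    i -= 1
                    j -= 1
                    continue
                if C[i, j] == E[i, j]:
                    state = 1
                    continue
            state = 2
        elif state == 1:  # gap in read: ref base j deleted
            ops[k, 0] = _OP_DEL
            ops[k, 1] = j
            ops[k, 2] = 0
            k += 1
            if E[i, j] == C[i, j - 1] + gap_open:
                state = 0
            j -= 1
        else:  # gap in ref: read base i inserted
            ops[k, 0] = _OP_INS
            ops[k, 1] = j
            ops[k, 2] = i
            k += 1
            if F[i, j] == C[i - 1, j] + gap_open:
                state = 0
            i -= 1
    return best, jstar, ops[:k][::-1].copy()


@dataclass
class AlignmentResult:
    """One read-to-amplicon alignment, in amplicon-global coordinates.

    ``ops`` is a list of (op, ref_pos, read_pos) with op in
    {'=', 'X', 'D', 'I'}; ref_pos is the 1-based reference position
    (for 'I', the reference base the insertion follows), read_pos the
    1-based read position (0 for 'D').
    """

    read_id: str
    amplicon_index: int
    score: int
    ops: list[tuple[str, int, int]]
    matches: int
    mismatches: int
    gap_columns: int
    unalignable: bool = False

    @property
    def identity(self) -> float:
        cols = self.matches + self.mismatches + self.gap_columns
        return self.matches / cols if cols else 0.0

    @property
    def ref_span(self) -> tuple[int, int]:
        """1-based inclusive reference span covered by aligned columns."""
        refpos = [p for op, p, _ in self.ops if op in ("=", "X", "D")]
        return (min(refpos), max(refpos)) if refpos else (0, -1)


_OP_CHARS = {_OP_MATCH: "=", _OP_MISMATCH: "X", _OP_DEL: "D", _OP_INS: "I"}


def align_read(
    insert: str,
    amplicon: AmpliconDef,
    reference: ReferenceSequence,
    scoring: Scoring = DEFAULT_SCORING,
    read_id: str = "",
) -> AlignmentResult:
    """Optimal semi-global alignment of one insert to its amplicon.

    Deterministic: on score ties the traceback prefers match/mismatch over
    deletion over insertion, and the rightmost end column. Inserts longer
    than ``max_length_ratio`` times the amplicon are flagged unalignable.
    """
    if not insert:
        raise DesignError("cannot align an empty insert")
    ref_seq = amplicon.insert_sequence(reference)
    if len(insert) > scoring.max_length_ratio * len(ref_seq):
        return AlignmentResult(read_id, amplicon.index, 0, [], 0, 0, 0, unalignable=True)
    read_arr = encode(insert)
    ref_arr = encode(ref_seq)
    C, E, F = _gotoh_fill(
        read_arr, ref_arr, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
    )
    score, _, raw_ops = _gotoh_traceback(
        read_arr, ref_arr, C, E, F,
        scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend,
    )
    offset = amplicon.ref_start - 1
    ops: list[tuple[str, int, int]] = []
    matches = mismatches = gaps = 0
    for op_code, ref_pos, read_pos in raw_ops:
        op = _OP_CHARS[int(op_code)]
        if op == "=":
            matches += 1
        elif op == "X":
            mismatches += 1
        else:
            gaps += 1
        ops.append((op, int(ref_pos) + offset, int(read_pos)))
    return AlignmentResult(
        read_id=read_id,
        amplicon_index=amplicon.index,
        score=int(score),
        ops=ops,
        matches=matches,
        mismatches=mismatches,
        gap_columns=gaps,
    )


def alignment_events(
    aln: AlignmentResult, insert: str, reference: ReferenceSequence, amplicon: AmpliconDef
) -> tuple[list[tuple[int, str, str]], list[tuple[int, str]], list[tuple[int, str]]]:
    """Extract (substitutions, deletions, insertions) from an alignment.

    Substitutions: (ref_pos, ref_base, alt_base). Deletions: (anchor = first
    deleted ref_pos, deleted seq). Insertions: (ref base followed, inserted
    seq). Indels are left-normalized; normalization never crosses the
    insert's boundary into a primer site.
    """
    subs: list[tuple[int, str, str]] = []
    dels: list[tuple[int, str]] = []
    ins: list[tuple[int, str]] = []
    pending_del: list[tuple[int, str]] = []
    pending_ins: list[tuple[int, str]] = []

    def flush_del() -> None:
        if pending_del:
            anchor = pending_del[0][0]
            seq = "".join(b for _, b in pending_del)
            pos, ref_a, _ = left_normalize(anchor, seq, "", reference.bases)
            if pos < amplicon.ref_start:
                pos, ref_a = anchor, seq
            dels.append((pos, ref_a))
            pending_del.clear()

    def flush_ins() -> None:
        if pending_ins:
            after = pending_ins[0][0]
            seq = "".join(b for _, b in pending_ins)
            pos, _, alt = left_normalize(after, "", seq, reference.bases)
            if pos < amplicon.ref_start - 1:
                pos, alt = after, seq
            ins.append((pos, alt))
            pending_ins.clear()

    for op, ref_pos, read_pos in aln.ops:
        if op == "D":
            flush_ins()
            pending_del.append((ref_pos, reference.bases[ref_pos - 1]))
        elif op == "I":
            flush_del()
            pending_ins.append((ref_pos, insert[read_pos - 1]))
        else:
            flush_del()
            flush_ins()
            if op == "X":
                subs.append((ref_pos, reference.bases[ref_pos - 1], insert[read_pos - 1]))
    flush_del()
    flush_ins()
    return subs, dels, ins


# ---------------------------------------------------------------------------
# Pileup
# ---------------------------------------------------------------------------

DELETION_MARK = "*"


@dataclass
class Pileup:
    """Per (sample, amplicon, 1-based position, strand) allele counts.

    ``base_counts`` tallies aligned bases plus a spanning-deletion mark per
    deleted position; multi-base deletion and insertion *events* live in
    separate ledgers keyed by their canonical anchor and full sequence, so a
    2-bp event is one event, not two.
    """

    base_counts: dict[tuple[str, int, int, str], dict[str, int]] = field(default_factory=dict)
    deletion_events: dict[tuple[str, int, int, str, str], int] = field(default_factory=dict)
    insertion_events: dict[tuple[str, int, int, str, str], int] = field(default_factory=dict)
    n_reads: int = 0
    qc_excluded: int = 0

    def _bump(self, sample: str, amp: int, pos: int, strand: str, allele: str) -> None:
        key = (sample, amp, pos, strand)
        d = self.base_counts.setdefault(key, {})
        d[allele] = d.get(allele, 0) + 1

    def depth(self, sample: str, pos: int, strand: Optional[str] = None) -> int:
        """Covering reads at a position (spanning deletions included)."""
        total = 0
        for (s, _a, p, st), counts in self.base_counts.items():
            if s == sample and p == pos and (strand is None or st == strand):
                total += sum(counts.values())
        return total

    def allele_count(
        self, sample: str, pos: int, allele: str, strand: Optional[str] = None
    ) -> int:
        total = 0
        for (s, _a, p, st), counts in self.base_counts.items():
            if s == sample and p == pos and (strand is None or st == strand):
                total += counts.get(allele, 0)
        return total

    def total_base_count(self) -> int:
        """Sum of all non-insertion counters (conservation checks)."""
        return sum(sum(c.values()) for c in self.base_counts.values())


def build_pileup(
    demuxed: Iterable[DemuxedRead],
    panel: PanelDef,
    reference: ReferenceSequence,
    scoring: Scoring = DEFAULT_SCORING,
) -> Pileup:
    """Align every demultiplexed read and accumulate the pileup.

    Every aligned base, spanned deletion position and insertion event
    increments exactly one counter; reads below the identity cutoff (or
    unalignable) go to the QC ledger instead. Accumulation is commutative,
    so the pileup is independent of read order.
    """
    pileup = Pileup()
    for read in demuxed:
        try:
            amplicon = panel.by_index(read.amplicon_index)
        except KeyError as exc:
            raise DesignError(f"read {read.read_id}: unknown amplicon") from exc
        aln = align_read(read.insert, amplicon, reference, scoring, read_id=read.read_id)
        if aln.unalignable or aln.identity < scoring.min_identity:
            pileup.qc_excluded += 1
            continue
        pileup.n_reads += 1
        s, amp, strand = read.sample_id, read.amplicon_index, read.strand
        for op, ref_pos, read_pos in aln.ops:
            if op in ("=", "X"):
                pileup._bump(s, amp, ref_pos, strand, read.insert[read_pos - 1])
            elif op == "D":
                pileup._bump(s, amp, ref_pos, strand, DELETION_MARK)
        _, dels, ins = alignment_events(aln, read.insert, reference, amplicon)
        for pos, seq in dels:
            key = (s, amp, pos, seq, strand)
            pileup.deletion_events[key] = pileup.deletion_events.get(key, 0) + 1
        for pos, seq in ins:
            key = (s, amp, pos, seq, strand)
            pileup.insertion_events[key] = pileup.insertion_events.get(key, 0) + 1
    return pileup


def consensus(pileup: Pileup, sample_id: str, amplicon: AmpliconDef) -> str:
    """Majority-allele consensus over one sample's amplicon (ties broken
    alphabetically; deletion mark wins only on strict majority)."""
    out = []
    merged_ins = _merged_insertions(pileup)
    for pos in range(amplicon.ref_start, amplicon.ref_end + 1):
        counts: dict[str, int] = {}
        for st in ("fwd", "rev"):
            c = pileup.base_counts.get((sample_id, amplicon.index, pos, st), {})
            for allele, n in c.items():
                counts[allele] = counts.get(allele, 0) + n
        if not counts:
            continue
        allele = max(sorted(counts), key=lambda a: counts[a])
        if allele != DELETION_MARK:
            out.append(allele)
        # insertions following this position, on strict majority of depth
        depth_here = sum(counts.values())
        for (s, a, p, seq, _st), n in merged_ins.items():
            if s == sample_id and a == amplicon.index and p == pos and n * 2 > depth_here:
                out.append(seq)
    return "".join(out)


def _merged_insertions(pileup: Pileup) -> dict[tuple[str, int, int, str, str], int]:
    merged: dict[tuple[str, int, int, str, str], int] = {}
    for (s, a, p, seq, _st), n in pileup.insertion_events.items():
        key = (s, a, p, seq, "*")
        merged[key] = merged.get(key, 0) + n
    return merged


def supporting_coverage(
    pileup: Pileup,
    position: int,
    ref_allele: str,
    alt_allele: str,
    sample_id: str,
    strand: Optional[str] = None,
) -> int:
    """Reads of one sample truly showing the alternate allele at a site —
    reads covering the site but showing the reference (or anything else) are
    excluded. Substitutions count alt bases; indel events count canonical
    ledger entries."""
    if ref_allele and alt_allele:  # substitution
        found = False
        for (s, _a, p, st) in pileup.base_counts:
            if s == sample_id and p == position:
                found = True
                break
        if not found:
            raise KeyError(f"sample {sample_id} has no coverage at {position}")
        return pileup.allele_count(sample_id, position, alt_allele, strand)
    total = 0
    ledger = pileup.deletion_events if not alt_allele else pileup.insertion_events
    seq = ref_allele or alt_allele
    for (s, _a, p, ev_seq, st), n in ledger.items():
        if s == sample_id and p == position and ev_seq == seq:
            if strand is None or st == strand:
                total += n
    return total


def write_pileup_tsv(pileup: Pileup, path: str | Path) -> None:
    """Serialise base counts as TSV (sample, amplicon, pos, strand, A, C, G,
    T, del, depth) for inspection."""
    import pandas as pd

    rows = []
    for (s, a, p, st), counts in sorted(pileup.base_counts.items()):
        row = {"sample": s, "amplicon": a, "pos": p, "strand": st}
        for allele in "ACGT":
            row[allele] = counts.get(allele, 0)
        row["del"] = counts.get(DELETION_MARK, 0)
        row["depth"] = sum(counts.values())
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
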