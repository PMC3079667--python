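"""Combinatorial dual-MID demultiplexing and primer-based amplicon routing.

A read is assigned to a sample only when *both* terminal MIDs decode — the
traceability contract of combinatorial barcoding: a read missing either tag
cannot be attributed and is dropped, never rescued from a single tag.
Decoding tolerates up to 2 edit-distance errors per MID; because every MID
set has pairwise edit distance >= 5, any tie between two tags implies >= 3
errors and the read is left unassigned rather than guessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import edlib
import pandas as pd

from .core_model import (
    AmpliconDef,
    DesignError,
    ExperimentDesign,
    MID_LENGTH,
    MidTag,
    PanelDef,
    revcomp,
)

#: Up to 2 sequencing errors in a MID are corrected.
DEFAULT_MAX_MID_ERRORS = 2

#: Terminal window searched for a MID: MID length + 2, tolerating indels.
MID_WINDOW = MID_LENGTH + 2

#: Each primer may diverge from the read terminus by at most 2 edits.
DEFAULT_MAX_PRIMER_ERRORS = 2

_PRIMER_WINDOW_SLACK = 4

# Unassignment reason codes.
REASON_MISSING_MID = "missing-MID"
REASON_AMBIGUOUS_MID = "ambiguous-MID"
REASON_UNKNOWN_PAIR = "unknown-pair"
REASON_PRIMER_MISMATCH = "primer-mismatch"
REASON_NO_AMPLICON = "no-amplicon"
REASON_EMPTY_INSERT = "empty-insert"

ALL_REASONS = (
    REASON_MISSING_MID,
    REASON_AMBIGUOUS_MID,
    REASON_UNKNOWN_PAIR,
    REASON_PRIMER_MISMATCH,
    REASON_NO_AMPLICON,
    REASON_EMPTY_INSERT,
)


@dataclass(frozen=True)
class MidMatch:
    """A decoded terminal MID: the tag, its edit distance, and where the
    matched prefix ends inside the observed window (for trimming)."""

    tag: MidTag
    errors: int
    window: str
    end: int  # 0-based inclusive end of the match within the window


@dataclass(frozen=True)
class DemuxedRead:
    read_id: str
    sample_id: str
    amplicon_index: int
    strand: str  # 'fwd' | 'rev' relative to the reference
    insert: str  # reference-oriented, MIDs and primers trimmed
    mid_errors: tuple[int, int]


@dataclass(frozen=True)
class UnassignedRead:
    read_id: str
    reason: str


@dataclass
class DemuxReport:
    """Per-reason accounting of one demultiplexing run."""

    total: int = 0
    assigned: int = 0
    by_reason: dict[str, int] = field(default_factory=dict)
    per_sample_amplicon: dict[tuple[str, int], int] = field(default_factory=dict)
    rate_defined: bool = True

    @property
    def unassigned(self) -> int:
        return self.total - self.assigned

    @property
    def assignment_rate(self) -> float:
        """Assignment percentage (0.0, flagged undefined, on empty input)."""
        if self.total == 0:
            return 0.0
        return round(100.0 * self.assigned / self.total, 1)


def _match_mid_detail(
    window: str, tag_set: Sequence[MidTag], max_errors: int
) -> tuple[Optional[MidMatch], bool]:
    """(unique best match or None, whether a tie at the minimum was seen)."""
    if not tag_set:
        raise DesignError("empty MID tag set")
    best: Optional[MidMatch] = None
    best_d = max_errors + 1
    tied = False
    for tag in tag_set:
        res = edlib.align(tag.sequence, window, mode="SHW", task="locations", k=max_errors)
        d = res["editDistance"]
        if d < 0:
            continue
        if d < best_d:
            best_d = d
            best = MidMatch(tag=tag, errors=d, window=window, end=res["locations"][0][1])
            tied = False
        elif d == best_d:
            tied = True
    if tied:
        return None, True
    return best, False


def match_mid(
    window: str,
    tag_set: Sequence[MidTag],
    max_errors: int = DEFAULT_MAX_MID_ERRORS,
) -> Optional[MidMatch]:
    """Decode the MID present as a (possibly indel-shifted) prefix of
    ``window``: the unique tag at minimum edit distance <= ``max_errors``.
    Ties yield ``None`` — with pairwise tag distance >= 5 a tie implies more
    errors than the design corrects.
    """
    match, _ = _match_mid_detail(window, tag_set, max_errors)
    return match


def _decode_ends(
    seq: str,
    fwd_set: Sequence[MidTag],
    rev_set: Sequence[MidTag],
    max_errors: int,
) -> tuple[Optional[MidMatch], Optional[MidMatch], bool]:
    """Try to decode a forward-set MID at the head and a reverse-set MID at
    the tail (read as written, head window vs fwd tags, revcomp'd tail
    window vs rev tags). Returns (fwd, rev, saw_ambiguity)."""
    if len(seq) < 2 * MID_LENGTH:
        return None, None, False
    head = seq[:MID_WINDOW]
    tail = revcomp(seq[-MID_WINDOW:])
    fm, amb_f = _match_mid_detail(head, fwd_set, max_errors)
    rm, amb_r = _match_mid_detail(tail, rev_set, max_errors)
    return fm, rm, amb_f or amb_r


def identify_amplicon(
    core: str,
    panel: PanelDef,
    max_primer_errors: int = DEFAULT_MAX_PRIMER_ERRORS,
) -> Optional[tuple[AmpliconDef, int, int, bool]]:
    """Route a MID-trimmed, reference-oriented read to an amplicon by its
    primer pair (each primer within ``max_primer_errors`` edits of the read
    terminus). Returns (amplicon, fwd primer end, rev primer start, unique);
    ``None`` when no amplicon qualifies; unique=False flags a tie.
    """
    rc_core = revcomp(core)
    best: Optional[tuple[AmpliconDef, int, int]] = None
    best_d = None
    tied = False
    for amp in panel:
        wlen_f = len(amp.fwd_primer) + _PRIMER_WINDOW_SLACK
        wlen_r = len(amp.rev_primer) + _PRIMER_WINDOW_SLACK
        rf = edlib.align(
            amp.fwd_primer, core[:wlen_f], mode="SHW", task="locations", k=max_primer_errors
        )
        if rf["editDistance"] < 0:
            continue
        rr = edlib.align(
            amp.rev_primer, rc_core[:wlen_r], mode="SHW", task="locations", k=max_primer_errors
        )
        if rr["editDistance"] < 0:
            continue
        d = rf["editDistance"] + rr["editDistance"]
        fwd_end = rf["locations"][0][1]  # 0-based inclusive end in core
        rev_start = len(core) - 1 - rr["locations"][0][1]  # 0-based start in core
        if best_d is None or d < best_d:
            best_d, best, tied = d, (amp, fwd_end, rev_start), False
        elif d == best_d:
            tied = True
    if best is None:
        return None
    return best[0], best[1], best[2], not tied


def trim_tags(
    seq: str,
    fwd_match: MidMatch,
    rev_match: MidMatch,
    fwd_primer_end: int,
    rev_primer_start: int,
) -> str:
    """Cut MIDs and primer binding sites out of a reference-oriented read,
    leaving the insert (the only part counted in amplicon-size accounting).
    """
    core_start = fwd_match.end + 1
    core_end = len(seq) - (rev_match.end + 1)
    core = seq[core_start:core_end]
    insert = core[fwd_primer_end + 1 : rev_primer_start]
    if not insert:
        raise DesignError("read degenerates to an empty insert after trimming")
    return insert


def assign_read(
    read_id: str,
    seq: str,
    group_id: int,
    design: ExperimentDesign,
    max_mid_errors: int = DEFAULT_MAX_MID_ERRORS,
    max_primer_errors: int = DEFAULT_MAX_PRIMER_ERRORS,
) -> Union[DemuxedRead, UnassignedRead]:
    """Assign one read within its group (plate-region) context.

    Both read orientations are tested; a forward-set MID must decode at one
    end and a reverse-set MID at the other. The (fwd, rev) pair indexes the
    group's sample matrix; the primer pair then routes the read to its
    amplicon, and tags plus primers are trimmed off.
    """
    seq = seq.upper()
    any_ambiguous = False
    chosen: Optional[tuple[str, str, MidMatch, MidMatch]] = None
    for oriented, strand in ((seq, "fwd"), (revcomp(seq), "rev")):
        fm, rm, amb = _decode_ends(
            oriented, design.fwd_mid_set, design.rev_mid_set, max_mid_errors
        )
        any_ambiguous = any_ambiguous or amb
        if fm is not None and rm is not None:
            if chosen is not None:
                return UnassignedRead(read_id, REASON_AMBIGUOUS_MID)
            chosen = (oriented, strand, fm, rm)
    if chosen is None:
        reason = REASON_AMBIGUOUS_MID if any_ambiguous else REASON_MISSING_MID
        return UnassignedRead(read_id, reason)
    oriented, strand, fm, rm = chosen
    sample = design.lookup_pair(group_id, fm.tag.id, rm.tag.id)
    if sample is None:
        return UnassignedRead(read_id, REASON_UNKNOWN_PAIR)
    core_start = fm.end + 1
    core_end = len(oriented) - (rm.end + 1)
    core = oriented[core_start:core_end]
    hit = identify_amplicon(core, design.panel, max_primer_errors)
    if hit is None:
        return UnassignedRead(read_id, REASON_PRIMER_MISMATCH)
    amp, fwd_end, rev_start, unique = hit
    if not unique:
        return UnassignedRead(read_id, REASON_NO_AMPLICON)
    insert = core[fwd_end + 1 : rev_start]
    if not insert:
        return UnassignedRead(read_id, REASON_EMPTY_INSERT)
    return DemuxedRead(
        read_id=read_id,
        sample_id=sample.sample_id,
        amplicon_index=amp.index,
        strand=strand,
        insert=insert,
        mid_errors=(fm.errors, rm.errors),
    )


def demux_reads(
    reads: Iterable[tuple[str, str, int]],
    design: ExperimentDesign,
    max_mid_errors: int = DEFAULT_MAX_MID_ERRORS,
) -> tuple[list[DemuxedRead], list[UnassignedRead]]:
    """Demultiplex (read_id, sequence, group_id) triples."""
    assigned, unassigned = [], []
    for read_id, seq, group_id in reads:
        res = assign_read(read_id, seq, group_id, design, max_mid_errors)
        if isinstance(res, DemuxedRead):
            assigned.append(res)
        else:
            unassigned.append(res)
    return assigned, unassigned


def demux_stats(
    assigned: Sequence[DemuxedRead], unassigned: Sequence[UnassignedRead]
) -> DemuxReport:
    """Aggregate a run into per-reason counts and an assignment percentage
    (one decimal). Every input read lands in exactly one category."""
    report = DemuxReport(
        total=len(assigned) + len(unassigned),
        assigned=len(assigned),
        rate_defined=(len(assigned) + len(unassigned)) > 0,
    )
    for u in unassigned:
        report.by_reason[u.reason] = report.by_reason.get(u.reason, 0) + 1
    for d in assigned:
        key = (d.sample_id, d.amplicon_index)
        report.per_sample_amplicon[key] = report.per_sample_amplicon.get(key, 0) + 1
    return report


def write_demux_report(report: DemuxReport, path: str | Path) -> None:
    rows = [
        {"category": "total", "count": report.total},
        {"category": "assigned", "count": report.assigned},
        {"category": "assignment_rate_pct", "count": report.assignment_rate},
    ]
    for reason in ALL_REASONS:
        rows.append({"category": reason, "count": report.by_reason.get(reason, 0)})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
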