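"""The variant-validation cascade.

Candidates are every non-reference allele seen at least once in the pileup.
Validation then applies, in a fixed order: (a) rejection of the two
pyrosequencing artifact classes (homopolymer under-reads and carry-forward
insertions) unless overridden by very strong multi-sample evidence; (b) the
both-strand criterion — a sample's evidence counts only if the variant was
read on both DNA strands; (c) the replicate-support criterion — at least
90% of the sample's covering reads must show the variant AND more than 10
reads must support it, with a rescue clause for >=90%-supported samples
with <=10 reads when another sample passes outright; (d) the
multi-individual criterion — variants seen in only one individual are
uninformative and possibly PCR error, so at least 2 independent carriers
are required.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .core_model import PanelDef, ReferenceSequence
from .alignment_pileup import DELETION_MARK, Pileup

FLAG_HOMOPOLYMER = "homopolymer-underread"
FLAG_CARRY_FORWARD = "carry-forward"


@dataclass(frozen=True)
class FilterThresholds:
    """Cascade thresholds; defaults are the published criteria."""

    min_support_fraction: float = 0.90
    #: strict bound: a sample passes outright only with total support > this
    min_total_supporting_reads: int = 10
    min_carrier_individuals: int = 2
    min_hp_len: int = 3
    #: interpret ">10 in both read directions" as >10 per strand
    strict_direction: bool = False
    #: artifact-flag override (codified stand-in for manual flowgram review)
    override_fraction: float = 0.95
    override_reads: int = 20

    def __post_init__(self) -> None:
        if not 0.0 < self.min_support_fraction <= 1.0:
            raise ValueError("min_support_fraction must be in (0, 1]")
        if self.min_total_supporting_reads < 1 or self.min_carrier_individuals < 1:
            raise ValueError("count thresholds must be positive")


@dataclass(frozen=True)
class SampleEvidence:
    """One sample's strand-resolved evidence for one candidate."""

    fwd: int
    rev: int
    depth: int  # covering reads, both strands, after QC

    @property
    def total(self) -> int:
        return self.fwd + self.rev

    @property
    def fraction(self) -> float:
        return self.total / self.depth if self.depth else 0.0


@dataclass
class CandidateVariant:
    position: int
    ref_allele: str
    alt_allele: str
    evidence: dict[str, SampleEvidence]
    flags: set[str] = field(default_factory=set)

    @property
    def kind(self) -> str:
        if self.ref_allele and self.alt_allele:
            return "substitution"
        return "insertion" if self.alt_allele else "deletion"

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.position, self.ref_allele, self.alt_allele)


@dataclass
class ValidatedVariant:
    position: int
    ref_allele: str
    alt_allele: str
    kind: str
    classification: str  # transition | transversion | insertion | deletion
    carriers: tuple[str, ...]
    supporting: dict[str, int]  # per-carrier total supporting reads
    evidence: dict[str, SampleEvidence]
    multiallelic_group: Optional[int] = None

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.position, self.ref_allele, self.alt_allele)


@dataclass
class FilterTrace:
    """Survivor counts after each cascade stage (non-increasing)."""

    n_raw: int = 0
    n_after_artifact: int = 0
    n_after_both_strand: int = 0
    n_after_support: int = 0
    n_validated: int = 0
    rejection_reasons: dict[tuple[int, str, str], str] = field(default_factory=dict)

    @property
    def stage_counts(self) -> tuple[int, int, int, int, int]:
        return (
            self.n_raw,
            self.n_after_artifact,
            self.n_after_both_strand,
            self.n_after_support,
            self.n_validated,
        )


# ---------------------------------------------------------------------------
# Candidate enumeration
# ---------------------------------------------------------------------------


def enumerate_candidates(
    pileup: Pileup, reference: ReferenceSequence
) -> list[CandidateVariant]:
    """One candidate per (position, alternate allele) ever observed, with
    per-sample strand-resolved support and covering depth."""
    depth_index: dict[tuple[str, int], dict[str, int]] = {}
    support: dict[tuple[int, str, str], dict[str, dict[str, int]]] = {}
    for (sample, _amp, pos, strand), counts in pileup.base_counts.items():
        d = depth_index.setdefault((sample, pos), {"fwd": 0, "rev": 0})
        d[strand] += sum(counts.values())
        ref_base = reference.bases[pos - 1]
        for allele, n in counts.items():
            if allele == ref_base or allele == DELETION_MARK or n == 0:
                continue
            key = (pos, ref_base, allele)
            support.setdefault(key, {}).setdefault(sample, {"fwd": 0, "rev": 0})[
                strand
            ] += n
    for (sample, _amp, pos, seq, strand), n in pileup.deletion_events.items():
        key = (pos, seq, "")
        support.setdefault(key, {}).setdefault(sample, {"fwd": 0, "rev": 0})[strand] += n
    for (sample, _amp, pos, seq, strand), n in pileup.insertion_events.items():
        key = (pos, "", seq)
        support.setdefault(key, {}).setdefault(sample, {"fwd": 0, "rev": 0})[strand] += n
    candidates = []
    for key in sorted(support):
        pos = key[0]
        evidence = {}
        for sample, strands in support[key].items():
            depth = sum(depth_index.get((sample, pos), {}).values())
            evidence[sample] = SampleEvidence(
                fwd=strands["fwd"], rev=strands["rev"], depth=depth
            )
        candidates.append(
            CandidateVariant(
                position=key[0], ref_allele=key[1], alt_allele=key[2], evidence=evidence
            )
        )
    return candidates


# ---------------------------------------------------------------------------
# Artifact flagging
# ---------------------------------------------------------------------------


def _run_length_at(bases: str, pos: int) -> int:
    """Length of the maximal identical-base run containing 1-based pos."""
    b = bases[pos - 1]
    left = pos - 1
    while left > 0 and bases[left - 1] == b:
        left -= 1
    right = pos - 1
    while right + 1 < len(bases) and bases[right + 1] == b:
        right += 1
    return right - left + 1


def flag_artifacts(
    candidate: CandidateVariant,
    reference: ReferenceSequence,
    min_hp_len: int = 3,
) -> CandidateVariant:
    """Set artifact flags from the reference context.

    Homopolymer under-read: a 1-bp deletion inside or adjacent to a run of
    >= ``min_hp_len`` identical bases. Carry-forward: a 1-bp insertion whose
    base duplicates a reference base 1-2 positions upstream of the insertion
    site; because events are left-normalized, the duplicated reference base
    may appear immediately downstream of the canonical anchor, so that
    position is checked too.
    """
    flags = set(candidate.flags)
    bases = reference.bases
    if candidate.kind == "deletion" and len(candidate.ref_allele) == 1:
        pos = candidate.position
        runs = [_run_length_at(bases, pos)]
        if pos > 1:
            runs.append(_run_length_at(bases, pos - 1))
        if pos < len(bases):
            runs.append(_run_length_at(bases, pos + 1))
        if max(runs) >= min_hp_len:
            flags.add(FLAG_HOMOPOLYMER)
    if candidate.kind == "insertion" and len(candidate.alt_allele) == 1:
        c = candidate.alt_allele
        p = candidate.position  # the reference base the insertion follows
        context = []
        for q in (p - 1, p, p + 1):
            if 1 <= q <= len(bases):
                context.append(bases[q - 1])
        if c in context:
            flags.add(FLAG_CARRY_FORWARD)
    return replace_flags(candidate, flags)


def replace_flags(candidate: CandidateVariant, flags: set[str]) -> CandidateVariant:
    return CandidateVariant(
        position=candidate.position,
        ref_allele=candidate.ref_allele,
        alt_allele=candidate.alt_allele,
        evidence=dict(candidate.evidence),
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Per-sample criteria
# ---------------------------------------------------------------------------


def filter_both_strands(candidate: CandidateVariant) -> dict[str, bool]:
    """Criterion: a sample supports the variant only if it was read on both
    DNA strands (>= 1 forward and >= 1 reverse supporting read)."""
    return {
        s: ev.fwd >= 1 and ev.rev >= 1 for s, ev in candidate.evidence.items()
    }


def _passes_outright(ev: SampleEvidence, thresholds: FilterThresholds) -> bool:
    if ev.depth == 0 or ev.fwd < 1 or ev.rev < 1:
        return False
    if ev.fraction < thresholds.min_support_fraction:
        return False
    n = thresholds.min_total_supporting_reads
    if thresholds.strict_direction:
        return ev.fwd > n and ev.rev > n
    return ev.total > n


def filter_support(
    candidate: CandidateVariant, thresholds: FilterThresholds
) -> dict[str, bool]:
    """Criterion: >=90% of a sample's covering reads support the variant and
    more than 10 reads in total do — except that a >=90%-supported sample
    with <=10 reads is rescued when any other sample passes outright.
    Zero-depth samples are excluded (absent from the result), not failed."""
    outright = {
        s: _passes_outright(ev, thresholds)
        for s, ev in candidate.evidence.items()
        if ev.depth > 0
    }
    any_outright = any(outright.values())
    result: dict[str, bool] = {}
    for s, ev in candidate.evidence.items():
        if ev.depth == 0:
            continue
        if outright[s]:
            result[s] = True
        elif (
            ev.fwd >= 1
            and ev.rev >= 1
            and ev.fraction >= thresholds.min_support_fraction
            and any(v for t, v in outright.items() if t != s)
        ):
            result[s] = True  # rescue clause
        else:
            result[s] = False
    return result


def filter_multi_individual(
    candidate: CandidateVariant,
    passing_samples: list[str],
    thresholds: FilterThresholds,
) -> Optional[ValidatedVariant]:
    """Criterion: reject variants found in only one individual."""
    if len(passing_samples) < thresholds.min_carrier_individuals:
        return None
    carriers = tuple(sorted(passing_samples))
    v = ValidatedVariant(
        position=candidate.position,
        ref_allele=candidate.ref_allele,
        alt_allele=candidate.alt_allele,
        kind=candidate.kind,
        classification="",
        carriers=carriers,
        supporting={s: candidate.evidence[s].total for s in carriers},
        evidence=dict(candidate.evidence),
    )
    v.classification = classify_variant(v)
    return v


TRANSITIONS = ({"A", "G"}, {"C", "T"})


def classify_variant(variant: ValidatedVariant | CandidateVariant) -> str:
    """Transition (purine<->purine or pyrimidine<->pyrimidine), transversion,
    insertion or deletion."""
    kind = variant.kind
    if kind != "substitution":
        return kind
    pair = {variant.ref_allele, variant.alt_allele}
    return "transition" if pair in TRANSITIONS else "transversion"


def group_multiallelic(validated: list[ValidatedVariant]) -> None:
    """Assign a shared group id to validated alternates at one position."""
    by_pos: dict[int, list[ValidatedVariant]] = {}
    for v in validated:
        by_pos.setdefault(v.position, []).append(v)
    gid = 0
    for pos in sorted(by_pos):
        if len(by_pos[pos]) > 1:
            gid += 1
            for v in by_pos[pos]:
                v.multiallelic_group = gid


# ---------------------------------------------------------------------------
# The cascade
# ---------------------------------------------------------------------------


def _artifact_overridden(
    candidate: CandidateVariant, thresholds: FilterThresholds
) -> bool:
    """Strong-evidence override of an artifact flag: the event is accepted
    as real when >= min_carrier_individuals samples each show it on both
    strands, at fraction >= override_fraction, with > override_reads total
    supporting reads."""
    n_strong = sum(
        1
        for ev in candidate.evidence.values()
        if ev.depth > 0
        and ev.fwd >= 1
        and ev.rev >= 1
        and ev.fraction >= thresholds.override_fraction
        and ev.total > thresholds.override_reads
    )
    return n_strong >= thresholds.min_carrier_individuals


def run_cascade(
    pileup: Pileup,
    reference: ReferenceSequence,
    panel: Optional[PanelDef] = None,
    thresholds: FilterThresholds = FilterThresholds(),
) -> tuple[list[ValidatedVariant], FilterTrace]:
    """Enumerate candidates and apply the full validation cascade.

    Stage order: enumerate -> artifact rejection -> both-strand -> support
    (with cross-sample rescue) -> multi-individual. The rescue clause is
    evaluated only after all per-sample fractions are known, so the result
    is independent of read order.
    """
    trace = FilterTrace()
    candidates = enumerate_candidates(pileup, reference)
    trace.n_raw = len(candidates)

    stage1: list[CandidateVariant] = []
    for c in candidates:
        c = flag_artifacts(c, reference, thresholds.min_hp_len)
        if c.flags and not _artifact_overridden(c, thresholds):
            trace.rejection_reasons[c.key] = "artifact:" + ",".join(sorted(c.flags))
            continue
        stage1.append(c)
    trace.n_after_artifact = len(stage1)

    stage2: list[CandidateVariant] = []
    for c in stage1:
        if any(filter_both_strands(c).values()):
            stage2.append(c)
        else:
            trace.rejection_reasons[c.key] = "both-strand"
    trace.n_after_both_strand = len(stage2)

    stage3: list[tuple[CandidateVariant, list[str]]] = []
    for c in stage2:
        passing = [s for s, ok in filter_support(c, thresholds).items() if ok]
        if passing:
            stage3.append((c, passing))
        else:
            trace.rejection_reasons[c.key] = "support"
    trace.n_after_support = len(stage3)

    validated: list[ValidatedVariant] = []
    for c, passing in stage3:
        v = filter_multi_individual(c, passing, thresholds)
        if v is None:
            trace.rejection_reasons[c.key] = "single-individual"
        else:
            validated.append(v)
    trace.n_validated = len(validated)
    validated.sort(key=lambda v: (v.position, v.alt_allele, v.ref_allele))
    group_multiallelic(validated)
    return validated, trace
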