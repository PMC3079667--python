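"""Ground-truth haplotype and 454-like read simulation.

Every downstream stage (demultiplexing, alignment, pileup, variant
validation, reporting) is exercised against data produced here, with full
per-read provenance so recovery can be checked exactly.

The emulated error spectrum is that of pyrosequencing: homopolymer
under-reads (a run of identical bases called one base short, i.e. a spurious
1-bp deletion), carry-forward events (a spurious 1-bp insertion duplicating
a nearby upstream base), uniform substitutions, and read truncations that
cost one terminal MID and hence traceability.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core_model import (
    AmpliconDef,
    DesignError,
    ExperimentDesign,
    MidTag,
    PanelDef,
    ReferenceSequence,
    SampleRecord,
    load_panel_table,
    packaged_mid_sets,
    revcomp,
)

_BASES = np.array(list("ACGT"))

#: Seed fixed once for the packaged sequence fixture (reference bases and
#: primers); the fixture is configuration, regenerated identically on demand.
_FIXTURE_SEED = 20110407

#: Primer length used for all synthetic primers.
PRIMER_LEN = 22

#: Spacer between amplicons on the synthetic reference.
_SPACER = 30


# ---------------------------------------------------------------------------
# Truth / model types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantTruth:
    """A planted variant with its carrier set.

    ``position`` is 1-based on the reference. Substitutions have single-base
    ``ref_allele``/``alt_allele``; deletions are anchored at the first
    deleted base (``alt_allele`` empty); insertions at the base they follow
    (``ref_allele`` empty).
    """

    position: int
    ref_allele: str
    alt_allele: str
    carrier_ids: frozenset[str]

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise DesignError("variant with alt == ref")
        if not self.carrier_ids:
            raise DesignError("variant with no carriers")

    @property
    def kind(self) -> str:
        if self.ref_allele and self.alt_allele:
            return "substitution"
        return "insertion" if self.alt_allele else "deletion"

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.position, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class ErrorModel:
    """Per-read/per-base error probabilities of the 454-like generator."""

    substitution_rate: float = 0.0
    hp_underread_rate: float = 0.0
    carry_forward_rate: float = 0.0
    truncation_rate: float = 0.0
    min_hp_len: int = 3

    def __post_init__(self) -> None:
        for name in (
            "substitution_rate",
            "hp_underread_rate",
            "carry_forward_rate",
            "truncation_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DesignError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class CoverageModel:
    """Reads per (individual, amplicon): rounded truncated normal, floor 0."""

    mean_depth: float = 27.3
    sd_depth: float = 11.74
    fwd_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise DesignError("mean_depth must be > 0")
        if not 0.0 < self.fwd_fraction < 1.0:
            raise DesignError("fwd_fraction must be in (0, 1)")

    def sample_depth(self, rng: np.random.Generator) -> int:
        if self.sd_depth == 0:
            return int(round(self.mean_depth))
        return max(0, int(round(rng.normal(self.mean_depth, self.sd_depth))))


@dataclass(frozen=True)
class ReadProvenance:
    """What was done to one emitted read."""

    sample_id: str
    amplicon_index: int
    strand: str  # 'fwd' | 'rev'
    n_substitutions: int = 0
    n_hp_deletions: int = 0
    n_carry_forward: int = 0
    truncated_end: Optional[str] = None  # 'start' | 'end' | None
    mid_errors_per_end: int = 0


@dataclass(frozen=True)
class SimRead:
    read_id: str
    group_id: int
    sequence: str


@dataclass
class GroundTruth:
    """The oracle for everything downstream: planted variants, per-read
    provenance and the depths actually sampled."""

    variants: list[VariantTruth]
    provenance: dict[str, ReadProvenance] = field(default_factory=dict)
    depths: dict[tuple[str, int], int] = field(default_factory=dict)
    total_read_bases: int = 0

    def variant_keys(self) -> set[tuple[int, str, str]]:
        return {v.key for v in self.variants}


# ---------------------------------------------------------------------------
# Sequence fixtures: reference, panel, designs
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def panel_from_inserts(
    inserts: Sequence[str],
    regions: Optional[Sequence[str]] = None,
    reference_id: str = "synthetic_mt",
    seed: int = _FIXTURE_SEED,
) -> tuple[ReferenceSequence, PanelDef]:
    """Build a synthetic reference plus panel from explicit insert sequences.

    The reference concatenates, per amplicon, a spacer, the forward primer,
    the insert and the reverse-complemented reverse primer, so each insert's
    1-based coordinates are exact and primers flank it as in a real design.
    """
    rng = np.random.default_rng(seed)
    if regions is None:
        regions = [f"REGION{i + 1}" for i in range(len(inserts))]
    parts: list[str] = []
    amps: list[AmpliconDef] = []
    pos = 0
    for i, insert in enumerate(inserts):
        fwd_primer = _random_seq(rng, PRIMER_LEN)
        rev_primer = _random_seq(rng, PRIMER_LEN)
        spacer = _random_seq(rng, _SPACER)
        parts.append(spacer + fwd_primer)
        pos += _SPACER + PRIMER_LEN
        ref_start = pos + 1
        parts.append(insert)
        pos += len(insert)
        ref_end = pos
        parts.append(revcomp(rev_primer))
        pos += PRIMER_LEN
        amps.append(
            AmpliconDef(
                index=i + 1,
                region_name=str(regions[i]),
                fwd_primer=fwd_primer,
                rev_primer=rev_primer,
                ref_start=ref_start,
                ref_end=ref_end,
            )
        )
    parts.append(_random_seq(rng, _SPACER))
    reference = ReferenceSequence(id=reference_id, bases="".join(parts))
    panel = PanelDef(reference_id=reference_id, amplicons=tuple(amps))
    panel.validate_against(reference)
    return reference, panel


def make_reference_and_panel(
    n_amplicons: Optional[int] = None, seed: int = _FIXTURE_SEED
) -> tuple[ReferenceSequence, PanelDef]:
    """The packaged 20-amplicon fixture: insert lengths and region names from
    the packaged panel table, sequences synthetic but deterministic."""
    table = load_panel_table()
    if n_amplicons is not None:
        table = table.iloc[:n_amplicons]
    rng = np.random.default_rng(seed)
    inserts = [_random_seq(rng, int(n)) for n in table["insert_length_bp"]]
    return panel_from_inserts(
        inserts, regions=list(table["region"]), seed=seed + 1
    )


def make_design(
    n_groups: int = 2,
    samples_per_group: int = 12,
    n_amplicons: int = 4,
    samples_per_location: int = 4,
    species: str = "Salmo salar",
    panel: Optional[PanelDef] = None,
    reference: Optional[ReferenceSequence] = None,
) -> tuple[ReferenceSequence, PanelDef, ExperimentDesign]:
    """A desk-scale experiment design over the packaged sequence fixture.

    Samples within a group receive MID pairs row-major over the 6x6
    combination matrix; locations are filled round-robin.
    """
    if panel is None or reference is None:
        reference, panel = make_reference_and_panel(n_amplicons=n_amplicons)
    fwd, rev = packaged_mid_sets()
    if samples_per_group > len(fwd) * len(rev):
        raise DesignError("samples_per_group exceeds available MID combinations")
    groups: dict[int, list[SampleRecord]] = {}
    counter = 0
    for g in range(1, n_groups + 1):
        groups[g] = []
        for k in range(samples_per_group):
            counter += 1
            groups[g].append(
                SampleRecord(
                    sample_id=f"S{counter:04d}",
                    species=species,
                    location_id=f"L{(counter - 1) // samples_per_location + 1:02d}",
                    group_id=g,
                    fwd_mid=fwd[k // len(rev)],
                    rev_mid=rev[k % len(rev)],
                )
            )
    design = ExperimentDesign(
        panel=panel, groups=groups, fwd_mid_set=fwd, rev_mid_set=rev
    )
    return reference, panel, design


def full_study_design() -> tuple[ReferenceSequence, PanelDef, ExperimentDesign]:
    """The full-scale design: 16 groups x 36 samples over all 20 amplicons,
    546 Atlantic salmon plus 12 brown trout and 18 Arctic charr (carried in
    the last group, as non-target placeholders), 48 sampling locations."""
    reference, panel = make_reference_and_panel()
    fwd, rev = packaged_mid_sets()
    groups: dict[int, list[SampleRecord]] = {}
    n_locations = 48
    salmon_counter = 0
    counter = 0
    for g in range(1, 17):
        groups[g] = []
        for k in range(36):
            counter += 1
            if g == 16 and k >= 6:
                species = "Salmo trutta" if k < 18 else "Salvelinus alpinus"
                location = f"X{k:02d}"
            else:
                species = "Salmo salar"
                salmon_counter += 1
                location = f"L{(salmon_counter - 1) % n_locations + 1:02d}"
            groups[g].append(
                SampleRecord(
                    sample_id=f"S{counter:04d}",
                    species=species,
                    location_id=location,
                    group_id=g,
                    fwd_mid=fwd[k // 6],
                    rev_mid=rev[k % 6],
                )
            )
    design = ExperimentDesign(
        panel=panel, groups=groups, fwd_mid_set=fwd, rev_mid_set=rev
    )
    return reference, panel, design


# ---------------------------------------------------------------------------
# Haplotype simulation
# ---------------------------------------------------------------------------

CarrierDist = Union[int, Sequence[int], Callable[[np.random.Generator], int]]

#: Indels are planted >= this many bp away from insert edges so a planted
#: event can never be absorbed into a free terminal gap of the semi-global
#: alignment.
_INDEL_EDGE_MARGIN = 10
_SUB_EDGE_MARGIN = 2
_MIN_VARIANT_SPACING = 4


def left_normalize(
    position: int, ref_allele: str, alt_allele: str, reference_bases: str
) -> tuple[int, str, str]:
    """Left-align a pure indel against the reference (no-op for
    substitutions), so equivalent event descriptions share one canonical
    coordinate — e.g. any one-base deletion within a homopolymer run is
    anchored at the run's first base."""
    if ref_allele and alt_allele:  # substitution
        return position, ref_allele, alt_allele
    seq = ref_allele or alt_allele
    pos = position
    if not alt_allele:  # deletion anchored at first deleted base (1-based)
        while pos > 1 and reference_bases[pos - 2] == seq[-1]:
            seq = seq[-1] + seq[:-1]
            pos -= 1
        return pos, seq, ""
    # insertion anchored at the base it follows
    while pos > 0 and reference_bases[pos - 1] == seq[-1]:
        seq = seq[-1] + seq[:-1]
        pos -= 1
    return pos, "", seq


def _draw_carriers(
    rng: np.random.Generator, dist: CarrierDist, sample_ids: Sequence[str]
) -> frozenset[str]:
    if callable(dist):
        c = int(dist(rng))
    elif isinstance(dist, int):
        c = dist
    else:
        c = int(rng.choice(np.asarray(dist)))
    c = max(1, min(c, len(sample_ids)))
    return frozenset(rng.choice(np.asarray(sample_ids), size=c, replace=False))


def simulate_haplotypes(
    design: ExperimentDesign,
    reference: ReferenceSequence,
    n_variants: int,
    carrier_count_distribution: CarrierDist = 2,
    indel_fraction: float = 0.0,
    seed: int = 0,
) -> list[VariantTruth]:
    """Plant ``n_variants`` unique-position variants inside amplicon inserts.

    Indels are 2-bp events (like the real D-loop insertion/deletion pair),
    deliberately distinct from the 1-bp artifact classes the error model
    produces, and are kept clear of insert edges. Deterministic for a fixed
    seed.
    """
    rng = np.random.default_rng(seed)
    sample_ids = [s.sample_id for s in design.samples]
    candidate_pos: list[int] = []
    for a in design.panel:
        lo = a.ref_start + _SUB_EDGE_MARGIN
        hi = a.ref_end - _SUB_EDGE_MARGIN
        candidate_pos.extend(range(lo, hi + 1))
    indel_ok = set()
    for a in design.panel:
        indel_ok.update(
            range(a.ref_start + _INDEL_EDGE_MARGIN, a.ref_end - _INDEL_EDGE_MARGIN)
        )
    variants: list[VariantTruth] = []
    used: set[int] = set()
    order = rng.permutation(len(candidate_pos))
    ptr = 0
    while len(variants) < n_variants:
        if ptr >= len(order):
            raise DesignError(
                f"cannot place {n_variants} variants: only {len(variants)} "
                "positions available with the required spacing"
            )
        pos = candidate_pos[order[ptr]]
        ptr += 1
        if any(abs(pos - u) < _MIN_VARIANT_SPACING for u in used):
            continue
        want_indel = rng.random() < indel_fraction
        if want_indel and pos not in indel_ok:
            continue
        ref_base = reference.bases[pos - 1]
        if want_indel:
            if rng.random() < 0.5:  # 2-bp deletion
                p, r, a_ = left_normalize(
                    pos, reference.bases[pos - 1 : pos + 1], "", reference.bases
                )
            else:  # 2-bp insertion after pos
                ins = _random_seq(rng, 2)
                p, r, a_ = left_normalize(pos, "", ins, reference.bases)
            if any(abs(p - u) < _MIN_VARIANT_SPACING for u in used):
                continue
        else:
            choices = [b for b in "ACGT" if b != ref_base]
            p, r, a_ = pos, ref_base, str(rng.choice(choices))
        if p in used:
            continue
        used.add(p)
        used.add(pos)
        variants.append(
            VariantTruth(
                position=p,
                ref_allele=r,
                alt_allele=a_,
                carrier_ids=_draw_carriers(rng, carrier_count_distribution, sample_ids),
            )
        )
    variants.sort(key=lambda v: v.position)
    return variants


def apply_variants_to_insert(
    amplicon: AmpliconDef,
    reference: ReferenceSequence,
    variants: Sequence[VariantTruth],
    sample_id: str,
) -> str:
    """The sample's haplotype sequence for one amplicon insert."""
    insert = list(amplicon.insert_sequence(reference))
    mine = [
        v
        for v in variants
        if sample_id in v.carrier_ids
        and amplicon.ref_start <= v.position <= amplicon.ref_end
    ]
    for v in sorted(mine, key=lambda v: v.position, reverse=True):
        off = v.position - amplicon.ref_start
        if v.kind == "substitution":
            insert[off] = v.alt_allele
        elif v.kind == "deletion":
            del insert[off : off + len(v.ref_allele)]
        else:  # insertion after the base at v.position
            insert[off + 1 : off + 1] = list(v.alt_allele)
    return "".join(insert)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def _homopolymer_runs(seq: str, min_len: int) -> list[tuple[int, int]]:
    """(start, length) of runs of identical bases with length >= min_len."""
    runs = []
    i, n = 0, len(seq)
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            runs.append((i, j - i))
        i = j
    return runs


def _apply_read_errors(
    insert: str, error_model: ErrorModel, rng: np.random.Generator
) -> tuple[str, int, int]:
    """Apply homopolymer under-reads and carry-forward insertions to one
    read's insert; substitutions/truncation act on the assembled read."""
    n_hp = 0
    if error_model.hp_underread_rate > 0:
        runs = _homopolymer_runs(insert, error_model.min_hp_len)
        chars = list(insert)
        for start, length in reversed(runs):
            if rng.random() < error_model.hp_underread_rate:
                del chars[start]  # run called one base short
                n_hp += 1
        insert = "".join(chars)
    n_cf = 0
    if error_model.carry_forward_rate > 0 and len(insert) > 2:
        if rng.random() < error_model.carry_forward_rate:
            j = int(rng.integers(2, len(insert)))
            # bias toward duplicating across a different intervening base
            d = 2 if insert[j - 2] != insert[j - 1] else 1
            insert = insert[:j] + insert[j - d] + insert[j:]
            n_cf += 1
    return insert, n_hp, n_cf


def _substitute(
    seq: str, rate: float, rng: np.random.Generator
) -> tuple[str, int]:
    if rate <= 0 or not seq:
        return seq, 0
    n = rng.binomial(len(seq), rate)
    if n == 0:
        return seq, 0
    positions = rng.choice(len(seq), size=min(n, len(seq)), replace=False)
    chars = list(seq)
    for p in positions:
        chars[p] = str(rng.choice([b for b in "ACGT" if b != chars[p]]))
    return "".join(chars), len(positions)


def _plant_mid_errors(seq: str, k: int, rng: np.random.Generator) -> str:
    """Substitute exactly k bases inside each terminal MID region."""
    chars = list(seq)
    for sl in (range(0, 10), range(len(seq) - 10, len(seq))):
        for p in rng.choice(list(sl), size=k, replace=False):
            chars[p] = str(rng.choice([b for b in "ACGT" if b != chars[p]]))
    return "".join(chars)


def simulate_reads(
    design: ExperimentDesign,
    reference: ReferenceSequence,
    variants: Sequence[VariantTruth],
    coverage_model: CoverageModel,
    error_model: ErrorModel,
    seed: int = 0,
    mid_errors_per_end: int = 0,
) -> tuple[list[SimRead], GroundTruth]:
    """Emit tagged amplicon reads for every (sample, amplicon) reaction.

    A forward-orientation read is ``fwd_MID + fwd_primer + haplotype insert
    (with sampled errors) + revcomp(rev_primer) + revcomp(rev_MID)``; a
    reverse-orientation read is its reverse complement. Truncated reads lose
    one terminal MID (plus up to 3 extra bases). Every read gets exactly one
    provenance record.
    """
    rng = np.random.default_rng(seed)
    reads: list[SimRead] = []
    truth = GroundTruth(variants=list(variants))
    counter = 0
    for sample in design.samples:
        for amplicon in design.panel:
            hap = apply_variants_to_insert(amplicon, reference, variants, sample.sample_id)
            depth = coverage_model.sample_depth(rng)
            truth.depths[(sample.sample_id, amplicon.index)] = depth
            for _ in range(depth):
                counter += 1
                read_id = f"r{counter:07d}"
                insert, n_hp, n_cf = _apply_read_errors(hap, error_model, rng)
                seq = (
                    sample.fwd_mid.sequence
                    + amplicon.fwd_primer
                    + insert
                    + revcomp(amplicon.rev_primer)
                    + revcomp(sample.rev_mid.sequence)
                )
                if mid_errors_per_end > 0:
                    seq = _plant_mid_errors(seq, mid_errors_per_end, rng)
                truth.total_read_bases += len(seq)
                seq, n_sub = _substitute(seq, error_model.substitution_rate, rng)
                truncated = None
                if error_model.truncation_rate > 0 and rng.random() < error_model.truncation_rate:
                    truncated = "start" if rng.random() < 0.5 else "end"
                    extra = int(rng.integers(0, 4))
                    cut = 10 + extra
                    seq = seq[cut:] if truncated == "start" else seq[:-cut]
                strand = "fwd" if rng.random() < coverage_model.fwd_fraction else "rev"
                if strand == "rev":
                    seq = revcomp(seq)
                reads.append(SimRead(read_id, sample.group_id, seq))
                truth.provenance[read_id] = ReadProvenance(
                    sample_id=sample.sample_id,
                    amplicon_index=amplicon.index,
                    strand=strand,
                    n_substitutions=n_sub,
                    n_hp_deletions=n_hp,
                    n_carry_forward=n_cf,
                    truncated_end=truncated,
                    mid_errors_per_end=mid_errors_per_end,
                )
    return reads, truth


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------


def write_fastq(reads: Sequence[SimRead], path: str | Path) -> None:
    """FASTQ with a constant Q30 placeholder quality — the validation
    cascade is count-based, not quality-based."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id} group={r.group_id}\n{r.sequence}\n+\n")
            fh.write("?" * len(r.sequence) + "\n")


def write_truth_tables(truth: GroundTruth, variants_path: str | Path, provenance_path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "position": v.position,
                "ref_allele": v.ref_allele,
                "alt_allele": v.alt_allele,
                "kind": v.kind,
                "carriers": ",".join(sorted(v.carrier_ids)),
            }
            for v in truth.variants
        ]
    ).to_csv(variants_path, sep="\t", index=False)
    pd.DataFrame(
        [
            {"read_id": rid, **dataclasses.asdict(p)}
            for rid, p in truth.provenance.items()
        ]
    ).to_csv(provenance_path, sep="\t", index=False)
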