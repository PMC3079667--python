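"""Domain types and I/O for multiplexed amplicon resequencing designs.

The experimental design modelled here is combinatorial dual barcoding of PCR
amplicons: every sample in a sequencing group is tagged with a (forward MID,
reverse MID) pair drawn from two small sets of 10-bp multiplex identifiers
(MIDs), the groups are sequenced in separate plate regions, and every read
must later be traced back to its source sample from the two terminal MIDs.

Coordinates are 1-based and inclusive on a linear reference (the
mitochondrial circle is treated as linear; no amplicon spans the origin).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

VALID_BASES = frozenset("ACGT")

#: Minimum pairwise edit distance within a MID role set that guarantees
#: unambiguous decoding when up to 2 sequencing errors are tolerated.
MIN_MID_PAIRWISE_DISTANCE = 5

#: MIDs are 10 bp in this design.
MID_LENGTH = 10


class DesignError(ValueError):
    """Raised when an input file or design violates a documented invariant."""


def revcomp(seq: str) -> str:
    """Reverse-complement an upper-case DNA string."""
    return str(Seq(seq).reverse_complement())


def _check_bases(seq: str, what: str) -> None:
    for i, b in enumerate(seq):
        if b not in VALID_BASES:
            raise DesignError(
                f"{what} contains non-ACGT character {b!r} at position {i + 1}"
            )


def edit_distance(a: str, b: str) -> int:
    """Plain Levenshtein distance (used for design validation of small sets)."""
    m, n = len(a), len(b)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        ai = a[i - 1]
        for j in range(1, n + 1):
            cur[j] = min(
                prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ai != b[j - 1])
            )
        prev = cur
    return prev[n]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferenceSequence:
    """A single linear reference sequence over {A,C,G,T}."""

    id: str
    bases: str

    def __post_init__(self) -> None:
        if len(self.bases) == 0:
            raise DesignError("reference sequence is empty")
        _check_bases(self.bases, f"reference {self.id!r}")

    @property
    def length(self) -> int:
        return len(self.bases)

    def slice(self, start: int, end: int) -> str:
        """Return bases for 1-based inclusive coordinates [start, end]."""
        if not (1 <= start <= end <= self.length):
            raise DesignError(
                f"coordinates {start}..{end} outside reference of length {self.length}"
            )
        return self.bases[start - 1 : end]


@dataclass(frozen=True)
class AmpliconDef:
    """One PCR amplicon: primer pair plus the insert it brackets.

    ``ref_start``/``ref_end`` are the 1-based inclusive coordinates of the
    insert only — primer binding sites are excluded, matching the accounting
    of amplicon sizes "excluding primer binding sites".
    """

    index: int
    region_name: str
    fwd_primer: str
    rev_primer: str
    ref_start: int
    ref_end: int

    def __post_init__(self) -> None:
        if self.ref_end < self.ref_start:
            raise DesignError(
                f"amplicon {self.index}: ref_end {self.ref_end} < ref_start {self.ref_start}"
            )
        _check_bases(self.fwd_primer, f"amplicon {self.index} fwd primer")
        _check_bases(self.rev_primer, f"amplicon {self.index} rev primer")

    @property
    def insert_length(self) -> int:
        return self.ref_end - self.ref_start + 1

    def insert_sequence(self, reference: ReferenceSequence) -> str:
        return reference.slice(self.ref_start, self.ref_end)


@dataclass(frozen=True)
class PanelDef:
    """An ordered panel of amplicons over one reference."""

    reference_id: str
    amplicons: tuple[AmpliconDef, ...]

    def __post_init__(self) -> None:
        indices = [a.index for a in self.amplicons]
        if len(indices) != len(set(indices)):
            raise DesignError("duplicate amplicon index in panel")

    def __len__(self) -> int:
        return len(self.amplicons)

    def __iter__(self) -> Iterator[AmpliconDef]:
        return iter(self.amplicons)

    def by_index(self, index: int) -> AmpliconDef:
        for a in self.amplicons:
            if a.index == index:
                return a
        raise KeyError(f"no amplicon with index {index}")

    @property
    def total_insert_length(self) -> int:
        return sum(a.insert_length for a in self.amplicons)

    @property
    def regions(self) -> tuple[str, ...]:
        seen: list[str] = []
        for a in self.amplicons:
            if a.region_name not in seen:
                seen.append(a.region_name)
        return tuple(seen)

    def amplicon_at(self, position: int) -> Optional[AmpliconDef]:
        """Amplicon whose insert contains the 1-based reference position."""
        for a in self.amplicons:
            if a.ref_start <= position <= a.ref_end:
                return a
        return None

    def validate_against(self, reference: ReferenceSequence) -> None:
        for a in self.amplicons:
            if a.ref_end > reference.length:
                raise DesignError(
                    f"amplicon {a.index}: coordinates {a.ref_start}..{a.ref_end} "
                    f"exceed reference length {reference.length}"
                )


@dataclass(frozen=True)
class MidTag:
    """A 10-bp multiplex identifier (barcode)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != MID_LENGTH:
            raise DesignError(
                f"MID {self.id}: length {len(self.sequence)} != {MID_LENGTH}"
            )
        _check_bases(self.sequence, f"MID {self.id}")


@dataclass(frozen=True)
class SampleRecord:
    """One physical sample with its group and MID-pair tag."""

    sample_id: str
    species: str
    location_id: str
    group_id: int
    fwd_mid: MidTag
    rev_mid: MidTag


@dataclass
class ExperimentDesign:
    """The full sequencing design: panel, MID sets and grouped samples."""

    panel: PanelDef
    groups: dict[int, list[SampleRecord]]
    fwd_mid_set: tuple[MidTag, ...]
    rev_mid_set: tuple[MidTag, ...]
    _pair_lookup: dict[tuple[int, str, str], SampleRecord] = field(
        init=False, repr=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        validate_mid_set(self.fwd_mid_set, "forward")
        validate_mid_set(self.rev_mid_set, "reverse")
        max_per_group = len(self.fwd_mid_set) * len(self.rev_mid_set)
        for gid, samples in self.groups.items():
            if len(samples) > max_per_group:
                raise DesignError(
                    f"group {gid} holds {len(samples)} samples; at most "
                    f"{max_per_group} MID combinations are available"
                )
            for s in samples:
                key = (gid, s.fwd_mid.id, s.rev_mid.id)
                if key in self._pair_lookup:
                    raise DesignError(
                        f"group {gid}: MID pair ({s.fwd_mid.id}, {s.rev_mid.id}) "
                        f"assigned to both {self._pair_lookup[key].sample_id} "
                        f"and {s.sample_id}; traceability would be lost"
                    )
                self._pair_lookup[key] = s

    @property
    def samples(self) -> list[SampleRecord]:
        return [s for gid in sorted(self.groups) for s in self.groups[gid]]

    @property
    def n_samples(self) -> int:
        return sum(len(v) for v in self.groups.values())

    def sample_by_id(self, sample_id: str) -> SampleRecord:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def lookup_pair(
        self, group_id: int, fwd_mid_id: str, rev_mid_id: str
    ) -> Optional[SampleRecord]:
        """Sample tagged with this (forward, reverse) MID pair in the group."""
        return self._pair_lookup.get((group_id, fwd_mid_id, rev_mid_id))


def validate_mid_set(
    tags: Iterable[MidTag], role: str, min_distance: int = MIN_MID_PAIRWISE_DISTANCE
) -> None:
    """Reject MID sets whose pairwise edit distance would make 2-error
    decoding ambiguous."""
    tags = list(tags)
    if not tags:
        raise DesignError(f"{role} MID set is empty")
    ids = [t.id for t in tags]
    if len(ids) != len(set(ids)):
        raise DesignError(f"{role} MID set has duplicate ids")
    for i, a in enumerate(tags):
        for b in tags[i + 1 :]:
            d = edit_distance(a.sequence, b.sequence)
            if d < min_distance:
                raise DesignError(
                    f"{role} MIDs {a.id} and {b.id} are at edit distance {d} "
                    f"< {min_distance}; 2-error decoding would be ambiguous"
                )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def load_reference(path: str | Path) -> ReferenceSequence:
    """Read a single-record FASTA reference; lowercase is normalised.

    Ambiguity codes are rejected: the downstream pileup and variant calling
    operate on a strict {A,C,G,T} alphabet.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise DesignError(f"{path}: empty or non-FASTA reference file")
    if len(records) > 1:
        raise DesignError(
            f"{path}: multi-record reference ({len(records)} records); exactly one expected"
        )
    rec = records[0]
    return ReferenceSequence(id=rec.id, bases=str(rec.seq).upper())


def write_reference(reference: ReferenceSequence, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{reference.id}\n")
        for i in range(0, reference.length, 70):
            fh.write(reference.bases[i : i + 70] + "\n")


PANEL_COLUMNS = ["amplicon", "region", "fwd_primer", "rev_primer", "ref_start", "ref_end"]


def load_panel(
    path: str | Path, reference: Optional[ReferenceSequence] = None
) -> PanelDef:
    """Load an amplicon panel from TSV (one row per amplicon).

    Columns: amplicon, region, fwd_primer, rev_primer, ref_start, ref_end
    and optionally insert_length (cross-checked when present) and
    reference_id.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise DesignError(f"{path}: panel file missing columns {missing}")
    amps = []
    for _, row in df.iterrows():
        amp = AmpliconDef(
            index=int(row["amplicon"]),
            region_name=str(row["region"]),
            fwd_primer=str(row["fwd_primer"]).upper(),
            rev_primer=str(row["rev_primer"]).upper(),
            ref_start=int(row["ref_start"]),
            ref_end=int(row["ref_end"]),
        )
        if "insert_length" in df.columns and not pd.isna(row["insert_length"]):
            stated = int(row["insert_length"])
            if stated != amp.insert_length:
                raise DesignError(
                    f"amplicon {amp.index}: stated insert_length {stated} != "
                    f"ref_end - ref_start + 1 = {amp.insert_length}"
                )
        amps.append(amp)
    ref_id = (
        str(df["reference_id"].iloc[0])
        if "reference_id" in df.columns
        else (reference.id if reference is not None else "reference")
    )
    panel = PanelDef(reference_id=ref_id, amplicons=tuple(amps))
    if reference is not None:
        panel.validate_against(reference)
    return panel


def write_panel(panel: PanelDef, path: str | Path) -> None:
    rows = [
        {
            "amplicon": a.index,
            "region": a.region_name,
            "fwd_primer": a.fwd_primer,
            "rev_primer": a.rev_primer,
            "ref_start": a.ref_start,
            "ref_end": a.ref_end,
            "insert_length": a.insert_length,
            "reference_id": panel.reference_id,
        }
        for a in panel.amplicons
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_mids(path: str | Path) -> tuple[tuple[MidTag, ...], tuple[MidTag, ...]]:
    """Load MID definitions (columns: mid_id, role in {fwd, rev}, sequence)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("mid_id", "role", "sequence"):
        if col not in df.columns:
            raise DesignError(f"{path}: MID file missing column {col!r}")
    fwd = tuple(
        MidTag(r["mid_id"], r["sequence"].upper())
        for _, r in df[df["role"] == "fwd"].iterrows()
    )
    rev = tuple(
        MidTag(r["mid_id"], r["sequence"].upper())
        for _, r in df[df["role"] == "rev"].iterrows()
    )
    validate_mid_set(fwd, "forward")
    validate_mid_set(rev, "reverse")
    return fwd, rev


def packaged_mid_sets() -> tuple[tuple[MidTag, ...], tuple[MidTag, ...]]:
    """The 12 packaged MIDs: 6 forward (MID1-6) and 6 reverse (MID7-12).

    Synthetic 10-mers with pairwise edit distance >= 5, mimicking the
    error-correcting property of the commercial MID sets they stand in for.
    """
    with importlib.resources.as_file(
        importlib.resources.files("amplisnp.data") / "mids.tsv"
    ) as p:
        return load_mids(p)


SAMPLE_SHEET_COLUMNS = [
    "sample_id",
    "species",
    "location_id",
    "group_id",
    "fwd_mid",
    "rev_mid",
]


def load_sample_sheet(
    path: str | Path,
    panel: PanelDef,
    fwd_mid_set: Iterable[MidTag],
    rev_mid_set: Iterable[MidTag],
) -> ExperimentDesign:
    """Load a TSV sample sheet into a validated :class:`ExperimentDesign`.

    MID-pair uniqueness is enforced per group; reuse of the same pair across
    groups is legitimate because groups are sequenced in separate plate
    regions.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise DesignError(f"{path}: sample sheet missing columns {missing}")
    fwd = {t.id: t for t in fwd_mid_set}
    rev = {t.id: t for t in rev_mid_set}
    groups: dict[int, list[SampleRecord]] = {}
    seen_ids: set[str] = set()
    for _, row in df.iterrows():
        sid = str(row["sample_id"])
        if sid in seen_ids:
            raise DesignError(f"duplicate sample_id {sid!r}")
        seen_ids.add(sid)
        fmid, rmid = str(row["fwd_mid"]), str(row["rev_mid"])
        if fmid not in fwd:
            raise DesignError(f"sample {sid}: unknown forward MID id {fmid!r}")
        if rmid not in rev:
            raise DesignError(f"sample {sid}: unknown reverse MID id {rmid!r}")
        rec = SampleRecord(
            sample_id=sid,
            species=str(row["species"]),
            location_id=str(row["location_id"]),
            group_id=int(row["group_id"]),
            fwd_mid=fwd[fmid],
            rev_mid=rev[rmid],
        )
        groups.setdefault(rec.group_id, []).append(rec)
    return ExperimentDesign(
        panel=panel,
        groups=groups,
        fwd_mid_set=tuple(fwd.values()),
        rev_mid_set=tuple(rev.values()),
    )


def write_sample_sheet(design: ExperimentDesign, path: str | Path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "species": s.species,
            "location_id": s.location_id,
            "group_id": s.group_id,
            "fwd_mid": s.fwd_mid.id,
            "rev_mid": s.rev_mid.id,
        }
        for s in design.samples
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Design arithmetic
# ---------------------------------------------------------------------------


def enumerate_reactions(
    design: ExperimentDesign, species_filter: Optional[str] = None
) -> list[tuple[str, int]]:
    """All (sample_id, amplicon index) PCR reactions the design implies.

    One reaction is run per sample per amplicon; ``species_filter`` restricts
    the listing to samples of one species (e.g. excluding the non-target
    species carried along in the sequencing setup).
    """
    out: list[tuple[str, int]] = []
    for s in design.samples:
        if species_filter is not None and s.species != species_filter:
            continue
        for a in design.panel:
            out.append((s.sample_id, a.index))
    return out


def count_reactions(
    design: ExperimentDesign, species_filter: Optional[str] = None
) -> int:
    return len(enumerate_reactions(design, species_filter))


def load_panel_table() -> pd.DataFrame:
    """The packaged per-amplicon summary table of the 20-amplicon design.

    Columns: region, region_size_bp, amplicon, insert_length_bp, n_snps,
    cov_mean, cov_sd, multiallelic, transitions, transversions, indels.
    The sequence-level panel fixture is generated from the insert lengths in
    this table (see :mod:`amplisnp.synthetic_data`).
    """
    with importlib.resources.as_file(
        importlib.resources.files("amplisnp.data") / "panel_table.tsv"
    ) as p:
        return pd.read_csv(p, sep="\t")
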