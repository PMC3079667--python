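"""MID decoding, read assignment, primer routing and demux accounting."""

import pytest

from amplisnp import (
    CoverageModel,
    DesignError,
    ErrorModel,
    assign_read,
    demux_reads,
    demux_stats,
    identify_amplicon,
    make_design,
    match_mid,
    packaged_mid_sets,
    simulate_reads,
)
from amplisnp.core_model import edit_distance, revcomp
from amplisnp.demultiplex import (
    DemuxedRead,
    REASON_AMBIGUOUS_MID,
    REASON_MISSING_MID,
    REASON_PRIMER_MISMATCH,
    UnassignedRead,
    trim_tags,
)

#: A window at prefix edit distance 2 from both MID2 (ACTGGCCGAA) and MID4
#: (TGTGCGGCGA): a constructed crossover tie that must decode to nothing.
TIE_WINDOW = "ACTGCGGCGAAA"


def prefix_edit_distance(tag: str, window: str) -> int:
    """Brute-force oracle: minimum edit distance of the tag to any prefix
    of the window (the MID sits at the window start, possibly indel-shifted)."""
    return min(
        edit_distance(tag, window[:k]) for k in range(1, len(window) + 1)
    )


class TestMatchMid:
    def test_exact_identity(self):
        fwd, _ = packaged_mid_sets()
        for tag in fwd:
            m = match_mid(tag.sequence + "GT", fwd)
            assert m is not None and m.tag.id == tag.id and m.errors == 0

    def test_two_errors_decoded_and_oracle_verified(self):
        fwd, _ = packaged_mid_sets()
        tag = fwd[0]
        mutated = "TT" + tag.sequence[2:]  # 2 substitutions
        window = mutated + "CA"
        dists = {t.id: prefix_edit_distance(t.sequence, window) for t in fwd}
        assert dists[tag.id] == 2
        assert all(d >= 4 for t, d in dists.items() if t != tag.id)
        m = match_mid(window, fwd)
        assert m is not None and m.tag.id == tag.id and m.errors == 2

    def test_three_errors_rejected(self):
        fwd, _ = packaged_mid_sets()
        tag = fwd[0]
        mutated = "TTT" + tag.sequence[3:]
        window = mutated + "CA"
        assert prefix_edit_distance(tag.sequence, window) == 3
        assert match_mid(window, fwd) is None

    def test_tie_yields_none(self):
        fwd, _ = packaged_mid_sets()
        dists = sorted(prefix_edit_distance(t.sequence, TIE_WINDOW) for t in fwd)
        assert dists[0] == dists[1] == 2
        assert match_mid(TIE_WINDOW, fwd) is None

    def test_empty_tag_set_rejected(self):
        with pytest.raises(DesignError):
            match_mid("ACGTACGTACGT", [])

    def test_exhaustive_oracle_equivalence(self):
        """For every (single-tag window, tag set) pair built from the
        packaged fixture, decoding equals exhaustive prefix-edit-distance
        search."""
        fwd, rev = packaged_mid_sets()
        for tag_set in (fwd, rev):
            for source in fwd + rev:
                window = source.sequence + "AC"
                dists = {
                    t.id: prefix_edit_distance(t.sequence, window) for t in tag_set
                }
                dmin = min(dists.values())
                unique = sum(1 for d in dists.values() if d == dmin) == 1
                m = match_mid(window, tag_set)
                if dmin <= 2 and unique:
                    assert m is not None
                    assert dists[m.tag.id] == dmin and m.errors == dmin
                else:
                    assert m is None


def _tagged_read(design, panel, reference, sample, amp_index, strand="fwd"):
    amp = panel.by_index(amp_index)
    seq = (
        sample.fwd_mid.sequence
        + amp.fwd_primer
        + amp.insert_sequence(reference)
        + revcomp(amp.rev_primer)
        + revcomp(sample.rev_mid.sequence)
    )
    return seq if strand == "fwd" else revcomp(seq)


@pytest.fixture(scope="module")
def ctx():
    return make_design(n_groups=2, samples_per_group=12, n_amplicons=4)


@pytest.fixture(scope="module")
def small_ctx():
    return make_design(n_groups=1, samples_per_group=1, n_amplicons=4)


class TestAssignRead:

    def test_pair_lookup(self, ctx):
        reference, panel, design = ctx
        sample = design.groups[2][7]
        read = _tagged_read(design, panel, reference, sample, 3)
        res = assign_read("r1", read, 2, design)
        assert isinstance(res, DemuxedRead)
        assert res.sample_id == sample.sample_id
        assert res.amplicon_index == 3
        assert res.strand == "fwd"

    def test_truncated_read_missing_mid(self, ctx):
        reference, panel, design = ctx
        sample = design.groups[1][0]
        read = _tagged_read(design, panel, reference, sample, 1)[12:]
        res = assign_read("r1", read, 1, design)
        assert isinstance(res, UnassignedRead)
        assert res.reason == REASON_MISSING_MID

    def test_tie_window_ambiguous(self, ctx):
        reference, panel, design = ctx
        sample = design.groups[1][0]
        amp = panel.by_index(1)
        read = (
            TIE_WINDOW
            + amp.fwd_primer
            + amp.insert_sequence(reference)
            + revcomp(amp.rev_primer)
            + revcomp(sample.rev_mid.sequence)
        )
        res = assign_read("r1", read, 1, design)
        assert isinstance(res, UnassignedRead)
        assert res.reason == REASON_AMBIGUOUS_MID

    def test_orientation_invariance(self, ctx):
        """A read and its reverse complement assign to the same sample and
        amplicon with flipped strand."""
        reference, panel, design = ctx
        sample = design.groups[1][5]
        fwd_read = _tagged_read(design, panel, reference, sample, 2, "fwd")
        rev_read = revcomp(fwd_read)
        a = assign_read("r1", fwd_read, 1, design)
        b = assign_read("r2", rev_read, 1, design)
        assert isinstance(a, DemuxedRead) and isinstance(b, DemuxedRead)
        assert (a.sample_id, a.amplicon_index) == (b.sample_id, b.amplicon_index)
        assert {a.strand, b.strand} == {"fwd", "rev"}
        assert a.insert == b.insert

    def test_no_misassignment_with_planted_mid_errors(self, ctx):
        """With <= 2 planted MID errors per end and no truncation, no
        assigned read ever contradicts its ground-truth provenance."""
        reference, panel, design = ctx
        reads, truth = simulate_reads(
            design, reference, [], CoverageModel(5, 0.0), ErrorModel(),
            seed=21, mid_errors_per_end=2,
        )
        assigned, _ = demux_reads(
            [(r.read_id, r.sequence, r.group_id) for r in reads], design
        )
        assert assigned  # the vast majority decodes
        for d in assigned:
            prov = truth.provenance[d.read_id]
            assert (d.sample_id, d.amplicon_index, d.strand) == (
                prov.sample_id, prov.amplicon_index, prov.strand
            )


class TestAmpliconRouting:
    def test_exact_primer_match(self, small_ctx):
        reference, panel, _ = small_ctx
        amp = panel.by_index(2)
        core = amp.fwd_primer + amp.insert_sequence(reference) + revcomp(amp.rev_primer)
        hit = identify_amplicon(core, panel)
        assert hit is not None and hit[0].index == 2 and hit[3]

    def test_one_substitution_in_primer_recovered(self, small_ctx):
        reference, panel, _ = small_ctx
        amp = panel.by_index(4)
        primer = list(amp.fwd_primer)
        primer[5] = {"A": "C", "C": "A", "G": "T", "T": "G"}[primer[5]]
        core = "".join(primer) + amp.insert_sequence(reference) + revcomp(amp.rev_primer)
        hit = identify_amplicon(core, panel)
        assert hit is not None and hit[0].index == 4

    def test_foreign_primers_rejected(self, small_ctx):
        reference, panel, design = small_ctx
        core = "ACGT" * 30
        assert identify_amplicon(core, panel) is None
        sample = design.samples[0]
        read = (
            sample.fwd_mid.sequence + core + revcomp(sample.rev_mid.sequence)
        )
        res = assign_read("r1", read, 1, design)
        assert isinstance(res, UnassignedRead)
        assert res.reason == REASON_PRIMER_MISMATCH

    def test_trim_reproduces_insert_length(self, small_ctx):
        reference, panel, design = small_ctx
        sample = design.samples[0]
        for amp in panel:
            read = _tagged_read(design, panel, reference, sample, amp.index)
            res = assign_read("r", read, 1, design)
            assert isinstance(res, DemuxedRead)
            assert len(res.insert) == amp.insert_length
            assert res.insert == amp.insert_sequence(reference)

    def test_degenerate_insert_rejected(self, small_ctx):
        _, panel, design = small_ctx
        from amplisnp.demultiplex import MidMatch

        fm = MidMatch(design.fwd_mid_set[0], 0, "", 9)
        rm = MidMatch(design.rev_mid_set[0], 0, "", 9)
        seq = design.fwd_mid_set[0].sequence + revcomp(design.rev_mid_set[0].sequence)
        with pytest.raises(DesignError, match="empty insert"):
            trim_tags(seq, fm, rm, -1, 0)


class TestDemuxStats:
    def test_empty_run(self):
        rep = demux_stats([], [])
        assert rep.total == 0
        assert rep.assignment_rate == 0.0
        assert rep.rate_defined is False

    def test_noise_free_rate_is_100(self, noise_free_run):
        rep = demux_stats(noise_free_run["assigned"], noise_free_run["unassigned"])
        assert rep.assignment_rate == 100.0
        assert rep.unassigned == 0

    def test_reason_partition(self, desk_design):
        """Every input read appears in exactly one report category."""
        reference, _, design = desk_design
        reads, _ = simulate_reads(
            design, reference, [], CoverageModel(8, 0.0),
            ErrorModel(truncation_rate=0.2, substitution_rate=0.01), seed=31,
        )
        assigned, unassigned = demux_reads(
            [(r.read_id, r.sequence, r.group_id) for r in reads], design
        )
        rep = demux_stats(assigned, unassigned)
        assert rep.assigned + rep.unassigned == rep.total == len(reads)
        assert sum(rep.by_reason.values()) == rep.unassigned
        assert sum(rep.per_sample_amplicon.values()) == rep.assigned
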