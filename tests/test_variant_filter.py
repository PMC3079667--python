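"""The validation cascade: artifact flags, per-sample criteria, rescue and
the multi-individual requirement."""

import pytest

from amplisnp import (
    CandidateVariant,
    FilterThresholds,
    SampleEvidence,
    classify_variant,
    enumerate_candidates,
    filter_both_strands,
    filter_multi_individual,
    filter_support,
    flag_artifacts,
    run_cascade,
)
from amplisnp.alignment_pileup import Pileup
from amplisnp.core_model import ReferenceSequence
from amplisnp.variant_filter import (
    FLAG_CARRY_FORWARD,
    FLAG_HOMOPOLYMER,
    group_multiallelic,
)


def _cand(position=100, ref="A", alt="G", evidence=None):
    return CandidateVariant(
        position=position,
        ref_allele=ref,
        alt_allele=alt,
        evidence=evidence or {},
    )


class TestEnumerate:
    def test_empty_pileup(self):
        ref = ReferenceSequence("r", "ACGT" * 30)
        assert enumerate_candidates(Pileup(), ref) == []

    def test_single_alt_read(self):
        ref = ReferenceSequence("r", "AAAACCCCGGGGTTTT")
        pile = Pileup()
        pile._bump("S1", 1, 5, "fwd", "T")  # alt over ref C
        cands = enumerate_candidates(pile, ref)
        assert len(cands) == 1
        c = cands[0]
        assert (c.position, c.ref_allele, c.alt_allele) == (5, "C", "T")
        assert c.evidence["S1"] == SampleEvidence(fwd=1, rev=0, depth=1)

    def test_reference_only_pileup_yields_nothing(self):
        ref = ReferenceSequence("r", "ACGTACGTAC")
        pile = Pileup()
        for pos in range(1, 11):
            pile._bump("S1", 1, pos, "fwd", ref.bases[pos - 1])
        assert enumerate_candidates(pile, ref) == []

    def test_candidates_equal_planted_when_noise_free(self, noise_free_run):
        run = noise_free_run
        cands = enumerate_candidates(run["pileup"], run["reference"])
        assert {c.key for c in cands} == run["truth"].variant_keys()


class TestArtifactFlags:
    REF = ReferenceSequence("r", "CCGT" + "AAAA" + "TGCG" + "CTAG" + "GCGC")

    def test_deletion_in_homopolymer_flagged(self):
        c = _cand(position=5, ref="A", alt="")
        assert FLAG_HOMOPOLYMER in flag_artifacts(c, self.REF).flags

    def test_deletion_outside_runs_unflagged(self):
        c = _cand(position=14, ref="T", alt="")
        assert flag_artifacts(c, self.REF).flags == set()

    def test_carry_forward_insertion_flagged(self):
        # inserted G after position 11 (C); reference G two upstream at 10,
        # with a non-G intervening base: the classic carry-forward pattern
        c = _cand(position=11, ref="", alt="G")
        assert FLAG_CARRY_FORWARD in flag_artifacts(c, self.REF).flags

    def test_two_bp_insertion_never_flagged(self):
        # multi-base events (like the D-loop CT insertion) are not artifact
        # classes and must survive artifact rejection
        c = _cand(position=11, ref="", alt="CT")
        assert flag_artifacts(c, self.REF).flags == set()

    def test_substitution_never_flagged(self):
        c = _cand(position=6, ref="A", alt="G")
        assert flag_artifacts(c, self.REF).flags == set()


class TestBothStrands:
    @pytest.mark.parametrize(
        "fwd,rev,expected",
        [(5, 0, False), (1, 1, True), (0, 0, False), (0, 7, False)],
    )
    def test_per_sample_rule(self, fwd, rev, expected):
        c = _cand(evidence={"S1": SampleEvidence(fwd, rev, 30)})
        assert filter_both_strands(c) == {"S1": expected}


class TestSupport:
    thresholds = FilterThresholds()

    def test_outright_pass(self):
        c = _cand(evidence={"S1": SampleEvidence(14, 13, 28)})  # 27/28 = 0.964
        assert filter_support(c, self.thresholds) == {"S1": True}

    def test_rescue_via_stronger_sample(self):
        c = _cand(
            evidence={
                "S1": SampleEvidence(5, 4, 10),  # 9/10 = 0.90, total <= 10
                "S2": SampleEvidence(15, 15, 30),  # passes outright
            }
        )
        assert filter_support(c, self.thresholds) == {"S1": True, "S2": True}

    def test_no_rescue_without_any_outright_pass(self):
        c = _cand(
            evidence={
                "S1": SampleEvidence(5, 4, 10),
                "S2": SampleEvidence(4, 5, 10),
            }
        )
        assert filter_support(c, self.thresholds) == {"S1": False, "S2": False}

    def test_low_fraction_fails_regardless(self):
        c = _cand(
            evidence={
                "S1": SampleEvidence(4, 4, 10),  # 8/10 = 0.80
                "S2": SampleEvidence(15, 15, 30),
            }
        )
        assert filter_support(c, self.thresholds)["S1"] is False

    def test_zero_depth_excluded_not_failed(self):
        c = _cand(
            evidence={
                "S1": SampleEvidence(0, 0, 0),
                "S2": SampleEvidence(15, 15, 30),
            }
        )
        assert filter_support(c, self.thresholds) == {"S2": True}

    def test_strict_direction_mode(self):
        strict = FilterThresholds(strict_direction=True)
        c = _cand(evidence={"S1": SampleEvidence(15, 8, 23)})
        assert filter_support(c, strict) == {"S1": False}
        c2 = _cand(evidence={"S1": SampleEvidence(15, 12, 27)})
        assert filter_support(c2, strict) == {"S1": True}


class TestMultiIndividual:
    def test_single_carrier_rejected(self):
        c = _cand(evidence={"S1": SampleEvidence(15, 15, 30)})
        assert filter_multi_individual(c, ["S1"], FilterThresholds()) is None

    def test_two_carriers_validated(self):
        c = _cand(
            evidence={
                "S1": SampleEvidence(15, 15, 30),
                "S2": SampleEvidence(12, 11, 24),
            }
        )
        v = filter_multi_individual(c, ["S1", "S2"], FilterThresholds())
        assert v is not None
        assert v.carriers == ("S1", "S2")
        assert v.supporting == {"S1": 30, "S2": 23}
        assert v.classification == "transition"


class TestClassification:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            ("A", "G", "transition"),
            ("G", "A", "transition"),
            ("C", "T", "transition"),
            ("C", "A", "transversion"),
            ("T", "G", "transversion"),
            ("", "CT", "insertion"),
            ("AG", "", "deletion"),
        ],
    )
    def test_classes(self, ref, alt, expected):
        assert classify_variant(_cand(ref=ref, alt=alt)) == expected

    def test_multiallelic_grouping(self):
        from amplisnp.variant_filter import ValidatedVariant

        def vv(pos, ref, alt):
            v = ValidatedVariant(
                position=pos, ref_allele=ref, alt_allele=alt,
                kind="substitution", classification="",
                carriers=("S1", "S2"), supporting={}, evidence={},
            )
            v.classification = classify_variant(v)
            return v

        vs = [vv(973, "A", "G"), vv(973, "A", "T"), vv(1000, "C", "T")]
        group_multiallelic(vs)
        assert vs[0].multiallelic_group == vs[1].multiallelic_group == 1
        assert vs[2].multiallelic_group is None
        # a transition and a transversion at the same locus
        assert {vs[0].classification, vs[1].classification} == {
            "transition", "transversion",
        }


class TestCascade:
    def test_empty_pileup(self):
        ref = ReferenceSequence("r", "ACGT" * 10)
        validated, trace = run_cascade(Pileup(), ref)
        assert validated == []
        assert trace.stage_counts == (0, 0, 0, 0, 0)

    def test_noise_free_recovery_is_exact(self, noise_free_run):
        """Errors off, >= 2 carriers, depth 25: the validated set equals
        the planted set and nothing is lost after enumeration."""
        run = noise_free_run
        called = {v.key for v in run["validated"]}
        assert called == run["truth"].variant_keys()
        first, *rest = run["trace"].stage_counts
        assert all(c == first for c in rest)

    def test_trace_monotone_under_errors(self, desk_design):
        from amplisnp import (
            CoverageModel, ErrorModel, build_pileup, demux_reads,
            simulate_haplotypes, simulate_reads,
        )

        reference, panel, design = desk_design
        variants = simulate_haplotypes(
            design, reference, 10, carrier_count_distribution=3, seed=41
        )
        reads, _ = simulate_reads(
            design, reference, variants, CoverageModel(20, 0.0),
            ErrorModel(substitution_rate=0.003, hp_underread_rate=0.05,
                       carry_forward_rate=0.02),
            seed=42,
        )
        assigned, _ = demux_reads(
            [(r.read_id, r.sequence, r.group_id) for r in reads], design
        )
        pile = build_pileup(assigned, panel, reference)
        validated, trace = run_cascade(pile, reference, panel)
        counts = trace.stage_counts
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert counts[0] > counts[-1]  # noise raw candidates get filtered
        # no false positives; most planted variants survive (the stringent
        # 90% criterion can legitimately drop a true variant whose alternate
        # allele extends a homopolymer run under homopolymer noise)
        called = {v.key for v in validated}
        planted = {v.key for v in variants}
        assert called <= planted
        assert len(called) >= len(planted) - 2
        # class counts always partition the validated set
        from collections import Counter

        classes = Counter(v.classification for v in validated)
        assert sum(classes.values()) == len(validated)

    def test_single_carrier_planted_variant_never_validated(self, desk_design):
        from amplisnp import (
            CoverageModel, ErrorModel, build_pileup, demux_reads,
            simulate_haplotypes, simulate_reads,
        )

        reference, panel, design = desk_design
        variants = simulate_haplotypes(
            design, reference, 8, carrier_count_distribution=1, seed=51
        )
        reads, _ = simulate_reads(
            design, reference, variants, CoverageModel(25, 0.0), ErrorModel(),
            seed=52,
        )
        assigned, _ = demux_reads(
            [(r.read_id, r.sequence, r.group_id) for r in reads], design
        )
        pile = build_pileup(assigned, panel, reference)
        validated, trace = run_cascade(pile, reference, panel)
        assert validated == []
        assert trace.n_after_support == 8
        assert all(
            reason == "single-individual"
            for reason in trace.rejection_reasons.values()
        )
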