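"""Junction signature detectors against worked examples and brute force."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_homeology, brute_microhomology

from crisismap import junctions as jx
from crisismap.models import BreakpointEnd, HomeologyCandidate, Junction


def make_junction(wa, wb, insert="", pad=0, rng=None):
    """Reference = [pad] + wa + wb + [pad]; junction fuses wa|wb."""
    left = right = ""
    if pad:
        r = rng or np.random.default_rng(0)
        left = "".join(r.choice(list("ACGT"), pad))
        right = "".join(r.choice(list("ACGT"), pad))
    ref = left + wa + wb + right
    p = len(left) + len(wa)
    j = Junction(BreakpointEnd("c", p, "left"), BreakpointEnd("c", p, "right"),
                 insert=insert, name="t")
    return j, ref


class TestMicrohomology:
    def test_fusion_overlap_with_ambiguity(self):
        # A ends ...TTAACG, B starts ACGTTC...: 3-nt overlap, 4 placements
        wa = "GATCGATCGATCGATTAACG"
        wb = "ACGTTCGGCTAGCTAGCTAG"
        j, ref = make_junction(wa, wb)
        sig = jx.detect_microhomology(j, ref)
        assert sig.kind == "microhomology"
        assert sig.homology_length == 3
        assert sig.ambiguity == 4

    def test_blunt_join(self):
        wa = "CCCCCCCCCCCCCCCCTTTT"
        wb = "GGGGAAAAAAAAAAAAAAAA"
        j, ref = make_junction(wa, wb)
        sig = jx.detect_microhomology(j, ref)
        assert sig.kind == "blunt"
        assert sig.homology_length == 0

    def test_seventy_nt_identity_is_not_microhomology(self):
        rng = np.random.default_rng(5)
        x = "".join(rng.choice(list("ACGT"), 70))
        j, ref = make_junction(x, x, pad=90, rng=rng)
        sig = jx.detect_microhomology(j, ref, window=80)
        assert sig.kind != "microhomology"
        assert sig.over_cap
        assert sig.homology_length >= 70

    def test_short_flank_raises_named_error(self):
        j = Junction(BreakpointEnd("c", 5, "left"), BreakpointEnd("c", 5, "right"),
                     name="edge")
        with pytest.raises(jx.FlankError, match="edge"):
            jx.detect_microhomology(j, "ACGTACGTACGT")

    @settings(derandomize=True, max_examples=60)
    @given(st.integers(1, 15), st.integers(0, 10**6))
    def test_planted_overlap_recovered(self, k, seed):
        rng = np.random.default_rng(seed)
        wa = "".join(rng.choice(list("ACGT"), 20))
        wb = wa[-k:] + "".join(rng.choice(list("ACGT"), 20 - k))
        assert jx.exact_overlap(wa, wb) >= k


class TestObservedParsing:
    def test_merged_insert_and_blunt_forms(self):
        wa, wb = "A" * 20, "C" * 20
        assert jx.parse_observed(wa + wb, wa, wb) == (0, "")
        assert jx.parse_observed(wa + "GTGTGTG" + wb, wa, wb) == (0, "GTGTGTG")
        wa2 = "G" * 17 + "ACG"
        wb2 = "ACG" + "T" * 17
        assert jx.parse_observed(wa2 + wb2[3:], wa2, wb2) == (3, "")

    def test_inconsistent_sequence_rejected(self):
        wa, wb = "A" * 20, "C" * 20
        with pytest.raises(ValueError):
            jx.parse_observed("T" * 45, wa, wb)


class TestMicrohomeology:
    def test_imperfect_tract_seven_of_eight(self):
        wa = "TTTTTTTTTTTTACGTACGT"
        wb = "ACGAACGTCCCCCCCCCCCC"
        j, ref = make_junction(wa, wb)
        cand = jx.detect_microhomeology(j, ref)
        assert cand.columns == 8
        assert cand.identity == pytest.approx(0.875)

    def test_perfect_identity_is_subsumed_by_microhomology(self):
        # identical 6-mer at the fusion satisfies both definitions;
        # the final signature must be microhomology
        rng = np.random.default_rng(2)
        wa = "".join(rng.choice(list("ACGT"), 14)) + "ACGTCA"
        wb = "ACGTCA" + "".join(rng.choice(list("ACGT"), 14))
        j, ref = make_junction(wa, wb)
        sig = jx.classify_junction(j, ref)
        assert sig.kind == "microhomology"

    def test_four_nt_perfect_match_rejected(self):
        # best candidate of 4 columns at 100% fails the >=5 length rule
        wa = "T" * 16 + "ACGT"
        wb = "ACGT" + "T" * 16
        # the T-runs themselves align, so scrub them with alternating bases
        wa = "TGTGTGTGTGTGTGTGACGT"
        wb = "ACGTCACACACACACACACA"
        cands = jx.homeology_candidates(wa, wb)
        assert all(c.columns >= 5 for c in cands)
        assert not any(
            c.columns == 4 and c.matches == 4 for c in cands
        )

    @pytest.mark.parametrize("seed", range(4))
    def test_precedence_microhomology_never_reported_as_homeology(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 10))
        wa = "".join(rng.choice(list("ACGT"), 20))
        wb = wa[-k:] + "".join(rng.choice(list("ACGT"), 20 - k))
        j, ref = make_junction(wa, wb)
        sig = jx.classify_junction(j, ref)
        assert sig.kind == "microhomology"

    def test_oracle_agreement_on_random_and_planted_windows(self):
        from crisismap.evaluation import oracle_equivalence

        rate = oracle_equivalence(17, brute_microhomology, brute_homeology, n=120)
        assert rate == 1.0


class TestInsertClassification:
    def test_untemplated_seven_bp(self, patient_sim):
        # the catastrophic cluster carries a forced 7-bp untemplated insert
        truth = patient_sim.truths["chr21"]
        tj = truth.junctions[0]
        assert tj.kind == "untemplated_insert"
        assert len(tj.insert) == 7
        sig = jx.classify_junction(tj.junction, patient_sim.refs["chr21"])
        assert sig.kind == "untemplated_insert"
        assert sig.insert_length == 7

    def test_templated_insert_source_recovered(self):
        rng = np.random.default_rng(3)
        wa = "".join(rng.choice(list("ACGT"), 20))
        wb = "".join(rng.choice(list("ACGT"), 20))
        j, ref = make_junction(wa, wb, pad=400, rng=rng)
        src = 100
        ins = ref[src : src + 12]
        j.insert = ins
        sig = jx.classify_insert(j, ref, search_radius=1000)
        assert sig.kind == "templated_insert"
        chrom, s, e, strand = sig.insert_source
        assert ref[s:e] == ins or jx.revcomp(ref[s:e]) == ins

    def test_empty_insert_rejected(self):
        j, ref = make_junction("A" * 20, "C" * 20)
        with pytest.raises(ValueError):
            jx.classify_insert(j, ref)

    def test_insert_absent_from_flanks_is_untemplated(self):
        rng = np.random.default_rng(4)
        wa = "".join(rng.choice(list("ACGT"), 20))
        wb = "".join(rng.choice(list("ACGT"), 20))
        j, ref = make_junction(wa, wb, pad=300, rng=rng)
        for _ in range(50):
            ins = "".join(rng.choice(list("ACGT"), 9))
            if ins not in ref and jx.revcomp(ins) not in ref:
                break
        j.insert = ins
        assert jx.classify_insert(j, ref).kind == "untemplated_insert"


class TestInterchromosomal:
    def test_junction_across_chromosomes_rejected(self):
        with pytest.raises(Exception, match="intrachromosomal"):
            Junction(BreakpointEnd("chr1", 100, "left"),
                     BreakpointEnd("chr2", 100, "right"))


class TestAnnotation:
    REPEATS = [("c", 400, 1200, "LINE"), ("c", 4500, 5400, "SINE")]
    TIMING = [("c", 100, 0.2), ("c", 2100, 0.8)]

    def test_repeat_within_two_kb(self):
        ann = jx.annotate_breakpoint("c", 500, repeats=self.REPEATS)
        assert ann.repeats == ["LINE"]
        ann = jx.annotate_breakpoint("c", 3000, repeats=self.REPEATS)
        assert ann.repeats == ["LINE", "SINE"]
        ann = jx.annotate_breakpoint("c", 8000, repeats=self.REPEATS)
        assert ann.repeats == []

    def test_nearest_timing_with_tie(self):
        ann = jx.annotate_breakpoint("c", 1100, timing=self.TIMING)
        assert ann.replication_timing == [0.2, 0.8]  # equidistant: both
        ann = jx.annotate_breakpoint("c", 300, timing=self.TIMING)
        assert ann.replication_timing == [0.2]

    def test_absent_tracks_stay_none(self):
        ann = jx.annotate_breakpoint("c", 100)
        assert ann.repeats is None
        assert ann.replication_timing is None
        assert ann.de_novo_snvs is None
        assert ann.chromatin_marks is None

    def test_de_novo_count_zero_without_child_private_alleles(self, patient_sim):
        from crisismap.trio import TrioSite

        sites = [
            TrioSite(chrom="chr6", pos=p, father_gt=(0, 1), mother_gt=(0, 0),
                     child_gt=(0, 1), father_ad=(20, 20), mother_ad=(40, 0),
                     child_ad=(20, 20))
            for p in (50_000, 50_050)
        ]
        ann = jx.annotate_breakpoint("chr6", 50_020, trio_sites=sites)
        assert ann.de_novo_snvs == 0
        # a child-private allele inside the window is counted
        sites.append(
            TrioSite(chrom="chr6", pos=50_060, father_gt=(0, 0), mother_gt=(0, 0),
                     child_gt=(0, 1), father_ad=(40, 0), mother_ad=(40, 0),
                     child_ad=(20, 20))
        )
        assert jx.annotate_breakpoint("chr6", 50_020, trio_sites=sites).de_novo_snvs == 1
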