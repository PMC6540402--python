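"""Derivative reconstruction and mechanism classification."""

import numpy as np
import pytest

from crisismap import clusters as cl
from crisismap import junctions as jx
from crisismap.models import (
    BreakpointEnd,
    Junction,
    JunctionSignature,
    RearrangementCluster,
)
from crisismap.simulator import EventSpec, ScenarioConfig, simulate_trio


def sim_cluster(kind, seed, noise=0.0, **extra):
    cfg = ScenarioConfig(
        chromosomes={"chrA": 80_000},
        events=[EventSpec(kind=kind, chrom="chrA", span=(20_000, 60_000), **extra)],
        probe_spacing=400, probe_noise_sd=noise, snv_density=1e-4,
    )
    sim = simulate_trio(cfg, seed)
    truth = sim.truths["chrA"]
    ref = sim.refs["chrA"]
    juncs = [tj.junction for tj in truth.junctions]
    sigs = [jx.classify_junction(j, ref) for j in juncs]
    cuts = cl.breakend_cuts(juncs, truth.length)
    cn = cl.cn_from_probes([(p, v) for _, p, v in sim.probes], cuts)
    return sim, truth, juncs, sigs, cn


class TestReconstruction:
    def test_tandem_duplication_walk(self):
        # head-to-tail junction over a CN-2 segment -> ...[a,b)[a,b)...
        j = Junction(BreakpointEnd("c", 20_000, "left"),
                     BreakpointEnd("c", 10_000, "right"), name="dup")
        cn = [(0, 10_000, 1), (10_000, 20_000, 2), (20_000, 30_000, 1)]
        layout, nwalks, deleted = cl.reconstruct_derivative([j], cn, 30_000)
        assert layout == [(0, 20_000, "+"), (10_000, 30_000, "+")]
        assert deleted == []

    def test_balanced_inversion_walk(self):
        a, b, L = 10_000, 20_000, 30_000
        j1 = Junction(BreakpointEnd("c", a, "left"), BreakpointEnd("c", b, "left"),
                      name="i1")
        j2 = Junction(BreakpointEnd("c", a, "right"), BreakpointEnd("c", b, "right"),
                      name="i2")
        cn = [(0, L, 1)]
        layout, nwalks, _ = cl.reconstruct_derivative([j1, j2], cn, L)
        assert layout == [(0, a, "+"), (a, b, "-"), (b, L, "+")]
        assert nwalks == 1

    def test_inconsistent_junction_set_raises(self):
        # a lone head-head junction over flat copy number has no walk
        j = Junction(BreakpointEnd("c", 10_000, "left"),
                     BreakpointEnd("c", 20_000, "left"), name="bad")
        with pytest.raises(cl.InconsistentJunctionsError, match="bad"):
            cl.reconstruct_derivative([j], [(0, 30_000, 1)], 30_000)

    @pytest.mark.parametrize("seed", range(6))
    def test_chromothripsis_truth_round_trip(self, seed):
        sim, truth, juncs, sigs, cn = sim_cluster("chromothripsis", seed,
                                                  fragments=6, delete_prob=0.34)
        layout, nwalks, deleted = cl.reconstruct_derivative(juncs, cn, truth.length)
        if nwalks == 1:
            assert layout == cl.ly_normalize(truth.planned_layout)
        # deleted fragments are exactly the CN-0 span
        zero = {(s, e) for s, e, c in cn if c == 0}
        assert set(deleted) <= zero or zero == set()

    @pytest.mark.parametrize("kind,extra", [
        ("tandem_duplication", {}),
        ("inverted_duplication_with_deletion", {}),
        ("double_inversion_with_deletion", {}),
        ("chromoanasynthesis", {"fragments": 6}),
    ])
    def test_linearize_regenerates_junction_set(self, kind, extra):
        sim, truth, juncs, sigs, cn = sim_cluster(kind, 3, **extra)
        layout, nwalks, _ = cl.reconstruct_derivative(juncs, cn, truth.length)
        regen = cl.linearize(layout, "chrA")
        key = lambda j: (j.end_a.pos, j.end_a.side, j.end_b.pos, j.end_b.side)
        swap = lambda j: (j.end_b.pos, j.end_b.side, j.end_a.pos, j.end_a.side)
        have = {key(j) for j in juncs} | {swap(j) for j in juncs}
        assert len(regen) == len(juncs)
        assert all(key(j) in have for j in regen)


class TestClassification:
    def make(self, juncs, sig_kinds, cn, insert_lengths=None):
        sigs = []
        for i, k in enumerate(sig_kinds):
            sigs.append(JunctionSignature(
                kind=k,
                insert_length=(insert_lengths or {}).get(i, 0),
                homology_length=3 if k == "microhomology" else 0,
            ))
        return RearrangementCluster(chrom="c", junctions=juncs, signatures=sigs,
                                    cn_segments=cn)

    def inv_junctions(self, n):
        out = []
        for i in range(n):
            a, b = 1000 * (i + 1), 1000 * (i + 10)
            out.append(Junction(BreakpointEnd("c", a, "left"),
                                BreakpointEnd("c", b, "left"), name=f"j{i}"))
        return out

    def test_catastrophic_cluster_is_chromothripsis(self):
        # many junctions, interspersed deletions, an untemplated insert,
        # per-haplotype CN never above 1
        cn = [(0, 5_000, 1), (5_000, 6_000, 0), (6_000, 9_000, 1),
              (9_000, 10_000, 0), (10_000, 20_000, 1)]
        c = self.make(self.inv_junctions(8),
                      ["blunt"] * 6 + ["untemplated_insert", "microhomology"],
                      cn, insert_lengths={6: 7})
        c = cl.classify_cluster(c)
        assert c.mechanism == "chromothripsis"
        assert set(c.junction_mechanisms) == {"chromothripsis_consistent"}

    def test_gain_with_templated_insert_is_chromoanasynthesis(self):
        cn = [(0, 5_000, 1), (5_000, 8_000, 2), (8_000, 20_000, 1)]
        c = self.make(self.inv_junctions(5),
                      ["templated_insert", "microhomology", "blunt", "blunt",
                       "blunt"], cn)
        assert cl.classify_cluster(c).mechanism == "chromoanasynthesis"

    def test_chromothripsis_never_called_with_templated_insert(self):
        # rule-order property: even a deletion-rich multi-junction cluster
        # cannot be chromothripsis once a templated insert is present
        cn = [(0, 5_000, 1), (5_000, 6_000, 0), (6_000, 20_000, 1)]
        c = self.make(self.inv_junctions(6), ["templated_insert"] + ["blunt"] * 5,
                      cn)
        assert cl.classify_cluster(c).mechanism != "chromothripsis"

    def test_single_gain_junction_with_microhomology(self):
        j = Junction(BreakpointEnd("c", 8_000, "left"),
                     BreakpointEnd("c", 3_000, "right"), name="d")
        cn = [(0, 3_000, 1), (3_000, 8_000, 2), (8_000, 20_000, 1)]
        c = self.make([j], ["microhomology"], cn)
        c = cl.classify_cluster(c)
        assert c.mechanism == "tandem_duplication"
        assert c.junction_mechanisms == ["replication_based"]
        assert c.secondary_possibility == "chromothripsis_not_excluded"

    def test_blunt_single_junction_is_nhej(self):
        j = Junction(BreakpointEnd("c", 8_000, "left"),
                     BreakpointEnd("c", 3_000, "right"), name="d")
        cn = [(0, 3_000, 1), (3_000, 8_000, 2), (8_000, 20_000, 1)]
        c = cl.classify_cluster(self.make([j], ["blunt"], cn))
        assert c.junction_mechanisms == ["NHEJ"]
        assert c.secondary_possibility == ""

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            cl.classify_cluster(RearrangementCluster(
                chrom="c", junctions=[], signatures=[], cn_segments=[]))

    def test_recovery_across_event_types(self):
        from crisismap.evaluation import EXPECTED_MECHANISM, mechanism_recovery

        assert mechanism_recovery(23, n_clusters=60) >= 0.95

    def test_recovery_degrades_gracefully_with_probe_noise(self):
        from crisismap.evaluation import mechanism_recovery

        r0 = mechanism_recovery(31, n_clusters=36, probe_noise_sd=0.0)
        r3 = mechanism_recovery(31, n_clusters=36, probe_noise_sd=0.3)
        assert r0 >= r3  # noise never helps


class TestCnFromProbes:
    def test_exact_at_zero_noise(self):
        rng = np.random.default_rng(0)
        cuts = [0, 1000, 2000, 3000]
        probes = []
        for lo, hi, cn in [(0, 1000, 2), (1000, 2000, 3), (2000, 3000, 1)]:
            for p in range(lo + 50, hi, 100):
                probes.append((p, float(np.log2(cn / 2.0))))
        cn = cl.cn_from_probes(probes, cuts)
        assert [c for _, _, c in cn] == [1, 2, 0]  # per transmitted haplotype

    def test_probeless_fragment_defaults_to_neutral(self):
        cn = cl.cn_from_probes([(50, 0.0)], [0, 100, 200])
        assert cn == [(0, 100, 1), (100, 200, 1)]
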