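"""Cluster reconstruction and rearrangement-mechanism classification.

Junctions are grouped per chromosome arm; the derivative chromosome is
reconstructed by walking the breakpoint graph from the proximal end,
consuming each junction edge once and each reference fragment as many
times as its per-haplotype copy number allows.  The cluster then receives
a mechanism label:

1. four or more junctions with per-haplotype copy number <= 1 everywhere,
   interspersed deletions and no templated inserts -> chromothripsis;
2. any copy gain together with templated inserts -> chromoanasynthesis;
3. a single junction over a uniform one-segment gain -> tandem duplication;
4. two orientation-flipping junctions with a balanced profile -> balanced
   inversion;
5. gain + flip + loss -> inverted duplication with deletion; flips + loss
   without gain -> complex inversion/deletion; otherwise unclassified.

A cluster with duplication and junctional microhomology keeps its simple
label but carries a secondary possibility that chromothripsis cannot be
excluded, since duplications and microhomology have been described in
chromothriptic germline events.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from . import layout as ly
from .models import Junction, JunctionSignature, RearrangementCluster

MIN_CHROMOTHRIPSIS_JUNCTIONS = 4


class InconsistentJunctionsError(ValueError):
    """No derivative walk is consistent with the junction set."""


# --------------------------------------------------------------------------
# copy number from probes
# --------------------------------------------------------------------------


def breakend_cuts(junctions: Sequence[Junction], chrom_len: int) -> list[int]:
    cuts = {0, chrom_len}
    for j in junctions:
        cuts.add(j.end_a.pos)
        cuts.add(j.end_b.pos)
    return sorted(cuts)


def cn_from_probes(
    probes: Sequence[tuple[int, float]],
    cuts: Sequence[int],
    min_probes: int = 1,
) -> list[tuple[int, int, int]]:
    """Per-haplotype copy number per fragment from probe log2 ratios.

    Total child copy number is 2 * 2^mean-log-ratio; the transmitted
    rearranged haplotype carries total - 1 copies (one homolog is always
    intact).  Fragments with fewer than ``min_probes`` probes inherit the
    neutral value 1; choose a probe spacing no larger than a third of the
    smallest expected fragment to avoid this.
    """
    positions = np.array([p for p, _ in probes])
    values = np.array([v for _, v in probes])
    out = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        mask = (positions >= a) & (positions < b)
        if mask.sum() < min_probes:
            out.append((a, b, 1))
            continue
        mean = float(values[mask].mean())
        total = 2.0 * 2.0 ** mean
        out.append((a, b, max(int(round(total)) - 1, 0)))
    return out


def _cn_at(cn_segments: Sequence[tuple[int, int, int]], pos: int) -> int:
    for s, e, c in cn_segments:
        if s <= pos < e:
            return c
    return 1


# --------------------------------------------------------------------------
# breakpoint-graph walk
# --------------------------------------------------------------------------


def reconstruct_derivative(
    junctions: Sequence[Junction],
    cn_segments: Sequence[tuple[int, int, int]],
    chrom_len: int,
    max_walks: int = 64,
) -> tuple[list[ly.Segment], int, list[tuple[int, int]]]:
    """Walk the breakpoint graph into an ordered, oriented fragment list.

    Starts at the proximal (position-0) end moving rightward, consumes
    each junction edge exactly once and each fragment up to its
    per-haplotype copy number, and must finish at the distal end with all
    junctions used and all copies consumed.  Returns ``(layout,
    number-of-consistent-walks, deleted fragments)``; with several
    consistent walks the deterministic junction-first, lowest-coordinate
    walk is returned.
    """
    cuts = breakend_cuts(junctions, chrom_len)
    frag_index = {a: i for i, (a, b) in enumerate(zip(cuts[:-1], cuts[1:]))}
    frags = list(zip(cuts[:-1], cuts[1:]))
    budgets = [_cn_at(cn_segments, (a + b) // 2) for a, b in frags]

    # junction ends keyed by (pos, arrival direction); several ends may
    # share a key (fold-back junctions, reused breakends of CN-2 fragments)
    ends: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for ji, j in enumerate(junctions):
        key_a = (j.end_a.pos, +1 if j.end_a.side == "left" else -1)
        key_b = (j.end_b.pos, +1 if j.end_b.side == "left" else -1)
        ends.setdefault(key_a, []).append((ji, 0))
        if key_b != key_a:  # fold-back: both ends are one and the same breakend
            ends.setdefault(key_b, []).append((ji, 1))

    solutions: list[list[ly.Segment]] = []
    first_solution: list[Optional[list[ly.Segment]]] = [None]
    count = [0]

    def record(path):
        count[0] += 1
        if first_solution[0] is None:
            first_solution[0] = list(path)

    def step(pos, direction, used, budget, path):
        """Traverse one fragment, then branch at the reached breakend."""
        if count[0] >= max_walks:
            return
        if direction > 0:
            if pos == chrom_len:
                if used == (1 << len(junctions)) - 1 and all(b == 0 for b in budget):
                    record(path)
                return
            fi = frag_index[pos]
            if budget[fi] <= 0:
                return
            budget[fi] -= 1
            a, b = frags[fi]
            path.append((a, b, "+"))
            _branch(b, +1, used, budget, path)
            path.pop()
            budget[fi] += 1
        else:
            if pos == 0:
                return  # a derivative never terminates at the proximal end
            fi = frag_index[cuts[cuts.index(pos) - 1]]
            if budget[fi] <= 0:
                return
            budget[fi] -= 1
            a, b = frags[fi]
            path.append((a, b, "-"))
            _branch(a, -1, used, budget, path)
            path.pop()
            budget[fi] += 1

    def _branch(pos, direction, used, budget, path):
        for ji, side_idx in ends.get((pos, direction), ()):
            if used & (1 << ji):
                continue
            j = junctions[ji]
            other = j.end_b if side_idx == 0 else j.end_a
            ndir = +1 if other.side == "right" else -1
            step(other.pos, ndir, used | (1 << ji), budget, path)
        # continuing through the reference past an available junction is the
        # branching-ambiguity case; both options are explored
        step(pos, direction, used, budget, path)

    step(0, +1, 0, budgets, [])

    if first_solution[0] is None:
        missing = [j.name for j in junctions]
        raise InconsistentJunctionsError(
            f"no consistent derivative walk for junction set {missing} "
            f"with copy numbers {cn_segments}"
        )
    layout = _normalize(first_solution[0])
    visited = set()
    walk = first_solution[0]
    for a, b, _ in walk:
        visited.add((a, b))
    deleted = [f for f, bud in zip(frags, budgets) if bud == 0 and f not in visited]
    return layout, count[0], deleted


def _normalize(path: list[ly.Segment]) -> list[ly.Segment]:
    """Merge reference-contiguous runs into maximal segments."""
    out: list[ly.Segment] = []
    for seg in path:
        if out:
            s0, e0, o0 = out[-1]
            s1, e1, o1 = seg
            if o0 == "+" and o1 == "+" and e0 == s1:
                out[-1] = (s0, e1, "+")
                continue
            if o0 == "-" and o1 == "-" and s0 == e1:
                out[-1] = (s1, e0, "-")
                continue
        out.append(seg)
    return out


def linearize(layout: list[ly.Segment], chrom: str) -> list[Junction]:
    """Junction set regenerated from a derivative layout."""
    return [j for _, j in ly.junctions_from_layout(ly_normalize(layout), chrom)]


def ly_normalize(layout: list[ly.Segment]) -> list[ly.Segment]:
    return _normalize(list(layout))


# --------------------------------------------------------------------------
# mechanism classification
# --------------------------------------------------------------------------


def _is_flip(j: Junction) -> bool:
    """True when the junction flips orientation (head-head or tail-tail)."""
    return (j.end_a.side == "left") == (j.end_b.side == "left")


def classify_cluster(
    cluster: RearrangementCluster,
    min_chromothripsis_junctions: int = MIN_CHROMOTHRIPSIS_JUNCTIONS,
) -> RearrangementCluster:
    """Assign the cluster mechanism and per-junction repair mechanisms."""
    if not cluster.junctions:
        raise ValueError("cannot classify an empty cluster")
    kinds = [s.kind for s in cluster.signatures]
    cn = cluster.cn_segments
    max_cn = max(c for _, _, c in cn)
    has_gain = max_cn >= 2
    has_loss = any(c == 0 for _, _, c in cn)
    has_templated = "templated_insert" in kinds
    has_flip = any(_is_flip(j) for j in cluster.junctions)
    nj = len(cluster.junctions)

    if (
        nj >= min_chromothripsis_junctions
        and max_cn <= 1
        and has_loss
        and not has_templated
    ):
        mech = "chromothripsis"
    elif has_gain and has_templated:
        mech = "chromoanasynthesis"
    elif nj == 1 and has_gain and not has_loss:
        mech = "tandem_duplication"
    elif nj == 2 and not has_gain and not has_loss and has_flip:
        mech = "balanced_inversion"
    elif has_gain and has_loss and has_flip:
        mech = "inverted_duplication_with_deletion"
    elif has_loss and has_flip and not has_gain:
        mech = "complex_inversion_deletion"
    else:
        mech = "unclassified"
    cluster.mechanism = mech

    per_junction = []
    for j, s in zip(cluster.junctions, cluster.signatures):
        if mech == "chromothripsis":
            per_junction.append("chromothripsis_consistent")
        elif s.kind in ("microhomology", "microhomeology") and has_gain:
            per_junction.append("replication_based")
        elif s.kind == "templated_insert":
            per_junction.append("replication_based")
        elif s.kind == "blunt" or (
            s.kind == "untemplated_insert" and s.insert_length <= 10
        ):
            per_junction.append("NHEJ")
        else:
            per_junction.append("ambiguous")
    cluster.junction_mechanisms = per_junction

    if mech in ("tandem_duplication", "inverted_duplication_with_deletion") and any(
        k in ("microhomology", "microhomeology") for k in kinds
    ):
        # duplication + microhomology has been described in chromothripsis
        cluster.secondary_possibility = "chromothripsis_not_excluded"
    return cluster


def build_cluster(
    chrom: str,
    junctions: Sequence[Junction],
    signatures: Sequence[JunctionSignature],
    cn_segments: Sequence[tuple[int, int, int]],
    chrom_len: int,
    reconstruct: bool = True,
    min_chromothripsis_junctions: int = MIN_CHROMOTHRIPSIS_JUNCTIONS,
) -> RearrangementCluster:
    """Assemble, reconstruct and classify one per-arm cluster."""
    cluster = RearrangementCluster(
        chrom=chrom,
        junctions=list(junctions),
        signatures=list(signatures),
        cn_segments=list(cn_segments),
    )
    if reconstruct:
        try:
            layout, nwalks, deleted = reconstruct_derivative(
                junctions, cn_segments, chrom_len
            )
            cluster.derivative = layout
            cluster.walk_count = nwalks
            cluster.deleted_fragments = deleted
        except InconsistentJunctionsError:
            cluster.derivative = None
            cluster.walk_count = 0
    return classify_cluster(cluster, min_chromothripsis_junctions)
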