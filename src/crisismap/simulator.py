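"""Trio simulator for germline complex rearrangements.

Generates, from a seed and a scenario configuration, a father-mother-child
trio in which the father's germline acquired one rearrangement cluster per
configured chromosome during premeiotic mitosis, optionally reshaped by a
single meiosis-I crossover inside a duplicated span.  Every emitted file
(reference FASTA, truth BEDPE + junction sequences, trio VCF, aCGH probe
table, microsatellite peak table, methylation table) is accompanied by
machine-readable ground truth, so the analysis modules can be validated
end to end without any external data.

Junction signatures are engineered into the reference: breakpoint
neighbourhoods are rejection-sampled until the intended signature (blunt,
microhomology, microhomeology, untemplated or templated insert) holds
under the package's own definitions against the emitted FASTA.
Untemplated inserts are sampled to be absent from both 1-kb flanks, since
a short random insert would otherwise frequently have a spurious template
nearby.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from . import junctions as jx
from . import layout as ly
from .models import BreakpointEnd, ConfigurationError, Junction

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

EVENT_KINDS = (
    "tandem_duplication",
    "balanced_inversion",
    "inverted_duplication_with_deletion",
    "double_inversion_with_deletion",
    "chromothripsis",
    "chromoanasynthesis",
)

#: default junction-signature proportions for non-replicative events
DEFAULT_SIGNATURE_MIX = {
    "blunt": 0.30,
    "microhomology": 0.30,
    "microhomeology": 0.20,
    "untemplated_insert": 0.20,
    "templated_insert": 0.0,
}

MIN_CHROM_LEN = 10_000


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


@dataclass
class EventSpec:
    """One rearrangement event on one chromosome.

    ``span`` is the affected interval.  ``crossover`` (events with a
    duplicated span only) is the position of the single meiosis-I
    crossover, as a fraction of the duplicated span.  ``forced_inserts``
    maps junction index to an insert length, e.g. to reproduce a
    junction carrying a 7-bp untemplated insertion.
    """

    kind: str
    chrom: str
    span: tuple[int, int]
    deletion_fraction: float = 0.3  # trailing part of span deleted (inv-dup-del)
    fragments: int = 8
    delete_prob: float = 1.0 / 3.0
    duplicate_count: int = 1  # chromoanasynthesis fragments gaining a copy
    crossover: Optional[float] = None
    signature_mix: Optional[dict[str, float]] = None
    forced_inserts: dict[int, int] = field(default_factory=dict)

    def validate(self, chrom_len: int) -> None:
        if self.kind not in EVENT_KINDS:
            raise ConfigurationError(f"unknown event kind {self.kind!r}")
        s, e = self.span
        if not (0 < s < e <= chrom_len - 1000):
            raise ConfigurationError(
                f"{self.kind} span {self.span} does not fit chromosome "
                f"{self.chrom} of length {chrom_len}"
            )
        if s < 1000:
            raise ConfigurationError("event span must leave a proximal flank")
        if self.kind in ("chromothripsis", "chromoanasynthesis") and self.fragments < 4:
            raise ConfigurationError("catastrophic events need >= 4 fragments")
        if self.crossover is not None and not (0.0 < self.crossover < 1.0):
            raise ConfigurationError("crossover fraction must lie strictly inside the span")

    @property
    def has_duplication(self) -> bool:
        return self.kind in ("tandem_duplication", "inverted_duplication_with_deletion")


@dataclass
class ScenarioConfig:
    """Scenario-level simulation parameters.

    Defaults mirror the study conditions of the analysed case: ~40x mean
    short-read depth, one rearrangement cluster per chromosome arm, a
    maternally methylated imprinted DMR inside the first duplicated span,
    and aCGH probes every kilobase.
    """

    chromosomes: dict[str, int]
    events: list[EventSpec]
    signature_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SIGNATURE_MIX)
    )
    depth: float = 40.0
    error_rate: float = 0.005
    snv_density: float = 5e-4  # informative sites per bp, per parent class
    probe_spacing: int = 1000
    probe_noise_sd: float = 0.15
    msat_per_dup: int = 3
    msat_outside: int = 2
    msat_area_sd: float = 0.05
    methylation_sites: int = 7
    methylation_noise_sd: float = 0.02
    methylation_ref_range: tuple[float, float] = (0.42, 0.58)
    insert_search_radius: int = 1000

    def validate(self) -> None:
        if self.depth <= 0:
            raise ConfigurationError("depth must be positive")
        for name, length in self.chromosomes.items():
            if length <= 0:
                raise ConfigurationError(f"chromosome {name} has zero length")
            if length < MIN_CHROM_LEN:
                raise ConfigurationError(
                    f"chromosome {name} shorter than {MIN_CHROM_LEN} bp"
                )
        _check_mix(self.signature_mix)
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for ev in self.events:
            if ev.chrom not in self.chromosomes:
                raise ConfigurationError(f"event on unknown chromosome {ev.chrom}")
            ev.validate(self.chromosomes[ev.chrom])
            if ev.signature_mix is not None:
                _check_mix(ev.signature_mix)
            per_chrom.setdefault(ev.chrom, []).append(tuple(ev.span))
        for chrom, spans in per_chrom.items():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans[:-1], spans[1:]):
                if s2 < e1 + 2000:
                    raise ConfigurationError(
                        f"events on {chrom} overlap or sit closer than 2 kb"
                    )

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ScenarioConfig":
        events = []
        for ev in raw.get("events", []):
            ev = dict(ev)
            ev["span"] = tuple(ev["span"])
            forced = {int(k): int(v) for k, v in ev.get("forced_inserts", {}).items()}
            ev["forced_inserts"] = forced
            events.append(EventSpec(**ev))
        kwargs = {k: v for k, v in raw.items() if k not in ("events",)}
        if "methylation_ref_range" in kwargs:
            kwargs["methylation_ref_range"] = tuple(kwargs["methylation_ref_range"])
        cfg = cls(events=events, **kwargs)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["events"] = [dataclasses.asdict(ev) for ev in self.events]
        return d


def _check_mix(mix: dict[str, float]) -> None:
    unknown = set(mix) - set(DEFAULT_SIGNATURE_MIX)
    if unknown:
        raise ConfigurationError(f"unknown signature kinds in mix: {sorted(unknown)}")
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError(f"signature mix proportions sum to {total}, not 1")
    if any(v < 0 for v in mix.values()):
        raise ConfigurationError("signature mix proportions must be non-negative")


# --------------------------------------------------------------------------
# ground truth containers
# --------------------------------------------------------------------------


@dataclass
class TruthJunction:
    junction: Junction  # observed sequence and insert filled in
    kind: str
    homology: int = 0
    insert: str = ""
    insert_source: Optional[tuple[str, int, int, str]] = None


@dataclass
class ChromTruth:
    chrom: str
    length: int
    event: Optional[EventSpec]
    planned_layout: list[ly.Segment]
    layout: list[ly.Segment]  # physical (homology tracts merged)
    junctions: list[TruthJunction]
    cn_segments: list[tuple[int, int, int]]  # per transmitted haplotype
    dup_span: Optional[tuple[int, int]] = None
    crossover_pos: Optional[int] = None
    allelic_segments: list[tuple[int, int, str]] = field(default_factory=list)
    origin_map: list[tuple[int, int, tuple[str, ...]]] = field(default_factory=list)
    parent: str = "father"

    def to_dict(self) -> dict:
        return {
            "chrom": self.chrom,
            "length": self.length,
            "event": None if self.event is None else dataclasses.asdict(self.event),
            "planned_layout": [list(s) for s in self.planned_layout],
            "layout": [list(s) for s in self.layout],
            "junctions": [
                {
                    "name": tj.junction.name,
                    "end_a": [tj.junction.end_a.pos, tj.junction.end_a.side],
                    "end_b": [tj.junction.end_b.pos, tj.junction.end_b.side],
                    "kind": tj.kind,
                    "homology": tj.homology,
                    "insert": tj.insert,
                    "insert_source": list(tj.insert_source) if tj.insert_source else None,
                    "observed": tj.junction.observed,
                }
                for tj in self.junctions
            ],
            "cn_segments": [list(s) for s in self.cn_segments],
            "dup_span": list(self.dup_span) if self.dup_span else None,
            "crossover_pos": self.crossover_pos,
            "allelic_segments": [list(s) for s in self.allelic_segments],
            "origin_map": [[s, e, list(o)] for s, e, o in self.origin_map],
            "parent": self.parent,
        }


@dataclass
class SimSite:
    """Ground truth plus sampled reads for one trio SNV site."""

    chrom: str
    pos: int
    ref: str
    alt: str
    informative_parent: str  # father | mother
    father_gt: tuple[int, int]
    mother_gt: tuple[int, int]
    child_gt: tuple[int, ...]
    father_ad: tuple[int, int]
    mother_ad: tuple[int, int]
    child_ad: tuple[int, int]
    truth_status: str  # diploid | diallelic | triallelic | deleted
    specific_fraction_truth: float


# --------------------------------------------------------------------------
# reference simulation
# --------------------------------------------------------------------------


def simulate_reference(
    chromosomes: dict[str, int], rng: np.random.Generator
) -> dict[str, str]:
    """Uniform-base random chromosomes, reproducible under a fixed seed."""
    refs = {}
    for name, length in chromosomes.items():
        if length <= 0:
            raise ConfigurationError(f"chromosome {name} has zero length")
        arr = BASES[rng.integers(0, 4, size=length)]
        refs[name] = arr.tobytes().decode()
    return refs


# --------------------------------------------------------------------------
# event layouts
# --------------------------------------------------------------------------


def _tandem_duplication_layout(ev, L):
    s, e = ev.span
    return [(0, e, "+"), (s, L, "+")], {"dup_span": (s, e)}


def _balanced_inversion_layout(ev, L):
    s, e = ev.span
    return [(0, s, "+"), (s, e, "-"), (e, L, "+")], {}


def _inv_dup_del_layout(ev, L):
    s, e = ev.span
    d = e - int(round((e - s) * ev.deletion_fraction))
    # duplicated (inverted second copy) [s, d), deleted [d, e)
    return [(0, d, "+"), (s, d, "-"), (e, L, "+")], {"dup_span": (s, d)}


def _double_inv_del_layout(ev, L):
    s, e = ev.span
    w = e - s
    a, b, c, d = s, s + int(w * 0.4), s + int(w * 0.6), e
    return [(0, a, "+"), (a, b, "-"), (c, d, "-"), (d, L, "+")], {}


def _cut_span(ev, rng) -> list[int]:
    s, e = ev.span
    n = ev.fragments
    min_frag = max(200, (e - s) // (4 * n))
    for _ in range(500):
        cuts = np.sort(rng.integers(s + min_frag, e - min_frag, size=n - 1))
        if len(set(cuts.tolist())) == n - 1 and np.all(np.diff(cuts) >= min_frag):
            return [s] + cuts.tolist() + [e]
    raise ConfigurationError(
        f"cannot cut span {ev.span} into {n} fragments of >= {min_frag} bp"
    )


def _shatter_layout(ev, L, rng):
    """Chromothripsis: shatter, drop a subset, permute/invert survivors."""
    bounds = _cut_span(ev, rng)
    frags = list(zip(bounds[:-1], bounds[1:]))
    for _ in range(2000):
        keep_mask = rng.random(len(frags)) >= ev.delete_prob
        # at least one fragment lost, and at least three kept so that the
        # rejoined arm can carry the four-junction chromothripsis minimum
        if not (3 <= int(keep_mask.sum()) <= len(frags) - 1):
            continue
        kept = [f for f, k in zip(frags, keep_mask) if k]
        order = rng.permutation(len(kept))
        orients = rng.random(len(kept)) < 0.5
        mid = [
            (kept[i][0], kept[i][1], "-" if inv else "+")
            for i, inv in zip(order, orients)
        ]
        lay = [(0, ev.span[0], "+")] + mid + [(ev.span[1], L, "+")]
        if len(ly.junctions_from_layout(lay, "x")) >= 4:
            return lay, {"deleted": [f for f, k in zip(frags, keep_mask) if not k]}
    raise ConfigurationError("cannot arrange chromothripsis fragments into >= 4 junctions")


def _chromoanasynthesis_layout(ev, L, rng):
    """Replicative catastrophe: shatter with >= 1 fragment copy gain."""
    bounds = _cut_span(ev, rng)
    frags = list(zip(bounds[:-1], bounds[1:]))
    ndup = max(1, min(ev.duplicate_count, len(frags) - 2))
    for _ in range(500):
        dup_idx = set(rng.choice(len(frags), size=ndup, replace=False).tolist())
        keep_mask = rng.random(len(frags)) >= 0.2
        for i in dup_idx:
            keep_mask[i] = True
        if 2 <= int(keep_mask.sum()):
            break
    else:
        raise ConfigurationError("cannot draw a chromoanasynthesis arrangement")
    pool = []
    for i, (f, k) in enumerate(zip(frags, keep_mask)):
        if not k:
            continue
        pool.append(f)
        if i in dup_idx:
            pool.append(f)
    for _ in range(500):
        order = rng.permutation(len(pool))
        orients = rng.random(len(pool)) < 0.5
        mid = [
            (pool[i][0], pool[i][1], "-" if inv else "+")
            for i, inv in zip(order, orients)
        ]
        lay = [(0, ev.span[0], "+")] + mid + [(ev.span[1], L, "+")]
        if len(ly.junctions_from_layout(lay, "x")) >= 2:
            return lay, {"gained": [frags[i] for i in sorted(dup_idx)]}
    raise ConfigurationError("cannot arrange chromoanasynthesis fragments")


def plan_event_layout(ev: EventSpec, chrom_len: int, rng: np.random.Generator):
    """Planned (untrimmed) whole-chromosome layout for one event."""
    if ev.kind == "tandem_duplication":
        return _tandem_duplication_layout(ev, chrom_len)
    if ev.kind == "balanced_inversion":
        return _balanced_inversion_layout(ev, chrom_len)
    if ev.kind == "inverted_duplication_with_deletion":
        return _inv_dup_del_layout(ev, chrom_len)
    if ev.kind == "double_inversion_with_deletion":
        return _double_inv_del_layout(ev, chrom_len)
    if ev.kind == "chromothripsis":
        return _shatter_layout(ev, chrom_len, rng)
    if ev.kind == "chromoanasynthesis":
        return _chromoanasynthesis_layout(ev, chrom_len, rng)
    raise ConfigurationError(f"unknown event kind {ev.kind!r}")


# --------------------------------------------------------------------------
# signature engineering
# --------------------------------------------------------------------------


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def _window_region(end: BreakpointEnd, n: int) -> tuple[int, int]:
    if end.side == "left":
        return end.pos - n, end.pos
    return end.pos, end.pos + n


def _write_b_window(ref: str, end: BreakpointEnd, wb: str) -> str:
    """Set the B-side flank window (derivative orientation ``wb``)."""
    lo, hi = _window_region(end, len(wb))
    content = wb if end.side == "right" else jx.revcomp(wb)
    return ref[:lo] + content + ref[hi:]


def _write_a_suffix(ref: str, end: BreakpointEnd, suffix: str) -> str:
    """Set the last ``len(suffix)`` bases of the A-side flank window."""
    k = len(suffix)
    if end.side == "left":
        lo, hi = end.pos - k, end.pos
        content = suffix
    else:
        lo, hi = end.pos, end.pos + k
        content = jx.revcomp(suffix)
    return ref[:lo] + content + ref[hi:]


def _windows_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


_OTHER = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}


def engineer_junction(
    ref: str,
    junction: Junction,
    kind: str,
    rng: np.random.Generator,
    radius: int = 1000,
    forced_insert_len: Optional[int] = None,
    blocked: Optional[list[tuple[int, int]]] = None,
) -> tuple[str, TruthJunction]:
    """Edit breakpoint neighbourhoods until the junction carries ``kind``.

    Returns the edited reference and the truth junction (homology length,
    insert, template source).  ``blocked`` intervals (other junctions'
    windows) are never edited and never used as templated-insert sources.
    """
    n = jx.SCAN_WINDOW
    reg_a = _window_region(junction.end_a, n)
    reg_b = _window_region(junction.end_b, n)
    foldback = _windows_overlap(reg_a, reg_b)
    blocked = blocked or []

    def current_kind(r: str) -> str:
        sig = jx.classify_junction(
            Junction(junction.end_a, junction.end_b, name=junction.name),
            r, window=n, insert_radius=radius,
        )
        return sig.kind

    if kind in ("untemplated_insert", "templated_insert"):
        if kind == "untemplated_insert":
            # a random insert much below 7 nt is nearly always matched by
            # chance within 1 kb, so it could never be called untemplated
            length = forced_insert_len or int(rng.integers(7, 13))
            for _ in range(500):
                ins = _rand_seq(rng, length)
                probe = Junction(junction.end_a, junction.end_b, insert=ins,
                                 name=junction.name)
                if jx.classify_insert(probe, ref, radius).kind == "untemplated_insert":
                    return ref, TruthJunction(
                        junction=probe, kind=kind, insert=ins)
            raise ConfigurationError("cannot sample an untemplated insert")
        length = forced_insert_len or int(rng.integers(10, 15))
        for _ in range(500):
            anchor = junction.end_a.pos if rng.random() < 0.5 else junction.end_b.pos
            off = int(rng.integers(60, radius - length - 10))
            src = anchor - off - length if rng.random() < 0.5 else anchor + off
            if src < 0 or src + length > len(ref):
                continue
            if any(_windows_overlap((src, src + length), b)
                   for b in blocked + [reg_a, reg_b]):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            seq = ref[src : src + length]
            ins = seq if strand == "+" else jx.revcomp(seq)
            probe = Junction(junction.end_a, junction.end_b, insert=ins,
                             name=junction.name)
            sig = jx.classify_insert(probe, ref, radius)
            if sig.kind == "templated_insert":
                return ref, TruthJunction(
                    junction=probe, kind=kind, insert=ins,
                    insert_source=(junction.chrom, src, src + length, strand))
        raise ConfigurationError("cannot place a templated insert source")

    # sequence-borne signatures: edit the B window (or the shared window
    # of a fold-back junction) until the classifier agrees
    for _ in range(500):
        if current_kind(ref) == kind:
            probe = Junction(junction.end_a, junction.end_b, name=junction.name)
            wa = jx.flank_a(ref, junction.end_a, n)
            wb = jx.flank_b(ref, junction.end_b, n)
            k = jx.exact_overlap(wa, wb)
            return ref, TruthJunction(junction=probe, kind=kind, homology=k)
        wa = jx.flank_a(ref, junction.end_a, n)
        if kind == "blunt":
            if foldback:
                ref = _write_a_suffix(ref, junction.end_a, _rand_seq(rng, n))
            else:
                ref = _write_b_window(ref, junction.end_b, _rand_seq(rng, n))
        elif kind == "microhomology":
            if foldback:
                half = int(rng.integers(1, 4))
                stem = _rand_seq(rng, half)
                pal = stem + jx.revcomp(stem)  # reverse-complement palindrome
                suffix = _rand_seq(rng, 6) + pal
                ref = _write_a_suffix(ref, junction.end_a, suffix)
            else:
                k = int(rng.integers(2, 9))
                wb = wa[-k:] + _rand_seq(rng, n - k)
                ref = _write_b_window(ref, junction.end_b, wb)
        elif kind == "microhomeology":
            if foldback:
                raise ConfigurationError(
                    "microhomeology cannot be engineered at a fold-back junction"
                )
            L = int(rng.integers(6, 11))
            nm = 1 if L <= 7 else 2
            tract = list(wa[-L:])
            for p in rng.choice(L, size=nm, replace=False):
                tract[p] = _OTHER[tract[p]][int(rng.integers(0, 3))]
            wb = "".join(tract) + _rand_seq(rng, n - L)
            ref = _write_b_window(ref, junction.end_b, wb)
        else:
            raise ConfigurationError(f"cannot engineer signature {kind!r}")
    raise ConfigurationError(
        f"signature engineering did not converge for {junction.name} ({kind})"
    )


def _draw_signature_kinds(
    ev: EventSpec,
    n_junctions: int,
    foldbacks: list[bool],
    mix: dict[str, float],
    rng: np.random.Generator,
) -> list[str]:
    kinds = []
    for i in range(n_junctions):
        m = dict(ev.signature_mix or mix)
        if ev.kind == "chromothripsis":
            m["templated_insert"] = 0.0
        if foldbacks[i]:
            # fold-back windows are reverse complements of the same bases:
            # only blunt, palindromic microhomology and inserts are realisable
            m["microhomeology"] = 0.0
        total = sum(m.values())
        if total <= 0:
            m = {"blunt": 1.0}
            total = 1.0
        names = sorted(m)
        probs = np.array([m[k] / total for k in names])
        kinds.append(names[int(rng.choice(len(names), p=probs))])
    if ev.kind == "chromoanasynthesis" and "templated_insert" not in kinds:
        free = [i for i, f in enumerate(foldbacks) if not f]
        kinds[free[0] if free else 0] = "templated_insert"
    for idx in ev.forced_inserts:
        kinds[idx] = "untemplated_insert"
    return kinds


# --------------------------------------------------------------------------
# per-chromosome assembly
# --------------------------------------------------------------------------


def apply_rearrangement(
    ref: str,
    ev: Optional[EventSpec],
    mix: dict[str, float],
    rng: np.random.Generator,
    radius: int = 1000,
) -> tuple[str, str, ChromTruth]:
    """Build the rearranged paternal haplotype for one chromosome.

    Returns ``(edited reference, derivative sequence, truth)``.  With no
    event the derivative equals the reference.
    """
    L = len(ref)
    chrom = ev.chrom if ev else "chr"
    if ev is None:
        truth = ChromTruth(
            chrom=chrom, length=L, event=None,
            planned_layout=[(0, L, "+")], layout=[(0, L, "+")],
            junctions=[], cn_segments=[(0, L, 1)],
            origin_map=[(0, L, ("H1",))],
        )
        return ref, ref, truth

    planned, meta = plan_event_layout(ev, L, rng)
    jplan = ly.junctions_from_layout(planned, ev.chrom)
    n = jx.SCAN_WINDOW
    nj = len(jplan)

    regions = []  # per junction: (A window, B window)
    for _, j in jplan:
        regions.append((_window_region(j.end_a, n), _window_region(j.end_b, n)))
    foldbacks = [_windows_overlap(ra, rb) for ra, rb in regions]
    kinds = _draw_signature_kinds(ev, nj, foldbacks, mix, rng)

    # a junction may edit its B window (its shared window when fold-back)
    # only if no other junction reads those bases; otherwise its signature
    # is whatever the sequence naturally carries
    editable = []
    for i, (ra, rb) in enumerate(regions):
        target = ra if foldbacks[i] else rb
        others = [r for j2, pair in enumerate(regions) if j2 != i for r in pair]
        editable.append(not any(_windows_overlap(target, o) for o in others))

    insert_kinds = ("untemplated_insert", "templated_insert")
    inserts = [""] * nj
    sources: list[Optional[tuple]] = [None] * nj
    for _pass in range(10):
        changed = False
        for i, (adj, junc) in enumerate(jplan):
            probe = Junction(junc.end_a, junc.end_b, insert=inserts[i],
                             name=junc.name)
            sig = jx.classify_junction(probe, ref, window=n, insert_radius=radius)
            if sig.kind == kinds[i]:
                continue
            changed = True
            blocked = [r for j2, pair in enumerate(regions) if j2 != i
                       for r in pair]
            if kinds[i] in insert_kinds:
                ref, tj = engineer_junction(
                    ref, junc, kinds[i], rng, radius=radius,
                    forced_insert_len=ev.forced_inserts.get(i),
                    blocked=blocked,
                )
                inserts[i], sources[i] = tj.insert, tj.insert_source
            elif editable[i]:
                inserts[i], sources[i] = "", None
                ref, tj = engineer_junction(
                    ref, junc, kinds[i], rng, radius=radius, blocked=blocked,
                )
            else:
                # window shared with another junction: accept the natural kind
                inserts[i], sources[i] = "", None
                kinds[i] = sig.kind
        if not changed:
            break
    else:
        raise ConfigurationError(
            f"junction signature engineering did not stabilise on {ev.chrom}"
        )

    truth_jx: list[TruthJunction] = []
    homologies: dict[int, int] = {}
    adj_inserts: dict[int, str] = {}
    for i, (adj, junc) in enumerate(jplan):
        wa = jx.flank_a(ref, junc.end_a, n)
        wb = jx.flank_b(ref, junc.end_b, n)
        k = 0 if inserts[i] else jx.exact_overlap(wa, wb)
        observed = wa + inserts[i] + wb[k:]
        truth_jx.append(
            TruthJunction(
                junction=Junction(junc.end_a, junc.end_b, observed=observed,
                                  insert=inserts[i], name=junc.name),
                kind=kinds[i], homology=k, insert=inserts[i],
                insert_source=sources[i],
            )
        )
        homologies[adj] = k
        adj_inserts[adj] = inserts[i]

    physical = ly.trim_layout(planned, homologies)
    derivative = _build_derivative(ref, physical, adj_inserts)
    cn = ly.coverage_segments(physical, L)

    truth = ChromTruth(
        chrom=ev.chrom, length=L, event=ev,
        planned_layout=planned, layout=physical,
        junctions=truth_jx, cn_segments=cn,
        dup_span=meta.get("dup_span"),
        origin_map=[],
    )
    return ref, derivative, truth


def _build_derivative(ref: str, physical: list[ly.Segment],
                      inserts: dict[int, str]) -> str:
    parts = []
    for i, (s, e, o) in enumerate(physical):
        seg = ref[s:e]
        parts.append(seg if o == "+" else jx.revcomp(seg))
        if i in inserts and inserts[i]:
            parts.append(inserts[i])
    return "".join(parts)


# --------------------------------------------------------------------------
# meiosis
# --------------------------------------------------------------------------


def simulate_meiosis(
    truth: ChromTruth, crossover_fraction: Optional[float]
) -> ChromTruth:
    """Apply at most one meiosis-I crossover inside the duplicated span.

    The transmitted chromosome derives from the carrier haplotype H1; with
    a crossover at x inside the duplicated span, one of the two duplicated
    copies — and everything distal to the span — derives from the
    non-carrier homolog H2.  Sites proximal to x are then diallelic (two
    H1 copies), sites distal are triallelic (one H1, one H2 copy).
    """
    L = truth.length
    if crossover_fraction is None:
        cuts = {0, L}
        for s, e, _ in truth.cn_segments:
            cuts.update((s, e))
        om = []
        for a, b in zip(sorted(cuts)[:-1], sorted(cuts)[1:]):
            c = ly.copies_at(truth.layout, a)
            om.append((a, b, ("H1",) * c))
        truth.origin_map = _merge_origin(om)
        if truth.dup_span:
            truth.allelic_segments = [(*truth.dup_span, "diallelic")]
        truth.crossover_pos = None
        return truth

    if not truth.dup_span:
        raise ConfigurationError(
            f"crossover requested on {truth.chrom} but the event has no duplicated span"
        )
    s, e = truth.dup_span
    x = s + int(round((e - s) * crossover_fraction))
    if not (s < x < e):
        raise ConfigurationError("crossover position falls outside the duplicated span")

    cuts = {0, L, x, s, e}
    for a, b, _ in truth.cn_segments:
        cuts.update((a, b))
    om = []
    for a, b in zip(sorted(cuts)[:-1], sorted(cuts)[1:]):
        c = ly.copies_at(truth.layout, a)
        if b <= x:
            origins = ("H1",) * c
        else:
            origins = ("H1",) * max(c - 1, 0) + (("H2",) if c >= 1 else ())
        om.append((a, b, origins))
    truth.origin_map = _merge_origin(om)
    truth.crossover_pos = x
    truth.allelic_segments = [(s, x, "diallelic"), (x, e, "triallelic")]
    return truth


def _merge_origin(om):
    out = []
    for seg in om:
        if out and out[-1][2] == seg[2] and out[-1][1] == seg[0]:
            out[-1] = (out[-1][0], seg[1], seg[2])
        else:
            out.append(seg)
    return out


def origins_at(truth: ChromTruth, pos: int) -> tuple[str, ...]:
    for s, e, o in truth.origin_map:
        if s <= pos < e:
            return o
    return ()


# --------------------------------------------------------------------------
# trio read simulation
# --------------------------------------------------------------------------


def simulate_trio_reads(
    refs: dict[str, str],
    truths: dict[str, ChromTruth],
    config: ScenarioConfig,
    rng: np.random.Generator,
) -> list[SimSite]:
    """Sample informative trio SNV sites with binomial read counts.

    Father-informative sites (father heterozygous, mother homozygous
    reference) and mother-informative sites are placed independently at
    ``snv_density`` per bp each.  The child's allele read counts are drawn
    binomially at the configured depth scaled by local copy number, with a
    flat per-read error rate.
    """
    if config.depth < 10:
        import warnings

        warnings.warn("mean depth below 10x: dosage calls will be unreliable")
    sites: list[SimSite] = []
    err = config.error_rate
    for chrom, ref in refs.items():
        truth = truths[chrom]
        L = truth.length
        for parent in ("father", "mother"):
            n = rng.poisson(config.snv_density * L)
            positions = np.sort(rng.choice(L - 2, size=min(n, L // 10), replace=False)) + 1
            for pos in positions.tolist():
                refb = ref[pos]
                altb = _OTHER[refb][int(rng.integers(0, 3))]
                origins = origins_at(truth, pos)
                cn_p = len(origins)
                total = cn_p + 1  # one maternal copy always transmitted
                if parent == "father":
                    alt_hap = "H1" if rng.random() < 0.5 else "H2"
                    f_gt, m_gt = (0, 1), (0, 0)
                    alt_copies = sum(1 for h in origins if h == alt_hap)
                else:
                    alt_hap = "M1" if rng.random() < 0.5 else "M2"
                    f_gt, m_gt = (0, 0), (0, 1)
                    alt_copies = 1 if alt_hap == "M1" else 0  # M1 is transmitted
                frac = alt_copies / total
                depth = max(int(rng.poisson(config.depth)), 1)
                p = frac * (1 - err) + (1 - frac) * err
                alt_reads = int(rng.binomial(depth, p))
                child_gt = tuple(sorted({0} if alt_copies == 0 else (
                    {1} if alt_copies == total else {0, 1})))
                pd = max(int(rng.poisson(config.depth)), 1)
                if parent == "father":
                    f_alt = int(rng.binomial(pd, 0.5))
                    f_ad, m_ad = (pd - f_alt, f_alt), _hom_ad(rng, config, err)
                else:
                    m_alt = int(rng.binomial(pd, 0.5))
                    m_ad, f_ad = (pd - m_alt, m_alt), _hom_ad(rng, config, err)
                if cn_p == 0:
                    status = "deleted"
                elif cn_p == 1:
                    status = "diploid"
                else:
                    status = "diallelic" if len(set(origins)) == 1 else "triallelic"
                sites.append(
                    SimSite(
                        chrom=chrom, pos=pos, ref=refb, alt=altb,
                        informative_parent=parent,
                        father_gt=f_gt, mother_gt=m_gt, child_gt=child_gt,
                        father_ad=f_ad, mother_ad=m_ad,
                        child_ad=(depth - alt_reads, alt_reads),
                        truth_status=status,
                        specific_fraction_truth=frac,
                    )
                )
    sites.sort(key=lambda s: (s.chrom, s.pos))
    return sites


def _hom_ad(rng, config, err):
    d = max(int(rng.poisson(config.depth)), 1)
    a = int(rng.binomial(d, err))
    return (d - a, a)


# --------------------------------------------------------------------------
# probes, microsatellites, methylation
# --------------------------------------------------------------------------


def simulate_probes(
    truths: dict[str, ChromTruth],
    spacing: int,
    noise_sd: float,
    rng: np.random.Generator,
) -> list[tuple[str, int, float]]:
    """aCGH probe log2 ratios: Normal(log2(CN/2), sd) on the total child CN."""
    rows = []
    for chrom, truth in truths.items():
        for pos in range(spacing // 2, truth.length, spacing):
            cn = len(origins_at(truth, pos)) + 1
            mu = np.log2(cn / 2.0) if cn > 0 else float("-inf")
            rows.append((chrom, pos, float(mu + rng.normal(0.0, noise_sd))))
    return rows


def simulate_microsatellites(
    truths: dict[str, ChromTruth],
    config: ScenarioConfig,
    rng: np.random.Generator,
):
    """Microsatellite peak tables: areas proportional to allele copy counts.

    Father haplotype H1 (carrier) and H2 carry one allele size each; the
    mother transmits M1.  Loci are placed inside each duplicated span (on
    both sides of any crossover) and in unrearranged regions.
    """
    rows = []  # (locus, chrom, pos, member, size, area)
    truth_calls = {}
    idx = 0
    for chrom, truth in truths.items():
        positions = []
        if truth.dup_span:
            s, e = truth.dup_span
            fr = np.linspace(0.15, 0.85, config.msat_per_dup)
            positions += [int(s + f * (e - s)) for f in fr]
    # outside loci from the first chromosome's proximal flank
        for pos in positions:
            idx += 1
            rows_l, call = _msat_locus(f"SIM{idx:02d}", chrom, pos, truths[chrom],
                                       config, rng)
            rows += rows_l
            truth_calls[f"SIM{idx:02d}"] = call
    first = next(iter(truths))
    for i in range(config.msat_outside):
        idx += 1
        pos = 500 + i * 97
        rows_l, call = _msat_locus(f"SIM{idx:02d}", first, pos, truths[first],
                                   config, rng)
        rows += rows_l
        truth_calls[f"SIM{idx:02d}"] = call
    return rows, truth_calls


def _msat_locus(name, chrom, pos, truth, config, rng):
    base = int(rng.integers(100, 200))
    f1 = base
    f2 = base + 2 * int(rng.integers(1, 6))
    m1 = base + 2 * int(rng.integers(-4, 5))
    m2 = base + 2 * int(rng.integers(-4, 5))
    hap_size = {"H1": f1, "H2": f2, "M1": m1}
    origins = origins_at(truth, pos)
    child_sizes = [hap_size[h] for h in origins] + [m1]
    rows = []
    for member, sizes in (
        ("child", child_sizes),
        ("father", [f1, f2]),
        ("mother", [m1, m2]),
    ):
        counts = {}
        for s in sizes:
            counts[s] = counts.get(s, 0) + 1
        for s, c in sorted(counts.items()):
            area = c * 1000.0 * (1.0 + rng.normal(0.0, config.msat_area_sd))
            rows.append((name, chrom, pos, member, s, max(area, 1.0)))
    if len(origins) == 2:
        call = "diallelic" if len(set(origins)) == 1 else "triallelic"
    else:
        call = "uninformative"
    return rows, call


def simulate_methylation(
    truths: dict[str, ChromTruth],
    config: ScenarioConfig,
    rng: np.random.Generator,
):
    """Methylation indexes of a maternally methylated imprinted DMR.

    The DMR sits inside the first duplicated span; the single maternal copy
    is methylated, paternal copies are not, so a paternal duplication gives
    index 1/(CN) ~ 1/3.
    """
    dup_chrom = None
    for chrom, truth in truths.items():
        if truth.dup_span:
            dup_chrom = chrom
            break
    rows = []
    lo, hi = config.methylation_ref_range
    if dup_chrom is None:
        return rows
    truth = truths[dup_chrom]
    s, e = truth.dup_span
    mid = (s + e) // 2
    for i in range(config.methylation_sites):
        pos = mid + i * 10
        cn = len(origins_at(truth, pos)) + 1
        index = 1.0 / cn + rng.normal(0.0, config.methylation_noise_sd)
        rows.append(
            (f"CpG{i + 1}", dup_chrom, pos, float(np.clip(index, 0.0, 1.0)), lo, hi)
        )
    return rows


# --------------------------------------------------------------------------
# scenario orchestration
# --------------------------------------------------------------------------


@dataclass
class SimulatedTrio:
    config: ScenarioConfig
    seed: int
    refs: dict[str, str]
    derivatives: dict[str, str]
    truths: dict[str, ChromTruth]
    sites: list[SimSite]
    probes: list[tuple[str, int, float]]
    msat_rows: list
    msat_truth: dict[str, str]
    methylation: list

    def truth_dict(self) -> dict:
        return {
            "seed": self.seed,
            "chromosomes": {c: t.to_dict() for c, t in self.truths.items()},
            "microsatellite_truth": self.msat_truth,
        }


def simulate_trio(config: ScenarioConfig, seed: int) -> SimulatedTrio:
    """Run the full generative model for one scenario and seed."""
    config.validate()
    rng = np.random.default_rng(seed)
    refs = simulate_reference(config.chromosomes, rng)
    events = {ev.chrom: ev for ev in config.events}
    derivatives = {}
    truths = {}
    for chrom in config.chromosomes:
        ev = events.get(chrom)
        ref, deriv, truth = apply_rearrangement(
            refs[chrom], ev, config.signature_mix, rng,
            radius=config.insert_search_radius,
        )
        if ev is None:
            truth.chrom = chrom
        refs[chrom] = ref
        derivatives[chrom] = deriv
        truths[chrom] = truth
        simulate_meiosis(truth, ev.crossover if ev else None)
    sites = simulate_trio_reads(refs, truths, config, rng)
    probes = simulate_probes(truths, config.probe_spacing, config.probe_noise_sd, rng)
    msat_rows, msat_truth = simulate_microsatellites(truths, config, rng)
    methyl = simulate_methylation(truths, config, rng)
    return SimulatedTrio(
        config=config, seed=seed, refs=refs, derivatives=derivatives,
        truths=truths, sites=sites, probes=probes,
        msat_rows=msat_rows, msat_truth=msat_truth, methylation=methyl,
    )


def patient_like_config(
    chrom_len: int = 200_000,
    depth: float = 40.0,
    probe_noise_sd: float = 0.15,
    snv_density: float = 5e-4,
) -> ScenarioConfig:
    """Five-cluster scenario emulating the analysed case.

    One cluster per chromosome arm: a tandem duplication (6q-like, with a
    meiosis-I crossover and the imprinted DMR), a balanced inversion
    (14q-like), two tandem inversions with a deletion (2q-like), an
    inverted duplication with a deletion (13q-like, with a crossover), and
    chromothripsis with one junction carrying a 7-bp untemplated insertion
    (21q-like).  All clusters are paternal.
    """
    L = chrom_len
    span = (L // 4, L * 3 // 4)
    return ScenarioConfig(
        chromosomes={f"chr{c}": L for c in (2, 6, 13, 14, 21)},
        events=[
            EventSpec(kind="double_inversion_with_deletion", chrom="chr2", span=span),
            EventSpec(kind="tandem_duplication", chrom="chr6", span=span,
                      crossover=0.5),
            EventSpec(kind="inverted_duplication_with_deletion", chrom="chr13",
                      span=span, crossover=0.4),
            EventSpec(kind="balanced_inversion", chrom="chr14", span=span),
            EventSpec(kind="chromothripsis", chrom="chr21", span=span,
                      fragments=8, forced_inserts={0: 7}),
        ],
        depth=depth,
        probe_noise_sd=probe_noise_sd,
        snv_density=snv_density,
    )
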