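"""Trio-based dosage, parental origin and mutational-timing inference.

In a heterozygous duplication the child carries three copies of the
region.  At informative SNVs (father heterozygous, mother homozygous) the
father-specific allele then accounts for ~2/3 of reads when both
duplicated copies carry it (diallelic: both copies from one paternal
haplotype) and ~1/3 when only one does (triallelic: the two copies derive
from different paternal haplotypes).  A duplicated span carrying both
diallelic and triallelic segments separated by a single change-point is
the footprint of a premeiotic duplication reshaped by one meiosis-I
crossover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from scipy.stats import binom

from .models import (
    DosageCall,
    MicrosatelliteCall,
    MicrosatelliteObservation,
    TrioSiteGenotype,
)

#: father-specific allele fraction hypotheses in a three-copy region
STATUS_P = {"triallelic": 1.0 / 3.0, "diploid": 0.5, "diallelic": 2.0 / 3.0}
MINOR_FILTER = (0.26, 0.40)
LLR_THRESHOLD = 2.0
# Per-site confidence for change-point segmentation.  At 40x a true-2/3
# site is called 1/3 with log-likelihood margin >= L at exact binomial
# rate ~1.4e-3 (L=5) vs ~6.5e-5 (L=7); only the latter keeps the chance
# of a spurious change-point over a ~100-site span near 1%.
TIMING_LLR = 7.0
MIN_DEPTH = 20


class NonInformativeSiteError(ValueError):
    """The caller must pre-filter to father-het / mother-hom sites."""


def call_site_dosage(
    site: TrioSiteGenotype,
    min_depth: int = MIN_DEPTH,
    llr_threshold: float = LLR_THRESHOLD,
    in_duplication: bool = False,
) -> DosageCall:
    """Binomial likelihood contest over the allele-fraction hypotheses.

    Hypotheses are father-specific fractions 1/3 (triallelic), 1/2
    (diploid) and 2/3 (diallelic); with ``in_duplication`` the region is
    known three-copy (e.g. from aCGH) and the diploid hypothesis is
    dropped.  The call is the maximum-likelihood status, ``ambiguous``
    when the top two log-likelihoods differ by less than
    ``llr_threshold`` or depth is below ``min_depth``.  The 26-40%
    minor-allele selection filter is evaluated and recorded, not imposed.
    """
    if not site.informative:
        raise NonInformativeSiteError(
            f"site {site.chrom}:{site.pos} is not father-het/mother-hom; "
            "pre-filter to informative sites"
        )
    k, n = site.child_father_reads, site.depth
    frac = k / n if n else float("nan")
    hyps = dict(STATUS_P)
    if in_duplication:
        hyps.pop("diploid")
    scores = sorted(
        ((float(binom.logpmf(k, n, p)), status) for status, p in hyps.items()),
        reverse=True,
    )
    llr = scores[0][0] - scores[1][0]
    status = scores[0][1]
    if n < min_depth or llr < llr_threshold:
        status = "ambiguous"
    minor = min(frac, 1.0 - frac)
    return DosageCall(
        chrom=site.chrom, pos=site.pos, status=status,
        father_fraction=frac, llr=llr,
        passes_minor_filter=MINOR_FILTER[0] <= minor <= MINOR_FILTER[1],
    )


# --------------------------------------------------------------------------
# microsatellites
# --------------------------------------------------------------------------


def call_msat_dosage(
    obs: MicrosatelliteObservation,
    total_cn: Optional[int] = None,
) -> MicrosatelliteCall:
    """Diallelic/triallelic call from trio peak areas at one locus.

    Child allele copy counts are the peak-area fractions rounded to
    integers summing to the total copy number (taken from probe data when
    known, otherwise fitted over {2, 3}).  The locus is triallelic when
    the child carries both paternal alleles plus a maternal one, diallelic
    when one paternal allele is present twice.  A child allele matching
    neither parent flags a mutation/stutter artefact with no call; a
    single shared size across the trio leaves a dosage-only call, flagged
    lower-confidence.
    """
    child_sizes = set(obs.child)
    father = set(obs.father)
    mother = set(obs.mother)
    if child_sizes - (father | mother):
        return MicrosatelliteCall(
            locus=obs.locus, status="uninformative", child_copy_counts={},
            flag="allele_outside_parents",
        )

    def counts_for(total: int) -> dict[int, int]:
        area_total = sum(obs.child.values())
        raw = {s: a / area_total * total for s, a in obs.child.items()}
        counts = {s: max(int(math.floor(v)), 0) for s, v in raw.items()}
        # largest-remainder rounding to the fixed total
        rem = sorted(raw, key=lambda s: raw[s] - counts[s], reverse=True)
        i = 0
        while sum(counts.values()) < total:
            counts[rem[i % len(rem)]] += 1
            i += 1
        return {s: c for s, c in counts.items() if c > 0}

    if total_cn is not None:
        candidates = [total_cn]
    else:
        # fit the total copy number by the area-fraction residual; ties
        # fall to the lower (parsimonious) total
        area_total = sum(obs.child.values())

        def residual(total: int) -> float:
            counts = counts_for(total)
            return sum(
                abs(a / area_total - counts.get(s, 0) / total)
                for s, a in obs.child.items()
            )

        candidates = sorted([2, 3], key=lambda t: (residual(t), t))

    for total in candidates:
        counts = counts_for(total)
        if total == 2:
            ok = _consistent_diploid(counts, father, mother)
            if ok:
                return MicrosatelliteCall(
                    locus=obs.locus, status="uninformative",
                    child_copy_counts=counts, flag="diploid_consistent",
                )
            continue
        verdicts = set()
        for m_allele in mother & child_sizes:
            rest = dict(counts)
            rest[m_allele] -= 1
            if rest[m_allele] == 0:
                del rest[m_allele]
            paternal = []
            for s, c in rest.items():
                paternal += [s] * c
            if len(paternal) != 2 or any(s not in father for s in paternal):
                continue
            if paternal[0] == paternal[1]:
                verdicts.add("diallelic")
            elif set(paternal) == father and len(father) == 2:
                verdicts.add("triallelic")
        if len(verdicts) == 1:
            status = verdicts.pop()
            dosage_only = len(child_sizes) == 1
            return MicrosatelliteCall(
                locus=obs.locus, status=status, child_copy_counts=counts,
                dosage_only=dosage_only,
                flag="dosage_only" if dosage_only else "",
            )
        if len(verdicts) > 1:
            return MicrosatelliteCall(
                locus=obs.locus, status="uninformative",
                child_copy_counts=counts, flag="ambiguous_assignment",
            )
    return MicrosatelliteCall(
        locus=obs.locus, status="uninformative", child_copy_counts={},
        flag="no_consistent_assignment",
    )


def _consistent_diploid(counts, father, mother):
    alleles = []
    for s, c in counts.items():
        alleles += [s] * c
    if len(alleles) != 2:
        return False
    a, b = alleles
    return (a in father and b in mother) or (a in mother and b in father)


# --------------------------------------------------------------------------
# parental origin
# --------------------------------------------------------------------------


@dataclass
class OriginCall:
    chrom: str
    start: int
    end: int
    cnv_kind: str  # gain | loss
    origin: str  # paternal | maternal | undetermined | conflicted
    n_informative: int
    detail: dict = field(default_factory=dict)


@dataclass
class TrioSite:
    """One VCF site with both parents' genotypes and the child's AD."""

    chrom: str
    pos: int
    father_gt: tuple[int, int]
    mother_gt: tuple[int, int]
    child_gt: tuple[int, ...]
    father_ad: tuple[int, int]
    mother_ad: tuple[int, int]
    child_ad: tuple[int, int]

    @property
    def informative_parent(self) -> Optional[str]:
        f_het = self.father_gt[0] != self.father_gt[1]
        m_het = self.mother_gt[0] != self.mother_gt[1]
        if f_het and not m_het:
            return "father"
        if m_het and not f_het:
            return "mother"
        return None

    def specific_site(self) -> Optional[TrioSiteGenotype]:
        """Recast with the informative parent in the father slot.

        The specific allele is the one the homozygous parent lacks; read
        counts are ordered (specific, other).
        """
        parent = self.informative_parent
        if parent is None:
            return None
        if parent == "father":
            hom_gt = self.mother_gt
            f_gt, m_gt = self.father_gt, self.mother_gt
        else:
            hom_gt = self.father_gt
            f_gt, m_gt = self.mother_gt, self.father_gt
        specific_allele = 1 if hom_gt[0] == 0 else 0
        spec = self.child_ad[1] if specific_allele == 1 else self.child_ad[0]
        other = sum(self.child_ad) - spec
        return TrioSiteGenotype(
            chrom=self.chrom, pos=self.pos,
            father_gt=f_gt, mother_gt=m_gt,
            child_father_reads=spec, child_other_reads=other,
        )


def assign_parent_of_origin(
    sites: Sequence[TrioSite],
    interval: tuple[str, int, int],
    cnv_kind: str,
    llr_threshold: float = LLR_THRESHOLD,
    min_depth: int = MIN_DEPTH,
    error_fraction: float = 0.05,
    absent_max_fraction: float = 0.15,
) -> OriginCall:
    """Infer which parent's chromosome carries a CNV.

    Gains: a parent whose specific allele reaches ~2/3 of reads at some
    informative sites contributed two identical copies, which only the
    duplicated haplotype can do; confident diallelic calls therefore vote
    for their informative parent, and the verdict is ``conflicted`` when
    both parents collect votes beyond an error bound.  Losses: the parent
    whose specific allele is absent from every informative site (while
    the other parent's allele is hemizygously present at about half of
    its sites) lost the region.
    """
    chrom, start, end = interval
    inside = [
        s for s in sites
        if s.chrom == chrom and start <= s.pos < end and s.informative_parent
    ]
    if not inside:
        return OriginCall(chrom, start, end, cnv_kind, "undetermined", 0)

    if cnv_kind == "gain":
        votes = {"father": 0, "mother": 0}
        confident = 0
        for s in inside:
            g = s.specific_site()
            call = call_site_dosage(g, min_depth=min_depth,
                                    llr_threshold=llr_threshold,
                                    in_duplication=True)
            if call.status == "diallelic":
                votes[s.informative_parent] += 1
                confident += 1
            elif call.status == "triallelic":
                confident += 1
        f, m = votes["father"], votes["mother"]
        bound = max(1, int(error_fraction * confident))
        if f > bound and m > bound:
            origin = "conflicted"
        elif f > m and f >= 1 and m <= bound:
            origin = "paternal"
        elif m > f and m >= 1 and f <= bound:
            origin = "maternal"
        else:
            origin = "undetermined"
        return OriginCall(chrom, start, end, cnv_kind, origin, len(inside),
                          {"diallelic_votes": votes})

    if cnv_kind == "loss":
        absent = {"father": [0, 0], "mother": [0, 0]}
        for s in inside:
            g = s.specific_site()
            n = g.depth
            if n == 0:
                continue
            frac = g.child_father_reads / n
            absent[s.informative_parent][1] += 1
            # well below the 1/2 a hemizygously present allele would show,
            # yet tolerant of a few error reads
            if frac <= absent_max_fraction:
                absent[s.informative_parent][0] += 1
        rates = {
            p: (a / t if t else float("nan")) for p, (a, t) in absent.items()
        }
        f, m = rates["father"], rates["mother"]
        if absent["father"][1] and f >= 0.9 and not (m >= 0.9):
            origin = "paternal"
        elif absent["mother"][1] and m >= 0.9 and not (f >= 0.9):
            origin = "maternal"
        else:
            origin = "undetermined"
        return OriginCall(chrom, start, end, cnv_kind, origin, len(inside),
                          {"absent_rates": rates})

    raise ValueError(f"unknown CNV kind {cnv_kind!r}")


def phase_consistency(
    flanking: Sequence[tuple[int, str]],
) -> tuple[str, dict[str, int]]:
    """Single-haplotype consistency of breakpoint-flanking phased variants.

    ``flanking`` holds (position, haplotype label) for phased variants
    around the breakpoints of one cluster.  All variants on one haplotype
    -> consistent, mirroring the expectation that a rearranged chromosome
    derives from a single parental homolog.
    """
    tally: dict[str, int] = {}
    for _, hap in flanking:
        tally[hap] = tally.get(hap, 0) + 1
    if not tally:
        return "undetermined", tally
    return ("consistent" if len(tally) == 1 else "inconsistent"), tally


# --------------------------------------------------------------------------
# timing
# --------------------------------------------------------------------------


@dataclass
class TimingCall:
    verdict: str  # premeiotic_with_meiotic_crossover | single_event_consistent | undetermined
    change_point: Optional[int] = None  # position between the flanking sites
    change_index: Optional[int] = None  # index of the last site before the switch
    n_sites: int = 0
    statuses: list[str] = field(default_factory=list)
    used_positions: list[int] = field(default_factory=list)


def infer_timing(
    calls: Sequence[DosageCall],
    min_sites: int = 3,
    llr_min: float = TIMING_LLR,
) -> TimingCall:
    """Premeiotic-vs-single-event verdict from dosage calls along a span.

    Confident diallelic/triallelic calls (LLR >= ``llr_min``; the
    stringent default keeps the per-site chance of a spurious switch from
    binomial read noise below ~1e-4 at 40x) are ordered by position.
    Both statuses present with exactly one switch -> a premeiotic
    duplication modified by one meiosis-I crossover; a uniform status ->
    consistent with a single event; more than one switch ->
    undetermined, with the status sequence returned as diagnostics.
    """
    used = [
        c for c in sorted(calls, key=lambda c: c.pos)
        if c.status in ("diallelic", "triallelic") and c.llr >= llr_min
    ]
    statuses = [c.status for c in used]
    positions = [c.pos for c in used]
    if len(used) < min_sites:
        return TimingCall("undetermined", n_sites=len(used), statuses=statuses,
                          used_positions=positions)
    switches = [
        i for i in range(len(used) - 1) if statuses[i] != statuses[i + 1]
    ]
    if not switches:
        return TimingCall("single_event_consistent", n_sites=len(used),
                          statuses=statuses, used_positions=positions)
    if len(switches) == 1:
        i = switches[0]
        return TimingCall(
            "premeiotic_with_meiotic_crossover",
            change_point=(used[i].pos + used[i + 1].pos) // 2,
            change_index=i,
            n_sites=len(used), statuses=statuses, used_positions=positions,
        )
    return TimingCall("undetermined", n_sites=len(used), statuses=statuses,
                      used_positions=positions)
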