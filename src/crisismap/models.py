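"""Core domain types shared across the package.

Coordinates are 0-based half-open everywhere in memory; conversions to
1-based (VCF) or BED conventions happen only in the I/O layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

Side = Literal["left", "right"]

#: Signature kinds a fusion junction can carry.
SIGNATURE_KINDS = (
    "blunt",
    "microhomology",
    "microhomeology",
    "untemplated_insert",
    "templated_insert",
)

#: Cluster-level mechanism labels.
MECHANISMS = (
    "tandem_duplication",
    "balanced_inversion",
    "inverted_duplication_with_deletion",
    "complex_inversion_deletion",
    "chromothripsis",
    "chromoanasynthesis",
    "unclassified",
)

#: Per-junction repair-mechanism labels.
JUNCTION_MECHANISMS = (
    "NHEJ",
    "replication_based",
    "chromothripsis_consistent",
    "ambiguous",
)


class ConfigurationError(ValueError):
    """Raised for invalid scenario or analysis configuration."""


class InterchromosomalJunctionError(ValueError):
    """Raised when a junction fuses two different chromosomes.

    The analysed rearrangement clusters are strictly intrachromosomal
    (interchromosomal translocations are excluded upstream, e.g. by
    multicolor FISH), so such input is rejected rather than analysed.
    """


@dataclass(frozen=True)
class BreakpointEnd:
    """One end of a fusion junction.

    ``side`` states on which side of ``pos`` the retained (fused) sequence
    lies: ``left`` means the fragment ends at ``pos`` (derivative sequence
    runs rightward into the fusion), ``right`` means the fragment starts at
    ``pos``.
    """

    chrom: str
    pos: int
    side: Side

    @property
    def strand(self) -> str:
        """BEDPE-style strand: '+' when the retained sequence is to the left."""
        return "+" if self.side == "left" else "-"


@dataclass
class Junction:
    """A fusion of two breakpoint ends with its observed joined sequence.

    ``observed`` spans the fusion with at least 20 nt of reference-matching
    flank on each side, written in derivative orientation.  ``insert`` is
    the (possibly empty) non-reference sequence at the fusion point.
    """

    end_a: BreakpointEnd
    end_b: BreakpointEnd
    observed: str = ""
    insert: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if self.end_a.chrom != self.end_b.chrom:
            raise InterchromosomalJunctionError(
                f"junction {self.name or '(unnamed)'} fuses {self.end_a.chrom} "
                f"and {self.end_b.chrom}; clusters are intrachromosomal"
            )

    @property
    def chrom(self) -> str:
        return self.end_a.chrom


@dataclass
class HomeologyCandidate:
    """One imperfect-homology alignment between the two flank windows.

    Offsets are relative to the analysed windows: ``a_start`` counts from
    the fusion-distal end of the A window, ``b_start`` from the start of
    the B window.  ``columns`` includes gap columns; identity is
    matches/columns.
    """

    a_start: int
    a_len: int
    b_start: int
    b_len: int
    columns: int
    matches: int
    gap_columns: int
    anchored: bool

    @property
    def identity(self) -> float:
        return self.matches / self.columns

    def sort_key(self):
        # best first: identity, then length, then smaller A offset, then B;
        # remaining fields only break ties deterministically
        return (
            -self.identity, -self.columns, self.a_start, self.b_start,
            self.gap_columns, self.a_len, self.b_len,
        )


@dataclass
class JunctionSignature:
    """Classification of the sequence signature at one fusion junction."""

    kind: str
    homology_length: int = 0
    homology_identity: float = 0.0
    insert_length: int = 0
    insert_source: Optional[tuple[str, int, int, str]] = None
    ambiguity: int = 1
    over_cap: bool = False  # exact homology >= 70 nt (not reported as microhomology)
    homeology: Optional[HomeologyCandidate] = None

    def __post_init__(self) -> None:
        if self.kind not in SIGNATURE_KINDS and self.kind != "none":
            raise ValueError(f"unknown signature kind {self.kind!r}")


@dataclass
class BreakpointAnnotation:
    """Genomic context of one breakpoint.

    Fields are ``None`` (never zero) when the corresponding track was not
    provided.  Replication timing is copied from the nearest tested locus,
    never interpolated; ties report every equidistant locus.
    """

    repeats: Optional[list[str]] = None
    replication_timing: Optional[list[float]] = None
    de_novo_snvs: Optional[int] = None
    chromatin_marks: Optional[list[str]] = None


@dataclass
class RearrangementCluster:
    """All junctions of one chromosome arm plus its copy-number profile."""

    chrom: str
    junctions: list[Junction]
    signatures: list[JunctionSignature]
    cn_segments: list[tuple[int, int, int]]  # (start, end, per-haplotype CN)
    derivative: Optional[list[tuple[int, int, str]]] = None  # (start, end, orient)
    mechanism: str = "unclassified"
    junction_mechanisms: list[str] = field(default_factory=list)
    secondary_possibility: str = ""
    walk_count: int = 1
    deleted_fragments: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class TrioSiteGenotype:
    """One SNV with trio genotypes and the child's per-allele read counts.

    ``child_father_reads`` counts reads of the father-specific allele (the
    allele the mother does not carry); informative sites require the father
    heterozygous and the mother homozygous.
    """

    chrom: str
    pos: int
    father_gt: tuple[int, int]
    mother_gt: tuple[int, int]
    child_father_reads: int
    child_other_reads: int

    @property
    def depth(self) -> int:
        return self.child_father_reads + self.child_other_reads

    @property
    def informative(self) -> bool:
        f_het = self.father_gt[0] != self.father_gt[1]
        m_hom = self.mother_gt[0] == self.mother_gt[1]
        return f_het and m_hom


@dataclass
class DosageCall:
    """Diallelic/triallelic/diploid call for one informative SNV."""

    chrom: str
    pos: int
    status: str  # diallelic | triallelic | diploid | ambiguous
    father_fraction: float
    llr: float
    passes_minor_filter: bool


@dataclass
class MicrosatelliteObservation:
    """Allele sizes (bp) and peak areas for one locus across the trio."""

    locus: str
    child: dict[int, float]   # allele size -> peak area
    father: dict[int, float]
    mother: dict[int, float]


@dataclass
class MicrosatelliteCall:
    locus: str
    status: str  # diallelic | triallelic | uninformative
    child_copy_counts: dict[int, int]
    dosage_only: bool = False
    flag: str = ""


@dataclass
class MosaicismAssessment:
    """aCGH log-ratio comparison against the theoretical non-mosaic value."""

    chrom: str
    start: int
    end: int
    probe_count: int
    mean_log2: float
    theoretical: float
    mosaic_fraction: float
    p_value: float
    verdict: str  # non_mosaic | mosaic_suspected | insufficient_probes


@dataclass
class MethylationSite:
    """One CpG methylation index with its population reference range."""

    site: str
    index: float
    ref_min: float
    ref_max: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.index <= 1.0):
            raise ValueError(f"methylation index {self.index} outside [0, 1]")
        if self.ref_min > self.ref_max:
            raise ValueError("reference range min exceeds max")
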