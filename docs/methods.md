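# Methods

`crisismap` analyses germline complex chromosomal rearrangements of the
kind that arise during spermatogenesis as a multifocal genomic crisis:
several independent rearrangement clusters, each confined to one
chromosome arm, ranging from simple tandem duplications and inversions to
chromothriptic shattering.  The package infers, from standard molecular
readouts (junction sequences, trio short-read genotypes, microsatellite
peak areas, aCGH probe ratios, bisulfite methylation indexes), what each
cluster is, which parental chromosome carries it, and when in germ-cell
development it arose.  A paired simulator generates trios with known
ground truth so every inference stage is testable without any external
data.

## Junction signatures

A fusion junction joins two breakpoint ends; the analysed 20-nt flank
windows are the reference sequence ending at end A and starting at end B,
both written in derivative orientation.

* **Microhomology** — a perfect suffix/prefix overlap of the two windows,
  0 < k < 70 nt.  The derivative carries the shared tract once, so a
  k-nt microhomology leaves k+1 equivalent fusion placements (the
  reported ambiguity interval).  The window can be extended to the 69-nt
  cap on request; an overlap of 70 nt or more is reported as over-cap,
  not as microhomology.
* **Microhomeology** — an imperfect tract of ≥ 5 aligned columns at
  ≥ 70% identity with no gap run longer than 2, scored as a local
  alignment with zero gap-opening penalty (match +1, mismatch −1, gap
  extension −1) and identity computed over all columns including gaps.
  Instead of a single optimal alignment followed by manual curation, the
  detector enumerates the complete candidate space — every ungapped local
  alignment plus every alignment with a single 1–2-column gap run — and
  applies the filter deterministically, ranking by (identity, length,
  A offset, B offset).  Alignments with two or more separate gap runs are
  excluded: within 20-column windows at 70% identity they are effectively
  unreachable, and the no->2-consecutive-gaps rule already forbids longer
  runs.
* **Signature assignment** requires a microhomeologous tract to be
  *anchored at the fusion point* (a suffix of the A window against a
  prefix of the B window).  This is deliberate: nearly every pair of
  random 20-mers contains some interior ≥5-nt/70% alignment, so an
  unanchored hit carries no information about the join itself.  The
  unanchored window-wide scan remains available as an annotation.
  Precedence: non-empty insert → templated/untemplated insert; perfect
  overlap → microhomology (subsuming any imperfect candidate); anchored
  homeology → microhomeology; otherwise blunt.
* **Inserts** are templated if found exactly (either strand) within a
  search radius of either breakpoint end, else untemplated.  The radius
  is an assumption exposed as a flag; the default is 1 kb.  Note the
  combinatorics this forces on the simulator: a random insert much
  shorter than 7 nt is almost surely matched by chance within 1 kb, so
  "untemplated" is only meaningful for inserts of roughly 7 nt and up.

Breakpoint annotation reports repeat classes within ±2 kb, the
replication timing of the nearest tested locus (copied, never
interpolated; ties report all equidistant loci), de novo SNVs — child
alleles absent from both parents — within ±100 bp, and overlapping
open-chromatin marks.  Absent tracks yield null fields, never zeros.

## Cluster reconstruction and mechanism

Junction breakends cut the arm into fragments; per-haplotype copy number
per fragment comes from aCGH probe means (total CN = 2·2^mean; the
transmitted haplotype carries total − 1, since the homolog is intact).
The derivative is reconstructed by walking the breakpoint graph from the
proximal end: each junction edge is consumed exactly once, each fragment
at most its copy number, and the walk must finish at the distal end with
everything consumed.  Branching ambiguity (a CN-2 fragment usable twice)
is enumerated up to a cap of 64 consistent walks; the deterministic
junction-first walk is returned together with the count.  Fragments with
zero copies and no visit are reported deleted.  Probe spacing should be
at most a third of the smallest expected fragment; fragments without
probes default to neutral copy number.

Mechanism rules, in order: (1) ≥ 4 junctions (configurable; no threshold
is established in the literature for this boundary, 4 is the package's
choice), per-haplotype CN ≤ 1 everywhere, at least one deletion, and no
templated insert → chromothripsis; (2) any copy gain together with a
templated insert → chromoanasynthesis; (3) one junction over a gain →
tandem duplication; (4) two orientation-flipping junctions, balanced →
balanced inversion; (5) gain + flip + loss → inverted duplication with
deletion; flips + loss without gain → complex inversion/deletion; else
unclassified.  "Balanced" is judged on the rounded per-fragment copy
numbers.  A duplication cluster whose junctions show microhomology keeps
its simple label but carries a secondary-possibility note that
chromothripsis cannot be excluded — duplications with microhomology have
been described in chromothriptic germline events — never a changed
primary label.  Per-junction repair labels: chromothripsis clusters mark
all junctions chromothripsis-consistent; microhomology/microhomeology
with a local gain (and templated inserts) → replication-based
template switching; blunt joins and short (≤ 10 nt) untemplated inserts →
NHEJ; otherwise ambiguous.

## Trio dosage, origin and timing

At an informative SNV (father heterozygous, mother homozygous) in a
three-copy region the father-specific allele accounts for 2/3 of reads
when both duplicated copies carry it (diallelic) and 1/3 when the two
copies derive from different paternal haplotypes (triallelic).  The
caller runs a binomial log-likelihood contest over fractions
{1/3, 1/2, 2/3}; a call is ambiguous when the top two hypotheses differ
by under 2 log-units (configurable) or depth is below 20.  Within a
region known three-copy from aCGH the diploid hypothesis is dropped —
without that restriction the 1/2-vs-2/3 contest at 40× leaves nearly half
of true diallelic sites ambiguous, which neither matches practice (sites
are genotyped *inside* established duplications) nor leaves the fractions
decidable at realistic depth.  The 26–40% minor-allele site-selection
filter is evaluated and recorded on every call, not imposed by the
caller.

Microsatellite dosage: child allele copy counts are the peak-area
fractions rounded (largest remainder) to the total copy number — taken
from probe data when known, otherwise fitted over {2, 3} by area-fraction
residual with ties to the lower total.  The locus is triallelic when the
child carries both paternal alleles plus a maternal one, diallelic when
one paternal allele is present twice; every consistent maternal
assignment is enumerated and the call is made only when the verdict is
unique.  A child allele matching neither parent flags a possible
mutation/stutter artefact with no call.  A single shared size across the
trio (the D6S270 pattern) still resolves combinatorially — a triallelic
configuration would have shown the second paternal size — but rests
entirely on dosage, so it is flagged lower-confidence.

Parental origin.  Gains: only the duplicated haplotype can drive a
specific allele to ~2/3 of reads, so confident diallelic calls vote for
their informative parent; the verdict is conflicted when both parents
collect votes beyond a small error bound.  Losses: the deleted parent's
specific allele is absent (fraction ≤ 0.15, a threshold sitting several
sigma from both the ~0.005 error fraction and the 1/2 of a hemizygously
present allele) at essentially all of its informative sites, while the
retained parent's allele is hemizygously present at about half of its
sites.  Balanced clusters carry no dosage signal; the pipeline falls back
to the haplotype-phase table of breakpoint-flanking variants and calls
the origin only when all flanking variants support a single parental
haplotype.

Timing.  Confident diallelic/triallelic calls ordered along a duplicated
span are segmented at status switches: one switch (both statuses
present) → a premeiotic duplication remodelled by a single meiosis-I
crossover; no switch → consistent with a single event; more than one →
undetermined, with the status sequence as diagnostics.  One change-point
maximum mirrors the single-crossover model; how many crossovers actually
remodelled a real duplicated span is not observable from dosage alone,
and multi-crossover histories are out of scope.  Segmentation uses a
stricter per-site confidence than reporting (7 log-units): the exact
Poisson-depth binomial calculation gives a confident 2/3→1/3 flip rate of
~1.4×10⁻³ per site at 5 log-units but ~6.5×10⁻⁵ at 7, and only the
latter keeps the probability of a spurious change-point across a
~100-site span near 1%, which a rule that forbids second change-points
needs.

## Mosaicism and methylation

For reference ploidy 2 the expected aCGH log2 ratio of a CNV present in a
fraction f of cells is log2(((1−f)·2 + f·CN)/2): +0.58 for a constitutive
heterozygous duplication, −1.0 for a deletion, −inf (reported
"below scale") for a complete homozygous deletion.  Mosaicism is a
one-sided z-test of the probe mean against the constitutive value, with
noise estimated from flanking diploid probes, significant at p < 0.01
(configurable) only when the deviation is toward diploid; the implied
mosaic fraction is back-solved from the mean and clipped to [0, 1].  At
least 10 probes are required.  The −0.8/+0.4 display thresholds are used
for plotting and segment seeding only, never for the verdict.

Methylation indexes are compared against per-site population reference
ranges as closed intervals (a boundary value is normal).  For a
maternally methylated imprinted DMR inside a paternal duplication the
expected index is 1 methylated copy of 3 ≈ 0.33 — mild hypomethylation —
and the report notes whether the observed pattern matches that
expectation.

## The simulator

The generative model is one father–mother–child trio.  Chromosomes are
uniform-random A/C/G/T (≥ 10 kb each).  Every configured event edits one
paternal haplotype (H1) during premeiotic mitosis: exact interval edits
for the simple events; chromothripsis partitions the span into n ≥ 4
fragments (boundaries uniform with a minimum fragment size), deletes each
with probability 1/3 (at least one lost, at least three kept so the
rejoined arm can reach the four-junction minimum), and permutes/inverts
the survivors; chromoanasynthesis additionally gives at least one
fragment an extra copy and at least one junction a templated insert.
Junction signatures are drawn from the configured mix (defaults 0.30
blunt, 0.30 microhomology, 0.20 microhomeology, 0.20 untemplated insert;
templated inserts are generated only for the replicative catastrophic
event so that labels and the mechanism rules stay consistent) and then
*engineered into the reference*: breakpoint neighbourhoods are
rejection-sampled until the package's own definitions classify the
junction as intended against the emitted FASTA.  Fold-back junctions
(both windows are reverse complements of the same bases) can only carry
blunt, palindromic-microhomology or insert signatures; where two
junctions share window bases (duplicated fragments), the shared junction
keeps whatever signature the sequence naturally carries.  Microhomology
tracts appear once in the derivative; homeologous tracts appear on both
sides of the join, as template switching leaves them.

Meiosis applies at most one crossover, at a configured fraction of the
duplicated span: proximal to it both copies derive from H1 (diallelic),
distal to it one copy — and the rest of the chromosome — derives from the
non-carrier homolog H2 (triallelic).  Reads: informative sites are placed
at a configurable density per parent class (default 5×10⁻⁴/bp, of the
order of informative het-site density in outbred human genomes); site
depth is Poisson(40), matching ~40× genome sequencing, with a flat 0.5%
per-read error; allele counts are binomial at the true copy fraction.
Probes are Normal(log2(CN/2), 0.15) every 1 kb.  Microsatellite peak
areas are proportional to copy counts with 5% multiplicative noise;
stutter and PCR bias are not modelled.  The methylation table emulates a
maternally methylated DMR of seven CpG sites inside the first duplicated
span, with reference range 0.42–0.58 standing in for population control
data.  Everything derives from one seed; identical configuration and seed
reproduce every output file byte for byte.

What the simulator does not emulate — alignment artefacts, mapping
ambiguity in repeats, GC-dependent coverage, linked-read barcode
structure, microsatellite stutter, aCGH wave artefacts — bounds what
passing tests show: they validate the inference logic on reads/probes
whose noise model is exactly the assumed one, not robustness to
real-platform systematics.

## Problem sizes and verification

The test suite and acceptance script run everything at the scale the
checks need, kept small by design: junction-detector equivalence against
a naive brute-force enumeration on 1,000 seeded window pairs (a third
with planted homology or homeology); mechanism recovery over 500
simulated clusters (~60 kb arms, all six event types, noise-free probes
every 400 bp) with a reported degradation check at probe noise 0.3;
change-point recovery over 50 runs of ~120 informative sites at 40×;
mosaicism calibration over 10,000 null simulations of 50 probes (sd 0.15,
200 flanking probes); and the five-cluster patient-like scenario
(200-kb chromosomes) end to end through the file formats.  Expected
father-specific fractions are verified both in closed form and by
simulation within three standard errors over ≥ 200 sites per class.

## Known limitations

* Interchromosomal junctions are rejected by design, not analysed.
* The breakpoint-graph walk assumes the derivative begins and ends at
  the arm's reference ends; ring or unanchored derivatives are out of
  scope, and walk enumeration is capped at 64.
* Copy numbers from probes are rounded to integers; sub-clonal CNVs are
  the mosaicism module's job, not the reconstruction's.
* The one-crossover timing model cannot distinguish multi-crossover
  histories; these surface as `undetermined` with diagnostics.
* Microhomeology search is bounded to one gap run of ≤ 2 columns within
  20-nt windows (69 nt available for exact-overlap extension only).
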