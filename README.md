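# crisismap

Forensics of germline complex chromosomal rearrangements.

Rarely, a child is born carrying several large de novo rearrangements at
once — simple tandem duplications and inversions side by side with
chromothriptic shattering, each cluster confined to one chromosome arm.
Working out what happened requires combining several lines of molecular
evidence, and `crisismap` implements that analysis as a tested, reusable
pipeline for geneticists studying such multifocal germline events:

* **Junction forensics** — classify each fusion junction's signature from
  its sequence: blunt join, microhomology (100% identical, < 70 nt, with
  its fusion-placement ambiguity interval), microhomeology (≥ 5 nt at
  ≥ 70% identity, no run of more than 2 gaps, scored with a zero
  gap-opening penalty), or a templated/untemplated insertion; annotate
  repeat proximity, replication timing and local de novo SNV burden.
* **Cluster reconstruction** — walk the breakpoint graph into the
  derivative chromosome, derive the copy-number profile from aCGH probes,
  and label the mechanism: NHEJ/replication-based simple events,
  chromothripsis (oscillating CN ≤ 1, interspersed deletions, no
  templated events) versus chromoanasynthesis (copy gains + templated
  inserts).
* **Trio origin and timing** — from father/mother/child genotypes with
  per-allele read depths: in a three-copy region the father-specific
  allele accounts for ~2/3 of reads when both extra copies derive from
  one paternal haplotype (diallelic) and ~1/3 when they derive from two
  (triallelic).  A duplicated span carrying diallelic and triallelic
  segments split by a single change-point is the footprint of a
  premeiotic duplication remodelled by one meiosis-I crossover.
  Microsatellite peak areas give an orthogonal dosage call.
* **Mosaicism and methylation** — compare probe means against the
  theoretical log2 ratios (+0.58 duplication, −1.0 deletion; in general
  log2(((1−f)·2 + f·CN)/2) at mosaic fraction f) and methylation indexes
  of imprinted CpG sites against population reference ranges (a paternal
  duplication over a maternally methylated DMR sits at ~1/3).
* **Simulator** — generate a full trio with a paternally derived
  rearrangement burden (reference FASTA, truth BEDPE + junction
  sequences, trio VCF, probe/microsatellite/methylation tables) with
  engineered junction signatures and complete ground truth, so every
  stage above is testable without any external download.

See `docs/methods.md` for the models, parameter choices and limitations.

## Worked example

Simulate and analyse the bundled five-cluster scenario (one cluster per
chromosome arm, all paternal, crossovers inside both duplicated spans,
one 7-bp untemplated insertion in the catastrophic cluster):

```sh
crisismap all --seed 1 --outdir case/
```

The consolidated report (`case/case_report.tsv`, one row per cluster)
prints:

```
chrom  mechanism                           origin    timing                             signatures
chr2   complex_inversion_deletion          paternal  not_applicable                     blunt:2;untemplated_insert:1
chr6   tandem_duplication                  paternal  premeiotic_with_meiotic_crossover  untemplated_insert:1
chr13  inverted_duplication_with_deletion  paternal  premeiotic_with_meiotic_crossover  blunt:1;microhomology:1
chr14  balanced_inversion                  paternal  not_applicable                     microhomology:2
chr21  chromothripsis                      paternal  not_applicable                     blunt:1;microhomeology:1;microhomology:1;untemplated_insert:2
```

Reading it: every cluster resides on a paternally derived chromosome
(dosage votes where a CNV exists, haplotype phase of breakpoint-flanking
variants for the balanced inversion); the two duplication-bearing arms
carry both diallelic and triallelic segments with one change-point each,
so those duplications arose in premeiotic mitosis and were remodelled by
a meiosis-I crossover; only the chr21 cluster — many junctions,
oscillating copy number, deletions, no templated events — is called
chromothripsis, and its chr13/chr6 neighbours keep their simple labels
(with a recorded secondary note that duplication plus microhomology does
not strictly exclude chromothripsis).  The methylation summary reports
7/7 imprinted CpG sites hypomethylated, consistent with one methylated
maternal copy in three (~index 1/3) under the paternal duplication.
Per-stage tables (`dosage_calls.tsv`, `mosaicism.tsv`,
`case_report.json`) and a checksummed `manifest.json` land in the same
directory; re-running with the same seed reproduces every file byte for
byte.

Individual stages are available as `crisismap simulate / junctions /
classify / msat / methylation`, and as library functions
(`crisismap.junctions.classify_junction`,
`crisismap.clusters.build_cluster`, `crisismap.trio.call_site_dosage`,
`crisismap.mosaic.assess_mosaicism`, ...).

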