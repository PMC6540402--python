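"""End-to-end case analysis: simulate -> junctions -> clusters -> origin ->
timing -> mosaicism -> methylation, with a consolidated per-case report.

``simulate_case`` writes a complete artifact directory from a scenario
configuration; ``analyze_case`` reads such a directory (simulated or
assembled from real calls) and produces the case report plus per-stage
tables; ``run_pipeline`` chains the two.  All randomness flows from the
single seed; re-running with the same configuration and seed reproduces
every artifact byte for byte (the manifest records SHA-256 checksums).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from . import clusters as cl
from . import io as cio
from . import junctions as jx
from . import mosaic as mz
from . import trio as tr
from .models import InterchromosomalJunctionError, Junction
from .simulator import ScenarioConfig, SimulatedTrio, simulate_trio

log = logging.getLogger("crisismap")

FLANK_PHASE_WINDOW = 10_000


@dataclass
class ClusterReport:
    chrom: str
    n_junctions: int
    signatures: dict[str, int]
    mechanism: str
    secondary_possibility: str
    origin: str
    origin_basis: str  # dosage | phase | none
    timing: str
    change_point: Optional[int]
    mosaic_verdicts: list[str]
    walk_count: int

    def to_row(self) -> dict:
        return {
            "chrom": self.chrom,
            "n_junctions": self.n_junctions,
            "signatures": ";".join(f"{k}:{v}" for k, v in sorted(self.signatures.items())),
            "mechanism": self.mechanism,
            "secondary_possibility": self.secondary_possibility,
            "origin": self.origin,
            "origin_basis": self.origin_basis,
            "timing": self.timing,
            "change_point": "" if self.change_point is None else self.change_point,
            "mosaicism": ";".join(self.mosaic_verdicts) or "no_cnv",
            "consistent_walks": self.walk_count,
        }


@dataclass
class CaseReport:
    clusters: list[ClusterReport]
    rejected_junctions: list[str]
    methylation: Optional[dict] = None

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def chromosomes_affected(self) -> list[str]:
        return sorted({c.chrom for c in self.clusters})

    def to_dict(self) -> dict:
        return {
            "n_clusters": self.n_clusters,
            "chromosomes_affected": self.chromosomes_affected,
            "rejected_junctions": self.rejected_junctions,
            "clusters": [c.to_row() for c in self.clusters],
            "methylation": self.methylation,
        }


# --------------------------------------------------------------------------
# artifact emission
# --------------------------------------------------------------------------


def simulate_case(config: ScenarioConfig, seed: int, outdir) -> SimulatedTrio:
    """Run the simulator and write the full artifact directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = simulate_trio(config, seed)

    cio.write_fasta(sim.refs, outdir / "reference.fa")
    cio.write_fasta(
        {f"{c}_derivative": d for c, d in sim.derivatives.items()},
        outdir / "derivative.fa",
    )
    bedpe_rows = []
    seq_rows = []
    for chrom, truth in sim.truths.items():
        for tj in truth.junctions:
            bedpe_rows.append((tj.junction, tj.kind))
            seq_rows.append((tj.junction.name, chrom, tj.junction.observed))
    cio.write_bedpe(bedpe_rows, outdir / "junctions.bedpe")
    cio.write_junction_sequences(seq_rows, outdir / "junction_sequences.tsv")
    cio.write_trio_vcf(sim.sites, config.chromosomes, outdir / "trio.vcf")
    cio.write_probes(sim.probes, outdir / "probes.tsv")
    cio.write_microsatellites(sim.msat_rows, outdir / "microsatellites.tsv")
    cio.write_methylation(sim.methylation, outdir / "methylation.tsv")
    _write_phase(sim, outdir / "phase.tsv")
    cio.write_truth_json(sim.truth_dict(), outdir / "truth.json")
    return sim


def _write_phase(sim: SimulatedTrio, path) -> None:
    """Haplotype support of breakpoint-flanking variants.

    Each row records, for a phased variant near a breakpoint, which
    parental haplotype the junction-spanning molecules support; in the
    generative model every rearrangement resides on the father's H1.
    """
    rows = []
    for chrom, truth in sim.truths.items():
        bp = set()
        for tj in truth.junctions:
            bp.add(tj.junction.end_a.pos)
            bp.add(tj.junction.end_b.pos)
        for s in sim.sites:
            if s.chrom != chrom or s.informative_parent != "father":
                continue
            if any(abs(s.pos - p) <= FLANK_PHASE_WINDOW for p in bp):
                rows.append((chrom, s.pos, "father", "H1", f"{chrom}_block1"))
    pd.DataFrame(
        rows, columns=["chrom", "pos", "parent", "hap", "block"]
    ).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# analysis
# --------------------------------------------------------------------------


def analyze_case(
    indir,
    outdir=None,
    min_chromothripsis_junctions: int = cl.MIN_CHROMOTHRIPSIS_JUNCTIONS,
    insert_radius: int = 1000,
) -> CaseReport:
    """Analyse an artifact directory into a per-cluster case report."""
    indir = Path(indir)
    outdir = Path(outdir) if outdir else indir
    outdir.mkdir(parents=True, exist_ok=True)

    refs = cio.read_fasta(indir / "reference.fa")
    raw_rows = cio.read_bedpe(indir / "junctions.bedpe")
    observed = cio.read_junction_sequences(indir / "junction_sequences.tsv")
    sites = cio.read_trio_vcf(indir / "trio.vcf")
    probes = cio.read_probes(indir / "probes.tsv")
    phase = None
    if (indir / "phase.tsv").exists():
        phase = pd.read_csv(indir / "phase.tsv", sep="\t")

    junctions_by_chrom: dict[str, list[Junction]] = {}
    rejected: list[str] = []
    for row in raw_rows:
        if row["chrom1"] != row["chrom2"]:
            log.warning("rejecting interchromosomal junction %s", row["name"])
            rejected.append(row["name"])
            continue
        try:
            j = cio.junction_from_bedpe_row(row, observed=observed.get(row["name"], ""))
        except InterchromosomalJunctionError:
            rejected.append(row["name"])
            continue
        junctions_by_chrom.setdefault(j.chrom, []).append(j)

    reports: list[ClusterReport] = []
    dosage_rows = []
    mosaic_rows = []
    gain_intervals: list[tuple[str, int, int]] = []

    for chrom in sorted(junctions_by_chrom):
        juncs = junctions_by_chrom[chrom]
        ref = refs[chrom]
        sigs = [
            jx.classify_junction(j, ref, insert_radius=insert_radius) for j in juncs
        ]
        chrom_probes = probes[probes["chrom"] == chrom]
        probe_pairs = list(zip(chrom_probes["pos"], chrom_probes["log2_ratio"]))
        cuts = cl.breakend_cuts(juncs, len(ref))
        cn = cl.cn_from_probes(probe_pairs, cuts)
        cluster = cl.build_cluster(
            chrom, juncs, sigs, cn, len(ref),
            min_chromothripsis_junctions=min_chromothripsis_junctions,
        )

        gains = _merge_intervals([(s, e) for s, e, c in cn if c >= 2])
        losses = _merge_intervals([(s, e) for s, e, c in cn if c == 0])
        chrom_sites = [s for s in sites if s.chrom == chrom]

        origin, basis = _cluster_origin(
            chrom, gains, losses, chrom_sites, phase, juncs
        )

        timing_verdict, change_point = "not_applicable", None
        if gains:
            calls = _span_dosage_calls(chrom_sites, gains)
            dosage_rows += [dataclasses.asdict(c) for c in calls]
            t = tr.infer_timing(calls)
            timing_verdict, change_point = t.verdict, t.change_point

        verdicts = []
        for (a, b), cn_exp in [(g, 3) for g in gains] + [(l, 1) for l in losses]:
            inside = chrom_probes[
                (chrom_probes["pos"] >= a) & (chrom_probes["pos"] < b)
            ]["log2_ratio"].to_numpy()
            flank = chrom_probes[
                (chrom_probes["pos"] < a - 1) | (chrom_probes["pos"] >= b + 1)
            ]
            neutral = flank[abs(flank["log2_ratio"]) < 0.3]["log2_ratio"].to_numpy()
            try:
                assessment = mz.assess_mosaicism(
                    inside, cn_exp, flanking_probes=neutral,
                    chrom=chrom, start=a, end=b,
                )
            except ValueError:
                continue
            verdicts.append(assessment.verdict)
            mosaic_rows.append(dataclasses.asdict(assessment))

        gain_intervals += [(chrom, a, b) for a, b in gains]
        reports.append(
            ClusterReport(
                chrom=chrom,
                n_junctions=len(juncs),
                signatures=_count([s.kind for s in sigs]),
                mechanism=cluster.mechanism,
                secondary_possibility=cluster.secondary_possibility,
                origin=origin,
                origin_basis=basis,
                timing=timing_verdict,
                change_point=change_point,
                mosaic_verdicts=verdicts,
                walk_count=cluster.walk_count,
            )
        )

    methylation_summary = None
    meth_path = indir / "methylation.tsv"
    if meth_path.exists():
        meth_df = pd.read_csv(meth_path, sep="\t")
        if len(meth_df):
            meth_sites = cio.read_methylation(meth_path)
            overlap = False
            if {"chrom", "pos"} <= set(meth_df.columns):
                paternal_gains = [
                    (c, a, b) for (c, a, b) in gain_intervals
                    if _origin_of(reports, c) == "paternal"
                ]
                overlap = any(
                    c == str(r["chrom"]) and a <= int(r["pos"]) < b
                    for _, r in meth_df.iterrows()
                    for (c, a, b) in paternal_gains
                )
            rep = mz.assess_methylation(meth_sites, paternal_gain_overlap=overlap)
            methylation_summary = {
                "n_hypo": rep.n_hypo, "n_normal": rep.n_normal,
                "n_hyper": rep.n_hyper, "note": rep.consistency_note,
                "per_site": rep.per_site,
            }

    report = CaseReport(
        clusters=reports, rejected_junctions=rejected,
        methylation=methylation_summary,
    )
    _write_report(report, dosage_rows, mosaic_rows, outdir)
    return report


def _origin_of(reports, chrom):
    for r in reports:
        if r.chrom == chrom:
            return r.origin
    return "undetermined"


def _count(kinds):
    out: dict[str, int] = {}
    for k in kinds:
        out[k] = out.get(k, 0) + 1
    return out


def _merge_intervals(ivals):
    out = []
    for s, e in sorted(ivals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _span_dosage_calls(chrom_sites, gains):
    calls = []
    for a, b in gains:
        for s in chrom_sites:
            if not (a <= s.pos < b) or s.informative_parent != "father":
                continue
            if len(set(s.child_gt)) < 2:
                continue  # the patient-heterozygous selection filter
            g = s.specific_site()
            calls.append(tr.call_site_dosage(g, in_duplication=True))
    return sorted(calls, key=lambda c: c.pos)


def _cluster_origin(chrom, gains, losses, chrom_sites, phase, juncs):
    verdicts = []
    for a, b in gains:
        call = tr.assign_parent_of_origin(chrom_sites, (chrom, a, b), "gain")
        verdicts.append(call.origin)
    for a, b in losses:
        call = tr.assign_parent_of_origin(chrom_sites, (chrom, a, b), "loss")
        verdicts.append(call.origin)
    informative = [v for v in verdicts if v in ("paternal", "maternal")]
    if informative:
        if len(set(informative)) == 1 and "conflicted" not in verdicts:
            return informative[0], "dosage"
        return "conflicted", "dosage"
    # balanced cluster: fall back to haplotype phase of flanking variants
    if phase is not None and len(phase):
        bp = set()
        for j in juncs:
            bp.add(j.end_a.pos)
            bp.add(j.end_b.pos)
        near = phase[
            (phase["chrom"] == chrom)
            & phase["pos"].apply(
                lambda p: any(abs(p - x) <= FLANK_PHASE_WINDOW for x in bp)
            )
        ]
        if len(near):
            status, _ = tr.phase_consistency(
                list(zip(near["pos"], near["parent"] + ":" + near["hap"]))
            )
            if status == "consistent":
                parent = near["parent"].iloc[0]
                return ("paternal" if parent == "father" else "maternal"), "phase"
            return "conflicted", "phase"
    return "undetermined", "none"


# --------------------------------------------------------------------------
# report + manifest
# --------------------------------------------------------------------------


def _write_report(report: CaseReport, dosage_rows, mosaic_rows, outdir: Path) -> None:
    pd.DataFrame([c.to_row() for c in report.clusters]).to_csv(
        outdir / "case_report.tsv", sep="\t", index=False
    )
    with open(outdir / "case_report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=1, sort_keys=True)
    if dosage_rows:
        pd.DataFrame(dosage_rows).to_csv(
            outdir / "dosage_calls.tsv", sep="\t", index=False, float_format="%.4f"
        )
    if mosaic_rows:
        pd.DataFrame(mosaic_rows).to_csv(
            outdir / "mosaicism.tsv", sep="\t", index=False, float_format="%.5f"
        )


def write_manifest(outdir, config: ScenarioConfig, seed: int) -> None:
    outdir = Path(outdir)
    files = {}
    for path in sorted(outdir.iterdir()):
        if path.name == "manifest.json" or path.is_dir():
            continue
        files[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest = {
        "tool": "crisismap",
        "version": __version__,
        "seed": seed,
        "config": config.to_dict(),
        "checksums": files,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def run_pipeline(config: ScenarioConfig, seed: int, outdir) -> CaseReport:
    """Simulate, analyse and manifest one case under one seed."""
    outdir = Path(outdir)
    simulate_case(config, seed, outdir)
    report = analyze_case(outdir, outdir)
    write_manifest(outdir, config, seed)
    return report
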