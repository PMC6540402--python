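"""Readers and writers for the formats the pipeline consumes and emits.

Conventions: coordinates are 0-based half-open in memory; VCF is written
and read 1-based; BEDPE breakends cover the breakpoint-adjacent base
([pos-1, pos) for a fragment retained to the left — strand ``+`` — and
[pos, pos+1) for one retained to the right — strand ``-``).
"""

from __future__ import annotations

import json
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import BreakpointEnd, Junction, MethylationSite, MicrosatelliteObservation
from .trio import TrioSite

# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# --------------------------------------------------------------------------
# BEDPE + junction sequences
# --------------------------------------------------------------------------

BEDPE_COLUMNS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "score", "strand1", "strand2", "signature",
]


def _end_to_bedpe(end: BreakpointEnd) -> tuple[int, int, str]:
    if end.side == "left":
        return end.pos - 1, end.pos, "+"
    return end.pos, end.pos + 1, "-"


def _end_from_bedpe(chrom: str, start: int, end: int, strand: str) -> BreakpointEnd:
    if strand == "+":
        return BreakpointEnd(chrom, end, "left")
    return BreakpointEnd(chrom, start, "right")


def write_bedpe(rows: Iterable[tuple[Junction, str]], path) -> None:
    """Write (junction, signature label) pairs as tagged BEDPE."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(BEDPE_COLUMNS) + "\n")
        for junction, signature in rows:
            s1, e1, st1 = _end_to_bedpe(junction.end_a)
            s2, e2, st2 = _end_to_bedpe(junction.end_b)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        junction.end_a.chrom, s1, e1,
                        junction.end_b.chrom, s2, e2,
                        junction.name, ".", st1, st2, signature,
                    )
                )
                + "\n"
            )


def read_bedpe(path) -> list[dict]:
    """Raw BEDPE rows (interchromosomal rows included; callers filter)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 10:
                raise ValueError(f"{path}:{ln}: BEDPE row has {len(parts)} columns")
            try:
                row = {
                    "chrom1": parts[0], "start1": int(parts[1]), "end1": int(parts[2]),
                    "chrom2": parts[3], "start2": int(parts[4]), "end2": int(parts[5]),
                    "name": parts[6], "strand1": parts[8], "strand2": parts[9],
                    "signature": parts[10] if len(parts) > 10 else "",
                }
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed BEDPE interval") from exc
            rows.append(row)
    return rows


def junction_from_bedpe_row(row: dict, observed: str = "", insert: str = "") -> Junction:
    end_a = _end_from_bedpe(row["chrom1"], row["start1"], row["end1"], row["strand1"])
    end_b = _end_from_bedpe(row["chrom2"], row["start2"], row["end2"], row["strand2"])
    return Junction(end_a, end_b, observed=observed, insert=insert, name=row["name"])


def write_junction_sequences(rows: Iterable[tuple[str, str, str]], path) -> None:
    """TSV of (junction name, chrom, observed joined sequence)."""
    with open(path, "w") as fh:
        fh.write("name\tchrom\tobserved\n")
        for name, chrom, observed in rows:
            fh.write(f"{name}\t{chrom}\t{observed}\n")


def read_junction_sequences(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["name"], df["observed"]))


# --------------------------------------------------------------------------
# VCF
# --------------------------------------------------------------------------

SAMPLES = ("FATHER", "MOTHER", "CHILD")


def write_trio_vcf(sites, chrom_lengths: dict[str, int], path) -> None:
    """Trio VCF (GT:AD:DP) from simulator site records."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths for the ref and alt alleles">\n'
        )
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(SAMPLES) + "\n")
        for s in sorted(sites, key=lambda x: (x.chrom, x.pos)):
            cols = [s.chrom, str(s.pos + 1), ".", s.ref, s.alt, ".", "PASS", ".",
                    "GT:AD:DP"]
            for gt, ad in (
                (s.father_gt, s.father_ad),
                (s.mother_gt, s.mother_ad),
                (s.child_gt, s.child_ad),
            ):
                gt_str = "/".join(str(a) for a in sorted(gt))
                cols.append(f"{gt_str}:{ad[0]},{ad[1]}:{ad[0] + ad[1]}")
            fh.write("\t".join(cols) + "\n")


def read_trio_vcf(path) -> list[TrioSite]:
    """Load a trio VCF (FATHER, MOTHER, CHILD samples) with AD fields."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    order = {name: i for i, name in enumerate(vcf.samples)}
    idx = [order[s] for s in SAMPLES]
    sites = []
    for var in vcf:
        gts = var.genotypes  # [allele, allele, phased] per sample
        ad = var.format("AD")
        def gt(i):
            return tuple(int(a) for a in gts[i][:-1] if a >= 0)
        def adp(i):
            return (int(ad[i][0]), int(ad[i][1]))
        sites.append(
            TrioSite(
                chrom=var.CHROM, pos=var.POS - 1,
                father_gt=gt(idx[0]) or (0, 0),
                mother_gt=gt(idx[1]) or (0, 0),
                child_gt=gt(idx[2]) or (0, 0),
                father_ad=adp(idx[0]), mother_ad=adp(idx[1]),
                child_ad=adp(idx[2]),
            )
        )
    return sites


# --------------------------------------------------------------------------
# TSV tables
# --------------------------------------------------------------------------


def write_probes(rows: Sequence[tuple[str, int, float]], path) -> None:
    pd.DataFrame(rows, columns=["chrom", "pos", "log2_ratio"]).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def read_probes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not set(df.columns) >= {"chrom", "pos", "log2_ratio"}:
        raise ValueError(f"{path}: expected columns chrom, pos, log2_ratio")
    return df.sort_values(["chrom", "pos"]).reset_index(drop=True)


def write_microsatellites(rows, path) -> None:
    pd.DataFrame(
        rows, columns=["locus", "chrom", "pos", "member", "allele_size_bp", "peak_area"]
    ).to_csv(path, sep="\t", index=False, float_format="%.2f")


def read_microsatellites(path) -> list[MicrosatelliteObservation]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for locus, grp in df.groupby("locus", sort=True):
        members: dict[str, dict[int, float]] = {"child": {}, "father": {}, "mother": {}}
        for _, row in grp.iterrows():
            members[row["member"]][int(row["allele_size_bp"])] = float(row["peak_area"])
        out.append(
            MicrosatelliteObservation(
                locus=str(locus), child=members["child"],
                father=members["father"], mother=members["mother"],
            )
        )
    return out


def write_methylation(rows, path) -> None:
    pd.DataFrame(
        rows, columns=["site", "chrom", "pos", "index", "ref_min", "ref_max"]
    ).to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_methylation(path) -> list[MethylationSite]:
    df = pd.read_csv(path, sep="\t")
    return [
        MethylationSite(
            site=str(r["site"]), index=float(r["index"]),
            ref_min=float(r["ref_min"]), ref_max=float(r["ref_max"]),
        )
        for _, r in df.iterrows()
    ]


def read_bed(path) -> list[tuple[str, int, int, str]]:
    """(chrom, start, end, name) intervals from a BED file."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED row needs >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed BED interval") from exc
            if end < start:
                raise ValueError(f"{path}:{ln}: BED end before start")
            rows.append((parts[0], start, end, parts[3] if len(parts) > 3 else "."))
    return rows


def read_timing(path) -> list[tuple[str, int, float]]:
    df = pd.read_csv(path, sep="\t")
    return [
        (str(r["chrom"]), int(r["pos"]), float(r["timing"])) for _, r in df.iterrows()
    ]


def write_truth_json(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
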