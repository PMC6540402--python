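"""aCGH log-ratio mosaicism assessment and methylation-index comparison.

For reference ploidy 2, probes in a non-mosaic heterozygous deletion
average log2(1/2) = -1.0 and in a duplication log2(3/2) = +0.58.  A CNV
present in only a fraction f of cells pulls the average toward 0:

    log2 ratio = log2( ((1 - f) * 2 + f * CN) / 2 )

so an observed mean significantly closer to diploid than the theoretical
value is a sign of mosaicism.  "Significantly" is operationalised as a
one-sided z-test at p < 0.01 against probe noise estimated from flanking
diploid probes; the implied mosaic fraction is back-solved from the mean.

Methylation indexes of imprinted CpG sites are compared against
population reference ranges (closed intervals); a maternally methylated
DMR inside a paternal duplication is expected at 1 methylated copy of 3,
index ~ 1/3, i.e. mild hypomethylation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .models import MethylationSite, MosaicismAssessment

MIN_PROBES = 10
MOSAIC_P = 0.01

#: display thresholds used for plotting/segment seeding only, never for
#: the mosaicism verdict
DISPLAY_LOSS_THRESHOLD = -0.8
DISPLAY_GAIN_THRESHOLD = 0.4


def theoretical_log_ratio(copy_number: int, mosaic_fraction: float = 1.0) -> float:
    """Expected aCGH log2 ratio of a CNV at a given mosaic fraction.

    Returns -inf ("below scale") for a homozygous deletion present in all
    cells.
    """
    if copy_number < 0:
        raise ValueError("copy number must be >= 0")
    if not 0.0 <= mosaic_fraction <= 1.0:
        raise ValueError("mosaic fraction must lie in [0, 1]")
    dose = (1.0 - mosaic_fraction) * 2.0 + mosaic_fraction * copy_number
    if dose == 0.0:
        return float("-inf")
    return math.log2(dose / 2.0)


def mosaic_fraction_from_mean(mean_log2: float, copy_number: int) -> float:
    """Back-solve the mosaic fraction from a mean log2 ratio (clipped to [0, 1])."""
    if copy_number == 2:
        raise ValueError("copy number 2 carries no mosaicism information")
    f = (2.0 ** (mean_log2 + 1.0) - 2.0) / (copy_number - 2.0)
    return float(np.clip(f, 0.0, 1.0))


def assess_mosaicism(
    cnv_probes: Sequence[float],
    expected_cn: int,
    flanking_probes: Optional[Sequence[float]] = None,
    noise_sd: Optional[float] = None,
    chrom: str = "",
    start: int = 0,
    end: int = 0,
    min_probes: int = MIN_PROBES,
    alpha: float = MOSAIC_P,
) -> MosaicismAssessment:
    """One-sided z-test of the probe mean against the theoretical value.

    ``expected_cn`` is the constitutional copy number of the CNV (1 or 3
    for the heterozygous case).  Noise is estimated as the standard
    deviation of ``flanking_probes`` (diploid neighbours) unless
    ``noise_sd`` is given.  The deviation must be *toward* diploid to
    count as mosaicism.
    """
    values = np.asarray(list(cnv_probes), dtype=float)
    n = values.size
    theo = theoretical_log_ratio(expected_cn, 1.0)
    if n < min_probes:
        return MosaicismAssessment(
            chrom=chrom, start=start, end=end, probe_count=int(n),
            mean_log2=float(values.mean()) if n else float("nan"),
            theoretical=theo, mosaic_fraction=float("nan"),
            p_value=float("nan"), verdict="insufficient_probes",
        )
    if noise_sd is None:
        if flanking_probes is None or len(flanking_probes) < 2:
            raise ValueError(
                "no flanking diploid probes: probe noise cannot be estimated"
            )
        noise_sd = float(np.std(np.asarray(flanking_probes, dtype=float), ddof=1))
    mean = float(values.mean())
    se = noise_sd / math.sqrt(n)
    # toward-diploid deviation: below +0.58 for gains, above -1.0 for losses
    z = (theo - mean) / se if expected_cn > 2 else (mean - theo) / se
    p = float(norm.sf(z))
    frac = mosaic_fraction_from_mean(mean, expected_cn)
    verdict = "mosaic_suspected" if p < alpha else "non_mosaic"
    return MosaicismAssessment(
        chrom=chrom, start=start, end=end, probe_count=int(n),
        mean_log2=mean, theoretical=theo, mosaic_fraction=frac,
        p_value=p, verdict=verdict,
    )


# --------------------------------------------------------------------------
# methylation
# --------------------------------------------------------------------------


@dataclass
class MethylationReport:
    per_site: list[tuple[str, str]]  # (site id, hypo|normal|hyper)
    n_hypo: int
    n_normal: int
    n_hyper: int
    consistency_note: str = ""


def assess_methylation(
    sites: Sequence[MethylationSite],
    paternal_gain_overlap: bool = False,
) -> MethylationReport:
    """Classify methylation indexes against their reference ranges.

    The reference interval is closed: an index equal to the boundary is
    normal.  When the sites lie in a maternally methylated DMR overlapped
    by a paternal duplication, the expected index is ~1/3 (one methylated
    maternal copy of three), and a consistency note records whether the
    observed pattern matches that expectation.
    """
    per_site = []
    for s in sites:
        if s.index < s.ref_min:
            cls = "hypo"
        elif s.index > s.ref_max:
            cls = "hyper"
        else:
            cls = "normal"
        per_site.append((s.site, cls))
    n_hypo = sum(1 for _, c in per_site if c == "hypo")
    n_hyper = sum(1 for _, c in per_site if c == "hyper")
    n_normal = len(per_site) - n_hypo - n_hyper
    note = ""
    if paternal_gain_overlap and sites:
        mean = float(np.mean([s.index for s in sites]))
        expected = 1.0 / 3.0
        if n_hypo == len(per_site) and abs(mean - expected) < 0.1:
            note = (
                "hypomethylation consistent with a paternal (unmethylated) "
                "copy gain over a maternally methylated DMR (expected index ~1/3)"
            )
        else:
            note = (
                f"pattern deviates from the ~1/3 index expected under a "
                f"paternal copy gain (mean {mean:.3f})"
            )
    return MethylationReport(
        per_site=per_site, n_hypo=n_hypo, n_normal=n_normal, n_hyper=n_hyper,
        consistency_note=note,
    )
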