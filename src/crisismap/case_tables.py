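"""Published trio microsatellite genotypes for the analysed case.

Six loci inside the duplicated regions on 6q and 13q, as PCR product
sizes (bp) per trio member.  Child peak areas are proportional to allele
copy counts; where the child shows fewer distinct sizes than copies the
repeated size carries the combined area.  ``assessment`` is the reported
diallelic/triallelic status the dosage caller is expected to reproduce.
"""

from __future__ import annotations

from .models import MicrosatelliteObservation

#: (locus, child {size: area}, father {size: area}, mother {size: area}, assessment)
MICROSATELLITE_TABLE = [
    ("D6S270", {139: 3.0}, {139: 1.0, 141: 1.0}, {129: 1.0, 139: 1.0}, "diallelic"),
    ("D6S292", {145: 2.0, 157: 1.0}, {145: 1.0, 157: 1.0}, {145: 1.0, 151: 1.0},
     "triallelic"),
    ("D6S1569", {129: 1.0, 133: 1.0, 135: 1.0}, {129: 1.0, 135: 1.0}, {133: 2.0},
     "triallelic"),
    ("D6S308", {194: 1.0, 198: 2.0}, {194: 1.0, 198: 1.0}, {198: 1.0, 200: 1.0},
     "triallelic"),
    ("D13S218", {188: 1.0, 190: 1.0, 192: 1.0}, {188: 1.0, 192: 1.0}, {190: 2.0},
     "triallelic"),
    ("D13S263", {141: 1.0, 147: 1.0, 149: 1.0}, {141: 1.0, 147: 1.0},
     {147: 1.0, 149: 1.0}, "triallelic"),
]


def microsatellite_observations() -> list[tuple[MicrosatelliteObservation, str]]:
    """The table as observation objects paired with the reported assessment."""
    return [
        (
            MicrosatelliteObservation(locus=name, child=dict(child),
                                      father=dict(father), mother=dict(mother)),
            assessment,
        )
        for name, child, father, mother, assessment in MICROSATELLITE_TABLE
    ]
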