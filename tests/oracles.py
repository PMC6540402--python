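"""Independent brute-force oracles for the junction detectors.

Written as plain enumerations over the definitions, deliberately separate
from the package's optimised implementations.
"""

from __future__ import annotations

from crisismap.models import HomeologyCandidate


def brute_microhomology(wa: str, wb: str) -> tuple[int, int]:
    """Maximal exact fusion overlap and its ambiguity, by direct scan."""
    best = 0
    for k in range(1, min(len(wa), len(wb)) + 1):
        if wa[len(wa) - k :] == wb[:k]:
            best = k
    return best, best + 1


def brute_homeology(
    wa: str,
    wb: str,
    min_len: int = 5,
    min_identity: float = 0.70,
    anchored_only: bool = False,
) -> list[HomeologyCandidate]:
    """Naive enumeration of every qualifying homeology candidate.

    Candidate space: ungapped local alignments plus alignments with one
    gap run of length 1-2 in either sequence; unanchored candidates must
    start and end on match columns, fusion-anchored ones (A segment ends
    on the A window's fusion edge, B segment starts at the B window's
    first base) are exempt.
    """
    la, lb = len(wa), len(wb)
    thr = min_identity - 1e-12
    # diagonal prefix sums so each candidate costs O(1)
    pfx = [[0] * (lb + 1) for _ in range(la + 1)]
    for x in range(la):
        row, prev = pfx[x + 1], pfx[x]
        for y in range(lb):
            row[y + 1] = prev[y] + (wa[x] == wb[y])

    def block(x, y, ln):
        return pfx[x + ln][y + ln] - pfx[x][y]

    out = []

    def consider(x, y, cols, matches, gaps, end_a, end_b):
        anchored = y == 0 and end_a == la
        if cols < min_len or matches < thr * cols:
            return
        if not anchored:
            if not (wa[x] == wb[y] and wa[end_a - 1] == wb[end_b - 1]):
                return
            if anchored_only:
                return
        alen, blen = end_a - x, end_b - y
        out.append(
            HomeologyCandidate(
                a_start=x, a_len=alen, b_start=y, b_len=blen,
                columns=cols, matches=matches, gap_columns=gaps,
                anchored=anchored,
            )
        )

    for x in range(la):
        for y in range(lb):
            if y != 0 and wa[x] != wb[y]:
                continue  # a valid unanchored candidate starts on a match
            for p in range(1, min(la - x, lb - y) + 1):
                consider(x, y, p, block(x, y, p), 0, x + p, y + p)
                for g in (1, 2):
                    for side in ("A", "B"):
                        if side == "B":  # dashes in B consume A bases
                            x2, y2 = x + p + g, y + p
                        else:
                            x2, y2 = x + p, y + p + g
                        qmax = min(la - x2, lb - y2)
                        m1 = block(x, y, p)
                        for q in range(1, qmax + 1):
                            consider(
                                x, y, p + q + g, m1 + block(x2, y2, q), g,
                                x2 + q, y2 + q,
                            )
    out.sort(key=HomeologyCandidate.sort_key)
    return out
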