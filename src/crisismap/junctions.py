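"""Breakpoint-junction forensics.

Detects the sequence signature at a fusion junction — blunt join,
microhomology, microhomeology, untemplated or templated insertion — and
annotates the genomic context of each breakpoint (repeat proximity,
replication timing of the nearest tested locus, local de novo SNV burden,
open-chromatin marks).

Definitions
-----------
Microhomology: perfectly identical sequence shared by the fragment end on
the A side of the fusion and the fragment start on the B side, shorter
than 70 nt.  A k-nt microhomology makes k+1 fusion placements equivalent;
the derivative carries the shared tract once.

Microhomeology: an imperfect shared tract of at least 5 aligned columns at
70% or more identity with no run of more than 2 consecutive gaps, found by
scanning the 20-nt flank windows with a zero gap-opening penalty (match
+1, mismatch -1, gap extension -1).  Candidates are enumerated
exhaustively over ungapped alignments plus alignments with a single gap
run of length 1-2, and ranked by (identity, length); this deterministic
filter replaces manual curation of alignment output.  A junction that
satisfies the microhomology definition is never reported as
microhomeology.

For signature assignment the microhomeologous tract must be anchored at
the fusion point (a suffix of the A window aligned to a prefix of the B
window): almost any two random 20-mers contain some interior >=5 nt/70%
alignment, so only fusion-anchored homeology is evidence about the join
itself.  The unanchored window-wide scan remains available as an
annotation.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .models import (
    BreakpointAnnotation,
    BreakpointEnd,
    HomeologyCandidate,
    Junction,
    JunctionSignature,
)

SCAN_WINDOW = 20
EXTENDED_WINDOW = 69
MICROHOMOLOGY_CAP = 70  # exact homology of this length or more is not microhomology
HOMEOLOGY_MIN_LEN = 5
HOMEOLOGY_MIN_IDENTITY = 0.70
MAX_GAP_RUN = 2

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class FlankError(ValueError):
    """Raised when a junction's flanks are too short for the scan window."""


def _check_range(ref: str, lo: int, hi: int, junction_name: str) -> None:
    if lo < 0 or hi > len(ref):
        raise FlankError(
            f"junction {junction_name or '(unnamed)'}: flank [{lo}, {hi}) "
            f"outside reference of length {len(ref)}"
        )


def flank_a(ref: str, end: BreakpointEnd, n: int, name: str = "") -> str:
    """Reference window ending at the A breakend, in derivative orientation."""
    if end.side == "left":
        _check_range(ref, end.pos - n, end.pos, name)
        return ref[end.pos - n : end.pos]
    _check_range(ref, end.pos, end.pos + n, name)
    return revcomp(ref[end.pos : end.pos + n])


def flank_b(ref: str, end: BreakpointEnd, n: int, name: str = "") -> str:
    """Reference window starting at the B breakend, in derivative orientation."""
    if end.side == "right":
        _check_range(ref, end.pos, end.pos + n, name)
        return ref[end.pos : end.pos + n]
    _check_range(ref, end.pos - n, end.pos, name)
    return revcomp(ref[end.pos - n : end.pos])


def exact_overlap(wa: str, wb: str) -> int:
    """Maximal k such that the last k nt of ``wa`` equal the first k of ``wb``."""
    for k in range(min(len(wa), len(wb)), 0, -1):
        if wa[-k:] == wb[:k]:
            return k
    return 0


def parse_observed(observed: str, wa: str, wb: str) -> tuple[int, str]:
    """Decompose an observed junction sequence into (homology k, insert).

    The observed sequence must begin with the A-side reference window and
    end with the B-side window, either merged over a shared k-suffix/prefix
    (microhomology), abutted directly, or separated by an insert.
    """
    if not observed.startswith(wa):
        raise ValueError("observed junction sequence does not begin with the A flank")
    rest = observed[len(wa) :]
    if len(rest) < len(wb):
        k = len(wb) - len(rest)
        if wb[k:] == rest and wa[-k:] == wb[:k]:
            return k, ""
        raise ValueError("observed junction sequence inconsistent with flanks")
    if rest.endswith(wb):
        return 0, rest[: len(rest) - len(wb)]
    raise ValueError("observed junction sequence does not end with the B flank")


def detect_microhomology(
    junction: Junction,
    ref: str,
    window: int = SCAN_WINDOW,
) -> JunctionSignature:
    """Exact-overlap scan at the fusion point.

    Returns a partial signature: ``microhomology`` for 0 < k < 70 with its
    ambiguity interval (k+1 equivalent placements), ``blunt`` for k = 0
    with an empty insert, kind ``none`` with ``over_cap`` set when the
    shared tract reaches 70 nt.  ``window`` defaults to the 20-nt scan and
    may be extended (e.g. to the 69-nt cap, or beyond to witness cap
    violations).
    """
    wa = flank_a(ref, junction.end_a, window, junction.name)
    wb = flank_b(ref, junction.end_b, window, junction.name)
    k = exact_overlap(wa, wb)
    if k >= MICROHOMOLOGY_CAP:
        return JunctionSignature(
            kind="none", homology_length=k, homology_identity=1.0,
            ambiguity=k + 1, over_cap=True,
        )
    if k > 0:
        return JunctionSignature(
            kind="microhomology", homology_length=k, homology_identity=1.0,
            ambiguity=k + 1,
        )
    kind = "blunt" if not junction.insert else "none"
    return JunctionSignature(kind=kind, homology_length=0, ambiguity=1)


def _block_sums(wa: str, wb: str):
    """Match matrix plus match counts of every ungapped run.

    Returns ``(m, runs)`` where ``m[x, y]`` is True when wa[x] == wb[y] and
    ``runs[x, y, l]`` counts matches in the run of length ``l`` starting at
    (x, y) (zero where the run leaves either window).
    """
    a = np.frombuffer(wa.encode(), dtype=np.uint8)
    b = np.frombuffer(wb.encode(), dtype=np.uint8)
    la, lb = len(a), len(b)
    m = a[:, None] == b[None, :]
    pfx = np.zeros((la + 1, lb + 1), dtype=np.int32)
    for x in range(la):
        pfx[x + 1, 1:] = pfx[x, :-1] + m[x]
    lmax = min(la, lb)
    x = np.arange(la + 1)[:, None, None]
    y = np.arange(lb + 1)[None, :, None]
    l = np.arange(lmax + 1)[None, None, :]
    ex, ey = x + l, y + l
    ok = (ex <= la) & (ey <= lb)
    runs = np.where(
        ok, pfx[np.clip(ex, 0, la), np.clip(ey, 0, lb)] - pfx[x, y], 0
    )
    return m, runs, ok


def _anchored_candidates(
    wa: str, wb: str, runs: np.ndarray, min_len: int, thr: float
) -> list[HomeologyCandidate]:
    """Fusion-anchored candidates only (fast path, same candidate space)."""
    la, lb = len(wa), len(wb)
    lmax = min(la, lb)
    out = []

    def run_m(x: int, y: int, ln: int) -> int:
        return int(runs[x, y, ln])

    # ungapped suffix/prefix alignments
    for ln in range(min_len, lmax + 1):
        if ln > la or ln > lb:
            break
        mtc = run_m(la - ln, 0, ln)
        if mtc >= thr * ln:
            out.append(HomeologyCandidate(
                a_start=la - ln, a_len=ln, b_start=0, b_len=ln,
                columns=ln, matches=mtc, gap_columns=0, anchored=True))
    # one gap run of length g: block1 (p), gap, block2 (q); B prefix at 0,
    # A suffix ending on the fusion edge
    for g in (1, 2):
        for side in ("A", "B"):
            for p in range(1, lmax + 1):
                for q in range(1, lmax + 1):
                    cols = p + q + g
                    if cols < min_len:
                        continue
                    alen = p + q + (g if side == "B" else 0)
                    blen = p + q + (g if side == "A" else 0)
                    if alen > la or blen > lb:
                        continue
                    x = la - alen
                    x2 = x + p + (g if side == "B" else 0)
                    y2 = p + (g if side == "A" else 0)
                    mtc = run_m(x, 0, p) + run_m(x2, y2, q)
                    if mtc >= thr * cols:
                        out.append(HomeologyCandidate(
                            a_start=x, a_len=alen, b_start=0, b_len=blen,
                            columns=cols, matches=mtc, gap_columns=g,
                            anchored=True))
    out.sort(key=HomeologyCandidate.sort_key)
    return out


def homeology_candidates(
    wa: str,
    wb: str,
    min_len: int = HOMEOLOGY_MIN_LEN,
    min_identity: float = HOMEOLOGY_MIN_IDENTITY,
    anchored_only: bool = False,
) -> list[HomeologyCandidate]:
    """All qualifying imperfect-homology alignments of the two windows.

    The candidate space is every ungapped local alignment plus every
    alignment with a single gap run of length 1 or 2 (in either sequence);
    longer or multiple gap runs are excluded by the no->2-consecutive-gaps
    rule.  Unanchored candidates must start and end on match columns (as
    any optimal local alignment does); fusion-anchored candidates — whose
    A segment ends on the window's fusion edge and whose B segment starts
    on it — are exempt, since anchoring asserts the tract's position, not
    its trimming.  Qualifying candidates are returned best first by
    (identity, length, A offset, B offset).
    """
    m, runs, run_ok = _block_sums(wa, wb)
    la, lb = len(wa), len(wb)
    lmax = min(la, lb)
    found: list[HomeologyCandidate] = []
    thr = min_identity - 1e-12

    if anchored_only:
        return _anchored_candidates(wa, wb, runs, min_len, thr)

    def harvest(matches, cols, valid, anchored, coords):
        """coords: callable idx -> (a_start, a_len, b_start, b_len, gaps)."""
        sel = np.nonzero(valid)
        if sel[0].size == 0:
            return
        for idx in zip(*sel):
            a0, alen, b0, blen, g = coords(idx)
            found.append(
                HomeologyCandidate(
                    a_start=a0, a_len=alen, b_start=b0, b_len=blen,
                    columns=int(cols[idx]), matches=int(matches[idx]),
                    gap_columns=g, anchored=bool(anchored[idx]),
                )
            )

    # --- ungapped candidates: indices (x, y, l) -----------------------------
    x = np.arange(la + 1)[:, None, None]
    y = np.arange(lb + 1)[None, :, None]
    l = np.arange(lmax + 1)[None, None, :]
    cols = np.broadcast_to(l, runs.shape)
    ok = run_ok & (l >= min_len)
    with np.errstate(divide="ignore", invalid="ignore"):
        qual = ok & (runs >= thr * cols)
    anchored = qual & (y == 0) & (x + l == la)
    first = m[np.clip(x, 0, la - 1), np.clip(y, 0, lb - 1)]
    last = m[np.clip(x + l - 1, 0, la - 1), np.clip(y + l - 1, 0, lb - 1)]
    valid = qual & (anchored | (first & last & (l >= 1)))
    if anchored_only:
        valid = valid & anchored
    harvest(
        runs, cols, valid, anchored,
        lambda i: (int(i[0]), int(i[2]), int(i[1]), int(i[2]), 0),
    )

    # --- one gap run of length g (dashes in A or in B): indices (x, y, p, q)
    xx = np.arange(la)[:, None, None, None]
    yy = np.arange(lb)[None, :, None, None]
    pp = np.arange(1, lmax + 1)[None, None, :, None]
    qq = np.arange(1, lmax + 1)[None, None, None, :]
    for g in (1, 2):
        for side in ("A", "B"):
            if side == "B":  # dashes in B: the gap consumes A bases
                x2 = xx + pp + g
                y2 = yy + pp
            else:  # dashes in A: the gap consumes B bases
                x2 = xx + pp
                y2 = yy + pp + g
            in1 = (xx + pp <= la) & (yy + pp <= lb)
            in2 = (x2 + qq <= la) & (y2 + qq <= lb)
            okg = in1 & in2
            m1 = runs[np.clip(xx, 0, la), np.clip(yy, 0, lb), pp]
            m2 = runs[
                np.clip(x2, 0, la), np.clip(y2, 0, lb), np.clip(qq, 0, lmax)
            ]
            matches = np.where(okg, m1 + m2, -1)
            colsg = np.broadcast_to(pp + qq + g, matches.shape)
            qual = okg & (colsg >= min_len) & (matches >= thr * colsg)
            end_a = x2 + qq  # total A bases consumed, from xx
            end_b = y2 + qq
            anchoredg = qual & (yy == 0) & (end_a == la)
            firstg = m[np.clip(xx, 0, la - 1), np.clip(yy, 0, lb - 1)]
            lastg = m[
                np.clip(end_a - 1, 0, la - 1), np.clip(end_b - 1, 0, lb - 1)
            ]
            validg = qual & (anchoredg | (firstg & lastg))
            if anchored_only:
                validg = validg & anchoredg

            def coords(i, side=side, g=g):
                a0, b0 = int(i[0]), int(i[1])
                p, q = int(i[2]) + 1, int(i[3]) + 1
                alen = p + q + (g if side == "B" else 0)
                blen = p + q + (g if side == "A" else 0)
                return a0, alen, b0, blen, g

            harvest(matches, colsg, validg, anchoredg, coords)

    found.sort(key=HomeologyCandidate.sort_key)
    return found


def detect_microhomeology(
    junction: Junction,
    ref: str,
    window: int = SCAN_WINDOW,
    anchored_only: bool = False,
) -> Optional[HomeologyCandidate]:
    """Best qualifying microhomeology candidate between the flank windows.

    Returns ``None`` when no alignment passes the >=5 nt / >=70% identity /
    no->2-gap-run filter.  With ``anchored_only`` the search is restricted
    to fusion-anchored tracts (the signature-assignment mode).
    """
    wa = flank_a(ref, junction.end_a, window, junction.name)
    wb = flank_b(ref, junction.end_b, window, junction.name)
    cands = homeology_candidates(wa, wb, anchored_only=anchored_only)
    return cands[0] if cands else None


def classify_insert(
    junction: Junction,
    ref: str,
    search_radius: int = 1000,
) -> JunctionSignature:
    """Classify a non-empty junction insert as templated or untemplated.

    The insert is searched exactly, on both strands, within
    ``search_radius`` of each breakpoint end; any hit makes it templated,
    with the first (leftmost, A end before B end, forward before reverse)
    source interval recorded.
    """
    ins = junction.insert
    if not ins:
        raise ValueError("classify_insert requires a non-empty insert")
    chrom = junction.chrom
    rc = revcomp(ins)
    for end in (junction.end_a, junction.end_b):
        lo = max(0, end.pos - search_radius)
        hi = min(len(ref), end.pos + search_radius)
        region = ref[lo:hi]
        for query, strand in ((ins, "+"), (rc, "-")):
            hit = region.find(query)
            if hit >= 0:
                return JunctionSignature(
                    kind="templated_insert",
                    insert_length=len(ins),
                    insert_source=(chrom, lo + hit, lo + hit + len(ins), strand),
                )
    return JunctionSignature(kind="untemplated_insert", insert_length=len(ins))


def classify_junction(
    junction: Junction,
    ref: str,
    window: int = SCAN_WINDOW,
    insert_radius: int = 1000,
) -> JunctionSignature:
    """Full signature assignment for one junction.

    Precedence: a non-empty insert is classified templated/untemplated; a
    perfect fusion overlap 0 < k < 70 is microhomology (subsuming any
    imperfect candidate); otherwise a fusion-anchored microhomeology
    candidate is reported; otherwise the junction is blunt.
    """
    wa = flank_a(ref, junction.end_a, window, junction.name)
    wb = flank_b(ref, junction.end_b, window, junction.name)
    insert = junction.insert
    if junction.observed:
        _, insert = parse_observed(junction.observed, wa, wb)
    if insert:
        jx = Junction(junction.end_a, junction.end_b, insert=insert,
                      name=junction.name)
        return classify_insert(jx, ref, insert_radius)
    k = exact_overlap(wa, wb)
    if k >= MICROHOMOLOGY_CAP:
        return JunctionSignature(kind="none", homology_length=k,
                                 homology_identity=1.0, ambiguity=k + 1,
                                 over_cap=True)
    if k > 0:
        return JunctionSignature(kind="microhomology", homology_length=k,
                                 homology_identity=1.0, ambiguity=k + 1)
    cands = homeology_candidates(wa, wb, anchored_only=True)
    if cands:
        best = cands[0]
        return JunctionSignature(kind="microhomeology",
                                 homology_length=best.columns,
                                 homology_identity=best.identity,
                                 homeology=best)
    return JunctionSignature(kind="blunt")


def annotate_breakpoint(
    chrom: str,
    pos: int,
    repeats: Optional[Sequence[tuple[str, int, int, str]]] = None,
    timing: Optional[Sequence[tuple[str, int, float]]] = None,
    trio_sites: Optional[Sequence] = None,
    chromatin: Optional[Sequence[tuple[str, int, int, str]]] = None,
    repeat_window: int = 2000,
    snv_window: int = 100,
) -> BreakpointAnnotation:
    """Annotate one breakpoint against optional context tracks.

    ``repeats``/``chromatin`` are (chrom, start, end, class) intervals,
    ``timing`` is (chrom, position, value) for tested loci, and
    ``trio_sites`` are records with ``chrom``, ``pos``, parental genotypes
    and a ``child_gt``.  Absent tracks yield ``None`` fields, never zero.
    Timing is copied from the nearest tested locus (ties report all).
    """
    ann = BreakpointAnnotation()
    if repeats is not None:
        lo, hi = pos - repeat_window, pos + repeat_window
        ann.repeats = sorted(
            {cls for (c, s, e, cls) in repeats if c == chrom and s < hi and e > lo}
        )
    if timing is not None:
        loci = [(abs(p - pos), v) for (c, p, v) in timing if c == chrom]
        if loci:
            dmin = min(d for d, _ in loci)
            ann.replication_timing = [v for d, v in loci if d == dmin]
        else:
            ann.replication_timing = []
    if trio_sites is not None:
        count = 0
        for site in trio_sites:
            if site.chrom != chrom:
                continue
            if not (pos - snv_window <= site.pos <= pos + snv_window):
                continue
            child = set(getattr(site, "child_gt", ()))
            parents = set(site.father_gt) | set(site.mother_gt)
            if child - parents:
                count += 1
        ann.de_novo_snvs = count
    if chromatin is not None:
        ann.chromatin_marks = sorted(
            {cls for (c, s, e, cls) in chromatin if c == chrom and s <= pos < e}
        )
    return ann
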