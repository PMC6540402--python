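"""Derivative-chromosome layouts.

A layout is an ordered list of ``(start, end, orient)`` reference segments
(0-based half-open, orient ``+``/``-``) whose concatenation — reverse
complementing ``-`` segments — spells the derivative chromosome.  Adjacent
segments that are reference-contiguous (``+``/``+`` with ``X.end ==
Y.start``) carry no junction; every other adjacency is exactly one fusion
junction.
"""

from __future__ import annotations

from .models import BreakpointEnd, Junction

Segment = tuple[int, int, str]


def segment_exit_end(seg: Segment, chrom: str) -> BreakpointEnd:
    """Breakend where the derivative leaves a segment (the A end)."""
    s, e, o = seg
    return BreakpointEnd(chrom, e, "left") if o == "+" else BreakpointEnd(chrom, s, "right")


def segment_entry_end(seg: Segment, chrom: str) -> BreakpointEnd:
    """Breakend where the derivative enters a segment (the B end)."""
    s, e, o = seg
    return BreakpointEnd(chrom, s, "right") if o == "+" else BreakpointEnd(chrom, e, "left")


def is_reference_adjacency(x: Segment, y: Segment) -> bool:
    """True when the two segments spell contiguous (possibly reverse
    complemented) reference sequence, leaving no discoverable junction."""
    if x[2] == "+" and y[2] == "+" and x[1] == y[0]:
        return True
    return x[2] == "-" and y[2] == "-" and x[0] == y[1]


def junctions_from_layout(layout: list[Segment], chrom: str) -> list[tuple[int, Junction]]:
    """Fusion junctions implied by a layout.

    Returns ``(adjacency_index, Junction)`` pairs, where the adjacency
    index ``i`` sits between ``layout[i]`` and ``layout[i+1]``.
    """
    out = []
    for i in range(len(layout) - 1):
        x, y = layout[i], layout[i + 1]
        if is_reference_adjacency(x, y):
            continue
        out.append(
            (
                i,
                Junction(
                    segment_exit_end(x, chrom),
                    segment_entry_end(y, chrom),
                    name=f"{chrom}_j{len(out)}",
                ),
            )
        )
    return out


def trim_layout(layout: list[Segment], homologies: dict[int, int]) -> list[Segment]:
    """Physical layout after merging each junction's microhomology tract.

    ``homologies`` maps adjacency index to homology length k; the entered
    segment is trimmed by k at its entry edge, because a k-nt
    microhomology-mediated fusion carries the shared tract once.
    """
    phys = [tuple(seg) for seg in layout]
    for idx, k in homologies.items():
        if k <= 0:
            continue
        s, e, o = phys[idx + 1]
        phys[idx + 1] = (s + k, e, o) if o == "+" else (s, e - k, o)
    return phys


def layout_length(layout: list[Segment]) -> int:
    return sum(e - s for s, e, _ in layout)


def coverage_segments(
    layout: list[Segment], chrom_len: int
) -> list[tuple[int, int, int]]:
    """Per-haplotype copy-number segments implied by a layout.

    Returns maximal ``(start, end, copies)`` runs over [0, chrom_len).
    """
    cuts = {0, chrom_len}
    for s, e, _ in layout:
        cuts.add(s)
        cuts.add(e)
    bounds = sorted(cuts)
    out = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        c = sum(1 for s, e, _ in layout if s <= a and b <= e)
        if out and out[-1][2] == c and out[-1][1] == a:
            out[-1] = (out[-1][0], b, c)
        else:
            out.append((a, b, c))
    return out


def copies_at(layout: list[Segment], pos: int) -> int:
    return sum(1 for s, e, _ in layout if s <= pos < e)
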