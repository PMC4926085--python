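"""Sanger run-off sequencing simulation and cut-site inference.

Run-off sequencing locates a scission by sequencing across it: the
polymerase copies the template strand until it falls off at the break and
then appends one untemplated adenine (Taq terminal-transferase activity).
A read on the top strand therefore terminates at the base paired with a
*bottom*-strand scission and ends in an extra A; a bottom-strand read of a
top-strand scission shows the same extra A, which displays as an extra T
in the top-strand frame.  Reads are modeled as error-free strings;
chromatogram parsing is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .digest import CutEvent
from .seqmodel import MethylatedDuplex

__all__ = ["RunoffRead", "CutCall", "simulate_runoff", "infer_cut", "compose_cut_notation"]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class RunoffRead:
    """A run-off sequencing read.

    ``primer_start`` is the top coordinate of the read's first base;
    ``bases`` are in the read strand's own 5'->3' sense.
    """

    primer_start: int
    read_strand: str  # 'top' | 'bottom'
    bases: str
    has_terminal_untemplated_A: bool
    partial_sites_downstream: int = 0  # sub-threshold sites skipped over


def _template_breaks(events: Iterable[CutEvent], read_strand: str) -> list[int]:
    """Scission coordinates on the template (opposite) strand."""
    breaks = []
    for e in events:
        if read_strand == "top":
            if e.kind in ("ds", "nick_bottom") and e.bottom_cut is not None:
                breaks.append(e.bottom_cut)
        else:
            if e.kind in ("ds", "nick_top") and e.top_cut is not None:
                breaks.append(e.top_cut)
    return sorted(set(breaks))


def simulate_runoff(
    d: MethylatedDuplex,
    events: Iterable[CutEvent],
    primer_start: int,
    read_strand: str = "top",
) -> RunoffRead:
    """Simulate one run-off read across the nearest downstream scission.

    The template of a read on strand S is the opposite strand, so the read
    terminates at the nearest scission on that opposite strand and gains
    one untemplated A.  With no scission downstream the read runs to the
    template end (linear molecules) with no extra base.
    """
    if read_strand not in ("top", "bottom"):
        raise ValueError("read_strand must be 'top' or 'bottom'")
    L = len(d.seq)
    events = list(events)
    breaks = _template_breaks(events, read_strand)
    if read_strand == "top":
        down = [b for b in breaks if b > primer_start]
        if d.circular and not down and breaks:
            down = [breaks[0] + L]
        if not down:
            if d.circular:
                raise ValueError("no scission downstream of the primer on a circle")
            return RunoffRead(primer_start, "top", d.seq[primer_start:], False)
        b = min(down)
        bases = "".join(d.base(i, "top") for i in range(primer_start, b)) + "A"
        return RunoffRead(primer_start, "top", bases, True)
    else:
        down = [t for t in breaks if t <= primer_start]
        if d.circular and not down and breaks:
            down = [breaks[-1] - L]
        if not down:
            if d.circular:
                raise ValueError("no scission downstream of the primer on a circle")
            bases = "".join(d.base(i, "bottom") for i in range(primer_start, -1, -1))
            return RunoffRead(primer_start, "bottom", bases, False)
        t = max(down)
        bases = "".join(d.base(i, "bottom") for i in range(primer_start, t - 1, -1)) + "A"
        return RunoffRead(primer_start, "bottom", bases, True)


@dataclass(frozen=True)
class CutCall:
    """An inferred scission: strand, top coordinate, ambiguity flag."""

    strand: Optional[str]  # scissile strand ('top'/'bottom'); None = no cut
    coordinate: Optional[int]  # break between coordinate-1 and coordinate
    ambiguous: bool = False


def infer_cut(read: RunoffRead, d: MethylatedDuplex) -> CutCall:
    """Invert :func:`simulate_runoff`: locate the scission a read reports.

    The read must match the reference from its primer.  One terminal A is
    treated as the untemplated extra base; if the reference base at the
    read's last position is itself A, the call is flagged ambiguous (the
    terminal A could be templated and the break one base further).
    """
    L = len(d.seq)
    n = len(read.bases)
    if n == 0:
        raise ValueError("empty read")

    def ref_base(k: int) -> str:
        if read.read_strand == "top":
            i = read.primer_start + k
        else:
            i = read.primer_start - k
        if d.circular:
            i %= L
        elif not 0 <= i < L:
            return ""
        return d.base(i, read.read_strand)

    m = 0
    while m < n and read.bases[m] == ref_base(m):
        m += 1

    template = "bottom" if read.read_strand == "top" else "top"

    def coord_of_break(k: int) -> int:
        # read terminated after copying read-frame position k-1
        if read.read_strand == "top":
            c = read.primer_start + k
        else:
            c = read.primer_start - k + 1
        return c % L if d.circular else c

    if m == n:
        at_end = ref_base(n) == ""
        if at_end:
            return CutCall(None, None, False)
        if read.bases[-1] == "A":
            # terminal A matches the reference A: cut here or one further
            return CutCall(template, coord_of_break(n - 1), True)
        return CutCall(template, coord_of_break(n), True)
    if m == n - 1 and read.bases[-1] == "A":
        return CutCall(template, coord_of_break(n - 1), False)
    raise ValueError(
        f"read does not match reference at primer {read.primer_start} "
        f"(first mismatch at read position {m})"
    )


def compose_cut_notation(
    pattern: str,
    top_cut: int,
    bottom_cut: Optional[int],
    site_start: int,
) -> str:
    """Canonical arrow notation for a site's scissions, e.g. ``GC/NGC``.

    ``top_cut``/``bottom_cut`` are top-frame scission coordinates within
    the site window starting at ``site_start``; the down-arrow marks the
    top-strand cut.  Appends the overhang classification (n-nt 5'/3'
    extension or blunt).  A single known scission yields one-sided nick
    notation.
    """
    n = len(pattern)
    off = top_cut - site_start
    if not 0 <= off <= n:
        raise ValueError(f"top scission {top_cut} outside site window [{site_start}, {site_start + n}]")
    marked = pattern[:off] + "↓" + pattern[off:]
    if bottom_cut is None:
        return f"{marked} / top-strand nick"
    if not site_start <= bottom_cut <= site_start + n:
        raise ValueError("bottom scission outside the site window")
    overhang = bottom_cut - top_cut
    if overhang > 0:
        kind = f"{overhang}-nt 5' overhang"
    elif overhang < 0:
        kind = f"{-overhang}-nt 3' overhang"
    else:
        kind = "blunt"
    return f"{marked} / {kind}"
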