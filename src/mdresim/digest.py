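"""Site scanning, cut/nick event generation, fragmentation and gel readouts.

A digestion run scans a :class:`~mdresim.seqmodel.MethylatedDuplex` for
every recognition-site occurrence of the requested enzymes, evaluates the
methylation requirement at each site, and turns qualifying sites into
double-strand cut events (which fragment the molecule) or nick events
(which do not).  Readouts mirror the two gel modes used to characterize
these enzymes: native gels separate double-stranded fragments, denaturing
gels separate single strands and therefore also reveal nicks.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

from .enzymes import (
    TIER_ORDER,
    EnzymeSpec,
    evaluate_site,
    get_enzyme,
)
from .seqmodel import (
    MethylatedDuplex,
    ModType,
    match_iupac,
    pattern_is_self_complementary,
)

__all__ = [
    "CutEvent",
    "Fragment",
    "FragmentEnd",
    "StrandLengths",
    "TargetingOligos",
    "find_sites",
    "digest",
    "denatured_strand_lengths",
    "virtual_gel",
    "design_targeting_oligos",
    "write_events_bed",
    "write_fragments_tsv",
]


@dataclass(frozen=True)
class CutEvent:
    """One enzymatic scission event at a recognition site.

    ``top_cut``/``bottom_cut`` are top-strand coordinates: the backbone is
    broken between ``cut-1`` and ``cut`` on the respective strand.  For
    double-strand events ``bottom_cut - top_cut`` equals the geometry's
    overhang (positive: 5' extension).
    """

    enzyme: str
    site_start: int
    site_strand: str          # strand the recognition pattern matched on
    kind: str                 # 'ds' | 'nick_top' | 'nick_bottom'
    tier: str
    top_cut: Optional[int] = None
    bottom_cut: Optional[int] = None
    nick_intermediate: Optional[str] = None
    star: bool = False
    pattern: str = ""


@dataclass(frozen=True)
class FragmentEnd:
    """Chemistry of one fragment end: overhang length, sign, and sequence."""

    overhang: int      # >0: 5' extension, 0: blunt, <0: 3' extension
    seq: str = ""      # single-stranded extension, 5'->3' on its own strand
    terminal: bool = False  # pre-existing molecule end, not an enzymatic cut


@dataclass(frozen=True)
class Fragment:
    """A duplex piece produced by double-strand cuts.

    ``start``/``end`` are the parent's top-strand cut coordinates bounding
    the fragment's top strand; ``length = end - start`` (mod parent length
    when the fragment wraps the origin of a circular parent).
    """

    start: int
    end: int
    length: int
    wraps: bool
    duplex: MethylatedDuplex
    left_end: FragmentEnd
    right_end: FragmentEnd
    carries_label: bool = False
    conflict: bool = False


def find_sites(
    d: MethylatedDuplex, pattern: str, collapse_palindromic: bool = True
) -> list[tuple[int, str]]:
    """All recognition-site occurrences on both strands.

    Returns (site_start, strand) with ``site_start`` the top coordinate of
    the window's leftmost base.  Overlapping occurrences are all reported;
    circular topology wraps.  For self-complementary patterns each duplex
    locus matches on both strands at the same window and is reported once
    (strand 'top') unless ``collapse_palindromic`` is false.
    """
    L = len(d.seq)
    n = len(pattern)
    if n == 0 or n > L:
        return []
    starts = range(L) if d.circular else range(L - n + 1)
    palindromic = pattern_is_self_complementary(pattern)
    out = []
    for s in starts:
        if match_iupac(pattern, d, s, "top"):
            out.append((s, "top"))
        if match_iupac(pattern, d, s, "bottom"):
            if not (palindromic and collapse_palindromic):
                out.append((s, "bottom"))
            elif not match_iupac(pattern, d, s, "top"):
                out.append((s, "bottom"))  # unreachable for true palindromes
    return out


def _event_for_site(
    d: MethylatedDuplex,
    spec: EnzymeSpec,
    start: int,
    strand: str,
    pattern: str,
    geometry,
    star_pattern: bool,
    star: bool,
    w_bump: bool,
) -> Optional[CutEvent]:
    action = evaluate_site(d, start, spec, star=star, strand=strand, w_bump=w_bump)
    if action.action == "NONE":
        return None
    L = len(d.seq)
    n = len(pattern)
    if strand == "top":
        tc = start + geometry.top_offset
        bc = start + n - geometry.bottom_offset
    else:
        tc = start + geometry.bottom_offset
        bc = start + n - geometry.top_offset
    if d.circular:
        tc, bc = tc % L, bc % L
    if action.action == "CUT":
        return CutEvent(spec.name, start, strand, "ds", action.tier,
                        top_cut=tc, bottom_cut=bc,
                        nick_intermediate=action.nick_intermediate,
                        star=star_pattern, pattern=pattern)
    kind = "nick_top" if action.action == "NICK_TOP" else "nick_bottom"
    cut = tc if kind == "nick_top" else bc
    return CutEvent(spec.name, start, strand, kind, action.tier,
                    top_cut=cut if kind == "nick_top" else None,
                    bottom_cut=cut if kind == "nick_bottom" else None,
                    nick_intermediate=action.nick_intermediate,
                    star=star_pattern, pattern=pattern)


def digest(
    d: MethylatedDuplex,
    enzymes: Sequence[Union[str, EnzymeSpec]],
    tier_threshold: str = "moderate",
    star: bool = False,
    w_bump: bool = False,
) -> tuple[list[CutEvent], list[Fragment]]:
    """Digest a substrate with one or more registry enzymes.

    Every matching site is evaluated and recorded as a :class:`CutEvent`
    (including sub-threshold "partial" events, distinguishable by tier).
    Only double-strand events at tier >= ``tier_threshold`` fragment the
    molecule; nicks never fragment a duplex in native mode.  Star/relaxed
    sites are scanned only when ``star`` is true.
    """
    if TIER_ORDER.get(tier_threshold) is None:
        raise ValueError(f"unknown tier threshold {tier_threshold!r}")
    specs = [e if isinstance(e, EnzymeSpec) else get_enzyme(e) for e in enzymes]
    events: list[CutEvent] = []
    seen = set()
    for spec in specs:
        models = [(spec.recognition, spec.geometry, False)]
        if star:
            models += [(s.recognition, s.geometry, True) for s in spec.star_specs]
        for pattern, geometry, is_star in models:
            for s, strand in find_sites(d, pattern):
                ev = _event_for_site(d, spec, s, strand, pattern, geometry,
                                     is_star, star, w_bump)
                if ev is None:
                    continue
                key = (ev.enzyme, ev.kind, ev.top_cut, ev.bottom_cut)
                if key in seen:
                    continue
                seen.add(key)
                events.append(ev)
    events.sort(key=lambda e: (e.site_start, e.top_cut if e.top_cut is not None else -1,
                               e.enzyme, e.kind))
    fragments = _fragment(d, events, tier_threshold)
    return events, fragments


def _fragment(
    d: MethylatedDuplex, events: Iterable[CutEvent], tier_threshold: str
) -> list[Fragment]:
    L = len(d.seq)
    cuts = sorted({
        (e.top_cut, e.bottom_cut)
        for e in events
        if e.kind == "ds" and TIER_ORDER[e.tier] >= TIER_ORDER[tier_threshold]
    })
    # coincident top-strand scissions from overlapping sites merge
    merged: list[tuple[int, int]] = []
    for tc, bc in cuts:
        if merged and merged[-1][0] == tc:
            continue
        merged.append((tc, bc))
    cuts = merged

    label = d.label

    def end_at(tc_left, bc_left, tc_right, bc_right, left_term, right_term):
        left = FragmentEnd(0, terminal=True) if left_term else \
            FragmentEnd(bc_left - tc_left, _span_seq(d, tc_left, bc_left, "top"))
        right = FragmentEnd(0, terminal=True) if right_term else \
            FragmentEnd(bc_right - tc_right, _span_seq(d, tc_right, bc_right, "bottom"))
        return left, right

    frags: list[Fragment] = []
    if not cuts:
        le = FragmentEnd(0, terminal=True)
        frags.append(Fragment(0, L, L, False, d, le, le,
                              carries_label=label is not None))
        return frags

    if d.circular:
        boundaries = cuts
        for i, (tc, bc) in enumerate(boundaries):
            tc2, bc2 = boundaries[(i + 1) % len(boundaries)]
            length = (tc2 - tc) % L or L
            wraps = tc2 <= tc
            dup = d.slice(tc, tc2 if tc2 != tc else tc + L)
            left, right = end_at(tc, bc, tc2, bc2, False, False)
            frags.append(Fragment(tc, tc2, length, wraps, dup, left, right,
                                  carries_label=False,
                                  conflict=_conflicts(L, tc, bc, tc2, bc2, True)))
    else:
        boundaries = [(0, 0)] + cuts + [(L, L)]
        for i in range(len(boundaries) - 1):
            tc, bc = boundaries[i]
            tc2, bc2 = boundaries[i + 1]
            dup = d.slice(tc, tc2)
            left, right = end_at(tc, bc, tc2, bc2, i == 0, i == len(boundaries) - 2)
            carries = _fragment_has_label(label, tc, tc2, L)
            frags.append(Fragment(tc, tc2, tc2 - tc, False, dup, left, right,
                                  carries_label=carries,
                                  conflict=_conflicts(L, tc, bc, tc2, bc2, False)))
    return frags


def _span_seq(d: MethylatedDuplex, a: int, b: int, strand: str) -> str:
    """Single-stranded extension between top coords a..b on one strand, 5'->3'."""
    L = len(d.seq)
    if a == b:
        return ""
    lo, hi = (a, b) if a < b else (b, a)
    if d.circular and hi - lo > L // 2:  # wrapped span
        idx = list(range(hi, L)) + list(range(0, lo))
    else:
        idx = list(range(lo, hi))
    bases = [d.base(i, strand) for i in idx]
    return "".join(bases) if strand == "top" else "".join(reversed(bases))


def _conflicts(L, tc, bc, tc2, bc2, circular) -> bool:
    """Neighboring staggered cuts closer than the overhang leave a degenerate end."""
    if circular:
        return ((bc - tc) % L) > ((tc2 - tc) % L or L)
    return bc > tc2 or bc2 < tc


def _fragment_has_label(label, start, end, L) -> bool:
    if label is None:
        return False
    if label.strand == "top":
        coord = 0 if label.end == "5prime" else L
    else:
        coord = L if label.end == "5prime" else 0
    return (start == 0 and coord == 0) or (end == L and coord == L)


@dataclass
class StrandLengths:
    """Single-strand length multisets after denaturation."""

    top: list[int] = field(default_factory=list)
    bottom: list[int] = field(default_factory=list)
    labeled_length: Optional[int] = None  # length of the label-carrying strand


def denatured_strand_lengths(
    d: MethylatedDuplex,
    events: Iterable[CutEvent],
    tier_threshold: str = "moderate",
) -> StrandLengths:
    """Single-strand lengths after splitting at ds cuts *and* nicks.

    This is the denaturing-gel readout: a nicked strand runs as two pieces
    even though the native duplex did not fragment.
    """
    L = len(d.seq)
    top_splits, bottom_splits = set(), set()
    for e in events:
        if TIER_ORDER[e.tier] < TIER_ORDER[tier_threshold]:
            continue
        if e.kind == "ds":
            top_splits.add(e.top_cut % L)
            bottom_splits.add(e.bottom_cut % L)
        elif e.kind == "nick_top":
            top_splits.add(e.top_cut % L)
        elif e.kind == "nick_bottom":
            bottom_splits.add(e.bottom_cut % L)
    result = StrandLengths()
    for strand, splits in (("top", top_splits), ("bottom", bottom_splits)):
        pieces = _strand_pieces(L, sorted(splits), d.circular)
        if strand == "top":
            result.top = pieces
        else:
            result.bottom = pieces
    if d.label is not None:
        splits = sorted(top_splits if d.label.strand == "top" else bottom_splits)
        result.labeled_length = _labeled_piece(L, splits, d)
    return result


def _strand_pieces(L: int, splits: list[int], circular: bool) -> list[int]:
    if not splits:
        return [L]
    if circular:
        return [(splits[(i + 1) % len(splits)] - s) % L or L
                for i, s in enumerate(splits)]
    bounds = [0] + splits + [L]
    return [bounds[i + 1] - bounds[i] for i in range(len(bounds) - 1)
            if bounds[i + 1] > bounds[i]]


def _labeled_piece(L: int, splits: list[int], d: MethylatedDuplex) -> Optional[int]:
    if d.circular:
        return None
    lab = d.label
    if not splits:
        return L
    if lab.strand == "top":
        return splits[0] if lab.end == "5prime" else L - splits[-1]
    # bottom strand: its 5' end is at top coordinate L
    return L - splits[-1] if lab.end == "5prime" else splits[0]


_LADDER = [1000, 700, 500, 400, 300, 200, 150, 100, 75, 50, 40, 34, 30, 25, 20, 15, 10, 5]


def virtual_gel(lanes: dict[str, Iterable[int]], mode: str = "native") -> str:
    """Plain-text gel rendering: one column per lane plus a size ladder.

    Migration rank is a deterministic monotone function of length (larger
    pieces stay near the top).  Co-migrating pieces share a row; band
    intensity marks multiplicity.
    """
    lane_data = {name: Counter(v) for name, v in lanes.items()}
    sizes = sorted({s for c in lane_data.values() for s in c} | set(_LADDER),
                   reverse=True)
    title = "virtual gel (%s)" % mode
    names = list(lane_data)
    width = max([6] + [len(n) for n in names]) + 2
    head = "size".rjust(6) + " |" + "".join(n.center(width) for n in ["ladder"] + names)
    rows = [title, head, "-" * len(head)]
    for s in sizes:
        cells = ["====".center(width) if s in _LADDER else " " * width]
        for n in names:
            k = lane_data[n].get(s, 0)
            band = {0: "", 1: "▬▬▬▬", 2: "▬▬▬▬ x2"}.get(k, f"▬▬▬▬ x{k}")
            cells.append(band.center(width))
        if any(c.strip() for c in cells):
            rows.append(f"{s:>6} |" + "".join(cells))
    return "\n".join(rows) + "\n"


@dataclass(frozen=True)
class TargetingOligos:
    """Modified oligo pair for directing a Group I enzyme to one GCNGC site.

    Annealing one 18-24 nt oligo carrying the site's two 5mC to a
    denatured/unmodified target creates a hemi-methylated site, which a
    hemi-competent enzyme converts to a strand-specific scission on the
    strand complementary to the oligo; supplying both oligos licenses a
    double-strand cut.
    """

    site_start: int
    top_oligo: str
    top_oligo_mods: tuple[int, ...]      # 0-based positions within the oligo
    bottom_oligo: str
    bottom_oligo_mods: tuple[int, ...]
    single_oligo_action: str             # predicted action on the hemi assembly
    both_oligos_action: str              # predicted action with both oligos


def design_targeting_oligos(
    d: MethylatedDuplex,
    site_start: int,
    flank: int,
    enzyme: Union[str, EnzymeSpec] = "BisI",
) -> TargetingOligos:
    """Design the 5mC-bearing oligo pair that targets one GCNGC site."""
    spec = enzyme if isinstance(enzyme, EnzymeSpec) else get_enzyme(enzyme)
    if spec.group != "I":
        raise ValueError(f"{spec.name} is not a Group I (hemi-competent) enzyme")
    pattern = spec.recognition
    n = len(pattern)
    if not match_iupac(pattern, d, site_start, "top"):
        raise ValueError(f"no {pattern} site at {site_start}")
    length = n + 2 * flank
    if not 18 <= length <= 24:
        raise ValueError(f"oligo length {length} outside the 18-24 nt window")
    start, end = site_start - flank, site_start + n + flank
    L = len(d.seq)
    if not d.circular and (start < 0 or end > L):
        raise ValueError("flank runs off the end of a linear target")
    window = d.slice(start, end)
    site_c = [flank + k for k, c in enumerate(pattern) if c == "C"]
    site_g = [flank + k for k, c in enumerate(pattern) if c == "G"]
    top_oligo = window.seq
    from .seqmodel import reverse_complement
    bottom_oligo = reverse_complement(window).seq
    bottom_mods = tuple(sorted(length - 1 - i for i in site_g))

    hemi = window.with_mods(top=[(i, ModType.M5C) for i in site_c])
    act1 = evaluate_site(hemi, flank, spec)
    if act1.action == "NONE" or TIER_ORDER[act1.tier] < TIER_ORDER["moderate"]:
        raise ValueError(f"{spec.name} does not act on the hemi-methylated assembly")
    full = hemi.with_mods(bottom=[(i, ModType.M5C) for i in site_g])
    act2 = evaluate_site(full, flank, spec)
    return TargetingOligos(
        site_start=site_start,
        top_oligo=top_oligo,
        top_oligo_mods=tuple(site_c),
        bottom_oligo=bottom_oligo,
        bottom_oligo_mods=bottom_mods,
        single_oligo_action=f"{act1.action}:{act1.tier}",
        both_oligos_action=f"{act2.action}:{act2.tier}",
    )


def write_events_bed(events: Iterable[CutEvent], dest, seq_name: str = "duplex") -> None:
    """Cut/nick events as BED6 (0-based half-open); strand column encodes
    the scissile strand for nicks ('+'/'-') and '.' for ds cuts."""
    close = False
    if isinstance(dest, (str, bytes)):
        dest = open(dest, "w")
        close = True
    try:
        for e in events:
            strand = {"ds": ".", "nick_top": "+", "nick_bottom": "-"}[e.kind]
            pos = e.top_cut if e.top_cut is not None else e.bottom_cut
            name = f"{e.enzyme}|{e.kind}|{e.tier}" + ("|star" if e.star else "")
            dest.write(f"{seq_name}\t{pos}\t{pos + 1}\t{name}\t0\t{strand}\n")
    finally:
        if close:
            dest.close()


def write_fragments_tsv(fragments: Iterable[Fragment], dest) -> None:
    close = False
    if isinstance(dest, (str, bytes)):
        dest = open(dest, "w")
        close = True
    try:
        dest.write("start\tend\tlength\tleft_end\tright_end\tlabel\n")
        for f in fragments:
            le = "terminus" if f.left_end.terminal else f"{f.left_end.overhang:+d}:{f.left_end.seq}"
            re_ = "terminus" if f.right_end.terminal else f"{f.right_end.overhang:+d}:{f.right_end.seq}"
            dest.write(f"{f.start}\t{f.end}\t{f.length}\t{le}\t{re_}\t{int(f.carries_label)}\n")
    finally:
        if close:
            dest.close()
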