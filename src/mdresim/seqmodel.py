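"""Core data model: duplex DNA with per-strand cytosine-modification tracks.

A :class:`MethylatedDuplex` is the universal substrate type of this package:
an unambiguous double-stranded DNA sequence (linear or circular) together
with the positions of modified cytosines on each strand.  Both strands are
addressed in a single coordinate frame — 0-based top-strand coordinates —
so a bottom-strand modification is stored at the top coordinate of the
paired base (which is a ``G`` on the top strand).

Supported modifications are 5-methylcytosine (m5C) and
5-hydroxymethylcytosine (hm5C), the two cytosine C5 variants recognized by
modification-dependent restriction enzymes of the BisI family.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "ModType",
    "StrandLabel",
    "MethylatedDuplex",
    "ModTrackRecord",
    "load_duplex",
    "read_track",
    "write_track",
    "write_fasta",
    "reverse_complement",
    "fully_modify",
    "match_iupac",
    "IUPAC_CLASSES",
    "iupac_class",
    "pattern_is_self_complementary",
    "revcomp_pattern",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Expansion of every IUPAC nucleotide code into its base class.
IUPAC_CLASSES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_CLASS_TO_CODE = {v: k for k, v in IUPAC_CLASSES.items()}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class ModType(enum.Enum):
    """Cytosine C5 modification."""

    M5C = "m5C"
    HM5C = "hm5C"

    @classmethod
    def parse(cls, text: str) -> "ModType":
        for m in cls:
            if m.value.lower() == text.strip().lower():
                return m
        raise ValueError(f"unknown modification code {text!r} (expected m5C or hm5C)")


@dataclass(frozen=True)
class StrandLabel:
    """A covalent end label, e.g. a 5'-FAM fluorophore on the top strand."""

    strand: str  # 'top' | 'bottom'
    end: str     # '5prime' | '3prime'
    tag: str = "FAM"


@dataclass(frozen=True)
class MethylatedDuplex:
    """Double-stranded DNA with per-strand cytosine-modification tracks.

    ``top_mods`` / ``bottom_mods`` map 0-based top-strand coordinates to a
    :class:`ModType`.  A top modification must sit on a top-strand ``C``; a
    bottom modification must sit opposite a top-strand ``G``.
    """

    seq: str
    topology: str = "linear"  # 'linear' | 'circular'
    top_mods: dict[int, ModType] = field(default_factory=dict)
    bottom_mods: dict[int, ModType] = field(default_factory=dict)
    label: Optional[StrandLabel] = None
    name: str = "duplex"

    def __post_init__(self) -> None:
        seq = self.seq.upper()
        object.__setattr__(self, "seq", seq)
        bad = set(seq) - set("ACGT")
        if bad:
            raise ValueError(
                f"substrate sequence contains non-ACGT characters {sorted(bad)}; "
                "IUPAC ambiguity codes are allowed only in patterns"
            )
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"topology must be 'linear' or 'circular', got {self.topology!r}")
        for i, mod in self.top_mods.items():
            if not 0 <= i < len(seq):
                raise ValueError(f"top modification at {i} out of range [0, {len(seq)})")
            if seq[i] != "C":
                raise ValueError(f"modification on non-cytosine: top strand position {i} is {seq[i]}")
            if not isinstance(mod, ModType):
                raise TypeError(f"modification at top {i} is not a ModType")
        for i, mod in self.bottom_mods.items():
            if not 0 <= i < len(seq):
                raise ValueError(f"bottom modification at {i} out of range [0, {len(seq)})")
            if seq[i] != "G":
                raise ValueError(
                    f"modification on non-cytosine: bottom strand base paired to top "
                    f"position {i} ({seq[i]}) is not C"
                )
            if not isinstance(mod, ModType):
                raise TypeError(f"modification at bottom {i} is not a ModType")
        if self.label is not None:
            if self.label.strand not in ("top", "bottom"):
                raise ValueError("label strand must be 'top' or 'bottom'")
            if self.label.end not in ("5prime", "3prime"):
                raise ValueError("label end must be '5prime' or '3prime'")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def circular(self) -> bool:
        return self.topology == "circular"

    def base(self, i: int, strand: str = "top") -> str:
        """Base at top coordinate ``i`` read on ``strand`` (wraps if circular)."""
        i = i % len(self.seq) if self.circular else i
        b = self.seq[i]
        return b if strand == "top" else b.translate(_COMPLEMENT)

    def strand_seq(self, strand: str) -> str:
        """The 5'->3' sequence of one strand."""
        if strand == "top":
            return self.seq
        return self.seq.translate(_COMPLEMENT)[::-1]

    def modification_at(self, i: int, strand: str) -> Optional[ModType]:
        i = i % len(self.seq) if self.circular else i
        track = self.top_mods if strand == "top" else self.bottom_mods
        return track.get(i)

    def with_mods(
        self,
        top: Iterable[tuple[int, ModType]] = (),
        bottom: Iterable[tuple[int, ModType]] = (),
    ) -> "MethylatedDuplex":
        """Return a copy with additional modifications (validated)."""
        return replace(
            self,
            top_mods={**self.top_mods, **dict(top)},
            bottom_mods={**self.bottom_mods, **dict(bottom)},
        )

    def slice(self, start: int, end: int, name: Optional[str] = None) -> "MethylatedDuplex":
        """Linear sub-duplex over top coordinates [start, end).

        On a circular molecule ``end`` may be <= ``start``, in which case the
        slice wraps through the origin.  Modification tracks are carried over
        and re-based; the end label is kept only if its anchoring end survives.
        """
        L = len(self.seq)
        if self.circular:
            start %= L
            end = end % L or L if end != start else end
            if end > start:
                idx = range(start, end)
            else:
                idx = list(range(start, L)) + list(range(0, end))
        else:
            if not (0 <= start <= end <= L):
                raise ValueError(f"slice [{start}, {end}) out of range for length {L}")
            idx = range(start, end)
        pos_map = {old: new for new, old in enumerate(idx)}
        seq = "".join(self.seq[i] for i in idx)
        label = None
        if self.label is not None and not self.circular:
            keep = (self.label.end == "5prime" and self.label.strand == "top" and start == 0) or \
                   (self.label.end == "3prime" and self.label.strand == "top" and end == L) or \
                   (self.label.end == "5prime" and self.label.strand == "bottom" and end == L) or \
                   (self.label.end == "3prime" and self.label.strand == "bottom" and start == 0)
            if keep:
                label = self.label
        return MethylatedDuplex(
            seq=seq,
            topology="linear",
            top_mods={pos_map[i]: m for i, m in self.top_mods.items() if i in pos_map},
            bottom_mods={pos_map[i]: m for i, m in self.bottom_mods.items() if i in pos_map},
            label=label,
            name=name or self.name,
        )


@dataclass(frozen=True)
class ModTrackRecord:
    """One line of a BED6-like modification track: a single modified base."""

    seq_name: str
    start: int
    end: int
    strand: str  # '+' -> top strand, '-' -> bottom strand
    mod: ModType

    def __post_init__(self) -> None:
        if self.end != self.start + 1:
            raise ValueError(f"track records are single-base: end must equal start+1, got [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


def read_track(source) -> list[ModTrackRecord]:
    """Parse a 6-column BED-like TSV: seq_name, start, end, mod, score, strand."""
    records = []
    close = False
    if isinstance(source, (str, bytes)):
        source = open(source)
        close = True
    try:
        for ln, line in enumerate(source, 1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"track line {ln}: expected 6 tab-separated columns, got {len(parts)}")
            name, start, end, mod, _score, strand = parts[:6]
            records.append(ModTrackRecord(name, int(start), int(end), strand, ModType.parse(mod)))
    finally:
        if close:
            source.close()
    return records


def write_track(d: MethylatedDuplex, dest) -> None:
    """Write the duplex's modification tracks as a 6-column BED-like TSV."""
    close = False
    if isinstance(dest, (str, bytes)):
        dest = open(dest, "w")
        close = True
    try:
        for strand_sym, track in (("+", d.top_mods), ("-", d.bottom_mods)):
            for i in sorted(track):
                dest.write(f"{d.name}\t{i}\t{i + 1}\t{track[i].value}\t0\t{strand_sym}\n")
    finally:
        if close:
            dest.close()


def write_fasta(d: MethylatedDuplex, dest) -> None:
    close = False
    if isinstance(dest, (str, bytes)):
        dest = open(dest, "w")
        close = True
    try:
        dest.write(f">{d.name}\n")
        for i in range(0, len(d.seq), 70):
            dest.write(d.seq[i : i + 70] + "\n")
    finally:
        if close:
            dest.close()


def load_duplex(fasta_source, track_source=None, topology: str = "linear") -> MethylatedDuplex:
    """Build a validated :class:`MethylatedDuplex` from FASTA + track files.

    The FASTA must contain exactly one record; every track record must
    reference that record's name.  Invariant violations (out-of-range
    positions, modification on a non-cytosine) raise ``ValueError`` with the
    offending position.
    """
    records = list(SeqIO.parse(fasta_source, "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record, found {len(records)}")
    rec = records[0]
    top: dict[int, ModType] = {}
    bottom: dict[int, ModType] = {}
    if track_source is not None:
        for tr in read_track(track_source):
            if tr.seq_name != rec.id:
                raise ValueError(f"track record names {tr.seq_name!r} but FASTA record is {rec.id!r}")
            target = top if tr.strand == "+" else bottom
            if tr.start in target:
                raise ValueError(f"duplicate modification record at position {tr.start} strand {tr.strand}")
            target[tr.start] = tr.mod
    return MethylatedDuplex(seq=str(rec.seq).upper(), topology=topology,
                            top_mods=top, bottom_mods=bottom, name=rec.id)


def reverse_complement(d: MethylatedDuplex) -> MethylatedDuplex:
    """Reverse-complement the whole record: sequence, both tracks, label.

    Coordinates map ``i -> L-1-i`` and the top/bottom tracks swap; applying
    this twice is the identity.
    """
    L = len(d.seq)
    label = d.label
    if label is not None:
        label = StrandLabel(
            strand="bottom" if label.strand == "top" else "top",
            end=label.end,
            tag=label.tag,
        )
    return MethylatedDuplex(
        seq=str(Seq(d.seq).reverse_complement()),
        topology=d.topology,
        top_mods={L - 1 - i: m for i, m in d.bottom_mods.items()},
        bottom_mods={L - 1 - i: m for i, m in d.top_mods.items()},
        label=label,
        name=d.name,
    )


def fully_modify(d: MethylatedDuplex, mod: ModType = ModType.M5C) -> MethylatedDuplex:
    """Modify every cytosine on both strands, emulating fully substituted
    phage genomes (XP12-like for m5C, T4gt-like for hm5C)."""
    return replace(
        d,
        top_mods={i: mod for i, b in enumerate(d.seq) if b == "C"},
        bottom_mods={i: mod for i, b in enumerate(d.seq) if b == "G"},
    )


def iupac_class(code: str) -> frozenset[str]:
    try:
        return IUPAC_CLASSES[code]
    except KeyError:
        raise ValueError(f"invalid IUPAC code {code!r}") from None


def revcomp_pattern(pattern: str) -> str:
    """Reverse complement of an IUPAC pattern (class-wise)."""
    return pattern.translate(_IUPAC_COMPLEMENT)[::-1]


def pattern_is_self_complementary(pattern: str) -> bool:
    """True when revcomp(P) equals P as IUPAC base classes."""
    return revcomp_pattern(pattern) == pattern


def match_iupac(pattern: str, d: MethylatedDuplex, pos: int, strand: str = "top") -> bool:
    """Does ``pattern`` match the ``strand``'s 5'->3' window starting at ``pos``?

    ``pos`` is a top-strand coordinate of the window's leftmost base in the
    top frame; for the bottom strand the window still occupies top
    coordinates [pos, pos+len) but is read right-to-left complemented.
    Circular topology wraps; on a linear molecule a window running off the
    end does not match.
    """
    L = len(d.seq)
    n = len(pattern)
    if n == 0:
        return True
    if not d.circular and (pos < 0 or pos + n > L):
        return False
    if d.circular and n > L:
        return False
    if strand == "top":
        window = [d.base(pos + k, "top") for k in range(n)]
    else:
        window = [d.base(pos + n - 1 - k, "bottom") for k in range(n)]
    return all(b in iupac_class(c) for c, b in zip(pattern, window))
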