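"""DNA methyltransferase models used to build modified substrates.

Each :class:`MTaseSpec` names an IUPAC recognition pattern and the offset of
the cytosine it methylates within that pattern.  Applying an MTase scans
both strands 5'->3' and installs the modification at every match — the
fully reacted end point of an in-vitro modification reaction.  Partial or
hemi-specific methylation kinetics are not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqmodel import MethylatedDuplex, ModType, iupac_class

__all__ = ["MTaseSpec", "apply_mtase", "builtin_mtases", "get_mtase"]


@dataclass(frozen=True)
class MTaseSpec:
    name: str
    recognition: str
    mod_offset: int
    mod: ModType = ModType.M5C

    def __post_init__(self) -> None:
        if not 0 <= self.mod_offset < len(self.recognition):
            raise ValueError(f"{self.name}: mod_offset {self.mod_offset} outside pattern")
        if "C" not in iupac_class(self.recognition[self.mod_offset]):
            raise ValueError(
                f"{self.name}: pattern position {self.mod_offset} "
                f"({self.recognition[self.mod_offset]}) cannot be a cytosine"
            )


def apply_mtase(d: MethylatedDuplex, spec: MTaseSpec) -> MethylatedDuplex:
    """Methylate every recognition-site match on both strands.

    For a top-strand match starting at ``s`` the modified base is the top C
    at ``s + mod_offset``; for a bottom-strand match the offset is counted
    along the bottom strand 5'->3' and stored at the corresponding top
    coordinate.  Existing modifications are preserved (never overwritten),
    so the operation is idempotent and monotone.
    """
    from .digest import find_sites  # local import to avoid a cycle

    L = len(d.seq)
    n = len(spec.recognition)
    top_new: dict[int, ModType] = {}
    bottom_new: dict[int, ModType] = {}
    for start, strand in find_sites(d, spec.recognition, collapse_palindromic=False):
        if strand == "top":
            pos = (start + spec.mod_offset) % L if d.circular else start + spec.mod_offset
            if d.seq[pos] == "C" and pos not in d.top_mods:
                top_new[pos] = spec.mod
        else:
            # offset along the bottom strand: its 5' end sits at top coord start+n-1
            pos = start + n - 1 - spec.mod_offset
            pos = pos % L if d.circular else pos
            if d.seq[pos] == "G" and pos not in d.bottom_mods:
                bottom_new[pos] = spec.mod
    return d.with_mods(top=top_new.items(), bottom=bottom_new.items())


_BUILTINS = [
    # name, recognition, offset of the methylated C within the pattern
    MTaseSpec("M.Fnu4HI", "GCNGC", 1),
    MTaseSpec("M.Dcm", "CCWGG", 1),
    MTaseSpec("M.SssI", "CG", 0),
    MTaseSpec("M.CviPI", "GC", 1),
    MTaseSpec("M.HhaI", "GCGC", 1),
    MTaseSpec("M.HpaII", "CCGG", 1),
]


def builtin_mtases() -> list[MTaseSpec]:
    """The m5C MTases used for in-vitro substrate construction."""
    return list(_BUILTINS)


def get_mtase(name: str) -> MTaseSpec:
    for m in _BUILTINS:
        if m.name.lower() == name.lower() or m.name.lower().lstrip("m.") == name.lower():
            return m
    known = ", ".join(m.name for m in _BUILTINS)
    raise KeyError(f"unknown MTase {name!r}; known MTases: {known}")
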