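"""Enzyme-specificity registry and per-site action evaluation.

BisI-family enzymes are Type IIM restriction endonucleases: they cleave
their recognition site only when enough cytosines inside it carry a C5
modification (5mC, and for some enzymes 5hmC at reduced efficiency).  The
family splits by its 5mC requirement on GCNGC:

* **Group I** (BisI-like) — cut with two to four 5mC, including
  hemi-methylated sites (both 5mC on one strand).
* **Group II** (NhoI-like) — require three to four 5mC; hemi sites are
  refractory or poorly cut; an asymmetric three-5mC site may accumulate a
  nicked intermediate on the strand carrying two modified cytosines.
* **all4** — SqiI, needing all four canonical cytosines modified.
* **esp638** — Esp638I, a blunt cutter at GCS/SGC (relaxed RCN/NGY) that
  needs at least four modified cytosines anywhere in the 6-bp site.
* **degenerate** — Bce1273I and Bth171I, which cleave unmodified sites.

"Canonical" cytosines of a GCNGC-class site are the four implied by the
literal G/C letters: the top-strand C's under pattern C's, and the
bottom-strand C's opposite pattern G's.  A C at the degenerate N position
never counts toward the requirement.

Qualitative activities from digestion assays are encoded as a four-level
tier (full > moderate > poor > none); downstream digestion applies a
user-selectable tier threshold (default: moderate and above cut).
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from typing import Optional

from .seqmodel import MethylatedDuplex, ModType, match_iupac

__all__ = [
    "TIER_ORDER",
    "CutGeometry",
    "MethylationConfig",
    "SiteAction",
    "RequirementEntry",
    "StarSpec",
    "EnzymeSpec",
    "builtin_enzymes",
    "builtin_registry_text",
    "load_registry",
    "get_enzyme",
    "relevant_c_positions",
    "evaluate_site",
    "min_m5c_for_cleavage",
]

TIER_ORDER = {"none": 0, "poor": 1, "moderate": 2, "full": 3}

KLASSES = ("full4", "asym3", "hemi2", "sym2", "sub2")


@dataclass(frozen=True)
class CutGeometry:
    """Scission positions within a site.

    Each offset counts nucleotides 5' of the scission on that strand,
    measured from the strand's own 5' end of the site.  For a site of
    length L the overhang is ``L - top_offset - bottom_offset``:
    positive = 5' extension, 0 = blunt, negative = 3' extension.
    """

    top_offset: int
    bottom_offset: int

    def overhang(self, site_len: int) -> int:
        return site_len - self.bottom_offset - self.top_offset

    def top_cut(self, site_start: int) -> int:
        """Top-strand scission: backbone broken between top_cut-1 and top_cut."""
        return site_start + self.top_offset

    def bottom_cut(self, site_start: int, site_len: int) -> int:
        """Bottom-strand scission in top coordinates (between bottom_cut-1 and bottom_cut)."""
        return site_start + site_len - self.bottom_offset


@dataclass(frozen=True)
class MethylationConfig:
    """Counts of modified canonical cytosines per strand, and their class."""

    n_top: int
    n_bottom: int

    @property
    def n_total(self) -> int:
        return self.n_top + self.n_bottom

    @property
    def klass(self) -> str:
        t = self.n_total
        if t >= 4:
            return "full4"
        if t == 3:
            return "asym3"
        if t == 2:
            return "hemi2" if (self.n_top == 0 or self.n_bottom == 0) else "sym2"
        return "sub2"


@dataclass(frozen=True)
class SiteAction:
    """Outcome of evaluating one enzyme on one site."""

    action: str  # CUT | NICK_TOP | NICK_BOTTOM | NONE
    tier: str    # full | moderate | poor | none
    nick_intermediate: Optional[str] = None  # 'top' | 'bottom' when a nicked
    # intermediate accumulates alongside (or instead of) complete cleavage

    def __post_init__(self) -> None:
        if (self.action == "NONE") != (self.tier == "none"):
            raise ValueError(f"action {self.action} inconsistent with tier {self.tier}")


NO_ACTION = SiteAction("NONE", "none")


@dataclass(frozen=True)
class RequirementEntry:
    action: str          # CUT | NICK | NONE
    tier: str
    nick: bool = False   # nicked intermediate on the two-modified-C strand


@dataclass(frozen=True)
class StarSpec:
    recognition: str
    geometry: CutGeometry
    methylation_independent: bool
    tier: str = "full"


@dataclass(frozen=True)
class EnzymeSpec:
    name: str
    recognition: str
    geometry: CutGeometry
    group: str  # I | II | all4 | esp638 | degenerate
    requirement: dict[str, RequirementEntry] = field(default_factory=dict)
    counting: str = "canonical"  # canonical | window
    min_total: int = 0           # threshold for window counting
    hm5c_tier: str = "poor"
    methylation_independent: bool = False
    independent_tier: str = "full"
    star_specs: tuple[StarSpec, ...] = ()
    w_site_bump: bool = False

    def __post_init__(self) -> None:
        L = len(self.recognition)
        for off in (self.geometry.top_offset, self.geometry.bottom_offset):
            if not 0 < off < L:
                raise ValueError(f"{self.name}: cut offset {off} outside site of length {L}")
        if not self.methylation_independent and self.counting == "canonical":
            missing = [k for k in KLASSES if k not in self.requirement]
            if missing:
                raise ValueError(f"{self.name}: requirement table missing classes {missing}")

    @property
    def overhang(self) -> int:
        return self.geometry.overhang(len(self.recognition))


def _parse_entry(text: str) -> RequirementEntry:
    parts = text.strip().split(":")
    action = parts[0].upper()
    if action == "NONE":
        return RequirementEntry("NONE", "none")
    if action not in ("CUT", "NICK"):
        raise ValueError(f"unknown action {action!r} in requirement entry {text!r}")
    tier = parts[1].lower() if len(parts) > 1 else "full"
    if tier not in TIER_ORDER:
        raise ValueError(f"unknown tier {tier!r} in requirement entry {text!r}")
    nick = "nick" in [p.lower() for p in parts[2:]]
    return RequirementEntry(action, tier, nick)


def _parse_geometry(text: str) -> CutGeometry:
    top, bottom = text.strip().split("/")
    return CutGeometry(int(top), int(bottom))


def load_registry(text: str) -> list[EnzymeSpec]:
    """Parse the plain-text enzyme registry format (see the built-in file)."""
    cp = configparser.ConfigParser(inline_comment_prefixes=("#",))
    cp.read_string(text)
    specs = []
    for name in cp.sections():
        sec = cp[name]
        independent = sec.getboolean("independent", fallback=False)
        requirement = {}
        if not independent and sec.get("counting", "canonical") == "canonical":
            requirement = {k: _parse_entry(sec[k]) for k in KLASSES}
        stars = []
        for entry in sec.get("star", "").split():
            pat, cut, mode, *rest = entry.split(";")
            stars.append(StarSpec(
                recognition=pat.upper(),
                geometry=_parse_geometry(cut),
                methylation_independent=(mode == "independent"),
                tier=rest[0] if rest else "full",
            ))
        specs.append(EnzymeSpec(
            name=name,
            recognition=sec["recognition"].upper(),
            geometry=_parse_geometry(sec["cut"]),
            group=sec["group"],
            requirement=requirement,
            counting=sec.get("counting", "canonical"),
            min_total=sec.getint("min_total", fallback=0),
            hm5c_tier=sec.get("hm5c_tier", "poor"),
            methylation_independent=independent,
            independent_tier=sec.get("tier", "full"),
            star_specs=tuple(stars),
            w_site_bump=sec.getboolean("w_site_bump", fallback=False),
        ))
    return specs


def builtin_registry_text() -> str:
    return resources.files("mdresim").joinpath("data/enzymes.cfg").read_text()


_REGISTRY: Optional[list[EnzymeSpec]] = None


def builtin_enzymes() -> list[EnzymeSpec]:
    """The shipped registry of characterized BisI-family enzymes."""
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = load_registry(builtin_registry_text())
    return list(_REGISTRY)


def get_enzyme(name: str) -> EnzymeSpec:
    for e in builtin_enzymes():
        if e.name.lower() == name.lower():
            return e
    known = ", ".join(e.name for e in builtin_enzymes())
    raise KeyError(f"unknown enzyme {name!r}; known enzymes: {known}")


def relevant_c_positions(
    site_start: int,
    pattern: str,
    d: MethylatedDuplex,
    strand: str = "top",
    counting: str = "canonical",
) -> list[tuple[str, int]]:
    """Cytosine positions that count toward the modification requirement.

    ``canonical``: top-strand C's under literal pattern C's and
    bottom-strand C's opposite literal pattern G's — four positions for
    GCNGC; a C at the degenerate N position is excluded.

    ``window``: every position inside the site that is a C on either
    strand (Esp638I accounting).

    Returns (strand, top-coordinate) pairs in molecule frame.
    """
    if not match_iupac(pattern, d, site_start, strand):
        raise ValueError(f"pattern {pattern} does not match at {site_start} ({strand})")
    L = len(d.seq)
    n = len(pattern)

    def topcoord(k: int) -> int:
        i = site_start + k if strand == "top" else site_start + n - 1 - k
        return i % L if d.circular else i

    out: list[tuple[str, int]] = []
    if counting == "canonical":
        for k, c in enumerate(pattern):
            if c == "C":
                out.append(("top" if strand == "top" else "bottom", topcoord(k)))
            elif c == "G":
                out.append(("bottom" if strand == "top" else "top", topcoord(k)))
    elif counting == "window":
        for k in range(n):
            i = topcoord(k)
            if d.seq[i] == "C":
                out.append(("top", i))
            elif d.seq[i] == "G":
                out.append(("bottom", i))
    else:
        raise ValueError(f"unknown counting mode {counting!r}")
    return out


def _count_mods(
    d: MethylatedDuplex, positions: list[tuple[str, int]], include_hm5c: bool
) -> MethylationConfig:
    n_top = n_bottom = 0
    for strand, i in positions:
        mod = d.modification_at(i, strand)
        if mod is None or (mod is ModType.HM5C and not include_hm5c):
            continue
        if strand == "top":
            n_top += 1
        else:
            n_bottom += 1
    return MethylationConfig(n_top, n_bottom)


def _requirement_action(spec: EnzymeSpec, cfg: MethylationConfig) -> RequirementEntry:
    if spec.counting == "window":
        if cfg.n_total >= spec.min_total:
            return RequirementEntry("CUT", "full")
        return RequirementEntry("NONE", "none")
    return spec.requirement[cfg.klass]


def _site_action(entry: RequirementEntry, cfg: MethylationConfig, tier: str) -> SiteAction:
    if entry.action == "NONE" or tier == "none":
        return NO_ACTION
    nick_strand = None
    if entry.nick or entry.action == "NICK":
        nick_strand = "top" if cfg.n_top >= cfg.n_bottom else "bottom"
    if entry.action == "NICK":
        return SiteAction("NICK_TOP" if nick_strand == "top" else "NICK_BOTTOM",
                          tier, nick_strand)
    return SiteAction("CUT", tier, nick_strand)


def evaluate_site(
    d: MethylatedDuplex,
    site_start: int,
    spec: EnzymeSpec,
    star: bool = False,
    strand: str = "top",
    w_bump: bool = False,
) -> SiteAction:
    """Evaluate one recognition-site occurrence and return the enzyme's action.

    With ``star=True`` the enzyme's star/relaxed sites are also accepted at
    ``site_start``.  5hmC counts as a modification but the achievable tier
    is capped at the enzyme's ``hm5c_tier`` whenever the outcome depends on
    it.  ``w_bump`` enables the optional one-level tier bump for enzymes
    that cleave W-interrupted sites (GCWGC) more completely than GCSGC.
    """
    # locate the pattern that matches here
    pattern, geometry = spec.recognition, spec.geometry
    matched = match_iupac(pattern, d, site_start, strand)
    star_model: Optional[StarSpec] = None
    if not matched and star:
        for s in spec.star_specs:
            if match_iupac(s.recognition, d, site_start, strand):
                pattern, geometry, star_model = s.recognition, s.geometry, s
                matched = True
                break
    if not matched:
        raise ValueError(f"{spec.name}: no recognition match at {site_start} ({strand})")

    if star_model is not None and star_model.methylation_independent:
        return SiteAction("CUT", star_model.tier)
    if spec.methylation_independent:
        return SiteAction("CUT", spec.independent_tier)

    positions = relevant_c_positions(site_start, pattern, d, strand, spec.counting)
    cfg_m5c = _count_mods(d, positions, include_hm5c=False)
    cfg_all = _count_mods(d, positions, include_hm5c=True)
    entry_m5c = _requirement_action(spec, cfg_m5c)
    entry_all = _requirement_action(spec, cfg_all)

    # 5hmC may raise the outcome only up to hm5c_tier
    if TIER_ORDER[entry_all.tier] > TIER_ORDER[entry_m5c.tier]:
        capped = min(TIER_ORDER[entry_all.tier], TIER_ORDER[spec.hm5c_tier])
        if capped > TIER_ORDER[entry_m5c.tier]:
            tier = next(t for t, r in TIER_ORDER.items() if r == capped)
            action = _site_action(entry_all, cfg_all, tier)
        else:
            action = _site_action(entry_m5c, cfg_m5c, entry_m5c.tier)
    else:
        action = _site_action(entry_m5c, cfg_m5c, entry_m5c.tier)

    if (
        w_bump
        and spec.w_site_bump
        and action.action == "CUT"
        and "N" in pattern
    ):
        k = pattern.index("N")
        i = site_start + k if strand == "top" else site_start + len(pattern) - 1 - k
        if d.base(i, "top") in "AT":
            bumped = min(TIER_ORDER[action.tier] + 1, TIER_ORDER["full"])
            action = SiteAction(action.action,
                                next(t for t, r in TIER_ORDER.items() if r == bumped),
                                action.nick_intermediate)
    return action


def min_m5c_for_cleavage(
    spec: EnzymeSpec,
    instance: MethylatedDuplex,
    site_start: int = 0,
    min_tier: str = "moderate",
) -> int:
    """Smallest number of 5mC that makes the enzyme cut a site instance.

    Enumerates every subset of the site's relevant cytosine positions on an
    unmodified copy of ``instance``, applies :func:`evaluate_site`, and
    returns the smallest total yielding CUT at tier >= ``min_tier``.
    Methylation-independent enzymes report 0.
    """
    if spec.methylation_independent:
        return 0
    bare = MethylatedDuplex(instance.seq, instance.topology, name=instance.name)
    positions = relevant_c_positions(site_start, spec.recognition, bare,
                                     counting=spec.counting)
    for n in range(len(positions) + 1):
        for subset in combinations(positions, n):
            top = [(i, ModType.M5C) for s, i in subset if s == "top"]
            bottom = [(i, ModType.M5C) for s, i in subset if s == "bottom"]
            action = evaluate_site(bare.with_mods(top, bottom), site_start, spec)
            if action.action == "CUT" and TIER_ORDER[action.tier] >= TIER_ORDER[min_tier]:
                return n
    raise ValueError(f"{spec.name}: no methylation configuration is cleavable")
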