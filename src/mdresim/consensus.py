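"""Recognition-consensus derivation from digested-fragment ends.

This reproduces in silico the digest -> clone -> map -> logo procedure used
to determine a cutter's specificity de novo: collect the sequence flanks of
every double-strand scission, stack both orientations so palindromic sites
align, and call a per-position IUPAC consensus from the base frequencies.
The scission sits at the center of every row, so the consensus string comes
with a cut offset; the overhang is taken from the paired strand scissions
of the collected events.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .digest import CutEvent
from .seqmodel import (
    IUPAC_CLASSES,
    MethylatedDuplex,
    iupac_class,
    revcomp_pattern,
)

__all__ = [
    "SiteMatrix",
    "Consensus",
    "collect_cut_flanks",
    "build_consensus",
    "iupac_covers",
    "write_matrix_fasta",
    "write_consensus_tsv",
    "plot_logo",
]

_CLASS_TO_CODE = {v: k for k, v in IUPAC_CLASSES.items()}


@dataclass(frozen=True)
class SiteMatrix:
    """Aligned cut-flank windows: each row is 2k nt with the top-strand
    scission between positions k-1 and k."""

    rows: tuple[str, ...]
    k: int
    overhangs: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("empty site matrix")
        if any(len(r) != 2 * self.k for r in self.rows):
            raise ValueError("all rows must have length 2k")

    @property
    def count(self) -> int:
        return len(self.rows)

    @property
    def modal_overhang(self) -> int:
        if not self.overhangs:
            return 0
        return Counter(self.overhangs).most_common(1)[0][0]

    def reverse_complement(self) -> "SiteMatrix":
        return SiteMatrix(tuple(revcomp_pattern(r) for r in self.rows),
                          self.k, self.overhangs)


@dataclass(frozen=True)
class Consensus:
    """Per-position base frequencies, information content, and IUPAC call."""

    frequencies: pd.DataFrame  # index: position, columns: A C G T
    information: np.ndarray    # bits, 2 - Shannon entropy, in [0, 2]
    iupac: str
    cut_offset: int            # scission precedes this 0-based position
    overhang: int
    count: int = 0

    def core(self, width: int) -> str:
        """The ``width`` consensus positions centered on the cut."""
        half = width // 2
        return self.iupac[self.cut_offset - half : self.cut_offset - half + width]


def collect_cut_flanks(d: MethylatedDuplex, events, k: int) -> SiteMatrix:
    """Extract the 2k window around every ds scission, in both orientations.

    The forward row is centered on the top-strand scission, the reverse row
    on the bottom-strand scission read on the bottom strand, so the rows of
    a palindromic cutter stack exactly.  Circular references wrap; on a
    linear reference an event whose flank runs off the end is skipped with
    a warning.
    """
    if k <= 0:
        raise ValueError("flank size k must be positive")
    L = len(d.seq)
    rows: list[str] = []
    overhangs: list[int] = []
    for e in events:
        if e.kind != "ds":
            continue
        tc, bc = e.top_cut, e.bottom_cut
        if d.circular:
            fwd = "".join(d.seq[(i % L)] for i in range(tc - k, tc + k))
            rev = revcomp_pattern("".join(d.seq[(i % L)] for i in range(bc - k, bc + k)))
            ov = (bc - tc) % L
            if ov > L // 2:
                ov -= L
        else:
            if tc - k < 0 or tc + k > L or bc - k < 0 or bc + k > L:
                warnings.warn(f"event at {tc} skipped: flank {k} exceeds the reference")
                continue
            fwd = d.seq[tc - k : tc + k]
            rev = revcomp_pattern(d.seq[bc - k : bc + k])
            ov = bc - tc
        rows.extend([fwd, rev])
        overhangs.extend([ov, ov])
    return SiteMatrix(tuple(rows), k, tuple(overhangs))


def build_consensus(m: SiteMatrix, call_threshold: float = 0.05) -> Consensus:
    """Position frequency matrix -> IUPAC consensus.

    The call at each position is the smallest degenerate class covering all
    bases whose frequency reaches ``call_threshold``; a position where no
    base reaches the threshold is called N.  Lowering the threshold can
    only widen calls toward N.
    """
    width = 2 * m.k
    counts = pd.DataFrame(0, index=range(width), columns=list("ACGT"))
    for row in m.rows:
        for i, b in enumerate(row):
            counts.loc[i, b] += 1
    freqs = counts.div(counts.sum(axis=1), axis=0)
    p = freqs.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.where(p > 0, p * np.log2(p), 0.0).sum(axis=1)
    information = 2.0 - ent
    calls = []
    for i in range(width):
        bases = frozenset(b for b in "ACGT" if freqs.loc[i, b] >= call_threshold)
        calls.append(_CLASS_TO_CODE[bases] if bases else "N")
    return Consensus(
        frequencies=freqs,
        information=information,
        iupac="".join(calls),
        cut_offset=m.k,
        overhang=m.modal_overhang,
        count=m.count,
    )


def iupac_covers(general: str, specific: str) -> bool:
    """True when every base class of ``specific`` is contained in the
    corresponding class of ``general`` (same length)."""
    if len(general) != len(specific):
        return False
    return all(iupac_class(s) <= iupac_class(g) for g, s in zip(general, specific))


def write_matrix_fasta(m: SiteMatrix, dest) -> None:
    close = False
    if isinstance(dest, (str, bytes)):
        dest = open(dest, "w")
        close = True
    try:
        for i, row in enumerate(m.rows):
            dest.write(f">flank_{i}\n{row}\n")
    finally:
        if close:
            dest.close()


def write_consensus_tsv(c: Consensus, dest) -> None:
    close = False
    if isinstance(dest, (str, bytes)):
        dest = open(dest, "w")
        close = True
    try:
        dest.write("position\tA\tC\tG\tT\tbits\tcall\tcut_here\n")
        for i in range(len(c.iupac)):
            f = c.frequencies.loc[i]
            cut = 1 if i == c.cut_offset else 0
            dest.write(
                f"{i}\t{f['A']:.4f}\t{f['C']:.4f}\t{f['G']:.4f}\t{f['T']:.4f}"
                f"\t{c.information[i]:.4f}\t{c.iupac[i]}\t{cut}\n"
            )
    finally:
        if close:
            dest.close()


def plot_logo(c: Consensus, path: str) -> None:
    """Information-scaled sequence-logo rendering of the consensus."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}
    width = len(c.iupac)
    fig, ax = plt.subplots(figsize=(max(4, width * 0.45), 3))
    for i in range(width):
        bottom = 0.0
        order = c.frequencies.loc[i].sort_values().items()
        for base, freq in order:
            h = float(freq) * float(c.information[i])
            if h <= 0:
                continue
            ax.bar(i, h, bottom=bottom, width=0.8, color=colors[base],
                   edgecolor="none")
            if h > 0.15:
                ax.text(i, bottom + h / 2, base, ha="center", va="center",
                        fontsize=9, color="white", fontweight="bold")
            bottom += h
    ax.axvline(c.cut_offset - 0.5, color="black", linestyle="--", linewidth=1)
    ax.set_ylim(0, 2)
    ax.set_ylabel("bits")
    ax.set_xticks(range(width))
    ax.set_xticklabels(list(c.iupac))
    ax.set_title(f"consensus {c.iupac} (cut before position {c.cut_offset})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
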