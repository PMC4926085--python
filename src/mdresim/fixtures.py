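"""Built-in test substrates: the published duplex-oligo assay set and
synthetic plasmid/phage generators.

The duplex oligos reproduce the 34-mer activity-assay substrates: a
5'-FAM-labeled top strand carrying two 5mC in its central GCAGC site,
annealed to bottom strands with two, one or zero 5mC, giving sites with
four (symmetric), three (asymmetric) or two (hemi-methylated) modified
cytosines.

The synthetic plasmid generator stands in for the pBRFM/pUCM substrates,
whose exact constructs are not published: it builds a circular sequence
with a requested number of isolated GCNGC and tandem GCNGCNGC loci and no
GCNGC elsewhere, so that M.Fnu4HI methylation yields exactly the two-5mC
(isolated) and three-5mC (tandem) site classes those plasmids carry.  The
synthetic phage generator emulates fully substituted genomes (every C as
5mC, XP12-like; or 5hmC, T4gt-like).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqmodel import MethylatedDuplex, ModType, StrandLabel, fully_modify

__all__ = ["OligoSet", "oligo_fixtures", "synth_plasmid", "synth_phage"]

# 34-mer assay oligos: 18-nt left flank + GCAGC site + 11-nt right flank
TOP_OLIGO = "AGATCCAAGCTTGAATTC" + "GCAGC" + "CATATGGCTCT"
BOTTOM_OLIGO = "AGAGCCATATG" + "GCTGC" + "GAATTCAAGCTTGGATCT"

# top-frame coordinates of the site's modified cytosines
_TOP_M5C = (19, 22)          # the two C's of GCAGC on the top strand
_BOTTOM_M5C_FULL = (18, 21)  # both C's of the bottom-strand GCTGC
_BOTTOM_M5C_ONE = (21,)      # internal C only


@dataclass(frozen=True)
class OligoSet:
    """The duplex-oligo assay substrates with 4, 3 and 2 (hemi) 5mC."""

    top: str
    bottom1: str  # two 5mC
    bottom2: str  # one 5mC (internal)
    bottom3: str  # unmodified
    four_m5C: MethylatedDuplex
    three_m5C: MethylatedDuplex
    hemi_two_m5C: MethylatedDuplex


def oligo_fixtures() -> OligoSet:
    """Assemble the printed 34-bp duplex substrates, FAM on the top 5' end."""
    label = StrandLabel(strand="top", end="5prime", tag="FAM")
    top_mods = {i: ModType.M5C for i in _TOP_M5C}

    def duplex(bottom_coords, name):
        return MethylatedDuplex(
            seq=TOP_OLIGO,
            topology="linear",
            top_mods=dict(top_mods),
            bottom_mods={i: ModType.M5C for i in bottom_coords},
            label=label,
            name=name,
        )

    return OligoSet(
        top=TOP_OLIGO,
        bottom1=BOTTOM_OLIGO,
        bottom2=BOTTOM_OLIGO,
        bottom3=BOTTOM_OLIGO,
        four_m5C=duplex(_BOTTOM_M5C_FULL, "oligo_4m5C"),
        three_m5C=duplex(_BOTTOM_M5C_ONE, "oligo_3m5C"),
        hemi_two_m5C=duplex((), "oligo_hemi_2m5C"),
    )


def _scan_gcngc(seq: str) -> list[int]:
    """Start positions of GCNGC on the top strand of a circular sequence.

    The pattern class is its own reverse complement, so a top-strand scan
    enumerates every duplex locus.
    """
    L = len(seq)
    ext = seq + seq[:4]
    return [i for i in range(L)
            if ext[i] == "G" and ext[i + 1] == "C" and ext[i + 3] == "G" and ext[i + 4] == "C"]


def synth_plasmid(
    seed: int,
    length: int = 3000,
    n_gcngc_isolated: int = 4,
    n_gcngc_tandem: int = 2,
) -> MethylatedDuplex:
    """Deterministic circular plasmid with a controlled GCNGC site layout.

    The returned molecule is unmodified; apply M.Fnu4HI to obtain the
    pBRFM-like modification classes (isolated sites: two 5mC, one per
    strand; tandem GCNGCNGC loci: two overlapping three-5mC sites).
    """
    spacing = 40  # nt reserved per planted locus, with padding
    need = (n_gcngc_isolated + n_gcngc_tandem) * spacing
    if need > length:
        raise ValueError(
            f"cannot place {n_gcngc_isolated}+{n_gcngc_tandem} loci in {length} bp"
        )
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seq = list(rng.choice(bases, size=length))

    # place motifs at evenly spaced, well-separated anchors
    n_loci = n_gcngc_isolated + n_gcngc_tandem
    anchors = [int(i * length / n_loci) + 10 for i in range(n_loci)]
    motifs = ["GCAGC"] * n_gcngc_isolated + ["GCAGCAGC"] * n_gcngc_tandem
    planted: set[int] = set()
    for a, motif in zip(anchors, motifs):
        for k, b in enumerate(motif):
            seq[(a + k) % length] = b
        planted.update((a + k) % length for k in range(len(motif)))

    # remove spurious GCNGC occurrences by mutating a non-planted base
    for _ in range(200):
        spurious = [s for s in _scan_gcngc("".join(seq))
                    if not all((s + k) % length in planted for k in range(5))]
        if not spurious:
            break
        for s in spurious:
            # break the site at its first non-planted literal position
            for k in (0, 1, 3, 4):
                i = (s + k) % length
                if i not in planted:
                    current = seq[i]
                    choices = [b for b in "AT" if b != current] or ["A"]
                    seq[i] = choices[int(rng.integers(len(choices)))]
                    break
    else:
        raise ValueError("could not scrub spurious GCNGC sites; try another seed")

    return MethylatedDuplex(seq="".join(seq), topology="circular",
                            name=f"synth_plasmid_seed{seed}")


def synth_phage(
    seed: int,
    length: int = 5000,
    mod: ModType = ModType.M5C,
) -> MethylatedDuplex:
    """Deterministic random linear genome with every cytosine modified.

    ``mod=M5C`` emulates an XP12-like fully 5mC-substituted genome;
    ``mod=HM5C`` a T4gt-like 5hmC genome (non-glucosylated).
    """
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(np.array(list("ACGT")), size=length))
    d = MethylatedDuplex(seq=seq, topology="linear",
                         name=f"synth_phage_seed{seed}_{mod.value}")
    return fully_modify(d, mod)
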