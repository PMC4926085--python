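# mdresim

In-silico digestion with **modification-dependent restriction enzymes**
(MDREs) of the BisI family.

Type IIM restriction endonucleases cleave only DNA whose recognition site
carries modified bases and leave unmodified DNA intact. The BisI family
recognizes GCNGC when enough of its cytosines carry 5-methylcytosine
(5mC), which makes these enzymes useful probes of CpG/CpH methylation
state: which sites in a molecule get cut is a direct readout of how many
modified cytosines each site contains. `mdresim` is for molecular
biologists and epigenomics tool builders who want to predict those
digestion outcomes — cut positions, nicked intermediates, fragment sizes,
gel banding, run-off sequencing traces — for a substrate whose per-strand
modification state they control.

## The model

A substrate is a duplex with per-strand modification tracks: an ACGT
sequence (linear or circular) plus the set of top-strand and bottom-strand
cytosines carrying 5mC or 5hmC, all addressed in 0-based top-strand
coordinates.

Each enzyme is a declarative specificity record:

* a recognition pattern in IUPAC code (GCNGC for most of the family;
  RCNNGY for Esp638I; RGNCY/RSNSY for the degenerate cutters);
* a cut geometry `top/bottom` — nucleotides 5' of each strand's scission,
  measured from that strand's own 5' end of the site. BisI is
  G^m5C↓NGC = `2/2` on a 5-mer, leaving a 1-nt 5' extension; Esp638I is
  GCS↓SGC = `3/3` on a 6-mer, blunt;
* a methylation requirement over the site's **canonical cytosines** — the
  four C's implied by the literal G/C letters of GCNGC (two per strand; a
  C at the degenerate N position never counts). Site classes are
  `full4` (4 modified), `asym3` (3), `hemi2` (2 on one strand),
  `sym2` (1 + 1) and `sub2` (≤ 1), and each class maps to an action and a
  qualitative tier (full/moderate/poor/none):
  * Group I (BisI, Bce95I, BceYI, Vsp586I, ...) cut 2–4 5mC including
    hemi-methylated sites;
  * Group II (NhoI, Eco15I, Sve396I, ...) need 3–4 5mC; on `asym3` sites
    some accumulate a nicked intermediate on the strand with two 5mC;
  * SqiI needs all four; Esp638I instead counts *every* modified C in its
    6-bp window on both strands and cuts at ≥ 4;
  * Bce1273I and Bth171I cleave regardless of modification.

  5hmC counts as a modification but caps the achievable tier at a
  per-enzyme level; star/relaxed sites (NhoI R^m5C NG^m5C, Sve396I GCGAC)
  are scanned only in star mode.

Digestion scans both strands (circularity wraps), evaluates every site,
fragments the molecule at double-strand cuts above a tier threshold
(default: moderate), and reports nicks without fragmenting. Run-off
simulation reproduces cut-site mapping by Sanger sequencing: a read
terminates opposite the template scission and gains one untemplated A
(displayed as an extra T when read from the other strand), and
`infer_cut` inverts that to a strand-resolved cut coordinate. The
consensus module stacks the flanks of observed cuts in both orientations
into a position frequency matrix and calls a degenerate IUPAC consensus
with information content in bits.

## Worked example

```python
from mdresim import digest, denatured_strand_lengths
from mdresim.fixtures import oligo_fixtures

oligos = oligo_fixtures()           # the 34-bp assay duplexes
events, fragments = digest(oligos.four_m5C, ["BisI"])
print([(f.length, f.carries_label) for f in fragments])
strands = denatured_strand_lengths(oligos.four_m5C, events)
print(strands.top, strands.bottom, strands.labeled_length)
```

prints

```
[(20, True), (14, False)]
[20, 14] [21, 13] 20
```

The fully methylated 34-bp duplex (four 5mC in its GCAGC site) is cut
once by the BisI model into a 20-bp product carrying the 5'-FAM label and
a 14-bp distal product; on a denaturing gel the top strand runs as 20 +
14 nt and the bottom strand as 21 + 13 nt because of the 1-nt 5'
overhang. The same substrate with only top-strand 5mC (hemi) is still cut
by Group I enzymes but not by NhoI:

```python
from mdresim import evaluate_site, get_enzyme
evaluate_site(oligos.hemi_two_m5C, 18, get_enzyme("BisI")).action   # 'CUT'
evaluate_site(oligos.hemi_two_m5C, 18, get_enzyme("NhoI")).action   # 'NONE'
```

A command-line interface mirrors the library
(`mdresim digest|sites|methylate|runoff|consensus|fixtures|registry`);
all file outputs use 0-based half-open top-strand coordinates.

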