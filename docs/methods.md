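# Methods

## Substrate model

A `MethylatedDuplex` is an unambiguous ACGT sequence with linear or
circular topology and two modification tracks, one per strand. Both
tracks use 0-based top-strand coordinates: a bottom-strand 5mC is stored
at the coordinate of the paired top-strand G. This single coordinate
frame keeps every downstream computation (site scanning, cut placement,
fragment slicing, run-off mapping) free of per-strand bookkeeping;
`reverse_complement` is an exact involution over the whole record,
including tracks and end labels, and is property-tested as such.

Only cytosine C5 modifications are modeled (5mC, 5hmC). Substrate
sequences must be concrete ACGT — IUPAC ambiguity codes are allowed in
recognition patterns only, because a modification position on an
ambiguous base is ill-defined. Circular molecules wrap for matching,
modification and slicing; a site never spans more than one revolution.

## MTase models

MTases are pattern + offset records (M.Fnu4HI GCNGC@1, M.Dcm CCWGG@1,
M.SssI CG@0, M.CviPI GC@1, M.HhaI GCGC@1, M.HpaII CCGG@1). Application
scans both strands and installs 5mC at every match; the operation is
idempotent and monotone, representing the fully reacted end point of an
in-vitro modification. Hemi-specific or partial methylation kinetics are
not modeled — the assays this package emulates always used complete
modification. When the N of GCNGC is itself a C, M.Fnu4HI does not
methylate it: only the offset position of each match is modified, which
is what makes the isolated-site (two 5mC) and tandem-site (three 5mC)
accounting come out right.

## Enzyme specificity models

The registry (`data/enzymes.cfg`, a plain-text config the CLI can emit
for editing) stores per enzyme: recognition pattern, cut offsets,
a methylation-requirement table, 5hmC tier, star sites and flags.

**Canonical-cytosine accounting.** For GCNGC-class sites only the four
cytosines implied by the literal G/C letters count (top C's under
pattern C's, bottom C's opposite pattern G's). The (n_top, n_bottom)
count maps to a class — full4, asym3, hemi2 (2+0/0+2), sym2 (1+1),
sub2 — and the class maps to an action and tier. The same rule applied
to the NhoI star pattern RCNGC yields three canonical positions, so a
fully modified star site evaluates as asym3, consistent with its
"3–4 modified C" relaxed specificity. Esp638I uses window accounting
instead: every modified C on either strand of its 6-bp window counts,
with a cut threshold of 4 (its S positions contribute variable C
content, 4–6 per site).

**Tiers.** Activity is qualitative in the source assays, so it is
encoded as an ordered tier (full > moderate > poor > none). Digestion
takes a tier threshold (default moderate): poor sites are recorded as
partial events but do not fragment. This default reproduces the
enzymes' headline minima — 2 modified C for Group I, 3 for Group II, 4
for SqiI — under exhaustive enumeration of all 16 configurations, and
those minima are cross-checked against an independent oracle that reads
the requirement table directly.

**Nicked intermediates.** NhoI and Pru4541I on asym3 sites, and Vsp586I
on hemi sites, accumulate a single-strand-nicked intermediate. The
model places the nick on the strand carrying two modified canonical
C's. The evidence for which strand is nicked is indirect (a band
consistent with a top-strand nick on a substrate whose two-5mC strand
was the top strand), so the two-mod-strand rule is a documented
assumption; it is the only strand-symmetric rule consistent with that
observation, and evaluation commutes with reverse-complement under it.

**5hmC.** 5hmC counts as a modification but the resulting tier is
capped at a per-enzyme `hm5c_tier` whenever the outcome depends on 5hmC
(NhoI: poor, from its 50–100-fold lower activity on 5hmC DNA; Bce95I
and BceYI: moderate, from partial digestion of 5hmC substrates). For
enzymes with no reported 5hmC data, including BisI itself, the default
is poor — an assumption, flagged here.

**Star sites.** Star/relaxed specificities (NhoI RCNGC, Sve396I GCGAC)
are scanned only when the star flag is set, since star activity is a
high-enzyme/low-salt condition, not default behavior. The GCGAC star
site is written on one strand only in the source; the bottom-strand
offset is stored as the mirrored value 2 and should be treated as
provisional. The GCWGC-over-GCSGC preference of some Group II enzymes
is available as an opt-in tier bump (`w_bump`), off by default.

## Digestion and readouts

All recognition-site occurrences on both strands are enumerated
(overlapping allowed; self-complementary pattern classes are reported
once per duplex locus). Double-strand cuts at or above the tier
threshold fragment the molecule: a linear parent with k cuts yields k+1
fragments, a circular parent k fragments, and top-frame fragment
lengths always sum to the parent length. Overlapping cleavable sites
(GCNGCNGC) produce two cut events; coincident same-strand scissions
merge; staggered cuts closer than the overhang are reported as
degenerate-end conflicts rather than rejected.

Fragment **length is a top-frame convention** (the count of top-strand
nucleotides between successive top-strand scissions), matching how the
34-bp assay products are reported as 20 and 14 bp. For staggered cuts
this naming is orientation-dependent by ±overhang, so the
reverse-complement equivariance guarantee is stated physically: event
coordinates reflect exactly, and the single-strand length multisets of
the two orientations swap (top↔bottom).

Nicks never fragment a duplex in native mode; `denatured_strand_lengths`
splits each strand at both ds scissions and nicks, reproducing the
denaturing-gel readout, and reports the label-carrying strand length.
The virtual gel is a deterministic text rendering (monotone
length→migration rank, co-migration collapsed with multiplicity).

`design_targeting_oligos` inverts the hemi-site behavior: for a chosen
GCNGC site it emits the 18–24 nt oligo(s) whose two site cytosines carry
5mC, verifies via `evaluate_site` that the resulting hemi assembly is
cleaved by a Group I enzyme (nicking the target strand complementary to
the oligo), and that both oligos together license a full double-strand
cut.

## Run-off model

The polymerase copies the template to the break and appends exactly one
untemplated A — the single extra peak seen in traces; +2 artifacts and
base-call errors are not modeled, and reads are plain strings.
`infer_cut` strips one terminal A and reports the scission on the strand
opposite the read. When the reference base at the termination position
is itself A the call is flagged ambiguous (the terminal A could be
templated); round-trip recovery is exact whenever the call is
unambiguous, which is property-tested across the whole registry. At
partially digested sites only the terminated read is emitted; real
traces would superimpose terminated and full-length signal.

## Consensus derivation

Cut flanks (2k nt, scission at center) are collected in both
orientations — forward rows centered on the top-strand scission,
reverse-complemented rows on the bottom-strand scission — so palindromic
sites stack exactly. Consensus calling is frequency-thresholded (default
0.05): the call at each position is the smallest IUPAC class covering
all bases at or above threshold. This reproduces logo-style degenerate
calls deterministically; below a threshold of 0.25 at least one base
always passes, and lowering the threshold can only widen calls. The
overhang attached to a consensus is the modal top/bottom scission
separation of the collected events, the in-silico analog of composing
paired run-off calls.

One behavior worth noting: simulating Esp638I on a fully modified
random circle cuts *every* RCNNGY site with ≥ 4 in-window modified C's,
and among those sites the marginal base frequencies at the R/S/Y
positions stay well above any reasonable call threshold (e.g. A at the
R position appears in ~4/11 of qualifying sites). The derived core is
therefore RCNNGY — the relaxed form — with the strict GCS↓SGC contained
within it. The strict form reflects a site *preference* that the
qualitative cut/no-cut model deliberately does not encode. Tests assert
GCSSGC ⊆ consensus core ⊆ RCNNGY and a zero overhang.

## Synthetic substrates

The printed 34-mer assay oligos are reproduced verbatim, with 5mC at
top coordinates 19/22 and bottom coordinates 21 (and 18 for the fully
modified duplex), giving the 4-, 3- and 2-(hemi)-modified site classes.

`synth_plasmid(seed, length, n_isolated, n_tandem)` emulates the
modification-class structure of the engineered assay plasmids, whose
exact constructs are not published: a circular random sequence carrying
exactly the requested isolated GCNGC and tandem GCNGCNGC loci and no
GCNGC elsewhere (spurious occurrences are scrubbed by mutating flanking
bases to A/T). After M.Fnu4HI treatment, isolated sites carry two 5mC
(sym2) and tandem loci two overlapping three-5mC sites (asym3) — the
substrate logic that separates Group I from Group II enzymes. Because
the layout is synthetic, exact published fragment-size lists for those
plasmids are out of scope. `synth_phage` produces a uniform-random
genome (GC ≈ 50%) with every cytosine modified, emulating fully
substituted phage DNA (5mC or 5hmC). Defaults: 3 kb plasmid with 4
isolated + 2 tandem loci; 5 kb phage — small enough for fast scans,
large enough that a 6-bp degenerate site yields ≥ 50 cut events for
consensus work. What these generators do not emulate: real coding
sequence composition, methylation heterogeneity, and enzyme site
preferences — so passing tests demonstrate model correctness, not
quantitative activity on genomic DNA.

## Numerical and edge-case choices

Scission coordinates are "break before this position"; overhang =
bottom_cut − top_cut (positive 5', zero blunt). Tier order is total
(none < poor < moderate < full); ties in the nick-strand rule resolve
to the top strand (only reachable for symmetric configurations that no
registry enzyme nicks). Site evaluation with both 5mC and 5hmC present
takes the better of the 5mC-only outcome and the 5hmC-capped outcome.
Consensus positions with no base above threshold call N. All
randomness flows through explicit integer seeds (numpy `default_rng` /
`random.Random`); every generator is deterministic per seed.

## Known limitations

No kinetics, units or partial-digest stochastics; no adenine
methylation; no cloning-vector simulation (fragment ends are collected
directly); no chromatogram parsing; enzyme turnover inhibition on
heavily modified DNA is not modeled. The Group II sym2/hemi2 "poor"
tiers encode qualitative gel readouts and should not be over-read as
rate measurements.
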