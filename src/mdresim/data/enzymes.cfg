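# Built-in specificity registry for BisI-family modification-dependent
# restriction endonucleases (MDREs) and related degenerate cutters.
#
# One section per enzyme.  Keys:
#   group        I | II | all4 | esp638 | degenerate
#   recognition  IUPAC pattern, written on the top strand
#   cut          top_offset/bottom_offset -- nt 5' of the scission on each
#                strand, each measured from that strand's own 5' end of the
#                site.  Derived overhang = len - top_offset - bottom_offset
#                (positive: 5' extension; 0: blunt).
#   hm5c_tier    max activity tier when 5hmC (not 5mC) provides the
#                modification: full | moderate | poor | none
#   full4/asym3/hemi2/sym2/sub2
#                action per methylation class of the 4 canonical cytosines
#                (the C's implied by the literal G/C letters of GCNGC; the
#                degenerate N never counts).  Entries are ACTION:tier with
#                optional :nick flag for a nicked-intermediate on the
#                strand carrying two modified C's.
#   counting     canonical (default) | window.  "window" counts every
#                modified C on either strand inside the site and compares
#                against min_total (Esp638I-style).
#   independent  true for enzymes that cut regardless of modification;
#                tier gives their activity level.
#   star         relaxed/star sites, applied only in star mode.  Entries
#                are pattern;top/bottom;dependent|independent;tier
#   w_site_bump  true if W (A/T) at the degenerate position is cleaved
#                more completely than S; the bump is opt-in at evaluation.

# ---- Group I: cut GCNGC with two to four m5C, incl. hemi-methylated ----

[BisI]
group = I
recognition = GCNGC
cut = 2/2
hm5c_tier = poor
full4 = CUT:full
asym3 = CUT:full
hemi2 = CUT:full
sym2 = CUT:full
sub2 = NONE

[Rfl17I]
group = I
recognition = GCNGC
cut = 2/2
hm5c_tier = poor
full4 = CUT:full
asym3 = CUT:full
hemi2 = CUT:full
sym2 = CUT:full
sub2 = NONE

[BceYI]
group = I
recognition = GCNGC
cut = 2/2
hm5c_tier = moderate
full4 = CUT:full
asym3 = CUT:full
hemi2 = CUT:full
sym2 = CUT:full
sub2 = NONE

[Bce95I]
group = I
recognition = GCNGC
cut = 2/2
hm5c_tier = moderate
full4 = CUT:full
asym3 = CUT:full
hemi2 = CUT:full
sym2 = CUT:full
sub2 = NONE

[Vsp586I]
group = I
recognition = GCNGC
cut = 2/2
hm5c_tier = poor
full4 = CUT:full
asym3 = CUT:full
hemi2 = CUT:moderate:nick
sym2 = CUT:full
sub2 = NONE

[KasKI]
group = I
recognition = GCNGC
cut = 2/2
hm5c_tier = poor
full4 = CUT:full
asym3 = CUT:full
hemi2 = CUT:full
sym2 = CUT:full
sub2 = NONE

[CbuDI]
group = I
recognition = GCNGC
cut = 2/2
hm5c_tier = poor
full4 = CUT:full
asym3 = CUT:full
hemi2 = CUT:full
sym2 = CUT:full
sub2 = NONE

[Pps170I]
group = I
recognition = GCNGC
cut = 2/2
hm5c_tier = poor
full4 = CUT:full
asym3 = CUT:full
hemi2 = CUT:moderate
sym2 = CUT:full
sub2 = NONE

[VspHI]
group = I
recognition = GCNGC
cut = 2/2
hm5c_tier = poor
full4 = CUT:full
asym3 = CUT:full
hemi2 = CUT:full
sym2 = CUT:full
sub2 = NONE

[MspAK21I]
group = I
recognition = GCNGC
cut = 2/2
hm5c_tier = poor
full4 = CUT:full
asym3 = CUT:full
hemi2 = CUT:full
sym2 = CUT:full
sub2 = NONE

[AspTB23I]
group = I
recognition = GCNGC
cut = 2/2
hm5c_tier = poor
full4 = CUT:full
asym3 = CUT:full
hemi2 = CUT:full
sym2 = CUT:full
sub2 = NONE

[LsaM18I]
group = I
recognition = GCNGC
cut = 2/2
hm5c_tier = poor
full4 = CUT:full
asym3 = CUT:full
hemi2 = CUT:full
sym2 = CUT:full
sub2 = NONE

# ---- Group II: require three to four m5C for efficient cleavage ----

[NhoI]
group = II
recognition = GCNGC
cut = 2/2
hm5c_tier = poor
full4 = CUT:full
asym3 = CUT:full:nick
hemi2 = NONE
sym2 = NONE
sub2 = NONE
w_site_bump = true
star = RCNGC;2/2;dependent;full

[Eco15I]
group = II
recognition = GCNGC
cut = 2/2
hm5c_tier = poor
full4 = CUT:full
asym3 = CUT:full
hemi2 = CUT:poor
sym2 = CUT:poor
sub2 = NONE

[Sde240I]
group = II
recognition = GCNGC
cut = 2/2
hm5c_tier = poor
full4 = CUT:full
asym3 = CUT:full
hemi2 = CUT:poor
sym2 = CUT:poor
sub2 = NONE

[Pan13I]
group = II
recognition = GCNGC
cut = 2/2
hm5c_tier = poor
full4 = CUT:full
asym3 = CUT:full
hemi2 = CUT:poor
sym2 = CUT:poor
sub2 = NONE

[Pru4541I]
group = II
recognition = GCNGC
cut = 2/2
hm5c_tier = poor
full4 = CUT:full
asym3 = CUT:full:nick
hemi2 = CUT:poor
sym2 = CUT:poor
sub2 = NONE

[AlaI]
group = II
recognition = GCNGC
cut = 2/2
hm5c_tier = poor
full4 = CUT:full
asym3 = CUT:full
hemi2 = CUT:poor
sym2 = CUT:poor
sub2 = NONE

[Sve396I]
group = II
recognition = GCNGC
cut = 2/2
hm5c_tier = poor
full4 = CUT:full
asym3 = CUT:full
hemi2 = CUT:poor
sym2 = CUT:poor
sub2 = NONE
star = GCGAC;2/2;independent;moderate

[Dsp20IU]
group = II
recognition = GCNGC
cut = 2/2
hm5c_tier = poor
full4 = CUT:full
asym3 = CUT:full
hemi2 = CUT:poor
sym2 = CUT:poor
sub2 = NONE
w_site_bump = true

[SmaAUI]
group = II
recognition = GCNGC
cut = 2/2
hm5c_tier = poor
full4 = CUT:full
asym3 = CUT:full
hemi2 = CUT:poor
sym2 = CUT:poor
sub2 = NONE

[MbaR4I]
group = II
recognition = GCNGC
cut = 2/2
hm5c_tier = poor
full4 = CUT:full
asym3 = CUT:full
hemi2 = NONE
sym2 = CUT:poor
sub2 = NONE

# ---- all4: requires all four cytosines modified ----

[SqiI]
group = all4
recognition = GCWGC
cut = 2/2
hm5c_tier = poor
full4 = CUT:full
asym3 = CUT:poor
hemi2 = NONE
sym2 = NONE
sub2 = NONE

# ---- Esp638I: blunt cutter, counts every in-window C on both strands ----

[Esp638I]
group = esp638
recognition = RCNNGY
cut = 3/3
hm5c_tier = poor
counting = window
min_total = 4

# ---- Degenerate cutters: active on unmodified DNA ----

[Bce1273I]
group = degenerate
recognition = RGNCY
cut = 2/2
independent = true
tier = moderate

[Bth171I]
group = degenerate
recognition = RSNSY
cut = 2/2
independent = true
tier = full
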