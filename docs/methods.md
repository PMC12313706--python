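# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic generator does and does
not emulate, and the numerical decisions a maintainer would want written
down. Every number quoted here is computed by the test suite or the analysis
scripts; nothing is asserted that the code does not measure.

## Genome model and coordinates

A plastome is a circular DNA sequence over {A,C,G,T,N} with an ordered list
of features. All interface coordinates are 1-based inclusive (the GenBank
convention); any half-open arithmetic is internal. Ambiguity codes other
than N are normalized to N with a warning. Features may cross the arbitrary
linearization origin; they are represented as two segments and flagged, and
`rotate_record` re-merges segments split by an earlier rotation. Minus-strand
features store segments in ascending genomic order; extraction concatenates
segments and reverse-complements, so the result always reads 5'→3' on the
coding strand. GenBank parsing is delegated to Biopython; `order(...)`
locations, mixed-strand compound locations and `/trans_splicing` qualifiers
mark a feature trans-spliced.

## Inverted-repeat detection

The quadripartite partition is found by exact-match seed-and-extend: k-mers
(k = min(min_len, 21)) of the sequence are indexed, each position's
reverse-complement k-mer is looked up, and every seed pair is extended
maximally in both directions under circular arithmetic, subject to the two
segments staying disjoint. The maximal pair of length ≥ `min_len`
(default 1000 bp) defines IRb/IRa; equally long non-nested candidates are
tie-broken towards the smallest start, with a warning. Exactness (mismatch
tolerance 0) is a deliberate contract: the IR copies of a correctly assembled
plastome are identical, and an exact detector has a testable planted-repeat
oracle. No tolerance knob is exposed because junction placement under
mismatches is not constrained by any ground truth we can test against.

Canonical orientation starts the linearization at the first base of the
longer single-copy arc (LSC), reading LSC→IRb→SSC→IRa. Junctions JLB, JSB,
JSA, JLA sit on the last base of the upstream region. A gene "spans" a
junction when it contains both the junction base and the next one; its
`overlap_bp` counts bases strictly inside the IR-side region (IRb at
JLB/JSB, IRa at JSA/JLA), which reproduces the convention "N bp located
within the IR" used for border genes like ndhF and chlL.

## CDS filtering

Codon-usage analysis uses CDS that: are not trans-spliced (their assembled
frame depends on annotation conventions); are unique after collapsing
identical IR duplicates (duplicate sequence would double-weight identical
data); are ≥ 300 bp and a multiple of 3; start with a plastid-code
(table 11) initiation codon ATG/GTG/TTG (an `atg_only` switch provides the
stricter rule); end with a stop; and contain no internal stop. Every
rejection carries a machine-readable reason, checked in the order
duplicate, trans-spliced, too short, frameshift, bad start, no stop,
internal stop — so a 299 bp fragment reports `too_short`, not
`not_triplet`. The terminal stop codon is removed before any codon metric.

## Codon-usage statistics

Each positional statistic is computed over its own codon-exclusion set:

| statistic | excluded codons | scale |
|---|---|---|
| GC1/GC2/GC3 | stops | percent |
| P1/P2/P3 (and P12 = (P1+P2)/2) | ATG, ATA, TGG, stops | fraction |
| A3s/T3s/C3s/G3s | ATG, ATT, ATC, ATA, TGG, stops | fraction |
| GC3s | ATG, TGG, stops | fraction |

RSCU_c = X_c · k / ΣX over each synonymous family of size k; Met and Trp are
reported as 1.0 by convention and unobserved families as NaN, so the family
sum equals k exactly whenever the family is observed (a tested invariant).

ENC follows Wright: per family with n observed codons,
F̂ = (nΣp_i² − 1)/(n − 1); class means F̄k over families with n ≥ 2 and
F̂ > 0 for k ∈ {2 (9 families), 3 (Ile), 4 (5 families), 6 (Leu, Ser, Arg)};
ENC = 2 + 9/F̄2 + 1/F̄3 + 5/F̄4 + 3/F̄6, capped at 61. A missing F̄3 is imputed
as (F̄2 + F̄4)/2; a missing F̄2, F̄4 or F̄6 makes ENC undefined (NaN) — the
table 11 family structure matches the standard code, so Wright's class
weights apply unchanged. Tested anchors: one codon per family gives exactly
20; counts (3,1,0,…) in every degenerate family give exactly 38; 5000
uniform codons land within 0.5 of 61.

## Diagnostics: separating mutation pressure from selection

**ENC–GC3s.** The expected curve is ENC*(s) = 2 + s + 29/(s² + (1−s)²).
Genes whose usage is driven only by third-position composition (parity
A=T, G=C within the eligible pool) trace this curve: the generator's
mutation-only gene set (2000 codons/gene) gives mean |(ENC*−ENC)/ENC*| below
0.02. A strong-selection gene set (one preferred codon per family at 85%)
sits far below the curve, with every deviation positive. Confidence bands
are not drawn: their construction varies between tools and none is defined
well enough to test.

**PR2.** Coordinates are y = A3s/(A3s+T3s) vs x = G3s/(G3s+C3s) with the
exclusion set above, plus a `fourfold_only` switch using the 8 four-fold
codon boxes. The default set keeps 15 T-ending and 15 C-ending but only 13
A- and 13 G-ending eligible codons, so even perfectly uniform usage sits
slightly lower-left of (0.5, 0.5) — a property worth knowing before reading
biology into a lower-left cluster. Under the four-fold restriction parity is
exact, and unbiased simulation gives quadrant counts indistinguishable from
uniform (chi-square, α = 0.01, 200 genes). Ties at exactly 0.5 are labelled
"center".

**Neutrality plot.** Ordinary least squares of P12 on P3 across genes
(scipy linregress), with Pearson r and its exact two-sided t-test p-value
(n − 2 df). The regression requires ≥ 3 genes and var(P3) > 0 and errors
otherwise, naming the condition. Calibration: gene sets in which a
gene-specific mutational GC pressure drives all positions (constraint 0)
recover slope ≈ 0.9; freezing positions 1–2 at a global composition
(constraint 1) gives slope ≈ 0; the slope decreases monotonically in the
constraint. The small shortfall from 1.0 at constraint 0 is attenuation from
sampling noise in P3 at 300 codons/gene. With few genes sharing a single
codon model (the 14-gene study genomes), the regression has no between-gene
signal and its slope mostly reflects within-codon sampling covariance
induced by stop avoidance and the exclusion sets — the calibration gene sets,
not the study genomes, are the meaningful recovery test.

## Nucleotide diversity

π over a window is the mean pairwise proportion of differing sites,
2/[n(n−1)] Σ_{i<j} d_ij, computed after removing every column containing a
gap or N (from numerator and denominator alike, the common DnaSP
convention). Windows are 600 bp at 200 bp steps on alignment coordinates,
starting at column 1 while a full window fits; a window longer than the
alignment collapses to one truncated window. Zero usable sites gives NaN
with `usable_sites = 0`. The genome-wide summary is the mean over windows
(an all-sites alternative is a one-liner via `nucleotide_diversity` on the
whole alignment). The implementation is tested against a naive all-pairs
recount to 1e-12 and against the closed-form star-tree expectation
2p(1−p) + (2/3)p² within 3 SE over 20 seeds. Window labels come from the
midpoint mapped to a reference genome: the covering gene's name, the
flanking pair "upstream~downstream" for intergenic midpoints, or
"unaligned" where the reference row is gapped. Alignments are consumed, not
produced; use any external aligner for real genomes.

## NG86 Ka/Ks

Codon alignment is protein-guided: translate under table 11 (terminal stops
removed; internal stops are an error naming the codon position), globally
align proteins (BLOSUM62, gap open −10, extend −0.5), back-translate, drop
gapped codon columns. Site counting: at each codon position, the synonymous
fraction is synonymous single-base changes over non-stop single-base
changes; a position whose every change creates a stop contributes 0 sites.
S is the average of the two sequences' sums and N = 3·(codon pairs) − S.
Differences are averaged over all orderings of the changed positions,
excluding orderings that pass through a stop codon; under the plastid code
every sense-codon pair keeps at least one stop-free ordering (verified
exhaustively in the tests), so the defensive "fully blocked" branch cannot
trigger on valid CDS. Proportions pN = Nd/N and pS = Sd/S are corrected with
Jukes–Cantor, d = −(3/4)ln(1 − 4p/3); p ≥ 3/4 yields a `saturated` sentinel
and Ks = 0 an `undefined_Ks0` sentinel rather than a division error.
ω = Ka/Ks is classified against a neutral band (default 0.95–1.05).

NG86 was chosen over codon-model (ML) estimators because every intermediate
quantity has a hand-computable oracle; two fully enumerated examples
(TTT/TTA → Ka 0.5716, Ks 0; GGGGGG/GGAGGG → Ks 0.8240, Ka 0) and a
brute-force pathway recount anchor the implementation. One consequence to
keep in mind: pathway averaging ascribes fractional nonsynonymous
differences to some purely synonymous histories inside six-fold families
(AGA→CGA→CGT is all-arginine, yet the averaged count over both orderings is
nd = sd = 1 because the other order passes through serine), so a gene
evolved with ω = 0 estimates as strongly purifying (Ka ≤ 0.05·Ks in the
tests) rather than exactly Ka = 0. Recovery: on simulated pairs at Ks ≈ 0.3
with 500 codons, the median estimate is within 20% of ω for
ω ∈ {0.1, 0.5, 1.0} and ≥ 90% of estimates fall in [ω/2, 2ω].

## The synthetic generator

`simulate_plastome` builds LSC + IRb + SSC + IRa with IRa the exact reverse
complement of IRb, intergenic composition at a given GC (defaults: 0.28
single-copy, 0.46 IR, matching the AT-rich plastome regime), and CDS
sampled from per-position base weights (default third-position GC 0.18,
first/second 0.43/0.37). Genes spanning JSB and JSA share mirrored IR
sequence, so gene sequences are resampled (deterministically, from the same
stream) until every planted CDS survives mirroring; the four bases flanking
the planted repeat are adjusted so the repeat is *maximal*, making the
planted coordinates the unique detection answer. Every operation is a pure
function of (spec, seed).

`diverge_genome` substitutes noncoding sites i.i.d. and proposes coding
substitutions site by site; a proposal drawing base G/C with probability
beta (default 0.25, AT-pressure). Synonymous proposals fix with probability
min(1, 1/ω) and nonsynonymous ones with min(1, ω) — a plain acceptance
probability cannot express ω > 1, whereas this parameterization keeps the
nonsynonymous/synonymous rate ratio equal to ω on both sides of 1. Start
and stop codons are immune so derived CDS stay filter-valid; sites whose IR
mirror image belongs to another gene are frozen so co-mutation cannot break
a reading frame; after mutation IRa is rebuilt from IRb, so the copies stay
exactly reverse-complementary. Substitutions adjacent to a junction can
extend the *maximal* repeat by a few bases, so detected coordinates on
derived genomes may exceed the planted ones slightly — planted-coordinate
recovery is exact for generator output, tolerant (≤ 20 bp) for derived
genomes.

The study conditions (`plastocub.study`): a 23 kb genome (12 kb LSC, 2.5 kb
IRs, 6 kb SSC) with 14 genes of 110–400 codons including an ndhF-like gene
64 bp into IRb and a chlL-like gene 5 bp into IRa; divergence at 0.02
coding / 0.06 noncoding proposal rate per site with ω = 0.15 background and
two genes (ycf66 at 2.0, ndhD at 1.8) under positive selection. These sizes
are scaled to desk scale — roughly a fifth of a real plastome with deeper
divergence than typical congeners — so that structural recovery is exact
while per-gene substitution counts remain large enough for class-level
selection summaries to be informative. At this depth single-pair per-gene ω
is still noisy (small genes often fix no synonymous change, giving Ks = 0
and an `undetermined` call); the analysis therefore reports class-pooled
counts over all genome pairs.

What the generator does **not** emulate, and what passing tests therefore do
not show about real data: no indels (so "alignment" is trivial and the π
machinery's gap handling is exercised only by constructed tests, not by the
study); no tRNA/rRNA genes — in particular the simulated IR is mostly
intergenic and diverges at the noncoding rate, whereas real IRs are
rRNA-rich and markedly less diverse than single-copy regions; no
amino-acid-composition differences between genes, so between-gene codon-
usage variation is purely sampling; no rate heterogeneity along the genome
beyond the coding/noncoding contrast; and mutational GC bias is a single
global beta, not context-dependent.

## Reproducibility

All randomness flows through explicit `numpy.random.default_rng` seeds;
report writing uses stable sort orders and fixed float formats (GC to 1
decimal, π to 4, ENC and rates to 4), so identical inputs give byte-identical
TSV/JSON output. `scripts/acceptance.py --seed N --out f.json` recomputes
the headline quantities from scratch in a few seconds; the analysis scripts
regenerate the study genomes from one fixed seed rather than passing
intermediate files.
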