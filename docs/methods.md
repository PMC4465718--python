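# Methods

## Overview

The package is organized as an analysis project: every computation lives in
the library (`src/hpsirna/`), the numbered scripts under `analysis/` are
narrative drivers, and a click CLI exposes the same stages for file-based
use. The pipeline has four layers: construct geometry, generative simulation,
exact read processing, and the descriptive analyses (profiles, cleavage,
methylation).

## Coordinates and alphabet

All coordinates are 1-based inclusive; conversion to 0-based half-open
happens only inside slicing code. The internal alphabet is uppercase DNA; U
is accepted on input and mapped to T (siRNA tables are customarily printed
as RNA, references as DNA), and candidate tables are rendered back as RNA.
Ambiguity codes (N etc.) are never treated as matching anything, including
themselves: in ungapped identity computation they count as mismatches, and
in methylation context classification they flag the site ambiguous. This is
deliberately conservative and keeps every comparison reproducible.

## Construct model

A `HairpinConstruct` is a validated T-DNA annotation: exactly one forward
arm, one loop intron and one reverse arm; equal arm lengths; the reverse arm
must be the exact reverse complement of the forward arm; the loop must lie
strictly between the arms; elements must be sorted and non-overlapping.
Each violated invariant raises a distinct error naming the element, so a
malformed element table fails loudly at load time rather than corrupting
coordinates downstream.

Ungapped identity between equal-length regions is
`100 × (L − mismatches) / L`; with the default 318-nt region, the divergent
family members at 96.5 % and 84.3 % identity carry exactly
`round(318 × 0.035) = 11` and `round(318 × 0.157) = 50` substitutions. A
318-nt stem supports `318 − 21 + 1 = 298` distinct 21-nt windows per strand;
the package counts windows on one strand, with the opposite strand handled
by the sense/antisense label rather than by doubling the enumeration.

## Synthetic data generator

The generator emulates the study conditions; all of it is a pure function
of (parameters, seed), and every sampled read carries a ground-truth origin
label (`stem_sense`, `stem_antisense`, `loop`, `transitive`, `background`)
that reconciles exactly with the emitted FASTQ.

**Dicing model.** Read lengths are drawn from a fixed size mixture over
18–25 nt; the default concentrates mass as 21 > 22 > 24
(0.55 / 0.18 / 0.12, small tails elsewhere), the DCL4 > DCL2 > DCL3 pattern
expected for an exogenous hairpin substrate. Per-window abundance is latent
log-normal (σ = 1.5), which reproduces the observed shape — a few prominent
siRNAs over a broad low-abundance floor — without asserting a mechanistic
law. Hot windows (defaults 80, 145, 275, the documented sense peaks) receive
`hotspot_concentration ×` the *mean* background window weight
(default 100×), so they dominate the profile by construction rather than by
lottery against the log-normal tail. The latent weights are drawn from a
separate `weights_seed`: lines sharing a `weights_seed` share the dicing
pattern — it is a property of the hairpin substrate, not of the sample —
while their reads remain independently sampled. This is what makes the
between-line top-N overlap high at depth, as observed in real line
comparisons. Guide-strand asymmetry is a single antisense fraction
(default 0.45, slightly under one half). Loop-derived reads (rate 0.005),
transitive reads (rate 0.01, drawn on both strands strictly outside the
buffered target region of a uniformly chosen transcript) and genomic
background reads (rate 0.10) complete the library. Base qualities are
constant; sequencing error, adapters and PCR duplicates are not modeled.

**Default scenario.** Three RNAi lines and a wild type. The high-expressing
line is simulated at 2×10⁵ reads and the others at 5×10⁴ — depths chosen as
desk-scale stand-ins that keep every recovery statistically comfortable
while the full pipeline runs in seconds; the wild type is 98 % genomic
background with a thin endogenous stem signal. The stem carries one
non-random anchor: the 40-nt sense segment reconstructed from the published
20-candidate siRNA table, planted at stem position 280 so that the cleavage
analysis has a realistic sequence context. The segment's final base falls
at position 319 and is truncated against the 318-nt stem; consequently the
20th qualified candidate window (start 299, end 319) can never be observed
from a strictly 318-nt stem, and the simulated scenario recovers 19 of 20
candidates. The published table itself implies siRNA windows extending one
base past the nominal region end — the package reproduces the full set of
20 from the printed table and the maximum producible set of 19 from the
simulated stem, and reports both.

**RACE model.** Each clone is directed cleavage with probability
`1 − degradation_fraction` (a weighted choice among dinucleotide cut sites)
or uniform degradation over a configurable span that may extend outside the
target region. Line-specific defaults plant the two major sites 297–298 and
301–302 (dominant in two lines), a degradation-prone shared site 274–275
(dominant in the third), and clone counts in the low twenties per line; the
wild type is pure degradation.

**Bisulfite model.** Every reference cytosine is methylated with its
context probability; unmethylated cytosines convert to T with probability
`conversion_rate`. Incomplete conversion therefore inflates apparent
methylation by the closed form `apparent = p + (1 − p)(1 − conversion_rate)`,
which the tests verify at conversion 0.98. Planted per-line probabilities
make transgene methylation anticorrelated with transgene expression (the
most silenced line is the most methylated) and give the endogenous promoter
~20 % methylation in one line only.

## Read processing

Reads are collapsed to distinct sequences with counts; reads outside
18–25 nt are dropped and tallied. Mapping is exact and full-length via a
hash index of every forward-strand k-mer (k = 18..25) of every reference: a
query is sense where it equals a stored k-mer and antisense where its
reverse complement does, which makes strand assignment involutive by
construction. Palindromic reads are reported once, as sense. The index is
checked against an independent scan-every-position oracle in the tests.

Any read from the inverted repeat necessarily matches both arms of the
construct (one forward, one as reverse complement). Hits are collapsed to a
single record in forward-arm stem coordinates (1..L) with strand defined
relative to the target mRNA, matching the single-axis ± convention of stem
profile plots. Multi-mapping across homologous family members is allowed
and reported per reference; there is no best-hit selection, because
off-target analysis re-maps the same siRNA set to each homolog
independently.

The CPM denominator is the count of 18–25-nt reads with at least one exact
genome hit, computed once per library. The synthetic genome includes the
background contig, the endogenous target loci and the integrated transgene,
so in simulation the denominator equals the library size and CPM recovers
read fractions exactly (conservation is asserted in the tests). Rendered
CPM values round half-up to two decimals (0.125 → 0.13).

## Profiles

Positional profiles are keyed by read start position (the 5′-most base on
the reference sense axis) — the axis convention is a documented choice, as
is counting the between-line Venn over sequences rather than
(sequence, strand) pairs. Replicate averaging is the arithmetic mean of
per-replicate CPM with missing sequences contributing zero. Hot spots are
operationalized as positions holding at least `min_fraction` (default 0.05)
of their strand's total CPM — a declared, configurable stand-in for what is
judged visually in practice. Top-N ties at the CPM boundary break
lexicographically for determinism. In the transitivity partition, a window
overlapping the target region or within 20 nt of its edges is classed
inside: a straddling or boundary-hugging read is not evidence of RdRP
activity, so "outside" is reserved for windows clear of the buffered region.

## Cleavage analysis

Clone termini are tallied per sample into per-site fractions; inside /
outside classification uses the target region on the same axis, and a site
is conserved only under exact dinucleotide equality across every sample of
the designated set (no ± slop), so the conserved set shrinks monotonically
as samples are added. Reports convert transcript-axis positions to the
1..318 region axis (degradation termini upstream of the region legitimately
render as coordinates below 1).

The candidate rule: window `[s, s+k−1]` qualifies for cut `(i, i+1)` iff
the offset `j = i − s + 1` lies in `[excl+1, k−excl−1]` — equivalently,
both nucleotides flanking the cut sit outside the terminal `excl` positions
at either window end. With k = 21 and excl = 2 one site admits 16 windows
and two sites distance d apart admit `(k − 2·excl − 1) + d` (= 20 at d = 4);
windows qualified by both sites count once. Selection intersects these
windows with the *observed* 21-nt antisense siRNAs and ranks by CPM in a
designated reference sample, ties lexicographic. The published 20-candidate
table ships as a packaged fixture (FASTA + CPM TSV); its sequences
reverse-complement-assemble by exact 20-nt overlap into one contiguous
40-nt sense segment with consecutive offsets 1..20, and feeding its printed
CPM column through the selection reproduces its rank order exactly.

Expected RACE product sizes take the adapter/primer extents as inputs
(primer designs are experiment-specific): `min = upstream + downstream`,
`max = min + region_length`, so the range width always equals the region
length.

## Methylation analysis

Context is computed on the reference, never the clone, because conversion
destroys the context. A following G decides CGN regardless of the third
base; cytosines whose deciding bases run past the 3′ end are flagged edge,
and non-ACGT deciding bases flag the site ambiguous — both are reported but
excluded from context percentages. Clones must be gapless and
length-matched (short amplicons are assumed pre-aligned; indel-containing
clones are rejected rather than realigned, keeping the caller exact). At a
reference cytosine, clone C counts methylated, T converted, anything else
is an excluded ambiguous call. Per-context percentages are pooled
(`100 × Σ methylated / Σ calls`); replicate clone sets can be pooled or
compared side by side via the long-format region comparison. No
significance machinery is attached: the outputs are descriptive
percentages.

## Numerical and testing choices

Determinism is enforced throughout: every simulator consumes an explicit
integer seed (no wall-clock seeding), hypothesis property tests run
derandomized, and the CLI's end-to-end determinism is asserted via checksum
manifests. Statistical recovery tests use binomial/multinomial 99 %
intervals at the planted parameters. Problem sizes in the tests and the
acceptance script (depths 5×10⁴–2×10⁵, 1000 RACE clones, 10–50 bisulfite
clones, 10⁴ mapper-oracle queries) are chosen so sampling error is far
below the assertion margins while the full suite stays fast.

## Known limitations

- The mapper is exact-match only; mismatch-tolerant alignment is out of
  scope, so sequencing error would deflate mapped fractions in real data.
- The simulator does not model adapter contamination, quality decay or PCR
  duplication; passing recovery tests demonstrates correctness of the
  analysis logic under the generative model, not robustness to artifacts of
  real libraries.
- Hot-spot calling is threshold-based and scale-free but has no
  significance model; prominent heavy-tail windows (like position 274 in
  the worked example) legitimately exceed the threshold.
- Degradation versus directed cleavage is reported, not adjudicated: the
  shared 274–275-type site appears in both RNAi and wild-type tallies and
  its attribution is left to the user.
- The transitive-read generator places secondary siRNAs uniformly outside
  the target region; real RdRP processivity is position-biased.
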