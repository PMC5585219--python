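# Methods

This note documents the models and procedures implemented in `barduplex`,
the defaults chosen where the design was genuinely open, and what the
synthetic-data tests do and do not demonstrate about real libraries.

## Adapter model

A semi-degenerate barcode is an IUPAC pattern whose positions each allow
a restricted base set; the shipped v2 design (`WSMRWSYWKMWW`, 12 nt, all
two-fold codes) spans 2¹² = 4,096 sequences per adapter, and the minus
oligo carries the reverse-complement pattern (`WWKMWRSWYKSW`). The legacy
v1 design is `WSWSW` (32 sequences). Degenerate positions are sampled
uniformly by default; per-position weight vectors can emulate the skewed
base ratios that machine-mixed oligo synthesis produces, but no published
table of those ratios exists, so uniform is the default.

Strand tags: each adapter couples one "plus" and one "minus"
tri-nucleotide tag from a permitted table. The shipped default derives
from a pool of six plus and four minus tags with exactly 19
non-complementary combinations (pairs excluded when one tag is the
reverse complement or the position-wise complement of the other). In this
package's read model one tag combination labels a molecule: reads from
the plus strand present `(plus_tag, minus_tag)` in 5′→3′ order and reads
from the minus strand present the swapped pair, so orientation is
assigned from the tags alone before alignment. Real Illumina chemistry
reads both strands from the P5 oligo, making mapping orientation the
ultimate arbiter; the tag-based contract used here is a deliberate
simplification that keeps read preparation independent of alignment, and
alignment orientation remains available as a cross-check.

UID diversity statistics (`uid_diversity_stats`) count multiplicities
before deduplication; the mean pairwise Hamming distance is computed
exactly from per-column base counts (O(N·L)), while the pairwise-distance
SD falls back to a seeded subsample of pairs above 8×10⁶ pairs. For
uniform two-fold degenerate positions the expected pairwise distance is
L/2 — 6.0 for the 12-nt barcode, 12.0 for the 24-nt combined UID — which
is what makes random UID collisions recognisable.

## Simulator

The generator emulates a capture-enriched cfDNA library:

* **Fragments**: length ~ Normal(170, 10) bp (rounded), one targeted
  site per locus on a deterministic pseudo-random 5×1 kb reference;
  fragments are placed uniformly around their site so it lies ≥10 bp from
  either end. The alt allele is carried with probability VAF.
* **Adapters**: each end draws a plus-oligo barcode from the pattern; the
  annealed minus oligo is its reverse complement except at mispaired
  positions, drawn per position from a profile that decreases toward the
  ligation site (defaults 0.28→0.09 over the outer six positions,
  0.035→0.005 over the terminal six). A mispaired position carries the
  complement of the *other* base the pattern allows there, so the
  canonicalised barcode still conforms to the pattern. The defaults were
  calibrated once so that ~80% of duplexes show zero terminal artifacts
  and most show ≤3 over all 24 positions, matching the artifact load
  observed in real libraries.
* **Amplification**: each parental strand independently draws a family
  size; the default zero-inflated negative binomial (p₀ = 0.25, mean 8,
  dispersion r = 4) reproduces both a read-weighted peak family size in
  the 6–12 range and duplex recovery below 50% (dropout q per strand
  implies recovery ≈ (1−q)/(1+q) before the ≥3-read filter). `fixed` and
  `poisson` models are available for controlled experiments.
* **Errors**: oxidative damage is applied once per molecule, pre-PCR, as
  C→A on the minus strand's insert (default rate 3×10⁻⁴ per C) — in
  reference orientation this is a G>T excess confined to minus-strand
  families, which is exactly what duplex consensus cancels. Polymerase
  errors (default 10⁻⁴/base) are drawn independently per read copy and
  sequencing errors (default 10⁻³/base) per read. Qualities are constant
  Q30.

Reads are emitted PE150 phred33 as `tag + barcode + T + insert + A +
minus-oligo block`, with the molecule id in the FASTQ comment and every
error recorded in the truth table. Identical config + seed reproduces
byte-identical output.

**What the simulator does not model**: shared early-cycle PCR "jackpot"
errors (copies err independently, so SSCS suppression is stronger in
simulation than on real data), indels, cycle-dependent quality decay,
capture chemistry and bait-efficiency variation, and adapter dimers.
Passing tests therefore demonstrate the pipeline's logic — accounting,
thresholds, cancellation properties, monotone error suppression — not the
absolute error rates achievable on patient libraries (~10⁻⁵ after SSCS
and ~10⁻⁶ after duplex consensus in published data), which desk-scale
synthetic runs cannot and do not reproduce.

## Read preparation

Merging scans every ungapped suffix/prefix overlap ≥30 nt and keeps the
one with the lowest mismatch fraction (≤0.1; ties to the longest);
disagreements take the higher-quality base, R1 winning ties. The
permissive defaults are safe because family clustering re-filters at 1%.
Pairs that fail to merge are routed to the reject bucket: with ~170 bp
inserts and PE150 every true pair overlaps by ~96 nt, so non-merging
indicates a defective pair rather than a long fragment. (Gap characters
remain first-class in consensus building, so gapped pseudo-merged input
from longer-insert protocols remains representable.) Barcodes failing
pattern validation reject the read (`barcode_pattern`; ~2% at default
error rates), and the first/last 2 insert bases are soft-trim masked —
excluded from error denominators and variant calls, not removed from
alignment — because end-repair concentrates artifacts there.

## Consensus and duplexes

Alignment is glocal (infix) edit-distance alignment of each insert
against every locus and strand via edlib; reads above 5% edit distance
are off-target. Coordinates are 0-based half-open internally and 1-based
in reports. Families are exact-coordinate buckets (locus, strand
orientation, start, end) refined by single-linkage UID clustering at
`max(1, ⌊0.01 × tagged-read length⌋)` mismatches; the production
incremental clustering is checked against an independent full-matrix
closure in the tests. SSCS consensus is count-based plurality (not
quality-weighted, matching the constant-Q simulator); any exact tie —
including ties among >2 bases — becomes `N`, recorded as ambiguous.

Duplex matching buckets SSCS by coordinates and ranks opposite-strand
candidate pairs by Hamming distance over the duplex key (terminal six
barcode positions per ligation site, half-swapped for minus-strand
records so true partners compare position-by-position), accepting ≤2
mismatches over the combined 12 positions. A per-6-block mode is
available (`per_block_key`) for the stricter reading of the rule. Key
ties fall back to the full 24-nt UID distance; exact ties on both leave
all contenders unpaired (greedy minimum-distance matching, deterministic
and order-independent; buckets are small enough that global optimal
assignment would change nothing in practice). Candidate pairs with
full-UID distance >5 are flagged spurious: true duplexes almost always
show ≤5 annealing mispairings while random coordinate collisions average
~12/24 mismatches, and the ~1.9% of random pairs that slip past the
12-position key (P[≤2 mismatches] = Σ₀²C(12,k)/2¹²) are exactly what
this second threshold removes. For the v1 design the key is the full 5+5
barcode with the same ≤2 tolerance. Note the spurious filter also
sacrifices the few true duplexes with ≥6 mispairings — the same trade the
threshold makes on real data.

## Quantification

VAF = n_alt / (n_ref + n_alt + n_other): third alleles count in the
denominator, ambiguities (`N`, gaps, soft-trim-masked site bases) do
not; a record whose site base is masked is tallied as ambiguous so the
per-site counts always sum to the number of spanning records. A site
covered by no record reports VAF as NA. High confidence requires duplex
support (≥1 alt duplex by default; `min_duplex_molecules` raises the
bar). Error profiles count non-reference calls per substitution class in
reference orientation over all non-excluded, non-masked, unambiguous
bases; C>A and G>T are tracked separately to expose damage asymmetry.
The "raw" profile applies the same masking to aligned merged reads before
any consensus, giving the raw ≥ SSCS ≥ duplex comparison a common
denominator definition. Replicate summaries use the sample SD (n−1);
expected copies from input mass are `round(ng × 1000 / pg_per_haploid)`
with 3.3 pg per haploid genome.

## Problem sizes and numerical choices

Test and acceptance runs use 40–300 molecules, family sizes 4–8, 5×1 kb
loci and 10-seed replications — sizes at which every distributional check
(binomial alt counts, family-size goodness-of-fit, mispair-profile
recovery, VAF interval coverage) has adequate power while the whole suite
runs in well under a minute. Monte-Carlo UID-distance estimates use
10,000–12,000 barcodes with the exact all-pairs column-count formula, so
the only stochastic error is barcode sampling itself. All tie-breaks
(consensus bases, bucket ordering, candidate ranking) are lexicographic
and documented in the code, making every pipeline stage deterministic
for a fixed seed.

## Known limitations

* No indel simulation or indel-aware consensus beyond tolerating gap
  columns; insertion/deletion error classes are reported but always zero
  on simulated data.
* Independent per-copy polymerase errors overstate SSCS suppression (see
  above).
* Tag-based orientation is a simplification of the physical read
  geometry (see Adapter model); libraries whose two adapters carry
  different tag combinations would need mapping-orientation assignment.
* Genome-scale alignment is out of scope: the glocal aligner expects a
  concatenated target reference of desk scale (loci ≲10 kb), as used for
  personalized panels; real whole-genome BAMs should be pre-filtered to
  on-target reads by a production aligner first.
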