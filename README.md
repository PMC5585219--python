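# barduplex

Error-suppressed quantification of circulating tumor DNA (ctDNA) from
targeted sequencing libraries built with **semi-degenerate barcoded
adapters**, plus a synthetic read simulator so the entire pipeline is
testable end-to-end without any external data.

## The problem and the method

Detecting tumor-derived mutations in plasma cell-free DNA (cfDNA) at
variant allele fractions (VAF) below 0.1% requires suppressing the
substitution errors introduced by DNA damage, PCR and sequencing. The
approach implemented here tags every original cfDNA duplex before
amplification with a pair of semi-degenerate barcodes — each of the 12
positions allows a two-letter IUPAC set (`WSMRWSYWKMWW` on the plus
oligo), giving 2¹² = 4,096 barcodes per adapter and 2²⁴ combined unique
molecular identifiers (UIDs) — together with non-complementary
tri-nucleotide strand tags that keep reads from the two parental strands
in separate PCR families.

The pipeline then:

1. **merges** overlapping read pairs and extracts/validates tags and
   barcodes (`readprep`);
2. **groups** reads into PCR families by mapping coordinates, strand and
   UID (single-linkage at 1% of the tagged read length) and calls a
   **single-strand consensus sequence (SSCS)** per family of ≥3 reads by
   per-column plurality, with exact ties marked `N` (`consensus`);
3. **matches opposite-strand SSCS into duplexes** using only the six
   barcode positions adjacent to each ligation site (6+6 = 12 nt), where
   adapter-annealing mispairings are rarest, tolerating ≤2 mismatches;
   candidate pairs whose full 24-nt UID distance exceeds 5 are flagged as
   spurious coordinate collisions (random UID pairs differ at ~12 of 24
   positions). Strand disagreements in the duplex consensus become
   ambiguities, which cancels strand-asymmetric artifacts such as
   8-oxoguanine-driven C>A calls (`duplex`);
4. **quantifies**: per-site molecule counts and VAF = alt/(ref+alt+other)
   at both consensus levels, duplex-support flags (a call is
   high-confidence only when both parental strands support it), and
   background error profiles per substitution class (`quantify`).

Duplex recovery is accounted as: with `n_fwd` forward and `n_rev` reverse
SSCS and `d` assembled duplexes, unique molecules = `(n_fwd−d) + (n_rev−d)
+ d` and recovery rate = `d / unique`; e.g. 1,000 + 1,000 with 600
duplexes → 1,400 unique molecules, rate 0.4286.

The `simulate` module generates ground-truthed paired FASTQ: ~170 bp
duplex fragments with a spiked-in variant at a chosen VAF, per-end
barcodes with position-dependent annealing mispairings (decreasing toward
the ligation site), zero-inflated negative-binomial PCR family sizes
(dropout models sub-50% duplex recovery; peak family size 6–12),
pre-amplification C>A damage on the minus strand, and per-copy
polymerase plus per-read sequencing errors.

## Worked example

```sh
barduplex simulate --out sim --seed 7 --n-molecules 200 --vaf 0.05
barduplex call --r1 sim/reads_R1.fastq.gz --r2 sim/reads_R2.fastq.gz \
    --reference sim/reference.fasta --targets sim/targets.bed --out call
```

The call step prints a run summary (abridged):

```json
{
  "reads_in": 2402, "merged": 2351,
  "rejected": {"barcode_pattern": 51},
  "families": 315, "sscs": 277,
  "sscs_fwd": 139, "sscs_rev": 138,
  "duplexes": 95, "spurious_pairs": 2,
  "unique_molecules": 182, "duplex_recovery_rate": 0.522
}
```

2,402 read pairs collapse to 277 single-strand consensus sequences, of
which 95 forward/reverse pairs assemble into duplexes (recovery 0.52);
~2% of reads are discarded for unexpected bases at barcode positions.
`call/calls.tsv` then reports per site, e.g. for the locus3 target
(simulated VAF 0.05):

```
locus3  501  T  A  sscs    62  6  0  0  0.088  True  True
locus3  501  T  A  duplex  22  2  0  0  0.083  True  True
```

six of 68 SSCS molecules and two of 24 duplex molecules carry the alt
allele, and the duplex support marks the call high-confidence.
`call/error_profiles.tsv` shows the error-suppression hierarchy the
method exists for — here raw reads 1.2×10⁻³, SSCS 4.4×10⁻⁵, duplex 0 —
and `calls.vcf` carries the same counts as a minimal VCF 4.2.

`barduplex stats` adds family-size histograms, UID-diversity and
annealing-mispairing reports; `barduplex adapters` summarises an adapter
design (barcode space, sampled mean pairwise UID distance ≈ 6.0 for the
12-nt pattern).

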