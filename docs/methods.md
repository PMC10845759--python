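# Methods

## Setting and model

The package analyses a haplotype-resolved autotetraploid gene complement:
four chromosome sets (hapA–hapD) that became one nucleus recently enough
that allelic gene copies are nearly identical (synonymous divergence of
order 10⁻²), while two older whole-genome duplications have left paralog
pairs at much larger distances inside every haplotype. *Alleles* are
homologous genes occupying the same locus on homologous chromosomes of
different haplotypes; genes without any allelic partner are *singletons*.

Three quantities carry the analysis: (i) collinearity of gene order
between haplotypes, which identifies loci; (ii) the synonymous
substitution rate K_s between gene pairs, whose distribution modes date
duplication events through T = K_s/(2r); and (iii) allelic read counts
across RNA-seq stages, which expose expression imbalance.

## Allele identification

Protein sequences are compared by global alignment (BLOSUM62, affine
gaps, open 10 / extend 1); percent identity is matches over alignment
columns, with terminal gaps counted. Exhaustive all-versus-all alignment
is avoided by a 4-mer prescreen that keeps the best 5 candidate partners
per gene before reciprocal-best-hit (RBH) resolution; the candidate union
is taken in both directions so the anchor set is symmetric in the two
haplotypes. Ties are broken lexicographically by gene id, making every
step deterministic.

Anchors of one chromosome pair are chained by dynamic programming over
gene-order indices: a chain must advance in both genomes (decreasing in
the second for inverted blocks) with at most `max_gap = 10` intervening
genes per step; chains are extracted best-first until none reaches
`min_block = 4` anchors, and each anchor joins at most one block. On
anchor sets small enough to enumerate, the DP provably returns the
maximum chain (tested against exhaustive search).

The allele table is the set of connected components of the in-block
anchor graph. A component holding two genes of one haplotype is split by
removing its lowest-identity edge (ties by gene-id pair) until the
one-gene-per-haplotype constraint holds. Homologous-group consistency is
*reported*, not enforced: a translocated allele supported by synteny
remains an allele. Singletons are classified by their best homolog among
all other genes (identity strictly above 80%), the homolog locus's allele
class, group retention, and an inversion flag comparing the singleton's
strand with the consensus strand relation of the nearest synteny block on
its chromosome (within 50 genes; `False` if no block is near).

## K_s estimation and dating

Gene pairs are protein-aligned and back-translated to codons; columns
with a gap, stop or ambiguous base are dropped. NG86 counting: each codon
position contributes one site, split synonymous/nonsynonymous by the
fraction of its non-stop single-nucleotide changes that preserve the
amino acid; differences between codons average the synonymous and
nonsynonymous steps over all minimal substitution paths, excluding paths
through stop codons (under the universal code no sense-codon pair loses
all its paths — asserted exhaustively in the tests). pS = S_d/S is
corrected with K_s = −(3/4)ln(1 − 4pS/3); pS ≥ 3/4 marks the estimate
undefined. NG86 was fixed as the estimator because it is fully
specifiable and oracle-checkable; the record carries a `method` tag so
ML estimators could be added alongside.

Peak detection filters K_s to (0, 2.0] — exact zeros are identical-gene
artifacts — and evaluates a Gaussian KDE (Silverman bandwidth) on a fixed
2048-point grid over [0, 2]; when the Silverman bandwidth would fall
below one grid step (degenerate spread) the kernel is floored at one grid
step so tight clusters still register. Peaks are local maxima at ≥10% of
the global maximum; the primary mode is the global one. A log₁₀ option
exists for widely separated old peaks. Dating is the linear map
T = K_s/(2r), default r = 3.39×10⁻⁹ sub·site⁻¹·yr⁻¹, reported in years
and rounded Mya.

## Allele-specific expression

Counts are TPM-normalised (rate count/length, scaled to 10⁶ per sample).
Within a stage, replicate counts are pooled and every allele pair of a
locus is tested with an exact binomial test whose null proportion
L_i/(L_i+L_j) absorbs gene-length differences; the fold change uses mean
TPM with a 0.1 pseudo-TPM (zero-versus-zero pairs are skipped). The
binomial test was chosen because the decision thresholds (|log₂FC| > 1,
P < 0.05, FDR < 0.05) are fixed but no specific test accompanies them;
it is recorded in the output metadata. Four-allele loci are tested over
all six pairs and judged by the best pair — the criterion is phrased
between *two* alleles. BH correction pools all locus×stage×pair tests of
the run (one FDR column in the output). Consistent ASEGs are significant
at every stage with one dominant allele; inconsistent at ≥1 stage
otherwise; balanced never.

Nominal error control applies to the per-record (locus×stage) decision.
Because negative-binomial counts are overdispersed relative to the
binomial null, the P-gate alone is anti-conservative; in practice the
fold-change gate does the filtering and the per-record false-positive
rate on balanced loci stays near or below the nominal 5% (measured
≈3–5% under the default generator conditions). The *locus-level* share
of loci ever significant across four stages is correspondingly higher
than the planted ASE fraction — a union over four decisions, not a
5%-level test — which is why the run summary's percent-significant
exceeds the planted 5.4% on synthetic data. A replicate-aware
overdispersed test (e.g. beta-binomial) would tighten this and is the
main known limitation.

## Family rules and chromosome landmarks

NLR candidates are proteins with ≥1 NB-ARC domain; classes follow the
presence of TIR, coiled-coil (CC) and LRR: NB-ARC alone → NBS, +TIR →
TIR-NBS, +CC → CC-NBS, +LRR → NBS-LRR, +CC+LRR → CNL, +TIR+LRR → TNL.
CC status is an input flag (coiled-coil prediction is outside scope); an
RPW8 domain also confers CC by default (configurable). TIR and CC
together resolve TIR-first (rare, logged). Any Pfam family starting with
"LRR" counts as LRR; all remaining domains are reported as integrated
domains, never invented. CBF/DREB1 calls require an AP2 domain with
DSXWR (X any residue, exact elsewhere) N-terminal of the AP2 envelope
and the 16-residue signature PKKPAGRKKFRETRHP C-terminal of it, matched
by sliding Hamming distance with ≤5 mismatches (no indels; tolerance and
sidedness are configurable because canonical CBF architecture, not a
stated convention, fixes them). Promoter scans take 3 kb upstream,
strand-aware, and report exact motif positions (GATAA by default).

Telomeres: terminal 50-kb windows are scanned for tandem runs of the
7-bp plant unit (CCCTAAA rotations at 5', TTTAGGG at 3'); a run extends
unit-by-unit while each unit stays within ⌈0.1·7⌉ = 1 mismatch and the
cumulative mismatch fraction within 10% — the per-unit cap stops runs at
the array edge instead of letting a long clean array bankroll extension
into unrelated sequence. Calls need ≥50 copies (the copy threshold is a
parameter; only the unit and the 50-kb window are given by convention).

Tandem arrays: the sequence is compared with itself at every period
2–200; runs where the period-smoothed self-match density stays ≥80% and
the span reaches 500 bp become arrays, reported at the smallest
explaining period, with homopolymers excluded by a period-1 prescan and
a per-column-majority consensus monomer. The centromere candidate is the
maximal run of 100-kb sliding windows (step 10 kb) with tandem-repeat
coverage ≥30%, clipped to the densest cluster of arrays inside it (so a
telomere run caught by the same window cannot stretch the call);
the representative monomer comes from the highest-copy array. One
candidate per chromosome is returned. This seeded detector replaces a
full tandem-repeat finder and is validated on synthetic fixtures only.

## Synthetic generator

The generator emulates the statistical structure the analysis targets,
with every event written to a truth ledger keyed by gene id:

| parameter | default | meaning |
|---|---|---|
| n_chromosomes × genes_per_chromosome | 4 × 150 | ancestral loci per haplotype |
| codons_per_gene | 200 | CDS length (600 nt) |
| ds_allelic | 0.007 | pairwise allelic K_s (tetraploidization) |
| ds_alpha / ds_beta | 0.127 / 0.50 | pairwise paralog K_s of the two WGDs, via T = K_s/2r at ~18.7 / ~73.7 Mya |
| omega | 0.15 | dN/dS of the substitution process |
| loss to 3/2/1 alleles | 0.10 / 0.12 / 0.20 | per-locus allele-loss probabilities (58% of loci keep 4) |
| inversion / translocation rate | 0.08 / 0.02 | fraction of genes in 6-gene rearranged segments per non-reference haplotype |
| ase_fraction / effect | 0.054 / 2.0 | share of four-allele loci with a 2^2-fold dominant allele |
| nb_dispersion | 0.1 | NB overdispersion of counts (stages × replicates = 4 × 3) |
| telomere_copies / centromere_copies | 80 / 300 | planted landmark sizes (monomer 150–180 bp) |

Codon evolution is event-based rather than a full Markov codon model:
synonymous and nonsynonymous substitution counts are Poisson-distributed
with expectations dS·S and ω·dS·N (S, N the NG86 site totals of the
input), allocated to codons by site weight and applied as random
non-stop single-nucleotide changes, so multiple hits occur and the
Jukes–Cantor correction of the estimator faces exactly the process it
assumes at this scale. Because tetraploidization adds dS_allelic on top
of a paralog pair's divergence, the ancestral duplicate branch is planted
at dS_event − dS_allelic so the *observed* pairwise divergence lands on
the configured value. Rearranged segments are 6 genes long — long enough
that one allele loss inside a segment still leaves a chainable block
(min_block = 4) — planted on haplotypes B–D with hapA as the reference
frame. Planted singleton copies (tandem: adjacent, same chromosome;
relocated: uniformly chosen other chromosome) diverge dS 0.02 from their
source so the true allele always wins the RBH and the copy stays above
the 80% homology threshold. Expression programs are shared across a
locus's alleles (lognormal base, median 300 counts, σ = 1; lognormal
stage multipliers); ASE loci multiply the dominant allele's mean by
2^effect, with the dominant haplotype fixed across stages for planted
consistent loci (half of planted loci by default — the published
consistent:inconsistent ratio is an outcome on real data, not a design
parameter, and both classes need enough loci to score recovery) and
re-drawn per stage otherwise. The NB dispersion and sequencing depth are
not documented for the motivating dataset; the defaults above are stated
as configuration, not as claims about it.

What the generator does **not** emulate: realistic intergenic or TE
sequence, codon-usage and GC structure, mapping ambiguity between
near-identical alleles (counts are generated per gene, whereas real
allele-level quantification must disambiguate reads), expression
correlation between stages, and assembly errors. Passing recovery tests
therefore demonstrates correctness of the algorithms under the stated
statistical structure, not robustness to real-data artifacts.

## Problem sizes and determinism

Default runs use 600 ancestral loci (~1,900 genes, ~2,450 allelic pairs,
~310 paralog pairs, 16 chromosomes of ~180 kb) — sizes chosen so the
full pipeline completes in about a minute on one CPU while keeping
binomial error on the recovered fractions a few percent. All randomness
flows from one master seed through named spawned streams (genome,
structure, chromosomes, expression), so a seed fixes every output
byte-for-byte; pipeline stages cache on a config hash and reruns with an
unchanged configuration reload existing tables.
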