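# polyka

Comparative analysis of haplotype-resolved autotetraploid genomes, built
around the recently tetraploidized kiwiberry (*Actinidia arguta*) setting:
four highly homogeneous haplotypes (hapA–hapD) whose gene complements
descend from shared whole-genome duplications (WGD), with allele loss,
segmental rearrangement and allelic expression imbalance accumulating
since the genome doubled.

The package is aimed at genome projects that have phased an autopolyploid
assembly and want to answer, reproducibly and at desk scale:

* **Which genes are alleles of one locus?** Reciprocal-best protein
  anchors between each haplotype pair are chained into collinear synteny
  blocks; connected components of in-block anchors (at most one gene per
  haplotype) become loci with 4, 3 or 2 alleles, the rest are singletons.
* **When did the WGDs and the tetraploidization happen?** Gene pairs are
  codon-aligned and their synonymous divergence estimated with the
  Nei–Gojobori (1986) method: per-codon synonymous site counts
  S = Σ fᵢ, path-averaged difference counts S_d, pS = S_d/S, and the
  Jukes–Cantor correction K_s = −(3/4)·ln(1 − (4/3)·pS). Modes of the
  K_s kernel-density estimate are converted to time with
  **T = K_s / (2r)**, r = 3.39×10⁻⁹ substitutions·site⁻¹·year⁻¹.
* **Which loci show allele-specific expression (ASE)?** Per locus and
  stage, pooled replicate counts of each allele pair are compared with an
  exact binomial test (null proportion L_i/(L_i+L_j) adjusts for gene
  length); a locus is significant when its best pair has |log₂FC| > 1,
  P < 0.05 and Benjamini–Hochberg FDR < 0.05, and is a *consistent* ASEG
  if one allele dominates every stage, *inconsistent* if dominance
  switches.
* **Where did singletons come from?** Best-homolog search (>80% global
  alignment identity) against allele-bearing loci, homologous-group
  retention and strand-versus-synteny orientation separate tandem-like
  copies, relocated copies and loss relics.
* **Rule-based families and landmarks.** NLR immune receptors are
  classified into NBS / TIR-NBS / CC-NBS / NBS-LRR / CNL / TNL from a
  Pfam-style domain table plus a coiled-coil flag; CBF/DREB1 candidates
  need an AP2 domain flanked by DSXWR and PKKPAGRKKFRETRHP; telomeres are
  CCCTAAA/TTTAGGG tandem runs within 50 kb of a chromosome terminus, and
  centromere candidates are the densest tandem-repeat region with a
  representative monomer.

A synthetic tetraploid generator (`polyka.simulate`) produces all inputs
with a complete ground-truth ledger, so every step above is scored by
parameter recovery rather than eyeballing.

## Worked example

```bash
python analysis/01_simulate.py      # synthetic tetraploid + truth ledger
python analysis/02_alleles.py       # anchors -> blocks -> allele table
python analysis/03_ks_dating.py     # NG86 Ks, KDE peaks, T = Ks/2r
python analysis/04_ase.py           # ASE records and ASEG classes
python analysis/05_chrom_features.py
python analysis/06_families.py
```

On the default conditions (seed 1) the dating step prints:

```
Ks estimated for 2448 allelic and 310 paralog pairs
  allelic peak: Ks = 0.0068  ->  1.01 Mya (n = 1627, bw = 0.0014)
  paralog peak: Ks = 0.1309  ->  19.31 Mya (n = 310, bw = 0.0649)
  paralog peak: Ks = 0.4846  ->  71.48 Mya (n = 310, bw = 0.0649)
```

i.e. the allelic K_s mode recovers the configured divergence (dS 0.007,
planted as the tetraploidization event, dated ~1 Mya) and the paralog
distribution shows both older WGD peaks (~0.127 and ~0.50, dated ~19 and
~72 Mya). The allele step prints the locus census
(`four=369 three=55 two=69 singleton=132`; the 4-allele fraction matches
the programmed loss rates) and the singleton origin table; the ASE step
reports significant/consistent/inconsistent counts against the 20 loci
the generator planted.

The same stages are scriptable via the `polyka` CLI
(`polyka simulate|alleles|ks|ase|families|chromfeat|all`).

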