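# hapweave

Read-based diploid haplotype phasing with optional merging of
statistically prephased blocks.

## The problem

A diploid genome carries two copies of every chromosome, but standard
variant calling reports unordered genotypes: at a heterozygous site we
know the two alleles, not which parental chromosome each sits on.
*Phasing* recovers that assignment. Sequencing reads that span two or
more heterozygous sites observe alleles in physical linkage and can
phase them directly — with high accuracy, independent of allele
frequency and reference panels, but only out to the read length.
Statistical phasers produce chromosome-scale haplotypes from population
panels but are weak at rare variants and inject occasional switch
errors. `hapweave` implements a read-based phaser plus a hybrid merge
that anchors read-backed blocks onto a statistical scaffold, keeping the
local precision of reads and the reach of the panel.

## The algorithm

Let S = {s₁ … sₘ} be the heterozygous sites of one sample (alleles
aᵢ ≠ bᵢ) and R = {r₁ … rₙ} the reads, each associated with the alleles
it carries at the sites it spans (via a CIGAR walk; ambiguous
observations are omitted, MAPQ < 20 reads are discarded). Phasing is a
pairwise distance-based unsupervised classification of reads into two
haplotype groups H₁, H₂:

- The first read of each connected component seeds H₁ of a new block.
- Each subsequent read r scores both haplotypes over all previously
  assigned overlapping reads k and the sites s they share:

      P_H(r) = Σ_k Σ_s ΔP_H,   ΔP_H = +w(s) if A_r(s) = A_k(s), k ∈ H
                               ΔP_H = −w(s) if A_r(s) ≠ A_k(s), k ∈ H

  with site weights w(s) = 2 for SNVs and 1 for indels. r joins H₁ if
  P₁ > P₂ and H₂ if P₂ > P₁; ties follow the single strongest pairwise
  connection. Reads supported by both haplotypes are flagged.
- Paired-end repair: a mate pair split across haplotypes of one block
  (M(rᵢ,rⱼ) = −1) is re-examined with a mate-consistency bonus and the
  weaker member flipped when that increases total agreement.
- A per-site weighted vote over the assigned reads turns components
  into haplotype blocks (VCF phase sets).
- Hybrid merge (optional): each read block is anchored to the prephased
  block b maximising the agreement weight A(b,h) = Σ w(s) over shared
  sites, flipped wholesale if the swapped labeling scores higher,
  bridged with other consistently anchored blocks, and panel-only sites
  fill the coverage gaps. Within a read block, read evidence is never
  overruled site-by-site.

Outputs: a phased VCF with `PS` phase sets, a BAM annotated with
`HP` (haplotype 1/2) and `HT` (block id) tags, two per-haplotype split
BAMs, and a BED of block extents. An evaluation module builds trio
truth sets (opposite-homozygote and het×hom parents) and computes
phased %, flip-invariant accuracy (overall / SNV / indel), block
counts, median block size, N50 and switch errors. A deterministic
simulator generates diploid references, reads with exact synthesized
alignments, truth VCFs, trios and switch-error-corrupted panels.

## Worked example

`python examples/01_phase_long_reads.py` — 100 kb at 1 het/100 bp,
10 kb noiseless reads at 30×:

```
het sites           : 1018
read observations   : 300
haplotype blocks    : 1
phased sites        : 98.9%
accuracy (phased)   : 100.0%
switch errors       : 0
block N50           : 98393 bp
```

Every covered site lands in a single block oriented exactly as the
simulated truth; only sites within a read length of the segment ends
stay unphased. `python examples/02_hybrid_merge.py` shows the hybrid
mode at genome-typical variant spacing, where paired 150 bp reads alone
fragment into 20 blocks phasing 43% of sites and merging with a
contig-wide panel yields 1 block phasing 100%; `examples/03_trio_truth.py`
builds a trio truth set and scores a phasing run against it.

The same pipeline runs from the shell:

```sh
hapweave simulate --out-dir sim --ref-len 100000 --read-len 10000 --seed 1
hapweave phase --bam sim/reads.bam --vcf sim/variants.vcf \
    --out-vcf phased.vcf --out-bam anno.bam --out-bed blocks.bed
hapweave evaluate --vcf phased.vcf --truth sim/truth.vcf --out metrics.tsv
```

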