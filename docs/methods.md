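# Methods

## Model and procedure

`hapweave` phases one diploid sample per run. The model is minimal:
the sample's heterozygous sites partition into two latent haplotypes,
every primary read derives wholly from one of them, and allele
observations disagree with the source haplotype only through sequencing
or alignment error. Phasing is then a two-class classification of reads
driven by pairwise weighted agreement, followed by a per-site consensus.

**Site identification.** Biallelic heterozygous genotypes (`0/1`, `1/2`;
any two distinct called alleles) are taken from the input VCF in
coordinate order. Records with QUAL below `qual_min` (default 20) are
flagged: they stay in the site list and in the output VCF but never
participate in scoring, block membership or hybrid merging. This is the
conservative reading — a low-confidence genotype is as likely to be a
calling artifact as a phaseable variant, and a wrong site hurts
propagation more than a missing one helps. Genotypes of ploidy ≠ 2 are
skipped with a warning; polyploid phasing is out of scope.

**Read–site association.** For each primary, non-duplicate alignment
with MAPQ ≥ `mapq_min` (default 20), the aligned query segment over each
overlapped site's reference footprint (REF-allele span, insertions
anchored inside it included) is compared with both allele sequences.
Exactly one exact match records the allele; a match to neither or both
(prefix-sharing indels at read ends), a deletion, clip or reference
skip over the footprint, or — for indel sites — a missing anchor base to
the right, omits the site from that read. Omission, never guessing: the
scoring step tolerates missing observations but is sensitive to wrong
ones. Base qualities are not used; the only weighting is by site class.

**Propagation.** Reads are processed in (coordinate, read-key) order, so
the sweep is deterministic and needs no randomness. The first read of a
connected component seeds haplotype 1 of a new block. Each later read
accumulates P₁ and P₂ as the sum of signed weighted agreements
(+w(s)/−w(s), w = 2 for SNVs, 1 for indels) against every already
assigned overlapping read of that haplotype, and takes the larger side.
Equal scores defer to the single neighbour with the largest
|pair score| (ties: lexicographically smallest read key); a read with no
assigned overlap starts a new block. Reads with min(P₁,P₂) > 0 — genuine
support on both sides — are flagged and counted in the stats log but
keep their better assignment. The propagation is a single sweep; scores
are not iterated to convergence. The bounded paired-end repair below
recovers the practically relevant cases an extra sweep would, and a
single pass keeps the output order-stable and linear in coverage.

**Paired-end repair.** For each mate pair assigned to different
haplotypes of the same block, both members' scores are recomputed
against the final assignment, each with a mate-consistency bonus equal
to the mate's margin |P₁ − P₂| credited to the mate's haplotype; the
member whose flip most increases total agreement flips. Sweeps repeat
until quiescent, at most `max_repair_passes` (default 3) times — each
flip strictly increases agreement, so a small bound guarantees
termination without cycling. Mates landing in different blocks are
untouched: cross-block pairing is bridging information, not an
inconsistency, and the optional weighted pair-link graph that would
exploit it is deliberately not implemented.

**Consensus.** Within each component, every site gets a weighted vote:
an H₁ read carrying allele a (or an H₂ read carrying allele b) votes
w(s) for a-on-haplotype-1. Tied votes leave the site unphased; blocks
retaining fewer than two phased sites are dropped. A block's identifier
(the VCF `PS` value) is the 1-based position of its leftmost phased
site, matching common phaser convention.

**Hybrid merge.** Each read block h is anchored to the prephased block b
sharing the most total weight and flipped iff the flipped agreement
strictly exceeds the same-orientation agreement; exact ties leave the
block unmerged and unflipped, so a statistical switch error sitting at
the balance point cannot silently re-orient read evidence. All strictly
anchored blocks of one scaffold block merge; scaffold-only sites are
filled contig-wide with the scaffold's orientation (statistical phasers
emit chromosome-scale blocks, so filling only inside merged spans would
forfeit most of the reach that motivates the merge). Inside a read
block only the whole-block flip can change orientations — read evidence
is never overruled site by site.

## Evaluation

Trio truth: a child het site is resolvable iff exactly one
(paternal, maternal) transmitted-allele assignment is compatible with
both parental genotypes — equivalently, opposite homozygous parents or
one het and one hom parent; double-het configurations are excluded and
Mendelian-inconsistent sites counted separately. Accuracy is
flip-invariant (each block scored under its majority orientation) and
its headline denominator is *all* truth het sites, so phased % bounds
accuracy from above; the phased-only variant is reported alongside
because the two readings differ exactly by the unphased truth sites.
Block N50 is the smallest span such that blocks at least that long
cover half the total phased span. Switch errors count orientation
changes between consecutive truth sites within a block.

## The simulator

The generator emulates the two regimes that matter for read-based
phasing: variant density (default 1 SNV/100 bp + 0.1 indels/100 bp,
the dense HLA-like regime; 1/500 bp for the genome-typical sparse
regime) and read geometry (150 bp proper pairs with a 400 ± 50 bp
insert, or multi-kb single-end long reads, both at 30×). Reads are
drawn uniformly, each wholly from one haplotype, and their alignments
are synthesized exactly from the known variant composition, with the
source haplotype hidden in an `XH` tag for oracle tests. Noise is
per-base substitution only, injected after the alignment is fixed.

What it does **not** emulate — and what passing tests therefore do not
show about real data: alignment and mapping-bias errors (simulated
CIGARs are exact; real indel misalignment is exercised only through the
omission rules), indel sequencing errors, non-uniform coverage, GC and
strand effects, genotyping error in the input VCF, and realistic
quality strings. Variant starts are kept ≥ 12 bp apart so reference
footprints never overlap; reads are fixed-length in reference
coordinates, so haplotype indels change the sequence length by up to
±3 bp. The corrupted panel is a first-order Markov switch process with
optional site drop-out over a single contig-wide phase set — a
structural stand-in for a statistical phaser's error profile, not a
calibrated one. Everything is deterministic per seed (numpy PCG64).

## Numerical and design choices

- All scores are small integers; no floating point enters the engine,
  so results are platform-stable and exactly reproducible.
- Deterministic orders everywhere: reads by (coordinate, key), tie
  breaks lexicographic, block ids from leftmost site positions.
- Degenerate inputs: empty read or site lists yield empty outputs;
  single-site components are dropped (nothing to phase relative to);
  a genotype whose alleles both match or both miss a read segment is
  simply unobserved.
- Multiallelic het genotypes (`1/2`) use the two called ALTs as the
  allele pair, keeping the site phaseable.
- `HP` is the haplotype label (1/2) and `HT` the block identifier; the
  two per-haplotype BAMs exclude unassigned reads by default, with an
  `--include-unassigned` flag that copies them to both files when
  downstream coverage must be preserved.
- Benchmark problem sizes (100 kb dense / 50 kb sparse segments, 20
  seeds for the stochastic checks, 200 instances for the exhaustive
  oracle) keep the whole bench comfortably within a laptop-minute while
  leaving hundreds of sites and blocks per run.

## Known limitations

Single-sample, diploid, biallelic only; no local realignment, so
reference mapping bias passes through; the merge is per-block greedy
anchoring rather than a global optimisation (conflicts are rare because
scaffold blocks are near-chromosome-scale); no MEC-optimal search —
the exhaustive minimum-disagreement assignment is used only as a
small-instance test oracle; distant blocks sharing no read or scaffold
evidence are never joined.
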