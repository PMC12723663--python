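"""Synthetic diploid data: haplotypes, reads, truth VCFs, trios, corrupted panels.

The generator emulates the regimes where read-based phasing is
informative: a diploid segment with ~1 heterozygous variant per 100 bp
(dense, HLA-like) down to 1 per 500–1000 bp (typical genome background),
covered either by ~150 bp paired-end short reads or multi-kb single-end
long reads.  Reads are drawn uniformly from one haplotype each and their
alignments are synthesised exactly (positions are known by
construction), so every downstream stage can be checked against hidden
truth without an external aligner.  Sequencing noise is a per-base
substitution process; alignments themselves are never corrupted.

Everything is deterministic per seed (numpy PCG64).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pysam

from .variant_io import INDEL, SNP, A_ALLELE, B_ALLELE, HetSite

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
#: truth tag on simulated reads: source haplotype (1 or 2)
TRUTH_TAG = "XH"

# variant starts are kept at least this far apart so no two reference
# footprints (max deletion length 3 + anchor) can overlap
_MIN_SPACING = 12
_MAX_INDEL = 3


@dataclass(frozen=True)
class PoolSite:
    """One biallelic variant definition shared by all individuals of a pool."""

    pos: int  # 1-based start
    ref_allele: str
    alt_allele: str
    vclass: str


@dataclass
class SitePool:
    """A reference segment plus the variant sites segregating on it."""

    chrom: str
    reference: str
    sites: list[PoolSite]

    def __len__(self) -> int:
        return len(self.sites)


@dataclass
class Diploid:
    """Two haplotypes over a site pool: 0 = reference allele, 1 = alternate."""

    pool: SitePool
    hap: np.ndarray  # shape (2, n_sites), int8

    def het_mask(self) -> np.ndarray:
        return self.hap[0] != self.hap[1]

    def het_sites(self, qual_flagged: Sequence[bool] | None = None) -> list[HetSite]:
        """The individual's het sites as the phasing pipeline sees them.

        allele_a is always the reference allele and allele_b the
        alternate, matching what loading the written (0/1) VCF yields.
        """
        out: list[HetSite] = []
        for j in np.flatnonzero(self.het_mask()):
            ps = self.pool.sites[j]
            out.append(
                HetSite(
                    chrom=self.pool.chrom,
                    pos=ps.pos,
                    allele_a=ps.ref_allele,
                    allele_b=ps.alt_allele,
                    ref_len=len(ps.ref_allele),
                    vclass=ps.vclass,
                    weight=2 if ps.vclass == SNP else 1,
                    qual_flagged=bool(qual_flagged[len(out)]) if qual_flagged else False,
                    site_index=len(out),
                )
            )
        return out

    def truth_orientation(self) -> dict[int, int]:
        """site_index -> allele code on haplotype 1, for het sites."""
        out: dict[int, int] = {}
        for rank, j in enumerate(np.flatnonzero(self.het_mask())):
            out[rank] = A_ALLELE if self.hap[0, j] == 0 else B_ALLELE
        return out


def _random_reference(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def simulate_site_pool(
    ref_len: int,
    snp_rate: float = 0.01,
    indel_rate: float = 0.001,
    seed: int = 0,
) -> SitePool:
    """Draw a reference segment and per-bp Bernoulli variant positions.

    Variant starts closer than the minimum spacing (or too close to the
    segment ends) are dropped so reference footprints never overlap.
    """
    rng = np.random.default_rng(seed)
    reference = _random_reference(rng, ref_len)
    u = rng.random(ref_len)
    candidates = np.flatnonzero(u < (snp_rate + indel_rate))
    is_snp = u[candidates] < snp_rate

    sites: list[PoolSite] = []
    last = -(10**9)
    for p0, snp in zip(candidates.tolist(), is_snp.tolist()):
        if p0 - last < _MIN_SPACING or p0 < _MIN_SPACING or p0 > ref_len - _MIN_SPACING:
            continue
        last = p0
        base = reference[p0]
        if snp:
            alt = base
            while alt == base:
                alt = chr(_BASES[rng.integers(0, 4)])
            sites.append(PoolSite(pos=p0 + 1, ref_allele=base, alt_allele=alt, vclass=SNP))
        else:
            length = int(rng.integers(1, _MAX_INDEL + 1))
            if rng.random() < 0.5:  # insertion
                ins = _random_reference(rng, length)
                sites.append(
                    PoolSite(pos=p0 + 1, ref_allele=base, alt_allele=base + ins, vclass=INDEL)
                )
            else:  # deletion
                ref = reference[p0 : p0 + 1 + length]
                sites.append(PoolSite(pos=p0 + 1, ref_allele=ref, alt_allele=base, vclass=INDEL))
    return SitePool(chrom="sim1", reference=reference, sites=sites)


def simulate_diploid(
    ref_len: int,
    snp_rate: float = 0.01,
    indel_rate: float = 0.001,
    seed: int = 0,
) -> Diploid:
    """A fully heterozygous diploid: every pool site is het, phase random."""
    pool = simulate_site_pool(ref_len, snp_rate, indel_rate, seed)
    rng = np.random.default_rng(seed + 1)
    h1 = rng.integers(0, 2, size=len(pool), dtype=np.int8)
    return Diploid(pool=pool, hap=np.stack([h1, 1 - h1]))


def diploid_from_pool(pool: SitePool, seed: int, alt_freq: float = 0.5) -> Diploid:
    """An individual with independently drawn alleles (for trio parents)."""
    rng = np.random.default_rng(seed)
    hap = (rng.random((2, len(pool))) < alt_freq).astype(np.int8)
    return Diploid(pool=pool, hap=hap)


# ---------------------------------------------------------------------------
# reads


@dataclass
class SimRead:
    qname: str
    hap: int  # 0/1
    start: int  # 0-based adjusted reference start
    cigar: list[tuple[int, int]]
    seq: str
    flag: int
    mate_start: int = -1
    tlen: int = 0


def _hap_variants(diploid: Diploid, h: int) -> list[PoolSite]:
    return [
        diploid.pool.sites[j]
        for j in np.flatnonzero(diploid.hap[h] == 1)
    ]


def _build_read(
    variants: list[PoolSite],
    vpos: np.ndarray,
    reference: str,
    h: int,
    rs: int,
    re_: int,
) -> tuple[int, list[tuple[int, int]], str]:
    """Synthesize sequence+CIGAR of a read copying haplotype h over [rs, re)."""
    # shift edges off any straddled variant footprint
    lo = int(np.searchsorted(vpos, rs - _MAX_INDEL - 1))
    for v in variants[lo : lo + 2]:
        p0 = v.pos - 1
        if p0 < rs < p0 + len(v.ref_allele):
            rs = p0 + len(v.ref_allele)
    hi = int(np.searchsorted(vpos, re_))
    for v in variants[max(hi - 2, 0) : hi]:
        p0 = v.pos - 1
        if p0 < re_ < p0 + len(v.ref_allele):
            re_ = p0
    chunks: list[str] = []
    cigar: list[tuple[int, int]] = []

    def emit(op: int, length: int) -> None:
        if length <= 0:
            return
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + length)
        else:
            cigar.append((op, length))

    cur = rs
    lo = int(np.searchsorted(vpos, rs))
    for v in variants[lo:]:
        p0 = v.pos - 1
        rl = len(v.ref_allele)
        if p0 + rl > re_:
            break
        chunks.append(reference[cur:p0])
        emit(0, p0 - cur)
        chunks.append(v.alt_allele)
        al = len(v.alt_allele)
        if rl == al:  # SNV (or MNV)
            emit(0, rl)
        elif al > rl:  # insertion: anchor base(s) then inserted seq
            emit(0, rl)
            emit(1, al - rl)
        else:  # deletion: kept base(s) then deleted span
            emit(0, al)
            emit(2, rl - al)
        cur = p0 + rl
    chunks.append(reference[cur:re_])
    emit(0, re_ - cur)
    return rs, cigar, "".join(chunks)


def _inject_errors(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(arr.size) < error_rate)
    for i in hits:
        new = arr[i]
        while new == arr[i]:
            new = _BASES[rng.integers(0, 4)]
        arr[i] = new
    return arr.tobytes().decode()


def simulate_reads(
    diploid: Diploid,
    read_len: int = 150,
    coverage: float = 30.0,
    error_rate: float = 0.0,
    paired: bool = False,
    insert_mean: int = 400,
    insert_sd: int = 50,
    seed: int = 0,
) -> list[SimRead]:
    """Uniformly sampled reads, each wholly from one haplotype.

    Paired mode emits proper forward/reverse pairs with a normal insert
    size; single-end mode emits forward reads only.  Substitution errors
    are injected after the alignment is fixed, so CIGARs stay exact.
    Each read carries the source haplotype in the ``XH`` tag for oracle
    tests.
    """
    rng = np.random.default_rng(seed)
    L = len(diploid.pool.reference)
    reference = diploid.pool.reference
    variants = [_hap_variants(diploid, h) for h in (0, 1)]
    vpos = [np.array([v.pos - 1 for v in vs], dtype=np.int64) for vs in variants]

    reads: list[SimRead] = []
    n_reads = max(1, round(coverage * L / read_len))
    if paired:
        n_frags = max(1, n_reads // 2)
        for i in range(n_frags):
            h = int(rng.integers(0, 2))
            insert = max(read_len, int(round(rng.normal(insert_mean, insert_sd))))
            insert = min(insert, L)
            fs = int(rng.integers(0, L - insert + 1))
            qname = f"sim{i:07d}"
            s1, c1, q1 = _build_read(variants[h], vpos[h], reference, h, fs, fs + read_len)
            s2, c2, q2 = _build_read(
                variants[h], vpos[h], reference, h, fs + insert - read_len, fs + insert
            )
            q1 = _inject_errors(q1, rng, error_rate)
            q2 = _inject_errors(q2, rng, error_rate)
            tlen = (fs + insert) - s1
            reads.append(
                SimRead(qname, h, s1, c1, q1, flag=99, mate_start=s2, tlen=tlen)
            )
            reads.append(
                SimRead(qname, h, s2, c2, q2, flag=147, mate_start=s1, tlen=-tlen)
            )
    else:
        span = min(read_len, L)
        for i in range(n_reads):
            h = int(rng.integers(0, 2))
            rs = int(rng.integers(0, L - span + 1))
            s, c, q = _build_read(variants[h], vpos[h], reference, h, rs, rs + span)
            q = _inject_errors(q, rng, error_rate)
            reads.append(SimRead(f"sim{i:07d}", h, s, c, q, flag=0))
    reads.sort(key=lambda r: (r.start, r.qname, r.flag))
    return reads


# ---------------------------------------------------------------------------
# writers


def sam_header(pool: SitePool) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": pool.chrom, "LN": len(pool.reference)}],
    }


def write_sam(reads: Sequence[SimRead], pool: SitePool, path: str) -> None:
    """Write simulated reads as a coordinate-sorted SAM/BAM."""
    mode = "wb" if str(path).endswith(".bam") else "w"
    header = sam_header(pool)
    with pysam.AlignmentFile(path, mode, header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.qname
            a.flag = r.flag
            a.reference_id = 0
            a.reference_start = r.start
            a.mapping_quality = 60
            a.cigartuples = r.cigar
            a.query_sequence = r.seq
            a.query_qualities = pysam.qualitystring_to_array("I" * len(r.seq))
            if r.flag & 0x1:
                a.next_reference_id = 0
                a.next_reference_start = r.mate_start
                a.template_length = r.tlen
            else:
                a.next_reference_id = -1
                a.next_reference_start = -1
            a.set_tag(TRUTH_TAG, r.hap + 1, value_type="i")
            out.write(a)
    if mode == "wb":
        pysam.index(str(path))


def write_reference(pool: SitePool, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f">{pool.chrom}\n")
        seq = pool.reference
        for i in range(0, len(seq), 60):
            fh.write(seq[i : i + 60] + "\n")


def _vcf_header(pool: SitePool, with_ps: bool) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.contigs.add(pool.chrom, length=len(pool.reference))
    header.formats.add("GT", "1", "String", "Genotype")
    if with_ps:
        header.formats.add("PS", "1", "Integer", "Phase set identifier")
    header.add_sample("SAMPLE")
    return header


def write_vcf(
    diploid: Diploid,
    path: str,
    phased: bool = False,
    het_only: bool = True,
    qual: float = 60.0,
    qual_override: Optional[dict[int, float]] = None,
) -> None:
    """Write the individual's variants as a VCF.

    ``phased=True`` emits the true haplotype assignment with pipe
    separators (the truth VCF); otherwise genotypes are unphased — the
    variant-caller-style input to the phasing pipeline.
    ``qual_override`` maps pool-site index to a QUAL value, e.g. to
    plant low-confidence records.
    """
    pool = diploid.pool
    header = _vcf_header(pool, with_ps=False)
    with pysam.VariantFile(path, "w", header=header) as out:
        for j, ps in enumerate(pool.sites):
            g = (int(diploid.hap[0, j]), int(diploid.hap[1, j]))
            if het_only and g[0] == g[1]:
                continue
            rec = out.new_record(
                contig=pool.chrom,
                start=ps.pos - 1,
                alleles=(ps.ref_allele, ps.alt_allele),
                qual=qual_override.get(j, qual) if qual_override else qual,
            )
            rec.samples["SAMPLE"]["GT"] = g
            rec.samples["SAMPLE"].phased = phased
            out.write(rec)


def corrupt_prephased(
    diploid: Diploid,
    path: str,
    switch_rate: float = 0.0,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> int:
    """Write a statistical-phaser stand-in: truth with injected switch errors.

    A Markov switch process flips the emitted orientation after each het
    site with probability ``switch_rate``; sites are dropped with
    probability ``missing_rate``.  All records share PS=1 (one
    contig-wide block).  Returns the number of switches injected.
    """
    rng = np.random.default_rng(seed)
    pool = diploid.pool
    header = _vcf_header(pool, with_ps=True)
    flipped = False
    n_switches = 0
    with pysam.VariantFile(path, "w", header=header) as out:
        for j, ps in enumerate(pool.sites):
            g = (int(diploid.hap[0, j]), int(diploid.hap[1, j]))
            if g[0] == g[1]:
                continue
            drop = rng.random() < missing_rate
            if not drop:
                gt = (g[1], g[0]) if flipped else g
                rec = out.new_record(
                    contig=pool.chrom,
                    start=ps.pos - 1,
                    alleles=(ps.ref_allele, ps.alt_allele),
                    qual=60,
                )
                rec.samples["SAMPLE"]["GT"] = gt
                rec.samples["SAMPLE"].phased = True
                rec.samples["SAMPLE"]["PS"] = 1
                out.write(rec)
            if rng.random() < switch_rate:
                flipped = not flipped
                n_switches += 1
    return n_switches


# ---------------------------------------------------------------------------
# trios


def simulate_trio(
    father: Diploid, mother: Diploid, seed: int = 0
) -> tuple[Diploid, dict[int, tuple[str, str]], dict[int, tuple[str, str]]]:
    """Transmit one haplotype per parent (no recombination) to a child.

    Returns the child plus parental genotype tables keyed by the child's
    het-site rank (site_index), as allele-sequence pairs — the inputs
    trio truth construction expects.  Child haplotype 1 is paternal.
    """
    if father.pool is not mother.pool and father.pool.sites != mother.pool.sites:
        raise ValueError("parents must share a site pool")
    rng = np.random.default_rng(seed)
    tf, tm = int(rng.integers(0, 2)), int(rng.integers(0, 2))
    child = Diploid(pool=father.pool, hap=np.stack([father.hap[tf], mother.hap[tm]]))

    def table(parent: Diploid) -> dict[int, tuple[str, str]]:
        out: dict[int, tuple[str, str]] = {}
        for rank, j in enumerate(np.flatnonzero(child.het_mask())):
            ps = parent.pool.sites[j]
            alleles = (ps.ref_allele, ps.alt_allele)
            out[rank] = (alleles[parent.hap[0, j]], alleles[parent.hap[1, j]])
        return out

    return child, table(father), table(mother)
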