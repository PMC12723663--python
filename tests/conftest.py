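"""Shared fixtures: hand-written VCF/SAM fixtures and small simulated runs."""

from __future__ import annotations

import pysam
import pytest

from hapweave import collect_observations, run_phasing
from hapweave import simulate as sim

VCF_TEXT = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=100000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE
chr1\t100\t.\tA\tG\t50\tPASS\t.\tGT\t0/0
chr1\t200\t.\tC\tT\t50\tPASS\t.\tGT\t0/1
chr1\t300\t.\tG\tA\t3\tPASS\t.\tGT\t0/1
chr1\t400\t.\tT\tC\t50\tPASS\t.\tGT\t1/1
chr1\t500\t.\tA\tAT\t50\tPASS\t.\tGT\t0/1
chr1\t600\t.\tA\tG,T\t50\tPASS\t.\tGT\t1/2
"""


@pytest.fixture
def hand_vcf(tmp_path):
    """Six hand-written records: hom-ref, SNV, low-QUAL SNV, hom-alt, indel, multi-allelic."""
    path = tmp_path / "hand.vcf"
    path.write_text(VCF_TEXT)
    return str(path)


def write_sam(path, records, ref_len=100_000):
    """Write AlignedSegment-like tuples to a SAM file.

    Each record: (qname, flag, pos0, mapq, cigartuples, seq).
    """
    header = {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": "chr1", "LN": ref_len}]}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for qname, flag, pos0, mapq, cigar, seq in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = qname
            a.flag = flag
            a.reference_id = 0
            a.reference_start = pos0
            a.mapping_quality = mapq
            a.cigartuples = cigar
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            out.write(a)
    return str(path)


@pytest.fixture(scope="session")
def long_read_run(tmp_path_factory):
    """30 kb dense diploid with error-free 3 kb reads, phased end to end."""
    out = tmp_path_factory.mktemp("longrun")
    diploid = sim.simulate_diploid(30_000, snp_rate=0.01, indel_rate=0.001, seed=11)
    sites = diploid.het_sites()
    reads = sim.simulate_reads(diploid, read_len=3_000, coverage=30, error_rate=0.0, seed=12)
    bam = str(out / "reads.bam")
    sim.write_sam(reads, diploid.pool, bam)
    observations = collect_observations(bam, sites=sites)
    state, blocks = run_phasing(observations, sites)
    return {
        "diploid": diploid,
        "sites": sites,
        "bam": bam,
        "observations": observations,
        "state": state,
        "blocks": blocks,
    }


@pytest.fixture(scope="session")
def paired_run(tmp_path_factory):
    """Sparse 30 kb diploid with paired-end short reads: many small blocks."""
    out = tmp_path_factory.mktemp("pairedrun")
    diploid = sim.simulate_diploid(30_000, snp_rate=0.002, indel_rate=0.0002, seed=21)
    sites = diploid.het_sites()
    reads = sim.simulate_reads(
        diploid, read_len=150, coverage=30, error_rate=0.0,
        paired=True, insert_mean=400, insert_sd=50, seed=22,
    )
    bam = str(out / "reads.bam")
    sim.write_sam(reads, diploid.pool, bam)
    observations = collect_observations(bam, sites=sites)
    state, blocks = run_phasing(observations, sites)
    return {
        "diploid": diploid,
        "sites": sites,
        "bam": bam,
        "observations": observations,
        "state": state,
        "blocks": blocks,
    }
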