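"""VCF input and output: heterozygous-site extraction, prephased blocks, phased output.

A *heterozygous site* is any biallelic genotype whose two called alleles
differ.  Sites are ranked in coordinate order; the rank (``site_index``)
is the key every other module uses to refer to a site.  Low-QUAL records
are kept in the site list but flagged: flagged sites take no part in
phase scoring or block membership and are emitted unphased.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pysam

logger = logging.getLogger(__name__)

SNP = "SNP"
INDEL = "INDEL"

#: allele codes used throughout: 0 = allele_a, 1 = allele_b
A_ALLELE = 0
B_ALLELE = 1


class InputError(Exception):
    """Missing or malformed input file."""


class ConfigurationError(Exception):
    """Inconsistent configuration (e.g. sample not present in the VCF)."""


class ConsistencyError(Exception):
    """Internal cross-file consistency violation."""


@dataclass(frozen=True)
class HetSite:
    """One biallelic heterozygous variant.

    ``allele_a``/``allele_b`` are the two called allele sequences in
    genotype-index order (for 0/1 that is REF then ALT; for 1/2 the two
    ALTs).  ``ref_len`` is the length of the VCF REF allele and defines
    the site's footprint on the reference, which the read walker needs
    to extract the aligned query segment.  SNVs carry weight 2, any
    other class weight 1.
    """

    chrom: str
    pos: int  # 1-based
    allele_a: str
    allele_b: str
    ref_len: int
    vclass: str
    weight: int
    qual_flagged: bool
    site_index: int

    @property
    def end(self) -> int:
        """1-based inclusive end of the reference footprint."""
        return self.pos + self.ref_len - 1

    def allele(self, code: int) -> str:
        return self.allele_a if code == A_ALLELE else self.allele_b


@dataclass
class PrephasedBlock:
    """A phase set imported from an externally phased VCF.

    ``sites`` holds ``(site_index, h1_allele)`` pairs where ``h1_allele``
    is 0 when ``allele_a`` sits on the source's haplotype 1 and 1 when
    ``allele_b`` does.  ``block_id`` is the source PS value, or the
    leftmost site position when the source carries no PS tag (a
    statistical phaser's output is then treated as one contig-wide
    block).
    """

    block_id: int
    chrom: str
    sites: list[tuple[int, int]]

    @property
    def site_indices(self) -> list[int]:
        return [si for si, _ in self.sites]


def _classify(allele_a: str, allele_b: str) -> tuple[str, int]:
    if len(allele_a) == 1 and len(allele_b) == 1:
        return SNP, 2
    return INDEL, 1


def _parse_region(region: Optional[str]) -> tuple[Optional[str], Optional[int], Optional[int]]:
    if region is None:
        return None, None, None
    if ":" not in region:
        return region, None, None
    contig, _, rng = region.partition(":")
    start_s, _, end_s = rng.partition("-")
    return contig, int(start_s.replace(",", "")) - 1, int(end_s.replace(",", ""))


def _pick_sample(vcf: pysam.VariantFile, sample: Optional[str]) -> str:
    samples = list(vcf.header.samples)
    if not samples:
        raise ConfigurationError("VCF has no sample columns")
    if sample is None:
        return samples[0]
    if sample not in samples:
        raise ConfigurationError(f"sample {sample!r} not found in VCF (has: {samples})")
    return sample


def _iter_records(vcf: pysam.VariantFile, region: Optional[str]):
    contig, start, end = _parse_region(region)
    if contig is None:
        yield from vcf
    else:
        try:
            yield from vcf.fetch(contig, start, end)
        except ValueError as exc:
            raise InputError(f"region query {region!r} requires an indexed VCF: {exc}") from exc


def load_het_sites(
    vcf_path: str,
    region: Optional[str] = None,
    qual_min: float = 20.0,
    sample: Optional[str] = None,
) -> list[HetSite]:
    """Extract the biallelic heterozygous genotypes of one sample, in coordinate order.

    Homozygous, missing and half-called genotypes are excluded; genotypes
    with ploidy other than 2 are skipped with a warning (polyploid data
    is unsupported).  Records whose QUAL is below ``qual_min`` yield a
    site with ``qual_flagged=True``: such sites stay in the list (and in
    any written VCF, unphased) but are never scored or phased.
    """
    try:
        vcf = pysam.VariantFile(vcf_path)
    except (FileNotFoundError, OSError) as exc:
        raise InputError(f"cannot open VCF {vcf_path!r}: {exc}") from exc
    with vcf:
        sample_name = _pick_sample(vcf, sample)
        sites: list[HetSite] = []
        last_key: Optional[tuple[str, int]] = None
        for rec in _iter_records(vcf, region):
            call = rec.samples[sample_name]
            gt = call.get("GT")
            if gt is None or len(gt) == 0:
                continue
            if len(gt) != 2:
                logger.warning(
                    "skipping non-diploid genotype at %s:%d (ploidy %d)", rec.chrom, rec.pos, len(gt)
                )
                continue
            if gt[0] is None or gt[1] is None or gt[0] == gt[1]:
                continue
            allele_a = rec.alleles[min(gt)]
            allele_b = rec.alleles[max(gt)]
            vclass, weight = _classify(allele_a, allele_b)
            flagged = rec.qual is not None and rec.qual < qual_min
            key = (rec.chrom, rec.pos)
            if last_key is not None and key[0] == last_key[0] and key[1] < last_key[1]:
                raise InputError(f"VCF not coordinate-sorted at {rec.chrom}:{rec.pos}")
            last_key = key
            sites.append(
                HetSite(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    allele_a=allele_a,
                    allele_b=allele_b,
                    ref_len=len(rec.ref),
                    vclass=vclass,
                    weight=weight,
                    qual_flagged=flagged,
                    site_index=len(sites),
                )
            )
    return sites


def load_prephased(
    vcf_path: str,
    sites: Sequence[HetSite],
    sample: Optional[str] = None,
) -> list[PrephasedBlock]:
    """Read a phased VCF (e.g. a statistical phaser's output) into blocks.

    Only phased (pipe-separated), heterozygous records whose alleles match
    the sample's het sites are used; everything else is skipped, with a
    warning when alleles disagree.  Records sharing a PS value form one
    block; records without PS form a single contig-wide block.
    """
    by_locus = {(s.chrom, s.pos): s for s in sites}
    try:
        vcf = pysam.VariantFile(vcf_path)
    except (FileNotFoundError, OSError) as exc:
        raise InputError(f"cannot open prephased VCF {vcf_path!r}: {exc}") from exc

    groups: dict[tuple[str, object], list[tuple[int, int]]] = {}
    order: list[tuple[str, object]] = []
    with vcf:
        sample_name = _pick_sample(vcf, sample)
        for rec in vcf:
            call = rec.samples[sample_name]
            gt = call.get("GT")
            if gt is None or len(gt) != 2 or gt[0] is None or gt[1] is None:
                continue
            if not call.phased or gt[0] == gt[1]:
                continue
            site = by_locus.get((rec.chrom, rec.pos))
            if site is None or site.qual_flagged:
                continue
            h1, h2 = rec.alleles[gt[0]], rec.alleles[gt[1]]
            if {h1, h2} != {site.allele_a, site.allele_b}:
                logger.warning(
                    "prephased alleles %s/%s at %s:%d do not match sample alleles %s/%s; dropped",
                    h1, h2, rec.chrom, rec.pos, site.allele_a, site.allele_b,
                )
                continue
            ps = call.get("PS")
            key = (rec.chrom, ps)
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append((site.site_index, A_ALLELE if h1 == site.allele_a else B_ALLELE))

    blocks: list[PrephasedBlock] = []
    for chrom, ps in order:
        entries = sorted(groups[(chrom, ps)])
        block_id = int(ps) if ps is not None else sites[entries[0][0]].pos
        blocks.append(PrephasedBlock(block_id=block_id, chrom=chrom, sites=entries))
    return blocks


def write_phased_vcf(
    sites: Sequence[HetSite],
    blocks: Iterable,
    template_vcf: str,
    out_path: str,
    sample: Optional[str] = None,
) -> None:
    """Write the template VCF with phased genotypes and PS annotations.

    Each site belonging to a block gets a pipe-separated genotype ordered
    haplotype-1-first and a PS equal to the block identifier; all other
    records pass through untouched.  ``blocks`` may be any objects with
    ``block_id`` and ``site_orientation`` (pairs of site_index and the
    allele code on haplotype 1) — both read-based and merged blocks
    qualify.
    """
    phase_of: dict[int, tuple[int, int]] = {}
    for blk in blocks:
        for si, h1_code in blk.site_orientation:
            if si in phase_of:
                raise ConsistencyError(f"site index {si} appears in more than one block")
            phase_of[si] = (blk.block_id, h1_code)

    by_locus = {(s.chrom, s.pos): s for s in sites}
    vin = pysam.VariantFile(template_vcf)
    header = vin.header.copy()
    if "PS" not in header.formats:
        header.formats.add("PS", "1", "Integer", "Phase set identifier")
    with vin, pysam.VariantFile(out_path, "w", header=header) as vout:
        sample_name = _pick_sample(vin, sample)
        for rec in vin:
            rec.translate(header)
            site = by_locus.get((rec.chrom, rec.pos))
            if site is not None and site.site_index in phase_of:
                block_id, h1_code = phase_of[site.site_index]
                h1_seq = site.allele(h1_code)
                h2_seq = site.allele(1 - h1_code)
                try:
                    gt = (rec.alleles.index(h1_seq), rec.alleles.index(h2_seq))
                except ValueError as exc:
                    raise ConsistencyError(
                        f"alleles at {rec.chrom}:{rec.pos} do not match the site list"
                    ) from exc
                call = rec.samples[sample_name]
                call["GT"] = gt
                call.phased = True
                call["PS"] = block_id
            vout.write(rec)
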