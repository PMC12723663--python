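"""Associate aligned reads with the alleles they carry at heterozygous sites.

For every read that passes the mapping-quality filter we walk its CIGAR
and, at each overlapped het site, compare the aligned query segment over
the site's reference footprint against the two allele sequences.  An
exact match to exactly one allele records that allele; anything
ambiguous — a match to neither or to both (indels sharing a prefix), a
deletion, clip or reference skip covering the site — omits the site.
Omission is deliberate: downstream scoring tolerates a missing
observation far better than a wrong one.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pysam

from .variant_io import A_ALLELE, B_ALLELE, SNP, HetSite, InputError

logger = logging.getLogger(__name__)

_CONSUMES_QUERY = {0, 1, 4, 7, 8}  # M, I, S, =, X
_CONSUMES_REF = {0, 2, 3, 7, 8}  # M, D, N, =, X


@dataclass(frozen=True)
class ReadObservation:
    """One read's allele calls across the het sites it spans.

    ``obs`` is ordered by site index; calls are ``A_ALLELE``/``B_ALLELE``
    codes.  Mates of a pair are separate observations linked through
    ``mate_key``.
    """

    qname: str
    segment: int  # 1 = single-end or first of pair, 2 = second of pair
    mapq: int
    start: int  # 0-based leftmost reference coordinate, for ordering
    obs: tuple[tuple[int, int], ...]
    paired: bool = False

    @property
    def read_key(self) -> str:
        return f"{self.qname}/{self.segment}"

    @property
    def mate_key(self) -> Optional[str]:
        if not self.paired:
            return None
        return f"{self.qname}/{3 - self.segment}"

    def call_map(self) -> dict[int, int]:
        return dict(self.obs)


@dataclass
class AssociationStats:
    """Counters kept while walking the alignment file."""

    records: int = 0
    skipped_filtered: int = 0  # unmapped/secondary/supplementary/duplicate
    skipped_mapq: int = 0
    no_informative_site: int = 0
    observations: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _aligned_segment_map(read: pysam.AlignedSegment):
    """Return (ref_pos -> query index or -1 for deletion/skip, insertions after ref_pos).

    Both maps are restricted to the read's aligned reference span.
    Reference skips (N) map to -2 so covered sites can be omitted.
    """
    ref_map: dict[int, int] = {}
    ins_map: dict[int, tuple[int, int]] = {}  # ref pos -> (qstart, qend) inserted after it
    qpos = 0
    rpos = read.reference_start
    for op, length in read.cigartuples:
        if op in (0, 7, 8):  # M/=/X
            for i in range(length):
                ref_map[rpos + i] = qpos + i
            qpos += length
            rpos += length
        elif op == 1:  # I — anchored after the previous reference base
            ins_map[rpos - 1] = (qpos, qpos + length)
            qpos += length
        elif op == 2:  # D
            for i in range(length):
                ref_map[rpos + i] = -1
            rpos += length
        elif op == 3:  # N
            for i in range(length):
                ref_map[rpos + i] = -2
            rpos += length
        elif op in (4,):  # S
            qpos += length
        # H (5) and P (6) consume nothing we track
    return ref_map, ins_map


def _extract_allele_call(
    read: pysam.AlignedSegment,
    site: HetSite,
    ref_map: dict[int, int],
    ins_map: dict[int, tuple[int, int]],
) -> Optional[int]:
    """Compare the query segment over the site's footprint to both alleles."""
    pos0 = site.pos - 1
    span_end = pos0 + site.ref_len
    if read.reference_start > pos0 or read.reference_end < span_end:
        return None
    # Indel alleles need an anchored base to the right so a trailing
    # insertion cannot hide in a clip.
    if site.vclass != SNP and read.reference_end < span_end + 1:
        return None
    query = read.query_sequence
    parts: list[str] = []
    for p in range(pos0, span_end):
        q = ref_map.get(p)
        if q is None or q == -2:
            return None  # clipped or reference-skipped
        if q >= 0:
            parts.append(query[q])
        # q == -1: base deleted in the read; contributes nothing
        ins = ins_map.get(p)
        if ins is not None:
            parts.append(query[ins[0] : ins[1]])
    segment = "".join(parts)
    hit_a = segment == site.allele_a
    hit_b = segment == site.allele_b
    if hit_a == hit_b:  # neither, or both (prefix-sharing indels)
        return None
    return A_ALLELE if hit_a else B_ALLELE


def observe_read(
    alignment: pysam.AlignedSegment,
    sites: Sequence[HetSite],
    mapq_min: int = 20,
    site_starts: Optional[Sequence[int]] = None,
) -> Optional[ReadObservation]:
    """Build the observation for one primary alignment, or None.

    ``sites`` must be the coordinate-ordered het-site list for the
    alignment's contig; ``site_starts`` may pass their 0-based positions
    to avoid recomputation.  Flagged sites are never observed.
    """
    if alignment.is_unmapped or alignment.mapping_quality < mapq_min:
        return None
    if site_starts is None:
        site_starts = [s.pos - 1 for s in sites]
    lo = bisect_left(site_starts, alignment.reference_start)
    hi = bisect_right(site_starts, alignment.reference_end)
    if lo >= hi:
        return None
    ref_map = ins_map = None
    obs: list[tuple[int, int]] = []
    for site in sites[lo:hi]:
        if site.qual_flagged or site.chrom != alignment.reference_name:
            continue
        if site.pos - 1 < alignment.reference_start or site.end > alignment.reference_end:
            continue
        if ref_map is None:
            ref_map, ins_map = _aligned_segment_map(alignment)
        call = _extract_allele_call(alignment, site, ref_map, ins_map)
        if call is not None:
            obs.append((site.site_index, call))
    if not obs:
        return None
    return ReadObservation(
        qname=alignment.query_name,
        segment=2 if alignment.is_read2 else 1,
        mapq=alignment.mapping_quality,
        start=alignment.reference_start,
        obs=tuple(obs),
        paired=alignment.is_paired,
    )


def collect_observations(
    bam_path: str,
    region: Optional[str] = None,
    sites: Sequence[HetSite] = (),
    mapq_min: int = 20,
    reference: Optional[str] = None,
    stats: Optional[AssociationStats] = None,
) -> list[ReadObservation]:
    """Walk a coordinate-sorted alignment file and collect all observations.

    Returns observations in (leftmost coordinate, read key) order — the
    deterministic order the phase engine propagates in.  CRAM input
    needs ``reference``.
    """
    if stats is None:
        stats = AssociationStats()
    by_contig: dict[str, list[HetSite]] = {}
    for s in sites:
        by_contig.setdefault(s.chrom, []).append(s)
    starts_by_contig = {c: [s.pos - 1 for s in ss] for c, ss in by_contig.items()}
    kwargs = {"reference_filename": reference} if reference else {}
    try:
        af = pysam.AlignmentFile(bam_path, **kwargs)
    except (FileNotFoundError, OSError) as exc:
        raise InputError(f"cannot open alignment file {bam_path!r}: {exc}") from exc
    out: list[ReadObservation] = []
    with af:
        if region is not None:
            try:
                it = af.fetch(region=region.replace(",", ""))
            except ValueError as exc:
                raise InputError(
                    f"region query {region!r} requires a coordinate-sorted, indexed file: {exc}"
                ) from exc
        else:
            it = af.fetch(until_eof=True)
        for rec in it:
            stats.records += 1
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary or rec.is_duplicate:
                stats.skipped_filtered += 1
                continue
            if rec.mapping_quality < mapq_min:
                stats.skipped_mapq += 1
                continue
            contig_sites = by_contig.get(rec.reference_name)
            if not contig_sites:
                stats.no_informative_site += 1
                continue
            ob = observe_read(
                rec,
                contig_sites,
                mapq_min=mapq_min,
                site_starts=starts_by_contig[rec.reference_name],
            )
            if ob is None:
                stats.no_informative_site += 1
                continue
            stats.observations += 1
            out.append(ob)
    out.sort(key=lambda o: (o.start, o.read_key))
    return out
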