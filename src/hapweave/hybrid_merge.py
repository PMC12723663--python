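"""Merge read-based haplotype blocks with an externally prephased scaffold.

Statistical phasers produce near-chromosome-scale blocks whose long-range
structure is usually right but which carry occasional switch errors and
are weak at rare variants.  Read-based blocks are locally precise but
short.  The merge anchors each read block to the prephased block it
shares the most site weight with, flips the read block wholesale when
the flipped agreement A(b, h_flipped) beats the same-orientation
agreement, fuses all consistently anchored read blocks into one block
per scaffold block, and fills read-coverage gaps with the scaffold's
own orientations.  Read evidence is never overruled site-by-site: inside
a read block only the whole-block flip can change orientations.
"""

from __future__ import annotations

from typing import Optional, Sequence

from .phase_engine import H1, H2, HaplotypeBlock, PhaseState
from .variant_io import HetSite, PrephasedBlock


def alignment_score(
    b: PrephasedBlock,
    h: HaplotypeBlock,
    sites: Sequence[HetSite],
) -> tuple[int, int]:
    """Weighted agreement between a prephased and a read-based block.

    Returns ``(score_same, score_flipped)``: the summed site weights on
    which the two blocks place the same allele on haplotype 1, with h's
    labels as-is and with h's labels swapped.  The two components add up
    to the total shared weight.
    """
    h_orient = h.orientation_map()
    same = flipped = 0
    for si, pre_code in b.sites:
        code = h_orient.get(si)
        if code is None:
            continue
        w = sites[si].weight
        if code == pre_code:
            same += w
        else:
            flipped += w
    return same, flipped


def merge_prephased(
    read_blocks: Sequence[HaplotypeBlock],
    prephased: Sequence[PrephasedBlock],
    sites: Sequence[HetSite],
    return_remap: bool = False,
):
    """Fuse read blocks with prephased blocks; optionally report the remap.

    Each read block is anchored to the prephased block with which it
    shares the most total weight and flipped iff the flipped agreement
    strictly wins; ties leave it unmerged and unflipped.  Read blocks
    anchored (with a strict winner) to the same prephased block merge
    into one output block whose id is the leftmost site position of the
    union; sites phased only by the scaffold are added with the
    scaffold orientation.  With ``return_remap`` the second return value
    maps each original read-block id to ``(new_block_id, flipped)`` so
    per-read haplotype labels can be carried over.
    """
    remap: dict[int, tuple[int, bool]] = {}
    passthrough: list[HaplotypeBlock] = []
    anchored: dict[int, list[tuple[HaplotypeBlock, bool]]] = {}
    used_sites: set[int] = set()
    for h in read_blocks:
        used_sites.update(si for si, _ in h.site_orientation)

    for h in read_blocks:
        best: Optional[PrephasedBlock] = None
        best_scores = (0, 0)
        for b in prephased:
            if b.chrom != h.chrom:
                continue
            same, flipped = alignment_score(b, h, sites)
            if same + flipped > sum(best_scores) or (
                best is not None
                and same + flipped == sum(best_scores)
                and same + flipped > 0
                and b.block_id < best.block_id
            ):
                best, best_scores = b, (same, flipped)
        if best is None or sum(best_scores) == 0 or best_scores[0] == best_scores[1]:
            passthrough.append(h)
            remap[h.block_id] = (h.block_id, False)
            continue
        flip = best_scores[1] > best_scores[0]
        anchored.setdefault(best.block_id, []).append((h, flip))

    merged: list[HaplotypeBlock] = []
    for b in prephased:
        group = anchored.get(b.block_id)
        fill = [(si, code) for si, code in b.sites if si not in used_sites]
        if not group:
            # scaffold-only region: emit the scaffold's own block
            if len(fill) >= 2:
                merged.append(_build_block(fill, b.chrom, sites, n_reads=0))
                used_sites.update(si for si, _ in fill)
            continue
        orient: dict[int, int] = {}
        n_reads = 0
        for h, flip in group:
            hh = h.flipped() if flip else h
            orient.update(hh.site_orientation)
            n_reads += h.n_reads
        orient.update(fill)
        used_sites.update(si for si, _ in fill)
        entries = sorted(orient.items())
        block = _build_block(entries, b.chrom, sites, n_reads=n_reads)
        merged.append(block)
        for h, flip in group:
            remap[h.block_id] = (block.block_id, flip)

    out = sorted(merged + passthrough, key=lambda blk: (blk.chrom, blk.block_id))
    if return_remap:
        return out, remap
    return out


def _build_block(
    entries: Sequence[tuple[int, int]],
    chrom: str,
    sites: Sequence[HetSite],
    n_reads: int,
) -> HaplotypeBlock:
    first, last = sites[entries[0][0]], sites[entries[-1][0]]
    return HaplotypeBlock(
        block_id=first.pos,
        chrom=chrom,
        site_orientation=tuple(entries),
        span=(first.pos, last.pos),
        n_reads=n_reads,
    )


def apply_remap_to_state(state: PhaseState, remap: dict[int, tuple[int, bool]]) -> PhaseState:
    """Carry per-read haplotype labels over to merged block ids.

    Reads of a flipped block swap H1 and H2 so BAM haplotype tags stay
    consistent with the merged VCF orientation.
    """
    for key, old_id in list(state.block_of.items()):
        if old_id not in remap:
            continue
        new_id, flip = remap[old_id]
        state.block_of[key] = new_id
        if flip:
            hp = state.assignment.get(key)
            if hp == H1:
                state.assignment[key] = H2
            elif hp == H2:
                state.assignment[key] = H1
    return state
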