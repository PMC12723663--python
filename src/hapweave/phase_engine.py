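"""Seed–score–propagate phasing of read observations.

The engine performs pairwise distance-based unsupervised classification
of reads into two haplotype groups.  Reads are processed in coordinate
order.  The first read of each connected component (reads linked by
shared het sites) seeds haplotype 1 of a new block; every later read r
accumulates a phase score against each haplotype H:

    P_H(r) = sum over assigned overlapping reads k in H,
             sum over shared sites s of +w(s) if the allele calls agree
                                       -w(s) if they disagree

with w(s) = 2 for SNVs and 1 for indels, and takes the haplotype with
the larger score.  Equal scores fall back to the single strongest
pairwise connection.  Reads supported by both haplotypes
(min(P1, P2) > 0) are flagged as conflicted but keep their best
assignment.  A bounded paired-end repair pass then flips members of
discordant mate pairs when that increases total agreement, and a final
per-site weighted vote turns read assignments into haplotype blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .read_association import ReadObservation
from .variant_io import A_ALLELE, SNP, HetSite

UNASSIGNED = 0
H1 = 1
H2 = 2


def site_weight(site: HetSite) -> int:
    """Phasing weight of a het site: 2 for a SNV, 1 for anything else."""
    return 2 if site.vclass == SNP else 1


def pair_score(
    r: ReadObservation,
    k: ReadObservation,
    weights: Sequence[int],
    k_calls: Optional[dict[int, int]] = None,
) -> int:
    """Signed weighted agreement between two reads over their shared sites.

    Positive when the reads look like they come from the same haplotype,
    negative when from opposite haplotypes, zero with no shared sites.
    ``weights`` maps site_index -> w(s).
    """
    if k_calls is None:
        k_calls = k.call_map()
    score = 0
    for si, call in r.obs:
        other = k_calls.get(si)
        if other is None:
            continue
        w = weights[si]
        score += w if call == other else -w
    return score


@dataclass
class PhaseState:
    """Mutable state of the propagation: per-read labels, blocks, scores."""

    assignment: dict[str, int] = field(default_factory=dict)  # read_key -> H1/H2
    block_of: dict[str, int] = field(default_factory=dict)  # read_key -> final PS
    comp_of: dict[str, int] = field(default_factory=dict)  # read_key -> component id
    scores: dict[str, tuple[int, int]] = field(default_factory=dict)
    conflicted: set[str] = field(default_factory=set)
    stats: dict = field(default_factory=dict)

    def haplotype(self, read_key: str) -> int:
        return self.assignment.get(read_key, UNASSIGNED)


def phase_scores(
    r: ReadObservation,
    state: PhaseState,
    assigned_overlaps: Iterable[ReadObservation],
    weights: Sequence[int],
) -> tuple[int, int]:
    """(P1, P2) of ``r`` against the currently assigned overlapping reads."""
    p1 = p2 = 0
    for k in assigned_overlaps:
        hp = state.haplotype(k.read_key)
        if hp == UNASSIGNED:
            continue
        s = pair_score(r, k, weights)
        if hp == H1:
            p1 += s
        else:
            p2 += s
    return p1, p2


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[int, int] = {}

    def make(self, x: int) -> None:
        self.parent.setdefault(x, x)

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _site_weights(sites: Sequence[HetSite]) -> list[int]:
    return [site_weight(s) for s in sites]


def run_phasing(
    observations: Sequence[ReadObservation],
    sites: Sequence[HetSite],
) -> tuple[PhaseState, list["HaplotypeBlock"]]:
    """Single-sweep propagation over coordinate-ordered observations.

    Returns the phase state and the consensus haplotype blocks.  The
    sweep is fully deterministic: ties in the phase scores are broken by
    the strongest single pairwise connection, then by lexicographic read
    key.  Blocks are the connected components of the read–site incidence
    graph, identified by the position of their leftmost phased site.
    """
    weights = _site_weights(sites)
    state = PhaseState()
    uf = _UnionFind()
    site_readers: dict[int, list[int]] = {}  # site_index -> obs indices already placed
    n_ties = 0
    n_zero_ties = 0

    call_maps = [ob.call_map() for ob in observations]
    for idx, r in enumerate(observations):
        # assigned observations sharing at least one site with r
        cand: set[int] = set()
        for si, _ in r.obs:
            cand.update(site_readers.get(si, ()))
        uf.make(idx)
        p1 = p2 = 0
        best_mag = 0
        best_hint = UNASSIGNED
        best_key: Optional[str] = None
        if cand:
            for j in sorted(cand):
                k = observations[j]
                s = pair_score(r, k, weights, k_calls=call_maps[j])
                hp = state.assignment[k.read_key]
                if hp == H1:
                    p1 += s
                else:
                    p2 += s
                mag = abs(s)
                hint = UNASSIGNED
                if s > 0:
                    hint = hp
                elif s < 0:
                    hint = H1 if hp == H2 else H2
                if mag > best_mag or (
                    mag == best_mag and best_key is not None and mag > 0 and k.read_key < best_key
                ):
                    best_mag, best_hint, best_key = mag, hint, k.read_key
                uf.union(idx, j)

        if not cand:
            hp = H1  # seed of a new component
        elif p1 > p2:
            hp = H1
        elif p2 > p1:
            hp = H2
        else:
            n_ties += 1
            if best_mag > 0:
                hp = best_hint  # strongest single phase connection decides
            else:
                n_zero_ties += 1
                hp = H1
        state.assignment[r.read_key] = hp
        state.scores[r.read_key] = (p1, p2)
        if min(p1, p2) > 0:
            state.conflicted.add(r.read_key)
        for si, _ in r.obs:
            site_readers.setdefault(si, []).append(idx)

    for idx, r in enumerate(observations):
        state.comp_of[r.read_key] = uf.find(idx)
    state.stats.update(
        n_reads=len(observations),
        n_ties=n_ties,
        n_zero_score_ties=n_zero_ties,
        n_conflicted=len(state.conflicted),
    )
    blocks = consensus_sites(state, observations, sites)
    return state, blocks


def _components(
    state: PhaseState, observations: Sequence[ReadObservation]
) -> dict[int, list[int]]:
    comps: dict[int, list[int]] = {}
    for idx, ob in enumerate(observations):
        comps.setdefault(state.comp_of[ob.read_key], []).append(idx)
    return comps


def mate_pair_repair(
    state: PhaseState,
    observations: Sequence[ReadObservation],
    sites: Sequence[HetSite],
    max_repair_passes: int = 3,
) -> PhaseState:
    """Repair mate pairs assigned to different haplotypes of the same block.

    For each discordant pair, both members' phase scores are recomputed
    with a mate-consistency bonus equal to the mate's score margin
    |P1 - P2| credited to the mate's haplotype; the member whose flip
    most increases total agreement is flipped.  Sweeps repeat until no
    flip helps or ``max_repair_passes`` is reached.  Mates in different
    blocks are left alone.
    """
    weights = _site_weights(sites)
    by_key = {ob.read_key: i for i, ob in enumerate(observations)}
    call_maps = [ob.call_map() for ob in observations]
    # neighbour index: for each obs, assigned obs sharing >=1 site
    site_readers: dict[int, list[int]] = {}
    for i, ob in enumerate(observations):
        for si, _ in ob.obs:
            site_readers.setdefault(si, []).append(i)

    def fresh_scores(i: int) -> tuple[int, int]:
        r = observations[i]
        cand: set[int] = set()
        for si, _ in r.obs:
            cand.update(site_readers.get(si, ()))
        cand.discard(i)
        p1 = p2 = 0
        for j in sorted(cand):
            k = observations[j]
            hp = state.haplotype(k.read_key)
            if hp == UNASSIGNED:
                continue
            s = pair_score(r, k, weights, k_calls=call_maps[j])
            if hp == H1:
                p1 += s
            else:
                p2 += s
        return p1, p2

    n_flips = 0
    for _ in range(max_repair_passes):
        flipped_this_pass = False
        for i, ob in enumerate(observations):
            mk = ob.mate_key
            if mk is None or mk not in by_key or ob.read_key > mk:
                continue  # visit each pair once, from its lexicographic head
            j = by_key[mk]
            ki, kj = ob.read_key, mk
            if state.comp_of.get(ki) != state.comp_of.get(kj):
                continue
            hi, hj = state.haplotype(ki), state.haplotype(kj)
            if hi == UNASSIGNED or hj == UNASSIGNED or hi == hj:
                continue  # M(r_i, r_j) = +1: concordant, nothing to do
            pi = fresh_scores(i)
            pj = fresh_scores(j)
            bonus_i = abs(pj[0] - pj[1])  # mate's margin credited to mate's haplotype
            bonus_j = abs(pi[0] - pi[1])
            # gain from flipping member x to its mate's haplotype
            gain_i = (pi[hj - 1] + bonus_i) - pi[hi - 1]
            gain_j = (pj[hi - 1] + bonus_j) - pj[hj - 1]
            if gain_i <= 0 and gain_j <= 0:
                continue
            if gain_i > gain_j or (gain_i == gain_j and ki < kj):
                state.assignment[ki] = hj
                state.scores[ki] = pi
            else:
                state.assignment[kj] = hi
                state.scores[kj] = pj
            n_flips += 1
            flipped_this_pass = True
        if not flipped_this_pass:
            break
    state.stats["n_mate_repairs"] = state.stats.get("n_mate_repairs", 0) + n_flips
    return state


@dataclass
class HaplotypeBlock:
    """A maximal set of sites whose relative phase is resolved.

    ``site_orientation`` pairs each site_index with the allele code
    (0 = allele_a, 1 = allele_b) placed on haplotype 1.  ``block_id`` is
    the 1-based position of the leftmost phased site and doubles as the
    VCF PS value.
    """

    block_id: int
    chrom: str
    site_orientation: tuple[tuple[int, int], ...]
    span: tuple[int, int]
    n_reads: int

    @property
    def n_sites(self) -> int:
        return len(self.site_orientation)

    @property
    def span_bp(self) -> int:
        return self.span[1] - self.span[0] + 1

    def orientation_map(self) -> dict[int, int]:
        return dict(self.site_orientation)

    def flipped(self) -> "HaplotypeBlock":
        return HaplotypeBlock(
            block_id=self.block_id,
            chrom=self.chrom,
            site_orientation=tuple((si, 1 - c) for si, c in self.site_orientation),
            span=self.span,
            n_reads=self.n_reads,
        )


def consensus_sites(
    state: PhaseState,
    observations: Sequence[ReadObservation],
    sites: Sequence[HetSite],
    min_block_sites: int = 2,
) -> list[HaplotypeBlock]:
    """Per-site weighted vote of read assignments into haplotype blocks.

    For each connected component and site, haplotype-1 reads vote for
    the allele they carry and haplotype-2 reads for the opposite one,
    each vote weighted by w(s); a tied vote leaves the site unphased.
    Components retaining fewer than ``min_block_sites`` phased sites are
    dropped.  Updates ``state.block_of`` to the surviving block ids.
    """
    state.block_of.clear()
    blocks: list[HaplotypeBlock] = []
    for comp_id, idxs in sorted(_components(state, observations).items()):
        votes: dict[int, int] = {}  # site_index -> net weight for allele_a on H1
        for i in idxs:
            ob = observations[i]
            hp = state.haplotype(ob.read_key)
            if hp == UNASSIGNED:
                continue
            for si, call in ob.obs:
                w = sites[si].weight
                # an H1 read carrying allele_a, or an H2 read carrying
                # allele_b, supports allele_a on haplotype 1
                supports_a = (call == A_ALLELE) == (hp == H1)
                votes[si] = votes.get(si, 0) + (w if supports_a else -w)
        orient = tuple(
            (si, A_ALLELE if net > 0 else 1 - A_ALLELE)
            for si, net in sorted(votes.items())
            if net != 0
        )
        if len(orient) < min_block_sites:
            continue
        first, last = sites[orient[0][0]], sites[orient[-1][0]]
        block = HaplotypeBlock(
            block_id=first.pos,
            chrom=first.chrom,
            site_orientation=orient,
            span=(first.pos, last.pos),
            n_reads=len(idxs),
        )
        blocks.append(block)
        for i in idxs:
            state.block_of[observations[i].read_key] = block.block_id
    blocks.sort(key=lambda b: (b.chrom, b.block_id))
    return blocks
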