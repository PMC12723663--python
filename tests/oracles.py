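"""Independent oracles for the test suite.

These deliberately avoid the package's own propagation/consensus code
paths: the phasing oracle enumerates every read labeling, the N50 oracle
scans candidate lengths.  Both are only feasible at tiny n, which is the
point.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from hapweave.read_association import ReadObservation
from hapweave.variant_io import INDEL, SNP, HetSite


def make_sites(alleles: Sequence[tuple[str, str]], spacing: int = 100) -> list[HetSite]:
    """Synthetic het-site list from (allele_a, allele_b) pairs."""
    sites = []
    for i, (a, b) in enumerate(alleles):
        snp = len(a) == 1 and len(b) == 1
        sites.append(
            HetSite(
                chrom="chr1",
                pos=spacing * (i + 1),
                allele_a=a,
                allele_b=b,
                ref_len=len(a),
                vclass=SNP if snp else INDEL,
                weight=2 if snp else 1,
                qual_flagged=False,
                site_index=i,
            )
        )
    return sites


def make_obs(
    name: str,
    calls: dict[int, int],
    segment: int = 1,
    paired: bool = False,
    start: int | None = None,
) -> ReadObservation:
    """In-memory read observation (no SAM involved)."""
    first = min(calls) if calls else 0
    return ReadObservation(
        qname=name,
        segment=segment,
        mapq=60,
        start=start if start is not None else first,
        obs=tuple(sorted(calls.items())),
        paired=paired,
    )


def pairwise_disagreement(
    labels: Sequence[int],
    observations: Sequence[ReadObservation],
    weights: Sequence[int],
) -> int:
    """Total weighted disagreement of a read labeling (labels in {0,1}).

    For every read pair sharing sites: same label -> each differing call
    costs w(s); different labels -> each agreeing call costs w(s).
    """
    maps = [dict(ob.obs) for ob in observations]
    cost = 0
    for i in range(len(observations)):
        for j in range(i + 1, len(observations)):
            for si, ci in maps[i].items():
                cj = maps[j].get(si)
                if cj is None:
                    continue
                agree = ci == cj
                if (labels[i] == labels[j]) != agree:
                    cost += weights[si]
    return cost


def exhaustive_min_disagreement(
    observations: Sequence[ReadObservation],
    weights: Sequence[int],
) -> int:
    """Minimum pairwise disagreement over all 2^n read labelings.

    Enumerates every labeling; per pair the cost is (T_ij - s_i s_j Q_ij)/2
    with s in {-1,+1}, T the shared weight and Q the signed agreement —
    an exact rewrite of :func:`pairwise_disagreement` that vectorizes the
    enumeration (cross-checked against the plain loop in the unit tests).
    """
    n = len(observations)
    assert n <= 14, "exhaustive oracle is for tiny instances"
    if n == 0:
        return 0
    maps = [dict(ob.obs) for ob in observations]
    T = np.zeros((n, n))
    Q = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            for si, ci in maps[i].items():
                cj = maps[j].get(si)
                if cj is None:
                    continue
                T[i, j] += weights[si]
                Q[i, j] += weights[si] if ci == cj else -weights[si]
    codes = np.arange(2**n, dtype=np.int64)
    signs = 1 - 2 * ((codes[:, None] >> np.arange(n)) & 1)
    cost = (T.sum() - np.einsum("ki,ij,kj->k", signs, Q, signs)) / 2
    return int(round(cost.min()))


def random_conflict_free_instance(rng: np.random.Generator):
    """Random sites, truth orientation and error-free reads from it.

    Reads copy the truth exactly, so the minimum pairwise disagreement
    is zero and the truth orientation is an optimal solution.
    Returns (sites, truth codes per site, observations).
    """
    n_sites = int(rng.integers(2, 9))
    n_reads = int(rng.integers(2, 11))
    alleles = [("C", "T") if rng.random() < 0.8 else ("A", "AT") for _ in range(n_sites)]
    sites = make_sites(alleles)
    truth = rng.integers(0, 2, size=n_sites)
    observations = []
    for i in range(n_reads):
        lo = int(rng.integers(0, n_sites - 1))
        hi = int(rng.integers(lo + 2, n_sites + 1))  # span >= 2 sites
        hap = int(rng.integers(0, 2))
        calls = {
            si: int(truth[si]) if hap == 0 else int(1 - truth[si])
            for si in range(lo, hi)
        }
        observations.append(make_obs(f"r{i:03d}", calls, start=lo))
    observations.sort(key=lambda o: (o.start, o.read_key))
    return sites, truth, observations


def blocks_match_truth(blocks, truth) -> bool:
    """Every block's orientation equals the truth up to a whole-block flip."""
    for b in blocks:
        matches = {code == int(truth[si]) for si, code in b.site_orientation}
        if len(matches) > 1:
            return False
    return True


def n50_oracle(sizes: Sequence[int]) -> int:
    """Scan candidate lengths: smallest L with sum(sizes >= L) covering half."""
    total = sum(sizes)
    if total == 0:
        return 0
    best = None
    for cand in sorted(set(sizes)):
        covered = sum(s for s in sizes if s >= cand)
        if 2 * covered >= total:
            best = cand  # larger candidates cover less; keep the last passing one
    # candidates are scanned ascending; the *largest* passing L is the N50
    return best if best is not None else min(sizes)
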