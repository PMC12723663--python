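"""Phasing evaluation: trio truth sets and block/accuracy metrics.

Accuracy is flip-invariant: a haplotype block's H1/H2 polarity is
arbitrary, so each block is compared to the truth under the better of
its two orientations (majority flip).  The headline accuracy divides
correctly phased truth sites by *all* truth heterozygous sites, so an
unphased truth site counts as a failure and phased % bounds accuracy
from above; the phased-only variant is reported alongside for
sensitivity.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .phase_engine import HaplotypeBlock
from .variant_io import A_ALLELE, B_ALLELE, SNP, HetSite

__all__ = [
    "TruthSet",
    "PhasingMetrics",
    "build_trio_truth",
    "score_phasing",
    "n50",
    "common_site_errors",
]


@dataclass
class TruthSet:
    """Phase truth at trio-resolvable sites.

    ``paternal`` maps site_index to the allele code (0 = allele_a,
    1 = allele_b) transmitted by parent 1.  Sites where transmission is
    not uniquely determined by the parental genotypes are absent;
    Mendelian-inconsistent sites are counted in ``n_inconsistent``.
    """

    paternal: dict[int, int] = field(default_factory=dict)
    n_inconsistent: int = 0
    n_ambiguous: int = 0

    def __len__(self) -> int:
        return len(self.paternal)


def build_trio_truth(
    child_sites: Sequence[HetSite],
    father_gt: Mapping[int, tuple[str, str]],
    mother_gt: Mapping[int, tuple[str, str]],
) -> TruthSet:
    """Resolve child phase from parental genotypes at Mendelian-informative loci.

    Parental genotypes are given as allele-sequence pairs keyed by the
    child's site_index.  A site enters the truth set iff exactly one
    (paternal, maternal) transmitted-allele assignment is compatible
    with both parents — which covers opposite-homozygote parents and
    het × hom parents, and excludes the double-het configuration.
    """
    truth = TruthSet()
    for site in child_sites:
        fg = father_gt.get(site.site_index)
        mg = mother_gt.get(site.site_index)
        if fg is None or mg is None:
            continue
        child = {site.allele_a, site.allele_b}
        assignments = {
            (fa, mo)
            for fa in set(fg)
            for mo in set(mg)
            if {fa, mo} == child
        }
        if not assignments:
            truth.n_inconsistent += 1
            continue
        if len(assignments) > 1:
            truth.n_ambiguous += 1
            continue
        fa, _ = next(iter(assignments))
        truth.paternal[site.site_index] = A_ALLELE if fa == site.allele_a else B_ALLELE
    return truth


@dataclass
class PhasingMetrics:
    """The per-sample summary statistics of one phasing run."""

    phased_pct: float
    accuracy_pct: float
    accuracy_snp_pct: float
    accuracy_indel_pct: float
    accuracy_of_phased_pct: float  # phased truth sites only in the denominator
    n_blocks: int
    median_block_bp: float
    n50_bp: int
    total_phased_bp: int
    switch_errors: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _pct(num: float, den: float) -> float:
    return 100.0 * num / den if den else 0.0


def score_phasing(
    blocks: Sequence[HaplotypeBlock],
    truth: TruthSet,
    sites: Sequence[HetSite],
) -> PhasingMetrics:
    """Score blocks against a truth set.

    Per block the orientation (as-is vs flipped) maximising agreement
    over the block's truth sites is chosen; a truth site is correct iff
    its orientation matches under that flip.  Block-size statistics are
    computed on the block spans in bp.
    """
    phased_sites: set[int] = set()
    for b in blocks:
        phased_sites.update(si for si, _ in b.site_orientation)

    correct: dict[int, bool] = {}
    switch_errors = 0
    for b in blocks:
        entries = [(si, code) for si, code in b.site_orientation if si in truth.paternal]
        if not entries:
            continue
        agree = sum(1 for si, code in entries if code == truth.paternal[si])
        flip = agree < len(entries) - agree
        prev_ok: Optional[bool] = None
        for si, code in entries:
            ok = (code == truth.paternal[si]) != flip
            correct[si] = ok
            if prev_ok is not None and ok != prev_ok:
                switch_errors += 1
            prev_ok = ok

    truth_sites = set(truth.paternal)
    n_truth = len(truth_sites)
    n_correct = sum(correct.values())
    snp_truth = {si for si in truth_sites if sites[si].vclass == SNP}
    indel_truth = truth_sites - snp_truth
    phased_truth = truth_sites & phased_sites

    spans = sorted(b.span_bp for b in blocks)
    return PhasingMetrics(
        phased_pct=_pct(len(phased_sites), len(sites)),
        accuracy_pct=_pct(n_correct, n_truth),
        accuracy_snp_pct=_pct(
            sum(1 for si in snp_truth if correct.get(si, False)), len(snp_truth)
        ),
        accuracy_indel_pct=_pct(
            sum(1 for si in indel_truth if correct.get(si, False)), len(indel_truth)
        ),
        accuracy_of_phased_pct=_pct(n_correct, len(phased_truth)),
        n_blocks=len(blocks),
        median_block_bp=float(statistics.median(spans)) if spans else 0.0,
        n50_bp=n50(blocks),
        total_phased_bp=sum(spans),
        switch_errors=switch_errors,
    )


def n50(blocks) -> int:
    """Smallest block span such that blocks at least that long cover half the total span.

    Accepts HaplotypeBlocks or plain integer sizes; returns 0 for empty
    input.
    """
    sizes = sorted(
        (b if isinstance(b, int) else b.span_bp) for b in blocks
    )
    total = sum(sizes)
    if total == 0:
        return 0
    acc = 0
    for size in reversed(sizes):
        acc += size
        if 2 * acc >= total:
            return size
    return sizes[0]  # pragma: no cover


def common_site_errors(
    results_by_method: Mapping[str, Sequence[HaplotypeBlock]],
    truth: TruthSet,
) -> dict[str, Optional[float]]:
    """Error % per method over the truth sites phased by *every* method.

    Restricting to the common set makes the comparison independent of
    how aggressively each method phases.  With an empty intersection the
    result is None for every method.
    """
    common: Optional[set[int]] = None
    for blocks in results_by_method.values():
        phased = set()
        for b in blocks:
            phased.update(si for si, _ in b.site_orientation)
        phased &= set(truth.paternal)
        common = phased if common is None else (common & phased)
    if not common:
        return {name: None for name in results_by_method}

    out: dict[str, Optional[float]] = {}
    for name, blocks in results_by_method.items():
        n_wrong = 0
        for b in blocks:
            entries = [
                (si, code) for si, code in b.site_orientation if si in common
            ]
            if not entries:
                continue
            agree = sum(1 for si, code in entries if code == truth.paternal[si])
            n_wrong += min(agree, len(entries) - agree)
        out[name] = _pct(n_wrong, len(common))
    return out
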