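"""Alignment-side outputs: haplotagged BAM, per-haplotype split BAMs, block BED.

Reads that ended up in a surviving haplotype block are tagged with
``HP`` (haplotype, 1 or 2) and ``HT`` (block identifier, equal to the
VCF PS value); everything else passes through untouched, so the
annotated file has exactly the record count of the input.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pysam

from .phase_engine import HaplotypeBlock, PhaseState
from .variant_io import ConsistencyError, InputError


def _open_in(path: str, reference: str | None = None) -> pysam.AlignmentFile:
    kwargs = {"reference_filename": reference} if reference else {}
    try:
        return pysam.AlignmentFile(path, **kwargs)
    except (FileNotFoundError, OSError) as exc:
        raise InputError(f"cannot open alignment file {path!r}: {exc}") from exc


def _open_out(path: str, template: pysam.AlignmentFile) -> pysam.AlignmentFile:
    mode = "wb" if str(path).endswith(".bam") else "w"
    return pysam.AlignmentFile(path, mode, template=template)


def _record_key(rec: pysam.AlignedSegment) -> str:
    return f"{rec.query_name}/{2 if rec.is_read2 else 1}"


def _maybe_index(path: str) -> None:
    if str(path).endswith(".bam"):
        try:
            pysam.index(str(path))
        except pysam.SamtoolsError:  # pragma: no cover - unsorted input
            pass


def _tagged_keys(state: PhaseState, blocks: Iterable[HaplotypeBlock]) -> dict[str, tuple[int, int]]:
    valid = {b.block_id for b in blocks}
    out: dict[str, tuple[int, int]] = {}
    for key, block_id in state.block_of.items():
        if block_id in valid:
            out[key] = (state.assignment[key], block_id)
    return out


def write_annotated_bam(
    bam_in: str,
    state: PhaseState,
    blocks: Sequence[HaplotypeBlock],
    bam_out: str,
    reference: str | None = None,
) -> None:
    """Copy the alignment file, adding HP/HT tags to assigned reads."""
    tags = _tagged_keys(state, blocks)
    seen: set[str] = set()
    with _open_in(bam_in, reference) as fin, _open_out(bam_out, fin) as fout:
        for rec in fin.fetch(until_eof=True):
            if not (rec.is_secondary or rec.is_supplementary):
                key = _record_key(rec)
                entry = tags.get(key)
                if entry is not None:
                    seen.add(key)
                    rec.set_tag("HP", entry[0], value_type="i")
                    rec.set_tag("HT", entry[1], value_type="i")
            fout.write(rec)
    missing = set(tags) - seen
    if missing:
        raise ConsistencyError(
            f"{len(missing)} phased reads absent from {bam_in!r} (e.g. {sorted(missing)[:3]})"
        )
    _maybe_index(bam_out)


def write_split_bams(
    bam_in: str,
    state: PhaseState,
    blocks: Sequence[HaplotypeBlock],
    out_h1: str,
    out_h2: str,
    include_unassigned: bool = False,
    reference: str | None = None,
) -> None:
    """Split the alignment into one file per haplotype.

    Assigned reads go to the file of their haplotype only.  Unassigned
    reads are dropped by default; with ``include_unassigned`` they are
    written to both files so per-haplotype coverage stays comparable to
    the input.
    """
    tags = _tagged_keys(state, blocks)
    with _open_in(bam_in, reference) as fin, _open_out(out_h1, fin) as f1, _open_out(
        out_h2, fin
    ) as f2:
        for rec in fin.fetch(until_eof=True):
            if rec.is_secondary or rec.is_supplementary:
                continue
            entry = tags.get(_record_key(rec))
            if entry is None:
                if include_unassigned:
                    f1.write(rec)
                    f2.write(rec)
                continue
            (f1 if entry[0] == 1 else f2).write(rec)
    _maybe_index(out_h1)
    _maybe_index(out_h2)


def write_blocks_bed(blocks: Sequence[HaplotypeBlock], out: str) -> None:
    """BED5 of block extents: 0-based half-open, name = PS, score = site count."""
    ordered = sorted(blocks, key=lambda b: (b.chrom, b.span[0]))
    with open(out, "w") as fh:
        for b in ordered:
            fh.write(f"{b.chrom}\t{b.span[0] - 1}\t{b.span[1]}\t{b.block_id}\t{b.n_sites}\n")
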