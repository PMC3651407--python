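"""Contig-end linkage from mate-pair read mappings, with gap-size estimates.

A mate-pair library of nominal insert size I places two reads at the outer
ends of an I-bp genomic fragment.  When the mates map to two different
contigs the pair spans the gap between them, and the gap size is the insert
minus the two distances from each mate's outer (fragment-boundary) base to
its contig's attached end:  gap = I - d_a - d_b.  Negative estimates mean
the contigs are predicted to overlap.

Alignment is not done here: an already-mapped SAM file (pysam-readable,
with @SQ headers naming the contigs) is consumed, and only the filtering,
end-attachment and gap arithmetic live in this module.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import pysam

from .errors import SamFormatError
from .graph_core import EndNode, contig_id_from_name

MIN_MAPQ = 20
MIN_CONTIG = 500
MIN_SUPPORT = 3


@dataclass(frozen=True)
class MateMapping:
    contig_id: int
    start: int  # 1-based leftmost aligned position
    strand: str  # '+' | '-'
    aligned_span: int
    mapq: int


@dataclass(frozen=True)
class PairMapping:
    pair_id: str
    mate_a: MateMapping
    mate_b: MateMapping
    library_insert: int
    library_orientation: str  # 'FR' | 'RF'


@dataclass
class ScaffoldLink:
    end_a: EndNode
    end_b: EndNode
    support: int
    gap_estimates: list[int] = field(default_factory=list)

    @property
    def gap_median(self) -> float:
        return statistics.median(self.gap_estimates)


def read_pair_mappings(
    sam_path: Union[str, Path],
    insert: int,
    orientation: str = "FR",
    min_mapq: int = MIN_MAPQ,
    min_contig: int = MIN_CONTIG,
) -> tuple[list[PairMapping], dict[str, int]]:
    """Load spanning mate pairs from a SAM file.

    Keeps only primary, non-duplicate alignments where both mates map to
    *different* contigs, each with mapq >= ``min_mapq``, and both contigs
    are longer than ``min_contig`` (the >500 bp rule: tiny contigs attract
    ambiguous mappings).  Intra-contig pairs carry no linkage information
    and are discarded.  Returns the pairs and a tally of discard reasons.
    """
    orientation = orientation.upper()
    if orientation not in ("FR", "RF"):
        raise ValueError(f"orientation must be FR or RF, got {orientation!r}")
    stats = {"intra_contig": 0, "low_mapq": 0, "small_contig": 0, "kept": 0}
    pending: dict[str, MateMapping] = {}
    with pysam.AlignmentFile(str(sam_path), "r") as sam:
        lengths = {sq["SN"]: sq["LN"] for sq in sam.header.get("SQ", [])}
        pairs: list[PairMapping] = []
        for aln in sam:
            if (
                aln.is_unmapped
                or aln.mate_is_unmapped
                or aln.is_secondary
                or aln.is_supplementary
                or aln.is_duplicate
                or not aln.is_paired
            ):
                continue
            if aln.reference_name not in lengths:
                raise SamFormatError(
                    f"alignment references {aln.reference_name!r} absent from @SQ"
                )
            mate = MateMapping(
                contig_id=contig_id_from_name(aln.reference_name),
                start=aln.reference_start + 1,
                strand="-" if aln.is_reverse else "+",
                aligned_span=aln.reference_length or len(aln.query_sequence or ""),
                mapq=aln.mapping_quality,
            )
            other = pending.pop(aln.query_name, None)
            if other is None:
                pending[aln.query_name] = mate
                continue
            a, b = other, mate
            if a.contig_id == b.contig_id:
                stats["intra_contig"] += 1
                continue
            if a.mapq < min_mapq or b.mapq < min_mapq:
                stats["low_mapq"] += 1
                continue
            len_by_id = {contig_id_from_name(n): l for n, l in lengths.items()}
            if len_by_id[a.contig_id] <= min_contig or len_by_id[b.contig_id] <= min_contig:
                stats["small_contig"] += 1
                continue
            stats["kept"] += 1
            pairs.append(
                PairMapping(
                    pair_id=aln.query_name,
                    mate_a=a,
                    mate_b=b,
                    library_insert=insert,
                    library_orientation=orientation,
                )
            )
    return pairs, stats


def _attach(mate: MateMapping, contig_len: int, orientation: str) -> tuple[str, int]:
    """Which contig end a mate attaches to, and the distance d from the
    mate's outermost (fragment-boundary) base to that end, 1-based inclusive.

    FR: a '+' mate's outer base is its 5' start and the fragment continues
    rightwards past the contig 3' end, so it attaches E with
    d = length - start + 1; a '-' mate attaches S with d = start + span - 1.
    RF points the reads outwards, which swaps the two cases.
    """
    strand = mate.strand
    if orientation == "RF":  # outward-facing reads behave like the flipped strand
        strand = "-" if strand == "+" else "+"
    if strand == "+":
        return "E", contig_len - mate.start + 1
    return "S", mate.start + mate.aligned_span - 1


def pair_to_end_link(
    pm: PairMapping, contig_lengths: Mapping[int, int]
) -> Optional[tuple[EndNode, EndNode, int, int]]:
    """Convert one spanning pair to (end_a, end_b, d_a, d_b).

    Returns None (anomaly) when a distance exceeds its contig length —
    geometrically impossible for a genuine spanning pair.
    """
    out = []
    for mate in (pm.mate_a, pm.mate_b):
        length = contig_lengths[mate.contig_id]
        end, d = _attach(mate, length, pm.library_orientation)
        if d > length or d < 0:
            return None
        out.append((EndNode(mate.contig_id, end), d))
    (end_a, d_a), (end_b, d_b) = out
    return end_a, end_b, d_a, d_b


def estimate_gap(insert: int, d_a: int, d_b: int) -> int:
    """Gap size = insert - d_a - d_b; negative means predicted overlap."""
    if insert <= 0:
        raise ValueError("insert must be > 0")
    if d_a < 0 or d_b < 0:
        raise ValueError("distances must be >= 0")
    return insert - d_a - d_b


def aggregate_links(
    pairs: list[PairMapping],
    contig_lengths: Mapping[int, int],
    min_support: int = MIN_SUPPORT,
) -> list[ScaffoldLink]:
    """Group spanning pairs by unordered end pair into ScaffoldLinks.

    Support is the group size, the gap estimate is the exact median, and
    groups below ``min_support`` are dropped.  Sorted by support, descending.
    """
    groups: dict[tuple, ScaffoldLink] = {}
    for pm in pairs:
        converted = pair_to_end_link(pm, contig_lengths)
        if converted is None:
            continue
        end_a, end_b, d_a, d_b = converted
        if end_b.sort_key < end_a.sort_key:
            end_a, end_b = end_b, end_a
        key = (end_a.sort_key, end_b.sort_key)
        link = groups.get(key)
        if link is None:
            link = groups[key] = ScaffoldLink(end_a, end_b, support=0)
        link.support += 1
        link.gap_estimates.append(estimate_gap(pm.library_insert, d_a, d_b))
    out = [lk for lk in groups.values() if lk.support >= min_support]
    out.sort(key=lambda lk: (-lk.support, lk.end_a.sort_key, lk.end_b.sort_key))
    return out


def links_table(links: list[ScaffoldLink]) -> list[tuple[str, str, int]]:
    """ScaffoldLinks as (endA, endB, support) rows for graph building."""
    return [(lk.end_a.label, lk.end_b.label, lk.support) for lk in links]
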