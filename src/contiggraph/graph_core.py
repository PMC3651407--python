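"""Contig-relationship graph: data model, coverage statistics, classification.

The graph models each contig as an *edge* between two end-nodes, ``<id>S``
(the 5' start) and ``<id>E`` (the 3' end).  Evidence that two contig ends are
adjacent in the genome — split 454 reads, spanning mate pairs, or rows of a
CRS file — becomes a *link edge* between end-nodes of different contigs (or
between the two ends of one contig, for a circular single-contig replicon).

Coverage statistics drive repeat detection: a contig whose read depth is at
least ``repeat_min`` (default 2.0) times the average genome coverage is
called a repeat contig, below ``unique_max`` (default 1.5) a unique contig,
and in between a probable repeat that needs PCR confirmation.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

from .errors import (
    ContigGraphError,
    EndLabelError,
    ReferentialIntegrityError,
    UndefinedValueError,
)

LARGE_CONTIG_MIN = 20_000
UNIQUE_MAX_RATIO = 1.5
REPEAT_MIN_RATIO = 2.0


class ContigClass(str, Enum):
    UNIQUE = "UNIQUE"
    PROBABLE_REPEAT = "PROBABLE_REPEAT"
    REPEAT = "REPEAT"
    UNCLASSIFIED = "UNCLASSIFIED"


class LinkSource(str, Enum):
    ACE_SPLIT_READ = "ACE_SPLIT_READ"
    MATE_PAIR = "MATE_PAIR"
    CRS = "CRS"
    MANUAL = "MANUAL"


class CoverageMode(str, Enum):
    #: total assembled read bases / total contig length
    ACE_TOTAL = "ACE_TOTAL"
    #: unweighted mean per-contig coverage over contigs larger than 20 kb
    CRS_LARGE_CONTIG_MEAN = "CRS_LARGE_CONTIG_MEAN"


_END_LABEL_RE = re.compile(r"^(\d+)([SE])$")
_TRAILING_DIGITS_RE = re.compile(r"(\d+)\s*$")


@dataclass(frozen=True)
class EndNode:
    """One terminus of a contig: ``end`` is 'S' (position 1) or 'E'."""

    contig_id: int
    end: str  # 'S' | 'E'

    def __post_init__(self):
        if self.contig_id <= 0:
            raise EndLabelError(f"contig id must be positive, got {self.contig_id}")
        if self.end not in ("S", "E"):
            raise EndLabelError(f"end must be 'S' or 'E', got {self.end!r}")

    @property
    def label(self) -> str:
        return f"{self.contig_id}{self.end}"

    @property
    def sort_key(self) -> tuple[int, int]:
        return (self.contig_id, 0 if self.end == "S" else 1)

    def other(self) -> "EndNode":
        return EndNode(self.contig_id, "E" if self.end == "S" else "S")

    def __str__(self) -> str:
        return self.label


def parse_end_label(token: str) -> EndNode:
    """Parse '106S' / '106E' style labels; raise EndLabelError otherwise."""
    m = _END_LABEL_RE.match(str(token).strip())
    if not m:
        raise EndLabelError(f"malformed end label: {token!r}")
    return EndNode(int(m.group(1)), m.group(2))


def contig_id_from_name(name: str) -> int:
    """Map a contig name to its numeric id via the trailing digits.

    'contig00042' -> 42, '7' -> 7.  Names without digits are rejected:
    graph node labels are '<id>S'/'<id>E' and need numeric ids.
    """
    m = _TRAILING_DIGITS_RE.search(str(name))
    if not m:
        raise ContigGraphError(f"contig name {name!r} has no numeric suffix")
    n = int(m.group(1))
    if n <= 0:
        raise ContigGraphError(f"contig name {name!r} maps to non-positive id {n}")
    return n


@dataclass
class Contig:
    id: int
    name: str
    length: int
    abundance: float = 0.0
    klass: ContigClass = ContigClass.UNCLASSIFIED
    copy_number: float = 0.0
    sequence: Optional[str] = None

    def __post_init__(self):
        if self.length <= 0:
            raise ContigGraphError(f"contig {self.name}: length must be > 0")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ContigGraphError(
                f"contig {self.name}: sequence length {len(self.sequence)} "
                f"!= declared length {self.length}"
            )


@dataclass
class LinkEdge:
    """Evidence edge joining two contig ends.  Canonically ordered."""

    end_a: EndNode
    end_b: EndNode
    support: int
    source: LinkSource = LinkSource.CRS
    display_weight: float = 0.0

    def __post_init__(self):
        if self.support < 1:
            raise ContigGraphError("link support must be >= 1")
        if self.end_b.sort_key < self.end_a.sort_key:
            self.end_a, self.end_b = self.end_b, self.end_a

    @property
    def key(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return (self.end_a.sort_key, self.end_b.sort_key)

    @property
    def is_self_link(self) -> bool:
        return self.end_a.contig_id == self.end_b.contig_id

    def touches(self, node: EndNode) -> bool:
        return self.end_a == node or self.end_b == node


@dataclass
class ContigGraph:
    """Contigs (edges with two end-nodes each) plus inter-contig link edges."""

    contigs: dict[int, Contig] = field(default_factory=dict)
    links: list[LinkEdge] = field(default_factory=list)
    avg_coverage: float = 0.0
    z_norm: float = 1.0
    coverage_mode: CoverageMode = CoverageMode.CRS_LARGE_CONTIG_MEAN

    # -- structure ---------------------------------------------------------
    def end_nodes(self) -> list[EndNode]:
        nodes = []
        for cid in sorted(self.contigs):
            nodes.append(EndNode(cid, "S"))
            nodes.append(EndNode(cid, "E"))
        return nodes

    def links_at(self, node: EndNode) -> list[LinkEdge]:
        out = []
        for lk in self.links:
            if lk.touches(node):
                out.append(lk)
                if lk.end_a == lk.end_b == node:  # degenerate, never built
                    out.append(lk)
        return out

    def link_degree(self, node: EndNode) -> int:
        """Number of link edges incident to an end-node (self-links at the
        same contig count once per touched end)."""
        return len(self.links_at(node))

    def neighbors(self, node: EndNode) -> list[EndNode]:
        out = []
        for lk in self.links:
            if lk.end_a == node:
                out.append(lk.end_b)
            elif lk.end_b == node:
                out.append(lk.end_a)
        return sorted(out, key=lambda n: n.sort_key)

    def get_link(self, end_a, end_b) -> LinkEdge:
        if isinstance(end_a, str):
            end_a = parse_end_label(end_a)
        if isinstance(end_b, str):
            end_b = parse_end_label(end_b)
        want = tuple(sorted((end_a.sort_key, end_b.sort_key)))
        for lk in self.links:
            if tuple(sorted((lk.end_a.sort_key, lk.end_b.sort_key))) == want:
                return lk
        from .errors import GraphLookupError

        raise GraphLookupError(f"no link {end_a}~{end_b} in graph")

    def class_tally(self) -> dict[ContigClass, int]:
        tally = {k: 0 for k in ContigClass}
        for c in self.contigs.values():
            tally[c.klass] += 1
        return tally


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def average_coverage(
    contigs: Sequence[Contig],
    mode: CoverageMode,
    large_min: int = LARGE_CONTIG_MIN,
    read_bases: Optional[float] = None,
) -> float:
    """Average genome coverage.

    ACE_TOTAL: total assembled read bases over total contig length (requires
    ``read_bases``).  CRS_LARGE_CONTIG_MEAN: unweighted mean of per-contig
    coverage over contigs strictly larger than ``large_min`` — repeat contigs
    above 20 kb are rare in microbial genomes, so this estimates the unique
    (single-copy) coverage without repeat inflation.  If no contig qualifies,
    falls back to the mean over all contigs.
    """
    contigs = list(contigs)
    if not contigs:
        raise ContigGraphError("average_coverage: no contigs")
    if mode == CoverageMode.ACE_TOTAL:
        if read_bases is None:
            raise ContigGraphError("ACE_TOTAL mode requires read_bases")
        total_len = sum(c.length for c in contigs)
        return read_bases / total_len
    large = [c for c in contigs if c.length > large_min]
    pool = large if large else contigs
    return sum(c.abundance for c in pool) / len(pool)


def classify_contig(
    abundance: float,
    avg: float,
    unique_max: float = UNIQUE_MAX_RATIO,
    repeat_min: float = REPEAT_MIN_RATIO,
) -> ContigClass:
    """Classify by depth ratio: <1.5 unique, [1.5, 2) probable repeat, >=2 repeat.

    A non-positive average (e.g. a purely relational CRS file without
    coverage) yields UNCLASSIFIED with a warning rather than an exception.
    """
    if not (0 < unique_max <= repeat_min):
        raise ContigGraphError("thresholds must satisfy 0 < unique_max <= repeat_min")
    if avg <= 0:
        warnings.warn(
            "average coverage <= 0; contigs left UNCLASSIFIED", stacklevel=2
        )
        return ContigClass.UNCLASSIFIED
    ratio = abundance / avg
    if ratio < unique_max:
        return ContigClass.UNIQUE
    if ratio < repeat_min:
        return ContigClass.PROBABLE_REPEAT
    return ContigClass.REPEAT


def copy_number(abundance: float, avg: float) -> float:
    """Contig abundance over average genome coverage (the repetition rate)."""
    if avg <= 0:
        raise UndefinedValueError("copy_number undefined for avg <= 0")
    return abundance / avg


def z_normalizer(
    graph: ContigGraph,
    large_min: int = LARGE_CONTIG_MIN,
    source: Optional[LinkSource] = None,
) -> float:
    """Mean link support among large-contig pairs; sets display weights.

    Z is the mean support over link edges both of whose contigs are at least
    ``large_min`` long.  support / Z becomes each edge's display width.
    Fallbacks keep weights finite: with no qualifying link, Z is the mean
    over all links; with no links at all, Z = 1 (weights equal raw support).
    Restrict to one evidence ``source`` to get a per-source Z (weights are
    then set on that source's edges only).
    """
    pool = graph.links if source is None else [l for l in graph.links if l.source == source]
    qualifying = [
        lk
        for lk in pool
        if graph.contigs[lk.end_a.contig_id].length >= large_min
        and graph.contigs[lk.end_b.contig_id].length >= large_min
    ]
    basis = qualifying or pool
    z = (sum(lk.support for lk in basis) / len(basis)) if basis else 1.0
    for lk in pool:
        lk.display_weight = lk.support / z
    if source is None:
        graph.z_norm = z
    return z


def unlinked_end_nodes(graph: ContigGraph) -> list[EndNode]:
    """End-nodes with no incident link edge (contig edges don't count).

    These are the positions needing extra scaffolding information or PCR.
    """
    touched: set[EndNode] = set()
    for lk in graph.links:
        touched.add(lk.end_a)
        touched.add(lk.end_b)
    return [n for n in graph.end_nodes() if n not in touched]


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def build_graph(
    contig_table: Iterable[tuple],
    link_table: Iterable[tuple],
    *,
    coverage_mode: CoverageMode = CoverageMode.CRS_LARGE_CONTIG_MEAN,
    source: LinkSource = LinkSource.CRS,
    read_bases: Optional[float] = None,
    names: Optional[Mapping[int, str]] = None,
    sequences: Optional[Mapping[int, str]] = None,
    unique_max: float = UNIQUE_MAX_RATIO,
    repeat_min: float = REPEAT_MIN_RATIO,
    large_min: int = LARGE_CONTIG_MIN,
) -> ContigGraph:
    """Build a ContigGraph from (id, length, abundance) and (endA, endB, support) rows.

    Duplicate unordered end pairs are merged by summing support.  Links that
    reference ids absent from the contig table are a referential-integrity
    error.  Coverage average, classification, copy numbers and Z-normalized
    display weights are computed on the way out.
    """
    contigs: dict[int, Contig] = {}
    for row in contig_table:
        cid, length, abundance = int(row[0]), int(row[1]), float(row[2])
        if cid <= 0:
            raise ContigGraphError(f"contig id must be positive: {cid}")
        if cid in contigs:
            raise ContigGraphError(f"duplicate contig id {cid}")
        name = names[cid] if names and cid in names else str(cid)
        seq = sequences.get(cid) if sequences else None
        contigs[cid] = Contig(id=cid, name=name, length=length,
                              abundance=abundance, sequence=seq)

    merged: dict[tuple, LinkEdge] = {}
    unknown: set[int] = set()
    for row in link_table:
        a = row[0] if isinstance(row[0], EndNode) else parse_end_label(row[0])
        b = row[1] if isinstance(row[1], EndNode) else parse_end_label(row[1])
        support = int(row[2]) if len(row) > 2 else 1
        if support < 1:
            raise ContigGraphError(f"link {a}~{b}: support must be >= 1")
        for node in (a, b):
            if node.contig_id not in contigs:
                unknown.add(node.contig_id)
        if unknown:
            continue
        edge = LinkEdge(a, b, support, source=source)
        if edge.key in merged:
            merged[edge.key].support += support
        else:
            merged[edge.key] = edge
    if unknown:
        raise ReferentialIntegrityError(
            "links reference contigs absent from the contig table: "
            + ", ".join(str(i) for i in sorted(unknown))
        )

    graph = ContigGraph(
        contigs=contigs,
        links=sorted(merged.values(), key=lambda e: e.key),
        coverage_mode=coverage_mode,
    )
    recompute_statistics(
        graph,
        read_bases=read_bases,
        unique_max=unique_max,
        repeat_min=repeat_min,
        large_min=large_min,
    )
    return graph


def recompute_statistics(
    graph: ContigGraph,
    *,
    read_bases: Optional[float] = None,
    unique_max: float = UNIQUE_MAX_RATIO,
    repeat_min: float = REPEAT_MIN_RATIO,
    large_min: int = LARGE_CONTIG_MIN,
) -> None:
    """(Re)derive avg coverage, classes, copy numbers and display weights."""
    if not graph.contigs:
        graph.avg_coverage = 0.0
        graph.z_norm = 1.0
        return
    if graph.coverage_mode == CoverageMode.ACE_TOTAL and read_bases is None:
        # total read bases recoverable from abundances: sum(ab * length)
        read_bases = sum(c.abundance * c.length for c in graph.contigs.values())
    graph.avg_coverage = average_coverage(
        list(graph.contigs.values()),
        graph.coverage_mode,
        large_min=large_min,
        read_bases=read_bases,
    )
    with warnings.catch_warnings():
        if graph.avg_coverage <= 0:
            warnings.simplefilter("once")
        for c in graph.contigs.values():
            c.klass = classify_contig(c.abundance, graph.avg_coverage,
                                      unique_max, repeat_min)
            c.copy_number = (
                copy_number(c.abundance, graph.avg_coverage)
                if graph.avg_coverage > 0
                else 0.0
            )
    z_normalizer(graph, large_min=large_min)


def filter_by_size(graph: ContigGraph, min_len: int) -> ContigGraph:
    """New graph keeping contigs of length >= min_len and surviving links.

    Statistics are recomputed on the filtered graph; the input is untouched.
    """
    if min_len < 0:
        raise ContigGraphError("min_len must be >= 0")
    kept = {cid: replace(c) for cid, c in graph.contigs.items() if c.length >= min_len}
    links = [
        LinkEdge(lk.end_a, lk.end_b, lk.support, lk.source)
        for lk in graph.links
        if lk.end_a.contig_id in kept and lk.end_b.contig_id in kept
    ]
    out = ContigGraph(contigs=kept, links=links, coverage_mode=graph.coverage_mode)
    if kept:
        recompute_statistics(out)
    return out
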