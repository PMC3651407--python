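"""CRS (Contig Relationship Scape) two-file exchange format.

``tabbed.txt`` holds end-to-end link counts (endA, endB, count) and
``tabbedCov.txt`` holds per-contig length and coverage (contig, length,
coverage).  Both are strict three-column, tab-separated UTF-8 text; lines
beginning '#' and blank lines are comments.  Scaffolder outputs (SSPACE,
OPERA, ...) are imported by converting to this generic 3-column form.
"""

from __future__ import annotations

from typing import Iterable, TextIO, Union

from .errors import CrsFormatError, ReferentialIntegrityError
from .graph_core import (
    ContigGraph,
    CoverageMode,
    LinkSource,
    build_graph,
    parse_end_label,
)

LINKS_HEADER = "#endA\tendB\tcount"
COVERAGE_HEADER = "#contig\tlength\tcoverage"


def _rows(stream: Union[str, TextIO], what: str) -> Iterable[tuple[int, list[str]]]:
    text = stream if isinstance(stream, str) else stream.read()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n\r")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 3:
            raise CrsFormatError(
                f"{what}: expected 3 tab-separated columns, got {len(cols)}",
                line=lineno,
            )
        yield lineno, [c.strip() for c in cols]


def read_crs(links_stream: Union[str, TextIO],
             coverage_stream: Union[str, TextIO]) -> ContigGraph:
    """Build a ContigGraph from tabbed.txt + tabbedCov.txt content.

    Coverage averaging uses the large-contig mean (the 20 kb rule), as the
    original assembly is not available in CRS form.  End labels in the link
    file must resolve to contigs present in the coverage file.
    """
    contig_rows = []
    for lineno, (cid_s, length_s, cov_s) in _rows(coverage_stream, "tabbedCov"):
        try:
            cid, length, cov = int(cid_s), int(length_s), float(cov_s)
        except ValueError as exc:
            raise CrsFormatError(f"tabbedCov: {exc}", line=lineno) from None
        if length <= 0:
            raise CrsFormatError(f"tabbedCov: non-positive length {length}", line=lineno)
        if cov < 0:
            raise CrsFormatError(f"tabbedCov: negative coverage {cov}", line=lineno)
        contig_rows.append((cid, length, cov))

    link_rows = []
    known = {cid for cid, _, _ in contig_rows}
    offenders = set()
    for lineno, (a_s, b_s, n_s) in _rows(links_stream, "tabbed"):
        try:
            count = int(n_s)
        except ValueError as exc:
            raise CrsFormatError(f"tabbed: {exc}", line=lineno) from None
        if count < 1:
            raise CrsFormatError(f"tabbed: count must be >= 1, got {count}", line=lineno)
        a, b = parse_end_label(a_s), parse_end_label(b_s)
        for node in (a, b):
            if node.contig_id not in known:
                offenders.add(node.contig_id)
        link_rows.append((a, b, count))
    if offenders:
        raise ReferentialIntegrityError(
            "tabbed.txt references contigs absent from tabbedCov.txt: "
            + ", ".join(str(i) for i in sorted(offenders))
        )

    return build_graph(
        contig_rows,
        link_rows,
        coverage_mode=CoverageMode.CRS_LARGE_CONTIG_MEAN,
        source=LinkSource.CRS,
    )


def write_crs(graph: ContigGraph) -> tuple[str, str]:
    """Serialize a graph to (tabbed.txt text, tabbedCov.txt text).

    Output is deterministic: coverage rows sorted by contig id, link rows by
    canonical end order.  read_crs(write_crs(g)) reproduces contigs, links
    and supports exactly.
    """
    cov_lines = [COVERAGE_HEADER]
    for cid in sorted(graph.contigs):
        c = graph.contigs[cid]
        # repr round-trips floats exactly; integral coverages print as '30'
        cov = int(c.abundance) if float(c.abundance).is_integer() else repr(c.abundance)
        cov_lines.append(f"{cid}\t{c.length}\t{cov}")
    link_lines = [LINKS_HEADER]
    for lk in sorted(graph.links, key=lambda e: e.key):
        link_lines.append(f"{lk.end_a.label}\t{lk.end_b.label}\t{lk.support}")
    return "\n".join(link_lines) + "\n", "\n".join(cov_lines) + "\n"
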