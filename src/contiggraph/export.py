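"""Cytoscape-loadable graph serialization and primer-design sequence export.

Node/edge attribute conventions follow the display style used for gap
closing: repeat contigs red, unique contigs dark blue, probable repeats
orange; contig edges labelled with length, link edges with supporting read
count and a Z-normalized width.  Colors travel as a plain node attribute
(users map attribute -> color in Cytoscape), not as a VizMap file.

Sequence export re-targets the interactive "show the two contig ends"
feature as FASTA: per contig, the two 1,000 bp termini joined by 20 'N';
per link, the two flanks oriented 5'->3' across the gap, ready for primer
design.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import networkx as nx
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import ContigGraphError, GraphLookupError
from .graph_core import ContigClass, ContigGraph, LinkEdge, contig_id_from_name

END_LEN = 1000
N_SPACER = 20

NODE_COLORS = {
    ContigClass.REPEAT: "red",
    ContigClass.UNIQUE: "darkblue",
    ContigClass.PROBABLE_REPEAT: "orange",
    ContigClass.UNCLASSIFIED: "gray",
}


def _as_multigraph(graph: ContigGraph) -> nx.MultiGraph:
    g = nx.MultiGraph()
    for cid in sorted(graph.contigs):
        contig = graph.contigs[cid]
        for end in "SE":
            g.add_node(
                f"{cid}{end}",
                contig_id=cid,
                end=end,
                klass=contig.klass.value,
                color=NODE_COLORS[contig.klass],
                copy_number=round(contig.copy_number, 4),
            )
        g.add_edge(f"{cid}S", f"{cid}E", kind="contig", length=contig.length)
    for lk in sorted(graph.links, key=lambda e: e.key):
        g.add_edge(
            lk.end_a.label,
            lk.end_b.label,
            kind="link",
            support=lk.support,
            weight=round(lk.display_weight, 6),
            source=lk.source.value,
        )
    return g


def export_graph(graph: ContigGraph, format: str = "GRAPHML") -> str:
    """Serialize to SIF or GraphML text (deterministic, sorted)."""
    fmt = format.upper()
    if fmt == "SIF":
        rows = []
        for cid in sorted(graph.contigs):
            rows.append(f"{cid}S\tcontig\t{cid}E")
        for lk in sorted(graph.links, key=lambda e: e.key):
            rows.append(f"{lk.end_a.label}\tlink\t{lk.end_b.label}")
        return "\n".join(rows) + ("\n" if rows else "")
    if fmt == "GRAPHML":
        return "\n".join(nx.generate_graphml(_as_multigraph(graph))) + "\n"
    raise ContigGraphError(f"unsupported export format: {format!r} (SIF|GRAPHML)")


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def load_contig_sequences(
    fasta: Union[str, Path, Mapping[int, str]]
) -> dict[int, tuple[str, str]]:
    """FASTA path (or {id: seq} mapping) -> {contig_id: (record_id, sequence)}.

    FASTA ids map to contig ids through their trailing digits
    ('contig00042' -> 42).
    """
    if isinstance(fasta, Mapping):
        return {int(cid): (str(cid), str(seq)) for cid, seq in fasta.items()}
    out: dict[int, tuple[str, str]] = {}
    for rec in SeqIO.parse(str(fasta), "fasta"):
        out[contig_id_from_name(rec.id)] = (rec.id, str(rec.seq).upper())
    return out


def _wrap(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def _fasta_record(rid: str, seq: str) -> str:
    body = _wrap(seq)
    return f">{rid}\n{body}\n" if body else f">{rid}\n"


def export_end_sequences(
    contig_fasta,
    end_len: int = END_LEN,
    n_spacer: int = N_SPACER,
    contig_ids: Optional[Iterable[int]] = None,
    warn_missing: bool = True,
) -> str:
    """Per contig: first end_len bases + 'N' * n_spacer + last end_len bases.

    Contigs shorter than 2*end_len are emitted whole, unmodified.  Record
    ids are '<fasta id>_ends'.
    """
    seqs = load_contig_sequences(contig_fasta)
    wanted = sorted(seqs) if contig_ids is None else list(contig_ids)
    records = []
    for cid in wanted:
        if cid not in seqs:
            if warn_missing:
                import warnings

                warnings.warn(f"no sequence for contig {cid}; skipped", stacklevel=2)
            continue
        rid, seq = seqs[cid]
        if len(seq) >= 2 * end_len:
            merged = seq[:end_len] + "N" * n_spacer + seq[-end_len:] if end_len else "N" * n_spacer
        else:
            merged = seq
        records.append(_fasta_record(f"{rid}_ends", merged))
    return "".join(records)


def _flank(seq: str, end: str, end_len: int, into_gap: bool) -> str:
    """Terminal end_len bases of a contig, oriented 5'->3' relative to the gap.

    An E terminus read toward the gap is the contig's own 3' tail; an S
    terminus read toward the gap is the reverse complement of the 5' head.
    Reading *out of* the gap is the mirror image of each case.
    """
    if end == "E":
        piece = seq[-end_len:] if end_len else ""
        native_into_gap = True
    else:
        piece = seq[:end_len] if end_len else ""
        native_into_gap = False
    if into_gap != native_into_gap:
        piece = str(Seq(piece).reverse_complement())
    return piece


def export_junction(
    graph: ContigGraph,
    link: Union[LinkEdge, tuple],
    contig_fasta,
    end_len: int = END_LEN,
    n_spacer: int = N_SPACER,
) -> str:
    """Gap-facing junction sequence for one link, as a FASTA record.

    Left flank: end_a's terminus, 5'->3' into the gap.  Right flank: end_b's
    terminus, 5'->3' out of the gap.  Contigs shorter than end_len
    contribute their whole sequence.  Record id '<a>__<b>'.
    """
    from .graph_core import parse_end_label

    if isinstance(link, LinkEdge):
        end_a, end_b = link.end_a, link.end_b
    else:
        end_a = link[0] if not isinstance(link[0], str) else parse_end_label(link[0])
        end_b = link[1] if not isinstance(link[1], str) else parse_end_label(link[1])
    graph.get_link(end_a, end_b)  # membership check; keep the caller's order
    seqs = load_contig_sequences(contig_fasta)
    for node in (end_a, end_b):
        if node.contig_id not in seqs:
            raise GraphLookupError(f"no sequence for contig {node.contig_id}")
    seq_a = seqs[end_a.contig_id][1]
    seq_b = seqs[end_b.contig_id][1]
    left = _flank(seq_a, end_a.end, min(end_len, len(seq_a)), into_gap=True)
    right = _flank(seq_b, end_b.end, min(end_len, len(seq_b)), into_gap=False)
    rid = f"{end_a.label}__{end_b.label}"
    return _fasta_record(rid, left + "N" * n_spacer + right)
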