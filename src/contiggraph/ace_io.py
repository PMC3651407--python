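"""ACE assemblies: parsing, fm/to split-read tags, abundance, linkage table.

The 454 Newbler assembler splits a read that crosses a contig junction into
two placements and encodes the sibling contig in the read name: a suffix
``fmX`` means the read's 5' portion lies in contigX, ``toY`` that its 3'
portion lies in contigY.  Pairing the two fragments of one read yields a
relationship like "5'-end of contig 1 linked to 3'-end of contig 2" — the
raw evidence for the contig-relationship graph.

Parsing of the AS/CO/AF/RD/QA records is delegated to Biopython
(Bio.Sequencing.Ace); this module adds header validation, AF<->RD pairing
by read name, aligned-length accounting, and everything fm/to.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field
from typing import Optional, TextIO, Union

from Bio.Sequencing import Ace as _Ace

from .errors import AceFormatError
from .graph_core import contig_id_from_name

#: accepts both "name.fm63" and "name.12-455.fm63"
DEFAULT_NAME_PATTERN = r"^(?P<base>.+?)(?:\.\d+-\d+)?\.(?P<dir>fm|to)(?P<partner>\d+)$"

#: how close (padded positions) a fragment must sit to a contig terminus to
#: attach to that end; absorbs pads, as split fragments terminate at edges
DEFAULT_END_WINDOW = 10


@dataclass
class AcePlacement:
    read_name: str
    complemented: bool
    padded_offset: int  # 1-based padded start in contig
    aligned_length: int  # unpadded bases contributing to the contig
    padded_span: int  # padded width of the clipped alignment
    qa_clip: tuple[int, int]  # 1-based inclusive, in read padded coords

    @property
    def padded_end(self) -> int:
        return self.padded_offset + self.padded_span - 1


@dataclass
class AceContig:
    name: str
    number: int
    padded_sequence: str
    placements: list[AcePlacement] = field(default_factory=list)

    @property
    def padded_length(self) -> int:
        return len(self.padded_sequence)

    @property
    def unpadded_length(self) -> int:
        return len(self.padded_sequence) - self.padded_sequence.count("*")


@dataclass
class AceAssembly:
    contigs: list[AceContig]

    @property
    def n_placements(self) -> int:
        return sum(len(c.placements) for c in self.contigs)

    def by_number(self) -> dict[int, AceContig]:
        return {c.number: c for c in self.contigs}


@dataclass(frozen=True)
class SplitReadTag:
    base_name: str
    direction: str  # 'fm': read's 5' portion is in partner; 'to': its 3' is
    partner_number: int
    host_contig: int
    host_end: str  # 'S' | 'E'
    host_offset: int


@dataclass(frozen=True)
class TagAnomaly:
    read_name: str
    host_contig: int
    reason: str


def _as_header(text: str) -> tuple[int, int]:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if parts[0] != "AS" or len(parts) != 3:
            raise AceFormatError(
                f"expected 'AS <contigs> <reads>' header, got {line!r}", line=lineno
            )
        try:
            return int(parts[1]), int(parts[2])
        except ValueError:
            raise AceFormatError(f"non-numeric AS header {line!r}", line=lineno)
    raise AceFormatError("empty stream: no AS header", line=1)


def parse_ace(stream: Union[str, TextIO]) -> AceAssembly:
    """Parse ACE text into an AceAssembly.

    AF records lacking a matching RD are kept as placements with
    aligned_length 0 (dangling-read warning); contig/read counts are checked
    against the AS header.
    """
    text = stream if isinstance(stream, str) else stream.read()
    n_contigs, n_reads = _as_header(text)

    # Bio's parser requires every contig to carry at least one read (true of
    # assembler output); contigs sampled at ~zero depth are peeled off here.
    empty: list[tuple[int, AceContig]] = []
    kept_chunks: list[str] = []
    chunks = re.split(r"(?m)^(?=CO )", text)
    preamble, co_chunks = chunks[0], chunks[1:]
    kept_reads = 0
    for index, chunk in enumerate(co_chunks):
        header = chunk.split("\n", 1)[0].split()
        if len(header) < 4:
            raise AceFormatError(f"malformed CO line: {chunk.splitlines()[0]!r}")
        if int(header[3]) == 0:
            seq_lines = []
            for line in chunk.splitlines()[1:]:
                if not line.strip() or line.split()[0] in ("BQ", "AF", "BS", "RD"):
                    break
                seq_lines.append(line.strip())
            empty.append(
                (index, AceContig(
                    name=header[1],
                    number=contig_id_from_name(header[1]),
                    padded_sequence="".join(seq_lines),
                ))
            )
        else:
            kept_chunks.append(chunk)
            kept_reads += int(header[3])
    if kept_chunks:
        bio_text = f"AS {len(kept_chunks)} {kept_reads}\n\n" + "".join(kept_chunks)
        try:
            rec = _Ace.read(io.StringIO(bio_text))
        except (ValueError, IndexError) as exc:
            raise AceFormatError(
                f"truncated or malformed ACE stream: {exc}"
            ) from exc
        parsed = list(rec.contigs)
    else:
        parsed = []

    contigs: list[AceContig] = []
    total_placements = 0
    for co in parsed:
        contig = AceContig(
            name=co.name,
            number=contig_id_from_name(co.name),
            padded_sequence=co.sequence,
        )
        reads_by_name = {}
        for rd in co.reads:
            if rd.rd is not None:
                reads_by_name[rd.rd.name] = rd
        for af in co.af:
            rd = reads_by_name.get(af.name)
            if rd is None:
                warnings.warn(
                    f"contig {co.name}: AF read {af.name!r} has no RD record",
                    stacklevel=2,
                )
                contig.placements.append(
                    AcePlacement(af.name, af.coru == "C", af.padded_start, 0, 0, (0, 0))
                )
                continue
            qa = rd.qa
            # QA -1 -1 marks a fully clipped read
            if qa is None or qa.qual_clipping_start in (None, -1):
                clip = (1, len(rd.rd.sequence))
            else:
                clip = (qa.qual_clipping_start, qa.qual_clipping_end)
            lo, hi = clip
            clipped = rd.rd.sequence[lo - 1 : hi] if lo <= hi else ""
            contig.placements.append(
                AcePlacement(
                    read_name=af.name,
                    complemented=af.coru == "C",
                    padded_offset=af.padded_start + lo - 1,
                    aligned_length=len(clipped) - clipped.count("*"),
                    padded_span=len(clipped),
                    qa_clip=clip,
                )
            )
        total_placements += len(contig.placements)
        contigs.append(contig)

    # restore original contig order, re-inserting the zero-read contigs
    merged: list[AceContig] = []
    it = iter(contigs)
    empty_at = dict(empty)
    for index in range(len(co_chunks)):
        merged.append(empty_at[index] if index in empty_at else next(it))
    contigs = merged

    if len(contigs) != n_contigs:
        raise AceFormatError(
            f"AS header promises {n_contigs} contigs, found {len(contigs)}"
        )
    if total_placements != n_reads:
        warnings.warn(
            f"AS header promises {n_reads} reads, found {total_placements} placements",
            stacklevel=2,
        )
    return AceAssembly(contigs=contigs)


# ---------------------------------------------------------------------------
# fm/to tags
# ---------------------------------------------------------------------------

def extract_split_tags(
    assembly: AceAssembly,
    name_pattern: str = DEFAULT_NAME_PATTERN,
    end_window: int = DEFAULT_END_WINDOW,
) -> tuple[list[SplitReadTag], list[TagAnomaly]]:
    """Collect fm/to tags from placements whose names match the dialect.

    The host end is the contig terminus the fragment abuts: S when the
    aligned start falls within ``end_window`` of position 1, E when the
    aligned end falls within ``end_window`` of the padded 3' terminus.  A
    fragment touching both termini (contig shorter than the read) is
    disambiguated by which read portion continues elsewhere: an ``fm``
    fragment (5' part elsewhere) breaks at its read-5' edge, a ``to``
    fragment at its read-3' edge, flipped when the placement is
    complemented.  Fragments matching neither window, or naming partner
    number 0, are anomalies, not tags.
    """
    rx = re.compile(name_pattern)
    tags: list[SplitReadTag] = []
    anomalies: list[TagAnomaly] = []
    for contig in assembly.contigs:
        length = contig.padded_length
        for pl in contig.placements:
            m = rx.match(pl.read_name)
            if not m:
                continue
            direction = m.group("dir")
            partner = int(m.group("partner"))
            if partner == 0:
                anomalies.append(TagAnomaly(pl.read_name, contig.number, "partner 0"))
                continue
            # partner == host is legal: reads wrapping the origin of a
            # circular single-contig replicon split into fm/to fragments of
            # the same contig (the S-E self-link of Fig-style plasmids);
            # direction conflicts surface later as pairing ambiguities.
            touches_s = pl.padded_offset <= end_window
            touches_e = pl.padded_end >= length - end_window + 1
            if touches_s and touches_e:
                # read-5' edge is the left edge unless complemented
                five_prime_left = not pl.complemented
                breaks_at_5p = direction == "fm"
                host_end = "S" if (breaks_at_5p == five_prime_left) else "E"
            elif touches_s:
                host_end = "S"
            elif touches_e:
                host_end = "E"
            else:
                anomalies.append(
                    TagAnomaly(
                        pl.read_name,
                        contig.number,
                        f"fragment at {pl.padded_offset}-{pl.padded_end} "
                        f"touches neither terminus of {length} bp contig",
                    )
                )
                continue
            tags.append(
                SplitReadTag(
                    base_name=m.group("base"),
                    direction=direction,
                    partner_number=partner,
                    host_contig=contig.number,
                    host_end=host_end,
                    host_offset=pl.padded_offset,
                )
            )
    return tags, anomalies


@dataclass
class LinkExtraction:
    links: list[tuple[str, str, int]]
    singletons: list[SplitReadTag]
    ambiguities: list[list[SplitReadTag]]


def links_from_tags(tags: list[SplitReadTag]) -> LinkExtraction:
    """Pair fm/to siblings by base read name into an end-to-end link table.

    A read's ``fm`` fragment (hosted in Y, naming X) and its ``to`` sibling
    (hosted in X, naming Y) join Y's and X's attachment ends; support counts
    distinct base reads per unordered end pair.  Unpaired tags are
    low-confidence singletons (their partner end cannot be oriented), and
    reads with more than two fragments — or inconsistent partners — are
    ambiguities; neither becomes a link.
    """
    by_base: dict[str, list[SplitReadTag]] = {}
    for t in tags:
        by_base.setdefault(t.base_name, []).append(t)

    supports: dict[tuple[str, str], set[str]] = {}
    singletons: list[SplitReadTag] = []
    ambiguities: list[list[SplitReadTag]] = []
    for base in sorted(by_base):
        group = by_base[base]
        if len(group) == 1:
            singletons.append(group[0])
            continue
        if len(group) > 2:
            ambiguities.append(group)
            continue
        a, b = group
        consistent = (
            {a.direction, b.direction} == {"fm", "to"}
            and a.partner_number == b.host_contig
            and b.partner_number == a.host_contig
        )
        if not consistent:
            ambiguities.append(group)
            continue
        ends = sorted(
            (f"{a.host_contig}{a.host_end}", f"{b.host_contig}{b.host_end}"),
            key=lambda lbl: (int(lbl[:-1]), lbl[-1] != "S"),
        )
        supports.setdefault((ends[0], ends[1]), set()).add(base)

    links = [
        (a, b, len(bases))
        for (a, b), bases in sorted(
            supports.items(),
            key=lambda kv: (int(kv[0][0][:-1]), kv[0][0][-1] != "S",
                            int(kv[0][1][:-1]), kv[0][1][-1] != "S"),
        )
    ]
    return LinkExtraction(links=links, singletons=singletons, ambiguities=ambiguities)


def abundance_from_ace(assembly: AceAssembly) -> tuple[dict[int, float], float]:
    """Per-contig abundance (assembled read bases / contig size) and the total.

    Aligned (quality-clipped) bases are counted.  Zero-length contigs are
    excluded with a warning.
    """
    abundances: dict[int, float] = {}
    total = 0.0
    for contig in assembly.contigs:
        length = contig.unpadded_length
        bases = float(sum(p.aligned_length for p in contig.placements))
        if length == 0:
            warnings.warn(
                f"contig {contig.name} has unpadded length 0; excluded", stacklevel=2
            )
            continue
        abundances[contig.number] = bases / length
        total += bases
    return abundances, total


def from_ace(
    stream: Union[str, TextIO],
    name_pattern: str = DEFAULT_NAME_PATTERN,
    end_window: int = DEFAULT_END_WINDOW,
    coverage_mode=None,
):
    """ACE text -> (ContigGraph, LinkExtraction, anomalies).

    Classification uses the large-contig-mean coverage estimator by default:
    the total-bases/total-size ratio includes the repeat contigs' own excess
    reads, which mathematically caps a clean two-copy repeat just below the
    2.0 threshold; averaging contigs above 20 kb (rarely repeats in
    microbial genomes) estimates the single-copy coverage instead.  Pass
    ``coverage_mode=CoverageMode.ACE_TOTAL`` for the raw total ratio.
    """
    from .graph_core import CoverageMode, LinkSource, build_graph

    if coverage_mode is None:
        coverage_mode = CoverageMode.CRS_LARGE_CONTIG_MEAN
    assembly = parse_ace(stream)
    tags, anomalies = extract_split_tags(assembly, name_pattern, end_window)
    extraction = links_from_tags(tags)
    abundances, total_bases = abundance_from_ace(assembly)
    contig_rows = [
        (c.number, c.unpadded_length, abundances.get(c.number, 0.0))
        for c in assembly.contigs
        if c.unpadded_length > 0
    ]
    names = {c.number: c.name for c in assembly.contigs}
    graph = build_graph(
        contig_rows,
        extraction.links,
        coverage_mode=coverage_mode,
        source=LinkSource.ACE_SPLIT_READ,
        read_bases=total_bases,
        names=names,
    )
    return graph, extraction, anomalies
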