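"""Synthetic genomes with repeats and plasmids, plus the data they produce.

The generator emulates what a 454-era assembler hands the gap-closing
pipeline, not the assembler itself:

* a genome described as ordered segments — unique sections, exact-copy
  repeat family members, and unsequencable coverage gaps — arranged into
  linear or circular replicons with a per-replicon copy count;
* the *collapsed* assembly of that genome: one contig per unique segment
  and one per repeat family (all copies collapse onto it);
* shotgun reads placed on those contigs, with reads that cross a contig
  junction split into two fm/to-named fragments terminating exactly at the
  boundary (the split-read naming convention the ACE reader consumes);
* mate-pair SAM with mates placed on the collapsed contigs;
* the ground-truth adjacency graph (which contig ends abut, at what
  distance) and expected copy numbers — the oracle the other modules are
  tested against.

Read starts are stratified by default (one read per depth window, uniform
jitter within it), so a stated fold-coverage is realized tightly even on
kilobase-scale test genomes; ``sampling="random"`` gives plain uniform
sampling.  No sequencing-error model: linkage extraction is error-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import yaml

from .errors import GenomeSpecError

ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_READ_LENGTH = 400
DEFAULT_DEPTH = 30.0
DEFAULT_INSERT = 3000
DEFAULT_INSERT_SD = 150
DEFAULT_MP_READ_LENGTH = 100
MIN_SPLIT_OVERLAP = 5


@dataclass
class Segment:
    name: str
    length: int
    family: Optional[str] = None  # repeat family; members are exact copies
    gap: bool = False  # unsequencable region: no contig, no reads


@dataclass
class Replicon:
    name: str
    topology: str  # 'linear' | 'circular'
    order: list[str]  # segment names, 5'->3'
    copy_count: int = 1


@dataclass
class GenomeSpec:
    segments: list[Segment]
    replicons: list[Replicon]
    read_length: int = DEFAULT_READ_LENGTH
    depth: float = DEFAULT_DEPTH
    insert: int = DEFAULT_INSERT
    insert_sd: float = DEFAULT_INSERT_SD
    mp_read_length: int = DEFAULT_MP_READ_LENGTH
    orientation: str = "FR"
    seed: int = 0
    min_split_overlap: int = MIN_SPLIT_OVERLAP
    sampling: str = "stratified"  # 'stratified' | 'random'

    def validate(self) -> None:
        if not self.segments or not self.replicons:
            raise GenomeSpecError("spec needs segments and replicons")
        by_name = {}
        for seg in self.segments:
            if seg.name in by_name:
                raise GenomeSpecError(f"duplicate segment name {seg.name!r}")
            if seg.length <= 0:
                raise GenomeSpecError(f"segment {seg.name}: length must be > 0")
            if not seg.gap and seg.length <= self.read_length:
                raise GenomeSpecError(
                    f"segment {seg.name}: length {seg.length} must exceed "
                    f"read_length {self.read_length}"
                )
            by_name[seg.name] = seg
        fam_len: dict[str, int] = {}
        for seg in self.segments:
            if seg.family:
                if seg.gap:
                    raise GenomeSpecError(f"gap segment {seg.name} cannot be a repeat")
                if fam_len.setdefault(seg.family, seg.length) != seg.length:
                    raise GenomeSpecError(
                        f"family {seg.family}: members must be exact copies "
                        "(equal lengths)"
                    )
        used: set[str] = set()
        for rep in self.replicons:
            if rep.topology not in ("linear", "circular"):
                raise GenomeSpecError(f"replicon {rep.name}: bad topology {rep.topology}")
            if rep.copy_count < 1:
                raise GenomeSpecError(f"replicon {rep.name}: copy_count must be >= 1")
            for name in rep.order:
                if name not in by_name:
                    raise GenomeSpecError(
                        f"replicon {rep.name} references unknown segment {name!r}"
                    )
                if name in used:
                    raise GenomeSpecError(f"segment {name!r} used more than once")
                used.add(name)
        unused = set(by_name) - used
        if unused:
            raise GenomeSpecError(f"unused segments: {sorted(unused)}")

    @classmethod
    def from_yaml(cls, text: str) -> "GenomeSpec":
        raw = yaml.safe_load(text)
        segments = [Segment(**s) for s in raw.pop("segments")]
        replicons = [Replicon(**r) for r in raw.pop("replicons")]
        return cls(segments=segments, replicons=replicons, **raw)


@dataclass(frozen=True)
class TruthJunction:
    end_a: str  # end label, e.g. '1E'
    end_b: str
    distance: int  # 0 = abutting; >0 = gap of that many bases


@dataclass
class TruthGraph:
    contig_lengths: dict[int, int]
    contig_names: dict[int, str]
    junctions: list[TruthJunction]
    copy_numbers: dict[int, float]

    def zero_gap_pairs(self) -> set[frozenset[str]]:
        return {
            frozenset((j.end_a, j.end_b)) for j in self.junctions if j.distance == 0
        }

    def to_tsv(self) -> str:
        rows = ["#endA\tendB\tdistance"]
        for j in sorted(self.junctions, key=lambda j: (j.end_a, j.end_b)):
            rows.append(f"{j.end_a}\t{j.end_b}\t{j.distance}")
        return "\n".join(rows) + "\n"


@dataclass
class _Occurrence:
    segment: Segment
    contig_id: Optional[int]  # None for gaps
    rep_start: int  # 0-based within replicon


@dataclass
class Genome:
    spec: GenomeSpec
    contig_ids: dict[str, int]  # segment/family name -> contig id
    contig_seqs: dict[int, str]
    contig_names: dict[int, str]
    layouts: dict[str, list[_Occurrence]]  # replicon name -> occurrences
    replicon_seqs: dict[str, str]
    truth: TruthGraph

    def contig_fasta(self) -> str:
        out = []
        for cid in sorted(self.contig_seqs):
            seq = self.contig_seqs[cid]
            wrapped = "\n".join(seq[i : i + 60] for i in range(0, len(seq), 60))
            out.append(f">{self.contig_names[cid]}\n{wrapped}\n")
        return "".join(out)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return ALPHABET[rng.integers(0, 4, size=length)].tobytes().decode()


def build_genome(spec: GenomeSpec) -> Genome:
    """Generate sequences and derive the ground-truth adjacency graph.

    Deterministic given ``spec.seed``.  Repeat family members are
    byte-identical; one collapsed contig is assigned per unique segment and
    per family, numbered in order of first appearance.
    """
    spec.validate()
    rng = np.random.default_rng([int(spec.seed) % (2**31), 11])

    # sequence per unique segment / per family / per gap
    seg_seq: dict[str, str] = {}
    fam_seq: dict[str, str] = {}
    contig_ids: dict[str, int] = {}
    contig_seqs: dict[int, str] = {}
    contig_names: dict[int, str] = {}
    next_id = 1
    for seg in spec.segments:
        if seg.family:
            if seg.family not in fam_seq:
                fam_seq[seg.family] = _random_seq(rng, seg.length)
                contig_ids[seg.family] = next_id
                contig_seqs[next_id] = fam_seq[seg.family]
                contig_names[next_id] = f"contig{next_id:05d}"
                next_id += 1
            seg_seq[seg.name] = fam_seq[seg.family]
        else:
            seg_seq[seg.name] = _random_seq(rng, seg.length)
            if not seg.gap:
                contig_ids[seg.name] = next_id
                contig_seqs[next_id] = seg_seq[seg.name]
                contig_names[next_id] = f"contig{next_id:05d}"
                next_id += 1

    by_name = {s.name: s for s in spec.segments}

    def cid_of(seg: Segment) -> Optional[int]:
        if seg.gap:
            return None
        return contig_ids[seg.family or seg.name]

    layouts: dict[str, list[_Occurrence]] = {}
    replicon_seqs: dict[str, str] = {}
    junctions: list[TruthJunction] = []
    occ_weight: dict[int, float] = {}
    for rep in spec.replicons:
        occs: list[_Occurrence] = []
        pos = 0
        for name in rep.order:
            seg = by_name[name]
            occs.append(_Occurrence(segment=seg, contig_id=cid_of(seg), rep_start=pos))
            pos += seg.length
        layouts[rep.name] = occs
        replicon_seqs[rep.name] = "".join(seg_seq[o.segment.name] for o in occs)
        for occ in occs:
            if occ.contig_id is not None:
                occ_weight[occ.contig_id] = (
                    occ_weight.get(occ.contig_id, 0.0) + rep.copy_count
                )

        # adjacencies between consecutive assembled occurrences
        assembled = [o for o in occs if o.contig_id is not None]
        if not assembled:
            continue
        pairs = list(zip(assembled, assembled[1:]))
        if rep.topology == "circular" and len(assembled) >= 1:
            pairs.append((assembled[-1], assembled[0]))
        rep_len = pos
        for left, right in pairs:
            if left is right and len(assembled) == 1 and rep.topology == "circular":
                gap = rep_len - left.segment.length  # surrounding gap material
            else:
                left_end = left.rep_start + left.segment.length
                gap = (right.rep_start - left_end) % rep_len if rep.topology == "circular" else right.rep_start - left_end
            junctions.append(
                TruthJunction(
                    end_a=f"{left.contig_id}E",
                    end_b=f"{right.contig_id}S",
                    distance=gap,
                )
            )

    lengths = {cid: len(seq) for cid, seq in contig_seqs.items()}
    base = min(occ_weight.values()) if occ_weight else 1.0
    copy_numbers = {cid: occ_weight.get(cid, 0.0) / base for cid in lengths}
    truth = TruthGraph(
        contig_lengths=lengths,
        contig_names=dict(contig_names),
        junctions=junctions,
        copy_numbers=copy_numbers,
    )
    return Genome(
        spec=spec,
        contig_ids=contig_ids,
        contig_seqs=contig_seqs,
        contig_names=contig_names,
        layouts=layouts,
        replicon_seqs=replicon_seqs,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# shotgun reads -> ACE
# ---------------------------------------------------------------------------

@dataclass
class _Block:
    """A maximal gap-free run of occurrences, read-samplable as one unit."""

    occs: list[_Occurrence]
    starts: list[int]  # block-local start of each occurrence
    length: int
    circular: bool  # reads may wrap the block origin


def _blocks(genome: Genome) -> list[_Block]:
    blocks: list[_Block] = []
    for rep in genome.spec.replicons:
        occs = genome.layouts[rep.name]
        runs: list[list[_Occurrence]] = []
        current: list[_Occurrence] = []
        for occ in occs:
            if occ.contig_id is None:
                if current:
                    runs.append(current)
                    current = []
            else:
                current.append(occ)
        if current:
            runs.append(current)
        if not runs:
            continue
        whole = len(runs) == 1 and len(runs[0]) == len(occs)
        if rep.topology == "circular" and not whole and len(runs) > 1:
            # wrap continuity: merge trailing run into the leading one
            if occs[0].contig_id is not None and occs[-1].contig_id is not None:
                runs[0] = runs.pop() + runs[0]
        rep_blocks = []
        for run in runs:
            starts, pos = [], 0
            for occ in run:
                starts.append(pos)
                pos += occ.segment.length
            rep_blocks.append(
                _Block(
                    occs=run,
                    starts=starts,
                    length=pos,
                    circular=(rep.topology == "circular" and whole),
                )
            )
        # each physical copy of the replicon is sampled independently
        for _ in range(rep.copy_count):
            blocks.extend(rep_blocks)
    return blocks


def _read_starts(
    rng: np.random.Generator, n: int, span: int, sampling: str
) -> np.ndarray:
    """n start positions over [0, span): stratified jitter or plain uniform."""
    if n <= 0:
        return np.empty(0, dtype=int)
    if sampling == "random":
        return rng.integers(0, span, size=n)
    u = (np.arange(n) + rng.random(n)) / n
    return np.minimum((u * span).astype(int), span - 1)


def _fragments_for_read(
    block: _Block, start: int, read_len: int, min_overlap: int
) -> list[tuple[int, int, int, int]]:
    """(contig_id, contig_start_1based, read_start_1based, length) per piece."""
    pieces = []
    if start + read_len <= block.length:
        pieces.append((start, read_len, 0))
    else:  # wraps the circular origin
        first = block.length - start
        pieces.append((start, first, 0))
        pieces.append((0, read_len - first, first))
    frags = []
    for piece_start, piece_len, read_off in pieces:
        for occ, occ_start in zip(block.occs, block.starts):
            occ_end = occ_start + occ.segment.length
            lo = max(piece_start, occ_start)
            hi = min(piece_start + piece_len, occ_end)
            if hi <= lo:
                continue
            frags.append(
                (
                    occ.contig_id,
                    lo - occ_start + 1,
                    read_off + (lo - piece_start) + 1,
                    hi - lo,
                )
            )
    # assembler-like minimum overlap: slivers at a junction are clipped off
    return [f for f in frags if f[3] >= min_overlap]


def emit_ace(genome: Genome) -> str:
    """Shotgun-sample the genome and write the collapsed assembly as ACE text.

    Reads wholly inside one contig become a single placement; junction
    spanning reads split into two placements named
    ``<read>.<from>-<to>.fm<X>`` / ``...to<Y>`` per the split-read dialect,
    each terminating exactly at the contig boundary.  Deterministic given
    the spec seed.
    """
    spec = genome.spec
    rng = np.random.default_rng([int(spec.seed) % (2**31), 101])
    placements: dict[int, list[tuple[str, int, str]]] = {
        cid: [] for cid in genome.contig_seqs
    }
    counter = 0
    for block in _blocks(genome):
        span = block.length if block.circular else block.length - spec.read_length + 1
        if span <= 0:
            continue
        n = int(round(spec.depth * block.length / spec.read_length))
        for start in _read_starts(rng, n, span, spec.sampling):
            frags = _fragments_for_read(
                block, int(start), spec.read_length, spec.min_split_overlap
            )
            if not frags:
                continue
            counter += 1
            base = f"rd{counter:07d}"
            for i, (cid, cstart, rstart, flen) in enumerate(frags):
                if len(frags) == 1:
                    name = base
                elif i == 0:
                    name = f"{base}.{rstart}-{rstart + flen - 1}.to{frags[1][0]}"
                elif i == len(frags) - 1:
                    name = f"{base}.{rstart}-{rstart + flen - 1}.fm{frags[i - 1][0]}"
                else:
                    name = f"{base}.{rstart}-{rstart + flen - 1}"
                seq = genome.contig_seqs[cid][cstart - 1 : cstart - 1 + flen]
                placements[cid].append((name, cstart, seq))

    total = sum(len(p) for p in placements.values())
    out = [f"AS {len(genome.contig_seqs)} {total}", ""]
    for cid in sorted(genome.contig_seqs):
        cseq = genome.contig_seqs[cid]
        rows = placements[cid]
        out.append(f"CO {genome.contig_names[cid]} {len(cseq)} {len(rows)} 0 U")
        out.extend(cseq[i : i + 60] for i in range(0, len(cseq), 60))
        out.append("")
        out.append("BQ")
        quals = ["30"] * len(cseq)
        out.extend(" ".join(quals[i : i + 30]) for i in range(0, len(quals), 30))
        out.append("")
        for name, cstart, _ in rows:
            out.append(f"AF {name} U {cstart}")
        out.append("")
        for name, _, seq in rows:
            out.append(f"RD {name} {len(seq)} 0 0")
            out.extend(seq[i : i + 60] for i in range(0, len(seq), 60))
            out.append("")
            out.append(f"QA 1 {len(seq)} 1 {len(seq)}")
            out.append(f"DS CHROMAT_FILE: {name} PHD_FILE: {name}.phd.1 TIME: 0")
            out.append("")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# mate pairs -> SAM
# ---------------------------------------------------------------------------

def emit_matepairs(genome: Genome, n_pairs: Optional[int] = None) -> str:
    """Sample mate-pair fragments and emit SAM of both mates on the contigs.

    Fragment sizes are Normal(insert, insert_sd), sampled per replicon
    (weighted by length x copy count, wrapping circular origins).  A mate
    falling in a gap or straddling a contig boundary leaves the pair
    unusable and it is dropped.  Deterministic given the spec seed.
    """
    spec = genome.spec
    rng = np.random.default_rng([int(spec.seed) % (2**31), 202])
    reps = genome.spec.replicons
    rep_lens = {r.name: len(genome.replicon_seqs[r.name]) for r in reps}
    for r in reps:
        if spec.insert > rep_lens[r.name]:
            raise GenomeSpecError(
                f"insert {spec.insert} exceeds replicon {r.name} "
                f"length {rep_lens[r.name]}"
            )
    if n_pairs is None:
        total = sum(rep_lens[r.name] * r.copy_count for r in reps)
        n_pairs = int(round(spec.depth * total / (2 * spec.mp_read_length)))

    weights = np.array([rep_lens[r.name] * r.copy_count for r in reps], dtype=float)
    weights /= weights.sum()
    choices = rng.choice(len(reps), size=n_pairs, p=weights)
    frag_sizes = rng.normal(spec.insert, spec.insert_sd, size=n_pairs)
    R = spec.mp_read_length

    def locate(rep_name: str, pos0: int, length: int):
        """Map a replicon interval to (contig_id, 1-based start); None if it
        touches a gap or crosses an occurrence boundary."""
        for occ in genome.layouts[rep_name]:
            occ_end = occ.rep_start + occ.segment.length
            if occ.rep_start <= pos0 and pos0 + length <= occ_end:
                if occ.contig_id is None:
                    return None
                return occ.contig_id, pos0 - occ.rep_start + 1
        return None

    header = ["@HD\tVN:1.6\tSO:unsorted"]
    for cid in sorted(genome.contig_seqs):
        header.append(
            f"@SQ\tSN:{genome.contig_names[cid]}\tLN:{len(genome.contig_seqs[cid])}"
        )
    lines = list(header)
    emitted = 0
    for idx in range(n_pairs):
        rep = reps[int(choices[idx])]
        rep_len = rep_lens[rep.name]
        frag = int(round(frag_sizes[idx]))
        frag = max(frag, 2 * R + 1)
        if frag > rep_len:
            continue
        if rep.topology == "circular":
            s = int(rng.integers(0, rep_len))
        else:
            s = int(rng.integers(0, rep_len - frag + 1))
        a_pos = s % rep_len
        b_pos = (s + frag - R) % rep_len
        a = locate(rep.name, a_pos, R) if a_pos + R <= rep_len else None
        b = locate(rep.name, b_pos, R) if b_pos + R <= rep_len else None
        if a is None or b is None:
            continue
        if spec.orientation.upper() == "FR":
            a_rev, b_rev = False, True
        else:
            a_rev, b_rev = True, False
        emitted += 1
        qname = f"mp{emitted:06d}"
        for (cid, cstart), rev, mrev, first, (ocid, ostart) in (
            (a, a_rev, b_rev, True, b),
            (b, b_rev, a_rev, False, a),
        ):
            flag = 0x1 | (0x40 if first else 0x80)
            if rev:
                flag |= 0x10
            if mrev:
                flag |= 0x20
            seq = genome.contig_seqs[cid][cstart - 1 : cstart - 1 + R]
            rnext = "=" if ocid == cid else genome.contig_names[ocid]
            lines.append(
                "\t".join(
                    [
                        qname,
                        str(flag),
                        genome.contig_names[cid],
                        str(cstart),
                        "60",
                        f"{R}M",
                        rnext,
                        str(ostart),
                        "0",
                        seq,
                        "*",
                    ]
                )
            )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# canned study genomes and random graphs
# ---------------------------------------------------------------------------

def fig3_style_spec(seed: int = 7, **overrides) -> GenomeSpec:
    """Four 25 kb unique sections and two exact copies of a 1.2 kb repeat.

    Layout U1-R-U2 | 3 kb coverage gap | U3-R-U4 on one linear chromosome:
    the collapsed assembly has four unique contigs and one repeat contig at
    twice the unique coverage, carrying exactly four linkage edges — the
    canonical repeat-resolution picture for 454 assemblies.
    """
    params = dict(read_length=400, depth=30.0, seed=seed)
    params.update(overrides)
    return GenomeSpec(
        segments=[
            Segment("u1", 25_000),
            Segment("r1", 1_200, family="R"),
            Segment("u2", 25_000),
            Segment("gap23", 3_000, gap=True),
            Segment("u3", 25_000),
            Segment("r2", 1_200, family="R"),
            Segment("u4", 25_000),
        ],
        replicons=[
            Replicon(
                "chromosome",
                "linear",
                ["u1", "r1", "u2", "gap23", "u3", "r2", "u4"],
            )
        ],
        **params,
    )


def replicon_panel_spec(seed: int = 7, **overrides) -> GenomeSpec:
    """A chromosome plus the plasmid menagerie of replicon topologies.

    Two 30 kb chromosome arms around a gap; a 3 kb circular single-contig
    plasmid at copy 3; a three-contig circular plasmid at copy 2; a linear
    two-contig plasmid at copy 3 (both termini linkless); a 3.5 kb
    single-contig linear plasmid at copy 4 (fully linkless, the candidate
    high-copy linear plasmid); and a single-copy linear plasmid that is
    indistinguishable from an ordinary unique contig.
    """
    params = dict(read_length=400, depth=30.0, seed=seed)
    params.update(overrides)
    return GenomeSpec(
        segments=[
            Segment("chrA", 30_000),
            Segment("chr_gap", 2_000, gap=True),
            Segment("chrB", 30_000),
            Segment("p_circ1", 3_000),
            Segment("q1", 2_500),
            Segment("q2", 2_200),
            Segment("q3", 2_600),
            Segment("t1", 2_000),
            Segment("t2", 4_000),
            Segment("iso_hi", 3_500),
            Segment("iso_lo", 3_000),
        ],
        replicons=[
            Replicon("chromosome", "linear", ["chrA", "chr_gap", "chrB"]),
            Replicon("pCirc1", "circular", ["p_circ1"], copy_count=3),
            Replicon("pCirc3", "circular", ["q1", "q2", "q3"], copy_count=2),
            Replicon("pLin2", "linear", ["t1", "t2"], copy_count=3),
            Replicon("pIsoHigh", "linear", ["iso_hi"], copy_count=4),
            Replicon("pIsoSingle", "linear", ["iso_lo"], copy_count=1),
        ],
        **params,
    )


def matepair_gap_spec(seed: int = 7, **overrides) -> GenomeSpec:
    """Two 30 kb contigs around a known 1 kb gap, plus a 450 bp contig.

    The 3 kb +/- 150 bp mate-pair library bridges the 1 kb gap; the 450 bp
    contig sits behind a second gap and is below the >500 bp linkage rule,
    so it must attract no scaffold links.
    """
    params = dict(
        read_length=400,
        depth=30.0,
        insert=3000,
        insert_sd=150,
        mp_read_length=100,
        seed=seed,
    )
    params.update(overrides)
    return GenomeSpec(
        segments=[
            Segment("u1", 30_000),
            Segment("gap12", 1_000, gap=True),
            Segment("u2", 30_000),
            Segment("gap23", 1_500, gap=True),
            Segment("tiny", 450),
        ],
        replicons=[
            Replicon("chromosome", "linear", ["u1", "gap12", "u2", "gap23", "tiny"])
        ],
        **params,
    )


def random_contig_graph(rng: np.random.Generator, n_contigs: int = 50):
    """A random but structurally valid ContigGraph, for round-trip tests."""
    from .graph_core import CoverageMode, LinkSource, build_graph

    n = max(int(n_contigs), 1)
    contig_rows = [
        (
            cid,
            int(rng.integers(600, 60_000)),
            float(np.round(rng.uniform(2.0, 120.0), 3)),
        )
        for cid in range(1, n + 1)
    ]
    pairs = set()
    n_links = int(rng.integers(0, max(2 * n, 2)))
    for _ in range(n_links):
        a = (int(rng.integers(1, n + 1)), "SE"[int(rng.integers(0, 2))])
        b = (int(rng.integers(1, n + 1)), "SE"[int(rng.integers(0, 2))])
        if a == b:
            continue
        pairs.add(tuple(sorted((a, b))))
    link_rows = [
        (f"{a[0]}{a[1]}", f"{b[0]}{b[1]}", int(rng.integers(1, 400)))
        for a, b in sorted(pairs)
    ]
    return build_graph(
        contig_rows,
        link_rows,
        coverage_mode=CoverageMode.CRS_LARGE_CONTIG_MEAN,
        source=LinkSource.CRS,
    )
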