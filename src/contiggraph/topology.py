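"""Replicon topology: circular/linear plasmids, telomeres, repeat traversals.

Because the graph keeps every contig's two ends as separate nodes, the
shape of a plasmid or chromosome end is readable from link degrees alone:

* a contig whose S and E are joined by a self-link and that touches nothing
  else is a circular single-contig replicon;
* a connected component in which every end-node carries exactly one link is
  an alternating contig/link cycle — a circular multi-contig replicon;
* a repeat contig with one linkless end marks a linear replicon end
  (telomere or linear-plasmid terminus), and the special case "one end two
  links, the other none, copy number about two" is the collapsed terminal
  inverted repeat of a linear chromosome;
* a repeat contig with no links at all is a candidate high-copy linear
  plasmid.  A single-copy linear plasmid is indistinguishable from an
  ordinary unique contig and gets no call.

A repeat contig with several link partners on each end admits k! ways of
matching the flanking contigs through its copies; enumerating those
matchings as end-label chains is what a PCR plan has to disambiguate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .graph_core import ContigClass, ContigGraph, EndNode, LinkEdge

#: copy number window accepted as "about 2" for terminal-inverted-repeat calls
TIR_COPY_RANGE = (1.6, 2.6)

#: links supported by less than this fraction of the strongest link on a
#: shared end-node are flagged as probable nonspecific joins
WEAK_LINK_FRACTION = 0.05


class RepliconKind(str, Enum):
    CIRCULAR_MULTI = "CIRCULAR_MULTI"
    CIRCULAR_SINGLE = "CIRCULAR_SINGLE"
    LINEAR_END = "LINEAR_END"
    ISOLATED_LINEAR = "ISOLATED_LINEAR"
    TIR_CHROMOSOME_END = "TIR_CHROMOSOME_END"
    AMBIGUOUS = "AMBIGUOUS"


@dataclass
class RepliconCall:
    kind: RepliconKind
    members: frozenset[int]
    mean_copy_number: float
    notes: str = ""

    def __post_init__(self):
        if not self.members:
            raise ValueError("RepliconCall needs at least one member")
        if self.kind in (RepliconKind.CIRCULAR_SINGLE, RepliconKind.ISOLATED_LINEAR):
            if len(self.members) != 1:
                raise ValueError(f"{self.kind.value} must have exactly one member")


def flag_weak_links(
    graph: ContigGraph, fraction: float = WEAK_LINK_FRACTION
) -> set[tuple]:
    """Keys of links much weaker than the strongest link sharing an end-node.

    An 800-read link and a 10-read link on the same end usually mean the
    latter is a nonspecific join from a few overlapping reads; such links
    are kept in the graph but excluded from cycle detection by default.
    """
    strongest: dict[EndNode, int] = {}
    for lk in graph.links:
        for node in (lk.end_a, lk.end_b):
            strongest[node] = max(strongest.get(node, 0), lk.support)
    weak = set()
    for lk in graph.links:
        limit = fraction * max(strongest[lk.end_a], strongest[lk.end_b])
        if lk.support < limit:
            weak.add(lk.key)
    return weak


def _active_links(graph: ContigGraph, exclude_weak: bool) -> list[LinkEdge]:
    if not exclude_weak:
        return list(graph.links)
    weak = flag_weak_links(graph)
    return [lk for lk in graph.links if lk.key not in weak]


def _degrees(links: list[LinkEdge]) -> dict[EndNode, int]:
    deg: dict[EndNode, int] = {}
    for lk in links:
        deg[lk.end_a] = deg.get(lk.end_a, 0) + 1
        deg[lk.end_b] = deg.get(lk.end_b, 0) + 1
    return deg


def _components(graph: ContigGraph, links: list[LinkEdge]) -> list[set[int]]:
    """Connected components over contigs, via contig edges + link edges."""
    parent = {cid: cid for cid in graph.contigs}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for lk in links:
        a, b = find(lk.end_a.contig_id), find(lk.end_b.contig_id)
        if a != b:
            parent[a] = b
    comps: dict[int, set[int]] = {}
    for cid in graph.contigs:
        comps.setdefault(find(cid), set()).add(cid)
    return sorted(comps.values(), key=min)


def detect_circular_single(
    graph: ContigGraph, exclude_weak: bool = True
) -> list[RepliconCall]:
    """Self-linked contigs with no other links -> CIRCULAR_SINGLE; contigs
    carrying a self-link plus outside links fall to AMBIGUOUS."""
    links = _active_links(graph, exclude_weak)
    calls = []
    for cid in sorted(graph.contigs):
        s, e = EndNode(cid, "S"), EndNode(cid, "E")
        mine = [lk for lk in links if lk.touches(s) or lk.touches(e)]
        self_links = [lk for lk in mine if lk.is_self_link]
        if not self_links:
            continue
        contig = graph.contigs[cid]
        if len(mine) == len(self_links):
            calls.append(
                RepliconCall(
                    RepliconKind.CIRCULAR_SINGLE,
                    frozenset({cid}),
                    contig.copy_number,
                    notes=f"self-link support {self_links[0].support}",
                )
            )
        else:
            calls.append(
                RepliconCall(
                    RepliconKind.AMBIGUOUS,
                    frozenset({cid}),
                    contig.copy_number,
                    notes="self-link plus external links",
                )
            )
    return calls


def detect_circular_multi(
    graph: ContigGraph, exclude_weak: bool = True
) -> list[RepliconCall]:
    """Components forming one alternating contig/link cycle -> CIRCULAR_MULTI.

    Every end-node in the component must carry exactly one link (the contig
    edges supply the other half of the cycle).  Closed components where some
    end-node carries two or more links cannot be ordered without PCR and are
    reported AMBIGUOUS instead.
    """
    links = _active_links(graph, exclude_weak)
    deg = _degrees(links)
    calls = []
    for comp in _components(graph, links):
        if len(comp) < 2:
            continue
        nodes = [EndNode(cid, end) for cid in comp for end in "SE"]
        degs = [deg.get(n, 0) for n in nodes]
        if any(d == 0 for d in degs):
            continue  # open chain or partially linked: not a closed replicon
        mean_copy = sum(graph.contigs[c].copy_number for c in comp) / len(comp)
        if all(d == 1 for d in degs):
            calls.append(
                RepliconCall(
                    RepliconKind.CIRCULAR_MULTI,
                    frozenset(comp),
                    mean_copy,
                    notes=f"{len(comp)}-contig cycle",
                )
            )
        else:
            profile = ",".join(
                f"{n.label}:{deg.get(n, 0)}" for n in sorted(nodes, key=lambda n: n.sort_key)
            )
            calls.append(
                RepliconCall(
                    RepliconKind.AMBIGUOUS,
                    frozenset(comp),
                    mean_copy,
                    notes=f"closed but not a simple cycle; degrees {profile}",
                )
            )
    return calls


def detect_linear_ends(
    graph: ContigGraph,
    exclude_weak: bool = True,
    tir_copy_range: tuple[float, float] = TIR_COPY_RANGE,
) -> list[RepliconCall]:
    """Repeat contigs with one linkless end -> LINEAR_END (telomere or
    linear-plasmid terminus); the one-end-two-links, copy-about-2 sub-case
    -> TIR_CHROMOSOME_END (collapsed terminal inverted repeat)."""
    links = _active_links(graph, exclude_weak)
    deg = _degrees(links)
    calls = []
    for cid in sorted(graph.contigs):
        contig = graph.contigs[cid]
        if contig.klass is not ContigClass.REPEAT:
            continue
        ds = deg.get(EndNode(cid, "S"), 0)
        de = deg.get(EndNode(cid, "E"), 0)
        if min(ds, de) != 0 or max(ds, de) == 0:
            continue
        lo, hi = tir_copy_range
        if max(ds, de) == 2 and lo <= contig.copy_number <= hi:
            kind = RepliconKind.TIR_CHROMOSOME_END
            note = "one end with two links, copy number about 2"
        else:
            kind = RepliconKind.LINEAR_END
            note = f"linkless {'S' if ds == 0 else 'E'} end"
        calls.append(RepliconCall(kind, frozenset({cid}), contig.copy_number, note))
    return calls


def detect_isolated(graph: ContigGraph, exclude_weak: bool = True) -> list[RepliconCall]:
    """Linkless repeat contigs -> ISOLATED_LINEAR (candidate high-copy
    linear plasmid).  Linkless unique contigs get no call: a single-copy
    linear plasmid cannot be told apart from an ordinary contig."""
    links = _active_links(graph, exclude_weak)
    deg = _degrees(links)
    calls = []
    for cid in sorted(graph.contigs):
        contig = graph.contigs[cid]
        if deg.get(EndNode(cid, "S"), 0) or deg.get(EndNode(cid, "E"), 0):
            continue
        if contig.klass is ContigClass.REPEAT:
            calls.append(
                RepliconCall(
                    RepliconKind.ISOLATED_LINEAR,
                    frozenset({cid}),
                    contig.copy_number,
                    notes="no links on either end",
                )
            )
    return calls


def call_replicons(graph: ContigGraph, exclude_weak: bool = True) -> list[RepliconCall]:
    """Run all detectors; one pass over the graph, calls in a stable order."""
    calls = (
        detect_circular_single(graph, exclude_weak)
        + detect_circular_multi(graph, exclude_weak)
        + detect_linear_ends(graph, exclude_weak)
        + detect_isolated(graph, exclude_weak)
    )
    return calls


# ---------------------------------------------------------------------------
# repeat traversal enumeration
# ---------------------------------------------------------------------------

@dataclass
class TraversalAlternative:
    """One way of matching a repeat's S-side partners to its E-side partners,
    rendered as hyphen-joined chains of end labels."""

    matching: tuple[tuple[str, str], ...]  # (S-partner label, E-partner label)
    chains: list[list[str]] = field(default_factory=list)
    partial: bool = False

    def render(self) -> str:
        return " / ".join("-".join(chain) for chain in self.chains)


def _merge_chains(segments: list[list[str]]) -> list[list[str]]:
    """Merge pair-paths that run through the same flanking contig into
    maximal walks (e.g. ...-41S-41E + 41S-41E-... -> one chain)."""
    chains = [list(s) for s in segments]
    merged = True
    while merged and len(chains) > 1:
        merged = False
        for i in range(len(chains)):
            for j in range(len(chains)):
                if i == j:
                    continue
                a, b = chains[i], chains[j]
                for candidate in (b, b[::-1]):
                    if a[-2:] == candidate[:2]:
                        chains[i] = a + candidate[2:]
                        del chains[j]
                        merged = True
                        break
                if merged:
                    break
            if merged:
                break
    return chains


def enumerate_traversals(
    graph: ContigGraph,
    repeat_id: int,
    max_alternatives: int = 64,
    exclude_weak: bool = False,
) -> tuple[list[TraversalAlternative], bool]:
    """All perfect matchings of a repeat's S-side vs E-side link partners.

    For k partners on each end there are k! alternatives; with unequal
    partner counts the matchings of the smaller side are returned with
    ``partial=True`` on each.  The second return value flags truncation at
    ``max_alternatives``.

    Each alternative is rendered as chains like
    ``37S-37E-106S-106E-41S-41E-106E-106S-42E-42S``: flanking contigs are
    traversed from their far end into their linking end, the repeat is
    crossed once per matched pair, and pair-paths sharing a flanking contig
    are merged into one walk.
    """
    links = _active_links(graph, exclude_weak)
    s_node, e_node = EndNode(repeat_id, "S"), EndNode(repeat_id, "E")
    s_partners = sorted(
        (lk.end_b if lk.end_a == s_node else lk.end_a for lk in links if lk.touches(s_node)),
        key=lambda n: n.sort_key,
    )
    e_partners = sorted(
        (lk.end_b if lk.end_a == e_node else lk.end_a for lk in links if lk.touches(e_node)),
        key=lambda n: n.sort_key,
    )
    if not s_partners or not e_partners:
        raise ValueError(
            f"contig {repeat_id} needs at least one link on each end to traverse"
        )
    partial = len(s_partners) != len(e_partners)
    if len(s_partners) > len(e_partners):
        small, big, s_side_small = e_partners, s_partners, False
    else:
        small, big, s_side_small = s_partners, e_partners, True

    alternatives: list[TraversalAlternative] = []
    truncated = False
    for combo in itertools.permutations(big, len(small)):
        if len(alternatives) >= max_alternatives:
            truncated = True
            break
        pairs = list(zip(small, combo)) if s_side_small else [
            (s, e) for e, s in zip(small, combo)
        ]
        segments = []
        for s_p, e_p in pairs:
            segments.append(
                [s_p.other().label, s_p.label, s_node.label, e_node.label,
                 e_p.label, e_p.other().label]
            )
        alternatives.append(
            TraversalAlternative(
                matching=tuple((s.label, e.label) for s, e in pairs),
                chains=_merge_chains(segments),
                partial=partial,
            )
        )
    return alternatives, truncated
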