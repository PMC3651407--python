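# Methods

## The contig-relationship graph

`contiggraph` addresses the last phase of microbial genome sequencing: after
*de novo* assembly, tens to hundreds of contigs remain, separated by
coverage gaps and collapsed repeats, and the finishing team must decide
which contig ends abut before designing PCR across the gaps.

The central data structure models each contig as an **edge between two
end-nodes**, `<id>S` (the 5' start, position 1) and `<id>E` (the 3' end,
position *length*).  Evidence that two contig ends are adjacent in the
genome becomes a **link edge** between end-nodes.  Keeping the two ends as
separate vertices is what makes topology readable: a circular plasmid is a
closed alternating cycle of contig and link edges, a telomere is a repeat
contig with one linkless end, and a repeat with *k* link partners per end
exposes exactly the *k*! traversal ambiguities PCR has to resolve.

Three evidence sources feed the same graph:

1. **Split 454 reads** (`ace_io`).  The Newbler assembler splits a read
   that crosses a contig junction into two placements and encodes the
   sibling contig in the read name: suffix `fmX` means the read's 5'
   portion lies in contig X, `toY` that its 3' portion lies in contig Y
   (both `name.fm63` and `name.12-455.fm63` forms are accepted; the regex
   is configurable).  Pairing the two fragments of one read by base name
   yields one unit of linkage evidence between two contig ends; support is
   the number of distinct reads, not fragments.  Unpaired tags cannot be
   oriented and are surfaced as singletons, never edges; reads with more
   than two fragments, or with inconsistent fm/to directions, are
   ambiguities.  A *self-partner* pair (both fragments in one contig, at
   its two ends) is legal evidence: it is precisely how a read wrapping the
   origin of a circular single-contig plasmid appears, and it yields the
   S–E self-link that marks those replicons.
2. **Mate pairs** (`scaffold`), below.
3. **CRS files** (`crs_io`): the two-file exchange format (`tabbed.txt`:
   endA/endB/count; `tabbedCov.txt`: contig/length/coverage), strict
   three-column TSV.  Scaffolder output (SSPACE, OPERA, ...) enters the
   graph by conversion to this generic form.

## Coverage statistics and repeat detection

*Abundance* of a contig is total assembled read bases divided by contig
length (mean depth).  *Copy number* is abundance over the average genome
coverage.  Classification is by the depth ratio with two thresholds, both
user-settable:

* ratio < 1.5 → unique contig;
* 1.5 ≤ ratio < 2.0 → probable repeat (needs end-link counting or PCR);
* ratio ≥ 2.0 → repeat contig ("at least twice the average").

Boundary conventions: exactly 1.5 falls in the probable band (unique is
*strictly less* than 1.5); exactly 2.0 is a repeat.

Two estimators of average genome coverage are provided:

* `ACE_TOTAL`: total assembled read bases / total contig length;
* `CRS_LARGE_CONTIG_MEAN` (the "20 kb rule"): the unweighted mean of
  per-contig coverage over contigs strictly larger than 20 kb.  Repeat
  contigs above 20 kb are rare in microbial genomes (plasmids aside), so
  this estimates the single-copy coverage without repeat inflation.  If no
  contig qualifies, it falls back to the mean over all contigs.

The ACE pipeline defaults to the large-contig mean for classification, and
this is a deliberate design choice.  The total ratio includes the repeat
contigs' own excess reads in the denominator: for a clean two-copy repeat
of length *r* in a genome of collapsed length *C*, the expected ratio is
2*C*/(*C*+*r*) — strictly below 2.0 for every genome, so the definitional
two-copy repeat could never reach the repeat class under the total ratio.
The large-contig mean estimates unique coverage directly and classifies the
two-copy case correctly; the total ratio remains available via
`coverage_mode=CoverageMode.ACE_TOTAL`.

A non-positive average (e.g. a purely relational CRS file with zero
coverage) leaves contigs UNCLASSIFIED with a warning rather than raising,
so such files still render.

**Edge-width normalization.**  Z is the mean link support among link edges
whose both contigs are at least 20 kb long ("size ≥ 20 kb", deliberately
closed where the coverage rule is strictly "bigger than"; both are
configurable).  Each edge's display weight is support/Z, so the mean weight
over the qualifying set is 1 and widths are comparable across genomes.
Fallbacks keep weights finite: no qualifying link → Z is the mean over all
links; no links → Z = 1.  Z may also be computed per evidence source;
the default is over all sources combined.

## Mate-pair linkage and gap sizes

`scaffold` consumes an already-aligned SAM file (alignment itself is out of
scope; any aligner works).  Filtering keeps primary, non-duplicate
alignments with both mates mapped to *different* contigs, each with
mapq ≥ 20 (default), both contigs > 500 bp (tiny contigs attract ambiguous
mappings); intra-contig pairs carry no linkage information.

End attachment is determined by strand and library orientation.  For an FR
library, a `+` mate's outer (fragment-boundary) base is its 5' start and
the fragment continues past the contig's 3' end, so the mate attaches E
with d = length − start + 1; a `−` mate attaches S with
d = start + span − 1.  An RF (outward-facing) library swaps the two cases.
Distances are 1-based inclusive from the mate's outermost aligned base.
The gap estimate for a pair is

    gap = insert − d_a − d_b

(negative values predict contig overlap), and the identity
gap + d_a + d_b = insert holds exactly.  Pairs are grouped by unordered end
pair; support is the group size, the reported gap is the exact median, and
groups with support < 3 (default) are dropped.  The nominal insert size
comes from library configuration and is not re-estimated from intra-contig
pairs.

## Replicon topology

Classification over the link structure, run per connected component or per
contig (see `topology`):

* **CIRCULAR_SINGLE** — S and E joined by a self-link, no other links.
* **CIRCULAR_MULTI** — component in which every end-node carries exactly
  one link: the contig and link edges form a single alternating cycle.
  Closed components where some end carries ≥ 2 links are **AMBIGUOUS**
  (reported with their degree profile; resolution is for PCR).
* **LINEAR_END** — repeat-class contig with one linkless end: a telomere or
  a linear-plasmid terminus (the graph alone cannot tell which; the label
  is left to the user).
* **TIR_CHROMOSOME_END** — the sub-case with two links on the other end and
  copy number ≈ 2 (window [1.6, 2.6], configurable; tolerance covers
  sampling noise at 30× on short repeats): the collapsed terminal inverted
  repeat of a linear chromosome.
* **ISOLATED_LINEAR** — repeat-class contig with no links at all: candidate
  high-copy linear plasmid.  A linkless *unique* contig gets no call: a
  single-copy linear plasmid is indistinguishable from an ordinary contig.

**Weak links.**  A link whose support is below 5% (configurable) of the
strongest link sharing an end-node is flagged as a probable nonspecific
join (the 800-vs-10 pattern caused by slight read overlap); flagged links
are kept in the graph but excluded from topology detection by default.

**Traversal enumeration.**  For a repeat contig with S-side partners
{s₁…s_k} and E-side partners {e₁…e_k}, each way of matching S partners to
E partners is one biological resolution of the repeat; there are k!
matchings (enumerated exactly, brute-force-verified for k ≤ 4, truncated
with a flag above `max_alternatives`).  Each alternative is rendered as
hyphen-joined end-label chains — e.g. the two-per-end case prints
`37S-37E-106S-106E-41S-41E-106E-106S-42E-42S` and its sibling — by walking
flanking contigs far-end → linking-end, crossing the repeat once per
matched pair, and merging walks that share a flanking contig.  With unequal
partner counts the matchings of the smaller side are returned flagged
PARTIAL.

## Export conventions

SIF rows use interaction type `contig` for S–E edges and `link` for
linkage edges; GraphML carries node attributes (contig id, end, class,
color category, copy number) and edge attributes (kind, length or support,
normalized weight).  Colors follow the finishing convention — repeat red,
unique dark blue, probable repeat orange — as a plain attribute, not a
style file.  Output is deterministically sorted.

Sequence export emits FASTA (60-column):

* per contig, the first 1,000 bp + 20 `N` + the last 1,000 bp (contigs
  shorter than 2,000 bp are emitted whole);
* per link, the junction sequence: end A's terminal 1,000 bp oriented
  5'→3' *into* the gap, the 20-`N` spacer, then end B's terminal 1,000 bp
  oriented 5'→3' *out of* the gap.  Concretely, an S terminus is
  reverse-complemented on the left flank and taken as-is on the right; an E
  terminus the reverse.  This gap-facing convention is what primer-design
  tools expect, and it makes `junction(a,b)` the exact reverse complement
  of `junction(b,a)` (the N spacer is its own complement).

## The synthetic-data generator

`simgen` emulates the *assembler's output*, not the assembler: a genome is
declared as ordered segments — unique sections, exact-copy repeat-family
members, and unsequencable gap segments — arranged into linear or circular
replicons with per-replicon copy counts.  The collapsed assembly has one
contig per unique segment and one per repeat family.  From this it emits:

* **ACE**: reads of fixed length sampled at the stated depth from each
  gap-free run of the genome (circular replicons wrap the origin).  Reads
  crossing a contig junction are split into fm/to-named fragments that
  terminate exactly at the boundary; fragments shorter than 5 bp
  (configurable) are clipped rather than split, mirroring assembler
  minimum-overlap behaviour.  All placements are uncomplemented
  (consensus-oriented); strandedness and segment inversions are not
  simulated.  No base errors or quality values — linkage extraction is
  error-agnostic, so an error model would only add noise without
  exercising different code paths.
* **SAM**: mate pairs with Normal(insert, sd) fragment sizes; a mate
  landing in a gap or straddling a boundary leaves the pair unusable.
* **Truth**: the expected end-to-end adjacencies with true gap distances,
  and expected copy numbers — the oracle for the round-trip tests.

Read starts are **stratified** by default: one read per window of
read_length/depth bases, uniformly jittered within the window.  This
realizes the declared fold-coverage tightly at desk-genome scale, so a
two-copy repeat measures within a few percent of ratio 2 regardless of the
seed; plain uniform sampling is available as `sampling="random"`.  What the
generator deliberately does **not** model — sequencing error, chimeras,
strand effects, repeat divergence, GC bias — means green tests demonstrate
the correctness of the graph logic, not robustness to dirty data.

### Study genome defaults

* `fig3_style_spec`: four 25 kb unique sections and two copies of a 1.2 kb
  repeat, laid out U1–R–U2 │ 3 kb gap │ U3–R–U4 on one linear chromosome,
  30×, 400 bp reads.  The gap severs the U2/U3 junction, so the collapsed
  repeat carries exactly four link edges; the repeat length is in the IS
  element range and the gap is of the size a 3 kb mate-pair library
  bridges.  Expected recovery: 4 unique + 1 repeat contig, repeat copy
  number ≈ 2.0 (measured ≈ 2.02; contig-end coverage ramps depress the
  large-contig average slightly below the nominal depth).
* `replicon_panel_spec`: a two-arm chromosome plus one replicon of each
  topology class, with copy counts (3, 2, 3, 4, 1) chosen so every
  detector fires — and the single-copy linear plasmid, correctly, never
  does.
* `matepair_gap_spec`: two 30 kb contigs around a known 1,000 bp gap plus
  a 450 bp contig behind a second gap (it must attract no links under the
  >500 bp rule); 3,000 ± 150 bp inserts, 100 bp mates.  With 3,000
  sampled pairs ≈ 90 span the gap, putting the standard error of the
  median gap (≈ 1.25·σ/√n ≈ 20 bp) well inside the ±100 bp check.

## Numerical and degenerate-input choices

* Contig ids are the trailing digits of the contig name
  (`contig00042` → 42); names without digits are rejected, id collisions
  are an error.  Link rows referencing unknown contigs raise listing all
  offenders.  Duplicate link rows for the same unordered end pair merge by
  summing support.
* ACE coordinates are 1-based padded positions; abundance counts aligned
  (quality-clipped) bases; pads (`*`) are excluded from lengths.  End
  attachment uses a 10-position window around each terminus; a fragment
  touching neither window is an anomaly, and one touching both (contig
  shorter than the read) is disambiguated by which read portion continues
  elsewhere (fm breaks at the read-5' edge, to at the read-3' edge,
  flipped for complemented placements).
* Zero-read contigs (possible at near-zero simulated depth, never in real
  assembler output) are parsed directly rather than through the ACE
  library, which requires at least one read per contig.
* `filter_by_size` keeps contigs of length ≥ the cutoff, drops links with
  a removed endpoint, recomputes all statistics, and never mutates its
  input; it is idempotent.
* Median of an even number of gap estimates is the mean of the middle two.

## Known limitations

* Strandedness: segment inversions and reverse-strand reads are not
  simulated, and complemented-placement end attachment is exercised only at
  unit level.
* The scaffold module trusts the declared library orientation and nominal
  insert size; neither is estimated from the data.
* Replicon calls are structural; distinguishing telomere from
  linear-plasmid end, and confirming any plasmid call, requires PCR,
  sequencing and annotation — the tool narrows the candidates, it does not
  finish the genome.
* Graph layout, interactive editing and network-complexity metrics are out
  of scope; the exports are meant to be loaded into Cytoscape.
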