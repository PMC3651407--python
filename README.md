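# contiggraph

Contig-relationship graphs for microbial genome gap closing.

After *de novo* assembly of a bacterial genome, tens to hundreds of contigs
remain, separated by coverage gaps and collapsed repeats.  Finishing teams
need to know which contig ends abut — and where the repeats, plasmids and
chromosome ends are — before designing PCR across the gaps.  `contiggraph`
builds that picture: it extracts end-to-end linkage evidence from 454-style
ACE assemblies (Newbler's split `fm`/`to` read names), from mate-pair
mappings in SAM, or from CRS link/coverage file pairs; flags repeat contigs
by read coverage; classifies replicon topologies; and exports
Cytoscape-loadable graphs and junction sequences for primer design.

## The model

Each contig is one **edge between two end-nodes**, `XS` (5' start) and
`XE` (3' end); each piece of adjacency evidence is a **link edge** between
end-nodes, weighted by supporting reads.  Coverage statistics drive repeat
detection:

- abundance = assembled read bases / contig length,
- copy number = abundance / average genome coverage,
- class: ratio < 1.5 → unique; 1.5 ≤ ratio < 2 → probable repeat;
  ratio ≥ 2 → repeat.

Average coverage is estimated as the unweighted mean over contigs larger
than 20 kb (rarely repeats in microbial genomes), with the raw
total-bases/total-length ratio available as an option.  Link widths are
normalized by Z, the mean support among large-contig links.  Mate pairs
joining two contigs give a gap estimate

```
gap = insert − d_a − d_b
```

where d is the distance from each mate's outermost aligned base to its
attached contig end.  Replicon shapes fall out of the link degrees of the
end-nodes: circular plasmids are alternating contig/link cycles, telomeres
are repeat contigs with one linkless end, and a repeat with k link partners
per end has exactly k! possible traversals, printed as end-label chains for
PCR planning.  See `docs/methods.md` for the full account.

## Worked example

Simulate the classic repeat-resolution picture — four unique 25 kb sections
and two exact copies of a 1.2 kb repeat on one linear chromosome, 30×
coverage, 400 bp reads — then recover the graph from the ACE file:

```
$ contiggraph simulate genome.yaml -o fx
wrote fixtures for 5 contigs to fx
$ contiggraph from-ace fx/assembly.ace -o out
5 contigs, 4 links, 0 singletons, 0 anomalies
$ contiggraph stats out/tabbed.txt out/tabbedCov.txt
contigs 5
links   4
unique  4
probable_repeat 0
repeat  1
unclassified    0
avg_coverage    29.994
z_norm  29.500
unlinked_end_nodes      4
```

The two genomic repeat copies collapsed into contig 2, which carries twice
the average coverage (60.5× vs 29.99×, copy number 2.02 → class repeat) and
all four linkage edges (`1E–2S`, `2S–4E`, `2E–3S`, `2E–5S`, 29–30 reads
each); the four unlinked end-nodes are the chromosome termini and the two
gap flanks.  The repeat admits two traversals, which only PCR can decide:

```
$ contiggraph traverse out/tabbed.txt out/tabbedCov.txt --repeat 2
1S-1E-2S-2E-3S-3E / 4S-4E-2S-2E-5S-5E
1S-1E-2S-2E-5S-5E / 4S-4E-2S-2E-3S-3E
```

Junction sequence for one link, ready for primer design (1 kb per flank,
20 N spacer):

```
$ contiggraph junction out/tabbed.txt out/tabbedCov.txt fx/genome.fasta --link 1E:2S
```

Mate-pair SAM goes through `contiggraph scaffold reads.sam --insert 3000
--orientation fr`, producing CRS link rows plus a gap-size table; replicon
calls come from `contiggraph topology`.  Everything is also available as a
library (`contiggraph.build_graph`, `ace_io.from_ace`,
`scaffold.aggregate_links`, `topology.call_replicons`, `export.*`,
`simgen.*`).

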