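# Methods

## Model and assumptions

`binrefine` treats the assembly graph as an undirected graph over
contigs. Overlap orientations recorded by the assembler (GFA `L`
records, ASQG `ED` records) are discarded on load: every refinement rule
uses only connectivity, so directed/bidirected semantics would add
bookkeeping without changing any decision. Contig ids stay opaque
strings end to end; no integer re-indexing is exposed, because assembler
naming schemes differ and the binning CSV must remain comparable to the
input (bin ids are likewise preserved verbatim).

Two modelling assumptions drive everything:

* a genome corresponds (ideally) to a path in the assembly graph, so
  contigs of one genome are linked through contigs of the same genome —
  this justifies the *supported/unsupported* rule and the
  unlabelled-interior path restriction used throughout;
* coverage is proportional to organism abundance, so contigs of one
  genome have similar coverage and a contig shared by several genomes
  has coverage close to the *sum* of those genomes' coverages — this
  justifies the coverage term in propagation and the subset-sum
  decomposition behind multi-bin inference.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `alpha` | 1.5 | — | inconsistency factor; a label is corrected when `alpha * S(v, own) <= S(v, other)`. Larger values make correction more conservative. Must exceed 1 or every tie would flip. |
| `bfs_depth_cap` | 5 | edges | depth limit of the unlabelled-interior BFS used by scoring (stage 2) and propagation (stage 3). Stage 1's component computation is deliberately uncapped — supportedness is a connectivity property, not a proximity one. |
| `max_components_for_subset` | 4 | components | largest number of adjacent foreign components for which the 2^k subset enumeration is attempted. In practice a vertex borders fewer than 5 distinct components; a vertex exceeding the limit is skipped with a warning rather than truncated, so no silent approximation occurs. |
| `threads` | 8 | — | accepted for interface compatibility. Multi-bin inference is specified to be schedule-independent (all decisions are made against the stage-entry labelling), so the implementation simply runs serially; outputs are byte-identical for any thread count. |

## Numerical and tie-break choices

* Distances are integers; scores are sums of powers of two in double
  precision, hence exact for any realistic depth cap. Unreachability is
  a sentinel, never a large number, so unreachable vertices contribute
  exactly 0 to scores.
* The inconsistency test uses the printed `<=` (boundary equality
  triggers correction). Labels with zero score are not admitted as
  competitors, otherwise a vertex with an all-zero score row would
  "lose" to an arbitrary label on `0 <= 0`.
* Stages 1, 2 and 4 score against a snapshot of the labelling at stage
  entry and apply all changes simultaneously; results are independent of
  vertex iteration order. Whether a stage-2 correction may cascade into
  further corrections is left open by the method's description; this
  implementation performs a single snapshot pass.
* Stage-3 execution order is (distance, coverage difference), with
  remaining ties broken by target contig id then source contig id
  (string comparison). The published order is only a strict weak order;
  the extra tie-break makes runs reproducible. After each executed
  action, candidates are refreshed only for unlabelled vertices within
  unlabelled-path reach of the newly labelled vertex; a test asserts
  this is observationally identical to full recomputation.
* Subset-sum ties (equal |sum − target|) prefer fewer components, then
  the lexicographically smallest id tuple. Comparisons are exact; no
  epsilon is introduced because none is defined by the method.
* Stage 4 requires strictly `c(v) > c(P)` and considers only components
  reachable by a *direct* edge from `v`, matching the worked examples;
  no distance relaxation is applied. Components are maximal same-label
  connected subgraphs computed after propagation.

## The packaged example graph

The 26-vertex example is reconstructed from narrated constraints: the
quoted adjacencies and the support path 18–19–14–15, the four distance-1
blue neighbours of vertex 18, the seven propagation tuples, coverages
108 and 142 at the two multi-bin vertices, and component averages 95, 19
and 49. The remaining edges and coverages (marked `RECONSTRUCTED_*` in
`binrefine/datasets.py`) are the fixture's own choices, picked minimal
so that *every* narrated value is reproduced simultaneously — including
that exactly one label is unsupported and exactly two vertices are
inconsistent. Tests pin the narrated values; reconstructed details are
asserted only through the behaviour they exist to produce.

One narrated distance is internally inconsistent in its source (a
distance quoted between vertices 8 and 17 while the score being formed
concerns vertex 18); the fixture realises the only reading compatible
with the printed score, namely D(8, 18) = 3.

## Synthetic data: what it emulates, what it does not

`SyntheticSpec`/`simulate` plant `n_genomes` genomes as vertex-disjoint
paths of contigs. `n_shared` contigs are each spliced into the paths of
two genomes and receive the sum of both genomes' coverages; all
coverages then get multiplicative lognormal noise (`noise_sd`, default
5% — lognormal because coverage is positive and sequencing depth noise
is multiplicative). Contig lengths are uniform on 500–8000 bp. The
initial labelling mimics a length-thresholded binner: only contigs of at
least 1000 bp are ever labelled, a `label_fraction` (default 0.5) of
those receive their genome's bin, and a `mislabel_fraction` (default
0.1) of the labelled ones are flipped to a wrong bin. Shared contigs are
never labelled initially, so recovering them exercises propagation plus
multi-bin inference together.

Path lengths default to 40–80 contigs per genome. Real metagenome
genomes fragment into tens to hundreds of contigs, and the choice
matters: with very short paths, splice neighbourhoods — where two
genomes meet at an unlabelled shared contig and labels can be seen
across it at distance 2 — dominate the graph and boundary effects swamp
the signal the method relies on.

What the generator does **not** emulate: composition signal (there are
no sequences), intra-genome repeats and tangles (each genome is a clean
path), chimeric contigs, coverage variation along a genome, and more
than two genomes sharing one contig. Passing recovery tests therefore
demonstrates the label-propagation and coverage-decomposition logic
under the model's own assumptions, not performance on real assemblies.

Known residual failure mode (observed in seed-level traces, left as-is
because it is faithful method behaviour): when the initial labelling is
corrupted immediately next to a splice, or a genome's own labels are
sparse within the depth cap there, the score test can flip a boundary
vertex to the neighbouring genome's bin and propagation then extends the
wrong label over the adjacent unlabelled stretch. This caps recovery
rates a few percent below perfect at the default corruption levels.

## Formats

GFA 1.0 (`S`/`L`), SGA ASQG (`VT`/`ED`), the SPAdes contigs-paths file,
SPAdes-style FASTA headers (`NODE_i_length_L_cov_c`), abundance TSV and
two-column binning CSV are parsed by small hand-written readers — the
formats are line-oriented and no installed library covers them. For
segment-level SPAdes graphs the contig graph is formed by the stated
convention: two contigs are joined when their segment paths share a
segment or contain segments linked by an `L` record. An explicit
abundance file always overrides header-derived coverage. Output rows are
sorted (contig id, then bin id) so equal inputs give byte-identical
files.

## Limitations

* The refiner never merges or splits bins; it only relabels, extends and
  overlaps the bins it was given, so systematic errors of the initial
  binner (e.g. two genomes fused into one bin) persist.
* Multi-bin inference assigns at most the labels of directly adjacent
  components; a shared contig whose true partners were mislabelled at
  the boundary cannot be recovered.
* Coverage decomposition assumes additive coverages with modest noise;
  strain mixtures with near-identical abundances are not separable by
  it.
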