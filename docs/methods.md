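# Methods

## Model

A tumor's amplified regions are modelled as disjoint contiguous intervals
of the gene order on each chromosome. A targeted panel observes only its
own genes; the report reduces each observed gene to a binary label
(amplified / not amplified). Inference inverts this censoring under two
assumptions:

1. **Faithful calls.** Every assayed gene inside an amplified region is
   reported amplified, and every assayed gene outside is not. The method
   inherits whatever error the vendor's calling pipeline has; it adds no
   probabilistic error model of its own. The adjacency flag is the one
   concession to miscalls: two inferred amplicons separated by very few
   assayed non-amplified genes are flagged, because a single missed call
   would merge them.
2. **Rank space.** "Between" and "nearest" are defined over the rank of a
   gene within its chromosome (sorted by start, then end, then symbol),
   never over base pairs. This matches how the evidence arrives (an
   ordered list of observed genes), gives deterministic behaviour for
   nested or overlapping genes, and makes every statement about
   boundaries a statement about gene counts.

Given reported set A and panel P, the algorithm is exactly the set logic
described in the README: maximal runs of reported genes uninterrupted by
P \ A genes form amplicons; each amplicon's core spans its outermost
reported genes; the nearest P \ A gene per side bounds a possibly-amplified
region, exclusive of that boundary gene. Amplified regions may span the
centromere; no distance cap is imposed on merges, because the data provide
no evidence for one — the region label and coordinates are surfaced so a
reader can judge a suspiciously wide region themselves.

### Edge behaviour and degenerate inputs

- A side with no assayed non-amplified gene extends to the chromosome end
  and is marked *unbounded* in every output format.
- A boundary gene immediately adjacent to the core yields an empty
  possibly-amplified set on that side (the interval is exclusive on both
  ends).
- Query genes off the panel but present in the genome are treated as
  assayed and amplified (the report evidently measured them; this also
  supports pasted custom panels), with a warning. Query genes absent from
  the genome are a hard error, demotable to a warning with
  `--skip-unknown`. Panel genes absent from the genome are dropped with a
  warning — they can neither bound nor join an amplicon.
- Coordinate loads are all-or-nothing: a malformed row or duplicate symbol
  rejects the file with the offending line or symbol named. Multiple
  intervals per symbol are rejected rather than silently collapsed;
  collapsing transcripts is a data-preparation step.
- Zero inferred amplicons is a success, rendered as a well-formed empty
  document.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `--adjacency-gap` | 1 | flag amplicon pairs separated by at most this many assayed non-amplified genes (units: genes). 1 is the shared-boundary-gene situation; separated amplicons always have ≥ 1 separator, so 0 is rejected. |
| `--dialect` | `tsv5` | coordinate-file layout; all dialects are 0-based half-open. |
| `--link-template` | COSMIC gene page | URL built per listed gene; string construction only, never fetched. |

Annotation conventions: the count of potentially co-amplified genes is
|core ∪ boundary| − |reported| — core and boundary are pooled because the
report deliberately does not grade likely vs possibly co-amplified, and
reported genes are excluded because they are the co-amplification *anchors*.
Census genes are listed over the same pooled extent and include reported
genes that are census members. Region labels use the pooled extent's first
and last gene cytoband (collapsing when equal), falling back to
`chrom:start-end` without cytoband data.

## Synthetic data

`make_toy_genome` lays non-overlapping genes left-to-right with random
lengths (200–20 000 bp) and gaps (100–5 000 bp) from a seeded
`random.Random`; all randomness in the package flows through explicitly
passed seeds, never global state. `simulate_profile` samples the panel
uniformly without replacement and places disjoint true amplicons (length
up to n/(3k) genes, ≥ 1 gene between neighbours) uniformly at random; the
implied report is exactly the assayed genes inside true amplicons. A gene
is truly amplified iff its rank lies in a true interval — rank containment,
matching the inference convention.

What the simulator emulates: the *censoring* a sparse panel applies to a
clean copy-number profile. What it does not emulate: vendor miscalls,
copy-number magnitude, deletions, or correlated amplicon placement
(real amplicons cluster at fragile sites). Passing recovery tests
therefore demonstrates correctness of the combinatorial inversion, not
robustness to noisy calls.

**Recovery guarantee.** When every true amplicon and every gap between
consecutive true amplicons contains ≥ 1 assayed gene
(`truth_is_visible`), inferred calls are in bijection with true
amplicons, every core lies inside its truth, and every truly amplified
gene lies in core ∪ boundary of its call. The property suite checks this
on simulated profiles; `boundary_error` treats any violation as an
inference bug and raises. Profiles failing the visibility condition are
excluded from recovery metrics — with an invisible truth the call/truth
correspondence is ill-defined (two truths merge, or a truth vanishes).

**Boundary resolution experiment.** `density_sweep` measures mean per-side
overshoot (genes between the true edge and the inferred possibly-amplified
edge) across panel densities {0.1, 0.2, 0.5, 1.0}, 100 seeds per density,
500-gene genomes over 5 chromosomes, 3 true amplicons — sizes chosen so
the full sweep runs in seconds while leaving ~100+ matched amplicons per
density. Overshoot falls monotonically with density and is ≤ 1 gene per
side (exactly 0 in practice) at density 1.0, where every gene adjacent to
a true edge is assayed.

## Bundled data

The packaged coordinate/panel/census files are synthetic stand-ins, marked
`.synthetic.` in their filenames and headers. The coordinate table covers
~67 genes at the loci of the documented use cases with approximate hg38
positions but reference-faithful gene *order* — the only property the
algorithm consumes. The 329-gene panel and 191-gene census are
reconstructions in the style of, not copies of, a commercial assay list
and the COSMIC Tier 1/2 census. Consequences: co-amplified counts on the
bundled data are much smaller than they would be with a full annotation
(they count only bundled genes), and analyses of other loci require real
files. Amplicon groupings, adjacency flags, census columns and region
labels at the covered loci are insensitive to the approximation because
they depend only on gene order and set membership.

## Design choices

- **Merge rule made explicit:** consecutive reported genes merge iff zero
  assayed non-amplified genes separate them. Not-assayed genes never
  separate — the assay says nothing about them.
- **Flagging operates on core spans** and counts assayed non-amplified
  separators directly from the status map; this needs the gene catalog,
  which is why `flag_adjacent` takes the index and statuses alongside the
  calls.
- **Case-insensitive symbols everywhere** (reports are typographically
  inconsistent, e.g. `C15ORF65` vs `C15orf65`); output always uses the
  coordinate file's casing. No alias or gene-history resolution is
  attempted: exact symbols only.
- **No interval arithmetic:** an interval tree would add nothing — every
  query the algorithm makes is a rank-neighbour scan on a sorted tuple.
- **Determinism as a contract:** sorted iteration, explicit seeds,
  stable id assignment (`amp1…ampN` by chromosome order then start rank),
  `sort_keys` JSON. The CLI determinism tests assert byte-identical
  output.

## Limitations

- Binary input: no copy-number magnitude, no deletions, no confidence
  intervals on boundaries.
- Resolution is bounded by panel spacing; between the core and the
  boundary gene the method can only say "possibly amplified".
- Gene-order fidelity of the coordinate table is load-bearing; a stale or
  misassembled table shifts boundaries silently.
- The adjacency flag is a heuristic prompt for human review, not a
  statistical test of regional amplification.
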