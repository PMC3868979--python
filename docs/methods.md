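# Methods

## The detection statistic

The screen treats a tRNA gene as a pair (scaffold, anticodon). Within one
species, all genes are aligned with their anticodon triplet masked as `NNN`,
a tree is built from the masked alignment, and for each gene two nearest-leaf
patristic distances are computed: `d_same`, to the closest gene with the same
(unmasked) anticodon, and `d_diff`, to the closest gene with a different
anticodon. A gene is called *switched* iff `d_diff < d_same`, strictly. The
logic: under concerted evolution, copies of one family are nearly identical,
so `d_same` should be tiny; a gene whose scaffold clusters inside a
differently-labeled family instead must have acquired its anticodon after the
scaffold's ancestry was set.

Evaluation requires the gene's anticodon to occur at least twice in the
species (otherwise `d_same` is undefined) and at least one differently
labeled gene to exist. `d_diff` minimizes over *all* other tRNAs regardless
of amino acid; a `same_aa_only` flag restricts the comparison set when a
within-isoacceptor analysis is wanted. Reports carry amino-acid labels so
such filtering is possible downstream.

Assumptions worth stating:

- Within-family identity far exceeds between-family identity. When families
  are themselves intermixed (ancient switching, horizontal transfer,
  alignment failure), the statistic loses meaning gene by gene.
- Branch lengths approximate substitutions/site. Neighbor joining on
  Jukes–Cantor distances provides this without external tools; a
  maximum-likelihood program can be substituted through the tree-builder
  adapter (gapped FASTA in, newick out) when model adequacy matters.
- The anticodon must be masked *before* alignment and tree inference, so the
  three anticodon sites can never pull a chimera toward its donor family.

## Pipeline parameters

| parameter | default | units | notes |
|---|---|---|---|
| COVE threshold | 40.0 | bits | genes scoring strictly below are removed as pseudogenes; equality is kept |
| distance model | JC | — | `p` (raw mismatch fraction) also available |
| JC saturation cap | 5.0 | subs/site | applied when pairwise p ≥ 0.74, keeping saturated pairs finite and comparable |
| aligner scores | +1 / −1 / −4 / −1 | — | match / mismatch / gap open / gap extend; `N` scores 0 against anything (neutral), so masked triplets neither attract nor repel |
| bootstrap replicates | 0 (off) | — | column resampling + NJ; supports are reported only, never used in calling |
| tie tolerance | 1e−9 | subs/site | see "Numerical choices" |
| control triplets | 6 | — | 0-based starts 2, 14, 26, 43, 54, 64 for a 72-nt gene, scaled with length, shifted minimally off the anticodon; all configurable |
| minimum species size | 3 | genes | smaller post-filter repertoires are skipped with a logged reason |

The guide order for the progressive aligner is average-linkage clustering of
3-mer count distances; records are processed in lexicographic gene-id order,
which makes the alignment (and everything downstream) invariant to input
ordering. tRNA genes of one species are nearly equal length and highly
similar, so alignments are typically gapless; the affine-gap machinery exists
for the occasional length variant.

## Branch support

Supports are nonparametric bootstrap proportions over alignment columns:
each replicate resamples columns with replacement, recomputes distances and
an NJ tree, and counts internal bipartitions. They stand in for
likelihood-based support measures and are attached to the newick output as
internal node labels. Calls depend only on distances, so support choice
cannot change a call.

## The simulator

`simulate_repertoire` draws a uniform random root sequence (default 72 nt),
evolves one ancestor per family at `delta_between` substitutions/site under
Jukes–Cantor, writes the family anticodon at the anticodon window (default
offset 33, the anticodon-loop position of a 72-nt gene), evolves each copy a
further `delta_within`, and restores the anticodon window — family identity
is an assignment, not an evolutionary outcome, so truth labels are exact.
Defaults (3 families × 6 copies, `delta_between` 0.20, `delta_within` 0.01,
2 injected switches, 10% pseudogene decoys) model a small repertoire with
strong concerted evolution. A switch event overwrites only the recipient's
anticodon triplet with a donor family's anticodon; recipients are drawn
without replacement, donors uniformly among the other families. Pseudogene
decoys are root-derived sequences scoring Uniform(10, 39.5) bits; genuine
genes score Uniform(50, 90) — only the 40-bit threshold matters. Optional
per-window rate multipliers create fast-evolving regions for adversarial
control-triplet scenarios.

What the simulator does **not** emulate: indels (tRNA genes are
near-constant length), the cloverleaf's site-specific constraint profile,
GC-content and codon-usage biases, gene birth–death dynamics, and intron
splicing. Passing recovery tests therefore demonstrates that the statistic
and its implementation behave correctly under the idealized two-level
family structure; they do not certify performance on real repertoires, where
alignment quality and heterogeneous rates add error modes the simulation
does not contain.

## Numerical choices

- **Tie tolerance.** Patristic distances are path sums; two mathematically
  equal paths (e.g. both through identical sequences) can differ by ~1e−13
  in floating point, silently turning an exact tie into a strict inequality
  in an arbitrary direction. `call_switches` treats `d_same − d_diff ≤ 1e−9`
  as a tie (not switched). The tolerance is far below any biologically
  meaningful branch length (one substitution in a 72-nt gene is ~0.014).
- **Saturated pairs** (p ≥ 0.74) get distance 5.0 with a warning rather than
  ±∞, so nearest-neighbor minimization stays well defined.
- **Negative NJ branch lengths** are clamped to 0, keeping patristic
  distances nonnegative.
- **Determinism.** All ties (nearest neighbors, NJ agglomeration input
  order, guide-tree order) break by lexicographic gene id; rerunning with
  the same inputs and seed reproduces outputs byte for byte.
- **Degenerate inputs.** Two taxa yield the single-edge tree; one maskable
  record is an error ("nothing to align"); a pair with zero comparable
  columns is an error naming both genes (inside the bootstrap it is capped
  instead, since a column resample can drop all shared columns).

## Design choices that were genuinely open

- **Position-attribution partner.** The triplet compared against is the
  nearest different-anticodon leaf — the gene achieving `d_diff` — as the
  minimal-assumption choice; it is recorded per call so any other convention
  can be recomputed from the table.
- **Control-offset geometry.** Control windows are evenly spread along the
  sequence and shifted minimally off the anticodon; they are honest controls
  (same masking, alignment, tree and grouping machinery) rather than
  structure-anchored positions.
- **Intron handling.** The tabular reader records intron coordinates but
  does not splice; spliced and unspliced genes should not be mixed within a
  species.

## Known limitations

- **Collateral flagging around true chimeras.** After masking, a chimeric
  gene is statistically indistinguishable from one more copy of its scaffold
  family. Its genuine siblings then see it as a *different-anticodon*
  neighbor at within-family distance, and whenever the chimera happens to be
  a sibling's strictly nearest leaf, that sibling is also flagged. With
  6-copy families and ~0.7 expected scaffold substitutions per copy, roughly
  one sibling per injected event is flagged in simulation (a ~10% spurious
  proportion among evaluated non-switched genes under the default scenario),
  while the no-switch scenario stays at 0. This is a property of the
  `d_diff < d_same` statistic itself, not of the implementation: every such
  spurious call has the injected chimera as its nearest different-anticodon
  neighbor, so in practice flagged genes arrive in clusters around each true
  event, and per-event (rather than per-gene) interpretation is advisable.
  Under the same default scenario the per-gene recall of injected events is
  ~0.93–0.98 (two events landing in one family with the same donor anticodon
  can shadow each other), and position attribution of recovered events is
  ~0.99–1.0.
- Near-zero within-family divergence produces exact distance ties, which are
  conservatively never called.
- NJ is a distance method; on real data with strongly non-clocklike or
  saturated families an ML tree via the adapter may reorder borderline
  calls.
- COVE scores are consumed, not computed; inputs lacking scores cannot be
  pseudogene-filtered.
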