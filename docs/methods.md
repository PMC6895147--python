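# Methods

## The census model

The unit of analysis is a rooted gene-family tree. For a focal group of
n species the quantity of interest is the empirical distribution over the
(2n−3)!! rooted binary leaf-labelled topologies — 15 for n = 4 — of the
extracted focal clades, together with a majority-rule consensus annotated
with the percentage of gene trees supporting each clade.

Topology identity is decided by the rooted Robinson–Foulds distance: with
C(T) the set of non-trivial clades of T (leaf-label sets of internal
nodes, excluding singletons and the full leaf set), d(T₁,T₂) =
|C(T₁) △ C(T₂)|. On trees with identical leaf sets this is a metric and
d = 0 iff the rooted topologies coincide, so classification reduces to
finding the unique catalogue entry at distance 0. A rooted binary tree on
n leaves has exactly n−2 non-trivial clades.

Canonical serialization orders the children of every node by their
smallest descendant leaf label, which makes topology identity equivalent
to string equality of length-free Newick — the catalogue is sorted and
numbered by that string, so ids are stable across runs and machines.

## Extraction rules and their order

Families are processed reroot → extract → collapse → classify. Rejection
reasons are evaluated in a fixed order, and only the first applies:

1. `unrootable` — no tip of any outgroup-priority species. Gene trees from
   maximum-likelihood programs are effectively unrooted; we root on the
   edge subtending the smallest clade containing all tips of the
   highest-priority outgroup species present, splitting that edge's length
   equally. We deliberately do not midpoint-root: a wrong root silently
   reshuffles rooted topology counts.
2. `too_few_species` — fewer than n−1 focal species present (n−1 is only
   admitted when n ≥ 4 and one-missing handling is enabled; a 3-taxon
   rooted topology is still informative, a 2-taxon one is not).
3. `cross_species_duplication` — some focal species has ≥ 2 tips that are
   not monophyletic in the family tree. This is checked *before* focal
   monophyly: a stray paralog sitting among the outgroups also makes the
   focal tip set paraphyletic, but the phenomenon is a duplication
   artifact, and the category should say so. `paraphyletic_focal_group` is
   therefore reserved for genuinely misplaced single-copy lineages.
4. `paraphyletic_focal_group` — the smallest clade containing the focal
   tips contains a non-focal tip.
5. `unresolved_polytomy` — the collapsed clade is not binary, so no binary
   catalogue entry can be at RF distance 0. Polytomies only arise from
   input polytomies or from the optional `polytomy_epsilon` contraction of
   short internal branches (default: off; near-zero ML branch lengths stay
   resolved unless the user opts in).

Within-species duplicates are collapsed by keeping the tip with the
shortest terminal branch (ties broken lexicographically); suppressed
degree-2 nodes have their branch lengths summed, so the survivor's
root-to-tip path length is preserved. The survivor is relabelled with the
species id. A family that is both one-missing and duplicated is collapsed
first and then categorized by the missing-species check, i.e. as
one-missing.

One-missing families are classified against the catalogue on their
reduced 3-species set; because ids are local to each reduced catalogue,
machine output keys one-missing counts by canonical Newick rather than id.

## Aggregation conventions

* Proportions are per category (complete, one-missing,
  duplicated-collapsed), each summing to 1 over classified families;
  a pooled complete+collapsed distribution is also reported because the
  consensus is built from that pool by default (`consensus_scope` can
  restrict it to complete families only).
* The consensus keeps clades in strictly more than 50% of inputs; exact
  ties at 50% are excluded. Support percentages are rounded to integers
  for display, exact fractions kept in machine output. Since a clade
  occurs in a subtree iff the subtree's topology contains it, consensus
  support equals the summed pooled proportions of supporting topologies —
  an identity the tests assert exactly.
* Mean branch length of a family is the unweighted arithmetic mean over
  all extracted-subtree edges, terminal and internal, excluding the root's
  absent parent edge; the per-topology summary is the mean of per-family
  means (per-gene-first, not pooled). Families with any missing edge
  length are excluded from this summary only. One-missing families are
  excluded because their subtrees span a different taxon set.

## The simulator

The generator draws gene trees under the multispecies coalescent on a
user-supplied focal species tree with branch lengths in coalescent units:
within each species-tree branch, the k extant lineages coalesce with
exponential waiting times at rate k(k−1)/2; populations merge at each
ancestral node; remaining lineages coalesce freely above the root. One
haploid lineage is sampled per species, matching a
one-transcriptome-per-species design; population sizes are absorbed into
the coalescent-unit branch lengths, which assumes a constant effective
size and hence an ultrametric species tree (validated, tolerance 1e-6).

The default model is `(((A:6,B:6):2,C:8):2,D:10)`: an asymmetric four-taxon
tree whose two internal branches of 2 coalescent units put it in the
moderate-ILS regime (per-branch concordance 1 − (2/3)e⁻² ≈ 0.91, joint
recovery of the species topology ≈ 0.83), with perturbation rates
p_dropout = 0.1, p_duplicate = 0.1, p_paralog = 0.05 — enough to populate
every census category at a few hundred loci without drowning the signal.

Scaffold outgroups attach basally at fixed depths (default: species-tree
height + 3, 6, 9, … coalescent units) with no coalescent variance of their
own: they exist to exercise rooting and extraction, not to model outgroup
evolution. When a deep coalescence pushes the gene-tree root above the
first configured depth (probability e⁻³ ≈ 5% per excess unit for the last
pair), the attachment stack shifts up just enough to keep all branch
lengths positive.

Perturbations, per family and focal species: dropout deletes the tip;
duplication replaces it by a cherry with 0.01-unit terminal branches
(small but nonzero, keeping trees strictly binary and the duplicates
trivially monophyletic); a paralog grafts an extra copy at a uniform point
of a random scaffold tip edge, guaranteeing a cross-species-duplication
rejection downstream. Each family records the perturbations applied and
the category a correct census must assign, enabling exact end-to-end
truth checks. The RNG is keyed by (seed, locus index, stream), so per-locus
substreams are stable: increasing `n_loci` never reshuffles earlier loci,
and identical seeds give byte-identical Newick output.

The simulator's independent oracle is the rooted-triplet closed form
(concordant probability 1 − (2/3)e^(−T)); four-taxon simulations are
additionally checked by marginalizing to each embedded triplet, whose
distribution must match the closed form for the induced species tree —
a consequence of the coalescent's sampling consistency.

### What the synthetic data does not emulate

Real transcriptome-derived gene trees carry estimation error (finite
alignment length, model misspecification), non-ultrametric rate variation,
hybridization/introgression, and alleles that are not cleanly assignable
to species. The simulator models none of these: passing tests demonstrate
that the census rules and bookkeeping are correct under the stated
coalescent-plus-perturbation generative process, not that inference on
real data is unbiased. Introgression in particular would shift topology
proportions in ways this generator cannot produce; the census only
*measures* proportions and makes no attempt to separate ILS from gene
flow.

## Numerical and design choices

* Branch lengths serialize with 6 significant digits by default
  (configurable); round-tripping preserves topology exactly and lengths to
  that precision.
* Newick parsing accepts quoted labels, internal (support) labels and
  branch lengths; `[...]` comment blocks are stripped with a warning;
  malformed input errors name the character offset. Networks and NEXUS are
  out of scope.
* Rerooting is exactly idempotent: a tree already rooted with the outgroup
  clade as a child of a two-child root is returned unchanged (no repeated
  halving of the root edge). Leaf-to-leaf path lengths are preserved by
  rerooting.
* The chi-square goodness-of-fit helper pools categories with expected
  count < 5 (smallest first) and uses k−1 degrees of freedom after
  pooling.
* Topology enumeration is guarded at n ≤ 8 ((2·8−3)!! = 135,135 entries);
  the census itself only ever enumerates the focal n and its (n−1)-subsets.
* Test problem sizes — 10,000 loci for triplet calibration, 4,000 for
  marginalization checks, 500 for end-to-end recovery, 250 randomized
  families for accounting properties — were chosen to hold binomial
  standard errors a few times below the asserted margins while keeping the
  suite fast.

## Known limitations

* One lineage per focal species: allele-level sampling (two or more
  haplotypes per species) is not modelled; the duplicate-cherry
  perturbation imitates its footprint in the census categories only.
* The one-missing pathway requires n ≥ 4 and exactly one absent species;
  groups of three get no such allowance.
* `cross_species_duplication` takes precedence over
  `paraphyletic_focal_group`, so a family with both phenomena is counted
  under the former; counts of the two rejection classes are not
  independent of this ordering.
* The simulator's scaffold is a fixed ladder; it cannot produce rogue
  outgroup placements, so the `unrootable` path is exercised only by
  hand-written fixtures.
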