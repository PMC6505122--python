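# Methods

This note documents the models, conventions and numerical choices behind
`karyophylo`, and what the simulation-based tests do and do not show.

## Karyotypes at paint resolution

A karyotype is a list of chromosome pairs, each an ordered (pter→qter)
list of *paint segments*: blocks homologous to a reference species'
chromosomes, arms (`p`/`q`) or arm halves (`q prox`/`q dist` etc. — the
finest granularity painting maps resolve). The `centromere_index` counts
segments on the p side of the centromere; 0 marks an acrocentric, and a
value equal to the segment count marks a bi-armed chromosome whose
centromere falls inside its last (unsplit) segment. Conserved bi-armed
reference chromosomes are represented as `[Xp, Xq]` two-segment
chromosomes so that centromere position is explicit; acrocentric reference
chromosomes conserved whole are single `whole` segments.

Bookkeeping follows the cytogenetic conventions:

* `2n = 2·(autosomal pairs) + 2` (a diploid sex pair is always assumed;
  heteromorphic pairs such as XY change nothing);
* `FN = 4·(bi-armed pairs) + 2·(acrocentric pairs)` over the autosomes
  only, with subtelocentrics counted as bi-armed — the two-way
  bi-armed/acrocentric bookkeeping that reproduces every published
  2n/FN pairing used in the tests (e.g. 15 bi-armed pairs ⇒ FN 60).
  Table-style sources occasionally disagree with a text formula by one
  arm pair; where that happened we followed the formula consistent with
  the stated bi-armed count.

A *syntenic association* is an unordered pair of reference segments
adjacent on one chromosome, canonicalised by label so `8q/12q` and
`12q/8q` are one value. Chromosomes bearing a single reference segment
(whole-chromosome syntenies) contribute no association.

## Rearrangement algebra

`apply_event` implements five event kinds with hard conservation
contracts (checked over 10,000 random events in the acceptance suite):
Robertsonian fusion (Δ2n = −2, ΔFN = 0; requires two acrocentrics, the
first operand re-reads cen→pter as the new p arm), tandem fusion
(−2, −2; acrocentric donor appended to the acceptor's q terminus),
centric fission (+2, 0; a bi-armed chromosome splits at its centromere
into two acrocentrics), distal fission (+2, +2; a terminal block without
the centromere detaches as a new acrocentric pair while the donor keeps
its morphology — the mechanism by which a 2n = 40/FN = 68 complement can
gain an acrocentric pair and reach 2n = 42/FN = 70 with its bi-armed
count intact), para-/pericentric inversion (0, 0, except a pericentric
inversion that relocates the centromere to a chromosome end or off it,
±2), and WART, the whole-arm reciprocal translocation (0, 0). Every event
conserves the multiset of segments.

`count_events` is deliberately a *greedy lower bound*, not an exact
rearrangement distance (no DCJ): ancestral chromosomes scattered over k
derived chromosomes contribute k−1 fissions, derived chromosomes drawing
from k ancestral sources k−1 fusions, and a derived chromosome counts one
inversion when any of its single-source segment runs is not a contiguous
forward or reversed block of its source. Published event tallies of this
kind are narrative counts over unsigned, partially ordered segments;
exact distances are underdetermined at this resolution. On simulated
histories in which no chromosome is rearranged twice, the greedy
fission/fusion counts equal the true event log (tested).

## Character coding

`build_matrix` codes the union of all observed associations: 1 when a
taxon carries the association, 0 when it was painted with the relevant
probes but lacks it, `?` when those probes were never hybridised onto it
(e.g. literature taxa mapped with a different probe set). Inversion and
morphology characters are accepted as pre-declared extra columns rather
than auto-detected — painting alone does not define an extraction rule
for them. Polarization flips exactly the columns where the outgroup
scores 1 and stores the flip mask; parsimony-informative filtering keeps
characters with at least two taxa in each of two states. NEXUS I/O uses
the standard datatype with `SYMBOLS="01" MISSING=?`; the reader accepts
sequential and interleaved dialects (cells parsed with dendropy) and
recovers per-character labels from `CHARSTATELABELS`, which the writer
emits so matrices round-trip losslessly.

## Maximum parsimony

Characters are unordered and binary; `?` contributes the full state set
in Fitch sets, so an all-missing column costs nothing on any tree. The
search engine packs every character's state set two bits wide into one
Python integer per node visit, giving an exact whole-matrix Fitch pass in
a handful of bitwise operations; a numpy per-character pass provides the
step vectors for CI/RI. Exhaustive search enumerates all (2n−5)!!
unrooted topologies by stepwise addition; branch-and-bound prunes partial
trees whose Fitch length already exceeds an upper bound obtained from a
short heuristic run (the length of a leaf-restricted tree never exceeds
that of its completions, so pruning is safe and the optimum set is
complete). Optimal trees are deduplicated by unrooted topology. The
heuristic uses random-addition starting trees with first-improvement NNI
and SPR hill-climbing, is fully seeded, and on random 8-taxon matrices
matches the exact optimum in ≥95 % of starts-of-10 runs (tested against
branch-and-bound).

CI and RI are reported on the informative-only character set by default —
the convention used for headline published values — with
`CI = M/L` (defined as 1 when L = 0) and `RI = (G−L)/(G−M)` (defined as
1 when G = M).

The bootstrap resamples character columns with replacement, reruns the
search per replicate (heuristic with 3 random-addition starts by
default), and reports clade frequencies in percent on a majority-rule
consensus; replicates with several optima contribute 1/#optima per tree.
Strict and majority-rule consensus trees are built from split sets;
splits are normalised to the side not containing the lexicographically
first taxon.

## Bayesian inference

The two-state symmetric Mk model (stationary frequencies ½, ½;
`P(same, t) = ½(1 + e^(−2t))`) is evaluated by Felsenstein pruning;
missing cells marginalise over both states. An optional `variable_only`
ascertainment divides each character's likelihood by 1 − P(constant
pattern) — the standard restriction-site correction — and is flagged, not
silently applied. The sampler is a single Metropolis–Hastings chain over
(topology, branch lengths): NNI, single-branch log-scale multipliers and
whole-tree scaling, with an Exponential(10) branch-length prior and a
uniform topology prior; no Metropolis coupling and no rate heterogeneity,
the minimal defaults for a model whose published applications rarely
report those settings. Likelihoods are recomputed in full each step
(matrices here are dozens of characters; numerical underflow is not a
concern at these sizes — a known limitation for much larger matrices).
Desk-scale default run length is 200k generations. Correctness is checked
three ways: the pruning likelihood against brute-force enumeration on
quartets (to 1e−10 relative error), a prior-only chain against the
uniform-topology prior's split frequencies, and a congruent quartet
reaching ≥0.95 posterior for the true split.

## Ancestral karyotype assembly

`reconstruct_states` runs the Fitch downpass and uppass, yielding the MPR
state set at every node of an outgroup-rooted tree (verified against
brute-force enumeration of all labelings on trees of up to six leaves).
`assemble_akp` chains the associations present at a chosen node into
linear chromosomes (a segment with three association partners, or a
cycle, is reported as a conflict naming the characters), adds declared
whole-chromosome syntenies, and leaves the remaining reference segments
in the free acrocentric form. A chromosome is assigned bi-armed
morphology iff it spans p and q material of one reference chromosome or
joins segments across a declared centric junction — morphology at this
point is information painting cannot supply alone, so centric junctions
are supplied by the caller (typically from the reference complement's own
centromere positions, as banding data supply them in practice). Ambiguous
{0, 1} node states resolve to the plesiomorphic absence by default
(configurable to presence), and are always reported.

Assembly is intended for the *ingroup root* of an outgroup-rooted tree
rather than a naked bifurcating root: at a two-child root, any character
gained or lost along one basal branch has an ambiguous MPR root state,
whereas the uppass at the ingroup root resolves such cases using the
outgroup. The recovery experiment therefore scores ancestor
reconstruction at the basal ingroup node (the root child with the larger
subtree, the smaller side acting as outgroup) against the true simulated
karyotype at that node.

## The simulator and what the tests show

`simulate_tree` draws a Yule (pure-birth) tree via dendropy, extends all
tips by the waiting time to the next unrealised birth (avoiding
zero-length pendant edges), and rescales to mean branch length 1.
`evolve` draws per-branch event counts from Poisson(rate × length) per
event kind and picks operands uniformly among the valid ones; events with
no valid operand (e.g. a Robertsonian fusion with fewer than two
acrocentrics) are skipped and logged. Default rates — 0.15 fusions, 0.09
fissions, 0.04 inversions and 0.015 WARTs per unit branch length, i.e.
about 0.3 events per branch — define the package's low-rate study regime:
enough change to resolve most branches while keeping homoplasy
(independent gain or loss of the same association) rare. Fusions choose
the Robertsonian form with probability 0.8 when two acrocentrics exist,
fissions are distal with probability 0.25, matching the dominance of
centric events in the karyotype literature. A `non_overlapping` mode
forbids touching any chromosome twice along a lineage, the regime in
which greedy event counting is provably exact.

Under these conditions, 50 eight-taxon replicates place the true unrooted
topology among the parsimony optima in ≥90 % of informative replicates
and recover the scored ancestral node's exact 2n and FN in ≥90 % — the
package's acceptance bands. What this does *not* show: real painting data
add probe-resolution artifacts, intraspecific polymorphism, and
non-uniform rearrangement processes (hotspots, lineage-specific rate
shifts) that the uniform-operand Poisson model deliberately omits; the
simulator validates the inference machinery, not the biological model.

## Numerical and degenerate-input choices

* All randomness flows through explicit integer seeds (numpy Generators
  or `random.Random`); identical configurations give byte-identical
  outputs.
* Ties in greedy stepwise addition and hill climbing break toward the
  first candidate in a deterministic enumeration order.
* Matrices with fewer than two taxa, duplicate taxa or labels, non-binary
  cells, or leaf/taxon mismatches are rejected with named errors; an
  all-uninformative matrix is legal (its optimum is every topology).
* Zero-length branches are rejected by the likelihood (the transition
  matrix would be singular in log space); the parsimony side ignores
  branch lengths entirely.
* Consensus support is reported in percent for bootstrap and as
  probabilities in [0, 1] for posteriors, following each field
  convention.

## Known limitations

Exact search is practical to roughly 12–15 taxa on hard (homoplasy-rich)
matrices, though clean matrices of 24 taxa complete in seconds thanks to
the heuristic upper bound. The Mk sampler is a correctness-first
reference implementation, not a speed-optimised one. `count_events` is a
lower bound by construction. Physical band coordinates, heterochromatin,
NOR and telomeric-repeat features are outside the data model.
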