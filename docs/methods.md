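# Methods

## From complex structures to comparable interfaces

Each binary interaction is represented by one two-chain complex structure
(PDB or mmCIF, read with gemmi; first model only; for alternate
conformations the highest-occupancy location of each atom is kept).
Self-interactions (both chains mapping to the same accession) are rejected.
Because the same protein is numbered differently across structures, every
chain is renumbered to canonical sequence coordinates: the observed chain
sequence is globally aligned to the canonical sequence (match +1, mismatch
−1, gap open −5, gap extend −1) and aligned positions inherit the canonical
1-based index. Residues that cannot be mapped are dropped and logged; a
chain whose mapped region falls below 90% identity to the canonical
sequence is rejected outright — the alignment floor is a package choice,
made to catch mismatched accession/structure pairs rather than to rescue
them. A structure file containing chains that the chain→protein mapping
does not name is likewise rejected rather than silently subset.

Interface residues follow two definitions. Under `cbeta_7p5` each residue
is represented by its Cβ atom (Cα for glycine; when a non-glycine residue
lacks a Cβ in the model, its Cα is used and a warning logged) and
qualifies when that atom is *strictly* closer than 7.5 Å to some
representative atom of the other chain. Under `heavy_4p0` all non-hydrogen
atoms count (hydrogens are excluded by element symbol) and the 4.0 Å bound
is inclusive. The strict/inclusive readings follow the wording of the two
definitions ("less than" vs "no more than"); both boundaries are covered by
explicit tests at 7.4/7.5/7.6 and 3.9/4.0/4.1 Å.

Interface burial is quantified with the Shrake–Rupley numerical ASA
(biotite's implementation, probe radius 1.4 Å, 960 sphere points by
default, element-based van der Waals radii). ΔASA = ASA(chains isolated) −
ASA(complex), summed over both chains, so each interaction edge carries one
strength value. Tests check the isolated-atom closed form 4π(r+1.4)², the
zero-burial case, and a two-atom configuration against an independent
100 000-point spherical integration.

## Network assembly

For every common protein, each pair of its partners with non-empty
recorded interfaces is compared by Jaccard similarity of their interface
residue sets on that common protein; a partner whose extracted interface is
empty contributes no evidence for that common protein (an unobserved
interface cannot be compared — if no evidence remains anywhere, the pair
gets no edge). The pair's edge takes the maximum Jaccard over all shared
common proteins, is labelled competitive iff that maximum is ≥ the
threshold (default 0.1, exposed as a parameter), and keeps the full
evidence list. Edges are unweighted for topology; the maximal Jaccard is an
attribute only. Identifiers are opaque strings compared exactly.

Species-specific proteins are the focal-network proteins carrying at least
one domain that occurs in no reference-network protein (domain tables are
plain two-column TSVs; Pfam- or PANTHER-style identifiers are equally
acceptable since only exact identity matters). The *basic* network is the
induced subgraph after removing them, with newly isolated nodes dropped.

## Topology

Hubs are the nodes at the top `hub_fraction` (default 0.2) of the degree
distribution; the cutoff is the degree at rank ⌈fraction·N⌉ and all ties at
the cutoff are included, so equal degrees are never split arbitrarily.
Categories use the competitive-edge fraction with the modest band as the
closed interval [1/3, 2/3] — the three bands then tile [0,1] exactly.
The clustering coefficient optionally restricts both the neighbourhood and
the neighbour–neighbour edges to one edge colour; the main analysis uses
both colours.

The degree distribution is fit to P(k) = a·k^(−γ) by least squares on
(log k, log P(k)) over degrees with non-zero frequency, reported with r².
Log–log least squares was chosen as the default over maximum likelihood
because the quantity of interest here is the printed (a, γ) pair of a
tabulated distribution, not a tail estimate.

MCL is implemented directly (no packaged implementation of the algorithm is
available in the environment): per connected component, the column-
stochastic transition matrix with unit self-loops is alternately squared
(expansion) and elementwise raised to the inflation power with column
renormalisation (inflation, default 2.0), pruning entries below 1e−6, until
the matrix changes by less than 1e−8 or 200 iterations. Clusters are read
off the attractor rows; attractor systems are merged, and any node
supported by several attractors goes to the one granting it the largest
mass (ties to the lowest module index). The procedure is seedless and
deterministic; the graph is treated as unweighted. Modules of at most
`min_module_size` (default 4) nodes are flagged as not retained.

The participation coefficient p_i = 1 − Σ_s (k_is/k_i)² is computed after
removing non-retained modules; neighbours in removed modules are excluded
from both k_i and k_is, because the module sum only runs over retained
modules (keeping the full degree instead would make p_i depend on links
whose modules no longer exist; that variant is deliberately not offered).
A node whose own module was removed, or with no neighbour in a retained
module, is undefined and excluded from comparisons.

Hub-associated modules are the MCL modules of the competitive subgraph
containing at least one competitive hub; competitive pairs are labelled
intra-module (both ends in the same hub-associated module), inter-module
(exactly one end in a hub-associated module, the other elsewhere), or left
unlabelled.

## Statistics

All tests are one-tailed with directions fixed a priori by the claim being
tested. Fisher's exact test delegates to scipy. The Wilcoxon rank-sum test
enumerates all label assignments of the pooled midranks exactly when the
pooled sample size is ≤ 12 (exact even under ties), and otherwise uses the
normal approximation with tie correction and continuity correction; the
switch point trades exactness against runtime and is tested for agreement
with full enumeration on one side and the asymptotic mode on the other.
Pairwise sequence identity uses the same global alignment scoring as the
renumbering step (the scheme is a package choice and configurable) with
identity = identical columns / alignment length including gaps.

## Regulation analyses

Protein-pair expression correlation maps each protein to its gene IDs
(one-to-many allowed) and averages the available gene-pair PCCs; pairs with
no available value are excluded, never imputed. The competitive-vs-
cooperative PCC comparison reports the one-tailed rank-sum p and both
medians. Isoform enrichment builds the 2×2 table (isoform count > 1 vs = 1;
specific vs non-specific) and tests enrichment of multi-isoform proteins
among the specific group. The fraction of annotated residues within
interaction domains is a residue-level interval intersection.

The competition-strength scan ranks competitive edges by mean ΔASA of the
two competitor–common-protein interactions, where the common protein is the
one behind the edge's maximal Jaccard (consistent with the edge's assigned
similarity; averaging over all evidence is available as an option). For
each removal fraction f in {0, 0.1, …, 0.9} the ⌊f·n⌉ weakest edges are
dropped, the specific proteins still incident to a competitive edge are
re-collected, and the enrichment test re-run against the unchanged
non-specific group; the resulting p-value trajectory is reported without
asserting monotonicity. At f = 1 the scan reports an undefined point.

## Synthetic data: what it emulates and what it does not

The generators produce every input class with recorded ground truth under
one seed (NumPy `default_rng`; identical configs give byte-identical
files).

*Toy complexes* place one Cβ pseudo-atom per residue on a 10 Å grid, with
planted contact pairs moved to a configurable contact distance (6.5 Å for
the Cβ definition, 3.9 Å to satisfy both definitions) while all other
inter-chain pairs stay ≥ 10 Å apart — extraction must recover exactly the
planted pairs. *Interactomes* plant competitive cliques: each of 4 clusters
has 8 partners sharing a core interface on one common protein (pairwise
Jaccard from {0.3, 0.5}, via core size c = 2pJ/(1−J) with p = 4 private
residues each), designated cooperative hubs reach the same degree through
disjoint-interface pairings spread over 7 common proteins, a Poisson(1)
number of extra cooperative contacts per clique member adds noise, and 30
background common proteins contribute degree-1 cooperative pairs. These
counts were chosen so that hubs (top 20% with ties) are exactly the planted
clique members plus the designated cooperative hubs. *Expression* gives
each pair-group a shared latent factor: x_i = √ρ·f_g + √(1−ρ)·ε_i, so
within-group pairs correlate at ρ (0.1 competitive, 0.5 cooperative —
mirroring the observed yeast medians; 100 samples). The shared-factor
construction guarantees a valid joint distribution at any scale but is
exact only when labelled pairs are disjoint; the benchmark uses disjoint
pairs (200 per class). *Annotations* plant 5 specific domains on a
designated 20% of nodes, cycle the shared domains through the reference
set so every shared domain genuinely occurs there, and draw isoform counts
with multi-isoform rates 0.7 (specific) vs 0.5 (non-specific), echoing the
published table's proportions.

None of this emulates real protein geometry, sequence evolution, assortative
degree structure, or annotation noise. Passing the recovery benchmarks
therefore shows that the pipeline's inference is correct when its model
assumptions hold exactly — not that the biological conclusions would
survive noisy structures or incomplete annotation, which is why the
published contingency tables are re-tested directly from their counts.

## Problem sizes and numerics

The benchmark network has ~160 proteins and ~200 edges; recovery rates use
100 seeded replicates per signal. These sizes keep every analysis script
and the full test suite in the seconds-to-a-minute range while leaving all
statistical comparisons well-powered (the planted effects are detected in
100/100 replicates). ASA uses 960 sphere points by default (≈1% accuracy
against a 10⁵-point reference); interface extraction is exact arithmetic on
coordinates. Degenerate inputs — empty interface sets, all-zero
contingency tables, zero-variance expression, empty domain unions — raise
errors or return flagged undefined values rather than guessing.

## Known limitations

* MCL cluster extraction resolves overlapping attractor support by largest
  mass; pathological near-ties could flip a node between modules across
  platforms, though the pruning and convergence thresholds make this
  unlikely at these sizes.
* The published extreme rank-sum p-values (down to ~10⁻⁵⁷) are reachable
  only through the asymptotic approximation; exact enumeration is
  restricted to pooled n ≤ 12.
* The strength scan filters only the specific group by remaining
  competition, leaving the non-specific comparison group unchanged; the
  alternative (filtering both) is a one-line change but alters the
  hypothesis being tested.
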