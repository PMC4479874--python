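# ccrn — competition–cooperation relationship networks

When several proteins bind the same partner, a binary protein–protein
interaction (PPI) network cannot say whether they do so simultaneously.
With a *structural* interactome — one representative complex structure per
interaction — the question becomes geometric: two partners of a common
protein either occupy overlapping interfaces (they **compete**) or distinct
ones (they can **cooperate**). This package builds the resulting bicolor
*competition–cooperation relationship network* (CCRN) and runs the
topological and regulatory analyses that characterise it. It is aimed at
computational/systems biologists working with structural interactome data
(Interactome3D-style inputs) or wanting a fully synthetic, ground-truthed
testbed for interface-overlap analyses.

## The model

For each binary interaction, **interface residues** are extracted from the
complex structure under one of two definitions:

* `cbeta_7p5` — a residue is at the interface when its Cβ atom (Cα for
  glycine) lies strictly within 7.5 Å of some Cβ/Cα of the partner chain;
* `heavy_4p0` — any heavy atom within 4.0 Å of a partner heavy atom.

Residue numbering is unified to canonical (UniProt-style) coordinates by
global pairwise alignment, so interfaces from different structures of the
same protein are comparable. For two partners *B*, *C* of a common protein
*A*, with interface residue sets *I(BA)*, *I(CA)* on *A*, the Jaccard
interface similarity is

    J = |I(BA) ∩ I(CA)| / |I(BA) ∪ I(CA)|

and the pair is **competitive** iff max *J* over all shared common proteins
is ≥ 0.1 (a threshold above zero absorbs marginal overlaps from modelling
artifacts), otherwise **cooperative**.

On the CCRN, **hubs** (top 20% of the degree distribution, ties included)
are classified by their fraction *f* of competitive incident edges:
cooperative (*f* < 1/3), modest (1/3 ≤ *f* ≤ 2/3), competitive (*f* > 2/3).
Their neighbourhood texture is measured by the clustering coefficient
c\_i = 2e\_i / (k\_i(k\_i−1)) and, after Markov clustering (MCL, inflation
2.0) of the largest connected component and removal of modules of ≤ 4
nodes, by the participation coefficient p\_i = 1 − Σ\_s (k\_is/k\_i)².
Regulatory analyses compare expression correlations (PCC) of competitive vs
cooperative pairs, isoform counts of species-specific vs non-specific
proteins (one-tailed Fisher's exact test), and re-run the enrichment while
progressively removing weak competitive edges ranked by interface burial
(ΔASA = ASA\_unbound − ASA\_bound, Shrake–Rupley).

## Worked example

The `analysis/` scripts run the full study on a synthetic benchmark with
known ground truth (planted competitive cliques around designated hubs,
planted expression correlations 0.1/0.5, planted species-specific domains):

```bash
python analysis/01_simulate.py            # writes scratch/synthetic/
python analysis/02_build_network.py
python analysis/03_hub_topology.py
python analysis/04_regulation.py
python analysis/05_published_tables.py
python analysis/06_recovery_benchmarks.py
```

`02_build_network.py` prints, among others:

```
                      quantity    value
                    n_proteins 159.0000
           n_competitive_edges 112.0000
           n_cooperative_edges  93.0000
edge_label_mismatches_vs_truth   0.0000
```

— the rebuilt bicolor network matches every planted edge label. Then
`03_hub_topology.py` reports

```
36 hubs: 32 competitive, 4 cooperative
clustering coefficients, competitive vs cooperative hubs: one-tailed rank-sum p = 0.00045
```

(the planted competitive cliques give competitive hubs near-maximal
clustering, cooperative hubs spread their links), and `04_regulation.py`

```
median PCC: competitive 0.139 vs cooperative 0.422 (one-tailed rank-sum p = 2.03e-12)
```

recovering the planted transcriptional divergence of competitive pairs.
`05_published_tables.py` reruns the one-tailed Fisher's exact tests on the
published hub-essentiality and isoform contingency tables:

```
yeast_essential_in_cooperative_hubs: p = 3.6e-04
human_essential_in_cooperative_hubs: p = 4.4e-05
human_specific_multi_isoform: p = 7.2e-03
```

A `ccrn` command-line tool exposes the same steps
(`ccrn simulate`, `ccrn build-ccrn`, `ccrn topology`, `ccrn full`).

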