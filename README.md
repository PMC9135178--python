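# metnc

Rule-based prediction and ranking of *in vivo* metabolites of natural
compounds.

Natural compounds from medicinal plants are transformed *in vivo* by a messy
mixture of liver enzymes, gastric chemistry and gut microbiota, and the
products — deglycosylated aglycones, hydrolysates, oxidation products — are
often the actual bioactive or blood-accessible species. Identifying them
experimentally requires reference standards for every candidate, so a ranked
shortlist of *likely* metabolites is valuable before any LC-MS work starts.
`metnc` produces that shortlist for an input structure with a three-layer,
fully deterministic pipeline:

1. **Generation** — enzyme-free biotransformation rules, written as reaction
   SMARTS and bucketed into eight functional-group categories (*alcohols,
   alkanes, alkenes, amines, aromatics, esters, ethers, others*), are applied
   at every matching site of the parent; multi-fragment products are split
   and the pool deduplicated by stereo-stripped canonical SMILES.
2. **Priority ranking** — candidates are ordered by their producing rule's
   category under a priority permutation of the eight labels. The shipped
   default, `esters > ethers > aromatics > others > amines > alkanes >
   alkenes > alcohols`, is the optimum found by exhaustively scoring all
   8! = 40,320 permutations on training pairs; the search is part of the
   package (`optimize_order`).
3. **Steric fine sort** — within a priority tier, candidates are sorted by a
   topological steric-hindrance score of the reaction site,
   Σ 1/(d+1) over heavy atoms within 3 bonds of the site, so less hindered
   sites rank first. The top 50 candidates are returned.

Predictions over a substrate–metabolite pair dataset are scored with

    CS = 100 · C · S,   C = n_hit / n_total,   S = (1/n) Σᵢ 1/Orderᵢ

where C is coverage (fraction of known metabolites recovered anywhere in the
list) and S is sorting ability (mean reciprocal rank of the recovered
metabolites). CS ranges 0–100 and is 100 exactly when every known metabolite
is ranked first.

## Worked example

```sh
$ metnc predict --smiles "CCOC(C)=O"
parent_id,rank,product_smiles,rule_id,category,site_atoms,steric_score,provenance_count
mol1,1,CC(=O)O,E01,esters,1;2;3;5,1.0,1
mol1,2,CCO,E01,esters,1;2;3;5,1.0,1
mol1,3,CC(=O)OCCO,N01,alkanes,0,1.0833333333333333,1
mol1,4,CCOC(=O)CO,N01,alkanes,4,1.4166666666666665,1
```

Ethyl acetate's ester bond is cleaved by rule E01, and both hydrolysis
fragments (acetic acid, ethanol) outrank the alkane-hydroxylation decoys
because *esters* leads the default priority order; within the ester tier the
two fragments share a reaction site (identical steric score 1.0) and are
ordered by canonical SMILES.

Evaluating the built-in curated panel (18 pairs, ≥ 2 per category, each
metabolite reachable by exactly one shipped rule):

```sh
$ metnc evaluate --out eval.json
n=18 hits=18 C=1.0000 S=0.3927 CS=39.27
```

Coverage 1.0 confirms closure (every curated metabolite is generated and
ranked within the Top-50); S < 1 reflects decoy candidates outranking some
true metabolites. Other entry points: `metnc optimize-order` (exhaustive or
seeded-sample priority search), `metnc make-fixture` (planted-truth
datasets), `metnc rules validate`, and `metnc evaluate --ranklist` to score
any external tool's rank lists with the same CS metric.

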