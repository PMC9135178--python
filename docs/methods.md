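# Methods

## Model

`metnc` treats *in vivo* biotransformation of a natural compound as a
one-step application of enzyme-free reaction rules followed by a ranking
heuristic. The assumptions, in decreasing order of importance:

* **Transformations are local and organ-agnostic.** Each rule is a reaction
  SMARTS describing a bond edit (hydrolysis, cleavage, oxidation,
  reduction, conjugation) without reference to the enzyme or compartment
  that performs it. This fits the observation that natural-compound
  metabolism data rarely resolve the catalyst (liver CYPs vs. gut
  microbiota vs. gastric chemistry), and it is what lets a small rule set
  cover microbiota-mediated reactions such as deglycosylation.
* **One metabolic step.** The candidate pool is generated once and ranked;
  no iteration. `generate_candidates(depth=n)` exists for multi-step
  exploration but the shipped pipeline, tests and metrics all use depth 1.
* **Reactivity is governed by functional-group class first, site crowding
  second.** The category of the *producing rule* (not of the product)
  determines the coarse rank; a topological steric score refines it.

### Identity

All equality decisions use the stereo-stripped canonical SMILES of the
sanitised structure (`Molecule.canonical_key`). Literature metabolite
records frequently omit stereocentres, so stereo-aware matching would turn
transcription noise into false misses. Multi-fragment products are split and
each organic fragment with ≥ 2 heavy atoms becomes its own candidate;
smaller fragments (water, CO₂) are leaving groups, not metabolites. A hit on
*either* fragment of a cleavage counts, since pair datasets record one
metabolite per substrate and do not say which fragment was observed.

### Steric-hindrance score

The published description of the fine sort is a figure-only pseudocode; the
concrete descriptor here is this package's own reconstruction and is the
simplest scheme with the properties the sort needs:

    score(site) = Σ_{a ∉ site, d(a, site) ≤ radius} weight(d),
    d = topological (bond-count) distance to the nearest site atom,
    radius = 3, weight(d) = 1/(d+1).

It is deterministic, renumbering-invariant (graph distances only), cheap,
and hand-verifiable: a hydroxyl site scores 0.5 in methanol, 0.8333… in
ethanol and 1.5 in tert-butanol, separating primary/secondary/tertiary
environments. Radius 3 is the smallest neighbourhood that does so; both
`radius` and `weight` are arguments of `steric_hindrance_score`. It is a 2D
surrogate: it knows nothing about conformers, Taft parameters or through-
space contacts.

### Ranking and tie-breaks

Final order = stable sort by (category priority, steric score, canonical
key), truncated to `top_k = 50`, the recommended shortlist length. The
lexicographic third key is not chemistry — it exists so that identical
inputs always produce byte-identical outputs. The steric sort is applied
across the whole category tier, not only among same-formula isomers;
`rank_candidates` operates on whatever pool it is given, so an isomer-only
variant can be built by pre-grouping, but the tier-wide sort is the default
because it needs no extra convention for mixed-formula tiers.

When two rules produce the same structure, the retained provenance is the
rule whose category ranks highest under the active order (ties: smaller
rule id, then smaller site tuple), and `provenance_count` records the
multiplicity. This matters: a product reachable through both an ester and
an ether rule is ranked as an ester product under the default order.

## Evaluation metric

CS = 100·C·S combines coverage C = n_hit/n_total with sorting ability
S = (1/n)Σ 1/Orderᵢ. The denominator n of S is ambiguous when some
metabolites are missed; this package defaults to **hits only** (misses
already penalise C, and Orderᵢ does not exist for a miss) and exposes
`s_denominator="all"` for the alternative reading. A known metabolite
outside the Top-K list is a miss. Rank-distribution comparisons between two
priority orders use a two-sample Student's t-test on per-pair reciprocal
ranks with misses encoded as 0; when both samples are constant the
degenerate cases are reported explicitly as (0, 1) or (±inf, 0) instead of
NaN.

## Priority-order optimisation

All 8! = 40,320 permutations of the category labels are enumerated
lexicographically. Candidate pools do not depend on the order, so the
optimiser generates each substrate's pool once and re-ranks it per
permutation with vectorised rank arithmetic (counting candidates ahead of
the hit instead of sorting); the test suite pins this fast path to naive
per-order re-prediction. Objectives: `cs` (default) and `top1`; the
selection criterion behind the shipped default order is not documented
beyond "optimal", so both are offered. Ties break toward the
lexicographically smallest order, which the enumeration sweep gives for
free. A seeded `sample=N` mode evaluates a random subset for quick runs.

## Shipped rule set

`data/default_rules.yaml` holds 15 curated rules spanning all eight
categories (hydrolyses, ether/glycoside cleavage, aromatic and aliphatic
hydroxylation, alkene reduction/hydration, alcohol oxidations,
glucuronidation, N-demethylation/acetylation, ketone reduction, amide
hydrolysis, decarboxylation). It is a representative working set, not an
exhaustive catalogue of in vivo chemistry; the loader accepts any YAML/TSV
rule file in the same schema, so larger curated sets drop in without code
changes. Categories are assigned by the curator in the rule file — e.g.
glucuronidation acts on hydroxyls and is filed under *alcohols* even when
it fires on a phenol.

## Synthetic data

Two generators stand in for curated substrate–metabolite data:

* the **toy panel** (18 hand-curated pairs, ≥ 2 per category, each
  metabolite reachable by exactly one shipped rule) proves closure of the
  whole pipeline;
* the **randomized generator** samples scaffolds from ~30 embedded
  natural-product-like motifs in shuffled round-robin cycles per category
  (so decoy chemistry stays balanced at any size and seed), applies a
  seeded-random rule of the requested category, and plants the rule's
  *principal product* — the candidate the ranker would list first within
  that rule's own products (minimal steric score, then canonical key) — as
  the known metabolite. Planting the principal product makes rank-recovery
  well-defined: when the planted category leads the priority order, the
  planted metabolite is the Top-1 candidate, so the order optimiser must
  recover the planted category in first position.

What these fixtures do **not** emulate: the molecular weight and polycyclic
complexity of real herbal ingredients, multi-step metabolism, noisy or
stereo-inconsistent literature SMILES, and reactions outside the shipped
rule set. Passing closure tests therefore demonstrates machinery
correctness, not real-world coverage; on real data coverage is bounded by
how much chemistry the rule file encodes.

## Problem sizes and defaults

| parameter | default | meaning |
|---|---|---|
| `top_k` | 50 | shortlist length; hits below it are misses |
| `steric.radius` | 3 bonds | neighbourhood of the steric score |
| `steric.weight` | 1/(d+1) | distance decay of the steric score |
| `s_denominator` | `hits` | denominator convention of S |
| planted dataset | 50 pairs | size used by tests and the acceptance script |
| order search | 40,320 orders | always exhaustive unless `sample` is set |

The planted-truth experiments use 50 pairs with a 100 %-ester mix: large
enough that every ester scaffold (and hence every decoy category) appears
several times per dataset, small enough that the exhaustive order search
over all 40,320 permutations completes in seconds with the cached
re-ranking path.

## Known limitations

* Reaction SMARTS are applied without feasibility modelling; implausible
  products are only demoted by ranking, never filtered.
* The steric descriptor is topological; conformational shielding and
  through-space effects are invisible to it.
* Category masking rules (ester oxygen never an ether; amide nitrogen never
  an amine; "alkanes" requires a C–H with no heteroatom within two bonds)
  are pattern conventions of this package, documented in `chem.py`, and
  other reasonable conventions exist.
* Fragments below two heavy atoms are unconditionally discarded as leaving
  groups, so single-heavy-atom metabolites (methane, CO₂) are never
  reported; cleavages are credited through the retained fragment(s).
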