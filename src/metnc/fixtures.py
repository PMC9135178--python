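"""Self-contained toy datasets with planted ground truth.

Two generators back the test and benchmark harnesses without any download:

* :func:`builtin_toy_pairs` — a hand-curated panel of substrate/metabolite
  pairs, at least two per functional-group category, each metabolite
  reachable through exactly one shipped rule (the phenyl-glucoside → phenol
  pair is a miniature of the classic microbiota deglycosylation of plant
  O-glycosides).
* :func:`make_randomized_dataset` — seeded sampling from an embedded
  scaffold library: a rule of the requested category is applied to a
  scaffold and its principal product recorded as the "known" metabolite, so
  recovery of the planted answer (and of the planted category priority) is
  guaranteed by construction.

The scaffolds are deliberately small natural-product-like motifs (aryl
glycoside, flavanone-like ketones, terpenoid fragments, benzylamines); what
they do not emulate is the polycyclic complexity and molecular weight of
real herbal ingredients, so closure results here say the machinery is
correct, not that real-world coverage is high.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .chem import Molecule, RuleSet, parse_molecule
from .evaluation import Pair, PairDataset
from .generation import apply_rule
from .ranking import steric_hindrance_score


class ScaffoldExhausted(RuntimeError):
    """No embedded scaffold supports the requested category mix."""


# substrate_id, substrate, metabolite, producing rule (recorded as evidence)
_TOY_PAIRS: list[tuple[str, str, str, str]] = [
    # esters
    ("toy01", "CCOC(C)=O", "CC(=O)O", "E01 ester hydrolysis"),
    ("toy02", "CC(=O)Oc1ccccc1C(=O)O", "O=C(O)c1ccccc1O", "E01 ester hydrolysis"),
    # ethers (glycosidic and aryl-alkyl)
    ("toy03", "OCC1OC(Oc2ccccc2)C(O)C(O)C1O", "Oc1ccccc1", "T01 ether cleavage"),
    ("toy04", "COc1ccc2ccccc2c1", "Oc1ccc2ccccc2c1", "T01 ether cleavage"),
    # aromatics
    ("toy05", "c1ccc2ccccc2c1", "Oc1cccc2ccccc12", "A01 aromatic hydroxylation"),
    ("toy06", "c1ccc(-c2ccccc2)cc1", "Oc1ccc(-c2ccccc2)cc1", "A01 aromatic hydroxylation"),
    # alkenes
    ("toy07", "C=Cc1ccccc1", "CCc1ccccc1", "K01 alkene reduction"),
    ("toy08", "C=CCc1ccccc1", "OCCCc1ccccc1", "K02 alkene hydration"),
    # amines
    ("toy09", "CN(C)Cc1ccccc1", "CNCc1ccccc1", "M01 N-demethylation"),
    ("toy10", "NCCc1ccccc1", "CC(=O)NCCc1ccccc1", "M02 N-acetylation"),
    # alkanes
    ("toy11", "Cc1ccc(C(C)C)cc1", "OCc1ccc(C(C)C)cc1", "N01 methyl hydroxylation"),
    ("toy12", "CCCCc1ccccc1", "CCC(O)Cc1ccccc1", "N02 methylene hydroxylation"),
    # alcohols
    ("toy13", "OCc1ccccc1", "O=C(O)c1ccccc1", "L01 primary alcohol oxidation"),
    ("toy14", "CC(O)c1ccccc1", "CC(=O)c1ccccc1", "L02 secondary alcohol oxidation"),
    ("toy15", "Oc1ccc2ccccc2c1", "O=C(O)C1OC(Oc2ccc3ccccc3c2)C(O)C(O)C1O", "L03 glucuronidation"),
    # others
    ("toy16", "CC(=O)c1ccccc1", "CC(O)c1ccccc1", "O01 ketone reduction"),
    ("toy17", "O=C1CCCCC1", "OC1CCCCC1", "O01 ketone reduction"),
    ("toy18", "CC(=O)Nc1ccccc1", "Nc1ccccc1", "O02 amide hydrolysis"),
]


def builtin_toy_pairs() -> PairDataset:
    """The curated, repo-embedded substrate-metabolite panel (two+ per category)."""
    pairs = [
        Pair(
            substrate_id=pid,
            substrate=parse_molecule(substrate),
            metabolite=parse_molecule(metabolite),
            evidence=evidence,
        )
        for pid, substrate, metabolite, evidence in _TOY_PAIRS
    ]
    return PairDataset(pairs=pairs, source_path=None)


#: Embedded scaffold library: simple natural-product-like motifs chosen so
#: every category's rules find substrates and every substrate offers decoy
#: sites for several other categories.
SCAFFOLDS: tuple[str, ...] = (
    # ester-bearing (each also carries at least one decoy functionality)
    "CCOC(C)=O",                  # ethyl acetate (alkane decoys)
    "C=CCOC(C)=O",                # allyl acetate (alkene decoys)
    "CC(=O)Oc1ccccc1",            # phenyl acetate (aromatic decoys)
    "CC(=O)Oc1ccccc1C(=O)O",      # aspirin (aromatic + acid decoys)
    "COCCOC(C)=O",                # 2-methoxyethyl acetate (ether decoys)
    "CC(=O)CCCOC(C)=O",           # 4-oxopentyl acetate (ketone decoys)
    "CN(C)CCOC(C)=O",             # dimethylaminoethyl acetate (amine decoys)
    "CCOC(=O)CO",                 # ethyl glycolate (alcohol decoys)
    "COC(=O)c1ccccc1",            # methyl benzoate (aromatic decoys)
    "CC(=O)OCc1ccccc1",           # benzyl acetate (aromatic decoys)
    # ethers / glycosides
    "COc1ccccc1",                 # anisole
    "CCOc1ccccc1",                # phenetole
    "OCC1OC(Oc2ccccc2)C(O)C(O)C1O",  # phenyl glucoside
    "COc1ccc(C)cc1",              # 4-methylanisole
    # aromatics
    "c1ccc2ccccc2c1",             # naphthalene
    "Cc1ccccc1",                  # toluene
    "c1ccc(-c2ccccc2)cc1",        # biphenyl
    # alkenes
    "C=Cc1ccccc1",                # styrene
    "C=CCc1ccccc1",               # allylbenzene
    "CC1=CCC(C(C)=C)CC1",         # limonene
    # amines
    "CNc1ccccc1",                 # N-methylaniline
    "CN(C)Cc1ccccc1",             # N,N-dimethylbenzylamine
    "CC(N)Cc1ccccc1",             # amphetamine-like amine
    # alkanes
    "CCCCc1ccccc1",               # butylbenzene
    "Cc1ccc(C(C)C)cc1",           # p-cymene
    "C1CCC2CCCCC2C1",             # decalin
    # alcohols
    "OCc1ccccc1",                 # benzyl alcohol
    "CC(O)c1ccccc1",              # 1-phenylethanol
    "CC(C)C1CCC(C)CC1O",          # menthol-like cyclohexanol
    # ketones / amides ("others" substrates)
    "CC(=O)c1ccccc1",             # acetophenone
    "O=C1CCCCC1",                 # cyclohexanone
    "CC(=O)Nc1ccccc1",            # acetanilide
)


@dataclass
class FixtureSpec:
    """Parameters of a randomized planted-truth dataset."""

    seed: int
    n_pairs: int
    #: proportions per category label; must sum to 1
    category_mix: dict[str, float]
    #: scaffolds qualify only if, beyond the planting rule, at least this
    #: many other rules apply (so decoy candidates exist by construction)
    decoy_rules_per_pair: int = 1

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        total = sum(self.category_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category_mix proportions must sum to 1, got {total}")


def _category_counts(spec: FixtureSpec) -> dict[str, int]:
    """Largest-remainder apportionment of n_pairs over the category mix."""
    raw = {c: p * spec.n_pairs for c, p in spec.category_mix.items()}
    counts = {c: int(v) for c, v in raw.items()}
    short = spec.n_pairs - sum(counts.values())
    for c in sorted(raw, key=lambda c: raw[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    return counts


def _principal_product(parent: Molecule, candidates) -> Molecule:
    """The candidate a ranked prediction would list first within one rule's
    products: minimal (steric score, canonical key)."""
    scored = [
        (steric_hindrance_score(parent, c.site_atoms), c.canonical_key, c)
        for c in candidates
    ]
    return min(scored)[2].product


def make_randomized_dataset(spec: FixtureSpec, rules: RuleSet) -> PairDataset:
    """Build a planted-truth dataset: per pair, pick a scaffold, apply a rule
    of the requested category, and record its principal product as the known
    metabolite. Deterministic for a given seed.

    Scaffolds are consumed in shuffled round-robin cycles per category, so
    every eligible scaffold appears once per cycle; this keeps the decoy
    chemistry balanced at any dataset size.
    """
    if len(rules) == 0:
        raise ValueError("rules must be non-empty")
    rng = random.Random(spec.seed)
    scaffolds = [parse_molecule(s) for s in SCAFFOLDS]

    # eligibility: scaffold supports >=1 rule of the category and enough decoys
    eligible: dict[str, list[tuple[Molecule, list]]] = {}
    for category in spec.category_mix:
        rows = []
        for scaffold in scaffolds:
            matching = [r for r in rules if r.category == category and apply_rule(scaffold, r)]
            decoys = [
                r
                for r in rules
                if r.category != category and apply_rule(scaffold, r)
            ]
            if matching and len(decoys) >= spec.decoy_rules_per_pair:
                rows.append((scaffold, matching))
        if not rows:
            raise ScaffoldExhausted(
                f"no embedded scaffold supports category {category!r} "
                f"with {spec.decoy_rules_per_pair} decoy rule(s)"
            )
        eligible[category] = rows

    pairs: list[Pair] = []
    counts = _category_counts(spec)
    serial = 0
    for category in sorted(counts):
        rows = eligible[category]
        cycle: list[int] = []
        for _ in range(counts[category]):
            if not cycle:
                cycle = list(range(len(rows)))
                rng.shuffle(cycle)
            scaffold, matching = rows[cycle.pop()]
            rule = rng.choice(matching)
            metabolite = _principal_product(scaffold, apply_rule(scaffold, rule))
            serial += 1
            pairs.append(
                Pair(
                    substrate_id=f"fx{serial:03d}",
                    substrate=scaffold,
                    metabolite=metabolite,
                    evidence=f"planted:{rule.rule_id}",
                )
            )
    return PairDataset(pairs=pairs, source_path=None)
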