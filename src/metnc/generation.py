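"""Candidate metabolite generation: apply reaction rules to a parent structure.

One metabolic step applies every rule at every matching site, splits
multi-fragment products, and pools the results. Deduplication is two-level:

* within one rule, candidates are unique per ``(product key, site atoms)``;
* across rules, candidates are unique per product key, and the retained
  provenance is the rule whose category ranks highest under the active group
  order (ties broken by rule id, then by site), with ``provenance_count``
  recording how many rule applications produced the structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from rdkit import Chem

from .chem import Molecule, ReactionRule, RuleSet, parse_molecule

logger = logging.getLogger(__name__)

#: Fragments below this heavy-atom count (water, halides...) are discarded as
#: leaving groups rather than reported as metabolites.
MIN_FRAGMENT_HEAVY_ATOMS = 2


@dataclass
class CandidateMetabolite:
    """A generated product with provenance back to the producing rule and site."""

    product: Molecule
    rule_id: str
    category: str
    site_atoms: tuple[int, ...]
    steric_score: float | None = None
    provenance_count: int = 1
    #: molecule the site indices refer to (differs from the root parent only
    #: for multi-step generation)
    parent: Molecule | None = field(default=None, repr=False)

    @property
    def canonical_key(self) -> str:
        return self.product.canonical_key


def _is_organic(frag: Chem.Mol) -> bool:
    return any(atom.GetAtomicNum() == 6 for atom in frag.GetAtoms())


def apply_rule(parent: Molecule, rule: ReactionRule) -> list[CandidateMetabolite]:
    """Apply one rule at every matching site of ``parent``.

    Returns one candidate per distinct ``(product key, site)``. Multi-fragment
    products are split; each organic fragment with at least
    :data:`MIN_FRAGMENT_HEAVY_ATOMS` heavy atoms becomes its own candidate.
    Identity products and products that fail sanitisation are dropped.
    """
    try:
        product_sets = rule.rxn.RunReactants((parent.mol,))
    except Exception as exc:
        logger.warning("rule %s failed on %s: %s", rule.rule_id, parent.canonical_smiles, exc)
        return []

    seen: dict[tuple[str, tuple[int, ...]], CandidateMetabolite] = {}
    for product_set in product_sets:
        # Site = parent atoms matched by the mapped reactant-template atoms,
        # collected across every product of this one application.
        site: set[int] = set()
        frag_smiles: list[str] = []
        for product in product_set:
            for atom in product.GetAtoms():
                if atom.HasProp("old_mapno") and atom.HasProp("react_atom_idx"):
                    site.add(atom.GetIntProp("react_atom_idx"))
            try:
                Chem.SanitizeMol(product)
            except Exception:
                logger.warning(
                    "rule %s on %s: dropped unsanitisable product",
                    rule.rule_id,
                    parent.canonical_smiles,
                )
                continue
            for frag in Chem.GetMolFrags(product, asMols=True, sanitizeFrags=False):
                if frag.GetNumHeavyAtoms() >= MIN_FRAGMENT_HEAVY_ATOMS and _is_organic(frag):
                    frag_smiles.append(Chem.MolToSmiles(frag))
        site_key = tuple(sorted(site))
        for smiles in frag_smiles:
            try:
                molecule = parse_molecule(smiles)
            except Exception:
                logger.warning(
                    "rule %s on %s: product %r does not re-parse, dropped",
                    rule.rule_id,
                    parent.canonical_smiles,
                    smiles,
                )
                continue
            if molecule.canonical_key == parent.canonical_key:
                continue  # identity product: rule fired but nothing changed
            key = (molecule.canonical_key, site_key)
            if key in seen:
                seen[key].provenance_count += 1
            else:
                seen[key] = CandidateMetabolite(
                    product=molecule,
                    rule_id=rule.rule_id,
                    category=rule.category,
                    site_atoms=site_key,
                    parent=parent,
                )
    return sorted(
        seen.values(), key=lambda c: (c.canonical_key, c.site_atoms)
    )


def generate_candidates(
    parent: Molecule,
    rules: RuleSet | Iterable[ReactionRule],
    order: "Sequence[str] | None" = None,
    depth: int = 1,
) -> list[CandidateMetabolite]:
    """Pool of candidate metabolites for ``parent`` over all rules, deduplicated.

    Parameters
    ----------
    order
        Active group order (sequence of the eight category labels); decides
        which provenance is kept when several rules yield the same structure.
        Defaults to the shipped optimised order.
    depth
        Number of metabolic steps. The default single step mirrors the
        generate-then-rank pipeline; ``depth > 1`` re-applies the rules to
        each product (provenance then points at the intermediate parent).
    """
    from .ranking import DEFAULT_GROUP_ORDER  # local import: no module cycle at import time

    if order is None:
        priority = {c: i for i, c in enumerate(DEFAULT_GROUP_ORDER.sequence)}
    else:
        priority = {c: i for i, c in enumerate(order)}

    pool: dict[str, CandidateMetabolite] = {}

    def provenance_rank(c: CandidateMetabolite) -> tuple:
        return (priority[c.category], c.rule_id, c.site_atoms)

    def absorb(candidates: Iterable[CandidateMetabolite]) -> list[CandidateMetabolite]:
        fresh = []
        for cand in candidates:
            key = cand.canonical_key
            if key == parent.canonical_key:
                continue
            held = pool.get(key)
            if held is None:
                pool[key] = cand
                fresh.append(cand)
            else:
                count = held.provenance_count + cand.provenance_count
                keep = min(held, cand, key=provenance_rank)
                keep.provenance_count = count
                pool[key] = keep
        return fresh

    frontier: list[Molecule] = [parent]
    for _ in range(max(1, depth)):
        produced: list[CandidateMetabolite] = []
        for mol in frontier:
            for rule in rules:
                for cand in apply_rule(mol, rule):
                    produced.append(cand)
        fresh = absorb(produced)
        frontier = [c.product for c in fresh]
        if not frontier:
            break

    return sorted(pool.values(), key=lambda c: c.canonical_key)


def candidates_to_frame(candidates: Sequence[CandidateMetabolite], parent_id: str = ""):
    """Serialise candidates to a DataFrame (CSV layout used by the CLI)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "parent_id": parent_id,
            "rank": range(1, len(candidates) + 1),
            "product_smiles": [c.product.canonical_smiles for c in candidates],
            "rule_id": [c.rule_id for c in candidates],
            "category": [c.category for c in candidates],
            "site_atoms": [";".join(map(str, c.site_atoms)) for c in candidates],
            "steric_score": [c.steric_score for c in candidates],
            "provenance_count": [c.provenance_count for c in candidates],
        }
    )
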