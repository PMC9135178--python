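"""Independent brute-force oracles used to cross-check the rule engine.

Each oracle enumerates substructure matches itself and performs the bond
edits explicitly on an editable molecule — no reaction SMARTS machinery —
so agreement with ``apply_rule`` is a genuine dual-route check.
"""

from itertools import combinations

from rdkit import Chem


def _fragment_keys(mol, min_heavy=2):
    """Stereo-stripped canonical keys of organic fragments of an edited mol."""
    keys = set()
    Chem.SanitizeMol(mol)
    for frag in Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True):
        if frag.GetNumHeavyAtoms() >= min_heavy and any(
            a.GetAtomicNum() == 6 for a in frag.GetAtoms()
        ):
            keys.add(Chem.MolToSmiles(frag, isomericSmiles=False))
    return keys


def ester_hydrolysis_products(smiles: str) -> set[str]:
    """Break every C(=O)O-C ester bond by hand; return product keys."""
    parent = Chem.MolFromSmiles(smiles)
    pattern = Chem.MolFromSmarts("[CX3](=[OX1])[OX2][#6]")
    keys: set[str] = set()
    for acyl_c, _, bridge_o, alkyl_c in parent.GetSubstructMatches(pattern):
        editable = Chem.RWMol(parent)
        editable.RemoveBond(bridge_o, alkyl_c)
        new_o = editable.AddAtom(Chem.Atom(8))
        editable.AddBond(alkyl_c, new_o, Chem.BondType.SINGLE)
        keys |= _fragment_keys(editable.GetMol())
    return keys


def aromatic_hydroxylation_products(smiles: str) -> set[str]:
    """Attach OH at every aromatic CH by hand; return product keys."""
    parent = Chem.MolFromSmiles(smiles)
    pattern = Chem.MolFromSmarts("[cH]")
    keys: set[str] = set()
    for (site,) in parent.GetSubstructMatches(pattern):
        editable = Chem.RWMol(parent)
        new_o = editable.AddAtom(Chem.Atom(8))
        editable.AddBond(site, new_o, Chem.BondType.SINGLE)
        editable.GetAtomWithIdx(site).SetNumExplicitHs(0)
        keys |= _fragment_keys(editable.GetMol())
    return keys


def alkene_reduction_products(smiles: str) -> set[str]:
    """Saturate every non-carbonyl C=C by hand; return product keys."""
    parent = Chem.MolFromSmiles(smiles)
    pattern = Chem.MolFromSmarts("[CX3;!$([CX3]=[OX1])]=[CX3]")
    keys: set[str] = set()
    for a, b in parent.GetSubstructMatches(pattern):
        editable = Chem.RWMol(parent)
        editable.GetBondBetweenAtoms(a, b).SetBondType(Chem.BondType.SINGLE)
        keys |= _fragment_keys(editable.GetMol())
    return keys


def permutation_test_mean_diff(sample_a, sample_b) -> float:
    """Exhaustive two-sided permutation p-value for a difference in means."""
    pooled = list(sample_a) + list(sample_b)
    n_a = len(sample_a)
    observed = abs(sum(sample_a) / n_a - sum(sample_b) / len(sample_b))
    indices = range(len(pooled))
    extreme = 0
    total = 0
    for chosen in combinations(indices, n_a):
        chosen_set = set(chosen)
        group_a = [pooled[i] for i in chosen]
        group_b = [pooled[i] for i in indices if i not in chosen_set]
        diff = abs(sum(group_a) / len(group_a) - sum(group_b) / len(group_b))
        total += 1
        if diff >= observed - 1e-12:
            extreme += 1
    return extreme / total
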