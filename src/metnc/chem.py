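"""Structure parsing, canonical identity, functional-group classification and rule I/O.

All downstream modules treat molecules through the :class:`Molecule` wrapper,
which fixes a single canonicalisation policy:

* ``canonical_smiles`` — RDKit canonical SMILES after sanitisation;
* ``canonical_key`` — the stereo-stripped canonical SMILES, used for every
  equality decision in the package (candidate deduplication, hit matching).

Stereochemistry is deliberately dropped from the identity key because
literature metabolite records frequently omit or garble stereocentres;
matching on the flat graph is the robust convention for this kind of data.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import yaml
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

# RDKit is chatty about every sanitisation failure; product-level failures are
# expected (and handled) when generic transforms hit exotic scaffolds.
RDLogger.DisableLog("rdApp.error")
RDLogger.DisableLog("rdApp.warning")

#: The eight functional-group categories used to bucket reaction rules.
#: The vocabulary is closed: rule files may not introduce other labels.
CATEGORIES: tuple[str, ...] = (
    "alcohols",
    "alkanes",
    "alkenes",
    "amines",
    "aromatics",
    "esters",
    "ethers",
    "others",
)


class InvalidSmiles(ValueError):
    """Raised when a SMILES string cannot be parsed or sanitised."""


class RuleFileError(ValueError):
    """Raised when a rule file violates the schema (first offending record named)."""


@dataclass(frozen=True)
class Molecule:
    """A parsed, sanitised structure with a canonical identity key."""

    input_smiles: str
    canonical_smiles: str
    canonical_key: str
    heavy_atom_count: int
    mol: Chem.Mol = field(repr=False, compare=False)

    def __hash__(self) -> int:  # identity follows the stereo-stripped key
        return hash(self.canonical_key)


def parse_molecule(smiles: str) -> Molecule:
    """Parse and sanitise a SMILES string into a :class:`Molecule`.

    Raises
    ------
    InvalidSmiles
        If the text cannot be parsed or sanitised; the message names the
        offending input.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise InvalidSmiles(f"empty or non-text SMILES input: {smiles!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmiles(f"cannot parse SMILES: {smiles!r}")
    if mol.GetNumHeavyAtoms() < 1:
        raise InvalidSmiles(f"no heavy atoms in SMILES: {smiles!r}")
    return Molecule(
        input_smiles=smiles,
        canonical_smiles=Chem.MolToSmiles(mol),
        canonical_key=Chem.MolToSmiles(mol, isomericSmiles=False),
        heavy_atom_count=mol.GetNumHeavyAtoms(),
        mol=mol,
    )


def canonical_key(mol: Molecule) -> str:
    """Stereo-stripped canonical identifier; equal structures give equal keys."""
    return mol.canonical_key


# One detection pattern per named category.  "others" is the complement: it is
# reported only when none of the seven named chemistries match.
#
# Two masking choices matter:
#  * the bridging oxygen of an ester never counts as an ether (both ether
#    carbons must be non-carbonyl);
#  * "alkanes" means an unfunctionalised sp3 C-H: the carbon carries no
#    heteroatom and none of its carbon neighbours does either, so ethanol is
#    an alcohol, not an alcohol-plus-alkane.
_CATEGORY_SMARTS: dict[str, str] = {
    "alcohols": "[CX4][OX2H]",
    "alkanes": "[CX4;!H0;!$([CX4][!#6;!#1]);!$([CX4][#6][!#6;!#1])]",
    "alkenes": "[CX3]=[CX3]",
    "amines": "[NX3;!$([NX3][CX3]=[OX1]);$([NX3][#6])]",
    "aromatics": "a",
    "esters": "[CX3](=[OX1])[OX2][#6]",
    "ethers": "[#6;!$([CX3]=[OX1])][OX2][#6;!$([CX3]=[OX1])]",
}

_CATEGORY_PATTERNS = {
    label: Chem.MolFromSmarts(smarts) for label, smarts in _CATEGORY_SMARTS.items()
}


def classify_functional_groups(mol: Molecule) -> frozenset[str]:
    """Return every functional-group category whose pattern matches ``mol``.

    ``others`` is returned (alone) only when no named category matches.
    """
    hits = frozenset(
        label
        for label, pattern in _CATEGORY_PATTERNS.items()
        if mol.mol.HasSubstructMatch(pattern)
    )
    return hits if hits else frozenset({"others"})


@dataclass
class ReactionRule:
    """One enzyme-free transformation expressed as a single-reactant reaction SMARTS."""

    rule_id: str
    name: str
    category: str
    reaction_smarts: str
    notes: str = ""
    _rxn: AllChem.ChemicalReaction | None = field(
        default=None, repr=False, compare=False
    )

    @property
    def rxn(self) -> AllChem.ChemicalReaction:
        """The compiled RDKit reaction (compiled once, cached)."""
        if self._rxn is None:
            self._rxn = compile_reaction(self.reaction_smarts)
        return self._rxn


def compile_reaction(reaction_smarts: str) -> AllChem.ChemicalReaction:
    """Compile a reaction SMARTS, requiring exactly one reactant template."""
    try:
        rxn = AllChem.ReactionFromSmarts(reaction_smarts)
    except Exception as exc:  # RDKit raises bare RuntimeError on bad SMARTS
        raise RuleFileError(f"uncompilable reaction SMARTS {reaction_smarts!r}: {exc}")
    if rxn is None:
        raise RuleFileError(f"uncompilable reaction SMARTS {reaction_smarts!r}")
    if rxn.GetNumReactantTemplates() != 1:
        raise RuleFileError(
            f"reaction SMARTS must have exactly one reactant template, got "
            f"{rxn.GetNumReactantTemplates()}: {reaction_smarts!r}"
        )
    rxn.Initialize()
    return rxn


@dataclass
class RuleSet:
    """An ordered, validated collection of :class:`ReactionRule`."""

    rules: list[ReactionRule]
    source_path: str | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rule in self.rules:
            if rule.rule_id in seen:
                raise RuleFileError(f"duplicate rule_id {rule.rule_id!r}")
            seen.add(rule.rule_id)
            if rule.category not in CATEGORIES:
                raise RuleFileError(
                    f"rule {rule.rule_id!r}: unknown category {rule.category!r} "
                    f"(allowed: {', '.join(CATEGORIES)})"
                )

    def __iter__(self) -> Iterator[ReactionRule]:
        return iter(self.rules)

    def __len__(self) -> int:
        return len(self.rules)

    def __getitem__(self, rule_id: str) -> ReactionRule:
        for rule in self.rules:
            if rule.rule_id == rule_id:
                return rule
        raise KeyError(rule_id)

    @property
    def categories(self) -> frozenset[str]:
        return frozenset(rule.category for rule in self.rules)

    def checksum(self) -> str:
        """SHA-256 over the rule records, for provenance stamping of reports."""
        digest = hashlib.sha256()
        for rule in self.rules:
            digest.update(
                "\t".join(
                    [rule.rule_id, rule.name, rule.category, rule.reaction_smarts]
                ).encode()
            )
            digest.update(b"\n")
        return digest.hexdigest()


_RULE_FIELDS = ("rule_id", "name", "category", "reaction_smarts", "notes")


def _rule_from_record(record: dict, where: str) -> ReactionRule:
    missing = [f for f in ("rule_id", "name", "category", "reaction_smarts") if not record.get(f)]
    if missing:
        raise RuleFileError(f"{where}: missing field(s) {', '.join(missing)}")
    rule = ReactionRule(
        rule_id=str(record["rule_id"]),
        name=str(record["name"]),
        category=str(record["category"]),
        reaction_smarts=str(record["reaction_smarts"]),
        notes=str(record.get("notes") or ""),
    )
    if rule.category not in CATEGORIES:
        raise RuleFileError(
            f"{where} (rule {rule.rule_id!r}): unknown category {rule.category!r}"
        )
    try:
        rule.rxn  # compile now so load fails loudly on bad SMARTS
    except RuleFileError as exc:
        raise RuleFileError(f"{where} (rule {rule.rule_id!r}): {exc}")
    return rule


def load_ruleset(path: str | Path) -> RuleSet:
    """Load and validate a rule file (YAML list of records, or TSV with header).

    The schema is ``rule_id, name, category, reaction_smarts[, notes]`` with
    ``category`` drawn from the closed eight-label vocabulary.
    """
    path = Path(path)
    if not path.exists():
        raise RuleFileError(f"rule file not found: {path}")
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() in (".tsv", ".txt", ".tab"):
        records = _parse_tsv_rules(text, path)
    else:
        records = _parse_yaml_rules(text, path)
    rules = [
        _rule_from_record(rec, f"{path.name} record {i + 1}")
        for i, rec in enumerate(records)
    ]
    if not rules:
        raise RuleFileError(f"{path}: no rules found")
    return RuleSet(rules=rules, source_path=str(path))


def _parse_yaml_rules(text: str, path: Path) -> list[dict]:
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise RuleFileError(f"{path}: invalid YAML: {exc}")
    if isinstance(data, dict) and "rules" in data:
        data = data["rules"]
    if not isinstance(data, list):
        raise RuleFileError(f"{path}: expected a YAML list of rule records")
    return data


def _parse_tsv_rules(text: str, path: Path) -> list[dict]:
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise RuleFileError(f"{path}: empty TSV")
    header = lines[0].rstrip("\n").split("\t")
    if header[0] != "rule_id":
        raise RuleFileError(
            f"{path}: TSV header must start with 'rule_id' "
            f"(expected columns {', '.join(_RULE_FIELDS)})"
        )
    records = []
    for ln in lines[1:]:
        values = ln.split("\t")
        records.append(dict(zip(header, values)))
    return records


def save_ruleset(ruleset: RuleSet, path: str | Path) -> None:
    """Serialise a RuleSet back to YAML (round-trips with :func:`load_ruleset`)."""
    records = [
        {
            "rule_id": r.rule_id,
            "name": r.name,
            "category": r.category,
            "reaction_smarts": r.reaction_smarts,
            "notes": r.notes,
        }
        for r in ruleset.rules
    ]
    Path(path).write_text(
        yaml.safe_dump(records, sort_keys=False, allow_unicode=True), encoding="utf-8"
    )


def default_rules_path() -> Path:
    """Path of the curated rule file shipped with the package."""
    return Path(__file__).parent / "data" / "default_rules.yaml"


def default_ruleset() -> RuleSet:
    """The shipped rule set: a curated subset covering all eight categories."""
    return load_ruleset(default_rules_path())


def read_smiles_input(path: str | Path) -> list[tuple[str, str]]:
    """Read a batch input file into ``(id, smiles)`` tuples.

    ``.smi`` files carry one ``SMILES [id]`` per line; ``.csv`` files need
    ``id`` and ``smiles`` columns.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        import pandas as pd

        frame = pd.read_csv(path)
        cols = {c.lower(): c for c in frame.columns}
        if "smiles" not in cols:
            raise InvalidSmiles(f"{path}: CSV input needs a 'smiles' column")
        id_col = cols.get("id")
        out = []
        for i, row in frame.iterrows():
            ident = str(row[id_col]) if id_col else f"mol{i + 1}"
            out.append((ident, str(row[cols["smiles"]])))
        return out
    out = []
    for i, line in enumerate(path.read_text(encoding="utf-8").splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        smiles = parts[0]
        ident = parts[1] if len(parts) > 1 else f"mol{i + 1}"
        out.append((ident, smiles))
    return out
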