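"""Evaluation of metabolite predictions: coverage, sorting ability and CS.

The combined score is

    CS = 100 * C * S

where coverage ``C`` is the fraction of known metabolites recovered anywhere
in the returned Top-K list, and sorting ability ``S`` is the mean reciprocal
rank ``(1/n) * sum(1/Order_i)`` of the recovered metabolites. By default
``n`` counts the hits only (misses already penalise C); set
``s_denominator="all"`` to average the reciprocal ranks over every known
metabolite instead.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chem import InvalidSmiles, Molecule, RuleSet, parse_molecule
from .ranking import DEFAULT_GROUP_ORDER, GroupOrder, predict

logger = logging.getLogger(__name__)

TOPN_LEVELS = (1, 3, 5, 10, 20, 50)


class PairFileError(ValueError):
    """Raised when a substrate-metabolite pairs file violates the schema."""


@dataclass(frozen=True)
class Pair:
    substrate_id: str
    substrate: Molecule
    metabolite: Molecule
    evidence: str = ""


@dataclass
class PairDataset:
    """A validated list of substrate -> known-metabolite pairs."""

    pairs: list[Pair]
    source_path: str | None = None
    #: (line number, reason) for rows dropped in lenient mode
    skipped: list[tuple[int, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "substrate_id": [p.substrate_id for p in self.pairs],
                "substrate_smiles": [p.substrate.canonical_smiles for p in self.pairs],
                "metabolite_smiles": [p.metabolite.canonical_smiles for p in self.pairs],
                "evidence": [p.evidence for p in self.pairs],
            }
        )

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_pairs(path: str | Path, strict: bool = False) -> PairDataset:
    """Load a pairs CSV (``substrate_id,substrate_smiles,metabolite_smiles[,evidence]``).

    Rows whose SMILES do not parse, or where substrate and metabolite are the
    same structure, are dropped and reported (lenient, the default) or abort
    the load with a :class:`PairFileError` listing the lines (strict).
    """
    path = Path(path)
    if not path.exists():
        raise PairFileError(f"pairs file not found: {path}")
    try:
        frame = pd.read_csv(path)
    except Exception as exc:
        raise PairFileError(f"{path}: cannot read CSV: {exc}")
    required = ("substrate_id", "substrate_smiles", "metabolite_smiles")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise PairFileError(f"{path}: missing column(s) {', '.join(missing)}")

    pairs: list[Pair] = []
    bad: list[tuple[int, str]] = []
    for i, row in frame.iterrows():
        line = i + 2  # header is line 1
        try:
            substrate = parse_molecule(str(row["substrate_smiles"]))
            metabolite = parse_molecule(str(row["metabolite_smiles"]))
        except InvalidSmiles as exc:
            bad.append((line, str(exc)))
            continue
        if substrate.canonical_key == metabolite.canonical_key:
            bad.append((line, "substrate and metabolite are the same structure"))
            continue
        evidence = str(row["evidence"]) if "evidence" in frame.columns and pd.notna(row.get("evidence")) else ""
        pairs.append(Pair(str(row["substrate_id"]), substrate, metabolite, evidence))
    if bad and strict:
        detail = "; ".join(f"line {ln}: {why}" for ln, why in bad)
        raise PairFileError(f"{path}: invalid rows — {detail}")
    for ln, why in bad:
        logger.warning("%s line %d skipped: %s", path, ln, why)
    return PairDataset(pairs=pairs, source_path=str(path), skipped=bad)


def coverage(n_hit: int, n_total: int) -> float:
    """C = correctly predicted / total known metabolites."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_hit <= n_total:
        raise ValueError(f"n_hit must lie in [0, n_total], got {n_hit}/{n_total}")
    return n_hit / n_total


def sorting_ability(hit_ranks: Sequence[int], n: int | None = None) -> float:
    """S = (1/n) * sum of reciprocal ranks of the correctly predicted metabolites.

    ``n`` defaults to the number of hits; pass the total number of known
    metabolites for the all-pairs denominator convention.
    """
    if not hit_ranks:
        raise ValueError("sorting ability is undefined with no hits (report CS = 0)")
    if any(r < 1 for r in hit_ranks):
        raise ValueError("ranks must be >= 1")
    denominator = len(hit_ranks) if n is None else n
    return sum(1.0 / r for r in hit_ranks) / denominator


def cs_score(c: float, s: float) -> float:
    """CS = 100 * C * S, in [0, 100]."""
    if not (0.0 <= c <= 1.0 and 0.0 <= s <= 1.0):
        raise ValueError(f"C and S must lie in [0, 1], got C={c}, S={s}")
    return 100.0 * c * s


@dataclass
class EvalResult:
    """Aggregate scores of a prediction run over a pair dataset."""

    n_total: int
    n_hit: int
    C: float
    S: float
    CS: float
    hit_ranks: list[int]
    topn_counts: dict[int, int]
    top_k: int = 50
    group_order: GroupOrder | None = None
    s_denominator: str = "hits"
    #: substrate_id -> rank of the known metabolite (None = miss)
    per_pair: dict[str, int | None] = field(default_factory=dict)

    def ranks_with_misses(self) -> list[int]:
        """Per-pair ranks with misses encoded as 0 (for distribution tests)."""
        return [r if r is not None else 0 for r in self.per_pair.values()]

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_hit": self.n_hit,
            "C": self.C,
            "S": self.S,
            "CS": self.CS,
            "hit_ranks": list(self.hit_ranks),
            "topn_counts": {str(k): v for k, v in self.topn_counts.items()},
            "top_k": self.top_k,
            "group_order": list(self.group_order.sequence) if self.group_order else None,
            "s_denominator": self.s_denominator,
            "per_pair": self.per_pair,
        }


def _summarise(
    per_pair: dict[str, int | None],
    top_k: int,
    group_order: GroupOrder | None,
    s_denominator: str,
) -> EvalResult:
    n_total = len(per_pair)
    hit_ranks = [r for r in per_pair.values() if r is not None]
    n_hit = len(hit_ranks)
    c = coverage(n_hit, n_total) if n_total else 0.0
    if n_hit == 0:
        s = 0.0
    elif s_denominator == "all":
        s = sorting_ability(hit_ranks, n=n_total)
    else:
        s = sorting_ability(hit_ranks)
    levels = sorted(set(TOPN_LEVELS) | {top_k})
    topn = {n: sum(1 for r in hit_ranks if r <= n) for n in levels if n <= top_k}
    return EvalResult(
        n_total=n_total,
        n_hit=n_hit,
        C=c,
        S=s,
        CS=cs_score(c, s),
        hit_ranks=sorted(hit_ranks),
        topn_counts=topn,
        top_k=top_k,
        group_order=group_order,
        s_denominator=s_denominator,
        per_pair=per_pair,
    )


def evaluate(
    dataset: PairDataset,
    rules: RuleSet,
    order: GroupOrder = DEFAULT_GROUP_ORDER,
    top_k: int = 50,
    steric_radius: int = 3,
    s_denominator: str = "hits",
    strict: bool = True,
) -> EvalResult:
    """Predict every substrate and score recovery of the known metabolites.

    A pair is a hit when the known metabolite's canonical key appears among
    the Top-K candidates; its ``Order_i`` is the 1-based rank. In lenient
    mode (``strict=False``) substrates whose prediction fails are dropped
    from ``n_total``; in strict mode any failure aborts.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    per_pair: dict[str, int | None] = {}
    for pair in dataset:
        try:
            prediction = predict(
                pair.substrate.canonical_smiles,
                rules,
                order=order,
                top_k=top_k,
                steric_radius=steric_radius,
            )
        except Exception:
            if strict:
                raise
            logger.warning("prediction failed for %s; row dropped", pair.substrate_id)
            continue
        per_pair[pair.substrate_id] = prediction.rank_of(pair.metabolite.canonical_key)
    return _summarise(per_pair, top_k, order, s_denominator)


def load_rank_list(path: str | Path) -> pd.DataFrame:
    """Read an external predictor's rank list CSV (``substrate_id,rank,candidate_smiles``)."""
    frame = pd.read_csv(path)
    required = ("substrate_id", "rank", "candidate_smiles")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise PairFileError(f"{path}: missing column(s) {', '.join(missing)}")
    return frame


def evaluate_rank_lists(
    dataset: PairDataset,
    rank_lists: pd.DataFrame,
    top_k: int = 50,
    s_denominator: str = "hits",
) -> EvalResult:
    """Score any tool's pre-computed rank lists with the same CS metric.

    Candidates are matched to the known metabolites by stereo-stripped
    canonical key, exactly as for native predictions, so external tools can
    be compared head-to-head without re-running them.
    """
    keyed: dict[str, list[tuple[int, str]]] = {}
    for _, row in rank_lists.iterrows():
        try:
            key = parse_molecule(str(row["candidate_smiles"])).canonical_key
        except InvalidSmiles:
            continue
        keyed.setdefault(str(row["substrate_id"]), []).append((int(row["rank"]), key))
    per_pair: dict[str, int | None] = {}
    for pair in dataset:
        rank = None
        for r, key in sorted(keyed.get(pair.substrate_id, [])):
            if key == pair.metabolite.canonical_key and r <= top_k:
                rank = r
                break
        per_pair[pair.substrate_id] = rank
    return _summarise(per_pair, top_k, None, s_denominator)


def topn_curve(result: EvalResult, n_total: int | None = None) -> list[tuple[int, float]]:
    """Cumulative coverage at each N (distinct hit ranks, plus the Top-K cut)."""
    total = result.n_total if n_total is None else n_total
    points = []
    levels = sorted(set(result.hit_ranks) | {result.top_k})
    for n in levels:
        points.append((n, sum(1 for r in result.hit_ranks if r <= n) / total))
    return points


def compare_rank_distributions(
    ranks_a: Sequence[int], ranks_b: Sequence[int]
) -> tuple[float, float]:
    """Two-sample t-test on reciprocal ranks (misses encoded as rank 0).

    Returns ``(statistic, two-sided p-value)``. When both samples are
    constant the test is degenerate: (0, 1) for equal means, (inf, 0)
    otherwise, reported in place of scipy's NaN.
    """
    if not ranks_a or not ranks_b:
        raise ValueError("both rank lists must be non-empty")
    recip_a = np.array([1.0 / r if r >= 1 else 0.0 for r in ranks_a])
    recip_b = np.array([1.0 / r if r >= 1 else 0.0 for r in ranks_b])
    if recip_a.std() == 0.0 and recip_b.std() == 0.0:
        if recip_a.mean() == recip_b.mean():
            return 0.0, 1.0
        return float("inf"), 0.0
    import warnings

    with warnings.catch_warnings():
        # constant samples (all Top-1, say) trip scipy's precision warning
        warnings.simplefilter("ignore", RuntimeWarning)
        statistic, p_value = stats.ttest_ind(recip_a, recip_b, equal_var=True)
    return float(statistic), float(p_value)


def write_report(result: EvalResult, path: str | Path, config: dict | None = None) -> None:
    """Write an evaluation report JSON (scores + Top-N table + config echo)."""
    payload = result.to_dict()
    payload["topn_curve"] = topn_curve(result)
    if config:
        payload["config"] = config
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def plot_topn_curve(results: dict[str, EvalResult], path: str | Path) -> None:
    """Plot cumulative Top-N coverage curves for one or more labelled results."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, result in results.items():
        points = topn_curve(result)
        xs = [0] + [n for n, _ in points]
        ys = [0.0] + [c for _, c in points]
        ax.step(xs, ys, where="post", label=label)
    ax.set_xlabel("Top-N")
    ax.set_ylabel("cumulative coverage")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
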