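import math

import pytest
from hypothesis import given, settings, strategies as st

from metnc.chem import parse_molecule
from metnc.evaluation import (
    EvalResult,
    PairDataset,
    PairFileError,
    compare_rank_distributions,
    coverage,
    cs_score,
    evaluate,
    evaluate_rank_lists,
    load_pairs,
    load_rank_list,
    sorting_ability,
    topn_curve,
)
from metnc.ranking import DEFAULT_GROUP_ORDER

from oracles import permutation_test_mean_diff

ranks_lists = st.lists(st.integers(min_value=1, max_value=50), min_size=1, max_size=30)


class TestClosedForms:
    @pytest.mark.parametrize(
        "n_hit, n_total, expected",
        [(578, 850, 0.68), (0, 10, 0.0), (14, 14, 1.0)],
    )
    def test_coverage(self, n_hit, n_total, expected):
        assert coverage(n_hit, n_total) == pytest.approx(expected)

    def test_coverage_domain_errors(self):
        with pytest.raises(ValueError):
            coverage(1, 0)
        with pytest.raises(ValueError):
            coverage(5, 3)

    @pytest.mark.parametrize(
        "ranks, expected",
        [([1, 1, 1], 1.0), ([1, 2, 4], (1 + 0.5 + 0.25) / 3), ([50], 0.02)],
    )
    def test_sorting_ability(self, ranks, expected):
        assert sorting_ability(ranks) == pytest.approx(expected)

    def test_sorting_ability_empty_is_a_domain_error(self):
        with pytest.raises(ValueError):
            sorting_ability([])

    @pytest.mark.parametrize(
        "c, s, expected", [(1.0, 1.0, 100.0), (0.0, 0.7, 0.0), (0.5, 0.5, 25.0)]
    )
    def test_cs_score(self, c, s, expected):
        assert cs_score(c, s) == pytest.approx(expected)

    def test_independent_dataset_hand_ranks(self):
        # nine recovered metabolites of fourteen, at ranks 1,1,1,1,1,1,2,3,7
        ranks = [1, 1, 1, 1, 1, 1, 2, 3, 7]
        c = coverage(len(ranks), 14)
        s = sorting_ability(ranks)
        assert c == pytest.approx(9 / 14)
        assert s == pytest.approx((6 + 0.5 + 1 / 3 + 1 / 7) / 9)
        assert cs_score(c, s) == pytest.approx(49.83, abs=0.01)

    @given(ranks=ranks_lists)
    @settings(max_examples=60, derandomize=True)
    def test_cs_bounds_and_perfection(self, ranks):
        s = sorting_ability(ranks)
        value = cs_score(1.0, s)
        assert 0.0 <= value <= 100.0
        assert (value == 100.0) == all(r == 1 for r in ranks)

    @given(ranks=ranks_lists, which=st.integers(min_value=0, max_value=29))
    @settings(max_examples=60, derandomize=True)
    def test_improving_one_rank_strictly_increases_s(self, ranks, which):
        which %= len(ranks)
        if ranks[which] == 1:
            return
        improved = list(ranks)
        improved[which] -= 1
        assert sorting_ability(improved) > sorting_ability(ranks)


class TestPairFiles:
    def write(self, tmp_path, text, name="pairs.csv"):
        path = tmp_path / name
        path.write_text(text)
        return path

    def test_load_valid_pairs(self, tmp_path):
        path = self.write(
            tmp_path,
            "substrate_id,substrate_smiles,metabolite_smiles,evidence\n"
            "p1,CCOC(C)=O,CC(=O)O,rat plasma\n"
            "p2,COc1ccccc1,Oc1ccccc1,\n",
        )
        dataset = load_pairs(path)
        assert len(dataset) == 2
        assert dataset.pairs[0].evidence == "rat plasma"

    def test_identity_rows_rejected_and_reported(self, tmp_path):
        path = self.write(
            tmp_path,
            "substrate_id,substrate_smiles,metabolite_smiles\n"
            "p1,CCO,OCC\n"
            "p2,CCOC(C)=O,CC(=O)O\n",
        )
        dataset = load_pairs(path)
        assert len(dataset) == 1
        assert dataset.skipped and dataset.skipped[0][0] == 2

    def test_strict_mode_aborts_with_line_numbers(self, tmp_path):
        path = self.write(
            tmp_path,
            "substrate_id,substrate_smiles,metabolite_smiles\np1,C(,CC(=O)O\n",
        )
        with pytest.raises(PairFileError, match="line 2"):
            load_pairs(path, strict=True)

    def test_missing_column(self, tmp_path):
        path = self.write(tmp_path, "substrate_id,substrate_smiles\np1,CCO\n")
        with pytest.raises(PairFileError, match="metabolite_smiles"):
            load_pairs(path)


class TestEvaluate:
    def test_toy_pairs_fully_covered(self, toy_pairs, ruleset):
        result = evaluate(toy_pairs, ruleset)
        assert result.C == 1.0
        assert result.n_hit == result.n_total == len(toy_pairs)
        assert max(result.hit_ranks) <= 50

    def test_unreachable_metabolites_score_zero(self, ruleset):
        # substrates whose recorded metabolite no rule can make
        from metnc.evaluation import Pair

        pairs = PairDataset(
            pairs=[
                Pair("x1", parse_molecule("CCO"), parse_molecule("c1ccncc1")),
                Pair("x2", parse_molecule("CCCC"), parse_molecule("C1CC1")),
            ]
        )
        result = evaluate(pairs, ruleset)
        assert result.C == 0.0 and result.CS == 0.0 and result.S == 0.0

    def test_duplicated_dataset_scores_identically(self, ruleset, toy_pairs):
        from metnc.evaluation import Pair

        doubled = PairDataset(
            pairs=toy_pairs.pairs
            + [
                Pair(p.substrate_id + "_dup", p.substrate, p.metabolite, p.evidence)
                for p in toy_pairs.pairs
            ]
        )
        single = evaluate(toy_pairs, ruleset)
        double = evaluate(doubled, ruleset)
        assert double.C == pytest.approx(single.C)
        assert double.S == pytest.approx(single.S)
        assert double.CS == pytest.approx(single.CS)

    def test_coverage_nondecreasing_in_top_k(self, ruleset, toy_pairs):
        results = [evaluate(toy_pairs, ruleset, top_k=k) for k in (1, 3, 5, 10, 50)]
        coverages = [r.C for r in results]
        assert coverages == sorted(coverages)

    def test_topn_counts_nondecreasing_and_capped(self, ruleset, toy_pairs):
        result = evaluate(toy_pairs, ruleset)
        levels = sorted(result.topn_counts)
        values = [result.topn_counts[n] for n in levels]
        assert values == sorted(values)
        assert result.topn_counts[result.top_k] == result.n_hit

    def test_s_denominator_all_convention(self, ruleset, toy_pairs):
        hits_conv = evaluate(toy_pairs, ruleset, s_denominator="hits")
        all_conv = evaluate(toy_pairs, ruleset, s_denominator="all")
        # full coverage here, so the two conventions coincide
        assert all_conv.S == pytest.approx(hits_conv.S * hits_conv.n_hit / hits_conv.n_total)


class TestTopnCurve:
    def test_all_rank_one_curve_is_flat(self):
        result = _result_from_ranks([1, 1, 1], n_total=3)
        assert topn_curve(result) == [(1, 1.0), (50, 1.0)]

    def test_no_hits_curve_is_zero(self):
        result = _result_from_ranks([], n_total=4)
        assert topn_curve(result) == [(50, 0.0)]

    def test_hand_counted_curve(self):
        result = _result_from_ranks([1, 3], n_total=4)
        assert topn_curve(result) == [(1, 0.25), (3, 0.5), (50, 0.5)]


def _result_from_ranks(hit_ranks, n_total, top_k=50):
    per_pair = {f"s{i}": r for i, r in enumerate(hit_ranks)}
    for j in range(n_total - len(hit_ranks)):
        per_pair[f"m{j}"] = None
    from metnc.evaluation import _summarise

    return _summarise(per_pair, top_k, DEFAULT_GROUP_ORDER, "hits")


class TestExternalRankLists:
    def test_external_mode_scores_like_native(self, tmp_path, ruleset):
        pairs = tmp_path / "pairs.csv"
        pairs.write_text(
            "substrate_id,substrate_smiles,metabolite_smiles\n"
            "p1,CCOC(C)=O,CC(=O)O\n"
            "p2,COc1ccccc1,Oc1ccccc1\n"
            "p3,CCCC,C1CC1\n"
        )
        ranklist = tmp_path / "ranks.csv"
        ranklist.write_text(
            "substrate_id,rank,candidate_smiles\n"
            "p1,1,CC(=O)O\n"
            "p1,2,CCO\n"
            "p2,3,Oc1ccccc1\n"
            "p3,1,CCO\n"
        )
        dataset = load_pairs(pairs)
        result = evaluate_rank_lists(dataset, load_rank_list(ranklist))
        assert result.n_total == 3 and result.n_hit == 2
        assert sorted(result.hit_ranks) == [1, 3]
        assert result.C == pytest.approx(2 / 3)

    def test_missing_columns_rejected(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("substrate_id,candidate_smiles\np1,CCO\n")
        with pytest.raises(PairFileError):
            load_rank_list(bad)


class TestRankDistributionComparison:
    def test_identical_lists_give_zero_statistic(self):
        statistic, p_value = compare_rank_distributions([1, 2, 4], [1, 2, 4])
        assert statistic == pytest.approx(0.0)
        assert p_value == pytest.approx(1.0)

    def test_constant_equal_lists_handled_explicitly(self):
        assert compare_rank_distributions([1] * 5, [1] * 5) == (0.0, 1.0)

    def test_extreme_separation_is_significant(self):
        _, p_value = compare_rank_distributions([1] * 100, [50] * 100)
        assert p_value < 1e-10

    def test_misses_encoded_as_zero_lower_the_mean(self):
        stat_with_miss, _ = compare_rank_distributions([1, 1, 0, 0], [1, 1, 1, 1])
        assert stat_with_miss < 0

    @pytest.mark.parametrize(
        "ranks_a, ranks_b",
        [
            ([1, 2, 3, 10, 0], [4, 5, 6, 7, 0]),
            ([1, 1, 2, 3], [5, 8, 13, 21]),
            ([1, 3, 5, 7, 9], [2, 4, 6, 8, 10]),
        ],
    )
    def test_p_value_tracks_exhaustive_permutation_oracle(self, ranks_a, ranks_b):
        _, p_t = compare_rank_distributions(ranks_a, ranks_b)
        recip = lambda rs: [1.0 / r if r >= 1 else 0.0 for r in rs]
        p_perm = permutation_test_mean_diff(recip(ranks_a), recip(ranks_b))
        assert abs(p_t - p_perm) < 0.15
        assert (p_t < 0.05) == (p_perm < 0.05) or min(p_t, p_perm) > 0.01
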