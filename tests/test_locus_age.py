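"""Insertion dating, orthology checks and rank-sum statistics."""

import itertools
import logging

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hervh_crc.locus_age import (
    DEFAULT_NODE_AGES, DEFAULT_SPECIES, SpeciesAgeTree, assign_age,
    assign_ages, compare_category_ages, flank_orthology_check,
    presence_from_coverage, rank_sum_test, u_null_counts)

TREE = SpeciesAgeTree.default()


class TestPresenceFromCoverage:
    def test_boundaries(self):
        assert presence_from_coverage(0.9)
        assert not presence_from_coverage(0.0)
        assert presence_from_coverage(0.5)  # inclusive at the threshold

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            presence_from_coverage(1.2)

    def test_dataframe_form(self):
        cov = pd.DataFrame({"human": [1.0, 1.0], "chimp": [0.6, 0.3]})
        presence = presence_from_coverage(cov)
        assert presence["chimp"].tolist() == [True, False]


class TestFlankOrthology:
    def test_identical_sequences(self):
        seq = "ACGT" * 125
        assert flank_orthology_check(seq, seq)

    def test_random_dna_fails_default_cutoff(self):
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        a = "".join(rng.choice(bases, 500))
        b = "".join(rng.choice(bases, 500))
        assert not flank_orthology_check(a, b)

    def test_ten_percent_mutations_pass(self):
        rng = np.random.default_rng(1)
        bases = "ACGT"
        a = "".join(rng.choice(list(bases), 500))
        b = list(a)
        for i in rng.choice(500, 50, replace=False):
            b[i] = bases[(bases.index(b[i]) + 1) % 4]
        assert flank_orthology_check(a, "".join(b))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            flank_orthology_check("", "ACGT")


class TestSpeciesAgeTree:
    def test_default_is_valid_and_ordered(self):
        ages = [TREE.node_age[s] for s in TREE.species]
        assert ages == sorted(ages) and ages[0] == 0.0

    def test_non_increasing_ages_rejected(self):
        with pytest.raises(ValueError, match="increase"):
            SpeciesAgeTree(("human", "chimp", "gorilla"),
                           {"human": 0.0, "chimp": 9.0, "gorilla": 6.0})

    def test_from_table_round_trip(self):
        table = pd.DataFrame({
            "species": list(DEFAULT_SPECIES),
            "split_age_My": [DEFAULT_NODE_AGES[s] for s in DEFAULT_SPECIES]})
        tree = SpeciesAgeTree.from_table(table)
        assert tree.node_age == TREE.node_age

    def test_from_newick_ultrametric(self, tmp_path):
        newick = "(((human:6.6,chimp:6.6):2.0,gorilla:8.6):7.1,orangutan:15.7);"
        path = tmp_path / "tree.nwk"
        path.write_text(newick)
        tree = SpeciesAgeTree.from_newick(str(path))
        assert tree.node_age["chimp"] == pytest.approx(6.6)
        assert tree.node_age["gorilla"] == pytest.approx(8.6)
        assert tree.node_age["orangutan"] == pytest.approx(15.7)


class TestAssignAge:
    def _row(self, present):
        return {s: s in present for s in DEFAULT_SPECIES}

    def test_human_chimp_only(self):
        res = assign_age(self._row({"human", "chimp"}), TREE, "L")
        assert res.defining_species == "chimp"
        assert res.age == DEFAULT_NODE_AGES["chimp"]
        assert not res.presence_gap

    def test_all_species_gives_most_distant(self):
        res = assign_age(self._row(set(DEFAULT_SPECIES)), TREE, "L")
        assert res.defining_species == "bushbaby"
        assert res.age == DEFAULT_NODE_AGES["bushbaby"]

    def test_presence_gap_still_aged_by_most_distant(self, caplog):
        with caplog.at_level(logging.WARNING):
            res = assign_age(self._row({"human", "gibbon"}), TREE, "L")
        assert res.defining_species == "gibbon"
        assert res.presence_gap
        assert "gap" in caplog.text

    def test_human_absent_rejected(self):
        with pytest.raises(ValueError, match="human"):
            assign_age(self._row({"chimp"}), TREE, "L")

    def test_matches_brute_force_on_random_rows(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            present = {"human"} | {s for s in DEFAULT_SPECIES[1:]
                                   if rng.random() < 0.4}
            res = assign_age(self._row(present), TREE, "L")
            assert res.age == max(DEFAULT_NODE_AGES[s] for s in present)


def exact_p_by_enumeration(x, y):
    """Two-sided exact rank-sum p by brute-force enumeration of rank sets."""
    n1, n2 = len(x), len(y)
    ranks = sps.rankdata(np.concatenate([x, y]))
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for combo in itertools.combinations(range(n1 + n2), n1):
        r = sum(c + 1 for c in combo)
        us.append(r - n1 * (n1 + 1) / 2)
    us = np.array(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(1.0, p)


class TestRankSum:
    def test_complete_separation_two_vs_two(self):
        u, p = rank_sum_test([1.0, 2.0], [3.0, 4.0])
        assert u == 0.0
        assert p == pytest.approx(2 / 6)

    def test_identical_multisets_not_significant(self):
        _, p = rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p > 0.5

    def test_null_counts_match_enumeration(self):
        for n1, n2 in [(2, 2), (3, 4), (5, 5), (6, 3)]:
            counts = u_null_counts(n1, n2)
            us = [sum(c) - n1 * (n1 - 1) // 2
                  for c in itertools.combinations(range(n1 + n2), n1)]
            brute = np.bincount(np.array(us), minlength=n1 * n2 + 1)
            assert (counts == brute).all()

    def test_exact_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x = rng.normal(0, 1, int(rng.integers(2, 7)))
            y = rng.normal(0.5, 1, int(rng.integers(2, 7)))
            _, p = rank_sum_test(x, y)
            assert p == pytest.approx(exact_p_by_enumeration(x, y), abs=1e-12)

    def test_approximation_close_to_exact_at_eight_vs_eight(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.normal(0, 1, 8)
            y = rng.normal(0.7, 1, 8)
            _, p_exact = rank_sum_test(x, y, exact=True)
            _, p_approx = rank_sum_test(x, y, exact=False)
            assert abs(p_exact - p_approx) < 0.02

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        u, p = rank_sum_test(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
        assert u == ref.statistic
        assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0, 2.0, 3.0, 4.0])


class TestCompareCategoryAges:
    def _ages(self, crc, silent, constitutive):
        rows = ([("crc", c, "crc_specific") for c in crc]
                + [("sil", s, "silent") for s in silent]
                + [("con", k, "constitutive") for k in constitutive])
        return pd.DataFrame(
            {"age": [r[1] for r in rows], "category": [r[2] for r in rows]},
            index=[f"{r[0]}{i}" for i, r in enumerate(rows)])

    def test_complete_separation_significant(self):
        ages = self._ages(crc=np.linspace(4, 9, 14),
                          silent=np.linspace(25, 40, 5),
                          constitutive=np.linspace(28, 44, 4))
        contrasts = {c.groups: c for c in compare_category_ages(ages)}
        assert contrasts[("crc_specific",
                          "silent+constitutive")].p_value < 0.01
        assert contrasts[("crc_specific", "silent")].p_value < 0.05

    def test_empty_category_skipped(self, caplog):
        ages = self._ages(crc=[5, 6, 7], silent=[20, 25, 30],
                          constitutive=[])
        with caplog.at_level(logging.WARNING):
            contrasts = compare_category_ages(ages)
        assert len(contrasts) == 2  # crc-vs-silent and crc-vs-union survive
        assert "empty" in caplog.text

    def test_reports_group_sizes_and_medians(self):
        ages = self._ages(crc=[5, 6, 7, 8], silent=[20, 25, 30],
                          constitutive=[22, 28])
        c = compare_category_ages(ages)[2]  # crc vs silent+constitutive
        assert c.n_per_group == (4, 5)
        assert c.median_ages[0] == pytest.approx(6.5)


class TestAgeRecoveryFromGenerator:
    def test_clean_mode_recovers_insertion_nodes(self):
        from hervh_crc.synthetic_cohort import generate_presence_matrix

        probs = np.zeros(11)
        probs[[0, 2, 5]] = [0.5, 0.3, 0.2]
        presence, nodes = generate_presence_matrix(
            {f"L{i}": "c" for i in range(300)}, DEFAULT_SPECIES,
            {"c": probs}, rng=np.random.default_rng(7))
        ages = assign_ages(presence, TREE)
        assert (ages["defining_species"] == nodes).all()
        assert not ages["presence_gap"].any()
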