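from __future__ import annotations

import itertools
import math
from collections import Counter

import numpy as np
import pytest

from tcrgroups.scoring import (
    score_expansion,
    score_hla_enrichment,
    score_length_bias,
    score_vgene_bias,
    simpson,
)
from tcrgroups.types import PatientProfile, SpecificityGroup

N_PERM = 10_000


def make_group(members, group_id="G"):
    return SpecificityGroup(group_id=group_id, method="LOCAL", pattern="local XXX", members=members)


def exhaustive_simpson_tail(member_values, pool_values):
    """Fraction of same-size subsets of the pool at least as concentrated."""
    obs = simpson(member_values)
    m = len(member_values)
    total = hits = 0
    for combo in itertools.combinations(pool_values, m):
        total += 1
        if simpson(combo) >= obs - 1e-12:
            hits += 1
    return hits / total


def exhaustive_expansion_tail(member_counts, pool_counts):
    obs = sum(member_counts)
    m = len(member_counts)
    total = hits = 0
    for combo in itertools.combinations(pool_counts, m):
        total += 1
        if sum(combo) >= obs:
            hits += 1
    return hits / total


def assert_within_3se(estimate, exact, n_perm=N_PERM):
    se = math.sqrt(max(exact * (1 - exact), 1e-12) / n_perm)
    assert abs(estimate - exact) <= 3 * se + 1 / (n_perm + 1)


class TestSimpson:
    def test_uniform_pair(self):
        assert simpson(["A", "B"]) == pytest.approx(0.5)

    def test_monomorphic(self):
        assert simpson(["TRBV5-1"] * 3) == pytest.approx(1.0)


class TestVgeneBias:
    def test_monomorphic_group_scores_one(self, rec):
        group = make_group([rec("CASSAAAAAAF"), rec("CASSCCCCCCF"), rec("CASSDDDDDDF")])
        pool = group.members + [rec("CASSEEEEEEF", v="TRBV2"), rec("CASSFFFFFFF", v="TRBV9")]
        s, _ = score_vgene_bias(group, pool, n_perm=100, seed=0)
        assert s == pytest.approx(1.0)

    def test_permutation_matches_exhaustive_enumeration(self, rec):
        # dataset V genes [A, A, B, B, C]; group of two A's: exact p = 2/10
        vs = ["TRBV-A", "TRBV-A", "TRBV-B", "TRBV-B", "TRBV-C"]
        pool = [rec(f"CASSAAAAA{aa}F", v=v) for aa, v in zip("CDEFG", vs)]
        group = make_group(pool[:2])
        exact = exhaustive_simpson_tail([m.v_gene for m in group.members], vs)
        assert exact == pytest.approx(0.2)
        _, p = score_vgene_bias(group, pool, n_perm=N_PERM, seed=11)
        assert_within_3se(p, exact)

    def test_undersized_group_rejected(self, rec):
        with pytest.raises(ValueError):
            score_vgene_bias(make_group([rec("CASSAAAAAAF")]), [rec("CASSAAAAAAF")], 10, 0)

    def test_reproducible_under_fixed_seed(self, rec):
        pool = [rec(f"CASSAAAAA{aa}F", v=f"TRBV{i%3}") for i, aa in enumerate("ACDEFGHK")]
        group = make_group(pool[:3])
        assert score_vgene_bias(group, pool, 500, seed=42) == score_vgene_bias(
            group, pool, 500, seed=42
        )


class TestLengthBias:
    def test_same_length_group_scores_one(self, rec):
        group = make_group([rec("CASSAAAAAAF"), rec("CASSCCCCCCF")])
        pool = group.members + [rec("CASSDDDDDDDDF")]
        s, _ = score_length_bias(group, pool, n_perm=100, seed=0)
        assert s == pytest.approx(1.0)

    def test_two_lengths_score_half(self, rec):
        group = make_group([rec("CASSAAAAAAF"), rec("CASSCCCCCCCF")])
        s, _ = score_length_bias(group, group.members, n_perm=100, seed=0)
        assert s == pytest.approx(0.5)

    @pytest.mark.parametrize("lengths", [(11, 11, 12, 13, 14), (11, 11, 11, 12, 12, 13)])
    def test_permutation_matches_exhaustive_enumeration(self, rec, lengths):
        pool = [
            rec("CASS" + "A" * (ln - 5) + "F", sample=f"S{i}") for i, ln in enumerate(lengths)
        ]
        group = make_group(pool[:2])
        exact = exhaustive_simpson_tail(
            [len(m.cdr3b_aa) for m in group.members], list(lengths)
        )
        _, p = score_length_bias(group, pool, n_perm=N_PERM, seed=5)
        assert_within_3se(p, exact)


class TestExpansion:
    def test_exhaustive_singleton_case(self, rec):
        pool = [
            rec("CASSAAAAAAF", count=5),
            rec("CASSCCCCCCF", count=1),
            rec("CASSDDDDDDF", count=1),
            rec("CASSEEEEEEF", count=1),
        ]
        group = make_group([pool[0]])
        exact = exhaustive_expansion_tail([5], [5, 1, 1, 1])
        assert exact == pytest.approx(0.25)
        p = score_expansion(group, pool, n_perm=N_PERM, seed=3)
        assert_within_3se(p, exact)

    def test_largest_counts_match_exact_tail(self, rec):
        # only the identical draw ties the two dominant clonotypes: exact 1/15
        pool = [rec(f"CASSAAAAA{aa}F", count=c) for aa, c in zip("ACDEFG", (9, 8, 1, 1, 1, 1))]
        group = make_group(pool[:2])
        exact = exhaustive_expansion_tail([9, 8], [9, 8, 1, 1, 1, 1])
        assert exact == pytest.approx(1 / 15)
        p = score_expansion(group, pool, n_perm=N_PERM, seed=2)
        assert_within_3se(p, exact)

    def test_whole_dataset_group_scores_one(self, rec):
        pool = [rec(f"CASSAAAAA{aa}F", count=i + 1) for i, aa in enumerate("ACD")]
        assert score_expansion(make_group(pool), pool, n_perm=500, seed=0) == 1.0

    def test_all_zero_counts_warns_p_one(self, rec):
        pool = [rec(f"CASSAAAAA{aa}F", count=0) for aa in "ACD"]
        assert score_expansion(make_group(pool[:2]), pool, n_perm=100, seed=0) == 1.0

    def test_p_in_valid_range_and_deterministic(self, rec):
        pool = [rec(f"CASSAAAAA{aa}F", count=i % 4) for i, aa in enumerate("ACDEFGHK")]
        group = make_group(pool[2:5])
        p1 = score_expansion(group, pool, n_perm=200, seed=9)
        p2 = score_expansion(group, pool, n_perm=200, seed=9)
        assert p1 == p2
        assert 1 / 201 <= p1 <= 1.0


class TestHlaEnrichment:
    def _profiles(self, carriers, n=10, allele="B*44"):
        return {
            f"P{i}": PatientProfile(
                patient_id=f"P{i}",
                hla_alleles=frozenset({allele} if i < carriers else set()),
            )
            for i in range(n)
        }

    def test_hypergeometric_closed_form(self, rec):
        profiles = self._profiles(carriers=3)
        members = [rec(f"CASSAAAAA{aa}F", patient=f"P{i}") for i, aa in enumerate("ACD")]
        (result,) = score_hla_enrichment(make_group(members), profiles)
        allele, n_carriers, p = result
        assert allele == "B*44" and n_carriers == 3
        assert p == pytest.approx(1 / math.comb(10, 3), rel=1e-9)

    def test_single_carrier_not_reported(self, rec):
        profiles = self._profiles(carriers=1)
        members = [rec(f"CASSAAAAA{aa}F", patient=f"P{i}") for i, aa in enumerate("ACD")]
        assert score_hla_enrichment(make_group(members), profiles) == []

    def test_universal_allele_scores_one(self, rec):
        profiles = self._profiles(carriers=10)
        members = [rec(f"CASSAAAAA{aa}F", patient=f"P{i}") for i, aa in enumerate("ACD")]
        (result,) = score_hla_enrichment(make_group(members), profiles)
        assert result[2] == pytest.approx(1.0)

    def test_no_hla_data_gives_empty_list(self, rec):
        members = [rec("CASSAAAAAAF", patient="P0"), rec("CASSCCCCCCF", patient="P1")]
        assert score_hla_enrichment(make_group(members), {}) == []
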