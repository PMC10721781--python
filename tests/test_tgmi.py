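"""Discretisation, information estimators vs direct-summation oracles,
permutation significance and interference-frequency ranking."""
import math

import numpy as np
import pandas as pd
import pytest

from tfcollab.tgmi import (TFRanking, TripleRecord, conditional_mi, discretize,
                           mutual_information, rank_tfs, score_triples,
                           _triple_stats, _joint_table)
from .conftest import make_matrix


def oracle_cmi(x, y, z) -> float:
    """Direct triple-loop summation over the joint table (independent of
    the vectorised implementation)."""
    n = len(x)
    from collections import Counter

    cxyz = Counter(zip(x, y, z))
    cxz = Counter(zip(x, z))
    cyz = Counter(zip(y, z))
    cz = Counter(z)
    total = 0.0
    for (a, b, c), m in cxyz.items():
        p = m / n
        total += p * math.log2((p * (cz[c] / n)) / ((cxz[(a, c)] / n) * (cyz[(b, c)] / n)))
    return max(total, 0.0)


class TestDiscretize:
    def test_tertiles(self):
        labels = discretize(np.arange(1, 10), bins=3)
        assert list(labels) == [0, 0, 0, 1, 1, 1, 2, 2, 2]

    def test_constant_single_label(self):
        with pytest.warns(UserWarning):
            labels = discretize(np.full(8, 3.0))
        assert set(labels) == {0}

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        a = discretize(x)
        b = discretize(np.exp(2 * x) + 5)
        assert np.array_equal(a, b)

    def test_ties_share_lower_bin(self):
        labels = discretize(np.array([1, 1, 1, 1, 2, 3]), bins=2)
        assert list(labels) == [0, 0, 0, 0, 1, 1]


class TestInformationEstimators:
    def test_copy_channel_is_one_bit(self):
        x = np.array([0, 1] * 8)
        z = np.array([0, 0, 1, 1] * 4)
        assert conditional_mi(x, x, z) == pytest.approx(1.0, abs=1e-12)
        assert mutual_information(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_independent_balanced_table_is_zero(self):
        # all 8 binary combinations equally often -> exact independence
        rows = np.array([[a, b, c] for a in (0, 1) for b in (0, 1) for c in (0, 1)] * 2)
        assert conditional_mi(rows[:, 0], rows[:, 1], rows[:, 2]) == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_summation_oracle_random(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(6, 40))
            x = rng.integers(0, 3, n)
            y = rng.integers(0, 3, n)
            z = rng.integers(0, 3, n)
            assert conditional_mi(x, y, z) == pytest.approx(
                oracle_cmi(x, y, z), abs=1e-12)

    def test_exhaustive_binary_tables(self):
        # every 2x2x2 contingency table with cell counts <= 2
        from itertools import product

        for cells in product(range(3), repeat=8):
            if sum(cells) < 2:
                continue
            x, y, z = [], [], []
            idx = 0
            for a in (0, 1):
                for b in (0, 1):
                    for c in (0, 1):
                        x += [a] * cells[idx]
                        y += [b] * cells[idx]
                        z += [c] * cells[idx]
                        idx += 1
            got = conditional_mi(np.array(x), np.array(y), np.array(z))
            assert got == pytest.approx(oracle_cmi(x, y, z), abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            conditional_mi([0, 1], [0, 1, 0], [0, 0, 1])


class TestTripleStats:
    def test_swap_symmetry(self):
        rng = np.random.default_rng(2)
        t = rng.integers(0, 3, 60)
        g1 = rng.integers(0, 3, 60)
        g2 = rng.integers(0, 3, 60)
        s12 = _triple_stats(_joint_table(t, g1, g2, 3))
        s21 = _triple_stats(_joint_table(t, g2, g1, 3))
        # components 1<->2 swap, pair component invariant
        assert s12[0] == pytest.approx(s21[1], abs=1e-12)
        assert s12[1] == pytest.approx(s21[0], abs=1e-12)
        assert s12[2] == pytest.approx(s21[3], abs=1e-12)
        assert s12[4] == pytest.approx(s21[4], abs=1e-12)


def _matrix_from_rows(rows, ids):
    arr = np.vstack(rows)
    arr = arr - arr.min() + 0.5          # keep the FPKM-scale invariant
    return make_matrix(arr, gene_ids=ids)


class TestScoreTriples:
    def _planted(self, seed, rho=0.8, n=78):
        rng = np.random.default_rng(seed)
        t = rng.normal(0, 1, n)
        s = np.sqrt(1 - rho ** 2)
        g1 = rho * t + rng.normal(0, s, n)
        g2 = rho * t + rng.normal(0, s, n)
        return _matrix_from_rows([t, g1, g2], ["T", "G1", "G2"])

    def test_planted_triple_significant(self):
        X = self._planted(0)
        (rec,) = score_triples(X, ["T"], ["G1", "G2"], n_perm=500, seed=1)
        assert rec.significant
        assert rec.adj_p[0] <= 0.05 and rec.adj_p[1] <= 0.05

    def test_p_lower_bound_is_add_one(self):
        X = self._planted(1, rho=0.95)
        (rec,) = score_triples(X, ["T"], ["G1", "G2"], n_perm=1000, seed=2)
        assert min(rec.p_values) >= 1 / 1001 - 1e-12

    def test_deterministic_under_seed(self):
        X = self._planted(2, rho=0.3)
        a = score_triples(X, ["T"], ["G1", "G2"], n_perm=200, seed=7)
        b = score_triples(X, ["T"], ["G1", "G2"], n_perm=200, seed=7)
        assert a[0].p_values == b[0].p_values
        c = score_triples(X, ["T"], ["G1", "G2"], n_perm=200, seed=8)
        assert a[0].cmi == c[0].cmi       # statistics identical, null reseeded

    def test_scale_invariance_raw_vs_log(self):
        X = self._planted(3)
        Xlog = make_matrix(np.log2(X.values.to_numpy() + 1),
                           gene_ids=X.gene_ids)
        a = score_triples(X, ["T"], ["G1", "G2"], n_perm=100, seed=4)
        b = score_triples(Xlog, ["T"], ["G1", "G2"], n_perm=100, seed=4)
        assert a[0].cmi == b[0].cmi and a[0].p_values == b[0].p_values

    def test_tf_in_bp_set_skipped_with_warning(self):
        X = self._planted(4)
        with pytest.warns(UserWarning, match="T"):
            recs = score_triples(X, ["T"], ["T", "G1", "G2"], n_perm=50, seed=5)
        assert {(r.tf_id, r.g1_id, r.g2_id) for r in recs} == {("T", "G1", "G2")}

    def test_all_pairs_enumerated(self):
        rng = np.random.default_rng(6)
        rows = [rng.normal(size=30) for _ in range(5)]
        X = _matrix_from_rows(rows, ["T", "a", "b", "c", "d"])
        recs = score_triples(X, ["T"], ["a", "b", "c", "d"], n_perm=20, seed=0)
        assert len(recs) == 6             # C(4,2) unordered pairs


class TestRankTFs:
    def _rec(self, tf, g1, g2, sig):
        return TripleRecord(tf_id=tf, g1_id=g1, g2_id=g2, mi=(0, 0),
                            cmi=(0, 0, 0), p_values=(1, 1, 1),
                            adj_p=(1, 1, 1), significant=sig)

    def test_full_interference_is_bp_count(self):
        bp = [f"b{i}" for i in range(6)]
        recs = [self._rec("tf1", a, b, True)
                for i, a in enumerate(bp) for b in bp[i + 1:]]
        (r,) = rank_tfs(recs)
        assert r.interference_frequency == 6

    def test_counted_once_per_gene(self):
        # 3 significant triples over the same two BP genes -> frequency 2
        recs = [self._rec("tf1", "b1", "b2", True)] * 3
        (r,) = rank_tfs(recs)
        assert r.interference_frequency == 2

    def test_zero_frequency_ranked_last_ties_by_id(self):
        recs = [self._rec("tfB", "b1", "b2", True),
                self._rec("tfA", "b1", "b2", False),
                self._rec("tfC", "b1", "b3", True)]
        ranks = rank_tfs(recs)
        assert [r.tf_id for r in ranks] == ["tfB", "tfC", "tfA"]
        assert ranks[-1].interference_frequency == 0
        assert [r.rank for r in ranks] == [1, 2, 3]
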