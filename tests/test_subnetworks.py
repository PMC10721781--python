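"""Triple-Link decomposition: planted-module recovery, determinism,
disjointness, and CCG merging/classification oracles."""
import numpy as np
import pytest

from tfcollab.ccg import CCGRanking, SCCM
from tfcollab.subnetworks import (assign_ccgs, classify_ccgs, decompose,
                                  unassigned_tfs)


def block_sccm(sizes, intra, inter, k=100, rng=None, min_shared=25):
    """SCCM with planted diagonal blocks: intra-block counts >= min_shared,
    inter-block counts below it. Returns (SCCM, planted label list)."""
    n = sum(sizes)
    ids = [f"tf{i:03d}" for i in range(n)]
    labels = np.concatenate([[b] * s for b, s in enumerate(sizes)])
    C = np.full((n, n), inter, dtype=np.int64)
    if rng is not None:
        C = rng.integers(0, inter + 1, size=(n, n))
        C = np.minimum(C, C.T)
    for b in range(len(sizes)):
        mask = labels == b
        block = np.full((mask.sum(), mask.sum()), intra)
        if rng is not None:
            block = rng.integers(intra, k + 1, size=block.shape)
            block = np.maximum(block, block.T)
        C[np.ix_(mask, mask)] = block
    np.fill_diagonal(C, k)
    C = np.ascontiguousarray(np.minimum(C, C.T))
    np.fill_diagonal(C, k)
    return SCCM(tf_ids=ids, counts=C, k=k, min_shared=min_shared), list(labels)


class TestDecompose:
    def test_two_planted_cliques_recovered(self):
        # oracle: connected components of the thresholded graph coincide here
        S, labels = block_sccm([5, 5], intra=30, inter=0)
        subnets = decompose(S, min_shared=25)
        assert len(subnets) == 2
        got = [set(s.member_tfs) for s in subnets]
        expected = [{t for t, l in zip(S.tf_ids, labels) if l == b} for b in (0, 1)]
        assert got[0] in expected and got[1] in expected and got[0] != got[1]

    def test_all_below_threshold_yields_nothing(self):
        S, _ = block_sccm([4, 4], intra=24, inter=0)
        assert decompose(S, min_shared=25) == []

    def test_single_strong_pair(self):
        n = 5
        C = np.zeros((n, n), dtype=np.int64)
        C[0, 1] = C[1, 0] = 40
        np.fill_diagonal(C, 100)
        S = SCCM([f"t{i}" for i in range(n)], C, k=100)
        subnets = decompose(S, min_shared=25)
        assert len(subnets) == 1
        assert set(subnets[0].member_tfs) == {"t0", "t1"}
        assert subnets[0].seed_weight == 40
        assert set(unassigned_tfs(S, subnets)) == {"t2", "t3", "t4"}

    def test_empty_sccm(self):
        S = SCCM([], np.zeros((0, 0), dtype=int), k=100)
        assert decompose(S) == []

    def test_deterministic_pure_function(self):
        rng = np.random.default_rng(11)
        S, _ = block_sccm([4, 3, 5], intra=26, inter=10, rng=rng)
        a = decompose(S)
        b = decompose(S)
        assert [s.member_tfs for s in a] == [s.member_tfs for s in b]

    def test_disjoint_members(self):
        rng = np.random.default_rng(13)
        C = rng.integers(0, 60, size=(20, 20))
        C = np.minimum(C, C.T)
        np.fill_diagonal(C, 100)
        S = SCCM([f"t{i:02d}" for i in range(20)], C, k=100)
        subnets = decompose(S, min_shared=25)
        members = [t for s in subnets for t in s.member_tfs]
        assert len(members) == len(set(members))

    def test_monotone_seed_weights(self):
        rng = np.random.default_rng(17)
        S, _ = block_sccm([4, 4, 4, 4], intra=25, inter=5, rng=rng)
        subnets = decompose(S, min_shared=25)
        weights = [s.seed_weight for s in subnets]
        assert weights == sorted(weights, reverse=True)

    def test_planted_recovery_ari(self):
        from sklearn.metrics import adjusted_rand_score

        for seed in range(5):
            rng = np.random.default_rng(seed)
            sizes = list(rng.integers(2, 7, size=int(rng.integers(3, 7))))
            S, labels = block_sccm(sizes, intra=25, inter=24, rng=rng)
            subnets = decompose(S, min_shared=25)
            pred = {}
            for s in subnets:
                for t in s.member_tfs:
                    pred[t] = s.id
            assert set(pred) == set(S.tf_ids)
            y_true = labels
            y_pred = [pred[t] for t in S.tf_ids]
            assert adjusted_rand_score(y_true, y_pred) == 1.0

    def test_later_subnetworks_smaller_on_average(self):
        # heterogeneous planted SCCMs: extraction order tracks edge weight
        from scipy.stats import spearmanr

        rhos = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            sizes = [6, 5, 4, 3, 2]
            S, _ = block_sccm(sizes, intra=25, inter=0, rng=rng)
            subnets = decompose(S, min_shared=25)
            if len(subnets) < 3:
                continue
            pos = {t: i for i, t in enumerate(S.tf_ids)}
            mean_w = []
            for s in subnets:
                ws = [S.counts[pos[a], pos[b]] for x, a in enumerate(s.member_tfs)
                      for b in s.member_tfs[x + 1:]]
                mean_w.append(np.mean(ws))
            rho = spearmanr(range(len(subnets)), mean_w).statistic
            if not np.isnan(rho):
                rhos.append(rho)
        assert np.mean(rhos) < 0


class TestCCGAssignment:
    def _rank(self, tf, genes):
        return CCGRanking(tf_id=tf, ranked_genes=list(genes),
                          scores=np.linspace(1, 0, len(genes)), k=len(genes))

    def _subnet(self, members):
        from tfcollab.subnetworks import Subnetwork

        return Subnetwork(id=1, member_tfs=list(members))

    def test_identical_lists_merge_to_k(self):
        genes = [f"g{i}" for i in range(100)]
        rk = [self._rank("a", genes), self._rank("b", genes)]
        (s,) = assign_ccgs([self._subnet(["a", "b"])], rk)
        assert len(s.merged_ccgs) == 100

    def test_disjoint_lists_merge_to_2k(self):
        rk = [self._rank("a", [f"g{i}" for i in range(100)]),
              self._rank("b", [f"h{i}" for i in range(100)])]
        (s,) = assign_ccgs([self._subnet(["a", "b"])], rk)
        assert len(s.merged_ccgs) == 200

    def test_random_lists_match_union_oracle(self):
        rng = np.random.default_rng(3)
        pool = [f"g{i:03d}" for i in range(80)]
        lists = [list(rng.choice(pool, 30, replace=False)) for _ in range(3)]
        rk = [self._rank(t, l) for t, l in zip("abc", lists)]
        (s,) = assign_ccgs([self._subnet(["a", "b", "c"])], rk)
        assert set(s.merged_ccgs) == set().union(*map(set, lists))

    def test_missing_ranking_names_tf(self):
        rk = [self._rank("a", ["g1", "g2"])]
        with pytest.raises(KeyError, match="b"):
            assign_ccgs([self._subnet(["a", "b"])], rk)


class TestClassifyCCGs:
    def _subnet_with(self, ccgs, members=("a", "b")):
        from tfcollab.subnetworks import Subnetwork

        return Subnetwork(id=1, member_tfs=list(members), merged_ccgs=list(ccgs))

    def test_no_tf_ccgs(self):
        df = classify_ccgs([self._subnet_with(["x", "y", "z"])], {"a", "b"})
        assert df.loc[0, "frac_non_tf"] == 1.0

    def test_all_member_tfs(self):
        df = classify_ccgs([self._subnet_with(["a", "b"])], {"a", "b", "c"})
        assert df.loc[0, "frac_tf_member"] == 1.0

    def test_mixed_partition_matches_hand_count(self):
        ccgs = ["a", "c", "x", "y"]          # member TF, outside TF, 2 non-TF
        df = classify_ccgs([self._subnet_with(ccgs)], {"a", "b", "c"})
        assert (df.loc[0, "tf_member"], df.loc[0, "tf_outside"],
                df.loc[0, "non_tf"]) == (1, 1, 2)
        assert df.loc[0, ["frac_non_tf", "frac_tf_outside",
                          "frac_tf_member"]].sum() == pytest.approx(1.0)
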