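"""PWM parsing, promoter scanning vs an exhaustive oracle, and TFBS
enrichment."""
import numpy as np
import pytest

from tfcollab.enrichment import hypergeom_tail
from tfcollab.motifs import (PWM, estimate_background, load_pwms,
                             motif_enrichment_test, scan_promoter, write_meme)

RC = str.maketrans("ACGT", "TGCA")


def near_deterministic_pwm(consensus, p=0.97):
    mat = np.full((4, len(consensus)), (1 - p) / 3)
    for j, b in enumerate(consensus):
        mat["ACGT".index(b), j] = p
    return PWM("toy", mat)


def oracle_scan(seq, pwm, background, threshold):
    """Exhaustive per-window, per-strand scorer (independent of the
    vectorised implementation)."""
    import math

    bg = background
    L = pwm.length
    smin = sum(min(math.log2(pwm.matrix[i, j] / bg["ACGT"[i]]) for i in range(4))
               for j in range(L))
    smax = sum(max(math.log2(pwm.matrix[i, j] / bg["ACGT"[i]]) for i in range(4))
               for j in range(L))
    hits = []
    for start in range(len(seq) - L + 1):
        window = seq[start:start + L]
        if "N" in window:
            continue
        for strand in "+-":
            w = window if strand == "+" else window.translate(RC)[::-1]
            raw = sum(math.log2(pwm.matrix["ACGT".index(b), j] / bg[b])
                      for j, b in enumerate(w))
            norm = (raw - smin) / (smax - smin)
            if norm >= threshold:
                hits.append((start, strand, round(raw, 9)))
    return sorted(hits)


class TestPWMLoading:
    def test_meme_minimal(self, tmp_path):
        pwm = near_deterministic_pwm("ACGTA")
        p = tmp_path / "m.meme"
        write_meme([pwm], p)
        (back,) = load_pwms(p)
        assert back.length == 5
        assert back.consensus() == "ACGTA"
        assert np.allclose(back.matrix.sum(axis=0), 1.0)

    def test_cisbp_text(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("Pos\tA\tC\tG\tT\n1\t1\t0\t0\t0\n2\t0\t0\t1\t0\n")
        (pwm,) = load_pwms(p)
        assert pwm.length == 2
        # zero cells floored and renormalised; argmax preserved
        assert pwm.matrix.min() > 0
        assert pwm.consensus() == "AG"

    def test_malformed_column_sum(self):
        with pytest.raises(ValueError, match="column"):
            PWM("bad", np.array([[0.5, 0.2], [0.2, 0.2], [0.2, 0.2], [0.2, 0.2]]))

    def test_unrecognised_format(self, tmp_path):
        p = tmp_path / "x.txt"
        p.write_text("not a motif file\n")
        with pytest.raises(ValueError):
            load_pwms(p)


class TestScanPromoter:
    BG = {b: 0.25 for b in "ACGT"}

    def test_planted_consensus_scores_one(self):
        pwm = near_deterministic_pwm("TGACGTCA")
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 100))
        seq = seq[:40] + "TGACGTCA" + seq[48:]
        hits = scan_promoter(seq, pwm, self.BG, threshold=0.99)
        plus = [h for h in hits if h.strand == "+"]
        assert any(h.start == 40 and h.norm_score == pytest.approx(1.0, abs=1e-12)
                   for h in plus)

    def test_reverse_complement_hit_same_score(self):
        pwm = near_deterministic_pwm("TGACTTAA")
        rc = "TGACTTAA".translate(RC)[::-1]
        seq = "C" * 30 + rc + "C" * 30
        hits = scan_promoter(seq, pwm, self.BG, threshold=0.99)
        minus = [h for h in hits if h.strand == "-"]
        assert len(minus) == 1 and minus[0].start == 30
        fwd = scan_promoter("C" * 30 + "TGACTTAA" + "C" * 30, pwm, self.BG, 0.99)
        fwd_plus = [h for h in fwd if h.strand == "+"]
        assert minus[0].raw_score == pytest.approx(fwd_plus[0].raw_score, abs=1e-9)

    def test_matches_exhaustive_oracle_random_sequences(self):
        pwm = near_deterministic_pwm("ACGT", p=0.7)
        rng = np.random.default_rng(7)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGTN"), 200, p=[0.24] * 4 + [0.04]))
            got = sorted((h.start, h.strand, round(h.raw_score, 9))
                         for h in scan_promoter(seq, pwm, self.BG, threshold=0.6))
            want = oracle_scan(seq, pwm, self.BG, 0.6)
            assert got == want

    def test_threshold_monotonicity(self):
        pwm = near_deterministic_pwm("ACGT", p=0.6)
        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list("ACGT"), 500))
        counts = [len(scan_promoter(seq, pwm, self.BG, t))
                  for t in (0.3, 0.5, 0.7, 0.9)]
        assert counts == sorted(counts, reverse=True)

    def test_strand_symmetry_of_score_multiset(self):
        pwm = near_deterministic_pwm("GATTACA", p=0.8)
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGT"), 300))
        fwd = scan_promoter(seq, pwm, self.BG, threshold=0.5)
        rev = scan_promoter(seq.translate(RC)[::-1], pwm, self.BG, threshold=0.5)
        assert sorted(round(h.raw_score, 9) for h in fwd) == \
            sorted(round(h.raw_score, 9) for h in rev)
        # strands swap and positions mirror
        L = pwm.length
        mapped = sorted((len(seq) - h.start - L, "+-"[h.strand == "+"]) for h in rev)
        assert mapped == sorted((h.start, h.strand) for h in fwd)

    def test_short_promoter_empty(self):
        pwm = near_deterministic_pwm("ACGTACGT")
        assert scan_promoter("ACG", pwm, self.BG) == []

    def test_anti_consensus_scores_zero(self):
        pwm = near_deterministic_pwm("AAAA", p=0.7)
        hits = scan_promoter("TTTT", pwm, self.BG, threshold=0.0)
        assert min(h.norm_score for h in hits if h.strand == "+") == pytest.approx(0.0, abs=1e-12)


class TestBackground:
    def test_estimated_frequencies(self):
        bg = estimate_background(["AACC", "GGTT"])
        assert bg["A"] == pytest.approx(0.25)
        assert sum(bg.values()) == pytest.approx(1.0)


class TestMotifEnrichmentTest:
    def test_extreme_design_minimal_p(self):
        fg = {f"f{i}" for i in range(5)}
        allg = fg | {f"b{i}" for i in range(15)}
        hits = {g: [object()] for g in fg}
        e = motif_enrichment_test(fg, allg, hits)
        from math import comb

        assert e.p_value == pytest.approx(1 / comb(20, 5), rel=1e-9)
        assert e.pct_ccgs_with_motif == 1.0

    def test_planted_design_enriched(self):
        # 80% of 50 fg genes carry the motif vs 10% of background, N=1000
        rng = np.random.default_rng(2)
        fg = [f"f{i}" for i in range(50)]
        bg = [f"b{i}" for i in range(950)]
        hits = {}
        for g in fg:
            if rng.random() < 0.8:
                hits[g] = [1]
        for g in bg:
            if rng.random() < 0.1:
                hits[g] = [1]
        e = motif_enrichment_test(set(fg), set(fg) | set(bg), hits)
        assert e.p_value < 0.01

    def test_uniform_null_is_calibrated(self):
        # oracle: empirical null over many simulated hit assignments
        rng = np.random.default_rng(3)
        fg = {f"g{i:03d}" for i in range(30)}
        allg = {f"g{i:03d}" for i in range(300)}
        ps = []
        for _ in range(300):
            hit_genes = rng.choice(sorted(allg), 60, replace=False)
            hits = {g: [1] for g in hit_genes}
            ps.append(motif_enrichment_test(fg, allg, hits).p_value)
        # upper-tail p-values should not be anti-conservative
        assert np.mean(np.array(ps) <= 0.05) <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / 300)

    def test_empty_foreground_error(self):
        with pytest.raises(ValueError):
            motif_enrichment_test(set(), {"a"}, {})
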