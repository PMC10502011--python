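"""LTR orientation, alignment, gamma-K2P distances, pair statistics,
Poisson-null classification, burst clusters and the NRR pair deficit."""

import math

import numpy as np
import pytest

from tedyn.config import LtrConfig
from tedyn.core import Interval, TECopy
from tedyn.ltr import (
    LTRPairRecord,
    LtrSeqs,
    SaturationError,
    align_pair,
    build_poisson_null,
    burst_clusters,
    classify_pairs,
    copy_age_comparison,
    count_pq,
    gamma_k2p,
    k2p_gamma_distance,
    ltr_pair_records,
    nrr_pair_deficit,
    orient_ltrs,
    pair_distance,
    pair_substitution_counts,
)


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestOrientLtrs:
    left = Interval("c", 0, 500)
    right = Interval("c", 5000, 5500)

    def make_copy(self):
        return TECopy("t", Interval("c", 0, 5500))

    def test_plus_strand_left_ltr_is_five_prime(self):
        copy, status = orient_ltrs(self.make_copy(), [self.left, self.right], "+")
        assert status == "oriented"
        assert copy.ltr5 == self.left and copy.ltr3 == self.right

    def test_minus_strand_right_ltr_is_five_prime(self):
        copy, status = orient_ltrs(self.make_copy(), [self.left, self.right], "-")
        assert copy.ltr5 == self.right and copy.ltr3 == self.left

    def test_unknown_orientation_excluded(self):
        copy, status = orient_ltrs(self.make_copy(), [self.left, self.right], None)
        assert copy is None and status == "unoriented"

    def test_more_than_two_ltrs_excluded_as_nested(self):
        mid = Interval("c", 2000, 2500)
        copy, status = orient_ltrs(
            self.make_copy(), [self.left, mid, self.right], "+"
        )
        assert copy is None and status == "nested"


class TestAlignPair:
    def test_identical_sequences(self, rng):
        s = random_dna(rng, 100)
        P, Q, L = count_pq(*align_pair(s, s))
        assert (P, Q, L) == (0.0, 0.0, 100)

    def test_single_substitution_is_one_mismatch_column(self, rng):
        s = random_dna(rng, 100)
        t = s[:50] + ("A" if s[50] != "A" else "C") + s[51:]
        P, Q, L = count_pq(*align_pair(s, t))
        assert L == 100 and P + Q == pytest.approx(1 / 100)

    def test_three_base_deletion_excluded_from_sites(self, rng):
        s = random_dna(rng, 100)
        t = s[:40] + s[43:]
        a, b = align_pair(s, t)
        assert b.count("-") == 3
        P, Q, L = count_pq(a, b)
        assert L == 97 and P == 0.0 and Q == 0.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_pair("", "ACGT")


class TestGammaK2P:
    def test_zero_divergence(self):
        assert k2p_gamma_distance(0.0, 0.0, 1.0) == 0.0

    def test_closed_form_alpha_one(self):
        d = k2p_gamma_distance(0.1, 0.05, 1.0)
        assert d == pytest.approx(0.19444, abs=1e-5)

    def test_large_alpha_converges_to_plain_k2p(self):
        plain = -0.5 * math.log(1 - 0.2 - 0.05) - 0.25 * math.log(1 - 0.1)
        assert plain == pytest.approx(0.17018, abs=5e-6)
        assert k2p_gamma_distance(0.1, 0.05, 1e6) == pytest.approx(plain, abs=1e-4)

    def test_saturated_alignment_raises(self):
        with pytest.raises(SaturationError):
            k2p_gamma_distance(0.45, 0.15, 1.0)
        with pytest.raises(SaturationError):
            k2p_gamma_distance(0.1, 0.5, 1.0)

    def test_pq_agree_with_per_site_oracle_on_random_pairs(self, rng):
        """P/Q from the alignment pathway equal brute-force per-site counts
        on gapless equal-length pairs; d matches the formula to 1e-12."""
        transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
        for _ in range(100):
            n = int(rng.integers(50, 200))
            a = random_dna(rng, n)
            b = list(a)
            n_mut = int(rng.integers(0, max(2, n // 10)))
            pos = rng.choice(n, size=n_mut, replace=False)
            for p in pos:
                b[p] = "ACGT"[int(rng.integers(4))]
            b = "".join(b)
            ts = sum((x, y) in transitions for x, y in zip(a, b))
            tv = sum(
                x != y and (x, y) not in transitions for x, y in zip(a, b)
            )
            res = gamma_k2p((a, b), alpha=1.0)
            assert res.P == pytest.approx(ts / n, abs=1e-15)
            assert res.Q == pytest.approx(tv / n, abs=1e-15)
            assert res.d == pytest.approx(
                k2p_gamma_distance(ts / n, tv / n, 1.0), abs=1e-12
            )


class TestPairing:
    def test_identical_copies_give_zero_counts(self):
        s = "ACGT" * 100
        copy = LtrSeqs("a", s, s)
        other = LtrSeqs("b", s, s)
        rec = pair_substitution_counts(copy, [copy, other])
        assert rec.closest_copy_id == "b"
        assert rec.N1 == 0.0 and rec.N2 == 0.0

    def test_equidistant_candidates_tie_break_lexicographic(self, rng):
        s = random_dna(rng, 200)
        variant = s[:100] + ("A" if s[100] != "A" else "C") + s[101:]
        copy = LtrSeqs("z", s, s)
        cands = [LtrSeqs("b", variant, None), LtrSeqs("a", variant, None)]
        rec = pair_substitution_counts(copy, [copy] + cands)
        assert rec.closest_copy_id == "a"

    def test_burst_pair_counts_match_poisson_expectation(self, ltr_history, ltr_only_config):
        """For burst siblings of age a, both N1 and N2 average 2 mu a L."""
        copies, _ = ltr_history
        seqs = [LtrSeqs(c.copy_id, c.ltr5, c.ltr3) for c in copies]
        recs = ltr_pair_records(seqs, enforce_min_copies=False)
        by_id = {c.copy_id: c for c in copies}
        mu = ltr_only_config.mu
        n2_old = [
            r.N2 for r in recs
            if r.N2 is not None and by_id[r.copy_id].burst_age_my == 2.0
        ]
        expected = 2 * mu * 2.0 * 300
        assert np.mean(n2_old) == pytest.approx(expected, rel=0.15)

    def test_minimum_copy_rule_refused_with_message(self):
        seqs = [LtrSeqs(f"c{i}", "ACGT" * 50, "ACGT" * 50) for i in range(10)]
        with pytest.raises(ValueError, match="at least 100 copies"):
            ltr_pair_records(seqs, LtrConfig())
        # overridable for small studies
        recs = ltr_pair_records(seqs, LtrConfig(min_copies=5))
        assert len(recs) == 10

    def test_unpaired_without_candidates(self):
        rec = pair_substitution_counts(LtrSeqs("a", "ACGT" * 50, "ACGT" * 50), [])
        assert rec.classification == "unpaired"


class TestPoissonNull:
    def make_records(self, n2_values):
        return [
            LTRPairRecord(f"c{i}", "x", 0.0, v) for i, v in enumerate(n2_values)
        ]

    def test_zero_lambda_collapses_thresholds(self):
        null = build_poisson_null(self.make_records([0.0, 0.0]), seed=1)
        assert null.lambda_hat == 0.0
        assert (null.lower_D_threshold, null.upper_D_threshold) == (0.0, 0.0)

    def test_simulated_mean_matches_lambda(self):
        null = build_poisson_null(self.make_records([4.0] * 10), m=10000, seed=2)
        rng = np.random.default_rng(2)
        x1 = rng.poisson(4.0, 10000)
        assert abs(x1.mean() - 4.0) < 3 * math.sqrt(4.0 / 10000)
        assert null.lambda_hat == 4.0

    def test_fixed_seed_reproduces_thresholds(self):
        recs = self.make_records([2.0] * 20)
        n1 = build_poisson_null(recs, seed=7, alpha_level=0.01)
        n2 = build_poisson_null(recs, seed=7, alpha_level=0.01)
        assert (n1.upper_D_threshold, n1.lower_D_threshold) == (
            n2.upper_D_threshold, n2.lower_D_threshold
        )

    def test_skellam_tail_outlier_classified_conversion(self):
        """(N1=0, N2=20) under lambda=2: brute-force Skellam tail
        probability << 0.001, so the point must fall outside the cloud."""
        from scipy import stats

        lam = 2.0
        # P(D >= 20) for D = X2 - X1, X iid Poisson(2): pmf convolution
        tail = float(1 - stats.skellam.cdf(19, lam, lam))
        assert tail < 1e-6
        recs = self.make_records([lam] * 50)
        null = build_poisson_null(recs, m=10000, alpha_level=0.001, seed=3)
        points = [
            LTRPairRecord("bisector", "x", 2.0, 2.0),
            LTRPairRecord("conv", "x", 0.0, 20.0),
            LTRPairRecord("orphan", "x", 20.0, 0.0),
        ]
        out = {r.copy_id: r.classification for r in classify_pairs(points, null)}
        assert out == {
            "bisector": "burst",
            "conv": "conversion_candidate",
            "orphan": "parent_missing",
        }

    def test_classification_invariant_to_record_order(self):
        recs = self.make_records([2.0] * 50)
        null = build_poisson_null(recs, seed=3)
        pts = [
            LTRPairRecord("a", "x", 0.0, 15.0),
            LTRPairRecord("b", "x", 3.0, 2.0),
            LTRPairRecord("c", "x", 12.0, 1.0),
        ]
        fwd = {r.copy_id: r.classification for r in classify_pairs(pts, null)}
        rev = {r.copy_id: r.classification for r in classify_pairs(pts[::-1], null)}
        assert fwd == rev


class TestBurstClusters:
    def test_identical_copies_form_one_cluster(self):
        seqs = [LtrSeqs(f"c{i}", "ACGT" * 75, None) for i in range(10)]
        (cluster,) = burst_clusters(seqs, theta=0.01, min_size=5)
        assert cluster.size == 10

    def test_distinct_bursts_stay_disjoint(self, rng):
        anc1, anc2 = random_dna(rng, 300), random_dna(rng, 300)
        seqs = []
        for i in range(6):
            s = list(anc1)
            s[i] = "A"
            seqs.append(LtrSeqs(f"young{i}", "".join(s), None))
        for i in range(6):
            s = list(anc2)
            for p in rng.choice(300, 2, replace=False):
                s[p] = "ACGT"[int(rng.integers(4))]
            seqs.append(LtrSeqs(f"old{i}", "".join(s), None))
        clusters = burst_clusters(seqs, theta=0.01, min_size=5)
        assert len(clusters) == 2
        member_sets = [set(c.members) for c in clusters]
        assert {f"young{i}" for i in range(6)} in member_sets
        assert {f"old{i}" for i in range(6)} in member_sets

    def test_all_distant_copies_give_no_clusters(self, rng):
        seqs = [LtrSeqs(f"c{i}", random_dna(rng, 300), None) for i in range(8)]
        assert burst_clusters(seqs, theta=0.01, min_size=2) == []


class TestNrrPairDeficit:
    def test_all_nrr_copies_give_zero_deficit(self):
        recs = [
            LTRPairRecord(f"c{i}", f"c{(i + 1) % 10}", 1.0, 1.0,
                          compartment="NRR:black",
                          closest_compartment="NRR:black")
            for i in range(10)
        ]
        observed, expected, deficit = nrr_pair_deficit(recs, n_perm=200, seed=0)
        assert observed == 10
        assert deficit == pytest.approx(0.0)

    def test_constructed_avoidance_gives_full_deficit(self):
        # half the copies NRR, but every pair crosses compartments
        recs = []
        for i in range(10):
            recs.append(
                LTRPairRecord(
                    f"n{i}", f"a{i}", 1.0, 1.0,
                    compartment="NRR:black", closest_compartment="autosome",
                )
            )
            recs.append(
                LTRPairRecord(
                    f"a{i}", f"n{i}", 1.0, 1.0,
                    compartment="autosome", closest_compartment="NRR:black",
                )
            )
        observed, expected, deficit = nrr_pair_deficit(recs, n_perm=500, seed=1)
        assert observed == 0
        assert expected > 0
        assert deficit == pytest.approx(100.0)

    def test_random_labels_give_near_zero_deficit(self, rng):
        """Permutation null: with randomly assigned compartments the
        observed both-NRR count matches its permutation expectation."""
        n = 500
        labels = ["NRR:black" if rng.random() < 0.5 else "autosome"
                  for _ in range(n)]
        partners = [(i + 1) % n for i in range(n)]
        recs = [
            LTRPairRecord(f"c{i}", f"c{partners[i]}", 1.0, 1.0,
                          compartment=labels[i],
                          closest_compartment=labels[partners[i]])
            for i in range(n)
        ]
        _, _, deficit = nrr_pair_deficit(recs, n_perm=1000, seed=2)
        assert abs(deficit) < 5.0


class TestCopyAgeComparison:
    def make_records(self, n2_nrr, n2_auto):
        recs = []
        for i, v in enumerate(n2_nrr):
            recs.append(LTRPairRecord(f"n{i}", "x", 1.0, v,
                                      compartment="NRR:black", species="sp1"))
        for i, v in enumerate(n2_auto):
            recs.append(LTRPairRecord(f"a{i}", "x", 1.0, v,
                                      compartment="autosome", species="sp1"))
        return recs

    def test_identical_distributions_not_significant(self, rng):
        vals = rng.gamma(2.0, 2.0, 100)
        res = copy_age_comparison(self.make_records(vals, vals))
        tukey = [r for r in res if r.test_name.startswith("tukey")][0]
        assert tukey.adjusted_p > 0.5

    def test_planted_age_difference_detected(self, rng):
        nrr = rng.poisson(15.0, 200).astype(float)    # 5x older copies
        auto = rng.poisson(3.0, 200).astype(float)
        res = copy_age_comparison(self.make_records(nrr, auto))
        anova = [r for r in res if r.test_name.startswith("anova")][0]
        tukey = [r for r in res if r.test_name.startswith("tukey")][0]
        assert anova.p_value < 0.01
        assert tukey.adjusted_p < 0.01
        assert np.mean(nrr) > np.mean(auto)

    def test_single_compartment_is_an_error(self):
        with pytest.raises(ValueError):
            copy_age_comparison(self.make_records([1.0, 2.0], []))
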