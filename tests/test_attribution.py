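"""Dinucleotide shuffles, expected-gradient attributions, PWM scanning,
motif contribution tables and TF-set enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from enhancerkit.attribution import (
    AttributionMap,
    attribute,
    dinucleotide_shuffle,
    enrichment_test,
    motif_contribution_table,
    pwm_from_consensus,
    scan_motifs,
)
from enhancerkit.models import ArchitectureSpec, ModelEnsemble, build_model
from enhancerkit.sequences import dinucleotide_counts, one_hot, reverse_complement

TINY = ArchitectureSpec(
    conv_filters=[6, 4], conv_kernels=[7, 3], pool_size=4, dense_units=[8], dropout=0.0, input_length=60
)


class TestDinucleotideShuffle:
    def test_acgt_preserves_dinucleotide_counts(self):
        for s in dinucleotide_shuffle("ACGT", n=10, seed=1):
            assert np.array_equal(dinucleotide_counts(s), dinucleotide_counts("ACGT"))
            assert len(s) == 4

    def test_homopolymer_returns_itself_with_warning(self):
        with pytest.warns(UserWarning, match="unique"):
            out = dinucleotide_shuffle("AAAA", n=5, seed=0)
        assert out == ["AAAA"] * 5

    def test_long_random_sequence_exact_conservation(self, rng):
        seq = "".join("ACGT"[b] for b in rng.integers(0, 4, 1001))
        ref = dinucleotide_counts(seq)
        shuffles = dinucleotide_shuffle(seq, n=20, seed=3)
        assert len(set(shuffles)) > 1  # actually shuffles
        for s in shuffles:
            assert np.array_equal(dinucleotide_counts(s), ref)

    def test_deterministic_per_seed(self):
        seq = "ACGTACGGTTAACCGGATCGATCG"
        assert dinucleotide_shuffle(seq, n=5, seed=7) == dinucleotide_shuffle(seq, n=5, seed=7)

    def test_rejects_n_bases(self):
        with pytest.raises(ValueError, match="ACGT"):
            dinucleotide_shuffle("ACGTN", n=1, seed=0)


class _LinearMember:
    """f(x) = sum(w * x): attribution has a closed form."""

    def __init__(self, w):
        self.w = np.asarray(w, dtype=np.float64)
        self.head = "linear"
        self.spec = None

    def predict(self, X, output="response", batch_size=256):
        return np.tensordot(X, self.w, axes=([1, 2], [0, 1]))

    def input_gradient(self, X):
        return np.broadcast_to(self.w, X.shape).copy()


class TestAttribute:
    def test_constant_model_gives_zero_scores(self, rng):
        member = _LinearMember(np.zeros((40, 4)))
        ens = ModelEnsemble(members=[member], task="accessibility", tissue="t")
        seq = "".join("ACGT"[b] for b in rng.integers(0, 4, 40))
        amap = attribute(ens, seq, n_refs=5, steps=4, seed=0)
        assert np.allclose(amap.actual, 0.0)
        assert np.allclose(amap.hypothetical, 0.0)

    def test_completeness_exact_for_linear_model(self, rng):
        w = rng.normal(size=(40, 4))
        ens = ModelEnsemble(members=[_LinearMember(w)], task="accessibility", tissue="t")
        seq = "".join("ACGT"[b] for b in rng.integers(0, 4, 40))
        amap = attribute(ens, seq, n_refs=8, steps=4, seed=1)
        assert amap.actual.sum() == pytest.approx(amap.prediction - amap.reference_mean, rel=1e-6)
        assert amap.completeness_gap < 1e-6

    def test_motif_positions_carry_positive_score(self, rng):
        # toy model: weight mass only on a planted motif's positions/bases
        seq = list("".join("ACGT"[b] for b in rng.integers(0, 4, 40)))
        motif = "TTACGTAA"
        seq[10:18] = motif
        seq = "".join(seq)
        w = np.zeros((40, 4))
        w[np.arange(10, 18), [("ACGT".index(c)) for c in motif]] = 1.0
        ens = ModelEnsemble(members=[_LinearMember(w)], task="accessibility", tissue="t")
        amap = attribute(ens, seq, n_refs=20, steps=4, seed=2)
        pos_score = np.maximum(amap.actual, 0)
        assert pos_score[10:18].sum() / pos_score.sum() > 0.9

    def test_completeness_on_trained_cnn_within_tolerance(self, rng):
        model = build_model(TINY, seed=3)
        model.spec = TINY
        ens = ModelEnsemble(members=[model], task="accessibility", tissue="t")
        for trial in range(3):
            seq = "".join("ACGT"[b] for b in rng.integers(0, 4, 60))
            amap = attribute(ens, seq, n_refs=10, steps=500, seed=trial)
            assert amap.completeness_gap < 0.05

    def test_wrong_length_rejected(self, rng):
        model = build_model(TINY, seed=3)
        model.spec = TINY
        ens = ModelEnsemble(members=[model], task="accessibility", tissue="t")
        with pytest.raises(ValueError, match="60"):
            attribute(ens, "ACGT" * 4, n_refs=2, steps=2)


class TestScanMotifs:
    def test_exact_planted_hit_forward(self, rng):
        seq = list("".join("ACGT"[b] for b in rng.integers(0, 4, 200)))
        seq[50:58] = "CTAAATAG"
        seqs = {"s1": "".join(seq)}
        hits = scan_motifs(seqs, {"m": pwm_from_consensus("CTAAATAG")})
        fwd = hits[(hits["strand"] == "+") & (hits["start"] == 50)]
        assert len(fwd) == 1 and fwd.iloc[0]["end"] == 58

    def test_reverse_complement_hit(self, rng):
        seq = list("".join("ACGT"[b] for b in rng.integers(0, 4, 200)))
        seq[50:58] = reverse_complement("CTAAATAG")
        hits = scan_motifs({"s": "".join(seq)}, {"m": pwm_from_consensus("CTAAATAG")})
        rev = hits[(hits["strand"] == "-") & (hits["start"] == 50)]
        assert len(rev) == 1

    def test_zero_sum_pwm_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            scan_motifs({"s": "ACGTACGT"}, {"bad": np.zeros((4, 4))})

    def test_threshold_matches_brute_force_width5(self):
        # exact DP tail probability vs enumeration of all 4^5 windows
        from enhancerkit.attribution import _pwm_threshold

        rng = np.random.default_rng(4)
        pwm = rng.dirichlet(np.ones(4) * 0.5, size=5)
        bg = np.full(4, 0.25)
        logodds = np.log2((pwm + 1e-3) / (pwm + 1e-3).sum(axis=1, keepdims=True) / bg)
        int_scores = np.rint(logodds * 100).astype(int)
        for cutoff in (5e-5, 1e-3, 0.05):
            thr = _pwm_threshold(int_scores, bg, cutoff)
            scores = []
            for idx in range(4**5):
                digits = [(idx // 4**p) % 4 for p in range(5)]
                scores.append(sum(int_scores[i, d] for i, d in enumerate(digits)))
            scores = np.array(scores)
            # exceedance probability under the uniform background
            assert (scores >= thr).mean() <= cutoff
            if thr > scores.min():
                assert (scores >= thr - 1).mean() > cutoff or (scores >= thr).mean() == 0


class TestMotifContributionTable:
    @staticmethod
    def _inputs(pwm_means):
        """One instance per PWM in its own 10-bp window of one sequence."""
        n = len(pwm_means)
        instances = pd.DataFrame(
            {
                "seq_id": "s",
                "start": [10 * i for i in range(n)],
                "end": [10 * i + 8 for i in range(n)],
                "strand": "+",
                "pwm_id": [f"p{i}" for i in range(n)],
                "score": 10.0,
            }
        )
        vec = np.zeros(10 * n)
        for i, m in enumerate(pwm_means):
            vec[10 * i : 10 * i + 8] = m
        actuals = {"accessibility": {"heart": {"s": vec}}, "activity": {"heart": {"s": vec}}}
        return instances, actuals

    def test_identical_means_give_zero_z_nothing_retained(self):
        instances, actuals = self._inputs([1.0] * 6)
        out = motif_contribution_table(instances, actuals, z_min=2.0)
        assert np.allclose(out.table.filter(like="z_").to_numpy(), 0.0)
        assert len(out.retained) == 0

    def test_outlier_pwm_retained_as_group_representative(self):
        means = [0.0, 0.01, -0.01, 0.02, -0.02, 5.0]
        instances, actuals = self._inputs(means)
        groups = {f"p{i}": "grp" if i >= 4 else f"p{i}" for i in range(6)}
        out = motif_contribution_table(instances, actuals, z_min=2.0, redundancy_groups=groups)
        assert list(out.retained.index) == ["p5"]

    def test_empty_instance_pwm_dropped(self):
        instances, actuals = self._inputs([1.0, 2.0, 3.0])
        instances = pd.concat(
            [instances, pd.DataFrame([{"seq_id": "missing", "start": 0, "end": 8, "strand": "+",
                                       "pwm_id": "ghost", "score": 1.0}])],
            ignore_index=True,
        )
        out = motif_contribution_table(instances, actuals, z_min=2.0)
        assert "ghost" in out.dropped_pwms


class TestEnrichment:
    def test_cluster_equals_category_is_extreme(self):
        background = {f"tf{i}" for i in range(100)}
        cluster = {f"tf{i}" for i in range(10)}
        df = enrichment_test({"c1": cluster}, {"g1": cluster}, background)
        assert df.iloc[0]["p_value"] < 1e-10
        assert np.isinf(df.iloc[0]["odds_ratio"]) or df.iloc[0]["odds_ratio"] > 100

    def test_matches_hypergeometric_oracle(self):
        # table a=5, b=5, c=5, d=585 from a background of 600
        background = {f"tf{i}" for i in range(600)}
        cluster = {f"tf{i}" for i in range(10)}  # 5 in category, 5 out
        category = {f"tf{i}" for i in range(5)} | {f"tf{i}" for i in range(10, 15)}
        df = enrichment_test({"c": cluster}, {"g": category}, background)
        # P(X >= 5) with M=600, n=10 draws, K=10 category members
        oracle = stats.hypergeom.sf(4, 600, 10, 10)
        assert df.iloc[0]["p_value"] == pytest.approx(oracle, abs=1e-10)

    def test_fisher_matches_hypergeometric_on_small_tables(self, rng):
        background = {f"tf{i}" for i in range(50)}
        for _ in range(20):
            cl = set(rng.choice(sorted(background), size=rng.integers(2, 20), replace=False))
            cat = set(rng.choice(sorted(background), size=rng.integers(2, 20), replace=False))
            df = enrichment_test({"c": cl}, {"g": cat}, background)
            a = len(cl & cat)
            oracle = stats.hypergeom.sf(a - 1, 50, len(cat), len(cl))
            assert df.iloc[0]["p_value"] == pytest.approx(oracle, rel=1e-9, abs=1e-12)

    def test_independent_sets_rarely_survive_fdr(self, rng):
        background = {f"tf{i}" for i in range(200)}
        clusters = {
            f"c{j}": set(rng.choice(sorted(background), size=20, replace=False)) for j in range(10)
        }
        categories = {
            f"g{j}": set(rng.choice(sorted(background), size=20, replace=False)) for j in range(10)
        }
        df = enrichment_test(clusters, categories, background)
        assert len(df) == 100
        assert (df["p_value"] < 0.05).sum() <= 15  # ~5 expected
        assert df["significant"].sum() <= 2  # ~0 after FDR

    def test_empty_background_raises(self):
        with pytest.raises(ValueError, match="background"):
            enrichment_test({"c": set()}, {"g": set()}, set())
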