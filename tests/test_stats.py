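"""Mann-Whitney, Bonferroni, Pearson, ROC and the contrast-plan driver."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvniche import blind_labels, bonferroni, mann_whitney, pearson, roc, run_comparisons

from conftest import auc_concordance, exact_mwu_p, u_statistic


class TestMannWhitney:
    def test_fully_separated_exact_p(self):
        """a={1,2,3} vs b={4,5,6}: U=0, exact two-sided p = 2/20."""
        r = mann_whitney([1, 2, 3], [4, 5, 6])
        assert r.U in (0.0, 9.0)
        assert r.p_raw == pytest.approx(0.1)
        assert r.p_raw == pytest.approx(exact_mwu_p([1, 2, 3], [4, 5, 6]))

    def test_symmetric_samples_p_one(self):
        """Perfectly interleaved tie-free samples: U = n²/2, exact p = 1."""
        r = mann_whitney([1, 4, 6, 7], [2, 3, 5, 8])
        assert r.U == pytest.approx(8.0)
        assert r.p_raw == pytest.approx(1.0)

    def test_identical_multisets_near_one(self):
        """Identical samples: U = n²/2; ties force the corrected normal
        approximation, which stays close to (but below) 1."""
        r = mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert r.U == pytest.approx(8.0)
        assert r.p_raw > 0.8

    def test_exact_matches_enumeration(self, rng):
        """Exact p equals full enumeration for several tie-free layouts."""
        for _ in range(5):
            a = list(rng.permutation(100)[:5] + rng.random(5))
            b = list(rng.permutation(100)[:6] + rng.random(6))
            r = mann_whitney(a, b)
            assert r.p_raw == pytest.approx(exact_mwu_p(a, b), abs=1e-12)

    def test_large_sample_approx_near_exact(self, rng):
        """Normal approximation within 0.01 of enumeration at n=8+8."""
        a = list(rng.normal(0, 1, 8))
        b = list(rng.normal(0.8, 1, 8))
        r = mann_whitney(a, b)  # n=16 > 12 → asymptotic path
        assert r.p_raw == pytest.approx(exact_mwu_p(a, b), abs=0.01)

    def test_u_range_and_statistic(self, rng):
        a, b = list(rng.random(7)), list(rng.random(9))
        r = mann_whitney(a, b)
        assert 0 <= r.U <= 7 * 9
        assert r.U == pytest.approx(u_statistic(a, b))

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.integers(0, 1000), min_size=2, max_size=6, unique=True),
        st.lists(st.integers(1001, 2000), min_size=2, max_size=6, unique=True),
        st.sampled_from(["exp", "cube", "affine"]),
    )
    def test_invariant_under_monotone_transform(self, a, b, transform):
        f = {"exp": lambda v: np.exp(v / 500.0), "cube": lambda v: v**3,
             "affine": lambda v: 3.0 * v + 17.0}[transform]
        r1 = mann_whitney(a, b)
        r2 = mann_whitney(f(np.array(a, float)), f(np.array(b, float)))
        assert r1.U == pytest.approx(r2.U)
        assert r1.p_raw == pytest.approx(r2.p_raw)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty or all-NA"):
            mann_whitney([], [1.0])
        with pytest.raises(ValueError, match="empty or all-NA"):
            mann_whitney([np.nan, np.nan], [1.0])


class TestBonferroni:
    def test_multiplication(self):
        assert bonferroni([0.01], 4)[0] == pytest.approx(0.04)

    def test_clipping_at_one(self):
        assert bonferroni([0.5], 4)[0] == 1.0

    def test_family_of_one_unchanged(self):
        assert bonferroni([0.321], 1)[0] == pytest.approx(0.321)

    def test_never_decreases_and_order_preserving(self, rng):
        p = np.sort(rng.random(20))
        adj = bonferroni(p, 20)
        assert np.all(adj >= p)
        assert np.all(np.diff(adj) >= 0)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([1.2], 2)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p = pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_perfect_negative(self):
        x = np.arange(5.0)
        r, _ = pearson(x, -x)
        assert r == pytest.approx(-1.0)

    def test_orthogonal_pattern(self):
        r, p = pearson([-1, 0, 1], [1, -2, 1])
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_is_error_not_nan(self):
        with pytest.raises(ValueError, match="zero-variance"):
            pearson([1, 1, 1], [1, 2, 3])


class TestRoc:
    def test_perfect_separation(self):
        r = roc([1, 2, 3, 10, 11, 12], ["n", "n", "n", "p", "p", "p"], "p")
        assert r.auc == pytest.approx(1.0)
        assert r.quality.startswith("good")

    def test_half_interleaved(self):
        """scores {1,2,3,4}: labels −−++ → AUC 1; −+−+ → AUC 0.75."""
        r1 = roc([1, 2, 3, 4], ["n", "n", "p", "p"], "p")
        r2 = roc([1, 2, 3, 4], ["n", "p", "n", "p"], "p")
        assert r1.auc == pytest.approx(1.0)
        assert r2.auc == pytest.approx(0.75)

    def test_random_scores_near_half(self, rng):
        scores = rng.random(2000)
        labels = rng.choice(["p", "n"], 2000)
        r = roc(scores, labels, "p")
        assert r.auc == pytest.approx(0.5, abs=0.05)

    def test_matches_concordance_count(self, rng):
        scores = rng.normal(size=40)
        labels = rng.choice(["p", "n"], 40)
        r = roc(scores, labels, "p")
        assert r.auc == pytest.approx(auc_concordance(scores, labels, "p"))

    def test_auc_u_identity(self, rng):
        """AUC × n₁·n₂ equals the Mann-Whitney U on tie-free data."""
        scores = rng.permutation(50).astype(float)
        labels = np.array(["p"] * 20 + ["n"] * 30)
        r = roc(scores, labels, "p")
        u = mann_whitney(scores[labels == "p"], scores[labels == "n"]).U
        assert r.auc * 20 * 30 == pytest.approx(u)

    def test_inverted_scores_flagged_not_flipped(self):
        r = roc([10, 11, 12, 1, 2, 3], ["n", "n", "n", "p", "p", "p"], "p")
        assert r.auc == pytest.approx(0.0)
        assert r.inverted

    def test_curve_endpoints(self, rng):
        r = roc(rng.random(30), ["p"] * 15 + ["n"] * 15, "p")
        assert (r.fpr[0], r.tpr[0]) == (0.0, 0.0)
        assert (r.fpr[-1], r.tpr[-1]) == (1.0, 1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc([1, 2], ["p", "p"], "p")


class TestRunComparisons:
    def _tumor_table(self, rng, effect=1.0):
        rows = []
        for grp, treat, out in [("NAC_DF", "NAC", "DF"), ("NAC_Mets", "NAC", "Mets")]:
            for t in range(6):
                base = rng.normal(100, 10)
                rows.append(
                    {"tumor_id": f"{grp}_T{t}", "group": grp, "treatment": treat,
                     "outcome": out, "compartment": "STROMA_PV", "selector": "TAM",
                     "value": base * (effect if grp == "NAC_DF" else 1.0)}
                )
        return pd.DataFrame(rows)

    def test_family_size_applied_to_each_row(self, rng):
        plan = [{
            "name": "blockA",
            "contrasts": [
                {"selector": "TAM", "compartment": "STROMA_PV",
                 "group_by": "outcome", "arms": ["DF", "Mets"]},
            ] * 3,
        }]
        out = run_comparisons(self._tumor_table(rng), plan)
        assert len(out) == 3
        assert (out["family_size"] == 3).all()
        assert np.allclose(out["p_adjusted"],
                           np.minimum(1.0, out["p_raw"] * 3))

    def test_detects_large_effect(self, rng):
        plan = [{"name": "b", "contrasts": [
            {"selector": "TAM", "compartment": "STROMA_PV",
             "group_by": "outcome", "arms": ["DF", "Mets"]}]}]
        out = run_comparisons(self._tumor_table(rng, effect=5.0), plan)
        assert bool(out["significant"].iloc[0])

    def test_empty_arm_rejected(self, rng):
        plan = [{"name": "b", "contrasts": [
            {"selector": "TAM", "compartment": "STROMA_PV",
             "group_by": "outcome", "arms": ["DF", "NoSuch"]}]}]
        with pytest.raises(ValueError, match="no tumors"):
            run_comparisons(self._tumor_table(rng), plan)

    def test_paired_compartment_contrast(self, rng):
        tt = self._tumor_table(rng)
        far = tt.copy()
        far["compartment"] = "STROMA_NONPV"
        far["value"] = far["value"] * 0.1
        plan = [{"name": "pv", "contrasts": [
            {"selector": "TAM", "compartment_a": "STROMA_PV",
             "compartment_b": "STROMA_NONPV", "where": {"treatment": "NAC"}}]}]
        out = run_comparisons(pd.concat([tt, far]), plan)
        assert bool(out["significant"].iloc[0])


class TestBlinding:
    def test_codes_hide_and_key_restores(self, rng):
        table = pd.DataFrame(
            {"tumor_id": ["a", "b", "c", "d"],
             "group": ["NAC_DF", "NAC_Mets", "untreated_DF", "untreated_Mets"],
             "treatment": ["NAC", "NAC", "untreated", "untreated"],
             "outcome": ["DF", "Mets", "DF", "Mets"]}
        )
        blinded, key = blind_labels(table, rng)
        assert set(blinded["group"]) == {"G1", "G2", "G3", "G4"}
        restored = blinded["group"].map(key)
        assert sorted(restored) == sorted(table["group"])
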