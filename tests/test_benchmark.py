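"""Power/FPR counting, control masking, subsampling and the grid runner."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from keju.benchmark import (MaskingPlan, apply_masking, compute_fpr,
                            compute_power, mask_negative_controls, run_grid,
                            stratify_significance, subsample_barcodes,
                            summarize_grid)
from keju.data import CountTable
from conftest import make_toy_frame


def calls_frame(significant, others=()):
    enh = list(significant) + list(others)
    return pd.DataFrame({
        "enhancer": enh,
        "post_mean": np.linspace(1, 0.1, len(enh)),
        "lfsr": [0.01] * len(significant) + [0.4] * len(others),
        "significant": [True] * len(significant) + [False] * len(others),
    })


class TestPower:
    def test_counting_oracle(self):
        calls = calls_frame(["a", "b"], ["c"])
        assert compute_power(calls, {"a", "b", "c"}) == pytest.approx(2 / 3)

    def test_bounds(self):
        assert compute_power(calls_frame(["a", "b", "c"]), {"a", "b"}) == 1.0
        assert compute_power(calls_frame([], ["a", "b"]), {"a", "b"}) == 0.0

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_power(calls_frame(["a"]), set())


class TestMasking:
    def test_half_split_of_306_controls(self):
        controls = [f"c{i}" for i in range(306)]
        plans = mask_negative_controls(controls, n_reps=10, seed=1)
        assert len(plans) == 10
        for plan in plans:
            assert len(plan.masked) == 153 and len(plan.labeled) == 153
            assert plan.masked | plan.labeled == set(controls)
            assert not plan.masked & plan.labeled

    def test_odd_count_split_rule(self):
        plans = mask_negative_controls([f"c{i}" for i in range(5)],
                                       n_reps=3, seed=0)
        for plan in plans:
            assert sorted([len(plan.labeled), len(plan.masked)]) == [2, 3]

    def test_same_seed_gives_identical_plans(self):
        a = mask_negative_controls(["c1", "c2", "c3", "c4"], 5, seed=7)
        b = mask_negative_controls(["c1", "c2", "c3", "c4"], 5, seed=7)
        assert a == b
        c = mask_negative_controls(["c1", "c2", "c3", "c4"], 5, seed=8)
        assert a != c

    def test_too_few_controls_rejected(self):
        with pytest.raises(ValueError, match="2"):
            mask_negative_controls(["only"], 3, seed=0)

    def test_plan_invariants_enforced(self):
        with pytest.raises(ValueError):
            MaskingPlan(0, frozenset("ab"), frozenset("bc"), 0)
        with pytest.raises(ValueError):
            MaskingPlan(0, frozenset("abc"), frozenset("d"), 0)

    def test_apply_masking_relabels_and_pseudo_motifs(self):
        df = make_toy_frame(n_enhancers=4, controls=("e0", "e1"),
                            motifs=True)
        table = CountTable(df)
        plan = MaskingPlan(0, frozenset(["e0"]), frozenset(["e1"]), 0)
        masked = apply_masking(table, plan)
        assert masked.control_enhancers == ["e0"]
        assert "e1" in masked.candidate_enhancers
        motif_of = masked.enhancer_label_map("motif")
        assert motif_of["e1"].startswith("masked_")
        kept = apply_masking(table, plan, motif_handling="keep")
        assert not kept.enhancer_label_map("motif")["e1"].startswith("masked")


class TestFpr:
    def test_counting_oracle(self):
        masked = frozenset(f"m{i}" for i in range(100))
        labeled = frozenset(f"l{i}" for i in range(100))
        sig = [f"m{i}" for i in range(10)]
        rest = sorted(masked - set(sig))
        plan = MaskingPlan(0, labeled, masked, 0)
        assert compute_fpr(calls_frame(sig, rest), plan) == pytest.approx(0.1)

    def test_none_significant_gives_zero(self):
        masked = frozenset(["m1", "m2"])
        plan = MaskingPlan(0, frozenset(["l1", "l2"]), masked, 0)
        assert compute_fpr(calls_frame([], sorted(masked)), plan) == 0.0

    def test_missing_masked_control_rejected(self):
        plan = MaskingPlan(0, frozenset(["l1"]), frozenset(["m1", "m2"]), 0)
        with pytest.raises(ValueError, match="missing"):
            compute_fpr(calls_frame(["m1"]), plan)


class TestSubsampleBarcodes:
    def _numbered(self, n_bc, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for j in rng.permutation(n_bc):       # shuffled row order
            rows.append({"barcode": f"bc{j+1}",
                         "dna_count": int(rng.integers(1, 50)),
                         "rna_count": int(rng.integers(1, 50)),
                         "enhancer": "e1", "rna_batch": "b1",
                         "dna_batch": "d1", "condition": "control"})
        return CountTable(pd.DataFrame(rows))

    def test_small_enhancers_unchanged(self):
        t = self._numbered(7)
        assert len(subsample_barcodes(t, 10)) == 7

    def test_numbered_selection_keeps_lowest_indices(self):
        t = self._numbered(100)
        sub = subsample_barcodes(t, 25)
        kept = {int(b[2:]) for b in sub.frame["barcode"]}
        assert kept == set(range(1, 26))

    def test_cap_at_or_above_size_is_identity(self):
        t = self._numbered(40)
        assert subsample_barcodes(t, 100).frame.equals(t.frame)

    @given(st.integers(0, 2 ** 31 - 1), st.integers(1, 8))
    @settings(max_examples=20, deadline=None)
    def test_matches_brute_force_selection(self, seed, cap):
        df = make_toy_frame(n_enhancers=3, barcodes=6, seed=seed)
        sub = subsample_barcodes(CountTable(df), cap)
        for e, grp in df.groupby("enhancer"):
            want = set(sorted(grp["barcode"].unique(),
                              key=lambda b: int(b.rsplit("bc", 1)[-1]))[:cap])
            got = set(sub.frame.loc[sub.frame["enhancer"] == e, "barcode"])
            assert got == want


class FakeFitter:
    """Deterministic stand-in for the MCMC fit in bookkeeping tests."""

    def __init__(self):
        self.n_fits = 0

    def __call__(self, table, G, prior=None, threshold=0.05, **kwargs):
        self.n_fits += 1
        cands = table.candidate_enhancers
        return pd.DataFrame({
            "enhancer": cands,
            "post_mean": np.ones(len(cands)),
            "lfsr": np.zeros(len(cands)),
            "significant": True,
        })


class TestRunGrid:
    def _table(self):
        return CountTable(make_toy_frame(n_enhancers=5, barcodes=6,
                                         controls=("e0", "e1"), motifs=True,
                                         covariates=True, seed=3))

    def test_grid_bookkeeping_counts(self):
        fitter = FakeFitter()
        plans = mask_negative_controls(["e0", "e1"], n_reps=2, seed=0)
        out = run_grid(self._table(), G_values=[1, 3], caps=[2, 6],
                       fitter=fitter, masking_plans=plans, truth_G=3)
        assert (out["metric"] == "power").sum() == 4
        assert (out["metric"] == "fpr").sum() == 4 * 2
        assert out["value"].between(0, 1).all()

    def test_anchor_cell_reuses_truth_fit(self):
        fitter = FakeFitter()
        out = run_grid(self._table(), G_values=[3], caps=[6], fitter=fitter,
                       truth_G=3)
        assert fitter.n_fits == 1       # truth fit only; cell reused
        anchor = out[(out["G"] == 3) & (out["cap"] == 6)]
        assert (anchor["value"] == 1.0).all()

    def test_summary_reports_mean_and_se(self):
        res = pd.DataFrame({
            "metric": ["fpr"] * 4, "G": [1] * 4, "cap": [10] * 4,
            "value": [0.0, 0.1, 0.2, 0.1], "replicate": range(4),
        })
        summ = summarize_grid(res)
        assert summ["mean"].iloc[0] == pytest.approx(0.1)
        assert summ["se"].iloc[0] == pytest.approx(
            np.std([0.0, 0.1, 0.2, 0.1], ddof=1) / 2)


class TestStratification:
    def test_decile_fractions(self):
        df = make_toy_frame(n_enhancers=20, barcodes=4, covariates=True,
                            seed=5)
        table = CountTable(df)
        calls = pd.DataFrame({
            "enhancer": [f"e{i}" for i in range(20)],
            "covariate": [f"p{i % 2}" for i in range(20)],
            "significant": [i % 3 == 0 for i in range(20)],
        })
        out = stratify_significance(calls, table, n_bins=5)
        assert out["frac_significant"].between(0, 1).all()
        assert out["n"].sum() == 20
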