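"""Preprocessing: reading, validation, filtering, normalization, designs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from keju.data import (CountTable, SchemaError, ValidationError,
                       assign_dispersion_bins, build_design_matrices,
                       compute_dna_offsets, filter_low_coverage,
                       read_count_table, upper_quartile_size_factors)
from conftest import make_toy_frame


# ---------------------------------------------------------------- reading
class TestReadCountTable:
    def test_round_trip_identity(self, tmp_path):
        df = make_toy_frame(n_enhancers=2, barcodes=3, rna_batches=("b1",))
        path = tmp_path / "counts.tsv"
        df.to_csv(path, sep="\t", index=False)
        table = read_count_table(path)
        assert len(table) == 6
        pd.testing.assert_frame_equal(
            table.frame[df.columns].reset_index(drop=True), df)

    def test_negative_count_rejected(self, tmp_path):
        df = make_toy_frame(n_enhancers=2, barcodes=2, rna_batches=("b1",))
        df.loc[0, "rna_count"] = -3
        path = tmp_path / "bad.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValidationError, match="negative"):
            read_count_table(path)

    def test_missing_column_is_schema_error(self, tmp_path):
        df = make_toy_frame().drop(columns=["dna_batch"])
        path = tmp_path / "bad.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(SchemaError, match="dna_batch"):
            read_count_table(path)

    def test_schema_remapping(self, tmp_path):
        df = make_toy_frame(n_enhancers=2, barcodes=2, rna_batches=("b1",))
        df = df.rename(columns={"barcode": "BC", "dna_count": "plasmid"})
        path = tmp_path / "renamed.csv"
        df.to_csv(path, index=False)
        table = read_count_table(path, schema={"barcode": "BC",
                                               "dna_count": "plasmid"})
        assert "barcode" in table.frame.columns

    def test_pooled_dna_counts_filled_from_matching_barcode(self, tmp_path):
        """1 DNA pool, 3 RNA batches, 4 barcodes: 12 rows, DNA joined in."""
        rng = np.random.default_rng(5)
        barcodes = [f"bc{i}" for i in range(4)]
        dna = {bc: int(rng.integers(10, 80)) for bc in barcodes}
        rows = []
        for b_i, rb in enumerate(["r1", "r2", "r3"]):
            for bc in barcodes:
                rows.append({
                    "barcode": bc,
                    # DNA present only in the first batch's rows
                    "dna_count": dna[bc] if b_i == 0 else np.nan,
                    "rna_count": int(rng.integers(0, 100)),
                    "enhancer": "e1", "rna_batch": rb, "dna_batch": "pool",
                    "condition": "control",
                })
        path = tmp_path / "pooled.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        table = read_count_table(path)
        assert len(table) == 12
        # row-wise join oracle: every row carries its barcode's DNA count
        for _, row in table.frame.iterrows():
            assert row["dna_count"] == dna[row["barcode"]]

    def test_duplicate_barcode_batch_rejected(self):
        df = make_toy_frame(n_enhancers=1, barcodes=2, rna_batches=("b1",))
        dup = pd.concat([df, df.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValidationError, match="duplicate"):
            CountTable(dup)


# ---------------------------------------------------------------- filtering
def brute_force_filter(df, floor, min_avg):
    """Independent per-enhancer recomputation of the coverage rule."""
    n_batches = df["rna_batch"].nunique()
    kept = []
    for e, sub in df.groupby("enhancer"):
        ok = ((sub["dna_count"] > floor) & (sub["rna_count"] > floor)).sum()
        if ok / n_batches >= min_avg:
            kept.append(e)
    return set(kept)


class TestFilterLowCoverage:
    def _table(self, per_batch_qualifying):
        """Enhancer 'e' with given qualifying barcode counts per batch."""
        rows = []
        for b_i, n_ok in enumerate(per_batch_qualifying):
            for j in range(12):
                good = j < n_ok
                rows.append({
                    "barcode": f"bc{j}", "dna_count": 50 if good else 1,
                    "rna_count": 50 if good else 1, "enhancer": "e",
                    "rna_batch": f"b{b_i}", "dna_batch": f"d{b_i}",
                    "condition": "control",
                })
        return CountTable(pd.DataFrame(rows))

    def test_enhancer_above_threshold_retained(self):
        out, removed = filter_low_coverage(self._table([12, 12]))
        assert removed == [] and len(out.enhancers) == 1

    def test_average_below_threshold_removed(self):
        # 12 qualifying in batch 1, 6 in batch 2: average 9 < 10
        out, removed = filter_low_coverage(self._table([12, 6]))
        assert removed == ["e"] and len(out) == 0

    def test_all_low_counts_gives_empty_output(self):
        out, removed = filter_low_coverage(self._table([0, 0]))
        assert len(out) == 0 and removed == ["e"]

    def test_empty_table_warns(self):
        empty = CountTable(make_toy_frame().iloc[:0])
        with pytest.warns(UserWarning):
            out, removed = filter_low_coverage(empty)
        assert len(out) == 0

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_brute_force_on_random_tables(self, seed):
        df = make_toy_frame(n_enhancers=6, barcodes=8, seed=seed)
        out, removed = filter_low_coverage(CountTable(df), count_floor=20,
                                           min_avg_barcodes=3)
        expected = brute_force_filter(df, 20, 3)
        assert set(out.enhancers) == expected
        assert set(removed) == set(df["enhancer"]) - expected


# ---------------------------------------------------------------- size factors
class TestUpperQuartile:
    def _two_batch(self, counts_a, counts_b):
        rows = []
        for b, counts in (("b1", counts_a), ("b2", counts_b)):
            for j, c in enumerate(counts):
                rows.append({"barcode": f"bc{j}", "dna_count": 10,
                             "rna_count": c, "enhancer": "e1",
                             "rna_batch": b, "dna_batch": "d1",
                             "condition": "control"})
        return CountTable(pd.DataFrame(rows))

    def test_identical_batches_get_unit_factors(self):
        sf = upper_quartile_size_factors(self._two_batch([1, 5, 9, 13],
                                                         [1, 5, 9, 13]))
        np.testing.assert_allclose(sf.rna.to_numpy(), [1.0, 1.0])

    def test_scale_equivariance(self):
        a = [3, 8, 21, 40, 55]
        sf = upper_quartile_size_factors(
            self._two_batch(a, [2 * x for x in a]))
        assert sf.rna["b2"] / sf.rna["b1"] == pytest.approx(2.0)

    def test_percentile_oracle(self):
        # brute-force 75th percentile (linear interpolation) per batch
        a, b = [1, 2, 3, 4, 100], [1, 2, 3, 8, 100]
        sf = upper_quartile_size_factors(self._two_batch(a, b))
        qa, qb = np.percentile(a, 75), np.percentile(b, 75)
        assert sf.rna["b2"] / sf.rna["b1"] == pytest.approx(qb / qa)
        assert qa == 4.0 and qb == 8.0     # the 4:8 pre-rescaling ratio
        assert sf.rna.mean() == pytest.approx(1.0)

    def test_zero_upper_quartile_names_batch(self):
        with pytest.raises(ValidationError, match="b1"):
            upper_quartile_size_factors(self._two_batch([0, 0, 0, 0],
                                                        [5, 6, 7, 8]))

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_invariant_to_row_order_and_barcode_labels(self, seed):
        rng = np.random.default_rng(seed)
        df = make_toy_frame(n_enhancers=5, barcodes=6, seed=seed)
        base = upper_quartile_size_factors(CountTable(df))
        shuffled = df.sample(frac=1, random_state=rng.integers(1e6))
        shuffled = shuffled.assign(
            barcode=shuffled["barcode"].astype(str) + "_x")
        perm = upper_quartile_size_factors(
            CountTable(shuffled.reset_index(drop=True)))
        pd.testing.assert_series_equal(base.rna, perm.rna)
        pd.testing.assert_series_equal(base.dna, perm.dna)


# ---------------------------------------------------------------- offsets
class TestDnaOffsets:
    def test_zero_count_floor_and_arithmetic(self, toy_table):
        sf = upper_quartile_size_factors(toy_table)
        sf.dna[:] = 1.0
        df = toy_table.frame.copy()
        df.loc[0, "dna_count"] = 0
        df.loc[1, "dna_count"] = 9
        t = CountTable(df)
        d = compute_dna_offsets(t, sf, pseudocount=1)
        assert d[0] == pytest.approx(1.0)          # floor case
        sf.dna[:] = 2.0
        d = compute_dna_offsets(t, sf, pseudocount=1)
        assert d[1] == pytest.approx(5.0)          # (9 + 1) / 2
        assert (d > 0).all()

    def test_exact_equivariance_without_pseudocount(self, toy_table):
        sf = upper_quartile_size_factors(toy_table)
        d1 = compute_dna_offsets(toy_table, sf, pseudocount=0)
        doubled = toy_table.frame.copy()
        doubled["dna_count"] *= 2
        sf2 = sf
        sf2.dna[:] = sf.dna * 2
        d2 = compute_dna_offsets(CountTable(doubled), sf2, pseudocount=0)
        np.testing.assert_allclose(d1, d2)


# ---------------------------------------------------------------- binning
class TestDispersionBins:
    def test_g1_gives_one_bin_per_enhancer_batch(self, toy_table):
        bm = assign_dispersion_bins(toy_table, G=1)
        n_pairs = len(toy_table.frame[["enhancer", "rna_batch"]]
                      .drop_duplicates())
        assert bm.n_bins == n_pairs
        assert bm.frame["bin"].nunique() == n_pairs

    def test_seven_enhancers_chunk_into_3_3_1(self):
        df = make_toy_frame(n_enhancers=7, barcodes=2, rna_batches=("b1",))
        bm = assign_dispersion_bins(CountTable(df), G=3)
        sizes = sorted(bm.frame.groupby("bin").size().tolist())
        assert sizes == [1, 3, 3]

    def test_bin_means_nondecreasing_within_batch(self, toy_table):
        bm = assign_dispersion_bins(toy_table, G=2)
        df = toy_table.frame
        means = df.groupby(["rna_batch", "enhancer"])["rna_count"].mean()
        merged = bm.frame.assign(
            mean=[means[(b, e)] for e, b in
                  zip(bm.frame["enhancer"], bm.frame["rna_batch"])])
        for _, sub in merged.groupby("rna_batch"):
            bin_means = sub.groupby("bin")["mean"].mean()
            assert (bin_means.sort_index().diff().dropna() >= 0).all()

    def test_bins_partition_each_batch(self, toy_table):
        bm = assign_dispersion_bins(toy_table, G=3)
        for batch, sub in bm.frame.groupby("rna_batch"):
            enh_in_batch = set(
                toy_table.frame.loc[toy_table.frame["rna_batch"] == batch,
                                    "enhancer"])
            assert set(sub["enhancer"]) == enh_in_batch
            assert not sub.duplicated(subset=["enhancer"]).any()
        # no bin spans batches
        spans = bm.frame.groupby("bin")["rna_batch"].nunique()
        assert (spans == 1).all()

    def test_invalid_G_rejected(self, toy_table):
        with pytest.raises(ValueError, match="G"):
            assign_dispersion_bins(toy_table, G=0)


# ---------------------------------------------------------------- designs
class TestDesignMatrices:
    def test_all_control_condition_gives_zero_matrices(self):
        df = make_toy_frame(covariates=True)
        df["condition"] = "control"
        X, Y, _, _ = build_design_matrices(CountTable(df))
        assert not X.any() and not Y.any()

    def test_counting_oracle_on_mixed_fixture(self):
        df = make_toy_frame(n_enhancers=2, barcodes=4, covariates=True,
                            controls=("e0",))
        df["covariate"] = "p0"
        table = CountTable(df)
        X, Y, candidates, covariates = build_design_matrices(table)
        assert candidates == ["e1"] and covariates == ["p0"]
        alt = df["condition"] == "alternate"
        assert X.sum() == (alt & (df["enhancer"] == "e1")).sum()
        assert Y.sum() == alt.sum()

    def test_negative_controls_never_enter_X(self, small_dataset):
        table, truth = small_dataset
        X, _, candidates, _ = build_design_matrices(table)
        assert set(candidates).isdisjoint(table.control_enhancers)
        ctrl_rows = table.frame["is_control"].to_numpy()
        assert not X[ctrl_rows].any()

    def test_row_sums_zero_exactly_on_control_condition(self, small_dataset):
        table, _ = small_dataset
        X, Y, _, _ = build_design_matrices(table)
        assert set(np.unique(X.sum(axis=1))) <= {0, 1}
        assert set(np.unique(Y.sum(axis=1))) <= {0, 1}
        ctrl = (table.frame["condition"] == "control").to_numpy()
        assert not Y[ctrl].any()
        assert Y[~ctrl].sum(axis=1).all()   # every alternate row hits Y

    def test_partial_covariate_labels_rejected(self):
        df = make_toy_frame(covariates=True)
        df.loc[0, "covariate"] = np.nan
        with pytest.raises(ValidationError, match="covariate"):
            CountTable(df)
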