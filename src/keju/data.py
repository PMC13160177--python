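"""Reading, validation, filtering and normalization of barcode-level MPRA counts.

The central container is :class:`CountTable`, a thin validated wrapper around
a pandas DataFrame with one row per barcode observation: a DNA count, an RNA
count, and labels mapping the observation to its enhancer, RNA batch, DNA
batch, condition and (optionally) motif, covariate (e.g. minimal promoter)
and negative-control status.

From a validated table the preprocessing pipeline produces a
:class:`ModelInput`: upper-quartile size factors per batch, DNA offsets
``d_n = (D_n + pseudocount) / S_bd``, a batch-specific dispersion bin map
grouping enhancers by mean RNA count, and the indicator design matrices for
effect sizes (X) and covariate correction factors (Y).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CountTable", "SizeFactors", "BinMap", "ModelInput",
    "read_count_table", "filter_low_coverage", "upper_quartile_size_factors",
    "compute_dna_offsets", "assign_dispersion_bins", "build_design_matrices",
    "prepare_model_input",
]

REQUIRED_COLUMNS = ("barcode", "dna_count", "rna_count", "enhancer",
                    "rna_batch", "dna_batch", "condition")
OPTIONAL_COLUMNS = ("motif", "covariate", "is_control")
CONDITIONS = ("control", "alternate")


class SchemaError(ValueError):
    """A required column is missing or misnamed."""


class ValidationError(ValueError):
    """The table violates a structural invariant."""


@dataclass
class CountTable:
    """Validated barcode-level count observations.

    Attributes
    ----------
    frame : pandas.DataFrame
        Canonical columns: barcode, dna_count, rna_count, enhancer,
        rna_batch, dna_batch, condition, and optionally motif, covariate,
        is_control.  One row per (barcode, RNA batch) observation.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    @property
    def has_motifs(self) -> bool:
        return "motif" in self.frame.columns

    @property
    def has_covariates(self) -> bool:
        return "covariate" in self.frame.columns

    @property
    def enhancers(self) -> list:
        return sorted(self.frame["enhancer"].unique().tolist(), key=str)

    @property
    def control_enhancers(self) -> list:
        if "is_control" not in self.frame.columns:
            return []
        mask = self.frame["is_control"].astype(bool)
        return sorted(self.frame.loc[mask, "enhancer"].unique().tolist(),
                      key=str)

    @property
    def candidate_enhancers(self) -> list:
        ctrl = set(self.control_enhancers)
        return [e for e in self.enhancers if e not in ctrl]

    @property
    def rna_batches(self) -> list:
        return sorted(self.frame["rna_batch"].unique().tolist(), key=str)

    @property
    def dna_batches(self) -> list:
        return sorted(self.frame["dna_batch"].unique().tolist(), key=str)

    def enhancer_label_map(self, column: str) -> dict:
        """Enhancer -> unique label in ``column`` (motif or covariate)."""
        sub = self.frame[["enhancer", column]].drop_duplicates()
        return dict(zip(sub["enhancer"], sub[column]))

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        df = self.frame
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required columns: {missing}")
        for col in ("dna_count", "rna_count"):
            vals = df[col]
            if vals.isna().any():
                raise ValidationError(f"{col} contains missing values")
            if (vals < 0).any():
                raise ValidationError(f"{col} contains negative counts")
        bad = set(df["condition"].unique()) - set(CONDITIONS)
        if bad:
            raise ValidationError(
                f"condition values must be in {CONDITIONS}, got {sorted(map(str, bad))}")
        dup = df.duplicated(subset=["barcode", "rna_batch"])
        if dup.any():
            pair = df.loc[dup, ["barcode", "rna_batch"]].iloc[0].tolist()
            raise ValidationError(
                f"duplicate (barcode, rna_batch) observation: {pair}")
        # each RNA batch maps to exactly one DNA batch
        nb = df.groupby("rna_batch")["dna_batch"].nunique()
        if (nb > 1).any():
            raise ValidationError(
                f"RNA batches map to multiple DNA batches: "
                f"{nb.index[nb > 1].tolist()}")
        for col in ("motif", "covariate"):
            if col in df.columns:
                if df[col].isna().any():
                    raise ValidationError(
                        f"{col} labels present for some rows but missing "
                        f"for others")
                nuniq = df.groupby("enhancer")[col].nunique()
                if (nuniq > 1).any():
                    raise ValidationError(
                        f"enhancers with more than one {col}: "
                        f"{nuniq.index[nuniq > 1].tolist()}")
        if "is_control" in df.columns:
            nuniq = df.groupby("enhancer")["is_control"].nunique()
            if (nuniq > 1).any():
                raise ValidationError("inconsistent is_control flags within "
                                      "an enhancer")

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def read_count_table(path: str | Path, schema: dict[str, str] | None = None,
                     sep: str | None = None) -> CountTable:
    """Read a delimited count file into a validated :class:`CountTable`.

    Parameters
    ----------
    path : str
        Delimited text file with a header row.
    schema : dict, optional
        Mapping from canonical column names (``barcode``, ``dna_count``, ...)
        to the column names used in the file.
    sep : str, optional
        Field delimiter; inferred from the file when omitted.

    In pooled designs one DNA batch serves several RNA batches and the DNA
    count may be present on only one row per barcode; missing DNA counts are
    filled from the matching (dna_batch, enhancer, barcode) observation.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if schema:
        rename = {v: k for k, v in schema.items()}
        df = df.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    if df["dna_count"].isna().any():
        key = ["dna_batch", "enhancer", "barcode"]
        known = (df.dropna(subset=["dna_count"])
                   .drop_duplicates(subset=key)
                   .set_index(key)["dna_count"])
        idx = pd.MultiIndex.from_frame(df[key])
        filled = known.reindex(idx).to_numpy()
        df["dna_count"] = np.where(df["dna_count"].isna(), filled,
                                   df["dna_count"])
        if pd.isna(df["dna_count"]).any():
            raise ValidationError("DNA counts missing with no matching "
                                  "barcode row to fill from")
    df["dna_count"] = df["dna_count"].astype(np.int64)
    df["rna_count"] = df["rna_count"].astype(np.int64)
    if "is_control" in df.columns:
        df["is_control"] = df["is_control"].astype(bool)
    return CountTable(df.reset_index(drop=True))


def filter_low_coverage(table: CountTable, count_floor: int = 5,
                        min_avg_barcodes: float = 10,
                        ) -> tuple[CountTable, list]:
    """Drop enhancers with too few well-covered barcodes.

    An enhancer is kept when its average number of barcodes per RNA batch
    with both DNA and RNA counts strictly above ``count_floor`` is at least
    ``min_avg_barcodes``.  The average runs over all RNA batches in the
    table.  Returns the filtered table and the list of removed enhancers.
    """
    df = table.frame
    if df.empty:
        warnings.warn("filter_low_coverage called on an empty table")
        return table, []
    n_batches = df["rna_batch"].nunique()
    ok = (df["dna_count"] > count_floor) & (df["rna_count"] > count_floor)
    qualifying = df.loc[ok].groupby("enhancer").size()
    avg = qualifying.reindex(pd.Index(table.enhancers), fill_value=0) / n_batches
    removed = sorted(avg.index[avg < min_avg_barcodes].tolist(), key=str)
    kept = df[~df["enhancer"].isin(removed)].reset_index(drop=True)
    return CountTable(kept), removed


@dataclass
class SizeFactors:
    """Per-batch sequencing-depth normalizers (mean 1 within each modality)."""

    rna: pd.Series   # indexed by rna_batch
    dna: pd.Series   # indexed by dna_batch

    def __post_init__(self) -> None:
        for name, s in (("rna", self.rna), ("dna", self.dna)):
            if (s <= 0).any():
                raise ValidationError(f"non-positive {name} size factor")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"batch": b, "modality": "rna", "factor": f}
                for b, f in self.rna.items()]
        rows += [{"batch": b, "modality": "dna", "factor": f}
                 for b, f in self.dna.items()]
        return pd.DataFrame(rows)


def _uq_factors(values: pd.Series, groups: pd.Series, modality: str,
                positive_only: bool) -> pd.Series:
    if positive_only:
        keep = values > 0
        values, groups = values[keep], groups[keep]
    uq = values.groupby(groups).quantile(0.75)
    if (uq == 0).any():
        bad = uq.index[uq == 0].tolist()
        raise ValidationError(
            f"upper quartile of {modality} counts is zero in batch(es) {bad}")
    return uq / uq.mean()


def upper_quartile_size_factors(table: CountTable,
                                positive_only: bool = False) -> SizeFactors:
    """Upper-quartile normalization factors per RNA batch and per DNA batch.

    Each factor is proportional to the 75th percentile (linear interpolation)
    of the batch's counts and rescaled so factors average 1 within each
    modality.  DNA factors are computed on deduplicated (dna_batch, enhancer,
    barcode) observations so pooled duplication does not enter twice.
    """
    df = table.frame
    rna = _uq_factors(df["rna_count"], df["rna_batch"], "RNA", positive_only)
    ddf = df.drop_duplicates(subset=["dna_batch", "enhancer", "barcode"])
    dna = _uq_factors(ddf["dna_count"], ddf["dna_batch"], "DNA", positive_only)
    return SizeFactors(rna=rna.sort_index(), dna=dna.sort_index())


def compute_dna_offsets(table: CountTable, sf: SizeFactors,
                        pseudocount: float = 1) -> np.ndarray:
    """Fixed DNA offsets ``d_n = (D_n + pseudocount) / S_bd`` per observation."""
    s_bd = table.frame["dna_batch"].map(sf.dna).to_numpy(float)
    d = (table.frame["dna_count"].to_numpy(float) + pseudocount) / s_bd
    if pseudocount > 0 and (d <= 0).any():
        raise ValidationError("non-positive offset despite pseudocount")
    return d


@dataclass
class BinMap:
    """Batch-specific dispersion bins: (enhancer, rna_batch) -> bin index.

    Bins are chunks of ``G`` enhancers ordered by mean RNA count within each
    RNA batch; bin indices are dense over the whole table and never span
    batches.
    """

    frame: pd.DataFrame      # columns enhancer, rna_batch, bin
    n_bins: int
    G: int

    def lookup(self) -> dict:
        return {(e, b): g for e, b, g in
                self.frame[["enhancer", "rna_batch", "bin"]].itertuples(index=False)}


def assign_dispersion_bins(table: CountTable, G: int = 50) -> BinMap:
    """Group enhancers into batch-specific mean-count bins of size ``G``.

    Per RNA batch, enhancers are sorted by mean RNA count ascending (ties
    broken by enhancer label, stable) and chunked into consecutive groups of
    ``G``; the final group keeps the remainder.  ``G=1`` gives every
    (enhancer, batch) pair its own dispersion parameter.
    """
    if G < 1:
        raise ValueError(f"G must be >= 1, got {G}")
    df = table.frame
    means = (df.groupby(["rna_batch", "enhancer"])["rna_count"]
               .mean().reset_index(name="mean_rna"))
    rows = []
    offset = 0
    for batch in table.rna_batches:
        sub = means[means["rna_batch"] == batch].copy()
        sub["_key"] = sub["enhancer"].astype(str)
        sub = sub.sort_values(["mean_rna", "_key"], kind="stable")
        local = np.arange(len(sub)) // G
        for enh, bin_ in zip(sub["enhancer"], local + offset):
            rows.append((enh, batch, int(bin_)))
        offset += int(local.max()) + 1 if len(sub) else 0
    frame = pd.DataFrame(rows, columns=["enhancer", "rna_batch", "bin"])
    return BinMap(frame=frame, n_bins=offset, G=G)


def build_design_matrices(table: CountTable
                          ) -> tuple[np.ndarray, np.ndarray, list, list]:
    """Indicator designs for effect sizes (X) and correction factors (Y).

    ``X`` is N x (E - C): row n has a single 1 in the column of its enhancer
    iff n is a candidate (non-control) enhancer observed in the alternate
    condition; negative controls never enter X (they carry no effect size).
    ``Y`` is N x K: row n has a 1 in its covariate's column iff n is in the
    alternate condition — including negative controls, which is how controls
    anchor the covariate-specific null.  Control-condition rows are all-zero
    in both.  Returns (X, Y, candidate_labels, covariate_labels).
    """
    df = table.frame
    candidates = table.candidate_enhancers
    cand_col = {e: j for j, e in enumerate(candidates)}
    n = len(df)
    alt = (df["condition"] == "alternate").to_numpy()

    X = np.zeros((n, len(candidates)), dtype=np.int8)
    e_col = df["enhancer"].map(cand_col)
    rows = np.where(alt & e_col.notna().to_numpy())[0]
    X[rows, e_col.to_numpy(float)[rows].astype(int)] = 1

    if table.has_covariates:
        covariates = sorted(df["covariate"].unique().tolist(), key=str)
        cov_col = {k: j for j, k in enumerate(covariates)}
        Y = np.zeros((n, len(covariates)), dtype=np.int8)
        k_col = df["covariate"].map(cov_col).to_numpy(int)
        rows = np.where(alt)[0]
        Y[rows, k_col[rows]] = 1
    else:
        covariates = []
        Y = np.zeros((n, 0), dtype=np.int8)
    return X, Y, candidates, covariates


@dataclass
class ModelInput:
    """Everything the regression model needs, aligned to the table's rows."""

    table: CountTable
    offsets: np.ndarray
    size_factors: SizeFactors
    bin_map: BinMap
    X: np.ndarray
    Y: np.ndarray
    candidates: list
    covariates: list
    pseudocount: float = 1.0
    # dense index arrays derived from the above
    enhancer_index: np.ndarray = field(init=False)
    bin_index: np.ndarray = field(init=False)
    scale: np.ndarray = field(init=False)    # S_br * d_n per observation

    def __post_init__(self) -> None:
        df = self.table.frame
        enh_ix = {e: i for i, e in enumerate(self.table.enhancers)}
        self.enhancer_index = df["enhancer"].map(enh_ix).to_numpy(int)
        lut = self.bin_map.lookup()
        self.bin_index = np.array(
            [lut[(e, b)] for e, b in zip(df["enhancer"], df["rna_batch"])],
            dtype=int)
        s_br = df["rna_batch"].map(self.size_factors.rna).to_numpy(float)
        self.scale = s_br * self.offsets

    @property
    def rna_counts(self) -> np.ndarray:
        return self.table.frame["rna_count"].to_numpy(np.int64)


def prepare_model_input(table: CountTable, G: int = 50,
                        pseudocount: float = 1,
                        count_floor: int | None = 5,
                        min_avg_barcodes: float | None = 10,
                        positive_only_uq: bool = False,
                        apply_filter: bool = True,
                        size_factors: SizeFactors | None = None) -> ModelInput:
    """Run the full preprocessing pipeline on a validated table.

    ``size_factors`` overrides upper-quartile estimation, e.g. to reuse a
    source dataset's factors on simulated data or to condition on known
    normalization in recovery studies.
    """
    if apply_filter and count_floor is not None:
        table, _ = filter_low_coverage(table, count_floor, min_avg_barcodes)
    if size_factors is not None:
        sf = SizeFactors(
            rna=size_factors.rna.loc[table.rna_batches],
            dna=size_factors.dna.loc[table.dna_batches])
    else:
        sf = upper_quartile_size_factors(table, positive_only=positive_only_uq)
    offsets = compute_dna_offsets(table, sf, pseudocount=pseudocount)
    bins = assign_dispersion_bins(table, G=G)
    X, Y, candidates, covariates = build_design_matrices(table)
    return ModelInput(table=table, offsets=offsets, size_factors=sf,
                      bin_map=bins, X=X, Y=Y, candidates=candidates,
                      covariates=covariates, pseudocount=pseudocount)
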