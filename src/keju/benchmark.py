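"""Power, masked-control false positive rate, and subsampling benchmarks.

Protocols:

* **Power** against a ground-truth call set: the fraction of ground-truth
  significant enhancers that a method also calls significant.
* **Half-control masking**: negative controls are split in half; one half
  keeps its control label (anchoring the covariate null), the other half is
  relabeled as candidates.  Any masked control called significant is a false
  positive, so FPR = fraction of masked controls called significant.
* **Subsampling grid**: refit at each combination of barcode cap and
  dispersion-bin size G, scoring power against the full-data G=50 calls and
  FPR from reused masking plans.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CountTable
from .model import KejuModel, PriorSpec

__all__ = [
    "MaskingPlan", "compute_power", "mask_negative_controls",
    "apply_masking", "compute_fpr", "subsample_barcodes", "fit_and_call",
    "run_grid", "stratify_significance",
]


@dataclass(frozen=True)
class MaskingPlan:
    """One half-split of the negative controls."""

    replicate: int
    labeled: frozenset
    masked: frozenset
    seed: int

    def __post_init__(self) -> None:
        if self.labeled & self.masked:
            raise ValueError("labeled and masked control sets overlap")
        if abs(len(self.labeled) - len(self.masked)) > 1:
            raise ValueError("half-split sizes differ by more than 1")


def _significant_set(calls) -> set:
    if isinstance(calls, pd.DataFrame):
        return set(calls.loc[calls["significant"], "enhancer"])
    return set(calls)


def compute_power(calls, truth_calls) -> float:
    """Fraction of ground-truth significant enhancers recovered by ``calls``."""
    truth = set(truth_calls)
    if not truth:
        raise ValueError("empty ground-truth call set")
    sig = _significant_set(calls)
    return len(sig & truth) / len(truth)


def mask_negative_controls(control_ids, n_reps: int = 10,
                           seed: int = 0) -> list[MaskingPlan]:
    """Random half-splits of the control set, one plan per replicate.

    With an odd number of controls the labeled half keeps the extra one.
    """
    controls = sorted(set(control_ids), key=str)
    if len(controls) < 2:
        raise ValueError("need at least 2 negative controls to mask")
    n_masked = len(controls) // 2
    plans = []
    for rep in range(n_reps):
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), rep)))
        perm = rng.permutation(len(controls))
        masked = frozenset(controls[i] for i in perm[:n_masked])
        labeled = frozenset(controls[i] for i in perm[n_masked:])
        plans.append(MaskingPlan(replicate=rep, labeled=labeled,
                                 masked=masked, seed=seed))
    return plans


def apply_masking(table: CountTable, plan: MaskingPlan,
                  motif_handling: str = "pseudo") -> CountTable:
    """Relabel the plan's masked controls as candidates.

    Masked controls get ``is_control = False`` so they receive effect-size
    parameters in the refit.  With ``motif_handling="pseudo"`` (default)
    each masked control also gets its own pseudo-motif, disabling shrinkage
    toward any real motif group; ``"keep"`` leaves motif labels untouched.
    """
    if motif_handling not in ("pseudo", "keep"):
        raise ValueError(f"unknown motif_handling {motif_handling!r}")
    df = table.frame.copy()
    masked = df["enhancer"].isin(plan.masked)
    df.loc[masked, "is_control"] = False
    if motif_handling == "pseudo" and "motif" in df.columns:
        df.loc[masked, "motif"] = "masked_" + df.loc[masked, "enhancer"].astype(str)
    return CountTable(df)


def compute_fpr(calls, plan: MaskingPlan) -> float:
    """Fraction of the plan's masked controls called significant."""
    if isinstance(calls, pd.DataFrame):
        present = set(calls["enhancer"])
        missing = plan.masked - present
        if missing:
            raise ValueError(f"masked controls missing from calls: "
                             f"{sorted(missing, key=str)[:5]}")
    sig = _significant_set(calls)
    return len(sig & plan.masked) / len(plan.masked)


_TRAILING_INT = re.compile(r"(\d+)\s*$")


def _barcode_order_key(codes: pd.Series) -> np.ndarray:
    """Numeric barcode order when every id ends in digits, else lexicographic."""
    s = codes.astype(str)
    nums = s.str.extract(_TRAILING_INT, expand=False)
    if nums.notna().all():
        return nums.astype(int).to_numpy()
    ranks = np.empty(len(s), dtype=int)
    ranks[np.argsort(s.to_numpy(), kind="stable")] = np.arange(len(s))
    return ranks


def subsample_barcodes(table: CountTable, max_barcodes: int) -> CountTable:
    """Keep each enhancer's first ``max_barcodes`` barcodes.

    Barcodes are ordered by their trailing number when ids are numbered,
    otherwise by sorted id, mirroring numbered-barcode subsampling designs.
    """
    if max_barcodes < 1:
        raise ValueError("max_barcodes must be >= 1")
    df = table.frame
    bc = df[["enhancer", "barcode"]].drop_duplicates().copy()
    bc["_key"] = _barcode_order_key(bc["barcode"])
    bc = bc.sort_values(["enhancer", "_key", "barcode"], kind="stable")
    bc["_rank"] = bc.groupby("enhancer").cumcount()
    keep = set(map(tuple, bc.loc[bc["_rank"] < max_barcodes,
                                 ["enhancer", "barcode"]].to_numpy()))
    mask = [(e, b) in keep for e, b in zip(df["enhancer"], df["barcode"])]
    return CountTable(df.loc[mask].reset_index(drop=True))


def fit_and_call(table: CountTable, G: int = 50,
                 prior: PriorSpec | None = None, threshold: float = 0.05,
                 chains: int = 2, warmup: int = 300, samples: int = 300,
                 seed: int = 0, **fit_kwargs) -> pd.DataFrame:
    """Preprocess, fit and return the significance table (one-stop helper)."""
    model = KejuModel.from_count_table(table, prior=prior, G=G)
    res = model.fit(chains=chains, warmup=warmup, samples=samples, seed=seed,
                    **fit_kwargs)
    return res.significance_table(threshold=threshold)


def _max_barcodes(table: CountTable) -> int:
    bc = table.frame[["enhancer", "barcode"]].drop_duplicates()
    return int(bc.groupby("enhancer").size().max())


def run_grid(table: CountTable, G_values=(1, 10, 25, 50),
             caps=(10, 25, 40, 60, 80, 100), prior: PriorSpec | None = None,
             threshold: float = 0.05, truth_G: int = 50,
             masking_plans: list[MaskingPlan] | None = None,
             motif_handling: str = "pseudo", chains: int = 2,
             warmup: int = 300, samples: int = 300, seed: int = 0,
             fitter=None, **fit_kwargs) -> pd.DataFrame:
    """Fit at every (barcode cap, G) cell and score power (and FPR).

    Ground truth is the significance call set of the full-data fit at
    ``truth_G``; the grid cell at (max cap, truth_G) is that same fit, so
    its power is 1 by construction.  When ``masking_plans`` is given, each
    cell is also refit once per plan with masked controls as candidates to
    measure FPR.  Returns a long-format frame of results.
    """
    mcmc = dict(chains=chains, warmup=warmup, samples=samples, seed=seed,
                **fit_kwargs)
    if fitter is None:
        fitter = fit_and_call
    truth_calls = fitter(table, G=truth_G, prior=prior,
                         threshold=threshold, **mcmc)
    truth_set = _significant_set(truth_calls)
    full_cap = _max_barcodes(table)

    rows = []
    for cap in caps:
        sub = subsample_barcodes(table, cap) if cap < full_cap else table
        for G in G_values:
            if cap >= full_cap and G == truth_G:
                calls = truth_calls       # identical computation by definition
            else:
                calls = fitter(sub, G=G, prior=prior,
                               threshold=threshold, **mcmc)
            if truth_set:
                rows.append(dict(method="keju", metric="power",
                                 value=compute_power(calls, truth_set),
                                 replicate=0, G=G, cap=cap,
                                 threshold=threshold))
            for plan in masking_plans or []:
                masked_tab = apply_masking(sub, plan,
                                           motif_handling=motif_handling)
                mcalls = fitter(masked_tab, G=G, prior=prior,
                                threshold=threshold, **mcmc)
                rows.append(dict(method="keju", metric="fpr",
                                 value=compute_fpr(mcalls, plan),
                                 replicate=plan.replicate, G=G, cap=cap,
                                 threshold=threshold))
    out = pd.DataFrame(rows)
    bad = ~out["value"].between(0, 1)
    assert not bad.any()
    return out


def summarize_grid(results: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error per (metric, G, cap) cell."""
    g = results.groupby(["metric", "G", "cap"])["value"]
    out = g.agg(["mean", "count", "std"]).reset_index()
    out["se"] = out["std"] / np.sqrt(out["count"])
    return out.drop(columns="std")


def stratify_significance(calls: pd.DataFrame, table: CountTable,
                          n_bins: int = 10,
                          by: str | None = "covariate") -> pd.DataFrame:
    """Fraction of enhancers called significant per mean-count decile.

    Enhancers are binned by their mean RNA count in the control condition
    (bin 1 lowest); within each bin the fraction significant is reported,
    optionally stratified by a label column such as the covariate.
    """
    ctrl = table.frame[table.frame["condition"] == "control"]
    means = ctrl.groupby("enhancer")["rna_count"].mean()
    sub = calls[calls["enhancer"].isin(means.index)].copy()
    sub["_mean"] = sub["enhancer"].map(means)
    sub["count_bin"] = pd.qcut(sub["_mean"].rank(method="first"), n_bins,
                               labels=range(1, n_bins + 1))
    keys = ["count_bin"]
    if by is not None and by in sub.columns:
        keys.append(by)
    out = (sub.groupby(keys, observed=True)["significant"]
              .agg(frac_significant="mean", n="size").reset_index())
    return out
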