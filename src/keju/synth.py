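"""Synthetic MPRA data with known ground truth.

Generates barcode-level paired DNA/RNA count tables with the structure the
inference model assumes: negative-binomial counts, paired or pooled batch
designs, motif groupings, promoter-style covariates with slope/intercept
effects on transcription rate, covariate correction factors and negative
controls.  Every realized parameter is recorded in a :class:`TruthSet` so
parameter recovery, calibration and power can be measured exactly.

Terminology: a "replicate" is one biological RNA replicate measured in both
conditions; each (replicate, condition) pair is a distinct RNA sample and is
what the count table's ``rna_batch`` column holds.  In a paired design each
replicate has its own DNA plasmid pool; in a pooled design several
replicates share one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .data import CountTable

__all__ = ["SynthConfig", "TruthSet", "generate", "make_null_dataset",
           "draw_negative_binomial"]


def draw_negative_binomial(rng: np.random.Generator, mu, phi) -> np.ndarray:
    """Draw NB counts with mean ``mu`` and variance ``mu + mu^2/phi``.

    Uses the gamma-Poisson mixture, so ``phi`` is the gamma shape: larger
    ``phi`` means closer to Poisson.
    """
    mu = np.asarray(mu, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mu.shape)
    lam = rng.gamma(shape=phi, scale=mu / phi)
    return rng.poisson(lam)


@dataclass
class SynthConfig:
    """Study-design and effect-model settings for the generator.

    Defaults describe a small two-replicate paired experiment: 100 enhancers
    of which 20 are scramble negative controls, 20 candidate motifs, two
    minimal promoters (covariates), 10 barcodes per enhancer, and an
    increasing mean-dispersion trend on the RNA counts.
    """

    n_enhancers: int = 100          # E, including controls
    n_controls: int = 20            # C scramble negative controls
    n_motifs: int = 20              # candidate motif groups
    n_control_motifs: int = 2       # scramble groups the controls fall into
    n_covariates: int = 1           # K minimal promoters
    n_replicates: int = 2           # replicates, each measured in 2 conditions
    n_dna_batches: int | None = None  # defaults: paired -> n_replicates
    design: str = "paired"          # "paired" or "pooled"
    barcodes: int | tuple[int, int] = 10   # per enhancer; int or (lo, hi)
    # effect model
    frac_active_motifs: float = 0.4
    effect_mean_sd: float = 1.0     # spread of motif-level effect means mu_m
    effect_sd: float = 0.25         # within-motif effect spread sigma_m
    effect_sizes: Sequence[float] | None = None  # fixed |beta| grid override
    gamma: Sequence[float] | None = None   # per-covariate correction factors
    # transcription model
    theta_sd: float = 1.0           # motif-level transcription spread
    alpha_sd: float = 0.5           # within-motif transcription spread eps_m
    slopes: Sequence[float] | None = None       # promoter slopes r_k
    intercepts: Sequence[float] | None = None   # promoter intercepts t_k
    # count model
    dna_log_mean: float = float(np.log(100.0))
    dna_log_sd: float = 0.4
    rna_phi: Sequence[float] | float = (4.0, 8.0, 16.0, 32.0)  # by count rank
    dna_phi: Sequence[float] | float = 100.0
    size_factor_sd: float = 0.15
    offset_mode: str = "realized"   # RNA mean uses realized DNA offsets
    pseudocount: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if not 0 <= self.n_controls < self.n_enhancers:
            problems.append("need 0 <= n_controls < n_enhancers")
        if self.n_covariates < 1:
            problems.append("need n_covariates >= 1")
        if self.design not in ("paired", "pooled"):
            problems.append(f"unknown design {self.design!r}")
        bd = self.dna_batch_count
        if self.design == "pooled" and bd >= self.n_replicates:
            problems.append("pooled design requires n_dna_batches < "
                            "n_replicates")
        if np.min(np.atleast_1d(self.rna_phi)) <= 0 or \
                np.min(np.atleast_1d(self.dna_phi)) <= 0:
            problems.append("dispersions must be positive")
        if isinstance(self.barcodes, tuple) and self.barcodes[0] < 1:
            problems.append("barcode range must start at >= 1")
        if problems:
            raise ValueError("invalid SynthConfig: " + "; ".join(problems))

    @property
    def dna_batch_count(self) -> int:
        if self.n_dna_batches is not None:
            return self.n_dna_batches
        return self.n_replicates if self.design == "paired" else 1


@dataclass
class TruthSet:
    """Realized ground-truth parameters behind a generated table."""

    enhancers: pd.DataFrame         # enhancer, motif, covariate, is_control, alpha, beta
    gamma: pd.Series                # per covariate
    theta: pd.Series                # per motif
    slopes: pd.Series               # r_k per covariate
    intercepts: pd.Series           # t_k per covariate
    rna_size_factors: pd.Series
    dna_size_factors: pd.Series
    dna_log_offsets: pd.DataFrame   # enhancer, dna_batch, d
    rna_phi: pd.DataFrame           # enhancer, rna_batch, phi
    dna_phi: pd.DataFrame           # enhancer, dna_batch, phi
    config: SynthConfig = field(repr=False, default=None)  # type: ignore


def _phi_by_rank(order_keys: np.ndarray, phis) -> np.ndarray:
    """Map items to dispersion values by ascending rank of their mean."""
    phis = np.atleast_1d(np.asarray(phis, dtype=float))
    n = len(order_keys)
    ranks = np.empty(n, dtype=int)
    ranks[np.argsort(order_keys, kind="stable")] = np.arange(n)
    groups = np.minimum((ranks * len(phis)) // max(n, 1), len(phis) - 1)
    return phis[groups]


def _covariate_defaults(cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    K = cfg.n_covariates
    r = np.zeros(K)
    t = np.zeros(K)
    if cfg.slopes is not None:
        r[:] = np.asarray(cfg.slopes, dtype=float)
    elif K >= 2:
        r[1] = 1.0   # one strong promoter doubling the motif slope
    if cfg.intercepts is not None:
        t[:] = np.asarray(cfg.intercepts, dtype=float)
    elif K >= 2:
        t[1] = 0.5
    return r, t


def generate(config: SynthConfig, seed: int | None = None
             ) -> tuple[CountTable, TruthSet]:
    """Sample a count table and its ground truth from the configured design."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    E, C = config.n_enhancers, config.n_controls
    K = config.n_covariates
    n_reps, n_bd = config.n_replicates, config.dna_batch_count

    enh = np.array([f"E{i:04d}" for i in range(E)])
    is_control = np.zeros(E, dtype=bool)
    control_ix = rng.choice(E, size=C, replace=False)
    is_control[control_ix] = True

    motifs = np.empty(E, dtype=object)
    cand_motifs = [f"M{j:03d}" for j in range(config.n_motifs)]
    ctrl_motifs = [f"scramble{j}" for j in range(max(config.n_control_motifs, 1))]
    motifs[~is_control] = [cand_motifs[j % len(cand_motifs)]
                           for j in range((~is_control).sum())]
    motifs[is_control] = [ctrl_motifs[j % len(ctrl_motifs)]
                          for j in range(C)]

    cov_labels = [f"P{k}" for k in range(K)]
    covariates = np.array([cov_labels[i % K] for i in range(E)], dtype=object)

    all_motifs = cand_motifs + ctrl_motifs
    theta = pd.Series(rng.normal(0.0, config.theta_sd, len(all_motifs)),
                      index=all_motifs)
    r_k, t_k = _covariate_defaults(config)
    cov_ix = np.array([cov_labels.index(c) for c in covariates])
    motif_theta = theta[motifs].to_numpy()
    alpha = ((1.0 + r_k[cov_ix]) * motif_theta + t_k[cov_ix]
             + rng.normal(0.0, config.alpha_sd, E))

    beta = np.zeros(E)
    if config.effect_sizes is not None:
        # fixed-magnitude grid: candidates cycle through |beta| values with
        # random signs (power-curve designs)
        mags = np.asarray(config.effect_sizes, dtype=float)
        j = 0
        for i in range(E):
            if not is_control[i]:
                beta[i] = mags[j % len(mags)] * rng.choice([-1.0, 1.0])
                j += 1
    else:
        # motif-level differential effects: a fraction of candidate motifs
        # is active and candidates in an active motif share a mean mu_m
        n_active = int(round(config.frac_active_motifs * len(cand_motifs)))
        active = set(rng.choice(cand_motifs, size=n_active, replace=False))
        mu_m = {m: rng.normal(0.0, config.effect_mean_sd) for m in active}
        for i in range(E):
            if not is_control[i] and motifs[i] in active:
                beta[i] = mu_m[motifs[i]] + rng.normal(0.0, config.effect_sd)

    gamma = np.zeros(K) if config.gamma is None \
        else np.asarray(config.gamma, dtype=float)

    def _size_factors(labels):
        f = rng.lognormal(0.0, config.size_factor_sd, len(labels))
        return pd.Series(f / f.mean(), index=labels)

    rep_labels = [f"r{i+1}" for i in range(n_reps)]
    rna_batches = [f"{r}_{c}" for r in rep_labels
                   for c in ("control", "alternate")]
    dna_batches = [f"d{j+1}" for j in range(n_bd)]
    rep_to_dna = {rep_labels[i]: dna_batches[i % n_bd] for i in range(n_reps)}
    s_rna = _size_factors(rna_batches)
    s_dna = _size_factors(dna_batches)

    d_ebd = rng.normal(config.dna_log_mean, config.dna_log_sd, (E, n_bd))

    if isinstance(config.barcodes, tuple):
        lo, hi = config.barcodes
        n_bc = rng.integers(lo, hi + 1, size=E)
    else:
        n_bc = np.full(E, int(config.barcodes))

    # DNA layer: one count per (enhancer, barcode, DNA batch), NB around
    # the latent per-(enhancer, batch) log offset
    dna_phi_rows = []
    dna_counts: dict[tuple[int, int], np.ndarray] = {}
    for j, bd in enumerate(dna_batches):
        phi_d = _phi_by_rank(d_ebd[:, j], config.dna_phi)
        for i in range(E):
            mu = s_dna[bd] * np.exp(d_ebd[i, j]) * np.ones(n_bc[i])
            dna_counts[(i, j)] = draw_negative_binomial(rng, mu, phi_d[i])
            dna_phi_rows.append((enh[i], bd, phi_d[i]))

    # RNA layer per (replicate, condition) sample
    eta_alt = alpha + np.where(is_control, 0.0, beta) + gamma[cov_ix]
    eta_ctl = alpha
    rna_phi_rows = []
    frames = []
    for rep in rep_labels:
        bd = rep_to_dna[rep]
        j = dna_batches.index(bd)
        for cond in ("control", "alternate"):
            sample = f"{rep}_{cond}"
            eta = eta_alt if cond == "alternate" else eta_ctl
            # mean-count rank within sample determines the dispersion bin
            latent_mean = d_ebd[:, j] + eta
            phi_r = _phi_by_rank(latent_mean, config.rna_phi)
            for i in range(E):
                d_cnt = dna_counts[(i, j)]
                if config.offset_mode == "realized":
                    d_n = (d_cnt + config.pseudocount) / s_dna[bd]
                else:
                    d_n = np.exp(d_ebd[i, j]) * np.ones(n_bc[i])
                mu = s_rna[sample] * d_n * np.exp(eta[i])
                r_cnt = draw_negative_binomial(rng, mu, phi_r[i])
                frames.append(pd.DataFrame({
                    "barcode": [f"{enh[i]}_b{b:03d}" for b in range(n_bc[i])],
                    "dna_count": d_cnt,
                    "rna_count": r_cnt,
                    "enhancer": enh[i],
                    "rna_batch": sample,
                    "dna_batch": bd,
                    "condition": cond,
                    "motif": motifs[i],
                    "covariate": covariates[i],
                    "is_control": is_control[i],
                }))
            rna_phi_rows += [(enh[i], sample, phi_r[i]) for i in range(E)]

    table = CountTable(pd.concat(frames, ignore_index=True))
    truth = TruthSet(
        enhancers=pd.DataFrame({
            "enhancer": enh, "motif": motifs, "covariate": covariates,
            "is_control": is_control, "alpha": alpha, "beta": beta}),
        gamma=pd.Series(gamma, index=cov_labels),
        theta=theta,
        slopes=pd.Series(r_k, index=cov_labels),
        intercepts=pd.Series(t_k, index=cov_labels),
        rna_size_factors=s_rna, dna_size_factors=s_dna,
        dna_log_offsets=pd.DataFrame(
            [(enh[i], dna_batches[j], d_ebd[i, j])
             for i in range(E) for j in range(n_bd)],
            columns=["enhancer", "dna_batch", "d"]),
        rna_phi=pd.DataFrame(rna_phi_rows,
                             columns=["enhancer", "rna_batch", "phi"]),
        dna_phi=pd.DataFrame(dna_phi_rows,
                             columns=["enhancer", "dna_batch", "phi"]),
        config=config,
    )
    return table, truth


def make_null_dataset(config: SynthConfig, seed: int | None = None
                      ) -> tuple[CountTable, TruthSet]:
    """Generate data with every differential effect forced to zero.

    Covariate correction factors ``gamma`` may still be nonzero, exercising
    the covariate-specific null that negative controls anchor.
    """
    null_cfg = replace(config, frac_active_motifs=0.0, effect_sizes=None)
    return generate(null_cfg, seed=seed)
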