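"""Alternate two-GLM generative model for fair simulation benchmarking.

Unlike the primary regression, which conditions on DNA counts, this model
fits both modalities: one NB GLM on the DNA counts and one on the RNA
counts, with per-enhancer, per-modality overdispersions and a per-(enhancer,
DNA batch) mean log offset:

    D ~ NB( mu = S_bd * exp(d_{e,bd}),                              phi_e^d )
    R ~ NB( mu = S_br * exp(d_{e,bd} + alpha_e + X' beta + Y' gamma), phi_e^r )

with noninformative priors alpha_e, beta_e, gamma_k, d_{e,bd} ~ N(0, 2) and
phi_e^d, phi_e^r ~ Exp(1).  It deliberately has neither batch-specific RNA
dispersion nor motif-level shrinkage, so simulations drawn from its
posterior favor no benchmarked method.

DNA counts are deduplicated to one observation per (DNA batch, enhancer,
barcode) before fitting; feeding the duplicated pooled layout would deflate
the apparent DNA dispersion.

Fitted posteriors drive :meth:`AlternateResults.simulate`: each replicate
picks one posterior draw uniformly at random and regenerates counts from the
model above, mirroring the source table's (enhancer, batch, condition)
scaffolding, capping barcodes per enhancer and adding a pseudocount to the
simulated DNA counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, digamma

from .data import (CountTable, SizeFactors, build_design_matrices,
                   upper_quartile_size_factors)
from .mcmc import sample_nuts
from .model import McmcSettings, nb_loglik
from .synth import draw_negative_binomial

__all__ = ["AlternateModel", "AlternateResults", "SimProtocol",
           "simulate_datasets"]

_PRIOR_SD = 2.0    # N(0, 2) on alpha, beta, gamma and the d offsets


@dataclass
class SimProtocol:
    """How many replicates to draw and how to treat barcodes and DNA counts."""

    n_sims: int = 10
    barcode_cap: int = 25
    dna_pseudocount: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sims < 1 or self.barcode_cap < 1 or self.dna_pseudocount < 0:
            raise ValueError("invalid simulation protocol")


class AlternateModel:
    """Joint DNA+RNA NB model built from a validated count table."""

    def __init__(self, table: CountTable,
                 size_factors: SizeFactors | None = None):
        self.table = table
        self.size_factors = size_factors or upper_quartile_size_factors(table)
        df = table.frame

        self.enhancers = table.enhancers
        self.E = len(self.enhancers)
        enh_ix = {e: i for i, e in enumerate(self.enhancers)}

        # deduplicated DNA observations, one per (dna_batch, enhancer, barcode)
        dna = df.drop_duplicates(subset=["dna_batch", "enhancer", "barcode"])
        if dna.duplicated(subset=["dna_batch", "enhancer", "barcode"]).any():
            raise ValueError("duplicated DNA observations after dedup")
        self.n_d = len(dna)
        pairs = (df[["enhancer", "dna_batch"]].drop_duplicates()
                 .sort_values(["enhancer", "dna_batch"], key=lambda s: s.astype(str))
                 .reset_index(drop=True))
        self.pairs = pairs
        pair_ix = {(e, b): i for i, (e, b) in
                   enumerate(zip(pairs["enhancer"], pairs["dna_batch"]))}
        self.P = len(pairs)

        self.d_obs = dna["dna_count"].to_numpy(float)
        self.d_pair = np.array([pair_ix[(e, b)] for e, b in
                                zip(dna["enhancer"], dna["dna_batch"])])
        self.d_enh = np.array([enh_ix[e] for e in dna["enhancer"]])
        self.d_scale = dna["dna_batch"].map(self.size_factors.dna).to_numpy(float)

        self.r_obs = df["rna_count"].to_numpy(float)
        self.r_pair = np.array([pair_ix[(e, b)] for e, b in
                                zip(df["enhancer"], df["dna_batch"])])
        self.r_enh = np.array([enh_ix[e] for e in df["enhancer"]])
        self.r_scale = df["rna_batch"].map(self.size_factors.rna).to_numpy(float)

        X, Y, self.candidates, self.covariates = build_design_matrices(table)
        self.n_candidates = len(self.candidates)
        self.K = len(self.covariates)
        xs = X.sum(axis=1)
        self.beta_col = np.where(xs > 0, X.argmax(axis=1), -1)
        ys = Y.sum(axis=1)
        self.gamma_col = np.where(ys > 0, Y.argmax(axis=1), -1) \
            if self.K else np.full(len(df), -1)

        self._lgr_d = gammaln(self.d_obs + 1.0)
        self._lgr_r = gammaln(self.r_obs + 1.0)

        # layout: d (P), alpha (E), beta, gamma, u_phi_d (E), u_phi_r (E)
        sizes = [("d", self.P), ("alpha", self.E),
                 ("beta", self.n_candidates), ("gamma", self.K),
                 ("u_phi_d", self.E), ("u_phi_r", self.E)]
        self.slices, off = {}, 0
        for name, size in sizes:
            self.slices[name] = slice(off, off + size)
            off += size
        self.dim = off

    # ------------------------------------------------------------------
    def _linear_predictors(self, d, alpha, beta, gamma):
        eta_d = np.log(self.d_scale) + d[self.d_pair]
        eta_r = np.log(self.r_scale) + d[self.r_pair] + alpha[self.r_enh]
        if self.n_candidates:
            bc = self.beta_col
            eta_r = eta_r + np.where(bc >= 0, beta[np.maximum(bc, 0)], 0.0)
        if self.K:
            gc = self.gamma_col
            eta_r = eta_r + np.where(gc >= 0, gamma[np.maximum(gc, 0)], 0.0)
        return eta_d, eta_r

    def log_likelihood(self, d, alpha, beta=None, gamma=None,
                       phi_d=None, phi_r=None) -> float:
        """Two-NB log likelihood at explicit natural parameters."""
        d = np.asarray(d, float)
        alpha = np.asarray(alpha, float)
        beta = np.zeros(self.n_candidates) if beta is None else np.asarray(beta, float)
        gamma = np.zeros(self.K) if gamma is None else np.asarray(gamma, float)
        phi_d = np.ones(self.E) if phi_d is None \
            else np.broadcast_to(np.asarray(phi_d, float), (self.E,))
        phi_r = np.ones(self.E) if phi_r is None \
            else np.broadcast_to(np.asarray(phi_r, float), (self.E,))
        eta_d, eta_r = self._linear_predictors(d, alpha, beta, gamma)
        ll = np.sum(nb_loglik(self.d_obs, np.exp(eta_d), phi_d[self.d_enh]))
        ll += np.sum(nb_loglik(self.r_obs, np.exp(eta_r), phi_r[self.r_enh]))
        return float(ll)

    def logp_and_grad(self, z: np.ndarray) -> tuple[float, np.ndarray]:
        s = self.slices
        if np.max(np.abs(z)) > 100.0:
            return -np.inf, np.zeros(self.dim)
        d = z[s["d"]]
        alpha = z[s["alpha"]]
        beta = z[s["beta"]]
        gamma = z[s["gamma"]]
        u_pd = z[s["u_phi_d"]]
        u_pr = z[s["u_phi_r"]]
        phi_d = np.exp(u_pd)
        phi_r = np.exp(u_pr)

        grad = np.zeros(self.dim)
        eta_d, eta_r = self._linear_predictors(d, alpha, beta, gamma)
        if max(np.max(np.abs(eta_d)), np.max(np.abs(eta_r))) > 200.0:
            return -np.inf, grad

        def nb_terms(y, eta, phi_e, enh, lgr):
            mu = np.exp(eta)
            phi = phi_e[enh]
            phimu = phi + mu
            ll = float(np.sum(gammaln(y + phi) - gammaln(phi) - lgr
                              + phi * (np.log(phi) - np.log(phimu))
                              + y * (eta - np.log(phimu))))
            g_eta = y - (y + phi) * mu / phimu
            g_phi = (digamma(y + phi) - digamma(phi)
                     + np.log(phi) - np.log(phimu)
                     + 1.0 - (y + phi) / phimu)
            return ll, g_eta, g_phi

        logp, g_eta_d, g_phi_d_obs = nb_terms(self.d_obs, eta_d, phi_d,
                                              self.d_enh, self._lgr_d)
        ll_r, g_eta_r, g_phi_r_obs = nb_terms(self.r_obs, eta_r, phi_r,
                                              self.r_enh, self._lgr_r)
        logp += ll_r

        g_d = (np.bincount(self.d_pair, weights=g_eta_d, minlength=self.P)
               + np.bincount(self.r_pair, weights=g_eta_r, minlength=self.P))
        g_alpha = np.bincount(self.r_enh, weights=g_eta_r, minlength=self.E)
        if self.n_candidates:
            mask = self.beta_col >= 0
            g_beta = np.bincount(self.beta_col[mask],
                                 weights=g_eta_r[mask],
                                 minlength=self.n_candidates)
        else:
            g_beta = np.zeros(0)
        if self.K:
            mask = self.gamma_col >= 0
            g_gamma = np.bincount(self.gamma_col[mask],
                                  weights=g_eta_r[mask], minlength=self.K)
        else:
            g_gamma = np.zeros(0)

        v = _PRIOR_SD ** 2
        logp += float(-0.5 * (np.sum(d ** 2) + np.sum(alpha ** 2)
                              + np.sum(beta ** 2) + np.sum(gamma ** 2)) / v)
        grad[s["d"]] = g_d - d / v
        grad[s["alpha"]] = g_alpha - alpha / v
        grad[s["beta"]] = g_beta - beta / v
        grad[s["gamma"]] = g_gamma - gamma / v

        # Exp(1) priors on both dispersions, log transform with Jacobian
        gpd = np.bincount(self.d_enh, weights=g_phi_d_obs,
                          minlength=self.E) * phi_d
        gpr = np.bincount(self.r_enh, weights=g_phi_r_obs,
                          minlength=self.E) * phi_r
        logp += float(np.sum(-phi_d + u_pd) + np.sum(-phi_r + u_pr))
        grad[s["u_phi_d"]] = gpd - phi_d + 1.0
        grad[s["u_phi_r"]] = gpr - phi_r + 1.0
        return logp, grad

    # ------------------------------------------------------------------
    def fit(self, chains: int = 4, warmup: int = 1000, samples: int = 1000,
            seed: int = 0, target_accept: float = 0.8,
            max_treedepth: int = 10,
            settings: McmcSettings | None = None) -> "AlternateResults":
        if settings is None:
            settings = McmcSettings(chains=chains, warmup=warmup,
                                    samples=samples, seed=seed,
                                    target_accept=target_accept,
                                    max_treedepth=max_treedepth)
        chain_results = sample_nuts(
            self.logp_and_grad, self.dim, chains=settings.chains,
            warmup=settings.warmup, samples=settings.samples,
            seed=settings.seed, target_accept=settings.target_accept,
            max_treedepth=settings.max_treedepth, warm_start=True)
        raw = np.stack([c.draws for c in chain_results])
        s = self.slices
        draws = {
            "d": raw[..., s["d"]],
            "alpha": raw[..., s["alpha"]],
            "beta": raw[..., s["beta"]],
            "gamma": raw[..., s["gamma"]],
            "phi_d": np.exp(raw[..., s["u_phi_d"]]),
            "phi_r": np.exp(raw[..., s["u_phi_r"]]),
        }
        return AlternateResults(model=self, settings=settings, draws=draws,
                                chain_results=chain_results)


@dataclass
class AlternateResults:
    """Posterior of the alternate model; the simulation engine hangs off it."""

    model: AlternateModel
    settings: McmcSettings
    draws: dict[str, np.ndarray]
    chain_results: list
    draw_log: list = field(default_factory=list)   # (replicate, draw index)

    def stacked(self, name: str) -> np.ndarray:
        d = self.draws[name]
        return d.reshape(-1, d.shape[-1])

    @property
    def n_draws(self) -> int:
        d = self.draws["alpha"]
        return d.shape[0] * d.shape[1]

    def posterior_median(self, name: str) -> np.ndarray:
        return np.median(self.stacked(name), axis=0)

    # ------------------------------------------------------------------
    def simulate(self, n_sims: int = 10, barcode_cap: int = 25,
                 dna_pseudocount: int = 1, seed: int = 0,
                 protocol: SimProtocol | None = None) -> list[CountTable]:
        """Draw simulated count tables from the posterior.

        Each replicate picks one retained posterior draw uniformly at
        random (seeded per replicate), regenerates DNA and RNA counts from
        the generative model, keeps the source table's (enhancer, batch,
        condition) scaffolding with barcodes capped per enhancer, and adds
        ``dna_pseudocount`` to every simulated DNA count.  Chosen draw
        indices are recorded in :attr:`draw_log`.
        """
        if protocol is None:
            protocol = SimProtocol(n_sims=n_sims, barcode_cap=barcode_cap,
                                   dna_pseudocount=dna_pseudocount, seed=seed)
        m = self.model
        df = m.table.frame

        # barcode capping: keep the first `cap` barcodes per enhancer by
        # sorted barcode label (deterministic)
        bc_rank = (df[["enhancer", "barcode"]].drop_duplicates()
                   .sort_values(["enhancer", "barcode"],
                                key=lambda s: s.astype(str)))
        bc_rank["rank"] = bc_rank.groupby("enhancer").cumcount()
        keep_pairs = set(map(tuple, bc_rank.loc[
            bc_rank["rank"] < protocol.barcode_cap,
            ["enhancer", "barcode"]].to_numpy()))
        keep_mask = np.array([(e, b) in keep_pairs for e, b in
                              zip(df["enhancer"], df["barcode"])])
        scaffold = df.loc[keep_mask].reset_index(drop=True)

        # per-kept-row indices into model arrays
        row_ix = np.where(keep_mask)[0]
        r_pair = m.r_pair[row_ix]
        r_enh = m.r_enh[row_ix]
        beta_col = m.beta_col[row_ix]
        gamma_col = m.gamma_col[row_ix]
        r_scale = m.r_scale[row_ix]

        # deduplicated DNA scaffold for the kept barcodes
        dna_scaffold = scaffold.drop_duplicates(
            subset=["dna_batch", "enhancer", "barcode"])
        dkey = list(zip(dna_scaffold["dna_batch"], dna_scaffold["enhancer"],
                        dna_scaffold["barcode"]))
        enh_ix = {e: i for i, e in enumerate(m.enhancers)}
        pair_ix = {(e, b): i for i, (e, b) in
                   enumerate(zip(m.pairs["enhancer"], m.pairs["dna_batch"]))}
        d_pair = np.array([pair_ix[(e, b)] for b, e, _ in dkey])
        d_enh = np.array([enh_ix[e] for b, e, _ in dkey])
        d_scale = dna_scaffold["dna_batch"].map(m.size_factors.dna).to_numpy(float)

        alpha_s = self.stacked("alpha")
        beta_s = self.stacked("beta")
        gamma_s = self.stacked("gamma")
        d_s = self.stacked("d")
        phi_d_s = self.stacked("phi_d")
        phi_r_s = self.stacked("phi_r")

        tables = []
        for rep in range(protocol.n_sims):
            rng = np.random.default_rng(
                np.random.SeedSequence((int(protocol.seed), rep)))
            ix = int(rng.integers(self.n_draws))
            self.draw_log.append((rep, ix))
            d, alpha = d_s[ix], alpha_s[ix]
            beta, gamma = beta_s[ix], gamma_s[ix]
            phi_d, phi_r = phi_d_s[ix], phi_r_s[ix]

            mu_d = d_scale * np.exp(d[d_pair])
            dna_draw = draw_negative_binomial(rng, mu_d, phi_d[d_enh])
            dna_draw = dna_draw + protocol.dna_pseudocount
            dna_lut = {k: v for k, v in zip(dkey, dna_draw)}

            eta = d[r_pair] + alpha[r_enh]
            if m.n_candidates:
                eta = eta + np.where(beta_col >= 0,
                                     beta[np.maximum(beta_col, 0)], 0.0)
            if m.K:
                eta = eta + np.where(gamma_col >= 0,
                                     gamma[np.maximum(gamma_col, 0)], 0.0)
            mu_r = r_scale * np.exp(eta)
            rna_draw = draw_negative_binomial(rng, mu_r, phi_r[r_enh])

            sim = scaffold.copy()
            sim["dna_count"] = [dna_lut[(b, e, c)] for b, e, c in
                                zip(sim["dna_batch"], sim["enhancer"],
                                    sim["barcode"])]
            sim["rna_count"] = rna_draw
            tables.append(CountTable(sim))
        return tables


def simulate_datasets(fit: AlternateResults,
                      protocol: SimProtocol) -> list[CountTable]:
    """Functional form of :meth:`AlternateResults.simulate`."""
    return fit.simulate(protocol=protocol)
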