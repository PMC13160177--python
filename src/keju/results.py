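"""Posterior summaries, significance calling and promoter trend lines."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["KejuResults", "compute_lfsr", "call_significance"]


def compute_lfsr(draws: np.ndarray) -> np.ndarray:
    """Local false sign rate from posterior draws.

    ``lfsr = min(Pr(effect >= 0), Pr(effect <= 0))`` estimated as the
    corresponding fractions of draws; 0 means the sign is certain, 0.5 means
    the sign is a coin flip.  ``draws`` has shape (n_draws, n_effects).
    """
    draws = np.asarray(draws, dtype=float)
    frac_nonneg = np.mean(draws >= 0, axis=0)
    frac_nonpos = np.mean(draws <= 0, axis=0)
    return np.minimum(frac_nonneg, frac_nonpos)


def call_significance(table: pd.DataFrame, threshold: float = 0.05
                      ) -> pd.DataFrame:
    """Flag effects with ``lfsr < threshold`` (strict inequality).

    Returns the table sorted by (lfsr ascending, |posterior mean|
    descending) with a boolean ``significant`` column.
    """
    if not 0.0 < threshold <= 0.5:
        raise ValueError(f"threshold must be in (0, 0.5], got {threshold}")
    out = table.copy()
    out["significant"] = out["lfsr"] < threshold
    out["_absmean"] = out["post_mean"].abs()
    out = (out.sort_values(["lfsr", "_absmean"], ascending=[True, False],
                           kind="stable")
              .drop(columns="_absmean").reset_index(drop=True))
    return out


@dataclass
class KejuResults:
    """Posterior draws, diagnostics and derived summaries for a fitted model.

    ``draws`` maps parameter names (alpha, beta, gamma, phi, theta, eps2,
    mu_m, sigma2, r, t where applicable) to arrays of shape
    (chains, samples, size); labels in :attr:`model` map positions back to
    enhancer / motif / covariate / bin identities.
    """

    model: object
    settings: object
    draws: dict[str, np.ndarray]
    raw_draws: np.ndarray
    chain_results: list
    diagnostics: dict = field(init=False)

    def __post_init__(self) -> None:
        self.diagnostics = self._diagnose()
        if self.diagnostics["divergences"] > 0:
            warnings.warn(
                f"{self.diagnostics['divergences']} divergent transitions "
                f"after warmup")
        if self.diagnostics["max_rhat"] > self.settings.rhat_tolerance:
            warnings.warn(
                f"max split-Rhat {self.diagnostics['max_rhat']:.3f} exceeds "
                f"{self.settings.rhat_tolerance}")

    # -- diagnostics -----------------------------------------------------
    def _diagnose(self) -> dict:
        div = int(sum(c.divergences for c in self.chain_results))
        max_rhat, min_ess = 1.0, float("inf")
        if self.raw_draws.shape[0] >= 2 and self.raw_draws.shape[1] >= 4:
            import arviz as az
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                idata = az.from_dict(posterior={"z": self.raw_draws})
                max_rhat = float(az.rhat(idata)["z"].max())
                min_ess = float(az.ess(idata)["z"].min())
        return {
            "divergences": div,
            "warmup_divergences": int(sum(c.warmup_divergences
                                          for c in self.chain_results)),
            "max_rhat": max_rhat,
            "min_ess": min_ess,
            "step_sizes": [float(c.step_size) for c in self.chain_results],
        }

    # -- draw access -----------------------------------------------------
    def stacked(self, name: str) -> np.ndarray:
        """Draws for ``name`` pooled across chains: (chains*samples, size)."""
        d = self.draws[name]
        return d.reshape(-1, d.shape[-1]) if d.ndim == 3 else d.reshape(-1)

    @property
    def n_draws(self) -> int:
        return self.raw_draws.shape[0] * self.raw_draws.shape[1]

    # -- summaries -------------------------------------------------------
    def _summarize(self, name: str, labels: list) -> pd.DataFrame:
        d = self.stacked(name)
        return pd.DataFrame({
            "label": labels,
            "post_mean": d.mean(axis=0),
            "post_sd": d.std(axis=0, ddof=1),
            "ci5": np.quantile(d, 0.05, axis=0),
            "ci95": np.quantile(d, 0.95, axis=0),
        })

    def summary(self) -> pd.DataFrame:
        """Posterior mean/sd and 90% interval for every parameter block."""
        m = self.model
        blocks = [("alpha", m.enhancers), ("beta", m.candidates),
                  ("phi", list(range(m.n_bins)))]
        if m.K:
            blocks.append(("gamma", m.covariates))
        if m.prior.case != "flat":
            blocks += [("theta", m.motifs), ("eps2", m.motifs),
                       ("mu_m", m.cand_motifs), ("sigma2", m.cand_motifs)]
            if getattr(m, "_use_rt", False):
                blocks += [("r", m.covariates), ("t", m.covariates)]
        parts = []
        for name, labels in blocks:
            if name not in self.draws:
                continue
            part = self._summarize(name, labels)
            part.insert(0, "parameter", name)
            parts.append(part)
        return pd.concat(parts, ignore_index=True)

    def transcription_rates(self) -> pd.DataFrame:
        """Per-enhancer posterior summary of the transcription rate alpha."""
        out = self._summarize("alpha", self.model.enhancers)
        return out.rename(columns={"label": "enhancer"})

    # -- significance ----------------------------------------------------
    def lfsr(self) -> pd.Series:
        """Per-candidate local false sign rate of the effect size beta."""
        return pd.Series(compute_lfsr(self.stacked("beta")),
                         index=self.model.candidates, name="lfsr")

    def significance_table(self, threshold: float = 0.05) -> pd.DataFrame:
        """Per-candidate effect summary with LFSR-based significance calls."""
        m = self.model
        beta = self.stacked("beta")
        tab = pd.DataFrame({
            "enhancer": m.candidates,
            "post_mean": beta.mean(axis=0),
            "ci5": np.quantile(beta, 0.05, axis=0),
            "ci95": np.quantile(beta, 0.95, axis=0),
            "lfsr": compute_lfsr(beta),
        })
        table = m.input.table
        if table.has_motifs:
            motif_of = table.enhancer_label_map("motif")
            tab["motif"] = [motif_of[e] for e in m.candidates]
        if table.has_covariates:
            cov_of = table.enhancer_label_map("covariate")
            tab["covariate"] = [cov_of[e] for e in m.candidates]
        return call_significance(tab, threshold=threshold)

    # -- promoter trends -------------------------------------------------
    def promoter_trend(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Promoter-level slope/intercept posteriors and per-(motif,
        covariate) trend predictions ``t_k + (1 + r_k) * theta_m``.

        Predictions cover every motif x covariate combination, including
        pairs unobserved in the data (the trend line is exactly what lets
        the model extrapolate to unseen promoter-motif pairings).
        """
        m = self.model
        if m.prior.case != "promoter_motif":
            raise ValueError("promoter_trend requires the promoter_motif "
                             "prior case")
        r = self.stacked("r")
        t = self.stacked("t")
        lines = pd.DataFrame({
            "covariate": m.covariates,
            "intercept_mean": t.mean(axis=0),
            "intercept_ci5": np.quantile(t, 0.05, axis=0),
            "intercept_ci95": np.quantile(t, 0.95, axis=0),
            "slope_mean": (1.0 + r).mean(axis=0),
            "slope_ci5": np.quantile(1.0 + r, 0.05, axis=0),
            "slope_ci95": np.quantile(1.0 + r, 0.95, axis=0),
        })
        theta = self.stacked("theta")
        rows = []
        for j, motif in enumerate(m.motifs):
            pred = t + (1.0 + r) * theta[:, [j]]    # (draws, K)
            for k, cov in enumerate(m.covariates):
                rows.append({
                    "motif": motif, "covariate": cov,
                    "trend_mean": float(pred[:, k].mean()),
                    "trend_ci5": float(np.quantile(pred[:, k], 0.05)),
                    "trend_ci95": float(np.quantile(pred[:, k], 0.95)),
                })
        return lines, pd.DataFrame(rows)

    # -- persistence -----------------------------------------------------
    def save(self, outdir: str | Path, threshold: float = 0.05) -> None:
        """Write significance, rates, trends, draws and a run manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.significance_table(threshold).to_csv(
            outdir / "significance.tsv", sep="\t", index=False)
        self.transcription_rates().to_csv(
            outdir / "transcription_rates.tsv", sep="\t", index=False)
        if self.model.prior.case == "promoter_motif":
            lines, trends = self.promoter_trend()
            lines.to_csv(outdir / "promoter_lines.tsv", sep="\t", index=False)
            trends.to_csv(outdir / "promoter_trends.tsv", sep="\t",
                          index=False)
        cols = {}
        for name, d in self.draws.items():
            flat = d.reshape(self.n_draws, -1)
            for j in range(flat.shape[1]):
                cols[f"{name}[{j}]"] = flat[:, j]
        pd.DataFrame(cols).to_csv(outdir / "draws.tsv.gz", sep="\t",
                                  index=False, compression="gzip")
        import keju
        manifest = {
            "settings": {k: getattr(self.settings, k) for k in
                         ("chains", "warmup", "samples", "seed",
                          "rhat_tolerance")},
            "prior_case": self.model.prior.case,
            "diagnostics": self.diagnostics,
            "lfsr_threshold": threshold,
            "keju_version": keju.__version__,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
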