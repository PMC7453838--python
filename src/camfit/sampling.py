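"""Metropolis Monte-Carlo sampling and chain summaries.

The sampler is a plain random-walk Metropolis with symmetric Gaussian
proposals: from the current state a proposal is drawn, and it is accepted with
probability ``min(1, p1/p0)``.  The saved samples represent the posterior
distribution of the fitted parameters; means, standard deviations and central
credible intervals are reported from the post-burn-in chain.

During the burn-in phase (discarded) the proposal is adapted: a global scale
factor targets a 20-40 % acceptance rate, and once enough burn-in samples have
accumulated the proposal covariance is replaced by the scaled empirical
covariance of the chain (Haario-style).  The kernel is frozen after burn-in,
so the retained samples come from a fixed, valid Metropolis kernel.
"""

from __future__ import annotations

import dataclasses
import io
import json
import warnings

import numpy as np
import pandas as pd

__all__ = ["ChainSummary", "metropolis_sample", "ZeroAcceptanceError"]


class ZeroAcceptanceError(RuntimeError):
    """No proposal was accepted over the whole chain."""


@dataclasses.dataclass
class ChainSummary:
    """Posterior samples of a Metropolis run plus summary statistics.

    Attributes
    ----------
    samples : ndarray, shape (n_kept, n_params)
        Post-burn-in samples.
    param_names : list of str
    acceptance_rate : float
        Fraction of accepted proposals over the full run (including burn-in).
    seed : int or None
        Seed used for the run, for reproducibility bookkeeping.
    """

    samples: np.ndarray
    param_names: list
    acceptance_rate: float
    seed: int | None = None
    n_iter: int | None = None
    n_burn: int | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-d (iteration x parameter)")
        if len(self.param_names) != self.samples.shape[1]:
            raise ValueError("param_names must match the number of columns")
        if not (0.0 < self.acceptance_rate <= 1.0):
            warnings.warn(
                f"acceptance rate {self.acceptance_rate:.3f} outside (0, 1]",
                stacklevel=2)
        mean, lo95, hi95 = self.mean, self.ci95[:, 0], self.ci95[:, 1]
        if np.any((mean < lo95) | (mean > hi95)):
            warnings.warn("posterior mean lies outside the 95% credible "
                          "interval; the chain may be multimodal or poorly "
                          "mixed", stacklevel=2)

    @property
    def mean(self) -> np.ndarray:
        return self.samples.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        return self.samples.std(axis=0, ddof=1)

    @property
    def ci68(self) -> np.ndarray:
        return np.quantile(self.samples, [0.16, 0.84], axis=0).T

    @property
    def ci95(self) -> np.ndarray:
        return np.quantile(self.samples, [0.025, 0.975], axis=0).T

    def __getitem__(self, name: str) -> np.ndarray:
        return self.samples[:, self.param_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=self.param_names)

    def summary_dict(self) -> dict:
        out = {}
        for j, name in enumerate(self.param_names):
            out[name] = {
                "mean": float(self.mean[j]),
                "sd": float(self.sd[j]),
                "ci68": [float(v) for v in self.ci68[j]],
                "ci95": [float(v) for v in self.ci95[j]],
            }
        return out

    def summary(self) -> str:
        """Plain-text summary table (mean, sd, credible intervals)."""
        buf = io.StringIO()
        buf.write(f"{'parameter':<16}{'mean':>12}{'sd':>12}"
                  f"{'16%':>12}{'84%':>12}{'2.5%':>12}{'97.5%':>12}\n")
        buf.write("-" * 88 + "\n")
        for j, name in enumerate(self.param_names):
            buf.write(f"{name:<16}{self.mean[j]:>12.4f}{self.sd[j]:>12.4f}"
                      f"{self.ci68[j, 0]:>12.4f}{self.ci68[j, 1]:>12.4f}"
                      f"{self.ci95[j, 0]:>12.4f}{self.ci95[j, 1]:>12.4f}\n")
        buf.write(f"\nacceptance rate: {self.acceptance_rate:.3f}"
                  f"   samples: {self.samples.shape[0]}"
                  f"   seed: {self.seed}\n")
        return buf.getvalue()

    def save(self, samples_csv, summary_json) -> None:
        """Write the samples as CSV and the summary statistics as JSON."""
        self.to_frame().to_csv(samples_csv, index=False)
        payload = {
            "parameters": self.summary_dict(),
            "acceptance_rate": self.acceptance_rate,
            "seed": self.seed,
            "n_iter": self.n_iter,
            "n_burn": self.n_burn,
        }
        with open(summary_json, "w") as fh:
            json.dump(payload, fh, indent=2)

    def plot_posteriors(self, axes=None):
        """Histogram of each marginal posterior (matplotlib)."""
        import matplotlib.pyplot as plt

        d = self.samples.shape[1]
        if axes is None:
            _, axes = plt.subplots(1, d, figsize=(3 * d, 2.5))
        axes = np.atleast_1d(axes)
        for j, (ax, name) in enumerate(zip(axes, self.param_names)):
            ax.hist(self.samples[:, j], bins=50, density=True)
            ax.axvline(self.mean[j], color="k", lw=1)
            ax.set_xlabel(name)
        return axes


def metropolis_sample(loglik, init_params, proposal_scales, n_iter: int,
                      seed=None, *, burn_in_frac: float = 0.2,
                      adapt: bool = True, param_names=None,
                      rng: np.random.Generator | None = None) -> ChainSummary:
    """Random-walk Metropolis sampling of ``loglik``.

    Parameters
    ----------
    loglik : callable
        Maps a parameter vector to a (possibly -inf) log probability.
    init_params : array_like
        Starting point; its log probability must be finite.
    proposal_scales : array_like
        Initial per-parameter Gaussian proposal standard deviations.
    n_iter : int
        Total number of iterations; the first ``burn_in_frac`` fraction is
        discarded before summaries.
    seed : int, optional
        Seed for the internal generator (ignored when ``rng`` is given).
        Identical seeds yield bit-identical chains.
    adapt : bool
        Adapt the proposal during burn-in (scale targeting 20-40 % acceptance,
        then empirical-covariance proposals); frozen after burn-in.

    Raises
    ------
    ValueError
        If the initial log probability is not finite.
    ZeroAcceptanceError
        If no proposal was accepted; suggests adjusting the proposal scales.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    x = np.asarray(init_params, dtype=float).copy()
    d = x.size
    scales = np.asarray(proposal_scales, dtype=float).copy()
    if scales.size != d:
        raise ValueError("proposal_scales must match init_params")
    if rng is None:
        rng = np.random.default_rng(seed)
    lp = float(loglik(x))
    if not np.isfinite(lp):
        raise ValueError("initial parameters have non-finite log probability")

    n_burn = int(round(burn_in_frac * n_iter))
    chain = np.empty((n_iter, d))
    accepted = 0
    window_acc = 0
    window = 100
    scale_factor = 1.0
    chol = None  # switched on once burn-in covariance is available

    for i in range(n_iter):
        z = rng.standard_normal(d)
        if chol is not None:
            step = scale_factor * (chol @ z)
        else:
            step = scale_factor * scales * z
        prop = x + step
        lp_prop = float(loglik(prop))
        logu = np.log(rng.uniform())
        if lp_prop - lp >= logu:
            x, lp = prop, lp_prop
            accepted += 1
            window_acc += 1
        chain[i] = x

        if adapt and i < n_burn:
            if (i + 1) % window == 0:
                rate = window_acc / window
                window_acc = 0
                if rate < 0.20:
                    scale_factor *= 0.7
                elif rate > 0.40:
                    scale_factor *= 1.4
            if i + 1 == max(2 * d + 10, n_burn // 2):
                cov = np.cov(chain[: i + 1].T).reshape(d, d)
                cov += np.diag(np.maximum(1e-12, 1e-8 * scales ** 2))
                try:
                    chol = np.linalg.cholesky((2.38 ** 2 / d) * cov)
                    scale_factor = 1.0
                except np.linalg.LinAlgError:
                    chol = None

    if accepted == 0:
        raise ZeroAcceptanceError(
            "no Metropolis proposal was accepted over the whole chain; "
            "reduce the proposal scales (or check the log-likelihood)")

    if param_names is None:
        param_names = [f"p{j}" for j in range(d)]
    return ChainSummary(samples=chain[n_burn:], param_names=list(param_names),
                        acceptance_rate=accepted / n_iter,
                        seed=seed, n_iter=n_iter, n_burn=n_burn)
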