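"""Predictive model-assessment criteria.

From a posterior fit this module computes

* DIC: posterior mean deviance D-bar, plug-in deviance D(theta-bar),
  effective number of parameters p_D = D-bar - D(theta-bar), and
  DIC = D-bar + p_D.  The standardizing term log h(y) is fixed to 0, so
  only DIC *differences* across models are meaningful.
* per-observation logarithmic scores LS_ij = -log CPO_ij and their mean
  (lower = better; a strictly proper scoring rule on the leave-one-out
  predictive);
* adjusted PIT values for count predictives,
  PIT_ij = Pr(y_new < y_ij | y_-ij) + 0.5 Pr(y_new = y_ij | y_-ij),
  uniform under calibration; the continuous arcsinh normal model uses the
  plain predictive CDF;
* the back-transformation of the arcsinh-scale mean log score onto the
  count scale, which makes the normal mixed model's mean score comparable
  with the count models' scores.  Only the mean can be back-transformed,
  never the observation-level scores, so permutation tests against count
  models are not applicable for the transformed-outcome model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mcmc import MCMCConfig, PosteriorFit, loo_predictive, plug_in_deviance

__all__ = [
    "DICResult",
    "Assessment",
    "compute_dic",
    "compute_log_scores",
    "compute_pit",
    "pit_histogram",
    "backtransform_mean_ls",
    "assess",
]


@dataclass(frozen=True)
class DICResult:
    d_bar: float
    d_hat: float
    p_d: float
    dic: float

    def as_tuple(self):
        return (self.d_bar, self.d_hat, self.p_d, self.dic)


@dataclass
class Assessment:
    """Per-observation predictive diagnostics plus global criteria."""

    model: str
    family: str
    cpo: np.ndarray
    ls: np.ndarray
    pit: np.ndarray | None
    flags: np.ndarray
    dic: DICResult
    mean_ls: float
    scale: str                    # 'original' | 'arcsinh_backtransformed'
    mean_ls_transformed: float | None = None
    dic_comparable: bool = True
    data_checksum: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_obs(self) -> int:
        return len(self.ls)

    def table(self) -> pd.DataFrame:
        cols = {"cpo": self.cpo, "ls": self.ls, "flagged": self.flags}
        if self.pit is not None:
            cols["pit"] = self.pit
        return pd.DataFrame(cols)


def compute_dic(fit: PosteriorFit) -> DICResult:
    """Deviance information criterion from the log-likelihood matrix.

    D-bar is the posterior mean of -2 log f(y | theta); the plug-in
    deviance evaluates the same likelihood at the component-wise posterior
    means of all latent quantities (fixed effects, random effects and
    hyperparameters), so p_D counts effective observation-level
    parameters.
    """
    d_bar = float((-2.0 * fit.loglik_matrix.sum(axis=1)).mean())
    d_hat = plug_in_deviance(fit)
    p_d = d_bar - d_hat
    return DICResult(d_bar=d_bar, d_hat=d_hat, p_d=p_d, dic=d_bar + p_d)


def compute_log_scores(cpo: np.ndarray) -> tuple[np.ndarray, float]:
    """LS_ij = -log CPO_ij and the unweighted mean over all observations.

    A zero CPO produces an infinite score, reported as such rather than
    masked.
    """
    cpo = np.asarray(cpo, dtype=float)
    if np.any(cpo < 0):
        raise ValueError("CPO values must be non-negative")
    with np.errstate(divide="ignore"):
        ls = -np.log(cpo)
    return ls, float(ls.mean())


def compute_pit(fit: PosteriorFit, method: str = "mixed",
                n_draws: int | None = None,
                grid_size: int | None = None) -> np.ndarray:
    """Adjusted leave-one-out PIT per observation.

    Count families get the non-randomized adjustment (half credit for the
    predictive mass at the observed value); the continuous arcsinh normal
    model returns the predictive CDF at the observation.
    """
    cpo, _, prob_below = loo_predictive(
        fit, method=method, n_draws=n_draws, grid_size=grid_size,
        want_cdf=True)
    if fit.spec.is_count:
        pit = prob_below + 0.5 * cpo
    else:
        pit = prob_below
    return np.clip(pit, 0.0, 1.0)


def pit_histogram(pit: np.ndarray, n_bins: int = 10) -> pd.DataFrame:
    """Relative PIT frequencies on [0, 1] with the flat reference height.

    Bins are half-open [l, u) except the last, which includes 1.0, so a
    PIT of exactly 1 lands in the rightmost bin.  Frequencies sum to 1;
    the reference height 1/n_bins is the perfectly calibrated value.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    pit = np.asarray(pit, dtype=float)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(pit, bins=edges)  # last bin closed
    return pd.DataFrame({
        "bin_left": edges[:-1],
        "bin_right": edges[1:],
        "frequency": counts / max(len(pit), 1),
        "reference": np.full(n_bins, 1.0 / n_bins),
    })


def backtransform_mean_ls(mean_ls_transformed: float, y: np.ndarray,
                          transform: str = "arcsinh") -> float:
    """Convert a transformed-scale mean log score to the count scale.

    For z = g(y) with density psi on the transformed scale, the
    change of variables gives
    E[-log phi(Y)] = E[-log psi(Z)] - E[log g'(g^{-1}(Z))], so the
    correction subtracts the empirical mean of log g'(y).  For
    g = arcsinh, g'(y) = 1 / sqrt(1 + y^2); the identity transform has a
    zero correction.
    """
    y = np.asarray(y, dtype=float)
    if transform == "identity":
        return float(mean_ls_transformed)
    if transform != "arcsinh":
        raise ValueError(f"unknown transform {transform!r}")
    mean_log_gprime = float(np.mean(-0.5 * np.log1p(y ** 2)))
    return float(mean_ls_transformed - mean_log_gprime)


def assess(fit: PosteriorFit, *, pit: bool = True, cpo_method: str = "mixed",
           n_draws: int | None = None,
           grid_size: int | None = None) -> Assessment:
    """Full predictive assessment of one fitted model.

    For the arcsinh normal model the observation-level scores live on the
    transformed scale; ``mean_ls`` is back-transformed to the count scale
    (flagged by ``scale``) so that model ranking can mix transformed and
    count models, while ``dic_comparable`` is False because a deviance on
    a transformed outcome cannot be compared with count-scale deviances.
    """
    cpo, flags, _ = loo_predictive(fit, method=cpo_method, n_draws=n_draws,
                                   grid_size=grid_size, want_cdf=False)
    ls, mean_ls = compute_log_scores(cpo)
    pit_vals = (compute_pit(fit, method=cpo_method, n_draws=n_draws,
                            grid_size=grid_size) if pit else None)
    dic = compute_dic(fit)
    is_nmm = fit.spec.family == "nmm_arcsinh"
    if is_nmm:
        y = fit.data.counts()
        mean_ls_bt = backtransform_mean_ls(mean_ls, y)
        return Assessment(
            model=fit.spec.label(), family=fit.spec.family, cpo=cpo, ls=ls,
            pit=pit_vals, flags=flags, dic=dic, mean_ls=mean_ls_bt,
            scale="arcsinh_backtransformed", mean_ls_transformed=mean_ls,
            dic_comparable=False, data_checksum=fit.meta["data_checksum"],
            meta={"cpo_method": cpo_method})
    return Assessment(
        model=fit.spec.label(), family=fit.spec.family, cpo=cpo, ls=ls,
        pit=pit_vals, flags=flags, dic=dic, mean_ls=mean_ls,
        scale="original", dic_comparable=True,
        data_checksum=fit.meta["data_checksum"],
        meta={"cpo_method": cpo_method})
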