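"""Candidate model families for longitudinal counts.

Five rival mixed models share one linear predictor on the link scale,

    eta_ij = (beta0 + b0_i) + (beta1 + b1_i) * t_ij + beta2 * x_i
             + beta3 * x_i * t_ij,

and differ in the conditional observation distribution:

* ``poisson``      Y_ij ~ Poi(mu_ij),               mu_ij = exp(eta_ij)
* ``nb``           Y_ij ~ NB(k, p_ij),              p_ij = k/(k + mu_ij)
* ``zip``/``zinb`` zero-inflated mixtures: 0 with probability Pi0, else
                   the Poisson/NB draw
* ``nmm_arcsinh``  Gaussian errors for the arcsinh-transformed count,
                   identity link (a variance-stabilized normal mixed model)

The random-effects structure is either a subject intercept only (``I``) or
a correlated intercept + slope pair (``IS``) with a Wishart hyperprior on
the 2x2 precision matrix.  Everything here is a pure function of data and
parameters; sampling lives in :mod:`glmmscore.mcmc`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .data import LongCountData

__all__ = [
    "FAMILIES",
    "PriorSpec",
    "ModelSpec",
    "ParamState",
    "design_matrix",
    "prepare_arrays",
    "linear_predictor",
    "loglik_obs",
    "count_logpmf",
    "count_cdf",
    "arcsinh_transform",
    "arcsinh_inverse",
    "vst_negbin",
    "derive_gamma_prior",
    "re_precision_matrix",
    "re_covariance_matrix",
]

FAMILIES = ("poisson", "nb", "zip", "zinb", "nmm_arcsinh")
COUNT_FAMILIES = ("poisson", "nb", "zip", "zinb")
ZI_FAMILIES = ("zip", "zinb")

_FORMULAS = {
    # intercept, time, group, group x time
    "main_interaction": ("intercept", "time", "group", "group:time"),
    # the pre-study parameterization drops the group main effect: groups
    # share a baseline level and differ only in slope
    "pre_study": ("intercept", "time", "group:time"),
}


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the (weakly informative) priors.

    * independent N(0, 1/beta_precision) on each fixed effect;
    * Gamma(a, b) (shape/rate) on the random-intercept precision for
      structure ``I`` — integrating it out gives a Student-t marginal for
      the intercept, see :func:`derive_gamma_prior`;
    * Wishart(r, R^-1) on the 2x2 random-effects precision for ``IS``;
    * diffuse Gamma on the NB size k, Beta on the zero-inflation mass Pi0,
      Gamma on the residual precision of the arcsinh normal model.
    """

    beta_precision: float = 0.001
    intercept_prec_a: float = 0.5
    intercept_prec_b: float = 0.001115
    wishart_r: float = 4.0
    wishart_R: tuple[tuple[float, float], tuple[float, float]] = (
        (1.0, 0.0), (0.0, 1.0))
    k_a: float = 0.01
    k_b: float = 0.01
    pi0_a: float = 1.0
    pi0_b: float = 1.0
    eps_prec_a: float = 1.0
    eps_prec_b: float = 5e-5

    def __post_init__(self) -> None:
        if self.intercept_prec_a <= 0 or self.intercept_prec_b <= 0:
            raise ValueError("Gamma prior needs a > 0, b > 0")
        if self.wishart_r <= 1:
            raise ValueError("Wishart degrees of freedom must exceed 1 "
                             "for a proper prior")
        R = np.asarray(self.wishart_R, dtype=float)
        if not np.allclose(R, R.T) or np.any(np.linalg.eigvalsh(R) <= 0):
            raise ValueError("Wishart R must be symmetric positive definite")

    @property
    def R(self) -> np.ndarray:
        return np.asarray(self.wishart_R, dtype=float)


@dataclass(frozen=True)
class ModelSpec:
    """One candidate GLMM: family + random structure + formula + priors."""

    family: str
    random_structure: str = "I"
    fixed_formula: str = "main_interaction"
    priors: PriorSpec = field(default_factory=PriorSpec)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.random_structure not in {"I", "IS", "none"}:
            raise ValueError("random_structure must be 'I', 'IS' or 'none'")
        if self.fixed_formula not in _FORMULAS:
            raise ValueError(f"unknown formula {self.fixed_formula!r}")

    @property
    def n_random(self) -> int:
        return {"none": 0, "I": 1, "IS": 2}[self.random_structure]

    @property
    def is_count(self) -> bool:
        return self.family in COUNT_FAMILIES

    @property
    def coef_names(self) -> tuple[str, ...]:
        return _FORMULAS[self.fixed_formula]

    def label(self) -> str:
        fam = {"poisson": "Poisson", "nb": "NB", "zip": "ZIP",
               "zinb": "ZINB", "nmm_arcsinh": "arcsinh"}[self.family]
        return f"{fam}({self.random_structure})"


@dataclass
class ParamState:
    """One point in parameter space (a posterior draw or a plug-in value).

    ``b`` is the (N, q) matrix of subject effects; ``tau_b0``/``tau_b1``
    are marginal precisions and ``rho`` the intercept-slope correlation,
    so the IS covariance is [[1/tau_b0, rho/sqrt(tau_b0*tau_b1)], [., 1/tau_b1]].
    """

    beta: np.ndarray
    b: np.ndarray
    tau_b0: float | None = None
    tau_b1: float | None = None
    rho: float = 0.0
    k: float | None = None
    pi0: float | None = None
    sigma_eps: float | None = None

    def validate(self) -> None:
        for nm in ("tau_b0", "tau_b1"):
            v = getattr(self, nm)
            if v is not None and v <= 0:
                raise ValueError(f"{nm} must be > 0")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("|rho| must be < 1")


def re_covariance_matrix(tau_b0: float, tau_b1: float, rho: float) -> np.ndarray:
    s0, s1 = 1.0 / np.sqrt(tau_b0), 1.0 / np.sqrt(tau_b1)
    return np.array([[s0 * s0, rho * s0 * s1], [rho * s0 * s1, s1 * s1]])


def re_precision_matrix(tau_b0: float, tau_b1: float, rho: float) -> np.ndarray:
    return np.linalg.inv(re_covariance_matrix(tau_b0, tau_b1, rho))


# ---------------------------------------------------------------------------
# design matrices


def design_matrix(data: LongCountData, formula: str) -> np.ndarray:
    t = data.table["time"].to_numpy(dtype=float)
    x = data.table["group"].to_numpy(dtype=float)
    cols = {
        "intercept": np.ones_like(t),
        "time": t,
        "group": x,
        "group:time": x * t,
    }
    return np.column_stack([cols[c] for c in _FORMULAS[formula]])


def prepare_arrays(data: LongCountData, spec: ModelSpec) -> dict:
    """Shared array bundle: response, design, subject codes."""
    tab = data.table
    sid, codes = np.unique(tab["subject_id"].to_numpy(), return_inverse=True)
    y = tab["count"].to_numpy(dtype=float)
    if spec.is_count and not np.allclose(y, np.round(y)):
        raise ValueError("count families require integer responses")
    return {
        "y": y,
        "z": arcsinh_transform(y),
        "t": tab["time"].to_numpy(dtype=float),
        "X": design_matrix(data, spec.fixed_formula),
        "subj": codes,
        "subject_ids": sid,
        "n_subjects": len(sid),
    }


def linear_predictor(state: ParamState, data: LongCountData,
                     spec: ModelSpec) -> np.ndarray:
    """eta_ij for every row of ``data``, dropping terms absent from the
    spec (no group main effect under ``pre_study``; no b1 under ``I``)."""
    arr = prepare_arrays(data, spec)
    X, subj, t = arr["X"], arr["subj"], arr["t"]
    beta = np.asarray(state.beta, dtype=float)
    if beta.shape != (X.shape[1],):
        raise ValueError(
            f"beta has shape {beta.shape}, formula needs {X.shape[1]} terms")
    eta = X @ beta
    q = spec.n_random
    if q:
        b = np.atleast_2d(np.asarray(state.b, dtype=float))
        if b.shape[0] != arr["n_subjects"] or b.shape[1] < q:
            raise ValueError("random-effect matrix does not match data")
        eta = eta + b[subj, 0]
        if q == 2:
            eta = eta + b[subj, 1] * t
    return eta


# ---------------------------------------------------------------------------
# observation likelihoods


def _poisson_logpmf(y, eta):
    return y * eta - np.exp(eta) - special.gammaln(y + 1.0)


def _nb_logpmf(y, eta, k):
    mu = np.exp(eta)
    lkm = np.log(k + mu)
    return (special.gammaln(y + k) - special.gammaln(k)
            - special.gammaln(y + 1.0)
            + k * (np.log(k) - lkm) + y * (eta - lkm))


def _zi_mix(y, base, pi0):
    if pi0 == 0.0:
        return base
    out = np.log1p(-pi0) + base
    at0 = y == 0
    if np.any(at0):
        out = np.where(
            at0, np.logaddexp(np.log(pi0), np.log1p(-pi0) + base), out)
    return out


def count_logpmf(y, eta, family: str, k: float | None = None,
                 pi0: float | None = None) -> np.ndarray:
    """log f(y | eta, hyper) for any count family (vectorized)."""
    y = np.asarray(y, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if family == "poisson":
        return _poisson_logpmf(y, eta)
    if family == "nb":
        return _nb_logpmf(y, eta, k)
    base = (_poisson_logpmf(y, eta) if family == "zip"
            else _nb_logpmf(y, eta, k))
    return _zi_mix(y, base, 0.0 if pi0 is None else pi0)


def count_cdf(y, eta, family: str, k: float | None = None,
              pi0: float | None = None) -> np.ndarray:
    """P(Y <= y | eta, hyper); y may be negative (returns 0)."""
    y, eta = np.broadcast_arrays(np.asarray(y, dtype=float),
                                 np.asarray(eta, dtype=float))
    mu = np.exp(eta)
    neg = y < 0
    yc = np.where(neg, 0.0, np.floor(y))
    if family in ("poisson", "zip"):
        base = special.pdtr(yc, mu)
    else:
        p = k / (k + mu)
        base = special.betainc(k, yc + 1.0, p)
    if family in ZI_FAMILIES and pi0:
        base = pi0 + (1.0 - pi0) * base
    return np.where(neg, 0.0, base)


def loglik_obs(state: ParamState, y, eta, spec: ModelSpec) -> np.ndarray:
    """Per-observation conditional log-likelihood log f(y | theta, b).

    ``y`` and ``eta`` broadcast; for count families ``mu = exp(eta)``, for
    the arcsinh normal model the Gaussian density is evaluated for
    arcsinh(y) at mean ``eta`` (identity link on the transformed scale).
    """
    y = np.asarray(y, dtype=float)
    if spec.is_count:
        if np.any(y < 0) or not np.allclose(y, np.round(y)):
            raise ValueError("count families require non-negative integers")
        return count_logpmf(y, eta, spec.family, k=state.k, pi0=state.pi0)
    z = arcsinh_transform(y)
    s = state.sigma_eps
    return -0.5 * np.log(2.0 * np.pi) - np.log(s) \
        - 0.5 * ((z - np.asarray(eta, dtype=float)) / s) ** 2


class ObsLoglik:
    """Precomputed per-dataset likelihood kernels for the sampler.

    Splits the zero-inflated families into a count part (function of eta
    and k) and a mixing step (function of Pi0 only), so Pi0 updates do not
    re-evaluate Gamma functions.  Caches gammaln(y + k) per value of k.
    """

    def __init__(self, y: np.ndarray, family: str):
        self.family = family
        self.y = np.asarray(y, dtype=float)
        self.z = arcsinh_transform(self.y)
        self._lgy1 = special.gammaln(self.y + 1.0)
        self._at0 = self.y == 0
        self._k_cache: dict[float, np.ndarray] = {}
        self.base_family = {"zip": "poisson", "zinb": "nb"}.get(family, family)

    def _lgyk(self, k: float) -> np.ndarray:
        # two LRU slots: the current value of k and one live proposal
        hit = self._k_cache.pop(k, None)
        if hit is None:
            if len(self._k_cache) >= 2:
                self._k_cache.pop(next(iter(self._k_cache)))
            hit = special.gammaln(self.y + k)
        self._k_cache[k] = hit
        return hit

    def base(self, eta: np.ndarray, k: float | None = None,
             sigma: float | None = None) -> np.ndarray:
        fam = self.base_family
        if fam == "poisson":
            with np.errstate(over="ignore"):  # exp overflow -> -inf loglik
                return self.y * eta - np.exp(eta) - self._lgy1
        if fam == "nb":
            with np.errstate(over="ignore"):
                lkm = np.log(k + np.exp(eta))
                return (self._lgyk(k) - special.gammaln(k) - self._lgy1
                        + k * (np.log(k) - lkm) + self.y * (eta - lkm))
        # arcsinh normal
        return -0.5 * np.log(2.0 * np.pi) - np.log(sigma) \
            - 0.5 * ((self.z - eta) / sigma) ** 2

    def mix(self, base: np.ndarray, pi0: float | None) -> np.ndarray:
        if self.family not in ZI_FAMILIES or not pi0:
            return base
        shifted = np.log1p(-pi0) + base
        # _at0 broadcasts against (..., n_obs)-shaped likelihood grids
        return np.where(self._at0,
                        np.logaddexp(np.log(pi0), shifted), shifted)

    def full(self, eta: np.ndarray, k: float | None = None,
             pi0: float | None = None,
             sigma: float | None = None) -> np.ndarray:
        return self.mix(self.base(eta, k=k, sigma=sigma), pi0)

    def cdf_below(self, eta: np.ndarray, k: float | None = None,
                  pi0: float | None = None,
                  sigma: float | None = None) -> np.ndarray:
        """P(Y_new < y) for counts (CDF at y-1); P(Z_new <= z) for the
        continuous arcsinh model."""
        if self.family in COUNT_FAMILIES:
            return count_cdf(self.y - 1.0, eta, self.family, k=k, pi0=pi0)
        return stats.norm.cdf(self.z, loc=eta, scale=sigma)


# ---------------------------------------------------------------------------
# transforms and prior derivation


def arcsinh_transform(y):
    """arcsinh(y) = log(y + sqrt(y^2 + 1)); strictly increasing, maps
    [0, inf) to [0, inf) and behaves like log(2y) for large counts."""
    return np.arcsinh(np.asarray(y, dtype=float))


def arcsinh_inverse(z):
    """g^-1(z) = (e^z - e^-z) / 2 = sinh(z)."""
    return np.sinh(np.asarray(z, dtype=float))


def vst_negbin(y, z):
    """Asymptotic variance-stabilizing transform for NB counts.

    With variance function v(u) = u (z u + 1), z = 1/k, the stabilizer is
    T(y) = int_0^y v(u)^{-1/2} du = 2 arcsinh(sqrt(z y)) / sqrt(z),
    which tends to the Poisson stabilizer 2 sqrt(y) as z -> 0.
    """
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if np.any(y < 0):
        raise ValueError("y must be >= 0")
    if np.any(z < 0):
        raise ValueError("overdispersion z = 1/k must be >= 0")
    sz = np.sqrt(z)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(z == 0, 2.0 * np.sqrt(y),
                       2.0 * np.arcsinh(np.sqrt(z * y)) / np.where(sz == 0, 1.0, sz))
    return out if out.ndim else float(out)


def derive_gamma_prior(range95: float, a: float = 0.5) -> tuple[float, float]:
    """Gamma(a, b) prior on a normal precision from a 95% marginal range.

    If tau ~ Gamma(a, b) and x | tau ~ N(0, 1/tau), the marginal of x is a
    Student t with 2a degrees of freedom and scale sqrt(b/a).  Given the
    target symmetric 95% range [-q, q], solve
    t_{0.975, 2a} * sqrt(b/a) = q  =>  b = a * (q / t_{0.975, 2a})^2.

    ``derive_gamma_prior(0.6, 0.5)`` gives the rate 0.001115 (marginal
    t_1(0, 0.00223, 1), i.e. a Cauchy) used for the simulation-study
    random-intercept precision.
    """
    if range95 <= 0 or a <= 0:
        raise ValueError("range95 and a must be > 0")
    tq = stats.t.ppf(0.975, df=2.0 * a)
    return a, a * (range95 / tq) ** 2
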