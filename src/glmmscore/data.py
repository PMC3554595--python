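"""Synthetic longitudinal count data.

Generators for repeated-count trial data with subject-level random effects:

* a negative-binomial (or Poisson) random-intercept process on a balanced
  visit grid, mimicking a two-arm trial in which the two groups share a
  baseline level but decay at different rates;
* zero-inflated variants of the same process;
* a vertigo-trial-like dataset (two dose groups, five visits at months
  0, 3, 6, 9, 12) with correlated subject-specific intercepts and slopes,
  for exercising intercept-only versus intercept+slope model fits.

Counts are drawn per subject from an independent, counter-keyed random
substream, so enlarging ``n_per_group`` appends new subjects without
changing the data of existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DGPConfig",
    "LongCountData",
    "generate_nb_longitudinal",
    "generate_zero_inflated",
    "generate_vertigo_like",
]

COLUMNS = ["subject_id", "visit", "time", "group", "count"]

#: Largest conditional mean tolerated before the generator refuses to draw.
_MU_MAX = 1e12


@dataclass(frozen=True)
class DGPConfig:
    """Parameters of the longitudinal count data-generating process.

    The linear predictor on the log scale is

        log mu_ij = alpha + a_i + t_ij * (beta2 * G_i + beta1 * (1 - G_i)),

    with a_i ~ N(0, sigma_a^2) a subject-specific intercept and G_i the
    binary group indicator. Conditional on a_i, counts are negative binomial
    with size ``k`` (``family='nb'``) or Poisson (``family='poisson'``);
    zero-inflated variants replace each draw by 0 with probability ``pi0``.

    Defaults are the balanced two-group, four-visit design used throughout
    the simulation study: alpha=3, sigma_a=0.3, beta1=-0.3, beta2=-0.5,
    times (0, 1, 2, 3).
    """

    alpha: float = 3.0
    beta1: float = -0.3
    beta2: float = -0.5
    sigma_a: float = 0.3
    k: float = 5.0
    n_per_group: int = 50
    times: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0)
    family: str = "nb"
    pi0: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_a < 0:
            raise ValueError("sigma_a must be >= 0")
        if self.k <= 0:
            raise ValueError("NB size parameter k must be > 0")
        if not 0.0 <= self.pi0 < 1.0:
            raise ValueError("pi0 must lie in [0, 1)")
        if len(self.times) < 2:
            raise ValueError("need at least two visit times")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.family not in {"nb", "poisson", "zip", "zinb"}:
            raise ValueError(f"unknown family {self.family!r}")


@dataclass
class LongCountData:
    """Long-format repeated counts: one row per subject-visit.

    ``table`` has columns subject_id, visit (1-based), time, group (0/1)
    and count.  ``scale`` is ``'count'`` for integer counts; the normal
    mixed model transforms to the arcsinh scale internally and flags its
    outputs accordingly, the data container always stores raw counts.
    """

    table: pd.DataFrame
    scale: str = "count"

    def __post_init__(self) -> None:
        self.table = self.table.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        tab = self.table
        missing = [c for c in COLUMNS if c not in tab.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if self.scale == "count":
            y = tab["count"].to_numpy()
            if np.any(y < 0) or not np.allclose(y, np.round(y)):
                raise ValueError("counts must be non-negative integers")
        if tab.duplicated(["subject_id", "visit"]).any():
            raise ValueError("duplicate (subject_id, visit) pair")
        for sid, sub in tab.groupby("subject_id"):
            if sub["group"].nunique() > 1:
                raise ValueError(f"group not constant within subject {sid}")
            tt = sub.sort_values("visit")["time"].to_numpy()
            if np.any(np.diff(tt) < 0):
                raise ValueError(f"times decrease within subject {sid}")

    @property
    def n_subjects(self) -> int:
        return self.table["subject_id"].nunique()

    @property
    def n_obs(self) -> int:
        return len(self.table)

    def counts(self) -> np.ndarray:
        return self.table["count"].to_numpy(dtype=float)

    def checksum(self) -> int:
        """Cheap fingerprint used to refuse cross-dataset comparisons."""
        y = self.table["count"].to_numpy(dtype=float)
        t = self.table["time"].to_numpy(dtype=float)
        return hash((len(y), float(y.sum()), float((y * (1 + t)).sum())))

    def to_csv(self, path: str | Path) -> None:
        self.table[COLUMNS].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LongCountData":
        return cls(pd.read_csv(path))


def _subject_rng(*key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(key)))


def _draw_counts(rng: np.random.Generator, mu: np.ndarray, family: str,
                 k: float) -> np.ndarray:
    # NB as a Gamma(k, k)-mixed Poisson: exact, and the same path serves as
    # the base process of the zero-inflated NB.
    if family == "poisson":
        return rng.poisson(mu)
    g = rng.gamma(shape=k, scale=1.0 / k, size=mu.shape)
    return rng.poisson(mu * g)


def _generate_base(cfg: DGPConfig, base_family: str) -> pd.DataFrame:
    times = np.asarray(cfg.times, dtype=float)
    rows = []
    sid = 0
    for g in (0, 1):
        slope = cfg.beta2 if g == 1 else cfg.beta1
        for j in range(cfg.n_per_group):
            sid += 1
            rng = _subject_rng(cfg.seed, g, j)
            a_i = rng.normal(0.0, cfg.sigma_a) if cfg.sigma_a > 0 else 0.0
            mu = np.exp(cfg.alpha + a_i + slope * times)
            if not np.all(np.isfinite(mu)) or np.any(mu > _MU_MAX):
                raise FloatingPointError(
                    f"non-finite conditional mean for subject {sid} "
                    f"(group {g}, a_i={a_i:.3f})")
            y = _draw_counts(rng, mu, base_family, cfg.k)
            if cfg.pi0 > 0.0:
                # Zero mask comes from a spawned substream so that pi0=0
                # reproduces the base-family draws exactly.
                mask_rng = _subject_rng(cfg.seed, g, j, 1)
                y = np.where(mask_rng.random(y.shape) < cfg.pi0, 0, y)
            for v, (t, yy) in enumerate(zip(times, y), start=1):
                rows.append((sid, v, t, g, int(yy)))
    return pd.DataFrame(rows, columns=COLUMNS)


def generate_nb_longitudinal(cfg: DGPConfig) -> LongCountData:
    """Draw a balanced two-group longitudinal count dataset.

    Conditional on the subject intercept a_i ~ N(0, sigma_a^2), counts are
    NB(k, p_ij) with p_ij = k / (k + mu_ij), so that E[Y_ij | a_i] = mu_ij
    and Var[Y_ij | a_i] = mu_ij + mu_ij^2 / k.  ``family='poisson'`` drops
    the Gamma mixing (the k -> infinity limit).
    """
    if cfg.family not in {"nb", "poisson"}:
        raise ValueError("use generate_zero_inflated for zip/zinb families")
    return LongCountData(_generate_base(replace(cfg, pi0=0.0), cfg.family))


def generate_zero_inflated(cfg: DGPConfig) -> LongCountData:
    """Zero-inflated counts: each observation is 0 with probability pi0,
    otherwise drawn from the base (Poisson or NB) process."""
    if cfg.family not in {"zip", "zinb"}:
        raise ValueError("family must be 'zip' or 'zinb'")
    base = "poisson" if cfg.family == "zip" else "nb"
    return LongCountData(_generate_base(cfg, base))


@dataclass(frozen=True)
class VertigoLikeTruth:
    """Ground-truth parameters of the vertigo-like generator.

    A Poisson process with correlated subject intercepts and slopes on the
    log scale; magnitudes chosen to give month-0 attack rates around
    exp(1.6) ~ 5 per month, decaying faster in the high-dose arm.  The
    slope-heterogeneity scale makes between-subject recovery rates vary
    materially relative to the mean slope (some non-responders worsen),
    so intercept-only and intercept+slope model structures are genuinely
    distinguishable — the model-choice question the dataset exists to
    exercise.
    """

    beta0: float = 1.6
    beta_time: float = -0.19
    beta_dose_time: float = -0.17
    sigma_b0: float = 0.65
    sigma_b1: float = 0.12
    rho: float = -0.2


def generate_vertigo_like(n_low: int, n_high: int, seed: int, *,
                          truth: VertigoLikeTruth | None = None,
                          dropout: float = 0.0,
                          return_latent: bool = False):
    """Vertigo-trial-like dataset: two dose groups, visits at months
    0, 3, 6, 9, 12, Poisson counts with subject-specific intercept and
    slope.  ``dropout`` removes post-baseline visits completely at random
    to exercise imbalanced per-subject visit counts.
    """
    if n_low < 1 or n_high < 1:
        raise ValueError("need at least one subject per group")
    if not 0.0 <= dropout < 1.0:
        raise ValueError("dropout must lie in [0, 1)")
    tr = truth if truth is not None else VertigoLikeTruth()
    times = np.array([0.0, 3.0, 6.0, 9.0, 12.0])
    cov = np.array([
        [tr.sigma_b0 ** 2, tr.rho * tr.sigma_b0 * tr.sigma_b1],
        [tr.rho * tr.sigma_b0 * tr.sigma_b1, tr.sigma_b1 ** 2],
    ])
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(2))
    rows, latent = [], []
    sid = 0
    for g, n_g in ((0, n_low), (1, n_high)):
        for j in range(n_g):
            sid += 1
            rng = _subject_rng(seed, 7, g, j)
            b0, b1 = chol @ rng.normal(size=2)
            eta = (tr.beta0 + b0 + (tr.beta_time + b1) * times
                   + tr.beta_dose_time * g * times)
            y = rng.poisson(np.exp(eta))
            keep = np.ones(times.shape, dtype=bool)
            if dropout > 0.0:
                drop_rng = _subject_rng(seed, 7, g, j, 1)
                keep[1:] = drop_rng.random(len(times) - 1) >= dropout
            for v, t in enumerate(times, start=1):
                if keep[v - 1]:
                    rows.append((sid, v, t, g, int(y[v - 1])))
            latent.append((sid, b0, b1))
    data = LongCountData(pd.DataFrame(rows, columns=COLUMNS))
    if return_latent:
        lat = pd.DataFrame(latent, columns=["subject_id", "b0", "b1"])
        return data, lat
    return data
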