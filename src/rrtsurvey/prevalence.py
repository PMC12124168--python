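"""Prevalence estimation from masked binary responses.

Under the unrelated-question design each observed answer is a two-component
mixture: with probability ``p_s`` it reports the sensitive behavior
(Bernoulli ``pi_s``), otherwise the unrelated item (Bernoulli ``pi_ns``).
Three routes to the posterior of ``pi_s`` are provided:

* :func:`mom_estimate` — the closed-form moment inversion
  ``(p_obs - (1 - p_s) * pi_ns) / p_s``;
* :func:`fit_prevalence_gibbs` — a data-augmentation Gibbs sampler that
  alternates the latent question assignments with conjugate Beta updates;
* :func:`grid_posterior_oracle` — exact evaluation of the marginal posterior
  on a grid, used to verify the sampler.

With a single masked sample, ``pi_s`` and ``pi_ns`` are not separately
identifiable from binary answers alone; ``pi_ns`` therefore defaults to
*known* mode, and ``beta_prior`` mode warns about the likelihood ridge.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy import stats

from ._seeds import derive_seed

__all__ = [
    "MixtureModelSpec",
    "McmcConfig",
    "PosteriorSummary",
    "MomEstimate",
    "GridPosterior",
    "CellPosterior",
    "ContrastSummary",
    "IdentifiabilityWarning",
    "ConvergenceWarning",
    "RHAT_THRESHOLD",
    "mom_estimate",
    "fit_prevalence_gibbs",
    "fit_cell_gibbs",
    "grid_posterior_oracle",
    "summarize_posterior",
    "contrast_strata",
    "CELL_KEYS",
]

logger = logging.getLogger(__name__)

CELL_KEYS = ["municipality", "urbanization", "item_domain", "season"]
RHAT_THRESHOLD = 1.01


class IdentifiabilityWarning(UserWarning):
    """Emitted when the model is run in a mode with a known likelihood ridge."""


class ConvergenceWarning(UserWarning):
    """Emitted when rhat exceeds the convergence threshold."""


@dataclass(frozen=True)
class MixtureModelSpec:
    """Mixture model specification for one or more cells.

    ``pi_ns_mode``: ``"known"`` fixes the unrelated-item prevalence at
    ``pi_ns_value``; ``"beta_prior"`` places a Beta prior on it and samples
    it jointly (weakly identified — see module docstring).
    """

    p_s: float
    pi_ns_mode: str = "known"
    pi_ns_value: float | None = None
    pi_ns_prior: tuple[float, float] = (1.0, 1.0)
    pi_s_prior: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if not 0.0 < self.p_s <= 1.0:
            raise ValueError(f"p_s must be in (0, 1], got {self.p_s}")
        if self.pi_ns_mode not in ("known", "beta_prior"):
            raise ValueError(f"pi_ns_mode must be 'known' or 'beta_prior', got {self.pi_ns_mode!r}")
        if self.pi_ns_mode == "known":
            if self.pi_ns_value is None or not 0.0 <= self.pi_ns_value <= 1.0:
                raise ValueError(f"known mode requires pi_ns_value in [0, 1], got {self.pi_ns_value!r}")
        else:
            warnings.warn(
                "beta_prior mode: pi_s and pi_ns are only weakly identified from "
                "binary masked responses (posterior has a ridge); interpret with care",
                IdentifiabilityWarning,
                stacklevel=2,
            )
        for name in ("pi_ns_prior", "pi_s_prior"):
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                raise ValueError(f"{name} hyperparameters must be > 0, got ({a}, {b})")


@dataclass(frozen=True)
class McmcConfig:
    n_burnin: int = 50_000
    n_samples: int = 25_000
    n_chains: int = 2
    seed: int = 0
    thin: int = 1

    def __post_init__(self) -> None:
        for name in ("n_burnin", "n_samples", "n_chains", "thin"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class PosteriorSummary:
    mean: float
    median: float
    cri_low: float
    cri_high: float
    rhat: float  # nan when a single chain makes it unavailable
    ess: float

    def format_percent(self) -> str:
        """Render as e.g. ``'21% [95% CI 7-34]'`` (whole-percent rounding)."""
        return (
            f"{round(self.mean * 100):.0f}% "
            f"[95% CI {round(self.cri_low * 100):.0f}–{round(self.cri_high * 100):.0f}]"
        )


@dataclass(frozen=True)
class MomEstimate:
    estimate: float
    raw: float
    clipped: bool


def mom_estimate(p_obs: float, p_s: float, pi_ns: float) -> MomEstimate:
    """Method-of-moments inversion of the mixture identity.

    Returns the estimate clipped to [0, 1]; ``clipped`` flags when the raw
    inversion fell outside, which is expected at small n.
    """
    if p_s == 0:
        raise ValueError("p_s = 0: the sensitive question is never asked")
    if not 0.0 <= p_obs <= 1.0:
        raise ValueError(f"p_obs must be in [0, 1], got {p_obs}")
    raw = (p_obs - (1.0 - p_s) * pi_ns) / p_s
    est = min(1.0, max(0.0, raw))
    return MomEstimate(estimate=est, raw=raw, clipped=(est != raw))


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------


@dataclass
class CellPosterior:
    """Posterior draws for one cell: arrays of shape (n_chains, n_samples)."""

    cell: tuple
    n: int
    pi_s: np.ndarray
    pi_ns: np.ndarray | None
    summary: PosteriorSummary = field(init=False)

    def __post_init__(self) -> None:
        self.summary = summarize_posterior(self.pi_s)


def _gibbs_chain(
    n1: int,
    n0: int,
    spec: MixtureModelSpec,
    n_iter: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray | None]:
    """One chain of the data-augmentation Gibbs cycle.

    The data reduce to counts (n1 yes, n0 no).  Each iteration draws, for
    the yes and no groups, how many latent assignments point at the
    sensitive question (a Binomial), then updates pi_s (and pi_ns in
    beta_prior mode) from its conjugate Beta full conditional.
    """
    a_s, b_s = spec.pi_s_prior
    known = spec.pi_ns_mode == "known"
    a_n, b_n = spec.pi_ns_prior
    p_s = spec.p_s

    pi_s = rng.beta(a_s, b_s)
    pi_ns = spec.pi_ns_value if known else rng.beta(a_n, b_n)

    out_s = np.empty(n_iter)
    out_n = None if known else np.empty(n_iter)
    for t in range(n_iter):
        num1 = p_s * pi_s
        den1 = num1 + (1.0 - p_s) * pi_ns
        w1 = num1 / den1 if den1 > 0 else 1.0
        num0 = p_s * (1.0 - pi_s)
        den0 = num0 + (1.0 - p_s) * (1.0 - pi_ns)
        w0 = num0 / den0 if den0 > 0 else 1.0
        s1 = rng.binomial(n1, w1) if n1 else 0  # sensitive-assigned among yes
        s0 = rng.binomial(n0, w0) if n0 else 0  # sensitive-assigned among no
        pi_s = rng.beta(a_s + s1, b_s + s0)
        if not known:
            pi_ns = rng.beta(a_n + (n1 - s1), b_n + (n0 - s0))
            out_n[t] = pi_ns
        out_s[t] = pi_s
    return out_s, out_n


def fit_cell_gibbs(
    y: np.ndarray, spec: MixtureModelSpec, mcmc: McmcConfig, cell: tuple = ()
) -> CellPosterior:
    """Fit the mixture posterior for a single cell of binary responses."""
    y = np.asarray(y, dtype=int)
    if y.size == 0:
        raise ValueError("empty cell")
    n1 = int(y.sum())
    n0 = int(y.size - n1)
    n_iter = mcmc.n_burnin + mcmc.n_samples * mcmc.thin
    keep = slice(mcmc.n_burnin, n_iter, mcmc.thin)
    chains_s, chains_n = [], []
    for c in range(mcmc.n_chains):
        rng = np.random.default_rng(derive_seed(mcmc.seed, "gibbs", *cell, c))
        draws_s, draws_n = _gibbs_chain(n1, n0, spec, n_iter, rng)
        chains_s.append(draws_s[keep])
        if draws_n is not None:
            chains_n.append(draws_n[keep])
    pi_s = np.stack(chains_s)
    pi_ns = np.stack(chains_n) if chains_n else None
    post = CellPosterior(cell=cell, n=int(y.size), pi_s=pi_s, pi_ns=pi_ns)
    if np.isfinite(post.summary.rhat) and post.summary.rhat > RHAT_THRESHOLD:
        warnings.warn(
            f"cell {cell}: rhat {post.summary.rhat:.3f} exceeds {RHAT_THRESHOLD}",
            ConvergenceWarning,
            stacklevel=2,
        )
    return post


def fit_prevalence_gibbs(
    responses: pd.DataFrame,
    spec: MixtureModelSpec,
    mcmc: McmcConfig,
    pi_ns_by_domain: dict[str, float] | None = None,
) -> dict[tuple, CellPosterior]:
    """Fit every (municipality, urbanization, item_domain, season) cell.

    ``pi_ns_by_domain`` optionally overrides the known unrelated-item
    prevalence per item domain.  Empty cells are skipped with a logged
    warning.  Per-cell seeds are derived from ``mcmc.seed`` and the cell key.
    """
    results: dict[tuple, CellPosterior] = {}
    for cell, group in responses.groupby(CELL_KEYS, sort=True, observed=True):
        y = group["use"].to_numpy()
        if y.size == 0:  # pragma: no cover - groupby never yields empty groups
            logger.warning("cell %s: empty, skipped", cell)
            continue
        cell_spec = spec
        if pi_ns_by_domain is not None and spec.pi_ns_mode == "known":
            domain = cell[CELL_KEYS.index("item_domain")]
            cell_spec = MixtureModelSpec(
                p_s=spec.p_s,
                pi_ns_mode="known",
                pi_ns_value=float(pi_ns_by_domain[domain]),
                pi_ns_prior=spec.pi_ns_prior,
                pi_s_prior=spec.pi_s_prior,
            )
        results[cell] = fit_cell_gibbs(y, cell_spec, mcmc, cell=cell)
    return results


# ---------------------------------------------------------------------------
# Grid-posterior oracle
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridPosterior:
    """Normalized posterior over pi_s on a uniform midpoint grid."""

    grid: np.ndarray
    mass: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.sum(self.grid * self.mass))

    def quantile(self, q: float) -> float:
        cdf = np.cumsum(self.mass)
        return float(self.grid[int(np.searchsorted(cdf, q))])

    def interval(self, level: float = 0.95) -> tuple[float, float]:
        alpha = (1.0 - level) / 2.0
        return self.quantile(alpha), self.quantile(1.0 - alpha)


def grid_posterior_oracle(
    y: np.ndarray, spec: MixtureModelSpec, grid_size: int = 2000
) -> GridPosterior:
    """Exact marginal posterior of pi_s evaluated on a uniform grid.

    In ``known`` mode this is a 1-D evaluation; in ``beta_prior`` mode the
    joint (pi_s, pi_ns) posterior is evaluated on a 2-D grid and pi_ns is
    marginalized out.  Independent of the Gibbs code path by construction.
    """
    if grid_size < 50:
        raise ValueError(f"grid_size must be >= 50, got {grid_size}")
    y = np.asarray(y, dtype=int)
    n1 = int(y.sum())
    n0 = int(y.size - n1)
    a_s, b_s = spec.pi_s_prior
    g = np.linspace(0.5 / grid_size, 1.0 - 0.5 / grid_size, grid_size)

    if spec.pi_ns_mode == "known":
        q1 = spec.p_s * g + (1.0 - spec.p_s) * spec.pi_ns_value
        with np.errstate(divide="ignore"):
            logpost = (
                n1 * np.log(q1)
                + n0 * np.log1p(-q1)
                + stats.beta.logpdf(g, a_s, b_s)
            )
    else:
        a_n, b_n = spec.pi_ns_prior
        q1 = spec.p_s * g[:, None] + (1.0 - spec.p_s) * g[None, :]
        with np.errstate(divide="ignore"):
            logjoint = (
                n1 * np.log(q1)
                + n0 * np.log1p(-q1)
                + stats.beta.logpdf(g, a_s, b_s)[:, None]
                + stats.beta.logpdf(g, a_n, b_n)[None, :]
            )
        m = logjoint.max()
        logpost = m + np.log(np.exp(logjoint - m).sum(axis=1))

    logpost -= logpost.max()
    mass = np.exp(logpost)
    mass /= mass.sum()
    return GridPosterior(grid=g, mass=mass)


# ---------------------------------------------------------------------------
# Summaries and contrasts
# ---------------------------------------------------------------------------


def _as_chain_draw(draws: np.ndarray) -> np.ndarray:
    draws = np.asarray(draws, dtype=float)
    if draws.ndim == 1:
        draws = draws[None, :]
    if draws.ndim != 2:
        raise ValueError("draws must be 1-D or (n_chains, n_draws)")
    if not np.all(np.isfinite(draws)):
        raise ValueError("draws must be finite")
    return draws


def summarize_posterior(draws: np.ndarray) -> PosteriorSummary:
    """Equal-tailed 95% summary with rank-normalized split-chain rhat.

    With a single chain rhat and a multi-chain ess are not defined; rhat is
    reported as nan.
    """
    draws = _as_chain_draw(draws)
    flat = draws.ravel()
    lo, hi = np.percentile(flat, [2.5, 97.5])
    if draws.shape[0] >= 2:
        rhat = float(az.rhat(az.convert_to_dataset(draws))["x"].values)
        ess = float(az.ess(az.convert_to_dataset(draws))["x"].values)
    else:
        rhat = float("nan")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ess = float(az.ess(az.convert_to_dataset(draws))["x"].values)
    return PosteriorSummary(
        mean=float(flat.mean()),
        median=float(np.median(flat)),
        cri_low=float(lo),
        cri_high=float(hi),
        rhat=rhat,
        ess=ess,
    )


@dataclass(frozen=True)
class ContrastSummary:
    difference: PosteriorSummary
    p_a_gt_b: float
    differs: bool


def contrast_strata(
    draws_a: np.ndarray, draws_b: np.ndarray, *, paired: bool = True
) -> ContrastSummary:
    """Posterior contrast of two cells: summary of A - B and P(A > B).

    ``paired=True`` pairs draws by iteration (same length required);
    otherwise both sets are treated as independent and compared via the
    cross-product estimator on flattened draws.
    """
    a = _as_chain_draw(draws_a)
    b = _as_chain_draw(draws_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty draws")
    if paired:
        if a.shape != b.shape:
            raise ValueError(f"paired contrast requires equal shapes, got {a.shape} vs {b.shape}")
        diff = a - b
        p_gt = float((a > b).mean())
    else:
        fa, fb = a.ravel(), b.ravel()
        m = min(fa.size, fb.size)
        diff = (fa[:m] - fb[:m])[None, :]
        # exact cross-product P(A > B) without the n_a x n_b matrix
        fb_sorted = np.sort(fb)
        p_gt = float(np.searchsorted(fb_sorted, fa, side="left").sum() / (fa.size * fb.size))
    summary = summarize_posterior(diff)
    differs = summary.cri_low > 0.0 or summary.cri_high < 0.0
    return ContrastSummary(difference=summary, p_a_gt_b=p_gt, differs=differs)
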