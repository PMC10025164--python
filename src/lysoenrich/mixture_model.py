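"""Two-component Gaussian mixture modelling of pooled SILAC log2 ratios.

Each cell line's pooled log2 SPIONs/control distribution is treated as a
mixture of a background component (unspecific bead binders, centred near 0)
and a right-shifted enriched component (lysosomal proteins). Parameters
(lambda, mu1, sigma1, mu2, sigma2) are estimated by expectation-maximization
and each protein receives the posterior probability

    P(x) = phi(x; mu2, sigma2) / (phi(x; mu1, sigma1) + phi(x; mu2, sigma2))

where phi is the normal density and the components are labelled so that
mu2 >= mu1. The default posterior deliberately omits the mixing weights; a
lambda-weighted variant is available via ``weighted=True``. Enrichment is
called by Benjamini-Hochberg adjusting p = 1 - P(x) (or, optionally, the
upper-tail probability under the background component) at a significance
level alpha. Sentinel-coded one-channel detections never enter the fit or
the multiple-testing input: their posteriors are forced to exactly 1
(SPIONs-only) or 0 (control-only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError
from .ratio_pipeline import HIGH, LOW, NONE

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)

#: p-value definitions accepted by :func:`score_dataset`
P_COMPLEMENT = "one_minus_posterior"
P_BACKGROUND_TAIL = "background_tail"


@dataclass(frozen=True)
class EMConfig:
    """EM settings; defaults expand the published scalar starting values
    (mu = 0.5, sigma = 1.1) to two components."""

    init_mu: tuple[float, float] = (0.0, 0.5)
    init_sigma: tuple[float, float] = (1.1, 1.1)
    init_lambda: tuple[float, float] = (0.5, 0.5)
    max_iter: int = 1000
    tol: float = 1e-8
    sigma_floor: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.init_lambda) - 1.0) > 1e-12:
            raise ValueError("init_lambda must sum to 1")
        if min(self.init_sigma) <= 0:
            raise ValueError("init_sigma must be positive")


@dataclass
class MixtureFit:
    """Estimated two-component mixture for one cell line.

    Component 1 is the background (smaller mean), component 2 the enriched
    population. ``loglik_trace`` holds the log-likelihood after every
    iteration; EM guarantees it is nondecreasing up to numerical slack.
    """

    lambda1: float
    lambda2: float
    mu1: float
    sigma1: float
    mu2: float
    sigma2: float
    loglik: float
    n_iter: int
    converged: bool
    loglik_trace: list[float] = field(default_factory=list, repr=False)


def normal_density(x, mu: float, sigma: float):
    """Normal probability density; scalar in, scalar out (arrays broadcast)."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    x = np.asarray(x, dtype=float)
    z = (x - mu) / sigma
    out = np.exp(-0.5 * z * z) / (sigma * math.sqrt(2.0 * math.pi))
    return out if out.ndim else float(out)


def _log_normal_density(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    z = (x - mu) / sigma
    return -0.5 * z * z - math.log(sigma) - _LOG_SQRT_2PI


def em_fit(values, config: EMConfig | None = None) -> MixtureFit:
    """Fit a two-component univariate normal mixture by EM.

    Requires at least 10 finite values with nonzero variance. Standard
    alternation of responsibilities (E) and weighted moment updates (M)
    until the absolute log-likelihood change drops below ``config.tol`` or
    ``config.max_iter`` is reached. Standard deviations are clamped at
    ``config.sigma_floor``; a clamp active at exit marks the fit
    non-converged. Components are relabelled so mu2 >= mu1 (ties broken by
    the larger sigma as the enriched component).
    """
    config = config or EMConfig()
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise DegenerateInputError(
            f"need >= 10 finite values for the mixture fit, got {x.size}"
        )
    if np.ptp(x) == 0.0:
        raise DegenerateInputError("all values identical; mixture fit undefined")

    lam = np.array(config.init_lambda, dtype=float)
    mu = np.array(config.init_mu, dtype=float)
    sigma = np.array(config.init_sigma, dtype=float)

    loglik_trace: list[float] = []
    ll_old = -np.inf
    converged = False
    clamped = np.zeros(2, dtype=bool)
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        # E-step: lambda-weighted log densities -> responsibilities
        logd = np.stack(
            [np.log(lam[j]) + _log_normal_density(x, mu[j], sigma[j])
             for j in range(2)]
        )
        norm = logsumexp(logd, axis=0)
        ll = float(norm.sum())
        loglik_trace.append(ll)
        resp = np.exp(logd - norm)

        # M-step: weighted moments
        weights = resp.sum(axis=1)
        lam = weights / x.size
        mu = (resp @ x) / weights
        var = np.array(
            [(resp[j] @ (x - mu[j]) ** 2) / weights[j] for j in range(2)]
        )
        sigma = np.sqrt(var)
        clamped = sigma < config.sigma_floor
        sigma = np.maximum(sigma, config.sigma_floor)

        if abs(ll - ll_old) < config.tol:
            converged = True
            break
        ll_old = ll

    order = np.lexsort((sigma, mu))  # ascending mean; smaller sigma first on ties
    lam, mu, sigma, clamped = lam[order], mu[order], sigma[order], clamped[order]
    return MixtureFit(
        lambda1=float(lam[0]),
        lambda2=float(lam[1]),
        mu1=float(mu[0]),
        sigma1=float(sigma[0]),
        mu2=float(mu[1]),
        sigma2=float(sigma[1]),
        loglik=loglik_trace[-1],
        n_iter=n_iter,
        converged=bool(converged and not clamped.any()),
        loglik_trace=loglik_trace,
    )


def posterior_probability(x, fit: MixtureFit, weighted: bool = False):
    """Posterior probability that x belongs to the enriched component.

    With ``weighted=False`` (default) this is the published density ratio
    phi2/(phi1+phi2), ignoring mixing weights; ``weighted=True`` gives the
    usual lambda-weighted responsibility. Computed in log space, so it is
    well-behaved far into the tails.
    """
    arr = np.asarray(x, dtype=float)
    log1 = _log_normal_density(arr, fit.mu1, fit.sigma1)
    log2 = _log_normal_density(arr, fit.mu2, fit.sigma2)
    if weighted:
        log1 = log1 + math.log(fit.lambda1)
        log2 = log2 + math.log(fit.lambda2)
    # phi2/(phi1+phi2) = 1/(1+exp(log1-log2)), via expit for stability
    from scipy.special import expit

    post = expit(log2 - log1)
    return post if post.ndim else float(post)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in the input order.

    q(i) = min over j >= i (in sorted order) of m*p(j)/j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or p.min() < 0.0 or p.max() > 1.0:
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def score_dataset(
    pooled_line: pd.DataFrame,
    config: EMConfig | None = None,
    alpha: float = 0.05,
    weighted: bool = False,
    p_mode: str = P_COMPLEMENT,
    strict_cutoff: bool = False,
) -> tuple[MixtureFit, pd.DataFrame]:
    """Fit one cell line's mixture and call enrichment per protein.

    ``pooled_line`` is a single cell line's pooled table (columns
    protein_id, x_log2, extreme) after extreme substitution. The EM fit and
    the BH adjustment use only non-extreme proteins; extreme HIGH proteins
    get posterior 1 / p 0 / q 0 / enriched, extreme LOW the reverse.
    Enrichment is called at q <= alpha (q < alpha with
    ``strict_cutoff=True``).
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if p_mode not in (P_COMPLEMENT, P_BACKGROUND_TAIL):
        raise ValueError(f"unknown p_mode {p_mode!r}")

    table = pooled_line.reset_index(drop=True).copy()
    finite_mask = (table["extreme"] == NONE).to_numpy()
    x_fit = table.loc[finite_mask, "x_log2"].to_numpy(dtype=float)
    fit = em_fit(x_fit, config)

    posterior = np.empty(len(table))
    p_value = np.empty(len(table))
    q_value = np.empty(len(table))

    post_fin = np.asarray(posterior_probability(x_fit, fit, weighted=weighted))
    if p_mode == P_COMPLEMENT:
        p_fin = 1.0 - post_fin
    else:
        from scipy.stats import norm as _norm

        p_fin = _norm.sf(x_fit, loc=fit.mu1, scale=fit.sigma1)
    q_fin = bh_adjust(p_fin)

    posterior[finite_mask] = post_fin
    p_value[finite_mask] = p_fin
    q_value[finite_mask] = q_fin

    is_high = (table["extreme"] == HIGH).to_numpy()
    is_low = (table["extreme"] == LOW).to_numpy()
    posterior[is_high], p_value[is_high], q_value[is_high] = 1.0, 0.0, 0.0
    posterior[is_low], p_value[is_low], q_value[is_low] = 0.0, 1.0, 1.0

    enriched = q_value < alpha if strict_cutoff else q_value <= alpha
    # forced calls override the cutoff (relevant only at degenerate alpha)
    enriched[is_high] = True
    enriched[is_low] = False

    out = table[["protein_id", "x_log2", "extreme"]].copy()
    out["posterior"] = posterior
    out["p_value"] = p_value
    out["q_value"] = q_value
    out["enriched"] = enriched
    if "cell_line" in table.columns:
        out.insert(0, "cell_line", table["cell_line"])
    return fit, out


def score_all_lines(
    pooled,
    config: EMConfig | None = None,
    alpha: float = 0.05,
    weighted: bool = False,
    p_mode: str = P_COMPLEMENT,
    strict_cutoff: bool = False,
) -> tuple[dict[str, MixtureFit], pd.DataFrame]:
    """Apply :func:`score_dataset` to every cell line of a PooledRatios.

    Returns per-line fits and one concatenated enrichment table.
    """
    fits: dict[str, MixtureFit] = {}
    parts: list[pd.DataFrame] = []
    for line in sorted(pooled.table["cell_line"].unique()):
        fit, scored = score_dataset(
            pooled.for_line(line),
            config=config,
            alpha=alpha,
            weighted=weighted,
            p_mode=p_mode,
            strict_cutoff=strict_cutoff,
        )
        fits[line] = fit
        parts.append(scored)
    combined = pd.concat(parts, ignore_index=True)
    return fits, combined


def fits_to_frame(fits: dict[str, MixtureFit]) -> pd.DataFrame:
    """Tabular view of per-line mixture fits (for mixture_fits.tsv)."""
    rows = [
        {
            "cell_line": line,
            "lambda1": f.lambda1,
            "lambda2": f.lambda2,
            "mu1": f.mu1,
            "sigma1": f.sigma1,
            "mu2": f.mu2,
            "sigma2": f.sigma2,
            "loglik": f.loglik,
            "n_iter": f.n_iter,
            "converged": f.converged,
        }
        for line, f in sorted(fits.items())
    ]
    return pd.DataFrame(rows)
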