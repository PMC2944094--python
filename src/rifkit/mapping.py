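"""Disease mapping: raw SIR fields, shrinkage smoothing, exceedance maps.

Two smoothers for the per-area relative risk RR_i, both for counts
O_i ~ Poisson(E_i RR_i):

Empirical Bayes (Poisson-gamma)
    RR_i ~ Gamma(alpha, nu) a priori; (alpha, nu) are estimated by
    maximizing the negative-binomial marginal likelihood of the observed
    counts, and the posterior mean (O_i + alpha) / (E_i + nu) shrinks each
    raw SIR toward the global mean alpha/nu.  Shrinkage is strongest where
    E_i is small — exactly the sparse areas whose raw SIRs are noisiest.

Full Bayes (Besag-York-Mollie)
    log RR_i = mu + u_i + v_i with a spatially structured intrinsic CAR
    (ICAR) effect u and an unstructured iid normal effect v, so risk is
    smoothed toward the *local* (neighbourhood) mean rather than the global
    one.  Fitted by a seeded Metropolis-within-Gibbs sampler: random-walk
    Metropolis for mu, u and v (u updated in graph-colour blocks so that
    simultaneous single-site updates remain exact), conjugate Gibbs draws
    for the precisions tau_u, tau_v, and per-component sum-to-zero
    recentring of u each sweep.

Posterior exceedance probabilities Pr[RR_i > 1 | data] classify areas as
"elevated" (posterior mean RR > 1 and exceedance > 0.8), "lowered"
(RR < 1 and exceedance < 0.2) or "uncertain".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, special

from .geo import AdjacencyGraph

__all__ = [
    "GammaHyperparams",
    "EBResult",
    "BYMResult",
    "eb_poisson_gamma",
    "bym_fit",
    "exceedance",
    "classify",
    "smoothed_risk_field",
]


# ---------------------------------------------------------------------------
# Empirical Bayes: Poisson-gamma
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GammaHyperparams:
    """Gamma prior on relative risk: shape alpha, rate nu.

    Prior mean alpha/nu, prior variance alpha/nu^2.
    """

    alpha: float
    nu: float

    def __post_init__(self):
        if self.alpha <= 0 or self.nu <= 0:
            raise ValueError("gamma hyperparameters must be strictly positive")

    @property
    def mean(self) -> float:
        return self.alpha / self.nu

    @property
    def variance(self) -> float:
        return self.alpha / self.nu**2


@dataclass
class EBResult:
    prior: GammaHyperparams
    eb_rr: np.ndarray
    converged: bool
    log_marginal: float


def _nb_negloglik(log_params, o, e):
    a, nu = np.exp(log_params)
    # marginal: O_i ~ NB(shape a, success prob nu/(nu+E_i))
    ll = (
        special.gammaln(o + a)
        - special.gammaln(a)
        - special.gammaln(o + 1)
        + a * (np.log(nu) - np.log(nu + e))
        + o * (np.log(e) - np.log(nu + e))
    )
    return -float(ll.sum())


def _moment_estimates(o, e):
    m = o.sum() / e.sum()
    smr = o / e
    w = e / e.sum()
    s2 = float(np.sum(w * (smr - m) ** 2))
    prior_var = max(s2 - m / e.mean(), 1e-4)
    return m, prior_var


def eb_poisson_gamma(observed, expected) -> EBResult:
    """Fit the Poisson-gamma model and shrink SIRs toward the global mean.

    The gamma prior (alpha, nu) maximizes the negative-binomial marginal
    likelihood prod_i NB(O_i; alpha, nu/(nu+E_i)), optimized over
    (log alpha, log nu) by L-BFGS-B from moment-based starting values.
    Each area's EB estimate is the conjugate posterior mean
    ``(O_i + alpha) / (E_i + nu)``, which lies strictly between the raw SIR
    and the prior mean and approaches the raw SIR as E_i grows.

    Areas with E_i = 0 must be removed first (see
    :func:`smoothed_risk_field`); at least 3 areas are required.
    """
    o = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    if len(o) != len(e):
        raise ValueError("observed and expected differ in length")
    if len(o) < 3:
        raise ValueError("need at least 3 areas to estimate the prior")
    if np.any(e <= 0):
        raise ValueError("all expected counts must be positive (drop E=0 areas first)")
    if o.sum() == 0:
        raise ValueError("all observed counts are zero; prior is unidentifiable")

    m, prior_var = _moment_estimates(o, e)
    x0 = np.log([m**2 / prior_var, m / prior_var])
    res = optimize.minimize(
        _nb_negloglik, x0, args=(o, e), method="L-BFGS-B",
        bounds=[(-12, 12), (-12, 12)], options={"ftol": 1e-8, "gtol": 1e-8},
    )
    if res.success:
        alpha, nu = np.exp(res.x)
        converged = True
        logm = -res.fun
    else:
        warnings.warn(
            f"EB optimizer did not converge ({res.message}); "
            "falling back to moment estimates", stacklevel=2,
        )
        alpha, nu = np.exp(x0)
        converged = False
        logm = -_nb_negloglik(x0, o, e)
    prior = GammaHyperparams(float(alpha), float(nu))
    eb_rr = (o + prior.alpha) / (e + prior.nu)
    return EBResult(prior=prior, eb_rr=eb_rr, converged=converged, log_marginal=logm)


# ---------------------------------------------------------------------------
# Full Bayes: BYM via Metropolis-within-Gibbs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GammaPrior:
    shape: float
    rate: float

    def __post_init__(self):
        if self.shape <= 0 or self.rate <= 0:
            raise ValueError("gamma prior parameters must be strictly positive")


#: WinBUGS-convention vague hyperprior for random-effect precisions.
DEFAULT_PRECISION_PRIOR = GammaPrior(shape=0.5, rate=0.0005)


@dataclass
class BYMResult:
    """Retained posterior samples and summaries from the BYM sampler."""

    area_ids: list[str]
    rr_samples: np.ndarray        # (n_kept, n_areas)
    posterior_mean_rr: np.ndarray
    mcse: np.ndarray              # naive Monte-Carlo SE of the posterior mean
    mu_samples: np.ndarray
    tau_u_samples: np.ndarray
    tau_v_samples: np.ndarray
    acceptance: dict[str, float]
    seed: int
    n_iter: int
    n_burn: int
    thin: int

    def exceedance(self, threshold: float = 1.0) -> np.ndarray:
        return exceedance(self.rr_samples, threshold)


def _colour_classes(graph: nx.Graph, nodes: list) -> list[np.ndarray]:
    """Independent sets covering the graph: within a class no two nodes are
    adjacent, so their full conditionals are mutually independent and can be
    Metropolis-updated simultaneously without breaking detailed balance."""
    colouring = nx.greedy_color(graph, strategy="largest_first")
    index = {a: i for i, a in enumerate(nodes)}
    classes: dict[int, list[int]] = {}
    for node, colour in colouring.items():
        classes.setdefault(colour, []).append(index[node])
    return [np.array(sorted(ix), dtype=int) for _, ix in sorted(classes.items())]


def bym_fit(observed, expected, adjacency: AdjacencyGraph, *, seed: int,
            area_ids: list[str] | None = None,
            tau_u_prior: GammaPrior = DEFAULT_PRECISION_PRIOR,
            tau_v_prior: GammaPrior = DEFAULT_PRECISION_PRIOR,
            n_iter: int = 11_000, n_burn: int = 1_000, thin: int = 5) -> BYMResult:
    """Fit the BYM model O_i ~ Poisson(E_i exp(mu + u_i + v_i)) by MCMC.

    Parameters
    ----------
    observed, expected
        Per-area counts and expected counts, ordered as ``adjacency`` (or
        as ``area_ids`` if given).  All E_i must be positive.
    adjacency
        Neighbourhood graph for the ICAR effect.  Disconnected graphs are
        handled by per-component sum-to-zero recentring; isolated areas get
        u_i fixed at 0 (their risk is then smoothed only through v).
    seed
        Mandatory RNG seed; identical seeds give bitwise-identical chains.
    n_iter, n_burn, thin
        Total sweeps, burn-in sweeps discarded, and thinning of the rest.
        Random-walk scales adapt toward 30-50% acceptance during burn-in
        only, so the retained chain is a fixed Markov kernel.
    """
    o = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    if np.any(e <= 0):
        raise ValueError("all expected counts must be positive (drop E=0 areas first)")

    def poisson_loglik(eta: np.ndarray) -> np.ndarray:
        return o * eta - e * np.exp(eta)

    init_mu = float(np.log(max(o.sum() / e.sum(), 1e-8)))
    return _sample_chain(
        poisson_loglik, adjacency, seed=seed, area_ids=area_ids,
        tau_u_prior=tau_u_prior, tau_v_prior=tau_v_prior,
        n_iter=n_iter, n_burn=n_burn, thin=thin, init_mu=init_mu,
    )


def _sample_chain(loglik, adjacency: AdjacencyGraph, *, seed: int,
                  area_ids=None, tau_u_prior=DEFAULT_PRECISION_PRIOR,
                  tau_v_prior=DEFAULT_PRECISION_PRIOR,
                  n_iter=11_000, n_burn=1_000, thin=5, init_mu=0.0,
                  fix_mu: float | None = None,
                  fix_tau_u: float | None = None,
                  fix_tau_v: float | None = None) -> BYMResult:
    """Metropolis-within-Gibbs over (mu, u, v, tau_u, tau_v).

    ``loglik(eta)`` returns the per-area log-likelihood at linear predictor
    eta_i = mu + u_i + v_i; :func:`bym_fit` supplies the Poisson terms.
    Exposing the likelihood (and the ``fix_*`` arguments) lets validation
    harnesses run the identical kernel against conjugate closed forms.
    """
    if n_iter <= n_burn:
        raise ValueError("n_iter must exceed n_burn")
    if seed is None:
        raise ValueError("seed is mandatory")

    nodes = area_ids if area_ids is not None else adjacency.area_ids
    n = len(nodes)
    index = {a: i for i, a in enumerate(nodes)}
    graph = adjacency.to_networkx()
    if set(graph.nodes) != set(nodes):
        raise ValueError("adjacency areas do not match area_ids")

    from scipy import sparse

    rows, cols = [], []
    for a in nodes:
        for b in adjacency.neighbours[a]:
            rows.append(index[a])
            cols.append(index[b])
    adj = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    degree = np.asarray(adj.sum(axis=1)).ravel()
    isolated = degree == 0
    if isolated.any():
        warnings.warn(
            f"{int(isolated.sum())} isolated area(s): structured effect fixed at 0",
            stacklevel=2,
        )
    components = [np.array(sorted(index[a] for a in comp), dtype=int)
                  for comp in nx.connected_components(graph)]
    big_components = [c for c in components if len(c) > 1]
    # rank of the ICAR precision = (non-isolated nodes) - (their components)
    icar_rank = sum(len(c) - 1 for c in big_components)
    colour_sets = _colour_classes(graph, nodes)

    rng = np.random.default_rng(seed)
    mu = init_mu if fix_mu is None else fix_mu
    u = np.zeros(n)
    v = np.zeros(n)
    tau_u = 1.0 if fix_tau_u is None else fix_tau_u
    tau_v = 1.0 if fix_tau_v is None else fix_tau_v

    s_mu = 0.1
    s_u = np.full(n, 0.1)
    s_v = np.full(n, 0.1)
    acc = {"mu": 0, "u": np.zeros(n), "v": np.zeros(n)}
    tries = {"mu": 0, "u": np.zeros(n), "v": np.zeros(n)}
    window = {"mu": [0, 0], "u": np.zeros((n, 2)), "v": np.zeros((n, 2))}
    ADAPT_EVERY, TARGET = 50, 0.4

    ll = loglik(mu + u + v)

    kept_rr, kept_mu, kept_tu, kept_tv = [], [], [], []

    for sweep in range(n_iter):
        adapting = sweep < n_burn

        # --- mu: scalar random walk (flat prior) -------------------------
        if fix_mu is None:
            prop = mu + s_mu * rng.standard_normal()
            ll_prop = loglik(prop + u + v)
            if np.log(rng.random()) < ll_prop.sum() - ll.sum():
                mu, ll = prop, ll_prop
                acc["mu"] += 1
                window["mu"][0] += 1
            tries["mu"] += 1
            window["mu"][1] += 1

        # --- u: per-colour-class vectorized single-site Metropolis -------
        for cls in colour_sets:
            cls = cls[~isolated[cls]]
            if len(cls) == 0:
                continue
            nbr_sum = (adj @ u)[cls]
            d = degree[cls]
            u_new = u[cls] + s_u[cls] * rng.standard_normal(len(cls))
            eta_old = mu + u[cls] + v[cls]
            eta_new = mu + u_new + v[cls]
            ll_new = loglik_at(loglik, eta_new, cls, n)
            ll_old = ll[cls]
            # ICAR full conditional: u_i | u_-i ~ N(nbr mean, 1/(tau_u d_i))
            lp = -0.5 * tau_u * d * ((u_new - nbr_sum / d) ** 2
                                     - (u[cls] - nbr_sum / d) ** 2)
            accept = np.log(rng.random(len(cls))) < ll_new - ll_old + lp
            take = cls[accept]
            u[take] = u_new[accept]
            ll[take] = ll_new[accept]
            acc["u"][take] += 1
            tries["u"][cls] += 1
            window["u"][take, 0] += 1
            window["u"][cls, 1] += 1

        # --- v: all areas at once (conditionally independent) ------------
        v_new = v + s_v * rng.standard_normal(n)
        ll_new = loglik(mu + u + v_new)
        lp = -0.5 * tau_v * (v_new**2 - v**2)
        accept = np.log(rng.random(n)) < ll_new - ll + lp
        v[accept] = v_new[accept]
        ll[accept] = ll_new[accept]
        acc["v"][accept] += 1
        tries["v"] += 1
        window["v"][accept, 0] += 1
        window["v"][:, 1] += 1

        # --- recentre u per connected component (sum-to-zero) -------------
        for comp in big_components:
            shift = u[comp].mean()
            if shift != 0.0:
                u[comp] -= shift
        ll = loglik(mu + u + v)

        # --- precisions: conjugate Gibbs ----------------------------------
        if fix_tau_u is None and icar_rank > 0:
            # sum over edges (u_i - u_j)^2 = u' (D - A) u
            quad = float(u @ (degree * u) - u @ (adj @ u))
            tau_u = rng.gamma(tau_u_prior.shape + 0.5 * icar_rank,
                              1.0 / (tau_u_prior.rate + 0.5 * quad))
        if fix_tau_v is None:
            tau_v = rng.gamma(tau_v_prior.shape + 0.5 * n,
                              1.0 / (tau_v_prior.rate + 0.5 * np.sum(v**2)))

        # --- scale adaptation during burn-in ------------------------------
        if adapting and (sweep + 1) % ADAPT_EVERY == 0:
            if window["mu"][1] > 0:
                rate = window["mu"][0] / window["mu"][1]
                s_mu *= np.exp(rate - TARGET)
            for key, s in (("u", s_u), ("v", s_v)):
                w = window[key]
                mask = w[:, 1] > 0
                rates = np.where(mask, w[:, 0] / np.maximum(w[:, 1], 1), TARGET)
                s *= np.exp(rates - TARGET)
            window = {"mu": [0, 0], "u": np.zeros((n, 2)), "v": np.zeros((n, 2))}

        if sweep >= n_burn and (sweep - n_burn) % thin == 0:
            kept_rr.append(np.exp(mu + u + v))
            kept_mu.append(mu)
            kept_tu.append(tau_u)
            kept_tv.append(tau_v)

    rr = np.array(kept_rr)
    k = len(rr)
    acceptance = {
        "mu": acc["mu"] / max(tries["mu"], 1),
        "u": float(np.mean(acc["u"][~isolated] / np.maximum(tries["u"][~isolated], 1)))
        if (~isolated).any() else float("nan"),
        "v": float(np.mean(acc["v"] / np.maximum(tries["v"], 1))),
    }
    return BYMResult(
        area_ids=list(nodes), rr_samples=rr,
        posterior_mean_rr=rr.mean(axis=0),
        mcse=rr.std(axis=0, ddof=1) / np.sqrt(k),
        mu_samples=np.array(kept_mu), tau_u_samples=np.array(kept_tu),
        tau_v_samples=np.array(kept_tv), acceptance=acceptance,
        seed=seed, n_iter=n_iter, n_burn=n_burn, thin=thin,
    )


def loglik_at(loglik, eta_subset, idx, n):
    """Evaluate per-area log-likelihood terms for a subset of areas.

    The likelihood factorizes over areas, so terms for the proposal subset
    can be computed by embedding the proposal into a full eta vector; the
    returned values for other areas are ignored.
    """
    full = np.zeros(n)
    full[idx] = eta_subset
    return loglik(full)[idx]


# ---------------------------------------------------------------------------
# Exceedance probabilities and classification
# ---------------------------------------------------------------------------

def exceedance(samples: np.ndarray, threshold: float = 1.0) -> np.ndarray:
    """Per-area posterior probability Pr[RR > threshold | data].

    ``samples`` is (n_samples, n_areas); at least 100 retained samples are
    required for a stable tail estimate.
    """
    s = np.asarray(samples, dtype=float)
    if s.ndim == 1:
        s = s[:, None]
    if s.shape[0] == 0:
        raise ValueError("empty sample set")
    if s.shape[0] < 100:
        raise ValueError(f"need >= 100 retained samples, got {s.shape[0]}")
    return (s > threshold).mean(axis=0)


def classify(rr_mean: float, exceedance_prob: float,
             hi: float = 0.8, lo: float = 0.2) -> str:
    """Classify an area's risk: 'elevated', 'lowered' or 'uncertain'.

    Elevated means posterior mean RR > 1 *and* Pr[RR > 1 | data] > ``hi``
    (we are 80% confident of an excess risk at the default); lowered means
    RR < 1 and exceedance < ``lo``; anything else is uncertain.
    """
    if not 0 <= exceedance_prob <= 1:
        raise ValueError(f"exceedance must be in [0, 1], got {exceedance_prob}")
    if rr_mean > 1 and exceedance_prob > hi:
        return "elevated"
    if rr_mean < 1 and exceedance_prob < lo:
        return "lowered"
    return "uncertain"


# ---------------------------------------------------------------------------
# Combined per-area risk field
# ---------------------------------------------------------------------------

def smoothed_risk_field(observed, expected, adjacency: AdjacencyGraph, *, seed: int,
                        area_ids: list[str] | None = None,
                        hi: float = 0.8, lo: float = 0.2,
                        **bym_kwargs) -> pd.DataFrame:
    """Raw, EB-smoothed and fully Bayesian RR per area, with classification.

    Returns a DataFrame indexed by area_id with columns ``observed,
    expected, raw_rr, eb_rr, fb_mean_rr, exceedance, classification``.
    Areas with E_i = 0 are reported with missing values (their risk is not
    estimable), never as RR 0.
    """
    nodes = area_ids if area_ids is not None else adjacency.area_ids
    o = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    ok = e > 0
    if (~ok).any():
        warnings.warn(
            f"{int((~ok).sum())} area(s) with zero expected count excluded "
            "from smoothing", stacklevel=2,
        )

    sub_nodes = [a for a, keep in zip(nodes, ok) if keep]
    sub_adj = AdjacencyGraph({
        a: [b for b in adjacency.neighbours[a] if b in set(sub_nodes)]
        for a in sub_nodes
    })
    eb = eb_poisson_gamma(o[ok], e[ok])
    fb = bym_fit(o[ok], e[ok], sub_adj, seed=seed, area_ids=sub_nodes, **bym_kwargs)
    exc = fb.exceedance()

    df = pd.DataFrame(index=pd.Index(nodes, name="area_id"),
                      columns=["observed", "expected", "raw_rr", "eb_rr",
                               "fb_mean_rr", "exceedance", "classification"],
                      dtype=object)
    df["observed"] = o
    df["expected"] = e
    df.loc[sub_nodes, "raw_rr"] = o[ok] / e[ok]
    df.loc[sub_nodes, "eb_rr"] = eb.eb_rr
    df.loc[sub_nodes, "fb_mean_rr"] = fb.posterior_mean_rr
    df.loc[sub_nodes, "exceedance"] = exc
    df.loc[sub_nodes, "classification"] = [
        classify(m, p, hi=hi, lo=lo) for m, p in zip(fb.posterior_mean_rr, exc)
    ]
    for col in ["observed", "expected", "raw_rr", "eb_rr", "fb_mean_rr", "exceedance"]:
        df[col] = pd.to_numeric(df[col])
    return df
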