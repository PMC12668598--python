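"""Posterior exploration of causal configurations.

Small regions are enumerated exhaustively; otherwise a shotgun stochastic
search scores the add/delete/swap neighborhood of the current configuration
and moves proportionally to unnormalized posterior mass.  Every distinct
configuration ever scored contributes to the reported posterior summaries
(PIPs, the distribution of the number of causal variants and its
expectation, credible sets), which is the standard behavior of
configuration-space fine-mapping and slightly truncates the true posterior
toward the explored set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from scipy.linalg import solve
from scipy.special import logsumexp

from .bf import DEFAULT_TAU2, CausalConfig, LikelihoodModel, log_bf
from .io import LDMatrix, MetaGWAS, ValidationError
from .overlap import build_meta_covariance, build_overlap_matrix

__all__ = [
    "PriorSpec",
    "PosteriorSummary",
    "CredibleSet",
    "log_prior",
    "enumerate_posterior",
    "shotgun_search",
    "credible_sets",
    "compute_k_distribution",
    "fine_map_meta",
]


@dataclass
class PriorSpec:
    """Prior over causal configurations.

    The default is the truncated binomial ``p(gamma) propto (1/p)^{|gamma|}
    ((p-1)/p)^{p-|gamma|} 1(|gamma| <= kmax)``, i.e. one causal variant
    expected a priori.  ``per_k`` overrides the size-k weight directly.
    """

    kmax: int
    p: int
    kind: str = "truncated_binomial"
    per_k: np.ndarray | None = None

    def __post_init__(self):
        if self.kmax < 1:
            raise ValidationError("kmax must be >= 1")
        if self.kind == "custom_per_k":
            if self.per_k is None:
                raise ValidationError("custom_per_k prior needs per-k weights")
            self.per_k = np.asarray(self.per_k, dtype=float)
            if np.any(self.per_k < 0) or not np.all(np.isfinite(self.per_k)):
                raise ValidationError("per-k weights must be non-negative and finite")
        elif self.kind != "truncated_binomial":
            raise ValidationError(f"unknown prior kind {self.kind!r}")


def log_prior(config, prior: PriorSpec) -> float:
    """Unnormalized log prior of a configuration (``-inf`` beyond kmax)."""
    k = config.k if isinstance(config, CausalConfig) else len(config)
    if k > prior.kmax:
        return -np.inf
    if prior.kind == "custom_per_k":
        w = prior.per_k[k] if k < len(prior.per_k) else 0.0
        if w == 0.0:
            return -np.inf
        # spread the size-k mass evenly over the C(p, k) configurations
        return float(np.log(w) - np.log(comb(prior.p, k)))
    p = prior.p
    if p == 1:  # degenerate single-variant region: all mass on the full config
        return 0.0 if k == 1 else -np.inf
    return k * np.log(1.0 / p) + (p - k) * np.log((p - 1.0) / p)


# ---------------------------------------------------------------------------
# batched Bayes factors
# ---------------------------------------------------------------------------

def _batch_log_bf(model: LikelihoodModel, fixed: tuple, candidates: np.ndarray) -> np.ndarray:
    """log BF of the configurations ``fixed + {l}`` for each candidate l.

    Uses the block (Schur-complement) structure of the inner k x k matrix:
    the block belonging to ``fixed`` is shared, so only scalar updates are
    needed per candidate.  Infeasible candidates score -inf.
    """
    tau2 = model.tau2
    g, v = model.gram, model.v
    c_l = 1.0 + tau2 * g[candidates, candidates]
    v_l = v[candidates]
    if len(fixed) == 0:
        with np.errstate(invalid="ignore", divide="ignore"):
            out = -0.5 * (np.log(c_l) - tau2 * v_l ** 2 / c_l)
        out[c_l <= 0] = -np.inf
        return out
    f = list(fixed)
    a = tau2 * g[np.ix_(f, f)]
    a[np.diag_indices_from(a)] += 1.0
    try:
        a_inv = solve(a, np.eye(len(f)), assume_a="pos")
    except np.linalg.LinAlgError:
        return np.array([log_bf(CausalConfig(fixed + (int(l),)), model) for l in candidates])
    sign, logdet_a = np.linalg.slogdet(a)
    b = tau2 * g[np.ix_(f, candidates)]          # (k-1) x m
    a_inv_b = a_inv @ b
    schur = c_l - np.einsum("ij,ij->j", b, a_inv_b)
    v_f = v[f]
    a_inv_vf = a_inv @ v_f
    base_quad = float(v_f @ a_inv_vf)
    resid = v_l - b.T @ a_inv_vf
    with np.errstate(invalid="ignore", divide="ignore"):
        logdet = logdet_a + np.log(schur)
        quad = base_quad + resid ** 2 / schur
        out = -0.5 * (logdet - tau2 * quad)
    out[schur <= 0] = -np.inf
    return out


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

@dataclass
class CredibleSet:
    """A theta-level credible set for one causal signal.

    ``members`` are ordered by decreasing conditional probability ``b_bar``;
    their probabilities sum to at least theta.
    """

    theta: float
    anchor_variant: int
    members: list[int]
    member_probs: np.ndarray


@dataclass
class PosteriorSummary:
    """Everything the search learned about a region's posterior."""

    configs: dict
    pip: np.ndarray
    penc: float
    k_dist: np.ndarray
    credible_sets: list = field(default_factory=list)
    search_meta: dict = field(default_factory=dict)


def _summarize(scores: dict, prior: PriorSpec, p: int, search_meta: dict) -> PosteriorSummary:
    configs = {}
    log_posts = np.empty(len(scores))
    keys = list(scores.keys())
    for i, cfg in enumerate(keys):
        lp = log_prior(cfg, prior)
        lpost = scores[cfg] + lp
        configs[cfg] = (scores[cfg], lp, lpost)
        log_posts[i] = lpost
    norm = logsumexp(log_posts)
    probs = np.exp(log_posts - norm)
    pip = np.zeros(p)
    k_dist = np.zeros(prior.kmax + 1)
    for cfg, pr in zip(keys, probs):
        k_dist[len(cfg)] += pr
        for j in cfg:
            pip[j] += pr
    penc = float(np.arange(prior.kmax + 1) @ k_dist)
    return PosteriorSummary(configs=configs, pip=pip, penc=penc, k_dist=k_dist,
                            search_meta=search_meta)


def compute_k_distribution(scores: dict, prior: PriorSpec) -> np.ndarray:
    """Posterior over the number of causal variants from a scored set.

    ``scores`` maps configuration tuples to log Bayes factors and must be
    non-empty and include the null configuration (log BF 0).
    """
    if not scores:
        raise ValidationError("cannot normalize over an empty configuration set")
    if () not in scores:
        raise ValidationError("the scored set must include the null configuration")
    log_posts = np.array([lbf + log_prior(cfg, prior) for cfg, lbf in scores.items()])
    ks = np.array([len(cfg) for cfg in scores])
    probs = np.exp(log_posts - logsumexp(log_posts))
    k_dist = np.zeros(prior.kmax + 1)
    np.add.at(k_dist, ks, probs)
    return k_dist


# ---------------------------------------------------------------------------
# exploration
# ---------------------------------------------------------------------------

def enumerate_posterior(model: LikelihoodModel, prior: PriorSpec,
                        kmax: int | None = None, cap: int = 2_000_000) -> PosteriorSummary:
    """Score every configuration up to kmax (exact posterior on that set)."""
    kmax = prior.kmax if kmax is None else kmax
    p = model.p
    total = sum(comb(p, k) for k in range(kmax + 1))
    if total > cap:
        raise ValidationError(
            f"enumeration would score {total} configurations (> cap {cap}); "
            f"use shotgun_search instead")
    scores = {(): 0.0}
    idx = np.arange(p)
    for k in range(1, kmax + 1):
        if k == 1:
            vals = _batch_log_bf(model, (), idx)
            scores.update({(int(j),): float(vals[j]) for j in idx})
        else:
            for head in combinations(range(p), k - 1):
                tail = idx[idx > head[-1]]
                if tail.size == 0:
                    continue
                vals = _batch_log_bf(model, tuple(head), tail)
                for l, val in zip(tail, vals):
                    scores[head + (int(l),)] = float(val)
    return _summarize(scores, prior, p, {"method": "enumeration", "n_evaluated": len(scores)})


def _neighborhood(current: tuple, p: int, kmax: int):
    """Single-variant add, delete and swap moves from ``current``."""
    cur = set(current)
    others = np.array([l for l in range(p) if l not in cur], dtype=int)
    moves = []
    if len(current) < kmax and others.size:
        moves.append((current, others))                       # adds
    for j in current:
        rest = tuple(i for i in current if i != j)
        moves.append((rest, np.array([-1])))                  # delete marker
        if others.size:
            moves.append((rest, others))                      # swaps of j
    return moves


def shotgun_search(model: LikelihoodModel, prior: PriorSpec, iters: int = 50,
                   seed: int = 0, init: tuple = ()) -> PosteriorSummary:
    """Shotgun stochastic search over causal configurations.

    Starting from ``init`` (default: the null configuration), each iteration
    scores the full add/delete/swap neighborhood of the current configuration
    and samples the next one with probability proportional to its
    unnormalized posterior within the neighborhood.  Scores are cached, every
    scored configuration enters the summary, and the walk is deterministic
    given ``seed``.
    """
    rng = np.random.default_rng(seed)
    p = model.p
    scores: dict = {(): 0.0}
    current = tuple(sorted(int(i) for i in init))
    if current:
        scores[current] = log_bf(CausalConfig(current), model)
    for _ in range(iters):
        neigh_cfgs: list[tuple] = []
        for fixed, cands in _neighborhood(current, p, prior.kmax):
            if cands.size == 1 and cands[0] == -1:           # pure delete
                cfg = fixed
                if cfg not in scores:
                    scores[cfg] = log_bf(CausalConfig(cfg), model) if cfg else 0.0
                neigh_cfgs.append(cfg)
                continue
            new_mask = np.array([tuple(sorted(fixed + (int(l),))) not in scores
                                 for l in cands])
            if new_mask.any():
                vals = _batch_log_bf(model, fixed, cands[new_mask])
                for l, val in zip(cands[new_mask], vals):
                    scores[tuple(sorted(fixed + (int(l),)))] = float(val)
            neigh_cfgs.extend(tuple(sorted(fixed + (int(l),))) for l in cands)
        log_posts = np.array([scores[cfg] + log_prior(cfg, prior) for cfg in neigh_cfgs])
        with np.errstate(over="ignore"):
            w = np.exp(log_posts - np.max(log_posts))
        w_sum = w.sum()
        if not np.isfinite(w_sum) or w_sum <= 0:
            break
        current = neigh_cfgs[int(rng.choice(len(neigh_cfgs), p=w / w_sum))]
    return _summarize(scores, prior, p,
                      {"method": "sss", "iters": iters, "seed": seed,
                       "n_evaluated": len(scores)})


# ---------------------------------------------------------------------------
# credible sets
# ---------------------------------------------------------------------------

def credible_sets(model: LikelihoodModel, prior: PriorSpec, posterior: PosteriorSummary,
                  k: int | None = None, theta: float = 0.95) -> list[CredibleSet]:
    """Per-signal credible sets at coverage theta.

    For the top configuration with k causal variants and each anchor j in
    it, every single-variant replacement of j is scored; the normalized
    conditional probabilities ``b_bar`` are accumulated in decreasing order
    until they exceed theta.  ``k`` defaults to the posterior expected
    number of causal variants, rounded and clamped to [1, kmax].
    """
    if not (0.0 < theta < 1.0):
        raise ValidationError("theta must lie in (0, 1)")
    if k is None:
        k = int(np.clip(round(posterior.penc), 1, prior.kmax))
    k_configs = {cfg: v for cfg, v in posterior.configs.items() if len(cfg) == k}
    if not k_configs:
        raise ValidationError(f"no configuration of size {k} has been scored")
    top = max(k_configs, key=lambda cfg: k_configs[cfg][2])
    sets = []
    for j in top:
        fixed = tuple(i for i in top if i != j)
        cands = np.array([l for l in range(model.p) if l not in fixed], dtype=int)
        lbf = _batch_log_bf(model, fixed, cands)
        b_bar = np.exp(lbf - logsumexp(lbf))
        # decreasing b_bar, ties broken toward the lower index
        order = np.lexsort((cands, -b_bar))
        cum = np.cumsum(b_bar[order])
        m = int(np.argmax(cum > theta)) if np.any(cum > theta) else len(order) - 1
        boundary = b_bar[order][m]
        while m + 1 < len(order) and np.isclose(b_bar[order][m + 1], boundary, rtol=0, atol=1e-15):
            m += 1
        chosen = order[: m + 1]
        sets.append(CredibleSet(theta=theta, anchor_variant=int(j),
                                members=[int(cands[i]) for i in chosen],
                                member_probs=b_bar[chosen]))
    return sets


# ---------------------------------------------------------------------------
# high-level entry point
# ---------------------------------------------------------------------------

def fine_map_meta(meta: MetaGWAS, ld: LDMatrix, method: str = "miss",
                  tau2: float = DEFAULT_TAU2, kmax: int = 5, iters: int = 50,
                  seed: int = 0, theta: float = 0.95, b_mode: str = "unit",
                  n_classic: float | None = None, search: str = "sss",
                  cs_k: int | None = None) -> PosteriorSummary:
    """Fine-map a meta-analysis end to end and attach credible sets.

    ``method="miss"`` uses the missingness-aware likelihood (overlap matrix
    from the meta weights, per-variant sample sizes and INFO).
    ``method="classic"`` runs the complete-data model as a naive analyst
    would: covariance R, a single common sample size ``n_classic`` (default:
    total meta sample size) and unit INFO.
    """
    if method == "miss":
        m = build_overlap_matrix(meta.weights, b_mode=b_mode)
        om = build_meta_covariance(ld, m)
        model = LikelihoodModel.from_meta(om, meta.z, meta.n_eff, meta.info_meta, ld, tau2)
    elif method == "classic":
        p = meta.p
        om = build_meta_covariance(ld, np.ones((p, p)))
        if n_classic is None:
            n_classic = (float(np.sum(meta.study_sizes)) if meta.study_sizes is not None
                         else float(np.max(meta.n_eff)))
        model = LikelihoodModel.from_meta(om, meta.z, np.full(p, n_classic),
                                          np.ones(p), ld, tau2)
    else:
        raise ValidationError(f"unknown method {method!r}")
    prior = PriorSpec(kmax=kmax, p=meta.p)
    if search == "sss":
        summary = shotgun_search(model, prior, iters=iters, seed=seed)
    elif search == "enumerate":
        summary = enumerate_posterior(model, prior)
    else:
        raise ValidationError(f"unknown search {search!r}")
    summary.credible_sets = credible_sets(model, prior, summary, k=cs_k, theta=theta)
    summary.search_meta.update(method=f"finemap-{method}", tau2=tau2, kmax=kmax,
                               theta=theta, ridge_used=om.ridge_used)
    return summary
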