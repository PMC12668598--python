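"""Sample-overlap structure of an inverse-variance weighted meta-analysis.

When every variant is present in every study, the meta-analyzed z-scores
have covariance equal to the LD matrix R.  With variant-specific
missingness the covariance attenuates: for variants j1, j2 it becomes
``R[j1,j2] * M[j1,j2]`` where the sample-overlap matrix

    M[j1,j2] = sum_u sqrt(w_j1u * w_j2u) * B_j1j2u
               / sqrt( sum_u w_j1u * sum_u w_j2u )

sums over the studies u, with inverse-variance weights ``w_ju = s_ju**-2``
(zero where a variant is missing) and a correction term B that is 1 up to
terms quadratic in the standardized effect sizes.  The meta covariance
``R_M = R (hadamard) M`` is factorized once and reused for every
configuration scored downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .io import LDMatrix, MetaGWAS, StudyGWAS, ValidationError, VariantPanel

__all__ = [
    "OverlapModel",
    "meta_analyze",
    "build_overlap_matrix",
    "weights_from_presence",
    "build_meta_covariance",
    "solve_with_factor",
    "infer_presence",
]

DEFAULT_RIDGE_LADDER = (0.0, 1e-8, 1e-6, 1e-4)


@dataclass
class OverlapModel:
    """The meta covariance R_M = R * M with a reusable Cholesky factor."""

    m: np.ndarray
    r_meta: np.ndarray
    factor: tuple
    ridge_used: float

    @property
    def p(self) -> int:
        return self.r_meta.shape[0]

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        return cho_solve(self.factor, rhs)

    def logdet(self) -> float:
        """log |R_M + ridge I| from the cached factor."""
        c = self.factor[0]
        return 2.0 * float(np.sum(np.log(np.diag(c))))


def meta_analyze(studies: list[StudyGWAS], panel: VariantPanel) -> MetaGWAS:
    """Inverse-variance weighted meta-analysis of aligned study results.

    ``z_j = sum_u w_ju * beta_ju / sqrt(sum_u w_ju)`` with ``w_ju = s_ju**-2``
    where present and 0 otherwise.  Variants absent from every study are not
    removed here; callers should drop them first (see ``io.read_presence``).
    """
    p = panel.p
    d = len(studies)
    if d == 0:
        raise ValidationError("need at least one study")
    for st in studies:
        if st.present.size != p:
            raise ValidationError(f"study {st.study_id} not aligned to panel (p={p})")
        if st.scale != "standardized":
            raise ValidationError(f"study {st.study_id} must be on the standardized scale")
    weights = np.zeros((d, p))
    wb = np.zeros((d, p))
    presence = np.zeros((d, p), dtype=bool)
    info = np.zeros((d, p))
    for u, st in enumerate(studies):
        obs = st.present
        presence[u] = obs
        weights[u, obs] = st.se[obs] ** -2
        wb[u, obs] = weights[u, obs] * st.beta_hat[obs]
        info[u] = st.info
    w_sum = weights.sum(axis=0)
    if np.any(w_sum <= 0):
        bad = np.flatnonzero(w_sum <= 0)
        raise ValidationError(
            f"{bad.size} variant(s) have zero total weight (absent everywhere), e.g. {int(bad[0])}")
    z = wb.sum(axis=0) / np.sqrt(w_sum)
    n_u = np.array([st.n for st in studies], dtype=float)
    n_eff = presence.T @ n_u
    info_meta = (weights * info).sum(axis=0) / w_sum
    return MetaGWAS(panel=panel, z=z, n_eff=n_eff, presence=presence, weights=weights,
                    info_meta=info_meta, study_ids=[st.study_id for st in studies],
                    study_sizes=n_u)


def weights_from_presence(presence: np.ndarray, n_u: np.ndarray,
                          maf: np.ndarray | None = None,
                          info: np.ndarray | None = None) -> np.ndarray:
    """Approximate IVW weights when per-study standard errors are unavailable.

    For a standardized quantitative trait ``s_ju**-2 ~ n_u * Var(x_ju)``, so
    ``w_ju`` proportional to ``n_u * 2 f_j (1 - f_j) * INFO_ju`` is used.
    Only weight *ratios across studies* enter the overlap matrix, so
    variant-specific factors are harmless; they matter only if weights are
    reused for effect-size meta-analysis.
    """
    presence = np.asarray(presence, dtype=bool)
    d, p = presence.shape
    w = np.tile(np.asarray(n_u, dtype=float)[:, None], (1, p))
    if maf is not None:
        w = w * (2.0 * maf * (1.0 - maf))[None, :]
    if info is not None:
        info = np.asarray(info, dtype=float)
        w = w * (info if info.ndim == 2 else np.tile(info[None, :], (d, 1)))
    w[~presence] = 0.0
    return w


def _b_term(beta1, i1, beta2, i2, r12, reading: str) -> np.ndarray:
    """Quadratic-in-beta correction to the overlap covariance (default 1)."""
    if reading == "product":
        num = 1.0 - (beta1 * i1) ** 2 - (beta2 * i2) ** 2 + beta1 * beta2 * r12 * i1 * i2
    elif reading == "ratio":
        num = 1.0 - (beta1 / i1) ** 2 - (beta2 / i2) ** 2 + beta1 * beta2 * r12 / (i1 * i2)
    else:
        raise ValidationError(f"unknown B-term reading {reading!r}")
    den = np.sqrt((1.0 - (i1 * beta1) ** 2) * (1.0 - (i2 * beta2) ** 2))
    return num / den


def build_overlap_matrix(weights: np.ndarray, b_mode: str = "unit",
                         studies: list[StudyGWAS] | None = None,
                         ld: LDMatrix | None = None,
                         b_reading: str = "product") -> np.ndarray:
    """Build the p x p sample-overlap matrix M from d x p IVW weights.

    ``b_mode="unit"`` sets every B term to 1 (the default: B deviates from 1
    only by terms quadratic in standardized effects, which are O(1/n));
    ``b_mode="exact"`` needs per-study results and the LD matrix.
    """
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValidationError("weights must be non-negative")
    sw = np.sqrt(weights)
    w_sum = weights.sum(axis=0)
    if np.any(w_sum <= 0):
        raise ValidationError("every variant needs positive total weight")
    denom = np.sqrt(np.outer(w_sum, w_sum))
    if b_mode == "unit":
        num = sw.T @ sw
    elif b_mode == "exact":
        if studies is None or ld is None:
            raise ValidationError(
                "b_mode='exact' requires per-study effect estimates and the LD matrix; "
                "use b_mode='unit' when only presence information is available")
        p = weights.shape[1]
        num = np.zeros((p, p))
        for u, st in enumerate(studies):
            beta = np.where(st.present, st.beta_hat, 0.0)
            i_u = np.sqrt(st.info)
            b_u = _b_term(beta[:, None], i_u[:, None], beta[None, :], i_u[None, :],
                          ld.r, b_reading)
            num += np.outer(sw[u], sw[u]) * b_u
    else:
        raise ValidationError(f"unknown b_mode {b_mode!r}")
    m = num / denom
    return 0.5 * (m + m.T)


def build_meta_covariance(ld: LDMatrix, m: np.ndarray,
                          ridge_ladder=DEFAULT_RIDGE_LADDER) -> OverlapModel:
    """Form R_M = R * M and factorize it, escalating a diagonal ridge.

    The ridge ladder is expressed as multiples of the mean diagonal; the
    first rung at which the Cholesky factorization succeeds is recorded in
    ``ridge_used``.  Failure at the largest rung raises with the smallest
    eigenvalue for diagnosis.
    """
    m = np.asarray(m, dtype=float)
    if m.shape != ld.r.shape:
        raise ValidationError("LD and overlap matrices are not conformable")
    # elementwise product of two (validated) symmetric matrices; with
    # complete overlap (M = 1) this leaves R untouched bit-for-bit
    r_meta = ld.r * m
    scale = float(np.mean(np.diag(r_meta)))
    for rel in ridge_ladder:
        ridge = rel * scale
        try:
            factor = cho_factor(r_meta + ridge * np.eye(r_meta.shape[0]), lower=True)
        except np.linalg.LinAlgError:
            continue
        return OverlapModel(m=np.asarray(m, dtype=float), r_meta=r_meta,
                            factor=factor, ridge_used=ridge)
    w_min = float(np.linalg.eigvalsh(r_meta)[0])
    raise ValidationError(
        f"meta covariance not positive definite at maximum ridge "
        f"{ridge_ladder[-1]:g} * mean diag; smallest eigenvalue {w_min:.3e}")


def solve_with_factor(model: OverlapModel, rhs: np.ndarray) -> np.ndarray:
    """Solve ``r_meta @ x = rhs`` using the cached triangular factor."""
    rhs = np.asarray(rhs, dtype=float)
    if rhs.shape[0] != model.p:
        raise ValidationError(f"rhs has leading dimension {rhs.shape[0]}, expected {model.p}")
    return model.solve(rhs)


def infer_presence(n_eff: np.ndarray, n_u: np.ndarray, rtol: float = 1e-6) -> np.ndarray:
    """Infer the presence pattern from per-variant total sample sizes.

    Each variant's total n must be expressible as the sum of a unique subset
    of the study sample sizes; an ambiguous or unattainable total raises,
    listing the candidate subsets.  Useful for public meta-analyses that
    report only totals.
    """
    n_u = np.asarray(n_u, dtype=float)
    d = n_u.size
    subsets: dict[float, list[tuple[int, ...]]] = {}
    for k in range(1, d + 1):
        for comb in combinations(range(d), k):
            subsets.setdefault(round(float(n_u[list(comb)].sum()), 6), []).append(comb)
    presence = np.zeros((d, len(n_eff)), dtype=bool)
    for j, total in enumerate(np.asarray(n_eff, dtype=float)):
        matches = [combs for s, combs in subsets.items()
                   if np.isclose(s, total, rtol=rtol)]
        flat = [c for group in matches for c in group]
        if not flat:
            raise ValidationError(f"variant {j}: total n={total:g} matches no study subset")
        if len(flat) > 1:
            raise ValidationError(
                f"variant {j}: total n={total:g} is ambiguous between subsets {flat}")
        presence[list(flat[0]), j] = True
    return presence
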