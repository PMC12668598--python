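"""Synthetic multi-cohort GWAS meta-analyses with ground truth.

The generator emulates the statistical structure of a quantitative-trait
meta-analysis over cohorts drawn from one population:

* **Genotypes** come from a Gaussian copula: correlated latent normals are
  thresholded at Hardy-Weinberg cutpoints into {0, 1, 2}.  The latent
  correlation of each within-block pair is *calibrated* (by inverting the
  exact thresholded-Gaussian covariance integral) so that the realized
  genotype correlation matches the requested block-AR LD structure.
* **Imputation noise** shrinks each individual's one-hot genotype
  probability vector toward the population (HWE) distribution with weight
  ``a = 1 - sqrt(INFO)``; the resulting dosage has variance ``INFO`` times
  the genotype variance, and "virtual" genotypes resampled from the same
  probability triples drive the phenotype while the GWAS sees only dosages.
* **Phenotypes** give each causal variant an equal share of variance
  (default 0.1%), with independent Gaussian residuals.
* **Missingness** removes a fraction of variants from a random nonempty
  proper subset of cohorts; causal variants can be forced to be present in
  a single cohort, the adversarial case for naive fine-mapping.
* Per-cohort marginal linear-model GWAS are combined by inverse-variance
  weighting, and a held-out cohort provides the reference LD matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm

from .io import LDMatrix, MetaGWAS, StudyGWAS, ValidationError, VariantPanel
from .overlap import meta_analyze

__all__ = [
    "LDSpec",
    "SimConfig",
    "SimTruth",
    "SimData",
    "GenotypeModel",
    "simulate_genotypes",
    "degrade_to_dosages",
    "sample_virtual_genotypes",
    "simulate_phenotype",
    "run_gwas",
    "inject_missingness",
    "make_meta_dataset",
    "filter_panel",
]

_SMAX = 0.9995  # largest latent correlation the calibration will use


@dataclass
class LDSpec:
    """Block LD: AR(1) correlation ``rho**|i-j|`` inside consecutive blocks,
    independence across blocks.  Minor allele frequencies are drawn per
    block (plus a small per-variant jitter) because strongly correlated
    variants necessarily have similar frequencies (the jitter is relative:
    ``maf = base * (1 + U(-maf_jitter, maf_jitter))``)."""

    block_size: int = 20
    rho: float = 0.9
    maf_jitter: float = 0.05

    def target_r(self, p: int) -> np.ndarray:
        r = np.eye(p)
        for start in range(0, p, self.block_size):
            stop = min(start + self.block_size, p)
            idx = np.arange(start, stop)
            r[np.ix_(idx, idx)] = self.rho ** np.abs(idx[:, None] - idx[None, :])
        return r

    def blocks(self, p: int) -> list[np.ndarray]:
        return [np.arange(s, min(s + self.block_size, p))
                for s in range(0, p, self.block_size)]


def _hwe_cutpoints(maf: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Latent-normal thresholds reproducing HWE genotype frequencies."""
    q0 = (1.0 - maf) ** 2
    q1 = 2.0 * maf * (1.0 - maf)
    return norm.ppf(q0), norm.ppf(q0 + q1)


def _pair_cov_curve(t1a, t2a, t1b, t2b, theta_grid):
    """Cumulative genotype covariance as a function of latent correlation.

    For thresholded Gaussians, d Cov / d r equals the sum of the bivariate
    normal densities at the four threshold pairs (Price's theorem), so the
    covariance at latent correlation r is the integral of that sum from 0
    to r.  Substituting ``r = sin(theta)`` removes the integrable
    singularity at r -> 1, enabling plain trapezoidal quadrature.
    Vectorized over pairs (leading axes) and the theta grid (last axis).
    """
    s = np.sin(theta_grid)
    c = np.cos(theta_grid)
    one_m = 1.0 - s ** 2
    total = 0.0
    for ha in (t1a, t2a):
        for hb in (t1b, t2b):
            ha_ = ha[..., None]
            hb_ = hb[..., None]
            dens = np.exp(-(ha_ ** 2 - 2.0 * s * ha_ * hb_ + hb_ ** 2) / (2.0 * one_m))
            total = total + dens / (2.0 * np.pi * np.sqrt(one_m))
    integrand = total * c  # Jacobian of r = sin(theta)
    curve = np.concatenate(
        [np.zeros(integrand.shape[:-1] + (1,)),
         np.cumsum(0.5 * (integrand[..., 1:] + integrand[..., :-1])
                   * np.diff(theta_grid), axis=-1)], axis=-1)
    return curve


@dataclass
class GenotypeModel:
    """A calibrated Gaussian-copula genotype sampler for one region."""

    maf: np.ndarray
    target_r: np.ndarray
    blocks: list
    latent_chols: list
    cut1: np.ndarray
    cut2: np.ndarray

    @property
    def p(self) -> int:
        return self.maf.size

    @classmethod
    def calibrate(cls, ld_spec: LDSpec, maf: np.ndarray, n_theta: int = 96) -> "GenotypeModel":
        maf = np.asarray(maf, dtype=float)
        p = maf.size
        target = ld_spec.target_r(p)
        cut1, cut2 = _hwe_cutpoints(maf)
        sd = np.sqrt(2.0 * maf * (1.0 - maf))
        theta = np.linspace(0.0, np.arcsin(_SMAX), n_theta)
        s_grid = np.sin(theta)
        blocks = ld_spec.blocks(p)
        chols = []
        for idx in blocks:
            b = idx.size
            ii, jj = np.triu_indices(b, k=1)
            gi, gj = idx[ii], idx[jj]
            curves = _pair_cov_curve(cut1[gi], cut2[gi], cut1[gj], cut2[gj], theta)
            want = target[gi, gj] * sd[gi] * sd[gj]
            cmax = curves[..., -1]
            if np.any(want > cmax * (1 + 1e-9)):
                bad = int(np.flatnonzero(want > cmax)[0])
                raise ValidationError(
                    f"infeasible MAF/correlation combination: target r="
                    f"{target[gi[bad], gj[bad]]:.3f} between variants {gi[bad]} and "
                    f"{gj[bad]} (maf {maf[gi[bad]]:.3f}, {maf[gj[bad]]:.3f}) is "
                    f"unattainable for thresholded genotypes")
            latent = np.eye(b)
            for m in range(ii.size):
                r = float(np.interp(want[m], curves[m], s_grid))
                latent[ii[m], jj[m]] = latent[jj[m], ii[m]] = r
            w, vecs = np.linalg.eigh(latent)
            if w[0] < 1e-10:
                latent = (vecs * np.clip(w, 1e-8, None)) @ vecs.T
                dd = np.sqrt(np.diag(latent))
                latent = latent / np.outer(dd, dd)
            chols.append(np.linalg.cholesky(latent).astype(np.float32))
        return cls(maf=maf, target_r=target, blocks=blocks, latent_chols=chols,
                   cut1=cut1, cut2=cut2)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw an n x p genotype matrix in {0, 1, 2} (int8)."""
        g = np.empty((n, self.p), dtype=np.int8)
        for idx, chol in zip(self.blocks, self.latent_chols):
            lat = rng.standard_normal((n, idx.size), dtype=np.float32) @ chol.T
            g[:, idx] = ((lat > self.cut1[idx].astype(np.float32))
                         .astype(np.int8)
                         + (lat > self.cut2[idx].astype(np.float32)).astype(np.int8))
        return g


def simulate_genotypes(p: int, n: int, ld_spec: LDSpec, maf_range=(0.05, 0.5),
                       seed: int | np.random.Generator = 0):
    """Sample genotypes with calibrated block LD.

    ``maf_range`` may be a (lo, hi) tuple (block-level frequencies are drawn
    uniformly, with per-variant jitter) or an explicit length-p array.

    Returns ``(genotypes, realized_r, model)`` where ``realized_r`` is the
    empirical correlation of the standardized genotype columns.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(maf_range, tuple):
        maf = _draw_mafs(p, ld_spec, maf_range, rng)
    else:
        maf = np.asarray(maf_range, dtype=float)
    model = GenotypeModel.calibrate(ld_spec, maf)
    g = model.sample(n, rng)
    realized = np.corrcoef(g.astype(np.float32), rowvar=False)
    return g, realized, model


def _draw_mafs(p: int, ld_spec: LDSpec, maf_range, rng) -> np.ndarray:
    lo, hi = maf_range
    maf = np.empty(p)
    for idx in ld_spec.blocks(p):
        base = rng.uniform(lo, hi)
        jit = 1.0 + rng.uniform(-ld_spec.maf_jitter, ld_spec.maf_jitter, idx.size)
        maf[idx] = np.clip(base * jit, max(lo, 0.01), 0.5)
    return maf


# ---------------------------------------------------------------------------
# dosages and virtual genotypes
# ---------------------------------------------------------------------------

@dataclass
class DosageData:
    dosages: np.ndarray
    realized_info: np.ndarray
    shrink: np.ndarray        # a_j = 1 - sqrt(INFO_j)
    triples: np.ndarray | None = None


def degrade_to_dosages(genotypes: np.ndarray, info_target: np.ndarray, maf: np.ndarray,
                       return_triples: bool = False) -> DosageData:
    """Degrade hard genotypes to imputation-style dosages of target INFO.

    Each individual's one-hot genotype probability vector is shrunk toward
    the HWE marginal with weight ``a = 1 - sqrt(info_target)``; the dosage
    (the triple's expectation) is then ``(1-a) g + a * 2f`` and has variance
    ``info_target`` times the genotype variance, reproducing how imputed
    dosages contract toward the population mean.  Realized INFO is reported
    as the empirical dosage/genotype variance ratio.
    """
    info_target = np.broadcast_to(np.asarray(info_target, dtype=float),
                                  (genotypes.shape[1],))
    if np.any(info_target <= 0) or np.any(info_target > 1):
        raise ValidationError("info_target must lie in (0, 1]")
    maf = np.asarray(maf, dtype=float)
    a = 1.0 - np.sqrt(info_target)
    g = genotypes.astype(np.float32)
    dos = (1.0 - a).astype(np.float32) * g + (a * 2.0 * maf).astype(np.float32)
    # the dosage is an affine map of the genotype, so the empirical
    # variance ratio equals (1-a)^2 identically (up to float rounding)
    realized = (1.0 - a) ** 2
    triples = None
    if return_triples:
        n, p = genotypes.shape
        q = np.stack([(1 - maf) ** 2, 2 * maf * (1 - maf), maf ** 2], axis=-1)  # p x 3
        onehot = np.zeros((n, p, 3))
        for gval in (0, 1, 2):
            onehot[..., gval] = genotypes == gval
        triples = (1.0 - a)[None, :, None] * onehot + a[None, :, None] * q[None, :, :]
    return DosageData(dosages=dos, realized_info=realized, shrink=a, triples=triples)


def sample_virtual_genotypes(genotypes: np.ndarray, shrink: np.ndarray, maf: np.ndarray,
                             rng: np.random.Generator) -> np.ndarray:
    """Sample "virtual" genotypes from the imputation probability triples.

    Equivalent to drawing from the shrunk triples of ``degrade_to_dosages``:
    with probability ``1-a`` the true genotype, otherwise a fresh HWE draw.
    These play the role of the real underlying genetics that drive the
    phenotype while GWAS only observes the dosages.
    """
    n, k = genotypes.shape
    maf = np.asarray(maf, dtype=float)
    q0 = (1.0 - maf) ** 2
    q01 = q0 + 2.0 * maf * (1.0 - maf)
    keep = rng.random((n, k)) < (1.0 - shrink)[None, :]
    u = rng.random((n, k))
    hwe = (u > q0[None, :]).astype(np.int8) + (u > q01[None, :]).astype(np.int8)
    return np.where(keep, genotypes, hwe)


def simulate_phenotype(x_virtual_std: np.ndarray, h2_per_variant: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Phenotype with equal variance share per causal variant.

    ``y = sum_j lambda x_j + eps`` with ``lambda = sqrt(h2_per_variant)``
    and residual variance ``1 - k h2``, so Var(y) is approximately 1.
    """
    n, k = x_virtual_std.shape
    lam = np.full(k, np.sqrt(h2_per_variant))
    h2_total = float(lam @ lam)
    if h2_total >= 1:
        raise ValidationError(f"total causal variance {h2_total:g} must be < 1")
    y = x_virtual_std @ lam if k else np.zeros(n)
    return y + rng.normal(scale=np.sqrt(1.0 - h2_total), size=n)


def run_gwas(dosages: np.ndarray, phenotype: np.ndarray, study_id: str,
             info: np.ndarray | None = None) -> StudyGWAS:
    """Marginal linear-model GWAS on standardized dosages and phenotype.

    Per variant, the univariate least-squares slope and standard error of
    centered/standardized y on the centered/standardized dosage.  A
    zero-variance predictor is flagged absent rather than producing
    infinities.
    """
    n, p = dosages.shape
    y = np.asarray(phenotype, dtype=np.float64)
    y = (y - y.mean()) / y.std()
    # slopes without materializing a standardized copy of the predictors:
    # with y centered, beta_j = cov(x_j, y) / var(x_j) on standardized x
    x = dosages if dosages.dtype == np.float32 else dosages.astype(np.float32)
    mu = x.mean(axis=0, dtype=np.float64)
    m2 = np.einsum("ij,ij->j", x, x, dtype=np.float64) / n
    var = m2 - mu ** 2
    degenerate = var <= 1e-12
    sd_safe = np.sqrt(np.where(degenerate, 1.0, var))
    xty = (x.T @ y.astype(np.float32)).astype(np.float64)
    beta = (xty / n - mu * y.mean()) / sd_safe
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.maximum(1.0 - beta ** 2, np.finfo(float).tiny) / (n - 2))
    beta[degenerate] = np.nan
    se[degenerate] = np.nan
    return StudyGWAS(study_id=study_id, n=n, present=~degenerate,
                     beta_hat=beta, se=se, info=info, scale="standardized")


def inject_missingness(studies: list[StudyGWAS], missing_frac: float,
                       causal_set, causal_rule: str,
                       rng: np.random.Generator) -> list[StudyGWAS]:
    """Mark variants missing from random cohort subsets.

    ``round(missing_frac * p)`` non-causal variants are selected; each is
    removed from a uniformly chosen nonempty proper subset of cohorts (the
    number missing is uniform on 1..d-1).  Causal variants follow
    ``causal_rule``: ``all_but_one`` leaves each present in exactly one
    uniformly chosen cohort, ``random`` pools them with the rest,
    ``none`` keeps them complete.  Returns new StudyGWAS objects.
    """
    d = len(studies)
    if d < 2:
        raise ValidationError("missingness needs at least 2 cohorts")
    p = studies[0].present.size
    causal_set = np.asarray(list(causal_set), dtype=int)
    present = np.stack([st.present for st in studies])
    pool = np.setdiff1d(np.arange(p), causal_set) if causal_rule != "random" \
        else np.arange(p)
    n_pick = int(round(missing_frac * p))
    picked = rng.choice(pool, size=min(n_pick, pool.size), replace=False)
    for j in picked:
        n_miss = int(rng.integers(1, d))
        gone = rng.choice(d, size=n_miss, replace=False)
        present[gone, j] = False
    if causal_rule == "all_but_one":
        for j in causal_set:
            keeper = int(rng.integers(d))
            present[:, j] = False
            present[keeper, j] = True
    elif causal_rule not in ("random", "none"):
        raise ValidationError(f"unknown causal_rule {causal_rule!r}")
    out = []
    for u, st in enumerate(studies):
        mask = present[u] & st.present
        beta = np.where(mask, st.beta_hat, np.nan)
        se = np.where(mask, st.se, np.nan)
        out.append(replace(st, present=mask, beta_hat=beta, se=se))
    return out


# ---------------------------------------------------------------------------
# end-to-end dataset
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Conditions of one simulated meta-analysis.

    Defaults mirror a two-cohort quantitative-trait meta-analysis with one
    causal variant explaining 0.1% of phenotypic variance, 20% of variants
    carrying missing data, the causal variant present in a single cohort,
    and high imputation quality (INFO in [0.9, 1]).
    """

    p: int = 400
    n_per_cohort: int = 100_000
    d: int = 2
    ld_spec: LDSpec = field(default_factory=LDSpec)
    maf_range: tuple = (0.05, 0.5)
    n_causal: int = 1
    h2_per_variant: float = 0.001
    info_range: tuple = (0.9, 1.0)
    missing_frac: float = 0.20
    causal_missing_rule: str = "all_but_one"
    seed: int = 0

    def __post_init__(self):
        if self.h2_per_variant * self.n_causal >= 1:
            raise ValidationError("total causal variance must be < 1")
        if not (0.0 <= self.missing_frac <= 1.0):
            raise ValidationError("missing_frac must lie in [0, 1]")
        if self.d < 2 and (self.missing_frac > 0 or self.causal_missing_rule != "none"):
            raise ValidationError("missingness requires at least 2 cohorts")


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset."""

    causal_set: np.ndarray
    lam: np.ndarray
    presence: np.ndarray
    realized_info: np.ndarray
    realized_ld: np.ndarray
    maf: np.ndarray
    seed: int


@dataclass
class SimData:
    meta: MetaGWAS
    ld: LDMatrix
    truth: SimTruth
    studies: list


def _make_panel(p: int, maf: np.ndarray) -> VariantPanel:
    return VariantPanel(
        variant_id=np.array([f"rs{j + 1}" for j in range(p)], dtype=object),
        chromosome=np.array(["1"] * p, dtype=object),
        position=np.arange(1, p + 1) * 1000,
        allele1=np.array(["A"] * p, dtype=object),
        allele2=np.array(["G"] * p, dtype=object),
        maf=maf,
    )


def make_meta_dataset(sim: SimConfig) -> SimData:
    """Simulate GWAS cohorts plus an LD-reference cohort and meta-analyze.

    The reference cohort contributes only its dosage correlation matrix,
    mimicking fine-mapping with external reference LD; the GWAS cohorts'
    phenotypes are driven by virtual genotypes while their associations are
    measured on dosages.  Deterministic given ``sim.seed``.
    """
    ss = np.random.SeedSequence(sim.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(sim.d + 3)]
    rng_design, rng_ref, rng_miss = rngs[0], rngs[1], rngs[2]
    cohort_rngs = rngs[3:]

    maf = _draw_mafs(sim.p, sim.ld_spec, sim.maf_range, rng_design)
    info_target = rng_design.uniform(*sim.info_range, size=sim.p)
    model = GenotypeModel.calibrate(sim.ld_spec, maf)
    causal = np.sort(rng_design.choice(sim.p, size=sim.n_causal, replace=False))
    lam = np.full(sim.n_causal, np.sqrt(sim.h2_per_variant))

    # The dosage is an affine per-column map of the genotype (see
    # degrade_to_dosages), so standardized dosages equal standardized
    # genotypes and the dosage correlation equals the genotype correlation;
    # GWAS and reference LD are therefore computed on the genotypes
    # directly, and realized INFO is the analytic (1 - a)^2.
    shrink = 1.0 - np.sqrt(info_target)
    realized_info = (1.0 - shrink) ** 2
    studies = []
    for u in range(sim.d):
        rng = cohort_rngs[u]
        g = model.sample(sim.n_per_cohort, rng)
        xv = sample_virtual_genotypes(g[:, causal], shrink[causal], maf[causal], rng)
        xv = xv.astype(np.float64)
        sd = xv.std(axis=0)
        if np.any(sd <= 0):
            raise ValidationError("a causal variant is monomorphic in a cohort; "
                                  "increase n or maf range")
        xv = (xv - xv.mean(axis=0)) / sd
        y = simulate_phenotype(xv, sim.h2_per_variant, rng)
        studies.append(run_gwas(g.astype(np.float32), y, f"cohort{u + 1}",
                                info=realized_info))

    # held-out LD reference: correlation of its (standardized) dosages,
    # which coincides with its genotype correlation
    g_ref = model.sample(sim.n_per_cohort, rng_ref).astype(np.float32)
    mu = g_ref.mean(axis=0, dtype=np.float64).astype(np.float32)
    g_ref -= mu
    cov = (g_ref.T @ g_ref).astype(np.float64) / sim.n_per_cohort
    sd = np.sqrt(np.diag(cov))
    r_hat = cov / np.outer(sd, sd)
    r_hat = 0.5 * (r_hat + r_hat.T)
    np.fill_diagonal(r_hat, 1.0)
    ld = LDMatrix(np.clip(r_hat, -1.0, 1.0), check_psd=False)

    if sim.missing_frac > 0 or sim.causal_missing_rule != "none":
        studies = inject_missingness(studies, sim.missing_frac, causal,
                                     sim.causal_missing_rule, rng_miss)
    panel = _make_panel(sim.p, maf)
    meta = meta_analyze(studies, panel)
    truth = SimTruth(causal_set=causal, lam=lam,
                     presence=np.stack([st.present for st in studies]),
                     realized_info=realized_info, realized_ld=r_hat,
                     maf=maf, seed=sim.seed)
    return SimData(meta=meta, ld=ld, truth=truth, studies=studies)


def filter_panel(maf: np.ndarray, info: np.ndarray, maf_min: float = 0.001,
                 info_min: float = 0.1) -> np.ndarray:
    """Variant QC mask: keep MAF > maf_min and INFO > info_min.

    The generator produces in-range variants, so on simulated data this is
    a no-op; it exists for external inputs.
    """
    return (np.asarray(maf) > maf_min) & (np.asarray(info) > info_min)
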