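"""Summary-statistics imputation of unobserved z-scores.

Under the null, the z-scores of a study are jointly N(0, R), so an
unobserved z can be predicted from the observed set O as the conditional
mean ``z_{j|O} = R_jO R_OO^-1 z_O`` ("unscaled").  Because the conditional
mean is shrunk toward zero, a variance-rescaled version
``z*_{j|O} = z_{j|O} / sqrt(R_jO R_OO^-1 R_Oj)`` ("scaled") is commonly
preferred.  Imputing each study's missing variants and then meta-analyzing
the completed studies is the baseline against which the missingness-aware
likelihood is compared; note it requires the study-level results, which
public meta-analyses often do not provide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .io import LDMatrix, MetaGWAS, StudyGWAS, ValidationError, VariantPanel
from .overlap import meta_analyze

__all__ = ["ImputationResult", "impute_z", "impute_study", "impute_study_then_meta"]

DEFAULT_RIDGE = 1e-4   # multiple of mean diag added to R_OO
R2PRED_FLOOR = 1e-4    # below this predictive r2, scaled imputation refuses


@dataclass
class ImputationResult:
    """Completed z-scores of one study plus imputation quality."""

    z_imputed: np.ndarray
    scaled: bool
    r2pred: np.ndarray
    source_mask: np.ndarray  # True where observed, False where imputed


def _roo_factor(r: np.ndarray, observed: np.ndarray, ridge: float):
    roo = r[np.ix_(observed, observed)]
    reg = ridge * float(np.mean(np.diag(roo)))
    try:
        return cho_factor(roo + reg * np.eye(roo.shape[0]), lower=True)
    except np.linalg.LinAlgError as err:
        raise ValidationError(
            f"observed LD block is singular beyond ridge {ridge:g}") from err


def impute_z(z_obs: np.ndarray, ld: LDMatrix | np.ndarray, observed_set: np.ndarray,
             target_j: int, scaled: bool = False, ridge: float = DEFAULT_RIDGE) -> float:
    """Impute a single variant's z-score from the observed set.

    With ``ridge=0`` and the target inside the observed set this returns the
    target's own z (the conditional expectation of an observed coordinate).
    A target uncorrelated with every observed variant yields 0 unscaled and
    is an error scaled (the predictive variance vanishes).
    """
    r = ld.r if isinstance(ld, LDMatrix) else np.asarray(ld, dtype=float)
    observed = np.asarray(observed_set, dtype=int)
    if observed.size == 0:
        raise ValidationError("observed set is empty")
    z_obs = np.asarray(z_obs, dtype=float)
    if z_obs.size != observed.size:
        raise ValidationError("z_obs must align with observed_set")
    f = _roo_factor(r, observed, ridge)
    rj = r[target_j, observed]
    coef = cho_solve(f, z_obs)
    val = float(rj @ coef)
    if not scaled:
        return val
    r2 = float(rj @ cho_solve(f, rj))
    if r2 <= R2PRED_FLOOR:
        raise ValidationError(
            f"variant {target_j}: predictive r2 {r2:.2e} below floor {R2PRED_FLOOR:g}; "
            f"unpredictable from the observed panel")
    return val / np.sqrt(r2)


def impute_study(study: StudyGWAS, ld: LDMatrix, scaled: bool = True,
                 ridge: float = DEFAULT_RIDGE) -> ImputationResult:
    """Complete one study's z-scores, imputing every missing variant at once.

    All observed variants of the region are used as the conditioning set.
    Missing variants whose predictive r2 falls below the floor are left NaN
    (reported unimputable rather than inflated).
    """
    r = ld.r
    obs = np.flatnonzero(study.present)
    mis = np.flatnonzero(~study.present)
    z = study.z.copy()
    r2pred = np.ones(study.present.size)
    if mis.size:
        if obs.size == 0:
            raise ValidationError(f"study {study.study_id} has no observed variants")
        f = _roo_factor(r, obs, ridge)
        coef = cho_solve(f, study.z[obs])
        rmo = r[np.ix_(mis, obs)]
        z_imp = rmo @ coef
        r2 = np.einsum("ij,ji->i", rmo, cho_solve(f, rmo.T))
        r2pred[mis] = r2
        if scaled:
            bad = r2 <= R2PRED_FLOOR
            with np.errstate(invalid="ignore", divide="ignore"):
                z_imp = np.where(bad, np.nan, z_imp / np.sqrt(np.maximum(r2, R2PRED_FLOOR)))
        z[mis] = z_imp
    return ImputationResult(z_imputed=z, scaled=scaled, r2pred=r2pred,
                            source_mask=study.present.copy())


def impute_study_then_meta(studies: list[StudyGWAS], panel: VariantPanel, ld: LDMatrix,
                           scaled: bool = True, ridge: float = DEFAULT_RIDGE) -> MetaGWAS:
    """Impute each study's missing z-scores, then meta-analyze as if complete.

    Observed entries keep their inverse-variance weights ``s**-2``; imputed
    entries get the approximation ``n_u * 2 f (1-f) * INFO`` (the weight an
    observed standardized-trait association of that study would carry).
    Variants unimputable in some study fall back to their observed studies
    only.  With no missingness anywhere this reduces exactly to the plain
    meta-analysis.
    """
    if not studies:
        raise ValidationError("need at least one study")
    if all(st.present.all() for st in studies):
        return meta_analyze(studies, panel)
    p = panel.p
    d = len(studies)
    zs = np.zeros((d, p))
    weights = np.zeros((d, p))
    for u, st in enumerate(studies):
        obs = st.present
        if not obs.any():
            continue  # nothing observed: the study cannot contribute
        res = impute_study(st, ld, scaled=scaled, ridge=ridge)
        zs[u] = res.z_imputed
        weights[u, obs] = st.se[obs] ** -2
        f = panel.maf
        approx_w = st.n * 2.0 * f * (1.0 - f) * st.info
        weights[u, ~obs] = approx_w[~obs]
        weights[u, np.isnan(zs[u])] = 0.0
        zs[u, np.isnan(zs[u])] = 0.0
    w_sum = weights.sum(axis=0)
    if np.any(w_sum <= 0):
        raise ValidationError("some variant has zero weight in every completed study")
    # z-score meta-analysis: sum_u sqrt(w_ju) z_ju / sqrt(sum_u w_ju), which
    # equals the IVW effect-scale combination wherever z = beta/se.
    z_meta = (np.sqrt(weights) * zs).sum(axis=0) / np.sqrt(w_sum)
    n_u = np.array([st.n for st in studies], dtype=float)
    presence = weights > 0
    n_eff = presence.T @ n_u
    info = np.stack([st.info for st in studies])
    info_meta = (weights * info).sum(axis=0) / w_sum
    return MetaGWAS(panel=panel, z=z_meta, n_eff=n_eff, presence=presence,
                    weights=weights, info_meta=info_meta,
                    study_ids=[st.study_id for st in studies], study_sizes=n_u)
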