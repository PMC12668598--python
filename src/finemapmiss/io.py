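"""Domain types and plain-text readers/writers.

The package speaks three whitespace-delimited input formats borrowed from
common fine-mapping practice:

* **z-file** — one row per variant with columns
  ``rsid chromosome position allele1 allele2 maf beta se`` and optional
  ``n info``.  Effects may be per-allele or on the standardized-genotype
  scale; per-allele effects are rescaled by ``sqrt(2 f (1 - f))`` on load.
* **LD file** — a square, headerless p x p correlation matrix of the
  (possibly dosage) genotype predictors.
* **presence table** — a TSV describing which study contributed data to
  which variant, with per-study sample sizes in a leading comment line.

Outputs are ``.snp`` (per-variant PIPs), ``.config`` (top causal
configurations) and ``.cred`` (credible sets), all plain text with a
provenance header.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("finemapmiss")

__all__ = [
    "FormatError",
    "ValidationError",
    "VariantPanel",
    "StudyGWAS",
    "MetaGWAS",
    "LDMatrix",
    "read_zfile",
    "write_zfile",
    "read_ld",
    "write_ld",
    "read_presence",
    "write_presence",
    "write_snp",
    "write_config",
    "write_cred",
]


class FormatError(ValueError):
    """A file does not conform to the expected layout."""


class ValidationError(ValueError):
    """Parsed values violate a model invariant."""


ZFILE_COLUMNS = ("rsid", "chromosome", "position", "allele1", "allele2", "maf", "beta", "se")


@dataclass
class VariantPanel:
    """Identity and allele-frequency information for the variants of a region.

    Positions are 1-based.  Allele order is taken as the orientation of the
    LD matrix; no strand flipping or harmonization is attempted.
    """

    variant_id: np.ndarray
    chromosome: np.ndarray
    position: np.ndarray
    allele1: np.ndarray
    allele2: np.ndarray
    maf: np.ndarray

    def __post_init__(self) -> None:
        self.variant_id = np.asarray(self.variant_id, dtype=object)
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.position = np.asarray(self.position, dtype=np.int64)
        self.allele1 = np.asarray(self.allele1, dtype=object)
        self.allele2 = np.asarray(self.allele2, dtype=object)
        self.maf = np.asarray(self.maf, dtype=float)
        if len(set(self.variant_id)) != self.p:
            raise ValidationError("variant ids must be unique")
        if np.any(self.maf <= 0) or np.any(self.maf > 0.5):
            bad = int(np.flatnonzero((self.maf <= 0) | (self.maf > 0.5))[0])
            raise ValidationError(f"maf must lie in (0, 0.5]; offending row {bad}")
        for chrom in np.unique(self.chromosome.astype(str)):
            pos = self.position[self.chromosome.astype(str) == chrom]
            if np.any(np.diff(pos) < 0):
                raise ValidationError(f"positions must be non-decreasing within chromosome {chrom}")

    @property
    def p(self) -> int:
        return len(self.variant_id)

    def subset(self, idx: np.ndarray) -> "VariantPanel":
        return VariantPanel(
            self.variant_id[idx], self.chromosome[idx], self.position[idx],
            self.allele1[idx], self.allele2[idx], self.maf[idx],
        )


@dataclass
class StudyGWAS:
    """Marginal association results of a single study on a shared panel.

    ``beta_hat`` and ``se`` are on the standardized-genotype scale unless
    ``scale == "allelic"``.  Entries where ``present`` is False are ignored
    (conventionally NaN).  ``info`` is the imputation INFO score, so the
    effective predictor scale factor is ``I_j = sqrt(info_j)``.
    """

    study_id: str
    n: int
    present: np.ndarray
    beta_hat: np.ndarray
    se: np.ndarray
    info: np.ndarray | None = None
    scale: str = "standardized"

    def __post_init__(self) -> None:
        self.present = np.asarray(self.present, dtype=bool)
        self.beta_hat = np.asarray(self.beta_hat, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        p = self.present.size
        if self.info is None:
            self.info = np.ones(p)
        self.info = np.asarray(self.info, dtype=float)
        if self.n <= 0:
            raise ValidationError(f"study {self.study_id}: sample size must be positive")
        if self.scale not in ("standardized", "allelic"):
            raise ValidationError(f"unknown scale flag {self.scale!r}")
        obs = self.present
        if np.any(self.se[obs] <= 0) or not np.all(np.isfinite(self.se[obs])):
            raise ValidationError(f"study {self.study_id}: se must be finite and > 0 where present")
        if not np.all(np.isfinite(self.beta_hat[obs])):
            raise ValidationError(f"study {self.study_id}: beta must be finite where present")
        if np.any(self.info <= 0) or np.any(self.info > 1):
            raise ValidationError(f"study {self.study_id}: info must lie in (0, 1]")

    @property
    def z(self) -> np.ndarray:
        """Marginal z-scores (NaN where absent)."""
        with np.errstate(invalid="ignore"):
            return self.beta_hat / self.se


@dataclass
class MetaGWAS:
    """An inverse-variance weighted meta-analysis aligned to one panel.

    ``presence`` and ``weights`` are d x p (studies by variants); weights are
    zero exactly where a study did not contribute.  ``n_eff[j]`` is the sum
    of sample sizes of the studies contributing variant j.
    """

    panel: VariantPanel
    z: np.ndarray
    n_eff: np.ndarray
    presence: np.ndarray
    weights: np.ndarray
    info_meta: np.ndarray
    study_ids: list[str] = field(default_factory=list)
    study_sizes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.n_eff = np.asarray(self.n_eff, dtype=float)
        self.presence = np.asarray(self.presence, dtype=bool)
        self.weights = np.asarray(self.weights, dtype=float)
        self.info_meta = np.asarray(self.info_meta, dtype=float)
        if not np.all(np.isfinite(self.z)):
            raise ValidationError("meta z-scores must be finite")
        if np.any(self.n_eff <= 0):
            raise ValidationError("every retained variant needs n_eff > 0")
        if np.any(self.weights[~self.presence] != 0):
            raise ValidationError("weights must be exactly 0 where a study is absent")

    @property
    def p(self) -> int:
        return self.panel.p

    @property
    def d(self) -> int:
        return self.presence.shape[0]


@dataclass
class LDMatrix:
    """A p x p LD (correlation) matrix of the genotype predictors."""

    r: np.ndarray
    check_psd: bool = True

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        r = self.r
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValidationError(f"LD matrix must be square, got shape {r.shape}")
        if np.max(np.abs(r - r.T)) > 1e-10:
            raise ValidationError("LD matrix must be symmetric (tolerance 1e-10)")
        if np.max(np.abs(np.diag(r) - 1.0)) > 1e-10:
            raise ValidationError("LD matrix must have a unit diagonal")
        if np.any(r < -1 - 1e-12) or np.any(r > 1 + 1e-12):
            raise ValidationError("LD entries must lie in [-1, 1]")
        if self.check_psd:
            w = np.linalg.eigvalsh(r)
            if w[0] < -1e-8:
                raise ValidationError(f"LD matrix has eigenvalue {w[0]:.3e} < -1e-8")

    @property
    def p(self) -> int:
        return self.r.shape[0]


# ---------------------------------------------------------------------------
# z-file
# ---------------------------------------------------------------------------

def read_zfile(path, scale: str = "standardized"):
    """Read a z-file into a panel plus a summary-statistic frame.

    Parameters
    ----------
    path
        Whitespace-delimited file with the mandatory header columns
        ``rsid chromosome position allele1 allele2 maf beta se`` and
        optional ``n`` and ``info``.
    scale
        ``"standardized"`` takes beta/se as already on the standardized
        genotype scale; ``"allelic"`` converts per-allele effects by
        multiplying beta and se by ``sqrt(2 f (1 - f))``.

    Returns
    -------
    (VariantPanel, pandas.DataFrame)
        The frame holds ``beta``/``se`` on the standardized scale plus any
        ``n``/``info`` columns, in file row order.
    """
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    missing = [c for c in ZFILE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"z-file {path} lacks mandatory column(s): {', '.join(missing)}")
    if (df["se"] <= 0).any():
        row = int(np.flatnonzero(df["se"].to_numpy() <= 0)[0])
        raise ValidationError(f"non-positive se at z-file row {row}")
    panel = VariantPanel(
        df["rsid"].to_numpy(), df["chromosome"].astype(str).to_numpy(),
        df["position"].to_numpy(), df["allele1"].to_numpy(),
        df["allele2"].to_numpy(), df["maf"].to_numpy(),
    )
    stats = df.drop(columns=[c for c in ("rsid", "chromosome", "position", "allele1", "allele2") if c in df])
    stats = stats.reset_index(drop=True)
    if scale == "allelic":
        f = panel.maf
        s = np.sqrt(2.0 * f * (1.0 - f))
        stats["beta"] = stats["beta"].to_numpy() * s
        stats["se"] = stats["se"].to_numpy() * s
    elif scale != "standardized":
        raise ValidationError(f"unknown scale {scale!r}")
    return panel, stats


def write_zfile(path, panel: VariantPanel, stats: pd.DataFrame, header_lines: Sequence[str] = ()) -> None:
    """Write a z-file (standardized scale) with optional ``#`` header lines."""
    out = pd.DataFrame({
        "rsid": panel.variant_id, "chromosome": panel.chromosome,
        "position": panel.position, "allele1": panel.allele1,
        "allele2": panel.allele2, "maf": panel.maf,
    })
    for col in stats.columns:
        out[col] = stats[col].to_numpy()
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        out.to_csv(fh, sep=" ", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# LD matrix
# ---------------------------------------------------------------------------

def read_ld(path, p_expected: int | None = None, check_psd: bool = True) -> LDMatrix:
    """Read a whitespace-delimited square LD matrix.

    Asymmetry up to 1e-8 is repaired by averaging with the transpose; a
    diagonal off unity by more than 1e-6 or a wrong dimension is an error.
    """
    r = np.loadtxt(path, ndmin=2)
    if r.shape[0] != r.shape[1]:
        raise FormatError(f"LD file {path} is {r.shape[0]}x{r.shape[1]}, expected square")
    if p_expected is not None and r.shape[0] != p_expected:
        raise FormatError(f"LD file {path}: found {r.shape[0]} variants, expected {p_expected}")
    asym = np.max(np.abs(r - r.T))
    if asym > 1e-8:
        raise ValidationError(f"LD file {path}: asymmetry {asym:.3e} exceeds 1e-8")
    r = 0.5 * (r + r.T)
    if np.max(np.abs(np.diag(r) - 1.0)) > 1e-6:
        raise ValidationError(f"LD file {path}: diagonal deviates from 1 beyond 1e-6")
    if np.any(np.abs(r) > 1.0 + 1e-10):
        raise ValidationError(f"LD file {path}: correlations outside [-1, 1]")
    np.fill_diagonal(r, 1.0)
    return LDMatrix(np.clip(r, -1.0, 1.0), check_psd=check_psd)


def write_ld(path, ld: LDMatrix) -> None:
    np.savetxt(path, ld.r, fmt="%.17g")


# ---------------------------------------------------------------------------
# presence table
# ---------------------------------------------------------------------------

def read_presence(path):
    """Read a study-presence TSV.

    Layout::

        #n_u<TAB>100000<TAB>100000
        cohort1<TAB>cohort2
        1<TAB>0
        ...

    The first (comment) line carries per-study sample sizes, the second the
    study ids, and the remaining p rows hold 0/1 flags aligned to the z-file
    row order.

    Returns
    -------
    (study_ids, n_u, presence, dropped)
        ``presence`` is d x p boolean.  ``dropped`` lists indices of variants
        present in zero studies; they are reported, not removed, so callers
        control the drop policy.
    """
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("#"):
            raise FormatError(f"presence file {path}: first line must carry '#n_u' sample sizes")
        parts = first.lstrip("#").split("\t")
        if parts[0].strip() not in ("n_u", "n"):
            raise FormatError(f"presence file {path}: expected '#n_u' header, got {first!r}")
        n_u = np.array([float(x) for x in parts[1:]])
        study_ids = fh.readline().strip().split("\t")
        if len(study_ids) != n_u.size:
            raise FormatError(
                f"presence file {path}: {len(study_ids)} study ids vs {n_u.size} sample sizes")
        body = np.loadtxt(fh, dtype=int, ndmin=2)
    if body.shape[1] != len(study_ids):
        raise FormatError(
            f"presence file {path}: {body.shape[1]} columns vs {len(study_ids)} studies")
    presence = body.T.astype(bool)
    dropped = np.flatnonzero(~presence.any(axis=0)).tolist()
    if dropped:
        logger.warning("presence table %s: %d variant(s) present in zero studies: %s",
                       path, len(dropped), dropped[:10])
    return study_ids, n_u, presence, dropped


def write_presence(path, study_ids: Sequence[str], n_u: np.ndarray, presence: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("#n_u\t" + "\t".join(f"{x:g}" for x in np.asarray(n_u)) + "\n")
        fh.write("\t".join(study_ids) + "\n")
        np.savetxt(fh, np.asarray(presence, dtype=int).T, fmt="%d", delimiter="\t")


def check_n_consistency(panel_n: np.ndarray, presence: np.ndarray, n_u: np.ndarray,
                        strict: bool = False) -> np.ndarray:
    """Compare a per-variant n column against presence-derived totals.

    The presence table is the structural input the likelihood needs, so on
    disagreement it wins and a warning is logged (``strict=True`` raises
    instead).  Returns the indices that disagree.
    """
    derived = presence.T @ np.asarray(n_u, dtype=float)
    mismatch = np.flatnonzero(~np.isclose(np.asarray(panel_n, dtype=float), derived, rtol=1e-6))
    if mismatch.size:
        msg = (f"per-variant n disagrees with presence-derived totals at "
               f"{mismatch.size} variant(s), e.g. row {int(mismatch[0])}; presence table wins")
        if strict:
            raise ValidationError(msg)
        logger.warning(msg)
    return mismatch


# ---------------------------------------------------------------------------
# result writers
# ---------------------------------------------------------------------------

def _write_header(fh, meta: dict | None) -> None:
    if meta:
        for key, value in meta.items():
            fh.write(f"# {key}={value}\n")


def write_snp(path, panel: VariantPanel, pip: np.ndarray, meta: dict | None = None) -> None:
    """Write the per-variant PIP table (``.snp``), ranked by decreasing PIP."""
    order = np.argsort(-np.asarray(pip))
    rank = np.empty(len(order), dtype=int)
    rank[order] = np.arange(1, len(order) + 1)
    with open(path, "w") as fh:
        _write_header(fh, meta)
        fh.write("rsid chromosome position pip rank\n")
        for j in range(panel.p):
            fh.write(f"{panel.variant_id[j]} {panel.chromosome[j]} {panel.position[j]} "
                     f"{pip[j]:.10g} {rank[j]}\n")


def write_config(path, panel: VariantPanel, configs, meta: dict | None = None, top: int = 50) -> None:
    """Write the ``.config`` table of top causal configurations.

    ``configs`` maps index tuples to (log_bf, log_prior, log_post_unnorm);
    posterior probabilities are normalized over the evaluated set.
    """
    from scipy.special import logsumexp

    items = sorted(configs.items(), key=lambda kv: -kv[1][2])
    log_norm = logsumexp([v[2] for v in configs.values()])
    with open(path, "w") as fh:
        _write_header(fh, meta)
        fh.write("rank config k log10bf posterior\n")
        for rank, (cfg, (lbf, _lp, lpost)) in enumerate(items[:top], start=1):
            name = ",".join(str(panel.variant_id[j]) for j in cfg) if cfg else "NULL"
            fh.write(f"{rank} {name} {len(cfg)} {lbf / np.log(10):.6g} "
                     f"{np.exp(lpost - log_norm):.6g}\n")


def write_cred(path, panel: VariantPanel, credible_sets, meta: dict | None = None) -> None:
    """Write credible sets (``.cred``), one block per set."""
    with open(path, "w") as fh:
        _write_header(fh, meta)
        for i, cs in enumerate(credible_sets, start=1):
            fh.write(f"## credible_set {i} theta={cs.theta:g} "
                     f"anchor={panel.variant_id[cs.anchor_variant]} size={len(cs.members)}\n")
            fh.write("rsid prob\n")
            for j, b in zip(cs.members, cs.member_probs):
                fh.write(f"{panel.variant_id[j]} {b:.10g}\n")
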