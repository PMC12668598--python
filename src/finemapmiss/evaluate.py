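"""Fine-mapping quality metrics over replicate simulations.

Given many replicates with known causal variants, fine-mapping output is
judged by:

* **PIP-bin calibration** — variants are pooled across replicates and
  stratified by estimated PIP; in each bin the observed fraction of truly
  causal variants should agree with the mean PIP.  Wilson score intervals
  quantify the binomial uncertainty of the observed fraction.
* **Credible-set power** — how often the reported credible sets contain a
  causal variant.
* **C-PIP / MNC-PIP** — the PIP assigned to the causal variants versus the
  largest PIP wasted on a non-causal variant.
* **False-positive threshold curves** — the fraction of replicates whose
  results contain a non-causal variant above a PIP threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ReplicateResult",
    "DEFAULT_PIP_BINS",
    "pip_bin_calibration",
    "cs_power",
    "cpip_mncpip",
    "fp_threshold_curve",
    "plot_calibration",
    "plot_fp_curve",
]

DEFAULT_PIP_BINS = (0.0, 0.01, 0.1, 0.25, 0.5, 0.75, 0.9, 1.0)


@dataclass
class ReplicateResult:
    """One replicate's fine-mapping output aligned with its ground truth."""

    pip: np.ndarray
    causal_set: np.ndarray
    credible_sets: list = field(default_factory=list)
    penc: float = np.nan
    method_label: str = ""

    def __post_init__(self):
        self.pip = np.asarray(self.pip, dtype=float)
        self.causal_set = np.asarray(self.causal_set, dtype=int)
        if self.pip.size and (self.pip.min() < -1e-12 or self.pip.max() > 1 + 1e-12):
            raise ValueError("PIPs must lie in [0, 1]")

    @property
    def causal_mask(self) -> np.ndarray:
        mask = np.zeros(self.pip.size, dtype=bool)
        mask[self.causal_set] = True
        return mask


def pip_bin_calibration(replicates: list[ReplicateResult],
                        bin_edges=DEFAULT_PIP_BINS,
                        ci_level: float = 0.95) -> pd.DataFrame:
    """Calibration table of observed causal fraction per PIP bin.

    Bins are left-open, right-closed except the first, which includes 0.
    Each row reports the bin's mean PIP, the observed fraction of truly
    causal variants with its Wilson ``ci_level`` interval, and a
    ``calibrated`` flag (CI overlaps the mean PIP).  Empty bins are emitted
    with ``n_variants=0`` and no interval.
    """
    if not (0.0 < ci_level < 1.0):
        raise ValueError("ci_level must lie in (0, 1)")
    edges = np.asarray(bin_edges, dtype=float)
    pips = np.concatenate([r.pip for r in replicates])
    causal = np.concatenate([r.causal_mask for r in replicates])
    which = np.clip(np.searchsorted(edges, pips, side="left") - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        sel = which == b
        n = int(sel.sum())
        if n == 0:
            rows.append({"bin_low": edges[b], "bin_high": edges[b + 1],
                         "mean_pip": np.nan, "observed_fraction": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan,
                         "n_variants": 0, "n_causal": 0, "calibrated": np.nan})
            continue
        successes = int(causal[sel].sum())
        lo, hi = proportion_confint(successes, n, alpha=1 - ci_level, method="wilson")
        mean_pip = float(pips[sel].mean())
        rows.append({"bin_low": edges[b], "bin_high": edges[b + 1],
                     "mean_pip": mean_pip, "observed_fraction": successes / n,
                     "ci_low": float(lo), "ci_high": float(hi),
                     "n_variants": n, "n_causal": successes,
                     "calibrated": bool(lo <= mean_pip <= hi)})
    return pd.DataFrame(rows)


def cs_power(replicates: list[ReplicateResult], mode: str = "any_causal") -> float:
    """Fraction of replicates (or signals) whose credible sets hit a causal variant.

    ``any_causal``: a replicate counts if any of its credible sets contains
    any causal variant.  ``per_signal``: the unit is (replicate x causal
    variant), counted when that variant appears in some credible set.
    """
    if mode == "any_causal":
        hits = [any(set(cs.members) & set(r.causal_set.tolist())
                    for cs in r.credible_sets)
                for r in replicates]
        return float(np.mean(hits)) if hits else 0.0
    if mode == "per_signal":
        total, hit = 0, 0
        for r in replicates:
            covered = set().union(*(set(cs.members) for cs in r.credible_sets)) \
                if r.credible_sets else set()
            for j in r.causal_set:
                total += 1
                hit += int(j in covered)
        return hit / total if total else 0.0
    raise ValueError(f"unknown mode {mode!r}")


def cpip_mncpip(replicates: list[ReplicateResult]) -> tuple[float, float]:
    """(mean C-PIP, mean MNC-PIP) across replicates.

    C-PIP is the mean PIP of the causal variants within a replicate;
    MNC-PIP is the largest PIP among the non-causal ones.
    """
    cpips, mncs = [], []
    for r in replicates:
        mask = r.causal_mask
        cpips.append(float(r.pip[mask].mean()))
        mncs.append(float(r.pip[~mask].max()) if (~mask).any() else 0.0)
    return float(np.mean(cpips)), float(np.mean(mncs))


def fp_threshold_curve(replicates: list[ReplicateResult], thresholds) -> pd.DataFrame:
    """Per-threshold fraction of replicates with a non-causal PIP above it."""
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(thresholds) < 0):
        raise ValueError("thresholds must be sorted ascending")
    max_nc = np.array([r.pip[~r.causal_mask].max() if (~r.causal_mask).any() else 0.0
                       for r in replicates])
    frac = [(max_nc > t).mean() for t in thresholds]
    return pd.DataFrame({"threshold": thresholds, "fraction": frac})


def plot_calibration(table: pd.DataFrame, ax=None, label: str = ""):
    """PIP-bin calibration plot: observed fraction with Wilson bars vs mean PIP."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    sub = table[table["n_variants"] > 0]
    x = sub["mean_pip"]
    ax.errorbar(x, sub["observed_fraction"],
                yerr=[sub["observed_fraction"] - sub["ci_low"],
                      sub["ci_high"] - sub["observed_fraction"]],
                fmt="o", capsize=3, label=label or None)
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=1)
    ax.set_xlabel("mean PIP in bin")
    ax.set_ylabel("observed causal fraction")
    if label:
        ax.legend()
    return ax


def plot_fp_curve(curve: pd.DataFrame, ax=None, label: str = ""):
    """Fraction of replicates with a non-causal PIP above each threshold."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.plot(curve["threshold"], curve["fraction"], marker="o", label=label or None)
    ax.set_xlabel("PIP threshold")
    ax.set_ylabel("fraction with non-causal PIP above")
    ax.set_ylim(-0.02, 1.02)
    if label:
        ax.legend()
    return ax
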