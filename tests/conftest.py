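import numpy as np
import pytest

from finemapmiss.evaluate import ReplicateResult
from finemapmiss.io import LDMatrix, StudyGWAS, VariantPanel
from finemapmiss.posterior import fine_map_meta
from finemapmiss.simulate import SimConfig, make_meta_dataset

# Conditions of the scaled-down replicate study: a two-cohort quantitative
# trait meta-analysis, one causal variant at 0.1% of phenotypic variance,
# 20% of variants with missing data, the causal variant present in a single
# cohort, block-AR LD, high imputation quality.
STUDY_KW = dict(p=200, n_per_cohort=100_000, d=2, n_causal=1,
                h2_per_variant=0.001, missing_frac=0.20,
                causal_missing_rule="all_but_one", info_range=(0.9, 1.0))
N_REPLICATES = 200
STUDY_SEED = 20_240_101


def make_panel(p, maf=0.3):
    maf = np.full(p, maf) if np.isscalar(maf) else np.asarray(maf)
    return VariantPanel(
        variant_id=np.array([f"rs{j}" for j in range(p)], dtype=object),
        chromosome=np.array(["1"] * p, dtype=object),
        position=np.arange(1, p + 1) * 100,
        allele1=np.array(["A"] * p, dtype=object),
        allele2=np.array(["C"] * p, dtype=object),
        maf=maf,
    )


def random_ld(p, rng, strength=3):
    """A well-conditioned random correlation matrix."""
    a = rng.normal(size=(p, strength * p))
    return LDMatrix(np.corrcoef(a))


def make_study(study_id, n, beta, se, present=None, info=None):
    beta = np.asarray(beta, dtype=float)
    present = np.ones(beta.size, dtype=bool) if present is None else np.asarray(present)
    return StudyGWAS(study_id=study_id, n=n, present=present,
                     beta_hat=np.where(present, beta, np.nan),
                     se=np.where(present, np.asarray(se, dtype=float), np.nan),
                     info=info)


@pytest.fixture(scope="session")
def replicate_study():
    """Fine-map N_REPLICATES simulated meta-analyses with both likelihoods.

    Returns {"miss": [ReplicateResult...], "classic": [...]}; shared by the
    calibration and credible-set-power checks (the expensive part of the
    suite, ~10 minutes).
    """
    seeds = np.random.SeedSequence(STUDY_SEED).generate_state(N_REPLICATES)
    out = {"miss": [], "classic": []}
    for i in range(N_REPLICATES):
        seed = int(seeds[i] % (2 ** 31))
        data = make_meta_dataset(SimConfig(seed=seed, **STUDY_KW))
        for method in ("miss", "classic"):
            s = fine_map_meta(data.meta, data.ld, method=method, seed=seed)
            out[method].append(ReplicateResult(
                pip=s.pip, causal_set=data.truth.causal_set,
                credible_sets=s.credible_sets, penc=s.penc, method_label=method))
    return out
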