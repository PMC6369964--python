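"""Desk-scale validation experiments with frozen study conditions.

Each function here runs a replicated simulation experiment at sizes chosen to
finish on a single CPU in minutes while leaving the quantity under study
resolvable above Monte-Carlo noise: constant populations of tens-to-hundreds
of diploids with a 10N-generation burn-in, scaled mutation rates giving
θ = 4Nu in the tens, and effect sizes of a few tenths of a trait SD.  The
same conditions back both the test suite and the reproduction script, so the
numbers they report come from one place.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .sbeta import bin_mean_beta
from .simulate import DemographicModel, TraitModelParams, run_forward_simulation

__all__ = [
    "neutral_binned_mean_experiment",
    "neutral_sfs_experiment",
    "ensemble_beta_daf",
    "STABILIZING_PARAMS",
    "SHIFT_PARAMS",
    "STABILIZING_DEMOG",
]

# stabilizing-selection study conditions: mutational bias toward
# trait-decreasing alleles, a wide fitness function (weak per-allele
# selection, the polygenic regime where the bias composition dominates the
# high-frequency bins), and enough polygenicity that every frequency decile
# is populated across replicates
STABILIZING_PARAMS = TraitModelParams(
    delta=0.4, fitness_width=2.0, mutation_rate=0.3, effect_scale=0.2)
#: same trait, plus a recent +2 SD optimum shift
SHIFT_PARAMS = TraitModelParams(
    delta=0.4, dphi=2.0, ts=100, fitness_width=2.0,
    mutation_rate=0.3, effect_scale=0.2)
STABILIZING_DEMOG = DemographicModel.constant(150, 150)


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2 ** 31, size=n)


def neutral_binned_mean_experiment(
    n_replicates: int = 100,
    pop_size: int = 50,
    generations: int = 200,
    mutation_rate: float = 0.2,
    effect_scale: float = 0.3,
    seed: int = 0,
) -> dict:
    """Replicated neutral runs with unbiased mutation (δ = 0.5, no selection).

    For each replicate, variants are grouped into 1% DAF bins; the replicate
    statistic is the average of β̄ over non-empty bins.  Returns the grand
    mean across replicates, its Monte-Carlo standard error, and the per-
    replicate values.  Under neutrality without bias the expectation is
    β̄ = 0 in every bin, hence a grand mean of zero.
    """
    params = TraitModelParams(delta=0.5, fitness_width=None,
                              mutation_rate=mutation_rate,
                              effect_scale=effect_scale)
    demog = DemographicModel.constant(pop_size, generations)
    seeds = _spawn_seeds(seed, n_replicates)
    per_rep = []
    for s in seeds:
        out = run_forward_simulation(params, demog, seed=int(s))
        if out.n_segregating == 0:
            continue
        profile = bin_mean_beta((out.true_beta, out.daf), yw=0.01)
        filled = ~profile.empty_mask
        per_rep.append(float(profile.bin_means[filled].mean()))
    per_rep = np.asarray(per_rep)
    return {
        "grand_mean": float(per_rep.mean()),
        "mc_se": float(per_rep.std(ddof=1) / np.sqrt(per_rep.size)),
        "per_replicate": per_rep,
        "n_replicates": int(per_rep.size),
    }


def neutral_sfs_experiment(
    n_replicates: int = 100,
    pop_size: int = 50,
    generations: int = 100,
    mutation_rate: float = 0.2,
    n_sample: int = 20,
    seed: int = 12345,
) -> dict:
    """Constant-N neutral runs against the closed-form SFS expectation.

    In a sample of n haplotypes from a constant-size neutral population at
    mutation-drift equilibrium, the expected number of sites with derived
    count i is θ/i (θ = 4Nu).  Each replicate's population counts are
    down-sampled hypergeometrically to ``n_sample`` haplotypes.  Returns the
    per-count replicate means, Monte-Carlo standard errors, expectations,
    and z-scores.
    """
    params = TraitModelParams(delta=0.5, fitness_width=None,
                              mutation_rate=mutation_rate)
    demog = DemographicModel.constant(pop_size, generations)
    theta = 4.0 * pop_size * mutation_rate
    rng = np.random.default_rng(seed)
    sfs = np.zeros((n_replicates, n_sample - 1))
    for r in range(n_replicates):
        out = run_forward_simulation(params, demog,
                                     seed=int(rng.integers(2 ** 31)))
        counts = np.round(out.daf * out.n_haplotypes).astype(int)
        sub = rng.hypergeometric(counts, out.n_haplotypes - counts, n_sample)
        for i in range(1, n_sample):
            sfs[r, i - 1] = np.count_nonzero(sub == i)
    mean = sfs.mean(axis=0)
    se = sfs.std(axis=0, ddof=1) / np.sqrt(n_replicates)
    expected = theta / np.arange(1, n_sample)
    return {
        "mean": mean,
        "mc_se": se,
        "expected": expected,
        "z": (mean - expected) / se,
        "theta": theta,
    }


def ensemble_beta_daf(
    params: TraitModelParams,
    demog: Optional[DemographicModel] = None,
    n_replicates: int = 50,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pool (beta, daf) over replicate runs; the substrate of ensemble βDAF plots."""
    demog = demog or STABILIZING_DEMOG
    seeds = _spawn_seeds(seed, n_replicates)
    betas, dafs = [], []
    for s in seeds:
        out = run_forward_simulation(params, demog, seed=int(s))
        betas.append(out.true_beta)
        dafs.append(out.daf)
    return np.concatenate(betas), np.concatenate(dafs)
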