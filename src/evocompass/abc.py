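"""Rejection-sampling (ABC) inference of mutational bias and optimum shifts.

The observed data are reduced to a normalized cumulative summary: Sβ(0.01, x)
scaled by Sβ(0.01, 0.99) on a grid of frequencies x, computed after dropping
variants with DAF < 0.01 (rare variants are the most exposed to
stratification and ancestral-state error).  Parameters (δ, Δφ, shift time,
heritability, mutation target, effect scale) are drawn from independent
priors; each draw is pushed through the forward simulator with a
deterministic child seed and summarized the same way; the draws whose
summaries are closest to the observed summary (Euclidean distance after
per-coordinate scaling; see :class:`InferenceConfig`) are kept as the
approximate posterior.

The method is a noisy estimator of the magnitudes of δ and Δφ but is
informative about their directions, which is what the sign-power diagnostic
measures.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .sbeta import (
    DegenerateNormalizerError,
    as_beta_daf,
    bin_mean_beta,
    normalized_sbeta_vector,
)
from .simulate import DemographicModel, TraitModelParams, run_forward_simulation

logger = logging.getLogger(__name__)

__all__ = [
    "Uniform",
    "PriorSpec",
    "InferenceConfig",
    "PosteriorSample",
    "observed_summary",
    "summary_distance",
    "rejection_sample",
    "sign_power",
    "posterior_predictive",
]

DEFAULT_GRID = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.99)


@dataclass(frozen=True)
class Uniform:
    """Uniform(lo, hi) prior; with ``log=True`` uniform on log10 scale."""

    lo: float
    hi: float
    log: bool = False

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError(f"empty prior support ({self.lo}, {self.hi})")

    def sample(self, rng: np.random.Generator) -> float:
        if self.log:
            return float(10.0 ** rng.uniform(math.log10(self.lo),
                                             math.log10(self.hi)))
        return float(rng.uniform(self.lo, self.hi))


@dataclass(frozen=True)
class PriorSpec:
    """Independent priors over the inferred trait-model parameters.

    ``ts`` is in generations before the present and should sit inside the
    simulated span of the inference configuration's demography.
    """

    delta: Uniform = Uniform(0.1, 0.9)
    dphi: Uniform = Uniform(-2.0, 2.0)
    ts: Uniform = Uniform(10.0, 100.0)
    h2: Uniform = Uniform(0.2, 0.9)
    mutation_rate: Uniform = Uniform(0.1, 0.5, log=True)
    effect_scale: Uniform = Uniform(0.1, 1.0, log=True)

    def sample(self, rng: np.random.Generator) -> dict[str, float]:
        draw = {name: getattr(self, name).sample(rng) for name in self.names()}
        draw["ts"] = float(int(round(draw["ts"])))
        return draw

    @staticmethod
    def names() -> tuple[str, ...]:
        return ("delta", "dphi", "ts", "h2", "mutation_rate", "effect_scale")


@dataclass(frozen=True)
class InferenceConfig:
    """Fixed (non-inferred) pieces of the simulation used inside ABC."""

    demog: DemographicModel = field(
        default_factory=lambda: DemographicModel.constant(40, 160))
    base_params: TraitModelParams = field(
        default_factory=lambda: TraitModelParams(fitness_width=1.0))
    grid: tuple[float, ...] = DEFAULT_GRID
    yw: float = 0.01
    min_daf: float = 0.01
    signed_summary: bool = True  # preserve curve sign; see normalized_sbeta_vector
    # winsorization bound for summary elements: when an optimum shift nearly
    # cancels S_beta(0.01, 0.99), normalized curves explode and would dominate
    # Euclidean distances with pure noise; the blow-up itself (not its exact
    # magnitude) is the informative signature, so elements are clipped here
    summary_clip: Optional[float] = 5.0
    # scale each summary coordinate by its median absolute deviation across
    # the simulated pool before computing distances, so high-variance
    # low-frequency coordinates do not drown the rest
    standardize_distance: bool = True


def observed_summary(variants, grid: Sequence[float] = DEFAULT_GRID,
                     yw: float = 0.01, min_daf: float = 0.01,
                     signed: bool = True) -> np.ndarray:
    """Normalized Sβ summary of a variant set, after removing DAF < min_daf.

    Equivalent to composing the low-frequency filter, βDAF binning, and
    cumulative normalization; raises if no variant survives the filter or the
    normalizer is degenerate.  ``signed=True`` scales by the magnitude of
    the normalizer so the curve keeps its overall sign (required for
    direction inference; see :func:`evocompass.sbeta.normalized_sbeta_vector`).
    """
    beta, daf = as_beta_daf(variants)
    keep = daf >= min_daf
    if not np.any(keep):
        raise ValueError(f"no variants with DAF >= {min_daf}")
    profile = bin_mean_beta((beta[keep], daf[keep]), yw=yw)
    return normalized_sbeta_vector(profile, grid, signed=signed)


def summary_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Euclidean distance between two summary vectors of equal length."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"summary length mismatch: {u.shape} vs {v.shape}")
    return float(np.linalg.norm(u - v))


@dataclass
class PosteriorSample:
    """One prior draw with its simulation distance and acceptance flag."""

    params: dict[str, float]
    distance: float
    accepted: bool
    seed: int


def _child_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic per-draw simulation seeds below 2**31."""
    return np.random.default_rng(master_seed).integers(0, 2 ** 31, size=n)


def _simulate_summary(draw: dict[str, float], config: InferenceConfig,
                      seed: int) -> Optional[np.ndarray]:
    """Run one forward simulation at a parameter draw and summarize it.

    Returns None when the run yields no usable summary (no variants above the
    frequency floor, or a degenerate normalizer).
    """
    params = replace(
        config.base_params,
        delta=draw["delta"],
        dphi=draw["dphi"],
        ts=int(draw["ts"]) if draw["dphi"] != 0.0 else None,
        h2=draw["h2"],
        mutation_rate=draw["mutation_rate"],
        effect_scale=draw["effect_scale"],
    )
    out = run_forward_simulation(params, config.demog, seed=seed)
    if out.n_segregating == 0:
        return None
    try:
        vec = observed_summary(
            (out.betas_for_analysis(), out.daf),
            grid=config.grid, yw=config.yw, min_daf=config.min_daf,
            signed=config.signed_summary,
        )
    except (ValueError, DegenerateNormalizerError):
        return None
    if config.summary_clip is not None:
        vec = np.clip(vec, -config.summary_clip, config.summary_clip)
    return vec


def rejection_sample(
    obs_vec: np.ndarray,
    prior: PriorSpec,
    n_sims: int,
    accept_fraction: float,
    config: InferenceConfig,
    master_seed: int,
) -> list[PosteriorSample]:
    """Draw from the prior, simulate, and accept the closest fraction.

    Child seeds are a deterministic function of ``master_seed`` and the draw
    index, so a rerun reproduces the accepted set exactly.  Draws whose
    simulation produced no usable summary get infinite distance and are never
    accepted (their count is logged).
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if not 0.0 < accept_fraction <= 1.0:
        raise ValueError("accept_fraction must lie in (0, 1]")
    obs_vec = np.asarray(obs_vec, dtype=float)
    if config.summary_clip is not None:
        obs_vec = np.clip(obs_vec, -config.summary_clip, config.summary_clip)
    prior_rng = np.random.default_rng(master_seed)
    seeds = _child_seeds(master_seed + 1, n_sims)
    samples: list[PosteriorSample] = []
    vectors: list[Optional[np.ndarray]] = []
    n_degenerate = 0
    for i in range(n_sims):
        draw = prior.sample(prior_rng)
        vec = _simulate_summary(draw, config, int(seeds[i]))
        if vec is None:
            n_degenerate += 1
        vectors.append(vec)
        samples.append(PosteriorSample(draw, math.inf, False, int(seeds[i])))
    if config.standardize_distance:
        pool = np.vstack([v for v in vectors if v is not None]) \
            if n_degenerate < n_sims else np.zeros((0, obs_vec.size))
        mad = np.median(np.abs(pool - np.median(pool, axis=0)), axis=0) \
            if pool.size else np.ones(obs_vec.size)
        scale = np.where(mad > 0, mad, 1.0)
    else:
        scale = np.ones(obs_vec.size)
    for s, vec in zip(samples, vectors):
        if vec is not None:
            s.distance = summary_distance(obs_vec / scale, vec / scale)
    if n_degenerate:
        logger.info("%d/%d draws had degenerate summaries", n_degenerate, n_sims)
    n_finite = n_sims - n_degenerate
    if n_finite == 0:
        raise RuntimeError("every prior draw produced a degenerate summary")
    # degenerate (infinite-distance) draws are never accepted
    n_accept = min(max(1, int(round(accept_fraction * n_sims))), n_finite)
    order = np.argsort([s.distance for s in samples], kind="stable")
    for idx in order[:n_accept]:
        samples[idx].accepted = True
    return samples


def _posterior_median(samples: list[PosteriorSample], name: str) -> float:
    vals = [s.params[name] for s in samples if s.accepted]
    return float(np.median(vals))


def sign_power(
    true_params: dict[str, float],
    n_replicates: int,
    prior: PriorSpec,
    config: InferenceConfig,
    n_sims: int = 500,
    accept_fraction: float = 0.05,
    master_seed: int = 0,
) -> tuple[float, float]:
    """Fraction of replicate inferences recovering the signs of δ−0.5 and Δφ.

    Each replicate simulates fresh observed data at the true parameters, runs
    the full rejection sampler, and scores whether the posterior medians of
    δ − 0.5 and Δφ share the true signs.  A true parameter exactly at the
    boundary (δ = 0.5 or Δφ = 0) makes the corresponding sign a coin flip.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    hits_delta = hits_dphi = 0
    obs_seeds = _child_seeds(master_seed + 104729, n_replicates)
    for r in range(n_replicates):
        vec = _simulate_summary(dict(true_params), config, int(obs_seeds[r]))
        if vec is None:
            continue  # unusable observed replicate counts as a miss
        samples = rejection_sample(vec, prior, n_sims, accept_fraction,
                                   config, master_seed=master_seed + 13 * r + 1)
        med_delta = _posterior_median(samples, "delta") - 0.5
        med_dphi = _posterior_median(samples, "dphi")
        if np.sign(med_delta) == np.sign(true_params["delta"] - 0.5):
            hits_delta += 1
        if np.sign(med_dphi) == np.sign(true_params["dphi"]):
            hits_dphi += 1
    return hits_delta / n_replicates, hits_dphi / n_replicates


def posterior_predictive(
    accepted: list[PosteriorSample],
    n_draws: int,
    config: InferenceConfig,
    seed: int = 0,
    quantiles: tuple[float, float, float] = (0.25, 0.5, 0.75),
) -> dict[str, np.ndarray]:
    """Out-of-sample envelope of simulated summaries under accepted parameters.

    Resamples accepted parameter draws with replacement, re-simulates each with
    a fresh seed, and returns per-grid-point quantiles of the resulting
    normalized Sβ curves (keys "q25", "q50", "q75" for the defaults, plus
    "grid" and "n_used").
    """
    acc = [s for s in accepted if s.accepted]
    if not acc:
        raise ValueError("no accepted samples to resample from")
    rng = np.random.default_rng(seed)
    sim_seeds = _child_seeds(seed + 7919, n_draws)
    picks = rng.integers(0, len(acc), size=n_draws)
    curves = []
    for i in range(n_draws):
        vec = _simulate_summary(dict(acc[picks[i]].params), config,
                                int(sim_seeds[i]))
        if vec is not None:
            curves.append(vec)
    if not curves:
        raise ValueError("all posterior-predictive simulations were degenerate")
    mat = np.vstack(curves)
    out = {"grid": np.asarray(config.grid, dtype=float),
           "n_used": np.array(len(curves))}
    for q in quantiles:
        out[f"q{int(round(q * 100))}"] = np.quantile(mat, q, axis=0)
    return out
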