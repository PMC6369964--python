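"""Forward-time Wright-Fisher simulation of a polygenic trait.

The model: a diploid population of size N(t) carries trait-altering mutations
at unlinked (freely recombining) sites.  Each mutation has an additive effect
β on the trait; new mutations arise at rate ``mutation_rate`` per gamete per
generation, with |β| drawn from a configurable distribution and sign positive
with probability δ (the mutational bias; δ = 0.5 is unbiased).  An
individual's genetic value is the sum of its allelic effects plus the fixed
background; its phenotype adds Gaussian environmental noise whose variance is
set each generation so the heritability stays at h².  Fitness is a Gaussian
function of the phenotype centered on the optimum φo with width w; parents
are sampled proportionally to fitness.  At a configurable time before the
present the optimum may shift by Δφ, expressed in standard deviations of the
phenotype distribution just before the shift — either instantaneously or as
a linear ramp.

Setting ``fitness_width=None`` disables selection entirely (neutral drift),
in which case the constant-N site frequency spectrum has the classical
expectation θ/i derived counts with θ = 4Nu, which serves as the simulator's
correctness oracle.

An alternative mode couples effects to fitness the other way around
(Eyre-Walker): each mutation first draws a deleterious selection coefficient
s and its trait effect is a noisy monotone function of s, with selection
acting directly through s rather than through the trait.

Population sizes, times, and mutation rates are intended to be used rescaled
(a scaling factor Q shrinks N and times while keeping θ and relative drift
fixed); a rescaled Gravel-style European history (expansion, out-of-Africa
bottleneck, European founding with growth) is provided as a preset.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Epoch",
    "DemographicModel",
    "TraitModelParams",
    "GWASNoiseParams",
    "SimulationOutput",
    "draw_effect",
    "gaussian_fitness",
    "run_forward_simulation",
    "eyre_walker_mode",
    "add_estimation_noise",
    "apply_misorientation",
]


@dataclass(frozen=True)
class Epoch:
    """A span of ``duration`` generations starting at ``size`` diploids.

    With ``growth_rate`` r ≠ 0 the size grows exponentially within the epoch:
    N(t) = size · exp(r·t) for t generations into the epoch.
    """

    duration: int
    size: int
    growth_rate: float = 0.0


@dataclass(frozen=True)
class DemographicModel:
    """Contiguous epochs preceded by a burn-in at the first epoch's size."""

    epochs: tuple[Epoch, ...]
    burn_in: Optional[int] = None  # None -> 10 * first epoch size

    def __post_init__(self):
        if not self.epochs:
            raise ValueError("at least one epoch is required")

    @classmethod
    def constant(cls, size: int, generations: int = 0,
                 burn_in: Optional[int] = None) -> "DemographicModel":
        return cls((Epoch(generations, size),), burn_in=burn_in)

    @classmethod
    def gravel_european(cls, Q: float = 100.0) -> "DemographicModel":
        """Rescaled Gravel-style European history.

        Unscaled: ancestral size 7310 expanding to 14474 at 5920 generations
        ago, out-of-Africa bottleneck to 1861 at 2040 generations ago, and a
        European founding bottleneck to 1032 at 920 generations ago followed
        by 0.38%/generation exponential growth.  Scaling by Q divides sizes
        and durations by Q and multiplies growth rates by Q, preserving the
        products N·t and N·r that control drift.
        """
        def n(x):
            return max(2, int(round(x / Q)))

        def g(x):
            return max(1, int(round(x / Q)))

        return cls((
            Epoch(g(5920 - 2040), n(14474)),
            Epoch(g(2040 - 920), n(1861)),
            Epoch(g(920), n(1032), growth_rate=0.0038 * Q),
        ), burn_in=None if Q <= 1 else 10 * n(7310))

    def sizes(self) -> np.ndarray:
        """Diploid size for every simulated generation, burn-in included."""
        n0 = self.epochs[0].size
        burn = 10 * n0 if self.burn_in is None else self.burn_in
        out = [n0] * burn
        for ep in self.epochs:
            if ep.growth_rate == 0.0:
                out.extend([ep.size] * ep.duration)
            else:
                t = np.arange(ep.duration)
                out.extend(
                    np.maximum(2, np.round(ep.size * np.exp(ep.growth_rate * t)))
                    .astype(int).tolist()
                )
        sizes = np.asarray(out, dtype=int)
        if np.any(sizes < 2):
            raise ValueError("all scaled population sizes must be >= 2")
        return sizes


@dataclass(frozen=True)
class TraitModelParams:
    """Everything the trait simulator needs.

    delta
        Proportion of trait-altering de novo mutations that increase the
        trait; 0.5 means no mutational bias.
    dphi
        Optimum shift, in SDs of the phenotype distribution at the shift
        time (0 = no shift).
    ts
        Time of the shift in generations *before the present*; None disables
        the shift.
    shift_duration
        0 for an instantaneous shift, otherwise the optimum ramps linearly
        over this many generations.
    fitness_width
        SD ``w`` of the Gaussian fitness function, in trait units; None
        disables selection (neutral drift).
    mutation_rate
        Expected trait-altering mutations per gamete per generation, so the
        population-scaled rate is θ = 4·N·mutation_rate.
    effect_dist / effect_scale
        Distribution family of |β| ("exponential" or "constant") and its
        scale, in trait units.
    h2
        Narrow-sense heritability; environmental variance is recomputed each
        generation as V_E = V_G (1 − h²)/h² so h² stays fixed.
    """

    delta: float = 0.5
    dphi: float = 0.0
    ts: Optional[int] = None
    shift_duration: int = 0
    fitness_width: Optional[float] = 1.0
    mutation_rate: float = 0.1
    effect_dist: str = "exponential"
    effect_scale: float = 0.3
    h2: float = 0.5
    phi_o: float = 0.0
    ve_floor: float = 1e-8
    mode: str = "stabilizing"       # or "eyre_walker"
    ew_tau: float = 0.5
    ew_noise_sd: float = 0.0
    ew_s_mean: float = 0.05
    ew_s_shape: float = 0.5

    def __post_init__(self):
        if not 0.0 < self.delta < 1.0:
            raise ValueError("delta must lie in (0, 1)")
        if self.fitness_width is not None and self.fitness_width <= 0:
            raise ValueError("fitness_width must be positive")
        if not 0.0 < self.h2 <= 1.0:
            raise ValueError("h2 must lie in (0, 1]")
        if self.mode not in ("stabilizing", "eyre_walker"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "eyre_walker" and self.ew_tau < 0:
            raise ValueError("ew_tau must be >= 0")


@dataclass(frozen=True)
class GWASNoiseParams:
    """Finite-sample GWAS estimation noise: var(β̂ − β) = σ²/(2·n·x(1−x))."""

    n_gwas: int
    residual_var: float = 1.0

    def __post_init__(self):
        if self.n_gwas < 1:
            raise ValueError("n_gwas must be >= 1")


@dataclass
class SimulationOutput:
    """Segregating variants at the end of a run, plus run-level summaries."""

    true_beta: np.ndarray
    daf: np.ndarray
    origin_generation: np.ndarray
    n_haplotypes: int
    fixed_count: int
    lost_count: int
    phi_trajectory: np.ndarray      # (generation, mean phenotype) rows
    v_g: float
    v_p: float
    beta_hat: Optional[np.ndarray] = None
    seed: Optional[int] = None

    @property
    def n_segregating(self) -> int:
        return int(self.true_beta.size)

    def betas_for_analysis(self) -> np.ndarray:
        """GWAS-style estimates when present, otherwise the true effects."""
        return self.true_beta if self.beta_hat is None else self.beta_hat

    def to_dataframe(self):
        import pandas as pd
        df = pd.DataFrame({
            "true_beta": self.true_beta,
            "daf": self.daf,
            "origin_generation": self.origin_generation,
        })
        if self.beta_hat is not None:
            df["beta_hat"] = self.beta_hat
        return df


def draw_effect(params: TraitModelParams, rng: np.random.Generator,
                size: int = 1) -> np.ndarray:
    """Draw ``size`` signed effect sizes: |β| from the effect distribution,
    sign positive with probability δ."""
    if params.effect_dist == "exponential":
        mag = rng.exponential(params.effect_scale, size=size)
    elif params.effect_dist == "constant":
        mag = np.full(size, params.effect_scale)
    else:
        raise ValueError(f"unknown effect distribution {params.effect_dist!r}")
    sign = np.where(rng.random(size) < params.delta, 1.0, -1.0)
    return sign * mag


def gaussian_fitness(phi, phi_o: float, w: float):
    """exp(−(φ − φo)² / (2w²)): symmetric, maximal (=1) at the optimum."""
    if w <= 0:
        raise ValueError("fitness width must be positive")
    phi = np.asarray(phi, dtype=float)
    out = np.exp(-((phi - phi_o) ** 2) / (2.0 * w * w))
    return float(out) if out.ndim == 0 else out


def eyre_walker_mode(params: TraitModelParams, tau: float,
                     noise_sd: float) -> TraitModelParams:
    """Return params switched to the selection-coefficient-coupled effect rule.

    Each mutation draws a deleterious coefficient s (gamma with mean
    ``ew_s_mean`` and shape ``ew_s_shape``); its trait effect is
    β = sign · |s|^tau · (1 + e) with e ~ Normal(0, noise_sd²), and selection
    acts multiplicatively through s (log-fitness −s per derived copy·½)
    rather than through the trait.
    """
    return replace(params, mode="eyre_walker", ew_tau=tau, ew_noise_sd=noise_sd)


def _draw_parents(rng: np.random.Generator, n_next: int, weights: Optional[np.ndarray],
                  n_current: int) -> np.ndarray:
    """2·n_next parent indices, fitness-weighted when weights are given."""
    if weights is None:
        return rng.integers(0, n_current, size=2 * n_next)
    total = weights.sum()
    if total <= 0.0 or not np.isfinite(total):
        logger.warning("all fitness weights vanished; falling back to uniform")
        return rng.integers(0, n_current, size=2 * n_next)
    cdf = np.cumsum(weights)
    return np.searchsorted(cdf, rng.random(2 * n_next) * cdf[-1], side="right")


def run_forward_simulation(
    params: TraitModelParams,
    demog: DemographicModel,
    seed: Optional[int] = None,
    log_interval: Optional[int] = None,
) -> SimulationOutput:
    """Individual-based diploid Wright-Fisher simulation.

    Each generation: phenotypes are formed from genetic values plus
    environmental noise, parents are sampled proportionally to Gaussian
    fitness (uniformly when selection is off), each offspring receives one
    gamete per parent with each unlinked site transmitted independently
    (Mendelian segregation = free recombination), and new mutations are
    placed on fresh sites in random offspring.  Fixed sites fold into a
    constant genetic background; lost sites are dropped.

    The returned variants are all sites still segregating at the end, with
    DAF measured on the whole population (2N chromosomes).
    """
    rng = np.random.default_rng(seed)
    sizes = demog.sizes()
    total_gens = len(sizes)
    neutral = params.fitness_width is None and params.mode == "stabilizing"
    ew = params.mode == "eyre_walker"

    shift_gen: Optional[int] = None
    if params.ts is not None and params.dphi != 0.0:
        shift_gen = total_gens - int(params.ts)
        if not 0 < shift_gen < total_gens:
            raise ValueError(
                f"shift time ts={params.ts} falls outside the simulated span "
                f"of {total_gens} generations"
            )

    n = int(sizes[0])
    geno = np.zeros((n, 0), dtype=np.uint8)
    beta = np.zeros(0)
    sel = np.zeros(0)        # Eyre-Walker selection coefficients
    origin = np.zeros(0, dtype=int)
    phi_fixed = 0.0
    phi_o = params.phi_o
    fixed_count = lost_count = 0
    traj: list[tuple[int, float]] = []
    ramp_left = 0
    ramp_step = 0.0
    prev_pheno_sd: Optional[float] = None
    v_g = v_p = 0.0
    warned_vg0 = False

    need_pheno = (not neutral and not ew) or shift_gen is not None or \
        log_interval is not None

    for t in range(total_gens):
        n = geno.shape[0]
        # --- phenotypes of the current generation ---
        if need_pheno:
            g = (geno @ beta if beta.size else np.zeros(n)) + phi_fixed
            v_g = float(np.var(g))
            if params.h2 < 1.0:
                v_e = v_g * (1.0 - params.h2) / params.h2
                if v_e <= 0.0:
                    # V_G = 0 at generation 0 (no sites yet) is normal startup
                    if not warned_vg0 and t > 0:
                        logger.warning(
                            "V_G = 0 with h2 < 1; using environmental floor %g",
                            params.ve_floor)
                        warned_vg0 = True
                    v_e = params.ve_floor
                pheno = g + rng.normal(0.0, math.sqrt(v_e), size=n)
            else:
                pheno = g
            v_p = float(np.var(pheno))
            if log_interval is not None and (t % log_interval == 0
                                             or t == total_gens - 1):
                traj.append((t, float(pheno.mean())))
        else:
            pheno = None

        # --- optimum shift (needs SD of the pre-shift phenotype) ---
        if shift_gen is not None:
            if t == shift_gen - 1:
                prev_pheno_sd = float(np.std(pheno)) if pheno is not None else 0.0
            if t == shift_gen:
                sd = prev_pheno_sd if prev_pheno_sd and prev_pheno_sd > 0 else 1.0
                move = params.dphi * sd
                if params.shift_duration <= 0:
                    phi_o += move
                else:
                    ramp_left = params.shift_duration
                    ramp_step = move / params.shift_duration
            if ramp_left > 0 and t >= shift_gen:
                phi_o += ramp_step
                ramp_left -= 1

        # --- fitness and parent sampling ---
        if neutral:
            weights = None
        elif ew:
            load = geno @ sel if sel.size else np.zeros(n)
            weights = np.exp(-0.5 * load)
        else:
            weights = gaussian_fitness(pheno, phi_o, params.fitness_width)
        n_next = int(sizes[min(t + 1, total_gens - 1)]) if t + 1 < total_gens \
            else int(sizes[-1])
        parents = _draw_parents(rng, n_next, weights, n)

        # --- transmission: each site independently, Bernoulli(g/2) per gamete ---
        n_sites = geno.shape[1]
        if n_sites:
            pg = geno[parents]  # (2*n_next, n_sites)
            gametes = (rng.random(pg.shape) * 2.0 < pg)
            geno = (gametes[0::2].astype(np.uint8) + gametes[1::2])
        else:
            geno = np.zeros((n_next, 0), dtype=np.uint8)

        # --- new mutations on fresh sites ---
        n_mut = rng.poisson(2.0 * n_next * params.mutation_rate)
        if n_mut:
            cols = np.zeros((n_next, n_mut), dtype=np.uint8)
            cols[rng.integers(0, n_next, size=n_mut), np.arange(n_mut)] = 1
            geno = np.concatenate([geno, cols], axis=1)
            if ew:
                s_new = rng.gamma(params.ew_s_shape,
                                  params.ew_s_mean / params.ew_s_shape,
                                  size=n_mut)
                signs = np.where(rng.random(n_mut) < params.delta, 1.0, -1.0)
                noise = (1.0 + rng.normal(0.0, params.ew_noise_sd, size=n_mut)
                         if params.ew_noise_sd > 0 else 1.0)
                b_new = signs * np.abs(s_new) ** params.ew_tau * noise
                sel = np.concatenate([sel, s_new])
            else:
                b_new = draw_effect(params, rng, size=n_mut)
            beta = np.concatenate([beta, b_new])
            origin = np.concatenate([origin, np.full(n_mut, t, dtype=int)])

        # --- prune fixed and lost sites ---
        if geno.shape[1]:
            counts = geno.sum(axis=0, dtype=np.int64)
            two_n = 2 * geno.shape[0]
            fixed = counts == two_n
            lost = counts == 0
            if fixed.any() or lost.any():
                fixed_count += int(fixed.sum())
                lost_count += int(lost.sum())
                phi_fixed += 2.0 * float(beta[fixed].sum())
                keep = ~(fixed | lost)
                geno = geno[:, keep]
                beta = beta[keep]
                origin = origin[keep]
                if ew:
                    sel = sel[keep]

    counts = geno.sum(axis=0, dtype=np.int64)
    two_n = 2 * geno.shape[0]
    daf = counts / two_n
    return SimulationOutput(
        true_beta=beta.copy(),
        daf=daf,
        origin_generation=origin.copy(),
        n_haplotypes=two_n,
        fixed_count=fixed_count,
        lost_count=lost_count,
        phi_trajectory=np.array(traj) if traj else np.zeros((0, 2)),
        v_g=v_g,
        v_p=v_p,
        seed=seed,
    )


def add_estimation_noise(
    output: SimulationOutput,
    noise: GWASNoiseParams,
    rng: np.random.Generator,
) -> SimulationOutput:
    """Attach GWAS-style estimates β̂ = β + N(0, σ²/(2·n·x(1−x))) per variant.

    The variance mirrors the sampling variance of an OLS per-variant effect
    estimate: largest for rare variants, smallest at x = 0.5, vanishing as
    the GWAS sample size grows.
    """
    x = output.daf
    sd = np.sqrt(noise.residual_var / (2.0 * noise.n_gwas * x * (1.0 - x)))
    out = replace_output(output)
    out.beta_hat = output.true_beta + rng.normal(0.0, 1.0, size=x.size) * sd
    return out


def apply_misorientation(
    output: SimulationOutput,
    eps_anc: float,
    rng: np.random.Generator,
) -> SimulationOutput:
    """Independently flip each variant's orientation with probability eps_anc.

    A flip models a misidentified ancestral state: the effect sign reverses
    and the frequency maps to its complement, β → −β and x → 1 − x.
    """
    if not 0.0 <= eps_anc <= 1.0:
        raise ValueError("eps_anc must lie in [0, 1]")
    flip = rng.random(output.daf.size) < eps_anc
    sign = np.where(flip, -1.0, 1.0)
    out = replace_output(output)
    out.true_beta = output.true_beta * sign
    out.daf = np.where(flip, 1.0 - output.daf, output.daf)
    if output.beta_hat is not None:
        out.beta_hat = output.beta_hat * sign
    return out


def replace_output(output: SimulationOutput) -> SimulationOutput:
    """Shallow copy of a SimulationOutput with copied variant arrays."""
    return SimulationOutput(
        true_beta=output.true_beta.copy(),
        daf=output.daf.copy(),
        origin_generation=output.origin_generation.copy(),
        n_haplotypes=output.n_haplotypes,
        fixed_count=output.fixed_count,
        lost_count=output.lost_count,
        phi_trajectory=output.phi_trajectory.copy(),
        v_g=output.v_g,
        v_p=output.v_p,
        beta_hat=None if output.beta_hat is None else output.beta_hat.copy(),
        seed=output.seed,
    )
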