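"""Synthetic GWAS-like datasets with block structure.

These fixtures emulate the *null* the permutation scheme is built for:
variants with a neutral (∝ 1/x) derived-allele-frequency spectrum and
zero-mean effect-size noise that is equicorrelated within linkage blocks —
the simplest surrogate for LD-induced correlation of effect estimates.
Generation is a pure function of its configuration (same config, same
bytes), which the calibration suites rely on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gwas import LinkageBlockMap, PolarizedVariant

__all__ = ["FixtureConfig", "generate_neutral_gwas", "toy_fixture"]

_BLOCK_SPAN = 1000  # synthetic bp per block


@dataclass(frozen=True)
class FixtureConfig:
    n_variants: int = 2000
    n_blocks: int = 200
    rho: float = 0.5            # within-block equicorrelation of betas
    daf_law: str = "neutral"    # "neutral" (∝ 1/x) or "uniform"
    beta_sd: float = 0.1
    bias_mean: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_blocks > self.n_variants:
            raise ValueError("n_blocks must not exceed n_variants")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        if self.daf_law not in ("neutral", "uniform"):
            raise ValueError(f"unknown daf_law {self.daf_law!r}")


def _draw_daf(cfg: FixtureConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = 1e-3, 1.0 - 1e-3
    u = rng.random(cfg.n_variants)
    if cfg.daf_law == "neutral":
        # inverse-CDF of the 1/x density truncated to (lo, hi)
        return lo * (hi / lo) ** u
    return lo + (hi - lo) * u


def generate_neutral_gwas(
    cfg: FixtureConfig,
) -> tuple[list[PolarizedVariant], LinkageBlockMap]:
    """Neutral GWAS-like variants with block-correlated effect noise.

    Betas within block b are beta_sd·(√ρ·z_b + √(1−ρ)·e_i) + bias_mean with a
    shared z_b per block, giving pairwise correlation ρ within blocks and
    independence across blocks.  Blocks are contiguous runs of variants laid
    out on one synthetic chromosome.
    """
    rng = np.random.default_rng(cfg.seed)
    daf = _draw_daf(cfg, rng)
    # near-equal contiguous block sizes
    block_of = np.floor(
        np.arange(cfg.n_variants) * cfg.n_blocks / cfg.n_variants
    ).astype(int)
    z_block = rng.standard_normal(cfg.n_blocks)
    e = rng.standard_normal(cfg.n_variants)
    beta = cfg.bias_mean + cfg.beta_sd * (
        np.sqrt(cfg.rho) * z_block[block_of] + np.sqrt(1.0 - cfg.rho) * e
    )
    # positions: variant i of block b sits inside [b*span, (b+1)*span)
    within = np.zeros(cfg.n_variants, dtype=int)
    for b in range(cfg.n_blocks):
        m = block_of == b
        within[m] = np.arange(m.sum())
    pos_1based = block_of * _BLOCK_SPAN + within + 1
    variants = [
        PolarizedVariant(f"v{i:06d}", "1", int(pos_1based[i]),
                         float(beta[i]), float(daf[i]), int(block_of[i]))
        for i in range(cfg.n_variants)
    ]
    blocks = LinkageBlockMap([
        ("1", b * _BLOCK_SPAN, (b + 1) * _BLOCK_SPAN, b)
        for b in range(cfg.n_blocks)
    ])
    return variants, blocks


def toy_fixture() -> tuple[list[PolarizedVariant], LinkageBlockMap]:
    """A fixed 12-variant, 3-block dataset for worked examples and enumeration tests.

    Values are hand-set and byte-identical across runs; with yw = 0.25 the
    four bin means are 0.15, 0.10, −0.20, 0.05 so Sβ(0, 1) = 0.10.
    """
    rows = [
        # (id, pos, beta, daf, block)
        ("t01", 101, 0.10, 0.05, 0),
        ("t02", 151, 0.20, 0.10, 0),
        ("t03", 201, 0.15, 0.20, 0),
        ("t04", 251, 0.20, 0.30, 0),
        ("t05", 1101, -0.10, 0.35, 1),
        ("t06", 1151, 0.20, 0.45, 1),
        ("t07", 1201, -0.40, 0.55, 1),
        ("t08", 1251, -0.20, 0.60, 1),
        ("t09", 2101, 0.00, 0.70, 2),
        ("t10", 2151, 0.25, 0.80, 2),
        ("t11", 2201, -0.15, 0.90, 2),
        ("t12", 2251, 0.05, 0.95, 2),
    ]
    variants = [
        PolarizedVariant(vid, "1", pos, beta, daf, block)
        for vid, pos, beta, daf, block in rows
    ]
    blocks = LinkageBlockMap([
        ("1", 0, 1000, 0), ("1", 1000, 2000, 1), ("1", 2000, 3000, 2)
    ])
    return variants, blocks
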