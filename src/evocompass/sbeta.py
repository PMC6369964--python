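"""βDAF profiles and the Sβ statistic.

A βDAF profile bins derived alleles into derived-allele-frequency (DAF) bins
of width ``yw`` (default 1%) and records the mean effect size β̄ within each
bin.  The statistic

    Sβ(fi, fj) = Σ_{bins in [fi, fj]} β̄(bin)

approximates the area under the βDAF curve and is the core test quantity:
it is zero in expectation for a neutrally evolving trait without mutational
bias, picks up a constant offset per bin under pure mutational bias (hence a
linear Sβ(0, x) in x), and bends under selection.

Conventions: bin k covers the half-open interval (k·yw, (k+1)·yw], so a DAF
exactly on a bin edge belongs to the lower bin and every DAF in (0, 1) maps
to exactly one bin.  Empty bins carry β̄ = 0 and are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "BetaDAFProfile",
    "DegenerateNormalizerError",
    "bin_mean_beta",
    "sbeta",
    "sbeta_curve",
    "normalized_sbeta_vector",
    "binomial_enrichment",
    "as_beta_daf",
]

_EDGE_TOL = 1e-9


class DegenerateNormalizerError(ValueError):
    """The normalizing Sβ(0.01, 0.99) is too close to zero to scale by."""


def as_beta_daf(variants) -> tuple[np.ndarray, np.ndarray]:
    """Coerce a variant collection to (beta, daf) float arrays.

    Accepts a list of :class:`~evocompass.gwas.PolarizedVariant`, a pandas
    DataFrame with BETA_DERIVED/DAF columns, or a (beta, daf) pair of arrays.
    """
    if isinstance(variants, tuple) and len(variants) == 2:
        beta = np.asarray(variants[0], dtype=float)
        daf = np.asarray(variants[1], dtype=float)
    elif hasattr(variants, "columns"):
        beta = variants["BETA_DERIVED"].to_numpy(dtype=float)
        daf = variants["DAF"].to_numpy(dtype=float)
    else:
        beta = np.array([v.beta_derived for v in variants], dtype=float)
        daf = np.array([v.daf for v in variants], dtype=float)
    return beta, daf


def _n_bins(yw: float) -> int:
    n = round(1.0 / yw)
    if abs(n * yw - 1.0) > _EDGE_TOL:
        raise ValueError(f"bin width {yw} does not divide 1 exactly")
    return n


def bin_index(daf: np.ndarray, yw: float) -> np.ndarray:
    """Map DAF values in (0,1) to bin indices with (lower, upper] membership."""
    n = _n_bins(yw)
    idx = np.ceil(np.asarray(daf, dtype=float) / yw - _EDGE_TOL).astype(int) - 1
    return np.clip(idx, 0, n - 1)


@dataclass
class BetaDAFProfile:
    """Per-bin mean derived-allele effect sizes and counts."""

    yw: float
    bin_means: np.ndarray
    bin_counts: np.ndarray

    def __post_init__(self):
        self.bin_means = np.asarray(self.bin_means, dtype=float)
        self.bin_counts = np.asarray(self.bin_counts, dtype=int)
        n = _n_bins(self.yw)
        if len(self.bin_means) != n or len(self.bin_counts) != n:
            raise ValueError(f"profile with yw={self.yw} needs exactly {n} bins")

    @property
    def n_bins(self) -> int:
        return len(self.bin_means)

    @property
    def empty_mask(self) -> np.ndarray:
        """True for bins with no variants (their β̄ is recorded as 0)."""
        return self.bin_counts == 0

    @property
    def edges(self) -> np.ndarray:
        """All bin edges 0, yw, 2·yw, …, 1."""
        return np.linspace(0.0, 1.0, self.n_bins + 1)

    @property
    def is_empty(self) -> bool:
        return int(self.bin_counts.sum()) == 0

    def edge_index(self, f: float) -> int:
        """Index of edge ``f`` among bin edges; raise naming neighbours otherwise."""
        edges = self.edges
        i = int(np.argmin(np.abs(edges - f)))
        if abs(edges[i] - f) > _EDGE_TOL:
            lo = edges[max(i - 1, 0)] if edges[i] > f else edges[i]
            hi = edges[min(i + 1, self.n_bins)] if edges[i] < f else edges[i]
            raise ValueError(
                f"{f} is not a bin edge for yw={self.yw}; "
                f"nearest valid edges are {lo:g} and {hi:g}"
            )
        return i


def bin_mean_beta(variants, yw: float = 0.01) -> BetaDAFProfile:
    """Build a βDAF profile: mean beta_derived within each DAF bin of width ``yw``.

    An empty variant list yields an all-empty (but valid) profile.
    """
    beta, daf = as_beta_daf(variants)
    n = _n_bins(yw)
    if beta.size == 0:
        return BetaDAFProfile(yw, np.zeros(n), np.zeros(n, dtype=int))
    if np.any(daf <= 0.0) or np.any(daf >= 1.0):
        raise ValueError("all DAF values must lie strictly in (0, 1)")
    idx = bin_index(daf, yw)
    counts = np.bincount(idx, minlength=n)
    sums = np.bincount(idx, weights=beta, minlength=n)
    means = np.divide(sums, counts, out=np.zeros(n), where=counts > 0)
    return BetaDAFProfile(yw, means, counts)


def sbeta(profile: BetaDAFProfile, fi: float, fj: float) -> float:
    """Sβ(fi, fj): sum of β̄ over bins whose interval lies within [fi, fj].

    ``fi`` and ``fj`` must lie on bin edges; empty bins contribute 0.
    """
    if not fi < fj:
        raise ValueError(f"need fi < fj, got ({fi}, {fj})")
    i = profile.edge_index(fi)
    j = profile.edge_index(fj)
    return float(profile.bin_means[i:j].sum())


def sbeta_curve(profile: BetaDAFProfile) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative curve (x, Sβ(0, x)) evaluated at every bin upper edge."""
    x = profile.edges[1:]
    return x, np.cumsum(profile.bin_means)


def normalized_sbeta_vector(
    profile: BetaDAFProfile,
    grid: Sequence[float],
    lo: float = 0.01,
    hi: float = 0.99,
    floor_rel: float = 1e-12,
    signed: bool = False,
) -> np.ndarray:
    """Sβ(lo, x) for each x in ``grid``, scaled by Sβ(lo, hi).

    With ``signed=False`` the scaling divides by the signed normalizer, so a
    grid ending at ``hi`` always ends at exactly 1.  With ``signed=True`` the
    scaling divides by |Sβ(lo, hi)|, preserving the overall sign of the
    curve.  The signed form is what inference uses: the model is exactly
    symmetric under jointly flipping the mutational bias (δ → 1−δ) and the
    optimum shift (Δφ → −Δφ), which negates every β̄, and a sign-free
    summary cannot separate those mirror scenarios — the curve's sign is the
    compass needle.

    A normalizer smaller in magnitude than ``floor_rel`` times the
    count-weighted mean |β̄| is treated as degenerate and raises
    :class:`DegenerateNormalizerError`.
    """
    denom = sbeta(profile, lo, hi)
    total = int(profile.bin_counts.sum())
    scale = (
        np.abs(profile.bin_means * profile.bin_counts).sum() / total
        if total else 0.0
    )
    if abs(denom) <= floor_rel * scale or denom == 0.0:
        raise DegenerateNormalizerError(
            f"|S_beta({lo},{hi})| = {abs(denom):.3g} is below the degeneracy floor"
        )
    if signed:
        denom = abs(denom)
    return np.array([sbeta(profile, lo, x) for x in grid]) / denom


def binomial_enrichment(k: int, n: int, p: float) -> float:
    """Upper-tail probability P(X >= k) for X ~ Binomial(n, p).

    Used to ask whether the number of phenotypes with small test p-values is
    larger than expected among a panel of tested traits.
    """
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not (0.0 < p < 1.0):
        raise ValueError(f"need 0 < p < 1, got p={p}")
    return float(stats.binom.sf(k - 1, n, p))
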