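"""Cascade parameter selection.

The cascade stores every unique read at some level, and the cost model is
per-element: a filter holding n elements at false-positive rate F = c**rho
needs about rho = log(1/F)/log(1/c) bits per element at the optimal hash
count.  Level sizes alternate between n-driven and genome-driven expected
counts (2g queries per scan, both strands), giving the infinite-cascade
cost per read

    rho * (1 + (2g/n) * c**rho) / (1 - c**rho)

which is minimised numerically over rho.  The minimiser fixes the common
per-level false-positive rate F = c**rho*; each level's (h, m) is then
chosen for its own element count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize_scalar

from ._hashing import derive_seed
from .bloom import MIN_FILTER_BITS, OPTIMAL_BASE, required_bits
from .errors import ValidationError

__all__ = [
    "DEFAULT_SIZE_CAP",
    "DEFAULT_MASTER_SEED",
    "LevelParams",
    "CascadeParams",
    "bits_per_read",
    "truncated_bits_per_read",
    "optimize_rho",
    "choose_level_params",
    "expected_level_counts",
    "plan_cascade",
]

#: Uncompressed per-filter cap: 500 MiB, the operational threshold that keeps
#: a single filter's resident size bounded on commodity hardware.
DEFAULT_SIZE_CAP = 500 * 2**20

#: Fixed default master seed for the hash family, so that archives produced
#: with default settings are reproducible byte for byte.
DEFAULT_MASTER_SEED = 0x0C0FFEE1CA5CADE5

#: Maximum hash count considered when sizing a level.
H_MAX = 32

#: Tolerated uncompressed overhead of a level relative to the real-h optimal
#: size m = n*ln(1/F)/ln(2)^2.  Small h makes filters sparse (compressible,
#: fast to query) at the price of a larger bit array; this bounds that price
#: so the cascade stays within the per-element cost model's envelope.
DENSITY_SLACK = 1.25


def bits_per_read(rho: float, g: int, n: int) -> float:
    """Infinite-cascade expected bits per read at budget rho, F = c**rho."""
    if rho <= 0:
        raise ValidationError(f"rho must be positive, got {rho}")
    if g < 1 or n < 1:
        raise ValidationError(f"need g >= 1 and n >= 1, got g={g}, n={n}")
    F = OPTIMAL_BASE**rho
    return rho * (1.0 + (2.0 * g / n) * F) / (1.0 - F)


def truncated_bits_per_read(rho: float, g: int, n: int, num_levels: int = 4) -> float:
    """Per-read cost of a finite cascade: rho bits per expected element."""
    F = OPTIMAL_BASE**rho
    counts = expected_level_counts(g, n, F, num_levels)
    return rho * sum(counts) / n


def _objective_grid(g: int, n: int, lo: float, hi: float, step: float):
    grid = np.arange(lo, hi + step / 2, step)
    F = OPTIMAL_BASE**grid
    obj = grid * (1.0 + (2.0 * g / n) * F) / (1.0 - F)
    return grid, obj


def optimize_rho(g: int, n: int, lo: float = 0.1, hi: float = 100.0) -> tuple[float, float]:
    """Minimise bits_per_read over rho in [lo, hi]; returns (rho*, F*)."""
    if g < 1 or n < 1:
        raise ValidationError(f"need g >= 1 and n >= 1, got g={g}, n={n}")
    grid, obj = _objective_grid(g, n, lo, hi, 0.01)
    if not np.all(np.isfinite(obj)):
        raise ValidationError("non-finite objective on the search grid")
    i = int(np.argmin(obj))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(
        lambda r: bits_per_read(r, g, n),
        bounds=(float(a), float(b)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    rho = float(res.x)
    if bits_per_read(rho, g, n) > obj[i]:
        rho = float(grid[i])
    return rho, float(OPTIMAL_BASE**rho)


def choose_level_params(
    n_level: int,
    F: float,
    size_cap: int = DEFAULT_SIZE_CAP,
    *,
    h_max: int = H_MAX,
    density_slack: float = DENSITY_SLACK,
) -> tuple[int, int, bool]:
    """Pick (h, m) for one cascade level; returns (h, m, fits_cap).

    h is incremented from 1 to the smallest value whose exact size
    required_bits(n_level, F, h) fits both the absolute uncompressed cap
    and a bounded-overhead budget relative to the real-h optimum.  If no
    h fits the cap, the size-minimising h is returned with fits_cap False.
    """
    if n_level < 0:
        raise ValidationError(f"element count must be >= 0, got {n_level}")
    if not 0.0 < F < 1.0:
        raise ValidationError(f"false-positive rate must be in (0,1), got {F}")
    if n_level == 0:
        return 1, MIN_FILTER_BITS, True
    cap_bits = 8 * size_cap
    m_opt = n_level * math.log(1.0 / F) / (math.log(2.0) ** 2)
    budget = max(math.ceil(density_slack * m_opt), MIN_FILTER_BITS)
    best_m, best_h = None, None
    for h in range(1, h_max + 1):
        m = required_bits(n_level, F, h)
        if best_m is None or m < best_m:
            best_m, best_h = m, h
        if m <= cap_bits and m <= budget:
            return h, m, True
    return best_h, best_m, best_m <= cap_bits


def expected_level_counts(g: int, n: int, F: float, num_levels: int) -> list[float]:
    """A-priori expected element counts per level.

    Level 1 holds the n unique reads.  Even levels hold genome-scan false
    positives (~2g*F^(j/2) for level j); odd levels >= 3 hold read-side
    false positives (~n*F^((j-1)/2)).
    """
    if num_levels < 1:
        raise ValidationError(f"need at least one level, got {num_levels}")
    counts: list[float] = [float(n)]
    for j in range(2, num_levels + 1):
        if j % 2 == 0:
            counts.append(2.0 * g * F ** (j // 2))
        else:
            counts.append(float(n) * F ** ((j - 1) // 2))
    return counts


@dataclass
class LevelParams:
    """Everything needed to rebuild one filter of the cascade."""

    n_level: int
    h: int
    m: int
    seed_a: int
    seed_b: int
    fits_cap: bool = True


@dataclass
class CascadeParams:
    """Budget rho, common per-level rate F, and per-level (h, m, seeds)."""

    rho: float
    F: float
    g: int
    n: int
    levels: list[LevelParams] = field(default_factory=list)
    size_cap: int = DEFAULT_SIZE_CAP
    num_levels: int = 4
    master_seed: int = DEFAULT_MASTER_SEED

    def level_seeds(self, j: int) -> tuple[int, int]:
        """Hash-seed pair of 1-based level j, derived from the master seed."""
        return derive_seed(self.master_seed, 2 * j), derive_seed(self.master_seed, 2 * j + 1)

    def with_actual_count(self, j: int, n_actual: int) -> LevelParams:
        """Re-size 1-based level j for an exactly known element count."""
        h, m, fits = choose_level_params(n_actual, self.F, self.size_cap)
        sa, sb = self.level_seeds(j)
        lvl = LevelParams(n_actual, h, m, sa, sb, fits)
        if j - 1 < len(self.levels):
            self.levels[j - 1] = lvl
        return lvl

    def to_dict(self) -> dict:
        return {
            "rho": self.rho,
            "F": self.F,
            "g": self.g,
            "n": self.n,
            "size_cap": self.size_cap,
            "num_levels": self.num_levels,
            "levels": [
                {"n_level": l.n_level, "h": l.h, "m": l.m, "fits_cap": l.fits_cap}
                for l in self.levels
            ],
        }


def plan_cascade(
    g: int,
    n: int,
    size_cap: int = DEFAULT_SIZE_CAP,
    num_levels: int = 4,
    master_seed: int = DEFAULT_MASTER_SEED,
) -> CascadeParams:
    """A-priori cascade plan from genome length g and unique-read count n.

    Level 1 is sized for n; deeper levels for their expected counts.  The
    encoder replaces expectations with actual counts as each level's
    insert set becomes known.
    """
    rho, F = optimize_rho(g, max(n, 1))
    params = CascadeParams(
        rho=rho, F=F, g=g, n=n, size_cap=size_cap,
        num_levels=num_levels, master_seed=master_seed,
    )
    counts = expected_level_counts(g, max(n, 1), F, num_levels)
    counts[0] = float(n)
    for j, cnt in enumerate(counts, start=1):
        n_exp = int(round(cnt))
        h, m, fits = choose_level_params(n_exp, F, size_cap)
        sa, sb = params.level_seeds(j)
        params.levels.append(LevelParams(n_exp, h, m, sa, sb, fits))
    return params
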