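"""Independent brute-force oracles used by the tests.

These deliberately re-derive expectations from first principles (explicit
enumeration of gamete combinations, dense likelihood grids) without
touching the estimation code paths they check.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

_OBS = {
    "codominant": (0, 1, 2),
    "dominant_AB_BB": (1, 1, 2),
    "dominant_AB_AA": (0, 1, 1),
}


def _cell_prob_grid(grid: np.ndarray, type_a: str, type_b: str,
                    phase: str) -> np.ndarray:
    """P(observed cell | r) for every r on the grid, shape (G, 9).

    Enumerates the 16 ordered gamete combinations of a selfed double
    heterozygote: parental haplotypes have probability (1-r)/2 each,
    recombinant ones r/2 each.
    """
    if phase == "coupling":
        parental, recomb = [(0, 0), (1, 1)], [(0, 1), (1, 0)]
    else:
        parental, recomb = [(0, 1), (1, 0)], [(0, 0), (1, 1)]
    gametes = [(h, 0) for h in parental] + [(h, 1) for h in recomb]
    w = [((1 - grid) / 2), (grid / 2)]
    probs = np.zeros((grid.size, 9))
    for h1, k1 in gametes:
        for h2, k2 in gametes:
            ga, gb = h1[0] + h2[0], h1[1] + h2[1]
            cell = 3 * _OBS[type_a][ga] + _OBS[type_b][gb]
            probs[:, cell] += w[k1] * w[k2]
    return probs


def grid_ml_r(counts: np.ndarray, type_a: str = "codominant",
              type_b: str = "codominant", coarse_step: float = 5e-4,
              fine_step: float = 1e-6) -> Tuple[float, str, float]:
    """Exhaustive maximum-likelihood recombination fraction.

    Scans r in [0, 0.5] on a coarse grid for both phases, then refines
    around the coarse argmax.  Returns (r, phase, loglik).
    """
    counts = np.asarray(counts, dtype=float).reshape(9)
    best = (-np.inf, 0.5, "coupling")

    def scan(grid: np.ndarray, phase: str) -> Tuple[float, float]:
        probs = _cell_prob_grid(grid, type_a, type_b, phase)
        with np.errstate(divide="ignore", invalid="ignore"):
            logp = np.log(probs)
            terms = np.where(counts[None, :] > 0, counts[None, :] * logp, 0.0)
        ll = terms.sum(axis=1)
        ll[np.isnan(ll)] = -np.inf
        i = int(np.argmax(ll))
        return float(ll[i]), float(grid[i])

    for phase in ("coupling", "repulsion"):
        coarse = np.arange(0.0, 0.5 + coarse_step / 2, coarse_step)
        ll, r0 = scan(coarse, phase)
        fine = np.arange(max(r0 - 2 * coarse_step, 0.0),
                         min(r0 + 2 * coarse_step, 0.5) + fine_step / 2,
                         fine_step)
        llf, rf = scan(fine, phase)
        if llf > best[0]:
            best = (llf, rf, phase)
    return best[1], best[2], best[0]


def random_joint_table(rng: np.random.Generator, max_n: int = 30) -> np.ndarray:
    """A random small 3x3 joint count table (possibly sparse)."""
    n = int(rng.integers(4, max_n + 1))
    cells = rng.integers(0, 9, size=n)
    return np.bincount(cells, minlength=9).astype(float)


def calls_from_table(counts: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Expand a 3x3 joint count table into two call-code vectors."""
    counts = np.asarray(counts, dtype=int).reshape(9)
    a = np.repeat(np.arange(9) // 3, counts)
    b = np.repeat(np.arange(9) % 3, counts)
    return a.astype(np.int8), b.astype(np.int8)
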