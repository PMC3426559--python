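"""Significance and robustness analyses around the Procrustes similarity.

* Permutation test: shuffle the population -> location assignment (all
  individuals of a population move together), recompute t0 each time, and
  report the exceedance fraction M/N.  PCA is not recomputed per
  permutation — only the geographic side changes.
* Leave-one-out: drop one population at a time, rerun standardization and
  PCA on the remaining individuals (without repeating the outlier search),
  and score the new map against geography (t0') and against the original
  map on the shared individuals (t_PCA).
* Marker curve: t0 as a function of the number of subsampled loci.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .genotype import GenotypeMatrix, subsample_loci
from .geo import GeoTable, expand_to_individuals
from .pca import run_pca, standardize
from .procrustes import procrustes_fit

__all__ = [
    "PermutationResult",
    "LeaveOneOutRecord",
    "MarkerCurve",
    "permutation_test",
    "leave_one_out",
    "marker_curve",
]


@dataclass
class PermutationResult:
    t0_observed: float
    null_t: np.ndarray
    N: int
    exceed_count: int
    p_value: float          # M / N
    p_value_display: str    # "M/N", or "< 1/N" when M = 0
    exhaustive: bool
    seed: int | None


@dataclass
class LeaveOneOutRecord:
    excluded_population: str
    t0_prime: float
    t_pca: float
    reflection_used_geo: bool


@dataclass
class MarkerCurve:
    L_values: list[int]
    t0_at_L: list[float]
    seed: int


def _pop_rows(G: GenotypeMatrix) -> tuple[list[str], list[np.ndarray]]:
    pops = G.unique_populations()
    labels = np.asarray(G.populations)
    return pops, [np.flatnonzero(labels == p) for p in pops]


def permutation_test(pc_scores: np.ndarray, geo: GeoTable, G: GenotypeMatrix,
                     N: int = 100_000, seed: int | None = None,
                     allow_reflection: bool = True,
                     exhaustive: bool = False) -> PermutationResult:
    """Permutation test of the Procrustes similarity between a PC map and
    population geography.

    Each permutation reassigns the multiset of population locations to
    populations uniformly at random, expands locations to individuals, and
    recomputes t0 with the same Procrustes settings as the observed fit.
    ``p = M/N`` where M counts permutations with t0_pi >= t0_observed;
    with M = 0 the display is "< 1/N".  ``exhaustive=True`` enumerates all
    K! assignments of K populations (K <= 8) and N is ignored.
    """
    pops, rows = _pop_rows(G)
    K = len(pops)
    if K < 3:
        raise ValueError("permutation test needs at least 3 populations")
    pc = np.asarray(pc_scores, dtype=float)
    if pc.shape != (G.n_individuals, 2):
        raise ValueError("pc_scores must be (n, 2) aligned with G")

    locations = np.array([geo.planar(p) for p in pops], dtype=float)
    X_obs = expand_to_individuals(geo, G)
    t0_obs = procrustes_fit(X_obs, pc, allow_reflection=allow_reflection).t0

    n = G.n_individuals
    X_perm = np.empty((n, 2))

    def t0_of(assignment: np.ndarray) -> float:
        for k, loc_idx in enumerate(assignment):
            X_perm[rows[k]] = locations[loc_idx]
        return procrustes_fit(X_perm, pc, allow_reflection=allow_reflection).t0

    if exhaustive:
        if K > 8:
            raise ValueError("exhaustive enumeration limited to 8 populations")
        null = np.array([t0_of(np.asarray(perm))
                         for perm in itertools.permutations(range(K))])
    else:
        if N < 1:
            raise ValueError("N must be positive")
        rng = np.random.default_rng(seed)
        null = np.array([t0_of(rng.permutation(K)) for _ in range(N)])

    N_eff = len(null)
    M = int((null >= t0_obs - 1e-12).sum())
    display = f"< 1/{N_eff}" if M == 0 else f"{M}/{N_eff}"
    return PermutationResult(
        t0_observed=t0_obs,
        null_t=null,
        N=N_eff,
        exceed_count=M,
        p_value=M / N_eff,
        p_value_display=display,
        exhaustive=exhaustive,
        seed=seed,
    )


def leave_one_out(G: GenotypeMatrix, geo: GeoTable,
                  allow_reflection: bool = True) -> list[LeaveOneOutRecord]:
    """Exclude each population in turn and rescore the resulting PC map.

    Input is the post-QC matrix; the outlier search is not repeated.  For
    each excluded population, t0' compares the new PC1-PC2 map with
    geography and t_PCA compares it with the original PC1-PC2 coordinates
    restricted to the shared individuals (alignment by individual ID).
    """
    pops = G.unique_populations()
    if len(pops) < 4:
        raise ValueError("leave-one-out needs at least 4 populations")
    full_pca = run_pca(standardize(G))
    full_pc12 = {iid: full_pca.pc12[i] for i, iid in enumerate(G.individual_ids)}

    records = []
    for pop in pops:
        reduced = G.drop_populations({pop})
        if len(reduced.unique_populations()) < 3 or reduced.n_individuals < 3:
            raise ValueError(f"excluding {pop!r} leaves too few populations/individuals")
        red_pca = run_pca(standardize(reduced))
        X_geo = expand_to_individuals(geo, reduced)
        fit_geo = procrustes_fit(X_geo, red_pca.pc12, allow_reflection=allow_reflection)
        original = np.array([full_pc12[iid] for iid in reduced.individual_ids])
        fit_pca = procrustes_fit(original, red_pca.pc12, allow_reflection=allow_reflection)
        records.append(LeaveOneOutRecord(
            excluded_population=pop,
            t0_prime=fit_geo.t0,
            t_pca=fit_pca.t0,
            reflection_used_geo=fit_geo.reflection_used,
        ))
    return records


def marker_curve(G: GenotypeMatrix, geo: GeoTable, L_values: list[int],
                 seed: int, allow_reflection: bool = True) -> MarkerCurve:
    """t0 recomputed on random marker subsets of increasing size.

    The locus selection at each L depends only on (seed, L), so curves for
    different datasets sharing locus IDs use the same marker subsets.
    """
    L_values = sorted(int(v) for v in L_values)
    if not L_values or L_values[0] < 1 or L_values[-1] > G.n_loci:
        raise ValueError("L_values out of range")
    X_geo = expand_to_individuals(geo, G)
    t0s = []
    for L_sub in L_values:
        sub = subsample_loci(G, L_sub, seed=seed)
        pca = run_pca(standardize(sub))
        t0s.append(procrustes_fit(X_geo, pca.pc12,
                                  allow_reflection=allow_reflection).t0)
    return MarkerCurve(L_values=L_values, t0_at_L=t0s, seed=seed)
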