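"""Multi-population, multi-locus FST by the Weir-Cockerham (1984) estimator.

Per locus, three variance components are computed from population sample
sizes n_i, sample allele frequencies p_i, and observed heterozygote
frequencies h_i (genotypic form, no Hardy-Weinberg assumption):

    a — among-population component,
    b — among-individual-within-population component,
    c — within-individual component.

The multi-locus estimate combines loci as a ratio of sums,
theta = sum(a) / sum(a + b + c), not a mean of per-locus ratios.  Loci that
are monomorphic overall, or observed in fewer than two populations, or with
mean sample size n_bar <= 1, contribute to neither sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype import GenotypeMatrix

__all__ = ["FstEstimate", "weir_cockerham_fst"]


@dataclass
class FstEstimate:
    theta: float
    per_locus_components: np.ndarray  # (L, 3) columns a, b, c; NaN where dropped
    n_pops: int
    loci_used: int


def weir_cockerham_fst(G: GenotypeMatrix) -> FstEstimate:
    """Weir-Cockerham theta over all usable loci, combined as ratio of sums."""
    pops = G.unique_populations()
    r_all = len(pops)
    if r_all < 2:
        raise ValueError("FST needs at least 2 populations")
    pop_index = {p: k for k, p in enumerate(pops)}
    memb = np.zeros((r_all, G.n_individuals), dtype=bool)
    for i, p in enumerate(G.populations):
        memb[pop_index[p], i] = True

    obs = ~G.missing                                   # (n, L)
    vals = np.where(G.missing, 0, G.values).astype(float)
    het = np.where(G.missing, 0, G.values == 1).astype(float)

    n_il = memb @ obs.astype(float)                    # (r, L) sample sizes
    allele_sum = memb @ vals                           # (r, L) ref-allele counts
    het_sum = memb @ het                               # (r, L) het counts

    L = G.n_loci
    comps = np.full((L, 3), np.nan)
    for l in range(L):
        present = n_il[:, l] > 0
        r = int(present.sum())
        if r < 2:
            continue
        n_i = n_il[present, l]
        p_i = allele_sum[present, l] / (2 * n_i)
        h_i = het_sum[present, l] / n_i
        n_bar = n_i.mean()
        if n_bar <= 1:
            continue
        n_tot = n_i.sum()
        n_c = (n_tot - (n_i ** 2).sum() / n_tot) / (r - 1)
        p_bar = (n_i * p_i).sum() / n_tot
        if p_bar <= 0.0 or p_bar >= 1.0:
            continue  # monomorphic overall
        s2 = (n_i * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum() / n_tot

        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar)
            - (r - 1) / r * s2
            - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2
        comps[l] = (a, b, c)

    used = ~np.isnan(comps[:, 0])
    if not used.any():
        raise ValueError("no usable loci (all monomorphic or undersampled)")
    a_sum = comps[used, 0].sum()
    total = comps[used].sum()
    if total == 0:
        raise ValueError("total variance component is zero")
    return FstEstimate(
        theta=float(a_sum / total),
        per_locus_components=comps,
        n_pops=r_all,
        loci_used=int(used.sum()),
    )
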