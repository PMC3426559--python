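"""Genotype matrices: containers, readers, and sample-level quality control.

The central object is :class:`GenotypeMatrix`, an individuals x loci matrix of
reference-allele counts (0, 1, 2) with an explicit missing mask and a
population label per individual.  Quality control follows the two-step
convention used in population-structure studies: drop individuals with a high
missing-data fraction, then iteratively remove principal-component outliers
until a PCA pass flags nobody.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "QCReport",
    "load_genotype_matrix",
    "write_genotype_tsv",
    "load_population_map",
    "filter_missing_individuals",
    "iterative_outlier_removal",
    "subsample_loci",
]


@dataclass
class GenotypeMatrix:
    """Diploid genotype matrix (individuals x loci) with missing mask.

    Parameters
    ----------
    values
        ``(n, L)`` integer array of reference-allele counts in {0, 1, 2}.
        Entries under the missing mask are ignored (conventionally 0).
    missing
        ``(n, L)`` boolean array, True where the genotype is missing.
    individual_ids
        Length-``n`` list of unique sample identifiers.
    populations
        Length-``n`` list of population labels, aligned with
        ``individual_ids``.
    locus_ids
        Length-``L`` list of unique locus identifiers.
    """

    values: np.ndarray
    missing: np.ndarray
    individual_ids: list[str]
    populations: list[str]
    locus_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.missing = np.asarray(self.missing, dtype=bool)
        self.individual_ids = list(self.individual_ids)
        self.populations = list(self.populations)
        self.locus_ids = list(self.locus_ids)
        n, L = self.values.shape
        if self.missing.shape != (n, L):
            raise ValueError("values and missing mask shapes differ")
        if n < 2 or L < 1:
            raise ValueError(f"need at least 2 individuals and 1 locus, got {n}x{L}")
        if len(self.individual_ids) != n or len(self.populations) != n:
            raise ValueError("individual_ids/populations length mismatch")
        if len(self.locus_ids) != L:
            raise ValueError("locus_ids length mismatch")
        if len(set(self.individual_ids)) != n:
            raise ValueError("duplicate individual IDs")
        if len(set(self.locus_ids)) != L:
            raise ValueError("duplicate locus IDs")
        observed = self.values[~self.missing]
        if observed.size and (observed.min() < 0 or observed.max() > 2):
            bad = observed[(observed < 0) | (observed > 2)][0]
            raise ValueError(f"non-diploid genotype code {bad}: entries must be 0, 1 or 2")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_loci(self) -> int:
        return self.values.shape[1]

    @property
    def population_of(self) -> dict[str, str]:
        """Mapping individual_id -> population label."""
        return dict(zip(self.individual_ids, self.populations))

    def unique_populations(self) -> list[str]:
        """Population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p, None)
        return list(seen)

    def missing_fraction(self) -> np.ndarray:
        """Per-individual fraction of missing genotypes over all current loci."""
        return self.missing.mean(axis=1)

    def take_individuals(self, index: np.ndarray | list[int]) -> "GenotypeMatrix":
        """Row subset (pure row selection; genotype values untouched)."""
        index = np.asarray(index)
        return GenotypeMatrix(
            values=self.values[index],
            missing=self.missing[index],
            individual_ids=[self.individual_ids[i] for i in index],
            populations=[self.populations[i] for i in index],
            locus_ids=self.locus_ids,
        )

    def drop_populations(self, labels: set[str] | list[str]) -> "GenotypeMatrix":
        labels = set(labels)
        keep = [i for i, p in enumerate(self.populations) if p not in labels]
        if len(keep) < 2:
            raise ValueError("dropping populations leaves fewer than 2 individuals")
        return self.take_individuals(keep)


@dataclass
class QCReport:
    """Record of sample removals during quality control."""

    removed_high_missing: list[str] = field(default_factory=list)
    removed_outliers: list[tuple[int, str]] = field(default_factory=list)
    iterations: int = 0


def load_population_map(popmap_path) -> dict[str, str]:
    """Read a two-column TSV (individual_id, population) into a dict."""
    df = pd.read_csv(popmap_path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("population map needs columns individual_id and population")
    cols = list(df.columns)
    id_col = "individual_id" if "individual_id" in cols else cols[0]
    pop_col = "population" if "population" in cols else cols[1]
    if df[id_col].duplicated().any():
        dup = df[id_col][df[id_col].duplicated()].iloc[0]
        raise ValueError(f"duplicate individual {dup!r} in population map")
    return dict(zip(df[id_col], df[pop_col]))


def _load_tsv(path, missing_code: str = "NA"):
    """Parse the canonical genotype TSV: locus rows, individual columns."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    locus_ids = df.iloc[:, 0].tolist()
    individual_ids = list(df.columns[1:])
    raw = df.iloc[:, 1:].to_numpy(dtype=object).T  # individuals x loci
    missing = raw == missing_code
    values = np.zeros(raw.shape, dtype=np.int8)
    obs = ~missing
    try:
        values[obs] = np.asarray(raw[obs], dtype=np.int64)
    except ValueError as exc:
        raise ValueError(
            f"unparseable genotype token (not 0/1/2/{missing_code}): {exc}"
        ) from None
    return values, missing, individual_ids, locus_ids


def _load_vcf(path):
    """Read diploid GT fields from a VCF into alt-allele counts."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individual_ids = list(vcf.samples)
    locus_ids: list[str] = []
    rows = []
    miss_rows = []
    for var in vcf:
        if len(var.ALT) > 1:
            raise ValueError(
                f"locus {var.ID or f'{var.CHROM}:{var.POS}'} is not biallelic"
            )
        locus_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        gts = np.asarray(var.genotypes, dtype=object)
        alleles = np.array([[g[0], g[1]] for g in gts], dtype=np.int64)
        miss = (alleles < 0).any(axis=1)
        counts = alleles.clip(min=0).sum(axis=1)
        counts[miss] = 0
        rows.append(counts)
        miss_rows.append(miss)
    values = np.array(rows, dtype=np.int8).T
    missing = np.array(miss_rows, dtype=bool).T
    return values, missing, individual_ids, locus_ids


def load_genotype_matrix(path, format: str = "tsv", popmap_path=None,
                         popmap: dict[str, str] | None = None) -> GenotypeMatrix:
    """Load and validate a genotype matrix plus population assignments.

    Parameters
    ----------
    path
        Genotype file. For ``format="tsv"``: tab-delimited, header row of
        individual IDs, one row per locus, cells in {0, 1, 2, NA}.
        For ``format="vcf"``: a VCF v4.x with diploid GT fields.
    format
        ``"tsv"`` or ``"vcf"``.
    popmap_path, popmap
        Population assignment, either as a TSV path (columns individual_id,
        population) or a ready dict. Every sample must be assigned.
    """
    if format == "tsv":
        values, missing, individual_ids, locus_ids = _load_tsv(path)
    elif format == "vcf":
        values, missing, individual_ids, locus_ids = _load_vcf(path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    if popmap is None:
        if popmap_path is None:
            raise ValueError("a population map is required")
        popmap = load_population_map(popmap_path)
    unassigned = [i for i in individual_ids if i not in popmap]
    if unassigned:
        raise ValueError(f"individuals absent from population map: {unassigned[:5]}")
    populations = [popmap[i] for i in individual_ids]
    return GenotypeMatrix(values, missing, individual_ids, populations, locus_ids)


def write_genotype_tsv(G: GenotypeMatrix, path, missing_code: str = "NA") -> None:
    """Write the canonical genotype TSV (inverse of the tsv reader)."""
    cells = G.values.astype(object).T  # loci x individuals
    cells[G.missing.T] = missing_code
    df = pd.DataFrame(cells, columns=G.individual_ids)
    df.insert(0, "locus_id", G.locus_ids)
    df.to_csv(path, sep="\t", index=False)


def filter_missing_individuals(
    G: GenotypeMatrix, max_missing_fraction: float = 0.05
) -> tuple[GenotypeMatrix, list[str]]:
    """Remove individuals with strictly more missing data than the threshold.

    The cutoff is strict ("more than 5%"): an individual at exactly the
    threshold is retained.  Order of retained individuals is preserved.
    """
    if not (0 <= max_missing_fraction < 1):
        raise ValueError("max_missing_fraction must be in [0, 1)")
    frac = G.missing_fraction()
    keep = np.flatnonzero(frac <= max_missing_fraction)
    removed = [G.individual_ids[i] for i in np.flatnonzero(frac > max_missing_fraction)]
    if keep.size == 0:
        raise ValueError("all individuals exceed the missing-data threshold")
    if not removed:
        return G, []
    return G.take_individuals(keep), removed


def iterative_outlier_removal(
    G: GenotypeMatrix, sd_threshold: float = 10.0, n_pcs: int = 10
) -> tuple[GenotypeMatrix, QCReport]:
    """Iteratively remove PCA outliers until a pass flags nobody.

    Each pass standardizes the current matrix, runs PCA, and flags any
    individual whose score on at least one of the top ``min(n_pcs, n-1)``
    PCs lies more than ``sd_threshold`` sample standard deviations from that
    PC's mean.  Flagged individuals are removed and the pass repeats; the
    report records removals per iteration.
    """
    from .pca import run_pca, standardize

    report = QCReport()
    current = G
    while True:
        report.iterations += 1
        S = standardize(current)
        if S.monomorphic_mask.all():
            raise ValueError("degenerate matrix: all loci monomorphic")
        pca = run_pca(S)
        k = min(n_pcs, pca.scores.shape[1])
        scores = pca.scores[:, :k]
        mean = scores.mean(axis=0)
        sd = scores.std(axis=0, ddof=1)
        sd[sd == 0] = np.inf
        z = np.abs(scores - mean) / sd
        flagged = np.flatnonzero((z > sd_threshold).any(axis=1))
        if flagged.size == 0:
            return current, report
        for i in flagged:
            report.removed_outliers.append((report.iterations, current.individual_ids[i]))
        keep = np.setdiff1d(np.arange(current.n_individuals), flagged)
        if keep.size < 3:
            raise ValueError("outlier removal would leave fewer than 3 individuals")
        current = current.take_individuals(keep)


def subsample_loci(G: GenotypeMatrix, L_sub: int, seed: int) -> GenotypeMatrix:
    """Restrict to ``L_sub`` loci drawn uniformly without replacement.

    The selection depends only on ``(seed, L_sub, L)``, so the same marker
    subset can be reused across datasets sharing locus IDs and their results
    stay comparable.
    """
    L = G.n_loci
    if not (1 <= L_sub <= L):
        raise ValueError(f"L_sub must be in [1, {L}], got {L_sub}")
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(L, size=L_sub, replace=False))
    return GenotypeMatrix(
        values=G.values[:, chosen],
        missing=G.missing[:, chosen],
        individual_ids=G.individual_ids,
        populations=G.populations,
        locus_ids=[G.locus_ids[j] for j in chosen],
    )
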