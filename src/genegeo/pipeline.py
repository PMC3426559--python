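"""End-to-end region analysis: QC -> PCA -> Procrustes -> permutation test,
with optional leave-one-out, marker-curve, and FST stages.

:func:`analyze_dataset` is the in-memory core; :func:`run_region_analysis`
wraps it with file I/O driven by a :class:`RegionConfig` (loadable from
YAML), producing a JSON report plus TSV side outputs.  The report carries
the same column schema as a per-region summary table: sample counts before
and after QC, variance explained by PC1/PC2, t0, rotation angle, p-value
and FST.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fst import weir_cockerham_fst
from .genotype import (GenotypeMatrix, filter_missing_individuals,
                       iterative_outlier_removal, load_genotype_matrix)
from .geo import (GeoTable, expand_to_individuals, gall_peters_project,
                  load_geo_table, shift_americas)
from .inference import leave_one_out, marker_curve, permutation_test
from .pca import run_pca, standardize
from .procrustes import procrustes_fit

__all__ = ["RegionConfig", "RegionReport", "analyze_dataset",
           "run_region_analysis", "prepare_geo"]


@dataclass
class RegionConfig:
    """Configuration of one region-style analysis (YAML-serializable)."""

    genotype_path: str
    popmap_path: str
    coords_path: str
    genotype_format: str = "tsv"
    projection: str = "unprojected"       # "unprojected" | "gall_peters"
    shift_threshold: float = -40.0        # Americas shift, worldwide only
    max_missing: float = 0.05
    outlier_sd: float = 10.0
    outlier_pcs: int = 10
    permutations: int = 100_000
    seed: int = 0
    allow_reflection: bool = True
    run_leave_one_out: bool = False
    marker_curve_L: list[int] = field(default_factory=list)
    run_fst: bool = True
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RegionConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class RegionReport:
    n_individuals_input: int
    n_removed_high_missing: int
    n_removed_outliers: int
    n_individuals_analyzed: int
    n_populations: int
    n_loci: int
    removed_high_missing: list[str]
    removed_outliers: list[tuple[int, str]]
    qc_iterations: int
    variance_explained_pc1_pct: float
    variance_explained_pc2_pct: float
    t0: float
    rotation_deg: float
    reflection_used: bool
    p_value: float
    p_value_display: str
    fst_pct: float | None = None
    leave_one_out: list[dict] | None = None
    marker_curve: dict | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def prepare_geo(geo: GeoTable, projection: str,
                shift_threshold: float = -40.0) -> GeoTable:
    """Apply the worldwide coordinate convention if requested: shift the
    Americas east, then Gall-Peters project.  Regional analyses keep
    unprojected (lon, lat)."""
    if projection == "gall_peters":
        return gall_peters_project(shift_americas(geo, threshold_lon=shift_threshold))
    if projection != "unprojected":
        raise ValueError(f"unknown projection {projection!r}")
    return geo


def analyze_dataset(G: GenotypeMatrix, geo: GeoTable, *,
                    max_missing: float = 0.05,
                    outlier_sd: float = 10.0,
                    outlier_pcs: int = 10,
                    permutations: int = 100_000,
                    seed: int = 0,
                    allow_reflection: bool = True,
                    run_loo: bool = False,
                    marker_curve_L: list[int] | None = None,
                    run_fst: bool = True) -> RegionReport:
    """Run the full analysis on an in-memory dataset.

    ``geo`` must already carry the desired planar convention (projected for
    worldwide, unprojected for regional) — see :func:`prepare_geo`.
    """
    n_input = G.n_individuals
    G1, removed_missing = filter_missing_individuals(G, max_missing)
    G2, qc = iterative_outlier_removal(G1, sd_threshold=outlier_sd, n_pcs=outlier_pcs)

    pca = run_pca(standardize(G2))
    X_geo = expand_to_individuals(geo, G2)
    fit = procrustes_fit(X_geo, pca.pc12, allow_reflection=allow_reflection)
    perm = permutation_test(pca.pc12, geo, G2, N=permutations, seed=seed,
                            allow_reflection=allow_reflection)

    report = RegionReport(
        n_individuals_input=n_input,
        n_removed_high_missing=len(removed_missing),
        n_removed_outliers=len(qc.removed_outliers),
        n_individuals_analyzed=G2.n_individuals,
        n_populations=len(G2.unique_populations()),
        n_loci=G2.n_loci,
        removed_high_missing=removed_missing,
        removed_outliers=qc.removed_outliers,
        qc_iterations=qc.iterations,
        variance_explained_pc1_pct=100.0 * float(pca.variance_explained[0]),
        variance_explained_pc2_pct=100.0 * float(pca.variance_explained[1]),
        t0=fit.t0,
        rotation_deg=fit.rotation_deg,
        reflection_used=fit.reflection_used,
        p_value=perm.p_value,
        p_value_display=perm.p_value_display,
    )
    if run_fst:
        report.fst_pct = 100.0 * weir_cockerham_fst(G2).theta
    if run_loo:
        report.leave_one_out = [dataclasses.asdict(r)
                                for r in leave_one_out(G2, geo, allow_reflection)]
    if marker_curve_L:
        curve = marker_curve(G2, geo, marker_curve_L, seed=seed,
                             allow_reflection=allow_reflection)
        report.marker_curve = {"L_values": curve.L_values, "t0_at_L": curve.t0_at_L}
    return report


def run_region_analysis(cfg: RegionConfig) -> RegionReport:
    """File-driven pipeline: load inputs, analyze, write report artifacts."""
    G = load_genotype_matrix(cfg.genotype_path, format=cfg.genotype_format,
                             popmap_path=cfg.popmap_path)
    geo = prepare_geo(load_geo_table(cfg.coords_path), cfg.projection,
                      cfg.shift_threshold)
    report = analyze_dataset(
        G, geo,
        max_missing=cfg.max_missing,
        outlier_sd=cfg.outlier_sd,
        outlier_pcs=cfg.outlier_pcs,
        permutations=cfg.permutations,
        seed=cfg.seed,
        allow_reflection=cfg.allow_reflection,
        run_loo=cfg.run_leave_one_out,
        marker_curve_L=cfg.marker_curve_L or None,
        run_fst=cfg.run_fst,
    )
    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)
        if report.leave_one_out:
            pd.DataFrame(report.leave_one_out).to_csv(
                out / "leave_one_out.tsv", sep="\t", index=False)
        if report.marker_curve:
            pd.DataFrame(report.marker_curve).to_csv(
                out / "marker_curve.tsv", sep="\t", index=False)
    return report
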