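"""Genotype container, file readers, and sample-level QC."""

import numpy as np
import pytest

from genegeo import (GenotypeMatrix, filter_missing_individuals,
                     iterative_outlier_removal, load_genotype_matrix,
                     simulate_lattice_dataset, SimConfig, square_grid,
                     subsample_loci, write_genotype_tsv)


def write_popmap(path, ids, pops):
    lines = ["individual_id\tpopulation"] + [f"{i}\t{p}" for i, p in zip(ids, pops)]
    path.write_text("\n".join(lines) + "\n")


class TestContainer:
    def test_rejects_non_diploid_code(self):
        with pytest.raises(ValueError, match="non-diploid"):
            GenotypeMatrix(np.array([[0, 3], [1, 2]]), np.zeros((2, 2), bool),
                           ["a", "b"], ["p", "p"], ["l1", "l2"])

    def test_rejects_duplicate_ids(self):
        with pytest.raises(ValueError, match="duplicate"):
            GenotypeMatrix(np.zeros((2, 1), int), np.zeros((2, 1), bool),
                           ["a", "a"], ["p", "p"], ["l1"])

    def test_population_map_property(self, tiny_matrix):
        assert tiny_matrix.population_of == {"a": "p1", "b": "p1", "c": "p2"}
        assert tiny_matrix.unique_populations() == ["p1", "p2"]


class TestIO:
    def test_tsv_with_na_cell(self, tmp_path):
        (tmp_path / "g.tsv").write_text(
            "locus_id\ti1\ti2\ti3\nl1\t0\t1\t2\nl2\t2\tNA\t0\n")
        write_popmap(tmp_path / "pm.tsv", ["i1", "i2", "i3"], ["x", "x", "y"])
        G = load_genotype_matrix(tmp_path / "g.tsv", popmap_path=tmp_path / "pm.tsv")
        assert G.missing.sum() == 1
        assert G.missing[1, 1]
        assert G.values[0, 0] == 0 and G.values[2, 0] == 2

    def test_unparseable_token_errors(self, tmp_path):
        (tmp_path / "g.tsv").write_text("locus_id\ti1\ti2\nl1\t0\tX\n")
        write_popmap(tmp_path / "pm.tsv", ["i1", "i2"], ["x", "x"])
        with pytest.raises(ValueError, match="unparseable"):
            load_genotype_matrix(tmp_path / "g.tsv", popmap_path=tmp_path / "pm.tsv")

    def test_individual_absent_from_popmap(self, tmp_path):
        (tmp_path / "g.tsv").write_text("locus_id\ti1\ti2\nl1\t0\t1\n")
        write_popmap(tmp_path / "pm.tsv", ["i1"], ["x"])
        with pytest.raises(ValueError, match="absent"):
            load_genotype_matrix(tmp_path / "g.tsv", popmap_path=tmp_path / "pm.tsv")

    def test_tsv_round_trip(self, tmp_path):
        cfg = SimConfig(grid=square_grid(2, 1), n_per_pop=5, L=50,
                        missing_rate=0.1, seed=3)
        G = simulate_lattice_dataset(cfg).genotypes
        write_genotype_tsv(G, tmp_path / "g.tsv")
        write_popmap(tmp_path / "pm.tsv", G.individual_ids, G.populations)
        G2 = load_genotype_matrix(tmp_path / "g.tsv", popmap_path=tmp_path / "pm.tsv")
        assert np.array_equal(G.missing, G2.missing)
        assert np.array_equal(G.values[~G.missing], G2.values[~G2.missing])
        assert G.individual_ids == G2.individual_ids
        assert G.locus_ids == G2.locus_ids

    def test_vcf_reader(self, tmp_path):
        vcf = (
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=1,length=1000>\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ti1\ti2\ti3\n"
            "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
            "1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t./.\t0/0\t0/1\n"
        )
        (tmp_path / "v.vcf").write_text(vcf)
        write_popmap(tmp_path / "pm.tsv", ["i1", "i2", "i3"], ["x", "x", "y"])
        G = load_genotype_matrix(tmp_path / "v.vcf", format="vcf",
                                 popmap_path=tmp_path / "pm.tsv")
        assert G.locus_ids == ["rs1", "rs2"]
        assert list(G.values[:, 0]) == [0, 1, 2]
        assert G.missing[0, 1] and not G.missing[1, 1]

    def test_vcf_triallelic_errors_naming_locus(self, tmp_path):
        vcf = (
            "##fileformat=VCFv4.2\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ti1\ti2\n"
            "1\t100\trs9\tA\tG,T\t.\tPASS\t.\tGT\t0/1\t1/2\n"
        )
        (tmp_path / "v.vcf").write_text(vcf)
        write_popmap(tmp_path / "pm.tsv", ["i1", "i2"], ["x", "x"])
        with pytest.raises(ValueError, match="rs9"):
            load_genotype_matrix(tmp_path / "v.vcf", format="vcf",
                                 popmap_path=tmp_path / "pm.tsv")


class TestMissingFilter:
    def make(self, fracs, L=100):
        """One individual per requested missing fraction."""
        n = len(fracs)
        rng = np.random.default_rng(0)
        values = rng.integers(0, 3, size=(n, L)).astype(np.int8)
        missing = np.zeros((n, L), bool)
        for i, f in enumerate(fracs):
            missing[i, : int(round(f * L))] = True
        return GenotypeMatrix(values, missing, [f"i{k}" for k in range(n)],
                              ["p"] * n, [f"l{j}" for j in range(L)])

    def test_strictly_above_threshold_removed_exact_retained(self):
        G = self.make([0.0, 0.05, 0.06])
        filtered, removed = filter_missing_individuals(G, 0.05)
        assert removed == ["i2"]
        assert filtered.individual_ids == ["i0", "i1"]

    def test_fully_observed_unchanged(self):
        G = self.make([0.0, 0.0, 0.0])
        filtered, removed = filter_missing_individuals(G)
        assert removed == [] and filtered is G

    def test_all_removed_errors(self):
        G = self.make([0.5, 0.5])
        with pytest.raises(ValueError, match="all individuals"):
            filter_missing_individuals(G, 0.05)

    def test_removal_preserves_retained_rows(self):
        G = self.make([0.0, 0.2, 0.0])
        filtered, _ = filter_missing_individuals(G)
        assert np.array_equal(filtered.values, G.values[[0, 2]])
        assert np.array_equal(filtered.missing, G.missing[[0, 2]])


def homogeneous_with_outliers(n=150, L=400, shifts=(), seed=5):
    """Homogeneous binomial matrix; individual i draws from frequencies
    shifted additively by shifts[i] on every locus (toward the farther
    allele-frequency boundary, so the displacement is full size)."""
    rng = np.random.default_rng(seed)
    base = rng.uniform(0.2, 0.8, size=L)
    direction = np.where(base <= 0.5, 1.0, -1.0)
    freqs = np.tile(base, (n, 1))
    for i, shift in enumerate(shifts):
        freqs[i] = np.clip(base + shift * direction, 0.01, 0.99)
    values = rng.binomial(2, freqs).astype(np.int8)
    return GenotypeMatrix(values, np.zeros((n, L), bool),
                          [f"i{k}" for k in range(n)], ["p"] * n,
                          [f"l{j}" for j in range(L)])


class TestOutlierRemoval:
    def test_homogeneous_matrix_is_clean(self):
        G = homogeneous_with_outliers()
        cleaned, report = iterative_outlier_removal(G)
        assert report.removed_outliers == []
        assert report.iterations == 1
        assert cleaned.n_individuals == G.n_individuals

    def test_planted_outlier_removed(self):
        G = homogeneous_with_outliers(n=200, L=1500, shifts=(0.45,))
        cleaned, report = iterative_outlier_removal(G)
        assert [iid for _, iid in report.removed_outliers] == ["i0"]
        assert "i0" not in cleaned.individual_ids

    def test_two_stage_cascade(self):
        # i0 is extreme; i1 shifts along the same direction but is masked by
        # i0's inflation of the per-PC standard deviation until i0 is gone
        G = homogeneous_with_outliers(n=200, L=4000, shifts=(0.45, 0.22))
        cleaned, report = iterative_outlier_removal(G)
        removed = [iid for _, iid in report.removed_outliers]
        assert set(removed) == {"i0", "i1"}
        assert report.iterations >= 3
        iter_of = dict((iid, it) for it, iid in report.removed_outliers)
        assert iter_of["i0"] < iter_of["i1"]

    def test_removal_is_pure_row_deletion(self):
        G = homogeneous_with_outliers(n=200, L=1500, shifts=(0.45,))
        cleaned, _ = iterative_outlier_removal(G)
        keep = [G.individual_ids.index(i) for i in cleaned.individual_ids]
        assert np.array_equal(cleaned.values, G.values[keep])

    def test_degenerate_all_monomorphic_errors(self):
        values = np.full((5, 4), 2, dtype=np.int8)
        G = GenotypeMatrix(values, np.zeros((5, 4), bool),
                           [f"i{k}" for k in range(5)], ["p"] * 5,
                           [f"l{j}" for j in range(4)])
        with pytest.raises(ValueError, match="monomorphic"):
            iterative_outlier_removal(G)


class TestSubsampleLoci:
    def test_full_subsample_is_identity(self, tiny_matrix):
        sub = subsample_loci(tiny_matrix, tiny_matrix.n_loci, seed=1)
        assert sub.locus_ids == tiny_matrix.locus_ids
        assert np.array_equal(sub.values, tiny_matrix.values)

    def test_deterministic_under_seed(self, structured_dataset):
        G = structured_dataset.genotypes
        a = subsample_loci(G, 1, seed=42)
        b = subsample_loci(G, 1, seed=42)
        assert a.locus_ids == b.locus_ids
        assert np.array_equal(a.values, b.values)

    def test_out_of_range_errors(self, tiny_matrix):
        with pytest.raises(ValueError):
            subsample_loci(tiny_matrix, 3, seed=0)

    def test_uniform_selection(self):
        values = np.zeros((2, 4), dtype=np.int8)
        G = GenotypeMatrix(values, np.zeros((2, 4), bool), ["a", "b"],
                           ["p", "p"], ["l0", "l1", "l2", "l3"])
        counts = {f"l{j}": 0 for j in range(4)}
        n_draws = 2000
        for s in range(n_draws):
            for lid in subsample_loci(G, 2, seed=s).locus_ids:
                counts[lid] += 1
        # each locus picked with prob 1/2; allow 3 binomial SEs
        se = np.sqrt(0.5 * 0.5 / n_draws)
        for lid, c in counts.items():
            assert abs(c / n_draws - 0.5) < 3 * se, lid


def test_qc_pipeline_idempotent():
    """Missing filter then outlier removal, run twice, changes nothing more."""
    G = homogeneous_with_outliers(n=200, L=1500, shifts=(0.45,), seed=9)
    G.missing[3, :225] = True  # 15% missing for one individual
    G1, removed = filter_missing_individuals(G)
    assert removed == ["i3"]
    G2, _ = iterative_outlier_removal(G1)
    G3, removed2 = filter_missing_individuals(G2)
    assert removed2 == []
    G4, rep = iterative_outlier_removal(G3)
    assert rep.removed_outliers == []
    assert G4.individual_ids == G2.individual_ids
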