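"""Plot data contracts: threshold classes, track tables, rare-variant track."""

import numpy as np
import pandas as pd
import pytest

from postgwas.formats_io import GeneModel, GwasResult, read_vcf_region
from postgwas.ld_core import ld_matrix
from postgwas.synthetic_fixtures import (
    FixtureSpec,
    simulate_gene_models,
    simulate_genotypes,
    simulate_gwas,
    write_toy_vcf,
)
from postgwas.visualization import (
    PlotError,
    RegionSpec,
    TrackLayout,
    classify_thresholds,
    manhattanplot,
    point_size,
    rare_variant_track,
    regionalplot,
)


def _gwas(rows, label="t"):
    return GwasResult(label, pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "p"]))


class TestTrackLayout:
    def test_bands_must_not_overlap(self):
        layout = TrackLayout()
        layout.add_track("a", 0.0, 0.5)
        with pytest.raises(ValueError):
            layout.add_track("b", 0.4, 0.8)

    def test_custom_band_reservable(self):
        layout = TrackLayout()
        layout.add_track("pvalues", 0.5, 1.0)
        layout.add_track("custom", 0.0, 0.4)
        assert layout.band("custom") == (0.0, 0.4)


class TestManhattan:
    def test_threshold_classification_matches_oracle(self):
        rng = np.random.default_rng(0)
        p = 10 ** rng.uniform(-12, 0, 1000)
        got = classify_thresholds(p)
        oracle = ["genomewide" if x < 5e-8 else "suggestive" if x < 1e-5 else "none"
                  for x in p]
        assert list(got) == oracle

    def test_genomewide_hit_labeled_with_covering_gene(self, tmp_path, two_gene_map):
        gwas = _gwas([("rs1", "1", 150, 1e-9), ("rs2", "1", 350, 0.5)])
        table = manhattanplot(gwas, tmp_path / "m.png", genes=two_gene_map)
        row = table.set_index("snp_id").loc["rs1"]
        assert row["threshold_class"] == "genomewide"
        assert row["label"] == "GENE1"

    def test_intergenic_hit_labeled_with_flanks(self, two_gene_map):
        gwas = _gwas([("rs1", "1", 250, 1e-9)])
        table = manhattanplot(gwas, genes=two_gene_map)
        assert table.loc[0, "label"] == "GENE1|GENE2"

    def test_no_hits_no_labels(self, two_gene_map):
        gwas = _gwas([("rs1", "1", 150, 0.2), ("rs2", "1", 350, 0.5)])
        table = manhattanplot(gwas, genes=two_gene_map)
        assert (table["label"] == "").all()
        assert (table["threshold_class"] == "none").all()

    def test_snp_id_annotation_mode(self):
        gwas = _gwas([("rs1", "1", 150, 1e-9)])
        table = manhattanplot(gwas, annotate="snp_ids")
        assert table.loc[0, "label"] == "rs1"

    def test_suggestive_class_between_thresholds(self):
        gwas = _gwas([("rs1", "1", 100, 1e-6)])
        assert manhattanplot(gwas).loc[0, "threshold_class"] == "suggestive"

    def test_empty_results_raise(self):
        empty = GwasResult("t", pd.DataFrame(columns=["snp_id", "chrom", "pos", "p"]))
        with pytest.raises(PlotError):
            manhattanplot(empty)

    def test_equal_p_equal_point_size(self):
        assert point_size(1e-6) == point_size(1e-6)
        assert point_size(1e-8) > point_size(1e-4)


@pytest.fixture
def region_setup(tmp_path):
    spec = FixtureSpec(n_samples=120, blocks=[(30, 0.7), (30, 0.2)], n_genes=4, seed=5)
    genotypes = simulate_genotypes(spec)
    genes = simulate_gene_models(spec)
    gwas = simulate_gwas(spec, genes, dataset_label="discovery")
    gwas2 = simulate_gwas(FixtureSpec(**{**spec.__dict__, "seed": 6}), genes,
                          dataset_label="replication")
    return spec, genotypes, genes, gwas, gwas2


class TestRegionalPlot:
    def test_two_datasets_two_line_tables(self, tmp_path, region_setup):
        spec, genotypes, genes, gwas, gwas2 = region_setup
        region = RegionSpec("1", 100_000, 160_000, [gwas, gwas2], genes, genotypes)
        (tables,) = regionalplot([region], tmp_path / "r.pdf")
        assert set(tables["pvalues"]["dataset"]) == {"discovery", "replication"}

    def test_ld_table_is_upper_triangle_after_interleaving(self, tmp_path, region_setup):
        spec, genotypes, genes, gwas, _ = region_setup
        region = RegionSpec("1", 100_000, 220_000, [gwas], genes, genotypes,
                            max_ld_snps=20)
        (tables,) = regionalplot([region], tmp_path / "r.pdf")
        assert len(tables["ld"]) == 20 * 19 / 2
        # exact agreement with ld_matrix on the same interleaved subset
        snps = sorted(set(tables["ld"]["snp_a"]) | set(tables["ld"]["snp_b"]),
                      key=lambda s: int(s[2:]))
        expect = ld_matrix(genotypes, snps).upper_triangle()
        pd.testing.assert_frame_equal(
            tables["ld"].reset_index(drop=True), expect.reset_index(drop=True))

    def test_intergenic_window_renders_empty_gene_track(self, tmp_path, region_setup):
        spec, genotypes, genes, gwas, _ = region_setup
        region = RegionSpec("1", 100_000, 104_000, [gwas], genes=[], genotypes=genotypes)
        (tables,) = regionalplot([region], tmp_path / "r.pdf")
        assert tables["genes"].empty
        assert not tables["pvalues"].empty

    def test_region_without_snps_raises(self, tmp_path, region_setup):
        spec, genotypes, genes, gwas, _ = region_setup
        region = RegionSpec("9", 1, 100, [gwas], genes, genotypes)
        with pytest.raises(PlotError):
            regionalplot([region], tmp_path / "r.pdf")

    def test_multiple_regions_yield_multipage_pdf(self, tmp_path, region_setup):
        spec, genotypes, genes, gwas, _ = region_setup
        regions = [
            RegionSpec("1", 100_000, 140_000, [gwas], genes, genotypes),
            RegionSpec("1", 150_000, 200_000, [gwas], genes, genotypes),
        ]
        out = tmp_path / "multi.pdf"
        tables = regionalplot(regions, out)
        assert len(tables) == 2
        data = out.read_bytes()
        # one /Type /Page object per page (minus the /Pages tree node)
        n_pages = data.count(b"/Type /Page") - data.count(b"/Type /Pages")
        assert n_pages == 2

    def test_custom_panel_hook_receives_region_and_layout(self, tmp_path, region_setup):
        spec, genotypes, genes, gwas, _ = region_setup
        seen = {}

        def hook(region, track_layout, tables, ax):
            seen["region"] = region
            seen["tracks"] = [r[0] for r in track_layout.rows]

        region = RegionSpec("1", 100_000, 140_000, [gwas], genes, genotypes)
        regionalplot([region], tmp_path / "r.pdf", panel_fn=hook,
                     extra_tracks=[("custom", -0.2, -0.05)])
        assert seen["region"] == ("1", 100_000, 140_000)
        assert "custom" in seen["tracks"]

    def test_panel_hook_errors_propagate_with_context(self, tmp_path, region_setup):
        spec, genotypes, genes, gwas, _ = region_setup

        def bad_hook(**kwargs):
            raise RuntimeError("boom")

        region = RegionSpec("1", 100_000, 140_000, [gwas], genes, genotypes)
        with pytest.raises(PlotError, match="boom"):
            regionalplot([region], tmp_path / "r.pdf", panel_fn=bad_hook)

    def test_more_than_two_vcfs_rejected(self):
        with pytest.raises(ValueError):
            RegionSpec("1", 1, 100, vcf_paths=["a", "b", "c"])


class TestRareVariantTrack:
    def _variants(self, tmp_path, **kw):
        vcf = write_toy_vcf(tmp_path / "t.vcf", **kw)
        return read_vcf_region(vcf, "1", 1, 10**9)

    def test_one_bar_per_variant_without_filters(self, tmp_path):
        track = rare_variant_track(self._variants(tmp_path))
        assert len(track) == 5
        assert list(track["af"]) == pytest.approx([0.0, 0.001, 0.005, 0.02, 0.3], rel=1e-4)

    def test_de_novo_filter_marks_matching_selected(self, tmp_path):
        recs = self._variants(tmp_path,
                              effects=("DE_NOVO", "KNOWN", "DE_NOVO", "KNOWN", "KNOWN"))
        track = rare_variant_track(recs, select_info_regex="DE_NOVO")
        assert int(track["selected"].sum()) == 2

    def test_comparative_mode_pairs_by_position_and_alleles(self, tmp_path):
        a = self._variants(tmp_path / "a" if False else tmp_path)
        b = read_vcf_region(write_toy_vcf(tmp_path / "b.vcf", afs=(0.02,),
                                          start_pos=100_000 + 3 * 5_000),
                            "1", 1, 10**9)
        track = rare_variant_track(a, b)
        paired = track[track["af_b"].notna()]
        assert len(paired) == 1
        assert paired.iloc[0]["af"] == pytest.approx(0.02, rel=1e-4)
        assert paired.iloc[0]["af_b"] == pytest.approx(0.02, rel=1e-4)

    def test_mismatched_minor_alleles_error(self, tmp_path):
        a = self._variants(tmp_path)
        # AF 0.8 folds to REF minor; same position as a's 4th variant (AF 0.02, ALT minor)
        b = read_vcf_region(write_toy_vcf(tmp_path / "b.vcf", afs=(0.8,),
                                          start_pos=100_000 + 3 * 5_000),
                            "1", 1, 10**9)
        with pytest.raises(ValueError, match="minor alleles"):
            rare_variant_track(a, b)

    def test_effect_class_parsed_from_info(self, tmp_path):
        recs = self._variants(tmp_path,
                              effects=("NON_SYNONYMOUS_CODING", "SYNONYMOUS_CODING",
                                       "INTERGENIC", "STOP_GAINED", "INTRON"))
        track = rare_variant_track(recs, effect_class_map=[
            (r"NON_SYNONYMOUS|STOP_GAINED", "damaging"),
            (r"SYNONYMOUS", "silent"),
        ])
        assert list(track["effect_class"]) == ["damaging", "silent", "", "damaging", ""]
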