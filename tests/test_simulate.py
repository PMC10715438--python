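"""Synthetic generator: geometry, Poisson sampling, seeding, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pvniche import (
    SimulationConfig,
    classify_cells,
    detect_clusters,
    generate_cohort,
    generate_roi_geometry,
    phenotype_table,
    sample_cells,
    seed_clusters,
)
from pvniche.io import sha256_of
from pvniche.simulate import RoiContext


def small_config(**kw) -> SimulationConfig:
    base = dict(
        seed=5, n_tumors_per_group=1, rois_per_tumor=1,
        roi_width_um=300.0, roi_height_um=300.0, pixel_size_um=1.0,
        n_vessels_per_roi=2,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw", [{"tci_fraction": 1.5}, {"rois_per_tumor": 0},
               {"n_vessels_per_roi": -1},
               {"phenotype_intensities": {"TAM": {"stroma": -5.0}}},
               {"pv_enrichment": {"TAM": -1.0}}],
    )
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            small_config(**kw)

    def test_expected_intensity_composition(self):
        cfg = small_config(
            pv_enrichment={"TAM": 3.0},
            group_effects={"NAC_DF": {"TAM": {"*": 2.0}}},
        )
        base = cfg.base_intensity("TAM", "stroma")
        assert cfg.expected_intensity("TAM", "STROMA_PV", "NAC_DF") == base * 3.0 * 2.0
        assert cfg.expected_intensity("TAM", "STROMA_NONPV", "NAC_DF") == base * 2.0
        assert cfg.expected_intensity("TAM", "STROMA_NONPV", "untreated_DF") == base


class TestGeometryGeneration:
    def test_zero_tci_fraction_all_stroma(self, rng):
        g = generate_roi_geometry(small_config(tci_fraction=0.0), rng)
        assert g.tci_polygons == []

    def test_zero_vessels_empty_pv_band(self, rng):
        from pvniche import compartment_areas

        g = generate_roi_geometry(small_config(n_vessels_per_roi=0), rng)
        a = compartment_areas(g, 50.0)
        assert a["STROMA_PV"] == 0.0 and a["TCI_PV"] == 0.0

    def test_tci_fraction_within_tolerance(self):
        cfg = small_config(tci_fraction=0.35)
        for seed in range(4):
            g = generate_roi_geometry(cfg, np.random.default_rng(seed))
            frac = sum(p.area for p in g.tci_polygons) / (300.0 * 300.0)
            assert 0.8 * 0.35 <= frac <= 1.2 * 0.35

    def test_vessels_in_stroma(self, rng):
        g = generate_roi_geometry(small_config(n_vessels_per_roi=3), rng)
        assert len(g.vessel_polygons) == 3
        for v in g.vessel_polygons:
            assert v.intersection(g.tci_union).area == 0.0

    def test_deterministic_given_seed(self):
        cfg = small_config()
        g1 = generate_roi_geometry(cfg, np.random.default_rng(7))
        g2 = generate_roi_geometry(cfg, np.random.default_rng(7))
        assert [p.wkt for p in g1.tci_polygons] == [p.wkt for p in g2.tci_polygons]
        assert [p.wkt for p in g1.vessel_polygons] == [p.wkt for p in g2.vessel_polygons]


class TestSampleCells:
    def test_poisson_mean_on_uniform_roi(self, rng):
        """100 cells/mm² on a 1 mm² all-stroma ROI lands in the Poisson
        99% interval around 100."""
        cfg = small_config(
            roi_width_um=1000.0, roi_height_um=1000.0, tci_fraction=0.0,
            n_vessels_per_roi=0,
            phenotype_intensities={"TAM": {"stroma": 100.0, "tci": 0.0}},
        )
        g = generate_roi_geometry(cfg, rng)
        cells, _ = sample_cells(g, cfg, "untreated_DF", rng)
        lo, hi = sps.poisson.interval(0.99, 100)
        assert lo <= len(cells) <= hi

    def test_no_cell_inside_vessel(self, rng):
        cfg = small_config(n_vessels_per_roi=4)
        g = generate_roi_geometry(cfg, rng)
        cells, _ = sample_cells(g, cfg, "untreated_DF", rng)
        assert not g.contains_vessel(
            cells["x_um"].to_numpy(), cells["y_um"].to_numpy()
        ).any()

    def test_markers_gate_back_to_generating_phenotype(self, rng):
        """Round trip: the gating module recovers every generated label."""
        cfg = small_config()
        g = generate_roi_geometry(cfg, rng)
        cells, _ = sample_cells(g, cfg, "NAC_DF", rng)
        labeled, qc = phenotype_table(cells)
        assert (labeled["label"] == labeled["true_phenotype"]).all()
        assert sum(qc.values()) == 0

    def test_no_enrichment_gives_unit_pv_ratio(self):
        """With ρ=1 everywhere the PV and non-PV densities agree."""
        cfg = small_config(
            tci_fraction=0.0,
            pv_enrichment={},
            phenotype_intensities={"TAM": {"stroma": 300.0, "tci": 0.0}},
        )
        counts = {"STROMA_PV": 0, "STROMA_NONPV": 0}
        areas = {"STROMA_PV": 0.0, "STROMA_NONPV": 0.0}
        for seed in range(100):
            rng = np.random.default_rng(seed)
            g = generate_roi_geometry(cfg, rng)
            ctx = RoiContext.build(g, cfg.pv_threshold_um)
            cells, _ = sample_cells(g, cfg, "untreated_DF", rng, context=ctx)
            comp = classify_cells(cells, g, cfg.pv_threshold_um)
            for c in counts:
                counts[c] += int((comp == c).sum())
                areas[c] += ctx.areas.areas_mm2[c]
        ratio = (counts["STROMA_PV"] / areas["STROMA_PV"]) / (
            counts["STROMA_NONPV"] / areas["STROMA_NONPV"]
        )
        # ~3σ band for the Poisson count ratio at this sample size
        assert ratio == pytest.approx(1.0, rel=0.12)

    def test_ground_truth_records_expected_densities(self, rng):
        cfg = small_config(pv_enrichment={"TAM": 2.0})
        g = generate_roi_geometry(cfg, rng)
        _, truth = sample_cells(g, cfg, "untreated_DF", rng)
        assert truth.expected_density["TAM"]["STROMA_PV"] == pytest.approx(
            2.0 * cfg.base_intensity("TAM", "stroma")
        )
        assert sum(truth.areas_mm2.values()) == pytest.approx(g.area_mm2, rel=0.005)


class TestSeedClusters:
    def test_zero_clusters_is_identity(self, rng):
        cfg = small_config(n_seeded_clusters_per_roi=0)
        g = generate_roi_geometry(cfg, rng)
        cells, _ = sample_cells(g, cfg, "untreated_DF", rng)
        out, recs = seed_clusters(g, cells, cfg, "untreated_DF", rng)
        assert len(out) == len(cells) and recs == []

    def test_members_perivascular_and_in_contact(self, rng):
        cfg = small_config(n_seeded_clusters_per_roi=4)
        g = generate_roi_geometry(cfg, rng)
        cells, _ = sample_cells(g, cfg, "untreated_DF", rng)
        out, recs = seed_clusters(g, cells, cfg, "untreated_DF", rng)
        assert len(recs) == 4
        for rec in recs:
            members = out[out["cell_id"].isin(rec["member_ids"])]
            comp = classify_cells(members, g, cfg.pv_threshold_um)
            assert (comp == "STROMA_PV").all()
            xy = members[["x_um", "y_um"]].to_numpy()
            d = np.sqrt(((xy[:, None] - xy[None, :]) ** 2).sum(-1))
            assert d.max() <= cfg.contact_threshold_um

    def test_detector_finds_all_seeded(self, rng):
        cfg = small_config(n_seeded_clusters_per_roi=5)
        g = generate_roi_geometry(cfg, rng)
        cells, _ = sample_cells(g, cfg, "untreated_DF", rng)
        out, recs = seed_clusters(g, cells, cfg, "untreated_DF", rng)
        labeled, _ = phenotype_table(out)
        detected = detect_clusters(labeled, g, cfg.contact_threshold_um,
                                   cfg.pv_threshold_um)
        found = set(zip(detected["tam_id"], detected["tcell_id"], detected["treg_id"]))
        for rec in recs:
            assert tuple(rec["member_ids"]) in found
        assert len(detected) >= 5

    def test_no_pv_stroma_is_error(self, rng):
        cfg = small_config(n_vessels_per_roi=0, n_seeded_clusters_per_roi=1)
        g = generate_roi_geometry(cfg, rng)
        cells, _ = sample_cells(g, cfg, "untreated_DF", rng)
        with pytest.raises(RuntimeError, match="no perivascular stroma"):
            seed_clusters(g, cells, cfg, "untreated_DF", rng)


class TestGenerateCohort:
    def test_file_counts(self, tmp_path):
        cfg = small_config(n_tumors_per_group=2, rois_per_tumor=3)
        generate_cohort(cfg, out_dir=tmp_path / "s")
        assert len(list((tmp_path / "s" / "cells").glob("*.csv"))) == 4 * 2 * 3
        assert len(list((tmp_path / "s" / "geometry").glob("*.json"))) == 24
        assert (tmp_path / "s" / "manifest.csv").exists()

    def test_byte_identical_across_runs(self, tmp_path):
        cfg = small_config(n_tumors_per_group=1, rois_per_tumor=2,
                           n_seeded_clusters_per_roi=1)
        generate_cohort(cfg, out_dir=tmp_path / "a")
        generate_cohort(cfg, out_dir=tmp_path / "b")
        a_files = sorted((tmp_path / "a").rglob("*.*"))
        b_files = sorted((tmp_path / "b").rglob("*.*"))
        assert [f.name for f in a_files] == [f.name for f in b_files]
        for fa, fb in zip(a_files, b_files):
            assert sha256_of(fa) == sha256_of(fb), fa.name

    def test_round_trip_through_study_dir(self, tmp_path):
        from pvniche import load_study

        cfg = small_config(n_tumors_per_group=1, rois_per_tumor=1)
        bundle = generate_cohort(cfg, out_dir=tmp_path / "s")
        back = load_study(tmp_path / "s")
        assert set(back.cells) == set(bundle.cells)
        key = next(iter(bundle.cells))
        pd.testing.assert_series_equal(
            back.cells[key]["CD163"], bundle.cells[key]["CD163"], check_names=False
        )
        assert back.manifest.table.equals(bundle.manifest.table)
        assert back.ground_truth[key[0]][key[1]].areas_mm2 == pytest.approx(
            bundle.ground_truth[key[0]][key[1]].areas_mm2
        )

    def test_group_effect_shifts_only_target_group(self, small_cohort):
        gt = small_cohort.ground_truth
        cfg = small_cohort.config
        for tumor, rois in gt.items():
            for roi, tr in rois.items():
                grp = tumor.rsplit("_T", 1)[0]
                assert tr.expected_density["TAM"]["STROMA_NONPV"] == pytest.approx(
                    cfg.expected_intensity("TAM", "STROMA_NONPV", grp)
                )
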