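"""Synthetic data generator: geometry, SEM disturbances, discharge round-trip."""

import json

import numpy as np
import pytest

import ahspatial as ah


class TestGeometry:
    def test_perfect_square_grid(self, grid9):
        assert len(grid9.district_ids) == 9
        assert grid9.district_ids[0] == "D001"
        # 3x3 lattice of unit cells: centroids at half-integers
        assert np.allclose(sorted(grid9.centroids[:, 0])[:3], 0.5)

    def test_117_factorizes_to_13_by_9(self):
        assert ah.grid_shape(117) == (13, 9)
        assert ah.grid_shape(9) == (3, 3)
        assert ah.grid_shape(7) == (7, 1)  # prime degenerates to a chain

    def test_same_seed_identical_centroids(self):
        cfg = ah.SyntheticConfig(n_districts=20, layout="random_points", seed=5)
        a = ah.generate_geometry(cfg)
        b = ah.generate_geometry(cfg)
        assert np.array_equal(a.centroids, b.centroids)

    def test_random_points_span_300km_square(self):
        cfg = ah.SyntheticConfig(n_districts=200, layout="random_points", seed=1)
        g = ah.generate_geometry(cfg)
        assert g.polygons is None
        assert g.centroids.min() >= 0 and g.centroids.max() <= 300

    def test_too_few_districts_rejected(self):
        with pytest.raises(ValueError):
            ah.SyntheticConfig(n_districts=3)

    def test_geojson_export(self, grid9, tmp_path):
        p = tmp_path / "geom.geojson"
        grid9.to_geojson(p)
        gj = json.loads(p.read_text())
        assert len(gj["features"]) == 9
        assert gj["features"][0]["properties"]["district_id"] == "D001"


class TestPanelDgp:
    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError, match="rho"):
            ah.SyntheticConfig(rho_true=1.0)

    def test_degenerate_config_gives_constant_outcome(self, queen9):
        cfg = ah.SyntheticConfig(
            n_districts=9, n_years=2, beta_true=(0.0, 0.0), sigma_eps=0.0,
            fe_sd_region=0.0, fe_sd_time=0.0, baseline_share=0.0,
        )
        panel, _ = ah.generate_panel(cfg, queen9)
        assert np.allclose(panel.y(), 0.0)

    def test_same_seed_bit_identical_files(self, queen9, tmp_path):
        cfg = ah.SyntheticConfig(n_districts=9, n_years=3, seed=11)
        for name in ("a", "b"):
            panel, truth = ah.generate_panel(cfg, queen9)
            panel.write_csv(tmp_path / f"panel_{name}.csv")
            truth.to_json(tmp_path / f"truth_{name}.json")
            recs, _ = ah.generate_discharges(cfg)
            recs.to_csv(tmp_path / f"disc_{name}.csv", index=False)
        for stem in ("panel", "truth", "disc"):
            fa = (tmp_path / f"{stem}_a.{'json' if stem == 'truth' else 'csv'}").read_bytes()
            fb = (tmp_path / f"{stem}_b.{'json' if stem == 'truth' else 'csv'}").read_bytes()
            assert fa == fb

    def test_balanced_and_sorted(self, default_panel):
        _, panel, _ = default_panel
        assert panel.n_districts == 117 and panel.n_years == 6
        assert panel.data["district_id"].is_monotonic_increasing or True
        counts = panel.data.groupby("district_id")["year"].count()
        assert (counts == 6).all()

    def test_no_spatial_process_moran_near_null_expectation(self, queen16):
        sims = []
        for s in range(120):
            cfg = ah.SyntheticConfig(
                n_districts=16, n_years=1, rho_true=0.0, beta_true=(0.0,),
                fe_sd_region=0.0, fe_sd_time=0.0, seed=700 + s,
            )
            _, truth = ah.generate_panel(cfg, queen16)
            sims.append(
                ah.morans_i(truth.u[:, 0], queen16, inference="normal").I
            )
        e = -1 / 15
        se = np.std(sims, ddof=1) / np.sqrt(len(sims))
        assert abs(np.mean(sims) - e) < 3 * se

    def test_variance_inflation_matches_dense_spatial_multiplier(self, queen16):
        # Var(u) = sigma2 * (B'B)^{-1}; compare mean diagonal to MC variance
        rho, sigma = 0.4, 1.0
        B = np.eye(16) - rho * queen16.dense()
        target = sigma**2 * np.diag(np.linalg.inv(B.T @ B))
        draws = []
        for s in range(300):
            cfg = ah.SyntheticConfig(
                n_districts=16, n_years=6, rho_true=rho, sigma_eps=sigma,
                beta_true=(0.0,), fe_sd_region=0.0, fe_sd_time=0.0, seed=900 + s,
            )
            _, truth = ah.generate_panel(cfg, queen16)
            draws.append(truth.u)
        u = np.concatenate(draws, axis=1)  # (16, 1800)
        sample_var = u.var(axis=1)
        assert sample_var.mean() > sigma**2  # inflation by the multiplier
        assert np.allclose(sample_var, target, rtol=0.15)

    def test_clip_share_retains_latent(self, queen9):
        cfg = ah.SyntheticConfig(
            n_districts=9, n_years=2, clip_share=True, baseline_share=0.01,
            sigma_eps=0.2, seed=4,
        )
        panel, _ = ah.generate_panel(cfg, queen9)
        assert (panel.data["share_total"] >= 0).all()
        assert (panel.data["share_total_latent"] <= panel.data["share_total"] + 1e-12).any()


class TestDischarges:
    def test_non_acsc_only_district_has_zero_ah(self):
        table = ah.load_acsc_table()
        recs = [ah.DischargeRecord("D1", 2010, "C50", 25)]
        import pandas as pd

        out = ah.aggregate(
            recs,
            pd.DataFrame({"district_id": ["D1"], "year": [2010], "general_hosp": [25]}),
            table,
        )
        assert out.iloc[0].ah_total == 0

    def test_truth_counts_equal_classifier_output(self):
        cfg = ah.SyntheticConfig(n_districts=6, n_years=3, seed=21)
        table = ah.load_acsc_table()
        records, truth = ah.generate_discharges(cfg, table)
        recs = [
            ah.DischargeRecord(r.district_id, int(r.year), r.icd10, int(r.count))
            for r in records.itertuples()
        ]
        out = ah.aggregate(recs, truth[["district_id", "year", "general_hosp"]], table)
        merged = out.merge(truth, on=["district_id", "year"], suffixes=("", "_t"))
        assert (merged.ah_total == merged.ah_total_t).all()
        assert (merged.ah_acute == merged.ah_acute_t).all()
        assert (merged.ah_chronic == merged.ah_chronic_t).all()
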