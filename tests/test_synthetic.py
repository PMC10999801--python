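"""Synthetic biopsy generator: geometry, nuclei, rendering, fixture I/O."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import ielquant as iq
from ielquant.core import (
    BACKGROUND,
    CD3_POS,
    LAMINA_PROPRIA,
    SURFACE_EPITHELIUM,
)
from ielquant.stains import rgb_to_od
from ielquant.synthetic import (
    GenerationParams,
    generate_biopsy,
    generate_tissue_geometry,
    get_render_profile,
    place_nuclei,
    read_fixture,
    render,
    write_fixture,
)


def make_params(**kw) -> GenerationParams:
    base = dict(image_height_px=192, image_width_px=256, n_crypts=0, seed=7)
    base.update(kw)
    return GenerationParams(**base)


class TestParams:
    def test_json_round_trip_is_lossless(self):
        p = make_params(surface_iel_rate=12.5, band_thickness_um=2.0)
        assert GenerationParams.from_json(p.to_json()) == p

    @pytest.mark.parametrize(
        "field,value",
        [("um_per_px", 0.0), ("surface_iel_rate", -1.0), ("lp_cd3_density", -5.0), ("n_crypts", -1)],
    )
    def test_invalid_values_rejected(self, field, value):
        with pytest.raises(Exception):
            make_params(**{field: value})

    def test_unknown_stain_profile_rejected(self):
        with pytest.raises(Exception, match="stain_profile_id"):
            make_params(stain_profile_id="giemsa")


class TestGeometry:
    def test_no_crypts_gives_exactly_three_labels(self):
        geom = generate_tissue_geometry(make_params(n_crypts=0))
        assert set(np.unique(geom.compartment_mask)) == {0, 1, 3}

    def test_zero_band_thickness_gives_empty_band(self):
        geom = generate_tissue_geometry(make_params(band_thickness_um=0.0))
        assert not geom.band_mask.any()

    def test_band_vertical_extent_matches_run_length_oracle(self):
        # 2 um at 0.5 um/px: every column with surface should carry a 4-px run
        geom = generate_tissue_geometry(make_params(band_thickness_um=2.0, um_per_px=0.5))
        runs = geom.band_mask.sum(axis=0)
        assert np.all(np.abs(runs - 4) <= 1)
        assert np.median(runs) == 4

    def test_band_lies_directly_beneath_surface(self):
        geom = generate_tissue_geometry(make_params(band_thickness_um=2.0))
        rows, cols = np.nonzero(geom.band_mask)
        assert np.all(geom.compartment_mask[rows, cols] == LAMINA_PROPRIA)
        # first band row per column is the surface_bottom row
        first = pd.DataFrame({"c": cols, "r": rows}).groupby("c")["r"].min()
        assert np.all(first.to_numpy() == geom.surface_bottom[first.index.to_numpy()])

    def test_crypts_do_not_touch_top_lumen(self):
        geom = generate_tissue_geometry(make_params(n_crypts=2, image_width_px=384))
        for c in geom.crypts:
            assert c.row - c.ry > geom.surface_bottom.max()

    def test_unplaceable_crypts_raise(self):
        with pytest.raises(ValueError, match="crypts"):
            generate_tissue_geometry(make_params(n_crypts=40))

    def test_deterministic_given_seed(self):
        p = make_params(n_crypts=2, image_width_px=384)
        a = generate_tissue_geometry(p)
        b = generate_tissue_geometry(p)
        assert np.array_equal(a.compartment_mask, b.compartment_mask)
        assert np.array_equal(a.band_mask, b.band_mask)


class TestPlaceNuclei:
    def test_zero_rate_gives_zero_surface_positives(self):
        gt = generate_biopsy(make_params(surface_iel_rate=0.0))
        surf = gt.cells[gt.cells["compartment"] == "SURFACE"]
        assert (surf["true_class"] == CD3_POS).sum() == 0

    def test_cell_table_schema_and_compartments(self):
        gt = generate_biopsy(make_params(n_crypts=1, image_width_px=384))
        assert list(gt.cells.columns) == [
            "cell_id", "row_px", "col_px", "area_px", "true_class", "compartment",
        ]
        rr = gt.cells["row_px"].round().astype(int)
        cc = gt.cells["col_px"].round().astype(int)
        assert np.all(gt.compartment_mask[rr, cc] != BACKGROUND)

    def test_min_center_distance_enforced(self):
        gt = generate_biopsy(make_params(lp_cd3_density=800, n_crypts=1, image_width_px=384))
        pts = gt.cells[["row_px", "col_px"]].to_numpy()
        from scipy.spatial import cKDTree

        d, _ = cKDTree(pts).query(pts, k=2)
        assert d[:, 1].min() >= gt.params.min_center_dist_px - 1.5  # disc-raster resolution

    def test_unplaceable_density_raises(self):
        with pytest.raises(ValueError, match="unplaceable"):
            generate_biopsy(make_params(lp_cd3_density=50000.0))

    def test_lp_count_matches_poisson_oracle(self):
        # mean realized CD3+ count over seeds vs Poisson mean density*area
        density = 500.0
        counts, areas = [], []
        for seed in range(60):
            p = make_params(lp_cd3_density=density, lp_negative_density=0.0, seed=seed)
            gt = generate_biopsy(p)
            lp = gt.cells["compartment"] == "LAMINA_PROPRIA"
            counts.append(int((gt.cells[lp]["true_class"] == CD3_POS).sum()))
            areas.append((gt.compartment_mask == LAMINA_PROPRIA).sum() * p.um_per_px**2 / 1e6)
        mean_expected = density * np.mean(areas)
        se = np.sqrt(mean_expected / len(counts))  # Poisson variance = mean
        assert abs(np.mean(counts) - mean_expected) <= 3 * se

    def test_surface_rate_within_binomial_interval(self):
        # pooled positives across seeds vs exact binomial 99% interval at rate 10
        rate = 10.0
        pos = neg = 0
        seed = 0
        while pos + neg < 2000:
            gt = generate_biopsy(make_params(surface_iel_rate=rate, image_width_px=768, seed=seed))
            surf = gt.cells[gt.cells["compartment"] == "SURFACE"]["true_class"]
            pos += int((surf == CD3_POS).sum())
            neg += int((surf != CD3_POS).sum())
            seed += 1
        n = pos + neg
        p_true = rate / (100.0 + rate)
        lo, hi = sps.binom.ppf([0.005, 0.995], n, p_true)
        assert lo <= pos <= hi

    def test_deterministic_given_seed(self):
        p = make_params(n_crypts=1, image_width_px=384)
        pd.testing.assert_frame_equal(generate_biopsy(p).cells, generate_biopsy(p).cells)


class TestRender:
    def test_background_is_blank_at_full_intensity(self):
        p = make_params(noise_sd=0.0)
        gt = generate_biopsy(p)
        img = render(gt, "ihc_cd3")
        bg = gt.compartment_mask == BACKGROUND
        assert np.allclose(img.pixels[bg], 1.0)

    def test_stroma_matches_beer_lambert_closed_form(self):
        p = make_params(noise_sd=0.0, band_thickness_um=0.0, lp_cd3_density=0.0, lp_negative_density=0.0)
        gt = generate_biopsy(p)
        img = render(gt, "ihc_cd3")
        prof = get_render_profile("ihc_cd3")
        expected = 10.0 ** (-(prof.stain_profile.od_matrix @ prof.stroma_c))
        # a lamina propria pixel away from any nucleus
        lp = gt.compartment_mask == LAMINA_PROPRIA
        rr, cc = np.nonzero(lp)
        far = rr > gt.surface_bottom.max() + 20
        assert np.allclose(img.pixels[rr[far][0], cc[far][0]], expected, atol=1e-12)

    def test_unknown_profile_lists_known_ones(self, ground_truth):
        with pytest.raises(ValueError, match="ihc_cd3"):
            render(ground_truth, "giemsa")

    def test_render_deterministic(self, ground_truth):
        a = render(ground_truth, "ihc_cd3")
        b = render(ground_truth, "ihc_cd3")
        assert np.array_equal(a.pixels, b.pixels)

    def test_band_visible_on_connective_stain_invisible_on_he(self):
        """Mean band-region OD contrast vs adjacent stroma: ~0 under HE,
        strong under a connective stain (the HE-vs-special-stain dissociation)."""
        p = make_params(band_thickness_um=2.0, noise_sd=0.0)
        gt = generate_biopsy(p)
        eps = 0.02
        contrasts = {}
        for stain in ("he", "vg"):
            img = render(gt, stain)
            od = rgb_to_od(img).sum(axis=2)
            band = od[gt.band_mask].mean()
            below = np.zeros_like(gt.band_mask)
            shift = 8
            below[shift:, :] = gt.band_mask[:-shift, :]
            below &= gt.compartment_mask == LAMINA_PROPRIA
            contrasts[stain] = abs(band - od[below].mean())
        assert contrasts["he"] < eps
        assert contrasts["vg"] > 10 * eps


class TestFixtureIO:
    def test_round_trip(self, tmp_path, ground_truth, cd3_image):
        write_fixture(ground_truth, cd3_image, tmp_path, basename="t")
        gt2, img2 = read_fixture(tmp_path, basename="t")
        assert np.array_equal(gt2.compartment_mask, ground_truth.compartment_mask)
        assert np.array_equal(gt2.band_mask, ground_truth.band_mask)
        assert len(gt2.cells) == len(ground_truth.cells)
        assert gt2.params == ground_truth.params
        assert np.array_equal(img2.to_uint8(), cd3_image.to_uint8())

    def test_cell_csv_row_count(self, tmp_path, ground_truth, cd3_image):
        files = write_fixture(ground_truth, cd3_image, tmp_path)
        assert len(pd.read_csv(files["cells"])) == len(ground_truth.cells)
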