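"""Per-biopsy metrics: IELs/100, LP density, hotspot windows, band, diagnosis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ielquant.core import CD3_NEG, CD3_POS, LAMINA_PROPRIA, SURFACE_EPITHELIUM
from ielquant.quantify import (
    UndefinedMetricError,
    band_thickness,
    classify_mc,
    hotspot_count,
    iel_per_100,
    lp_density,
    order_surface_cells,
    quantify_biopsy,
)


def cell_table(pos=0, neg=0, compartment="SURFACE", start_col=0.0):
    n = pos + neg
    return pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "row_px": 10.0,
            "col_px": start_col + np.arange(n, dtype=float),
            "area_px": 29,
            "true_class": [CD3_POS] * pos + [CD3_NEG] * neg,
            "compartment": compartment,
        }
    )


def sequence_table(classes):
    n = len(classes)
    return pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "row_px": 0.0,
            "col_px": np.arange(n, dtype=float),
            "area_px": 1,
            "true_class": list(classes),
            "compartment": "SURFACE",
        }
    )


class TestIelPer100:
    @pytest.mark.parametrize("pos,neg,expected", [(5, 100, 5.0), (0, 37, 0.0), (8, 50, 16.0)])
    def test_arithmetic(self, pos, neg, expected):
        assert iel_per_100(cell_table(pos, neg), "SURFACE").per_100 == expected

    def test_zero_denominator_is_explicit_error(self):
        with pytest.raises(UndefinedMetricError):
            iel_per_100(cell_table(3, 0), "SURFACE")

    def test_invalid_compartment_rejected(self):
        with pytest.raises(ValueError, match="compartment"):
            iel_per_100(cell_table(1, 1), "LAMINA_PROPRIA")

    def test_alternative_denominator(self):
        r = iel_per_100(cell_table(5, 95), "SURFACE", denominator="pos_plus_neg")
        assert r.per_100 == 5.0

    @settings(deadline=None, max_examples=30)
    @given(pos=st.integers(0, 40), neg=st.integers(1, 200), k=st.integers(1, 5))
    def test_scale_invariance(self, pos, neg, k):
        a = iel_per_100(cell_table(pos, neg), "SURFACE").per_100
        b = iel_per_100(cell_table(pos * k, neg * k), "SURFACE").per_100
        assert a == pytest.approx(b)


class TestLpDensity:
    def _mask(self, n_lp_px, um_per_px):
        side = int(np.sqrt(n_lp_px))
        assert side * side == n_lp_px
        return np.full((side, side), LAMINA_PROPRIA, dtype=np.uint8)

    def test_100_cells_in_1mm2(self):
        # 100x100 px at 10 um/px = 1 mm^2
        mask = self._mask(10000, 10.0)
        cells = cell_table(pos=100, compartment="LAMINA_PROPRIA")
        cells["col_px"] = cells["col_px"] % 100
        r = lp_density(cells, mask, 10.0)
        assert r.density_per_mm2 == pytest.approx(100.0)
        assert r.area_mm2 == pytest.approx(1.0)

    def test_half_area_doubles_density(self):
        mask = self._mask(2500, 10.0)  # 0.25 mm^2
        cells = cell_table(pos=50, compartment="LAMINA_PROPRIA")
        cells["col_px"] = cells["col_px"] % 50
        assert lp_density(cells, mask, 10.0).density_per_mm2 == pytest.approx(200.0)

    def test_zero_area_rejected(self):
        with pytest.raises(UndefinedMetricError):
            lp_density(cell_table(1, 1), np.zeros((4, 4), dtype=np.uint8), 0.5)

    def test_area_bookkeeping_matches_pixel_count(self, ground_truth):
        r = lp_density(ground_truth.cells, ground_truth.compartment_mask, ground_truth.params.um_per_px)
        n_px = (ground_truth.compartment_mask == LAMINA_PROPRIA).sum()
        assert r.area_mm2 == pytest.approx(n_px * 0.25 / 1e6)


class TestHotspot:
    def test_clustered_positives_dominate(self):
        # 20 positives inside one 100-negative stretch, far more negatives total
        seq = [CD3_NEG] * 200 + [CD3_POS] * 20 + [CD3_NEG] * 100 + [CD3_NEG] * 200
        r = hotspot_count(sequence_table(seq), 100)
        assert r.per_100 == 20.0

    def test_window_larger_than_negatives_falls_back_to_global(self):
        r = hotspot_count(sequence_table([CD3_POS] + [CD3_NEG] * 50), 100)
        assert r.fallback
        assert r.per_100 == pytest.approx(100.0 / 50)

    def test_uniform_mixing_is_close_to_global(self):
        rng = np.random.default_rng(0)
        seq = np.where(rng.random(5000) < 0.05, CD3_POS, CD3_NEG)
        r = hotspot_count(sequence_table(seq), 100)
        glob = 100.0 * (seq == CD3_POS).sum() / (seq == CD3_NEG).sum()
        assert glob <= r.per_100 <= 3 * glob

    def test_small_window_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            hotspot_count(sequence_table([CD3_NEG] * 20), 5)

    def test_hotspot_at_least_global_property(self):
        """For N >= W(W+1) negatives the window maximum can never fall below
        the whole-compartment value."""
        from ielquant.experiments import hotspot_ordering_experiment

        assert hotspot_ordering_experiment(seed=123, n_configs=200) == 1.0

    def test_order_surface_cells_uses_column_order(self, ground_truth):
        ordered = order_surface_cells(ground_truth.cells)
        assert (ordered["compartment"] == "SURFACE").all()
        assert ordered["col_px"].is_monotonic_increasing


class TestBandThickness:
    def _mask_with_surface(self, h=40, w=30, surf_rows=(5, 10)):
        mask = np.full((h, w), LAMINA_PROPRIA, dtype=np.uint8)
        mask[: surf_rows[0]] = 0
        mask[surf_rows[0] : surf_rows[1]] = SURFACE_EPITHELIUM
        return mask

    def test_no_band_gives_zero(self):
        mask = self._mask_with_surface()
        r = band_thickness(np.zeros(mask.shape, dtype=bool), mask, 0.5)
        assert r.thickness_um == 0

    @pytest.mark.parametrize("t_px,um_per_px", [(2, 0.5), (4, 0.5), (3, 1.0)])
    def test_flat_slab_closed_form(self, t_px, um_per_px):
        mask = self._mask_with_surface()
        ev = np.zeros(mask.shape, dtype=bool)
        ev[10 : 10 + t_px] = True
        r = band_thickness(ev, mask, um_per_px)
        assert r.thickness_um == round(t_px * um_per_px)

    def test_missing_surface_rejected(self):
        mask = np.full((10, 10), LAMINA_PROPRIA, dtype=np.uint8)
        with pytest.raises(ValueError, match="surface"):
            band_thickness(np.zeros((10, 10), dtype=bool), mask, 0.5)

    def test_generator_round_trip(self):
        from ielquant.synthetic import GenerationParams, generate_biopsy

        p = GenerationParams(image_height_px=192, image_width_px=256, n_crypts=0,
                             band_thickness_um=2.0, seed=3)
        gt = generate_biopsy(p)
        r = band_thickness(gt.band_mask, gt.compartment_mask, p.um_per_px)
        assert r.thickness_um == 2


class TestClassifyMC:
    @pytest.mark.parametrize(
        "iel,band,expected",
        [
            (25, 0, ("LC", "NORMAL")),
            (15, 7, ("LCi", "CCi")),
            (5, 1, ("NORMAL", "NORMAL")),
            (20, 10, ("LCi", "CCi")),  # closed upper endpoints → incomplete
            (10, 5, ("LCi", "CCi")),  # closed lower endpoints
            (20.01, 10.5, ("LC", "CC")),
            (9.99, 4.99, ("NORMAL", "NORMAL")),
        ],
    )
    def test_criteria(self, iel, band, expected):
        call = classify_mc(iel, band)
        assert (call.lymphocytic, call.collagenous) == expected

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            classify_mc(-1, 0)

    @settings(deadline=None, max_examples=50)
    @given(iel=st.floats(0, 40), band=st.floats(0, 20), d_iel=st.floats(0, 10), d_band=st.floats(0, 5))
    def test_monotone_never_towards_normal(self, iel, band, d_iel, d_band):
        order = {"NORMAL": 0, "LCi": 1, "LC": 2, "CCi": 1, "CC": 2}
        a = classify_mc(iel, band)
        b = classify_mc(iel + d_iel, band + d_band)
        assert order[b.lymphocytic] >= order[a.lymphocytic]
        assert order[b.collagenous] >= order[a.collagenous]


class TestQuantifyBiopsy:
    def test_row_internally_consistent(self, ground_truth):
        res = quantify_biopsy(
            ground_truth.cells, ground_truth.compartment_mask, ground_truth.params.um_per_px,
            band_evidence=ground_truth.band_mask, biopsy_id="b0", location="ILEUM",
        )
        row = res.to_row()
        assert row["surface_iel_per_100"] == pytest.approx(100 * row["surface_pos"] / row["surface_neg"])
        assert row["lp_density_per_mm2"] == pytest.approx(row["lp_pos_count"] / row["lp_area_mm2"])
        assert row["band_thickness_um"] == round(ground_truth.params.band_thickness_um)
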