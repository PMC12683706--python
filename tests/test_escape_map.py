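import numpy as np
import pandas as pd
import pytest

from escapes.escape_map import EScape, EScapeBuilder, IEITable, compute_hri, compute_iei, sample_hri
from escapes.habitat import edge_area
from escapes.raster import MARSH, OTHER, WATER, Raster

from .conftest import all_water


def make_iei_table(medians):
    summary = pd.DataFrame(
        {
            "source": ["phytoplankton", "benthic", "marsh"],
            "median": medians,
            "q25": medians,
            "q75": medians,
            "n_points": 1,
        }
    )
    return IEITable(points=pd.DataFrame(), summary=summary)


class TestComputeIEI:
    def test_ratio_arithmetic(self):
        # constant chlorophyll 0.34 on all-water: f_phyto = 0.34 everywhere,
        # so IEI_phyto = 0.68 / 0.34 = 2 exactly at every point
        hab, chl = all_water(n=40, chl_value=0.34)
        edge = edge_area(hab)
        iei = compute_iei(hab, chl, edge, (0.68, 0.23, 0.09), n_points=50, radius=80.0, seed=0)
        med = iei.summary.set_index("source")["median"]
        assert med["phytoplankton"] == pytest.approx(2.0, abs=1e-12)
        # marsh/benthic habitats absent: dropped per source, not infinite
        assert iei.dropped["marsh"] == 50
        assert iei.dropped["benthic"] == 50
        assert np.isnan(med["marsh"])

    def test_same_seed_reproducible(self, small_landscape):
        hab, chl = small_landscape
        edge = edge_area(hab)
        a = compute_iei(hab, chl, edge, (0.68, 0.23, 0.09), n_points=100, seed=42)
        b = compute_iei(hab, chl, edge, (0.68, 0.23, 0.09), n_points=100, seed=42)
        pd.testing.assert_frame_equal(a.points, b.points)

    def test_across_seed_stability(self, small_landscape):
        hab, chl = small_landscape
        edge = edge_area(hab)
        tables = [
            compute_iei(hab, chl, edge, (0.68, 0.23, 0.09), n_points=300, seed=s).summary.set_index("source")
            for s in (1, 2)
        ]
        for source in ("phytoplankton", "benthic", "marsh"):
            iqr = tables[0].loc[source, "q75"] - tables[0].loc[source, "q25"]
            spread = abs(tables[0].loc[source, "median"] - tables[1].loc[source, "median"])
            assert spread < iqr / 4

    def test_invalid_inputs(self, small_landscape):
        hab, chl = small_landscape
        edge = edge_area(hab)
        with pytest.raises(ValueError):
            compute_iei(hab, chl, edge, (0.9, 0.2, 0.1), n_points=10, seed=0)
        with pytest.raises(ValueError):
            compute_iei(hab, chl, edge, (0.68, 0.23, 0.09), n_points=0, seed=0)


class TestComputeHRI:
    def test_weighted_sum_against_hand_fractions(self):
        # one 100 m unit of 10x10 cells: 20 marsh cells, 80 water at chl
        # values summing to a known phytoplankton fraction
        vals = np.full((10, 10), WATER)
        vals[:2, :] = MARSH
        hab = Raster(vals, cell_size=10.0)
        chl = Raster(np.where(vals == WATER, 0.125, np.nan), cell_size=10.0)
        edge = edge_area(hab)
        f_marsh = 0.2
        f_phyto = 0.8 * 0.125
        f_edge = edge.values.sum() / (100 * 100.0)
        medians = np.array([6.2, 3.9, 0.5])
        esc = compute_hri(hab, chl, edge, make_iei_table(medians), unit=100.0)
        expected = 6.2 * f_phyto + 3.9 * f_edge + 0.5 * f_marsh
        assert esc.hri.values.shape == (1, 1)
        assert esc.hri.values[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_printed_arithmetic_example(self):
        # medians (6.2, 3.9, 0.5) with fractions (0.10, 0.05, 0.20) -> 0.915
        medians = np.array([6.2, 3.9, 0.5])
        fractions = np.array([0.10, 0.05, 0.20])
        assert float(medians @ fractions) == pytest.approx(0.915)

    def test_all_other_unit_is_zero(self):
        hab = Raster(np.full((10, 10), OTHER), cell_size=10.0)
        chl = Raster(np.full((10, 10), np.nan), cell_size=10.0)
        edge = edge_area(hab)
        esc = compute_hri(hab, chl, edge, make_iei_table([6.2, 3.9, 0.5]), unit=100.0)
        assert esc.hri.values[0, 0] == 0.0

    def test_unit_smaller_than_cell_rejected(self, small_landscape):
        hab, chl = small_landscape
        edge = edge_area(hab)
        with pytest.raises(ValueError):
            compute_hri(hab, chl, edge, make_iei_table([1, 1, 1]), unit=5.0)

    def test_linearity_in_medians(self, small_landscape):
        hab, chl = small_landscape
        edge = edge_area(hab)
        base = compute_hri(hab, chl, edge, make_iei_table([6.2, 3.9, 0.5]), unit=200.0)
        doubled = compute_hri(hab, chl, edge, make_iei_table([12.4, 3.9, 0.5]), unit=200.0)
        phyto_only = compute_hri(hab, chl, edge, make_iei_table([6.2, 0.0, 0.0]), unit=200.0)
        np.testing.assert_allclose(
            doubled.hri.values - base.hri.values, phyto_only.hri.values, atol=1e-12
        )

    def test_translation_invariance(self, small_landscape):
        hab, chl = small_landscape
        edge = edge_area(hab)
        table = make_iei_table([6.2, 3.9, 0.5])
        a = compute_hri(hab, chl, edge, table, unit=200.0)
        shift = 5 * hab.cell_size
        hab2 = Raster(hab.values, hab.cell_size, origin=(shift, shift))
        chl2 = Raster(chl.values, chl.cell_size, origin=(shift, shift))
        edge2 = Raster(edge.values, edge.cell_size, origin=(shift, shift))
        b = compute_hri(hab2, chl2, edge2, table, unit=200.0)
        np.testing.assert_allclose(a.hri.values, b.hri.values, equal_nan=True)


class TestSampleHRI:
    def _escape(self):
        hri = Raster(np.array([[1.0, 2.0], [3.0, 4.0]]), cell_size=1000.0)
        return EScape(hri=hri, iei=make_iei_table([1, 1, 1]))

    def test_centroid_lookup(self):
        esc = self._escape()
        assert sample_hri(esc, [(500.0, 500.0)])[0] == 1.0
        assert sample_hri(esc, [(1500.0, 1500.0)])[0] == 4.0

    def test_boundary_half_open(self):
        esc = self._escape()
        # point on the shared x-boundary belongs to the right-hand unit
        assert sample_hri(esc, [(1000.0, 0.0)])[0] == 2.0
        assert sample_hri(esc, [(0.0, 1000.0)])[0] == 3.0

    def test_outside_is_missing_not_zero(self):
        esc = self._escape()
        vals = sample_hri(esc, [(-1.0, 0.0), (500.0, 500.0)])
        assert np.isnan(vals[0]) and vals[1] == 1.0

    def test_log_hri_never_negative_infinity(self):
        hri = Raster(np.array([[0.0, 2.0]]), cell_size=1000.0)
        esc = EScape(hri=hri, iei=make_iei_table([1, 1, 1]))
        logs = esc.log_hri().values
        assert np.isnan(logs[0, 0]) and logs[0, 1] == pytest.approx(np.log(2.0))


class TestEScapeBuilder:
    def test_sklearn_param_interface(self):
        b = EScapeBuilder(n_points=10)
        assert b.get_params()["n_points"] == 10
        b.set_params(radius=250.0)
        assert b.radius == 250.0
        with pytest.raises(ValueError):
            b.set_params(bogus=1)

    def test_fit_transform(self, small_landscape):
        hab, chl = small_landscape
        b = EScapeBuilder(n_points=50, unit=200.0, random_state=0)
        esc = b.fit_transform((hab, chl))
        assert hasattr(b, "iei_table_")
        assert np.nanmin(esc.hri.values) >= 0

    def test_transform_before_fit_raises(self, small_landscape):
        with pytest.raises(RuntimeError):
            EScapeBuilder().transform(small_landscape)
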