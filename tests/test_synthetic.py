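import numpy as np
import pytest

from nichesdm.synthetic import (
    InsufficientHabitatError,
    InvalidSpecError,
    ShiftScenario,
    SyntheticClimateSpec,
    VirtualNicheSpec,
    generate_climate_stack,
    make_shift_scenario,
    niche_truth,
    sample_occurrences,
    true_suitability,
    two_regime_climate,
)


def _spec(**kw):
    base = dict(
        extent=(0.0, 40.0, 12.5, 52.5),
        resolution=48.0,  # 50 x 50 cells
        layer_names=("bio5",),
        value_ranges={"bio5": (10.0, 40.0)},
        autocorrelation_length=0.0,
        seed=3,
    )
    base.update(kw)
    return SyntheticClimateSpec(**base)


def test_climate_determinism():
    a = generate_climate_stack(_spec())
    b = generate_climate_stack(_spec())
    assert np.array_equal(a.layers["bio5"], b.layers["bio5"])


def test_white_noise_has_no_lag1_autocorrelation():
    field = generate_climate_stack(_spec()).layers["bio5"]
    x = field - field.mean()
    rho = (x[:, :-1] * x[:, 1:]).sum() / (x**2).sum()
    assert abs(rho) < 0.1


def test_smoothing_increases_lag1_autocorrelation():
    def lag1(ac):
        f = generate_climate_stack(_spec(autocorrelation_length=ac)).layers["bio5"]
        x = f - f.mean()
        return (x[:, :-1] * x[:, 1:]).sum() / (x**2).sum()

    assert lag1(4.0) > lag1(0.0) + 0.5


def test_value_range_clamped():
    field = generate_climate_stack(_spec()).layers["bio5"]
    assert field.min() >= 10.0 and field.max() <= 40.0


def test_uniform_marginal_is_flat():
    field = generate_climate_stack(
        _spec(autocorrelation_length=3.0, marginal="uniform")
    ).layers["bio5"]
    hist, _ = np.histogram(field, bins=10, range=(10, 40))
    assert hist.max() / hist.min() < 1.05


@pytest.mark.parametrize(
    "bad",
    [
        dict(resolution=0.0),
        dict(extent=(10.0, 0.0, 0.0, 40.0)),
        dict(value_ranges={"bio5": (40.0, 10.0)}),
        dict(marginal="exotic"),
    ],
)
def test_invalid_climate_spec(bad):
    with pytest.raises(InvalidSpecError):
        generate_climate_stack(_spec(**bad))


class TestTrueSuitability:
    def test_optimum_cell_has_max_suitability(self, small_climate):
        env = small_climate.layers
        niche = VirtualNicheSpec(
            ("bio5", "bio12"),
            optimum=(float(env["bio5"][10, 10]), float(env["bio12"][10, 10])),
            breadth=(3.0, 300.0),
        )
        s = true_suitability(small_climate, niche)
        assert s.values[10, 10] == pytest.approx(1.0)

    def test_one_breadth_deviation(self):
        niche = VirtualNicheSpec(("a",), optimum=(5.0,), breadth=(2.0,))
        assert niche.response(np.array([[7.0]]), truncate=None)[0] == pytest.approx(
            np.exp(-0.5)
        )

    def test_zero_max_suitability(self, small_climate):
        niche = VirtualNicheSpec(
            ("bio5", "bio12"), (20.0, 1000.0), (3.0, 300.0), max_suitability=0.0
        )
        s = true_suitability(small_climate, niche)
        assert np.nanmax(s.values) == 0.0

    def test_missing_layer_raises(self, small_climate):
        niche = VirtualNicheSpec(("bio99",), (0.0,), (1.0,))
        with pytest.raises(KeyError):
            true_suitability(small_climate, niche)

    def test_nodata_propagates(self, small_climate):
        from nichesdm.raster import ClimateStack

        masked = ClimateStack(
            layers=small_climate.layers,
            transform=small_climate.transform,
            nodata_mask=small_climate.nodata_mask.copy(),
        )
        masked.nodata_mask[0, 0] = True
        niche = VirtualNicheSpec(("bio5", "bio12"), (20.0, 1000.0), (3.0, 300.0))
        assert np.isnan(true_suitability(masked, niche).values[0, 0])


class TestSampleOccurrences:
    def test_exhaustive_uniform_draw(self, small_climate):
        from nichesdm.raster import SuitabilityMap

        uniform = SuitabilityMap(
            values=np.full(small_climate.shape, 0.5),
            transform=small_climate.transform,
        )
        n = small_climate.shape[0] * small_climate.shape[1]
        occ = sample_occurrences(uniform, n, seed=0)
        rows, cols = small_climate.transform.cell_of(
            occ["lon"].to_numpy(), occ["lat"].to_numpy()
        )
        assert len(set(zip(rows.tolist(), cols.tolist()))) == n

    def test_zero_suitability_never_drawn(self):
        from nichesdm.raster import GridTransform, SuitabilityMap

        smap = SuitabilityMap(
            values=np.array([[0.9, 0.0]]), transform=GridTransform(0.0, 1.0, 1.0)
        )
        for seed in range(300):
            occ = sample_occurrences(smap, 1, seed=seed)
            assert occ["lon"].iloc[0] == pytest.approx(0.5)

    def test_sampling_tracks_suitability(self, small_climate):
        niche = VirtualNicheSpec(("bio5", "bio12"), (22.0, 1200.0), (4.0, 400.0))
        truth = true_suitability(small_climate, niche)
        rows, cols = small_climate.valid_cells()
        map_mean = truth.values[rows, cols].mean()
        for seed in (0, 1, 2):
            occ = sample_occurrences(truth, 500, seed=seed)
            r, c = small_climate.transform.cell_of(
                occ["lon"].to_numpy(), occ["lat"].to_numpy()
            )
            assert truth.values[r, c].mean() > map_mean

    def test_insufficient_habitat(self, small_climate):
        niche = VirtualNicheSpec(
            ("bio5", "bio12"), (20.0, 1000.0), (3.0, 300.0), max_suitability=0.0
        )
        truth = true_suitability(small_climate, niche)
        with pytest.raises(InsufficientHabitatError):
            sample_occurrences(truth, 10, seed=0)

    def test_records_at_cell_centres(self, small_climate):
        niche = VirtualNicheSpec(("bio5", "bio12"), (22.0, 1200.0), (4.0, 400.0))
        occ = sample_occurrences(true_suitability(small_climate, niche), 50, seed=1)
        t = small_climate.transform
        r, c = t.cell_of(occ["lon"].to_numpy(), occ["lat"].to_numpy())
        lon, lat = t.cell_center(r, c)
        assert np.allclose(lon, occ["lon"]) and np.allclose(lat, occ["lat"])


class TestNicheTruthOracle:
    LAYERS = ("bio5", "bio12")

    def _niche(self, opt5, br5=2.5, opt12=1000.0, br12=150.0):
        return VirtualNicheSpec(self.LAYERS, (opt5, opt12), (br5, br12))

    def test_identical_niches(self, uniform_wide_climate):
        n = self._niche(30.0)
        t = niche_truth(uniform_wide_climate, n, n)
        assert t.d == pytest.approx(1.0, abs=1e-6)
        assert t.expansion == pytest.approx(0.0, abs=1e-6)
        assert t.unfilling == pytest.approx(0.0, abs=1e-6)

    def test_distant_niches_disjoint(self, uniform_wide_climate):
        a = self._niche(15.0)
        b = self._niche(45.0)  # 12 breadths away
        t = niche_truth(uniform_wide_climate, a, b)
        assert t.d < 0.01
        assert t.expansion > 0.99

    def test_role_swap_symmetry(self, uniform_wide_climate):
        a = self._niche(25.0)
        b = self._niche(32.0, br5=4.0)
        t_ab = niche_truth(uniform_wide_climate, a, b)
        t_ba = niche_truth(uniform_wide_climate, b, a)
        assert t_ab.d == pytest.approx(t_ba.d, abs=1e-12)
        assert t_ab.expansion == pytest.approx(t_ba.unfilling, abs=1e-12)
        assert t_ab.unfilling == pytest.approx(t_ba.expansion, abs=1e-12)

    def test_nested_niche_has_zero_expansion(self, uniform_wide_climate):
        outer = self._niche(30.0, br5=5.0, br12=200.0)
        inner = self._niche(30.0, br5=2.0, br12=80.0)
        t = niche_truth(uniform_wide_climate, outer, inner)
        assert t.expansion == pytest.approx(0.0, abs=1e-6)
        assert t.unfilling > 0.1


class TestShiftScenario:
    def test_scenario_validation(self):
        n = VirtualNicheSpec(("bio5",), (20.0,), (2.0,))
        other = VirtualNicheSpec(("bio12",), (1000.0,), (100.0,))
        with pytest.raises(InvalidSpecError):
            ShiftScenario(n, other).validate()
        with pytest.raises(InvalidSpecError):
            ShiftScenario(n, n, n_native=5).validate()

    def test_make_shift_scenario_outputs(self, uniform_wide_climate):
        n = VirtualNicheSpec(("bio5", "bio12"), (25.0, 1000.0), (3.0, 150.0))
        i = VirtualNicheSpec(("bio5", "bio12"), (30.0, 1000.0), (3.0, 150.0))
        occ_n, occ_i, truth = make_shift_scenario(
            ShiftScenario(n, i, 50, 60, seed=4), uniform_wide_climate
        )
        assert len(occ_n) == 50 and len(occ_i) == 60
        assert set(occ_n["status"]) == {"native"}
        assert set(occ_i["status"]) == {"invasive"}
        assert 0 <= truth.d <= 1
        assert truth.stability == pytest.approx(1 - truth.expansion)

    def test_reproducible_from_seed(self, uniform_wide_climate):
        n = VirtualNicheSpec(("bio5", "bio12"), (25.0, 1000.0), (3.0, 150.0))
        sc = ShiftScenario(n, n, 40, 40, seed=9)
        a = make_shift_scenario(sc, uniform_wide_climate)
        b = make_shift_scenario(sc, uniform_wide_climate)
        assert a[0].equals(b[0]) and a[1].equals(b[1])


def test_two_regime_climate_has_disjoint_bio5_regimes():
    clim = two_regime_climate(seed=0)
    rows, cols = clim.valid_cells()
    bio5 = clim.layers["bio5"][rows, cols]
    assert ((bio5 <= 20.0) | (bio5 >= 36.0)).all()
    assert (bio5 <= 20.0).any() and (bio5 >= 36.0).any()
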