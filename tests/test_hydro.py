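import numpy as np
import pytest

from stemecho import (
    ElasticMedium,
    ImmersionRecord,
    bulk_density,
    immersion_analysis,
    load_bundled_immersion,
    longitudinal_velocity,
    mass_moisture,
    sample_volume,
    track_correlation,
    velocity_from_echo,
    volumetric_moisture,
)
from reference_immersion import (
    DENSITY,
    MASS_MOISTURE,
    VOLUMETRIC_MOISTURE,
    round_half_up_2dp,
)

V6 = np.pi * 3.0**2 * 6.0  # 6 cm diameter x 6 cm high cylinder, cm^3


class TestLongitudinalVelocity:
    def test_reduces_to_sqrt_e_over_rho_at_zero_poisson(self):
        assert longitudinal_velocity(ElasticMedium(1.0, 1.0, 0.0)) == pytest.approx(1.0)

    def test_density_scaling_law(self):
        v1 = longitudinal_velocity(ElasticMedium(5e9, 400.0, 0.25))
        v2 = longitudinal_velocity(ElasticMedium(5e9, 800.0, 0.25))
        assert v2 == pytest.approx(v1 / np.sqrt(2.0))

    def test_closed_form_value(self):
        # sqrt((1e10/600) * 0.7 / (1.3 * 0.4))
        expected = np.sqrt((1e10 / 600.0) * 0.7 / (1.3 * 0.4))
        got = longitudinal_velocity(ElasticMedium(1e10, 600.0, 0.3))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_e_and_rho(self):
        es = [1e9, 2e9, 5e9, 1e10]
        vs = [longitudinal_velocity(ElasticMedium(e, 500.0, 0.2)) for e in es]
        assert all(b > a for a, b in zip(vs, vs[1:]))
        rhos = [300.0, 500.0, 900.0, 1200.0]
        vs = [longitudinal_velocity(ElasticMedium(5e9, r, 0.2)) for r in rhos]
        assert all(b < a for a, b in zip(vs, vs[1:]))

    def test_poisson_domain(self):
        with pytest.raises(ValueError):
            ElasticMedium(1e9, 500.0, 0.5)


class TestVelocityFromEcho:
    def test_basic_and_proportionality(self):
        assert velocity_from_echo(1.0, 2.0) == pytest.approx(1.0)
        assert velocity_from_echo(1.0, 1.0) == pytest.approx(2 * velocity_from_echo(1.0, 2.0))

    def test_roundtrip_against_measured_velocity(self):
        # 2 cm half-path at the fastest bundled velocity: t = 2D / v
        v = 4706.0
        t = 2 * 0.02 / v
        assert velocity_from_echo(0.02, t) == pytest.approx(v)

    def test_rejects_nonpositive(self):
        for d, t in [(0.0, 1.0), (1.0, 0.0), (-1.0, 1.0)]:
            with pytest.raises(ValueError):
                velocity_from_echo(d, t)


def _cyl(d, h, sample_id="s", t=0.0, mass=100.0, v=None):
    return ImmersionRecord(sample_id, "cylinder", (d, h), t, mass, v)


class TestGeometryAndMoisture:
    def test_cylinder_and_cuboid_volumes(self):
        assert sample_volume(_cyl(6.0, 6.0)) == pytest.approx(np.pi * 9 * 6)
        assert sample_volume(_cyl(10.0, 10.0)) == pytest.approx(np.pi * 25 * 10)
        block = ImmersionRecord("b", "cuboid", (2.0, 4.0, 10.0), 0.0, 50.0)
        assert sample_volume(block) == pytest.approx(80.0)

    def test_bulk_density_published_spot_values(self):
        assert round_half_up_2dp(bulk_density(102.60, V6)) == 0.60
        assert round_half_up_2dp(bulk_density(294.00, np.pi * 25 * 10)) == 0.37
        assert bulk_density(80.0, 80.0) == pytest.approx(1.0)

    def test_volumetric_moisture_published_spot_values(self):
        assert volumetric_moisture(100.0, 100.0, 1.0, 50.0) == 0.0
        assert round_half_up_2dp(volumetric_moisture(173.60, 102.60, 1.0, V6)) == 0.42
        assert round_half_up_2dp(volumetric_moisture(115.80, 102.60, 1.0, V6)) == 0.08

    def test_mass_moisture_published_spot_values(self):
        assert round_half_up_2dp(mass_moisture(173.60, 102.60)) == 0.41
        assert round_half_up_2dp(mass_moisture(106.60, 102.60)) == 0.04
        assert mass_moisture(77.7, 77.7) == 0.0

    def test_mass_loss_is_rejected(self):
        with pytest.raises(ValueError):
            volumetric_moisture(90.0, 100.0, 1.0, 50.0)
        with pytest.raises(ValueError):
            mass_moisture(90.0, 100.0)


class TestImmersionAnalysis:
    def test_bundled_dataset_reproduces_all_published_derived_rows(self):
        analysis = immersion_analysis(load_bundled_immersion())
        table = analysis.table
        for column, expected in (
            ("density_g_cm3", DENSITY),
            ("mass_moisture", MASS_MOISTURE),
            ("volumetric_moisture", VOLUMETRIC_MOISTURE),
        ):
            for sid, row in expected.items():
                got = (
                    table[table.sample_id == sid]
                    .sort_values("timepoint_h")[column]
                    .map(round_half_up_2dp)
                    .tolist()
                )
                assert got == row, f"{column} row mismatch for {sid}"

    def test_bundled_dataset_fit_quality(self):
        analysis = immersion_analysis(load_bundled_immersion())
        assert analysis.mean_correlation >= 0.98
        assert set(analysis.fits) == {"cyl6", "cyl7", "cyl10"}

    def test_moisture_is_nondecreasing_over_soaking_time(self):
        table = immersion_analysis(load_bundled_immersion()).table
        for sid, group in table.groupby("sample_id"):
            g = group.sort_values("timepoint_h")
            assert g.volumetric_moisture.is_monotonic_increasing
            assert g.mass_moisture.is_monotonic_increasing

    def test_exact_quadratic_data_gives_unit_correlation(self):
        theta_targets = np.linspace(0.0, 0.4, 8)
        m0, vol = 100.0, 200.0
        records = [
            _cyl(
                6.0,
                200.0 / (np.pi * 9.0),
                "q",
                t=float(i),
                mass=m0 + th * vol,
                v=4000.0 - 5000.0 * th + 2000.0 * th**2,
            )
            for i, th in enumerate(theta_targets)
        ]
        analysis = immersion_analysis(records)
        assert analysis.fits["q"].correlation == pytest.approx(1.0)

    def test_fit_matches_independent_normal_equations(self, rng):
        theta = np.linspace(0.0, 0.4, 15)
        velocity = 4700.0 - 7000.0 * theta + 3000.0 * theta**2 + rng.normal(0, 40, 15)
        m0 = 100.0
        h = 200.0 / (np.pi * 9.0)
        records = [
            _cyl(6.0, h, "n", t=float(i), mass=m0 + th * 200.0, v=float(v))
            for i, (th, v) in enumerate(zip(theta, velocity))
        ]
        fit = immersion_analysis(records).fits["n"]
        # independent solve of the normal equations for the quadratic design
        design = np.vander(theta, 3)
        beta = np.linalg.solve(design.T @ design, design.T @ velocity)
        np.testing.assert_allclose(fit.coefficients, beta, rtol=1e-8)

    def test_beta_rescales_volumetric_moisture(self):
        records = load_bundled_immersion()
        base = immersion_analysis(records, beta=1.0).table
        scaled = immersion_analysis(records, beta=0.998).table
        np.testing.assert_allclose(
            scaled.volumetric_moisture, base.volumetric_moisture / 0.998
        )

    def test_too_few_points_warns_and_excludes(self):
        records = [_cyl(6.0, 6.0, "tiny", t=float(i), mass=100.0 + i, v=4000.0 - i)
                   for i in range(3)]
        records += load_bundled_immersion()
        with pytest.warns(UserWarning, match="tiny"):
            analysis = immersion_analysis(records)
        assert "tiny" not in analysis.fits


class TestTrackCorrelation:
    def test_identical_and_negated_series(self):
        picks = [(float(t), 1.0 + 0.1 * t) for t in range(9, 19)]
        assert track_correlation(picks, picks) == pytest.approx(1.0)
        negated = [(t, -v) for t, v in picks]
        assert track_correlation(picks, negated) == pytest.approx(-1.0)

    def test_recovers_known_bivariate_correlation(self):
        rho = 0.9
        r = np.random.default_rng(7)
        cov = [[1.0, rho], [rho, 1.0]]
        xy = r.multivariate_normal([0, 0], cov, size=500)
        times = np.arange(500.0)
        got = track_correlation(list(zip(times, xy[:, 0])), list(zip(times, xy[:, 1])))
        assert got == pytest.approx(rho, abs=0.05)

    def test_window_restricts_alignment(self):
        picks = [(float(t), float(t % 7)) for t in range(20)]
        cov = [(float(t), float((t * 3) % 5)) for t in range(20)]
        full = track_correlation(picks, cov)
        windowed = track_correlation(picks, cov, window=(5.0, 15.0))
        assert -1.0 <= windowed <= 1.0 and windowed != full

    def test_too_few_aligned_points(self):
        picks = [(0.0, 1.0), (1.0, 2.0), (2.0, 3.0)]
        cov = [(10.0, 1.0), (11.0, 2.0), (12.0, 3.0)]
        with pytest.raises(ValueError, match="aligned"):
            track_correlation(picks, cov)
        with pytest.raises(ValueError, match="aligned"):
            track_correlation(picks, [(0.0, 1.0), (1.0, 2.0), (9.0, 0.0)], window=(0.0, 1.0))

    def test_zero_variance_is_undefined(self):
        picks = [(float(t), 5.0) for t in range(5)]
        cov = [(float(t), float(t)) for t in range(5)]
        with pytest.raises(ValueError, match="zero variance"):
            track_correlation(picks, cov)
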