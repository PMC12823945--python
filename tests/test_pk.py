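import numpy as np
import pytest

from itdispersion.diffusion import ConcentrationField, build_grid, solve_diffusion
from itdispersion.pk import (
    DoseEvent,
    PKParameters,
    mass_balance_report,
    mass_transfer_flux,
    moment_comparison,
    simulate_pk,
)
from itdispersion.synthetic import NOISE_OFF, NoiseSpec, simulate_tracer_experiment


@pytest.fixture(scope="module")
def grid():
    return build_grid(-6.0, 59.0, 650)


@pytest.fixture(scope="module")
def bolus(grid):
    x = grid.cell_centers
    return np.exp(-(x**2) / 2.0)


class TestMassTransferFlux:
    def test_vanishes_at_partition_equilibrium(self):
        assert mass_transfer_flux(2.0, 1.0, sigma=0.5, k=2.0) == 0.0

    def test_zero_sigma(self):
        assert mass_transfer_flux(10.0, 0.0, sigma=0.0, k=1.0) == 0.0

    def test_direct_substitution(self):
        assert mass_transfer_flux(2.0, 1.0, sigma=0.5, k=1.0) == pytest.approx(0.5)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            mass_transfer_flux(1.0, 1.0, sigma=-0.1, k=1.0)


class TestReductionToDiffusion:
    def test_bit_for_bit_equivalence(self, grid, bolus):
        """All reaction/transfer off: the PK step IS the diffusion solver."""
        times = np.arange(1.0, 11.0)
        traj = simulate_pk(PKParameters(deff=7.4), [], grid, times, initial_c1=bolus)
        ref = solve_diffusion(
            ConcentrationField(grid=grid, times=np.array([0.0]), values=bolus),
            7.4,
            times,
        )
        assert np.array_equal(traj.c1, ref.values)


class TestMassBalance:
    def test_closed_system_conserves_mass(self, grid):
        params = PKParameters(
            deff=7.4,
            sigma12=0.1,
            k12=2.0,
            sigma15=0.05,
            k15=1.0,
            lumped_transfer={
                "c1_c3": (0.02, 1.0),
                "c3_c4": (0.01, 1.0),
                "c3_c5": (0.01, 1.0),
                "c5_c6": (0.005, 1.0),
            },
        )
        doses = [DoseEvent(start_time=0.0, duration=1.0, rate=2.0, concentration=1.0)]
        traj = simulate_pk(params, doses, grid, np.arange(1.0, 31.0, 3.0))
        report = mass_balance_report(traj, params)
        assert np.all(np.abs(report["relative_residual"]) < 1e-10)
        assert report["injected"][-1] == pytest.approx(2.0, rel=1e-12)

    def test_first_order_decay_is_exact(self, grid, bolus):
        params = PKParameters(deff=7.4, k1=0.05)
        times = np.arange(1.0, 11.0)
        traj = simulate_pk(params, [], grid, times, initial_c1=bolus)
        amount = traj.c1.sum(axis=1) * grid.dx * params.csf_area
        expected = bolus.sum() * grid.dx * np.exp(-0.05 * times)
        assert np.allclose(amount, expected, rtol=1e-12)
        # the loss is accounted in the degradation ledger
        report = mass_balance_report(traj, params)
        assert np.all(np.abs(report["relative_residual"]) < 1e-10)

    def test_one_way_leak_monotone_blood(self, grid, bolus):
        params = PKParameters(deff=7.4, sigma15=0.1, k15=0.0)
        traj = simulate_pk(params, [], grid, np.arange(1.0, 11.0), initial_c1=bolus)
        assert np.all(np.diff(traj.c5) >= 0)


class TestPartitionEquilibrium:
    @pytest.mark.parametrize("k12", [1.0, 2.0])
    def test_csf_tissue_ratio(self, grid, k12):
        """Coupled pools settle at C1 = K * C2 while conserving total mass."""
        params = PKParameters(deff=0.0, sigma12=0.5, k12=k12)
        init = np.ones(grid.n_cells)
        traj = simulate_pk(params, [], grid, [300.0], initial_c1=init)
        c1, c2 = traj.c1[-1][0], traj.c2[-1][0]
        assert c1 / c2 == pytest.approx(k12, rel=1e-9)
        total = (traj.c1[-1] + traj.c2[-1]).sum() * grid.dx
        assert total == pytest.approx(init.sum() * grid.dx, rel=1e-12)

    def test_nonnegative_concentrations(self, grid, bolus):
        params = PKParameters(deff=7.4, k1=0.1, sigma12=0.3, k12=2.0, sigma15=0.2)
        traj = simulate_pk(params, [], grid, np.arange(1.0, 21.0, 4.0), initial_c1=bolus)
        for arr in (traj.c1, traj.c2, traj.c3, traj.c4, traj.c5, traj.c6):
            assert arr.min() >= 0.0


class TestMultiDose:
    def test_each_dose_adds_its_mass(self, grid):
        params = PKParameters(deff=7.4)
        doses = [
            DoseEvent(start_time=0.0, duration=1.0, rate=2.0, concentration=1.0),
            DoseEvent(start_time=30.0, duration=1.0, rate=2.0, concentration=1.0),
        ]
        traj = simulate_pk(params, doses, grid, np.array([10.0, 29.0, 40.0]))
        masses = traj.c1.sum(axis=1) * grid.dx
        assert masses[0] == pytest.approx(2.0, rel=1e-10)
        assert masses[2] == pytest.approx(4.0, rel=1e-10)

    def test_negative_parameter_rejected(self):
        with pytest.raises(ValueError):
            PKParameters(deff=-1.0)
        with pytest.raises(ValueError):
            DoseEvent(start_time=0.0, duration=-1.0, rate=1.0, concentration=1.0)


class TestMomentComparison:
    def test_self_comparison_is_zero(self, grid):
        record = simulate_tracer_experiment(d_true=7.4, noise=NOISE_OFF, grid=grid)
        traj = simulate_pk(
            PKParameters(deff=7.4), [], grid, record.times[1:],
            initial_c1=record.intensities[0],
        )
        result = moment_comparison(traj, record)
        assert result["rms_m2_left_difference"] == pytest.approx(0.0, abs=1e-12)
        assert result["rms_m1_difference"] == pytest.approx(0.0, abs=1e-12)

    def test_noise_floor_bound(self, grid):
        """Matched simulation vs noisy record: RMS m2 gap below 5% of final m2."""
        record = simulate_tracer_experiment(
            d_true=7.4, noise=NoiseSpec(0.05, 0.0), seed=2, grid=grid
        )
        traj = simulate_pk(
            PKParameters(deff=7.4), [], grid, record.times[1:],
            initial_c1=record.intensities[0],
        )
        result = moment_comparison(traj, record)
        assert result["rms_m2_left_difference"] < 0.05 * result["obs_m2_left"][-1]

    def test_mismatched_deff_grows_gap(self, grid):
        record = simulate_tracer_experiment(d_true=7.4, noise=NOISE_OFF, grid=grid)
        traj = simulate_pk(
            PKParameters(deff=14.8), [], grid, record.times[1:],
            initial_c1=record.intensities[0],
        )
        result = moment_comparison(traj, record)
        gap = np.abs(result["sim_m2_left"] - result["obs_m2_left"])
        assert gap[-1] > gap[0]

    def test_no_overlap_errors(self, grid, bolus):
        traj = simulate_pk(PKParameters(deff=7.4), [], grid, [0.25], initial_c1=bolus)
        record = simulate_tracer_experiment(d_true=7.4, noise=NOISE_OFF, grid=grid)
        with pytest.raises(ValueError):
            moment_comparison(traj, record)


def test_multi_month_multi_dose_runs_quickly(grid):
    """90 days with monthly doses integrates in seconds at modest stepping."""
    import time

    params = PKParameters(deff=7.4, k1=1e-4, sigma12=1e-3, k12=2.0, sigma15=1e-3)
    day = 1440.0
    doses = [
        DoseEvent(start_time=k * 30 * day, duration=1.0, rate=2.0, concentration=1.0)
        for k in range(3)
    ]
    out = np.linspace(1.0, 90 * day, 30)
    start = time.time()
    traj = simulate_pk(params, doses, grid, out, dt_max=120.0)
    elapsed = time.time() - start
    report = mass_balance_report(traj, params)
    assert np.all(np.abs(report["relative_residual"]) < 1e-9)
    assert elapsed < 60.0
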