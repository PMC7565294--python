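"""Restricted-diffusion random walk: steps, reflection, MSD statistics."""

import math

import numpy as np
import pytest

from tddc import (
    CellGeometry2D,
    Circle,
    RWConfig,
    default_yeast_geometry,
    es_model,
    msd_to_D,
    n_steps,
    simulate,
    simulated_attenuation,
    simulated_tddc,
    step_length,
)

UM = 1e-6


@pytest.fixture(scope="module")
def geometry():
    return default_yeast_geometry()


@pytest.fixture(scope="module")
def bare_disk():
    """A single empty cell whose inner (cytoplasm) disk has R = 1 um."""
    return CellGeometry2D(
        domain_side=10 * UM,
        cell=Circle(0, 0, 1.1 * UM),
        wall_thickness=0.1 * UM,
        organelles={},
        region_D0={"exterior": 1.64e-9, "cytoplasm": 0.68e-9, "wall": 0.03e-9},
    )


class TestStepBookkeeping:
    def test_step_length(self):
        assert step_length(0.0, 5e-6) == 0.0
        assert step_length(0.676e-9, 5e-6) == pytest.approx(1.16e-7, rel=3e-3)
        assert step_length(4e-9, 5e-6) == pytest.approx(2 * step_length(1e-9, 5e-6))

    @pytest.mark.parametrize("tm, expected", [(0.2e-3, 40), (40e-3, 8000),
                                              (5e-6, 1)])
    def test_n_steps(self, tm, expected):
        assert n_steps(tm, 5e-6) == expected

    def test_non_multiple_rejected(self):
        with pytest.raises(ValueError):
            n_steps(7e-6, 5e-6)

    def test_msd_to_d_identities(self):
        D = 1.3e-9
        assert msd_to_D(2 * D * 0.01, 0.01, d=1) == pytest.approx(D)
        assert msd_to_D(0.0, 0.01, d=2) == 0.0
        with pytest.raises(ValueError):
            msd_to_D(1e-12, 0.0, d=2)


class TestWalk:
    def test_seed_determinism(self, bare_disk):
        cfg = RWConfig(tm_list=(0.5e-3, 1e-3), n_particles=300, seed=11)
        a = simulate(bare_disk, "cytoplasm", cfg).table
        b = simulate(bare_disk, "cytoplasm", cfg).table
        assert a.equals(b)

    def test_confinement_every_step(self, geometry):
        """No walker ends a step outside its region, including the annular
        wall and the multiply-connected cytoplasm."""
        for region in ("cytoplasm", "wall", "vacuole"):
            cfg = RWConfig(tm_list=(1e-3,), n_particles=150, seed=5)
            simulate(geometry, region, cfg, check_confinement=True)

    def test_free_diffusion_msd_linear(self, geometry):
        cfg = RWConfig(tm_list=tuple(np.arange(1, 9) * 0.5e-3),
                       n_particles=3000, seed=2)
        summ = simulate(geometry, "exterior", cfg)
        t = summ.table["tm"].to_numpy()
        msd = summ.table["msd_axis"].to_numpy()
        slope, icpt = np.polyfit(t, msd, 1)
        D0 = geometry.region_D0["exterior"]
        assert slope / 2 == pytest.approx(D0, rel=0.05)
        resid = msd - (icpt + slope * t)
        r2 = 1 - (resid @ resid) / ((msd - msd.mean()) @ (msd - msd.mean()))
        assert r2 >= 0.999

    def test_free_diffusion_recovery(self, geometry):
        cfg = RWConfig(tm_list=(1e-3, 10e-3), n_particles=3000, seed=8)
        summ = simulate(geometry, "exterior", cfg)
        assert np.allclose(summ.D(d=2), geometry.region_D0["exterior"],
                           rtol=0.05)

    def test_disk_plateau_stationary_moment(self, bare_disk):
        """Long-time displacement from the disk center approaches the
        stationary uniform moments: <r^2> = R^2/2, per-axis R^2/4."""
        R = bare_disk.inner_circle.r
        # equilibration time R^2/D0 ~ 1.5 ms; record well beyond it
        cfg = RWConfig(tm_list=(6e-3, 12e-3), n_particles=2000, seed=9,
                       seed_mode="center", t_s=1e-6)
        summ = simulate(bare_disk, "cytoplasm", cfg)
        assert summ.table["msd_r2"].iloc[-1] == pytest.approx(R**2 / 2, rel=0.05)
        assert summ.table["msd_axis"].iloc[-1] == pytest.approx(R**2 / 4, rel=0.05)


class TestTDDCProducts:
    def test_confined_region_motional_averaging(self, geometry):
        """A 0.25 um organelle is fully explored within ~1 ms: its apparent D
        collapses far below bulk and is bounded by the localization law."""
        cfg = RWConfig(tm_list=(1e-3, 2e-3, 4e-3), n_particles=800, seed=3,
                       seed_mode="center")
        out = simulated_tddc(geometry, cfg, regions=["mitochondrion"])
        df = out["mitochondrion"]
        R = geometry.organelles["mitochondrion"].r
        D0 = geometry.region_D0["mitochondrion"]
        assert (df["D"] < 0.1 * D0).all()
        bound = es_model(df["tm"].to_numpy(), R, d=2)
        assert np.all(df["D"].to_numpy() <= 2.1 * bound)

    def test_cytoplasm_tddc_decreases(self, bare_disk):
        cfg = RWConfig(tm_list=(0.5e-3, 2e-3, 8e-3, 24e-3), n_particles=800,
                       seed=4, seed_mode="center")
        out = simulated_tddc(bare_disk, cfg, regions=["cytoplasm"])
        D = out["cytoplasm"]["D"].to_numpy()
        assert np.all(np.diff(D) < 0)
        assert "D_piecewise" in out["cytoplasm"]

    def test_simulated_attenuation(self):
        tm_list = [1e-3, 2e-3]
        table = simulated_attenuation(
            {"exterior": [1.64e-9, 1.64e-9], "slow": [1.64e-10, 1.64e-10]},
            tm_list, targets=[1.0, 0.1, 0.01],
        )
        at_one = table[table.E == 1.0]
        assert (at_one.b == 0).all()
        ext = table[(table.region == "exterior") & (table.E == 0.01)].b.iloc[0]
        slow = table[(table.region == "slow") & (table.E == 0.01)].b.iloc[0]
        assert ext == pytest.approx(2.81e9, rel=2e-3)
        assert slow == pytest.approx(10 * ext, rel=1e-9)

    def test_zero_coefficient_infinite_b(self):
        table = simulated_attenuation({"dead": [0.0]}, [1e-3],
                                      targets=[1.0, 0.5])
        assert math.isinf(table[table.E == 0.5].b.iloc[0])
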