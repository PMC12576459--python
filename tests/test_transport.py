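import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from ctdosim.attenuation import material_partial_mu_rho, material_table
from ctdosim.geometry import ScannerGeometry
from ctdosim.phantom import VoxelPhantom
from ctdosim.transport import (MaterialGrid, TallyResult, branch_probabilities,
                               compton_energy, compton_scatter,
                               estimate_uncertainty, run_projection,
                               sample_compton, sample_interaction,
                               sample_rayleigh, transport_batch)
from tests.conftest import uniform_phantom


def _pencil(n, energy, x0=-60.0):
    pos = np.tile([x0, 0.0, 0.0], (n, 1))
    d = np.tile([1.0, 0.0, 0.0], (n, 1))
    return pos, d, np.full(n, float(energy)), np.ones(n)


def _water_slab(dims=(20, 20, 10)):
    ph = uniform_phantom("water", 1.0, dims=dims)
    grid = MaterialGrid.for_phantom(ph)
    return ph, grid, grid.majorant(ph)


class TestBeerLambert:
    def test_slab_transmission_within_3_sigma(self):
        ph, grid, maj = _water_slab()
        n = 400_000
        pos, d, e, w = _pencil(n, 60.0)
        _, _, unc = transport_batch(pos, d, e, w, ph, grid, maj, seed=11,
                                    return_uncollided=True)
        thickness_cm = ph.dims[0] * ph.spacing[0] / 10.0
        mu = material_table("water").mu_at(60.0)
        expected = np.exp(-mu * thickness_cm)
        sigma = np.sqrt(expected * (1 - expected) / n)
        assert abs(unc / n - expected) < 3 * sigma


class TestWoodcockVsDirect:
    """Two-estimator equivalence: the Woodcock engine against an independent
    vectorized mini-MC using direct exponential path sampling (valid because
    the medium is homogeneous) and inverse-CDF angle sampling."""

    @staticmethod
    def _direct_mc(n, energy, half_xy_mm, half_z_mm, depth_mm, rng):
        """Returns (total edep keV, depth histogram of deposits)."""
        t = material_partial_mu_rho("water")
        grid_e = t["energy_kev"]
        mu_of = lambda e: np.interp(e, grid_e,
                                    t["photoelectric"] + t["incoherent"]
                                    + t["coherent"])  # rho = 1
        # tabulated inverse CDF of the KN cosine at any alpha via discretization
        def kn_cos(e_kev, u):
            a = e_kev / 510.99895
            mu_grid = np.linspace(-1, 1, 2001)
            eta = 1 + a * (1 - mu_grid)
            pdf = (1 / eta) ** 2 * (eta + 1 / eta - (1 - mu_grid**2))
            cdf = np.cumsum(pdf)
            cdf /= cdf[-1]
            return np.interp(u, cdf, mu_grid)

        pos = np.zeros((n, 3))
        pos[:, 0] = -depth_mm / 2.0
        dirs = np.tile([1.0, 0.0, 0.0], (n, 1))
        e = np.full(n, float(energy))
        alive = np.ones(n, bool)
        edep_total = 0.0
        depth_edges = np.linspace(-depth_mm / 2, depth_mm / 2, 21)
        depth_hist = np.zeros(20)
        for _ in range(200):
            if not alive.any():
                break
            idx = np.flatnonzero(alive)
            mu = mu_of(e[idx])
            step = rng.exponential(1.0 / mu) * 10.0  # cm -> mm
            pos[idx] += dirs[idx] * step[:, None]
            inside = ((np.abs(pos[idx, 0]) <= depth_mm / 2)
                      & (np.abs(pos[idx, 1]) <= half_xy_mm)
                      & (np.abs(pos[idx, 2]) <= half_z_mm))
            alive[idx[~inside]] = False
            idx = idx[inside]
            if idx.size == 0:
                continue
            p = np.stack([np.interp(e[idx], grid_e, t["photoelectric"]),
                          np.interp(e[idx], grid_e, t["incoherent"]),
                          np.interp(e[idx], grid_e, t["coherent"])])
            p /= p.sum(axis=0)
            u = rng.random(idx.size)
            branch = (u > p[0]).astype(int) + (u > p[0] + p[1]).astype(int)

            deposits = np.zeros(idx.size)
            pe = branch == 0
            deposits[pe] = e[idx[pe]]
            alive[idx[pe]] = False
            co = branch == 1
            if co.any():
                mu_c = np.array([kn_cos(ei, ui) for ei, ui in
                                 zip(e[idx[co]], rng.random(co.sum()))])
                e_new = e[idx[co]] / (1 + e[idx[co]] / 510.99895 * (1 - mu_c))
                deposits[co] = e[idx[co]] - e_new
                low = e_new < 5.0
                deposits[np.flatnonzero(co)[low]] += e_new[low]
                alive[idx[co][low]] = False
                e[idx[co]] = np.where(low, e_new, e_new)
                # rotate survivors
                surv = idx[co][~low]
                if surv.size:
                    dirs[surv] = _rotated(dirs[surv], mu_c[~low], rng)
            ra = branch == 2
            if ra.any():
                mu_r = _thomson_inverse(rng.random(ra.sum()))
                dirs[idx[ra]] = _rotated(dirs[idx[ra]], mu_r, rng)
            edep_total += deposits.sum()
            h, _ = np.histogram(pos[idx, 0], depth_edges, weights=deposits)
            depth_hist += h
        return edep_total, depth_hist

    def test_total_edep_agrees(self):
        ph, grid, maj = _water_slab(dims=(20, 20, 20))
        n = 100_000
        pos, d, e, w = _pencil(n, 80.0)
        edep, _ = transport_batch(pos, d, e, w, ph, grid, maj, seed=21)
        woodcock = edep.sum() / n

        rng = np.random.default_rng(22)
        direct_total, _ = self._direct_mc(n, 80.0, half_xy_mm=50.0,
                                          half_z_mm=50.0, depth_mm=100.0, rng=rng)
        direct = direct_total / n
        # both estimators have sub-percent standard errors at this budget
        assert woodcock == pytest.approx(direct, rel=0.02)

    def test_depth_profile_agrees(self):
        ph, grid, maj = _water_slab(dims=(20, 20, 20))
        n = 100_000
        pos, d, e, w = _pencil(n, 80.0)
        edep, _ = transport_batch(pos, d, e, w, ph, grid, maj, seed=31)
        woodcock_depth = edep.sum(axis=(1, 2))

        rng = np.random.default_rng(32)
        _, direct_hist = self._direct_mc(n, 80.0, half_xy_mm=50.0,
                                         half_z_mm=50.0, depth_mm=100.0, rng=rng)
        a = woodcock_depth / woodcock_depth.sum()
        b = direct_hist / direct_hist.sum()
        np.testing.assert_allclose(a, b, atol=0.01)


def _rotated(dirs, cos_t, rng):
    sin_t = np.sqrt(np.clip(1 - cos_t**2, 0, None))
    phi = rng.uniform(0, 2 * np.pi, cos_t.size)
    out = np.empty_like(dirs)
    for i, (u, ct, st, ph_) in enumerate(zip(dirs, cos_t, sin_t, phi)):
        if abs(u[2]) < 0.99999:
            den = np.sqrt(1 - u[2] ** 2)
            v = np.array([
                u[0] * ct + st * (u[0] * u[2] * np.cos(ph_) - u[1] * np.sin(ph_)) / den,
                u[1] * ct + st * (u[1] * u[2] * np.cos(ph_) + u[0] * np.sin(ph_)) / den,
                u[2] * ct - den * st * np.cos(ph_)])
        else:
            v = np.array([st * np.cos(ph_), st * np.sin(ph_),
                          ct if u[2] > 0 else -ct])
        out[i] = v / np.linalg.norm(v)
    return out


def _thomson_inverse(u):
    # solve CDF(mu) = u for pdf ~ (1 + mu^2) on [-1, 1] via dense table
    mu_grid = np.linspace(-1, 1, 2001)
    cdf = np.cumsum(1 + mu_grid**2)
    cdf /= cdf[-1]
    return np.interp(u, cdf, mu_grid)


class TestComptonSampling:
    def test_forward_scatter_no_deposit(self):
        assert compton_energy(60.0, 1.0) == pytest.approx(60.0, rel=1e-15)

    def test_backscatter_at_electron_rest_energy(self):
        e = 510.99895
        assert compton_energy(e, -1.0) == pytest.approx(e / 3.0, rel=1e-12)

    def test_scatter_event_consistency(self):
        e_out, theta, dep = compton_scatter(60.0, 5)
        assert e_out + dep == pytest.approx(60.0, rel=1e-12)
        assert e_out == pytest.approx(compton_energy(60.0, np.cos(theta)), rel=1e-9)

    @pytest.mark.parametrize("energy", [30.0, 60.0, 120.0])
    def test_angular_distribution_matches_klein_nishina(self, energy):
        cos_t, e_out = sample_compton(energy, 150_000, seed=7)
        np.testing.assert_allclose(
            e_out, energy / (1 + energy / 510.99895 * (1 - cos_t)), rtol=1e-12)

        def kn_pdf(mu):
            a = energy / 510.99895
            eta = 1 + a * (1 - mu)
            return (1 / eta) ** 2 * (eta + 1 / eta - (1 - mu * mu))

        edges = np.linspace(-1, 1, 37)
        obs, _ = np.histogram(cos_t, edges)
        probs = np.array([quad(kn_pdf, lo, hi)[0]
                          for lo, hi in zip(edges[:-1], edges[1:])])
        probs /= probs.sum()
        _, p = stats.chisquare(obs, probs * obs.sum())
        assert p > 0.01

    def test_invalid_energy_rejected(self):
        with pytest.raises(ValueError):
            compton_scatter(-1.0, 0)


class TestRayleighSampling:
    def test_no_energy_deposit_by_construction(self):
        # Rayleigh leaves energy unchanged: deposit is identically zero in the
        # engine; the standalone sampler returns only an angle
        cos_t = sample_rayleigh(100, seed=1)
        assert cos_t.shape == (100,)

    def test_symmetric_about_90_degrees(self):
        cos_t = sample_rayleigh(200_000, seed=9)
        assert abs(cos_t.mean()) < 3.0 * cos_t.std() / np.sqrt(cos_t.size)

    def test_matches_thomson_density(self):
        cos_t = sample_rayleigh(200_000, seed=9)
        edges = np.linspace(-1, 1, 37)
        obs, _ = np.histogram(cos_t, edges)
        probs = np.array([(hi - lo) + (hi**3 - lo**3) / 3.0
                          for lo, hi in zip(edges[:-1], edges[1:])])
        probs /= probs.sum()
        _, p = stats.chisquare(obs, probs * obs.sum())
        assert p > 0.01


class TestInteractionSampling:
    def test_probabilities_sum_to_one(self):
        p = branch_probabilities("water", 60.0)
        assert sum(p.values()) == pytest.approx(1.0, rel=1e-12)

    def test_compton_modal_in_water_at_120kev(self):
        p = branch_probabilities("water", 120.0)
        assert p["compton"] == max(p.values())
        assert p["compton"] > 0.9

    def test_frequencies_match_table_ratios(self, rng):
        n = 200_000
        draws = sample_interaction("water", 40.0, rng, size=n)
        p = branch_probabilities("water", 40.0)
        obs = np.array([(draws == b).sum()
                        for b in ("photoelectric", "compton", "rayleigh")])
        exp = np.array([p["photoelectric"], p["compton"], p["rayleigh"]]) * n
        _, pval = stats.chisquare(obs, exp)
        assert pval > 0.01

    def test_energy_out_of_range_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_interaction("water", 1000.0, rng)


class TestEngineContracts:
    def test_vacuum_phantom_zero_deposit(self, geometry, calibrated_spectrum):
        ph = uniform_phantom("air", 1.0, dims=(4, 4, 4))
        ph.density[:] = 0.0
        with pytest.warns(UserWarning, match="missed"):
            res = run_projection(ph, geometry, calibrated_spectrum, None,
                                 0.0, 0.0, n_photons=200, seed=1)
        assert res.total_edep_kev() == 0.0

    def test_below_cutoff_photon_deposits_locally_and_dies(self):
        ph, grid, maj = _water_slab(dims=(4, 4, 4))
        pos = np.array([[0.0, 0.0, 0.0]])
        d = np.array([[1.0, 0.0, 0.0]])
        edep, _ = transport_batch(pos, d, np.array([4.9]), np.ones(1),
                                  ph, grid, maj, seed=2)
        assert edep.sum() == pytest.approx(4.9, rel=1e-12)
        # all in the voxel containing the starting point
        assert edep[2, 2, 2] == pytest.approx(4.9, rel=1e-12)

    def test_bit_identical_reruns(self, geometry, calibrated_spectrum):
        ph, _, _ = _water_slab(dims=(8, 8, 8))
        a = run_projection(ph, geometry, calibrated_spectrum, None, 0.0, 0.0,
                           n_photons=5000, seed=42)
        b = run_projection(ph, geometry, calibrated_spectrum, None, 0.0, 0.0,
                           n_photons=5000, seed=42)
        np.testing.assert_array_equal(a.voxel_edep_kev, b.voxel_edep_kev)
        np.testing.assert_array_equal(a.label_edep_kev, b.label_edep_kev)

    def test_energy_conservation(self):
        ph, grid, maj = _water_slab()
        n = 20_000
        pos, d, e, w = _pencil(n, 100.0)
        edep, _, unc = transport_batch(pos, d, e, w, ph, grid, maj, seed=3,
                                       return_uncollided=True)
        assert edep.sum() <= (w * e).sum()
        assert unc > 0  # some photons escaped, so inequality is strict
        assert edep.sum() < (w * e).sum()

    def test_center_dose_below_surface_dose_in_water_cylinder(
            self, geometry, calibrated_spectrum):
        # depth-dose ordering under exponential attenuation
        ph = uniform_phantom("water", 1.0, dims=(24, 24, 8),
                             voxel_mm=(10.0, 10.0, 10.0))
        res = run_projection(ph, geometry, calibrated_spectrum, None, 0.0, 0.0,
                             n_photons=100_000, seed=5)
        profile = res.voxel_edep_kev[12, :, 4]  # along beam axis (top enters at +y)
        entry = profile[-2]
        center = profile[12]
        assert center < entry

    def test_non_finite_state_rejected(self):
        ph, grid, maj = _water_slab(dims=(4, 4, 4))
        pos = np.array([[np.nan, 0.0, 0.0]])
        d = np.array([[1.0, 0.0, 0.0]])
        with pytest.raises(ValueError):
            transport_batch(pos, d, np.array([60.0]), np.ones(1), ph, grid,
                            maj, seed=1)

    def test_n_photons_must_be_positive(self, geometry, calibrated_spectrum):
        ph, _, _ = _water_slab(dims=(4, 4, 4))
        with pytest.raises(ValueError):
            run_projection(ph, geometry, calibrated_spectrum, None, 0.0, 0.0,
                           n_photons=0, seed=1)


class TestUncertainty:
    def test_identical_batches_zero(self):
        batches = np.ones((5, 3))
        np.testing.assert_array_equal(estimate_uncertainty(batches), 0.0)

    def test_single_batch_rejected(self):
        with pytest.raises(ValueError):
            estimate_uncertainty(np.ones((1, 3)))

    def test_clt_scaling(self, geometry, calibrated_spectrum):
        ph = uniform_phantom("water", 1.0, dims=(10, 10, 6), label_all=1)
        rels = []
        for n in (10_000, 160_000):
            res = run_projection(ph, geometry, calibrated_spectrum, None,
                                 0.0, 0.0, n_photons=n, seed=17)
            rels.append(res.relative_uncertainty()[1])
        ratio = rels[0] / rels[1]
        assert 4.0 / 1.5 < ratio < 4.0 * 1.5

    def test_tally_uncertainty_reported(self, geometry, calibrated_spectrum):
        ph = uniform_phantom("water", 1.0, dims=(16, 16, 8), label_all=1)
        res = run_projection(ph, geometry, calibrated_spectrum, None, 0.0, 0.0,
                             n_photons=80_000, seed=2)
        rel = res.relative_uncertainty()
        assert 0.0 < rel[1] < 0.1
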