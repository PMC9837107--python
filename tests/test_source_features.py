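"""eLORETA kernel properties and the per-IC feature matrix contract."""

import numpy as np
import pytest

from musedecode import headmodel as hm
from musedecode import preprocess as pp
from musedecode import source_features as sf
from tests.conftest import ar2_sources


def eloreta_reference(L, alpha, tol=1e-6, max_iter=100):
    """Independent plain-loop reimplementation of the eLORETA fixed point."""
    n_ch = L.shape[0]
    n_src = L.shape[1] // 3
    H = np.eye(n_ch) - np.ones((n_ch, n_ch)) / n_ch
    W = [np.eye(3) for _ in range(n_src)]
    for _ in range(max_iter):
        G = np.zeros((n_ch, n_ch))
        for v in range(n_src):
            Lv = L[:, 3 * v : 3 * v + 3]
            G += Lv @ np.linalg.pinv(W[v]) @ Lv.T
        M = np.linalg.pinv(G + alpha * np.trace(G) / n_ch * H)
        W_new = []
        for v in range(n_src):
            Lv = L[:, 3 * v : 3 * v + 3]
            A = Lv.T @ M @ Lv
            w, U = np.linalg.eigh((A + A.T) / 2)
            w = np.maximum(w, 1e-12 * max(w.max(), 1e-12))
            W_new.append((U * np.sqrt(w)) @ U.T)
        change = max(
            np.linalg.norm(Wn - Wo) / max(np.linalg.norm(Wo), 1e-300)
            for Wn, Wo in zip(W_new, W)
        )
        W = W_new
        if change < tol:
            break
    G = np.zeros((n_ch, n_ch))
    for v in range(n_src):
        Lv = L[:, 3 * v : 3 * v + 3]
        G += Lv @ np.linalg.pinv(W[v]) @ Lv.T
    M = np.linalg.pinv(G + alpha * np.trace(G) / n_ch * H)
    K = np.vstack(
        [
            np.linalg.pinv(W[v]) @ L[:, 3 * v : 3 * v + 3].T @ M
            for v in range(n_src)
        ]
    )
    return K


class TestEloretaKernel:
    def test_matches_independent_reference(self, sensors):
        lf = hm.build_spherical_leadfield(sensors, grid_spacing_mm=40.0)
        inv = sf.eloreta_kernel(lf, alpha=0.05)
        K_ref = eloreta_reference(lf.gain, alpha=0.05)
        scale = np.abs(K_ref).max()
        assert np.abs(inv.kernel - K_ref).max() < 1e-8 * scale

    def test_zero_localization_error_all_truths(self, coarse_leadfield):
        """Noiseless single-dipole data localises to the true grid point for
        every truth and orientation (eLORETA's defining property)."""
        lf = coarse_leadfield
        inv = sf.eloreta_kernel(lf, alpha=1e-3)
        assert inv.converged
        K = inv.kernel.reshape(lf.n_sources, 3, lf.n_channels)
        for v in range(lf.n_sources):
            for o in range(3):
                moment = K @ lf.gain_at(v)[:, o]
                power = (moment**2).sum(axis=1)
                assert int(np.argmax(power)) == v

    def test_deterministic(self, coarse_leadfield):
        a = sf.eloreta_kernel(coarse_leadfield, alpha=0.05)
        b = sf.eloreta_kernel(coarse_leadfield, alpha=0.05)
        assert np.array_equal(a.kernel, b.kernel)

    def test_nonconvergence_flagged(self, coarse_leadfield, caplog):
        with caplog.at_level("WARNING"):
            inv = sf.eloreta_kernel(coarse_leadfield, alpha=0.05, tol=0.0,
                                    max_iter=2)
        assert not inv.converged
        assert "did not converge" in caplog.text

    def test_common_mode_offsets_map_to_zero(self, coarse_leadfield, rng):
        """Reference invariance: adding a common offset to every channel
        leaves the source estimate unchanged."""
        inv = sf.eloreta_kernel(coarse_leadfield, alpha=0.05)
        X = rng.standard_normal((coarse_leadfield.n_channels, 50))
        offset = np.ones((coarse_leadfield.n_channels, 1)) * 7.5
        a = inv.kernel @ X
        b = inv.kernel @ (X + offset)
        assert np.abs(a - b).max() < 1e-9 * np.abs(a).max()


def test_lcmv_beamformer_recovers_active_dipole(coarse_leadfield, rng):
    """The LCMV kernel, driven by the data covariance of a single strong
    source, localises that source and reconstructs its time course."""
    lf = coarse_leadfield
    v, ori = 21, np.array([1.0, 0.0, 0.0])
    s = ar2_sources(rng, n=1, T=4000)[0]
    data = 50.0 * (lf.gain_at(v) @ ori)[:, None] * s[None, :]
    scale = np.abs(data).max() or 1.0
    data = data + 1e-4 * scale * rng.standard_normal(data.shape)
    C = np.cov(data)
    inv_op = sf.lcmv_kernel(lf, C, alpha=0.01)
    out = sf.estimate_sources(inv_op, data, lf.grid[[3, v, 40]])
    assert int(np.argmax(out.var(axis=1))) == 1
    assert abs(np.corrcoef(out[1], s)[0, 1]) > 0.99


@pytest.fixture(scope="module")
def inv(coarse_leadfield):
    return sf.eloreta_kernel(coarse_leadfield, alpha=0.05)


class TestEstimateSources:
    def test_zero_input_zero_output(self, coarse_leadfield, inv):
        out = sf.estimate_sources(
            inv, np.zeros((coarse_leadfield.n_channels, 20)),
            coarse_leadfield.grid[[3, 10]],
        )
        assert out.shape == (2, 20)
        assert np.all(out == 0)

    def test_active_dipole_row_has_largest_variance(self, coarse_leadfield,
                                                    inv, rng):
        lf = coarse_leadfield
        v = 17
        s = ar2_sources(rng, n=1, T=1000)[0]
        ori = np.array([0.0, 0.0, 1.0])
        data = (lf.gain_at(v) @ ori)[:, None] * s[None, :]
        dip_idx = [3, v, 30, 44]
        out = sf.estimate_sources(inv, data, lf.grid[dip_idx])
        assert int(np.argmax(out.var(axis=1))) == dip_idx.index(v)

    def test_four_dipoles_four_rows(self, coarse_leadfield, inv, rng):
        data = rng.standard_normal((coarse_leadfield.n_channels, 64))
        out = sf.estimate_sources(inv, data, coarse_leadfield.grid[:4])
        assert out.shape == (4, 64)

    def test_snapping_and_distance_error(self, coarse_leadfield, inv, rng):
        data = rng.standard_normal((coarse_leadfield.n_channels, 16))
        near = coarse_leadfield.grid[5] + np.array([4.0, -3.0, 2.0])
        out_near = sf.estimate_sources(inv, data, near[None, :])
        out_exact = sf.estimate_sources(
            inv, data, coarse_leadfield.grid[[5]]
        )
        assert np.allclose(out_near, out_exact)
        far = np.array([150.0, 150.0, 150.0])  # outside the grid hull
        with pytest.raises(ValueError, match="grid spacing"):
            sf.estimate_sources(inv, data, far[None, :])


@pytest.fixture(scope="module")
def setup(coarse_leadfield, sensors):
    rng = np.random.default_rng(5)
    lf = coarse_leadfield
    inv_op = sf.eloreta_kernel(lf, alpha=0.05)
    n_ch = lf.n_channels
    S = ar2_sources(rng, n=n_ch, T=1500, freqs=np.linspace(3, 45, n_ch))
    A = rng.standard_normal((n_ch, n_ch))
    decomp = pp.sobi(A @ S, lags=range(1, 30))
    dipoles = lf.grid[[5, 15, 25, 35]]
    return decomp, inv_op, dipoles


class TestBuildFeatures:
    def test_feature_matrix_dimensions(self, setup):
        """M = 31 components and n_l = 4 dipoles give exactly 124 rows."""
        decomp, inv, dipoles = setup
        fm = sf.build_features(decomp, inv, dipoles)
        assert decomp.n_components == 31
        assert fm.values.shape[0] == 124
        assert fm.n_components == 31 and fm.n_l == 4
        # row_map is a bijection onto (IC, dipole) pairs
        assert sorted(fm.row_map) == [
            (i, d) for i in range(31) for d in range(4)
        ]

    def test_blocks_sum_to_full_source_estimate(self, setup):
        """Linearity: the per-IC blocks sum to the source estimate of the
        full reconstructed data under the shared orientations."""
        decomp, inv, dipoles = setup
        fm = sf.build_features(decomp, inv, dipoles)
        n_l = fm.n_l
        total = np.zeros((n_l, fm.n_samples))
        for i in range(fm.n_components):
            total += fm.values[i * n_l : (i + 1) * n_l]
        full = decomp.mixing @ decomp.sources
        ori = sf.principal_orientations(inv, full, dipoles)
        direct = sf.estimate_sources(inv, full, dipoles, orientations=ori)
        assert np.abs(total - direct).max() < 1e-6 * np.abs(direct).max()

    def test_single_component_equals_direct_estimate(self, coarse_leadfield,
                                                     rng):
        lf = coarse_leadfield
        inv = sf.eloreta_kernel(lf, alpha=0.05)
        s = ar2_sources(rng, n=1, T=800)[0]
        a = rng.standard_normal(lf.n_channels)
        X = a[:, None] * s[None, :]
        decomp = pp.sobi(X, lags=range(1, 10))
        assert decomp.n_components == 1
        dipoles = lf.grid[[4, 22]]
        fm = sf.build_features(decomp, inv, dipoles)
        ori = sf.principal_orientations(inv, decomp.mixing @ decomp.sources,
                                        dipoles)
        direct = sf.estimate_sources(inv, X, dipoles, orientations=ori)
        assert np.abs(fm.values - direct).max() < 1e-6 * np.abs(direct).max()
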