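"""ROI diagonal filters: floor-sqrt indexing, gain contracts, Monte-Carlo
validation of the closed forms, cuboid quadrature, and the ROI split."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import roitsss as rt
from roitsss._harmonics import lm_ordering
from roitsss.roi_filter import (
    DiagonalFilter,
    _gains_from_energy_fractions,
    volume_energy_fraction_sphere,
)
from roitsss.sss_core import estimate_moments


# ---------------------------------------------------------------- indexing
def test_l_of_index_matches_column_enumeration():
    ordering = lm_ordering(8)
    for n in range(1, 81):
        assert rt.l_of_index(n) == ordering[n - 1][0]


def test_l_of_index_boundaries():
    assert rt.l_of_index(1) == 1
    assert rt.l_of_index(3) == 1
    assert rt.l_of_index(4) == 2
    assert rt.l_of_index(80) == 8
    for bad in (0, 81):
        with pytest.raises(IndexError):
            rt.l_of_index(bad)


# ---------------------------------------------------------------- effective R
def test_effective_r_examples():
    assert rt.effective_R([0, 0, 0], [0, 0, 0], 0.08) == pytest.approx(0.08)
    assert rt.effective_R([0.03, 0, 0], [0, 0, 0], 0.08) == pytest.approx(0.11)
    # origin-centred ROI with the sweep geometry: R stays the array radius
    assert rt.effective_R([0, 0, 0], [0, 0, 0], 0.08) == pytest.approx(0.08)
    with pytest.raises(ValueError):
        rt.effective_R([0, 0, 0], [0, 0, 0], -0.1)


# ---------------------------------------------------------------- sphere gains
def test_sphere_gains_closed_form_literal():
    """The implementation reproduces the printed closed forms exactly."""
    r, R, L = 0.05, 0.11, 8
    ls = np.arange(1, L + 1)
    g_expected = (R**5 - r**5) * r ** (2 * ls - 2) * (2 * ls + 3) / (
        (R ** (2 * ls + 3) - r ** (2 * ls + 3)) * 5
    )
    gn_expected = (
        r ** (2 * L - 2 * ls)
        * (R ** (2 * ls + 3) - r ** (2 * ls + 3))
        * (2 * L + 3)
        / ((R ** (2 * L + 3) - r ** (2 * L + 3)) * (2 * ls + 3))
    )
    g = rt.g_roi_sphere(r, R, L)
    gn = rt.g_not_roi_sphere(r, R, L)
    for l in ls:
        assert g.diag[g.l_index == l][0] == pytest.approx(g_expected[l - 1], rel=1e-12)
        assert gn.diag[gn.l_index == l][0] == pytest.approx(gn_expected[l - 1], rel=1e-12)


def test_sphere_gains_range_and_monotonicity():
    R, L = 0.08, 8
    radii = np.linspace(0.005, 0.075, 15)
    prev_g = prev_gn = None
    for r in radii:
        g = rt.g_roi_sphere(r, R, L).diag
        gn = rt.g_not_roi_sphere(r, R, L).diag
        assert np.all(g >= 0) and np.all(g <= 1 + 1e-12)
        assert np.all(gn >= 0) and np.all(gn <= 1 + 1e-12)
        if prev_g is not None:
            assert np.all(g >= prev_g - 1e-12)
            assert np.all(gn >= prev_gn - 1e-12)
        prev_g, prev_gn = g, gn


def test_sphere_gain_limits():
    """Shrinking ROI: gains vanish for l >= 2 while the dipole order stays
    fully attributed to the ROI (the normalisation of the closed form);
    growing ROI: all gains approach 1."""
    R = 0.08
    g_small = rt.g_roi_sphere(1e-4 * R, R, 8)
    assert g_small.diag[g_small.l_index == 1] == pytest.approx(1.0)
    assert np.all(g_small.diag[g_small.l_index >= 2] <= 1e-6)
    gn_small = rt.g_not_roi_sphere(1e-4 * R, R, 8)
    assert gn_small.diag[gn_small.l_index == 8] == pytest.approx(1.0)
    g_big = rt.g_roi_sphere(0.999999 * R, R, 8)
    assert np.all(g_big.diag >= 1 - 1e-4)
    gn_big = rt.g_not_roi_sphere(0.999999 * R, R, 8)
    assert gn_big.diag[gn_big.l_index == 8] == pytest.approx(1.0)


def test_sphere_gain_invalid_geometry():
    with pytest.raises(ValueError):
        rt.g_roi_sphere(0.09, 0.08)
    with pytest.raises(ValueError):
        rt.g_not_roi_sphere(0.08, 0.08)


def test_sphere_gains_match_monte_carlo_oracle():
    """The radial energy integrals behind the closed forms agree with a
    Monte-Carlo volume oracle (uniform points in the inner ball) within 1%."""
    rng = np.random.default_rng(1234)
    r, R, L = 0.05, 0.08, 8
    pts = rng.uniform(-R, R, size=(3_000_000, 3))
    a2 = np.sum(pts**2, axis=1)
    a2 = a2[a2 <= R * R]
    in_roi = a2 <= r * r
    ls = np.arange(1, L + 1)
    W_mc = np.array([np.sum(a2[in_roi] ** l) / np.sum(a2**l) for l in ls])
    W_an = volume_energy_fraction_sphere(r, R, ls)
    assert np.max(np.abs(W_mc - W_an) / W_an) <= 0.01
    g_mc, gn_mc = _gains_from_energy_fractions(W_mc, L)
    g_an, gn_an = _gains_from_energy_fractions(W_an, L)
    assert np.max(np.abs(g_mc - g_an) / g_an) <= 0.01
    assert np.max(np.abs(gn_mc - gn_an) / gn_an) <= 0.01


def test_complementarity_audit():
    """G_ROI + G_notROI is NOT the identity: the sum is ~1 at the
    normalisation degrees (l = 1 and l = L_in) and dips below 1 in between."""
    r, R, L = 0.04, 0.1, 8
    g = rt.g_roi_sphere(r, R, L)
    gn = rt.g_not_roi_sphere(r, R, L)
    total = g.diag + gn.diag
    assert total[g.l_index == 1][0] == pytest.approx(1.0, abs=1e-3)
    assert total[g.l_index == L][0] == pytest.approx(1.0, abs=1e-3)
    mid = total[(g.l_index > 1) & (g.l_index < L)]
    assert np.all(mid < 1.0)


@given(
    t=st.floats(min_value=1e-3, max_value=0.999),
    L=st.integers(min_value=2, max_value=10),
)
def test_gain_contract_property(t, L):
    """For any ROI fraction and truncation order, all gains lie in [0, 1]
    and follow the floor-sqrt degree indexing."""
    R = 0.1
    g = rt.g_roi_sphere(t * R, R, L)
    gn = rt.g_not_roi_sphere(t * R, R, L)
    for f in (g, gn):
        assert np.all(f.diag >= 0) and np.all(f.diag <= 1 + 1e-9)
        assert np.array_equal(
            f.l_index, np.floor(np.sqrt(np.arange(1, f.diag.size + 1))).astype(int)
        )


# ---------------------------------------------------------------- cuboid gains
def test_cuboid_below_matched_sphere():
    """A cube inscribed in a sphere recovers no more than the sphere, at
    every degree and every size."""
    R = 0.1
    for r in (0.02, 0.04, 0.06):
        side = 2 * r / np.sqrt(3)
        cube = rt.CuboidROI(center=np.zeros(3), sides=np.full(3, side))
        g_cube = rt.g_roi_cuboid(cube, np.zeros(3), R)
        g_sph = rt.g_roi_sphere(r, R)
        assert np.all(g_cube.diag <= g_sph.diag + 1e-9)


def test_cuboid_gain_vanishes_with_volume():
    cube = rt.CuboidROI(center=np.zeros(3), sides=np.full(3, 1e-5))
    g = rt.g_roi_cuboid(cube, np.zeros(3), 0.08)
    assert np.all(g.diag[g.l_index >= 2] <= 1e-6)


def test_cuboid_quadrature_converged():
    cube = rt.CuboidROI(center=np.zeros(3), sides=[0.10, 0.04, 0.02])
    g_coarse = rt.g_roi_cuboid(cube, np.zeros(3), 0.09, quadrature_nodes=10)
    g_fine = rt.g_roi_cuboid(cube, np.zeros(3), 0.09, quadrature_nodes=16)
    assert np.allclose(g_coarse.diag, g_fine.diag, rtol=1e-12)


def test_cuboid_rotation_invariance():
    from scipy.spatial.transform import Rotation

    rot = Rotation.from_euler("xyz", [20, 45, -30], degrees=True).as_matrix()
    sides = np.array([0.05, 0.03, 0.02])
    g0 = rt.g_roi_cuboid(rt.CuboidROI(center=np.zeros(3), sides=sides), np.zeros(3), 0.09)
    g1 = rt.g_roi_cuboid(
        rt.CuboidROI(center=np.zeros(3), sides=sides, rotation=rot), np.zeros(3), 0.09
    )
    assert np.allclose(g0.diag, g1.diag, rtol=1e-12)


def test_cuboid_monte_carlo_oracle():
    """Cuboid volume-energy fractions from Gauss-Legendre match uniform
    random sampling of the box within 1%."""
    from roitsss.roi_filter import _cuboid_moment_integral

    rng = np.random.default_rng(77)
    sides = np.array([0.06, 0.04, 0.03])
    pts = rng.uniform(-0.5, 0.5, size=(1_000_000, 3)) * sides
    vol = np.prod(sides)
    for l in (1, 3, 6, 8):
        mc = vol * np.mean(np.sum(pts**2, axis=1) ** l)
        gl = _cuboid_moment_integral(sides, l, l + 3)
        assert abs(mc - gl) / gl <= 0.01


def test_cuboid_too_large_rejected():
    cube = rt.CuboidROI(center=np.zeros(3), sides=np.full(3, 0.2))
    with pytest.raises(ValueError, match="circumscribing"):
        rt.g_roi_cuboid(cube, np.zeros(3), 0.08)


# ---------------------------------------------------------------- split
def _interior_moments(rec_data, basis):
    return estimate_moments(rec_data, basis)


def test_split_identity_filters(two_shell, two_shell_basis):
    """G_ROI = I, G_notROI = 0 reproduces b_in exactly."""
    b = rt.dipole_forward([0, 0.01, 0.03], [1e-8, 0, 0], two_shell)
    m = _interior_moments(b[:, None], two_shell_basis)
    ones = DiagonalFilter(
        diag=np.ones(80),
        l_index=np.floor(np.sqrt(np.arange(1, 81))).astype(int),
        provenance="sphere_closed_form",
    )
    zeros = DiagonalFilter(
        diag=np.zeros(80), l_index=ones.l_index.copy(), provenance="sphere_closed_form"
    )
    b_roi, b_not = rt.split_by_roi(m, (ones, zeros), two_shell_basis)
    b_in, _ = rt.reconstruct_components(m, two_shell_basis)
    assert np.array_equal(b_roi.data, b_in.data)
    assert not b_not.data.any()


def test_split_deep_versus_superficial(helmet, helmet_basis):
    """A deep source inside the ROI stays in the ROI subspace; a superficial
    source sheds far more power into the non-ROI subspace."""
    roi = rt.SphericalROI(center=[0, 0, 0.04], radius=0.04)
    arr = float(np.median(np.linalg.norm(helmet.positions, axis=1)))
    R = rt.effective_R(roi.center, np.zeros(3), arr)
    g = rt.g_roi_sphere(roi.radius, R)
    gn = rt.g_not_roi_sphere(roi.radius, R)

    def not_share(pos):
        b = rt.dipole_forward(pos, [1e-8, 1e-9, 0], helmet, sphere_radius=0.065)
        m = _interior_moments(b[:, None], helmet_basis)
        b_roi, b_not = rt.split_by_roi(m, (g, gn), helmet_basis)
        p_r, p_n = np.sum(b_roi.data**2), np.sum(b_not.data**2)
        return p_n / (p_r + p_n)

    deep = not_share([0, 0, 0.04])           # inside the ROI
    superficial = not_share([0.05, 0.03, -0.01])  # near the phantom surface
    assert 1 - deep >= 0.95
    assert superficial >= 30 * deep


def test_split_commutes_with_scaling(two_shell_basis):
    rng = np.random.default_rng(2)
    x = rng.normal(size=(80, 5))
    g = rt.g_roi_sphere(0.04, 0.09)
    gn = rt.g_not_roi_sphere(0.04, 0.09)
    a1, _ = rt.split_by_roi(7.5 * x, (g, gn), two_shell_basis)
    a2, _ = rt.split_by_roi(x, (g, gn), two_shell_basis)
    assert np.allclose(a1.data, 7.5 * a2.data, rtol=1e-13)


def test_split_dimension_mismatch(two_shell_basis):
    g = rt.g_roi_sphere(0.04, 0.09, L_in=6)  # 48 entries, basis expects 80
    gn = rt.g_not_roi_sphere(0.04, 0.09, L_in=6)
    with pytest.raises(ValueError, match="filter length"):
        rt.split_by_roi(np.zeros((80, 2)), (g, gn), two_shell_basis)
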