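import math

import numpy as np
import pandas as pd
import pytest
import biotite.structure as struc

from dmsallo.structure import (
    MAX_ASA,
    PAULING_RADII,
    compute_sasa,
    distance_profile,
    distance_to_anchor,
    enrichment_test,
    make_synthetic_chain,
    relative_sasa,
    sector_contact,
)


def atom_array(entries):
    """entries: list of (res_id, res_name, atom_name, element, xyz)."""
    arr = struc.AtomArray(len(entries))
    arr.coord = np.array([e[4] for e in entries], dtype=float)
    arr.chain_id[:] = "A"
    arr.res_id = np.array([e[0] for e in entries])
    arr.res_name = np.array([e[1] for e in entries])
    arr.atom_name = np.array([e[2] for e in entries])
    arr.element = np.array([e[3] for e in entries])
    arr.hetero[:] = False
    return arr


def shrake_rupley_oracle(coords, radii, probe=1.4, n_points=4000, seed=0):
    """Independent brute-force rolling-probe surface area per atom."""
    rng = np.random.default_rng(seed)
    # uniform sphere points by normalized Gaussians
    pts = rng.normal(size=(n_points, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    areas = []
    for i, (c, r) in enumerate(zip(coords, radii)):
        rr = r + probe
        surface = c + rr * pts
        exposed = np.ones(n_points, dtype=bool)
        for j, (c2, r2) in enumerate(zip(coords, radii)):
            if j == i:
                continue
            exposed &= np.linalg.norm(surface - c2, axis=1) > (r2 + probe)
        areas.append(4 * math.pi * rr**2 * exposed.mean())
    return np.array(areas)


def test_single_atom_area_is_analytic_sphere():
    arr = atom_array([(1, "GLY", "CA", "C", (0.0, 0.0, 0.0))])
    area = compute_sasa(arr, n_points=10_000)["area"][0]
    expected = 4 * math.pi * (1.7 + 1.4) ** 2
    assert area == pytest.approx(expected, rel=1e-2)


def test_buried_atom_has_zero_area():
    # central atom caged by a dense shell of atoms at 2 A
    rng = np.random.default_rng(3)
    pts = rng.normal(size=(80, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    entries = [(1, "GLY", "CA", "C", (0.0, 0.0, 0.0))]
    entries += [(2, "GLY", "CA", "C", tuple(2.0 * p)) for p in pts]
    arr = atom_array(entries)
    sasa = struc.sasa(arr, probe_radius=1.4, point_number=960, vdw_radii="Single")
    assert sasa[0] == 0.0


def test_areas_match_independent_rolling_probe_oracle():
    coords = np.array([[0.0, 0.0, 0.0], [2.0, 0.3, 0.1], [3.5, -0.5, 0.4]])
    entries = [
        (1, "GLY", "N", "N", tuple(coords[0])),
        (1, "GLY", "CA", "C", tuple(coords[1])),
        (1, "GLY", "C", "C", tuple(coords[2])),
    ]
    arr = atom_array(entries)
    impl = struc.sasa(arr, probe_radius=1.4, point_number=10_000, vdw_radii="Single")
    radii = [1.55, 1.7, 1.7]  # the "Single" set values for N and C
    oracle = shrake_rupley_oracle(coords, radii, n_points=20_000)
    assert np.allclose(impl, oracle, rtol=0.03)


def test_point_density_convergence(toy_chain):
    a_coarse = compute_sasa(toy_chain, n_points=960)["area"].to_numpy()
    a_fine = compute_sasa(toy_chain, n_points=1920)["area"].to_numpy()
    assert np.all(np.abs(a_coarse - a_fine) / a_fine < 0.05)


def test_relative_sasa_strict_cutoff():
    areas = pd.DataFrame(
        {
            "res_id": [1, 2, 3, 4],
            "res_name": ["ALA", "GLY", "TRP", "XXX"],
            "area": [MAX_ASA["ALA"], 0.25 * MAX_ASA["GLY"], 0.0, 10.0],
        }
    )
    out = relative_sasa(areas)
    assert out.loc[0, "rsa"] == pytest.approx(1.0) and bool(out.loc[0, "surface"])
    assert not out.loc[1, "surface"]  # exactly 25% is NOT surface
    assert not out.loc[2, "surface"]  # fully buried
    assert math.isnan(out.loc[3, "rsa"]) and not out.loc[3, "surface"]


def test_contact_threshold_is_sharp():
    limit = 1.2 * (PAULING_RADII["C"] + PAULING_RADII["N"])
    for eps, expected in [(-1e-6, True), (+1e-6, False)]:
        arr = atom_array(
            [
                (1, "ALA", "C", "C", (0.0, 0.0, 0.0)),
                (2, "ALA", "N", "N", (limit + eps, 0.0, 0.0)),
            ]
        )
        flags = sector_contact(arr, sector_residues={2}, backbone_atoms=("N", "C", "O"))
        assert flags[1] is expected


def test_contact_matches_brute_force_oracle(rng):
    chain = make_synthetic_chain("ACDEF", rng=rng, jitter=0.3)
    sector = {3}
    flags = sector_contact(chain, sector)
    elem_r = np.array([PAULING_RADII[e] for e in chain.element])
    for rid in np.unique(chain.res_id):
        if rid in sector:
            continue
        expected = False
        m = (chain.res_id == rid) & np.isin(chain.atom_name, ["N", "C", "O"])
        s = np.isin(chain.res_id, list(sector))
        for i in np.flatnonzero(m):
            for j in np.flatnonzero(s):
                d = np.linalg.norm(chain.coord[i] - chain.coord[j])
                if d <= 1.2 * (elem_r[i] + elem_r[j]):
                    expected = True
        assert flags[int(rid)] == expected


def test_distance_profile_on_collinear_calphas():
    entries = [(i, "GLY", "CA", "C", (5.0 * (i - 1), 0.0, 0.0)) for i in range(1, 8)]
    arr = atom_array(entries)
    d = distance_to_anchor(arr, anchor=1)
    assert d[1] == 0.0 and d[3] == pytest.approx(10.0)
    profile = distance_profile(
        {"near": [1, 2, 3], "far": [6, 7], "empty": []}, d, bins=[10.0, 30.0]
    )
    assert profile.loc[10.0, "near"] == pytest.approx(1.0)  # 0, 5, 10 A
    assert profile.loc[10.0, "far"] == pytest.approx(0.0)  # 25, 30 A
    assert profile.loc[30.0, "far"] == pytest.approx(1.0)
    assert math.isnan(profile.loc[10.0, "empty"])


def test_anchor_without_calpha_raises():
    arr = atom_array([(1, "GLY", "CA", "C", (0, 0, 0))])
    with pytest.raises(ValueError):
        distance_to_anchor(arr, anchor=121)


def test_rigid_motion_invariance(toy_chain):
    theta = 0.7
    rot = np.array(
        [
            [math.cos(theta), -math.sin(theta), 0],
            [math.sin(theta), math.cos(theta), 0],
            [0, 0, 1],
        ]
    )
    moved = toy_chain.copy()
    moved.coord = toy_chain.coord @ rot.T + np.array([10.0, -3.0, 7.0])
    sector = {5, 6}
    assert sector_contact(toy_chain, sector) == sector_contact(moved, sector)
    d0 = distance_to_anchor(toy_chain, anchor=10)
    d1 = distance_to_anchor(moved, anchor=10)
    assert np.allclose(d0.to_numpy(), d1.to_numpy(), atol=1e-6)


def fisher_two_sided_oracle(a, b, c, d):
    """Exact two-sided Fisher p by hypergeometric enumeration (math.comb)."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    denom = math.comb(n, c1)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    pmf = {
        k: math.comb(r1, k) * math.comb(n - r1, c1 - k) / denom
        for k in range(lo, hi + 1)
    }
    p_obs = pmf[a]
    return sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-12))


def test_perfect_association_table():
    universe = set(range(20))
    table = enrichment_test(set(range(10)), set(range(10)), universe)
    assert table.p_value == pytest.approx(2 / math.comb(20, 10), rel=1e-9)
    assert table.in_class_in_annot == 10 and table.out_class_out_annot == 10
    assert table.odds_ratio > 1  # Haldane-corrected (zero cells)


def test_independent_sets_and_degenerate_class():
    universe = set(range(16))
    # maximally expected table at these margins: p = 1
    cls = {0, 1, 2, 3, 4, 5, 6, 7}
    ann = {0, 1, 2, 3, 8, 9, 10, 11}
    assert enrichment_test(cls, ann, universe).p_value == pytest.approx(1.0)
    assert enrichment_test(universe, ann, universe).p_value == pytest.approx(1.0)
    with pytest.raises(ValueError):
        enrichment_test(cls, ann, set())


def test_fisher_matches_enumeration_on_random_tables(rng):
    from scipy.stats import fisher_exact

    for _ in range(50):
        a, b, c, d = rng.integers(0, 12, size=4)
        if a + b + c + d == 0:
            continue
        _, p = fisher_exact([[a, b], [c, d]])
        assert p == pytest.approx(fisher_two_sided_oracle(a, b, c, d), rel=1e-9)
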