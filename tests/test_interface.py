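"""Superposition, trajectory metrics, energies, contacts, and the panel."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from crydimer import (
    Ensemble,
    FixtureSpec,
    HBondCriteria,
    NonbondedParams,
    RadiiSet,
    SaltBridgeCriteria,
    Structure,
    assign_minimal_params,
    build_interface_panel,
    detect_hbonds,
    detect_salt_bridges,
    interaction_energy,
    interface_area,
    kabsch_superpose,
    make_dimer_pose,
    pair_energy,
    radius_of_gyration,
    rmsd_series,
    rmsf,
    switching_factor,
    synthesize_trajectory,
)
from crydimer.geometry import backbone_mask, carbon_mask

from conftest import two_chain_points


def quaternion_rmsd(x, y):
    """Independent minimal-RMSD via the Horn quaternion eigenvalue method."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    s = xc.T @ yc
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    f = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(f)[-1]
    g = (xc**2).sum() + (yc**2).sum()
    return np.sqrt(max(0.0, g - 2.0 * lam) / len(x))


# --- Kabsch ------------------------------------------------------------------


def test_kabsch_identity():
    x = np.random.default_rng(0).normal(size=(10, 3))
    sup = kabsch_superpose(x, x)
    assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-12)


def test_kabsch_recovers_known_transform():
    rng = np.random.default_rng(1)
    x = rng.normal(size=(30, 3))
    rot = Rotation.from_euler("zxz", [10, 70, -30], degrees=True).as_matrix()
    t = np.array([1.0, -2.0, 3.0])
    y = x @ rot.T + t
    sup = kabsch_superpose(x, y)
    assert sup.rmsd <= 1e-8
    np.testing.assert_allclose(sup.rotation, rot, atol=1e-9)
    np.testing.assert_allclose(sup.translation, t, atol=1e-9)


def test_kabsch_agrees_with_quaternion_oracle_and_stays_proper():
    rng = np.random.default_rng(7)
    for _ in range(100):
        x = rng.normal(size=(50, 3))
        y = rng.normal(size=(50, 3))
        sup = kabsch_superpose(x, y)
        assert abs(sup.rmsd - quaternion_rmsd(x, y)) <= 1e-6
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)


def test_kabsch_input_validation():
    x = np.zeros((5, 3))
    with pytest.raises(ValueError, match="mismatch"):
        kabsch_superpose(x, np.zeros((4, 3)))
    with pytest.raises(ValueError):
        kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


# --- RMSD series -------------------------------------------------------------


def test_rmsd_series_identical_frames_zero(pose5):
    ens = Ensemble([pose5] * 4)
    vals, mean, sd = rmsd_series(ens, 0)
    np.testing.assert_allclose(vals, 0.0, atol=1e-6)
    assert mean == pytest.approx(0.0, abs=1e-6)
    assert sd == pytest.approx(0.0, abs=1e-6)


def test_rmsd_series_removes_rigid_motion(pose5):
    rng = np.random.default_rng(5)
    frames = [pose5]
    for _ in range(3):
        rot = Rotation.random(random_state=rng.integers(1 << 31)).as_matrix()
        frames.append(pose5.transformed(rot, rng.normal(size=3)))
    vals, _, _ = rmsd_series(Ensemble(frames), 0)
    np.testing.assert_allclose(vals, 0.0, atol=1e-5)


def test_rmsd_series_matches_quaternion_oracle(monomer, monomer_spec):
    spec = FixtureSpec(**{**monomer_spec.__dict__, "seed": 13,
                          "n_frames": 5, "jitter_sigma": 0.3})
    ens = synthesize_trajectory(monomer, spec)
    sel = backbone_mask(ens.topology)
    vals, _, _ = rmsd_series(ens, 0, sel)
    ref = ens[0].coords[sel].astype(float)
    expected = [
        quaternion_rmsd(fr.coords[sel].astype(float), ref) for fr in ens
    ]
    np.testing.assert_allclose(vals, expected, atol=1e-6)


def test_rmsd_series_empty_selection_rejected(pose5):
    ens = Ensemble([pose5, pose5])
    with pytest.raises(ValueError, match="selection"):
        rmsd_series(ens, 0, np.zeros(pose5.n_atoms, dtype=bool))


# --- RMSF --------------------------------------------------------------------


def test_rmsf_zero_for_identical_frames(pose5):
    vals = rmsf(Ensemble([pose5] * 3))
    np.testing.assert_allclose(vals, 0.0, atol=1e-6)


def test_rmsf_single_frame_undefined(pose5):
    with pytest.raises(ValueError):
        rmsf(Ensemble([pose5]))


def test_rmsf_single_mobile_atom():
    rng = np.random.default_rng(3)
    base = np.array(
        [[0, 0, 0], [4, 0, 0], [0, 4, 0], [0, 0, 4], [4, 4, 0], [4, 0, 4]],
        dtype=float,
    )
    frames = []
    for _ in range(200):
        c = base.copy()
        c[5] += rng.normal(scale=0.5, size=3)
        frames.append(Structure.from_arrays(c, ["C"] * 6))
    # fit on the five fixed atoms so the mobile one carries all motion
    fit_sel = np.array([True] * 5 + [False])
    vals = rmsf(Ensemble(frames), np.ones(6, dtype=bool), fit_sel)
    assert np.all(vals[:5] < 0.05)
    assert vals[5] > 0.5


def test_rmsf_recovers_isotropic_jitter_sigma():
    spec = FixtureSpec(helix_length=6, seed=21, n_frames=2000,
                       jitter_sigma=0.5)
    from crydimer import make_helix_monomer

    mono = make_helix_monomer(spec)
    ens = synthesize_trajectory(mono, spec)
    vals = rmsf(ens, carbon_mask(ens.topology))
    expected = 0.5 * np.sqrt(3.0)
    assert np.all(np.abs(vals / expected - 1.0) < 0.05)


# --- radius of gyration ------------------------------------------------------


def test_rg_closed_forms():
    single = Structure.from_arrays([[1.0, 2.0, 3.0]], ["C"])
    assert radius_of_gyration(single) == pytest.approx(0.0)
    two = Structure.from_arrays([[-1.0, 0, 0], [1.0, 0, 0]], ["C", "C"])
    assert radius_of_gyration(two) == pytest.approx(1.0)


def test_rg_matches_direct_summation():
    rng = np.random.default_rng(8)
    coords = rng.uniform(-10, 10, (100, 3))
    elements = rng.choice(["C", "N", "O", "S"], size=100)
    s = Structure.from_arrays(coords, elements)
    from crydimer.geometry import ATOMIC_MASS

    m = np.array([ATOMIC_MASS[e] for e in elements])
    c32 = s.coords.astype(float)
    com = (m[:, None] * c32).sum(0) / m.sum()
    direct = np.sqrt((m * ((c32 - com) ** 2).sum(1)).sum() / m.sum())
    assert radius_of_gyration(s) == pytest.approx(direct, abs=1e-10)


# --- interaction energy ------------------------------------------------------


def _charged_pair(d):
    return two_chain_points(
        [[0, 0, 0]], [[d, 0, 0]], elements="N", atom_name="NZ",
        res_name="LYS",
    )


def test_coulomb_closed_form_inside_switch_region():
    p = NonbondedParams(charge=[1.0, -1.0], epsilon=[0, 0], rmin2=[1, 1])
    _, ee, et = interaction_energy(_charged_pair(5.0), ("A", "B"), p)
    assert et == pytest.approx(-332.0636 / 5.0, rel=1e-6)


def test_zero_beyond_cutoff():
    p = NonbondedParams(charge=[1.0, -1.0], epsilon=[0.2, 0.2],
                        rmin2=[2.0, 2.0])
    assert interaction_energy(_charged_pair(13.0), ("A", "B"), p) == (
        0.0, 0.0, 0.0,
    )


def test_lj_minimum_value():
    p = NonbondedParams(charge=[0, 0], epsilon=[0.2, 0.2], rmin2=[2.0, 2.0])
    ev, _, _ = interaction_energy(_charged_pair(4.0), ("A", "B"), p)
    assert ev == pytest.approx(-0.2, rel=1e-6)


def test_switching_function_shape():
    assert switching_factor(9.0, 10.0, 12.0) == 1.0
    assert switching_factor(12.0, 10.0, 12.0) == 0.0
    mid = switching_factor(11.0, 10.0, 12.0)
    assert 0.0 < mid < 1.0


def test_energy_continuity_across_switch_boundaries():
    grid = np.arange(9.5, 12.5, 0.001)
    ev, ee = pair_energy(grid, 1.0, -1.0, 0.2, 0.2, 2.0, 2.0)
    e = ev + ee
    assert np.all(np.isfinite(e))
    assert np.all(e[grid >= 12.0] == 0.0)
    for boundary in (10.0, 12.0):
        below = np.sum(pair_energy(boundary - 1e-8, 1.0, -1.0, 0.2, 0.2,
                                   2.0, 2.0))
        above = np.sum(pair_energy(boundary + 1e-8, 1.0, -1.0, 0.2, 0.2,
                                   2.0, 2.0))
        assert abs(above - below) < 1e-6


def test_minimal_params_and_errors(pose5):
    params = assign_minimal_params(pose5)
    assert len(params.charge) == pose5.n_atoms
    # lysine NZ carries the formal +1
    nz = (pose5.atoms.res_name == "LYS") & (pose5.atoms.atom_name == "NZ")
    assert np.all(params.charge[np.flatnonzero(nz)] == 1.0)
    bad = Structure.from_arrays([[0, 0, 0], [5, 0, 0]], ["C", "XX"],
                                chain_ids=["A", "B"])
    with pytest.raises(KeyError):
        assign_minimal_params(bad)
    with pytest.raises(ValueError, match="switch_start"):
        NonbondedParams(charge=[0], epsilon=[0], rmin2=[1],
                        cutoff=10.0, switch_start=12.0)


def test_energy_invariant_under_rigid_motion(pose5):
    params = assign_minimal_params(pose5)
    rot = Rotation.from_euler("xyz", [11, 23, 37], degrees=True).as_matrix()
    moved = pose5.transformed(rot, np.array([3.0, 1.0, -6.0]))
    e0 = interaction_energy(pose5, ("A", "B"), params)
    e1 = interaction_energy(moved, ("A", "B"), params)
    np.testing.assert_allclose(e0, e1, rtol=1e-3, atol=1e-4)


# --- interface area ----------------------------------------------------------

R_EXT = 3.1  # carbon + water probe


def test_interface_area_zero_when_separated():
    d = 2 * R_EXT + 1.0
    s = two_chain_points([[0, 0, 0]], [[d, 0, 0]], elements="C",
                         atom_name="C", res_name="ALA")
    assert interface_area(s, ("A", "B")) == 0.0


def test_interface_area_two_sphere_cap_value():
    d = 3.1
    s = two_chain_points([[0, 0, 0]], [[d, 0, 0]], elements="C",
                         atom_name="C", res_name="ALA")
    a_is = interface_area(s, ("A", "B"), RadiiSet(n_sphere_points=960))
    exact = 2 * 2 * np.pi * R_EXT * (R_EXT - d / 2.0)
    assert a_is == pytest.approx(exact, rel=0.01)
    assert exact == pytest.approx(60.38, abs=0.01)


def test_interface_area_non_increasing_with_separation():
    seps = [3.1, 4.0, 5.0, 6.0, 7.5]
    vals = []
    for d in seps:
        s = two_chain_points([[0, 0, 0]], [[d, 0, 0]], elements="C",
                             atom_name="C", res_name="ALA")
        vals.append(interface_area(s, ("A", "B")))
    assert all(a >= b for a, b in zip(vals, vals[1:]))
    assert vals[-1] == 0.0


def test_interface_area_symmetric_under_chain_relabel(pose5):
    ab = interface_area(pose5, ("A", "B"))
    ba = interface_area(pose5, ("B", "A"))
    assert ab == pytest.approx(ba, rel=1e-9)
    assert ab > 0


# --- hydrogen bonds ----------------------------------------------------------


def _nho(angle_deg):
    """Donor N at origin, H at 1 Å, acceptor placed at the given D-H-A angle."""
    h = np.array([1.0, 0.0, 0.0])
    theta = np.deg2rad(180.0 - angle_deg)
    acc = h + 1.9 * np.array([np.cos(theta), np.sin(theta), 0.0])
    return Structure.from_arrays(
        [[0, 0, 0], h, acc],
        ["N", "H", "O"],
        atom_names=["N", "H", "O"],
        res_names=["ALA", "ALA", "SER"],
        res_ids=[1, 1, 2],
        chain_ids=["A", "A", "B"],
    )


def test_ideal_linear_hbond_detected():
    bonds = detect_hbonds(_nho(180.0), ("A", "B"))
    assert len(bonds) == 1
    assert bonds[0].angle == pytest.approx(180.0)
    assert bonds[0].distance == pytest.approx(2.9, abs=0.01)


def test_bent_hbond_rejected():
    assert detect_hbonds(_nho(90.0), ("A", "B")) == []


def test_hbond_angle_floor_is_honoured():
    assert detect_hbonds(_nho(139.0), ("A", "B")) == []
    assert len(detect_hbonds(_nho(141.0), ("A", "B"))) == 1


def test_hbond_ladder_matches_brute_force():
    # two parallel strands, four N-H...O=C rungs at 2.9 Å, perfectly linear
    coords, els, names, res_ids, chains = [], [], [], [], []
    for i in range(4):
        z = 3.5 * i
        coords += [[0, 0, z], [1, 0, z], [2.9, 0, z], [3.9, 0, z]]
        els += ["N", "H", "O", "C"]
        names += ["N", "H", "O", "C"]
        res_ids += [i + 1, i + 1, i + 1, i + 1]
        chains += ["A", "A", "B", "B"]
    s = Structure.from_arrays(coords, els, atom_names=names,
                              res_names=["GLY"] * len(els),
                              res_ids=res_ids, chain_ids=chains)
    crit = HBondCriteria()
    found = detect_hbonds(s, ("A", "B"), crit)
    assert len(found) == 4

    # brute force triple loop over (donor, hydrogen, acceptor)
    c = np.array(coords, dtype=float)
    brute = 0
    for i in range(len(els)):
        if chains[i] != "A" or els[i] != "N":
            continue
        for h in range(len(els)):
            if els[h] != "H" or res_ids[h] != res_ids[i]:
                continue
            for j in range(len(els)):
                if chains[j] != "B" or els[j] not in ("N", "O", "S"):
                    continue
                d = np.linalg.norm(c[j] - c[i])
                v1, v2 = c[i] - c[h], c[j] - c[h]
                ang = np.degrees(
                    np.arccos(
                        np.dot(v1, v2)
                        / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    )
                )
                if d <= crit.max_da_distance and ang >= crit.min_dha_angle:
                    brute += 1
    assert brute == 4


def test_hbond_requires_hydrogens_unless_fallback():
    s = two_chain_points([[0, 0, 0]], [[2.9, 0, 0]], elements="N",
                         atom_name="N", res_name="ALA")
    with pytest.raises(ValueError, match="fallback"):
        detect_hbonds(s, ("A", "B"))
    bonds = detect_hbonds(s, ("A", "B"), heavy_only_fallback=True)
    assert len(bonds) == 1
    assert np.isnan(bonds[0].angle)


# --- salt bridges ------------------------------------------------------------


def _scheduled_ensemble(monomer, occupancies, n_frames=100):
    pairs = [(("A", 17), ("B", 15)), (("A", 17), ("B", 4))]
    schedule = {
        pairs[i]: occ for i, occ in enumerate(occupancies)
    }
    pose = make_dimer_pose(monomer, 5.0, c2=True, seed=1)
    spec = FixtureSpec(
        helix_length=20, cys_positions=(10,), lys_positions=(4, 15),
        asp_positions=(17,), seed=2, n_frames=n_frames, jitter_sigma=0.0,
        occupancy_schedule=schedule,
    )
    return synthesize_trajectory(pose, spec)


@pytest.mark.parametrize(
    "occ,retained", [(0.05, False), (0.10, False), (0.11, True)]
)
def test_occupancy_filter_is_strict(monomer, occ, retained):
    ens = _scheduled_ensemble(monomer, [occ])
    bridges = detect_salt_bridges(ens, ("A", "B"))
    labels = {(b.anionic[:2], b.cationic[:2]) for b in bridges}
    present = (("A", 17), ("B", 15)) in labels
    assert present == retained
    if retained:
        b = next(iter(bridges))
        assert b.occupancy == pytest.approx(occ)


def test_salt_bridge_return_all_reports_subthreshold(monomer):
    ens = _scheduled_ensemble(monomer, [0.05])
    all_bridges = detect_salt_bridges(ens, ("A", "B"), return_all=True)
    assert any(b.occupancy == pytest.approx(0.05) for b in all_bridges)


# --- panel -------------------------------------------------------------------


def test_static_panel_has_zero_sds_and_single_frame_means(pose5):
    bonded = pose5
    ens = Ensemble([bonded] * 5)
    radii = RadiiSet(n_sphere_points=960)
    panel = build_interface_panel(ens, ("A", "B"), radii=radii)
    assert panel.e_tot[1] == pytest.approx(0.0, abs=1e-9)
    assert panel.r_g[1] == pytest.approx(0.0, abs=1e-9)
    assert panel.a_is[1] == pytest.approx(0.0, abs=1e-9)
    params = assign_minimal_params(bonded)
    _, _, et = interaction_energy(bonded, ("A", "B"), params)
    assert panel.e_tot[0] == pytest.approx(et, rel=1e-9)
    assert panel.r_g[0] == pytest.approx(radius_of_gyration(bonded), rel=1e-9)
    assert panel.a_is[0] == pytest.approx(
        interface_area(bonded, ("A", "B"), radii), rel=1e-9
    )
    assert panel.rmsd[0] == pytest.approx(0.0, abs=1e-9)
    assert panel.rmsd[1] == pytest.approx(0.0, abs=1e-9)


def test_panel_counts_scheduled_bridges(monomer):
    # lysines 4 and 15 both face Asp17 of the partner; a third pairing uses
    # the other chain's aspartate
    schedule = {
        (("A", 17), ("B", 15)): 0.5,
        (("A", 17), ("B", 4)): 0.5,
        (("B", 17), ("A", 15)): 0.5,
        (("B", 17), ("A", 4)): 0.05,
    }
    pose = make_dimer_pose(monomer, 5.0, c2=True, seed=1)
    spec = FixtureSpec(
        helix_length=20, cys_positions=(10,), lys_positions=(4, 15),
        asp_positions=(17,), seed=6, n_frames=20, jitter_sigma=0.0,
        occupancy_schedule=schedule,
    )
    ens = synthesize_trajectory(pose, spec)
    bridges = detect_salt_bridges(ens, ("A", "B"))
    assert len(bridges) == 3
    occs = sorted(b.occupancy for b in bridges)
    assert occs == [0.5, 0.5, 0.5]


def test_panel_is_compositionally_consistent(monomer, monomer_spec):
    pose = make_dimer_pose(monomer, 5.0, c2=True, seed=1)
    spec = FixtureSpec(**{**monomer_spec.__dict__, "seed": 30,
                          "n_frames": 4, "jitter_sigma": 0.2})
    ens = synthesize_trajectory(pose, spec)
    radii = RadiiSet(n_sphere_points=960)
    panel = build_interface_panel(ens, ("A", "B"), radii=radii)
    params = assign_minimal_params(pose)
    e_tot = [interaction_energy(f, ("A", "B"), params)[2] for f in ens]
    assert panel.e_tot[0] == pytest.approx(np.mean(e_tot), rel=1e-9)
    rg = [radius_of_gyration(f) for f in ens]
    assert panel.r_g[0] == pytest.approx(np.mean(rg), rel=1e-9)
    ais = [interface_area(f, ("A", "B"), radii) for f in ens]
    assert panel.a_is[0] == pytest.approx(np.mean(ais), rel=1e-9)
    _, rmsd_mean, _ = rmsd_series(ens, 0)
    assert panel.rmsd[0] == pytest.approx(rmsd_mean, rel=1e-9)
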