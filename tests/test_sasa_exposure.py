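"""Surface-area engine and exposure normalisation against analytic oracles."""

import numpy as np
import pandas as pd
import pytest

from crydimer import (
    Ensemble,
    ExposureProfile,
    FixtureSpec,
    RadiiSet,
    Structure,
    classify_cysteines,
    compute_msa_reference,
    count_accessible_cysteines,
    fit_dtnb_calibration,
    make_helix_monomer,
    make_tripeptide,
    residue_exposure,
    shrake_rupley_sasa,
    synthesize_trajectory,
    time_average_exposure,
)
from crydimer.sasa import UnmappedElementError, sphere_points

from conftest import single_atom_structure, two_chain_points

R_EXT = 1.7 + 1.4  # carbon + water probe


def two_sphere_exposed_area(r_ext: float, d: float) -> float:
    """Exposed area of one of two equal spheres at centre distance d."""
    cap_h = r_ext - d / 2.0
    return 4.0 * np.pi * r_ext**2 - 2.0 * np.pi * r_ext * cap_h


def test_isolated_sphere_matches_closed_form():
    s = single_atom_structure("C")
    area = shrake_rupley_sasa(s, RadiiSet(n_sphere_points=960))[0]
    exact = 4.0 * np.pi * R_EXT**2
    assert area == pytest.approx(exact, rel=0.01)


def test_well_separated_atoms_are_isolated():
    d = 2 * R_EXT + 0.5
    s = Structure.from_arrays([[0, 0, 0], [d, 0, 0]], ["C", "C"])
    areas = shrake_rupley_sasa(s, RadiiSet(n_sphere_points=960))
    exact = 4.0 * np.pi * R_EXT**2
    np.testing.assert_allclose(areas, exact, rtol=1e-12)


@pytest.mark.parametrize("n_points,rtol", [(960, 0.01), (10000, 0.002)])
def test_two_sphere_cap_oracle(n_points, rtol):
    d = 3.1
    s = Structure.from_arrays([[0, 0, 0], [d, 0, 0]], ["C", "C"])
    areas = shrake_rupley_sasa(s, RadiiSet(n_sphere_points=n_points))
    exact = two_sphere_exposed_area(R_EXT, d)
    np.testing.assert_allclose(areas, exact, rtol=rtol)


def test_sphere_lattice_is_unit_and_quasi_uniform():
    pts = sphere_points(960)
    np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
    # centroid of a uniform point set is near the origin
    assert np.linalg.norm(pts.mean(axis=0)) < 5e-3


def test_rigid_motion_invariance(monomer):
    from scipy.spatial.transform import Rotation

    radii = RadiiSet(n_sphere_points=960)
    base = shrake_rupley_sasa(monomer, radii)
    rot = Rotation.from_euler("zyx", [31.0, -57.0, 13.0], degrees=True)
    moved = monomer.transformed(rot.as_matrix(), np.array([5.0, -3.0, 8.0]))
    after = shrake_rupley_sasa(moved, radii)
    # lattice is fixed in space, so only near-identity is expected
    assert abs(after.sum() / base.sum() - 1.0) < 0.005


def test_unmapped_element_is_reported():
    s = single_atom_structure("XX")
    with pytest.raises(UnmappedElementError, match="XX"):
        shrake_rupley_sasa(s)


def test_accuracy_floor_refused():
    with pytest.raises(ValueError, match="32"):
        RadiiSet(n_sphere_points=16)


# --- exposure normalisation -------------------------------------------------


def _cys_profile(atom_sasa_value, msa_table):
    trip = make_tripeptide("CYS")
    sasa = shrake_rupley_sasa(trip, RadiiSet())
    return residue_exposure(sasa, trip, msa_table)


def test_exposure_is_100_when_sasa_equals_msa(msa_small, radii960):
    trip = make_tripeptide("CYS")
    sasa = shrake_rupley_sasa(trip, radii960)
    profile = residue_exposure(sasa, trip, msa_small, scope="sidechain")
    # the MSA reference was built from exactly this conformer
    cys_row = profile.table[profile.table.residue_name == "CYS"].iloc[0]
    assert cys_row.exposure_pct == pytest.approx(100.0, abs=1e-9)


def test_exposure_direct_arithmetic_and_scale_invariance(monomer, msa_small):
    from crydimer.exposure import MsaTable

    sasa = shrake_rupley_sasa(monomer)
    base = residue_exposure(sasa, monomer, msa_small)
    factor = 3.7
    scaled_msa = MsaTable(
        whole={k: v * factor for k, v in msa_small.whole.items()},
        sidechain={k: v * factor for k, v in msa_small.sidechain.items()},
    )
    scaled = residue_exposure(sasa * factor, monomer, scaled_msa)
    np.testing.assert_allclose(
        scaled.table.exposure_pct, base.table.exposure_pct, rtol=1e-12
    )


def test_buried_residue_scores_zero(msa_small):
    spec = FixtureSpec(helix_length=20, cys_positions=(10,), buried_cys=(10,))
    mono = make_helix_monomer(spec)
    sasa = shrake_rupley_sasa(mono)
    profile = residue_exposure(sasa, mono, msa_small)
    assert profile.exposure_of("A", 10) < 1.0


def test_exposure_over_reference_flagged_not_clamped(msa_small):
    from crydimer.exposure import MsaTable

    tiny = MsaTable(
        whole={k: 1.0 for k in msa_small.whole},
        sidechain={k: 1.0 for k in msa_small.sidechain},
    )
    trip = make_tripeptide("CYS")
    sasa = shrake_rupley_sasa(trip)
    profile = residue_exposure(sasa, trip, tiny)
    cys = profile.table[profile.table.residue_name == "CYS"]
    assert (cys.exposure_pct > 100).all()
    assert cys.over_reference.all()


def _profile_from_exposures(exposures):
    rows = [
        {
            "chain": "A",
            "residue_seq": i + 1,
            "residue_name": "CYS",
            "sasa_abs": e,
            "msa": 100.0,
            "exposure_pct": e,
            "over_reference": False,
        }
        for i, e in enumerate(exposures)
    ]
    return ExposureProfile(table=pd.DataFrame(rows))


def test_classify_thresholds_are_strict():
    classes = classify_cysteines(_profile_from_exposures([25.0, 5.0, 20.0, 7.0]))
    assert [c[1] for c in classes["exposed"]] == [1]
    assert [c[1] for c in classes["buried"]] == [2]
    # exactly-at-threshold values are intermediate on both sides
    assert sorted(c[1] for c in classes["intermediate"]) == [3, 4]


def test_classify_orders_by_descending_exposure():
    classes = classify_cysteines(_profile_from_exposures([30.0, 90.0, 55.0]))
    assert [c[2] for c in classes["exposed"]] == [90.0, 55.0, 30.0]


def test_six_surface_five_buried_fixture(msa_small):
    surface = (2, 10, 13, 21, 24, 32)
    buried = (6, 17, 28, 37, 41)
    spec = FixtureSpec(
        helix_length=42,
        cys_positions=surface + buried,
        buried_cys=buried,
    )
    mono = make_helix_monomer(spec)
    sasa = shrake_rupley_sasa(mono)
    profile = residue_exposure(sasa, mono, msa_small)
    classes = classify_cysteines(profile)
    assert len(classes["exposed"]) == 6
    assert len(classes["intermediate"]) == 0
    assert len(classes["buried"]) == 5
    assert {c[1] for c in classes["exposed"]} == set(surface)


# --- MSA reference -----------------------------------------------------------


def test_msa_single_conformer_equals_direct_sasa(radii960):
    trip = make_tripeptide("CYS")
    table = compute_msa_reference({"CYS": Ensemble([trip])}, radii960)
    sasa = shrake_rupley_sasa(trip, radii960)
    central = trip.atoms.res_id == 2
    assert table.whole["CYS"] == pytest.approx(sasa[central].sum(), rel=1e-12)


def test_msa_max_and_mean_modes(radii960):
    trip = make_tripeptide("LYS")
    spec = FixtureSpec(helix_length=3, seed=5, n_frames=3, jitter_sigma=0.35)
    ens = synthesize_trajectory(trip, spec)
    per_frame = []
    for frame in ens:
        sasa = shrake_rupley_sasa(frame, radii960)
        per_frame.append(sasa[frame.atoms.res_id == 2].sum())
    t_max = compute_msa_reference({"LYS": ens}, radii960, mode="max")
    t_mean = compute_msa_reference({"LYS": ens}, radii960, mode="mean")
    assert t_max.whole["LYS"] == pytest.approx(max(per_frame), rel=1e-12)
    assert t_mean.whole["LYS"] == pytest.approx(
        np.mean(per_frame), rel=1e-12
    )


def test_msa_rejects_non_gly_x_gly(radii960):
    helix = make_helix_monomer(FixtureSpec(helix_length=3))
    with pytest.raises(ValueError):
        compute_msa_reference({"ALA": Ensemble([helix])}, radii960)


def test_msa_all_twenty_standard_residues_positive_and_ordered(radii960):
    codes = (
        "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER "
        "THR TRP TYR VAL"
    ).split()
    trips = {r: Ensemble([make_tripeptide(r)]) for r in codes}
    table = compute_msa_reference(trips, radii960)
    assert all(v > 0 for v in table.whole.values())
    assert all(v > 0 for v in table.sidechain.values())
    assert table.sidechain["GLY"] < table.sidechain["TRP"]


# --- time averaging ----------------------------------------------------------


def test_time_average_identical_frames_equals_single(monomer, msa_small,
                                                     radii960):
    ens = Ensemble([monomer, monomer, monomer])
    avg = time_average_exposure(ens, radii960, msa_small)
    single = residue_exposure(
        shrake_rupley_sasa(monomer, radii960), monomer, msa_small
    )
    np.testing.assert_allclose(
        avg.table.exposure_pct, single.table.exposure_pct, rtol=1e-12
    )
    assert avg.n_frames == 3


def test_time_average_matches_per_frame_loop(msa_small, radii960):
    spec = FixtureSpec(helix_length=8, cys_positions=(5,), seed=9,
                       n_frames=6, jitter_sigma=0.3)
    mono = make_helix_monomer(spec)
    ens = synthesize_trajectory(mono, spec)
    avg = time_average_exposure(ens, radii960, msa_small)
    naive = np.mean(
        [
            residue_exposure(
                shrake_rupley_sasa(fr, radii960), fr, msa_small
            ).table.exposure_pct.to_numpy()
            for fr in ens
        ],
        axis=0,
    )
    np.testing.assert_allclose(avg.table.exposure_pct, naive, rtol=1e-12)


# --- Ellman arithmetic -------------------------------------------------------


def test_two_point_calibration_slope():
    assert fit_dtnb_calibration([0, 10], [0, 0.12]) == pytest.approx(0.012)


def test_noiseless_calibration_recovers_slope_exactly():
    conc = np.array([0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0])
    slope = fit_dtnb_calibration(conc, 0.012 * conc)
    assert slope == pytest.approx(0.012, abs=1e-15)


def test_calibration_estimator_unbiased_under_noise():
    rng = np.random.default_rng(42)
    conc = np.array([0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0])
    sigma = 0.005
    estimates = [
        fit_dtnb_calibration(
            conc, 0.012 * conc + rng.normal(scale=sigma, size=conc.size)
        )
        for _ in range(1000)
    ]
    sxx = np.sum((conc - conc.mean()) ** 2)
    se_single = sigma / np.sqrt(sxx)
    assert abs(np.mean(estimates) - 0.012) < 3 * se_single / np.sqrt(1000)


def test_calibration_errors():
    with pytest.raises(ValueError):
        fit_dtnb_calibration([5.0], [0.06])
    with pytest.raises(ValueError, match="degenerate"):
        fit_dtnb_calibration([5.0, 5.0, 5.0], [0.06, 0.05, 0.07])


def test_n_cys_arithmetic():
    res = count_accessible_cysteines(0.30, 0.012, 5.0)
    assert res.n_cys == pytest.approx(5.0)
    assert count_accessible_cysteines(0.0, 0.012, 5.0).n_cys == 0.0
    with pytest.raises(ValueError):
        count_accessible_cysteines(0.3, -0.01, 5.0)
    with pytest.raises(ValueError):
        count_accessible_cysteines(0.3, 0.012, 0.0)


def test_n_cys_forward_backward_consistency():
    # wild-type style measurement: E=0.30 at c=5 μM reading N=4.78
    implied_slope = 0.30 / (4.78 * 5.0)
    back = count_accessible_cysteines(0.30, implied_slope, 5.0)
    assert back.n_cys == pytest.approx(4.78, abs=1e-12)


def test_n_cys_linearity():
    base = count_accessible_cysteines(0.2, 0.01, 4.0).n_cys
    assert count_accessible_cysteines(0.4, 0.01, 4.0).n_cys == pytest.approx(
        2 * base
    )
    assert count_accessible_cysteines(0.2, 0.02, 4.0).n_cys == pytest.approx(
        base / 2
    )
    assert count_accessible_cysteines(0.2, 0.01, 8.0).n_cys == pytest.approx(
        base / 2
    )
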