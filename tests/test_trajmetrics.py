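"""RMSD/RMSF/Rg/SASA: closed forms, invariances and an independent
superposition oracle (scipy's Kabsch via Rotation.align_vectors)."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ctbind.errors import ValidationError
from ctbind.trajmetrics import (
    ConformationEnsemble,
    fibonacci_sphere,
    kabsch_superpose,
    radius_of_gyration,
    read_pdb_ensemble,
    read_xyz_ensemble,
    rmsd_series,
    rmsf_per_atom,
    sasa,
    sasa_series,
)

RNG = np.random.default_rng(1234)


def _ensemble(frames, masses=None, radii=None):
    frames = np.asarray(frames, dtype=float)
    n = frames.shape[1]
    return ConformationEnsemble(
        frames=frames,
        masses=np.ones(n) if masses is None else np.asarray(masses, float),
        radii=np.full(n, 0.17) if radii is None else np.asarray(radii, float),
    )


def _random_rigid(coords, rng):
    rotation = Rotation.random(random_state=np.random.RandomState(7)).as_matrix()
    translation = rng.normal(size=3)
    return coords @ rotation.T + translation


def test_rmsd_zero_for_identical_and_rigidly_moved_frames():
    base = RNG.normal(size=(12, 3))
    moved = _random_rigid(base, RNG)
    ensemble = _ensemble([base, base.copy(), moved])
    series = rmsd_series(ensemble, reference_index=0)
    assert series[0] == pytest.approx(0.0, abs=1e-10)
    assert series[1] == pytest.approx(0.0, abs=1e-10)
    assert series[2] == pytest.approx(0.0, abs=1e-10)


def test_rmsd_matches_scipy_kabsch_oracle():
    """Weighted superposition agrees with scipy's independent Kabsch."""
    base = RNG.normal(size=(8, 3))
    distorted = base + 0.05 * RNG.normal(size=(8, 3))
    masses = RNG.uniform(1.0, 16.0, size=8)
    weights = masses / masses.sum()

    ref_c = (weights[:, None] * base).sum(axis=0)
    mob_c = (weights[:, None] * distorted).sum(axis=0)
    rotation, _ = Rotation.align_vectors(
        base - ref_c, distorted - mob_c, weights=weights
    )
    fitted_oracle = (distorted - mob_c) @ rotation.as_matrix().T + ref_c
    rmsd_oracle = np.sqrt(
        (weights * ((fitted_oracle - base) ** 2).sum(axis=1)).sum()
    )

    ensemble = _ensemble([base, distorted], masses=masses)
    series = rmsd_series(ensemble, reference_index=0)
    assert series[1] == pytest.approx(rmsd_oracle, abs=1e-10)


def test_rmsd_needs_three_atoms_and_valid_reference():
    two = _ensemble(RNG.normal(size=(2, 2, 3)))
    with pytest.raises(ValidationError):
        rmsd_series(two)
    ensemble = _ensemble(RNG.normal(size=(2, 5, 3)))
    with pytest.raises(ValidationError):
        rmsd_series(ensemble, reference_index=9)


def test_rmsf_zero_for_static_ensemble():
    frame = RNG.normal(size=(10, 3))
    ensemble = _ensemble([frame, frame, frame])
    assert np.allclose(rmsf_per_atom(ensemble), 0.0, atol=1e-12)


def test_rmsf_of_two_state_oscillator_equals_amplitude():
    """One atom hopping +/- d along x while a rigid tetrahedral anchor stays
    fixed: its RMSF is exactly d when alignment uses the anchor atoms."""
    anchor = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )
    d = 0.37
    frames = []
    for sign in (1, -1, 1, -1):
        frame = np.vstack([anchor, [5.0 + sign * d, 0.0, 0.0]])
        frames.append(frame)
    ensemble = _ensemble(frames)
    mask = np.array([True, True, True, True, False])
    rmsf = rmsf_per_atom(ensemble, align_mask=mask)
    assert np.allclose(rmsf[:4], 0.0, atol=1e-12)
    assert rmsf[4] == pytest.approx(d, abs=1e-12)


def test_rmsf_single_frame_rejected():
    ensemble = _ensemble(RNG.normal(size=(1, 5, 3)))
    with pytest.raises(ValidationError):
        rmsf_per_atom(ensemble)


def test_rg_point_mass_and_dimer():
    assert radius_of_gyration(np.zeros((1, 3))) == 0.0
    d = 0.8
    dimer = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
    assert radius_of_gyration(dimer, np.array([1.0, 1.0])) == pytest.approx(
        d / 2.0
    )


def test_rg_uniform_ball_closed_form():
    """Uniform density in a ball of radius R has Rg = sqrt(3/5) R."""
    rng = np.random.default_rng(42)
    radius = 2.0
    points = rng.normal(size=(200_000, 3))
    points /= np.linalg.norm(points, axis=1, keepdims=True)
    points *= radius * rng.uniform(0, 1, size=(200_000, 1)) ** (1 / 3)
    assert radius_of_gyration(points) == pytest.approx(
        np.sqrt(3.0 / 5.0) * radius, rel=0.02
    )


def test_observables_invariant_under_global_rigid_motion():
    frames = RNG.normal(size=(4, 9, 3))
    ensemble = _ensemble(frames)
    # same rigid motion applied to every frame
    rotation = Rotation.random(random_state=np.random.RandomState(3)).as_matrix()
    shift = np.array([1.0, -2.0, 0.5])
    moved_same = _ensemble(frames @ rotation.T + shift)
    assert np.allclose(
        rmsd_series(ensemble), rmsd_series(moved_same), atol=1e-10
    )
    assert np.allclose(
        rmsf_per_atom(ensemble), rmsf_per_atom(moved_same), atol=1e-8
    )
    for original, transformed in zip(ensemble.frames, moved_same.frames):
        assert radius_of_gyration(
            transformed, ensemble.masses
        ) == pytest.approx(radius_of_gyration(original, ensemble.masses))
        # SASA is rotation-invariant only in the infinite-lattice limit:
        # the finite Fibonacci point set is fixed in space
        assert sasa(
            transformed, ensemble.radii, n_sphere_points=960
        ) == pytest.approx(
            sasa(original, ensemble.radii, n_sphere_points=960), rel=5e-3
        )


def test_sasa_single_sphere_closed_form():
    area = sasa(
        np.zeros((1, 3)), np.array([0.2]), probe_radius=0.14, n_sphere_points=960
    )
    assert area == pytest.approx(4.0 * np.pi * 0.34**2, rel=0.01)


def test_sasa_coincident_atoms_count_one_sphere():
    frame = np.zeros((2, 3))
    radii = np.array([0.2, 0.2])
    area = sasa(frame, radii, probe_radius=0.14, n_sphere_points=960)
    assert area == pytest.approx(4.0 * np.pi * 0.34**2, rel=0.01)


def test_sasa_distant_atoms_are_additive():
    frame = np.array([[0.0, 0.0, 0.0], [5.0, 0.0, 0.0]])
    radii = np.array([0.2, 0.15])
    area = sasa(frame, radii, probe_radius=0.14, n_sphere_points=960)
    expected = 4.0 * np.pi * (0.34**2 + 0.29**2)
    assert area == pytest.approx(expected, rel=1e-9)


def test_sasa_monotone_as_third_atom_approaches():
    pair = np.array([[0.0, 0.0, 0.0], [0.3, 0.0, 0.0]])
    radii = np.full(3, 0.17)
    previous = np.inf
    for x in [3.0, 1.0, 0.6, 0.4, 0.3]:
        frame = np.vstack([pair, [x, 0.15, 0.0]])
        area = sasa(frame, radii, n_sphere_points=512)
        assert area <= previous + 1e-9
        previous = area


def test_sasa_lattice_convergence():
    """Doubling the Fibonacci lattice changes the area by < 0.5%."""
    rng = np.random.default_rng(11)
    frame = rng.uniform(0, 0.8, size=(10, 3))
    radii = np.full(10, 0.17)
    coarse = sasa(frame, radii, n_sphere_points=960)
    fine = sasa(frame, radii, n_sphere_points=1920)
    assert abs(fine - coarse) / fine < 0.005


def test_fibonacci_lattice_is_unit_and_balanced():
    points = fibonacci_sphere(500)
    assert np.allclose(np.linalg.norm(points, axis=1), 1.0)
    assert np.linalg.norm(points.mean(axis=0)) < 0.01


def test_pdb_and_xyz_readers(tmp_path):
    pdb = tmp_path / "toy.pdb"
    pdb.write_text(
        "MODEL        1\n"
        "ATOM      1  C1  LIG A   1       0.000   0.000   0.000  1.00  0.00           C\n"
        "ATOM      2  O1  LIG A   1       1.500   0.000   0.000  1.00  0.00           O\n"
        "ATOM      3  N1  LIG A   1       0.000   1.500   0.000  1.00  0.00           N\n"
        "ENDMDL\n"
        "MODEL        2\n"
        "ATOM      1  C1  LIG A   1       0.000   0.000   0.000  1.00  0.00           C\n"
        "ATOM      2  O1  LIG A   1       1.600   0.000   0.000  1.00  0.00           O\n"
        "ATOM      3  N1  LIG A   1       0.000   1.500   0.000  1.00  0.00           N\n"
        "ENDMDL\nEND\n"
    )
    ensemble = read_pdb_ensemble(pdb)
    assert ensemble.n_frames == 2 and ensemble.n_atoms == 3
    assert ensemble.frames[0][1][0] == pytest.approx(0.15)  # A -> nm
    assert ensemble.masses[1] == pytest.approx(15.999)

    xyz = tmp_path / "toy.xyz"
    xyz.write_text(
        "3\nframe 1\nC 0.0 0.0 0.0\nO 1.5 0.0 0.0\nN 0.0 1.5 0.0\n"
        "3\nframe 2\nC 0.0 0.0 0.0\nO 1.6 0.0 0.0\nN 0.0 1.5 0.0\n"
    )
    from_xyz = read_xyz_ensemble(xyz)
    assert from_xyz.n_frames == 2
    assert np.allclose(from_xyz.frames, ensemble.frames)
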