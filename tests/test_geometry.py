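"""Geometric primitives against brute-force and library oracles."""

import numpy as np
import pytest

from opsindiff.geometry import (
    bond_angle,
    com_distance_series,
    dihedral_angle,
    helix_bend_angle,
    kabsch_superpose,
    radius_of_gyration_series,
    rmsd_series,
    rmsf,
)
from opsindiff.model_io import Atom, AtomSelection, Frame, Topology, Trajectory


def _toy_traj(coords_per_frame, masses=None):
    """Trajectory over an anonymous carbon topology from raw coordinates."""
    n_atoms = coords_per_frame[0].shape[0]
    masses = masses if masses is not None else [12.0] * n_atoms
    atoms = [
        Atom(serial=i + 1, name=f"C{i}", element="C", residue_name="TOY",
             residue_id=1, chain_id="A", mass=m)
        for i, m in enumerate(masses)
    ]
    topo = Topology(atoms)
    frames = [Frame(index=t, coordinates=c) for t, c in enumerate(coords_per_frame)]
    return Trajectory(topo, frames)


def _all(traj):
    return AtomSelection(traj.topology, range(traj.topology.n_atoms))


# --- Kabsch ----------------------------------------------------------------


def test_kabsch_identical_sets_zero_rmsd(rng):
    pts = rng.normal(size=(10, 3))
    res = kabsch_superpose(pts, pts)
    assert res.rmsd == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(res.rotation @ res.rotation.T, np.eye(3), atol=1e-10)


def test_kabsch_recovers_rigid_transform(rng):
    from scipy.spatial.transform import Rotation

    pts = rng.normal(size=(8, 3))
    rot = Rotation.random(random_state=7).as_matrix()
    moved = pts @ rot.T + np.array([1.0, -2.0, 3.0])
    res = kabsch_superpose(moved, pts)
    assert res.rmsd < 1e-6
    assert np.linalg.det(res.rotation) == pytest.approx(1.0)


def test_kabsch_matches_independent_optimiser(rng):
    """scipy's align_vectors is the independent superposition oracle."""
    from scipy.spatial.transform import Rotation

    for _ in range(50):
        mob = rng.normal(size=(5, 3))
        ref = rng.normal(size=(5, 3))
        res = kabsch_superpose(mob, ref)
        rot, rssd = Rotation.align_vectors(ref - ref.mean(0), mob - mob.mean(0))
        oracle_rmsd = rssd / np.sqrt(len(mob))
        assert res.rmsd == pytest.approx(oracle_rmsd, abs=1e-6)


def test_kabsch_rejects_degenerate_input():
    with pytest.raises(ValueError):
        kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
    line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    with pytest.raises(ValueError):
        kabsch_superpose(line, line)


# --- RMSD / RMSF / Rg ------------------------------------------------------


def test_rmsd_series_static_and_translated(rng):
    base = rng.normal(size=(6, 3))
    traj = _toy_traj([base.copy() for _ in range(4)])
    sel = _all(traj)
    assert np.allclose(rmsd_series(traj, sel, traj.frames[0], False).values, 0.0)
    shifted = _toy_traj([base + np.array([5.0, 0, 0]) for _ in range(4)])
    vals = rmsd_series(shifted, _all(shifted), Frame(0, base), True).values
    assert np.allclose(vals, 0.0, atol=1e-9)


def test_rmsd_series_matches_direct_formula(rng):
    base = rng.normal(size=(7, 3))
    frames = [base + rng.normal(scale=0.3, size=base.shape) for _ in range(10)]
    traj = _toy_traj(frames)
    vals = rmsd_series(traj, _all(traj), traj.frames[0], superpose=False).values
    expected = [np.sqrt(np.mean(np.sum((f - frames[0]) ** 2, axis=1))) for f in frames]
    np.testing.assert_allclose(vals, expected, atol=1e-9)


def test_superposed_rmsd_never_exceeds_unsuperposed(rng):
    base = rng.normal(size=(6, 3))
    frames = [base + rng.normal(scale=0.5, size=base.shape) for _ in range(8)]
    traj = _toy_traj(frames)
    sel = _all(traj)
    fit = rmsd_series(traj, sel, traj.frames[0], True).values
    raw = rmsd_series(traj, sel, traj.frames[0], False).values
    assert np.all(fit <= raw + 1e-9)


def test_rmsf_static_zero_and_alternating_amplitude():
    base = np.array([[0.0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3], [3, 3, 0]])
    static = _toy_traj([base.copy() for _ in range(5)])
    assert np.allclose(rmsf(static, _all(static)), 0.0)
    a = 0.7
    frames = []
    for t in range(10):
        c = base.copy()
        c[0, 0] += a if t % 2 == 0 else -a  # one atom oscillates about its mean
        frames.append(c)
    traj = _toy_traj(frames)
    align = AtomSelection(traj.topology, [1, 2, 3, 4])
    vals = rmsf(traj, _all(traj), align)
    assert vals[0] == pytest.approx(a, abs=1e-9)
    np.testing.assert_allclose(vals[1:], 0.0, atol=1e-9)


def test_rmsf_matches_direct_formula(rng):
    frames = [rng.normal(size=(5, 3)) for _ in range(12)]
    traj = _toy_traj(frames)
    vals = rmsf(traj, _all(traj), None)
    stack = np.stack(frames)
    expected = np.sqrt(np.mean(np.sum((stack - stack.mean(0)) ** 2, axis=2), axis=0))
    np.testing.assert_allclose(vals, expected, atol=1e-9)


def test_rmsf_requires_two_frames(rng):
    traj = _toy_traj([rng.normal(size=(4, 3))])
    with pytest.raises(ValueError):
        rmsf(traj, _all(traj))


def test_radius_of_gyration_known_cases(rng):
    pair = np.array([[0.0, 0, 0], [4.0, 0, 0]])
    traj = _toy_traj([pair, pair + 1.0])
    vals = radius_of_gyration_series(traj, _all(traj)).values
    np.testing.assert_allclose(vals, 2.0, atol=1e-12)  # d/2 for equal masses
    single = _toy_traj([np.array([[1.0, 2, 3]])])
    assert radius_of_gyration_series(single, _all(single)).values[0] == 0.0


def test_radius_of_gyration_matches_direct_formula(rng):
    coords = rng.normal(size=(20, 3))
    masses = rng.uniform(1, 16, size=20)
    traj = _toy_traj([coords], masses=list(masses))
    val = radius_of_gyration_series(traj, _all(traj), mass_weighted=True).values[0]
    com = (masses[:, None] * coords).sum(0) / masses.sum()
    expected = np.sqrt((masses * np.sum((coords - com) ** 2, axis=1)).sum() / masses.sum())
    assert val == pytest.approx(expected, abs=1e-9)


# --- angles ----------------------------------------------------------------


def test_dihedral_reference_cases():
    f = Frame(0, np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0], [2, 1, 0]]))
    assert dihedral_angle(f, 0, 1, 2, 3) == pytest.approx(180.0)
    f = Frame(0, np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]]))
    assert dihedral_angle(f, 0, 1, 2, 3) == pytest.approx(0.0, abs=1e-12)


def test_dihedral_matches_reference_library(rng):
    bs = pytest.importorskip("biotite.structure")
    for _ in range(50):
        p = rng.normal(size=(4, 3))
        mine = dihedral_angle(Frame(0, p), 0, 1, 2, 3)
        ref = np.degrees(bs.dihedral(p[0], p[1], p[2], p[3]))
        # biotite computes in float32; agreement is limited by its precision
        assert abs((mine - ref + 180) % 360 - 180) < 1e-4


def test_dihedral_reversal_and_mirror_symmetry(rng):
    for _ in range(20):
        p = rng.normal(size=(4, 3))
        f = Frame(0, p)
        d = dihedral_angle(f, 0, 1, 2, 3)
        assert dihedral_angle(f, 3, 2, 1, 0) == pytest.approx(d, abs=1e-9)
        mirrored = Frame(0, p * np.array([1.0, 1.0, -1.0]))
        dm = dihedral_angle(mirrored, 0, 1, 2, 3)
        if abs(abs(d) - 180.0) > 1e-6:  # ±180 identified on the circle
            assert dm == pytest.approx(-d, abs=1e-9)


def test_dihedral_collinear_errors():
    f = Frame(0, np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0]]))
    with pytest.raises(ValueError):
        dihedral_angle(f, 0, 1, 2, 3)


def test_bond_angle_cases_and_oracle(rng):
    f = Frame(0, np.array([[-1.0, 0, 0], [0, 0, 0], [1, 0, 0]]))
    assert bond_angle(f, 0, 1, 2) == pytest.approx(180.0)
    f = Frame(0, np.array([[1.0, 0, 0], [0, 0, 0], [0, 1, 0]]))
    assert bond_angle(f, 0, 1, 2) == pytest.approx(90.0)
    for _ in range(50):
        p = rng.normal(size=(3, 3))
        v1, v2 = p[0] - p[1], p[2] - p[1]
        expected = np.degrees(
            np.arccos(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
        )
        assert bond_angle(Frame(0, p), 0, 1, 2) == pytest.approx(expected, abs=1e-9)


# --- COM distance / helix bend ---------------------------------------------


def test_com_distance_known_cases():
    coords = np.array([[0.0, 0, 0], [4.0, 0, 0], [10.0, 0, 0]])
    traj = _toy_traj([coords], masses=[1.0, 3.0, 1.0])
    a = AtomSelection(traj.topology, [0, 1])  # COM at x = 3
    b = AtomSelection(traj.topology, [2])
    assert com_distance_series(traj, a, b).values[0] == pytest.approx(7.0)
    single = _toy_traj([np.array([[0.0, 0, 0], [0, 5.0, 0]])])
    s = com_distance_series(
        single, AtomSelection(single.topology, [0]), AtomSelection(single.topology, [1])
    )
    assert s.values[0] == pytest.approx(5.0)


def test_com_distance_matches_direct_oracle(rng):
    coords = [rng.normal(size=(6, 3)) for _ in range(5)]
    masses = list(rng.uniform(1, 20, size=6))
    traj = _toy_traj(coords, masses=masses)
    a = AtomSelection(traj.topology, [0, 1, 2])
    b = AtomSelection(traj.topology, [3, 4, 5])
    vals = com_distance_series(traj, a, b).values
    w = np.array(masses)
    for t, c in enumerate(coords):
        ca = (w[:3, None] * c[:3]).sum(0) / w[:3].sum()
        cb = (w[3:, None] * c[3:]).sum(0) / w[3:].sum()
        assert vals[t] == pytest.approx(np.linalg.norm(ca - cb), abs=1e-9)


def _helix_ca(n=12, rise=1.5, twist=100.0, radius=2.3):
    t = np.arange(n) * np.radians(twist)
    return np.column_stack([radius * np.cos(t), radius * np.sin(t), np.arange(n) * rise])


def test_helix_bend_line_and_constructed_kink(rng):
    line = np.column_stack([np.zeros(10), np.zeros(10), np.arange(10.0)])
    traj = _toy_traj([line])
    assert helix_bend_angle(traj.frames[0], _all(traj)) == pytest.approx(0.0, abs=1e-4)
    # rotate the second half axis by 30 degrees about the midpoint
    kinked = line.copy()
    ang = np.radians(30.0)
    rot = np.array([[np.cos(ang), 0, np.sin(ang)], [0, 1, 0], [-np.sin(ang), 0, np.cos(ang)]])
    mid = line[5]
    kinked[5:] = (line[5:] - mid) @ rot.T + mid
    traj = _toy_traj([kinked])
    assert helix_bend_angle(traj.frames[0], _all(traj)) == pytest.approx(30.0, abs=2.0)


def test_helix_bend_ideal_helix_is_nearly_straight():
    traj = _toy_traj([_helix_ca(14)])
    assert helix_bend_angle(traj.frames[0], _all(traj)) < 5.0


def test_helix_bend_requires_eight_atoms():
    traj = _toy_traj([_helix_ca(6)])
    with pytest.raises(ValueError):
        helix_bend_angle(traj.frames[0], _all(traj))


# --- rigid-motion invariance ------------------------------------------------


def test_geometry_invariant_under_global_rigid_motion(rng):
    from scipy.spatial.transform import Rotation

    coords = [rng.normal(size=(8, 3)) for _ in range(6)]
    traj = _toy_traj(coords)
    rot = Rotation.random(random_state=11).as_matrix()
    shift = np.array([3.0, -1.0, 7.0])
    moved = _toy_traj([c @ rot.T + shift for c in coords])
    sel, msel = _all(traj), _all(moved)
    np.testing.assert_allclose(
        radius_of_gyration_series(traj, sel).values,
        radius_of_gyration_series(moved, msel).values,
        atol=1e-8,
    )
    np.testing.assert_allclose(
        com_distance_series(traj, AtomSelection(traj.topology, [0, 1]),
                            AtomSelection(traj.topology, [2, 3])).values,
        com_distance_series(moved, AtomSelection(moved.topology, [0, 1]),
                            AtomSelection(moved.topology, [2, 3])).values,
        atol=1e-8,
    )
    for f, g in zip(traj.frames, moved.frames):
        assert bond_angle(f, 0, 1, 2) == pytest.approx(bond_angle(g, 0, 1, 2), abs=1e-8)
        assert dihedral_angle(f, 0, 1, 2, 3) == pytest.approx(
            dihedral_angle(g, 0, 1, 2, 3), abs=1e-8
        )
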