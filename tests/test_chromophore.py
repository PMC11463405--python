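"""Chromophore internal coordinates, modality calls and key distances."""

import numpy as np
import pytest

from opsindiff.chromophore import (
    ChromophoreSpec,
    chromophore_profile,
    circular_histogram,
    circular_mean,
    classify_modality,
    default_chromophore_spec,
    internal_coordinate_series,
    key_distance_series,
    resolve_chromophore,
)
from opsindiff.model_io import Atom, AtomSelection, Frame, Topology, Trajectory, select_atoms
from opsindiff.synthetic import (
    CHROMOPHORE_RESID,
    ToySystemConfig,
    build_toy_system,
    default_two_system_config,
    simulate_two_system_trajectories,
)


def test_resolve_complete_map_on_toy_topology(small_system):
    topo, _ = small_system
    mapping = resolve_chromophore(topo, default_chromophore_spec())
    expected = {"N+", "CA", "CD", "CE", "C20"} | {f"C{i}" for i in range(1, 17)}
    assert set(mapping) == expected
    assert topo.names[mapping["N+"]] == "NZ"


def test_resolve_reports_missing_atom(small_system):
    topo, _ = small_system
    atoms = [a for a in topo.atoms if not (a.residue_name == "LYR" and a.name == "C16")]
    broken = Topology(atoms)
    with pytest.raises(ValueError, match="C16"):
        resolve_chromophore(broken, default_chromophore_spec())


def test_resolve_composite_qualified_aliases(small_system):
    """RET + linked-LYS style topologies resolve through qualified aliases."""
    topo, _ = small_system
    spec = default_chromophore_spec()
    aliases = dict(spec.atom_aliases)
    aliases["N+"] = f"LYR{CHROMOPHORE_RESID}:NZ"  # qualified lookup
    spec2 = ChromophoreSpec(
        residue_name="LYR", atom_aliases=aliases,
        torsion_defs=spec.torsion_defs, angle_defs=spec.angle_defs,
    )
    mapping = resolve_chromophore(topo, spec2)
    assert topo.names[mapping["N+"]] == "NZ"


def test_resolve_rejects_ambiguous_residue(small_system):
    topo, _ = small_system
    doubled = Topology(
        list(topo.atoms)
        + [
            Atom(serial=10_000 + i, name=a.name, element=a.element,
                 residue_name="LYR", residue_id=401, chain_id="A", mass=a.mass,
                 hetero=True)
            for i, a in enumerate(topo.atoms)
            if a.residue_name == "LYR"
        ]
    )
    with pytest.raises(ValueError, match="multiple"):
        resolve_chromophore(doubled, default_chromophore_spec())


def test_internal_coordinate_static_and_unknown_name(small_system):
    topo, frame = small_system
    traj = Trajectory(topo, [Frame(i, frame.coordinates) for i in range(10)])
    spec = default_chromophore_spec()
    series = internal_coordinate_series(traj, spec, "SB_twist")
    assert np.ptp(series.values) == pytest.approx(0.0, abs=1e-9)
    with pytest.raises(KeyError):
        internal_coordinate_series(traj, spec, "C9-C10")


def test_programmed_torsion_recovered_by_circular_mean(short_pair):
    _, traj_a, _, _ = short_pair
    series = internal_coordinate_series(traj_a, default_chromophore_spec(), "SB_twist")
    assert abs(circular_mean(series.values) - 170.0) < 2.0


def test_classify_modality_known_distributions(rng):
    call = classify_modality(np.full(200, 42.0))
    assert call.label == "monomodal" and call.peaks[0] == pytest.approx(42.0, abs=1.0)
    mono = np.degrees(rng.vonmises(np.radians(180.0), 8.0, size=2000))
    assert classify_modality(mono).label == "monomodal"
    half = rng.vonmises(np.radians(-65.0), 8.0, size=1000)
    other = rng.vonmises(np.radians(65.0), 8.0, size=1000)
    call = classify_modality(np.degrees(np.concatenate([half, other])))
    assert call.label == "bimodal"
    assert sorted(round(p) for p in call.peaks) == pytest.approx([-65, 65], abs=10)


def test_classify_modality_requires_samples():
    with pytest.raises(ValueError):
        classify_modality(np.zeros(99))


def test_circular_statistics_invariant_to_wrapping(rng):
    samples = np.degrees(rng.vonmises(np.radians(170.0), 6.0, size=1500))
    call1 = classify_modality(samples)
    call2 = classify_modality(samples + 360.0)
    assert call1.label == call2.label and call1.peaks == call2.peaks
    h1, _ = circular_histogram(samples)
    h2, _ = circular_histogram(samples + 360.0)
    np.testing.assert_allclose(h1, h2)
    assert circular_mean(samples) == pytest.approx(circular_mean(samples - 720.0), abs=1e-9)
    # order invariance
    perm = rng.permutation(len(samples))
    assert classify_modality(samples[perm]).peaks == call1.peaks


def test_histogram_mass_sums_to_one(rng):
    h, edges = circular_histogram(rng.uniform(-180, 180, size=500))
    assert h.sum() == pytest.approx(1.0)
    assert len(h) == 36 and edges[0] == -180.0 and edges[-1] == 180.0


def test_chromophore_profile_static_trajectory(small_system):
    topo, frame = small_system
    traj = Trajectory(topo, [Frame(i, frame.coordinates) for i in range(5)])
    prof = chromophore_profile(traj, default_chromophore_spec())
    assert all(v == pytest.approx(0.0, abs=1e-9) for v in prof.per_atom_rmsf.values())
    assert np.ptp(prof.rg_series.values) == pytest.approx(0.0, abs=1e-12)
    for hist, _ in prof.torsion_histograms.values():
        assert np.count_nonzero(hist) == 1  # single occupied bin


def test_profile_detects_programmed_bimodal_torsion(short_pair):
    _, _, traj_b, truth = short_pair
    prof = chromophore_profile(traj_b, default_chromophore_spec())
    assert prof.modality_labels["ring_chain_1"].label == "bimodal"
    assert prof.modality_labels["ring_chain_2"].label == "monomodal"
    assert prof.modality_labels["SB_twist"].label == "monomodal"


def test_profile_equals_individual_operations(short_pair):
    from opsindiff.geometry import radius_of_gyration_series

    _, traj_a, _, _ = short_pair
    spec = default_chromophore_spec()
    prof = chromophore_profile(traj_a, spec)
    series = internal_coordinate_series(traj_a, spec, "SB_twist")
    hist, _ = circular_histogram(series.values)
    np.testing.assert_allclose(prof.torsion_histograms["SB_twist"][0], hist)
    mapping = resolve_chromophore(traj_a.topology, spec)
    heavy = [i for i in sorted(set(mapping.values())) if traj_a.topology.heavy_mask[i]]
    rg = radius_of_gyration_series(traj_a, AtomSelection(traj_a.topology, heavy))
    np.testing.assert_allclose(prof.rg_series.values, rg.values)


def _two_residue_system():
    """Chromophore plus two side-chain-bearing sites for key distances."""
    cfg = ToySystemConfig(n_cage_residues=6, n_waters=0)
    topo, frame = build_toy_system(cfg)
    return topo, frame


def test_key_distance_constructed_and_identical_systems():
    topo, frame = _two_residue_system()
    traj = Trajectory(topo, [Frame(i, frame.coordinates) for i in range(3)])
    spec = default_chromophore_spec()
    residue_map = {"122": ("A", 1), "181": ("A", 2)}
    s1 = key_distance_series(traj, spec, "d181_122", residue_map)
    og1 = frame.coordinates[np.nonzero((topo.residue_ids == 1) & (topo.names == "OG"))[0][0]]
    og2 = frame.coordinates[np.nonzero((topo.residue_ids == 2) & (topo.names == "OG"))[0][0]]
    assert s1.values[0] == pytest.approx(np.linalg.norm(og1 - og2), abs=1e-9)
    assert np.ptp(s1.values) == pytest.approx(0.0, abs=1e-12)
    # hand-computed centroid oracle for the ring target
    s2 = key_distance_series(traj, spec, "d122_ring", residue_map)
    mapping = resolve_chromophore(topo, spec)
    ring = frame.coordinates[[mapping[f"C{i}"] for i in range(1, 7)]].mean(axis=0)
    assert s2.values[0] == pytest.approx(np.linalg.norm(og1 - ring), abs=1e-9)


def test_key_distance_unknown_pair_errors():
    topo, frame = _two_residue_system()
    traj = Trajectory(topo, [frame])
    with pytest.raises(ValueError):
        key_distance_series(traj, default_chromophore_spec(), "d99_ring",
                            {"122": ("A", 1), "181": ("A", 2)})


def test_chromophore_rmsf_consistent_with_geometry_rmsf(short_pair):
    from opsindiff.geometry import rmsf

    _, traj_a, _, _ = short_pair
    spec = default_chromophore_spec()
    ca = select_atoms(traj_a.topology, "name CA and protein")
    prof = chromophore_profile(traj_a, spec, ca)
    mapping = resolve_chromophore(traj_a.topology, spec)
    idx = np.array(sorted(set(mapping.values())))
    direct = rmsf(traj_a, AtomSelection(traj_a.topology, idx), ca)
    inverse = {v: k for k, v in mapping.items()}
    for i, v in zip(idx, direct):
        assert prof.per_atom_rmsf[inverse[i]] == pytest.approx(v, abs=1e-9)
        assert v >= 0.0
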