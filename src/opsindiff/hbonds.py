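"""Geometric hydrogen-bond detection, occupancies and water bridges.

A hydrogen bond is present in a frame when the donor–acceptor heavy-atom
distance is at most ``d_max`` (default 3.5 Å) and the D–H···A angle is at
least ``theta_min`` (default 150°) for some hydrogen attached to the donor
— the common geometric criterion in MD analysis.  Occupancy is the fraction
of frames in which the bond is present; a water bridge requires both water
hydrogen bonds (water↔site A and water↔site B, either polarity) in the
same frame.  Hydrogen positions are required: unprotonated structures are
rejected with an explicit error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .model_io import Topology, Trajectory

__all__ = [
    "HBCriteria",
    "DonorAcceptorAssignment",
    "OccupancyTable",
    "WaterBridgeRecord",
    "HydrogenError",
    "assign_donors_acceptors",
    "hbond_occupancy_table",
    "water_bridge_occupancy",
]

_BOND_H_CUTOFF = 1.3  # Å; covalent D–H inferred by intra-residue distance

# Default lone-pair capacity rules: every O accepts; N accepts only when it
# carries no hydrogen (e.g. histidine ND1-like sites).  Overrides are keyed
# by (residue_name, atom_name) → bool.
DEFAULT_ACCEPTOR_OVERRIDES: dict = {}


class HydrogenError(ValueError):
    """Raised when H-bond analysis is attempted on an unprotonated structure."""


@dataclass
class HBCriteria:
    d_max: float = 3.5
    theta_min: float = 150.0

    def __post_init__(self):
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        if not 0 < self.theta_min <= 180:
            raise ValueError("theta_min must be in (0, 180]")


@dataclass
class DonorAcceptorAssignment:
    """Donor heavy atoms with attached hydrogens, and acceptor heavy atoms."""

    donors: list  # (donor_index, [h_index, ...])
    acceptors: np.ndarray

    @property
    def donor_indices(self) -> np.ndarray:
        return np.array([d for d, _ in self.donors], dtype=int)


@dataclass
class OccupancyTable:
    """Per donor/acceptor pair: fraction of frames the bond is present."""

    rows: pd.DataFrame
    n_frames: int

    def occupancy(self, donor_label: str, acceptor_label: str) -> float:
        m = (self.rows["donor"] == donor_label) & (self.rows["acceptor"] == acceptor_label)
        if not m.any():
            return 0.0
        return float(self.rows.loc[m, "occupancy"].iloc[0])


@dataclass
class WaterBridgeRecord:
    site_a: int
    site_b: int
    water_residue_id: int
    occupancy: float


def _atom_label(topology: Topology, i: int) -> str:
    return (
        f"{topology.residue_names[i]}{topology.residue_ids[i]}"
        f":{topology.names[i]}"
    )


def assign_donors_acceptors(
    topology: Topology,
    frame_coordinates: np.ndarray,
    acceptor_overrides: dict | None = None,
) -> DonorAcceptorAssignment:
    """Identify H-bond donors (N/O/S with ≥1 bonded H) and acceptors (N/O).

    Covalent D–H bonds are inferred from intra-residue distances < 1.3 Å in
    the supplied coordinates (the multi-model PDB dialect carries no CONECT
    records for protein hydrogens).  Water oxygens are both donor and
    acceptor.  The override table, keyed by ``(residue_name, atom_name)``,
    forces acceptor capacity on or off.
    """
    overrides = DEFAULT_ACCEPTOR_OVERRIDES if acceptor_overrides is None else acceptor_overrides
    h_idx = np.nonzero(~topology.heavy_mask)[0]
    if h_idx.size == 0:
        raise HydrogenError(
            "structure contains no hydrogens: H-bond analysis requires a "
            "protonated input (add hydrogens before running)"
        )
    donors: list = []
    attached_h: dict[int, list[int]] = {}
    res_of = topology.residue_ids
    chain_of = topology.chain_ids
    heavy_don = np.nonzero(topology.heavy_mask & np.isin(topology.elements, ["N", "O", "S"]))[0]
    for d in heavy_don:
        same_res = h_idx[(res_of[h_idx] == res_of[d]) & (chain_of[h_idx] == chain_of[d])]
        if same_res.size == 0:
            continue
        dist = np.linalg.norm(frame_coordinates[same_res] - frame_coordinates[d], axis=1)
        hs = same_res[dist < _BOND_H_CUTOFF].tolist()
        if hs:
            donors.append((int(d), hs))
            attached_h[int(d)] = hs
    acceptors = []
    heavy_acc = np.nonzero(topology.heavy_mask & np.isin(topology.elements, ["N", "O"]))[0]
    for a in heavy_acc:
        key = (topology.residue_names[a], topology.names[a])
        if key in overrides:
            accepts = overrides[key]
        elif topology.elements[a] == "O":
            accepts = True
        else:
            accepts = a not in attached_h
        if accepts:
            acceptors.append(int(a))
    return DonorAcceptorAssignment(donors=donors, acceptors=np.array(acceptors, dtype=int))


def detect_frame_hbonds(
    topology: Topology,
    coordinates: np.ndarray,
    assignment: DonorAcceptorAssignment,
    criteria: HBCriteria,
) -> set[tuple[int, int]]:
    """(donor_index, acceptor_index) pairs bonded in one frame."""
    bonds: set[tuple[int, int]] = set()
    if assignment.acceptors.size == 0:
        return bonds
    tree = cKDTree(coordinates[assignment.acceptors])
    cos_min = np.cos(np.radians(criteria.theta_min))
    for d, hs in assignment.donors:
        near = tree.query_ball_point(coordinates[d], criteria.d_max)
        for j in near:
            a = int(assignment.acceptors[j])
            if a == d:
                continue
            for h in hs:
                if a == h:
                    continue
                v1 = coordinates[d] - coordinates[h]
                v2 = coordinates[a] - coordinates[h]
                n1 = np.linalg.norm(v1)
                n2 = np.linalg.norm(v2)
                if n1 < 1e-9 or n2 < 1e-9:
                    continue
                # angle >= theta_min  <=>  cos(angle) <= cos(theta_min)
                if np.dot(v1, v2) / (n1 * n2) <= cos_min:
                    bonds.add((int(d), a))
                    break
    return bonds


def hbond_occupancy_table(
    traj: Trajectory,
    assignment: DonorAcceptorAssignment | None = None,
    criteria: HBCriteria | None = None,
    restrict_to: set[int] | None = None,
) -> OccupancyTable:
    """Occupancy (fraction of frames) for every observed donor/acceptor pair.

    Pairs never bonded are omitted.  ``restrict_to`` keeps only rows where
    the donor's or acceptor's residue id belongs to the given set.
    """
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    criteria = criteria or HBCriteria()
    topo = traj.topology
    if assignment is None:
        assignment = assign_donors_acceptors(topo, traj.frames[0].coordinates)
    counts: dict[tuple[int, int], int] = {}
    for frame in traj.frames:
        for pair in detect_frame_hbonds(topo, frame.coordinates, assignment, criteria):
            counts[pair] = counts.get(pair, 0) + 1
    rows = []
    for (d, a), c in sorted(counts.items()):
        if restrict_to is not None and not (
            int(topo.residue_ids[d]) in restrict_to or int(topo.residue_ids[a]) in restrict_to
        ):
            continue
        rows.append(
            {
                "donor": _atom_label(topo, d),
                "acceptor": _atom_label(topo, a),
                "donor_index": d,
                "acceptor_index": a,
                "occupancy": c / traj.n_frames,
                "n_frames": traj.n_frames,
            }
        )
    df = pd.DataFrame(rows, columns=["donor", "acceptor", "donor_index",
                                     "acceptor_index", "occupancy", "n_frames"])
    return OccupancyTable(rows=df, n_frames=traj.n_frames)


def water_bridge_occupancy(
    traj: Trajectory,
    site_a: int,
    site_b: int,
    assignment: DonorAcceptorAssignment | None = None,
    criteria: HBCriteria | None = None,
) -> list[WaterBridgeRecord]:
    """Per-water occupancy of simultaneous H-bonds to two residue sites.

    For every water residue and frame, a bridge holds when the water is
    hydrogen bonded (either polarity) to site_a and to site_b in the same
    frame.  Waterless systems return an empty list.
    """
    criteria = criteria or HBCriteria()
    topo = traj.topology
    water_res = sorted(
        {int(topo.residue_ids[i]) for i in np.nonzero(topo.water_mask)[0]}
    )
    if not water_res:
        return []
    if assignment is None:
        assignment = assign_donors_acceptors(topo, traj.frames[0].coordinates)
    res_of_pair = lambda i: int(topo.residue_ids[i])  # noqa: E731
    counts = {w: 0 for w in water_res}
    for frame in traj.frames:
        bonds = detect_frame_hbonds(topo, frame.coordinates, assignment, criteria)
        linked: dict[int, set[int]] = {w: set() for w in water_res}
        for d, a in bonds:
            rd, ra = res_of_pair(d), res_of_pair(a)
            if rd in counts and ra in (site_a, site_b):
                linked[rd].add(ra)
            elif ra in counts and rd in (site_a, site_b):
                linked[ra].add(rd)
        for w, sites in linked.items():
            if site_a in sites and site_b in sites:
                counts[w] += 1
    return [
        WaterBridgeRecord(site_a=site_a, site_b=site_b, water_residue_id=w,
                          occupancy=c / traj.n_frames)
        for w, c in counts.items()
        if c > 0
    ]
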