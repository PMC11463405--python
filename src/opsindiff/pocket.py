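"""Binding-pocket residue identification, grid volume and hydration.

The pocket volume follows a POVME-style construction: a cubic grid is laid
over an inclusion region (union of spheres centred on the chromophore heavy
atoms), grid points blocked by protein heavy atoms (van der Waals radius +
probe margin) are deleted, and the remaining points are counted.  Absolute
volumes depend on the inclusion radius and carry no solvent-contiguity
filter; relative (between-system, over-time) behaviour is the meaningful
output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import SeriesResult
from .model_io import AtomSelection, Frame, Topology, Trajectory

__all__ = [
    "BONDI_RADII",
    "PocketDefinition",
    "GridSpec",
    "VolumeSeries",
    "pocket_residues",
    "pocket_volume_series",
    "hydration_count_series",
]

# Bondi van der Waals radii (Å)
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
}
_DEFAULT_RADIUS = 1.70


@dataclass
class PocketDefinition:
    """Residues lining the chromophore within a distance cutoff."""

    chromophore_selection: AtomSelection
    cutoff: float
    residues: list[tuple[str, int, str]]

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        self.residues = sorted(self.residues, key=lambda r: (r[0], r[1]))

    @property
    def residue_ids(self) -> list[int]:
        return [r[1] for r in self.residues]

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class GridSpec:
    """Grid parameters for the pocket-volume estimator."""

    spacing: float = 0.5
    inclusion_radius: float = 8.0
    vdw_radii: dict = field(default_factory=lambda: dict(BONDI_RADII))
    probe_margin: float = 0.0

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.inclusion_radius <= self.spacing:
            raise ValueError("inclusion_radius must exceed spacing")


@dataclass
class VolumeSeries:
    """Per-frame pocket volume (Å³) plus the grid used to compute it."""

    series: SeriesResult
    grid: GridSpec

    @property
    def values(self) -> np.ndarray:
        return self.series.values


def pocket_residues(
    topology: Topology,
    frame: Frame,
    chromophore: AtomSelection,
    cutoff: float = 4.5,
    exclude_link_residue: bool = False,
) -> PocketDefinition:
    """Protein residues with any heavy atom within ``cutoff`` of the chromophore.

    Waters and other hetero residues are excluded, as is any residue that
    contributes atoms to the chromophore selection itself.  With
    ``exclude_link_residue`` the residue covalently bonded to the chromophore
    (any heavy atom within 1.8 Å, i.e. the Schiff-base lysine) is dropped too.
    """
    if len(chromophore) == 0:
        raise ValueError("empty chromophore selection")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    chrom_idx = chromophore.indices
    chrom_heavy = chrom_idx[topology.heavy_mask[chrom_idx]]
    chrom_coords = frame.coordinates[chrom_heavy]
    tree = cKDTree(chrom_coords)

    chrom_residues = {
        (topology.chain_ids[i], topology.residue_ids[i]) for i in chrom_idx
    }
    protein_mask = ~topology.hetero_mask & ~topology.water_mask & topology.heavy_mask
    prot_idx = np.nonzero(protein_mask)[0]
    dists, _ = tree.query(frame.coordinates[prot_idx], k=1)

    hits: dict[tuple[str, int, str], float] = {}
    for i, d in zip(prot_idx, dists):
        key = (topology.chain_ids[i], int(topology.residue_ids[i]), topology.residue_names[i])
        if (key[0], key[1]) in chrom_residues:
            continue
        if d <= cutoff:
            hits.setdefault(key, d)
        hits[key] = min(hits.get(key, np.inf), d)
    selected = [k for k, d in hits.items() if d <= cutoff]
    if exclude_link_residue:
        linked = {k for k, d in hits.items() if d <= 1.8}
        selected = [k for k in selected if k not in linked]
    return PocketDefinition(chromophore_selection=chromophore, cutoff=cutoff, residues=selected)


def _frame_volume(
    chrom_coords: np.ndarray,
    blocker_coords: np.ndarray,
    blocker_radii: np.ndarray,
    grid: GridSpec,
) -> float:
    s = grid.spacing
    lo = chrom_coords.min(axis=0) - grid.inclusion_radius
    hi = chrom_coords.max(axis=0) + grid.inclusion_radius
    # grid anchored on the chromophore bounding box
    axes = [np.arange(lo[k], hi[k] + s, s) for k in range(3)]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    dist_chrom, _ = cKDTree(chrom_coords).query(pts, k=1)
    inside = dist_chrom <= grid.inclusion_radius
    pts = pts[inside]
    if blocker_coords.shape[0]:
        keep = np.ones(len(pts), dtype=bool)
        for r in np.unique(blocker_radii):
            sub = blocker_coords[blocker_radii == r]
            d, _ = cKDTree(sub).query(pts, k=1)
            keep &= d > r + grid.probe_margin
        pts = pts[keep]
    return float(len(pts)) * s**3


def pocket_volume_series(
    traj: Trajectory,
    grid: GridSpec,
    chromophore: AtomSelection,
    protein: AtomSelection,
    stride: int = 1,
) -> VolumeSeries:
    """Grid-count pocket volume per frame (Å³).

    Blockers are the protein selection's heavy atoms; chromophore atoms are
    excluded from the blockers so the chromophore-occupied space counts as
    pocket.  A ``stride`` > 1 subsamples frames for long trajectories.
    """
    if grid.spacing > grid.inclusion_radius / 3:
        raise ValueError("spacing must be <= inclusion_radius / 3")
    if len(chromophore) == 0:
        raise ValueError("empty chromophore selection")
    topo = traj.topology
    chrom_idx = chromophore.indices
    chrom_heavy = chrom_idx[topo.heavy_mask[chrom_idx]]
    blocker_idx = np.setdiff1d(protein.indices, chrom_idx)
    blocker_idx = blocker_idx[topo.heavy_mask[blocker_idx]]
    if blocker_idx.size == 0:
        warnings.warn("empty protein selection: returning inclusion-region volume")
    radii = np.array(
        [grid.vdw_radii.get(topo.elements[i], _DEFAULT_RADIUS) for i in blocker_idx]
    )
    frame_ids = np.arange(0, traj.n_frames, stride)
    values = np.empty(len(frame_ids))
    for j, t in enumerate(frame_ids):
        coords = traj.frames[t].coordinates
        values[j] = _frame_volume(coords[chrom_heavy], coords[blocker_idx], radii, grid)
    series = SeriesResult("pocket_volume", frame_ids, values, "A^3")
    return VolumeSeries(series=series, grid=grid)


def hydration_count_series(
    traj: Trajectory,
    chromophore: AtomSelection,
    water_oxygens: AtomSelection,
    cutoff: float = 4.0,
) -> SeriesResult:
    """Per-frame count of water oxygens within ``cutoff`` of the chromophore."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    topo = traj.topology
    chrom_idx = chromophore.indices
    chrom_heavy = chrom_idx[topo.heavy_mask[chrom_idx]]
    values = np.zeros(traj.n_frames)
    if len(water_oxygens) > 0:
        for t, frame in enumerate(traj.frames):
            tree = cKDTree(frame.coordinates[chrom_heavy])
            d, _ = tree.query(frame.coordinates[water_oxygens.indices], k=1)
            values[t] = int(np.sum(d <= cutoff))
    return SeriesResult("hydration_count", np.arange(traj.n_frames), values, "count")
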