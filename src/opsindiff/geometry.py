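"""Geometric primitives underlying every trajectory statistic.

All angles are reported in degrees; dihedrals follow the IUPAC sign
convention on the interval (−180, 180] (0° = syn-periplanar/cis, 180° =
anti-periplanar/trans).  Mass weighting defaults ON for centre-of-mass and
radius-of-gyration quantities and OFF for RMSD/RMSF, which are
conventionally computed on unweighted Cα sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_io import AtomSelection, Frame, Trajectory

__all__ = [
    "SuperpositionResult",
    "SeriesResult",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf",
    "radius_of_gyration_series",
    "dihedral_angle",
    "bond_angle",
    "com_distance_series",
    "helix_bend_angle",
    "dihedral_series",
    "angle_series",
]


@dataclass
class SuperpositionResult:
    """Optimal proper rotation + translation and the post-fit RMSD (Å)."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class SeriesResult:
    """A named per-frame scalar series."""

    name: str
    frame_indices: np.ndarray
    values: np.ndarray
    units: str = ""

    def __post_init__(self):
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.frame_indices.shape != self.values.shape:
            raise ValueError("one value per frame required")

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Least-squares optimal proper rotation of ``mobile`` onto ``reference``.

    Classic Kabsch solution via SVD of the weighted covariance, with the
    determinant correction that excludes improper rotations.  Requires at
    least 3 points that are not all collinear.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must both have shape (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition requires at least 3 points")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w <= 0):
            raise ValueError("weights must be positive, one per point")
    w = w / w.sum()
    mob_c = mobile - (w[:, None] * mobile).sum(axis=0)
    ref_c = reference - (w[:, None] * reference).sum(axis=0)
    if np.linalg.matrix_rank(ref_c, tol=1e-9) < 2 or np.linalg.matrix_rank(mob_c, tol=1e-9) < 2:
        raise ValueError("degenerate (collinear) point configuration")
    cov = (w[:, None] * mob_c).T @ ref_c
    u, _, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    ref_com = (w[:, None] * reference).sum(axis=0)
    mob_com = (w[:, None] * mobile).sum(axis=0)
    translation = ref_com - rotation @ mob_com
    fitted = mobile @ rotation.T + translation
    rmsd = float(np.sqrt((w * np.sum((fitted - reference) ** 2, axis=1)).sum()))
    return SuperpositionResult(rotation=rotation, translation=translation, rmsd=rmsd)


def rmsd_series(
    traj: Trajectory,
    selection: AtomSelection,
    reference: Frame,
    superpose: bool = True,
) -> SeriesResult:
    """Per-frame RMSD (Å) of a selection against a reference frame."""
    if len(selection) == 0:
        raise ValueError("empty selection")
    ref = selection.coordinates(reference)
    values = np.empty(traj.n_frames)
    for t, frame in enumerate(traj.frames):
        mob = selection.coordinates(frame)
        if superpose:
            values[t] = kabsch_superpose(mob, ref).rmsd
        else:
            values[t] = np.sqrt(np.mean(np.sum((mob - ref) ** 2, axis=1)))
    return SeriesResult("rmsd", np.arange(traj.n_frames), values, "A")


def rmsf(
    traj: Trajectory,
    selection: AtomSelection,
    align_selection: AtomSelection | None = None,
) -> np.ndarray:
    """Per-atom root mean square fluctuation (Å).

    Frames are first Kabsch-aligned to frame 0 on ``align_selection`` (no
    alignment when None); RMSF_i = sqrt(mean_t |x_i(t) − ⟨x_i⟩|²).
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF requires at least 2 frames")
    if len(selection) == 0:
        raise ValueError("empty selection")
    coords = np.empty((traj.n_frames, len(selection), 3))
    ref_align = align_selection.coordinates(traj.frames[0]) if align_selection else None
    for t, frame in enumerate(traj.frames):
        if align_selection is not None and len(align_selection) > 0:
            fit = kabsch_superpose(align_selection.coordinates(frame), ref_align)
            coords[t] = fit.apply(selection.coordinates(frame))
        else:
            coords[t] = selection.coordinates(frame)
    mean = coords.mean(axis=0)
    return np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))


def radius_of_gyration_series(
    traj: Trajectory, selection: AtomSelection, mass_weighted: bool = True
) -> SeriesResult:
    """Rg(t) = sqrt(Σ w_i |x_i − x_com|² / Σ w_i) in Å."""
    if len(selection) == 0:
        raise ValueError("empty selection")
    w = selection.masses() if mass_weighted else np.ones(len(selection))
    w = w / w.sum()
    values = np.empty(traj.n_frames)
    for t, frame in enumerate(traj.frames):
        x = selection.coordinates(frame)
        com = (w[:, None] * x).sum(axis=0)
        values[t] = np.sqrt((w * np.sum((x - com) ** 2, axis=1)).sum())
    return SeriesResult("radius_of_gyration", np.arange(traj.n_frames), values, "A")


def _dihedral_batch(p0, p1, p2, p3) -> np.ndarray:
    """Signed dihedrals (degrees) for batched (n, 3) point arrays."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - np.sum(b0 * b1n, axis=-1, keepdims=True) * b1n
    w = b2 - np.sum(b2 * b1n, axis=-1, keepdims=True) * b1n
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1n, v) * w, axis=-1)
    # IUPAC sign convention, matching the sign returned by the standard MD
    # analysis libraries (MDAnalysis, biotite, mdtraj)
    ang = np.degrees(np.arctan2(y, x))
    ang = np.where(ang <= -180.0, ang + 360.0, ang)
    ang = np.where(ang > 180.0, ang - 360.0, ang)
    return ang


def dihedral_angle(frame: Frame, a: int, b: int, c: int, d: int) -> float:
    """Signed torsion a-b-c-d in degrees on (−180, 180]."""
    if len({a, b, c, d}) != 4:
        raise ValueError("dihedral needs four distinct atoms")
    p = frame.coordinates[[a, b, c, d]]
    bc = p[2] - p[1]
    if np.linalg.norm(np.cross(p[0] - p[1], bc)) < 1e-10 or np.linalg.norm(
        np.cross(p[3] - p[2], bc)
    ) < 1e-10:
        raise ValueError("collinear atoms: dihedral plane undefined")
    val = float(_dihedral_batch(p[0][None], p[1][None], p[2][None], p[3][None])[0])
    return 180.0 if val == -180.0 else val


def _angle_batch(p0, p1, p2) -> np.ndarray:
    v1 = p0 - p1
    v2 = p2 - p1
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    cosang = np.sum(v1 * v2, axis=-1) / (n1 * n2)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def bond_angle(frame: Frame, a: int, b: int, c: int) -> float:
    """Interior angle at b in degrees on [0, 180]."""
    if len({a, b, c}) != 3:
        raise ValueError("angle needs three distinct atoms")
    p = frame.coordinates[[a, b, c]]
    if np.linalg.norm(p[0] - p[1]) < 1e-10 or np.linalg.norm(p[2] - p[1]) < 1e-10:
        raise ValueError("zero-length vector: angle undefined")
    return float(_angle_batch(p[0][None], p[1][None], p[2][None])[0])


def dihedral_series(traj: Trajectory, a: int, b: int, c: int, d: int) -> np.ndarray:
    coords = traj.coordinate_array()
    return _dihedral_batch(coords[:, a], coords[:, b], coords[:, c], coords[:, d])


def angle_series(traj: Trajectory, a: int, b: int, c: int) -> np.ndarray:
    coords = traj.coordinate_array()
    return _angle_batch(coords[:, a], coords[:, b], coords[:, c])


def com_distance_series(
    traj: Trajectory,
    sel_a: AtomSelection,
    sel_b: AtomSelection,
    mass_weighted: bool = True,
) -> SeriesResult:
    """Per-frame Euclidean distance (Å) between two selection centres."""
    if len(sel_a) == 0 or len(sel_b) == 0:
        raise ValueError("empty selection")
    wa = sel_a.masses() if mass_weighted else np.ones(len(sel_a))
    wb = sel_b.masses() if mass_weighted else np.ones(len(sel_b))
    wa = wa / wa.sum()
    wb = wb / wb.sum()
    coords = traj.coordinate_array()
    com_a = np.einsum("i,tij->tj", wa, coords[:, sel_a.indices])
    com_b = np.einsum("i,tij->tj", wb, coords[:, sel_b.indices])
    values = np.linalg.norm(com_a - com_b, axis=1)
    return SeriesResult("com_distance", np.arange(traj.n_frames), values, "A")


def _principal_axis(points: np.ndarray) -> np.ndarray:
    # collapse the helical radius onto the axis with a one-turn (4-residue)
    # moving average before the line fit; a raw fit to half a helix is badly
    # biased whenever the half covers a non-integer number of turns
    if len(points) >= 6:
        kernel = np.ones(4) / 4.0
        points = np.column_stack(
            [np.convolve(points[:, k], kernel, mode="valid") for k in range(3)]
        )
    centred = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centred)
    return vt[0]


def helix_bend_angle(frame: Frame, helix_ca: AtomSelection) -> float:
    """Bend of a helix as the angle between half-split principal axes.

    The ordered Cα list is split in half; each half is smoothed with a
    4-residue moving average (collapsing one helical turn onto the axis) and
    its best-fit line (leading singular vector of the centred coordinates)
    taken as the local helix axis; the returned angle between the two axes
    lies in [0, 90] degrees.
    """
    if len(helix_ca) < 8:
        raise ValueError("helix bend needs at least 8 Cα atoms")
    pts = helix_ca.coordinates(frame)
    half = len(pts) // 2
    ax1 = _principal_axis(pts[:half])
    ax2 = _principal_axis(pts[half:])
    cosang = abs(float(np.dot(ax1, ax2)))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
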