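"""Internal coordinates and descriptors of the retinal–lysine chromophore.

The chromophore (residue LYR: 11-cis retinal Schiff-base linked to the
binding-site lysine) is addressed through logical atom names (``N+``,
``C1`` … ``C16``, ``C20``, ``CA``, ``CD``, ``CE``) mapped onto structure
atom names, so the same analysis runs on differently named topologies,
including a composite RET + linked-LYS arrangement.  Named torsions cover
the Schiff-base twist (CD-CE-N+-C15) and the ring–chain linkage around C6
(C7-C6-C1-C16 and C5-C6-C7-C8); the β-ionone ring is C1–C6 and the polyene
chain C7–C15.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .geometry import SeriesResult
from .model_io import AtomSelection, Topology, Trajectory

__all__ = [
    "ChromophoreSpec",
    "ChromophoreProfile",
    "ModalityCall",
    "default_chromophore_spec",
    "resolve_chromophore",
    "internal_coordinate_series",
    "chromophore_profile",
    "classify_modality",
    "circular_mean",
    "circular_histogram",
    "key_distance_series",
]

_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT", "H", "HA", "HN"}


@dataclass
class ChromophoreSpec:
    """Logical-name map and named internal coordinates of the chromophore."""

    residue_name: str = "LYR"
    atom_aliases: dict = field(default_factory=dict)
    torsion_defs: dict = field(default_factory=dict)
    angle_defs: dict = field(default_factory=dict)
    ring_atoms: tuple = ("C1", "C2", "C3", "C4", "C5", "C6")
    polyene_atoms: tuple = ("C7", "C8", "C9", "C10", "C11", "C12", "C13", "C14", "C15")

    def __post_init__(self):
        if set(self.ring_atoms) & set(self.polyene_atoms):
            raise ValueError("ring and polyene atom sets must be disjoint")
        for name, atoms in {**self.torsion_defs, **self.angle_defs}.items():
            missing = [a for a in atoms if a not in self.logical_names()]
            if missing:
                raise ValueError(f"coordinate {name} uses undeclared atoms {missing}")

    def logical_names(self) -> set:
        names = set(self.atom_aliases)
        names.update(self.ring_atoms)
        names.update(self.polyene_atoms)
        return names

    def coordinate_atoms(self, name: str) -> tuple:
        if name in self.torsion_defs:
            return tuple(self.torsion_defs[name])
        if name in self.angle_defs:
            return tuple(self.angle_defs[name])
        raise KeyError(f"coordinate '{name}' not declared in ChromophoreSpec")


def default_chromophore_spec() -> ChromophoreSpec:
    """Spec for a LYR residue whose atoms carry their logical names directly."""
    aliases = {f"C{i}": f"C{i}" for i in range(1, 17)}
    aliases.update({"C20": "C20", "N+": "NZ", "CA": "CA", "CD": "CD", "CE": "CE"})
    return ChromophoreSpec(
        residue_name="LYR",
        atom_aliases=aliases,
        torsion_defs={
            "SB_twist": ("CD", "CE", "N+", "C15"),
            "ring_chain_1": ("C7", "C6", "C1", "C16"),
            "ring_chain_2": ("C5", "C6", "C7", "C8"),
        },
        angle_defs={
            "ang1": ("CA", "N+", "C13"),
            "ang2": ("C14", "C10", "C2"),
        },
    )


@dataclass
class ModalityCall:
    """Mono/bimodal classification of a circular torsion distribution."""

    label: str
    peaks: list
    peak_heights: list
    multimodal: bool = False

    def __post_init__(self):
        if self.label == "bimodal" and len(self.peaks) != 2:
            raise ValueError("bimodal calls report exactly 2 peaks")


@dataclass
class ChromophoreProfile:
    """Bundle of chromophore descriptors over a trajectory."""

    rg_series: SeriesResult
    per_atom_rmsf: dict
    torsion_histograms: dict
    angle_histograms: dict
    modality_labels: dict


def resolve_chromophore(topology: Topology, spec: ChromophoreSpec) -> dict:
    """Map every logical atom name of the ChromophoreSpec to an atom index.

    Unqualified aliases are looked up inside the unique residue matching
    ``spec.residue_name``; qualified aliases of the form ``RES:ATOM`` or
    ``RES123:ATOM`` (e.g. ``LYS296:NZ``, ``RET:C5``) are looked up anywhere,
    which supports composite retinal + linked-lysine topologies.
    """
    matches = [
        idx for key, idx in zip(topology.residues,
                                (topology._residues[k] for k in topology.residues))
        if key[2] == spec.residue_name
    ]
    aliases = dict(spec.atom_aliases)
    for name in list(spec.ring_atoms) + list(spec.polyene_atoms):
        aliases.setdefault(name, name)
    needs_host = any(":" not in v for v in aliases.values())
    host_atoms: list[int] = []
    if needs_host:
        if len(matches) == 0:
            raise ValueError(f"no residue named {spec.residue_name} in topology")
        if len(matches) > 1:
            raise ValueError(f"multiple residues named {spec.residue_name} in topology")
        host_atoms = matches[0]

    mapping: dict = {}
    missing: list[str] = []
    for logical, target in aliases.items():
        if ":" in target:
            res_spec, atom_name = target.split(":")
            res_name = res_spec.rstrip("0123456789")
            res_id = res_spec[len(res_name):]
            cand = [
                i for i in range(topology.n_atoms)
                if topology.residue_names[i] == res_name
                and topology.names[i] == atom_name
                and (not res_id or topology.residue_ids[i] == int(res_id))
            ]
        else:
            cand = [i for i in host_atoms if topology.names[i] == target]
        if len(cand) != 1:
            missing.append(logical)
        else:
            mapping[logical] = cand[0]
    if missing:
        raise ValueError(f"unresolvable chromophore atoms: {sorted(missing)}")
    return mapping


def internal_coordinate_series(
    traj: Trajectory, spec: ChromophoreSpec, coordinate_name: str
) -> SeriesResult:
    """Per-frame value (degrees) of a named chromophore torsion or angle."""
    atoms = spec.coordinate_atoms(coordinate_name)  # KeyError for unknown names
    mapping = resolve_chromophore(traj.topology, spec)
    idx = [mapping[a] for a in atoms]
    if len(idx) == 4:
        values = geometry.dihedral_series(traj, *idx)
    else:
        values = geometry.angle_series(traj, *idx)
    return SeriesResult(coordinate_name, np.arange(traj.n_frames), values, "deg")


def circular_mean(samples_deg: np.ndarray) -> float:
    """Circular mean in degrees on (−180, 180]."""
    rad = np.radians(np.asarray(samples_deg, dtype=float))
    mean = np.degrees(np.arctan2(np.mean(np.sin(rad)), np.mean(np.cos(rad))))
    return 180.0 if mean <= -180.0 else float(mean)


def circular_histogram(samples_deg: np.ndarray, n_bins: int = 36) -> tuple:
    """Normalised histogram over (−180, 180]; masses sum to 1."""
    wrapped = (np.asarray(samples_deg, dtype=float) + 180.0) % 360.0 - 180.0
    # map the closed endpoint −180 → +180 so the interval is (−180, 180]
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    counts, _ = np.histogram(np.clip(wrapped, -179.9999, 180.0), bins=edges)
    return counts / counts.sum(), edges


def classify_modality(
    samples_deg: np.ndarray,
    kappa: float = 50.0,
    height_fraction: float = 0.10,
    min_separation: float = 30.0,
) -> ModalityCall:
    """Classify a circular sample as monomodal or bimodal.

    A von Mises kernel density (concentration ``kappa``) is evaluated on a
    1° grid; local maxima above ``height_fraction`` of the global maximum
    and pairwise separated by at least ``min_separation`` degrees count as
    peaks.  More than two surviving peaks are reported as the top two with
    the ``multimodal`` flag set.  Peak heights are the fractions of samples
    closest (circularly) to each peak.
    """
    samples = np.asarray(samples_deg, dtype=float)
    if samples.size < 100:
        raise ValueError("modality classification needs at least 100 samples")
    grid = np.arange(-179.0, 181.0, 1.0)
    rad_g = np.radians(grid)[:, None]
    rad_s = np.radians(samples)[None, :]
    density = np.exp(kappa * (np.cos(rad_g - rad_s) - 1.0)).sum(axis=1)
    n = len(grid)
    is_max = (density >= np.roll(density, 1)) & (density > np.roll(density, -1))
    cand = np.nonzero(is_max & (density >= height_fraction * density.max()))[0]
    # greedy peak pruning by height with a circular separation floor
    order = cand[np.argsort(density[cand])[::-1]]
    kept: list[int] = []
    for i in order:
        if all(_circ_dist(grid[i], grid[j]) >= min_separation for j in kept):
            kept.append(i)
    kept.sort(key=lambda i: -density[i])
    if len(kept) == 0:  # flat density; fall back to the global maximum
        kept = [int(np.argmax(density))]
    multimodal = len(kept) > 2
    kept = kept[:2]
    peaks = [float(grid[i]) for i in kept]
    assign = np.argmin(
        np.stack([_circ_dist(samples, p) for p in peaks]), axis=0
    )
    heights = [float(np.mean(assign == k)) for k in range(len(peaks))]
    label = "monomodal" if len(peaks) == 1 else "bimodal"
    return ModalityCall(label=label, peaks=peaks, peak_heights=heights, multimodal=multimodal)


def _circ_dist(a, b):
    d = np.abs(np.asarray(a) - np.asarray(b)) % 360.0
    return np.where(d > 180.0, 360.0 - d, d)


def chromophore_profile(
    traj: Trajectory,
    spec: ChromophoreSpec,
    align_selection: AtomSelection | None = None,
    n_bins: int = 36,
) -> ChromophoreProfile:
    """Rg, per-atom RMSF, torsion/angle histograms and modality calls."""
    if traj.n_frames < 2:
        raise ValueError("profile requires at least 2 frames")
    mapping = resolve_chromophore(traj.topology, spec)
    topo = traj.topology
    atom_idx = np.array(sorted(set(mapping.values())))
    heavy_idx = atom_idx[topo.heavy_mask[atom_idx]]
    heavy_sel = AtomSelection(topo, heavy_idx)
    rg = geometry.radius_of_gyration_series(traj, heavy_sel, mass_weighted=True)
    rg.name = "chromophore_rg"
    sel = AtomSelection(topo, atom_idx)
    rmsf_vals = geometry.rmsf(traj, sel, align_selection)
    inverse = {v: k for k, v in mapping.items()}
    per_atom_rmsf = {inverse[i]: float(v) for i, v in zip(atom_idx, rmsf_vals) if i in inverse}

    torsion_histograms: dict = {}
    modality: dict = {}
    for name in spec.torsion_defs:
        series = internal_coordinate_series(traj, spec, name)
        torsion_histograms[name] = circular_histogram(series.values, n_bins)
        if traj.n_frames >= 100:
            modality[name] = classify_modality(series.values)
    angle_histograms: dict = {}
    for name in spec.angle_defs:
        series = internal_coordinate_series(traj, spec, name)
        angle_histograms[name] = circular_histogram(series.values, n_bins)
    return ChromophoreProfile(
        rg_series=rg,
        per_atom_rmsf=per_atom_rmsf,
        torsion_histograms=torsion_histograms,
        angle_histograms=angle_histograms,
        modality_labels=modality,
    )


def _residue_group_indices(
    topology: Topology, chain_id: str, residue_id: int, group: str
) -> np.ndarray:
    atoms = topology.residue_atoms(chain_id, residue_id)
    if not atoms:
        raise ValueError(f"residue {chain_id}:{residue_id} not found")
    heavy = [i for i in atoms if topology.heavy_mask[i]]
    if group == "carboxylate":
        for names in (("CD", "OE1", "OE2"), ("CG", "OD1", "OD2")):
            sel = [i for i in heavy if topology.names[i] in names]
            if len(sel) == len(names):
                return np.array(sel)
        group = "sidechain"  # fall back for residues without a carboxylate
    sel = [i for i in heavy if topology.names[i] not in _BACKBONE_NAMES]
    if not sel:
        raise ValueError(
            f"residue {chain_id}:{residue_id} has no side-chain heavy atoms"
        )
    return np.array(sel)


def key_distance_series(
    traj: Trajectory,
    spec: ChromophoreSpec,
    pair: str,
    residue_map: dict,
) -> SeriesResult:
    """Per-frame centroid distances between key tuning residues and the chromophore.

    ``pair`` is one of ``d122_ring`` (site-122 side-chain centroid to the
    β-ionone ring centroid), ``d181_polyene`` (site-181 carboxylate centroid
    to the polyene centroid) and ``d181_122`` (side-chain to side-chain).
    ``residue_map`` maps site labels (``"122"``, ``"181"``) to
    ``(chain_id, residue_id)``.  Centroids are unweighted.
    """
    mapping = resolve_chromophore(traj.topology, spec)
    coords = traj.coordinate_array()

    def centroid(indices: np.ndarray) -> np.ndarray:
        return coords[:, indices].mean(axis=1)

    if pair == "d122_ring":
        a = centroid(_residue_group_indices(traj.topology, *residue_map["122"], "sidechain"))
        b = centroid(np.array([mapping[n] for n in spec.ring_atoms]))
    elif pair == "d181_polyene":
        a = centroid(_residue_group_indices(traj.topology, *residue_map["181"], "carboxylate"))
        b = centroid(np.array([mapping[n] for n in spec.polyene_atoms]))
    elif pair == "d181_122":
        a = centroid(_residue_group_indices(traj.topology, *residue_map["181"], "sidechain"))
        b = centroid(_residue_group_indices(traj.topology, *residue_map["122"], "sidechain"))
    else:
        raise ValueError(f"unknown key-distance pair '{pair}'")
    values = np.linalg.norm(a - b, axis=1)
    return SeriesResult(pair, np.arange(traj.n_frames), values, "A")
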