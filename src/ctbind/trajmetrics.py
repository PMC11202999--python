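"""Trajectory summary observables: RMSD, RMSF, Rg and SASA.

Self-contained implementations of the four standard stability/compactness
metrics over multi-frame coordinate sets, with weighted Kabsch superposition
and a deterministic Shrake-Rupley surface-area estimator (Fibonacci sphere
lattice).  Coordinates are in nanometres throughout; PDB/XYZ readers convert
from angstroms on input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from ctbind.errors import ValidationError

#: Standard water-probe radius for SASA, nm.
DEFAULT_PROBE_RADIUS = 0.14

#: Default number of Shrake-Rupley lattice points per atom.
DEFAULT_SPHERE_POINTS = 960

# Van der Waals radii (nm) for common elements; fallback is the carbon radius.
VDW_RADII_NM = {
    "H": 0.120,
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "P": 0.180,
    "S": 0.180,
}
DEFAULT_VDW_RADIUS = 0.170

# Atomic masses (amu) for common elements; fallback is carbon.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "NA": 22.990,
    "MG": 24.305,
    "K": 39.098,
    "CL": 35.45,
    "FE": 55.845,
    "ZN": 65.38,
}
DEFAULT_MASS = 12.011


@dataclass
class ConformationEnsemble:
    """Frames x atoms x 3 coordinates (nm) with per-atom masses and radii."""

    frames: np.ndarray
    masses: np.ndarray
    radii: np.ndarray
    atom_labels: list = field(default_factory=list)
    frame_times: Optional[np.ndarray] = None  # ps

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValidationError("frames must have shape (F, N, 3)")
        n = self.frames.shape[1]
        self.masses = np.asarray(self.masses, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if self.masses.shape != (n,) or self.radii.shape != (n,):
            raise ValidationError("masses and radii must have one value per atom")
        if np.any(self.masses <= 0) or np.any(self.radii <= 0):
            raise ValidationError("masses and radii must be positive")
        if not self.atom_labels:
            self.atom_labels = [f"atom{i}" for i in range(n)]

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """Least-squares superposition of ``mobile`` onto ``reference``.

    Returns the transformed copy of ``mobile`` after the optimal weighted
    rigid-body rotation + translation (proper rotation only: reflections are
    repaired via the SVD determinant correction).
    """
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    mob_center = (w[:, None] * mobile).sum(axis=0)
    ref_center = (w[:, None] * reference).sum(axis=0)
    mob = mobile - mob_center
    ref = reference - ref_center
    covariance = (w[:, None] * mob).T @ ref
    u, _, vt = np.linalg.svd(covariance)
    d = np.sign(np.linalg.det(u @ vt))
    correction = np.diag([1.0, 1.0, d])
    rotation = u @ correction @ vt
    return (mobile - mob_center) @ rotation + ref_center


def _resolve_mask(mask, n_atoms: int) -> np.ndarray:
    if mask is None:
        return np.ones(n_atoms, dtype=bool)
    mask = np.asarray(mask)
    if mask.dtype == bool:
        if mask.shape != (n_atoms,):
            raise ValidationError("boolean mask must have one entry per atom")
        return mask
    out = np.zeros(n_atoms, dtype=bool)
    out[mask] = True
    return out


def _weighted_rmsd(a: np.ndarray, b: np.ndarray, masses: np.ndarray) -> float:
    diff2 = ((a - b) ** 2).sum(axis=1)
    return float(np.sqrt((masses * diff2).sum() / masses.sum()))


def rmsd_series(
    ensemble: ConformationEnsemble,
    reference_index: int = 0,
    align_mask=None,
) -> np.ndarray:
    """Mass-weighted RMSD of every frame to a reference frame.

    Each frame is first optimally superposed on the reference (weighted
    Kabsch) over the atoms selected by ``align_mask`` (default: all), and
    the RMSD is computed over the same selection.
    """
    if ensemble.n_atoms < 3:
        raise ValidationError("superposition needs at least 3 atoms")
    if not 0 <= reference_index < ensemble.n_frames:
        raise ValidationError(f"invalid reference frame index {reference_index}")
    mask = _resolve_mask(align_mask, ensemble.n_atoms)
    masses = ensemble.masses[mask]
    reference = ensemble.frames[reference_index][mask]
    out = np.empty(ensemble.n_frames)
    for i, frame in enumerate(ensemble.frames):
        fitted = kabsch_superpose(frame[mask], reference, masses)
        out[i] = _weighted_rmsd(fitted, reference, masses)
    return out


def rmsf_per_atom(
    ensemble: ConformationEnsemble,
    align_mask=None,
    max_iterations: int = 10,
    tol: float = 1e-10,
) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the mean structure.

    All frames are iteratively superposed (weighted Kabsch over
    ``align_mask`` atoms) onto their running mean structure until the mean
    converges, then RMSF_i = sqrt(<|x_i - <x_i>|^2>) over frames.  Report
    the ensemble average alongside via ``.mean()``.
    """
    if ensemble.n_frames < 2:
        raise ValidationError("RMSF needs at least 2 frames")
    if ensemble.n_atoms < 3:
        raise ValidationError("superposition needs at least 3 atoms")
    mask = _resolve_mask(align_mask, ensemble.n_atoms)
    masses_sel = ensemble.masses[mask]
    frames = ensemble.frames.copy()
    mean = frames[0].copy()
    for _ in range(max_iterations):
        for i in range(len(frames)):
            fitted_sel = kabsch_superpose(frames[i][mask], mean[mask], masses_sel)
            # re-derive the full-frame transform from the selection fit
            frames[i] = _apply_selection_transform(
                frames[i], frames[i][mask], fitted_sel, masses_sel
            )
        new_mean = frames.mean(axis=0)
        if np.max(np.abs(new_mean - mean)) < tol:
            mean = new_mean
            break
        mean = new_mean
    fluct2 = ((frames - mean) ** 2).sum(axis=2).mean(axis=0)
    return np.sqrt(fluct2)


def _apply_selection_transform(
    full: np.ndarray,
    sel_before: np.ndarray,
    sel_after: np.ndarray,
    weights: np.ndarray,
) -> np.ndarray:
    """Recover the rigid transform mapping sel_before -> sel_after and apply
    it to the full coordinate set."""
    w = weights / weights.sum()
    c_before = (w[:, None] * sel_before).sum(axis=0)
    c_after = (w[:, None] * sel_after).sum(axis=0)
    covariance = (w[:, None] * (sel_before - c_before)).T @ (sel_after - c_after)
    u, _, vt = np.linalg.svd(covariance)
    d = np.sign(np.linalg.det(u @ vt))
    rotation = u @ np.diag([1.0, 1.0, d]) @ vt
    return (full - c_before) @ rotation + c_after


# ---------------------------------------------------------------------------
# Compactness and surface
# ---------------------------------------------------------------------------

def radius_of_gyration(frame: np.ndarray, masses=None) -> float:
    """Mass-weighted radius of gyration sqrt(sum m|x - com|^2 / sum m), nm."""
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or frame.shape[1] != 3 or frame.shape[0] < 1:
        raise ValidationError("frame must have shape (N, 3) with N >= 1")
    if masses is None:
        masses = np.ones(frame.shape[0])
    masses = np.asarray(masses, dtype=float)
    com = (masses[:, None] * frame).sum(axis=0) / masses.sum()
    return float(
        np.sqrt((masses * ((frame - com) ** 2).sum(axis=1)).sum() / masses.sum())
    )


def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (golden-angle spiral)."""
    i = np.arange(n_points, dtype=float)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n_points
    theta = 2.0 * np.pi * i / golden
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def sasa(
    frame: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_SPHERE_POINTS,
) -> float:
    """Shrake-Rupley solvent-accessible surface area, nm^2.

    Each atom's sphere is expanded by the probe radius and sampled with a
    deterministic Fibonacci lattice; a sample point is accessible iff it
    lies outside every other expanded sphere.  The per-atom area is the
    accessible fraction times 4*pi*(r_i + probe)^2.
    """
    if probe_radius < 0:
        raise ValidationError("probe_radius must be >= 0")
    if n_sphere_points < 32:
        raise ValidationError("n_sphere_points must be >= 32")
    frame = np.asarray(frame, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = frame.shape[0]
    expanded = radii + probe_radius
    lattice = fibonacci_sphere(n_sphere_points)
    total = 0.0
    # pairwise neighbor pre-filter keeps the inner loop small
    deltas = frame[:, None, :] - frame[None, :, :]
    dist2 = (deltas**2).sum(axis=2)
    # Points exactly on a neighbouring sphere (coincident atoms) are resolved
    # by an index tie-break so a duplicated sphere contributes its area once.
    tie = 1e-9
    for i in range(n):
        cutoff2 = (expanded[i] + expanded) ** 2
        neighbors = np.where((dist2[i] < cutoff2) & (np.arange(n) != i))[0]
        points = frame[i] + expanded[i] * lattice
        if neighbors.size:
            sep2 = (
                (points[:, None, :] - frame[neighbors][None, :, :]) ** 2
            ).sum(axis=2)
            margin = np.where(neighbors < i, 1.0 + tie, 1.0 - tie)
            accessible = np.all(
                sep2 >= expanded[neighbors] ** 2 * margin, axis=1
            )
            frac = accessible.mean()
        else:
            frac = 1.0
        total += frac * 4.0 * np.pi * expanded[i] ** 2
    return float(total)


def sasa_series(
    ensemble: ConformationEnsemble,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_SPHERE_POINTS,
) -> np.ndarray:
    """SASA of every frame in an ensemble."""
    return np.array(
        [
            sasa(frame, ensemble.radii, probe_radius, n_sphere_points)
            for frame in ensemble.frames
        ]
    )


# ---------------------------------------------------------------------------
# File readers
# ---------------------------------------------------------------------------

def _element_mass(element: str) -> float:
    return ATOMIC_MASSES.get(element.upper(), DEFAULT_MASS)


def _element_radius(element: str) -> float:
    return VDW_RADII_NM.get(element.upper(), DEFAULT_VDW_RADIUS)


def read_pdb_ensemble(path) -> ConformationEnsemble:
    """Read a (multi-MODEL) PDB file into an ensemble, converting A -> nm."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("traj", str(path))
    frames = []
    labels: list[str] = []
    elements: list[str] = []
    for model in structure:
        atoms = list(model.get_atoms())
        coords = np.array([a.coord for a in atoms], dtype=float) * 0.1
        frames.append(coords)
        if not labels:
            labels = [a.get_name() for a in atoms]
            elements = [
                (a.element or a.get_name()[0]).strip() or "C" for a in atoms
            ]
    if not frames:
        raise ValidationError(f"{path}: no MODEL records / atoms found")
    counts = {f.shape[0] for f in frames}
    if len(counts) != 1:
        raise ValidationError(f"{path}: frames differ in atom count: {counts}")
    masses = np.array([_element_mass(e) for e in elements])
    radii = np.array([_element_radius(e) for e in elements])
    return ConformationEnsemble(
        frames=np.stack(frames), masses=masses, radii=radii, atom_labels=labels
    )


def read_xyz_ensemble(path) -> ConformationEnsemble:
    """Read a multi-frame XYZ file (coordinates in angstroms) into nm."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    frames = []
    elements: list[str] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise ValidationError(f"{path}: truncated XYZ frame")
        coords = []
        frame_elements = []
        for row in block:
            parts = row.split()
            frame_elements.append(parts[0])
            coords.append([float(v) for v in parts[1:4]])
        if not elements:
            elements = frame_elements
        elif frame_elements != elements:
            raise ValidationError(f"{path}: inconsistent atoms between frames")
        frames.append(np.array(coords) * 0.1)
        i += 2 + n
    if not frames:
        raise ValidationError(f"{path}: no frames found")
    masses = np.array([_element_mass(e) for e in elements])
    radii = np.array([_element_radius(e) for e in elements])
    return ConformationEnsemble(
        frames=np.stack(frames), masses=masses, radii=radii, atom_labels=elements
    )
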