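"""Superposition-based trajectory geometry.

Least-squares rigid superposition (with the improper-rotation determinant
correction), RMSD time series, RMSF about the iteratively superposed
window-average structure, cation displacement distributions, and ligand
dihedral populations with circular histograms and mode reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import GeometryError, UsageError
from .model_io import Topology, Trajectory


@dataclass
class Superposition:
    rotation: np.ndarray   # 3x3, det +1
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class IonSite:
    label: str
    atom_id: int
    reference_position: np.ndarray


@dataclass
class DihedralDefinition:
    name: str
    atom_ids: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if len(set(self.atom_ids)) != 4:
            raise ValueError("dihedral atoms must be distinct")


def superpose(reference: np.ndarray, mobile: np.ndarray,
              selection: np.ndarray | None = None) -> Superposition:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Kabsch algorithm on the selected atoms; the returned transform maps
    mobile coordinates onto the reference frame and attains the reported
    RMSD. Degenerate (collinear or < 3 atom) selections are an error.
    """
    ref = np.asarray(reference, dtype=float)
    mob = np.asarray(mobile, dtype=float)
    if selection is not None:
        sel = np.asarray(selection)
        ref_s, mob_s = ref[sel], mob[sel]
    else:
        ref_s, mob_s = ref, mob
    if ref_s.shape != mob_s.shape or ref_s.shape[0] < 3:
        raise GeometryError("superposition needs >= 3 paired atoms")
    ref_c = ref_s.mean(axis=0)
    mob_c = mob_s.mean(axis=0)
    a = ref_s - ref_c
    b = mob_s - mob_c
    if np.linalg.matrix_rank(a, tol=1e-8) < 2:
        raise GeometryError("degenerate (collinear) selection")
    h = b.T @ a
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = ref_c - rot @ mob_c
    moved = mob_s @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref_s) ** 2, axis=1))))
    return Superposition(rotation=rot, translation=trans, rmsd=rmsd)


def rmsd_series(trajectory: Trajectory, selection: np.ndarray | None,
                reference: np.ndarray) -> np.ndarray:
    """Superposed RMSD of every frame against a reference coordinate set."""
    return np.array([superpose(reference, f.positions, selection).rmsd
                     for f in trajectory.frames])


def average_structure(trajectory: Trajectory, selection: np.ndarray | None = None,
                      n_iter: int = 2, tol: float = 1e-4) -> np.ndarray:
    """Window-average structure after iterative superposition.

    Frames are superposed on the current average (initially the first
    frame), re-averaged, and iterated; stops after ``n_iter`` passes or
    when the average moves less than ``tol`` A RMS.
    """
    if trajectory.n_frames < 2:
        raise UsageError("average structure needs >= 2 frames")
    avg = trajectory.frames[0].positions.copy()
    for _ in range(n_iter):
        fitted = []
        for f in trajectory.frames:
            sp = superpose(avg, f.positions, selection)
            fitted.append(sp.apply(f.positions))
        new_avg = np.mean(fitted, axis=0)
        shift = float(np.sqrt(np.mean(np.sum((new_avg - avg) ** 2, axis=1))))
        avg = new_avg
        if shift < tol:
            break
    return avg


def rmsf(trajectory: Trajectory, selection: np.ndarray | None = None,
         window: tuple[float | None, float | None] | None = None
         ) -> tuple[np.ndarray, dict]:
    """Per-atom and per-residue fluctuation about the average structure.

    Each frame is superposed (on ``selection``) onto the iteratively
    computed window-average structure; the per-atom RMSF is the root mean
    square deviation from that average. Residue values average the
    selected atoms of each residue.
    """
    traj = trajectory if window is None else trajectory.window(*window)
    if traj.n_frames < 2:
        raise UsageError("rmsf needs a window of >= 2 frames")
    avg = average_structure(traj, selection)
    sq = np.zeros(avg.shape[0])
    for f in traj.frames:
        sp = superpose(avg, f.positions, selection)
        moved = sp.apply(f.positions)
        sq += np.sum((moved - avg) ** 2, axis=1)
    per_atom = np.sqrt(sq / traj.n_frames)

    per_residue: dict = {}
    atoms = traj.topology.atoms
    sel = set(range(len(atoms))) if selection is None else set(np.asarray(selection).tolist())
    buckets: dict = {}
    for a in atoms:
        if a.atom_id in sel:
            buckets.setdefault(a.residue_key, []).append(per_atom[a.atom_id])
    for key, vals in buckets.items():
        per_residue[key] = float(np.mean(vals))
    return per_atom, per_residue


def terminal_strand_rmsf(per_residue: dict, n_terminal: int = 8) -> dict:
    """Mean fluctuation of the first/last ``n_terminal`` residues."""
    keys = sorted(per_residue.keys())
    return {
        "n_terminal": float(np.mean([per_residue[k] for k in keys[:n_terminal]])),
        "c_terminal": float(np.mean([per_residue[k] for k in keys[-n_terminal:]])),
    }


def ion_displacement_distribution(trajectory: Trajectory, sites: list[IonSite],
                                  align_selection: np.ndarray,
                                  bin_width: float = 0.1) -> dict:
    """Per-site displacement series and the joint 2D histogram.

    Every frame is superposed on ``align_selection`` against the first
    frame; each ion's displacement from its reference position is
    recorded. With two sites the joint histogram pairs site I (x) with
    site II (y).
    """
    if not sites:
        raise UsageError("at least one ion site is required")
    n_atoms = trajectory.topology.n_atoms
    for s in sites:
        if not 0 <= s.atom_id < n_atoms:
            raise UsageError(f"ion atom id {s.atom_id} missing from topology")
    labels = [s.label for s in sites]
    if len(set(labels)) != len(labels):
        raise UsageError("ion site labels must be unique")
    ref = trajectory.frames[0].positions
    series: dict[str, list[float]] = {s.label: [] for s in sites}
    for f in trajectory.frames:
        sp = superpose(ref, f.positions, align_selection)
        moved = sp.apply(f.positions)
        for s in sites:
            disp = float(np.linalg.norm(moved[s.atom_id] - s.reference_position))
            series[s.label].append(disp)
    out: dict = {"series": {k: np.array(v) for k, v in series.items()}}
    if len(sites) >= 2:
        a = out["series"][sites[0].label]
        b = out["series"][sites[1].label]
        top = max(float(a.max()), float(b.max()), bin_width)
        edges = np.arange(0.0, top + bin_width, bin_width)
        hist, ex, ey = np.histogram2d(a, b, bins=[edges, edges])
        out["histogram"] = hist / hist.sum()
        out["edges"] = (ex, ey)
    return out


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed torsion angle in (-180, 180] degrees.

    Standard convention: invariant under full atom-order reversal;
    negated by mirror reflection.
    """
    b0 = np.asarray(p0, float) - np.asarray(p1, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    nb1 = np.linalg.norm(b1)
    if nb1 == 0:
        raise GeometryError("central dihedral bond has zero length")
    b1u = b1 / nb1
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    if np.linalg.norm(v) < 1e-12 or np.linalg.norm(w) < 1e-12:
        raise GeometryError("collinear atoms: dihedral undefined")
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def dihedral_series(trajectory: Trajectory, definition: DihedralDefinition,
                    bin_width: float = 5.0, fold: bool = False) -> dict:
    """Angle series, circular histogram and smoothed-histogram mode report.

    ``fold`` maps angles modulo 180 deg (for two-fold symmetric rings
    where 0 and 180 are equivalent). Frames with collinear triples are
    recorded as NaN and counted in ``n_flagged``. Histogram mass sums to
    1 over all bins. Modes are local maxima of the 3-bin moving-average
    smoothed histogram; each mode's population is the raw mass of its
    watershed segment (split at smoothed minima between modes).
    """
    i, j, k, l = definition.atom_ids
    angles = np.empty(trajectory.n_frames)
    flagged = 0
    for fi, f in enumerate(trajectory.frames):
        p = f.positions
        try:
            a = dihedral_angle(p[i], p[j], p[k], p[l])
        except GeometryError:
            a = math.nan
            flagged += 1
        angles[fi] = a
    valid = angles[np.isfinite(angles)]
    work = np.mod(valid, 180.0) if fold else valid
    lo, hi = (0.0, 180.0) if fold else (-180.0, 180.0)
    nbins = int(round((hi - lo) / bin_width))
    hist, edges = np.histogram(work, bins=nbins, range=(lo, hi))
    mass = hist / max(1, hist.sum())
    smooth = (np.roll(mass, 1) + mass + np.roll(mass, -1)) / 3.0

    modes = []
    n = len(smooth)
    for b in range(n):
        left, right = smooth[(b - 1) % n], smooth[(b + 1) % n]
        if smooth[b] > 0 and smooth[b] >= left and smooth[b] > right:
            modes.append(b)
    mode_report = []
    if modes:
        # watershed: assign each bin to the mode reached by ascending the
        # smoothed histogram (ties go to the nearer mode circularly)
        boundaries = []
        ordered = sorted(modes)
        for a, b in zip(ordered, ordered[1:] + [ordered[0] + n]):
            seg = [(smooth[c % n], c % n) for c in range(a, b + 1)]
            boundaries.append(min(seg)[1])
        # bins strictly after boundary idx-1 up to and including boundary
        # idx belong to the mode sitting between those two minima
        assign = np.zeros(n, dtype=int)
        for idx in range(len(ordered)):
            start = boundaries[idx - 1]
            end = boundaries[idx]
            span = (end - start) % n or n
            for step in range(span):
                assign[(start + step + 1) % n] = idx
        for mi, m in enumerate(ordered):
            frac = float(mass[assign == mi].sum())
            center = lo + (m + 0.5) * bin_width
            mode_report.append({"angle": center, "fraction": frac})
        mode_report.sort(key=lambda r: -r["fraction"])
    return {
        "angles": angles,
        "histogram": mass,
        "edges": edges,
        "modes": mode_report,
        "n_flagged": flagged,
        "folded": fold,
    }


def backbone_selection(topology: Topology) -> np.ndarray:
    """Atom ids of protein backbone heavy atoms (N, CA, C, O)."""
    ids = [a.atom_id for a in topology.atoms
           if a.name in ("N", "CA", "C", "O")
           and topology.molecule_class.get(a.residue_key) == "protein"]
    return np.array(ids, dtype=int)
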