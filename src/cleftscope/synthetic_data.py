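"""Synthetic fixtures: toy complexes, planted trajectories, energy tables
and analytic toy potentials.

Planted geometries are constructed analytically (donor-H-acceptor placed
collinear at 2.9 A for "on" frames, stretched to 4.5 A for "off" frames),
not by energy minimisation: the pipeline tests detectors, not physics.
Episodes are contiguous so lifetime statistics are recoverable. All
generators are seed-deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import SpecificationError
from .model_io import (AtomRecord, Frame, Structure, Topology, Trajectory,
                       annotate_topology)

ON_DISTANCE = 2.9    # donor-acceptor distance in planted "on" frames, A
OFF_DISTANCE = 4.5   # stretched distance in "off" frames, A
PIPI_ON_OFFSET = 3.5  # centroid separation along the ring normal, A
PIPI_OFF_OFFSET = 8.0


@dataclass
class FixtureSpec:
    """Parameters shared by every planted trajectory."""

    seed: int = 0
    n_frames: int = 100
    timestep: float = 1.0  # ps
    jitter_sigma: float = 0.0  # per-axis Gaussian positional noise, A

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")


@dataclass
class PlantedInteraction:
    """An interaction scheduled to hold in a target fraction of frames."""

    kind: str  # {"hbond", "saltbridge", "pipi"}
    target_occupancy: float = 1.0
    episode_length: int = 10
    donor: int | None = None      # heavy-atom id (hbond/saltbridge)
    hydrogen: int | None = None
    acceptor: int | None = None
    ring_a: int | None = None     # ring indices into Topology.rings (pipi)
    ring_b: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_occupancy <= 1.0:
            raise ValueError("target_occupancy must lie in [0, 1]")
        if self.kind not in ("hbond", "saltbridge", "pipi"):
            raise ValueError(f"unknown interaction kind {self.kind!r}")


@dataclass
class IonSiteModel:
    """Gaussian positional model for one cation site, with optional drift."""

    site_label: str  # "I" or "II"
    anchor: np.ndarray = field(default_factory=lambda: np.zeros(3))
    sigma: float = 0.1  # A
    drift: np.ndarray | None = None  # A per ns

    def __post_init__(self) -> None:
        self.anchor = np.asarray(self.anchor, dtype=float)
        if self.drift is not None:
            self.drift = np.asarray(self.drift, dtype=float)
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


# ---------------------------------------------------------------------------
# Toy complex
# ---------------------------------------------------------------------------

def _hexagon(center, radius=1.39, start_angle=0.0, z=0.0):
    pts = []
    for k in range(6):
        a = math.radians(start_angle + 60.0 * k)
        pts.append(np.array([center[0] + radius * math.cos(a),
                             center[1] + radius * math.sin(a),
                             center[2] + z]))
    return pts


def _ring_substituent(center, ring_point, extra):
    """Extend outward from the ring center through a ring atom."""
    u = ring_point - np.asarray(center, dtype=float)
    u = u / np.linalg.norm(u)
    return ring_point + extra * u


def make_toy_complex(n_waters: int = 0) -> tuple[Structure, Topology]:
    """Build the deterministic toy complex and its annotated topology.

    A protein-like scaffold (Gly91, Met120, Leu136, Phe156, Lys158,
    Gly159, Val160, Glu161), a three-ring ligand with labelled protons
    H9/H10, H12/H13, H16/H17 and three named dihedrals, two calcium ions,
    and an optional small water shell (<= 30 molecules).
    """
    if n_waters > 30:
        raise ValueError("water shell is capped at 30 molecules")

    atoms: list[AtomRecord] = []

    def add(name, element, resname, resseq, chain, pos):
        atoms.append(AtomRecord(atom_id=len(atoms), name=name, element=element,
                                residue_name=resname, residue_index=resseq,
                                chain_id=chain, position=np.asarray(pos, dtype=float)))

    def backbone(resname, resseq, o):
        ox, oy, oz = o
        add("N", "N", resname, resseq, "A", (ox, oy + 1.2, oz))
        add("H", "H", resname, resseq, "A", (ox, oy + 2.2, oz))
        add("CA", "C", resname, resseq, "A", (ox, oy, oz))
        add("C", "C", resname, resseq, "A", (ox + 1.3, oy - 0.5, oz))
        add("O", "O", resname, resseq, "A", (ox + 1.9, oy - 1.6, oz))

    protein = [("GLY", 91), ("MET", 120), ("LEU", 136), ("PHE", 156),
               ("LYS", 158), ("GLY", 159), ("VAL", 160), ("GLU", 161)]
    for i, (resname, resseq) in enumerate(protein):
        o = np.array([6.0 * i, 0.0, 0.0])
        backbone(resname, resseq, o)
        if resname == "GLY":
            continue
        cb = o + np.array([-0.8, -1.2, 0.5])
        add("CB", "C", resname, resseq, "A", cb)
        if resname == "MET":
            cg = cb + np.array([0.0, -1.4, 0.3])
            sd = cg + np.array([0.0, -1.6, 0.2])
            ce = sd + np.array([1.2, -1.0, 0.0])
            add("CG", "C", resname, resseq, "A", cg)
            add("SD", "S", resname, resseq, "A", sd)
            add("CE", "C", resname, resseq, "A", ce)
            add("HE1", "H", resname, resseq, "A", ce + np.array([0.9, 0.4, 0.3]))
            add("HE2", "H", resname, resseq, "A", ce + np.array([0.5, -0.5, 0.9]))
            add("HE3", "H", resname, resseq, "A", ce + np.array([0.6, -0.6, -0.8]))
        elif resname == "LEU":
            cg = cb + np.array([0.0, -1.5, 0.0])
            cd1 = cg + np.array([-1.2, -0.8, 0.0])
            add("CG", "C", resname, resseq, "A", cg)
            add("CD1", "C", resname, resseq, "A", cd1)
            add("CD2", "C", resname, resseq, "A", cg + np.array([1.2, -0.8, 0.0]))
            add("HD11", "H", resname, resseq, "A", cd1 + np.array([-0.9, 0.4, 0.3]))
            add("HD12", "H", resname, resseq, "A", cd1 + np.array([-0.4, -0.6, 0.8]))
            add("HD13", "H", resname, resseq, "A", cd1 + np.array([-0.5, -0.5, -0.8]))
        elif resname == "PHE":
            cg_center = cb + np.array([0.0, -2.9, 0.0])
            ring = _hexagon(cg_center, start_angle=90.0)
            for name, p in zip(["CG", "CD1", "CE1", "CZ", "CE2", "CD2"], ring):
                add(name, "C", resname, resseq, "A", p)
        elif resname == "LYS":
            cg = cb + np.array([0.0, -1.4, 0.0])
            ce = cg + np.array([0.0, -1.5, 0.0])
            nz = ce + np.array([0.0, -1.3, 0.0])
            add("CG", "C", resname, resseq, "A", cg)
            add("CE", "C", resname, resseq, "A", ce)
            add("NZ", "N", resname, resseq, "A", nz)
            add("HZ1", "H", resname, resseq, "A", nz + np.array([0.0, -1.0, 0.0]))
            add("HZ2", "H", resname, resseq, "A", nz + np.array([0.9, -0.4, 0.0]))
            add("HZ3", "H", resname, resseq, "A", nz + np.array([-0.9, -0.4, 0.0]))
        elif resname == "VAL":
            cg1 = cb + np.array([-1.2, -0.9, 0.0])
            add("CG1", "C", resname, resseq, "A", cg1)
            add("CG2", "C", resname, resseq, "A", cb + np.array([1.2, -0.9, 0.0]))
            add("HG11", "H", resname, resseq, "A", cg1 + np.array([-0.9, 0.4, 0.3]))
            add("HG12", "H", resname, resseq, "A", cg1 + np.array([-0.4, -0.6, 0.8]))
            add("HG13", "H", resname, resseq, "A", cg1 + np.array([-0.5, -0.5, -0.8]))
        elif resname == "GLU":
            cg = cb + np.array([0.0, -1.4, 0.0])
            cd = cg + np.array([0.0, -1.5, 0.0])
            add("CG", "C", resname, resseq, "A", cg)
            add("CD", "C", resname, resseq, "A", cd)
            add("OE1", "O", resname, resseq, "A", cd + np.array([-1.0, -0.7, 0.0]))
            add("OE2", "O", resname, resseq, "A", cd + np.array([1.0, -0.7, 0.0]))

    # --- ligand (chain L, residue EGX 1): three rings + linker ------------
    L = "EGX"
    c_ac = np.array([12.0, -10.0, 0.0])
    ring_ac = _hexagon(c_ac, start_angle=0.0)
    c_b = np.array([18.0, -10.0, 0.0])
    ring_b = _hexagon(c_b, start_angle=180.0)
    c_bp = np.array([18.0, -15.2, 0.0])
    ring_bp = _hexagon(c_bp, start_angle=150.0)

    for name, p in zip(["CA1", "CA2", "CA3", "CA4", "CA5", "CA6"], ring_ac):
        add(name, "C", L, 1, "L", p)
    add("H12", "H", L, 1, "L", _ring_substituent(c_ac, ring_ac[3], 1.08))
    add("H13", "H", L, 1, "L", _ring_substituent(c_ac, ring_ac[4], 1.08))
    add("OA1", "O", L, 1, "L", _ring_substituent(c_ac, ring_ac[1], 1.36))
    add("HOA1", "H", L, 1, "L", _ring_substituent(c_ac, ring_ac[1], 2.33))
    add("OA2", "O", L, 1, "L", _ring_substituent(c_ac, ring_ac[2], 1.36))
    add("HOA2", "H", L, 1, "L", _ring_substituent(c_ac, ring_ac[2], 2.33))

    add("CL1", "C", L, 1, "L", np.array([15.0, -10.0, 0.4]))
    add("CL2", "C", L, 1, "L", np.array([15.0, -11.5, 0.6]))
    add("OL1", "O", L, 1, "L", np.array([16.0, -12.4, 0.3]))

    for name, p in zip(["CB1", "CB2", "CB3", "CB4", "CB5", "CB6"], ring_b):
        add(name, "C", L, 1, "L", p)
    add("H16", "H", L, 1, "L", _ring_substituent(c_b, ring_b[3], 1.08))
    add("H17", "H", L, 1, "L", _ring_substituent(c_b, ring_b[4], 1.08))
    add("OB1", "O", L, 1, "L", _ring_substituent(c_b, ring_b[1], 1.36))
    add("HOB1", "H", L, 1, "L", _ring_substituent(c_b, ring_b[1], 2.33))
    add("OB2", "O", L, 1, "L", _ring_substituent(c_b, ring_b[2], 1.36))
    add("HOB2", "H", L, 1, "L", _ring_substituent(c_b, ring_b[2], 2.33))
    add("OB3", "O", L, 1, "L", _ring_substituent(c_b, ring_b[5], 1.36))
    add("HOB3", "H", L, 1, "L", _ring_substituent(c_b, ring_b[5], 2.33))

    for name, p in zip(["CP1", "CP2", "CP3", "CP4", "CP5", "CP6"], ring_bp):
        add(name, "C", L, 1, "L", p)
    add("H9", "H", L, 1, "L", _ring_substituent(c_bp, ring_bp[3], 1.08))
    add("H10", "H", L, 1, "L", _ring_substituent(c_bp, ring_bp[4], 1.08))
    add("OP1", "O", L, 1, "L", _ring_substituent(c_bp, ring_bp[1], 1.36))
    add("HOP1", "H", L, 1, "L", _ring_substituent(c_bp, ring_bp[1], 2.33))
    add("OP2", "O", L, 1, "L", _ring_substituent(c_bp, ring_bp[2], 1.36))
    add("HOP2", "H", L, 1, "L", _ring_substituent(c_bp, ring_bp[2], 2.33))
    add("OP3", "O", L, 1, "L", _ring_substituent(c_bp, ring_bp[5], 1.36))
    add("HOP3", "H", L, 1, "L", _ring_substituent(c_bp, ring_bp[5], 2.33))

    # --- cation sites ------------------------------------------------------
    add("CA", "CA", "CA", 1, "I", np.array([40.0, 3.0, 2.0]))
    add("CA", "CA", "CA", 2, "I", np.array([20.0, 4.0, 2.0]))

    # --- optional water shell ---------------------------------------------
    for w in range(n_waters):
        o = np.array([2.0 + 5.0 * (w % 8), -20.0 - 5.0 * (w // 8), 1.0])
        add("O", "O", "HOH", w + 1, "W", o)
        add("H1", "H", "HOH", w + 1, "W", o + np.array([0.76, 0.59, 0.0]))
        add("H2", "H", "HOH", w + 1, "W", o + np.array([-0.76, 0.59, 0.0]))

    structure = Structure(atoms=atoms)
    topology = annotate_topology(structure)
    return structure, topology


def _episode_mask(n_frames: int, occupancy: float, episode_length: int) -> np.ndarray:
    """Boolean mask with ceil(occupancy*n) True frames in contiguous episodes."""
    n_on = math.ceil(occupancy * n_frames)
    if n_on > n_frames:
        raise SpecificationError(
            f"occupancy schedule needs {n_on} on-frames in {n_frames} frames")
    mask = np.zeros(n_frames, dtype=bool)
    if n_on == 0:
        return mask
    episode_length = max(1, min(episode_length, n_on))
    n_episodes = math.ceil(n_on / episode_length)
    gap_total = n_frames - n_on
    # distribute the total gap as evenly as possible after each episode
    base, extra = divmod(gap_total, n_episodes)
    pos = 0
    remaining = n_on
    for e in range(n_episodes):
        length = min(episode_length, remaining)
        mask[pos:pos + length] = True
        remaining -= length
        pos += length + base + (1 if e < extra else 0)
    assert int(mask.sum()) == n_on
    return mask


def plant_trajectory(spec: FixtureSpec,
                     interactions: Sequence[PlantedInteraction] = (),
                     ions: Sequence[IonSiteModel] = (),
                     complex: tuple[Structure, Topology] | None = None,
                     ) -> tuple[Trajectory, dict]:
    """Generate a trajectory with scheduled interactions and ion models.

    Returns the trajectory plus a manifest dict recording, per planted
    interaction, the frame mask actually used (the ground truth an
    occupancy detector must recover).
    """
    structure, topology = complex if complex is not None else make_toy_complex()
    n_atoms = structure.n_atoms
    base = structure.coords

    moved: set[int] = set()
    for pi in interactions:
        if pi.kind in ("hbond", "saltbridge"):
            if pi.donor is None or pi.hydrogen is None or pi.acceptor is None:
                raise SpecificationError("hbond/saltbridge plants need donor, "
                                         "hydrogen and acceptor atom ids")
            for aid in (pi.donor, pi.hydrogen, pi.acceptor):
                if not 0 <= aid < n_atoms:
                    raise SpecificationError(f"atom id {aid} not in the toy complex")
            if pi.acceptor in moved:
                raise SpecificationError(
                    f"acceptor atom {pi.acceptor} planted in two interactions")
            moved.add(pi.acceptor)
        else:
            if pi.ring_a is None or pi.ring_b is None:
                raise SpecificationError("pipi plants need ring_a and ring_b indices")
            for r in (pi.ring_a, pi.ring_b):
                if not 0 <= r < len(topology.rings):
                    raise SpecificationError(f"ring index {r} not in topology")
            moved.update(topology.rings[pi.ring_b])

    ion_ids = {}
    ion_residues = sorted(topology.residues_of_class("ion"))
    for model in ions:
        idx = {"I": 0, "II": 1}.get(model.site_label)
        if idx is None or idx >= len(ion_residues):
            raise SpecificationError(f"no ion residue for site {model.site_label!r}")
        reskey = ion_residues[idx]
        ids = [a.atom_id for a in structure.atoms if a.residue_key == reskey]
        ion_ids[model.site_label] = ids[0]

    rng = np.random.default_rng(spec.seed)
    masks = [_episode_mask(spec.n_frames, pi.target_occupancy, pi.episode_length)
             for pi in interactions]

    frames: list[Frame] = []
    for f in range(spec.n_frames):
        pos = base.copy()
        if spec.jitter_sigma > 0:
            pos += rng.normal(0.0, spec.jitter_sigma, size=pos.shape)
        for pi, mask in zip(interactions, masks):
            on = bool(mask[f])
            if pi.kind in ("hbond", "saltbridge"):
                d = pos[pi.donor]
                u = pos[pi.hydrogen] - d
                u = u / np.linalg.norm(u)
                dist = ON_DISTANCE if on else OFF_DISTANCE
                pos[pi.acceptor] = d + dist * u
            else:
                ra = topology.rings[pi.ring_a]
                rb = topology.rings[pi.ring_b]
                pa = pos[ra]
                centroid = pa.mean(axis=0)
                centered = pa - centroid
                _, _, vt = np.linalg.svd(centered)
                normal = vt[2]
                offset = PIPI_ON_OFFSET if on else PIPI_OFF_OFFSET
                target = centroid + offset * normal
                pos[rb] = pos[ra] - centroid + target  # parallel copy of ring_a
        t_ps = f * spec.timestep
        for model in ions:
            p = model.anchor.copy()
            if model.drift is not None:
                p = p + model.drift * (t_ps / 1000.0)
            if model.sigma > 0:
                p = p + rng.normal(0.0, model.sigma, size=3)
            pos[ion_ids[model.site_label]] = p
        frames.append(Frame(time=t_ps, positions=pos))

    traj = Trajectory(topology=topology, frames=frames, timestep=spec.timestep)
    manifest = {
        "seed": spec.seed,
        "n_frames": spec.n_frames,
        "timestep": spec.timestep,
        "jitter_sigma": spec.jitter_sigma,
        "planted": [
            {"kind": pi.kind, "donor": pi.donor, "hydrogen": pi.hydrogen,
             "acceptor": pi.acceptor, "ring_a": pi.ring_a, "ring_b": pi.ring_b,
             "target_occupancy": pi.target_occupancy,
             "episode_length": pi.episode_length,
             "on_frames": int(mask.sum()),
             "mask": mask.astype(int).tolist()}
            for pi, mask in zip(interactions, masks)
        ],
        "ions": [{"site": m.site_label, "sigma": m.sigma,
                  "anchor": m.anchor.tolist(),
                  "drift": None if m.drift is None else m.drift.tolist()}
                 for m in ions],
    }
    return traj, manifest


# ---------------------------------------------------------------------------
# Energy tables
# ---------------------------------------------------------------------------

def make_energy_table(seed: int,
                      rows: Sequence[tuple[str, float, float, float, float]],
                      n_samples: int) -> pd.DataFrame:
    """Per-snapshot Gaussian samples of (dH, -TdS) for each model label.

    ``rows`` holds (label, mean_dH, sd_dH, mean_mTdS, sd_mTdS). Columns:
    model, snapshot, dH, mTdS. Sample statistics converge to the planted
    truth as n_samples grows.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    rng = np.random.default_rng(seed)
    out = []
    for label, m_dh, s_dh, m_mtds, s_mtds in rows:
        dh = rng.normal(m_dh, s_dh, size=n_samples) if s_dh > 0 else np.full(n_samples, m_dh)
        mtds = (rng.normal(m_mtds, s_mtds, size=n_samples) if s_mtds > 0
                else np.full(n_samples, m_mtds))
        for i in range(n_samples):
            out.append((label, i, dh[i], mtds[i]))
    return pd.DataFrame(out, columns=["model", "snapshot", "dH", "mTdS"])


# ---------------------------------------------------------------------------
# Toy potentials
# ---------------------------------------------------------------------------

@dataclass
class ToyPotential:
    """An analytic potential with energy/gradient and reference landmarks."""

    form: str
    params: dict
    dim: int
    domain: np.ndarray  # (dim, 2) bounds, A
    energy: Callable[[np.ndarray], np.ndarray]
    gradient: Callable[[np.ndarray], np.ndarray]
    reference: dict = field(default_factory=dict)


def make_toy_potential(form: str, params: dict | None = None) -> ToyPotential:
    """Construct a named analytic potential.

    ``double_well_1d``: U(x) = barrier * ((x/half_sep)^2 - 1)^2 with
    minima at +-half_sep (U=0) and a barrier of ``barrier`` kcal/mol at 0.

    ``separable_3d``: U(x, y, z) = f(x, y) + g(z) with f a pair of coupled
    double wells and g harmonic; exactly separable in z.
    """
    params = dict(params or {})
    if form == "double_well_1d":
        barrier = float(params.setdefault("barrier", 3.0))
        a = float(params.setdefault("half_sep", 1.0))
        lo = float(params.setdefault("lo", -2.5 * a))
        hi = float(params.setdefault("hi", 2.5 * a))
        if barrier <= 0 or a <= 0:
            raise ValueError("barrier and half_sep must be > 0")

        def energy(x):
            x = np.asarray(x, dtype=float)
            return barrier * ((x / a) ** 2 - 1.0) ** 2

        def gradient(x):
            x = np.asarray(x, dtype=float)
            return 4.0 * barrier * x * ((x / a) ** 2 - 1.0) / a**2

        return ToyPotential(form=form, params=params, dim=1,
                            domain=np.array([[lo, hi]]),
                            energy=energy, gradient=gradient,
                            reference={"minima": [-a, a], "barrier": barrier,
                                       "barrier_location": 0.0})

    if form == "separable_3d":
        hx = float(params.setdefault("hx", 2.0))
        hy = float(params.setdefault("hy", 1.5))
        cxy = float(params.setdefault("cxy", 0.5))
        kz = float(params.setdefault("kz", 2.0))
        bound = float(params.setdefault("bound", 2.5))

        def energy(v):
            v = np.asarray(v, dtype=float)
            x, y, z = v[..., 0], v[..., 1], v[..., 2]
            f = hx * (x**2 - 1.0) ** 2 + hy * (y**2 - 1.0) ** 2 + cxy * x * y
            g = 0.5 * kz * z**2
            return f + g

        def gradient(v):
            v = np.asarray(v, dtype=float)
            x, y, z = v[..., 0], v[..., 1], v[..., 2]
            gx = 4.0 * hx * x * (x**2 - 1.0) + cxy * y
            gy = 4.0 * hy * y * (y**2 - 1.0) + cxy * x
            gz = kz * z
            return np.stack([gx, gy, gz], axis=-1)

        return ToyPotential(form=form, params=params, dim=3,
                            domain=np.array([[-bound, bound]] * 3),
                            energy=energy, gradient=gradient,
                            reference={"separable_axis": 2})

    raise ValueError(f"unknown potential form {form!r}")
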