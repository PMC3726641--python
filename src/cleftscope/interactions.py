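"""Geometric interaction fingerprinting.

Hydrogen bonds: donor-acceptor distance strictly below 3.5 A (4.0 A when
the acceptor is a methionine sulphur) and a donor-H-acceptor angle
(vertex at H, 180 deg = linear) strictly above 120 deg. Pi-pi stacking:
ring centroid distance strictly below 5 A with the inter-normal angle,
folded to [0, 90] deg, strictly below 45 deg. Inequalities at the cutoffs
are strict throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from . import UsageError
from .model_io import Frame, ResidueKey, Topology, Trajectory
from .templates import BACKBONE_ATOMS


@dataclass
class HBondCriteria:
    da_cutoff: float = 3.5
    da_cutoff_sulphur: float = 4.0
    dha_min_angle: float = 120.0

    def __post_init__(self) -> None:
        if self.da_cutoff <= 0 or self.da_cutoff_sulphur <= 0:
            raise ValueError("cutoffs must be > 0")
        if not 0 < self.dha_min_angle <= 180:
            raise ValueError("dha_min_angle must lie in (0, 180]")


@dataclass
class PiPiCriteria:
    centroid_cutoff: float = 5.0
    normal_max_angle: float = 45.0

    def __post_init__(self) -> None:
        if self.centroid_cutoff <= 0:
            raise ValueError("centroid_cutoff must be > 0")
        if not 0 < self.normal_max_angle <= 90:
            raise ValueError("normal_max_angle must lie in (0, 90]")


@dataclass(frozen=True)
class InteractionRecord:
    """One detected contact in one frame."""

    frame_index: int
    kind: str  # "hbond" or "pipi"
    donor: int | None = None
    hydrogen: int | None = None
    acceptor: int | None = None
    ring_a: int | None = None
    ring_b: int | None = None
    partner_class: str | None = None

    @property
    def pair(self) -> tuple:
        if self.kind == "hbond":
            return ("hbond", self.donor, self.hydrogen, self.acceptor)
        return ("pipi",) + tuple(sorted((self.ring_a, self.ring_b)))


@dataclass
class InteractionSummary:
    """Trajectory-level averages of per-frame contact events."""

    n_frames: int
    mean_total: float
    mean_by_class: dict[str, float]
    per_residue: dict[ResidueKey, float]
    occupancy: dict[tuple, float]
    lifetime_fraction: dict[tuple, float]
    salt_bridge_mean: float | None = None
    salt_bridge_percentage: int | None = None
    salt_bridge_undefined: bool = False
    occupancy_threshold: float = 0.3


def _check_annotated(topology: Topology) -> None:
    if not isinstance(topology, Topology):
        raise UsageError("an annotated Topology is required (run annotate_topology)")


def hbond_frame(topology: Topology, frame: Frame,
                criteria: HBondCriteria | None = None,
                include_intra_residue: bool = False) -> list[InteractionRecord]:
    """All (donor heavy, H, acceptor) triples satisfying the criteria.

    Donor and acceptor in the same residue are excluded unless
    ``include_intra_residue`` is set. Each hydrogen on a donor is tested
    independently, giving one record per satisfying (H, acceptor) pair.
    """
    _check_annotated(topology)
    criteria = criteria or HBondCriteria()
    pos = frame.positions
    acc_ids = np.fromiter(topology.acceptors.keys(), dtype=int)
    if acc_ids.size == 0 or not topology.donors:
        return []
    acc_pos = pos[acc_ids]
    cutoffs = np.array([criteria.da_cutoff_sulphur
                        if topology.acceptors[int(a)] == "S" else criteria.da_cutoff
                        for a in acc_ids])
    records: list[InteractionRecord] = []
    cos_max = math.cos(math.radians(criteria.dha_min_angle))
    for heavy, hydrogen in topology.donors:
        d = pos[heavy]
        h = pos[hydrogen]
        da = acc_pos - d
        dist = np.linalg.norm(da, axis=1)
        close = dist < cutoffs
        if not close.any():
            continue
        hd = d - h
        nhd = np.linalg.norm(hd)
        donor_res = topology.residue_of(heavy)
        for j in np.flatnonzero(close):
            a_id = int(acc_ids[j])
            if a_id == heavy or a_id == hydrogen:
                continue
            acc_res = topology.residue_of(a_id)
            if acc_res == donor_res and not include_intra_residue:
                continue
            ha = acc_pos[j] - h
            denom = nhd * np.linalg.norm(ha)
            if denom == 0:
                continue
            cos_dha = float(np.dot(hd, ha)) / denom
            # angle > dha_min_angle  <=>  cos(angle) < cos(dha_min_angle)
            if cos_dha < cos_max:
                records.append(InteractionRecord(
                    frame_index=0, kind="hbond", donor=heavy,
                    hydrogen=hydrogen, acceptor=a_id))
    return records


def ring_geometry(positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit normal of a ring via least-squares plane fit."""
    finite = np.isfinite(positions).all(axis=1)
    if finite.sum() < 3:
        from . import GeometryError
        raise GeometryError("ring has fewer than 3 finite atoms")
    pts = positions[finite]
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    return centroid, vt[2]


def pipi_frame(topology: Topology, frame: Frame,
               criteria: PiPiCriteria | None = None) -> list[InteractionRecord]:
    """All unordered ring pairs within the centroid/normal-angle criteria.

    Ring pairs within the same residue are skipped. The inter-normal angle
    is folded to [0, 90] deg so the result is independent of normal sign
    and of ring-pair ordering.
    """
    _check_annotated(topology)
    criteria = criteria or PiPiCriteria()
    pos = frame.positions
    geo = [ring_geometry(pos[np.array(ring)]) for ring in topology.rings]
    records: list[InteractionRecord] = []
    for i in range(len(topology.rings)):
        for j in range(i + 1, len(topology.rings)):
            res_i = topology.residue_of(topology.rings[i][0])
            res_j = topology.residue_of(topology.rings[j][0])
            if res_i == res_j:
                continue
            ci, ni = geo[i]
            cj, nj = geo[j]
            if np.linalg.norm(ci - cj) >= criteria.centroid_cutoff:
                continue
            cosang = abs(float(np.dot(ni, nj)))
            angle = math.degrees(math.acos(min(1.0, cosang)))
            if angle < criteria.normal_max_angle:
                records.append(InteractionRecord(frame_index=0, kind="pipi",
                                                 ring_a=i, ring_b=j))
    return records


def classify_partner(record: InteractionRecord, topology: Topology,
                     subject: set[ResidueKey]) -> str:
    """Partner class of a record relative to a subject residue set."""
    if record.kind == "hbond":
        res_a = topology.residue_of(record.donor)
        res_b = topology.residue_of(record.acceptor)
    else:
        res_a = topology.residue_of(topology.rings[record.ring_a][0])
        res_b = topology.residue_of(topology.rings[record.ring_b][0])
    in_a, in_b = res_a in subject, res_b in subject
    if in_a and in_b:
        return "intramolecular"
    partner = res_b if in_a else res_a
    mol = topology.molecule_class.get(partner, "protein")
    if mol in ("solvent", "ion"):
        return "solvent"
    if mol == "ligand":
        return "ligand"
    return "protein"


def _partner_residue(record: InteractionRecord, topology: Topology,
                     subject: set[ResidueKey]) -> ResidueKey:
    res_d = topology.residue_of(record.donor)
    res_a = topology.residue_of(record.acceptor)
    return res_a if res_d in subject else res_d


def is_salt_bridge(record: InteractionRecord, topology: Topology) -> bool:
    """Side-chain H-bond between oppositely charged residues."""
    if record.kind != "hbond":
        return False
    donor_atom = topology.atom(record.donor)
    acceptor_atom = topology.atom(record.acceptor)
    if donor_atom.name in BACKBONE_ATOMS or acceptor_atom.name in BACKBONE_ATOMS:
        return False
    cd = topology.charge_class.get(donor_atom.residue_key)
    ca = topology.charge_class.get(acceptor_atom.residue_key)
    return {cd, ca} == {"positive", "negative"}


def salt_bridge_percentage(mean_hbonds: float, mean_salt_bridges: float) -> int:
    """100 x salt-bridge mean / H-bond mean, reported as an integer.

    The integer is obtained by truncation (e.g. 78.57 -> 78, 72.33 -> 72),
    the convention consistent with the reference table rows this
    bookkeeping reproduces.
    """
    if mean_hbonds == 0:
        raise UsageError("salt-bridge percentage undefined: zero hydrogen bonds")
    return int(math.floor(100.0 * mean_salt_bridges / mean_hbonds + 1e-9))


def salt_bridge_filter(records: Iterable[InteractionRecord], topology: Topology
                       ) -> tuple[list[InteractionRecord], int | None]:
    """Subset of salt-bridge records plus their integer percentage.

    With zero input H-bonds the percentage is None (undefined, not zero).
    """
    records = list(records)
    subset = [r for r in records if is_salt_bridge(r, topology)]
    if not records:
        return subset, None
    return subset, salt_bridge_percentage(len(records), len(subset))


def summarize_interactions(trajectory: Trajectory,
                           criteria: HBondCriteria | None = None,
                           window: tuple[float | None, float | None] | None = None,
                           subject: set[ResidueKey] | None = None,
                           occupancy_threshold: float = 0.3,
                           kind: str = "hbond",
                           pipi_criteria: PiPiCriteria | None = None,
                           include_intra_residue: bool = True,
                           ) -> InteractionSummary:
    """Means, occupancies and lifetimes over an analysis window.

    ``subject`` selects the residues whose contacts are being summarised
    (default: ligand residues, falling back to all residues); records not
    touching the subject are ignored. Occupancy of a unique pair is the
    fraction of window frames in which it is present; the lifetime
    fraction is its longest contiguous run divided by the window length.
    """
    _check_annotated(trajectory.topology)
    traj = trajectory if window is None else trajectory.window(*window)
    if traj.n_frames == 0:
        raise UsageError("empty analysis window")
    topology: Topology = traj.topology
    if subject is None:
        subject = topology.residues_of_class("ligand") or set(topology.molecule_class)

    n = traj.n_frames
    class_counts: dict[str, float] = {}
    residue_counts: dict[ResidueKey, float] = {}
    presence: dict[tuple, np.ndarray] = {}
    total = 0
    sb_total = 0

    for fi, frame in enumerate(traj.frames):
        if kind == "hbond":
            recs = hbond_frame(topology, frame, criteria,
                               include_intra_residue=include_intra_residue)
        elif kind == "pipi":
            recs = pipi_frame(topology, frame, pipi_criteria)
        else:
            raise UsageError(f"unknown interaction kind {kind!r}")
        for r in recs:
            pclass = classify_partner(r, topology, subject)
            if r.kind == "hbond":
                touches = (topology.residue_of(r.donor) in subject
                           or topology.residue_of(r.acceptor) in subject)
            else:
                touches = (topology.residue_of(topology.rings[r.ring_a][0]) in subject
                           or topology.residue_of(topology.rings[r.ring_b][0]) in subject)
            if not touches:
                continue
            total += 1
            class_counts[pclass] = class_counts.get(pclass, 0) + 1
            if r.kind == "hbond":
                partner = _partner_residue(r, topology, subject)
                residue_counts[partner] = residue_counts.get(partner, 0) + 1
                if is_salt_bridge(r, topology):
                    sb_total += 1
            key = r.pair
            if key not in presence:
                presence[key] = np.zeros(n, dtype=bool)
            presence[key][fi] = True

    occupancy = {k: float(v.sum()) / n for k, v in presence.items()}
    lifetime = {k: _longest_run(v) / n for k, v in presence.items()}
    per_residue = {k: v / n for k, v in residue_counts.items()
                   if v / n > occupancy_threshold}

    mean_total = total / n
    mean_by_class = {k: v / n for k, v in class_counts.items()}
    sb_mean = sb_total / n if kind == "hbond" else None
    if kind == "hbond" and mean_total > 0:
        sb_pct: int | None = salt_bridge_percentage(mean_total, sb_mean)
        undefined = False
    else:
        sb_pct = None
        undefined = kind == "hbond"
    return InteractionSummary(
        n_frames=n, mean_total=mean_total, mean_by_class=mean_by_class,
        per_residue=per_residue, occupancy=occupancy, lifetime_fraction=lifetime,
        salt_bridge_mean=sb_mean, salt_bridge_percentage=sb_pct,
        salt_bridge_undefined=undefined, occupancy_threshold=occupancy_threshold)


def _longest_run(mask: np.ndarray) -> int:
    best = run = 0
    for v in mask:
        run = run + 1 if v else 0
        best = max(best, run)
    return best


def partner_split_total(sub_totals: dict[str, float]) -> float:
    """Total mean contact count from its per-class decomposition.

    The per-class means are a partition of the total, so the total is
    their sum (conservation).
    """
    return float(sum(sub_totals.values()))
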