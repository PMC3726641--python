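import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cleftscope import UsageError
from cleftscope import interactions as ia
from cleftscope import synthetic_data as syn
from cleftscope.model_io import AtomRecord, Frame, Structure, Topology


# ---------------------------------------------------------------------------
# independent brute-force oracle
# ---------------------------------------------------------------------------

def oracle_hbonds(topology, frame, criteria=None, include_intra_residue=False):
    """Exhaustive O(donors x acceptors) re-implementation used as ground truth."""
    criteria = criteria or ia.HBondCriteria()
    pos = frame.positions
    found = set()
    for heavy, hydrogen in topology.donors:
        for acc, klass in topology.acceptors.items():
            if acc in (heavy, hydrogen):
                continue
            if (topology.residue_of(acc) == topology.residue_of(heavy)
                    and not include_intra_residue):
                continue
            cutoff = (criteria.da_cutoff_sulphur if klass == "S"
                      else criteria.da_cutoff)
            da = math.dist(pos[heavy], pos[acc])
            if da >= cutoff:
                continue
            v1 = pos[heavy] - pos[hydrogen]
            v2 = pos[acc] - pos[hydrogen]
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
            if angle > criteria.dha_min_angle:
                found.add((heavy, hydrogen, acc))
    return found


def _random_hbond_topology(rng, n_donors=12, n_acceptors=18, with_sulphur=True):
    atoms = []
    donors = []
    acceptors = {}

    def add(name, element, resname, resi, pos):
        atoms.append(AtomRecord(atom_id=len(atoms), name=name, element=element,
                                residue_name=resname, residue_index=resi,
                                chain_id="A", position=pos))
        return atoms[-1].atom_id

    resi = 0
    for _ in range(n_donors):
        resi += 1
        heavy_pos = rng.uniform(0, 12, 3)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        heavy = add("N", "N", "GLY", resi, heavy_pos)
        hyd = add("H", "H", "GLY", resi, heavy_pos + direction)
        donors.append((heavy, hyd))
    for k in range(n_acceptors):
        resi += 1
        klass = "S" if with_sulphur and k % 5 == 0 else "ON"
        aid = add("SD" if klass == "S" else "O", "S" if klass == "S" else "O",
                  "MET" if klass == "S" else "HOH", resi, rng.uniform(0, 12, 3))
        acceptors[aid] = klass
    charge = {a.residue_key: "neutral" for a in atoms}
    molecule = {a.residue_key: "protein" for a in atoms}
    topo = Topology(atoms=atoms, donors=donors, acceptors=acceptors,
                    charge_class=charge, molecule_class=molecule)
    return topo


class TestHBondGeometry:
    def _one_bond_topology(self, acc_pos, acc_class="ON"):
        atoms = [
            AtomRecord(0, "N", "N", "GLY", 1, "A", np.array([0.0, 0.0, 0.0])),
            AtomRecord(1, "H", "H", "GLY", 1, "A", np.array([1.0, 0.0, 0.0])),
            AtomRecord(2, "SD" if acc_class == "S" else "O", "O", "MET", 2, "A",
                       np.array(acc_pos, dtype=float)),
        ]
        return Topology(atoms=atoms, donors=[(0, 1)], acceptors={2: acc_class},
                        charge_class={("A", 1): "neutral", ("A", 2): "neutral"},
                        molecule_class={("A", 1): "protein", ("A", 2): "protein"})

    def _frame(self, topo):
        return Frame(0.0, np.array([a.position for a in topo.atoms]))

    def test_linear_2p9_detected(self):
        topo = self._one_bond_topology([2.9, 0, 0])
        assert len(ia.hbond_frame(topo, self._frame(topo))) == 1

    def test_3p6_rejected(self):
        topo = self._one_bond_topology([3.6, 0, 0])
        assert ia.hbond_frame(topo, self._frame(topo)) == []

    def test_sulphur_cutoff_accepts_3p8(self):
        topo = self._one_bond_topology([3.8, 0, 0], acc_class="S")
        assert len(ia.hbond_frame(topo, self._frame(topo))) == 1
        topo_on = self._one_bond_topology([3.8, 0, 0], acc_class="ON")
        assert ia.hbond_frame(topo_on, self._frame(topo_on)) == []

    @pytest.mark.parametrize("angle,expected", [(119.0, 0), (121.0, 1)])
    def test_angle_threshold(self, angle, expected):
        # D-H-A angle just below / above the 120 deg cutoff
        a = np.array([1.0, 0.0, 0.0]) + 1.5 * np.array(
            [math.cos(math.radians(180.0 - angle)),
             math.sin(math.radians(180.0 - angle)), 0.0])
        topo = self._one_bond_topology(a)
        assert len(ia.hbond_frame(topo, self._frame(topo))) == expected

    def test_same_residue_excluded_by_default(self):
        atoms = [
            AtomRecord(0, "N", "N", "GLY", 1, "A", np.array([0.0, 0.0, 0.0])),
            AtomRecord(1, "H", "H", "GLY", 1, "A", np.array([1.0, 0.0, 0.0])),
            AtomRecord(2, "O", "O", "GLY", 1, "A", np.array([2.9, 0.0, 0.0])),
        ]
        topo = Topology(atoms=atoms, donors=[(0, 1)], acceptors={2: "ON"},
                        charge_class={("A", 1): "neutral"},
                        molecule_class={("A", 1): "protein"})
        f = Frame(0.0, np.array([a.position for a in atoms]))
        assert ia.hbond_frame(topo, f) == []
        assert len(ia.hbond_frame(topo, f, include_intra_residue=True)) == 1

    def test_unannotated_topology_usage_error(self):
        s = Structure(atoms=[AtomRecord(0, "N", "N", "GLY", 1, "A", np.zeros(3))])
        with pytest.raises(UsageError):
            ia.hbond_frame(s, Frame(0.0, np.zeros((1, 3))))

    def test_matches_oracle_on_random_frames(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            topo = _random_hbond_topology(rng)
            frame = Frame(0.0, topo.coords)
            got = {(r.donor, r.hydrogen, r.acceptor)
                   for r in ia.hbond_frame(topo, frame)}
            assert got == oracle_hbonds(topo, frame)

    @given(scale=st.floats(min_value=0.0, max_value=1.0),
           angle_relax=st.floats(min_value=0.0, max_value=60.0))
    @settings(max_examples=25, deadline=None)
    def test_criteria_monotonicity(self, scale, angle_relax):
        rng = np.random.default_rng(7)
        topo = _random_hbond_topology(rng, n_donors=6, n_acceptors=8)
        frame = Frame(0.0, topo.coords)
        base = ia.HBondCriteria()
        wider = ia.HBondCriteria(da_cutoff=base.da_cutoff + scale,
                                 da_cutoff_sulphur=base.da_cutoff_sulphur + scale,
                                 dha_min_angle=base.dha_min_angle - angle_relax)
        small = {(r.donor, r.hydrogen, r.acceptor)
                 for r in ia.hbond_frame(topo, frame, base)}
        large = {(r.donor, r.hydrogen, r.acceptor)
                 for r in ia.hbond_frame(topo, frame, wider)}
        assert small <= large


def _ring_pair_topology(offset, tilt_deg):
    """Two hexagons: one in the xy-plane, the other translated by `offset`
    and tilted by `tilt_deg` about the x-axis."""
    atoms = []

    def hexagon(center, rot=None):
        pts = []
        for k in range(6):
            a = math.radians(60 * k)
            p = np.array([1.39 * math.cos(a), 1.39 * math.sin(a), 0.0])
            if rot is not None:
                p = rot @ p
            pts.append(np.asarray(center) + p)
        return pts

    t = math.radians(tilt_deg)
    rot = np.array([[1, 0, 0],
                    [0, math.cos(t), -math.sin(t)],
                    [0, math.sin(t), math.cos(t)]])
    for i, p in enumerate(hexagon(np.zeros(3))):
        atoms.append(AtomRecord(i, f"C{i}", "C", "PHE", 1, "A", p))
    for i, p in enumerate(hexagon(np.asarray(offset), rot)):
        atoms.append(AtomRecord(6 + i, f"D{i}", "C", "PHE", 2, "A", p))
    topo = Topology(atoms=atoms, rings=[[0, 1, 2, 3, 4, 5], [6, 7, 8, 9, 10, 11]],
                    charge_class={("A", 1): "neutral", ("A", 2): "neutral"},
                    molecule_class={("A", 1): "protein", ("A", 2): "protein"})
    return topo, Frame(0.0, topo.coords)


class TestPiPi:
    def test_parallel_offset_3p5_detected(self):
        topo, f = _ring_pair_topology([0, 0, 3.5], 0.0)
        recs = ia.pipi_frame(topo, f)
        assert len(recs) == 1

    def test_perpendicular_rejected(self):
        topo, f = _ring_pair_topology([0, 0, 3.5], 90.0)
        assert ia.pipi_frame(topo, f) == []

    def test_parallel_5p2_rejected(self):
        topo, f = _ring_pair_topology([0, 0, 5.2], 0.0)
        assert ia.pipi_frame(topo, f) == []

    def test_angle_folding_beyond_90(self):
        # 150 deg tilt folds to 30 deg < 45 -> detected
        topo, f = _ring_pair_topology([0, 0, 3.5], 150.0)
        assert len(ia.pipi_frame(topo, f)) == 1

    def test_symmetric_in_ring_order(self):
        topo, f = _ring_pair_topology([0, 1.0, 3.3], 20.0)
        swapped = Topology(atoms=topo.atoms, rings=list(reversed(topo.rings)),
                           charge_class=topo.charge_class,
                           molecule_class=topo.molecule_class)
        assert bool(ia.pipi_frame(topo, f)) == bool(ia.pipi_frame(swapped, f))


class TestSummaries:
    def test_partner_class_means_sum_to_total(self, toy_complex):
        structure, topo = toy_complex
        wd = structure.atom_id("O", residue_name="HOH", residue_index=2)
        wh = structure.atom_id("H1", residue_name="HOH", residue_index=2)
        la = structure.atom_id("OB1", residue_name="EGX")
        gd = structure.atom_id("N", residue_name="GLY", residue_index=159)
        gh = structure.atom_id("H", residue_name="GLY", residue_index=159)
        lo = structure.atom_id("OA1", residue_name="EGX")
        plants = [
            syn.PlantedInteraction(kind="hbond", donor=wd, hydrogen=wh, acceptor=la,
                                   target_occupancy=0.7, episode_length=35),
            syn.PlantedInteraction(kind="hbond", donor=gd, hydrogen=gh, acceptor=lo,
                                   target_occupancy=0.4, episode_length=20),
        ]
        spec = syn.FixtureSpec(seed=3, n_frames=200, jitter_sigma=0.02)
        traj, _ = syn.plant_trajectory(spec, plants, complex=toy_complex)
        summ = ia.summarize_interactions(traj)  # subject defaults to the ligand
        assert sum(summ.mean_by_class.values()) == pytest.approx(summ.mean_total)
        assert summ.mean_by_class["solvent"] >= 0.7 - 1e-9
        assert summ.mean_by_class["protein"] >= 0.4 - 1e-9

    def test_lifetime_fraction_single_episode(self, toy_complex, planted_hbond_ids):
        spec = syn.FixtureSpec(seed=0, n_frames=1000, jitter_sigma=0.0)
        pi = syn.PlantedInteraction(kind="hbond", target_occupancy=0.08,
                                    episode_length=80, **planted_hbond_ids)
        traj, _ = syn.plant_trajectory(spec, [pi], complex=toy_complex)
        summ = ia.summarize_interactions(traj, subject=set(traj.topology.molecule_class))
        key = ("hbond", pi.donor, pi.hydrogen, pi.acceptor)
        assert summ.lifetime_fraction[key] == pytest.approx(0.08)

    def test_empty_window_is_usage_error(self, toy_complex, planted_hbond_ids):
        spec = syn.FixtureSpec(seed=0, n_frames=10)
        pi = syn.PlantedInteraction(kind="hbond", target_occupancy=1.0,
                                    episode_length=10, **planted_hbond_ids)
        traj, _ = syn.plant_trajectory(spec, [pi], complex=toy_complex)
        with pytest.raises(UsageError, match="empty"):
            ia.summarize_interactions(traj, window=(1e6, None))

    def test_occupancy_threshold_filters_per_residue(self, toy_complex,
                                                     planted_hbond_ids):
        spec = syn.FixtureSpec(seed=0, n_frames=100, jitter_sigma=0.0)
        pi = syn.PlantedInteraction(kind="hbond", target_occupancy=0.2,
                                    episode_length=20, **planted_hbond_ids)
        traj, _ = syn.plant_trajectory(spec, [pi], complex=toy_complex)
        subject = {traj.topology.residue_of(pi.donor)}
        low = ia.summarize_interactions(traj, subject=subject, occupancy_threshold=0.1)
        high = ia.summarize_interactions(traj, subject=subject, occupancy_threshold=0.3)
        acc_res = traj.topology.residue_of(pi.acceptor)
        assert acc_res in low.per_residue
        assert acc_res not in high.per_residue


class TestSaltBridges:
    def test_printed_percentages(self):
        assert ia.salt_bridge_percentage(11.2, 8.8) == 78
        assert ia.salt_bridge_percentage(15.9, 11.5) == 72

    def test_zero_hbonds_flagged_not_zero(self):
        with pytest.raises(UsageError, match="undefined"):
            ia.salt_bridge_percentage(0.0, 0.0)

    def test_filter_keeps_only_opposite_charges(self, toy_complex, planted_hbond_ids):
        structure, topo = toy_complex
        spec = syn.FixtureSpec(seed=0, n_frames=5, jitter_sigma=0.0)
        pi = syn.PlantedInteraction(kind="saltbridge", target_occupancy=1.0,
                                    episode_length=5, **planted_hbond_ids)
        traj, _ = syn.plant_trajectory(spec, [pi], complex=toy_complex)
        recs = ia.hbond_frame(topo, traj.frames[0], include_intra_residue=True)
        subset, pct = ia.salt_bridge_filter(recs, topo)
        assert all(ia.is_salt_bridge(r, topo) for r in subset)
        assert any(r.donor == pi.donor and r.acceptor == pi.acceptor for r in subset)
        assert pct is not None

    def test_backbone_atoms_never_salt_bridge(self, toy_complex):
        structure, topo = toy_complex
        # GLY159 backbone N-H donor to GLU OE2: opposite charges are not
        # enough, the donor must be a side-chain atom
        rec = ia.InteractionRecord(
            frame_index=0, kind="hbond",
            donor=structure.atom_id("N", residue_name="GLY", residue_index=159),
            hydrogen=structure.atom_id("H", residue_name="GLY", residue_index=159),
            acceptor=structure.atom_id("OE2", residue_name="GLU"))
        assert not ia.is_salt_bridge(rec, topo)

    def test_no_charged_partner_no_bridges(self, toy_complex):
        structure, topo = toy_complex
        rec = ia.InteractionRecord(
            frame_index=0, kind="hbond",
            donor=structure.atom_id("O", residue_name="HOH", residue_index=1),
            hydrogen=structure.atom_id("H1", residue_name="HOH", residue_index=1),
            acceptor=structure.atom_id("OB1", residue_name="EGX"))
        subset, _ = ia.salt_bridge_filter([rec], topo)
        assert subset == []


class TestPartnerSplit:
    def test_total_is_sum_of_subtotals(self):
        assert ia.partner_split_total({"solvent": 12.5, "protein": 3.9}) == \
            pytest.approx(16.4)
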