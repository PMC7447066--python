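"""Contact operators: criteria, protonation awareness, partitions, oracles."""

import numpy as np
import pytest

from psitraj.core import assign_protonation
from psitraj.contacts import (
    CONTACT_CUTOFF,
    HB_DISTANCE_CUTOFF,
    HYDROGEN_BOND_LENGTH,
    SIDECHAIN_ACCEPTORS,
    SIDECHAIN_DONORS,
    BACKBONE_SET,
    cation_pi_screen,
    hydrogen_bonds,
    hydrophobic_contacts,
    partition_pair,
    partition_and_summarize,
    salt_bridges,
)
from psitraj.synthetic import SIDECHAIN_OFFSETS

from conftest import toy_topology, toy_trajectory


def hb_toy(d, angle_deg, with_h=True):
    """Donor N (res 1) vs acceptor O (res 5) at distance d; H at angle_deg."""
    entries = [("A", 1, "GLY", "N")]
    if with_h:
        entries.append(("A", 1, "GLY", "H1", "H"))
    entries.append(("A", 5, "GLY", "O"))
    top = toy_topology(entries)
    theta = np.deg2rad(angle_deg)
    coords = [[0.0, 0.0, 0.0]]
    if with_h:
        coords.append([0.1 * np.cos(theta), 0.1 * np.sin(theta), 0.0])
    coords.append([d, 0.0, 0.0])
    return np.array(coords), top


class TestHydrogenBonds:
    @pytest.mark.parametrize(
        "d,angle,expected",
        [(0.34, 10.0, 1), (0.36, 10.0, 0), (0.34, 40.0, 0)],
    )
    def test_distance_and_angle_criteria(self, d, angle, expected):
        coords, top = hb_toy(d, angle)
        assert len(hydrogen_bonds(coords, top)) == expected

    def test_idealized_hydrogen_when_absent(self):
        """Without explicit H the angle test passes by idealized placement."""
        coords, top = hb_toy(0.34, 0.0, with_h=False)
        assert len(hydrogen_bonds(coords, top)) == 1

    def test_sequence_adjacent_pairs_excluded(self):
        top = toy_topology([("A", 1, "GLY", "N"), ("A", 2, "GLY", "O")])
        coords = np.array([[0.0, 0, 0], [0.3, 0, 0]])
        assert hydrogen_bonds(coords, top) == set()


class TestHydrophobicContacts:
    def hi_toy(self, res2_name, d):
        top = toy_topology(
            [("A", 1, "LEU", "CB"), ("A", 5, res2_name, "CB")]
        )
        coords = np.array([[0.0, 0, 0], [d, 0, 0]])
        return coords, top

    def test_within_cutoff_counted(self):
        coords, top = self.hi_toy("ILE", 0.44)
        assert hydrophobic_contacts(coords, top) == {(("A", 1), ("A", 5))}

    def test_lysine_never_counts(self):
        """The aliphatic part of amphipathic sidechains is not hydrophobic."""
        coords, top = self.hi_toy("LYS", 0.30)
        assert hydrophobic_contacts(coords, top) == set()

    def test_beyond_cutoff_not_counted(self):
        coords, top = self.hi_toy("ILE", 0.46)
        assert hydrophobic_contacts(coords, top) == set()


def sb_toy():
    """Glu-1 carboxylate 0.44 nm from Lys-5 NZ (single chain)."""
    top = toy_topology(
        [("A", 1, "GLU", "OE1"), ("A", 1, "GLU", "OE2"), ("A", 5, "LYS", "NZ")]
    )
    coords = np.array([[0.0, 0, 0], [0.05, 0.1, 0], [0.44, 0, 0]])
    return coords, top


class TestSaltBridges:
    def test_counted_at_neutral_ph(self):
        coords, top = sb_toy()
        pm = assign_protonation(top, 7.4)
        assert salt_bridges(coords, top, pm) == {(("A", 1), ("A", 5))}

    def test_protonated_carboxylate_cannot_bridge(self):
        """Identical geometry at pH 3.0: the neutral Glu forms no bridge."""
        coords, top = sb_toy()
        pm = assign_protonation(top, 3.0)
        assert salt_bridges(coords, top, pm) == set()

    def test_histidine_omitted_at_neutral_ph(self):
        top = toy_topology(
            [("A", 1, "ASP", "OD1"), ("A", 1, "ASP", "OD2"),
             ("A", 5, "HIS", "ND1"), ("A", 5, "HIS", "NE2"), ("A", 5, "HIS", "CE1")]
        )
        coords = np.array(
            [[0, 0, 0], [0.05, 0.1, 0], [0.3, 0, 0], [0.35, 0.05, 0], [0.32, -0.05, 0]]
        )
        pm = assign_protonation(top, 7.4)
        assert salt_bridges(coords, top, pm) == set()
        # at pH 3.0 His is charged, and with the acid forced deprotonated the
        # same geometry does bridge
        pm3 = assign_protonation(top, 3.0, overrides={"Asp1": "deprotonated"})
        assert salt_bridges(coords, top, pm3) == {(("A", 1), ("A", 5))}

    def test_missing_site_atom_names_residue(self):
        top = toy_topology(
            [("A", 1, "GLU", "OE1"), ("A", 1, "GLU", "OE2"), ("A", 5, "LYS", "CB")]
        )
        pm = assign_protonation(top, 7.4)
        with pytest.raises(KeyError, match="NZ.*LYS5"):
            salt_bridges(np.zeros((3, 3)), top, pm)

    def test_ph_monotonicity_on_identical_geometry(self, dimer_trajectory):
        """pH 3.0 neutralizes a superset of acidics: SB count never exceeds pH 7.4."""
        top = dimer_trajectory.topology
        pm3 = assign_protonation(top, 3.0)
        pm7 = assign_protonation(top, 7.4)
        for f in range(0, dimer_trajectory.n_frames, 10):
            frame = dimer_trajectory.coords[f]
            sb3 = {p for p in salt_bridges(frame, top, pm3)}
            sb7 = {p for p in salt_bridges(frame, top, pm7)}
            assert len(sb3) <= len(sb7)


class TestCationPi:
    def cp_toy(self, d):
        ring = [("A", 5, "PHE", nm) for nm, _ in SIDECHAIN_OFFSETS["PHE"]]
        top = toy_topology([("A", 1, "LYS", "NZ")] + ring)
        centroid = np.array([d, 0.0, 0.0])
        ring_coords = [
            centroid + np.array([0.07 * np.cos(k * np.pi / 3), 0.07 * np.sin(k * np.pi / 3), 0])
            for k in range(6)
        ]
        coords = np.vstack([[0.0, 0.0, 0.0]] + ring_coords)
        return coords, top

    def test_candidate_within_cutoff(self):
        coords, top = self.cp_toy(0.55)
        pm = assign_protonation(top, 7.4)
        assert cation_pi_screen(coords, top, pm) == {(("A", 1), ("A", 5))}

    def test_not_candidate_beyond_cutoff(self):
        coords, top = self.cp_toy(0.65)
        pm = assign_protonation(top, 7.4)
        assert cation_pi_screen(coords, top, pm) == set()

    def test_no_aromatics_empty(self):
        top = toy_topology([("A", 1, "LYS", "NZ")])
        pm = assign_protonation(top, 7.4)
        assert cation_pi_screen(np.zeros((1, 3)), top, pm) == set()


class TestPartitions:
    LOOP = (40, 63)

    @pytest.mark.parametrize(
        "pair,part,loop_cat",
        [
            ((("A", 45), ("A", 50)), "intra-A", "intra-loop"),
            ((("A", 45), ("B", 80)), "inter", "loop-nonloop"),
            ((("A", 45), ("A", 80)), "intra-A", "loop-nonloop"),
            ((("B", 10), ("B", 80)), "intra-B", None),
            ((("A", 10), ("B", 80)), "inter", None),
        ],
    )
    def test_partition_assignment(self, pair, part, loop_cat):
        assert partition_pair(pair, self.LOOP) == (part, loop_cat)

    def test_partitions_are_exhaustive_and_disjoint(self):
        rng = np.random.default_rng(21)
        for _ in range(300):
            chains = rng.choice(["A", "B"], size=2)
            resids = rng.integers(1, 105, size=2)
            if (chains[0], resids[0]) == (chains[1], resids[1]):
                continue
            pair = tuple(sorted(zip(chains, map(int, resids))))
            part, loop_cat = partition_pair(pair, self.LOOP)
            assert part in ("intra-A", "intra-B", "inter")
            assert loop_cat in ("intra-loop", "loop-nonloop", None)

    def test_summary_pools_chains_and_replicates(self):
        frames_rep = [
            [{"HI": {(("A", 45), ("A", 50)), (("A", 10), ("B", 80))}}],
            [{"HI": {(("B", 45), ("B", 50))}}],
        ]
        census = partition_and_summarize(frames_rep, _dimer_topology())
        mean, _ = census.value("HI", "intra")
        # 4 pooled chain-frames (2 reps x 2 chains) hold 2 intra contacts
        assert mean == pytest.approx(0.5)
        inter_mean, _ = census.value("HI", "inter")
        assert inter_mean == pytest.approx(0.5)
        row = census.summary
        assert set(row[row["partition"] == "intra"]["n"]) == {4}
        assert set(row[row["partition"] == "inter"]["n"]) == {2}


def _dimer_topology():
    from psitraj.synthetic import SyntheticSpec, make_topology

    return make_topology(SyntheticSpec())


# ---------------------------------------------------------------------------
# brute-force oracle equivalence on random small systems


RESIDUE_POOL = ["GLY", "ALA", "LEU", "ILE", "LYS", "GLU", "ASP", "HIS", "PHE", "SER", "ARG"]


def random_system(rng):
    n_res = int(rng.integers(3, 7))
    entries = []
    for i in range(1, n_res + 1):
        resname = str(rng.choice(RESIDUE_POOL))
        entries.append(("A", i, resname, "N"))
        entries.append(("A", i, resname, "CA"))
        entries.append(("A", i, resname, "O"))
        if resname != "GLY":
            entries.append(("A", i, resname, "CB"))
        for nm, _ in SIDECHAIN_OFFSETS[resname]:
            entries.append(("A", i, resname, nm))
    top = toy_topology(entries)
    coords = rng.uniform(0.0, 1.2, size=(top.n_atoms, 3))
    return coords, top


def oracle_hydrophobic(coords, top, cutoff=CONTACT_CUTOFF):
    out = set()
    chain, resid = top.atom_chain(), top.atom_resid()
    resname = [top.residues[ri].name for ri in top.atom_resindex]
    n = top.n_atoms
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if resname[i] not in top.hydrophobic_set or resname[j] not in top.hydrophobic_set:
                continue
            if top.atom_names[i] in BACKBONE_SET or top.atom_names[j] in BACKBONE_SET:
                continue
            a, b = (chain[i], int(resid[i])), (chain[j], int(resid[j]))
            if a == b or (a[0] == b[0] and abs(a[1] - b[1]) < 2):
                continue
            if np.linalg.norm(coords[i] - coords[j]) <= cutoff:
                out.add(tuple(sorted((a, b))))
    return out


def oracle_hbonds(coords, top, cutoff=HB_DISTANCE_CUTOFF):
    out = set()
    chain, resid = top.atom_chain(), top.atom_resid()
    resname = [top.residues[ri].name for ri in top.atom_resindex]
    n = top.n_atoms
    for i in range(n):
        is_donor = (top.atom_names[i] == "N" and resname[i] != "PRO") or (
            top.atom_names[i] in SIDECHAIN_DONORS.get(resname[i], ())
        )
        if not is_donor:
            continue
        for j in range(n):
            is_acc = top.atom_names[j] == "O" or (
                top.atom_names[j] in SIDECHAIN_ACCEPTORS.get(resname[j], ())
            )
            if not is_acc or top.atom_resindex[i] == top.atom_resindex[j]:
                continue
            a, b = (chain[i], int(resid[i])), (chain[j], int(resid[j]))
            if a[0] == b[0] and abs(a[1] - b[1]) < 2:
                continue
            if np.linalg.norm(coords[i] - coords[j]) <= cutoff:
                out.add(tuple(sorted((a, b))))  # no explicit H: angle idealized
    return out


def oracle_salt_bridges(coords, top, pm, cutoff=CONTACT_CUTOFF):
    from psitraj.contacts import ACIDIC_OXYGENS, BASIC_SITES

    table = top.atom_table()
    out = set()
    for ra in top.residues:
        if ra.name not in ACIDIC_OXYGENS or not pm.is_charged(ra.chain, ra.index):
            continue
        for rb in top.residues:
            if rb.name not in BASIC_SITES:
                continue
            if rb.name == "HIS" and pm.ph == 7.4:
                continue
            if not pm.is_charged(rb.chain, rb.index):
                continue
            if (ra.chain, ra.index) == (rb.chain, rb.index):
                continue
            if ra.chain == rb.chain and abs(ra.index - rb.index) < 2:
                continue
            pts = np.array([coords[table[(rb.chain, rb.index, nm)]] for nm in BASIC_SITES[rb.name]])
            ms = np.array([top.atom_masses[table[(rb.chain, rb.index, nm)]] for nm in BASIC_SITES[rb.name]])
            site = (pts * ms[:, None]).sum(axis=0) / ms.sum()
            dmin = min(
                np.linalg.norm(coords[table[(ra.chain, ra.index, nm)]] - site)
                for nm in ACIDIC_OXYGENS[ra.name]
            )
            if dmin <= cutoff:
                out.add(tuple(sorted(((ra.chain, ra.index), (rb.chain, rb.index)))))
    return out


class TestOracleEquivalence:
    def test_contact_operators_match_brute_force(self):
        """All contact operators agree with the all-pairs oracle on 100
        random small systems."""
        rng = np.random.default_rng(99)
        for _ in range(100):
            coords, top = random_system(rng)
            assert top.n_atoms <= 50
            pm = assign_protonation(top, 7.4)
            assert hydrophobic_contacts(coords, top) == oracle_hydrophobic(coords, top)
            assert hydrogen_bonds(coords, top) == oracle_hbonds(coords, top)
            assert salt_bridges(coords, top, pm) == oracle_salt_bridges(coords, top, pm)
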