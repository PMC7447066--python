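"""Hydrogen-bond, hydrophobic, salt-bridge and cation-pi contact censuses.

Contacts are counted at residue-pair granularity: a residue pair inside the
geometric criterion in a frame counts once for that frame, however many
atom pairs qualify.  Sequence-adjacent pairs (|i - j| < 2 on the same
chain) are excluded from all censuses so covalent neighbours never pollute
the counts.

Criteria
--------
* hydrogen bond: donor(N/O with H)-acceptor(N/O) distance <= 0.35 nm and
  H-donor-acceptor angle <= 30 deg.  When the topology carries no explicit
  hydrogens an idealized H is placed along the donor->acceptor axis (the
  angle test then always passes); results flag this approximation.
* hydrophobic: minimum sidechain heavy-atom distance <= 0.45 nm, both
  residues in the wholly-hydrophobic set (default Ala/Val/Leu/Ile/Pro/
  Phe/Met/Trp — amphipathic sidechains such as Lys are never counted).
* salt bridge: minimum distance <= 0.45 nm between a deprotonated acidic
  sidechain oxygen and the basic nitrogen site (Lys NZ; Arg centre of mass
  of NE/NH1/NH2; His centre of mass of ND1/NE2/CE1).  His is omitted
  entirely at pH 7.4.
* cation-pi screen: cation site within 0.6 nm of an aromatic ring centroid;
  candidates are reported separately and never merged into census totals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core import ProtonationMap, Topology, Trajectory

__all__ = [
    "ContactRule",
    "ContactCensus",
    "hydrogen_bonds",
    "hydrophobic_contacts",
    "salt_bridges",
    "cation_pi_screen",
    "contact_census",
    "partition_pair",
    "partition_and_summarize",
]

HB_DISTANCE_CUTOFF = 0.35   # nm, donor-acceptor
HB_ANGLE_CUTOFF = 30.0      # deg, H-donor-acceptor
CONTACT_CUTOFF = 0.45       # nm, hydrophobic + salt bridge minimum distance
CATION_PI_CUTOFF = 0.6      # nm, cation to ring centroid
HYDROGEN_BOND_LENGTH = 0.12  # nm, max D-H covalent distance for H association

BACKBONE_SET = {"N", "CA", "C", "O"}

# Sidechain donor atoms (N/O that carry hydrogens) by residue name; the
# backbone amide N is a donor for every residue except proline.
SIDECHAIN_DONORS = {
    "LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"}, "HIS": {"ND1", "NE2"},
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "ASN": {"ND2"}, "GLN": {"NE2"}, "TRP": {"NE1"},
}
# Sidechain acceptor atoms by residue name; the backbone carbonyl O is an
# acceptor for every residue.
SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"}, "GLN": {"OE1"},
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "HIS": {"ND1", "NE2"},
}

ACIDIC_OXYGENS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASIC_SITES = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2", "CE1"),
}
AROMATIC_RINGS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
}

PairKey = tuple[tuple[str, int], tuple[str, int]]


@dataclass(frozen=True)
class ContactRule:
    """Geometric criterion for one contact kind."""

    kind: str                       # "HB" | "HI" | "SB" | "cation-pi"
    distance_cutoff: float
    angle_cutoff: float | None = None

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0:
            raise ValueError("distance cutoff must be positive")
        if self.angle_cutoff is not None and self.angle_cutoff <= 0:
            raise ValueError("angle cutoff must be positive")


def _pair_key(chain_a: str, res_a: int, chain_b: str, res_b: int) -> PairKey:
    a, b = (chain_a, res_a), (chain_b, res_b)
    return (a, b) if a <= b else (b, a)


def _sequence_adjacent(key: PairKey) -> bool:
    (ca, ra), (cb, rb) = key
    return ca == cb and abs(ra - rb) < 2


# ---------------------------------------------------------------------------
# contact operators (single frame)


def hydrogen_bonds(
    coords: np.ndarray,
    topology: Topology,
    distance_cutoff: float = HB_DISTANCE_CUTOFF,
    angle_cutoff: float = HB_ANGLE_CUTOFF,
) -> set[PairKey]:
    """Residue pairs linked by at least one hydrogen bond in this frame."""
    names = topology.atom_names
    chain = topology.atom_chain()
    resid = topology.atom_resid()
    resname = np.array(
        [topology.residues[ri].name for ri in topology.atom_resindex], dtype=object
    )

    donor_idx, acceptor_idx = [], []
    for i in range(topology.n_atoms):
        nm, rn = names[i], resname[i]
        if nm == "N" and rn != "PRO":
            donor_idx.append(i)
        elif nm in SIDECHAIN_DONORS.get(rn, ()):
            donor_idx.append(i)
        if nm == "O":
            acceptor_idx.append(i)
        elif nm in SIDECHAIN_ACCEPTORS.get(rn, ()):
            acceptor_idx.append(i)
    if not donor_idx or not acceptor_idx:
        return set()
    donor_idx = np.array(donor_idx)
    acceptor_idx = np.array(acceptor_idx)

    # Explicit hydrogens, associated to their donor geometrically.
    h_idx = np.nonzero(topology.atom_elements == "H")[0]
    donor_h: dict[int, list[int]] = {}
    for d in donor_idx:
        if len(h_idx):
            same_res = h_idx[topology.atom_resindex[h_idx] == topology.atom_resindex[d]]
            if len(same_res):
                dd = np.linalg.norm(coords[same_res] - coords[d], axis=1)
                donor_h[d] = list(same_res[dd <= HYDROGEN_BOND_LENGTH])

    dist = cdist(coords[donor_idx], coords[acceptor_idx])
    out: set[PairKey] = set()
    cos_cut = np.cos(np.deg2rad(angle_cutoff))
    for di, ai in zip(*np.nonzero(dist <= distance_cutoff)):
        d, a = donor_idx[di], acceptor_idx[ai]
        if topology.atom_resindex[d] == topology.atom_resindex[a]:
            continue
        key = _pair_key(chain[d], resid[d], chain[a], resid[a])
        if _sequence_adjacent(key) or key in out:
            continue
        hs = donor_h.get(d)
        if hs:
            v_da = coords[a] - coords[d]
            ok = False
            for h in hs:
                v_dh = coords[h] - coords[d]
                denom = np.linalg.norm(v_dh) * np.linalg.norm(v_da)
                if denom > 0 and np.dot(v_dh, v_da) / denom >= cos_cut:
                    ok = True
                    break
            if not ok:
                continue
        # no explicit H: idealized placement along D->A, angle 0 -> passes
        out.add(key)
    return out


def hydrophobic_contacts(
    coords: np.ndarray,
    topology: Topology,
    cutoff: float = CONTACT_CUTOFF,
    hydrophobic_set: frozenset[str] | None = None,
) -> set[PairKey]:
    """Residue pairs of wholly-hydrophobic sidechains within minimum distance."""
    hset = hydrophobic_set if hydrophobic_set is not None else topology.hydrophobic_set
    resname = np.array(
        [topology.residues[ri].name for ri in topology.atom_resindex], dtype=object
    )
    mask = np.array(
        [
            resname[i] in hset
            and topology.atom_names[i] not in BACKBONE_SET
            and topology.atom_elements[i] != "H"
            for i in range(topology.n_atoms)
        ]
    )
    idx = np.nonzero(mask)[0]
    if len(idx) == 0:
        return set()
    chain = topology.atom_chain()[idx]
    resid = topology.atom_resid()[idx]
    dist = cdist(coords[idx], coords[idx])
    out: set[PairKey] = set()
    for i, j in zip(*np.nonzero(dist <= cutoff)):
        if i >= j:
            continue
        if chain[i] == chain[j] and resid[i] == resid[j]:
            continue
        key = _pair_key(chain[i], resid[i], chain[j], resid[j])
        if not _sequence_adjacent(key):
            out.add(key)
    return out


def _basic_sites(
    coords: np.ndarray, topology: Topology, protonation: ProtonationMap
) -> list[tuple[str, int, np.ndarray]]:
    """Charged basic-residue interaction sites (chain, resid, point)."""
    table = topology.atom_table()
    sites = []
    for r in topology.residues:
        if r.name not in BASIC_SITES:
            continue
        if r.name == "HIS" and protonation.ph == 7.4:
            continue  # His omitted entirely from the census at neutral pH
        if not protonation.is_charged(r.chain, r.index):
            continue
        pts, ms = [], []
        for nm in BASIC_SITES[r.name]:
            key = (r.chain, r.index, nm)
            if key not in table:
                raise KeyError(f"missing atom {nm!r} in residue {r.label}")
            i = table[key]
            pts.append(coords[i])
            ms.append(topology.atom_masses[i])
        pts, ms = np.array(pts), np.array(ms)
        site = (pts * ms[:, None]).sum(axis=0) / ms.sum()
        sites.append((r.chain, r.index, site))
    return sites


def salt_bridges(
    coords: np.ndarray,
    topology: Topology,
    protonation: ProtonationMap,
    cutoff: float = CONTACT_CUTOFF,
) -> set[PairKey]:
    """Acidic-O to basic-N-site pairs within cutoff, protonation-aware.

    Acidic residues contribute their sidechain oxygens only when
    deprotonated (charged); basic residues contribute the per-residue
    nitrogen site.  Missing named atoms raise KeyError naming the residue.
    """
    table = topology.atom_table()
    acid_pts, acid_ids = [], []
    for r in topology.residues:
        if r.name not in ACIDIC_OXYGENS:
            continue
        if not protonation.is_charged(r.chain, r.index):
            continue  # protonated carboxylate: no salt bridge possible
        for nm in ACIDIC_OXYGENS[r.name]:
            key = (r.chain, r.index, nm)
            if key not in table:
                raise KeyError(f"missing atom {nm!r} in residue {r.label}")
            acid_pts.append(coords[table[key]])
            acid_ids.append((r.chain, r.index))
    basics = _basic_sites(coords, topology, protonation)
    if not acid_pts or not basics:
        return set()
    acid_pts = np.array(acid_pts)
    out: set[PairKey] = set()
    for chain_b, resid_b, site in basics:
        d = np.linalg.norm(acid_pts - site, axis=1)
        for k in np.nonzero(d <= cutoff)[0]:
            chain_a, resid_a = acid_ids[k]
            if (chain_a, resid_a) == (chain_b, resid_b):
                continue
            key = _pair_key(chain_a, resid_a, chain_b, resid_b)
            if not _sequence_adjacent(key):
                out.add(key)
    return out


def cation_pi_screen(
    coords: np.ndarray,
    topology: Topology,
    protonation: ProtonationMap,
    cutoff: float = CATION_PI_CUTOFF,
) -> set[PairKey]:
    """Candidate cation-aromatic pairs (advisory; never merged into totals)."""
    table = topology.atom_table()
    rings = []
    for r in topology.residues:
        if r.name not in AROMATIC_RINGS:
            continue
        pts = [
            coords[table[(r.chain, r.index, nm)]]
            for nm in AROMATIC_RINGS[r.name]
            if (r.chain, r.index, nm) in table
        ]
        if len(pts) >= 3:
            rings.append((r.chain, r.index, np.mean(pts, axis=0)))
    if not rings:
        return set()
    out: set[PairKey] = set()
    for chain_c, resid_c, site in _basic_sites(coords, topology, protonation):
        for chain_r, resid_r, centroid in rings:
            if (chain_c, resid_c) == (chain_r, resid_r):
                continue
            if np.linalg.norm(site - centroid) <= cutoff:
                key = _pair_key(chain_c, resid_c, chain_r, resid_r)
                if not _sequence_adjacent(key):
                    out.add(key)
    return out


# ---------------------------------------------------------------------------
# census over a trajectory + partitioning


def contact_census(
    traj: Trajectory,
    protonation: ProtonationMap,
    kinds: Iterable[str] = ("HB", "HI", "SB"),
) -> list[dict[str, set[PairKey]]]:
    """Per-frame contact pairs by kind over all frames of ``traj``."""
    out = []
    for fi in range(traj.n_frames):
        frame = traj.coords[fi]
        entry: dict[str, set[PairKey]] = {}
        for kind in kinds:
            if kind == "HB":
                entry[kind] = hydrogen_bonds(frame, traj.topology)
            elif kind == "HI":
                entry[kind] = hydrophobic_contacts(frame, traj.topology)
            elif kind == "SB":
                entry[kind] = salt_bridges(frame, traj.topology, protonation)
            elif kind == "cation-pi":
                entry[kind] = cation_pi_screen(frame, traj.topology, protonation)
            else:
                raise ValueError(f"unknown contact kind {kind!r}")
        out.append(entry)
    return out


def partition_pair(key: PairKey, loop_span: tuple[int, int]) -> tuple[str, str | None]:
    """(monomer partition, loop category) for one residue pair.

    Monomer partition is exactly one of intra-A / intra-B / inter.  Loop
    category is intra-loop (both residues in the loop, same chain),
    loop-nonloop (exactly one residue in the loop, attributed to the loop
    residue's chain), or None.
    """
    (ca, ra), (cb, rb) = key
    lo, hi = loop_span
    in_a, in_b = lo <= ra <= hi, lo <= rb <= hi
    part = f"intra-{ca}" if ca == cb else "inter"
    if in_a and in_b and ca == cb:
        loop_cat = "intra-loop"
    elif in_a ^ in_b:
        loop_cat = "loop-nonloop"
    else:
        loop_cat = None
    return part, loop_cat


@dataclass
class ContactCensus:
    """Pooled frame-level contact counts by kind and partition."""

    summary: pd.DataFrame   # kind, partition, mean, sd, n, n_frames_pooled

    def value(self, kind: str, partition: str) -> tuple[float, float]:
        row = self.summary[
            (self.summary["kind"] == kind) & (self.summary["partition"] == partition)
        ]
        if row.empty:
            raise KeyError(f"no census entry for ({kind}, {partition})")
        return float(row["mean"].iloc[0]), float(row["sd"].iloc[0])


def partition_and_summarize(
    per_replicate_frames: list[list[dict[str, set[PairKey]]]],
    topology: Topology,
) -> ContactCensus:
    """Partitioned, pooled contact census across replicates.

    Input is one per-frame contact record per replicate (the analysis
    window should already be applied).  Frame-level counts are pooled into
    one data set per (kind, partition): intra-monomer and loop categories
    pool both chains across replicates (n = 2 x replicates), inter-monomer
    pools replicates only (n = replicates).  Mean and population SD of the
    pooled frame counts are reported.
    """
    if not per_replicate_frames:
        raise ValueError("no replicates")
    loop = topology.loop_span
    kinds = sorted({k for rep in per_replicate_frames for fr in rep for k in fr})
    pooled: dict[tuple[str, str], list[int]] = {}
    n_series: dict[tuple[str, str], int] = {}
    n_rep = len(per_replicate_frames)

    for kind in kinds:
        for rep in per_replicate_frames:
            per_chain_counts = {"A": [], "B": []}
            inter_counts = []
            loop_counts = {("A", "intra-loop"): [], ("B", "intra-loop"): [],
                           ("A", "loop-nonloop"): [], ("B", "loop-nonloop"): []}
            for fr in rep:
                tallies = {"intra-A": 0, "intra-B": 0, "inter": 0}
                loop_tallies = {k: 0 for k in loop_counts}
                for key in fr.get(kind, ()):
                    part, loop_cat = partition_pair(key, loop)
                    tallies[part] += 1
                    if loop_cat is not None:
                        loop_chain = _loop_chain(key, loop)
                        loop_tallies[(loop_chain, loop_cat)] += 1
                per_chain_counts["A"].append(tallies["intra-A"])
                per_chain_counts["B"].append(tallies["intra-B"])
                inter_counts.append(tallies["inter"])
                for k, v in loop_tallies.items():
                    loop_counts[k].append(v)
            pooled.setdefault((kind, "intra"), []).extend(
                per_chain_counts["A"] + per_chain_counts["B"]
            )
            pooled.setdefault((kind, "inter"), []).extend(inter_counts)
            for cat in ("intra-loop", "loop-nonloop"):
                pooled.setdefault((kind, cat), []).extend(
                    loop_counts[("A", cat)] + loop_counts[("B", cat)]
                )
    rows = []
    for (kind, partition), counts in pooled.items():
        arr = np.array(counts, dtype=float)
        n = n_rep if partition == "inter" else 2 * n_rep
        rows.append(
            {
                "kind": kind,
                "partition": partition,
                "mean": arr.mean(),
                "sd": arr.std(ddof=0),
                "n": n,
                "n_frames_pooled": len(arr),
            }
        )
    return ContactCensus(summary=pd.DataFrame(rows))


def _loop_chain(key: PairKey, loop_span: tuple[int, int]) -> str:
    """Chain to which a loop-involving pair is attributed (the loop residue's)."""
    (ca, ra), (cb, rb) = key
    lo, hi = loop_span
    if lo <= ra <= hi:
        return ca
    return cb
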