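"""Synthetic dimer trajectories and DSSP series with known ground truth.

Every analysis stage in this package is exercised against ensembles whose
true parameters are planted by construction: per-residue fluctuation
amplitudes, S-gamma pair-distance laws, Markov secondary-structure
switching rates, and contact geometries.  The generator emulates the
study system — a two-chain, 104-residue-per-chain saposin-fold dimer with
cysteines at 6/31/37/68/71/99 and a disordered loop at residues 40-63 —
without being a physical simulator: no forces, no solvent, fixtures only.

Geometry is a coarse pseudo-atom representation: full backbone (N, CA, C,
O) on an idealized helical path (0.15 nm rise, 100 deg/residue twist) and
minimal sidechains carrying exactly the atoms the analyses name (SG on
Cys, NZ on Lys, guanidinium nitrogens on Arg, ring atoms on aromatics,
carboxyl oxygens on Asp/Glu, ...).  The two chains face each other across
the dimer interface with sidechains pointing inward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    NATIVE_CYS_PAIRS,
    ONE_TO_THREE,
    Residue,
    Topology,
    Trajectory,
    resolve_condition,
)
from .sulfur import INTACT_SS_DISTANCE
from .traj_io import SSCodeFrame

__all__ = [
    "TEMPLATE_SEQUENCE",
    "DistanceLaw",
    "PlantedContact",
    "SyntheticSpec",
    "spec_for_condition",
    "make_topology",
    "make_trajectory",
    "make_ss_series",
]

#: 104-residue template emulating (not claiming to be) the saposin-fold
#: monomer: Cys at 6/31/37/68/71/99, Asp40, Glu54/56/58/72, a Gly/Ser-rich
#: disordered loop at 40-63, and hydrophobics lining the helices.
TEMPLATE_SEQUENCE = (
    "SGALK" "CVIAL"            # 1-10
    "NQYLA" "HVAGS"            # 11-20
    "PTVIL" "ARVNL"            # 21-30
    "CASVI" "LCQTD"            # 31-40
    "GSNGT" "SPGSN"            # 41-50
    "TGSEG" "ESEGN"            # 51-60
    "SGGPV" "ALCAV"            # 61-70
    "CEIAF" "KVLSG"            # 71-80
    "SAWVR" "LAIQN"            # 81-90
    "VLKAV" "HSACG"            # 91-100
    "KSTL"                     # 101-104
)

DEFAULT_HELIX_SPANS = {"h1": (3, 19), "h2": (23, 39), "h3": (64, 78), "h4": (82, 98)}
DEFAULT_LOOP_SPAN = (40, 63)

# Geometry constants (nm): residue rise along the chain path, helical twist
# radius, hairpin leg separation, inter-chain interface separation.
RESIDUE_RISE = 0.15
HELIX_TWIST_DEG = 100.0
HELIX_RADIUS = 0.10
LEG_SEPARATION = 0.30
CHAIN_SEPARATION = 1.20

# Sidechain pseudo-atom offsets relative to CA, (x, y, z) with +z pointing
# into the dimer interface.  Every residue except Gly also gets CB.
_RING6 = [
    (f"C{nm}", (0.07 * np.cos(k * np.pi / 3), 0.07 * np.sin(k * np.pi / 3), 0.30))
    for k, nm in enumerate(["G", "D1", "E1", "Z", "E2", "D2"])
]
_RING6_TRP = [
    (nm, (0.07 * np.cos(k * np.pi / 3), 0.07 * np.sin(k * np.pi / 3), 0.30))
    for k, nm in enumerate(["CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"])
]
SIDECHAIN_OFFSETS: dict[str, list[tuple[str, tuple[float, float, float]]]] = {
    "GLY": [],
    "ALA": [],
    "CYS": [("SG", (0.0, 0.0, 0.25))],
    "SER": [("OG", (0.0, 0.0, 0.20))],
    "THR": [("OG1", (0.0, 0.0, 0.20))],
    "VAL": [("CG1", (0.05, 0.0, 0.22)), ("CG2", (-0.05, 0.0, 0.22))],
    "LEU": [("CG", (0.0, 0.05, 0.25))],
    "ILE": [("CG1", (0.0, 0.05, 0.25))],
    "PRO": [("CG", (0.0, 0.05, 0.18))],
    "MET": [("SD", (0.0, 0.0, 0.25)), ("CE", (0.0, 0.05, 0.33))],
    "LYS": [("NZ", (0.0, 0.0, 0.35))],
    "ARG": [("NE", (-0.05, 0.0, 0.30)), ("NH1", (0.05, 0.05, 0.35)), ("NH2", (0.05, -0.05, 0.35))],
    "HIS": [("ND1", (-0.06, 0.0, 0.30)), ("NE2", (0.06, 0.0, 0.30)), ("CE1", (0.0, 0.06, 0.33))],
    "ASP": [("OD1", (-0.06, 0.0, 0.25)), ("OD2", (0.06, 0.0, 0.25))],
    "GLU": [("OE1", (-0.06, 0.0, 0.30)), ("OE2", (0.06, 0.0, 0.30))],
    "ASN": [("OD1", (-0.06, 0.0, 0.25)), ("ND2", (0.06, 0.0, 0.25))],
    "GLN": [("OE1", (-0.06, 0.0, 0.30)), ("NE2", (0.06, 0.0, 0.30))],
    "PHE": _RING6,
    "TYR": _RING6 + [("OH", (0.0, 0.0, 0.42))],
    "TRP": _RING6_TRP + [("NE1", (0.09, 0.05, 0.25))],
}


@dataclass(frozen=True)
class DistanceLaw:
    """Per-frame distance distribution for an S-gamma pair.

    ``kind`` is "constant" (value = mu), "normal" (mu, sigma, truncated at
    0.01 nm) or "uniform" (lo = mu, hi = sigma-slot).
    """

    kind: str
    mu: float
    sigma: float = 0.0

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "constant":
            return np.full(n, self.mu)
        if self.kind == "normal":
            return np.clip(rng.normal(self.mu, self.sigma, size=n), 0.01, None)
        if self.kind == "uniform":
            return rng.uniform(self.mu, self.sigma, size=n)
        raise ValueError(f"unknown distance law {self.kind!r}")


@dataclass(frozen=True)
class PlantedContact:
    """A contact planted at an exact site-site distance every frame.

    Supported kinds: "HI" (CB-CB of two hydrophobic residues) and "SB"
    (acidic carboxylate oxygens vs a Lys NZ).  Residues are (chain, resid).
    """

    kind: str
    residue_a: tuple[str, int]
    residue_b: tuple[str, int]
    distance: float

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("planted distance must be positive")
        if self.kind not in ("HI", "SB"):
            raise ValueError(f"planted contact kind must be HI or SB, got {self.kind!r}")


@dataclass
class SyntheticSpec:
    """Full recipe for one synthetic replicate (seed makes it reproducible)."""

    n_residues: int = 104
    sequence: str = TEMPLATE_SEQUENCE
    cys_positions: tuple[int, ...] = (6, 31, 37, 68, 71, 99)
    loop_span: tuple[int, int] = DEFAULT_LOOP_SPAN
    helix_spans: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_HELIX_SPANS)
    )
    sigma_nonloop: float = 0.015        # nm, per-residue jitter outside the loop
    sigma_loop: float = 0.04            # nm, inside the loop
    sigma_profile: np.ndarray | None = None  # explicit per-residue override
    sg_laws: dict[tuple[int, int], DistanceLaw] = field(default_factory=dict)
    planted_contacts: tuple[PlantedContact, ...] = ()
    ss_switch_p: float = 0.1            # Markov per-step switch probability
    loop_disordered: bool = True        # loop residues cycle DSSP coil letters
    n_frames: int = 1001
    frame_interval_ps: float = 10.0
    seed: int = 0

    def resolved_sigma(self) -> np.ndarray:
        if self.sigma_profile is not None:
            prof = np.asarray(self.sigma_profile, dtype=float)
            if len(prof) != self.n_residues:
                raise ValueError("sigma_profile length must equal n_residues")
            if np.any(prof < 0):
                raise ValueError("sigma must be non-negative")
            return prof
        prof = np.full(self.n_residues, self.sigma_nonloop)
        lo, hi = self.loop_span
        prof[lo - 1 : hi] = self.sigma_loop
        return prof


def spec_for_condition(ph: float, code: str, **overrides) -> SyntheticSpec:
    """Study-condition spec: S-gamma laws follow the disulfide state.

    Intact pairs sit tightly at the bonded separation (0.2038 nm).  Reduced
    pairs follow the separations observed per pair: 6-99 near 0.50 nm,
    31-71 near 0.35 nm, and the labile 37-68 near 0.40 nm at pH 3.0 but
    0.50 nm at pH 7.4, with a wider spread.
    """
    intact, reduced = resolve_condition(code)
    reduced_mu = {
        (6, 99): (0.50, 0.03),
        (31, 71): (0.35, 0.02),
        (37, 68): (0.40, 0.05) if ph == 3.0 else (0.50, 0.05),
    }
    laws: dict[tuple[int, int], DistanceLaw] = {}
    for pair in intact:
        laws[pair] = DistanceLaw("normal", INTACT_SS_DISTANCE, 0.002)
    for pair in reduced:
        mu, sigma = reduced_mu[pair]
        laws[pair] = DistanceLaw("normal", mu, sigma)
    return SyntheticSpec(sg_laws=laws, **overrides)


# ---------------------------------------------------------------------------
# topology


def make_topology(spec: SyntheticSpec) -> Topology:
    """Two identical chains of pseudo-atom residues from the spec's sequence."""
    if len(set(spec.cys_positions)) != len(spec.cys_positions):
        raise ValueError(f"duplicate cysteine positions in {spec.cys_positions}")
    for p in spec.cys_positions:
        if not (1 <= p <= spec.n_residues):
            raise ValueError(f"cysteine position {p} outside chain of {spec.n_residues}")
    seq = list(spec.sequence[: spec.n_residues].ljust(spec.n_residues, "A"))
    for p in spec.cys_positions:
        seq[p - 1] = "C"

    residues: list[Residue] = []
    atom_names: list[str] = []
    atom_elements: list[str] = []
    atom_resindex: list[int] = []
    for chain in ("A", "B"):
        for i, one in enumerate(seq, start=1):
            resname = ONE_TO_THREE[one]
            ri = len(residues)
            residues.append(Residue(index=i, name=resname, chain=chain))
            names = ["N", "CA", "C", "O"]
            if resname != "GLY":
                names.append("CB")
            names.extend(nm for nm, _ in SIDECHAIN_OFFSETS[resname])
            for nm in names:
                atom_names.append(nm)
                atom_elements.append(nm[0])
                atom_resindex.append(ri)
    from .core import ELEMENT_MASSES

    masses = [ELEMENT_MASSES[e] for e in atom_elements]
    cys_pairs = NATIVE_CYS_PAIRS if set(spec.cys_positions) == {6, 31, 37, 68, 71, 99} else ()
    return Topology(
        residues=residues,
        atom_names=np.array(atom_names, dtype=object),
        atom_elements=np.array(atom_elements, dtype=object),
        atom_masses=np.array(masses, dtype=float),
        atom_resindex=np.array(atom_resindex, dtype=int),
        cys_pairs=cys_pairs,
        loop_span=spec.loop_span,
        helix_spans=dict(spec.helix_spans),
    )


def _base_coordinates(spec: SyntheticSpec, topology: Topology) -> np.ndarray:
    """Idealized static dimer geometry (n_atoms, 3), nm."""
    n = spec.n_residues
    half = (n + 1) // 2
    ca = np.zeros((n, 3))
    for i in range(1, n + 1):
        if i <= half:
            ca[i - 1] = (RESIDUE_RISE * i, 0.0, 0.0)
        else:
            ca[i - 1] = (RESIDUE_RISE * (n + 1 - i), LEG_SEPARATION, 0.0)
    # helical twist within helix spans (plausibility only)
    for a, b in spec.helix_spans.values():
        for i in range(a, b + 1):
            theta = np.deg2rad(HELIX_TWIST_DEG) * (i - a)
            ca[i - 1] += (0.0, HELIX_RADIUS * np.cos(theta), HELIX_RADIUS * np.sin(theta))

    # chain direction per residue, for backbone placement
    u = np.zeros((n, 3))
    u[:-1] = ca[1:] - ca[:-1]
    u[-1] = u[-2]
    u /= np.linalg.norm(u, axis=1, keepdims=True)

    per_chain: dict[str, np.ndarray] = {}
    coords_a = {}
    for i in range(1, n + 1):
        base = ca[i - 1]
        d = u[i - 1]
        coords_a[(i, "N")] = base - 0.05 * d
        coords_a[(i, "CA")] = base
        coords_a[(i, "C")] = base + 0.05 * d
        coords_a[(i, "O")] = base + 0.05 * d + np.array([0.0, -0.06, -0.03])

    out = np.zeros((topology.n_atoms, 3))
    table_positions: dict[tuple[str, int, str], np.ndarray] = {}
    for chain, inward in (("A", 1.0), ("B", -1.0)):
        for i in range(1, n + 1):
            resname = topology.residue_at("A", i).name
            side = [("CB", (0.0, 0.0, 0.15))] if resname != "GLY" else []
            side += SIDECHAIN_OFFSETS[resname]
            for nm in ("N", "CA", "C", "O"):
                p = coords_a[(i, nm)].copy()
                if chain == "B":
                    p = np.array([p[0], LEG_SEPARATION - p[1], CHAIN_SEPARATION - p[2]])
                table_positions[(chain, i, nm)] = p
            for nm, (dx, dy, dz) in side:
                p = coords_a[(i, "CA")] + np.array([dx, dy, dz])
                if chain == "B":
                    base = coords_a[(i, "CA")]
                    p = np.array(
                        [base[0] + dx, LEG_SEPARATION - base[1] - dy,
                         CHAIN_SEPARATION - base[2] - dz]
                    )
                table_positions[(chain, i, nm)] = p

    table = topology.atom_table()
    for key, idx in table.items():
        out[idx] = table_positions[key]
    return out


# ---------------------------------------------------------------------------
# trajectory


def make_trajectory(spec: SyntheticSpec, topology: Topology | None = None) -> Trajectory:
    """Jittered ensemble with planted S-gamma laws and contact geometries.

    Per frame, every residue receives an isotropic Gaussian displacement of
    its spec'd sigma (rigid within the residue, independent across residues
    and frames); S-gamma pairs with a distance law are then moved
    symmetrically along their separation axis to the drawn distance; planted
    contacts are enforced exactly by repositioning the second residue's
    sidechain site atoms.
    """
    if topology is None:
        topology = make_topology(spec)
    rng = np.random.default_rng(spec.seed)
    base = _base_coordinates(spec, topology)
    sigma = spec.resolved_sigma()
    table = topology.atom_table()
    n_res = spec.n_residues

    _check_constraint_conflicts(spec, topology, table)

    # pre-draw S-gamma distances per (pair, chain)
    sg_draws: dict[tuple[tuple[int, int], str], np.ndarray] = {}
    for pair, law in spec.sg_laws.items():
        for chain in ("A", "B"):
            sg_draws[(pair, chain)] = law.sample(spec.n_frames, rng)

    # per-residue jitter: (frames, 2*n_res, 3)
    res_sigma = np.concatenate([sigma, sigma])
    jitter = rng.normal(size=(spec.n_frames, 2 * n_res, 3)) * res_sigma[None, :, None]

    coords = np.empty((spec.n_frames, topology.n_atoms, 3))
    res_of_atom = topology.atom_resindex
    for f in range(spec.n_frames):
        frame = base + jitter[f, res_of_atom]
        for (pair, chain), draws in sg_draws.items():
            i = table[(chain, pair[0], "SG")]
            j = table[(chain, pair[1], "SG")]
            v = frame[j] - frame[i]
            norm = np.linalg.norm(v)
            uhat = v / norm if norm > 1e-9 else np.array([0.0, 0.0, 1.0])
            mid = 0.5 * (frame[i] + frame[j])
            frame[i] = mid - 0.5 * draws[f] * uhat
            frame[j] = mid + 0.5 * draws[f] * uhat
        for pc in spec.planted_contacts:
            _apply_planted_contact(frame, pc, topology, table)
        coords[f] = frame
    times = np.arange(spec.n_frames, dtype=float) * spec.frame_interval_ps
    return Trajectory(topology=topology, times=times, coords=coords)


def _contact_site_atoms(
    pc: PlantedContact, residue: tuple[str, int], topology: Topology
) -> list[str]:
    """Atoms the census measures for this residue under the planted kind."""
    chain, resid = residue
    resname = topology.residue_at(chain, resid).name
    if pc.kind == "HI":
        if resname not in topology.hydrophobic_set:
            raise ValueError(f"planted HI contact needs hydrophobic residues, got {resname}")
        # the census takes the minimum over all sidechain heavy atoms
        return ["CB"] + [nm for nm, _ in SIDECHAIN_OFFSETS[resname]]
    # SB: acidic side contributes carboxylate oxygens, basic side Lys NZ
    if resname in ("ASP", "GLU"):
        return ["OD1", "OD2"] if resname == "ASP" else ["OE1", "OE2"]
    if resname == "LYS":
        return ["NZ"]
    raise ValueError(
        f"planted SB contact supports Asp/Glu vs Lys partners, got {resname}"
    )


def _apply_planted_contact(
    frame: np.ndarray, pc: PlantedContact, topology: Topology,
    table: dict[tuple[str, int, str], int],
) -> None:
    """Rigidly move residue_b's site atoms so the minimum site-site distance
    is exactly the planted value.

    The b-site is translated along the a->b axis; because the minimum
    pairwise distance grows monotonically (and asymptotically 1:1) with
    separation along that axis, a few fixed-point corrections land the
    minimum on the target to machine precision.
    """
    atoms_a = [table[(*pc.residue_a, nm)] for nm in _contact_site_atoms(pc, pc.residue_a, topology)]
    atoms_b = [table[(*pc.residue_b, nm)] for nm in _contact_site_atoms(pc, pc.residue_b, topology)]
    pts_a = frame[atoms_a]
    centroid_a = pts_a.mean(axis=0)
    u = frame[atoms_b].mean(axis=0) - centroid_a
    norm = np.linalg.norm(u)
    u = u / norm if norm > 1e-9 else np.array([0.0, 0.0, 1.0])
    # start well outside the a-site cloud, then correct the minimum distance
    spread = np.linalg.norm(pts_a - centroid_a, axis=1).max()
    start = centroid_a + (pc.distance + spread + 0.1) * u
    frame[atoms_b] += start - frame[atoms_b].mean(axis=0)
    for _ in range(50):
        d = np.linalg.norm(frame[atoms_a][:, None, :] - frame[atoms_b][None, :, :], axis=2)
        err = d.min() - pc.distance
        if abs(err) < 1e-12:
            return
        frame[atoms_b] -= err * u
    raise RuntimeError(
        f"planted contact {pc.residue_a}-{pc.residue_b} did not converge to "
        f"{pc.distance} nm"
    )


def _check_constraint_conflicts(
    spec: SyntheticSpec, topology: Topology, table: dict[tuple[str, int, str], int]
) -> None:
    """Reject specs that put one atom under two positional constraints."""
    owned: dict[int, str] = {}
    for pair in spec.sg_laws:
        for chain in ("A", "B"):
            for resid in pair:
                key = (chain, resid, "SG")
                if key not in table:
                    raise ValueError(f"S-gamma law references non-cysteine residue {chain}:{resid}")
                idx = table[key]
                tag = f"sg-law {pair}/{chain}"
                if idx in owned:
                    raise ValueError(
                        f"atom {chain}:{resid}:SG constrained by both {owned[idx]} and {tag}"
                    )
                owned[idx] = tag
    for pc in spec.planted_contacts:
        # only residue_b's atoms are moved
        for nm in _contact_site_atoms(pc, pc.residue_b, topology):
            key = (*pc.residue_b, nm)
            if key not in table:
                raise ValueError(f"planted contact references missing atom {key}")
            idx = table[key]
            tag = f"planted {pc.kind} {pc.residue_a}-{pc.residue_b}"
            if idx in owned:
                raise ValueError(f"atom {key} constrained by both {owned[idx]} and {tag}")
            owned[idx] = tag


# ---------------------------------------------------------------------------
# secondary-structure series


def make_ss_series(
    spec: SyntheticSpec, seed_offset: int = 1
) -> dict[str, list[SSCodeFrame]]:
    """Per-chain, per-residue Markov DSSP letters over n_frames.

    Non-loop residues follow a 2-state {H, C} chain with per-step switch
    probability ``ss_switch_p`` (initial state H inside helix spans, C
    elsewhere).  When ``loop_disordered`` is set, loop residues instead
    cycle i.i.d. through the disordered DSSP letters {C, T, S}: their
    letters flicker but their 3-class label never leaves "disordered".
    """
    p = spec.ss_switch_p
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"switch probability must be in [0, 1], got {p}")
    rng = np.random.default_rng(spec.seed + seed_offset)
    n = spec.n_residues
    lo, hi = spec.loop_span
    in_loop = np.array([lo <= i <= hi for i in range(1, n + 1)])
    in_helix = np.zeros(n, dtype=bool)
    for a, b in spec.helix_spans.values():
        in_helix[a - 1 : b] = True

    out: dict[str, list[SSCodeFrame]] = {}
    for chain in ("A", "B"):
        # 2-state Markov: state 0 = H, 1 = C; switches are Bernoulli(p)
        switches = rng.random(size=(spec.n_frames - 1, n)) < p
        state = np.where(in_helix, 0, 1).astype(np.int8)
        states = np.empty((spec.n_frames, n), dtype=np.int8)
        states[0] = state
        for f in range(1, spec.n_frames):
            states[f] = states[f - 1] ^ switches[f - 1]
        letters = np.where(states == 0, "H", "C").astype(object)
        if spec.loop_disordered and in_loop.any():
            coil = np.array(list("CTS"), dtype=object)
            loop_draw = rng.integers(0, 3, size=(spec.n_frames, int(in_loop.sum())))
            letters[:, in_loop] = coil[loop_draw]
        frames = [
            SSCodeFrame(
                chain=chain,
                time_ps=f * spec.frame_interval_ps,
                codes="".join(letters[f]),
            )
            for f in range(spec.n_frames)
        ]
        out[chain] = frames
    return out
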