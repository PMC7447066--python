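"""Domain model for the saposin-fold dimer analyses.

Defines the topology/trajectory containers shared by every analysis stage,
the disulfide-reduction condition-code registry (AI, D1..D6, AR), and the
rule-based pH protonation assignment used by the salt-bridge census.

The system modelled is a homodimer of a ~100-residue saposin-like domain
(the plant-specific insert of an aspartic protease) with three native
disulfide bonds per monomer: Cys6-Cys99, Cys31-Cys71 and Cys37-Cys68, and a
disordered loop spanning residues 40-63 between helices 2 and 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "AMINO_ACIDS_3",
    "NATIVE_CYS_PAIRS",
    "NON_NATIVE_CYS_PAIRS",
    "CONDITION_CODES",
    "Residue",
    "Topology",
    "Trajectory",
    "ConditionCode",
    "ProtonationMap",
    "resolve_condition",
    "assign_protonation",
]

#: Three-letter codes of the 20 standard amino acids.
AMINO_ACIDS_3 = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}

#: Native disulfide pairs of the dimer template, in registry order.
NATIVE_CYS_PAIRS: tuple[tuple[int, int], ...] = ((6, 99), (31, 71), (37, 68))

#: Geometrically feasible non-native (interchange) pairs.
NON_NATIVE_CYS_PAIRS: tuple[tuple[int, int], ...] = ((31, 37), (68, 71))

# Condition-code registry: for each code, intact/reduced flag per native pair
# in NATIVE_CYS_PAIRS order.  "I" = intact, "R" = reduced.
CONDITION_CODES: dict[str, tuple[str, str, str]] = {
    "AI": ("I", "I", "I"),
    "D1": ("R", "I", "I"),
    "D2": ("I", "R", "I"),
    "D3": ("I", "I", "R"),
    "D4": ("R", "R", "I"),
    "D5": ("I", "R", "R"),
    "D6": ("R", "I", "R"),
    "AR": ("R", "R", "R"),
}

SUPPORTED_PH = (3.0, 7.4)

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: Default atomic masses (amu) for the elements in the coarse topology.
ELEMENT_MASSES = {"C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "H": 1.008}

ACIDIC_RESIDUES = frozenset({"ASP", "GLU"})
BASIC_RESIDUES = frozenset({"LYS", "ARG", "HIS"})
TITRATABLE_RESIDUES = ACIDIC_RESIDUES | BASIC_RESIDUES


@dataclass(frozen=True)
class Residue:
    """One residue of the dimer: 1-based sequence index, 3-letter name, chain."""

    index: int
    name: str
    chain: str

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"residue index must be >= 1, got {self.index}")
        if self.name not in AMINO_ACIDS_3:
            raise ValueError(f"unknown residue name {self.name!r}")
        if self.chain not in ("A", "B"):
            raise ValueError(f"chain must be 'A' or 'B', got {self.chain!r}")

    @property
    def label(self) -> str:
        return f"{self.chain}:{self.name}{self.index}"


@dataclass
class Topology:
    """Static description of the dimer: residues, atoms, and analysis regions.

    Atoms are stored as parallel arrays; ``atom_resindex`` points into
    ``residues``.  The homodimer invariant (identical residue rosters on
    chains A and B) is enforced at construction.
    """

    residues: list[Residue]
    atom_names: np.ndarray          # (n_atoms,) str
    atom_elements: np.ndarray       # (n_atoms,) str
    atom_masses: np.ndarray         # (n_atoms,) float, amu
    atom_resindex: np.ndarray       # (n_atoms,) int, index into residues
    cys_pairs: tuple[tuple[int, int], ...] = NATIVE_CYS_PAIRS
    loop_span: tuple[int, int] = (40, 63)
    helix_spans: dict[str, tuple[int, int]] = field(default_factory=dict)
    hydrophobic_set: frozenset[str] = frozenset(
        {"ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "TRP"}
    )

    def __post_init__(self) -> None:
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.atom_elements = np.asarray(self.atom_elements, dtype=object)
        self.atom_masses = np.asarray(self.atom_masses, dtype=float)
        self.atom_resindex = np.asarray(self.atom_resindex, dtype=int)
        n = len(self.atom_names)
        if not (len(self.atom_elements) == len(self.atom_masses) == len(self.atom_resindex) == n):
            raise ValueError("atom arrays must have equal length")
        if n and (self.atom_resindex.min() < 0 or self.atom_resindex.max() >= len(self.residues)):
            raise ValueError("atom_resindex out of range: parent residue must exist")
        rosters = {
            chain: [(r.index, r.name) for r in self.residues if r.chain == chain]
            for chain in ("A", "B")
        }
        # Homodimer invariant: when both chains are populated their rosters
        # must match.  Single-chain systems (test fixtures) are permitted.
        if rosters["A"] and rosters["B"] and rosters["A"] != rosters["B"]:
            raise ValueError("homodimer invariant violated: chain rosters differ")
        lo, hi = self.loop_span
        if lo > hi:
            raise ValueError(f"loop span {self.loop_span} is empty")
        for name, (a, b) in self.helix_spans.items():
            if a > b:
                raise ValueError(f"helix span {name} is empty")
            if not (b < lo or a > hi):
                raise ValueError(f"helix span {name}={a, b} overlaps loop {self.loop_span}")

    # -- lookups ---------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues_per_chain(self) -> int:
        return sum(1 for r in self.residues if r.chain == "A")

    @property
    def chains(self) -> tuple[str, ...]:
        return ("A", "B")

    def residue_at(self, chain: str, index: int) -> Residue:
        for r in self.residues:
            if r.chain == chain and r.index == index:
                return r
        raise KeyError(f"no residue {chain}:{index}")

    def atom_index(self, chain: str, resid: int, atom_name: str) -> int:
        """Flat atom index of a named atom, or KeyError naming the residue."""
        for i, ri in enumerate(self.atom_resindex):
            r = self.residues[ri]
            if r.chain == chain and r.index == resid and self.atom_names[i] == atom_name:
                return i
        raise KeyError(f"atom {atom_name!r} not found in residue {chain}:{resid}")

    def _build_atom_table(self) -> dict[tuple[str, int, str], int]:
        table: dict[tuple[str, int, str], int] = {}
        for i, ri in enumerate(self.atom_resindex):
            r = self.residues[ri]
            table[(r.chain, r.index, self.atom_names[i])] = i
        return table

    def atom_table(self) -> dict[tuple[str, int, str], int]:
        if not hasattr(self, "_atom_table_cache"):
            self._atom_table_cache = self._build_atom_table()
        return self._atom_table_cache

    def atom_chain(self) -> np.ndarray:
        """Chain id per atom."""
        return np.array([self.residues[ri].chain for ri in self.atom_resindex], dtype=object)

    def atom_resid(self) -> np.ndarray:
        """1-based residue index per atom."""
        return np.array([self.residues[ri].index for ri in self.atom_resindex], dtype=int)

    def in_loop(self, resid: int) -> bool:
        lo, hi = self.loop_span
        return lo <= resid <= hi

    # -- selections ------------------------------------------------------

    def select(
        self,
        chain: str | None = None,
        atom_names: Iterable[str] | None = None,
        resid_interval: tuple[int, int] | None = None,
        exclude_loop: bool = False,
        residue_names: Iterable[str] | None = None,
    ) -> np.ndarray:
        """Flat atom indices matching all given predicates (AND-combined)."""
        mask = np.ones(self.n_atoms, dtype=bool)
        res_chain = self.atom_chain()
        res_id = self.atom_resid()
        if chain is not None:
            mask &= res_chain == chain
        if atom_names is not None:
            names = set(atom_names)
            mask &= np.array([nm in names for nm in self.atom_names])
        if resid_interval is not None:
            lo, hi = resid_interval
            mask &= (res_id >= lo) & (res_id <= hi)
        if exclude_loop:
            lo, hi = self.loop_span
            mask &= ~((res_id >= lo) & (res_id <= hi))
        if residue_names is not None:
            rnames = set(residue_names)
            resnames = np.array([self.residues[ri].name for ri in self.atom_resindex], dtype=object)
            mask &= np.array([nm in rnames for nm in resnames])
        return np.nonzero(mask)[0]

    def backbone(self, chain: str | None = None, exclude_loop: bool = False) -> np.ndarray:
        return self.select(chain=chain, atom_names=BACKBONE_ATOMS, exclude_loop=exclude_loop)


@dataclass
class Trajectory:
    """Ordered coordinate frames (nm) over a fixed topology.

    ``coords`` has shape (n_frames, n_atoms, 3); ``times`` are in ps and must
    be strictly increasing.
    """

    topology: Topology
    times: np.ndarray               # (n_frames,) ps
    coords: np.ndarray              # (n_frames, n_atoms, 3) nm
    box: np.ndarray | None = None   # optional (3, 3) nm

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] != len(self.times):
            raise ValueError("times and coords disagree on frame count")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"every frame needs {self.topology.n_atoms} atoms, "
                f"got {self.coords.shape[1]}"
            )
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def __len__(self) -> int:
        return self.n_frames


@dataclass(frozen=True)
class ConditionCode:
    """A simulated condition: pH plus disulfide-reduction code."""

    ph: float
    code: str

    def __post_init__(self) -> None:
        if self.ph not in SUPPORTED_PH:
            raise ValueError(f"pH must be one of {SUPPORTED_PH}, got {self.ph}")
        if self.code not in CONDITION_CODES:
            raise ValueError(
                f"unknown condition code {self.code!r}; valid codes: "
                + ", ".join(CONDITION_CODES)
            )

    @property
    def reduced_pairs(self) -> tuple[tuple[int, int], ...]:
        return resolve_condition(self.code)[1]

    @property
    def intact_pairs(self) -> tuple[tuple[int, int], ...]:
        return resolve_condition(self.code)[0]


def resolve_condition(code: str) -> tuple[tuple[tuple[int, int], ...], tuple[tuple[int, int], ...]]:
    """Partition the native disulfide pairs into (intact, reduced) for a code.

    The eight codes form a bijection with the subsets of the three native
    pairs: AI keeps all three intact, D1-D3 reduce one, D4-D6 reduce two and
    AR reduces all three.
    """
    if code not in CONDITION_CODES:
        raise ValueError(
            f"unknown condition code {code!r}; valid codes: " + ", ".join(CONDITION_CODES)
        )
    flags = CONDITION_CODES[code]
    intact = tuple(p for p, f in zip(NATIVE_CYS_PAIRS, flags) if f == "I")
    reduced = tuple(p for p, f in zip(NATIVE_CYS_PAIRS, flags) if f == "R")
    return intact, reduced


@dataclass
class ProtonationMap:
    """Charge state of every titratable sidechain at a given pH.

    ``states`` maps (chain, resid) -> "charged" | "neutral"; ``provenance``
    records whether each entry came from the default pH rule or an override.
    Termini are carried as pseudo-keys (chain, 0) for the N-terminus and
    (chain, -1) for the C-terminus.
    """

    ph: float
    states: dict[tuple[str, int], str]
    provenance: dict[tuple[str, int], str]

    def is_charged(self, chain: str, resid: int) -> bool:
        return self.states[(chain, resid)] == "charged"

    def charged_acidics(self, topology: Topology) -> list[Residue]:
        return [
            r for r in topology.residues
            if r.name in ACIDIC_RESIDUES and self.is_charged(r.chain, r.index)
        ]


def _default_state(resname: str, ph: float) -> str:
    """Default charge state of a titratable sidechain at the supported pHs.

    At pH 3.0 the carboxylates (Asp/Glu) are below their pKa and neutral;
    His (pKa ~6) is protonated and charged.  At pH 7.4 carboxylates are
    deprotonated/charged and His is neutral.  Lys/Arg are charged at both.
    """
    if resname in ACIDIC_RESIDUES:
        return "neutral" if ph == 3.0 else "charged"
    if resname == "HIS":
        return "charged" if ph == 3.0 else "neutral"
    if resname in ("LYS", "ARG"):
        return "charged"
    raise ValueError(f"{resname} is not titratable")


def assign_protonation(
    topology: Topology,
    ph: float,
    overrides: Mapping[object, str] | None = None,
) -> ProtonationMap:
    """Build the complete protonation map for all titratable residues.

    Override keys may be ``(chain, resid)`` tuples or residue labels like
    ``"Glu72"`` (applied to both chains); values are "charged" or "neutral".
    Overrides win over the pH defaults and are flagged in provenance.
    """
    if ph not in SUPPORTED_PH:
        raise ValueError(f"pH must be one of {SUPPORTED_PH}, got {ph}")
    states: dict[tuple[str, int], str] = {}
    provenance: dict[tuple[str, int], str] = {}
    titratable = {(r.chain, r.index): r for r in topology.residues if r.name in TITRATABLE_RESIDUES}
    for (chain, resid), r in titratable.items():
        states[(chain, resid)] = _default_state(r.name, ph)
        provenance[(chain, resid)] = "default-rule"
    # Termini: amine charged at both pHs; carboxyl neutral at pH 3.0.
    for chain in topology.chains:
        states[(chain, 0)] = "charged"
        states[(chain, -1)] = "neutral" if ph == 3.0 else "charged"
        provenance[(chain, 0)] = provenance[(chain, -1)] = "default-rule"

    if overrides:
        for key, state in overrides.items():
            targets = _resolve_override_key(key, titratable)
            for tgt in targets:
                states[tgt] = _normalize_state(state, titratable[tgt].name)
                provenance[tgt] = "override"
    return ProtonationMap(ph=ph, states=states, provenance=provenance)


def _normalize_state(state: str, resname: str) -> str:
    """Map protonated/deprotonated wording onto charged/neutral per residue type.

    A protonated carboxylate is neutral while a protonated amine is charged,
    so the chemical wording is resolved against the residue's type.
    """
    if state in ("charged", "neutral"):
        return state
    acidic = resname in ACIDIC_RESIDUES
    if state == "protonated":
        return "neutral" if acidic else "charged"
    if state == "deprotonated":
        return "charged" if acidic else "neutral"
    raise ValueError(
        f"override state must be charged|neutral|protonated|deprotonated, got {state!r}"
    )


def _resolve_override_key(
    key: object, titratable: Mapping[tuple[str, int], Residue]
) -> list[tuple[str, int]]:
    if isinstance(key, tuple) and len(key) == 2:
        chain, resid = key
        if (chain, resid) not in titratable:
            raise ValueError(f"override references nonexistent titratable residue {chain}:{resid}")
        return [(chain, resid)]
    if isinstance(key, str):
        # "Glu72" style: 3-letter (or 1-letter) name + 1-based index, both chains.
        name_part = "".join(c for c in key if c.isalpha())
        num_part = "".join(c for c in key if c.isdigit())
        if not num_part:
            raise ValueError(f"cannot parse override key {key!r}")
        resid = int(num_part)
        resname = name_part.upper() if len(name_part) == 3 else ONE_TO_THREE.get(name_part.upper(), "")
        hits = [
            k for k, r in titratable.items()
            if k[1] == resid and (not resname or r.name == resname)
        ]
        if not hits:
            raise ValueError(f"override references nonexistent titratable residue {key!r}")
        return hits
    raise ValueError(f"cannot parse override key {key!r}")
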