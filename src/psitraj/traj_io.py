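"""Trajectory and secondary-structure I/O plus analysis-window selection.

Two coordinate formats are supported behind the same :class:`~psitraj.core.Trajectory`
contract:

* multi-model PDB (standard; coordinates converted Å -> nm on read), and
* a light frame-CSV dialect with one row per atom per frame and columns
  ``frame, time_ps, chain, resid, atomname, x, y, z`` (nm), plus optional
  ``resname`` and ``element`` columns.

Secondary-structure input is a per-frame DSSP code-string table
(``frame, time_ps, chain, codes``), one single-letter DSSP code per residue.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
import biotite.structure as bst
import biotite.structure.io.pdb as bpdb

from .core import (
    ELEMENT_MASSES,
    Residue,
    Topology,
    Trajectory,
)

__all__ = [
    "DSSP_CODES",
    "SSCodeFrame",
    "AnalysisWindow",
    "read_ensemble",
    "write_ensemble",
    "read_dssp_series",
    "write_dssp_series",
    "select_window",
]

#: Legal single-letter DSSP codes ('~' and ' ' denote no assigned structure).
DSSP_CODES = frozenset("HGIEBTSC ~")

#: Bonded-atom guard threshold (nm): any backbone bonded distance above this
#: is taken as a dimer broken across periodic images.
BROKEN_IMAGE_CUTOFF = 0.5


@dataclass(frozen=True)
class SSCodeFrame:
    """Per-frame DSSP assignment for one chain: one code per residue."""

    chain: str
    time_ps: float
    codes: str

    def __post_init__(self) -> None:
        bad = set(self.codes) - DSSP_CODES
        if bad:
            raise ValueError(f"illegal DSSP code(s) {sorted(bad)} in frame at {self.time_ps} ps")


@dataclass(frozen=True)
class AnalysisWindow:
    """Tail fraction of a trajectory (default last 10%), or an explicit
    ``(t_start, t_end)`` ps interval."""

    fraction: float | None = 0.10
    interval: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.interval is None:
            if self.fraction is None or not (0.0 < self.fraction <= 1.0):
                raise ValueError(f"window fraction must be in (0, 1], got {self.fraction}")
        else:
            t0, t1 = self.interval
            if t1 < t0:
                raise ValueError(f"empty window interval {self.interval}")

    def mask(self, times: np.ndarray) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        if self.interval is not None:
            t0, t1 = self.interval
            m = (times >= t0) & (times <= t1)
        else:
            t0, t1 = times[0], times[-1]
            cutoff = t0 + (1.0 - self.fraction) * (t1 - t0)
            m = times >= cutoff
        if not m.any():
            raise ValueError("analysis window selects no frames")
        return m


# ---------------------------------------------------------------------------
# coordinate ensembles


def read_ensemble(
    path: str | Path,
    fmt: str | None = None,
    frame_interval_ps: float = 1.0,
    check_bonds: bool = True,
) -> Trajectory:
    """Read a coordinate ensemble into a Trajectory (coordinates in nm).

    ``fmt`` is ``"pdb"`` or ``"csv"``; when omitted it is inferred from the
    file suffix.  PDB coordinates (Å) are divided by 10.  When the file
    carries no time information, frame times are model index x
    ``frame_interval_ps``.
    """
    path = Path(path)
    if fmt is None:
        fmt = {".pdb": "pdb", ".ent": "pdb", ".csv": "csv"}.get(path.suffix.lower())
    if fmt == "pdb":
        traj = _read_pdb(path, frame_interval_ps)
    elif fmt == "csv":
        traj = _read_frame_csv(path)
    else:
        raise ValueError(f"unknown ensemble format {fmt!r} (expected 'pdb' or 'csv')")
    if check_bonds:
        _guard_broken_images(traj)
    return traj


def _check_constant_roster(path: Path) -> None:
    """Pre-parse MODEL blocks so a roster mismatch names the offending model."""
    counts: list[int] = []
    current: int | None = None
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                current = 0
            elif rec in ("ATOM", "HETATM"):
                if current is None:  # no MODEL records: single implicit model
                    current = 0
                current += 1
            elif rec == "ENDMDL":
                counts.append(current or 0)
                current = None
    if current is not None and current > 0:
        counts.append(current)
    if len(set(counts)) > 1:
        ref = counts[0]
        for i, c in enumerate(counts[1:], start=2):
            if c != ref:
                raise ValueError(
                    f"atom roster mismatch: model {i} has {c} atoms, model 1 has {ref}"
                )


def _read_pdb(path: Path, frame_interval_ps: float) -> Trajectory:
    _check_constant_roster(path)
    pdb_file = bpdb.PDBFile.read(str(path))
    stack = pdb_file.get_structure(model=None)
    if isinstance(stack, bst.AtomArray):  # single model
        stack = bst.stack([stack])
    topology = _topology_from_atom_array(stack[0])
    coords = stack.coord.astype(float) / 10.0  # Å -> nm
    times = np.arange(coords.shape[0], dtype=float) * frame_interval_ps
    box = None
    if stack.box is not None:
        box = np.asarray(stack.box[0], dtype=float) / 10.0
    return Trajectory(topology=topology, times=times, coords=coords, box=box)


def _topology_from_atom_array(arr: bst.AtomArray) -> Topology:
    residues: list[Residue] = []
    res_key_to_idx: dict[tuple[str, int], int] = {}
    resindex = np.empty(arr.array_length(), dtype=int)
    elements = []
    masses = []
    for i in range(arr.array_length()):
        chain = str(arr.chain_id[i]) or "A"
        resid = int(arr.res_id[i])
        key = (chain, resid)
        if key not in res_key_to_idx:
            res_key_to_idx[key] = len(residues)
            residues.append(Residue(index=resid, name=str(arr.res_name[i]), chain=chain))
        resindex[i] = res_key_to_idx[key]
        elem = str(arr.element[i]).upper() or str(arr.atom_name[i])[0]
        elements.append(elem)
        masses.append(ELEMENT_MASSES.get(elem, 12.011))
    return Topology(
        residues=residues,
        atom_names=np.array([str(n) for n in arr.atom_name], dtype=object),
        atom_elements=np.array(elements, dtype=object),
        atom_masses=np.array(masses, dtype=float),
        atom_resindex=resindex,
    )


def _read_frame_csv(path: Path) -> Trajectory:
    df = pd.read_csv(path)
    required = {"frame", "time_ps", "chain", "resid", "atomname", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"frame-CSV missing required columns: {sorted(missing)}")
    if "resname" not in df.columns:
        df["resname"] = "GLY"
    if "element" not in df.columns:
        df["element"] = df["atomname"].astype(str).str[0]

    frames = sorted(df["frame"].unique())
    first = df[df["frame"] == frames[0]].reset_index(drop=True)
    roster = list(zip(first["chain"], first["resid"], first["atomname"]))

    residues: list[Residue] = []
    res_key_to_idx: dict[tuple[str, int], int] = {}
    resindex = np.empty(len(first), dtype=int)
    for i, row in first.iterrows():
        key = (str(row["chain"]), int(row["resid"]))
        if key not in res_key_to_idx:
            res_key_to_idx[key] = len(residues)
            residues.append(Residue(index=key[1], name=str(row["resname"]), chain=key[0]))
        resindex[i] = res_key_to_idx[key]
    elements = first["element"].astype(str).to_numpy(dtype=object)
    topology = Topology(
        residues=residues,
        atom_names=first["atomname"].astype(str).to_numpy(dtype=object),
        atom_elements=elements,
        atom_masses=np.array([ELEMENT_MASSES.get(e, 12.011) for e in elements]),
        atom_resindex=resindex,
    )

    coords = np.empty((len(frames), len(first), 3))
    times = np.empty(len(frames))
    for fi, f in enumerate(frames):
        sub = df[df["frame"] == f].reset_index(drop=True)
        if list(zip(sub["chain"], sub["resid"], sub["atomname"])) != roster:
            raise ValueError(f"atom roster mismatch: frame {f} differs from frame {frames[0]}")
        coords[fi] = sub[["x", "y", "z"]].to_numpy(dtype=float)
        times[fi] = float(sub["time_ps"].iloc[0])
    return Trajectory(topology=topology, times=times, coords=coords)


def _backbone_bond_pairs(topology: Topology) -> np.ndarray:
    """Index pairs of bonded backbone atoms (N-CA, CA-C, C-O, C-N(next))."""
    table = topology.atom_table()
    pairs: list[tuple[int, int]] = []
    for chain in ("A", "B"):
        resids = sorted(r.index for r in topology.residues if r.chain == chain)
        for rid in resids:
            def idx(name: str, rid: int = rid):
                return table.get((chain, rid, name))
            for a, b in (("N", "CA"), ("CA", "C"), ("C", "O")):
                ia, ib = idx(a), idx(b)
                if ia is not None and ib is not None:
                    pairs.append((ia, ib))
            ic, inext = idx("C"), table.get((chain, rid + 1, "N"))
            if ic is not None and inext is not None:
                pairs.append((ic, inext))
    return np.array(pairs, dtype=int).reshape(-1, 2)


def _guard_broken_images(traj: Trajectory) -> None:
    pairs = _backbone_bond_pairs(traj.topology)
    if len(pairs) == 0:
        return
    d = np.linalg.norm(traj.coords[:, pairs[:, 0]] - traj.coords[:, pairs[:, 1]], axis=2)
    bad = np.nonzero(d.max(axis=1) > BROKEN_IMAGE_CUTOFF)[0]
    if len(bad):
        raise ValueError(
            f"frame {bad[0]} has a bonded-atom distance > {BROKEN_IMAGE_CUTOFF} nm; "
            "the dimer looks broken across periodic images"
        )


def write_ensemble(traj: Trajectory, path: str | Path, fmt: str | None = None) -> None:
    """Write a Trajectory as multi-model PDB (nm -> Å) or frame-CSV (nm)."""
    path = Path(path)
    if fmt is None:
        fmt = {".pdb": "pdb", ".csv": "csv"}.get(path.suffix.lower())
    if fmt == "pdb":
        _write_pdb(traj, path)
    elif fmt == "csv":
        _write_frame_csv(traj, path)
    else:
        raise ValueError(f"unknown ensemble format {fmt!r} (expected 'pdb' or 'csv')")


def _write_pdb(traj: Trajectory, path: Path) -> None:
    top = traj.topology
    n = top.n_atoms
    arr = bst.AtomArray(n)
    arr.chain_id = np.array(top.atom_chain(), dtype="U4")
    arr.res_id = top.atom_resid()
    arr.res_name = np.array(
        [top.residues[ri].name for ri in top.atom_resindex], dtype="U5"
    )
    arr.atom_name = np.array(top.atom_names, dtype="U6")
    arr.element = np.array(top.atom_elements, dtype="U2")
    arr.hetero = np.zeros(n, dtype=bool)
    stack = bst.stack([arr] * traj.n_frames)
    stack.coord = traj.coords * 10.0  # nm -> Å
    pdb_file = bpdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


def _write_frame_csv(traj: Trajectory, path: Path) -> None:
    top = traj.topology
    chain = top.atom_chain()
    resid = top.atom_resid()
    resname = np.array([top.residues[ri].name for ri in top.atom_resindex], dtype=object)
    rows = []
    for fi in range(traj.n_frames):
        rows.append(
            pd.DataFrame(
                {
                    "frame": fi,
                    "time_ps": traj.times[fi],
                    "chain": chain,
                    "resid": resid,
                    "resname": resname,
                    "atomname": top.atom_names,
                    "element": top.atom_elements,
                    "x": traj.coords[fi, :, 0],
                    "y": traj.coords[fi, :, 1],
                    "z": traj.coords[fi, :, 2],
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# DSSP code tables


def read_dssp_series(source) -> dict[str, list[SSCodeFrame]]:
    """Read per-frame DSSP code strings into ordered per-chain frame lists.

    ``source`` is a CSV path or DataFrame with columns
    ``frame, time_ps, chain, codes``, or a mapping ``chain -> list of code
    strings`` (times default to the frame index in ps).  Code-string length
    must be constant within a chain.
    """
    if isinstance(source, dict):
        out = {
            chain: [SSCodeFrame(chain=chain, time_ps=float(i), codes=str(c))
                    for i, c in enumerate(codes)]
            for chain, codes in source.items()
        }
    else:
        df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, keep_default_na=False)
        required = {"frame", "time_ps", "chain", "codes"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"DSSP table missing required columns: {sorted(missing)}")
        out = {}
        for chain, sub in df.groupby("chain", sort=True):
            sub = sub.sort_values("frame")
            out[str(chain)] = [
                SSCodeFrame(chain=str(chain), time_ps=float(t), codes=str(c))
                for t, c in zip(sub["time_ps"], sub["codes"])
            ]
    for chain, frames in out.items():
        lengths = {len(f.codes) for f in frames}
        if len(lengths) > 1:
            raise ValueError(
                f"chain {chain}: DSSP code-string length drifts across frames ({sorted(lengths)})"
            )
    return out


def write_dssp_series(series: dict[str, list[SSCodeFrame]], path: str | Path) -> None:
    rows = []
    for chain, frames in series.items():
        for i, f in enumerate(frames):
            rows.append({"frame": i, "time_ps": f.time_ps, "chain": chain, "codes": f.codes})
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# window selection


def select_window(obj, window: AnalysisWindow | float = 0.10):
    """Restrict a Trajectory or DSSP series to the analysis window (tail).

    The cutoff is inclusive: frames with ``t >= t0 + (1 - fraction) * span``
    are kept, so a fraction of 1.0 is the identity.
    """
    if not isinstance(window, AnalysisWindow):
        window = AnalysisWindow(fraction=float(window))
    if isinstance(obj, Trajectory):
        m = window.mask(obj.times)
        return Trajectory(
            topology=obj.topology, times=obj.times[m], coords=obj.coords[m], box=obj.box
        )
    if isinstance(obj, dict):  # per-chain SSCodeFrame lists
        out = {}
        for chain, frames in obj.items():
            times = np.array([f.time_ps for f in frames])
            m = window.mask(times)
            out[chain] = [f for f, keep in zip(frames, m) if keep]
        return out
    if isinstance(obj, (list, tuple)):  # flat SSCodeFrame list
        times = np.array([f.time_ps for f in obj])
        m = window.mask(times)
        return [f for f, keep in zip(obj, m) if keep]
    raise TypeError(f"cannot window object of type {type(obj).__name__}")
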