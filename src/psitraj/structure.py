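"""Global structure metrics: superposition, RMSD, RMSF, Rg, COM separation.

The disordered loop (residues 40-63) dominates the dimer's motion, so RMSD
is fitted on non-loop backbone atoms and both with-loop and no-loop
variants of RMSD and Rg are reported.  RMSF is offered raw and filtered
through the first covariance eigenvector (essential-dynamics style): the
analysis-window trajectory is projected onto its first principal component
and the fluctuation recomputed from the rank-1 reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BACKBONE_ATOMS, Trajectory

__all__ = [
    "StructureMetricSeries",
    "superpose",
    "rmsd_series",
    "rmsf_profile",
    "pool_rmsf",
    "radius_of_gyration",
    "com_separation",
    "summarize_series",
]


@dataclass
class StructureMetricSeries:
    """A per-frame (or per-residue) metric in nm with a variant tag."""

    metric: str
    values: np.ndarray
    times: np.ndarray | None = None
    variant: str = ""           # e.g. "with-loop" | "no-loop"
    residue_index: np.ndarray | None = None  # set for per-residue metrics

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -1e-12):
            raise ValueError(f"{self.metric}: negative metric values")


def summarize_series(values_per_replicate: list[np.ndarray], error: str = "sem") -> dict:
    """Replicate-level summary: mean of per-replicate means ± SEM (n = replicates)."""
    means = np.array([np.mean(v) for v in values_per_replicate], dtype=float)
    n = len(means)
    out = {"mean": float(means.mean()), "n": n}
    if error == "sem":
        out["sem"] = float(means.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    else:
        out["sd"] = float(means.std(ddof=0))
    return out


# ---------------------------------------------------------------------------
# superposition (Kabsch)


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_indices: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    The optimal proper rotation (det = +1) is found on the fit selection via
    SVD of the cross-covariance (Kabsch) and applied to all atoms.  Returns
    ``(rotation, translation, transformed)`` with
    ``transformed = (mobile - com_mobile) @ R.T + com_reference``.

    Degenerate fit sets (fewer than 3 atoms, or collinear/coincident
    points) are rejected.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if fit_indices is None:
        fit_indices = np.arange(mobile.shape[0])
    fit_indices = np.asarray(fit_indices, dtype=int)
    if len(fit_indices) < 3:
        raise ValueError("superposition needs at least 3 fit atoms")
    m = mobile[fit_indices]
    r = reference[fit_indices]
    mc = m.mean(axis=0)
    rc = r.mean(axis=0)
    m0 = m - mc
    r0 = r - rc
    if np.linalg.matrix_rank(m0, tol=1e-10) < 2 or np.linalg.matrix_rank(r0, tol=1e-10) < 2:
        raise ValueError("degenerate fit selection (collinear or coincident atoms)")
    H = m0.T @ r0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    transformed = (mobile - mc) @ R.T + rc
    t = rc - R @ mc
    return R, t, transformed


# ---------------------------------------------------------------------------
# RMSD


def rmsd_series(
    traj: Trajectory,
    reference: np.ndarray | None = None,
    fit_selection: np.ndarray | None = None,
    measure_selection: np.ndarray | None = None,
    fit: bool = True,
    variant: str = "",
) -> StructureMetricSeries:
    """Per-frame RMSD (nm) after superposition on the fit selection.

    Defaults follow the study convention: fit on non-loop backbone atoms,
    measure on the full backbone (``variant='with-loop'``) or the non-loop
    backbone (``variant='no-loop'``); the reference is the first frame.
    RMSD is unweighted over the measured atoms.
    """
    top = traj.topology
    if fit_selection is None:
        fit_selection = top.backbone(exclude_loop=True)
    if measure_selection is None:
        measure_selection = top.backbone()
    if len(measure_selection) == 0:
        raise ValueError("empty measure selection")
    if reference is None:
        reference = traj.coords[0]
    out = np.empty(traj.n_frames)
    for fi in range(traj.n_frames):
        if fit:
            _, _, moved = superpose(traj.coords[fi], reference, fit_selection)
        else:
            moved = traj.coords[fi]
        diff = moved[measure_selection] - reference[measure_selection]
        out[fi] = np.sqrt(np.mean(np.sum(diff**2, axis=1)))
    return StructureMetricSeries(metric="rmsd", values=out, times=traj.times, variant=variant)


# ---------------------------------------------------------------------------
# RMSF


def _superposed_coords(traj: Trajectory, fit_selection: np.ndarray) -> np.ndarray:
    ref = traj.coords[0]
    out = np.empty_like(traj.coords)
    for fi in range(traj.n_frames):
        _, _, out[fi] = superpose(traj.coords[fi], ref, fit_selection)
    return out


def rmsf_profile(
    traj: Trajectory,
    chain: str,
    mode: str = "raw",
    atom_names: tuple[str, ...] = BACKBONE_ATOMS,
    fit: bool = True,
) -> StructureMetricSeries:
    """Per-residue RMSF (nm) for one chain.

    ``raw``: RMSF_i = sqrt(mean_t ||x_i(t) - <x_i>||^2), averaged over the
    residue's selected atoms after superposing every frame on the chain's
    backbone.  ``pc1-filtered``: the superposed coordinates are first
    reconstructed from their projection onto the first eigenvector of the
    positional covariance (rank-1 essential-dynamics filter), then the same
    formula is applied; filtering can only remove variance, so the filtered
    profile is bounded above by the raw one.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    if mode not in ("raw", "pc1-filtered"):
        raise ValueError(f"unknown RMSF mode {mode!r}")
    top = traj.topology
    sel = top.select(chain=chain, atom_names=atom_names)
    if len(sel) == 0:
        raise ValueError(f"no atoms selected for chain {chain}")
    fit_sel = top.backbone(chain=chain) if fit else None
    coords = _superposed_coords(traj, fit_sel)[:, sel] if fit else traj.coords[:, sel]

    F = coords.shape[0]
    X = coords.reshape(F, -1)
    mean = X.mean(axis=0)
    Xc = X - mean
    if mode == "pc1-filtered":
        # First right singular vector of the centered frame matrix = first
        # covariance eigenvector; rank-1 reconstruction keeps only motion
        # along it.
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        Xc = np.outer(U[:, 0] * S[0], Vt[0])
    flucts = Xc.reshape(F, -1, 3)
    msf_atom = np.mean(np.sum(flucts**2, axis=2), axis=0)  # per atom

    resid = top.atom_resid()[sel]
    residues = np.unique(resid)
    rmsf = np.array([np.sqrt(msf_atom[resid == r].mean()) for r in residues])
    return StructureMetricSeries(
        metric=f"rmsf[{mode}]", values=rmsf, residue_index=residues, variant=mode
    )


def pool_rmsf(profiles: list[StructureMetricSeries]) -> dict:
    """Pool per-residue RMSF over chains x replicates: mean and SD (n pooled)."""
    if not profiles:
        raise ValueError("no RMSF profiles to pool")
    resid = profiles[0].residue_index
    mat = np.stack([p.values for p in profiles])
    return {
        "residue": resid,
        "mean": mat.mean(axis=0),
        "sd": mat.std(axis=0, ddof=0),
        "n": len(profiles),
    }


# ---------------------------------------------------------------------------
# Rg and COM separation


def radius_of_gyration(
    traj: Trajectory,
    selection: np.ndarray | None = None,
    variant: str = "",
) -> StructureMetricSeries:
    """Mass-weighted radius of gyration (nm) per frame over ``selection``."""
    top = traj.topology
    if selection is None:
        selection = np.arange(top.n_atoms)
    if len(selection) == 0:
        raise ValueError("empty selection for Rg")
    masses = top.atom_masses[selection]
    total = masses.sum()
    if total <= 0:
        raise ValueError("zero total mass in Rg selection")
    xyz = traj.coords[:, selection]
    com = np.einsum("fai,a->fi", xyz, masses) / total
    d2 = np.sum((xyz - com[:, None, :]) ** 2, axis=2)
    rg = np.sqrt(np.einsum("fa,a->f", d2, masses) / total)
    return StructureMetricSeries(metric="rg", values=rg, times=traj.times, variant=variant)


def com_separation(
    traj: Trajectory,
    group_a: np.ndarray,
    group_b: np.ndarray,
    variant: str = "",
) -> StructureMetricSeries:
    """Per-frame distance (nm) between mass-weighted centroids of two groups."""
    top = traj.topology
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("COM separation needs two non-empty groups")
    coms = []
    for grp in (group_a, group_b):
        m = top.atom_masses[grp]
        coms.append(np.einsum("fai,a->fi", traj.coords[:, grp], m) / m.sum())
    d = np.linalg.norm(coms[0] - coms[1], axis=1)
    return StructureMetricSeries(
        metric="com_separation", values=d, times=traj.times, variant=variant
    )
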