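"""Cysteine S-gamma separations, pooled histograms and reformability calls.

A reduced disulfide whose two S-gamma atoms stay near the bonded separation
(0.2038 nm in an intact bond) is geometrically poised to reform; the
analysis histograms the per-frame pair distances (bin width 0.01 nm),
pools both monomers across replicates (n = replicates x 2), and calls a
pair "likely to reform" when a majority of samples sit below a 0.4 nm
cutoff.  Non-native pairs (31-37 and 68-71) are screened the same way for
disulfide-interchange feasibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import NON_NATIVE_CYS_PAIRS, Trajectory

__all__ = [
    "DistanceSeries",
    "HistogramSummary",
    "sg_distances",
    "interchange_pairs",
    "pooled_histogram",
    "reformability",
]

#: S-S separation in an intact disulfide bond (nm).
INTACT_SS_DISTANCE = 0.2038

#: Default histogram bin width (nm).
DEFAULT_BIN_WIDTH = 0.01

#: Default S-gamma separation cutoff (nm) for reformability / interchange.
REFORM_CUTOFF = 0.4


@dataclass
class DistanceSeries:
    """Per-frame S-gamma distance (nm) for one pair on one chain/replicate."""

    pair: tuple[int, int]
    chain: str
    replicate: int
    distances: np.ndarray
    native: bool = True

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if np.any(self.distances < 0):
            raise ValueError("distances must be non-negative")
        if np.any(self.distances == 0):
            warnings.warn(
                f"pair {self.pair} chain {self.chain}: coincident S-gamma atoms "
                "(zero distance) in at least one frame",
                stacklevel=2,
            )

    @property
    def label(self) -> str:
        return f"{self.pair[0]}-{self.pair[1]}"


@dataclass
class HistogramSummary:
    """Per-bin mean and SD of normalized frequencies pooled over series."""

    bin_edges: np.ndarray      # (n_bins + 1,)
    mean: np.ndarray           # (n_bins,)
    sd: np.ndarray             # (n_bins,)
    n: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "mean_frequency": self.mean,
                "sd_frequency": self.sd,
                "n": self.n,
            }
        )


def sg_distances(
    traj: Trajectory,
    pairs: list[tuple[int, int]] | tuple[tuple[int, int], ...] | None = None,
    replicate: int = 0,
    native: bool = True,
) -> list[DistanceSeries]:
    """Euclidean S-gamma pair distances per chain over the trajectory.

    ``pairs`` defaults to the topology's native cysteine-pair registry.  A
    missing SG atom raises a KeyError naming the residue.
    """
    top = traj.topology
    if pairs is None:
        pairs = top.cys_pairs
    table = top.atom_table()
    out: list[DistanceSeries] = []
    for pair in pairs:
        for chain in top.chains:
            idx = []
            for resid in pair:
                key = (chain, resid, "SG")
                if key not in table:
                    raise KeyError(f"no S-gamma (SG) atom in residue {chain}:{resid}")
                idx.append(table[key])
            d = np.linalg.norm(traj.coords[:, idx[0]] - traj.coords[:, idx[1]], axis=1)
            out.append(
                DistanceSeries(
                    pair=tuple(pair), chain=chain, replicate=replicate,
                    distances=d, native=native,
                )
            )
    return out


def interchange_pairs(traj: Trajectory, replicate: int = 0) -> list[DistanceSeries]:
    """S-gamma distances for the feasible non-native pairs (31-37, 68-71)."""
    return sg_distances(traj, pairs=NON_NATIVE_CYS_PAIRS, replicate=replicate, native=False)


def pooled_histogram(
    series: list[DistanceSeries] | list[np.ndarray],
    bin_width: float = DEFAULT_BIN_WIDTH,
    sd_mode: str = "population",
) -> HistogramSummary:
    """Pool per-series normalized frequency histograms on a shared grid.

    Each series is histogrammed with uniform ``bin_width`` bins spanning
    [0, ceil(max/width)*width] and normalized so its frequencies sum to 1;
    the per-bin mean and SD across series are returned with n = number of
    pooled series.  SD is the population SD by default (``sd_mode="sample"``
    switches to the n-1 form).
    """
    if len(series) == 0:
        raise ValueError("no distance series to pool")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    arrays = [
        s.distances if isinstance(s, DistanceSeries) else np.asarray(s, dtype=float)
        for s in series
    ]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty distance series cannot be histogrammed")
    dmax = max(a.max() for a in arrays)
    n_bins = max(1, int(np.ceil(dmax / bin_width - 1e-12)))
    edges = np.arange(n_bins + 1) * bin_width
    freqs = np.empty((len(arrays), n_bins))
    for i, a in enumerate(arrays):
        counts, _ = np.histogram(a, bins=edges)
        freqs[i] = counts / a.size
    ddof = 0 if sd_mode == "population" else 1
    sd = freqs.std(axis=0, ddof=ddof) if len(arrays) > ddof else np.zeros(n_bins)
    return HistogramSummary(bin_edges=edges, mean=freqs.mean(axis=0), sd=sd, n=len(arrays))


@dataclass
class ReformabilityVerdict:
    fraction_below: float
    cutoff: float
    likely_reform: bool
    n_samples: int

    def to_dict(self) -> dict:
        return {
            "fraction_below_cutoff": self.fraction_below,
            "cutoff_nm": self.cutoff,
            "likely_reform": self.likely_reform,
            "n_samples": self.n_samples,
        }


def reformability(
    data,
    cutoff: float = REFORM_CUTOFF,
    verdict_threshold: float = 0.5,
) -> ReformabilityVerdict:
    """Fraction of S-gamma samples below ``cutoff`` plus a reform verdict.

    ``data`` may be a DistanceSeries, a list of them (pooled), or a raw
    array of distances.  The verdict is "likely reform" iff the fraction is
    at least ``verdict_threshold``; the fraction is always reported so the
    qualitative call never hides the quantity.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if isinstance(data, DistanceSeries):
        samples = data.distances
    elif isinstance(data, (list, tuple)):
        samples = np.concatenate(
            [s.distances if isinstance(s, DistanceSeries) else np.asarray(s, dtype=float)
             for s in data]
        )
    else:
        samples = np.asarray(data, dtype=float)
    if samples.size == 0:
        raise ValueError("no samples")
    frac = float(np.mean(samples < cutoff))
    return ReformabilityVerdict(
        fraction_below=frac,
        cutoff=cutoff,
        likely_reform=frac >= verdict_threshold,
        n_samples=int(samples.size),
    )
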