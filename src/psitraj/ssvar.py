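"""Secondary-structure variation index, per-residue mode, region summaries.

DSSP letters are collapsed to three classes (helical: H/G/I, beta: E/B,
disordered: T/S/C/blank/~).  The variation index counts, per residue, the
frames at which the 3-class label differs from the previous frame, and
normalizes by the maximum possible count (frames - 1, e.g. 1000 for a
1001-frame window — a change every frame).  Profiles are pooled across
monomers and replicates (mean and SD, n = chains x replicates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .traj_io import AnalysisWindow, SSCodeFrame

__all__ = [
    "SS_CLASS_OF_CODE",
    "CLASS_NAMES",
    "SSSeries",
    "VariationProfile",
    "RegionSummary",
    "classify_codes",
    "variation_index",
    "ss_mode",
    "region_summary",
    "dimer_net_variation",
]

CLASS_NAMES = ("helix", "beta", "disordered")
HELIX, BETA, DISORDERED = 0, 1, 2

#: DSSP letter -> 3-class index.  3-10 (G) and pi (I) helices count as
#: helical character; turns, bends and coil are disordered.
SS_CLASS_OF_CODE = {
    "H": HELIX, "G": HELIX, "I": HELIX,
    "E": BETA, "B": BETA,
    "T": DISORDERED, "S": DISORDERED, "C": DISORDERED,
    " ": DISORDERED, "~": DISORDERED,
}

#: Mode tie-break precedence: helix beats beta beats disordered.
MODE_PRECEDENCE = (HELIX, BETA, DISORDERED)


@dataclass
class SSSeries:
    """3-class labels, shape (n_frames, n_residues), for one chain."""

    chain: str
    classes: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=np.int8)
        self.times = np.asarray(self.times, dtype=float)
        if self.classes.ndim != 2:
            raise ValueError("classes must be (n_frames, n_residues)")
        if len(self.times) != self.classes.shape[0]:
            raise ValueError("times and classes disagree on frame count")

    @property
    def n_frames(self) -> int:
        return self.classes.shape[0]

    @property
    def n_residues(self) -> int:
        return self.classes.shape[1]


@dataclass
class VariationProfile:
    """Pooled per-residue variation: mean, SD and the raw counts per series."""

    mean: np.ndarray                 # (n_residues,) pooled mean normalized variation
    sd: np.ndarray                   # (n_residues,) pooled SD
    n: int                           # pooled series count (chains x replicates)
    raw_counts: np.ndarray           # (n_series, n_residues) integer change events
    max_theoretical: int             # frames - 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue": np.arange(1, len(self.mean) + 1),
                "mean_variation": self.mean,
                "sd_variation": self.sd,
                "n": self.n,
            }
        )


@dataclass
class RegionSummary:
    interval: tuple[int, int]
    total: float
    per_residue: float

    def to_dict(self) -> dict:
        return {
            "interval": list(self.interval),
            "total_variation": self.total,
            "per_residue_variation": self.per_residue,
        }


def classify_codes(frames: list[SSCodeFrame]) -> SSSeries:
    """Collapse a chain's DSSP code frames into a 3-class SSSeries."""
    if not frames:
        raise ValueError("no DSSP frames")
    chain = frames[0].chain
    n_res = len(frames[0].codes)
    classes = np.empty((len(frames), n_res), dtype=np.int8)
    for fi, f in enumerate(frames):
        for ri, code in enumerate(f.codes):
            try:
                classes[fi, ri] = SS_CLASS_OF_CODE[code]
            except KeyError:
                raise ValueError(f"unknown DSSP letter {code!r}") from None
    times = np.array([f.time_ps for f in frames])
    return SSSeries(chain=chain, classes=classes, times=times)


def _change_counts(series: SSSeries) -> np.ndarray:
    """Integer change events per residue (label differs from previous frame)."""
    return np.sum(series.classes[1:] != series.classes[:-1], axis=0).astype(int)


def variation_index(
    series_list: list[SSSeries] | SSSeries,
    window: AnalysisWindow | float | None = None,
) -> VariationProfile:
    """Normalized change-event rate per residue, pooled across series.

    raw_i = #frames where the 3-class label of residue i differs from the
    previous frame; normalized_i = raw_i / (frames - 1).  Pooling across the
    given series (one per chain x replicate) yields the mean and population
    SD, with n = number of series.
    """
    if isinstance(series_list, SSSeries):
        series_list = [series_list]
    if not series_list:
        raise ValueError("no SS series")
    processed = []
    for s in series_list:
        if window is not None:
            frac = window if isinstance(window, AnalysisWindow) else AnalysisWindow(float(window))
            m = frac.mask(s.times)
            s = SSSeries(chain=s.chain, classes=s.classes[m], times=s.times[m])
        if s.n_frames < 2:
            raise ValueError("variation index needs at least 2 frames in the window")
        processed.append(s)
    n_frames = {s.n_frames for s in processed}
    if len(n_frames) > 1:
        raise ValueError(f"pooled series must share frame count, got {sorted(n_frames)}")
    max_theoretical = processed[0].n_frames - 1
    raw = np.stack([_change_counts(s) for s in processed])
    norm = raw / max_theoretical
    return VariationProfile(
        mean=norm.mean(axis=0),
        sd=norm.std(axis=0, ddof=0),
        n=len(processed),
        raw_counts=raw,
        max_theoretical=max_theoretical,
    )


def ss_mode(
    series: SSSeries,
    window: AnalysisWindow | float | None = None,
) -> np.ndarray:
    """Most frequent 3-class label per residue (ties: helix > beta > disordered)."""
    classes = series.classes
    if window is not None:
        frac = window if isinstance(window, AnalysisWindow) else AnalysisWindow(float(window))
        classes = classes[frac.mask(series.times)]
    if classes.shape[0] < 1:
        raise ValueError("mode needs at least 1 frame")
    counts = np.stack([(classes == c).sum(axis=0) for c in MODE_PRECEDENCE])
    best = counts.argmax(axis=0)  # argmax picks the first max -> precedence order
    return np.array([MODE_PRECEDENCE[b] for b in best], dtype=np.int8)


def region_summary(profile: VariationProfile, interval: tuple[int, int]) -> RegionSummary:
    """Total and per-residue pooled variation over a 1-based inclusive interval."""
    lo, hi = interval
    if lo > hi or lo < 1 or hi > len(profile.mean):
        raise ValueError(f"interval {interval} outside profile of {len(profile.mean)} residues")
    vals = profile.mean[lo - 1 : hi]
    total = float(vals.sum())
    return RegionSummary(interval=(lo, hi), total=total, per_residue=total / len(vals))


def dimer_net_variation(profiles: list[VariationProfile] | VariationProfile) -> dict:
    """Net variation over the whole dimer: sum of pooled means and per-residue mean.

    Pass one pooled profile covering both chains, or a list of per-chain
    profiles to concatenate.
    """
    if isinstance(profiles, VariationProfile):
        profiles = [profiles]
    means = np.concatenate([p.mean for p in profiles])
    return {
        "sum": float(means.sum()),
        "per_residue": float(means.mean()),
        "n_residues": int(means.size),
    }
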