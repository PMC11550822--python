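"""MS1 deisotoping and cumulative precursor mass-bin histograms.

Time-resolved, deconvoluted MS1 observations are collapsed into a
one-dimensional array of 0.1-Da precursor mass bins (the "glycome
histogram"): every feature's intensity is added to the bin containing its
singly protonated monoisotopic mass, summed over the whole chromatographic
time range.  Bins are centered on a regular grid (centers lo, lo+w, ...;
membership [center-w/2, center+w/2)), so a printed bin mass like 2371.9
covers [2371.85, 2371.95).

A deliberately simple greedy deisotoper converts centroided MS1 scans into
features for fully synthetic inputs; externally deconvoluted feature tables
can be imported instead via :func:`glycosnog.spectra_io.read_feature_csv`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .glycomass import PROTON
from .spectra_io import Ms1Feature, Ms1Scan

__all__ = [
    "ISOTOPE_SPACING",
    "BinGrid",
    "MassHistogram",
    "deisotope_scan",
    "accumulate",
    "threshold",
    "tic_normalize",
    "eic",
]

log = logging.getLogger(__name__)

ISOTOPE_SPACING = 1.00235  # Da, average mass difference between isotopologues


@dataclass(frozen=True)
class BinGrid:
    """Regular precursor-mass bin grid (default 0.1-Da bins over 1000-5000 Da)."""

    lo: float = 1000.0
    hi: float = 5000.0
    width: float = 0.1

    def __post_init__(self) -> None:
        if not (self.lo < self.hi and self.width > 0):
            raise ValueError("require lo < hi and width > 0")

    @property
    def n_bins(self) -> int:
        return int(round((self.hi - self.lo) / self.width))

    def center(self, k: int) -> float:
        return self.lo + k * self.width

    def index_of(self, mh: float) -> int | None:
        """Bin index containing mh, or None if outside the grid."""
        k = int(np.floor((mh - self.lo + self.width / 2) / self.width))
        return k if 0 <= k < self.n_bins else None


@dataclass
class MassHistogram:
    """Cumulative per-bin intensity over a BinGrid for one sample."""

    grid: BinGrid
    intensity: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (self.grid.n_bins,):
            raise ValueError(
                f"intensity length {self.intensity.shape} != bin count {self.grid.n_bins}"
            )
        if (self.intensity < 0).any():
            raise ValueError("negative bin intensity")

    @property
    def tic(self) -> float:
        return float(self.intensity.sum())

    def centers(self) -> np.ndarray:
        return self.grid.lo + np.arange(self.grid.n_bins) * self.grid.width


def deisotope_scan(scan: Ms1Scan, max_charge: int = 6, tol: float = 0.01,
                   max_isotopes: int = 5, max_ratio: float = 1.4) -> list[Ms1Feature]:
    """Greedy isotope-envelope search on one centroided scan.

    Peaks are visited in order of descending intensity.  For each unassigned
    apex peak and each charge z in 1..max_charge, isotopologues are sought
    at apex ± k*(1.00235/z) within ``tol`` (k up to ``max_isotopes`` in each
    direction): rightward to higher isotopes and leftward toward the
    monoisotopic peak, which for heavier analytes is not the most intense
    member of the envelope.  Envelopes are assumed unimodal, so walking away
    from the apex each member may be at most ``max_ratio`` times its
    predecessor (the first rightward step is unconstrained).  The charge
    matching the most isotopes wins (ties go to the lower charge); envelopes
    need at least 2 peaks.  Each accepted envelope yields one feature with
    mh = z*mz_mono - (z-1)*proton computed from the leftmost (monoisotopic)
    member and the summed envelope intensity; members are marked assigned.
    Unassignable peaks are dropped and counted.
    """
    n = len(scan.mz)
    assigned = np.zeros(n, dtype=bool)
    order = np.argsort(scan.intensity)[::-1]
    features: list[Ms1Feature] = []

    def _find(mz_target: float, exclude: list[int]) -> int | None:
        lo = np.searchsorted(scan.mz, mz_target - tol, side="left")
        hi = np.searchsorted(scan.mz, mz_target + tol, side="right")
        best, best_int = None, -1.0
        for j in range(lo, hi):
            if not assigned[j] and j not in exclude and scan.intensity[j] > best_int:
                best, best_int = j, scan.intensity[j]
        return best

    for i in order:
        if assigned[i]:
            continue
        best_members: list[int] = []
        best_z = 0
        for z in range(1, max_charge + 1):
            spacing = ISOTOPE_SPACING / z
            members = [int(i)]
            prev_int = scan.intensity[i]
            for k in range(1, max_isotopes + 1):  # toward higher isotopes
                j = _find(scan.mz[i] + k * spacing, members)
                if j is None:
                    break
                if k > 1 and scan.intensity[j] > max_ratio * prev_int:
                    break
                members.append(j)
                prev_int = scan.intensity[j]
            prev_int = scan.intensity[i]
            for k in range(1, max_isotopes + 1):  # toward the monoisotopic peak
                j = _find(scan.mz[i] - k * spacing, members)
                if j is None:
                    break
                if scan.intensity[j] > max_ratio * prev_int:
                    break
                members.insert(0, j)
                prev_int = scan.intensity[j]
            if len(members) > len(best_members):  # strict: ties keep lower z
                best_members, best_z = members, z
        if len(best_members) >= 2:
            assigned[best_members] = True
            mono_mz = scan.mz[min(best_members, key=lambda j: scan.mz[j])]
            mh = best_z * mono_mz - (best_z - 1) * PROTON
            features.append(
                Ms1Feature(
                    mh=float(mh),
                    rt=scan.rt,
                    intensity=float(scan.intensity[best_members].sum()),
                    charge=best_z,
                )
            )
    n_dropped = int((~assigned).sum())
    if n_dropped:
        log.debug("deisotope_scan rt=%.1f: %d unassignable peak(s) dropped",
                  scan.rt, n_dropped)
    return features


def accumulate(features: Iterable[Ms1Feature], grid: BinGrid | None = None,
               sample_id: str = "") -> MassHistogram:
    """Sum feature intensities into mass bins across the whole time range.

    Features outside the grid are dropped (and counted in the log); the
    histogram total equals the summed intensity of in-range features exactly.
    """
    if grid is None:
        grid = BinGrid()
    intensity = np.zeros(grid.n_bins)
    n_dropped = 0
    for f in features:
        k = grid.index_of(f.mh)
        if k is None:
            n_dropped += 1
            continue
        intensity[k] += f.intensity
    if n_dropped:
        log.info("accumulate[%s]: dropped %d feature(s) outside [%g, %g)",
                 sample_id, n_dropped, grid.lo, grid.hi)
    return MassHistogram(grid=grid, intensity=intensity, sample_id=sample_id)


def threshold(h: MassHistogram, min_intensity: float = 5e6) -> MassHistogram:
    """Zero all bins with cumulative intensity strictly below ``min_intensity``."""
    if min_intensity < 0:
        raise ValueError("min_intensity must be non-negative")
    kept = np.where(h.intensity >= min_intensity, h.intensity, 0.0)
    n_removed = int(((h.intensity > 0) & (kept == 0)).sum())
    if n_removed:
        log.info("threshold[%s]: removed %d bin(s) below %.3g",
                 h.sample_id, n_removed, min_intensity)
    return MassHistogram(grid=h.grid, intensity=kept, sample_id=h.sample_id)


def tic_normalize(h: MassHistogram) -> MassHistogram:
    """Scale bin intensities to sum to 1."""
    total = h.tic
    if total <= 0:
        raise ValueError(f"cannot TIC-normalize zero-intensity histogram {h.sample_id!r}")
    return MassHistogram(grid=h.grid, intensity=h.intensity / total, sample_id=h.sample_id)


def eic(features: Iterable[Ms1Feature], target_mh: float, tol: float = 0.05):
    """Extracted ion chromatogram: time-ordered (rt, intensity) arrays.

    Features whose mh lies within ±tol of the target contribute; intensities
    of features sharing a retention time are summed.  Empty trace if none.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    pts: dict[float, float] = {}
    for f in features:
        if abs(f.mh - target_mh) <= tol:
            pts[f.rt] = pts.get(f.rt, 0.0) + f.intensity
    if not pts:
        return np.array([]), np.array([])
    rts = np.array(sorted(pts))
    return rts, np.array([pts[t] for t in rts])
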