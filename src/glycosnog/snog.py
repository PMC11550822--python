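"""Diagnostic-ion detection, SNOG/eSNOG scoring and spectral counting.

The SNOG score of an MS/MS spectrum is the intensity of the reduced-end
HexNAc oxonium ion (alditol GlcNAc fragment, ~224.11 m/z) divided by the
total ion current of the spectrum.  Spectra of chemically reduced glycans
produce this fragment prominently, so spectra with SNOG above an empirical
cutoff (default 0.03, strictly greater) are deemed glycan-derived.

eSNOG extends the same relative-intensity score to sub-structure-specific
diagnostic ions (sialic-acid variants, distal fucose, alpha-Gal, bisecting
GlcNAc, rare epitopes); ions of one category pool their matched intensities,
and a category is flagged when its pooled score reaches the category
threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .glycomass import REDUCED_HEXNAC_MZ, DiagnosticIon, default_registry
from .spectra_io import MsmsSpectrum

__all__ = [
    "DEFAULT_TOL",
    "DEFAULT_SNOG_CUT",
    "IonMatch",
    "SpectrumScore",
    "matched_intensity",
    "snog_score",
    "esnog_scores",
    "score_spectra",
    "filter_spectra",
    "count_diagnostic",
    "rt_count_histogram",
]

log = logging.getLogger(__name__)

DEFAULT_TOL = 0.05  # amu, fragment-ion matching tolerance
DEFAULT_SNOG_CUT = 0.03


@dataclass(frozen=True)
class IonMatch:
    ion: DiagnosticIon
    matched_mz: float  # 0 if no peak matched
    matched_intensity: float  # 0 if no peak matched


@dataclass
class SpectrumScore:
    """SNOG and per-category eSNOG scores for one spectrum."""

    scan_id: str
    snog: float
    esnog: dict[str, float]
    flags: set[str]
    mh: float | None = None  # singly protonated precursor mass, if known
    rt: float = 0.0


def matched_intensity(s: MsmsSpectrum, mz: float, tol: float = DEFAULT_TOL) -> IonMatch:
    """Maximum-intensity peak within ``[mz - tol, mz + tol]``.

    Returns an IonMatch with zero intensity when no peak falls in the window.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    ion = DiagnosticIon(label=f"query-{mz:.4f}", mz=mz)
    lo = np.searchsorted(s.mz, mz - tol, side="left")
    hi = np.searchsorted(s.mz, mz + tol, side="right")
    if hi <= lo:
        return IonMatch(ion, 0.0, 0.0)
    window = s.intensity[lo:hi]
    k = int(np.argmax(window))
    return IonMatch(ion, float(s.mz[lo + k]), float(window[k]))


def snog_score(s: MsmsSpectrum, tol: float = DEFAULT_TOL,
               denominator: str = "tic") -> float:
    """SNOG score: reduced-HexNAc ion intensity over total spectrum intensity.

    ``denominator`` may be ``"tic"`` (default) or ``"base_peak"``.
    All-zero spectra score 0.
    """
    total = s.tic if denominator == "tic" else float(s.intensity.max(initial=0.0))
    if total <= 0:
        return 0.0
    return matched_intensity(s, REDUCED_HEXNAC_MZ, tol).matched_intensity / total


def esnog_scores(s: MsmsSpectrum, registry: Sequence[DiagnosticIon] | None = None,
                 tol: float = DEFAULT_TOL) -> SpectrumScore:
    """Per-category eSNOG scores and threshold flags for one spectrum.

    Each category's score is the sum of its ions' matched intensities over
    the spectrum TIC; ions of a category (e.g. Neu5Ac with and without water
    loss) act as pooled, alternative reporters of the same sub-structure.
    """
    if registry is None:
        registry = default_registry()
    if not registry:
        raise ValueError("registry must be non-empty")
    total = s.tic
    esnog: dict[str, float] = {}
    thresholds: dict[str, float] = {}
    for ion in registry:
        if ion.category in ("generic", "reduced_hexnac"):
            continue
        hit = matched_intensity(s, ion.mz, tol)
        esnog[ion.category] = esnog.get(ion.category, 0.0) + hit.matched_intensity
        thresholds[ion.category] = min(
            thresholds.get(ion.category, 1.0), ion.esnog_threshold
        )
    if total > 0:
        esnog = {c: v / total for c, v in esnog.items()}
    else:
        esnog = {c: 0.0 for c in esnog}
    flags = {c for c, v in esnog.items() if v >= thresholds[c] and v > 0}
    return SpectrumScore(
        scan_id=s.scan_id,
        snog=snog_score(s, tol),
        esnog=esnog,
        flags=flags,
        rt=s.rt,
    )


def score_spectra(spectra: Iterable[MsmsSpectrum],
                  registry: Sequence[DiagnosticIon] | None = None,
                  tol: float = DEFAULT_TOL) -> list[SpectrumScore]:
    """Score all spectra, attaching the precursor mh where the charge is known."""
    from .spectra_io import UnknownChargeError, precursor_mh

    scores = []
    n_unknown = 0
    for s in spectra:
        sc = esnog_scores(s, registry, tol)
        try:
            sc.mh = precursor_mh(s)
        except UnknownChargeError:
            sc.mh = None
            n_unknown += 1
        scores.append(sc)
    if n_unknown:
        log.info("score_spectra: %d spectra with unknown charge (no precursor mass)",
                 n_unknown)
    return scores


def filter_spectra(spectra: Sequence[MsmsSpectrum],
                   snog_cut: float = DEFAULT_SNOG_CUT,
                   tol: float = DEFAULT_TOL):
    """Partition spectra into (kept, rejected) by SNOG strictly greater than the cut."""
    if not 0.0 <= snog_cut <= 1.0:
        raise ValueError("snog_cut must lie in [0, 1]")
    kept, rejected = [], []
    for s in spectra:
        (kept if snog_score(s, tol) > snog_cut else rejected).append(s)
    log.info("filter_spectra: kept %d / rejected %d of %d spectra (cut %.3g)",
             len(kept), len(rejected), len(spectra), snog_cut)
    return kept, rejected


def count_diagnostic(spectra: Iterable[MsmsSpectrum],
                     categories: Sequence[str] | None = None,
                     registry: Sequence[DiagnosticIon] | None = None,
                     tol: float = DEFAULT_TOL,
                     require_224: bool = True):
    """Binary per-spectrum counting of diagnostic-ion categories.

    A spectrum counts toward a category if any of that category's registry
    ions has a matched peak (presence, not intensity).  With ``require_224``
    (the default) only spectra containing the reduced-HexNAc ion participate,
    and the returned total is the number of such glycan spectra.

    Returns ``(counts, total_glycan_count)``.
    """
    if registry is None:
        registry = default_registry()
    by_cat: dict[str, list[DiagnosticIon]] = {}
    for ion in registry:
        if ion.category in ("generic", "reduced_hexnac"):
            continue
        by_cat.setdefault(ion.category, []).append(ion)
    if categories is None:
        categories = sorted(by_cat)
    counts = {c: 0 for c in categories}
    total = 0
    for s in spectra:
        has_224 = matched_intensity(s, REDUCED_HEXNAC_MZ, tol).matched_intensity > 0
        if require_224 and not has_224:
            continue
        total += 1
        for cat in categories:
            ions = by_cat.get(cat, [])
            if any(matched_intensity(s, ion.mz, tol).matched_intensity > 0 for ion in ions):
                counts[cat] += 1
    return counts, total


def rt_count_histogram(spectra: Iterable[MsmsSpectrum],
                       registry: Sequence[DiagnosticIon] | None = None,
                       bin_width: float = 10.0,
                       tol: float = DEFAULT_TOL) -> dict[float, dict[str, int]]:
    """Per-retention-time-bin counts of spectra containing each diagnostic ion.

    Bins are left-closed ``[k*bin_width, (k+1)*bin_width)``; the mapping key
    is the bin's left edge.  Each bin additionally carries a ``total``
    spectrum count, so bin totals conserve the number of input spectra.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if registry is None:
        registry = default_registry()
    out: dict[float, dict[str, int]] = {}
    for s in spectra:
        key = float(np.floor(s.rt / bin_width) * bin_width)
        row = out.setdefault(key, {"total": 0})
        row["total"] += 1
        for ion in registry:
            if matched_intensity(s, ion.mz, tol).matched_intensity > 0:
                row[ion.label] = row.get(ion.label, 0) + 1
    return dict(sorted(out.items()))
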