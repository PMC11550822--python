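"""Glycome assembly: MS/MS-to-mass-bin alignment, stratification, annotation.

The reconstructed glycome is the set of 0.1-Da precursor mass bins that
(i) exceed the cumulative MS1 intensity threshold and (ii) carry at least
one attached MS/MS spectrum with SNOG score above the cut — the evidence
that the precursor really is a reduced glycan.  Glycan bins are then
stratified into sub-structural categories from the eSNOG flags of their
spectra, and annotated with candidate compositions from an in-silico
composition database by mass match within ±0.05 Da.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .glycomass import GlycanComposition, reduced_glycan_mh
from .ms1_profile import MassHistogram
from .snog import DEFAULT_SNOG_CUT, SpectrumScore

__all__ = [
    "MassBin",
    "GlycoDB",
    "GlycoDbConstraints",
    "CategoryProfile",
    "DECORATED_CATEGORIES",
    "attach_msms",
    "assign_flags",
    "stratify",
    "build_glycodb",
    "annotate",
    "unknown_fraction",
]

log = logging.getLogger(__name__)

# Categories that make a glycan bin "decorated"; a glycan bin carrying none
# of these is classified undecorated.
DECORATED_CATEGORIES = frozenset(
    {"distal_fucose", "NeuAc", "NeuGc", "alpha_gal", "oligomannose"}
)


@dataclass
class MassBin:
    """One occupied precursor mass bin of the reconstructed glycome."""

    center_mh: float
    intensity: float
    spectra: list[SpectrumScore] = field(default_factory=list)
    categories: set[str] = field(default_factory=set)
    annotations: list[tuple[GlycanComposition, float]] = field(default_factory=list)
    is_glycan: bool = False
    ambiguous: bool = False

    @property
    def best_annotation(self) -> GlycanComposition | None:
        return self.annotations[0][0] if self.annotations else None

    @property
    def is_unknown(self) -> bool:
        return self.is_glycan and not self.annotations


@dataclass
class GlycoDbConstraints:
    """Composition-enumeration rule set for the in-silico glycan database.

    Ranges are inclusive.  Biosynthetic constraints: at least the two core
    HexNAc; sialic acids at most one per antenna (HexNAc - 2); fucoses at
    most HexNAc + 1 (core plus one per antennary HexNAc).
    """

    hex_range: tuple[int, int] = (3, 12)
    hexnac_range: tuple[int, int] = (2, 8)
    fuc_range: tuple[int, int] = (0, 6)
    sia_range: tuple[int, int] = (0, 5)  # Neu5Ac + Neu5Gc combined

    def __post_init__(self) -> None:
        for name in ("hex_range", "hexnac_range", "fuc_range", "sia_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"invalid {name}: ({lo}, {hi})")
        if self.hexnac_range[0] < 2:
            raise ValueError("N-glycans require at least 2 core HexNAc")


@dataclass
class GlycoDB:
    """In-silico composition database: (composition, reduced [M+H]+) entries."""

    entries: list[tuple[GlycanComposition, float]]
    constraints: GlycoDbConstraints

    @property
    def n_entries(self) -> int:
        return len(self.entries)

    def n_mass_bins(self, width: float = 0.1) -> int:
        """Number of distinct precursor mass bins covered on a 0.1-Da grid."""
        return len({int(np.floor(mh / width)) for _, mh in self.entries})


@dataclass
class CategoryProfile:
    """Per-sample TIC fractions of sub-structural categories (multi-label)."""

    sample_id: str
    fractions: dict[str, float]
    bin_counts: dict[str, int] = field(default_factory=dict)


def attach_msms(h: MassHistogram, scored: Iterable[SpectrumScore],
                snog_cut: float = DEFAULT_SNOG_CUT) -> list[MassBin]:
    """Align scored MS/MS spectra to the occupied bins of a thresholded histogram.

    Each spectrum with a known precursor mass is attached to the bin
    containing it; a bin is a glycan bin iff at least one attached spectrum
    has SNOG strictly greater than the cut.  Spectra outside the grid (or
    with unknown precursor mass) are logged and skipped.
    """
    grid = h.grid
    occupied = {k: MassBin(center_mh=grid.center(k), intensity=float(v))
                for k, v in enumerate(h.intensity) if v > 0}
    n_skipped = 0
    for sc in scored:
        if sc.mh is None:
            n_skipped += 1
            continue
        k = grid.index_of(sc.mh)
        if k is None or k not in occupied:
            n_skipped += 1
            continue
        occupied[k].spectra.append(sc)
    for b in occupied.values():
        b.is_glycan = any(sc.snog > snog_cut for sc in b.spectra)
    bins = [occupied[k] for k in sorted(occupied)]
    n_glycan = sum(b.is_glycan for b in bins)
    log.info("attach_msms[%s]: %d occupied bins, %d glycan bins retained, "
             "%d bins rejected, %d spectra unattached",
             h.sample_id, len(bins), n_glycan, len(bins) - n_glycan, n_skipped)
    return bins


def _is_oligomannose(c: GlycanComposition) -> bool:
    return (
        c["HexNAc"] == 2
        and 4 <= c["Hex"] <= 12
        and c.total_residues == c["Hex"] + 2
        and c.n_sulfate == 0
        and c.n_acetyl == 0
    )


def assign_flags(bins: Sequence[MassBin],
                 snog_cut: float = DEFAULT_SNOG_CUT) -> list[MassBin]:
    """Set each glycan bin's categories to the union of its passing spectra's flags.

    Existential rule: one attached spectrum passing the SNOG cut and flagging
    a category suffices for the bin to carry it.
    """
    for b in bins:
        if b.is_glycan:
            passing = [sc.flags for sc in b.spectra if sc.snog > snog_cut]
            b.categories = set().union(*passing) if passing else set()
        else:
            b.categories = set()
    return list(bins)


def stratify(bins: Sequence[MassBin], sample_id: str = "",
             snog_cut: float = DEFAULT_SNOG_CUT) -> CategoryProfile:
    """Per-bin category sets and intensity-weighted category fractions.

    A glycan bin's categories are the union of the eSNOG flags of its
    passing spectra; oligomannose is assigned from the best annotation
    (HexNAc2 Hex4-12, nothing else) since no diagnostic fragment singles it
    out, and takes precedence over undecorated.  Undecorated = glycan bin
    carrying none of the decorated categories.  Fractions are per category:
    summed intensity of bins carrying it over summed glycan-bin intensity
    (multi-label, so fractions need not sum to 1).
    """
    glycan_bins = [b for b in bins if b.is_glycan]
    for b in glycan_bins:
        if not b.categories:
            passing = [sc.flags for sc in b.spectra if sc.snog > snog_cut]
            b.categories = set().union(*passing) if passing else set()
        b.categories.discard("undecorated")
        if b.best_annotation is not None and _is_oligomannose(b.best_annotation):
            b.categories.add("oligomannose")
        if not b.categories & DECORATED_CATEGORIES:
            b.categories.add("undecorated")
    total = sum(b.intensity for b in glycan_bins)
    all_cats = set().union(*(b.categories for b in glycan_bins)) if glycan_bins else set()
    fractions = {}
    bin_counts = {}
    for cat in sorted(all_cats):
        carrying = [b for b in glycan_bins if cat in b.categories]
        fractions[cat] = (sum(b.intensity for b in carrying) / total) if total else 0.0
        bin_counts[cat] = len(carrying)
    return CategoryProfile(sample_id=sample_id, fractions=fractions, bin_counts=bin_counts)


def build_glycodb(constraints: GlycoDbConstraints | None = None) -> GlycoDB:
    """Enumerate canonical N-glycan compositions under biosynthetic constraints.

    Defaults: Hex 3-12, HexNAc 2-8, Fuc 0-6, Neu5Ac+Neu5Gc 0-5, subject to
    sialic acids <= max(HexNAc-2, 0) and Fuc <= HexNAc+1.  Entries are
    deduplicated by composition and sorted by mass.
    """
    c = constraints or GlycoDbConstraints()
    entries: dict[GlycanComposition, float] = {}
    for n_hex in range(c.hex_range[0], c.hex_range[1] + 1):
        for n_hexnac in range(c.hexnac_range[0], c.hexnac_range[1] + 1):
            max_fuc = min(c.fuc_range[1], n_hexnac + 1)
            max_sia = min(c.sia_range[1], max(n_hexnac - 2, 0))
            for n_fuc in range(c.fuc_range[0], max_fuc + 1):
                for n_sia in range(c.sia_range[0], max_sia + 1):
                    for n_ac in range(n_sia + 1):
                        n_gc = n_sia - n_ac
                        comp = GlycanComposition({
                            "Hex": n_hex, "HexNAc": n_hexnac, "dHex": n_fuc,
                            "Neu5Ac": n_ac, "Neu5Gc": n_gc,
                        })
                        entries.setdefault(comp, reduced_glycan_mh(comp))
    ordered = sorted(entries.items(), key=lambda kv: kv[1])
    db = GlycoDB(entries=ordered, constraints=c)
    log.info("glycoDB: %d compositions, %d distinct 0.1-Da mass bins",
             db.n_entries, db.n_mass_bins())
    return db


def _flag_consistency(c: GlycanComposition, flags: set[str]) -> int:
    """How many residue-implying eSNOG flags the composition satisfies."""
    implied = {
        "NeuAc": c["Neu5Ac"] > 0,
        "NeuGc": c["Neu5Gc"] > 0,
        "distal_fucose": c["dHex"] > 0,
        "lewisY": c["dHex"] >= 2,
        "hnk1": c["HexA"] > 0,
        "hnk1_sulfo": c["HexA"] > 0 and c.n_sulfate > 0,
        "sulfo_hexnac": c.n_sulfate > 0,
        "ac_neuac": c["Neu5Ac"] > 0 and c.n_acetyl > 0,
        "ac_neugc": c["Neu5Gc"] > 0 and c.n_acetyl > 0,
    }
    return sum(1 for f in flags if implied.get(f, False))


def annotate(bins: Sequence[MassBin], db: GlycoDB, tol: float = 0.05) -> list[MassBin]:
    """Attach all database compositions within ±tol of each glycan bin center.

    Candidates are ordered by consistency with the bin's eSNOG flags (exact
    isobars such as Neu5Gc+Fuc vs Neu5Ac+Hex are resolved this way), then by
    |mass delta|.  Bins with no candidate remain unknown; unresolved isobar
    ties keep all candidates and set the ambiguous flag.
    """
    if not db.entries:
        raise ValueError("composition database is empty")
    masses = np.array([mh for _, mh in db.entries])
    for b in bins:
        if not b.is_glycan:
            b.annotations = []
            continue
        lo = np.searchsorted(masses, b.center_mh - tol, side="left")
        hi = np.searchsorted(masses, b.center_mh + tol, side="right")
        cands = [(db.entries[j][0], db.entries[j][1] - b.center_mh) for j in range(lo, hi)]
        cands.sort(key=lambda cd: (-_flag_consistency(cd[0], b.categories), abs(cd[1])))
        b.annotations = cands
        b.ambiguous = (
            len(cands) >= 2
            and _flag_consistency(cands[0][0], b.categories)
            == _flag_consistency(cands[1][0], b.categories)
            and abs(abs(cands[0][1]) - abs(cands[1][1])) < 1e-6
        )
    return list(bins)


def unknown_fraction(bins: Sequence[MassBin]) -> float:
    """TIC fraction of glycan bins with no composition annotation."""
    glycan = [b for b in bins if b.is_glycan]
    total = sum(b.intensity for b in glycan)
    if total <= 0:
        raise ValueError("no glycan TIC: cannot compute unknown fraction")
    return sum(b.intensity for b in glycan if b.is_unknown) / total
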