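"""Monoisotopic mass engine for reduced N-glycans and B-type oxonium fragments.

All glycan masses in this package derive from a small table of monoisotopic
atomic masses and fixed elemental compositions of the anhydro monosaccharide
residues.  Released N-glycans are assumed to be chemically reduced to the
alditol form (sodium borohydride), so the intact-glycan ion is
``[M_red + H]+ = sum(residues) + H2O + 2H + proton``.

The module also ships the diagnostic-ion registry: the set of oxonium-ion
m/z values used for glycan-spectrum identification and sub-structural
classification, each tagged with a category and an eSNOG intensity threshold.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "MONOSACCHARIDES",
    "PROTON",
    "WATER",
    "REDUCTION",
    "SULFATE",
    "ACETYL",
    "GlycanComposition",
    "DiagnosticIon",
    "residue_mass",
    "reduced_glycan_mh",
    "oxonium_mz",
    "parse_composition",
    "format_composition",
    "default_registry",
    "load_registry",
    "save_registry",
    "REDUCED_HEXNAC_MZ",
    "MAN5_MH",
]

# IUPAC monoisotopic atomic masses (full precision; residue masses are always
# derived from these, never hard-coded).
_ATOMIC = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
}

PROTON = 1.00727646688  # mass of H+ (H atom minus electron)
WATER = 2 * _ATOMIC["H"] + _ATOMIC["O"]
REDUCTION = 2 * _ATOMIC["H"]  # alditol: open-ring reduced end gains 2 H
SULFATE = _ATOMIC["S"] + 3 * _ATOMIC["O"]  # +SO3 (esterified sulfate)
ACETYL = 2 * _ATOMIC["C"] + 2 * _ATOMIC["H"] + _ATOMIC["O"]  # +C2H2O (O-acetyl)

# Anhydro residue elemental compositions.
_RESIDUE_FORMULAE: dict[str, dict[str, int]] = {
    "Hex": {"C": 6, "H": 10, "O": 5},
    "HexNAc": {"C": 8, "H": 13, "N": 1, "O": 5},
    "dHex": {"C": 6, "H": 10, "O": 4},
    "Neu5Ac": {"C": 11, "H": 17, "N": 1, "O": 8},
    "Neu5Gc": {"C": 11, "H": 17, "N": 1, "O": 9},
    "HexA": {"C": 6, "H": 8, "O": 6},
}


def _formula_mass(formula: Mapping[str, int]) -> float:
    return sum(_ATOMIC[el] * n for el, n in formula.items())


_RESIDUE_MASSES = {name: _formula_mass(f) for name, f in _RESIDUE_FORMULAE.items()}

MONOSACCHARIDES = tuple(_RESIDUE_MASSES)


class VocabularyError(KeyError):
    """Unknown monosaccharide name."""


class CompositionError(ValueError):
    """Invalid glycan composition."""


def residue_mass(name: str) -> float:
    """Monoisotopic mass of an anhydro monosaccharide residue in Da."""
    try:
        return _RESIDUE_MASSES[name]
    except KeyError:
        raise VocabularyError(
            f"unknown monosaccharide {name!r}; known: {', '.join(MONOSACCHARIDES)}"
        ) from None


@dataclass(frozen=True)
class GlycanComposition:
    """Monosaccharide count vector with optional sulfate / O-acetyl counts.

    ``counts`` maps canonical residue names (``Hex``, ``HexNAc``, ``dHex``,
    ``Neu5Ac``, ``Neu5Gc``, ``HexA``) to non-negative integers.  ``n_acetyl``
    counts O-acetyl groups on sialic acids and may not exceed the number of
    sialic acid residues.
    """

    counts: Mapping[str, int]
    n_sulfate: int = 0
    n_acetyl: int = 0

    def __post_init__(self) -> None:
        clean = {}
        for name, n in self.counts.items():
            if name not in _RESIDUE_MASSES:
                raise VocabularyError(f"unknown monosaccharide {name!r}")
            if n < 0:
                raise CompositionError(f"negative count for {name}")
            if n:
                clean[name] = int(n)
        object.__setattr__(self, "counts", clean)
        if self.n_sulfate < 0 or self.n_acetyl < 0:
            raise CompositionError("modification counts must be non-negative")
        if self.total_residues < 1:
            raise CompositionError("composition must contain at least one residue")
        n_sia = clean.get("Neu5Ac", 0) + clean.get("Neu5Gc", 0)
        if self.n_acetyl > n_sia:
            raise CompositionError(
                f"n_acetyl={self.n_acetyl} exceeds sialic acid count {n_sia}"
            )

    @property
    def total_residues(self) -> int:
        return sum(self.counts.values())

    def __getitem__(self, name: str) -> int:
        return self.counts.get(name, 0)

    def residue_sum(self) -> float:
        """Sum of anhydro residue masses plus modification masses, in Da."""
        m = sum(_RESIDUE_MASSES[name] * n for name, n in self.counts.items())
        return m + self.n_sulfate * SULFATE + self.n_acetyl * ACETYL

    def __str__(self) -> str:
        return format_composition(self)

    def __hash__(self) -> int:
        return hash((frozenset(self.counts.items()), self.n_sulfate, self.n_acetyl))


def reduced_glycan_mh(c: GlycanComposition) -> float:
    """[M+H]+ of the chemically reduced (alditol) glycan, in Da.

    Residue masses + H2O (ring closure of the free glycan) + 2H (borohydride
    reduction) + one proton.
    """
    return c.residue_sum() + WATER + REDUCTION + PROTON


def oxonium_mz(c: GlycanComposition, reduced_end: bool = False) -> float:
    """Singly protonated fragment-ion m/z for a glycan sub-composition.

    Non-reducing-end B-type oxonium ions are bare residue sums plus a proton.
    Fragments that retain the reduced (alditol) end additionally carry the
    water and the two reduction hydrogens of the intact glycan.
    """
    m = c.residue_sum() + PROTON
    if reduced_end:
        m += WATER + REDUCTION
    return m


# ---------------------------------------------------------------------------
# Composition string grammar

# order matters: longest tokens first so e.g. "HexNAc" is not read as "Hex"
_TOKEN_RE = re.compile(r"(HexNAc|HexA|Hex|Neu5Ac|Neu5Gc|dHex|Fuc|SO4|Ac)(\d+)")

_CANONICAL_ORDER = ("Hex", "HexNAc", "Fuc", "Neu5Ac", "Neu5Gc", "HexA")


class ParseError(ValueError):
    """Composition string does not match the token grammar."""


def parse_composition(s: str) -> GlycanComposition:
    """Parse a composition string like ``"Hex5HexNAc4Fuc1Neu5Ac2"``.

    ``Fuc`` and ``dHex`` are accepted as synonyms (canonical output uses
    ``Fuc``); ``SO4``/``Ac`` tokens set the sulfate / O-acetyl counts.
    Underscore-separated variants (``Hex_5_HexNAc_4_``) are tolerated.
    """
    compact = s.replace("_", "").strip()
    counts: dict[str, int] = {}
    n_sulfate = 0
    n_acetyl = 0
    pos = 0
    while pos < len(compact):
        m = _TOKEN_RE.match(compact, pos)
        if m is None:
            raise ParseError(f"cannot parse composition {s!r} at {compact[pos:pos+8]!r}")
        token, num = m.group(1), int(m.group(2))
        if token == "SO4":
            n_sulfate += num
        elif token == "Ac":
            n_acetyl += num
        else:
            name = "dHex" if token == "Fuc" else token
            counts[name] = counts.get(name, 0) + num
        pos = m.end()
    return GlycanComposition(counts, n_sulfate=n_sulfate, n_acetyl=n_acetyl)


def format_composition(c: GlycanComposition) -> str:
    """Canonical composition string (dHex printed as Fuc)."""
    parts = []
    for name in _CANONICAL_ORDER:
        key = "dHex" if name == "Fuc" else name
        n = c[key]
        if n:
            parts.append(f"{name}{n}")
    if c.n_sulfate:
        parts.append(f"SO4{c.n_sulfate}")
    if c.n_acetyl:
        parts.append(f"Ac{c.n_acetyl}")
    return "".join(parts)


# Frequently needed reference ions / masses.
REDUCED_HEXNAC_MZ = oxonium_mz(GlycanComposition({"HexNAc": 1}), reduced_end=True)
MAN5_MH = reduced_glycan_mh(parse_composition("Hex5HexNAc2"))


# ---------------------------------------------------------------------------
# Diagnostic-ion registry


@dataclass(frozen=True)
class DiagnosticIon:
    """One diagnostic fragment ion: m/z, category tag, eSNOG threshold."""

    label: str
    mz: float
    category: str = "generic"
    esnog_threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("mz must be positive")
        if not 0.0 <= self.esnog_threshold <= 1.0:
            raise ValueError("esnog_threshold must lie in [0, 1]")


# Default eSNOG thresholds by ion class: single-residue sialic-acid ions are
# intense when present (0.01); di/tri-saccharide epitope ions weaker (0.005);
# large or modified-sialic ions weakest (0.002).  Declared data, overridable.
_T_SIA = 0.01
_T_MED = 0.005
_T_LOW = 0.002

# The 49 diagnostic oxonium m/z values used for MS/MS filtering, verbatim as
# printed (matching tolerance ±0.05 amu absorbs rounding conventions).  Ions
# with an established sub-structural assignment carry a category tag; the
# remainder are generic glycan-evidence ions.
_DEFAULT_REGISTRY: tuple[tuple[str, float, str, float], ...] = (
    ("dHex-ol", 167.0914, "generic", 0.0),
    ("Hex-ol", 183.0863, "generic", 0.0),
    ("HexNAc", 204.0867, "generic", 0.0),
    ("HexNAc+H2O", 222.0972, "generic", 0.0),
    ("HexNAc-ol", 224.1118, "reduced_hexnac", 0.03),
    ("unassigned-243", 243.0264, "generic", 0.0),
    ("Neu5Ac-H2O", 274.0921, "NeuAc", _T_SIA),
    ("HexNAc-SO4", 284.0435, "sulfo_hexnac", _T_LOW),
    ("Neu5Gc-H2O", 290.087, "NeuGc", _T_SIA),
    ("Neu5Ac", 292.1027, "NeuAc", _T_SIA),
    ("Neu5Gc", 308.0976, "NeuGc", _T_SIA),
    ("unassigned-312", 312.1289, "generic", 0.0),
    ("unassigned-316", 316.1027, "generic", 0.0),
    ("unassigned-328", 328.1238, "generic", 0.0),
    ("unassigned-332", 332.0976, "generic", 0.0),
    ("Ac-Neu5Ac", 334.1133, "ac_neuac", _T_LOW),
    ("Ac-Neu5Gc", 350.1082, "ac_neugc", _T_LOW),
    ("Hex1HexNAc1", 366.1395, "generic", 0.0),
    ("Fuc1HexNAc1-ol", 370.1697, "generic", 0.0),
    ("HexNAc2", 407.1661, "generic", 0.0),
    ("Neu5Ac1HexNAc1", 495.1821, "sialyl_hexnac_ac", _T_LOW),
    ("Neu5Gc1HexNAc1", 511.177, "sialyl_hexnac_gc", _T_LOW),
    ("Fuc1Hex1HexNAc1", 512.1974, "distal_fucose", _T_MED),
    ("Hex2HexNAc1", 528.1923, "alpha_gal", _T_MED),
    ("HexA1Hex1HexNAc1", 542.1716, "hnk1", _T_LOW),
    ("Fuc1HexNAc2", 553.224, "fuc_lacdinac", _T_MED),
    ("Hex1HexNAc2", 569.21887, "generic", 0.0),
    ("SO4-HexA1Hex1HexNAc1", 622.1284, "hnk1_sulfo", _T_LOW),
    ("Neu5Ac1Hex1HexNAc1", 657.2349, "generic", 0.0),
    ("Fuc2Hex1HexNAc1", 658.2553, "lewisY", _T_MED),
    ("Neu5Gc1Hex1HexNAc1", 673.2298, "generic", 0.0),
    ("Neu5Ac1HexNAc2", 698.2615, "generic", 0.0),
    ("Ac-Neu5Ac1Hex1HexNAc1", 699.2455, "generic", 0.0),
    ("Neu5Gc1HexNAc2", 714.2564, "generic", 0.0),
    ("Ac-Neu5Gc1Hex1HexNAc1", 715.2404, "generic", 0.0),
    ("Fuc1Hex1HexNAc2", 715.27677, "generic", 0.0),
    ("Hex1HexNAc3-ol", 792.3234, "bisect", _T_LOW),
    ("Neu5Ac1Fuc1Hex1HexNAc1", 803.2928, "generic", 0.0),
    ("Neu5Gc1Fuc1Hex1HexNAc1", 819.2877, "generic", 0.0),
    ("Neu5Ac1Hex1HexNAc2", 860.31427, "sda", _T_LOW),
    ("Neu5Gc1Hex1HexNAc2", 876.30917, "generic", 0.0),
    ("Neu5Ac2Hex1HexNAc1", 948.3303, "disialyl_lewisC_ac", _T_LOW),
    ("Neu5Gc2Hex1HexNAc1", 980.3201, "disialyl_lewisC_gc", _T_LOW),
    ("SO4-Hex1HexNAc1", 446.09627, "generic", 0.0),
    ("SO4-Hex1HexNAc2", 649.17567, "generic", 0.0),
    ("Hex2HexNAc2", 731.27167, "generic", 0.0),
    ("Fuc1Hex2HexNAc2", 877.32957, "generic", 0.0),
    ("Fuc2Hex2HexNAc2", 1023.38747, "generic", 0.0),
    ("Fuc3Hex2HexNAc2", 1169.44537, "generic", 0.0),
)


def default_registry() -> list[DiagnosticIon]:
    """The built-in diagnostic-ion registry (49 ions)."""
    ions = [DiagnosticIon(label, mz, cat, thr) for label, mz, cat, thr in _DEFAULT_REGISTRY]
    _check_registry(ions)
    return ions


def _check_registry(ions: Iterable[DiagnosticIon]) -> None:
    ions = sorted(ions, key=lambda i: i.mz)
    for a, b in zip(ions, ions[1:]):
        if abs(a.mz - b.mz) <= 0.001:
            raise ValueError(f"registry m/z values not unique within 0.001: {a} / {b}")


def save_registry(ions: Iterable[DiagnosticIon], path: str | Path) -> None:
    """Write a registry to YAML (or JSON if the suffix is .json)."""
    records = [
        {"label": i.label, "mz": i.mz, "category": i.category, "threshold": i.esnog_threshold}
        for i in ions
    ]
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(records, indent=1))
    else:
        path.write_text(yaml.safe_dump(records, sort_keys=False))


def load_registry(path: str | Path) -> list[DiagnosticIon]:
    """Read a registry from a YAML or JSON file (schema: label/mz/category/threshold)."""
    text = Path(path).read_text()
    records = yaml.safe_load(text)
    ions = [
        DiagnosticIon(
            label=r["label"],
            mz=float(r["mz"]),
            category=r.get("category", "generic"),
            esnog_threshold=float(r.get("threshold", 0.0)),
        )
        for r in records
    ]
    _check_registry(ions)
    return ions
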