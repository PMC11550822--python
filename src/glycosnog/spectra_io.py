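"""Readers and writers for MS/MS (MGF), MS1 data and tabular artifacts.

MGF is the reference MS/MS exchange format; parsing goes through
:mod:`pyteomics.mgf`.  Retention times are stored in seconds everywhere.
Pre-deconvoluted MS1 feature tables are imported from CSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .glycomass import PROTON

__all__ = [
    "Peak",
    "MsmsSpectrum",
    "Ms1Scan",
    "Ms1Feature",
    "UnknownChargeError",
    "read_mgf",
    "write_mgf",
    "precursor_mh",
    "read_feature_csv",
    "write_feature_csv",
    "write_histogram_tsv",
    "read_histogram_tsv",
    "write_counts_tsv",
    "read_counts_tsv",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float


def _as_sorted_arrays(mz, intensity):
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if mz.shape != intensity.shape:
        raise ValueError("mz and intensity arrays must have the same length")
    order = np.argsort(mz, kind="stable")
    return mz[order], intensity[order]


@dataclass
class MsmsSpectrum:
    """One fragmentation spectrum; peaks kept sorted ascending by m/z."""

    scan_id: str
    precursor_mz: float
    charge: int  # 1..6; 0 = unknown
    rt: float  # seconds
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz, self.intensity = _as_sorted_arrays(self.mz, self.intensity)
        if self.rt < 0:
            raise ValueError(f"negative retention time for scan {self.scan_id}")

    @classmethod
    def from_peaks(cls, scan_id: str, precursor_mz: float, charge: int, rt: float,
                   peaks: Sequence[Peak | tuple]) -> "MsmsSpectrum":
        mz = [p[0] if isinstance(p, tuple) else p.mz for p in peaks]
        it = [p[1] if isinstance(p, tuple) else p.intensity for p in peaks]
        return cls(scan_id, precursor_mz, charge, rt, np.array(mz), np.array(it))

    @property
    def peaks(self) -> list[Peak]:
        return [Peak(m, i) for m, i in zip(self.mz, self.intensity)]

    @property
    def tic(self) -> float:
        return float(self.intensity.sum())


@dataclass
class Ms1Scan:
    """One centroided MS1 scan."""

    rt: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz, self.intensity = _as_sorted_arrays(self.mz, self.intensity)


@dataclass(frozen=True)
class Ms1Feature:
    """Deconvoluted, deisotoped precursor observation."""

    mh: float  # singly-protonated monoisotopic mass, Da
    rt: float  # seconds
    intensity: float
    charge: int = 0  # original charge state, 0 if unknown

    def __post_init__(self) -> None:
        if self.mh <= 0:
            raise ValueError("mh must be positive")
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")


class UnknownChargeError(ValueError):
    """Spectrum charge state is unknown; precursor mass cannot be computed."""


def precursor_mh(s: MsmsSpectrum) -> float:
    """Singly protonated precursor mass from (precursor m/z, charge)."""
    if s.charge < 1:
        raise UnknownChargeError(f"scan {s.scan_id} has unknown charge state")
    return s.charge * s.precursor_mz - (s.charge - 1) * PROTON


# ---------------------------------------------------------------------------
# MGF


def read_mgf(path: str | Path) -> list[MsmsSpectrum]:
    """Read an MGF file into MsmsSpectrum objects.

    PEPMASS: first token is the precursor m/z.  CHARGE: "2+" style; missing
    charge yields 0.  RT from RTINSECONDS, falling back to RTINMINUTES*60,
    else 0.
    """
    spectra: list[MsmsSpectrum] = []
    with _mgf.MGF(str(path), convert_arrays=1) as reader:
        for i, entry in enumerate(reader):
            params = entry["params"]
            title = str(params.get("title", f"scan_{i}"))
            try:
                pepmass = params.get("pepmass", (0.0,))
                prec_mz = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
                charge_param = params.get("charge")
                charge = int(charge_param[0]) if charge_param else 0
                if "rtinseconds" in params:
                    rt = float(params["rtinseconds"])
                elif "rtinminutes" in params:
                    rt = float(params["rtinminutes"]) * 60.0
                else:
                    rt = 0.0
                spectra.append(
                    MsmsSpectrum(title, prec_mz, charge, rt,
                                 entry["m/z array"], entry["intensity array"])
                )
            except (TypeError, ValueError, KeyError) as exc:
                raise ValueError(f"malformed MGF block {title!r}: {exc}") from exc
    return spectra


def write_mgf(spectra: Iterable[MsmsSpectrum], path: str | Path) -> None:
    """Write spectra to MGF with deterministic formatting."""
    lines: list[str] = []
    for s in spectra:
        lines.append("BEGIN IONS")
        lines.append(f"TITLE={s.scan_id}")
        lines.append(f"PEPMASS={s.precursor_mz:.6f}")
        if s.charge >= 1:
            lines.append(f"CHARGE={s.charge}+")
        lines.append(f"RTINSECONDS={s.rt:.3f}")
        for m, i in zip(s.mz, s.intensity):
            lines.append(f"{m:.6f} {i:.6f}")
        lines.append("END IONS")
        lines.append("")
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# MS1 feature CSV

_DEFAULT_COLUMNS = {"mass": "mass", "rt": "rt_seconds", "intensity": "intensity",
                    "charge": "charge"}


def read_feature_csv(path: str | Path, mass_is_neutral: bool = False,
                     columns: dict | None = None) -> list[Ms1Feature]:
    """Import a pre-deconvoluted MS1 feature table.

    The mass column holds singly protonated masses unless ``mass_is_neutral``
    is set, in which case a proton is added.  Rows failing numeric parsing
    are skipped and counted in a log report.
    """
    colmap = dict(_DEFAULT_COLUMNS, **(columns or {}))
    df = pd.read_csv(path)
    missing = [c for c in (colmap["mass"], colmap["rt"], colmap["intensity"]) if c not in df.columns]
    if missing:
        raise ValueError(f"feature CSV {path} lacks mandatory column(s): {missing}")
    features: list[Ms1Feature] = []
    n_skipped = 0
    has_charge = colmap["charge"] in df.columns
    for row in df.itertuples(index=False):
        rec = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        try:
            mass = float(rec[colmap["mass"]])
            rt = float(rec[colmap["rt"]])
            intensity = float(rec[colmap["intensity"]])
            charge = int(rec[colmap["charge"]]) if has_charge else 0
            if not np.isfinite([mass, rt, intensity]).all():
                raise ValueError("non-finite value")
            mh = mass + PROTON if mass_is_neutral else mass
            features.append(Ms1Feature(mh=mh, rt=rt, intensity=intensity, charge=charge))
        except (TypeError, ValueError):
            n_skipped += 1
    if n_skipped:
        log.warning("feature CSV %s: skipped %d unparseable row(s)", path, n_skipped)
    return features


def write_feature_csv(features: Iterable[Ms1Feature], path: str | Path) -> None:
    lines = ["mass,rt_seconds,intensity,charge"]
    for f in features:
        lines.append(f"{f.mh:.4f},{f.rt:.2f},{f.intensity:.6e},{f.charge}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# TSV artifacts (mass 4 d.p., intensity scientific 6 s.f.)


def write_histogram_tsv(histogram, path: str | Path) -> None:
    """Write a MassHistogram as TSV with a provenance header."""
    g = histogram.grid
    lines = [
        f"# sample_id={histogram.sample_id}",
        f"# lo={g.lo:.4f}\thi={g.hi:.4f}\twidth={g.width:.4f}",
        "center_mh\tintensity",
    ]
    for k, v in enumerate(histogram.intensity):
        lines.append(f"{g.center(k):.4f}\t{v:.6e}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_histogram_tsv(path: str | Path):
    """Read a histogram TSV written by :func:`write_histogram_tsv`."""
    from .ms1_profile import BinGrid, MassHistogram

    text = Path(path).read_text().splitlines()
    sample_id = text[0].split("=", 1)[1] if text and text[0].startswith("# sample_id") else ""
    meta = dict(item.split("=") for item in text[1].lstrip("# ").split("\t"))
    grid = BinGrid(lo=float(meta["lo"]), hi=float(meta["hi"]), width=float(meta["width"]))
    values = [float(line.split("\t")[1]) for line in text[3:] if line]
    return MassHistogram(grid=grid, intensity=np.array(values), sample_id=sample_id)


def write_counts_tsv(counts: dict, path: str | Path, total: int | None = None) -> None:
    """Write per-category spectral counts (and fractions of glycan spectra)."""
    lines = ["category\tcount\tfraction_of_glycan_spectra"]
    for cat in sorted(counts):
        n = counts[cat]
        frac = n / total if total else float("nan")
        lines.append(f"{cat}\t{n}\t{frac:.6e}")
    if total is not None:
        lines.append(f"total_glycan_spectra\t{total}\t{1.0:.6e}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
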