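"""Synthetic PGC-LC-MS/MS run generator with ground truth.

Generates, from a seed, the artifacts the pipeline consumes — an MGF of
MS/MS spectra and a CSV of deconvoluted MS1 features — together with a
truth table, emulating the statistical structure the pipeline assumes:

* glycan MS/MS spectra carry the reduced-HexNAc diagnostic ion (>5% of TIC)
  plus category-specific oxonium ions over a background of noise peaks;
* co-eluting polyhexose contaminants (dextran/maltodextrin-like ladders)
  produce intense MS1 signals whose MS/MS spectra contain no peak within
  ±0.05 of the reduced-HexNAc ion, so they must fail the SNOG filter;
* each composition elutes as 1-3 Gaussian isomer peaks (sigma = 5 s,
  sampled at 1 s) at fixed multiples of the Man5 retention time;
* trace decoy masses sit below the 5e6 cumulative-intensity threshold.

Fragment intensities are declarative fractions of spectrum TIC per
category, not a physical model: the pipeline only consumes relative
intensities.  Noise peaks avoid all category-diagnostic m/z windows so the
planted category truth is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .glycomass import (
    PROTON,
    REDUCED_HEXNAC_MZ,
    WATER,
    REDUCTION,
    GlycanComposition,
    default_registry,
    parse_composition,
    reduced_glycan_mh,
    residue_mass,
)
from .ms1_profile import BinGrid
from .spectra_io import Ms1Feature, MsmsSpectrum, write_feature_csv, write_mgf

__all__ = [
    "PanelEntry",
    "SynthSpec",
    "TruthTable",
    "default_panel",
    "simulate_spectrum",
    "simulate_run",
]

# primary diagnostic ions planted per category: (m/z ..., fraction range)
_CATEGORY_IONS: dict[str, list[tuple[float, tuple[float, float]]]] = {
    "NeuAc": [(292.1027, (0.025, 0.06)), (274.0921, (0.015, 0.04))],
    "NeuGc": [(308.0976, (0.025, 0.06)), (290.087, (0.015, 0.04))],
    "distal_fucose": [(512.1974, (0.012, 0.03))],
    "alpha_gal": [(528.1923, (0.012, 0.03))],
    "bisect": [(792.3234, (0.006, 0.015))],
    "lewisY": [(658.2553, (0.012, 0.03))],
    "sda": [(860.31427, (0.006, 0.015))],
    "hnk1": [(542.1716, (0.006, 0.015))],
    "hnk1_sulfo": [(622.1284, (0.006, 0.015))],
    "sulfo_hexnac": [(284.0435, (0.006, 0.015))],
    "fuc_lacdinac": [(553.224, (0.012, 0.03))],
    "ac_neuac": [(334.1133, (0.006, 0.015))],
    "ac_neugc": [(350.1082, (0.006, 0.015))],
    "sialyl_hexnac_ac": [(495.1821, (0.006, 0.015))],
    "sialyl_hexnac_gc": [(511.177, (0.006, 0.015))],
    "disialyl_lewisC_ac": [(948.3303, (0.006, 0.015))],
    "disialyl_lewisC_gc": [(980.3201, (0.006, 0.015))],
}

_DECORATED = frozenset({"distal_fucose", "NeuAc", "NeuGc", "alpha_gal", "oligomannose"})


@dataclass(frozen=True)
class PanelEntry:
    """One glycan composition of the synthetic panel with its ground truth."""

    composition: str  # composition string
    abundance: float  # total MS1 intensity across isomers
    categories: frozenset[str]  # diagnostic-ion category truth
    isomer_multiples: tuple[float, ...] = (1.0,)  # apex rts as Man5 multiples
    known: bool = True  # expected to be annotatable by the default glycoDB

    def parsed(self) -> GlycanComposition:
        return parse_composition(self.composition)

    @property
    def mh(self) -> float:
        return reduced_glycan_mh(self.parsed())

    def effective_categories(self) -> frozenset[str]:
        """Truth categories including derived oligomannose / undecorated."""
        c = self.parsed()
        cats = set(self.categories)
        if c["HexNAc"] == 2 and 4 <= c["Hex"] <= 12 and c.total_residues == c["Hex"] + 2 \
                and c.n_sulfate == 0 and c.n_acetyl == 0:
            cats.add("oligomannose")
        if not cats & _DECORATED:
            cats.add("undecorated")
        return frozenset(cats)


def _entry(comp: str, abundance: float, cats: Sequence[str] = (),
           isomers: Sequence[float] = (1.0,), known: bool = True) -> PanelEntry:
    return PanelEntry(comp, abundance, frozenset(cats), tuple(isomers), known)


def default_panel() -> list[PanelEntry]:
    """The default 50-composition panel with category and isomer ground truth.

    A cross-section of the murine N-glycome: oligomannose series,
    undecorated truncated/complex glycans (core fucose only), Neu5Ac- and
    Neu5Gc-sialylated, distally fucosylated, alpha-galactosylated, and a few
    non-canonical compositions (sulfated, HNK-1, O-acetylated, polysialyl)
    that the default composition database does not cover.
    """
    return [
        # oligomannose series (Man4-Man9)
        _entry("Hex4HexNAc2", 4.0e8),
        _entry("Hex5HexNAc2", 9.0e8),  # Man5: retention-time reference, single apex
        _entry("Hex6HexNAc2", 5.0e8, isomers=(0.90, 1.10)),
        _entry("Hex7HexNAc2", 3.5e8, isomers=(0.95, 1.12)),
        _entry("Hex8HexNAc2", 2.5e8),
        _entry("Hex9HexNAc2", 2.0e8, isomers=(1.05, 1.25)),
        # undecorated (at most core fucose)
        _entry("Hex3HexNAc3", 1.5e8),
        _entry("Hex3HexNAc2Fuc1", 3.0e8),
        _entry("Hex3HexNAc3Fuc1", 2.5e8, isomers=(0.75, 1.05)),
        _entry("Hex4HexNAc3", 1.2e8),
        _entry("Hex5HexNAc4", 2.2e8),
        _entry("Hex5HexNAc4Fuc1", 6.0e8, isomers=(1.10, 1.35)),
        _entry("Hex3HexNAc5Fuc1", 2.8e8, isomers=(0.70, 1.00, 1.30)),
        _entry("Hex4HexNAc4Fuc1", 1.6e8),
        # Neu5Ac-sialylated
        _entry("Hex5HexNAc4Neu5Ac1", 5.5e8, ["NeuAc"], isomers=(1.15, 1.45)),
        _entry("Hex5HexNAc4Neu5Ac2", 7.0e8, ["NeuAc"], isomers=(1.20, 1.50)),
        _entry("Hex5HexNAc4Fuc1Neu5Ac2", 8.0e8, ["NeuAc"], isomers=(1.25, 1.55)),
        _entry("Hex4HexNAc3Fuc1Neu5Ac1", 1.8e8, ["NeuAc"]),
        _entry("Hex6HexNAc3Fuc1Neu5Ac1", 2.4e8, ["NeuAc"]),
        _entry("Hex6HexNAc5Neu5Ac3", 2.0e8, ["NeuAc"]),
        _entry("Hex5HexNAc5Fuc1Neu5Ac2", 1.4e8, ["NeuAc", "bisect"]),
        _entry("Hex7HexNAc6Fuc3Neu5Ac2", 1.1e8, ["NeuAc", "distal_fucose"]),
        # Neu5Gc-sialylated
        _entry("Hex5HexNAc4Neu5Gc1", 6.5e8, ["NeuGc"], isomers=(1.18, 1.42)),
        _entry("Hex5HexNAc4Neu5Gc2", 7.5e8, ["NeuGc"], isomers=(1.22, 1.48)),
        _entry("Hex5HexNAc4Fuc1Neu5Gc2", 5.2e8, ["NeuGc"], isomers=(1.28, 1.52)),
        _entry("Hex6HexNAc3Fuc1Neu5Gc1", 1.9e8, ["NeuGc"]),
        _entry("Hex5HexNAc4Fuc1Neu5Gc3", 1.3e8, ["NeuGc", "disialyl_lewisC_gc"],
               known=False),
        _entry("Hex5HexNAc4Fuc1Neu5Ac1Neu5Gc1", 4.5e8, ["NeuAc", "NeuGc"]),
        # distally fucosylated
        _entry("Hex5HexNAc4Fuc3", 4.8e8, ["distal_fucose"], isomers=(0.80, 1.20)),
        _entry("Hex5HexNAc5Fuc3", 8.5e8, ["distal_fucose", "bisect"]),
        _entry("Hex6HexNAc5Fuc3", 4.2e8, ["distal_fucose"]),
        _entry("Hex6HexNAc6Fuc3", 2.6e8, ["distal_fucose", "bisect"]),
        _entry("Hex7HexNAc6Fuc4", 2.1e8, ["distal_fucose"]),
        _entry("Hex7HexNAc7Fuc5", 1.2e8, ["distal_fucose"]),
        _entry("Hex5HexNAc4Fuc4", 1.6e8, ["distal_fucose", "lewisY"]),
        _entry("Hex6HexNAc5Fuc5", 1.0e8, ["distal_fucose", "lewisY"]),
        _entry("Hex3HexNAc4Fuc2", 1.4e8, ["distal_fucose", "fuc_lacdinac"]),
        # alpha-galactosylated
        _entry("Hex7HexNAc4Fuc1", 5.8e8, ["alpha_gal"], isomers=(1.30, 1.60)),
        _entry("Hex6HexNAc4Fuc1", 3.9e8, ["alpha_gal"]),
        _entry("Hex7HexNAc4", 2.3e8, ["alpha_gal"]),
        _entry("Hex8HexNAc5Fuc2", 1.7e8, ["alpha_gal", "distal_fucose"]),
        _entry("Hex7HexNAc5Fuc3", 2.9e8, ["alpha_gal", "distal_fucose"]),
        _entry("Hex6HexNAc4Fuc2", 1.5e8, ["alpha_gal"]),
        # sialylated HexNAc / Sda
        _entry("Hex5HexNAc5Fuc1Neu5Ac1", 1.3e8, ["NeuAc", "sda"]),
        _entry("Hex5HexNAc4Neu5Ac1Neu5Gc2", 1.0e8, ["NeuAc", "NeuGc"], known=False),
        # O-acetylated sialic acid: exactly isobaric with a canonical entry,
        # so it is annotated (as the isobar) and counts as known
        _entry("Hex5HexNAc4Fuc1Neu5Gc1Ac1", 2.2e8, ["NeuGc", "ac_neugc"]),
        # non-canonical compositions absent from the default glycoDB
        _entry("Hex6HexNAc5Fuc2HexA1", 1.8e8, ["distal_fucose", "hnk1"], known=False),
        _entry("Hex5HexNAc5Fuc1HexA1SO41", 1.1e8, ["hnk1", "hnk1_sulfo"], known=False),
        _entry("Hex5HexNAc3Fuc1Neu5Ac2", 1.2e8, ["NeuAc", "disialyl_lewisC_ac"],
               known=False),
        _entry("Hex5HexNAc4Fuc1SO42", 1.0e8, ["sulfo_hexnac"], known=False),
    ]


@dataclass
class SynthSpec:
    """Parameters of one synthetic run."""

    panel: list[PanelEntry] = field(default_factory=default_panel)
    man5_rt: float = 900.0  # s; elution apex of the Man5 reference
    peak_sigma: float = 5.0  # s, Gaussian isomer peak width
    sample_step: float = 1.0  # s, MS1 sampling interval
    n_noise_peaks: int = 40
    msms_per_isomer: int = 3
    contaminant_hex_range: tuple[int, int] = (3, 12)  # polyhexose ladder Hex_n
    contaminant_intensity: float = 4.0e7  # per ladder member: above threshold
    decoy_masses: tuple[float, ...] = (1500.63, 2222.22, 3333.33)
    decoy_intensity: float = 1.0e6  # below the 5e6 cumulative threshold
    seed: int = 0

    def __post_init__(self) -> None:
        if any(e.abundance <= 0 for e in self.panel):
            raise ValueError("panel abundances must be positive")
        if not any(e.composition == "Hex5HexNAc2" for e in self.panel):
            raise ValueError("panel must include the Man5 retention reference")


@dataclass
class TruthTable:
    """Ground truth of one synthetic run, consistent with the emitted files."""

    entries: list[dict]  # per panel composition
    contaminants: list[dict]  # per polyhexose ladder member
    decoys: list[dict]

    def category_fractions(self) -> dict[str, float]:
        """Intensity-weighted truth fraction per category (multi-label)."""
        total = sum(e["intensity"] for e in self.entries)
        cats = set().union(*(e["categories"] for e in self.entries))
        return {
            c: sum(e["intensity"] for e in self.entries if c in e["categories"]) / total
            for c in sorted(cats)
        }

    def glycan_bin_indices(self, grid: BinGrid) -> set[int]:
        return {k for e in self.entries
                if (k := grid.index_of(e["mh"])) is not None}

    def contaminant_bin_indices(self, grid: BinGrid) -> set[int]:
        return {k for e in self.contaminants
                if (k := grid.index_of(e["mh"])) is not None}

    def write_tsv(self, path: str | Path) -> None:
        lines = ["kind\tname\tmh\tintensity\tcategories\tknown\tisomer_multiples"]
        for e in self.entries:
            lines.append(
                "glycan\t{name}\t{mh:.4f}\t{intensity:.6e}\t{cats}\t{known}\t{iso}".format(
                    name=e["composition"], mh=e["mh"], intensity=e["intensity"],
                    cats=",".join(sorted(e["categories"])), known=int(e["known"]),
                    iso=",".join(f"{m:g}" for m in e["isomer_multiples"]),
                )
            )
        for c in self.contaminants:
            lines.append(f"contaminant\t{c['name']}\t{c['mh']:.4f}\t"
                         f"{c['intensity']:.6e}\t\t0\t")
        for d in self.decoys:
            lines.append(f"decoy\t\t{d['mh']:.4f}\t{d['intensity']:.6e}\t\t0\t")
        Path(path).write_text("\n".join(lines) + "\n")


def _polyhexose_mh(n: int) -> float:
    """Reduced (alditol) hexose oligomer [M+H]+ (dextran/maltodextrin-like)."""
    return n * residue_mass("Hex") + WATER + REDUCTION + PROTON


def _protected_windows(margin: float = 0.06) -> list[tuple[float, float]]:
    """m/z windows noise peaks must avoid: every category-diagnostic ion + 224."""
    centers = [REDUCED_HEXNAC_MZ]
    for ions in _CATEGORY_IONS.values():
        centers.extend(mz for mz, _ in ions)
    return [(c - margin, c + margin) for c in sorted(centers)]


_PROTECTED = _protected_windows()


def _noise_mz(rng: np.random.Generator, lo: float, hi: float) -> float:
    while True:
        mz = float(rng.uniform(lo, hi))
        if not any(a <= mz <= b for a, b in _PROTECTED):
            return mz


def simulate_spectrum(entry_or_comp, rng: np.random.Generator,
                      categories: frozenset[str] | None = None,
                      rt: float = 0.0, charge: int = 2,
                      scan_id: str = "scan") -> MsmsSpectrum:
    """One glycan MS/MS spectrum with planted diagnostic-ion fractions.

    The reduced-HexNAc ion carries 6-15% of the spectrum TIC, each truth
    category's ions carry fractions above their eSNOG thresholds, and the
    remaining intensity is spread over noise peaks that avoid all
    diagnostic windows.  The precursor m/z is consistent with the glycan
    [M+H]+ at the given charge.
    """
    if isinstance(entry_or_comp, PanelEntry):
        comp = entry_or_comp.parsed()
        categories = entry_or_comp.categories if categories is None else categories
    else:
        comp = entry_or_comp
        categories = categories or frozenset()
    mh = reduced_glycan_mh(comp)
    tic = 1.0e6
    peaks: list[tuple[float, float]] = []
    used = float(rng.uniform(0.06, 0.15))
    peaks.append((REDUCED_HEXNAC_MZ, used * tic))
    for cat in sorted(categories):
        for mz, (flo, fhi) in _CATEGORY_IONS.get(cat, []):
            f = float(rng.uniform(flo, fhi))
            peaks.append((mz, f * tic))
            used += f
    remaining = max(1.0 - used, 0.05)
    n_noise = max(int(rng.integers(30, 50)), 1)
    weights = rng.uniform(0.2, 1.0, size=n_noise)
    weights = weights / weights.sum() * remaining * tic
    mz_hi = min(mh, 2000.0)
    for w in weights:
        peaks.append((_noise_mz(rng, 150.0, mz_hi), float(w)))
    precursor_mz = (mh + (charge - 1) * PROTON) / charge
    mzs, ints = zip(*peaks)
    return MsmsSpectrum(scan_id, precursor_mz, charge, rt,
                        np.array(mzs), np.array(ints))


def simulate_contaminant_spectrum(n_hex: int, rng: np.random.Generator,
                                  rt: float = 0.0, charge: int = 2,
                                  scan_id: str = "contaminant") -> MsmsSpectrum:
    """Polyhexose contaminant MS/MS: hexose-ladder ions, nothing near 224.11."""
    mh = _polyhexose_mh(n_hex)
    tic = 1.0e6
    peaks: list[tuple[float, float]] = []
    n_ladder = max(n_hex - 1, 1)
    ladder_frac = 0.6
    for k in range(1, n_ladder + 1):
        mz = k * residue_mass("Hex") + PROTON  # B-type hexose oligomer ions
        peaks.append((mz, ladder_frac / n_ladder * tic * float(rng.uniform(0.5, 1.5))))
    n_noise = max(int(rng.integers(20, 40)), 1)
    weights = rng.uniform(0.2, 1.0, size=n_noise)
    weights = weights / weights.sum() * (1 - ladder_frac) * tic
    for w in weights:
        peaks.append((_noise_mz(rng, 150.0, min(mh, 2000.0)), float(w)))
    precursor_mz = (mh + (charge - 1) * PROTON) / charge
    mzs, ints = zip(*peaks)
    return MsmsSpectrum(scan_id, precursor_mz, charge, rt,
                        np.array(mzs), np.array(ints))


def _gaussian_feature_block(mh: float, apex_rt: float, total: float,
                            sigma: float, step: float, charge: int,
                            rng: np.random.Generator) -> list[Ms1Feature]:
    """Gaussian elution peak sampled on the time grid; intensities sum to total."""
    rts = np.arange(apex_rt - 5 * sigma, apex_rt + 5 * sigma + step / 2, step)
    y = np.exp(-0.5 * ((rts - apex_rt) / sigma) ** 2)
    y = y * rng.uniform(0.95, 1.05, size=len(y))  # mild scan-to-scan jitter
    y = y / y.sum() * total
    return [Ms1Feature(mh=mh, rt=float(t), intensity=float(v), charge=charge)
            for t, v in zip(rts, y) if v > 0]


def simulate_run(spec: SynthSpec | None = None, out_dir: str | Path = ".",
                 prefix: str = "synthetic"):
    """Generate one synthetic run: MGF + feature CSV + truth table.

    Returns ``(mgf_path, feature_csv_path, truth)``.  Deterministic given
    ``spec.seed``: identical specs yield byte-identical files.
    """
    spec = spec or SynthSpec()
    rng = np.random.default_rng(spec.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    grid = BinGrid()
    bins_seen: dict[int, str] = {}
    features: list[Ms1Feature] = []
    spectra: list[MsmsSpectrum] = []
    truth_entries: list[dict] = []
    scan_no = 0

    for e in spec.panel:
        mh = e.mh
        k = grid.index_of(mh)
        if k is not None:
            if k in bins_seen:
                raise ValueError(
                    f"panel mass-bin collision: {e.composition} vs {bins_seen[k]}"
                )
            bins_seen[k] = e.composition
        shares = rng.dirichlet(np.full(len(e.isomer_multiples), 5.0))
        entry_features: list[Ms1Feature] = []
        for mult, share in zip(e.isomer_multiples, shares):
            apex = mult * spec.man5_rt
            charge = int(rng.integers(2, 5))
            entry_features.extend(
                _gaussian_feature_block(mh, apex, e.abundance * float(share),
                                        spec.peak_sigma, spec.sample_step,
                                        charge, rng)
            )
            for j in range(spec.msms_per_isomer):
                scan_no += 1
                z = int(rng.integers(2, 4))
                rt = apex + (j - spec.msms_per_isomer // 2) * 3.0
                spectra.append(
                    simulate_spectrum(e, rng, rt=rt, charge=z,
                                      scan_id=f"glycan_{scan_no:05d}_{e.composition}")
                )
        features.extend(entry_features)
        truth_entries.append({
            "composition": e.composition,
            "mh": mh,
            "intensity": sum(f.intensity for f in entry_features),
            "categories": e.effective_categories(),
            "known": e.known,
            "isomer_multiples": e.isomer_multiples,
        })

    contaminants: list[dict] = []
    for n_hex in range(spec.contaminant_hex_range[0], spec.contaminant_hex_range[1] + 1):
        mh = _polyhexose_mh(n_hex)
        k = grid.index_of(mh)
        if k is not None and k in bins_seen:
            raise ValueError(f"contaminant Hex{n_hex} collides with {bins_seen[k]}")
        apex = float(rng.uniform(0.3, 0.7)) * spec.man5_rt
        block = _gaussian_feature_block(mh, apex, spec.contaminant_intensity,
                                        spec.peak_sigma, spec.sample_step, 2, rng)
        features.extend(block)
        for j in range(2):
            scan_no += 1
            spectra.append(
                simulate_contaminant_spectrum(
                    n_hex, rng, rt=apex + 3.0 * j, charge=2,
                    scan_id=f"contaminant_{scan_no:05d}_Hex{n_hex}")
            )
        contaminants.append({"name": f"Hex{n_hex}",
                             "mh": mh,
                             "intensity": sum(f.intensity for f in block)})

    decoys: list[dict] = []
    for mh in spec.decoy_masses:
        apex = float(rng.uniform(0.3, 1.5)) * spec.man5_rt
        block = _gaussian_feature_block(mh, apex, spec.decoy_intensity,
                                        spec.peak_sigma, spec.sample_step, 2, rng)
        features.extend(block)
        decoys.append({"mh": mh, "intensity": sum(f.intensity for f in block)})

    spectra.sort(key=lambda s: (s.rt, s.scan_id))
    features.sort(key=lambda f: (f.rt, f.mh))

    mgf_path = out_dir / f"{prefix}.mgf"
    csv_path = out_dir / f"{prefix}_features.csv"
    truth_path = out_dir / f"{prefix}_truth.tsv"
    write_mgf(spectra, mgf_path)
    write_feature_csv(features, csv_path)
    truth = TruthTable(entries=truth_entries, contaminants=contaminants, decoys=decoys)
    truth.write_tsv(truth_path)
    return mgf_path, csv_path, truth
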