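"""Glycome assembly tests: bin retention rules, stratification, glycoDB, annotation."""

import numpy as np
import pytest

from glycosnog.assembly import (
    GlycoDbConstraints,
    MassBin,
    annotate,
    assign_flags,
    attach_msms,
    build_glycodb,
    stratify,
    unknown_fraction,
)
from glycosnog.glycomass import parse_composition, reduced_glycan_mh
from glycosnog.ms1_profile import BinGrid, MassHistogram
from glycosnog.snog import SpectrumScore


def _score(mh, snog=0.08, flags=(), scan_id="s"):
    return SpectrumScore(scan_id=scan_id, snog=snog, esnog={}, flags=set(flags), mh=mh)


def _hist(bin_values: dict[float, float], grid=None):
    grid = grid or BinGrid()
    intensity = np.zeros(grid.n_bins)
    for mh, v in bin_values.items():
        intensity[grid.index_of(mh)] = v
    return MassHistogram(grid, intensity, sample_id="t")


class TestAttach:
    def test_passing_spectrum_makes_glycan_bin(self):
        h = _hist({2371.86: 9e6})
        (b,) = attach_msms(h, [_score(2371.88, snog=0.08)])
        assert b.is_glycan
        assert len(b.spectra) == 1

    def test_low_scores_reject_bin(self):
        h = _hist({2371.86: 9e6})
        (b,) = attach_msms(h, [_score(2371.88, snog=0.01), _score(2371.9, snog=0.03)])
        assert not b.is_glycan  # 0.03 itself is not strictly greater

    def test_spectrum_outside_grid_or_unknown_mass_skipped(self):
        h = _hist({2371.86: 9e6})
        below_grid = _score(999.0)
        unknown_mass = SpectrumScore("u", 0.5, {}, set(), mh=None)
        (b,) = attach_msms(h, [below_grid, unknown_mass])
        assert b.spectra == []

    def test_bin_without_spectra_not_glycan(self):
        h = _hist({1500.0: 6e6, 2371.86: 9e6})
        bins = attach_msms(h, [_score(2371.88)])
        by_center = {round(b.center_mh, 1): b for b in bins}
        assert by_center[2371.9].is_glycan
        assert not by_center[1500.0].is_glycan


class TestStratify:
    def _bin(self, mh, intensity, flags=(), snog=0.08):
        g = BinGrid()
        b = MassBin(center_mh=g.center(g.index_of(mh)), intensity=intensity)
        b.spectra = [_score(mh, snog=snog, flags=flags)]
        b.is_glycan = snog > 0.03
        return b

    def test_oligomannose_beats_undecorated(self):
        b = self._bin(reduced_glycan_mh(parse_composition("Hex5HexNAc2")), 1e7)
        annotate([b], build_glycodb())
        profile = stratify([b])
        assert "oligomannose" in b.categories
        assert "undecorated" not in b.categories
        assert profile.fractions["oligomannose"] == 1.0

    def test_multi_label_counted_in_both(self):
        b1 = self._bin(2371.86, 6e6, flags=("NeuAc", "distal_fucose"))
        b2 = self._bin(1789.67, 4e6, flags=())
        profile = stratify([b1, b2])
        assert profile.fractions["NeuAc"] == pytest.approx(0.6)
        assert profile.fractions["distal_fucose"] == pytest.approx(0.6)
        assert profile.fractions["undecorated"] == pytest.approx(0.4)

    def test_core_fucosylated_composition_is_undecorated(self):
        # fucose in composition but no distal-fucose diagnostic flag
        mh = reduced_glycan_mh(parse_composition("Hex3HexNAc3Fuc1"))
        b = self._bin(mh, 1e7, flags=())
        profile = stratify([b])
        assert "undecorated" in b.categories
        assert profile.fractions["undecorated"] == 1.0

    def test_undecorated_disjoint_from_decorated(self):
        bins = [self._bin(2371.86, 6e6, flags=("NeuAc",)),
                self._bin(1789.67, 4e6, flags=())]
        stratify(bins)
        for b in bins:
            if b.categories & {"NeuAc", "NeuGc", "distal_fucose", "alpha_gal",
                               "oligomannose"}:
                assert "undecorated" not in b.categories

    def test_flags_require_passing_spectrum(self):
        b = self._bin(2371.86, 6e6, flags=("NeuAc",), snog=0.08)
        b.spectra.append(_score(2371.86, snog=0.01, flags=("NeuGc",)))
        assign_flags([b])
        assert b.categories == {"NeuAc"}  # failing spectrum contributes nothing


class TestGlycoDb:
    def test_single_entry_constraints(self):
        db = build_glycodb(GlycoDbConstraints(hex_range=(5, 5), hexnac_range=(2, 2),
                                              fuc_range=(0, 0), sia_range=(0, 0)))
        assert db.n_entries == 1
        comp, mh = db.entries[0]
        assert str(comp) == "Hex5HexNAc2"
        assert mh == pytest.approx(1237.456, abs=1e-3)

    def test_default_db_contains_reference_composition(self):
        db = build_glycodb()
        target = reduced_glycan_mh(parse_composition("Hex5HexNAc4Fuc1Neu5Ac2"))
        assert any(str(c) == "Hex5HexNAc4Fuc1Neu5Ac2" for c, _ in db.entries)
        masses = [mh for _, mh in db.entries]
        assert min(abs(m - target) for m in masses) < 1e-9

    def test_mass_range_and_dedup(self):
        db = build_glycodb()
        masses = [mh for _, mh in db.entries]
        # range oracle: the constraint extremes bound every entry
        lo = reduced_glycan_mh(parse_composition("Hex3HexNAc2"))
        hi = reduced_glycan_mh(parse_composition("Hex12HexNAc8Fuc6Neu5Gc5"))
        assert all(lo - 1e-9 <= m <= hi + 1e-9 for m in masses)
        assert len({str(c) for c, _ in db.entries}) == db.n_entries
        assert db.n_mass_bins() <= db.n_entries

    def test_biosynthetic_constraints_enforced(self):
        db = build_glycodb()
        for c, _ in db.entries:
            assert c["Neu5Ac"] + c["Neu5Gc"] <= max(c["HexNAc"] - 2, 0)
            assert c["dHex"] <= c["HexNAc"] + 1

    def test_invalid_constraints(self):
        with pytest.raises(ValueError):
            GlycoDbConstraints(hex_range=(5, 3))


class TestAnnotate:
    def _glycan_bin(self, center, intensity=1e7, flags=()):
        b = MassBin(center_mh=center, intensity=intensity)
        b.spectra = [_score(center, flags=flags)]
        b.is_glycan = True
        b.categories = set(flags)
        return b

    def test_mass_match_within_tolerance(self):
        db = build_glycodb()
        b = self._glycan_bin(2371.9)
        annotate([b], db)
        assert b.annotations
        assert any(str(c) == "Hex5HexNAc4Fuc1Neu5Ac2" for c, _ in b.annotations)
        assert all(abs(d) <= 0.05 for _, d in b.annotations)

    def test_flag_disambiguates_exact_isobars(self):
        # Neu5Gc+Fuc vs Neu5Ac+Hex are exactly isobaric; the NeuGc eSNOG flag
        # must promote the Neu5Gc-containing candidate
        db = build_glycodb()
        b_gc = self._glycan_bin(2387.9, flags=("NeuGc",))
        b_ac = self._glycan_bin(2387.9, flags=("NeuAc",))
        annotate([b_gc, b_ac], db)
        assert b_gc.best_annotation["Neu5Gc"] > 0
        assert b_ac.best_annotation["Neu5Ac"] > 0

    def test_no_candidate_marks_unknown(self):
        db = build_glycodb()
        b = self._glycan_bin(1500.0)
        annotate([b], db)
        assert b.annotations == []
        assert b.is_unknown

    def test_symmetric_tolerance(self):
        db = build_glycodb()
        target = reduced_glycan_mh(parse_composition("Hex5HexNAc4Fuc1"))
        inside = self._glycan_bin(target + 0.049)
        outside = self._glycan_bin(target + 0.051)
        annotate([inside, outside], db)
        assert any(str(c) == "Hex5HexNAc4Fuc1" for c, _ in inside.annotations)
        assert not any(str(c) == "Hex5HexNAc4Fuc1" for c, _ in outside.annotations)


class TestUnknownFraction:
    def _bin(self, intensity, annotated, glycan=True):
        b = MassBin(center_mh=2000.0, intensity=intensity, is_glycan=glycan)
        if annotated:
            b.annotations = [(parse_composition("Hex5HexNAc4"), 0.0)]
        return b

    def test_all_annotated_zero(self):
        assert unknown_fraction([self._bin(1e7, True)]) == 0.0

    def test_fraction_of_tic(self):
        bins = [self._bin(9e7, True), self._bin(1e7, False)]
        assert unknown_fraction(bins) == pytest.approx(0.1)

    def test_zero_glycan_tic_raises(self):
        with pytest.raises(ValueError):
            unknown_fraction([self._bin(1e7, True, glycan=False)])
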