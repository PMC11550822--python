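# Methods

## Analytes and mass model

The tool targets N-glycans enzymatically released from tissue proteins,
reduced to alditols with sodium borohydride, and analyzed by PGC-LC-MS/MS
in positive mode. All masses are monoisotopic and derive from a single
table of full-precision IUPAC atomic masses (H 1.00782503, C 12, N
14.00307400, O 15.99491462, S 31.97207100; proton 1.00727647). Residue
masses are computed from fixed anhydro elemental compositions (Hex C6H10O5,
HexNAc C8H13NO5, dHex C6H10O4, Neu5Ac C11H17NO8, Neu5Gc C11H17NO9, HexA
C6H8O6), never hard-coded, so an independent elemental oracle can verify
them. Modifications are additive: sulfate +SO3 (79.95681), O-acetyl +C2H2O
(42.01056).

Ion types:

- intact reduced glycan: [M+H]+ = Σresidues + H2O + 2H + proton;
- B-type oxonium fragment: Σresidues + proton;
- reduced-end fragment (retains the alditol): Σresidues + H2O + 2H + proton.

Full precision matters: deriving residue masses from 5-decimal atomic
masses accumulates +1e-4-level drift over trisaccharide fragments and
breaks agreement with conventionally published fragment m/z values at
their fourth decimal.

The reduced-end HexNAc diagnostic ion is used internally at its theoretical
m/z 224.1129. Published lists sometimes carry 224.1118 (a protonation
convention that adds 2×proton rather than 2×H for the reduction); the
±0.05 amu matching tolerance absorbs this difference, and the shipped
registry stores published values verbatim as data.

## Diagnostic-ion registry

The default registry holds 49 oxonium m/z values. Ions with an established
sub-structural meaning carry a category tag (NeuAc: 292.1027/274.0921;
NeuGc: 308.0976/290.087; distal fucose: 512.1974; alpha-Gal: 528.1923;
bisecting GlcNAc: 792.3234; Lewis Y: 658.2553; Sda: 860.31427; HNK-1:
542.1716, sulfated 622.1284; sulfo-HexNAc: 284.0435; fucosylated LacdiNAc:
553.224; O-acetyl Neu5Ac/Neu5Gc: 334.1133/350.1082; sialylated HexNAc:
495.1821/511.177; di-sialyl Lewis C: 948.3303/980.3201); the remainder are
generic glycan-evidence ions. The registry is config-overridable
(YAML/JSON, schema `{label, mz, category, threshold}`) and round-trips bit
exactly.

## SNOG and eSNOG scores

SNOG(s) = (maximum peak intensity within ±0.05 amu of the reduced-HexNAc
ion) / (total ion current of the spectrum). The TIC denominator keeps the
score in [0, 1], makes it invariant under uniform intensity scaling, and
is the natural reading of a relative-intensity score; a base-peak
denominator is available behind a switch. Spectra with SNOG strictly
greater than 0.03 are treated as glycan-derived. The cutoff is an
empirical property of the acquisition (collision energy etc.) and is
exposed as a parameter; the boundary is deliberately strict and tested.

eSNOG extends this per category: the matched intensities of a category's
ions are pooled (summed) and divided by TIC; a category is flagged when
its pooled score reaches the category threshold. Pooling treats water-loss
pairs (292/274, 308/290) as alternative reporters of one residue. Default
thresholds are declared data, chosen by ion class — 0.01 for single-residue
sialic ions, 0.005 for di/tri-saccharide epitope ions, 0.002 for large or
modified-sialic ions (larger, rarer fragments are less intense) — and are
config-overridable; they are not claimed to equal any previously published
threshold set.

## MS1 processing and the glycome histogram

Deconvoluted features (singly protonated monoisotopic mass, retention
time, intensity) either come from an external feature table (CSV import)
or from the built-in deisotoper. The deisotoper is deliberately simple:
peaks are visited in descending intensity; for each charge 1–6 the
isotope ladder (spacing 1.00235/z) is followed within ±0.01 Da both toward
higher isotopes and leftward toward the monoisotopic peak, assuming a
unimodal envelope (each step away from the apex at most 1.4× its
predecessor); the charge matching the most isotopes wins, ties to the
lower charge, envelopes need ≥2 peaks; mh is computed from the leftmost
member. The leftward walk is essential: above ~2 kDa the envelope apex is
usually the +1/+2 isotope, and an apex-only reading would be
systematically heavy by k×1.00235. No attempt is made to resolve
overlapping envelopes; the feature-CSV import is the path for data
deconvoluted by specialized tools.

Histograms accumulate feature intensities into 0.1-Da bins over
1000–5000 Da by default. One published description of the analysis window
gives 1000–4000 Da and another 1000–5000; the processing-level figure
(1000–5000) is the default and the range is a flag. Bins are centered on
multiples of the width starting at the lower bound (centers 1000.0,
1000.1, …; membership [c−0.05, c+0.05), half-open so assignment is total
and deterministic — a printed bin mass of 2371.9 covers [2371.85,
2371.95)). Accumulation conserves intensity exactly; bins below the
cumulative threshold (default 5×10⁶, strict less-than) are zeroed;
thresholding is idempotent.

Whether per-scan peak intensities or per-feature intensities are summed is
an open representational choice; this implementation sums deisotoped
feature intensities.

## Assembly, stratification, annotation

A bin is part of the reconstructed glycome iff it survives the intensity
threshold and carries ≥1 attached MS/MS spectrum (matched by precursor
mass into the bin) with SNOG > cut. Category flags are existential: one
passing, flagged spectrum suffices (mirroring the retention rule).
Oligomannose cannot be called from fragments (no specific diagnostic ion),
so it is annotation-assigned: best candidate composition HexNAc2 with
Hex 4–12 and nothing else. Precedence: oligomannose beats undecorated;
undecorated means a glycan bin carrying none of {distal fucose, NeuAc,
NeuGc, alpha-Gal, oligomannose}. Fractions are intensity-weighted and
multi-label, so they can sum past 1.

The composition database enumerates Hex 3–12, HexNAc 2–8, Fuc 0–6,
Neu5Ac+Neu5Gc 0–5 under two biosynthetic constraints (sialic acids ≤
HexNAc−2, i.e. one per antenna; Fuc ≤ HexNAc+1, core plus one per
antennary HexNAc). These rules are this package's own declared defaults
(5240 compositions, 2021 distinct 0.1-Da bins); no claim is made that they
reproduce any particular published database, and entry/bin counts are
reported, not asserted. Annotation attaches every entry within ±0.05 Da of
the bin center, ordered by consistency with the bin's eSNOG flags, then
|Δm|. Exact isobars (Neu5Gc+Fuc = Neu5Ac+Hex) are resolved by the
sialic-acid flags where possible; unresolved ties keep all candidates and
set an ambiguous marker. Glycan bins with no candidate constitute the
unknown fraction (of glycan TIC).

## Cross-sample comparison and isomer profiles

Histograms are TIC-normalized and compared by Pearson correlation. The 2-D
embedding uses t-SNE (exact gradient — sample counts are tens at most, and
the Barnes-Hut approximation is unstable on degenerate inputs) with fixed
seed (default 42) and perplexity min(5, n−1), both recorded in the output;
hierarchical clustering is Ward's variance criterion on Euclidean
distances of the embedding coordinates, serialized as Newick.

Isomer profiles are extracted ion chromatograms at the composition's
reduced [M+H]+ (±0.05 Da) with the retention axis divided by the run's
Man5 apex retention time — the ratio is the only dimensionless reading of
"normalized to Man5", and it pins the Man5 apex at 1.0 in every run. With
multiple Man5-mass elution peaks the most intense apex is the reference.
Profiles are max-normalized for shape comparison (raw intensities behind a
flag). Apexes are local maxima with prominence ≥10% of the trace maximum,
which suppresses scan-to-scan jitter. The tool emits profiles and apex
positions only; assigning exact isomer structures (α2,3 vs α2,6 sialic
linkage, Lewis X vs blood-group H, bisected vs tri-antennary) requires
external retention libraries and is out of scope.

## Synthetic runs and what passing tests show

The generator emulates exactly the statistical structure the pipeline
consumes: a 50-composition panel (oligomannose series, undecorated,
Neu5Ac/Neu5Gc-sialylated, distally fucosylated, alpha-galactosylated, and
five non-canonical compositions absent from the default database), each
eluting as 1–3 Gaussian isomer peaks (σ = 5 s, 1-s sampling) at fixed
multiples of the Man5 retention time (900 s); per-composition abundances
are fixed panel constants spanning 1×10⁸–9×10⁸ so every panel bin clears
the 5×10⁶ threshold; polyhexose contaminant ladders (Hex3–Hex12 alditols,
4×10⁷ each) whose MS/MS spectra contain hexose-ladder ions but no peak
within ±0.05 of 224.11; and trace decoy masses (1×10⁶) that must fall to
the intensity threshold. Glycan MS/MS spectra carry the 224.11 ion at
6–15% of TIC and each truth category's ions above threshold; noise peaks
avoid all diagnostic windows, so category truth is exact by construction.
MS1 features sit at the exact composition mass (no m/z jitter) with ±5%
scan-to-scan intensity jitter. Everything derives from one seed;
identical specs give byte-identical files.

Consequently, passing end-to-end tests demonstrates the correctness of
the bookkeeping — scoring, filtering, binning, alignment, stratification,
annotation and normalization — under the model's assumptions. They do not
demonstrate robustness to what real data adds: chimeric spectra from
co-isolation, gas-phase fucose rearrangement, isotope-envelope overlap,
mass-calibration drift, charge-state errors, or diagnostic-ion intensities
near threshold. The problem sizes used in tests (50 compositions, ~200
spectra, ~4000 features, 500 deisotoping envelopes, 10 samples for
clustering) were chosen as the smallest that exercise every rule,
including all category branches.

## Numerical choices

- Fragment matching tolerance ±0.05 amu; annotation tolerance ±0.05 Da
  (symmetric); both parameters.
- Strict inequalities: SNOG cut (>), intensity threshold (below removed,
  i.e. <). Both tested at the boundary.
- Bin edges are half-open; values exactly on an edge follow IEEE-754
  rounding of the index computation (edges are not exactly representable).
- Zero-TIC spectra score 0; zero-TIC histograms refuse normalization with
  an error; Man5 absence raises a reference-not-found error rather than
  producing unnormalized profiles.
- Printed-value tests compare computed masses within one unit of the last
  printed digit (absolute floor 5e-5): published tables mix rounding and
  protonation conventions at the 1e-5–1e-4 level.

## Known limitations

- The deisotoper assumes unimodal, non-overlapping envelopes; dense
  regions should be deconvoluted externally and imported via CSV.
- SNOG thresholds are acquisition-dependent; defaults fit stepped-HCD-like
  fragment intensity patterns and must be recalibrated for other schemes.
- O-glycans, adducts (Na+/K+), in-source fragments and multiply
  sulfated/phosphorylated species are not modeled in the database.
- Isomer profiles are descriptive; no retention-time prediction or linkage
  assignment is attempted.
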