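# glycosnog

Non-targeted, MS/MS-centric N-glycomics data analysis for PGC-LC-MS/MS
(porous graphitic carbon liquid chromatography, tandem mass spectrometry)
experiments on released, reduced N-glycans.

Instead of targeting a list of anticipated glycan masses, the workflow lets
the fragmentation data identify the glycans:

1. **Diagnostic-ion spectral counting** — every MS/MS spectrum is screened
   for glycan-specific oxonium ions (e.g. HexNAc 204.09, Neu5Ac 292.10,
   Neu5Gc 308.10, dHex·Hex·HexNAc 512.20) and counted per category,
   giving fast precursor-independent profiles of sialylation, fucosylation,
   bisecting GlcNAc, and rarer epitopes.
2. **SNOG scoring and filtering** — the SNOG score of a spectrum is the
   relative intensity of the reduced-end HexNAc oxonium ion (the alditol
   GlcNAc fragment at ~224.11 m/z, unique to chemically reduced glycans):

   `SNOG(s) = I(224.11 ± 0.05) / TIC(s)`

   Spectra with SNOG > 0.03 are accepted as glycan-derived; hexose-oligomer
   contaminants (dextrans, glycogen degradation products) fail the cut.
3. **Glycome reconstruction** — deconvoluted MS1 intensities are summed
   into 0.1-Da bins of singly protonated mass over the whole elution window
   (default 1000–5000 Da), bins below a cumulative intensity of 5×10⁶ are
   removed, and only bins backed by at least one SNOG-passing MS/MS spectrum
   are retained. The result is a MALDI-like semi-quantitative glycome
   histogram per sample.
4. **Sub-structural stratification (eSNOG)** — per-category relative
   intensities of diagnostic ions classify each mass bin as
   distal-fucosylated, Neu5Ac-/Neu5Gc-sialylated, alpha-galactosylated,
   oligomannosidic, or undecorated (multi-label), plus deep-mining
   categories (Lewis Y, Sda, HNK-1, sulfo-HexNAc, fucosylated LacdiNAc,
   O-acetylated sialic acids, di-sialyl Lewis C).
5. **Annotation** — an in-silico composition database (rule-based
   enumeration over Hex/HexNAc/Fuc/Neu5Ac/Neu5Gc) annotates bins by mass
   match within ±0.05 Da; eSNOG flags disambiguate exact isobars
   (Neu5Gc+Fuc vs Neu5Ac+Hex); unannotated glycan bins are reported as an
   unknown-mass fraction.
6. **Comparison and isomer profiling** — TIC-normalized histograms are
   compared across samples (Pearson correlation, t-SNE embedding, Ward
   clustering on the embedding), and per-composition extracted ion
   chromatograms are reported on a retention axis normalized to the Man5
   (Hex5HexNAc2) apex, exposing PGC-separable structural isomers.

A fully seeded synthetic-run generator (`glycosnog.synth`) produces MGF +
feature-CSV + ground-truth files with the statistical structure the
pipeline assumes, so the whole workflow is testable end to end without any
instrument data.

## Worked example

Masses come from a small elemental table (anhydro residues; reduced glycan
[M+H]+ = residues + H₂O + 2H + proton):

```python
>>> from glycosnog import parse_composition, reduced_glycan_mh, oxonium_mz
>>> c = parse_composition("Hex5HexNAc4Fuc1Neu5Ac2")
>>> print(f"{reduced_glycan_mh(c):.4f}")
2371.8638
>>> print(f"{oxonium_mz(parse_composition('Fuc1Hex1HexNAc1')):.4f}")
512.1974
```

2371.8638 is the singly protonated mass of the reduced, core-fucosylated,
doubly Neu5Ac-sialylated biantennary glycan (2371.9 at the 0.1-Da bin
level); 512.1974 is the fucosylated-antenna fragment diagnostic of distal
fucosylation.

End-to-end on a synthetic run:

```bash
glycosnog simulate --out-dir demo --seed 1
glycosnog profile --mgf demo/synthetic.mgf \
    --features demo/synthetic_features.csv --out-dir demo/out --sample-id demo
```

The log reports the filter attrition
(`56 occupied bins, 50 glycan bins retained, 6 bins rejected`): the six
rejected bins are the in-range polyhexose contaminant ladders, removed
because none of their spectra contain the 224.11 ion. `demo/out/categories.tsv`
then holds the stratified glycome (excerpt):

```
category        tic_fraction    n_bins
NeuAc           0.235443        12
NeuGc           0.190506        8
alpha_gal       0.114557        6
distal_fucose   0.220886        13
oligomannose    0.164557        6
undecorated     0.144937        10
```

Fractions are multi-label (a bin can be both sialylated and fucosylated) so
they need not sum to 1. `demo/out/unknown_fraction.json` reports the TIC
fraction of glycan bins that no database composition explains (0.047 here —
the generator's planted non-canonical compositions).

Other subcommands: `count` (per-category spectral counts from an MGF),
`histogram` (mass-bin accumulation from a feature CSV), `compare`
(correlation TSV, embedding TSV, Newick dendrogram), `isomer`
(Man5-normalized elution profile of one composition).

## Layout

- `src/glycosnog/glycomass.py` — mass engine, composition grammar, diagnostic-ion registry
- `src/glycosnog/spectra_io.py` — MGF / feature-CSV / TSV readers and writers
- `src/glycosnog/snog.py` — SNOG/eSNOG scoring, filtering, spectral counting
- `src/glycosnog/ms1_profile.py` — deisotoping, mass-bin histograms, EICs
- `src/glycosnog/assembly.py` — MS/MS-to-bin alignment, stratification, glycoDB, annotation
- `src/glycosnog/comparative_isomer.py` — cross-sample statistics, isomer profiles
- `src/glycosnog/synth.py` — seeded synthetic-run generator with ground truth
- `src/glycosnog/cli.py` — command-line pipeline
- `docs/methods.md` — model, parameters, numerical choices, limitations
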