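"""Cross-sample glycome comparison and isomer elution profiling.

Comparison works on TIC-normalized mass-bin histograms: Pearson correlation
between samples, a 2-D t-SNE embedding, and Ward hierarchical clustering on
Euclidean distances of the embedding coordinates.

Isomer profiling exploits the isomer selectivity of porous graphitic carbon
chromatography: for one glycan composition, the extracted ion chromatogram
shows one elution peak per structural isomer.  To compare elution profiles
across runs, retention times are divided by the apex retention time of the
Man5 glycan (Hex5HexNAc2), the ubiquitously detected reference structure,
so the Man5 apex sits at normalized retention time 1.0 in every run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.signal import find_peaks
from sklearn.manifold import TSNE

from .glycomass import MAN5_MH, GlycanComposition, reduced_glycan_mh
from .ms1_profile import MassHistogram, eic, tic_normalize
from .spectra_io import Ms1Feature

__all__ = [
    "SampleMatrix",
    "ElutionProfile",
    "Man5NotFoundError",
    "pearson_matrix",
    "embed_cluster",
    "top_split_labels",
    "linkage_to_newick",
    "man5_rt",
    "elution_profile",
]


@dataclass
class SampleMatrix:
    """Sample x bin matrix of TIC-normalized histogram intensities."""

    samples: list[str]
    values: np.ndarray  # shape (n_samples, n_bins), rows sum to 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.samples):
            raise ValueError("values must be a (n_samples, n_bins) matrix")

    @classmethod
    def from_histograms(cls, histograms: Sequence[MassHistogram]) -> "SampleMatrix":
        if not histograms:
            raise ValueError("no histograms")
        grid = histograms[0].grid
        for h in histograms:
            if h.grid != grid:
                raise ValueError("histograms must share one bin grid")
        normalized = [tic_normalize(h) for h in histograms]
        return cls(
            samples=[h.sample_id for h in normalized],
            values=np.vstack([h.intensity for h in normalized]),
        )


@dataclass
class ElutionProfile:
    """Man5-normalized elution trace of one glycan composition."""

    composition: GlycanComposition
    normalized_rt: np.ndarray
    intensity: np.ndarray  # max-normalized unless raw requested
    man5_rt: float

    @property
    def apexes(self) -> np.ndarray:
        """Normalized retention times of prominent local maxima of the trace.

        Peaks must rise at least 10% of the trace maximum above their
        surroundings, which suppresses scan-to-scan intensity jitter.
        """
        y = self.intensity
        if len(y) < 3:
            return self.normalized_rt[:len(y)][y > 0] if len(y) else np.array([])
        idx, _ = find_peaks(y, prominence=0.1 * float(y.max()))
        return self.normalized_rt[idx]


class Man5NotFoundError(ValueError):
    """The Man5 reference glycan was not detected; normalization impossible."""


def pearson_matrix(m: SampleMatrix) -> np.ndarray:
    """Sample-by-sample Pearson correlation matrix."""
    if len(m.samples) < 2 or m.values.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 bins")
    sd = m.values.std(axis=1)
    for name, s in zip(m.samples, sd):
        if s == 0:
            raise ValueError(f"zero-variance sample {name!r}")
    return np.corrcoef(m.values)


def embed_cluster(m: SampleMatrix, seed: int = 42, perplexity: float | None = None):
    """2-D t-SNE embedding plus Ward dendrogram on the embedded coordinates.

    Deterministic given the seed.  Default perplexity min(5, n_samples - 1).
    Returns ``(embedding, linkage_matrix)``.
    """
    n = len(m.samples)
    if n < 3:
        raise ValueError("need at least 3 samples to embed and cluster")
    if perplexity is None:
        perplexity = min(5.0, n - 1.0)
    if perplexity >= n:
        raise ValueError("perplexity must be smaller than the number of samples")
    if np.array_equal(m.values, np.tile(m.values[0], (n, 1))):
        # fully degenerate input: identical samples embed at one point
        embedding = np.zeros((n, 2))
        return embedding, linkage(embedding, method="ward", metric="euclidean")
    # exact gradient: sample counts here are tens, and the Barnes-Hut
    # approximation is unstable on degenerate (duplicate-sample) inputs
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
                init="pca", learning_rate="auto", method="exact")
    embedding = tsne.fit_transform(m.values)
    Z = linkage(embedding, method="ward", metric="euclidean")
    return embedding, Z


def top_split_labels(Z: np.ndarray, n_samples: int) -> np.ndarray:
    """Two-group labels from the top split of a dendrogram."""
    return fcluster(Z, t=2, criterion="maxclust")


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree with branch lengths."""
    n = len(labels)

    def node(i: int, parent_height: float) -> str:
        if i < n:
            return f"{labels[i]}:{parent_height:.6g}"
        row = Z[i - n]
        h = row[2]
        left = node(int(row[0]), h / 2)
        right = node(int(row[1]), h / 2)
        return f"({left},{right}):{max(parent_height - h / 2, 0.0):.6g}"

    root = Z[-1]
    h = root[2]
    left = node(int(root[0]), h / 2)
    right = node(int(root[1]), h / 2)
    return f"({left},{right});"


def man5_rt(features: Sequence[Ms1Feature], tol: float = 0.05) -> float:
    """Apex retention time (s) of the Man5 extracted ion trace.

    With multiple Man5-mass peaks the apex of the most intense sample wins.
    """
    rts, ys = eic(features, MAN5_MH, tol)
    if len(rts) == 0:
        raise Man5NotFoundError(
            f"no features within ±{tol} of Man5 [M+H]+ {MAN5_MH:.4f}"
        )
    return float(rts[int(np.argmax(ys))])


def elution_profile(features: Sequence[Ms1Feature], c: GlycanComposition,
                    tol: float = 0.05, reference_rt: float | None = None,
                    normalize_intensity: bool = True) -> ElutionProfile:
    """Man5-normalized extracted ion chromatogram of one composition.

    The retention axis is divided by the run's Man5 apex retention time;
    intensities are max-normalized for cross-tissue shape comparison unless
    ``normalize_intensity`` is disabled.  Absent compositions yield an empty
    profile.
    """
    ref = reference_rt if reference_rt is not None else man5_rt(features, tol)
    if ref <= 0:
        raise Man5NotFoundError("Man5 reference retention time must be positive")
    rts, ys = eic(features, reduced_glycan_mh(c), tol)
    if len(ys) and normalize_intensity and ys.max() > 0:
        ys = ys / ys.max()
    return ElutionProfile(
        composition=c,
        normalized_rt=rts / ref if len(rts) else rts,
        intensity=ys,
        man5_rt=ref,
    )
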