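"""Multilevel wavelet decomposition of (reordered) feature vectors.

Each sample's feature vector is decomposed with the pyramid scheme: the
level-1 approximation cA_1 and detail cD_1 come from low-/high-pass
filtering followed by dyadic downsampling, and level j recurses on the
running approximation cA_{j-1}. The transformed representation of a
sample concatenates [cD_1, ..., cD_J, cA_J].

The full graph-wavelet feature matrix stacks that decomposition for the
feature vector in three arrangements — the original column order, the
greedy minimum-similarity order (smooth) and the greedy maximum-similarity
order (oscillatory) — so low- and high-frequency structure are both
exposed to the regressor. Single-block variants (plain decomposition of
the original order; magnitude Fourier spectrum) serve the feature-
extraction ablation arms.

Boundary handling defaults to periodic wrap-around ("periodization"),
which keeps coefficient counts dyadic and, for orthonormal filters,
preserves energy (Parseval) and allows exact reconstruction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt

from .feature_graph import FeatureOrdering, apply_ordering
from .preprocess import FeatureMatrix

_BOUNDARY_MODES = {"periodic": "periodization", "symmetric": "symmetric"}


@dataclass
class WaveletFilterPair:
    """A discrete wavelet family's analysis filter bank."""

    name: str
    low_pass: np.ndarray
    high_pass: np.ndarray

    @classmethod
    def from_name(cls, name: str = "haar") -> "WaveletFilterPair":
        w = pywt.Wavelet(name)
        return cls(name=name,
                   low_pass=np.asarray(w.dec_lo, dtype=np.float64),
                   high_pass=np.asarray(w.dec_hi, dtype=np.float64))

    @property
    def is_orthonormal(self) -> bool:
        return bool(pywt.Wavelet(self.name).orthogonal)


@dataclass
class WaveletDecomposition:
    levels: int
    details: list[np.ndarray]         # [cD_1, ..., cD_J]
    approximation: np.ndarray         # cA_J
    boundary_mode: str
    input_length: int
    filter_name: str

    def coefficient_vector(self) -> np.ndarray:
        """[cD_1, ..., cD_J, cA_J] concatenated."""
        return np.concatenate(self.details + [self.approximation])


def max_levels(n: int, filters: WaveletFilterPair,
               boundary_mode: str = "periodic") -> int:
    """Deepest feasible decomposition for a length-n vector.

    Periodic wrap-around stays exactly invertible down to length-1
    approximations, so the cap is the dyadic one, floor(log2(n)).
    Symmetric padding uses the filter-length-aware limit instead.
    """
    if boundary_mode == "periodic":
        return int(np.floor(np.log2(n)))
    return pywt.dwt_max_level(n, pywt.Wavelet(filters.name))


def dwt_decompose(x: np.ndarray, filters: WaveletFilterPair,
                  levels: int, boundary_mode: str = "periodic",
                  ) -> WaveletDecomposition:
    """Multilevel pyramid decomposition of a 1-D vector."""
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[0]
    if n < 2:
        raise ValueError("input vector must have length >= 2")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if boundary_mode not in _BOUNDARY_MODES:
        raise ValueError(f"unknown boundary mode {boundary_mode!r}")
    jmax = max_levels(n, filters, boundary_mode)
    if levels > jmax:
        raise ValueError(
            f"levels={levels} too deep for length {n} with {filters.name!r}; "
            f"maximum feasible is {jmax}")
    with warnings.catch_warnings():
        # pywt flags levels beyond its filter-length heuristic; periodization
        # remains exactly invertible there, so the depth cap above governs
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(x, filters.name,
                              mode=_BOUNDARY_MODES[boundary_mode], level=levels)
    cA = coeffs[0]
    details = list(reversed(coeffs[1:]))     # back to [cD_1, ..., cD_J]
    return WaveletDecomposition(levels=levels, details=details,
                                approximation=cA, boundary_mode=boundary_mode,
                                input_length=n, filter_name=filters.name)


def dwt_reconstruct(dec: WaveletDecomposition) -> np.ndarray:
    """Inverse multilevel transform; exact for orthonormal periodic filters."""
    coeffs = [dec.approximation] + list(reversed(dec.details))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        x = pywt.waverec(coeffs, dec.filter_name,
                         mode=_BOUNDARY_MODES[dec.boundary_mode])
    return x[:dec.input_length]


@dataclass
class TransformedFeatureMatrix:
    """Sample x coefficient matrix with a named block layout."""

    values: np.ndarray                        # (M, N')
    block_layout: list[tuple[str, int, int]] = field(default_factory=list)
    # each entry: (label like "min/cD_1", start col, stop col)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def block(self, label: str) -> np.ndarray:
        for lab, lo, hi in self.block_layout:
            if lab == label:
                return self.values[:, lo:hi]
        raise KeyError(label)


def _decompose_rows(values: np.ndarray, filters: WaveletFilterPair,
                    levels: int, boundary_mode: str, prefix: str,
                    ) -> tuple[np.ndarray, list[tuple[str, int, int]]]:
    first = dwt_decompose(values[0], filters, levels, boundary_mode)
    sizes = [d.shape[0] for d in first.details] + [first.approximation.shape[0]]
    labels = [f"{prefix}/cD_{j}" for j in range(1, levels + 1)] + [f"{prefix}/cA_{levels}"]
    rows = np.empty((values.shape[0], sum(sizes)))
    rows[0] = first.coefficient_vector()
    for i in range(1, values.shape[0]):
        rows[i] = dwt_decompose(values[i], filters, levels,
                                boundary_mode).coefficient_vector()
    layout = []
    lo = 0
    for lab, s in zip(labels, sizes):
        layout.append((lab, lo, lo + s))
        lo += s
    return rows, layout


def default_levels(n_features: int,
                   filters: WaveletFilterPair | None = None) -> int:
    filters = filters or WaveletFilterPair.from_name("haar")
    return max(1, min(3, max_levels(n_features, filters)))


def assemble_features(X: FeatureMatrix,
                      u_min: FeatureOrdering, u_max: FeatureOrdering,
                      filters: WaveletFilterPair | None = None,
                      levels: int | None = None,
                      boundary_mode: str = "periodic",
                      ) -> TransformedFeatureMatrix:
    """Graph-wavelet features: decompositions of original, min and max orders."""
    filters = filters or WaveletFilterPair.from_name("haar")
    levels = levels if levels is not None else default_levels(X.shape[1], filters)
    blocks = []
    layout: list[tuple[str, int, int]] = []
    offset = 0
    for prefix, ordered in (("original", X),
                            ("min", apply_ordering(X, u_min)),
                            ("max", apply_ordering(X, u_max))):
        rows, sub = _decompose_rows(ordered.values, filters, levels,
                                    boundary_mode, prefix)
        blocks.append(rows)
        layout.extend((lab, lo + offset, hi + offset) for lab, lo, hi in sub)
        offset += rows.shape[1]
    return TransformedFeatureMatrix(values=np.hstack(blocks), block_layout=layout)


def dwt_only_features(X: FeatureMatrix,
                      filters: WaveletFilterPair | None = None,
                      levels: int | None = None,
                      boundary_mode: str = "periodic",
                      ) -> TransformedFeatureMatrix:
    """Ablation arm: plain multilevel decomposition of the original order."""
    filters = filters or WaveletFilterPair.from_name("haar")
    levels = levels if levels is not None else default_levels(X.shape[1], filters)
    rows, layout = _decompose_rows(X.values, filters, levels, boundary_mode,
                                   "original")
    return TransformedFeatureMatrix(values=rows, block_layout=layout)


def fourier_features(X: FeatureMatrix) -> TransformedFeatureMatrix:
    """Ablation arm: magnitude of the non-redundant half of the DFT per row."""
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features for a Fourier transform")
    mags = np.abs(np.fft.rfft(X.values, axis=1))
    return TransformedFeatureMatrix(values=mags,
                                    block_layout=[("fourier/magnitude", 0,
                                                   mags.shape[1])])


def identity_features(X: FeatureMatrix) -> TransformedFeatureMatrix:
    """No transform: raw standardized columns (the network-only ablation arm)."""
    return TransformedFeatureMatrix(values=np.asarray(X.values, dtype=np.float64),
                                    block_layout=[("raw", 0, X.shape[1])])
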