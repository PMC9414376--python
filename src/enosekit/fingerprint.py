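"""Aroma digital fingerprints: Z-score, PCA, RGB image rendering.

A fingerprint is a deterministic 128×128 RGB image encoding one block of
up to 100 feature vectors: features are Z-score normalized, projected onto
the leading three principal components, and each sample's (PC1, PC2, PC3)
score becomes the (R, G, B) color of one cell in a 10×10 mosaic that is
upsampled to 128×128. The image is an archivable signature of an aroma
class — invertible back to scores given the stored per-channel scaling.

PCA here is authored from first principles (SVD of the centered matrix)
rather than delegated, because the decomposition and its exact
conventions — population vs sample divisors, eigenvector sign, component
order — are part of the fingerprint's reproducibility contract.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
from PIL import Image

from .exceptions import DimensionError, ValidationError

__all__ = [
    "NormalizationParams",
    "PCAModel",
    "FingerprintImage",
    "zscore_fit",
    "zscore_apply",
    "pca_fit",
    "pca_transform",
    "pca_inverse_transform",
    "render_fingerprint",
    "build_fingerprint_library",
]

IMAGE_SIZE = 128
GRID = 10
NEUTRAL = 128  # gray used for empty cells and constant channels


@dataclass
class NormalizationParams:
    """Per-feature Z-score parameters (population SD, divisor n)."""

    means: np.ndarray
    sds: np.ndarray
    zero_variance: np.ndarray = field(default=None)  # bool mask of constant columns

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if self.means.shape != self.sds.shape or self.means.ndim != 1:
            raise DimensionError("means and sds must be 1-D of equal length")
        if np.any(self.sds < 0):
            raise ValidationError("sds must be >= 0")
        if self.zero_variance is None:
            self.zero_variance = np.zeros(len(self.means), dtype=bool)


@dataclass
class PCAModel:
    """Principal axes of a feature matrix.

    ``loadings`` is D×C with orthonormal unit-norm columns sorted by
    descending eigenvalue; ``eigenvalues`` are the corresponding variances
    (covariance divisor n−1). ``total_variance`` is the trace of the full
    covariance matrix, kept so explained-variance ratios do not depend on
    how many components were retained. The sign of each axis is fixed so
    its largest-magnitude loading is positive.
    """

    feature_means: np.ndarray
    loadings: np.ndarray
    eigenvalues: np.ndarray
    total_variance: float
    n_samples: int

    def __post_init__(self) -> None:
        self.feature_means = np.asarray(self.feature_means, dtype=float)
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.loadings.ndim != 2:
            raise DimensionError("loadings must be D×C")
        if self.loadings.shape[0] != len(self.feature_means):
            raise DimensionError("loadings rows must match feature dimension")
        if self.loadings.shape[1] != len(self.eigenvalues):
            raise DimensionError("one eigenvalue per retained component")
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValidationError("eigenvalues must be sorted non-increasing")

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def explained_variance_ratio(self) -> np.ndarray:
        if self.total_variance == 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / self.total_variance

    def to_json(self) -> str:
        return json.dumps(
            {
                "feature_means": self.feature_means.tolist(),
                "loadings": self.loadings.tolist(),
                "eigenvalues": self.eigenvalues.tolist(),
                "total_variance": self.total_variance,
                "n_samples": self.n_samples,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PCAModel":
        d = json.loads(text)
        return cls(
            feature_means=np.array(d["feature_means"]),
            loadings=np.array(d["loadings"]),
            eigenvalues=np.array(d["eigenvalues"]),
            total_variance=float(d["total_variance"]),
            n_samples=int(d["n_samples"]),
        )


@dataclass
class FingerprintImage:
    """A rendered fingerprint: pixels plus the provenance to invert it."""

    pixels: np.ndarray  # 128×128×3 uint8
    block_ids: list[str]
    scaling: list[tuple[float, float]]  # per-channel (min, max) of the scores
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.shape != (IMAGE_SIZE, IMAGE_SIZE, 3):
            raise DimensionError(f"pixels must be {IMAGE_SIZE}×{IMAGE_SIZE}×3")
        if self.pixels.dtype != np.uint8:
            if np.any(self.pixels < 0) or np.any(self.pixels > 255):
                raise ValidationError("pixel values must be in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)

    def save_png(self, path: str | Path) -> None:
        Image.fromarray(self.pixels, mode="RGB").save(str(path), format="PNG")


def zscore_fit(features: np.ndarray) -> NormalizationParams:
    """Column means and population SDs (divisor n).

    Constant columns get SD replaced by 1 (the transform maps them to 0)
    and a warning — never a division by zero.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("need an N×D matrix with N >= 2")
    if not np.all(np.isfinite(X)):
        raise ValidationError("non-finite entries in feature matrix")
    means = X.mean(axis=0)
    sds = X.std(axis=0)  # population (ddof=0)
    zero = sds == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance feature column(s); "
            "their SD is set to 1 so they normalize to 0",
            stacklevel=2,
        )
        sds = np.where(zero, 1.0, sds)
    return NormalizationParams(means=means, sds=sds, zero_variance=zero)


def zscore_apply(features: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """(x − mean)/sd per column; a pure function of its arguments."""
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != len(params.means):
        raise DimensionError(
            f"{X.shape[1]} columns vs {len(params.means)} normalization params"
        )
    return (X - params.means) / params.sds


def pca_fit(normalized: np.ndarray, n_components: int) -> PCAModel:
    """Fit principal axes by SVD of the centered matrix.

    Equivalent to eigendecomposition of the covariance matrix with divisor
    N−1; SVD is used for numerical stability. Deterministic: ties in the
    spectrum are broken by the SVD's ordering and the sign convention.
    """
    X = np.asarray(normalized, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("need an N×D matrix with N >= 2")
    n, d = X.shape
    if not 1 <= n_components <= min(n - 1, d):
        raise ValidationError(
            f"n_components must be in [1, min(N-1, D)] = [1, {min(n - 1, d)}]"
        )
    means = X.mean(axis=0)
    Xc = X - means
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals_full = s**2 / (n - 1)
    loadings = vt[:n_components].T.copy()
    # sign convention: largest-|loading| entry of each axis is positive
    for c in range(loadings.shape[1]):
        col = loadings[:, c]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, c] = -col
    total_var = float(Xc.var(axis=0, ddof=1).sum())
    return PCAModel(
        feature_means=means,
        loadings=loadings,
        eigenvalues=eigvals_full[:n_components],
        total_variance=total_var,
        n_samples=n,
    )


def pca_transform(normalized: np.ndarray, model: PCAModel) -> np.ndarray:
    """Project onto the principal axes: (x − feature_means) · loadings."""
    X = np.asarray(normalized, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.loadings.shape[0]:
        raise DimensionError(
            f"{X.shape[1]} features vs model dimension {model.loadings.shape[0]}"
        )
    return (X - model.feature_means) @ model.loadings


def pca_inverse_transform(scores: np.ndarray, model: PCAModel) -> np.ndarray:
    """Map scores back to feature space (exact when all components kept)."""
    S = np.asarray(scores, dtype=float)
    if S.ndim == 1:
        S = S[None, :]
    if S.shape[1] != model.n_components:
        raise DimensionError(
            f"{S.shape[1]} score columns vs {model.n_components} components"
        )
    return S @ model.loadings.T + model.feature_means


def _scale_channel(values: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    lo, hi = float(values.min()), float(values.max())
    if hi > lo:
        scaled = np.rint(255.0 * (values - lo) / (hi - lo)).astype(np.uint8)
    else:
        scaled = np.full(values.shape, NEUTRAL, dtype=np.uint8)
    return scaled, (lo, hi)


def render_fingerprint(
    features_block: np.ndarray,
    pca: PCAModel,
    norm: NormalizationParams,
    block_ids: Sequence[str] | None = None,
) -> FingerprintImage:
    """Render up to 100 feature vectors as one 128×128 RGB fingerprint.

    Scores on the first three principal components become R, G, B. Samples
    occupy a 10×10 cell grid in row-major order; empty cells are neutral
    gray (128, 128, 128). Each channel is min–max scaled to [0, 255] over
    the block (a constant channel maps to 128), and the grid is upsampled
    by nearest neighbor: pixel (i, j) takes cell (⌊i·10/128⌋, ⌊j·10/128⌋).
    """
    X = np.asarray(features_block, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    n = X.shape[0]
    if n < 1:
        raise ValidationError("empty feature block")
    if n > GRID * GRID:
        raise ValidationError(f"block size {n} exceeds {GRID * GRID}")
    if block_ids is None:
        block_ids = [str(i) for i in range(n)]
    elif len(block_ids) != n:
        raise ValidationError("one block id per sample required")

    scores = pca_transform(zscore_apply(X, norm), pca)
    if scores.shape[1] < 3:
        # degenerate low-dimensional model: pad missing channels with zeros
        scores = np.hstack([scores, np.zeros((n, 3 - scores.shape[1]))])
    scores = scores[:, :3]

    grid = np.full((GRID, GRID, 3), NEUTRAL, dtype=np.uint8)
    scaling: list[tuple[float, float]] = []
    for c in range(3):
        scaled, lohi = _scale_channel(scores[:, c])
        grid.reshape(-1, 3)[:n, c] = scaled
        scaling.append(lohi)

    idx = (np.arange(IMAGE_SIZE) * GRID) // IMAGE_SIZE
    pixels = grid[idx][:, idx]
    return FingerprintImage(
        pixels=pixels,
        block_ids=list(block_ids),
        scaling=scaling,
        metadata={
            "n_samples": n,
            "pca_components": pca.n_components,
            "grid": GRID,
            "image_size": IMAGE_SIZE,
        },
    )


def build_fingerprint_library(
    features: np.ndarray,
    labels: Sequence[str],
    source_ids: Sequence[str],
    pca: PCAModel,
    norm: NormalizationParams,
    output_dir: str | Path,
    block_size: int = 100,
) -> dict:
    """Render and store per-label fingerprints, blocks of ``block_size``.

    For each label, consecutive samples (input order) are chunked into
    blocks of up to ``block_size``, each rendered and written as a PNG; an
    incomplete final block is padded with neutral gray so every sample
    appears in exactly one fingerprint. Returns (and writes) a JSON
    manifest of label, block index, file, source ids and scaling.
    Idempotent: same inputs give byte-identical files.
    """
    X = np.asarray(features, dtype=float)
    labels = list(labels)
    source_ids = list(source_ids)
    if not (len(labels) == len(source_ids) == X.shape[0]):
        raise ValidationError("features, labels and source_ids must align")
    if not 1 <= block_size <= GRID * GRID:
        raise ValidationError(f"block_size must be in [1, {GRID * GRID}]")
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)

    by_label: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        by_label.setdefault(lab, []).append(i)

    entries = []
    for lab, idxs in by_label.items():
        for bi in range(0, len(idxs), block_size):
            chunk = idxs[bi : bi + block_size]
            img = render_fingerprint(
                X[chunk], pca, norm, block_ids=[source_ids[i] for i in chunk]
            )
            safe = "".join(ch if ch.isalnum() or ch in "-_" else "_" for ch in lab)
            fname = f"{safe}_block{bi // block_size:03d}.png"
            img.save_png(out / fname)
            entries.append(
                {
                    "label": lab,
                    "block_index": bi // block_size,
                    "file": fname,
                    "source_ids": img.block_ids,
                    "scaling": img.scaling,
                }
            )
    manifest = {"n_images": len(entries), "block_size": block_size, "images": entries}
    (out / "fingerprints.json").write_text(json.dumps(manifest, indent=2))
    return manifest
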