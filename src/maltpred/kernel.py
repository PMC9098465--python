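"""Metabolomic similarity matrix M = QQ'/m.

Built from the standardized feature matrix the same way a genomic
relationship matrix is built from centered/scaled marker genotypes
(VanRaden's first method): the cross-product of the feature matrix divided
by the number of features. With divisor-n standardization upstream the mean
diagonal of M is exactly 1, so the variance component attached to M is on
the phenotypic scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["KernelMatrix", "build_similarity"]


@dataclass
class KernelMatrix:
    """Symmetric PSD similarity matrix over samples."""

    sample_ids: list[str]
    M: np.ndarray
    m_features: int
    feature_mask_label: str = "all"

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        n = len(self.sample_ids)
        if self.M.shape != (n, n):
            raise ValueError("M shape does not match sample_ids")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def mean_diag(self) -> float:
        return float(np.mean(np.diag(self.M)))

    def index_of(self, ids) -> np.ndarray:
        """Positions of the given sample ids in kernel order."""
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[str(s)] for s in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"sample id {exc.args[0]!r} not in kernel") from exc


def build_similarity(Q, feature_mask=None, label: str | None = None) -> KernelMatrix:
    """Compute M = Q_sub Q_sub' / m_sub from a StandardizedMatrix.

    ``feature_mask`` optionally selects a column subset (boolean mask or
    integer indices) to support kernels restricted to, e.g., heritable
    features; the divisor is always the number of selected columns. No
    re-centering happens here — Q's statistics live in preprocessing.
    """
    mat = Q.Q
    if feature_mask is not None:
        mask = np.asarray(feature_mask)
        if mask.dtype == bool:
            if mask.size != mat.shape[1]:
                raise ValueError("boolean feature_mask length mismatch")
            idx = np.flatnonzero(mask)
        else:
            idx = mask.astype(int)
        if idx.size == 0:
            raise ValueError("feature_mask selects no columns")
        if idx.size < 2:
            raise ValueError("feature_mask must select at least 2 columns")
        mat = mat[:, idx]
        label = label or "subset"
    m = mat.shape[1]
    M = (mat @ mat.T) / m
    M = (M + M.T) / 2.0  # enforce exact symmetry against fp round-off
    return KernelMatrix(
        sample_ids=list(Q.plot_ids),
        M=M,
        m_features=m,
        feature_mask_label=label or "all",
    )
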