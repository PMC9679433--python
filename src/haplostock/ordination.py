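"""Principal coordinate analysis (classical metric MDS) of a distance matrix.

Gower double-centering of -1/2 d^2 followed by an eigendecomposition.
Coordinates are eigenvectors scaled by the square root of their (positive)
eigenvalues; negative eigenvalues — which arise when the distances are not
Euclidean-embeddable — are reported as-is, with no Cailliez/Lingoes
correction. Variance percentages are taken over the positive eigenvalues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import TooFewSamplesError
from .popgen import DistanceMatrix

_EIG_TOL = 1e-9


@dataclass
class PcoaResult:
    """PCoA embedding of a distance matrix."""

    ids: list[str]
    coordinates: np.ndarray          #: (n, n_axes), axes for positive eigenvalues
    eigenvalues: np.ndarray          #: all eigenvalues, non-increasing
    pct_variance_explained: np.ndarray  #: per retained axis, over positive eigenvalues
    n_axes: int

    def frame(self) -> pd.DataFrame:
        cols = [f"axis{i + 1}" for i in range(self.n_axes)]
        return pd.DataFrame(self.coordinates, index=self.ids, columns=cols)


def pcoa(dm: DistanceMatrix | np.ndarray, ids: list[str] | None = None) -> PcoaResult:
    """Classical PCoA of pairwise distances.

    Accepts either a :class:`DistanceMatrix` (nucleotide-difference counts)
    or a raw symmetric distance array. A fully degenerate (all-zero) matrix
    yields all-zero coordinates with a warning rather than an error.

    Axis signs are fixed by forcing the largest-magnitude coordinate on each
    axis to be positive, so results are reproducible across runs and BLAS
    implementations.
    """
    if isinstance(dm, DistanceMatrix):
        d = dm.d.astype(float)
        ids = list(dm.ids)
    else:
        d = np.asarray(dm, dtype=float)
        if ids is None:
            ids = [str(i) for i in range(d.shape[0])]
    n = d.shape[0]
    if n < 3:
        raise TooFewSamplesError("PCoA needs at least 3 samples")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")

    if not d.any():
        warnings.warn("all distances are zero; returning all-zero coordinates")
        return PcoaResult(
            ids=ids, coordinates=np.zeros((n, 1)), eigenvalues=np.zeros(n),
            pct_variance_explained=np.zeros(1), n_axes=1,
        )

    # Gower double-centering: B = -1/2 J d^2 J with J = I - 11'/n
    a = -0.5 * d**2
    row_means = a.mean(axis=1, keepdims=True)
    b = a - row_means - row_means.T + a.mean()
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    positive = eigvals > _EIG_TOL * abs(eigvals[0])
    n_axes = int(positive.sum())
    coords = eigvecs[:, :n_axes] * np.sqrt(eigvals[:n_axes])
    for j in range(n_axes):  # deterministic axis orientation
        if coords[np.argmax(np.abs(coords[:, j])), j] < 0:
            coords[:, j] = -coords[:, j]
    pos_sum = eigvals[:n_axes].sum()
    pct = 100.0 * eigvals[:n_axes] / pos_sum if pos_sum > 0 else np.zeros(n_axes)
    return PcoaResult(
        ids=ids, coordinates=coords, eigenvalues=eigvals,
        pct_variance_explained=pct, n_axes=n_axes,
    )
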