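"""Principal Coordinate Analysis (metric multidimensional scaling).

Classical PCoA: Gower double-centering of -1/2 d^2, eigendecomposition,
coordinates = eigenvectors scaled by sqrt(eigenvalue) for the positive
spectrum.  Negative eigenvalues (non-Euclidean input) are counted and
excluded from the percent-variance denominator.  When the input matrix
already holds *squared* distances (metric tag ``squared-euclidean``, the
GenAlEx band-mismatch convention) its entries are used as d^2 directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distances import DistanceMatrix

_EIG_TOL = 1e-9


@dataclass
class PcoaResult:
    labels: list[str]
    coordinates: np.ndarray  # (n, n_axes)
    eigenvalues: np.ndarray  # positive eigenvalues, decreasing
    pct_variance: np.ndarray  # 100 * eigenvalue / sum(positive eigenvalues)
    n_negative_eigenvalues: int

    def to_frame(self) -> pd.DataFrame:
        cols = [f"axis{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.labels, columns=cols)


def pcoa(d: DistanceMatrix, n_axes: int | None = None) -> PcoaResult:
    """Principal coordinates of a distance matrix.

    ``n_axes`` larger than the positive rank is truncated to it.  Axis
    signs are fixed by making each axis's largest-magnitude loading
    positive, so results are reproducible across platforms.
    """
    values = d.values
    d2 = values if d.metric == "squared-euclidean" else values**2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    b = (b + b.T) / 2.0  # enforce symmetry against round-off
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    scale = max(abs(eigval[0]), 1.0)
    n_neg = int((eigval < -_EIG_TOL * scale).sum())
    pos = eigval > _EIG_TOL * scale
    lam = eigval[pos]
    vec = eigvec[:, pos]

    rank = lam.size
    k = rank if n_axes is None else min(n_axes, rank)
    lam_k, vec_k = lam[:k], vec[:, :k]
    coords = vec_k * np.sqrt(lam_k)
    # deterministic axis orientation
    for a in range(k):
        imax = np.argmax(np.abs(coords[:, a]))
        if coords[imax, a] < 0:
            coords[:, a] = -coords[:, a]
    pct = 100.0 * lam_k / lam.sum()
    return PcoaResult(
        labels=list(d.labels),
        coordinates=coords,
        eigenvalues=lam_k,
        pct_variance=pct,
        n_negative_eigenvalues=n_neg,
    )
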