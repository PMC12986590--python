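"""Genetic distances and UPGMA trees for band profiles.

Nei's standard genetic identity between two frequency profiles x, y over
L loci, counting both band states (present with frequency p, absent with
1-p) as alleles:

    Jxy = mean_l [ x_l y_l + (1-x_l)(1-y_l) ]
    Jx  = mean_l [ x_l^2 + (1-x_l)^2 ]      (Jy likewise)
    I_N = Jxy / sqrt(Jx Jy),   D = -ln I_N

Individual accessions use their raw 0/1 band vectors as frequency
profiles, which makes an accession-level Nei matrix well defined for a
dominant panel.  UPGMA (size-weighted average linkage) turns any of the
distance matrices into an ultrametric dendrogram with Newick export.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .io_core import MISSING, BandMatrix, PopulationMap
from .diversity import dominant_allele_frequencies


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    metric: str = "nei"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if not np.isfinite(self.values).all():
            raise ValueError("distance matrix has non-finite entries")
        if (self.values < -1e-12).any():
            raise ValueError("distance matrix has negative entries")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


def nei_identity(
    freq_x: np.ndarray, freq_y: np.ndarray, both_states: bool = True
) -> float:
    """Nei's normalised gene identity I_N between two frequency profiles."""
    x = np.asarray(freq_x, dtype=float)
    y = np.asarray(freq_y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("frequency vectors differ in length")
    if ((x < 0) | (x > 1) | (y < 0) | (y > 1)).any():
        raise ValueError("frequencies must lie in [0, 1]")
    if both_states:
        jxy = float(np.mean(x * y + (1 - x) * (1 - y)))
        jx = float(np.mean(x * x + (1 - x) * (1 - x)))
        jy = float(np.mean(y * y + (1 - y) * (1 - y)))
    else:
        jxy = float(np.mean(x * y))
        jx = float(np.mean(x * x))
        jy = float(np.mean(y * y))
    if jx == 0.0 or jy == 0.0:
        raise ValueError("gene identity undefined: a profile has zero homozygosity sum")
    return jxy / math.sqrt(jx * jy)


def nei_distance(
    freq_x: np.ndarray, freq_y: np.ndarray, both_states: bool = True
) -> float:
    """Nei's standard genetic distance D = -ln I_N (0 for identical profiles)."""
    i_n = nei_identity(freq_x, freq_y, both_states=both_states)
    if np.allclose(freq_x, freq_y):
        return 0.0
    if i_n <= 0.0:
        raise ValueError("gene identity is zero: Nei distance undefined (infinite)")
    return -math.log(min(i_n, 1.0))


def _profile_rows(
    m: BandMatrix, level: str, pops: PopulationMap | None
) -> tuple[list[str], np.ndarray]:
    if level == "individuals":
        calls = m.calls.astype(float)
        calls[m.calls == MISSING] = np.nan
        return list(m.accession_ids), calls
    if level == "populations":
        if pops is None:
            raise ValueError("population level requires a PopulationMap")
        pops.validate(m)
        rows = np.vstack(
            [dominant_allele_frequencies(m, pops.members(g)) for g in pops.groups]
        )
        return list(pops.groups), rows
    raise ValueError(f"unknown level {level!r}")


def pairwise_matrix(
    m: BandMatrix,
    level: str = "individuals",
    metric: str = "nei",
    pops: PopulationMap | None = None,
    both_states: bool = True,
) -> DistanceMatrix:
    """All-pairs distance matrix at the individual or population level.

    ``squared-euclidean`` is the band-mismatch count on complete binary
    data; with missing calls, pairs are computed over pairwise-complete
    loci and rescaled by L / L_complete.
    """
    labels, profiles = _profile_rows(m, level, pops)
    n = len(labels)
    l_total = profiles.shape[1]
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            xi, xj = profiles[i], profiles[j]
            ok = ~(np.isnan(xi) | np.isnan(xj))
            if not ok.any():
                raise ValueError(
                    f"no pairwise-complete loci between {labels[i]!r} and {labels[j]!r}"
                )
            x, y = xi[ok], xj[ok]
            if metric == "nei":
                d = nei_distance(x, y, both_states=both_states)
            elif metric == "squared-euclidean":
                d = float(np.sum((x - y) ** 2)) * l_total / ok.sum()
            elif metric == "euclidean":
                d = math.sqrt(float(np.sum((x - y) ** 2)) * l_total / ok.sum())
            else:
                raise ValueError(f"unknown metric {metric!r}")
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels, values, metric=metric)


# -- UPGMA ----------------------------------------------------------------------


@dataclass
class TreeNode:
    label: str | None = None
    children: list["TreeNode"] = field(default_factory=list)
    height: float = 0.0  # ultrametric height of this node
    length: float = 0.0  # branch length to the parent

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class Tree:
    root: TreeNode
    labels: list[str]

    def leaf_depths(self) -> dict[str, float]:
        depths: dict[str, float] = {}

        def walk(node: TreeNode, depth: float) -> None:
            d = depth + node.length
            if node.is_leaf:
                depths[node.label] = d
            for c in node.children:
                walk(c, d)

        walk(self.root, -self.root.length)
        return depths

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        depths = list(self.leaf_depths().values())
        return max(depths) - min(depths) <= tol

    def to_newick(self) -> str:
        def quote(label: str) -> str:
            if any(c in label for c in " (),:;'\t"):
                return "'" + label.replace("'", "''") + "'"
            return label

        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{quote(node.label)}:{node.length:.10g}"
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}):{node.length:.10g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"


def upgma(d: DistanceMatrix) -> Tree:
    """Size-weighted average-linkage (UPGMA) tree from a distance matrix.

    Node height is half the merge distance, so the result is exactly
    ultrametric; branch length is the height difference to the parent.
    """
    if len(d.labels) < 2:
        raise ValueError("need at least 2 labels")
    z = linkage(d.condensed(), method="average")
    nodes: dict[int, TreeNode] = {
        i: TreeNode(label=lab) for i, lab in enumerate(d.labels)
    }
    n = len(d.labels)
    for k, (a, b, dist, _) in enumerate(z):
        left, right = nodes.pop(int(a)), nodes.pop(int(b))
        height = dist / 2.0
        left.length = height - left.height
        right.length = height - right.height
        nodes[n + k] = TreeNode(children=[left, right], height=height)
    root = nodes.popitem()[1]
    root.length = 0.0
    return Tree(root=root, labels=list(d.labels))


def write_distance_matrix(d: DistanceMatrix, path) -> None:
    d.to_frame().to_csv(path, sep="\t")


def read_distance_matrix(path, metric: str = "nei") -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix([str(c) for c in df.columns], df.to_numpy(), metric=metric)
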