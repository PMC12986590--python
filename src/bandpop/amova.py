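"""One-level AMOVA with PhiPT and a permutation test for dominant data.

The analysis partitions the pairwise squared Euclidean distances among
individuals (band-mismatch counts on binary profiles) into among-group
and within-group sums of squares:

    SS_total  = sum_{i<j} d2_ij / N
    SS_within = sum_g sum_{i<j in g} d2_ij / n_g
    SS_among  = SS_total - SS_within

with df_among = G-1, df_within = N-G, the average-sample-size
coefficient n0 = (N - sum n_g^2 / N) / (G-1), variance components
Va = (MS_among - MS_within)/n0 (truncated at 0) and Vw = MS_within, and

    PhiPT = Va / (Va + Vw),

the F_ST analogue for dominant markers.  Significance comes from freely
permuting individuals among groups (sizes held fixed) and comparing the
permuted PhiPT to the observed one with an add-one p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import BandMatrix, PopulationMap
from .distances import pairwise_matrix


@dataclass
class AmovaResult:
    df_among: int
    df_within: int
    SS_among: float
    SS_within: float
    SS_total: float
    MS_among: float
    MS_within: float
    n0: float
    Va: float
    Vw: float
    pct_among: float
    pct_within: float
    PhiPT: float
    p_perm: float | None
    n_permutations: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "df": [self.df_among, self.df_within, self.df_among + self.df_within],
                "SS": [self.SS_among, self.SS_within, self.SS_total],
                "MS": [self.MS_among, self.MS_within, np.nan],
                "Est. Var.": [self.Va, self.Vw, self.Va + self.Vw],
                "% Variation": [self.pct_among, self.pct_within, 100.0],
            },
            index=["Among Groups", "Within Groups", "Total"],
        )


def phi_from_components(va: float, vw: float) -> float:
    """PhiPT = Va / (Va + Vw) from non-negative variance components."""
    if va < 0 or vw < 0:
        raise ValueError("variance components must be non-negative")
    if va + vw == 0:
        raise ValueError("PhiPT undefined: both variance components are zero")
    return va / (va + vw)


def _ss_within(d2: np.ndarray, group_indices: list[np.ndarray]) -> float:
    ss = 0.0
    for idx in group_indices:
        if idx.size > 1:
            block = d2[np.ix_(idx, idx)]
            ss += block.sum() / (2.0 * idx.size)
    return ss


def _components(
    d2: np.ndarray, group_indices: list[np.ndarray]
) -> tuple[float, float, float, float, float, float, float]:
    n = d2.shape[0]
    g = len(group_indices)
    ss_total = d2.sum() / (2.0 * n)
    ss_within = _ss_within(d2, group_indices)
    ss_among = ss_total - ss_within
    df_among = g - 1
    df_within = n - g
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within
    sizes = np.array([idx.size for idx in group_indices], dtype=float)
    n0 = (n - (sizes**2).sum() / n) / df_among
    va = (ms_among - ms_within) / n0
    return ss_total, ss_within, ss_among, ms_among, ms_within, n0, va


def amova(
    m: BandMatrix,
    pops: PopulationMap,
    permutations: int = 999,
    seed: int | None = None,
) -> AmovaResult:
    """One-level AMOVA on individual band-mismatch distances.

    ``permutations=0`` skips the significance test (p_perm is None).
    """
    pops.validate(m)
    groups = pops.groups
    if len(groups) < 2:
        raise ValueError("no among-group level: need at least 2 groups")
    n = m.n_accessions
    if n <= len(groups):
        raise ValueError("need more individuals than groups")

    d2 = pairwise_matrix(m, level="individuals", metric="squared-euclidean").values
    acc_index = {a: i for i, a in enumerate(m.accession_ids)}
    group_indices = [
        np.array([acc_index[a] for a in pops.members(g)], dtype=int) for g in groups
    ]

    ss_total, ss_within, ss_among, ms_among, ms_within, n0, va = _components(
        d2, group_indices
    )
    if va < 0:
        warnings.warn("negative among-group variance component truncated to 0", stacklevel=2)
        va = 0.0
    vw = ms_within
    phi = phi_from_components(va, vw)

    p_perm: float | None = None
    if permutations > 0:
        rng = np.random.default_rng(seed)
        sizes = [idx.size for idx in group_indices]
        bounds = np.cumsum(sizes)[:-1]
        count = 0
        for _ in range(permutations):
            perm = rng.permutation(n)
            perm_groups = np.split(perm, bounds)
            *_, ms_a, ms_w, n0_p, va_p = _components(d2, perm_groups)
            va_p = max(va_p, 0.0)
            if va_p + ms_w == 0:
                phi_p = 0.0
            else:
                phi_p = va_p / (va_p + ms_w)
            if phi_p >= phi:
                count += 1
        p_perm = (1.0 + count) / (1.0 + permutations)

    total_var = va + vw
    return AmovaResult(
        df_among=len(groups) - 1,
        df_within=n - len(groups),
        SS_among=ss_among,
        SS_within=ss_within,
        SS_total=ss_total,
        MS_among=ms_among,
        MS_within=ms_within,
        n0=n0,
        Va=va,
        Vw=vw,
        pct_among=100.0 * va / total_var,
        pct_within=100.0 * vw / total_var,
        PhiPT=phi,
        p_perm=p_perm,
        n_permutations=permutations,
    )
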