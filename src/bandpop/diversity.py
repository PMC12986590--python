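"""Within-population diversity indices for dominant band data.

Per group the per-locus within-group band frequency p drives, under the
zero-allele convention for bands absent from the whole group:

    Na contribution: 2 if 0 < p < 1, 1 if p = 1, 0 if p = 0
    Ne contribution: 1/(p^2 + q^2) if p > 0, else 0
    He = 2 p q ; I = -(p ln p + q ln q), both 0 at p in {0, 1}

Group values are means over ALL loci in the dataset, so groups carrying
few of the panel's bands can show Na < 1.  TB counts loci with the band
present in at least one member; Pb counts bands private to the group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import MISSING, BandMatrix, PopulationMap


@dataclass
class PopDiversity:
    group: str
    N: int
    TB: int
    Pb: int
    PBpct_pop: float
    Na: float
    Ne: float
    I: float
    He: float


def dominant_allele_frequencies(
    m: BandMatrix, accessions: list[str], estimator: str = "phenotypic"
) -> np.ndarray:
    """Per-locus frequencies within a set of accessions.

    ``phenotypic`` returns the raw band frequency p (the convention the
    band-state indices here assume).  ``sqrt`` returns the Hardy-Weinberg
    dominant-marker allele-frequency estimate 1 - sqrt(1 - p); a locus
    fixed for the band then maps to allele frequency 1 (no null allele
    observed).
    """
    if not accessions:
        raise ValueError("empty accession set")
    idx = [m.accession_ids.index(a) for a in accessions]
    sub = m.calls[idx].astype(float)
    sub[sub == MISSING] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-missing column -> nan
        p = np.nanmean(sub, axis=0)
    if estimator == "phenotypic":
        return p
    if estimator == "sqrt":
        return 1.0 - np.sqrt(1.0 - p)
    raise ValueError(f"unknown estimator {estimator!r}")


def _group_frequencies(
    m: BandMatrix, pops: PopulationMap, estimator: str
) -> dict[str, np.ndarray]:
    pops.validate(m)
    return {
        g: dominant_allele_frequencies(m, pops.members(g), estimator)
        for g in pops.groups
    }


def population_diversity(
    m: BandMatrix, pops: PopulationMap, estimator: str = "phenotypic"
) -> list[PopDiversity]:
    """Per-group diversity rows over the full locus set."""
    freqs = _group_frequencies(m, pops, estimator)
    l_total = m.n_loci
    present = {g: freqs[g] > 0 for g in freqs}  # nan > 0 is False
    out: list[PopDiversity] = []
    for g in pops.groups:
        n = len(pops.members(g))
        if n < 2:
            warnings.warn(
                f"group {g!r} has a single member; within-group polymorphism "
                "is not meaningful",
                stacklevel=2,
            )
        p = freqs[g]
        others = np.zeros(l_total, dtype=bool)
        for h in pops.groups:
            if h != g:
                others |= present[h]
        tb = int(present[g].sum())
        pb = int((present[g] & ~others).sum())

        poly = (p > 0) & (p < 1)
        fixed = p == 1
        with np.errstate(invalid="ignore"):
            na = np.where(poly, 2.0, np.where(fixed, 1.0, 0.0))
            q = 1.0 - p
            ne = np.where(p > 0, 1.0 / (p * p + q * q), 0.0)
            he = 2.0 * p * q
            pi = np.clip(p, 1e-300, 1.0)
            qi = np.clip(q, 1e-300, 1.0)
            shannon = np.where(poly, -(p * np.log(pi) + q * np.log(qi)), 0.0)
        # loci unscored within the group contribute nothing
        valid = ~np.isnan(p)
        denom = valid.sum()
        out.append(
            PopDiversity(
                group=g,
                N=n,
                TB=tb,
                Pb=pb,
                PBpct_pop=100.0 * float(poly[valid].sum()) / denom,
                Na=float(np.nansum(na[valid]) / denom),
                Ne=float(np.nansum(ne[valid]) / denom),
                I=float(np.nansum(shannon[valid]) / denom),
                He=float(np.nansum(he[valid]) / denom),
            )
        )
    return out


def diversity_frame(rows: list[PopDiversity], with_mean: bool = True) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in rows]).set_index("group")
    if with_mean:
        df.loc["Mean"] = df.mean(axis=0)
    return df


@dataclass
class GenotypeSpecificLoci:
    """Loci diagnostic for single accessions.

    ``unique_present``: accession -> loci whose band only it carries;
    ``unique_absent``: accession -> loci whose band only it lacks.
    """

    unique_present: dict[str, list[str]]
    unique_absent: dict[str, list[str]]

    @property
    def n_unique_present(self) -> int:
        return sum(len(v) for v in self.unique_present.values())


def genotype_specific_loci(m: BandMatrix) -> GenotypeSpecificLoci:
    """Find loci carried by exactly one accession (or missing from exactly one)."""
    present: dict[str, list[str]] = {a: [] for a in m.accession_ids}
    absent: dict[str, list[str]] = {a: [] for a in m.accession_ids}
    calls = m.calls
    for j, loc in enumerate(m.locus_ids):
        col = calls[:, j]
        scored = col != MISSING
        ones = np.flatnonzero((col == 1) & scored)
        zeros = np.flatnonzero((col == 0) & scored)
        if ones.size == 1 and zeros.size >= 1:
            present[m.accession_ids[ones[0]]].append(loc)
        if zeros.size == 1 and ones.size >= 1:
            absent[m.accession_ids[zeros[0]]].append(loc)
    return GenotypeSpecificLoci(
        {a: v for a, v in present.items() if v},
        {a: v for a, v in absent.items() if v},
    )
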