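"""Per-primer marker-informativeness statistics for dominant markers.

For a primer with PB polymorphic and MB monomorphic (always-present)
bands and per-locus band frequencies f_i over all accessions:

    PIC_i = 2 f_i (1 - f_i)               (per locus; primer value = mean)
    beta  = PB / (PB + MB)
    EMR   = n x beta    with n the primer's fragment count (default)
    MI    = EMR x PIC
    RP    = sum_i Ib_i,  Ib_i = 1 - 2|0.5 - f_i|

plus the locus-level allele statistics over band states (p, 1-p):
Na (2 if polymorphic else 1), Ne = 1/(p^2 + q^2), gene diversity
H = 2pq and Shannon's I = -(p ln p + q ln q).

Loci whose band is absent in every accession are not "bands" of the
primer: they count toward neither PB nor MB and are reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import (
    MONOMORPHIC_ABSENT,
    MONOMORPHIC_PRESENT,
    POLYMORPHIC,
    BandMatrix,
    LocusSummary,
    summarize_loci,
)


def pic_locus(f: float) -> float:
    """Two-state polymorphic information content 2f(1-f); max 0.5 at f=0.5."""
    return 2.0 * f * (1.0 - f)


def band_informativeness(f: float) -> float:
    """Resolving-power term Ib = 1 - 2|0.5 - f|; 1 at f=0.5, 0 when fixed."""
    return 1.0 - 2.0 * abs(0.5 - f)


def na_from_band_counts(pb: int, mb: int) -> float:
    """Mean allele number over a primer's bands: (2 PB + MB) / (PB + MB)."""
    if pb + mb == 0:
        raise ValueError("primer has no amplified bands")
    return (2.0 * pb + mb) / (pb + mb)


@dataclass
class PrimerStats:
    primer_id: str
    PB: int
    MB: int
    n_absent: int
    PBpct: float
    beta: float
    n_frag: float
    EMR: float
    PIC: float
    MI: float
    RP: float


@dataclass
class PrimerAlleleStats:
    """Per-primer means of the locus-level allele statistics (Na, Ne, H, I)."""

    primer_id: str
    Na: float
    Ne: float
    H: float
    I: float


def _primer_summaries(
    summaries: list[LocusSummary], primer_id: str
) -> list[LocusSummary]:
    rows = [s for s in summaries if s.primer_id == primer_id]
    if not rows:
        raise KeyError(f"primer {primer_id!r} has no loci")
    return rows


def primer_stats(
    m: BandMatrix,
    primer_id: str,
    emr_n: str = "primer_total",
    _summaries: list[LocusSummary] | None = None,
) -> PrimerStats:
    """Informativeness row for one primer.

    ``emr_n`` selects the fragment count n entering EMR: the primer's own
    band count (``primer_total``, default) or the matrix-wide mean band
    count per primer (``global_mean``).
    """
    summaries = _summaries if _summaries is not None else summarize_loci(m)
    rows = _primer_summaries(summaries, primer_id)
    pb = sum(1 for s in rows if s.status == POLYMORPHIC)
    mb = sum(1 for s in rows if s.status == MONOMORPHIC_PRESENT)
    n_absent = sum(1 for s in rows if s.status == MONOMORPHIC_ABSENT)
    if pb + mb == 0:
        raise ValueError(f"primer {primer_id!r}: no amplified bands")
    amplified = [s for s in rows if s.status != MONOMORPHIC_ABSENT]
    beta = pb / (pb + mb)
    if emr_n == "primer_total":
        n_frag = float(pb + mb)
    elif emr_n == "global_mean":
        amp_total = sum(
            1 for s in summaries if s.status != MONOMORPHIC_ABSENT
        )
        n_frag = amp_total / len({s.primer_id for s in summaries})
    else:
        raise ValueError(f"unknown emr_n {emr_n!r}")
    pic = float(np.mean([pic_locus(s.band_frequency) for s in amplified]))
    emr = n_frag * beta
    return PrimerStats(
        primer_id=primer_id,
        PB=pb,
        MB=mb,
        n_absent=n_absent,
        PBpct=100.0 * pb / (pb + mb),
        beta=beta,
        n_frag=n_frag,
        EMR=emr,
        PIC=pic,
        MI=emr * pic,
        RP=float(sum(band_informativeness(s.band_frequency) for s in amplified)),
    )


def primer_table(
    m: BandMatrix, emr_n: str = "primer_total"
) -> tuple[list[PrimerStats], dict[str, float]]:
    """All primers' stats plus a totals/means summary.

    The summary sums PB and MB and averages PB%, EMR, RP, MI and PIC over
    primers; ``mean_PB`` is the mean polymorphic-band count per primer.
    """
    summaries = summarize_loci(m)
    rows = [
        primer_stats(m, p, emr_n=emr_n, _summaries=summaries) for p in m.primer_ids
    ]
    summary = {
        "total_PB": float(sum(r.PB for r in rows)),
        "total_MB": float(sum(r.MB for r in rows)),
        "total_bands": float(sum(r.PB + r.MB for r in rows)),
        "mean_PB": float(np.mean([r.PB for r in rows])),
        "mean_PBpct": float(np.mean([r.PBpct for r in rows])),
        "mean_EMR": float(np.mean([r.EMR for r in rows])),
        "mean_RP": float(np.mean([r.RP for r in rows])),
        "mean_MI": float(np.mean([r.MI for r in rows])),
        "mean_PIC": float(np.mean([r.PIC for r in rows])),
    }
    return rows, summary


def summarize_primer_counts(table: pd.DataFrame) -> dict[str, float]:
    """Totals/means from an already-tabulated per-primer table.

    Accepts a DataFrame with integer ``PB``/``MB`` columns (one row per
    primer) and optional numeric columns (``PIC``, ``Na``, ``H`` ...);
    recomputes PB% per primer and returns totals plus column means.  This
    lets published per-primer summaries be re-analysed without the
    underlying band matrix.
    """
    if not {"PB", "MB"} <= set(table.columns):
        raise ValueError("table needs PB and MB columns")
    pb = table["PB"].to_numpy(dtype=float)
    mb = table["MB"].to_numpy(dtype=float)
    out: dict[str, float] = {
        "total_PB": float(pb.sum()),
        "total_MB": float(mb.sum()),
        "total_bands": float((pb + mb).sum()),
        "mean_PB": float(pb.mean()),
        "mean_PBpct": float((100.0 * pb / (pb + mb)).mean()),
    }
    for col in table.columns:
        if col in ("PB", "MB") or not pd.api.types.is_numeric_dtype(table[col]):
            continue
        out[f"mean_{col}"] = float(table[col].mean())
    return out


def locus_allele_stats(p: float) -> tuple[float, float, float, float]:
    """(Na, Ne, H, I) for one locus with band-state frequencies (p, 1-p)."""
    q = 1.0 - p
    na = 2.0 if 0.0 < p < 1.0 else 1.0
    ne = 1.0 / (p * p + q * q)
    h = 2.0 * p * q
    i = 0.0
    if 0.0 < p < 1.0:
        i = -(p * np.log(p) + q * np.log(q))
    return na, ne, h, float(i)


def per_locus_allele_stats(
    m: BandMatrix, primer_id: str, _summaries: list[LocusSummary] | None = None
) -> PrimerAlleleStats:
    """Primer-level means of Na, Ne, H, I over its amplified loci."""
    summaries = _summaries if _summaries is not None else summarize_loci(m)
    rows = [
        s
        for s in _primer_summaries(summaries, primer_id)
        if s.status != MONOMORPHIC_ABSENT
    ]
    if not rows:
        raise ValueError(f"primer {primer_id!r}: no amplified bands")
    vals = np.array([locus_allele_stats(s.band_frequency) for s in rows])
    na, ne, h, i = vals.mean(axis=0)
    return PrimerAlleleStats(primer_id, float(na), float(ne), float(h), float(i))


def allele_stats_table(m: BandMatrix) -> tuple[list[PrimerAlleleStats], dict[str, float]]:
    summaries = summarize_loci(m)
    rows = [per_locus_allele_stats(m, p, _summaries=summaries) for p in m.primer_ids]
    summary = {
        "mean_Na": float(np.mean([r.Na for r in rows])),
        "mean_Ne": float(np.mean([r.Ne for r in rows])),
        "mean_H": float(np.mean([r.H for r in rows])),
        "mean_I": float(np.mean([r.I for r in rows])),
    }
    return rows, summary


def primer_table_frame(m: BandMatrix, emr_n: str = "primer_total") -> pd.DataFrame:
    """Combined per-primer table (informativeness + allele stats) for export."""
    stats, _ = primer_table(m, emr_n=emr_n)
    alleles = {r.primer_id: r for r in allele_stats_table(m)[0]}
    recs = []
    for r in stats:
        a = alleles[r.primer_id]
        recs.append(
            {
                "primer_id": r.primer_id,
                "PB": r.PB,
                "MB": r.MB,
                "PBpct": r.PBpct,
                "EMR": r.EMR,
                "RP": r.RP,
                "MI": r.MI,
                "PIC": r.PIC,
                "Na": a.Na,
                "Ne": a.Ne,
                "H": a.H,
                "I": a.I,
            }
        )
    return pd.DataFrame(recs).set_index("primer_id")
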