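"""Data model and file formats for dominant-marker band matrices.

A band matrix records, for each accession (row) and scored fragment
position ("locus" or "band", column), whether the band was amplified
(1), absent (0), or could not be scored (missing).  Every locus belongs
to exactly one primer.  This module owns the in-memory containers used
by every downstream analysis plus delimited-text readers/writers and a
GenAlEx-style binary export for interoperability.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING: int = -1
#: tokens accepted as "missing" on input
MISSING_TOKENS = {".", "", "NA", "na", "nan", "NaN"}

MONOMORPHIC_PRESENT = "monomorphic-present"
MONOMORPHIC_ABSENT = "monomorphic-absent"
POLYMORPHIC = "polymorphic"


class BandMatrixError(ValueError):
    """Raised when a band matrix or one of its companion maps is invalid."""


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise BandMatrixError(f"duplicate {what} id: {lab!r}")
        seen.add(lab)


@dataclass
class BandMatrix:
    """Accessions x loci binary presence calls with a primer per locus.

    Parameters
    ----------
    accession_ids : sequence of str
        Ordered, unique row labels (>= 2).
    locus_ids : sequence of str
        Ordered, unique column labels (>= 1).
    calls : ndarray of int8, shape (n_accessions, n_loci)
        Entries in {0, 1, -1}; -1 marks a missing call.
    locus_primer : mapping locus_id -> primer_id
        Every locus must be assigned to exactly one primer.
    """

    accession_ids: list[str]
    locus_ids: list[str]
    calls: np.ndarray
    locus_primer: dict[str, str]

    def __post_init__(self) -> None:
        self.accession_ids = [str(a) for a in self.accession_ids]
        self.locus_ids = [str(l) for l in self.locus_ids]
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if len(self.accession_ids) < 2:
            raise BandMatrixError("need at least 2 accessions")
        if len(self.locus_ids) < 1:
            raise BandMatrixError("need at least 1 locus")
        _check_unique(self.accession_ids, "accession")
        _check_unique(self.locus_ids, "locus")
        if self.calls.shape != (len(self.accession_ids), len(self.locus_ids)):
            raise BandMatrixError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.accession_ids)} accessions x {len(self.locus_ids)} loci"
            )
        bad = ~np.isin(self.calls, (0, 1, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise BandMatrixError(
                f"non-binary call {self.calls[i, j]} at accession "
                f"{self.accession_ids[i]!r}, locus {self.locus_ids[j]!r}"
            )
        for loc in self.locus_ids:
            if loc not in self.locus_primer:
                raise BandMatrixError(f"locus {loc!r} has no primer assignment")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def primer_ids(self) -> list[str]:
        """Primer ids in order of first appearance along the locus axis."""
        out: list[str] = []
        seen: set[str] = set()
        for loc in self.locus_ids:
            p = self.locus_primer[loc]
            if p not in seen:
                seen.add(p)
                out.append(p)
        return out

    def loci_for_primer(self, primer_id: str) -> list[str]:
        loci = [l for l in self.locus_ids if self.locus_primer[l] == primer_id]
        if not loci:
            raise KeyError(f"primer {primer_id!r} has no loci in this matrix")
        return loci

    def locus_index(self, locus_id: str) -> int:
        return self.locus_ids.index(locus_id)

    def has_missing(self) -> bool:
        return bool((self.calls == MISSING).any())

    def to_frame(self) -> pd.DataFrame:
        """Calls as a DataFrame with NaN for missing."""
        arr = self.calls.astype(float)
        arr[self.calls == MISSING] = np.nan
        return pd.DataFrame(arr, index=self.accession_ids, columns=self.locus_ids)

    def subset(self, accessions: Sequence[str]) -> "BandMatrix":
        idx = [self.accession_ids.index(a) for a in accessions]
        return BandMatrix(
            list(accessions),
            list(self.locus_ids),
            self.calls[idx],
            dict(self.locus_primer),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BandMatrix):
            return NotImplemented
        return (
            self.accession_ids == other.accession_ids
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.calls, other.calls)
            and {l: self.locus_primer[l] for l in self.locus_ids}
            == {l: other.locus_primer[l] for l in other.locus_ids}
        )


@dataclass
class PopulationMap:
    """Assignment of every accession to one group/population."""

    assignment: dict[str, str]

    @property
    def groups(self) -> list[str]:
        out: list[str] = []
        seen: set[str] = set()
        for g in self.assignment.values():
            if g not in seen:
                seen.add(g)
                out.append(g)
        return out

    def members(self, group: str) -> list[str]:
        return [a for a, g in self.assignment.items() if g == group]

    def sizes(self) -> dict[str, int]:
        return {g: len(self.members(g)) for g in self.groups}

    def validate(self, m: BandMatrix) -> None:
        for a in m.accession_ids:
            if a not in self.assignment:
                raise BandMatrixError(f"accession {a!r} has no group assignment")
        for a in self.assignment:
            if a not in m.accession_ids:
                raise BandMatrixError(f"assigned accession {a!r} not in matrix")


@dataclass
class LocusSummary:
    locus_id: str
    primer_id: str
    band_frequency: float
    status: str
    n_scored: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.band_frequency <= 1.0:
            raise BandMatrixError(
                f"band frequency {self.band_frequency} out of [0, 1] "
                f"at locus {self.locus_id!r}"
            )


def summarize_loci(m: BandMatrix) -> list[LocusSummary]:
    """Per-locus band frequency and polymorphism status.

    Missing calls are excluded locus-wise from the frequency; a locus
    with no scored calls at all is an error (its frequency is undefined).
    """
    out: list[LocusSummary] = []
    for j, loc in enumerate(m.locus_ids):
        col = m.calls[:, j]
        scored = col[col != MISSING]
        if scored.size == 0:
            raise BandMatrixError(f"locus {loc!r}: all calls missing, frequency undefined")
        p = float(scored.mean())
        if p == 0.0:
            status = MONOMORPHIC_ABSENT
        elif p == 1.0:
            status = MONOMORPHIC_PRESENT
        else:
            status = POLYMORPHIC
        out.append(LocusSummary(loc, m.locus_primer[loc], p, status, int(scored.size)))
    return out


# -- delimited-text formats ----------------------------------------------------

_EMBEDDED_PRIMER_RE = re.compile(r"^(?P<primer>.+)\.(?P<band>\d+)$")


def _sep_for(path: Path, dialect: str | None) -> str:
    if dialect == "csv":
        return ","
    if dialect == "tsv":
        return "\t"
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_band_matrix(
    path: str | Path,
    locus_map: str | Path | Mapping[str, str] | None = None,
    dialect: str | None = None,
    require_complete: bool = False,
) -> BandMatrix:
    """Read a band matrix from delimited text.

    The header row gives locus ids and the first column accession ids.
    Tokens ``0``/``1`` are calls; ``.``, ``NA`` and empty cells are
    missing.  The locus -> primer map is either embedded in the locus ids
    (``PRIMER.k``) or supplied separately as a two-column file or mapping.
    """
    path = Path(path)
    sep = _sep_for(path, dialect)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    accession_ids = [str(a) for a in df.index]
    locus_ids = [str(c) for c in df.columns]

    calls = np.empty(df.shape, dtype=np.int8)
    for i, acc in enumerate(accession_ids):
        for j, loc in enumerate(locus_ids):
            tok = df.iat[i, j].strip()
            if tok in MISSING_TOKENS:
                calls[i, j] = MISSING
            elif tok in ("0", "1"):
                calls[i, j] = int(tok)
            else:
                raise BandMatrixError(
                    f"non-binary token {tok!r} at row {acc!r}, column {loc!r}"
                )

    if locus_map is None:
        primer_map: dict[str, str] = {}
        for loc in locus_ids:
            mobj = _EMBEDDED_PRIMER_RE.match(loc)
            if mobj is None:
                raise BandMatrixError(
                    f"locus {loc!r} is not of the form PRIMER.k and no locus map given"
                )
            primer_map[loc] = mobj.group("primer")
    elif isinstance(locus_map, (str, Path)):
        primer_map = read_locus_map(locus_map)
    else:
        primer_map = {str(k): str(v) for k, v in locus_map.items()}

    m = BandMatrix(accession_ids, locus_ids, calls, primer_map)
    if require_complete and m.has_missing():
        raise BandMatrixError("matrix contains missing calls (complete data required)")
    return m


def write_band_matrix(m: BandMatrix, path: str | Path, dialect: str | None = None) -> None:
    path = Path(path)
    sep = _sep_for(path, dialect)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("accession" + sep + sep.join(m.locus_ids) + "\n")
        for i, acc in enumerate(m.accession_ids):
            toks = ["." if c == MISSING else str(int(c)) for c in m.calls[i]]
            fh.write(acc + sep + sep.join(toks) + "\n")


def read_locus_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV ``locus_id<TAB>primer_id`` (header optional)."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise BandMatrixError(f"{path}:{ln}: expected 2 columns, got {len(parts)}")
            if ln == 1 and parts[0].lower() in ("locus", "locus_id"):
                continue
            if parts[0] in out:
                raise BandMatrixError(f"{path}:{ln}: duplicate locus id {parts[0]!r}")
            out[parts[0]] = parts[1]
    return out


def write_locus_map(locus_primer: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("locus_id\tprimer_id\n")
        for loc, primer in locus_primer.items():
            fh.write(f"{loc}\t{primer}\n")


def read_population_map(path: str | Path) -> PopulationMap:
    """Two-column TSV ``accession_id<TAB>group`` (header optional)."""
    assignment: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise BandMatrixError(f"{path}:{ln}: expected 2 columns, got {len(parts)}")
            if ln == 1 and parts[0].lower() in ("accession", "accession_id", "sample"):
                continue
            if parts[0] in assignment:
                raise BandMatrixError(f"{path}:{ln}: duplicate accession {parts[0]!r}")
            assignment[parts[0]] = parts[1]
    return PopulationMap(assignment)


def write_population_map(pops: PopulationMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("accession_id\tgroup\n")
        for acc, group in pops.assignment.items():
            fh.write(f"{acc}\t{group}\n")


# -- GenAlEx-style binary export ----------------------------------------------


def write_genalex(
    m: BandMatrix,
    pops: PopulationMap,
    path: str | Path,
    title: str = "band matrix",
) -> None:
    """Write a GenAlEx-style binary (haploid 0/1) worksheet as CSV.

    Layout: row 1 holds ``n_loci, n_samples, n_pops, size_1, ..., size_G``;
    row 2 the title and the population names above their size cells; row 3
    the column header (``Sample, Pop, locus...``); then one row per sample
    grouped by population.  Missing calls are written as ``-1``.
    """
    pops.validate(m)
    groups = pops.groups
    sizes = pops.sizes()
    with open(Path(path), "w", encoding="utf-8") as fh:
        row1 = [str(m.n_loci), str(m.n_accessions), str(len(groups))]
        row1 += [str(sizes[g]) for g in groups]
        fh.write(",".join(row1) + "\n")
        row2 = [title, "", ""] + list(groups)
        fh.write(",".join(row2) + "\n")
        fh.write(",".join(["Sample", "Pop"] + m.locus_ids) + "\n")
        for g in groups:
            for acc in pops.members(g):
                i = m.accession_ids.index(acc)
                toks = [str(int(c)) for c in m.calls[i]]
                fh.write(",".join([acc, g] + toks) + "\n")


def read_genalex(
    path: str | Path, locus_map: Mapping[str, str] | None = None
) -> tuple[BandMatrix, PopulationMap]:
    """Read a GenAlEx-style binary worksheet written by :func:`write_genalex`."""
    with open(Path(path), encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    hdr = lines[0].split(",")
    n_loci, n_samples = int(hdr[0]), int(hdr[1])
    cols = lines[2].split(",")
    locus_ids = cols[2 : 2 + n_loci]
    accession_ids: list[str] = []
    group_of: dict[str, str] = {}
    calls = np.empty((n_samples, n_loci), dtype=np.int8)
    for i, line in enumerate(lines[3 : 3 + n_samples]):
        parts = line.split(",")
        accession_ids.append(parts[0])
        group_of[parts[0]] = parts[1]
        calls[i] = [int(t) for t in parts[2 : 2 + n_loci]]
    if locus_map is None:
        locus_map = {
            loc: (_EMBEDDED_PRIMER_RE.match(loc).group("primer")
                  if _EMBEDDED_PRIMER_RE.match(loc) else loc)
            for loc in locus_ids
        }
    m = BandMatrix(accession_ids, locus_ids, calls, dict(locus_map))
    return m, PopulationMap(group_of)
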