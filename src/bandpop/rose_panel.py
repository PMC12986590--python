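"""Published summary statistics of a 15-primer SCoT panel on 38 rose accessions.

A widely used benchmark for this package: a dominant-marker survey of 38
oil-bearing rose accessions (Rosa damascena breeding material and
cultivars, R. gallica, R. alba, R. centifolia, one admixed hybrid
cultivar and an unidentified clonal population) genotyped with 15 SCoT
primers yielding 238 bands.  The raw band matrix was not deposited, but
the published per-primer and AMOVA summaries below serve as inputs for
consistency checks: the package's table-level statistics must reproduce
the derived columns (PB%, totals, means, the Na identity) from these
counts.

``PER_PRIMER`` columns: PB/MB are polymorphic/monomorphic band counts;
PIC, Na, Ne, H, I are the reported per-primer means.
"""

from __future__ import annotations

import pandas as pd

# per-primer band counts and reported index means
_PER_PRIMER_ROWS = [
    # primer,   PB, MB,  PIC,   Na,   Ne,    H,    I
    ("SCoT2",   12,  3, 0.47, 1.80, 1.30, 0.24, 0.37),
    ("SCoT3",   19,  1, 0.50, 1.95, 1.56, 0.32, 0.48),
    ("SCoT6",    2,  0, 0.78, 2.00, 1.99, 0.50, 0.69),
    ("SCoT11",  17,  1, 0.60, 1.88, 1.37, 0.26, 0.39),
    ("SCoT12",  15,  4, 0.41, 1.79, 1.33, 0.21, 0.34),
    ("SCoT13",  17,  1, 0.48, 1.94, 1.53, 0.31, 0.64),
    ("SCoT15",  11,  4, 0.38, 1.73, 1.21, 0.14, 0.30),
    ("SCoT17",  10,  4, 0.72, 1.77, 1.40, 0.25, 0.38),
    ("SCoT19",  16,  3, 0.53, 1.80, 1.43, 0.26, 0.41),
    ("SCoT21",  18,  0, 0.75, 2.00, 1.52, 0.33, 0.49),
    ("SCoT22",   7,  3, 0.45, 1.70, 1.38, 0.23, 0.34),
    ("SCoT25",  16,  5, 0.59, 1.76, 1.45, 0.26, 0.39),
    ("SCoT31",  13,  4, 0.50, 1.76, 1.34, 0.21, 0.33),
    ("SCoT33",  14,  5, 0.48, 1.73, 1.14, 0.22, 0.34),
    ("SCoT36",   7,  6, 0.20, 1.54, 1.29, 0.15, 0.24),
]

PER_PRIMER: pd.DataFrame = pd.DataFrame(
    _PER_PRIMER_ROWS, columns=["primer_id", "PB", "MB", "PIC", "Na", "Ne", "H", "I"]
).set_index("primer_id")

#: group labels and sizes of the 38-accession panel
GROUP_SIZES: dict[str, int] = {
    "Kl": 8,   # unidentified clonal population
    "G": 5,    # R. gallica
    "P": 9,    # R. damascena breeding population
    "A": 4,    # R. alba
    "C": 2,    # R. centifolia
    "R": 2,    # admixed hybrid cultivar
    "I": 2,    # cultivar pair
    "Y": 2,    # cultivar pair
    "E": 2,    # cultivar pair
    "SV": 2,   # cultivar pair
}

#: reported AMOVA variance components for the panel (among / within groups)
AMOVA_VA = 12.759
AMOVA_VW = 20.153
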