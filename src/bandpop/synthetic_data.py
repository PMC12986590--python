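"""Synthetic dominant-marker band matrices with known truth.

Bands are simulated as haploid binary phenotypes: each of K ancestral
clusters carries a per-locus band-presence probability f_kl drawn around
an ancestral frequency via the Balding-Nichols parameterisation, and an
accession with ancestry vector q (rows of the true Q matrix) shows a
band with probability sum_k q_k * f_kl.  Clonal groups copy a single
drawn parent genotype; symmetric per-call flip noise emulates scoring
error.  Every downstream stage of the pipeline has a parameter-recovery
test against the truth object returned here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_core import BandMatrix, PopulationMap


class ConfigError(ValueError):
    """Raised for an invalid simulation configuration."""


@dataclass
class GroupSpec:
    """One simulated group: label, size, ancestry over the K clusters, clonality."""

    label: str
    size: int
    ancestry: tuple[float, ...]
    clonal: bool = False

    def validate(self, k: int) -> None:
        if self.size < 1:
            raise ConfigError(f"group {self.label!r}: size must be >= 1")
        anc = np.asarray(self.ancestry, dtype=float)
        if anc.shape != (k,):
            raise ConfigError(
                f"group {self.label!r}: ancestry vector has length {anc.size}, expected {k}"
            )
        if (anc < 0).any() or not np.isclose(anc.sum(), 1.0):
            raise ConfigError(
                f"group {self.label!r}: ancestry must be non-negative and sum to 1"
            )


@dataclass
class SimulationConfig:
    n_clusters: int
    groups: list[GroupSpec]
    primers: list[tuple[str, int]]
    freq_prior: tuple[float, float] = (1.0, 1.0)
    divergence: float = 0.0
    noise_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_clusters < 1:
            raise ConfigError("n_clusters must be >= 1")
        if not self.groups:
            raise ConfigError("need at least one group")
        for g in self.groups:
            g.validate(self.n_clusters)
        if not self.primers or any(nb < 1 for _, nb in self.primers):
            raise ConfigError("every primer needs >= 1 band")
        if not 0.0 <= self.divergence < 1.0:
            raise ConfigError("divergence must be in [0, 1)")
        if not 0.0 <= self.noise_rate < 0.5:
            raise ConfigError("noise_rate must be in [0, 0.5)")

    @property
    def n_accessions(self) -> int:
        return sum(g.size for g in self.groups)

    @property
    def n_loci(self) -> int:
        return sum(nb for _, nb in self.primers)


@dataclass
class SimTruth:
    """Ground truth of a simulation run.

    cluster_freqs : (K, L) band-presence probabilities per cluster.
    true_q        : (N, K) ancestry proportions per accession.
    clone_map     : accession -> clone-parent accession (clonal groups only).
    """

    cluster_freqs: np.ndarray
    true_q: np.ndarray
    clone_map: dict[str, str] = field(default_factory=dict)


# frequencies are kept strictly inside (0, 1)
_FREQ_EPS = 1e-4


def simulate(cfg: SimulationConfig) -> tuple[BandMatrix, PopulationMap, SimTruth]:
    """Draw a band matrix, its population map and the generating truth.

    Deterministic under a fixed ``cfg.seed``: a single generator stream
    drives ancestral frequencies, cluster divergence, genotypes and noise.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    k, n, l = cfg.n_clusters, cfg.n_accessions, cfg.n_loci

    a, b = cfg.freq_prior
    ancestral = rng.beta(a, b, size=l)
    ancestral = np.clip(ancestral, _FREQ_EPS, 1.0 - _FREQ_EPS)

    d = cfg.divergence
    if d > 0.0:
        # Balding-Nichols: Beta(p(1-d)/d, (1-p)(1-d)/d) around the ancestral p
        shape1 = ancestral * (1.0 - d) / d
        shape2 = (1.0 - ancestral) * (1.0 - d) / d
        freqs = rng.beta(shape1[None, :], shape2[None, :], size=(k, l))
    else:
        freqs = np.tile(ancestral, (k, 1))
    freqs = np.clip(freqs, _FREQ_EPS, 1.0 - _FREQ_EPS)

    accession_ids: list[str] = []
    group_of: dict[str, str] = {}
    true_q = np.zeros((n, k))
    calls = np.zeros((n, l), dtype=np.int8)
    clone_map: dict[str, str] = {}

    row = 0
    for g in cfg.groups:
        anc = np.asarray(g.ancestry, dtype=float)
        p_band = anc @ freqs  # (L,) mixture presence probability
        members = [f"{g.label}{i + 1}" for i in range(g.size)]
        if g.clonal:
            parent = (rng.random(l) < p_band).astype(np.int8)
            for acc in members:
                calls[row] = parent
                clone_map[acc] = members[0]
                row += 1
        else:
            for _ in members:
                calls[row] = (rng.random(l) < p_band).astype(np.int8)
                row += 1
        for acc in members:
            accession_ids.append(acc)
            group_of[acc] = g.label
        true_q[row - g.size : row] = anc

    if cfg.noise_rate > 0.0:
        flips = rng.random((n, l)) < cfg.noise_rate
        calls = np.where(flips, 1 - calls, calls).astype(np.int8)

    locus_ids: list[str] = []
    locus_primer: dict[str, str] = {}
    for primer, nb in cfg.primers:
        for i in range(nb):
            loc = f"{primer}.{i + 1}"
            locus_ids.append(loc)
            locus_primer[loc] = primer

    m = BandMatrix(accession_ids, locus_ids, calls, locus_primer)
    pops = PopulationMap(group_of)
    return m, pops, SimTruth(freqs, true_q, clone_map)


def config_to_yaml(cfg: SimulationConfig, path) -> None:
    """Write a SimulationConfig as YAML (round-trips with config_from_yaml)."""
    import yaml

    data = {
        "n_clusters": cfg.n_clusters,
        "groups": [
            {
                "label": g.label,
                "size": g.size,
                "ancestry": list(map(float, g.ancestry)),
                "clonal": g.clonal,
            }
            for g in cfg.groups
        ],
        "primers": [[p, int(n)] for p, n in cfg.primers],
        "freq_prior": list(map(float, cfg.freq_prior)),
        "divergence": cfg.divergence,
        "noise_rate": cfg.noise_rate,
        "seed": cfg.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def config_from_yaml(path) -> SimulationConfig:
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    cfg = SimulationConfig(
        n_clusters=int(data["n_clusters"]),
        groups=[
            GroupSpec(
                g["label"], int(g["size"]), tuple(g["ancestry"]),
                bool(g.get("clonal", False)),
            )
            for g in data["groups"]
        ],
        primers=[(p, int(n)) for p, n in data["primers"]],
        freq_prior=tuple(data.get("freq_prior", (1.0, 1.0))),
        divergence=float(data.get("divergence", 0.0)),
        noise_rate=float(data.get("noise_rate", 0.0)),
        seed=int(data.get("seed", 0)),
    )
    cfg.validate()
    return cfg


#: per-primer band counts of the 15-primer SCoT rose panel (238 bands total)
ROSE_PANEL_PRIMERS: list[tuple[str, int]] = [
    ("SCoT2", 15),
    ("SCoT3", 20),
    ("SCoT6", 2),
    ("SCoT11", 18),
    ("SCoT12", 19),
    ("SCoT13", 18),
    ("SCoT15", 15),
    ("SCoT17", 14),
    ("SCoT19", 19),
    ("SCoT21", 18),
    ("SCoT22", 10),
    ("SCoT25", 21),
    ("SCoT31", 17),
    ("SCoT33", 19),
    ("SCoT36", 13),
]


def rose_panel_config(
    divergence: float = 0.5, noise_rate: float = 0.01, seed: int = 0
) -> SimulationConfig:
    """Configuration emulating a 38-accession oil-bearing rose SCoT panel.

    Ten groups (sizes 8, 5, 9, 4, 2, 2, 2, 2, 2, 2; 38 accessions) typed
    at 15 primers totalling 238 bands, with five ancestral clusters:
    an unidentified vegetatively propagated population (Kl), R. gallica
    (G), a heterogeneous R. damascena breeding population (P) sharing its
    cluster with four clonal cultivar pairs (I, Y, E, SV), R. alba (A),
    R. centifolia (C), and one admixed hybrid group (R) split between the
    damascena and gallica clusters.

    The default divergence (0.5) puts the clusters at species-level
    differentiation, where the marginal posterior of the admixture model
    identifies all five ancestral clusters even for the 2-member groups;
    at divergences around 0.3 the small groups fall below identifiability
    and the model prefers merging them (see the methods note).
    """
    c = {name: tuple(1.0 if i == j else 0.0 for i in range(5)) for j, name in
         enumerate(["centifolia", "alba", "damascena", "gallica", "unknown"])}
    groups = [
        GroupSpec("Kl", 8, c["unknown"], clonal=True),
        GroupSpec("G", 5, c["gallica"]),
        GroupSpec("P", 9, c["damascena"]),
        GroupSpec("A", 4, c["alba"]),
        GroupSpec("C", 2, c["centifolia"], clonal=True),
        GroupSpec("R", 2, (0.0, 0.0, 0.5, 0.5, 0.0)),
        GroupSpec("I", 2, c["damascena"], clonal=True),
        GroupSpec("Y", 2, c["damascena"], clonal=True),
        GroupSpec("E", 2, c["damascena"], clonal=True),
        GroupSpec("SV", 2, c["damascena"], clonal=True),
    ]
    return SimulationConfig(
        n_clusters=5,
        groups=groups,
        primers=list(ROSE_PANEL_PRIMERS),
        freq_prior=(1.0, 1.0),
        divergence=divergence,
        noise_rate=noise_rate,
        seed=seed,
    )


def two_cluster_config(
    n_per_group: int = 10,
    n_loci: int = 120,
    divergence: float = 0.3,
    noise_rate: float = 0.01,
    seed: int = 0,
    admixed: int = 0,
) -> SimulationConfig:
    """Two diverged clusters; the standard admixture/AMOVA benchmark.

    ``admixed`` extra accessions with ancestry (0.5, 0.5) can be planted
    as a third group labelled ``H``.
    """
    groups = [
        GroupSpec("X", n_per_group, (1.0, 0.0)),
        GroupSpec("Z", n_per_group, (0.0, 1.0)),
    ]
    if admixed:
        groups.append(GroupSpec("H", admixed, (0.5, 0.5)))
    return SimulationConfig(
        n_clusters=2,
        groups=groups,
        primers=[("P1", n_loci)],
        divergence=divergence,
        noise_rate=noise_rate,
        seed=seed,
    )
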