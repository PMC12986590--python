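"""End-to-end pipeline: band matrix in, full analysis out.

Runs the stages in order — per-primer marker statistics, per-population
diversity, distance matrices, UPGMA tree, PCoA, AMOVA, the admixture K
grid with the Evanno table and admixture calls — and writes a JSON
manifest recording the seed, package version and a SHA-256 hash of every
output so that identical configurations are verifiably reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .admixture import align_runs, call_admixed, delta_k, run_k_grid
from .amova import amova
from .distances import pairwise_matrix, upgma, write_distance_matrix
from .diversity import diversity_frame, genotype_specific_loci, population_diversity
from .io_core import BandMatrix, PopulationMap, read_band_matrix, read_population_map
from .marker_stats import primer_table_frame
from .ordination import pcoa

log = logging.getLogger("bandpop")


@dataclass
class PipelineConfig:
    input: str
    pops: str
    out_dir: str
    loci: str | None = None
    estimator: str = "phenotypic"
    permutations: int = 999
    pcoa_axes: int = 3
    upgma_metric: str = "nei"
    k_min: int = 2
    k_max: int = 8
    structure_runs: int = 5
    burn_in: int = 5000
    samples: int = 5000
    admixed_threshold: float = 0.6
    seed: int = 0
    skip: list[str] = field(default_factory=list)

    def validate(self) -> None:
        for p in (self.input, self.pops):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        if self.loci is not None and not Path(self.loci).exists():
            raise FileNotFoundError(self.loci)
        if self.k_min < 1 or self.k_max < self.k_min:
            raise ValueError("invalid K range")
        if not 0.0 < self.admixed_threshold <= 1.0:
            raise ValueError("admixed threshold must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(cfg: PipelineConfig) -> dict:
    """Run every stage; returns (and writes) the output manifest."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    m = read_band_matrix(cfg.input, locus_map=cfg.loci)
    pops = read_population_map(cfg.pops)
    pops.validate(m)

    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "n_accessions": m.n_accessions,
        "n_loci": m.n_loci,
        "outputs": {},
    }
    stage = "start"
    try:
        stage = "marker_stats"
        if stage not in cfg.skip:
            log.info("stage %s", stage)
            primer_table_frame(m).to_csv(out / "primer_stats.tsv", sep="\t")
            manifest["outputs"]["marker_stats"] = ["primer_stats.tsv"]

        stage = "diversity"
        if stage not in cfg.skip:
            log.info("stage %s", stage)
            rows = population_diversity(m, pops, estimator=cfg.estimator)
            diversity_frame(rows).to_csv(out / "diversity.tsv", sep="\t")
            gsl = genotype_specific_loci(m)
            with open(out / "genotype_specific_loci.json", "w") as fh:
                json.dump(
                    {
                        "unique_present": gsl.unique_present,
                        "unique_absent": gsl.unique_absent,
                    },
                    fh,
                    indent=1,
                )
            manifest["outputs"]["diversity"] = [
                "diversity.tsv",
                "genotype_specific_loci.json",
            ]

        stage = "distance"
        d_nei = d_sq = None
        if stage not in cfg.skip:
            log.info("stage %s", stage)
            d_nei = pairwise_matrix(m, level="individuals", metric="nei")
            d_sq = pairwise_matrix(m, level="individuals", metric="squared-euclidean")
            d_pop = pairwise_matrix(m, level="populations", metric="nei", pops=pops)
            write_distance_matrix(d_nei, out / "dist_nei_individuals.tsv")
            write_distance_matrix(d_sq, out / "dist_sqeuclidean_individuals.tsv")
            write_distance_matrix(d_pop, out / "dist_nei_populations.tsv")
            manifest["outputs"]["distance"] = [
                "dist_nei_individuals.tsv",
                "dist_sqeuclidean_individuals.tsv",
                "dist_nei_populations.tsv",
            ]

        stage = "upgma"
        if stage not in cfg.skip and d_nei is not None:
            log.info("stage %s", stage)
            d_tree = d_nei if cfg.upgma_metric == "nei" else d_sq
            tree = upgma(d_tree)
            (out / "upgma.nwk").write_text(tree.to_newick() + "\n")
            manifest["outputs"]["upgma"] = ["upgma.nwk"]

        stage = "pcoa"
        if stage not in cfg.skip and d_sq is not None:
            log.info("stage %s", stage)
            res = pcoa(d_sq, n_axes=cfg.pcoa_axes)
            res.to_frame().to_csv(out / "pcoa_coordinates.tsv", sep="\t")
            with open(out / "pcoa_eigen.tsv", "w") as fh:
                fh.write("axis\teigenvalue\tpct_variance\n")
                for i, (ev, pct) in enumerate(zip(res.eigenvalues, res.pct_variance)):
                    fh.write(f"{i + 1}\t{ev:.6g}\t{pct:.4f}\n")
            manifest["outputs"]["pcoa"] = ["pcoa_coordinates.tsv", "pcoa_eigen.tsv"]

        stage = "amova"
        if stage not in cfg.skip:
            log.info("stage %s (seed %d)", stage, cfg.seed)
            res = amova(m, pops, permutations=cfg.permutations, seed=cfg.seed)
            frame = res.to_frame()
            frame.loc["PhiPT"] = [np.nan] * 4 + [res.PhiPT]
            frame.to_csv(out / "amova.tsv", sep="\t")
            with open(out / "amova.json", "w") as fh:
                json.dump(
                    {
                        "PhiPT": res.PhiPT,
                        "p_perm": res.p_perm,
                        "n_permutations": res.n_permutations,
                        "pct_among": res.pct_among,
                        "pct_within": res.pct_within,
                    },
                    fh,
                    indent=1,
                )
            manifest["outputs"]["amova"] = ["amova.tsv", "amova.json"]

        stage = "structure"
        if stage not in cfg.skip:
            log.info(
                "stage %s (K %d-%d, %d runs, seed %d)",
                stage, cfg.k_min, cfg.k_max, cfg.structure_runs, cfg.seed,
            )
            grid = run_k_grid(
                m, cfg.k_min, cfg.k_max, runs=cfg.structure_runs,
                burn_in=cfg.burn_in, samples=cfg.samples, seed=cfg.seed,
            )
            files = []
            for k, fits in grid.items():
                agg = align_runs(fits)
                q_path = out / f"structure_K{k}_Q.tsv"
                q_frame = fits[0].q_frame().copy()
                q_frame.loc[:, :] = agg
                q_frame.to_csv(q_path, sep="\t")
                files.append(q_path.name)
            manifest["outputs"]["structure"] = files

            stage = "deltak"
            table = delta_k(grid)
            table.to_frame().to_csv(out / "delta_k.tsv", sep="\t")
            manifest["outputs"]["deltak"] = ["delta_k.tsv"]
            manifest["best_k"] = table.best_k

            stage = "admixture_calls"
            if table.best_k is not None:
                best_fits = grid[table.best_k]
                agg = align_runs(best_fits)
                calls = call_admixed(
                    agg, threshold=cfg.admixed_threshold,
                    accession_ids=m.accession_ids,
                )
                calls.to_csv(out / "admixture_calls.tsv", sep="\t")
                manifest["outputs"]["admixture_calls"] = ["admixture_calls.tsv"]
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest["hashes"] = {
        name: _sha256(out / name)
        for names in manifest["outputs"].values()
        for name in names
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
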