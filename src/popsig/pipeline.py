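"""End-to-end orchestration: simulate/ingest -> diversity -> ROH -> scans ->
f-statistics -> report bundle.

Every stage is also callable on its own through the library API; the
pipeline wires them together with one config, writes fixed-name TSV/BED
outputs under a run directory, and records a machine-readable manifest
(parameters, versions, seed, per-stage row counts) so a run is fully
reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diversity import diversity_summary, nucleotide_diversity_windows, observed_heterozygosity, pairwise_ibs_distance
from .fstats import f3, f4
from .io import GenotypeMatrix, PopulationMap, read_population_map, read_vcf, write_population_map, write_vcf
from .roh import ROHParams, categorize_roh, detect_roh_all, froh_by_sample, summarize_counts
from .selection import add_z, call_outliers, fst_windows, hp_windows
from .sim import SimConfig, simulate

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Provide either a :class:`SimConfig` (synthetic cohort) or paths to a
    VCF and a population map.  ``comparisons`` lists (test, reference)
    population pairs for the FST scan; the Hp scan runs on each test
    population.  ``autosome_length`` defaults to the span actually covered
    by the input (per-chromosome last SNP position) so F_ROH is meaningful
    on synthetic genomes; set it to 2.4e9 for real caprine data.
    """

    sim: SimConfig | None = None
    vcf: str | None = None
    popmap: str | None = None
    comparisons: list[tuple[str, str]] = field(default_factory=list)
    window: int = 100_000
    step: int = 25_000
    min_snps: int = 30
    tail: float = 0.01
    fst_dialect: str = "mean"
    pi_window: int = 100_000
    pi_step: int = 50_000
    roh_params: ROHParams = field(default_factory=ROHParams)
    autosome_length: float | None = None
    f3_tests: list[tuple[str, str, str]] = field(default_factory=list)
    f4_tests: list[tuple[str, str, str, str]] = field(default_factory=list)
    fstat_block_size: int = 500
    outdir: str = "popsig_run"
    seed: int = 0


def _load_inputs(cfg: RunConfig) -> tuple[GenotypeMatrix, PopulationMap]:
    if cfg.sim is not None:
        sim_cfg = dataclasses.replace(cfg.sim, seed=cfg.seed)
        g, pops, _truth = simulate(sim_cfg)
        return g, pops
    if not cfg.vcf or not cfg.popmap:
        raise ValueError("RunConfig needs either sim= or vcf= and popmap=")
    g = read_vcf(cfg.vcf)
    pops = read_population_map(cfg.popmap)
    pops.validate_against(g)
    return g, pops


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and write the report bundle to ``cfg.outdir``.

    Returns the manifest dict.  Any stage failure aborts with an error
    naming the stage.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "popsig_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": cfg.seed,
        "parameters": {
            "window": cfg.window, "step": cfg.step, "min_snps": cfg.min_snps,
            "tail": cfg.tail, "fst_dialect": cfg.fst_dialect,
            "pi_window": cfg.pi_window, "pi_step": cfg.pi_step,
            "roh": dataclasses.asdict(cfg.roh_params),
            "fstat_block_size": cfg.fstat_block_size,
        },
        "stages": {},
        "warnings": [],
    }

    def stage(name):
        t0 = time.perf_counter()

        def done(**counts):
            manifest["stages"][name] = {
                "seconds": round(time.perf_counter() - t0, 3), **counts
            }
            logger.info("stage %s done: %s", name, counts)

        return done

    try:
        done = stage("ingest")
        g, pops = _load_inputs(cfg)
        if cfg.sim is not None:
            write_vcf(g, str(out / "cohort.vcf"))
            write_population_map(pops, str(out / "cohort.popmap.tsv"))
        done(n_samples=g.n_samples, n_variants=g.n_variants,
             n_populations=len(pops.populations))
    except Exception as exc:
        raise RuntimeError(f"stage 'ingest' failed: {exc}") from exc

    auto_len = cfg.autosome_length
    if auto_len is None:
        auto_len = float(
            g.variants.groupby("chrom", sort=False)["pos"].max().sum()
        )
        manifest["parameters"]["autosome_length"] = auto_len

    try:
        done = stage("roh")
        segments = detect_roh_all(g, cfg.roh_params)
        segments.to_csv(out / "roh_segments.tsv", sep="\t", index=False)
        fr = froh_by_sample(segments, g.samples, auto_len)
        fr.to_csv(out / "froh_per_sample.tsv", sep="\t", header=True)
        if len(segments):
            summary = summarize_counts(categorize_roh(segments, pops))
        else:
            summary = pd.DataFrame()
            manifest["warnings"].append("no ROH segments detected")
        summary.to_csv(out / "roh_summary.tsv", sep="\t")
        done(n_segments=int(len(segments)))
    except Exception as exc:
        raise RuntimeError(f"stage 'roh' failed: {exc}") from exc

    try:
        done = stage("diversity")
        summary = diversity_summary(
            g, pops, froh_by_sample=fr, pi_window=cfg.pi_window, pi_step=cfg.pi_step
        )
        summary.to_csv(out / "diversity_summary.tsv", sep="\t")
        ho, _ = observed_heterozygosity(g, pops)
        ho.to_csv(out / "ho_per_sample.tsv", sep="\t", header=True)
        dist = pairwise_ibs_distance(g)
        dist.matrix("d").to_csv(out / "distance_matrix.tsv", sep="\t")
        for pop in pops.populations:
            piw = nucleotide_diversity_windows(g, pops, pop, cfg.pi_window, cfg.pi_step)
            piw.to_csv(out / f"pi_windows_{pop}.tsv", sep="\t", index=False)
        done(n_populations=len(pops.populations))
    except Exception as exc:
        raise RuntimeError(f"stage 'diversity' failed: {exc}") from exc

    try:
        done = stage("scan")
        n_regions = {}
        comparisons = cfg.comparisons or _default_comparisons(pops)
        for test_pop, ref_pop in comparisons:
            fst = add_z(
                fst_windows(g, pops, test_pop, ref_pop, cfg.window, cfg.step,
                            cfg.min_snps, cfg.fst_dialect), "fst"
            )
            hp = add_z(
                hp_windows(g, pops, test_pop, cfg.window, cfg.step,
                           min_snps=cfg.min_snps), "hp"
            )
            tag = f"{test_pop}_vs_{ref_pop}"
            fst.to_csv(out / f"fst_{tag}.tsv", sep="\t", index=False)
            hp.to_csv(out / f"hp_{test_pop}.tsv", sep="\t", index=False)
            regions = call_outliers(fst, hp, cfg.tail, strict_grid=False)
            regions.to_csv(out / f"candidates_{tag}.tsv", sep="\t", index=False)
            with open(out / f"candidates_{tag}.bed", "w") as fh:
                for r in regions.itertuples():
                    fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end - 1}\n")
            n_regions[tag] = int(len(regions))
        done(**n_regions)
    except Exception as exc:
        raise RuntimeError(f"stage 'scan' failed: {exc}") from exc

    try:
        done = stage("fstats")
        rows = []
        for t, b, c in cfg.f3_tests:
            r = f3(g, pops, t, b, c, cfg.fstat_block_size)
            rows.append(dict(test="f3", pops=f"({t}; {b}, {c})", value=r.value,
                             se=r.se, z=r.z, n_blocks=r.n_blocks, n_sites=r.n_sites))
        for a, b, c, d in cfg.f4_tests:
            r = f4(g, pops, a, b, c, d, cfg.fstat_block_size)
            rows.append(dict(test="f4", pops=f"({a}, {b}; {c}, {d})", value=r.value,
                             se=r.se, z=r.z, n_blocks=r.n_blocks, n_sites=r.n_sites))
        pd.DataFrame(
            rows, columns=["test", "pops", "value", "se", "z", "n_blocks", "n_sites"]
        ).to_csv(out / "fstats.tsv", sep="\t", index=False)
        done(n_tests=len(rows))
    except Exception as exc:
        raise RuntimeError(f"stage 'fstats' failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _default_comparisons(pops: PopulationMap) -> list[tuple[str, str]]:
    """Every population against the last one (the outgroup-style design of
    testing each focal population against a common reference)."""
    labels = pops.populations
    if len(labels) < 2:
        raise ValueError("need >=2 populations for an FST comparison")
    ref = labels[-1]
    return [(p, ref) for p in labels[:-1]]
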