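"""Pipeline orchestration: stages, configuration, seeds, manifest.

A declarative YAML/JSON configuration drives the synthetic demo run:
simulate -> consensus -> gscore -> cooccur -> sweep -> lineage -> growth
-> synergy.  A single global seed is expanded into per-stage seeds with
``numpy.random.SeedSequence`` so any stage can be rerun alone and
reproduce its output byte-for-byte; the run manifest records the config
hash, seeds, stage wall times and all input/output paths.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bliss_synergy import frame_to_pairings, pairings_to_frame, synergy_report
from .growth_kinetics import PlateAssay, fit_growth, minimal_permissive_density
from .parallel_evolution import GeneCatalog, gscore_analysis
from .sc_lineage import MutationMatrix, infer_ml_tree
from .synthetic_data import (
    CallerProfile,
    SimConfig,
    SweepSpec,
    make_gene_catalog,
    simulate_caller_outputs,
    simulate_growth_plate,
    simulate_lines,
    simulate_pairings,
    simulate_single_cells,
    random_mutation_tree,
    true_variants_from_hits,
    write_caller_vcfs,
)
from .trajectory_stats import (
    AssociationSpec,
    detect_sweep,
    frame_to_lines,
    lines_to_frame,
    permutation_pvalue,
)
from .variant_filtering import (
    consensus_calls,
    read_caller_vcf,
    read_consensus_tsv,
    write_consensus_tsv,
)

__all__ = [
    "STAGES",
    "RunManifest",
    "PipelineError",
    "default_config",
    "run_pipeline",
    "validate_inputs",
]

logger = logging.getLogger("syntrophevo")

STAGES = (
    "simulate", "consensus", "gscore", "cooccur",
    "sweep", "lineage", "growth", "synergy",
)


class PipelineError(RuntimeError):
    """A stage failed fast: missing upstream output or schema violation."""


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: list[str]
    inputs: dict[str, list[str]]
    outputs: dict[str, list[str]]
    versions: dict[str, str]
    wall_times: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def default_config(seed: int = 7) -> dict:
    """The single-command synthetic demo configuration.

    All filter thresholds carry the pipeline defaults: consensus at >= 2
    callers and >= 0.20 frequency, single-cell filters at coverage >= 8,
    >= 2 cells and >= 0.80 frequency, fd = 6.04e-5, ad = 0.21545, 1000
    null simulations, a 1.5-fold dilution series.
    """
    return {
        "seed": seed,
        "simulate": {
            "n_lines": 13,
            "generations": [100, 300, 500, 780, 1000],
            "n_genes": 50,
            "gene_length_range": [300, 3000],
            "mutation_rate": 12.0,
            "parallel_genes": {"G0005": 6.0, "G0012": 4.0},
            "sweep": {
                "line": "L03",
                "interval": [500, 780],
                "replaced": {"Dv": ["G0020", "G0021"], "Mm": ["G0008"]},
                "novel": {"Dv": ["G0030"], "Mm": ["G0031", "IG_184033"]},
            },
            "fd": 6.04e-5,
            "ad": 0.21545,
            "missing_rate": 0.02,
            "n_cells": 90,
            "n_tree_mutations": 5,
            "callers": {
                "gatk": {"fp_rate": 0.002, "fn_rate": 0.05, "freq_sd": 0.02},
                "varscan": {"fp_rate": 0.003, "fn_rate": 0.08, "freq_sd": 0.02},
                "bcftools": {"fp_rate": 0.002, "fn_rate": 0.10, "freq_sd": 0.02},
            },
            "growth_params": [0.03, 20.0, 0.6],
            "noise_sd": 0.005,
            "dilution_fold": 1.5,
            "plate": {
                "n_dilutions": 8,
                "n_replicates": 4,
                "min_permissive_density": 0.004,
            },
            "pairings": {
                "base_rate": 0.05,
                "base_yield": 0.5,
                "f_dv": 0.3,
                "f_mm": 0.3,
                "mode": "synergistic",
                "effect_size": 0.15,
                "n_replicates": 6,
                "noise_sd": 0.03,
            },
        },
        "consensus": {"min_callers": 2, "min_frequency": 0.20},
        "gscore": {"n_sims": 1000, "count_mode": "pooled"},
        "cooccur": {
            "pair": ["G0005", "G0012"],
            "mode": "co_occurrence",
            "n": 2000,
            "min_common_timepoints": 2,
        },
        "lineage": {"search": "exhaustive", "fd": 6.04e-5, "ad": 0.21545},
        "growth": {"growth_threshold": 0.05, "min_replicates_growing": 1},
        "synergy": {"normalization": "relative_to_baseline"},
    }


def _config_hash(config: Mapping) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _stage_seed(base_seed: int, stage: str) -> int:
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([base_seed, idx]).generate_state(1)[0] % 2**31)


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise PipelineError(f"stage {stage!r}: missing upstream output {path}")
    return path


def _sim_config(cfg: Mapping, seed: int, sweep: SweepSpec | None) -> SimConfig:
    return SimConfig(
        seed=seed,
        n_lines=cfg.get("n_lines", 13),
        generations=tuple(cfg.get("generations", (100, 300, 500, 780, 1000))),
        n_genes=cfg.get("n_genes", 50),
        gene_length_range=tuple(cfg.get("gene_length_range", (300, 3000))),
        mutation_rate=cfg.get("mutation_rate", 12.0),
        parallel_genes=cfg.get("parallel_genes", {}),
        sweep_spec=sweep,
        fd=cfg.get("fd", 6.04e-5),
        ad=cfg.get("ad", 0.21545),
        missing_rate=cfg.get("missing_rate", 0.02),
        growth_params=tuple(cfg.get("growth_params", (0.03, 20.0, 0.6))),
        noise_sd=cfg.get("noise_sd", 0.005),
        dilution_fold=cfg.get("dilution_fold", 1.5),
    )


# ---------------------------------------------------------------------------
# Stage implementations (each returns (input paths, output paths))


def _stage_simulate(config: Mapping, out: Path, seed: int):
    cfg = config["simulate"]
    sweep_cfg = cfg.get("sweep")
    lines_all = []
    catalog = None
    hits_dv = None
    for i, organism in enumerate(("Dv", "Mm")):
        sweep = None
        if sweep_cfg:
            sweep = SweepSpec(
                line=sweep_cfg["line"],
                interval=tuple(sweep_cfg["interval"]),
                replaced=frozenset(sweep_cfg["replaced"][organism]),
                novel=frozenset(sweep_cfg["novel"][organism]),
            )
        sim = _sim_config(cfg, seed + i, sweep if organism else None)
        lines, truth = simulate_lines(sim, organism=organism)
        lines_all.extend(lines)
        if organism == "Dv":
            catalog, hits_dv = truth.catalog, truth.hits

    traj_path = out / "trajectories.tsv"
    lines_to_frame(lines_all).to_csv(traj_path, sep="\t", index=False)
    catalog_path = out / "catalog_dv.tsv"
    catalog.to_tsv(catalog_path)

    variants = true_variants_from_hits(hits_dv, catalog)
    profiles = {
        name: CallerProfile(**p) for name, p in cfg.get("callers", {}).items()
    } or {
        "gatk": CallerProfile(0.002, 0.05, 0.02),
        "varscan": CallerProfile(0.003, 0.08, 0.02),
        "bcftools": CallerProfile(0.002, 0.10, 0.02),
    }
    call_sets = simulate_caller_outputs(variants, profiles, seed=seed + 101)
    vcf_paths = write_caller_vcfs(call_sets, out / "callers")

    tree = random_mutation_tree(cfg.get("n_tree_mutations", 5), seed=seed + 202)
    matrix, sc_truth = simulate_single_cells(
        tree,
        n_cells=cfg.get("n_cells", 90),
        fd=cfg.get("fd", 6.04e-5),
        ad=cfg.get("ad", 0.21545),
        missing_rate=cfg.get("missing_rate", 0.02),
        seed=seed + 303,
    )
    matrix_path = out / "matrix.csv"
    matrix.to_csv(matrix_path)

    plate_cfg = cfg.get("plate", {})
    sim0 = _sim_config(cfg, seed, None)
    plate, plate_truth = simulate_growth_plate(
        sim0,
        n_dilutions=plate_cfg.get("n_dilutions", 8),
        n_replicates=plate_cfg.get("n_replicates", 4),
        min_permissive_density=plate_cfg.get("min_permissive_density", 0.004),
    )
    plate_path, map_path = out / "plate.csv", out / "plate_map.csv"
    plate.to_csv(plate_path, map_path)

    pair_cfg = cfg.get("pairings", {})
    pairings, pair_truth = simulate_pairings(
        base_rate=pair_cfg.get("base_rate", 0.05),
        base_yield=pair_cfg.get("base_yield", 0.5),
        f_dv_true=pair_cfg.get("f_dv", 0.3),
        f_mm_true=pair_cfg.get("f_mm", 0.3),
        mode=pair_cfg.get("mode", "synergistic"),
        effect_size=pair_cfg.get("effect_size", 0.15),
        n_replicates=pair_cfg.get("n_replicates", 6),
        seed=seed + 404,
        noise_sd=pair_cfg.get("noise_sd", 0.03),
    )
    pairings_path = out / "pairings.csv"
    pairings_to_frame(pairings).to_csv(pairings_path, index=False)

    truth_path = out / "ground_truth.json"
    truth_path.write_text(
        json.dumps(
            {
                "parallel_genes": sorted(cfg.get("parallel_genes", {})),
                "sweep": sweep_cfg,
                "tree_parents": list(tree.parents),
                "tree_labels": list(tree.labels),
                "plate_min_permissive_density": plate_cfg.get(
                    "min_permissive_density", 0.004
                ),
                "pairing_mode": pair_truth.pairing_mode,
                "planted_eob": pair_truth.planted_eob,
            },
            indent=2,
        )
    )
    outputs = [traj_path, catalog_path, matrix_path, plate_path, map_path,
               pairings_path, truth_path, *vcf_paths.values()]
    return [], outputs


def _stage_consensus(config: Mapping, out: Path, seed: int):
    caller_dir = _require(out / "callers", "consensus")
    vcfs = sorted(caller_dir.glob("*.vcf"))
    if len(vcfs) < 2:
        raise PipelineError("stage 'consensus': need >= 2 caller VCFs")
    sets = [read_caller_vcf(p) for p in vcfs]
    cfg = config.get("consensus", {})
    calls = consensus_calls(
        sets,
        min_callers=cfg.get("min_callers", 2),
        min_frequency=cfg.get("min_frequency", 0.20),
    )
    out_path = out / "consensus.tsv"
    write_consensus_tsv(calls, out_path)
    logger.info("consensus: %d calls from %d callers", len(calls), len(vcfs))
    return vcfs, [out_path]


def _stage_gscore(config: Mapping, out: Path, seed: int):
    consensus_path = _require(out / "consensus.tsv", "gscore")
    catalog_path = _require(out / "catalog_dv.tsv", "gscore")
    calls = read_consensus_tsv(consensus_path)
    calls = [c for c in calls if not c.locus.startswith("DECOY")]
    catalog = GeneCatalog.from_tsv(catalog_path)
    cfg = config.get("gscore", {})
    report = gscore_analysis(
        calls,
        catalog,
        n_sims=cfg.get("n_sims", 1000),
        seed=seed,
        count_mode=cfg.get("count_mode", "pooled"),
    )
    genes_path = out / "gscore_genes.tsv"
    report.per_gene_table().to_csv(genes_path, sep="\t", index=False)
    summary_path = out / "gscore_summary.json"
    summary_path.write_text(
        json.dumps(
            {
                "g_observed": report.total,
                "null_mean": report.null_mean,
                "null_sd": report.null_sd,
                "z": report.zscore,
                "n_mutations": report.n_mutations,
                "n_sims": report.n_sims,
                "seed": seed,
            },
            indent=2,
        )
    )
    return [consensus_path, catalog_path], [genes_path, summary_path]


def _stage_cooccur(config: Mapping, out: Path, seed: int):
    traj_path = _require(out / "trajectories.tsv", "cooccur")
    lines = [
        ln
        for ln in frame_to_lines(pd.read_csv(traj_path, sep="\t"))
        if ln.organism == "Dv"
    ]
    cfg = config.get("cooccur", {})
    locus_a, locus_b = cfg.get("pair", ["G0005", "G0012"])
    spec = AssociationSpec(
        locus_a=locus_a,
        locus_b=locus_b,
        mode=cfg.get("mode", "co_occurrence"),
        min_common_timepoints=cfg.get("min_common_timepoints", 2),
    )
    result = permutation_pvalue(lines, spec, n=cfg.get("n", 2000), seed=seed)
    out_path = out / "cooccur.json"
    out_path.write_text(json.dumps(asdict(result), indent=2))
    return [traj_path], [out_path]


def _stage_sweep(config: Mapping, out: Path, seed: int):
    traj_path = _require(out / "trajectories.tsv", "sweep")
    lines = frame_to_lines(pd.read_csv(traj_path, sep="\t"))
    sweep_cfg = config.get("simulate", {}).get("sweep") or {}
    line_id = sweep_cfg.get("line", "L03")
    pair = [ln for ln in lines if ln.line == line_id]
    if len(pair) != 2:
        raise PipelineError(f"stage 'sweep': expected 2 organisms for line {line_id}")
    record = detect_sweep(pair[0], pair[1])
    out_path = out / "sweep.json"
    payload = None
    if record is not None:
        payload = {
            "line": record.line,
            "interval": list(record.interval),
            "replaced": {k: sorted(v) for k, v in record.replaced.items()},
            "novel": {k: sorted(v) for k, v in record.novel.items()},
        }
    out_path.write_text(json.dumps({"sweep": payload}, indent=2))
    return [traj_path], [out_path]


def _stage_lineage(config: Mapping, out: Path, seed: int):
    matrix_path = _require(out / "matrix.csv", "lineage")
    cfg = config.get("lineage", {})
    matrix = MutationMatrix.from_csv(
        matrix_path, fd=cfg.get("fd", 6.04e-5), ad=cfg.get("ad", 0.21545)
    )
    tree, ll = infer_ml_tree(
        matrix,
        search=cfg.get("search", "exhaustive"),
        seed=seed,
        chain_length=cfg.get("chain_length", 100_000),
    )
    nwk_path = out / "lineage_tree.nwk"
    nwk_path.write_text(tree.to_newick() + "\n")
    json_path = out / "lineage.json"
    json_path.write_text(
        json.dumps(
            {
                "log_likelihood": ll,
                "parents": list(tree.parents),
                "labels": list(tree.labels),
                "ties": [list(t) for t in tree.ties],
                "flags": list(tree.flags),
            },
            indent=2,
        )
    )
    return [matrix_path], [nwk_path, json_path]


def _stage_growth(config: Mapping, out: Path, seed: int):
    plate_path = _require(out / "plate.csv", "growth")
    map_path = _require(out / "plate_map.csv", "growth")
    plate = PlateAssay.from_csv(plate_path, map_path)
    cfg = config.get("growth", {})
    threshold = cfg.get("growth_threshold", 0.05)
    rows = []
    for well in sorted(plate.wells):
        kind, _ = plate.well_map[well]
        if kind == "blank":
            continue
        fit = fit_growth(plate.wells[well], growth_threshold=threshold)
        rows.append(
            {
                "well": well,
                "density": plate.densities[kind],
                "model": fit.model or "",
                "mu": fit.mu,
                "lam": fit.lam,
                "A": fit.A,
                "grew": fit.grew,
            }
        )
    fits_path = out / "growth_fits.tsv"
    pd.DataFrame(rows).to_csv(fits_path, sep="\t", index=False)
    minimal, profile = minimal_permissive_density(
        plate,
        growth_threshold=threshold,
        min_replicates_growing=cfg.get("min_replicates_growing", 1),
    )
    minimal_path = out / "minimal_density.json"
    minimal_path.write_text(
        json.dumps(
            {"minimal_permissive_density": minimal,
             "profile": profile.to_dict(orient="records")},
            indent=2,
        )
    )
    return [plate_path, map_path], [fits_path, minimal_path]


def _stage_synergy(config: Mapping, out: Path, seed: int):
    pairings_path = _require(out / "pairings.csv", "synergy")
    measurements = frame_to_pairings(pd.read_csv(pairings_path))
    cfg = config.get("synergy", {})
    reports = {
        metric: asdict(
            synergy_report(
                measurements,
                metric=metric,
                normalization=cfg.get("normalization", "relative_to_baseline"),
            )
        )
        for metric in ("growth_rate", "yield")
    }
    out_path = out / "synergy.json"
    out_path.write_text(json.dumps(reports, indent=2))
    return [pairings_path], [out_path]


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "consensus": _stage_consensus,
    "gscore": _stage_gscore,
    "cooccur": _stage_cooccur,
    "sweep": _stage_sweep,
    "lineage": _stage_lineage,
    "growth": _stage_growth,
    "synergy": _stage_synergy,
}


def run_pipeline(
    config: Mapping | str | Path,
    stages: Sequence[str] | None = None,
    out_dir: str | Path = "syntroph_run",
) -> RunManifest:
    """Execute pipeline stages in order and write a run manifest.

    ``config`` may be a mapping or a path to a YAML/JSON file; ``stages``
    defaults to all stages.  Stage dependencies are enforced through
    their input files: running a stage whose upstream outputs are absent
    raises :class:`PipelineError` naming the stage.  Reruns with the same
    config + seed reproduce outputs exactly.
    """
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    stages = list(stages) if stages is not None else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stages {sorted(unknown)}")
    stages.sort(key=STAGES.index)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))

    inputs: dict[str, list[str]] = {}
    outputs: dict[str, list[str]] = {}
    wall: dict[str, float] = {}
    for stage in stages:
        t0 = time.perf_counter()
        stage_seed = _stage_seed(seed, stage)
        logger.info("stage %s (seed %d)", stage, stage_seed)
        ins, outs = _STAGE_FNS[stage](config, out, stage_seed)
        wall[stage] = round(time.perf_counter() - t0, 3)
        inputs[stage] = [str(p) for p in ins]
        outputs[stage] = [str(p) for p in outs]

    manifest = RunManifest(
        config_hash=_config_hash(config),
        seed=seed,
        stages=stages,
        inputs=inputs,
        outputs=outputs,
        versions={
            "syntrophevo": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        wall_times=wall,
    )
    manifest.to_json(out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# Input validation


@dataclass
class ValidationReport:
    schema: str
    n_rows: int
    columns: list[str]
    violations: list[str]

    @property
    def ok(self) -> bool:
        return not self.violations


_SCHEMAS = {
    "trajectory": {
        "sep": "\t",
        "columns": ["line", "organism", "generation", "locus", "frequency"],
    },
    "consensus": {"sep": "\t", "columns": ["chrom", "position", "alt", "frequency"]},
    "catalog": {"sep": "\t", "columns": ["gene", "length", "genome_length"]},
    "matrix": {"sep": ",", "columns": ["cell"]},
    "plate": {"sep": ",", "columns": ["time"]},
    "pairings": {"sep": ",", "columns": ["pairing", "metric", "replicate", "value"]},
}


def validate_inputs(path: str | Path, schema: str) -> ValidationReport:
    """Schema report for a pipeline input file: columns, row counts and
    range/domain violations (frequencies in [0, 1], matrix states in
    {0, 1, 3}, nonnegative OD readings, positive gene lengths)."""
    path = Path(path)
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; known: {sorted(_SCHEMAS)}")
    if not path.exists():
        raise FileNotFoundError(path)
    spec = _SCHEMAS[schema]
    df = pd.read_csv(path, sep=spec["sep"])
    violations: list[str] = []
    missing = [c for c in spec["columns"] if c not in df.columns]
    if missing:
        violations.append(f"missing columns: {missing}")

    if not missing:
        if schema in ("trajectory", "consensus"):
            bad = df[(df["frequency"] < 0) | (df["frequency"] > 1)]
            for i in bad.index:
                violations.append(
                    f"row {i}: frequency {df.loc[i, 'frequency']} outside [0, 1]"
                )
        if schema == "catalog":
            bad = df[df["length"] <= 0]
            for i in bad.index:
                violations.append(f"row {i}: nonpositive gene length")
        if schema == "matrix":
            states = df.drop(columns=["cell"]).to_numpy()
            bad_mask = ~np.isin(states, [0, 1, 3])
            for r, c in zip(*np.nonzero(bad_mask)):
                violations.append(
                    f"row {r}: state {states[r, c]} outside {{0, 1, 3}}"
                )
        if schema == "plate":
            numeric = df.to_numpy(dtype=float)
            if (numeric < 0).any():
                violations.append("negative OD or time values present")
    return ValidationReport(
        schema=schema,
        n_rows=len(df),
        columns=list(df.columns),
        violations=violations,
    )
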