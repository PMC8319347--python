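"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the study design of a two-species syntrophic
coculture evolution experiment: replicate evolution lines sampled at a
handful of generations (default 100, 300, 500, 780, 1000) with per-gene
mutation-frequency trajectories, per-caller variant call sets with
caller-specific error, single-cell {0, 1, 3} mutation matrices drawn from
a known mutation tree under a false-positive / allelic-dropout error
model, logistic growth curves over a 1.5-fold dilution series, and
clone-pairing measurements with additive, synergistic or antagonistic
interaction effects.  Every simulated observation traces back to a
:class:`GroundTruth` record, and identical configuration + seed yields
identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bliss_synergy import PairingMeasurement, bliss_expected
from .growth_kinetics import GrowthCurve, PlateAssay, logistic_model
from .parallel_evolution import GeneCatalog
from .sc_lineage import MISSING, MutationMatrix, MutationTree
from .trajectory_stats import EvolutionLine, TrajectorySample
from .variant_filtering import MutationCall

__all__ = [
    "SimConfig",
    "SweepSpec",
    "CallerProfile",
    "GroundTruth",
    "make_gene_catalog",
    "simulate_lines",
    "simulate_caller_outputs",
    "simulate_single_cells",
    "simulate_growth_plate",
    "simulate_pairings",
    "random_mutation_tree",
    "write_caller_vcfs",
]


@dataclass(frozen=True)
class SweepSpec:
    """A planted cross-species selective sweep.

    Within ``line``, over the sampled interval (``interval[0]``,
    ``interval[1]``], the ``replaced`` loci drop from dominance to below
    detection while the disjoint ``novel`` loci rise from below detection
    to dominance.
    """

    line: str
    interval: tuple[int, int]
    replaced: frozenset[str]
    novel: frozenset[str]

    def __post_init__(self) -> None:
        if self.interval[0] >= self.interval[1]:
            raise ValueError("sweep interval must be increasing")
        if self.replaced & self.novel:
            raise ValueError("replaced and novel locus sets must be disjoint")
        if not self.replaced or not self.novel:
            raise ValueError("replaced and novel locus sets must be nonempty")


@dataclass(frozen=True)
class CallerProfile:
    """Error profile of one variant caller."""

    fp_rate: float = 0.0   # per decoy site
    fn_rate: float = 0.0   # per true variant
    freq_sd: float = 0.0   # sd of frequency jitter on true calls

    def __post_init__(self) -> None:
        for name, p in (("fp_rate", self.fp_rate), ("fn_rate", self.fn_rate)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.freq_sd < 0:
            raise ValueError("freq_sd must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic evolution experiment.

    Defaults mirror the emulated design: 13 evolution lines sampled at
    generations 100, 300, 500, 780 and 1000; single-cell error rates
    fd = 6.04e-5 and ad = 0.21545; a 1.5-fold dilution series.
    """

    seed: int = 0
    n_lines: int = 13
    generations: tuple[int, ...] = (100, 300, 500, 780, 1000)
    n_genes: int = 50
    gene_length_range: tuple[int, int] = (300, 3000)
    mutation_rate: float = 10.0            # expected mutation events per line
    parallel_genes: Mapping[str, float] = field(default_factory=dict)  # gene -> enrichment >= 1
    fixation_threshold: float = 0.95
    detection_limit: float = 0.05
    selected_fraction: float = 0.6         # chance a non-planted event is under selection
    sweep_spec: SweepSpec | None = None
    fd: float = 6.04e-5
    ad: float = 0.21545
    missing_rate: float = 0.02
    growth_params: tuple[float, float, float] = (0.03, 20.0, 0.6)  # mu OD/h, lag h, capacity OD
    noise_sd: float = 0.005                # OD noise
    dilution_fold: float = 1.5

    def __post_init__(self) -> None:
        for name, p in (
            ("fixation_threshold", self.fixation_threshold),
            ("detection_limit", self.detection_limit),
            ("selected_fraction", self.selected_fraction),
            ("fd", self.fd),
            ("ad", self.ad),
            ("missing_rate", self.missing_rate),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        gens = self.generations
        if len(gens) == 0:
            raise ValueError("need at least one sampled generation")
        if any(b <= a for a, b in zip(gens, gens[1:])):
            raise ValueError("generations must be strictly increasing")
        if any(e < 1.0 for e in self.parallel_genes.values()):
            raise ValueError("enrichment factors must be >= 1")
        if self.dilution_fold <= 1.0:
            raise ValueError("dilution_fold must be > 1")
        if self.n_genes < 1:
            raise ValueError("need a nonempty gene catalog")
        if self.mutation_rate < 0:
            raise ValueError("mutation_rate must be >= 0")


@dataclass
class GroundTruth:
    """What was planted: the key for validating every downstream stage."""

    parallel_genes: frozenset[str] = frozenset()
    catalog: GeneCatalog | None = None
    hits: pd.DataFrame | None = None       # line, gene, appear_generation, selected, annotation
    sweep: SweepSpec | None = None
    tree: MutationTree | None = None
    attachments: dict[str, int] | None = None
    growth_grew: dict[str, bool] | None = None   # well -> should grow
    growth_params: tuple[float, float, float] | None = None
    pairing_mode: str | None = None
    planted_eob: float | None = None


# ---------------------------------------------------------------------------
# Evolution-line trajectories


def make_gene_catalog(config: SimConfig, prefix: str = "G") -> GeneCatalog:
    """Deterministic gene catalog from the configuration seed.

    Gene lengths are uniform over ``gene_length_range``; the genome length
    equals the summed gene length (the simulated genomes carry no
    intergenic sequence unless a catalog with one is supplied explicitly).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes).astype(float)
    ids = tuple(f"{prefix}{i:04d}" for i in range(config.n_genes))
    return GeneCatalog(gene_ids=ids, lengths=lengths, genome_length=int(lengths.sum()))


_ANNOTATIONS = (
    ("nonsynonymous_coding", 0.60),
    ("frameshift", 0.12),
    ("stop_gained", 0.06),
    ("codon_insertion_or_change", 0.07),
    ("synonymous_coding", 0.12),
    ("nonsynonymous_start", 0.03),
)
_NONSYN_POOL = ("nonsynonymous_coding", "frameshift", "stop_gained")


def _selected_trajectory(
    n_samples: int, t0: int, rng: np.random.Generator, noise_sd: float = 0.02
) -> np.ndarray:
    """Logistic frequency rise starting at sample index t0."""
    f = np.zeros(n_samples)
    k = np.arange(n_samples) - t0
    rise = 1.0 / (1.0 + np.exp(-1.8 * (k - 1.0)))
    f[k >= 0] = rise[k >= 0]
    f += rng.normal(0.0, noise_sd, size=n_samples) * (f > 0)
    return np.clip(f, 0.0, 1.0)


def _neutral_trajectory(
    n_samples: int, t0: int, rng: np.random.Generator, detection_limit: float
) -> np.ndarray:
    level = rng.uniform(detection_limit + 0.02, 0.35)
    f = np.zeros(n_samples)
    f[t0:] = level + rng.normal(0.0, 0.02, size=n_samples - t0)
    return np.clip(f, 0.0, 1.0)


def simulate_lines(
    config: SimConfig,
    organism: str = "Dv",
    catalog: GeneCatalog | None = None,
    line_names: Sequence[str] | None = None,
) -> tuple[list[EvolutionLine], GroundTruth]:
    """Simulate per-line, per-generation mutation-frequency trajectories.

    Mutation events per line are Poisson(``mutation_rate``); each event
    hits a gene with probability proportional to length x enrichment
    (enrichment 1 for all genes is exactly length-proportional
    multinomial sampling).  Events under selection follow a monotone
    logistic rise toward fixation from their appearance generation;
    neutral events persist at low frequency.  Planted parallel genes are
    always under selection and carry function-affecting annotations.  A
    configured :class:`SweepSpec` overrides the affected line so the
    replaced loci fall below detection and the novel loci rise to
    dominance within the stated interval.
    """
    if catalog is None:
        catalog = make_gene_catalog(config)
    if len(catalog.gene_ids) == 0:
        raise ValueError("empty gene catalog")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    gens = list(config.generations)
    n_samples = len(gens)
    if line_names is None:
        line_names = [f"L{i + 1:02d}" for i in range(config.n_lines)]

    enrich = np.ones(len(catalog.gene_ids))
    for gene, e in config.parallel_genes.items():
        enrich[catalog.index_of(gene)] = e
    p_hit = catalog.lengths * enrich
    p_hit = p_hit / p_hit.sum()

    ann_names = [a for a, _ in _ANNOTATIONS]
    ann_probs = np.array([p for _, p in _ANNOTATIONS])

    lines: list[EvolutionLine] = []
    hit_rows: list[dict] = []
    for line_name in line_names:
        n_events = rng.poisson(config.mutation_rate)
        gene_idx = rng.choice(len(catalog.gene_ids), size=n_events, p=p_hit)
        freqs: list[dict[str, float]] = [dict() for _ in range(n_samples)]
        for gi in gene_idx:
            gene = catalog.gene_ids[gi]
            planted = gene in config.parallel_genes
            t0 = int(rng.integers(0, n_samples))
            selected = planted or rng.random() < config.selected_fraction
            if planted:
                ann = _NONSYN_POOL[int(rng.integers(0, len(_NONSYN_POOL)))]
            else:
                ann = ann_names[int(rng.choice(len(ann_names), p=ann_probs))]
            traj = (
                _selected_trajectory(n_samples, t0, rng)
                if selected
                else _neutral_trajectory(n_samples, t0, rng, config.detection_limit)
            )
            hit_rows.append(
                {
                    "line": line_name,
                    "organism": organism,
                    "gene": gene,
                    "appear_generation": gens[t0],
                    "selected": selected,
                    "annotation": ann,
                    "final_frequency": float(traj[-1]),
                }
            )
            # one trajectory per gene per line; later hits in the same gene
            # are counted as events but do not overwrite the trajectory
            for k in range(n_samples):
                if traj[k] > 0 and gene not in freqs[k]:
                    freqs[k][gene] = float(traj[k])

        sweep = config.sweep_spec
        if sweep is not None and line_name == sweep.line:
            g1, g2 = sweep.interval
            for locus in sweep.replaced:
                for k, g in enumerate(gens):
                    freqs[k][locus] = 0.9 if g <= g1 else 0.0
            for locus in sweep.novel:
                for k, g in enumerate(gens):
                    freqs[k][locus] = 0.0 if g <= g1 else 0.95

        samples = [
            TrajectorySample(line_name, g, {l: f for l, f in fr.items() if f > 0})
            for g, fr in zip(gens, freqs)
        ]
        lines.append(EvolutionLine(line_name, organism, samples))

    hits = pd.DataFrame(
        hit_rows,
        columns=[
            "line", "organism", "gene", "appear_generation",
            "selected", "annotation", "final_frequency",
        ],
    )
    truth = GroundTruth(
        parallel_genes=frozenset(config.parallel_genes),
        catalog=catalog,
        hits=hits,
        sweep=config.sweep_spec,
    )
    return lines, truth


def true_variants_from_hits(
    hits: pd.DataFrame, catalog: GeneCatalog, chrom: str = "genome"
) -> list[MutationCall]:
    """One true variant call per mutation event, positioned inside its gene."""
    starts = np.concatenate([[0], np.cumsum(catalog.lengths)]).astype(int)
    gene_pos = {g: starts[i] + 1 for i, g in enumerate(catalog.gene_ids)}
    calls = []
    offsets: dict[tuple[str, str], int] = {}
    for rec in hits.itertuples():
        key = (rec.line, rec.gene)
        off = offsets.get(key, 0)
        offsets[key] = off + 1
        calls.append(
            MutationCall(
                locus=rec.gene,
                position=gene_pos[rec.gene] + off,
                ref="A",
                alt="T",
                frequency=max(float(rec.final_frequency), 0.01),
                callers=frozenset({"truth"}),
                annotation=rec.annotation,
                line=rec.line,
                generation=int(rec.appear_generation),
                chrom=chrom,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# Per-caller variant call sets


def simulate_caller_outputs(
    true_variants: Sequence[MutationCall],
    caller_profiles: Mapping[str, CallerProfile],
    seed: int | None = None,
    n_decoy_sites: int = 1000,
) -> dict[str, list[MutationCall]]:
    """Per-caller call sets: truth minus dropouts plus spurious calls.

    Each caller misses each true variant with its false-negative rate,
    jitters reported frequencies with Gaussian noise of sd ``freq_sd``
    (clipped to (0, 1]), and adds each of ``n_decoy_sites`` decoy sites
    with its false-positive rate at a low random frequency.
    """
    if len(caller_profiles) < 2:
        raise ValueError("need at least 2 caller profiles")
    rng = np.random.default_rng(seed)
    max_pos = max((v.position for v in true_variants), default=0)
    decoy_positions = max_pos + 1 + np.arange(n_decoy_sites)
    out: dict[str, list[MutationCall]] = {}
    for name in sorted(caller_profiles):
        prof = caller_profiles[name]
        calls: list[MutationCall] = []
        for v in true_variants:
            if rng.random() < prof.fn_rate:
                continue
            freq = v.frequency
            if prof.freq_sd > 0:
                freq = float(np.clip(freq + rng.normal(0, prof.freq_sd), 0.01, 1.0))
            calls.append(
                MutationCall(
                    locus=v.locus,
                    position=v.position,
                    ref=v.ref,
                    alt=v.alt,
                    frequency=freq,
                    callers=frozenset({name}),
                    annotation=v.annotation,
                    line=v.line,
                    generation=v.generation,
                    chrom=v.chrom,
                )
            )
        if prof.fp_rate > 0:
            hit = rng.random(n_decoy_sites) < prof.fp_rate
            for pos in decoy_positions[hit]:
                calls.append(
                    MutationCall(
                        locus=f"DECOY_{pos}",
                        position=int(pos),
                        ref="A",
                        alt="G",
                        frequency=float(rng.uniform(0.05, 0.6)),
                        callers=frozenset({name}),
                        annotation="nonsynonymous_coding",
                        chrom=true_variants[0].chrom if true_variants else "genome",
                    )
                )
        out[name] = calls
    return out


def write_caller_vcfs(
    call_sets: Mapping[str, Sequence[MutationCall]],
    out_dir: str | Path,
    contig: str = "genome",
    contig_length: int = 10_000_000,
) -> dict[str, Path]:
    """Write one uncompressed VCF per caller (CHROM, POS, REF, ALT, INFO)."""
    import pysam

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, calls in call_sets.items():
        header = pysam.VariantHeader()
        header.contigs.add(contig, length=contig_length)
        header.info.add("AF", "A", "Float", "Variant frequency")
        header.info.add("GENE", "1", "String", "Locus id")
        header.info.add("ANN", "1", "String", "Annotation term")
        header.info.add("LINE", "1", "String", "Evolution line")
        header.info.add("GEN", "1", "Integer", "Generation sampled")
        path = out_dir / f"{name}.vcf"
        with pysam.VariantFile(str(path), "w", header=header) as vcf:
            for call in sorted(calls, key=lambda c: (c.position, c.alt, c.line)):
                rec = vcf.new_record(
                    contig=contig,
                    start=call.position - 1,
                    alleles=(call.ref, call.alt),
                )
                rec.info["AF"] = (call.frequency,)
                rec.info["GENE"] = call.locus
                rec.info["ANN"] = call.annotation
                if call.line:
                    rec.info["LINE"] = call.line
                rec.info["GEN"] = call.generation
                vcf.write(rec)
        paths[name] = path
    return paths


# ---------------------------------------------------------------------------
# Single-cell matrices


def random_mutation_tree(
    m: int, seed: int | None = None, labels: Sequence[str] | None = None
) -> MutationTree:
    """Uniform-ish random rooted mutation tree on ``m`` labeled nodes
    (each node's parent drawn among earlier nodes or the root)."""
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = tuple(f"M{i}" for i in range(m))
    order = rng.permutation(m)
    parents = [m] * m
    for rank, node in enumerate(order):
        if rank == 0:
            parents[node] = m
        else:
            choices = np.append(order[:rank], m)
            parents[node] = int(rng.choice(choices))
    return MutationTree(parents=tuple(parents), labels=tuple(labels))


def simulate_single_cells(
    tree: MutationTree,
    n_cells: int,
    fd: float = 6.04e-5,
    ad: float = 0.21545,
    missing_rate: float = 0.0,
    seed: int | None = None,
) -> tuple[MutationMatrix, GroundTruth]:
    """Observed single-cell states from a known mutation tree.

    Each cell attaches uniformly to a tree node (including the root: a
    root-attached cell carries no mutations); its true genotype is the
    root-to-node path.  A true 0 is observed as 1 with probability ``fd``,
    a true 1 as 0 with probability ``ad``, and any entry becomes 3
    (missing) with probability ``missing_rate``, overriding the other two.
    """
    if tree.m == 0:
        raise ValueError("tree must carry at least one mutation")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    for name, p in (("fd", fd), ("ad", ad), ("missing_rate", missing_rate)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    A = tree.ancestor_matrix()
    attach = rng.integers(0, tree.m + 1, size=n_cells)
    genotypes = A[attach].astype(np.int8)
    flips_10 = rng.random(genotypes.shape) < ad
    flips_01 = rng.random(genotypes.shape) < fd
    observed = np.where(genotypes == 1,
                        np.where(flips_10, 0, 1),
                        np.where(flips_01, 1, 0)).astype(np.int8)
    missing = rng.random(genotypes.shape) < missing_rate
    observed[missing] = MISSING
    cells = tuple(f"C{i:03d}" for i in range(n_cells))
    matrix = MutationMatrix(
        cells=cells, mutations=tree.labels, states=observed, fd=fd, ad=ad
    )
    truth = GroundTruth(
        tree=tree,
        attachments={c: int(a) for c, a in zip(cells, attach)},
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Growth plates


def simulate_growth_plate(
    config: SimConfig,
    n_dilutions: int = 8,
    n_replicates: int = 4,
    min_permissive_density: float = 0.004,
    top_density: float = 0.02,
    baseline: float = 0.04,
    t_max: float = 96.0,
    dt: float = 2.0,
) -> tuple[PlateAssay, GroundTruth]:
    """A dilution plate with a planted minimal growth-permissive density.

    Densities follow a ``dilution_fold`` series from ``top_density``.
    Wells seeded at or above ``min_permissive_density`` grow as logistic
    curves with the configured (mu, lag, A) — the lag lengthening by one
    doubling time per dilution step — plus truncated Gaussian OD noise;
    wells below it stay flat at baseline + noise.  The first column is
    blank wells.
    """
    if n_dilutions < 2:
        raise ValueError("need at least 2 dilutions")
    if min_permissive_density < 0 or top_density <= 0:
        raise ValueError("densities must be nonnegative")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
    mu, lag, A = config.growth_params
    times = np.arange(0.0, t_max + 1e-9, dt)
    densities = tuple(top_density / config.dilution_fold**k for k in range(n_dilutions))
    doubling_shift = math.log(2) * A / (4 * mu)  # h per dilution step

    wells: dict[str, GrowthCurve] = {}
    well_map: dict[str, tuple[str, int]] = {}
    grew_truth: dict[str, bool] = {}
    for rep in range(n_replicates):
        well = f"{chr(ord('A') + rep)}1"
        od = np.clip(baseline + rng.normal(0, config.noise_sd, size=times.shape), 0, None)
        wells[well] = GrowthCurve(times, od, well, 0.0)
        well_map[well] = ("blank", rep)
    for j, density in enumerate(densities):
        grows = density >= min_permissive_density
        for rep in range(n_replicates):
            well = f"{chr(ord('A') + rep)}{j + 2}"
            signal = (
                logistic_model(times, A, mu, lag + j * doubling_shift)
                if grows
                else np.zeros_like(times)
            )
            od = np.clip(
                baseline + signal + rng.normal(0, config.noise_sd, size=times.shape),
                0.0,
                None,
            )
            wells[well] = GrowthCurve(times, od, well, density)
            well_map[well] = (j, rep)
            grew_truth[well] = bool(grows)
    plate = PlateAssay(densities, wells, well_map, config.dilution_fold)
    truth = GroundTruth(growth_grew=grew_truth, growth_params=config.growth_params)
    return plate, truth


# ---------------------------------------------------------------------------
# Clone pairings


def simulate_pairings(
    base_rate: float,
    base_yield: float,
    f_dv_true: float,
    f_mm_true: float,
    mode: str,
    effect_size: float = 0.15,
    n_replicates: int = 6,
    seed: int | None = None,
    noise_sd: float = 0.0,
) -> tuple[list[PairingMeasurement], GroundTruth]:
    """2x2 clone-pairing measurements with a planted interaction mode.

    The Ev x Ev combined fractional effect equals the Bliss expectation
    (``additive``), exceeds it by ``effect_size`` (``synergistic``) or
    falls short of it by ``effect_size`` (``antagonistic``); replicate
    values carry multiplicative Gaussian noise of relative sd
    ``noise_sd``.
    """
    if mode not in ("additive", "synergistic", "antagonistic"):
        raise ValueError(f"invalid mode {mode!r}")
    for f in (f_dv_true, f_mm_true):
        if not 0.0 <= f < 1.0:
            raise ValueError("fractional effects must be in [0, 1)")
    if n_replicates < 2:
        raise ValueError("need >= 2 replicates")
    rng = np.random.default_rng(seed)
    f_bliss = bliss_expected(f_dv_true, f_mm_true)
    delta = {"additive": 0.0, "synergistic": effect_size, "antagonistic": -effect_size}
    f_z = f_bliss + delta[mode]
    if not 0.0 <= f_z <= 1.0:
        raise ValueError("planted combined effect outside [0, 1]; reduce effect_size")

    fractions = {"AcAc": 0.0, "EvAc": f_dv_true, "AcEv": f_mm_true, "EvEv": f_z}
    out: list[PairingMeasurement] = []
    for metric, base in (("growth_rate", base_rate), ("yield", base_yield)):
        for pairing, f in fractions.items():
            mean = base * (1.0 + f)
            reps = mean * (1.0 + rng.normal(0.0, noise_sd, size=n_replicates))
            out.append(PairingMeasurement(pairing, metric, tuple(float(v) for v in reps)))
    truth = GroundTruth(pairing_mode=mode, planted_eob=100.0 * delta[mode])
    return out, truth
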