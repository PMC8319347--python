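"""Temporal mutation-pattern statistics across evolution lines.

Longitudinal per-line mutation-frequency trajectories are scanned for
co-occurrence of mutated genes, simultaneous fixation, temporally nested
fixation, and cross-species selective sweeps.  Statistical support comes
from a margin-preserving permutation null: gene identities are reassigned
to mutation events by checkerboard swap-randomization of the line x gene
presence matrix (preserving the number of mutations per line and the
number of lines per gene), with within-line shuffling of which observed
trajectory carries which gene label.  Empirical P values follow
P = (s + 1) / (n + 1), where s counts null replicates with an equal or
stronger association than observed.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrajectorySample",
    "EvolutionLine",
    "AssociationResult",
    "AssociationSpec",
    "SweepRecord",
    "detect_fixation",
    "association_statistic",
    "permutation_pvalue",
    "detect_sweep",
    "lines_to_frame",
    "frame_to_lines",
]


@dataclass(frozen=True)
class TrajectorySample:
    """Per-line mutation frequencies at one sampled generation."""

    line: str
    generation: int
    frequencies: dict[str, float]

    def __post_init__(self) -> None:
        if self.generation < 0:
            raise ValueError("generation must be >= 0")
        for locus, f in self.frequencies.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"frequency {f} for {locus} outside [0, 1]")


@dataclass
class EvolutionLine:
    """One organism's longitudinal trajectory within one evolution line."""

    line: str
    organism: str
    samples: list[TrajectorySample]

    def __post_init__(self) -> None:
        gens = [s.generation for s in self.samples]
        if any(b <= a for a, b in zip(gens, gens[1:])):
            raise ValueError("samples must be strictly increasing in generation")

    @property
    def generations(self) -> list[int]:
        return [s.generation for s in self.samples]

    def loci(self) -> set[str]:
        out: set[str] = set()
        for s in self.samples:
            out.update(s.frequencies)
        return out

    def series(self, locus: str) -> tuple[list[int], list[float]]:
        """(generations, frequencies) for one locus; absent means 0."""
        gens = self.generations
        freqs = [s.frequencies.get(locus, 0.0) for s in self.samples]
        return gens, freqs


@dataclass(frozen=True)
class AssociationResult:
    statistic: str
    observed: float
    s: int
    n: int
    p_value: float
    method: str = "monte_carlo"   # or "exact"

    def __post_init__(self) -> None:
        if not 0 <= self.s <= self.n:
            raise ValueError("need 0 <= s <= n")


@dataclass(frozen=True)
class AssociationSpec:
    """Specification of an association statistic between two loci."""

    locus_a: str
    locus_b: str
    mode: str  # co_occurrence | simultaneous_fixation | nested_fixation
    min_common_timepoints: int = 2
    detection_limit: float = 0.05
    fixation_threshold: float = 0.95


@dataclass(frozen=True)
class SweepRecord:
    """A cross-species selective sweep detected in one sampling interval."""

    line: str
    interval: tuple[int, int]
    replaced: dict[str, frozenset[str]]  # organism -> loci that disappeared
    novel: dict[str, frozenset[str]]     # organism -> loci that rose to dominance


# ---------------------------------------------------------------------------
# Fixation and association statistics


def detect_fixation(
    generations: Sequence[int],
    frequencies: Sequence[float],
    threshold: float = 0.95,
) -> int | None:
    """Earliest sampled generation at which the frequency reaches
    ``threshold`` and stays there at all later samples; ``None`` if never.

    Transient excursions above the threshold that later fall back do not
    count as fixation.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    if len(generations) == 0 or len(generations) != len(frequencies):
        raise ValueError("need equal-length, nonempty generations/frequencies")
    fixed_from = None
    for gen, f in zip(reversed(generations), reversed(frequencies)):
        if f >= threshold:
            fixed_from = gen
        else:
            break
    return fixed_from


def _first_detection(
    line: EvolutionLine, locus: str, detection_limit: float
) -> int | None:
    for s in line.samples:
        if s.frequencies.get(locus, 0.0) >= detection_limit:
            return s.generation
    return None


def _line_association(
    line: EvolutionLine, spec: AssociationSpec, freq_a: list[float], freq_b: list[float]
) -> bool:
    """Does this line show the specified association, given the two loci's
    frequency series on the line's sampled generations?"""
    gens = line.generations
    if spec.mode == "co_occurrence":
        common = sum(
            1
            for fa, fb in zip(freq_a, freq_b)
            if fa >= spec.detection_limit and fb >= spec.detection_limit
        )
        return common >= spec.min_common_timepoints
    if spec.mode == "simultaneous_fixation":
        fix_a = detect_fixation(gens, freq_a, spec.fixation_threshold)
        fix_b = detect_fixation(gens, freq_b, spec.fixation_threshold)
        return fix_a is not None and fix_a == fix_b
    if spec.mode == "nested_fixation":
        det_a = next((g for g, f in zip(gens, freq_a) if f >= spec.detection_limit), None)
        det_b = next((g for g, f in zip(gens, freq_b) if f >= spec.detection_limit), None)
        fix_a = detect_fixation(gens, freq_a, spec.fixation_threshold)
        fix_b = detect_fixation(gens, freq_b, spec.fixation_threshold)
        return (
            det_a is not None
            and det_b is not None
            and det_b > det_a
            and fix_a is not None
            and fix_b is not None
            and fix_b <= fix_a
        )
    raise ValueError(f"unknown association mode {spec.mode!r}")


def association_statistic(
    lines: Sequence[EvolutionLine],
    locus_a: str,
    locus_b: str,
    mode: str,
    min_common_timepoints: int = 2,
    detection_limit: float = 0.05,
    fixation_threshold: float = 0.95,
) -> int:
    """Count of evolution lines showing the given pairwise association.

    Modes: ``co_occurrence`` (both loci detected at >= k common sampled
    time points), ``simultaneous_fixation`` (both loci first fix at the
    same sampled generation), ``nested_fixation`` (locus B rises above
    detection after locus A yet fixes no later than A does).
    """
    if mode not in ("co_occurrence", "simultaneous_fixation", "nested_fixation"):
        raise ValueError(f"unknown association mode {mode!r}")
    spec = AssociationSpec(
        locus_a, locus_b, mode, min_common_timepoints, detection_limit, fixation_threshold
    )
    count = 0
    for line in lines:
        _, fa = line.series(locus_a)
        _, fb = line.series(locus_b)
        if _line_association(line, spec, fa, fb):
            count += 1
    return count


# ---------------------------------------------------------------------------
# Margin-preserving permutation null


def _presence_and_events(
    lines: Sequence[EvolutionLine], detection_limit: float
) -> tuple[np.ndarray, list[str], list[list[list[float]]]]:
    """Presence matrix (lines x genes) plus each line's observed trajectories.

    An event is a locus ever detected (>= detection limit) in a line; its
    trajectory (frequency series on the line's grid) is kept as an
    exchangeable object for relabeling under the null.
    """
    loci = sorted(set().union(*(ln.loci() for ln in lines)))
    presence = np.zeros((len(lines), len(loci)), dtype=bool)
    events: list[list[list[float]]] = []
    for i, ln in enumerate(lines):
        row_events = []
        for j, locus in enumerate(loci):
            _, f = ln.series(locus)
            if max(f) >= detection_limit:
                presence[i, j] = True
                row_events.append(f)
        events.append(row_events)
    return presence, loci, events


def _curveball_trade(row_sets: list[set[int]], rng: random.Random) -> None:
    """One curveball trade: redistribute the symmetric difference of two
    random rows.  Preserves both row and column margins exactly and mixes
    like a batch of checkerboard swaps."""
    r1, r2 = rng.sample(range(len(row_sets)), 2)
    a, b = row_sets[r1], row_sets[r2]
    shared = a & b
    only_a = list(a - shared)
    only_b = list(b - shared)
    if not only_a or not only_b:
        return
    pool = only_a + only_b
    rng.shuffle(pool)
    row_sets[r1] = shared | set(pool[: len(only_a)])
    row_sets[r2] = shared | set(pool[len(only_a):])


def _has_any_swap(presence: np.ndarray) -> bool:
    n_rows, n_cols = presence.shape
    for r1, r2 in itertools.combinations(range(n_rows), 2):
        diff = presence[r1] != presence[r2]
        if diff.sum() >= 2:
            vals = presence[r1, diff]
            if vals.any() and not vals.all():
                return True
    return False


def _replicate_statistic(
    row_sets: list[set[int]],
    loci: list[str],
    events: list[list[list[float]]],
    lines: Sequence[EvolutionLine],
    spec: AssociationSpec,
    rng: random.Random,
) -> int:
    """Statistic on one null replicate: assign each line's observed
    trajectories uniformly at random to the genes present in that line.

    Only the trajectories landing on the two loci of interest matter, so
    the uniform within-line bijection is sampled marginally: an ordered
    pair of distinct events when both loci are present, a single event
    otherwise.  This is distribution-identical to shuffling the full
    assignment and much cheaper.
    """
    ja = loci.index(spec.locus_a)
    jb = loci.index(spec.locus_b)
    count = 0
    for i, ln in enumerate(lines):
        row = row_sets[i]
        has_a, has_b = ja in row, jb in row
        if not (has_a or has_b):
            continue
        evs = events[i]
        n_ev = len(evs)
        nz = [0.0] * len(ln.samples)
        if has_a and has_b:
            ia = rng.randrange(n_ev)
            ib = rng.randrange(n_ev - 1)
            if ib >= ia:
                ib += 1
            fa, fb = evs[ia], evs[ib]
        elif has_a:
            fa, fb = evs[rng.randrange(n_ev)], nz
        else:
            fa, fb = nz, evs[rng.randrange(n_ev)]
        if _line_association(ln, spec, fa, fb):
            count += 1
    return count


def _exact_pvalue(
    presence: np.ndarray,
    loci: list[str],
    events: list[list[list[float]]],
    lines: Sequence[EvolutionLine],
    spec: AssociationSpec,
    observed: int,
    rng: random.Random,
    max_placements: int = 200_000,
) -> AssociationResult:
    """Exhaustive enumeration fallback for degenerate matrices.

    Each gene is placed independently and uniformly over the line subsets
    of its observed size (column margins preserved); the two loci of
    interest are enumerated jointly, all other genes are irrelevant to the
    pairwise statistic.  Within each placement, trajectories are assigned
    by a seeded shuffle (exact for presence-determined statistics).
    """
    ja = loci.index(spec.locus_a)
    jb = loci.index(spec.locus_b)
    n_lines = presence.shape[0]
    ka = int(presence[:, ja].sum())
    kb = int(presence[:, jb].sum())
    from math import comb

    total = comb(n_lines, ka) * comb(n_lines, kb)
    if total > max_placements:
        raise ValueError(
            f"exact enumeration infeasible: {total} placements > {max_placements}"
        )
    s = 0
    n = 0
    base = presence.copy()
    for sub_a in itertools.combinations(range(n_lines), ka):
        for sub_b in itertools.combinations(range(n_lines), kb):
            base[:, ja] = False
            base[:, jb] = False
            base[list(sub_a), ja] = True
            base[list(sub_b), jb] = True
            # row sums change across placements; reuse each line's observed
            # trajectories, padding with low-frequency copies if a line
            # gained events relative to the data.
            stat = 0
            for i, ln in enumerate(lines):
                row = base[i]
                if not (row[ja] or row[jb]):
                    continue
                pool = list(events[i])
                need = int(row.sum())
                while len(pool) < need:
                    pool.append([spec.detection_limit] * len(ln.samples))
                perm = rng.sample(range(len(pool)), len(pool))
                present = np.flatnonzero(row)
                assignment = {int(g): pool[k] for g, k in zip(present, perm)}
                nzero = [0.0] * len(ln.samples)
                if _line_association(
                    ln, spec, assignment.get(ja, nzero), assignment.get(jb, nzero)
                ):
                    stat += 1
            n += 1
            if stat >= observed:
                s += 1
    return AssociationResult(
        statistic=spec.mode,
        observed=float(observed),
        s=s,
        n=n,
        p_value=s / n,
        method="exact",
    )


def permutation_pvalue(
    lines: Sequence[EvolutionLine],
    spec: AssociationSpec,
    n: int = 1_000_000,
    seed: int | None = None,
    burn_in_factor: int = 10,
) -> AssociationResult:
    """Empirical P value for a pairwise association statistic.

    The null preserves both margins of the line x gene presence matrix:
    replicates come from a serial curveball-trade chain (each trade
    redistributes the symmetric difference of two random rows; burn-in of
    ``burn_in_factor`` x the row count in trades, one row-count sweep of
    thinning between replicates), and within each line the observed
    trajectories are reassigned uniformly over the genes present in that
    line.  ``s`` counts replicates with a statistic >= observed, and
    P = (s + 1) / (n + 1).

    When the matrix admits no checkerboard swap (both margins pin the
    matrix down), an exact column-margin enumeration is used instead and
    P = s / n over all placements.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = random.Random(seed)
    observed = association_statistic(
        lines,
        spec.locus_a,
        spec.locus_b,
        spec.mode,
        spec.min_common_timepoints,
        spec.detection_limit,
        spec.fixation_threshold,
    )
    presence, loci, events = _presence_and_events(lines, spec.detection_limit)
    if spec.locus_a not in loci or spec.locus_b not in loci:
        raise ValueError("both loci must be present in the data")

    if not _has_any_swap(presence):
        return _exact_pvalue(presence, loci, events, lines, spec, observed, rng)

    row_sets = [set(np.flatnonzero(row).tolist()) for row in presence]
    sweep = max(len(row_sets), 1)
    for _ in range(burn_in_factor * sweep):
        _curveball_trade(row_sets, rng)
    s = 0
    for _ in range(n):
        for _ in range(sweep):
            _curveball_trade(row_sets, rng)
        if _replicate_statistic(row_sets, loci, events, lines, spec, rng) >= observed:
            s += 1
    return AssociationResult(
        statistic=spec.mode,
        observed=float(observed),
        s=s,
        n=n,
        p_value=(s + 1) / (n + 1),
        method="monte_carlo",
    )


# ---------------------------------------------------------------------------
# Cross-species sweep detection


def detect_sweep(
    line_a: EvolutionLine,
    line_b: EvolutionLine,
    detection_limit: float = 0.05,
    dominance: float = 0.5,
) -> SweepRecord | None:
    """Earliest sampling interval with a joint two-species sweep.

    Over one interval (g1, g2], in *both* organisms, some nonempty locus
    set must drop from >= ``dominance`` to < ``detection_limit`` while a
    disjoint nonempty set rises from < ``detection_limit`` to >=
    ``dominance``.  Returns the interval and both locus sets, or ``None``.
    """
    if line_a.generations != line_b.generations:
        raise ValueError("mismatched generation grids between organisms")
    gens = line_a.generations
    for t in range(len(gens) - 1):
        record: dict[str, dict[str, frozenset[str]]] = {}
        ok = True
        for ln in (line_a, line_b):
            s1, s2 = ln.samples[t], ln.samples[t + 1]
            loci = set(s1.frequencies) | set(s2.frequencies)
            dropped = frozenset(
                l
                for l in loci
                if s1.frequencies.get(l, 0.0) >= dominance
                and s2.frequencies.get(l, 0.0) < detection_limit
            )
            risen = frozenset(
                l
                for l in loci
                if s1.frequencies.get(l, 0.0) < detection_limit
                and s2.frequencies.get(l, 0.0) >= dominance
            )
            if not dropped or not risen:
                ok = False
                break
            record[ln.organism] = {"replaced": dropped, "novel": risen}
        if ok:
            return SweepRecord(
                line=line_a.line,
                interval=(gens[t], gens[t + 1]),
                replaced={org: r["replaced"] for org, r in record.items()},
                novel={org: r["novel"] for org, r in record.items()},
            )
    return None


# ---------------------------------------------------------------------------
# Trajectory TSV I/O


def lines_to_frame(lines: Iterable[EvolutionLine]) -> pd.DataFrame:
    rows = []
    for ln in lines:
        for s in ln.samples:
            for locus, f in sorted(s.frequencies.items()):
                rows.append(
                    {
                        "line": ln.line,
                        "organism": ln.organism,
                        "generation": s.generation,
                        "locus": locus,
                        "frequency": f,
                    }
                )
    return pd.DataFrame(
        rows, columns=["line", "organism", "generation", "locus", "frequency"]
    )


def frame_to_lines(df: pd.DataFrame) -> list[EvolutionLine]:
    out = []
    for (line, org), grp in df.groupby(["line", "organism"], sort=True):
        samples = []
        for gen, g in grp.groupby("generation", sort=True):
            freqs = dict(zip(g["locus"].astype(str), g["frequency"].astype(float)))
            samples.append(TrajectorySample(str(line), int(gen), freqs))
        out.append(EvolutionLine(str(line), str(org), samples))
    return out
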