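"""Single-cell mutation matrices and ML mutation-tree inference.

Single-cell genotyping after whole-genome amplification is noisy: a true
absence can be read as present with false-positive probability ``fd`` and
a true presence as absent with allelic-dropout probability ``ad``; sites
with insufficient coverage are coded 3 (missing).  Given a cells x
mutations matrix over {0, 1, 3}, the mutation history is modelled as a
rooted tree whose non-root nodes each carry one mutation; a cell attaches
to a node and its true genotype is the set of mutations on the root-to-
node path.  The tree likelihood marginalizes cell attachments (MAP
attachment by default) and the maximum-likelihood tree is found either by
exhaustive enumeration of parent vectors (small m) or by a seeded
Metropolis search with prune-and-reattach and label-swap moves.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MutationMatrix",
    "MutationTree",
    "build_mutation_matrix",
    "tree_loglikelihood",
    "infer_ml_tree",
    "order_trunk_by_generations",
]

MISSING = 3


@dataclass
class MutationMatrix:
    """Cells x mutations state matrix over {0, 1, 3} with the error model."""

    cells: tuple[str, ...]
    mutations: tuple[str, ...]
    states: np.ndarray
    fd: float = 6.04e-5
    ad: float = 0.21545

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.shape != (len(self.cells), len(self.mutations)):
            raise ValueError("states shape must be (n_cells, n_mutations)")
        if not np.isin(self.states, [0, 1, MISSING]).all():
            raise ValueError("states must be in {0, 1, 3}")
        for name, p in (("fd", self.fd), ("ad", self.ad)):
            if not 0.0 <= p < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_mutations(self) -> int:
        return len(self.mutations)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.states, index=list(self.cells),
                     columns=list(self.mutations)).to_csv(path, index_label="cell")

    @classmethod
    def from_csv(cls, path: str | Path, fd: float = 6.04e-5,
                 ad: float = 0.21545) -> "MutationMatrix":
        df = pd.read_csv(path, index_col="cell")
        return cls(
            cells=tuple(df.index.astype(str)),
            mutations=tuple(df.columns.astype(str)),
            states=df.to_numpy(dtype=np.int8),
            fd=fd,
            ad=ad,
        )


@dataclass
class MutationTree:
    """Rooted mutation tree as a parent vector.

    ``parents[i]`` is the parent of mutation ``i``; the value ``m`` (the
    number of mutations) denotes the unlabeled root.  ``labels[i]`` is the
    mutation id at node ``i`` (a bijection with the matrix's mutation ids).
    """

    parents: tuple[int, ...]
    labels: tuple[str, ...]
    attachments: dict[str, int] | None = None  # cell id -> node (m = root)
    ties: tuple[tuple[str, str], ...] = ()     # label pairs swappable at equal likelihood
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        m = len(self.labels)
        if len(self.parents) != m:
            raise ValueError("parents and labels must have equal length")
        if len(set(self.labels)) != m:
            raise ValueError("labels must be distinct")
        for i, p in enumerate(self.parents):
            if p == i or not 0 <= p <= m:
                raise ValueError("invalid parent vector")
        if not _is_acyclic(self.parents):
            raise ValueError("parent vector contains a cycle")

    @property
    def m(self) -> int:
        return len(self.labels)

    def ancestor_matrix(self) -> np.ndarray:
        """(m + 1) x m boolean: row j = genotype of a cell attached at node j
        (last row is the root: all-zero genotype)."""
        return _ancestor_matrix(np.asarray(self.parents), self.m)

    def children(self, node: int) -> list[int]:
        return [i for i, p in enumerate(self.parents) if p == node]

    def trunk(self) -> list[int]:
        """Maximal single-child chain of nodes starting at the root."""
        out: list[int] = []
        node = self.m
        while True:
            kids = self.children(node)
            if len(kids) != 1:
                break
            node = kids[0]
            out.append(node)
        return out

    def to_newick(self) -> str:
        """Newick string with every node labeled by its mutation."""
        kids: dict[int, list[int]] = {}
        for i, p in enumerate(self.parents):
            kids.setdefault(p, []).append(i)

        def fmt(node: int) -> str:
            label = "root" if node == self.m else self.labels[node]
            ch = sorted(kids.get(node, []))
            if not ch:
                return label
            return "(" + ",".join(fmt(c) for c in ch) + ")" + label

        return fmt(self.m) + ";"


def _is_acyclic(parents: Sequence[int]) -> bool:
    m = len(parents)
    for start in range(m):
        node, steps = start, 0
        while node != m:
            node = parents[node]
            steps += 1
            if steps > m:
                return False
    return True


def _ancestor_matrix(parents: np.ndarray, m: int) -> np.ndarray:
    A = np.zeros((m + 1, m), dtype=bool)
    for node in range(m):
        j = node
        while j != m:
            A[node, j] = True
            j = parents[j]
    return A


# ---------------------------------------------------------------------------
# Matrix construction from per-cell calls


def build_mutation_matrix(
    per_cell_calls: pd.DataFrame,
    min_coverage: int = 8,
    min_cells: int = 2,
    min_frequency: float = 0.80,
    fd: float = 6.04e-5,
    ad: float = 0.21545,
) -> MutationMatrix:
    """Threshold per-cell variant records into a {0, 1, 3} matrix.

    ``per_cell_calls`` needs columns ``cell``, ``mutation``, ``coverage``,
    ``frequency``.  A cell's state at a site is 3 when coverage <
    ``min_coverage``, else 1 when the within-cell frequency >=
    ``min_frequency``, else 0.  Mutation columns are retained only when at
    least ``min_cells`` cells carry state 1.
    """
    required = {"cell", "mutation", "coverage", "frequency"}
    if per_cell_calls.empty:
        raise ValueError("empty per-cell call table")
    if not required <= set(per_cell_calls.columns):
        raise ValueError(f"per-cell calls need columns {sorted(required)}")
    if min_coverage < 0 or min_cells < 0 or not 0.0 < min_frequency <= 1.0:
        raise ValueError("thresholds outside valid ranges")

    cells = tuple(dict.fromkeys(per_cell_calls["cell"].astype(str)))
    muts = tuple(dict.fromkeys(per_cell_calls["mutation"].astype(str)))
    cell_ix = {c: i for i, c in enumerate(cells)}
    mut_ix = {m: j for j, m in enumerate(muts)}
    states = np.zeros((len(cells), len(muts)), dtype=np.int8)
    for rec in per_cell_calls.itertuples():
        i, j = cell_ix[str(rec.cell)], mut_ix[str(rec.mutation)]
        if rec.coverage < min_coverage:
            states[i, j] = MISSING
        elif rec.frequency >= min_frequency:
            states[i, j] = 1
        else:
            states[i, j] = 0
    keep = (states == 1).sum(axis=0) >= min_cells
    return MutationMatrix(
        cells=cells,
        mutations=tuple(m for m, k in zip(muts, keep) if k),
        states=states[:, keep],
        fd=fd,
        ad=ad,
    )


# ---------------------------------------------------------------------------
# Likelihood


def _obs_logprobs(matrix: MutationMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(L0, L1): per-cell, per-mutation log P(obs | true=0) and | true=1).
    Missing observations contribute log 1 = 0 either way."""
    S = matrix.states
    fd, ad = matrix.fd, matrix.ad
    # finite surrogate for log 0 keeps the vectorized scoring free of
    # inf * 0 artifacts while still dominating any achievable score
    log0 = -1e10
    L0 = np.zeros(S.shape)
    L1 = np.zeros(S.shape)
    L0[S == 0] = np.log1p(-fd)
    L0[S == 1] = np.log(fd) if fd > 0 else log0
    L1[S == 0] = np.log(ad) if ad > 0 else log0
    L1[S == 1] = np.log1p(-ad)
    return L0, L1


def _scores_for_tree(
    parents: np.ndarray, L0: np.ndarray, L1: np.ndarray
) -> np.ndarray:
    """n_cells x (m + 1) matrix of log P(cell | attachment node)."""
    m = L0.shape[1]
    A = _ancestor_matrix(parents, m)
    base = L0.sum(axis=1)
    return base[:, None] + (L1 - L0) @ A.T


def _tree_loglik(
    parents: np.ndarray, L0: np.ndarray, L1: np.ndarray, attachment: str
) -> float:
    scores = _scores_for_tree(parents, L0, L1)
    if attachment == "max":
        return float(scores.max(axis=1).sum())
    if attachment == "sum":
        from scipy.special import logsumexp

        m1 = scores.shape[1]
        return float((logsumexp(scores, axis=1) - np.log(m1)).sum())
    raise ValueError(f"unknown attachment mode {attachment!r}")


def tree_loglikelihood(
    tree: MutationTree, matrix: MutationMatrix, attachment: str = "max"
) -> float:
    """Log-likelihood of a mutation tree under the fd/ad error model.

    Per cell and candidate attachment node, each mutation contributes
    P(obs 1 | true 0) = fd, P(obs 0 | true 0) = 1 - fd,
    P(obs 0 | true 1) = ad, P(obs 1 | true 1) = 1 - ad; a missing state (3)
    contributes a factor 1.  ``attachment='max'`` scores each cell at its
    best (MAP) attachment; ``'sum'`` averages over attachments (uniform
    prior over the m + 1 nodes including the root).
    """
    if set(tree.labels) != set(matrix.mutations):
        raise ValueError("tree labels must match matrix mutation ids")
    if matrix.fd >= 1 or matrix.ad >= 1:
        raise ValueError("fd and ad must be < 1")
    # align matrix columns to tree node order
    col = [matrix.mutations.index(lbl) for lbl in tree.labels]
    L0, L1 = _obs_logprobs(matrix)
    return _tree_loglik(np.asarray(tree.parents), L0[:, col], L1[:, col], attachment)


def _map_attachments(
    tree: MutationTree, matrix: MutationMatrix
) -> dict[str, int]:
    col = [matrix.mutations.index(lbl) for lbl in tree.labels]
    L0, L1 = _obs_logprobs(matrix)
    scores = _scores_for_tree(np.asarray(tree.parents), L0[:, col], L1[:, col])
    best = scores.argmax(axis=1)
    return {cell: int(b) for cell, b in zip(matrix.cells, best)}


# ---------------------------------------------------------------------------
# Search


def _enumerate_parent_vectors(m: int):
    """All acyclic parent vectors over nodes 0..m-1 with root index m."""
    for parents in itertools.product(*(
        [p for p in range(m + 1) if p != i] for i in range(m)
    )):
        if _is_acyclic(parents):
            yield parents


def infer_ml_tree(
    matrix: MutationMatrix,
    search: str = "exhaustive",
    seed: int | None = None,
    chain_length: int = 100_000,
    attachment: str = "max",
) -> tuple[MutationTree, float]:
    """Maximum-likelihood mutation tree.

    ``search='exhaustive'`` enumerates every labeled rooted mutation tree
    (parent vector) and requires m <= 7; ``'mcmc'`` runs a seeded
    Metropolis chain over prune-and-reattach and label-swap moves and
    returns the best tree visited.  Likelihood ties are broken by the
    lexicographically smallest parent vector; swappable tied label pairs
    are recorded on the returned tree and flagged.
    """
    m = matrix.n_mutations
    if m == 0:
        raise ValueError("matrix has zero retained mutations")
    labels = matrix.mutations
    L0, L1 = _obs_logprobs(matrix)

    if search == "exhaustive":
        if m > 7:
            raise ValueError("exhaustive search supports at most 7 mutations")
        best_ll = -np.inf
        best: list[tuple[int, ...]] = []
        for parents in _enumerate_parent_vectors(m):
            ll = _tree_loglik(np.asarray(parents), L0, L1, attachment)
            if ll > best_ll + 1e-9:
                best_ll, best = ll, [parents]
            elif ll > best_ll - 1e-9:
                best.append(parents)
        best.sort()
        parents = best[0]
        ties = _tied_label_pairs(best, labels)
        flags = ("likelihood_tie",) if len(best) > 1 else ()
        tree = MutationTree(parents=parents, labels=labels, ties=ties, flags=flags)
        tree.attachments = _map_attachments(tree, matrix)
        return tree, float(best_ll)

    if search == "mcmc":
        return _mcmc_search(matrix, L0, L1, seed, chain_length, attachment)
    raise ValueError(f"unknown search mode {search!r}")


def _tied_label_pairs(
    optima: list[tuple[int, ...]], labels: tuple[str, ...]
) -> tuple[tuple[str, str], ...]:
    """Adjacent label pairs of the first optimum whose swap is also optimal."""
    if len(optima) < 2:
        return ()
    canon = optima[0]
    others = set(optima[1:])
    pairs = []
    for i, p in enumerate(canon):
        if p == len(canon):
            continue
        swapped = _swap_labels(canon, i, p)
        if swapped in others:
            pairs.append(tuple(sorted((labels[i], labels[p]))))
    return tuple(sorted(set(pairs)))


def _swap_labels(parents: tuple[int, ...], a: int, b: int) -> tuple[int, ...]:
    """Parent vector after exchanging the labels at node indices a and b."""
    def rename(x: int) -> int:
        if x == a:
            return b
        if x == b:
            return a
        return x

    out = list(parents)
    out[a], out[b] = parents[b], parents[a]
    return tuple(rename(p) for p in out)


def _descendants(parents: Sequence[int], node: int) -> set[int]:
    m = len(parents)
    kids: dict[int, list[int]] = {}
    for i, p in enumerate(parents):
        kids.setdefault(p, []).append(i)
    out: set[int] = set()
    stack = [node]
    while stack:
        n = stack.pop()
        for c in kids.get(n, []):
            out.add(c)
            stack.append(c)
    return out


def _mcmc_search(
    matrix: MutationMatrix,
    L0: np.ndarray,
    L1: np.ndarray,
    seed: int | None,
    chain_length: int,
    attachment: str,
) -> tuple[MutationTree, float]:
    rng = np.random.default_rng(seed)
    m = matrix.n_mutations
    # start from a random star-ish tree
    parents = list(rng.integers(0, m + 1, size=m))
    for i in range(m):
        parents[i] = m  # star tree is always valid
    cur = tuple(parents)
    cur_ll = _tree_loglik(np.asarray(cur), L0, L1, attachment)
    best, best_ll = cur, cur_ll
    for _ in range(chain_length):
        prop = list(cur)
        if m >= 2 and rng.random() < 0.5:
            a, b = rng.choice(m, size=2, replace=False)
            prop = list(_swap_labels(cur, int(a), int(b)))
        else:
            node = int(rng.integers(0, m))
            forbidden = _descendants(cur, node) | {node}
            choices = [p for p in range(m + 1) if p not in forbidden]
            prop[node] = int(choices[int(rng.integers(0, len(choices)))])
        prop_t = tuple(prop)
        prop_ll = _tree_loglik(np.asarray(prop_t), L0, L1, attachment)
        if prop_ll >= cur_ll or rng.random() < np.exp(prop_ll - cur_ll):
            cur, cur_ll = prop_t, prop_ll
        if cur_ll > best_ll or (cur_ll == best_ll and cur < best):
            best, best_ll = cur, cur_ll
    tree = MutationTree(parents=best, labels=matrix.mutations)
    tree.attachments = _map_attachments(tree, matrix)
    return tree, float(best_ll)


# ---------------------------------------------------------------------------
# Cross-referencing with longitudinal data


def order_trunk_by_generations(
    tree: MutationTree,
    lines,
    detection_limit: float = 0.05,
) -> MutationTree:
    """Resolve likelihood-tied trunk orderings using bulk time series.

    For each recorded tied label pair that is parent-child on the trunk,
    the mutation detected earlier in the longitudinal data (first sampled
    generation with frequency >= ``detection_limit``) is placed first.
    Mutations absent from the longitudinal data keep their tree order and
    receive a ``rare/below-detection`` flag.  Annotation-only: the
    likelihood is unchanged.
    """
    from .trajectory_stats import EvolutionLine, _first_detection

    if isinstance(lines, EvolutionLine):
        lines = [lines]

    def first_gen(label: str) -> int | None:
        gens = [
            g
            for ln in lines
            if (g := _first_detection(ln, label, detection_limit)) is not None
        ]
        return min(gens) if gens else None

    parents = tuple(tree.parents)
    flags = list(tree.flags)
    trunk = tree.trunk()
    label_at = {tree.labels[i]: i for i in range(tree.m)}
    for la, lb in tree.ties:
        ia, ib = label_at[la], label_at[lb]
        if ia not in trunk or ib not in trunk:
            continue
        # order as parent-first along the trunk
        first, second = (ia, ib) if trunk.index(ia) < trunk.index(ib) else (ib, ia)
        g_first = first_gen(tree.labels[first])
        g_second = first_gen(tree.labels[second])
        if g_first is None or g_second is None:
            missing = tree.labels[first] if g_first is None else tree.labels[second]
            flags.append(f"rare/below-detection:{missing}")
            continue
        if g_second < g_first:
            parents = _swap_labels(parents, first, second)
            flags.append(f"reordered:{tree.labels[second]}<{tree.labels[first]}")
    return replace(tree, parents=parents, flags=tuple(flags))
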