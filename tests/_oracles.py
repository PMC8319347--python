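"""Independent brute-force oracles shared by the test suite.

These deliberately avoid the package's vectorized code paths: explicit
python loops over cells, attachment nodes and sites, and exhaustive
enumeration of parent vectors.
"""

import itertools
import math

import numpy as np


def oracle_loglik(parents, states, fd, ad, attachment="max"):
    """Mutation-tree log-likelihood by explicit loops."""
    m = len(parents)

    def genotype(node):
        g = [0] * m
        while node != m:
            g[node] = 1
            node = parents[node]
        return g

    genos = [genotype(j) for j in range(m)] + [[0] * m]
    total = 0.0
    for row in states:
        probs = []
        for g in genos:
            p = 1.0
            for obs, true in zip(row, g):
                if obs == 3:
                    continue
                if true == 1:
                    p *= (1 - ad) if obs == 1 else ad
                else:
                    p *= fd if obs == 1 else (1 - fd)
            probs.append(p)
        cell_p = max(probs) if attachment == "max" else sum(probs) / len(probs)
        total += math.log(cell_p)
    return total


def oracle_best_trees(states, fd, ad):
    """All globally optimal parent vectors over every labeled rooted tree."""
    m = states.shape[1]

    def acyclic(parents):
        for start in range(m):
            node, steps = start, 0
            while node != m:
                node = parents[node]
                steps += 1
                if steps > m:
                    return False
        return True

    best_ll, best = -np.inf, []
    for parents in itertools.product(
        *([p for p in range(m + 1) if p != i] for i in range(m))
    ):
        if not acyclic(parents):
            continue
        ll = oracle_loglik(parents, states, fd, ad)
        if ll > best_ll + 1e-9:
            best_ll, best = ll, [parents]
        elif ll > best_ll - 1e-9:
            best.append(parents)
    return best_ll, sorted(best)


def oracle_cooccurrence_p(n_lines, ka, kb, observed):
    """Exhaustive column-margin placement null for pairwise co-occurrence."""
    hits = total = 0
    for sa in itertools.combinations(range(n_lines), ka):
        for sb in itertools.combinations(range(n_lines), kb):
            total += 1
            if len(set(sa) & set(sb)) >= observed:
                hits += 1
    return hits / total
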