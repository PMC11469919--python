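"""Independent oracles shared by the unit and acceptance suites.

Each function here is deliberately implemented without reference to the
package code paths it is used to check: exhaustive window matching for the
motif scanner, exhaustive alignment enumeration for the affine-gap aligner,
and path-sum matrices of explicitly constructed random trees for neighbor
joining.
"""

import math

import numpy as np
from skbio import DistanceMatrix


def brute_force_hits(seq: str, definition) -> list[tuple[int, str]]:
    """Check every window of the motif's length against its position sets."""
    span = len(definition)
    out = []
    for start in range(1, len(seq) - span + 2):
        window = seq[start - 1:start - 1 + span]
        ok = all(allowed is None or ch in allowed
                 for ch, allowed in zip(window, definition.positions))
        if ok:
            out.append((start, window))
    return out


def brute_force_score(a, b, matrix_fn, gap_open, gap_extend):
    """Enumerate every global alignment; a gap run of length k costs
    open + k*extend."""
    best = -math.inf

    def score(pairs):
        total, run_a, run_b = 0.0, 0, 0
        for x, y in pairs:
            if x is None:
                run_a += 1
                if run_b:
                    total -= gap_open + run_b * gap_extend
                    run_b = 0
            elif y is None:
                run_b += 1
                if run_a:
                    total -= gap_open + run_a * gap_extend
                    run_a = 0
            else:
                for run in (run_a, run_b):
                    if run:
                        total -= gap_open + run * gap_extend
                run_a = run_b = 0
                total += matrix_fn(x, y)
        for run in (run_a, run_b):
            if run:
                total -= gap_open + run * gap_extend
        return total

    def walk(i, j, pairs):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score(pairs))
            return
        if i < len(a) and j < len(b):
            walk(i + 1, j + 1, pairs + [(a[i], b[j])])
        if i < len(a):
            walk(i + 1, j, pairs + [(a[i], None)])
        if j < len(b):
            walk(i, j + 1, pairs + [(None, b[j])])

    walk(0, 0, [])
    return best


def additive_matrix_from_random_tree(n, rng) -> DistanceMatrix:
    """Path-sum distance matrix of a random binary tree with random branch
    lengths (the additive-matrix oracle for neighbor joining)."""
    labels = [f"L{i}" for i in range(n)]
    leaf_dists = {lab: {lab: 0.0} for lab in labels}
    keys = list(labels)
    dist = {}
    while len(keys) > 1:
        i, j = sorted(rng.choice(len(keys), 2, replace=False))
        a, b = keys[i], keys[j]
        la, lb = rng.uniform(0.1, 2.0, 2).round(3)
        for x, dx in leaf_dists[a].items():
            for y, dy in leaf_dists[b].items():
                dist[(x, y)] = dist[(y, x)] = dx + la + dy + lb
        merged = {x: dx + la for x, dx in leaf_dists[a].items()}
        merged.update({y: dy + lb for y, dy in leaf_dists[b].items()})
        leaf_dists[a + b] = merged
        keys = [k for k in keys if k not in (a, b)] + [a + b]
    mat = np.zeros((n, n))
    for x in range(n):
        for y in range(n):
            if x != y:
                mat[x, y] = dist[(labels[x], labels[y])]
    return DistanceMatrix(mat, labels)
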