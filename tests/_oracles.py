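"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity by exhaustive enumeration or a naive
algorithm, sharing no code with the implementation it checks.
"""

from __future__ import annotations

import sys

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def brute_force_profile_score(profile, target: str) -> float:
    """Maximal local profile-target score by exhaustive path enumeration.

    Enumerates every monotone local alignment (any start cell, any end
    cell, affine gaps with no gap-to-gap transitions) of the profile
    against the target.  Feasible for model_length <= 4, target <= 8.
    """
    length, n = profile.model_length, len(target)
    go, ge = profile.gap_open, profile.gap_extend
    best = 0.0
    sys.setrecursionlimit(100000)

    def rec(i: int, j: int, last: str | None, score: float) -> None:
        nonlocal best
        best = max(best, score)
        if i < length and j < n:
            rec(i + 1, j + 1, "M", score + profile.column_scores(target[j])[i])
        if i < length and last != "Iy":
            rec(i + 1, j, "Ix", score + (ge if last == "Ix" else go))
        if j < n and last != "Ix":
            rec(i, j + 1, "Iy", score + (ge if last == "Iy" else go))

    for i0 in range(length):
        for j0 in range(n):
            rec(i0, j0, None, 0.0)
    return best


def enumerate_semiglobal(
    a: str,
    b: str,
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
):
    """Exhaustive global end-gap-free alignment of two short sequences.

    Terminal gap runs are free and excluded from the identity denominator;
    interior gaps are affine and counted as core columns.  An insertion
    column may never sit next to a deletion column (the pairwise-aligner
    convention), so each end's overhang lives in exactly one sequence and
    every alignment is: overhang, core starting and ending with an aligned
    pair, overhang.  All admissible (start, end) anchor pairs are
    enumerated with every monotone interior path between them.  Returns
    ``(best_score, pids)`` with ``pids`` the set of percent identities
    (identities / core columns) over all score-optimal alignments.
    """
    best = [-float("inf"), set()]
    la, lb = len(a), len(b)
    sys.setrecursionlimit(100000)

    def record(score: float, ident: int, core: int) -> None:
        pid = round(100.0 * ident / core, 6) if core else 0.0
        if score > best[0] + 1e-9:
            best[0] = score
            best[1] = {pid}
        elif abs(score - best[0]) <= 1e-9:
            best[1].add(pid)

    def affine(run: int) -> float:
        return (gap_open + gap_extend * (run - 1)) if run else 0.0

    def pair(i: int, j: int) -> tuple[float, int]:
        return float(_BLOSUM62[a[i], b[j]]), int(a[i] == b[j])

    def rec(i, j, i1, j1, score, ident, core, run, kind) -> None:
        # (i, j): next unconsumed positions; the alignment must end with
        # the aligned pair (i1, j1)
        if i == i1 and j == j1:  # closing pair (any open gap run is interior)
            s, eq = pair(i1, j1)
            record(score + affine(run) + s, ident + eq, core + run + 1)
            return
        if i < i1 and j < j1:  # interior aligned pair closes any gap run
            s, eq = pair(i, j)
            rec(i + 1, j + 1, i1, j1, score + affine(run) + s,
                ident + eq, core + run + 1, 0, None)
        if i < i1 and kind in (None, "a"):  # interior gap consuming a
            rec(i + 1, j, i1, j1, score, ident, core, run + 1, "a")
        if j < j1 and kind in (None, "b"):  # interior gap consuming b
            rec(i, j + 1, i1, j1, score, ident, core, run + 1, "b")

    for i0 in range(la):
        for j0 in range(lb):
            if i0 > 0 and j0 > 0:  # left overhang in one sequence only
                continue
            s0, eq0 = pair(i0, j0)
            for i1 in range(i0, la):
                for j1 in range(j0, lb):
                    if i1 < la - 1 and j1 < lb - 1:  # same at the right end
                        continue
                    if (i0, j0) == (i1, j1):
                        record(s0, eq0, 1)
                    else:
                        rec(i0 + 1, j0 + 1, i1, j1, s0, eq0, 1, 0, None)
    # the fully disjoint alignment (each sequence entirely in the other's
    # terminal gap run) scores 0 with no aligned columns
    record(0.0, 0, 0)
    return best[0], best[1]


def dfs_components(nodes, edges):
    """Connected components by iterative depth-first search."""
    adjacency = {n: [] for n in nodes}
    for u, v in edges:
        adjacency[u].append(v)
        adjacency[v].append(u)
    seen: set = set()
    components = []
    for start in nodes:
        if start in seen:
            continue
        stack = [start]
        comp = set()
        while stack:
            node = stack.pop()
            if node in comp:
                continue
            comp.add(node)
            stack.extend(nb for nb in adjacency[node] if nb not in comp)
        seen |= comp
        components.append(frozenset(comp))
    return components
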