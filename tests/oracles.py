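"""Independent brute-force oracles used by the tests.

These deliberately re-derive results from first principles (enumeration,
direct criterion evaluation, closed forms) rather than calling the package
code they check.
"""

from itertools import combinations

import numpy as np


def brute_force_stability(labels) -> tuple[int, bool]:
    """Evaluate all eight stability criteria literally and apply precedence.

    Plain-Python transcription of the scoring table: fractions on
    artifact-free denominators, thirds by wall-clock position, minimum
    satisfied score among 1-6, else 8, else 7 (flagged when nothing holds).
    """
    labels = list(labels)
    n = len(labels)
    thirds = [labels[:n // 3], labels[n // 3:(2 * n) // 3],
              labels[(2 * n) // 3:]]

    def frac(lst, members):
        free = [x for x in lst if x != "ARTIFACT"]
        if not free:
            return 0.0
        return sum(x in members for x in free) / len(free)

    sat = {
        1: frac(thirds[0], {"B23"}) >= 1 / 3,
        2: frac(thirds[1], {"B23"}) >= 1 / 3,
        3: frac(thirds[2], {"B23"}) >= 1 / 3,
        4: frac(thirds[0], {"B1"}) >= 1 / 3,
        5: frac(thirds[1], {"B1"}) >= 1 / 3,
        6: frac(thirds[2], {"B1"}) >= 1 / 3,
    }
    low = [s for s, ok in sat.items() if ok]
    if low:
        return min(low), False
    if frac(labels, {"0", "A1"}) > 2 / 3:
        return 8, False
    if frac(labels, {"0", "A1", "A2", "A3"}) >= 2 / 3:
        return 7, False
    return 7, True


def exact_mannwhitney_p(x, y) -> float:
    """Exact two-sided Mann-Whitney p by enumerating all rank assignments.

    Valid for tie-free samples; enumerates every way of choosing which
    combined ranks belong to x and compares U statistics.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    combined = np.sort(np.concatenate([x, y]))
    ranks = {v: i + 1 for i, v in enumerate(combined)}
    u_obs = sum(ranks[v] for v in x) - n1 * (n1 + 1) / 2
    u_obs = min(u_obs, n1 * n2 - u_obs)  # two-sided via the smaller U
    count = total = 0
    for subset in combinations(range(1, n1 + n2 + 1), n1):
        u = sum(subset) - n1 * (n1 + 1) / 2
        u = min(u, n1 * n2 - u)
        total += 1
        if u <= u_obs:
            count += 1
    return count / total


def brute_force_kruskal_h(groups) -> float:
    """Kruskal-Wallis H from the definition, with mid-ranks and tie
    correction."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    combined = np.concatenate(groups)
    n = combined.size
    order = np.argsort(combined, kind="mergesort")
    ranks = np.empty(n)
    sorted_vals = combined[order]
    i = 0
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(combined, return_counts=True)
    correction = 1 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / correction


def markov_absorption_time(p_down: float, start_index: int, n_states: int
                           ) -> float:
    """Expected steps to absorption at the bottom of a pure-decline chain.

    Fundamental-matrix computation N = (I - Q)^-1 for the transient block of
    the one-step-down chain with per-step probability ``p_down``.
    """
    n_trans = n_states - 1
    q = np.zeros((n_trans, n_trans))
    for i in range(n_trans):
        q[i, i] = 1 - p_down
        if i + 1 < n_trans:
            q[i, i + 1] = p_down
    fundamental = np.linalg.inv(np.eye(n_trans) - q)
    return float(fundamental[start_index].sum())
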