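"""Independent oracles used to cross-check the package implementation.

Each oracle deliberately takes a different computational route from the
code under test: transport problems are solved by exhaustive enumeration
of integer transport tables or by network simplex on an integerized
min-cost-flow graph, edit distances come from edlib on character-mapped
tokens, and regression coefficients from the closed-form normal
equations.
"""

from __future__ import annotations

import itertools

import numpy as np


def transport_bruteforce(
    counts_a: list[int], counts_b: list[int], cost: np.ndarray
) -> float:
    """Exact nBOW transport cost by enumerating integer transport tables.

    Token-count vectors define nBOW weights ``counts/sum``.  Scaling row
    masses by ``sum(counts_b)`` and column masses by ``sum(counts_a)``
    makes all marginals integral; because the transportation polytope
    with integral marginals has integral vertices, enumerating integer
    tables with those marginals visits an optimal solution.  Feasible for
    small documents only.
    """
    na, nb = sum(counts_a), sum(counts_b)
    rows = [c * nb for c in counts_a]
    cols = [c * na for c in counts_b]
    n, m = len(rows), len(cols)
    best = [np.inf]

    def fill(i: int, remaining_cols: tuple[int, ...], acc: float) -> None:
        if acc >= best[0]:
            return
        if i == n:
            if all(r == 0 for r in remaining_cols):
                best[0] = acc
            return
        # enumerate all ways to split row i's mass across columns
        def split(j: int, left: int, cols_state: list[int], acc_row: float) -> None:
            if acc + acc_row >= best[0]:
                return
            if j == m - 1:
                if left <= cols_state[j]:
                    cols_state[j] -= left
                    fill(i + 1, tuple(cols_state), acc + acc_row + left * cost[i, j])
                    cols_state[j] += left
                return
            for t in range(min(left, cols_state[j]) + 1):
                cols_state[j] -= t
                split(j + 1, left - t, cols_state, acc_row + t * cost[i, j])
                cols_state[j] += t

        split(0, rows[i], list(remaining_cols), 0.0)

    fill(0, tuple(cols), 0.0)
    return float(best[0]) / (na * nb)


def transport_network_simplex(
    counts_a: list[int], counts_b: list[int], cost: np.ndarray
) -> float:
    """Exact nBOW transport cost via networkx network simplex.

    Same integral scaling as :func:`transport_bruteforce`; edge costs are
    integerized at 1e-8 resolution, exact for network simplex, so the
    returned objective is within 1e-8 of the true optimum.
    """
    import networkx as nx

    na, nb = sum(counts_a), sum(counts_b)
    scale = 10**8
    graph = nx.DiGraph()
    for i, c in enumerate(counts_a):
        graph.add_node(("a", i), demand=-c * nb)
    for j, c in enumerate(counts_b):
        graph.add_node(("b", j), demand=c * na)
    for i in range(len(counts_a)):
        for j in range(len(counts_b)):
            graph.add_edge(("a", i), ("b", j), weight=int(round(cost[i, j] * scale)))
    flow_cost, _ = nx.network_simplex(graph)
    return flow_cost / (scale * na * nb)


def edit_distance_edlib(ref: list[str], hyp: list[str]) -> int:
    """Unit-cost edit distance between token sequences via edlib.

    Tokens are mapped to single unicode characters so the alignment runs
    on strings; edlib returns the Levenshtein distance.
    """
    import edlib

    alphabet: dict[str, str] = {}
    for token in itertools.chain(ref, hyp):
        if token not in alphabet:
            alphabet[token] = chr(0x100 + len(alphabet))
    a = "".join(alphabet[t] for t in ref)
    b = "".join(alphabet[t] for t in hyp)
    if not a and not b:
        return 0
    return edlib.align(a, b, task="distance")["editDistance"]


def ols_normal_equations(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """OLS coefficients [intercept, b1, ...] from the normal equations."""
    design = np.column_stack([np.ones(len(x)), x])
    return np.linalg.solve(design.T @ design, design.T @ y)


def welch_p_numerical(t: float, df: float) -> float:
    """Two-sided p-value by numerical integration of the t density."""
    from scipy.integrate import quad
    from scipy.special import gammaln

    log_norm = (
        gammaln((df + 1) / 2) - gammaln(df / 2) - 0.5 * np.log(df * np.pi)
    )

    def density(u: float) -> float:
        return float(np.exp(log_norm - (df + 1) / 2 * np.log1p(u**2 / df)))

    tail, _ = quad(density, abs(t), np.inf)
    return 2 * tail
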