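"""Regional distribution and local diversity change statistics.

Two complementary views of ensemble projections: per-category pixel counts
(regional distribution — how much area each forest category keeps) and
per-pixel category richness (local diversity — how many categories coexist
in a cell).  States (historical, each sub-CEM) are compared with chi-square
homogeneity tests, at full-domain or per-region level, and summarized with a
compact letter display.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ChiSquareResult:
    state_a: str
    state_b: str
    statistic: float
    df: int
    pvalue: float
    alpha: float
    significant: bool


def _stack_states(state_maps: dict[str, dict[str, np.ndarray]]) -> tuple[list[str], list[str]]:
    states = list(state_maps)
    categories = list(next(iter(state_maps.values())))
    shape = None
    for st, cats in state_maps.items():
        if list(cats) != categories:
            raise ValueError(f"state {st!r} has a different category set")
        for cat, m in cats.items():
            if shape is None:
                shape = m.shape
            elif m.shape != shape:
                raise ValueError(f"grid mismatch for ({st!r}, {cat!r})")
    return states, categories


def _region_iter(region_mask: np.ndarray | None, shape: tuple[int, int]):
    if region_mask is None:
        yield None, np.ones(shape, dtype=bool)
        return
    region_mask = np.asarray(region_mask)
    if region_mask.shape != shape:
        raise ValueError("region mask grid mismatch")
    for label in np.unique(region_mask):
        yield label, region_mask == label


def distribution_table(
    state_maps: dict[str, dict[str, np.ndarray]],
    region_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Pixel counts of presence per category per state (optionally per region).

    ``state_maps[state][category]`` is a binary presence map; all maps must
    share one grid.  Without a region mask the index is the state; with one
    it is (region, state).
    """
    states, categories = _stack_states(state_maps)
    shape = next(iter(next(iter(state_maps.values())).values())).shape
    rows = []
    for label, sel in _region_iter(region_mask, shape):
        for st in states:
            row = {cat: int(np.asarray(state_maps[st][cat], dtype=bool)[sel].sum())
                   for cat in categories}
            key = {"state": st} if label is None else {"region": label, "state": st}
            rows.append({**key, **row})
    df = pd.DataFrame(rows)
    index = ["state"] if region_mask is None else ["region", "state"]
    return df.set_index(index)


def richness(maps: dict[str, np.ndarray]) -> np.ndarray:
    """Per-pixel count of categories present."""
    return np.sum([np.asarray(m, dtype=bool).astype(int) for m in maps.values()], axis=0)


def diversity_table(
    state_maps: dict[str, dict[str, np.ndarray]],
    region_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Histogram of per-pixel category richness per state.

    Columns are richness values 0..n_categories; an extra ``most_frequent``
    column holds the most frequent nonzero richness (the smallest value on
    ties, NaN when no pixel hosts any category).
    """
    states, categories = _stack_states(state_maps)
    n_cat = len(categories)
    shape = next(iter(next(iter(state_maps.values())).values())).shape
    rows = []
    for label, sel in _region_iter(region_mask, shape):
        for st in states:
            rich = richness(state_maps[st])[sel]
            hist = np.bincount(rich, minlength=n_cat + 1)
            row = {r: int(hist[r]) for r in range(n_cat + 1)}
            nonzero = hist[1:]
            row["most_frequent"] = int(nonzero.argmax()) + 1 if nonzero.sum() > 0 else np.nan
            key = {"state": st} if label is None else {"region": label, "state": st}
            rows.append({**key, **row})
    df = pd.DataFrame(rows)
    index = ["state"] if region_mask is None else ["region", "state"]
    return df.set_index(index)


def _pool_bins(table: np.ndarray, min_expected: float = 5.0) -> np.ndarray:
    """Merge adjacent columns until every expected count reaches the floor."""
    table = table.astype(float)
    while table.shape[1] > 2:
        total = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
        low = np.flatnonzero(expected.min(axis=0) < min_expected)
        if low.size == 0:
            break
        j = low[0]
        k = j + 1 if j + 1 < table.shape[1] else j - 1
        merged = table.copy()
        merged[:, min(j, k)] += merged[:, max(j, k)]
        table = np.delete(merged, max(j, k), axis=1)
    return table


def compare_states(
    counts_a: np.ndarray | pd.Series,
    counts_b: np.ndarray | pd.Series,
    alpha: float = 0.001,
    state_a: str = "A",
    state_b: str = "B",
    min_expected: float = 5.0,
) -> ChiSquareResult:
    """Chi-square homogeneity test between two count distributions.

    The 2 × k contingency table (states × bins) is tested without continuity
    correction; adjacent bins are pooled until every expected count reaches
    ``min_expected``.  Identical rows give statistic 0 and p-value 1.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("count vectors must be 1-D with matching length")
    table = np.vstack([a, b])
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    if table.shape[1] < 2:
        raise ValueError("fewer than 2 usable bins")
    table = _pool_bins(table, min_expected=min_expected)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if expected.min() < 1.0:
        raise ValueError("expected counts below 1 even after pooling")
    if np.allclose(table[0] / table[0].sum(), table[1] / table[1].sum()):
        stat, p, df = 0.0, 1.0, table.shape[1] - 1
    else:
        stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    return ChiSquareResult(
        state_a=state_a,
        state_b=state_b,
        statistic=float(stat),
        df=int(df),
        pvalue=float(p),
        alpha=alpha,
        significant=bool(p < alpha),
    )


def pairwise_compare(
    tables: dict[str, np.ndarray | pd.Series], alpha: float = 0.001, holm: bool = False
) -> list[ChiSquareResult]:
    """All pairwise state comparisons, optionally Holm-adjusted."""
    names = list(tables)
    results = [
        compare_states(tables[a], tables[b], alpha=alpha, state_a=a, state_b=b)
        for a, b in combinations(names, 2)
    ]
    if holm:
        order = np.argsort([r.pvalue for r in results])
        m = len(results)
        adjusted_max = 0.0
        for rank, i in enumerate(order):
            adj = min((m - rank) * results[i].pvalue, 1.0)
            adjusted_max = max(adjusted_max, adj)
            results[i].pvalue = adjusted_max
            results[i].significant = adjusted_max < alpha
    return results


def letter_groups(states: list[str], results: list[ChiSquareResult]) -> dict[str, str]:
    """Compact letter display from pairwise chi-square results.

    States that are *not* significantly different share at least one letter.
    Letters are the maximal cliques of the not-different graph, ordered by
    their smallest state index for determinism.
    """
    sig = {}
    for r in results:
        sig[frozenset((r.state_a, r.state_b))] = r.significant
    for a, b in combinations(states, 2):
        if frozenset((a, b)) not in sig:
            raise ValueError(f"missing pairwise result for ({a!r}, {b!r})")

    g = nx.Graph()
    g.add_nodes_from(states)
    for a, b in combinations(states, 2):
        if not sig[frozenset((a, b))]:
            g.add_edge(a, b)

    pos = {s: i for i, s in enumerate(states)}
    cliques = sorted(
        (sorted(c, key=pos.get) for c in nx.find_cliques(g)),
        key=lambda c: [pos[s] for s in c],
    )
    letters = {s: "" for s in states}
    for i, clique in enumerate(cliques):
        letter = chr(ord("A") + i)
        for s in clique:
            letters[s] += letter
    return {s: "".join(sorted(letters[s])) for s in states}
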