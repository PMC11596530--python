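"""Independent reference implementations used only to check the package.

Each oracle recomputes a quantity by a different route than the library:
recursive/brute-force alignment scoring, exhaustive nearest-neighbour
search, and exact enumeration of rank-sum assignments.
"""

from functools import lru_cache
from itertools import combinations
from math import ceil, comb


def recursive_semiglobal_score(a: str, b: str, match=1.0, mismatch=-1.0, gap=-2.0) -> float:
    """Optimal semi-global score by top-down recursion over suffixes.

    Independently structured from the library's bottom-up matrix fill:
    trailing gaps are modelled as a free stop once either suffix is
    exhausted, leading gaps as a free choice of starting offset.
    """
    n, m = len(a), len(b)

    @lru_cache(maxsize=None)
    def from_cell(i: int, j: int) -> float:
        opts = []
        if i == n or j == m:
            opts.append(0.0)  # stop: remaining terminal gaps are free
        if i < n and j < m:
            opts.append((match if a[i] == b[j] else mismatch) + from_cell(i + 1, j + 1))
        if i < n:
            opts.append(gap + from_cell(i + 1, j))
        if j < m:
            opts.append(gap + from_cell(i, j + 1))
        return max(opts)

    starts = [from_cell(i, 0) for i in range(n + 1)] + [from_cell(0, j) for j in range(m + 1)]
    return max(starts)


def _all_global_scores(a: str, b: str, match, mismatch, gap):
    """Scores of every gapped alignment of a vs b with ALL gaps penalised."""
    if not a and not b:
        yield 0.0
        return
    if a and b:
        for s in _all_global_scores(a[1:], b[1:], match, mismatch, gap):
            yield (match if a[0] == b[0] else mismatch) + s
    if a:
        for s in _all_global_scores(a[1:], b, match, mismatch, gap):
            yield gap + s
    if b:
        for s in _all_global_scores(a, b[1:], match, mismatch, gap):
            yield gap + s


def enumerate_semiglobal_score(a: str, b: str, match=1.0, mismatch=-1.0, gap=-2.0) -> float:
    """Optimal semi-global score by enumerating every alignment.

    Tries every (start, end) span pair in which leading/trailing overhangs
    are free — one sequence's overhang at each end — and enumerates all
    penalised alignments of the cores.  Exponential; intended for sequences
    of length <= 5.
    """
    n, m = len(a), len(b)
    best = 0.0  # the empty alignment (everything a terminal gap) scores 0
    for si in range(n + 1):
        for sj in range(m + 1):
            if si and sj:
                continue  # a leading overhang may come from only one sequence
            for ei in range(si, n + 1):
                for ej in range(sj, m + 1):
                    if ei != n and ej != m:
                        continue
                    core = max(
                        _all_global_scores(a[si:ei], b[sj:ej], match, mismatch, gap)
                    )
                    best = max(best, core)
    return best


def exhaustive_nearest(query, references, soil_ids, substrate_ids, min_coverage=0.5):
    """Nearest source reference by exhaustive re-search.

    Recomputes every p-distance (through the public alignment API, but with
    an independently written search: a flat loop, its own coverage filter and
    its own tie handling) and re-takes the minimum.  Returns
    (nearest_id, distance_value, possible_source).
    """
    from primertrace import global_align, p_distance

    rows = []
    for ref in references:
        try:
            d = p_distance(global_align(query.sequence, ref.sequence))
        except ValueError:
            continue
        rows.append((ref.asv_id, d.value, d.n_compared_columns, min(len(query), len(ref))))
    covered = [r for r in rows if r[2] >= ceil(min_coverage * r[3])]
    if not covered:
        covered = rows
    dmin = min(r[1] for r in covered)
    winners = [r for r in covered if r[1] <= dmin + 1e-12]
    has_soil = any(r[0] in soil_ids for r in winners)
    has_sub = any(r[0] in substrate_ids for r in winners)
    source = "Common" if (has_soil and has_sub) else ("Soil" if has_soil else "Substrate")
    return winners[0][0], winners[0][1], source


def exact_rank_sum_two_sided(x, y) -> float:
    """Exact two-sided rank-sum p by direct enumeration of assignments."""
    pooled = sorted(list(x) + list(y))

    def rank_of(v):
        idx = [i for i, p in enumerate(pooled) if p == v]
        return sum(i + 1 for i in idx) / len(idx)

    ranks = [rank_of(v) for v in list(x) + list(y)]
    n, N = len(x), len(ranks)
    mu = n * (N + 1) / 2
    w_obs = sum(ranks[:n])
    hits = sum(
        1 for c in combinations(ranks, n) if abs(sum(c) - mu) >= abs(w_obs - mu) - 1e-9
    )
    return hits / comb(N, n)
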