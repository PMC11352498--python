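"""Independent brute-force oracles used by several test modules."""

from mirforge.hairpin import MIN_LOOP, pair_energy


def enumerate_min_energy(seq: str) -> float:
    """Minimum pseudo-energy over ALL nested structures by explicit
    uncached enumeration: the leftmost free base is left unpaired or paired
    with every admissible partner, which (crossings being forbidden) splits
    the remainder into independent inside/outside sets.  Feasible for
    n <= ~30."""

    def rec(avail: tuple[int, ...]) -> float:
        if not avail:
            return 0.0
        i = avail[0]
        rest = avail[1:]
        best = rec(rest)  # i unpaired
        for j in rest:
            if j - i <= MIN_LOOP:
                continue
            e = pair_energy(seq[i], seq[j])
            if e == float("inf"):
                continue
            inside = tuple(p for p in rest if p < j)
            outside = tuple(p for p in rest if p > j)
            cand = e + rec(inside) + rec(outside)
            if cand < best:
                best = cand
        return best

    return rec(tuple(range(len(seq))))


def average_linkage_oracle(dist: dict) -> list:
    """Naive agglomerative average-linkage clustering.

    ``dist`` maps frozenset({a, b}) -> distance over leaf labels; returns the
    merge history [(members_a, members_b, height), ...] with deterministic
    lexicographic tie-breaking.
    """
    leaves = sorted({x for pair in dist for x in pair})
    clusters: list[tuple] = [(leaf,) for leaf in leaves]

    def d(ca, cb):
        return sum(dist[frozenset((a, b))] for a in ca for b in cb) / (len(ca) * len(cb))

    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                key = (d(clusters[i], clusters[j]), clusters[i], clusters[j])
                if best is None or key < best[0]:
                    best = (key, i, j)
        (height, _, _), i, j = best
        merged = tuple(sorted(clusters[i] + clusters[j]))
        merges.append((clusters[i], clusters[j], height))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
        clusters.sort()
    return merges
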