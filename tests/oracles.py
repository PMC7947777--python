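"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's algorithms: tail sums use
exact rational arithmetic, the rank-sum null is enumerated over label
assignments, and synteny chains are found by exhaustive enumeration of all
valid chains rather than dynamic programming.
"""

from fractions import Fraction
from itertools import combinations
from math import comb

from macrosyn.types import Anchor, SyntenyBlock


def binom_tail_ge(k: int, n: int, p: Fraction) -> Fraction:
    """P(X >= k) for X ~ Binomial(n, p), exact rational arithmetic."""
    return sum(
        Fraction(comb(n, i)) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1)
    )


def ranksum_exact_p(x, y, sided="two"):
    """Exact rank-sum p by enumerating which pooled positions belong to x."""
    pooled = list(x) + list(y)
    n1 = len(x)
    n = len(pooled)
    # midranks computed from scratch
    order = sorted(range(n), key=lambda i: pooled[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        mid = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    u_obs = sum(ranks[:n1]) - n1 * (n1 + 1) / 2.0
    mean_u = n1 * (n - n1) / 2.0
    total = ge = extreme = 0
    for idx in combinations(range(n), n1):
        u = sum(ranks[i] for i in idx) - n1 * (n1 + 1) / 2.0
        total += 1
        if u >= u_obs - 1e-9:
            ge += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-9:
            extreme += 1
    return (ge / total) if sided == "one-greater" else (extreme / total)


def _all_chains(ra, rb, max_gap):
    """Every valid chain (strictly increasing ra and rb, per-genome gaps
    <= max_gap) as a list of index tuples; anchors are pre-sorted by ra."""
    n = len(ra)
    chains = []

    def extend(chain):
        chains.append(tuple(chain))
        last = chain[-1]
        for j in range(last + 1, n):
            if (
                ra[j] > ra[last]
                and ra[j] - ra[last] - 1 <= max_gap
                and rb[j] > rb[last]
                and rb[j] - rb[last] - 1 <= max_gap
            ):
                chain.append(j)
                extend(chain)
                chain.pop()

    for i in range(n):
        extend([i])
    return chains


def oracle_blocks(anchors, min_genes, max_gap, max_multiplicity=2):
    """Exhaustive-enumeration counterpart of chain_blocks: repeatedly pick
    the best chain (most anchors; ties by lexicographically smallest rank-A
    tuple, then '+' before '-'), remove its anchors, stop below min_genes;
    then apply the same region-multiplicity cap."""
    groups = {}
    for a in anchors:
        groups.setdefault((a.chrom_a, a.chrom_b), []).append(a)

    blocks = []
    block_id = 0
    for key in sorted(groups):
        remaining = sorted(groups[key], key=lambda a: a.rank_a)
        while len(remaining) >= min_genes:
            ra = [a.rank_a for a in remaining]
            best = None
            for orient_idx, sign in enumerate((1, -1)):
                rb = [sign * a.rank_b for a in remaining]
                for chain in _all_chains(ra, rb, max_gap):
                    cand = (-len(chain), tuple(ra[i] for i in chain), orient_idx, chain)
                    if best is None or cand < best:
                        best = cand
            if best is None or -best[0] < min_genes:
                break
            _, _, orient_idx, chain = best
            members = [remaining[i] for i in chain]
            blocks.append(
                SyntenyBlock(
                    block_id=block_id,
                    chrom_a=key[0],
                    chrom_b=key[1],
                    orientation="+-"[orient_idx],
                    anchors=members,
                )
            )
            block_id += 1
            taken = set(chain)
            remaining = [a for i, a in enumerate(remaining) if i not in taken]

    kept = []
    for blk in blocks:
        lo_a = min(a.rank_a for a in blk.anchors)
        hi_a = max(a.rank_a for a in blk.anchors)
        lo_b = min(a.rank_b for a in blk.anchors)
        hi_b = max(a.rank_b for a in blk.anchors)
        n_a = n_b = 0
        for other in kept:
            if other.chrom_a == blk.chrom_a:
                o_lo = min(a.rank_a for a in other.anchors)
                o_hi = max(a.rank_a for a in other.anchors)
                if o_lo <= hi_a and lo_a <= o_hi:
                    n_a += 1
            if other.chrom_b == blk.chrom_b:
                o_lo = min(a.rank_b for a in other.anchors)
                o_hi = max(a.rank_b for a in other.anchors)
                if o_lo <= hi_b and lo_b <= o_hi:
                    n_b += 1
        if n_a < max_multiplicity and n_b < max_multiplicity:
            kept.append(blk)
    return kept


def random_anchor_instance(rng, n_max=40, rank_space=60):
    """A random one-to-one anchor instance on a single chromosome pair."""
    n = int(rng.integers(5, n_max + 1))
    ra = rng.choice(rank_space, size=n, replace=False)
    rb = rng.choice(rank_space, size=n, replace=False)
    return [
        Anchor(f"a{i}", f"b{i}", "cA", "cB", int(ra[i]), int(rb[i]))
        for i in range(n)
    ]
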