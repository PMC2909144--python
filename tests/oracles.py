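"""Brute-force reference implementations used only to check the package.

Everything here is deliberately naive — python loops, itertools enumeration —
and shares no code with the implementation under test.
"""

from itertools import combinations
from math import comb


def percentile_ranks_by_counting(values):
    """Fractional tied percentile rank of each value by direct counting."""
    n = len(values)
    out = []
    for v in values:
        below = sum(1 for u in values if u < v)
        tied = sum(1 for u in values if u == v)
        # average rank of the tied block: below + (tied + 1) / 2
        out.append((below + (tied + 1) / 2) / n)
    return out


def wilcoxon_exact_p_at_top(n, member_ranks):
    """Exact P(rank sum <= observed) for k members among ranks 1..n.

    Enumerates every k-subset of ranks; the one-sided alternative is
    "members sit nearer the top" (small rank sum).
    """
    k = len(member_ranks)
    obs = sum(member_ranks)
    hits = sum(1 for c in combinations(range(1, n + 1), k) if sum(c) <= obs)
    return hits / comb(n, k)


def gsea_es_stepwise(scores, member_flags, p=0.0):
    """Running-sum ES by an explicit per-position loop.

    ``scores`` already in ranked (descending) order; ``member_flags`` marks
    set members per position. Returns (es, running_sum_list).
    """
    n = len(scores)
    n_hit = sum(member_flags)
    n_miss = n - n_hit
    denom = sum(abs(s) ** p for s, h in zip(scores, member_flags) if h)
    if denom == 0:
        denom = 1.0  # zero-weight hits contribute nothing
        weights = [0.0] * n
    else:
        weights = [abs(s) ** p if h else 0.0 for s, h in zip(scores, member_flags)]
    running = []
    acc = 0.0
    for i in range(n):
        if member_flags[i]:
            acc += weights[i] / denom
        else:
            acc -= 1.0 / n_miss if n_miss else 0.0
        running.append(acc)
    es = max(running, key=abs)
    return es, running


def welch_t(xs, ys):
    """Textbook Welch statistic and degrees of freedom on two samples."""
    nx, ny = len(xs), len(ys)
    mx = sum(xs) / nx
    my = sum(ys) / ny
    vx = sum((x - mx) ** 2 for x in xs) / (nx - 1)
    vy = sum((y - my) ** 2 for y in ys) / (ny - 1)
    se2 = vx / nx + vy / ny
    t = (mx - my) / se2 ** 0.5
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return t, df
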