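"""Independent brute-force oracles used by the test suite.

These implement the checked quantities directly from their definitions
(explicit sums, greedy SSE agglomeration, combinatorial tail summation,
exhaustive scan enumeration) without calling the library code paths they
verify.
"""

from __future__ import annotations

from math import comb, log2, sqrt


def pearson_oracle(x, y) -> float:
    """Pearson r straight from the definition (explicit sums)."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / sqrt(sxx * syy)


def ward_greedy_oracle(points):
    """Greedy Ward agglomeration by direct SSE computation.

    At each step, merges the pair of clusters whose union minimises the
    increase in total within-cluster sum of squared Euclidean distances to
    the centroid.  Returns (merge_costs, partitions) where partitions[k] is
    the frozenset-of-frozensets partition with k clusters.
    """
    def sse(cluster):
        dims = len(points[0])
        total = 0.0
        for d in range(dims):
            vals = [points[i][d] for i in cluster]
            mu = sum(vals) / len(vals)
            total += sum((v - mu) ** 2 for v in vals)
        return total

    clusters = [frozenset([i]) for i in range(len(points))]
    partitions = {len(clusters): frozenset(clusters)}
    costs = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                delta = (sse(clusters[i] | clusters[j])
                         - sse(clusters[i]) - sse(clusters[j]))
                if best is None or delta < best[0] - 1e-12:
                    best = (delta, i, j)
        delta, i, j = best
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
        costs.append(delta)
        partitions[len(clusters)] = frozenset(clusters)
    return costs, partitions


def hypergeom_tail_oracle(M: int, K: int, n: int, k: int) -> float:
    """P(overlap >= k) by direct summation of hypergeometric terms."""
    denom = comb(M, n)
    total = 0
    for j in range(k, min(K, n) + 1):
        total += comb(K, j) * comb(M - K, n - j)
    return total / denom


def best_scan_oracle(seq: str, matrix, background) -> float:
    """Best log2-odds PWM hit by exhaustive enumeration over both strands."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    L = len(matrix[0])
    best = None
    for strand_seq in (seq, "".join(comp[b] for b in reversed(seq))):
        for off in range(len(strand_seq) - L + 1):
            score = 0.0
            for c in range(L):
                base = strand_seq[off + c]
                score += log2(matrix[idx[base]][c] / background[idx[base]])
            if best is None or score > best:
                best = score
    return best


def chi2_df1_tail_oracle(statistic: float) -> float:
    """Upper chi-square tail at df=1 via the normal-tail identity
    P(X > s) = 2 * (1 - Phi(sqrt(s))), computed with erfc."""
    from math import erfc
    return erfc(sqrt(statistic / 2.0))
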