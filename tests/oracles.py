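"""Independent brute-force oracles used to cross-check the engine."""

import numpy as np


def brute_force_select(candidates, k):
    """O(n^2) NSGA-II oracle: repeated extraction of non-dominated sets plus
    an independently coded crowding computation on the boundary front."""

    def dominates(f, g):
        return f[0] >= g[0] and f[1] >= g[1] and (f[0] > g[0] or f[1] > g[1])

    remaining = list(range(len(candidates)))
    fits = [c[1].objectives() for c in candidates]
    chosen = []
    while remaining and len(chosen) < k:
        front = [i for i in remaining
                 if not any(dominates(fits[j], fits[i]) for j in remaining if j != i)]
        front.sort()
        if len(chosen) + len(front) <= k:
            chosen.extend(front)
        else:
            if len(front) <= 2:
                dist = dict.fromkeys(front, float("inf"))
            else:
                dist = dict.fromkeys(front, 0.0)
                for obj in (0, 1):
                    order = sorted(front, key=lambda i: (fits[i][obj], i))
                    dist[order[0]] = dist[order[-1]] = float("inf")
                    span = fits[order[-1]][obj] - fits[order[0]][obj]
                    if span and np.isfinite(span):
                        for lo, mid, hi in zip(order, order[1:], order[2:]):
                            if np.isfinite(dist[mid]):
                                dist[mid] += (fits[hi][obj] - fits[lo][obj]) / span
            chosen.extend(sorted(front, key=lambda i: (-dist[i], i))[: k - len(chosen)])
        remaining = [i for i in remaining if i not in front]
    return [candidates[i][0] for i in chosen]
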