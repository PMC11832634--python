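"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: matching by full
enumeration, posteriors by explicit Gaussian densities, placement ranking
by direct product-of-probabilities enumeration.
"""

from __future__ import annotations

import itertools
import math
from decimal import Decimal

import numpy as np
from scipy.stats import multivariate_normal

from tcassign.tracking import pair_cost


def brute_force_match(a, b, gates) -> tuple[int, float]:
    """(max #pairs, min cost among max-cardinality matchings) by enumeration."""
    na, nb = len(a.peaks), len(b.peaks)
    costs = np.array(
        [[pair_cost(a.peaks[i], b.peaks[j], gates) for j in range(nb)] for i in range(na)]
    )
    best_pairs, best_cost = 0, 0.0
    for k in range(min(na, nb), -1, -1):
        found = False
        for rows in itertools.combinations(range(na), k):
            for cols in itertools.permutations(range(nb), k):
                total = sum(costs[r, c] for r, c in zip(rows, cols))
                if math.isinf(total):
                    continue
                if not found or total < best_cost:
                    best_pairs, best_cost, found = k, total, True
        if found:
            return best_pairs, best_cost
    return 0, 0.0


def gaussian_posterior_oracle(model, system) -> dict[str, float]:
    """Posterior by explicit multivariate-normal density times prior."""
    raw = np.array([system.feature(f) for f in model.subset.features], dtype=float)
    z = (raw - model.center) / model.scale
    dens = np.array(
        [
            pi * multivariate_normal.pdf(z, mean=mu, cov=model.pooled_cov)
            for mu, pi in zip(model.means, model.priors)
        ]
    )
    dens /= dens.sum()
    return dict(zip(model.classes, dens))


def enumerate_placements(
    posteriors, sequence, left_boundary="break", right_boundary="break",
    boundary_constraints=False, occupied=(),
):
    """All admissible (start, product probability) pairs, naively.

    Returns a list of (start, norm_prob) sorted by descending probability,
    ties by ascending start.
    """
    n = len(posteriors)
    occupied = set(occupied)
    raw = []
    for start in range(1, len(sequence) - n + 2):
        if boundary_constraints:
            if left_boundary == "proline" and (start < 2 or sequence[start - 2] != "P"):
                continue
            if left_boundary == "terminus" and start != 1:
                continue
            end = start + n - 1
            if right_boundary == "proline" and (end >= len(sequence) or sequence[end] != "P"):
                continue
            if right_boundary == "terminus" and end != len(sequence):
                continue
        if occupied.intersection(range(start, start + n)):
            continue
        prod = Decimal(1)  # Decimal: no underflow for products of tiny posteriors
        for i, post in enumerate(posteriors):
            table = post.posteriors if hasattr(post, "posteriors") else post
            prod *= Decimal(table.get(sequence[start + i - 1], 0.0))
        if prod > 0:
            raw.append((start, prod))
    total = sum(p for _, p in raw)
    raw.sort(key=lambda sp: (-sp[1], sp[0]))
    return [(s, float(p / total)) for s, p in raw]
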