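"""Subpathway enrichment by exact hypergeometric tail probabilities.

Given a significant metabolite set drawn from a background of N tested
metabolites, a subpathway containing K of the background and overlapping
the significant set in k members is scored with both inclusive tails of
the hypergeometric distribution:

* over-enrichment  ``p_over  = P(X ≥ k)``
* under-enrichment ``p_under = P(X ≤ k)``

where X ~ Hypergeom(N, K, n) and n is the significant-set size.  A
subpathway is called significant when ``min(p_over, p_under) < alpha``
(no doubling correction; both tails are reported).  Subpathways with
fewer than ``min_size`` background members are excluded from testing and
listed separately.  The background is the set of metabolites surviving
preprocessing — only tested metabolites can be significant.
"""

from __future__ import annotations

from math import comb

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["enrich_subpathways", "enrichment_oracle"]


def enrich_subpathways(significant_set, background_set, annotation: pd.DataFrame,
                       min_size: int = 5, alpha: float = 0.05,
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hypergeometric enrichment of every subpathway of size ≥ min_size.

    Returns ``(tested, skipped)``: the tested table has one row per
    subpathway with columns ``superpathway, N, K, n, k, p_over, p_under,
    direction, significant``; the skipped table lists subpathways below
    ``min_size`` and the count of unannotated significant metabolites is
    attached as ``tested.attrs['n_unannotated']``.
    """
    significant = set(significant_set)
    background = set(background_set)
    if not significant <= background:
        raise ValueError("significant set must be a subset of the background")

    ann = annotation[annotation["metabolite_id"].isin(background)]
    annotated = set(ann["metabolite_id"])
    n_unannotated = len(significant - annotated)

    N = len(annotated)
    n = len(significant & annotated)
    tested_rows, skipped_rows = [], []
    for (sub, sup), g in ann.groupby(["subpathway", "superpathway"], sort=True):
        members = set(g["metabolite_id"])
        K = len(members)
        k = len(members & significant)
        if K < min_size:
            skipped_rows.append({"subpathway": sub, "superpathway": sup,
                                 "K": K, "k": k})
            continue
        rv = stats.hypergeom(N, K, n)
        p_over = float(rv.sf(k - 1))
        p_under = float(rv.cdf(k))
        direction = "over" if p_over <= p_under else "under"
        tested_rows.append({
            "subpathway": sub, "superpathway": sup,
            "N": N, "K": K, "n": n, "k": k,
            "p_over": p_over, "p_under": p_under,
            "direction": direction,
            "significant": min(p_over, p_under) < alpha,
        })
    cols = ["subpathway", "superpathway", "N", "K", "n", "k",
            "p_over", "p_under", "direction", "significant"]
    tested = pd.DataFrame(tested_rows, columns=cols)
    skipped = pd.DataFrame(skipped_rows, columns=["subpathway", "superpathway", "K", "k"])
    tested.attrs["n_unannotated"] = n_unannotated
    return tested, skipped


def enrichment_oracle(N: int, K: int, n: int, k: int) -> tuple[float, float]:
    """Exact tails by explicit summation of hypergeometric point masses.

    Independent cross-check for small problems (N ≤ 30): enumerates
    P(X = j) = C(K, j) C(N−K, n−j) / C(N, n) over the support and sums the
    inclusive tails.  Intended for tests, not production use.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"inconsistent hypergeometric parameters "
                         f"N={N}, K={K}, n={n}, k={k}")
    if N > 30:
        raise ValueError("oracle is for N <= 30")
    total = comb(N, n)
    lo = max(0, n - (N - K))
    hi = min(K, n)
    pmf = {j: comb(K, j) * comb(N - K, n - j) / total for j in range(lo, hi + 1)}
    p_over = float(sum(p for j, p in pmf.items() if j >= k))
    p_under = float(sum(p for j, p in pmf.items() if j <= k))
    return min(p_over, 1.0), min(p_under, 1.0)
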