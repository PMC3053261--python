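"""One-tailed Fisher-exact over-representation tests and fold enrichment.

The test statistic is the hypergeometric upper tail: given a 2x2 table

                in set   not in set
    in target      a         b
    out target     c         d

the one-tailed p-value is P(X >= a) for X ~ Hypergeometric(N, a+c, a+b)
with N = a+b+c+d.  The tail is accumulated in log space (log-pmf +
logsumexp), which stays finite and positive for p far below 1e-300 —
needed because genome-scale overlaps routinely produce such values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .io import GeneSetCollection

__all__ = [
    "ContingencyResult",
    "fisher_one_tailed",
    "log10_fisher_one_tailed",
    "fold_enrichment",
    "bonferroni_threshold",
    "enrich_sets",
    "overlap_analysis",
]


@dataclass(frozen=True)
class ContingencyResult:
    """2x2 over-representation test result."""

    a: int
    b: int
    c: int
    d: int
    p: float
    log10_p: float
    odds_ratio: float
    fold_enrichment: float
    expected: float

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def _check_counts(*counts: int) -> None:
    for x in counts:
        if x < 0 or x != int(x):
            raise ValueError(f"counts must be nonnegative integers, got {x}")


def log10_fisher_one_tailed(a: int, b: int, c: int, d: int, depletion: bool = False) -> float:
    """log10 of the one-tailed Fisher exact p (over-representation tail
    by default; lower tail with ``depletion=True``)."""
    _check_counts(a, b, c, d)
    a, b, c, d = int(a), int(b), int(c), int(d)
    N = a + b + c + d
    K = a + c  # set size
    n = a + b  # target size
    if N == 0:
        return 0.0
    lo = max(0, n - (N - K))
    hi = min(K, n)
    xs = np.arange(a, hi + 1) if not depletion else np.arange(lo, a + 1)
    if xs.size == 0:
        return -np.inf
    # hypergeometric log-pmf via log-gamma: log C(K,x) + log C(N-K,n-x) - log C(N,n)
    lg = gammaln
    logpmf = (
        lg(K + 1) - lg(xs + 1) - lg(K - xs + 1)
        + lg(N - K + 1) - lg(n - xs + 1) - lg(N - K - n + xs + 1)
        - (lg(N + 1) - lg(n + 1) - lg(N - n + 1))
    )
    logp = logsumexp(logpmf)
    return float(min(logp, 0.0) / np.log(10))


def fisher_one_tailed(a: int, b: int, c: int, d: int, depletion: bool = False) -> float:
    """One-tailed Fisher exact p-value, P(X >= a) under fixed margins."""
    return float(10.0 ** log10_fisher_one_tailed(a, b, c, d, depletion=depletion))


def fold_enrichment(a: int, n_target: int, K: int, N: int) -> tuple[float, float]:
    """Observed/expected enrichment of a set within a target.

    Returns ``(fold, expected)`` where ``fold = (a/n_target) / (K/N)`` and
    ``expected = n_target * K / N``.
    """
    _check_counts(a, n_target, K, N)
    if n_target == 0 or K == 0 or N == 0:
        raise ValueError("n_target, K and N must be positive")
    return (a / n_target) / (K / N), n_target * K / N


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance cut-off alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def display_threshold(threshold: float) -> float:
    """Round a cut-off to one significant digit for display (0.0019.. -> 0.002)."""
    if threshold <= 0:
        return threshold
    exp = int(np.floor(np.log10(threshold)))
    return float(round(threshold, -exp))


def _contingency(target: set, members: set, universe: set, depletion: bool = False) -> ContingencyResult:
    a = len(target & members)
    b = len(target - members)
    c = len(members - target)
    d = len(universe) - a - b - c
    log10p = log10_fisher_one_tailed(a, b, c, d, depletion=depletion)
    K, n, N = a + c, a + b, len(universe)
    if n and K and N:
        fold, expected = fold_enrichment(a, n, K, N)
    else:
        fold, expected = float("nan"), 0.0
    odds = (a * d) / (b * c) if b * c else float("inf") if a * d else float("nan")
    return ContingencyResult(
        a=a, b=b, c=c, d=d,
        p=float(10.0**log10p), log10_p=log10p,
        odds_ratio=odds, fold_enrichment=fold, expected=expected,
    )


def enrich_sets(
    target: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
    alpha: float = 0.05,
    correction: str = "bonferroni",
    depletion: bool = False,
) -> pd.DataFrame:
    """Test every set of *collection* for over-representation in *target*
    relative to *universe* (all genes represented on the array).

    Sets are intersected with the universe before testing; with
    ``correction="bonferroni"`` the significance threshold alpha/m over the
    m tested sets is reported alongside raw p-values.
    """
    target = set(target)
    universe = set(universe)
    offenders = sorted(target - universe)
    if offenders:
        raise ValueError(f"target genes outside the universe: {offenders[:10]}")
    rows = []
    m = len(collection.sets)
    threshold = bonferroni_threshold(alpha, m) if correction == "bonferroni" else alpha
    for name, members in collection.sets.items():
        res = _contingency(target, set(members) & universe, universe, depletion=depletion)
        rows.append(
            {
                "set": name,
                "top_level": name in collection.top_level,
                "a": res.a, "b": res.b, "c": res.c, "d": res.d,
                "expected": res.expected,
                "fold_enrichment": res.fold_enrichment,
                "odds_ratio": res.odds_ratio,
                "p": res.p,
                "log10_p": res.log10_p,
                "threshold": threshold,
                "significant": res.p < threshold,
            }
        )
    return pd.DataFrame(rows).sort_values("log10_p", kind="stable").reset_index(drop=True)


def overlap_analysis(
    gene_set_1: Iterable[str],
    gene_set_2: Iterable[str],
    universe: Iterable[str] | int,
    disjoint: bool = False,
) -> dict:
    """Overlap between two gene sets with both conditional shares and a
    one-tailed Fisher p.

    By default the first set is compared against the *whole* universe rate of
    membership in the second set (table ``|1∩2|, |1∖2|, |2|, N−|2|``) — the
    convention used when asking "is the in-set rate higher than the overall
    array rate".  With ``disjoint=True`` the classical partitioned table
    ``|1∩2|, |1∖2|, |2∖1|, N−|1∪2|`` is used instead.

    *universe* may be an iterable of ids or simply the universe size when the
    sets are given as counts elsewhere.
    """
    s1, s2 = set(gene_set_1), set(gene_set_2)
    if not s1 or not s2:
        raise ValueError("both gene sets must be non-empty")
    if isinstance(universe, int):
        N = universe
    else:
        uni = set(universe)
        missing = sorted((s1 | s2) - uni)
        if missing:
            raise ValueError(f"set members outside the universe: {missing[:10]}")
        N = len(uni)
    inter = len(s1 & s2)
    if disjoint:
        a, b = inter, len(s1) - inter
        c, d = len(s2) - inter, N - len(s1 | s2)
    else:
        a, b = inter, len(s1) - inter
        c, d = len(s2), N - len(s2)
    log10p = log10_fisher_one_tailed(a, b, c, d)
    return {
        "n_set1": len(s1),
        "n_set2": len(s2),
        "n_overlap": inter,
        "share_of_set1": inter / len(s1),
        "share_of_set2": inter / len(s2),
        "p": float(10.0**log10p),
        "log10_p": log10p,
        "table": (a, b, c, d),
    }
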