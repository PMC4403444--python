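"""Cross-depletion concordance analytics.

Pairwise Pearson correlation of log2-fold-change profiles with average-
linkage clustering on 1 - r, sign-quadrant classification of genes
responding to two perturbations with Fisher's exact test, hypergeometric
set-overlap tests, and a generic gene-set over-representation scan.

Fisher's two-sided p uses the minimum-likelihood rule — the sum of
hypergeometric probabilities (margins fixed) of all tables at most as
probable as the observed one — evaluated in exact rational arithmetic so
float round-off cannot flip tie comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom

__all__ = [
    "CorrelationMatrix",
    "QuadrantResult",
    "pearson_lfc_matrix",
    "cluster_correlations",
    "fisher_exact_2x2",
    "quadrant_overlap",
    "set_overlap_test",
    "gene_set_enrichment",
]


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson r of fold-change profiles with per-pair gene counts."""

    r: pd.DataFrame
    n_genes: pd.DataFrame

    @property
    def labels(self) -> list[str]:
        return list(self.r.index)


@dataclass
class QuadrantResult:
    """Sign-quadrant counts of genes responding in both comparisons."""

    up_up: int
    up_down: int
    down_up: int
    down_down: int
    odds_ratio: float  # nan when undefined (0/0)
    p_value: float
    threshold: float

    @property
    def counts(self) -> np.ndarray:
        return np.array([[self.up_up, self.up_down], [self.down_up, self.down_down]])


def pearson_lfc_matrix(profiles: dict[str, pd.Series]) -> CorrelationMatrix:
    """Pairwise Pearson r over genes present (and finite) in both profiles.

    A profile with zero variance yields missing r for its pairs.
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 profiles")
    labels = list(profiles)
    r = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    n = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for lab in labels:
        n.loc[lab, lab] = profiles[lab].dropna().size
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            joined = pd.concat([profiles[a], profiles[b]], axis=1, join="inner").dropna()
            if len(joined) < 3:
                raise ValueError(f"pair ({a}, {b}) shares < 3 genes")
            x, y = joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy()
            n.loc[a, b] = n.loc[b, a] = len(joined)
            if x.std() == 0 or y.std() == 0:
                r.loc[a, b] = r.loc[b, a] = np.nan
            else:
                r.loc[a, b] = r.loc[b, a] = float(np.corrcoef(x, y)[0, 1])
    return CorrelationMatrix(r=r, n_genes=n)


def cluster_correlations(corr: CorrelationMatrix):
    """Average-linkage agglomeration on distance 1 - r.

    Returns a scipy linkage matrix (rows: merged cluster ids, height, size);
    leaf order follows ``corr.labels``. Ties break deterministically by the
    condensed-distance ordering, i.e. label order.
    """
    d = 1.0 - corr.r.to_numpy()
    np.fill_diagonal(d, 0.0)
    condensed = squareform(np.clip(d, 0.0, None), checks=False)
    return linkage(condensed, method="average")


def _fisher_p_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Minimum-likelihood two-sided Fisher p in exact rational arithmetic."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    masses = {
        x: math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)
    }
    obs = masses[a]
    tail = sum(m for m in masses.values() if m <= obs)
    return Fraction(tail, denom)


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table: (odds ratio, two-sided p).

    p sums the fixed-margin hypergeometric probabilities of every table at
    most as probable as the observed one; ties are exact because the
    enumeration runs on integers. The odds ratio is ad/bc, with nan when
    0/0. An all-zero table (or any zero margin) gives p = 1.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("table cells must be non-negative integers")
    a, b, c, d = int(t[0, 0]), int(t[0, 1]), int(t[1, 0]), int(t[1, 1])
    if a + b + c + d == 0:
        return float("nan"), 1.0
    if b * c == 0:
        odds = float("nan") if a * d == 0 else float("inf")
    else:
        odds = (a * d) / (b * c)
    return odds, float(_fisher_p_exact(a, b, c, d))


def quadrant_overlap(
    lfc_a: pd.Series, lfc_b: pd.Series, threshold: float = 0.58
) -> QuadrantResult:
    """Classify genes exceeding |threshold| in BOTH comparisons by sign quadrant.

    The 2x2 of signs (rows: sign in a; columns: sign in b) is tested with
    Fisher's exact test; a concordant response pattern gives an odds ratio
    above 1. Genes must clear the threshold in both profiles to enter any
    quadrant.
    """
    joined = pd.concat([lfc_a, lfc_b], axis=1, join="inner").dropna()
    x, y = joined.iloc[:, 0], joined.iloc[:, 1]
    both = (x.abs() > threshold) & (y.abs() > threshold)
    x, y = x[both], y[both]
    uu = int(((x > 0) & (y > 0)).sum())
    ud = int(((x > 0) & (y < 0)).sum())
    du = int(((x < 0) & (y > 0)).sum())
    dd = int(((x < 0) & (y < 0)).sum())
    odds, p = fisher_exact_2x2(np.array([[uu, ud], [du, dd]]))
    return QuadrantResult(
        up_up=uu, up_down=ud, down_up=du, down_down=dd,
        odds_ratio=odds, p_value=p, threshold=threshold,
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def set_overlap_test(set_a, set_b, universe) -> tuple[int, float, float]:
    """Overlap of two gene sets against a hypergeometric null.

    Returns (overlap size, overlap as an integer percentage of |set_a|
    rounded half away from zero, upper-tail hypergeometric p of an overlap
    at least as large). ``fraction`` is nan for empty ``set_a``.
    """
    sa, sb, uni = set(set_a), set(set_b), set(universe)
    if not sa <= uni or not sb <= uni:
        raise ValueError("both sets must be subsets of the universe")
    k = len(sa & sb)
    frac = float("nan") if not sa else float(_round_half_away(100.0 * k / len(sa)))
    p = float(hypergeom.sf(k - 1, len(uni), len(sb), len(sa)))
    return k, frac, min(1.0, p)


def gene_set_enrichment(
    de_genes,
    annotation_sets: dict[str, set],
    universe,
    p_max: float = 0.1,
    min_count: int = 3,
) -> pd.DataFrame:
    """Hypergeometric over-representation of named gene sets in a DEG list.

    Retains sets with upper-tail p < ``p_max`` and overlap count >=
    ``min_count``, sorted by p. This is a plain hypergeometric test, not
    DAVID's jackknifed EASE variant.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("universe must be non-empty")
    de = set(de_genes) & uni
    rows = []
    for name, members in annotation_sets.items():
        members = set(members) & uni
        k = len(de & members)
        p = float(hypergeom.sf(k - 1, len(uni), len(members), len(de)))
        rows.append((name, len(members), k, min(1.0, p)))
    out = pd.DataFrame(rows, columns=["set", "set_size", "count", "p_value"])
    out = out[(out["p_value"] < p_max) & (out["count"] >= min_count)]
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)
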