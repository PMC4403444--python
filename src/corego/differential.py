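"""Differential-expression calling.

Two callers are provided:

* a single-replicate fold-change caller: log2(CPM+1) differences against the
  reference condition, DEG iff |log2FC| > 0.58 (1.5-fold);
* a replicated two-test caller: a negative-binomial exact test (conditioning
  on the pooled count after library equalization) and a log2-median-ratio
  statistic whose p-value comes from a pooled label-permutation null. The
  two p-values are combined with Stouffer's method after both are made
  one-sided in the direction of the observed median ratio, and calls
  additionally require the |log2-median ratio| to clear a permutation-derived
  effect cutoff (the mean of the magnitudes of the null's 2.5th and 97.5th
  percentiles).

The exact test's two-sided p sums the conditional probabilities of all group
totals whose mass does not exceed the observed total's (minimum-likelihood
rule); with dispersion 0 the conditional law is binomial.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import norm as normal

from .formats_io import CountMatrix, GeneAnnotation
from .normalization import NormalizedMatrix, log2_plus_one, tmm_cpm, tmm_factors

__all__ = [
    "PermutationNull",
    "expressed_genes",
    "log2fc_table",
    "call_degs_by_fc",
    "nb_exact_test",
    "estimate_common_dispersion",
    "equalize_libraries",
    "log2_median_ratio",
    "build_permutation_null",
    "empirical_p",
    "stouffer_combine",
    "permutation_ratio_cutoff",
    "call_degs_replicated",
    "differential_lincrnas",
    "run_fc_pipeline",
    "run_replicated_pipeline",
    "FC_THRESHOLD",
]

#: default DEG fold-change cutoff: log2 of a 1.5-fold change, to 2 decimals
FC_THRESHOLD = round(float(np.log2(1.5)), 2)


@dataclass
class PermutationNull:
    """Pooled permuted log2-median-ratio values across genes and relabelings."""

    statistics: np.ndarray
    n_partitions: int
    seed: int

    def __post_init__(self) -> None:
        self.statistics = np.asarray(self.statistics, dtype=float)
        if self.statistics.size == 0:
            raise ValueError("permutation null must be non-empty")

    def __len__(self) -> int:
        return self.statistics.size


def expressed_genes(
    norm: NormalizedMatrix, min_cpm: float = 1.0, conditions: list[str] | None = None
) -> pd.Series:
    """Flag genes whose mean CPM exceeds ``min_cpm`` in >= 1 condition.

    The comparison is strict (> min_cpm), so a gene at exactly the threshold
    everywhere is not expressed.
    """
    if norm.kind != "cpm":
        raise ValueError("expressed_genes expects CPM values")
    design = norm.design
    if conditions is None:
        conditions = list(dict.fromkeys(design["condition"]))
    flag = pd.Series(False, index=norm.gene_ids, name="expressed")
    for cond in conditions:
        samples = [
            s for s in norm.sample_ids if design.loc[s, "condition"] == cond
        ]
        if not samples:
            raise ValueError(f"condition {cond!r} has no samples")
        flag |= norm.values[samples].mean(axis=1) > min_cpm
    return flag


def log2fc_table(
    norm: NormalizedMatrix, reference: str, treatment: str
) -> pd.Series:
    """log2(CPM+1) difference, treatment minus reference (condition means)."""
    design = norm.design
    ref_s = [s for s in norm.sample_ids if design.loc[s, "condition"] == reference]
    trt_s = [s for s in norm.sample_ids if design.loc[s, "condition"] == treatment]
    if not ref_s or not trt_s:
        raise ValueError("reference/treatment condition has no samples")
    ref = log2_plus_one(norm.values[ref_s].mean(axis=1).to_numpy())
    trt = log2_plus_one(norm.values[trt_s].mean(axis=1).to_numpy())
    return pd.Series(trt - ref, index=norm.gene_ids, name="log2fc")


def call_degs_by_fc(
    lfc: pd.Series, expressed: pd.Series | None = None, threshold: float = FC_THRESHOLD
) -> pd.Series:
    """DEG direction per gene: up iff log2FC > threshold, down iff < -threshold.

    The comparison is strict, so a gene at exactly +-threshold is not called.
    Non-expressed genes are never called.
    """
    deg = pd.Series("none", index=lfc.index, name="deg")
    deg[lfc > threshold] = "up"
    deg[lfc < -threshold] = "down"
    if expressed is not None:
        deg[~expressed.reindex(lfc.index, fill_value=False)] = "none"
    return deg


def _conditional_logpmf(total: int, n_a: int, n_b: int, dispersion: float) -> np.ndarray:
    """Log conditional pmf of group-A total s = 0..total given the pooled total.

    For NB counts with equalized libraries the conditional law is negative
    hypergeometric with shapes r_a = n_a/phi, r_b = n_b/phi; for phi = 0 it is
    Binomial(total, n_a/(n_a+n_b)).
    """
    s = np.arange(total + 1, dtype=float)
    # grouped as h_a(s) + h_b(total-s) so that equal group sizes give a
    # bitwise-symmetric pmf (float addition is commutative)
    if dispersion == 0:
        logw = (s * np.log(n_a) - gammaln(s + 1.0)) + (
            (total - s) * np.log(n_b) - gammaln(total - s + 1.0)
        )
    else:
        r_a = n_a / dispersion
        r_b = n_b / dispersion
        logw = (gammaln(s + r_a) - gammaln(s + 1.0)) + (
            gammaln(total - s + r_b) - gammaln(total - s + 1.0)
        )
    return logw - logsumexp(logw)


def nb_exact_test(
    counts_a: np.ndarray, counts_b: np.ndarray, dispersion: float
) -> float:
    """Two-sided exact-test p for equal group means, conditioning on the sum.

    ``counts_a``/``counts_b`` are replicate count vectors on equalized
    libraries. All group-A totals whose conditional probability does not
    exceed the observed one's contribute to p (a 1+1e-12 relative gate
    absorbs float round-off of exact ties).
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("counts must be non-negative")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    s_obs = int(round(a.sum()))
    total = s_obs + int(round(b.sum()))
    if total == 0:
        return 1.0
    logp = _conditional_logpmf(total, len(a), len(b), dispersion)
    p_all = np.exp(logp)
    p_obs = p_all[s_obs]
    return float(min(1.0, p_all[p_all <= p_obs * (1.0 + 1e-12)].sum()))


def equalize_libraries(
    counts: pd.DataFrame, effective_libs: pd.Series
) -> pd.DataFrame:
    """Scale counts to the geometric mean of the effective library sizes.

    Scaled values are rounded to the nearest integer so the conditional
    (exact-test) argument applies to exchangeable libraries.
    """
    eff = effective_libs.reindex(counts.columns).to_numpy(dtype=float)
    target = float(np.exp(np.mean(np.log(eff))))
    scaled = counts.to_numpy(dtype=float) * (target / eff)
    return pd.DataFrame(
        np.rint(scaled).astype(np.int64), index=counts.index, columns=counts.columns
    )


def estimate_common_dispersion(
    counts: CountMatrix, max_dispersion: float = 4.0
) -> float:
    """Single NB dispersion maximizing the conditional likelihood over genes.

    Uses every condition with >= 2 replicates; counts are library-equalized
    first. The conditional log-likelihood of a gene's replicate vector given
    its condition total depends only on phi, which a bounded 1-D search
    maximizes. Returns 0 at the lower boundary.
    """
    from scipy.optimize import minimize_scalar

    design = counts.design
    groups = []
    for cond in counts.conditions:
        samples = counts.condition_samples(cond)
        if len(samples) >= 2:
            eff = counts.library_sizes[samples].astype(float) * tmm_factors(
                CountMatrix(counts.counts[samples], design.loc[samples])
            )
            eq = equalize_libraries(counts.counts[samples], eff)
            groups.append(eq.to_numpy(dtype=float))
    if not groups:
        raise ValueError(
            "no condition has >= 2 replicates; use the fold-change caller"
        )

    def neg_loglik(phi: float) -> float:
        r = 1.0 / phi
        ll = 0.0
        for y in groups:
            n = y.shape[1]
            t = y.sum(axis=1)
            ll += float(
                np.sum(gammaln(y + r)) - y.size * gammaln(r)
                - np.sum(gammaln(t + n * r)) + t.size * gammaln(n * r)
            )
        return -ll

    res = minimize_scalar(
        neg_loglik, bounds=(1e-6, max_dispersion), method="bounded",
        options={"xatol": 1e-6},
    )
    phi = float(res.x)
    if phi <= 5e-6 or neg_loglik(phi) >= neg_loglik(1e-6):
        return 0.0
    return phi


def log2_median_ratio(
    values_a: np.ndarray, values_b: np.ndarray, pseudocount: float = 1.0
) -> float:
    """log2((median(a)+c)/(median(b)+c)) on CPM vectors; c guards zeros."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("vectors must be non-empty")
    return float(
        np.log2((np.median(a) + pseudocount) / (np.median(b) + pseudocount))
    )


def _lmr_per_gene(
    values: np.ndarray, idx_a: list[int], idx_b: list[int], pseudocount: float = 1.0
) -> np.ndarray:
    med_a = np.median(values[:, idx_a], axis=1)
    med_b = np.median(values[:, idx_b], axis=1)
    return np.log2((med_a + pseudocount) / (med_b + pseudocount))


def _informative_partitions(
    samples: list[str], group_a: list[str], group_b: list[str]
) -> list[tuple[list[int], list[int]]]:
    """Distinct relabelings into groups of the original sizes.

    Excludes the identity partition (and, for equal group sizes, its mirror
    and each partition's unordered duplicate). For a 2v2 design this yields
    the 2 informative partitions of the 3 distinct ones.
    """
    n_a = len(group_a)
    pos = {s: i for i, s in enumerate(samples)}
    observed = frozenset(pos[s] for s in group_a)
    all_idx = frozenset(range(len(samples)))
    parts = []
    seen = set()
    for combo in itertools.combinations(range(len(samples)), n_a):
        g1 = frozenset(combo)
        g2 = all_idx - g1
        if len(g2) == n_a:  # unordered when sizes match
            key = frozenset((g1, g2))
            if key in seen:
                continue
            seen.add(key)
            if g1 == observed or g2 == observed:
                continue
        else:
            if g1 == observed:
                continue
        parts.append((sorted(g1), sorted(g2)))
    return parts


def build_permutation_null(
    norm: NormalizedMatrix,
    reference: str,
    treatment: str,
    seed: int = 0,
    genes: pd.Index | None = None,
    max_partitions: int | None = None,
    pseudocount: float = 1.0,
) -> PermutationNull:
    """Pooled log2-median-ratio null from sample-label permutations.

    Every informative relabeling of the reference+treatment samples into two
    groups of the original sizes contributes one statistic per gene; all
    values are pooled. ``seed`` only matters when ``max_partitions``
    subsamples the relabelings of a large design.
    """
    design = norm.design
    ref_s = [s for s in norm.sample_ids if design.loc[s, "condition"] == reference]
    trt_s = [s for s in norm.sample_ids if design.loc[s, "condition"] == treatment]
    if len(ref_s) < 2 or len(trt_s) < 2:
        raise ValueError("permutation null needs >= 2 samples per group")
    samples = trt_s + ref_s
    parts = _informative_partitions(samples, trt_s, ref_s)
    if max_partitions is not None and len(parts) > max_partitions:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(parts), size=max_partitions, replace=False)
        parts = [parts[i] for i in sorted(keep)]
    values = norm.values[samples]
    if genes is not None:
        values = values.loc[genes]
    arr = values.to_numpy(dtype=float)
    pooled = np.concatenate(
        [_lmr_per_gene(arr, list(a), list(b), pseudocount) for a, b in parts]
    )
    return PermutationNull(statistics=pooled, n_partitions=len(parts), seed=seed)


def empirical_p(statistic, null: PermutationNull) -> np.ndarray | float:
    """Two-sided add-one empirical p: (1 + #{|null| >= |stat|}) / (1 + #null)."""
    abs_null = np.sort(np.abs(null.statistics))
    stats = np.atleast_1d(np.asarray(statistic, dtype=float))
    n_ge = abs_null.size - np.searchsorted(abs_null, np.abs(stats), side="left")
    p = (1.0 + n_ge) / (1.0 + abs_null.size)
    return float(p[0]) if np.isscalar(statistic) or np.ndim(statistic) == 0 else p


def stouffer_combine(p_values, weights=None) -> float:
    """Stouffer's combined p: Z = sum(w z) / sqrt(sum w^2), z = Phi^-1(1-p).

    p-values at exactly 0 or 1 are clamped into the open unit interval with a
    warning. The result is the upper-tail probability of Z; callers decide
    sidedness of the inputs.
    """
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if ((p == 0) | (p == 1)).any():
        warnings.warn("p-values at 0/1 clamped into the open interval", stacklevel=2)
        tiny = np.finfo(float).tiny
        p = np.clip(p, tiny, 1.0 - 1e-16)
    w = np.ones_like(p) if weights is None else np.asarray(weights, dtype=float)
    z = normal.isf(p)
    big_z = float(np.sum(w * z) / np.sqrt(np.sum(w**2)))
    return float(normal.sf(big_z))


def permutation_ratio_cutoff(
    null: PermutationNull, lo: float = 2.5, hi: float = 97.5
) -> float:
    """Effect cutoff = mean of the magnitudes of the null's lo/hi percentiles.

    Percentiles use linear interpolation. For a symmetric null this equals
    the magnitude of either tail percentile; taking magnitudes rather than
    the raw signed mean keeps the cutoff a positive effect-size bound.
    """
    q_lo = np.percentile(null.statistics, lo)
    q_hi = np.percentile(null.statistics, hi)
    return float((abs(q_lo) + abs(q_hi)) / 2.0)


def call_degs_replicated(
    table: pd.DataFrame, alpha: float = 0.05, cutoff: float = 0.0
) -> pd.Series:
    """DEG call: p_combined < alpha AND |lmr| >= cutoff; direction = sign(lmr)."""
    deg = pd.Series("none", index=table.index, name="deg")
    hit = (table["p_combined"] < alpha) & (table["lmr"].abs() >= cutoff)
    if "expressed" in table:
        hit &= table["expressed"].astype(bool)
    deg[hit & (table["lmr"] > 0)] = "up"
    deg[hit & (table["lmr"] < 0)] = "down"
    return deg


def differential_lincrnas(
    table: pd.DataFrame,
    annotation: GeneAnnotation,
    threshold: float = FC_THRESHOLD,
) -> pd.DataFrame:
    """Restrict the fold-change caller's output to the lincRNA universe.

    ``table`` must carry ``log2fc`` (and optionally ``expressed``); the
    returned subset is re-called at ``threshold``.
    """
    linc_ids = annotation.lincrna_ids()
    if len(linc_ids) == 0:
        warnings.warn("empty lincRNA universe", stacklevel=2)
    keep = table.index.intersection(linc_ids)
    sub = table.loc[keep].copy()
    sub["deg"] = call_degs_by_fc(
        sub["log2fc"], sub.get("expressed"), threshold=threshold
    )
    return sub


def run_fc_pipeline(
    counts: CountMatrix,
    reference: str,
    treatment: str,
    threshold: float = FC_THRESHOLD,
    min_cpm: float = 1.0,
) -> pd.DataFrame:
    """Single-replicate caller: TMM -> CPM -> expressed filter -> |log2FC| rule."""
    norm = tmm_cpm(counts)
    expressed = expressed_genes(norm, min_cpm=min_cpm)
    lfc = log2fc_table(norm, reference, treatment)
    table = pd.DataFrame({"expressed": expressed, "log2fc": lfc})
    table["deg"] = call_degs_by_fc(lfc, expressed, threshold=threshold)
    return table


def run_replicated_pipeline(
    counts: CountMatrix,
    reference: str,
    treatment: str,
    alpha: float = 0.05,
    cutoff: float | None = None,
    min_cpm: float = 1.0,
    dispersion: float | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicated two-test caller with Stouffer combination and effect cutoff.

    Steps: TMM/CPM; expressed filter; NB exact test on library-equalized
    counts with a common estimated dispersion; log2-median-ratio statistic
    with a pooled permutation null; both p-values made one-sided in the
    direction of the observed median ratio, Stouffer-combined, and reported
    two-sided; calls require p_combined < alpha and |lmr| >= cutoff
    (``cutoff=None`` derives it from the permutation null's 2.5/97.5
    percentiles).
    """
    norm = tmm_cpm(counts)
    expressed = expressed_genes(norm, min_cpm=min_cpm)
    design = counts.design
    ref_s = counts.condition_samples(reference)
    trt_s = counts.condition_samples(treatment)
    if not ref_s or not trt_s:
        raise ValueError("reference/treatment condition has no samples")

    sub = counts.counts[trt_s + ref_s]
    eff = norm.effective_library[trt_s + ref_s]
    eq = equalize_libraries(sub, eff)
    if dispersion is None:
        dispersion = estimate_common_dispersion(
            CountMatrix(sub, design.loc[trt_s + ref_s])
        )

    expr_idx = expressed[expressed].index
    eq_trt = eq.loc[expr_idx, trt_s].to_numpy()
    eq_ref = eq.loc[expr_idx, ref_s].to_numpy()
    p_exact = np.array(
        [
            nb_exact_test(eq_trt[i], eq_ref[i], dispersion)
            for i in range(len(expr_idx))
        ]
    )
    exact_sign = np.sign(
        eq_trt.mean(axis=1) - eq_ref.mean(axis=1)
    )

    cpm_vals = norm.values.loc[expr_idx]
    lmr = _lmr_per_gene(
        cpm_vals[trt_s + ref_s].to_numpy(),
        list(range(len(trt_s))),
        list(range(len(trt_s), len(trt_s) + len(ref_s))),
    )
    null = build_permutation_null(
        norm, reference, treatment, seed=seed, genes=expr_idx
    )
    p_lmr = empirical_p(lmr, null)

    # one-sided conversion in the direction of the observed median ratio
    direction = np.sign(lmr)
    direction = np.where(direction == 0, exact_sign, direction)
    p_lmr_1s = np.clip(p_lmr / 2.0, np.finfo(float).tiny, 1 - 1e-16)
    agree = (exact_sign == direction) | (direction == 0)
    p_exact_1s = np.where(agree, p_exact / 2.0, 1.0 - p_exact / 2.0)
    p_exact_1s = np.clip(p_exact_1s, np.finfo(float).tiny, 1 - 1e-16)

    z_exact = normal.isf(p_exact_1s)
    z_lmr = normal.isf(p_lmr_1s)
    # The exact test and the median-ratio test measure the same group
    # difference on the same counts, so their scores are strongly dependent;
    # an equal-weight 1/sqrt(2) denominator would roughly double the false-
    # positive rate. The Stouffer denominator therefore carries the empirical
    # correlation of the signed scores across genes (Hartung-style):
    # Var(z1 + z2) = 2 + 2*rho, exactly 2 only for independent tests.
    signed_e = np.where(direction == 0, z_exact, direction * z_exact)
    signed_l = np.where(direction == 0, z_lmr, direction * z_lmr)
    if len(signed_e) >= 10 and signed_e.std() > 0 and signed_l.std() > 0:
        rho = float(np.clip(np.corrcoef(signed_e, signed_l)[0, 1], 0.0, 1.0))
    else:
        rho = 0.0
    big_z = (z_exact + z_lmr) / np.sqrt(2.0 + 2.0 * rho)
    p_combined = np.clip(2.0 * normal.sf(np.abs(big_z)), 0.0, 1.0)

    table = pd.DataFrame(
        {
            "expressed": expressed,
            "lmr": pd.Series(lmr, index=expr_idx),
            "p_exact": pd.Series(p_exact, index=expr_idx),
            "p_lmr": pd.Series(p_lmr, index=expr_idx),
            "z_exact": pd.Series(z_exact, index=expr_idx),
            "z_lmr": pd.Series(z_lmr, index=expr_idx),
            "p_combined": pd.Series(p_combined, index=expr_idx),
        },
        index=counts.gene_ids,
    )
    if cutoff is None:
        cutoff = permutation_ratio_cutoff(null)
    table.attrs["cutoff"] = cutoff
    table.attrs["dispersion"] = dispersion
    table.attrs["z_correlation"] = rho
    table["deg"] = call_degs_replicated(table.fillna({"p_combined": 1.0, "lmr": 0.0}),
                                        alpha=alpha, cutoff=cutoff)
    return table
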