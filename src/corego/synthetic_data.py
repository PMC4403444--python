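"""Synthetic expression and ChIP data with recorded ground truth.

The expression generator plants differentially expressed genes (DEGs) with
known log2 effects into negative-binomial counts (var = mu + phi * mu^2,
edgeR-style; phi = 0 degenerates to Poisson). Two depletion conditions can
share a controllable fraction of sign-concordant DEGs, which gives the
downstream concordance statistics a tunable true odds ratio. The ChIP
generator plants bound promoters with a controllable IP/control fold
enrichment and a controllable binding correlation between an anchor factor
and co-factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats_io import CountMatrix, GeneAnnotation, ReadIntervalSet

__all__ = [
    "ExpressionSimSpec",
    "ChipSimSpec",
    "simulate_expression",
    "simulate_chip",
    "simulate_annotation",
]


@dataclass
class ExpressionSimSpec:
    """Parameters of the expression simulation.

    conditions: ordered (label, n_replicates) pairs; the first label is the
    reference and never receives planted effects.
    baseline_meanlog/sdlog: natural-log parameters of the log-normal baseline
    mean expression; defaults give a median of ~200 counts, a realistic
    profile for genes surviving a CPM > 1 expressed filter.
    dispersion: NB phi in var = mu + phi mu^2.
    deg_fraction: fraction of genes planted as DEGs in each non-reference
    condition.
    effect_size/effect_sd: |log2FC| of planted DEGs ~ effect_size +
    effect_sd * |N(0,1)|; sign up/down with equal probability.
    shared_fraction: probability that a DEG of the first non-reference
    condition is planted, sign-concordant, in the second as well; the
    remainder of the second condition's quota is filled uniformly at random,
    so 0 means independent DEG sets and 1 means a superset relationship.
    """

    n_genes: int = 2000
    lincrna_fraction: float = 0.05
    conditions: tuple = (("WT", 1), ("KO_A", 1), ("KO_B", 1))
    baseline_meanlog: float = float(np.log(200.0))
    baseline_sdlog: float = 1.0
    baseline_min: float = 0.0
    dispersion: float = 0.1
    deg_fraction: float = 0.25
    effect_size: float = 1.5
    effect_sd: float = 0.0
    shared_fraction: float = 0.0
    library_size: int = 0  # 0 -> each sample's library emerges from the draws
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("at least one condition required")
        for frac in (self.lincrna_fraction, self.deg_fraction, self.shared_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB(mu, phi) with var = mu + phi mu^2; phi=0 -> Poisson."""
    mean = np.asarray(mean, dtype=float)
    if phi == 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_expression(spec: ExpressionSimSpec) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate a count matrix and its ground-truth table.

    Returns the CountMatrix and a truth DataFrame indexed by gene id with,
    per non-reference condition C, columns ``is_deg_C`` and ``lfc_C``, plus
    ``is_lincRNA`` and ``baseline_mean``. Identical seeds give bit-identical
    output.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    gene_ids = pd.Index([f"g{i:05d}" for i in range(n)], name="gene_id")

    baseline = np.exp(rng.normal(spec.baseline_meanlog, spec.baseline_sdlog, size=n))
    if spec.baseline_min > 0:
        baseline = np.maximum(baseline, spec.baseline_min)

    n_linc = int(round(spec.lincrna_fraction * n))
    linc_idx = rng.choice(n, size=n_linc, replace=False)
    is_linc = np.zeros(n, dtype=bool)
    is_linc[linc_idx] = True

    labels = [c for c, _ in spec.conditions]
    ref = labels[0]
    treat_labels = labels[1:]
    n_deg = int(round(spec.deg_fraction * n))

    lfc = {c: np.zeros(n) for c in treat_labels}
    is_deg = {c: np.zeros(n, dtype=bool) for c in treat_labels}

    def draw_magnitudes(k):
        return spec.effect_size + spec.effect_sd * np.abs(rng.standard_normal(k))

    if treat_labels and n_deg > 0:
        first = treat_labels[0]
        deg_a = rng.choice(n, size=n_deg, replace=False)
        signs_a = rng.choice([-1.0, 1.0], size=n_deg)
        is_deg[first][deg_a] = True
        lfc[first][deg_a] = signs_a * draw_magnitudes(n_deg)

        for cond in treat_labels[1:]:
            shared_mask = rng.random(n_deg) < spec.shared_fraction
            shared = deg_a[shared_mask]
            is_deg[cond][shared] = True
            # sign-concordant with the first condition, magnitude redrawn
            lfc[cond][shared] = np.sign(lfc[first][shared]) * draw_magnitudes(
                len(shared)
            )
            remaining = n_deg - len(shared)
            pool = np.setdiff1d(np.arange(n), shared)
            extra = rng.choice(pool, size=remaining, replace=False)
            is_deg[cond][extra] = True
            lfc[cond][extra] = rng.choice([-1.0, 1.0], size=remaining) * draw_magnitudes(
                remaining
            )

    sample_cols = {}
    design_rows = []
    for cond, n_rep in spec.conditions:
        cond_lfc = lfc.get(cond, np.zeros(n))
        mu = baseline * np.power(2.0, cond_lfc)
        if spec.library_size > 0:
            mu = mu * (spec.library_size / mu.sum())
        for rep in range(1, n_rep + 1):
            sid = f"{cond}_{rep}"
            sample_cols[sid] = _nb_draw(rng, mu, spec.dispersion).astype(np.int64)
            design_rows.append((sid, cond, rep))

    counts = pd.DataFrame(sample_cols, index=gene_ids)
    design = pd.DataFrame(
        design_rows, columns=["sample_id", "condition", "replicate"]
    ).set_index("sample_id")

    truth = pd.DataFrame(index=gene_ids)
    truth["baseline_mean"] = baseline
    truth["is_lincRNA"] = is_linc
    for cond in treat_labels:
        truth[f"is_deg_{cond}"] = is_deg[cond]
        truth[f"lfc_{cond}"] = lfc[cond]

    return CountMatrix(counts=counts, design=design), truth


def simulate_annotation(
    n_genes: int,
    lincrna_fraction: float = 0.05,
    seed: int = 0,
    chrom: str = "chr1",
    spacing: int = 10_000,
) -> GeneAnnotation:
    """A synthetic gene annotation: evenly spaced TSSs, random strands.

    Gene ids match :func:`simulate_expression` (``g00000`` ...), so the same
    spec size can drive both the expression and ChIP arms of a simulation.
    """
    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    n_linc = int(round(lincrna_fraction * n_genes))
    linc = set(rng.choice(n_genes, size=n_linc, replace=False).tolist())
    strands = rng.choice(["+", "-"], size=n_genes)
    table = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": chrom,
            "strand": strands,
            "tss": 5_000 + spacing * np.arange(n_genes, dtype=np.int64),
            "biotype": [
                "lincRNA" if i in linc else "protein_coding" for i in range(n_genes)
            ],
        }
    ).set_index("gene_id")
    return GeneAnnotation(table=table)


@dataclass
class ChipSimSpec:
    """Parameters of the promoter ChIP simulation.

    background: expected control read count per promoter.
    enrichment_fold: multiplier on the IP rate at truly bound promoters.
    cofactor_rho: per co-factor probability that a gene's bound status copies
    the anchor's; otherwise it is an independent Bernoulli(bound_fraction)
    draw. rho=1 duplicates the anchor's bound set, rho=0 is independent.
    ip_depth / ctrl_depth: relative sequencing-depth multipliers on the IP
    and control read rates (library sizes then emerge from the draws).
    """

    bound_fraction: float = 0.2
    enrichment_fold: float = 8.0
    background: float = 20.0
    cofactor_rho: dict = field(default_factory=dict)  # name -> rho
    ip_depth: float = 1.0
    ctrl_depth: float = 1.0
    read_length: int = 50
    promoter_up: int = 2500
    promoter_down: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.bound_fraction <= 1.0:
            raise ValueError("bound_fraction must lie in [0, 1]")
        if self.enrichment_fold < 1.0:
            raise ValueError("enrichment_fold must be >= 1")
        for name, rho in self.cofactor_rho.items():
            if not 0.0 <= rho <= 1.0:
                raise ValueError(f"cofactor rho for {name!r} must lie in [0, 1]")


def _place_reads(
    rng: np.random.Generator,
    windows: pd.DataFrame,
    counts: np.ndarray,
    read_length: int,
    tag: str,
) -> ReadIntervalSet:
    """Place ``counts[i]`` reads uniformly within window i; BED-like records."""
    total = int(counts.sum())
    starts = np.empty(total, dtype=np.int64)
    chroms = np.empty(total, dtype=object)
    pos = 0
    for (wstart, wend, chrom), k in zip(
        windows[["start", "end", "chrom"]].itertuples(index=False), counts
    ):
        if k == 0:
            continue
        hi = max(wstart + 1, wend - read_length)
        starts[pos : pos + k] = rng.integers(wstart, hi, size=k)
        chroms[pos : pos + k] = chrom
        pos += k
    reads = pd.DataFrame(
        {
            "chrom": chroms,
            "start": starts,
            "end": starts + read_length,
            "name": [f"{tag}_r{i}" for i in range(total)],
            "strand": rng.choice(["+", "-"], size=total),
            "mapq": np.full(total, 30, dtype=np.int64),
            "unique": True,
        }
    )
    return ReadIntervalSet(reads=reads, library_size=total)


def simulate_chip(
    spec: ChipSimSpec, annotation: GeneAnnotation
) -> tuple[dict[str, ReadIntervalSet], dict[str, ReadIntervalSet], pd.DataFrame]:
    """Simulate promoter-localized ChIP reads for an anchor plus co-factors.

    Per promoter, IP read counts are Poisson(background * ip_depth * fold) at
    bound genes and Poisson(background * ip_depth) elsewhere; each factor
    gets its own control sample, Poisson(background * ctrl_depth) — factors
    measured in different experiments do not share control noise, and a
    shared control would leak spurious correlation into the binned co-binding
    profile. Reads are placed uniformly within the promoter window (clipped
    at position 0). Returns ({factor -> IP ReadIntervalSet},
    {factor -> control ReadIntervalSet}, truth table with per-factor
    ``bound_<name>`` columns). The anchor factor is named ``anchor``.
    """
    from .chip_enrichment import promoter_windows

    rng = np.random.default_rng(spec.seed)
    windows = promoter_windows(
        annotation, up=spec.promoter_up, down=spec.promoter_down
    )
    n = len(windows)

    bound_anchor = rng.random(n) < spec.bound_fraction
    bound = {"anchor": bound_anchor}
    for name, rho in spec.cofactor_rho.items():
        copy = rng.random(n) < rho
        indep = rng.random(n) < spec.bound_fraction
        bound[name] = np.where(copy, bound_anchor, indep)

    ip_sets = {}
    controls = {}
    for name, flags in bound.items():
        rate = spec.background * spec.ip_depth * np.where(
            flags, spec.enrichment_fold, 1.0
        )
        counts = rng.poisson(rate)
        ip_sets[name] = _place_reads(rng, windows, counts, spec.read_length, name)
        ctrl_counts = rng.poisson(np.full(n, spec.background * spec.ctrl_depth))
        controls[name] = _place_reads(
            rng, windows, ctrl_counts, spec.read_length, f"{name}_ctrl"
        )

    truth = pd.DataFrame(index=windows.index)
    for name, flags in bound.items():
        truth[f"bound_{name}"] = flags
    return ip_sets, controls, truth
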