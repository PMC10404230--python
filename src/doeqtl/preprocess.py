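"""Expression QC and normalization ahead of eQTL mapping.

Covers the path from transcript-level counts to the residualized,
log-scale expression matrix the genome scans consume: transcript-to-gene
summation, TMM between-sample normalization, the voom-style logCPM
transform (without precision weights — the downstream scan is a
homoscedastic Gaussian model), sex-chromosome aneuploidy flagging,
choroid-plexus contamination scoring and residualization, and
haplotype-probability-based sample-mixup resolution via optimal
assignment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .synthetic import FounderProbs

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Counts -> normalized log expression
# ---------------------------------------------------------------------------

def sum_transcripts_to_genes(
    transcript_counts: pd.DataFrame, tx2gene: pd.DataFrame
) -> pd.DataFrame:
    """Sum transcript-level expected counts to gene level.

    ``transcript_counts`` is samples × transcripts; ``tx2gene`` has
    columns ``transcript_id, gene_id`` mapping each transcript to at most
    one gene.  Transcripts without a mapping are dropped (count logged).
    """
    if transcript_counts.columns.duplicated().any():
        raise ValueError("duplicate transcript columns in count matrix")
    if tx2gene["transcript_id"].duplicated().any():
        dups = tx2gene.loc[tx2gene["transcript_id"].duplicated(), "transcript_id"]
        raise ValueError(f"transcripts mapped more than once: {sorted(set(dups))[:5]}")
    mapping = dict(zip(tx2gene["transcript_id"], tx2gene["gene_id"]))
    mapped = [t for t in transcript_counts.columns if t in mapping]
    dropped = transcript_counts.shape[1] - len(mapped)
    if dropped:
        logger.info("dropping %d unmapped transcripts", dropped)
    sub = transcript_counts[mapped]
    return sub.T.groupby([mapping[t] for t in mapped]).sum().T


def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    a_cutoff: float = -1e10,
) -> pd.DataFrame:
    """Trimmed mean of M-values (TMM) normalization factors.

    Implements the published TMM algorithm: the reference sample is the
    one whose 75th-percentile count fraction is closest to the mean across
    samples; each sample's factor is ``2**(weighted trimmed mean)`` of the
    gene-wise log2 expression ratios M against the reference, restricted
    to genes positive in both libraries, after trimming the most extreme
    ``trim_m`` of M-values and ``trim_a`` of average log intensities A,
    with inverse approximate-binomial-variance weights.  Factors are
    rescaled to geometric mean 1.

    Returns a DataFrame indexed by sample with columns ``factor`` and
    ``effective_lib_size``.
    """
    if counts.shape[0] < 2:
        raise ValueError("TMM needs at least two samples")
    X = counts.to_numpy(dtype=float)
    lib = X.sum(axis=1)
    if np.any(lib <= 0):
        raise ValueError("sample with zero library size")
    # reference: upper-quartile count fraction closest to the mean
    f75 = np.quantile(X / lib[:, None], 0.75, axis=1)
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    r, nr = X[ref], lib[ref]
    factors = np.ones(len(X))
    for i in range(len(X)):
        if i == ref:
            factors[i] = 1.0
            continue
        factors[i] = _tmm_pair(X[i], lib[i], r, nr, trim_m, trim_a, a_cutoff)
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.DataFrame(
        {"factor": factors, "effective_lib_size": lib * factors},
        index=counts.index,
    )


def _tmm_pair(
    x: np.ndarray, n: float, r: np.ndarray, nr: float,
    trim_m: float, trim_a: float, a_cutoff: float,
) -> float:
    keep = (x > 0) & (r > 0)
    x, r = x[keep], r[keep]
    m = np.log2((x / n) / (r / nr))
    a = 0.5 * np.log2((x / n) * (r / nr))
    w = (n - x) / (n * x) + (nr - r) / (nr * r)
    ok = np.isfinite(m) & np.isfinite(a) & (a > a_cutoff)
    m, a, w = m[ok], a[ok], w[ok]
    if m.size == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0
    # double trim by rank, as in the reference implementation
    ng = m.size
    lo_m = np.floor(ng * trim_m) + 1
    hi_m = ng + 1 - lo_m
    lo_a = np.floor(ng * trim_a) + 1
    hi_a = ng + 1 - lo_a
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    kept = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not kept.any():
        return 1.0
    f = np.sum(m[kept] / w[kept]) / np.sum(1.0 / w[kept])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def log_cpm(
    counts: pd.DataFrame,
    factors: pd.DataFrame | None = None,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """The voom logCPM transform (without precision weights).

    ``log2((count + prior) / (libsize * factor + 1) * 1e6)``, per sample.
    """
    X = counts.to_numpy(dtype=float)
    lib = X.sum(axis=1)
    f = np.ones(len(X)) if factors is None else factors["factor"].to_numpy()
    eff = lib * f + 1.0
    out = np.log2((X + prior_count) / eff[:, None] * 1e6)
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


# ---------------------------------------------------------------------------
# Sample QC
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Per-sample QC flags and scores; every sample appears exactly once."""

    table: pd.DataFrame  # sample_id, flag, x_score, y_score, x_z

    @property
    def flagged(self) -> list[str]:
        bad = self.table["flag"] != "ok"
        return list(self.table.loc[bad, "sample_id"])


def _robust_z(scores: np.ndarray) -> np.ndarray:
    med = np.median(scores)
    mad = np.median(np.abs(scores - med))
    if mad == 0:
        return np.zeros_like(scores)
    return (scores - med) / (1.4826 * mad)


def detect_sex_anomalies(
    expr: pd.DataFrame,
    covariates: pd.DataFrame,
    x_gene_ids: list[str],
    y_gene_ids: list[str],
    mad_k: float = 4.0,
) -> QCReport:
    """Flag sex-chromosome aneuploidies from X/Y gene expression.

    X-score and Y-score are per-sample means over the given gene sets.
    Within each annotated sex, a robust z (median/MAD) of the X-score
    flags ``X0-like`` females (X-z below ``-mad_k``) and ``XXY-like``
    males (X-z above ``+mad_k`` with a Y-score above the female Y
    median, confirming a retained Y).
    """
    if not x_gene_ids or not y_gene_ids:
        raise ValueError("X and Y gene sets must be non-empty")
    cov = covariates.set_index("sample_id").loc[expr.index]
    x_score = expr[x_gene_ids].mean(axis=1).to_numpy()
    y_score = expr[y_gene_ids].mean(axis=1).to_numpy()
    sex = cov["sex"].to_numpy()
    x_z = np.zeros(len(expr))
    for s in ("F", "M"):
        mask = sex == s
        if mask.any():
            x_z[mask] = _robust_z(x_score[mask])
    female_y_median = np.median(y_score[sex == "F"]) if (sex == "F").any() else -np.inf
    flags = np.array(["ok"] * len(expr), dtype=object)
    flags[(sex == "F") & (x_z < -mad_k)] = "X0-like"
    flags[(sex == "M") & (x_z > mad_k) & (y_score > female_y_median)] = "XXY-like"
    return QCReport(
        pd.DataFrame(
            {
                "sample_id": expr.index,
                "flag": flags,
                "x_score": x_score,
                "y_score": y_score,
                "x_z": x_z,
            }
        ).reset_index(drop=True)
    )


def contamination_scores(
    expr: pd.DataFrame, marker_gene_ids: tuple[str, ...]
) -> pd.Series:
    """Per-sample contamination score: mean of the (log-scale) marker genes.

    The markers are the analogs of klotho (Kl) and transthyretin (Ttr),
    unambiguous choroid-plexus markers in striatal tissue.
    """
    missing = [g for g in marker_gene_ids if g not in expr.columns]
    if missing:
        raise KeyError(f"marker genes absent from expression matrix: {missing}")
    return expr[list(marker_gene_ids)].mean(axis=1).rename("contamination_score")


def residualize(expr: pd.DataFrame, covariate: pd.Series | np.ndarray) -> pd.DataFrame:
    """Residualize every gene on intercept + one covariate (OLS).

    Used to remediate choroid-plexus contamination before mapping: the
    returned matrix is, per gene, the residual of expression regressed on
    the contamination score, hence orthogonal to it.
    """
    c = np.asarray(covariate, dtype=float)
    if len(c) != len(expr):
        raise ValueError("covariate length does not match sample count")
    X = np.column_stack([np.ones(len(c)), c])
    Y = expr.to_numpy()
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return pd.DataFrame(resid, index=expr.index, columns=expr.columns)


# ---------------------------------------------------------------------------
# Sample mixup resolution
# ---------------------------------------------------------------------------

def correlate_haplotype_probs(
    probs_a: FounderProbs, probs_b: FounderProbs
) -> pd.DataFrame:
    """Cross-correlate two haplotype-probability sets sample by sample.

    Entry (a, b) is the Pearson correlation of sample a's flattened
    8 × M probability vector in set A with sample b's in set B, over the
    common marker grid.  A zero-variance (uniform-simplex) sample yields
    NaN with a warning.
    """
    common = [
        m for m in probs_a.markers["marker_id"] if m in set(probs_b.markers["marker_id"])
    ]
    if not common:
        raise ValueError("no common markers between probability sets")
    ia = {m: i for i, m in enumerate(probs_a.markers["marker_id"])}
    ib = {m: i for i, m in enumerate(probs_b.markers["marker_id"])}
    A = probs_a.values[:, :, [ia[m] for m in common]].reshape(probs_a.n_samples, -1)
    B = probs_b.values[:, :, [ib[m] for m in common]].reshape(probs_b.n_samples, -1)
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    sa = np.sqrt((A**2).sum(axis=1))
    sb = np.sqrt((B**2).sum(axis=1))
    if np.any(sa == 0) or np.any(sb == 0):
        warnings.warn("zero-variance probability vector; correlations set to NaN")
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (A @ B.T) / np.outer(sa, sb)
    corr[~np.isfinite(corr)] = np.nan
    return pd.DataFrame(corr, index=probs_a.sample_ids, columns=probs_b.sample_ids)


@dataclass
class AssignmentResult:
    """Bijection between expression-annotated and genotype sample ids."""

    assignment: dict[str, str]
    pair_correlation: dict[str, float]
    swaps: list[tuple[str, str]] = field(default_factory=list)
    low_correlation: list[str] = field(default_factory=list)

    @property
    def total_correlation(self) -> float:
        return float(sum(self.pair_correlation.values()))


def resolve_sample_mixups(
    corr: pd.DataFrame, min_accept_r: float = 0.8
) -> AssignmentResult:
    """Resolve sample mixups by maximum-total-correlation assignment.

    The Hungarian algorithm finds the bijection between expression and
    genotype samples maximizing total haplotype-probability correlation;
    pairs that differ from the annotated pairing are reported as swaps.
    Ties are broken in favour of the annotated pairing.  Samples whose
    assigned correlation falls below ``min_accept_r`` are flagged
    low-correlation rather than silently accepted.
    """
    if corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    C = corr.to_numpy(dtype=float).copy()
    C[~np.isfinite(C)] = -1.0
    # nudge the diagonal so exact ties resolve to the annotated pairing
    C = C + 1e-9 * np.eye(len(C))
    rows, cols = linear_sum_assignment(-C)
    expr_ids = list(corr.index)
    geno_ids = list(corr.columns)
    assignment = {expr_ids[i]: geno_ids[j] for i, j in zip(rows, cols)}
    pair_r = {
        expr_ids[i]: float(corr.iloc[i, j]) for i, j in zip(rows, cols)
    }
    swaps = [
        (e, g) for e, g in assignment.items() if e != g
    ]
    low = [e for e, r in pair_r.items() if not np.isfinite(r) or r < min_accept_r]
    if swaps:
        logger.info("sample mixups corrected: %d reassignments", len(swaps))
    return AssignmentResult(assignment, pair_r, swaps, low)
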