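"""Founder-haplotype linear mixed-model genome scans.

The mapping model, fit per gene, is

    y_i = s_i b_s + gen_i b_gen + sum_{j=1}^{7} g_ij b_j + gamma_i + eps_i

where ``g_ij`` is the probability of founder ancestry ``j`` at the tested
marker, ``gamma ~ MVN(0, sigma_g^2 K)`` models the polygenic effect with a
realized-relationship (kinship) matrix ``K``, and one of the eight founder
columns is dropped (absorbed by the intercept) for identifiability.
Kinship is leave-one-chromosome-out (LOCO): the scanned chromosome's
markers are excluded from ``K`` so the locus does not absorb itself.

The polygenic variance fraction ``hsq`` is estimated once per
(gene, LOCO kinship) under the covariates-only null and held fixed across
markers — the standard genome-scan approximation — after which each marker
is a generalized-least-squares fit on eigen-rotated data and

    LOD = (n / 2) * log10(RSS_null / RSS_marker)

on the weighted (rotated) residual sums of squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .synthetic import FOUNDER_LABELS, N_FOUNDERS, FounderProbs

logger = logging.getLogger(__name__)

DEFAULT_LOD_THRESHOLD = 7.0
DEFAULT_CIS_WINDOW_BP = 2_000_000


# ---------------------------------------------------------------------------
# Kinship
# ---------------------------------------------------------------------------

@dataclass
class KinshipSet:
    """Overall and leave-one-chromosome-out realized-relationship matrices."""

    overall: np.ndarray
    loco: dict[str, np.ndarray] = field(default_factory=dict)
    _eig_cache: dict = field(default_factory=dict, repr=False)

    def eig(self, chrom: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Cached eigendecomposition (eigenvalues, eigenvectors) of K."""
        key = chrom
        if key not in self._eig_cache:
            K = self.overall if chrom is None else self.loco[chrom]
            lam, U = np.linalg.eigh(K)
            self._eig_cache[key] = (np.clip(lam, 0.0, None), U)
        return self._eig_cache[key]

    def validate(self) -> None:
        mats = [("overall", self.overall)] + list(self.loco.items())
        for name, K in mats:
            if not np.allclose(K, K.T, atol=1e-10):
                raise ValueError(f"kinship {name} not symmetric")
            if np.any(np.diag(K) <= 0):
                raise ValueError(f"kinship {name} has non-positive diagonal")
            if np.linalg.eigvalsh(K).min() < -1e-8:
                raise ValueError(f"kinship {name} not positive semidefinite")


def kinship_from_probs(probs: FounderProbs, loco: bool = True) -> KinshipSet:
    """Realized-relationship matrices from founder probabilities.

    ``K_ab = (1/M) sum_m sum_j p_amj p_bmj`` over included markers; the
    LOCO matrix for a chromosome excludes that chromosome's markers.
    """
    chroms = probs.chromosomes
    if loco and len(chroms) < 2:
        raise ValueError("LOCO kinship needs at least two chromosomes")
    n, _, M = probs.values.shape
    flat = probs.values.reshape(n, -1)  # (n, 8*M) with markers fastest? no:
    # values is (n, 8, M); reshape keeps founder-major blocks, which is fine
    # because the sum runs over all (founder, marker) pairs.
    total = probs.values.reshape(n, -1) @ probs.values.reshape(n, -1).T
    overall = total / M
    loco_mats: dict[str, np.ndarray] = {}
    if loco:
        for chrom in chroms:
            idx = probs.chrom_indices(chrom)
            sub = probs.values[:, :, idx].reshape(n, -1)
            loco_mats[chrom] = (total - sub @ sub.T) / (M - len(idx))
    ks = KinshipSet(overall, loco_mats)
    return ks


# ---------------------------------------------------------------------------
# Covariate design
# ---------------------------------------------------------------------------

def covariate_design(covariates: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Intercept + sex + generation dummy design from a covariate table."""
    n = len(covariates)
    cols = [np.ones(n)]
    names = ["intercept"]
    if "sex" in covariates:
        cols.append((covariates["sex"].to_numpy() == "M").astype(float))
        names.append("sexM")
    if "generation" in covariates:
        levels = sorted(covariates["generation"].unique())
        for lev in levels[1:]:  # first level absorbed by intercept
            cols.append((covariates["generation"].to_numpy() == lev).astype(float))
            names.append(f"gen{lev}")
    return np.column_stack(cols), names


def _check_full_rank(X: np.ndarray, names: list[str] | None = None) -> None:
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    bad = np.flatnonzero(diag < tol)
    if bad.size:
        labels = (
            [names[i] for i in bad] if names is not None else list(map(int, bad))
        )
        raise ValueError(f"design matrix rank-deficient; collinear columns: {labels}")


# ---------------------------------------------------------------------------
# Null model (polygenic variance estimation)
# ---------------------------------------------------------------------------

@dataclass
class NullFit:
    """Covariates-only mixed-model fit for one gene."""

    hsq: float
    sigma2_total: float
    loglik: float
    coefficients: np.ndarray
    #: rotated/weighted ingredients reused by the scan
    weights: np.ndarray | None = None


def _rotate(y, X, eig):
    if eig is None:
        return y, X
    lam, U = eig
    return U.T @ y, U.T @ X


def _gls_rss(yt, Xt, w):
    sw = np.sqrt(w)
    Xw = Xt * sw[:, None]
    yw = yt * sw
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    r = yw - Xw @ beta
    return float(r @ r), beta


def _neg_profile_loglik(h, lam, yt, Xt):
    v = h * lam + (1.0 - h)
    rss, _ = _gls_rss(yt, Xt, 1.0 / v)
    n = len(yt)
    sigma2 = rss / n
    ll = -0.5 * n * np.log(2 * np.pi * sigma2) - 0.5 * np.sum(np.log(v)) - 0.5 * n
    return -ll


def fit_null(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray | None = None,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
    names: list[str] | None = None,
) -> NullFit:
    """Fit the covariates-only LMM, profiling the likelihood over hsq.

    The kinship is eigendecomposed once (``K = U diag(lam) U^T``); y and X
    are rotated by ``U^T``, after which the covariance is diagonal with
    weights ``1 / (hsq * lam_k + 1 - hsq)`` and the profile log-likelihood
    is maximized over ``hsq`` by bounded scalar (Brent-style) search on
    ``[0, 1 - 1e-6]``.  With ``K = None`` (or identity) this degenerates
    to OLS.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if y.shape[0] != X.shape[0]:
        raise ValueError("y and design have different sample counts")
    _check_full_rank(X, names)
    n = len(y)
    if K is None and eig is None:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        rss = float(r @ r)
        sigma2 = rss / n
        ll = -0.5 * n * np.log(2 * np.pi * sigma2) - 0.5 * n
        return NullFit(0.0, sigma2, ll, beta, weights=np.ones(n))
    if eig is None:
        lam, U = np.linalg.eigh(K)
        lam = np.clip(lam, 0.0, None)
        eig = (lam, U)
    lam, U = eig
    yt, Xt = _rotate(y, X, eig)
    res = minimize_scalar(
        _neg_profile_loglik,
        bounds=(0.0, 1.0 - 1e-6),
        args=(lam, yt, Xt),
        method="bounded",
        options={"xatol": 1e-6},
    )
    hsq = float(res.x)
    # the bounded optimizer never evaluates the exact boundary; make sure a
    # boundary solution is not missed
    for h0 in (0.0,):
        if _neg_profile_loglik(h0, lam, yt, Xt) < res.fun:
            hsq = h0
            res.fun = _neg_profile_loglik(h0, lam, yt, Xt)
    v = hsq * lam + (1.0 - hsq)
    w = 1.0 / v
    rss, beta = _gls_rss(yt, Xt, w)
    return NullFit(hsq, rss / n, -float(res.fun), beta, weights=w)


# ---------------------------------------------------------------------------
# Genome scan
# ---------------------------------------------------------------------------

@dataclass
class LodCurve:
    """Per-marker LOD scores for one gene, aligned with a marker map."""

    gene_id: str
    lod: np.ndarray
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.lod) != len(self.markers):
            raise ValueError("LOD length does not match marker map")
        self.lod = np.clip(np.asarray(self.lod, dtype=float), 0.0, None)


def _marker_lods(yw, Xw, Pw, rss0, n):
    """LOD at each marker given pre-weighted y, covariates and probs.

    ``Pw`` is (n, 8, M_c) already rotated and weighted; the last founder
    column is dropped (reference founder absorbed by the intercept).
    """
    M = Pw.shape[2]
    lods = np.empty(M)
    for m in range(M):
        D = np.hstack([Xw, Pw[:, : N_FOUNDERS - 1, m]])
        beta, *_ = np.linalg.lstsq(D, yw, rcond=None)
        r = yw - D @ beta
        rss1 = float(r @ r)
        lods[m] = 0.5 * n * np.log10(rss0 / rss1) if rss1 > 0 else np.inf
    return lods


def scan_haplotypes(
    y: np.ndarray,
    probs: FounderProbs,
    X: np.ndarray,
    kinship: KinshipSet | None = None,
    gene_id: str = "",
) -> LodCurve:
    """Genome scan: GLS founder-haplotype regression at every marker.

    Per chromosome, the LOCO kinship's ``hsq`` is estimated under the
    covariates-only null and held fixed; the marker model adds 7 founder
    probability columns.  Degenerate markers (identical probabilities in
    every sample) score LOD 0 and are logged, not fatal.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if probs.n_samples != n or X.shape[0] != n:
        raise ValueError("sample order/count mismatch between y, probs, design")
    lod = np.zeros(probs.n_markers)
    for chrom in probs.chromosomes:
        idx = probs.chrom_indices(chrom)
        eig = kinship.eig(chrom) if kinship is not None else None
        null = fit_null(y, X, eig=eig)
        w = null.weights
        sw = np.sqrt(w)
        yt, Xt = _rotate(y, X, eig)
        yw, Xw = yt * sw, Xt * sw[:, None]
        rss0, _ = _gls_rss(yt, Xt, w)
        P = probs.values[:, :, idx]
        degenerate = np.flatnonzero(np.ptp(P, axis=0).max(axis=0) < 1e-12)
        if eig is not None:
            _, U = eig
            P = np.einsum("ki,kjm->ijm", U, P)
        Pw = P * sw[:, None, None]
        lods = _marker_lods(yw, Xw, Pw, rss0, n)
        if degenerate.size:
            logger.info(
                "chromosome %s: %d degenerate markers scored LOD 0",
                chrom, degenerate.size,
            )
            lods[degenerate] = 0.0
        lod[idx] = lods
    return LodCurve(gene_id, lod, probs.markers)


# ---------------------------------------------------------------------------
# Peaks, cis/trans, founder effects
# ---------------------------------------------------------------------------

@dataclass
class EqtlPeak:
    """One per-chromosome LOD maximum above threshold."""

    gene_id: str
    chromosome: str
    peak_marker_id: str
    peak_bp: int
    lod: float
    cis_trans: str | None = None
    founder_effects: np.ndarray | None = None


def find_peaks(
    curve: LodCurve, threshold: float = DEFAULT_LOD_THRESHOLD
) -> list[EqtlPeak]:
    """One peak per chromosome: the argmax marker if its LOD exceeds the
    threshold (strictly); ties broken by smallest bp position."""
    peaks = []
    mm = curve.markers.reset_index(drop=True)
    for chrom, sub in mm.groupby("chromosome", sort=False):
        lods = curve.lod[sub.index.to_numpy()]
        best = int(np.argmax(lods))  # argmax returns first (smallest bp) on ties
        if lods[best] > threshold:
            row = sub.iloc[best]
            peaks.append(
                EqtlPeak(
                    gene_id=curve.gene_id,
                    chromosome=str(chrom),
                    peak_marker_id=str(row["marker_id"]),
                    peak_bp=int(row["position_bp"]),
                    lod=float(lods[best]),
                )
            )
    return peaks


def classify_cis_trans(
    peak: EqtlPeak,
    gene_chromosome: str,
    gene_tss_bp: int,
    window_bp: int = DEFAULT_CIS_WINDOW_BP,
) -> str:
    """cis iff the peak is on the gene's chromosome within ±window of the
    TSS (boundary inclusive); otherwise trans."""
    if str(peak.chromosome) == str(gene_chromosome) and abs(
        peak.peak_bp - gene_tss_bp
    ) <= window_bp:
        return "cis"
    return "trans"


def founder_effects_at(
    marker_id: str,
    y: np.ndarray,
    probs: FounderProbs,
    X: np.ndarray,
    kinship: KinshipSet | None = None,
) -> np.ndarray:
    """Eight mean-centered founder allele effects at one marker.

    GLS coefficients of the 7 retained founder columns, with the dropped
    (reference) founder set to 0 before centering — the display convention
    for allele-effect plots.
    """
    y = np.asarray(y, dtype=float)
    hits = np.flatnonzero((probs.markers["marker_id"] == marker_id).to_numpy())
    if hits.size != 1:
        raise KeyError(f"marker {marker_id!r} not found")
    chrom = str(probs.markers.iloc[hits[0]]["chromosome"])
    eig = kinship.eig(chrom) if kinship is not None else None
    null = fit_null(y, X, eig=eig)
    w = null.weights
    sw = np.sqrt(w)
    yt, Xt = _rotate(y, X, eig)
    G = probs.marker_values(marker_id)
    if eig is not None:
        _, U = eig
        G = U.T @ G
    D = np.hstack([Xt, G[:, : N_FOUNDERS - 1]]) * sw[:, None]
    beta, *_ = np.linalg.lstsq(D, yt * sw, rcond=None)
    effects = np.append(beta[X.shape[1]:], 0.0)
    return effects - effects.mean()


def heritability(
    y: np.ndarray, X: np.ndarray, kinship: KinshipSet | np.ndarray
) -> float:
    """Polygenic fraction of phenotypic variance under the overall kinship.

    The null LMM is fit with the kinship as given, then the model-scale
    variance ratio is converted to the *realized* population scale: the
    genetic component ``sigma^2 h K`` contributes ``sigma^2 h c`` to the
    observable trait variance, where ``c = mean(diag K) - mean(K)`` is the
    kinship's variance-contribution factor (for founder-probability
    kinships the diagonal is ~0.5, not 1, so the raw ratio would
    overstate heritability).  The returned value is directly comparable
    with a simulated realized variance fraction.
    """
    if isinstance(kinship, KinshipSet):
        K = kinship.overall
        eig = kinship.eig(None)
        fit = fit_null(y, X, eig=eig)
    else:
        K = np.asarray(kinship)
        fit = fit_null(y, X, K=K)
    c = float(np.mean(np.diag(K)) - np.mean(K))
    h = fit.hsq
    denom = h * c + (1.0 - h)
    return float(h * c / denom) if denom > 0 else 0.0


# ---------------------------------------------------------------------------
# SNP association
# ---------------------------------------------------------------------------

def validate_sdp_table(sdp_table: pd.DataFrame) -> None:
    """SDPs are 8-bit founder->allele patterns; monomorphic ones rejected."""
    for col in ("snp_id", "chromosome", "position_bp", "sdp"):
        if col not in sdp_table.columns:
            raise ValueError(f"SDP table missing column {col!r}")
    sdp = sdp_table["sdp"].to_numpy()
    if np.any((sdp <= 0) | (sdp >= 2**N_FOUNDERS - 1)):
        raise ValueError("monomorphic SDP (all-0 or all-1) in table")


def _sdp_bits(sdp: int) -> np.ndarray:
    return np.array([(int(sdp) >> j) & 1 for j in range(N_FOUNDERS)], dtype=float)


def interpolate_probs(
    probs: FounderProbs, chrom: str, position_bp: float
) -> np.ndarray:
    """(n, 8) founder probabilities at an arbitrary bp position, linearly
    interpolated between the flanking markers (clamped at chromosome ends)."""
    idx = probs.chrom_indices(chrom)
    bp = probs.markers.iloc[idx]["position_bp"].to_numpy()
    P = probs.values[:, :, idx]
    if position_bp <= bp[0]:
        return P[:, :, 0]
    if position_bp >= bp[-1]:
        return P[:, :, -1]
    hi = int(np.searchsorted(bp, position_bp, side="left"))
    lo = hi - 1
    t = (position_bp - bp[lo]) / (bp[hi] - bp[lo])
    return (1 - t) * P[:, :, lo] + t * P[:, :, hi]


def snp_association(
    y: np.ndarray,
    probs: FounderProbs,
    sdp_table: pd.DataFrame,
    region: tuple[str, int, int],
    X: np.ndarray,
    kinship: KinshipSet | None = None,
) -> pd.DataFrame:
    """1-df SNP association scan within a region.

    Each SNP's dosage is the founder-probability-weighted allele count
    ``d_i = sum_j p_ij(pos) * allele_j(sdp)`` with probabilities linearly
    interpolated in bp; the scan is a single-dosage-column GLS fit with
    the same LOD definition as the haplotype scan.

    Returns a DataFrame ``snp_id, chromosome, position_bp, lod``.
    """
    validate_sdp_table(sdp_table)
    chrom, start, end = region
    sub = sdp_table[
        (sdp_table["chromosome"].astype(str) == str(chrom))
        & (sdp_table["position_bp"] >= start)
        & (sdp_table["position_bp"] <= end)
    ]
    y = np.asarray(y, dtype=float)
    n = len(y)
    eig = kinship.eig(str(chrom)) if kinship is not None else None
    null = fit_null(y, X, eig=eig)
    w = null.weights
    sw = np.sqrt(w)
    yt, Xt = _rotate(y, X, eig)
    yw, Xw = yt * sw, Xt * sw[:, None]
    rss0, _ = _gls_rss(yt, Xt, w)
    _, U = eig if eig is not None else (None, None)
    rows = []
    for _, snp in sub.iterrows():
        dose = interpolate_probs(probs, str(chrom), float(snp["position_bp"])) @ _sdp_bits(
            snp["sdp"]
        )
        if U is not None:
            dose = U.T @ dose
        D = np.hstack([Xw, (dose * sw)[:, None]])
        beta, *_ = np.linalg.lstsq(D, yw, rcond=None)
        r = yw - D @ beta
        rss1 = float(r @ r)
        lod = max(0.5 * n * np.log10(rss0 / rss1), 0.0) if rss1 > 0 else np.inf
        rows.append((snp["snp_id"], str(chrom), int(snp["position_bp"]), lod))
    return pd.DataFrame(rows, columns=["snp_id", "chromosome", "position_bp", "lod"])


# ---------------------------------------------------------------------------
# Gene-set export
# ---------------------------------------------------------------------------

def export_gene_sets(peaks: pd.DataFrame) -> dict[str, list[str]]:
    """Group eQTL genes into GMT-ready sets: all-cis, all-trans, and
    per-chromosome cis/trans (keyed by the peak's chromosome)."""
    sets: dict[str, list[str]] = {"eqtl-cis": [], "eqtl-trans": []}
    for _, row in peaks.iterrows():
        kind = row["cis_trans"]
        gene = row["gene_id"]
        chrom = row["chromosome"]
        sets[f"eqtl-{kind}"].append(gene)
        key = f"eqtl-chr{chrom}-{kind}"
        sets.setdefault(key, []).append(gene)
    return {k: sorted(dict.fromkeys(v)) for k, v in sets.items() if v or k in
            ("eqtl-cis", "eqtl-trans")}
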