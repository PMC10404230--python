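"""Conditional-LOD-drop mediation analysis.

A target gene's eQTL is re-tested at its peak marker while conditioning,
one at a time, on candidate mediator transcripts added as covariates.  A
mediator that transmits the locus's effect to the target absorbs the
association, so the conditioned LOD collapses; the LOD drop (baseline
minus conditioned) ranks candidates, with the largest drop nominating the
causal intermediate.  Evaluation is at the single peak marker only — the
viewer's click-the-peak behaviour — not a full genome re-scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .eqtl import KinshipSet, _gls_rss, _rotate, fit_null
from .synthetic import N_FOUNDERS, FounderProbs

logger = logging.getLogger(__name__)


@dataclass
class MediationResult:
    target_gene: str
    peak_marker: str
    baseline_lod: float
    table: pd.DataFrame  # mediator_gene, conditioned_lod, lod_drop, flag


def _lod_at_marker(y, X, G, eig):
    """LOD of the 7-founder-column model vs covariates-only at one marker,
    with hsq re-estimated under the (possibly augmented) null."""
    null = fit_null(y, X, eig=eig)
    w = null.weights
    sw = np.sqrt(w)
    yt, Xt = _rotate(y, X, eig)
    rss0, _ = _gls_rss(yt, Xt, w)
    Gr = G if eig is None else eig[1].T @ G
    D = np.hstack([Xt, Gr[:, : N_FOUNDERS - 1]]) * sw[:, None]
    beta, *_ = np.linalg.lstsq(D, yt * sw, rcond=None)
    r = yt * sw - D @ beta
    rss1 = float(r @ r)
    n = len(y)
    if rss1 <= 0:
        return np.inf
    return max(0.5 * n * np.log10(rss0 / rss1), 0.0)


def mediate(
    target_y: np.ndarray,
    peak_marker: str,
    mediators: pd.DataFrame,
    probs: FounderProbs,
    X: np.ndarray,
    kinship: KinshipSet | None = None,
    target_gene: str = "",
    window_bp: float | None = None,
    mediator_positions: pd.DataFrame | None = None,
) -> MediationResult:
    """Condition the target's peak-marker QTL on each candidate mediator.

    ``mediators`` is samples × candidate genes (the target itself must be
    excluded).  For every candidate z the null and marker models are refit
    with z appended to the covariates, re-estimating ``hsq`` under the
    augmented null (a mediator can absorb polygenic variance).  Rows are
    sorted by descending LOD drop, ties by gene id.  A mediator collinear
    with the existing covariates is flagged, not fatal.

    ``window_bp`` (with ``mediator_positions``: gene_id, chromosome,
    tss_bp) optionally restricts candidates to genes local to the peak;
    default off.
    """
    y = np.asarray(target_y, dtype=float)
    if len(mediators) != len(y) or probs.n_samples != len(y):
        raise ValueError("sample alignment mismatch")
    if target_gene and target_gene in mediators.columns:
        raise ValueError("mediator matrix must exclude the target gene")
    hits = np.flatnonzero((probs.markers["marker_id"] == peak_marker).to_numpy())
    if hits.size != 1:
        raise KeyError(f"peak marker {peak_marker!r} not found")
    row = probs.markers.iloc[hits[0]]
    chrom = str(row["chromosome"])
    peak_bp = int(row["position_bp"])
    eig = kinship.eig(chrom) if kinship is not None else None
    G = probs.marker_values(peak_marker)

    candidates = list(mediators.columns)
    if window_bp is not None:
        if mediator_positions is None:
            raise ValueError("window_bp filter requires mediator_positions")
        pos = mediator_positions.set_index("gene_id")
        candidates = [
            g for g in candidates
            if g in pos.index
            and str(pos.loc[g, "chromosome"]) == chrom
            and abs(int(pos.loc[g, "tss_bp"]) - peak_bp) <= window_bp
        ]

    baseline = _lod_at_marker(y, X, G, eig)
    rows = []
    for g in candidates:
        z = mediators[g].to_numpy(dtype=float)
        X_aug = np.hstack([X, z[:, None]])
        if np.linalg.matrix_rank(X_aug) < X_aug.shape[1]:
            logger.warning("mediator %s collinear with covariates; flagged", g)
            rows.append((g, np.nan, np.nan, "collinear"))
            continue
        conditioned = _lod_at_marker(y, X_aug, G, eig)
        rows.append((g, conditioned, baseline - conditioned, "ok"))
    table = pd.DataFrame(
        rows, columns=["mediator_gene", "conditioned_lod", "lod_drop", "flag"]
    )
    table = table.sort_values(
        ["lod_drop", "mediator_gene"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
    return MediationResult(target_gene, peak_marker, baseline, table)
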