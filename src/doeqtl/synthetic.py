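"""Synthetic Diversity Outbred (DO) data generator.

DO mice descend from eight inbred founder strains, so each genome is a
fine-grained mosaic of the eight founder haplotypes.  This module simulates
that mosaic structure together with the downstream observables an eQTL
study consumes — founder haplotype probabilities, kinship-structured gene
expression, negative-binomial RNA-seq counts — plus the corruption
processes a real study has to detect and repair: choroid-plexus
contamination, sex-chromosome aneuploidies (X0 females, XXY males) and
sample-label swaps.  Every injected signal is recorded in a
:class:`SimTruth` object so recovery can be scored exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The eight DO founder strains, in the conventional A–H letter order:
#: A/J, C57BL/6J, 129S1/SvImJ, NOD/ShiLtJ, NZO/HlLtJ, CAST/EiJ, PWK/PhJ,
#: WSB/EiJ.
FOUNDER_LABELS: tuple[str, ...] = ("A", "B", "C", "D", "E", "F", "G", "H")
FOUNDER_STRAINS: dict[str, str] = {
    "A": "AJ", "B": "B6", "C": "129", "D": "NOD",
    "E": "NZO", "F": "CAST", "G": "PWK", "H": "WSB",
}
N_FOUNDERS = 8

#: Fixed genetic-map scaling: 0.5 cM per Mb, i.e. cM = bp * 5e-7.
CM_PER_BP = 5e-7

MARKER_MAP_COLUMNS = ["marker_id", "chromosome", "position_bp", "position_cM"]


# ---------------------------------------------------------------------------
# Marker maps
# ---------------------------------------------------------------------------

def make_marker_map(
    n_chromosomes: int,
    chrom_length_mb: float,
    markers_per_chromosome: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Build a marker map with evenly spaced markers on each chromosome.

    Markers are placed on an even grid spanning the whole chromosome
    (both ends included), so a 100 Mb chromosome spans exactly 50 cM under
    the fixed 0.5 cM/Mb conversion.  The map is deterministic; ``seed`` is
    accepted for interface uniformity with the stochastic simulators.

    Returns a DataFrame with columns ``marker_id, chromosome, position_bp,
    position_cM``, sorted by chromosome then position.
    """
    if n_chromosomes < 1:
        raise ValueError("n_chromosomes must be >= 1")
    if markers_per_chromosome < 2:
        raise ValueError("markers_per_chromosome must be >= 2")
    if chrom_length_mb <= 0:
        raise ValueError("chrom_length_mb must be positive")
    length_bp = int(round(chrom_length_mb * 1e6))
    if markers_per_chromosome > length_bp:
        raise ValueError("more markers than base pairs requested")
    rows = []
    for c in range(1, n_chromosomes + 1):
        chrom = str(c)
        bp = np.linspace(0, length_bp, markers_per_chromosome)
        bp = np.round(bp).astype(np.int64)
        if np.any(np.diff(bp) <= 0):  # pragma: no cover - guarded above
            raise ValueError("marker spacing collapsed; too many markers")
        for i, p in enumerate(bp):
            rows.append((f"m{chrom}_{i + 1}", chrom, int(p), float(p) * CM_PER_BP))
    mm = pd.DataFrame(rows, columns=MARKER_MAP_COLUMNS)
    validate_marker_map(mm)
    return mm


def validate_marker_map(marker_map: pd.DataFrame) -> None:
    """Raise ``ValueError`` if the map violates its invariants."""
    missing = [c for c in MARKER_MAP_COLUMNS if c not in marker_map.columns]
    if missing:
        raise ValueError(f"marker map missing columns: {missing}")
    if marker_map["marker_id"].duplicated().any():
        dups = marker_map.loc[marker_map["marker_id"].duplicated(), "marker_id"]
        raise ValueError(f"duplicate marker ids: {sorted(set(dups))[:5]}")
    if (marker_map["position_bp"] < 0).any():
        raise ValueError("negative bp positions in marker map")
    for chrom, sub in marker_map.groupby("chromosome", sort=False):
        bp = sub["position_bp"].to_numpy()
        cm = sub["position_cM"].to_numpy()
        if np.any(np.diff(bp) <= 0):
            raise ValueError(
                f"marker positions not strictly increasing on chromosome {chrom}"
            )
        if np.any(np.diff(cm) < 0):
            raise ValueError(
                f"cM positions decreasing on chromosome {chrom}"
            )


# ---------------------------------------------------------------------------
# Founder probabilities
# ---------------------------------------------------------------------------

@dataclass
class FounderProbs:
    """Per-sample, per-marker probabilities over the 8 founder ancestries.

    ``values`` has shape (n_samples, 8, n_markers), aligned with
    ``markers`` (a marker-map DataFrame).  Every (sample, marker) slice is
    a probability simplex.
    """

    values: np.ndarray
    sample_ids: list[str]
    markers: pd.DataFrame
    founder_labels: tuple[str, ...] = FOUNDER_LABELS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1] != N_FOUNDERS:
            raise ValueError("values must have shape (n, 8, M)")
        if self.values.shape[0] != len(self.sample_ids):
            raise ValueError("sample count mismatch")
        if self.values.shape[2] != len(self.markers):
            raise ValueError("marker count mismatch")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[2]

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.markers["chromosome"]))

    def chrom_indices(self, chrom: str) -> np.ndarray:
        idx = np.flatnonzero((self.markers["chromosome"] == chrom).to_numpy())
        if idx.size == 0:
            raise KeyError(f"chromosome {chrom!r} not in marker map")
        return idx

    def chrom_values(self, chrom: str) -> np.ndarray:
        """(n, 8, M_c) view of one chromosome's probabilities."""
        return self.values[:, :, self.chrom_indices(chrom)]

    def marker_values(self, marker_id: str) -> np.ndarray:
        """(n, 8) probabilities at a single marker."""
        hits = np.flatnonzero((self.markers["marker_id"] == marker_id).to_numpy())
        if hits.size != 1:
            raise KeyError(f"marker {marker_id!r} not found")
        return self.values[:, :, hits[0]]

    def validate(self, atol: float = 1e-8) -> None:
        if (self.values < -atol).any():
            raise ValueError("negative founder probabilities")
        sums = self.values.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=atol):
            raise ValueError("founder probabilities do not sum to 1")

    def reorder_samples(self, permutation: np.ndarray) -> "FounderProbs":
        """Return a copy with rows (data and ids) permuted together."""
        perm = np.asarray(permutation)
        return FounderProbs(
            self.values[perm].copy(),
            [self.sample_ids[i] for i in perm],
            self.markers,
            self.founder_labels,
        )


def simulate_founder_mosaics(
    marker_map: pd.DataFrame,
    n_samples: int,
    crossover_density_per_morgan: float = 30.0,
    prob_blur_alpha: float = 0.0,
    seed: int = 0,
) -> FounderProbs:
    """Simulate DO-like founder mosaics and their haplotype probabilities.

    Each sample carries two chromatids per chromosome.  A chromatid is
    partitioned by a Poisson number of breakpoints (rate =
    ``crossover_density_per_morgan`` × chromosome length in Morgans)
    placed uniformly in genetic distance, and each segment is assigned a
    founder uniformly at random.  The probability vector at a marker is
    half the sum of the two chromatid indicator vectors, then blurred
    toward the uniform simplex: ``p <- (1 - alpha) p + alpha / 8``,
    modelling haplotype-reconstruction uncertainty.

    The default density of 30 crossovers/Morgan mimics the short ancestral
    haplotype blocks accumulated over ~20 DO outbreeding generations.
    """
    validate_marker_map(marker_map)
    if len(marker_map) == 0:
        raise ValueError("empty marker map")
    if crossover_density_per_morgan <= 0:
        raise ValueError("crossover density must be positive")
    if not 0 <= prob_blur_alpha < 1:
        raise ValueError("prob_blur_alpha must be in [0, 1)")
    rng = np.random.default_rng(seed)
    mm = marker_map.reset_index(drop=True)
    n_markers = len(mm)
    values = np.zeros((n_samples, N_FOUNDERS, n_markers))
    for chrom, sub in mm.groupby("chromosome", sort=False):
        idx = sub.index.to_numpy()
        cm = sub["position_cM"].to_numpy()
        span_morgan = max((cm[-1] - cm[0]) / 100.0, 1e-9)
        for s in range(n_samples):
            dose = np.zeros((N_FOUNDERS, len(idx)))
            for _chromatid in range(2):
                n_bp = rng.poisson(crossover_density_per_morgan * span_morgan)
                breaks = np.sort(rng.uniform(cm[0], cm[-1], size=n_bp))
                founders = rng.integers(0, N_FOUNDERS, size=n_bp + 1)
                seg = np.searchsorted(breaks, cm, side="right")
                dose[founders[seg], np.arange(len(idx))] += 0.5
            values[s, :, idx] = dose.T
    if prob_blur_alpha > 0:
        values = (1 - prob_blur_alpha) * values + prob_blur_alpha / N_FOUNDERS
    sample_ids = [f"DO{i + 1:04d}" for i in range(n_samples)]
    probs = FounderProbs(values, sample_ids, marker_map.reset_index(drop=True))
    probs.validate()
    return probs


# ---------------------------------------------------------------------------
# Gene architectures and expression
# ---------------------------------------------------------------------------

@dataclass
class GeneArchitecture:
    """Ground-truth generative parameters for one gene.

    ``founder_effects`` are the 8 allele effects (mean-centered);
    ``qtl_var_frac`` and ``h2_polygenic`` are the fractions of trait
    variance attributable to the causal locus and to the kinship-structured
    polygenic term.  ``mediator_of`` builds a complete-mediation chain:
    this gene's expression feeds into the named target gene with path
    coefficient ``mediation_b`` (handled by the caller assembling chains).
    """

    gene_id: str
    chromosome: str
    tss_bp: int
    causal_marker_id: str | None = None
    founder_effects: np.ndarray | None = None
    qtl_var_frac: float = 0.0
    h2_polygenic: float = 0.0
    sex_effect: float = 0.0
    gen_effects: dict[str, float] = field(default_factory=dict)
    contamination_loading: float = 0.0
    mediator_of: str | None = None
    mediation_b: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.qtl_var_frac < 1 or not 0 <= self.h2_polygenic < 1:
            raise ValueError("variance fractions must be in [0, 1)")
        if self.qtl_var_frac + self.h2_polygenic >= 1:
            raise ValueError("qtl_var_frac + h2_polygenic must be < 1")
        if self.founder_effects is not None:
            fe = np.asarray(self.founder_effects, dtype=float)
            if fe.shape != (N_FOUNDERS,):
                raise ValueError("founder_effects must have length 8")
            self.founder_effects = fe - fe.mean()


@dataclass
class SimTruth:
    """Everything needed to score recovery of injected signals."""

    architectures: dict[str, GeneArchitecture]
    kinship: np.ndarray | None = None
    seed: int | None = None
    #: expression label -> genotype label it truly corresponds to
    true_pairing: dict[str, str] = field(default_factory=dict)
    swaps: list[tuple[str, str]] = field(default_factory=list)
    aneuploidies: list[tuple[str, str]] = field(default_factory=list)
    contamination: dict[str, float] = field(default_factory=dict)
    #: realized (scaled) founder effects actually used in generation
    realized_effects: dict[str, np.ndarray] = field(default_factory=dict)


def random_architectures(
    marker_map: pd.DataFrame,
    n_genes: int,
    qtl_var_frac: float = 0.2,
    h2_polygenic: float = 0.4,
    frac_with_qtl: float = 1.0,
    effect_scale: float = 1.0,
    seed: int = 0,
    gene_prefix: str = "G",
) -> list[GeneArchitecture]:
    """Draw gene architectures with cis QTL at random markers.

    Genes with a QTL get their TSS placed at the causal marker (the
    archetypal cis gene); founder effects are standard-normal draws,
    mean-centered.  A ``1 - frac_with_qtl`` fraction are null genes
    (no causal locus) whose TSS is placed at a random marker.
    """
    rng = np.random.default_rng(seed)
    archs = []
    for g in range(n_genes):
        row = marker_map.iloc[rng.integers(0, len(marker_map))]
        has_qtl = rng.random() < frac_with_qtl and qtl_var_frac > 0
        archs.append(
            GeneArchitecture(
                gene_id=f"{gene_prefix}{g + 1:05d}",
                chromosome=str(row["chromosome"]),
                tss_bp=int(row["position_bp"]),
                causal_marker_id=str(row["marker_id"]) if has_qtl else None,
                founder_effects=(
                    rng.normal(0, effect_scale, N_FOUNDERS) if has_qtl else None
                ),
                qtl_var_frac=qtl_var_frac if has_qtl else 0.0,
                h2_polygenic=h2_polygenic,
            )
        )
    return archs


def make_covariates(
    sample_ids: list[str],
    generations: tuple[str, ...] = ("G21", "G22", "G23"),
    seed: int = 0,
) -> pd.DataFrame:
    """Random sex/generation covariate table (one row per sample)."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "sex": rng.choice(["F", "M"], size=len(sample_ids)),
            "generation": rng.choice(list(generations), size=len(sample_ids)),
        }
    )


def _kinship_overall(values: np.ndarray) -> np.ndarray:
    n, _, m = values.shape
    flat = values.reshape(n, -1)
    return (flat @ flat.T) / m


def simulate_expression(
    probs: FounderProbs,
    architectures: list[GeneArchitecture],
    covariates: pd.DataFrame,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Generate latent log-scale expression under the scan's own model.

    For each gene: ``y = sex*b_s + gen*b_gen + sum_j g_j beta_j + gamma +
    eps`` with ``gamma ~ MVN(0, s_g^2 K)`` where ``K`` is the realized
    kinship of ``probs``.  The QTL and polygenic components are rescaled to
    their requested *realized* variance fractions (relative to total
    genetic+noise variance); covariate effects ride on top.  Mediation
    chains (``mediator_of``) add ``b * mediator_expression`` to the target
    after all genes are drawn.

    Returns the samples × genes latent matrix and a :class:`SimTruth`.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = np.random.default_rng(seed)
    n = probs.n_samples
    if len(covariates) != n:
        raise ValueError("covariate table does not match sample count")
    marker_ids = set(probs.markers["marker_id"])
    for a in architectures:
        if a.causal_marker_id is not None and a.causal_marker_id not in marker_ids:
            raise ValueError(
                f"gene {a.gene_id}: causal marker {a.causal_marker_id!r} "
                "not in marker map"
            )

    K = _kinship_overall(probs.values)
    # symmetric square root for polygenic draws
    lam, U = np.linalg.eigh(K)
    lam = np.clip(lam, 0, None)
    L = U * np.sqrt(lam)

    sex = (covariates["sex"].to_numpy() == "M").astype(float)
    gen_levels = sorted(covariates["generation"].unique())
    gen_dummies = {
        lev: (covariates["generation"].to_numpy() == lev).astype(float)
        for lev in gen_levels
    }

    truth = SimTruth(
        architectures={a.gene_id: a for a in architectures},
        kinship=K,
        seed=seed,
    )
    Y = np.empty((n, len(architectures)))
    for gi, a in enumerate(architectures):
        resid_frac = 1.0 - a.qtl_var_frac - a.h2_polygenic
        total_var = noise_sd**2 / resid_frac
        y = rng.normal(0, noise_sd, n)
        realized = np.zeros(N_FOUNDERS)
        if a.causal_marker_id is not None and a.qtl_var_frac > 0:
            g = probs.marker_values(a.causal_marker_id)
            if a.founder_effects is None:
                raise ValueError(f"gene {a.gene_id}: QTL without founder effects")
            q = g @ a.founder_effects
            vq = q.var()
            if vq > 0 and np.any(a.founder_effects != 0):
                scale = np.sqrt(a.qtl_var_frac * total_var / vq)
                y += q * scale
                realized = a.founder_effects * scale
        truth.realized_effects[a.gene_id] = realized
        if a.h2_polygenic > 0:
            gamma = L @ rng.standard_normal(n)
            sg = gamma.std()
            if sg > 0:
                y += gamma * (np.sqrt(a.h2_polygenic * total_var) / sg)
        y += sex * a.sex_effect
        for lev, beta in a.gen_effects.items():
            y += gen_dummies.get(lev, 0.0) * beta
        Y[:, gi] = y

    gene_ids = [a.gene_id for a in architectures]
    expr = pd.DataFrame(Y, index=pd.Index(probs.sample_ids, name="sample_id"),
                        columns=gene_ids)
    # mediation chains: target += b * mediator (after base draws)
    for a in architectures:
        if a.mediator_of is not None:
            if a.mediator_of not in expr.columns:
                raise ValueError(
                    f"mediation target {a.mediator_of!r} of {a.gene_id} unknown"
                )
            expr[a.mediator_of] = expr[a.mediator_of] + a.mediation_b * expr[a.gene_id]
    return expr, truth


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def latent_to_counts(
    latent: pd.DataFrame,
    lib_size_mean: float = 2e7,
    lib_size_cv: float = 0.2,
    nb_dispersion: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Turn latent log2 abundances into negative-binomial read counts.

    Per sample, gene means are ``libsize * 2^y / sum_g 2^y``; counts are
    NB with dispersion ``phi`` (variance ``mu + phi mu^2``), degenerating
    to Poisson at ``phi = 0``.  Library sizes are lognormal with the given
    mean and coefficient of variation.
    """
    if nb_dispersion < 0:
        raise ValueError("nb_dispersion must be >= 0")
    if lib_size_mean <= 0:
        raise ValueError("library size must be positive")
    rng = np.random.default_rng(seed)
    n, g = latent.shape
    if lib_size_cv > 0:
        sigma2 = np.log1p(lib_size_cv**2)
        mu = np.log(lib_size_mean) - sigma2 / 2
        libsizes = rng.lognormal(mu, np.sqrt(sigma2), size=n)
    else:
        libsizes = np.full(n, lib_size_mean)
    Y = latent.to_numpy()
    rel = np.exp2(Y - Y.max(axis=1, keepdims=True))
    frac = rel / rel.sum(axis=1, keepdims=True)
    mean = frac * libsizes[:, None]
    if nb_dispersion == 0:
        counts = rng.poisson(mean)
    else:
        shape = 1.0 / nb_dispersion
        lam = rng.gamma(shape, mean * nb_dispersion)
        counts = rng.poisson(lam)
    return pd.DataFrame(counts, index=latent.index, columns=latent.columns)


# ---------------------------------------------------------------------------
# Corruption processes
# ---------------------------------------------------------------------------

def inject_contamination(
    latent: pd.DataFrame,
    marker_gene_ids: list[str],
    lambda_sd: float = 0.5,
    loadings: dict[str, float] | None = None,
    marker_loading: float = 4.0,
    seed: int = 0,
    truth: SimTruth | None = None,
) -> pd.DataFrame:
    """Add choroid-plexus-like contamination to the latent expression.

    Per sample, a non-negative contamination score ``lambda_i ~
    |N(0, lambda_sd)|``.  Marker genes (the Kl/Ttr analogs) get
    ``+lambda_i * marker_loading``; any other gene listed in ``loadings``
    gets ``+lambda_i * loading_g``.  Scores are recorded in ``truth``.
    """
    if lambda_sd < 0:
        raise ValueError("lambda_sd must be >= 0")
    rng = np.random.default_rng(seed)
    out = latent.copy()
    lam = np.abs(rng.normal(0, lambda_sd, len(latent))) if lambda_sd > 0 else np.zeros(len(latent))
    for g in marker_gene_ids:
        if g not in out.columns:
            raise KeyError(f"marker gene {g!r} not in expression matrix")
        out[g] = out[g] + lam * marker_loading
    for g, load in (loadings or {}).items():
        if g in marker_gene_ids:
            continue
        out[g] = out[g] + lam * load
    if truth is not None:
        truth.contamination = dict(zip(latent.index, lam))
    return out


def inject_sex_anomalies(
    latent: pd.DataFrame,
    covariates: pd.DataFrame,
    x_gene_ids: list[str],
    y_gene_ids: list[str],
    anomaly_list: list[tuple[str, str]],
    x0_shift: float = -1.0,
    xxy_x_shift: float = np.log2(1.5),
    xxy_y_shift: float = 2.0,
    truth: SimTruth | None = None,
) -> pd.DataFrame:
    """Inject sex-chromosome aneuploidies into selected samples.

    ``anomaly_list`` holds ``(sample_id, kind)`` with kind in
    ``{"X0", "XXY"}``.  X0 (a female missing one X) shifts X-linked genes
    by ``x0_shift`` log2 units (one copy instead of two = -1 by default);
    XXY (a male with an extra X) shifts X genes by ``+log2(1.5)`` and adds
    ``xxy_y_shift`` to Y genes, keeping the Y present.  Shift magnitudes
    are configurable defaults, not literature estimates.
    """
    out = latent.copy()
    sex = dict(zip(covariates["sample_id"], covariates["sex"]))
    for sample_id, kind in anomaly_list:
        if sample_id not in out.index:
            raise KeyError(f"sample {sample_id!r} not in expression matrix")
        if kind == "X0":
            if sex.get(sample_id) != "F":
                raise ValueError(f"X0 anomaly requires a female sample ({sample_id})")
            out.loc[sample_id, x_gene_ids] += x0_shift
        elif kind == "XXY":
            if sex.get(sample_id) != "M":
                raise ValueError(f"XXY anomaly requires a male sample ({sample_id})")
            out.loc[sample_id, x_gene_ids] += xxy_x_shift
            out.loc[sample_id, y_gene_ids] += xxy_y_shift
        else:
            raise ValueError(f"unknown anomaly kind {kind!r}")
    if truth is not None:
        truth.aneuploidies = list(anomaly_list)
    return out


def inject_swaps(
    expression: pd.DataFrame,
    n_swaps: int,
    seed: int = 0,
    truth: SimTruth | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Apply ``n_swaps`` disjoint label transpositions to expression rows.

    Genotype labels are untouched: after the swap, the expression row
    labelled ``a`` holds the data of sample ``b`` and vice versa.  Returns
    the permuted matrix and the row permutation applied (so companion
    RNA-derived arrays can be permuted identically).  The true pairing
    (expression label -> genotype label) is recorded in ``truth``.
    """
    n = len(expression)
    if n_swaps < 0 or 2 * n_swaps > n:
        raise ValueError("n_swaps out of range")
    rng = np.random.default_rng(seed)
    perm = np.arange(n)
    chosen = rng.choice(n, size=2 * n_swaps, replace=False)
    swapped_pairs = []
    for k in range(n_swaps):
        i, j = chosen[2 * k], chosen[2 * k + 1]
        perm[i], perm[j] = perm[j], perm[i]
        swapped_pairs.append((expression.index[i], expression.index[j]))
    out = pd.DataFrame(
        expression.to_numpy()[perm], index=expression.index,
        columns=expression.columns,
    )
    pairing = {
        str(expression.index[i]): str(expression.index[perm[i]]) for i in range(n)
    }
    if truth is not None:
        truth.true_pairing = pairing
        truth.swaps = swapped_pairs
    return out, perm
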