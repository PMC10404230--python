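"""Co-expression networks: bicor, signed WGCNA-style modules, paracliques.

Two network layers are built from the same expression matrix, exactly as
each is used downstream:

* a *signed* weighted network ``a_ij = ((1 + bicor_ij) / 2)^power`` whose
  soft-threshold power is the lowest one reaching a scale-free topology
  fit R^2 >= 0.9, clustered into modules via topological overlap; and
* an *unsigned* thresholded graph (edge iff ``|bicor| >= 0.5``) from which
  paracliques — maximum cliques grown by a proportional glom factor — are
  extracted.

The biweight midcorrelation (bicor) is a median/MAD-weighted robust
correlation: observations far from the median are smoothly down-weighted,
so single outliers barely move it where Pearson swings wildly.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Biweight midcorrelation
# ---------------------------------------------------------------------------

def _bicor_transform(x: np.ndarray) -> np.ndarray | None:
    """Biweight-transformed, unit-norm column; None if MAD is zero."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return None
    u = (x - med) / (9.0 * mad)
    w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
    xt = (x - med) * w
    norm = np.sqrt(np.sum(xt**2))
    if norm == 0:
        return None
    return xt / norm


def _pearson_transform(x: np.ndarray) -> np.ndarray | None:
    c = x - x.mean()
    norm = np.sqrt(np.sum(c**2))
    if norm == 0:
        return None
    return c / norm


def bicor(x: np.ndarray, y: np.ndarray) -> float:
    """Biweight midcorrelation of two vectors (n >= 4 observations).

    ``u_i = (x_i - med) / (9 MAD)``, weight ``(1 - u_i^2)^2`` inside the
    unit interval and 0 outside; the correlation is the normalized inner
    product of the weighted, median-centered vectors.  A variable with
    MAD = 0 falls back to Pearson (logged); if it is constant outright the
    value is undefined and NaN is returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("bicor needs two equal-length vectors, n >= 4")
    xs, ys = _bicor_transform(x), _bicor_transform(y)
    if xs is None or ys is None:
        logger.info("MAD = 0 for at least one variable; Pearson fallback")
        xs = xs if xs is not None else _pearson_transform(x)
        ys = ys if ys is not None else _pearson_transform(y)
        if xs is None or ys is None:
            logger.warning("constant vector: correlation undefined, returning NaN")
            return float("nan")
    return float(np.clip(xs @ ys, -1.0, 1.0))


def bicor_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Gene × gene bicor matrix of a samples × genes expression frame.

    Zero-MAD genes use Pearson standardization for every pair involving
    them (logged); fully constant genes get NaN rows/columns.
    """
    X = expr.to_numpy(dtype=float)
    if X.shape[0] < 4:
        raise ValueError("bicor needs at least 4 samples")
    n, g = X.shape
    cols = np.empty((n, g))
    dead = []
    fallback = 0
    for j in range(g):
        t = _bicor_transform(X[:, j])
        if t is None:
            t = _pearson_transform(X[:, j])
            fallback += 1
        if t is None:
            dead.append(j)
            t = np.zeros(n)
        cols[:, j] = t
    if fallback:
        logger.info("%d genes with MAD = 0 used Pearson standardization", fallback)
    C = np.clip(cols.T @ cols, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    for j in dead:
        C[j, :] = np.nan
        C[:, j] = np.nan
    return pd.DataFrame(C, index=expr.columns, columns=expr.columns)


# ---------------------------------------------------------------------------
# Signed network and scale-free fit
# ---------------------------------------------------------------------------

def signed_adjacency(corr: pd.DataFrame | np.ndarray, power: float) -> np.ndarray:
    """Signed adjacency ``((1 + corr) / 2)^power`` with zero diagonal."""
    C = np.asarray(corr, dtype=float)
    A = ((1.0 + C) / 2.0) ** power
    np.fill_diagonal(A, 0.0)
    return A


def scale_free_fit(adjacency: np.ndarray, n_bins: int = 10) -> tuple[float, float, float]:
    """Signed scale-free topology fit of a weighted network.

    Connectivities ``k_i = sum_j a_ij`` are binned into ``n_bins``
    equal-width bins; log10(frequency) is regressed on log10(bin mean k)
    over non-empty bins.  Returns ``(signed R^2, mean k, median k)`` where
    the sign is ``-sign(slope)`` — positive when the degree distribution
    decays, as a scale-free network's does.
    """
    k = np.asarray(adjacency).sum(axis=0)
    mean_k, median_k = float(k.mean()), float(np.median(k))
    if np.ptp(k) == 0:
        return 0.0, mean_k, median_k
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        kb = k[mask].mean()
        if kb <= 0:
            continue
        xs.append(np.log10(kb))
        ys.append(np.log10(mask.sum()))
    if len(xs) < 3:
        return 0.0, mean_k, median_k
    xs, ys = np.array(xs), np.array(ys)
    slope, intercept = np.polyfit(xs, ys, 1)
    yhat = slope * xs + intercept
    ss_res = np.sum((ys - yhat) ** 2)
    ss_tot = np.sum((ys - ys.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(-np.sign(slope) * r2), mean_k, median_k


@dataclass
class SoftThresholdReport:
    """Per-power scale-free diagnostics and the selected power."""

    table: pd.DataFrame  # power, signed_r2, mean_k, median_k
    selected_power: int | None
    r2_target: float


def pick_soft_threshold(
    expr: pd.DataFrame,
    powers: tuple[int, ...] = tuple(range(1, 21)),
    r2_target: float = 0.9,
    n_bins: int = 10,
) -> SoftThresholdReport:
    """Select the lowest soft-threshold power whose signed scale-free fit
    R^2 reaches the target, on the bicor-based signed adjacency."""
    corr = bicor_matrix(expr).to_numpy()
    rows = []
    selected = None
    for p in powers:
        r2, mk, medk = scale_free_fit(signed_adjacency(corr, p), n_bins)
        rows.append((p, r2, mk, medk))
        if selected is None and r2 >= r2_target:
            selected = int(p)
    return SoftThresholdReport(
        pd.DataFrame(rows, columns=["power", "signed_r2", "mean_k", "median_k"]),
        selected,
        r2_target,
    )


# ---------------------------------------------------------------------------
# Modules (TOM clustering with a static cut)
# ---------------------------------------------------------------------------

@dataclass
class ModuleAssignment:
    """gene -> module label (0 = unassigned), labels ordered by size."""

    labels: pd.Series
    min_module_size: int

    def modules(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for g, l in self.labels.items():
            if l > 0:
                out.setdefault(int(l), []).append(g)
        return out


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a weighted adjacency (zero diagonal):
    ``TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)``."""
    A = np.asarray(adjacency, dtype=float)
    k = A.sum(axis=0)
    num = A @ A + A
    den = np.minimum.outer(k, k) + 1.0 - A
    T = num / den
    np.fill_diagonal(T, 1.0)
    return T


def detect_modules(
    expr: pd.DataFrame,
    power: int,
    min_module_size: int = 30,
    cut_height: float = 0.99,
) -> ModuleAssignment:
    """Simplified signed-network module detection.

    bicor -> signed adjacency -> TOM; average-linkage hierarchical
    clustering of 1 - TOM with a *static* cut at ``cut_height`` (a
    documented simplification of the dynamic hybrid tree cut).  Clusters
    at or above ``min_module_size`` become modules labelled 1..N by
    decreasing size; everything else is label 0.
    """
    corr = bicor_matrix(expr).to_numpy()
    A = signed_adjacency(corr, power)
    tom = topological_overlap(A)
    dis = 1.0 - tom
    dis = (dis + dis.T) / 2.0
    np.fill_diagonal(dis, 0.0)
    Z = linkage(squareform(dis, checks=False), method="average")
    raw = fcluster(Z, t=cut_height, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    keep = sizes[sizes >= min_module_size].index
    order = sorted(keep, key=lambda c: (-sizes[c], c))
    relabel = {c: i + 1 for i, c in enumerate(order)}
    labels = pd.Series(
        [relabel.get(c, 0) for c in raw], index=expr.columns, name="module"
    )
    return ModuleAssignment(labels, min_module_size)


# ---------------------------------------------------------------------------
# Paraclique extraction
# ---------------------------------------------------------------------------

@dataclass
class Paraclique:
    members: list[str]
    seed_size: int
    density: float

    @property
    def final_size(self) -> int:
        return len(self.members)


def _max_clique(G: nx.Graph) -> list:
    """Exact maximum clique via Bron–Kerbosch with pivoting; ties broken
    lexicographically for determinism."""
    best_key: tuple[int, tuple] | None = None
    best_clique: list = []
    for clique in nx.find_cliques(G):
        key = (-len(clique), tuple(sorted(map(str, clique))))
        if best_key is None or key < best_key:
            best_key, best_clique = key, sorted(clique, key=str)
    return best_clique


def _density(G: nx.Graph, members: list) -> float:
    s = len(members)
    if s < 2:
        return 1.0
    sub = G.subgraph(members)
    return sub.number_of_edges() / (s * (s - 1) / 2)


def _glom_threshold(size: int, glom: float, rule: str) -> int:
    if rule == "proportional":
        return math.ceil((1.0 - glom) * size)
    if rule == "missed_edges":
        return size - math.floor(glom * size)
    raise ValueError(f"unknown glom rule {rule!r}")


def _accrete(G: nx.Graph, seed: list, glom: float, rule: str) -> list:
    """Grow a clique by sequentially admitting the best-connected outside
    vertex that is adjacent to enough current members.

    One vertex per step (highest adjacency count, lexicographic
    tie-break), re-testing after each admission; this guarantees the
    emitted set's edge density is at least ``1 - glom``.
    """
    members = set(seed)
    while True:
        need = _glom_threshold(len(members), glom, rule)
        best_v, best_count = None, -1
        for v in G.nodes:
            if v in members:
                continue
            count = sum(1 for u in G[v] if u in members)
            if count >= need and (
                count > best_count
                or (count == best_count and str(v) < str(best_v))
            ):
                best_v, best_count = v, count
        if best_v is None:
            break
        members.add(best_v)
    return sorted(members, key=str)


def correlation_graph(
    corr: pd.DataFrame, threshold: float = 0.5
) -> nx.Graph:
    """Unsigned thresholded graph: edge iff ``|corr| >= threshold``."""
    C = corr.to_numpy()
    if not np.allclose(C, C.T, atol=1e-10, equal_nan=True):
        raise ValueError("correlation matrix must be symmetric")
    genes = list(corr.index)
    G = nx.Graph()
    G.add_nodes_from(genes)
    iu = np.triu_indices(len(genes), k=1)
    mask = np.abs(C[iu]) >= threshold
    G.add_edges_from(
        (genes[i], genes[j]) for i, j in zip(iu[0][mask], iu[1][mask])
    )
    return G


def paraclique_extract(
    corr: pd.DataFrame,
    threshold: float = 0.5,
    min_seed: int = 5,
    min_size: int = 10,
    glom: float = 0.2,
    max_vertices: int = 2000,
    glom_rule: str = "proportional",
) -> list[Paraclique]:
    """Extract paracliques from the unsigned |bicor| >= threshold graph.

    Repeatedly: find the exact maximum clique (stop when below
    ``min_seed``); grow it by glom-factor accretion (a vertex is admitted
    while adjacent to at least ``ceil((1 - glom) * |P|)`` current members
    — or ``|P| - floor(glom * |P|)`` under ``glom_rule='missed_edges'``);
    emit the paraclique if it reaches ``min_size``; remove its members
    and continue.  Exact maximum clique is exponential in the worst case,
    so graphs beyond ``max_vertices`` are rejected with advice to
    pre-filter rather than silently switching to a heuristic.
    """
    if len(corr) > max_vertices:
        raise ValueError(
            f"{len(corr)} vertices exceeds the exact max-clique bound "
            f"({max_vertices}); pre-filter genes or raise max_vertices"
        )
    G = correlation_graph(corr, threshold)
    out: list[Paraclique] = []
    while G.number_of_nodes() > 0:
        clique = _max_clique(G)
        if len(clique) < min_seed:
            break
        members = _accrete(G, clique, glom, glom_rule)
        if len(members) >= min_size:
            dens = _density(G, members)
            assert dens >= 1.0 - glom - 1e-12, "density invariant violated"
            out.append(Paraclique(members, seed_size=len(clique), density=dens))
        G.remove_nodes_from(members)
    return out
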