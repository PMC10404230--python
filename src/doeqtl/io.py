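"""File formats, run configuration and the viewer-style analysis bundle.

Tabular data travels as TSV with a small ``#``-prefixed header stating the
coordinate convention (1-based bp, inclusive cis windows); founder
probabilities live in a single HDF5 container with one dataset per
chromosome plus sample/marker index tables; gene sets are GMT.  The final
deliverable of a run is an *analysis bundle*: a directory mirroring the
field layout of the QTL-viewer data object (genoprobs, kinship, map,
markers, and a dataset record with annotations, covariates, expression and
LOD peaks), validated for internal consistency before being written.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .eqtl import KinshipSet
from .synthetic import (
    FOUNDER_LABELS,
    MARKER_MAP_COLUMNS,
    FounderProbs,
    validate_marker_map,
)

logger = logging.getLogger(__name__)

COORD_HEADER = "# coordinates: 1-based bp; cis windows inclusive"


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(COORD_HEADER + "\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_marker_map(marker_map: pd.DataFrame, path: str | Path) -> None:
    validate_marker_map(marker_map)
    write_table(marker_map[MARKER_MAP_COLUMNS], path)


def read_marker_map(path: str | Path) -> pd.DataFrame:
    mm = read_table(path)
    mm["chromosome"] = mm["chromosome"].astype(str)
    if len(mm) == 0:
        raise ValueError(f"{path}: empty marker map")
    validate_marker_map(mm)
    return mm


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    """Samples × features matrix with the sample id as first column."""
    out = df.copy()
    out.index.name = out.index.name or "sample_id"
    write_table(out.reset_index(), path)


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    if len(df) == 0:
        raise ValueError(f"{path}: matrix has no samples")
    first = df.columns[0]
    if df[first].duplicated().any():
        raise ValueError(f"{path}: duplicated sample ids")
    return df.set_index(first)


def write_covariates(cov: pd.DataFrame, path: str | Path) -> None:
    write_table(cov, path)


def read_covariates(path: str | Path) -> pd.DataFrame:
    cov = read_table(path)
    if cov["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicated sample ids in covariates")
    return cov


def write_annotations(annot: pd.DataFrame, path: str | Path) -> None:
    write_table(annot, path)


def read_annotations(path: str | Path) -> pd.DataFrame:
    annot = read_table(path)
    if annot["gene_id"].duplicated().any():
        raise ValueError(f"{path}: duplicated gene ids in annotations")
    annot["chromosome"] = annot["chromosome"].astype(str)
    return annot


# ---------------------------------------------------------------------------
# Founder-probability container (HDF5)
# ---------------------------------------------------------------------------

def write_probs(probs: FounderProbs, path: str | Path) -> None:
    """Single-file hierarchical container: /probs/<chrom> (n × 8 × M_c)
    datasets plus /samples and /markers index tables."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        grp = f.create_group("probs")
        for chrom in probs.chromosomes:
            grp.create_dataset(str(chrom), data=probs.chrom_values(chrom), track_times=False)
        f.create_dataset(
            "samples", data=np.array(probs.sample_ids, dtype="S"),
            track_times=False,
        )
        mk = f.create_group("markers")
        mk.create_dataset(
            "marker_id",
            data=probs.markers["marker_id"].astype(str).to_numpy(dtype="S"),
            track_times=False,
        )
        mk.create_dataset(
            "chromosome",
            data=probs.markers["chromosome"].astype(str).to_numpy(dtype="S"),
            track_times=False,
        )
        mk.create_dataset("position_bp", data=probs.markers["position_bp"].to_numpy(), track_times=False)
        mk.create_dataset("position_cM", data=probs.markers["position_cM"].to_numpy(), track_times=False)
        f.attrs["founder_labels"] = ",".join(probs.founder_labels)


def read_probs(path: str | Path) -> FounderProbs:
    with h5py.File(path, "r") as f:
        samples = [s.decode() for s in f["samples"][:]]
        if not samples:
            raise ValueError(f"{path}: container holds zero samples")
        markers = pd.DataFrame(
            {
                "marker_id": [m.decode() for m in f["markers/marker_id"][:]],
                "chromosome": [c.decode() for c in f["markers/chromosome"][:]],
                "position_bp": f["markers/position_bp"][:].astype(np.int64),
                "position_cM": f["markers/position_cM"][:],
            }
        )
        validate_marker_map(markers)
        blocks = []
        for chrom in dict.fromkeys(markers["chromosome"]):
            blocks.append(f["probs"][str(chrom)][:])
        values = np.concatenate(blocks, axis=2)
    probs = FounderProbs(values, samples, markers)
    probs.validate()
    return probs


# ---------------------------------------------------------------------------
# Peaks and gene sets
# ---------------------------------------------------------------------------

PEAK_COLUMNS = [
    "gene_id", "chromosome", "peak_marker", "peak_bp", "lod", "cis_trans",
] + [f"effect_{l}" for l in FOUNDER_LABELS]


def peaks_to_frame(peaks: list) -> pd.DataFrame:
    """EqtlPeak list -> 14-column table (8 founder-effect columns)."""
    rows = []
    for p in peaks:
        eff = p.founder_effects if p.founder_effects is not None else [np.nan] * 8
        rows.append(
            [p.gene_id, p.chromosome, p.peak_marker_id, p.peak_bp, p.lod,
             p.cis_trans] + list(eff)
        )
    return pd.DataFrame(rows, columns=PEAK_COLUMNS)


def write_peaks(peaks: pd.DataFrame | list, path: str | Path) -> None:
    df = peaks if isinstance(peaks, pd.DataFrame) else peaks_to_frame(peaks)
    if list(df.columns) != PEAK_COLUMNS:
        raise ValueError("peak table has unexpected columns")
    write_table(df, path)


def read_peaks(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    if list(df.columns) != PEAK_COLUMNS:
        raise ValueError(f"{path}: malformed peak table header")
    df["chromosome"] = df["chromosome"].astype(str)
    return df


def write_gene_sets(sets: dict[str, list[str]], path: str | Path) -> None:
    """GMT: one line per set — name, description, tab-separated gene ids."""
    if len(set(sets)) != len(sets):  # dict keys are unique by construction
        raise ValueError("duplicate gene-set names")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, genes in sets.items():
            if "\t" in name:
                raise ValueError(f"gene-set name contains a tab: {name!r}")
            fh.write("\t".join([name, name] + list(genes)) + "\n")


def read_gene_sets(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: malformed GMT line")
            if parts[0] in sets:
                raise ValueError(f"{path}: duplicate gene-set name {parts[0]!r}")
            sets[parts[0]] = parts[2:]
    return sets


# ---------------------------------------------------------------------------
# Kinship container
# ---------------------------------------------------------------------------

def write_kinship(kinship: KinshipSet, sample_ids: list[str], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("overall", data=kinship.overall, track_times=False)
        grp = f.create_group("loco")
        for chrom, K in kinship.loco.items():
            grp.create_dataset(str(chrom), data=K, track_times=False)
        f.create_dataset("samples", data=np.array(sample_ids, dtype="S"), track_times=False)


def read_kinship(path: str | Path) -> tuple[KinshipSet, list[str]]:
    with h5py.File(path, "r") as f:
        overall = f["overall"][:]
        loco = {c: f["loco"][c][:] for c in f["loco"]}
        samples = [s.decode() for s in f["samples"][:]]
    return KinshipSet(overall, loco), samples


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All knobs of a synthetic end-to-end run; YAML/JSON round-trippable."""

    seed: int = 0
    # synthetic genome / cohort
    n_samples: int = 96
    n_genes: int = 200
    n_chromosomes: int = 3
    chrom_length_mb: float = 100.0
    markers_per_chromosome: int = 40
    crossover_density_per_morgan: float = 30.0
    prob_blur_alpha: float = 0.05
    # gene architecture
    qtl_var_frac: float = 0.2
    h2_polygenic: float = 0.4
    frac_with_qtl: float = 0.5
    noise_sd: float = 1.0
    # corruption
    n_swaps: int = 2
    contamination_lambda_sd: float = 0.5
    # counts
    lib_size_mean: float = 5e6
    lib_size_cv: float = 0.2
    nb_dispersion: float = 0.05
    # thresholds
    lod_threshold: float = 7.0
    cis_window_bp: int = 2_000_000
    min_accept_r: float = 0.8
    bicor_edge_threshold: float = 0.5
    scale_free_r2_target: float = 0.9
    min_module_size: int = 30
    module_cut_height: float = 0.99
    paraclique_min_seed: int = 5
    paraclique_min_size: int = 10
    paraclique_glom: float = 0.2
    # network sizing: cap the number of most-variable genes fed to networks
    network_top_genes: int = 200
    # stage toggles
    run_mediation: bool = True
    run_network: bool = True
    display_name: str = "DO synthetic striatum"

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        payload = dataclasses.asdict(self)
        with open(path, "w") as fh:
            if path.suffix == ".json":
                json.dump(payload, fh, indent=2, sort_keys=True)
            else:
                yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            payload = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


# ---------------------------------------------------------------------------
# Analysis bundle
# ---------------------------------------------------------------------------

BUNDLE_ELEMENTS = {
    "genoprobs": "genoprobs.h5",
    "kinship": "kinship.h5",
    "markers": "markers.tsv",
    "annot_mrna": "dataset/annot_mrna.tsv",
    "annot_samples": "dataset/annot_samples.tsv",
    "covar_info": "dataset/covar_info.tsv",
    "covar_matrix": "dataset/covar_matrix.tsv",
    "data": "dataset/data.tsv",
    "lod_peaks": "dataset/lod_peaks.tsv",
    "dataset_info": "dataset/dataset.json",
}


def assemble_bundle(
    outdir: str | Path,
    probs: FounderProbs,
    kinship: KinshipSet,
    annotations: pd.DataFrame,
    covariates: pd.DataFrame,
    covar_matrix: pd.DataFrame,
    expression: pd.DataFrame,
    peaks: pd.DataFrame,
    config: RunConfig,
    datatype: str = "mRNA",
) -> Path:
    """Write a validated viewer-style analysis bundle.

    The directory mirrors the viewer object's elements: genoprobs,
    kinship (overall + LOCO), the marker map, and a dataset record with
    mRNA annotations, sample annotations, covariate info and matrix, the
    expression matrix used for mapping, and the LOD peak table.  Element
    presence, sample-id consistency and the peak threshold are validated
    before anything is written; a manifest records config, seed and code
    version.
    """
    _validate_bundle_inputs(probs, kinship, covariates, covar_matrix,
                            expression, peaks, config)
    outdir = Path(outdir)
    (outdir / "dataset").mkdir(parents=True, exist_ok=True)
    write_probs(probs, outdir / BUNDLE_ELEMENTS["genoprobs"])
    write_kinship(kinship, probs.sample_ids, outdir / BUNDLE_ELEMENTS["kinship"])
    write_marker_map(probs.markers, outdir / BUNDLE_ELEMENTS["markers"])
    write_annotations(annotations, outdir / BUNDLE_ELEMENTS["annot_mrna"])
    write_covariates(covariates, outdir / BUNDLE_ELEMENTS["annot_samples"])
    covar_info = pd.DataFrame(
        {
            "column": list(covar_matrix.columns),
            "display_name": list(covar_matrix.columns),
        }
    )
    write_table(covar_info, outdir / BUNDLE_ELEMENTS["covar_info"])
    write_matrix(covar_matrix, outdir / BUNDLE_ELEMENTS["covar_matrix"])
    write_matrix(expression, outdir / BUNDLE_ELEMENTS["data"])
    write_peaks(peaks, outdir / BUNDLE_ELEMENTS["lod_peaks"])
    with open(outdir / BUNDLE_ELEMENTS["dataset_info"], "w") as fh:
        json.dump(
            {
                "datatype": datatype,
                "display.name": config.display_name,
                "annotation.source": "synthetic",
                "lod.threshold": config.lod_threshold,
            },
            fh, indent=2, sort_keys=True,
        )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(
            {
                "config": dataclasses.asdict(config),
                "seed": config.seed,
                "code_version": __version__,
            },
            fh, indent=2, sort_keys=True,
        )
    return outdir


def _validate_bundle_inputs(probs, kinship, covariates, covar_matrix,
                            expression, peaks, config) -> None:
    ids = list(probs.sample_ids)
    for name, other in (
        ("covar.matrix", list(covar_matrix.index)),
        ("data", list(expression.index)),
        ("annot.samples", list(covariates["sample_id"])),
    ):
        if list(other) != ids:
            offenders = sorted(set(ids).symmetric_difference(other))[:5]
            raise ValueError(
                f"sample ids of {name} disagree with genoprobs "
                f"(first offenders: {offenders})"
            )
    if kinship.overall.shape[0] != len(ids):
        raise ValueError("kinship dimension does not match sample count")
    if not kinship.loco:
        raise ValueError("bundle element missing: kinship (LOCO matrices)")
    if len(peaks) and (peaks["lod"] <= config.lod_threshold).any():
        raise ValueError("lod.peaks contains entries at or below the threshold")


def validate_bundle(path: str | Path) -> dict:
    """Re-open a bundle on disk and check its invariants; returns the
    manifest."""
    path = Path(path)
    for name, rel in BUNDLE_ELEMENTS.items():
        if not (path / rel).exists():
            raise ValueError(f"bundle element missing: {name} ({rel})")
    probs = read_probs(path / BUNDLE_ELEMENTS["genoprobs"])
    kinship, ksamples = read_kinship(path / BUNDLE_ELEMENTS["kinship"])
    expr = read_matrix(path / BUNDLE_ELEMENTS["data"])
    covm = read_matrix(path / BUNDLE_ELEMENTS["covar_matrix"])
    covariates = read_covariates(path / BUNDLE_ELEMENTS["annot_samples"])
    peaks = read_peaks(path / BUNDLE_ELEMENTS["lod_peaks"])
    with open(path / BUNDLE_ELEMENTS["dataset_info"]) as fh:
        info = json.load(fh)
    ids = probs.sample_ids
    if ksamples != ids or list(expr.index) != ids or list(covm.index) != ids \
            or list(covariates["sample_id"]) != ids:
        raise ValueError("sample ids inconsistent across bundle elements")
    if len(peaks) and (peaks["lod"] <= info["lod.threshold"]).any():
        raise ValueError("lod.peaks below recorded threshold")
    with open(path / "manifest.json") as fh:
        return json.load(fh)
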