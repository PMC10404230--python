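"""End-to-end orchestration of the synthetic eQTL study.

Each stage function consumes the on-disk outputs of earlier stages and
writes its own, so stages are independently re-runnable from the CLI; the
whole chain (simulate -> preprocess -> scan -> mediate -> network ->
paraclique -> bundle) is deterministic given one seed.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import coexpression, eqtl, io, mediation, preprocess, synthetic

logger = logging.getLogger(__name__)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent child seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _timed(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            out = fn(*args, **kwargs)
            logger.info("stage %s finished in %.1fs", name, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

@_timed("simulate")
def stage_simulate(cfg: io.RunConfig, outdir: str | Path) -> Path:
    """Generate the full synthetic study and write its raw inputs.

    Emits: marker map, two founder-probability containers (array-side
    clean; RNA-side blurred and swap-permuted, the analog of an
    RNA-derived haplotype reconstruction), transcript counts with a
    transcript-to-gene map, covariates, gene annotations, an SDP table and
    ground-truth tables.
    """
    outdir = Path(outdir)
    seeds = _spawn_seeds(cfg.seed, 10)
    mm = synthetic.make_marker_map(
        cfg.n_chromosomes, cfg.chrom_length_mb, cfg.markers_per_chromosome,
        seed=seeds[0],
    )
    probs = synthetic.simulate_founder_mosaics(
        mm, cfg.n_samples, cfg.crossover_density_per_morgan,
        prob_blur_alpha=0.0, seed=seeds[1],
    )
    covariates = synthetic.make_covariates(probs.sample_ids, seed=seeds[2])
    archs = synthetic.random_architectures(
        mm, cfg.n_genes, cfg.qtl_var_frac, cfg.h2_polygenic,
        frac_with_qtl=cfg.frac_with_qtl, seed=seeds[3],
    )
    # two contamination marker genes (Kl / Ttr analogs) on top
    archs.append(synthetic.GeneArchitecture("Kl_like", "1", 0))
    archs.append(synthetic.GeneArchitecture("Ttr_like", "1", 0))
    latent, truth = synthetic.simulate_expression(
        probs, archs, covariates, noise_sd=cfg.noise_sd, seed=seeds[4]
    )
    latent = synthetic.inject_contamination(
        latent, ["Kl_like", "Ttr_like"], cfg.contamination_lambda_sd,
        seed=seeds[5], truth=truth,
    )
    swapped, perm = synthetic.inject_swaps(
        latent, cfg.n_swaps, seed=seeds[6], truth=truth
    )
    counts = synthetic.latent_to_counts(
        swapped, cfg.lib_size_mean, cfg.lib_size_cv, cfg.nb_dispersion,
        seed=seeds[7],
    )
    # RNA-side haplotype reconstruction: blurred and carrying the same
    # label permutation as the expression data
    rna_probs = synthetic.simulate_founder_mosaics(
        mm, cfg.n_samples, cfg.crossover_density_per_morgan,
        prob_blur_alpha=0.0, seed=seeds[1],
    )
    rna_values = (1 - cfg.prob_blur_alpha) * rna_probs.values[perm] \
        + cfg.prob_blur_alpha / synthetic.N_FOUNDERS
    rna_probs = synthetic.FounderProbs(rna_values, probs.sample_ids, mm)

    # transcript-level counts: split each gene into 1-2 transcripts
    rng = np.random.default_rng(seeds[8])
    tx_rows, tx_cols = [], []
    tx_data = []
    for g in counts.columns:
        n_tx = int(rng.integers(1, 3))
        split = rng.dirichlet(np.ones(n_tx))
        for t in range(n_tx):
            tx_cols.append(f"{g}.t{t + 1}")
            tx_rows.append(g)
            tx_data.append(np.round(counts[g].to_numpy() * split[t]).astype(int))
    tx_counts = pd.DataFrame(
        np.column_stack(tx_data), index=counts.index, columns=tx_cols
    )
    tx2gene = pd.DataFrame({"transcript_id": tx_cols, "gene_id": tx_rows})

    annotations = pd.DataFrame(
        {
            "gene_id": [a.gene_id for a in archs],
            "symbol": [a.gene_id for a in archs],
            "chromosome": [a.chromosome for a in archs],
            "tss_bp": [a.tss_bp for a in archs],
            "strand": "+",
        }
    )
    sdp = _random_sdp_table(mm, n_per_chrom=25, seed=seeds[9])

    io.write_marker_map(mm, outdir / "markers.tsv")
    io.write_probs(probs, outdir / "genoprobs_array.h5")
    io.write_probs(rna_probs, outdir / "genoprobs_rnaseq.h5")
    io.write_matrix(tx_counts, outdir / "transcript_counts.tsv")
    io.write_table(tx2gene, outdir / "tx2gene.tsv")
    io.write_covariates(covariates, outdir / "covariates.tsv")
    io.write_annotations(annotations, outdir / "annotations.tsv")
    io.write_table(sdp, outdir / "sdp.tsv")
    truth_table = pd.DataFrame(
        {
            "gene_id": [a.gene_id for a in archs],
            "causal_marker_id": [a.causal_marker_id or "" for a in archs],
            "qtl_var_frac": [a.qtl_var_frac for a in archs],
            "h2_polygenic": [a.h2_polygenic for a in archs],
        }
    )
    io.write_table(truth_table, outdir / "truth_genes.tsv")
    pairing = pd.DataFrame(
        sorted(truth.true_pairing.items()), columns=["expression_id", "genotype_id"]
    )
    io.write_table(pairing, outdir / "truth_pairing.tsv")
    contam = pd.DataFrame(
        {"sample_id": list(truth.contamination),
         "lambda": list(truth.contamination.values())}
    )
    io.write_table(contam, outdir / "truth_contamination.tsv")
    return outdir


def _random_sdp_table(mm: pd.DataFrame, n_per_chrom: int, seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, sub in mm.groupby("chromosome", sort=False):
        lo = int(sub["position_bp"].min())
        hi = int(sub["position_bp"].max())
        pos = np.sort(rng.integers(lo, hi + 1, size=n_per_chrom))
        for i, p in enumerate(pos):
            sdp = int(rng.integers(1, 2**synthetic.N_FOUNDERS - 1))
            rows.append((f"snp{chrom}_{i + 1}", str(chrom), int(p), sdp))
    return pd.DataFrame(rows, columns=["snp_id", "chromosome", "position_bp", "sdp"])


# ---------------------------------------------------------------------------
# preprocess
# ---------------------------------------------------------------------------

@_timed("preprocess")
def stage_preprocess(cfg: io.RunConfig, simdir: str | Path, outdir: str | Path) -> Path:
    """Counts + metadata -> mixup-corrected, residualized expression."""
    simdir, outdir = Path(simdir), Path(outdir)
    tx_counts = io.read_matrix(simdir / "transcript_counts.tsv")
    tx2gene = io.read_table(simdir / "tx2gene.tsv")
    covariates = io.read_covariates(simdir / "covariates.tsv")
    geno = io.read_probs(simdir / "genoprobs_array.h5")
    rna = io.read_probs(simdir / "genoprobs_rnaseq.h5")

    counts = preprocess.sum_transcripts_to_genes(tx_counts, tx2gene)
    factors = preprocess.tmm_factors(counts)
    expr = preprocess.log_cpm(counts, factors)

    corr = preprocess.correlate_haplotype_probs(rna, geno)
    assignment = preprocess.resolve_sample_mixups(corr, cfg.min_accept_r)
    # reorder expression rows so they match the genotype labels
    inverse = {g: e for e, g in assignment.assignment.items()}
    expr = expr.loc[[inverse[g] for g in geno.sample_ids]]
    expr.index = pd.Index(geno.sample_ids, name="sample_id")

    scores = preprocess.contamination_scores(expr, ("Kl_like", "Ttr_like"))
    resid = preprocess.residualize(expr, scores)

    io.write_matrix(expr, outdir / "expression_logcpm.tsv")
    io.write_matrix(resid, outdir / "expression_residualized.tsv")
    io.write_table(
        factors.reset_index().rename(columns={"index": "sample_id"}),
        outdir / "tmm_factors.tsv",
    )
    io.write_table(
        pd.DataFrame(
            {
                "sample_id": list(assignment.assignment),
                "assigned_genotype_id": list(assignment.assignment.values()),
                "correlation": [assignment.pair_correlation[s]
                                for s in assignment.assignment],
            }
        ),
        outdir / "sample_assignment.tsv",
    )
    io.write_table(
        pd.DataFrame({"sample_id": scores.index, "score": scores.to_numpy()}),
        outdir / "contamination_scores.tsv",
    )
    return outdir


# ---------------------------------------------------------------------------
# scan
# ---------------------------------------------------------------------------

@_timed("scan")
def stage_scan(cfg: io.RunConfig, simdir: str | Path, predir: str | Path,
               outdir: str | Path) -> Path:
    """LOCO-kinship genome scans for every gene; peaks, effects, gene sets."""
    simdir, predir, outdir = Path(simdir), Path(predir), Path(outdir)
    probs = io.read_probs(simdir / "genoprobs_array.h5")
    covariates = io.read_covariates(simdir / "covariates.tsv")
    annotations = io.read_annotations(simdir / "annotations.tsv")
    expr = io.read_matrix(predir / "expression_residualized.tsv")
    expr = expr.loc[probs.sample_ids]
    kinship = eqtl.kinship_from_probs(probs, loco=True)
    X, names = eqtl.covariate_design(covariates)
    annot = annotations.set_index("gene_id")
    all_peaks: list[eqtl.EqtlPeak] = []
    her_rows = []
    for gene in expr.columns:
        y = expr[gene].to_numpy()
        curve = eqtl.scan_haplotypes(y, probs, X, kinship, gene_id=gene)
        her_rows.append((gene, eqtl.heritability(y, X, kinship)))
        for p in eqtl.find_peaks(curve, cfg.lod_threshold):
            p.cis_trans = eqtl.classify_cis_trans(
                p, str(annot.loc[gene, "chromosome"]),
                int(annot.loc[gene, "tss_bp"]), cfg.cis_window_bp,
            )
            p.founder_effects = eqtl.founder_effects_at(
                p.peak_marker_id, y, probs, X, kinship
            )
            all_peaks.append(p)
    peaks_df = io.peaks_to_frame(all_peaks)
    io.write_peaks(peaks_df, outdir / "lod_peaks.tsv")
    io.write_table(
        pd.DataFrame(her_rows, columns=["gene_id", "heritability"]),
        outdir / "heritability.tsv",
    )
    io.write_gene_sets(eqtl.export_gene_sets(peaks_df), outdir / "eqtl_sets.gmt")
    return outdir


# ---------------------------------------------------------------------------
# mediate / snp association
# ---------------------------------------------------------------------------

@_timed("mediate")
def stage_mediate(cfg: io.RunConfig, simdir: str | Path, predir: str | Path,
                  scandir: str | Path, outdir: str | Path,
                  n_targets: int = 3) -> Path:
    """Mediation of the strongest peaks against all other genes."""
    simdir, predir, scandir, outdir = map(Path, (simdir, predir, scandir, outdir))
    probs = io.read_probs(simdir / "genoprobs_array.h5")
    covariates = io.read_covariates(simdir / "covariates.tsv")
    expr = io.read_matrix(predir / "expression_residualized.tsv").loc[probs.sample_ids]
    peaks = io.read_peaks(scandir / "lod_peaks.tsv")
    kinship = eqtl.kinship_from_probs(probs, loco=True)
    X, _ = eqtl.covariate_design(covariates)
    top = peaks.sort_values("lod", ascending=False).head(n_targets)
    frames = []
    for _, row in top.iterrows():
        gene = row["gene_id"]
        res = mediation.mediate(
            expr[gene].to_numpy(), row["peak_marker"],
            expr.drop(columns=[gene]), probs, X, kinship, target_gene=gene,
        )
        t = res.table.copy()
        t.insert(0, "target_gene", gene)
        t.insert(1, "peak_marker", res.peak_marker)
        t.insert(2, "baseline_lod", res.baseline_lod)
        frames.append(t)
    io.write_table(
        pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["target_gene", "peak_marker", "baseline_lod",
                     "mediator_gene", "conditioned_lod", "lod_drop", "flag"]
        ),
        outdir / "mediation.tsv",
    )
    return outdir


@_timed("snp_assoc")
def stage_snp_assoc(cfg: io.RunConfig, simdir: str | Path, predir: str | Path,
                    scandir: str | Path, outdir: str | Path,
                    window_bp: int = 10_000_000) -> Path:
    """SNP association within the top peak's interval."""
    simdir, predir, scandir, outdir = map(Path, (simdir, predir, scandir, outdir))
    probs = io.read_probs(simdir / "genoprobs_array.h5")
    covariates = io.read_covariates(simdir / "covariates.tsv")
    expr = io.read_matrix(predir / "expression_residualized.tsv").loc[probs.sample_ids]
    peaks = io.read_peaks(scandir / "lod_peaks.tsv")
    sdp = io.read_table(simdir / "sdp.tsv")
    sdp["chromosome"] = sdp["chromosome"].astype(str)
    kinship = eqtl.kinship_from_probs(probs, loco=True)
    X, _ = eqtl.covariate_design(covariates)
    frames = []
    for _, row in peaks.sort_values("lod", ascending=False).head(3).iterrows():
        region = (
            str(row["chromosome"]),
            int(row["peak_bp"]) - window_bp,
            int(row["peak_bp"]) + window_bp,
        )
        t = eqtl.snp_association(
            expr[row["gene_id"]].to_numpy(), probs, sdp, region, X, kinship
        )
        t.insert(0, "gene_id", row["gene_id"])
        frames.append(t)
    io.write_table(
        pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["gene_id", "snp_id", "chromosome", "position_bp", "lod"]
        ),
        outdir / "snp_association.tsv",
    )
    return outdir


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def _network_expression(cfg: io.RunConfig, predir: Path) -> pd.DataFrame:
    expr = io.read_matrix(predir / "expression_residualized.tsv")
    variances = expr.var(axis=0)
    top = variances.sort_values(ascending=False).head(cfg.network_top_genes).index
    return expr[sorted(top)]


@_timed("network")
def stage_network(cfg: io.RunConfig, predir: str | Path, outdir: str | Path) -> Path:
    """Soft-threshold selection and module detection on the top genes."""
    predir, outdir = Path(predir), Path(outdir)
    expr = _network_expression(cfg, predir)
    report = coexpression.pick_soft_threshold(
        expr, r2_target=cfg.scale_free_r2_target
    )
    power = report.selected_power if report.selected_power is not None else 6
    modules = coexpression.detect_modules(
        expr, power, cfg.min_module_size, cfg.module_cut_height
    )
    io.write_table(report.table, outdir / "soft_threshold.tsv")
    io.write_table(
        pd.DataFrame(
            {"gene_id": modules.labels.index, "module": modules.labels.to_numpy()}
        ),
        outdir / "modules.tsv",
    )
    io.write_gene_sets(
        {f"module-{m}": genes for m, genes in modules.modules().items()}
        or {"module-none": []},
        outdir / "module_sets.gmt",
    )
    return outdir


@_timed("paraclique")
def stage_paraclique(cfg: io.RunConfig, predir: str | Path, outdir: str | Path) -> Path:
    predir, outdir = Path(predir), Path(outdir)
    expr = _network_expression(cfg, predir)
    corr = coexpression.bicor_matrix(expr)
    cliques = coexpression.paraclique_extract(
        corr, cfg.bicor_edge_threshold, cfg.paraclique_min_seed,
        cfg.paraclique_min_size, cfg.paraclique_glom,
    )
    rows = [
        (i + 1, p.seed_size, p.final_size, p.density, ";".join(p.members))
        for i, p in enumerate(cliques)
    ]
    io.write_table(
        pd.DataFrame(
            rows, columns=["paraclique", "seed_size", "final_size", "density",
                           "members"]
        ),
        outdir / "paracliques.tsv",
    )
    io.write_gene_sets(
        {f"paraclique-{i + 1}": p.members for i, p in enumerate(cliques)}
        or {"paraclique-none": []},
        outdir / "paraclique_sets.gmt",
    )
    return outdir


# ---------------------------------------------------------------------------
# bundle + full run
# ---------------------------------------------------------------------------

@_timed("bundle")
def stage_bundle(cfg: io.RunConfig, simdir: str | Path, predir: str | Path,
                 scandir: str | Path, outdir: str | Path) -> Path:
    simdir, predir, scandir, outdir = map(Path, (simdir, predir, scandir, outdir))
    probs = io.read_probs(simdir / "genoprobs_array.h5")
    kinship = eqtl.kinship_from_probs(probs, loco=True)
    covariates = io.read_covariates(simdir / "covariates.tsv")
    annotations = io.read_annotations(simdir / "annotations.tsv")
    expr = io.read_matrix(predir / "expression_residualized.tsv").loc[probs.sample_ids]
    peaks = io.read_peaks(scandir / "lod_peaks.tsv")
    X, names = eqtl.covariate_design(covariates)
    covar_matrix = pd.DataFrame(
        X[:, 1:], index=pd.Index(probs.sample_ids, name="sample_id"),
        columns=names[1:],
    )
    return io.assemble_bundle(
        outdir, probs, kinship, annotations, covariates, covar_matrix,
        expr, peaks, cfg,
    )


def run_pipeline(cfg: io.RunConfig, outdir: str | Path) -> Path:
    """Run every stage in order under one output directory."""
    outdir = Path(outdir)
    stage_simulate(cfg, outdir / "sim")
    stage_preprocess(cfg, outdir / "sim", outdir / "pre")
    stage_scan(cfg, outdir / "sim", outdir / "pre", outdir / "scan")
    if cfg.run_mediation:
        stage_mediate(cfg, outdir / "sim", outdir / "pre", outdir / "scan",
                      outdir / "mediation")
        stage_snp_assoc(cfg, outdir / "sim", outdir / "pre", outdir / "scan",
                        outdir / "snp")
    if cfg.run_network:
        stage_network(cfg, outdir / "pre", outdir / "network")
        stage_paraclique(cfg, outdir / "pre", outdir / "network")
    stage_bundle(cfg, outdir / "sim", outdir / "pre", outdir / "scan",
                 outdir / "bundle")
    return outdir
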