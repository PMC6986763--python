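"""End-to-end pipeline over the synthetic study.

``run(config, outdir)`` executes every stage in dependency order on a
generated dataset — fragment processing, peak calling with replicate
confirmation, consensus building, counting/FPKM, differential accessibility
per mutant, regulatory-element annotation, trajectory clustering, priming
statistics and motif analysis — writing each stage's tables as TSV under
``outdir`` plus a JSON manifest with the resolved configuration, seed and
input digests.  All stage parameters default to the published procedural
constants (130 bp NFR cutoff, 20 bp bins, FDR 5%, |log2FC| 1.5, k = 5,
2 kb promoters, 1 kb distal, 20 kb links, 5 quintiles, 10 score bins,
100 heatmap quantiles).
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate, dynamics, fragments, motifs, peaks, priming, quantify
from .io import write_manifest, write_tsv
from .simulate import (MUTANTS, SimulationConfig, generate_all_fragments,
                       generate_annotation, generate_chip_and_sequence,
                       generate_control_fragments, generate_expression)


@dataclass
class PipelineConfig:
    """Resolved stage parameters; defaults are the published constants."""

    seed: int = 0
    nfr_cutoff: int = 130
    bin_size: int = 20
    fdr: float = 0.05
    lfc_threshold: float = 1.5
    k: int = 5
    promoter_window: int = 2000
    distal_min: int = 1000
    link_max: int = 20_000
    n_quintiles: int = 5
    n_score_bins: int = 10
    n_quantiles: int = 100
    min_peak_width: int = 100
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self):
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**self.simulation)
        if self.simulation.seed != self.seed:
            object.__setattr__(self, "simulation",
                               self.simulation.with_(seed=self.seed))


def _digest(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        pd.util.hash_pandas_object(df, index=False).to_numpy().tobytes()
    ).hexdigest()[:16]


def run(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the full pipeline; returns a dict of in-memory results.

    Tables land under ``outdir`` (TSV), the manifest in ``manifest.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    chrom_sizes = sim.chrom_sizes
    results: dict = {}

    # --- simulate -----------------------------------------------------------
    truth = generate_annotation(sim)
    expression = generate_expression(sim, truth)
    chip, signal, seqs = generate_chip_and_sequence(sim, truth)
    raw_frags = generate_all_fragments(sim, truth)
    control_raw = generate_control_fragments(sim)
    results["truth"] = truth

    # --- fragment processing ------------------------------------------------
    nfr, nuc, dropped, lib_total = {}, {}, {}, {}
    for name, df in raw_frags.items():
        adj, n_drop = fragments.adjust_cut_sites(df)
        dropped[name] = n_drop
        lib_total[name] = len(adj)   # size factors use total, not NFR, counts
        nfr[name], nuc[name] = fragments.split_by_size(adj, config.nfr_cutoff)
    control_adj, _ = fragments.adjust_cut_sites(control_raw)
    control_nfr, _ = fragments.split_by_size(control_adj, config.nfr_cutoff)

    stage_of = {}
    for name in raw_frags:
        cond, stage, _rep = name.split("_")
        stage_of[name] = (cond, stage)

    # --- peak calling -------------------------------------------------------
    control_track = fragments.event_count_track(control_nfr, chrom_sizes, config.bin_size)
    replicated = {}
    for stage in sim.stages:
        reps = [n for n, (c, s) in stage_of.items() if c == "wt" and s == stage]
        pooled_frags = pd.concat([nfr[r] for r in reps], ignore_index=True)
        pooled_track = fragments.event_count_track(pooled_frags, chrom_sizes, config.bin_size)
        pooled_peaks = peaks.call_peaks(pooled_track, control_track, fdr=config.fdr,
                                        min_width=config.min_peak_width,
                                        name_prefix=f"{stage}_pooled")
        rep_peak_sets = []
        for r in reps:
            t = fragments.event_count_track(nfr[r], chrom_sizes, config.bin_size)
            rep_peak_sets.append(peaks.call_peaks(t, control_track, fdr=config.fdr,
                                                  min_width=config.min_peak_width,
                                                  name_prefix=r))
        replicated[stage] = peaks.confirm_replicated(pooled_peaks, rep_peak_sets)
    consensus = peaks.build_consensus(replicated)
    results["consensus"] = consensus
    write_tsv(consensus, outdir / "consensus_peaks.tsv")

    # --- counting, FPKM, clustering ----------------------------------------
    wt_samples = {n: nfr[n] for n, (c, _s) in stage_of.items() if c == "wt"}
    counts = quantify.count_over_peaks(consensus[["chrom", "start", "end", "name"]],
                                       wt_samples)
    widths = (consensus["end"] - consensus["start"]).to_numpy()
    stage_map = {n: stage_of[n][1] for n in wt_samples}
    fpkm_stage = quantify.fpkm(counts, widths,
                               library_sizes={n: lib_total[n] for n in wt_samples},
                               stage_of_sample=stage_map)
    fpkm_stage = fpkm_stage[[s for s in sim.stages]]
    write_tsv(fpkm_stage.reset_index(names="peak_id"), outdir / "fpkm_by_stage.tsv")
    results["counts"], results["fpkm"] = counts, fpkm_stage

    clust = dynamics.cluster_dynamics(fpkm_stage, k=config.k, seed=config.seed)
    qmat = dynamics.quantile_bin(fpkm_stage, n_quantiles=config.n_quantiles)
    results["clusters"] = clust
    write_tsv(pd.DataFrame({"peak_id": fpkm_stage.index, "cluster": clust.labels}),
              outdir / "cluster_labels.tsv")
    write_tsv(pd.DataFrame(qmat, index=fpkm_stage.index, columns=fpkm_stage.columns)
              .reset_index(names="peak_id"), outdir / "quantile_matrix.tsv")

    # --- differential accessibility per mutant ------------------------------
    mutant_stage = sim.mutant_stage
    wt_ref = [n for n, (c, s) in stage_of.items() if c == "wt" and s == mutant_stage]
    diff_results = {}
    for mutant in MUTANTS:
        mcols = [n for n in raw_frags if n.startswith(mutant)]
        sub = {n: nfr[n] for n in wt_ref + mcols}
        mcounts = quantify.count_over_peaks(consensus[["chrom", "start", "end", "name"]], sub)
        cond = {n: ("wt" if n in wt_ref else mutant) for n in sub}
        res = quantify.differential(mcounts, cond,
                                    size_factors={n: float(lib_total[n]) for n in sub},
                                    lfc_threshold=config.lfc_threshold,
                                    fdr=config.fdr)
        diff_results[mutant] = res.set_index("peak_id")
        write_tsv(res, outdir / f"differential_{mutant}.tsv")
    results["differential"] = diff_results

    # --- annotation ---------------------------------------------------------
    tss = truth.genes.rename(columns={"tss": "tss"})[["gene_id", "chrom", "tss", "strand"]]
    promoters = annotate.define_promoters(tss, window=config.promoter_window,
                                          chrom_sizes=chrom_sizes)
    core_chip = {tf: chip[tf] for tf in ("Pou5f1", "Sox2", "Nanog")}
    dev_chip = {tf: chip[tf] for tf in chip if tf not in core_chip}
    enhancers = annotate.define_enhancers(consensus, tss, core_chip, dev_chip,
                                          distal_min=config.distal_min)
    links = annotate.link_to_genes(enhancers, tss, link_max=config.link_max)
    gene_sets = annotate.classify_gene_sets(expression, list(sim.stages))
    write_tsv(enhancers, outdir / "enhancers.tsv")
    write_tsv(links, outdir / "enhancer_gene_links.tsv")
    results.update(promoters=promoters, enhancers=enhancers, links=links,
                   gene_sets=gene_sets)

    # --- priming statistics -------------------------------------------------
    i0, i1 = sim.stages[0], mutant_stage
    element_tbl = _element_table(consensus, promoters, enhancers, links, fpkm_stage,
                                 diff_results, signal, expression, truth,
                                 stage_from=i0, stage_to=i1)
    results["elements"] = element_tbl
    write_tsv(element_tbl, outdir / "element_table.tsv")

    linked = element_tbl.dropna(subset=["expression_outcome", "mean_mutant_log2fc"])
    q_summary, q_tests = priming.quintile_outcome(
        linked["delta_access"], linked["expression_outcome"],
        n_bins=config.n_quintiles, ids=linked["element_id"])
    grid, grid_n = priming.priming_grid(
        linked["delta_access"], linked["mean_mutant_log2fc"],
        linked["expression_outcome"], n_bins=config.n_quintiles,
        ids=linked["element_id"])
    write_tsv(q_summary, outdir / "priming_quintiles.tsv")
    write_tsv(grid.reset_index(names="effect_bin"), outdir / "priming_grid.tsv")
    results.update(priming_quintiles=(q_summary, q_tests),
                   priming_grid=(grid, grid_n))
    if "H3K27ac" in element_tbl.columns:
        zgrid, _ = priming.priming_grid(
            linked["delta_access"], linked["mean_mutant_log2fc"],
            linked["H3K27ac"], statistic="zscore", n_bins=config.n_quintiles,
            ids=linked["element_id"])
        results["priming_grid_h3k27ac"] = zgrid
        write_tsv(zgrid.reset_index(names="effect_bin"), outdir / "priming_grid_h3k27ac.tsv")

    # --- motif analysis -----------------------------------------------------
    pwms = motifs.default_pwms()
    region_seqs = dict(seqs)
    scan = motifs.scan_best_hit(region_seqs, pwms["pou_like"])
    fc_map = element_tbl.set_index("region_id")["MZpou5f3_log2fc"].dropna() \
        if "MZpou5f3_log2fc" in element_tbl.columns else pd.Series(dtype=float)
    joined = scan.set_index("sequence_id").join(fc_map, how="inner")
    if len(joined) >= config.n_score_bins:
        bins_tbl = motifs.score_bins_vs_effect(joined["score"], joined["MZpou5f3_log2fc"],
                                               n_bins=config.n_score_bins)
        write_tsv(bins_tbl, outdir / "motif_score_bins.tsv")
        results["motif_score_bins"] = bins_tbl

    cfg = asdict(config)
    cfg["simulation"]["cluster_profiles"] = np.asarray(
        cfg["simulation"]["cluster_profiles"]).tolist()
    write_manifest(outdir / "manifest.json", config=cfg, seed=config.seed,
                   n_samples=len(raw_frags),
                   digests={"consensus": _digest(consensus),
                            "expression": _digest(expression)},
                   dropped_fragments=dropped)
    return results


def _element_table(consensus, promoters, enhancers, links, fpkm_stage,
                   diff_results, signal, expression, truth,
                   stage_from: str, stage_to: str) -> pd.DataFrame:
    """One row per regulatory element with the covariates the priming
    statistics consume: accessibility increase, per-mutant and mean mutant
    log2FC, linked gene, its later-stage expression, truth region id and
    planted H3K27ac signal."""
    cons = consensus.set_index("name")
    delta = (fpkm_stage[stage_to] - fpkm_stage[stage_from])

    rows = []
    enh_gene = dict(zip(links["element_id"], links["gene_id"]))

    elements = pd.concat([
        promoters.assign(element_class="promoter"),
        enhancers.assign(gene_id=enhancers["element_id"].map(enh_gene)),
    ], ignore_index=True)[["element_id", "chrom", "start", "end",
                           "element_class", "gene_id"]]

    peak_of = _match_to_peaks(elements, consensus)
    expr = expression.set_index("gene_id")
    sig = signal.set_index("region_id") if signal is not None else None
    region_of_peak = _match_to_peaks(
        truth.regions.rename(columns={"region_id": "element_id"}), consensus)
    peak_to_region = {p: r for r, p in zip(truth.regions["region_id"], region_of_peak)
                      if p is not None}

    for (eid, chrom, start, end, klass, gene), pk in zip(
            elements.itertuples(index=False), peak_of):
        if pk is None:
            continue
        row = {"element_id": eid, "element_class": klass, "peak_id": pk,
               "gene_id": gene, "chrom": chrom, "start": start, "end": end}
        row["delta_access"] = float(delta.get(pk, np.nan))
        fcs = []
        for mutant, res in diff_results.items():
            fc = res["log2_fold_change"].get(pk, np.nan)
            row[f"{mutant}_log2fc"] = fc
            fcs.append(fc)
        row["mean_mutant_log2fc"] = float(np.nanmean(fcs)) if fcs else np.nan
        outcome = np.nan
        if isinstance(gene, str) and gene in expr.index and "sphere" in expr.columns:
            outcome = float(expr.loc[gene, "sphere"])
        row["expression_outcome"] = outcome
        rid = peak_to_region.get(pk)
        row["region_id"] = rid
        if sig is not None and rid in sig.index:
            for col in sig.columns:
                row[col] = float(sig.loc[rid, col])
        rows.append(row)
    return pd.DataFrame(rows)


def _match_to_peaks(elements: pd.DataFrame, consensus: pd.DataFrame) -> list:
    """Per element, the name of the consensus peak with the largest overlap
    (None if no overlap)."""
    by_chrom = {c: g.sort_values("start") for c, g in
                consensus.groupby("chrom", observed=True)}
    out = []
    for row in elements.itertuples(index=False):
        grp = by_chrom.get(row.chrom)
        best, best_ov = None, 0
        if grp is not None:
            s_arr = grp["start"].to_numpy()
            e_arr = grp["end"].to_numpy()
            lo = np.searchsorted(e_arr, row.start, side="right")
            hi = np.searchsorted(s_arr, row.end, side="left")
            for k in range(lo, hi):
                ov = min(row.end, e_arr[k]) - max(row.start, s_arr[k])
                if ov > best_ov:
                    best, best_ov = grp["name"].iloc[k], ov
        out.append(best)
    return out
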