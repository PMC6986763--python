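"""Define regulatory elements, link them to genes, and compute the priming
statistics.

Promoters are 2 kb TSS windows; putative enhancers are distal consensus
peaks (>= 1 kb from any TSS) supported by >= 1 core and >= 1 developmental
TF ChIP peak; elements link to the nearest TSS within 20 kb.  The priming
analyses ask whether the accessibility increase between 256-cell and
oblong, and its dependence on the maternal factors, predicts sphere-stage
expression: quintile violin summaries, the 5 x 5 increase x mutant-effect
grid, TF enrichment by mutant-effect quintile, and effects stratified by
bound-TF combination.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from zgaprime import annotate, priming
from zgaprime.io import read_bed, read_tsv, write_tsv

ROOT = Path(__file__).resolve().parents[1] / "results"
CORE = ["Pou5f1", "Sox2", "Nanog"]

if __name__ == "__main__":
    from importlib import import_module
    sys.path.insert(0, str(Path(__file__).parent))
    config = import_module("01_simulate").config

    consensus = read_tsv(ROOT / "consensus_peaks.tsv")
    genes = read_tsv(ROOT / "dataset" / "truth_genes.tsv")
    tss = genes[["gene_id", "chrom", "tss", "strand"]]
    chip = {p.stem: read_bed(p) for p in sorted((ROOT / "dataset" / "chip").glob("*.bed"))}

    promoters = annotate.define_promoters(tss, chrom_sizes=config.chrom_sizes)
    enhancers = annotate.define_enhancers(
        consensus, tss, {tf: chip[tf] for tf in CORE},
        {tf: df for tf, df in chip.items() if tf not in CORE})
    links = annotate.link_to_genes(enhancers, tss)
    write_tsv(enhancers, ROOT / "enhancers.tsv")
    write_tsv(links, ROOT / "enhancer_gene_links.tsv")
    print(f"{len(promoters)} promoters; {len(enhancers)} putative enhancers, "
          f"{len(links)} linked to a gene within 20 kb")

    expression = read_tsv(ROOT / "dataset" / "expression.tsv")
    gene_sets = annotate.classify_gene_sets(expression, list(config.stages))
    print(f"{int(gene_sets['late_activated'].sum())} late-activated genes, "
          f"{int(gene_sets['never_expressed'].sum())} never expressed")

    # element-level covariates assembled from upstream tables
    fpkm = read_tsv(ROOT / "fpkm_by_stage.tsv").set_index("peak_id")
    delta = fpkm["oblong"] - fpkm["s256cell"]
    diff = {m: read_tsv(ROOT / f"differential_{m}.tsv").set_index("peak_id")
            for m in ["MZpou5f3", "MZsox19b", "MZnanog"]}
    expr = expression.set_index("gene_id")["sphere"]

    rows = []
    enh_gene = links.set_index("element_id")["gene_id"]
    for elements, gene_col in ((promoters, promoters.set_index("element_id")["gene_id"]),
                               (enhancers, enh_gene)):
        for row in elements.itertuples():
            peak = consensus[(consensus["chrom"] == row.chrom) &
                             (consensus["start"] < row.end) &
                             (consensus["end"] > row.start)]
            if not len(peak):
                continue
            pk = peak.iloc[0]["name"]
            gene = gene_col.get(row.element_id)
            fcs = [diff[m].loc[pk, "log2_fold_change"] for m in diff]
            rows.append({
                "element_id": row.element_id, "peak_id": pk, "gene_id": gene,
                "delta_access": float(delta.get(pk, np.nan)),
                "mean_mutant_log2fc": float(np.nanmean(fcs)),
                "outcome": float(expr.get(gene, np.nan)),
            })
    el = pd.DataFrame(rows).dropna()
    write_tsv(el, ROOT / "priming_elements.tsv")

    q_summary, q_tests = priming.quintile_outcome(
        el["delta_access"], el["outcome"], ids=el["element_id"])
    write_tsv(q_summary, ROOT / "priming_quintiles.tsv")
    write_tsv(q_tests, ROOT / "priming_quintile_tests.tsv")
    print("quintile medians (low -> high accessibility increase):",
          [round(x, 2) for x in q_summary["median_outcome"]])

    grid, counts = priming.priming_grid(
        el["delta_access"], el["mean_mutant_log2fc"], el["outcome"],
        ids=el["element_id"])
    write_tsv(grid.reset_index(names="effect_bin"), ROOT / "priming_grid.tsv")
    am = np.unravel_index(np.nanargmax(grid.to_numpy()), grid.shape)
    print(f"priming grid maximum median {np.nanmax(grid.to_numpy()):.2f} at "
          f"(mutant-loss bin {am[0] + 1}, increase bin {am[1] + 1}) "
          "(bin 1 = greatest loss / smallest increase)")

    # TF binding enrichment across mutant-effect quintiles
    signal = read_tsv(ROOT / "dataset" / "signal.tsv").set_index("region_id")
    truth_regions = read_tsv(ROOT / "dataset" / "truth_regions.tsv")
    region_for_peak = {}
    for r in truth_regions.itertuples():
        hit = consensus[(consensus["chrom"] == r.chrom) &
                        (consensus["start"] < r.end) & (consensus["end"] > r.start)]
        if len(hit):
            region_for_peak[hit.iloc[0]["name"]] = r.region_id
    el2 = el[el["peak_id"].isin(region_for_peak)]
    mx = signal.loc[[region_for_peak[p] for p in el2["peak_id"]], "Mxtx2"].to_numpy()
    summary, tests = priming.tf_enrichment_by_bin(
        el2["mean_mutant_log2fc"], mx, normalization="genome_mean")
    write_tsv(summary, ROOT / "tf_enrichment_by_effect_bin.tsv")
    print("Mxtx2 signal by mutant-effect quintile (greatest loss first):",
          [round(x, 2) for x in summary["median_signal"]])
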