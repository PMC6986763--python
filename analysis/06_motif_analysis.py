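"""Motif-strength analysis of mutant accessibility loss.

Scans every region sequence with the bundled pou-type matrix, keeps the
best hit per sequence, bins scores into 10 equal-frequency bins, and asks
whether stronger motifs lose more accessibility in MZpou5f3 (they should:
the generator plants depletion proportional to occupancy, and planted
motifs mark bound regions).  Also runs the presence/absence enrichment of
all bundled motifs in the top-20% opening regions versus the bottom.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from zgaprime import motifs
from zgaprime.io import read_fasta, read_tsv, write_tsv

ROOT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    seqs = read_fasta(ROOT / "dataset" / "sequences.fa")
    pwms = motifs.default_pwms()
    el = read_tsv(ROOT / "priming_elements.tsv")
    truth_regions = read_tsv(ROOT / "dataset" / "truth_regions.tsv")
    consensus = read_tsv(ROOT / "consensus_peaks.tsv")
    diff = read_tsv(ROOT / "differential_MZpou5f3.tsv").set_index("peak_id")

    region_for_peak = {}
    for r in truth_regions.itertuples():
        hit = consensus[(consensus["chrom"] == r.chrom) &
                        (consensus["start"] < r.end) & (consensus["end"] > r.start)]
        if len(hit):
            region_for_peak[hit.iloc[0]["name"]] = r.region_id

    scan = motifs.scan_best_hit(seqs, pwms["pou_like"]).set_index("sequence_id")
    pairs = [(scan.loc[rid, "score"], diff.loc[pk, "log2_fold_change"])
             for pk, rid in region_for_peak.items()
             if rid in scan.index and pk in diff.index]
    scores, fc = map(np.array, zip(*pairs))
    bins = motifs.score_bins_vs_effect(scores, fc, n_bins=10)
    write_tsv(bins, ROOT / "motif_score_bins.tsv")
    print("median MZpou5f3 log2FC by pou-motif score bin (weak -> strong):")
    print([round(x, 2) for x in bins["median_log2fc"]])

    # enrichment in top-opening regions
    fpkm = read_tsv(ROOT / "fpkm_by_stage.tsv").set_index("peak_id")
    delta = (fpkm["oblong"] - fpkm["s256cell"]).sort_values()
    peak_seq = {pk: seqs[rid] for pk, rid in region_for_peak.items()}
    ranked = [p for p in delta.index if p in peak_seq]
    n_top = max(len(ranked) // 5, 1)
    fg = {p: peak_seq[p] for p in ranked[-n_top:]}
    bg = {p: peak_seq[p] for p in ranked[:len(ranked) - n_top]}
    enr = motifs.enrichment_top_regions(fg, bg, pwms)
    write_tsv(enr, ROOT / "motif_enrichment_top20.tsv")
    print("motif enrichment in top-20% opening regions:")
    for row in enr.itertuples():
        print(f"  {row.motif_id}: fg {row.fg_fraction:.2f} vs bg "
              f"{row.bg_fraction:.2f}, q = {row.q_value:.2e}")
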