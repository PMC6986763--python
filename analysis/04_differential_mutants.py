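"""Differential accessibility in the maternal-zygotic mutants at oblong.

For each of MZpou5f3, MZsox19b and MZnanog: counts NFR fragments over
consensus peaks in mutant and wild-type oblong samples, tests with the NB
Wald model (size factors = total fragment counts), and calls decreases at
log2FC <= -1.5 and FDR < 5%.  Writes per-mutant result tables and a
volcano summary annotated with the planted bound-TF sets.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from zgaprime import fragments, quantify
from zgaprime.io import read_bed, read_tsv, write_tsv

ROOT = Path(__file__).resolve().parents[1] / "results"
MUTANTS = ["MZpou5f3", "MZsox19b", "MZnanog"]

if __name__ == "__main__":
    consensus = read_tsv(ROOT / "consensus_peaks.tsv")
    peaks = consensus[["chrom", "start", "end", "name"]]

    def load(pattern):
        nfr, lib = {}, {}
        for bed in sorted((ROOT / "dataset" / "fragments").glob(pattern)):
            adj, _ = fragments.adjust_cut_sites(read_bed(bed))
            lib[bed.stem] = float(len(adj))
            nfr[bed.stem], _ = fragments.split_by_size(adj)
        return nfr, lib

    wt, wt_lib = load("wt_oblong_*.bed")
    for mutant in MUTANTS:
        mu, mu_lib = load(f"{mutant}_*.bed")
        counts = quantify.count_over_peaks(peaks, {**wt, **mu})
        cond = {n: ("wt" if n in wt else mutant) for n in counts.columns}
        res = quantify.differential(counts, cond, size_factors={**wt_lib, **mu_lib})
        write_tsv(res, ROOT / f"differential_{mutant}.tsv")
        n_dec = int((res["call"] == "decrease").sum())
        n_inc = int((res["call"] == "increase").sum())
        print(f"{mutant}: {n_dec} peaks lose accessibility, {n_inc} gain "
              f"(|log2FC| >= 1.5, FDR < 5%), of {len(res)} tested")
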