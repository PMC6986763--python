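"""Process fragments and build the cross-stage consensus peak set.

Reads the fragment BEDs from 01, applies the Tn5 +4/-5 correction and the
130 bp nucleosome-free split, calls peaks per stage (pooled and per
replicate) against the genomic-DNA control, confirms peaks in all
replicates, and merges everything into consensus peaks with per-stage
presence flags (results/consensus_peaks.tsv).
"""

import sys
from collections import defaultdict
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from zgaprime import fragments, peaks
from zgaprime.io import read_bed, write_tsv

ROOT = Path(__file__).resolve().parents[1] / "results"
DATASET = ROOT / "dataset"

if __name__ == "__main__":
    from importlib import import_module
    sys.path.insert(0, str(Path(__file__).parent))
    config = import_module("01_simulate").config
    sizes = config.chrom_sizes

    nfr_by_stage = defaultdict(list)
    for bed in sorted((DATASET / "fragments").glob("wt_*.bed")):
        adj, n_drop = fragments.adjust_cut_sites(read_bed(bed))
        nfr, _nuc = fragments.split_by_size(adj)
        stage = bed.stem.split("_")[1]
        nfr_by_stage[stage].append(nfr)

    control_adj, _ = fragments.adjust_cut_sites(read_bed(DATASET / "control.bed"))
    control_nfr, _ = fragments.split_by_size(control_adj)
    control = fragments.event_count_track(control_nfr, sizes)

    replicated = {}
    for stage in config.stages:
        reps = nfr_by_stage[stage]
        pooled_track = fragments.event_count_track(pd.concat(reps), sizes)
        pooled = peaks.call_peaks(pooled_track, control, name_prefix=stage)
        per_rep = [peaks.call_peaks(fragments.event_count_track(r, sizes), control)
                   for r in reps]
        replicated[stage] = peaks.confirm_replicated(pooled, per_rep)
        print(f"{stage}: {len(pooled)} pooled peaks, "
              f"{len(replicated[stage])} confirmed in all {len(reps)} replicates")

    consensus = peaks.build_consensus(replicated)
    write_tsv(consensus, ROOT / "consensus_peaks.tsv")
    present = consensus[[c for c in consensus.columns if c.startswith("present_")]]
    print(f"consensus: {len(consensus)} peaks; "
          f"{int(present.all(axis=1).sum())} present at every stage")
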