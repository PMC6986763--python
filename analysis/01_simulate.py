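"""Generate the synthetic ATAC-seq study used by all downstream analyses.

Writes per-sample fragment BEDs for seven wild-type stages (2-3 replicates
each), the three maternal-zygotic mutant conditions at oblong stage, a
genomic-DNA control, TF ChIP peak sets and signal tables, a per-gene
per-stage expression table, region sequences, and the planted ground truth,
under results/dataset/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from zgaprime.io import write_bed
from zgaprime.simulate import SimulationConfig, generate_control_fragments, write_run

OUT = Path(__file__).resolve().parents[1] / "results" / "dataset"

config = SimulationConfig(seed=0, n_genes=250, n_regions=600,
                          chrom_length=6_000_000, fragment_depth=150_000)

if __name__ == "__main__":
    truth = write_run(config, OUT)
    write_bed(generate_control_fragments(config), OUT / "control.bed")
    n_samples = len(list((OUT / "fragments").glob("*.bed")))
    n_enh = int(truth.regions["is_enhancer"].sum())
    print(f"dataset written to {OUT}")
    print(f"{n_samples} fragment samples; {len(truth.regions)} regions "
          f"({n_enh} planted enhancers) across {config.n_chroms} chromosomes; "
          f"{len(truth.genes)} genes, of which "
          f"{int(truth.genes['never_expressed'].sum())} planted silent")
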