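"""Synthetic ATAC-seq study generator with planted ground truth.

Emulates the design of a zebrafish zygotic-genome-activation accessibility
time course: seven developmental stages (256-cell through 80% epiboly) with
2-3 biological replicates each, maternal-zygotic transcription-factor mutant
samples at oblong stage, a transcription-inhibited condition, TF ChIP peak
sets and per-region signal tables, per-gene per-stage expression (RPKM), and
region sequences with planted binding motifs.

Every planted effect is recorded in a :class:`GroundTruth` object so that
downstream stages (peak calling, differential accessibility, clustering,
enhancer annotation, priming statistics, motif binning) can be scored
against the truth.

Model summary
-------------
* Regions follow one of five accessibility trajectory archetypes across
  stages (always-open, ZGA-opening, two gastrulation-opening shapes, and a
  flat moderately-open background class).
* Per-sample region fragment counts are negative-binomial around the
  trajectory mean, with multiplicative log-normal region-by-replicate noise.
* Mutant samples deplete regions bound by the removed factor by
  ``2**-mutant_effect``.
* Fragment lengths are a two-component truncated log-normal mixture with
  modes near 80 bp (sub-nucleosomal) and 180 bp (mono-nucleosomal), so a
  130 bp nucleosome-free cutoff separates the components exactly.
* Late (sphere-stage) expression of a gene is ``baseline + priming_beta *
  delta_access`` of its linked elements (the accessibility increase between
  256-cell and oblong) plus Gaussian noise; a fraction of genes is planted
  as never expressed (summed RPKM below the silent cutoff).

Emitted fragments are *raw* alignment-style intervals: the generator first
draws the transposase insertion interval and then un-applies the +4/-5
cut-site correction, so the fragment-processing stage recovers the planted
coordinates exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .io import write_bed, write_fasta, write_manifest, write_tsv

STAGES = ("s256cell", "high", "oblong", "sphere", "dome", "shield", "epiboly80")
#: replicate structure of the study design: 2 replicates for 256-cell,
#: sphere, shield and 80% epiboly; 3 for high, oblong and dome
DEFAULT_REPLICATES = {
    "s256cell": 2, "high": 3, "oblong": 3, "sphere": 2,
    "dome": 3, "shield": 2, "epiboly80": 2,
}

CORE_TFS = ("Pou5f1", "Sox2", "Nanog")
DEVELOPMENTAL_TFS = ("Smad2", "FoxH1", "Mxtx2", "Eomesodermin", "Ta", "Tbx16", "Mixl1")
#: maternal-zygotic mutants and the core factor whose binding they remove
MUTANTS = {"MZpou5f3": "Pou5f1", "MZsox19b": "Sox2", "MZnanog": "Nanog"}

# five trajectory archetypes (expected relative accessibility per stage);
# cluster 1 is open before ZGA and rises rapidly by oblong, 2 opens during
# ZGA (mostly after oblong), 3 and 4 open progressively later during
# gastrulation, 5 stays moderately open throughout; the archetypes differ
# deliberately in their 256-cell -> oblong increment (7, 3.5, 0.5, 0, 0
# units) so early-increase quantiles map onto interpretable classes
DEFAULT_CLUSTER_PROFILES = np.array([
    [3.0, 7.0, 10.0, 10.0, 10.0, 10.0, 10.0],
    [0.5, 1.5, 4.0, 8.0, 9.0, 9.0, 9.0],
    [0.5, 0.5, 1.0, 2.5, 5.0, 8.0, 9.0],
    [0.5, 0.5, 0.5, 1.0, 2.0, 4.0, 8.0],
    [1.5, 1.5, 1.5, 1.5, 1.5, 1.5, 1.5],
])


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study; defaults are the study conditions.

    Counts are positive integers, coordinates in bp, ``mutant_effect`` a
    log2 depletion, ``priming_beta`` in RPKM per FPKM-increase unit.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 3_200_000
    n_genes: int = 150
    n_regions: int = 300
    stages: tuple[str, ...] = STAGES
    n_replicates_per_stage: dict = field(default_factory=lambda: dict(DEFAULT_REPLICATES))
    cluster_profiles: np.ndarray = field(default_factory=lambda: DEFAULT_CLUSTER_PROFILES.copy())
    fraction_enhancer: float = 0.4
    mutant_effect: float = 2.0
    priming_beta: float = 1.0
    bound_expression_boost: float = 0.75
    expression_baseline: float = 1.5
    expression_noise_sd: float = 0.5
    fraction_never_expressed: float = 0.1
    noise_sd: float = 0.25          # log-normal region x replicate noise (log scale sd)
    nb_dispersion: float = 0.05     # NB: var = mu + disp * mu^2
    fragment_depth: int = 150_000   # expected fragments per sample
    background_fraction: float = 0.25
    nfr_fraction: float = 0.65      # sub-nucleosomal share of in-region fragments
    nfr_cutoff: int = 130
    mutant_stage: str = "oblong"
    n_mutant_replicates: int = 2

    def __post_init__(self):
        if len(self.stages) < 2:
            raise ValueError("need at least two stages")
        for name in ("n_chroms", "chrom_length", "n_genes", "n_regions"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        profiles = np.asarray(self.cluster_profiles, dtype=float)
        if profiles.ndim != 2 or profiles.shape[1] != len(self.stages):
            raise ValueError("cluster_profiles must be (n_clusters, n_stages)")
        if (profiles < 0).any():
            raise ValueError("cluster_profiles must be non-negative")
        object.__setattr__(self, "cluster_profiles", profiles)
        missing = [s for s in self.stages if s not in self.n_replicates_per_stage]
        if missing:
            raise ValueError(f"replicate counts missing for stages: {missing}")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Planted truth: region table, gene table, links and motif placements.

    ``regions`` columns: region_id, chrom, start, end, cluster (1-based),
    is_enhancer, bound_by (comma-joined TF names, '' if unbound), gene_id,
    tss_distance, plus one ``traj_<stage>`` column per stage with the true
    mean fragment count.  ``genes`` columns: gene_id, chrom, tss, strand,
    never_expressed, activation_stage, late_expression, delta_access.
    """

    regions: pd.DataFrame
    genes: pd.DataFrame
    links: pd.DataFrame                 # element_id, gene_id, distance
    motif_positions: pd.DataFrame       # region_id, motif_id, offset

    def trajectory(self, stages) -> np.ndarray:
        return self.regions[[f"traj_{s}" for s in stages]].to_numpy()

    def bound_sets(self) -> pd.Series:
        return self.regions["bound_by"].map(
            lambda s: frozenset(s.split(",")) if s else frozenset()
        )

    def strength_maps(self) -> pd.Series:
        """Per region, dict of bound TF -> planted occupancy strength."""
        def parse(row):
            if not row.bound_by:
                return {}
            tfs = row.bound_by.split(",")
            vals = [float(x) for x in row.bound_strength.split(",")]
            return dict(zip(tfs, vals))
        return pd.Series([parse(r) for r in self.regions.itertuples()],
                         index=self.regions.index)


def _rng(seed: int, label: str) -> np.random.Generator:
    """One independent, reproducible stream per output, keyed by label."""
    return np.random.default_rng([seed, zlib.crc32(label.encode())])


def _truncated_lognormal(rng, mode: float, sigma: float, lo: float, hi: float, size: int):
    """Log-normal with the given mode, truncated to [lo, hi] by inverse CDF."""
    mu = np.log(mode) + sigma**2
    dist = stats.lognorm(s=sigma, scale=np.exp(mu))
    a, b = dist.cdf(lo), dist.cdf(hi)
    u = rng.uniform(a, b, size=size)
    return dist.ppf(u)


# ---------------------------------------------------------------------------
# annotation / truth

def generate_annotation(config: SimulationConfig) -> GroundTruth:
    """Place genes and regions and assign all planted labels.

    Promoter-class regions overlap their gene's TSS; enhancer-class regions
    sit 2-16 kb away (always >= 1 kb from every TSS and always linkable
    within the 20 kb rule).  Raises ValueError when the chromosomes are too
    short for the requested gene count.
    """
    rng = _rng(config.seed, "annotation")
    per_chrom = int(np.ceil(config.n_genes / config.n_chroms))
    spacing = config.chrom_length // (per_chrom + 1)
    if spacing < 40_000:
        raise ValueError(
            f"chromosomes too short: gene spacing {spacing} bp < 40 kb needed "
            "to keep enhancers distal and links unambiguous"
        )

    genes = []
    for g in range(config.n_genes):
        chrom = f"chr{g % config.n_chroms + 1}"
        slot = g // config.n_chroms
        tss = (slot + 1) * spacing + int(rng.integers(-2000, 2001))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append((f"gene{g:04d}", chrom, tss, strand))
    genes_df = pd.DataFrame(genes, columns=["gene_id", "chrom", "tss", "strand"])

    n_regions = config.n_regions
    n_enh = int(round(config.fraction_enhancer * n_regions))
    n_clusters = config.cluster_profiles.shape[0]
    # trajectory archetypes are assigned per gene: a gene's regulatory
    # elements open coordinately, so regions inherit their host gene's
    # cluster (this is also what makes element-level priming informative)
    gene_cluster = rng.integers(1, n_clusters + 1, size=config.n_genes)

    host = rng.permutation(np.arange(n_regions) % config.n_genes)
    clusters = gene_cluster[host]
    regions, links, used_genes = [], [], set()
    for r in range(n_regions):
        gene = genes_df.iloc[host[r]]
        width = int(rng.integers(300, 801))
        is_enh = r < n_enh
        if is_enh:
            # distal: 2-16 kb from the TSS, strandless direction
            offset = int(rng.integers(2000, 16001)) * (1 if rng.random() < 0.5 else -1)
            start = gene.tss + offset - width // 2
        else:
            # promoter-class: centered within +/-300 bp of the TSS
            start = gene.tss + int(rng.integers(-300, 301)) - width // 2
        start = max(0, min(start, config.chrom_length - width))
        end = start + width
        if gene.tss < start:
            dist = start - gene.tss
        elif gene.tss >= end:
            dist = gene.tss - (end - 1)
        else:
            dist = 0
        if is_enh:
            core = [tf for tf in CORE_TFS if rng.random() < 0.5]
            if not core:
                core = [CORE_TFS[rng.integers(len(CORE_TFS))]]
            dev = [tf for tf in DEVELOPMENTAL_TFS if rng.random() < 0.25]
            if not dev:
                dev = [DEVELOPMENTAL_TFS[rng.integers(len(DEVELOPMENTAL_TFS))]]
            bound = core + dev
        else:
            # some promoters are also core-factor bound (mutant-affected)
            bound = [tf for tf in CORE_TFS if rng.random() < 0.3] if rng.random() < 0.5 else []
        # continuous occupancy per bound factor: scales mutant depletion,
        # ChIP signal and the expression contribution (strong sites lose
        # the most accessibility in mutants, as seen for motif strength)
        strengths = {tf: float(rng.uniform(0.5, 1.5)) for tf in bound}
        rid = f"region{r:04d}"
        regions.append((rid, gene.chrom, start, end, clusters[r], is_enh,
                        ",".join(bound),
                        ",".join(f"{strengths[tf]:.4f}" for tf in bound),
                        gene.gene_id, dist))
        links.append((rid, gene.gene_id, dist))
        used_genes.add(gene.gene_id)

    regions_df = pd.DataFrame(regions, columns=[
        "region_id", "chrom", "start", "end", "cluster", "is_enhancer",
        "bound_by", "bound_strength", "gene_id", "tss_distance"])
    regions_df = regions_df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)

    # true mean fragment counts per stage: scaled so that at the most open
    # stage the regions take (1 - background_fraction) of the library; each
    # sample is sequenced to the same expected depth and the background
    # absorbs the remainder, so the fraction of reads in regions rises as
    # chromatin opens (as in real ATAC libraries)
    profiles = config.cluster_profiles
    traj = profiles[regions_df["cluster"].to_numpy() - 1]
    scale = config.fragment_depth * (1 - config.background_fraction) / traj.sum(axis=0).max()
    traj = traj * scale
    for j, s in enumerate(config.stages):
        regions_df[f"traj_{s}"] = traj[:, j]

    links_df = pd.DataFrame(links, columns=["element_id", "gene_id", "distance"])

    genes_df["never_expressed"] = False
    unused = ~genes_df["gene_id"].isin(used_genes)
    n_silent = int(round(config.fraction_never_expressed * config.n_genes))
    silent_idx = list(genes_df.index[unused][:n_silent])
    if len(silent_idx) < n_silent:
        extra = rng.choice(genes_df.index[~genes_df.index.isin(silent_idx)],
                           size=n_silent - len(silent_idx), replace=False)
        silent_idx.extend(extra.tolist())
    genes_df.loc[silent_idx, "never_expressed"] = True

    truth = GroundTruth(regions=regions_df, genes=genes_df, links=links_df,
                        motif_positions=pd.DataFrame(columns=["region_id", "motif_id", "offset"]))
    return truth


# ---------------------------------------------------------------------------
# fragments

def _sample_names(config: SimulationConfig, condition) -> list[str]:
    kind = condition[0]
    if kind == "wt":
        stage = condition[1]
        if stage not in config.stages:
            raise ValueError(f"unknown stage {stage!r}")
        n = config.n_replicates_per_stage[stage]
        return [f"wt_{stage}_rep{i + 1}" for i in range(n)]
    if kind == "mutant":
        name = condition[1]
        if name not in MUTANTS:
            raise ValueError(f"unknown mutant {name!r}")
        return [f"{name}_{config.mutant_stage}_rep{i + 1}" for i in range(config.n_mutant_replicates)]
    if kind == "amanitin":
        return [f"amanitin_{config.mutant_stage}_rep{i + 1}" for i in range(config.n_mutant_replicates)]
    raise ValueError(f"unknown condition {condition!r}")


def generate_fragments(config: SimulationConfig, truth: GroundTruth,
                       condition) -> dict[str, pd.DataFrame]:
    """Draw per-sample raw fragment sets for one condition.

    ``condition`` is ``("wt", stage)``, ``("mutant", name)`` with name in
    MUTANTS, or ``("amanitin",)`` (transcription-inhibited; accessibility is
    planted as unaffected, matching the biology it emulates).  Returns
    ``{sample_name: BED-like DataFrame}`` with raw (un-shifted) coordinates.
    """
    kind = condition[0]
    stage = config.mutant_stage if kind in ("mutant", "amanitin") else condition[1]
    names = _sample_names(config, condition)
    stage_idx = config.stages.index(stage)
    means = truth.trajectory(config.stages)[:, stage_idx].copy()
    if kind == "mutant":
        removed = MUTANTS[condition[1]]
        strength = truth.strength_maps().map(lambda m: m.get(removed, 0.0)).to_numpy()
        means = means * 2.0 ** (-config.mutant_effect * strength)

    regions = truth.regions
    out = {}
    for name in names:
        rng = _rng(config.seed, f"fragments/{name}")
        noise = rng.lognormal(mean=-0.5 * config.noise_sd**2, sigma=config.noise_sd,
                              size=len(means)) if config.noise_sd > 0 else 1.0
        mu = means * noise
        if config.nb_dispersion > 0:
            n_param = 1.0 / config.nb_dispersion
            counts = rng.negative_binomial(n_param, n_param / (n_param + np.maximum(mu, 1e-12)))
        else:
            counts = rng.poisson(mu)
        counts = np.where(mu <= 0, 0, counts)
        if config.fragment_depth == 0:
            counts = np.zeros_like(counts)

        frags, frag_chroms = [], []
        for (start, end), chrom, c in zip(regions[["start", "end"]].to_numpy(),
                                          regions["chrom"].to_numpy(), counts):
            if c == 0:
                continue
            width = end - start
            is_nfr = rng.random(c) < config.nfr_fraction
            lengths = np.empty(c)
            if is_nfr.any():
                lengths[is_nfr] = _truncated_lognormal(
                    rng, 80, 0.25, 25, config.nfr_cutoff, int(is_nfr.sum()))
            if (~is_nfr).any():
                lengths[~is_nfr] = _truncated_lognormal(
                    rng, 180, 0.15, config.nfr_cutoff + 1, 450, int((~is_nfr).sum()))
            lengths = np.round(lengths).astype(int)
            lengths = np.clip(lengths, 25, None)
            span = np.maximum(width - lengths, 1)
            s = start + (rng.random(c) * span).astype(int)
            frags.append(np.column_stack([s, s + lengths]))
            frag_chroms.extend([chrom] * c)
        # background takes whatever the regions leave of the fixed depth
        expected_bg = max(config.fragment_depth - float(means.sum()),
                          0.02 * config.fragment_depth)
        n_bg = rng.poisson(expected_bg) if config.fragment_depth > 0 else 0
        all_chroms = list(frag_chroms)
        all_coords = [np.concatenate(frags) if frags else np.empty((0, 2), dtype=int)]
        if n_bg:
            chrom_idx = rng.integers(0, config.n_chroms, size=n_bg)
            lengths = np.round(_truncated_lognormal(rng, 180, 0.3, 40, 450, n_bg)).astype(int)
            s = (rng.random(n_bg) * (config.chrom_length - lengths - 10)).astype(int)
            all_chroms.extend(f"chr{i + 1}" for i in chrom_idx)
            all_coords.append(np.column_stack([s, s + lengths]))
        coords = np.concatenate(all_coords)
        df = pd.DataFrame({
            "chrom": all_chroms,
            "start": coords[:, 0] - 4,       # un-apply the Tn5 +4 shift
            "end": coords[:, 1] + 5,         # un-apply the Tn5 -5 shift
        })
        df["start"] = df["start"].clip(lower=0)
        df["name"] = name
        df["score"] = 0
        df["strand"] = np.where(_rng(config.seed, f"strand/{name}").random(len(df)) < 0.5, "+", "-")
        df = df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)
        out[name] = df
    return out


def generate_all_fragments(config: SimulationConfig, truth: GroundTruth,
                           mutants: bool = True) -> dict[str, pd.DataFrame]:
    """All wild-type stage samples plus (optionally) the mutant samples."""
    out = {}
    for stage in config.stages:
        out.update(generate_fragments(config, truth, ("wt", stage)))
    if mutants:
        for m in MUTANTS:
            out.update(generate_fragments(config, truth, ("mutant", m)))
    return out


def generate_control_fragments(config: SimulationConfig,
                               depth: int | None = None) -> pd.DataFrame:
    """Naked genomic-DNA Tn5 digestion control: uniform fragments genome-wide.

    This is the background library peak calling tests enrichment against;
    it carries no region structure.
    """
    rng = _rng(config.seed, "control")
    n = rng.poisson(depth if depth is not None else config.fragment_depth)
    chrom_idx = rng.integers(0, config.n_chroms, size=n)
    lengths = np.round(_truncated_lognormal(rng, 150, 0.35, 40, 450, n)).astype(int)
    s = (rng.random(n) * (config.chrom_length - lengths - 10)).astype(int)
    df = pd.DataFrame({
        "chrom": [f"chr{i + 1}" for i in chrom_idx],
        "start": s - 4,
        "end": s + lengths + 5,
    })
    df["start"] = df["start"].clip(lower=0)
    df["name"] = "gdna_control"
    df["score"] = 0
    df["strand"] = np.where(rng.random(n) < 0.5, "+", "-")
    return df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# expression

def generate_expression(config: SimulationConfig, truth: GroundTruth,
                        silent_max: float = 0.1) -> pd.DataFrame:
    """Per-gene per-stage RPKM table with the planted priming relationship.

    Expression from sphere stage onward equals ``baseline + priming_beta *
    delta_access + bound_expression_boost * core_bound + N(0,
    expression_noise_sd)`` (floored at 0), where delta_access is the
    planted mean accessibility increase of the gene's linked elements
    between the first stage and oblong (trajectory divided by its grand
    mean) and core_bound is the summed occupancy strength of the core
    maternal factors at those elements — accessibility established by the
    maternal factors carries extra predictive weight, which is what the
    priming grid measures.
    Genes planted as never expressed receive near-zero values summing
    below ``silent_max``.
    Also records ``late_expression``, ``delta_access`` and
    ``activation_stage`` on ``truth.genes``.
    """
    rng = _rng(config.seed, "expression")
    stages = config.stages
    i0, i1 = 0, stages.index("oblong") if "oblong" in stages else 1
    traj = truth.trajectory(stages)
    rel = traj / traj.mean()                      # dimensionless accessibility
    delta_region = rel[:, i1] - rel[:, i0]
    gene_idx = truth.regions["gene_id"].to_numpy()
    delta_by_gene = (pd.Series(delta_region, index=gene_idx)
                     .groupby(level=0).mean())
    core_strength = truth.strength_maps().map(
        lambda m: sum(v for tf, v in m.items() if tf in CORE_TFS)).to_numpy()
    core_by_gene = pd.Series(core_strength, index=gene_idx,
                             dtype=float).groupby(level=0).mean()

    genes = truth.genes
    delta = genes["gene_id"].map(delta_by_gene).fillna(0.0).to_numpy()
    core = genes["gene_id"].map(core_by_gene).fillna(0.0).to_numpy()
    noise = rng.normal(0, config.expression_noise_sd, size=len(genes))
    late = np.maximum(config.expression_baseline + config.priming_beta * delta
                      + config.bound_expression_boost * core + noise, 0.0)

    sphere_idx = stages.index("sphere") if "sphere" in stages else len(stages) - 2
    expr = np.zeros((len(genes), len(stages)))
    pre = rng.uniform(0, 0.05, size=(len(genes), sphere_idx))
    expr[:, :sphere_idx] = pre
    for j in range(sphere_idx, len(stages)):
        expr[:, j] = late * rng.lognormal(-0.005, 0.1, size=len(genes))

    silent = genes["never_expressed"].to_numpy()
    if silent.any():
        n_s = int(silent.sum())
        tiny = rng.uniform(0, silent_max / (len(stages) * 2), size=(n_s, len(stages)))
        expr[silent] = tiny
        late[silent] = tiny[:, sphere_idx]

    table = pd.DataFrame(expr, columns=list(stages))
    table.insert(0, "gene_id", genes["gene_id"].to_numpy())

    genes = genes.copy()
    genes["delta_access"] = delta
    genes["late_expression"] = late
    act = np.where(silent, "never", np.where(late >= 1.0, stages[sphere_idx], "weak"))
    genes["activation_stage"] = act
    truth.genes = genes
    return table


# ---------------------------------------------------------------------------
# ChIP peaks, signal tables, sequences

BASES = np.array(list("ACGT"))


def generate_chip_and_sequence(config: SimulationConfig, truth: GroundTruth,
                               pwms: dict[str, "object"] | None = None):
    """Emit per-TF ChIP peak sets, a per-region signal table, and sequences.

    Returns ``(chip_peaks, signal, sequences)``: a dict TF -> peak DataFrame
    covering every region bound by that TF (interval jittered but always
    overlapping), a region x TF ChIP/Input ratio table (log-normal around 1
    for unbound regions, around 4 for bound ones) with an extra H3K27ac
    column correlated with the linked gene's late expression, and a dict
    region_id -> DNA string with each bound core factor's motif consensus
    planted at a recorded offset (``truth.motif_positions``).
    """
    if pwms is None:
        from .motifs import default_pwms
        pwms = default_pwms()
    rng = _rng(config.seed, "chip")
    regions = truth.regions
    bound = truth.bound_sets()

    chip_peaks: dict[str, list] = {tf: [] for tf in CORE_TFS + DEVELOPMENTAL_TFS}
    for row, bset in zip(regions.itertuples(), bound):
        width = row.end - row.start
        for tf in bset:
            jitter = int(rng.integers(-width // 4, width // 4 + 1))
            chip_peaks[tf].append((row.chrom, max(0, row.start + jitter),
                                   row.end + jitter, f"{tf}_{row.region_id}"))
    chip_dfs = {
        tf: pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
        if rows else pd.DataFrame(columns=["chrom", "start", "end", "name"])
        for tf, rows in chip_peaks.items()
    }

    n = len(regions)
    signal = pd.DataFrame({"region_id": regions["region_id"].to_numpy()})
    strengths = truth.strength_maps()
    for tf in CORE_TFS + DEVELOPMENTAL_TFS:
        s = strengths.map(lambda m: m.get(tf, 0.0)).to_numpy()
        ratio = rng.lognormal(0.0, 0.3, size=n)
        ratio *= 4.0 ** s            # ChIP/Input rises with planted occupancy
        signal[tf] = ratio

    late = truth.genes.set_index("gene_id")["late_expression"] \
        if "late_expression" in truth.genes.columns else None
    if late is not None:
        base = regions["gene_id"].map(late).fillna(0.0).to_numpy()
        signal["H3K27ac"] = np.maximum(base + rng.normal(0, 0.5, size=n), 0.0)

    # sequences with planted motif consensus for bound core factors
    tf_motif = {"Pou5f1": "pou_like", "Sox2": "sox_like"}
    seqs: dict[str, str] = {}
    placements = []
    for row, bset in zip(regions.itertuples(), bound):
        width = row.end - row.start
        seq = rng.choice(BASES, size=width)
        offset = width // 2
        motif_ids = [tf_motif[tf] for tf in CORE_TFS if tf in bset and tf in tf_motif]
        if "Pou5f1" in bset and "Sox2" in bset and "pou_sox_double" in pwms:
            motif_ids = ["pou_sox_double"]
        for mid in motif_ids:
            cons = pwms[mid].consensus
            if len(cons) > width:
                raise ValueError(f"PWM {mid} wider than region {row.region_id}")
            pos = min(offset, width - len(cons))
            seq[pos:pos + len(cons)] = list(cons)
            placements.append((row.region_id, mid, pos))
            offset = pos + len(cons) + 2
        seqs[row.region_id] = "".join(seq)

    truth.motif_positions = pd.DataFrame(placements, columns=["region_id", "motif_id", "offset"])
    return chip_dfs, signal, seqs


# ---------------------------------------------------------------------------
# full run writer

def write_run(config: SimulationConfig, outdir, mutants: bool = True):
    """Generate everything and write it under ``outdir``; returns the truth.

    Layout: fragments/<sample>.bed, chip/<TF>.bed, signal.tsv,
    expression.tsv, sequences.fa, truth_regions.tsv, truth_genes.tsv,
    manifest.json.
    """
    from pathlib import Path

    outdir = Path(outdir)
    (outdir / "fragments").mkdir(parents=True, exist_ok=True)
    (outdir / "chip").mkdir(exist_ok=True)

    truth = generate_annotation(config)
    expr = generate_expression(config, truth)
    chip, signal, seqs = generate_chip_and_sequence(config, truth)
    frags = generate_all_fragments(config, truth, mutants=mutants)

    for name, df in frags.items():
        write_bed(df, outdir / "fragments" / f"{name}.bed")
    for tf, df in chip.items():
        write_bed(df, outdir / "chip" / f"{tf}.bed", columns=["chrom", "start", "end", "name"])
    write_tsv(signal, outdir / "signal.tsv")
    write_tsv(expr, outdir / "expression.tsv")
    write_fasta(seqs, outdir / "sequences.fa")
    write_tsv(truth.regions, outdir / "truth_regions.tsv")
    write_tsv(truth.genes, outdir / "truth_genes.tsv")
    write_tsv(truth.links, outdir / "truth_links.tsv")
    cfg = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
           for k, v in vars(config).items()}
    cfg["stages"] = list(config.stages)
    write_manifest(outdir / "manifest.json", config=cfg, samples=sorted(frags))
    return truth
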