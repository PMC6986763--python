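"""PWM motif scanning, best-hit scoring, score binning and enrichment.

A PWM is a per-position nucleotide probability model scored as log-odds
against a 0-order background.  Scanning slides the matrix over both strands
of each sequence (N bases contribute zero log-odds) and keeps the best hit
per sequence.  Score p-values come from the exact distribution of the
log-odds score under the background model, computed by dynamic programming
over a rounded score lattice (granularity 0.05 bits by default).

The package ships three synthetic stand-in matrices for the canonical
pou-type, sox-type and pou-sox composite motifs (see ``data/``); they are
constructed consensus-plus-noise matrices, not database entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

ALPHABET = "ACGT"
_IDX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = np.array([3, 2, 1, 0])  # A<->T, C<->G in index space


@dataclass
class PWM:
    """Position probability matrix with derived log-odds scoring."""

    motif_id: str
    probs: np.ndarray                       # width x 4, rows sum to 1
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudo: float = 1e-3

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must be width x 4")
        if self.width < 3:
            raise ValueError("PWM width must be >= 3")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("each PWM position must sum to 1")
        self.background = np.asarray(self.background, dtype=float)
        p = (self.probs + self.pseudo) / (1 + 4 * self.pseudo)
        self.log_odds = np.log2(p / self.background)

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=1))

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @classmethod
    def from_counts(cls, motif_id: str, counts: np.ndarray, **kw) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        return cls(motif_id, counts / counts.sum(axis=1, keepdims=True), **kw)

    def score_distribution(self, granularity: float = 0.05):
        """Exact background distribution of the per-window score.

        Dynamic programming over the integer lattice of rounded per-position
        log-odds; returns (support, pmf) with support in score units.
        """
        q = np.round(self.log_odds / granularity).astype(int)
        pmf, lo = None, 0
        for i in range(self.width):
            lo_i, hi_i = int(q[i].min()), int(q[i].max())
            if pmf is None:
                pmf = np.zeros(hi_i - lo_i + 1)
                for s, p in zip(q[i], self.background):
                    pmf[s - lo_i] += p
            else:
                new = np.zeros(len(pmf) + hi_i - lo_i)
                for s, p in zip(q[i], self.background):
                    new[s - lo_i:s - lo_i + len(pmf)] += p * pmf
                pmf = new
            lo += lo_i
        support = (np.arange(len(pmf)) + lo) * granularity
        return support, pmf

    def score_pvalue(self, score: float, granularity: float = 0.05) -> float:
        """P(background window score >= score), exact by DP."""
        support, pmf = self.score_distribution(granularity)
        return float(pmf[support >= score - granularity / 2].sum())


def read_jaspar(path: str | Path) -> dict[str, PWM]:
    """Parse JASPAR-style count matrices (``>id name`` then A/C/G/T rows)."""
    pwms: dict[str, PWM] = {}
    motif_id, rows = None, {}
    for line in Path(path).read_text().splitlines() + [">"]:
        line = line.strip()
        if line.startswith(">"):
            if motif_id is not None and len(rows) == 4:
                counts = np.array([rows[b] for b in ALPHABET]).T  # width x 4
                pwms[motif_id] = PWM.from_counts(motif_id, counts)
            motif_id = line[1:].split()[0] if len(line) > 1 else None
            rows = {}
        elif line:
            base = line[0].upper()
            nums = line[line.index("[") + 1: line.index("]")].split() \
                if "[" in line else line.split()[1:]
            rows[base] = [float(x) for x in nums]
    return pwms


def read_meme(path: str | Path) -> dict[str, PWM]:
    """Parse MEME-format text motif files (letter-probability matrices)."""
    pwms: dict[str, PWM] = {}
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            motif_id = line.split()[1]
            while i < len(lines) and "letter-probability" not in lines[i]:
                i += 1
            rows = []
            i += 1
            while i < len(lines):
                parts = lines[i].split()
                if len(parts) == 4 and all(_is_float(p) for p in parts):
                    rows.append([float(p) for p in parts])
                    i += 1
                else:
                    break
            if rows:
                pwms[motif_id] = PWM(motif_id, np.array(rows))
        else:
            i += 1
    return pwms


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def default_pwms() -> dict[str, PWM]:
    """The bundled synthetic stand-in motifs (pou-like, sox-like, composite)."""
    path = Path(__file__).parent / "data" / "synthetic_core_motifs.jaspar"
    return read_jaspar(path)


def encode(seq: str) -> np.ndarray:
    """Sequence to integer codes; anything outside ACGT becomes 4 (N)."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(len(arr), 4, dtype=np.int8)
    for base, i in _IDX.items():
        out[arr == ord(base)] = i
    return out


def _window_scores(codes: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Score of every window on one strand; N contributes 0 log-odds."""
    w = log_odds.shape[0]
    n = len(codes) - w + 1
    if n <= 0:
        return np.empty(0)
    padded = np.column_stack([log_odds, np.zeros(w)])  # column 4 = N
    scores = np.zeros(n)
    for i in range(w):
        scores += padded[i, codes[i:i + n]]
    return scores


def scan_best_hit(sequences: dict[str, str], pwm: PWM,
                  p_threshold: float = 0.05,
                  granularity: float = 0.05) -> pd.DataFrame:
    """Best motif hit per sequence over both strands.

    Returns one row per sequence: offset, strand, score, p_value (exact DP
    background p-value of the best window score), seq_p_value (Sidak
    correction of that p over the number of windows scanned, i.e. the
    probability a background sequence of the same length would contain at
    least one window this strong) and ``significant`` (seq_p <= threshold).
    Raises on sequences shorter than the motif.
    """
    support, pmf = pwm.score_distribution(granularity)
    tail = np.concatenate([np.cumsum(pmf[::-1])[::-1], [0.0]])

    def pval(score: float) -> float:
        i = np.searchsorted(support, score - granularity / 2, side="left")
        return float(tail[i])

    rows = []
    for name, seq in sequences.items():
        if len(seq) < pwm.width:
            raise ValueError(f"sequence {name} shorter than motif {pwm.motif_id}")
        codes = encode(seq)
        fwd = _window_scores(codes, pwm.log_odds)
        rc = _COMPLEMENT[np.clip(codes[::-1], 0, 3)]
        rc[codes[::-1] == 4] = 4
        rev = _window_scores(rc, pwm.log_odds)
        best_f = int(np.argmax(fwd))
        best_r = int(np.argmax(rev))
        if rev[best_r] > fwd[best_f]:
            offset = len(seq) - pwm.width - best_r
            strand, score = "-", float(rev[best_r])
        else:
            offset, strand, score = best_f, "+", float(fwd[best_f])
        p = pval(score)
        n_windows = 2 * max(len(fwd), 1)
        seq_p = 1.0 - (1.0 - min(p, 1.0)) ** n_windows
        rows.append((name, offset, strand, score, p, seq_p,
                     seq_p <= p_threshold))
    return pd.DataFrame(rows, columns=["sequence_id", "offset", "strand",
                                       "score", "p_value", "seq_p_value",
                                       "significant"])


def score_bins_vs_effect(best_scores, mutant_log2fc, n_bins: int = 10):
    """Mutant-effect distributions across equal-frequency motif-score bins.

    Bin 1 holds the weakest motif scores.  Returns a per-bin summary table
    (n, median score, median and mean log2FC).
    """
    from .priming import quantile_bins

    scores = np.asarray(best_scores, dtype=float)
    fc = np.asarray(mutant_log2fc, dtype=float)
    if len(scores) < n_bins:
        raise ValueError("fewer regions than bins")
    bins = quantile_bins(scores, n_bins=n_bins)
    rows = []
    for b in range(1, n_bins + 1):
        sel = bins == b
        rows.append((b, int(sel.sum()), float(np.median(scores[sel])),
                     float(np.median(fc[sel])), float(np.mean(fc[sel]))))
    return pd.DataFrame(rows, columns=["bin", "n", "median_score",
                                       "median_log2fc", "mean_log2fc"])


def enrichment_top_regions(foreground: dict[str, str], background: dict[str, str],
                           pwms: dict[str, PWM], p_threshold: float = 0.05,
                           families: dict[str, str] | None = None) -> pd.DataFrame:
    """Presence/absence motif enrichment of foreground vs background sets.

    Per motif: the fraction of sequences with >= 1 hit at ``p_threshold``
    in each set, a one-sided Fisher exact test (enrichment in foreground),
    and BH-adjusted p-values across motifs.  With ``families`` given
    (motif id -> family name) a family-level summary is attached in
    ``.attrs['families']``, reporting the minimal adjusted p-value and the
    maximal foreground hit fraction per family.
    """
    if not foreground:
        raise ValueError("empty foreground set")
    rows = []
    for mid, pwm in pwms.items():
        fg = scan_best_hit(foreground, pwm, p_threshold=p_threshold)
        bg = scan_best_hit(background, pwm, p_threshold=p_threshold)
        a = int(fg["significant"].sum())
        b = len(fg) - a
        c = int(bg["significant"].sum())
        d = len(bg) - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append((mid, a / len(fg), c / len(bg) if len(bg) else 0.0, odds, p))
    out = pd.DataFrame(rows, columns=["motif_id", "fg_fraction", "bg_fraction",
                                      "odds_ratio", "p_value"])
    _, out["q_value"], _, _ = multipletests(out["p_value"], method="fdr_bh")
    out = out.sort_values("q_value", kind="stable").reset_index(drop=True)
    if families:
        fam = out.assign(family=out["motif_id"].map(families))
        summary = fam.groupby("family").agg(
            min_q_value=("q_value", "min"),
            max_fg_fraction=("fg_fraction", "max")).reset_index()
        out.attrs["families"] = summary
    return out
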