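"""Readers and writers for the plain-text formats used throughout the pipeline.

Everything is tab-separated text: fragments and peaks travel as BED
(0-based, half-open), signal and expression tables as TSV with a header,
sequences as FASTA, and run metadata as JSON manifests.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a 3-6 column BED file into a DataFrame.

    Raises ValueError naming the file and line on malformed rows.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            rows.append(fields[:6])
    if not rows:
        return pd.DataFrame(columns=BED6_COLUMNS[:3]).astype({"start": int, "end": int})
    ncol = max(len(r) for r in rows)
    df = pd.DataFrame(rows, columns=BED6_COLUMNS[:ncol])
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if "score" in df.columns:
        df["score"] = pd.to_numeric(df["score"], errors="coerce")
    return df


def write_bed(df: pd.DataFrame, path: str | Path, columns: list[str] | None = None) -> None:
    """Write interval DataFrame as BED; picks standard columns that are present."""
    if columns is None:
        columns = [c for c in BED6_COLUMNS if c in df.columns]
    df.to_csv(path, sep="\t", header=False, index=False, columns=columns)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line.upper())
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_manifest(path: str | Path, **entries) -> None:
    """JSON manifest recording configuration, seeds and provenance of a run."""
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_bedgraph(track, path: str | Path) -> None:
    """Write a CoverageTrack as bedGraph (text substitute for bigwig)."""
    with open(path, "w") as fh:
        for chrom, values in track.values.items():
            bs = track.bin_size
            for i, v in enumerate(values):
                if v != 0:
                    start = i * bs
                    end = min((i + 1) * bs, track.chrom_sizes[chrom])
                    fh.write(f"{chrom}\t{start}\t{end}\t{v:.6g}\n")
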