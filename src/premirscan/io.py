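"""Readers and writers for the plain-text formats used across the package.

FASTA via Biopython; Vienna-style 3-line structure records, BED6 and
TSV feature matrices (with a JSON schema sidecar) implemented here.
All round trips are lossless for the fields each format carries.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path) -> list[tuple[str, str]]:
    """Return (id, sequence) tuples; sequences uppercased, not normalised."""
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


def write_fasta(records, path) -> None:
    """Write (id, sequence) tuples as FASTA."""
    seqs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records]
    SeqIO.write(seqs, str(path), "fasta")


_VIENNA_STRUCT_RE = re.compile(r"^([.()]+)(?:\s+\(\s*(-?\d+(?:\.\d+)?)\s*\))?\s*$")


def read_vienna(path) -> list[tuple[str, str, str, float | None]]:
    """Read Vienna 3-line records: (id, sequence, dotbracket, energy|None)."""
    out = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.startswith(">"):
            raise ValueError(f"line {i + 1}: expected '>' header, got {line!r}")
        if i + 2 >= len(lines):
            raise ValueError(f"line {i + 1}: truncated record")
        rid = line[1:].split()[0]
        seq = lines[i + 1].strip().upper()
        m = _VIENNA_STRUCT_RE.match(lines[i + 2].strip())
        if m is None:
            raise ValueError(f"line {i + 3}: malformed structure line")
        struct = m.group(1)
        if len(struct) != len(seq):
            raise ValueError(f"line {i + 3}: structure/sequence length mismatch")
        energy = float(m.group(2)) if m.group(2) is not None else None
        out.append((rid, seq, struct, energy))
        i += 3
    return out


def write_vienna(records, path) -> None:
    """Write (id, seq, struct, energy|None) tuples as Vienna 3-line records."""
    with open(path, "w") as fh:
        for rid, seq, struct, energy in records:
            fh.write(f">{rid}\n{seq}\n{struct}")
            if energy is not None:
                fh.write(f" ({energy:.2f})")
            fh.write("\n")


def write_bed(intervals, path) -> None:
    """Write BED6 lines from (chrom, start, end, name, score, strand).

    Coordinates are 0-based half-open; score is clamped to [0, 1000].
    """
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in intervals:
            if not 0 <= start < end:
                raise ValueError(f"invalid interval [{start}, {end}) for {name}")
            score = int(max(0, min(1000, round(score))))
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def read_bed(path) -> list[tuple[str, int, int, str, int, str]]:
    out = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("track", "#")):
            continue
        f = line.split("\t")
        if len(f) < 6:
            raise ValueError(f"line {ln}: BED6 requires 6 fields")
        out.append((f[0], int(f[1]), int(f[2]), f[3], int(f[4]), f[5]))
    return out


def write_tsv_matrix(df: pd.DataFrame, path, schema: list[dict] | None = None) -> None:
    """Write a feature matrix as TSV (index = hairpin id); schema rows go to
    a ``<path>.schema.json`` sidecar."""
    df.to_csv(path, sep="\t", index_label="id")
    if schema is not None:
        Path(str(path) + ".schema.json").write_text(json.dumps(schema, indent=1))


def read_tsv_matrix(path) -> tuple[pd.DataFrame, list[dict] | None]:
    df = pd.read_csv(path, sep="\t", index_col="id")
    df.index.name = None
    sidecar = Path(str(path) + ".schema.json")
    schema = json.loads(sidecar.read_text()) if sidecar.exists() else None
    return df, schema
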