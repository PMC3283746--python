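"""File I/O: FASTA, aligned FASTA, TSV and BED.

TSV is the universal tabular dialect of the pipeline: tab-separated with
'#'-prefixed header/comment lines (the first '#' line holds tool version,
seed and config hash).  BED intervals are 0-based half-open.  Protein and
CDS FASTA files must share record ids; a trailing stop codon in a CDS is
stripped on load, records with internal stops are rejected with a warning.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .disorder import DisorderAnnotation
from .repeatscan import ProteinRecord

logger = logging.getLogger("aarscan")

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "read_tsv",
    "write_tsv",
    "read_bed",
    "write_bed",
    "load_proteins",
    "read_disorder_tsv",
    "write_disorder_tsv",
    "config_hash",
]

STOPS = {"TAA", "TAG", "TGA"}


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping.

    Wrapped sequence lines are reassembled; duplicate ids are an error."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"{path}: no FASTA records")
    return out


def write_fasta(path: str | Path, records: dict[str, str], width: int = 60) -> None:
    seqs = [SeqRecord(Seq(s), id=i, description="") for i, s in records.items()]
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta")
    del width  # biopython wraps at 60 by default


def read_alignment(path: str | Path) -> dict[str, str]:
    """Read an aligned FASTA; rows of unequal length raise an error naming
    the offending record."""
    rows = read_fasta(path)
    widths = {len(s) for s in rows.values()}
    if len(widths) > 1:
        ref = len(next(iter(rows.values())))
        for rid, s in rows.items():
            if len(s) != ref:
                raise ValueError(
                    f"{path}: alignment row {rid!r} has length {len(s)}, expected {ref}"
                )
    return rows


def load_proteins(
    protein_fasta: str | Path,
    cds_fasta: str | Path | None = None,
    species: str = "",
) -> list[ProteinRecord]:
    """Pair protein and CDS FASTA records by id.

    A CDS of length 3(L+1) ending in a stop codon has the stop stripped;
    records with internal stop codons (or unpairable lengths) are rejected
    with a logged warning rather than aborting the run.
    """
    prots = read_fasta(protein_fasta)
    cds = read_fasta(cds_fasta) if cds_fasta else {}
    out = []
    for pid, seq in prots.items():
        seq = seq.rstrip("*")
        c = cds.get(pid)
        if c is not None:
            if len(c) == 3 * (len(seq) + 1) and c[-3:] in STOPS:
                c = c[:-3]
            if len(c) != 3 * len(seq):
                logger.warning("record %s: cds/protein length mismatch; dropped", pid)
                continue
            internal = any(c[i : i + 3] in STOPS for i in range(0, len(c) - 3, 3))
            if internal or c[-3:] in STOPS:
                logger.warning("record %s: internal stop codon; dropped", pid)
                continue
        elif cds_fasta:
            logger.warning("record %s: no matching CDS; dropped", pid)
            continue
        out.append(ProteinRecord(pid, seq, cds=c, species=species))
    return out


def config_hash(config) -> str:
    """Short stable hash of a config dataclass / dict for output headers."""
    if hasattr(config, "__dataclass_fields__"):
        from dataclasses import asdict

        config = asdict(config)
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header_lines(seed: int | None, cfg_hash: str | None, note: str | None) -> list[str]:
    parts = [f"aarscan v{__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if cfg_hash:
        parts.append(f"config={cfg_hash}")
    lines = ["# " + " | ".join(parts)]
    if note:
        lines.append(f"# {note}")
    return lines


def write_tsv(
    path: str | Path,
    df: pd.DataFrame,
    seed: int | None = None,
    cfg_hash: str | None = None,
    note: str | None = None,
) -> None:
    """Write a TSV with a '#'-prefixed provenance header."""
    with open(path, "w") as fh:
        for line in _header_lines(seed, cfg_hash, note):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3/BED4 file (0-based half-open intervals)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED line needs >= 3 fields")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(f"{path}:{ln}: empty/inverted interval")
            row = {"chrom": chrom, "start": start, "end": end}
            if len(parts) > 3:
                row["name"] = parts[3]
            rows.append(row)
    if not rows:
        raise ValueError(f"{path}: no BED intervals")
    return pd.DataFrame(rows)


def write_bed(path: str | Path, df: pd.DataFrame) -> None:
    cols = ["chrom", "start", "end"] + (["name"] if "name" in df.columns else [])
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_disorder_tsv(path: str | Path) -> dict[str, DisorderAnnotation]:
    """Read per-protein disorder calls from a two-column TSV
    (protein_id, calls-string of 0/1)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)  # keep leading zeros
    if list(df.columns[:2]) != ["protein_id", "calls"]:
        raise ValueError(f"{path}: expected columns protein_id, calls")
    return {
        r.protein_id: DisorderAnnotation(r.protein_id, str(r.calls))
        for r in df.itertuples()
    }


def write_disorder_tsv(
    path: str | Path, anns: dict[str, DisorderAnnotation], **header
) -> None:
    df = pd.DataFrame(
        {"protein_id": list(anns), "calls": [a.calls for a in anns.values()]}
    )
    write_tsv(path, df, **header)
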