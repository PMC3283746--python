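"""Detection of tandem amino acid repeats (AARs) and repeat-content statistics.

An AAR (homopeptide) is an uninterrupted run of four or more identical amino
acids.  Repeat content of a protein or protein segment is summarised as RRPK
(Repeated Residues per Kilo amino acids): the total number of residues lying
inside AARs divided by the segment length, times 1000.  A protein with at
least one AAR is called a repeat-containing protein (RCP).

Coordinates are 0-based half-open throughout the library; written reports use
1-based inclusive coordinates (stated in their headers).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "STANDARD_AA",
    "ProteinRecord",
    "AAR",
    "RepeatProfile",
    "RegionalProfile",
    "detect_aars",
    "compute_rrpk",
    "gc_content",
    "regional_profile",
    "aar_residue_composition",
    "classify_gc_rich",
    "species_summary",
]

#: The 20 standard amino acids.  Ambiguous residues ('X' or anything else)
#: break runs and never seed a repeat: an ambiguous residue cannot be asserted
#: identical to its neighbours.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Amino acids encoded exclusively by GC-rich codons; alanine, glycine and
#: proline repeats track coding GC content.
GC_RICH_RESIDUES = frozenset("AGP")


@dataclass
class ProteinRecord:
    """A protein sequence with an optional paired coding sequence.

    ``cds`` must be 3x the protein length; a trailing stop codon is expected
    to have been stripped on load (see :mod:`aarscan.io`).
    """

    id: str
    sequence: str
    cds: str | None = None
    species: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        if "-" in self.sequence:
            raise ValueError(f"protein {self.id!r}: sequence contains gap characters")
        if self.cds is not None and len(self.cds) != 3 * len(self.sequence):
            raise ValueError(
                f"protein {self.id!r}: cds length {len(self.cds)} != "
                f"3 x protein length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AAR:
    """A detected repeat: a maximal uniform run ``sequence[start:end]``."""

    protein_id: str
    residue: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RepeatProfile:
    """Per-protein repeat summary."""

    protein_id: str
    aars: list[AAR]
    rrpk: float
    gc: float | None
    is_rcp: bool


@dataclass
class RegionalProfile:
    """RRPK and GC of the N-terminal, middle and C-terminal thirds."""

    protein_id: str
    rrpk_n: float
    rrpk_mid: float
    rrpk_c: float
    gc_n: float | None = None
    gc_mid: float | None = None
    gc_c: float | None = None
    bounds: tuple[int, int, int, int] = field(default=(0, 0, 0, 0))


def detect_aars(protein: ProteinRecord, min_len: int = 4) -> list[AAR]:
    """Return all maximal uniform runs of length >= ``min_len``.

    Runs are reported left to right and never overlap.  Only the 20 standard
    amino acids can form a run; 'X' and any other letter break runs.
    """
    if min_len < 1:
        raise ValueError("min_len must be positive")
    seq = protein.sequence
    out: list[AAR] = []
    for m in re.finditer(rf"(.)\1{{{min_len - 1},}}", seq):
        if m.group(1) in STANDARD_AA:
            out.append(AAR(protein.id, m.group(1), m.start(), m.end()))
    return out


def compute_rrpk(sequence_length: int, aars: list[AAR]) -> float:
    """RRPK = 1000 x (total repeat residues) / (sequence length)."""
    if sequence_length <= 0:
        raise ValueError("sequence_length must be positive")
    total = 0
    for a in aars:
        if a.start < 0 or a.end > sequence_length:
            raise ValueError(f"AAR [{a.start},{a.end}) outside [0,{sequence_length})")
        total += a.length
    return 1000.0 * total / sequence_length


def gc_content(cds: str) -> float | None:
    """GC fraction over the unambiguous bases of a nucleotide string.

    IUPAC ambiguity codes are excluded from numerator and denominator.
    Returns ``None`` when no unambiguous base is present.
    """
    if not cds:
        raise ValueError("empty nucleotide string")
    s = cds.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        return None
    return gc / (gc + at)


def thirds_partition(n: int) -> tuple[int, int, int]:
    """Segment sizes splitting ``n`` residues into thirds.

    For n = 3q + r the remainder goes to the N-terminal side first: the first
    ``r`` segments get q+1 residues.  Fixed so that N-terminal accumulation is
    measured against a stated convention.
    """
    q, r = divmod(n, 3)
    return tuple(q + (1 if i < r else 0) for i in range(3))  # type: ignore[return-value]


def _segment_repeat_residues(aars: list[AAR], lo: int, hi: int) -> int:
    """Repeat residues of ``aars`` falling inside [lo, hi)."""
    return sum(max(0, min(a.end, hi) - max(a.start, lo)) for a in aars)


def regional_profile(protein: ProteinRecord, aars: list[AAR]) -> RegionalProfile:
    """Split the protein into thirds and compute regional RRPK (and GC).

    An AAR spanning a boundary contributes its residues to each side, which
    keeps ``sum(segment_len * rrpk_seg) / 1000`` equal to the total repeat
    residue count.  Regional GC projects the residues' codons when a CDS is
    attached.
    """
    n = len(protein)
    if n < 3:
        raise ValueError("protein shorter than 3 residues cannot be split into thirds")
    s1, s2, s3 = thirds_partition(n)
    b0, b1, b2, b3 = 0, s1, s1 + s2, n
    rrpks = []
    gcs: list[float | None] = []
    for lo, hi in ((b0, b1), (b1, b2), (b2, b3)):
        rep = _segment_repeat_residues(aars, lo, hi)
        rrpks.append(1000.0 * rep / (hi - lo))
        if protein.cds is not None:
            gcs.append(gc_content(protein.cds[3 * lo : 3 * hi]))
        else:
            gcs.append(None)
    return RegionalProfile(
        protein.id, rrpks[0], rrpks[1], rrpks[2], gcs[0], gcs[1], gcs[2],
        bounds=(b0, b1, b2, b3),
    )


def aar_residue_composition(
    proteins: list[ProteinRecord], aars_by_protein: dict[str, list[AAR]]
) -> pd.DataFrame:
    """Residue composition inside AARs vs the whole protein set.

    Returns a DataFrame indexed by amino acid with columns ``repeat_fraction``
    and ``background_fraction``; each column sums to 1.  Only standard
    residues are tallied (in both vectors, so the two are comparable).  When
    the set contains no AAR the repeat column is all-NaN (flagged).
    """
    if not proteins:
        raise ValueError("empty protein set")
    aa_order = sorted(STANDARD_AA)
    rep = dict.fromkeys(aa_order, 0)
    bg = dict.fromkeys(aa_order, 0)
    for p in proteins:
        for aa in p.sequence:
            if aa in STANDARD_AA:
                bg[aa] += 1
        for a in aars_by_protein.get(p.id, []):
            rep[a.residue] += a.length
    rep_total = sum(rep.values())
    bg_total = sum(bg.values())
    df = pd.DataFrame(index=aa_order)
    df["repeat_fraction"] = (
        [rep[aa] / rep_total for aa in aa_order] if rep_total else float("nan")
    )
    df["background_fraction"] = [bg[aa] / bg_total for aa in aa_order]
    return df


def classify_gc_rich(aar: AAR) -> bool:
    """True iff the repeat residue is encoded by GC-rich codons (A, G or P)."""
    return aar.residue in GC_RICH_RESIDUES


def repeat_profile(protein: ProteinRecord, min_len: int = 4) -> RepeatProfile:
    """Detect AARs and summarise a single protein."""
    aars = detect_aars(protein, min_len=min_len)
    return RepeatProfile(
        protein_id=protein.id,
        aars=aars,
        rrpk=compute_rrpk(len(protein), aars),
        gc=gc_content(protein.cds) if protein.cds else None,
        is_rcp=bool(aars),
    )


def species_summary(proteins: list[ProteinRecord], min_len: int = 4) -> pd.DataFrame:
    """Per-species mean RRPK, mean GC and AARs per protein.

    Mean RRPK is the unweighted mean of per-protein RRPK; AARs per protein is
    the total AAR count over the protein count.
    """
    if not proteins:
        raise ValueError("empty protein set")
    rows = []
    for p in proteins:
        prof = repeat_profile(p, min_len=min_len)
        rows.append(
            {
                "species": p.species,
                "rrpk": prof.rrpk,
                "gc": prof.gc,
                "n_aars": len(prof.aars),
                "is_rcp": prof.is_rcp,
            }
        )
    df = pd.DataFrame(rows)
    out = df.groupby("species", sort=True).agg(
        n_proteins=("rrpk", "size"),
        mean_rrpk=("rrpk", "mean"),
        mean_gc=("gc", "mean"),
        aars_per_protein=("n_aars", "mean"),
        rcp_fraction=("is_rcp", "mean"),
    )
    return out.reset_index()
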