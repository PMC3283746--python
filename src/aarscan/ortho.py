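"""Repeat conservation and flanking-region evolution in ortholog alignments.

Operates on groups of 1-to-1 orthologous proteins with a protein multiple
sequence alignment and a codon alignment obtained by back-translation.  The
analyses: map each repeat onto its alignment-column span; classify it as
failing to align (the corresponding region in every other ortholog is filled
with gaps) or partially aligned; find conserved long repeats (length >= 8
supported by >= 8 other orthologs at >= 50% identity over the span); extract
up-to-33-residue flanking regions; and compare flank vs whole-protein dN/dS
per species with a Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median

import numpy as np
import pandas as pd

from .dnds import DnDsResult, codon_indices, ng86_from_indices
from .repeatscan import AAR, ProteinRecord, detect_aars
from .stats import TestReport, mann_whitney_u

__all__ = [
    "OrthologGroup",
    "AlignedAAR",
    "FlankRegion",
    "map_aar_to_columns",
    "conservation_status",
    "find_conserved_long_aars",
    "extract_flanks",
    "project_to_codons",
    "pair_codon_strings",
    "flank_vs_whole_comparison",
]

GAP = "-"


@dataclass
class OrthologGroup:
    """Aligned orthologous proteins with their codon alignment."""

    group_id: str
    members: list[tuple[str, ProteinRecord]]  # (species, record)
    msa: list[str]
    codon_msa: list[str]

    def __post_init__(self) -> None:
        widths = {len(r) for r in self.msa}
        if len(widths) != 1:
            raise ValueError(f"group {self.group_id}: unequal alignment row lengths")
        (w,) = widths
        for (sp, rec), row, crow in zip(self.members, self.msa, self.codon_msa):
            if row.replace(GAP, "") != rec.sequence:
                raise ValueError(
                    f"group {self.group_id}, member {rec.id}: ungapped row != sequence"
                )
            if len(crow) != 3 * w:
                raise ValueError(
                    f"group {self.group_id}, member {rec.id}: codon row not 3x protein row"
                )
            for col, aa in enumerate(row):
                codon = crow[3 * col : 3 * col + 3]
                if (aa == GAP) != (codon == GAP * 3):
                    raise ValueError(
                        f"group {self.group_id}, member {rec.id}: codon gap not "
                        f"co-located with protein gap at column {col}"
                    )

    @property
    def width(self) -> int:
        return len(self.msa[0])

    def column_maps(self) -> list[np.ndarray]:
        """For each member, residue index -> alignment column."""
        maps = []
        for row in self.msa:
            maps.append(np.flatnonzero(np.frombuffer(row.encode(), dtype=np.uint8) != ord(GAP)))
        return maps


@dataclass(frozen=True)
class AlignedAAR:
    """A repeat with its alignment-column span in its own row."""

    aar: AAR
    member_index: int
    col_start: int
    col_end: int

    @property
    def span(self) -> tuple[int, int]:
        return self.col_start, self.col_end


@dataclass(frozen=True)
class FlankRegion:
    """Up to ``flank_len`` residues abutting one side of a repeat."""

    protein_id: str
    side: str  # "left" | "right"
    start: int
    end: int


def back_translate_row(row: str, cds: str) -> str:
    """Codon-alignment row for a protein row: gaps become '---', residues
    consume successive codons of the unaligned CDS."""
    if len(cds) != 3 * len(row.replace(GAP, "")):
        raise ValueError(
            f"cds length {len(cds)} != 3 x ungapped row length "
            f"{len(row.replace(GAP, ''))}"
        )
    parts = []
    k = 0
    for ch in row:
        if ch == GAP:
            parts.append(GAP * 3)
        else:
            parts.append(cds[3 * k : 3 * k + 3])
            k += 1
    return "".join(parts)


def group_from_files(
    group_id: str,
    msa_rows: dict[str, str],
    cds_by_id: dict[str, str],
    species_by_id: dict[str, str],
) -> OrthologGroup:
    """Assemble an OrthologGroup from an aligned protein FASTA, unaligned
    CDS records (matched by id; back-translation done here) and species
    labels."""
    members = []
    msa = []
    codon_msa = []
    for rid, row in msa_rows.items():
        if rid not in cds_by_id:
            raise ValueError(f"group {group_id}: no CDS for member {rid!r}")
        cds = cds_by_id[rid]
        seq = row.replace(GAP, "")
        rec = ProteinRecord(rid, seq, cds=cds, species=species_by_id.get(rid, ""))
        members.append((rec.species, rec))
        msa.append(row)
        codon_msa.append(back_translate_row(row, cds))
    return OrthologGroup(group_id, members, msa, codon_msa)


def map_aar_to_columns(group: OrthologGroup, focal_member: int, aar: AAR) -> AlignedAAR:
    """Minimal column span whose ungapped focal content is the repeat tract."""
    cmap = group.column_maps()[focal_member]
    if aar.start < 0 or aar.end > len(cmap):
        raise ValueError(f"AAR [{aar.start},{aar.end}) outside member sequence")
    return AlignedAAR(aar, focal_member, int(cmap[aar.start]), int(cmap[aar.end - 1]) + 1)


def conservation_status(
    group: OrthologGroup, aligned: AlignedAAR, gap_frac_threshold: float = 0.5
) -> str:
    """'fails_to_align' iff every other member's gap fraction over the span
    strictly exceeds ``gap_frac_threshold``; otherwise 'partially_aligned'."""
    lo, hi = aligned.span
    width = hi - lo
    for i, row in enumerate(group.msa):
        if i == aligned.member_index:
            continue
        gap_frac = row.count(GAP, lo, hi) / width
        if gap_frac <= gap_frac_threshold:
            return "partially_aligned"
    return "fails_to_align"


def region_identity(row: str, span: tuple[int, int], residue: str) -> float:
    """Fraction of span columns where ``row`` carries ``residue`` (gaps mismatch)."""
    lo, hi = span
    return row.count(residue, lo, hi) / (hi - lo)


def find_conserved_long_aars(
    group: OrthologGroup,
    min_repeat_len: int = 8,
    min_supporting: int = 8,
    min_identity: float = 0.5,
    min_len: int = 4,
) -> list[AlignedAAR]:
    """Conserved long repeats: length >= ``min_repeat_len`` and supported by
    >= ``min_supporting`` other members at region identity >= ``min_identity``.

    A member's region identity is the fraction of span columns carrying the
    repeat's amino acid (gap columns count as mismatches).
    """
    if len(group.members) < min_supporting + 1:
        raise ValueError(
            f"group {group.group_id}: needs >= {min_supporting + 1} members"
        )
    out = []
    for m, (_, rec) in enumerate(group.members):
        for aar in detect_aars(rec, min_len=min_len):
            if aar.length < min_repeat_len:
                continue
            aligned = map_aar_to_columns(group, m, aar)
            support = sum(
                1
                for i, row in enumerate(group.msa)
                if i != m and region_identity(row, aligned.span, aar.residue) >= min_identity
            )
            if support >= min_supporting:
                out.append(aligned)
    return out


def extract_flanks(
    protein: ProteinRecord, aars: list[AAR], flank_len: int = 33
) -> list[FlankRegion]:
    """Flanking regions: up to ``flank_len`` residues on both sides of each
    repeat, truncated at the protein ends and at adjacent repeats.  The region
    between two repeats closer than 2x``flank_len`` is shared by both (each
    side truncated at the other repeat's boundary); zero-length regions are
    dropped.  Flanks never overlap any repeat.
    """
    aars = sorted(aars, key=lambda a: a.start)
    n = len(protein)
    out = []
    for k, a in enumerate(aars):
        prev_end = aars[k - 1].end if k > 0 else 0
        nxt_start = aars[k + 1].start if k + 1 < len(aars) else n
        lo = max(0, a.start - flank_len, prev_end)
        if lo < a.start:
            out.append(FlankRegion(protein.id, "left", lo, a.start))
        hi = min(n, a.end + flank_len, nxt_start)
        if a.end < hi:
            out.append(FlankRegion(protein.id, "right", a.end, hi))
    return out


def project_to_codons(group: OrthologGroup, region_cols: tuple[int, int]) -> tuple[int, int]:
    """Codon-column span [3*col_start, 3*col_end) of a protein-column span."""
    lo, hi = region_cols
    if not (0 <= lo <= hi <= group.width):
        raise ValueError(f"column span [{lo},{hi}) outside alignment width {group.width}")
    return 3 * lo, 3 * hi


_AMBIG = set("RYSWKMBDHVNU")


def pair_codon_strings(
    group: OrthologGroup, i: int, j: int, col_spans: list[tuple[int, int]]
) -> tuple[str, str]:
    """Gap-free codon strings for a member pair over protein-column spans.

    Columns where either member has a gap, an ambiguity code or a stop-free
    violation are excluded listwise for this pair.
    """
    from .dnds import CODON_INDEX, _tables

    rows = (group.codon_msa[i], group.codon_msa[j])
    a_parts: list[str] = []
    b_parts: list[str] = []
    sense = _tables()["is_sense"]
    for lo, hi in col_spans:
        for col in range(lo, hi):
            ca = rows[0][3 * col : 3 * col + 3]
            cb = rows[1][3 * col : 3 * col + 3]
            if GAP in ca or GAP in cb:
                continue
            if set(ca) & _AMBIG or set(cb) & _AMBIG:
                continue
            ia, ib = CODON_INDEX.get(ca), CODON_INDEX.get(cb)
            if ia is None or ib is None or not (sense[ia] and sense[ib]):
                continue
            a_parts.append(ca)
            b_parts.append(cb)
    return "".join(a_parts), "".join(b_parts)


def _merged_spans(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open spans, so no codon is counted twice per protein."""
    if not spans:
        return []
    spans = sorted(spans)
    out = [list(spans[0])]
    for lo, hi in spans[1:]:
        if lo <= out[-1][1]:
            out[-1][1] = max(out[-1][1], hi)
        else:
            out.append([lo, hi])
    return [(lo, hi) for lo, hi in out]


def _complement_spans(spans: list[tuple[int, int]], width: int) -> list[tuple[int, int]]:
    """Half-open spans covering [0, width) minus the given merged spans."""
    out = []
    cur = 0
    for lo, hi in spans:
        if lo > cur:
            out.append((cur, lo))
        cur = max(cur, hi)
    if cur < width:
        out.append((cur, width))
    return out


def _mean_pairwise_ratio(
    group: OrthologGroup,
    focal: int,
    spans: list[tuple[int, int]],
    min_codons: int = 10,
    aggregation: str = "pooled",
) -> tuple[float | None, list[DnDsResult]]:
    """Per-protein dN/dS of the focal member over the spans, across all pairs.

    ``aggregation='pooled'`` (default) sums synonymous/nonsynonymous site and
    difference counts over every ortholog pair before forming a single ratio;
    pooling keeps the estimator nearly unbiased even when each region
    contributes few substitutions, whereas averaging per-pair ratios
    ('mean') inflates short regions by the sampling variance of their dS.
    """
    from math import log

    ratios = []
    results = []
    sd = nd = s_sites = n_sites = 0.0
    for j in range(len(group.members)):
        if j == focal:
            continue
        ca, cb = pair_codon_strings(group, focal, j, spans)
        if len(ca) < 3 * min_codons:
            continue
        res = ng86_from_indices(
            codon_indices(ca),
            codon_indices(cb),
            (group.members[focal][1].id, group.members[j][1].id),
        )
        results.append(res)
        sd += res.syn_diffs
        nd += res.nonsyn_diffs
        s_sites += res.s_sites
        n_sites += res.n_sites
        if res.ratio is not None and "saturated" not in res.flags:
            ratios.append(res.ratio)
    if aggregation == "mean":
        return (float(np.mean(ratios)) if ratios else None), results
    if s_sites <= 0 or n_sites <= 0:
        return None, results
    ps, pn = sd / s_sites, nd / n_sites
    if ps >= 0.75 or pn >= 0.75 or ps == 0:
        return None, results
    ds = -0.75 * log(1 - (4.0 / 3.0) * ps)
    dn = 0.0 if pn == 0 else -0.75 * log(1 - (4.0 / 3.0) * pn)
    return dn / ds, results


def flank_vs_whole_comparison(
    groups: list[OrthologGroup],
    flank_len: int = 33,
    min_len: int = 4,
    min_codons: int = 10,
) -> pd.DataFrame:
    """Per-species comparison of flank vs whole-protein dN/dS over RCPs.

    For every repeat-containing member of every group, computes (a) the
    average pairwise NG86 dN/dS over the union of its repeat-flanking regions
    and (b) over the whole protein; per species, tests flanks vs wholes with a
    Mann-Whitney U test and reports medians and the fraction of flank values
    exceeding 1 (positive-selection candidates).  The pooled row aggregates
    all species.
    """
    per_species: dict[str, dict[str, list[float]]] = {}
    for g in groups:
        cmap = g.column_maps()
        for m, (species, rec) in enumerate(g.members):
            aars = detect_aars(rec, min_len=min_len)
            if not aars:
                continue
            flanks = extract_flanks(rec, aars, flank_len=flank_len)
            if not flanks:
                continue
            flank_spans = _merged_spans(
                [(int(cmap[m][f.start]), int(cmap[m][f.end - 1]) + 1) for f in flanks]
            )
            # whole protein minus the repeat tracts themselves: a maintained
            # homopolymer contributes no nonsynonymous signal by definition,
            # so it is excluded from the baseline rather than diluting it
            aar_spans = _merged_spans(
                [(int(cmap[m][a.start]), int(cmap[m][a.end - 1]) + 1) for a in aars]
            )
            whole_spans = _complement_spans(aar_spans, g.width)
            fl, _ = _mean_pairwise_ratio(g, m, flank_spans, min_codons)
            wh, _ = _mean_pairwise_ratio(g, m, whole_spans, min_codons)
            if fl is None or wh is None:
                continue
            d = per_species.setdefault(species, {"flank": [], "whole": []})
            d["flank"].append(fl)
            d["whole"].append(wh)

    rows = []
    pooled = {"flank": [], "whole": []}
    for species in sorted(per_species):
        d = per_species[species]
        pooled["flank"] += d["flank"]
        pooled["whole"] += d["whole"]
        rows.append(_comparison_row(species, d))
    if pooled["flank"]:
        rows.append(_comparison_row("__pooled__", pooled))
    return pd.DataFrame(rows)


def _comparison_row(species: str, d: dict[str, list[float]]) -> dict:
    fl, wh = d["flank"], d["whole"]
    reliable = len(fl) >= 2 and len(wh) >= 2
    if reliable:
        rep: TestReport = mann_whitney_u(fl, wh, method="asymptotic")
        u, p = rep.statistic, rep.p_value
    else:
        u, p = float("nan"), float("nan")
    return {
        "species": species,
        "n_proteins": len(fl),
        "median_flank_dnds": median(fl),
        "median_whole_dnds": median(wh),
        "mw_u": u,
        "mw_p": p,
        "frac_flank_gt1": sum(1 for v in fl if v > 1) / len(fl),
        "reliable": reliable,
    }
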