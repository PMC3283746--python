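"""Transcript-level regulation statistics for repeat-containing proteins.

Covers: expression normalization and the tissue-specificity index
TSI = sum_i(1 - x_i/x_max) / (N - 1) over N tissues (0 = uniform,
1 = single-tissue); per-locus aggregation of probe-level statistics; the
mRNA half-life comparison (Welch's t); splice-class repeat content
(alternative vs constitutive exons); and recombination-hotspot neighbour
enrichment (Fisher's exact 2x2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .repeatscan import AAR, ProteinRecord
from .stats import TestReport, fisher_exact_2x2, welch_t

__all__ = [
    "ExpressionMatrix",
    "TissueSpecificityResult",
    "GeneModelTable",
    "ExonSegment",
    "normalize_expression",
    "tissue_specificity_index",
    "aggregate_per_locus",
    "compare_rcp_half_lives",
    "classify_exons",
    "exon_segment_rrpk",
    "hotspot_neighbor_enrichment",
]


@dataclass
class ExpressionMatrix:
    """Gene/probe x tissue values; NaN marks below-background (absent) calls."""

    values: pd.DataFrame  # index: gene/probe ids, columns: tissue labels
    log_scale: bool = False

    def __post_init__(self) -> None:
        if self.values.shape[1] < 2:
            raise ValueError("expression matrix needs at least 2 tissues")


@dataclass
class TissueSpecificityResult:
    gene: str
    tsi: float
    n_tissues_used: int
    defined: bool = True
    floored: bool = False


def normalize_expression(raw: ExpressionMatrix) -> ExpressionMatrix:
    """log2-transform present values, subtract each tissue's mean, then add
    the grand mean over all present log values.

    After normalization every column mean equals the grand mean, removing
    between-tissue scale differences while keeping values on a common level.
    """
    if raw.log_scale:
        raise ValueError("matrix already log scale")
    v = raw.values
    if (v <= 0).any().any():
        raise ValueError("raw expression values must be positive where present")
    logv = np.log2(v)
    grand = float(np.nanmean(logv.to_numpy()))
    norm = logv - logv.mean(axis=0) + grand
    return ExpressionMatrix(norm, log_scale=True)


def tissue_specificity_index(x) -> TissueSpecificityResult:
    """TSI = sum_i(1 - x_i/x_max) / (N - 1) over the usable tissues.

    Masked (NaN) tissues are dropped; negative values are floored at 0 first
    (the index assumes nonnegative input; flooring is flagged).  Undefined
    (flagged) when fewer than 2 tissues are usable or x_max <= 0.
    """
    arr = np.asarray(x, dtype=float)
    name = getattr(x, "name", "") or ""
    arr = arr[~np.isnan(arr)]
    n = len(arr)
    if n < 2:
        return TissueSpecificityResult(name, float("nan"), n, defined=False)
    floored = bool((arr < 0).any())
    arr = np.maximum(arr, 0.0)
    xmax = arr.max()
    if xmax <= 0:
        return TissueSpecificityResult(name, float("nan"), n, defined=False, floored=floored)
    tsi = float(np.sum(1.0 - arr / xmax) / (n - 1))
    return TissueSpecificityResult(name, tsi, n, floored=floored)


def aggregate_per_locus(values: pd.Series, probe_map: pd.Series) -> pd.Series:
    """Unweighted mean of probe-level statistics per locus.

    ``probe_map`` maps probe id -> locus id; probes without a locus and loci
    without probes are absent from the output.
    """
    df = pd.DataFrame({"value": values})
    df["locus"] = df.index.map(probe_map)
    df = df.dropna(subset=["locus"])
    return df.groupby("locus")["value"].mean()


def compare_rcp_half_lives(
    half_lives: pd.Series, rcp_flags: pd.Series
) -> TestReport:
    """Welch's t-test of RCP vs non-RCP transcript half-lives (hours)."""
    common = half_lives.index.intersection(rcp_flags.index)
    hl = half_lives.loc[common]
    fl = rcp_flags.loc[common].astype(bool)
    a = hl[fl].to_numpy()
    b = hl[~fl].to_numpy()
    if len(a) < 2 or len(b) < 2:
        rep = TestReport(float("nan"), float("nan"), (len(a), len(b)), "welch_t")
        rep.reliable = False
        rep.extra = {
            "mean_a": float(np.mean(a)) if len(a) else float("nan"),
            "mean_b": float(np.mean(b)) if len(b) else float("nan"),
        }
        return rep
    rep = welch_t(a, b)
    rep.extra["direction"] = "rcp_shorter" if a.mean() < b.mean() else "rcp_longer"
    return rep


@dataclass
class GeneModelTable:
    """Gene models as lists of genomic exon intervals (0-based half-open)."""

    gene: str
    models: dict[str, list[tuple[int, int]]]
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError(f"gene {self.gene}: needs >= 1 model")
        for mid, exons in self.models.items():
            s = sorted(exons)
            for (a1, b1), (a2, b2) in zip(s, s[1:]):
                if a2 < b1:
                    raise ValueError(f"gene {self.gene} model {mid}: overlapping exons")

    @property
    def alternatively_spliced(self) -> bool:
        return len(self.models) >= 2


@dataclass
class ExonSegment:
    protein_id: str
    exon_class: str  # "alternative" | "constitutive"
    start: int  # residue coordinates, half-open
    end: int
    rrpk: float = 0.0
    repeat_residues: int = 0


def classify_exons(models: GeneModelTable) -> dict[tuple[int, int], str]:
    """Classify each exon interval of the gene.

    An exon (by exact genomic interval) is constitutive iff the identical
    interval occurs in every model; otherwise alternative.  Single-model
    genes have all exons constitutive.
    """
    all_models = [set(ex) for ex in models.models.values()]
    shared = set.intersection(*all_models)
    out = {}
    for exons in models.models.values():
        for iv in exons:
            out[iv] = "constitutive" if iv in shared else "alternative"
    return out


def exon_segment_rrpk(
    protein: ProteinRecord,
    aars: list[AAR],
    exons: list[tuple[int, int, str]],
) -> list[ExonSegment]:
    """Per-exon-segment repeat content of a protein.

    ``exons`` lists the representative model's coding exons in translation
    order as (genomic_start, genomic_end, class); their lengths must sum to
    the CDS length (3x protein length).  Each residue maps to the exon
    containing the *first base of its codon* (junction codons go to the
    upstream/5' exon).  Boundary-spanning repeats are split by residue, so
    per-class repeat residues sum to the protein's total.
    """
    lens = [e - s for s, e, _ in exons]
    if sum(lens) != 3 * len(protein):
        raise ValueError(
            f"{protein.id}: coding-exon lengths sum to {sum(lens)}, "
            f"expected {3 * len(protein)}"
        )
    # CDS offset boundaries of the exons
    bounds = np.concatenate([[0], np.cumsum(lens)])
    segments: list[ExonSegment] = []
    for k, (_, _, cls) in enumerate(exons):
        # residues whose codon's first base (cds position 3*i) lies in exon k
        lo_res = int(np.ceil(bounds[k] / 3))
        hi_res = int(np.ceil(bounds[k + 1] / 3))
        if hi_res <= lo_res:
            continue  # exon too short to own any codon start
        rep = sum(max(0, min(a.end, hi_res) - max(a.start, lo_res)) for a in aars)
        segments.append(
            ExonSegment(
                protein_id=protein.id,
                exon_class=cls,
                start=lo_res,
                end=hi_res,
                rrpk=1000.0 * rep / (hi_res - lo_res),
                repeat_residues=rep,
            )
        )
    return segments


def hotspot_neighbor_enrichment(
    gene_intervals: pd.DataFrame,
    hotspot_intervals: pd.DataFrame,
    rcp_flags: pd.Series,
) -> TestReport:
    """Fisher's exact test of hotspot neighbourhood vs repeat content.

    A gene is hotspot-neighbouring iff its interval overlaps any hotspot
    interval by >= 1 bp (half-open coordinates, shared chromosome naming).
    Both DataFrames need columns chrom/start/end; ``gene_intervals`` also
    needs ``name``.  Degenerate tables (a zero margin) are flagged.
    """
    neighbor = pd.Series(False, index=gene_intervals["name"].to_numpy())
    by_chrom = {c: df for c, df in hotspot_intervals.groupby("chrom")}
    for _, g in gene_intervals.iterrows():
        hs = by_chrom.get(g["chrom"])
        if hs is None:
            continue
        if ((hs["start"] < g["end"]) & (hs["end"] > g["start"])).any():
            neighbor[g["name"]] = True
    common = neighbor.index.intersection(rcp_flags.index)
    nb = neighbor.loc[common].astype(bool)
    rc = rcp_flags.loc[common].astype(bool)
    table = [
        [int((rc & nb).sum()), int((rc & ~nb).sum())],
        [int((~rc & nb).sum()), int((~rc & ~nb).sum())],
    ]
    rep = fisher_exact_2x2(table)
    n_rcp = table[0][0] + table[0][1]
    n_non = table[1][0] + table[1][1]
    rep.extra["frac_neighbor_rcp"] = table[0][0] / n_rcp if n_rcp else float("nan")
    rep.extra["frac_neighbor_nonrcp"] = table[1][0] / n_non if n_non else float("nan")
    if min(sum(r) for r in table) == 0 or min(table[0][0] + table[1][0],
                                              table[0][1] + table[1][1]) == 0:
        rep.reliable = False
    return rep
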