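"""Nei-Gojobori (1986) dN/dS estimation on codon sequences.

The NG86 method counts, for each codon, the expected numbers of synonymous
and nonsynonymous *sites* by the fractional method (at each codon position,
the fraction of the possible single-nucleotide changes that are synonymous;
changes to stop codons are excluded from the denominator), and the numbers of
synonymous and nonsynonymous *differences* between two codons by averaging
over all minimal mutational pathways (pathways passing through a stop codon
are discarded unless every pathway does).  Proportions pS = Sd/S and
pN = Nd/N are corrected for multiple hits with the Jukes-Cantor formula
d = -(3/4) ln(1 - (4/3) p).

Counting tables over the standard genetic code are precomputed once, so that
estimation over long sequences reduces to integer indexing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from math import log

import numpy as np

__all__ = ["DnDsResult", "ng86_dnds", "ng86_from_indices", "codon_indices"]

NUCS = "TCAG"
#: all 64 codons in TCAG order; index = 16*i1 + 4*i2 + i3
CODONS = [a + b + c for a in NUCS for b in NUCS for c in NUCS]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

_STANDARD_CODE = {}


def _build_code() -> dict[str, str]:
    from Bio.Data.CodonTable import standard_dna_table

    code = dict(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        code[stop] = "*"
    # Biopython's table uses T; fill any missing codons defensively
    return {c: code[c] for c in CODONS}


def _translate(codon: str) -> str:
    global _STANDARD_CODE
    if not _STANDARD_CODE:
        _STANDARD_CODE = _build_code()
    return _STANDARD_CODE[codon]


def _syn_sites(codon: str) -> float:
    """Expected synonymous sites of a sense codon (fractional method)."""
    aa = _translate(codon)
    s = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for n in NUCS:
            if n == codon[pos]:
                continue
            alt = codon[:pos] + n + codon[pos + 1 :]
            alt_aa = _translate(alt)
            if alt_aa == "*":
                continue  # mutations to stop codons are not counted
            valid += 1
            if alt_aa == aa:
                syn += 1
        if valid:
            s += syn / valid
    return s


def _pathway_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) differences between two codons.

    Enumerates every ordering of the differing positions; a pathway is
    dropped if any *intermediate* codon is a stop (unless all pathways are).
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff_pos):
        cur = c1
        sd = nd = 0
        through_stop = False
        for step, pos in enumerate(order):
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if _translate(nxt) == "*" and step < len(order) - 1:
                through_stop = True
            if _translate(nxt) == _translate(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((through_stop, sd, nd))
    usable = [p for p in paths if not p[0]] or paths
    sd = sum(p[1] for p in usable) / len(usable)
    nd = sum(p[2] for p in usable) / len(usable)
    return sd, nd


_TABLES: dict[str, np.ndarray] = {}


def _tables() -> dict[str, np.ndarray]:
    """Precomputed NG86 counting tables over all 64 codons."""
    if _TABLES:
        return _TABLES
    syn_sites = np.full(64, np.nan)
    is_sense = np.zeros(64, dtype=bool)
    for i, c in enumerate(CODONS):
        if _translate(c) != "*":
            is_sense[i] = True
            syn_sites[i] = _syn_sites(c)
    sd = np.full((64, 64), np.nan)
    nd = np.full((64, 64), np.nan)
    for i, c1 in enumerate(CODONS):
        if not is_sense[i]:
            continue
        for j, c2 in enumerate(CODONS):
            if not is_sense[j]:
                continue
            s, n = _pathway_diffs(c1, c2)
            sd[i, j] = s
            nd[i, j] = n
    _TABLES.update(syn_sites=syn_sites, is_sense=is_sense, sd=sd, nd=nd)
    return _TABLES


@dataclass
class DnDsResult:
    """NG86 estimate for one sequence pair."""

    pair: tuple[str, str]
    dn: float
    ds: float
    ratio: float | None
    n_sites: float
    s_sites: float
    n_codons: int = 0
    syn_diffs: float = 0.0
    nonsyn_diffs: float = 0.0
    flags: list[str] = field(default_factory=list)

    @property
    def defined(self) -> bool:
        return self.ratio is not None and not self.flags


def codon_indices(seq: str) -> np.ndarray:
    """Encode a gap-free codon string into codon indices (0..63)."""
    if len(seq) % 3:
        raise ValueError("sequence length not divisible by 3")
    s = seq.upper()
    try:
        return np.array(
            [CODON_INDEX[s[i : i + 3]] for i in range(0, len(s), 3)], dtype=np.int64
        )
    except KeyError as e:  # ambiguity codes must be pre-filtered
        raise ValueError(f"non-ACGT codon {e.args[0]!r}") from None


def _jc(p: float) -> float | None:
    """Jukes-Cantor correction; None when saturated (p >= 3/4)."""
    if p >= 0.75:
        return None
    if p == 0.0:
        return 0.0
    return -0.75 * log(1 - (4.0 / 3.0) * p)


def ng86_from_indices(
    idx_a: np.ndarray, idx_b: np.ndarray, pair: tuple[str, str] = ("a", "b")
) -> DnDsResult:
    """NG86 on pre-encoded codon index arrays (stop codons not allowed)."""
    t = _tables()
    if idx_a.shape != idx_b.shape:
        raise ValueError("unequal codon counts")
    if idx_a.size == 0:
        raise ValueError("empty codon sequences")
    if not (t["is_sense"][idx_a].all() and t["is_sense"][idx_b].all()):
        raise ValueError("stop codon in input; pre-filter before NG86")
    s_sites = float((t["syn_sites"][idx_a].sum() + t["syn_sites"][idx_b].sum()) / 2.0)
    n_codons = int(idx_a.size)
    n_sites = 3.0 * n_codons - s_sites
    sd = float(t["sd"][idx_a, idx_b].sum())
    nd = float(t["nd"][idx_a, idx_b].sum())
    flags: list[str] = []
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ds = _jc(ps)
    dn = _jc(pn)
    if ds is None or dn is None:
        return DnDsResult(
            pair, float("nan"), float("nan"), None, n_sites, s_sites, n_codons,
            syn_diffs=sd, nonsyn_diffs=nd, flags=["saturated"],
        )
    if ds == 0.0:
        ratio = None
        flags.append("undefined_ratio" if dn == 0.0 else "infinite_ratio")
    else:
        ratio = dn / ds
    return DnDsResult(
        pair, dn, ds, ratio, n_sites, s_sites, n_codons,
        syn_diffs=sd, nonsyn_diffs=nd, flags=flags,
    )


def ng86_dnds(codons_a: str, codons_b: str, pair: tuple[str, str] = ("a", "b")) -> DnDsResult:
    """NG86 dN/dS between two equal-length, gap-free codon strings."""
    if len(codons_a) != len(codons_b):
        raise ValueError("sequences must have equal length")
    return ng86_from_indices(codon_indices(codons_a), codon_indices(codons_b), pair)
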