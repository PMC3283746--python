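"""Synthetic input generator for the repeat-analysis pipeline.

Emulates, at desk scale, the statistical structure the analyses assume:

* per-species proteomes whose seeded repeat load rises linearly with coding
  GC (expected repeat residues per protein = base + beta * GC), while the
  amino-acid composition is GC-independent — coding GC varies only through
  synonymous codon usage, so with beta = 0 repeat content and GC are
  independent by construction;
* ortholog groups evolved from a group ancestor on a star phylogeny, with
  nonsynonymous substitutions accepted at a relaxed rate inside repeat
  flanks, repeat-tract indels only (so protein alignments are exact by
  construction) and tracts that are either conserved across all members or
  lineage-specific;
* per-residue disorder pseudo-annotations (two tracks with different
  sensitivity/specificity trade-offs), enriched inside repeats;
* log-normal tissue expression with configurable tissue-specific repeat
  proteins, exponential mRNA half-lives shortened for repeat proteins,
  multi-model gene structures whose alternative exons are repeat-enriched,
  and gene/hotspot intervals with a configurable repeat-hotspot overlap
  boost.

Ground-truth labels (tract positions, conserved tracts, class flags) are
always written alongside, so tests never re-derive them by a second method.
Identical seed + config produces a byte-identical bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .disorder import DisorderAnnotation
from .dnds import CODONS, _translate
from .ortho import GAP, OrthologGroup
from .regulation import ExpressionMatrix, GeneModelTable
from .repeatscan import ProteinRecord, detect_aars

__all__ = [
    "GeneratorConfig",
    "SyntheticBundle",
    "generate_bundle",
    "generate_proteome",
    "generate_ortholog_groups",
    "toy_disorder_annotator",
]

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_LETTERS)}

#: background amino-acid composition (broad eukaryotic average, normalized)
_BG_COMP = {
    "A": 0.079, "R": 0.051, "N": 0.043, "D": 0.054, "C": 0.019, "Q": 0.038,
    "E": 0.063, "G": 0.071, "H": 0.023, "I": 0.053, "L": 0.091, "K": 0.058,
    "M": 0.022, "F": 0.040, "P": 0.048, "S": 0.068, "T": 0.054, "W": 0.013,
    "Y": 0.032, "V": 0.065,
}

#: residues favoured inside seeded repeat tracts (disorder-promoting set)
_REPEAT_W = {
    "S": 0.22, "Q": 0.16, "A": 0.14, "G": 0.12, "P": 0.10, "E": 0.10,
    "T": 0.06, "D": 0.05, "N": 0.05,
}

#: mean of the seeded tract-length distribution (4 + truncated geometric)
MEAN_TRACT_LEN = 5.8


def _norm_vec(d: dict[str, float]) -> np.ndarray:
    v = np.array([d.get(a, 0.0) for a in AA_LETTERS])
    return v / v.sum()


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic generator, with the default study conditions.

    ``slippage_gc_coupling`` (beta) sets the expected seeded repeat residues
    per protein to ``base_repeat_residues + beta * GC_target``; beta = 0
    decouples repeat load from GC entirely.
    """

    seed: int = 0
    # proteomes
    n_species: int = 10
    n_proteins: int = 200
    protein_length_range: tuple[int, int] = (120, 300)
    gc_range: tuple[float, float] = (0.38, 0.62)
    base_repeat_residues: float = 0.5
    slippage_gc_coupling: float = 12.0
    # ortholog groups
    n_groups: int = 40
    group_size: int | None = None  # default: n_species
    group_length_range: tuple[int, int] = (160, 260)
    conserved_repeat_prob: float = 0.3
    mutation_rate: float = 0.30  # per codon, per species branch (pairwise dS ~ 0.3)
    nonsyn_acceptance: float = 0.25  # purifying selection strength (omega proxy)
    flank_relaxation: float = 3.0  # nonsyn acceptance multiplier in flanks
    flank_len: int = 33
    # disorder pseudo-tracks
    disorder_in_repeat_p: float = 0.90
    disorder_background_p: float = 0.30
    disorder_in_repeat_p2: float = 0.60
    disorder_background_p2: float = 0.12
    disorder_window: int = 10
    # regulation
    n_tissues: int = 6
    tissue_specific_rcp_frac: float = 0.5
    tissue_specific_bg_frac: float = 0.1
    rcp_halflife_factor: float = 0.6
    mean_halflife_h: float = 4.0
    alt_splice_prob: float = 0.15
    multi_probe_prob: float = 0.2
    absent_call_prob: float = 0.04
    n_hotspots: int = 40
    hotspot_rcp_boost: float = 3.0
    min_len: int = 4

    def __post_init__(self) -> None:
        lo, hi = self.protein_length_range
        if not (0 < lo <= hi):
            raise ValueError("protein_length_range must be positive and ordered")
        glo, ghi = self.group_length_range
        if not (0 < glo <= ghi):
            raise ValueError("group_length_range must be positive and ordered")
        for name in (
            "conserved_repeat_prob", "disorder_in_repeat_p", "disorder_background_p",
            "disorder_in_repeat_p2", "disorder_background_p2", "alt_splice_prob",
            "tissue_specific_rcp_frac", "tissue_specific_bg_frac",
            "multi_probe_prob", "absent_call_prob", "nonsyn_acceptance",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.slippage_gc_coupling < 0:
            raise ValueError("slippage_gc_coupling must be >= 0")
        if self.flank_relaxation < 1:
            raise ValueError("flank_relaxation must be >= 1")
        if self.rcp_halflife_factor <= 0:
            raise ValueError("rcp_halflife_factor must be > 0")
        if glo < 2 * self.flank_len + 14:
            raise ValueError(
                "group_length_range too short to place a tract with flanks"
            )

    @property
    def species_names(self) -> list[str]:
        return [f"sp{i + 1:02d}" for i in range(self.n_species)]

    @property
    def gc_targets(self) -> np.ndarray:
        lo, hi = self.gc_range
        if self.n_species == 1:
            return np.array([(lo + hi) / 2])
        return np.linspace(lo, hi, self.n_species)


# --- codon machinery -------------------------------------------------------

_SYN_SETS: dict[str, list[str]] = {}


def _syn_sets() -> dict[str, list[str]]:
    if not _SYN_SETS:
        for c in CODONS:
            aa = _translate(c)
            if aa != "*":
                _SYN_SETS.setdefault(aa, []).append(c)
    return _SYN_SETS


_CHOICE_CACHE: dict[float, dict] = {}


def _codon_choice_tables(gc_target: float):
    """Per-amino-acid codon arrays and cumulative GC-biased weights.

    Codon weight = g^nGC * (1-g)^(3-nGC) with g the species GC target, so the
    synonymous codon usage (hence coding GC) tracks the target while the
    protein sequence is untouched.
    """
    if gc_target in _CHOICE_CACHE:
        return _CHOICE_CACHE[gc_target]
    tables = {}
    for aa, codons in _syn_sets().items():
        ngc = np.array([c.count("G") + c.count("C") for c in codons])
        w = gc_target**ngc * (1 - gc_target) ** (3 - ngc)
        w = w / w.sum()
        tables[AA_INDEX[aa]] = (np.array(codons), np.cumsum(w))
    _CHOICE_CACHE[gc_target] = tables
    return tables


def _encode_cds(res_idx: np.ndarray, gc_target: float, rng: np.random.Generator) -> np.ndarray:
    """Choose a codon (string array) for every residue index."""
    tables = _codon_choice_tables(gc_target)
    codons = np.empty(len(res_idx), dtype="<U3")
    for aa_idx, (carr, cumw) in tables.items():
        mask = res_idx == aa_idx
        m = int(mask.sum())
        if m:
            codons[mask] = carr[np.searchsorted(cumw, rng.random(m), side="right").clip(max=len(carr) - 1)]
    return codons


def _draw_tract_lengths(rng: np.random.Generator, n: int) -> np.ndarray:
    return 4 + np.minimum(rng.geometric(0.35, n) - 1, 10)


# --- proteomes -------------------------------------------------------------


def generate_proteome(
    species: str, gc_target: float, cfg: GeneratorConfig, rng: np.random.Generator
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """One species' proteome plus its ground-truth tract table.

    Seeded tracts are reconciled with the final sequence (expanded to the
    maximal uniform run and merged), so the truth table lists exactly the
    seeded repeats as they stand in the emitted sequences.
    """
    comp = _norm_vec(_BG_COMP)
    repw = _norm_vec(_REPEAT_W)
    lo, hi = cfg.protein_length_range
    n = cfg.n_proteins
    lengths = rng.integers(lo, hi + 1, n)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    res = rng.choice(len(AA_LETTERS), int(lengths.sum()), p=comp).astype(np.int8)

    exp_rep = max(0.0, cfg.base_repeat_residues + cfg.slippage_gc_coupling * gc_target)
    lam = exp_rep / MEAN_TRACT_LEN
    k_arr = rng.poisson(lam, n)
    tract_bounds: list[list[tuple[int, int]]] = []
    for i in range(n):
        L = int(lengths[i])
        o = int(offsets[i])
        occupied: list[tuple[int, int]] = []
        k = int(k_arr[i])
        if k:
            tls = _draw_tract_lengths(rng, k)
            aas = rng.choice(len(AA_LETTERS), k, p=repw)
            for tl, aa in zip(tls, aas):
                tl = int(tl)
                if tl > L:
                    continue
                for _ in range(10):
                    s = int(rng.integers(0, L - tl + 1))
                    if all(s + tl <= a or s >= b for a, b in occupied):
                        res[o + s : o + s + tl] = aa
                        occupied.append((s, s + tl))
                        break
        tract_bounds.append(sorted(occupied))

    # codon assignment for the whole proteome at once (one pass per amino acid)
    all_codons = _encode_cds(res, gc_target, rng)

    # reconcile truth with the final sequences: expand to maximal runs, merge
    truth_rows = []
    proteins = []
    aa_bytes = np.frombuffer(AA_LETTERS.encode(), dtype=np.uint8)
    for i in range(n):
        L = int(lengths[i])
        o = int(offsets[i])
        sub = res[o : o + L]
        pid = f"{species}_p{i + 1:04d}"
        expanded = []
        for s, e in tract_bounds[i]:
            aa = sub[s]
            while s > 0 and sub[s - 1] == aa:
                s -= 1
            while e < L and sub[e] == aa:
                e += 1
            expanded.append((s, e))
        merged: list[list[int]] = []
        for s, e in sorted(expanded):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        seq = bytes(aa_bytes[sub]).decode()
        cds = "".join(all_codons[o : o + L])
        proteins.append(ProteinRecord(pid, seq, cds=cds, species=species))
        for s, e in merged:
            truth_rows.append(
                {"protein_id": pid, "species": species, "residue": seq[s],
                 "start": s, "end": e}
            )
    truth = pd.DataFrame(
        truth_rows, columns=["protein_id", "species", "residue", "start", "end"]
    )
    return proteins, truth


# --- disorder pseudo-annotation -------------------------------------------


def toy_disorder_annotator(
    protein: ProteinRecord,
    seed: int,
    config: GeneratorConfig,
    in_repeat_p: float | None = None,
    background_p: float | None = None,
) -> DisorderAnnotation:
    """Bernoulli per-residue disorder calls enriched in repeat neighbourhoods.

    Residues inside a detected repeat +/- ``disorder_window`` are called
    disordered with probability ``in_repeat_p``, all others with
    ``background_p``.  Deterministic given the seed.
    """
    p_in = config.disorder_in_repeat_p if in_repeat_p is None else in_repeat_p
    p_bg = config.disorder_background_p if background_p is None else background_p
    rng = np.random.default_rng(seed)
    L = len(protein)
    p = np.full(L, p_bg)
    for a in detect_aars(protein, min_len=config.min_len):
        lo = max(0, a.start - config.disorder_window)
        hi = min(L, a.end + config.disorder_window)
        p[lo:hi] = p_in
    calls = (rng.random(L) < p).astype(np.uint8) + ord("0")
    return DisorderAnnotation(protein.id, bytes(calls.tobytes()).decode())


# --- ortholog groups -------------------------------------------------------


def _mutate_codon(
    codon: str, rng: np.random.Generator, accept_nonsyn: float
) -> str:
    """One proposed point mutation; stops rejected, nonsynonymous changes
    accepted with probability ``accept_nonsyn``."""
    pos = int(rng.integers(3))
    alts = [n for n in "TCAG" if n != codon[pos]]
    alt = alts[int(rng.integers(3))]
    new = codon[:pos] + alt + codon[pos + 1 :]
    if _translate(new) == "*":
        return codon
    if _translate(new) != _translate(codon) and rng.random() >= accept_nonsyn:
        return codon
    return new


def generate_ortholog_groups(
    cfg: GeneratorConfig, rng: np.random.Generator
) -> tuple[list[OrthologGroup], pd.DataFrame]:
    """Ortholog groups with exact alignments built by construction.

    Each group descends from one ancestor carrying a single seeded repeat
    tract.  Tracts are conserved (all members keep the full tract, length
    8-12) with probability ``conserved_repeat_prob``, otherwise
    lineage-specific (only the first member keeps it; others retain 0-3
    residues, the rest becoming alignment gaps).  Nonsynonymous substitutions
    are accepted at ``nonsyn_acceptance`` genome-wide and at
    ``min(1, nonsyn_acceptance * flank_relaxation)`` within ``flank_len``
    residues of the tract.  Indels occur only inside tracts, so alignment
    columns are placed without an aligner.
    """
    comp = _norm_vec(_BG_COMP)
    repw = _norm_vec(_REPEAT_W)
    size = cfg.group_size or cfg.n_species
    species = [f"sp{i + 1:02d}" for i in range(size)]
    accept_bg = cfg.nonsyn_acceptance
    accept_flank = min(1.0, cfg.nonsyn_acceptance * cfg.flank_relaxation)
    groups = []
    truth_rows = []
    glo, ghi = cfg.group_length_range
    for gi in range(cfg.n_groups):
        L = int(rng.integers(glo, ghi + 1))
        anc = rng.choice(len(AA_LETTERS), L, p=comp).astype(np.int8)
        conserved = rng.random() < cfg.conserved_repeat_prob
        tl = int(rng.integers(8, 13)) if conserved else int(rng.integers(4, 9))
        margin = cfg.flank_len + 2
        ts = int(rng.integers(margin, L - margin - tl + 1))
        taa = int(rng.choice(len(AA_LETTERS), p=repw))
        anc[ts : ts + tl] = taa
        anc_codons = _encode_cds(anc, 0.5, rng)

        flank_lo = max(0, ts - cfg.flank_len)
        flank_hi = min(L, ts + tl + cfg.flank_len)

        member_codons = []
        member_tl = []
        for m in range(size):
            cods = anc_codons.copy()
            hit = np.flatnonzero(rng.random(L) < cfg.mutation_rate)
            for pos in hit:
                if ts <= pos < ts + tl:
                    # the tract is maintained: only synonymous changes fix,
                    # at the same per-site proposal rate as everywhere else
                    accept = 0.0
                elif flank_lo <= pos < flank_hi:
                    accept = accept_flank
                else:
                    accept = accept_bg
                cods[pos] = _mutate_codon(str(cods[pos]), rng, accept)
            if conserved or m == 0:
                keep = tl
            else:
                keep = int(rng.integers(0, 4))
            member_tl.append(keep)
            member_codons.append(cods)

        gid = f"g{gi + 1:03d}"
        members = []
        msa = []
        codon_msa = []
        for m, sp in enumerate(species):
            cods = member_codons[m]
            keep = member_tl[m]
            kept_idx = np.concatenate(
                [np.arange(ts), np.arange(ts, ts + keep), np.arange(ts + tl, L)]
            ).astype(int)
            seq_codons = cods[kept_idx]
            seq_aa = "".join(AA_LETTERS[AA_INDEX[_translate(str(c))]] for c in seq_codons)
            cds = "".join(seq_codons)
            rec = ProteinRecord(f"{gid}_{sp}", seq_aa, cds=cds, species=sp)
            members.append((sp, rec))
            row_parts = [seq_aa[:ts], seq_aa[ts : ts + keep], GAP * (tl - keep), seq_aa[ts + keep :]]
            msa.append("".join(row_parts))
            crow_parts = [cds[: 3 * ts], cds[3 * ts : 3 * (ts + keep)],
                          GAP * 3 * (tl - keep), cds[3 * (ts + keep) :]]
            codon_msa.append("".join(crow_parts))
        groups.append(OrthologGroup(gid, members, msa, codon_msa))
        truth_rows.append(
            {
                "group_id": gid,
                "residue": AA_LETTERS[taa],
                "tract_col_start": ts,
                "tract_col_end": ts + tl,
                "tract_len": tl,
                "conserved": conserved,
                "member_tract_lens": ",".join(str(k) for k in member_tl),
            }
        )
    return groups, pd.DataFrame(truth_rows)


# --- regulation inputs -----------------------------------------------------


def _generate_regulation(
    proteins: list[ProteinRecord],
    rcp_flags: pd.Series,
    cfg: GeneratorConfig,
    truth: pd.DataFrame,
    rng: np.random.Generator,
):
    genes = [p.id for p in proteins]
    tissues = [f"tissue_{j + 1}" for j in range(cfg.n_tissues)]

    # probes
    probe_rows = []
    for g in genes:
        k = 2 if rng.random() < cfg.multi_probe_prob else 1
        for j in range(k):
            probe_rows.append((f"{g}.probe{j + 1}", g))
    probe_map = pd.Series({p: g for p, g in probe_rows})

    # expression: log2 base level + tissue shift + specificity + noise
    spec_flag = {}
    for g in genes:
        frac = cfg.tissue_specific_rcp_frac if rcp_flags[g] else cfg.tissue_specific_bg_frac
        spec_flag[g] = rng.random() < frac
    tissue_shift = rng.normal(0, 0.5, cfg.n_tissues)
    rows = {}
    for p, g in probe_rows:
        base = rng.normal(7.0, 1.5)
        vals = base + tissue_shift + rng.normal(0, 0.3, cfg.n_tissues)
        if spec_flag[g]:
            dom = int(rng.integers(cfg.n_tissues))
            vals = vals - 2.5
            vals[dom] = base + tissue_shift[dom] + 3.0
        raw = np.power(2.0, vals)
        absent = rng.random(cfg.n_tissues) < cfg.absent_call_prob
        raw[absent] = np.nan
        rows[p] = raw
    expr = ExpressionMatrix(pd.DataFrame.from_dict(rows, orient="index", columns=tissues))
    expr.values.index.name = "probe"

    # half-lives (hours), exponential; RCP transcripts decay faster
    hl = {}
    for p, g in probe_rows:
        scale = cfg.mean_halflife_h * (cfg.rcp_halflife_factor if rcp_flags[g] else 1.0)
        hl[p] = rng.exponential(scale)
    half_lives = pd.Series(hl, name="half_life_h")

    # gene models: contiguous coding exons along one chromosome
    tracts_by_pid: dict[str, list[tuple[int, int]]] = {}
    for r in truth.itertuples():
        tracts_by_pid.setdefault(r.protein_id, []).append((r.start, r.end))
    models: list[GeneModelTable] = []
    gene_bed = []
    pos = 1000
    for p in proteins:
        cds_len = 3 * len(p)
        n_ex = int(rng.integers(1, 6))
        if n_ex > 1:
            cuts = np.sort(rng.choice(np.arange(1, cds_len), n_ex - 1, replace=False))
            bounds = np.concatenate([[0], cuts, [cds_len]])
        else:
            bounds = np.array([0, cds_len])
        exons = []
        cur = pos
        for k in range(len(bounds) - 1):
            ex_len = int(bounds[k + 1] - bounds[k])
            exons.append((cur, cur + ex_len))
            cur += ex_len + 120  # intron
        model_d = {"m1": exons}
        if len(exons) >= 2 and rng.random() < cfg.alt_splice_prob:
            # alternative exon preferentially the most repeat-rich one
            rep_per_exon = []
            for k in range(len(bounds) - 1):
                lo_res = int(np.ceil(bounds[k] / 3))
                hi_res = int(np.ceil(bounds[k + 1] / 3))
                rep = sum(
                    max(0, min(e, hi_res) - max(s, lo_res))
                    for s, e in tracts_by_pid.get(p.id, [])
                )
                rep_per_exon.append(rep)
            if max(rep_per_exon) > 0 and rng.random() < 0.7:
                drop = int(np.argmax(rep_per_exon))
            else:
                drop = int(rng.integers(len(exons)))
            model_d["m2"] = [e for k, e in enumerate(exons) if k != drop]
        models.append(GeneModelTable(p.id, model_d))
        gene_bed.append(("chr1", pos, cur - 120, p.id))
        pos = cur + 500
    genes_bed = pd.DataFrame(gene_bed, columns=["chrom", "start", "end", "name"])

    # hotspots: anchored on RCP genes with boosted probability
    chrom_end = int(genes_bed["end"].max() + 5000)
    w = np.where(rcp_flags[genes_bed["name"]].to_numpy(), cfg.hotspot_rcp_boost, 1.0)
    hs_rows = []
    for _ in range(cfg.n_hotspots):
        if rng.random() < 0.5:
            gi = int(rng.choice(len(genes_bed), p=w / w.sum()))
            g = genes_bed.iloc[gi]
            centre = int(rng.integers(g["start"], g["end"]))
        else:
            centre = int(rng.integers(0, chrom_end))
        hs_rows.append(("chr1", max(0, centre - 1000), centre + 1000))
    hotspots_bed = pd.DataFrame(hs_rows, columns=["chrom", "start", "end"])
    hotspots_bed = hotspots_bed.sort_values(["start", "end"]).reset_index(drop=True)

    return expr, probe_map, half_lives, models, genes_bed, hotspots_bed


# --- bundle ----------------------------------------------------------------


@dataclass
class SyntheticBundle:
    config: GeneratorConfig
    proteomes: dict[str, list[ProteinRecord]]
    tract_truth: pd.DataFrame
    groups: list[OrthologGroup]
    group_truth: pd.DataFrame
    disorder_tracks: dict[str, dict[str, DisorderAnnotation]]
    expression: ExpressionMatrix
    probe_map: pd.Series
    half_lives: pd.Series
    gene_models: list[GeneModelTable]
    genes_bed: pd.DataFrame
    hotspots_bed: pd.DataFrame
    rcp_flags: pd.Series = field(default_factory=pd.Series)

    @property
    def all_proteins(self) -> list[ProteinRecord]:
        return [p for ps in self.proteomes.values() for p in ps]


def generate_bundle(config: GeneratorConfig) -> SyntheticBundle:
    """Generate every pipeline input from one seed (see module docstring)."""
    rng = np.random.default_rng(config.seed)
    proteomes: dict[str, list[ProteinRecord]] = {}
    truth_frames = []
    for sp, gc in zip(config.species_names, config.gc_targets):
        prots, truth = generate_proteome(sp, float(gc), config, rng)
        proteomes[sp] = prots
        truth_frames.append(truth)
    tract_truth = pd.concat(truth_frames, ignore_index=True)

    groups, group_truth = generate_ortholog_groups(config, rng)

    tracks: dict[str, dict[str, DisorderAnnotation]] = {"vsl2b_like": {}, "iupred_like": {}}
    for p in [q for ps in proteomes.values() for q in ps]:
        s1, s2 = rng.integers(2**31, size=2)
        tracks["vsl2b_like"][p.id] = toy_disorder_annotator(p, int(s1), config)
        tracks["iupred_like"][p.id] = toy_disorder_annotator(
            p, int(s2), config,
            in_repeat_p=config.disorder_in_repeat_p2,
            background_p=config.disorder_background_p2,
        )

    focal = config.species_names[0]
    focal_truth_ids = set(tract_truth.loc[tract_truth["species"] == focal, "protein_id"])
    rcp_flags = pd.Series(
        {p.id: (p.id in focal_truth_ids) or bool(detect_aars(p, config.min_len))
         for p in proteomes[focal]}
    )
    expr, probe_map, half_lives, models, genes_bed, hotspots_bed = _generate_regulation(
        proteomes[focal], rcp_flags, config, tract_truth, rng
    )

    return SyntheticBundle(
        config=config,
        proteomes=proteomes,
        tract_truth=tract_truth,
        groups=groups,
        group_truth=group_truth,
        disorder_tracks=tracks,
        expression=expr,
        probe_map=probe_map,
        half_lives=half_lives,
        gene_models=models,
        genes_bed=genes_bed,
        hotspots_bed=hotspots_bed,
        rcp_flags=rcp_flags,
    )


def with_seed(cfg: GeneratorConfig, seed: int) -> GeneratorConfig:
    """A copy of ``cfg`` with a different seed."""
    return replace(cfg, seed=seed)
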