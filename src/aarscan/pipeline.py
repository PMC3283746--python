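"""End-to-end orchestration: simulate -> scan -> evolve -> disorder ->
regulate -> report.

Each stage is a pure function over a :class:`~aarscan.synth.SyntheticBundle`
(or equivalent loaded inputs) returning DataFrames; :func:`run_all` wires
them in dependency order, writes every table as TSV with a provenance header
(tool version, seed, config hash) and a human-readable summary.  With a fixed
seed the whole output directory is byte-identical across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .disorder import random_segment_null
from .io import config_hash, write_bed, write_disorder_tsv, write_fasta, write_tsv
from .ortho import (
    conservation_status,
    find_conserved_long_aars,
    flank_vs_whole_comparison,
    map_aar_to_columns,
)
from .regulation import (
    aggregate_per_locus,
    classify_exons,
    compare_rcp_half_lives,
    exon_segment_rrpk,
    hotspot_neighbor_enrichment,
    normalize_expression,
    tissue_specificity_index,
)
from .repeatscan import (
    aar_residue_composition,
    classify_gc_rich,
    detect_aars,
    regional_profile,
    repeat_profile,
    species_summary,
)
from .stats import grubbs_test, pearson, welch_t
from .synth import GeneratorConfig, SyntheticBundle, generate_bundle

logger = logging.getLogger("aarscan")

__all__ = ["PipelineConfig", "run_all", "scan_stage", "evolve_stage",
           "disorder_stage", "regulate_stage", "write_bundle"]


@dataclass
class PipelineConfig:
    out: Path
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    min_len: int = 4
    gap_frac_threshold: float = 0.5
    min_repeat_len: int = 8
    min_supporting: int = 8
    min_identity: float = 0.5
    flank_len: int = 33
    n_trials: int = 1000
    write_bundle_files: bool = True


# --- stage: scan -----------------------------------------------------------


def scan_stage(bundle: SyntheticBundle, min_len: int = 4) -> dict:
    """Per-protein profiles, per-AAR table, species summary with the
    RRPK-GC correlation and the Grubbs outlier call, regional RRPK and
    residue composition."""
    prof_rows, aar_rows, reg_rows = [], [], []
    for sp, prots in bundle.proteomes.items():
        for p in prots:
            prof = repeat_profile(p, min_len=min_len)
            prof_rows.append(
                {
                    "protein_id": p.id, "species": sp, "length": len(p),
                    "n_aars": len(prof.aars),
                    "total_repeat_len": sum(a.length for a in prof.aars),
                    "rrpk": prof.rrpk, "gc": prof.gc, "is_rcp": prof.is_rcp,
                }
            )
            for a in prof.aars:
                aar_rows.append(
                    {
                        "protein_id": p.id, "species": sp, "residue": a.residue,
                        "start_1based": a.start + 1, "end_1based": a.end,
                        "length": a.length, "gc_rich": classify_gc_rich(a),
                    }
                )
            reg = regional_profile(p, prof.aars)
            reg_rows.append(
                {
                    "protein_id": p.id, "species": sp,
                    "rrpk_n": reg.rrpk_n, "rrpk_mid": reg.rrpk_mid, "rrpk_c": reg.rrpk_c,
                    "gc_n": reg.gc_n, "gc_mid": reg.gc_mid, "gc_c": reg.gc_c,
                }
            )
    profiles = pd.DataFrame(prof_rows)
    aar_table = pd.DataFrame(aar_rows)
    summary = species_summary(bundle.all_proteins, min_len=min_len)

    try:
        corr = pearson(summary["mean_gc"], summary["mean_rrpk"])
        slope, intercept = np.polyfit(summary["mean_gc"], summary["mean_rrpk"], 1)
        residuals = summary["mean_rrpk"] - (slope * summary["mean_gc"] + intercept)
        grubbs = grubbs_test(residuals.to_numpy())
        outlier_species = summary["species"].iloc[grubbs.extra["outlier_index"]]
    except ValueError as e:  # < 3 species or degenerate variance
        logger.warning("species-level correlation skipped: %s", e)
        corr = grubbs = None
        outlier_species = ""

    regional = (
        pd.DataFrame(reg_rows)
        .groupby("species")[["rrpk_n", "rrpk_mid", "rrpk_c", "gc_n", "gc_mid", "gc_c"]]
        .mean()
        .reset_index()
    )
    aars_by_protein = {}
    for r in aar_rows:
        from .repeatscan import AAR

        aars_by_protein.setdefault(r["protein_id"], []).append(
            AAR(r["protein_id"], r["residue"], r["start_1based"] - 1, r["end_1based"])
        )
    composition = aar_residue_composition(bundle.all_proteins, aars_by_protein).reset_index(
        names="residue"
    )
    return {
        "profiles": profiles,
        "aars": aar_table,
        "species_summary": summary,
        "regional": regional,
        "composition": composition,
        "rrpk_gc_pearson": corr,
        "grubbs": grubbs,
        "grubbs_outlier_species": outlier_species,
    }


# --- stage: evolve ---------------------------------------------------------


def evolve_stage(
    bundle: SyntheticBundle,
    min_len: int = 4,
    gap_frac_threshold: float = 0.5,
    min_repeat_len: int = 8,
    min_supporting: int = 8,
    min_identity: float = 0.5,
    flank_len: int = 33,
) -> dict:
    """Conservation calls per AAR, conserved long AARs and the flank vs
    whole-protein dN/dS comparison."""
    cons_rows, conserved_rows = [], []
    for g in bundle.groups:
        for m, (sp, rec) in enumerate(g.members):
            for aar in detect_aars(rec, min_len=min_len):
                aligned = map_aar_to_columns(g, m, aar)
                status = conservation_status(g, aligned, gap_frac_threshold)
                cons_rows.append(
                    {
                        "group_id": g.group_id, "protein_id": rec.id, "species": sp,
                        "residue": aar.residue, "length": aar.length,
                        "col_start": aligned.col_start, "col_end": aligned.col_end,
                        "status": status,
                    }
                )
        if len(g.members) >= min_supporting + 1:
            for aligned in find_conserved_long_aars(
                g, min_repeat_len, min_supporting, min_identity, min_len
            ):
                rec = g.members[aligned.member_index][1]
                conserved_rows.append(
                    {
                        "group_id": g.group_id, "protein_id": rec.id,
                        "residue": aligned.aar.residue, "length": aligned.aar.length,
                        "col_start": aligned.col_start, "col_end": aligned.col_end,
                    }
                )
    conservation = pd.DataFrame(
        cons_rows,
        columns=["group_id", "protein_id", "species", "residue", "length",
                 "col_start", "col_end", "status"],
    )
    frac_fail = (
        float((conservation["status"] == "fails_to_align").mean())
        if len(conservation)
        else float("nan")
    )
    conserved = pd.DataFrame(
        conserved_rows,
        columns=["group_id", "protein_id", "residue", "length", "col_start", "col_end"],
    )
    flank_report = flank_vs_whole_comparison(
        bundle.groups, flank_len=flank_len, min_len=min_len
    )
    return {
        "conservation": conservation,
        "frac_fails_to_align": frac_fail,
        "conserved_long": conserved,
        "flank_report": flank_report,
    }


# --- stage: disorder -------------------------------------------------------


def disorder_stage(bundle: SyntheticBundle, n_trials: int = 1000, min_len: int = 4) -> dict:
    """Fully-disordered AAR fraction and the random-segment permutation p,
    per species and per annotation track."""
    rows = []
    seed_base = bundle.config.seed
    for si, (sp, prots) in enumerate(bundle.proteomes.items()):
        aars = []
        rcps = []
        for p in prots:
            found = detect_aars(p, min_len=min_len)
            if found:
                aars += found
                rcps.append(p)
        if not aars:
            logger.warning("species %s: no AARs; disorder test skipped", sp)
            continue
        for track, anns in bundle.disorder_tracks.items():
            res = random_segment_null(
                aars, rcps, anns, n_trials=n_trials,
                seed=(seed_base * 1009 + si) % (2**31),
            )
            rows.append(
                {
                    "species": sp, "track": track, "n_aars": len(aars),
                    "observed_fraction": res.observed_fraction,
                    "empirical_p": res.empirical_p, "n_trials": res.n_trials,
                    "seed": res.seed,
                }
            )
    return {"disorder": pd.DataFrame(rows)}


# --- stage: regulate -------------------------------------------------------


def regulate_stage(bundle: SyntheticBundle, min_len: int = 4) -> dict:
    """Tissue-specificity, half-life, splice-class and hotspot analyses for
    the focal species."""
    focal = bundle.config.species_names[0]
    prots = {p.id: p for p in bundle.proteomes[focal]}
    rcp = bundle.rcp_flags

    norm = normalize_expression(bundle.expression)
    tsi_probe = pd.Series(
        {pid: tissue_specificity_index(row).tsi for pid, row in norm.values.iterrows()}
    )
    tsi_locus = aggregate_per_locus(tsi_probe, bundle.probe_map)
    tsi_df = tsi_locus.rename("tsi").rename_axis("gene").reset_index()
    common = tsi_locus.index.intersection(rcp.index)
    tsi_rcp = tsi_locus[common][rcp[common]].dropna()
    tsi_non = tsi_locus[common][~rcp[common]].dropna()
    tsi_test = welch_t(tsi_rcp, tsi_non) if min(len(tsi_rcp), len(tsi_non)) >= 2 else None

    hl_locus = aggregate_per_locus(bundle.half_lives, bundle.probe_map)
    hl_test = compare_rcp_half_lives(hl_locus, rcp)

    # splice classes
    seg_rows = []
    models_by_gene = {m.gene: m for m in bundle.gene_models}
    for pid, model in models_by_gene.items():
        p = prots[pid]
        classes = classify_exons(model)
        rep_exons = [(s, e, classes[(s, e)]) for s, e in model.models["m1"]]
        aars = detect_aars(p, min_len=min_len)
        for seg in exon_segment_rrpk(p, aars, rep_exons):
            seg_rows.append(
                {"protein_id": pid, "exon_class": seg.exon_class,
                 "start": seg.start, "end": seg.end, "rrpk": seg.rrpk}
            )
    segments = pd.DataFrame(seg_rows)
    alt = segments.loc[segments["exon_class"] == "alternative", "rrpk"]
    con = segments.loc[segments["exon_class"] == "constitutive", "rrpk"]
    splice_test = welch_t(alt, con) if len(alt) >= 2 and len(con) >= 2 else None

    # alternatively spliced gene fraction, RCP vs non-RCP
    alt_flag = pd.Series({g: m.alternatively_spliced for g, m in models_by_gene.items()})
    from .stats import fisher_exact_2x2

    tab = [
        [int((rcp & alt_flag).sum()), int((rcp & ~alt_flag).sum())],
        [int((~rcp & alt_flag).sum()), int((~rcp & ~alt_flag).sum())],
    ]
    alt_fisher = fisher_exact_2x2(tab)

    hotspot_test = hotspot_neighbor_enrichment(
        bundle.genes_bed, bundle.hotspots_bed, rcp
    )
    return {
        "tsi": tsi_df,
        "tsi_test": tsi_test,
        "half_life_test": hl_test,
        "segments": segments,
        "splice_test": splice_test,
        "alt_splice_fisher": alt_fisher,
        "hotspot_test": hotspot_test,
    }


# --- bundle serialization --------------------------------------------------


def write_bundle(bundle: SyntheticBundle, out: Path) -> None:
    """Write every input file of a bundle in standard formats."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    seed = bundle.config.seed
    chash = config_hash(bundle.config)
    hdr = dict(seed=seed, cfg_hash=chash)
    for sp, prots in bundle.proteomes.items():
        write_fasta(out / f"{sp}.faa", {p.id: p.sequence for p in prots})
        write_fasta(out / f"{sp}.fna", {p.id: p.cds for p in prots})
    (out / "msa").mkdir(exist_ok=True)
    manifest_rows = []
    for g in bundle.groups:
        write_fasta(
            out / "msa" / f"{g.group_id}.afa",
            {rec.id: row for (sp, rec), row in zip(g.members, g.msa)},
        )
        for sp, rec in g.members:
            manifest_rows.append({"group_id": g.group_id, "member_id": rec.id, "species": sp})
    write_fasta(
        out / "groups.fna",
        {rec.id: rec.cds for g in bundle.groups for _, rec in g.members},
    )
    write_tsv(out / "groups.tsv", pd.DataFrame(manifest_rows), **hdr)
    for track, anns in bundle.disorder_tracks.items():
        write_disorder_tsv(out / f"disorder_{track}.tsv", anns, **hdr)
    expr = bundle.expression.values.reset_index()
    write_tsv(out / "expression.tsv", expr, **hdr,
              note="raw scale; empty cells are below-background (absent) calls")
    write_tsv(
        out / "probe_map.tsv",
        bundle.probe_map.rename("locus").rename_axis("probe").reset_index(),
        **hdr,
    )
    write_tsv(
        out / "half_lives.tsv",
        bundle.half_lives.rename("half_life_h").rename_axis("probe").reset_index(),
        **hdr,
    )
    model_rows = []
    for m in bundle.gene_models:
        for mid, exons in m.models.items():
            for k, (s, e) in enumerate(exons):
                model_rows.append(
                    {"gene": m.gene, "model": mid, "exon_index": k,
                     "start": s, "end": e, "strand": m.strand}
                )
    write_tsv(out / "gene_models.tsv", pd.DataFrame(model_rows), **hdr,
              note="genomic intervals, 0-based half-open")
    write_bed(out / "genes.bed", bundle.genes_bed)
    write_bed(out / "hotspots.bed", bundle.hotspots_bed)
    write_tsv(out / "truth_tracts.tsv", bundle.tract_truth, **hdr,
              note="ground truth; 0-based half-open residue coordinates")
    write_tsv(out / "truth_groups.tsv", bundle.group_truth, **hdr)


# --- run-all ---------------------------------------------------------------


def _fmt_test(rep) -> str:
    if rep is None:
        return "n/a"
    return f"stat={rep.statistic:.4g} p={rep.p_value:.3g} n={rep.n}"


def run_all(config: PipelineConfig) -> dict:
    """Execute all stages on a freshly generated bundle and write the report.

    Returns the in-memory results of every stage.  Stage failures abort with
    a stage-named error; the outputs written so far are kept.
    """
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.generator.seed
    chash = config_hash(config.generator)
    hdr = dict(seed=seed, cfg_hash=chash)

    results: dict = {}
    stage = "simulate"
    try:
        bundle = generate_bundle(config.generator)
        results["bundle"] = bundle
        if config.write_bundle_files:
            write_bundle(bundle, out / "bundle")

        stage = "scan"
        scan = scan_stage(bundle, min_len=config.min_len)
        results["scan"] = scan
        write_tsv(out / "profiles.tsv", scan["profiles"], **hdr)
        write_tsv(out / "aars.tsv", scan["aars"], **hdr,
                  note="coordinates 1-based inclusive")
        write_tsv(out / "species_summary.tsv", scan["species_summary"], **hdr)
        write_tsv(out / "regional_rrpk.tsv", scan["regional"], **hdr)
        write_tsv(out / "composition.tsv", scan["composition"], **hdr)

        stage = "evolve"
        evo = evolve_stage(
            bundle, config.min_len, config.gap_frac_threshold,
            config.min_repeat_len, config.min_supporting, config.min_identity,
            config.flank_len,
        )
        results["evolve"] = evo
        write_tsv(out / "conservation.tsv", evo["conservation"], **hdr)
        write_tsv(out / "conserved_long_aars.tsv", evo["conserved_long"], **hdr)
        write_tsv(out / "flank_vs_whole.tsv", evo["flank_report"], **hdr)

        stage = "disorder"
        dis = disorder_stage(bundle, n_trials=config.n_trials, min_len=config.min_len)
        results["disorder"] = dis
        write_tsv(out / "disorder.tsv", dis["disorder"], **hdr)

        stage = "regulate"
        reg = regulate_stage(bundle, min_len=config.min_len)
        results["regulate"] = reg
        write_tsv(out / "tsi.tsv", reg["tsi"], **hdr)
        write_tsv(out / "exon_segments.tsv", reg["segments"], **hdr)

        stage = "report"
        lines = [
            f"aarscan v{__version__} report (seed={seed}, config={chash})",
            "",
            f"species: {len(bundle.proteomes)}; proteins/species: "
            f"{config.generator.n_proteins}; ortholog groups: {len(bundle.groups)}",
            "",
            "RRPK vs GC across species: " + _fmt_test(scan["rrpk_gc_pearson"]),
            f"Grubbs outlier (regression residuals): {scan['grubbs_outlier_species']} "
            + _fmt_test(scan["grubbs"]),
            f"AARs failing to align in all other orthologs: "
            f"{evo['frac_fails_to_align']:.1%}",
            f"conserved long AARs: {len(evo['conserved_long'])}",
            "flank vs whole dN/dS (pooled): "
            + (
                _fmt_row(evo["flank_report"])
                if len(evo["flank_report"])
                else "no data"
            ),
            "",
            "disorder (per species x track): see disorder.tsv",
            "TSI RCP vs non-RCP: " + _fmt_test(reg["tsi_test"]),
            "half-life RCP vs non-RCP: " + _fmt_test(reg["half_life_test"]),
            "alt vs const exon RRPK: " + _fmt_test(reg["splice_test"]),
            "alt-spliced fraction RCP vs non-RCP (Fisher): "
            + _fmt_test(reg["alt_splice_fisher"]),
            "hotspot neighbours RCP vs non-RCP (Fisher): "
            + _fmt_test(reg["hotspot_test"]),
        ]
        (out / "summary.txt").write_text("\n".join(lines) + "\n")
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e
    return results


def _fmt_row(report: pd.DataFrame) -> str:
    row = report[report["species"] == "__pooled__"]
    if not len(row):
        row = report.iloc[[-1]]
    r = row.iloc[0]
    return (
        f"median flank={r['median_flank_dnds']:.3f} "
        f"whole={r['median_whole_dnds']:.3f} U={r['mw_u']:.1f} p={r['mw_p']:.3g} "
        f"frac(flank dN/dS>1)={r['frac_flank_gt1']:.1%}"
    )
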