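"""Repeat-seed experiments over the synthetic generator.

These are the property-based surrogates for the study's genome-scale
observations: since the real proteomes, arrays and third-party predictors are
not inputs here, the pipeline's behaviour is validated by parameter-recovery
and calibration experiments — does the analysis detect an effect the
generator put in, and stay silent when it did not?

Each experiment runs the full relevant analysis path (generation ->
detection -> statistic) once per seed and returns per-seed results.  Problem
sizes are scaled for desk use and stated in the docstrings.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .disorder import random_segment_null
from .dnds import CODONS, _translate, ng86_dnds
from .ortho import flank_vs_whole_comparison
from .repeatscan import detect_aars, species_summary
from .stats import pearson
from .synth import GeneratorConfig, generate_ortholog_groups, generate_proteome, toy_disorder_annotator

__all__ = [
    "rrpk_gc_experiment",
    "flank_relaxation_experiment",
    "permutation_calibration_experiment",
    "neutral_dnds_experiment",
]


def rrpk_gc_experiment(
    n_seeds: int,
    beta: float | None = None,
    base_seed: int = 0,
    config: GeneratorConfig | None = None,
) -> pd.DataFrame:
    """Per-seed Pearson correlation between species mean RRPK and mean GC.

    Generates the per-species proteomes at the configured slippage-GC
    coupling (``beta`` overrides the default), runs the repeat scanner and
    species summary, and correlates mean RRPK against mean coding GC across
    species.  Returns a DataFrame with one (r, p) row per seed.
    """
    cfg = config or GeneratorConfig()
    if beta is not None:
        cfg = replace(cfg, slippage_gc_coupling=beta)
    rows = []
    for k in range(n_seeds):
        seed = (base_seed + 104729 * k) % (2**31)
        rng = np.random.default_rng(seed)
        proteins = []
        for sp, gc in zip(cfg.species_names, cfg.gc_targets):
            prots, _ = generate_proteome(sp, float(gc), cfg, rng)
            proteins += prots
        summary = species_summary(proteins, min_len=cfg.min_len)
        rep = pearson(summary["mean_gc"], summary["mean_rrpk"])
        rows.append({"seed": seed, "r": rep.statistic, "p": rep.p_value})
    return pd.DataFrame(rows)


def flank_relaxation_experiment(
    n_seeds: int,
    flank_relaxation: float,
    base_seed: int = 0,
    config: GeneratorConfig | None = None,
) -> pd.DataFrame:
    """Per-seed pooled Mann-Whitney p for flank vs whole-protein dN/dS.

    Generates ortholog groups at the given flank relaxation multiplier
    (default experiment size: 40 groups of 10 members) and runs the flank vs
    whole comparison for one species ("sp01", the lineage carrying every
    repeat tract).  Testing within a species keeps the Mann-Whitney samples
    independent — each group contributes exactly one protein — whereas
    pooling all species would enter up to ten correlated members per group.
    The two-sided p is reported with the direction (median flank > whole).
    """
    cfg = config or GeneratorConfig(n_groups=40, group_size=10)
    cfg = replace(cfg, flank_relaxation=flank_relaxation)
    rows = []
    for k in range(n_seeds):
        seed = (base_seed + 7919 * k) % (2**31)
        rng = np.random.default_rng(seed)
        groups, _ = generate_ortholog_groups(cfg, rng)
        report = flank_vs_whole_comparison(
            groups, flank_len=cfg.flank_len, min_len=cfg.min_len
        )
        pooled = report[report["species"] == "sp01"].iloc[0]
        rows.append(
            {
                "seed": seed,
                "n_proteins": int(pooled["n_proteins"]),
                "median_flank": pooled["median_flank_dnds"],
                "median_whole": pooled["median_whole_dnds"],
                "p": pooled["mw_p"],
                "flank_exceeds": pooled["median_flank_dnds"] > pooled["median_whole_dnds"],
            }
        )
    return pd.DataFrame(rows)


def permutation_calibration_experiment(
    n_replications: int,
    n_trials: int = 200,
    disorder_p: float = 0.8,
    enriched: bool = False,
    base_seed: int = 0,
    config: GeneratorConfig | None = None,
) -> pd.DataFrame:
    """Empirical p of the random-segment disorder test over replications.

    Each replication generates one single-species proteome (default 200
    proteins), annotates disorder and runs :func:`random_segment_null`.
    With ``enriched=False`` disorder is i.i.d. Bernoulli(``disorder_p``) per
    residue, independent of repeats — the null is true and the empirical p
    should be approximately uniform.  With ``enriched=True`` repeats are
    annotated disordered with probability 1 and the background with
    ``disorder_p``; the test should then pin p at its minimum 1/(n_trials+1).
    """
    cfg = config or GeneratorConfig(n_proteins=200)
    rows = []
    for k in range(n_replications):
        seed = (base_seed + 15485863 * k) % (2**31)
        rng = np.random.default_rng(seed)
        prots, _ = generate_proteome("spx", 0.5, cfg, rng)
        p_in = 1.0 if enriched else disorder_p
        anns = {}
        for p in prots:
            anns[p.id] = toy_disorder_annotator(
                p, int(rng.integers(2**31)), cfg,
                in_repeat_p=p_in, background_p=disorder_p,
            )
        aars, rcps = [], []
        for p in prots:
            found = detect_aars(p, min_len=cfg.min_len)
            if found:
                aars += found
                rcps.append(p)
        res = random_segment_null(
            aars, rcps, anns, n_trials=n_trials, seed=int(rng.integers(2**31))
        )
        rows.append(
            {
                "seed": seed,
                "n_aars": len(aars),
                "observed": res.observed_fraction,
                "empirical_p": res.empirical_p,
            }
        )
    return pd.DataFrame(rows)


def _random_sense_codons(rng: np.random.Generator, n_codons: int) -> list[str]:
    sense = [c for c in CODONS if _translate(c) != "*"]
    return [sense[i] for i in rng.integers(len(sense), size=n_codons)]


def neutral_dnds_experiment(
    n_pairs: int = 200,
    n_codons: int = 300,
    divergence: float = 0.10,
    base_seed: int = 0,
) -> pd.DataFrame:
    """NG86 dN/dS of codon pairs diverged under a neutral mutation model.

    Sequence B is sequence A with each nucleotide site substituted with
    probability ``divergence`` to a uniformly chosen different base; changes
    creating a stop codon are redrawn (the only constraint).  Since the
    mutation process ignores the amino-acid consequence, dN/dS should centre
    on 1.
    """
    rows = []
    for k in range(n_pairs):
        rng = np.random.default_rng((base_seed + 6700417 * k) % (2**31))
        codons_a = _random_sense_codons(rng, n_codons)
        codons_b = []
        for c in codons_a:
            cur = c
            for pos in range(3):
                if rng.random() < divergence:
                    alts = [n for n in "TCAG" if n != cur[pos]]
                    rng.shuffle(alts)
                    for alt in alts:
                        cand = cur[:pos] + alt + cur[pos + 1 :]
                        if _translate(cand) != "*":
                            cur = cand
                            break
            codons_b.append(cur)
        res = ng86_dnds("".join(codons_a), "".join(codons_b))
        rows.append(
            {
                "seed": k,
                "dn": res.dn,
                "ds": res.ds,
                "ratio": res.ratio if res.ratio is not None else np.nan,
                "flags": ";".join(res.flags),
            }
        )
    return pd.DataFrame(rows)
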