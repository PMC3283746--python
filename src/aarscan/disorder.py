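"""Structural-disorder classification of repeats and the permutation null.

A repeat is *fully disordered* when every one of its residues is called
disordered by a per-residue binary annotation (e.g. thresholded predictor
output).  Whether repeats are fully disordered more often than chance is
tested against a random-segment null: in each trial, every repeat is matched
by a random segment of identical length drawn from the repeat-containing
proteins, and the trial's fraction of fully disordered segments is compared
with the observed fraction.  The empirical p uses the add-one estimator
(b+1)/(n+1), so 0 exceedances in 1000 trials gives p = 1/1001 (< 0.001).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .repeatscan import AAR, ProteinRecord
from .stats import empirical_p

__all__ = [
    "DisorderAnnotation",
    "DisorderTestResult",
    "is_fully_disordered",
    "fully_disordered_fraction",
    "random_segment_null",
]


@dataclass
class DisorderAnnotation:
    """Per-residue binary disorder calls ('1' disordered, '0' ordered)."""

    protein_id: str
    calls: str

    def __post_init__(self) -> None:
        if set(self.calls) - {"0", "1"}:
            raise ValueError(f"{self.protein_id}: calls must be over {{0,1}}")

    def as_array(self) -> np.ndarray:
        return np.frombuffer(self.calls.encode(), dtype=np.uint8) - ord("0")

    def __len__(self) -> int:
        return len(self.calls)


@dataclass
class DisorderTestResult:
    observed_fraction: float
    null_fractions: np.ndarray
    empirical_p: float
    n_trials: int
    seed: int


def is_fully_disordered(aar: AAR, ann: DisorderAnnotation) -> bool:
    """True iff every residue of the repeat is called disordered."""
    if aar.end > len(ann):
        raise ValueError(
            f"AAR [{aar.start},{aar.end}) outside annotation of length {len(ann)}"
        )
    return "0" not in ann.calls[aar.start : aar.end]


def fully_disordered_fraction(
    aars: list[AAR], anns: dict[str, DisorderAnnotation]
) -> float:
    """Fraction of repeats that are fully disordered."""
    if not aars:
        raise ValueError("no AARs supplied")
    hits = 0
    for a in aars:
        if a.protein_id not in anns:
            raise ValueError(f"no annotation for protein {a.protein_id}")
        hits += is_fully_disordered(a, anns[a.protein_id])
    return hits / len(aars)


def random_segment_null(
    aars: list[AAR],
    rcp_proteins: list[ProteinRecord],
    anns: dict[str, DisorderAnnotation],
    n_trials: int = 1000,
    seed: int = 0,
    same_protein: bool = False,
) -> DisorderTestResult:
    """Random-segment permutation test for fully-disordered enrichment.

    Per trial, each repeat is matched by one segment of identical length at a
    uniform position inside a repeat-containing protein; the trial statistic
    is the fraction of segments that are fully disordered.  By default the
    host protein is chosen uniformly at random among the RCPs long enough to
    hold the segment (``same_protein=True`` instead samples from the repeat's
    own protein).  Reproducible given ``seed``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not aars:
        raise ValueError("no AARs supplied")
    observed = fully_disordered_fraction(aars, anns)

    # prefix sums of disorder calls per protein, concatenated
    lengths = np.array([len(p) for p in rcp_proteins])
    offsets = np.concatenate([[0], np.cumsum(lengths + 1)])  # +1 for the 0-prefix slot
    prefix = np.zeros(int(offsets[-1]), dtype=np.int64)
    index_of = {}
    for k, p in enumerate(rcp_proteins):
        if p.id not in anns:
            raise ValueError(f"no annotation for RCP {p.id}")
        calls = anns[p.id].as_array()
        if len(calls) != len(p):
            raise ValueError(f"annotation length mismatch for {p.id}")
        prefix[offsets[k] + 1 : offsets[k] + 1 + len(p)] = np.cumsum(calls)
        index_of[p.id] = k

    rng = np.random.default_rng(seed)
    seg_lens = np.array([a.length for a in aars])
    if seg_lens.max() > lengths.max():
        raise ValueError("an AAR is longer than every RCP protein")

    m = len(aars)
    null = np.empty(n_trials)
    if same_protein:
        host = np.array([index_of[a.protein_id] for a in aars])
        host_all = np.broadcast_to(host, (n_trials, m))
    else:
        # uniform among proteins long enough for each segment length
        order = np.argsort(lengths, kind="stable")
        sorted_lens = lengths[order]
        # first index (in sorted order) of a protein with length >= L
        first_ok = np.searchsorted(sorted_lens, seg_lens, side="left")
        n_ok = len(rcp_proteins) - first_ok
        if (n_ok <= 0).any():
            raise ValueError("an AAR is longer than every RCP protein")
        pick = first_ok + (rng.random((n_trials, m)) * n_ok).astype(np.int64)
        host_all = order[pick]
    valid_starts = lengths[host_all] - seg_lens + 1
    starts = (rng.random((n_trials, m)) * valid_starts).astype(np.int64)
    base = offsets[host_all] + starts
    fully = prefix[base + seg_lens] - prefix[base] == seg_lens
    null = fully.mean(axis=1)

    return DisorderTestResult(
        observed_fraction=observed,
        null_fractions=null,
        empirical_p=empirical_p(observed, null, tail="ge"),
        n_trials=n_trials,
        seed=seed,
    )
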