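import numpy as np
import pytest

from aarscan.ortho import OrthologGroup
from aarscan.repeatscan import ProteinRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def brute_force_runs(seq: str, min_len: int = 4, alphabet=frozenset("ACDEFGHIKLMNPQRSTVWY")):
    """Independent oracle: test every substring for uniformity and maximality."""
    out = []
    n = len(seq)
    for i in range(n):
        for j in range(i + min_len, n + 1):
            sub = seq[i:j]
            if len(set(sub)) != 1 or sub[0] not in alphabet:
                continue
            if i > 0 and seq[i - 1] == sub[0]:
                continue
            if j < n and seq[j] == sub[0]:
                continue
            out.append((sub[0], i, j))
    return out


def make_group(rows: list[str], codon_rows: list[str] | None = None,
               group_id: str = "g", species=None) -> OrthologGroup:
    """Build an OrthologGroup from aligned protein rows; codon rows are
    synthesised from a fixed per-amino-acid codon if not given."""
    from aarscan.dnds import CODONS, _translate

    aa2codon = {}
    for c in CODONS:
        aa = _translate(c)
        if aa != "*" and aa not in aa2codon:
            aa2codon[aa] = c
    members = []
    codon_msa = []
    species = species or [f"s{i}" for i in range(len(rows))]
    for k, row in enumerate(rows):
        seq = row.replace("-", "")
        if codon_rows is None:
            crow = "".join("---" if ch == "-" else aa2codon[ch] for ch in row)
        else:
            crow = codon_rows[k]
        cds = crow.replace("-", "")
        members.append((species[k], ProteinRecord(f"{group_id}_m{k}", seq, cds=cds,
                                                  species=species[k])))
        codon_msa.append(crow)
    return OrthologGroup(group_id, members, rows, codon_msa)
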