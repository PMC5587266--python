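"""Haplotype collapsing and uncorrected p-distance divergence tables.

Works on pre-aligned, equal-length nucleotide sequences (e.g. complete
cytochrome *b* haplotypes).  The p-distance between two sequences is the
proportion of compared sites that differ, with pairwise deletion: sites
where either sequence carries a gap or an IUPAC ambiguity code (anything
outside A/C/G/T) are excluded from both numerator and denominator.
Group divergence tables report, per group pair, the unweighted mean and
maximum pairwise distance over unique haplotypes; the diagonal holds the
mean within-group distance.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "HaplotypeSet",
    "GroupDivergenceTable",
    "read_fasta",
    "collapse_haplotypes",
    "p_distance",
    "group_divergence",
]

_IUPAC = set("ACGTRYSWKMBDHVN-")


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    group_label: str
    bases: str

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.bases.upper()) - _IUPAC
        if bad:
            raise ValueError(f"sequence {self.id!r} has non-IUPAC characters {sorted(bad)}")
        object.__setattr__(self, "bases", self.bases.upper())


@dataclass
class HaplotypeSet:
    haplotypes: list[str]  # unique sequences, order of first occurrence
    counts: list[int]
    member_map: dict[str, int]  # record id -> haplotype index

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)


@dataclass
class GroupDivergenceTable:
    groups: list[str]
    within: dict[str, float]
    between: dict[frozenset, float]
    max_between: dict[frozenset, float]

    def to_frame(self) -> pd.DataFrame:
        """Square layout: within on the diagonal, mean between off-diagonal."""
        g = self.groups
        m = pd.DataFrame(np.nan, index=g, columns=g)
        for gi in g:
            m.loc[gi, gi] = self.within[gi]
        for pair, v in self.between.items():
            a, b = sorted(pair)
            m.loc[a, b] = v
            m.loc[b, a] = v
        return m


def read_fasta(path: str | Path, groups: dict[str, str] | None = None) -> list[SequenceRecord]:
    """Read FASTA into records; ``groups`` maps record id -> group label.

    Order-preserving; bases are upper-cased.  Duplicate ids and empty
    files are rejected.
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        label = groups.get(rec.id, "") if groups else ""
        records.append(SequenceRecord(id=rec.id, group_label=label, bases=str(rec.seq)))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def collapse_haplotypes(seqs: list[SequenceRecord]) -> HaplotypeSet:
    """Collapse to unique sequences (exact string identity).

    The representative of each haplotype is its first occurrence.
    Sequences must be aligned (equal length).
    """
    if not seqs:
        raise ValueError("no sequences to collapse")
    lengths = {len(s.bases) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(
            f"sequences have unequal lengths {sorted(lengths)}; align them first "
            "(e.g. with mafft) before collapsing"
        )
    haplotypes: list[str] = []
    counts: list[int] = []
    index: dict[str, int] = {}
    member_map: dict[str, int] = {}
    for s in seqs:
        if s.bases not in index:
            index[s.bases] = len(haplotypes)
            haplotypes.append(s.bases)
            counts.append(0)
        h = index[s.bases]
        counts[h] += 1
        member_map[s.id] = h
    return HaplotypeSet(haplotypes=haplotypes, counts=counts, member_map=member_map)


def _encode(bases: str) -> np.ndarray:
    """A/C/G/T -> 0..3, anything else (gap/ambiguity) -> -1 (missing)."""
    arr = np.frombuffer(bases.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.size, -1, dtype=np.int8)
    for code, b in enumerate(b"ACGT"):
        out[arr == b] = code
    return out


def p_distance(a: str, b: str) -> float:
    """Uncorrected p-distance with pairwise deletion.

    Proportion of sites with unambiguous, non-gap, differing bases among
    sites where both sequences are unambiguous and non-gap.  Symmetric,
    zero on identity; rejects pairs with no comparable sites.
    """
    if len(a) != len(b):
        raise ValueError("p-distance requires equal-length (aligned) sequences")
    ea, eb = _encode(a.upper()), _encode(b.upper())
    ok = (ea >= 0) & (eb >= 0)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no comparable sites (all gaps/ambiguities)")
    return float(np.sum(ea[ok] != eb[ok]) / n)


def _pairwise_matrix(haps: list[str]) -> np.ndarray:
    enc = np.stack([_encode(h) for h in haps])
    ok = enc >= 0
    n = len(haps)
    d = np.zeros((n, n))
    for i in range(n):
        both = ok[i] & ok
        diff = (enc[i] != enc) & both
        comp = both.sum(axis=1)
        if np.any(comp == 0):
            raise ValueError("a haplotype pair has no comparable sites")
        d[i] = diff.sum(axis=1) / comp
    return d


def group_divergence(seqs: list[SequenceRecord], collapse: bool = True) -> GroupDivergenceTable:
    """Within/between-group mean and max p-distances.

    ``collapse=True`` (default) computes over unique haplotypes per group,
    unweighted by haplotype frequency.  Groups of size 1 get within = 0
    (flagged with a warning).
    """
    if not seqs:
        raise ValueError("no sequences")
    if any(not s.group_label for s in seqs):
        raise ValueError("every sequence needs a group label")
    groups = list(dict.fromkeys(s.group_label for s in seqs))
    by_group: dict[str, list[str]] = {}
    for g in groups:
        bases = [s.bases for s in seqs if s.group_label == g]
        if collapse:
            bases = list(dict.fromkeys(bases))
        by_group[g] = bases

    all_haps = [h for g in groups for h in by_group[g]]
    labels = np.array([g for g in groups for _ in by_group[g]])
    d = _pairwise_matrix(all_haps)

    within: dict[str, float] = {}
    for g in groups:
        idx = np.flatnonzero(labels == g)
        if idx.size < 2:
            warnings.warn(f"group {g!r} has a single haplotype; within-distance set to 0")
            within[g] = 0.0
        else:
            sub = d[np.ix_(idx, idx)]
            within[g] = float(sub[np.triu_indices(idx.size, k=1)].mean())

    between: dict[frozenset, float] = {}
    max_between: dict[frozenset, float] = {}
    for g1, g2 in itertools.combinations(groups, 2):
        i1 = np.flatnonzero(labels == g1)
        i2 = np.flatnonzero(labels == g2)
        block = d[np.ix_(i1, i2)]
        key = frozenset({g1, g2})
        between[key] = float(block.mean())
        max_between[key] = float(block.max())

    return GroupDivergenceTable(groups=groups, within=within,
                                between=between, max_between=max_between)
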