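"""Core domain types for TCRα repertoire analysis.

A *clonotype* is the identity key of a T-cell clone. In bulk single-chain
data it is the triple (TRAV gene, TRAJ gene, CDR3 amino-acid sequence);
in paired single-cell data each chain carries its own (V, CDR3, J) triple.
Clonotype abundance is always measured in unique cDNA molecules (UMIs),
never in raw reads.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd


class RepertoireFormatError(ValueError):
    """Raised when an input file violates the expected tabular contract."""


class UndefinedDiversityError(ValueError):
    """Raised when diversity is requested for an empty abundance vector."""


_ALLELE_RE = re.compile(r"\*\d+$")


def normalize_gene(name: str) -> str:
    """Normalize a V/J gene name to IMGT-style uppercase without allele suffix.

    ``"Trav14-1*01"`` becomes ``"TRAV14-1"``. Comma-joined multi-gene strings
    (paralog-ambiguous calls) are normalized per component and re-joined in
    sorted order so the key is deterministic.
    """
    parts = [p.strip() for p in name.split(",") if p.strip()]
    norm = sorted(_ALLELE_RE.sub("", p).upper() for p in parts)
    return ",".join(norm)


class Clonotype(NamedTuple):
    """Bulk TCRα clonotype key.

    Equality is exact string equality of all three fields; tuple ordering
    gives the lexicographic (v_gene, j_gene, cdr3_aa) order used for
    deterministic tie-breaks.
    """

    v_gene: str
    j_gene: str
    cdr3_aa: str


@dataclass(frozen=True)
class JunctionAnnotation:
    """Per-molecule V–J junction editing annotation.

    Fields count nucleotides removed from the germline V / J segments and
    P (palindromic) / N (non-templated) nucleotides added at the joint.
    """

    v_deletions: int
    j_deletions: int
    p_additions: int
    n_additions: int
    paralog_ambiguous: bool = False

    def __post_init__(self) -> None:
        for name in ("v_deletions", "j_deletions", "p_additions", "n_additions"):
            v = getattr(self, name)
            if v is None:
                raise ValueError(f"junction field {name} is missing")
            if int(v) < 0:
                raise ValueError(f"junction field {name} must be >= 0, got {v}")


@dataclass
class AnnotatedRead:
    """One annotated sequencing read of a rearranged TCRα chain.

    ``v_calls`` holds one or more candidate V genes; more than one means the
    read is paralog-ambiguous (it aligned equally well to duplicated loci).
    ``(sample_id, umi)`` identifies the originating cDNA molecule; repeats
    collapse to a single molecule at aggregation time.
    """

    sample_id: str
    umi: str
    v_calls: tuple[str, ...]
    j_call: str
    cdr3_aa: str
    productive: bool
    junction: Optional[JunctionAnnotation] = None

    def __post_init__(self) -> None:
        if not self.v_calls:
            raise ValueError("v_calls must be non-empty")
        if not self.umi:
            raise ValueError("umi must be non-empty")
        if self.productive and not self.cdr3_aa:
            raise ValueError("productive read with empty CDR3")

    @property
    def paralog_ambiguous(self) -> bool:
        return len(self.v_calls) > 1

    def clonotype(self) -> Clonotype:
        """Clonotype key; paralog-ambiguous reads are keyed by the full
        sorted v_calls string so they stay distinct from unambiguous calls."""
        return Clonotype(
            normalize_gene(",".join(self.v_calls)),
            normalize_gene(self.j_call),
            self.cdr3_aa,
        )


@dataclass(frozen=True)
class PairedClonotype:
    """Paired-chain (αβ) clonotype at amino-acid V/CDR3/J resolution.

    Analyses retain only cells where both chains are in frame.
    """

    alpha: Clonotype
    beta: Clonotype
    in_frame_alpha: bool = True
    in_frame_beta: bool = True

    @property
    def in_frame(self) -> bool:
        return self.in_frame_alpha and self.in_frame_beta


@dataclass
class SampleMeta:
    """Sample annotation: genotype group, sorted-subset label, replicate."""

    sample_id: str
    group: str = ""
    subset: str = ""
    replicate: int = 0


class AbundanceTable:
    """Clonotype × sample matrix of unique-molecule (UMI) counts.

    ``counts`` is an integer DataFrame indexed by the MultiIndex
    (v_gene, j_gene, cdr3_aa) with one column per sample. Rows that are zero
    in every sample are dropped at construction. Column sums equal the number
    of retained unique molecules per sample.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        samples: Sequence[SampleMeta],
        excluded_paralog_fraction: Optional[dict[str, float]] = None,
        umi_conflict_rate: float = 0.0,
    ) -> None:
        sample_ids = [s.sample_id for s in samples]
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample_id in sample metadata")
        if list(counts.columns) != sample_ids:
            counts = counts.reindex(columns=sample_ids, fill_value=0)
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        counts = counts.astype(np.int64)
        counts = counts.loc[counts.sum(axis=1) > 0]
        counts.index = counts.index.set_names(["v_gene", "j_gene", "cdr3_aa"])
        self.counts = counts.sort_index()
        self.samples = list(samples)
        self.excluded_paralog_fraction = dict(excluded_paralog_fraction or {})
        self.umi_conflict_rate = umi_conflict_rate

    # -- accessors -----------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def clonotypes(self) -> list[Clonotype]:
        return [Clonotype(*key) for key in self.counts.index]

    def meta(self, sample_id: str) -> SampleMeta:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def vector(self, sample_id: str) -> np.ndarray:
        """Abundance vector of one sample over this table's clonotypes."""
        return self.counts[sample_id].to_numpy()

    def presence(self, min_umi: int = 1) -> pd.DataFrame:
        """Boolean presence matrix (count >= min_umi)."""
        if min_umi < 1:
            raise ValueError("min_umi must be >= 1")
        return self.counts >= min_umi

    def group_ids(self, group: str) -> list[str]:
        return [s.sample_id for s in self.samples if s.group == group]

    def subset_ids(self, subset: str) -> list[str]:
        return [s.sample_id for s in self.samples if s.subset == subset]

    def restrict(self, clonotypes: Sequence[Clonotype]) -> "AbundanceTable":
        """Sub-table over the given clonotype keys (intersection)."""
        keys = [tuple(c) for c in clonotypes]
        idx = self.counts.index.intersection(pd.MultiIndex.from_tuples(keys))
        return AbundanceTable(self.counts.loc[idx], self.samples)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AbundanceTable):
            return NotImplemented
        return (
            self.counts.equals(other.counts)
            and [(s.sample_id, s.group, s.subset, s.replicate) for s in self.samples]
            == [(s.sample_id, s.group, s.subset, s.replicate) for s in other.samples]
        )

    def __repr__(self) -> str:
        return (
            f"AbundanceTable({self.counts.shape[0]} clonotypes x "
            f"{self.counts.shape[1]} samples)"
        )
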