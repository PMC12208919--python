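"""Set-theoretic clonotype classification across samples and conditions.

Classifies clonotypes by their presence pattern across replicate samples:
recurrence (detected in at least ``min_samples`` of all samples), genotype
dependence (recurrent clonotypes found exclusively in one genotype's
samples are "dependent" on that genotype's condition; the mirror class are
"newcomers"; the rest are shared), and natural CD5 subrepertoires (present
in most samples of one sorted CD5 extreme, absent from all of the other).
Presence means at least ``min_umi`` unique molecules (default 1); counts
beyond presence are irrelevant to the class assignments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .diversity import hill_diversity
from .model import AbundanceTable, Clonotype, UndefinedDiversityError
from .io import PairedRepertoire


def recurrent_clonotypes(
    table: AbundanceTable, min_samples: int = 3, min_umi: int = 1
) -> set[Clonotype]:
    """Clonotypes present (count >= min_umi) in at least min_samples samples."""
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    if len(table.sample_ids) < min_samples:
        raise ValueError(
            f"table has {len(table.sample_ids)} samples, fewer than "
            f"min_samples={min_samples}"
        )
    pres = table.presence(min_umi=min_umi)
    mask = pres.sum(axis=1) >= min_samples
    return {Clonotype(*key) for key in pres.index[mask]}


@dataclass
class DependenceLabels:
    """Partition of the recurrent set into dependent / shared / newcomer.

    dependent: present in >=1 group-A sample and absent from all group-B
    samples; newcomer: the mirror; shared: present in >=1 sample of each.
    The three classes partition the recurrent set, and
    |present-in-A| + |present-in-B| - |shared| = |recurrent|.
    """

    recurrent: set[Clonotype]
    dependent: set[Clonotype]
    shared: set[Clonotype]
    newcomer: set[Clonotype]
    group_a: str = "A"
    group_b: str = "B"

    def label_of(self, clonotype: Clonotype) -> Optional[str]:
        if clonotype in self.dependent:
            return "dependent"
        if clonotype in self.newcomer:
            return "newcomer"
        if clonotype in self.shared:
            return "shared"
        return None

    @property
    def present_in_a(self) -> set[Clonotype]:
        return self.dependent | self.shared

    @property
    def present_in_b(self) -> set[Clonotype]:
        return self.newcomer | self.shared


def classify_dependence(
    table: AbundanceTable,
    recurrent: Iterable[Clonotype],
    group_a_ids: Sequence[str],
    group_b_ids: Sequence[str],
    min_umi: int = 1,
) -> DependenceLabels:
    """Classify recurrent clonotypes by genotype-exclusive presence."""
    group_a_ids = list(group_a_ids)
    group_b_ids = list(group_b_ids)
    if not group_a_ids or not group_b_ids:
        raise ValueError("both groups must be nonempty")
    all_ids = set(table.sample_ids)
    both = set(group_a_ids) | set(group_b_ids)
    if set(group_a_ids) & set(group_b_ids):
        raise ValueError("groups must be disjoint")
    if both != all_ids:
        raise ValueError("groups must partition the table's samples")
    recurrent = set(recurrent)
    table_keys = set(table.counts.index)
    for c in recurrent:
        if tuple(c) not in table_keys:
            raise ValueError(f"recurrent clonotype {c} not in table")

    pres = table.presence(min_umi=min_umi)
    in_a = pres[group_a_ids].any(axis=1)
    in_b = pres[group_b_ids].any(axis=1)
    dependent, shared, newcomer = set(), set(), set()
    for c in recurrent:
        a, b = bool(in_a.loc[tuple(c)]), bool(in_b.loc[tuple(c)])
        if a and b:
            shared.add(c)
        elif a:
            dependent.add(c)
        elif b:
            newcomer.add(c)
        # a recurrent clonotype is present somewhere, so a or b holds
    return DependenceLabels(
        recurrent=recurrent, dependent=dependent, shared=shared, newcomer=newcomer
    )


@dataclass
class CD5Labels:
    """Natural CD5lo / CD5hi clonotype sets; everything else unassigned."""

    natural_lo: set[Clonotype]
    natural_hi: set[Clonotype]
    unassigned: set[Clonotype]

    def label_of(self, clonotype: Clonotype) -> str:
        if clonotype in self.natural_lo:
            return "natural_lo"
        if clonotype in self.natural_hi:
            return "natural_hi"
        return "unassigned"


def classify_cd5(
    table: AbundanceTable,
    lo_ids: Sequence[str],
    hi_ids: Sequence[str],
    min_present: int = 3,
    min_umi: int = 1,
) -> CD5Labels:
    """Classify clonotypes into natural CD5lo/CD5hi subrepertoires.

    natural_lo: present in >= min_present of the CD5lo samples and absent
    from every CD5hi sample; natural_hi is the reciprocal pattern.
    """
    lo_ids, hi_ids = list(lo_ids), list(hi_ids)
    if set(lo_ids) & set(hi_ids):
        raise ValueError("CD5lo and CD5hi sample sets overlap")
    if len(lo_ids) < min_present or len(hi_ids) < min_present:
        raise ValueError(
            f"each subset needs >= min_present={min_present} samples"
        )
    pres = table.presence(min_umi=min_umi)
    n_lo = pres[lo_ids].sum(axis=1)
    n_hi = pres[hi_ids].sum(axis=1)
    lo_mask = (n_lo >= min_present) & (n_hi == 0)
    hi_mask = (n_hi >= min_present) & (n_lo == 0)
    natural_lo = {Clonotype(*k) for k in pres.index[lo_mask]}
    natural_hi = {Clonotype(*k) for k in pres.index[hi_mask]}
    unassigned = {
        Clonotype(*k) for k in pres.index[~(lo_mask | hi_mask)]
    }
    return CD5Labels(natural_lo=natural_lo, natural_hi=natural_hi, unassigned=unassigned)


@dataclass
class CrossAssignment:
    """Result of assigning a query clone set to dependence classes.

    Fractions are reported with two denominators: matched query clones only
    and all query clones (the unmatched remainder counted separately).
    """

    counts: dict[str, int]
    n_matched: int
    n_unmatched: int
    fractions_matched: dict[str, float]
    fractions_all: dict[str, float]


def cross_assign(query: Iterable[Clonotype], labels: DependenceLabels) -> CrossAssignment:
    """Assign each query clonotype its dependence class by exact key match."""
    query = set(query)
    if not query:
        raise ValueError("query clonotype set is empty")
    counts = {"dependent": 0, "shared": 0, "newcomer": 0}
    n_matched = 0
    for c in query:
        lab = labels.label_of(c)
        if lab is None:
            continue
        counts[lab] += 1
        n_matched += 1
    n_unmatched = len(query) - n_matched
    if n_matched == 0:
        warnings.warn("no query clonotypes matched the labelled inventory")
    fractions_matched = {
        k: (v / n_matched if n_matched else 0.0) for k, v in counts.items()
    }
    fractions_all = {k: v / len(query) for k, v in counts.items()}
    return CrossAssignment(
        counts=counts,
        n_matched=n_matched,
        n_unmatched=n_unmatched,
        fractions_matched=fractions_matched,
        fractions_all=fractions_all,
    )


def top_expanded(
    table: AbundanceTable, k: int = 10, pooled: bool = False
) -> pd.DataFrame:
    """Top-k clonotypes by mean (or pooled) relative frequency.

    Returns a DataFrame indexed by clonotype key with per-sample relative
    frequencies and the ranking frequency, sorted descending; ties broken
    by the lexicographic clonotype key.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    freqs = table.counts / table.counts.sum(axis=0)
    if pooled:
        rank_freq = table.counts.sum(axis=1) / table.counts.to_numpy().sum()
    else:
        rank_freq = freqs.mean(axis=1)
    out = freqs.copy()
    out["rank_freq"] = rank_freq
    out = out.sort_index().sort_values("rank_freq", ascending=False, kind="stable")
    if k > len(out):
        warnings.warn(
            f"k={k} exceeds the number of clonotypes ({len(out)}); returning all"
        )
        k = len(out)
    return out.iloc[:k]


def public_paired(
    rep: PairedRepertoire, genotype_a: str, genotype_b: str
) -> pd.DataFrame:
    """Paired clonotypes shared between two genotypes ("public" clones).

    Intersects the union-over-mice clonotype sets of each genotype and
    reports, per shared clonotype, the number of mice per genotype.
    """
    union_a = rep.union(genotype_a)
    union_b = rep.union(genotype_b)
    if not union_a or not union_b:
        warnings.warn("one of the genotypes has no paired clonotypes")
    shared = union_a & union_b
    rows = []
    for ct in shared:
        rows.append(
            (
                ct.alpha.v_gene,
                ct.alpha.cdr3_aa,
                ct.alpha.j_gene,
                ct.beta.v_gene,
                ct.beta.cdr3_aa,
                ct.beta.j_gene,
                rep.mouse_multiplicity(ct, genotype_a),
                rep.mouse_multiplicity(ct, genotype_b),
            )
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "alpha_v", "alpha_cdr3", "alpha_j",
            "beta_v", "beta_cdr3", "beta_j",
            f"n_mice_{genotype_a}", f"n_mice_{genotype_b}",
        ],
    )
    return df.sort_values(list(df.columns[:6])).reset_index(drop=True)


def subrepertoire_diversity(
    table: AbundanceTable, subset: Iterable[Clonotype], q: float = 1.0
) -> dict[str, Optional[float]]:
    """Per-sample Hill diversity of the table restricted to a clone subset.

    Samples whose restricted counts are all zero are reported as None
    (diversity undefined on an empty subrepertoire).
    """
    subset = list(subset)
    if not subset:
        raise ValueError("clonotype subset must be nonempty")
    restricted = table.restrict(subset)
    out: dict[str, Optional[float]] = {}
    for sid in table.sample_ids:
        vec = restricted.vector(sid) if len(restricted.counts) else np.array([])
        try:
            out[sid] = hill_diversity(vec, q=q)
        except UndefinedDiversityError:
            out[sid] = None
    return out
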