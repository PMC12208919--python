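"""Pairwise repertoire similarity via the Morisita–Horn index.

The Morisita–Horn index between two abundance vectors aligned on the union
clonotype set is C = 2 Σ p_i q_i / (Σ p_i² + Σ q_i²) with p, q the relative
abundances. It ranges from 0 (disjoint supports) to 1 (identical proportion
vectors) and is invariant to rescaling either sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import AbundanceTable


def morisita_horn(x, y) -> float:
    """Morisita–Horn similarity of two aligned abundance vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must be aligned on the same clonotype set")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be nonnegative")
    if x.sum() == 0 or y.sum() == 0:
        raise ValueError("Morisita–Horn undefined for a zero-total sample")
    p = x / x.sum()
    q = y / y.sum()
    denom = float(np.sum(p**2) + np.sum(q**2))
    return float(2.0 * np.sum(p * q) / denom)


@dataclass
class OverlapMatrix:
    """Symmetric sample × sample similarity matrix with pair grouping.

    ``pairs`` is a long-format table (sample_a, sample_b, category, value)
    over unordered pairs; category is "within_<group>" or "between".
    """

    matrix: pd.DataFrame
    pairs: pd.DataFrame = field(repr=False)

    def values_by_category(self) -> dict[str, list[float]]:
        out: dict[str, list[float]] = {}
        for cat, sub in self.pairs.groupby("category"):
            out[str(cat)] = [float(v) for v in sub["value"]]
        return out


def pairwise_overlap(table: AbundanceTable, group_key: str = "group") -> OverlapMatrix:
    """All pairwise Morisita–Horn similarities with within/between grouping.

    For a 3+3 two-group design this yields 3 within-A, 3 within-B and 9
    between pairs; for 4+4, 6 + 6 + 16.
    """
    ids = table.sample_ids
    if len(ids) < 2:
        warnings.warn("fewer than 2 samples: no pairs to compare")
    groups = {
        s.sample_id: getattr(s, group_key) if group_key != "subset" else s.subset
        for s in table.samples
    }
    if group_key == "subset":
        groups = {s.sample_id: s.subset for s in table.samples}
    elif group_key == "group":
        groups = {s.sample_id: s.group for s in table.samples}
    else:
        raise ValueError(f"unknown grouping key {group_key!r}")

    n = len(ids)
    mat = np.eye(n)
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            value = morisita_horn(table.vector(ids[i]), table.vector(ids[j]))
            mat[i, j] = mat[j, i] = value
            ga, gb = groups[ids[i]], groups[ids[j]]
            category = f"within_{ga}" if ga == gb else "between"
            rows.append((ids[i], ids[j], category, value))
    matrix = pd.DataFrame(mat, index=ids, columns=ids)
    pairs = pd.DataFrame(rows, columns=["sample_a", "sample_b", "category", "value"])
    return OverlapMatrix(matrix=matrix, pairs=pairs)
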