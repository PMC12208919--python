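"""Headline summaries reproducing the published repertoire comparisons.

These helpers glue the classification primitives into the three deposited-
data analyses: the two-genotype dependence inventory (recurrent / shared /
dependent / newcomer counts), the CD5 subrepertoire inventory with its
cross-assigned loss fractions, and the public paired-clonotype count. They
operate on any abundance tables with the right group/subset labels; to
reproduce the published numbers, point :func:`load_benchmark_tables` at a
directory containing the deposited source-data tables converted to this
package's abundance-TSV format:

    data/source_data/fig3_abundance.tsv   (3 control + 3 mutant samples)
    data/source_data/fig5_abundance.tsv   (4 CD5lo + 4 CD5hi samples)
    data/source_data/fig6_paired.tsv      (mouse_id, genotype, α/β fields)
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import pandas as pd

from .classification import (
    CD5Labels,
    DependenceLabels,
    classify_cd5,
    classify_dependence,
    cross_assign,
    public_paired,
    recurrent_clonotypes,
)
from .io import PairedCell, aggregate_paired, read_abundance
from .model import AbundanceTable, Clonotype, PairedClonotype


def dependence_summary(
    table: AbundanceTable,
    group_a: str = "control",
    group_b: str = "mutant",
    min_samples: int = 3,
) -> tuple[DependenceLabels, dict[str, int]]:
    """Recurrent/shared/dependent/newcomer counts for a two-genotype table."""
    recurrent = recurrent_clonotypes(table, min_samples=min_samples)
    labels = classify_dependence(
        table, recurrent, table.group_ids(group_a), table.group_ids(group_b)
    )
    summary = {
        "recurrent": len(labels.recurrent),
        "shared": len(labels.shared),
        "dependent": len(labels.dependent),
        "newcomer": len(labels.newcomer),
        "recurrent_in_a": len(labels.present_in_a),
        "recurrent_in_b": len(labels.present_in_b),
    }
    return labels, summary


def cd5_summary(
    table: AbundanceTable,
    labels: DependenceLabels,
    lo_subset: str = "CD5lo",
    hi_subset: str = "CD5hi",
    min_present: int = 3,
) -> dict[str, float]:
    """Natural CD5lo/CD5hi counts and dependent ("lost") fractions.

    The loss fraction of a natural CD5 class is the share of its clones
    cross-assigned to the dependent category of the genotype inventory;
    reported over matched clones, with the all-clones denominator alongside.
    """
    cd5 = classify_cd5(
        table,
        table.subset_ids(lo_subset),
        table.subset_ids(hi_subset),
        min_present=min_present,
    )
    out: dict[str, float] = {
        "natural_cd5lo": len(cd5.natural_lo),
        "natural_cd5hi": len(cd5.natural_hi),
    }
    for name, clones in (("cd5lo", cd5.natural_lo), ("cd5hi", cd5.natural_hi)):
        if clones:
            xa = cross_assign(clones, labels)
            out[f"loss_fraction_{name}"] = 100.0 * xa.fractions_matched["dependent"]
            out[f"loss_fraction_{name}_all"] = 100.0 * xa.fractions_all["dependent"]
            out[f"n_matched_{name}"] = xa.n_matched
    denom = len(labels.present_in_a)
    if denom:
        out["loss_fraction_overall"] = 100.0 * len(labels.dependent) / denom
    return out


def paired_summary(cells: list[PairedCell],
                   genotype_a: str = "control",
                   genotype_b: str = "mutant") -> dict[str, int]:
    """Per-genotype paired clonotype counts and public (shared) clones."""
    rep = aggregate_paired(cells)
    shared = public_paired(rep, genotype_a, genotype_b)
    return {
        "paired_clonotypes_a": len(rep.union(genotype_a)),
        "paired_clonotypes_b": len(rep.union(genotype_b)),
        "public_paired": len(shared),
    }


def read_paired_cells(path) -> list[PairedCell]:
    """Read a paired single-cell clonotype TSV into PairedCell records.

    Expected columns: mouse_id, genotype, alpha_v, alpha_cdr3, alpha_j,
    beta_v, beta_cdr3, beta_j and optional in_frame_alpha / in_frame_beta
    boolean columns (assumed true when absent).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = [
        "mouse_id", "genotype",
        "alpha_v", "alpha_cdr3", "alpha_j",
        "beta_v", "beta_cdr3", "beta_j",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s): {', '.join(missing)}")

    def flag(row, col):
        if col not in df.columns:
            return True
        return str(row[col]).strip().lower() in {"t", "true", "1", "yes"}

    cells = []
    for _, row in df.iterrows():
        cells.append(
            PairedCell(
                mouse_id=row["mouse_id"],
                genotype=row["genotype"],
                clonotype=PairedClonotype(
                    alpha=Clonotype(row["alpha_v"], row["alpha_j"], row["alpha_cdr3"]),
                    beta=Clonotype(row["beta_v"], row["beta_j"], row["beta_cdr3"]),
                    in_frame_alpha=flag(row, "in_frame_alpha"),
                    in_frame_beta=flag(row, "in_frame_beta"),
                ),
            )
        )
    return cells


def load_benchmark_tables(
    directory,
) -> tuple[AbundanceTable, Optional[AbundanceTable], Optional[list[PairedCell]]]:
    """Load deposited benchmark tables from a local directory.

    Raises FileNotFoundError if the genotype table is absent; the CD5 and
    paired tables are optional and returned as None when missing.
    """
    directory = Path(directory)
    fig3 = directory / "fig3_abundance.tsv"
    if not fig3.exists():
        raise FileNotFoundError(
            f"{fig3} not found: place the deposited source-data tables "
            "(converted to abundance TSV) under this directory"
        )
    genotype_table = read_abundance(fig3)
    cd5_path = directory / "fig5_abundance.tsv"
    cd5_table = read_abundance(cd5_path) if cd5_path.exists() else None
    paired_path = directory / "fig6_paired.tsv"
    cells = read_paired_cells(paired_path) if paired_path.exists() else None
    return genotype_table, cd5_table, cells
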