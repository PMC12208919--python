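"""Reading, writing and aggregation of repertoire data.

Input is the AIRR Rearrangement TSV dialect with the columns
``sample_id``, ``umi``, ``v_call``, ``j_call``, ``junction_aa`` (or
``cdr3_aa``), ``productive`` and, optionally, the junction-editing columns
``v_deletions``, ``j_deletions``, ``p_additions``, ``n_additions``.
Aggregation collapses reads sharing a (sample, UMI) pair into one cDNA
molecule and counts molecules per clonotype.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    AbundanceTable,
    AnnotatedRead,
    Clonotype,
    JunctionAnnotation,
    PairedClonotype,
    RepertoireFormatError,
    SampleMeta,
)

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("sample_id", "umi", "v_call", "j_call", "productive")
JUNCTION_COLUMNS = ("v_deletions", "j_deletions", "p_additions", "n_additions")
_TRUTHY = {"t", "true", "1", "yes", "y"}
_FALSY = {"f", "false", "0", "no", "n"}


def _parse_bool(value: str, row: int, column: str) -> bool:
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise RepertoireFormatError(f"row {row}: cannot parse {column}={value!r} as boolean")


def read_rearrangements(path) -> list[AnnotatedRead]:
    """Read an AIRR-style rearrangement TSV into AnnotatedRead records.

    The reader does not deduplicate UMIs; collapse happens at aggregation.
    Multi-valued ``v_call`` entries are split on commas. Junction columns are
    optional as a block: when absent, reads carry no junction annotation.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cdr3_col = None
    for cand in ("junction_aa", "cdr3_aa"):
        if cand in df.columns:
            cdr3_col = cand
            break
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if cdr3_col is None:
        missing.append("junction_aa")
    if missing:
        raise RepertoireFormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    have_junction = all(c in df.columns for c in JUNCTION_COLUMNS)

    reads: list[AnnotatedRead] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        rec = row._asdict()
        try:
            v_calls = tuple(
                p.strip() for p in str(rec["v_call"]).split(",") if p.strip()
            )
            junction = None
            if have_junction and all(str(rec[c]).strip() != "" for c in JUNCTION_COLUMNS):
                junction = JunctionAnnotation(
                    v_deletions=int(rec["v_deletions"]),
                    j_deletions=int(rec["j_deletions"]),
                    p_additions=int(rec["p_additions"]),
                    n_additions=int(rec["n_additions"]),
                    paralog_ambiguous=len(v_calls) > 1,
                )
            reads.append(
                AnnotatedRead(
                    sample_id=str(rec["sample_id"]),
                    umi=str(rec["umi"]),
                    v_calls=v_calls,
                    j_call=str(rec["j_call"]),
                    cdr3_aa=str(rec[cdr3_col]),
                    productive=_parse_bool(rec["productive"], i, "productive"),
                    junction=junction,
                )
            )
        except RepertoireFormatError:
            raise
        except (ValueError, KeyError) as exc:
            raise RepertoireFormatError(f"{path}: unreadable row {i}: {exc}") from exc
    return reads


def _collapse_umis(
    reads: Iterable[AnnotatedRead],
) -> tuple[dict[tuple[str, str], AnnotatedRead], float]:
    """Collapse reads to molecules by exact (sample_id, umi) match.

    A UMI group with conflicting clonotypes is assigned by majority vote,
    ties broken by the lexicographically smallest clonotype key. Returns the
    representative read per molecule and the fraction of conflicted groups.
    """
    groups: dict[tuple[str, str], list[AnnotatedRead]] = defaultdict(list)
    for r in reads:
        groups[(r.sample_id, r.umi)].append(r)

    molecules: dict[tuple[str, str], AnnotatedRead] = {}
    n_conflict = 0
    for key, members in groups.items():
        keys = Counter(m.clonotype() for m in members)
        if len(keys) > 1:
            n_conflict += 1
            top = max(keys.values())
            winner = min(k for k, c in keys.items() if c == top)
        else:
            winner = next(iter(keys))
        molecules[key] = next(m for m in members if m.clonotype() == winner)
    conflict_rate = n_conflict / len(groups) if groups else 0.0
    if n_conflict:
        logger.info(
            "UMI collapse: %d/%d molecule groups had conflicting clonotypes",
            n_conflict,
            len(groups),
        )
    return molecules, conflict_rate


def aggregate_bulk(
    reads: Sequence[AnnotatedRead],
    samples: Optional[Sequence[SampleMeta]] = None,
    productive_only: bool = True,
    drop_paralog_ambiguous: bool = False,
) -> AbundanceTable:
    """Aggregate annotated reads into a clonotype × sample UMI-count table.

    Each unique molecule contributes 1 to exactly one clonotype. By default,
    paralog-ambiguous molecules are kept, keyed by the full sorted v_calls
    string; with ``drop_paralog_ambiguous`` they are excluded and their
    per-sample fraction is recorded on the table.
    """
    for r in reads:
        if r.productive and not r.cdr3_aa:
            raise ValueError(f"productive read with empty CDR3 (umi={r.umi})")
    if samples is None:
        ids = sorted({r.sample_id for r in reads})
        samples = [SampleMeta(sample_id=i) for i in ids]
    known = {s.sample_id for s in samples}
    for r in reads:
        if r.sample_id not in known:
            raise ValueError(f"read references unknown sample id {r.sample_id!r}")

    if productive_only:
        reads = [r for r in reads if r.productive]
    molecules, conflict_rate = _collapse_umis(reads)

    per_sample_total: Counter = Counter()
    per_sample_excluded: Counter = Counter()
    counts: Counter = Counter()
    for (sample_id, _), mol in molecules.items():
        per_sample_total[sample_id] += 1
        if drop_paralog_ambiguous and mol.paralog_ambiguous:
            per_sample_excluded[sample_id] += 1
            continue
        counts[(mol.clonotype(), sample_id)] += 1

    sample_ids = [s.sample_id for s in samples]
    by_clone: dict[Clonotype, dict[str, int]] = defaultdict(dict)
    for (clone, sample_id), n in counts.items():
        by_clone[clone][sample_id] = n
    if by_clone:
        index = pd.MultiIndex.from_tuples(
            [tuple(c) for c in by_clone], names=["v_gene", "j_gene", "cdr3_aa"]
        )
        mat = pd.DataFrame(
            [[by_clone[c].get(s, 0) for s in sample_ids] for c in by_clone],
            index=index,
            columns=sample_ids,
        )
    else:
        mat = pd.DataFrame(
            np.zeros((0, len(sample_ids)), dtype=np.int64),
            index=pd.MultiIndex.from_tuples([], names=["v_gene", "j_gene", "cdr3_aa"]),
            columns=sample_ids,
        )
    excluded = {
        s: (per_sample_excluded[s] / per_sample_total[s] if per_sample_total[s] else 0.0)
        for s in sample_ids
    }
    return AbundanceTable(
        mat,
        samples,
        excluded_paralog_fraction=excluded,
        umi_conflict_rate=conflict_rate,
    )


@dataclass
class PairedCell:
    """One single-cell record: a paired clonotype observed in one mouse."""

    mouse_id: str
    genotype: str
    clonotype: PairedClonotype


@dataclass
class PairedRepertoire:
    """Per-mouse paired clonotype sets after once-per-mouse collapse."""

    by_mouse: dict[str, set] = field(default_factory=dict)
    genotype_of: dict[str, str] = field(default_factory=dict)
    rejected: list[tuple[PairedCell, str]] = field(default_factory=list)

    def mice(self, genotype: Optional[str] = None) -> list[str]:
        return sorted(
            m
            for m in self.by_mouse
            if genotype is None or self.genotype_of[m] == genotype
        )

    def union(self, genotype: Optional[str] = None) -> set:
        out: set = set()
        for m in self.mice(genotype):
            out |= self.by_mouse[m]
        return out

    def mouse_multiplicity(self, clonotype: PairedClonotype, genotype: str) -> int:
        """Number of mice of a genotype in which the clonotype was seen."""
        return sum(
            1 for m in self.mice(genotype) if clonotype in self.by_mouse[m]
        )


def aggregate_paired(cells: Sequence[PairedCell]) -> PairedRepertoire:
    """Collapse single-cell records to per-mouse paired clonotype sets.

    Each clonotype counts once per mouse regardless of how many cells carried
    it. Cells with either chain out of frame are rejected with a reason.
    """
    rep = PairedRepertoire()
    for cell in cells:
        ct = cell.clonotype
        if not ct.in_frame_alpha:
            rep.rejected.append((cell, "alpha chain out of frame"))
            continue
        if not ct.in_frame_beta:
            rep.rejected.append((cell, "beta chain out of frame"))
            continue
        prev = rep.genotype_of.get(cell.mouse_id)
        if prev is not None and prev != cell.genotype:
            raise ValueError(
                f"mouse {cell.mouse_id} assigned to both {prev!r} and {cell.genotype!r}"
            )
        rep.genotype_of[cell.mouse_id] = cell.genotype
        rep.by_mouse.setdefault(cell.mouse_id, set()).add(ct)
    return rep


# -- abundance table round-trip ---------------------------------------


def write_abundance(table: AbundanceTable, path) -> None:
    """Write an abundance table as TSV with sample-metadata header lines."""
    with open(path, "w") as fh:
        for s in table.samples:
            fh.write(
                f"# sample={s.sample_id}\tgroup={s.group}\tsubset={s.subset}"
                f"\treplicate={s.replicate}\n"
            )
        cols = "\t".join(["v_gene", "j_gene", "cdr3_aa"] + table.sample_ids)
        fh.write(cols + "\n")
        for key, row in table.counts.iterrows():
            fh.write("\t".join(list(key) + [str(int(v)) for v in row]) + "\n")


def read_abundance(path) -> AbundanceTable:
    """Read a TSV written by :func:`write_abundance` (round-trip identity)."""
    samples: list[SampleMeta] = []
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            fields = dict(
                kv.split("=", 1) for kv in line[1:].strip().split("\t") if "=" in kv
            )
            samples.append(
                SampleMeta(
                    sample_id=fields.get("sample", ""),
                    group=fields.get("group", ""),
                    subset=fields.get("subset", ""),
                    replicate=int(fields.get("replicate", 0)),
                )
            )
    df = pd.read_csv(path, sep="\t", skiprows=header_lines, dtype=str,
                     keep_default_na=False)
    for col in ("v_gene", "j_gene", "cdr3_aa"):
        if col not in df.columns:
            raise RepertoireFormatError(f"{path}: missing column {col}")
    sample_cols = [c for c in df.columns if c not in ("v_gene", "j_gene", "cdr3_aa")]
    counts = df[sample_cols]
    try:
        counts = counts.astype(np.int64)
    except ValueError as exc:
        raise RepertoireFormatError(f"{path}: non-integer count: {exc}") from exc
    if (counts.to_numpy() < 0).any():
        raise RepertoireFormatError(f"{path}: negative counts")
    counts.index = pd.MultiIndex.from_frame(df[["v_gene", "j_gene", "cdr3_aa"]])
    if not samples:
        samples = [SampleMeta(sample_id=c) for c in sample_cols]
    if [s.sample_id for s in samples] != sample_cols:
        raise RepertoireFormatError(
            f"{path}: metadata sample ids do not match count columns"
        )
    return AbundanceTable(counts, samples)
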