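"""Synthetic repertoire studies with planted ground truth.

The generator emulates the two study designs the analysis consumes:

* a two-genotype bulk design — replicate samples per genotype drawn from a
  shared clonotype pool in which some clones are selectable only in
  genotype A ("dependent"), some only in genotype B ("newcomer") and the
  rest in both;
* an optional 4+4 CD5-sorted design in which each clonotype carries a fixed
  latent CD5 class (lo or hi) and sorted samples draw only from clones of
  the matching class — the class is a property of the clone, not a per-cell
  coin flip.

Clone sizes follow a heavy-tailed log-normal law (a power-law option is
provided); each sample is a multinomial draw of a fixed number of cDNA
molecules from the availability-restricted relative abundances. Per-clone
junction edits are Poisson with a mean shift for newcomers, and positional
V/J gene usage is a discretized-normal categorical with a mean shift for
newcomers. All randomness flows from one seed through named substreams, so
regenerating any sample is order-independent.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .model import (
    AbundanceTable,
    Clonotype,
    JunctionAnnotation,
    PairedClonotype,
    SampleMeta,
)
from .io import PairedCell

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic generator.

    Defaults encode the study conditions the analysis is built around:
    a 1,000-clone pool with 500 genotype-A-only ("dependent") clones,
    100 genotype-B-only ("newcomer") clones and 400 clones available to
    both; 3+3 replicate samples at 50,000 molecules each; an optional
    4+4 CD5 design; log-normal clone sizes with sigma = 1; Poisson(1)
    junction edits raised by 2 for newcomers; positional usage shifted
    distally by 2 index units for newcomers.
    """

    s_shared: int = 400
    s_dependent: int = 500
    s_newcomer: int = 100
    clone_size_law: str = "lognormal"  # or "powerlaw"
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 1.0
    powerlaw_alpha: float = 2.5
    replicates: tuple[int, int] = (3, 3)
    reads_per_sample: int = 50_000
    cd5_design: bool = False
    cd5_replicates: tuple[int, int] = (4, 4)
    cd5_reads_per_sample: int = 50_000
    p_cd5_lo: float = 0.5
    lambda_edit: float = 1.0
    delta_edit: float = 2.0
    v_center: float = 15.0
    v_sd: float = 4.0
    v_max: int = 40
    j_center: float = 30.0
    j_sd: float = 8.0
    j_max: int = 60
    delta_pos: float = 2.0
    paralog_fraction: float = 0.0
    umi_collision_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("s_shared", "s_dependent", "s_newcomer"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.lognormal_sigma <= 0:
            raise ValueError("lognormal_sigma must be > 0")
        for name in ("p_cd5_lo", "paralog_fraction", "umi_collision_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.reads_per_sample < 1:
            raise ValueError("reads_per_sample must be >= 1")

    @property
    def s_total(self) -> int:
        return self.s_shared + self.s_dependent + self.s_newcomer


@dataclass
class SimulationResult:
    """Simulated abundance tables plus the planted ground truth."""

    genotype_table: AbundanceTable
    cd5_table: Optional[AbundanceTable]
    truth: pd.DataFrame
    config: SimulationConfig

    def clones_with_label(self, label: str) -> set[Clonotype]:
        sub = self.truth[self.truth["label"] == label]
        return {
            Clonotype(r.v_gene, r.j_gene, r.cdr3_aa)
            for r in sub.itertuples(index=False)
        }

    def junction_of(self, clonotype: Clonotype) -> JunctionAnnotation:
        row = self.truth[
            (self.truth["v_gene"] == clonotype.v_gene)
            & (self.truth["j_gene"] == clonotype.j_gene)
            & (self.truth["cdr3_aa"] == clonotype.cdr3_aa)
        ].iloc[0]
        return JunctionAnnotation(
            int(row.v_deletions),
            int(row.j_deletions),
            int(row.p_additions),
            int(row.n_additions),
            bool(row.paralog_ambiguous),
        )


def _substream(seed: int, *tags: str) -> np.random.Generator:
    """Named substream: deterministic per (seed, tags), order-independent."""
    digest = [zlib.crc32(f"clonalholes:{t}".encode()) % (2**31) for t in tags]
    return np.random.default_rng(np.random.SeedSequence([seed % (2**31), *digest]))


def _random_cdr3(rng: np.random.Generator, existing: set[str]) -> str:
    while True:
        length = int(rng.integers(8, 17))
        s = "C" + "".join(rng.choice(list(_AA), size=length)) + "F"
        if s not in existing:
            existing.add(s)
            return s


def _discrete_normal(
    rng: np.random.Generator, n: int, center: float, sd: float, maximum: int
) -> np.ndarray:
    vals = np.rint(rng.normal(center, sd, size=n)).astype(int)
    return np.clip(vals, 1, maximum)


def _clone_sizes(cfg: SimulationConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    if cfg.clone_size_law == "lognormal":
        return rng.lognormal(cfg.lognormal_mu, cfg.lognormal_sigma, size=n)
    if cfg.clone_size_law == "powerlaw":
        # Pareto tail with index alpha; ranks are exchangeable.
        return (1.0 - rng.random(n)) ** (-1.0 / (cfg.powerlaw_alpha - 1.0))
    raise ValueError(f"unknown clone_size_law {cfg.clone_size_law!r}")


def _make_pool(cfg: SimulationConfig, seed: int) -> pd.DataFrame:
    rng = _substream(seed, "pool")
    n = cfg.s_total
    if n == 0:
        raise ValueError("clonotype pool is empty")
    labels = np.array(
        ["shared"] * cfg.s_shared
        + ["dependent"] * cfg.s_dependent
        + ["newcomer"] * cfg.s_newcomer
    )
    is_new = labels == "newcomer"

    v_idx = _discrete_normal(rng, n, cfg.v_center, cfg.v_sd, cfg.v_max)
    j_idx = _discrete_normal(rng, n, cfg.j_center, cfg.j_sd, cfg.j_max)
    v_idx[is_new] = np.clip(
        np.rint(
            rng.normal(cfg.v_center + cfg.delta_pos, cfg.v_sd, size=is_new.sum())
        ).astype(int),
        1,
        cfg.v_max,
    )
    j_idx[is_new] = np.clip(
        np.rint(
            rng.normal(cfg.j_center + cfg.delta_pos, cfg.j_sd, size=is_new.sum())
        ).astype(int),
        1,
        cfg.j_max,
    )

    ambiguous = rng.random(n) < cfg.paralog_fraction
    v_gene = np.array(
        [
            f"TRAV{v},TRAV{v}D" if amb else f"TRAV{v}"
            for v, amb in zip(v_idx, ambiguous)
        ]
    )
    j_gene = np.array([f"TRAJ{j}" for j in j_idx])
    seen: set[str] = set()
    cdr3 = np.array([_random_cdr3(rng, seen) for _ in range(n)])

    abundance = _clone_sizes(cfg, rng, n)

    lam = np.where(is_new, cfg.lambda_edit + cfg.delta_edit, cfg.lambda_edit)
    totals = rng.poisson(lam)
    splits = np.array([rng.multinomial(t, [0.25] * 4) for t in totals])

    cd5 = np.where(rng.random(n) < cfg.p_cd5_lo, "lo", "hi")

    return pd.DataFrame(
        {
            "v_gene": v_gene,
            "j_gene": j_gene,
            "cdr3_aa": cdr3,
            "label": labels,
            "cd5_class": cd5,
            "rel_abundance": abundance / abundance.sum(),
            "v_index": v_idx,
            "j_index": j_idx,
            "v_deletions": splits[:, 0],
            "j_deletions": splits[:, 1],
            "p_additions": splits[:, 2],
            "n_additions": splits[:, 3],
            "paralog_ambiguous": ambiguous,
        }
    )


def _draw_sample(
    truth: pd.DataFrame,
    available: np.ndarray,
    reads: int,
    rng: np.random.Generator,
) -> np.ndarray:
    if not available.any():
        raise ValueError("zero available clonotypes for a sample")
    p = truth["rel_abundance"].to_numpy() * available
    counts = np.zeros(len(truth), dtype=np.int64)
    counts[available] = rng.multinomial(reads, p[available] / p[available].sum())
    return counts


def simulate_study(
    config: Optional[SimulationConfig] = None, seed: Optional[int] = None
) -> SimulationResult:
    """Simulate a two-genotype bulk study (and optional CD5 design).

    Returns the genotype abundance table (samples ctrl_1.. / mut_1.., groups
    "control"/"mutant"), the CD5 table if configured (subsets CD5lo/CD5hi
    within the control genotype), and the per-clonotype truth table.
    Deterministic per seed.
    """
    cfg = config or SimulationConfig()
    if seed is None:
        seed = cfg.seed
    truth = _make_pool(cfg, seed)
    labels = truth["label"].to_numpy()
    avail_a = labels != "newcomer"
    avail_b = labels != "dependent"

    index = pd.MultiIndex.from_frame(truth[["v_gene", "j_gene", "cdr3_aa"]])
    cols, metas = {}, []
    for g, (prefix, group, avail) in enumerate(
        [("ctrl", "control", avail_a), ("mut", "mutant", avail_b)]
    ):
        for r in range(cfg.replicates[g]):
            sid = f"{prefix}_{r + 1}"
            rng = _substream(seed, "bulk", sid)
            cols[sid] = _draw_sample(truth, avail, cfg.reads_per_sample, rng)
            metas.append(SampleMeta(sid, group=group, subset="M2", replicate=r + 1))
    genotype_table = AbundanceTable(pd.DataFrame(cols, index=index), metas)

    cd5_table = None
    if cfg.cd5_design:
        cd5 = truth["cd5_class"].to_numpy()
        cols5, metas5 = {}, []
        for g, (cls, nrep) in enumerate(zip(("lo", "hi"), cfg.cd5_replicates)):
            avail = avail_a & (cd5 == cls)
            for r in range(nrep):
                sid = f"cd5{cls}_{r + 1}"
                rng = _substream(seed, "cd5", sid)
                cols5[sid] = _draw_sample(truth, avail, cfg.cd5_reads_per_sample, rng)
                metas5.append(
                    SampleMeta(sid, group="control", subset=f"CD5{cls}", replicate=r + 1)
                )
        cd5_table = AbundanceTable(pd.DataFrame(cols5, index=index), metas5)

    return SimulationResult(
        genotype_table=genotype_table, cd5_table=cd5_table, truth=truth, config=cfg
    )


# -- paired single-cell design ----------------------------------------


@dataclass
class PairedSimulation:
    """Simulated per-mouse paired cells plus the planted public clone set."""

    cells: list[PairedCell]
    public_truth: set[PairedClonotype]
    config: dict = field(default_factory=dict)


def _paired_clonotype(rng: np.random.Generator, seen: set[str]) -> PairedClonotype:
    a_cdr3 = _random_cdr3(rng, seen)
    b_cdr3 = _random_cdr3(rng, seen)
    alpha = Clonotype(f"TRAV14-{int(rng.integers(1, 4))}",
                      f"TRAJ{int(rng.integers(1, 61))}", a_cdr3)
    beta = Clonotype(f"TRBV5", f"TRBJ{int(rng.integers(1, 8))}", b_cdr3)
    return PairedClonotype(alpha=alpha, beta=beta)


def simulate_paired(
    n_mice: tuple[int, int] = (3, 3),
    cells_per_mouse: int = 40,
    pool_private: tuple[int, int] = (120, 60),
    n_public: int = 5,
    seed: int = 0,
    genotypes: tuple[str, str] = ("control", "mutant"),
) -> PairedSimulation:
    """Simulate paired-chain single-cell clonotypes across mice.

    Exactly ``n_public`` clones are planted in at least one mouse of each
    genotype; private pools are disjoint between genotypes, so the shared
    set recovered downstream equals the planted set exactly.
    """
    if n_public < 0:
        raise ValueError("n_public must be >= 0")
    if n_public > 0 and (min(n_mice) < 1 or cells_per_mouse < 1):
        raise ValueError("cannot place public clones without mice and cells")
    if cells_per_mouse < 1:
        raise ValueError("cells_per_mouse must be >= 1")
    rng = _substream(seed, "paired-pool")
    seen: set[str] = set()
    public = [_paired_clonotype(rng, seen) for _ in range(n_public)]
    privates = [
        [_paired_clonotype(rng, seen) for _ in range(pool_private[g])]
        for g in range(2)
    ]

    cells: list[PairedCell] = []
    for g, genotype in enumerate(genotypes):
        pool = privates[g] + public
        weights = _substream(seed, "paired-weights", genotype).lognormal(
            0.0, 1.0, size=len(pool)
        )
        weights /= weights.sum()
        for m in range(n_mice[g]):
            mouse_id = f"{genotype}_m{m + 1}"
            mrng = _substream(seed, "paired", mouse_id)
            # guaranteed placement: public clone k lives in mouse k % n_mice
            planted = [
                public[k] for k in range(n_public) if k % n_mice[g] == m
            ]
            n_draw = max(cells_per_mouse - len(planted), 0)
            drawn = [
                pool[i]
                for i in mrng.choice(len(pool), size=n_draw, p=weights)
            ]
            for ct in planted + drawn:
                cells.append(PairedCell(mouse_id=mouse_id, genotype=genotype,
                                        clonotype=ct))
    return PairedSimulation(
        cells=cells,
        public_truth=set(public),
        config=dict(
            n_mice=n_mice,
            cells_per_mouse=cells_per_mouse,
            pool_private=pool_private,
            n_public=n_public,
            seed=seed,
        ),
    )


# -- AIRR emission ------------------------------------------------------


def emit_airr(result: SimulationResult, path, table: str = "genotype") -> None:
    """Write a simulated study as an AIRR rearrangement TSV.

    One row per cDNA molecule with a unique UMI (optionally colliding at
    the configured rate to exercise UMI collapse downstream); junction
    columns come from the planted per-clonotype annotations. Reading the
    file back and aggregating reproduces the simulated table exactly.
    """
    tab = result.genotype_table if table == "genotype" else result.cd5_table
    if tab is None:
        raise ValueError(f"no {table!r} table in this simulation")
    cfg = result.config
    truth = result.truth.set_index(
        pd.MultiIndex.from_frame(result.truth[["v_gene", "j_gene", "cdr3_aa"]])
    )
    rng = _substream(cfg.seed, "emit", table)
    with open(path, "w") as fh:
        fh.write(
            "sample_id\tumi\tv_call\tj_call\tjunction_aa\tproductive\t"
            "v_deletions\tj_deletions\tp_additions\tn_additions\n"
        )
        for sid in tab.sample_ids:
            counter = 0
            col = tab.counts[sid]
            for key, count in col[col > 0].items():
                tr = truth.loc[key]
                for _ in range(int(count)):
                    umi = f"{sid}-{counter:08d}"
                    counter += 1
                    n_rows = 1
                    if cfg.umi_collision_rate > 0 and rng.random() < cfg.umi_collision_rate:
                        n_rows = 2  # same molecule sequenced twice
                    for _ in range(n_rows):
                        fh.write(
                            f"{sid}\t{umi}\t{key[0]}\t{key[1]}\t{key[2]}\tT\t"
                            f"{int(tr.v_deletions)}\t{int(tr.j_deletions)}\t"
                            f"{int(tr.p_additions)}\t{int(tr.n_additions)}\n"
                        )


def write_truth(result: SimulationResult, path) -> None:
    """Write the planted per-clonotype truth table as TSV."""
    result.truth.to_csv(path, sep="\t", index=False)
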