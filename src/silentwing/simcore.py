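"""Forward-time Wright-Fisher simulation of two competing beneficial mutations.

The model: a constant-size population of ``N`` diploid, sexually reproducing
individuals with discrete, non-overlapping generations. Two unlinked
mutations segregate: ``m1`` (autosomal, dominance ``h1``) and ``m2`` (X-linked
by default, optionally autosomal with dominance ``h2``). Each mutation confers
a selective advantage ``s`` to males that express it; females have fitness 1.
When a male expresses both mutations, the combined fitness depends on the
epistasis mode:

- ``additive``:     1 + s*d1 + s*d2
- ``nonadditive``:  1 + s*max(d1, d2)   (no extra benefit from the second)
- ``negative``:     1 + s*max(d1, d2) - c   (an additive pleiotropic cost c)
- ``single_m1`` / ``single_m2``: only the named mutation affects fitness.

where d1, d2 are the dominance-weighted expression levels (0, h, or 1 for
genotypes 0/1/2; hemizygous X males express d2 = g2 in {0, 1}).

Reproduction is Wright-Fisher with soft selection: each of the N offspring
independently draws its mother uniformly among females and its father among
males with probability proportional to male fitness (polygyny allowed).
Autosomal alleles transmit Mendelianly; the X transmits mother -> all
offspring (one of her two X's), father -> daughters only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScenarioConfig",
    "PopulationState",
    "TrajectorySummary",
    "LineageExtinctionError",
    "MODES",
    "init_population",
    "male_fitness",
    "next_generation",
    "run_replicate",
    "run_experiment",
    "summarize_experiment",
    "epistasis_scenarios",
]

MODES = ("single_m1", "single_m2", "additive", "nonadditive", "negative")
LINKAGES = ("X", "autosomal")


class LineageExtinctionError(RuntimeError):
    """A generation came out all-male or all-female; the replicate cannot continue."""


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one simulation scenario.

    Defaults are the study conditions: N=500 individuals, selective advantage
    s=+0.3 expressed by males only, each mutation introduced into 5 distinct
    male genomes, dominance 0.75 for the autosomal mutation, X-linked m2.
    """

    N: int = 500
    s: float = 0.3
    h1: float = 0.75
    h2: float = 1.0
    m2_linkage: str = "X"
    mode: str = "additive"
    c: float = 0.1
    n_init: int = 5
    generations: int = 250
    sex_ratio: float = 0.5
    female_selection: bool = False  # sex-shared selection, for self-consistency checks

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError(f"N must be positive, got {self.N}")
        if self.s < 0:
            raise ValueError(f"s must be non-negative, got {self.s}")
        for name, h in (("h1", self.h1), ("h2", self.h2)):
            if not 0.0 <= h <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {h}")
        if self.c < 0:
            raise ValueError(f"c must be non-negative, got {self.c}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.m2_linkage not in LINKAGES:
            raise ValueError(f"m2_linkage must be one of {LINKAGES}, got {self.m2_linkage!r}")
        if not 0 <= self.n_init:
            raise ValueError(f"n_init must be non-negative, got {self.n_init}")
        if not 0.0 < self.sex_ratio < 1.0:
            raise ValueError(f"sex_ratio must be in (0, 1), got {self.sex_ratio}")
        if self.generations < 0:
            raise ValueError(f"generations must be non-negative, got {self.generations}")


@dataclass
class PopulationState:
    """Per-individual state: sex and allele counts at the two loci.

    ``male`` is boolean; ``g1`` in {0,1,2}; ``g2`` in {0,1,2} for females (and
    for everyone under autosomal linkage), {0,1} for males under X linkage.
    """

    male: np.ndarray
    g1: np.ndarray
    g2: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.male) == len(self.g1) == len(self.g2)):
            raise ValueError("state arrays must have equal length")

    @property
    def n(self) -> int:
        return len(self.male)

    def m1_frequency(self) -> float:
        return float(self.g1.sum()) / (2 * self.n)

    def m2_frequency(self, linkage: str = "X") -> float:
        """Allele frequency of m2; under X linkage the denominator is 2*N_f + N_m."""
        copies = float(self.g2.sum())
        if linkage == "X":
            n_m = int(self.male.sum())
            return copies / (2 * (self.n - n_m) + n_m)
        return copies / (2 * self.n)

    def male_carrier_frequencies(self) -> tuple[float, float, float]:
        """Fractions of males carrying m1, m2, and both (>=1 copy each)."""
        males = self.male
        n_m = int(males.sum())
        if n_m == 0:
            return (np.nan, np.nan, np.nan)
        c1 = self.g1[males] > 0
        c2 = self.g2[males] > 0
        return (c1.mean(), c2.mean(), (c1 & c2).mean())


@dataclass
class TrajectorySummary:
    """Per-generation frequencies from one replicate (index 0 = founding generation)."""

    freq_m1: np.ndarray
    freq_m2: np.ndarray
    male_carrier_m1: np.ndarray
    male_carrier_m2: np.ndarray
    male_carrier_both: np.ndarray
    status_m1: str  # "lost" | "fixed" | "segregating"
    status_m2: str

    def frequency_at(self, generation: int) -> tuple[float, float]:
        return float(self.freq_m1[generation]), float(self.freq_m2[generation])


def _status(freq: float) -> str:
    if freq == 0.0:
        return "lost"
    if freq == 1.0:
        return "fixed"
    return "segregating"


def init_population(cfg: ScenarioConfig, rng: np.random.Generator) -> PopulationState:
    """Found the population: assign sexes, then seed each mutation into a
    disjoint random subset of ``n_init`` male genomes (one copy per male).

    In ``single_m1``/``single_m2`` modes only the named mutation is seeded.
    """
    male = rng.random(cfg.N) < cfg.sex_ratio
    g1 = np.zeros(cfg.N, dtype=np.int64)
    g2 = np.zeros(cfg.N, dtype=np.int64)
    seed_m1 = cfg.mode != "single_m2"
    seed_m2 = cfg.mode != "single_m1"
    need = cfg.n_init * (int(seed_m1) + int(seed_m2))
    male_idx = np.flatnonzero(male)
    if male_idx.size < need:
        raise ValueError(
            f"cannot seed mutations: need {need} distinct male carriers "
            f"but only {male_idx.size} males were drawn"
        )
    if need:
        chosen = rng.choice(male_idx, size=need, replace=False)
        k = cfg.n_init if seed_m1 else 0
        if seed_m1:
            g1[chosen[:k]] = 1
        if seed_m2:
            g2[chosen[k:]] = 1
    return PopulationState(male=male, g1=g1, g2=g2)


def _expression(g: np.ndarray, h: float, hemizygous: np.ndarray | bool = False) -> np.ndarray:
    """Dominance-weighted expression level d in [0,1] for allele counts g.

    Hemizygous carriers (X-linked males) express d = g in {0, 1}.
    """
    g = np.asarray(g)
    d = np.where(g == 1, h, np.where(g >= 2, 1.0, 0.0))
    if np.any(hemizygous):
        d = np.where(hemizygous, np.minimum(g, 1).astype(float), d)
    return d


def male_fitness(
    g1: np.ndarray | int,
    g2: np.ndarray | int,
    cfg: ScenarioConfig,
    hemizygous: np.ndarray | bool | None = None,
) -> np.ndarray | float:
    """Relative fitness of males given allele counts at the two loci.

    ``hemizygous`` marks individuals whose g2 is a single X copy (defaults to
    True when cfg.m2_linkage == "X", the usual male case).
    """
    scalar = np.isscalar(g1) and np.isscalar(g2)
    if hemizygous is None:
        hemizygous = cfg.m2_linkage == "X"
    d1 = _expression(np.asarray(g1), cfg.h1)
    d2 = _expression(np.asarray(g2), cfg.h2, hemizygous)
    s = cfg.s
    if cfg.mode == "single_m1":
        w = 1.0 + s * d1
    elif cfg.mode == "single_m2":
        w = 1.0 + s * d2
    elif cfg.mode == "additive":
        w = 1.0 + s * d1 + s * d2
    elif cfg.mode == "nonadditive":
        w = 1.0 + s * np.maximum(d1, d2)
    else:  # negative
        w = 1.0 + s * np.maximum(d1, d2) - cfg.c * ((d1 > 0) & (d2 > 0))
    return float(w) if scalar else w


def _weighted_pick(idx: np.ndarray, weights: np.ndarray, size: int, rng: np.random.Generator) -> np.ndarray:
    cum = np.cumsum(weights)
    u = rng.random(size) * cum[-1]
    return idx[np.searchsorted(cum, u, side="right")]


def next_generation(pop: PopulationState, cfg: ScenarioConfig, rng: np.random.Generator) -> PopulationState:
    """Produce the next Wright-Fisher generation of N offspring.

    Fathers are drawn with probability proportional to male fitness, mothers
    uniformly among females (unless cfg.female_selection applies the same
    fitness function to females). Raises LineageExtinctionError if either sex
    is absent.
    """
    male_idx = np.flatnonzero(pop.male)
    female_idx = np.flatnonzero(~pop.male)
    if male_idx.size == 0 or female_idx.size == 0:
        missing = "males" if male_idx.size == 0 else "females"
        raise LineageExtinctionError(f"population has no {missing}; lineage cannot continue")

    N = cfg.N
    x_linked = cfg.m2_linkage == "X"
    w_m = np.asarray(male_fitness(pop.g1[male_idx], pop.g2[male_idx], cfg, hemizygous=x_linked), dtype=float)
    fathers = _weighted_pick(male_idx, w_m, N, rng)
    if cfg.female_selection:
        w_f = np.asarray(
            male_fitness(pop.g1[female_idx], pop.g2[female_idx], cfg, hemizygous=False), dtype=float
        )
        mothers = _weighted_pick(female_idx, w_f, N, rng)
    else:
        mothers = female_idx[rng.integers(0, female_idx.size, N)]

    male = rng.random(N) < cfg.sex_ratio

    g1 = (rng.random(N) < pop.g1[fathers] / 2.0).astype(np.int64) + (
        rng.random(N) < pop.g1[mothers] / 2.0
    ).astype(np.int64)

    if x_linked:
        maternal = (rng.random(N) < pop.g2[mothers] / 2.0).astype(np.int64)
        paternal = ((~male) & (pop.g2[fathers] > 0)).astype(np.int64)  # daughters only
        g2 = maternal + paternal
    else:
        g2 = (rng.random(N) < pop.g2[fathers] / 2.0).astype(np.int64) + (
            rng.random(N) < pop.g2[mothers] / 2.0
        ).astype(np.int64)

    return PopulationState(male=male, g1=g1, g2=g2)


def run_replicate(
    cfg: ScenarioConfig,
    rng: np.random.Generator,
    stop_at_absorption: bool = False,
) -> TrajectorySummary:
    """Simulate one replicate for cfg.generations generations.

    Records allele frequencies and male carrier fractions each generation
    (index 0 is the founding population). Once both loci are absorbed
    (frequency 0 or 1) the remaining entries are filled with the absorbed
    values without further simulation; with ``stop_at_absorption`` the loop
    additionally ignores cfg.generations and runs until absorption.
    """
    pop = init_population(cfg, rng)
    x = cfg.m2_linkage
    gens = cfg.generations
    cap = 100 * cfg.generations + 100_000 if stop_at_absorption else gens

    f1 = np.empty(gens + 1)
    f2 = np.empty(gens + 1)
    c1 = np.empty(gens + 1)
    c2 = np.empty(gens + 1)
    cb = np.empty(gens + 1)

    def record(t: int) -> None:
        if t <= gens:
            f1[t] = pop.m1_frequency()
            f2[t] = pop.m2_frequency(x)
            c1[t], c2[t], cb[t] = pop.male_carrier_frequencies()

    record(0)
    t = 0
    while t < cap:
        a1, a2 = pop.m1_frequency(), pop.m2_frequency(x)
        if a1 in (0.0, 1.0) and a2 in (0.0, 1.0):
            break
        pop = next_generation(pop, cfg, rng)
        t += 1
        record(t)
        if stop_at_absorption and t >= gens:
            a1, a2 = pop.m1_frequency(), pop.m2_frequency(x)
            if a1 in (0.0, 1.0) and a2 in (0.0, 1.0):
                break
    if t < gens:  # absorbed early: frequencies are constant from here on
        for arr in (f1, f2, c1, c2, cb):
            arr[t + 1 :] = arr[t]

    return TrajectorySummary(
        freq_m1=f1,
        freq_m2=f2,
        male_carrier_m1=c1,
        male_carrier_m2=c2,
        male_carrier_both=cb,
        status_m1=_status(pop.m1_frequency()),
        status_m2=_status(pop.m2_frequency(x)),
    )


def replicate_rng(base_seed: int, scenario_index: int, replicate: int, retry: int = 0) -> np.random.Generator:
    """The documented seed-spawning scheme: each replicate's generator is
    ``default_rng(SeedSequence([base_seed, scenario_index, replicate, retry]))``,
    so any single replicate reproduces in isolation. ``retry`` increments when
    a replicate aborts (all-male/all-female generation) and is re-run.
    """
    return np.random.default_rng(np.random.SeedSequence([base_seed, scenario_index, replicate, retry]))


def run_experiment(
    scenarios: Mapping[str, ScenarioConfig] | Sequence[ScenarioConfig],
    replicates: int,
    base_seed: int,
    checkpoints: Iterable[int] = (100, 250),
    max_retries: int = 10,
) -> pd.DataFrame:
    """Run ``replicates`` independent replicates of each scenario.

    Returns one row per (scenario, replicate) with m1/m2 allele frequencies
    and male carrier fractions at each checkpoint generation, the final
    status of each mutation, and the retry count (re-runs after single-sex
    generations, essentially always 0 at N >= 100).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if not isinstance(scenarios, Mapping):
        scenarios = {cfg.mode: cfg for cfg in scenarios}
    rows = []
    for si, (label, cfg) in enumerate(scenarios.items()):
        cps = sorted(g for g in checkpoints if g <= cfg.generations)
        if not cps:  # all checkpoints beyond the run: report the final generation
            cps = [cfg.generations]
        for rep in range(replicates):
            retry = 0
            while True:
                rng = replicate_rng(base_seed, si, rep, retry)
                try:
                    traj = run_replicate(cfg, rng)
                    break
                except LineageExtinctionError:
                    retry += 1
                    if retry > max_retries:
                        raise
            row: dict = {"scenario": label, "replicate": rep, "retries": retry}
            for g in cps:
                row[f"freq_m1_g{g}"] = traj.freq_m1[g]
                row[f"freq_m2_g{g}"] = traj.freq_m2[g]
                row[f"carrier_m1_g{g}"] = traj.male_carrier_m1[g]
                row[f"carrier_m2_g{g}"] = traj.male_carrier_m2[g]
            row["status_m1"] = traj.status_m1
            row["status_m2"] = traj.status_m2
            rows.append(row)
    return pd.DataFrame(rows)


def summarize_experiment(table: pd.DataFrame) -> pd.DataFrame:
    """Per-scenario medians, quartiles, fixation and loss proportions of each
    mutation at every checkpoint generation present in the table."""
    if table.empty:
        raise ValueError("experiment table is empty")
    freq_cols = [c for c in table.columns if c.startswith("freq_")]
    rows = []
    for scenario, sub in table.groupby("scenario", sort=False):
        for col in freq_cols:
            _, mut, gen = col.split("_")
            v = sub[col].to_numpy()
            rows.append(
                {
                    "scenario": scenario,
                    "mutation": mut,
                    "generation": int(gen[1:]),
                    "median": float(np.median(v)),
                    "q25": float(np.quantile(v, 0.25)),
                    "q75": float(np.quantile(v, 0.75)),
                    "prop_fixed": float((v == 1.0).mean()),
                    "prop_lost": float((v == 0.0).mean()),
                    "n": len(v),
                }
            )
    return pd.DataFrame(rows)


def epistasis_scenarios(
    h1: float = 0.75,
    m2_linkage: str = "X",
    generations: int = 250,
    include_singles: bool = True,
    **overrides,
) -> dict[str, ScenarioConfig]:
    """The standard scenario grid: additive / nonadditive / negative epistasis
    plus the two single-mutation controls, all else at study defaults."""
    modes = ("additive", "nonadditive", "negative") + (
        ("single_m1", "single_m2") if include_singles else ()
    )
    return {
        mode: ScenarioConfig(
            h1=h1, m2_linkage=m2_linkage, mode=mode, generations=generations, **overrides
        )
        for mode in modes
    }
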