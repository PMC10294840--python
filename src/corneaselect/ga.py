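"""Genetic-algorithm wrapper selection of a fixed-size feature-map subset.

A chromosome is a fixed-length set of distinct feature-map (channel)
indices; its fitness is the accuracy of a linear SVM trained on exactly
those channel-mean columns.  The algorithm is generational with elitist
truncation replacement:

* fitness-proportionate (or rank) parent selection,
* uniform crossover at rate CR with duplicate repair (re-drawing any
  duplicated gene uniformly from the indices absent from that child),
* per-gene mutation at rate MR that replaces a gene by a uniformly chosen
  index not already present in the chromosome,
* replacement of the least-fit members of the combined parent+offspring
  pool, which both "replaces the least fit" and "keeps the best in
  memory": best-so-far fitness is non-decreasing by construction.

Defaults mirror the published control parameters: population 40,
chromosome length 192, CR 0.5, MR 0.1, 1000 generations.

The model-object surface is :class:`GAFeatureSelector` /
:class:`GAFeatureSelectorResults`; the underlying operators are plain
functions so each stage can be tested in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import SplitSpec, accuracy, confusion, split, train_svm
from .features import FeatureTable

__all__ = [
    "GAConfig",
    "Chromosome",
    "GATrace",
    "SVMFitness",
    "init_population",
    "evaluate_fitness",
    "select_parents",
    "uniform_crossover",
    "mutate",
    "step_generation",
    "run_ga",
    "GAFeatureSelector",
    "GAFeatureSelectorResults",
]

logger = logging.getLogger(__name__)

_SCHEMES = ("fitness_proportionate", "rank")


@dataclass(frozen=True)
class GAConfig:
    """Control parameters of the selection GA (published defaults)."""

    population_size: int = 40
    chromosome_length: int = 192
    crossover_rate: float = 0.5
    mutation_rate: float = 0.1
    max_generations: int = 1000
    seed: int = 0
    selection_scheme: str = "fitness_proportionate"
    early_stop_patience: int | None = None  # generations without improvement

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.chromosome_length < 1:
            raise ValueError("chromosome_length must be >= 1")
        for name in ("crossover_rate", "mutation_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.max_generations < 0:
            raise ValueError("max_generations must be >= 0")
        if self.selection_scheme not in _SCHEMES:
            raise ValueError(f"selection_scheme must be one of {_SCHEMES}")


@dataclass(eq=False)
class Chromosome:
    """A candidate subset: distinct in-range channel indices + fitness."""

    genes: np.ndarray
    fitness: float | None = None

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=np.int64)
        if len(np.unique(self.genes)) != len(self.genes):
            raise ValueError("genes must be pairwise distinct")

    def sort_key(self) -> tuple[int, ...]:
        """Lexicographic tie-break key (sorted gene tuple)."""
        return tuple(sorted(int(g) for g in self.genes))

    def copy(self) -> "Chromosome":
        return Chromosome(self.genes.copy(), self.fitness)


@dataclass
class GATrace:
    """Per-generation convergence record."""

    generation: list[int] = field(default_factory=list)
    best_fitness: list[float] = field(default_factory=list)
    mean_fitness: list[float] = field(default_factory=list)
    best_genes: list[tuple[int, ...]] = field(default_factory=list)

    def append(self, gen: int, best: Chromosome, population: list[Chromosome]) -> None:
        self.generation.append(gen)
        self.best_fitness.append(float(best.fitness))
        self.mean_fitness.append(float(np.mean([c.fitness for c in population])))
        self.best_genes.append(best.sort_key())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": self.generation,
                "best_fitness": self.best_fitness,
                "mean_fitness": self.mean_fitness,
            }
        )


class SVMFitness:
    """Fitness = linear-SVM accuracy on the gene-indexed columns.

    The table handed to the GA is split once (stratified, seeded) into an
    internal fit/validation partition; every chromosome is scored on the
    same validation rows.  Hand the GA only your *training* data and this
    cannot leak test information; handing it the full dataset reproduces
    the literal published protocol in which fitness is held-out-set
    accuracy.
    """

    def __init__(
        self,
        seed: int = 0,
        train_fraction: float = 0.7,
        C: float = 1.0,
        standardize: bool = True,
        stratified: bool = True,
    ):
        self.spec = SplitSpec(train_fraction, stratified, seed)
        self.C = C
        self.standardize = standardize
        self._split: tuple[np.ndarray, np.ndarray] | None = None
        self._n: int | None = None

    def __call__(self, table: FeatureTable, genes: np.ndarray) -> float:
        if self._split is None or self._n != table.n_samples:
            self._split = split(table.labels, self.spec)
            self._n = table.n_samples
        fit_idx, val_idx = self._split
        sub = table.select(np.asarray(genes))
        model = train_svm(sub, fit_idx, C=self.C, standardize=self.standardize)
        return accuracy(confusion(model, sub, val_idx))


def evaluate_fitness(ch: Chromosome, table: FeatureTable, estimator) -> float:
    """Score a chromosome on exactly its gene-indexed columns."""
    genes = ch.genes
    if genes.min(initial=0) < 0 or genes.max(initial=-1) >= table.n_channels:
        raise ValueError("chromosome genes out of table range")
    try:
        ch.fitness = float(estimator(table, genes))
    except Exception as exc:
        raise RuntimeError(f"fitness estimator failed for genes {ch.sort_key()}") from exc
    return ch.fitness


def init_population(
    config: GAConfig,
    n_channels: int,
    rng: np.random.Generator,
    table: FeatureTable | None = None,
    estimator=None,
) -> list[Chromosome]:
    """Uniform random fixed-size subsets; evaluated if an estimator is given."""
    if config.chromosome_length > n_channels:
        raise ValueError("chromosome_length exceeds number of channels")
    population = [
        Chromosome(rng.choice(n_channels, size=config.chromosome_length, replace=False))
        for _ in range(config.population_size)
    ]
    if estimator is not None and table is not None:
        for ch in population:
            evaluate_fitness(ch, table, estimator)
    return population


def select_parents(
    population: list[Chromosome],
    scheme: str = "fitness_proportionate",
    rng: np.random.Generator | None = None,
    n_pairs: int | None = None,
) -> list[tuple[Chromosome, Chromosome]]:
    """Draw parent pairs with probability proportional to fitness (or rank)."""
    rng = rng if rng is not None else np.random.default_rng()
    if n_pairs is None:
        n_pairs = len(population) // 2
    fits = np.array([c.fitness for c in population], dtype=np.float64)
    if np.any(fits < 0) or np.any(np.isnan(fits)):
        raise ValueError("all fitnesses must be set and non-negative")
    if scheme == "fitness_proportionate":
        probs = fits
    elif scheme == "rank":
        # ascending fitness rank 1..N; ties share the mean rank
        order = np.argsort(fits, kind="stable")
        probs = np.empty(len(fits))
        probs[order] = np.arange(1, len(fits) + 1, dtype=np.float64)
    else:
        raise ValueError(f"unknown selection scheme: {scheme!r}")
    total = probs.sum()
    if total <= 0:
        logger.warning("all-zero selection weights; falling back to uniform sampling")
        probs = np.full(len(population), 1.0 / len(population))
    else:
        probs = probs / total
    picks = rng.choice(len(population), size=(n_pairs, 2), p=probs)
    return [(population[i], population[j]) for i, j in picks]


def _repair(genes: np.ndarray, n_channels: int, rng: np.random.Generator) -> np.ndarray:
    """Replace duplicated genes by uniform draws from the absent indices."""
    seen: set[int] = set()
    dup_pos = []
    for i, g in enumerate(genes):
        if int(g) in seen:
            dup_pos.append(i)
        else:
            seen.add(int(g))
    if not dup_pos:
        return genes
    absent = np.setdiff1d(np.arange(n_channels), genes)
    replacements = rng.choice(absent, size=len(dup_pos), replace=False)
    genes = genes.copy()
    genes[dup_pos] = replacements
    return genes


def uniform_crossover(
    p1: Chromosome,
    p2: Chromosome,
    crossover_rate: float,
    rng: np.random.Generator,
    n_channels: int,
) -> tuple[Chromosome, Chromosome]:
    """Per-gene routing of parental genes to the two children.

    For each position a uniform draw below CR routes p1's gene to child 1
    and p2's to child 2, otherwise the genes are swapped.  Routing distinct
    parents positionwise can duplicate a gene within a child; duplicates
    are repaired by uniform draws from the indices absent from that child,
    preserving the set encoding.
    """
    if len(p1.genes) != len(p2.genes):
        raise ValueError("parents must have equal length")
    draws = rng.random(len(p1.genes))
    keep = draws < crossover_rate
    g1 = np.where(keep, p1.genes, p2.genes)
    g2 = np.where(keep, p2.genes, p1.genes)
    g1 = _repair(g1, n_channels, rng)
    g2 = _repair(g2, n_channels, rng)
    return Chromosome(g1), Chromosome(g2)


def mutate(
    ch: Chromosome,
    mutation_rate: float,
    n_channels: int,
    rng: np.random.Generator,
) -> Chromosome:
    """Replace each gene, with probability MR, by an index absent from the
    chromosome.  When no foreign index exists (full-width chromosome) the
    gene is left unchanged."""
    genes = ch.genes.copy()
    present = set(int(g) for g in genes)
    draws = rng.random(len(genes))
    for i in np.flatnonzero(draws < mutation_rate):
        candidates = np.setdiff1d(np.arange(n_channels), genes)
        if len(candidates) == 0:
            logger.debug("mutation skipped: chromosome spans all channels")
            continue
        new = int(rng.choice(candidates))
        present.discard(int(genes[i]))
        genes[i] = new
        present.add(new)
    return Chromosome(genes)


def _pool_sort_key(ch: Chromosome):
    return (-ch.fitness, ch.sort_key())


def step_generation(
    population: list[Chromosome],
    config: GAConfig,
    table: FeatureTable,
    estimator,
    rng: np.random.Generator,
) -> tuple[list[Chromosome], dict]:
    """One elitist generation: select, cross, mutate, evaluate, truncate.

    The combined parent+offspring pool is truncated to ``population_size``
    by fitness (lexicographic gene order breaks ties), so the best
    chromosome ever seen survives and best fitness is non-decreasing.
    """
    n_channels = table.n_channels
    pairs = select_parents(
        population, config.selection_scheme, rng, n_pairs=(config.population_size + 1) // 2
    )
    offspring: list[Chromosome] = []
    for p1, p2 in pairs:
        for child in uniform_crossover(p1, p2, config.crossover_rate, rng, n_channels):
            if len(offspring) < config.population_size:
                child = mutate(child, config.mutation_rate, n_channels, rng)
                evaluate_fitness(child, table, estimator)
                offspring.append(child)
    pool = sorted(population + offspring, key=_pool_sort_key)
    new_population = pool[:config.population_size]
    record = {
        "best": new_population[0],
        "mean_fitness": float(np.mean([c.fitness for c in new_population])),
    }
    return new_population, record


class _CachedEstimator:
    """Memoize fitness on the sorted gene set (the encoding is a set)."""

    def __init__(self, estimator):
        self.estimator = estimator
        self.cache: dict[tuple[int, ...], float] = {}

    def __call__(self, table: FeatureTable, genes: np.ndarray) -> float:
        key = tuple(sorted(int(g) for g in genes))
        if key not in self.cache:
            self.cache[key] = float(self.estimator(table, genes))
        return self.cache[key]


def run_ga(
    table: FeatureTable,
    config: GAConfig,
    estimator=None,
    initial_population=None,
    callback=None,
) -> tuple[Chromosome, GATrace]:
    """Run the GA to ``max_generations`` (or an optional plateau stop).

    All stochastic stages draw from one seeded generator in a fixed order,
    so a fixed seed replays the run exactly.  Returns the best chromosome
    ever seen and the per-generation trace.

    ``initial_population`` (a list of gene sequences, e.g. a saved
    checkpoint) replaces the random initialisation; ``callback(gen,
    population)``, when given, is invoked after every generation and may
    be used to write checkpoints.
    """
    if config.chromosome_length > table.n_channels:
        raise ValueError("chromosome_length exceeds table width")
    rng = np.random.default_rng(config.seed)
    if estimator is None:
        estimator = SVMFitness(seed=config.seed)
    estimator = _CachedEstimator(estimator)
    if initial_population is not None:
        population = [Chromosome(np.asarray(g)) for g in initial_population]
        if len(population) != config.population_size:
            raise ValueError("checkpoint population size mismatch with config")
        for ch in population:
            evaluate_fitness(ch, table, estimator)
    else:
        population = init_population(config, table.n_channels, rng, table, estimator)
    best = min(population, key=_pool_sort_key).copy()
    trace = GATrace()
    stale = 0
    for gen in range(1, config.max_generations + 1):
        population, record = step_generation(population, config, table, estimator, rng)
        if record["best"].fitness > best.fitness:
            best = record["best"].copy()
            stale = 0
        else:
            stale += 1
        trace.append(gen, best, population)
        if callback is not None:
            callback(gen, population)
        if gen % 10 == 0 or gen == config.max_generations:
            logger.info(
                "generation %d: best %.4f mean %.4f",
                gen, best.fitness, record["mean_fitness"],
            )
        if config.early_stop_patience is not None and stale >= config.early_stop_patience:
            logger.info("plateau stop at generation %d", gen)
            break
    return best, trace


# ---------------------------------------------------------------------------
# model-object surface


class GAFeatureSelector:
    """Wrapper feature-selection model over a channel-mean feature table.

    Parameters
    ----------
    table : FeatureTable
        Channel means + labels.  Hand the *training* partition here to
        keep fitness free of test leakage.
    config : GAConfig, optional
        GA control parameters (published defaults).
    estimator : callable, optional
        Fitness contract ``estimator(table, genes) -> accuracy``; defaults
        to :class:`SVMFitness` seeded from the config.
    """

    def __init__(self, table: FeatureTable, config: GAConfig | None = None, estimator=None):
        self.table = table
        self.config = config if config is not None else GAConfig()
        self.estimator = estimator

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, label_col: str = "label",
        config: GAConfig | None = None, estimator=None,
    ) -> "GAFeatureSelector":
        df = df.copy()
        labels = df.pop(label_col).to_numpy()
        table = FeatureTable(df.to_numpy(dtype=np.float64), labels)
        return cls(table, config, estimator)

    def fit(self) -> "GAFeatureSelectorResults":
        best, trace = run_ga(self.table, self.config, self.estimator)
        return GAFeatureSelectorResults(self, best, trace)


class GAFeatureSelectorResults:
    """Fitted selection results: best chromosome, trace, diagnostics."""

    def __init__(self, model: GAFeatureSelector, best: Chromosome, trace: GATrace):
        self.model = model
        self.best = best
        self.trace = trace

    @property
    def config(self) -> GAConfig:
        return self.model.config

    @property
    def fitness(self) -> float:
        return float(self.best.fitness)

    @property
    def selected_channels(self) -> np.ndarray:
        """Selected original channel ids, 0-based, sorted."""
        return np.sort(self.model.table.channel_ids[self.best.genes])

    @property
    def selected_channels_1based(self) -> np.ndarray:
        return self.selected_channels + 1

    def summary(self) -> str:
        cfg = self.config
        gens = len(self.trace.generation)
        lines = [
            "GA feature selection results",
            "=" * 40,
            f"channels available:   {self.model.table.n_channels}",
            f"channels selected:    {cfg.chromosome_length}",
            f"population size:      {cfg.population_size}",
            f"CR / MR:              {cfg.crossover_rate} / {cfg.mutation_rate}",
            f"generations run:      {gens} (max {cfg.max_generations})",
            f"selection scheme:     {cfg.selection_scheme}",
            f"seed:                 {cfg.seed}",
            f"best fitness (acc):   {self.fitness:.4f}",
            "selected channel ids (1-based): "
            + ", ".join(str(int(c)) for c in self.selected_channels_1based[:20])
            + (" ..." if len(self.best.genes) > 20 else ""),
        ]
        return "\n".join(lines)

    def plot_convergence(self, ax=None):
        """Best/mean fitness per generation (convergence diagnostics)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.trace.to_dataframe()
        ax.plot(df["generation"], df["best_fitness"], label="best")
        ax.plot(df["generation"], df["mean_fitness"], label="mean")
        ax.set_xlabel("generation")
        ax.set_ylabel("fitness (SVM accuracy)")
        ax.legend()
        return ax

    def to_json(self, path, index_base: int = 1) -> None:
        """Serialize the best chromosome with provenance (1-based ids)."""
        payload = {
            "index_base": index_base,
            "channel_ids": [int(c) + index_base for c in self.selected_channels],
            "fitness": self.fitness,
            "config": dataclasses.asdict(self.config),
            "layer": None if self.model.table.layer is None else self.model.table.layer.name,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
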