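"""Keyword-library scoring of free-text diagnoses.

Free-text admission diagnoses are matched against per-module keyword
libraries (one library for the primary diagnosis, one for the other
diagnoses; seven modules each by default).  A patient's diagnostic score is

    F_i = sum_j  delta_j * N_ij

where ``N_ij`` is the number of keyword occurrences for module *j* in the
patient's normalized text and ``delta_j`` is the module weight, constrained
to the box [0, 5].  Module weights are chosen to maximize the population
variance of the score series,

    sigma^2 = (1/n) * sum_i (F_i - mean(F))^2,

the rationale being that a more dispersed score carries more information
about between-patient differences.  Because ``F`` is linear in ``delta``,
the objective is the quadratic form ``delta' C delta`` with ``C`` the
population covariance of the match-count matrix; a genetic algorithm
searches the (by default integer) box, and an exhaustive grid solver is
provided as an exact reference for small module counts.
"""

from __future__ import annotations

import itertools
import json
import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

WEIGHT_MAX = 5.0

__all__ = [
    "KeywordModule",
    "KeywordLibrary",
    "GAConfig",
    "WeightSolution",
    "normalize_text",
    "count_matches",
    "count_matrix",
    "diagnostic_score",
    "score_series",
    "variance_objective",
    "count_covariance",
    "grid_optimum",
    "optimize_weights",
]


@dataclass(frozen=True)
class KeywordModule:
    name: str
    keywords: tuple[str, ...]
    weight: float | None = None

    def __post_init__(self) -> None:
        if not self.keywords:
            raise ValueError(f"module {self.name!r} has an empty keyword list")


@dataclass(frozen=True)
class KeywordLibrary:
    """Ordered collection of diagnosis modules with exclusive keyword lists."""

    category: str
    modules: tuple[KeywordModule, ...]

    def __post_init__(self) -> None:
        names = [m.name for m in self.modules]
        if len(set(names)) != len(names):
            raise ValueError("module names must be unique")

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    @property
    def module_names(self) -> list[str]:
        return [m.name for m in self.modules]

    @property
    def weights(self) -> np.ndarray | None:
        """Configured module weights, or None if any module lacks one."""
        if any(m.weight is None for m in self.modules):
            return None
        return np.array([float(m.weight) for m in self.modules])

    def with_weights(self, weights: Sequence[float]) -> "KeywordLibrary":
        if len(weights) != self.n_modules:
            raise ValueError("weight vector length must equal module count")
        mods = tuple(
            KeywordModule(m.name, m.keywords, float(w))
            for m, w in zip(self.modules, weights)
        )
        return KeywordLibrary(self.category, mods)

    @classmethod
    def from_dict(cls, category: str, entries: Iterable[dict]) -> "KeywordLibrary":
        mods = tuple(
            KeywordModule(
                e["module"],
                tuple(e["keywords"]),
                e.get("weight"),
            )
            for e in entries
        )
        return cls(category, mods)

    @classmethod
    def load(cls, path: str | Path, category: str) -> "KeywordLibrary":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        return cls.from_dict(category, data[category])


def default_libraries() -> dict[str, KeywordLibrary]:
    """The packaged default keyword libraries (primary and other diagnoses)."""
    text = resources.files("traumaprog.data").joinpath("keywords.json").read_text(
        encoding="utf-8"
    )
    data = json.loads(text)
    return {cat: KeywordLibrary.from_dict(cat, data[cat]) for cat in data}


_PUNCT_RE = re.compile(r"[^\w\s]", flags=re.UNICODE)
_WS_RE = re.compile(r"\s+")


def normalize_text(text: str) -> str:
    """Lowercase, NFKC-normalize, strip punctuation, collapse whitespace.

    Matching is codepoint-substring based so non-space-delimited scripts
    (e.g. Chinese diagnosis text) work without tokenization.
    """
    text = unicodedata.normalize("NFKC", text or "").lower()
    text = _PUNCT_RE.sub(" ", text)
    return _WS_RE.sub(" ", text).strip()


def count_matches(text: str, library: KeywordLibrary) -> np.ndarray:
    """Per-module keyword occurrence counts ``N_j`` for one text.

    Every occurrence of every keyword counts; distinct keywords are counted
    independently, so a phrase containing another module's keyword as a
    substring contributes to both modules.  Empty text gives all zeros.
    """
    norm = normalize_text(text)
    counts = np.zeros(library.n_modules, dtype=np.int64)
    if not norm:
        return counts
    for j, module in enumerate(library.modules):
        counts[j] = sum(norm.count(normalize_text(kw)) for kw in module.keywords)
    return counts


def count_matrix(texts: Iterable[str], library: KeywordLibrary) -> np.ndarray:
    """Stack :func:`count_matches` over patients -> (n, J) integer matrix."""
    return np.vstack([count_matches(t, library) for t in texts])


def diagnostic_score(counts: np.ndarray, weights: np.ndarray) -> float:
    """F = sum_j delta_j * N_j for a single patient row."""
    counts = np.asarray(counts, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if counts.shape != weights.shape:
        raise ValueError("counts and weights must share module ordering/length")
    return float(counts @ weights)


def score_series(counts: np.ndarray, weights: np.ndarray) -> np.ndarray:
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    weights = np.asarray(weights, dtype=float)
    if counts.shape[1] != weights.shape[0]:
        raise ValueError("counts and weights must share module ordering/length")
    return counts @ weights


def variance_objective(scores: Sequence[float]) -> float:
    """Population variance (divisor n) of the score series."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score series")
    return float(np.var(scores))  # ddof=0


def count_covariance(counts: np.ndarray) -> np.ndarray:
    """Population covariance C of the count matrix; sigma^2(w) = w' C w."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2:
        raise ValueError("need a 2-D count matrix with at least 2 patients")
    centered = counts - counts.mean(axis=0)
    return centered.T @ centered / counts.shape[0]


@dataclass
class GAConfig:
    """Genetic-algorithm settings for the weight search.

    Defaults: population 60, 100 generations, uniform crossover at rate 0.8,
    per-gene mutation 0.1, elitism 2, tournament selection of size 3.
    ``encoding`` is ``"integer"`` (genes in {0..5}; matches the reported
    integer weight tables and admits an exhaustive reference solution) or
    ``"continuous"`` (genes in [0, 5]).
    """

    population: int = 60
    generations: int = 100
    crossover_rate: float = 0.8
    mutation_rate: float = 0.1
    elitism: int = 2
    tournament: int = 3
    encoding: str = "integer"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be at least 2")
        for r in (self.crossover_rate, self.mutation_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.encoding not in ("integer", "continuous"):
            raise ValueError("encoding must be 'integer' or 'continuous'")


@dataclass
class WeightSolution:
    weights: np.ndarray
    objective: float
    degenerate: bool = False
    history: list[float] = field(default_factory=list)  # best objective per generation


def _objective_batch(pop: np.ndarray, cov: np.ndarray) -> np.ndarray:
    return np.einsum("ij,jk,ik->i", pop, cov, pop)


def grid_optimum(
    counts: np.ndarray, weight_max: int = 5
) -> tuple[np.ndarray, float]:
    """Exact maximizer of the variance objective over the integer grid.

    Enumerates all (weight_max+1)^J integer weight vectors via the quadratic
    form; feasible up to J=7 (6^7 = 279,936 candidates).  Ties are broken by
    the lexicographically smallest vector.
    """
    cov = count_covariance(counts)
    J = cov.shape[0]
    if (weight_max + 1) ** J > 2_000_000:
        raise ValueError("grid too large; use the GA instead")
    grid = np.array(
        list(itertools.product(range(weight_max + 1), repeat=J)), dtype=float
    )
    vals = _objective_batch(grid, cov)
    best = np.max(vals)
    # itertools.product emits rows in lexicographic order, so the first
    # argmax within tolerance is the lexicographically smallest optimum.
    idx = int(np.flatnonzero(vals >= best - 1e-12)[0])
    return grid[idx].copy(), float(vals[idx])


def optimize_weights(
    counts: np.ndarray,
    config: GAConfig | None = None,
) -> WeightSolution:
    """Genetic-algorithm search for the variance-maximizing module weights.

    Returns the best weight vector visited and its objective.  An
    all-constant count matrix makes the objective identically zero; the
    result is then flagged ``degenerate`` and the zero vector returned.
    """
    config = config or GAConfig()
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2:
        raise ValueError("need at least 2 patients")
    cov = count_covariance(counts)
    J = cov.shape[0]
    if not np.any(np.abs(cov) > 1e-12):
        return WeightSolution(np.zeros(J), 0.0, degenerate=True)

    rng = np.random.default_rng(config.seed)
    integer = config.encoding == "integer"
    if integer:
        pop = rng.integers(0, 6, size=(config.population, J)).astype(float)
    else:
        pop = rng.uniform(0.0, WEIGHT_MAX, size=(config.population, J))

    best_w: np.ndarray | None = None
    best_f = -np.inf
    history: list[float] = []

    def consider(cand: np.ndarray, val: float) -> None:
        nonlocal best_w, best_f
        if val > best_f + 1e-12:
            best_f, best_w = val, cand.copy()
        elif abs(val - best_f) <= 1e-12 and best_w is not None:
            # deterministic reporting: lexicographically smallest optimum
            if tuple(cand) < tuple(best_w):
                best_w = cand.copy()

    for _ in range(config.generations):
        fitness = _objective_batch(pop, cov)
        order = np.argsort(-fitness)
        for i in order[: max(config.elitism, 1)]:
            consider(pop[i], float(fitness[i]))
        history.append(best_f)

        elite = pop[order[: config.elitism]].copy()
        # tournament selection
        n_off = config.population - config.elitism
        draws = rng.integers(0, config.population, size=(n_off, config.tournament))
        winners = draws[np.arange(n_off), np.argmax(fitness[draws], axis=1)]
        offspring = pop[winners].copy()
        # uniform crossover on consecutive pairs
        for i in range(0, n_off - 1, 2):
            if rng.random() < config.crossover_rate:
                mask = rng.random(J) < 0.5
                a, b = offspring[i].copy(), offspring[i + 1].copy()
                offspring[i, mask], offspring[i + 1, mask] = b[mask], a[mask]
        # mutation
        mut = rng.random(offspring.shape) < config.mutation_rate
        if integer:
            offspring[mut] = rng.integers(0, 6, size=int(mut.sum())).astype(float)
        else:
            offspring[mut] = np.clip(
                offspring[mut] + rng.normal(0.0, 1.0, size=int(mut.sum())),
                0.0,
                WEIGHT_MAX,
            )
        pop = np.vstack([elite, offspring])

    fitness = _objective_batch(pop, cov)
    for i in np.argsort(-fitness)[: max(config.elitism, 1)]:
        consider(pop[i], float(fitness[i]))

    assert best_w is not None
    return WeightSolution(best_w, best_f, degenerate=False, history=history)
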