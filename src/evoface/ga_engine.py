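"""Generational evolution of expression vectors.

One session mirrors the interactive procedure: an initialization trial shows
10 procedurally generated expressions; on every trial the observer selects
the candidates resembling the target emotion and flags the single best match;
the next generation is bred from the selections by uniform crossover and
Gaussian mutation, with the best match preserved unchanged (elitism).  After
``n_generations`` evolved generations the observer picks one face — the
*preferred expression*.  Trial numbering: trial 1 is initialization
(generation index 0), so the final pick happens on trial ``n_generations + 1``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .blendspace import N_CORE, cosine_distance, pairwise_cd, random_expression

SESSION_FORMAT_VERSION = 1


@dataclass
class GAConfig:
    population_size: int = 10
    n_generations: int = 10
    mutation_prob: float = 0.6
    mutation_sd: float = 0.35  # weight-fraction units, at generation 0
    mutation_decay: float = 0.8  # geometric per-generation shrink of the sd
    crossover: str = "uniform"  # "uniform" | "none"
    elitism: bool = True
    activation_prob: float = 0.3  # initialization sparsity
    magnitude_law: str = "uniform"
    seed: int | None = None

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if not (0.0 <= self.mutation_prob <= 1.0):
            raise ValueError("mutation_prob must be in [0, 1]")
        if self.mutation_sd < 0:
            raise ValueError("mutation_sd must be >= 0")
        if not (0.0 < self.mutation_decay <= 1.0):
            raise ValueError("mutation_decay must be in (0, 1]")
        if self.crossover not in ("uniform", "blend", "none"):
            raise ValueError(f"unknown crossover operator {self.crossover!r}")


@dataclass
class Generation:
    """One trial's candidate set plus the observer's selections."""

    index: int
    candidates: np.ndarray  # (population_size, N_CORE)
    selected: list[int] | None = None
    best_index: int | None = None

    def __post_init__(self):
        self.candidates = np.asarray(self.candidates, dtype=float)
        if self.candidates.ndim != 2 or self.candidates.shape[1] != N_CORE:
            raise ValueError(f"candidates must be (pop, {N_CORE})")
        if self.selected is not None:
            if len(self.selected) == 0:
                raise ValueError("selected set must be nonempty once recorded")
            if self.best_index is not None and self.best_index not in self.selected:
                raise ValueError("best_index must be one of the selected candidates")


@dataclass
class GASession:
    """Full record of one evolution, initialization through final choice."""

    config: GAConfig
    generations: list[Generation]
    preferred: np.ndarray
    seed: int | None = None

    def __post_init__(self):
        self.preferred = np.asarray(self.preferred, dtype=float)


def init_population(config: GAConfig, rng: np.random.Generator) -> Generation:
    """Initialization trial: 10 procedurally generated expressions."""
    candidates = np.stack(
        [
            random_expression(rng, config.activation_prob, config.magnitude_law)
            for _ in range(config.population_size)
        ]
    )
    return Generation(index=0, candidates=candidates)


def next_generation(
    current: Generation, config: GAConfig, rng: np.random.Generator
) -> Generation:
    """Breed the next candidate set from the current selections.

    Slot 0 carries the flagged best match unchanged when elitism is on; the
    remaining slots take two parents drawn uniformly with replacement from
    the selected candidates, combined by per-unit uniform crossover and then
    mutated: each core weight is perturbed with probability ``mutation_prob``
    by Gaussian noise and clipped to [0, 1].  The mutation sd anneals
    geometrically, ``mutation_sd * mutation_decay**generation``, so early
    generations explore broadly and late ones refine — matching the rapid
    early convergence and constant late-trial variance the procedure shows.
    """
    if not current.selected:
        raise ValueError(
            "no candidates selected on the previous trial; select at least one "
            "before breeding the next generation"
        )
    pool = current.candidates[np.asarray(current.selected, dtype=int)]
    n_pool = pool.shape[0]
    pop = config.population_size

    offspring = np.empty((pop, N_CORE))
    start = 0
    if config.elitism:
        offspring[0] = current.candidates[current.best_index]
        start = 1
    n_children = pop - start

    parent_idx = rng.integers(0, n_pool, size=(n_children, 2))
    p1 = pool[parent_idx[:, 0]]
    p2 = pool[parent_idx[:, 1]]
    if n_pool == 1 or config.crossover == "none":
        children = p1.copy()  # single-parent case degenerates to mutate-clone
    elif config.crossover == "uniform":
        take_p1 = rng.random((n_children, N_CORE)) < 0.5
        children = np.where(take_p1, p1, p2)
    else:  # blend: per-child convex combination of the two parents
        alpha = rng.random((n_children, 1))
        children = alpha * p1 + (1.0 - alpha) * p2

    sd = config.mutation_sd * config.mutation_decay**current.index
    mutate = rng.random((n_children, N_CORE)) < config.mutation_prob
    noise = rng.normal(0.0, sd, size=(n_children, N_CORE))
    children = np.clip(children + mutate * noise, 0.0, 1.0)
    offspring[start:] = children
    return Generation(index=current.index + 1, candidates=offspring)


def run_session(observer, config: GAConfig, rng: np.random.Generator | None = None) -> GASession:
    """Run a full evolution: initialization, ``n_generations`` evolved trials,
    and the final single choice stored as the preferred expression."""
    from .observers import observe  # local import to avoid a cycle

    seed = config.seed
    if rng is None:
        rng = np.random.default_rng(seed)
    generations: list[Generation] = []
    gen = init_population(config, rng)
    for _ in range(config.n_generations):
        selected, best = observe(observer, gen.candidates, rng)
        gen = replace(gen, selected=selected, best_index=best)
        generations.append(gen)
        gen = next_generation(gen, config, rng)
    # final trial: a single preferred face
    _, best = observe(observer, gen.candidates, rng)
    gen = replace(gen, selected=[best], best_index=best)
    generations.append(gen)
    return GASession(
        config=config, generations=generations, preferred=gen.candidates[best], seed=seed
    )


# ---------------------------------------------------------------------------
# convergence diagnostics


def convergence_profile(session: GASession, target=None) -> pd.DataFrame:
    """Per-generation dispersion of the selected candidates.

    Columns: ``generation``, ``n_selected``, ``selected_dispersion`` (mean
    pairwise cosine distance among that trial's selected candidates; 0 with
    ``single_selection=True`` when only one face was picked) and, if a target
    is given, ``mean_cd_to_target``.
    """
    if len(session.generations) < 2:
        raise ValueError("need a session with at least 2 generations")
    records = []
    for gen in session.generations:
        if not gen.selected:
            raise ValueError(f"generation {gen.index} has no recorded selections")
        chosen = gen.candidates[np.asarray(gen.selected, dtype=int)]
        single = chosen.shape[0] < 2
        dispersion = 0.0 if single else float(np.mean(pairwise_cd(chosen)))
        rec = {
            "generation": gen.index,
            "n_selected": chosen.shape[0],
            "selected_dispersion": dispersion,
            "single_selection": single,
        }
        if target is not None:
            rec["mean_cd_to_target"] = float(
                np.mean([cosine_distance(c, target) for c in chosen])
            )
        records.append(rec)
    return pd.DataFrame.from_records(records)


def plateau_generation(
    profile: pd.DataFrame,
    tolerance: float = 0.05,
    rel_to: str = "scale",
    exclude_single: bool = True,
) -> int:
    """First generation after which the selected-candidate dispersion is flat.

    Flat means the change between every later pair of consecutive generations
    stays below ``tolerance``, expressed relative to the profile's overall
    scale (its maximum dispersion; ``rel_to="previous"`` divides by the
    preceding value instead, which is noisier near the converged floor).
    Single-selection trials carry no within-trial dispersion (their flagged
    zeros are not evidence of convergence) and are excluded by default.
    """
    if exclude_single and "single_selection" in profile:
        profile = profile[~profile["single_selection"]]
    d = profile["selected_dispersion"].to_numpy(dtype=float)
    if len(d) < 2:
        return 0
    if rel_to == "scale":
        denom = np.full(len(d) - 1, max(d.max(), np.finfo(float).tiny))
    elif rel_to == "previous":
        denom = np.maximum(d[:-1], np.finfo(float).tiny)
    else:
        raise ValueError(f"unknown rel_to {rel_to!r}")
    rel_change = np.abs(np.diff(d)) / denom
    below = rel_change < tolerance
    # first index g with all subsequent consecutive changes below tolerance
    for g in range(len(d)):
        if below[g:].all():
            return g
    return len(d) - 1


# ---------------------------------------------------------------------------
# session logs (lossless JSON round trip)


def session_to_json(session: GASession) -> str:
    payload = {
        "format_version": SESSION_FORMAT_VERSION,
        "config": asdict(session.config),
        "seed": session.seed,
        "generations": [
            {
                "index": g.index,
                "candidates": g.candidates.tolist(),
                "selected": g.selected,
                "best_index": g.best_index,
            }
            for g in session.generations
        ],
        "preferred": session.preferred.tolist(),
    }
    return json.dumps(payload, indent=1)


def session_from_json(text: str) -> GASession:
    payload = json.loads(text)
    if payload.get("format_version") != SESSION_FORMAT_VERSION:
        raise ValueError(f"unsupported session format: {payload.get('format_version')}")
    config = GAConfig(**payload["config"])
    generations = [
        Generation(
            index=g["index"],
            candidates=np.asarray(g["candidates"], dtype=float),
            selected=g["selected"],
            best_index=g["best_index"],
        )
        for g in payload["generations"]
    ]
    return GASession(
        config=config,
        generations=generations,
        preferred=np.asarray(payload["preferred"], dtype=float),
        seed=payload.get("seed"),
    )
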