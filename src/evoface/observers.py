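"""Simulated participants and synthetic-cohort generation.

An observer holds a latent target expression and selects, on each trial, the
candidates scoring highest on ``-CD(candidate, target) + Gaussian noise``.
A cohort is built by jittering per-emotion category means to obtain each
simulated participant's latent targets, then running one full evolution per
(participant, emotion) cell and keeping the preferred expressions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .blendspace import EMOTIONS, N_CORE, as_core_vector, cross_cd
from .dataio import CohortDataset, cohort_from_arrays, default_category_means
from .ga_engine import GAConfig, run_session


@dataclass
class ObserverModel:
    """Latent target + selection rule + decision noise.

    ``selection_rule`` is ``"top_k"`` (pick the k best-scoring candidates,
    default k=3) or ``"threshold"`` (pick every candidate whose score exceeds
    ``-cd_threshold``; falls back to the single best when none does).
    ``decision_noise_sd`` perturbs the distance-based score of every
    candidate independently on each trial.
    """

    target: np.ndarray
    selection_rule: str = "top_k"
    k: int = 3
    cd_threshold: float = 0.3
    decision_noise_sd: float = 0.02

    def __post_init__(self):
        self.target = as_core_vector(self.target, "observer target")
        if self.target.max() == 0.0:
            raise ValueError("observer target must be a nonzero expression")
        if self.selection_rule not in ("top_k", "threshold"):
            raise ValueError(f"unknown selection rule {self.selection_rule!r}")
        if not (1 <= self.k <= 10):
            raise ValueError("k must be in [1, 10]")
        if self.decision_noise_sd < 0:
            raise ValueError("decision_noise_sd must be >= 0")


def observe(
    observer: ObserverModel, candidates, rng: np.random.Generator
) -> tuple[list[int], int]:
    """Selected candidate indices and the flagged best match.

    Scores are ``-CD(candidate, target)`` plus Gaussian decision noise; the
    best match is the top-scoring selected candidate.  At least one candidate
    is always selected.
    """
    candidates = np.asarray(candidates, dtype=float)
    # zero candidates (possible on a sparse initialization) are maximally
    # distant by convention: nothing about the target is expressed
    norms = np.linalg.norm(candidates, axis=1)
    cds = np.ones(candidates.shape[0])
    nz = norms > 0
    if nz.any():
        cds[nz] = cross_cd(candidates[nz], observer.target[None, :])[:, 0]
    scores = -cds
    if observer.decision_noise_sd > 0:
        scores = scores + rng.normal(0.0, observer.decision_noise_sd, size=scores.shape)
    order = np.argsort(-scores, kind="stable")
    if observer.selection_rule == "top_k":
        chosen = order[: min(observer.k, len(order))]
    else:
        chosen = np.flatnonzero(scores >= -observer.cd_threshold)
        if chosen.size == 0:
            chosen = order[:1]
    best = int(max(chosen, key=lambda i: (scores[i], -i)))
    return sorted(int(i) for i in chosen), best


@dataclass
class CohortSpec:
    """Recipe for a synthetic cohort: participants x four emotions.

    Latent targets are drawn per participant as
    ``clip(category_mean + N(0, between_subject_sd), 0, 1)``; the observer
    defaults apply to every simulated participant.
    """

    n_participants: int = 24
    between_subject_sd: float = 0.15
    category_means: dict[str, np.ndarray] | None = None
    selection_rule: str = "top_k"
    k: int = 3
    decision_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if self.between_subject_sd < 0:
            raise ValueError("between_subject_sd must be >= 0")

    def resolved_means(self) -> dict[str, np.ndarray]:
        means = self.category_means or default_category_means()
        missing = set(EMOTIONS) - set(means)
        if missing:
            raise ValueError(f"category means missing emotions: {sorted(missing)}")
        return {e: as_core_vector(means[e], f"{e} category mean") for e in EMOTIONS}


def make_observer(spec: CohortSpec, target: np.ndarray) -> ObserverModel:
    return ObserverModel(
        target=target,
        selection_rule=spec.selection_rule,
        k=spec.k,
        decision_noise_sd=spec.decision_noise_sd,
    )


def generate_cohort(
    spec: CohortSpec, config: GAConfig | None = None, rng: np.random.Generator | None = None
) -> CohortDataset:
    """Simulate one preferred expression per (participant, emotion) cell."""
    if config is None:
        config = GAConfig()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    means = spec.resolved_means()
    ids, emotions, rows, targets = [], [], [], []
    for i in range(spec.n_participants):
        pid = f"p{i + 1:03d}"
        for emotion in EMOTIONS:
            target = np.clip(
                means[emotion] + rng.normal(0.0, spec.between_subject_sd, N_CORE),
                0.0,
                1.0,
            )
            if target.max() == 0.0:  # pathological jitter; keep the mean
                target = means[emotion].copy()
            observer = make_observer(spec, target)
            session = run_session(observer, config, rng)
            ids.append(pid)
            emotions.append(emotion)
            rows.append(session.preferred)
            targets.append(target)
    meta = {
        "n_participants": spec.n_participants,
        "between_subject_sd": spec.between_subject_sd,
        "selection_rule": spec.selection_rule,
        "k": spec.k,
        "decision_noise_sd": spec.decision_noise_sd,
        "seed": spec.seed,
        "latent_targets": np.asarray(targets),
    }
    return cohort_from_arrays(ids, emotions, np.asarray(rows), meta=meta)
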