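"""Stochastic-noise thresholds for the evolutionary procedure.

Two evolved expressions can differ even when both observers aimed at exactly
the same target, because initialization, crossover, mutation and selection
noise are all stochastic.  Repeatedly evolving toward a fixed target (the
category centroid) yields a null distribution of pairwise cosine distances;
its mean is the *noise threshold* for that emotion.  The exceedance fraction
— the share of observed between-participant distances above the threshold —
quantifies how much of the observed heterogeneity the algorithm itself
cannot explain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .blendspace import EMOTIONS, pairwise_cd
from .dataio import CohortDataset
from .ga_engine import GAConfig, run_session
from .observers import ObserverModel


@dataclass
class NoiseDistribution:
    """Null distribution of pairwise CDs among same-target evolutions."""

    emotion: str
    final_expressions: np.ndarray  # (n_iter, N_CORE)
    cds: np.ndarray  # n_iter*(n_iter-1)/2 pairwise distances
    threshold: float
    threshold_rule: str = "mean"

    def __post_init__(self):
        if self.cds.size and not (
            self.cds.min() - 1e-12 <= self.threshold <= self.cds.max() + 1e-12
        ):
            raise ValueError("threshold must lie within the simulated CD range")


def simulate_noise(
    target,
    n_iter: int,
    config: GAConfig | None = None,
    observer_kwargs: dict | None = None,
    rng: np.random.Generator | None = None,
    emotion: str = "",
    threshold_rule: str = "mean",
) -> NoiseDistribution:
    """Evolve ``n_iter`` independent sessions toward one fixed target.

    ``threshold_rule``: ``"mean"`` (default) takes the arithmetic mean of the
    pairwise CDs; ``"p<q>"`` (e.g. ``"p95"``) takes that percentile.
    """
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    if config is None:
        config = GAConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    observer = ObserverModel(target=np.asarray(target, dtype=float), **(observer_kwargs or {}))
    finals = np.stack(
        [run_session(observer, config, rng).preferred for _ in range(n_iter)]
    )
    cds = pairwise_cd(finals)
    if threshold_rule == "mean":
        threshold = float(cds.mean())
    elif threshold_rule.startswith("p"):
        threshold = float(np.percentile(cds, float(threshold_rule[1:])))
    else:
        raise ValueError(f"unknown threshold rule {threshold_rule!r}")
    return NoiseDistribution(
        emotion=emotion,
        final_expressions=finals,
        cds=cds,
        threshold=threshold,
        threshold_rule=threshold_rule,
    )


def exceedance(observed_cds, threshold: float) -> float:
    """Fraction of observed CDs strictly greater than the threshold."""
    observed = np.asarray(observed_cds, dtype=float)
    if observed.size == 0:
        raise ValueError("observed_cds must be nonempty")
    return float(np.mean(observed > threshold))


def simulate_noise_by_emotion(
    cohort: CohortDataset,
    n_iter: int = 500,
    config: GAConfig | None = None,
    observer_kwargs: dict | None = None,
    rng: np.random.Generator | None = None,
    threshold_rule: str = "mean",
) -> dict[str, NoiseDistribution]:
    """One noise distribution per emotion, targeting the cohort's centroids.

    The fixed targets are the per-emotion mean expressions of the cohort
    under test, so the null mimics every observer aiming at the category
    average.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    out = {}
    for emotion in cohort.emotions:
        out[emotion] = simulate_noise(
            cohort.mean_expression(emotion),
            n_iter,
            config=config,
            observer_kwargs=observer_kwargs,
            rng=rng,
            emotion=emotion,
            threshold_rule=threshold_rule,
        )
    return out


def exceedance_report(
    cohort: CohortDataset, noise: dict[str, NoiseDistribution]
) -> dict:
    """Per-emotion and pooled exceedance of observed pairwise CDs.

    Each emotion's observed distances are compared against that emotion's own
    threshold; the pooled value counts every observed distance against its
    emotion's threshold.
    """
    per_emotion: dict[str, dict] = {}
    above = 0
    total = 0
    for emotion in cohort.emotions:
        if emotion not in noise:
            raise KeyError(f"no noise distribution for emotion {emotion!r}")
        mat = cohort.matrix(emotion)
        if mat.shape[0] < 2:
            raise ValueError(f"need >= 2 participants for emotion {emotion!r}")
        observed = pairwise_cd(mat)
        thr = noise[emotion].threshold
        per_emotion[emotion] = {
            "threshold": thr,
            "exceedance": exceedance(observed, thr),
            "n_pairs": int(observed.size),
            "observed_cds": observed,
        }
        above += int(np.sum(observed > thr))
        total += int(observed.size)
    return {
        "per_emotion": per_emotion,
        "pooled_exceedance": above / total,
        "n_pairs_total": total,
    }
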