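"""End-to-end pipeline: cohort simulation through recognition analysis.

Stages run in a fixed order — generate cohort, noise thresholds, category
structure (PCA + GMM + fingerprints + SVM), recognition simulation with the
permutation test — each seeded from the global seed and its stage label.
All tables are written under ``out_dir`` with the config hash and seed as
provenance; ``summary.json`` collects the headline numbers.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np

from . import category_stats, noise_sim, recognition
from .config import RunConfig, rng_for
from .dataio import CohortDataset
from .observers import CohortSpec, generate_cohort

log = logging.getLogger("evoface")


def run_pipeline(config: RunConfig) -> dict:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    provenance = {"config_hash": config.hash(), "seed": config.seed}
    summary: dict = {"provenance": provenance, "stages": []}
    stage = "setup"
    try:
        # -- cohort ------------------------------------------------------
        stage = "generate_cohort"
        cohort = generate_cohort(
            config.cohort, config.ga, rng_for(config.seed, "generate_cohort")
        )
        cohort.to_csv(out_dir / "cohort.csv", provenance)
        summary["stages"].append(stage)
        summary["cohort"] = {
            "n_participants": config.cohort.n_participants,
            "n_expressions": len(cohort),
        }

        # -- noise thresholds and exceedance ------------------------------
        stage = "noise_sim"
        noise = noise_sim.simulate_noise_by_emotion(
            cohort,
            n_iter=config.analysis.n_iter,
            config=config.ga,
            observer_kwargs={
                "selection_rule": config.cohort.selection_rule,
                "k": config.cohort.k,
                "decision_noise_sd": config.cohort.decision_noise_sd,
            },
            rng=rng_for(config.seed, "noise_sim"),
        )
        report = noise_sim.exceedance_report(cohort, noise)
        noise_out = {
            "pooled_exceedance": report["pooled_exceedance"],
            "per_emotion": {
                e: {"threshold": r["threshold"], "exceedance": r["exceedance"],
                    "n_pairs": r["n_pairs"]}
                for e, r in report["per_emotion"].items()
            },
        }
        _write_json(out_dir / "noise_report.json", noise_out, provenance)
        summary["stages"].append(stage)
        summary["noise"] = noise_out

        # -- category structure -------------------------------------------
        stage = "category_stats"
        pca = category_stats.run_pca(cohort, n_components=config.analysis.pcs)
        gmm = category_stats.fit_gmm_confusion(
            pca.scores,
            cohort.labels(),
            k=config.analysis.k_clusters,
            seed=int(rng_for(config.seed, "gmm").integers(2**31)),
        )
        with open(out_dir / "confusion.csv", "w", encoding="utf-8") as fh:
            for key, val in provenance.items():
                fh.write(f"# {key}={val}\n")
            gmm.confusion.to_csv(fh)
        fps = category_stats.fingerprint_table(cohort)
        with open(out_dir / "fingerprints.csv", "w", encoding="utf-8") as fh:
            for key, val in provenance.items():
                fh.write(f"# {key}={val}\n")
            fps.to_csv(fh, index=False)
        svm = category_stats.svm_category_cv(
            cohort,
            folds=config.analysis.svm_folds,
            seed=int(rng_for(config.seed, "svm").integers(2**31)),
        )
        _write_json(out_dir / "svm.json", svm, provenance)
        summary["stages"].append(stage)
        summary["category"] = {
            "pca_variance_fraction": pca.variance_fraction.tolist(),
            "gmm_diagonal": np.diag(gmm.confusion.to_numpy()).tolist(),
            "svm_overall": svm["overall"],
        }

        # -- recognition ---------------------------------------------------
        stage = "recognition"
        perceiver_spec = dataclasses.replace(
            config.cohort,
            n_participants=config.analysis.n_perceivers,
            seed=config.seed + 1,
        )
        perceivers = generate_cohort(
            perceiver_spec, config.ga, rng_for(config.seed, "perceiver_cohort")
        )
        trials = recognition.simulate_recognition(
            cohort,
            perceivers,
            temperature=config.analysis.recognition_temperature,
            rng=rng_for(config.seed, "recognition_sim"),
        )
        with open(out_dir / "trials.csv", "w", encoding="utf-8") as fh:
            for key, val in provenance.items():
                fh.write(f"# {key}={val}\n")
            trials.to_csv(fh, index=False)
        perm = recognition.permutation_test(
            trials,
            cohort,
            perceivers,
            n_perm=config.analysis.n_perm,
            n_bins=config.analysis.n_bins,
            rng=rng_for(config.seed, "permutation_test"),
        )
        perm_out = {
            "observed": perm["observed"].tolist(),
            "null_mean": perm["null_mean"].tolist(),
            "null_sd": perm["null_sd"].tolist(),
            "p_values": perm["p_values"].tolist(),
            "sidedness": perm["sidedness"],
            "n_perm": perm["n_perm"],
        }
        _write_json(out_dir / "permtest.json", perm_out, provenance)
        summary["stages"].append(stage)
        summary["recognition"] = perm_out
    except Exception as exc:
        summary["failed_stage"] = stage
        summary["error"] = str(exc)
        _write_json(out_dir / "summary.json", summary, provenance)
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    _write_json(out_dir / "summary.json", summary, provenance)
    log.info("pipeline complete: %s", out_dir / "summary.json")
    return summary


def _write_json(path: Path, payload: dict, provenance: dict) -> None:
    body = dict(payload)
    body.setdefault("provenance", provenance)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(body, fh, indent=1, sort_keys=True)
        fh.write("\n")
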