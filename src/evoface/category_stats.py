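"""Category structure of a cohort of preferred expressions.

PCA embeds the expressions; a four-component Gaussian mixture on the leading
principal components tests whether the emotion categories form separable,
normally distributed clusters (summarized by a confusion matrix against the
true labels); per-emotion blendshape fingerprints rank the most activated
and most variable core units with their FACS action-unit labels; and a
cross-validated SVM measures how predictable the targeted emotion is from
the evolved weights alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from .blendspace import EMOTIONS, CoreMap, au_label, default_au_table, default_core_map
from .dataio import CohortDataset


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAResult:
    loadings: np.ndarray  # components x dims
    scores: np.ndarray  # expressions x components
    variance_fraction: np.ndarray
    mean: np.ndarray
    standardized: bool = False
    rank_deficient: bool = False


def run_pca(
    cohort: CohortDataset,
    n_components: int = 10,
    representation: str = "rig",
    core_map: CoreMap | None = None,
    standardize: bool = False,
) -> PCAResult:
    """Centered PCA of the cohort's expressions.

    Weights all share the same [0, 1] activation unit, so dimensions are not
    variance-scaled by default (``standardize=True`` switches to correlation
    mode).  ``representation="rig"`` expands core weights through the
    coupling map to the 149-dim rig first; ``"core"`` stays in the 46-dim
    independent space.  If the data have lower rank than requested, as many
    components as the rank are returned and the result is flagged.
    """
    mat = cohort.matrix()
    if representation == "rig" and cohort.representation == "core":
        cmap = core_map or default_core_map()
        mat = np.clip(mat @ cmap.coupling.T, 0.0, 1.0)
    if mat.shape[0] <= n_components:
        raise ValueError(
            f"need more expressions ({mat.shape[0]}) than components ({n_components})"
        )
    if standardize:
        sd = mat.std(axis=0, ddof=0)
        mat = (mat - mat.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    rank = int(np.linalg.matrix_rank(mat - mat.mean(axis=0)))
    k = min(n_components, rank)
    rank_deficient = k < n_components
    if rank_deficient:
        warnings.warn(
            f"data rank {rank} < requested {n_components} components; returning {k}",
            stacklevel=2,
        )
    pca = PCA(n_components=k)
    scores = pca.fit_transform(mat)
    return PCAResult(
        loadings=pca.components_,
        scores=scores,
        variance_fraction=pca.explained_variance_ratio_,
        mean=pca.mean_,
        standardized=standardize,
        rank_deficient=rank_deficient,
    )


# ---------------------------------------------------------------------------
# Gaussian mixture + confusion matrix


@dataclass
class ClusterResult:
    assignments: np.ndarray  # per-expression emotion label via the cluster map
    posteriors: np.ndarray  # expressions x k
    cluster_to_emotion: dict[int, str]
    confusion: pd.DataFrame  # rows true emotion, columns assigned emotion
    regularized: bool = False


def fit_gmm_confusion(
    scores: np.ndarray,
    labels,
    k: int = 4,
    seed: int = 0,
    n_init: int = 10,
    reg_covar: float = 1e-6,
) -> ClusterResult:
    """Fit a k-component full-covariance Gaussian mixture and score it
    against the true emotion labels.

    Clusters are mapped to emotions by the bipartite matching that maximizes
    the total diagonal count, keeping the mapping a bijection even when one
    cluster absorbs two labels.  Confusion row e, column f is the fraction of
    expressions truly labeled e that fall in the cluster mapped to f.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape[0] < k:
        raise ValueError(f"need at least {k} expressions")
    present = [e for e in EMOTIONS if e in set(labels)]
    if len(present) < len(EMOTIONS):
        raise ValueError(f"all four emotions must be present, got {present}")

    regularized = False
    try:
        gmm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=n_init,
            random_state=seed,
            reg_covar=reg_covar,
        ).fit(scores)
    except Exception:
        regularized = True
        gmm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=n_init,
            random_state=seed,
            reg_covar=1e-3,
        ).fit(scores)
    if not np.all(np.isfinite(gmm.covariances_)):
        regularized = True

    hard = gmm.predict(scores)
    posteriors = gmm.predict_proba(scores)

    counts = np.zeros((len(EMOTIONS), k))
    for e_idx, emotion in enumerate(EMOTIONS):
        mask = labels == emotion
        for c in range(k):
            counts[e_idx, c] = np.sum(hard[mask] == c)
    rows, cols = linear_sum_assignment(-counts)
    cluster_to_emotion = {int(c): EMOTIONS[r] for r, c in zip(rows, cols)}
    # clusters left unmatched (k > 4) keep a placeholder label
    for c in range(k):
        cluster_to_emotion.setdefault(c, f"cluster_{c}")

    confusion = np.zeros((len(EMOTIONS), len(EMOTIONS)))
    emo_col = {e: j for j, e in enumerate(EMOTIONS)}
    for e_idx, emotion in enumerate(EMOTIONS):
        mask = labels == emotion
        n = int(mask.sum())
        for c in range(k):
            mapped = cluster_to_emotion[c]
            if mapped in emo_col:
                confusion[e_idx, emo_col[mapped]] += np.sum(hard[mask] == c) / n
    confusion_df = pd.DataFrame(confusion, index=list(EMOTIONS), columns=list(EMOTIONS))
    assignments = np.array([cluster_to_emotion[int(c)] for c in hard])
    return ClusterResult(
        assignments=assignments,
        posteriors=posteriors,
        cluster_to_emotion=cluster_to_emotion,
        confusion=confusion_df,
        regularized=regularized,
    )


# ---------------------------------------------------------------------------
# blendshape fingerprints


@dataclass
class Fingerprint:
    """Per-emotion profile of mean and SD core-blendshape weights."""

    emotion: str
    mean_weights: np.ndarray
    sd_weights: np.ndarray
    top_peaks: list[tuple[int, str, int, float]]  # (core, facs_name, au, mean)
    top_variable: list[tuple[int, str, int, float]]  # (core, facs_name, au, sd)
    mean_sd: float


def fingerprint(
    cohort: CohortDataset,
    emotion: str,
    au_table: pd.DataFrame | None = None,
    top_k: int = 5,
    ddof: int = 0,
) -> Fingerprint:
    """Mean/SD weight per core unit for one emotion, with AU-labeled rankings.

    SDs use the population convention (``ddof=0``) since the cohort is
    described in full, not sampled from; ``mean_sd`` (the mean SD across all
    units) is in weight-fraction units — multiply by 100 to report it as a
    percentage of the maximal extent of motion.
    """
    mat = cohort.matrix(emotion)
    if mat.shape[0] < 2:
        raise ValueError(f"need >= 2 expressions for emotion {emotion!r}")
    if cohort.representation != "core":
        raise ValueError("fingerprints are defined on the 46-unit core representation")
    if au_table is None:
        au_table = default_au_table()
    mean_w = mat.mean(axis=0)
    sd_w = mat.std(axis=0, ddof=ddof)

    def ranked(values: np.ndarray) -> list[tuple[int, str, int, float]]:
        order = np.argsort(-values, kind="stable")[:top_k]
        out = []
        for j in order:
            name, au = au_label(au_table, int(j))
            out.append((int(j), name, au, float(values[j])))
        return out

    return Fingerprint(
        emotion=emotion,
        mean_weights=mean_w,
        sd_weights=sd_w,
        top_peaks=ranked(mean_w),
        top_variable=ranked(sd_w),
        mean_sd=float(sd_w.mean()),
    )


def fingerprint_table(
    cohort: CohortDataset, au_table: pd.DataFrame | None = None, top_k: int = 5
) -> pd.DataFrame:
    """Long-format table of every emotion's peak and variability rankings."""
    rows = []
    for emotion in cohort.emotions:
        fp = fingerprint(cohort, emotion, au_table=au_table, top_k=top_k)
        for rank, (core, name, au, val) in enumerate(fp.top_peaks, 1):
            rows.append(
                {"emotion": emotion, "ranking": "peak", "rank": rank,
                 "core_index": core, "facs_name": name, "au_number": au, "value": val}
            )
        for rank, (core, name, au, val) in enumerate(fp.top_variable, 1):
            rows.append(
                {"emotion": emotion, "ranking": "variability", "rank": rank,
                 "core_index": core, "facs_name": name, "au_number": au, "value": val}
            )
        rows.append(
            {"emotion": emotion, "ranking": "mean_sd", "rank": 0,
             "core_index": -1, "facs_name": "all_units", "au_number": -1,
             "value": fp.mean_sd}
        )
    return pd.DataFrame.from_records(rows)


# ---------------------------------------------------------------------------
# SVM category prediction


def svm_category_cv(
    cohort: CohortDataset,
    folds: int = 5,
    seed: int = 0,
    kernel: str = "linear",
    C: float = 1.0,
) -> dict:
    """Stratified cross-validated SVM predicting emotion from core weights.

    Returns overall accuracy, per-emotion recall, and fold-wise accuracies.
    If some class has fewer members than ``folds``, the fold count is reduced
    and the report flagged.
    """
    mat = cohort.matrix()
    labels = cohort.labels()
    _, class_counts = np.unique(labels, return_counts=True)
    reduced = False
    min_count = int(class_counts.min())
    if min_count < folds:
        folds = max(2, min_count)
        reduced = True
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    clf = SVC(kernel=kernel, C=C)
    fold_scores = cross_val_score(clf, mat, labels, cv=cv)

    # per-class recall from out-of-fold predictions
    predictions = np.empty(len(labels), dtype=labels.dtype)
    for train, test in cv.split(mat, labels):
        predictions[test] = SVC(kernel=kernel, C=C).fit(mat[train], labels[train]).predict(mat[test])
    per_emotion = {
        e: float(np.mean(predictions[labels == e] == e)) for e in cohort.emotions
    }
    return {
        "overall": float(np.mean(predictions == labels)),
        "per_emotion": per_emotion,
        "fold_accuracies": fold_scores.tolist(),
        "fold_sd": float(fold_scores.std(ddof=0)),
        "folds": folds,
        "folds_reduced": reduced,
    }
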