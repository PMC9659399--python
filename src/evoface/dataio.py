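"""Cohort containers and delimited-text expression tables.

A cohort is the substrate of every downstream statistic: one preferred
expression per (participant, emotion) cell, stored as a tidy DataFrame with
columns ``participant_id, emotion, c01..c46`` (core representation) or
``participant_id, emotion, w001..w149`` (full rig).  Files are plain CSV;
lines starting with ``#`` carry provenance and are ignored on read.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .blendspace import EMOTIONS, N_CORE, N_RIG

CORE_COLUMNS = [f"c{j + 1:02d}" for j in range(N_CORE)]
RIG_COLUMNS = [f"w{j + 1:03d}" for j in range(N_RIG)]


@dataclass
class CohortDataset:
    """Participants x emotions matrix of preferred expressions.

    ``table`` holds one row per (participant, emotion); ``meta`` carries the
    generating spec/seed when the cohort is synthetic.
    """

    table: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.table = _validate_table(self.table.reset_index(drop=True))

    # -- structure -----------------------------------------------------

    @property
    def representation(self) -> str:
        return "core" if CORE_COLUMNS[0] in self.table.columns else "rig"

    @property
    def weight_columns(self) -> list[str]:
        return CORE_COLUMNS if self.representation == "core" else RIG_COLUMNS

    @property
    def participants(self) -> list[str]:
        return list(dict.fromkeys(self.table["participant_id"]))

    @property
    def emotions(self) -> list[str]:
        return [e for e in EMOTIONS if e in set(self.table["emotion"])]

    def __len__(self) -> int:
        return len(self.table)

    # -- accessors -----------------------------------------------------

    def matrix(self, emotion: str | None = None) -> np.ndarray:
        """Expression matrix (rows in table order), optionally one emotion."""
        sub = self.table if emotion is None else self.table[self.table["emotion"] == emotion]
        if emotion is not None and sub.empty:
            raise KeyError(f"no expressions for emotion {emotion!r}")
        return sub[self.weight_columns].to_numpy(dtype=float)

    def labels(self) -> np.ndarray:
        return self.table["emotion"].to_numpy()

    def preferred_map(self) -> dict[str, dict[str, np.ndarray]]:
        """participant_id -> emotion -> preferred expression vector."""
        cols = self.weight_columns
        out: dict[str, dict[str, np.ndarray]] = {}
        for _, row in self.table.iterrows():
            out.setdefault(row["participant_id"], {})[row["emotion"]] = (
                row[cols].to_numpy(dtype=float)
            )
        return out

    def mean_expression(self, emotion: str) -> np.ndarray:
        """Centroid of an emotion category (the 'average' expression)."""
        return self.matrix(emotion).mean(axis=0)

    # -- io ------------------------------------------------------------

    def to_csv(self, path, provenance: dict | None = None) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for key, val in (provenance or {}).items():
                fh.write(f"# {key}={val}\n")
            self.table.to_csv(fh, index=False)

    @classmethod
    def read_csv(cls, path) -> "CohortDataset":
        return read_expression_table(path)


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    for col in ("participant_id", "emotion"):
        if col not in table.columns:
            raise ValueError(f"expression table lacks column {col!r}")
    if set(CORE_COLUMNS).issubset(table.columns):
        cols = CORE_COLUMNS
    elif set(RIG_COLUMNS).issubset(table.columns):
        cols = RIG_COLUMNS
    else:
        raise ValueError(
            f"expression table needs weight columns {CORE_COLUMNS[0]}..{CORE_COLUMNS[-1]} "
            f"or {RIG_COLUMNS[0]}..{RIG_COLUMNS[-1]}"
        )
    bad_emotion = ~table["emotion"].isin(EMOTIONS)
    if bad_emotion.any():
        row = int(np.flatnonzero(bad_emotion.to_numpy())[0])
        raise ValueError(
            f"row {row + 1}: unknown emotion label {table['emotion'].iloc[row]!r} "
            f"(expected one of {', '.join(EMOTIONS)})"
        )
    weights = table[cols].to_numpy(dtype=float)
    out_of_range = (weights < 0.0) | (weights > 1.0) | ~np.isfinite(weights)
    if out_of_range.any():
        r, c = map(int, np.argwhere(out_of_range)[0])
        raise ValueError(
            f"row {r + 1}, column {cols[c]}: weight {weights[r, c]} outside [0, 1]"
        )
    return table


def read_expression_table(path) -> CohortDataset:
    """Read and validate a cohort expression table from delimited text."""
    try:
        table = pd.read_csv(path, comment="#")
    except Exception as exc:  # malformed CSV
        raise ValueError(f"cannot parse expression table {path}: {exc}") from exc
    return CohortDataset(table=table)


def cohort_from_arrays(
    participant_ids, emotions, matrix, representation: str = "core", meta: dict | None = None
) -> CohortDataset:
    """Assemble a CohortDataset from parallel arrays of ids, labels, weights."""
    matrix = np.asarray(matrix, dtype=float)
    cols = CORE_COLUMNS if representation == "core" else RIG_COLUMNS
    if matrix.shape[1] != len(cols):
        raise ValueError(f"matrix has {matrix.shape[1]} columns, expected {len(cols)}")
    table = pd.DataFrame(matrix, columns=cols)
    table.insert(0, "emotion", list(emotions))
    table.insert(0, "participant_id", list(participant_ids))
    return CohortDataset(table=table, meta=meta or {})


def default_category_means() -> dict[str, np.ndarray]:
    """Packaged per-emotion mean core vectors.

    Hand-authored so each emotion's most activated units carry that emotion's
    characteristic action units (e.g. lip-corner puller AU12 for happy), with
    the fear/sad and happy/sad overlaps real faces show.
    """
    ref = importlib.resources.files("evoface.data").joinpath("category_means.csv")
    with ref.open("r", encoding="utf-8") as fh:
        table = pd.read_csv(fh)
    return {
        str(row["emotion"]): row[CORE_COLUMNS].to_numpy(dtype=float)
        for _, row in table.iterrows()
    }
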