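"""Expression space: blendshape vectors, the core-to-rig coupling, AU labels,
and the cosine-distance metric used throughout the package.

The avatar face is posed by 149 rig blendshapes, each weighted by a fraction
of its maximal activation in [0, 1].  Only 46 *core* units can move
independently; a nonnegative coupling matrix drives the full rig from the
cores.  Dissimilarity between expressions is measured by cosine distance,
which is well behaved in this high-dimensional nonnegative space: it ranges
over [0, 1], ignores overall expression intensity, and is 0 exactly for
positively collinear expressions.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

N_RIG = 149
N_CORE = 46
EMOTIONS = ("happy", "fear", "angry", "sad")

COREMAP_FORMAT_VERSION = 1


def as_weights(x, n_dims: int | None = None, name: str = "weights") -> np.ndarray:
    """Validate a weight vector: finite, within [0, 1], optionally of fixed length.

    Returns a float64 copy.  Raises ``ValueError`` on any violation, naming the
    offending entry.
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be 1-D, got shape {arr.shape}")
    if n_dims is not None and arr.shape[0] != n_dims:
        raise ValueError(f"{name} must have {n_dims} entries, got {arr.shape[0]}")
    if not np.all(np.isfinite(arr)):
        idx = int(np.flatnonzero(~np.isfinite(arr))[0])
        raise ValueError(f"{name}[{idx}] is not finite")
    if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
        bad = int(np.flatnonzero((arr < 0.0) | (arr > 1.0))[0])
        raise ValueError(f"{name}[{bad}] = {arr[bad]} outside [0, 1]")
    return arr.copy()


def as_core_vector(x, name: str = "core vector") -> np.ndarray:
    return as_weights(x, N_CORE, name)


def as_rig_vector(x, name: str = "rig vector") -> np.ndarray:
    return as_weights(x, N_RIG, name)


def cosine_distance(a, b) -> float:
    """Cosine distance ``1 - a.b / (|a||b|)`` between two weight vectors.

    Both vectors must be nonnegative, of equal length and of nonzero
    magnitude; the result then lies in [0, 1] and is 0 iff the vectors are
    positively collinear.  A zero-magnitude input raises ``ValueError``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.ndim != 1:
        raise ValueError("expected 1-D weight vectors")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("weights must be nonnegative")
    na = float(np.linalg.norm(a))
    nb = float(np.linalg.norm(b))
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine distance undefined for a zero-magnitude expression")
    d = 1.0 - float(a @ b) / (na * nb)
    # guard rounding: exact bounds are [0, 1] on the nonnegative orthant
    return float(min(max(d, 0.0), 1.0))


def pairwise_cd(vectors) -> np.ndarray:
    """All n(n-1)/2 unordered-pair cosine distances.

    Pair order is the row-major upper triangle: (0,1), (0,2), ..., (n-2,n-1).
    """
    mat = np.asarray(vectors, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise ValueError("need at least 2 vectors of equal length")
    if np.any(mat < 0):
        raise ValueError("weights must be nonnegative")
    norms = np.linalg.norm(mat, axis=1)
    if np.any(norms == 0.0):
        bad = int(np.flatnonzero(norms == 0.0)[0])
        raise ValueError(f"vector {bad} has zero magnitude")
    return np.clip(pdist(mat, metric="cosine"), 0.0, 1.0)


def cross_cd(a, b) -> np.ndarray:
    """Cosine-distance matrix between the rows of ``a`` and the rows of ``b``."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    if np.any(na == 0.0) or np.any(nb == 0.0):
        raise ValueError("zero-magnitude expression in distance computation")
    sim = (a / na[:, None]) @ (b / nb[:, None]).T
    return np.clip(1.0 - sim, 0.0, 1.0)


# ---------------------------------------------------------------------------
# core-to-rig coupling


@dataclass
class CoreMap:
    """Nonnegative 149x46 coupling driving the rig from the 46 core units.

    ``expand`` realizes a rig pose as ``clip(coupling @ core, 0, 1)``: linear
    below the clipping bound, and monotone in every core weight because the
    coefficients are nonnegative.
    """

    coupling: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.coupling = np.asarray(self.coupling, dtype=float)
        if self.coupling.shape != (N_RIG, N_CORE):
            raise ValueError(
                f"coupling must be {N_RIG}x{N_CORE}, got {self.coupling.shape}"
            )
        if np.any(self.coupling < 0):
            raise ValueError("coupling coefficients must be nonnegative")
        driven = (self.coupling > 0).any(axis=1)
        if not driven.all():
            bad = int(np.flatnonzero(~driven)[0])
            raise ValueError(f"rig dimension {bad} is driven by no core unit")
        if not self.names:
            self.names = [f"core_{j:02d}" for j in range(N_CORE)]
        if len(self.names) != N_CORE:
            raise ValueError(f"need {N_CORE} core names, got {len(self.names)}")

    def expand(self, core) -> np.ndarray:
        core = as_core_vector(core)
        return np.clip(self.coupling @ core, 0.0, 1.0)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"format_version: {COREMAP_FORMAT_VERSION}\n")
            fh.write(f"n_rig: {N_RIG}\n")
            fh.write(f"n_core: {N_CORE}\n")
            fh.write("names: " + "\t".join(self.names) + "\n")
            fh.write("matrix:\n")
            for row in self.coupling:
                fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")

    @classmethod
    def load(cls, path) -> "CoreMap":
        with open(path, encoding="utf-8") as fh:
            lines = [ln.rstrip("\n") for ln in fh]
        header: dict[str, str] = {}
        i = 0
        while i < len(lines) and lines[i] != "matrix:":
            key, _, val = lines[i].partition(":")
            header[key.strip()] = val.strip()
            i += 1
        if header.get("format_version") != str(COREMAP_FORMAT_VERSION):
            raise ValueError(f"unsupported core-map format: {header.get('format_version')}")
        names = header["names"].split("\t")
        rows = [np.fromstring(ln, sep=" ") for ln in lines[i + 1 :] if ln.strip()]
        return cls(coupling=np.vstack(rows), names=names)


def default_core_map(au_table: "pd.DataFrame | None" = None) -> CoreMap:
    """Default coupling: the 149 rig dims are split into 46 contiguous groups,
    each driven identically (coefficient 1.0) by one core unit.

    The true production rig couples cores anatomically; this stand-in keeps
    the 46-independent / 149-rendered structure without inventing anatomy.
    Real rigs load through :meth:`CoreMap.load`.
    """
    coupling = np.zeros((N_RIG, N_CORE))
    sizes = np.full(N_CORE, N_RIG // N_CORE)
    sizes[: N_RIG % N_CORE] += 1  # 11 groups of 4, 35 of 3
    start = 0
    for j, size in enumerate(sizes):
        coupling[start : start + size, j] = 1.0
        start += size
    if au_table is None:
        au_table = default_au_table()
    names = list(au_table["facs_name"])
    return CoreMap(coupling=coupling, names=names)


def expand_core(core, core_map: CoreMap | None = None) -> np.ndarray:
    """Rig weights for a core vector: ``clip(coupling @ core, 0, 1)``."""
    if core_map is None:
        core_map = default_core_map()
    return core_map.expand(core)


# ---------------------------------------------------------------------------
# FACS action-unit labels

# AUs the per-emotion fingerprints rank: happy 12,13,6,7,1; fear 5,1,2,20,4;
# angry 4,10,11,9,16; sad 15,11,17,20,7.
REQUIRED_AUS = frozenset({1, 2, 4, 5, 6, 7, 9, 10, 11, 12, 13, 15, 16, 17, 20})


def default_au_table() -> pd.DataFrame:
    """Packaged table mapping each core unit to a FACS name and AU number."""
    ref = importlib.resources.files("evoface.data").joinpath("au_table.tsv")
    with ref.open("r", encoding="utf-8") as fh:
        table = pd.read_csv(fh, sep="\t")
    return validate_au_table(table)


def validate_au_table(table: pd.DataFrame) -> pd.DataFrame:
    expected = {"core_index", "facs_name", "au_number"}
    if not expected.issubset(table.columns):
        raise ValueError(f"AU table needs columns {sorted(expected)}")
    missing = REQUIRED_AUS - set(table["au_number"].astype(int))
    if missing:
        raise ValueError(f"AU table lacks required action units: {sorted(missing)}")
    return table


def au_label(table: pd.DataFrame, core_index: int) -> tuple[str, int]:
    """(FACS name, AU number) for a core unit; placeholder if unlabeled."""
    rows = table[table["core_index"] == core_index]
    if rows.empty:
        return (f"unlabeled_{core_index:02d}", -1)
    row = rows.iloc[0]
    return (str(row["facs_name"]), int(row["au_number"]))


# ---------------------------------------------------------------------------
# procedural expressions


def random_expression(
    rng: np.random.Generator,
    activation_prob: float = 0.3,
    magnitude_law: str = "uniform",
) -> np.ndarray:
    """Procedurally generated core vector, as used to seed the evolution.

    Each of the 46 core units is independently activated with probability
    ``activation_prob``; activated weights are drawn from ``magnitude_law``
    on [0, 1].  Laws: ``"uniform"``, ``"constant:<v>"``, ``"beta:<a>:<b>"``.
    Sparse activation (default 0.3) yields diverse but plausible poses.
    """
    if not (0.0 < activation_prob <= 1.0):
        raise ValueError(f"activation_prob must be in (0, 1], got {activation_prob}")
    active = rng.random(N_CORE) < activation_prob
    weights = np.zeros(N_CORE)
    n_active = int(active.sum())
    if n_active:
        weights[active] = _draw_magnitudes(rng, magnitude_law, n_active)
    return weights


def _draw_magnitudes(rng: np.random.Generator, law: str, n: int) -> np.ndarray:
    parts = law.split(":")
    kind = parts[0]
    if kind == "uniform":
        return rng.random(n)
    if kind == "constant":
        v = float(parts[1]) if len(parts) > 1 else 1.0
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"constant magnitude {v} outside [0, 1]")
        return np.full(n, v)
    if kind == "beta":
        a, b = (float(parts[1]), float(parts[2])) if len(parts) > 2 else (2.0, 2.0)
        return rng.beta(a, b, size=n)
    raise ValueError(f"unknown magnitude law: {law!r}")
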