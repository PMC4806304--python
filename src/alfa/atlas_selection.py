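"""Atlas selection strategies for multi-atlas brain extraction.

Two strategies are provided:

* **UAS (uniform atlas selection)** — a greedy max–min procedure in the spirit
  of the Kennard–Stone algorithm, but initialised at the image closest to the
  dataset mean rather than at the two mutually farthest images.  Each
  subsequent atlas maximises its minimum distance to the already-selected set,
  spreading the chosen atlases "uniformly" through the data space.  The
  selection is target-independent: one subset serves every test image.

* **MSAS (most-similar atlas selection)** — the conventional baseline that
  ranks the library by distance to a specific target and keeps the k nearest.

Images are compared as flattened intensity vectors over a common grid, after
affine alignment to a reference (skipped when the library is pre-aligned) and
histogram-landmark intensity standardization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .volumes import Volume, normalize_intensities, train_landmarks

__all__ = [
    "DataVectorSet",
    "SelectionResult",
    "pairwise_distance",
    "build_vectors",
    "select_uniform",
    "select_most_similar",
]


@dataclass
class SelectionResult:
    """Ordered outcome of an atlas selection run.

    ``min_distances`` records, for every atlas selected after the first, the
    max–min distance at which it was chosen (UAS) or its distance to the target
    (MSAS).
    """

    selected_ids: list[str]
    min_distances: list[float]
    strategy: str

    def __post_init__(self) -> None:
        if len(set(self.selected_ids)) != len(self.selected_ids):
            raise ValueError("selected_ids must be unique")


@dataclass
class DataVectorSet:
    """Flattened intensity vectors of a library over a common grid.

    ``landmarks`` records the intensity-standardization landmarks used when
    building the vectors, so that later comparisons (e.g. a test image in
    most-similar selection) can be standardized consistently.
    """

    ids: list[str]
    vectors: np.ndarray  # (N, D)
    mean_vector: np.ndarray = field(default=None)  # type: ignore[assignment]
    landmarks: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be a 2-D (N, D) array")
        if len(self.ids) != self.vectors.shape[0]:
            raise ValueError("ids and vectors length mismatch")
        if self.mean_vector is None:
            self.mean_vector = self.vectors.mean(axis=0)

    def __len__(self) -> int:
        return self.vectors.shape[0]


def pairwise_distance(a: np.ndarray, b: np.ndarray, metric: str = "l2") -> float:
    """Distance between two data vectors.

    ``l2`` (default, the classic Kennard–Stone metric), ``l1``, or ``ncc``
    (one minus the normalised cross-correlation; zero for perfectly correlated
    vectors).
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError(f"vector length mismatch: {a.shape} vs {b.shape}")
    if metric == "l2":
        return float(np.linalg.norm(a - b))
    if metric == "l1":
        return float(np.sum(np.abs(a - b)))
    if metric == "ncc":
        a0, b0 = a - a.mean(), b - b.mean()
        denom = np.linalg.norm(a0) * np.linalg.norm(b0)
        if denom == 0:
            return 0.0 if np.array_equal(a, b) else 1.0
        return float(1.0 - np.dot(a0, b0) / denom)
    raise ValueError(f"unknown metric {metric!r}")


def build_vectors(images: Sequence[Volume], reference: Volume | None = None,
                  prealigned: bool = True, normalize: bool = True,
                  backend=None,
                  landmarks: np.ndarray | None = None) -> DataVectorSet:
    """Align, standardize and flatten a library of images into data vectors.

    With ``prealigned=True`` images are assumed to already live on a common
    grid; otherwise each is affinely registered to ``reference`` using
    ``backend`` (any object with ``register``/``apply_transform``).
    """
    if len(images) == 0:
        raise ValueError("need at least one image")
    work = list(images)
    if not prealigned:
        if backend is None or reference is None:
            raise ValueError("registration backend and reference required "
                             "when images are not pre-aligned")
        aligned = []
        for img in work:
            t = backend.register(img, reference, mode="affine")
            aligned.append(backend.apply_transform(t, img, reference))
        work = aligned
    if normalize:
        if landmarks is None:
            landmarks = train_landmarks(work)
        work = [normalize_intensities(v, landmarks) for v in work]
    shapes = {v.shape for v in work}
    if len(shapes) != 1:
        raise ValueError(f"images are not on a common grid: shapes {shapes}")
    vectors = np.stack([v.data.ravel() for v in work])
    return DataVectorSet(ids=[v.id for v in images], vectors=vectors,
                         landmarks=landmarks)


def select_uniform(vectors: DataVectorSet, k: int,
                   metric: str = "l2") -> SelectionResult:
    """Greedy max–min (uniform) atlas selection.

    The first atlas is the one closest to the dataset mean; while fewer than
    ``k`` are selected, the next is the candidate whose minimum distance to the
    selected set is largest.  Ties break to the lowest library index.
    """
    n = len(vectors)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    dist: Callable[[int, int], float] = lambda i, j: pairwise_distance(
        vectors.vectors[i], vectors.vectors[j], metric)

    d_mean = np.array([pairwise_distance(vectors.vectors[i], vectors.mean_vector, metric)
                       for i in range(n)])
    selected = [int(np.argmin(d_mean))]
    min_distances: list[float] = []
    # min distance of every candidate to the selected set, updated incrementally
    d_min = np.array([dist(i, selected[0]) for i in range(n)])
    d_min[selected[0]] = -np.inf
    while len(selected) < k:
        nxt = int(np.argmax(d_min))
        min_distances.append(float(d_min[nxt]))
        selected.append(nxt)
        d_new = np.array([dist(i, nxt) for i in range(n)])
        d_min = np.minimum(d_min, d_new)
        d_min[nxt] = -np.inf
    return SelectionResult(selected_ids=[vectors.ids[i] for i in selected],
                           min_distances=min_distances, strategy="UAS")


def select_most_similar(vectors: DataVectorSet, target: Volume | np.ndarray,
                        k: int, metric: str = "l2",
                        normalize: bool = True,
                        landmarks: np.ndarray | None = None) -> SelectionResult:
    """Rank the library by distance to a target and keep the k nearest.

    ``target`` may be a :class:`~alfa.volumes.Volume` on the library grid (it is
    intensity-standardized with the library landmarks when ``normalize``) or an
    already-prepared data vector.  Ties break to the lowest library index;
    results are in ascending distance order.
    """
    n = len(vectors)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if isinstance(target, Volume):
        tv = target
        if normalize:
            marks = landmarks if landmarks is not None else vectors.landmarks
            if marks is not None:
                tv = normalize_intensities(tv, marks)
        tvec = tv.data.ravel()
    else:
        tvec = np.asarray(target, dtype=np.float64).ravel()
    d = np.array([pairwise_distance(vectors.vectors[i], tvec, metric) for i in range(n)])
    order = np.argsort(d, kind="stable")[:k]
    return SelectionResult(selected_ids=[vectors.ids[i] for i in order],
                           min_distances=[float(d[i]) for i in order],
                           strategy="MSAS")
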