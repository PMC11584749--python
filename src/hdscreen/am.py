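"""Associative-memory classifier: build, retrain, predict, rank.

The associative memory holds one integer prototype hypervector per
class.  Training is a single pass: each class prototype is the bundle
(element-wise sum) of the encoded training samples of that class.
Inference assigns a query to the class whose prototype has the highest
cosine similarity.  An optional retraining phase re-predicts the
training set and, for each misclassified sample, adds its hypervector
to the true-class prototype and subtracts it from the wrongly predicted
one — pushing the memory toward the perceptron-style decision surface
without any gradient machinery.

For binary screens a confidence score

    eta = 1/2 + (cos(h_q, h_1) - cos(h_q, h_0)) / 4

maps the similarity difference between the positive prototype ``h_1``
and the negative prototype ``h_0`` onto [0, 1]: eta > 0.5 exactly when
the query is more similar to the positive prototype.  Ranking a
compound library by descending eta is the screening primitive that the
enrichment metrics consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import numpy.typing as npt

__all__ = [
    "AssociativeMemory",
    "PredictionResult",
    "RankedScreen",
    "build_associative_memory",
    "retrain",
    "predict",
    "predict_batch",
    "confidence_score",
    "confidence_scores",
    "rank_compounds",
]

DEFAULT_BATCH_SIZE = 128


@dataclass
class AssociativeMemory:
    """K class prototypes over a shared hypervector dimension D.

    ``prototypes`` is a (K, D) int64 array; ``class_labels`` the K
    distinct labels in prototype order (binary screens use 0 =
    inactive, 1 = active).  ``meta`` carries provenance (encoder
    config, seeds, retraining epochs) for reproducibility logging.
    """

    prototypes: np.ndarray
    class_labels: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.prototypes = np.asarray(self.prototypes, dtype=np.int64)
        self.class_labels = np.asarray(self.class_labels)
        if self.prototypes.ndim != 2:
            raise ValueError("prototypes must be a (K, D) matrix")
        if self.prototypes.shape[0] != self.class_labels.shape[0]:
            raise ValueError("one prototype per class label required")
        if self.prototypes.shape[0] < 2:
            raise ValueError("an associative memory needs at least 2 classes")
        if len(set(self.class_labels.tolist())) != self.class_labels.shape[0]:
            raise ValueError("class labels must be unique")

    @property
    def n_classes(self) -> int:
        return self.prototypes.shape[0]

    @property
    def dim(self) -> int:
        return self.prototypes.shape[1]

    def label_index(self, label) -> int:
        idx = np.flatnonzero(self.class_labels == label)
        if idx.size == 0:
            raise KeyError(f"unknown class label {label!r}")
        return int(idx[0])

    def copy(self) -> "AssociativeMemory":
        return AssociativeMemory(
            prototypes=self.prototypes.copy(),
            class_labels=self.class_labels.copy(),
            meta=dict(self.meta),
        )

    def save(self, path) -> None:
        """Serialize prototypes, labels and metadata to an .npz file."""
        meta_keys = sorted(self.meta)
        np.savez_compressed(
            path,
            prototypes=self.prototypes,
            class_labels=self.class_labels,
            meta_keys=np.array(meta_keys, dtype=object).astype(str),
            meta_values=np.array(
                [str(self.meta[k]) for k in meta_keys], dtype=object
            ).astype(str),
        )

    @classmethod
    def load(cls, path) -> "AssociativeMemory":
        with np.load(path, allow_pickle=False) as data:
            meta = dict(zip(data["meta_keys"].tolist(), data["meta_values"].tolist()))
            return cls(
                prototypes=data["prototypes"],
                class_labels=data["class_labels"],
                meta=meta,
            )


@dataclass(frozen=True)
class PredictionResult:
    """A single query's predicted class and per-class cosine similarities."""

    predicted_class: object
    similarities: np.ndarray
    confidence: float | None = None


@dataclass
class RankedScreen:
    """Per-compound screening scores with optional labels and ids.

    ``scores`` are higher-is-more-active; the order of the arrays is
    the ranked order (descending score, stable in the input order on
    ties) once produced by :func:`rank_compounds`.
    """

    scores: np.ndarray
    ids: np.ndarray | None = None
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.ndim != 1 or self.scores.size == 0:
            raise ValueError("scores must be a non-empty 1-D array")
        if self.ids is not None:
            self.ids = np.asarray(self.ids)
            if self.ids.shape[0] != self.scores.shape[0]:
                raise ValueError("ids and scores must have equal length")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape[0] != self.scores.shape[0]:
                raise ValueError("labels and scores must have equal length")

    def __len__(self) -> int:
        return int(self.scores.shape[0])


def _as_matrix(encoded: npt.ArrayLike, dim: int | None = None) -> np.ndarray:
    mat = np.asarray(encoded, dtype=np.int64)
    if mat.ndim == 1:
        mat = mat[None, :]
    if mat.ndim != 2:
        raise ValueError("encoded samples must form an (N, D) matrix")
    if dim is not None and mat.shape[1] != dim:
        raise ValueError(
            f"encoded samples have dim {mat.shape[1]}, memory has dim {dim}"
        )
    return mat


def build_associative_memory(
    encoded: npt.ArrayLike,
    labels: Sequence,
    classes: Sequence | None = None,
    meta: dict | None = None,
) -> AssociativeMemory:
    """Single-pass construction: each prototype bundles its class's samples.

    ``classes`` fixes the prototype order (and hence argmax tie-breaking
    priority); it defaults to the sorted distinct labels.  Every class
    must have at least one sample.  Order-invariant in the samples.
    """
    mat = _as_matrix(encoded)
    labs = np.asarray(labels)
    if labs.shape[0] != mat.shape[0]:
        raise ValueError(
            f"{mat.shape[0]} encoded samples but {labs.shape[0]} labels"
        )
    cls = np.asarray(sorted(set(labs.tolist())) if classes is None else list(classes))
    protos = np.zeros((cls.shape[0], mat.shape[1]), dtype=np.int64)
    for k, c in enumerate(cls):
        members = labs == c
        if not members.any():
            raise ValueError(f"class {c!r} has no training samples")
        protos[k] = mat[members].sum(axis=0)
    unknown = set(labs.tolist()) - set(cls.tolist())
    if unknown:
        raise ValueError(f"labels {sorted(unknown)!r} not in the declared class set")
    return AssociativeMemory(prototypes=protos, class_labels=cls, meta=meta or {})


def _similarity_matrix(am: AssociativeMemory, queries: np.ndarray) -> np.ndarray:
    """Cosine of every query (rows) against every prototype (columns).

    Dot products and squared norms are computed in exact integer
    arithmetic, so the result for a given query is bit-identical
    whatever the batch it arrives in.
    """
    protos = am.prototypes
    proto_sq = np.einsum("kd,kd->k", protos, protos)
    if np.any(proto_sq == 0):
        dead = am.class_labels[proto_sq == 0].tolist()
        raise ValueError(
            f"prototype(s) for class(es) {dead!r} are all-zero; retrain or "
            "regroup the classes before predicting"
        )
    q = queries
    q_sq = np.einsum("nd,nd->n", q, q)
    if np.any(q_sq == 0):
        raise ValueError("query hypervector is all-zero")
    dots = (q @ protos.T).astype(np.float64)
    return dots / np.sqrt(np.outer(q_sq.astype(np.float64), proto_sq.astype(np.float64)))


def predict(am: AssociativeMemory, h_q: npt.ArrayLike) -> PredictionResult:
    """Nearest-prototype classification of one query by cosine similarity.

    Ties break toward the lowest prototype index (deterministic across
    platforms).  For binary memories the confidence eta is attached.
    """
    q = _as_matrix(h_q, am.dim)
    if q.shape[0] != 1:
        raise ValueError("predict takes a single query; use predict_batch")
    sims = _similarity_matrix(am, q)[0]
    k = int(np.argmax(sims))  # argmax returns the first (lowest) index on ties
    conf = None
    if am.n_classes == 2:
        conf = _eta_from_sims(sims, am)
    return PredictionResult(
        predicted_class=am.class_labels[k].item(),
        similarities=sims,
        confidence=conf,
    )


def predict_batch(
    am: AssociativeMemory,
    encoded: npt.ArrayLike,
    batch_size: int = DEFAULT_BATCH_SIZE,
) -> np.ndarray:
    """Predicted class labels for an (N, D) matrix of queries.

    Processes in batches of ``batch_size`` (bit-identical to
    one-by-one scoring; batching is purely a memory/throughput knob).
    """
    mat = _as_matrix(encoded, am.dim)
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    out = np.empty(mat.shape[0], dtype=am.class_labels.dtype)
    for start in range(0, mat.shape[0], batch_size):
        chunk = mat[start : start + batch_size]
        sims = _similarity_matrix(am, chunk)
        out[start : start + chunk.shape[0]] = am.class_labels[np.argmax(sims, axis=1)]
    return out


def retrain(
    am: AssociativeMemory,
    encoded: npt.ArrayLike,
    labels: Sequence,
    epochs: int = 10,
    learning_rate: int = 1,
    early_stop: bool = True,
) -> tuple[AssociativeMemory, list[float]]:
    """Error-driven refinement of the memory.

    Per epoch, each training sample is predicted with the *current*
    prototypes; on a mistake the sample hypervector (scaled by
    ``learning_rate``, default 1) is added to the true-class prototype
    and subtracted from the wrongly predicted one.  Correct samples
    leave the memory untouched, so a perfectly classified training set
    is a fixed point.  Stops early when an epoch makes zero updates.

    Returns the updated memory (the input is not mutated) and the
    per-epoch training accuracy trace measured before each epoch's
    updates.
    """
    if epochs < 0:
        raise ValueError("epochs must be >= 0")
    mat = _as_matrix(encoded, am.dim)
    labs = np.asarray(labels)
    if labs.shape[0] != mat.shape[0]:
        raise ValueError("labels and encoded samples must have equal length")
    label_idx = np.array([am.label_index(l) for l in labs.tolist()])
    out = am.copy()
    trace: list[float] = []
    for _ in range(epochs):
        n_correct = 0
        n_updates = 0
        for i in range(mat.shape[0]):
            sims = _similarity_matrix(out, mat[i : i + 1])[0]
            pred = int(np.argmax(sims))
            true = int(label_idx[i])
            if pred == true:
                n_correct += 1
            else:
                out.prototypes[true] += learning_rate * mat[i]
                out.prototypes[pred] -= learning_rate * mat[i]
                n_updates += 1
        trace.append(n_correct / mat.shape[0])
        if early_stop and n_updates == 0:
            break
    out.meta["retrain_epochs_run"] = len(trace)
    return out, trace


def _eta_from_sims(sims: np.ndarray, am: AssociativeMemory) -> float:
    """eta = 1/2 + (cos(q, h1) - cos(q, h0)) / 4 for a binary memory.

    Oriented so that eta > 0.5 exactly when the query is more similar
    to the positive (label 1 / higher-label) prototype.
    """
    i1 = am.label_index(1) if 1 in am.class_labels else 1
    i0 = 1 - i1
    return 0.5 + (sims[i1] - sims[i0]) / 4.0


def confidence_score(am: AssociativeMemory, h_q: npt.ArrayLike) -> float:
    """Confidence eta in [0, 1] for a binary associative memory.

    eta = 1/2 when the query is equally similar to both prototypes,
    1 at the positive endpoint (cos = +1 to positive, -1 to negative)
    and 0 at the opposite endpoint.
    """
    if am.n_classes != 2:
        raise ValueError(
            f"confidence is defined for binary screens only (K=2), got K={am.n_classes}"
        )
    q = _as_matrix(h_q, am.dim)
    if q.shape[0] != 1:
        raise ValueError("confidence_score takes a single query")
    sims = _similarity_matrix(am, q)[0]
    return _eta_from_sims(sims, am)


def confidence_scores(
    am: AssociativeMemory,
    encoded: npt.ArrayLike,
    batch_size: int = DEFAULT_BATCH_SIZE,
) -> np.ndarray:
    """Vectorised eta for an (N, D) query matrix (binary memories only)."""
    if am.n_classes != 2:
        raise ValueError(
            f"confidence is defined for binary screens only (K=2), got K={am.n_classes}"
        )
    mat = _as_matrix(encoded, am.dim)
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    i1 = am.label_index(1) if 1 in am.class_labels else 1
    i0 = 1 - i1
    out = np.empty(mat.shape[0], dtype=np.float64)
    for start in range(0, mat.shape[0], batch_size):
        sims = _similarity_matrix(am, mat[start : start + batch_size])
        out[start : start + sims.shape[0]] = 0.5 + (sims[:, i1] - sims[:, i0]) / 4.0
    return out


def rank_compounds(
    am: AssociativeMemory,
    encoded: npt.ArrayLike,
    ids: Sequence | None = None,
    labels: Sequence | None = None,
    batch_size: int = DEFAULT_BATCH_SIZE,
) -> RankedScreen:
    """Score every compound with eta and sort descending (stable on ties).

    Returns a :class:`RankedScreen` whose arrays are already in ranked
    order; the output ids are a permutation of the input ids.
    """
    mat = _as_matrix(encoded, am.dim)
    if mat.shape[0] == 0:
        raise ValueError("cannot rank an empty compound set")
    etas = confidence_scores(am, mat, batch_size=batch_size)
    order = np.argsort(-etas, kind="stable")
    ids_arr = np.arange(mat.shape[0]) if ids is None else np.asarray(ids)
    if ids_arr.shape[0] != mat.shape[0]:
        raise ValueError("ids and encoded samples must have equal length")
    labels_arr = None
    if labels is not None:
        labels_arr = np.asarray(labels, dtype=np.int64)[order]
    return RankedScreen(scores=etas[order], ids=ids_arr[order], labels=labels_arr)
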