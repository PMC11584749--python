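"""Bipolar hypervector algebra.

Hyperdimensional computing (HDC) represents items as very high-dimensional
vectors ("hypervectors") and composes them with three cheap operations:

* **binding** — element-wise (Hadamard) product; associates two
  hypervectors into a third that is quasi-orthogonal to both,
* **bundling** — element-wise sum; superimposes a set of hypervectors
  into an integer-valued prototype,
* **permutation** — cyclic rotation; injects positional information.

We work with *bipolar* hypervectors (entries in {-1, +1}).  Binding is
then self-inverse (``bind(a, a)`` is the all-ones identity) and the sign
function maps any real vector back onto the bipolar hypercube.
Similarity between hypervectors is measured with the cosine, which is
scale-invariant, so integer prototypes produced by bundling never need
renormalisation.

All functions operate on 1-D (or, where documented, 2-D batched) NumPy
integer/float arrays; helpers validate the bipolar invariant eagerly so
shape or domain bugs fail at the boundary rather than deep in a screen.
"""

from __future__ import annotations

import numpy as np
import numpy.typing as npt

__all__ = [
    "as_bipolar",
    "bind",
    "bundle",
    "permute",
    "quantize_sign",
    "cosine_similarity",
    "negate",
    "random_bipolar",
]


def as_bipolar(values: npt.ArrayLike, *, name: str = "hypervector") -> np.ndarray:
    """Validate and return ``values`` as an int8 bipolar hypervector.

    Raises ``ValueError`` if any entry is not exactly -1 or +1, or the
    array is empty / not 1-D or 2-D (2-D = a batch, one row per vector).
    """
    arr = np.asarray(values)
    if arr.ndim not in (1, 2):
        raise ValueError(f"{name} must be 1-D or 2-D, got ndim={arr.ndim}")
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if not np.all(np.abs(arr) == 1):
        bad = arr.flat[int(np.argmax(np.abs(arr) != 1))]
        raise ValueError(f"{name} entries must be -1 or +1, found {bad!r}")
    return arr.astype(np.int8, copy=False)


def _check_same_dim(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape[-1] != b.shape[-1]:
        raise ValueError(
            f"dimension mismatch: {a.shape[-1]} vs {b.shape[-1]}"
        )


def bind(a: npt.ArrayLike, b: npt.ArrayLike) -> np.ndarray:
    """Bind two bipolar hypervectors: the element-wise product.

    Commutative, associative, and self-inverse on bipolar input.
    """
    av = as_bipolar(a, name="a")
    bv = as_bipolar(b, name="b")
    _check_same_dim(av, bv)
    return (av * bv).astype(np.int8)


def bundle(hs) -> np.ndarray:
    """Bundle a non-empty sequence of hypervectors: the element-wise sum.

    Accepts bipolar hypervectors and/or integer prototypes; returns an
    int64 prototype.  Order-invariant.  A bundle of *m* bipolar vectors
    has every entry in [-m, +m] with the parity of *m*.
    """
    hs = list(hs)
    if len(hs) == 0:
        raise ValueError("cannot bundle an empty list of hypervectors")
    arrs = [np.asarray(h, dtype=np.int64) for h in hs]
    dim = arrs[0].shape[-1]
    for i, arr in enumerate(arrs):
        if arr.ndim != 1:
            raise ValueError(f"hypervector {i} must be 1-D, got ndim={arr.ndim}")
        if arr.shape[-1] != dim:
            raise ValueError(
                f"dimension mismatch in bundle: vector 0 has dim {dim}, "
                f"vector {i} has dim {arr.shape[-1]}"
            )
    return np.sum(arrs, axis=0, dtype=np.int64)


def permute(h: npt.ArrayLike, k: int) -> np.ndarray:
    """Cyclically rotate ``h`` by ``k`` positions toward higher indices.

    ``permute(permute(h, k), -k) == h`` for any integer ``k``; ``k`` may
    exceed the dimension (rotation is mod D).
    """
    arr = np.asarray(h)
    if arr.ndim != 1:
        raise ValueError(f"permute expects a 1-D hypervector, got ndim={arr.ndim}")
    return np.roll(arr, int(k))


def quantize_sign(z: npt.ArrayLike) -> np.ndarray:
    """Quantize a real vector onto the bipolar hypercube.

    Entries <= 0 map to -1 and entries > 0 map to +1 (the zero tie goes
    to -1).  Idempotent on bipolar input.  Works element-wise on 2-D
    input (one row per vector).
    """
    arr = np.asarray(z, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("cannot quantize an empty vector")
    if not np.all(np.isfinite(arr)):
        raise ValueError("quantize_sign requires finite entries")
    return np.where(arr > 0, 1, -1).astype(np.int8)


def cosine_similarity(a: npt.ArrayLike, b: npt.ArrayLike) -> float:
    """Cosine similarity between two hypervectors (bipolar or integer).

    Raises ``ValueError`` on a zero vector (undefined norm) or a
    dimension mismatch.  Scale-invariant: ``cos(c*a, b) == cos(a, b)``
    for any c > 0.
    """
    av = np.asarray(a, dtype=np.float64)
    bv = np.asarray(b, dtype=np.float64)
    if av.ndim != 1 or bv.ndim != 1:
        raise ValueError("cosine_similarity expects 1-D vectors")
    _check_same_dim(av, bv)
    na = np.linalg.norm(av)
    nb = np.linalg.norm(bv)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(av @ bv / (na * nb))


def negate(h: npt.ArrayLike) -> np.ndarray:
    """Element-wise negation (the bipolar complement)."""
    return -np.asarray(h)


def random_bipolar(
    dim: int, rng: np.random.Generator, size: int | None = None
) -> np.ndarray:
    """Draw uniform random bipolar hypervectors.

    Returns shape ``(dim,)`` when ``size`` is None, else ``(size, dim)``.
    """
    if dim < 1:
        raise ValueError(f"dim must be >= 1, got {dim}")
    shape = (dim,) if size is None else (int(size), dim)
    return rng.choice(np.array([-1, 1], dtype=np.int8), size=shape)
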