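"""Synthetic data with known structure for end-to-end testing and demos.

Three generators cover the three stages of the screening pipeline:

* :func:`generate_gaussian_features` — two multivariate-normal clusters
  with a controllable mean separation (in units of per-coordinate noise
  scale) and class imbalance; exercises the feature-projection encoder
  the way precomputed molecular embeddings would, including the heavily
  skewed 1:50 active:inactive regime of real screening decks.
* :func:`generate_prototype_noise_data` — bipolar samples generated as
  noisy copies (independent sign flips) of two hidden random
  generators; the associative memory should recover the generators,
  giving a direct parameter-recovery test for prototype learning.
* :func:`generate_toy_molecules` — small enumerated valid SMILES
  (alkanes, alcohols, ethers, amines and their aromatic counterparts)
  labelled by a substructure rule (active iff an aromatic ring is
  present), so fingerprint-based encoders face a learnable,
  ground-truth chemical signal.

All generators are pure functions of their spec (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hdc import random_bipolar
from .io import MoleculeTable

__all__ = [
    "SyntheticSpec",
    "generate_gaussian_features",
    "generate_prototype_noise_data",
    "generate_toy_molecules",
]


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic two-class dataset.

    ``separation`` is the Euclidean distance between class means in
    units of the per-coordinate noise scale (identity covariance);
    ``class_ratio`` is positives per negative (0.02 ≈ the 1:50 skew of
    large screening decks); ``noise_flip_prob`` is the per-coordinate
    sign-flip probability for bipolar prototype data.
    """

    n_per_class: int = 200
    feature_dim: int = 64
    separation: float = 4.0
    class_ratio: float = 1.0
    noise_flip_prob: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.feature_dim < 1:
            raise ValueError("feature_dim must be >= 1")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if self.class_ratio <= 0:
            raise ValueError("class_ratio must be > 0")
        if not 0.0 <= self.noise_flip_prob <= 0.5:
            raise ValueError("noise_flip_prob must be in [0, 0.5]")


def _class_sizes(spec: SyntheticSpec) -> tuple[int, int]:
    """(n_negative, n_positive); n_per_class is the negative-class size."""
    n_neg = spec.n_per_class
    n_pos = max(1, int(round(spec.n_per_class * spec.class_ratio)))
    return n_neg, n_pos


def generate_gaussian_features(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Two Gaussian clusters with mean distance ``spec.separation``.

    Returns an (N, n) float matrix and a length-N {0,1} label vector;
    negatives first, positives after (shuffle downstream if order
    matters).  The two means sit at ±separation/2 along a random unit
    direction (symmetric about the origin, since sign quantization is
    origin-sensitive and a class centered exactly at the origin would
    carry no sign signal); noise is standard normal per coordinate.
    """
    rng = np.random.default_rng(spec.seed)
    direction = rng.standard_normal(spec.feature_dim)
    direction /= np.linalg.norm(direction)
    offset = direction * (spec.separation / 2.0)
    n_neg, n_pos = _class_sizes(spec)
    x_neg = rng.standard_normal((n_neg, spec.feature_dim)) - offset
    x_pos = rng.standard_normal((n_pos, spec.feature_dim)) + offset
    x = np.vstack([x_neg, x_pos])
    y = np.concatenate([np.zeros(n_neg, dtype=np.int64), np.ones(n_pos, dtype=np.int64)])
    return x, y


def generate_prototype_noise_data(
    spec: SyntheticSpec, dim: int = 10_000
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Noisy copies of two hidden bipolar generators.

    Each sample copies its class generator with independent sign flips
    at ``spec.noise_flip_prob`` (< 0.5 required, else the classes carry
    no signal).  Returns (samples (N, D) int8, labels {0,1},
    generators (2, D) int8 — row k generates class k).
    """
    if spec.noise_flip_prob >= 0.5:
        raise ValueError("noise_flip_prob must be < 0.5 for recoverable structure")
    rng = np.random.default_rng(spec.seed)
    generators = random_bipolar(dim, rng, size=2)
    n_neg, n_pos = _class_sizes(spec)
    counts = (n_neg, n_pos)
    samples = np.empty((n_neg + n_pos, dim), dtype=np.int8)
    labels = np.empty(n_neg + n_pos, dtype=np.int64)
    row = 0
    for k in (0, 1):
        flips = rng.random((counts[k], dim)) < spec.noise_flip_prob
        samples[row : row + counts[k]] = np.where(flips, -generators[k], generators[k])
        labels[row : row + counts[k]] = k
        row += counts[k]
    return samples, labels, generators


# Building blocks for toy molecule enumeration: simple aliphatic scaffolds
# (label 0) and aromatic-ring-bearing scaffolds (label 1), decorated with
# small substituents.  All combinations are valid SMILES by construction.
_ALIPHATIC_CORES = ["C", "CC", "CCC", "CCCC", "CCCCC", "C1CCCCC1", "C1CCCC1", "CC(C)C"]
_AROMATIC_CORES = ["c1ccccc1", "c1ccncc1", "c1ccoc1", "c1ccsc1", "c1cc[nH]c1"]
_SUBSTITUENTS = ["", "C", "O", "N", "CC", "CO", "C(C)C", "CCO", "Cl", "Br"]


def generate_toy_molecules(count: int, seed: int = 0) -> MoleculeTable:
    """Enumerate ``count`` toy molecules with a substructure-defined label.

    Molecules are scaffold–substituent combinations; a molecule is
    labelled active (1) iff it carries an aromatic ring, giving the
    fingerprint encoders a noiseless ground-truth signal.  Classes are
    drawn in roughly equal proportion; duplicate structures receive
    distinct ids but identical fingerprints (as in real decks).
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    combos: list[tuple[str, int]] = []
    for core in _ALIPHATIC_CORES:
        for sub in _SUBSTITUENTS:
            combos.append((core + sub, 0))
    for core in _AROMATIC_CORES:
        for sub in _SUBSTITUENTS:
            combos.append((core + sub, 1))
    rng = np.random.default_rng(seed)
    neg = [c for c in combos if c[1] == 0]
    pos = [c for c in combos if c[1] == 1]
    n_pos = count // 2
    n_neg = count - n_pos
    picks = [neg[i] for i in rng.integers(0, len(neg), size=n_neg)]
    picks += [pos[i] for i in rng.integers(0, len(pos), size=n_pos)]
    order = rng.permutation(len(picks))
    ids = [f"mol{i:05d}" for i in range(len(picks))]
    smiles = [picks[j][0] for j in order]
    labels = np.array([picks[j][1] for j in order], dtype=np.int64)
    return MoleculeTable(ids=ids, smiles=smiles, labels=labels)
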