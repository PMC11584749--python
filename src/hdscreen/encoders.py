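"""Molecular encoders: SMILES / fingerprints / embeddings -> bipolar hypervectors.

Four encoding schemes map a molecule into a D-dimensional bipolar
hypervector:

* ``rpfp`` — random-projection fingerprint: an ECFP bit vector of length
  n is projected through a random D x n matrix with unit-norm rows and
  sign-quantized.
* ``decfp`` — direct ECFP: the fingerprint is computed with n_bits = D
  and its {0,1} bits are mapped to {-1,+1} directly (no projection; the
  sparse fingerprint itself serves as the hypervector).
* ``feature_projection`` — a real-valued per-molecule embedding (e.g.
  extracted from a pretrained SMILES language model or a graph
  contrastive model) is random-projected and sign-quantized.
* ``combo`` — element-wise (Hadamard) product of the ``decfp``
  hypervector with the ``feature_projection`` hypervector, binding the
  substructure signal to the learned-embedding signal.

Projection matrices have rows drawn isotropically from the unit sphere
(standard-normal rows, then row normalisation) and are reproducible from
their seed, so train and test encodings share the same matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import numpy.typing as npt
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

from .hdc import quantize_sign, bind

RDLogger.DisableLog("rdApp.*")

SCHEMES = ("rpfp", "decfp", "feature_projection", "combo")

__all__ = [
    "ProjectionMatrix",
    "EncoderConfig",
    "sample_projection_matrix",
    "compute_ecfp",
    "encode_rpfp",
    "encode_decfp",
    "encode_feature_projection",
    "encode_combo",
    "MoleculeEncoder",
    "InvalidSmilesError",
]


class InvalidSmilesError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""

    def __init__(self, smiles: str):
        self.smiles = smiles
        super().__init__(f"could not parse SMILES: {smiles!r}")


@dataclass(frozen=True)
class ProjectionMatrix:
    """Random projection matrix W (D x n) with unit-norm rows.

    Rows are points on the unit (n-1)-sphere; identical ``seed`` and
    shape reproduce the identical matrix.
    """

    matrix: np.ndarray
    seed: int

    @property
    def dim_out(self) -> int:
        return self.matrix.shape[0]

    @property
    def dim_in(self) -> int:
        return self.matrix.shape[1]


@dataclass
class EncoderConfig:
    """Configuration of a molecule encoder.

    Parameters
    ----------
    scheme
        One of ``rpfp``, ``decfp``, ``feature_projection``, ``combo``.
    dim
        Hypervector dimension D (default 10_000, the dimension at which
        quasi-orthogonality of random hypervectors is comfortably
        established and beyond which gains are marginal).
    n_bits
        ECFP fingerprint length n for ``rpfp`` (default 1024). Ignored
        by ``decfp``, which uses ``dim`` as the fingerprint length.
    radius
        ECFP radius r in bonds (default 1).
    seed
        Parent seed for the projection matrices.
    """

    scheme: str = "decfp"
    dim: int = 10_000
    n_bits: int = 1024
    radius: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(
                f"unknown scheme {self.scheme!r}; expected one of {SCHEMES}"
            )
        if self.dim < 1:
            raise ValueError(f"dim must be >= 1, got {self.dim}")
        if self.n_bits < 1:
            raise ValueError(f"n_bits must be >= 1, got {self.n_bits}")
        if self.radius < 0:
            raise ValueError(f"radius must be >= 0, got {self.radius}")


def sample_projection_matrix(dim_out: int, dim_in: int, seed: int) -> ProjectionMatrix:
    """Sample a D x n projection matrix with rows uniform on the unit sphere.

    Each row is a standard-normal draw normalised to unit Euclidean
    norm — the rotation-invariant construction of a uniform point on
    the sphere.  Deterministic given ``seed``.
    """
    if dim_out < 1 or dim_in < 1:
        raise ValueError(
            f"projection matrix dims must be positive, got D={dim_out}, n={dim_in}"
        )
    rng = np.random.default_rng(seed)
    w = rng.standard_normal((dim_out, dim_in))
    w /= np.linalg.norm(w, axis=1, keepdims=True)
    return ProjectionMatrix(matrix=w, seed=int(seed))


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(smiles)
    return mol


def compute_ecfp(smiles: str, n_bits: int = 1024, radius: int = 1) -> np.ndarray:
    """Compute the ECFP/Morgan fingerprint of a molecule as a {0,1} vector.

    Chemically identical SMILES spellings yield identical fingerprints
    (the toolkit canonicalises the molecular graph before hashing).
    Raises :class:`InvalidSmilesError` on an unparseable string.
    """
    if n_bits < 1:
        raise ValueError(f"n_bits must be >= 1, got {n_bits}")
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    mol = _mol_from_smiles(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprintAsNumPy(mol)
    return fp.astype(np.uint8)


def encode_rpfp(fp: npt.ArrayLike, w: ProjectionMatrix) -> np.ndarray:
    """Random-projection fingerprint encoding: sign(W @ fp)."""
    fpv = np.asarray(fp, dtype=np.float64)
    if fpv.ndim != 1:
        raise ValueError("fingerprint must be 1-D")
    if w.dim_in != fpv.shape[0]:
        raise ValueError(
            f"projection expects input dim {w.dim_in}, fingerprint has {fpv.shape[0]}"
        )
    return quantize_sign(w.matrix @ fpv)


def encode_decfp(smiles: str, dim: int = 10_000, radius: int = 1) -> np.ndarray:
    """Direct ECFP encoding: fingerprint of length D, bits mapped 0 -> -1, 1 -> +1."""
    fp = compute_ecfp(smiles, n_bits=dim, radius=radius)
    return np.where(fp > 0, 1, -1).astype(np.int8)


def encode_feature_projection(x: npt.ArrayLike, w: ProjectionMatrix) -> np.ndarray:
    """Project a real embedding through W and sign-quantize.

    Scale-invariant in ``x`` (the sign of W @ x ignores positive
    scaling), and approximately preserves the ordering of pairwise
    cosine similarities of the inputs for large D.
    """
    xv = np.asarray(x, dtype=np.float64)
    if xv.ndim != 1:
        raise ValueError("feature vector must be 1-D")
    if not np.all(np.isfinite(xv)):
        raise ValueError("feature vector must have finite entries")
    if w.dim_in != xv.shape[0]:
        raise ValueError(
            f"projection expects input dim {w.dim_in}, features have {xv.shape[0]}"
        )
    return quantize_sign(w.matrix @ xv)


def encode_combo(h_decfp: npt.ArrayLike, h_feat: npt.ArrayLike) -> np.ndarray:
    """Bind the direct-ECFP hypervector with the projected-feature hypervector."""
    return bind(h_decfp, h_feat)


@dataclass
class MoleculeEncoder:
    """Stateful encoder applying one scheme to a molecule table.

    Holds the projection matrix (when the scheme needs one) so that
    training and screening encode through the identical map.  Use
    :meth:`encode_dataset` for tables and :meth:`save` /
    :meth:`load` to persist the encoder state between runs.
    """

    config: EncoderConfig
    _w: ProjectionMatrix | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self._w is None and self.config.scheme in ("rpfp", "feature_projection"):
            # feature_projection's input dim is only known at first use
            if self.config.scheme == "rpfp":
                self._w = sample_projection_matrix(
                    self.config.dim, self.config.n_bits, self.config.seed
                )

    @property
    def projection(self) -> ProjectionMatrix | None:
        return self._w

    def _ensure_feature_projection(self, n_features: int) -> ProjectionMatrix:
        if self._w is None:
            self._w = sample_projection_matrix(
                self.config.dim, n_features, self.config.seed
            )
        elif self._w.dim_in != n_features:
            raise ValueError(
                f"encoder projection expects {self._w.dim_in} features, got {n_features}"
            )
        return self._w

    def encode_smiles(self, smiles: str, features: npt.ArrayLike | None = None) -> np.ndarray:
        """Encode one molecule; ``features`` required for embedding-based schemes."""
        cfg = self.config
        if cfg.scheme == "decfp":
            return encode_decfp(smiles, dim=cfg.dim, radius=cfg.radius)
        if cfg.scheme == "rpfp":
            fp = compute_ecfp(smiles, n_bits=cfg.n_bits, radius=cfg.radius)
            return encode_rpfp(fp, self._w)
        if features is None:
            raise ValueError(
                f"scheme {cfg.scheme!r} requires a per-molecule feature vector"
            )
        xv = np.asarray(features, dtype=np.float64)
        w = self._ensure_feature_projection(xv.shape[0])
        h_feat = encode_feature_projection(xv, w)
        if cfg.scheme == "feature_projection":
            return h_feat
        # combo
        return encode_combo(encode_decfp(smiles, dim=cfg.dim, radius=cfg.radius), h_feat)

    def encode_dataset(
        self,
        smiles: Sequence[str],
        features: npt.ArrayLike | None = None,
    ) -> np.ndarray:
        """Encode a list of molecules into an (N, D) int8 hypervector matrix.

        For embedding-based schemes ``features`` must be an (N, n)
        matrix whose row order matches ``smiles``; a row-count mismatch
        is a hard error, never a truncation.
        """
        n = len(smiles)
        feats = None
        if features is not None:
            feats = np.asarray(features, dtype=np.float64)
            if feats.ndim != 2:
                raise ValueError("feature matrix must be 2-D (one row per molecule)")
            if feats.shape[0] != n:
                raise ValueError(
                    f"feature matrix has {feats.shape[0]} rows but the molecule "
                    f"table has {n} rows"
                )
        out = np.empty((n, self.config.dim), dtype=np.int8)
        for i, smi in enumerate(smiles):
            row_feat = feats[i] if feats is not None else None
            out[i] = self.encode_smiles(smi, features=row_feat)
        return out

    def save(self, path) -> None:
        """Serialize config + projection matrix to a single .npz file."""
        cfg = self.config
        payload = {
            "scheme": np.array(cfg.scheme),
            "dim": np.array(cfg.dim),
            "n_bits": np.array(cfg.n_bits),
            "radius": np.array(cfg.radius),
            "seed": np.array(cfg.seed),
        }
        if self._w is not None:
            payload["w_matrix"] = self._w.matrix
            payload["w_seed"] = np.array(self._w.seed)
        np.savez_compressed(path, **payload)

    @classmethod
    def load(cls, path) -> "MoleculeEncoder":
        with np.load(path, allow_pickle=False) as data:
            cfg = EncoderConfig(
                scheme=str(data["scheme"]),
                dim=int(data["dim"]),
                n_bits=int(data["n_bits"]),
                radius=int(data["radius"]),
                seed=int(data["seed"]),
            )
            w = None
            if "w_matrix" in data:
                w = ProjectionMatrix(matrix=data["w_matrix"], seed=int(data["w_seed"]))
        enc = cls.__new__(cls)
        enc.config = cfg
        enc._w = w
        return enc
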