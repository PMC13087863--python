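"""2048-bit atom-pair fingerprints and the 10-D principal-component embedding.

The surrogate model never sees a molecule directly: each hexamer repeat is
encoded as a binary atom-pair fingerprint and the whole candidate library is
then projected onto the top 10 principal components of the 10 000 x 2048
fingerprint matrix.  The fingerprint enumerates every unordered pair of
heavy atoms separated by 1-5 covalent bonds and hashes the canonical tuple

    (descriptor(a), descriptor(b), topological distance)

into one of 2048 bits, where ``descriptor`` is the atom type
``(element, formal charge, hybridization class, in-ring flag, heavy-atom
degree)``.  Hashing uses 64-bit FNV-1a over the tuple's byte serialization,
a documented, stable, non-cryptographic hash, so fingerprints are
bit-identical across processes and platforms.  Hybridization is derived
from the bonding pattern alone (sp for a triple bond or two cumulated
double bonds, sp2 for aromatic atoms or one double bond, sp3 otherwise).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from sklearn.decomposition import PCA

from .errors import DimensionMismatch, DisconnectedGraph, TooFewSamples

N_BITS = 2048
MAX_BOND_DISTANCE = 5

_FNV_OFFSET = 0xCBF29CE484222325
_FNV_PRIME = 0x100000001B3
_MASK64 = 0xFFFFFFFFFFFFFFFF


@dataclass(frozen=True)
class AtomPairFingerprint:
    bits: np.ndarray  # uint8 vector of length N_BITS
    n_pairs: int

    def __post_init__(self):
        if self.bits.shape != (N_BITS,):
            raise DimensionMismatch(f"expected {N_BITS} bits, got {self.bits.shape}")


@dataclass
class EmbeddingModel:
    """Mean-centered PCA retaining the top ``n_components`` loadings."""

    mean_vector: np.ndarray            # (N_BITS,)
    components: np.ndarray             # (n_components, N_BITS), orthonormal rows
    explained_variance_fractions: np.ndarray  # (n_components,), non-increasing

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def to_json(self) -> str:
        return json.dumps(
            {
                "mean_vector": self.mean_vector.tolist(),
                "components": self.components.tolist(),
                "explained_variance_fractions":
                    self.explained_variance_fractions.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "EmbeddingModel":
        d = json.loads(text)
        return cls(
            np.asarray(d["mean_vector"], dtype=float),
            np.asarray(d["components"], dtype=float),
            np.asarray(d["explained_variance_fractions"], dtype=float),
        )


def fnv1a64(data: bytes) -> int:
    h = _FNV_OFFSET
    for byte in data:
        h ^= byte
        h = (h * _FNV_PRIME) & _MASK64
    return h


def _hybridization_class(atom: Chem.Atom) -> int:
    # 1 = sp, 2 = sp2, 3 = sp3; derived from the bonding pattern only
    if atom.GetIsAromatic():
        return 2
    n_double = n_triple = 0
    for b in atom.GetBonds():
        bt = b.GetBondType()
        if bt == Chem.BondType.DOUBLE:
            n_double += 1
        elif bt == Chem.BondType.TRIPLE:
            n_triple += 1
    if n_triple or n_double >= 2:
        return 1
    return 2 if n_double == 1 else 3


def atom_descriptor(atom: Chem.Atom) -> tuple:
    return (
        atom.GetSymbol(),
        atom.GetFormalCharge(),
        _hybridization_class(atom),
        int(atom.IsInRing()),
        atom.GetDegree(),
    )


def atom_pair_fingerprint(mol: Chem.Mol) -> AtomPairFingerprint:
    """Hash all heavy-atom pairs within 5 bonds into a 2048-bit vector.

    The pair tuple is sorted on the two atom descriptors so the encoding is
    orientation-free, and atom order in the input graph is immaterial.
    Raises :class:`DisconnectedGraph` for multi-fragment inputs.
    """
    if len(Chem.GetMolFrags(mol)) != 1:
        raise DisconnectedGraph("fingerprint requires a connected molecule")
    dm = Chem.GetDistanceMatrix(mol)
    descs = [atom_descriptor(a) for a in mol.GetAtoms()]
    bits = np.zeros(N_BITS, dtype=np.uint8)
    n_pairs = 0
    n = mol.GetNumAtoms()
    for i in range(n):
        row = dm[i]
        for j in range(i + 1, n):
            d = int(row[j])
            if 1 <= d <= MAX_BOND_DISTANCE:
                n_pairs += 1
                a, b = sorted((descs[i], descs[j]))
                key = repr((a, b, d)).encode("ascii")
                bits[fnv1a64(key) % N_BITS] = 1
    return AtomPairFingerprint(bits, n_pairs)


def fingerprint_matrix(mols) -> np.ndarray:
    """Stack fingerprints of an iterable of molecules into a float matrix."""
    return np.array([atom_pair_fingerprint(m).bits for m in mols], dtype=float)


def fit_embedding(fingerprints: np.ndarray, n_components: int = 10) -> EmbeddingModel:
    """Mean-centered PCA of a fingerprint matrix (no variance scaling).

    Uses the covariance eigendecomposition, which is exact and deterministic;
    requires at least ``n_components + 1`` samples.
    """
    X = np.asarray(fingerprints, dtype=float)
    if X.ndim != 2 or X.shape[1] != N_BITS:
        raise DimensionMismatch(f"expected (n, {N_BITS}) matrix, got {X.shape}")
    if X.shape[0] < n_components + 1:
        raise TooFewSamples(
            f"need at least {n_components + 1} fingerprints, got {X.shape[0]}"
        )
    pca = PCA(n_components=n_components, svd_solver="covariance_eigh")
    pca.fit(X)
    return EmbeddingModel(
        mean_vector=pca.mean_.copy(),
        components=pca.components_.copy(),
        explained_variance_fractions=pca.explained_variance_ratio_.copy(),
    )


def embed(fp: AtomPairFingerprint | np.ndarray, model: EmbeddingModel) -> np.ndarray:
    """Project a fingerprint onto the model's principal components."""
    bits = fp.bits if isinstance(fp, AtomPairFingerprint) else np.asarray(fp, float)
    if bits.shape[-1] != model.mean_vector.shape[0]:
        raise DimensionMismatch("fingerprint length does not match the model")
    return (bits - model.mean_vector) @ model.components.T


def embed_matrix(fingerprints: np.ndarray, model: EmbeddingModel) -> np.ndarray:
    X = np.asarray(fingerprints, dtype=float)
    if X.shape[1] != model.mean_vector.shape[0]:
        raise DimensionMismatch("fingerprint length does not match the model")
    return (X - model.mean_vector) @ model.components.T
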