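"""Chemical-space analytics: fingerprints, Tanimoto, t-SNE, k-medoids.

Molecules are compared with circular (Morgan-type) fingerprints of radius 3.
Two flavors are used: the plain connectivity fingerprint for similarity
reports, and the feature-class ("functional") variant for clustering into
catalogs.  Similarity reports use the unhashed on-bit sets; 2-D embeddings
use the 1024-bit hashed vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit.Chem import rdFingerprintGenerator
from sklearn.manifold import TSNE

from .chem_prep import MoleculeRecord

__all__ = [
    "FingerprintVector",
    "SimilarityReport",
    "EmbeddingMap",
    "ClusterAssignment",
    "fingerprint",
    "tanimoto",
    "nearest_training_similarity",
    "embed_2d",
    "cluster_k",
]

_RADIUS = 3
_N_BITS = 1024

_plain_gen = rdFingerprintGenerator.GetMorganGenerator(radius=_RADIUS, fpSize=_N_BITS)
_feature_gen = rdFingerprintGenerator.GetMorganGenerator(
    radius=_RADIUS,
    fpSize=_N_BITS,
    atomInvariantsGenerator=rdFingerprintGenerator.GetMorganFeatureAtomInvGen(),
)


@dataclass(frozen=True)
class FingerprintVector:
    """On-bit set of a radius-3 circular fingerprint.

    ``bits`` is a frozenset of feature identifiers (unhashed) or bit
    positions in [0, 1024) (hashed).  ``kind`` distinguishes the plain
    connectivity fingerprint from the pharmacophoric feature-class variant.
    """

    bits: frozenset[int]
    kind: str  # "circular-r3" | "functional-circular-r3"
    hashed: bool = False


def fingerprint(
    record: MoleculeRecord, kind: str = "circular-r3", hashed: bool = False
) -> FingerprintVector:
    """Radius-3 circular fingerprint; 1024-bit positions when hashed."""
    gen = {"circular-r3": _plain_gen, "functional-circular-r3": _feature_gen}[kind]
    mol = record.mol()
    if hashed:
        fp = gen.GetFingerprint(mol)
        bits = frozenset(fp.GetOnBits())
    else:
        bits = frozenset(gen.GetSparseFingerprint(mol).GetOnBits())
    return FingerprintVector(bits=bits, kind=kind, hashed=hashed)


def hashed_matrix(records: Sequence[MoleculeRecord], kind: str = "circular-r3") -> np.ndarray:
    """n x 1024 dense 0/1 matrix of hashed fingerprints."""
    mat = np.zeros((len(records), _N_BITS), dtype=np.float64)
    for i, rec in enumerate(records):
        for b in fingerprint(rec, kind=kind, hashed=True).bits:
            mat[i, b] = 1.0
    return mat


def tanimoto(a: FingerprintVector, b: FingerprintVector) -> float:
    """|A∩B| / |A∪B| over on-bits; 1.0 for two empty sets (identical)."""
    if a.kind != b.kind or a.hashed != b.hashed:
        raise ValueError("cannot compare fingerprints of different kinds")
    union = len(a.bits | b.bits)
    if union == 0:
        return 1.0
    return len(a.bits & b.bits) / union


@dataclass
class SimilarityReport:
    """Per-molecule nearest-training-neighbor Tanimoto values."""

    rows: pd.DataFrame  # columns: id, smiles, nearest_id, nearest_smiles, tanimoto

    def histogram(self, bins: int = 10) -> tuple[np.ndarray, np.ndarray]:
        return np.histogram(self.rows["tanimoto"].to_numpy(), bins=bins, range=(0, 1))

    def to_csv(self, path: str | Path) -> None:
        self.rows.to_csv(path, index=False)


def nearest_training_similarity(
    generated: Sequence[MoleculeRecord],
    training: Sequence[MoleculeRecord],
    kind: str = "circular-r3",
) -> SimilarityReport:
    """Exact (brute-force) max-Tanimoto of each generated molecule over the
    training set, with the argmax training molecule recorded."""
    if not training:
        raise ValueError("training set is empty")
    if not generated:
        raise ValueError("generated set is empty")
    train_fps = [fingerprint(r, kind=kind) for r in training]
    rows = []
    for g in generated:
        gfp = fingerprint(g, kind=kind)
        sims = [tanimoto(gfp, tfp) for tfp in train_fps]
        best = int(np.argmax(sims))
        rows.append(
            {
                "id": g.id,
                "smiles": g.smiles_canonical,
                "nearest_id": training[best].id,
                "nearest_smiles": training[best].smiles_canonical,
                "tanimoto": sims[best],
            }
        )
    return SimilarityReport(rows=pd.DataFrame(rows))


@dataclass
class EmbeddingMap:
    """2-D t-SNE coordinates with a group label per molecule."""

    coords: np.ndarray  # (n, 2)
    groups: list[str]
    records: list[MoleculeRecord]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "smiles": [r.smiles_canonical for r in self.records],
                "group": self.groups,
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
            }
        ).to_csv(path, index=False)

    def plot(self, path: str | Path) -> None:
        """Scatter plot, one color per group (training blue/green,
        generated yellow, references red/magenta)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        palette = ["tab:blue", "tab:green", "gold", "red", "magenta", "gray"]
        fig, ax = plt.subplots(figsize=(6, 5))
        for i, grp in enumerate(dict.fromkeys(self.groups)):
            mask = np.array([g == grp for g in self.groups])
            ax.scatter(
                self.coords[mask, 0], self.coords[mask, 1],
                s=12, label=grp, color=palette[i % len(palette)], alpha=0.7,
            )
        ax.legend()
        ax.set_xlabel("t-SNE 1")
        ax.set_ylabel("t-SNE 2")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def embed_2d(
    molecules: Sequence[MoleculeRecord],
    seed: int = 0,
    perplexity: float = 30.0,
    groups: Sequence[str] | None = None,
) -> EmbeddingMap:
    """t-SNE projection of hashed 1024-bit fingerprints to 2-D.

    Perplexity is auto-reduced to (n-1)/3 for small inputs.
    """
    n = len(molecules)
    if n < 3:
        raise ValueError("need at least 3 molecules to embed")
    perplexity = min(perplexity, (n - 1) / 3)
    mat = hashed_matrix(molecules)
    coords = TSNE(
        n_components=2, random_state=seed, perplexity=perplexity, init="pca"
    ).fit_transform(mat)
    grp = list(groups) if groups is not None else [m.source_tag for m in molecules]
    return EmbeddingMap(coords=np.asarray(coords), groups=grp, records=list(molecules))


@dataclass
class ClusterAssignment:
    """k-medoids partition under Tanimoto distance."""

    k: int
    labels: np.ndarray  # (n,) cluster id per molecule
    centers: list[MoleculeRecord]  # medoids, one per non-empty cluster
    center_indices: list[int]


def _tanimoto_distance_matrix(
    molecules: Sequence[MoleculeRecord], kind: str
) -> np.ndarray:
    fps = [fingerprint(r, kind=kind) for r in molecules]
    n = len(fps)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = 1.0 - tanimoto(fps[i], fps[j])
    return d


def cluster_k(
    molecules: Sequence[MoleculeRecord],
    k: int,
    kind: str = "functional-circular-r3",
    seed: int = 0,
    max_iter: int = 100,
) -> ClusterAssignment:
    """Partition-around-medoids clustering under 1 - Tanimoto distance.

    Medoid initialization is k-medoids++-style (seeded); the medoid of each
    cluster is the member minimizing summed distance to the cluster, ties
    broken by input order.  Deterministic for a fixed seed.
    """
    n = len(molecules)
    if not (1 <= k <= n):
        raise ValueError(f"need 1 <= k <= n; got k={k}, n={n}")
    d = _tanimoto_distance_matrix(molecules, kind)
    rng = np.random.default_rng(seed)

    medoids = [int(rng.integers(n))]
    while len(medoids) < k:
        dist_to_near = d[:, medoids].min(axis=1)
        total = dist_to_near.sum()
        if total <= 0:  # all remaining points coincide with a medoid
            remaining = [i for i in range(n) if i not in medoids]
            medoids.append(remaining[0])
            continue
        medoids.append(int(rng.choice(n, p=dist_to_near / total)))

    medoids = np.asarray(sorted(medoids))
    for _ in range(max_iter):
        labels = np.argmin(d[:, medoids], axis=1)
        new_medoids = medoids.copy()
        for c in range(len(medoids)):
            members = np.flatnonzero(labels == c)
            if members.size == 0:
                continue
            within = d[np.ix_(members, members)].sum(axis=1)
            new_medoids[c] = members[int(np.argmin(within))]
        if np.array_equal(new_medoids, medoids):
            break
        medoids = new_medoids
    labels = np.argmin(d[:, medoids], axis=1)

    center_indices = [int(m) for c, m in enumerate(medoids) if (labels == c).any()]
    centers = [
        MoleculeRecord(
            molecules[i].smiles_canonical, source_tag="cluster_center",
            id=molecules[i].id,
        )
        for i in center_indices
    ]
    return ClusterAssignment(
        k=k, labels=labels, centers=centers, center_indices=center_indices
    )
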