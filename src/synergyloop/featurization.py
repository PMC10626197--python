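"""Drug and cell-line featurization.

Drugs are represented by circular (Morgan) fingerprints concatenated with a
one-hot encoding of their identity within the library; either block can be
zeroed without changing the overall dimension, which is how the
feature-importance ablations are run.  Tanimoto similarity over fingerprints
drives both the k-medoids library design and the synthetic-library
diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

__all__ = [
    "DrugRecord",
    "DrugFeatureMatrix",
    "CellLineFeatures",
    "compute_fingerprint",
    "tanimoto_similarity",
    "tanimoto_matrix",
    "assemble_drug_features",
    "randomize_features",
    "cluster_library_medoids",
    "nearest_analogue",
    "cross_study_candidates",
    "cell_line_onehot",
    "read_drug_table",
    "write_drug_table",
]


@dataclass
class DrugRecord:
    """A library entry: identifier, optional structure, fingerprint, position."""

    drug_id: str
    smiles: str | None = None
    fingerprint: np.ndarray | None = None
    onehot_index: int | None = None

    def with_fingerprint(self, radius: int = 2, n_bits: int = 1024) -> "DrugRecord":
        if self.fingerprint is None:
            if self.smiles is None:
                raise ValueError(f"drug {self.drug_id} has neither SMILES nor fingerprint")
            self.fingerprint = compute_fingerprint(self.smiles, radius, n_bits)
        return self


@dataclass
class DrugFeatureMatrix:
    """Block matrix [fingerprint | one-hot] with fixed total width.

    Disabled blocks are identically zero; ``l_D`` never changes with the
    active-block flags, so ablated and full models share one architecture.
    """

    X: np.ndarray
    drug_ids: list[str]
    n_fp: int
    n_onehot: int
    active_blocks: dict = field(default_factory=lambda: {"fingerprint": True, "onehot": True})

    @property
    def l_D(self) -> int:
        return self.X.shape[1]

    @property
    def index(self) -> dict[str, int]:
        return {d: i for i, d in enumerate(self.drug_ids)}

    def row(self, drug_id: str) -> np.ndarray:
        return self.X[self.index[drug_id]]


@dataclass
class CellLineFeatures:
    X: np.ndarray
    cell_lines: list[str]
    encoding: str = "onehot"

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.encoding == "onehot" and not np.allclose(self.X.sum(axis=1), 1.0):
            raise ValueError("one-hot cell-line rows must sum to 1")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("cell-line features must be finite")

    @property
    def index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.cell_lines)}

    def row(self, cell_line: str) -> np.ndarray:
        return self.X[self.index[cell_line]]


def compute_fingerprint(smiles: str, radius: int = 2, n_bits: int = 1024) -> np.ndarray:
    """Circular fingerprint of a structure (radius 2, 1024 bits by default)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprintAsNumPy(mol)
    return np.asarray(fp, dtype=np.uint8)


def tanimoto_similarity(fp1: np.ndarray, fp2: np.ndarray) -> float:
    """Intersection-over-union of two bit vectors; 1 for two all-zero vectors."""
    fp1 = np.asarray(fp1).astype(bool)
    fp2 = np.asarray(fp2).astype(bool)
    if fp1.shape != fp2.shape:
        raise ValueError(f"fingerprint length mismatch: {fp1.shape} vs {fp2.shape}")
    union = np.logical_or(fp1, fp2).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(fp1, fp2).sum() / union)


def tanimoto_matrix(fps: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto similarity of a stack of bit vectors (n x bits)."""
    B = np.asarray(fps).astype(bool).astype(np.int64)
    inter = B @ B.T
    counts = B.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    return sim


def assemble_drug_features(
    library: list[DrugRecord],
    use_fingerprint: bool = True,
    use_onehot: bool = True,
) -> DrugFeatureMatrix:
    """Concatenate [fingerprint | one-hot] rows for a drug library.

    A disabled block is zero-filled in place so the feature dimension is
    invariant to the flags (the ablation contract: models never change shape,
    only which signal they see).
    """
    if not library:
        raise ValueError("empty drug library")
    if not use_fingerprint and not use_onehot:
        raise ValueError("at least one feature block must be active")
    n = len(library)
    fps = np.stack([np.asarray(d.with_fingerprint().fingerprint, dtype=float) for d in library])
    n_fp = fps.shape[1]
    onehot = np.eye(n)
    for i, d in enumerate(library):
        d.onehot_index = i
    X = np.hstack([
        fps if use_fingerprint else np.zeros_like(fps),
        onehot if use_onehot else np.zeros_like(onehot),
    ])
    return DrugFeatureMatrix(
        X=X, drug_ids=[d.drug_id for d in library], n_fp=n_fp, n_onehot=n,
        active_blocks={"fingerprint": use_fingerprint, "onehot": use_onehot},
    )


def randomize_features(
    X: DrugFeatureMatrix, fraction: float, seed: int
) -> DrugFeatureMatrix:
    """Permute the feature rows of a random subset of drugs among themselves.

    ``ceil(fraction * n_D)`` drugs are drawn without replacement and their
    whole feature rows (fingerprint and one-hot jointly) are shuffled among
    the drawn set, so each affected drug is represented by another affected
    drug's features.  Fixed points are allowed -- a uniform permutation, not
    a derangement.  ``fraction=0`` is the identity.
    """
    if not 0 <= fraction <= 1:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    n = X.X.shape[0]
    k = int(np.ceil(fraction * n))
    newX = X.X.copy()
    if k >= 2:
        subset = rng.choice(n, size=k, replace=False)
        perm = rng.permutation(k)
        newX[subset] = X.X[subset[perm]]
    return DrugFeatureMatrix(newX, list(X.drug_ids), X.n_fp, X.n_onehot,
                             dict(X.active_blocks))


def _assign(dist: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, float]:
    d = dist[:, medoids]
    labels = np.argmin(d, axis=1)
    return labels, float(d[np.arange(len(dist)), labels].sum())


def cluster_library_medoids(
    candidates: list[DrugRecord],
    k: int = 54,
    seed: int = 0,
    max_iter: int = 100,
    return_assignment: bool = False,
):
    """k-medoids over Tanimoto distance with k-medoids++ init and PAM swaps.

    Distance is ``1 - Tanimoto``; initial medoids follow the k-medoids++
    scheme (first uniform, then sampling proportional to squared distance to
    the nearest chosen medoid); refinement greedily applies the best
    medoid/non-medoid swap per cluster until no swap lowers the summed
    within-cluster distance or ``max_iter`` sweeps elapse.  Returns one
    representative :class:`DrugRecord` per cluster (and the label array when
    ``return_assignment``).
    """
    n = len(candidates)
    if n < k:
        raise ValueError(f"need at least k={k} candidates, got {n}")
    fps = np.stack([np.asarray(d.with_fingerprint().fingerprint) for d in candidates])
    dist = 1.0 - tanimoto_matrix(fps)
    rng = np.random.default_rng(seed)

    # k-medoids++ initialisation
    medoids = [int(rng.integers(n))]
    for _ in range(1, k):
        d2 = np.min(dist[:, medoids], axis=1) ** 2
        total = d2.sum()
        if total <= 0:
            remaining = [i for i in range(n) if i not in medoids]
            medoids.append(int(rng.choice(remaining)))
            continue
        probs = d2 / total
        medoids.append(int(rng.choice(n, p=probs)))
    medoids = np.array(sorted(set(medoids)))
    while len(medoids) < k:  # de-duplicate collisions
        extra = [i for i in range(n) if i not in medoids]
        medoids = np.append(medoids, rng.choice(extra))

    labels, cost = _assign(dist, medoids)
    for _ in range(max_iter):
        improved = False
        for ci in range(k):
            members = np.where(labels == ci)[0]
            if len(members) == 0:
                continue
            # best medoid within the cluster (PAM swap restricted to cluster)
            within = dist[np.ix_(members, members)].sum(axis=0)
            best = members[int(np.argmin(within))]
            if best != medoids[ci]:
                trial = medoids.copy()
                trial[ci] = best
                new_labels, new_cost = _assign(dist, trial)
                if new_cost < cost - 1e-12:
                    medoids, labels, cost = trial, new_labels, new_cost
                    improved = True
        if not improved:
            break
    reps = [candidates[int(m)] for m in medoids]
    if return_assignment:
        return reps, labels, [int(m) for m in medoids]
    return reps


def nearest_analogue(
    medoid: DrugRecord,
    cluster_members: list[DrugRecord],
    exclude: set[str] | None = None,
) -> DrugRecord:
    """Availability-replacement rule: the nearest same-cluster analogue.

    When a selected medoid is unavailable (vendor stock, solubility), swap it
    for the cluster member with the highest Tanimoto similarity to it.
    """
    exclude = (exclude or set()) | {medoid.drug_id}
    pool = [d for d in cluster_members if d.drug_id not in exclude]
    if not pool:
        raise ValueError(f"no analogue available for {medoid.drug_id}")
    sims = [tanimoto_similarity(medoid.with_fingerprint().fingerprint,
                                d.with_fingerprint().fingerprint) for d in pool]
    return pool[int(np.argmax(sims))]


def cross_study_candidates(
    seen_drugs: list[str], unseen_drugs: list[str]
) -> list[tuple[str, str]]:
    """All pairs joining one seen-library drug with one unseen-library drug.

    This is the prospective search-space construction: 54 annotated drugs
    from the training study crossed with 54 cluster representatives from
    outside it yields 54 * 54 = 2916 candidate combinations.
    """
    overlap = set(seen_drugs) & set(unseen_drugs)
    if overlap:
        raise ValueError(f"libraries overlap: {sorted(overlap)[:5]}")
    return [(a, b) for a in seen_drugs for b in unseen_drugs]


def cell_line_onehot(cell_lines: list[str]) -> CellLineFeatures:
    uniq = sorted(set(cell_lines))
    return CellLineFeatures(np.eye(len(uniq)), uniq, encoding="onehot")


def read_drug_table(path) -> list[DrugRecord]:
    """Drug table CSV: drug_id, optional smiles, optional fingerprint
    (a 0/1 bitstring, used for libraries without structures)."""
    df = pd.read_csv(path)
    if "drug_id" not in df.columns:
        raise ValueError("drug table requires a drug_id column")
    records = []
    for r in df.itertuples(index=False):
        smiles = (str(r.smiles) if "smiles" in df.columns
                  and pd.notna(r.smiles) and str(r.smiles) else None)
        fp = None
        if "fingerprint" in df.columns and pd.notna(r.fingerprint) and str(r.fingerprint):
            fp = np.frombuffer(str(r.fingerprint).encode(), dtype=np.uint8) - ord("0")
        records.append(DrugRecord(str(r.drug_id), smiles=smiles, fingerprint=fp))
    return records


def write_drug_table(library: list[DrugRecord], path) -> None:
    rows = []
    for d in library:
        fp = ("".join(map(str, np.asarray(d.fingerprint, dtype=int)))
              if d.fingerprint is not None else "")
        rows.append((d.drug_id, d.smiles if d.smiles else "", fp))
    pd.DataFrame(rows, columns=["drug_id", "smiles", "fingerprint"]).to_csv(
        path, index=False)
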