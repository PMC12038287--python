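"""Comorbidity clustering: one-hot feature matrix and Hamming K-means.

Encounters are encoded as binary vectors over demographics (age bin, sex,
race, ethnicity, location flags) plus the 500 most common diagnosis codes
and 500 most common list medications, then partitioned by a Lloyd-style
K-means under Hamming distance whose centroids are per-column majority
bits.  The cluster count is chosen by an elbow scan (k = 2..30) on a
10,000-row sample; the pipeline default is k = 4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AGE_BINS",
    "FeatureVocabulary",
    "ClusterModel",
    "bin_age",
    "build_vocabulary",
    "encode",
    "kmeans_hamming",
    "elbow_scan",
    "choose_k_elbow",
    "assign",
]

AGE_BINS = ("under_40", "40_60", "60_80", "80_plus")


def bin_age(age_years: float) -> str:
    """Bin an age in [18, 90] into [18,40), [40,60), [60,80), [80,90]."""
    if not 18 <= age_years <= 90:
        raise ValueError(f"age {age_years} outside [18, 90]")
    if age_years < 40:
        return AGE_BINS[0]
    if age_years < 60:
        return AGE_BINS[1]
    if age_years < 80:
        return AGE_BINS[2]
    return AGE_BINS[3]


@dataclass
class FeatureVocabulary:
    """Frequency-ranked code vocabularies plus the fixed demographic block."""

    top_diagnoses: list
    top_medications: list
    demographic_features: list = field(default_factory=list)

    @property
    def columns(self) -> list:
        return (
            list(self.demographic_features)
            + [f"dx:{c}" for c in self.top_diagnoses]
            + [f"med:{c}" for c in self.top_medications]
        )


def _top_codes(table: pd.DataFrame, code_col: str, max_size: int) -> list:
    # distinct-encounter counting; ties at the cut broken lexicographically
    counts = (
        table.drop_duplicates(["encounter_id", code_col])
        .groupby(code_col)
        .size()
        .reset_index(name="n")
        .sort_values(["n", code_col], ascending=[False, True], kind="stable")
    )
    return counts[code_col].head(max_size).tolist()


def build_vocabulary(
    diagnoses: pd.DataFrame,
    medications_list: pd.DataFrame,
    max_size: int = 500,
) -> FeatureVocabulary:
    """Rank codes by the number of distinct encounters they appear in and keep
    the top ``max_size`` of each kind (all, if fewer exist)."""
    if len(diagnoses) == 0 or len(medications_list) == 0:
        raise ValueError("diagnosis and medication tables must be nonempty")
    dx_col = "icd_code" if "icd_code" in diagnoses.columns else diagnoses.columns[1]
    med_col = "med_name" if "med_name" in medications_list.columns else medications_list.columns[1]
    demo = (
        [f"age_{b}" for b in AGE_BINS]
        + ["sex_F", "race_Caucasian", "race_Black", "race_Other",
           "eth_Hispanic", "icu", "telemetry", "stepdown", "obgyn"]
    )
    return FeatureVocabulary(
        top_diagnoses=_top_codes(diagnoses, dx_col, max_size),
        top_medications=_top_codes(medications_list, med_col, max_size),
        demographic_features=demo,
    )


def code_share(count: int, n_encounters: int, ndigits: int = 2) -> float:
    """Encounter-frequency share (percent) of one code token."""
    return round(100.0 * count / n_encounters, ndigits)


def encode(
    events: pd.DataFrame,
    vocab: FeatureVocabulary,
    diagnoses: pd.DataFrame | None = None,
    medications_list: pd.DataFrame | None = None,
) -> np.ndarray:
    """One-hot encode index events against a vocabulary.

    Rows follow ``events`` order; columns are ``vocab.columns``.  The code
    blocks are filled from the ``diagnoses``/``medications_list`` tables via
    ``encounter_id``; rows without any vocabulary code get all-zero blocks.
    """
    n = len(events)
    X = np.zeros((n, len(vocab.columns)), dtype=np.uint8)
    col_ix = {c: i for i, c in enumerate(vocab.columns)}

    bins = events["age_years"].map(bin_age)
    for b in AGE_BINS:
        X[:, col_ix[f"age_{b}"]] = (bins == b).to_numpy()
    X[:, col_ix["sex_F"]] = (events["sex"] == "F").to_numpy()
    for r in ("Caucasian", "Black", "Other"):
        X[:, col_ix[f"race_{r}"]] = (events["race"] == r).to_numpy()
    X[:, col_ix["eth_Hispanic"]] = (events["ethnicity"] == "Hispanic").to_numpy()
    for f in ("icu", "telemetry", "stepdown", "obgyn"):
        X[:, col_ix[f]] = events[f].astype(bool).to_numpy()

    row_of = pd.Series(np.arange(n), index=events["encounter_id"].to_numpy())
    for table, codes, prefix, col in (
        (diagnoses, vocab.top_diagnoses, "dx", None),
        (medications_list, vocab.top_medications, "med", None),
    ):
        if table is None or len(table) == 0:
            continue
        code_col = table.columns[1]
        keep = table[table[code_col].isin(codes) & table["encounter_id"].isin(row_of.index)]
        rows = row_of.reindex(keep["encounter_id"]).to_numpy()
        cols = keep[code_col].map(lambda c: col_ix[f"{prefix}:{c}"]).to_numpy()
        if len(rows):
            X[rows.astype(int), cols.astype(int)] = 1
    return X


@dataclass
class ClusterModel:
    """Fitted Hamming K-means: binary centroids plus the fit trace."""

    k: int
    centroids: np.ndarray
    labels: np.ndarray
    inertia: float
    inertia_trace: list
    n_iter: int
    seed: int

    def save(self, path) -> None:
        lines = [f"k={self.k}", f"inertia={self.inertia}", f"seed={self.seed}",
                 f"n_iter={self.n_iter}"]
        lines += ["".join(str(int(b)) for b in row) for row in self.centroids]
        from pathlib import Path
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path) -> "ClusterModel":
        from pathlib import Path
        lines = Path(path).read_text().splitlines()
        meta = dict(line.split("=", 1) for line in lines[:4])
        cents = np.array([[int(ch) for ch in line] for line in lines[4:]], dtype=np.uint8)
        return cls(k=int(meta["k"]), centroids=cents, labels=np.array([], dtype=int),
                   inertia=float(meta["inertia"]), inertia_trace=[],
                   n_iter=int(meta["n_iter"]), seed=int(meta["seed"]))


def _hamming_distances(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    Xf = X.astype(np.float32)
    Cf = C.astype(np.float32)
    return Xf.sum(1, keepdims=True) + Cf.sum(1)[None, :] - 2.0 * (Xf @ Cf.T)


def _majority_centroids(X: np.ndarray, labels: np.ndarray, k: int, prev: np.ndarray) -> np.ndarray:
    # per-column majority bit; exact 50/50 ties resolve to 0
    C = prev.copy()
    for j in range(k):
        members = X[labels == j]
        if len(members):
            C[j] = (2 * members.sum(0) > len(members)).astype(np.uint8)
    return C


def kmeans_hamming(
    X: np.ndarray, k: int, seed: int = 0, max_iter: int = 100, n_init: int = 4
) -> ClusterModel:
    """Lloyd-style K-means under Hamming distance on a binary matrix.

    Assignment is nearest-centroid (ties to the lowest cluster index);
    centroids are per-column majority bits, which minimize within-cluster
    Hamming inertia for a fixed assignment.  A cluster that empties is
    reseeded with the row currently farthest from its centroid.  Each
    restart stops when labels stabilize or after ``max_iter`` sweeps; the
    best of ``n_init`` seeded restarts (lowest inertia, first wins ties) is
    returned.  On matrices with few distinct rows every k-subset of distinct
    rows is tried as an initialization instead, which makes tiny instances
    deterministically reach the global optimum.
    """
    from itertools import combinations
    from math import comb

    Xa = np.ascontiguousarray(X, dtype=np.uint8)
    if k >= 2 and len(Xa) >= k:
        uniq = np.unique(Xa, axis=0)
        if len(uniq) >= k and comb(len(uniq), k) <= 64:
            best = None
            for subset in combinations(range(len(uniq)), k):
                model = _kmeans_single(Xa, k, seed=seed, max_iter=max_iter,
                                       init=uniq[list(subset)])
                if best is None or model.inertia < best.inertia:
                    best = model
            best.seed = seed
            return best
    best = None
    for i in range(max(1, n_init)):
        model = _kmeans_single(Xa, k, seed=seed + i, max_iter=max_iter)
        if best is None or model.inertia < best.inertia:
            best = model
    best.seed = seed
    return best


def _kmeans_single(
    X: np.ndarray, k: int, seed: int, max_iter: int, init: np.ndarray | None = None
) -> ClusterModel:
    X = np.ascontiguousarray(X, dtype=np.uint8)
    n = len(X)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError("need at least k rows")
    rng = np.random.default_rng(seed)

    if init is not None:
        C = np.ascontiguousarray(init, dtype=np.uint8).copy()
    else:
        uniq = np.unique(X, axis=0)
        if len(uniq) >= k:
            C = uniq[rng.choice(len(uniq), size=k, replace=False)].copy()
        else:
            C = X[rng.choice(n, size=k, replace=False)].copy()

    labels = np.full(n, -1)
    trace: list[float] = []
    for it in range(1, max_iter + 1):
        D = _hamming_distances(X, C)
        new_labels = D.argmin(axis=1)
        # reseed empty clusters with the farthest row from its centroid
        for j in range(k):
            if not (new_labels == j).any():
                far = D[np.arange(n), new_labels].argmax()
                C[j] = X[far]
                D = _hamming_distances(X, C)
                new_labels = D.argmin(axis=1)
        inertia = float(D[np.arange(n), new_labels].sum())
        trace.append(inertia)
        if (new_labels == labels).all():
            break
        labels = new_labels
        C = _majority_centroids(X, labels, k, C)

    D = _hamming_distances(X, C)
    labels = D.argmin(axis=1)
    inertia = float(D[np.arange(n), labels].sum())
    trace.append(inertia)
    return ClusterModel(k=k, centroids=C, labels=labels, inertia=inertia,
                        inertia_trace=trace, n_iter=it, seed=seed)


def assign(X: np.ndarray, model: ClusterModel) -> np.ndarray:
    """Nearest-centroid Hamming assignment (ties to the lowest index)."""
    X = np.asarray(X, dtype=np.uint8)
    if X.shape[1] != model.centroids.shape[1]:
        raise ValueError("column count does not match the fitted vocabulary")
    return _hamming_distances(X, model.centroids).argmin(axis=1)


def elbow_scan(
    X: np.ndarray,
    k_range=range(2, 31),
    seed: int = 0,
    sample_size: int = 10_000,
    max_iter: int = 100,
    n_init: int = 4,
) -> dict:
    """Inertia per k on a seeded without-replacement sample of the rows."""
    rng = np.random.default_rng(seed)
    n = len(X)
    if n > sample_size:
        idx = rng.choice(n, size=sample_size, replace=False)
        Xs = X[np.sort(idx)]
    else:
        Xs = X
    return {int(k): kmeans_hamming(Xs, k, seed=seed, max_iter=max_iter, n_init=n_init).inertia
            for k in k_range}


def choose_k_elbow(curve: dict) -> int:
    """Pick k by the maximum second difference of the inertia curve."""
    ks = sorted(curve)
    if len(ks) < 3:
        return ks[0]
    best_k, best = ks[1], -np.inf
    for i in range(1, len(ks) - 1):
        d2 = curve[ks[i - 1]] - 2 * curve[ks[i]] + curve[ks[i + 1]]
        if d2 > best:
            best, best_k = d2, ks[i]
    return best_k
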