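"""Mantel-test meta-analysis of pathway fingerprints.

Each mechanism's MetPA outcome places every pathway at a point in the
(-log10 p, impact) plane; the Euclidean distances between pathways form a
dissimilarity matrix. Two mechanisms' fingerprints are compared by unfolding
the lower triangles of their dissimilarity matrices and taking the Pearson
correlation (the Z_M score); significance comes from jointly permuting the
row/column (pathway) labels of one matrix — the only exchangeable Mantel
null. The test is one-sided for positive association: small and large
distances in one fingerprint co-occurring with small and large distances in
the other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io import ValidationError
from .pathways import PathwayFingerprint


@dataclass
class DissimilarityMatrix:
    pathway_ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.pathway_ids),) * 2:
            raise ValidationError("dissimilarity matrix shape mismatch")
        if not np.allclose(v, v.T):
            raise ValidationError("dissimilarity matrix not symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValidationError("dissimilarity matrix diagonal not zero")

    def lower_triangle(self) -> np.ndarray:
        i, j = np.tril_indices(len(self.pathway_ids), k=-1)
        return self.values[i, j]


@dataclass
class MantelResult:
    pair: tuple[str, str]
    r: float
    p_value: float
    n_pathways: int
    B: int

    def to_dict(self) -> dict:
        return {"pair": list(self.pair), "r": float(self.r),
                "p_value": float(self.p_value),
                "n_pathways": int(self.n_pathways), "B": int(self.B)}


def fingerprint_dissimilarity(
    fp: PathwayFingerprint,
    pathway_order: list[str],
    standardize: bool = False,
) -> DissimilarityMatrix:
    """Euclidean pathway-pathway distances in the (-log10 p, impact) plane.

    Pathways in ``pathway_order`` missing from the fingerprint are imputed at
    the null point (p = 1, impact = 0) with a warning. ``standardize``
    z-scales the two descriptors first (off by default: raw descriptors).
    """
    if len(pathway_order) < 3:
        raise ValidationError("need >= 3 shared pathways for a meaningful "
                              "dissimilarity structure")
    entries = fp.entries
    missing = [p for p in pathway_order if p not in entries.index]
    if missing:
        warnings.warn(
            f"{fp.mechanism or 'fingerprint'}: {len(missing)} pathway(s) absent; "
            f"imputed at (p=1, impact=0)"
        )
    coords = np.zeros((len(pathway_order), 2))
    for i, pid in enumerate(pathway_order):
        if pid in entries.index:
            coords[i, 0] = entries.loc[pid, "neg_log10_p"]
            coords[i, 1] = entries.loc[pid, "impact"]
    if standardize:
        sd = coords.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        coords = (coords - coords.mean(axis=0)) / sd
    d = squareform(pdist(coords, metric="euclidean"))
    return DissimilarityMatrix(list(pathway_order), d)


def mantel_r(d1: DissimilarityMatrix, d2: DissimilarityMatrix) -> float:
    """Pearson correlation of the unfolded lower triangles."""
    x, y = d1.lower_triangle(), d2.lower_triangle()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero-variance distance triangle: r undefined")
    return float(np.corrcoef(x, y)[0, 1])


def mantel_test(
    d1: DissimilarityMatrix,
    d2: DissimilarityMatrix,
    B: int = 999,
    seed: int = 0,
    pair: tuple[str, str] = ("A", "B"),
) -> MantelResult:
    """One-sided Mantel permutation test between two dissimilarity matrices
    over the same ordered pathway set. p = (#{r_perm >= r_obs} + 1)/(B + 1)."""
    if d1.pathway_ids != d2.pathway_ids:
        raise ValidationError("dissimilarity matrices use different pathway "
                              "orderings")
    if B < 1:
        raise ValidationError("B must be >= 1")
    r_obs = mantel_r(d1, d2)
    n = len(d1.pathway_ids)
    rng = np.random.default_rng(seed)
    tri = np.tril_indices(n, k=-1)
    x = d1.values[tri]
    x_c = x - x.mean()
    x_den = np.sqrt((x_c**2).sum())
    count = 0
    for _ in range(B):
        perm = rng.permutation(n)
        yp = d2.values[np.ix_(perm, perm)][tri]
        y_c = yp - yp.mean()
        r_perm = float((x_c @ y_c) / (x_den * np.sqrt((y_c**2).sum())))
        if r_perm >= r_obs:
            count += 1
    p = (count + 1) / (B + 1)
    return MantelResult(pair, r_obs, float(p), n, B)


def pairwise_mechanism_matrix(
    fingerprints: list[PathwayFingerprint],
    B: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
    standardize: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, list[MantelResult]]:
    """All unordered pairs of mechanism fingerprints on their common pathway
    universe. Returns (r matrix, p matrix, results); the r matrix is symmetric
    with unit diagonal, and ``p < alpha`` marks the significant pairs."""
    if len(fingerprints) < 2:
        raise ValidationError("need >= 2 fingerprints")
    universe = sorted(set().union(*(set(f.entries.index) for f in fingerprints)))
    mechs = [f.mechanism for f in fingerprints]
    dmats = {
        f.mechanism: fingerprint_dissimilarity(f, universe, standardize=standardize)
        for f in fingerprints
    }
    r = pd.DataFrame(np.eye(len(mechs)), index=mechs, columns=mechs)
    p = pd.DataFrame(np.nan, index=mechs, columns=mechs)
    results = []
    for i in range(len(mechs)):
        for j in range(i + 1, len(mechs)):
            a, b = mechs[i], mechs[j]
            res = mantel_test(dmats[a], dmats[b], B=B,
                              seed=seed + 1000 * i + j, pair=(a, b))
            results.append(res)
            r.loc[a, b] = r.loc[b, a] = res.r
            p.loc[a, b] = p.loc[b, a] = res.p_value
    return r, p, results
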