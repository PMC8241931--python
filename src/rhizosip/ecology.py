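"""Community-ecology statistics: Shannon diversity, Bray–Curtis
dissimilarity, principal coordinates analysis, and PERMANOVA."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .models import DataError


def shannon(counts, base: Optional[float] = None) -> float:
    """Shannon diversity H = −Σ pᵢ log pᵢ over nonzero proportions.

    Natural log by default; pass ``base`` for other units. Accepts raw
    counts or proportions (normalized internally).
    """
    if isinstance(counts, Mapping):
        counts = list(counts.values())
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise DataError("negative counts")
    total = x.sum()
    if total <= 0:
        raise DataError("all-zero count vector")
    p = x[x > 0] / total
    p = p[p > 0]  # re-filter: tiny counts can underflow to 0 after division
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


@dataclass
class DissimilarityMatrix:
    sample_keys: list
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.sample_keys):
            raise DataError("dissimilarity matrix shape does not match sample keys")
        if not np.allclose(v, v.T, atol=1e-12):
            raise DataError("dissimilarity matrix is not symmetric")
        if not np.allclose(np.diag(v), 0, atol=1e-12):
            raise DataError("dissimilarity matrix has nonzero diagonal")
        if (v < -1e-12).any():
            raise DataError("negative dissimilarity")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.sample_keys)


def bray_curtis(table: pd.DataFrame) -> DissimilarityMatrix:
    """Bray–Curtis dissimilarities between sample columns.

    d(j, k) = Σᵢ|xᵢⱼ − xᵢₖ| / Σᵢ(xᵢⱼ + xᵢₖ) over genera i.
    """
    x = table.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise DataError("need at least 2 samples")
    if (x < 0).any():
        raise DataError("negative abundances")
    totals = x.sum(axis=0)
    if (totals <= 0).any():
        key = table.columns[int(np.argmin(totals))]
        raise DataError(f"sample {key} has zero total abundance")
    n = x.shape[1]
    d = np.zeros((n, n))
    for j in range(n):
        for k in range(j + 1, n):
            num = np.abs(x[:, j] - x[:, k]).sum()
            den = (x[:, j] + x[:, k]).sum()
            d[j, k] = d[k, j] = num / den
    return DissimilarityMatrix(sample_keys=list(table.columns), values=d)


@dataclass
class OrdinationResult:
    sample_keys: list
    coordinates: np.ndarray  # sample × axis, axes ordered by eigenvalue
    eigenvalues: np.ndarray  # all eigenvalues, descending
    variance_explained: np.ndarray  # positive axes / sum of positive eigenvalues
    negative_eigenvalue_note: str


def pcoa(matrix: DissimilarityMatrix) -> OrdinationResult:
    """Classical (metric) multidimensional scaling of a dissimilarity matrix.

    Double-centers the −d²/2 Gower matrix and eigendecomposes it. Axes with
    negative eigenvalues (non-Euclidean input) carry no coordinates;
    variance explained is reported relative to the sum of positive
    eigenvalues, with the uncorrected total recorded in the note.
    """
    d = matrix.values
    n = d.shape[0]
    a = -0.5 * d**2
    centering = np.eye(n) - np.ones((n, n)) / n
    g = centering @ a @ centering
    eigval, eigvec = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    pos = eigval > max(1e-12, 1e-10 * abs(eigval).max())
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    total_pos = eigval[pos].sum()
    var_exp = eigval[pos] / total_pos if total_pos > 0 else np.array([])
    neg_sum = float(eigval[eigval < 0].sum())
    note = (
        f"{int((eigval < -1e-12).sum())} negative eigenvalues (sum {neg_sum:.3g}) "
        "dropped from the variance-explained denominator; relative to the raw "
        f"eigenvalue sum the leading axis explains "
        f"{(eigval[0] / eigval.sum() if eigval.sum() != 0 else np.nan):.4f}"
    )
    return OrdinationResult(
        sample_keys=list(matrix.sample_keys),
        coordinates=coords,
        eigenvalues=eigval,
        variance_explained=var_exp,
        negative_eigenvalue_note=note,
    )


@dataclass
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    p_string: str
    n_permutations: int
    seed: Optional[int]
    df_among: int
    df_within: int


def _ss_within(d2: np.ndarray, labels: np.ndarray) -> float:
    ss = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss += sub.sum() / (2.0 * idx.size)
    return ss


def permanova(
    matrix: DissimilarityMatrix,
    groups: Mapping[Hashable, Hashable] | Sequence[Hashable],
    n_permutations: int = 999,
    seed: Optional[int] = None,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a dissimilarity matrix.

    pseudo-F = (SS_among/df_among) / (SS_within/df_within) with sums of
    squared dissimilarities; R² = SS_among/SS_total; the permutation p-value
    uses the (1 + exceedances)/(1 + permutations) convention. When the
    observed F exceeds every permuted F, ``p_string`` reports the
    resolution bound (e.g. ``"< 0.001"``).
    """
    if isinstance(groups, Mapping):
        labels = np.asarray([groups[k] for k in matrix.sample_keys], dtype=object)
    else:
        labels = np.asarray(list(groups), dtype=object)
    if labels.shape[0] != matrix.n:
        raise DataError("group labels do not match matrix samples")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise DataError("PERMANOVA needs at least 2 groups")
    n = matrix.n
    a = uniq.size
    d2 = matrix.values**2
    ss_total = d2.sum() / (2.0 * n)
    ss_within = _ss_within(d2, labels)
    ss_among = ss_total - ss_within
    df_among, df_within = a - 1, n - a
    if ss_within <= 0 or df_within == 0:
        f_obs = np.inf
    else:
        f_obs = (ss_among / df_among) / (ss_within / df_within)
    r2 = ss_among / ss_total if ss_total > 0 else 0.0

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        ssw = _ss_within(d2, labels[perm])
        if ssw <= 0:
            f_perm = np.inf
        else:
            f_perm = ((ss_total - ssw) / df_among) / (ssw / df_within)
        if f_perm >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    p_string = f"< {1.0 / (n_permutations + 1):g}" if exceed == 0 else f"{p:g}"
    return PermanovaResult(
        pseudo_f=float(f_obs),
        r_squared=float(r2),
        p_value=float(p),
        p_string=p_string,
        n_permutations=n_permutations,
        seed=seed,
        df_among=df_among,
        df_within=df_within,
    )
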