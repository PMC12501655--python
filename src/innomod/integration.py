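"""Morphological integration statistics and trait-module identification.

Morphological integration — the tendency of trait sets to covary through
shared development, genetics or function — is quantified here by the
relative standard deviation of the eigenvalues of the trait correlation
matrix, SDrel(lambda). For an M x M correlation matrix R with eigenvalues
lambda_1..lambda_M (mean 1):

    SDrel = sqrt( sum_i (lambda_i - 1)^2 / (M (M - 1)) )

i.e. the population standard deviation of the eigenvalues divided by its
maximum sqrt(M - 1), so SDrel lies in [0, 1]: 0 for the identity matrix (no
integration), 1 when a single dimension carries all variance. Algebraically
SDrel equals the root-mean-square off-diagonal correlation, which makes an
equicorrelation matrix with parameter rho >= 0 score exactly rho.

Under the null hypothesis of no integration, the correlation matrix of M
independent traits estimated from N observations has off-diagonal entries
with variance ~ 1/N, giving the expected dispersion

    E[SDrel | no integration] ~= sqrt(1 / (2 N))

which depends on the sample size only.

Trait modules are identified from a correlation-based PCA: traits whose
loading vectors point the same way in the leading component plane covary as
a block, and average-linkage hierarchical clustering of the loading vectors
(cosine distance) makes that visual judgment programmatic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io import OsteometricTable, TableValidationError, _check_traits, complete_cases

__all__ = [
    "TraitPartition",
    "INNOMINATE_PARTITION",
    "IntegrationReport",
    "correlation_matrix",
    "sdrel_lambda",
    "sdrel_null_expectation",
    "integration_report",
    "pca_loadings",
    "PcaResult",
    "cluster_loadings",
]


class InsufficientDataError(ValueError):
    """Too few complete cases to estimate the requested quantity."""


class DegenerateDataError(ValueError):
    """A trait is constant (zero variance) among the complete cases."""


@dataclass(frozen=True)
class TraitPartition:
    """A disjoint, exhaustive grouping of trait names into modules.

    Module order is normalised (sorted by smallest member) so two
    partitions with the same groupings compare equal regardless of the
    order they were built in. ``labels``, when given, follow the modules
    through the normalisation.
    """

    modules: tuple[frozenset[str], ...]
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        mods = [frozenset(m) for m in self.modules]
        if not mods or any(not m for m in mods):
            raise TableValidationError("partition modules must be non-empty")
        all_traits = [t for m in mods for t in m]
        if len(all_traits) != len(set(all_traits)):
            raise TableValidationError("partition modules must be disjoint")
        labels = list(self.labels) if self.labels is not None else None
        if labels is not None and len(labels) != len(mods):
            raise TableValidationError("one label per module required")
        order = sorted(range(len(mods)), key=lambda i: min(mods[i]))
        object.__setattr__(self, "modules", tuple(mods[i] for i in order))
        if labels is not None:
            object.__setattr__(self, "labels", tuple(labels[i] for i in order))

    @property
    def trait_set(self) -> frozenset[str]:
        return frozenset(t for m in self.modules for t in m)

    def to_dict(self) -> dict:
        return {
            "modules": [sorted(m) for m in self.modules],
            "labels": list(self.labels) if self.labels else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TraitPartition":
        labels = d.get("labels")
        return cls(
            modules=tuple(frozenset(m) for m in d["modules"]),
            labels=tuple(labels) if labels else None,
        )


#: The three innominate modules: the isolated greater-sciatic-notch trait,
#: the pelvic outlet (overall pelvic breadth) and the pelvic inlet
#: (internal pelvic dimensions).
INNOMINATE_PARTITION = TraitPartition(
    modules=(
        frozenset({"IIMT"}),
        frozenset({"PUM", "SA", "SCOX"}),
        frozenset({"DCOX", "SS", "ISMM", "SPU"}),
    ),
    labels=("ilium", "pelvic outlet", "pelvic inlet"),
)


def correlation_matrix(
    table: OsteometricTable, traits: Iterable[str]
) -> tuple[pd.DataFrame, int]:
    """Pearson correlation matrix on complete cases for exactly *traits*.

    Returns ``(R, N)`` where ``N`` is the number of complete cases used.
    Because completeness is evaluated per subset, dropping a badly-missing
    trait can increase N.
    """
    traits = _check_traits(traits)
    cc = complete_cases(table, traits)
    n = len(cc)
    if n < 3:
        raise InsufficientDataError(
            f"only {n} complete case(s) for traits {traits}; need >= 3"
        )
    x = cc.values(traits)
    sds = x.std(axis=0, ddof=1)
    flat = [t for t, s in zip(traits, sds) if s == 0.0]
    if flat:
        raise DegenerateDataError(f"zero-variance trait(s): {', '.join(flat)}")
    r = np.corrcoef(x, rowvar=False)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=traits, columns=traits), n


def _as_corr_array(corr) -> np.ndarray:
    r = np.asarray(corr, dtype=float) if not isinstance(corr, pd.DataFrame) else corr.to_numpy()
    if r.ndim != 2 or r.shape[0] != r.shape[1] or r.shape[0] < 2:
        raise TableValidationError("correlation matrix must be square, M >= 2")
    if not np.allclose(r, r.T, atol=1e-8):
        raise TableValidationError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(r), 1.0, atol=1e-8):
        raise TableValidationError("correlation matrix must have unit diagonal")
    return r


def sdrel_lambda(corr) -> float:
    """Relative standard deviation of correlation-matrix eigenvalues.

    ``sqrt(sum (lambda_i - 1)^2 / (M (M-1)))`` — equal to the RMS
    off-diagonal correlation; in [0, 1].
    """
    r = _as_corr_array(corr)
    m = r.shape[0]
    lam = np.linalg.eigvalsh(r)
    return float(np.sqrt(np.sum((lam - 1.0) ** 2) / (m * (m - 1))))


def sdrel_null_expectation(n: int) -> float:
    """Expected SDrel for M independent traits sampled N times: sqrt(1/(2N)).

    Sampling noise alone inflates off-diagonal correlations (variance about
    1/N each), so the no-integration benchmark decreases with sample size.
    """
    if n < 2:
        raise TableValidationError(f"sample size must be >= 2, got {n}")
    return float(np.sqrt(1.0 / (2.0 * n)))


@dataclass(frozen=True)
class IntegrationReport:
    """Integration summary for one trait subset."""

    traits: tuple[str, ...]
    n: int                      # complete cases used
    m: int                      # number of traits
    eigenvalues: tuple[float, ...]
    sdrel: float
    null_expectation: float

    def to_dict(self) -> dict:
        return {
            "traits": list(self.traits),
            "N": self.n,
            "M": self.m,
            "eigenvalues": list(self.eigenvalues),
            "sdrel": self.sdrel,
            "null_expectation": self.null_expectation,
        }


def integration_report(
    table: OsteometricTable, traits: Iterable[str]
) -> IntegrationReport:
    """Assemble N, M, eigenvalues, SDrel and its null expectation for *traits*."""
    traits = _check_traits(traits)
    r, n = correlation_matrix(table, traits)
    lam = np.sort(np.linalg.eigvalsh(r.to_numpy()))[::-1]
    lam = np.clip(lam, 0.0, None)
    return IntegrationReport(
        traits=tuple(traits),
        n=n,
        m=len(traits),
        eigenvalues=tuple(float(v) for v in lam),
        sdrel=sdrel_lambda(r),
        null_expectation=sdrel_null_expectation(n),
    )


@dataclass(frozen=True)
class PcaResult:
    """Correlation-based PCA of a trait subset.

    ``loadings``: traits x PCs, orthonormal columns (eigenvectors of the
    correlation matrix), columns ordered by decreasing eigenvalue, each
    column signed so its largest-magnitude entry is positive.
    ``explained_variance``: the eigenvalues (summing to M).
    ``scores``: complete-case individuals x PCs, standardized data
    projected on the loadings.
    """

    loadings: pd.DataFrame
    explained_variance: tuple[float, ...]
    scores: pd.DataFrame
    n: int = field(default=0)


def pca_loadings(table: OsteometricTable, traits: Iterable[str]) -> PcaResult:
    """Eigen-decomposition of the complete-case correlation matrix."""
    traits = _check_traits(traits)
    r, n = correlation_matrix(table, traits)
    lam, vec = np.linalg.eigh(r.to_numpy())
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    # sign convention: largest-|entry| of each column positive
    for j in range(vec.shape[1]):
        i = int(np.argmax(np.abs(vec[:, j])))
        if vec[i, j] < 0:
            vec[:, j] = -vec[:, j]
    pcs = [f"PC{j + 1}" for j in range(len(traits))]
    loadings = pd.DataFrame(vec, index=traits, columns=pcs)
    cc = complete_cases(table, traits)
    x = cc.values(traits)
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    scores = pd.DataFrame(z @ vec, index=cc.ids, columns=pcs)
    return PcaResult(
        loadings=loadings,
        explained_variance=tuple(float(v) for v in lam),
        scores=scores,
        n=n,
    )


def cluster_loadings(
    loadings: pd.DataFrame, k: int = 3, n_pcs: int = 2
) -> TraitPartition:
    """Group traits by the direction of their loading vectors.

    Average-linkage hierarchical clustering of the trait loading vectors
    (rows restricted to the first *n_pcs* PCs) under distance
    1 - cosine similarity, cut at *k* clusters. Rows are processed in
    lexicographic trait order so linkage ties resolve deterministically.
    """
    traits = list(loadings.index)
    m = len(traits)
    if not 1 <= k <= m:
        raise TableValidationError(f"k must be in [1, {m}], got {k}")
    if not 1 <= n_pcs <= loadings.shape[1]:
        raise TableValidationError(
            f"n_pcs must be in [1, {loadings.shape[1]}], got {n_pcs}"
        )
    order = sorted(range(m), key=lambda i: traits[i])
    vecs = loadings.to_numpy()[order, :n_pcs]
    names = [traits[i] for i in order]
    norms = np.linalg.norm(vecs, axis=1)
    unit = np.divide(vecs, norms[:, None], out=np.zeros_like(vecs), where=norms[:, None] > 1e-12)
    dist = 1.0 - unit @ unit.T
    np.fill_diagonal(dist, 0.0)
    dist[dist < 0] = 0.0
    z = linkage(squareform(dist, checks=False), method="average")
    flat = fcluster(z, t=k, criterion="maxclust")
    groups: dict[int, set[str]] = {}
    for name, g in zip(names, flat):
        groups.setdefault(int(g), set()).add(name)
    return TraitPartition(modules=tuple(frozenset(g) for g in groups.values()))
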