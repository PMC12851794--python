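"""Cophylogenetic congruence between host and phage phylogenies.

Two complementary global-fit analyses are provided:

* **PACo** (Procrustes Approach to Cophylogeny): host and phage patristic
  distance matrices are embedded by principal coordinates analysis; for
  each host–phage association a row pairing the host's and the phage's
  coordinates is formed, and the phage configuration is superimposed onto
  the host configuration by least-squares Procrustes rotation/scaling.
  The global sum of squared residuals (m²) measures departure from
  codivergence, with significance from permutations of the phage column of
  the association list.  Per-association squared residuals rank individual
  links; those above the 95th percentile are flagged as candidate host
  jumps (host-switching events).

* **ParaFitGlobal**: the trace statistic ``sum(D**2)`` with
  ``D = C' A B`` — phage principal coordinates ``C``, binary association
  matrix ``A`` (phages × hosts) and host principal coordinates ``B`` —
  tested by independently permuting each phage's row of ``A``.

Negative PCoA eigenvalues (patristic matrices need not be Euclidean) are
handled by the Cailliez additive correction.  Permutation p-values use the
add-one estimator, so the smallest attainable p is ``1/(n_perm + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .io_formats import AssociationTable, LabeledMatrix

__all__ = [
    "Ordination",
    "ProcrustesFit",
    "CophylogenyResult",
    "pcoa",
    "procrustes_fit",
    "paco_global",
    "parafit_global",
    "classify_host_jumps",
]

_EIG_TOL = 1e-8


@dataclass
class Ordination:
    labels: list[str]
    coordinates: np.ndarray  # points x axes
    eigenvalues: np.ndarray  # per retained axis, decreasing
    correction_applied: str  # "none" | "cailliez"

    def row(self, label: str) -> np.ndarray:
        return self.coordinates[self.labels.index(label)]


@dataclass
class ProcrustesFit:
    rotation: np.ndarray
    scale: float
    translation: np.ndarray
    m2: float
    residuals_sq: np.ndarray


@dataclass
class CophylogenyResult:
    m2_observed: float
    p_value: float
    n_perm: int
    seed: int | None
    residuals_sq: np.ndarray
    associations: list[tuple[str, str]]
    jump_flags: np.ndarray | None = None
    threshold_value: float | None = None


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d
    row = a.mean(axis=0)
    return a - row[:, None] - row[None, :] + a.mean()


def _cailliez_constant(d: np.ndarray) -> float:
    """Smallest constant c such that d + c (off-diagonal) is Euclidean."""
    n = d.shape[0]
    delta1 = _gower_center(d**2)
    delta2 = _gower_center(d)
    upper = np.hstack([np.zeros((n, n)), 2.0 * delta1])
    lower = np.hstack([-np.eye(n), -4.0 * delta2])
    eigvals = scipy.linalg.eigvals(np.vstack([upper, lower]))
    real = eigvals.real[np.abs(eigvals.imag) < 1e-8]
    return float(real.max())


def pcoa(matrix: LabeledMatrix) -> Ordination:
    """Principal coordinates analysis of a distance matrix.

    Gower double-centering of ``-0.5 d**2`` followed by a symmetric
    eigendecomposition; axes with eigenvalue > 1e-8 are retained and scaled
    by the square root of their eigenvalue.  If a meaningfully negative
    eigenvalue appears the Cailliez additive correction is applied and the
    decomposition recomputed (the corrected matrix is Euclidean, so the
    embedding then reproduces ``d + c`` off-diagonal exactly).
    """
    d = np.asarray(matrix.values, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite distances")

    def decompose(dist: np.ndarray):
        b = _gower_center(dist**2)
        eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
        order = np.argsort(eigval)[::-1]
        return eigval[order], eigvec[:, order]

    correction = "none"
    eigval, eigvec = decompose(d)
    if eigval.min() < -_EIG_TOL:
        c = _cailliez_constant(d)
        d = d + c
        np.fill_diagonal(d, 0.0)
        correction = "cailliez"
        eigval, eigvec = decompose(d)
    keep = eigval > _EIG_TOL
    coords = eigvec[:, keep] * np.sqrt(eigval[keep])
    return Ordination(
        labels=list(matrix.labels),
        coordinates=coords,
        eigenvalues=eigval[keep],
        correction_applied=correction,
    )


def _pad_columns(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    width = max(x.shape[1], y.shape[1], 1)
    def pad(m: np.ndarray) -> np.ndarray:
        if m.shape[1] == width:
            return m
        out = np.zeros((m.shape[0], width))
        out[:, : m.shape[1]] = m
        return out
    return pad(x), pad(y)


def procrustes_fit(x: np.ndarray, y: np.ndarray) -> ProcrustesFit:
    """Least-squares superimposition of ``y`` onto ``x`` (asymmetric).

    Both configurations are column-centered; ``y`` is then rotated
    (orthogonal transform from the SVD of the cross-product) and uniformly
    scaled to minimise ``sum(||x - s y Q||**2)``.  ``m2`` is the minimised
    value; per-row squared residuals are returned.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape[0] != y.shape[0]:
        raise ValueError("x and y must have the same number of rows")
    if x.shape[0] < 2:
        raise ValueError("procrustes_fit requires at least 2 rows")
    x, y = _pad_columns(x, y)
    x_mean = x.mean(axis=0)
    y_mean = y.mean(axis=0)
    xc = x - x_mean
    yc = y - y_mean
    u, sv, vt = np.linalg.svd(yc.T @ xc)
    rotation = u @ vt
    yss = (yc**2).sum()
    scale = sv.sum() / yss if yss > 0 else 0.0
    fitted = scale * yc @ rotation
    residuals_sq = ((xc - fitted) ** 2).sum(axis=1)
    return ProcrustesFit(
        rotation=rotation,
        scale=float(scale),
        translation=x_mean - scale * y_mean @ rotation,
        m2=float(residuals_sq.sum()),
        residuals_sq=residuals_sq,
    )


def _association_rows(
    ordination: Ordination, ids: list[str]
) -> np.ndarray:
    index = {lab: i for i, lab in enumerate(ordination.labels)}
    try:
        rows = [index[i] for i in ids]
    except KeyError as exc:
        raise KeyError(f"unresolvable id {exc.args[0]!r}") from None
    return ordination.coordinates[rows]


def paco_global(
    host_d: LabeledMatrix,
    phage_d: LabeledMatrix,
    assoc: AssociationTable,
    n_perm: int = 10000,
    seed: int | None = None,
) -> CophylogenyResult:
    """PACo global-fit test.

    The null distribution is obtained by permuting the phage column of the
    association list (association count preserved) and re-fitting the
    Procrustes superimposition each time;
    ``p = (1 + #{m2_perm <= m2_obs}) / (1 + n_perm)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if len(host_d) < 3 or len(phage_d) < 3:
        raise ValueError("need at least 3 hosts and 3 phages")
    assoc.validate_against(host_d.labels, phage_d.labels)
    host_ord = pcoa(host_d)
    phage_ord = pcoa(phage_d)
    x = _association_rows(host_ord, assoc.hosts)
    y = _association_rows(phage_ord, assoc.phages)
    observed = procrustes_fit(x, y)
    rng = np.random.default_rng(seed)
    phages = list(assoc.phages)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(phages))
        y_perm = _association_rows(phage_ord, [phages[i] for i in perm])
        if procrustes_fit(x, y_perm).m2 <= observed.m2:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return CophylogenyResult(
        m2_observed=observed.m2,
        p_value=p,
        n_perm=n_perm,
        seed=seed,
        residuals_sq=observed.residuals_sq,
        associations=list(assoc.links),
    )


def classify_host_jumps(
    residuals_sq: np.ndarray, quantile: float = 0.95
) -> tuple[np.ndarray, float]:
    """Flag candidate host jumps from Procrustes squared residuals.

    The threshold is the empirical quantile with linear interpolation
    between order statistics (position ``1 + q(n-1)``); associations with
    residuals *strictly* above the threshold are flagged.
    """
    residuals_sq = np.asarray(residuals_sq, dtype=float)
    if residuals_sq.size < 2:
        raise ValueError("need at least 2 residuals")
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    threshold = float(np.quantile(residuals_sq, quantile, method="linear"))
    flags = residuals_sq > threshold
    return flags, threshold


def parafit_global(
    host_d: LabeledMatrix,
    phage_d: LabeledMatrix,
    assoc: AssociationTable,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """ParaFitGlobal statistic and permutation p-value.

    ``stat = sum(D**2)`` with ``D = C' A B``; the null permutes each
    phage's row of the binary association matrix independently;
    ``p = (1 + #{stat_perm >= stat_obs}) / (1 + n_perm)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if len(host_d) < 3 or len(phage_d) < 3:
        raise ValueError("need at least 3 hosts and 3 phages")
    assoc.validate_against(host_d.labels, phage_d.labels)
    host_ord = pcoa(host_d)
    phage_ord = pcoa(phage_d)
    b = host_ord.coordinates  # hosts x axes
    c = phage_ord.coordinates  # phages x axes
    host_index = {lab: i for i, lab in enumerate(host_d.labels)}
    phage_index = {lab: i for i, lab in enumerate(phage_d.labels)}
    a = np.zeros((len(phage_d), len(host_d)))
    for h, p in assoc.links:
        a[phage_index[p], host_index[h]] = 1.0

    def stat(mat: np.ndarray) -> float:
        d = c.T @ mat @ b
        return float((d**2).sum())

    observed = stat(a)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm_a = np.empty_like(a)
        for row in range(a.shape[0]):
            perm_a[row] = a[row, rng.permutation(a.shape[1])]
        if stat(perm_a) >= observed:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return observed, p
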