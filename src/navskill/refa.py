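"""Regularised exploratory factor analysis (REFA) of the task z-scores.

Small samples (n < 50) make the sample correlation matrix of the eight
task scores near-singular, so ordinary maximum-likelihood exploratory
factor analysis (ML EFA) behaves erratically.  REFA stabilises the fit by
assuming the unique variances are *proportional to a tentative estimate*:

    Psi = lambda * Psi_tilde,   Psi_tilde_j = 1 / (R^-1)_jj,

where Psi_tilde is the anti-image estimate (the variance of variable j
unexplained by all other variables) and the single proportionality
parameter lambda is estimated by maximum likelihood.  This replaces the p
free uniquenesses of ML EFA by one parameter.  ``lam=0`` requests the
unregularised standard ML EFA instead (p free uniquenesses), which serves
as the cross-check against independent ML-EFA implementations.

The number of factors is estimated by a permutation test (equivalent to
parallel analysis): the k-th factor is retained while the k-th observed
eigenvalue of R exceeds the (1 - alpha) quantile of the k-th eigenvalues
obtained after permuting each column of Z independently.

The unrotated ML solution is rotated by an oblique geomin rotation from
many random starts.  Geomin is multi-modal; converged solutions are
clustered (up to column permutation and sign) into distinct "sets" of
factors, each satisfying simple structure.  Communalities are rotation
invariant, so every set reports the same communalities.

Usage::

    model = REFA(z_matrix, n_factors=3)
    res = model.fit(seed=0)
    res.rotation_sets[0].loadings
    res.communality_report()
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "REFA",
    "REFAResults",
    "FactorSolution",
    "RotationSet",
    "RotationSetCollection",
    "CommunalityReport",
    "anti_image_unique_variances",
    "fit_ml_efa",
    "fit_refa",
    "estimate_n_factors_permutation",
    "geomin_criterion",
    "geomin_rotate",
    "communalities",
    "canonical_loadings",
    "tucker_congruence",
]

PSI_FLOOR = 0.005  # Heywood floor on uniquenesses


# ---------------------------------------------------------------------------
# tentative unique variances


def anti_image_unique_variances(R: np.ndarray) -> np.ndarray:
    """Anti-image estimate: Psi_tilde_j = 1 / (R^-1)_jj.

    The variance of variable j left unexplained by a regression on all the
    other variables; always <= 1 for a correlation matrix.
    """
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("R must be square")
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("R must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-8):
        raise ValueError("R must have a unit diagonal")
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "correlation matrix is singular; consider ridge pre-conditioning "
            "(add a small multiple of the identity) before the anti-image estimate"
        ) from exc
    cond = np.linalg.cond(R)
    if cond > 1e12:
        raise np.linalg.LinAlgError(
            f"correlation matrix is numerically singular (cond={cond:.2e}); "
            "consider ridge pre-conditioning"
        )
    return 1.0 / np.diag(Rinv)


# ---------------------------------------------------------------------------
# ML discrepancy profiled over loadings


def _profile_objective(psi: np.ndarray, R: np.ndarray, m: int) -> float:
    """ML discrepancy with loadings profiled out, as a function of psi."""
    sc = 1.0 / np.sqrt(psi)
    Rstar = R * np.outer(sc, sc)
    e = np.linalg.eigvalsh(Rstar)[::-1][m:]
    e = np.maximum(e, 1e-12)
    return float(np.sum(e - np.log(e) - 1.0))


def _loadings_from_psi(psi: np.ndarray, R: np.ndarray, m: int) -> np.ndarray:
    """Canonical ML loadings for fixed psi (Lambda' Psi^-1 Lambda diagonal)."""
    sc = 1.0 / np.sqrt(psi)
    Rstar = R * np.outer(sc, sc)
    w, V = np.linalg.eigh(Rstar)
    idx = np.argsort(w)[::-1][:m]
    lam = np.maximum(w[idx] - 1.0, 0.0)
    L = V[:, idx] * np.sqrt(lam)
    L = L * np.sqrt(psi)[:, None]
    # sign convention: largest-magnitude element of each column positive
    for j in range(m):
        k = np.argmax(np.abs(L[:, j]))
        if L[k, j] < 0:
            L[:, j] = -L[:, j]
    return L


def _profile_gradient(psi: np.ndarray, R: np.ndarray, m: int) -> np.ndarray:
    L = _loadings_from_psi(psi, R, m)
    Sigma_diag_gap = np.sum(L**2, axis=1) + psi - np.diag(R)
    return Sigma_diag_gap / psi**2


@dataclass
class FactorSolution:
    """An (un)rotated ML factor solution."""

    loadings: np.ndarray  # p x m
    uniquenesses: np.ndarray  # p
    factor_corr: np.ndarray  # m x m (identity when unrotated)
    lam: float | None  # regularisation parameter; None for free-psi ML EFA
    n_factors: int
    discrepancy: float
    heywood: bool = False
    converged: bool = True

    def __post_init__(self) -> None:
        if np.any(self.uniquenesses <= 0):
            raise ValueError("uniquenesses must be positive")
        Phi = self.factor_corr
        if not np.allclose(Phi, Phi.T, atol=1e-8) or not np.allclose(np.diag(Phi), 1.0, atol=1e-6):
            raise ValueError("factor correlation matrix must be symmetric with unit diagonal")

    @property
    def model_correlation(self) -> np.ndarray:
        """Reconstructed correlation matrix Lambda Phi Lambda' + Psi."""
        L, Phi = self.loadings, self.factor_corr
        return L @ Phi @ L.T + np.diag(self.uniquenesses)


def fit_ml_efa(R: np.ndarray, m: int, psi_start: np.ndarray | None = None) -> FactorSolution:
    """Standard ML exploratory factor analysis of a correlation matrix.

    Minimises the ML discrepancy over the p uniquenesses with the loadings
    profiled out; uniquenesses are floored at 0.005 (Heywood handling, the
    hit is flagged on the returned solution).
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    if m < 1:
        raise ValueError("number of factors must be >= 1")
    if m > p:
        raise ValueError(f"cannot extract {m} factors from {p} variables")
    if psi_start is None:
        psi_start = (1.0 - 0.5 * m / p) / np.diag(np.linalg.inv(R))
    res = optimize.minimize(
        _profile_objective,
        np.clip(psi_start, PSI_FLOOR, 1.0),
        args=(R, m),
        jac=_profile_gradient,
        method="L-BFGS-B",
        bounds=[(PSI_FLOOR, 1.0)] * p,
        options={"maxiter": 1000, "ftol": 1e-14, "gtol": 1e-10},
    )
    psi = res.x
    heywood = bool(np.any(psi <= PSI_FLOOR + 1e-9))
    if heywood:
        warnings.warn("Heywood case: uniqueness floored at 0.005", stacklevel=2)
    return FactorSolution(
        loadings=_loadings_from_psi(psi, R, m),
        uniquenesses=psi,
        factor_corr=np.eye(m),
        lam=None,
        n_factors=m,
        discrepancy=float(res.fun),
        heywood=heywood,
        converged=bool(res.success),
    )


def fit_refa(
    Z: np.ndarray | pd.DataFrame,
    m: int,
    lam: float | None = None,
) -> FactorSolution:
    """Fit the (regularised) ML factor model to a score matrix.

    lam=None  : one-parameter REFA — Psi = lambda * Psi_tilde with the
                scalar lambda estimated by ML (anti-image assumption).
    lam=0     : unregularised standard ML EFA (p free uniquenesses).
    lam>0     : Psi fixed at lam * Psi_tilde.
    """
    Z = np.asarray(Z, dtype=float)
    n, p = Z.shape
    if m < 1:
        raise ValueError("number of factors must be >= 1")
    if n < m + 1:
        raise ValueError(f"need at least m+1={m + 1} observations, got {n}")
    R = np.corrcoef(Z, rowvar=False)
    if lam is not None and lam == 0:
        return fit_ml_efa(R, m)
    psi_tilde = anti_image_unique_variances(R)
    if lam is None:
        lam_hi = 1.0 / float(np.max(psi_tilde))

        def f(lam_scalar: float) -> float:
            return _profile_objective(lam_scalar * psi_tilde, R, m)

        res = optimize.minimize_scalar(f, bounds=(1e-3, lam_hi), method="bounded")
        lam = float(res.x)
    if lam <= 0:
        raise ValueError("lam must be positive (or exactly 0 for plain ML EFA)")
    psi = np.clip(lam * psi_tilde, PSI_FLOOR, None)
    return FactorSolution(
        loadings=_loadings_from_psi(psi, R, m),
        uniquenesses=psi,
        factor_corr=np.eye(m),
        lam=lam,
        n_factors=m,
        discrepancy=_profile_objective(psi, R, m),
    )


# ---------------------------------------------------------------------------
# number of factors


def estimate_n_factors_permutation(
    Z: np.ndarray | pd.DataFrame,
    n_permutations: int = 500,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
    permute: str = "columns",
) -> int:
    """Permutation test (parallel analysis) for the number of factors.

    Each column of Z is permuted independently ``n_permutations`` times;
    the k-th factor is retained while the k-th observed eigenvalue of the
    correlation matrix exceeds the (1 - alpha) quantile of the permuted
    k-th eigenvalues, stopping at the first failure.
    """
    if permute != "columns":
        raise ValueError(
            "only independent column permutation breaks the correlation structure; "
            "permuting whole rows leaves R unchanged"
        )
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    rng = np.random.default_rng(rng)
    Z = np.asarray(Z, dtype=float)
    n, p = Z.shape
    obs = np.sort(np.linalg.eigvalsh(np.corrcoef(Z, rowvar=False)))[::-1]
    perm = np.empty((n_permutations, p))
    Zb = Z.copy()
    for b in range(n_permutations):
        for j in range(p):
            Zb[:, j] = Z[rng.permutation(n), j]
        perm[b] = np.sort(np.linalg.eigvalsh(np.corrcoef(Zb, rowvar=False)))[::-1]
    thresh = np.quantile(perm, 1.0 - alpha, axis=0)
    m = 0
    while m < p and obs[m] > thresh[m]:
        m += 1
    return m


# ---------------------------------------------------------------------------
# geomin rotation


def geomin_criterion(L: np.ndarray, eps: float = 0.01) -> float:
    """Geomin complexity: sum over rows of the geometric mean of l^2 + eps."""
    L2 = L**2 + eps
    return float(np.sum(np.exp(np.mean(np.log(L2), axis=1))))


def _geomin_grad(L: np.ndarray, eps: float) -> tuple[float, np.ndarray]:
    L2 = L**2 + eps
    part = np.exp(np.mean(np.log(L2), axis=1))
    q = float(np.sum(part))
    G = (2.0 / L.shape[1]) * part[:, None] * L / L2
    return q, G


def _gpf_oblique(
    A: np.ndarray,
    T0: np.ndarray,
    eps: float,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, float, bool, list[float]]:
    """Gradient-projection algorithm for oblique rotation (geomin criterion).

    Returns (rotated loadings, factor correlations, criterion, converged,
    criterion trace).  The criterion is non-increasing along the trace.
    """
    T = T0.copy()
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = _geomin_grad(L, eps)
    G = -(L.T @ Gq @ Ti).T
    trace = [f]
    al = 1.0
    converged = False
    for _ in range(max_iter):
        Gp = G - T * np.sum(T * G, axis=0)
        s = np.linalg.norm(Gp)
        if s < tol:
            converged = True
            break
        al *= 2.0
        improved = False
        for _ in range(60):
            X = T - al * Gp
            X /= np.sqrt(np.sum(X**2, axis=0))
            Ti_t = np.linalg.inv(X)
            Lt = A @ Ti_t.T
            ft, Gq_t = _geomin_grad(Lt, eps)
            if ft < f - 0.5 * s**2 * al:
                improved = True
                break
            al /= 2.0
        if not improved and ft >= f:
            converged = True  # line search stalled at a minimiser
            break
        T, Ti, L, f, Gq = X, Ti_t, Lt, ft, Gq_t
        G = -(L.T @ Gq @ Ti).T
        trace.append(f)
    Phi = T.T @ T
    return L, Phi, f, converged, trace


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Tucker's congruence coefficient between two loading columns."""
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


def _match_columns(L1: np.ndarray, L2: np.ndarray) -> float:
    """Minimum |congruence| after greedily matching columns up to
    permutation and sign."""
    m = L1.shape[1]
    C = np.abs(
        L1.T @ L2 / np.sqrt(np.outer(np.sum(L1**2, axis=0), np.sum(L2**2, axis=0)))
    )
    rows, cols = list(range(m)), list(range(m))
    worst = 1.0
    while rows:
        i, j = max(((i, j) for i in rows for j in cols), key=lambda ij: C[ij[0], ij[1]])
        worst = min(worst, C[i, j])
        rows.remove(i)
        cols.remove(j)
    return worst


@dataclass
class RotationSet:
    """One distinct geomin solution (a 'set' of factors)."""

    loadings: np.ndarray
    factor_corr: np.ndarray
    criterion: float
    basin_size: float  # fraction of random starts converging here


@dataclass
class RotationSetCollection:
    """Distinct oblique geomin solutions, ordered by criterion value."""

    sets: list[RotationSet]
    eps: float
    n_starts: int
    n_failed: int = 0

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, i: int) -> RotationSet:
        return self.sets[i]


def geomin_rotate(
    A: np.ndarray,
    eps: float = 0.01,
    n_starts: int = 100,
    rng: np.random.Generator | int | None = None,
    congruence_threshold: float = 0.95,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> RotationSetCollection:
    """Oblique geomin rotation from random orthonormal starts.

    Converged solutions are clustered into distinct sets: two solutions
    belong to the same set when their loading columns match to
    |congruence| >= ``congruence_threshold`` up to permutation and sign.
    Sets are ordered by criterion value (best first) with their basin
    sizes (fraction of starts).
    """
    if eps <= 0:
        raise ValueError("geomin eps must be positive")
    if n_starts < 1:
        raise ValueError("need at least one start")
    A = np.asarray(A, dtype=float)
    m = A.shape[1]
    rng = np.random.default_rng(rng)
    solutions: list[tuple[np.ndarray, np.ndarray, float]] = []
    n_failed = 0
    starts = [np.eye(m)]
    for _ in range(n_starts - 1):
        Q, _ = np.linalg.qr(rng.standard_normal((m, m)))
        starts.append(Q)
    for T0 in starts:
        L, Phi, f, conv, _ = _gpf_oblique(A, T0, eps, max_iter=max_iter, tol=tol)
        if not conv:
            n_failed += 1
            continue
        solutions.append((L, Phi, f))
    if not solutions:
        raise RuntimeError(f"geomin rotation failed to converge from all {n_starts} starts")
    clusters: list[list[tuple[np.ndarray, np.ndarray, float]]] = []
    for sol in solutions:
        for cl in clusters:
            if _match_columns(cl[0][0], sol[0]) >= congruence_threshold:
                cl.append(sol)
                break
        else:
            clusters.append([sol])
    sets = []
    for cl in clusters:
        best = min(cl, key=lambda s: s[2])
        L = _canonical_columns(best[0], best[1])
        sets.append(
            RotationSet(
                loadings=L[0],
                factor_corr=L[1],
                criterion=best[2],
                basin_size=len(cl) / len(solutions),
            )
        )
    sets.sort(key=lambda s: s.criterion)
    return RotationSetCollection(sets=sets, eps=eps, n_starts=n_starts, n_failed=n_failed)


def _canonical_columns(L: np.ndarray, Phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Order columns by descending sum of squared loadings; sign so the
    largest-magnitude loading of each column is positive."""
    order = np.argsort(-np.sum(L**2, axis=0))
    L = L[:, order]
    Phi = Phi[np.ix_(order, order)]
    signs = np.ones(L.shape[1])
    for j in range(L.shape[1]):
        if L[np.argmax(np.abs(L[:, j])), j] < 0:
            signs[j] = -1.0
    L = L * signs
    Phi = Phi * np.outer(signs, signs)
    return L, Phi


# ---------------------------------------------------------------------------
# communalities


@dataclass
class CommunalityReport:
    """Per-task and aggregate communalities."""

    per_task: np.ndarray
    total: float
    mean: float
    proportion: float  # of overall variance (total / n_tasks)
    n_factors: int

    def as_series(self, index=None) -> pd.Series:
        return pd.Series(self.per_task, index=index, name="communality")


def communalities(solution, factor_corr: np.ndarray | None = None) -> CommunalityReport:
    """Communalities h_i, their total, mean and share of overall variance.

    Accepts a :class:`FactorSolution`, a :class:`RotationSet` or a bare
    loading matrix (optionally with factor correlations for oblique
    solutions).  h_i = sum_j l_ij^2 for orthogonal loadings and
    (Lambda Phi Lambda')_ii for oblique ones.
    """
    if isinstance(solution, (FactorSolution, RotationSet)):
        L = solution.loadings
        Phi = solution.factor_corr
    else:
        L = np.asarray(solution, dtype=float)
        Phi = factor_corr
    if not np.all(np.isfinite(L)):
        raise ValueError("loadings must be finite")
    if Phi is None:
        h = np.sum(L**2, axis=1)
    else:
        h = np.einsum("ij,jk,ik->i", L, Phi, L)
    total = float(np.sum(h))
    m = L.shape[1]
    return CommunalityReport(
        per_task=h,
        total=total,
        mean=total / m,
        proportion=total / L.shape[0],
        n_factors=m,
    )


# ---------------------------------------------------------------------------
# model / results


class REFA:
    """Regularised exploratory factor analysis model.

    Parameters
    ----------
    data : (n, p) array or DataFrame
        Standardized score matrix (participants x tasks).
    n_factors : int, optional
        Number of common factors; estimated by the permutation test when
        omitted.
    lam : float, optional
        Regularisation parameter.  None (default) estimates the scalar by
        one-parameter ML under the anti-image assumption; 0 requests
        standard unregularised ML EFA.
    rotation : {"geomin", None}
        Oblique geomin rotation with local-solution enumeration, or no
        rotation.
    """

    def __init__(
        self,
        data,
        n_factors: int | None = None,
        lam: float | None = None,
        rotation: str | None = "geomin",
        geomin_eps: float = 0.01,
        n_starts: int = 100,
        n_permutations: int = 500,
        alpha: float = 0.05,
        congruence_threshold: float = 0.95,
    ):
        if isinstance(data, pd.DataFrame):
            self.task_names = list(data.columns)
            self.data = data.to_numpy(dtype=float)
        else:
            self.data = np.asarray(data, dtype=float)
            self.task_names = [f"task{i + 1}" for i in range(self.data.shape[1])]
        if rotation not in ("geomin", None):
            raise ValueError(f"unknown rotation {rotation!r}")
        self.n_factors = n_factors
        self.lam = lam
        self.rotation = rotation
        self.geomin_eps = geomin_eps
        self.n_starts = n_starts
        self.n_permutations = n_permutations
        self.alpha = alpha
        self.congruence_threshold = congruence_threshold

    def fit(self, seed: int | None = None) -> "REFAResults":
        rng = np.random.default_rng(seed)
        m = self.n_factors
        if m is None:
            m = estimate_n_factors_permutation(
                self.data, self.n_permutations, self.alpha, rng=rng
            )
            if m == 0:
                raise ValueError(
                    "permutation test retained 0 factors; no common structure to extract"
                )
        solution = fit_refa(self.data, m, lam=self.lam)
        rotation_sets = None
        if self.rotation == "geomin" and m > 1:
            rotation_sets = geomin_rotate(
                solution.loadings,
                eps=self.geomin_eps,
                n_starts=self.n_starts,
                rng=rng,
                congruence_threshold=self.congruence_threshold,
            )
        return REFAResults(model=self, solution=solution, rotation_sets=rotation_sets)


@dataclass
class REFAResults:
    """Fitted REFA: unrotated solution plus geomin rotation sets."""

    model: REFA
    solution: FactorSolution
    rotation_sets: RotationSetCollection | None = None
    _scores_cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_factors(self) -> int:
        return self.solution.n_factors

    @property
    def lam(self) -> float | None:
        return self.solution.lam

    def communality_report(self) -> CommunalityReport:
        """Rotation-invariant communalities from the unrotated solution."""
        return communalities(self.solution)

    def loadings_frame(self, set_index: int | None = 0) -> pd.DataFrame:
        """Loadings of one rotation set (or the unrotated solution)."""
        if set_index is None or self.rotation_sets is None:
            L = self.solution.loadings
        else:
            L = self.rotation_sets[set_index].loadings
        cols = [f"F{j + 1}" for j in range(L.shape[1])]
        return pd.DataFrame(L, index=self.model.task_names, columns=cols)

    def factor_scores(self, set_index: int | None = 0) -> np.ndarray:
        """Bartlett factor scores from one rotation set's pattern matrix."""
        key = set_index
        if key not in self._scores_cache:
            if set_index is None or self.rotation_sets is None:
                L = self.solution.loadings
            else:
                L = self.rotation_sets[set_index].loadings
            psi_inv = 1.0 / self.solution.uniquenesses
            M = L.T * psi_inv  # m x p
            Z = self.model.data
            Zc = Z - Z.mean(axis=0)
            self._scores_cache[key] = np.linalg.solve(M @ L, M @ Zc.T).T
        return self._scores_cache[key]

    def summary(self, salience_threshold: float = 0.6) -> str:
        """Text report: loadings per set (salient entries starred),
        factor correlations and communalities."""
        rep = self.communality_report()
        lines = [
            "Regularised exploratory factor analysis",
            f"  n = {self.model.data.shape[0]}, tasks = {self.model.data.shape[1]}, "
            f"factors = {self.n_factors}",
            f"  lambda = {'free (ML EFA)' if self.lam is None else format(self.lam, '.4f')}"
            + ("  [Heywood case flagged]" if self.solution.heywood else ""),
            f"  total communality = {rep.total:.3f} "
            f"({100 * rep.proportion:.1f}% of overall variance)",
            "",
        ]
        frames = (
            [(i, s) for i, s in enumerate(self.rotation_sets.sets)]
            if self.rotation_sets is not None
            else [(0, None)]
        )
        for i, s in frames:
            frame = self.loadings_frame(i if s is not None else None).round(3)
            mark = frame.abs() >= salience_threshold
            shown = frame.astype(str).where(~mark, frame.astype(str) + "*")
            title = f"Set {i + 1}" if s is not None else "Unrotated"
            extra = f" (criterion {s.criterion:.4f}, basin {100 * s.basin_size:.0f}%)" if s else ""
            lines += [f"{title}{extra}", shown.to_string(), ""]
        lines += [
            "Communalities:",
            rep.as_series(self.model.task_names).round(3).to_string(),
        ]
        return "\n".join(lines)


def canonical_loadings(L: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Transform a loading matrix to the canonical form in which
    Lambda' Psi^-1 Lambda is diagonal with descending elements (the form
    ML-EFA implementations agree on up to column signs; signs are fixed so
    each column's largest-magnitude loading is positive)."""
    L = np.asarray(L, dtype=float)
    psi = np.asarray(psi, dtype=float)
    M = (L.T / psi) @ L
    w, V = np.linalg.eigh(M)
    order = np.argsort(w)[::-1]
    Lc = L @ V[:, order]
    for j in range(Lc.shape[1]):
        if Lc[np.argmax(np.abs(Lc[:, j])), j] < 0:
            Lc[:, j] = -Lc[:, j]
    return Lc
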