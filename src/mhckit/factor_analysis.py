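"""Factor structure of the 29 recoded items.

Covers sampling adequacy (KMO), factor-count criteria (scree eigenvalues,
Horn's parallel analysis, Velicer's MAP), maximum-likelihood exploratory
extraction with direct-Oblimin (quartimin) rotation, threshold-based item
assignment, and a confirmatory fit with CFI/TLI/SRMR.

Analyses run on Pearson correlations of the 0/1 recoded items (the
recode-then-analyze order); pass ``tetrachoric=True`` to ``item_correlations``
for the optional tetrachoric route.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.multivariate.factor import Factor
from statsmodels.multivariate.factor_rotation import rotate_factors


def item_correlations(binary: pd.DataFrame | np.ndarray, tetrachoric: bool = False) -> np.ndarray:
    """Correlation matrix of the recoded items (Pearson by default)."""
    x = _as_matrix(binary)
    if not tetrachoric:
        return np.corrcoef(x, rowvar=False)
    p = x.shape[1]
    r = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            r[i, j] = r[j, i] = _tetrachoric_pair(x[:, i], x[:, j])
    return r


def _tetrachoric_pair(a: np.ndarray, b: np.ndarray) -> float:
    # ML over the latent bivariate-normal correlation with fixed thresholds
    n11 = float(((a == 1) & (b == 1)).sum()) + 0.5
    n10 = float(((a == 1) & (b == 0)).sum()) + 0.5
    n01 = float(((a == 0) & (b == 1)).sum()) + 0.5
    n00 = float(((a == 0) & (b == 0)).sum()) + 0.5
    n = n11 + n10 + n01 + n00
    h = stats.norm.ppf((n10 + n11) / n)
    k = stats.norm.ppf((n01 + n11) / n)

    def nll(rho):
        rho = np.clip(rho, -0.999, 0.999)
        p11 = stats.multivariate_normal.cdf([-h, -k], cov=[[1, rho], [rho, 1]])
        p11 = 1 - stats.norm.cdf(h) - stats.norm.cdf(k) + p11
        p11 = np.clip(p11, 1e-12, 1 - 1e-12)
        p1 = 1 - stats.norm.cdf(h)
        p2 = 1 - stats.norm.cdf(k)
        p10 = np.clip(p1 - p11, 1e-12, 1)
        p01 = np.clip(p2 - p11, 1e-12, 1)
        p00 = np.clip(1 - p1 - p2 + p11, 1e-12, 1)
        return -(n11 * np.log(p11) + n10 * np.log(p10)
                 + n01 * np.log(p01) + n00 * np.log(p00))

    res = optimize.minimize_scalar(nll, bounds=(-0.999, 0.999), method="bounded")
    return float(res.x)


def _as_matrix(data) -> np.ndarray:
    if isinstance(data, pd.DataFrame):
        cols = [c for c in data.columns if c != "subject_id"]
        return data[cols].to_numpy(dtype=float)
    return np.asarray(data, dtype=float)


def kmo(correlation: np.ndarray) -> float:
    """Kaiser-Meyer-Olkin sampling adequacy of a correlation matrix.

    KMO = sum r^2 / (sum r^2 + sum p^2) over off-diagonal simple correlations
    r and anti-image partial correlations p.
    """
    r = np.asarray(correlation, dtype=float)
    if r.ndim != 2 or r.shape[0] != r.shape[1] or not np.allclose(r, r.T, atol=1e-8):
        raise ValueError("correlation must be a symmetric square matrix")
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0 or logdet < -200:
        raise np.linalg.LinAlgError(
            "correlation matrix is singular (near-collinear variables); "
            "KMO undefined"
        )
    inv = np.linalg.inv(r)
    d = 1.0 / np.sqrt(np.diag(inv))
    partial = -inv * np.outer(d, d)
    off = ~np.eye(r.shape[0], dtype=bool)
    ssr = (r[off] ** 2).sum()
    ssp = (partial[off] ** 2).sum()
    return float(ssr / (ssr + ssp))


@dataclass
class FactorCountResult:
    eigenvalues: np.ndarray
    random_eigenvalue_quantiles: np.ndarray
    parallel_count: int
    map_values: np.ndarray
    map_count: int


def parallel_analysis(
    data, n_iter: int = 100, percentile: float = 95.0, seed: int = 0
) -> tuple[int, np.ndarray, np.ndarray]:
    """Horn's parallel analysis on the Pearson correlation eigenvalues.

    Retains leading factors whose observed eigenvalue exceeds the chosen
    percentile of eigenvalues from independent-normal data of the same shape;
    counting stops at the first non-exceedance.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    x = _as_matrix(data)
    n, p = x.shape
    obs = np.sort(np.linalg.eigvalsh(np.corrcoef(x, rowvar=False)))[::-1]
    rng = np.random.default_rng(seed)
    rand = np.empty((n_iter, p))
    for it in range(n_iter):
        z = rng.standard_normal((n, p))
        rand[it] = np.sort(np.linalg.eigvalsh(np.corrcoef(z, rowvar=False)))[::-1]
    q = np.percentile(rand, percentile, axis=0)
    count = 0
    for lam, thr in zip(obs, q):
        if lam > thr:
            count += 1
        else:
            break
    return count, obs, q


def velicer_map(data) -> tuple[int, np.ndarray]:
    """Velicer's minimum-average-partial factor count (squared partials)."""
    r = np.corrcoef(_as_matrix(data), rowvar=False)
    p = r.shape[0]
    eigval, eigvec = np.linalg.eigh(r)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    loadings = eigvec * np.sqrt(np.clip(eigval, 0, None))
    off = ~np.eye(p, dtype=bool)
    maps = np.empty(p - 1)
    maps[0] = (r[off] ** 2).mean()
    for m in range(1, p - 1):
        partial_cov = r - loadings[:, :m] @ loadings[:, :m].T
        d = np.sqrt(np.clip(np.diag(partial_cov), 1e-12, None))
        partial = partial_cov / np.outer(d, d)
        maps[m] = (partial[off] ** 2).mean()
    return int(np.argmin(maps)), maps


def count_factors(
    data, n_iter: int = 100, percentile: float = 95.0, seed: int = 0
) -> FactorCountResult:
    """Scree eigenvalues plus parallel-analysis and MAP factor counts."""
    pa_count, obs, q = parallel_analysis(data, n_iter, percentile, seed)
    map_count, maps = velicer_map(data)
    return FactorCountResult(
        eigenvalues=obs,
        random_eigenvalue_quantiles=q,
        parallel_count=pa_count,
        map_values=maps,
        map_count=map_count,
    )


@dataclass
class FactorSolution:
    """Oblique-rotated exploratory solution."""

    pattern: pd.DataFrame        # items x k pattern loadings
    phi: np.ndarray              # k x k factor correlations
    communalities: pd.Series
    uniquenesses: pd.Series
    method: str = "ml+oblimin(gamma=0)"
    warnings: list[str] = field(default_factory=list)

    @property
    def n_factors(self) -> int:
        return self.pattern.shape[1]

    def reproduced(self) -> np.ndarray:
        lam = self.pattern.to_numpy()
        return lam @ self.phi @ lam.T + np.diag(self.uniquenesses.to_numpy())


def _canonicalize(pattern: np.ndarray, phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # order columns by explained common variance, sign the dominant loading +
    order = np.argsort(-(pattern ** 2).sum(axis=0), kind="stable")
    pattern = pattern[:, order]
    phi = phi[np.ix_(order, order)]
    signs = np.sign(pattern[np.abs(pattern).argmax(axis=0), np.arange(pattern.shape[1])])
    signs[signs == 0] = 1.0
    pattern = pattern * signs
    phi = phi * np.outer(signs, signs)
    return pattern, phi


def efa(
    data=None,
    k: int = 5,
    correlation: np.ndarray | None = None,
    n_obs: int | None = None,
    item_names: list[str] | None = None,
) -> FactorSolution:
    """Maximum-likelihood EFA with direct-Oblimin (gamma=0, quartimin) rotation.

    Accepts either a raw 0/1 data table or a precomputed correlation matrix
    with ``n_obs``.  Columns are ordered by explained common variance and
    signed so each column's dominant loading is positive.  A Heywood case
    (communality reaching 1) is recorded as a warning, not an error.
    """
    if (data is None) == (correlation is None):
        raise ValueError("provide exactly one of data or correlation")
    if k < 1:
        raise ValueError("k must be >= 1")
    sol_warnings: list[str] = []
    if data is not None:
        if isinstance(data, pd.DataFrame) and item_names is None:
            item_names = [c for c in data.columns if c != "subject_id"]
        x = _as_matrix(data)
        corr = np.corrcoef(x, rowvar=False)
        n_obs = x.shape[0]
    else:
        corr = np.asarray(correlation, dtype=float)
        if n_obs is None:
            n_obs = 1000  # only scales test statistics, not loadings
    p = corr.shape[0]
    if k >= p:
        raise ValueError("k must be smaller than the number of items")
    if item_names is None:
        item_names = [f"x{i+1}" for i in range(p)]
    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")
        model = Factor(corr=corr, n_factor=k, method="ml", nobs=n_obs, smc=True)
        fit = model.fit()
    for w in caught:
        sol_warnings.append(str(w.message))
    unrotated = np.asarray(fit.loadings)
    if k > 1:
        pattern, t = rotate_factors(unrotated, "quartimin")
        phi = t.T @ t
    else:
        pattern, phi = unrotated.copy(), np.eye(1)
    pattern, phi = _canonicalize(pattern, phi)
    communality = (unrotated ** 2).sum(axis=1)
    if (communality > 1 - 1e-8).any():
        heywood = [item_names[i] for i in np.nonzero(communality > 1 - 1e-8)[0]]
        sol_warnings.append(f"Heywood case: communality at bound for {heywood}")
    communality = np.clip(communality, 0.0, 1.0)
    cols = [f"F{i+1}" for i in range(k)]
    return FactorSolution(
        pattern=pd.DataFrame(pattern, index=item_names, columns=cols),
        phi=phi,
        communalities=pd.Series(communality, index=item_names, name="communality"),
        uniquenesses=pd.Series(1 - communality, index=item_names, name="uniqueness"),
        warnings=sol_warnings,
    )


def assign_items(
    solution: FactorSolution | pd.DataFrame, threshold: float = 0.29
) -> tuple[dict[str, str], list[str]]:
    """Assign each item to its maximal-|loading| factor when above threshold.

    Returns (item -> factor map, unassigned items).  The default threshold
    0.29 reproduces the published block structure from its printed pattern
    matrix, whose smallest retained loading is 0.29.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    pattern = solution.pattern if isinstance(solution, FactorSolution) else solution
    assignment: dict[str, str] = {}
    unassigned: list[str] = []
    for item, row in pattern.iterrows():
        j = row.abs().idxmax()
        if abs(row[j]) >= threshold:
            assignment[item] = j
        else:
            unassigned.append(item)
    return assignment, unassigned


@dataclass
class FitIndices:
    cfi: float
    tli: float
    srmr: float
    chi2: float
    df: int
    chi2_baseline: float
    df_baseline: int
    n_obs: int
    converged: bool


@dataclass
class CFAResult:
    indices: FitIndices
    loadings: pd.DataFrame      # standardized loadings (items x factors, simple structure)
    phi: np.ndarray
    uniquenesses: pd.Series
    implied: np.ndarray


def _phi_from_params(w: np.ndarray, k: int) -> np.ndarray:
    # unit-norm rows of a lower-triangular square root -> correlation matrix
    L = np.eye(k)
    idx = np.tril_indices(k, -1)
    L[idx] = w
    norms = np.sqrt((L ** 2).sum(axis=1))
    L = L / norms[:, None]
    return L @ L.T


def cfa_fit(
    data=None,
    model: dict[str, str] | None = None,
    correlation: np.ndarray | None = None,
    n_obs: int | None = None,
    max_iter: int = 2000,
) -> CFAResult:
    """Confirmatory factor fit of a simple-structure item -> factor map.

    Minimizes the ML discrepancy
    F = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p
    over free loadings, uniquenesses, and factor correlations, then reports
    chi-square (= (n-1) F), CFI and TLI against the independence baseline,
    and SRMR over the standardized residuals (lower triangle incl. diagonal).
    """
    if model is None or not model:
        raise ValueError("model (item -> factor map) is required")
    factors = sorted(set(model.values()))
    for f in factors:
        if sum(1 for v in model.values() if v == f) < 2:
            raise ValueError(f"factor '{f}' has fewer than 2 items")
    items = list(model.keys())
    if data is not None:
        if isinstance(data, pd.DataFrame):
            x = data[items].to_numpy(dtype=float)
        else:
            x = np.asarray(data, dtype=float)
        s = np.corrcoef(x, rowvar=False)
        n_obs = x.shape[0]
    else:
        s = np.asarray(correlation, dtype=float)
        if n_obs is None:
            raise ValueError("n_obs is required with a correlation input")
    p = len(items)
    k = len(factors)
    fmap = np.array([factors.index(model[i]) for i in items])
    sign_s, logdet_s = np.linalg.slogdet(s)
    if sign_s <= 0:
        raise ValueError("sample correlation matrix is singular")

    n_phi = k * (k - 1) // 2

    def unpack(params):
        lam = params[:p]
        psi = np.exp(np.clip(params[p:2 * p], -12, 6))
        phi = _phi_from_params(params[2 * p:2 * p + n_phi], k)
        big = np.zeros((p, k))
        big[np.arange(p), fmap] = lam
        sigma = big @ phi @ big.T
        sigma[np.diag_indices(p)] += psi
        return big, phi, psi, sigma

    def discrepancy(params):
        _, _, _, sigma = unpack(params)
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            return 1e10
        try:
            tr = np.trace(np.linalg.solve(sigma, s))
        except np.linalg.LinAlgError:
            return 1e10
        return logdet + tr - logdet_s - p

    x0 = np.concatenate([
        np.full(p, 0.6), np.log(np.full(p, 0.5)), np.zeros(n_phi)
    ])
    res = optimize.minimize(
        discrepancy, x0, method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-9},
    )
    if not res.success and np.linalg.norm(res.jac) > 1e-3:
        raise RuntimeError(
            f"CFA did not converge after {max_iter} iterations "
            f"(|grad| = {np.linalg.norm(res.jac):.2e}): {res.message}"
        )
    big, phi, psi, sigma = unpack(res.x)
    # sign convention: dominant loading per factor positive
    for j in range(k):
        col = big[:, j]
        if col[np.abs(col).argmax()] < 0:
            big[:, j] = -col
            phi[j, :] *= -1
            phi[:, j] *= -1
    f_min = max(res.fun, 0.0)
    n_free = p + p + n_phi
    df = p * (p + 1) // 2 - n_free
    chi2 = (n_obs - 1) * f_min
    f_base = float(np.log(np.diag(s)).sum() - logdet_s)
    chi2_b = (n_obs - 1) * f_base
    df_b = p * (p - 1) // 2
    num = max(chi2 - df, 0.0)
    den = max(chi2_b - df_b, num, np.finfo(float).eps)
    cfi = 1.0 - num / den
    if df > 0 and df_b > 0 and chi2_b / df_b > 1:
        tli = (chi2_b / df_b - chi2 / df) / (chi2_b / df_b - 1.0)
    else:
        tli = 1.0
    d = np.sqrt(np.diag(s))
    resid = (s - sigma) / np.outer(d, d)
    tri = np.tril_indices(p)
    srmr = float(np.sqrt((resid[tri] ** 2).mean()))
    indices = FitIndices(
        cfi=float(cfi), tli=float(tli), srmr=srmr, chi2=float(chi2), df=int(df),
        chi2_baseline=float(chi2_b), df_baseline=int(df_b), n_obs=int(n_obs),
        converged=bool(res.success),
    )
    loadings = pd.DataFrame(big, index=items, columns=factors)
    return CFAResult(
        indices=indices, loadings=loadings, phi=phi,
        uniquenesses=pd.Series(psi, index=items, name="uniqueness"),
        implied=sigma,
    )
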