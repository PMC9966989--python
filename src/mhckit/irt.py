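"""Two-parameter logistic IRT on the recoded 0/1 items.

Marginal maximum likelihood via the Bock-Aitkin EM algorithm under a
standard-normal latent trait with Gauss-Hermite quadrature.  The latent scale
is oriented so that a higher trait value means worse psychosomatic status and
a response of 1 encodes the unfavourable pole, so discriminations come out
positive on well-behaved data.  Factor-level averaged response curves and
their 0.5-probability crossings order the complaints by the disorder level at
which they appear.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import brentq


def icc(theta, a: float, b: float):
    """2PL item characteristic curve P = 1 / (1 + exp(-a (theta - b)))."""
    theta = np.asarray(theta, dtype=float)
    with np.errstate(over="ignore"):
        out = 1.0 / (1.0 + np.exp(-a * (theta - b)))
    return out if out.ndim else float(out)


@dataclass
class ItemParams2PL:
    params: pd.DataFrame            # item, a, b
    log_likelihood: float
    n_iter: int
    converged: bool
    excluded: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    ll_trace: np.ndarray | None = None


def _quadrature(n_points: int) -> tuple[np.ndarray, np.ndarray]:
    # probabilists' Gauss-Hermite: nodes/weights for N(0, 1) expectation
    nodes, weights = hermegauss(n_points)
    return nodes, weights / weights.sum()


def _mstep_item(r: np.ndarray, n: np.ndarray, nodes: np.ndarray,
                c0: float, s0: float) -> tuple[float, float]:
    """Maximize the expected item log-likelihood over (intercept, slope).

    Weighted logistic regression of expected endorsements r against expected
    totals n on the quadrature grid, by Newton-Raphson; concave, so the full
    maximization keeps the EM ascent property.
    """
    c, s = c0, s0
    x = np.column_stack([np.ones_like(nodes), nodes])
    for _ in range(100):
        eta = c + s * nodes
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = x.T @ (r - n * p)
        w = n * p * (1 - p)
        hess = -(x * w[:, None]).T @ x
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        step = np.clip(step, -5, 5)
        c, s = c - step[0], s - step[1]
        if np.abs(step).max() < 1e-9:
            break
    return c, s


def fit_2pl(
    binary: pd.DataFrame | np.ndarray,
    quadrature: int = 21,
    tol: float = 1e-4,
    max_iter: int = 500,
    seed: int = 0,
) -> ItemParams2PL:
    """Bock-Aitkin marginal-ML fit of the 2PL model.

    The marginal log-likelihood is non-decreasing across EM iterations;
    convergence is declared when the largest parameter change drops below
    ``tol``.  Items with zero response variance are excluded with a warning.
    """
    if isinstance(binary, pd.DataFrame):
        item_names = [c for c in binary.columns if c != "subject_id"]
        x = binary[item_names].to_numpy(dtype=float)
    else:
        x = np.asarray(binary, dtype=float)
        item_names = [f"item{j+1}" for j in range(x.shape[1])]
    if not np.isin(x, (0.0, 1.0)).all():
        raise ValueError("binary matrix must contain only 0/1 values")
    warnings: list[str] = []
    keep = []
    excluded = []
    for j, name in enumerate(item_names):
        if x[:, j].min() == x[:, j].max():
            excluded.append(name)
            warnings.append(f"item '{name}' has zero response variance; excluded")
        else:
            keep.append(j)
    x = x[:, keep]
    names = [item_names[j] for j in keep]
    n_sub, n_items = x.shape
    if n_items == 0:
        raise ValueError("no items with response variance to fit")
    if n_sub < n_items:
        warnings.append("fewer subjects than items; estimates may be unstable")

    nodes, w = _quadrature(quadrature)
    # start: slope 1, intercept from marginal endorsement rate
    pbar = x.mean(axis=0).clip(1e-3, 1 - 1e-3)
    slopes = np.ones(n_items)
    intercepts = np.log(pbar / (1 - pbar))

    ll_trace = []
    prev_ll = -np.inf
    converged = False
    for it in range(1, max_iter + 1):
        eta = intercepts[None, :] + np.outer(nodes, slopes)  # Q x J
        with np.errstate(over="ignore"):
            p = 1.0 / (1.0 + np.exp(-eta))
        p = p.clip(1e-12, 1 - 1e-12)
        # E-step in logs: subject x quadrature joint likelihood
        log_lik = x @ np.log(p).T + (1 - x) @ np.log1p(-p).T  # N x Q
        log_joint = log_lik + np.log(w)[None, :]
        m = log_joint.max(axis=1, keepdims=True)
        joint = np.exp(log_joint - m)
        marg = joint.sum(axis=1)
        ll = float((np.log(marg) + m[:, 0]).sum())
        ll_trace.append(ll)
        post = joint / marg[:, None]                          # N x Q
        nq = post.sum(axis=0)                                 # Q
        rq = post.T @ x                                       # Q x J
        old = np.concatenate([slopes, intercepts])
        for j in range(n_items):
            intercepts[j], slopes[j] = _mstep_item(
                rq[:, j], nq, nodes, intercepts[j], slopes[j]
            )
        if ll < prev_ll - 1e-8:
            warnings.append(f"log-likelihood decreased at iteration {it}")
        prev_ll = ll
        change = np.abs(np.concatenate([slopes, intercepts]) - old).max()
        if change < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"2PL EM did not converge in {max_iter} iterations; "
            f"last max parameter change {change:.3e}, ll trace tail "
            f"{[round(v, 3) for v in ll_trace[-5:]]}"
        )
    a = slopes
    b = -intercepts / np.where(slopes == 0, np.nan, slopes)
    params = pd.DataFrame({"item": names, "a": a, "b": b})
    return ItemParams2PL(
        params=params, log_likelihood=prev_ll, n_iter=it, converged=converged,
        excluded=excluded, warnings=warnings,
        ll_trace=np.asarray(ll_trace),
    )


@dataclass
class ResponseCurve:
    theta: np.ndarray
    probability: np.ndarray
    items: list[str]
    item_params: pd.DataFrame

    def __call__(self, theta):
        """Analytic averaged curve at arbitrary theta."""
        theta = np.asarray(theta, dtype=float)
        total = np.zeros_like(theta, dtype=float)
        for _, row in self.item_params.iterrows():
            total += icc(theta, row["a"], row["b"])
        out = total / len(self.item_params)
        return out if out.ndim else float(out)


def factor_curve(
    items: list[str],
    params: ItemParams2PL | pd.DataFrame,
    grid: np.ndarray | None = None,
) -> ResponseCurve:
    """Pointwise mean of the member items' characteristic curves."""
    if not items:
        raise ValueError("factor_curve requires a nonempty item set")
    table = params.params if isinstance(params, ItemParams2PL) else params
    sub = table[table["item"].isin(items)]
    missing = sorted(set(items) - set(sub["item"]))
    if missing:
        raise ValueError(f"no fitted parameters for items: {missing}")
    theta = np.linspace(-4, 4, 161) if grid is None else np.asarray(grid, dtype=float)
    probs = np.zeros_like(theta)
    for _, row in sub.iterrows():
        probs += icc(theta, row["a"], row["b"])
    probs /= len(sub)
    return ResponseCurve(theta=theta, probability=probs,
                         items=list(sub["item"]), item_params=sub.reset_index(drop=True))


def threshold(curve: ResponseCurve) -> float:
    """Latent-trait value where the averaged curve crosses probability 0.5.

    Brackets the crossing on the grid, then refines by root-finding on the
    analytic averaged curve; monotone curves give a unique crossing.
    """
    p = curve.probability
    if p.min() > 0.5 or p.max() < 0.5:
        raise ValueError(
            "curve does not cross 0.5 on the grid; extend the theta grid "
            f"(range [{curve.theta[0]}, {curve.theta[-1]}], "
            f"p in [{p.min():.3f}, {p.max():.3f}])"
        )
    idx = int(np.argmax(p >= 0.5)) if p[0] < 0.5 else 0
    if p[idx] == 0.5:
        return float(curve.theta[idx])
    lo = curve.theta[max(idx - 1, 0)]
    hi = curve.theta[idx]
    if lo == hi:
        return float(lo)
    return float(brentq(lambda t: curve(t) - 0.5, lo, hi, xtol=1e-10))
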