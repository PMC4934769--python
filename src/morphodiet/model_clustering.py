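"""Gaussian-mixture model-based clustering with BIC model selection.

EM estimation over a small catalogue of covariance families, scored with the
Bayesian information criterion on the 2*loglik - df*ln(n) convention (larger
is better).  Used both for the wild/domestic admixture screen on
size-and-shape features and for grouping bone-collagen delta13C values.

Families follow the usual equal/variable covariance taxonomy:

=================  ====================================================
family tag         covariance structure
=================  ====================================================
``E`` / ``V``      1-D shorthand: single shared variance / per-component
``spherical-*``    sigma^2 * I, shared (``-equal``) or per-component
``diag-*``         diagonal covariance, shared or per-component
``full-*``         full covariance, shared or per-component
=================  ====================================================

Free-parameter counts: G*d for the means, G-1 for the weights, and the
per-family covariance parameters (1, d or d(d+1)/2), multiplied by G for
variable families.  In 1-D this gives df = 2G for equal variance (so a
two-component fit has df = 4) and df = 3G - 1 for variable variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus

from .procrustes_core import ShapeSet
from .shape_statistics import shape_pca

__all__ = [
    "MixtureFit",
    "ComponentCollapseError",
    "fit_gmm",
    "bic_score",
    "select_model",
    "admixture_screen",
]

_FAMILIES = {
    "E": ("spherical", True),
    "V": ("spherical", False),
    "spherical-equal": ("spherical", True),
    "spherical-variable": ("spherical", False),
    "diag-equal": ("diag", True),
    "diag-variable": ("diag", False),
    "full-equal": ("full", True),
    "full-variable": ("full", False),
}


class ComponentCollapseError(RuntimeError):
    """A mixture component collapsed onto too few points (variance -> 0)."""


def bic_score(loglik: float, df: int, n: int) -> float:
    """BIC on the 2*loglik - df*ln(n) convention (higher is better)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if df < 0:
        raise ValueError("df must be >= 0")
    return 2.0 * loglik - df * np.log(n)


@dataclass
class MixtureFit:
    """A fitted Gaussian mixture with its BIC bookkeeping."""

    G: int
    family: str
    means: np.ndarray              # (G, d)
    covariances: np.ndarray        # (G, d, d)
    weights: np.ndarray            # (G,)
    loglik: float
    df: int
    bic: float
    assignments: np.ndarray        # (n,) hard labels
    responsibilities: np.ndarray   # (n, G)
    converged: bool = True
    n_iter: int = 0
    loglik_trace: np.ndarray = field(default_factory=lambda: np.array([]))
    table: pd.DataFrame | None = None   # filled by select_model

    @property
    def n_obs(self) -> int:
        return self.responsibilities.shape[0]


def _df_count(g: int, d: int, structure: str, equal: bool) -> int:
    mean_df = g * d
    weight_df = g - 1
    cov_per = {"spherical": 1, "diag": d, "full": d * (d + 1) // 2}[structure]
    cov_df = cov_per if equal else cov_per * g
    return mean_df + weight_df + cov_df


def _log_gauss(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = x.shape[1]
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise np.linalg.LinAlgError("non-positive-definite component covariance")
    diff = x - mean
    sol = np.linalg.solve(cov, diff.T).T
    maha = np.sum(diff * sol, axis=1)
    return -0.5 * (d * np.log(2 * np.pi) + logdet + maha)


def _m_step_cov(
    x: np.ndarray, resp: np.ndarray, means: np.ndarray, structure: str, equal: bool,
    floor: float,
) -> np.ndarray:
    n, d = x.shape
    g = means.shape[0]
    nk = resp.sum(axis=0)
    covs = np.empty((g, d, d))
    for k in range(g):
        diff = x - means[k]
        wdiff = resp[:, k][:, None] * diff
        s = diff.T @ wdiff / nk[k]
        if structure == "spherical":
            covs[k] = np.eye(d) * max(np.trace(s) / d, 0.0)
        elif structure == "diag":
            covs[k] = np.diag(np.clip(np.diag(s), 0.0, None))
        else:
            covs[k] = s
    if equal:
        pooled = np.tensordot(nk, covs, axes=1) / nk.sum()
        covs = np.repeat(pooled[None, :, :], g, axis=0)
    # variance floor / collapse detection
    for k in range(g):
        evals = np.linalg.eigvalsh(covs[k])
        if evals.min() < floor:
            raise ComponentCollapseError(f"component {k} variance below floor")
    return covs


def fit_gmm(
    data,
    G: int,
    family: str = "E",
    seed: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-8,
    n_init: int = 5,
    n_restarts: int = 3,
) -> MixtureFit:
    """Fit a G-component Gaussian mixture by EM.

    Initialization is k-means++ with ``n_init`` seeded restarts, keeping the
    best final log-likelihood.  EM iterates until the log-likelihood change
    falls below ``tol`` or ``max_iter``; the log-likelihood trace is retained
    and is non-decreasing.  If a component collapses (variance below floor)
    the fit is restarted with jittered data up to ``n_restarts`` times before
    failing.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, d = x.shape
    if not np.all(np.isfinite(x)):
        raise ValueError("data must be finite")
    if n <= G:
        raise ValueError(f"need more observations ({n}) than components ({G})")
    if family not in _FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {sorted(_FAMILIES)}")
    structure, equal = _FAMILIES[family]
    if d == 1 and family not in ("E", "V"):
        structure, equal = _FAMILIES[family]
    scale = float(np.var(x)) if np.var(x) > 0 else 1.0
    floor = 1e-10 * scale
    rng = np.random.default_rng(seed)

    def _one_run(xr: np.ndarray, rs: int) -> MixtureFit:
        centers, _ = kmeans_plusplus(xr, n_clusters=G, random_state=rs)
        means = centers.astype(float)
        weights = np.full(G, 1.0 / G)
        cov0 = np.cov(xr.T).reshape(d, d) if n > 1 else np.eye(d)
        cov0 = cov0 + np.eye(d) * floor
        covs = np.repeat(cov0[None, :, :], G, axis=0)
        trace = []
        prev = -np.inf
        converged = False
        it = 0
        resp = np.full((n, G), 1.0 / G)
        for it in range(1, max_iter + 1):
            logp = np.column_stack(
                [np.log(weights[k]) + _log_gauss(xr, means[k], covs[k]) for k in range(G)]
            )
            norm = logsumexp(logp, axis=1)
            ll = float(norm.sum())
            trace.append(ll)
            resp = np.exp(logp - norm[:, None])
            if ll - prev < tol and it > 1:
                converged = True
                prev = ll
                break
            prev = ll
            nk = resp.sum(axis=0)
            if np.any(nk < 1e-10):
                raise ComponentCollapseError("empty component")
            weights = nk / n
            means = (resp.T @ xr) / nk[:, None]
            covs = _m_step_cov(xr, resp, means, structure, equal, floor)
        df = _df_count(G, d, structure, equal)
        assignments = np.argmax(resp, axis=1)
        return MixtureFit(
            G=G,
            family=family,
            means=means,
            covariances=covs,
            weights=weights,
            loglik=prev,
            df=df,
            bic=bic_score(prev, df, n),
            assignments=assignments,
            responsibilities=resp,
            converged=converged,
            n_iter=it,
            loglik_trace=np.array(trace),
        )

    last_err: Exception | None = None
    for restart in range(n_restarts):
        xr = x if restart == 0 else x + rng.normal(0, np.sqrt(scale) * 1e-6, size=x.shape)
        best: MixtureFit | None = None
        try:
            for _ in range(n_init):
                rs = int(rng.integers(0, 2**31 - 1))
                try:
                    fit = _one_run(xr, rs)
                except ComponentCollapseError as exc:
                    last_err = exc
                    continue
                if best is None or fit.loglik > best.loglik:
                    best = fit
        except np.linalg.LinAlgError as exc:
            last_err = exc
            best = None
        if best is not None:
            return best
    raise ComponentCollapseError(
        f"fit_gmm failed after {n_restarts} restarts: {last_err}"
    )


def select_model(
    data,
    G_range=(1, 2, 3),
    families=("E", "V"),
    seed: int | None = None,
    **fit_kwargs,
) -> MixtureFit:
    """Fit all (G, family) candidates and return the highest-BIC mixture.

    The full BIC table (one row per candidate, NaN where a fit failed) is
    attached to the returned fit as ``.table`` for reporting.
    """
    g_list = list(G_range)
    if not g_list:
        raise ValueError("G_range must be non-empty")
    rng = np.random.default_rng(seed)
    rows = []
    fits: list[MixtureFit] = []
    for g in g_list:
        for fam in families:
            sub = int(rng.integers(0, 2**31 - 1))
            try:
                fit = fit_gmm(data, G=g, family=fam, seed=sub, **fit_kwargs)
                rows.append(
                    {"G": g, "family": fam, "loglik": fit.loglik, "df": fit.df,
                     "bic": fit.bic, "error": ""}
                )
                fits.append(fit)
            except (ValueError, ComponentCollapseError) as exc:
                rows.append(
                    {"G": g, "family": fam, "loglik": np.nan, "df": np.nan,
                     "bic": np.nan, "error": str(exc)}
                )
    table = pd.DataFrame(rows)
    if not fits:
        raise RuntimeError(f"all mixture fits failed:\n{table}")
    best = max(fits, key=lambda f: f.bic)
    best.table = table
    return best


def admixture_screen(
    shapes: ShapeSet,
    grouping,
    wild_log_size_range: tuple[float, float] | None = None,
    G_range=(1, 2, 3),
    families=("spherical-equal", "spherical-variable", "diag-equal", "diag-variable"),
    min_n: int = 5,
    seed: int | None = None,
) -> list[dict]:
    """Per-group mixture screen for mixed wild/domestic size-shape modes.

    For each group label the 3-D feature (log centroid size, PC1, PC2) is
    submitted to BIC model selection.  A group is flagged when the best model
    has G >= 2 and — if a wild reference range of log centroid size is given —
    at least one component mean size falls inside that range; without a
    reference range any multimodal group is flagged.  Groups smaller than
    ``min_n`` are skipped with a notice.
    """
    grouping = np.asarray(grouping)
    pca = shape_pca(shapes)
    feats = np.column_stack(
        [np.log(shapes.centroid_sizes), pca.scores[:, 0], pca.scores[:, 1]]
    )
    rng = np.random.default_rng(seed)
    report = []
    for g in pd.unique(grouping):
        mask = grouping == g
        n = int(mask.sum())
        if n < min_n:
            report.append(
                {"group": g, "n": n, "skipped": True,
                 "reason": f"n < {min_n}", "flag": False}
            )
            continue
        sub_seed = int(rng.integers(0, 2**31 - 1))
        best = select_model(
            feats[mask], G_range=[gg for gg in G_range if gg < n],
            families=families, seed=sub_seed,
        )
        size_means = best.means[:, 0]
        if best.G >= 2:
            if wild_log_size_range is None:
                flag = True
            else:
                lo, hi = wild_log_size_range
                flag = bool(np.any((size_means >= lo) & (size_means <= hi)))
        else:
            flag = False
        report.append(
            {
                "group": g,
                "n": n,
                "skipped": False,
                "best_G": best.G,
                "family": best.family,
                "bic": best.bic,
                "component_log_size_means": size_means.tolist(),
                "component_weights": best.weights.tolist(),
                "flag": flag,
            }
        )
    return report
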