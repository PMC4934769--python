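"""Group-level size and shape inference for Procrustes-aligned samples.

Covers the ordination and testing toolkit of a landmark-based morphometric
study: PCA of Procrustes coordinates, one-way ANOVA with notched-boxplot
summaries of centroid size, a permutation test for static allometry and its
pooled within-group correction, MANOVA (Pillai / Wilks), canonical variate
analysis with cross-validated dimensionality selection, Mahalanobis
inter-group distances, an unrooted neighbor-joining phenogram, and normal
confidence ellipses for score plots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .procrustes_core import ShapeSet

__all__ = [
    "PCAResult",
    "SizeSummary",
    "AllometryResult",
    "AllometryCorrection",
    "CVAResult",
    "Ellipse",
    "shape_pca",
    "size_summary",
    "test_allometry",
    "remove_allometry",
    "manova_test",
    "select_pc_count",
    "cva",
    "nj_phenogram",
    "confidence_ellipse",
]


def _as_matrix(shapes) -> np.ndarray:
    if isinstance(shapes, ShapeSet):
        return shapes.flat()
    return np.asarray(shapes, dtype=float)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: np.ndarray        # (n, n_comp), centered
    eigenvalues: np.ndarray   # descending
    eigenvectors: np.ndarray  # (p, n_comp), columns are PCs
    mean: np.ndarray          # (p,)

    @property
    def explained_fraction(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        return self.eigenvalues / total if total > 0 else self.eigenvalues


def shape_pca(shapes) -> PCAResult:
    """PCA of the variance-covariance matrix of shape variables.

    Eigenvalues sum to the total sample variance (trace of the covariance
    matrix, n-1 denominator); scores are centered.
    """
    x = _as_matrix(shapes)
    n = x.shape[0]
    if n < 3:
        raise ValueError("shape_pca requires at least 3 specimens")
    mean = x.mean(axis=0)
    xc = x - mean
    cov = xc.T @ xc / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    scores = xc @ evecs
    return PCAResult(scores=scores, eigenvalues=evals, eigenvectors=evecs, mean=mean)


# ---------------------------------------------------------------------------
# Size summaries (notched boxplot statistics + ANOVA)
# ---------------------------------------------------------------------------

@dataclass
class SizeSummary:
    table: pd.DataFrame        # one row per group
    anova_F: float | None
    anova_p: float | None


def size_summary(sizes: Sequence[float], groups: Sequence) -> SizeSummary:
    """Per-group notched-boxplot statistics plus one-way ANOVA on size.

    The notch half-width is the conventional 95% median interval
    1.58 * IQR / sqrt(n).  With fewer than two groups (or any group smaller
    than 2) the ANOVA F/p are omitted.
    """
    sizes = np.asarray(sizes, dtype=float)
    groups = np.asarray(groups)
    rows = []
    labels = pd.unique(groups)
    samples = []
    for g in labels:
        v = sizes[groups == g]
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        rows.append(
            {
                "group": g,
                "n": len(v),
                "min": v.min(),
                "q1": q1,
                "median": med,
                "q3": q3,
                "max": v.max(),
                "notch_half_width": 1.58 * iqr / np.sqrt(len(v)),
            }
        )
        samples.append(v)
    table = pd.DataFrame(rows)
    f_val = p_val = None
    if len(labels) >= 2 and all(len(s) >= 2 for s in samples):
        if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
            f_val, p_val = 0.0, 1.0
        else:
            f_val, p_val = stats.f_oneway(*samples)
            f_val, p_val = float(f_val), float(p_val)
    return SizeSummary(table=table, anova_F=f_val, anova_p=p_val)


# ---------------------------------------------------------------------------
# Allometry
# ---------------------------------------------------------------------------

@dataclass
class AllometryResult:
    pct_variance_predicted: float
    p_value: float
    coefficients: np.ndarray   # (p,) slope of shape on log centroid size
    n_perm: int


def _allometry_pct(x: np.ndarray, y: np.ndarray) -> float:
    """% of total variance of y predicted by simple regression on x (both centered)."""
    ss_tot = float(np.sum(y**2))
    if ss_tot == 0:
        return 0.0
    xtx = float(x @ x)
    if xtx == 0:
        return 0.0
    beta = x @ y / xtx
    ss_mod = xtx * float(beta @ beta)
    return 100.0 * ss_mod / ss_tot


def test_allometry(shapes, n_perm: int = 1000, seed: int | None = None) -> AllometryResult:
    """Permutation test of the multivariate regression of shape on log size.

    The statistic is the percentage of total shape variance predicted by log
    centroid size; log sizes are permuted across specimens and the p-value
    uses the add-one convention (1 + #{perm >= obs}) / (1 + n_perm), so it is
    never zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not isinstance(shapes, ShapeSet):
        raise TypeError("test_allometry expects a ShapeSet")
    if np.any(shapes.centroid_sizes <= 0):
        raise ValueError("centroid sizes must be positive")
    y = shapes.flat()
    y = y - y.mean(axis=0)
    x = np.log(shapes.centroid_sizes)
    x = x - x.mean()
    obs = _allometry_pct(x, y)
    beta = (x @ y) / float(x @ x) if float(x @ x) > 0 else np.zeros(y.shape[1])

    rng = np.random.default_rng(seed)
    n = len(x)
    perms = np.empty((n_perm, n))
    for i in range(n_perm):
        perms[i] = x[rng.permutation(n)]
    # vectorized permuted statistics: per-permutation slope vectors
    xtx = float(x @ x)
    ss_tot = float(np.sum(y**2))
    xy = perms @ y                      # (n_perm, p)
    ss_mod = np.sum(xy**2, axis=1) / xtx
    perm_stats = 100.0 * ss_mod / ss_tot if ss_tot > 0 else np.zeros(n_perm)
    p = (1 + int(np.sum(perm_stats >= obs))) / (1 + n_perm)
    return AllometryResult(
        pct_variance_predicted=obs, p_value=p, coefficients=beta, n_perm=n_perm
    )


@dataclass
class AllometryCorrection:
    residuals: np.ndarray          # (n, p) allometry-free shape variables
    pooled_slope: np.ndarray       # (p,)
    excluded_groups: list = field(default_factory=list)
    keep_mask: np.ndarray | None = None


def remove_allometry(shapes, groups: Sequence) -> AllometryCorrection:
    """Residuals of the pooled within-group regression of shape on log size.

    A single slope is estimated from within-group centered shape and log-size
    variables, so group mean differences are preserved while the common
    allometric component is removed; the pooled within-group correlation of
    the residuals with log size is zero by least-squares construction.
    Groups of size 1 are excluded with a warning.
    """
    if not isinstance(shapes, ShapeSet):
        raise TypeError("remove_allometry expects a ShapeSet")
    y = shapes.flat()
    x = np.log(shapes.centroid_sizes)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    keep = np.ones(len(x), dtype=bool)
    excluded = []
    for g in labels:
        if np.sum(groups == g) < 2:
            keep[groups == g] = False
            excluded.append(g)
    if excluded:
        warnings.warn(f"groups of size 1 excluded from allometry correction: {excluded}")
    xk, yk, gk = x[keep], y[keep], groups[keep]
    xt = xk.copy()
    yt = yk.copy()
    for g in pd.unique(gk):
        m = gk == g
        xt[m] = xk[m] - xk[m].mean()
        yt[m] = yk[m] - yk[m].mean(axis=0)
    denom = float(xt @ xt)
    slope = (xt @ yt) / denom if denom > 0 else np.zeros(y.shape[1])
    residuals = yk - np.outer(xt, slope)
    return AllometryCorrection(
        residuals=residuals, pooled_slope=slope, excluded_groups=excluded, keep_mask=keep
    )


# ---------------------------------------------------------------------------
# MANOVA
# ---------------------------------------------------------------------------

def _scatter_matrices(x: np.ndarray, groups: np.ndarray):
    labels = pd.unique(groups)
    grand = x.mean(axis=0)
    p = x.shape[1]
    h = np.zeros((p, p))
    e = np.zeros((p, p))
    for g in labels:
        xg = x[groups == g]
        mg = xg.mean(axis=0)
        d = (mg - grand)[:, None]
        h += len(xg) * (d @ d.T)
        xc = xg - mg
        e += xc.T @ xc
    return h, e, len(labels)


def manova_test(vars, groups: Sequence) -> dict:
    """One-way MANOVA: Pillai's trace and Wilks' lambda with F approximations.

    Pillai uses the standard F approximation; Wilks uses Rao's.  A singular
    within-group scatter matrix raises, advising dimension reduction (e.g.
    project onto leading principal components first).
    """
    x = np.asarray(vars, dtype=float)
    groups = np.asarray(groups)
    n, p = x.shape
    h, e, g = _scatter_matrices(x, groups)
    if g < 2:
        raise ValueError("manova_test requires at least 2 groups")
    if n <= g + p - 1:
        raise ValueError(
            f"manova_test: n={n} too small for {g} groups and {p} variables; "
            "reduce dimensionality first"
        )
    sign, logdet_e = np.linalg.slogdet(e)
    if sign <= 0 or np.linalg.cond(e) > 1e12:
        raise np.linalg.LinAlgError(
            "singular within-group scatter: reduce the number of shape "
            "variables (e.g. keep fewer principal components) before MANOVA"
        )
    lam = np.linalg.eigvals(np.linalg.solve(e, h))
    lam = np.clip(np.real(lam), 0.0, None)
    lam = np.sort(lam)[::-1]
    s = min(p, g - 1)
    lam_s = lam[:s]

    pillai = float(np.sum(lam_s / (1.0 + lam_s)))
    wilks = float(np.prod(1.0 / (1.0 + lam_s)))

    # Pillai F approximation
    m = (abs(p - (g - 1)) - 1) / 2.0
    n_ = (n - g - p - 1) / 2.0
    df1_p = s * (2 * m + s + 1)
    df2_p = s * (2 * n_ + s + 1)
    f_pillai = ((2 * n_ + s + 1) / (2 * m + s + 1)) * pillai / (s - pillai)
    p_pillai = float(stats.f.sf(f_pillai, df1_p, df2_p))

    # Rao's F approximation for Wilks
    q = g - 1
    v = n - g
    denom = p**2 + q**2 - 5
    t = np.sqrt((p**2 * q**2 - 4) / denom) if denom > 0 else 1.0
    w = v + q - (p + q + 1) / 2.0
    df1_w = p * q
    df2_w = w * t - (p * q - 2) / 2.0
    lam_t = wilks ** (1.0 / t)
    f_wilks = (1 - lam_t) / lam_t * df2_w / df1_w
    p_wilks = float(stats.f.sf(f_wilks, df1_w, df2_w))

    return {
        "pillai": pillai,
        "wilks": wilks,
        "pillai_F": float(f_pillai),
        "pillai_df": (float(df1_p), float(df2_p)),
        "pillai_p": p_pillai,
        "wilks_F": float(f_wilks),
        "wilks_df": (float(df1_w), float(df2_w)),
        "wilks_p": p_wilks,
        "n": n,
        "n_groups": g,
        "n_vars": p,
    }


# ---------------------------------------------------------------------------
# CVA dimensionality selection
# ---------------------------------------------------------------------------

def select_pc_count(
    scores: np.ndarray,
    groups: Sequence,
    n_boot: int = 100,
    seed: int | None = None,
    max_pc: int | None = None,
    plateau_tol: float = 0.01,
) -> int:
    """Number of leading PCs maximizing balanced leave-one-out LDA accuracy.

    For each candidate count k, ``n_boot`` balanced subsamples (the smallest
    valid group size drawn from every group without replacement) are
    classified by leave-one-out LDA on the first k PCs; the smallest k whose
    mean accuracy is within ``plateau_tol`` of the maximum is returned.  The
    candidate range never exceeds n_min_group - 1.  Groups with fewer than 3
    members are flagged and excluded from the selection.
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    counts = {g: int(np.sum(groups == g)) for g in labels}
    small = [g for g in labels if counts[g] < 3]
    if small:
        warnings.warn(f"groups too small for PC selection, excluded: {small}")
    valid = [g for g in labels if counts[g] >= 3]
    if len(valid) < 2:
        raise ValueError("select_pc_count requires at least 2 groups of size >= 3")
    mask = np.isin(groups, valid)
    scores, groups = scores[mask], groups[mask]
    n_min = min(int(np.sum(groups == g)) for g in valid)
    cap = min(scores.shape[1], max(1, n_min - 1))
    if max_pc is not None:
        cap = min(cap, max_pc)
    rng = np.random.default_rng(seed)

    idx_by_group = {g: np.flatnonzero(groups == g) for g in valid}
    subsamples = []
    for _ in range(n_boot):
        idx = np.concatenate(
            [rng.choice(idx_by_group[g], size=n_min, replace=False) for g in valid]
        )
        subsamples.append(idx)

    mean_acc = np.zeros(cap)
    for ki in range(1, cap + 1):
        accs = []
        for idx in subsamples:
            xs, gs = scores[idx, :ki], groups[idx]
            correct = 0
            for i in range(len(idx)):
                tr = np.ones(len(idx), dtype=bool)
                tr[i] = False
                if len(pd.unique(gs[tr])) < 2:
                    continue
                clf = LinearDiscriminantAnalysis()
                clf.fit(xs[tr], gs[tr])
                correct += int(clf.predict(xs[i : i + 1])[0] == gs[i])
            accs.append(correct / len(idx))
        mean_acc[ki - 1] = float(np.mean(accs))
    best = float(mean_acc.max())
    for ki in range(1, cap + 1):
        if mean_acc[ki - 1] >= best - plateau_tol:
            return ki
    return cap


# ---------------------------------------------------------------------------
# CVA
# ---------------------------------------------------------------------------

@dataclass
class CVAResult:
    scores: np.ndarray            # (n, n_axes)
    eigenvalues: np.ndarray       # descending
    group_means: pd.DataFrame     # group label + mean canonical scores
    mahalanobis: pd.DataFrame     # symmetric distance matrix between groups
    cv_accuracy: float            # leave-one-out classification rate
    n_pc_used: int
    axis_shape_changes: np.ndarray | None  # (p_shape, n_axes) or None
    axes: np.ndarray              # (n_pc_used, n_axes) canonical vectors


def cva(
    vars,
    groups: Sequence,
    n_pc: int | None = None,
    shape_coords: np.ndarray | None = None,
) -> CVAResult:
    """Canonical variate analysis (multigroup LDA) on the leading variables.

    Canonical axes solve the generalized eigenproblem B a = lambda W a with
    the pooled within-group covariance W; axes are normalized so the pooled
    within-group covariance of the scores is the identity.  Mahalanobis
    distances between group means use the same W on the same subspace.  When
    ``shape_coords`` is given, per-axis shape deformation vectors are
    estimated by multivariate regression of the shape variables on the
    canonical scores.
    """
    x = np.asarray(vars, dtype=float)
    groups = np.asarray(groups)
    if n_pc is None:
        n_pc = x.shape[1]
    if n_pc > x.shape[1]:
        raise ValueError("n_pc exceeds the number of available variables")
    x = x[:, :n_pc]
    labels = pd.unique(groups)
    g = len(labels)
    if g < 2:
        raise ValueError("cva requires at least 2 groups")
    for lab in labels:
        if np.sum(groups == lab) < 2:
            raise ValueError(f"cva: group {lab!r} has fewer than 2 members")
    n = x.shape[0]
    h, e, _ = _scatter_matrices(x, groups)
    w = e / (n - g)
    b = h / (g - 1)
    if np.linalg.cond(w) > 1e12:
        raise np.linalg.LinAlgError(
            "singular pooled within-group covariance: use a smaller n_pc"
        )
    evals, evecs = linalg.eigh(b, w)   # ascending, vectors with a' W a = 1
    order = np.argsort(evals)[::-1]
    n_axes = min(g - 1, n_pc)
    evals = np.clip(evals[order][:n_axes], 0.0, None)
    axes = evecs[:, order][:, :n_axes]

    grand = x.mean(axis=0)
    scores = (x - grand) @ axes

    means = np.vstack([x[groups == lab].mean(axis=0) for lab in labels])
    winv = np.linalg.inv(w)
    dmat = np.zeros((g, g))
    for i in range(g):
        for j in range(i + 1, g):
            d = means[i] - means[j]
            dmat[i, j] = dmat[j, i] = np.sqrt(d @ winv @ d)
    maha = pd.DataFrame(dmat, index=labels, columns=labels)

    # leave-one-out classification accuracy
    correct = 0
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        clf = LinearDiscriminantAnalysis()
        clf.fit(x[tr], groups[tr])
        correct += int(clf.predict(x[i : i + 1])[0] == groups[i])
    cv_acc = correct / n

    axis_changes = None
    if shape_coords is not None:
        yc = np.asarray(shape_coords, dtype=float)
        yc = yc - yc.mean(axis=0)
        # scores have identity pooled within-covariance but regression uses
        # total covariance: ordinary least squares shape-on-scores
        sts = scores.T @ scores
        axis_changes = (np.linalg.solve(sts, scores.T @ yc)).T

    gm = pd.DataFrame(
        np.vstack([scores[groups == lab].mean(axis=0) for lab in labels]),
        index=labels,
        columns=[f"CV{i + 1}" for i in range(n_axes)],
    )
    return CVAResult(
        scores=scores,
        eigenvalues=evals,
        group_means=gm,
        mahalanobis=maha,
        cv_accuracy=cv_acc,
        n_pc_used=n_pc,
        axis_shape_changes=axis_changes,
        axes=axes,
    )


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_phenogram(dist, labels: Sequence[str]) -> str:
    """Unrooted neighbor-joining tree (Newick) from a distance matrix.

    Saitou-Nei NJ with a deterministic tie-break (lowest (row, column) index
    pair in the Q matrix).  Negative branch lengths are clamped to zero with
    a warning, as is standard practice.  For additive input distances the
    path lengths on the returned tree reproduce the matrix exactly.
    """
    d = np.array(dist, dtype=float)
    labels = [str(l) for l in labels]
    n = d.shape[0]
    if d.shape != (n, n) or len(labels) != n:
        raise ValueError("distance matrix and labels mismatch")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    if n < 3:
        raise ValueError("need at least 3 taxa")

    def _blen(x: float) -> float:
        if x < 0:
            warnings.warn("negative NJ branch length clamped to 0")
            return 0.0
        return x

    nodes = list(labels)
    active = list(range(n))
    dm = d.copy()

    while len(active) > 3:
        m = len(active)
        r = {i: sum(dm[i, j] for j in active if j != i) for i in active}
        best = None
        best_q = np.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * dm[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q = q
                    best = (i, j)
        i, j = best
        li = 0.5 * dm[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = dm[i, j] - li
        li, lj = _blen(li), _blen(lj)
        # new node distances
        new_idx = dm.shape[0]
        new_row = np.zeros(new_idx + 1)
        dm = np.pad(dm, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            dm[new_idx, k] = dm[k, new_idx] = 0.5 * (dm[i, k] + dm[j, k] - dm[i, j])
        nodes.append(f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})")
        active = [k for k in active if k not in (i, j)] + [new_idx]

    a, b, c = active
    la = _blen(0.5 * (dm[a, b] + dm[a, c] - dm[b, c]))
    lb = _blen(0.5 * (dm[a, b] + dm[b, c] - dm[a, c]))
    lc = _blen(0.5 * (dm[a, c] + dm[b, c] - dm[a, b]))
    return f"({nodes[a]}:{la:.10g},{nodes[b]}:{lb:.10g},{nodes[c]}:{lc:.10g});"


# ---------------------------------------------------------------------------
# Confidence ellipses
# ---------------------------------------------------------------------------

@dataclass
class Ellipse:
    center: np.ndarray
    semi_axes: np.ndarray      # descending lengths
    angle: float               # radians, orientation of the major axis
    level: float
    degenerate: bool = False

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the ellipse."""
        pts = np.atleast_2d(points) - self.center
        rot = np.array(
            [[np.cos(self.angle), np.sin(self.angle)],
             [-np.sin(self.angle), np.cos(self.angle)]]
        )
        local = pts @ rot.T
        with np.errstate(divide="ignore", invalid="ignore"):
            q = (local[:, 0] / self.semi_axes[0]) ** 2 + (
                local[:, 1] / self.semi_axes[1]
            ) ** 2
        return q <= 1.0


def confidence_ellipse(points: np.ndarray, level: float = 0.9) -> Ellipse:
    """Normal-theory confidence ellipse of 2-D scores at probability ``level``.

    Built from the sample mean and covariance with the chi-square(2) quantile:
    semi-axis lengths are sqrt(eigenvalue * chi2_2^{-1}(level)).  ``level=0``
    yields a degenerate point; a rank-deficient covariance is flagged as a
    degenerate (line-segment) ellipse.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("confidence_ellipse expects (n, 2) points")
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points")
    if not 0.0 <= level < 1.0:
        raise ValueError("level must be in [0, 1)")
    center = pts.mean(axis=0)
    cov = np.cov(pts.T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0.0, None), evecs[:, order]
    c2 = stats.chi2.ppf(level, df=2) if level > 0 else 0.0
    semi = np.sqrt(evals * c2)
    degenerate = level == 0.0 or evals[1] <= 1e-12 * max(evals[0], 1.0)
    angle = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
    return Ellipse(center=center, semi_axes=semi, angle=angle, level=level,
                   degenerate=degenerate)
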