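"""Generalized Procrustes analysis and thin-plate-spline semi-landmark sliding.

Shapes are standardized by removing position (centroid at origin), scale
(unit centroid size) and orientation (least-squares rotation to an iterated
consensus).  Partial Procrustes fitting is used: after rotation no extra
cos(rho) rescaling is applied.  Reflections are disallowed by default —
left/right molars are expected to be pre-standardized by mirroring.

Semi-landmarks are slid along outline tangent directions so as to minimize
the thin-plate-spline bending energy of each specimen relative to the current
consensus; after each sliding pass the sample is re-superimposed and the
consensus recomputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .tps_io import LandmarkConfiguration

__all__ = [
    "ShapeSet",
    "SlidingSpec",
    "DegenerateConfigurationError",
    "SingularKernelError",
    "centroid_size",
    "gpa_align",
    "bending_energy_matrix",
    "bending_energy",
    "slide_semilandmarks",
    "cyclic_neighbors",
]


class DegenerateConfigurationError(ValueError):
    """All points coincide; size and shape are undefined."""


class SingularKernelError(ValueError):
    """Thin-plate-spline kernel is singular (coincident reference points)."""


@dataclass
class ShapeSet:
    """A Procrustes-aligned sample of landmark configurations.

    ``aligned`` is an (n_specimens, k, 2) array with every shape centered at
    the origin and scaled to unit centroid size; ``consensus`` is the mean
    shape re-standardized to the same scale.  ``centroid_sizes`` keeps the
    original sizes removed during superimposition.
    """

    aligned: np.ndarray
    centroid_sizes: np.ndarray
    consensus: np.ndarray
    ids: list[str]
    meta: list[dict] = field(default_factory=list)
    fixed_indices: tuple[int, ...] = ()
    semi_indices: tuple[int, ...] = ()
    converged: bool = True
    n_iter: int = 0
    energy_trace: list[tuple[float, float]] = field(default_factory=list)

    @property
    def n_specimens(self) -> int:
        return self.aligned.shape[0]

    @property
    def n_points(self) -> int:
        return self.aligned.shape[1]

    def flat(self) -> np.ndarray:
        """Aligned coordinates flattened to (n, 2k) Procrustes variables."""
        n = self.aligned.shape[0]
        return self.aligned.reshape(n, -1)

    def copy(self) -> "ShapeSet":
        return ShapeSet(
            aligned=self.aligned.copy(),
            centroid_sizes=self.centroid_sizes.copy(),
            consensus=self.consensus.copy(),
            ids=list(self.ids),
            meta=[dict(m) for m in self.meta],
            fixed_indices=self.fixed_indices,
            semi_indices=self.semi_indices,
            converged=self.converged,
            n_iter=self.n_iter,
            energy_trace=list(self.energy_trace),
        )


@dataclass
class SlidingSpec:
    """Iteration control for bending-energy semi-landmark sliding.

    ``neighbors`` gives, for each semi-landmark (in ``semi_indices`` order),
    the two outline points used for the central-difference tangent estimate.
    """

    semi_indices: tuple[int, ...]
    neighbors: tuple[tuple[int, int], ...]
    max_iter: int = 10
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if len(self.neighbors) != len(self.semi_indices):
            raise ValueError("one (prev, next) neighbor pair per semi-landmark required")


def cyclic_neighbors(semi_indices: Sequence[int], closed: bool = True) -> tuple[tuple[int, int], ...]:
    """Neighbor pairs for semi-landmarks forming an outline in index order.

    For a closed outline the first/last semi-landmarks wrap around; for an
    open outline the endpoints use their single inner neighbor twice
    (one-sided difference).
    """
    s = list(semi_indices)
    m = len(s)
    out = []
    for j in range(m):
        if closed:
            out.append((s[(j - 1) % m], s[(j + 1) % m]))
        else:
            prev = s[j - 1] if j > 0 else s[j]
            nxt = s[j + 1] if j < m - 1 else s[j]
            if prev == s[j]:
                prev = s[j + 1]
                nxt = s[min(j + 2, m - 1)]
            if nxt == s[j]:
                nxt = s[j - 1]
                prev = s[max(j - 2, 0)]
            out.append((prev, nxt))
    return tuple(out)


# ---------------------------------------------------------------------------
# Centroid size and GPA
# ---------------------------------------------------------------------------

def _as_points(config) -> np.ndarray:
    if isinstance(config, LandmarkConfiguration):
        return np.asarray(config.points, dtype=float)
    return np.asarray(config, dtype=float)


def centroid_size(config) -> float:
    """Square root of the summed squared distances of all points to their centroid."""
    pts = _as_points(config)
    if pts.shape[0] < 2:
        raise DegenerateConfigurationError("need at least 2 points")
    centered = pts - pts.mean(axis=0)
    cs = float(np.sqrt(np.sum(centered**2)))
    if cs <= 0.0 or not np.isfinite(cs):
        raise DegenerateConfigurationError("all points coincide: centroid size is 0")
    return cs


def _standardize(pts: np.ndarray) -> np.ndarray:
    """Center at origin and scale to unit centroid size."""
    centered = pts - pts.mean(axis=0)
    cs = np.sqrt(np.sum(centered**2))
    if cs <= 0:
        raise DegenerateConfigurationError("degenerate configuration")
    return centered / cs

def optimal_rotation(source: np.ndarray, target: np.ndarray, allow_reflection: bool = False) -> np.ndarray:
    """Rotation R minimizing ||source @ R - target||_F (both pre-centered)."""
    h = source.T @ target
    u, _, vt = np.linalg.svd(h)
    r = u @ vt
    if not allow_reflection and np.linalg.det(r) < 0:
        u[:, -1] *= -1.0
        r = u @ vt
    return r


def gpa_align(
    configs: Sequence,
    tol: float = 1e-10,
    max_iter: int = 100,
    allow_reflection: bool = False,
) -> ShapeSet:
    """Generalized (partial) Procrustes superimposition of a sample.

    Iteratively rotates every standardized shape onto the running consensus
    and re-estimates the consensus until it stabilizes (Frobenius change
    below ``tol``).  All configurations must share the same point count and
    landmark role scheme.
    """
    if len(configs) == 0:
        raise ValueError("gpa_align: empty sample")
    ids, meta, mats = [], [], []
    fixed_idx: tuple[int, ...] = ()
    semi_idx: tuple[int, ...] = ()
    for i, cfg in enumerate(configs):
        if isinstance(cfg, LandmarkConfiguration):
            ids.append(cfg.specimen_id)
            meta.append(dict(cfg.meta))
            mats.append(np.asarray(cfg.points, dtype=float))
            if i == 0:
                fixed_idx, semi_idx = cfg.fixed_indices, cfg.semi_indices
            elif (cfg.fixed_indices, cfg.semi_indices) != (fixed_idx, semi_idx):
                raise ValueError("gpa_align: inconsistent landmark role schemes")
        else:
            ids.append(f"spec{i}")
            meta.append({})
            mats.append(np.asarray(cfg, dtype=float))
    k = mats[0].shape[0]
    for sid, m in zip(ids, mats):
        if m.shape != (k, 2):
            raise ValueError(
                f"gpa_align: specimen {sid} has point matrix {m.shape}, expected ({k}, 2)"
            )
    sizes = np.array([centroid_size(m) for m in mats])
    shapes = np.stack([_standardize(m) for m in mats])

    consensus = shapes[0].copy()
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        for i in range(shapes.shape[0]):
            shapes[i] = shapes[i] @ optimal_rotation(shapes[i], consensus, allow_reflection)
        new_consensus = _standardize(shapes.mean(axis=0))
        delta = np.linalg.norm(new_consensus - consensus)
        consensus = new_consensus
        if delta < tol:
            break

    return ShapeSet(
        aligned=shapes,
        centroid_sizes=sizes,
        consensus=consensus,
        ids=ids,
        meta=meta,
        fixed_indices=fixed_idx,
        semi_indices=semi_idx,
        converged=True,
        n_iter=n_iter,
    )


# ---------------------------------------------------------------------------
# Thin-plate-spline bending energy
# ---------------------------------------------------------------------------

def _tps_kernel(ref: np.ndarray) -> np.ndarray:
    d2 = np.sum((ref[:, None, :] - ref[None, :, :]) ** 2, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        k = d2 * np.log(d2)
    k[d2 == 0.0] = 0.0
    return k


def bending_energy_matrix(reference: np.ndarray) -> np.ndarray:
    """Bending-energy matrix of the 2-D thin-plate spline on ``reference``.

    Uses the kernel U(r) = r^2 log r^2.  The returned k x k matrix B is
    symmetric positive semi-definite and annihilates displacement fields that
    are affine transforms of the reference.  The energy of a displacement
    field v (one column per Cartesian coordinate) is
    ``v[:,0] @ B @ v[:,0] + v[:,1] @ B @ v[:,1]``.
    """
    ref = np.asarray(reference, dtype=float)
    k = ref.shape[0]
    d2 = np.sum((ref[:, None, :] - ref[None, :, :]) ** 2, axis=-1)
    if np.min(d2[~np.eye(k, dtype=bool)]) < 1e-24:
        raise SingularKernelError("coincident reference points in TPS kernel")
    kk = _tps_kernel(ref)
    q = np.column_stack([np.ones(k), ref])
    l = np.zeros((k + 3, k + 3))
    l[:k, :k] = kk
    l[:k, k:] = q
    l[k:, :k] = q.T
    try:
        linv = np.linalg.inv(l)
    except np.linalg.LinAlgError as exc:
        raise SingularKernelError("singular TPS system") from exc
    b = linv[:k, :k]
    return (b + b.T) / 2.0


def bending_energy(b: np.ndarray, displacement: np.ndarray) -> float:
    """Quadratic-form bending energy of a (k, 2) displacement field."""
    v = np.asarray(displacement, dtype=float)
    return float(v[:, 0] @ b @ v[:, 0] + v[:, 1] @ b @ v[:, 1])


# ---------------------------------------------------------------------------
# Semi-landmark sliding
# ---------------------------------------------------------------------------

def _slide_one(
    points: np.ndarray,
    consensus: np.ndarray,
    b: np.ndarray,
    semi: np.ndarray,
    neighbors: Sequence[tuple[int, int]],
) -> tuple[np.ndarray, float]:
    """Slide one specimen's semi-landmarks along tangents; return new points
    and the mean absolute sliding amount."""
    tangents = np.empty((len(semi), 2))
    for j, (p, q) in enumerate(neighbors):
        t = points[q] - points[p]
        norm = np.linalg.norm(t)
        if norm < 1e-12:
            t = np.array([1.0, 0.0])
            norm = 1.0
        tangents[j] = t / norm

    k = points.shape[0]
    m = len(semi)
    px = np.zeros((k, m))
    py = np.zeros((k, m))
    px[semi, np.arange(m)] = tangents[:, 0]
    py[semi, np.arange(m)] = tangents[:, 1]
    v = points - consensus
    a = px.T @ b @ px + py.T @ b @ py
    rhs = -(px.T @ b @ v[:, 0] + py.T @ b @ v[:, 1])
    a = a + np.eye(m) * (1e-12 * max(np.trace(a) / m, 1.0))
    t_amt = np.linalg.solve(a, rhs)
    new_points = points.copy()
    new_points[semi] += t_amt[:, None] * tangents
    return new_points, float(np.mean(np.abs(t_amt)))


def slide_semilandmarks(shapes: ShapeSet, spec: SlidingSpec) -> ShapeSet:
    """Slide semi-landmarks to minimize bending energy against the consensus.

    Each pass: estimate tangents from each specimen's outline neighbors,
    solve the per-specimen least-squares sliding amounts, then re-superimpose
    the sample and recompute the consensus.  Iterates until the mean sliding
    displacement falls below ``spec.tol`` or ``spec.max_iter`` passes; on
    non-convergence the last state is returned with ``converged=False``.
    Fixed landmarks are never moved.  ``energy_trace`` records the total
    bending energy (relative to the pass's consensus) before and after each
    sliding pass; within a pass it can only decrease.
    """
    semi = np.asarray(spec.semi_indices, dtype=int)
    if semi.size == 0:
        out = shapes.copy()
        out.converged = True
        return out
    if semi.max() >= shapes.n_points or semi.min() < 0:
        raise ValueError("semi-landmark index out of range")
    for p, q in spec.neighbors:
        if not (0 <= p < shapes.n_points and 0 <= q < shapes.n_points):
            raise ValueError("neighbor index out of range")

    current = shapes.copy()
    converged = False
    trace: list[tuple[float, float]] = []
    n_pass = 0
    for n_pass in range(1, spec.max_iter + 1):
        consensus = current.consensus
        b = bending_energy_matrix(consensus)
        before = sum(
            bending_energy(b, current.aligned[i] - consensus)
            for i in range(current.n_specimens)
        )
        new_shapes = np.empty_like(current.aligned)
        amounts = np.empty(current.n_specimens)
        for i in range(current.n_specimens):
            new_shapes[i], amounts[i] = _slide_one(
                current.aligned[i], consensus, b, semi, spec.neighbors
            )
        after = sum(
            bending_energy(b, new_shapes[i] - consensus)
            for i in range(current.n_specimens)
        )
        trace.append((before, after))

        realigned = gpa_align([new_shapes[i] for i in range(new_shapes.shape[0])])
        current = ShapeSet(
            aligned=realigned.aligned,
            centroid_sizes=current.centroid_sizes,
            consensus=realigned.consensus,
            ids=current.ids,
            meta=current.meta,
            fixed_indices=current.fixed_indices,
            semi_indices=current.semi_indices,
        )
        if float(np.mean(amounts)) < spec.tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"semi-landmark sliding did not converge in {spec.max_iter} passes",
            RuntimeWarning,
        )
    current.converged = converged
    current.n_iter = n_pass
    current.energy_trace = trace
    return current
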