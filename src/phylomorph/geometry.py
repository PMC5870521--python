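"""Landmark configurations and Procrustes superimposition with object symmetry.

The observational unit is a configuration of K homologous 3D landmarks
digitized on one specimen (the default scheme has K = 17 points on a catfish
neurocranium).  Generalized Procrustes analysis (GPA) removes position,
orientation and — optionally — size by iteratively superimposing all
configurations on their consensus.  Structures with internal bilateral
symmetry ("object symmetry") are handled by aligning each configuration
together with its reflected, relabeled copy; the average of the two aligned
copies is the symmetric shape component used by all downstream statistics,
and half their difference is the asymmetric component.

Missing landmarks are estimated before superimposition with a 3D thin-plate
spline (kernel U(r) = r plus an affine term) warping a complete reference
onto the specimen's present landmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LandmarkConfiguration",
    "SymmetryMap",
    "AlignedDataset",
    "DegenerateConfigurationError",
    "GPAConvergenceError",
    "centroid_size",
    "center",
    "optimal_superimpose",
    "gpa",
    "reflect_relabel",
    "symmetric_gpa",
    "procrustes_distance",
    "estimate_missing_tps",
]


class DegenerateConfigurationError(ValueError):
    """Raised when a configuration cannot support the requested operation."""


class GPAConvergenceError(RuntimeError):
    """Raised when iterative superimposition fails to converge."""

    def __init__(self, message: str, n_iter: int, last_change: float):
        super().__init__(message)
        self.n_iter = n_iter
        self.last_change = last_change


@dataclass
class LandmarkConfiguration:
    """One specimen's K x 3 landmark coordinates with a missing-value mask.

    Parameters
    ----------
    specimen_id
        Unique specimen label.
    coords
        (K, 3) array of coordinates in mm.  Rows whose ``present_mask`` entry
        is False are placeholders (their values are ignored).
    present_mask
        (K,) boolean array; True where the landmark was digitized.
    """

    specimen_id: str
    coords: np.ndarray
    present_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(
                f"coords must be (K, 3); got {self.coords.shape} "
                f"for specimen {self.specimen_id!r}"
            )
        if self.present_mask is None:
            self.present_mask = np.ones(self.coords.shape[0], dtype=bool)
        self.present_mask = np.asarray(self.present_mask, dtype=bool)
        if self.present_mask.shape != (self.coords.shape[0],):
            raise ValueError("present_mask must have one entry per landmark")
        if not np.all(np.isfinite(self.coords[self.present_mask])):
            raise ValueError(
                f"non-finite coordinates for present landmarks of "
                f"specimen {self.specimen_id!r}"
            )

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]

    @property
    def is_complete(self) -> bool:
        return bool(self.present_mask.all())


@dataclass(frozen=True)
class SymmetryMap:
    """Bilateral landmark pairing: (left, right) index pairs plus midline indices.

    Indices are 0-based internally; the JSON interchange format is 1-based
    (see :mod:`phylomorph.io`).  Paired and midline indices must not overlap
    and no index may appear twice.
    """

    paired: tuple[tuple[int, int], ...]
    midline: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "paired", tuple((int(a), int(b)) for a, b in self.paired))
        object.__setattr__(self, "midline", tuple(int(m) for m in self.midline))
        seen: list[int] = [i for pair in self.paired for i in pair]
        seen += list(self.midline)
        if len(set(seen)) != len(seen):
            raise ValueError("symmetry map indices overlap or repeat")
        if seen and min(seen) < 0:
            raise ValueError("symmetry map indices must be non-negative")

    def validate_for(self, k: int) -> None:
        idx = [i for pair in self.paired for i in pair] + list(self.midline)
        bad = [i for i in idx if i >= k]
        if bad:
            raise ValueError(f"symmetry map indices {bad} outside 0..{k - 1}")


@dataclass
class AlignedDataset:
    """Procrustes-aligned shapes: the input to every downstream statistic.

    ``shapes`` holds the symmetric component when produced by
    :func:`symmetric_gpa`, in which case ``asymmetric_components`` holds the
    per-specimen asymmetric remainder (aligned original = symmetric +
    asymmetric).
    """

    shapes: np.ndarray  # (n, K, 3)
    centroid_sizes: np.ndarray  # (n,)
    consensus: np.ndarray  # (K, 3)
    specimen_ids: list[str] = field(default_factory=list)
    asymmetric_components: np.ndarray | None = None

    @property
    def n_specimens(self) -> int:
        return self.shapes.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.shapes.shape[1]

    def flat(self) -> np.ndarray:
        """Shapes flattened to (n, 3K) row vectors."""
        return self.shapes.reshape(self.n_specimens, -1)

    def subset(self, index) -> "AlignedDataset":
        """Restrict to the specimens selected by a boolean mask or index array."""
        index = np.asarray(index)
        pos = np.flatnonzero(index) if index.dtype == bool else index
        return AlignedDataset(
            shapes=self.shapes[pos],
            centroid_sizes=self.centroid_sizes[pos],
            consensus=self.shapes[pos].mean(axis=0),
            specimen_ids=[self.specimen_ids[i] for i in pos],
            asymmetric_components=None
            if self.asymmetric_components is None
            else self.asymmetric_components[pos],
        )


def _as_coords(shape) -> np.ndarray:
    arr = np.asarray(shape, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError(f"expected a (K, 3) coordinate array, got {arr.shape}")
    return arr


def centroid_size(config) -> float:
    """Centroid size: sqrt of summed squared distances of landmarks to their centroid.

    Accepts a :class:`LandmarkConfiguration` (present landmarks only) or a
    bare (K, 3) array.
    """
    if isinstance(config, LandmarkConfiguration):
        pts = config.coords[config.present_mask]
    else:
        pts = _as_coords(config)
    if pts.shape[0] < 2 or np.unique(pts, axis=0).shape[0] < 2:
        raise DegenerateConfigurationError("need >= 2 distinct landmarks for centroid size")
    cs = float(np.sqrt(((pts - pts.mean(axis=0)) ** 2).sum()))
    if cs == 0.0:
        raise DegenerateConfigurationError("all landmarks coincide")
    return cs


def center(shape: np.ndarray) -> np.ndarray:
    """Translate a configuration so its centroid is at the origin."""
    shape = _as_coords(shape)
    return shape - shape.mean(axis=0)


def optimal_superimpose(moving: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, float]:
    """Rotate ``moving`` onto ``target`` by the optimal proper rotation.

    Both configurations must already be centered.  The rotation minimizing
    the summed squared landmark distances is obtained from the SVD of the
    cross-covariance matrix, with the determinant constrained to +1 so that
    reflections are never introduced.

    Returns
    -------
    rotated, residual
        The rotated configuration and the Procrustes (root-sum-of-squares)
        residual distance to the target.
    """
    moving = _as_coords(moving)
    target = _as_coords(target)
    if moving.shape != target.shape:
        raise ValueError(f"shape mismatch: {moving.shape} vs {target.shape}")
    u, _, vt = np.linalg.svd(moving.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    rotated = moving @ rot
    return rotated, float(np.linalg.norm(rotated - target))


def _check_complete(configs: list[LandmarkConfiguration]) -> np.ndarray:
    if len(configs) < 2:
        raise ValueError("need >= 2 configurations for superimposition")
    k = configs[0].n_landmarks
    for c in configs:
        if c.n_landmarks != k:
            raise ValueError(
                f"landmark count mismatch: {c.specimen_id!r} has {c.n_landmarks}, expected {k}"
            )
        if not c.is_complete:
            raise ValueError(
                f"specimen {c.specimen_id!r} has missing landmarks; "
                "run estimate_missing_tps first"
            )
    return np.stack([c.coords for c in configs])


def _gpa_arrays(
    arr: np.ndarray, scale: bool, tol: float = 1e-24, max_iter: int = 1000
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative GPA on an (n, K, 3) stack.  Returns aligned stack and consensus.

    Convergence is on the squared change of the consensus itself (default
    1e-24, i.e. consensus stable to ~1e-12), which makes the result
    invariant to input ordering and similarity transforms to ~1e-9.
    """
    n = arr.shape[0]
    sizes = np.array([centroid_size(a) for a in arr])
    work = np.stack([center(a) for a in arr])
    if scale:
        work = work / sizes[:, None, None]

    consensus = work[0].copy()
    if scale:
        consensus = consensus / centroid_size(consensus)
    change = np.inf
    for _ in range(max_iter):
        for i in range(n):
            work[i], _ = optimal_superimpose(work[i], consensus)
        new = work.mean(axis=0)
        new -= new.mean(axis=0)
        if scale:
            new = new / centroid_size(new)
        change = float(((new - consensus) ** 2).sum())
        consensus = new
        if change < tol:
            break
    else:
        raise GPAConvergenceError(
            f"GPA did not converge in {max_iter} iterations "
            f"(last consensus change {change:.3e})",
            n_iter=max_iter,
            last_change=change,
        )
    # final pass so every configuration is optimally rotated to the converged
    # consensus; the returned consensus is the plain arithmetic mean of the
    # aligned shapes (the unit-size rescale is only the iteration reference)
    for i in range(n):
        work[i], _ = optimal_superimpose(work[i], consensus)
    consensus = work.mean(axis=0)
    consensus -= consensus.mean(axis=0)
    return work, consensus


def gpa(
    configs: list[LandmarkConfiguration],
    scale: bool = True,
    tol: float = 1e-24,
    max_iter: int = 1000,
) -> AlignedDataset:
    """Generalized Procrustes analysis: translate, scale and rotate to consensus.

    Convergence is declared when the squared change of the consensus between
    iterations falls below ``tol``; the consensus is recentered (and rescaled
    to unit centroid size when ``scale``) every iteration.
    """
    arr = _check_complete(configs)
    sizes = np.array([centroid_size(a) for a in arr])
    aligned, consensus = _gpa_arrays(arr, scale=scale, tol=tol, max_iter=max_iter)
    return AlignedDataset(
        shapes=aligned,
        centroid_sizes=sizes,
        consensus=consensus,
        specimen_ids=[c.specimen_id for c in configs],
    )


def reflect_relabel(shape: np.ndarray, symmetry_map: SymmetryMap) -> np.ndarray:
    """Mirror a configuration and swap bilateral landmark labels.

    The reflection negates the first coordinate axis (the choice of plane is
    immaterial after superimposition, which removes orientation); paired
    landmarks then swap rows so left stays left.  Applying the operation
    twice returns the input exactly.
    """
    shape = _as_coords(shape)
    symmetry_map.validate_for(shape.shape[0])
    out = shape.copy()
    out[:, 0] = -out[:, 0]
    for a, b in symmetry_map.paired:
        out[[a, b]] = out[[b, a]]
    return out


def symmetric_gpa(
    configs: list[LandmarkConfiguration],
    symmetry_map: SymmetryMap,
    scale: bool = True,
    tol: float = 1e-24,
    max_iter: int = 1000,
) -> AlignedDataset:
    """GPA accounting for object symmetry.

    The 2n-set of originals plus reflected/relabeled copies is superimposed
    jointly; each specimen's symmetric component is the mean of its two
    aligned copies and its asymmetric component half their difference, so
    symmetric + asymmetric reconstructs the aligned original exactly.
    """
    arr = _check_complete(configs)
    symmetry_map.validate_for(arr.shape[1])
    mirrored = np.stack([reflect_relabel(a, symmetry_map) for a in arr])
    both = np.concatenate([arr, mirrored])
    aligned, consensus = _gpa_arrays(both, scale=scale, tol=tol, max_iter=max_iter)
    n = arr.shape[0]
    orig, mirr = aligned[:n], aligned[n:]
    symmetric = 0.5 * (orig + mirr)
    asymmetric = 0.5 * (orig - mirr)
    sizes = np.array([centroid_size(a) for a in arr])
    return AlignedDataset(
        shapes=symmetric,
        centroid_sizes=sizes,
        consensus=symmetric.mean(axis=0),
        specimen_ids=[c.specimen_id for c in configs],
        asymmetric_components=asymmetric,
    )


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean norm of the flattened coordinate difference of aligned shapes."""
    a = _as_coords(a)
    b = _as_coords(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


def _tps_system(src: np.ndarray) -> np.ndarray:
    """Assemble the (m+4, m+4) thin-plate-spline system matrix for 3D sources."""
    m = src.shape[0]
    r = np.linalg.norm(src[:, None, :] - src[None, :, :], axis=-1)
    p = np.hstack([np.ones((m, 1)), src])  # affine part: 1, x, y, z
    sys = np.zeros((m + 4, m + 4))
    sys[:m, :m] = r  # U(r) = r kernel (3D)
    sys[:m, m:] = p
    sys[m:, :m] = p.T
    return sys


def tps_warp(src: np.ndarray, dst: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Fit a 3D thin-plate spline mapping ``src`` -> ``dst`` and evaluate at ``query``.

    Uses the radial kernel U(r) = r with an affine polynomial part.  The
    linear system is solved directly; a numerically singular system (e.g.
    coplanar sources) is rejected.
    """
    src = _as_coords(src)
    dst = _as_coords(dst)
    if src.shape != dst.shape:
        raise ValueError("source and destination landmark sets differ in size")
    m = src.shape[0]
    if m < 4:
        raise DegenerateConfigurationError("TPS needs >= 4 common landmarks")
    sys = _tps_system(src)
    rhs = np.zeros((m + 4, 3))
    rhs[:m] = dst
    try:
        coef = np.linalg.solve(sys, rhs)
    except np.linalg.LinAlgError as exc:
        raise DegenerateConfigurationError(
            "degenerate (coplanar or coincident) common landmarks"
        ) from exc
    if not np.all(np.isfinite(coef)):
        raise DegenerateConfigurationError("TPS system numerically singular")
    w, a = coef[:m], coef[m:]
    rq = np.linalg.norm(query[:, None, :] - src[None, :, :], axis=-1)
    return rq @ w + np.hstack([np.ones((query.shape[0], 1)), query]) @ a


def estimate_missing_tps(
    incomplete: LandmarkConfiguration, reference: np.ndarray
) -> LandmarkConfiguration:
    """Estimate missing landmarks by warping a complete reference onto the specimen.

    A thin-plate spline is fit from the reference's landmarks at the
    specimen's present positions onto the specimen; missing positions are the
    spline images of the reference's corresponding landmarks.  Present
    landmarks are returned unchanged.  Because the spline's polynomial part
    is affine, any affine deformation of the reference is reproduced exactly.
    """
    reference = _as_coords(reference)
    if reference.shape[0] != incomplete.n_landmarks:
        raise ValueError("reference landmark count does not match specimen")
    mask = incomplete.present_mask
    if incomplete.is_complete:
        return incomplete
    n_common = int(mask.sum())
    if n_common < 4:
        raise DegenerateConfigurationError(
            f"only {n_common} common landmarks; TPS estimation needs >= 4"
        )
    # coplanarity check on the common landmarks
    common_ref = reference[mask]
    centered = common_ref - common_ref.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(centered).max())) < 3:
        raise DegenerateConfigurationError("common landmarks are coplanar")
    est = tps_warp(common_ref, incomplete.coords[mask], reference[~mask])
    coords = incomplete.coords.copy()
    coords[~mask] = est
    return LandmarkConfiguration(
        specimen_id=incomplete.specimen_id,
        coords=coords,
        present_mask=np.ones(incomplete.n_landmarks, dtype=bool),
    )
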