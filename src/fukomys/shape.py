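"""Landmark-based skull-shape analysis.

Covers the TPS landmark file format (tpsDIG-style LM= blocks), generalized
Procrustes analysis (GPA), relative warps (principal components of
Procrustes-aligned shape variation, uniform alpha = 0 weighting), replicate
averaging, and thin-plate-spline deformation grids with bending energy.

Skull photographs share an orientation, so reflections are never allowed in
the superimposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateShapeError, FormatError

#: Expected landmark counts per photographed skull surface.
VIEW_LANDMARKS = {"dorsal": 15, "ventral": 17}


@dataclass
class LandmarkConfig:
    """One digitized photograph: k 2-D landmarks plus labels."""

    coords: np.ndarray  # (k, 2)
    specimen: str = ""
    replicate: int = 0
    view: str | None = None
    group: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise FormatError("landmark coordinates must be (k, 2)")
        if not np.all(np.isfinite(self.coords)):
            raise FormatError("non-finite landmark coordinates")
        if self.view is not None and self.view in VIEW_LANDMARKS:
            k = VIEW_LANDMARKS[self.view]
            if self.coords.shape[0] != k:
                raise FormatError(
                    f"{self.view} view requires {k} landmarks, "
                    f"got {self.coords.shape[0]}"
                )


def read_tps(path, view: str | None = None) -> list[LandmarkConfig]:
    """Parse a TPS landmark file into one config per LM block.

    Recognizes LM=, ID=, IMAGE= and SCALE= fields; SCALE multiplies the raw
    coordinates.  If ``view`` is given, every block must carry the matching
    landmark count.
    """
    configs: list[LandmarkConfig] = []
    block_coords: list[list[float]] = []
    expected = 0
    meta: dict = {}

    def flush() -> None:
        nonlocal block_coords, meta, expected
        if expected == 0 and not block_coords:
            return
        if len(block_coords) != expected:
            raise FormatError(
                f"LM={expected} but {len(block_coords)} coordinate rows found"
            )
        coords = np.array(block_coords, dtype=float)
        coords *= meta.get("scale", 1.0)
        configs.append(
            LandmarkConfig(
                coords=coords,
                specimen=str(meta.get("id", meta.get("image", len(configs)))),
                view=view,
            )
        )
        block_coords, meta, expected = [], {}, 0

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM="):
                flush()
                expected = int(line.split("=", 1)[1])
            elif upper.startswith("ID="):
                meta["id"] = line.split("=", 1)[1].strip()
            elif upper.startswith("IMAGE="):
                meta["image"] = line.split("=", 1)[1].strip()
            elif upper.startswith("SCALE="):
                meta["scale"] = float(line.split("=", 1)[1])
            else:
                parts = line.split()
                if len(parts) != 2:
                    raise FormatError(f"unparseable TPS line: {line!r}")
                block_coords.append([float(parts[0]), float(parts[1])])
    flush()
    if not configs:
        raise FormatError(f"no landmark blocks in {path}")
    return configs


def write_tps(configs: list[LandmarkConfig], path) -> None:
    with open(path, "w") as fh:
        for cfg in configs:
            fh.write(f"LM={cfg.coords.shape[0]}\n")
            for x, y in cfg.coords:
                fh.write(f"{x:.10g} {y:.10g}\n")
            fh.write(f"ID={cfg.specimen}\n")


def centroid_size(coords: np.ndarray) -> float:
    c = coords - coords.mean(axis=0)
    return float(np.sqrt((c ** 2).sum()))


def _preshape(coords: np.ndarray) -> np.ndarray:
    """Center and scale to unit centroid size."""
    c = coords - coords.mean(axis=0)
    cs = np.sqrt((c ** 2).sum())
    if cs == 0:
        raise DegenerateShapeError("all landmarks coincide")
    return c / cs


def _optimal_rotation(x: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation (no reflection) aligning x onto target, least squares."""
    u, _, vt = np.linalg.svd(x.T @ target)
    r = u @ vt
    if np.linalg.det(r) < 0:  # flip smallest singular direction: pure rotation
        u[:, -1] *= -1
        r = u @ vt
    return r


@dataclass
class AlignedShapes:
    """Output of GPA: unit-size aligned configurations and their consensus."""

    coords: np.ndarray  # (n, k, 2)
    consensus: np.ndarray  # (k, 2)
    centroid_sizes: np.ndarray  # (n,) original sizes
    labels: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.coords.shape[0]


def gpa(
    configs,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> AlignedShapes:
    """Generalized Procrustes superimposition.

    Accepts a list of :class:`LandmarkConfig` or an (n, k, 2) array.  Each
    configuration is centered, scaled to unit centroid size, and rotated to
    the running consensus; iteration stops when the consensus moves by less
    than ``tol`` (RMS).
    """
    if isinstance(configs, np.ndarray):
        arrays = [configs[i] for i in range(configs.shape[0])]
        labels = list(range(len(arrays)))
    else:
        arrays = [c.coords for c in configs]
        labels = [
            (c.specimen, c.replicate) if isinstance(c, LandmarkConfig) else i
            for i, c in enumerate(configs)
        ]
    if len(arrays) < 2:
        raise DegenerateShapeError("GPA requires at least two configurations")
    ks = {a.shape[0] for a in arrays}
    if len(ks) != 1:
        raise DegenerateShapeError(f"mixed landmark counts: {sorted(ks)}")
    sizes = np.array([centroid_size(a) for a in arrays])
    shapes = np.stack([_preshape(a) for a in arrays])

    consensus = shapes[0].copy()
    for _ in range(max_iter):
        for i in range(shapes.shape[0]):
            shapes[i] = shapes[i] @ _optimal_rotation(shapes[i], consensus)
        new_consensus = shapes.mean(axis=0)
        new_consensus = _preshape(new_consensus)
        delta = np.sqrt(((new_consensus - consensus) ** 2).mean())
        consensus = new_consensus
        if delta < tol:
            break
    return AlignedShapes(
        coords=shapes, consensus=consensus, centroid_sizes=sizes, labels=labels
    )


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Full Procrustes distance between two configurations (no reflection)."""
    x, y = _preshape(a), _preshape(b)
    r = _optimal_rotation(x, y)
    return float(np.sqrt(((x @ r - y) ** 2).sum()))


def average_replicates(aligned: AlignedShapes, specimen_of=None) -> AlignedShapes:
    """Mean aligned configuration per specimen, re-normalized to unit size.

    ``specimen_of`` maps each aligned configuration's label to a specimen id;
    by default labels of the form (specimen, replicate) are grouped on their
    first element.
    """
    if specimen_of is None:
        def specimen_of(label):
            return label[0] if isinstance(label, tuple) else label

    order: list = []
    groups: dict = {}
    for i, lab in enumerate(aligned.labels):
        s = specimen_of(lab)
        if s not in groups:
            groups[s] = []
            order.append(s)
        groups[s].append(i)
    means = []
    sizes = []
    for s in order:
        mean_cfg = aligned.coords[groups[s]].mean(axis=0)
        means.append(_preshape(mean_cfg))
        sizes.append(float(aligned.centroid_sizes[groups[s]].mean()))
    return AlignedShapes(
        coords=np.stack(means),
        consensus=aligned.consensus,
        centroid_sizes=np.array(sizes),
        labels=order,
    )


@dataclass
class WarpScores:
    """Relative-warp ordination: per-specimen scores + variance fractions."""

    scores: np.ndarray  # (n, n_axes)
    axes: np.ndarray  # (n_axes, 2k) loadings
    variance_fractions: np.ndarray
    labels: list = field(default_factory=list)


def relative_warps(aligned: AlignedShapes) -> WarpScores:
    """PCA of aligned-coordinate deviations from the consensus (alpha = 0).

    Axes are ordered by explained variance; each axis's sign is fixed so its
    largest-magnitude loading is positive.
    """
    n = aligned.n
    if n < 2:
        raise DegenerateShapeError("relative warps require >= 2 specimens")
    flat = aligned.coords.reshape(n, -1)
    resid = flat - aligned.consensus.reshape(1, -1)
    resid = resid - resid.mean(axis=0)  # center on the sample mean
    u, s, vt = np.linalg.svd(resid, full_matrices=False)
    keep = s > max(s[0], 1e-300) * 1e-12 if s[0] > 0 else s > -1
    u, s, vt = u[:, keep], s[keep], vt[keep]
    for i in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    scores = u * s
    var = s ** 2
    fractions = var / var.sum() if var.sum() > 0 else var
    return WarpScores(
        scores=scores,
        axes=vt,
        variance_fractions=fractions,
        labels=list(aligned.labels),
    )


@dataclass
class TPSDeformation:
    """Thin-plate-spline map from a reference onto a target configuration."""

    reference: np.ndarray
    target: np.ndarray
    weights: np.ndarray  # (k, 2) non-affine weights
    affine: np.ndarray  # (3, 2) affine part [const; x; y]
    bending_energy: float
    grid: np.ndarray  # (res, res, 2) deformed lattice

    def transform(self, points: np.ndarray) -> np.ndarray:
        return _tps_map(points, self.reference, self.weights, self.affine)


def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    # U(r) = r^2 log r^2, with U(0) = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = r2 * np.log(r2)
    return np.where(r2 > 0, out, 0.0)


def _tps_map(points, reference, weights, affine):
    points = np.atleast_2d(points)
    d2 = ((points[:, None, :] - reference[None, :, :]) ** 2).sum(axis=2)
    u = _tps_kernel(d2)
    aff = affine[0] + points @ affine[1:]
    return aff + u @ weights


def tps_deformation(
    reference: np.ndarray,
    target: np.ndarray,
    grid_resolution: int = 20,
    margin: float = 0.1,
) -> TPSDeformation:
    """Exact thin-plate-spline interpolant mapping reference -> target.

    Solves the standard bordered system [[K P],[P' 0]]; the bending energy
    is ``sum_dim w' K w``.  A collinear reference makes the system singular
    and raises :class:`DegenerateShapeError`.
    """
    reference = np.asarray(reference, dtype=float)
    target = np.asarray(target, dtype=float)
    k = reference.shape[0]
    if reference.shape != target.shape or reference.shape[1] != 2:
        raise FormatError("reference and target must both be (k, 2)")
    d2 = ((reference[:, None, :] - reference[None, :, :]) ** 2).sum(axis=2)
    kmat = _tps_kernel(d2)
    p = np.hstack([np.ones((k, 1)), reference])
    if np.linalg.matrix_rank(p) < 3:
        raise DegenerateShapeError(
            "TPS system singular (collinear or coincident reference landmarks)"
        )
    sys = np.zeros((k + 3, k + 3))
    sys[:k, :k] = kmat
    sys[:k, k:] = p
    sys[k:, :k] = p.T
    rhs = np.zeros((k + 3, 2))
    rhs[:k] = target
    try:
        sol = np.linalg.solve(sys, rhs)
    except np.linalg.LinAlgError as exc:
        raise DegenerateShapeError(
            "TPS system singular (collinear or coincident reference landmarks)"
        ) from exc
    weights, affine = sol[:k], sol[k:]
    bending = float(sum(weights[:, dim] @ kmat @ weights[:, dim] for dim in (0, 1)))

    lo = reference.min(axis=0)
    hi = reference.max(axis=0)
    span = hi - lo
    lo = lo - margin * span
    hi = hi + margin * span
    gx = np.linspace(lo[0], hi[0], grid_resolution)
    gy = np.linspace(lo[1], hi[1], grid_resolution)
    lattice = np.stack(np.meshgrid(gx, gy), axis=-1).reshape(-1, 2)
    grid = _tps_map(lattice, reference, weights, affine).reshape(
        grid_resolution, grid_resolution, 2
    )
    return TPSDeformation(
        reference=reference,
        target=target,
        weights=weights,
        affine=affine,
        bending_energy=bending,
        grid=grid,
    )
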