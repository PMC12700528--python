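"""Structural connectomes: loading, validation, normalization, and synthesis.

The network substrate of every whole-brain model here is a square matrix of
non-negative inter-regional coupling weights (typically streamline counts in
empirical data), optionally accompanied by an inter-regional distance matrix
used to derive conduction delays. Weights are normalized by their global
maximum before simulation so that the global coupling parameter G keeps a
comparable scale across connectomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np

from .errors import (
    DegenerateInputError,
    PreconditionError,
    ShapeError,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "StructuralConnectome",
    "load_connectome",
    "save_connectome",
    "normalize_connectome",
    "delay_matrix",
    "generate_synthetic_connectome",
    "generate_regional_maps",
]


@dataclass(frozen=True)
class StructuralConnectome:
    """Structural connectivity weights plus optional distances and labels.

    Parameters
    ----------
    weights : (N, N) ndarray
        Non-negative coupling weights, zero diagonal. Dimensionless.
    distances : (N, N) ndarray, optional
        Symmetric inter-regional distances in millimetres, zero diagonal.
    labels : list of str
        Region identifiers, length N.
    normalized : bool
        True once the weights have been divided by their global maximum.
    """

    weights: np.ndarray
    distances: np.ndarray | None = None
    labels: list[str] = field(default_factory=list)
    normalized: bool = False

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ShapeError(f"weights must be square, got shape {w.shape}")
        if not np.all(np.isfinite(w)):
            raise ValidationError("weights contain NaN or Inf entries")
        if np.any(w < 0):
            raise ValidationError("weights contain negative entries")
        if np.any(np.diag(w) != 0):
            logger.warning("nonzero diagonal in weights; forcing self-connections to 0")
            w = w.copy()
            np.fill_diagonal(w, 0.0)
        object.__setattr__(self, "weights", w)

        if self.distances is not None:
            d = np.asarray(self.distances, dtype=float)
            if d.shape != w.shape:
                raise ShapeError(
                    f"distances shape {d.shape} does not match weights {w.shape}"
                )
            if not np.all(np.isfinite(d)):
                raise ValidationError("distances contain NaN or Inf entries")
            if np.any(d < 0):
                raise ValidationError("distances contain negative entries")
            if not np.allclose(d, d.T):
                raise ValidationError("distances must be symmetric")
            if np.any(np.diag(d) != 0):
                raise ValidationError("distances must have a zero diagonal")
            object.__setattr__(self, "distances", d)

        if not self.labels:
            object.__setattr__(
                self, "labels", [f"R{i:03d}" for i in range(w.shape[0])]
            )
        elif len(self.labels) != w.shape[0]:
            raise ShapeError(
                f"{len(self.labels)} labels for {w.shape[0]} regions"
            )
        if self.normalized and w.size and w.max() not in (0.0, 1.0):
            # an edgeless (all-zero) graph is trivially normalized
            raise ValidationError("normalized flag set but max(weights) != 1")

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


def _load_delimited(path: Path) -> np.ndarray:
    try:
        return np.loadtxt(path)
    except ValueError:
        return np.loadtxt(path, delimiter=",")


def load_connectome(path: str | Path, format: str | None = None) -> StructuralConnectome:
    """Load a connectome from delimited text, NPZ, or HDF5.

    ``format`` is one of ``{"delimited", "npz", "hdf5"}``; when None it is
    inferred from the file extension. Text files hold the weight matrix only;
    NPZ uses keys ``weights``/``distances``; HDF5 uses datasets
    ``/connectome/weights``, ``/connectome/distances``, ``/connectome/labels``.
    The result always has ``normalized=False``.
    """
    path = Path(path)
    if format is None:
        ext = path.suffix.lower()
        format = {"npz": "npz", "h5": "hdf5", "hdf5": "hdf5"}.get(ext.lstrip("."), "delimited")
    if format == "delimited":
        return StructuralConnectome(weights=np.atleast_2d(_load_delimited(path)))
    if format == "npz":
        with np.load(path) as f:
            dist = f["distances"] if "distances" in f else None
            labels = [str(x) for x in f["labels"]] if "labels" in f else []
            return StructuralConnectome(f["weights"], dist, labels)
    if format == "hdf5":
        with h5py.File(path, "r") as f:
            g = f["connectome"]
            dist = g["distances"][...] if "distances" in g else None
            labels = [s.decode() for s in g["labels"][...]] if "labels" in g else []
            return StructuralConnectome(g["weights"][...], dist, labels)
    raise ValueError(f"unknown format {format!r}")


def save_connectome(sc: StructuralConnectome, path: str | Path, format: str | None = None) -> Path:
    """Write a connectome in any of the supported formats (round-trip safe)."""
    path = Path(path)
    if format is None:
        ext = path.suffix.lower().lstrip(".")
        format = {"npz": "npz", "h5": "hdf5", "hdf5": "hdf5"}.get(ext, "delimited")
    if format == "delimited":
        np.savetxt(path, sc.weights)
    elif format == "npz":
        arrays = {"weights": sc.weights, "labels": np.array(sc.labels)}
        if sc.distances is not None:
            arrays["distances"] = sc.distances
        np.savez(path, **arrays)
    elif format == "hdf5":
        with h5py.File(path, "w") as f:
            g = f.create_group("connectome")
            g.create_dataset("weights", data=sc.weights)
            if sc.distances is not None:
                g.create_dataset("distances", data=sc.distances)
            g.create_dataset(
                "labels", data=np.array([s.encode() for s in sc.labels])
            )
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def normalize_connectome(sc: StructuralConnectome) -> StructuralConnectome:
    """Divide weights by their global maximum (idempotent).

    Max-normalization preserves the relative weight structure, so the global
    coupling parameters of the neural-mass models keep their usual scales.
    """
    if sc.normalized:
        return sc
    m = sc.weights.max() if sc.weights.size else 0.0
    if m <= 0:
        raise DegenerateInputError("cannot normalize an all-zero weight matrix")
    return replace(sc, weights=sc.weights / m, normalized=True)


def delay_matrix(sc: StructuralConnectome, velocity: float) -> np.ndarray:
    """Inter-regional conduction delays in seconds: T_jk = d_jk / v.

    Distances are stored in mm and ``velocity`` is in m/s, so the element-wise
    conversion is ``d[mm] * 1e-3 / v[m/s]`` seconds. Diagonal is zero.
    """
    if sc.distances is None:
        raise PreconditionError("connectome has no distance matrix")
    if velocity <= 0:
        raise PreconditionError("conduction velocity must be positive")
    return sc.distances * 1e-3 / velocity


def generate_synthetic_connectome(
    n: int,
    density: float = 1.0,
    seed: int = 0,
    *,
    log_mu: float = 0.0,
    log_sigma: float = 1.0,
    box_mm: float = 150.0,
    min_separation_mm: float = 10.0,
) -> StructuralConnectome:
    """Synthesize a connectome with empirically plausible structure.

    Weights are symmetric with log-normal magnitudes (heavy-tailed, like
    fiber-count matrices), zero diagonal, and the requested undirected edge
    density. Distances are Euclidean distances between random 3-D region
    centroids drawn uniformly in a cube of side ``box_mm``, with a minimum
    pairwise separation so that conduction delays stay resolvable at typical
    integration steps. Deterministic given ``seed``.
    """
    if n < 2:
        raise PreconditionError("need at least 2 regions")
    if not 0 < density <= 1:
        raise PreconditionError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)

    iu = np.triu_indices(n, k=1)
    n_pairs = len(iu[0])
    n_edges = max(1, int(round(density * n_pairs)))
    chosen = rng.choice(n_pairs, size=n_edges, replace=False)
    vals = rng.lognormal(mean=log_mu, sigma=log_sigma, size=n_edges)
    w = np.zeros((n, n))
    w[iu[0][chosen], iu[1][chosen]] = vals
    w = w + w.T

    # rejection-sample centroids until all pairs are >= min_separation apart
    for _ in range(200):
        cent = rng.uniform(0.0, box_mm, size=(n, 3))
        diff = cent[:, None, :] - cent[None, :, :]
        dist = np.sqrt((diff**2).sum(-1))
        np.fill_diagonal(dist, np.inf)
        if dist.min() >= min_separation_mm:
            break
    else:
        raise PreconditionError(
            f"could not place {n} centroids with {min_separation_mm} mm separation"
        )
    np.fill_diagonal(dist, 0.0)

    return StructuralConnectome(weights=w, distances=dist)


def generate_regional_maps(n: int, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic smooth regional maps in [0, 1] (myelin, FC gradient).

    Each map is a spatially smooth scalar field: region centroids are drawn in
    a cube and each map is the min-max-normalized projection of the centroids
    onto a random direction plus small roughness. Emulates the large-scale
    spatial gradients of T1w/T2w myelin maps and the principal FC gradient.
    """
    rng = np.random.default_rng(seed)
    cent = rng.uniform(0.0, 150.0, size=(n, 3))
    maps = []
    for _ in range(2):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        proj = cent @ direction + rng.normal(scale=5.0, size=n)
        lo, hi = proj.min(), proj.max()
        maps.append((proj - lo) / (hi - lo) if hi > lo else np.full(n, 0.5))
    return maps[0], maps[1]
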