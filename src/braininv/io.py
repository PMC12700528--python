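"""Dataset storage: HDF5 (primary) and NPZ (secondary) dialects.

Every stored group carries a SHA-256 checksum of its array bytes; a mismatch
on load (truncated or corrupted file) raises CorruptionError. Arrays
round-trip exactly in native float64 precision, and the two dialects load to
identical arrays.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np

from .errors import CorruptionError
from .inference import PosteriorSamples, PriorSpec, TrainingDataset
from .models.base import SimulationResult

__all__ = [
    "save_training_dataset",
    "load_training_dataset",
    "save_simulation_result",
    "load_simulation_result",
    "save_posterior_samples",
    "load_posterior_samples",
]


def _digest(*arrays: np.ndarray) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()


def _check(expected: str, *arrays: np.ndarray, what: str) -> None:
    if _digest(*arrays) != expected:
        raise CorruptionError(f"checksum mismatch in {what}: file corrupted or truncated")


# ---------------------------------------------------------------------------
# TrainingDataset
# ---------------------------------------------------------------------------

def save_training_dataset(ds: TrainingDataset, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(
            path,
            theta=ds.theta,
            features=ds.features,
            seeds=ds.seeds,
            prior_lower=ds.prior.lower,
            prior_upper=ds.prior.upper,
            prior_names=np.array(ds.prior.names),
            feature_names=np.array(ds.feature_names),
            recipe_id=np.array(ds.recipe_id),
            checksum=np.array(_digest(ds.theta, ds.features)),
        )
        return path
    with h5py.File(path, "w") as f:
        f.create_dataset("theta", data=ds.theta)
        g = f.create_group("features")
        g.create_dataset("values", data=ds.features)
        g.create_dataset("names", data=np.array([s.encode() for s in ds.feature_names]))
        m = f.create_group("meta")
        m.create_dataset("seeds", data=ds.seeds)
        m.attrs["recipe_id"] = ds.recipe_id
        m.attrs["prior"] = json.dumps({
            "names": list(ds.prior.names),
            "lower": ds.prior.lower.tolist(),
            "upper": ds.prior.upper.tolist(),
        })
        f.attrs["checksum"] = _digest(ds.theta, ds.features)
    return path


def load_training_dataset(path: str | Path, chunk_size: int = 4096) -> TrainingDataset:
    """Load a dataset; features are read in fixed-size chunks.

    The chunked read gives results independent of ``chunk_size`` while
    keeping peak memory bounded for large feature matrices.
    """
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as f:
            theta, feats = f["theta"], f["features"]
            _check(str(f["checksum"]), theta, feats, what=str(path))
            prior = PriorSpec(tuple(str(n) for n in f["prior_names"]),
                              f["prior_lower"], f["prior_upper"])
            return TrainingDataset(
                theta=theta, features=feats, prior=prior,
                recipe_id=str(f["recipe_id"]), seeds=f["seeds"],
                feature_names=[str(n) for n in f["feature_names"]],
            )
    with h5py.File(path, "r") as f:
        theta = f["theta"][...]
        dset = f["features/values"]
        parts = [dset[i:i + chunk_size] for i in range(0, dset.shape[0], chunk_size)]
        feats = np.concatenate(parts) if parts else np.zeros((0, 0))
        _check(f.attrs["checksum"], theta, feats, what=str(path))
        meta = json.loads(f["meta"].attrs["prior"])
        prior = PriorSpec(tuple(meta["names"]), meta["lower"], meta["upper"])
        return TrainingDataset(
            theta=theta, features=feats, prior=prior,
            recipe_id=str(f["meta"].attrs["recipe_id"]),
            seeds=f["meta/seeds"][...],
            feature_names=[s.decode() for s in f["features/names"][...]],
        )


# ---------------------------------------------------------------------------
# SimulationResult
# ---------------------------------------------------------------------------

def save_simulation_result(result: SimulationResult, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(
            path,
            states=result.states, time=result.time,
            dt=result.dt, model_id=np.array(result.model_id),
            seed=result.seed, params_digest=np.array(result.params_digest),
            time_unit=np.array(result.time_unit),
            checksum=np.array(_digest(result.states, result.time)),
            **{f"extra_{k}": v for k, v in result.extras.items()},
        )
        return path
    with h5py.File(path, "w") as f:
        g = f.create_group("sim")
        g.create_dataset("states", data=result.states)
        g.create_dataset("time", data=result.time)
        for k, v in result.extras.items():
            g.create_dataset(f"extra_{k}", data=v)
        g.attrs.update({
            "dt": result.dt, "model_id": result.model_id, "seed": result.seed,
            "params_digest": result.params_digest, "time_unit": result.time_unit,
            "checksum": _digest(result.states, result.time),
        })
    return path


def load_simulation_result(path: str | Path) -> SimulationResult:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as f:
            states, time = f["states"], f["time"]
            _check(str(f["checksum"]), states, time, what=str(path))
            extras = {k[6:]: f[k] for k in f.files if k.startswith("extra_")}
            return SimulationResult(
                time=time, states=states, dt=float(f["dt"]),
                model_id=str(f["model_id"]), seed=int(f["seed"]),
                params_digest=str(f["params_digest"]),
                time_unit=str(f["time_unit"]), extras=extras,
            )
    with h5py.File(path, "r") as f:
        g = f["sim"]
        states, time = g["states"][...], g["time"][...]
        _check(g.attrs["checksum"], states, time, what=str(path))
        extras = {k[6:]: g[k][...] for k in g if k.startswith("extra_")}
        return SimulationResult(
            time=time, states=states, dt=float(g.attrs["dt"]),
            model_id=str(g.attrs["model_id"]), seed=int(g.attrs["seed"]),
            params_digest=str(g.attrs["params_digest"]),
            time_unit=str(g.attrs["time_unit"]), extras=extras,
        )


# ---------------------------------------------------------------------------
# PosteriorSamples
# ---------------------------------------------------------------------------

def save_posterior_samples(ps: PosteriorSamples, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=ps.samples)
        f.create_dataset("x_obs", data=ps.x_obs)
        f.attrs["acceptance_fraction"] = ps.acceptance_fraction
        f.attrs["names"] = json.dumps(list(ps.names))
        f.attrs["checksum"] = _digest(ps.samples, ps.x_obs)
    return path


def load_posterior_samples(path: str | Path) -> PosteriorSamples:
    with h5py.File(path, "r") as f:
        samples, x_obs = f["samples"][...], f["x_obs"][...]
        _check(f.attrs["checksum"], samples, x_obs, what=str(path))
        return PosteriorSamples(
            samples=samples, x_obs=x_obs,
            acceptance_fraction=float(f.attrs["acceptance_fraction"]),
            names=tuple(json.loads(f.attrs["names"])),
        )
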