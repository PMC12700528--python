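"""Low-dimensional data features for simulation-based inference.

Converts regional time series (neural or BOLD) into fixed-length summary
vectors: spectral summaries of the PSD, statistical moments, functional
connectivity (FC) and its temporal dynamics (FCD), and seizure-envelope
features (total power and onset time). A FeatureRecipe fixes the extractor
set, their parameters, and the concatenation order, so every simulation in a
training set maps to the same feature space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

from .errors import DegenerateInputError, PreconditionError, RecipeError, ValidationError

__all__ = [
    "FeatureVector",
    "FCDMatrix",
    "fc_matrix",
    "fcd_matrix",
    "psd_summary",
    "stat_moments",
    "seizure_features",
    "fcd_fc_summary",
    "FeatureRecipe",
    "build_feature_recipe",
    "apply_recipe",
]


@dataclass
class FeatureVector:
    """Fixed-length feature vector with matching names and a recipe id."""

    values: np.ndarray
    names: list[str]
    recipe_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.names) != self.values.size:
            raise ValidationError(
                f"{len(self.names)} names for {self.values.size} values"
            )
        if self.values.size and not np.all(np.isfinite(self.values)):
            bad = [self.names[i] for i in np.flatnonzero(~np.isfinite(self.values))[:5]]
            raise ValidationError(f"non-finite feature values: {bad}")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class FCDMatrix:
    """Correlation between windowed FC patterns; W x W, symmetric, unit diag."""

    matrix: np.ndarray
    window: int
    stride: int


def fc_matrix(states: np.ndarray) -> np.ndarray:
    """Pearson functional connectivity of an (N, T) array."""
    states = np.asarray(states, dtype=float)
    if states.ndim != 2 or states.shape[1] < 3:
        raise PreconditionError("need an (N, T) array with T >= 3")
    sd = states.std(axis=1)
    if np.any(sd == 0):
        k = int(np.flatnonzero(sd == 0)[0])
        raise DegenerateInputError(f"region {k} has constant signal")
    fc = np.corrcoef(states)
    np.fill_diagonal(fc, 1.0)
    return np.clip(fc, -1.0, 1.0)


def fcd_matrix(states: np.ndarray, window: int, stride: int) -> FCDMatrix:
    """Functional connectivity dynamics of an (N, T) array.

    FC is computed in sliding windows; entry (i, j) of the FCD is the Pearson
    correlation between the vectorized upper triangles of window i's and
    window j's FC.
    """
    states = np.asarray(states, dtype=float)
    if window < 10:
        raise PreconditionError("window must be at least 10 samples")
    T = states.shape[1]
    if window == T:
        return FCDMatrix(np.ones((1, 1)), window, stride)
    if T < window + stride:
        raise PreconditionError(
            f"series length {T} shorter than window + stride = {window + stride}"
        )
    iu = np.triu_indices(states.shape[0], k=1)
    vecs = []
    for start in range(0, T - window + 1, stride):
        fc = fc_matrix(states[:, start:start + window])
        vecs.append(fc[iu])
    V = np.asarray(vecs)
    fcd = np.corrcoef(V)
    fcd = np.atleast_2d(fcd)
    np.fill_diagonal(fcd, 1.0)
    return FCDMatrix(np.clip(fcd, -1.0, 1.0), window, stride)


def _welch(states: np.ndarray, fs: float, segment_seconds: float = 2.0):
    # segment length: min(T, segment_seconds of samples), 50% overlap, Hann taper
    T = states.shape[1]
    nperseg = int(min(T, max(8, round(segment_seconds * fs))))
    return sps.welch(states, fs=fs, nperseg=nperseg, axis=1)


def psd_summary(
    states: np.ndarray,
    fs: float,
    bands: list[tuple[float, float]] | None = None,
    log_power: bool = False,
    segment_seconds: float = 2.0,
    pooled: bool = False,
) -> FeatureVector:
    """Spectral summaries from a segment-averaged tapered PSD.

    For each region: peak frequency, peak power, total power (area under the
    PSD), spectral centroid, spectral spread, then one band power per
    requested (lo, hi) band. With ``log_power=True`` the power-valued
    summaries are reported on a log10 (decibel-like) scale, which keeps
    order-of-magnitude power variation usable after feature standardization.

    With ``pooled=True`` the same summaries are instead computed on the
    across-region average PSD, followed by the across-region mean and SD of
    each per-region summary. Pooling averages out region-specific spectral
    resonances, which is the robust choice when the per-region fine structure
    is much more variable than the global spectral shape.
    """
    states = np.asarray(states, dtype=float)
    if np.all(states == 0):
        raise DegenerateInputError("all-zero signal has no spectrum")
    bands = bands or []
    f, pxx = _welch(states, fs, segment_seconds)
    if pooled:
        return _psd_pooled(f, pxx, bands, log_power)
    df = f[1] - f[0] if len(f) > 1 else 1.0
    tiny = 1e-300

    def _pw(p):
        return float(np.log10(p + tiny)) if log_power else float(p)

    vals, names = [], []
    for i in range(states.shape[0]):
        p = pxx[i]
        total = np.trapezoid(p, f)
        peak_idx = int(np.argmax(p))
        centroid = float(np.sum(f * p) / np.sum(p)) if np.sum(p) > 0 else 0.0
        spread = (float(np.sqrt(np.sum((f - centroid) ** 2 * p) / np.sum(p)))
                  if np.sum(p) > 0 else 0.0)
        row = [f[peak_idx], _pw(p[peak_idx]), _pw(total), centroid, spread]
        base = [f"psd_peak_freq_r{i}", f"psd_peak_power_r{i}", f"psd_total_power_r{i}",
                f"psd_centroid_r{i}", f"psd_spread_r{i}"]
        for lo, hi in bands:
            sel = (f >= lo) & (f <= hi)
            bp = (float(np.trapezoid(p[sel], f[sel])) if sel.sum() > 1
                  else float(p[sel].sum() * df))
            row.append(_pw(bp))
            base.append(f"psd_band_{lo:g}_{hi:g}_r{i}")
        vals.extend(row)
        names.extend(base)
    return FeatureVector(np.asarray(vals), names, recipe_id="psd_summary")


def _psd_row_summaries(f, p, bands, log_power):
    tiny = 1e-300

    def _pw(v):
        return float(np.log10(v + tiny)) if log_power else float(v)

    df = f[1] - f[0] if len(f) > 1 else 1.0
    total = np.trapezoid(p, f)
    centroid = float(np.sum(f * p) / np.sum(p)) if np.sum(p) > 0 else 0.0
    spread = (float(np.sqrt(np.sum((f - centroid) ** 2 * p) / np.sum(p)))
              if np.sum(p) > 0 else 0.0)
    row = [float(f[int(np.argmax(p))]), _pw(p.max()), _pw(total), centroid, spread]
    for lo, hi in bands:
        sel = (f >= lo) & (f <= hi)
        bp = (float(np.trapezoid(p[sel], f[sel])) if sel.sum() > 1
              else float(p[sel].sum() * df))
        row.append(_pw(bp))
    return row


def _psd_pooled(f, pxx, bands, log_power) -> FeatureVector:
    base = ["psd_peak_freq", "psd_peak_power", "psd_total_power",
            "psd_centroid", "psd_spread"]
    base += [f"psd_band_{lo:g}_{hi:g}" for lo, hi in bands]
    pooled_row = _psd_row_summaries(f, pxx.mean(axis=0), bands, log_power)
    per_region = np.array([_psd_row_summaries(f, pxx[i], bands, log_power)
                           for i in range(pxx.shape[0])])
    vals = (list(pooled_row) + per_region.mean(axis=0).tolist()
            + per_region.std(axis=0).tolist())
    names = ([f"{n}_pooled" for n in base] + [f"{n}_rmean" for n in base]
             + [f"{n}_rsd" for n in base])
    return FeatureVector(np.asarray(vals), names, recipe_id="psd_summary")


def stat_moments(states: np.ndarray) -> FeatureVector:
    """Per-region mean, variance, skewness, excess kurtosis.

    Constant rows get variance 0 and skewness/kurtosis reported as 0 (the
    degenerate convention) rather than NaN.
    """
    states = np.asarray(states, dtype=float)
    if states.shape[1] < 4:
        raise PreconditionError("need T >= 4 samples")
    mean = states.mean(axis=1)
    var = states.var(axis=1)
    with np.errstate(all="ignore"):
        skew = spstats.skew(states, axis=1)
        kurt = spstats.kurtosis(states, axis=1)
    const = var == 0
    skew = np.where(const | ~np.isfinite(skew), 0.0, skew)
    kurt = np.where(const | ~np.isfinite(kurt), 0.0, kurt)
    vals = np.column_stack([mean, var, skew, kurt]).ravel()
    names = [f"{m}_r{i}" for i in range(states.shape[0])
             for m in ("mean", "var", "skew", "kurt")]
    return FeatureVector(vals, names, recipe_id="stat_moments")


def _envelope(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    T = x.size
    hp_win = max(3, int(round(0.05 * T)))
    kernel = np.ones(hp_win) / hp_win
    trend = np.convolve(x, kernel, mode="same")
    raw = np.abs(x - trend)
    sm_win = max(3, int(round(0.01 * T)))
    env = np.convolve(raw, np.ones(sm_win) / sm_win, mode="same")
    return env, raw, hp_win


def seizure_features(
    states: np.ndarray,
    dt: float,
    k: float = 3.0,
    baseline_fraction: float = 0.1,
    log_power: bool = False,
) -> FeatureVector:
    """Per-region seizure total power and onset time.

    The envelope is the moving-average-smoothed absolute value of the
    high-pass-detrended signal; edge samples distorted by the moving-average
    boundary are excluded from onset detection. Total power is the area under
    the squared envelope (optionally log10-compressed, which keeps weakly
    recruited regions distinguishable from baseline next to strong seizures);
    onset is the first time the smoothed envelope exceeds baseline mean + k
    baseline SD (the SD of the unsmoothed envelope, which is robust to noise
    crossings), with the baseline taken from the first ``baseline_fraction``
    of samples and the total duration as the sentinel for regions that never
    cross threshold.
    """
    states = np.asarray(states, dtype=float)
    N, T = states.shape
    duration = T * dt
    vals, names = [], []
    n_base = max(4, int(round(baseline_fraction * T)))
    for i in range(N):
        env, raw, edge = _envelope(states[i])
        power = float(np.trapezoid(env**2, dx=dt))
        if log_power:
            power = float(np.log10(power + 1e-12))
        core = env[: T - edge]  # trailing boundary-artifact region excluded
        thr = core[:n_base].mean() + k * raw[:n_base].std()
        above = np.flatnonzero(core > thr)
        onset = float(above[0] * dt) if above.size else duration
        vals.extend([power, onset])
        names.extend([f"sz_power_r{i}", f"sz_onset_r{i}"])
    return FeatureVector(np.asarray(vals), names, recipe_id="seizure_features")


def _offdiag(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def _moments_of(v: np.ndarray) -> list[float]:
    if v.size == 0:
        return [0.0, 0.0, 0.0, 0.0]
    if v.std() == 0:
        return [float(v.mean()), 0.0, 0.0, 0.0]
    return [float(v.mean()), float(v.var()),
            float(spstats.skew(v)), float(spstats.kurtosis(v))]


def fcd_fc_summary(
    fc: np.ndarray,
    fcd: FCDMatrix,
    n_components: int = 0,
    projector: "PCAProjector | None" = None,
) -> FeatureVector:
    """Moments of off-diagonal FC and FCD entries, plus optional PC scores.

    When ``n_components`` > 0 a fitted ``projector`` (trained once on the
    training set and frozen in the recipe) maps the vectorized FC upper
    triangle onto its leading principal components.
    """
    vals = _moments_of(_offdiag(fc)) + _moments_of(_offdiag(fcd.matrix))
    names = [f"fc_{m}" for m in ("mean", "var", "skew", "kurt")]
    names += [f"fcd_{m}" for m in ("mean", "var", "skew", "kurt")]
    if n_components > 0:
        if projector is None or not projector.fitted:
            raise RecipeError("PC projection requested but projector not fitted")
        scores = projector.transform(_offdiag(fc))
        vals = vals + list(scores[:n_components])
        names += [f"fc_pc{j}" for j in range(n_components)]
    return FeatureVector(np.asarray(vals), names, recipe_id="fcd_fc_summary")


class PCAProjector:
    """PCA loadings fit once on training FC vectors, then frozen."""

    def __init__(self, n_components: int):
        self.n_components = n_components
        self.fitted = False
        self._pca = None

    def fit(self, vectors: np.ndarray) -> "PCAProjector":
        from sklearn.decomposition import PCA

        self._pca = PCA(n_components=self.n_components, random_state=0)
        self._pca.fit(np.asarray(vectors))
        self.fitted = True
        return self

    def transform(self, vec: np.ndarray) -> np.ndarray:
        return self._pca.transform(np.atleast_2d(vec))[0]

    @property
    def components(self) -> np.ndarray:
        return self._pca.components_


_EXTRACTORS = ("psd_summary", "stat_moments", "seizure_features", "fcd_fc_summary")


@dataclass
class FeatureRecipe:
    """Ordered, parameterized set of extractors defining one feature space.

    ``steps`` maps extractor name -> kwargs; application order is the fixed
    order of ``_EXTRACTORS``. Sampling frequency for spectral features is
    derived from the result being featurized unless given explicitly.
    """

    steps: dict = field(default_factory=dict)
    recipe_id: str = "recipe"
    projector: PCAProjector | None = None

    def __post_init__(self):
        unknown = set(self.steps) - set(_EXTRACTORS)
        if unknown:
            raise RecipeError(f"unknown extractors: {sorted(unknown)}")

    def apply(self, result) -> FeatureVector:
        states = result.states if hasattr(result, "states") else result.bold
        if hasattr(result, "states"):
            unit_scale = {"s": 1.0, "ms": 1e-3, "tau": 1.0}.get(result.time_unit, 1.0)
            fs = 1.0 / (result.dt * unit_scale)
            dt = result.dt
        else:
            fs = 1.0 / result.TR
            dt = result.TR
        parts: list[FeatureVector] = []
        for name in _EXTRACTORS:
            if name not in self.steps:
                continue
            kw = dict(self.steps[name])
            if name == "psd_summary":
                kw.setdefault("fs", fs)
                parts.append(psd_summary(states, **kw))
            elif name == "stat_moments":
                parts.append(stat_moments(states, **kw))
            elif name == "seizure_features":
                kw.setdefault("dt", dt)
                parts.append(seizure_features(states, **kw))
            elif name == "fcd_fc_summary":
                window = kw.pop("window")
                stride = kw.pop("stride")
                fc = fc_matrix(states)
                fcd = fcd_matrix(states, window=window, stride=stride)
                kw.setdefault("projector", self.projector)
                parts.append(fcd_fc_summary(fc, fcd, **kw))
        if not parts:
            return FeatureVector(np.zeros(0), [], recipe_id=self.recipe_id)
        values = np.concatenate([p.values for p in parts])
        names = sum((p.names for p in parts), [])
        return FeatureVector(values, names, recipe_id=self.recipe_id)


def build_feature_recipe(config: dict, recipe_id: str = "recipe") -> FeatureRecipe:
    """Build a FeatureRecipe from a plain dict of extractor kwargs."""
    return FeatureRecipe(steps=dict(config), recipe_id=recipe_id)


def apply_recipe(recipe: FeatureRecipe, result) -> FeatureVector:
    """Apply a recipe to a SimulationResult or BoldResult."""
    return recipe.apply(result)
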