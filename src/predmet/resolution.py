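"""Windowed multivariate curve resolution of raw GC-TOFMS cubes.

The raw data for each sample is a retention-time x m/z matrix; stacking the
samples gives a three-way cube.  Resolution proceeds window-wise: the cube is
baseline-corrected, the time axis is cut at minima of the mean total ion
current, and each window is factorized by multivariate curve resolution with
alternating least squares (MCR-ALS) under non-negativity on both factors and
unimodality on the elution profiles, initialized from purest-variable
selection.  Each resolved component yields a pure elution profile, a pure
fragment spectrum (unit sum) and a per-sample peak area — the relative
concentration that populates the feature table.

Peak areas are subsequently normalized by the per-sample geometric mean of
the internal-standard areas, and putative identities are assigned by cosine
matching against a spectral library gated on retention index.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter1d, minimum_filter1d, uniform_filter1d

from .simulate import RawDataCube
from .tables import FeatureTable

__all__ = [
    "Window",
    "ResolvedFeature",
    "SpectralLibrary",
    "baseline_correct",
    "segment_windows",
    "resolve_window",
    "resolve_cube",
    "assign_retention_index",
    "normalize_by_is",
    "match_library",
    "read_library",
    "write_library",
    "make_toy_library",
    "spectral_cosine",
]


@dataclasses.dataclass
class Window:
    """A half-open time slice ``[start, end)`` of the cube, in axis indices."""

    index: int
    start: int
    end: int
    tensor: np.ndarray  # sample x time x mz, restricted to the slice
    time: np.ndarray  # seconds, len == end - start
    mz: np.ndarray


@dataclasses.dataclass
class ResolvedFeature:
    """One resolved chromatographic component.

    ``elution_profile`` is the common (across-sample) profile with unit
    maximum; ``spectrum`` sums to one; ``areas`` maps sample id to the
    relative concentration in arbitrary detector units.
    """

    window: int
    elution_profile: np.ndarray
    spectrum: np.ndarray
    areas: pd.Series
    apex_time: float
    retention_index: float | None = None
    ri_extrapolated: bool = False
    putative_id: tuple[str, float] | None = None
    converged: bool = True
    feature_id: str = ""


@dataclasses.dataclass
class SpectralLibrary:
    """Reference spectra with retention indices; names are unique."""

    mz: np.ndarray
    entries: list  # [(name, spectrum unit-sum, retention_index), ...]

    def __post_init__(self) -> None:
        names = [e[0] for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("library names must be unique")


def baseline_correct(cube: RawDataCube, window_length: int = 21) -> RawDataCube:
    """Subtract a rolling-minimum-then-smoothed baseline per sample and channel.

    ``window_length`` (odd, >= 3, in scans) sets the rolling-minimum span; it
    should comfortably exceed the peak width at base so peaks are not eaten.
    Output is clipped at zero; the total ion current can only decrease.
    """
    if window_length < 3 or window_length % 2 == 0:
        raise ValueError("window_length must be odd and >= 3")
    if window_length > len(cube.time_axis):
        raise ValueError("window_length exceeds the time axis")
    x = cube.intensities
    # morphological opening (rolling min, then rolling max) tracks sloped
    # baselines without the half-window offset of a bare rolling minimum
    base = minimum_filter1d(x, size=window_length, axis=1, mode="nearest")
    base = maximum_filter1d(base, size=window_length, axis=1, mode="nearest")
    base = uniform_filter1d(base, size=window_length, axis=1, mode="nearest")
    corrected = np.clip(x - base, 0.0, None)
    return RawDataCube(
        samples=list(cube.samples),
        time_axis=cube.time_axis.copy(),
        mz_axis=cube.mz_axis.copy(),
        intensities=corrected,
        ri_markers=list(cube.ri_markers),
    )


def _local_minima(y: np.ndarray) -> list[int]:
    """Interior local minima; plateau runs contribute their middle index."""
    mins: list[int] = []
    n = len(y)
    i = 1
    while i < n - 1:
        if y[i] < y[i - 1]:
            j = i
            while j + 1 < n and y[j + 1] == y[i]:
                j += 1
            if j + 1 < n and y[j + 1] > y[i]:
                mins.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return mins


def segment_windows(
    cube: RawDataCube, n_windows: int, min_width: int = 5
) -> list[Window]:
    """Cut the time axis into ``n_windows`` half-open windows.

    The ``n_windows - 1`` interior boundaries are placed at the lowest local
    minima of the mean total-ion-current curve, greedily, subject to every
    window keeping at least ``min_width`` time points.  Windows tile the axis
    with 0-based half-open ``[start, end)`` indexing.
    """
    nt = len(cube.time_axis)
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    if n_windows * min_width > nt:
        raise ValueError("n_windows incompatible with min_width and the time axis")
    boundaries: list[int] = []
    if n_windows > 1:
        # smoothing at the minimum-width scale collapses noise dips so each
        # inter-peak valley contributes one candidate minimum
        smooth = max(5, min_width) | 1
        tic = uniform_filter1d(cube.tic().mean(axis=0), size=smooth, mode="nearest")
        candidates = _local_minima(tic)
        candidates.sort(key=lambda i: (tic[i], i))
        for i in candidates:
            if len(boundaries) == n_windows - 1:
                break
            ok = i >= min_width and i <= nt - min_width
            for b in boundaries:
                if abs(i - b) < min_width:
                    ok = False
                    break
            if ok:
                boundaries.append(i)
        if len(boundaries) < n_windows - 1:
            raise ValueError(
                "could not place enough window boundaries at TIC minima; "
                "reduce n_windows or min_width"
            )
        boundaries.sort()
    edges = [0] + boundaries + [nt]
    windows = []
    for w, (a, b) in enumerate(zip(edges[:-1], edges[1:])):
        windows.append(
            Window(
                index=w,
                start=a,
                end=b,
                tensor=cube.intensities[:, a:b, :],
                time=cube.time_axis[a:b],
                mz=cube.mz_axis,
            )
        )
    return windows


def _purest_variables(D: np.ndarray, k: int, noise_frac: float = 0.05) -> list[int]:
    """SIMPLISMA-style purest m/z channels of the unfolded window matrix."""
    mu = D.mean(axis=0)
    sd = D.std(axis=0)
    alpha = noise_frac * mu.max() if mu.max() > 0 else 1.0
    purity = sd / (mu + alpha)
    norm = np.sqrt(mu**2 + (sd + alpha) ** 2)
    cols = D / np.where(norm > 0, norm, 1.0)
    chosen: list[int] = []
    for _ in range(k):
        best, best_w = None, -np.inf
        for j in range(D.shape[1]):
            if j in chosen:
                continue
            block = cols[:, chosen + [j]]
            g = block.T @ block
            w = purity[j] * max(np.linalg.det(g), 0.0)
            if w > best_w:
                best, best_w = j, w
        chosen.append(best)
    return chosen


def _enforce_unimodal(c: np.ndarray) -> np.ndarray:
    """Clip a profile to be non-decreasing up to its apex, non-increasing after."""
    out = c.copy()
    a = int(np.argmax(out))
    for i in range(a - 1, -1, -1):
        if out[i] > out[i + 1]:
            out[i] = out[i + 1]
    for i in range(a + 1, len(out)):
        if out[i] > out[i - 1]:
            out[i] = out[i - 1]
    return out


def _select_rank(D: np.ndarray, max_components: int, energy: float = 0.99) -> int:
    s = np.linalg.svd(D, compute_uv=False)
    e = s**2
    total = e.sum()
    if total <= 0:
        return 0
    frac = np.cumsum(e) / total
    k = int(np.searchsorted(frac, energy) + 1)
    return min(k, max_components)


def resolve_window(
    window: Window,
    max_components: int = 5,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> list[ResolvedFeature]:
    """Factorize one window into pure elution profiles and spectra.

    The sample-stacked window matrix (samples*time x m/z) is decomposed as
    ``D = C @ S`` by alternating least squares with non-negativity on both
    factors and per-sample unimodality on the elution profiles.  The rank is
    the smallest number of singular values explaining >= 99% of the variance,
    capped at ``max_components``; the concentration factor is initialized
    from the purest m/z channels.  Per-sample areas are the least-squares
    scale of each sample's profile onto the common profile times the
    trapezoidal integral of that common profile.

    Non-convergence within ``max_iter`` flags the returned features
    (``converged=False``) rather than raising.
    """
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    if np.any(window.tensor < 0):
        raise ValueError("window tensor must be non-negative")
    n_samples, nt, n_mz = window.tensor.shape
    D = window.tensor.reshape(n_samples * nt, n_mz)
    k = _select_rank(D, max_components)
    if k == 0:
        return []

    C = D[:, _purest_variables(D, k)].astype(float)
    C = np.clip(C, 0.0, None) + 1e-12
    norm_D = np.linalg.norm(D)
    prev = np.inf
    converged = False
    S = None
    for _ in range(max_iter):
        S, *_ = np.linalg.lstsq(C, D, rcond=None)
        S = np.clip(S, 0.0, None)
        row_sums = S.sum(axis=1)
        row_sums[row_sums <= 0] = 1.0
        S /= row_sums[:, None]
        Ct, *_ = np.linalg.lstsq(S.T, D.T, rcond=None)
        C = np.clip(Ct.T, 0.0, None)
        # unimodality, enforced within each sample's segment
        C3 = C.reshape(n_samples, nt, k)
        for s in range(n_samples):
            for j in range(k):
                C3[s, :, j] = _enforce_unimodal(C3[s, :, j])
        C = C3.reshape(n_samples * nt, k)
        lof = np.linalg.norm(D - C @ S) / max(norm_D, 1e-300)
        if abs(prev - lof) < tol * max(prev, 1e-12):
            converged = True
            break
        prev = lof

    features = []
    C3 = C.reshape(n_samples, nt, k)
    for j in range(k):
        common = C3[:, :, j].mean(axis=0)
        peak = common.max()
        if peak <= 0:
            continue
        unit = common / peak
        denom = float(unit @ unit)
        scales = np.array([float(C3[s, :, j] @ unit) / denom for s in range(n_samples)])
        areas = np.clip(scales, 0.0, None) * np.trapezoid(unit, window.time)
        apex = float(window.time[int(np.argmax(unit))])
        features.append(
            ResolvedFeature(
                window=window.index,
                elution_profile=unit,
                spectrum=S[j],
                areas=pd.Series(areas, index=[str(s) for s in range(n_samples)]),
                apex_time=apex,
                converged=converged,
            )
        )
    # stable ordering: by apex time within the window
    features.sort(key=lambda f: f.apex_time)
    return features


def assign_retention_index(
    feature: ResolvedFeature, ri_markers: list[tuple[float, float]]
) -> float:
    """Linear interpolation of the apex time on the retention-index ladder.

    Apex times outside the marker range are linearly extrapolated from the
    nearest marker pair and flagged (``ri_extrapolated``).
    """
    if len(ri_markers) < 2:
        raise ValueError("need at least two retention-index markers")
    t = np.asarray([m[0] for m in ri_markers], dtype=float)
    r = np.asarray([m[1] for m in ri_markers], dtype=float)
    apex = feature.apex_time
    if apex < t[0] or apex > t[-1]:
        feature.ri_extrapolated = True
        pair = (0, 1) if apex < t[0] else (len(t) - 2, len(t) - 1)
        slope = (r[pair[1]] - r[pair[0]]) / (t[pair[1]] - t[pair[0]])
        ri = r[pair[0]] + slope * (apex - t[pair[0]])
    else:
        feature.ri_extrapolated = False
        ri = float(np.interp(apex, t, r))
    feature.retention_index = float(ri)
    return feature.retention_index


def normalize_by_is(
    features: list[ResolvedFeature],
    is_names: list[str],
    sample_ids: list[str] | None = None,
) -> FeatureTable:
    """Divide each sample's areas by its geometric mean internal-standard area.

    ``is_names`` selects internal-standard features by ``feature_id`` or by
    putative identity; those features are excluded from the output table.
    Samples in which any internal standard has a non-positive area are
    flagged for exclusion (``is_failed`` in ``sample_meta``) — mirroring how
    derivatization failures surface in real runs — but are kept in the table
    for the curation stage to act on.
    """
    if not features:
        raise ValueError("no features to normalize")
    is_set = set(is_names)

    def _is_internal(f: ResolvedFeature) -> bool:
        if f.feature_id and f.feature_id in is_set:
            return True
        return f.putative_id is not None and f.putative_id[0] in is_set

    internal = [f for f in features if _is_internal(f)]
    analytes = [f for f in features if not _is_internal(f)]
    if not internal:
        raise ValueError("no internal-standard features found")
    if sample_ids is None:
        sample_ids = list(features[0].areas.index)

    is_mat = np.vstack([f.areas.reindex(sample_ids).to_numpy(dtype=float) for f in internal])
    failed = np.any(~np.isfinite(is_mat) | (is_mat <= 0), axis=0)
    gm = np.ones(len(sample_ids))
    ok = ~failed
    if ok.any():
        gm[ok] = np.exp(np.log(is_mat[:, ok]).mean(axis=0))

    ids = []
    cols = {}
    meta_rows = []
    for i, f in enumerate(analytes):
        fid = f.feature_id or f"W{f.window}_{i}"
        ids.append(fid)
        cols[fid] = f.areas.reindex(sample_ids).to_numpy(dtype=float) / gm
        meta_rows.append(
            {
                "retention_index": f.retention_index,
                "putative_id": None if f.putative_id is None else f.putative_id[0],
                "match_score": None if f.putative_id is None else f.putative_id[1],
                "window": f.window,
            }
        )
    X = pd.DataFrame(cols, index=sample_ids)
    sample_meta = pd.DataFrame({"is_failed": failed}, index=sample_ids)
    feature_meta = pd.DataFrame(meta_rows, index=ids)
    return FeatureTable(X=X, sample_meta=sample_meta, feature_meta=feature_meta)


def spectral_cosine(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized dot product of two spectra on a shared m/z grid."""
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def match_library(
    feature: ResolvedFeature,
    library: SpectralLibrary,
    min_score: float = 0.8,
    ri_tol: float = 30.0,
) -> tuple[str, float] | None:
    """Best cosine match among library entries within the retention-index gate.

    Returns ``(name, score)`` if the best in-tolerance cosine reaches
    ``min_score``; otherwise ``None`` and the feature stays unidentified
    (unidentified features remain in the analysis).
    """
    if not library.entries:
        raise ValueError("library is empty")
    best = None
    for name, spec, ri in library.entries:
        if feature.retention_index is not None and abs(ri - feature.retention_index) > ri_tol:
            continue
        score = spectral_cosine(feature.spectrum, np.asarray(spec, dtype=float))
        if best is None or score > best[1]:
            best = (name, score)
    if best is not None and best[1] >= min_score:
        feature.putative_id = (best[0], float(best[1]))
        return feature.putative_id
    return None


def _merge_adjacent(features: list[ResolvedFeature], cos_thr: float = 0.98,
                    apex_tol_points: int = 2, dt: float = 1.0) -> list[ResolvedFeature]:
    """Merge split peaks: components in adjacent windows with near-identical
    spectra and apexes within ``apex_tol_points`` scans are summed."""
    merged: list[ResolvedFeature] = []
    for f in features:
        target = None
        for g in merged:
            if abs(g.window - f.window) == 1 and spectral_cosine(
                g.spectrum, f.spectrum
            ) > cos_thr and abs(g.apex_time - f.apex_time) <= apex_tol_points * dt:
                target = g
                break
        if target is None:
            merged.append(f)
        else:
            target.areas = target.areas.add(f.areas, fill_value=0.0)
    return merged


def resolve_cube(
    cube: RawDataCube,
    n_windows: int,
    max_components: int = 5,
    baseline_window: int | None = 21,
    library: SpectralLibrary | None = None,
    is_names: list[str] | None = None,
    min_score: float = 0.8,
    ri_tol: float = 30.0,
    merge_split_peaks: bool = True,
) -> tuple[FeatureTable | list[ResolvedFeature], list[ResolvedFeature]]:
    """End-to-end resolution of a cube into a feature table.

    Baseline-corrects, segments into windows, resolves each window, assigns
    retention indices, optionally matches the library, and — when internal
    standards are named — normalizes areas and returns a
    :class:`~predmet.tables.FeatureTable`.  Also returns the flat feature
    list for inspection.
    """
    work = baseline_correct(cube, baseline_window) if baseline_window else cube
    min_width = max(5, len(cube.time_axis) // (3 * n_windows))
    windows = segment_windows(work, n_windows, min_width=min_width)
    features: list[ResolvedFeature] = []
    for w in windows:
        features.extend(resolve_window(w, max_components=max_components))
    dt = float(np.median(np.diff(cube.time_axis)))
    if merge_split_peaks:
        features = _merge_adjacent(features, dt=dt)
    for i, f in enumerate(features):
        f.feature_id = f"R{i:03d}"
        f.areas.index = [str(s) for s in cube.samples]
        assign_retention_index(f, cube.ri_markers)
        if library is not None:
            match_library(f, library, min_score=min_score, ri_tol=ri_tol)
    if is_names:
        table = normalize_by_is(features, is_names, sample_ids=[str(s) for s in cube.samples])
        return table, features
    return features, features


# ---------------------------------------------------------------------------
# library I/O

def write_library(library: SpectralLibrary, path: str | Path) -> Path:
    """Delimited text: ``name  RI  mz:intensity,mz:intensity,...`` per line."""
    path = Path(path)
    lines = ["# name\tretention_index\tspectrum"]
    for name, spec, ri in library.entries:
        spec = np.asarray(spec, dtype=float)
        pairs = ",".join(
            f"{int(m)}:{v:.6g}" for m, v in zip(library.mz, spec) if v > 0
        )
        lines.append(f"{name}\t{ri:.1f}\t{pairs}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_library(path: str | Path, mz: np.ndarray) -> SpectralLibrary:
    entries = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        name, ri, pairs = line.split("\t")
        spec = np.zeros(len(mz), dtype=float)
        mz_index = {int(m): i for i, m in enumerate(mz)}
        for pair in pairs.split(","):
            m, v = pair.split(":")
            if int(m) in mz_index:
                spec[mz_index[int(m)]] = float(v)
        total = spec.sum()
        if total > 0:
            spec /= total
        entries.append((name, spec, float(ri)))
    return SpectralLibrary(mz=np.asarray(mz), entries=entries)


def make_toy_library(
    mz: np.ndarray,
    spectra: np.ndarray,
    ris: list[float],
    names: list[str] | None = None,
    n_decoys: int = 0,
    seed: int = 0,
) -> SpectralLibrary:
    """Build a small synthetic library from known spectra plus random decoys.

    This stands in for a reference spectral library in demos and tests; it is
    synthetic and carries no real metabolite spectra.
    """
    rng = np.random.default_rng(seed)
    if names is None:
        names = [f"compound_{i:02d}" for i in range(len(spectra))]
    entries = [
        (names[i], spectra[i] / spectra[i].sum(), float(ris[i]))
        for i in range(len(spectra))
    ]
    for d in range(n_decoys):
        spec = np.zeros(len(mz))
        idx = rng.choice(len(mz), size=10, replace=False)
        spec[idx] = rng.uniform(0.05, 1.0, size=10)
        entries.append((f"decoy_{d:02d}", spec / spec.sum(), float(rng.uniform(1000, 1000 + 100 * 8))))
    return SpectralLibrary(mz=np.asarray(mz), entries=entries)
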