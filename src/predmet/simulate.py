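"""Synthetic GC-TOFMS data with known ground truth.

Two levels of simulation are provided:

* :func:`generate_cube` emits raw three-way data — per-sample retention-time
  x m/z intensity matrices — built from Gaussian elution peaks grouped into
  time windows, sparse non-negative fragment spectra shared across samples,
  log-normal per-sample component areas, internal-standard components with
  class-independent areas, additive detector noise and a slow baseline.
* :func:`generate_feature_table` emits the post-resolution object directly: a
  strictly positive samples x features matrix with a small informative subset
  whose class means are separated by a chosen standardized difference on the
  log scale.

Both return a :class:`GroundTruth` so downstream recovery can be scored
exactly.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import FeatureTable

__all__ = [
    "GroundTruth",
    "RawDataCube",
    "generate_cube",
    "generate_feature_table",
    "inject_failures",
    "simulate_study_table",
    "write_cube",
    "read_cube",
    "write_ground_truth",
    "read_ground_truth",
]

# Geometry of the simulated chromatogram.  Windows tile the time axis; peaks
# sit in the central region of each window so the mean total ion current dips
# near window boundaries (which is what window segmentation exploits).
_POINTS_PER_WINDOW = 60
_DT = 0.5  # seconds per scan
_SIGMA_T = 2.0  # chromatographic peak SD, seconds
_N_MZ = 120
_MZ_START = 50
_FRAGMENTS_PER_SPECTRUM = 10


@dataclasses.dataclass
class GroundTruth:
    """Everything the generator knows that an analysis should recover."""

    component_spectra: np.ndarray  # component x m/z, rows sum to 1
    component_elutions: pd.DataFrame  # one row per component: window, center, sigma
    true_areas: np.ndarray  # sample x component, before recovery factors
    informative_features: list  # feature/component identifiers carrying the effect
    effect_size: float  # standardized mean difference on the log scale
    class_labels: np.ndarray  # per-sample 0/1
    is_components: list = dataclasses.field(default_factory=list)
    recovery_factors: np.ndarray | None = None  # per-sample global scale
    feature_ids: list = dataclasses.field(default_factory=list)
    sample_ids: list = dataclasses.field(default_factory=list)
    effect_signs: dict = dataclasses.field(default_factory=dict)


@dataclasses.dataclass
class RawDataCube:
    """Raw three-way data: sample x retention time x m/z.

    All samples share ``time_axis`` (seconds, strictly increasing) and
    ``mz_axis`` (integer bins).  ``ri_markers`` is a list of
    ``(time, retention_index)`` anchor pairs, strictly increasing in both
    coordinates, used for retention-index interpolation.
    """

    samples: list
    time_axis: np.ndarray
    mz_axis: np.ndarray
    intensities: np.ndarray  # sample x time x mz
    ri_markers: list  # [(time_s, ri), ...]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        t = np.asarray([m[0] for m in self.ri_markers], dtype=float)
        r = np.asarray([m[1] for m in self.ri_markers], dtype=float)
        if len(t) >= 2 and (np.any(np.diff(t) <= 0) or np.any(np.diff(r) <= 0)):
            raise ValueError("ri_markers must be strictly increasing in both coordinates")

    def tic(self) -> np.ndarray:
        """Total ion current, sample x time."""
        return self.intensities.sum(axis=2)


def _sparse_spectrum(rng: np.random.Generator, n_mz: int) -> np.ndarray:
    """Random sparse non-negative fragment spectrum with unit sum."""
    spec = np.zeros(n_mz)
    idx = rng.choice(n_mz, size=_FRAGMENTS_PER_SPECTRUM, replace=False)
    spec[idx] = rng.uniform(0.05, 1.0, size=_FRAGMENTS_PER_SPECTRUM)
    return spec / spec.sum()


def generate_cube(
    n_samples: int,
    n_windows: int,
    components_per_window: int,
    n_is: int = 0,
    overlap: float = 0.0,
    snr: float = np.inf,
    baseline_drift: float = 0.0,
    seed: int = 0,
    effect_size: float = 0.0,
    n_informative: int = 0,
    recovery_sd: float = 0.0,
    area_sd: float = 0.3,
) -> tuple[RawDataCube, GroundTruth]:
    """Simulate a raw GC-TOFMS cube.

    Parameters
    ----------
    n_samples, n_windows, components_per_window
        Layout of the chromatogram: each window holds the stated number of
        Gaussian elution peaks.
    n_is
        Number of internal-standard components (class-independent areas),
        appended round-robin to the windows on top of
        ``components_per_window`` analyte peaks.
    overlap
        Fraction in [0, 1] controlling co-elution: adjacent peak centers in a
        window are ``(1 - overlap) * 4 * sigma`` apart, floored at half a
        scan, so 0 gives baseline separation and values near 1 near-complete
        co-elution.
    snr
        Signal-to-noise amplitude ratio in the energy sense: the additive
        Gaussian noise SD is chosen so that the Frobenius norm of the
        noise-free signal is ``snr`` times the expected Frobenius norm of
        the noise.  ``inf`` disables noise.
    baseline_drift
        Amplitude of a slow non-negative sinusoidal baseline per sample.
    effect_size, n_informative
        Optional class effect: the first ``n_informative`` analyte components
        get their log-areas shifted by ``effect_size`` pooled SDs in class 1.
    recovery_sd
        Log-normal SD of a per-sample global recovery factor applied to the
        whole signal (internal standards included) — the nuisance that
        IS normalization is meant to remove.

    Returns
    -------
    (RawDataCube, GroundTruth)
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if components_per_window < 1:
        raise ValueError("components_per_window must be >= 1")
    if not 0.0 <= overlap <= 1.0:
        raise ValueError("overlap must be within [0, 1]")
    if not snr > 0:
        raise ValueError("snr must be positive")
    n_analyte = n_windows * components_per_window
    if n_is > n_analyte + n_is:  # defensive; n_is negative
        raise ValueError("invalid n_is")
    if n_is > 0 and n_is > n_analyte:
        raise ValueError("n_is may not exceed the number of analyte components")
    if n_informative > n_analyte:
        raise ValueError("n_informative may not exceed analyte components")

    rng = np.random.default_rng(seed)
    nt = n_windows * _POINTS_PER_WINDOW
    time_axis = np.arange(nt) * _DT
    mz_axis = np.arange(_MZ_START, _MZ_START + _N_MZ)

    # component layout: analytes first, then IS round-robin across windows
    rows = []
    comp_window = []
    for w in range(n_windows):
        w0 = w * _POINTS_PER_WINDOW * _DT
        w_center = w0 + _POINTS_PER_WINDOW * _DT / 2.0
        spacing = max((1.0 - overlap) * 4.0 * _SIGMA_T, _DT / 2.0)
        k = components_per_window
        centers = w_center + (np.arange(k) - (k - 1) / 2.0) * spacing
        for c in centers:
            rows.append((w, c, _SIGMA_T))
            comp_window.append(w)
    for j in range(n_is):
        w = j % n_windows
        w0 = w * _POINTS_PER_WINDOW * _DT
        # park IS peaks towards the front third of the window, clear of the
        # analyte cluster when overlap is small
        c = w0 + _POINTS_PER_WINDOW * _DT * 0.2
        rows.append((w, c, _SIGMA_T))
        comp_window.append(w)
    n_comp = len(rows)
    elutions = pd.DataFrame(rows, columns=["window", "center", "sigma"])

    spectra = np.vstack([_sparse_spectrum(rng, _N_MZ) for _ in range(n_comp)])

    class_labels = (np.arange(n_samples) % 2).astype(int)
    log_mu = np.log(100.0)
    log_areas = log_mu + area_sd * rng.standard_normal((n_samples, n_comp))
    informative = list(range(min(n_informative, n_analyte)))
    for j in informative:
        log_areas[class_labels == 1, j] += effect_size * area_sd
    is_components = list(range(n_analyte, n_analyte + n_is))
    for j in is_components:
        log_areas[:, j] = log_mu  # constant spiked amount
    true_areas = np.exp(log_areas)

    recovery = (
        np.exp(recovery_sd * rng.standard_normal(n_samples))
        if recovery_sd > 0
        else np.ones(n_samples)
    )

    # unit-area Gaussian elution shapes so component area == true area
    shapes = np.zeros((n_comp, nt))
    for j, (_, c, s) in enumerate(rows):
        g = np.exp(-0.5 * ((time_axis - c) / s) ** 2)
        shapes[j] = g / np.trapezoid(g, time_axis)

    intensities = np.einsum("sc,ct,cm->stm", true_areas * recovery[:, None], shapes, spectra)

    if np.isfinite(snr):
        signal_rms = np.linalg.norm(intensities) / np.sqrt(intensities.size)
        intensities = intensities + rng.normal(
            0.0, signal_rms / snr, size=intensities.shape
        )
    if baseline_drift > 0:
        phases = rng.uniform(0, 2 * np.pi, size=n_samples)
        t_norm = 2 * np.pi * time_axis / time_axis[-1]
        for s in range(n_samples):
            base = baseline_drift * 0.5 * (1.0 + np.sin(t_norm + phases[s]))
            intensities[s] += base[:, None]
    np.clip(intensities, 0.0, None, out=intensities)

    # linear retention-index ladder: one anchor every window boundary
    ri_markers = [
        (w * _POINTS_PER_WINDOW * _DT, 1000.0 + 100.0 * w) for w in range(n_windows + 1)
    ]

    sample_ids = [f"S{i:03d}" for i in range(n_samples)]
    feature_ids = [f"C{j:03d}" for j in range(n_analyte)] + [
        f"IS{j:02d}" for j in range(n_is)
    ]
    cube = RawDataCube(
        samples=sample_ids,
        time_axis=time_axis,
        mz_axis=mz_axis,
        intensities=intensities,
        ri_markers=ri_markers,
    )
    truth = GroundTruth(
        component_spectra=spectra,
        component_elutions=elutions,
        true_areas=true_areas,
        informative_features=[feature_ids[j] for j in informative],
        effect_size=effect_size,
        class_labels=class_labels,
        is_components=[feature_ids[j] for j in is_components],
        recovery_factors=recovery,
        feature_ids=feature_ids,
        sample_ids=sample_ids,
    )
    return cube, truth


def generate_feature_table(
    n_per_class: tuple[int, int],
    n_features: int,
    n_informative: int,
    effect_size: float,
    correlation: float = 0.0,
    seed: int = 0,
    log_sd: float = 0.5,
) -> tuple[FeatureTable, GroundTruth]:
    """Simulate a resolved, normalized feature table with a planted effect.

    Values are log-normal (strictly positive, relative-concentration
    semantics).  The first ``n_informative`` features carry a class-mean
    separation of ``effect_size`` pooled SDs on the log scale; an
    equicorrelated Gaussian block of strength ``correlation`` couples the
    informative set.  Remaining features are class-independent noise.
    """
    n0, n1 = n_per_class
    if n0 <= 0 or n1 <= 0 or n_features <= 0:
        raise ValueError("counts must be positive")
    if n_informative > n_features:
        raise ValueError("n_informative may not exceed n_features")
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    if not 0.0 <= correlation < 1.0:
        raise ValueError("correlation must be in [0, 1)")

    rng = np.random.default_rng(seed)
    n = n0 + n1
    labels = np.r_[np.zeros(n0, dtype=int), np.ones(n1, dtype=int)]

    Z = rng.standard_normal((n, n_features))
    if n_informative > 0 and correlation > 0:
        shared = rng.standard_normal((n, 1))
        Z[:, :n_informative] = (
            np.sqrt(correlation) * shared
            + np.sqrt(1.0 - correlation) * Z[:, :n_informative]
        )
    # per-feature baseline abundance on the log scale
    mu = rng.uniform(np.log(50.0), np.log(200.0), size=n_features)
    logX = mu + log_sd * Z
    # planted effect: randomly signed per informative feature
    signs = rng.choice([-1.0, 1.0], size=n_informative)
    for j in range(n_informative):
        logX[labels == 1, j] += signs[j] * effect_size * log_sd
    X = np.exp(logX)

    sample_ids = [f"S{i:03d}" for i in range(n)]
    feature_ids = [f"F{j:03d}" for j in range(n_features)]
    table = FeatureTable(
        X=pd.DataFrame(X, index=sample_ids, columns=feature_ids),
        sample_meta=pd.DataFrame({"group": labels}, index=sample_ids),
    )
    truth = GroundTruth(
        component_spectra=np.zeros((0, 0)),
        component_elutions=pd.DataFrame(columns=["window", "center", "sigma"]),
        true_areas=X,
        informative_features=feature_ids[:n_informative],
        effect_size=effect_size,
        class_labels=labels,
        feature_ids=feature_ids,
        sample_ids=sample_ids,
        effect_signs=dict(zip(feature_ids[:n_informative], signs)),
    )
    return table, truth


def inject_failures(
    table: FeatureTable,
    n_outliers: int,
    n_failed: int,
    seed: int = 0,
    outlier_factor: float = 8.0,
) -> FeatureTable:
    """Corrupt a table the way real runs fail.

    Outlier samples get their whole profile multiplied by a gross factor
    (an analytical error shifting them far outside the score-space cloud);
    failed samples — emulating unsuccessful derivatization — get a random
    majority (80%) of their features collapsed to near zero.  Affected
    sample ids are recorded in ``sample_meta`` under ``injected_outlier`` /
    ``injected_failed``.
    """
    if n_outliers + n_failed >= table.n_samples:
        raise ValueError("cannot corrupt every sample")
    out = table.copy()
    if n_outliers == 0 and n_failed == 0:
        return out
    rng = np.random.default_rng(seed)
    chosen = rng.choice(table.n_samples, size=n_outliers + n_failed, replace=False)
    outlier_idx = chosen[:n_outliers]
    failed_idx = chosen[n_outliers:]
    X = out.X.to_numpy(dtype=float)
    for i in outlier_idx:
        X[i] *= outlier_factor
    for i in failed_idx:
        cols = rng.choice(
            table.n_features, size=int(round(0.8 * table.n_features)), replace=False
        )
        X[i, cols] *= 1e-4
    out.X = pd.DataFrame(X, index=out.X.index, columns=out.X.columns)
    flags_out = np.zeros(table.n_samples, dtype=bool)
    flags_out[outlier_idx] = True
    flags_fail = np.zeros(table.n_samples, dtype=bool)
    flags_fail[failed_idx] = True
    out.sample_meta["injected_outlier"] = flags_out
    out.sample_meta["injected_failed"] = flags_fail
    return out


def simulate_study_table(
    n_gbm: int = 57,
    n_oligo: int = 20,
    n_features: int = 197,
    effect_size: float = 2.0,
    features_per_contrast: int = 10,
    seed: int = 0,
    log_sd: float = 0.5,
) -> tuple[FeatureTable, dict]:
    """Simulate a glioma-study-like table with diagnosis, grade and survival.

    The cohort mixes glioblastoma (grade IV) and oligodendroglioma (grade II
    and III) samples; survival times are drawn so that within each diagnosis
    both a short- and a long-survival group exist.  Four disjoint informative
    blocks of ``features_per_contrast`` features carry effects for the four
    contrasts of interest: diagnosis, oligodendroglioma grade, survival in
    glioblastoma, survival in oligodendroglioma.

    Returns the table plus a dict mapping contrast name to its informative
    feature ids.
    """
    rng = np.random.default_rng(seed)
    n = n_gbm + n_oligo
    diagnosis = np.array(["glioblastoma"] * n_gbm + ["oligodendroglioma"] * n_oligo)
    grade = np.array(
        ["IV"] * n_gbm
        + ["II" if i % 2 == 0 else "III" for i in range(n_oligo)]
    )
    survival = np.empty(n)
    # glioblastoma: mixture of short (<=4 mo), middle, long (>=36 mo)
    for i in range(n_gbm):
        u = i % 3
        if u == 0:
            survival[i] = rng.uniform(0.5, 4.0)
        elif u == 1:
            survival[i] = rng.uniform(6.0, 30.0)
        else:
            survival[i] = rng.uniform(36.0, 72.0)
    # oligodendroglioma: short (<=24 mo) vs long (>36 mo) with a thin middle
    for k in range(n_oligo):
        i = n_gbm + k
        u = k % 2
        survival[i] = rng.uniform(4.0, 24.0) if u == 0 else rng.uniform(37.0, 96.0)

    mu = rng.uniform(np.log(50.0), np.log(200.0), size=n_features)
    logX = mu + log_sd * rng.standard_normal((n, n_features))

    contrasts = {
        "diagnosis": diagnosis == "glioblastoma",
        "grade_oligo": (diagnosis == "oligodendroglioma") & (grade == "III"),
        "survival_gbm": (diagnosis == "glioblastoma") & (survival >= 36.0),
        "survival_oligo": (diagnosis == "oligodendroglioma") & (survival > 36.0),
    }
    feature_ids = [f"F{j:03d}" for j in range(n_features)]
    informative: dict[str, list[str]] = {}
    block = 0
    for name, members in contrasts.items():
        cols = range(block, block + features_per_contrast)
        informative[name] = [feature_ids[j] for j in cols]
        signs = rng.choice([-1.0, 1.0], size=features_per_contrast)
        for s_j, j in zip(signs, cols):
            logX[members, j] += s_j * effect_size * log_sd
        block += features_per_contrast

    sample_ids = [f"P{i:03d}" for i in range(n)]
    table = FeatureTable(
        X=pd.DataFrame(np.exp(logX), index=sample_ids, columns=feature_ids),
        sample_meta=pd.DataFrame(
            {
                "diagnosis": diagnosis,
                "grade": grade,
                "survival_months": np.round(survival, 1),
            },
            index=sample_ids,
        ),
    )
    return table, informative


# ---------------------------------------------------------------------------
# serialization

def write_cube(cube: RawDataCube, path: str | Path) -> Path:
    """Write a cube as netCDF (classic format) with named dimensions.

    Falls back transparently at read time; see :func:`read_cube`.
    """
    import xarray as xr

    path = Path(path)
    ds = xr.Dataset(
        {
            "intensities": (
                ("sample", "time", "mz"),
                np.asarray(cube.intensities, dtype="f8"),
            )
        },
        coords={
            "sample": [str(s) for s in cube.samples],
            "time": cube.time_axis,
            "mz": cube.mz_axis.astype("i4"),
        },
        attrs={"ri_markers": json.dumps([[float(t), float(r)] for t, r in cube.ri_markers])},
    )
    ds.to_netcdf(path, engine="scipy")
    return path


def read_cube(path: str | Path) -> RawDataCube:
    import xarray as xr

    ds = xr.open_dataset(Path(path), engine="scipy")
    try:
        cube = RawDataCube(
            samples=[str(s) for s in ds["sample"].values],
            time_axis=np.asarray(ds["time"].values, dtype=float),
            mz_axis=np.asarray(ds["mz"].values),
            intensities=np.asarray(ds["intensities"].values, dtype=float),
            ri_markers=[tuple(p) for p in json.loads(ds.attrs["ri_markers"])],
        )
    finally:
        ds.close()
    return cube


def write_cube_text(cube: RawDataCube, directory: str | Path) -> Path:
    """Delimited-text fallback: one TSV per sample plus an axes file."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    axes = {
        "samples": [str(s) for s in cube.samples],
        "time_axis": [float(t) for t in cube.time_axis],
        "mz_axis": [int(m) for m in cube.mz_axis],
        "ri_markers": [[float(t), float(r)] for t, r in cube.ri_markers],
    }
    (directory / "axes.json").write_text(json.dumps(axes))
    for i, s in enumerate(cube.samples):
        np.savetxt(directory / f"{s}.tsv", cube.intensities[i], delimiter="\t")
    return directory


def read_cube_text(directory: str | Path) -> RawDataCube:
    directory = Path(directory)
    axes = json.loads((directory / "axes.json").read_text())
    intensities = np.stack(
        [np.loadtxt(directory / f"{s}.tsv", delimiter="\t") for s in axes["samples"]]
    )
    return RawDataCube(
        samples=axes["samples"],
        time_axis=np.asarray(axes["time_axis"], dtype=float),
        mz_axis=np.asarray(axes["mz_axis"]),
        intensities=intensities,
        ri_markers=[tuple(p) for p in axes["ri_markers"]],
    )


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "component_spectra": np.asarray(truth.component_spectra).tolist(),
        "component_elutions": truth.component_elutions.to_dict(orient="list"),
        "true_areas": np.asarray(truth.true_areas).tolist(),
        "informative_features": list(truth.informative_features),
        "effect_size": float(truth.effect_size),
        "class_labels": np.asarray(truth.class_labels).tolist(),
        "is_components": list(truth.is_components),
        "recovery_factors": (
            None
            if truth.recovery_factors is None
            else np.asarray(truth.recovery_factors).tolist()
        ),
        "feature_ids": list(truth.feature_ids),
        "sample_ids": list(truth.sample_ids),
    }
    path.write_text(json.dumps(payload))
    return path


def read_ground_truth(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        component_spectra=np.asarray(d["component_spectra"], dtype=float),
        component_elutions=pd.DataFrame(d["component_elutions"]),
        true_areas=np.asarray(d["true_areas"], dtype=float),
        informative_features=d["informative_features"],
        effect_size=d["effect_size"],
        class_labels=np.asarray(d["class_labels"], dtype=int),
        is_components=d["is_components"],
        recovery_factors=(
            None if d["recovery_factors"] is None else np.asarray(d["recovery_factors"])
        ),
        feature_ids=d["feature_ids"],
        sample_ids=d["sample_ids"],
    )
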