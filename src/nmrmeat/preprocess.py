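"""Spectral pretreatment: bucketing, region exclusion, normalization, log.

The pretreatment chain per sample is

    bucket -> normalize to the reference integral -> drop excluded buckets
    -> log10 transform,

producing one row of the feature matrix.  Bucket values are *mean* intensities
(trapezoidal integral over the bucket divided by its width), which makes them
independent of the digital resolution of the input spectrum.  A bucket is
dropped when its half-open interval overlaps a closed exclusion interval at
all, so no excluded signal leaks into the features.  Normalization divides by
the trapezoidal integral of the *spectrum* over the reference region (for the
polar block: TSP at -0.5 to 0.5 ppm, which lies outside the bucketed range),
so it commutes with the exclusion step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .spectra import Spectrum, SpectrumSet


@dataclass(frozen=True)
class BucketSpec:
    """Pretreatment geometry and transform parameters.

    Defaults are the polar-block settings: 1000 buckets over 0.50-9.50 ppm,
    residual-water exclusion 4.84-5.10 ppm, TSP reference region -0.50 to
    0.50 ppm, log10 with additive offset 1e-6 and clipping of negatives at 0.
    """

    region: tuple[float, float] = (0.50, 9.50)
    n_buckets: int = 1000
    exclusions: tuple[tuple[float, float], ...] = ((4.84, 5.10),)
    norm_region: tuple[float, float] = (-0.50, 0.50)
    log_offset: float = 1e-6

    def __post_init__(self) -> None:
        if self.region[1] <= self.region[0]:
            raise ValueError("bucketing region must have positive width")
        if self.n_buckets < 1:
            raise ValueError("n_buckets must be >= 1")
        if self.log_offset <= 0:
            raise ValueError("log_offset must be > 0")
        object.__setattr__(
            self, "exclusions", tuple(tuple(e) for e in self.exclusions)
        )

    @property
    def width(self) -> float:
        return (self.region[1] - self.region[0]) / self.n_buckets

    def edges(self) -> np.ndarray:
        return np.linspace(self.region[0], self.region[1], self.n_buckets + 1)

    def centers(self) -> np.ndarray:
        e = self.edges()
        return 0.5 * (e[:-1] + e[1:])

    def record(self) -> dict:
        return {
            "region": list(self.region),
            "n_buckets": self.n_buckets,
            "exclusions": [list(e) for e in self.exclusions],
            "norm_region": list(self.norm_region),
            "log_offset": self.log_offset,
            "log_base": 10,
            "bucket_value": "mean_intensity",
        }


def default_polar_spec() -> BucketSpec:
    return BucketSpec()


def default_nonpolar_spec() -> BucketSpec:
    """Non-polar block: 0.50-6.80 ppm, 2000 buckets, water + methanol
    exclusions, normalization region 1.50-4.05 ppm."""
    return BucketSpec(
        region=(0.50, 6.80),
        n_buckets=2000,
        exclusions=((4.84, 5.10), (3.33, 4.40)),
        norm_region=(1.50, 4.05),
    )


def _piecewise_integrals(spectrum: Spectrum, edges: np.ndarray) -> np.ndarray:
    """Exact trapezoidal integrals of the linear interpolant between edges."""
    x, y = spectrum.ppm, spectrum.intensity
    inside = (x >= edges[0]) & (x <= edges[-1])
    xm = np.union1d(x[inside], edges)
    ym = np.interp(xm, x, y)
    cum = np.concatenate(([0.0], np.cumsum(0.5 * (ym[:-1] + ym[1:]) * np.diff(xm))))
    idx = np.searchsorted(xm, edges)
    return np.diff(cum[idx])


def spectrum_integral(spectrum: Spectrum, lo: float, hi: float) -> float:
    """Trapezoidal integral of the spectrum over [lo, hi]."""
    if not spectrum.covers(lo, hi):
        raise ValueError(
            f"sample {spectrum.sample_id!r}: axis does not cover [{lo}, {hi}]"
        )
    return float(_piecewise_integrals(spectrum, np.array([lo, hi]))[0])


def bucket(spectrum: Spectrum, spec: BucketSpec) -> np.ndarray:
    """Mean intensity per bucket over the bucketing region."""
    lo, hi = spec.region
    if not spectrum.covers(lo, hi):
        raise ValueError(
            f"sample {spectrum.sample_id!r}: axis does not span the bucketing "
            f"region [{lo}, {hi}]"
        )
    return _piecewise_integrals(spectrum, spec.edges()) / spec.width


def apply_exclusions(vector: np.ndarray, spec: BucketSpec) -> tuple[np.ndarray, np.ndarray]:
    """Drop every bucket whose interval overlaps an exclusion interval.

    Buckets are half-open [lo, hi); exclusions are closed.  Returns the
    retained values and the original indices of the retained buckets.
    """
    e = spec.edges()
    keep = np.ones(spec.n_buckets, dtype=bool)
    for ex_lo, ex_hi in spec.exclusions:
        keep &= ~((e[:-1] <= ex_hi) & (e[1:] > ex_lo))
    retained = np.flatnonzero(keep)
    return np.asarray(vector)[retained], retained


def normalize_to_reference(spectrum: Spectrum, vector: np.ndarray, spec: BucketSpec) -> np.ndarray:
    """Divide by the spectrum's integral over the reference region.

    The output is invariant to a global intensity rescaling of the input.
    """
    ref = spectrum_integral(spectrum, *spec.norm_region)
    if ref <= 0:
        raise ValueError(
            f"sample {spectrum.sample_id!r}: reference integral is {ref:g} "
            "(missing or negative reference signal)"
        )
    return np.asarray(vector) / ref


def log_transform(vector: np.ndarray, spec: BucketSpec) -> np.ndarray:
    """Elementwise x -> log10(max(x, 0) + offset); compresses large values."""
    return np.log10(np.clip(np.asarray(vector, dtype=float), 0.0, None) + spec.log_offset)


@dataclass
class FeatureMatrix:
    """Samples x retained-buckets matrix with provenance.

    ``pretreatment`` records the applied :class:`BucketSpec`; models refuse
    matrices whose record does not match their own.
    """

    values: np.ndarray
    bucket_centers: np.ndarray
    bucket_edges: np.ndarray  # (k, 2) lo/hi per retained bucket
    sample_ids: list[str]
    class_labels: list[str | None]
    pretreatment: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        n, k = self.values.shape
        if len(self.sample_ids) != n or len(self.class_labels) != n:
            raise ValueError("sample metadata length mismatch")
        if self.bucket_centers.shape != (k,) or self.bucket_edges.shape != (k, 2):
            raise ValueError("bucket metadata shape mismatch")
        if k > 1 and not np.all(np.diff(self.bucket_centers) > 0):
            raise ValueError("bucket centers must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_buckets(self) -> int:
        return self.values.shape[1]

    @property
    def labels(self) -> np.ndarray:
        if any(lbl is None for lbl in self.class_labels):
            raise ValueError("feature matrix contains unlabelled samples")
        return np.asarray(self.class_labels, dtype=object)

    def subset(self, rows: Sequence[int]) -> "FeatureMatrix":
        rows = list(rows)
        return FeatureMatrix(
            values=self.values[rows],
            bucket_centers=self.bucket_centers,
            bucket_edges=self.bucket_edges,
            sample_ids=[self.sample_ids[i] for i in rows],
            class_labels=[self.class_labels[i] for i in rows],
            pretreatment=dict(self.pretreatment),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=[f"{c:.3f}" for c in self.bucket_centers],
        )

    def save(self, prefix: str | Path) -> tuple[Path, Path]:
        """Write ``<prefix>.csv`` (values) and ``<prefix>.json`` (sidecar)."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        csv_path = prefix.with_suffix(".csv")
        json_path = prefix.with_suffix(".json")
        self.to_dataframe().to_csv(csv_path)
        sidecar = {
            "pretreatment": self.pretreatment,
            "sample_ids": self.sample_ids,
            "class_labels": self.class_labels,
            "bucket_centers": self.bucket_centers.tolist(),
            "bucket_edges": self.bucket_edges.tolist(),
        }
        json_path.write_text(json.dumps(sidecar))
        return csv_path, json_path

    @classmethod
    def load(cls, prefix: str | Path) -> "FeatureMatrix":
        prefix = Path(prefix)
        df = pd.read_csv(prefix.with_suffix(".csv"), index_col=0)
        sidecar = json.loads(prefix.with_suffix(".json").read_text())
        return cls(
            values=df.to_numpy(),
            bucket_centers=np.asarray(sidecar["bucket_centers"]),
            bucket_edges=np.asarray(sidecar["bucket_edges"]),
            sample_ids=list(sidecar["sample_ids"]),
            class_labels=list(sidecar["class_labels"]),
            pretreatment=sidecar["pretreatment"],
        )


def preprocess_spectrum(spectrum: Spectrum, spec: BucketSpec) -> np.ndarray:
    """Full pretreatment chain for one spectrum -> retained, transformed row."""
    raw = bucket(spectrum, spec)
    normed = normalize_to_reference(spectrum, raw, spec)
    retained, _ = apply_exclusions(normed, spec)
    return log_transform(retained, spec)


def preprocess_set(sset: SpectrumSet, spec: BucketSpec) -> FeatureMatrix:
    """Pretreat every spectrum of a same-block set into a feature matrix."""
    if len(sset) == 0:
        raise ValueError("cannot preprocess an empty spectrum set")
    rows = []
    for s in sset:
        try:
            rows.append(preprocess_spectrum(s, spec))
        except ValueError as err:
            raise ValueError(f"pretreatment failed for sample {s.sample_id!r}: {err}") from err
    _, retained = apply_exclusions(np.zeros(spec.n_buckets), spec)
    edges = spec.edges()
    record = spec.record()
    record["n_retained"] = int(retained.size)
    record["block"] = sset.block
    return FeatureMatrix(
        values=np.vstack(rows),
        bucket_centers=spec.centers()[retained],
        bucket_edges=np.column_stack((edges[:-1][retained], edges[1:][retained])),
        sample_ids=sset.sample_ids,
        class_labels=sset.class_labels,
        pretreatment=record,
    )
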