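"""Spectrum containers and plain-text I/O.

A processed 1D spectrum is a ppm axis with matching intensities plus sample
metadata.  Spectra are exchanged as two-column CSV files (``ppm,intensity``
with a header line) and grouped through a manifest CSV with columns
``sample_id, class, block, seed, file``.  The axis is always stored ascending;
descending input axes are silently reversed on load, anything non-monotone is
rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

POLAR = "polar"
NONPOLAR = "nonpolar"


@dataclass
class Spectrum:
    """One sample's spectrum: ppm axis, intensities and metadata."""

    ppm: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    class_label: str | None = None
    block: str = POLAR
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.ppm.shape != self.intensity.shape:
            raise ValueError("ppm and intensity must be 1-D arrays of equal length")
        if self.ppm.size >= 2:
            steps = np.diff(self.ppm)
            if np.all(steps < 0):  # stored ascending by convention
                self.ppm = self.ppm[::-1].copy()
                self.intensity = self.intensity[::-1].copy()
            elif not np.all(steps > 0):
                raise ValueError(
                    f"ppm axis of sample {self.sample_id!r} is not strictly monotone"
                )

    def __len__(self) -> int:
        return self.ppm.size

    def covers(self, lo: float, hi: float) -> bool:
        """Whether the axis spans the closed interval [lo, hi]."""
        return self.ppm.size > 0 and self.ppm[0] <= lo and self.ppm[-1] >= hi


@dataclass
class SpectrumSet:
    """Ordered collection of same-block spectra with unique sample ids."""

    spectra: list[Spectrum]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.spectra]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate sample ids: {sorted(dupes)}")
        blocks = {s.block for s in self.spectra}
        if len(blocks) > 1:
            raise ValueError(f"mixed blocks in one set: {sorted(blocks)}")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def __getitem__(self, i: int) -> Spectrum:
        return self.spectra[i]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.spectra]

    @property
    def classes(self) -> list[str]:
        return sorted({s.class_label for s in self.spectra if s.class_label is not None})

    @property
    def class_labels(self) -> list[str | None]:
        return [s.class_label for s in self.spectra]

    @property
    def block(self) -> str:
        if not self.spectra:
            raise ValueError("empty spectrum set has no block")
        return self.spectra[0].block


def write_spectrum_csv(spectrum: Spectrum, path: str | Path) -> Path:
    """Write one spectrum as a two-column ``ppm,intensity`` CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("ppm,intensity\n")
        for x, y in zip(spectrum.ppm, spectrum.intensity):
            fh.write(f"{x:.12g},{y:.12g}\n")
    return path


def read_spectrum_csv(
    path: str | Path,
    sample_id: str | None = None,
    class_label: str | None = None,
    block: str = POLAR,
) -> Spectrum:
    """Read a two-column spectrum CSV.

    Descending axes are reversed to ascending.  Non-numeric rows raise a
    ``ValueError`` naming the offending line (1-based, counting the header).
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (ppm, intensity)")
    cols = df.iloc[:, :2].apply(pd.to_numeric, errors="coerce")
    bad = cols.isna().any(axis=1)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # +1 header, +1 one-based
        raise ValueError(f"{path}: non-numeric value at line {line}")
    return Spectrum(
        ppm=cols.iloc[:, 0].to_numpy(),
        intensity=cols.iloc[:, 1].to_numpy(),
        sample_id=sample_id if sample_id is not None else path.stem,
        class_label=class_label,
        block=block,
    )


MANIFEST_COLUMNS = ("sample_id", "class", "block", "seed", "file")


def write_dataset(sset: SpectrumSet, out_dir: str | Path, manifest_name: str = "manifest.csv") -> Path:
    """Write every spectrum as CSV plus a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    spectra_dir = out_dir / "spectra"
    spectra_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in sset:
        fname = f"{s.sample_id}.csv"
        write_spectrum_csv(s, spectra_dir / fname)
        rows.append(
            {
                "sample_id": s.sample_id,
                "class": s.class_label if s.class_label is not None else "",
                "block": s.block,
                "seed": s.meta.get("seed", ""),
                "file": f"spectra/{fname}",
            }
        )
    manifest = out_dir / manifest_name
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(manifest, index=False)
    return manifest


def read_manifest(path: str | Path, base_dir: str | Path | None = None) -> SpectrumSet:
    """Load all spectra referenced by a manifest CSV, in manifest order.

    Rows with an empty class are allowed (external / test samples).  Duplicate
    sample ids or missing spectrum files raise ``ValueError``.
    """
    path = Path(path)
    base = Path(base_dir) if base_dir is not None else path.parent
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.empty:
        return SpectrumSet([])
    required = {"sample_id", "class", "block", "file"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    ids = df["sample_id"].tolist()
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"{path}: duplicate sample ids {sorted(dupes)}")
    spectra = []
    for _, row in df.iterrows():
        fpath = base / row["file"]
        if not fpath.exists():
            raise ValueError(f"{path}: spectrum file not found: {fpath}")
        label = row["class"] or None
        s = read_spectrum_csv(fpath, sample_id=row["sample_id"], class_label=label, block=row["block"])
        if "seed" in df.columns and row.get("seed", ""):
            try:
                s.meta["seed"] = int(row["seed"])
            except ValueError:
                pass
        spectra.append(s)
    return SpectrumSet(spectra)
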