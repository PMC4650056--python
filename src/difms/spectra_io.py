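"""Readers/writers and in-memory containers for peak lists and feature matrices.

File conventions
----------------
* Peak list: tab-separated text, two columns ``mz`` and ``intensity`` with a
  header row, sorted by ascending m/z. One file per
  sample × technical replicate × SIM window, named
  ``{sample_id}__{replicate_id}__{window_id}.tsv``.
* Feature matrix: CSV; first column ``sample_id``, remaining column headers
  are the representative feature m/z values printed at full double
  precision. Missing cells are written as ``NA`` — missing is never
  conflated with zero.
* Design table: CSV with columns ``sample_id, group, timepoint, temperature,
  pco2, qc``.

m/z values are held as double precision throughout; ppm differences are
computed as ``1e6 * |dm| / m_ref`` where ``m_ref`` is the theoretical mass
(annotation) or the cluster mean (alignment).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = "NA"


class ParseError(ValueError):
    """Malformed input file; carries the offending line number when known."""


@dataclass(frozen=True)
class Peak:
    """A single centroided signal: m/z (Th) and intensity (arbitrary units)."""

    mz: float
    intensity: float

    def __post_init__(self):
        if not self.mz > 0:
            raise ValueError(f"mz must be > 0, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"intensity must be >= 0, got {self.intensity}")


@dataclass
class PeakList:
    """Centroided peaks for one sample × technical replicate × SIM window.

    Peaks are stored as parallel numpy arrays sorted by ascending m/z.
    """

    sample_id: str
    replicate_id: str
    window_id: str
    mz: np.ndarray = field(default_factory=lambda: np.empty(0))
    intensity: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have the same length")
        if self.mz.size:
            if np.any(self.mz <= 0):
                raise ValueError("all m/z values must be > 0")
            if np.any(self.intensity < 0):
                raise ValueError("all intensities must be >= 0")
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return self.mz.size

    @property
    def peaks(self) -> list[Peak]:
        return [Peak(m, i) for m, i in zip(self.mz, self.intensity)]


@dataclass
class FeatureMatrix:
    """Samples × aligned-features intensity table.

    ``values`` is a 2-D float array (n_samples × n_features) with ``np.nan``
    marking missing cells; a missing measurement is distinct from an
    observed zero. ``feature_mzs`` holds one representative m/z per feature
    and is strictly increasing.
    """

    sample_ids: list[str]
    feature_mzs: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.feature_mzs = np.asarray(self.feature_mzs, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        n_s, n_f = self.values.shape if self.values.ndim == 2 else (0, 0)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples × features)")
        if len(self.sample_ids) != n_s:
            raise ValueError("sample_ids length does not match values rows")
        if self.feature_mzs.size != n_f:
            raise ValueError("feature_mzs length does not match values columns")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_id")
        if self.feature_mzs.size > 1 and not np.all(np.diff(self.feature_mzs) > 0):
            raise ValueError("feature_mzs must be strictly increasing")
        with np.errstate(invalid="ignore"):
            if np.any(self.values[~np.isnan(self.values)] < 0):
                raise ValueError("intensities must be >= 0 or missing")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(list(self.sample_ids), self.feature_mzs.copy(),
                             self.values.copy())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.sample_ids, name="sample_id"),
                            columns=self.feature_mzs)

    def subset_samples(self, ids: list[str]) -> "FeatureMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [pos[s] for s in ids]
        return FeatureMatrix(list(ids), self.feature_mzs.copy(), self.values[rows])


def peaklist_filename(sample_id: str, replicate_id: str, window_id: str) -> str:
    return f"{sample_id}__{replicate_id}__{window_id}.tsv"


def write_peaklist(pl: PeakList, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("mz\tintensity\n")
        for m, i in zip(pl.mz, pl.intensity):
            # repr of a Python float is the shortest round-trip representation
            fh.write(f"{float(m)!r}\t{float(i)!r}\n")


def read_peaklist(path: str | Path,
                  sample_id: str | None = None,
                  replicate_id: str | None = None,
                  window_id: str | None = None) -> PeakList:
    """Read a two-column peak-list TSV.

    Identifiers default to parsing the ``a__b__c.tsv`` naming convention and
    fall back to the bare stem.
    """
    path = Path(path)
    if sample_id is None:
        parts = path.stem.split("__")
        if len(parts) == 3:
            sample_id, replicate_id, window_id = parts
        else:
            sample_id, replicate_id, window_id = path.stem, "", ""
    mzs: list[float] = []
    intens: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if lineno == 1 and line.split("\t")[0] == "mz":
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(cols)}")
            try:
                m, i = float(cols[0]), float(cols[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if m <= 0:
                raise ParseError(f"{path}:{lineno}: non-positive m/z {m}")
            if i < 0:
                raise ParseError(f"{path}:{lineno}: negative intensity {i}")
            mzs.append(m)
            intens.append(i)
    return PeakList(sample_id, replicate_id or "", window_id or "",
                    np.array(mzs), np.array(intens))


def write_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(",".join(["sample_id"] + [repr(float(m)) for m in fm.feature_mzs])
                 + "\n")
        for sid, row in zip(fm.sample_ids, fm.values):
            cells = [MISSING if np.isnan(v) else repr(float(v)) for v in row]
            fh.write(",".join([sid] + cells) + "\n")


def read_matrix(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
        if not header or header[0] != "sample_id":
            raise ParseError(f"{path}:1: first column must be 'sample_id'")
        try:
            mzs = np.array([float(h) for h in header[1:]])
        except ValueError as exc:
            raise ParseError(f"{path}:1: bad m/z header: {exc}") from None
        sample_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split(",")
            if len(cols) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} columns, got {len(cols)}")
            sample_ids.append(cols[0])
            rows.append([np.nan if c == MISSING else float(c) for c in cols[1:]])
    values = np.array(rows, dtype=float) if rows else np.empty((0, mzs.size))
    return FeatureMatrix(sample_ids, mzs, values)


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, index=False)


def read_design(path: str | Path) -> pd.DataFrame:
    design = pd.read_csv(path, dtype={"sample_id": str, "group": str})
    if "sample_id" not in design.columns:
        raise ParseError(f"{path}: design table lacks a sample_id column")
    if design["sample_id"].duplicated().any():
        dup = design.loc[design["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(f"{path}: duplicate sample_id {dup!r}")
    if "qc" in design.columns:
        design["qc"] = design["qc"].astype(bool)
    return design
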