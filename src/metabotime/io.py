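"""Reading, writing and validation of intensity tables and study designs.

All formats are delimited text (tab or comma). An intensity table has feature
identifiers in the first column and one column per sample; a design table maps
every sample to a ``(condition, time_h, replicate)`` triple. Raw intensity
tables must be complete: a missing cell is a load error unless the caller
explicitly asks for floor imputation (the upstream quantification software's
convention for non-detections is unknown, so the default is strict failure).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError

#: Allowed condition labels, in canonical (column-major) order.
CONDITIONS = ("untreated", "treated")


@dataclass
class IntensityMatrix:
    """A feature x sample matrix of intensities.

    Values must be strictly positive for raw data; normalized matrices may
    hold any real values (``positive`` records which contract applies).
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    positive: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("values must be a 2-D array")
        nf, ns = self.values.shape
        if nf != len(self.feature_ids) or ns != len(self.sample_ids):
            raise DataError(
                f"shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        for kind, ids in (("feature", self.feature_ids), ("sample", self.sample_ids)):
            dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
            if dupes:
                raise DataError(f"duplicate {kind} id(s): {', '.join(map(str, dupes))}")
        if np.isnan(self.values).any():
            i, j = np.argwhere(np.isnan(self.values))[0]
            raise DataError(
                f"missing value at feature {self.feature_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if self.positive and (self.values <= 0).any():
            i, j = np.argwhere(self.values <= 0)[0]
            raise DataError(
                f"non-positive intensity at feature {self.feature_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.feature_ids, name="feature_id"),
            columns=self.sample_ids,
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, positive: bool = True) -> "IntensityMatrix":
        return cls(
            feature_ids=[str(i) for i in frame.index],
            sample_ids=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
            positive=positive,
        )

    def with_values(self, values: np.ndarray, positive: bool | None = None) -> "IntensityMatrix":
        """Same addressing, new values (used after normalization)."""
        return IntensityMatrix(
            feature_ids=list(self.feature_ids),
            sample_ids=list(self.sample_ids),
            values=values,
            positive=self.positive if positive is None else positive,
        )


@dataclass
class StudyDesign:
    """Maps samples to (condition, time_h, replicate); defines the time axis.

    Both conditions must share an identical, strictly increasing time axis and
    every (condition, timepoint) cell must contain at least two replicates.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = ["sample_id", "condition", "time_h", "replicate"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise DataError(f"design is missing column(s): {', '.join(missing)}")
        t = self.table.loc[:, required].copy()
        t["sample_id"] = t["sample_id"].astype(str)
        t["condition"] = t["condition"].astype(str)
        t["time_h"] = t["time_h"].astype(float)
        t["replicate"] = t["replicate"].astype(int)
        self.table = t.reset_index(drop=True)

        dupes = t["sample_id"][t["sample_id"].duplicated()].unique().tolist()
        if dupes:
            raise DataError(f"duplicate sample id(s) in design: {', '.join(dupes)}")
        bad = sorted(set(t["condition"]) - set(CONDITIONS))
        if bad:
            raise DataError(
                f"unknown condition label(s) {bad}; allowed labels are {list(CONDITIONS)}"
            )
        if (t["time_h"] <= 0).any():
            raise DataError("time_h values must be positive")
        axes = {
            cond: tuple(sorted(t.loc[t["condition"] == cond, "time_h"].unique()))
            for cond in CONDITIONS
            if (t["condition"] == cond).any()
        }
        if len(axes) < 2:
            raise DataError("design must contain both 'untreated' and 'treated' samples")
        if len(set(axes.values())) != 1:
            raise DataError(f"time axes differ between conditions: {axes}")
        counts = t.groupby(["condition", "time_h"]).size()
        thin = counts[counts < 2]
        if len(thin):
            cells = ", ".join(f"({c}, {h}h)" for c, h in thin.index)
            raise DataError(f"fewer than 2 replicates in design cell(s): {cells}")

    @property
    def timepoints(self) -> np.ndarray:
        """The ordered time axis (hours), shared by both conditions."""
        return np.sort(self.table["time_h"].unique())

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    def samples(self, condition: str, time_h: float) -> pd.DataFrame:
        cell = self.table[
            (self.table["condition"] == condition) & (self.table["time_h"] == time_h)
        ]
        return cell.sort_values("replicate")

    def replicate_ids(self, condition: str) -> list[int]:
        return sorted(self.table.loc[self.table["condition"] == condition, "replicate"].unique())

    def check_pairing(self, matrix: IntensityMatrix) -> None:
        """Refuse analysis unless matrix and design cover the same samples."""
        m, d = set(matrix.sample_ids), set(self.table["sample_id"])
        if m != d:
            only_m = sorted(m - d)
            only_d = sorted(d - m)
            raise DataError(
                "matrix and design sample ids differ; "
                f"only in matrix: {only_m or '-'}; only in design: {only_d or '-'}"
            )


def _detect_sep(path: str | Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_intensity_table(
    path: str | Path,
    sep: str | None = None,
    impute_missing: bool = False,
    positive: bool = True,
) -> IntensityMatrix:
    """Load a feature x sample intensity table from delimited text.

    Parameters
    ----------
    path
        File with feature ids in the first column and sample ids as header.
    sep
        Delimiter; auto-detected between tab and comma when ``None``.
    impute_missing
        When True, blank cells and zeros are replaced by half the smallest
        positive value in the same row before validation. Default is strict:
        any missing cell is a :class:`DataError`.
    positive
        Enforce strictly positive values (raw intensities). Pass False when
        loading an already-normalized table, which may hold any real values.
    """
    sep = _detect_sep(path, sep)
    try:
        frame = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise DataError(f"cannot parse {path}: {exc}") from exc
    frame.index = frame.index.astype(str)
    dupes = frame.index[frame.index.duplicated()].unique().tolist()
    if dupes:
        raise DataError(f"duplicate feature id(s): {', '.join(dupes)}")
    for col in frame.columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            row = frame.index[bad][0]
            raise DataError(
                f"non-numeric cell at feature {row!r}, sample {col!r}: "
                f"{frame.loc[row, col]!r}"
            )
        frame[col] = coerced
    values = frame.to_numpy(dtype=float)
    if impute_missing:
        miss = np.isnan(values) | (values == 0)
        if miss.any():
            with np.errstate(invalid="ignore"):
                pos = np.where(miss | (values <= 0), np.nan, values)
            row_floor = np.nanmin(pos, axis=1) / 2.0
            if np.isnan(row_floor).any():
                i = int(np.argwhere(np.isnan(row_floor))[0])
                raise DataError(
                    f"feature {frame.index[i]!r} has no positive value to impute from"
                )
            values = np.where(miss, row_floor[:, None], values)
    return IntensityMatrix(
        feature_ids=list(frame.index),
        sample_ids=[str(c) for c in frame.columns],
        values=values,
        positive=positive,
    )


def write_intensity_table(matrix: IntensityMatrix, path: str | Path, sep: str = "\t") -> None:
    matrix.to_frame().to_csv(path, sep=sep, float_format="%.17g")


def read_design(path: str | Path, sep: str | None = None) -> StudyDesign:
    sep = _detect_sep(path, sep)
    table = pd.read_csv(path, sep=sep)
    return StudyDesign(table)


def write_design(design: StudyDesign, path: str | Path, sep: str = "\t") -> None:
    design.table.to_csv(path, sep=sep, index=False)


def write_results(selection, scores: pd.DataFrame, distances: pd.DataFrame, outdir: str | Path) -> dict[str, Path]:
    """Write tidy per-feature result tables.

    One TSV per result kind: T² scores, distance-test results, and the
    membership table (per-approach flags, consensus = intersection flag,
    combined = union flag). Row order is the input feature order throughout.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "scores": outdir / "scores.tsv",
        "distances": outdir / "distances.tsv",
        "membership": outdir / "membership.tsv",
    }
    scores.to_csv(paths["scores"], sep="\t", index=False, float_format="%.12g")
    distances.to_csv(paths["distances"], sep="\t", index=False, float_format="%.12g")
    selection.membership.to_csv(paths["membership"], sep="\t", index=False)
    return paths
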