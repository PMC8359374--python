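"""On-disk formats and validated in-memory containers.

Everything the pipeline touches on disk is plain text: TSV for the beta
matrix, sample sheet and probe manifest, BED4 for interval tracks, and JSON
for trained models and reports. All readers validate on load and every
reader/writer pair is a lossless round trip.

Coordinate convention: all in-memory and BED coordinates are 0-based
half-open. Manifest files carry 1-based probe positions (as EPIC manifests
do) and are converted on read; the writer converts back, so round trips are
exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .config import GROUPS, PROBE_FLAGS, REGION_CATEGORIES, SEXES
from .model import EpisignatureModel


class FormatError(ValueError):
    """Raised when an input file violates its documented schema."""


# ---------------------------------------------------------------------------
# Beta matrix


@dataclass
class BetaMatrix:
    """Probes x samples matrix of methylation fractions in [0, 1].

    ``values`` is a float DataFrame indexed by probe id with one column per
    sample. ``detection_failure`` is an optional boolean DataFrame of the
    same shape marking entries whose detection failed; only flagged entries
    may hold out-of-range or missing values.
    """

    values: pd.DataFrame
    detection_failure: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] == 0:
            raise FormatError("no probes")
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()][0]
            raise FormatError(f"duplicate probe id {dup!r}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        self.values = v.astype(float)
        ok = self.values.to_numpy()
        mask = np.zeros(ok.shape, dtype=bool)
        if self.detection_failure is not None:
            f = self.detection_failure
            if f.shape != v.shape or list(f.index) != list(v.index) \
                    or list(f.columns) != list(v.columns):
                raise FormatError("detection_failure shape/labels do not match values")
            self.detection_failure = f.astype(bool)
            mask = self.detection_failure.to_numpy()
        bad = ~mask & (~np.isfinite(ok) | (ok < 0.0) | (ok > 1.0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"beta value {ok[i, j]!r} outside [0, 1] at probe "
                f"{v.index[i]!r}, sample {v.columns[j]!r}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset(self, probes: Iterable[str] | None = None,
               samples: Iterable[str] | None = None) -> "BetaMatrix":
        """Return a new matrix restricted to the given probes/samples (ordered)."""
        v = self.values
        f = self.detection_failure
        if probes is not None:
            probes = list(probes)
            v = v.loc[probes]
            f = f.loc[probes] if f is not None else None
        if samples is not None:
            samples = list(samples)
            v = v[samples]
            f = f[samples] if f is not None else None
        return BetaMatrix(v, f)


def read_beta_matrix(path: str | Path,
                     failure_path: str | Path | None = None) -> BetaMatrix:
    """Read a beta matrix TSV (first column probe ids, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0:
        raise FormatError("no probes")
    if df.index.name is None or df.shape[1] == 0:
        raise FormatError("malformed header: expected probe_id column plus samples")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    failure = None
    if failure_path is not None:
        failure = pd.read_csv(failure_path, sep="\t", index_col=0).astype(bool)
        failure.index = failure.index.astype(str)
        failure.columns = failure.columns.astype(str)
    return BetaMatrix(df, failure)


def write_beta_matrix(beta: BetaMatrix, path: str | Path,
                      failure_path: str | Path | None = None) -> None:
    # Default float formatting uses Python's shortest round-trip repr,
    # keeping write/read bit-identical.
    beta.values.to_csv(path, sep="\t", index_label="probe_id")
    if failure_path is not None and beta.detection_failure is not None:
        beta.detection_failure.astype(int).to_csv(
            failure_path, sep="\t", index_label="probe_id")


# ---------------------------------------------------------------------------
# Sample sheet


@dataclass
class SampleSheet:
    """Per-sample metadata: id, group, sex, age, optional cell proportions.

    Cell-proportion columns are any columns beyond the four required ones;
    when present they must be non-negative and sum to 1 (+-1e-6) per sample.
    An optional ``disorder`` column names the confounder pool an
    ``other_disorder`` sample belongs to.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "group", "sex", "age")

    def __post_init__(self) -> None:
        t = self.table.copy()
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise FormatError(f"sample sheet missing columns {missing}")
        t["sample_id"] = t["sample_id"].astype(str)
        if t["sample_id"].duplicated().any():
            raise FormatError("duplicate sample ids in sample sheet")
        bad_group = set(t["group"]) - set(GROUPS)
        if bad_group:
            raise FormatError(
                f"unknown group label(s) {sorted(bad_group)}; allowed: {list(GROUPS)}")
        bad_sex = set(t["sex"]) - set(SEXES)
        if bad_sex:
            raise FormatError(f"unknown sex label(s) {sorted(bad_sex)}; allowed: F, M")
        t["age"] = t["age"].astype(float)
        if (t["age"] < 0).any():
            raise FormatError("ages must be non-negative")
        props = self.cell_type_columns
        if props:
            p = t[props].to_numpy(dtype=float)
            if (p < 0).any():
                raise FormatError("cell proportions must be non-negative")
            s = p.sum(axis=1)
            if np.any(np.abs(s - 1.0) > 1e-6):
                i = int(np.argmax(np.abs(s - 1.0)))
                raise FormatError(
                    f"cell proportions for sample {t['sample_id'].iloc[i]!r} "
                    f"sum to {s[i]:.8f}, expected 1")
        self.table = t.reset_index(drop=True)

    @property
    def cell_type_columns(self) -> list[str]:
        skip = set(self.REQUIRED) | {"disorder"}
        return [c for c in self.table.columns if c not in skip]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def ids_of(self, group: str) -> list[str]:
        return list(self.table.loc[self.table["group"] == group, "sample_id"])

    def rows_for(self, sample_ids: Iterable[str]) -> "SampleSheet":
        t = self.table.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return SampleSheet(t)

    def cell_proportions(self) -> pd.DataFrame | None:
        """Cell proportions indexed by sample id, or None when absent."""
        cols = self.cell_type_columns
        if not cols:
            return None
        return self.table.set_index("sample_id")[cols]


def read_sample_sheet(path: str | Path) -> SampleSheet:
    return SampleSheet(pd.read_csv(path, sep="\t"))


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Probe manifest


@dataclass
class ProbeAnnotation:
    """Per-probe genomic annotation.

    ``table`` columns: probe_id, chrom, position (0-based, converted from the
    1-based on-disk manifest), region_category, flags (semicolon-joined
    subset of the QC flag vocabulary; empty string when unflagged).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.copy()
        required = ["probe_id", "chrom", "position", "region_category"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise FormatError(f"manifest missing columns {missing}")
        if "flags" not in t.columns:
            t["flags"] = ""
        t["probe_id"] = t["probe_id"].astype(str)
        if t["probe_id"].duplicated().any():
            raise FormatError("duplicate probe ids in manifest")
        t["position"] = t["position"].astype(int)
        if (t["position"] < 0).any():
            raise FormatError("probe positions must be non-negative")
        bad = set(t["region_category"]) - set(REGION_CATEGORIES)
        if bad:
            raise FormatError(
                f"unknown region category {sorted(bad)}; allowed: {list(REGION_CATEGORIES)}")
        t["flags"] = t["flags"].fillna("").astype(str)
        for fl in t["flags"]:
            parts = [p for p in fl.split(";") if p]
            unknown = set(parts) - set(PROBE_FLAGS)
            if unknown:
                raise FormatError(f"unknown probe flag(s) {sorted(unknown)}")
        self.table = t.reset_index(drop=True)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table["probe_id"])

    def flagged(self, flag: str) -> pd.Series:
        """Boolean mask (indexed by probe id) of probes carrying ``flag``."""
        if flag not in PROBE_FLAGS:
            raise ValueError(f"unknown flag {flag!r}")
        t = self.table.set_index("probe_id")
        return t["flags"].str.split(";").apply(lambda fs: flag in fs)

    def indexed(self) -> pd.DataFrame:
        return self.table.set_index("probe_id")


def read_manifest(path: str | Path) -> ProbeAnnotation:
    """Read a probe manifest TSV; on-disk positions are 1-based."""
    t = pd.read_csv(path, sep="\t", dtype={"flags": str})
    if "position" in t.columns:
        t["position"] = t["position"].astype(int) - 1
        if (t["position"] < 0).any():
            raise FormatError("manifest positions must be >= 1 (1-based)")
    return ProbeAnnotation(t)


def write_manifest(ann: ProbeAnnotation, path: str | Path) -> None:
    t = ann.table.copy()
    t["position"] = t["position"] + 1
    t.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Interval sets (BED4)


@dataclass
class IntervalSet:
    """A named set of genomic intervals, 0-based half-open.

    ``intervals`` columns: chrom, start, end, label (label may be empty).
    """

    name: str
    intervals: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["chrom", "start", "end", "label"]))

    def __post_init__(self) -> None:
        t = self.intervals.copy()
        for c in ("chrom", "start", "end"):
            if c not in t.columns:
                raise FormatError(f"interval set missing column {c!r}")
        if "label" not in t.columns:
            t["label"] = ""
        if len(t):
            t["start"] = t["start"].astype(int)
            t["end"] = t["end"].astype(int)
            if (t["start"] >= t["end"]).any():
                row = t[t["start"] >= t["end"]].iloc[0]
                raise FormatError(
                    f"interval start >= end at {row['chrom']}:{row['start']}-{row['end']}")
        t["label"] = t["label"].fillna("").astype(str)
        self.intervals = t[["chrom", "start", "end", "label"]].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.intervals)

    def sorted(self) -> "IntervalSet":
        t = self.intervals.sort_values(["chrom", "start", "end"], kind="stable")
        return IntervalSet(self.name, t.reset_index(drop=True))

    def total_span(self) -> int:
        """Total bp covered, counting overlapping intervals once."""
        total = 0
        for _, grp in self.intervals.groupby("chrom"):
            g = grp.sort_values("start")
            cur_s = cur_e = None
            for s, e in zip(g["start"], g["end"]):
                if cur_e is None or s > cur_e:
                    if cur_e is not None:
                        total += cur_e - cur_s
                    cur_s, cur_e = s, e
                else:
                    cur_e = max(cur_e, e)
            if cur_e is not None:
                total += cur_e - cur_s
        return total

    def by_label(self) -> dict[str, "IntervalSet"]:
        return {lab: IntervalSet(f"{self.name}:{lab}", grp.reset_index(drop=True))
                for lab, grp in self.intervals.groupby("label")}


def read_bed(path: str | Path, name: str | None = None) -> IntervalSet:
    """Read a BED3/BED4 file (0-based half-open, optional 4th label column)."""
    rows = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{ln}: expected at least 3 BED columns")
        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        if start >= end:
            raise FormatError(f"{path}:{ln}: start {start} >= end {end}")
        label = parts[3] if len(parts) > 3 else ""
        rows.append((chrom, start, end, label))
    return IntervalSet(name or Path(path).stem,
                       pd.DataFrame(rows, columns=["chrom", "start", "end", "label"]))


def write_bed(ivals: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in ivals.intervals.itertuples(index=False):
            fields = [row.chrom, str(row.start), str(row.end)]
            if row.label:
                fields.append(row.label)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Model persistence


def save_model(model: EpisignatureModel, path: str | Path) -> None:
    """Serialise a trained episignature model to a single JSON file."""
    Path(path).write_text(model.to_json())


def load_model(path: str | Path) -> EpisignatureModel:
    """Load a model saved by :func:`save_model`; raises on corruption."""
    return EpisignatureModel.from_json(Path(path).read_text())
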