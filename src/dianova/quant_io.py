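"""Reading, validation and writing of quantification, design and result tables.

The canonical in-memory containers are thin dataclasses around pandas
DataFrames with a fixed internal schema:

* :class:`PrecursorQuantSet` — one row per (protein, precursor, run, MS level)
  with a linear- or log2-scale intensity (``X_iprg`` in the model notation).
* :class:`DesignTable` — run → (condition group, replicate index) mapping.
* :class:`GroundTruthTable` — which proteins truly change, optionally by how
  much (log2 fold change for a designated group pair).
* :class:`TestResultTable` — one row per protein per method per contrast with
  fold change, test statistic, df, p-value and BH-adjusted p-value.

Files are plain delimited text (Spectronaut-style long exports, or wide
exports with separate MS1/MS2 quantity columns which are melted to long).
The delimiter is sniffed from the extension (``.csv`` → comma, anything else
→ tab) and can be overridden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

#: Default column names for each standard role in an input file.
ROLE_DEFAULTS: dict[str, str] = {
    "protein": "ProteinGroup",
    "precursor": "Precursor",
    "run": "Run",
    "ms_level": "MsLevel",
    "intensity": "Intensity",
    "ms1_intensity": "Ms1Quantity",
    "ms2_intensity": "Ms2Quantity",
    "group": "Condition",
    "replicate": "Replicate",
}

#: Internal long-format schema of a PrecursorQuantSet.
QUANT_COLUMNS = ["protein_id", "precursor_id", "run_id", "ms_level", "intensity", "is_missing"]
KEY_COLUMNS = ["protein_id", "precursor_id", "run_id", "ms_level"]

RESULT_COLUMNS = [
    "protein_id", "method", "contrast", "log2fc",
    "statistic", "df", "p_value", "adj_p_value",
]

VALID_METHODS = ("ms1", "ms2", "combined")


def _sniff_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrecursorQuantSet:
    """Long table of per-precursor intensities on both MS levels.

    Parameters
    ----------
    data : DataFrame with columns ``protein_id, precursor_id, run_id,
        ms_level, intensity, is_missing``; the key (first four columns) is
        unique.
    scale : ``"linear"`` or ``"log2"`` — scale of the ``intensity`` column.
    centered : True once per-(precursor, level) median centering has been
        applied (the combined-model workflow).
    """

    data: pd.DataFrame
    scale: str = "linear"
    centered: bool = False

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ConfigurationError(f"unknown intensity scale {self.scale!r}")
        missing_cols = [c for c in QUANT_COLUMNS if c not in self.data.columns]
        if missing_cols:
            raise ConfigurationError(f"quant table lacks internal columns {missing_cols}")
        levels = set(self.data["ms_level"].unique())
        if not levels <= {1, 2}:
            raise DataError(f"ms_level must be 1 or 2, found {sorted(levels - {1, 2})}")
        dup = self.data.duplicated(subset=KEY_COLUMNS)
        if dup.any():
            first = self.data.loc[dup.idxmax(), KEY_COLUMNS].tolist()
            raise DataError(
                "duplicate (protein, precursor, run, ms_level) key, first offender: "
                f"{tuple(first)}"
            )
        ok = self.data["is_missing"] | self.data["intensity"].notna()
        if not ok.all():
            raise DataError("non-missing record without an intensity value")
        if self.scale == "linear":
            vals = self.data.loc[~self.data["is_missing"], "intensity"]
            if (vals < 0).any():
                raise DataError("negative linear-scale intensity")

    # -- convenience accessors ------------------------------------------------
    @property
    def n_records(self) -> int:
        return len(self.data)

    @property
    def n_missing(self) -> int:
        return int(self.data["is_missing"].sum())

    @property
    def proteins(self) -> list[str]:
        return sorted(self.data["protein_id"].unique())

    @property
    def runs(self) -> list[str]:
        return sorted(self.data["run_id"].unique())

    def with_data(self, data: pd.DataFrame, **kwargs) -> "PrecursorQuantSet":
        """Return a copy carrying ``data`` (and any overridden flags)."""
        out = replace(self, data=data.reset_index(drop=True))
        return replace(out, **kwargs) if kwargs else out


#: A PrecursorQuantSet whose values are X′ = X − median over runs; the
#: ``centered`` flag distinguishes it at run time.
CenteredQuantSet = PrecursorQuantSet


@dataclass(frozen=True)
class DesignTable:
    """Run → (group, replicate) mapping defining G groups × R replicates."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["run_id", "group", "replicate"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ConfigurationError(f"design table lacks columns {missing}")
        if self.data["run_id"].duplicated().any():
            dup = self.data.loc[self.data["run_id"].duplicated(), "run_id"].iloc[0]
            raise DataError(f"duplicate run_id in design: {dup!r}")
        if self.data.duplicated(subset=["group", "replicate"]).any():
            raise DataError("duplicate (group, replicate) pair in design")
        if len(self.data) == 0:
            raise DataError("empty design table")

    @property
    def runs(self) -> list[str]:
        return list(self.data["run_id"])

    @property
    def groups(self) -> list[str]:
        # first-appearance order, stable across calls
        return list(dict.fromkeys(self.data["group"]))

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def replicate_counts(self) -> pd.Series:
        return self.data.groupby("group", sort=False)["run_id"].count()

    @property
    def is_balanced(self) -> bool:
        return self.replicate_counts.nunique() == 1

    @property
    def is_testable(self) -> bool:
        """At least two groups — a one-group design supports no comparison."""
        return self.n_groups >= 2

    def subset_groups(self, groups: Iterable[str]) -> "DesignTable":
        keep = list(groups)
        sub = self.data[self.data["group"].isin(keep)]
        if sub.empty:
            raise DataError(f"no runs left after restricting to groups {keep}")
        return DesignTable(sub.reset_index(drop=True))

    def subset_replicates(self, max_replicate: int) -> "DesignTable":
        """Keep replicates with index ≤ ``max_replicate`` in every group."""
        sub = self.data[self.data["replicate"] <= max_replicate]
        if sub.empty:
            raise DataError(f"no runs left with replicate <= {max_replicate}")
        return DesignTable(sub.reset_index(drop=True))


@dataclass(frozen=True)
class GroundTruthTable:
    """Which proteins truly change, and (optionally) their true log2 FC."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["protein_id", "is_changed"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ConfigurationError(f"ground-truth table lacks columns {missing}")
        if self.data["protein_id"].duplicated().any():
            raise DataError("duplicate protein_id in ground truth")
        if "true_log2fc" in self.data.columns:
            bad = self.data["true_log2fc"].notna() & ~self.data["is_changed"]
            if bad.any():
                raise DataError("true_log2fc present for unchanged protein(s)")

    @property
    def changed(self) -> set[str]:
        return set(self.data.loc[self.data["is_changed"], "protein_id"])

    @property
    def proteins(self) -> set[str]:
        return set(self.data["protein_id"])


@dataclass(frozen=True)
class TestResultTable:
    """Per-protein differential-abundance test results.

    ``df1`` is the numerator df of an F test (NaN for t tests); ``df2`` the
    denominator/t df. ``untestable`` lists proteins that could not be tested
    (degenerate data) together with the reason; they are excluded from the BH
    family.
    """

    __test__ = False  # "Test" here means hypothesis test, not pytest

    data: pd.DataFrame
    untestable: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["protein_id", "method", "reason"])
    )

    def __post_init__(self) -> None:
        required = ["protein_id", "method", "contrast", "log2fc",
                    "statistic", "df1", "df2", "p_value", "adj_p_value"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ConfigurationError(f"result table lacks columns {missing}")
        bad_method = set(self.data["method"]) - set(VALID_METHODS)
        if bad_method:
            raise DataError(f"unknown method label(s) {sorted(bad_method)}")
        for col in ("p_value", "adj_p_value"):
            vals = self.data[col].to_numpy(float)
            if len(vals) and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
                raise DataError(f"{col} outside [0, 1]")

    @property
    def n_results(self) -> int:
        return len(self.data)

    def family(self, method: str, contrast: str) -> pd.DataFrame:
        """One (method, contrast) BH family."""
        mask = (self.data["method"] == method) & (self.data["contrast"] == contrast)
        return self.data[mask].reset_index(drop=True)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_quant_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    scale: str = "linear",
    design: DesignTable | None = None,
    delimiter: str | None = None,
) -> PrecursorQuantSet:
    """Read a long (or wide MS1/MS2) quantification export.

    ``column_map`` maps standard roles (see :data:`ROLE_DEFAULTS`) to the
    file's column names. A file is treated as wide when it has the two
    per-level intensity columns instead of (``ms_level``, ``intensity``);
    wide rows are melted into two long records. Empty or NaN intensity cells
    become ``is_missing=True`` records. Duplicate keys are an error — never
    silently aggregated.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"quant file not found: {path}")
    roles = dict(ROLE_DEFAULTS)
    roles.update(column_map or {})

    raw = pd.read_csv(path, sep=_sniff_delimiter(path, delimiter), dtype=str,
                      keep_default_na=False, encoding="utf-8")

    for role in ("protein", "precursor", "run"):
        if roles[role] not in raw.columns:
            raise ConfigurationError(
                f"required column for role {role!r} ({roles[role]!r}) not in file"
            )

    wide = roles["ms1_intensity"] in raw.columns and roles["ms2_intensity"] in raw.columns
    long_ok = roles["ms_level"] in raw.columns and roles["intensity"] in raw.columns
    if not wide and not long_ok:
        raise ConfigurationError(
            "file is neither long (ms_level + intensity columns) nor wide "
            "(Ms1Quantity + Ms2Quantity columns)"
        )

    if wide and not long_ok:
        melted = raw.melt(
            id_vars=[roles["protein"], roles["precursor"], roles["run"]],
            value_vars=[roles["ms1_intensity"], roles["ms2_intensity"]],
            var_name="_levelcol", value_name="_intensity",
        )
        melted["_ms_level"] = np.where(melted["_levelcol"] == roles["ms1_intensity"], 1, 2)
        df = pd.DataFrame({
            "protein_id": melted[roles["protein"]],
            "precursor_id": melted[roles["precursor"]],
            "run_id": melted[roles["run"]],
            "ms_level": melted["_ms_level"],
            "_raw_intensity": melted["_intensity"],
        })
    else:
        df = pd.DataFrame({
            "protein_id": raw[roles["protein"]],
            "precursor_id": raw[roles["precursor"]],
            "run_id": raw[roles["run"]],
            "ms_level": pd.to_numeric(raw[roles["ms_level"]], errors="raise").astype(int),
            "_raw_intensity": raw[roles["intensity"]],
        })

    stripped = df["_raw_intensity"].astype(str).str.strip()
    empty = stripped.isin(["", "nan", "NaN", "NA"])
    parsed = pd.to_numeric(stripped.where(~empty), errors="coerce")
    unparseable = parsed.isna() & ~empty
    if unparseable.any():
        bad = stripped[unparseable].iloc[0]
        raise DataError(f"intensity cell not parseable as a number: {bad!r}")
    df["intensity"] = parsed
    df["is_missing"] = empty | parsed.isna()
    df = df.drop(columns="_raw_intensity")

    dup = df.duplicated(subset=KEY_COLUMNS)
    if dup.any():
        first = df.loc[dup.idxmax(), KEY_COLUMNS].tolist()
        raise DataError(f"duplicate quant key {tuple(first)} in {path.name}")

    quant = PrecursorQuantSet(df.reset_index(drop=True), scale=scale)
    if design is not None:
        unknown = set(quant.data["run_id"]) - set(design.runs)
        if unknown:
            raise DataError(f"run(s) absent from the design table: {sorted(unknown)}")
    return quant


def read_design(path: str | Path, delimiter: str | None = None) -> DesignTable:
    """Read and validate a run → (group, replicate) design table."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"design file not found: {path}")
    raw = pd.read_csv(path, sep=_sniff_delimiter(path, delimiter), encoding="utf-8")
    rename = {}
    for want, aliases in {
        "run_id": ("run_id", "Run", "run"),
        "group": ("group", "Condition", "condition"),
        "replicate": ("replicate", "Replicate"),
    }.items():
        for alias in aliases:
            if alias in raw.columns:
                rename[alias] = want
                break
        else:
            raise ConfigurationError(f"design table lacks a {want!r} column")
    df = raw.rename(columns=rename)[["run_id", "group", "replicate"]].copy()
    df["run_id"] = df["run_id"].astype(str)
    df["group"] = df["group"].astype(str)
    df["replicate"] = df["replicate"].astype(int)
    design = DesignTable(df)
    logger.info(
        "design: %d runs, %d group(s) %s, balanced=%s, testable=%s",
        len(df), design.n_groups, design.groups, design.is_balanced, design.is_testable,
    )
    if not design.is_testable:
        logger.warning("design has a single group — no differential test is possible")
    return design


def read_ground_truth(path: str | Path, delimiter: str | None = None) -> GroundTruthTable:
    """Read a ground-truth table (protein_id, is_changed[, true_log2fc])."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"ground-truth file not found: {path}")
    raw = pd.read_csv(path, sep=_sniff_delimiter(path, delimiter), encoding="utf-8")
    if "protein_id" not in raw.columns or "is_changed" not in raw.columns:
        raise ConfigurationError("ground truth needs protein_id and is_changed columns")
    df = raw.copy()
    df["protein_id"] = df["protein_id"].astype(str)
    df["is_changed"] = df["is_changed"].astype(bool)
    return GroundTruthTable(df)


# ---------------------------------------------------------------------------
# result round-trip
# ---------------------------------------------------------------------------

def _format_df(df1: float, df2: float) -> str:
    if np.isnan(df1):
        return f"{df2:.12g}"
    return f"{df1:.12g}/{df2:.12g}"


def _parse_df(text: str) -> tuple[float, float]:
    parts = str(text).split("/")
    if len(parts) == 2:
        return float(parts[0]), float(parts[1])
    return np.nan, float(parts[0])


def write_results(results: TestResultTable, path: str | Path,
                  delimiter: str | None = None) -> None:
    """Write a result table as delimited text (8 columns, lossless floats).

    The two-part F df pair is serialized as ``num/den`` in the single ``df``
    column; t tests write the single df. ``repr``-precision floats make the
    write → read round trip exact.
    """
    if results.n_results == 0:
        raise DataError("refusing to write an empty result table")
    path = Path(path)
    out = results.data.copy()
    out["df"] = [_format_df(a, b) for a, b in zip(out["df1"], out["df2"])]
    out = out[RESULT_COLUMNS]
    for col in ("log2fc", "statistic", "p_value", "adj_p_value"):
        out[col] = out[col].map(lambda v: repr(float(v)))
    out.to_csv(path, sep=_sniff_delimiter(path, delimiter), index=False)


def read_results(path: str | Path, delimiter: str | None = None) -> TestResultTable:
    """Read back a table written by :func:`write_results`."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"results file not found: {path}")
    raw = pd.read_csv(path, sep=_sniff_delimiter(path, delimiter), encoding="utf-8")
    missing = [c for c in RESULT_COLUMNS if c not in raw.columns]
    if missing:
        raise ConfigurationError(f"results file lacks columns {missing}")
    parsed = raw["df"].map(_parse_df)
    raw["df1"] = [p[0] for p in parsed]
    raw["df2"] = [p[1] for p in parsed]
    raw = raw.drop(columns="df")
    raw["protein_id"] = raw["protein_id"].astype(str)
    return TestResultTable(raw)


def write_ground_truth(truth: GroundTruthTable, path: str | Path) -> None:
    truth.data.to_csv(Path(path), sep=_sniff_delimiter(Path(path), None), index=False)


def write_design(design: DesignTable, path: str | Path) -> None:
    design.data.to_csv(Path(path), sep=_sniff_delimiter(Path(path), None), index=False)


def write_quant_table(quant: PrecursorQuantSet, path: str | Path,
                      float_format: str = "%.8g") -> None:
    """Write a quant set in the canonical long layout (empty cell = missing)."""
    path = Path(path)
    out = pd.DataFrame({
        "ProteinGroup": quant.data["protein_id"],
        "Precursor": quant.data["precursor_id"],
        "Run": quant.data["run_id"],
        "MsLevel": quant.data["ms_level"],
        "Intensity": quant.data["intensity"].where(~quant.data["is_missing"]),
    })
    out.to_csv(path, sep=_sniff_delimiter(path, None), index=False,
               float_format=float_format, na_rep="")
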