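"""Benchmarking metrics: CVs, MS1-MS2 correlation, TP curves, confusion counts.

These reproduce the standard spike-in benchmark readouts: per-condition
precursor CVs with the 20% reporting threshold, the per-precursor Pearson
correlation between the MS1 and MS2 run profiles, candidate-list
true-positive curves with Top-N cuts (Top200 for spike-in-style truth,
Top2000 for proteome-mixture-style truth), confusion counts at an FDR
threshold, and fold-change estimation accuracy against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .quant_io import DesignTable, GroundTruthTable, PrecursorQuantSet

#: Top-N defaults by benchmark style.
TOP_N_SPIKE_IN = 200
TOP_N_PROTEOME_MIX = 2000


@dataclass(frozen=True)
class CvTable:
    """Per (precursor, MS level, group) coefficient of variation.

    CVs are sd/mean on the LINEAR intensity scale with the sample (n−1)
    standard deviation; cells with < 2 values or non-positive mean are
    omitted (``n_omitted``).
    """

    data: pd.DataFrame          # protein_id, precursor_id, ms_level, group, cv
    n_omitted: int


@dataclass(frozen=True)
class CvSummary:
    counts: pd.DataFrame        # ms_level, group, n_below
    medians: pd.Series          # median CV per ms_level
    threshold: float


@dataclass(frozen=True)
class CorrelationResult:
    """Per-precursor Pearson r between MS1 and MS2 log2 run profiles."""

    data: pd.DataFrame          # protein_id, precursor_id, r
    median: float
    n_omitted: int


@dataclass(frozen=True)
class TpCurve:
    """Cumulative true positives along the ranked candidate list."""

    method: str
    contrast: str
    proteins: list[str]         # ranked order
    tp_cumulative: np.ndarray   # TP(k) for k = 1..len(proteins)
    top_n: int

    @property
    def tp_at_top_n(self) -> int:
        if len(self.tp_cumulative) == 0:
            return 0
        k = min(self.top_n, len(self.tp_cumulative))
        return int(self.tp_cumulative[k - 1])


@dataclass(frozen=True)
class Confusion:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def empirical_fdr(self) -> float:
        return self.fp / max(1, self.fp + self.tp)

    @property
    def sensitivity(self) -> float:
        pos = self.tp + self.fn
        return self.tp / pos if pos else np.nan

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def compute_cv(quant: PrecursorQuantSet, design: DesignTable) -> CvTable:
    """Within-condition CV per precursor, separately per MS level."""
    if quant.scale != "linear":
        raise DataError("CVs are defined on linear intensities; de-transform first")
    df = quant.data[~quant.data["is_missing"]].merge(
        design.data[["run_id", "group"]], on="run_id", how="inner")
    g = df.groupby(["protein_id", "precursor_id", "ms_level", "group"], sort=False)
    agg = g["intensity"].agg(["count", "mean", "std"]).reset_index()
    ok = (agg["count"] >= 2) & (agg["mean"] > 0)
    out = agg[ok].copy()
    out["cv"] = out["std"] / out["mean"]
    out = out.drop(columns=["count", "mean", "std"]).reset_index(drop=True)
    return CvTable(out, n_omitted=int((~ok).sum()))


def count_cv_below(cvs: CvTable, threshold: float = 0.20) -> CvSummary:
    """Count precursors with CV strictly below the threshold, per level/group."""
    df = cvs.data
    below = df[df["cv"] < threshold]
    counts = (below.groupby(["ms_level", "group"], sort=False).size()
              .rename("n_below").reset_index())
    # include empty cells as zero counts
    all_cells = df[["ms_level", "group"]].drop_duplicates()
    counts = all_cells.merge(counts, on=["ms_level", "group"], how="left")
    counts["n_below"] = counts["n_below"].fillna(0).astype(int)
    medians = df.groupby("ms_level")["cv"].median()
    return CvSummary(counts.reset_index(drop=True), medians, threshold)


def ms1_ms2_correlation(quant: PrecursorQuantSet, min_runs: int = 3) -> CorrelationResult:
    """Pearson r between each precursor's MS1 and MS2 log2 profiles."""
    if quant.scale != "log2":
        raise DataError("profile correlation is computed on log2 intensities")
    df = quant.data[~quant.data["is_missing"]]
    wide = df.pivot_table(index=["protein_id", "precursor_id", "run_id"],
                          columns="ms_level", values="intensity", aggfunc="first")
    wide = wide.dropna().reset_index()
    if wide.empty or not {1, 2} <= set(wide.columns[3:]):
        return CorrelationResult(
            pd.DataFrame(columns=["protein_id", "precursor_id", "r"]), np.nan, 0)
    g = wide.groupby(["protein_id", "precursor_id"], sort=False)
    stats = g.agg(n=(1, "size"),
                  m1=(1, "mean"), m2=(2, "mean"),
                  s1=(1, "std"), s2=(2, "std"))
    prod = (wide[1] * wide[2]).groupby(
        [wide["protein_id"], wide["precursor_id"]], sort=False).mean()
    stats["cov"] = (prod - stats["m1"] * stats["m2"]) * stats["n"] / (stats["n"] - 1)
    enough = stats["n"] >= min_runs
    nonzero = (stats["s1"] > 0) & (stats["s2"] > 0)
    ok = enough & nonzero
    out = stats[ok].reset_index()
    out["r"] = out["cov"] / (out["s1"] * out["s2"])
    out = out[["protein_id", "precursor_id", "r"]]
    median = float(out["r"].median()) if len(out) else np.nan
    return CorrelationResult(out, median, n_omitted=int((enough & ~nonzero).sum()))


def _check_truth_coverage(results: pd.DataFrame, truth: GroundTruthTable) -> None:
    missing = set(results["protein_id"]) - truth.proteins
    if missing:
        raise DataError(f"protein(s) absent from the ground truth: {sorted(missing)[:10]}")


def _one_family(results, method: str | None, contrast: str | None) -> pd.DataFrame:
    """Extract a single (method, contrast) family from a result table."""
    df = results.data if hasattr(results, "data") else results
    if method is not None:
        df = df[df["method"] == method]
    if contrast is not None:
        df = df[df["contrast"] == contrast]
    if df.empty:
        raise DataError("no results in the requested (method, contrast) family")
    if df["method"].nunique() > 1 or df["contrast"].nunique() > 1:
        raise DataError("result slice spans several (method, contrast) families; "
                        "pass method=/contrast= to select one")
    return df.reset_index(drop=True)


def rank_candidates(family: pd.DataFrame, top_n: int,
                    preselect_by_adjusted: bool = True) -> pd.DataFrame:
    """Rank a candidate list the way the benchmark reads it.

    Two-step: preselect the ``top_n`` proteins with the smallest adjusted
    p-values, then sort that list by raw p-value. Ties (common at the
    p-value floor) break by larger |log2fc| first, then protein_id.
    Set ``preselect_by_adjusted=False`` for a plain raw-p ranking.
    """
    fam = family.copy()
    fam["_abs_fc"] = fam["log2fc"].abs()
    if preselect_by_adjusted:
        pre = fam.sort_values(
            ["adj_p_value", "_abs_fc", "protein_id"],
            ascending=[True, False, True], kind="mergesort").head(top_n)
    else:
        pre = fam
    ranked = pre.sort_values(
        ["p_value", "_abs_fc", "protein_id"],
        ascending=[True, False, True], kind="mergesort")
    return ranked.drop(columns="_abs_fc").reset_index(drop=True)


def tp_curve(results, truth: GroundTruthTable, top_n: int = TOP_N_SPIKE_IN,
             method: str | None = None, contrast: str | None = None,
             preselect_by_adjusted: bool = True) -> TpCurve:
    """Cumulative-true-positive curve over the ranked candidate list."""
    fam = _one_family(results, method, contrast)
    _check_truth_coverage(fam, truth)
    ranked = rank_candidates(fam, top_n, preselect_by_adjusted)
    changed = truth.changed
    hits = ranked["protein_id"].isin(changed).to_numpy()
    return TpCurve(
        method=str(fam["method"].iloc[0]), contrast=str(fam["contrast"].iloc[0]),
        proteins=list(ranked["protein_id"]),
        tp_cumulative=np.cumsum(hits), top_n=top_n,
    )


def confusion_at_threshold(results, truth: GroundTruthTable, alpha: float = 0.05,
                           use_adjusted: bool = True,
                           method: str | None = None,
                           contrast: str | None = None) -> Confusion:
    """Confusion counts for calls at ``(adj_)p < alpha``."""
    fam = _one_family(results, method, contrast)
    _check_truth_coverage(fam, truth)
    pcol = "adj_p_value" if use_adjusted else "p_value"
    called = fam[pcol] < alpha
    changed = fam["protein_id"].isin(truth.changed)
    return Confusion(
        tp=int((called & changed).sum()), fp=int((called & ~changed).sum()),
        tn=int((~called & ~changed).sum()), fn=int((~called & changed).sum()),
    )


def fold_change_accuracy(results, truth: GroundTruthTable,
                         method: str | None = None,
                         contrast: str | None = None) -> tuple[pd.DataFrame, dict]:
    """Per-protein (estimated − true) log2 FC for the truly changed proteins.

    The truth's ``true_log2fc`` must refer to the same group pair as the
    selected contrast. Returns the per-protein error table and a summary
    (median error, IQR, median absolute error).
    """
    fam = _one_family(results, method, contrast)
    _check_truth_coverage(fam, truth)
    if "true_log2fc" not in truth.data.columns:
        raise DataError("ground truth carries no true_log2fc column")
    changed = truth.data[truth.data["is_changed"]]
    if changed["true_log2fc"].isna().any():
        raise DataError("true_log2fc missing for changed protein(s)")
    merged = fam.merge(changed[["protein_id", "true_log2fc"]], on="protein_id",
                       how="inner")
    merged["error"] = merged["log2fc"] - merged["true_log2fc"]
    err = merged["error"]
    summary = {
        "n": int(len(err)),
        "median_error": float(err.median()) if len(err) else np.nan,
        "iqr": float(err.quantile(0.75) - err.quantile(0.25)) if len(err) else np.nan,
        "median_abs_error": float(err.abs().median()) if len(err) else np.nan,
    }
    return merged[["protein_id", "log2fc", "true_log2fc", "error"]], summary
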