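"""Transformation, filtering, normalization, centering and summarization.

The model-ready inputs are built in the order the workflows use them:

linear intensities → MS1 detection floor → log2 → (optional global-median
normalization) → complete-case precursor filter → either

* per-level protein summarization (uncentered ``Z_irg``, one-way ANOVA
  workflows), or
* per-precursor median centering (``X′_iprg = X_iprg − median_rg X_iprg``)
  followed by summarization (``Z′_irg``, combined-model workflow).

All operations are pure: they return new containers and never mutate their
inputs. Median convention: the even-count median is the midpoint of the two
central order statistics (numpy's default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .errors import DataError
from .quant_io import CenteredQuantSet, DesignTable, PrecursorQuantSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProteinRunMatrix:
    """Protein-level summaries, one value per (protein, run, MS level).

    ``data`` columns: ``protein_id, run_id, ms_level, value``. ``centered``
    records whether values are precursor-centered (``Z′``) or raw (``Z``).
    """

    data: pd.DataFrame
    centered: bool

    @property
    def proteins(self) -> list[str]:
        return list(dict.fromkeys(self.data["protein_id"]))

    def for_protein(self, protein_id: str) -> pd.DataFrame:
        return self.data[self.data["protein_id"] == protein_id].reset_index(drop=True)


class FilterResult(NamedTuple):
    """Complete-case filter outcome: the filtered set plus bookkeeping."""

    quant: PrecursorQuantSet
    n_kept: int
    n_removed: int


def log2_transform(quant: PrecursorQuantSet) -> PrecursorQuantSet:
    """log2 every non-missing linear intensity; guard against re-application."""
    if quant.scale != "linear":
        raise DataError("log2_transform expects linear-scale input (already log2?)")
    vals = quant.data["intensity"]
    nonpos = (~quant.data["is_missing"]) & (vals <= 0)
    if nonpos.any():
        raise DataError(
            "non-positive linear intensity present; floor such values to missing "
            "before the log2 transform"
        )
    df = quant.data.copy()
    df.loc[~df["is_missing"], "intensity"] = np.log2(vals[~df["is_missing"]])
    return quant.with_data(df, scale="log2")


def apply_ms1_floor(quant: PrecursorQuantSet, floor: float = 100.0) -> PrecursorQuantSet:
    """Mark MS1 intensities strictly below the detection floor as missing.

    The default floor of 100 (linear scale) reflects the detection limit of
    the MS1 signal; values exactly at the floor are retained, MS2 records
    are never touched.
    """
    if quant.scale != "linear":
        raise DataError("the MS1 floor applies to linear-scale intensities")
    df = quant.data.copy()
    hit = (df["ms_level"] == 1) & (~df["is_missing"]) & (df["intensity"] < floor)
    df.loc[hit, "is_missing"] = True
    df.loc[hit, "intensity"] = np.nan
    if hit.any():
        logger.info("MS1 floor %.3g: %d record(s) set missing", floor, int(hit.sum()))
    return quant.with_data(df)


def filter_complete_precursors(quant: PrecursorQuantSet, design: DesignTable) -> FilterResult:
    """Keep precursors observed at both MS levels in every design run.

    A precursor with any missing MS1 or MS2 value over all the runs is
    dropped entirely. Idempotent.
    """
    n_runs = len(design.runs)
    df = quant.data
    present = df[~df["is_missing"] & df["run_id"].isin(design.runs)]
    counts = present.groupby(["protein_id", "precursor_id"], sort=False).size()
    complete = counts[counts == 2 * n_runs].index
    n_total = df.groupby(["protein_id", "precursor_id"], sort=False).ngroups
    keep = pd.MultiIndex.from_frame(df[["protein_id", "precursor_id"]]).isin(complete)
    out = quant.with_data(df[keep])
    n_kept = len(complete)
    return FilterResult(out, n_kept=n_kept, n_removed=n_total - n_kept)


def remove_proteins(quant: PrecursorQuantSet,
                    blocklist: Iterable[str],
                    precursors: bool = False) -> PrecursorQuantSet:
    """Drop every record of the blocklisted proteins (or precursors).

    Used for shared peptides between proteomes and for spike-in proteins
    that interfere with the background; the blocklist is caller-supplied.
    Unknown ids are ignored with a warning.
    """
    block = set(blocklist)
    if not block:
        return quant
    col = "precursor_id" if precursors else "protein_id"
    known = set(quant.data[col].unique())
    unknown = block - known
    if unknown:
        logger.warning("blocklist ids not present in the data: %s", sorted(unknown))
    mask = quant.data[col].isin(block)
    logger.info("removed %d record(s) for %d blocklisted %s(s)",
                int(mask.sum()), len(block & known), col[:-3])
    return quant.with_data(quant.data[~mask])


def normalize_global_median(quant: PrecursorQuantSet,
                            reference_proteins: Iterable[str] | None = None
                            ) -> PrecursorQuantSet:
    """Equalize per-run medians of a reference protein set, per MS level.

    For each level separately, every run is shifted by
    ``grand median − run median``, both medians taken over the reference
    records (housekeeping proteins when given, otherwise all proteins — the
    plain global-median normalization). Within-run differences are
    untouched; only a per-(run, level) constant moves.
    """
    if quant.scale != "log2":
        raise DataError("global-median normalization operates on log2 intensities")
    refs = set(reference_proteins) if reference_proteins is not None else None
    df = quant.data.copy()
    for level in (1, 2):
        level_mask = (df["ms_level"] == level) & ~df["is_missing"]
        if not level_mask.any():
            continue
        ref_mask = level_mask if refs is None else level_mask & df["protein_id"].isin(refs)
        runs_at_level = set(df.loc[level_mask, "run_id"])
        ref = df[ref_mask]
        run_medians = ref.groupby("run_id")["intensity"].median()
        uncovered = runs_at_level - set(run_medians.index)
        if uncovered:
            raise DataError(
                f"run(s) without reference-protein records at MS{level}: {sorted(uncovered)}"
            )
        grand = ref["intensity"].median()
        offsets = grand - run_medians
        df.loc[level_mask, "intensity"] = (
            df.loc[level_mask, "intensity"]
            + df.loc[level_mask, "run_id"].map(offsets).astype(float)
        )
    return quant.with_data(df)


def center_precursors(quant: PrecursorQuantSet) -> CenteredQuantSet:
    """Per (precursor, level), subtract the median across all runs.

    Produces ``X′_iprg = X_iprg − median_rg{X_iprg}`` — each precursor
    profile has zero median at each level, which makes MS1 and MS2 values of
    the same precursor directly comparable in the combined model. Requires
    complete-case data (filter first).
    """
    if quant.scale != "log2":
        raise DataError("centering operates on log2 intensities")
    if quant.data["is_missing"].any():
        raise DataError("missing values remain; apply filter_complete_precursors first")
    df = quant.data.copy()
    med = df.groupby(["protein_id", "precursor_id", "ms_level"], sort=False)[
        "intensity"].transform("median")
    df["intensity"] = df["intensity"] - med
    return quant.with_data(df, centered=True)


def restrict_to_design(quant: PrecursorQuantSet, design: DesignTable) -> PrecursorQuantSet:
    """Keep only records whose run appears in the design (for subsetting)."""
    return quant.with_data(quant.data[quant.data["run_id"].isin(design.runs)])


def preprocess_pipeline(quant: PrecursorQuantSet, design: DesignTable,
                        ms1_floor: float = 100.0,
                        normalize: bool = True,
                        reference_proteins: Iterable[str] | None = None,
                        blocklist: Iterable[str] | None = None) -> FilterResult:
    """The standard chain: blocklist → floor → log2 → normalize → filter.

    Returns the complete-case filtered, log2-scale set ready for
    ``run_workflow`` plus the filter counts.
    """
    quant = restrict_to_design(quant, design)
    if blocklist:
        quant = remove_proteins(quant, blocklist)
    if quant.scale == "linear":
        quant = apply_ms1_floor(quant, floor=ms1_floor)
        quant = log2_transform(quant)
    if normalize:
        quant = normalize_global_median(quant, reference_proteins)
    return filter_complete_precursors(quant, design)


def summarize_protein(quant: PrecursorQuantSet, design: DesignTable) -> ProteinRunMatrix:
    """Median over precursors per (protein, run, level): ``Z`` or ``Z′``.

    The centered flag of the input propagates to the output. Proteins whose
    precursors do not cover every design run are dropped with a warning (a
    complete-case-filtered input never triggers this).
    """
    if quant.data["is_missing"].any():
        raise DataError("missing values remain; apply filter_complete_precursors first")
    df = quant.data[quant.data["run_id"].isin(design.runs)]
    summ = (df.groupby(["protein_id", "run_id", "ms_level"], sort=False)["intensity"]
            .median().rename("value").reset_index())
    n_runs = len(design.runs)
    cover = summ.groupby("protein_id", sort=False).size()
    full = cover[cover == 2 * n_runs].index
    dropped = set(cover.index) - set(full)
    if dropped:
        logger.warning("dropping %d protein(s) without full run coverage: %s",
                       len(dropped), sorted(dropped)[:5])
        summ = summ[summ["protein_id"].isin(full)]
    return ProteinRunMatrix(summ.reset_index(drop=True), centered=quant.centered)
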