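"""Shared fixtures: small designs, hand-built quant sets, a demo simulation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dianova.quant_io import DesignTable, PrecursorQuantSet
from dianova.simulate import SimConfig

#: Config of the committed text fixture under tests/data/fixture (seed 42).
FIXTURE_CONFIG = SimConfig(
    n_proteins=20, fraction_changed=0.25, precursors_per_protein=(2, 3),
    groups={"A": 0.0, "B": 1.0}, replicates_per_group=3,
    baseline_log2_mean=14.0, baseline_log2_spread=1.5,
    sigma_bio=0.3, sigma_ms1=0.2, sigma_ms2=0.2,
    interference_prob=0.1, interference_max_fraction=1.0, seed=42,
)


def make_design(groups: dict[str, int]) -> DesignTable:
    """Design with the given per-group replicate counts; runs named g_Rr."""
    rows = [(f"{g}_R{r}", g, r) for g, n in groups.items() for r in range(1, n + 1)]
    return DesignTable(pd.DataFrame(rows, columns=["run_id", "group", "replicate"]))


def make_quant(records, scale="linear", centered=False) -> PrecursorQuantSet:
    """Build a quant set from (protein, precursor, run, level, intensity) tuples.

    ``intensity=None`` marks a missing record.
    """
    rows = []
    for prot, prec, run, level, val in records:
        rows.append((prot, prec, run, level,
                     np.nan if val is None else float(val), val is None))
    df = pd.DataFrame(rows, columns=["protein_id", "precursor_id", "run_id",
                                     "ms_level", "intensity", "is_missing"])
    return PrecursorQuantSet(df, scale=scale, centered=centered)


def complete_quant(values: dict, scale="log2", centered=False) -> PrecursorQuantSet:
    """Quant set from {(protein, precursor): {run: (ms1, ms2)}} mappings."""
    records = []
    for (prot, prec), runs in values.items():
        for run, (v1, v2) in runs.items():
            records.append((prot, prec, run, 1, v1))
            records.append((prot, prec, run, 2, v2))
    return make_quant(records, scale=scale, centered=centered)


@pytest.fixture(scope="session")
def design_2x3() -> DesignTable:
    return make_design({"A": 3, "B": 3})


@pytest.fixture(scope="session")
def design_3x4() -> DesignTable:
    return make_design({"g1": 4, "g2": 4, "g3": 4})
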