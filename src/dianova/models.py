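"""The three differential-abundance models and the testing workflow.

Per protein, on the summarized values:

* MS1-only / MS2-only — one-way ANOVA on the per-level protein summaries::

      Z_irg = mu + Group_ig + eps_irg,   sum_g Group_ig = 0,
      eps_irg ~ N(0, sigma_i^2)

  Omnibus F = MS_Group / MS_Error on (G-1, N-G) df; pairwise contrasts are
  t tests on the same error stratum.

* Combined — both MS levels enter as technical replicates of the same run,
  with a nested random replicate (run) effect::

      Z'_irg = mu + MS_i + Group_g + Replicate_r(g) + eps_irg,
      Replicate_r(g) ~ N(0, sigma_R^2),   eps_irg ~ N(0, sigma^2)

  On balanced designs the fit is the closed-form nested ANOVA: the Group
  test uses MS_Rep(Group) as its denominator — runs, not individual
  level-observations, are the experimental units — with df (G-1, G(R-1));
  method-of-moments variance components are ``sigma^2 = MS_Error`` and
  ``sigma_R^2 = max(0, (MS_Rep(Group) - MS_Error)/2)`` (two observations
  per run, one per MS level). Unbalanced designs fall back to a REML fit of
  the same model (statsmodels ``MixedLM``) with containment df
  ``sum_g (R_g - 1)`` for contrasts, which coincides with the balanced df.

p-values are BH-adjusted per (method, contrast) family across proteins;
degenerate proteins (no residual information) are flagged untestable and
excluded from the family rather than given p = 1.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .errors import DataError
from .preprocess import ProteinRunMatrix, center_precursors, summarize_protein
from .quant_io import DesignTable, PrecursorQuantSet, TestResultTable

logger = logging.getLogger(__name__)

#: Reported p-value for zero-residual perfect separation: the smallest
#: positive double, never exactly 0 (the event is "below resolution").
P_FLOOR = float(np.nextafter(0, 1))


# ---------------------------------------------------------------------------
# fitted-model containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SingleLevelFit:
    """One-way ANOVA fit of a single MS level for one protein."""

    protein_id: str
    ms_level: int
    group_labels: tuple[str, ...]
    group_means: np.ndarray          # per-group fitted means
    n_per_group: np.ndarray
    mu: float                        # grand (observation) mean
    group_effects: np.ndarray        # sum-to-zero deviations
    ms_group: float
    ms_error: float
    df_group: float
    df_error: float
    f_stat: float
    p_value: float
    sigma2: float                    # = MS_Error
    untestable: bool = False
    reason: str | None = None
    perfect_separation: bool = False

    @property
    def cov_group_means(self) -> np.ndarray:
        return np.diag(self.ms_error / self.n_per_group)

    @property
    def df_contrast(self) -> float:
        return self.df_error


@dataclass(frozen=True)
class CombinedFit:
    """Nested two-level (MS1+MS2) mixed-model fit for one protein."""

    protein_id: str
    group_labels: tuple[str, ...]
    group_means: np.ndarray
    n_runs_per_group: np.ndarray
    mu: float
    ms_effects: np.ndarray           # MS_i deviations, sum to zero
    group_effects: np.ndarray        # Group_g deviations, sum to zero
    sigma_r2: float                  # run-level (replicate) variance
    sigma2: float                    # residual per-level variance
    ms_group: float
    ms_rep: float
    ms_error: float
    df_group: float
    df_rep: float
    df_error: float
    f_stat: float
    p_value: float
    truncated: bool = False          # sigma_r2 moment estimate clipped at 0
    reml: bool = False               # unbalanced fallback used
    untestable: bool = False
    reason: str | None = None
    perfect_separation: bool = False
    cov_group_means_: np.ndarray | None = field(default=None, repr=False)

    @property
    def cov_group_means(self) -> np.ndarray:
        if self.cov_group_means_ is not None:
            return self.cov_group_means_
        # balanced: group means are independent with Var = E[MS_Rep]/(2 R_g)
        return np.diag(self.ms_rep / (2.0 * self.n_runs_per_group))

    @property
    def df_contrast(self) -> float:
        return self.df_rep


# ---------------------------------------------------------------------------
# vectorized sums-of-squares engines (one row per protein)
# ---------------------------------------------------------------------------

def _group_design(design: DesignTable) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """One-hot run→group matrix, per-group run counts, group order."""
    groups = design.groups
    gindex = {g: k for k, g in enumerate(groups)}
    codes = np.array([gindex[g] for g in design.data["group"]])
    m = np.zeros((len(codes), len(groups)))
    m[np.arange(len(codes)), codes] = 1.0
    return m, m.sum(axis=0), groups


def _oneway_arrays(y: np.ndarray, m: np.ndarray, n_g: np.ndarray) -> dict:
    """One-way ANOVA pieces for Y of shape (n_proteins, n_runs)."""
    n, n_groups = y.shape[1], m.shape[1]
    grand = y.mean(axis=1)
    means = (y @ m) / n_g
    ssb = ((means - grand[:, None]) ** 2 * n_g).sum(axis=1)
    ssw = np.maximum((y ** 2).sum(axis=1) - (means ** 2 * n_g).sum(axis=1), 0.0)
    df_b, df_w = n_groups - 1.0, n - n_groups
    with np.errstate(divide="ignore", invalid="ignore"):
        ms_b, ms_w = ssb / df_b, ssw / max(df_w, 1e-300)
        f = np.where(ssw > 0, ms_b / np.where(ms_w > 0, ms_w, np.nan), np.inf)
    return dict(grand=grand, means=means, ssb=ssb, ssw=ssw,
                ms_group=ms_b, ms_error=ms_w, df_group=df_b, df_error=df_w, f=f)


def _combined_arrays(y1: np.ndarray, y2: np.ndarray,
                     m: np.ndarray, n_g: np.ndarray) -> dict:
    """Nested two-level ANOVA pieces for paired (n_proteins, n_runs) arrays."""
    n, n_groups = y1.shape[1], m.shape[1]
    run_means = 0.5 * (y1 + y2)
    grand = run_means.mean(axis=1)
    lev1, lev2 = y1.mean(axis=1), y2.mean(axis=1)
    gmeans = (run_means @ m) / n_g
    ss_level = n * ((lev1 - grand) ** 2 + (lev2 - grand) ** 2)
    ss_group = 2.0 * ((gmeans - grand[:, None]) ** 2 * n_g).sum(axis=1)
    ss_rep = 2.0 * ((run_means - gmeans @ m.T) ** 2).sum(axis=1)
    ss_total = ((y1 - grand[:, None]) ** 2 + (y2 - grand[:, None]) ** 2).sum(axis=1)
    ss_err = np.maximum(ss_total - ss_level - ss_group - ss_rep, 0.0)
    df_group, df_rep, df_err = n_groups - 1.0, n - n_groups, n - 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ms_group = ss_group / df_group
        ms_rep = ss_rep / max(df_rep, 1e-300)
        ms_err = ss_err / df_err
        f = np.where(ss_rep > 0, ms_group / np.where(ms_rep > 0, ms_rep, np.nan), np.inf)
    sigma2 = ms_err
    sigma_r2 = (ms_rep - ms_err) / 2.0
    truncated = sigma_r2 < 0
    sigma_r2 = np.maximum(sigma_r2, 0.0)
    return dict(grand=grand, means=gmeans, lev1=lev1, lev2=lev2,
                ms_group=ms_group, ms_rep=ms_rep, ms_error=ms_err,
                ss_group=ss_group, ss_rep=ss_rep, ss_err=ss_err, ss_level=ss_level,
                df_group=df_group, df_rep=df_rep, df_error=df_err,
                f=f, sigma2=sigma2, sigma_r2=sigma_r2, truncated=truncated)


def _f_pvalue(f: np.ndarray, df1: float, df2: float) -> np.ndarray:
    p = np.where(np.isinf(f), P_FLOOR, stats.f.sf(np.where(np.isfinite(f), f, 1.0), df1, df2))
    return p


# ---------------------------------------------------------------------------
# per-protein fits (public API; the workflow uses the same engines)
# ---------------------------------------------------------------------------

def _matrix_to_arrays(matrix: ProteinRunMatrix, design: DesignTable,
                      ms_level: int) -> tuple[list[str], np.ndarray]:
    """Pivot one level into a (protein × design-run) array; error on gaps."""
    sub = matrix.data[matrix.data["ms_level"] == ms_level]
    if sub.empty:
        raise DataError(f"no MS{ms_level} values in the protein matrix")
    piv = sub.pivot(index="protein_id", columns="run_id", values="value")
    missing_runs = [r for r in design.runs if r not in piv.columns]
    if missing_runs:
        raise DataError(f"run(s) absent from the protein matrix: {missing_runs}")
    piv = piv.loc[:, design.runs]
    if piv.isna().any().any():
        raise DataError("protein matrix has missing (protein, run) cells")
    # preserve first-appearance protein order
    order = list(dict.fromkeys(sub["protein_id"]))
    piv = piv.loc[order]
    return order, piv.to_numpy(float)


def fit_single_level(matrix: ProteinRunMatrix, design: DesignTable,
                     ms_level: int) -> SingleLevelFit:
    """One-way ANOVA for a single protein's summaries at one MS level."""
    proteins, y = _matrix_to_arrays(matrix, design, ms_level)
    if len(proteins) != 1:
        raise DataError("fit_single_level expects a single-protein matrix")
    m, n_g, groups = _group_design(design)
    return _build_single_fits(proteins, y, m, n_g, groups, ms_level)[0]


def _build_single_fits(proteins, y, m, n_g, groups, ms_level) -> list[SingleLevelFit]:
    st = _oneway_arrays(y, m, n_g)
    fits = []
    for k, pid in enumerate(proteins):
        untestable, reason, perfect = False, None, False
        f, p = st["f"][k], np.nan
        if len(groups) < 2:
            untestable, reason = True, "fewer than two groups"
        elif st["df_error"] < 1:
            untestable, reason = True, "zero residual degrees of freedom"
        elif st["ssw"][k] <= 0 and st["ssb"][k] <= 0:
            untestable, reason = True, "constant values"
        elif st["ssw"][k] <= 0:
            perfect, f, p = True, np.inf, P_FLOOR
        else:
            p = float(stats.f.sf(f, st["df_group"], st["df_error"]))
        fits.append(SingleLevelFit(
            protein_id=pid, ms_level=ms_level, group_labels=tuple(groups),
            group_means=st["means"][k], n_per_group=n_g, mu=float(st["grand"][k]),
            group_effects=st["means"][k] - st["means"][k].mean(),
            ms_group=float(st["ms_group"][k]), ms_error=float(st["ms_error"][k]),
            df_group=float(st["df_group"]), df_error=float(st["df_error"]),
            f_stat=float(f), p_value=float(p) if not untestable else np.nan,
            sigma2=float(st["ms_error"][k]),
            untestable=untestable, reason=reason, perfect_separation=perfect,
        ))
    return fits


def fit_combined(matrix: ProteinRunMatrix, design: DesignTable) -> CombinedFit:
    """Nested mixed-model fit of both MS levels for a single protein.

    Balanced designs use the closed-form nested ANOVA; unbalanced designs
    are re-fit by REML of the identical model.
    """
    proteins1, y1 = _matrix_to_arrays(matrix, design, 1)
    proteins2, y2 = _matrix_to_arrays(matrix, design, 2)
    if proteins1 != proteins2:
        raise DataError("MS1 and MS2 protein sets differ in the matrix")
    if len(proteins1) != 1:
        raise DataError("fit_combined expects a single-protein matrix")
    m, n_g, groups = _group_design(design)
    if design.is_balanced:
        return _build_combined_fits(proteins1, y1, y2, m, n_g, groups)[0]
    return _fit_combined_reml(proteins1[0], y1[0], y2[0], design)


def _build_combined_fits(proteins, y1, y2, m, n_g, groups) -> list[CombinedFit]:
    st = _combined_arrays(y1, y2, m, n_g)
    fits = []
    for k, pid in enumerate(proteins):
        untestable, reason, perfect = False, None, False
        f, p = st["f"][k], np.nan
        if len(groups) < 2:
            untestable, reason = True, "fewer than two groups"
        elif st["df_rep"] < 1:
            untestable, reason = True, "no replicate-level denominator (R=1)"
        elif st["ss_rep"][k] <= 0 and st["ss_group"][k] <= 0:
            untestable, reason = True, "constant values"
        elif st["ss_rep"][k] <= 0:
            perfect, f, p = True, np.inf, P_FLOOR
        else:
            p = float(stats.f.sf(f, st["df_group"], st["df_rep"]))
        grand = float(st["grand"][k])
        fits.append(CombinedFit(
            protein_id=pid, group_labels=tuple(groups),
            group_means=st["means"][k], n_runs_per_group=n_g, mu=grand,
            ms_effects=np.array([st["lev1"][k] - grand, st["lev2"][k] - grand]),
            group_effects=st["means"][k] - st["means"][k].mean(),
            sigma_r2=float(st["sigma_r2"][k]), sigma2=float(st["sigma2"][k]),
            ms_group=float(st["ms_group"][k]), ms_rep=float(st["ms_rep"][k]),
            ms_error=float(st["ms_error"][k]),
            df_group=float(st["df_group"]), df_rep=float(st["df_rep"]),
            df_error=float(st["df_error"]),
            f_stat=float(f), p_value=float(p) if not untestable else np.nan,
            truncated=bool(st["truncated"][k]),
            untestable=untestable, reason=reason, perfect_separation=perfect,
        ))
    return fits


def fit_combined_all(matrix: ProteinRunMatrix, design: DesignTable) -> list[CombinedFit]:
    """Combined-model fits for every protein in the matrix at once.

    Balanced designs use the vectorized closed form; unbalanced designs
    fall back to per-protein REML.
    """
    proteins, y1 = _matrix_to_arrays(matrix, design, 1)
    proteins2, y2 = _matrix_to_arrays(matrix, design, 2)
    if proteins != proteins2:
        raise DataError("MS1 and MS2 protein sets differ in the matrix")
    m, n_g, groups = _group_design(design)
    if design.is_balanced:
        return _build_combined_fits(proteins, y1, y2, m, n_g, groups)
    return [_fit_combined_reml(pid, y1[k], y2[k], design)
            for k, pid in enumerate(proteins)]


def _fit_combined_reml(protein_id: str, y1: np.ndarray, y2: np.ndarray,
                       design: DesignTable) -> CombinedFit:
    """REML fallback for unbalanced designs (same model, containment df)."""
    groups = design.groups
    n_groups = len(groups)
    run_groups = list(design.data["group"])
    n_runs = len(run_groups)
    n_g = np.array([run_groups.count(g) for g in groups], float)
    df_rep = float(n_runs - n_groups)
    if n_groups < 2 or df_rep < 1:
        return CombinedFit(
            protein_id=protein_id, group_labels=tuple(groups),
            group_means=np.full(n_groups, np.nan), n_runs_per_group=n_g,
            mu=np.nan, ms_effects=np.full(2, np.nan),
            group_effects=np.full(n_groups, np.nan),
            sigma_r2=np.nan, sigma2=np.nan, ms_group=np.nan, ms_rep=np.nan,
            ms_error=np.nan, df_group=n_groups - 1.0, df_rep=df_rep,
            df_error=np.nan, f_stat=np.nan, p_value=np.nan, reml=True,
            untestable=True, reason="untestable design for the combined model",
        )

    # stacked observations: level 1 block then level 2 block
    endog = np.concatenate([y1, y2])
    level_col = np.concatenate([np.ones(n_runs), -np.ones(n_runs)])
    gidx = {g: k for k, g in enumerate(groups)}
    codes = np.array([gidx[g] for g in run_groups])
    # sum-to-zero (effects) coding, last group as -1 row
    eff = np.zeros((n_runs, n_groups - 1))
    for j in range(n_groups - 1):
        eff[codes == j, j] = 1.0
    eff[codes == n_groups - 1, :] = -1.0
    exog = np.column_stack([np.ones(2 * n_runs), level_col, np.vstack([eff, eff])])
    run_ids = np.tile(np.arange(n_runs), 2)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(endog, exog, groups=run_ids)
        result = model.fit(reml=True, method="lbfgs")

    n_fe = exog.shape[1]
    fe = np.asarray(result.fe_params, float)
    cov_fe = np.asarray(result.cov_params())[:n_fe, :n_fe]
    mu, level_eff = fe[0], fe[1]
    e = fe[2:]
    effects = np.append(e, -e.sum())
    group_means = mu + effects
    # covariance of the full effect vector via the (G-1)->G completion map
    a = np.vstack([np.eye(n_groups - 1), -np.ones(n_groups - 1)])
    cov_eff = a @ cov_fe[2:, 2:] @ a.T

    sigma_r2 = float(np.asarray(result.cov_re)[0, 0])
    sigma2 = float(result.scale)

    # Wald F for the group effects on the containment (replicate-stratum) df
    cov_e = cov_fe[2:, 2:]
    try:
        chi2 = float(e @ np.linalg.solve(cov_e, e))
    except np.linalg.LinAlgError:
        chi2 = np.nan
    f_stat = chi2 / (n_groups - 1)
    p = float(stats.f.sf(f_stat, n_groups - 1, df_rep)) if np.isfinite(f_stat) else np.nan

    return CombinedFit(
        protein_id=protein_id, group_labels=tuple(groups),
        group_means=group_means, n_runs_per_group=n_g, mu=float(mu),
        ms_effects=np.array([level_eff, -level_eff]),
        group_effects=effects,
        sigma_r2=sigma_r2, sigma2=sigma2,
        ms_group=np.nan, ms_rep=np.nan, ms_error=np.nan,
        df_group=n_groups - 1.0, df_rep=df_rep, df_error=np.nan,
        f_stat=float(f_stat), p_value=p, reml=True,
        cov_group_means_=cov_eff,
    )


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

def _t_row(est: float, var: float, df: float) -> tuple[float, float]:
    if var <= 0:
        if est == 0:
            return 0.0, 1.0
        return float(np.sign(est) * np.inf), P_FLOOR
    t = est / np.sqrt(var)
    return float(t), float(2.0 * stats.t.sf(abs(t), df))


def test_contrast(fit: SingleLevelFit | CombinedFit, group_a: str, group_b: str) -> dict:
    """Model-based pairwise contrast (log2 FC of ``group_a`` over ``group_b``).

    Single level: SE^2 = MS_Error (1/R_a + 1/R_b), df = N - G.
    Combined, balanced: SE^2 = MS_Rep(Group) (1/(2R_a) + 1/(2R_b)), df = G(R-1)
    — Var(diff) = (2 sigma_R^2 + sigma^2)/R = E[MS_Rep]/R on a balanced pair.
    """
    labels = list(fit.group_labels)
    for g in (group_a, group_b):
        if g not in labels:
            raise DataError(f"group {g!r} not in the fitted design {labels}")
    method = "combined" if isinstance(fit, CombinedFit) else f"ms{fit.ms_level}"
    contrast = f"{group_a}_vs_{group_b}"
    if fit.untestable:
        return dict(protein_id=fit.protein_id, method=method, contrast=contrast,
                    log2fc=np.nan, statistic=np.nan, df1=np.nan, df2=np.nan,
                    p_value=np.nan, untestable=True, reason=fit.reason)
    ia, ib = labels.index(group_a), labels.index(group_b)
    est = float(fit.group_means[ia] - fit.group_means[ib])
    cov = fit.cov_group_means
    var = float(cov[ia, ia] + cov[ib, ib] - 2.0 * cov[ia, ib])
    t, p = _t_row(est, var, fit.df_contrast)
    return dict(protein_id=fit.protein_id, method=method, contrast=contrast,
                log2fc=est, statistic=t, df1=np.nan, df2=float(fit.df_contrast),
                p_value=p, untestable=False, reason=None)


test_contrast.__test__ = False  # statistical test, not a pytest item


def omnibus_test(fit: SingleLevelFit | CombinedFit) -> dict:
    """Omnibus F test for any group effect (log2fc reported as 0)."""
    method = "combined" if isinstance(fit, CombinedFit) else f"ms{fit.ms_level}"
    if fit.untestable:
        return dict(protein_id=fit.protein_id, method=method, contrast="omnibus",
                    log2fc=np.nan, statistic=np.nan, df1=np.nan, df2=np.nan,
                    p_value=np.nan, untestable=True, reason=fit.reason)
    df2 = fit.df_contrast
    return dict(protein_id=fit.protein_id, method=method, contrast="omnibus",
                log2fc=0.0, statistic=float(fit.f_stat), df1=float(fit.df_group),
                df2=float(df2), p_value=float(fit.p_value),
                untestable=False, reason=None)


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or p.min() < 0 or p.max() > 1:
        raise DataError("p-values must lie in [0, 1] with no NaN")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# end-to-end workflow
# ---------------------------------------------------------------------------

def _resolve_contrasts(contrasts, groups: list[str]) -> tuple[list[tuple[str, str]], bool]:
    """Normalize a contrast spec into (pair list, include_omnibus)."""
    if contrasts == "all-pairs":
        return list(itertools.combinations(groups, 2)), False
    if contrasts == "omnibus":
        return [], True
    if contrasts == "both":
        return list(itertools.combinations(groups, 2)), True
    pairs = []
    for item in contrasts:
        if isinstance(item, str):
            a, b = item.split("_vs_")
        else:
            a, b = item
        if a not in groups or b not in groups:
            raise DataError(f"contrast ({a!r}, {b!r}) names an unknown group")
        pairs.append((a, b))
    return pairs, False


def run_workflow(quant: PrecursorQuantSet, design: DesignTable, method: str,
                 contrasts="all-pairs") -> TestResultTable:
    """Summarize, fit, test and BH-adjust every protein for one method.

    ``quant`` must be preprocessed: log2 scale, complete cases (floored,
    filtered, normalized upstream). For ``method="combined"`` the precursor
    centering step is applied here when the input is not yet centered.
    ``contrasts`` is ``"all-pairs"`` (default), ``"omnibus"``, ``"both"``,
    or an explicit list of group pairs. BH adjustment runs per
    (method, contrast) family over the testable proteins.
    """
    if method not in ("ms1", "ms2", "combined"):
        raise DataError(f"unknown method {method!r}")
    if quant.scale != "log2":
        raise DataError("run_workflow expects log2-scale input")
    if quant.data["is_missing"].any():
        raise DataError("missing values present; run the complete-case filter first")

    empty = pd.DataFrame(columns=["protein_id", "method", "contrast", "log2fc",
                                  "statistic", "df1", "df2", "p_value", "adj_p_value"])
    if not design.is_testable:
        untestable = pd.DataFrame({
            "protein_id": quant.proteins, "method": method,
            "reason": "single-group design",
        })
        return TestResultTable(empty, untestable=untestable)

    m, n_g, groups = _group_design(design)
    pairs, include_omnibus = _resolve_contrasts(contrasts, groups)

    if method == "combined":
        source = quant if quant.centered else center_precursors(quant)
        matrix = summarize_protein(source, design)
        fits = fit_combined_all(matrix, design)
    else:
        if quant.centered:
            raise DataError("single-level workflows use uncentered summaries")
        matrix = summarize_protein(quant, design)
        level = 1 if method == "ms1" else 2
        proteins, y = _matrix_to_arrays(matrix, design, level)
        fits = _build_single_fits(proteins, y, m, n_g, groups, level)

    rows: list[dict] = []
    for fit in fits:
        if include_omnibus:
            rows.append(omnibus_test(fit))
        for a, b in pairs:
            rows.append(test_contrast(fit, a, b))

    table = pd.DataFrame(rows)
    untestable = (table[table["untestable"]]
                  .drop_duplicates("protein_id")[["protein_id", "method", "reason"]]
                  .reset_index(drop=True))
    testable = table[~table["untestable"]].drop(columns=["untestable", "reason"])

    if testable.empty:
        return TestResultTable(empty, untestable=untestable)

    adjusted = []
    for _, fam in testable.groupby("contrast", sort=False):
        fam = fam.copy()
        fam["adj_p_value"] = adjust_bh(fam["p_value"].to_numpy())
        adjusted.append(fam)
    out = pd.concat(adjusted, ignore_index=True)
    n_unt = len(untestable)
    if n_unt:
        logger.info("%s: %d untestable protein(s) excluded from BH", method, n_unt)
    return TestResultTable(out, untestable=untestable)
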