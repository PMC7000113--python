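"""Synthetic dual-level DIA data with known ground truth.

The generative model mirrors the structure the combined model assumes, plus
the two nuisance features that motivate it:

* per protein: a log2 baseline abundance, and (for truly changed proteins)
  per-group log2 spike factors — a spike-in concentration series;
* per biological replicate run: a shared random effect applied to BOTH MS
  levels (maps to ``sigma_R``);
* per precursor: an ionization-efficiency offset shared across runs, and a
  constant MS1-vs-MS2 level offset (what the combined model's ``MS_i`` term
  absorbs after centering);
* per (precursor, run, level): independent Gaussian measurement noise with
  level-specific sd (``sigma_ms1``, ``sigma_ms2``);
* sparse multiplicative interference, independent between MS1 and MS2: with
  probability ``interference_prob`` a cell's LINEAR intensity is multiplied
  by ``1 + U``, ``U ~ Uniform(0, interference_max_fraction)`` — coeluting
  signal only ever inflates an extracted ion current;
* an MS1 detection floor: linear MS1 intensities strictly below
  ``ms1_floor`` are recorded as missing.

One ``numpy`` Generator seeded from ``SimConfig.seed`` drives everything;
draws happen in a fixed documented order (changed-protein selection →
baselines → precursor counts → precursor offsets → level offsets →
replicate effects → measurement noise → interference), so identical configs
give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .quant_io import (DesignTable, GroundTruthTable, PrecursorQuantSet,
                       write_design, write_ground_truth, write_quant_table)

#: UPS2 spike-in concentration series (amol/ul) for samples S1..S5.
SPIKE_IN_CONCENTRATIONS = (0.75, 0.83, 1.07, 2.04, 7.54)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic dual-level dataset.

    All abundance parameters are on the log2 scale except the linear
    ``ms1_floor`` and the multiplicative ``interference_max_fraction``.
    """

    n_proteins: int = 1000
    fraction_changed: float = 0.10
    precursors_per_protein: tuple[int, int] = (3, 8)
    #: group label → log2 spike factor applied to changed proteins
    groups: dict = field(default_factory=lambda: {"A": 0.0, "B": 1.0})
    replicates_per_group: int = 5
    baseline_log2_mean: float = 16.0
    baseline_log2_spread: float = 2.0
    precursor_offset_spread: float = 1.0
    level_offset_spread: float = 1.0
    sigma_bio: float = 0.3          # run-level biological sd (maps to sigma_R)
    sigma_ms1: float = 0.2          # MS1 measurement sd
    sigma_ms2: float = 0.2          # MS2 measurement sd
    interference_prob: float = 0.1
    interference_max_fraction: float = 1.0
    #: which MS levels receive interference (both by default; (2,) emulates
    #: a clean-MS1 / contaminated-MS2 acquisition)
    interference_levels: tuple[int, ...] = (1, 2)
    ms1_floor: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.replicates_per_group < 1:
            raise ConfigurationError("need at least one protein and one replicate")
        if not 0 <= self.fraction_changed <= 1:
            raise ConfigurationError("fraction_changed must lie in [0, 1]")
        if not 0 <= self.interference_prob <= 1:
            raise ConfigurationError("interference_prob must lie in [0, 1]")
        lo, hi = self.precursors_per_protein
        if lo < 1 or hi < lo:
            raise ConfigurationError("precursors_per_protein must be (min>=1, max>=min)")
        for name in ("baseline_log2_spread", "precursor_offset_spread",
                     "level_offset_spread", "sigma_bio", "sigma_ms1", "sigma_ms2",
                     "interference_max_fraction"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if len(self.groups) < 1:
            raise ConfigurationError("at least one group is required")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["precursors_per_protein"] = list(self.precursors_per_protein)
        d["interference_levels"] = list(self.interference_levels)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        for key in ("precursors_per_protein", "interference_levels"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class SimOutput:
    """A simulated dataset plus the latent values that generated it."""

    quant: PrecursorQuantSet        # linear scale, MS1 floor applied
    design: DesignTable
    truth: GroundTruthTable         # true_log2fc = last group vs first group
    latent: dict                    # group_shifts, rep_effects, interference masks
    config: SimConfig

    def truth_for_contrast(self, group_a: str, group_b: str) -> GroundTruthTable:
        """Ground truth with true_log2fc for an arbitrary group pair."""
        shifts = self.latent["group_shifts"]
        fc = shifts[group_a] - shifts[group_b]
        changed = self.truth.data["is_changed"].to_numpy()
        return GroundTruthTable(pd.DataFrame({
            "protein_id": shifts.index,
            "is_changed": changed,
            "true_log2fc": np.where(changed, fc, np.nan),
        }))


def simulate_dataset(config: SimConfig) -> SimOutput:
    """Generate one dataset under ``config`` (deterministic given the seed)."""
    rng = np.random.default_rng(config.seed)
    n_prot = config.n_proteins
    groups = list(config.groups)
    spikes = np.array([config.groups[g] for g in groups], float)
    n_groups, reps = len(groups), config.replicates_per_group
    n_runs = n_groups * reps

    prot_ids = np.array([f"P{k:05d}" for k in range(1, n_prot + 1)])
    n_changed = int(round(config.fraction_changed * n_prot))
    changed_idx = rng.choice(n_prot, size=n_changed, replace=False)
    is_changed = np.zeros(n_prot, bool)
    is_changed[changed_idx] = True

    baselines = rng.normal(config.baseline_log2_mean, config.baseline_log2_spread, n_prot)

    lo, hi = config.precursors_per_protein
    prec_counts = rng.integers(lo, hi + 1, n_prot)
    n_prec = int(prec_counts.sum())
    prot_of_prec = np.repeat(np.arange(n_prot), prec_counts)
    prec_ids = np.array([
        f"{prot_ids[i]}_p{j + 1}"
        for i, c in enumerate(prec_counts) for j in range(int(c))
    ])

    prec_offsets = rng.normal(0.0, config.precursor_offset_spread, n_prec)
    level_offsets = rng.normal(0.0, config.level_offset_spread, n_prec)

    # design: groups in config order, replicates 1..R within each
    run_group_idx = np.repeat(np.arange(n_groups), reps)
    run_ids = np.array([f"{groups[g]}_R{r + 1}"
                        for g in range(n_groups) for r in range(reps)])
    design = DesignTable(pd.DataFrame({
        "run_id": run_ids,
        "group": [groups[g] for g in run_group_idx],
        "replicate": np.tile(np.arange(1, reps + 1), n_groups),
    }))

    rep_effects = rng.normal(0.0, config.sigma_bio, (n_prot, n_runs))

    group_shift = np.where(is_changed[:, None], spikes[None, :], 0.0)  # (prot, G)
    true_run_profile = baselines[:, None] + group_shift[:, run_group_idx] \
        + rep_effects  # (prot, runs)
    cell_base = true_run_profile[prot_of_prec] + prec_offsets[:, None]  # (prec, runs)

    log2_vals, masks = {}, {}
    for level, sd, off_sign in ((1, config.sigma_ms1, +0.5), (2, config.sigma_ms2, -0.5)):
        noise = rng.normal(0.0, sd, (n_prec, n_runs))
        log2_vals[level] = cell_base + off_sign * level_offsets[:, None] + noise
    for level in (1, 2):
        mask = rng.random((n_prec, n_runs)) < config.interference_prob
        u = rng.uniform(0.0, config.interference_max_fraction, (n_prec, n_runs))
        if level not in config.interference_levels:
            mask = np.zeros_like(mask)
        linear = np.exp2(log2_vals[level])
        linear = linear * (1.0 + np.where(mask, u, 0.0))
        log2_vals[level] = linear      # now linear scale
        masks[level] = mask

    frames = []
    for level in (1, 2):
        linear = log2_vals[level]
        missing = (linear < config.ms1_floor) if level == 1 else np.zeros_like(linear, bool)
        frames.append(pd.DataFrame({
            "protein_id": np.repeat(prot_ids[prot_of_prec], n_runs),
            "precursor_id": np.repeat(prec_ids, n_runs),
            "run_id": np.tile(run_ids, n_prec),
            "ms_level": level,
            "intensity": np.where(missing, np.nan, linear).ravel(),
            "is_missing": missing.ravel(),
        }))
    long = pd.concat(frames, ignore_index=True)
    long = long.sort_values(["protein_id", "precursor_id", "run_id", "ms_level"],
                            kind="mergesort").reset_index(drop=True)
    quant = PrecursorQuantSet(long, scale="linear")

    shifts_df = pd.DataFrame(group_shift, index=prot_ids, columns=groups)
    true_fc = group_shift[:, -1] - group_shift[:, 0]
    truth = GroundTruthTable(pd.DataFrame({
        "protein_id": prot_ids,
        "is_changed": is_changed,
        "true_log2fc": np.where(is_changed, true_fc, np.nan),
    }))
    latent = {
        "group_shifts": shifts_df,
        "baselines": pd.Series(baselines, index=prot_ids),
        "rep_effects": pd.DataFrame(rep_effects, index=prot_ids, columns=run_ids),
        "interference_ms1": pd.DataFrame(masks[1], index=prec_ids, columns=run_ids),
        "interference_ms2": pd.DataFrame(masks[2], index=prec_ids, columns=run_ids),
    }
    return SimOutput(quant=quant, design=design, truth=truth, latent=latent,
                     config=config)


def spikein_series_config(n_background: int = 2000, n_spike: int = 48,
                          replicates_per_group: int = 5, seed: int = 0,
                          **overrides) -> SimConfig:
    """Config emulating the spike-in concentration series S1..S5.

    Five groups whose log2 spike factors follow the UPS2 concentration
    series normalized to S1 (log2 of 0.75/0.83/1.07/2.04/7.54 over 0.75),
    a small set of spiked proteins on a large unchanged background with
    biological run-to-run variation.
    """
    conc = np.array(SPIKE_IN_CONCENTRATIONS)
    factors = np.log2(conc / conc[0])
    n_total = n_background + n_spike
    cfg = dict(
        n_proteins=n_total,
        fraction_changed=n_spike / n_total,
        groups={f"S{k + 1}": float(f) for k, f in enumerate(factors)},
        replicates_per_group=replicates_per_group,
        seed=seed,
    )
    cfg.update(overrides)
    return SimConfig(**cfg)


def write_fixture(output: SimOutput, directory: str | Path) -> dict[str, Path]:
    """Write quant/design/truth plus a latent-values sidecar as TSV text.

    Regenerating with the same config (seed included) reproduces the files
    byte-identically.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "quant": directory / "quant.tsv",
        "design": directory / "design.tsv",
        "truth": directory / "truth.tsv",
        "latent_profiles": directory / "latent_profiles.tsv",
        "latent_interference": directory / "latent_interference.tsv",
        "config": directory / "config.yaml",
    }
    write_quant_table(output.quant, paths["quant"])
    write_design(output.design, paths["design"])
    write_ground_truth(output.truth, paths["truth"])

    shifts = output.latent["group_shifts"]
    profiles = (output.latent["baselines"].to_frame("baseline_log2")
                .join(shifts).reset_index(names="protein_id"))
    profiles.to_csv(paths["latent_profiles"], sep="\t", index=False,
                    float_format="%.8g")

    events = []
    for level in (1, 2):
        mask = output.latent[f"interference_ms{level}"]
        prec, run = np.nonzero(mask.to_numpy())
        events.append(pd.DataFrame({
            "precursor_id": mask.index[prec],
            "run_id": mask.columns[run],
            "ms_level": level,
        }))
    pd.concat(events, ignore_index=True).to_csv(
        paths["latent_interference"], sep="\t", index=False)
    output.config.to_yaml(paths["config"])
    return paths
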