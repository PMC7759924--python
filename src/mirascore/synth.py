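"""Synthetic matched case-control cohort and screen-matrix generator.

The generator reproduces the statistical structure the analysis assumes so
that every pipeline stage runs and is testable without patient data:

* a bivariate biomarker pair (miR-375, RASD1 normalized levels) with a
  negative target Spearman correlation, drawn from a Gaussian copula with
  log-normal marginals — the copula correlation is set by the closed form
  ρ_pearson = 2·sin(π·ρ_spearman/6), so the *population* Spearman rho equals
  the configured target;
* exponential relapse times whose hazard is multiplied by a configurable
  ratio in the MIR_HIGH stratum (miR-375 quartile above RASD1 quartile);
* administrative right censoring uniform on a follow-up window;
* an expression matrix with a planted subset of down-regulated predicted
  target genes for the pilot-screen stage.

The baseline hazard is, by default, calibrated so the marginal event fraction
matches the configured relapse:control mix (13 relapses / 40 controls in the
emulated validation cohort); see ``CohortConfig.calibrate_event_fraction``.
Every draw is deterministic for a fixed seed, and a truth record carries all
generating parameters.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .marker import BiomarkerPair, Stratum, combine
from .screen import CONTROL, RELAPSE, ExpressionMatrix, TargetListSet
from .survstats import SurvivalRecord

__all__ = [
    "CohortConfig",
    "ScreenSimConfig",
    "generate_cohort",
    "generate_screen_matrix",
    "write_cohort",
    "write_screen",
]


@dataclass(frozen=True)
class CohortConfig:
    """Generating parameters for a synthetic validation-style cohort.

    Defaults emulate the validation cohort: 53 patients with a 13/53 relapse
    mix, follow-up window 44–214 months, median time to local failure 77
    months, and a mildly negative miR-375–RASD1 rank correlation.
    """

    n_patients: int = 53
    relapse_fraction: float = 13 / 53
    spearman_rho_target: float = -0.3
    hazard_ratio_mir_high: float = 3.0
    baseline_median_relapse_months: float = 77.0
    censoring_window_months: tuple[float, float] = (44.0, 214.0)
    seed: int = 0
    #: when true (default) the baseline hazard is solved so the expected event
    #: fraction equals ``relapse_fraction`` under the censoring window; when
    #: false the latent relapse-time median is ``baseline_median_relapse_months``.
    calibrate_event_fraction: bool = True
    log_level_sd: float = 1.0  # sd of log normalized levels (log-normal marginals)

    def __post_init__(self) -> None:
        if self.n_patients < 8:
            raise ValueError("n_patients must be >= 8")
        if not 0 < self.relapse_fraction < 1:
            raise ValueError("relapse_fraction must be in (0, 1)")
        if self.relapse_fraction * self.n_patients < 1:
            raise ValueError("infeasible config: expected events < 1")
        if not -1 <= self.spearman_rho_target <= 0:
            raise ValueError("spearman_rho_target must be in [-1, 0]")
        if self.hazard_ratio_mir_high <= 0:
            raise ValueError("hazard_ratio_mir_high must be positive")
        if self.baseline_median_relapse_months <= 0:
            raise ValueError("baseline_median_relapse_months must be positive")
        a, b = self.censoring_window_months
        if not 0 < a <= b:
            raise ValueError("censoring window must satisfy 0 < low <= high")


@dataclass(frozen=True)
class ScreenSimConfig:
    """Generating parameters for a synthetic pilot-screen expression matrix."""

    n_genes: int = 2000
    n_predicted_targets: int = 150
    n_planted_down: int = 20
    effect_size_sd: float = 1.5
    n_per_group: int = 14
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_planted_down <= self.n_predicted_targets <= self.n_genes:
            raise ValueError("need n_planted_down <= n_predicted_targets <= n_genes")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def _copula_pearson(rho_spearman: float) -> float:
    """Gaussian-copula Pearson correlation giving the target population Spearman rho."""
    return 2.0 * math.sin(math.pi * rho_spearman / 6.0)


def _event_probability(lam: np.ndarray, low: float, high: float) -> np.ndarray:
    """P(Exp(lam) < Uniform(low, high)) in closed form, elementwise."""
    lam = np.asarray(lam, dtype=float)
    if high == low:
        return 1.0 - np.exp(-lam * low)
    return 1.0 - (np.exp(-lam * low) - np.exp(-lam * high)) / (lam * (high - low))


def _calibrate_baseline_hazard(
    multipliers: np.ndarray, window: tuple[float, float], target: float
) -> float:
    """Solve the baseline hazard so the mean event probability equals ``target``."""
    low, high = window

    def deficit(lam0: float) -> float:
        return float(np.mean(_event_probability(lam0 * multipliers, low, high))) - target

    return float(optimize.brentq(deficit, 1e-10, 10.0, xtol=1e-12))


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[BiomarkerPair], list[SurvivalRecord], dict]:
    """Draw one synthetic cohort: biomarker pairs, survival records, truth record.

    The marker pair is drawn from a Gaussian copula calibrated to the target
    Spearman rho and mapped to log-normal levels; the quartile-index strata
    are then formed exactly as the analysis will form them, and relapse times
    are exponential with the MIR_HIGH hazard multiplied by
    ``hazard_ratio_mir_high``.  Censoring is administrative, uniform on the
    follow-up window, so every observed time lies below its upper bound.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    rho_p = _copula_pearson(config.spearman_rho_target)
    z = rng.multivariate_normal(
        mean=[0.0, 0.0], cov=[[1.0, rho_p], [rho_p, 1.0]], size=n, method="cholesky"
    )
    levels = np.exp(config.log_level_sd * z)  # log-normal marginals, median 1
    pairs = [
        BiomarkerPair(patient_id=f"P{i + 1:03d}", mir375=float(levels[i, 0]), rasd1=float(levels[i, 1]))
        for i in range(n)
    ]

    markers = combine(pairs)
    multipliers = np.array(
        [config.hazard_ratio_mir_high if m.stratum is Stratum.MIR_HIGH else 1.0 for m in markers]
    )
    if config.calibrate_event_fraction:
        lam0 = _calibrate_baseline_hazard(
            multipliers, config.censoring_window_months, config.relapse_fraction
        )
    else:
        lam0 = math.log(2.0) / config.baseline_median_relapse_months

    relapse_time = rng.exponential(1.0 / (lam0 * multipliers))
    low, high = config.censoring_window_months
    censor_time = rng.uniform(low, high, size=n)
    observed = np.minimum(relapse_time, censor_time)
    event = (relapse_time <= censor_time).astype(int)
    records = [
        SurvivalRecord(patient_id=pairs[i].patient_id, time=float(observed[i]), event=int(event[i]))
        for i in range(n)
    ]

    truth = {
        "model": "gaussian-copula lognormal levels; exponential relapse; uniform censoring",
        "config": {**asdict(config), "censoring_window_months": list(config.censoring_window_months)},
        "copula_pearson_rho": rho_p,
        "baseline_hazard_per_month": lam0,
        "n_mir_high": int(np.sum(multipliers > 1)),
        "n_events": int(event.sum()),
    }
    return pairs, records, truth


def generate_screen_matrix(
    config: ScreenSimConfig,
) -> tuple[ExpressionMatrix, TargetListSet, set[str]]:
    """Draw one synthetic pilot-screen matrix with planted down-regulated targets.

    Null genes are i.i.d. normal noise; the planted subset of the predicted
    targets is shifted down by ``effect_size_sd × noise_sd`` in the relapse
    group.  Returns the matrix, the predicted-target list (as the truth-level
    database), and the planted gene set.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    predicted = set(rng.choice(genes, size=config.n_predicted_targets, replace=False))
    planted = set(rng.choice(sorted(predicted), size=config.n_planted_down, replace=False))

    n_rel = n_ctl = config.n_per_group
    samples = [f"R{i + 1:02d}" for i in range(n_rel)] + [f"C{i + 1:02d}" for i in range(n_ctl)]
    group = [RELAPSE] * n_rel + [CONTROL] * n_ctl
    values = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_rel + n_ctl))
    planted_idx = [i for i, g in enumerate(genes) if g in planted]
    values[np.ix_(planted_idx, range(n_rel))] -= config.effect_size_sd * config.noise_sd

    expr = ExpressionMatrix(genes=genes, samples=samples, values=values, group=group)
    targets = TargetListSet(database_name="sim_db", genes=frozenset(predicted))
    return expr, targets, planted


# ---------------------------------------------------------------------------
# file emission (same dialects the analysis stages consume)


def write_cohort(
    pairs: Sequence[BiomarkerPair],
    records: Sequence[SurvivalRecord],
    truth: dict,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write pairs.csv, survival.csv and truth.json into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pairs": outdir / "pairs.csv",
        "survival": outdir / "survival.csv",
        "truth": outdir / "truth.json",
    }
    pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in pairs],
            "mir375": [p.mir375 for p in pairs],
            "rasd1": [p.rasd1 for p in pairs],
        }
    ).to_csv(paths["pairs"], index=False, float_format="%.17g")
    pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "time_months": [r.time for r in records],
            "event": [r.event for r in records],
        }
    ).to_csv(paths["survival"], index=False, float_format="%.17g")
    paths["truth"].write_text(json.dumps(truth, indent=2))
    return paths


def write_screen(
    expr: ExpressionMatrix,
    targets: TargetListSet,
    planted: set[str],
    outdir: str | Path,
) -> dict[str, Path]:
    """Write expr.tsv, groups.csv, the target list file and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expr": outdir / "expr.tsv",
        "groups": outdir / "groups.csv",
        "targets": outdir / f"targets_{targets.database_name}.txt",
        "truth": outdir / "screen_truth.json",
    }
    pd.DataFrame(expr.values, index=expr.genes, columns=expr.samples).rename_axis("gene").to_csv(
        paths["expr"], sep="\t"
    )
    pd.DataFrame({"sample_id": expr.samples, "group": expr.group}).to_csv(
        paths["groups"], index=False
    )
    paths["targets"].write_text("\n".join(sorted(targets.genes)) + "\n")
    paths["truth"].write_text(
        json.dumps({"planted_down": sorted(planted), "database": targets.database_name}, indent=2)
    )
    return paths
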