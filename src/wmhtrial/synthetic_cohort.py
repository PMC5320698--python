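"""Synthetic mild-stroke cohorts with the statistical structure of the reference study.

The generator emulates a prospective cohort of patients with mild ischaemic
stroke followed for one year with brain MRI:

* baseline WMH volume: lognormal, moment-matched to mean 22.0 / SD 24.8 ml;
* baseline Fazekas score (0-6): ordered-logit in volume with slope
  ``log(1.21)`` per ml, cutpoints calibrated so the marginal category
  frequencies match the observed cohort;
* cardiovascular covariates: age, mean arterial pressure (MAP) and pulse
  pressure (PP, drawn jointly), and five binary risk factors at the observed
  prevalences;
* follow-up volume: linear in the ten baseline predictors with the published
  adjusted coefficients, Gaussian noise resampled until nonnegative; the
  intercept and residual SD are solved at calibration time so the mean 1-year
  progression is 1.27 ml and the model R-squared is 0.90;
* informative dropout: logistic in age and baseline Fazekas, calibrated to a
  28% overall rate and a 5.7-year age gap between completers and dropouts,
  with reasons assigned at the observed frequencies.

Everything is driven by a single integer seed; identical config + seed gives
bitwise-identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit

from .exceptions import (
    CalibrationError,
    ConfigurationError,
    DataError,
    DomainError,
)

__all__ = [
    "GeneratorConfig",
    "CohortTable",
    "COHORT_COLUMNS",
    "DROPOUT_REASONS",
    "TABLE_ADJUSTED_COEFS",
    "FAZEKAS_TARGET_PROPORTIONS",
    "lognormal_params_from_moments",
    "default_config",
    "calibrate_config",
    "validate_config",
    "calibrate_cutpoints",
    "expected_category_probs",
    "assign_fazekas",
    "generate_cohort",
    "simulate_followup",
    "apply_dropout",
    "generate_full_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
]

# Adjusted 1-year progression coefficients (ml of follow-up volume per unit
# of predictor) from the reference multivariable model.
TABLE_ADJUSTED_COEFS: dict[str, float] = {
    "baseline_volume": 0.73,
    "fazekas": 2.93,
    "map": -0.10,
    "pp": 0.03,
    "hypertension": -1.40,
    "age": -0.02,
    "subtype": -0.85,
    "smoking": 0.17,
    "diabetes": -1.98,
    "hyperlipidaemia": -1.10,
}

#: Observed baseline Fazekas 0-6 marginal proportions (percent, renormalised
#: when used as calibration targets).
FAZEKAS_TARGET_PROPORTIONS = (4.2, 9.0, 36.8, 12.6, 15.3, 9.0, 13.2)

#: Dropout reasons with their observed frequencies among the 74 non-completers
#: (declined 33, unwell 24, died 5, other 6, incomplete scan 6).
DROPOUT_REASONS = ("declined", "unwell", "died", "other", "incomplete_scan")
_REASON_PROBS = np.array([33, 24, 5, 6, 6], dtype=float) / 74.0

COHORT_COLUMNS = [
    "patient_id",
    "age",
    "map",
    "pp",
    "sbp",
    "dbp",
    "hypertension",
    "diabetes",
    "smoker",
    "hyperlipidaemia",
    "subtype",
    "wmh_baseline",
    "fazekas_baseline",
    "wmh_followup",
    "fazekas_followup",
    "dropout",
    "dropout_reason",
]

# Columns backing each named progression coefficient.
_COEF_COLUMNS = {
    "baseline_volume": "wmh_baseline",
    "fazekas": "fazekas_baseline",
    "map": "map",
    "pp": "pp",
    "hypertension": "hypertension",
    "age": "age",
    "subtype": "subtype",
    "smoking": "smoker",
    "diabetes": "diabetes",
    "hyperlipidaemia": "hyperlipidaemia",
}

_CALIBRATION_SEED = 739_421  # internal stream for calibration draws only
_CALIBRATION_N = 200_000


def lognormal_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Log-scale (mu, sigma) of a lognormal with the given mean and SD."""
    if mean <= 0 or sd <= 0:
        raise DomainError("mean and sd must be positive")
    cv2 = (sd / mean) ** 2
    sigma2 = math.log1p(cv2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


_VOL_LOG_MEAN, _VOL_LOG_SD = lognormal_params_from_moments(22.0, 24.8)


@dataclass(frozen=True)
class GeneratorConfig:
    """All parameters of the synthetic-cohort generator.

    Fields left as ``None`` (cutpoints, progression intercept/residual SD,
    dropout intercept/age coefficient) are solved by :func:`calibrate_config`
    so the generated cohort hits the study's marginal targets; the numbers are
    never hard-coded.
    """

    n_patients: int = 264
    seed: int = 0
    # baseline WMH volume (ml), lognormal on the log scale
    vol_log_mean: float = _VOL_LOG_MEAN
    vol_log_sd: float = _VOL_LOG_SD
    # ordered-logit map from volume to Fazekas 0-6
    faz_slope: float = math.log(1.21)
    faz_cutpoints: tuple[float, ...] | None = None
    # 1-year progression model
    prog_coefs: Mapping[str, float] = field(
        default_factory=lambda: dict(TABLE_ADJUSTED_COEFS)
    )
    prog_intercept: float | None = None
    resid_sd: float | None = None
    # covariates
    age_mean: float = 65.3
    age_sd: float = 11.3
    map_mean: float = 102.8
    map_sd: float = 15.4
    pp_mean: float = 63.0
    pp_sd: float = 20.7
    map_pp_corr: float = 0.3
    prev_hypertension: float = 0.747
    prev_lacunar: float = 0.458
    prev_smoker: float = 0.384
    prev_diabetes: float = 0.111
    prev_hyperlipidaemia: float = 0.611
    # informative-missingness model (logistic in age and baseline Fazekas)
    dropout_intercept: float | None = None
    dropout_age_coef: float | None = None
    dropout_faz_coef: float = 0.15


def validate_config(config: GeneratorConfig, *, require_calibrated: bool = False) -> None:
    """Raise :class:`ConfigurationError` naming the first offending field."""
    if config.n_patients < 0:
        raise ConfigurationError("n_patients must be nonnegative")
    for name in ("vol_log_sd", "age_sd", "map_sd", "pp_sd"):
        if getattr(config, name) <= 0:
            raise ConfigurationError(f"{name} must be strictly positive")
    if config.resid_sd is not None and config.resid_sd < 0:
        raise ConfigurationError("resid_sd must be nonnegative")
    if not -1 <= config.map_pp_corr <= 1:
        raise ConfigurationError("map_pp_corr must lie in [-1, 1]")
    for name in (
        "prev_hypertension",
        "prev_lacunar",
        "prev_smoker",
        "prev_diabetes",
        "prev_hyperlipidaemia",
    ):
        if not 0 <= getattr(config, name) <= 1:
            raise ConfigurationError(f"{name} must lie in [0, 1]")
    if set(config.prog_coefs) != set(TABLE_ADJUSTED_COEFS):
        raise ConfigurationError(
            "prog_coefs must contain exactly the ten named predictors: "
            + ", ".join(sorted(TABLE_ADJUSTED_COEFS))
        )
    if config.faz_cutpoints is not None:
        cp = np.asarray(config.faz_cutpoints, dtype=float)
        if cp.size != 6 or np.any(np.diff(cp) <= 0):
            raise ConfigurationError("faz_cutpoints must be 6 strictly increasing values")
    if require_calibrated:
        for name in (
            "faz_cutpoints",
            "prog_intercept",
            "resid_sd",
            "dropout_intercept",
            "dropout_age_coef",
        ):
            if getattr(config, name) is None:
                raise ConfigurationError(
                    f"{name} is not set; call calibrate_config() or default_config()"
                )


# ---------------------------------------------------------------------------
# Fazekas ordered-logit machinery


def _lognormal_quadrature(
    vol_log_mean: float, vol_log_sd: float, order: int = 96
) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Hermite nodes/weights for expectations over the volume distribution."""
    x, w = np.polynomial.hermite.hermgauss(order)
    volumes = np.exp(vol_log_mean + math.sqrt(2.0) * vol_log_sd * x)
    return volumes, w / math.sqrt(math.pi)


def expected_category_probs(
    cutpoints: Sequence[float],
    faz_slope: float,
    vol_log_mean: float,
    vol_log_sd: float,
) -> np.ndarray:
    """Marginal Fazekas category probabilities implied by the latent model.

    Integrates the ordered-logit category probabilities over the lognormal
    volume distribution by Gauss-Hermite quadrature (used both for cutpoint
    calibration and as an independent oracle in tests).
    """
    volumes, weights = _lognormal_quadrature(vol_log_mean, vol_log_sd)
    cp = np.asarray(cutpoints, dtype=float)
    cum = expit(cp[None, :] - faz_slope * volumes[:, None])  # (nodes, 6)
    cum = np.concatenate([cum, np.ones((cum.shape[0], 1))], axis=1)
    probs = np.diff(np.concatenate([np.zeros((cum.shape[0], 1)), cum], axis=1), axis=1)
    return weights @ probs


def calibrate_cutpoints(
    vol_log_mean: float,
    vol_log_sd: float,
    faz_slope: float,
    target_proportions: Sequence[float],
) -> tuple[float, ...]:
    """Back-solve ordered-logit cutpoints so marginal frequencies hit the targets.

    Each cumulative probability is a strictly increasing function of its own
    cutpoint, so the six cutpoints are found by independent 1-D root-finding
    (to 1e-10 in the integral).  Targets may be rounded percentages; they are
    renormalised.  With ``faz_slope = 0`` the solution is exactly the logit of
    the cumulative targets.
    """
    targets = np.asarray(target_proportions, dtype=float)
    if targets.size != 7 or np.any(targets <= 0):
        raise CalibrationError("target_proportions must be 7 positive values")
    targets = targets / targets.sum()
    cum_targets = np.cumsum(targets)[:-1]
    volumes, weights = _lognormal_quadrature(vol_log_mean, vol_log_sd)

    def marginal_cum(c: float) -> float:
        return float(weights @ expit(c - faz_slope * volumes))

    cutpoints = []
    for q in cum_targets:
        try:
            c = optimize.brentq(lambda c: marginal_cum(c) - q, -700.0, 700.0, xtol=1e-10)
        except ValueError as err:  # pragma: no cover - pathological slopes only
            raise CalibrationError(f"cannot bracket cutpoint for cumulative target {q}") from err
        cutpoints.append(float(c))
    if np.any(np.diff(cutpoints) <= 0):
        raise CalibrationError("calibrated cutpoints are not strictly increasing")
    return tuple(cutpoints)


def assign_fazekas(
    volume: np.ndarray | float,
    config: GeneratorConfig,
    noise_draw: np.ndarray | float,
) -> np.ndarray:
    """Draw Fazekas 0-6 from the ordered-logit model given volume.

    ``noise_draw`` is uniform(0, 1); the category is the smallest k whose
    cumulative probability ``expit(c_k - slope * volume)`` exceeds it, which
    makes the draw stochastically monotone in volume for fixed noise.
    """
    if config.faz_cutpoints is None:
        raise ConfigurationError("faz_cutpoints is not set; calibrate the config first")
    vol = np.atleast_1d(np.asarray(volume, dtype=float))
    if np.any(vol < 0):
        raise DomainError("volume must be nonnegative")
    u = np.atleast_1d(np.asarray(noise_draw, dtype=float))
    cp = np.asarray(config.faz_cutpoints, dtype=float)
    cum = expit(cp[None, :] - config.faz_slope * vol[:, None])  # (n, 6)
    return (u[:, None] > cum).sum(axis=1).astype(np.int64)


# ---------------------------------------------------------------------------
# calibration of progression and dropout models


def _draw_covariates(rng: np.random.Generator, config: GeneratorConfig, n: int) -> dict[str, np.ndarray]:
    """Draw baseline covariates in a fixed order (determinism contract)."""
    age = rng.normal(config.age_mean, config.age_sd, n)
    cov = config.map_pp_corr * config.map_sd * config.pp_sd
    mean = [config.map_mean, config.pp_mean]
    cov_matrix = [[config.map_sd**2, cov], [cov, config.pp_sd**2]]
    bp = rng.multivariate_normal(mean, cov_matrix, size=n)
    # pulse pressure must be positive (sbp > dbp); redraw the joint pair
    bad = bp[:, 1] <= 0
    while bad.any():
        bp[bad] = rng.multivariate_normal(mean, cov_matrix, size=int(bad.sum()))
        bad = bp[:, 1] <= 0
    out = {
        "age": age,
        "map": bp[:, 0],
        "pp": bp[:, 1],
        "hypertension": (rng.random(n) < config.prev_hypertension).astype(np.int64),
        "diabetes": (rng.random(n) < config.prev_diabetes).astype(np.int64),
        "smoker": (rng.random(n) < config.prev_smoker).astype(np.int64),
        "hyperlipidaemia": (rng.random(n) < config.prev_hyperlipidaemia).astype(np.int64),
        "subtype": (rng.random(n) < config.prev_lacunar).astype(np.int64),
        "wmh_baseline": rng.lognormal(config.vol_log_mean, config.vol_log_sd, n),
    }
    out["fazekas_baseline"] = assign_fazekas(out["wmh_baseline"], config, rng.random(n))
    return out


def _linear_predictor(cols: Mapping[str, np.ndarray], config: GeneratorConfig) -> np.ndarray:
    lp = np.zeros_like(np.asarray(cols["wmh_baseline"], dtype=float))
    for name, coef in config.prog_coefs.items():
        lp = lp + coef * np.asarray(cols[_COEF_COLUMNS[name]], dtype=float)
    return lp


def _truncated_mean(m: np.ndarray, sd: float) -> np.ndarray:
    """Mean of Normal(m, sd) conditioned on being nonnegative (resampling scheme)."""
    from scipy.stats import norm

    a = m / sd
    # phi(a)/Phi(a) is the inverse Mills ratio at -a; clip for numerical safety
    ratio = np.exp(norm.logpdf(a) - norm.logcdf(a))
    return m + sd * ratio


def _calibrate_progression(
    config: GeneratorConfig, mean_change: float, r_squared: float
) -> tuple[float, float]:
    """Solve (intercept, residual SD) for the target mean progression and R^2.

    Works on a large fixed-seed covariate draw: the residual SD follows from
    Var(linear predictor) and the target R^2; the intercept is the root of the
    truncation-corrected expected follow-up volume minus its target.
    """
    rng = np.random.default_rng(_CALIBRATION_SEED)
    cols = _draw_covariates(rng, config, _CALIBRATION_N)
    lp = _linear_predictor(cols, config)
    sd_lp = float(np.std(lp))
    resid_sd = sd_lp * math.sqrt((1.0 - r_squared) / r_squared)
    target = float(np.mean(cols["wmh_baseline"])) + mean_change

    def gap(b0: float) -> float:
        return float(np.mean(_truncated_mean(lp + b0, resid_sd))) - target

    try:
        b0 = optimize.brentq(gap, -200.0, 200.0, xtol=1e-8)
    except ValueError as err:  # pragma: no cover
        raise CalibrationError("cannot bracket progression intercept") from err
    return float(b0), float(resid_sd)


def _calibrate_dropout(
    config: GeneratorConfig, dropout_rate: float, age_gap_years: float
) -> tuple[float, float]:
    """Solve (intercept, age coefficient) of the missingness model.

    Targets: overall dropout probability and the expected age gap (dropouts
    minus completers, in years) under selection, with the Fazekas coefficient
    held at its configured value.  Solved on the fixed calibration draw.
    """
    rng = np.random.default_rng(_CALIBRATION_SEED + 1)
    cols = _draw_covariates(rng, config, _CALIBRATION_N)
    age = cols["age"]
    faz = cols["fazekas_baseline"].astype(float)
    bf = config.dropout_faz_coef

    def equations(params: np.ndarray) -> np.ndarray:
        b0, ba = params
        p = expit(b0 + ba * age + bf * faz)
        rate = p.mean()
        age_drop = float(np.sum(p * age) / np.sum(p))
        age_keep = float(np.sum((1 - p) * age) / np.sum(1 - p))
        return np.array([rate - dropout_rate, (age_drop - age_keep) - age_gap_years])

    start = np.array(
        [logit(dropout_rate) - 0.04 * config.age_mean - bf * float(faz.mean()), 0.04]
    )
    sol = optimize.root(equations, start, method="hybr", tol=1e-12)
    if not sol.success:  # pragma: no cover
        raise CalibrationError(f"dropout calibration failed: {sol.message}")
    return float(sol.x[0]), float(sol.x[1])


def calibrate_config(
    config: GeneratorConfig,
    *,
    fazekas_targets: Sequence[float] = FAZEKAS_TARGET_PROPORTIONS,
    mean_change: float = 1.27,
    r_squared: float = 0.90,
    dropout_rate: float = 0.28,
    age_gap_years: float = 5.7,
) -> GeneratorConfig:
    """Fill every ``None`` calibration field of a config.

    The targets default to the study conditions: +1.27 ml mean 1-year
    progression, multivariable R^2 0.90, 28% dropout, and a 5.7-year age gap
    between completers and non-completers.
    """
    validate_config(config)
    if config.faz_cutpoints is None:
        config = replace(
            config,
            faz_cutpoints=calibrate_cutpoints(
                config.vol_log_mean, config.vol_log_sd, config.faz_slope, fazekas_targets
            ),
        )
    if config.prog_intercept is None or config.resid_sd is None:
        b0, resid_sd = _calibrate_progression(config, mean_change, r_squared)
        config = replace(
            config,
            prog_intercept=b0 if config.prog_intercept is None else config.prog_intercept,
            resid_sd=resid_sd if config.resid_sd is None else config.resid_sd,
        )
    if config.dropout_intercept is None or config.dropout_age_coef is None:
        b0, ba = _calibrate_dropout(config, dropout_rate, age_gap_years)
        config = replace(
            config,
            dropout_intercept=b0
            if config.dropout_intercept is None
            else config.dropout_intercept,
            dropout_age_coef=ba
            if config.dropout_age_coef is None
            else config.dropout_age_coef,
        )
    validate_config(config, require_calibrated=True)
    return config


def default_config(n_patients: int = 264, seed: int = 0, **overrides) -> GeneratorConfig:
    """A fully calibrated config at the study conditions."""
    return calibrate_config(GeneratorConfig(n_patients=n_patients, seed=seed, **overrides))


# ---------------------------------------------------------------------------
# cohort generation


@dataclass
class CohortTable:
    """An ordered patient table plus the config (and seed) that produced it."""

    data: pd.DataFrame
    config: GeneratorConfig

    def __post_init__(self) -> None:
        if list(self.data.columns) != COHORT_COLUMNS:
            raise DataError("cohort table has unexpected columns")
        if self.data["patient_id"].duplicated().any():
            raise DataError("patient_id values must be unique")

    def __len__(self) -> int:
        return len(self.data)

    def completers(self) -> pd.DataFrame:
        return self.data[self.data["dropout"] == 0]

    def non_completers(self) -> pd.DataFrame:
        return self.data[self.data["dropout"] == 1]


def _empty_frame(n: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": pd.Series([f"P{i:06d}" for i in range(n)], dtype="string"),
        }
    )


def generate_cohort(config: GeneratorConfig) -> CohortTable:
    """Draw a baseline cohort (follow-up fields empty) from a calibrated config."""
    validate_config(config, require_calibrated=True)
    n = config.n_patients
    rng = np.random.default_rng([config.seed, 0])
    cols = _draw_covariates(rng, config, n)
    df = _empty_frame(n)
    for name in ("age", "map", "pp"):
        df[name] = cols[name]
    df["sbp"] = cols["map"] + 2.0 * cols["pp"] / 3.0
    df["dbp"] = cols["map"] - cols["pp"] / 3.0
    for name in ("hypertension", "diabetes", "smoker", "hyperlipidaemia", "subtype"):
        df[name] = cols[name]
    df["wmh_baseline"] = cols["wmh_baseline"]
    df["fazekas_baseline"] = cols["fazekas_baseline"]
    df["wmh_followup"] = np.full(n, np.nan)
    df["fazekas_followup"] = np.full(n, np.nan)
    df["dropout"] = np.zeros(n, dtype=np.int64)
    df["dropout_reason"] = pd.Series(["none"] * n, dtype="string")
    return CohortTable(df[COHORT_COLUMNS], config)


def simulate_followup(cohort: CohortTable, config: GeneratorConfig | None = None) -> CohortTable:
    """Add 1-year follow-up volume and Fazekas score to a baseline cohort.

    Follow-up volume is the linear progression model plus Gaussian noise,
    resampling the noise for any patient whose draw is negative (no point
    mass at zero).  Follow-up Fazekas is drawn from the same ordered-logit
    map as baseline, so scores may regress, mirroring observed volume
    decreases.
    """
    config = cohort.config if config is None else config
    validate_config(config, require_calibrated=True)
    df = cohort.data.copy()
    baseline_cols = [c for c in COHORT_COLUMNS if c not in
                     ("patient_id", "sbp", "dbp", "wmh_followup", "fazekas_followup",
                      "dropout", "dropout_reason")]
    missing = df.index[df[baseline_cols].isna().any(axis=1)]
    if len(missing):
        raise DataError(f"baseline fields missing for rows: {list(missing[:20])}")
    n = len(df)
    if n == 0:
        return CohortTable(df, config)
    rng = np.random.default_rng([config.seed, 1])
    m = config.prog_intercept + _linear_predictor(df, config)
    sd = config.resid_sd
    if sd == 0:
        if np.any(m < 0):
            raise DomainError(
                "deterministic follow-up (resid_sd=0) would be negative for some rows"
            )
        y = m.copy()
    else:
        y = m + sd * rng.standard_normal(n)
        bad = y < 0
        tries = 0
        while bad.any():
            y[bad] = m[bad] + sd * rng.standard_normal(int(bad.sum()))
            bad = y < 0
            tries += 1
            if tries > 100_000:  # pragma: no cover
                raise CalibrationError("nonnegativity resampling failed to terminate")
    df["wmh_followup"] = y
    df["fazekas_followup"] = assign_fazekas(y, config, rng.random(n)).astype(float)
    return CohortTable(df, config)


def apply_dropout(cohort: CohortTable, config: GeneratorConfig | None = None) -> CohortTable:
    """Draw informative dropout and blank the follow-up fields of dropouts.

    The missingness probability is logistic in age and baseline Fazekas, so
    older and more WMH-burdened patients drop out more; reasons follow the
    observed multinomial frequencies.
    """
    config = cohort.config if config is None else config
    validate_config(config, require_calibrated=True)
    df = cohort.data.copy()
    n = len(df)
    if n == 0:
        return CohortTable(df, config)
    rng = np.random.default_rng([config.seed, 2])
    p = expit(
        config.dropout_intercept
        + config.dropout_age_coef * df["age"].to_numpy()
        + config.dropout_faz_coef * df["fazekas_baseline"].to_numpy(dtype=float)
    )
    dropped = rng.random(n) < p
    reasons = np.full(n, "none", dtype=object)
    n_drop = int(dropped.sum())
    if n_drop:
        reasons[dropped] = rng.choice(DROPOUT_REASONS, size=n_drop, p=_REASON_PROBS)
    df["dropout"] = dropped.astype(np.int64)
    df.loc[dropped, "wmh_followup"] = np.nan
    df.loc[dropped, "fazekas_followup"] = np.nan
    df["dropout_reason"] = pd.Series(reasons, index=df.index, dtype="string")
    return CohortTable(df, config)


def generate_full_cohort(config: GeneratorConfig) -> CohortTable:
    """Baseline, follow-up and dropout in one deterministic pass."""
    return apply_dropout(simulate_followup(generate_cohort(config)))


# ---------------------------------------------------------------------------
# CSV round trip


def write_cohort_csv(cohort: CohortTable, path) -> None:
    """Write the fixed-header cohort CSV (missing follow-up as empty cells)."""
    cohort.data.to_csv(path, index=False)


def read_cohort_csv(path, config: GeneratorConfig | None = None) -> CohortTable:
    """Read a cohort CSV written by :func:`write_cohort_csv` (or user-supplied)."""
    df = pd.read_csv(
        path,
        dtype={"patient_id": "string", "dropout_reason": "string"},
    )
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"cohort CSV is missing columns: {missing}")
    return CohortTable(df[COHORT_COLUMNS], config or GeneratorConfig(n_patients=len(df)))
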