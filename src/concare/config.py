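"""Configuration for the synthetic linked-claims generator.

The defaults describe the study conditions the downstream pipeline is
exercised under: a newly diagnosed COPD cohort recruited over an
eight-year window, followed for five years, with outpatient visits
spread over a small personal provider pool and a planted log-odds
effect of low care continuity on unplanned utilization.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .errors import ConfigError

#: Log-odds coefficients of the outcome model. Covariates enter
#: standardized (age and comorbidity centred and scaled, marginalization
#: centred) so intercepts are interpretable at the cohort reference.
#: ``low_coci`` is the planted exposure effect: exp(0.8109...) = 2.25.
DEFAULT_OUTCOME_COEFFICIENTS: dict[str, float] = {
    "intercept": -0.6,
    "low_coci": math.log(2.25),
    "age": 0.30,
    "sex_m": 0.10,
    "adg": 0.25,
    "rural": 0.10,
    "marginalization": 0.10,
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic claims universe.

    Attributes
    ----------
    n_patients:
        Number of persons in the registry.
    seed:
        Root seed; one fixed root spawns independent substreams per
        table so each table is individually reproducible.
    recruitment_start, recruitment_end:
        ISO dates bounding first-diagnosis dates.
    study_end:
        Administrative censoring date.
    followup_years:
        Maximum follow-up after the index diagnosis.
    mean_visits:
        Mean of the 5-year outpatient visit count (negative binomial,
        heavy right tail: ~70% of patients exceed 20 visits at defaults).
    visit_dispersion:
        Negative-binomial size parameter (smaller = heavier tail).
    dispersion_alpha:
        Symmetric Dirichlet concentration governing how a patient's
        visits spread over their provider pool. Near 0 all visits go to
        one provider (COC -> 1); large values spread visits uniformly
        (COC -> 1/pool size).
    provider_pool_size:
        Providers available to each patient.
    p_specialist_predominant:
        Probability that a patient's pool is weighted toward the
        respirology-group specialists rather than family physicians.
    outcome_coefficients:
        Mapping covariate name -> log-odds coefficient for the planted
        logistic outcome model (see DEFAULT_OUTCOME_COEFFICIENTS).
    censoring_rates:
        Death / move-out hazards per person-year.
    ed_intercept_shift, readmission_intercept_shift:
        Intercept offsets applied to the shared linear predictor for
        stand-alone ED visits and per-discharge 30-day readmissions.
    """

    n_patients: int = 2000
    seed: int = 20080401
    recruitment_start: str = "2005-04-01"
    recruitment_end: str = "2013-03-31"
    study_end: str = "2018-03-31"
    followup_years: float = 5.0
    mean_visits: float = 30.0
    visit_dispersion: float = 4.0
    dispersion_alpha: float = 0.19
    provider_pool_size: int = 7
    p_specialist_predominant: float = 0.058
    outcome_coefficients: dict = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_COEFFICIENTS)
    )
    censoring_rates: dict = field(
        default_factory=lambda: {"death": 0.035, "move": 0.010}
    )
    ed_intercept_shift: float = 0.4
    readmission_intercept_shift: float = -1.2
    extra_admission_mean: float = 1.0
    p_rural: float = 0.154
    p_invalid_id: float = 0.002
    p_nonresident: float = 0.003
    p_prior_copd: float = 0.010
    p_late_coverage: float = 0.002

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`ConfigError` naming the first invalid field."""
        if not isinstance(self.n_patients, (int, np.integer)) or self.n_patients < 1:
            raise ConfigError("n_patients", "must be a positive integer")
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigError("seed", "must be an integer")
        try:
            start = np.datetime64(self.recruitment_start)
            end = np.datetime64(self.recruitment_end)
        except ValueError as exc:  # pragma: no cover - message path
            raise ConfigError("recruitment_window", str(exc)) from exc
        if not start < end:
            raise ConfigError("recruitment_window", "start must precede end")
        if np.datetime64(self.study_end) < end:
            raise ConfigError("study_end", "must not precede recruitment end")
        if self.followup_years <= 0:
            raise ConfigError("followup_years", "must be positive")
        if self.mean_visits <= 0:
            raise ConfigError("mean_visits", "must be positive")
        if self.visit_dispersion <= 0:
            raise ConfigError("visit_dispersion", "must be positive")
        if self.dispersion_alpha < 0:
            raise ConfigError("dispersion_alpha", "must be non-negative")
        if not isinstance(self.provider_pool_size, (int, np.integer)) or self.provider_pool_size < 1:
            raise ConfigError("provider_pool_size", "must be a positive integer")
        for name in (
            "p_specialist_predominant",
            "p_rural",
            "p_invalid_id",
            "p_nonresident",
            "p_prior_copd",
            "p_late_coverage",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(name, "must be a probability in [0, 1]")
        if not isinstance(self.outcome_coefficients, dict):
            raise ConfigError("outcome_coefficients", "must map names to numbers")
        for key, value in self.outcome_coefficients.items():
            if not isinstance(value, (int, float, np.floating, np.integer)) or not math.isfinite(value):
                raise ConfigError("outcome_coefficients", f"coefficient '{key}' is not a finite number")
        for key in ("death", "move"):
            rate = self.censoring_rates.get(key)
            if rate is None or rate < 0:
                raise ConfigError("censoring_rates", f"'{key}' hazard must be >= 0")
        if self.extra_admission_mean < 0:
            raise ConfigError("extra_admission_mean", "must be >= 0")

    # ------------------------------------------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(asdict(self), handle, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(sorted(unknown)[0], "unknown configuration field")
        cfg = cls(**raw)
        cfg.validate()
        return cfg
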