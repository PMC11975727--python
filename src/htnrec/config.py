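"""Configuration dataclasses shared by the pipeline stages.

Every constant with a stated clinical meaning (270-day treatment window,
365-day follow-up, JNC 8 thresholds, 20 ensemble members trained on 80%
subsamples) defaults to that value and is overridable here.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

__all__ = [
    "ConfigurationError",
    "ClassEffect",
    "GeneratorConfig",
    "ModelConfig",
    "RunConfig",
    "COMORBIDITIES",
    "RACES",
    "load_config",
    "save_config",
]

COMORBIDITIES = (
    "tachyarrhythmia",
    "type2_diabetes",
    "ischemic_heart_disease",
    "asthma",
    "chronic_kidney_disease",
    "congestive_heart_failure",
    "gout",
)

RACES = ("White", "Black", "Other")

#: diagnosis-code prefix per comorbidity (ICD-10-style)
COMORBIDITY_CODES = {
    "tachyarrhythmia": "I48",
    "type2_diabetes": "E11",
    "ischemic_heart_disease": "I25",
    "asthma": "J45",
    "chronic_kidney_disease": "N18",
    "congestive_heart_failure": "I50",
    "gout": "M10",
}


class ConfigurationError(ValueError):
    """Invalid configuration; names the offending field."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"config field {field_name!r}: {message}")


@dataclass
class ClassEffect:
    """Ground-truth logistic coefficients for one treatment class.

    ``intercept=None`` means "calibrate to the class success-rate target".
    ``age_per_decade`` multiplies (age - 60)/10, so two classes with
    opposite signs cross at age 60.  ``dose`` multiplies the mean relative
    dose deviation of the regimen's components.
    """

    intercept: float | None = None
    age_per_decade: float = 0.0
    black: float = 0.0
    other_race: float = 0.0
    female: float = 0.0
    dose: float = 0.0
    comorbidity: dict = field(default_factory=dict)


def _check_probs(name: str, probs: dict, tol: float = 1e-9) -> None:
    for k, v in probs.items():
        if not (0.0 <= v <= 1.0):
            raise ConfigurationError(name, f"probability for {k!r} is {v}, outside [0, 1]")
    total = sum(probs.values())
    if abs(total - 1.0) > tol:
        raise ConfigurationError(name, f"probabilities sum to {total}, not 1")


@dataclass
class GeneratorConfig:
    """Synthetic-cohort generator settings.

    Defaults emulate the study population: age-band mixture, sex and race
    fractions, comorbidity prevalences, per-class prescription
    likelihoods, and per-class ground-truth success targets whose
    likelihood-weighted mean is the 33.8% marginal success rate.
    """

    n_patients: int = 20_000
    seed: int = 0

    # demographic mixture: (lo, hi) age band -> probability
    age_band_probs: dict = field(default_factory=lambda: {
        (18, 39): 0.084, (40, 49): 0.129, (50, 59): 0.242,
        (60, 69): 0.270, (70, 79): 0.175, (80, 95): 0.100,
    })
    female_fraction: float = 0.493
    race_probs: dict = field(default_factory=lambda: {
        "White": 0.925, "Black": 0.033, "Other": 0.042})
    comorbidity_prevalences: dict = field(default_factory=lambda: {
        "tachyarrhythmia": 0.294, "type2_diabetes": 0.216,
        "ischemic_heart_disease": 0.153, "asthma": 0.116,
        "chronic_kidney_disease": 0.082, "congestive_heart_failure": 0.067,
        "gout": 0.033})

    # pre-treatment measurement distributions
    sbp_mean: float = 137.8
    sbp_sd: float = 18.9
    dbp_mean: float = 81.0
    dbp_sd: float = 11.5
    creatinine_mean: float = 1.0
    creatinine_sd: float = 0.2

    # prescription likelihood per class; "other" absorbs the remainder of
    # the observed class mix (misc single agents and misc combinations)
    class_likelihoods: dict = field(default_factory=lambda: {
        "ACEi": 0.265, "beta-blocker": 0.139, "thiazide": 0.126,
        "CCB": 0.112, "ARB": 0.086, "ACEi+thiazide": 0.054, "other": 0.218})
    #: fraction of "other"-bucket episodes that are 2-agent combinations,
    #: chosen so ~22% of all patients start on more than one agent
    other_combo_share: float = 0.7615

    #: class-conditional mean success targets; the "other" target is derived
    #: at calibration time so the marginal success rate equals marginal_success
    class_success_targets: dict = field(default_factory=lambda: {
        "ACEi": 0.391, "beta-blocker": 0.309, "thiazide": 0.385,
        "CCB": 0.296, "ARB": 0.354, "ACEi+thiazide": 0.445})
    marginal_success: float = 0.338

    # ground-truth logistic coefficients (intercepts calibrated when None)
    effect_coefficients: dict = field(default_factory=lambda: {
        "ACEi": ClassEffect(age_per_decade=-0.15, black=-0.5, dose=-0.05,
                            comorbidity={"chronic_kidney_disease": 0.3}),
        "ARB": ClassEffect(age_per_decade=-0.05, black=-0.4,
                           comorbidity={"chronic_kidney_disease": 0.3}),
        "thiazide": ClassEffect(age_per_decade=0.15, black=0.5,
                                comorbidity={"gout": -0.3}),
        "CCB": ClassEffect(age_per_decade=0.05, black=0.4),
        "beta-blocker": ClassEffect(comorbidity={"tachyarrhythmia": 0.3,
                                                 "asthma": -0.3}),
        "ACEi+thiazide": ClassEffect(dose=-0.05),
        "other": ClassEffect(),
    })

    # adverse-effect machinery
    #: class -> (mild, moderate, severe); mild is a per-episode event rate,
    #: moderate/severe are relative weights for documented-AE failures
    ae_rates: dict = field(default_factory=lambda: {
        "ACEi": (0.05, 0.7, 0.3), "ARB": (0.03, 0.7, 0.3),
        "thiazide": (0.04, 0.75, 0.25), "CCB": (0.05, 0.7, 0.3),
        "beta-blocker": (0.05, 0.7, 0.3), "other": (0.05, 0.7, 0.3),
    })
    #: probability that a ground-truth failure manifests through an
    #: adverse-effect criterion rather than uncontrolled blood pressure
    ae_failure_share: float = 0.30
    ae_mode_weights: dict = field(default_factory=lambda: {
        "documented_ae": 0.40, "hypotension": 0.10, "bradycardia": 0.05,
        "creatinine_rise": 0.15, "natremia": 0.05, "kalemia": 0.15,
        "glucose": 0.10})
    #: among BP failures, fraction violating the never-exceed cap
    bp_threshold_share: float = 0.30
    bp_failure_discontinue_frac: float = 0.20

    # visit schedule and measurement noise
    mean_outcome_readings: float = 4.0
    bp_noise_sd: float = 8.0
    #: fraction of successes whose outcome readings fall only in the
    #: 12-24-month fallback windows
    fallback_window_fraction: float = 0.05
    #: fraction of patients carrying an extra hospital-context BP row
    #: (exercises the measurement filter)
    invalid_bp_fraction: float = 0.08
    #: fraction of episodes split into two abutting prescriptions
    refill_split_fraction: float = 0.30
    #: successes/failures keep an open-ended prescription with this probability
    open_end_fraction: float = 0.70

    #: planted inclusion/exclusion violations: criterion -> patient fraction
    planted_violations: dict = field(default_factory=lambda: {
        "no_primary_htn": 0.010,
        "no_established_care": 0.010,
        "late_treatment": 0.010,
        "short_followup": 0.010,
        "no_baseline_bp": 0.010,
        "no_baseline_creatinine": 0.010,
        "new_diabetes": 0.010,
        "rare_pair": 0.002,
        "discontinued_controlled": 0.010,
        "no_outcome_bp": 0.010,
    })

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients", "must be >= 1")
        _check_probs("race_probs", self.race_probs)
        _check_probs("class_likelihoods", self.class_likelihoods)
        _check_probs("age_band_probs", self.age_band_probs)
        for name, val in (("female_fraction", self.female_fraction),
                          ("other_combo_share", self.other_combo_share),
                          ("ae_failure_share", self.ae_failure_share),
                          ("bp_threshold_share", self.bp_threshold_share),
                          ("bp_failure_discontinue_frac", self.bp_failure_discontinue_frac),
                          ("fallback_window_fraction", self.fallback_window_fraction),
                          ("invalid_bp_fraction", self.invalid_bp_fraction),
                          ("refill_split_fraction", self.refill_split_fraction),
                          ("open_end_fraction", self.open_end_fraction),
                          ("marginal_success", self.marginal_success)):
            if not (0.0 <= val <= 1.0):
                raise ConfigurationError(name, f"{val} outside [0, 1]")
        for cond, p in self.comorbidity_prevalences.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError("comorbidity_prevalences",
                                         f"{cond!r} prevalence {p} outside [0, 1]")
            if cond not in COMORBIDITIES:
                raise ConfigurationError("comorbidity_prevalences", f"unknown condition {cond!r}")
        for cls, rates in self.ae_rates.items():
            if len(rates) != 3 or any(not (0.0 <= r <= 1.0) for r in rates):
                raise ConfigurationError("ae_rates", f"{cls!r} rates {rates} invalid")
        for rate, frac in self.planted_violations.items():
            if not (0.0 <= frac <= 1.0):
                raise ConfigurationError("planted_violations", f"{rate!r} fraction invalid")
        if sum(self.planted_violations.values()) > 0.5:
            raise ConfigurationError("planted_violations", "total planted fraction > 0.5")
        if self.bp_noise_sd <= 0:
            raise ConfigurationError("bp_noise_sd", "must be positive")
        if self.mean_outcome_readings <= 0:
            raise ConfigurationError("mean_outcome_readings", "must be positive")


@dataclass
class ModelConfig:
    """Ensemble success-model settings: 20 members, each trained on an
    independent 80% subsample with its own seed; small feed-forward
    probability estimators; confidence tiers from ensemble dispersion plus
    training support."""

    n_members: int = 20
    subsample: float = 0.8
    hidden_layers: tuple = (24, 12)
    max_iter: int = 300
    learning_rate_init: float = 0.005
    alpha: float = 1e-4
    batch_size: int = 256
    #: median probability at or above this predicts "success"; None means
    #: "use the training-set success prevalence", the operating point at
    #: which precision/recall of a calibrated model are informative for a
    #: ~34%-prevalent outcome
    success_threshold: float | None = None
    # confidence tiers: dispersion = (p90 - p10) / (m (1 - m)) at the median
    # m; support = training episodes with the same treatment in the same
    # (race, age-decade) cell.  Dispersion cutoffs are recalibrated on the
    # training set at fit time (see calibration_fractions).
    support_min_medium: int = 5
    support_min_high: int = 10
    dispersion_medium: float = 1.25
    dispersion_high: float = 0.95
    #: fractions used when calibrating dispersion thresholds on a case set
    calibration_fractions: tuple = (0.418, 0.173)

    def validate(self) -> None:
        if self.n_members < 2:
            raise ConfigurationError("n_members", "need at least 2 ensemble members")
        if not (0.0 < self.subsample <= 1.0):
            raise ConfigurationError("subsample", "must be in (0, 1]")
        if self.success_threshold is not None and \
                not (0.0 < self.success_threshold < 1.0):
            raise ConfigurationError("success_threshold", "must be in (0, 1)")


@dataclass
class RunConfig:
    """End-to-end pipeline configuration."""

    out_dir: str = "htnrec_run"
    seed: int = 0
    n_validation: int = 1000
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    write_curves: bool = True

    def validate(self) -> None:
        if not self.out_dir:
            raise ConfigurationError("out_dir", "required path missing")
        if self.n_validation < 1:
            raise ConfigurationError("n_validation", "must be >= 1")
        self.generator.validate()
        self.model.validate()


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {("-".join(str(x) for x in k) if isinstance(k, tuple) else k):
                _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def save_config(cfg: RunConfig, path: str) -> None:
    plain = _to_plain(cfg)
    # age bands are tuple keys; serialize as "lo-hi"
    gen = plain["generator"]
    gen["age_band_probs"] = {f"{lo}-{hi}": p
                             for (lo, hi), p in cfg.generator.age_band_probs.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(plain, fh, sort_keys=True)


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        plain = yaml.safe_load(fh)
    gen = plain.get("generator", {})
    if "age_band_probs" in gen:
        gen["age_band_probs"] = {
            tuple(int(x) for x in k.split("-")): v
            for k, v in gen["age_band_probs"].items()}
    if "effect_coefficients" in gen:
        gen["effect_coefficients"] = {
            cls: ClassEffect(**eff) for cls, eff in gen["effect_coefficients"].items()}
    if "ae_rates" in gen:
        gen["ae_rates"] = {cls: tuple(r) for cls, r in gen["ae_rates"].items()}
    model = plain.get("model", {})
    for key in ("hidden_layers", "calibration_fractions"):
        if key in model:
            model[key] = tuple(model[key])
    cfg = RunConfig(
        out_dir=plain.get("out_dir", "htnrec_run"),
        seed=plain.get("seed", 0),
        n_validation=plain.get("n_validation", 1000),
        generator=GeneratorConfig(**gen),
        model=ModelConfig(**model),
        write_curves=plain.get("write_curves", True),
    )
    cfg.validate()
    return cfg
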