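"""Synthetic cohorts of overweight adults for studying weight-change effects.

The generator emulates an observational cohort of 10,000 overweight adults
(BMI 25-29.9 kg/m2 at enrolment) followed for 20 years with visits every
2 years.  Weight change between enrolment and the first follow-up visit is
the exposure (loss / maintenance / gain at +-5% of baseline weight), CVD
onset is the outcome, and confounding is built in deliberately:

* fixed covariates (age, sex, family history, baseline weight) and two
  binary confounders measured at enrolment and again at the first follow-up
  (smoking status, diuretic use) affect both the exposure category and the
  discrete-time CVD hazard — the backdoor paths C0 -> A, C0 -> O and
  C1 -> A, C1 -> O;
* chronic disease with onset during the first interval strongly increases
  both the probability of weight loss and the interval-1 CVD hazard — the
  reverse-causation channel that inflates naive weight-loss effects.

True conditional exposure effects are injected on the per-interval logit
scale: 0 for loss vs maintenance and 0.3 for gain vs maintenance.  Per-
interval event probabilities are kept below ~5% so the logit-scale odds
ratio coincides with the hazard ratio to the precision reported anywhere
in this package.  No death before CVD and no loss to follow-up.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

__all__ = [
    "SimParams",
    "Cohort",
    "default_params",
    "simulate_cohort",
    "classify_change",
    "write_cohort",
    "read_cohort",
]

# Covariates that enter the exposure and hazard linear predictors.
CONFOUNDER_NAMES = (
    "age0",
    "sex",
    "famhist",
    "weight0",
    "smoking0",
    "diuretics0",
    "smoking1",
    "diuretics1",
)

# Fixed centering constants for the continuous covariates, used identically
# in the generator's linear predictors (centering only shifts intercepts,
# so downstream model centering need not match).
AGE_CENTER = 52.5
WEIGHT_CENTER = 80.0

SUBJECT_COLUMNS = [
    "id",
    "age0",
    "sex",
    "famhist",
    "height",
    "weight0",
    "bmi0",
    "smoking0",
    "diuretics0",
    "smoking1",
    "diuretics1",
    "chronic1",
    "weight1",
    "change_category",
    "event_interval",
]

BMI_LOW, BMI_HIGH = 25.0, 29.9


@dataclass(frozen=True)
class SimParams:
    """Full parameterization of the cohort data-generating process.

    ``exposure_loss_effects`` / ``exposure_gain_effects`` are the
    confounder coefficients on the multinomial log-odds of the loss and
    gain categories (maintenance is the reference); ``hazard_effects`` are
    the confounder coefficients on the per-interval logit hazard.  Age is
    per year (centered at 52.5), baseline weight per kg (centered at 80).
    """

    n_subjects: int = 10_000
    n_intervals: int = 10
    interval_length: float = 2.0  # years; fixed by the study design
    change_threshold: float = 0.05
    true_loss_effect: float = 0.0
    true_gain_effect: float = 0.3
    baseline_hazard_logits: tuple[float, ...] = (-4.35,) * 10
    hazard_effects: dict[str, float] = field(
        default_factory=lambda: {
            "age0": 0.04,
            "sex": 0.3,
            "famhist": 0.4,
            "weight0": 0.01,
            "smoking0": 0.35,
            "diuretics0": 0.6,
            "smoking1": 0.4,
            "diuretics1": 0.35,
        }
    )
    exposure_loss_intercept: float = -1.05
    exposure_gain_intercept: float = -0.30
    exposure_loss_effects: dict[str, float] = field(
        default_factory=lambda: {
            "age0": 0.01,
            "sex": 0.0,
            "famhist": 0.0,
            "weight0": 0.01,
            "smoking0": 0.3,
            "diuretics0": 0.8,
            "smoking1": 0.7,
            "diuretics1": 0.5,
        }
    )
    exposure_gain_effects: dict[str, float] = field(
        default_factory=lambda: {
            "age0": -0.01,
            "sex": 0.0,
            "famhist": 0.0,
            "weight0": -0.01,
            "smoking0": -0.3,
            "diuretics0": -0.4,
            "smoking1": -0.7,
            "diuretics1": -0.5,
        }
    )
    # Chronic disease with onset in interval 1: incidence, effect on the
    # loss log-odds, and effect on the interval-1 hazard (reverse causation;
    # confined to interval 1 — see docs/methods.md).
    chronic_incidence: float = 0.05
    chronic_loss_effect: float = 2.5
    chronic_hazard_effect: float = 2.2
    # Baseline covariate prevalences and wave-1 transition parameters.
    sex_rate: float = 0.5
    famhist_rate: float = 0.15
    smoking_rate: float = 0.25
    diuretics_rate: float = 0.15
    smoking_persistence: float = 0.85
    smoking_initiation: float = 0.03
    diuretics1_intercept: float = -2.6  # logit of new use at age 52.5
    diuretics1_persistence: float = 1.2  # log-odds bump for wave-0 users
    diuretics1_age_effect: float = 0.04  # per year of age
    master_seed: int = 20230

    def validate(self) -> None:
        if self.n_intervals < 2:
            raise ValueError("n_intervals must be >= 2 (interval 1 forms the exposure)")
        if not 0 < self.change_threshold < 0.5:
            raise ValueError("change_threshold must lie in (0, 0.5)")
        if len(self.baseline_hazard_logits) != self.n_intervals:
            raise ValueError(
                "baseline_hazard_logits must have one entry per interval "
                f"({len(self.baseline_hazard_logits)} != {self.n_intervals})"
            )
        for name in CONFOUNDER_NAMES:
            for d in (
                self.hazard_effects,
                self.exposure_loss_effects,
                self.exposure_gain_effects,
            ):
                if name not in d:
                    raise ValueError(f"missing coefficient for {name!r}")
        # Rare-event regime: the per-interval event probability at covariate
        # means must not exceed 5%, so logit coefficients read as log HRs.
        means = {
            "age0": 0.0,
            "sex": self.sex_rate,
            "famhist": self.famhist_rate,
            "weight0": 0.0,
            "smoking0": self.smoking_rate,
            "diuretics0": self.diuretics_rate,
            "smoking1": self.smoking_rate,
            "diuretics1": self.diuretics_rate,
        }
        shift = sum(self.hazard_effects[k] * v for k, v in means.items())
        p_max = float(expit(np.max(self.baseline_hazard_logits) + shift))
        if p_max > 0.05:
            raise ValueError(
                f"per-interval event probability at covariate means is {p_max:.3f}"
                " > 0.05; hazards are no longer rare-event"
            )

    def replace(self, **changes) -> "SimParams":
        return dataclasses.replace(self, **changes)

    def null_confounding(self) -> "SimParams":
        """Copy with every confounder and chronic-disease effect zeroed.

        In this limiting case exposure is effectively randomized, so all
        three emulation methods are valid — a key sanity check.
        """
        zero = {name: 0.0 for name in CONFOUNDER_NAMES}
        return self.replace(
            hazard_effects=dict(zero),
            exposure_loss_effects=dict(zero),
            exposure_gain_effects=dict(zero),
            chronic_loss_effect=0.0,
            chronic_hazard_effect=0.0,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        d = dict(d)
        if "baseline_hazard_logits" in d:
            d["baseline_hazard_logits"] = tuple(d["baseline_hazard_logits"])
        return cls(**d)


@dataclass
class Cohort:
    """A simulated cohort: one row per subject plus the generating params."""

    params: SimParams
    subjects: pd.DataFrame
    seed_used: int

    @property
    def n(self) -> int:
        return len(self.subjects)

    def validate(self) -> None:
        missing = [c for c in SUBJECT_COLUMNS if c not in self.subjects.columns]
        if missing:
            raise ValueError(f"cohort table missing column(s): {missing}")
        ids = self.subjects["id"].to_numpy()
        if len(np.unique(ids)) != len(ids):
            raise ValueError("subject ids are not unique")
        bmi = self.subjects["bmi0"].to_numpy()
        bad = np.flatnonzero((bmi < BMI_LOW) | (bmi >= BMI_HIGH))
        if bad.size:
            raise ValueError(
                f"row {bad[0]}: bmi0 = {bmi[bad[0]]:.2f} outside eligibility "
                f"range [{BMI_LOW}, {BMI_HIGH})"
            )
        ev = self.subjects["event_interval"]
        obs = ev.dropna()
        if len(obs) and (
            (obs < 1).any() or (obs > self.params.n_intervals).any()
        ):
            raise ValueError("event_interval outside 1..n_intervals")


def default_params() -> SimParams:
    """The default study conditions (see docs/methods.md for rationale)."""
    return SimParams()


def classify_change(frac_change: np.ndarray, threshold: float) -> np.ndarray:
    """Three-level exposure from relative weight change.

    loss iff change <= -threshold, gain iff change >= +threshold,
    maintenance otherwise.
    """
    frac_change = np.asarray(frac_change, dtype=float)
    out = np.full(frac_change.shape, "maintain", dtype=object)
    out[frac_change <= -threshold] = "loss"
    out[frac_change >= threshold] = "gain"
    return out


def _confounder_matrix(df: pd.DataFrame) -> dict[str, np.ndarray]:
    """Centered covariate arrays keyed by name, ready for linear predictors."""
    return {
        "age0": df["age0"].to_numpy() - AGE_CENTER,
        "sex": df["sex"].to_numpy(dtype=float),
        "famhist": df["famhist"].to_numpy(dtype=float),
        "weight0": df["weight0"].to_numpy() - WEIGHT_CENTER,
        "smoking0": df["smoking0"].to_numpy(dtype=float),
        "diuretics0": df["diuretics0"].to_numpy(dtype=float),
        "smoking1": df["smoking1"].to_numpy(dtype=float),
        "diuretics1": df["diuretics1"].to_numpy(dtype=float),
    }


def _linpred(effects: dict[str, float], X: dict[str, np.ndarray]) -> np.ndarray:
    lp = np.zeros_like(X["age0"])
    for name, beta in effects.items():
        if beta != 0.0:
            lp += beta * X[name]
    return lp


def simulate_cohort(params: SimParams, seed: int | np.random.SeedSequence | None = None) -> Cohort:
    """Draw one cohort from the data-generating process.

    Identical (params, seed) pairs yield byte-identical cohorts.  When
    ``seed`` is omitted, ``params.master_seed`` is used.
    """
    params.validate()
    if seed is None:
        seed = params.master_seed
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(int(seed))
    seed_used = int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
    rng = np.random.Generator(np.random.PCG64(ss))
    n = params.n_subjects

    # --- enrolment covariates ----------------------------------------------
    age0 = rng.uniform(45.0, 60.0, n)
    sex = (rng.random(n) < params.sex_rate).astype(np.int64)  # 1 = male
    famhist = (rng.random(n) < params.famhist_rate).astype(np.int64)
    smoking0 = (rng.random(n) < params.smoking_rate).astype(np.int64)
    diuretics0 = (rng.random(n) < params.diuretics_rate).astype(np.int64)
    bmi0 = rng.uniform(BMI_LOW, BMI_HIGH, n)
    # Height only converts the BMI eligibility band into kilograms; all
    # modelling downstream uses fractional weight change, so it is inert.
    height = np.where(
        sex == 1,
        rng.normal(1.77, 0.07, n),
        rng.normal(1.64, 0.06, n),
    )
    weight0 = bmi0 * height**2

    # --- first-follow-up covariates ----------------------------------------
    p_smoke1 = np.where(
        smoking0 == 1, params.smoking_persistence, params.smoking_initiation
    )
    smoking1 = (rng.random(n) < p_smoke1).astype(np.int64)
    lp_diu = (
        params.diuretics1_intercept
        + params.diuretics1_persistence * diuretics0
        + params.diuretics1_age_effect * (age0 - AGE_CENTER)
    )
    diuretics1 = (rng.random(n) < expit(lp_diu)).astype(np.int64)
    chronic1 = (rng.random(n) < params.chronic_incidence).astype(np.int64)

    df = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "age0": age0,
            "sex": sex,
            "famhist": famhist,
            "height": height,
            "weight0": weight0,
            "bmi0": bmi0,
            "smoking0": smoking0,
            "diuretics0": diuretics0,
            "smoking1": smoking1,
            "diuretics1": diuretics1,
            "chronic1": chronic1,
        }
    )
    X = _confounder_matrix(df)

    # --- exposure category and consistent weight at first follow-up --------
    lp_loss = (
        params.exposure_loss_intercept
        + _linpred(params.exposure_loss_effects, X)
        + params.chronic_loss_effect * chronic1
    )
    lp_gain = params.exposure_gain_intercept + _linpred(params.exposure_gain_effects, X)
    e_loss, e_gain = np.exp(lp_loss), np.exp(lp_gain)
    denom = 1.0 + e_loss + e_gain
    p_loss, p_gain = e_loss / denom, e_gain / denom
    u = rng.random(n)
    category = np.full(n, "maintain", dtype=object)
    category[u < p_loss] = "loss"
    category[u >= p_loss + (1.0 - p_loss - p_gain)] = "gain"

    thr = params.change_threshold
    frac = np.empty(n)
    is_loss = category == "loss"
    is_gain = category == "gain"
    is_maint = ~(is_loss | is_gain)
    frac[is_loss] = rng.uniform(-3 * thr, -thr, is_loss.sum())
    frac[is_gain] = rng.uniform(thr, 3 * thr, is_gain.sum())
    frac[is_maint] = rng.uniform(-thr, thr, is_maint.sum())
    df["weight1"] = weight0 * (1.0 + frac)
    df["change_category"] = category

    # --- discrete-time CVD events ------------------------------------------
    # Interval 1: exposure has not yet occurred; hazard depends on enrolment
    # covariates and chronic-disease onset only.  Intervals >= 2: exposure
    # terms and the follow-up confounders enter.
    c0_effects = {
        k: v
        for k, v in params.hazard_effects.items()
        if k in ("age0", "sex", "famhist", "weight0", "smoking0", "diuretics0")
    }
    lp_base_c0 = _linpred(c0_effects, X)
    lp_full = _linpred(params.hazard_effects, X)
    expo = (
        params.true_loss_effect * is_loss.astype(float)
        + params.true_gain_effect * is_gain.astype(float)
    )

    event_interval = np.zeros(n, dtype=np.int64)  # 0 = no event
    at_risk = np.ones(n, dtype=bool)
    for t in range(1, params.n_intervals + 1):
        base = params.baseline_hazard_logits[t - 1]
        if t == 1:
            lp = base + lp_base_c0 + params.chronic_hazard_effect * chronic1
        else:
            lp = base + lp_full + expo
        hit = at_risk & (rng.random(n) < expit(lp))
        event_interval[hit] = t
        at_risk &= ~hit
    df["event_interval"] = pd.array(
        np.where(event_interval > 0, event_interval, np.nan), dtype="Int64"
    )

    cohort = Cohort(params=params, subjects=df, seed_used=seed_used)
    cohort.validate()
    return cohort


# --- plain-text persistence -------------------------------------------------

def write_cohort(cohort: Cohort, path: str) -> None:
    """Write the subject table as CSV plus a ``<path>.params.yaml`` sidecar."""
    cohort.subjects.to_csv(path, index=False)
    sidecar = {
        "params": cohort.params.to_dict(),
        "seed_used": cohort.seed_used,
    }
    with open(f"{path}.params.yaml", "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=False)


def read_cohort(path: str) -> Cohort:
    """Read a cohort written by :func:`write_cohort`, validating the contract."""
    df = pd.read_csv(path)
    missing = [c for c in SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    df["event_interval"] = df["event_interval"].astype("Int64")
    with open(f"{path}.params.yaml") as fh:
        sidecar = yaml.safe_load(fh)
    params = SimParams.from_dict(sidecar["params"])
    cohort = Cohort(params=params, subjects=df, seed_used=int(sidecar["seed_used"]))
    cohort.validate()
    return cohort
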