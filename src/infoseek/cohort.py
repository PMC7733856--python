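"""Generative simulator for the costed perceptual information-seeking task.

The task being emulated: on each trial an observer judges which of two
flickering-dot boxes holds more dots (one box always holds the 313-dot
baseline), rates confidence on a signed six-point scale, and may then pay
5 or 20 points (fixed per block) to view a stronger version of the stimulus
before an incentivized final judgment (100 points correct / 0 incorrect).
Task difficulty is calibrated per observer by an adaptive staircase so that
initial accuracy sits near 71%.

Every stochastic routine takes an explicit integer seed or
:class:`numpy.random.Generator`; there is no hidden global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import CalibrationError, InternalConsistencyError, InvalidArgumentError

BASELINE_DOTS = 313
MAX_DOT_DIFFERENCE = 313
COST_LEVELS = (5, 20)

# z-score of a uniform 3-level confidence rating: levels {1,2,3} map to
# (level - 2) / sqrt(2/3).  The fitting pipeline re-standardizes empirically;
# the generator uses this closed form so that subject beta values have a
# fixed, documented scale.
CONF_LEVEL_SCALE = math.sqrt(3.0 / 2.0)


def encode_confidence_level(level):
    """Map a 3-level confidence rating to the generator's predictor scale."""
    return (np.asarray(level, dtype=float) - 2.0) * CONF_LEVEL_SCALE


def encode_cost(cost_points):
    """High-cost indicator: 0 for the 5-point blocks, 1 for the 20-point blocks."""
    return (np.asarray(cost_points) == 20).astype(float)


def confidence_code6(choice, level):
    """Signed six-point confidence code: 'sure left' = 1 ... 'sure right' = 6."""
    level = int(level)
    if choice == "left":
        return 4 - level
    return 3 + level


def _as_rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class ObserverParams:
    """One simulated participant.

    Parameters
    ----------
    sensitivity
        d' per unit log dot difference: discrimination accuracy is
        ``Phi(sensitivity * log(1 + ddots/313) / sqrt(2))`` before lapses.
    lapse_rate
        Probability of a random initial response, in [0, 0.05].
    conf_criteria
        Two strictly increasing positive thresholds on absolute decision
        evidence partitioning confidence into levels {1, 2, 3}.
    betas
        Seek-policy coefficients (intercept, confidence slope, cost slope)
        on the encoded-predictor scale.
    dogmatism
        Standardized dogmatism factor score.
    """

    subject_id: str
    sensitivity: float
    lapse_rate: float
    conf_criteria: tuple
    betas: np.ndarray
    dogmatism: float
    age: float = 35.0
    gender: int = 0
    education: int = 3

    def __post_init__(self):
        if not self.sensitivity > 0:
            raise InvalidArgumentError(f"sensitivity must be > 0, got {self.sensitivity}")
        if not 0.0 <= self.lapse_rate <= 0.05:
            raise InvalidArgumentError(f"lapse_rate must be in [0, 0.05], got {self.lapse_rate}")
        c1, c2 = self.conf_criteria
        if not (0 < c1 < c2):
            raise InvalidArgumentError(f"conf_criteria must be increasing positive, got {self.conf_criteria}")
        if not np.isfinite(self.dogmatism):
            raise InvalidArgumentError("dogmatism must be finite")
        object.__setattr__(self, "betas", np.asarray(self.betas, dtype=float))
        if self.betas.shape != (3,) or not np.all(np.isfinite(self.betas)):
            raise InvalidArgumentError("betas must be a finite 3-vector")

    def p_correct(self, dot_difference):
        """Expected 2AFC accuracy at a given integer dot difference."""
        d = self.sensitivity * np.log1p(np.asarray(dot_difference, dtype=float) / BASELINE_DOTS)
        return (1.0 - self.lapse_rate) * norm.cdf(d / math.sqrt(2.0)) + self.lapse_rate * 0.5


@dataclass(frozen=True)
class PopulationParams:
    """Group-level distribution of the seek-policy betas.

    Each subject's coefficient k is drawn from
    ``N(mu_B[k] + rho[k] * dogmatism_i, sigma_B[k])`` — the covariate-shifted
    population distribution the hierarchical model estimates.
    """

    mu_B: np.ndarray = field(default_factory=lambda: np.array([-0.5, -1.0, -0.8]))
    sigma_B: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.5, 0.5]))
    rho: np.ndarray = field(default_factory=lambda: np.array([-0.24, 0.15, 0.0]))

    def __post_init__(self):
        for name in ("mu_B", "sigma_B", "rho"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,):
                raise InvalidArgumentError(f"{name} must have length 3")
            object.__setattr__(self, name, v)
        if not np.all(self.sigma_B > 0):
            raise InvalidArgumentError(f"all sigma_B must be > 0, got {self.sigma_B}")


@dataclass(frozen=True)
class FactorStructure:
    """Coefficients of the simulated relationships among factor scores.

    ``dogmatism = dog_lin*z + dog_quad*(z^2 - 1) + dog_noise*eps`` with z the
    standardized left-right orientation score, and
    ``superiority = sup_lin*z + sup_quad*(z^2 - 1) + sup_dog*dogmatism + sup_noise*eps``.
    Defaults give dogmatism a positive linear and quadratic dependence on
    orientation, and belief superiority a negative-linear / positive-quadratic
    dependence on orientation plus a positive dependence on dogmatism.
    """

    dog_lin: float = 0.30
    dog_quad: float = 0.20
    dog_noise: float = 1.0
    sup_lin: float = -0.20
    sup_quad: float = 0.30
    sup_dog: float = 0.40
    sup_noise: float = 1.0


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of one simulated study."""

    n_subjects: int = 50
    n_blocks: int = 4
    trials_per_block: int = 25
    cost_schedule: tuple = (5, 20, 5, 20)
    population: PopulationParams = field(default_factory=PopulationParams)
    factor_structure: FactorStructure = field(default_factory=FactorStructure)
    post_multiplier: float = 3.0
    calibration_trials: int = 120
    sensitivity_log_mean: float = math.log(8.0)
    sensitivity_log_sd: float = 0.25
    lapse_max: float = 0.02
    study: str = "sim"
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise InvalidArgumentError("n_subjects must be >= 1")
        if len(self.cost_schedule) != self.n_blocks:
            raise InvalidArgumentError("cost_schedule must assign one cost per block")
        if set(self.cost_schedule) != set(COST_LEVELS):
            raise InvalidArgumentError(f"cost_schedule must use exactly the costs {COST_LEVELS}")

    @property
    def trials_per_subject(self):
        return self.n_blocks * self.trials_per_block


def generate_factor_scores(n, factor_structure=None, seed=0):
    """Simulate subject factor scores (orientation, dogmatism, superiority).

    All three columns are standardized to mean 0, SD 1 on the generated
    sample.  With zero noise, zero quadratic terms and ``dog_lin=1`` the
    dogmatism column equals standardized orientation exactly.
    """
    if n < 1:
        raise InvalidArgumentError(f"n must be >= 1, got {n}")
    fs = factor_structure or FactorStructure()
    for name, value in vars(fs).items():
        if not np.isfinite(value):
            raise InvalidArgumentError(f"factor structure coefficient {name} is not finite")
    rng = _as_rng(seed)
    z = rng.standard_normal(n)
    quad = z**2 - 1.0
    dog = fs.dog_lin * z + fs.dog_quad * quad + fs.dog_noise * rng.standard_normal(n)
    sup = fs.sup_lin * z + fs.sup_quad * quad + fs.sup_dog * dog + fs.sup_noise * rng.standard_normal(n)

    def _std(x):
        s = x.std()
        return (x - x.mean()) / s if s > 0 else x - x.mean()

    return pd.DataFrame(
        {"orientation": _std(z), "dogmatism": _std(dog), "superiority": _std(sup)}
    )


def sample_subject_params(pop, dogmatism, seed=0):
    """Draw per-subject seek-policy betas from the covariate-shifted population.

    ``beta[i, k] ~ N(mu_B[k] + rho[k] * dogmatism[i], sigma_B[k])``,
    independent across subjects and coefficients.
    """
    pop = pop if isinstance(pop, PopulationParams) else PopulationParams(*pop)
    dogmatism = np.asarray(dogmatism, dtype=float)
    rng = _as_rng(seed)
    means = pop.mu_B[None, :] + pop.rho[None, :] * dogmatism[:, None]
    return means + pop.sigma_B[None, :] * rng.standard_normal((len(dogmatism), 3))


def calibrate_staircase(
    observer,
    n_trials=120,
    seed=0,
    accuracy_fn=None,
    start_dots=60.0,
    step_log=0.2,
    n_halving_reversals=3,
    n_final_reversals=6,
):
    """Adaptive two-down-one-up staircase on log dot difference.

    Difficulty decreases (fewer extra dots) after two consecutive correct
    responses and increases after every error; the step on log dot difference
    is halved after the first ``n_halving_reversals`` reversals and the
    returned value is the mean log difference over the last
    ``n_final_reversals`` reversals.  The two-down-one-up rule converges on
    the ~70.7%-correct point of the psychometric function.

    Parameters
    ----------
    accuracy_fn
        Optional override mapping dot difference -> response accuracy;
        defaults to the observer's Gaussian psychometric function.

    Returns
    -------
    int
        Calibrated dot difference (>= 1).
    """
    if n_trials < 20:
        raise InvalidArgumentError("n_trials must be >= 20")
    p_fn = accuracy_fn if accuracy_fn is not None else observer.p_correct
    if p_fn(MAX_DOT_DIFFERENCE) < 0.60:
        sid = getattr(observer, "subject_id", "<unknown>")
        raise CalibrationError(
            f"subject {sid}: accuracy below 60% even at the maximum dot difference"
        )
    rng = _as_rng(seed)
    log_d = math.log(start_dots)
    lo, hi = 0.0, math.log(MAX_DOT_DIFFERENCE)
    step = step_log
    n_correct_streak = 0
    last_direction = 0  # +1 easier, -1 harder
    reversal_points = []
    for _ in range(n_trials):
        correct = rng.random() < p_fn(math.exp(log_d))
        if correct:
            n_correct_streak += 1
            if n_correct_streak >= 2:
                direction = -1
                n_correct_streak = 0
            else:
                continue
        else:
            direction = +1
            n_correct_streak = 0
        if last_direction != 0 and direction != last_direction:
            reversal_points.append(log_d)
            if len(reversal_points) == n_halving_reversals:
                step /= 2.0
        last_direction = direction
        log_d = min(hi, max(lo, log_d + direction * step))
    tail = reversal_points[-n_final_reversals:] if reversal_points else [log_d]
    return max(1, round(math.exp(float(np.mean(tail)))))


@dataclass(frozen=True)
class TrialRecord:
    """One simulated task trial."""

    subject_id: str
    block: int
    trial_index: int
    cost_points: int
    dot_difference: int
    correct_side: str
    initial_choice: str
    initial_conf_level: int
    initial_conf_code6: int
    sought: bool
    final_choice: str
    final_conf_level: int
    initial_correct: bool
    final_correct: bool
    points: int


def simulate_trial(
    observer,
    dot_difference,
    cost_points,
    seed=0,
    post_multiplier=3.0,
    block=1,
    trial_index=1,
):
    """Simulate one complete trial for an observer at a fixed dot difference.

    Internal evidence is drawn as ``x ~ N(side * d'/sqrt(2), 1)`` with
    ``d' = sensitivity * log(1 + dot_difference/313)``, so initial accuracy is
    ``Phi(d'/sqrt(2))`` up to lapses.  The initial choice is the sign of x
    (with a lapse-rate chance of a random response); confidence is |x| cut at
    the observer's criteria.  The seek decision is Bernoulli with probability
    from the logistic policy on encoded confidence and cost.  Seeking adds a
    second, yoked evidence draw at ``post_multiplier`` times the calibrated
    log strength before the final choice; otherwise the final decision
    repeats the initial one.
    """
    if dot_difference < 1:
        raise InvalidArgumentError("dot_difference must be >= 1")
    if cost_points not in COST_LEVELS:
        raise InvalidArgumentError(f"cost_points must be one of {COST_LEVELS}, got {cost_points}")
    rng = _as_rng(seed)
    side = "left" if rng.random() < 0.5 else "right"
    sign = -1.0 if side == "left" else 1.0
    dprime = observer.sensitivity * math.log1p(dot_difference / BASELINE_DOTS)
    x = rng.normal(sign * dprime / math.sqrt(2.0), 1.0)
    if rng.random() < observer.lapse_rate:
        initial_choice = "left" if rng.random() < 0.5 else "right"
    else:
        initial_choice = "left" if x < 0 else "right"
    c1, c2 = observer.conf_criteria
    conf = 1 if abs(x) < c1 else (2 if abs(x) < c2 else 3)

    b0, b1, b2 = observer.betas
    eta = b0 + b1 * encode_confidence_level(conf) + b2 * encode_cost(cost_points)
    p_seek = 1.0 / (1.0 + math.exp(-min(35.0, max(-35.0, eta))))
    sought = bool(rng.random() < p_seek)

    if sought:
        x_final = x + rng.normal(sign * post_multiplier * dprime / math.sqrt(2.0), 1.0)
        final_choice = "left" if x_final < 0 else "right"
        final_conf = 1 if abs(x_final) < c1 else (2 if abs(x_final) < c2 else 3)
    else:
        final_choice = initial_choice
        final_conf = conf

    initial_correct = initial_choice == side
    final_correct = final_choice == side
    points = 100 * int(final_correct) - cost_points * int(sought)
    return TrialRecord(
        subject_id=observer.subject_id,
        block=block,
        trial_index=trial_index,
        cost_points=int(cost_points),
        dot_difference=int(dot_difference),
        correct_side=side,
        initial_choice=initial_choice,
        initial_conf_level=conf,
        initial_conf_code6=confidence_code6(initial_choice, conf),
        sought=sought,
        final_choice=final_choice,
        final_conf_level=final_conf,
        initial_correct=initial_correct,
        final_correct=final_correct,
        points=points,
    )


def _draw_observer(i, config, dogmatism, betas, rng):
    sensitivity = float(np.exp(rng.normal(config.sensitivity_log_mean, config.sensitivity_log_sd)))
    lapse = float(rng.uniform(0.0, config.lapse_max))
    c1 = float(rng.uniform(0.4, 0.8))
    c2 = c1 + float(rng.uniform(0.5, 1.0))
    age = float(np.clip(rng.normal(38.0, 12.0), 18.0, 75.0))
    gender = int(rng.choice(3, p=[0.53, 0.44, 0.03]))
    education = int(rng.integers(1, 6))
    return ObserverParams(
        subject_id=f"s{i + 1:04d}",
        sensitivity=sensitivity,
        lapse_rate=lapse,
        conf_criteria=(c1, c2),
        betas=betas,
        dogmatism=float(dogmatism),
        age=age,
        gender=gender,
        education=education,
    )


def simulate_cohort(config=None, **overrides):
    """Simulate a complete study: per-subject calibration plus the main task.

    Returns ``(trials, subjects)`` as two dataframes conforming to the
    package CSV schemas.  Fully reproducible from ``config.seed``.
    """
    from . import io as _io

    if config is None:
        config = CohortConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    rng = np.random.default_rng(config.seed)
    factors = generate_factor_scores(config.n_subjects, config.factor_structure, seed=rng)
    betas = sample_subject_params(config.population, factors["dogmatism"].to_numpy(), seed=rng)

    records = []
    covariate_rows = []
    for i in range(config.n_subjects):
        obs = _draw_observer(i, config, factors["dogmatism"].iloc[i], betas[i], rng)
        dots = calibrate_staircase(obs, n_trials=config.calibration_trials, seed=rng)
        t = 0
        for b, cost in enumerate(config.cost_schedule, start=1):
            for _ in range(config.trials_per_block):
                t += 1
                records.append(
                    simulate_trial(
                        obs,
                        dots,
                        cost,
                        seed=rng,
                        post_multiplier=config.post_multiplier,
                        block=b,
                        trial_index=t,
                    )
                )
        covariate_rows.append(
            {
                "subject_id": obs.subject_id,
                "study": config.study,
                "dogmatism": obs.dogmatism,
                "orientation": factors["orientation"].iloc[i],
                "superiority": factors["superiority"].iloc[i],
                "age": obs.age,
                "gender": obs.gender,
                "education": obs.education,
            }
        )

    trials = pd.DataFrame(records)
    trials.insert(1, "study", config.study)
    subjects = _io.aggregate_subjects(trials, pd.DataFrame(covariate_rows))
    for df, name in ((trials, "trial"), (subjects, "subject")):
        num = df.select_dtypes(include=[np.number])
        if num.isna().any().any():
            raise InternalConsistencyError(f"NaN values in generated {name} table")
    return trials, subjects
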