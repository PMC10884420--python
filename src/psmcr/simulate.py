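"""Weibull competing-risks data generation by cumulative-hazard inversion.

Latent event times for each cause follow a Weibull proportional-hazards
model with cumulative baseline hazard H(t) = lambda * t^gamma, so that with
U ~ Uniform(0, 1]

    t = [ -log(U) / (lambda * exp(x' beta)) ]^(1 / gamma).

Two latent times s1, s2 (one per competing cause) are drawn with independent
uniforms; the earlier one, if it precedes the administrative censoring time
c, determines the observed time and status (1 or 2); otherwise the subject
is censored at c with status 0. Baseline covariates are i.i.d. standard
normal.

A second generator, :func:`simulate_chemo_analog`, emulates the shape of a
chemoradiotherapy follow-up cohort over the four-state topology
LRC -> FP -> DP -> Death (536 subjects, six continuous baseline labs plus
gender, two competing death causes). Its transition rates are configuration,
chosen to give event counts of the same order as a typical cohort of that
size; they are not estimates of any real dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datasets import CompetingRisksDataset

__all__ = [
    "SimulationConfig",
    "PAPER_BETA_CAUSE1",
    "PAPER_BETA_CAUSE2",
    "draw_covariates",
    "weibull_event_time",
    "assign_final_status",
    "simulate_dataset",
    "simulate_chemo_analog",
    "CHEMO_ANALOG_CONFIG",
]

#: Generating coefficients of the reference simulation design.
PAPER_BETA_CAUSE1 = (-0.5, 0.01, 0.02)
PAPER_BETA_CAUSE2 = (-0.5, 0.43, 0.03)


@dataclass(frozen=True)
class SimulationConfig:
    """Design of one competing-risks simulation.

    Defaults are the reference design: 200 subjects, three standard-normal
    baseline covariates, Weibull shape 1.5 and scale 0.1 for both causes,
    administrative censoring at 5 years, 100 replicate datasets.
    """

    n: int = 200
    m: int = 3
    beta_cause1: tuple[float, ...] = PAPER_BETA_CAUSE1
    beta_cause2: tuple[float, ...] = PAPER_BETA_CAUSE2
    gamma: float = 1.5
    lam: float = 0.1
    censor_time: float = 5.0
    n_reps: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.gamma <= 0 or self.lam <= 0 or self.censor_time <= 0:
            raise ValueError("gamma, lam and censor_time must be positive")
        if len(self.beta_cause1) != self.m or len(self.beta_cause2) != self.m:
            raise ValueError("coefficient vectors must have length m")

    def replicate_seed(self, rep: int) -> int | None:
        """Derived seed for replicate ``rep`` (independently reproducible)."""
        return None if self.seed is None else int(self.seed) + int(rep)


def draw_covariates(n: int, m: int, seed=None) -> np.ndarray:
    """i.i.d. standard-normal baseline covariate matrix (n x m)."""
    if n < 1 or m < 1:
        raise ValueError("n and m must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.standard_normal((n, m))


def weibull_event_time(u, x, beta, lam: float, gamma: float):
    """Invert the Weibull cumulative hazard at -log(u).

    t = [-log(u) / (lam * exp(x' beta))]^(1/gamma); u in (0, 1].
    Vectorised over rows of ``x`` when ``u`` is an array.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0) or np.any(u > 1):
        raise ValueError("u must lie in (0, 1]")
    eta = np.asarray(x, dtype=float) @ np.asarray(beta, dtype=float)
    t = (-np.log(u) / (lam * np.exp(eta))) ** (1.0 / gamma)
    return float(t) if t.ndim == 0 else t


def assign_final_status(s1, s2, c: float):
    """Combine two latent cause-specific times with administrative censoring.

    The earlier latent time wins; exact ties go to cause 1. If the winner
    exceeds ``c`` the subject is censored at ``c`` with status 0.
    """
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if np.any(s1 <= 0) or np.any(s2 <= 0) or c <= 0:
        raise ValueError("latent times and censoring time must be positive")
    winner = np.minimum(s1, s2)
    cause = np.where(s1 <= s2, 1, 2)
    time = np.where(winner <= c, winner, c)
    status = np.where(winner <= c, cause, 0)
    if time.ndim == 0:
        return float(time), int(status)
    return time, status.astype(int)


def simulate_dataset(config: SimulationConfig, seed=None) -> CompetingRisksDataset:
    """Draw one competing-risks dataset under ``config``.

    ``seed`` overrides ``config.seed`` (used for per-replicate seeding).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    X = draw_covariates(config.n, config.m, rng)
    u1 = 1.0 - rng.random(config.n)  # in (0, 1]
    u2 = 1.0 - rng.random(config.n)
    s1 = weibull_event_time(u1, X, config.beta_cause1, config.lam, config.gamma)
    s2 = weibull_event_time(u2, X, config.beta_cause2, config.lam, config.gamma)
    times, statuses = assign_final_status(s1, s2, config.censor_time)
    return CompetingRisksDataset(
        ids=np.array([f"s{i + 1:04d}" for i in range(config.n)]),
        times=times,
        statuses=statuses,
        covariates=pd.DataFrame(X, columns=[f"x{j + 1}" for j in range(config.m)]),
        censoring_time=config.censor_time,
    )


# ---------------------------------------------------------------------------
# Chemoradiotherapy-analog generator (four-state topology)
# ---------------------------------------------------------------------------

#: Baseline lab distributions: (name, mean, sd) on clinically plausible scales
#: (hemoglobin g/dL, glucose mg/dL, creatinine mg/dL, albumin g/dL,
#: sodium mmol/L, potassium mmol/L).
_LABS = (
    ("cov1", 12.0, 1.5),
    ("cov2", 110.0, 25.0),
    ("cov3", 0.9, 0.2),
    ("cov4", 4.0, 0.5),
    ("cov5", 138.0, 4.0),
    ("cov6", 4.2, 0.4),
)


@dataclass(frozen=True)
class ChemoAnalogConfig:
    """Transition-level Weibull rates for the four-state analog cohort.

    ``rates`` maps each allowed transition to (lam, gamma) of its sojourn
    hazard (clock reset at state entry); covariate effects act
    proportionally on every transition through small coefficients on the
    standardised labs plus gender. Follow-up is administratively censored
    uniformly on (3, 6) years, emulating staggered accrual with a fixed
    study end.
    """

    n: int = 536
    rates: dict = field(
        default_factory=lambda: {
            (1, 2): (0.150, 1.10),
            (1, 4): (0.048, 1.00),
            (2, 3): (0.280, 1.10),
            (2, 4): (0.200, 1.10),
            (3, 4): (0.400, 1.10),
        }
    )
    #: effects on the linear predictor: standardised labs then male indicator
    coefs: tuple[float, ...] = (-0.15, 0.05, 0.10, -0.25, -0.05, 0.05, 0.25)
    followup_range: tuple[float, float] = (3.0, 6.0)
    male_prob: float = 0.55
    #: long-run fraction of subjects dying of each cause under the defaults
    #: (Monte-Carlo calibration of this configuration, used by checks only)
    expected_cause_fractions: tuple[float, float] = (0.289, 0.147)


CHEMO_ANALOG_CONFIG = ChemoAnalogConfig()


def _sojourn(rng, lam, gamma, eta, size):
    u = 1.0 - rng.random(size)
    return (-np.log(u) / (lam * np.exp(eta))) ** (1.0 / gamma)


def simulate_chemo_analog(
    seed=None, config: ChemoAnalogConfig = CHEMO_ANALOG_CONFIG
) -> pd.DataFrame:
    """Generate a wide four-state table shaped like a chemoradiotherapy cohort.

    Returns one row per subject with columns id, lrc_time, fp_time, dp_time,
    death_time, cause, last_followup, gender, cov1..cov6. Paths respect the
    forward-only topology; death from state 1 is competing risk 2, death
    after progression is competing risk 1.
    """
    rng = np.random.default_rng(seed)
    n = config.n
    labs = np.column_stack(
        [mean + sd * rng.standard_normal(n) for _, mean, sd in _LABS]
    )
    lab_z = (labs - labs.mean(axis=0)) / labs.std(axis=0)
    male = (rng.random(n) < config.male_prob).astype(int)
    Z = np.column_stack([lab_z, male])
    eta = Z @ np.asarray(config.coefs)
    cens = rng.uniform(*config.followup_range, size=n)

    t12 = _sojourn(rng, *config.rates[(1, 2)], eta, n)
    t14 = _sojourn(rng, *config.rates[(1, 4)], eta, n)
    t23 = _sojourn(rng, *config.rates[(2, 3)], eta, n)
    t24 = _sojourn(rng, *config.rates[(2, 4)], eta, n)
    t34 = _sojourn(rng, *config.rates[(3, 4)], eta, n)

    fp = np.full(n, np.nan)
    dp = np.full(n, np.nan)
    death = np.full(n, np.nan)
    cause = np.full(n, np.nan)
    for i in range(n):
        c = cens[i]
        # state 1
        if min(t12[i], t14[i]) > c:
            continue
        if t14[i] < t12[i]:
            death[i], cause[i] = t14[i], 2
            continue
        fp[i] = t12[i]
        # state 2 (clock reset)
        exit2 = fp[i] + min(t23[i], t24[i])
        if exit2 > c:
            continue
        if t24[i] <= t23[i]:
            death[i], cause[i] = exit2, 1
            continue
        dp[i] = exit2
        # state 3
        exit3 = dp[i] + t34[i]
        if exit3 <= c:
            death[i], cause[i] = exit3, 1
    wide = pd.DataFrame(
        {
            "id": [f"p{i + 1:04d}" for i in range(n)],
            "lrc_time": 0.0,
            "fp_time": fp,
            "dp_time": dp,
            "death_time": death,
            "cause": pd.array(
                [None if np.isnan(k) else int(k) for k in cause], dtype="Int64"
            ),
            "last_followup": cens,
            "gender": np.where(male == 1, "male", "female"),
        }
    )
    for j, (name, _, _) in enumerate(_LABS):
        wide[name] = labs[:, j]
    return wide
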