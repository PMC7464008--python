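"""Synthetic cohort generation.

Emulates every measurement channel of the study: EWA-agent choice data on
the 80-trial reversal task, questionnaire totals (CES-D, DAMS-D, PANAS
subscales), and the two interoception tasks (heartbeat counting, probe
detection).

Participant-level generative model
----------------------------------
True EWA parameters are drawn on the unconstrained scale,
``theta_i ~ Normal(mu_pop, sigma_pop)`` per parameter, and mapped to the
constrained scale by the same transforms the fitting machinery uses
(probit for alpha and rho, scaled probit for beta), so simulation and
estimation share one scale. Questionnaire and interoception measures are
tied to the parameters through a Gaussian copula: each measure's latent
score is a linear combination of the standardised parameter latents with
coefficients equal to the requested Pearson correlations, plus independent
noise, so the latent-scale correlation of each (measure, parameter) pair
equals its target exactly in expectation. Observed scores are produced
last (location/scale mapping, clipping to the instrument's range, and
integer rounding for questionnaires), so targets refer to the latent scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ewa import EWAParams, SessionData, simulate_agent
from .psychometrics import (
    HeartbeatTrial,
    ParticipantProfile,
    ProbeTrial,
    heartbeat_score,
    interoceptive_attention,
)
from .task import TaskConfig

__all__ = [
    "PARAM_NAMES",
    "MEASURE_NAMES",
    "DEFAULT_CORRELATION_TARGETS",
    "CohortSpec",
    "constrain_params",
    "simulate_cohort",
    "generate_heartbeat_trials",
    "generate_probe_trials",
]

PARAM_NAMES = ("alpha", "rho", "beta")
MEASURE_NAMES = ("ces_d", "dams_d", "panas_pa", "panas_na", "awareness", "attention")

#: Upper bound of the scaled-probit transform for beta.
BETA_SCALE = 10.0

#: Default (measure, parameter, latent Pearson r) targets, echoing the
#: salient baseline associations the task was designed to probe.
DEFAULT_CORRELATION_TARGETS: tuple[tuple[str, str, float], ...] = (
    ("dams_d", "beta", -0.419),
    ("panas_pa", "alpha", 0.368),
    ("attention", "beta", 0.361),
    ("ces_d", "beta", -0.240),
    ("awareness", "beta", 0.233),
)

# Observed-scale location/scale and admissible range per measure. The
# questionnaire moments echo typical baseline values in undergraduate
# samples; interoception moments sit where the two scorers produce them.
_MEASURE_MODELS: dict[str, dict] = {
    "ces_d": {"mean": 16.4, "sd": 9.2, "range": (0, 60), "integer": True},
    "dams_d": {"mean": 8.7, "sd": 3.6, "range": (3, 21), "integer": True},
    "panas_pa": {"mean": 29.6, "sd": 6.2, "range": (8, 48), "integer": True},
    "panas_na": {"mean": 22.6, "sd": 8.9, "range": (8, 48), "integer": True},
    "awareness": {"mean": 0.59, "sd": 0.28, "range": (0.0, 1.0), "integer": False},
    "attention": {"mean": 0.025, "sd": 0.06, "range": (-0.5, 0.5), "integer": False},
}


@dataclass
class CohortSpec:
    """Specification of a synthetic cohort.

    Population means/sds are on the unconstrained sampling scale shared
    with the hierarchical fit; the defaults place the constrained-scale
    population roughly at alpha ~ 0.63, rho ~ 0.33, beta ~ 1.5.
    """

    n_participants: int = 52
    population_means: dict[str, float] = field(
        default_factory=lambda: {"alpha": 0.332, "rho": -0.440, "beta": -1.036}
    )
    population_sds: dict[str, float] = field(
        default_factory=lambda: {"alpha": 0.50, "rho": 0.55, "beta": 0.20}
    )
    correlation_targets: tuple[tuple[str, str, float], ...] = DEFAULT_CORRELATION_TARGETS
    group_ratio: float = 27 / 52
    task: TaskConfig = field(default_factory=TaskConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be at least 2")
        for m, p, r in self.correlation_targets:
            if m not in _MEASURE_MODELS:
                raise ValueError(f"unknown measure {m!r}")
            if p not in PARAM_NAMES:
                raise ValueError(f"unknown parameter {p!r}")
            if abs(r) > 1:
                raise ValueError(f"correlation target |r| > 1 for ({m}, {p})")
        # Each measure's loadings must fit inside a unit-variance latent.
        for m in MEASURE_NAMES:
            ssq = sum(r**2 for mm, _, r in self.correlation_targets if mm == m)
            if ssq > 1.0:
                raise ValueError(
                    f"correlation targets for {m!r} are infeasible (sum of r^2 = {ssq:.3f} > 1)"
                )


def constrain_params(theta: np.ndarray) -> np.ndarray:
    """Map unconstrained (..., 3) parameter draws to (alpha, rho, beta)."""
    from scipy.stats import norm

    out = norm.cdf(np.asarray(theta, dtype=float))
    out[..., 2] *= BETA_SCALE
    return out


def generate_heartbeat_trials(
    true_awareness: float,
    rng: np.random.Generator,
    durations: tuple[float, ...] = (25.0, 35.0, 45.0),
    heart_rate_bpm: float = 70.0,
    error_shape: float = 25.0,
) -> list[HeartbeatTrial]:
    """Generate heartbeat-counting trials with a known expected accuracy.

    The per-trial relative miscount is ``(1 - true_awareness)`` times a
    mean-one gamma multiplier with a random sign, so the expected Schandry
    accuracy score equals ``true_awareness``. Perfect awareness yields
    reported == actual exactly.
    """
    if not 0.0 <= true_awareness <= 1.0:
        raise ValueError("true_awareness must be in [0, 1]")
    trials = []
    for d in durations:
        actual = int(round(d * heart_rate_bpm / 60.0))
        if true_awareness == 1.0:
            reported = actual
        else:
            frac = (1.0 - true_awareness) * rng.gamma(error_shape, 1.0 / error_shape)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            reported = max(0, int(round(actual * (1.0 - sign * frac))))
        trials.append(HeartbeatTrial(d, actual, reported))
    return trials


def generate_probe_trials(
    true_attention: float,
    rng: np.random.Generator,
    base_rt: float = 0.43,
    noise_sd: float = 0.05,
    outlier_rate: float = 0.02,
    n_blocks: int = 4,
    trials_per_block: int = 36,
    emotion_blocks: tuple[str, ...] = ("anger", "happiness", "neutrality", "disgust"),
) -> list[ProbeTrial]:
    """Generate probe-detection trials with a known attention advantage.

    Half the trials in each block carry an internal probe, half an
    external one; internal reaction times average ``true_attention``
    seconds below external ones. Gross lapse outliers (an extra 1-3 s) are
    injected at ``outlier_rate`` to exercise the Grubbs filter.
    """
    soas = (2.25, 3.0, 3.75)
    trials: list[ProbeTrial] = []
    half = trials_per_block // 2
    for b in range(n_blocks):
        emotion = emotion_blocks[b % len(emotion_blocks)]
        for k in range(trials_per_block):
            probe = "internal" if k < half else "external"
            mean = base_rt - true_attention if probe == "internal" else base_rt
            rt = mean + noise_sd * rng.standard_normal()
            if outlier_rate > 0 and rng.random() < outlier_rate:
                rt += rng.uniform(1.0, 3.0)
            rt = max(rt, 0.01)
            trials.append(ProbeTrial(probe, rt, emotion, soas[k % 3]))
    return trials


def _measure_latents(
    spec: CohortSpec, z_params: np.ndarray, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Standard-normal measure latents with the requested parameter loadings."""
    n = z_params.shape[0]
    loadings = {m: np.zeros(len(PARAM_NAMES)) for m in MEASURE_NAMES}
    for m, p, r in spec.correlation_targets:
        loadings[m][PARAM_NAMES.index(p)] += r
    out = {}
    for m in MEASURE_NAMES:
        lam = loadings[m]
        resid = math.sqrt(max(0.0, 1.0 - float(lam @ lam)))
        out[m] = z_params @ lam + resid * rng.standard_normal(n)
    return out


def simulate_cohort(
    spec: CohortSpec,
) -> tuple[list[SessionData], list[ParticipantProfile], pd.DataFrame]:
    """Simulate a full cohort: sessions, measured profiles, and ground truth.

    Returns
    -------
    sessions
        One EWA-agent session per participant on the configured task.
    profiles
        Measured questionnaire totals and interoception scores (the
        interoception entries are *scored from generated trials*, not the
        latent truths).
    truth
        DataFrame with the true parameters (both scales), the latent
        measure scores, and the latent interoception truths, for
        recovery/calibration analyses.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_participants
    mu = np.array([spec.population_means[p] for p in PARAM_NAMES])
    sd = np.array([spec.population_sds[p] for p in PARAM_NAMES])
    z_params = rng.standard_normal((n, 3))
    theta = mu + sd * z_params
    constrained = constrain_params(theta)

    latents = _measure_latents(spec, z_params, rng)

    # Observed questionnaire totals: location/scale, clip, round.
    observed: dict[str, np.ndarray] = {}
    for m in ("ces_d", "dams_d", "panas_pa", "panas_na"):
        model = _MEASURE_MODELS[m]
        x = model["mean"] + model["sd"] * latents[m]
        lo, hi = model["range"]
        observed[m] = np.clip(np.rint(x), lo, hi).astype(int)

    aw_model = _MEASURE_MODELS["awareness"]
    true_awareness = np.clip(
        aw_model["mean"] + aw_model["sd"] * latents["awareness"], 0.0, 1.0
    )
    at_model = _MEASURE_MODELS["attention"]
    true_attention = at_model["mean"] + at_model["sd"] * latents["attention"]

    n_exp = int(round(spec.group_ratio * n))
    groups = np.array(["experimental"] * n_exp + ["control"] * (n - n_exp))
    rng.shuffle(groups)

    sessions: list[SessionData] = []
    profiles: list[ParticipantProfile] = []
    rows = []
    for i in range(n):
        pid = f"P{i + 1:03d}"
        params = EWAParams(*constrained[i])
        session = simulate_agent(params, spec.task, rng)
        session.participant_id = pid
        sessions.append(session)

        hb = generate_heartbeat_trials(float(true_awareness[i]), rng)
        pr = generate_probe_trials(float(true_attention[i]), rng)
        profiles.append(
            ParticipantProfile(
                participant_id=pid,
                group=str(groups[i]),
                ces_d=int(observed["ces_d"][i]),
                dams_d=int(observed["dams_d"][i]),
                panas_pa=int(observed["panas_pa"][i]),
                panas_na=int(observed["panas_na"][i]),
                awareness=heartbeat_score(hb),
                attention=interoceptive_attention(pr),
                age=float(np.clip(24.5 + 6.0 * rng.standard_normal(), 18, 65)),
                gender="woman" if rng.random() < 37 / 52 else "man",
            )
        )
        rows.append(
            {
                "participant_id": pid,
                "alpha": constrained[i, 0],
                "rho": constrained[i, 1],
                "beta": constrained[i, 2],
                "theta_alpha": theta[i, 0],
                "theta_rho": theta[i, 1],
                "theta_beta": theta[i, 2],
                **{f"latent_{m}": latents[m][i] for m in MEASURE_NAMES},
                "true_awareness": true_awareness[i],
                "true_attention": true_attention[i],
            }
        )
    return sessions, profiles, pd.DataFrame(rows)
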