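"""Generative observer models of action/outcome timing reports.

Implements the thirteen observer models used to explain intentional
binding in the Libet-clock paradigm: eight Bayesian causal-inference
(BCI) variants crossing two temporal priors (unity vs. coupling) with
four decision strategies (joint posterior, model selection, model
averaging, probability matching), two mandatory-integration models,
a fixed-criterion averaging model, a false-report lapse model, and a
no-binding null model.

All timing quantities are milliseconds in an operant frame where the
action occurs at time 0 and the outcome at ``t_AO``.  An observer's
noisy percepts are

    tau_A ~ N(b_A, sigma_A^2),    tau_O ~ N(t_AO + b_O, sigma_O^2),

where ``b`` and ``sigma`` are per-event report bias and sensory noise,
estimated from single-event baseline blocks.  Under the causal scenario
(xi = 1) the observer holds a Gaussian coupling prior over the
action-outcome interval with mean ``mu_AO`` and SD ``sigma_AO``; under
the acausal scenario (xi = 0) the joint timing prior is flat over a
normalization range ``T``.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy.special import expit

__all__ = [
    "PARAM_BOUNDS",
    "ObserverParams",
    "FreeParams",
    "ModelSpec",
    "PerceptPair",
    "ConditionalEstimates",
    "MODELS",
    "MODEL_IDS",
    "RECOVERY_MODEL_IDS",
    "DEFAULT_BASELINES",
    "get_model",
    "sample_percepts",
    "conditional_estimates",
    "marginal_causal_posterior",
    "joint_posterior_ratio",
    "respond",
]

#: Uniform search/sampling ranges for the free parameters (ms where timed).
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "p_causal": (0.0, 1.0),
    "mu_AO": (0.0, 500.0),
    "phi": (0.0, 1000.0),
    "p_fr": (0.0, 1.0),
}


@dataclass(frozen=True)
class ObserverParams:
    """Fixed sensory parameters of one observer.

    ``b_A``/``b_O`` are report biases and ``sigma_A``/``sigma_O``
    sensory noise SDs for action and outcome (ms); ``sigma_AO`` is the
    SD of the coupling prior and ``T`` the normalization range of the
    flat acausal prior.  The latter two are fixed constants of the
    model family, not fitted.
    """

    b_A: float
    sigma_A: float
    b_O: float
    sigma_O: float
    sigma_AO: float = 10.0
    T: float = 250.0

    def __post_init__(self) -> None:
        for name in ("sigma_A", "sigma_O", "sigma_AO", "T"):
            value = getattr(self, name)
            if not (np.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be positive, got {value!r}")

    @property
    def sigma_tot_sq(self) -> float:
        """Total variance sigma_A^2 + sigma_O^2 + sigma_AO^2."""
        return self.sigma_A**2 + self.sigma_O**2 + self.sigma_AO**2


#: Baseline biases/noises of the study's average observer (ms).
DEFAULT_BASELINES = ObserverParams(b_A=-52.22, sigma_A=61.56, b_O=18.27, sigma_O=61.56)


@dataclass(frozen=True)
class FreeParams:
    """Free parameters of an observer model; fields are ``None`` when the
    owning model does not use them.

    ``p_causal``: prior causal probability P(xi=1); ``mu_AO``: coupling
    prior mean (ms); ``phi``: fixed integration criterion (ms);
    ``p_fr``: per-trial probability of reporting the non-target event.
    """

    p_causal: float | None = None
    mu_AO: float | None = None
    phi: float | None = None
    p_fr: float | None = None

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if value is None:
                continue
            lo, hi = PARAM_BOUNDS[f.name]
            if not (lo <= value <= hi):
                raise ValueError(
                    f"{f.name}={value!r} outside allowed range [{lo}, {hi}]"
                )

    def as_dict(self) -> dict[str, float]:
        return {
            f.name: getattr(self, f.name)
            for f in fields(self)
            if getattr(self, f.name) is not None
        }


@dataclass(frozen=True)
class ModelSpec:
    """Identity of one observer model.

    ``prior_type`` is ``"unity"`` (mu_AO fixed at 0), ``"coupling"``
    (mu_AO free unless the strategy is mandatory integration, where it
    is still free) or ``None`` for the non-Bayesian models.
    """

    id: str
    prior_type: str | None
    strategy: str
    free_param_names: tuple[str, ...]

    @property
    def n_free(self) -> int:
        return len(self.free_param_names)

    @property
    def is_bayesian(self) -> bool:
        return self.strategy in (
            "joint_posterior",
            "model_selection",
            "model_averaging",
            "probability_matching",
            "mandatory",
        )

    def bounds(self) -> list[tuple[float, float]]:
        return [PARAM_BOUNDS[name] for name in self.free_param_names]

    def free_from_vector(self, theta) -> FreeParams:
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        if theta.size != self.n_free:
            raise ValueError(
                f"model {self.id} expects {self.n_free} parameters, got {theta.size}"
            )
        return FreeParams(**dict(zip(self.free_param_names, theta)))

    def validate_free(self, free: FreeParams) -> None:
        for name in self.free_param_names:
            if getattr(free, name) is None:
                raise ValueError(f"model {self.id} requires free parameter {name!r}")

    def effective_prior(self, free: FreeParams) -> tuple[float, float]:
        """(p_causal, mu_AO) actually used by the Bayesian machinery,
        applying the fixed values implied by the model identity."""
        p_causal = 1.0 if self.strategy == "mandatory" else free.p_causal
        mu_AO = 0.0 if self.prior_type == "unity" else free.mu_AO
        if p_causal is None or mu_AO is None:
            raise ValueError(f"model {self.id} is missing a required free parameter")
        return float(p_causal), float(mu_AO)


def _build_registry() -> dict[str, ModelSpec]:
    specs = []
    strategies = {
        "JP": "joint_posterior",
        "MS": "model_selection",
        "MA": "model_averaging",
        "PM": "probability_matching",
    }
    for code, strategy in strategies.items():
        specs.append(ModelSpec(code + "up", "unity", strategy, ("p_causal",)))
        specs.append(ModelSpec(code + "cp", "coupling", strategy, ("p_causal", "mu_AO")))
    specs.append(ModelSpec("MIup", "unity", "mandatory", ()))
    specs.append(ModelSpec("MIcp", "coupling", "mandatory", ("mu_AO",)))
    specs.append(ModelSpec("FC", None, "fixed_criterion", ("phi",)))
    specs.append(ModelSpec("FR", None, "false_report", ("p_fr",)))
    specs.append(ModelSpec("NULL", None, "null", ()))
    return {spec.id: spec for spec in specs}


MODELS: dict[str, ModelSpec] = _build_registry()

#: The 12 candidate models compared in the recovery analyses (NULL excluded).
RECOVERY_MODEL_IDS: tuple[str, ...] = tuple(m for m in MODELS if m != "NULL")

#: All 13 model ids (12 candidates + NULL).
MODEL_IDS: tuple[str, ...] = tuple(MODELS)


def get_model(model: str | ModelSpec) -> ModelSpec:
    if isinstance(model, ModelSpec):
        return model
    try:
        return MODELS[model]
    except KeyError:
        raise KeyError(
            f"unknown model {model!r}; known ids: {', '.join(MODELS)}"
        ) from None


@dataclass(frozen=True)
class PerceptPair:
    """Noisy percepts (tau_A, tau_O); fields may be scalars or arrays."""

    tau_A: np.ndarray | float
    tau_O: np.ndarray | float


@dataclass(frozen=True)
class ConditionalEstimates:
    """MAP timing estimates conditional on the causal scenario.

    Under xi=1 the estimates shift toward each other by the
    reliability-weighted discrepancy from the prior interval; under
    xi=0 they equal the raw percepts.
    """

    t_hat_A_causal: np.ndarray | float
    t_hat_O_causal: np.ndarray | float
    t_hat_A_acausal: np.ndarray | float
    t_hat_O_acausal: np.ndarray | float


def sample_percepts(
    params: ObserverParams,
    t_AO: float,
    n: int,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> PerceptPair:
    """Draw ``n`` independent percept pairs for one condition.

    tau_A ~ N(b_A, sigma_A^2) and tau_O ~ N(t_AO + b_O, sigma_O^2),
    with the action anchored at time 0.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    tau_A = rng.normal(params.b_A, params.sigma_A, size=n)
    tau_O = rng.normal(t_AO + params.b_O, params.sigma_O, size=n)
    return PerceptPair(tau_A=tau_A, tau_O=tau_O)


def conditional_estimates(
    pp: PerceptPair, params: ObserverParams, mu_AO: float
) -> ConditionalEstimates:
    """MAP estimates under each causal scenario.

    Causal: t_hat_A = tau_A + (sigma_A^2/sigma_tot^2) d and
    t_hat_O = tau_O - (sigma_O^2/sigma_tot^2) d with
    d = tau_O - tau_A - mu_AO; acausal: the raw percepts.
    """
    d = np.asarray(pp.tau_O) - np.asarray(pp.tau_A) - mu_AO
    st2 = params.sigma_tot_sq
    return ConditionalEstimates(
        t_hat_A_causal=pp.tau_A + (params.sigma_A**2 / st2) * d,
        t_hat_O_causal=pp.tau_O - (params.sigma_O**2 / st2) * d,
        t_hat_A_acausal=np.asarray(pp.tau_A) + 0.0,
        t_hat_O_acausal=np.asarray(pp.tau_O) + 0.0,
    )


def _causal_log_odds(pp, params, p_causal, mu_AO, scale_sigma):
    # log[p/(1-p)] + log[T / (sqrt(2 pi) scale)] - d^2 / (2 sigma_tot^2)
    # With scale = sigma_tot this is the marginal-posterior log-odds of
    # xi=1; with scale = sigma_AO it is the log of the joint-posterior
    # peak ratio r. Boundary priors map to -inf/+inf rather than erroring.
    d = np.asarray(pp.tau_O, dtype=float) - np.asarray(pp.tau_A, dtype=float) - mu_AO
    if not 0.0 <= p_causal <= 1.0:
        raise ValueError(f"p_causal must lie in [0, 1], got {p_causal!r}")
    with np.errstate(divide="ignore"):
        prior_odds = np.log(p_causal) - np.log1p(-p_causal)
    const = np.log(params.T / (np.sqrt(2.0 * np.pi) * scale_sigma))
    return prior_odds + const - d**2 / (2.0 * params.sigma_tot_sq)


def marginal_causal_posterior(
    pp: PerceptPair, params: ObserverParams, p_causal: float, mu_AO: float
):
    """Posterior probability P(xi=1 | tau_A, tau_O).

    Depends on the percepts only through the discrepancy
    d = tau_O - tau_A - mu_AO; its complement is 1 - the returned value
    by construction.
    """
    sigma_tot = np.sqrt(params.sigma_tot_sq)
    return expit(_causal_log_odds(pp, params, p_causal, mu_AO, sigma_tot))


def joint_posterior_ratio(
    pp: PerceptPair, params: ObserverParams, p_causal: float, mu_AO: float
):
    """Ratio r of the causal to acausal joint-posterior peak values.

    r > 1 selects the causal MAP estimates.  At the prior boundaries
    the ratio degenerates: p_causal=0 gives r=0, p_causal=1 gives
    r=+inf; both are returned as such, not raised.
    """
    return np.exp(_causal_log_odds(pp, params, p_causal, mu_AO, params.sigma_AO))


def respond(
    model: str | ModelSpec,
    free: FreeParams,
    pp: PerceptPair,
    params: ObserverParams,
    target: str,
    u,
):
    """The model's reported time (ms) of the target event for each percept pair.

    ``u`` is one uniform draw per trial; it drives the stochastic
    scenario choice of probability matching and the report swap of the
    false-report model and is ignored by the deterministic strategies.
    """
    model = get_model(model)
    model.validate_free(free)
    if target not in ("action", "outcome"):
        raise ValueError(f"target must be 'action' or 'outcome', got {target!r}")
    is_action = target == "action"
    tau_t = np.asarray(pp.tau_A if is_action else pp.tau_O, dtype=float)
    tau_other = np.asarray(pp.tau_O if is_action else pp.tau_A, dtype=float)
    u = np.asarray(u, dtype=float)

    strategy = model.strategy
    if strategy == "null":
        return tau_t + 0.0
    if strategy == "false_report":
        return np.where(u < free.p_fr, tau_other, tau_t)
    if strategy == "fixed_criterion":
        integrate = (np.asarray(pp.tau_O) - np.asarray(pp.tau_A)) <= free.phi
        midpoint = (np.asarray(pp.tau_A) + np.asarray(pp.tau_O)) / 2.0
        return np.where(integrate, midpoint, tau_t)

    p_causal, mu_AO = model.effective_prior(free)
    est = conditional_estimates(pp, params, mu_AO)
    causal = np.asarray(est.t_hat_A_causal if is_action else est.t_hat_O_causal)
    if strategy == "mandatory":
        return causal + 0.0
    if strategy == "model_averaging":
        w = marginal_causal_posterior(pp, params, p_causal, mu_AO)
        return w * causal + (1.0 - w) * tau_t
    if strategy == "joint_posterior":
        take = _causal_log_odds(pp, params, p_causal, mu_AO, params.sigma_AO) > 0.0
    elif strategy == "model_selection":
        take = marginal_causal_posterior(pp, params, p_causal, mu_AO) > 0.5
    elif strategy == "probability_matching":
        take = marginal_causal_posterior(pp, params, p_causal, mu_AO) > u
    else:  # pragma: no cover - registry is closed
        raise ValueError(f"unknown strategy {strategy!r}")
    return np.where(take, causal, tau_t)
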