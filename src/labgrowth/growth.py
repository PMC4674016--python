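"""Bayesian three-class unit-error mixture growth model for dog heights.

Owner-reported shoulder heights follow a monomolecular (saturating
exponential) growth curve

    mu(age) = a * (1 - exp(-b * (age + c)))

with ``a`` the asymptotic mean height (cm), ``b`` the growth rate per day
(the gap to ``a`` halves every ln2/b days) and ``c`` an age offset giving a
non-zero height at birth.  Each stored height additionally belongs to one of
three latent unit-error classes (see :mod:`labgrowth.units`): entered in the
wrong field so the stored value is 2.54x too large, correct, or 2.54x too
small.  Observed heights are normally distributed around the class-distorted
mean with a common precision tau:

    h_i ~ Normal(mu(age_i) * m_{class_i}, 1/tau)
    class_i ~ Categorical(pi)

Priors: a ~ N(56, precision 0.01) centred on the Kennel Club breed standard,
b ~ U(0, 1.5), c ~ U(0, 100), tau ~ Gamma(0.001, 0.001) and
pi ~ Dirichlet(0.1, 0.8, 0.1).  Each sex is fitted separately.

Inference is Metropolis-within-Gibbs: exact Gibbs draws for the class
indicators, conjugate updates for a (normal), tau (gamma) and pi
(Dirichlet), and reflecting random-walk Metropolis steps for b and c whose
proposal scales are tuned during a discarded adaptation phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .units import CLASS_LABELS, CLASS_MEAN_MULTIPLIERS, correction_multiplier

__all__ = [
    "GrowthParams",
    "ClassModel",
    "PriorSpec",
    "MCMCConfig",
    "PosteriorResult",
    "TABLE_PARAMS",
    "BREED_STANDARD_CM",
    "filter_extreme_heights",
    "mean_height",
    "log_likelihood",
    "class_conditional_posterior",
    "sample_posterior",
    "classify_and_correct",
    "breed_standard_fraction",
    "convergence_diagnostics",
]


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of the saturating growth curve plus observation noise."""

    a: float  # asymptotic mean height, cm
    b: float  # growth rate, 1/day
    c: float  # age offset, days
    sd: float  # observation noise sd, cm

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("a must be positive")
        if not 0 <= self.b <= 1.5:
            raise ValueError("b must lie in [0, 1.5]")
        if not 0 <= self.c <= 100:
            raise ValueError("c must lie in [0, 100]")
        if self.sd <= 0:
            raise ValueError("sd must be positive")

    @property
    def tau(self) -> float:
        """Noise precision, 1/sd^2."""
        return 1.0 / self.sd**2

    @property
    def half_life_days(self) -> float:
        """Days for the gap to the asymptote to halve: ln2/b."""
        return float(np.log(2.0) / self.b)


#: Published posterior means per sex; used as synthetic-cohort ground truth.
TABLE_PARAMS: Mapping[str, GrowthParams] = {
    "female": GrowthParams(a=55.1, b=0.0132, c=7.03, sd=4.67),
    "male": GrowthParams(a=59.0, b=0.0126, c=9.37, sd=5.01),
}

#: UK Kennel Club ideal height band (cm) for Labrador Retrievers, per sex.
BREED_STANDARD_CM: Mapping[str, tuple[float, float]] = {
    "female": (55.0, 56.0),
    "male": (56.0, 57.0),
}


@dataclass(frozen=True)
class ClassModel:
    """The three unit-error classes with their fixed mean multipliers."""

    labels: tuple[str, str, str] = CLASS_LABELS
    mean_multipliers: tuple[float, float, float] = CLASS_MEAN_MULTIPLIERS
    pi: tuple[float, float, float] = (0.1, 0.8, 0.1)

    def __post_init__(self) -> None:
        if len(self.pi) != 3 or not np.isclose(sum(self.pi), 1.0):
            raise ValueError("pi must be a probability 3-vector")


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the published priors (precision parameterization)."""

    a_mean: float = 56.0
    a_precision: float = 0.01  # prior sd = 10 cm
    b_range: tuple[float, float] = (0.0, 1.5)
    c_range: tuple[float, float] = (0.0, 100.0)
    tau_shape: float = 0.001
    tau_rate: float = 0.001
    dirichlet_alpha: tuple[float, float, float] = (0.1, 0.8, 0.1)


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler schedule: adaptation, burn-in and retained iterations."""

    n_adapt: int = 1000
    n_burn: int = 2000
    n_keep: int = 5000
    seed: int = 0
    proposal_scales: Mapping[str, float] = field(
        default_factory=lambda: {"b": 1e-3, "c": 3.0}
    )

    def __post_init__(self) -> None:
        if min(self.n_adapt, self.n_burn) < 0 or self.n_keep < 1:
            raise ValueError("iteration counts must be nonnegative, n_keep >= 1")


@dataclass
class PosteriorResult:
    """Chains, per-observation class posteriors and sampler diagnostics."""

    chains: dict[str, np.ndarray]  # keys a,b,c,tau,sd (n_keep,) and pi (n_keep,3)
    class_post: np.ndarray  # (n_obs, 3) posterior class-membership frequencies
    acceptance: dict[str, float]
    proposal_scales: dict[str, float]
    n_obs: int
    seed: int

    @property
    def n_misreported(self) -> int:
        """Observations whose most probable class is not 'ok'."""
        return int(np.sum(np.argmax(self.class_post, axis=1) != 1))

    def posterior_mean(self, name: str) -> float:
        return float(np.mean(self.chains[name]))

    def credible_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        lo = (1.0 - level) / 2.0
        q = np.quantile(self.chains[name], [lo, 1.0 - lo])
        return float(q[0]), float(q[1])

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in ("a", "b", "c", "tau", "sd"):
            lo, hi = self.credible_interval(name)
            rows.append({"param": name, "mean": self.posterior_mean(name),
                         "ci_lower": lo, "ci_upper": hi})
        pi = self.chains["pi"]
        for k, lab in enumerate(CLASS_LABELS):
            q = np.quantile(pi[:, k], [0.025, 0.975])
            rows.append({"param": f"pi_{lab}", "mean": float(pi[:, k].mean()),
                         "ci_lower": float(q[0]), "ci_upper": float(q[1])})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# deterministic pieces


def filter_extreme_heights(
    observations: pd.DataFrame, threshold: float = 1.0
) -> tuple[pd.DataFrame, pd.DataFrame, list]:
    """Drop physically impossible stored heights (zero or one cm by default).

    Returns ``(kept, removed, fully_removed_dogs)`` where the last element
    lists dog ids that lost every observation.
    """
    h = observations["height_recorded_cm"].to_numpy(dtype=float)
    mask = h > threshold
    kept = observations.loc[mask]
    removed = observations.loc[~mask]
    fully_removed = sorted(
        set(observations["dog_id"]) - set(kept["dog_id"])
    )
    return kept, removed, fully_removed


def mean_height(age_days, params: GrowthParams):
    """Expected true height mu(age) = a*(1 - exp(-b*(age + c))).

    The class multiplier is applied by the caller.  Strictly increasing in
    age (for b > 0) and bounded above by ``a``.
    """
    age = np.asarray(age_days, dtype=float)
    if np.any(age < 0):
        raise ValueError("age_days must be nonnegative")
    out = params.a * (1.0 - np.exp(-params.b * (age + params.c)))
    return out if out.ndim else float(out)


def _component_logpdfs(h, age, params: GrowthParams, class_model: ClassModel):
    """(3, n) log-density of each observation under each error class."""
    mu = mean_height(age, params)
    m = np.asarray(class_model.mean_multipliers)[:, None]
    resid = np.asarray(h)[None, :] - np.atleast_1d(mu)[None, :] * m
    tau = params.tau
    return 0.5 * np.log(tau / (2.0 * np.pi)) - 0.5 * tau * resid**2


def log_likelihood(
    observations: pd.DataFrame, params: GrowthParams, class_model: ClassModel
) -> float:
    """Log marginal likelihood over classes: sum_i log sum_k pi_k N_k(h_i)."""
    h = observations["height_recorded_cm"].to_numpy(dtype=float)
    age = observations["age_days"].to_numpy(dtype=float)
    logp = _component_logpdfs(h, age, params, class_model)
    with np.errstate(divide="ignore"):
        logpi = np.log(np.asarray(class_model.pi))[:, None]
    from scipy.special import logsumexp

    return float(np.sum(logsumexp(logp + logpi, axis=0)))


def class_conditional_posterior(
    height_cm, age_days, params: GrowthParams, class_model: ClassModel
) -> np.ndarray:
    """Exact full conditional of the latent class indicator.

    p_k  propto  pi_k * Normal(h; mu(age)*m_k, 1/tau), normalized.  Accepts
    scalars or arrays; returns shape (3,) or (n, 3).
    """
    h = np.atleast_1d(np.asarray(height_cm, dtype=float))
    age = np.atleast_1d(np.asarray(age_days, dtype=float))
    logp = _component_logpdfs(h, age, params, class_model)
    with np.errstate(divide="ignore"):  # log(0) = -inf for degenerate pi
        logp = logp + np.log(np.asarray(class_model.pi))[:, None]
    logp -= logp.max(axis=0, keepdims=True)
    p = np.exp(logp)
    p /= p.sum(axis=0, keepdims=True)
    out = p.T
    return out[0] if np.isscalar(height_cm) or np.ndim(height_cm) == 0 else out


# ---------------------------------------------------------------------------
# sampler


def _reflect(x: float, lo: float, hi: float) -> float:
    """Fold a proposal back into [lo, hi] (symmetric, preserves detailed balance)."""
    width = hi - lo
    x = (x - lo) % (2.0 * width)
    return lo + (width - abs(x - width) if x > width else x)


def sample_posterior(
    observations: pd.DataFrame,
    priors: PriorSpec | None = None,
    mcmc: MCMCConfig | None = None,
    class_model: ClassModel | None = None,
    fixed: Mapping[str, object] | None = None,
) -> PosteriorResult:
    """Fit the mixture growth model to one sex's observations by MCMC.

    ``observations`` needs columns ``age_days`` and ``height_recorded_cm``
    and must contain a single sex (enforced if a ``sex`` column is present).
    ``fixed`` may pin any of ``b``, ``c``, ``pi`` or ``classes`` (an integer
    array) at given values — a diagnostic hook used to compare the sampler
    against low-dimensional numerical posteriors.
    """
    priors = priors or PriorSpec()
    mcmc = mcmc or MCMCConfig()
    class_model = class_model or ClassModel()
    fixed = dict(fixed or {})

    if len(observations) == 0:
        raise ValueError("no observations to fit")
    if "sex" in observations.columns and observations["sex"].nunique() > 1:
        raise ValueError("sample_posterior fits a single sex; split the data first")

    h = observations["height_recorded_cm"].to_numpy(dtype=float)
    age = observations["age_days"].to_numpy(dtype=float)
    n = h.size
    m = np.asarray(class_model.mean_multipliers)
    alpha = np.asarray(priors.dirichlet_alpha, dtype=float)
    b_lo, b_hi = priors.b_range
    c_lo, c_hi = priors.c_range

    rng = np.random.default_rng(mcmc.seed)

    # Moderate starting values; b near typical juvenile growth rates so the
    # curve is not saturated at recruitment ages.
    a = priors.a_mean
    b = float(fixed.get("b", 0.01))
    c = float(fixed.get("c", 10.0))
    tau = 1.0 / 25.0
    pi = np.asarray(fixed.get("pi", alpha / alpha.sum()), dtype=float)
    g = 1.0 - np.exp(-b * (age + c))

    classes = fixed.get("classes")
    if classes is not None:
        classes = np.asarray(classes, dtype=np.intp)
    else:
        classes = np.ones(n, dtype=np.intp)

    scales = {"b": float(mcmc.proposal_scales.get("b", 1e-3)),
              "c": float(mcmc.proposal_scales.get("c", 3.0))}
    fix_b = "b" in fixed
    fix_c = "c" in fixed
    fix_pi = "pi" in fixed
    fix_classes = "classes" in fixed

    n_total = mcmc.n_adapt + mcmc.n_burn + mcmc.n_keep
    keep_from = mcmc.n_adapt + mcmc.n_burn
    out = {k: np.empty(mcmc.n_keep) for k in ("a", "b", "c", "tau")}
    out_pi = np.empty((mcmc.n_keep, 3))
    class_counts = np.zeros((n, 3))
    acc = {"b": 0, "c": 0}
    prop = {"b": 0, "c": 0}
    adapt_acc = {"b": 0, "c": 0}
    adapt_prop = {"b": 0, "c": 0}
    ADAPT_BATCH = 50
    rows = np.arange(n)

    for it in range(n_total):
        adapting = it < mcmc.n_adapt

        # -- latent classes: exact Gibbs
        if not fix_classes:
            mu = a * g
            resid = h[None, :] - mu[None, :] * m[:, None]
            logp = np.log(pi)[:, None] - 0.5 * tau * resid**2
            logp -= logp.max(axis=0, keepdims=True)
            p = np.exp(logp)
            p /= p.sum(axis=0, keepdims=True)
            u = rng.random(n)
            classes = (np.cumsum(p, axis=0) < u[None, :]).sum(axis=0)
            classes = np.minimum(classes, 2)

        x = g * m[classes]  # design vector: h_i ~ N(a * x_i, 1/tau)

        # -- asymptote a: conjugate normal
        prec = priors.a_precision + tau * x @ x
        mean = (priors.a_precision * priors.a_mean + tau * x @ h) / prec
        a = rng.normal(mean, 1.0 / np.sqrt(prec))

        # -- growth rate b and offset c: reflecting random-walk Metropolis
        r = h - a * x
        ll = -0.5 * tau * (r @ r)
        for name, fix in (("b", fix_b), ("c", fix_c)):
            if fix:
                continue
            if name == "b":
                cand = _reflect(b + scales["b"] * rng.standard_normal(), b_lo, b_hi)
                g_cand = 1.0 - np.exp(-cand * (age + c))
            else:
                cand = _reflect(c + scales["c"] * rng.standard_normal(), c_lo, c_hi)
                g_cand = 1.0 - np.exp(-b * (age + cand))
            r_cand = h - a * g_cand * m[classes]
            ll_cand = -0.5 * tau * (r_cand @ r_cand)
            prop[name] += 0 if adapting else 1
            adapt_prop[name] += 1 if adapting else 0
            if np.log(rng.random()) < ll_cand - ll:
                if name == "b":
                    b = cand
                else:
                    c = cand
                g, ll = g_cand, ll_cand
                x = g * m[classes]
                acc[name] += 0 if adapting else 1
                adapt_acc[name] += 1 if adapting else 0

        # -- noise precision tau: conjugate gamma
        r = h - a * x
        tau = rng.gamma(priors.tau_shape + 0.5 * n,
                        1.0 / (priors.tau_rate + 0.5 * (r @ r)))

        # -- mixing weights pi: conjugate Dirichlet
        if not fix_pi:
            counts = np.bincount(classes, minlength=3)
            pi = rng.dirichlet(alpha + counts)

        # -- proposal-scale adaptation (discarded phase only)
        if adapting and (it + 1) % ADAPT_BATCH == 0:
            for name in ("b", "c"):
                if adapt_prop[name] == 0:
                    continue
                rate = adapt_acc[name] / adapt_prop[name]
                scales[name] *= float(np.exp(1.5 * (rate - 0.3)))
                adapt_acc[name] = adapt_prop[name] = 0

        if it >= keep_from:
            j = it - keep_from
            out["a"][j], out["b"][j], out["c"][j], out["tau"][j] = a, b, c, tau
            out_pi[j] = pi
            class_counts[rows, classes] += 1.0

    chains = {**out, "sd": 1.0 / np.sqrt(out["tau"]), "pi": out_pi}
    acceptance = {
        name: (acc[name] / prop[name]) if prop[name] else float("nan")
        for name in ("b", "c")
    }
    return PosteriorResult(
        chains=chains,
        class_post=class_counts / mcmc.n_keep,
        acceptance=acceptance,
        proposal_scales=dict(scales),
        n_obs=n,
        seed=mcmc.seed,
    )


# ---------------------------------------------------------------------------
# post-processing


def classify_and_correct(
    observations: pd.DataFrame,
    result: PosteriorResult,
    threshold: float = 0.5,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Assign each observation its most probable class and correct the height.

    Ties go to ``ok``; a non-``ok`` assignment additionally requires its
    posterior probability to reach ``threshold``, otherwise the observation
    falls back to ``ok`` (never correct without posterior support).  Returns
    the observations with ``class_label``, ``multiplier_applied`` and
    ``height_corrected_cm`` columns appended, plus per-class assignment
    counts.
    """
    post = np.asarray(result.class_post)
    if len(post) != len(observations):
        raise ValueError("class posteriors do not match the observations")
    best = np.argmax(post, axis=1)
    best_p = post[np.arange(len(post)), best]
    # argmax breaks ties toward the lowest index; force exact ties to "ok"
    ties = post.max(axis=1, keepdims=True) == post
    best = np.where(ties.sum(axis=1) > 1, 1, best)
    best = np.where((best != 1) & (best_p < threshold), 1, best)

    labels = np.asarray(CLASS_LABELS)[best]
    mult = np.asarray([correction_multiplier(lab) for lab in CLASS_LABELS])[best]
    corrected = observations.copy()
    corrected["class_label"] = labels
    corrected["multiplier_applied"] = mult
    corrected["height_corrected_cm"] = (
        corrected["height_recorded_cm"].to_numpy(dtype=float) * mult
    )
    report = {lab: int(np.sum(labels == lab)) for lab in CLASS_LABELS}
    return corrected, report


def breed_standard_fraction(
    corrected: pd.DataFrame,
    sex: str,
    min_age_days: float = 365.0,
    level: float = 0.95,
):
    """Fraction of corrected measurements inside the breed-standard band.

    Considers measurements of the given sex at age > ``min_age_days``;
    the band is the closed interval [55, 56] cm for females and [56, 57] cm
    for males.  Returns a ProportionCI (exact binomial interval).
    """
    from .stats import binomial_ci

    lo, hi = BREED_STANDARD_CM[sex]
    sel = corrected
    if "sex" in sel.columns:
        sel = sel[sel["sex"] == sex]
    sel = sel[sel["age_days"].to_numpy(dtype=float) > min_age_days]
    if len(sel) == 0:
        raise ValueError(f"no {sex} measurements above {min_age_days} days")
    height = sel["height_corrected_cm"].to_numpy(dtype=float)
    k = int(np.sum((height >= lo) & (height <= hi)))
    return binomial_ci(k, len(sel), level)


def convergence_diagnostics(
    result: PosteriorResult | Sequence[PosteriorResult],
    ess_floor: float = 100.0,
) -> pd.DataFrame:
    """Effective sample sizes, acceptance rates and (multi-chain) R-hat.

    Accepts one PosteriorResult or several (parallel chains of the same
    model).  Parameters with ESS below ``ess_floor`` are flagged.
    """
    import arviz as az

    results = [result] if isinstance(result, PosteriorResult) else list(result)
    names = ("a", "b", "c", "tau")
    stacked = {k: np.stack([r.chains[k] for r in results]) for k in names}
    idata = az.from_dict(posterior=stacked)
    ess = az.ess(idata)
    rhat = az.rhat(idata) if len(results) > 1 else None

    rows = []
    for k in names:
        e = float(ess[k].values)
        row = {"param": k, "ess": e, "flagged": e < ess_floor}
        if rhat is not None:
            row["rhat"] = float(rhat[k].values)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["acceptance"] = [r.acceptance for r in results]
    return df


def effective_sample_size(chain: np.ndarray) -> float:
    """ESS of a single scalar chain (arviz bulk method)."""
    import arviz as az

    return float(az.ess(np.asarray(chain)[None, :]))
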