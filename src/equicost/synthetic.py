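"""Synthetic exit-interview surveys with known equity structure.

The generator emulates the statistical features the equity pipeline
assumes, at the scale of the study it mirrors: ~1400 patients sampled at
up to 10 per facility across ~150 facilities, ~82% public facilities,
~83% rural residents, ~71% travelling on foot with wealth-dependent mode
choice, heavily zero-inflated transport (~21% pay) and medical (~18% pay)
costs, travel and waiting times declining in wealth rank, and a flat
consultation time.

Each patient has a latent household wealth ``w ~ N(0, 1)``.  Binary asset
indicators are drawn with probability ``logistic(alpha_j + lambda_j w)``,
so the wealth index recovered by PCA is a noisy proxy of ``w``.  Every
outcome has a linear-in-rank expectation ``E[y | R] = a + b R`` (before
any zero-inflation), which yields a closed-form large-sample
concentration index

    CI_inf = 2 b var(R) / mu  ->  b / (6a + 3b)

(using var(R) -> 1/12, mu = a + b/2) — a quantitative oracle for
parameter-recovery testing.  A rank-independent payment layer multiplies
the mean by a constant and leaves the CI unchanged; wealth-dependent
structural zeros (transport cost is forced to 0 for foot travellers, and
foot travel is pro-poor) push the realised transport-cost CI above the
amount-process closed form, as in real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .survey_data import ASSET_PREFIX, Dataset
from .wealth import fractional_ranks

__all__ = [
    "OutcomeSpec",
    "GeneratorConfig",
    "generate_survey",
    "closed_form_ci",
    "closed_form_gap",
    "default_config",
]


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class OutcomeSpec:
    """Linear-in-rank outcome model: E[y | R] = intercept + rank_slope * R.

    ``family`` is the continuous noise family around that mean ("gamma"
    for times — shape = ``dispersion``; "lognormal" for costs — sigma =
    ``dispersion``).  ``pay_prob`` (if set) thins the outcome to zero with
    rank-independent probability ``1 - pay_prob`` before missingness.
    """

    intercept: float
    rank_slope: float
    family: str = "gamma"
    dispersion: float = 2.0
    pay_prob: float | None = None
    missing_rate: float = 0.0

    def validate(self, name: str) -> None:
        if self.family not in ("gamma", "lognormal"):
            raise ValueError(f"{name}: unknown noise family {self.family!r}")
        if self.dispersion <= 0:
            raise ValueError(f"{name}: dispersion must be positive")
        # linear mean must stay positive on (0, 1): check both endpoints
        if self.intercept <= 0 or self.intercept + self.rank_slope <= 0:
            raise ValueError(f"{name}: a + b*R must stay positive on (0, 1)")
        if self.pay_prob is not None and not 0 <= self.pay_prob <= 1:
            raise ValueError(f"{name}: pay_prob outside [0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError(f"{name}: missing_rate outside [0, 1)")


def _default_outcomes() -> dict[str, OutcomeSpec]:
    # Intercepts/slopes (minutes; TZS for costs) are calibrated to the
    # study's printed magnitudes: means 30.1 / 46.7 / 12.9 min, overall
    # costs 0.41 / 0.23 USD at 1600 TZS per USD, pay rates 21.3% / 17.8%,
    # travel-time CI near -0.11.  Missing rates reproduce the per-outcome
    # n of the study table (1143 / 1394 / 1374 / 1299 / 1399 of 1407).
    return {
        "travel_time_min": OutcomeSpec(40.0, -20.0, "gamma", 2.0,
                                       missing_rate=0.188),
        "waiting_time_min": OutcomeSpec(56.2, -19.0, "gamma", 2.0,
                                        missing_rate=0.009),
        "consultation_time_min": OutcomeSpec(12.9, 0.0, "gamma", 2.0,
                                             missing_rate=0.023),
        # amounts among payers; thinning handled by pay probabilities
        "transport_cost_tzs": OutcomeSpec(800.0, 4560.0, "lognormal", 0.8,
                                          missing_rate=0.077),
        "medical_cost_tzs": OutcomeSpec(280.0, 3560.0, "lognormal", 0.8,
                                        pay_prob=0.178, missing_rate=0.006),
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic survey; ``seed`` is mandatory."""

    seed: int
    n_patients: int = 1400
    n_facilities: int = 150
    public_share: float = 0.82
    rural_share: float = 0.828
    rural_wealth_slope: float = -0.7
    level_shares: tuple[float, float, float] = (12 / 150, 32 / 150, 106 / 150)
    service_shares: tuple[float, float, float, float] = (
        334 / 1407, 380 / 1407, 136 / 1407, 557 / 1407)
    insurance_share: float = 0.089
    n_assets: int = 42
    asset_loadings: tuple[float, ...] | None = None   # default: all 1.0
    asset_intercepts: tuple[float, ...] | None = None  # default: spread [-1.5, 1.5]
    mode_targets: tuple[float, float, float] = (0.711, 0.085, 0.205)  # foot/car/mb
    mode_wealth_slopes: tuple[float, float, float] = (-0.8, 1.0, 0.5)
    pay_prob_transport: float = 0.213
    pay_prob_medical: float = 0.178
    outcomes: dict[str, OutcomeSpec] = field(default_factory=_default_outcomes)

    def validate(self) -> None:
        if self.n_patients < 1 or self.n_facilities < 1:
            raise ValueError("n_patients and n_facilities must be positive")
        if self.n_patients > 10 * self.n_facilities:
            raise ValueError("cannot place more than 10 patients per facility")
        for name, p in [("public_share", self.public_share),
                        ("rural_share", self.rural_share),
                        ("insurance_share", self.insurance_share),
                        ("pay_prob_transport", self.pay_prob_transport),
                        ("pay_prob_medical", self.pay_prob_medical)]:
            if not 0 <= p <= 1:
                raise ValueError(f"{name} outside [0, 1]")
        for shares, k in [(self.level_shares, 3), (self.service_shares, 4),
                          (self.mode_targets, 3)]:
            if len(shares) != k or any(s < 0 for s in shares):
                raise ValueError("invalid share vector")
        if self.n_assets < 2:
            raise ValueError("need at least 2 asset indicators")
        if self.asset_loadings is not None and len(self.asset_loadings) != self.n_assets:
            raise ValueError("asset_loadings length must equal n_assets")
        if self.asset_intercepts is not None and len(self.asset_intercepts) != self.n_assets:
            raise ValueError("asset_intercepts length must equal n_assets")
        for name, spec in self.outcomes.items():
            spec.validate(name)


def default_config(seed: int, **overrides) -> GeneratorConfig:
    """Study-scale default configuration with the given seed."""
    return replace(GeneratorConfig(seed=seed), **overrides)


def closed_form_ci(a: float, b: float) -> float:
    """Large-sample CI implied by E[y | R] = a + bR: CI = b / (6a + 3b).

    Follows from CI = 2 b var(R) / mu with var(R) -> 1/12 and
    mu = a + b/2.  Scale-free in (a, b), so it also applies after any
    rank-independent thinning of the outcome.
    """
    mu = a + b / 2.0
    if mu <= 0:
        raise ValueError("mean a + b/2 must be positive")
    return b / (6.0 * a + 3.0 * b)


def closed_form_gap(b: float) -> float:
    """Large-sample poorest − least-poor gap: (a + b·0.1) − (a + b·0.9) = −0.8 b.

    Uses E[R | quintile 1] = 0.1 and E[R | quintile 5] = 0.9.
    """
    return -0.8 * b


# ---------------------------------------------------------------------------
# Deterministic calibration of logit intercepts to marginal shares
# ---------------------------------------------------------------------------

def _hermite_nodes(k: int = 64) -> tuple[np.ndarray, np.ndarray]:
    """Gauss–Hermite nodes/weights for E over w ~ N(0, 1)."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(k)
    return nodes, weights / weights.sum()


def _calibrate_multinomial(targets: np.ndarray, slopes: np.ndarray,
                           iters: int = 200) -> np.ndarray:
    """Intercepts c so that E_w[softmax(c + slope*w)] matches ``targets``."""
    targets = np.asarray(targets, float)
    targets = targets / targets.sum()
    nodes, wts = _hermite_nodes()
    c = np.log(np.clip(targets, 1e-12, None))
    zero = targets == 0
    for _ in range(iters):
        u = c[:, None] + slopes[:, None] * nodes[None, :]
        u -= u.max(axis=0, keepdims=True)
        p = np.exp(u)
        p /= p.sum(axis=0, keepdims=True)
        marg = p @ wts
        c[~zero] += np.log(targets[~zero]) - np.log(marg[~zero])
        c[zero] = -1e3
        c -= c[~zero].max()
    return c


def _calibrate_binary(target: float, slope: float) -> float:
    """Intercept c so that E_w[logistic(c + slope*w)] = target."""
    if target <= 0:
        return -1e3
    if target >= 1:
        return 1e3
    nodes, wts = _hermite_nodes()
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if float(_logistic(mid + slope * nodes) @ wts) < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _draw_outcome(rng: np.random.Generator, spec: OutcomeSpec,
                  mean: np.ndarray) -> np.ndarray:
    if spec.family == "gamma":
        k = spec.dispersion
        return rng.gamma(shape=k, scale=mean / k)
    sigma = spec.dispersion
    return np.exp(rng.normal(np.log(mean) - sigma ** 2 / 2.0, sigma))


def generate_survey(
    config: GeneratorConfig,
    *,
    return_truth: bool = False,
):
    """Draw one synthetic exit-interview dataset.

    Fully reproducible for a fixed config (single root generator seeded
    by ``config.seed``).  With ``return_truth=True`` also returns a
    per-patient ground-truth frame (latent wealth, true fractional rank)
    and a per-outcome parameter frame with the analytic large-sample CI
    and extreme-quintile gap where the closed form applies.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    # latent household wealth and its true fractional rank
    w = rng.normal(size=n)
    true_rank = fractional_ranks(w)

    # asset indicators: Bernoulli(logistic(alpha_j + lambda_j * w))
    loadings = np.asarray(config.asset_loadings if config.asset_loadings
                          is not None else np.ones(config.n_assets), float)
    intercepts = np.asarray(config.asset_intercepts if config.asset_intercepts
                            is not None else np.linspace(-1.5, 1.5,
                                                         config.n_assets), float)
    p_assets = _logistic(intercepts[None, :] + w[:, None] * loadings[None, :])
    assets = (rng.random((n, config.n_assets)) < p_assets).astype(float)

    # travel mode: multinomial logit in wealth, intercepts calibrated to
    # the configured marginal shares
    slopes = np.asarray(config.mode_wealth_slopes, float)
    c = _calibrate_multinomial(np.asarray(config.mode_targets, float), slopes)
    u = c[None, :] + w[:, None] * slopes[None, :]
    u -= u.max(axis=1, keepdims=True)
    pm = np.exp(u)
    pm /= pm.sum(axis=1, keepdims=True)
    cum = np.cumsum(pm, axis=1)
    draw = rng.random(n)[:, None]
    mode_idx = (draw > cum).sum(axis=1)
    modes = np.array(["foot", "car", "motorbike_bicycle"])[mode_idx]

    # residence: rural probability declining in wealth, calibrated marginal
    c_rural = _calibrate_binary(config.rural_share, config.rural_wealth_slope)
    rural = rng.random(n) < _logistic(c_rural + config.rural_wealth_slope * w)
    residence = np.where(rural, "rural", "urban")

    # facilities: ownership/level per facility, patients placed <= 10 each
    n_fac = config.n_facilities
    fac_ids = np.array([f"f{i:04d}" for i in range(n_fac)])
    fac_public = rng.random(n_fac) < config.public_share
    level_labels = np.array(["hospital", "health_centre", "dispensary"])
    fac_level = rng.choice(level_labels, size=n_fac,
                           p=np.asarray(config.level_shares) /
                           sum(config.level_shares))
    slots = np.repeat(np.arange(n_fac), 10)
    rng.shuffle(slots)
    fac_of_patient = slots[:n]
    ownership = np.where(fac_public[fac_of_patient], "public", "private")
    # split the non-public facilities between FBO and fully private
    nonpub = ~fac_public[fac_of_patient]
    fbo = rng.random(n) < 0.5
    ownership = np.where(nonpub & fbo, "fbo", ownership)

    service = rng.choice(np.array(["anc", "pnc", "vaccination", "checkup"]),
                         size=n, p=np.asarray(config.service_shares) /
                         sum(config.service_shares))

    df = pd.DataFrame({
        "patient_id": [f"p{i:05d}" for i in range(n)],
        "facility_id": fac_ids[fac_of_patient],
        "ownership": ownership,
        "level": fac_level[fac_of_patient],
        "service": service,
        "residence": residence,
        "travel_mode": modes,
    })

    foot = modes == "foot"
    foot_target = config.mode_targets[0] / sum(config.mode_targets)
    truth_rows = []
    for name, spec in config.outcomes.items():
        mean = spec.intercept + spec.rank_slope * true_rank
        y = _draw_outcome(rng, spec, mean)
        ci_inf: float | None = closed_form_ci(spec.intercept, spec.rank_slope)
        if name == "transport_cost_tzs":
            # structural zeros: foot travellers pay nothing; remaining
            # travellers pay with the probability that hits the marginal
            # payment target
            p_cond = min(1.0, config.pay_prob_transport / max(1e-12,
                                                              1 - foot_target))
            pays = (~foot) & (rng.random(n) < p_cond)
            y = np.where(pays, y, 0.0)
            ci_inf = None  # wealth-dependent zeros: closed form not exact
        elif spec.pay_prob is not None:
            pays = rng.random(n) < spec.pay_prob
            y = np.where(pays, y, 0.0)
        if spec.missing_rate > 0:
            y = np.where(rng.random(n) < spec.missing_rate, np.nan, y)
        df[name] = y
        truth_rows.append({
            "outcome": name, "intercept": spec.intercept,
            "rank_slope": spec.rank_slope, "family": spec.family,
            "ci_infinity": np.nan if ci_inf is None else ci_inf,
            "gap_infinity": closed_form_gap(spec.rank_slope),
        })

    df["insurance"] = rng.random(n) < config.insurance_share
    asset_names = [f"item{j:02d}" for j in range(config.n_assets)]
    for j, name in enumerate(asset_names):
        df[ASSET_PREFIX + name] = assets[:, j]

    dataset = Dataset(df=df, asset_names=asset_names)
    if not return_truth:
        return dataset
    truth = pd.DataFrame({
        "patient_id": df["patient_id"],
        "latent_wealth": w,
        "true_rank": true_rank,
    })
    params = pd.DataFrame(truth_rows)
    return dataset, truth, params
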