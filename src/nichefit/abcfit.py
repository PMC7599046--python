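"""ABC-rejection fitting of niche-neutral RSA models.

The fitter is likelihood-free: for each of ``n_sims`` iterations a
parameter set is proposed from the priors, a community with the observed
species richness is simulated from it, and the proposal is accepted when
the simulated Preston plot is close enough to the empirical one.  Two
acceptance conditions must both hold:

1. in every octave where the data count is positive, the absolute
   difference between simulated and data counts is at most 30% of the
   data count;
2. a Skellam-motivated chi-squared statistic — each octave difference is
   treated as the difference of two Poisson counts, standardized and
   squared —

       chi2 = sum_i (mu_i1 - mu_i2)^2 / (mu_i1 + mu_i2)

   summed over octaves with at least one count, with degrees of freedom
   equal to the number of such octaves, must satisfy
   CDF_chi2(df)(chi2) < 0.5.

Fits are hierarchical in two steps: step 1 runs per-sample rejection
under uninformative priors (rates log-uniform, weights uniform), keeps at
most 5 accepted draws per sample (smallest chi2 first), pools them across
the dataset and refits Gamma (rates) / Beta (mixture weight) hyperpriors;
step 2 reruns the rejection under those dataset-informed priors.  Point
estimates are per-parameter medians of the accepted draws after each draw
is relabeled rare/abundant by expected abundance, which removes
label-switching before any pooling.

Model choice between the 1-, 2- and 3-niche models uses the acceptance
rate as an (unnormalized) posterior probability; log Bayes factors are
ratios of those rates with a small pseudo-count guarding zeros.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.special import chdtr

from .niche import MixtureModel, NicheRates, theta, ztnb_mean
from .rsa import AbundanceVector, PrestonHistogram, preston_histogram

__all__ = [
    "Prior",
    "PriorSpec",
    "ABCConfig",
    "AcceptedDraw",
    "SamplePosterior",
    "HyperPrior",
    "FitResult",
    "ABCError",
    "default_priors",
    "acceptance_test",
    "propose",
    "abc_rejection",
    "cap_draws",
    "fit_hyperpriors",
    "two_step_fit",
    "point_estimates",
    "model_posterior",
    "log_bayes_factor",
]

RESAMPLE_CAP = 10_000
RATE_NAMES = ("b", "d", "s")


class ABCError(RuntimeError):
    """Raised when the ABC pipeline cannot proceed (e.g. empty step-1 pool)."""


@dataclass(frozen=True)
class Prior:
    """A one-dimensional prior: log-uniform/uniform/gamma/beta."""

    family: str
    params: tuple[float, float]

    def __post_init__(self) -> None:
        a, b = self.params
        if self.family in ("log-uniform", "uniform"):
            if not a < b:
                raise ValueError(f"{self.family} needs lo < hi, got {self.params}")
            if self.family == "log-uniform" and a <= 0:
                raise ValueError("log-uniform needs a positive lower bound")
        elif self.family in ("gamma", "beta"):
            if a <= 0 or b <= 0:
                raise ValueError(f"{self.family} hyperparameters must be positive")
        else:
            raise ValueError(f"unknown prior family {self.family!r}")

    def sample(self, rng: np.random.Generator) -> float:
        a, b = self.params
        if self.family == "log-uniform":
            return math.exp(rng.uniform(math.log(a), math.log(b)))
        if self.family == "uniform":
            return rng.uniform(a, b)
        if self.family == "gamma":  # (shape, scale)
            return rng.gamma(a, b)
        return rng.beta(a, b)


# The RSA depends on the rates only through x = b/d and r = s/b, so the
# rate range merely sets the spread of the induced log-ratio priors.
# Log-uniform rates on [0.1, 10] put r = s/b log-uniform-triangular on
# [1e-2, 1e2], wide enough to cover gut-like RSA fits while keeping the
# step-1 acceptance rate at the scale full-size runs report (~1e-4).
UNINFORMATIVE_RATE = Prior("log-uniform", (0.1, 10.0))
UNINFORMATIVE_WEIGHT = Prior("uniform", (0.0, 1.0))


@dataclass(frozen=True)
class PriorSpec:
    """Priors for every parameter of a K-niche model.

    In the default ``space="rates"`` each niche's mapping carries priors
    for "b"/"d"/"s"; in ``space="ratios"`` it carries priors for the
    identifiable coordinates "x" (= b/d, support (0, 1)) and "r" (= s/b),
    from which rates are reconstructed as (b, d, s) = (x, 1, r x) —
    b < d holds automatically.  ``weight_priors`` holds K-1 priors for
    the free mixture coefficients (the last weight is the complement).
    """

    niche_priors: tuple[Mapping[str, Prior], ...]
    weight_priors: tuple[Prior, ...]
    space: str = "rates"

    def __post_init__(self) -> None:
        if not 1 <= len(self.niche_priors) <= 3:
            raise ValueError("1 to 3 niches supported")
        if len(self.weight_priors) != len(self.niche_priors) - 1:
            raise ValueError("need K-1 weight priors for a K-niche model")
        if self.space not in ("rates", "ratios"):
            raise ValueError("space must be 'rates' or 'ratios'")
        names = RATE_NAMES if self.space == "rates" else ("x", "r")
        for pr in self.niche_priors:
            missing = set(names) - set(pr)
            if missing:
                raise ValueError(f"missing niche priors: {sorted(missing)}")

    @property
    def k(self) -> int:
        return len(self.niche_priors)


def default_priors(k: int) -> PriorSpec:
    """Uninformative step-1 priors: rates log-uniform on [0.1, 10],
    mixture weights uniform on [0, 1]."""
    rate = {name: UNINFORMATIVE_RATE for name in RATE_NAMES}
    return PriorSpec(
        niche_priors=tuple(dict(rate) for _ in range(k)),
        weight_priors=tuple(UNINFORMATIVE_WEIGHT for _ in range(k - 1)),
    )


@dataclass(frozen=True)
class ABCConfig:
    """Tuning knobs of the rejection sampler.

    ``n_sims`` is first-class: full-scale analyses use 1e7 proposals per
    sample and step; the package default (1e5) is sized for desk runs.
    """

    n_sims: int = 100_000
    bin_tolerance: float = 0.30
    chi2_cdf_cutoff: float = 0.5
    max_accept_pooling: int = 5
    pseudo_count: float = 1e-7
    df_mode: str = "either"      # count bins non-zero in either histogram ("data": data-only)
    cap_rule: str = "best"       # cap-5 keeps smallest chi2 ("random": uniform under seed)
    hyperprior_space: str = "ratios"  # refit x/r per niche ("rates": b, d, s marginally)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.bin_tolerance < 1:
            raise ValueError("bin_tolerance must lie in (0, 1)")
        if not 0 < self.chi2_cdf_cutoff < 1:
            raise ValueError("chi2_cdf_cutoff must lie in (0, 1)")
        if self.n_sims < 0:
            raise ValueError("n_sims must be >= 0")
        if self.df_mode not in ("either", "data"):
            raise ValueError("df_mode must be 'either' or 'data'")
        if self.cap_rule not in ("best", "random"):
            raise ValueError("cap_rule must be 'best' or 'random'")
        if self.hyperprior_space not in ("ratios", "rates"):
            raise ValueError("hyperprior_space must be 'ratios' or 'rates'")


@dataclass(frozen=True)
class AcceptedDraw:
    """A parameter set that passed both acceptance conditions."""

    model: MixtureModel
    chi2: float
    df: int
    order: int  # acceptance order within the run (tie-break for cap-5)


@dataclass
class SamplePosterior:
    """All accepted draws of one sample under one model kind."""

    sample_id: str
    model_kind: str  # "1nb" | "2nb" | "3nb"
    draws: list[AcceptedDraw]
    n_proposals: int

    @property
    def n_accepted(self) -> int:
        return len(self.draws)

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / self.n_proposals if self.n_proposals else 0.0


@dataclass(frozen=True)
class HyperPrior:
    """Dataset-level priors refitted from pooled step-1 draws."""

    spec: PriorSpec
    n_pooled: int
    degenerate_params: tuple[str, ...] = ()


@dataclass
class FitResult:
    """Point estimates for one sample: niche-wise parameter medians and
    the Hubbell numbers theta (rare/abundant for K >= 2)."""

    sample_id: str
    model_kind: str
    n_accepted: int
    n_proposals: int
    acceptance_rate: float
    theta_by_label: dict[str, float] = field(default_factory=dict)
    param_medians: dict[str, dict[str, float]] = field(default_factory=dict)
    flags: tuple[str, ...] = ()

    @property
    def theta_rare(self) -> float | None:
        return self.theta_by_label.get("rare")

    @property
    def theta_abundant(self) -> float | None:
        return self.theta_by_label.get("abundant")

    @property
    def theta_single(self) -> float | None:
        return self.theta_by_label.get("single")


def _model_kind(kind: int | str) -> int:
    if isinstance(kind, str):
        kind = kind.lower().rstrip("nb")
        kind = int(kind)
    if kind not in (1, 2, 3):
        raise ValueError("model kind must be 1NB, 2NB or 3NB")
    return kind


def _kind_name(k: int) -> str:
    return f"{k}nb"


# ---------------------------------------------------------------------------
# acceptance test
# ---------------------------------------------------------------------------

def _accept_arrays(
    data: np.ndarray,
    sim: np.ndarray,
    bin_tolerance: float,
    chi2_cdf_cutoff: float,
    df_mode: str,
) -> tuple[bool, float, int]:
    """Both acceptance conditions on zero-padded octave-count arrays."""
    nd, ns = data.size, sim.size
    if nd < ns:
        data = np.concatenate([data, np.zeros(ns - nd, dtype=data.dtype)])
    elif ns < nd:
        sim = np.concatenate([sim, np.zeros(nd - ns, dtype=sim.dtype)])
    # condition 1: 30% band around every positive data count (a band around
    # zero would be the empty set, so zero-data octaves are left to chi2)
    pos = data > 0
    diff = np.abs(sim - data)
    cond1 = bool(np.all(diff[pos] <= bin_tolerance * data[pos]))
    total = data + sim
    nonzero = total > 0
    chi2 = float(np.sum((data[nonzero] - sim[nonzero]) ** 2 / total[nonzero]))
    df = int(nonzero.sum()) if df_mode == "either" else int(pos.sum())
    if df == 0:
        raise ValueError("both histograms are empty")
    accept = cond1 and bool(chdtr(df, chi2) < chi2_cdf_cutoff)
    return accept, chi2, df


def acceptance_test(
    data_bins: PrestonHistogram,
    sim_bins: PrestonHistogram,
    config: ABCConfig | None = None,
) -> tuple[bool, float, int]:
    """Accept/reject a simulated Preston plot against the data's.

    Returns ``(accept, chi2, df)``; ``accept`` is True only when both the
    30%-band rule and the Skellam chi-squared rule hold.
    """
    config = config or ABCConfig()
    return _accept_arrays(
        np.asarray(data_bins.bin_counts, dtype=np.float64),
        np.asarray(sim_bins.bin_counts, dtype=np.float64),
        config.bin_tolerance,
        config.chi2_cdf_cutoff,
        config.df_mode,
    )


# ---------------------------------------------------------------------------
# proposals
# ---------------------------------------------------------------------------

def _compile_prior(p: Prior) -> tuple[int, float, float]:
    """(family code, a, b) with log-uniform bounds pre-logged."""
    a, b = p.params
    if p.family == "log-uniform":
        return (0, math.log(a), math.log(b))
    if p.family == "uniform":
        return (1, a, b)
    if p.family == "gamma":
        return (2, a, b)
    return (3, a, b)


def _compile_priors(priors: PriorSpec):
    if priors.space == "rates":
        names: tuple[str, ...] = RATE_NAMES
    else:
        names = ("x", "r")
    return (
        tuple(
            tuple(_compile_prior(pr[name]) for name in names)
            for pr in priors.niche_priors
        ),
        tuple(_compile_prior(p) for p in priors.weight_priors),
        priors.space == "ratios",
    )


def _draw1(code: int, a: float, b: float, rng: np.random.Generator) -> float:
    if code == 0:
        return math.exp(rng.uniform(a, b))
    if code == 1:
        return rng.uniform(a, b)
    if code == 2:
        return rng.gamma(a, b)
    return rng.beta(a, b)


def _propose_raw(compiled, k: int, rng: np.random.Generator):
    """Raw proposal: ((b, d, s) per niche, weights), no object wrapping."""
    niche_priors, weight_priors, ratio_space = compiled
    niches = []
    if ratio_space:
        for px, pr_ in niche_priors:
            for _ in range(RESAMPLE_CAP):
                x = _draw1(px[0], px[1], px[2], rng)
                if 0.0 < x < 1.0:
                    break
            else:
                raise ABCError(
                    f"no x in (0, 1) within {RESAMPLE_CAP} attempts (prior {px})"
                )
            r = _draw1(pr_[0], pr_[1], pr_[2], rng)
            niches.append((x, 1.0, r * x))
    else:
        for pb, pd_, ps in niche_priors:
            for _ in range(RESAMPLE_CAP):
                b = _draw1(pb[0], pb[1], pb[2], rng)
                d = _draw1(pd_[0], pd_[1], pd_[2], rng)
                if b < d:
                    break
            else:
                raise ABCError(
                    f"no b < d proposal within {RESAMPLE_CAP} attempts "
                    f"(priors b~{pb}, d~{pd_})"
                )
            s = _draw1(ps[0], ps[1], ps[2], rng)
            niches.append((b, d, s))
    if k == 1:
        weights: tuple[float, ...] = (1.0,)
    elif k == 2:
        a = _draw1(*weight_priors[0], rng)
        weights = (a, 1.0 - a)
    else:
        for _ in range(RESAMPLE_CAP):
            a = _draw1(*weight_priors[0], rng)
            bta = _draw1(*weight_priors[1], rng)
            if a + bta <= 1.0:
                break
        else:
            raise ABCError(
                f"no simplex-feasible (alpha, beta) within {RESAMPLE_CAP} "
                f"attempts (priors {weight_priors})"
            )
        weights = (a, bta, 1.0 - a - bta)
    return tuple(niches), weights


def propose(
    priors: PriorSpec, model_kind: int | str, rng: np.random.Generator
) -> MixtureModel:
    """Draw one parameter set from the priors.

    RNG consumption contract (mirrored by the reference-loop check): per
    niche, (b, d) pairs are redrawn together until b < d, then s is
    drawn; afterwards the free mixture weights are drawn (for K = 3,
    (alpha, beta) pairs are redrawn until alpha + beta <= 1).
    """
    k = _model_kind(model_kind)
    if priors.k != k:
        raise ValueError(f"priors specify {priors.k} niches, requested {k}")
    raw_niches, weights = _propose_raw(_compile_priors(priors), k, rng)
    return MixtureModel(
        niches=tuple(NicheRates(b=b, d=d, s=s) for b, d, s in raw_niches),
        weights=weights,
    )


# ---------------------------------------------------------------------------
# rejection loop
# ---------------------------------------------------------------------------

def abc_rejection(
    av: AbundanceVector,
    model_kind: int | str,
    priors: PriorSpec,
    config: ABCConfig,
    rng: np.random.Generator,
) -> SamplePosterior:
    """One full rejection run for one sample.

    Per proposal: draw parameters, simulate a community with the sample's
    species richness, octave-bin it and apply the acceptance test.
    Proposals whose community sampling hits an abundance or rejection cap
    count as rejected.  An empty accepted set is a valid outcome.
    """
    from ._engine import STATUS_CAP, STATUS_PRIOR_ERROR, abc_kernel

    k = _model_kind(model_kind)
    data_bins = preston_histogram(av).bin_counts.astype(np.float64)
    n_obs = av.n_obs
    ratio_space = priors.space == "ratios"
    names = ("x", "r") if ratio_space else RATE_NAMES
    prior_code = np.zeros((k, 3), dtype=np.int64)
    prior_a = np.zeros((k, 3), dtype=np.float64)
    prior_b = np.ones((k, 3), dtype=np.float64)
    for j, pr in enumerate(priors.niche_priors):
        for c, name in enumerate(names):
            prior_code[j, c], prior_a[j, c], prior_b[j, c] = _compile_prior(pr[name])
    wcode = np.empty(k - 1, dtype=np.int64)
    wa = np.empty(k - 1, dtype=np.float64)
    wb = np.empty(k - 1, dtype=np.float64)
    for j, p in enumerate(priors.weight_priors):
        wcode[j], wa[j], wb[j] = _compile_prior(p)
    max_acc = min(config.n_sims, 1_000_000) if config.n_sims else 1
    acc_params = np.empty((max_acc, 4 * k), dtype=np.float64)
    acc_chi2 = np.empty(max_acc, dtype=np.float64)
    acc_df = np.empty(max_acc, dtype=np.int64)
    n_acc, status = abc_kernel(
        rng,
        config.n_sims,
        k,
        ratio_space,
        prior_code,
        prior_a,
        prior_b,
        wcode,
        wa,
        wb,
        n_obs,
        data_bins,
        config.bin_tolerance,
        config.chi2_cdf_cutoff,
        config.df_mode == "data",
        acc_params,
        acc_chi2,
        acc_df,
    )
    if status == STATUS_PRIOR_ERROR:
        raise ABCError(
            f"prior resampling cap ({RESAMPLE_CAP}) exceeded: the priors "
            "essentially never satisfy b < d (or the weight simplex)"
        )
    if status == STATUS_CAP:
        raise ABCError(
            f"accepted-draw buffer ({max_acc}) overflowed; tighten the "
            "acceptance conditions or lower n_sims"
        )
    draws: list[AcceptedDraw] = []
    for i in range(n_acc):
        row = acc_params[i]
        model = MixtureModel(
            niches=tuple(
                NicheRates(b=row[3 * j], d=row[3 * j + 1], s=row[3 * j + 2])
                for j in range(k)
            ),
            weights=tuple(row[3 * k : 4 * k]),
        )
        draws.append(
            AcceptedDraw(model=model, chi2=float(acc_chi2[i]), df=int(acc_df[i]), order=i)
        )
    return SamplePosterior(
        sample_id=av.sample_id,
        model_kind=_kind_name(k),
        draws=draws,
        n_proposals=config.n_sims,
    )


def cap_draws(
    posterior: SamplePosterior,
    k: int = 5,
    rule: str = "best",
    rng: np.random.Generator | None = None,
) -> list[AcceptedDraw]:
    """At most ``k`` draws per sample, for balanced hyperprior pooling.

    ``rule="best"`` keeps the k smallest-chi2 draws (ties by acceptance
    order); ``rule="random"`` keeps a uniform seeded subset, available as
    a sensitivity check.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(posterior.draws) <= k:
        return list(posterior.draws)
    if rule == "best":
        return sorted(posterior.draws, key=lambda dr: (dr.chi2, dr.order))[:k]
    if rule == "random":
        if rng is None:
            raise ValueError("rule='random' needs an rng")
        idx = rng.choice(len(posterior.draws), size=k, replace=False)
        return [posterior.draws[i] for i in sorted(idx)]
    raise ValueError(f"unknown cap rule {rule!r}")


# ---------------------------------------------------------------------------
# hyperprior refit (step 1 -> step 2)
# ---------------------------------------------------------------------------

def _relabel(draw_model: MixtureModel) -> tuple[tuple[NicheRates, ...], tuple[float, ...]]:
    """Niches (with their weights) sorted by expected abundance, so that
    slot 0 is always the rare niche.  Removes label switching."""
    means = [ztnb_mean(rt) for rt in draw_model.ratios]
    order = sorted(range(draw_model.k), key=lambda i: (means[i], i))
    return (
        tuple(draw_model.niches[i] for i in order),
        tuple(draw_model.weights[i] for i in order),
    )


def _fit_gamma(values: np.ndarray, name: str, degenerate: list[str]) -> Prior:
    values = np.asarray(values, dtype=np.float64)
    n = values.size
    mean = float(values.mean())
    var = float(values.var(ddof=1)) if n > 1 else 0.0
    if var <= (1e-9 * max(mean, 1e-300)) ** 2:
        # constant pooled values: apply a variance floor of 5% CV
        degenerate.append(name)
        var = max((0.05 * mean) ** 2, 1e-300)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            shape, _, scale = stats.gamma.fit(values, floc=0)
        if not (np.isfinite(shape) and np.isfinite(scale) and shape > 0 and scale > 0):
            raise ValueError
    except Exception:
        shape = mean**2 / var
        scale = var / mean
    # an n-point pool cannot support a concentration beyond ~n: cap the
    # fitted shape there (mean preserved) so tiny pools yield honest,
    # wide hyperpriors instead of near-delta artifacts of the MLE
    if shape > n:
        degenerate.append(f"{name}:overconfident")
        shape = float(n)
        scale = mean / shape
    return Prior("gamma", (float(shape), float(scale)))


def _fit_beta(values: np.ndarray, name: str, degenerate: list[str]) -> Prior:
    values = np.clip(np.asarray(values, dtype=np.float64), 1e-9, 1.0 - 1e-9)
    n = values.size
    mean = float(values.mean())
    var = float(values.var(ddof=1)) if n > 1 else 0.0
    if var <= 1e-18:
        degenerate.append(name)
        var = max(0.05**2 * mean * (1.0 - mean), 1e-6)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a, b, _, _ = stats.beta.fit(values, floc=0, fscale=1)
        if not (np.isfinite(a) and np.isfinite(b) and a > 0 and b > 0):
            raise ValueError
    except Exception:
        common = mean * (1.0 - mean) / var - 1.0
        common = max(common, 1e-3)
        a, b = mean * common, (1.0 - mean) * common
    # same information cap as the gamma refit: concentration <= n + 2
    if a + b > n + 2:
        degenerate.append(f"{name}:overconfident")
        nu = float(n + 2)
        a, b = mean * nu, (1.0 - mean) * nu
    return Prior("beta", (float(a), float(b)))


def fit_hyperpriors(
    pooled: Sequence[AcceptedDraw], model_kind: int | str, space: str = "ratios"
) -> HyperPrior:
    """Fit parametric hyperpriors to pooled accepted draws.

    Draws are relabeled rare -> abundant before pooling, so each niche
    slot's values are commensurable across draws.  Mixture weights get a
    Beta family; in the default ``space="ratios"`` each niche's
    identifiable coordinates get a Beta (x = b/d) and a Gamma (r = s/b) —
    fitting the raw rates marginally (``space="rates"``, Gamma per rate)
    is also available, but redrawing b and d independently in step 2
    scrambles the x the data actually constrain.  Maximum likelihood with
    a method-of-moments fallback; constant pooled values get a variance
    floor, and fitted concentrations are capped by the pool size (an
    n-point fit cannot support more), both flagged.
    """
    k = _model_kind(model_kind)
    if len(pooled) < 2:
        raise ABCError(
            f"hyperprior refit needs >= 2 pooled draws, got {len(pooled)}; "
            "fall back to the step-1 priors"
        )
    relabeled = [_relabel(dr.model) for dr in pooled]
    degenerate: list[str] = []
    niche_priors = []
    for slot in range(k):
        slot_priors = {}
        if space == "ratios":
            xs = np.array([nr[slot].ratios.x for nr, _ in relabeled])
            rs = np.array([nr[slot].ratios.r for nr, _ in relabeled])
            slot_priors["x"] = _fit_beta(xs, f"niche{slot}.x", degenerate)
            slot_priors["r"] = _fit_gamma(rs, f"niche{slot}.r", degenerate)
        else:
            for name in RATE_NAMES:
                vals = np.array([getattr(nr[slot], name) for nr, _ in relabeled])
                slot_priors[name] = _fit_gamma(vals, f"niche{slot}.{name}", degenerate)
        niche_priors.append(slot_priors)
    weight_priors = []
    for slot in range(k - 1):
        vals = np.array([w[slot] for _, w in relabeled])
        weight_priors.append(_fit_beta(vals, f"weight{slot}", degenerate))
    return HyperPrior(
        spec=PriorSpec(
            niche_priors=tuple(niche_priors),
            weight_priors=tuple(weight_priors),
            space=space,
        ),
        n_pooled=len(pooled),
        degenerate_params=tuple(degenerate),
    )


# ---------------------------------------------------------------------------
# point estimates and the two-step pipeline
# ---------------------------------------------------------------------------

def point_estimates(posterior: SamplePosterior, n_obs: int) -> FitResult:
    """Componentwise medians of the accepted draws, after rare/abundant
    relabeling, plus the median Hubbell numbers (one per niche slot)."""
    k = _model_kind(posterior.model_kind)
    base = dict(
        sample_id=posterior.sample_id,
        model_kind=posterior.model_kind,
        n_accepted=posterior.n_accepted,
        n_proposals=posterior.n_proposals,
        acceptance_rate=posterior.acceptance_rate,
    )
    if posterior.n_accepted == 0:
        return FitResult(**base, flags=("none-accepted",))
    if k == 1:
        slot_labels = ("single",)
    elif k == 2:
        slot_labels = ("rare", "abundant")
    else:
        slot_labels = ("rare", "middle", "abundant")
    per_slot: dict[str, dict[str, list[float]]] = {
        lab: {name: [] for name in (*RATE_NAMES, "weight", "theta")}
        for lab in slot_labels
    }
    degenerate = False
    for dr in posterior.draws:
        niches, weights = _relabel(dr.model)
        means = [ztnb_mean(nr.ratios) for nr in niches]
        degenerate = degenerate or len(set(means)) < k
        for lab, nr, w in zip(slot_labels, niches, weights):
            per_slot[lab]["b"].append(nr.b)
            per_slot[lab]["d"].append(nr.d)
            per_slot[lab]["s"].append(nr.s)
            per_slot[lab]["weight"].append(w)
            per_slot[lab]["theta"].append(theta(nr.ratios, n_obs))
    theta_by_label = {
        lab: float(np.median(vals["theta"])) for lab, vals in per_slot.items()
    }
    param_medians = {
        lab: {
            name: float(np.median(vals[name]))
            for name in (*RATE_NAMES, "weight")
        }
        for lab, vals in per_slot.items()
    }
    flags = []
    if degenerate:
        flags.append("degenerate")
    if posterior.n_accepted < 5:
        flags.append("low-acceptance")
    return FitResult(
        **base,
        theta_by_label=theta_by_label,
        param_medians=param_medians,
        flags=tuple(flags),
    )


def _sample_rng(seed: int, step: int, kind: int, sample_id: str) -> np.random.Generator:
    """Deterministic per-(step, model, sample) stream, independent of the
    order samples are processed in."""
    sid = zlib.crc32(sample_id.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(step, kind, sid))
    return np.random.Generator(np.random.Philox(ss))


def two_step_fit(
    dataset: Sequence[AbundanceVector],
    model_kind: int | str,
    config: ABCConfig | None = None,
    return_details: bool = False,
    step1_priors: PriorSpec | None = None,
):
    """The hierarchical two-step fit over a dataset of samples.

    Step 1 fits every sample under uninformative priors (or
    ``step1_priors`` when given) and pools at most
    ``max_accept_pooling`` accepted draws per sample into Gamma/Beta
    hyperpriors.  Step 2 refits every sample under the dataset-level
    hyperpriors and reports per-sample point estimates.

    Returns a list of FitResult (plus, with ``return_details``, the
    hyperprior and the step-2 posteriors).
    """
    if len(dataset) == 0:
        raise ValueError("dataset must contain at least one sample")
    k = _model_kind(model_kind)
    config = config or ABCConfig()
    tagged: list[tuple[str, AcceptedDraw]] = []
    priors1 = step1_priors or default_priors(k)
    for av in dataset:
        rng = _sample_rng(config.seed, 1, k, av.sample_id)
        post = abc_rejection(av, k, priors1, config, rng)
        cap_rng = _sample_rng(config.seed, 10, k, av.sample_id)
        for dr in cap_draws(post, config.max_accept_pooling, config.cap_rule, cap_rng):
            tagged.append((av.sample_id, dr))
    # canonical pool order: results must not depend on dataset order
    tagged.sort(key=lambda t: (t[0], t[1].order))
    pooled = [dr for _, dr in tagged]
    if len(pooled) == 0:
        raise ABCError(
            "step-1 pool is empty: no sample accepted any proposal; "
            "increase n_sims or loosen the acceptance conditions"
        )
    if len(pooled) < 2:
        raise ABCError(
            "step-1 pool has a single draw; hyperprior refit needs >= 2"
        )
    hyper = fit_hyperpriors(pooled, k, config.hyperprior_space)
    results = []
    posteriors = []
    for av in dataset:
        rng = _sample_rng(config.seed, 2, k, av.sample_id)
        post = abc_rejection(av, k, hyper.spec, config, rng)
        posteriors.append(post)
        results.append(point_estimates(post, av.n_obs))
    if return_details:
        return results, hyper, posteriors
    return results


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

def model_posterior(
    posteriors: Mapping[str, SamplePosterior]
) -> dict[str, float]:
    """Unnormalized posterior probability of each model kind: the
    acceptance rate accepted/n_sims (all runs must share n_sims)."""
    n_sims = {p.n_proposals for p in posteriors.values()}
    if len(n_sims) > 1:
        raise ValueError(f"runs used different n_sims: {sorted(n_sims)}")
    return {kind: p.acceptance_rate for kind, p in posteriors.items()}


def log_bayes_factor(p_a: float, p_b: float, pseudo_count: float = 1e-7) -> float:
    """ln((p_a + eps) / (p_b + eps)); positive favors model a.

    The pseudo-count floor keeps the ratio finite when a model accepted
    nothing.
    """
    if p_a < 0 or p_b < 0:
        raise ValueError("posterior probabilities must be >= 0")
    return math.log((p_a + pseudo_count) / (p_b + pseudo_count))
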