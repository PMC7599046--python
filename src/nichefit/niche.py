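"""Zero-truncated negative-binomial niche models and Hubbell biodiversity.

The underlying community model is a neutral birth-death process with a
constant immigration influx: every species in a niche has the same
per-capita birth rate ``b``, death rate ``d`` and immigration term ``s``.
Its stationary relative species abundance (RSA) distribution is a
zero-truncated Negative Binomial (ZTNB) in the abundance ``n >= 1``:

    P(n) = x^n * Gamma(n + r) / (n! * Gamma(r) * ((1 - x)^(-r) - 1))

which depends on the rates only through the ratios ``x = b/d`` (in (0, 1),
stationarity) and ``r = s/b``.  A K-niche community (K = 1, 2, 3) is a
mixture of K such laws; the niches do not interact and each species
belongs to exactly one of them.

The fundamental biodiversity number of a niche is Hubbell's theta,

    theta = N_obs / (((1 - x)^(-r) - 1) * Gamma(r))

with ``N_obs`` the observed species richness.  For a two-niche community
the niche with the smaller expected abundance is labeled "rare" and the
other "abundant", giving theta_rare and theta_abundant.

All Gamma-function arithmetic is done in log space so that large ``r``
(up to ~1e3 and beyond) does not overflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln

__all__ = [
    "NicheRates",
    "NicheRatios",
    "MixtureModel",
    "ThetaEstimate",
    "SamplingCapError",
    "ztnb_logpmf",
    "ztnb_pmf",
    "ztnb_mean",
    "mixture_pmf",
    "expected_sad",
    "sample_community",
    "sample_community_counts",
    "sample_ztnb",
    "theta",
    "label_niches",
]

#: a single sampled abundance above this aborts the draw (near-critical x)
ABUNDANCE_CAP = 10**9
#: hard cap on consecutive zero-rejections in the truncated sampler
REJECTION_CAP = 10**6


class SamplingCapError(RuntimeError):
    """Community sampling aborted: pathological parameters hit a cap."""

    def __init__(self, message: str, ratios: "NicheRatios | None" = None):
        super().__init__(message)
        self.ratios = ratios


@dataclass(frozen=True)
class NicheRates:
    """Per-capita birth/death rates and immigration influx of one niche.

    Stationarity of the birth-death-immigration process requires b < d;
    s > 0 keeps the zero-truncated support non-degenerate.
    """

    b: float
    d: float
    s: float

    def __post_init__(self) -> None:
        if not (self.b > 0 and self.d > 0 and self.s > 0):
            raise ValueError(f"rates must be positive: b={self.b}, d={self.d}, s={self.s}")
        if not self.b < self.d:
            raise ValueError(f"stationarity requires b < d (got b={self.b}, d={self.d})")

    @property
    def ratios(self) -> "NicheRatios":
        return NicheRatios(x=self.b / self.d, r=self.s / self.b)


@dataclass(frozen=True)
class NicheRatios:
    """The identifiable parameters of the ZTNB: x = b/d and r = s/b."""

    x: float
    r: float

    def __post_init__(self) -> None:
        if not (0.0 < self.x < 1.0):
            raise ValueError(f"x = b/d must lie in (0, 1), got {self.x}")
        if not self.r > 0.0:
            raise ValueError(f"r = s/b must be positive, got {self.r}")

    @property
    def log_norm(self) -> float:
        """log((1 - x)^(-r) - 1), the log of the zero-truncation constant."""
        # (1-x)^(-r) - 1 = expm1(-r * log(1 - x))
        return float(np.log(np.expm1(-self.r * np.log1p(-self.x))))

    @property
    def positive_mass(self) -> float:
        """P(N >= 1) = 1 - (1 - x)^r of the untruncated Negative Binomial."""
        return float(-np.expm1(self.r * np.log1p(-self.x)))


def _as_ratios(obj: NicheRates | NicheRatios) -> NicheRatios:
    return obj.ratios if isinstance(obj, NicheRates) else obj


@dataclass(frozen=True)
class MixtureModel:
    """A 1-, 2- or 3-niche community: ZTNB components with mixture weights."""

    niches: tuple[NicheRates, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        niches = tuple(self.niches)
        weights = tuple(float(w) for w in self.weights)
        if not 1 <= len(niches) <= 3:
            raise ValueError("a mixture has 1 to 3 niches")
        if len(weights) != len(niches):
            raise ValueError("one weight per niche required")
        if any(w < 0 or w > 1 for w in weights):
            raise ValueError(f"weights must lie in [0, 1]: {weights}")
        if abs(sum(weights) - 1.0) > 1e-12:
            raise ValueError(f"weights must sum to 1: {weights}")
        object.__setattr__(self, "niches", niches)
        object.__setattr__(self, "weights", weights)

    @property
    def k(self) -> int:
        return len(self.niches)

    @property
    def ratios(self) -> tuple[NicheRatios, ...]:
        return tuple(n.ratios for n in self.niches)


@dataclass(frozen=True)
class ThetaEstimate:
    """Per-niche Hubbell biodiversity numbers with rare/abundant labels."""

    theta_by_niche: tuple[float, ...]
    labels: tuple[str, ...]
    degenerate: bool = False

    def __getitem__(self, label: str) -> float:
        return self.theta_by_niche[self.labels.index(label)]


def ztnb_logpmf(n, ratios: NicheRates | NicheRatios):
    """Log-probability of abundance ``n >= 1`` under the ZTNB."""
    rt = _as_ratios(ratios)
    n = np.asarray(n)
    if (n < 1).any() or not np.issubdtype(n.dtype, np.integer) and not np.all(n == np.floor(n)):
        raise ValueError("ZTNB support is the positive integers")
    n = n.astype(np.float64)
    return (
        n * np.log(rt.x)
        + gammaln(n + rt.r)
        - gammaln(n + 1.0)
        - gammaln(rt.r)
        - rt.log_norm
    )


def ztnb_pmf(n, ratios: NicheRates | NicheRatios):
    """P(abundance = n) under the zero-truncated Negative Binomial."""
    out = np.exp(ztnb_logpmf(n, ratios))
    return float(out) if out.ndim == 0 else out


def ztnb_mean(ratios: NicheRates | NicheRatios) -> float:
    """Expected abundance r*x / ((1-x) * (1 - (1-x)^r)); always >= 1."""
    rt = _as_ratios(ratios)
    return rt.r * rt.x / ((1.0 - rt.x) * rt.positive_mass)


def mixture_pmf(n, model: MixtureModel):
    """Weighted sum of the component ZTNB pmfs."""
    n = np.asarray(n)
    out = np.zeros(n.shape, dtype=np.float64)
    for w, rt in zip(model.weights, model.ratios):
        if w > 0.0:
            out += w * np.exp(ztnb_logpmf(n, rt))
    return float(out) if out.ndim == 0 else out


def expected_sad(n, model: MixtureModel, n_obs: int):
    """Expected number of species with abundance n: N_obs * P_mix(n)."""
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    return n_obs * mixture_pmf(n, model)


def theta(ratios: NicheRates | NicheRatios, n_obs: int) -> float:
    """Hubbell's fundamental biodiversity number of one niche.

    theta = N_obs / (((1-x)^(-r) - 1) * Gamma(r)), evaluated in log space.
    Exactly linear in ``n_obs``.
    """
    rt = _as_ratios(ratios)
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    return float(np.exp(np.log(n_obs) - rt.log_norm - gammaln(rt.r)))


#: table sampler gives up past this support size (heavy log-series tails)
TABLE_CAP = 1 << 25
#: below this P(N >= 1), zero-rejection is hopeless and the table is used
REJECTION_PPOS = 0.5


def _sample_ztnb_rejection(
    rt: NicheRatios, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Rejection of zeros from the untruncated NB(r, 1-x), in chunks.

    Each round draws enough candidates to cover the remaining slots in
    expectation and keeps the positive ones in draw order, which leaves
    the accepted values exactly ZTNB-distributed.
    """
    p_pos = rt.positive_mass
    out = np.empty(size, dtype=np.int64)
    filled = 0
    rejections = 0
    # numpy's negative_binomial(n, p) has success probability p per trial
    # and pmf proportional to (1-p)^k, so p = 1 - x.
    p = 1.0 - rt.x
    while filled < size:
        need = size - filled
        m = min(int(need / p_pos * 1.2) + 16, 4_000_000)
        cand = rng.negative_binomial(rt.r, p, size=m)
        pos = cand[cand > 0]
        take = min(need, pos.size)
        out[filled : filled + take] = pos[:take]
        filled += take
        rejections += m - int(pos.size)
        if rejections > REJECTION_CAP:
            raise SamplingCapError(
                f"more than {REJECTION_CAP} zero-rejections "
                f"(x={rt.x:.4g}, r={rt.r:.4g})",
                rt,
            )
    if out.max() > ABUNDANCE_CAP:
        raise SamplingCapError(
            f"sampled abundance exceeds {ABUNDANCE_CAP} "
            f"(x={rt.x:.4g}, r={rt.r:.4g})",
            rt,
        )
    return out


def _sample_ztnb_table(
    rt: NicheRatios, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Exact inverse-CDF draw from the ZTNB via the pmf recursion.

    Uses pmf(k) = pmf(k-1) * x * (k - 1 + r) / k, accumulated with
    cumulative products in doubling chunks until the table covers the
    largest uniform; cheap precisely where rejection is hopeless (small
    P(N >= 1), i.e. the log-series-like regime r -> 0).
    """
    u = rng.random(size)
    umax = float(u.max())
    x, r = rt.x, rt.r
    chunks: list[np.ndarray] = []
    start = 1  # first abundance of the next chunk
    total = 0.0
    last_pmf = None
    chunk = 64
    while True:
        ks = np.arange(start, start + chunk, dtype=np.float64)
        ratios = x * (ks - 1.0 + r) / ks
        if start == 1:
            # seed the recursion: pmf(1) = x * r / ((1-x)^(-r) - 1)
            ratios[0] = x * r / np.expm1(-r * np.log1p(-x))
        else:
            ratios[0] *= last_pmf
        pmf = np.cumprod(ratios)
        cdf = total + np.cumsum(pmf)
        chunks.append(cdf)
        new_total = float(cdf[-1])
        if new_total >= umax or new_total <= total:  # covered or underflowed
            break
        last_pmf = float(pmf[-1])
        total = new_total
        start += chunk
        if start > TABLE_CAP:
            raise SamplingCapError(
                f"ZTNB quantile table exceeds {TABLE_CAP} entries "
                f"(x={rt.x:.4g}, r={rt.r:.4g})",
                rt,
            )
        chunk = min(chunk * 2, TABLE_CAP)
    full = chunks[0] if len(chunks) == 1 else np.concatenate(chunks)
    return np.searchsorted(full, u, side="left").astype(np.int64) + 1


def sample_ztnb(
    ratios: NicheRates | NicheRatios, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``size`` abundances from the zero-truncated NB.

    Zeros of the untruncated NB(r, 1-x) are rejected when P(N >= 1) is
    large enough for that to terminate quickly; otherwise an exact
    inverse-CDF table built from the pmf recursion is used.  Parameters
    whose mean abundance makes draws exceed ``ABUNDANCE_CAP``, or whose
    quantile table would be absurdly long (deep log-series tails, x very
    close to 1), abort with SamplingCapError.
    """
    rt = _as_ratios(ratios)
    if size < 1:
        raise ValueError("size must be >= 1")
    mean_untrunc = rt.r * rt.x / (1.0 - rt.x)
    if mean_untrunc > 1e3 * ABUNDANCE_CAP:
        raise SamplingCapError(
            f"mean abundance {mean_untrunc:.3g} beyond the abundance cap "
            f"(x={rt.x:.4g}, r={rt.r:.4g})",
            rt,
        )
    if rt.positive_mass >= REJECTION_PPOS:
        return _sample_ztnb_rejection(rt, size, rng)
    return _sample_ztnb_table(rt, size, rng)


def _sample_counts_from_ratios(
    ratios_seq: Sequence[NicheRatios],
    weights: Sequence[float],
    n_obs: int,
    rng: np.random.Generator,
) -> np.ndarray:
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    k = len(ratios_seq)
    if k == 1:
        return sample_ztnb(ratios_seq[0], n_obs, rng)
    cumw = np.cumsum(weights[:-1])
    assignment = np.searchsorted(cumw, rng.random(n_obs), side="right")
    parts = []
    for i in range(k):
        m = int(np.count_nonzero(assignment == i))
        if m:
            parts.append(sample_ztnb(ratios_seq[i], m, rng))
    return np.concatenate(parts) if len(parts) > 1 else parts[0]


def sample_community_counts(
    model: MixtureModel, n_obs: int, rng: np.random.Generator
) -> np.ndarray:
    """Abundances of ``n_obs`` species as a plain array, niche-index order.

    RNG consumption order (the determinism contract relied on by the ABC
    engine's reference-loop check): for K > 1, one uniform per species for
    the niche assignment, then each niche's truncated draws in niche-index
    order.
    """
    return _sample_counts_from_ratios(model.ratios, model.weights, n_obs, rng)


def sample_community(
    model: MixtureModel, n_obs: int, rng: np.random.Generator
):
    """Sample the abundances of ``n_obs`` species from a mixture model.

    Each species is assigned to a niche by the mixture weights, then its
    abundance is drawn from that niche's ZTNB.  Matches the observed
    species richness only (total read count is not conditioned on).
    """
    from .rsa import AbundanceVector

    return AbundanceVector(counts=sample_community_counts(model, n_obs, rng))


def label_niches(model: MixtureModel, n_obs: int) -> ThetaEstimate:
    """Label niches rare/abundant (plus middle for K = 3) by expected
    abundance and report each niche's Hubbell number.

    The niche with the smaller ZTNB mean is "rare"; exact ties break by
    list position (lower index = rare) and set the degenerate flag.
    Labels are attached to the parameters, not the list order.
    """
    means = [ztnb_mean(rt) for rt in model.ratios]
    thetas = tuple(theta(rt, n_obs) for rt in model.ratios)
    if model.k == 1:
        return ThetaEstimate(theta_by_niche=thetas, labels=("single",))
    order = sorted(range(model.k), key=lambda i: (means[i], i))
    degenerate = len(set(means)) < model.k
    labels = [""] * model.k
    if model.k == 2:
        labels[order[0]] = "rare"
        labels[order[1]] = "abundant"
    else:
        labels[order[0]] = "rare"
        labels[order[1]] = "middle"
        labels[order[2]] = "abundant"
    return ThetaEstimate(
        theta_by_niche=thetas, labels=tuple(labels), degenerate=degenerate
    )
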