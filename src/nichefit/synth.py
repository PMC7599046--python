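"""Synthetic communities and cohorts with known generating truth.

Every generator returns both the data and a complete truth record (the
generating rates, ratios and Hubbell numbers), so recovery tests always
have access to the quantities the fitters are supposed to estimate, and
every fixture regenerates bit-identically from (spec, seed).

The cohort generator emulates the structure the cohort statistics
assume: subjects with an age, sex, pseudo-dataset label and log-normally
varying read depth, whose two-niche community parameters follow smooth
age trajectories.  The default trajectories reproduce the qualitative
aging pattern of human gut biodiversity — rising through youth, flat in
the middle ages, rising again in old age — by scaling the immigration-
to-birth ratio of both niches down along that trend (for the default
parameter ranges, Hubbell's theta falls as r grows, so a declining r(age)
yields a rising theta(age)).  Read depth does not resample the community:
the niche model describes species counts, not reads (an optional
multinomial read-resampling switch exists for robustness checks).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cohort import classify_health
from .niche import MixtureModel, NicheRates, sample_community, theta, ztnb_mean
from .rsa import AbundanceVector, OTUTable

__all__ = [
    "CohortSpec",
    "default_recovery_model",
    "make_community",
    "make_cohort",
    "make_elderly_cohort",
    "aging_trend",
]


def default_recovery_model() -> MixtureModel:
    """The standard two-niche recovery fixture: well-separated niches with
    expected abundances 1.5 (rare, weight 0.7) and 50 (abundant)."""
    return MixtureModel(
        niches=(
            NicheRates(b=1.0, d=3.0, s=1.0),      # x = 1/3,  r = 1, mean 1.5
            NicheRates(b=0.98, d=1.0, s=0.98),    # x = 0.98, r = 1, mean 50
        ),
        weights=(0.7, 0.3),
    )


def _truth_record(model: MixtureModel, n_obs: int) -> dict:
    """Generating rates, ratios and per-niche Hubbell numbers."""
    rec: dict = {"n_obs": n_obs, "k": model.k}
    means = [ztnb_mean(rt) for rt in model.ratios]
    order = sorted(range(model.k), key=lambda i: (means[i], i))
    if model.k == 1:
        labels = {order[0]: "single"}
    elif model.k == 2:
        labels = {order[0]: "rare", order[1]: "abundant"}
    else:
        labels = {order[0]: "rare", order[1]: "middle", order[2]: "abundant"}
    for i, (nr, rt, w) in enumerate(zip(model.niches, model.ratios, model.weights)):
        lab = labels[i]
        rec[f"{lab}_b"] = nr.b
        rec[f"{lab}_d"] = nr.d
        rec[f"{lab}_s"] = nr.s
        rec[f"{lab}_x"] = rt.x
        rec[f"{lab}_r"] = rt.r
        rec[f"{lab}_weight"] = w
        rec[f"{lab}_mean"] = means[i]
        rec[f"theta_{lab}"] = theta(rt, n_obs)
    return rec


def make_community(
    model: MixtureModel, n_obs: int, seed: int, sample_id: str = "S0"
) -> tuple[OTUTable, dict]:
    """One-sample OTU table drawn from a mixture model, plus its truth."""
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))
    av = sample_community(model, n_obs, rng)
    table = OTUTable(
        sample_ids=(sample_id,),
        otu_ids=tuple(f"OTU{i:05d}" for i in range(n_obs)),
        counts=av.counts[None, :],
    )
    return table, _truth_record(model, n_obs)


def aging_trend(age) -> np.ndarray:
    """Smooth aging profile in [0, 1]: rising through youth (to ~40),
    flat in the middle ages, rising again after ~70."""
    age = np.asarray(age, dtype=np.float64)
    young = 0.5 / (1.0 + np.exp(-(age - 30.0) / 6.0))
    old = 0.5 / (1.0 + np.exp(-(age - 80.0) / 6.0))
    return young + old


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic cohort with age/sex/reads/dataset structure.

    The per-niche trajectories map age (years) to the ZTNB parameters of
    the rare and abundant niches; they must stay inside the valid domain
    (0 < x < 1, r > 0) over the whole age range.  Health scores (for
    elderly cohorts) are linear in standardized theta_rare with Gaussian
    noise of the stated sd.
    """

    n_subjects: int = 600
    age_range: tuple[float, float] = (20.0, 100.0)
    n_datasets: int = 3
    x_rare: Callable[[float], float] = lambda age: 1.0 / 3.0
    r_rare: Callable[[float], float] = lambda age: 1.2 * math.exp(
        -0.5 * float(aging_trend(age))
    )
    x_abundant: Callable[[float], float] = lambda age: 0.98
    r_abundant: Callable[[float], float] = lambda age: 1.5 * math.exp(
        -0.8 * float(aging_trend(age))
    )
    weight_rare: float = 0.7
    n_obs: int = 500
    read_depth_log_mean: float = math.log(5e4)
    read_depth_log_sd: float = 0.4
    sex_p_female: float = 0.5
    sample_communities: bool = False   # draw the full OTU table (slower)
    resample_reads: bool = False       # multinomial read-resampling switch
    index_noise_sd: float = 0.2        # log-normal sd of observed theta around truth
    health_slope: float = 3.0          # score units per sd of theta_rare
    health_noise_sd: float = 1.0
    seed: int = 0

    def model_at(self, age: float) -> MixtureModel:
        return MixtureModel(
            niches=(
                _rates_from_ratios(self.x_rare(age), self.r_rare(age)),
                _rates_from_ratios(self.x_abundant(age), self.r_abundant(age)),
            ),
            weights=(self.weight_rare, 1.0 - self.weight_rare),
        )

    def validate_trajectories(self, n_grid: int = 101) -> None:
        for age in np.linspace(*self.age_range, n_grid):
            for name, x, r in (
                ("rare", self.x_rare(age), self.r_rare(age)),
                ("abundant", self.x_abundant(age), self.r_abundant(age)),
            ):
                if not (0.0 < x < 1.0 and r > 0.0):
                    raise ValueError(
                        f"{name} trajectory leaves the valid domain at age "
                        f"{age:.1f}: x={x}, r={r}"
                    )


def _rates_from_ratios(x: float, r: float) -> NicheRates:
    # any rates with b/d = x and s/b = r; fix d = 1
    return NicheRates(b=x, d=1.0, s=r * x)


def make_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, OTUTable | None]:
    """Synthetic cohort table (one row per subject) and, when
    ``spec.sample_communities``, the matching OTU table.

    The returned frame carries both the observable covariates (age, sex,
    dataset, total_reads) and the generating truth (theta_rare,
    theta_abundant and the niche parameters per subject).
    """
    spec.validate_trajectories()
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(spec.seed)))
    ages = rng.uniform(*spec.age_range, size=spec.n_subjects)
    sexes = (rng.random(spec.n_subjects) < spec.sex_p_female).astype(int)
    datasets = np.array(
        [f"D{i % spec.n_datasets + 1}" for i in range(spec.n_subjects)]
    )
    depths = np.exp(
        rng.normal(spec.read_depth_log_mean, spec.read_depth_log_sd, spec.n_subjects)
    ).astype(np.int64)
    rows = []
    communities: list[np.ndarray] = []
    for i in range(spec.n_subjects):
        model = spec.model_at(float(ages[i]))
        truth = _truth_record(model, spec.n_obs)
        row = {
            "sample_id": f"subj{i:04d}",
            "age": float(ages[i]),
            "sex": int(sexes[i]),
            "dataset": datasets[i],
            "total_reads": int(depths[i]),
            **{k: v for k, v in truth.items() if k != "k"},
        }
        if spec.sample_communities:
            counts = sample_community(model, spec.n_obs, rng).counts
            if spec.resample_reads:
                p = counts / counts.sum()
                counts = rng.multinomial(int(depths[i]), p)
            communities.append(counts)
        rows.append(row)
    cohort = pd.DataFrame(rows)
    # observed diversity = truth with log-normal estimation noise; truth
    # stays available under *_true for recovery checks
    for col in ("theta_rare", "theta_abundant"):
        cohort[f"{col}_true"] = cohort[col]
        if spec.index_noise_sd > 0:
            noise = rng.normal(0.0, spec.index_noise_sd, spec.n_subjects)
            cohort[col] = cohort[col] * np.exp(noise)
    table = None
    if spec.sample_communities:
        width = max(c.size for c in communities)
        mat = np.zeros((spec.n_subjects, width), dtype=np.int64)
        for i, c in enumerate(communities):
            mat[i, : c.size] = c
        table = OTUTable(
            sample_ids=tuple(cohort["sample_id"]),
            otu_ids=tuple(f"OTU{i:05d}" for i in range(width)),
            counts=mat,
        )
    return cohort, table


def make_elderly_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Elderly cohort with Barthel/MMSE/FIM scores and residence setting.

    Health scores are linear in standardized theta_rare plus Gaussian
    noise (sd ``health_noise_sd``), then clipped to their instruments'
    ranges (Barthel 0-20, MMSE 0-30, FIM 18-126).  Residence is sampled
    with log-odds increasing in the same latent health.  Truth labels are
    obtained by running the four-criterion classifier on the generated
    scores.
    """
    if spec.age_range[0] < 60:
        spec = replace(spec, age_range=(65.0, 95.0))
    cohort, _ = make_cohort(spec)
    rng = np.random.Generator(
        np.random.Philox(np.random.SeedSequence(entropy=spec.seed, spawn_key=(1,)))
    )
    th = cohort["theta_rare_true"].to_numpy()
    z = (th - th.mean()) / th.std(ddof=0) if th.std(ddof=0) > 0 else np.zeros(len(th))
    n = len(cohort)
    latent = spec.health_slope * z + rng.normal(0.0, spec.health_noise_sd, n)
    cohort["barthel"] = np.clip(np.round(16.0 + 2.0 * latent), 0, 20)
    cohort["mmse"] = np.clip(np.round(25.0 + 2.5 * latent), 0, 30)
    cohort["fim"] = np.clip(np.round(105.0 + 10.0 * latent), 18, 126)
    if spec.health_noise_sd == 0:
        in_community = latent >= 0
    else:
        odds = 1.0 / (1.0 + np.exp(-1.5 * latent))
        in_community = rng.random(n) < odds
    cohort["residence"] = np.where(in_community, "Community", "Long-stay")
    cohort["healthy"] = [
        classify_health(b, m, f, r).healthy
        for b, m, f, r in zip(
            cohort["barthel"], cohort["mmse"], cohort["fim"], cohort["residence"]
        )
    ]
    return cohort
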