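"""Straight-line pure-Python reference of the ABC rejection engine.

Reimplements, draw for draw, the engine's documented RNG consumption
contract with plain scalar code and scipy, so the compiled kernel can be
checked against an independent implementation of the same algorithm.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import chdtr

ABUNDANCE_CAP = 10**9
REJECTION_CAP = 10**6
TABLE_CAP = 1 << 25
RESAMPLE_CAP = 10_000


def _draw(prior, rng):
    family, (a, b) = prior.family, prior.params
    if family == "log-uniform":
        return math.exp(rng.uniform(math.log(a), math.log(b)))
    if family == "uniform":
        return rng.uniform(a, b)
    if family == "gamma":
        return rng.gamma(a, b)
    return rng.beta(a, b)


def _propose(priors, k, rng):
    niches = []
    if priors.space == "ratios":
        for pr in priors.niche_priors:
            for _ in range(RESAMPLE_CAP):
                x = _draw(pr["x"], rng)
                if 0.0 < x < 1.0:
                    break
            else:
                raise RuntimeError("x resampling cap")
            r = _draw(pr["r"], rng)
            niches.append((x, 1.0, r * x))
    else:
        for pr in priors.niche_priors:
            for _ in range(RESAMPLE_CAP):
                b = _draw(pr["b"], rng)
                d = _draw(pr["d"], rng)
                if b < d:
                    break
            else:
                raise RuntimeError("b < d resampling cap")
            s = _draw(pr["s"], rng)
            niches.append((b, d, s))
    if k == 1:
        weights = [1.0]
    elif k == 2:
        a = _draw(priors.weight_priors[0], rng)
        weights = [a, 1.0 - a]
    else:
        for _ in range(RESAMPLE_CAP):
            a = _draw(priors.weight_priors[0], rng)
            bta = _draw(priors.weight_priors[1], rng)
            if a + bta <= 1.0:
                break
        else:
            raise RuntimeError("simplex resampling cap")
        weights = [a, bta, 1.0 - a - bta]
    return niches, weights


def _prescreen_skip(niches, weights, n_obs, data_bins, tol):
    """Expected-octave Chernoff screen, scalar arithmetic in engine order."""
    n_screen, support = 9, 511
    n_bins = len(data_bins)
    exp_oct = [0.0] * n_screen
    resid = 1.0
    for (b, d, s), w in zip(niches, weights):
        x, r = b / d, s / b
        norm = math.expm1(-r * math.log1p(-x))
        pmf = x * r / norm
        kk = 1.0
        o = 0
        edge = 2.0
        acc = 0.0
        for _ in range(support):
            acc += pmf
            kk += 1.0
            if kk >= edge:
                exp_oct[o] += w * acc
                resid -= w * acc
                acc = 0.0
                o += 1
                edge *= 2.0
            pmf *= x * (kk - 1.0 + r) / kk
    def logbound(a, p):
        q = a / n_obs
        if q <= 0.0 or q >= 1.0:
            return 0.0
        return -n_obs * (q * math.log(q / p) + (1 - q) * math.log((1 - q) / (1 - p)))
    for i in range(n_screen):
        db = data_bins[i] if i < n_bins else 0.0
        p_i = min(max(exp_oct[i], 1e-300), 1.0 - 1e-15)
        if db > 0.0:
            lo, hi = db - tol * db, db + tol * db
            mean_i = n_obs * p_i
            if mean_i < lo and logbound(lo, p_i) < -27.7:
                return True
            if mean_i > hi and logbound(hi, p_i) < -27.7:
                return True
    if n_bins <= n_screen and resid > 0.0:
        p_r = min(resid, 1.0 - 1e-15)
        if n_obs * p_r > 64.0 and logbound(64.0, p_r) < -27.7:
            return True
    return False


def _sample_ztnb(x, r, m, rng):
    """Scalar hybrid ZTNB sampler following the engine's branch rule."""
    p_pos = -math.expm1(r * math.log1p(-x))
    if r * x / (1.0 - x) > 1e3 * ABUNDANCE_CAP:
        raise OverflowError
    est = int(40.0 / (-math.log(x))) + 64 if x > 0 else 64
    if est > 40 * m + 1024 or est > TABLE_CAP:
        out = []
        rejections = 0
        p = 1.0 - x
        for _ in range(m):
            v = rng.negative_binomial(r, p)
            while v == 0:
                rejections += 1
                if rejections > REJECTION_CAP:
                    raise OverflowError
                v = rng.negative_binomial(r, p)
            if v > ABUNDANCE_CAP:
                raise OverflowError
            out.append(v)
        return out
    us = [rng.random() for _ in range(m)]
    umax = max(us)
    norm = math.expm1(-r * math.log1p(-x))
    length = max(64, est)
    table = []
    pmf = x * r / norm
    cum = 0.0
    kk = 1.0
    while True:
        while len(table) < length:
            cum += pmf
            table.append(cum)
            kk += 1.0
            pmf *= x * (kk - 1.0 + r) / kk
        if cum >= umax or pmf <= 0.0:
            break
        if length >= TABLE_CAP:
            raise OverflowError
        length = min(length * 2, TABLE_CAP)
    arr = np.array(table)
    return [min(int(np.searchsorted(arr, u)), len(table) - 1) + 1 for u in us]


def reference_abc(av, k, priors, config, rng):
    """Accepted (params, chi2, df) triples of a full rejection run."""
    from nichefit.rsa import preston_histogram

    data_bins = list(preston_histogram(av).bin_counts.astype(float))
    n_bins = len(data_bins)
    n_obs = av.n_obs
    accepted = []
    for _ in range(config.n_sims):
        niches, weights = _propose(priors, k, rng)
        if _prescreen_skip(niches, weights, n_obs, data_bins, config.bin_tolerance):
            continue
        try:
            if k == 1:
                b, d, s = niches[0]
                counts = _sample_ztnb(b / d, s / b, n_obs, rng)
            else:
                assign = []
                for _ in range(n_obs):
                    u = rng.random()
                    cum = 0.0
                    nich = k - 1
                    for j in range(k - 1):
                        cum += weights[j]
                        if u < cum:
                            nich = j
                            break
                    assign.append(nich)
                counts = []
                for j in range(k):
                    m = assign.count(j)
                    if m:
                        b, d, s = niches[j]
                        counts.extend(_sample_ztnb(b / d, s / b, m, rng))
        except OverflowError:
            continue
        sim = {}
        for v in counts:
            o = int(v).bit_length() - 1
            sim[o] = sim.get(o, 0) + 1
        max_oct = max(sim)
        ok = True
        for i, db in enumerate(data_bins):
            if db > 0 and abs(sim.get(i, 0) - db) > config.bin_tolerance * db:
                ok = False
                break
        if not ok:
            continue
        chi2 = 0.0
        df = 0
        for i in range(max(n_bins, max_oct + 1)):
            db = data_bins[i] if i < n_bins else 0.0
            sb = float(sim.get(i, 0))
            if db + sb > 0:
                chi2 += (db - sb) ** 2 / (db + sb)
                df += 1
        if config.df_mode == "data":
            df = sum(1 for v in data_bins if v > 0)
        if chdtr(df, chi2) < config.chi2_cdf_cutoff:
            accepted.append((niches, weights, chi2, df))
    return accepted
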