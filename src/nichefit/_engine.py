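"""Compiled inner loop of the ABC rejection fitter.

The kernel replays, per proposal: prior draws (with the b < d resampling
rule), community sampling at the observed richness, octave binning and
both acceptance conditions.  It is compiled with numba, whose
``np.random.Generator`` methods are bit-compatible with numpy's, so a
plain-Python loop making the same sequence of Generator calls reproduces
the kernel draw for draw (the tests rely on this to cross-check the
engine against a straight-line reference implementation).

RNG consumption contract, per proposal:

1. per niche in index order: (b, d) pairs until b < d, then s;
2. for K > 1, the K-1 free mixture weights (for K = 3 an (alpha, beta)
   pair is redrawn until alpha + beta <= 1);
3. for K > 1, one uniform per species for the niche assignment;
4. per niche in index order, its species' abundances: one uniform per
   species inverted through a cumulative ZTNB table built from the pmf
   recursion when the needed support (~40/(-ln x) entries) is short
   relative to the draw count, otherwise one ``negative_binomial(r, 1-x)``
   call per species with zeros redrawn.

Proposals whose sampling hits the abundance or table caps consume no
further randomness and count as rejected.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# mirrored from niche.py; duplicated literals keep the kernel self-contained
ABUNDANCE_CAP = 10**9
REJECTION_CAP = 10**6
TABLE_CAP = 1 << 25
REJECTION_PPOS = 0.5
RESAMPLE_CAP = 10_000
MAX_OCTAVES = 64

STATUS_OK = 0
STATUS_CAP = -1          # sampling cap hit -> proposal rejected
STATUS_PRIOR_ERROR = -2  # b < d (or simplex) resampling cap exceeded


@njit(cache=True)
def _draw1(code, a, b, rng):
    if code == 0:
        return math.exp(rng.uniform(a, b))  # log-uniform, bounds pre-logged
    if code == 1:
        return rng.uniform(a, b)
    if code == 2:
        return rng.gamma(a, b)
    return rng.beta(a, b)


@njit(cache=True)
def _chi2_cdf(df, x):
    """Regularized lower incomplete gamma P(df/2, x/2): series for small x,
    Lentz continued fraction otherwise (Numerical-Recipes style)."""
    a = 0.5 * df
    x = 0.5 * x
    if x <= 0.0:
        return 0.0
    gln = math.lgamma(a)
    if x < a + 1.0:
        ap = a
        s = 1.0 / a
        delta = s
        for _ in range(500):
            ap += 1.0
            delta *= x / ap
            s += delta
            if abs(delta) < abs(s) * 1e-15:
                break
        return s * math.exp(-x + a * math.log(x) - gln)
    # continued fraction for Q(a, x)
    tiny = 1e-300
    b0 = x + 1.0 - a
    c = 1.0 / tiny
    d = 1.0 / b0
    h = d
    for i in range(1, 500):
        an = -i * (i - a)
        b0 += 2.0
        d = an * d + b0
        if abs(d) < tiny:
            d = tiny
        c = b0 + an / c
        if abs(c) < tiny:
            c = tiny
        d = 1.0 / d
        delta = d * c
        h *= delta
        if abs(delta - 1.0) < 1e-15:
            break
    q = math.exp(-x + a * math.log(x) - gln) * h
    return 1.0 - q


@njit(cache=True)
def _binom_tail_log_bound(n, a, p):
    """Chernoff log-bound on P(Bin(n, p) >= a) for a/n > p, or
    P(Bin(n, p) <= a) for a/n < p: -n * KL(a/n || p)."""
    q = a / n
    if q <= 0.0 or q >= 1.0:
        return 0.0
    return -n * (
        q * math.log(q / p) + (1.0 - q) * math.log((1.0 - q) / (1.0 - p))
    )


@njit(cache=True)
def _sample_ztnb_seg(rng, x, r, out, start, m):
    """Fill out[start:start+m] with ZTNB(x, r) draws; returns a status."""
    log1mx = math.log1p(-x)
    p_pos = -math.expm1(r * log1mx)
    mean_untrunc = r * x / (1.0 - x)
    if mean_untrunc > 1e3 * ABUNDANCE_CAP:
        return STATUS_CAP
    # the inverse-CDF table needs ~40/(-ln x) entries to cover the tail;
    # prefer it whenever that is cheap relative to per-draw rejection
    est = int(40.0 / (-math.log(x))) + 64 if x > 0.0 else 64
    if est > 40 * m + 1024 or est > TABLE_CAP:
        p = 1.0 - x
        rejections = 0
        for i in range(m):
            v = rng.negative_binomial(r, p)
            while v == 0:
                rejections += 1
                if rejections > REJECTION_CAP:
                    return STATUS_CAP
                v = rng.negative_binomial(r, p)
            if v > ABUNDANCE_CAP:
                return STATUS_CAP
            out[start + i] = v
        return STATUS_OK
    # inverse-CDF table from the pmf recursion (log-series-like regime)
    us = np.empty(m, dtype=np.float64)
    umax = 0.0
    for i in range(m):
        u = rng.random()
        us[i] = u
        if u > umax:
            umax = u
    norm = math.expm1(-r * log1mx)
    length = 64 if est < 64 else est
    table = np.empty(length, dtype=np.float64)
    pmf = x * r / norm  # pmf(1)
    cum = 0.0
    idx = 0
    kk = 1.0
    while True:
        while idx < length:
            cum += pmf
            table[idx] = cum
            idx += 1
            kk += 1.0
            pmf *= x * (kk - 1.0 + r) / kk
        if cum >= umax or pmf <= 0.0:
            break
        if length >= TABLE_CAP:
            return STATUS_CAP
        new_len = length * 2
        if new_len > TABLE_CAP:
            new_len = TABLE_CAP
        new_table = np.empty(new_len, dtype=np.float64)
        new_table[:length] = table
        table = new_table
        length = new_len
    for i in range(m):
        k = np.searchsorted(table[:idx], us[i])
        if k >= idx:
            k = idx - 1
        out[start + i] = k + 1
    return STATUS_OK


@njit(cache=True)
def abc_kernel(
    rng,
    n_sims,
    k,
    ratio_space,  # priors parameterize (x, r) instead of (b, d, s)
    prior_code,   # (k, 3) int64: family codes for b, d, s (or x, r, unused)
    prior_a,      # (k, 3) float64
    prior_b,      # (k, 3) float64
    wcode,        # (k-1,) int64
    wa,           # (k-1,) float64
    wb,           # (k-1,) float64
    n_obs,
    data_bins,    # float64[:]
    bin_tolerance,
    chi2_cdf_cutoff,
    df_data_only,  # bool: df counts data-positive bins only
    acc_params,    # (max_acc, 4*k) float64 out: b,d,s per niche then weights
    acc_chi2,      # (max_acc,) float64 out
    acc_df,        # (max_acc,) int64 out
):
    """Full rejection run; returns (n_accepted, status).

    status < 0 reports a prior resampling failure or an overflowing
    accept buffer (callers raise); sampling-cap proposals are silently
    rejected, as the acceptance conditions would almost surely reject
    their astronomically sized communities anyway.
    """
    n_bins = data_bins.shape[0]
    counts = np.empty(n_obs, dtype=np.int64)
    mcount = np.empty(k, dtype=np.int64)
    assign = np.empty(n_obs, dtype=np.int64)
    bs = np.empty(k, dtype=np.float64)
    ds = np.empty(k, dtype=np.float64)
    ss = np.empty(k, dtype=np.float64)
    ws = np.empty(k, dtype=np.float64)
    simb = np.zeros(MAX_OCTAVES, dtype=np.float64)
    n_screen = 9           # octaves screened analytically
    screen_support = 511   # abundances 1..511 cover those octaves
    exp_oct = np.empty(n_screen, dtype=np.float64)
    df_pos = 0
    for i in range(n_bins):
        if data_bins[i] > 0:
            df_pos += 1
    max_acc = acc_chi2.shape[0]
    n_acc = 0
    for _ in range(n_sims):
        # --- propose ---------------------------------------------------
        if ratio_space:
            for j in range(k):
                attempts = 0
                while True:
                    x = _draw1(prior_code[j, 0], prior_a[j, 0], prior_b[j, 0], rng)
                    if 0.0 < x < 1.0:
                        break
                    attempts += 1
                    if attempts >= RESAMPLE_CAP:
                        return n_acc, STATUS_PRIOR_ERROR
                r = _draw1(prior_code[j, 1], prior_a[j, 1], prior_b[j, 1], rng)
                bs[j] = x
                ds[j] = 1.0
                ss[j] = r * x
        else:
            for j in range(k):
                attempts = 0
                while True:
                    b = _draw1(prior_code[j, 0], prior_a[j, 0], prior_b[j, 0], rng)
                    d = _draw1(prior_code[j, 1], prior_a[j, 1], prior_b[j, 1], rng)
                    if b < d:
                        break
                    attempts += 1
                    if attempts >= RESAMPLE_CAP:
                        return n_acc, STATUS_PRIOR_ERROR
                bs[j] = b
                ds[j] = d
                ss[j] = _draw1(prior_code[j, 2], prior_a[j, 2], prior_b[j, 2], rng)
        if k == 1:
            ws[0] = 1.0
        elif k == 2:
            a0 = _draw1(wcode[0], wa[0], wb[0], rng)
            ws[0] = a0
            ws[1] = 1.0 - a0
        else:
            attempts = 0
            while True:
                a0 = _draw1(wcode[0], wa[0], wb[0], rng)
                b0 = _draw1(wcode[1], wa[1], wb[1], rng)
                if a0 + b0 <= 1.0:
                    break
                attempts += 1
                if attempts >= RESAMPLE_CAP:
                    return n_acc, STATUS_PRIOR_ERROR
            ws[0] = a0
            ws[1] = b0
            ws[2] = 1.0 - a0 - b0
        # --- expected-octave prescreen --------------------------------
        # Exact octave masses of the proposal mixture over the first
        # ``n_screen`` octaves, from the pmf recursion.  A proposal is
        # rejected without sampling (consuming no randomness) when a
        # Chernoff bound puts the probability of any screened data octave
        # landing in its 30% band, or of the beyond-data octaves staying
        # below the chi-squared ceiling, under 1e-12.
        for i in range(n_screen):
            exp_oct[i] = 0.0
        resid = 1.0  # mixture mass beyond the screened octaves
        for j in range(k):
            x = bs[j] / ds[j]
            r = ss[j] / bs[j]
            norm = math.expm1(-r * math.log1p(-x))
            pmf = x * r / norm  # pmf(1)
            w = ws[j]
            kk = 1.0
            o = 0
            edge = 2.0
            acc = 0.0
            for i in range(screen_support):
                acc += pmf
                kk += 1.0
                if kk >= edge:
                    exp_oct[o] += w * acc
                    resid -= w * acc
                    acc = 0.0
                    o += 1
                    edge *= 2.0
                pmf *= x * (kk - 1.0 + r) / kk
        skip = False
        for i in range(n_screen):
            db = data_bins[i] if i < n_bins else 0.0
            p_i = exp_oct[i]
            if p_i <= 0.0:
                p_i = 1e-300
            elif p_i >= 1.0:
                p_i = 1.0 - 1e-15
            if db > 0.0:
                lo = db - bin_tolerance * db
                hi = db + bin_tolerance * db
                mean_i = n_obs * p_i
                if mean_i < lo:
                    if _binom_tail_log_bound(n_obs, lo, p_i) < -27.7:
                        skip = True
                        break
                elif mean_i > hi:
                    if _binom_tail_log_bound(n_obs, hi, p_i) < -27.7:
                        skip = True
                        break
        if not skip and n_bins <= n_screen and resid > 0.0:
            # every species beyond the screened octaves adds >= 1 to chi2,
            # and the acceptance ceiling is below df <= 64
            p_r = resid if resid < 1.0 - 1e-15 else 1.0 - 1e-15
            if n_obs * p_r > 64.0:
                if _binom_tail_log_bound(n_obs, 64.0, p_r) < -27.7:
                    skip = True
        if skip:
            continue
        # --- sample the community -------------------------------------
        if k == 1:
            status = _sample_ztnb_seg(rng, bs[0] / ds[0], ss[0] / bs[0],
                                      counts, 0, n_obs)
            if status != STATUS_OK:
                continue
        else:
            for j in range(k):
                mcount[j] = 0
            for i in range(n_obs):
                u = rng.random()
                cum = 0.0
                nich = k - 1
                for j in range(k - 1):
                    cum += ws[j]
                    if u < cum:
                        nich = j
                        break
                assign[i] = nich
                mcount[nich] += 1
            failed = False
            start = 0
            for j in range(k):
                if mcount[j] == 0:
                    continue
                status = _sample_ztnb_seg(
                    rng, bs[j] / ds[j], ss[j] / bs[j], counts, start, mcount[j]
                )
                if status != STATUS_OK:
                    failed = True
                    break
                start += mcount[j]
            if failed:
                continue
        # --- octave binning -------------------------------------------
        max_oct = 0
        for i in range(MAX_OCTAVES):
            simb[i] = 0.0
        for i in range(n_obs):
            v = counts[i]
            o = 0
            while v > 1:
                v >>= 1
                o += 1
            simb[o] += 1.0
            if o > max_oct:
                max_oct = o
        # --- condition 1: 30% band on data-positive octaves -----------
        ok = True
        for i in range(n_bins):
            db = data_bins[i]
            if db > 0.0 and abs(simb[i] - db) > bin_tolerance * db:
                ok = False
                break
        if not ok:
            continue
        # --- condition 2: Skellam-motivated chi-squared ----------------
        nb_total = n_bins if n_bins > max_oct + 1 else max_oct + 1
        chi2 = 0.0
        df = 0
        for i in range(nb_total):
            db = data_bins[i] if i < n_bins else 0.0
            tot = db + simb[i]
            if tot > 0.0:
                diff = db - simb[i]
                chi2 += diff * diff / tot
                df += 1
        if df_data_only:
            df = df_pos
        if _chi2_cdf(df, chi2) >= chi2_cdf_cutoff:
            continue
        # --- record ----------------------------------------------------
        if n_acc >= max_acc:
            return n_acc, STATUS_CAP
        for j in range(k):
            acc_params[n_acc, 3 * j] = bs[j]
            acc_params[n_acc, 3 * j + 1] = ds[j]
            acc_params[n_acc, 3 * j + 2] = ss[j]
        for j in range(k):
            acc_params[n_acc, 3 * k + j] = ws[j]
        acc_chi2[n_acc] = chi2
        acc_df[n_acc] = df
        n_acc += 1
    return n_acc, STATUS_OK
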