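"""Independent brute-force oracles used to validate the package.

Everything here is written deliberately naively — explicit Python loops
and textbook formulas — and never calls into socialconcord, so it can
serve as an independent reference on tiny instances.
"""

import math
from itertools import combinations, permutations

import numpy as np


def brute_pearson(x, y):
    """Textbook product-moment correlation on complete pairs."""
    pairs = [(a, b) for a, b in zip(x, y)
             if not (math.isnan(a) or math.isnan(b))]
    if len(pairs) < 3:
        return float("nan")
    xs = [a for a, _ in pairs]
    ys = [b for _, b in pairs]
    mx = sum(xs) / len(xs)
    my = sum(ys) / len(ys)
    sxx = sum((a - mx) ** 2 for a in xs)
    syy = sum((b - my) ** 2 for b in ys)
    sxy = sum((a - mx) * (b - my) for a, b in zip(xs, ys))
    if sxx == 0 or syy == 0:
        return float("nan")
    return sxy / math.sqrt(sxx * syy)


def brute_mean_over_last(cube):
    """Missing-aware mean over the trailing axis, cell by cell."""
    n_i, n_f, n_r = cube.shape
    out = np.full((n_i, n_f), np.nan)
    for i in range(n_i):
        for j in range(n_f):
            vals = [cube[i, j, r] for r in range(n_r)
                    if not math.isnan(cube[i, j, r])]
            if vals:
                out[i, j] = sum(vals) / len(vals)
    return out


def brute_agreement(machine_mean, human_mean):
    """Column-by-column correlation of two item x feature matrices."""
    return np.array([
        brute_pearson(machine_mean[:, j], human_mean[:, j])
        for j in range(machine_mean.shape[1])
    ])


def brute_intersubject_consistency(cube):
    """Leave-one-out consistency feature by feature, rater by rater."""
    n_i, n_f, n_r = cube.shape
    out = np.full(n_f, np.nan)
    for j in range(n_f):
        rs = []
        for r in range(n_r):
            own = cube[:, j, r]
            others = np.array([
                brute_mean_over_last(
                    cube[i:i + 1, j:j + 1,
                         [k for k in range(n_r) if k != r]])[0, 0]
                for i in range(n_i)
            ])
            rr = brute_pearson(own, others)
            if not math.isnan(rr):
                rs.append(rr)
        if rs:
            out[j] = sum(rs) / len(rs)
    return out


def brute_group_consistency(cube, g):
    """All unordered disjoint split pairs, averaged feature by feature."""
    n_i, n_f, n_r = cube.shape
    splits = []
    for a in combinations(range(n_r), g):
        for b in combinations([r for r in range(n_r) if r not in a], g):
            if a < b:
                splits.append((a, b))
    out = np.full(n_f, np.nan)
    for j in range(n_f):
        rs = []
        for a, b in splits:
            ma = brute_mean_over_last(cube[:, j:j + 1, list(a)])[:, 0]
            mb = brute_mean_over_last(cube[:, j:j + 1, list(b)])[:, 0]
            rr = brute_pearson(ma, mb)
            if not math.isnan(rr):
                rs.append(rr)
        if rs:
            out[j] = sum(rs) / len(rs)
    return out, len(splits)


def brute_matrix_similarity(a, b):
    """Upper-triangle correlation via explicit index loops."""
    f = a.shape[0]
    xs, ys = [], []
    for i in range(f):
        for j in range(i + 1, f):
            xs.append(a[i, j])
            ys.append(b[i, j])
    return brute_pearson(xs, ys)


def brute_welch_t(x, y):
    """Closed-form Welch two-sample t with Satterthwaite df."""
    nx, ny = len(x), len(y)
    mx = sum(x) / nx
    my = sum(y) / ny
    vx = sum((a - mx) ** 2 for a in x) / (nx - 1)
    vy = sum((a - my) ** 2 for a in y) / (ny - 1)
    se2 = vx / nx + vy / ny
    t = (mx - my) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return t, df


def brute_ols_slope(x, y):
    """Simple-regression slope cov(x, y) / var(x)."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    return sxy / sxx


def brute_one_sample_t(values):
    """mean / (sd / sqrt(n)) with ddof 1."""
    n = len(values)
    m = sum(values) / n
    sd = math.sqrt(sum((v - m) ** 2 for v in values) / (n - 1))
    return m / (sd / math.sqrt(n))


def brute_convolved_regressor(clips, values, tr, n_volumes, hrf_kernel,
                              microtime=16):
    """Direct discrete convolution of the intensity boxcar with a kernel."""
    dt = tr / microtime
    n_fine = n_volumes * microtime
    box = np.zeros(n_fine + len(hrf_kernel))
    for item, onset, dur in clips:
        a = int(round(onset / dt))
        b = int(round((onset + dur) / dt))
        box[a:b] = values[item]
    conv = np.zeros(n_fine)
    for t in range(n_fine):
        s = 0.0
        for k in range(min(t + 1, len(hrf_kernel))):
            s += box[t - k] * hrf_kernel[k]
        conv[t] = s
    samples = conv[np.arange(n_volumes) * microtime]
    return samples - samples.mean()


def exhaustive_mantel_p(a, b):
    """Exact permutation p-value over all F! joint row/column permutations."""
    f = a.shape[0]
    obs = brute_matrix_similarity(a, b)
    null = []
    for p in permutations(range(f)):
        bp = b[np.ix_(p, p)]
        null.append(brute_matrix_similarity(a, bp))
    return sum(1 for v in null if v >= obs - 1e-12) / len(null)


def brute_pcoa_distances(loadings):
    """Pairwise Euclidean distances of full-rank PCoA coordinates."""
    f = loadings.shape[0]
    d = np.zeros((f, f))
    for i in range(f):
        for j in range(f):
            d[i, j] = math.sqrt(((loadings[i] - loadings[j]) ** 2).sum())
    return d
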