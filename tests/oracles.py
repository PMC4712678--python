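"""Independent reference implementations used only to check the package.

Each oracle is a direct, unoptimized transcription of the defining
procedure (full dynamic program, exhaustive enumeration, closed formula),
sharing no code with the implementation under test.
"""

import itertools
import math

import numpy as np
from numba import njit

NEG = -(10**9)


@njit(cache=True)
def full_dp_score(read, ref, match, mismatch, go, ge):
    """Unbanded affine semi-global score: read consumed fully, free
    end-gaps on the reference.  Plain full-matrix dynamic program."""
    n = read.shape[0]
    m = ref.shape[0]
    M = np.full((n + 1, m + 1), NEG, np.int64)
    X = np.full((n + 1, m + 1), NEG, np.int64)
    Y = np.full((n + 1, m + 1), NEG, np.int64)
    for j in range(m + 1):
        M[0, j] = 0
    for i in range(1, n + 1):
        for j in range(m + 1):
            a = M[i - 1, j] + go
            b = X[i - 1, j] + ge
            X[i, j] = a if a > b else b
            if j > 0:
                a = M[i, j - 1] + go
                b = Y[i, j - 1] + ge
                Y[i, j] = a if a > b else b
                diag = M[i - 1, j - 1]
                if X[i - 1, j - 1] > diag:
                    diag = X[i - 1, j - 1]
                if Y[i - 1, j - 1] > diag:
                    diag = Y[i - 1, j - 1]
                if diag > NEG // 2:
                    s = match if read[i - 1] == ref[j - 1] else mismatch
                    M[i, j] = diag + s
    best = NEG
    for j in range(m + 1):
        if M[n, j] > best:
            best = M[n, j]
        if X[n, j] > best:
            best = X[n, j]
    return best


def bh_stepup(p_values, fdr):
    """Benjamini-Hochberg by literal step-up enumeration: sort ascending,
    find the largest rank i with p(i) <= (i/m)*fdr, reject ranks <= i."""
    p = list(p_values)
    m = len(p)
    order = sorted(range(m), key=lambda k: p[k])
    cutoff_rank = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank / m * fdr:
            cutoff_rank = rank
    rejected = [False] * m
    for rank, idx in enumerate(order, start=1):
        if rank <= cutoff_rank:
            rejected[idx] = True
    return rejected


def bh_qvalues(p_values):
    """Monotone-adjusted BH q-values: q(i) = min_{k>=i} p(k)*m/k."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return q


def welch_t(a, b):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    from scipy.stats import t as tdist

    p = 2 * tdist.sf(abs(t), df)
    return t, p


def student_t(a, b):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    from scipy.stats import t as tdist

    p = 2 * tdist.sf(abs(t), na + nb - 2)
    return t, p


def mw_exact(a, b):
    """Exact two-sided Mann-Whitney p by enumerating every assignment of
    the pooled values to the two groups (requires no ties)."""
    pooled = list(a) + list(b)
    na = len(a)
    nm = na * len(b)

    def u_stat(group_a, group_b):
        return sum(1 for x in group_a for y in group_b if x > y)

    u_obs = u_stat(a, b)
    extreme_obs = min(u_obs, nm - u_obs)
    count = 0
    total = 0
    idx = range(len(pooled))
    for combo in itertools.combinations(idx, na):
        ga = [pooled[i] for i in combo]
        gb = [pooled[i] for i in idx if i not in set(combo)]
        u = u_stat(ga, gb)
        if min(u, nm - u) <= extreme_obs:
            count += 1
        total += 1
    return u_obs, count / total


def anova_two_way_balanced(table):
    """Hand sums-of-squares decomposition of a balanced two-way layout.

    ``table[i][j]`` is the list of replicates for level i of factor A and
    level j of factor B.  Returns dict of (F, df, SS) per effect.
    """
    a_levels = len(table)
    b_levels = len(table[0])
    r = len(table[0][0])
    all_vals = np.array(table, dtype=float)  # a x b x r
    grand = all_vals.mean()
    mean_ab = all_vals.mean(axis=2)
    mean_a = all_vals.mean(axis=(1, 2))
    mean_b = all_vals.mean(axis=(0, 2))
    ss_a = b_levels * r * ((mean_a - grand) ** 2).sum()
    ss_b = a_levels * r * ((mean_b - grand) ** 2).sum()
    ss_ab = r * (
        (mean_ab - mean_a[:, None] - mean_b[None, :] + grand) ** 2
    ).sum()
    ss_err = ((all_vals - mean_ab[:, :, None]) ** 2).sum()
    df_a = a_levels - 1
    df_b = b_levels - 1
    df_ab = df_a * df_b
    df_err = a_levels * b_levels * (r - 1)
    ms_err = ss_err / df_err
    return {
        "A": (ss_a / df_a / ms_err, df_a, ss_a),
        "B": (ss_b / df_b / ms_err, df_b, ss_b),
        "AB": (ss_ab / df_ab / ms_err, df_ab, ss_ab),
        "error": (np.nan, df_err, ss_err),
    }


def binomial_ci(k, n, alpha=0.01):
    """Clopper-Pearson interval via the beta quantiles."""
    from scipy.stats import beta

    lo = 0.0 if k == 0 else beta.ppf(alpha / 2, k, n - k + 1)
    hi = 1.0 if k == n else beta.ppf(1 - alpha / 2, k + 1, n - k)
    return lo, hi
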