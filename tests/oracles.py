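"""Independent reference computations used to cross-check the package.

Everything here is deliberately written by a different route than the
implementation it checks: exhaustive enumeration for rule mining,
regression-residual partial correlations for KMO, and from-definition
fit-index formulas on an externally computed chi-square.
"""

from itertools import combinations

import numpy as np


def brute_force_frequent_itemsets(transactions, min_support):
    """Support of every itemset over the full powerset of the vocabulary."""
    vocab = sorted(set().union(*transactions)) if transactions else []
    n = len(transactions)
    out = {}
    for size in range(1, len(vocab) + 1):
        for combo in combinations(vocab, size):
            cset = frozenset(combo)
            count = sum(1 for t in transactions if cset <= t)
            if count >= min_support * n:
                out[cset] = count / n
    return out


def brute_force_rules(transactions, min_support, min_confidence, min_lift,
                      consequents, antecedent_universe=None):
    """All X -> y rules by direct counting, no Apriori structure."""
    n = len(transactions)

    def support(s):
        return sum(1 for t in transactions if s <= t) / n

    freq = brute_force_frequent_itemsets(transactions, min_support)
    rules = set()
    for iset, sup_xy in freq.items():
        for y in iset:
            if y not in consequents:
                continue
            x = iset - {y}
            if not x or any(el in consequents for el in x):
                continue
            if antecedent_universe is not None and not x <= antecedent_universe:
                continue
            conf = sup_xy / support(x)
            lift = conf / support(frozenset((y,)))
            if conf >= min_confidence and lift > min_lift:
                rules.add((x, y, round(sup_xy, 12), round(conf, 12), round(lift, 12)))
    return rules


def kmo_via_regression(data):
    """KMO with partial correlations from OLS residuals, not matrix inverses."""
    x = np.asarray(data, dtype=float)
    x = (x - x.mean(0)) / x.std(0, ddof=1)
    p = x.shape[1]
    r = np.corrcoef(x, rowvar=False)
    q = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            others = [k for k in range(p) if k not in (i, j)]
            if others:
                z = x[:, others]
                beta_i = np.linalg.lstsq(z, x[:, i], rcond=None)[0]
                beta_j = np.linalg.lstsq(z, x[:, j], rcond=None)[0]
                ri = x[:, i] - z @ beta_i
                rj = x[:, j] - z @ beta_j
            else:
                ri, rj = x[:, i], x[:, j]
            q[i, j] = q[j, i] = np.corrcoef(ri, rj)[0, 1]
    off = ~np.eye(p, dtype=bool)
    return float(np.sum(r[off] ** 2) / (np.sum(r[off] ** 2) + np.sum(q[off] ** 2)))


def reference_fit_indices(s, sigma, n, df_m):
    """GFI/AGFI/RMSEA/SRMR/NFI/TLI/CFI straight from their definitions."""
    s = np.asarray(s, float)
    sigma = np.asarray(sigma, float)
    p = s.shape[0]
    f_m = (np.linalg.slogdet(sigma)[1]
           + np.trace(s @ np.linalg.inv(sigma))
           - np.linalg.slogdet(s)[1] - p)
    chi2_m = (n - 1) * f_m
    f_b = float(np.sum(np.log(np.diag(s))) - np.linalg.slogdet(s)[1])
    chi2_b = (n - 1) * f_b
    df_b = p * (p - 1) / 2
    g = np.linalg.inv(sigma) @ s
    gfi = 1 - np.trace((g - np.eye(p)) @ (g - np.eye(p))) / np.trace(g @ g)
    agfi = 1 - (p * (p + 1) / (2 * df_m)) * (1 - gfi)
    rmsea = np.sqrt(max(chi2_m - df_m, 0) / (df_m * (n - 1)))
    resid = (s - sigma) / np.sqrt(np.outer(np.diag(s), np.diag(s)))
    srmr = np.sqrt(np.mean(resid[np.tril_indices(p)] ** 2))
    nfi = (chi2_b - chi2_m) / chi2_b
    tli = (chi2_b / df_b - chi2_m / df_m) / (chi2_b / df_b - 1)
    denom = max(chi2_b - df_b, chi2_m - df_m, 0)
    cfi = 1 - max(chi2_m - df_m, 0) / denom if denom > 0 else 1.0
    return {"chi2": chi2_m, "GFI": gfi, "AGFI": agfi, "RMSEA": rmsea,
            "SRMR": srmr, "NFI": nfi, "TLI": tli, "CFI": cfi}


def random_transaction_table(rng, n_elements, n_transactions):
    """Random baskets over a small vocabulary with clustered co-occurrence."""
    vocab = [f"E{k}" for k in range(n_elements)]
    probs = rng.uniform(0.15, 0.7, size=n_elements)
    transactions = []
    for _ in range(n_transactions):
        common = rng.random() < 0.4
        t = {v for v, p in zip(vocab, probs)
             if rng.random() < (min(p + 0.3, 0.95) if common else p)}
        if not t:
            t = {vocab[int(rng.integers(n_elements))]}
        transactions.append(frozenset(t))
    return transactions
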