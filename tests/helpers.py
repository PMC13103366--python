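"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorised code paths: set-based
Jaccard with explicit double loops, and full enumeration of label
assignments for the exact KS and rank-sum null distributions.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd


def set_jaccard(a: set, b: set) -> float:
    union = a | b
    if not union:
        raise ValueError("empty supports")
    return 1.0 - len(a & b) / len(union)


def brute_force_mu(bits: pd.DataFrame, focal: str, include_focal: bool = True):
    """µ⁺, µ⁻, ∆µ via explicit pair loops over set supports."""
    species = [c for c in bits.columns if include_focal or c != focal]
    supports = {
        s: {sp for sp in species if bits.loc[s, sp] > 0} for s in bits.index
    }
    plus = [s for s in bits.index if bits.loc[s, focal] > 0]
    minus = [s for s in bits.index if bits.loc[s, focal] == 0]

    def mean_pairs(samples):
        vals = [
            set_jaccard(supports[a], supports[b])
            for a, b in combinations(samples, 2)
        ]
        return float(np.mean(vals))

    mu_p = mean_pairs(plus)
    mu_m = mean_pairs(minus)
    return mu_p, mu_m, mu_p - mu_m


def _ks_D(x, y):
    x, y = np.sort(x), np.sort(y)
    allv = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, allv, side="right") / len(x)
    cdf_y = np.searchsorted(y, allv, side="right") / len(y)
    return float(np.max(np.abs(cdf_x - cdf_y)))


def enum_ks_p(x, y) -> tuple[float, float]:
    """Exact two-sided KS p by enumerating all label assignments
    (tie-free pooled data assumed)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n = len(x)
    d_obs = _ks_D(x, y)
    count = total = 0
    for idx in combinations(range(len(pooled)), n):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        if _ks_D(xs, ys) >= d_obs - 1e-12:
            count += 1
        total += 1
    return d_obs, count / total


def enum_wilcoxon_p(x, y) -> tuple[float, float]:
    """Exact two-sided rank-sum p by enumeration (tie-free data assumed).

    Returns (U statistic of x, p) where p is the probability under the
    permutation null of |U − nm/2| at least as large as observed.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank().to_numpy()
    n, m = len(x), len(y)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    center = n * m / 2
    count = total = 0
    for idx in combinations(range(n + m), n):
        u = ranks[list(idx)].sum() - n * (n + 1) / 2
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            count += 1
        total += 1
    return float(u_obs), count / total


def c_score_oracle(bits: pd.DataFrame) -> float:
    """Mean checkerboard unit count via an explicit species-pair loop."""
    vals = []
    for i, j in combinations(bits.columns, 2):
        bi = bits[i].to_numpy() > 0
        bj = bits[j].to_numpy() > 0
        s = int((bi & bj).sum())
        vals.append((int(bi.sum()) - s) * (int(bj.sum()) - s))
    return float(np.mean(vals))


def random_presence_frame(rng, n_samples, n_species, p=0.5) -> pd.DataFrame:
    """Random 0/1 frame with no all-zero samples and no degenerate focal
    split for the first species (regenerated until valid)."""
    while True:
        bits = (rng.random((n_samples, n_species)) < p).astype(int)
        df = pd.DataFrame(
            bits,
            index=[f"s{i}" for i in range(n_samples)],
            columns=[f"sp{j}" for j in range(n_species)],
        )
        if (bits.sum(axis=1) == 0).any():
            continue
        col = bits[:, 0]
        if 2 <= col.sum() <= n_samples - 2:
            return df
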