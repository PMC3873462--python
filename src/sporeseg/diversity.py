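"""Richness estimation and the sporulation-bottleneck statistic.

Chao1 here is the bias-corrected minimum-richness estimator

    S_chao1 = S_obs + n1 (n1 - 1) / (2 (n2 + 1))

with the classical log-normal 95% confidence interval built on
T = S_chao1 - S_obs, using the standard variance expressions for the
n2 > 0, n2 = 0 and n1 = 0 branches.  The asymmetric intervals this
construction yields (upper bound further from the point estimate than the
lower) are exactly the shape reported for skewed amplicon allele
distributions.

The sporulation bottleneck is the estimated fraction of parental richness
missing from an observed unit:  100 * (1 - S_obs / S_chao1), with bounds
obtained by substituting the CI endpoints of S_chao1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaln

from .alleles import RULE_CONVENTIONAL, call_variants, mask_singleton_states


@dataclass
class DiversityEstimate:
    s_obs: int
    n1: int
    n2: int
    chao1: float
    lci: float
    hci: float

    def __post_init__(self) -> None:
        if self.chao1 < self.s_obs - 1e-9:
            raise ValueError("chao1 below observed richness")
        if not (self.lci - 1e-9 <= self.chao1 <= self.hci + 1e-9):
            raise ValueError("confidence interval does not bracket the estimate")


@dataclass
class BottleneckEstimate:
    """Percent reduction of observed richness relative to estimated
    minimum richness, with CI-propagated bounds."""

    point_pct: float
    lower_pct: float
    upper_pct: float

    def rounded(self) -> tuple[int, int, int]:
        return (_round_half_up(self.point_pct),
                _round_half_up(self.lower_pct),
                _round_half_up(self.upper_pct))


@dataclass
class SaturationCurve:
    depths: list[int]
    mean_distinct: np.ndarray
    ci_half_width: np.ndarray  # 1.96 * sd of the replicate counts


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def chao1(counts: Sequence[int]) -> DiversityEstimate:
    """Bias-corrected Chao1 with a log-normal 95% CI.

    ``counts`` is the abundance vector of one community; zeros are
    ignored.  When there are no singletons the estimate collapses to
    S_obs and the CI comes from the zero-singleton variance.
    """
    c = np.asarray(counts, dtype=int)
    if np.any(c < 0):
        raise ValueError("negative abundance")
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("community is empty")
    s_obs = int(c.size)
    n = int(c.sum())
    n1 = int(np.sum(c == 1))
    n2 = int(np.sum(c == 2))

    est = s_obs + n1 * (n1 - 1) / (2.0 * (n2 + 1))

    if n1 > 0 and n2 > 0:
        var = (n1 * (n1 - 1) / (2.0 * (n2 + 1))
               + n1 * (2 * n1 - 1) ** 2 / (4.0 * (n2 + 1) ** 2)
               + n1**2 * n2 * (n1 - 1) ** 2 / (4.0 * (n2 + 1) ** 4))
    elif n1 > 0:  # n2 == 0
        t = n1 * (n1 - 1) / 2.0
        var = (n1 * (n1 - 1) / 2.0
               + n1 * (2 * n1 - 1) ** 2 / 4.0
               - n1**4 / (4.0 * (s_obs + t)))
    else:  # no singletons: estimate degenerates to S_obs
        e = math.exp(-n / s_obs) if s_obs else 0.0
        var = s_obs * e * (1 - e)

    t = est - s_obs
    if t > 1e-12:
        k = math.exp(1.96 * math.sqrt(math.log(1.0 + var / t**2)))
        lci = s_obs + t / k
        hci = s_obs + t * k
    else:
        sd = math.sqrt(max(var, 0.0))
        lci = max(float(s_obs), s_obs - 1.96 * sd)
        hci = s_obs + 1.96 * sd
    lci = max(lci, float(s_obs))
    hci = max(hci, est)
    return DiversityEstimate(s_obs=s_obs, n1=n1, n2=n2, chao1=float(est),
                             lci=float(lci), hci=float(hci))


def rarefaction(counts: Sequence[int], depths: Sequence[int]) -> np.ndarray:
    """Exact expected richness at each subsampling depth.

    E[S(n)] = sum_i 1 - C(N - N_i, n) / C(N, n), evaluated in log space.
    """
    c = np.asarray(counts, dtype=int)
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("community is empty")
    N = int(c.sum())
    out = np.empty(len(depths), dtype=float)
    for k, n in enumerate(depths):
        if not (0 <= n <= N):
            raise ValueError(f"depth {n} exceeds total count {N}")
        if n == 0:
            out[k] = 0.0
            continue
        # log C(N - Ni, n) - log C(N, n); terms with N - Ni < n contribute 1
        keep = (N - c) >= n
        term = np.zeros(c.size)
        m = (N - c[keep]).astype(float)
        term_keep = (gammaln(m + 1) - gammaln(m - n + 1)
                     - (gammaln(N + 1) - gammaln(N - n + 1)))
        term[keep] = np.exp(term_keep)
        out[k] = float(np.sum(1.0 - term))
    return out


def bottleneck(s_obs: int, est: DiversityEstimate) -> BottleneckEstimate:
    """Percent of estimated minimum richness missing from the observed
    unit: 100 * (1 - s_obs / chao1), bounded via the Chao1 CI."""
    if s_obs < 1:
        raise ValueError("s_obs must be >= 1")
    if est.chao1 < s_obs - 1e-9:
        raise ValueError("chao1 estimate below observed richness")
    if est.lci < s_obs - 1e-9:
        raise ValueError("inconsistent estimate: lci below s_obs")
    point = 100.0 * (1.0 - s_obs / est.chao1)
    lower = 100.0 * (1.0 - s_obs / est.lci)
    upper = 100.0 * (1.0 - s_obs / est.hci)
    return BottleneckEstimate(point_pct=point, lower_pct=lower, upper_pct=upper)


def shared_chao1(counts_a: Sequence[int], counts_b: Sequence[int]) -> float:
    """Chao's two-community shared-richness estimator.

    S12 = D12 + f1+^2/(2 f2+) + f+1^2/(2 f+2) + f11 f1+ f+1 / (4 f2+ f+2),
    where D12 is the observed shared richness, f1+/f2+ count shared
    species that are singletons/doubletons in community A, f+1/f+2 the
    same in B, and f11 shared species singleton in both.  A +1 correction
    is applied to any zero doubleton denominator.
    """
    a = np.asarray(counts_a, dtype=int)
    b = np.asarray(counts_b, dtype=int)
    if a.shape != b.shape:
        raise ValueError("abundance vectors must share one allele indexing")
    shared = (a > 0) & (b > 0)
    d12 = int(shared.sum())
    if d12 == 0:
        return 0.0
    f1p = int(np.sum(shared & (a == 1)))
    f2p = int(np.sum(shared & (a == 2)))
    fp1 = int(np.sum(shared & (b == 1)))
    fp2 = int(np.sum(shared & (b == 2)))
    f11 = int(np.sum(shared & (a == 1) & (b == 1)))
    k2p = f2p if f2p > 0 else f2p + 1
    kp2 = fp2 if fp2 > 0 else fp2 + 1
    est = (d12
           + (f1p**2) / (2.0 * k2p)
           + (fp1**2) / (2.0 * kp2)
           + (f11 * f1p * fp1) / (4.0 * k2p * kp2))
    return float(est)


def saturation_mc(
    seqs: Sequence[str],
    depths: Sequence[int],
    n_reps: int = 1000,
    rule: str = RULE_CONVENTIONAL,
    seed: int = 0,
) -> SaturationCurve:
    """Monte Carlo variant-saturation curve.

    At each depth, subsample the sequence multiset without replacement
    ``n_reps`` times and count distinct variants under the given calling
    rule; the band is mean +/- 1.96 * sd of the replicate counts.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    seqs = list(seqs)
    total = len(seqs)
    rng = np.random.default_rng(seed)
    means, hws = [], []

    def distinct(sub: list[str]) -> int:
        if len(sub) < 2:
            return len(set(sub))
        return call_variants(sub, rule=rule).distinct_sequences

    for n in depths:
        if not (1 <= n <= total):
            raise ValueError(f"depth {n} exceeds multiset size {total}")
        vals = np.empty(n_reps)
        for r in range(n_reps):
            idx = rng.choice(total, size=n, replace=False)
            vals[r] = distinct([seqs[i] for i in idx])
        means.append(vals.mean())
        hws.append(1.96 * vals.std(ddof=0))
    return SaturationCurve(depths=list(depths),
                           mean_distinct=np.array(means),
                           ci_half_width=np.array(hws))


def nucleotide_diversity_pi(
    seqs: Sequence[str],
    abundances: Sequence[int],
    window: int = 10,
    step: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Abundance-weighted nucleotide diversity per sliding window.

    Per column, pi = 1 - sum_s f_s^2 with f_s the relative frequency of
    state s (population formulation, no small-sample correction); a
    window's value is the mean over its columns.  Returns (window start
    positions, pi values).
    """
    if len({len(s) for s in seqs}) > 1:
        raise ValueError("sequences must be aligned to equal length")
    L = len(seqs[0])
    if window > L:
        raise ValueError("window exceeds alignment length")
    w = np.asarray(abundances, dtype=float)
    if w.size != len(seqs) or np.any(w < 0) or w.sum() <= 0:
        raise ValueError("invalid abundance vector")
    p = w / w.sum()
    arr = np.array([list(s) for s in seqs])
    per_col = np.empty(L)
    for j in range(L):
        freqs: dict[str, float] = {}
        for s, pi_ in zip(arr[:, j], p):
            freqs[s] = freqs.get(s, 0.0) + pi_
        per_col[j] = 1.0 - sum(f * f for f in freqs.values())
    starts = np.arange(0, L - window + 1, step)
    vals = np.array([per_col[s:s + window].mean() for s in starts])
    return starts, vals


def diversity_summary(table, unit: str = "sample"):
    """Table-1-style summary: per unit S_obs, Chao1 with CI, and the
    bottleneck percentages relative to that unit's own Chao1."""
    import pandas as pd  # local import to keep module deps light

    rows = []
    units: list[tuple[str, np.ndarray]] = [("all", table.pooled_counts())]
    if unit in ("group", "all"):
        units += [(g, table.group_counts(g)) for g in table.groups]
    if unit in ("sample", "all"):
        units += [(s, table.sample_counts(s)) for s in table.samples]
    for name, counts in units:
        counts = counts[counts > 0]
        est = chao1(counts)
        bn = bottleneck(est.s_obs, est)
        pt, lo, hi = bn.rounded()
        rows.append({
            "unit": name, "reads": int(counts.sum()), "alleles": est.s_obs,
            "chao1": est.chao1, "chao1_lci": est.lci, "chao1_hci": est.hci,
            "bottleneck_pct": pt, "bottleneck_lci_pct": lo, "bottleneck_hci_pct": hi,
            "bottleneck_pct_raw": bn.point_pct,
        })
    return pd.DataFrame(rows)
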