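"""Per-domain relative-solvent-accessibility summaries and nonparametric
comparison between domains.

RSA prediction itself is an upstream step (NetSurfP-style per-residue
tables are consumed, not computed). This module slices a per-residue
profile by 1-based domain intervals, reports mean +/- sample standard
deviation per domain (n-1 denominator; n is printed so readers can
convert), and compares two domains' value sets with a two-sided
Mann-Whitney U test: exact null distribution when the smaller group has at
most 8 values and there are no ties, normal approximation with tie
correction otherwise. Significance is judged at alpha = 0.01 by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .domains import DomainAnnotation
from .errors import CoordinateError, InputError
from .seqio import RSAProfile

EXACT_MAX_N = 8


@dataclass(frozen=True)
class DomainRSASummary:
    domain: str
    n: int
    mean: float
    sd: float
    protein_mean: float


@dataclass(frozen=True)
class RSAComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    u_statistic: float  # U of group_a; U_a + U_b == n_a * n_b
    p_value: float
    alpha: float
    significant: bool
    method: str  # "exact" | "asymptotic"


def domain_values(profile: RSAProfile, domain: DomainAnnotation) -> np.ndarray:
    """The profile values over a domain's 1-based inclusive interval."""
    if domain.end > len(profile):
        raise CoordinateError(
            f"domain {domain.name!r} ({domain.start}-{domain.end}) exceeds "
            f"profile {profile.id!r} of length {len(profile)}"
        )
    return np.asarray(profile.values[domain.start - 1:domain.end], dtype=float)


def domain_rsa_summary(profile: RSAProfile,
                       domains: Sequence[DomainAnnotation]
                       ) -> list[DomainRSASummary]:
    """Mean and sample sd of RSA per domain, plus the whole-protein mean."""
    protein_mean = float(np.mean(profile.values))
    out = []
    for dom in domains:
        vals = domain_values(profile, dom)
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        out.append(DomainRSASummary(domain=dom.name, n=len(vals),
                                    mean=float(np.mean(vals)), sd=sd,
                                    protein_mean=protein_mean))
    return out


def summary_table(summaries: list[DomainRSASummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"domain": s.domain, "n": s.n, "mean": s.mean, "sd": s.sd,
          "protein_mean": s.protein_mean} for s in summaries],
        columns=["domain", "n", "mean", "sd", "protein_mean"])


def compare_domains(values_a: Sequence[float], values_b: Sequence[float],
                    alpha: float = 0.01,
                    name_a: str = "a", name_b: str = "b") -> RSAComparison:
    """Two-sided Mann-Whitney U comparison of two value sets.

    Uses the exact null distribution when ``min(n_a, n_b) <= 8`` and no
    value is shared between or within groups; otherwise the normal
    approximation with tie correction (and continuity correction).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("cannot compare empty groups")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    if min(a.size, b.size) <= EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(min(1.0, res.pvalue))
    return RSAComparison(
        group_a=name_a, group_b=name_b, n_a=int(a.size), n_b=int(b.size),
        u_statistic=float(res.statistic), p_value=p, alpha=alpha,
        significant=bool(p < alpha), method=method,
    )


def compare_all_domains(profile: RSAProfile,
                        domains: Sequence[DomainAnnotation],
                        alpha: float = 0.01) -> pd.DataFrame:
    """All pairwise domain comparisons for one profile, as a table."""
    rows = []
    for i in range(len(domains)):
        for j in range(i + 1, len(domains)):
            va = domain_values(profile, domains[i])
            vb = domain_values(profile, domains[j])
            cmp_ = compare_domains(va, vb, alpha=alpha,
                                   name_a=domains[i].name,
                                   name_b=domains[j].name)
            rows.append({
                "group_a": cmp_.group_a, "group_b": cmp_.group_b,
                "n_a": cmp_.n_a, "n_b": cmp_.n_b,
                "u_statistic": cmp_.u_statistic, "p_value": cmp_.p_value,
                "method": cmp_.method, "alpha": cmp_.alpha,
                "significant": cmp_.significant,
            })
    return pd.DataFrame(rows, columns=["group_a", "group_b", "n_a", "n_b",
                                       "u_statistic", "p_value", "method",
                                       "alpha", "significant"])


def rsa_boxplot(profile: RSAProfile, domains: Sequence[DomainAnnotation],
                path: str):
    """Optional boxplot of per-domain RSA with the protein mean as a dashed
    line. Requires matplotlib (the ``plot`` extra); never load-bearing."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = [domain_values(profile, d) for d in domains]
    fig, ax = plt.subplots(figsize=(1.2 * len(domains) + 2, 4))
    ax.boxplot(data, tick_labels=[d.name for d in domains])
    ax.axhline(float(np.mean(profile.values)), color="red", linestyle="--",
               linewidth=1, label="protein mean")
    ax.set_ylabel("relative solvent accessibility")
    ax.set_ylim(0, 1)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def exact_mannwhitney_pvalue(values_a: Sequence[float],
                             values_b: Sequence[float]) -> float:
    """Exact two-sided Mann-Whitney p-value by full enumeration of group
    assignments. Exponential in the pooled size; intended for small-sample
    cross-checks of :func:`compare_domains`."""
    from itertools import combinations

    a = list(map(float, values_a))
    b = list(map(float, values_b))
    pooled = a + b
    n_a = len(a)

    def u_stat(group_a: Sequence[float], group_b: Sequence[float]) -> float:
        u = 0.0
        for x in group_a:
            for y in group_b:
                u += (x > y) + 0.5 * (x == y)
        return u

    observed = u_stat(a, b)
    mean_u = n_a * len(b) / 2.0
    dev = abs(observed - mean_u)
    total = 0
    extreme = 0
    idx = range(len(pooled))
    for chosen in combinations(idx, n_a):
        chosen_set = set(chosen)
        ga = [pooled[i] for i in chosen]
        gb = [pooled[i] for i in idx if i not in chosen_set]
        u = u_stat(ga, gb)
        total += 1
        if abs(u - mean_u) >= dev - 1e-12:
            extreme += 1
    return extreme / total
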