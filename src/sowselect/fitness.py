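"""Accession frequencies, relative fitness and exact pattern statistics.

Because every accession is sown at equal frequency 1/N, fitness at a site
is read out directly as the accession's frequency among sampled
experimental-class individuals. Relative fitness rescales by the neutral
expectation: ``relative_fitness = N x frequency``, so 1 means no change
and a frequency of 20% with N = 200 means a 40-fold increase.

Two exact combinatorial statistics quantify group-level consistency
across experiments: the probability that *some* one of k exchangeable
groups ranks last in all m experiments, and the exact binomial upper
tail for a recurring per-experiment pattern.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .assignment import SiteComposition


def accession_frequencies(
    composition: SiteComposition,
    exclusions: pd.DataFrame | None = None,
    denominator: str = "experimental",
) -> pd.DataFrame:
    """Per-(accession, site) counts, frequencies and relative fitness.

    Frequencies are computed over experimental-class samples only (or all
    samples with ``denominator='all'`` for sensitivity). Accessions
    excluded by the native filter are removed at the flagged site and the
    remaining frequencies renormalised; zero-count accessions keep
    frequency 0 (no pseudocounts — fitness is a frequency estimate, not a
    likelihood). Sites with zero experimental samples are dropped with a
    warning.

    Returns a long DataFrame with columns: site_id, accession_id, count,
    included, frequency, relative_fitness, fold_change.
    """
    counts = composition.accession_counts
    n_accessions = counts.shape[1]
    if denominator == "experimental":
        denom = composition.n_experimental
    elif denominator == "all":
        denom = composition.n_samples
    else:
        raise ValueError("denominator must be 'experimental' or 'all'")

    excluded_pairs: set[tuple[str, str]] = set()
    if exclusions is not None and len(exclusions):
        ex = exclusions[exclusions.get("excluded", False) == True]  # noqa: E712
        excluded_pairs = set(zip(ex["site_id"], ex["accession_id"]))

    rows = []
    for site in counts.index:
        if composition.n_experimental.loc[site] == 0:
            warnings.warn(f"site {site!r} has no experimental samples; dropped")
            continue
        site_counts = counts.loc[site]
        incl = np.array(
            [(site, acc) not in excluded_pairs for acc in counts.columns]
        )
        total = denom.loc[site]
        removed = site_counts[~incl].sum()
        denom_site = total - removed
        for j, acc in enumerate(counts.columns):
            c = int(site_counts.iloc[j])
            if incl[j] and denom_site > 0:
                freq = c / denom_site
            else:
                freq = np.nan
            rel = freq * n_accessions if np.isfinite(freq) else np.nan
            rows.append(
                {
                    "site_id": site,
                    "accession_id": acc,
                    "count": c,
                    "included": bool(incl[j]),
                    "frequency": freq,
                    "relative_fitness": rel,
                    # starting frequency is 1/N, so the fold-change vs the
                    # start equals the relative fitness
                    "fold_change": rel,
                }
            )
    return pd.DataFrame(rows)


def relative_fitness(freq: float | np.ndarray, n_accessions: int) -> float | np.ndarray:
    """Frequency rescaled by the neutral expectation 1/N."""
    freq = np.asarray(freq, dtype=float)
    if ((freq < 0) | (freq > 1)).any():
        raise ValueError("frequencies must lie in [0, 1]")
    out = freq * n_accessions
    return float(out) if out.ndim == 0 else out


def prob_any_group_extreme(n_groups: int, n_experiments: int) -> float:
    """P(some one of k exchangeable groups ranks last in all m experiments).

    Under exchangeability each group is last in one experiment with
    probability 1/k independently across experiments, and the k events
    "group g is always last" are disjoint for m >= 1, so the probability
    is k x (1/k)^m = (1/k)^(m-1).
    """
    if n_groups < 2:
        raise ValueError("need at least two groups")
    if n_experiments < 1:
        raise ValueError("need at least one experiment")
    return n_groups * (1.0 / n_groups) ** n_experiments


def binomial_tail(successes: int, trials: int, p_success: float) -> float:
    """Exact upper tail P(X >= successes) for X ~ Binomial(trials, p).

    Computed by direct summation of the binomial mass function — no
    normal approximation, so tiny tail probabilities are exact to
    floating-point precision.
    """
    if not 0 <= successes <= trials:
        raise ValueError("need 0 <= successes <= trials")
    if not 0.0 <= p_success <= 1.0:
        raise ValueError("p_success must lie in [0, 1]")
    q = 1.0 - p_success
    total = 0.0
    for k in range(successes, trials + 1):
        total += math.comb(trials, k) * p_success**k * q ** (trials - k)
    return min(total, 1.0)


def group_summaries(
    freq_table: pd.DataFrame,
    group_labels: dict[str, str] | pd.Series,
) -> pd.DataFrame:
    """Per-(group, site) distribution of relative fitness, with group ranks.

    Returns one row per group and site with n, median, lower/upper
    quartiles of relative fitness over included accessions, and the
    within-site rank of the group medians (1 = highest median). Groups
    with no included accessions are reported with n = 0 and no stats.
    """
    if isinstance(group_labels, dict):
        group_labels = pd.Series(group_labels)
    df = freq_table.copy()
    missing = set(df["accession_id"]) - set(group_labels.index)
    if missing:
        raise ValueError(f"accessions without a group label: {sorted(missing)[:5]}")
    df["group"] = df["accession_id"].map(group_labels)

    rows = []
    for site, site_df in df.groupby("site_id"):
        incl = site_df[site_df["included"]]
        for grp in sorted(group_labels.unique()):
            vals = incl.loc[incl["group"] == grp, "relative_fitness"].dropna()
            if len(vals):
                rows.append(
                    {
                        "site_id": site,
                        "group": grp,
                        "n": len(vals),
                        "median": float(vals.median()),
                        "q1": float(vals.quantile(0.25)),
                        "q3": float(vals.quantile(0.75)),
                    }
                )
            else:
                rows.append(
                    {
                        "site_id": site,
                        "group": grp,
                        "n": 0,
                        "median": np.nan,
                        "q1": np.nan,
                        "q3": np.nan,
                    }
                )
    out = pd.DataFrame(rows)
    out["rank"] = (
        out.groupby("site_id")["median"].rank(ascending=False, method="min").astype("Int64")
    )
    return out
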