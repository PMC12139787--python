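"""Assign field-sampled genotypes to panel accessions.

Each low-coverage sample is compared to every inbred accession in the
panel by its mismatch rate: the fraction of discordant homozygous calls
among sites where both the sample and the accession have a non-missing
homozygous call. Classification follows a fixed precedence:

1. samples with an excessive fraction of heterozygous calls are
   ``heterozygous`` (recent outcrossing or contamination) — an
   extensively heterozygous sample is never called experimental;
2. samples without enough informative sites are ``low_data``;
3. otherwise the minimum-mismatch accession wins if its mismatch is at
   most the threshold (default 0.015) → ``experimental``;
4. a homozygous sample matching no accession is a ``native_volunteer``.

Ties on the minimum mismatch are never broken arbitrarily: the sample is
classified ``low_data`` and both candidates are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import HET, MISSING, GenotypePanel, SampleCalls
from .simulate import stage_rng

DEFAULT_MISMATCH_THRESHOLD = 0.015
DEFAULT_MIN_INFORMATIVE = 10_000
DEFAULT_HET_THRESHOLD = 0.05

CLASSES = ("experimental", "native_volunteer", "heterozygous", "low_data")


@dataclass
class AssignmentResult:
    sample_id: str
    site_id: str
    sample_class: str
    best_accession: str | None
    mismatch: float
    n_informative: int
    het_fraction: float
    candidates: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sample_class not in CLASSES:
            raise ValueError(f"unknown class {self.sample_class!r}")


@dataclass
class SiteComposition:
    """Per-site sample-class counts and per-accession experimental counts."""

    #: rows = sites, columns = accession ids; experimental-class counts.
    accession_counts: pd.DataFrame
    #: rows = sites, columns = the four sample classes.
    class_counts: pd.DataFrame

    @property
    def n_experimental(self) -> pd.Series:
        return self.accession_counts.sum(axis=1).rename("n_experimental")

    @property
    def n_samples(self) -> pd.Series:
        return self.class_counts.sum(axis=1).rename("n_samples")

    def class_fractions(self) -> pd.DataFrame:
        totals = self.class_counts.sum(axis=1)
        return self.class_counts.div(totals.where(totals > 0), axis=0)

    def frequencies(self, denominator: str = "experimental") -> pd.DataFrame:
        """Per-site accession frequencies.

        ``denominator='experimental'`` divides by experimental-class
        samples only (the estimand-consistent choice);
        ``denominator='all'`` divides by every sample at the site.
        """
        if denominator == "experimental":
            denom = self.n_experimental
        elif denominator == "all":
            denom = self.n_samples
        else:
            raise ValueError("denominator must be 'experimental' or 'all'")
        return self.accession_counts.div(denom.where(denom > 0), axis=0)


def _informative_stats(
    calls: np.ndarray, genotypes: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mismatch and informative-site matrices between samples and panel.

    ``calls`` is (m, L) in {0,1,HET,MISSING}; ``genotypes`` is (n, L) in
    {0,1,MISSING}. Heterozygous and missing entries are excluded from
    both numerator and denominator. Uses float32 matmuls; counts stay
    exactly representable up to 2**24 sites.
    """
    ones_s = (calls == 1).astype(np.float32)
    inf_s = ((calls == 0) | (calls == 1)).astype(np.float32)
    ones_p = (genotypes == 1).astype(np.float32)
    valid_p = (genotypes != MISSING).astype(np.float32)
    zeros_p = valid_p - ones_p

    n_inf = inf_s @ valid_p.T
    discord = ones_s @ zeros_p.T + (inf_s - ones_s) @ ones_p.T
    with np.errstate(invalid="ignore", divide="ignore"):
        mm = np.where(n_inf > 0, discord / np.maximum(n_inf, 1), np.nan)
    return mm, n_inf.astype(np.int64)


def mismatch_rate(sample_calls: np.ndarray, accession_genotypes: np.ndarray) -> float:
    """Fraction of discordant homozygous calls among informative sites.

    Informative sites are those where the sample call is homozygous (0/1)
    and the accession genotype is non-missing. Returns ``nan`` when there
    are no informative sites (undefined mismatch).
    """
    s = np.asarray(sample_calls)
    g = np.asarray(accession_genotypes)
    if s.shape != g.shape:
        raise ValueError("sample and accession vectors must have equal length")
    informative = ((s == 0) | (s == 1)) & (g != MISSING)
    n = int(informative.sum())
    if n == 0:
        return float("nan")
    return float((s[informative] != g[informative]).sum() / n)


def assign_samples(
    calls: SampleCalls,
    panel: GenotypePanel,
    mismatch_threshold: float = DEFAULT_MISMATCH_THRESHOLD,
    min_informative: int = DEFAULT_MIN_INFORMATIVE,
    het_threshold: float = DEFAULT_HET_THRESHOLD,
) -> list[AssignmentResult]:
    """Classify every sample against the panel (vectorised)."""
    if panel.n_accessions == 0:
        raise ValueError("panel is empty")
    calls.check_aligned(panel)

    mm, n_inf = _informative_stats(calls.calls, panel.genotypes)
    n_het = (calls.calls == HET).sum(axis=1)
    n_called = (calls.calls != MISSING).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        het_frac = np.where(n_called > 0, n_het / np.maximum(n_called, 1), 0.0)

    results: list[AssignmentResult] = []
    acc_ids = panel.accession_ids
    for i, sample_id in enumerate(calls.sample_ids):
        site = calls.site_ids[i]
        hf = float(het_frac[i])
        row = mm[i]
        if hf > het_threshold:
            results.append(
                AssignmentResult(sample_id, site, "heterozygous", None, np.nan, 0, hf)
            )
            continue
        if np.isnan(row).all():
            results.append(
                AssignmentResult(sample_id, site, "low_data", None, np.nan, 0, hf)
            )
            continue
        best = int(np.nanargmin(row))
        best_mm = float(row[best])
        best_inf = int(n_inf[i, best])
        if best_inf < min_informative:
            results.append(
                AssignmentResult(sample_id, site, "low_data", None, best_mm, best_inf, hf)
            )
            continue
        if best_mm <= mismatch_threshold:
            # a tie between two matching accessions is genuine ambiguity:
            # refuse to assign rather than pick arbitrarily
            tied = np.flatnonzero(row == best_mm)
            if len(tied) > 1:
                results.append(
                    AssignmentResult(
                        sample_id,
                        site,
                        "low_data",
                        None,
                        best_mm,
                        best_inf,
                        hf,
                        candidates=[acc_ids[j] for j in tied],
                    )
                )
            else:
                results.append(
                    AssignmentResult(
                        sample_id, site, "experimental", acc_ids[best], best_mm,
                        best_inf, hf,
                    )
                )
        else:
            results.append(
                AssignmentResult(
                    sample_id, site, "native_volunteer", None, best_mm, best_inf, hf
                )
            )
    return results


def assign_sample(
    sample: SampleCalls,
    panel: GenotypePanel,
    mismatch_threshold: float = DEFAULT_MISMATCH_THRESHOLD,
    min_informative: int = DEFAULT_MIN_INFORMATIVE,
    het_threshold: float = DEFAULT_HET_THRESHOLD,
) -> AssignmentResult:
    """Classify a single sample (first row of ``sample``)."""
    res = assign_samples(
        sample,
        panel,
        mismatch_threshold=mismatch_threshold,
        min_informative=min_informative,
        het_threshold=het_threshold,
    )
    return res[0]


def assignments_to_frame(results: list[AssignmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "site_id": [r.site_id for r in results],
            "class": [r.sample_class for r in results],
            "best_accession": [r.best_accession or "" for r in results],
            "mismatch": [r.mismatch for r in results],
            "n_informative": [r.n_informative for r in results],
            "het_fraction": [r.het_fraction for r in results],
            "candidates": [",".join(r.candidates) for r in results],
        }
    )


@dataclass
class MinSnpResult:
    """Outcome of the minimum-SNP-count simulation."""

    min_k: int | None
    per_k: pd.DataFrame  # columns: k, n_failures, all_identified
    indistinguishable_pairs: list[tuple[str, str]]


def min_snps_by_simulation(
    panel: GenotypePanel,
    k_grid: list[int],
    n_reps: int = 10,
    mismatch_threshold: float = DEFAULT_MISMATCH_THRESHOLD,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> MinSnpResult:
    """Smallest SNP count at which every accession is uniquely identified.

    For each k in the (ascending) grid, ``n_reps`` random k-SNP subsets
    are drawn; identification succeeds in a replicate if every accession
    has mismatch 0 to itself and mismatch above the threshold to every
    other accession. Exact duplicate accessions (mismatch 0 over the full
    panel) are permanently indistinguishable: they are reported
    separately and excluded from the k criterion, which therefore applies
    to the distinguishable pairs only. ``missing_rate`` degrades the
    query copy of each accession to emulate low-coverage sampling.
    """
    if list(k_grid) != sorted(k_grid):
        raise ValueError("k_grid must be ascending")
    n_acc, n_snp = panel.genotypes.shape
    if any(k > n_snp for k in k_grid):
        raise ValueError("k_grid entries cannot exceed the panel SNP count")
    rng = stage_rng(seed, "min_snps")

    full_mm, _ = _informative_stats(panel.genotypes, panel.genotypes)
    dup_mask = np.zeros((n_acc, n_acc), dtype=bool)
    pairs: list[tuple[str, str]] = []
    for i in range(n_acc):
        for j in range(i + 1, n_acc):
            if full_mm[i, j] == 0:
                pairs.append((panel.accession_ids[i], panel.accession_ids[j]))
                dup_mask[i, j] = dup_mask[j, i] = True

    off_diag = ~np.eye(n_acc, dtype=bool)
    checkable = off_diag & ~dup_mask
    rows = []
    min_k: int | None = None
    for k in k_grid:
        failures = 0
        for _ in range(n_reps):
            cols = rng.choice(n_snp, size=k, replace=False)
            query = panel.genotypes[:, cols].copy()
            if missing_rate > 0:
                query[rng.random(query.shape) < missing_rate] = MISSING
            mm, _ = _informative_stats(query, panel.genotypes[:, cols])
            self_ok = np.nan_to_num(np.diag(mm), nan=1.0) == 0
            with np.errstate(invalid="ignore"):
                others_ok = np.where(np.isnan(mm), False, mm > mismatch_threshold)
            if not (self_ok.all() and others_ok[checkable].all()):
                failures += 1
        ok = failures == 0
        rows.append({"k": k, "n_failures": failures, "all_identified": ok})
        if ok and min_k is None:
            min_k = k
    return MinSnpResult(
        min_k=min_k,
        per_k=pd.DataFrame(rows),
        indistinguishable_pairs=pairs,
    )


def summarize_composition(
    assignments: list[AssignmentResult] | pd.DataFrame,
    accession_ids: list[str] | None = None,
    sites: list[str] | None = None,
) -> SiteComposition:
    """Tabulate per-site class counts and per-accession experimental counts.

    ``sites`` declares the expected sites (empty sites get zero rows);
    assignments at undeclared sites raise. ``accession_ids`` fixes the
    column order; accessions never observed get zero columns.
    """
    if isinstance(assignments, pd.DataFrame):
        df = assignments.copy()
    else:
        df = assignments_to_frame(assignments)
    if sites is None:
        sites = sorted(df["site_id"].unique())
    else:
        unknown = set(df["site_id"]) - set(sites)
        if unknown:
            raise ValueError(f"assignments reference undeclared sites: {sorted(unknown)}")
    if accession_ids is None:
        exp_acc = df.loc[df["class"] == "experimental", "best_accession"]
        accession_ids = sorted(a for a in exp_acc.unique() if a)

    class_counts = (
        df.groupby(["site_id", "class"])
        .size()
        .unstack(fill_value=0)
        .reindex(index=sites, columns=list(CLASSES), fill_value=0)
        .fillna(0)
        .astype(int)
    )
    exp = df[df["class"] == "experimental"]
    accession_counts = (
        exp.groupby(["site_id", "best_accession"])
        .size()
        .unstack(fill_value=0)
        .reindex(index=sites, columns=accession_ids, fill_value=0)
        .fillna(0)
        .astype(int)
    )
    accession_counts.index.name = "site_id"
    class_counts.index.name = "site_id"
    return SiteComposition(accession_counts=accession_counts, class_counts=class_counts)
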