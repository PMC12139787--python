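"""Drift-null allele-frequency scan with Ne estimation.

Model. Between sowing and sampling, the experimental population at a site
is treated as a Wright-Fisher multinomial sample of size Ne from the
equal-frequency starting population, and the genotyped sample as a
binomial sample of (known) size n from it. For a SNP with starting
frequency p0, the frequency change Δp then has E[Δp] = 0 and

    Var[Δp] = (1/n + 1/Ne + 1/(n·Ne)) · p0(1 − p0)

(the exact three-term form is used throughout; the familiar
1/n + 1/Ne approximation differs negligibly for n in the hundreds).
Ne is estimated by regressing per-SNP (Δp)² on p0(1 − p0) through the
origin and inverting the variance law at the known n. Per-SNP deviations
are standardised by the null standard deviation — optionally after
subtracting the genome-wide mean Δp, which absorbs reference-allele
bias — and converted to two-sided normal p-values. Experiments are
combined by multiplying per-site p-values; the product is a ranking
score, not a calibrated p-value, so a Fisher chi-square transform is
offered alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import MISSING, GenotypePanel

DEFAULT_MAF_FLOOR = 0.03
MIN_SNPS_FOR_NE = 100


def starting_freqs(panel: GenotypePanel) -> pd.Series:
    """Starting allele frequency per SNP: unweighted mean over accessions.

    All accessions are sown in equal numbers, so p0 is the plain column
    mean of the panel genotypes; missing panel calls are excluded from
    that SNP's mean, and SNPs missing in every accession are dropped with
    a warning. Indexed by (chrom, pos).
    """
    if panel.n_accessions == 0:
        raise ValueError("panel is empty")
    g = panel.genotypes.astype(float)
    g[panel.genotypes == MISSING] = np.nan
    n_called = (~np.isnan(g)).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p0 = np.nanmean(g, axis=0)
    s = pd.Series(p0, index=panel.snp_index(), name="p0")
    dead = n_called == 0
    if dead.any():
        warnings.warn(f"dropped {int(dead.sum())} SNPs missing in all accessions")
        s = s[~dead]
    return s


def null_variance(
    p0: float | np.ndarray, n_sample: int, ne: float
) -> float | np.ndarray:
    """Exact drift-plus-sampling null variance of Δp."""
    if n_sample < 1 or ne < 1:
        raise ValueError("n_sample and ne must be >= 1")
    p0 = np.asarray(p0, dtype=float)
    out = (1.0 / n_sample + 1.0 / ne + 1.0 / (n_sample * ne)) * p0 * (1.0 - p0)
    return float(out) if out.ndim == 0 else out


@dataclass
class NeEstimate:
    """Effective population size from the variance-slope fit at one site."""

    site_id: str
    n_sample: int
    slope: float
    ne: float  # nan when invalid
    valid: bool
    n_snps_used: int
    maf_floor: float

    def __str__(self) -> str:
        ne = f"{self.ne:.1f}" if self.valid else "invalid (slope <= 1/n)"
        return (
            f"NeEstimate(site={self.site_id}, n={self.n_sample}, "
            f"slope={self.slope:.5g}, Ne={ne}, snps={self.n_snps_used})"
        )


def estimate_ne(
    delta: np.ndarray,
    p0: np.ndarray,
    n_sample: int,
    maf_floor: float = DEFAULT_MAF_FLOOR,
    site_id: str = "site",
) -> NeEstimate:
    """Estimate Ne from the regression of (Δp)² on p0(1 − p0).

    Least squares through the origin over SNPs above the MAF floor gives
    the slope s; inverting the exact variance law at the known sample
    size yields Ne = (1 + 1/n)/(s − 1/n). A slope at or below 1/n (no
    variance beyond sampling) cannot be inverted and is reported invalid
    rather than fabricated.
    """
    delta = np.asarray(delta, dtype=float)
    p0 = np.asarray(p0, dtype=float)
    if delta.shape != p0.shape:
        raise ValueError("delta and p0 must be aligned")
    maf = np.minimum(p0, 1.0 - p0)
    keep = np.isfinite(delta) & np.isfinite(p0) & (maf >= maf_floor)
    if keep.sum() < MIN_SNPS_FOR_NE:
        raise ValueError(
            f"only {int(keep.sum())} SNPs above the MAF floor; "
            f"need at least {MIN_SNPS_FOR_NE} for the variance fit"
        )
    x = p0[keep] * (1.0 - p0[keep])
    y = delta[keep] ** 2
    slope = float(np.dot(y, x) / np.dot(x, x))
    inv_n = 1.0 / n_sample
    if slope > inv_n:
        ne = (1.0 + inv_n) / (slope - inv_n)
        valid = True
    else:
        ne = float("nan")
        valid = False
    return NeEstimate(
        site_id=site_id,
        n_sample=int(n_sample),
        slope=slope,
        ne=ne,
        valid=valid,
        n_snps_used=int(keep.sum()),
        maf_floor=maf_floor,
    )


def scan(
    delta: np.ndarray, var0: np.ndarray, center: bool = True
) -> tuple[np.ndarray, np.ndarray, int]:
    """Standardise Δp against the null and compute two-sided p-values.

    z = (Δp − c)/sqrt(var0) with c the genome-wide mean Δp when
    ``center`` is on (absorbing reference-allele bias) and 0 otherwise.
    SNPs with var0 = 0 (fixed starting frequency) are excluded — their z
    and p are nan — and their count is returned.
    """
    delta = np.asarray(delta, dtype=float)
    var0 = np.asarray(var0, dtype=float)
    if delta.shape != var0.shape:
        raise ValueError("delta and var0 must be aligned")
    if (var0 < 0).any():
        raise ValueError("null variances must be non-negative")
    ok = var0 > 0
    n_excluded = int((~ok).sum())
    c = float(np.nanmean(delta[ok])) if center else 0.0
    z = np.full(delta.shape, np.nan)
    z[ok] = (delta[ok] - c) / np.sqrt(var0[ok])
    p = np.full(delta.shape, np.nan)
    p[ok] = 2.0 * stats.norm.sf(np.abs(z[ok]))
    return z, p, n_excluded


def combine_experiments(
    p_tables: dict[str, pd.Series], fisher: bool = False
) -> pd.DataFrame:
    """Combine per-site scans by multiplying p-values per SNP.

    ``p_tables`` maps site id to a p-value Series indexed by
    (chrom, pos); SNPs are aligned on that index, sites missing a SNP are
    skipped and the number of contributing sites reported. The product is
    a score for ranking, not a calibrated p-value; with ``fisher=True`` a
    chi-square-calibrated Fisher p-value over the contributing sites is
    added.

    Returns columns: combined_score, neg_log10_combined, n_sites
    (+ fisher_p).
    """
    if not p_tables:
        raise ValueError("no p-value tables given")
    wide = pd.DataFrame({site: s for site, s in p_tables.items()})
    n_sites = wide.notna().sum(axis=1)
    if (n_sites == 0).all():
        raise ValueError("no overlapping SNPs across experiments")
    combined = wide.prod(axis=1, min_count=1)
    with np.errstate(divide="ignore"):
        neg_log10 = -np.log10(combined)
    out = pd.DataFrame(
        {
            "combined_score": combined,
            "neg_log10_combined": neg_log10,
            "n_sites": n_sites,
        }
    )
    if fisher:
        with np.errstate(divide="ignore"):
            chi2 = -2.0 * np.log(combined)
        out["fisher_p"] = stats.chi2.sf(chi2, df=2 * n_sites)
    return out[n_sites > 0]


def write_scan(table: pd.DataFrame, path) -> None:
    """Write a scan table as TSV, sorted by (chrom, pos), round-trippable."""
    df = table.reset_index() if table.index.nlevels > 1 else table.copy()
    if not {"chrom", "pos"}.issubset(df.columns):
        raise ValueError("scan table needs chrom and pos")
    df = df.sort_values(["chrom", "pos"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


def read_scan(path) -> pd.DataFrame:
    # round_trip parsing keeps write -> read -> write byte-identical
    return pd.read_csv(
        path,
        sep="\t",
        float_precision="round_trip",  # keeps write -> read -> write byte-identical
        keep_default_na=False,
        na_values=[""],  # site ids like "NA" are data, not missing values
    )


class DriftScan:
    """Selection-scan model over one or more experimental sites.

    Parameters
    ----------
    p0 : Series
        Starting allele frequencies indexed by (chrom, pos); typically
        :func:`starting_freqs` of the sowing panel.
    p_hat : dict of site id -> Series
        Sampled allele frequencies per site, indexed like ``p0``.
    n_sample : dict of site id -> int
        Genotyped sample size per site.
    maf_floor : float
        MAF filter applied to the Ne variance fit (not to the scan).
    center : bool
        Subtract the genome-wide mean Δp before standardising.

    ``fit()`` estimates Ne per site (unless overridden), standardises
    per-SNP deviations, and combines sites into one score, returning a
    :class:`DriftScanResults`.
    """

    def __init__(
        self,
        p0: pd.Series,
        p_hat: dict[str, pd.Series],
        n_sample: dict[str, int],
        maf_floor: float = DEFAULT_MAF_FLOOR,
        center: bool = True,
    ) -> None:
        if set(p_hat) != set(n_sample):
            raise ValueError("p_hat and n_sample must cover the same sites")
        if not p_hat:
            raise ValueError("need at least one site")
        self.p0 = p0.astype(float)
        self.p_hat = {s: v.reindex(p0.index).astype(float) for s, v in p_hat.items()}
        self.n_sample = {s: int(n) for s, n in n_sample.items()}
        self.maf_floor = maf_floor
        self.center = center

    @classmethod
    def from_panel(
        cls,
        panel: GenotypePanel,
        p_hat: dict[str, pd.Series],
        n_sample: dict[str, int],
        **kwargs,
    ) -> "DriftScan":
        return cls(starting_freqs(panel), p_hat, n_sample, **kwargs)

    def fit(self, ne: dict[str, float] | None = None) -> "DriftScanResults":
        """Run the scan; ``ne`` optionally overrides per-site estimates."""
        p0 = self.p0.to_numpy()
        table = pd.DataFrame(index=self.p0.index)
        table["p0"] = p0
        ne_estimates: dict[str, NeEstimate] = {}
        p_tables: dict[str, pd.Series] = {}
        excluded: dict[str, int] = {}
        for site in sorted(self.p_hat):
            ph = self.p_hat[site].to_numpy()
            n = self.n_sample[site]
            delta = ph - p0
            if ne is not None and site in ne:
                est = NeEstimate(
                    site_id=site,
                    n_sample=n,
                    slope=float("nan"),
                    ne=float(ne[site]),
                    valid=True,
                    n_snps_used=0,
                    maf_floor=self.maf_floor,
                )
            else:
                est = estimate_ne(delta, p0, n, maf_floor=self.maf_floor, site_id=site)
            ne_estimates[site] = est
            if not est.valid:
                raise ValueError(
                    f"site {site}: variance slope {est.slope:.4g} <= 1/n; "
                    "cannot standardise — supply ne explicitly to override"
                )
            var0 = null_variance(p0, n, est.ne)
            z, p, n_exc = scan(delta, var0, center=self.center)
            excluded[site] = n_exc
            table[f"p_hat_{site}"] = ph
            table[f"delta_{site}"] = delta
            table[f"z_{site}"] = z
            table[f"p_{site}"] = p
            p_tables[site] = pd.Series(p, index=self.p0.index)
        comb = combine_experiments(p_tables)
        table = table.join(comb)
        return DriftScanResults(
            model=self, table=table, ne_estimates=ne_estimates, n_var0_excluded=excluded
        )


@dataclass
class DriftScanResults:
    """Fitted scan: per-SNP table, per-site Ne estimates, diagnostics."""

    model: DriftScan
    table: pd.DataFrame
    ne_estimates: dict[str, NeEstimate]
    n_var0_excluded: dict[str, int]

    def top_snps(self, n: int = 10) -> pd.DataFrame:
        return self.table.nsmallest(n, "combined_score")

    def summary(self) -> str:
        lines = [
            "Drift-null selection scan",
            "=" * 60,
            f"SNPs: {len(self.table)}   sites: {len(self.ne_estimates)}   "
            f"centering: {'on' if self.model.center else 'off'}",
            "",
            f"{'site':<8}{'n':>6}{'slope':>12}{'Ne':>9}{'SNPs(fit)':>11}{'var0=0':>8}",
            "-" * 60,
        ]
        for site, est in sorted(self.ne_estimates.items()):
            slope = f"{est.slope:.5f}" if np.isfinite(est.slope) else "(given)"
            lines.append(
                f"{site:<8}{est.n_sample:>6}{slope:>12}{est.ne:>9.1f}"
                f"{est.n_snps_used:>11}{self.n_var0_excluded.get(site, 0):>8}"
            )
        top = self.top_snps(5)
        lines += ["", "Top SNPs by combined score:"]
        for (chrom, pos), row in top.iterrows():
            lines.append(
                f"  {chrom}:{pos}  p0={row['p0']:.3f}  "
                f"-log10(score)={row['neg_log10_combined']:.2f}"
            )
        return "\n".join(lines)

    def write(self, path) -> None:
        write_scan(self.table, path)
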