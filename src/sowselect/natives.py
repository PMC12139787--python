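"""Geographic filtering of accessions confounded by cryptic natives.

Selection-experiment sites can harbour wild individuals of the local
population ("native volunteers"). Most are distinguishable from the sown
panel, but an experimental accession originally collected close to a site
may have wild relatives there that are genotypically identical —
inflating its apparent fitness. Because the species shows strong
isolation by distance, the probability that two individuals are
genetically identical decays rapidly with the distance between their
collection points, which justifies a simple distance cutoff (default
5.6 km, boundary inclusive) for flagging potentially confounded
(accession, site) pairs, plus frequency-outlier rules for deciding which
flagged accessions to exclude from fitness estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .assignment import _informative_stats
from .panel import GenotypePanel

EARTH_RADIUS_KM = 6371.0
DEFAULT_CUTOFF_KM = 5.6


def geo_distance(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle (haversine) distance in km between (lat, lon) points."""
    lat1, lon1 = a
    lat2, lon2 = b
    for lat, lon in ((lat1, lon1), (lat2, lon2)):
        if not (-90.0 <= lat <= 90.0) or not (-180.0 <= lon <= 180.0):
            raise ValueError(f"coordinates out of range: ({lat}, {lon})")
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2 - lon1)
    h = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


def _pairwise_distances_km(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    phi = np.radians(lat)[:, None]
    lam = np.radians(lon)[:, None]
    dphi = phi - phi.T
    dlam = lam - lam.T
    h = np.sin(dphi / 2.0) ** 2 + np.cos(phi) * np.cos(phi.T) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


@dataclass
class IbdDecay:
    """Isolation-by-distance decay of pairwise genotype identity.

    ``bins`` holds non-overlapping ascending distance bins (edges in km)
    with the proportion of pairs that are genotype-identical in each;
    ``fitted`` is a monotone-decreasing curve evaluated on a fine
    distance grid; ``cutoff_km`` is the smallest distance at which the
    fitted identity probability falls below the configured floor (nan if
    it never does, 0 if no identical pairs exist anywhere).
    """

    bin_edges: np.ndarray
    bin_mid: np.ndarray
    proportion_identical: np.ndarray
    n_pairs: np.ndarray
    grid_km: np.ndarray
    fitted: np.ndarray
    cutoff_km: float
    floor: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low_km": self.bin_edges[:-1],
                "bin_high_km": self.bin_edges[1:],
                "bin_mid_km": self.bin_mid,
                "proportion_identical": self.proportion_identical,
                "n_pairs": self.n_pairs,
            }
        )


def identity_vs_distance(
    panel: GenotypePanel,
    identity_mismatch_max: float = 0.015,
    n_bins: int = 20,
    floor: float = 0.01,
) -> IbdDecay:
    """Decay of pairwise genotype identity with geographic distance.

    All accession pairs are classified identical when their mismatch rate
    is at most ``identity_mismatch_max`` (tolerating genotyping error,
    same ceiling as assignment). Binned identical proportions are fitted
    with a monotone decreasing (isotonic) curve, and ``cutoff_km`` is the
    smallest distance where the fit drops below ``floor``.
    """
    ok = ~(np.isnan(panel.lat) | np.isnan(panel.lon))
    if ok.sum() < 2:
        raise ValueError("need at least two accessions with coordinates")
    g = panel.genotypes[ok]
    mm, _ = _informative_stats(g, g)
    dist = _pairwise_distances_km(panel.lat[ok], panel.lon[ok])
    iu = np.triu_indices(g.shape[0], k=1)
    pair_d = dist[iu]
    with np.errstate(invalid="ignore"):
        pair_ident = mm[iu] <= identity_mismatch_max

    edges = np.linspace(0.0, max(pair_d.max(), 1e-9), n_bins + 1)
    idx = np.clip(np.digitize(pair_d, edges) - 1, 0, n_bins - 1)
    n_pairs = np.bincount(idx, minlength=n_bins)
    n_ident = np.bincount(idx, weights=pair_ident.astype(float), minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(n_pairs > 0, n_ident / np.maximum(n_pairs, 1), np.nan)
    mid = 0.5 * (edges[:-1] + edges[1:])

    occupied = n_pairs > 0
    grid = np.linspace(0.0, edges[-1], 512)
    if occupied.sum() < 2:
        # everything in one bin: no decay can be fitted
        fitted = np.full_like(grid, prop[occupied][0] if occupied.any() else np.nan)
    else:
        iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
        iso.fit(mid[occupied], prop[occupied], sample_weight=n_pairs[occupied])
        fitted = iso.predict(grid)

    if not pair_ident.any():
        cutoff = 0.0
    else:
        below = np.flatnonzero(fitted < floor)
        cutoff = float(grid[below[0]]) if below.size else float("nan")
    return IbdDecay(
        bin_edges=edges,
        bin_mid=mid,
        proportion_identical=prop,
        n_pairs=n_pairs,
        grid_km=grid,
        fitted=fitted,
        cutoff_km=cutoff,
        floor=floor,
    )


def flag_potential_natives(
    accession_coords: pd.DataFrame,
    site_coords: pd.DataFrame,
    cutoff_km: float = DEFAULT_CUTOFF_KM,
) -> pd.DataFrame:
    """Flag (accession, site) pairs within the distance cutoff.

    An accession is a potential native at a site iff the great-circle
    distance from its collection point to the site is at most
    ``cutoff_km`` (boundary inclusive — conservative). Accessions with
    missing coordinates are reported ``unflaggable`` rather than silently
    passed.

    Parameters
    ----------
    accession_coords : DataFrame with columns accession_id, lat, lon
    site_coords : DataFrame with columns site_id, lat, lon
    """
    if cutoff_km <= 0:
        raise ValueError("cutoff_km must be positive")
    rows = []
    for _, acc in accession_coords.iterrows():
        missing = pd.isna(acc["lat"]) or pd.isna(acc["lon"])
        for _, site in site_coords.iterrows():
            if missing:
                rows.append(
                    {
                        "accession_id": acc["accession_id"],
                        "site_id": site["site_id"],
                        "distance_km": np.nan,
                        "potential_native": False,
                        "unflaggable": True,
                    }
                )
                continue
            d = geo_distance(
                (float(acc["lat"]), float(acc["lon"])),
                (float(site["lat"]), float(site["lon"])),
            )
            rows.append(
                {
                    "accession_id": acc["accession_id"],
                    "site_id": site["site_id"],
                    "distance_km": d,
                    "potential_native": d <= cutoff_km,
                    "unflaggable": False,
                }
            )
    return pd.DataFrame(rows)


def flag_frequency_outliers(
    frequencies: pd.DataFrame,
    flags: pd.DataFrame,
    mode: str = "threshold",
    home_away_ratio: float = 3.0,
    min_home_freq: float = 0.10,
) -> pd.DataFrame:
    """Decide which potential-native accessions to exclude at their home site.

    Two modes:

    * ``"threshold"`` — exclude a potential native at its home site iff
      its home-site frequency is at least ``min_home_freq`` AND at least
      ``home_away_ratio`` times its maximum frequency at non-home sites.
    * ``"top1"`` — exclude a potential native that has the single largest
      frequency at its home site (mirrors excluding obvious outliers by
      judgment).

    Parameters
    ----------
    frequencies : DataFrame, rows = sites, columns = accessions.
    flags : output of :func:`flag_potential_natives`.

    Returns the flags table with ``excluded`` and ``reason`` columns
    added. Exclusion never touches other accessions' counts; only
    downstream renormalisation changes.
    """
    if mode not in ("threshold", "top1"):
        raise ValueError("mode must be 'threshold' or 'top1'")
    out = flags.copy()
    out["excluded"] = False
    out["reason"] = ""
    for idx, row in out.iterrows():
        if not row["potential_native"]:
            continue
        acc, site = row["accession_id"], row["site_id"]
        if site not in frequencies.index or acc not in frequencies.columns:
            continue
        home = float(frequencies.loc[site, acc])
        away = frequencies.loc[frequencies.index != site, acc].astype(float)
        away_max = float(away.max()) if len(away) else 0.0
        if mode == "threshold":
            ratio_ok = home >= home_away_ratio * away_max
            if home >= min_home_freq and ratio_ok:
                out.loc[idx, "excluded"] = True
                out.loc[idx, "reason"] = (
                    f"home_freq={home:.4f}>={min_home_freq} and "
                    f">={home_away_ratio}x away_max={away_max:.4f}"
                )
        else:  # top1
            site_freqs = frequencies.loc[site].astype(float)
            top = site_freqs.idxmax()
            if top == acc and home > 0 and (site_freqs == home).sum() == 1:
                out.loc[idx, "excluded"] = True
                out.loc[idx, "reason"] = f"largest home-site frequency ({home:.4f})"
    return out
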