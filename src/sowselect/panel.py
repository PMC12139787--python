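"""In-memory containers for genotype panels and field-sample calls.

Genotypes are biallelic and coded as ``int8``: 0 and 1 are the two
homozygous states (accessions are inbred, so the panel itself is purely
homozygous), :data:`HET` (2) marks a heterozygous call in a field sample,
and :data:`MISSING` (-1) marks a missing call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING: int = -1
HET: int = 2


def _as_int8_matrix(genotypes, allowed: tuple[int, ...]) -> np.ndarray:
    g = np.asarray(genotypes, dtype=np.int8)
    if g.ndim != 2:
        raise ValueError(f"genotype matrix must be 2-D, got shape {g.shape}")
    bad = ~np.isin(g, allowed)
    if bad.any():
        raise ValueError(
            f"invalid genotype codes {sorted(np.unique(g[bad]).tolist())}; "
            f"allowed: {sorted(allowed)}"
        )
    return g


@dataclass
class GenotypePanel:
    """Accession-by-SNP genotype matrix for the reference panel at sowing.

    Parameters
    ----------
    accession_ids : list of str
        One id per panel accession (row).
    group_labels : list of str
        Genetic-group label per accession.
    lat, lon : ndarray
        Collection coordinates per accession, decimal degrees. ``nan``
        marks unknown origin.
    chrom : list of str
        Chromosome per SNP (column).
    pos : ndarray
        1-based position per SNP.
    genotypes : ndarray of int8, shape (n_accessions, n_snps)
        Entries in {0, 1, MISSING}. Heterozygous entries are rejected:
        accessions are inbred lines.
    """

    accession_ids: list[str]
    group_labels: list[str]
    lat: np.ndarray
    lon: np.ndarray
    chrom: list[str]
    pos: np.ndarray
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = _as_int8_matrix(self.genotypes, (0, 1, MISSING))
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        n_acc, n_snp = self.genotypes.shape
        if len(self.accession_ids) != n_acc or len(self.group_labels) != n_acc:
            raise ValueError("accession_ids/group_labels length must match rows")
        if self.lat.shape != (n_acc,) or self.lon.shape != (n_acc,):
            raise ValueError("coordinate arrays must have one entry per accession")
        if len(self.chrom) != n_snp or self.pos.shape != (n_snp,):
            raise ValueError("chrom/pos length must match genotype columns")
        if (self.pos <= 0).any():
            raise ValueError("positions are 1-based and must be positive")
        if len(set(self.accession_ids)) != n_acc:
            dupes = pd.Index(self.accession_ids)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValueError(f"duplicate accession ids: {dupes}")

    @property
    def n_accessions(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def snp_index(self) -> pd.MultiIndex:
        """(chrom, pos) index identifying each SNP column."""
        return pd.MultiIndex.from_arrays([self.chrom, self.pos], names=["chrom", "pos"])

    def metadata(self) -> pd.DataFrame:
        """Accession metadata as a DataFrame (id, group, lat, lon)."""
        return pd.DataFrame(
            {
                "accession_id": self.accession_ids,
                "group": self.group_labels,
                "lat": self.lat,
                "lon": self.lon,
            }
        )


@dataclass
class SampleCalls:
    """Per-SNP genotype calls for field-collected samples.

    Calls are aligned to a panel's SNP order: column ``j`` of ``calls``
    refers to the same (chrom, pos) as column ``j`` of the panel the
    samples will be assigned against. Entries are in
    {0, 1, HET, MISSING}.
    """

    sample_ids: list[str]
    site_ids: list[str]
    chrom: list[str]
    pos: np.ndarray
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = _as_int8_matrix(self.calls, (0, 1, HET, MISSING))
        self.pos = np.asarray(self.pos, dtype=np.int64)
        n_samp, n_snp = self.calls.shape
        if len(self.sample_ids) != n_samp or len(self.site_ids) != n_samp:
            raise ValueError("sample_ids/site_ids length must match call rows")
        if len(self.chrom) != n_snp or self.pos.shape != (n_snp,):
            raise ValueError("chrom/pos length must match call columns")

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    def snp_index(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_arrays([self.chrom, self.pos], names=["chrom", "pos"])

    def check_aligned(self, panel: GenotypePanel) -> None:
        """Raise if the sample SNPs are not the panel SNPs in panel order."""
        if self.n_snps != panel.n_snps or not (
            self.chrom == panel.chrom and np.array_equal(self.pos, panel.pos)
        ):
            raise ValueError(
                "sample calls are not aligned to the panel SNP order; join on "
                "(chrom, pos) before assignment"
            )


@dataclass
class TruthRecord:
    """Ground truth for simulated samples.

    ``source`` holds, per sample, the originating accession id, or the
    sentinel classes ``"native"`` / ``"heterozygous"``. Every simulated
    sample carries exactly one truth label.
    """

    sample_ids: list[str]
    site_ids: list[str]
    source: list[str]
    true_ne: dict[str, int] = field(default_factory=dict)
    true_fitness: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.sample_ids) == len(self.site_ids) == len(self.source)):
            raise ValueError("every sample needs exactly one truth label")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "site_id": self.site_ids,
                "source": self.source,
            }
        )

    def composition(self) -> pd.DataFrame:
        """True per-site counts of experimental accessions (natives/hets excluded)."""
        df = self.to_frame()
        exp = df[~df["source"].isin(["native", "heterozygous"])]
        return (
            exp.groupby(["site_id", "source"]).size().rename("count").reset_index()
        )
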