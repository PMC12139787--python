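"""Configuration objects for simulation and pipeline runs.

Defaults mirror the study design the generator emulates: 200 inbred
accessions in 4 differentiated genetic groups sown at equal frequency
(40 seeds x 200 accessions = 8,000 seeds per subplot), four experimental
sites with small effective population sizes and per-site sample sizes in
the low hundreds, with a substantial share of native volunteers and
heterozygous/contaminated samples among the field-collected genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

#: Per-site defaults: (effective population size, genotyped sample size).
DEFAULT_SITES: dict[str, tuple[int, int]] = {
    "NA": (17, 171),
    "NB": (70, 199),
    "SR": (34, 208),
    "ST": (16, 137),
}

#: Site coordinates (decimal degrees) used for the geographic layer.
DEFAULT_SITE_COORDS: dict[str, tuple[float, float]] = {
    "NA": (62.862, 18.338),
    "NB": (62.87, 18.381),
    "SR": (55.906, 14.260),
    "ST": (55.60, 14.304),
}

SEEDS_PER_ACCESSION_PER_SUBPLOT = 40


@dataclass
class SimConfig:
    """Knobs of the synthetic-data generator.

    Parameters
    ----------
    n_accessions : int
        Panel size; every accession is sown at frequency ``1/n_accessions``.
    n_snps : int
        Number of biallelic SNPs simulated.
    n_groups : int
        Number of differentiated genetic groups.
    differentiation : float
        Balding-Nichols style F_ST parameter in [0, 1) controlling
        group-level allele-frequency divergence.
    fitness : ndarray or None
        Strictly positive relative-fitness weight per accession; ``None``
        means neutral (all equal).
    ne_per_site, n_sample_per_site : dict
        Effective population size and genotyped sample size per site.
    native_fraction : float
        Share of field samples that are native volunteers not present in
        the panel.
    het_fraction : float
        Share of field samples that are extensively heterozygous
        (outcrossed or contaminated).
    het_call_fraction : float
        Within a heterozygous sample, the portion of calls drawn from a
        mixture of two accessions (heterozygous wherever the two differ).
    genotype_error_rate, missing_rate : float
        Per-call flip and drop-out probabilities emulating low-coverage
        genotyping of small, half-dead field samples.
    rng_seed : int
        Root seed; all stages draw from documented substreams of it.
    """

    n_accessions: int = 200
    n_snps: int = 10_000
    n_groups: int = 4
    differentiation: float = 0.2
    fitness: Any = None
    ne_per_site: dict[str, int] = field(
        default_factory=lambda: {s: ne for s, (ne, _) in DEFAULT_SITES.items()}
    )
    n_sample_per_site: dict[str, int] = field(
        default_factory=lambda: {s: n for s, (_, n) in DEFAULT_SITES.items()}
    )
    site_coords: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SITE_COORDS)
    )
    native_fraction: float = 0.158
    het_fraction: float = 0.088
    het_call_fraction: float = 0.5
    genotype_error_rate: float = 0.01
    missing_rate: float = 0.5
    seeds_per_accession: int = SEEDS_PER_ACCESSION_PER_SUBPLOT
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_accessions", "n_snps", "n_groups"):
            if getattr(self, name) < 0 or (name != "n_snps" and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")
        if self.n_groups > self.n_accessions:
            raise ValueError("n_groups cannot exceed n_accessions")
        if not 0.0 <= self.differentiation < 1.0:
            raise ValueError("differentiation must lie in [0, 1)")
        for name in (
            "native_fraction",
            "het_fraction",
            "het_call_fraction",
            "genotype_error_rate",
            "missing_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.fitness is not None:
            import numpy as np

            self.fitness = np.asarray(self.fitness, dtype=float)
            if self.fitness.shape != (self.n_accessions,):
                raise ValueError("fitness needs one weight per accession")
            if (self.fitness <= 0).any():
                raise ValueError("fitness weights must be strictly positive")
        sites_ne = set(self.ne_per_site)
        if sites_ne != set(self.n_sample_per_site):
            raise ValueError("ne_per_site and n_sample_per_site must cover the same sites")
        for site in sites_ne:
            if self.ne_per_site[site] < 1 or self.n_sample_per_site[site] < 1:
                raise ValueError("per-site Ne and sample sizes must be >= 1")

    @property
    def sites(self) -> list[str]:
        return sorted(self.ne_per_site)

    @property
    def seeds_per_subplot(self) -> int:
        """Total seeds sown per subplot (equal numbers of every accession)."""
        return self.seeds_per_accession * self.n_accessions

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        if d["fitness"] is not None:
            d["fitness"] = [float(x) for x in d["fitness"]]
        d["site_coords"] = {k: list(v) for k, v in d["site_coords"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimConfig":
        d = dict(d)
        if "site_coords" in d:
            d["site_coords"] = {k: tuple(v) for k, v in d["site_coords"].items()}
        return cls(**d)


@dataclass
class RunConfig:
    """Configuration of an end-to-end pipeline run.

    Either ``sim`` (a :class:`SimConfig` for a self-contained synthetic
    run) or the real-input paths (``panel_path`` + ``samples_path`` +
    ``metadata_path`` + ``sites_path``) must be present — not neither.
    """

    out_dir: str = "sowselect_run"
    seed: int = 0
    sim: SimConfig | None = None
    panel_path: str | None = None
    samples_path: str | None = None
    metadata_path: str | None = None
    sites_path: str | None = None
    mismatch_threshold: float = 0.015
    min_informative: int = 10_000
    het_threshold: float = 0.05
    cutoff_km: float = 5.6
    outlier_mode: str = "threshold"
    home_away_ratio: float = 3.0
    min_home_freq: float = 0.10
    maf_floor: float = 0.03
    center_scan: bool = True
    liability: dict[str, Any] | None = None

    def __post_init__(self) -> None:
        have_real = all(
            p is not None
            for p in (self.panel_path, self.samples_path, self.metadata_path, self.sites_path)
        )
        if self.sim is None and not have_real:
            raise ValueError(
                "config needs either a 'sim' block or all real-input paths "
                "(panel, samples, metadata, sites)"
            )
        if self.outlier_mode not in ("threshold", "top1"):
            raise ValueError("outlier_mode must be 'threshold' or 'top1'")
        for name in ("mismatch_threshold", "het_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.cutoff_km <= 0:
            raise ValueError("cutoff_km must be positive")
        if self.min_informative < 1:
            raise ValueError("min_informative must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a run configuration from YAML or JSON."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} does not hold a mapping")
        if data.get("sim") is not None:
            data["sim"] = SimConfig.from_dict(data["sim"])
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        if self.sim is not None:
            d["sim"] = self.sim.to_dict()
        return d
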