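"""Synthetic panels, selection experiments and degraded genotype calls.

The generator emulates a sow-and-sequence experimental design: a panel of
inbred accessions from a small number of differentiated genetic groups is
sown at equal frequency at several field sites; the surviving population
at each site is modelled as a Wright-Fisher multinomial sample of size Ne
drawn with accession fitness weights, and the genotyped sample is a second
multinomial draw from that population. Field genotyping of tiny,
half-dead seedlings is emulated by per-call drop-out and error, by
heterozygous "contaminated" samples built as mixtures of two accessions,
and by native volunteers whose genotypes come from the local group's
allele frequencies but match no panel accession.

All randomness flows from one root seed through named per-stage
substreams, so identical configurations give bit-identical outputs.
"""

from __future__ import annotations

import zlib

import numpy as np

from .config import SimConfig
from .panel import HET, MISSING, GenotypePanel, SampleCalls, TruthRecord

#: Default number of chromosomes SNPs are spread over.
N_CHROM = 5


def stage_rng(root_seed: int, stage: str) -> np.random.Generator:
    """A reproducible per-stage substream of the root seed.

    The stage name is hashed (CRC-32, stable across runs and platforms)
    and combined with the root seed into a :class:`numpy.random.SeedSequence`.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(root_seed), zlib.crc32(stage.encode("utf-8"))])
    )


def _group_sizes(n_accessions: int, n_groups: int) -> np.ndarray:
    base = n_accessions // n_groups
    sizes = np.full(n_groups, base, dtype=int)
    sizes[: n_accessions - base * n_groups] += 1
    return sizes


def simulate_panel(config: SimConfig) -> GenotypePanel:
    """Simulate an inbred accession panel with group structure.

    Group allele frequencies follow a Balding-Nichols draw: the ancestral
    frequency of each SNP is Uniform(0.05, 0.95) and each group's
    frequency is Beta-distributed around it with the configured
    differentiation F, i.e. Beta(p(1-F)/F, (1-p)(1-F)/F). Accessions are
    homozygous Bernoulli draws from their group's frequencies, and their
    collection coordinates are jittered around per-group geographic
    centres so groups are spatially clustered.
    """
    rng = stage_rng(config.rng_seed, "panel")
    n_acc, n_snp, n_grp = config.n_accessions, config.n_snps, config.n_groups
    f = config.differentiation

    ancestral = rng.uniform(0.05, 0.95, size=n_snp)
    if f > 0:
        a = ancestral * (1.0 - f) / f
        b = (1.0 - ancestral) * (1.0 - f) / f
        group_freqs = rng.beta(a, b, size=(n_grp, n_snp))
    else:
        group_freqs = np.tile(ancestral, (n_grp, 1))

    sizes = _group_sizes(n_acc, n_grp)
    group_of = np.repeat(np.arange(n_grp), sizes)
    genotypes = (rng.random((n_acc, n_snp)) < group_freqs[group_of]).astype(np.int8)

    # Spatially clustered origins: group centres spread south-to-north.
    centre_lat = np.linspace(55.6, 63.0, n_grp) if n_grp > 1 else np.array([59.0])
    centre_lon = np.linspace(13.9, 18.3, n_grp) if n_grp > 1 else np.array([16.0])
    lat = centre_lat[group_of] + rng.normal(0.0, 0.15, size=n_acc)
    lon = centre_lon[group_of] + rng.normal(0.0, 0.15, size=n_acc)

    width = max(3, len(str(n_acc)))
    accession_ids = [f"acc{i + 1:0{width}d}" for i in range(n_acc)]
    group_labels = [f"G{g + 1}" for g in group_of]

    if n_snp > 0:
        chrom_of = np.minimum(np.arange(n_snp) * N_CHROM // max(n_snp, 1), N_CHROM - 1)
        chrom = [f"Chr{c + 1}" for c in chrom_of]
        # positions restart per chromosome, spaced ~100 bp
        pos = np.empty(n_snp, dtype=np.int64)
        for c in range(N_CHROM):
            mask = chrom_of == c
            pos[mask] = 100 * (np.arange(mask.sum()) + 1)
    else:
        chrom, pos = [], np.empty(0, dtype=np.int64)

    return GenotypePanel(
        accession_ids=accession_ids,
        group_labels=group_labels,
        lat=lat,
        lon=lon,
        chrom=chrom,
        pos=pos,
        genotypes=genotypes,
    )


def group_allele_freqs(panel: GenotypePanel) -> dict[str, np.ndarray]:
    """Per-group allele frequencies (missing panel calls excluded)."""
    g = panel.genotypes.astype(float)
    g[panel.genotypes == MISSING] = np.nan
    labels = np.asarray(panel.group_labels)
    out: dict[str, np.ndarray] = {}
    for grp in sorted(set(panel.group_labels)):
        sub = g[labels == grp]
        with np.errstate(invalid="ignore"):
            out[grp] = np.nanmean(sub, axis=0)
    return out


def simulate_selection_experiment(
    panel: GenotypePanel,
    fitness: np.ndarray | None,
    ne: int,
    n_sample: int,
    seed: int,
    site_id: str = "S1",
) -> tuple[SampleCalls, TruthRecord]:
    """Two-stage Wright-Fisher sampling of one experimental site.

    Stage 1 draws the surviving population: a multinomial of size ``ne``
    over accessions with probabilities proportional to (1/N) x fitness.
    Stage 2 draws the genotyped sample: ``n_sample`` individuals
    multinomially from the stage-1 population composition. Each sampled
    individual carries its accession's full panel genotype.
    """
    if panel.n_accessions == 0:
        raise ValueError("cannot run a selection experiment on an empty panel")
    if ne < 1 or n_sample < 1:
        raise ValueError("ne and n_sample must be >= 1")
    n_acc = panel.n_accessions
    if fitness is None:
        fitness = np.ones(n_acc)
    fitness = np.asarray(fitness, dtype=float)
    if fitness.shape != (n_acc,):
        raise ValueError("fitness needs one weight per accession")
    if (fitness <= 0).any():
        raise ValueError("fitness weights must be strictly positive")

    rng = stage_rng(seed, f"experiment:{site_id}")
    probs = fitness / fitness.sum()
    survivors = rng.multinomial(ne, probs)  # stage 1: drift + selection
    sampled = rng.multinomial(n_sample, survivors / ne)  # stage 2: sampling

    acc_idx = np.repeat(np.arange(n_acc), sampled)
    rng.shuffle(acc_idx)
    calls = panel.genotypes[acc_idx].copy()
    sample_ids = [f"{site_id}_s{i + 1:04d}" for i in range(n_sample)]
    source = [panel.accession_ids[j] for j in acc_idx]

    sc = SampleCalls(
        sample_ids=sample_ids,
        site_ids=[site_id] * n_sample,
        chrom=list(panel.chrom),
        pos=panel.pos.copy(),
        calls=calls,
    )
    truth = TruthRecord(
        sample_ids=list(sample_ids),
        site_ids=[site_id] * n_sample,
        source=source,
        true_ne={site_id: int(ne)},
        true_fitness={site_id: fitness.copy()},
    )
    return sc, truth


def degrade_calls(
    calls: SampleCalls,
    missing_rate: float,
    error_rate: float,
    het_fraction_of_samples: float = 0.0,
    seed: int = 0,
    het_call_fraction: float = 0.5,
    protect: np.ndarray | None = None,
    stream: str = "degrade",
) -> tuple[SampleCalls, np.ndarray]:
    """Degrade clean calls into low-coverage field-genotyping output.

    A ``het_fraction_of_samples`` share of samples (an exact rounded
    count, chosen among rows where ``protect`` is False) is turned into
    two-accession mixtures: on a random ``het_call_fraction`` portion of
    sites the call becomes heterozygous wherever the sample and a random
    partner row disagree. Then every homozygous call is independently
    flipped with ``error_rate``, and every call dropped to missing with
    ``missing_rate``.

    Returns the degraded calls and the (sorted) row indices that were
    made heterozygous.
    """
    for name, v in (
        ("missing_rate", missing_rate),
        ("error_rate", error_rate),
        ("het_fraction_of_samples", het_fraction_of_samples),
        ("het_call_fraction", het_call_fraction),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    rng = stage_rng(seed, stream)
    out = calls.calls.copy()
    n_samp, n_snp = out.shape

    eligible = np.arange(n_samp)
    if protect is not None:
        eligible = eligible[~np.asarray(protect, dtype=bool)]
    n_het = int(round(het_fraction_of_samples * n_samp))
    if n_het > len(eligible):
        raise ValueError("not enough unprotected samples to spike heterozygotes")
    het_rows = np.sort(rng.choice(eligible, size=n_het, replace=False))

    # a spiked sample must be *visibly* heterozygous (its class is assigned,
    # not sampled), so partners are redrawn until the mixture leaves an
    # unambiguous share of het calls
    min_het_share = 0.10
    for i in het_rows:
        choices = eligible[eligible != i]
        best_mask = None
        for _ in range(10):
            partner = int(rng.choice(choices)) if len(choices) else i
            mixed = rng.random(n_snp) < het_call_fraction
            differ = (
                (out[i] != out[partner])
                & (out[i] != MISSING)
                & (out[partner] != MISSING)
            )
            mask = mixed & differ
            if best_mask is None or mask.sum() > best_mask.sum():
                best_mask = mask
            if n_snp == 0 or mask.sum() / n_snp >= min_het_share:
                break
        if best_mask is not None:
            out[i, best_mask] = HET

    if error_rate > 0 and n_snp:
        homo = (out == 0) | (out == 1)
        flip = (rng.random(out.shape) < error_rate) & homo
        out[flip] = 1 - out[flip]
    if missing_rate > 0 and n_snp:
        out[rng.random(out.shape) < missing_rate] = MISSING

    degraded = SampleCalls(
        sample_ids=list(calls.sample_ids),
        site_ids=list(calls.site_ids),
        chrom=list(calls.chrom),
        pos=calls.pos.copy(),
        calls=out,
    )
    return degraded, het_rows


def spike_natives(
    calls: SampleCalls,
    panel: GenotypePanel,
    native_fraction: float,
    seed: int = 0,
    truth: TruthRecord | None = None,
    mismatch_threshold: float = 0.015,
    max_attempts: int = 50,
    stream: str = "natives",
) -> tuple[SampleCalls, TruthRecord]:
    """Replace a share of samples with native volunteers.

    The replaced samples (an exact rounded count) get genotypes drawn
    from a random group's allele frequencies, redrawn until they mismatch
    every panel accession by more than ``mismatch_threshold`` — natives
    share the local population structure but are, by construction,
    distinguishable from every experimental accession.

    Raises
    ------
    ValueError
        If distinguishable natives cannot be constructed with the
        available number of SNPs.
    """
    if not 0.0 <= native_fraction <= 1.0:
        raise ValueError("native_fraction must lie in [0, 1]")
    rng = stage_rng(seed, stream)
    n_samp, n_snp = calls.calls.shape
    n_native = int(round(native_fraction * n_samp))

    source = list(truth.source) if truth is not None else ["unknown"] * n_samp
    out = calls.calls.copy()
    if n_native == 0:
        new_truth = TruthRecord(
            sample_ids=list(calls.sample_ids),
            site_ids=list(calls.site_ids),
            source=source,
            true_ne=dict(truth.true_ne) if truth else {},
            true_fitness=dict(truth.true_fitness) if truth else {},
        )
        return calls, new_truth

    freqs = group_allele_freqs(panel)
    group_names = sorted(freqs)
    g = panel.genotypes
    informative_panel = g != MISSING
    rows = np.sort(rng.choice(n_samp, size=n_native, replace=False))
    for i in rows:
        grp = group_names[int(rng.integers(len(group_names)))]
        p = np.nan_to_num(freqs[grp], nan=0.5)
        for _ in range(max_attempts):
            cand = (rng.random(n_snp) < p).astype(np.int8)
            disc = (cand[None, :] != g) & informative_panel
            n_inf = informative_panel.sum(axis=1)
            with np.errstate(invalid="ignore"):
                mm = np.where(n_inf > 0, disc.sum(axis=1) / np.maximum(n_inf, 1), np.nan)
            if np.nanmin(mm) > mismatch_threshold:
                break
        else:
            raise ValueError(
                f"could not construct a native distinguishable from all "
                f"{panel.n_accessions} accessions with {n_snp} SNPs"
            )
        out[i] = cand
        source[i] = "native"

    spiked = SampleCalls(
        sample_ids=list(calls.sample_ids),
        site_ids=list(calls.site_ids),
        chrom=list(calls.chrom),
        pos=calls.pos.copy(),
        calls=out,
    )
    new_truth = TruthRecord(
        sample_ids=list(calls.sample_ids),
        site_ids=list(calls.site_ids),
        source=source,
        true_ne=dict(truth.true_ne) if truth else {},
        true_fitness=dict(truth.true_fitness) if truth else {},
    )
    return spiked, new_truth


def simulate_site_samples(
    panel: GenotypePanel,
    config: SimConfig,
    site_id: str,
) -> tuple[SampleCalls, TruthRecord]:
    """Full per-site sample generation: experiment, natives, degradation.

    Classes are assigned with exact rounded counts: ``native_fraction``
    of samples become native volunteers and ``het_fraction`` of the
    remaining samples become heterozygous mixtures, before low-coverage
    missingness and genotype error are applied to everything.
    """
    ne = config.ne_per_site[site_id]
    n_sample = config.n_sample_per_site[site_id]
    clean, truth = simulate_selection_experiment(
        panel,
        config.fitness,
        ne,
        n_sample,
        seed=config.rng_seed,
        site_id=site_id,
    )
    spiked, truth = spike_natives(
        clean,
        panel,
        config.native_fraction,
        seed=config.rng_seed,
        truth=truth,
        stream=f"natives:{site_id}",
    )
    native_mask = np.array([s == "native" for s in truth.source])
    degraded, het_rows = degrade_calls(
        spiked,
        missing_rate=config.missing_rate,
        error_rate=config.genotype_error_rate,
        het_fraction_of_samples=config.het_fraction,
        seed=config.rng_seed,
        het_call_fraction=config.het_call_fraction,
        protect=native_mask,
        stream=f"degrade:{site_id}",
    )
    source = list(truth.source)
    for i in het_rows:
        source[i] = "heterozygous"
    truth = TruthRecord(
        sample_ids=list(truth.sample_ids),
        site_ids=list(truth.site_ids),
        source=source,
        true_ne=truth.true_ne,
        true_fitness=truth.true_fitness,
    )
    return degraded, truth
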