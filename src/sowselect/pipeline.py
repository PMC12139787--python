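"""End-to-end pipeline: simulate → assign → natives → fitness → scan → liability.

A run is driven by a :class:`~sowselect.config.RunConfig` (self-contained
synthetic run, or real panel/sample/metadata files), writes every
intermediate as TSV/VCF/CSV under the output directory, and finishes with
a JSON manifest recording inputs, parameters, seeds and per-stage row
counts. Identical configurations produce identical outputs; all
randomness derives from the one root seed via named substreams.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .assignment import assign_samples, assignments_to_frame, summarize_composition
from .config import RunConfig, SimConfig
from .driftscan import DriftScan
from .fitness import accession_frequencies, group_summaries
from .liability import fit_liability, simulate_survival
from .natives import flag_frequency_outliers, flag_potential_natives
from .panel import MISSING, GenotypePanel, SampleCalls
from .simulate import simulate_panel, simulate_site_samples, stage_rng

log = logging.getLogger("sowselect")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)  # results never on stderr; logs only
    _h.setFormatter(logging.Formatter("[%(name)s:%(stage)s] %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


def _stage_log(stage: str, msg: str) -> None:
    log.info(msg, extra={"stage": stage})


def align_calls_to_panel(calls: SampleCalls, panel: GenotypePanel) -> SampleCalls:
    """Reorder sample calls onto the panel SNP axis, joining on (chrom, pos).

    Panel SNPs absent from the sample file become missing calls; sample
    SNPs absent from the panel are an error (allele bookkeeping must be
    resolved upstream, never silently).
    """
    panel_idx = {key: j for j, key in enumerate(zip(panel.chrom, panel.pos.tolist()))}
    matrix = np.full((calls.n_samples, panel.n_snps), MISSING, dtype=np.int8)
    unknown = []
    for j, key in enumerate(zip(calls.chrom, calls.pos.tolist())):
        tgt = panel_idx.get(key)
        if tgt is None:
            unknown.append(key)
        else:
            matrix[:, tgt] = calls.calls[:, j]
    if unknown:
        raise ValueError(
            f"{len(unknown)} sample SNPs absent from the panel, e.g. {unknown[:3]}"
        )
    return SampleCalls(
        sample_ids=list(calls.sample_ids),
        site_ids=list(calls.site_ids),
        chrom=list(panel.chrom),
        pos=panel.pos.copy(),
        calls=matrix,
    )


def validate_inputs(
    panel: GenotypePanel,
    calls: SampleCalls,
    metadata: pd.DataFrame | None = None,
    panel_alleles: pd.DataFrame | None = None,
    call_alleles: pd.DataFrame | None = None,
) -> list[str]:
    """Cross-check panel, samples and metadata; returns every violation found."""
    violations: list[str] = []

    panel_keys = set(zip(panel.chrom, panel.pos.tolist()))
    sample_keys = list(zip(calls.chrom, calls.pos.tolist()))
    extra = [k for k in sample_keys if k not in panel_keys]
    for k in extra:
        violations.append(f"sample SNP {k[0]}:{k[1]} absent from the panel")

    bad_lat = np.flatnonzero(~np.isnan(panel.lat) & (np.abs(panel.lat) > 90))
    bad_lon = np.flatnonzero(~np.isnan(panel.lon) & (np.abs(panel.lon) > 180))
    for i in bad_lat:
        violations.append(f"accession {panel.accession_ids[i]}: latitude out of range")
    for i in bad_lon:
        violations.append(f"accession {panel.accession_ids[i]}: longitude out of range")

    if metadata is not None:
        dup = metadata["accession_id"][metadata["accession_id"].duplicated()]
        for d in sorted(dup.unique()):
            violations.append(f"duplicated accession id in metadata: {d}")
        absent = set(panel.accession_ids) - set(metadata["accession_id"])
        for a in sorted(absent):
            violations.append(f"panel accession {a} absent from metadata")

    dup_samples = pd.Index(calls.sample_ids)
    for d in sorted(dup_samples[dup_samples.duplicated()].unique()):
        violations.append(f"duplicated sample id: {d}")

    if panel_alleles is not None and call_alleles is not None:
        pa = panel_alleles.set_index(["chrom", "pos"])
        ca = call_alleles.set_index(["chrom", "pos"])
        shared = pa.index.intersection(ca.index)
        mism = shared[
            (pa.loc[shared, "ref"].to_numpy() != ca.loc[shared, "ref"].to_numpy())
            | (pa.loc[shared, "alt"].to_numpy() != ca.loc[shared, "alt"].to_numpy())
        ]
        for chrom, pos in mism[:20]:
            violations.append(
                f"allele encoding differs between panel and samples at {chrom}:{pos}"
            )
    return violations


def _load_real_inputs(config: RunConfig):
    for p in (
        config.panel_path,
        config.samples_path,
        config.metadata_path,
        config.sites_path,
    ):
        if not Path(p).exists():
            raise FileNotFoundError(f"input file not readable: {p}")
    metadata = sio.read_accession_metadata(config.metadata_path)
    sites = sio.read_site_metadata(config.sites_path)
    site_coords = {
        r["site_id"]: (float(r["lat"]), float(r["lon"])) for _, r in sites.iterrows()
    }
    panel_alleles = call_alleles = None
    if str(config.panel_path).endswith(".vcf"):
        panel, panel_alleles = sio.read_panel_vcf(config.panel_path, metadata)
    else:
        panel = sio.read_panel_tsv(config.panel_path, metadata)
    site_map = pd.read_csv(
        str(config.samples_path) + ".sites.tsv", sep="\t",
        keep_default_na=False, na_values=[""],
    ).set_index("sample_id")["site_id"]
    if str(config.samples_path).endswith(".vcf"):
        calls, call_alleles = sio.read_calls_vcf(config.samples_path, site_map)
    else:
        calls = sio.read_calls_tsv(config.samples_path, site_map)
    return panel, calls, metadata, site_coords, panel_alleles, call_alleles, None


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order; returns the run manifest.

    Any stage failure aborts with the stage name attached; outputs of
    completed stages are left on disk.
    """
    out = sio.ensure_dir(config.out_dir)
    # the manifest describes the run, not where it lives: identical configs
    # must give byte-identical manifests regardless of output location
    config_dict = config.to_dict()
    config_dict.pop("out_dir", None)
    manifest: dict = {
        "config": config_dict,
        "seed": config.seed,
        "versions": _versions(),
        "stages": {},
        "files": {},
    }
    stage = "setup"
    try:
        # ---- stage: inputs -------------------------------------------
        stage = "simulate"
        if config.sim is not None:
            sim = config.sim
            if sim.rng_seed != config.seed:
                sim = SimConfig.from_dict({**sim.to_dict(), "rng_seed": config.seed})
            _stage_log(stage, f"simulating panel: {sim.n_accessions} accessions, "
                              f"{sim.n_snps} SNPs, {sim.n_groups} groups")
            panel = simulate_panel(sim)
            parts, truths = [], []
            for site in sim.sites:
                c, t = simulate_site_samples(panel, sim, site)
                parts.append(c)
                truths.append(t)
            calls = sio.concat_calls(parts)
            truth = sio.concat_truth(truths)
            site_coords = dict(sim.site_coords)
            metadata = panel.metadata()
            panel_alleles = call_alleles = None

            sio.write_panel_vcf(panel, out / "panel.vcf")
            sio.write_panel_tsv(panel, out / "panel.tsv")
            sio.write_accession_metadata(panel, out / "accessions.csv")
            sio.write_site_metadata(site_coords, out / "sites.csv")
            sio.write_calls_tsv(calls, out / "samples.tsv", out / "samples.tsv.sites.tsv")
            sio.write_truth(truth, out / "truth.tsv")
            manifest["files"].update(
                panel="panel.vcf", samples="samples.tsv", truth="truth.tsv"
            )
            manifest["stages"][stage] = {
                "n_accessions": panel.n_accessions,
                "n_snps": panel.n_snps,
                "n_samples": calls.n_samples,
                "seeds_per_subplot": sim.seeds_per_subplot,
            }
        else:
            stage = "load"
            (panel, calls, metadata, site_coords, panel_alleles, call_alleles, truth
             ) = _load_real_inputs(config)
            calls = align_calls_to_panel(calls, panel)
            manifest["stages"][stage] = {
                "n_accessions": panel.n_accessions,
                "n_snps": panel.n_snps,
                "n_samples": calls.n_samples,
            }

        # ---- stage: validate -----------------------------------------
        stage = "validate"
        violations = validate_inputs(
            panel, calls, metadata, panel_alleles, call_alleles
        )
        manifest["stages"][stage] = {"n_violations": len(violations),
                                     "violations": violations[:50]}
        if violations:
            raise ValueError(f"input validation failed: {violations[:5]}")

        # ---- stage: assign -------------------------------------------
        stage = "assign"
        # the informative-site floor cannot exceed what the SNP set can
        # provide; cap it at half the panel SNPs for small synthetic panels
        eff_min_informative = min(config.min_informative, max(panel.n_snps // 2, 1))
        if eff_min_informative != config.min_informative:
            _stage_log(
                stage,
                f"min_informative capped at {eff_min_informative} "
                f"({panel.n_snps} panel SNPs)",
            )
        _stage_log(stage, f"assigning {calls.n_samples} samples")
        results = assign_samples(
            calls,
            panel,
            mismatch_threshold=config.mismatch_threshold,
            min_informative=eff_min_informative,
            het_threshold=config.het_threshold,
        )
        adf = assignments_to_frame(results)
        adf.to_csv(out / "assignments.tsv", sep="\t", index=False)
        comp = summarize_composition(
            results, accession_ids=panel.accession_ids, sites=sorted(site_coords)
        )
        comp.class_counts.to_csv(out / "class_counts.tsv", sep="\t")
        comp.accession_counts.to_csv(out / "accession_counts.tsv", sep="\t")
        manifest["stages"][stage] = {
            "n_assignments": len(adf),
            "min_informative": eff_min_informative,
            "class_counts": comp.class_counts.sum(axis=0).to_dict(),
        }

        # ---- stage: natives ------------------------------------------
        stage = "natives"
        sites_df = pd.DataFrame(
            [{"site_id": s, "lat": la, "lon": lo} for s, (la, lo) in sorted(site_coords.items())]
        )
        flags = flag_potential_natives(metadata, sites_df, cutoff_km=config.cutoff_km)
        prelim = comp.frequencies()
        flags = flag_frequency_outliers(
            prelim,
            flags,
            mode=config.outlier_mode,
            home_away_ratio=config.home_away_ratio,
            min_home_freq=config.min_home_freq,
        )
        flags.to_csv(out / "native_flags.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "n_potential_native": int(flags["potential_native"].sum()),
            "n_excluded": int(flags["excluded"].sum()),
        }

        # ---- stage: fitness ------------------------------------------
        stage = "fitness"
        freq = accession_frequencies(comp, exclusions=flags)
        freq.to_csv(out / "fitness.tsv", sep="\t", index=False)
        groups = group_summaries(
            freq, pd.Series(panel.group_labels, index=panel.accession_ids)
        )
        groups.to_csv(out / "group_summaries.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {"n_rows": len(freq)}

        # ---- stage: scan ---------------------------------------------
        stage = "scan"
        p_hat, n_sample = {}, {}
        for site in comp.accession_counts.index:
            n_exp = int(comp.n_experimental.loc[site])
            if n_exp == 0:
                continue
            w = comp.accession_counts.loc[site].to_numpy(dtype=float) / n_exp
            geno = np.where(panel.genotypes == MISSING, np.nan, panel.genotypes)
            ph = np.nansum(geno * w[:, None], axis=0)
            p_hat[site] = pd.Series(ph, index=panel.snp_index())
            n_sample[site] = n_exp
        model = DriftScan.from_panel(
            panel, p_hat, n_sample, maf_floor=config.maf_floor, center=config.center_scan
        )
        try:
            scan_res = model.fit()
        except ValueError as err:
            # a flat slope can occur on tiny panels; fall back to sampling-only null
            _stage_log(stage, f"Ne estimation failed ({err}); using configured Ne")
            fallback = {
                s: float(config.sim.ne_per_site[s]) if config.sim else float("nan")
                for s in p_hat
            }
            scan_res = model.fit(ne=fallback)
        scan_res.write(out / "scan.tsv")
        manifest["stages"][stage] = {
            "n_snps": len(scan_res.table),
            "ne_estimates": {
                s: {"slope": e.slope, "ne": e.ne, "valid": e.valid, "n": e.n_sample}
                for s, e in scan_res.ne_estimates.items()
            },
        }

        # ---- stage: liability ----------------------------------------
        stage = "liability"
        if config.liability is not None:
            lb = dict(config.liability)
            if "survival_path" in lb:
                surv = pd.read_csv(lb["survival_path"], sep="\t",
                                   keep_default_na=False, na_values=[""])
                mild, harsh = lb["mild_site"], lb["harsh_site"]
                wide = surv.pivot(
                    index="accession", columns="site", values=["survived", "total"]
                )
                pairs = pd.DataFrame(
                    {
                        "survived_mild": wide[("survived", mild)],
                        "total_mild": wide[("total", mild)],
                        "p_mild": wide[("survived", mild)] / wide[("total", mild)],
                        "p_harsh": wide[("survived", harsh)] / wide[("total", harsh)],
                        "total_harsh": wide[("total", harsh)],
                    }
                ).dropna()
            else:
                rng = stage_rng(config.seed, "liability")
                n_acc = int(lb.get("n_accessions", panel.n_accessions))
                # accession liability means are widely dispersed so survival
                # probabilities span nearly the full unit interval, as
                # overwinter-survival distributions do across accessions
                mu = rng.normal(
                    lb.get("mu_mean", 0.0), lb.get("mu_sd", 2.0), size=n_acc
                )
                n_trials = int(lb.get("n_trials", 24))
                mild = simulate_survival(
                    mu, lb.get("tau_mild", 0.5), lb.get("sigma_mild", 1.2),
                    n_trials, seed=config.seed + 1,
                )
                harsh = simulate_survival(
                    mu, lb.get("tau_harsh", 0.0), lb.get("sigma_harsh", 1.0),
                    n_trials, seed=config.seed + 2,
                )
                pairs = pd.DataFrame(
                    {
                        "survived_mild": mild["survived"],
                        "total_mild": mild["total"],
                        "p_mild": mild["p_obs"],
                        "p_harsh": harsh["p_obs"],
                        "total_harsh": harsh["total"],
                    }
                )
            res = fit_liability(pairs, seed=config.seed)
            payload = {
                "alpha": res.alpha,
                "beta": res.beta,
                "se_alpha": float(res.bse[0]),
                "se_beta": float(res.bse[1]),
                "converged": res.converged,
                "n_obs": res.n_obs,
            }
            (out / "liability.json").write_text(json.dumps(payload, indent=2) + "\n")
            manifest["stages"][stage] = payload

        stage = "manifest"
        manifest_text = json.dumps(manifest, indent=2, sort_keys=True, default=str)
        (out / "manifest.json").write_text(manifest_text + "\n")
        return manifest
    except Exception as err:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {err}") from err


def _versions() -> dict[str, str]:
    import scipy
    import sklearn

    from . import __version__

    return {
        "sowselect": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "sklearn": sklearn.__version__,
    }
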