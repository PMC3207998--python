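"""Orchestration of the survey stages over an on-disk input bundle.

Stage order follows the data dependencies: seed-site scanning first, then
SNP intersection and created-site detection, then the independent density,
enrichment and F_ST analyses, and finally the fixture-table report.  Every
output file starts with a metadata comment line carrying the package
version, seed and thresholds, and reruns with an identical configuration
reproduce byte-identical bodies.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .creation import ProxyScoringParams, detect_created_sites, extract_window, write_cnm_hits
from .density import seed_average, window_density, write_profile
from .enrichment import (
    load_gwas_catalog,
    load_ld_table,
    merge_catalog_loci,
    observed_overlap,
    resample_null,
    tail_probability,
)
from .papertables import load_table1, load_table2, summarize_table1, summarize_table2
from .popgen import FstRecord, bin_counts, boxcox_fit, compare_groups, fst_many, fst_outliers
from .seedcore import read_bed, read_fasta, scan_utr, write_hits_bed
from .variants import (
    classify_disruption,
    read_vcf_snps,
    snp_in_site,
    summarize_by_seed_type,
    write_disruption_calls,
)

ALL_STAGES = ("scan", "intersect", "cnm", "density", "enrich", "fst", "report")


def _meta_line(config: PipelineConfig) -> str:
    t = (
        f"phastcons_min={config.phastcons_min} mirsvr_max={config.mirsvr_max} "
        f"r2_min={config.r2_min} maf_min={config.maf_min} score_min={config.score_min} "
        f"energy_max={config.energy_max} reps={config.reps} outlier_k={config.outlier_k}"
    )
    return f"# seedvar={__version__} seed={config.rng_seed} {t}\n"


def _prepend_meta(path, config: PipelineConfig) -> None:
    with open(path) as fh:
        body = fh.read()
    with open(path, "w") as fh:
        fh.write(_meta_line(config))
        fh.write(body)


def run_pipeline(config: PipelineConfig, stages: Optional[Iterable[str]] = None) -> dict:
    """Run the requested stages in dependency order; returns result summary.

    Raises before any stage runs if a referenced input is missing.
    """
    stages = set(ALL_STAGES if stages is None else stages)
    unknown = stages - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")

    need_seq = stages & {"scan", "intersect", "cnm", "density"}
    required = []
    if need_seq:
        required += [config.mirs_fasta, config.utrs_fasta, config.utrs_bed]
    if stages & {"intersect", "cnm", "density", "enrich"}:
        required.append(config.snps_vcf)
    if "enrich" in stages:
        required += [config.ld_tsv, config.catalog_tsv]
    if "fst" in stages:
        required.append(config.group_freqs_tsv)
    for path in required:
        if not path or not os.path.exists(path):
            raise FileNotFoundError(f"missing required input: {path!r}")

    os.makedirs(config.outdir, exist_ok=True)
    results: dict = {"version": __version__, "seed": config.rng_seed}

    mirs = utrs = placements = snps = None
    if need_seq:
        mir_seqs = read_fasta(config.mirs_fasta)
        from .seedcore import MicroRNA

        mirs = [MicroRNA(s.name, s) for s in mir_seqs]
        utrs = read_fasta(config.utrs_fasta)
        placements = read_bed(config.utrs_bed)
    if stages & {"intersect", "cnm", "density", "enrich"}:
        snps = read_vcf_snps(config.snps_vcf, pop_af_keys=config.pop_af_keys)

    sites = []
    if stages & {"scan", "intersect", "density"}:
        for utr in utrs:
            sites.extend(scan_utr(utr, mirs, placement=placements.get(utr.name)))
        if "scan" in stages:
            path = os.path.join(config.outdir, "sites.bed")
            write_hits_bed(sites, path)
            results["n_sites"] = len(sites)

    mress_snps: set[str] = set()
    if "intersect" in stages:
        utr_by_name = {u.name: u for u in utrs}
        mir_by_name = {m.name: m for m in mirs}
        calls = []
        for site in sites:
            for snp in snps:
                if snp_in_site(site, snp) is not None:
                    calls.append(
                        classify_disruption(
                            site, snp, mir_by_name[site.mir_name], utr_by_name[site.utr_name]
                        )
                    )
        path = os.path.join(config.outdir, "disruption_calls.tsv")
        write_disruption_calls(calls, path)
        _prepend_meta(path, config)
        mress_snps = {c.snp.rsid for c in calls if c.verdict in ("abolished", "downgraded")}
        results["n_disruption_calls"] = len(calls)
        results["disruptions_by_seed_type"] = dict(summarize_by_seed_type(calls))

    cnm_snps: set[str] = set()
    if "cnm" in stages:
        params = ProxyScoringParams(score_min=config.score_min, energy_max=config.energy_max)
        by_chrom: dict[str, list] = {}
        for utr in utrs:
            p = placements.get(utr.name)
            if p is not None:
                by_chrom.setdefault(p.chrom, []).append((utr, p))
        hits = []
        for snp in snps:
            for utr, p in by_chrom.get(snp.chrom, []):
                if p.start < snp.pos <= p.end:
                    window = extract_window(utr, snp, placement=p, flank=config.cnm_flank)
                    hits.extend(detect_created_sites(window, mirs, params))
        path = os.path.join(config.outdir, "cnm_hits.tsv")
        write_cnm_hits(hits, path)
        _prepend_meta(path, config)
        cnm_snps = {h.snp.rsid for h in hits}
        results["n_cnm_hits"] = len(hits)
        results["n_cnm_snps"] = len(cnm_snps)

    if "density" in stages:
        profile = window_density(sites, snps, window=config.window, flank=config.flank)
        path = os.path.join(config.outdir, "density.tsv")
        write_profile(profile, path)
        _prepend_meta(path, config)
        results["seed_average_density"] = seed_average(profile)

    if "enrich" in stages:
        catalog = load_gwas_catalog(config.catalog_tsv)
        ld = load_ld_table(config.ld_tsv)
        n_loci = merge_catalog_loci(catalog, ld, config.r2_min)
        overlap = observed_overlap(catalog, ld, mress_snps, cnm_snps, config.r2_min)
        null = resample_null(
            snps,
            mress_snps | cnm_snps,
            ld,
            n_draw=n_loci,
            reps=config.reps,
            maf_min=config.maf_min,
            rng_seed=config.rng_seed,
            r2_min=config.r2_min,
        )
        tail = tail_probability(null, overlap.n_total)
        blob = {
            "n_catalog_snps": len(catalog.snps),
            "n_loci": n_loci,
            "observed": {
                "mress": overlap.n_mress, "cnm": overlap.n_cnm, "total": overlap.n_total
            },
            "null_mean": null.mean,
            "null_sd": null.sd,
            "reps": null.reps,
            "n_draw": null.n_draw,
            "rng_seed": config.rng_seed,
            "z": tail.z,
            "p_normal": tail.p_normal,
            "p_empirical": tail.p_empirical,
            "thresholds": {"r2_min": config.r2_min, "maf_min": config.maf_min},
            "replicate_counts": null.replicate_counts.tolist(),
        }
        with open(os.path.join(config.outdir, "enrichment.json"), "w") as fh:
            json.dump(blob, fh, indent=1)
        results["enrichment"] = {k: blob[k] for k in ("observed", "null_mean", "null_sd", "p_empirical")}

    if "fst" in stages:
        gf = pd.read_csv(config.group_freqs_tsv, sep="\t")
        pivot_c = gf.pivot(index="rsid", columns="group", values="alt_count")
        pivot_n = gf.pivot(index="rsid", columns="group", values="n_alleles")
        theta = fst_many(pivot_c.to_numpy(float), pivot_n.to_numpy(float))
        mre_set = mress_snps | cnm_snps
        lam, transformed = boxcox_fit(theta)
        records = [
            FstRecord(rsid=r, fst=float(f), is_mre=r in mre_set, transformed=float(t))
            for r, f, t in zip(pivot_c.index, theta, transformed)
        ]
        mre_vals = [r.transformed for r in records if r.is_mre]
        other_vals = [r.transformed for r in records if not r.is_mre]
        summary = {"boxcox_lambda": lam, "n_mre": len(mre_vals), "n_other": len(other_vals)}
        if len(mre_vals) >= 2 and len(other_vals) >= 2:
            t_stat, p_val = compare_groups(mre_vals, other_vals)
            summary["t"] = t_stat
            summary["p"] = p_val
        mre_records = [r for r in records if r.is_mre]
        if len(mre_records) >= 2:
            outliers = fst_outliers(mre_records, k=config.outlier_k)
            summary["n_outliers"] = len(outliers)
            summary["outliers"] = [
                {"rsid": r.rsid, "fst": r.fst} for r in sorted(outliers, key=lambda x: -x.fst)
            ]
        path = os.path.join(config.outdir, "fst.tsv")
        with open(path, "w") as fh:
            fh.write("rsid\tfst\tis_mre\ttransformed\n")
            for r in records:
                fh.write(f"{r.rsid}\t{r.fst:.6g}\t{int(r.is_mre)}\t{r.transformed:.6g}\n")
        _prepend_meta(path, config)
        with open(os.path.join(config.outdir, "fst_summary.json"), "w") as fh:
            json.dump(summary, fh, indent=1)
        results["fst"] = {k: summary[k] for k in summary if k != "outliers"}

    if "report" in stages:
        s1 = summarize_table1(load_table1())
        s2 = summarize_table2(load_table2())
        report = {
            "table1": asdict(s1),
            "table2": asdict(s2),
        }
        with open(os.path.join(config.outdir, "paper_tables.json"), "w") as fh:
            json.dump(report, fh, indent=1)
        results["paper_tables"] = report

    return results
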