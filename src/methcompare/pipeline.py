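"""End-to-end study orchestration with config files and run manifests.

Two studies are wired here: the genome-wide concordance study (strand
collapse, per-CpG metrics, coverage filtering, beta-binomial
differential testing, cross-method concordance and motif/GC analyses)
and the loci-specific three-way study (reference rotation, signed
transcription coordinates, deep-coverage masking, per-method mean betas
and pairwise residual-versus-GC comparisons).

Configs are declarative YAML mappings; every emitted table carries the
seed and threshold set in '#'-prefixed header lines, and a run manifest
records versions, seeds and all thresholds, so re-running a config
reproduces outputs bit-exactly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, concordance, differential, loci, simulate
from .strand import collapse_strands

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {
    "min_cov": 5,
    "min_samples": 3,
    "delta_prefilter": 0.1,
    "concordance_threshold": 0.15,
    "window_flank": 50,
    "loci_min_cov": 50,
    "ont_low": 0.2,
    "ont_high": 0.8,
    "epic_alpha": 100.0,
    "alpha": 0.05,
    "pearson_sample_n": None,
}


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as handle:
            return yaml.safe_load(handle)
    return dict(config)


def _write_table(df: pd.DataFrame, path: Path, header: dict) -> None:
    with open(path, "w") as handle:
        for key, value in header.items():
            handle.write(f"# {key}={value}\n")
        df.to_csv(handle, sep="\t", index=False)


def _manifest(outdir: Path, config: dict, extras: dict) -> None:
    manifest = {
        "package_version": __version__,
        "config": config,
        **extras,
    }
    with open(outdir / "run_manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, default=str, sort_keys=True)


def _simulation_config(section: dict) -> simulate.SimulationConfig:
    mix = section.get("beta_mixture", {})
    return simulate.SimulationConfig(
        genome_length=int(section.get("genome_length", 100_000)),
        gc_profile=float(section.get("gc_fraction", 0.42)),
        n_cpg=int(section.get("n_cpg", 1000)),
        beta_mixture=simulate.BetaMixture(
            w_low=float(mix.get("w_low", 0.3)),
            low=tuple(mix.get("low", (1.0, 8.0))),
            high=tuple(mix.get("high", (8.0, 1.0))),
        ),
        n_replicates=int(section.get("n_replicates", 4)),
        seed=int(section["seed"]),
    )


def run_concordance_study(config, outdir: str | Path) -> dict:
    """Run the genome-wide cross-method concordance study.

    The config needs a ``simulation`` section (study conditions and
    seed) plus sample ``metadata`` (patient/visit labels for the
    replicates); thresholds default to the study's printed values.
    Returns a summary dict; tables land in ``outdir``.
    """
    config = _load_config(config)
    if "simulation" not in config:
        raise ValueError("config must name input tables or a simulation section")
    if "metadata" not in config:
        raise ValueError("config must carry sample metadata")
    thresholds = {**DEFAULT_THRESHOLDS, **config.get("thresholds", {})}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    sim_cfg = _simulation_config(config["simulation"])
    seed = sim_cfg.seed
    study = simulate.simulate_study(sim_cfg)
    header = {"seed": seed, **thresholds}

    metadata = config["metadata"]  # list of {patient, visit} per replicate
    if len(metadata) != sim_cfg.n_replicates:
        raise ValueError("metadata must describe every replicate")

    # per-sample strand collapse -> beta/coverage matrices
    collapsed: dict[str, list[pd.DataFrame]] = {}
    beta_cols, cov_cols, sample_meta = {}, {}, []
    for method, reports in study.short_reads.items():
        collapsed[method] = []
        for i, report in enumerate(reports):
            sites = collapse_strands(report)
            collapsed[method].append(sites)
            sid = f"{metadata[i]['patient']}{metadata[i]['visit']}-{method}"
            beta_cols[sid] = sites.set_index(["chrom", "pos"])["beta"]
            cov_cols[sid] = sites.set_index(["chrom", "pos"])["coverage"]
            sample_meta.append(
                {"sample_id": sid, "method": method, **metadata[i]}
            )
    beta = pd.DataFrame(beta_cols)
    cov = pd.DataFrame(cov_cols)

    # per-method coverage filter (min_cov x in min_samples of n)
    methods = pd.Series(
        [m["method"] for m in sample_meta],
        index=[m["sample_id"] for m in sample_meta],
    )
    kept = None
    for method in methods.unique():
        cols = methods.index[methods == method]
        idx = differential.coverage_filter(
            cov[cols], thresholds["min_cov"], thresholds["min_samples"]
        )
        kept = idx if kept is None else kept.intersection(idx)
    beta_f = beta.loc[kept].sort_index()
    cov_f = cov.loc[kept].sort_index()

    # differential EM-seq vs WGBS on the filtered positions
    groups = {}
    for method in ("EM-seq", "WGBS"):
        frames = collapsed[method]
        m = np.column_stack(
            [
                f.set_index(["chrom", "pos"])
                .loc[kept, ["n_meth_w", "n_meth_c"]]
                .sum(axis=1)
                for f in frames
            ]
        )
        n = np.column_stack(
            [f.set_index(["chrom", "pos"]).loc[kept, "coverage"] for f in frames]
        )
        groups[method] = (m, n)
    positions = pd.DataFrame(
        [{"chrom": c, "pos": p} for c, p in kept]
    )
    diff = differential.differential_test(
        *groups["EM-seq"], *groups["WGBS"],
        positions=positions,
        delta_prefilter=thresholds["delta_prefilter"],
        alpha=thresholds["alpha"],
    )
    _write_table(diff, outdir / "differential.tsv", header)

    # concordance statistics
    corr = concordance.pairwise_pearson(
        beta_f, n_sample=thresholds["pearson_sample_n"], seed=seed
    )
    _write_table(corr.reset_index(), outdir / "pearson.tsv", header)

    same_method = []
    labels = []
    cols = list(beta_f.columns)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            r = corr.iloc[i, j]
            if np.isnan(r):
                continue
            same_method.append(r)
            labels.append(
                "intra" if methods[cols[i]] == methods[cols[j]] else "inter"
            )
    ttest = None
    if len(set(labels)) == 2:
        ttest = concordance.grouped_correlation_ttest(same_method, labels)

    mean_beta = {}
    for method in methods.unique():
        mcols = methods.index[methods == method]
        mean_beta[method] = beta_f[mcols].mean(axis=1)
    mean_beta = pd.DataFrame(mean_beta)
    pct, n_complete = concordance.delta_beta_concordance(
        mean_beta["EM-seq"], mean_beta["WGBS"],
        thresholds["concordance_threshold"],
    )

    truth = study.truth_table().set_index(["chrom", "pos"])
    gc = truth.loc[kept, "window_gc"].to_numpy()
    resid = concordance.residual_vs_gc(
        mean_beta["WGBS"].to_numpy(), mean_beta["EM-seq"].to_numpy(), gc
    )
    _write_table(resid.binned, outdir / "residual_vs_gc.tsv", header)

    summary = {
        "seed": seed,
        "n_positions_simulated": int(sim_cfg.n_cpg),
        "n_positions_filtered": int(len(kept)),
        "n_significant": int(diff["significant"].sum()) if len(diff) else 0,
        "prefilter": diff.attrs.get("prefilter"),
        "concordance_pct": pct,
        "concordance_n": n_complete,
        "residual_slope": resid.slope,
        "intra_vs_inter_ttest": (
            {"t": ttest.t, "p": ttest.p, "means": ttest.group_means}
            if ttest
            else None
        ),
    }
    _manifest(outdir, config, {"summary": summary})
    logger.info("concordance study complete: %s", summary)
    return summary


def run_loci_study(config, outdir: str | Path) -> dict:
    """Run the loci-specific three-way study on a simulated GC-rich locus.

    Simulates a single-contig, GC-rich multicopy-locus readout for
    EM-seq, WGBS and ONT, expresses positions in signed transcription
    coordinates, applies the deep-coverage mask, and emits the three
    pairwise residual-versus-GC tables.
    """
    config = _load_config(config)
    if "simulation" not in config:
        raise ValueError("config must name a simulation section")
    thresholds = {**DEFAULT_THRESHOLDS, **config.get("thresholds", {})}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    section = dict(config["simulation"])
    upstream_len = int(section.pop("upstream_len", 1000))
    sim_cfg = _simulation_config({"gc_fraction": 0.72, "n_cpg": 300,
                                  "genome_length": 14_000, **section})
    if upstream_len >= sim_cfg.genome_length:
        raise ValueError("upstream_len exceeds the reference length")
    seed = sim_cfg.seed
    header = {"seed": seed, **thresholds}
    profiles = {
        "EM-seq": simulate.MethodProfile(
            name="EM-seq", base_coverage=900.0,
            gc_bias=simulate._emseq_gc_bias, coverage_dispersion=20.0,
        ),
        "WGBS": simulate.MethodProfile(
            name="WGBS", base_coverage=700.0,
            gc_bias=simulate._wgbs_gc_bias, recovery_bias=2.0,
            coverage_dispersion=20.0,
        ),
        "ONT": simulate.MethodProfile(
            name="ONT", base_coverage=600.0, coverage_dispersion=20.0,
        ),
    }
    study = simulate.simulate_study(sim_cfg, profiles=profiles)

    # per-method mean betas on the deep-coverage mask
    betas, coverages = {}, {}
    for method in ("EM-seq", "WGBS"):
        per_rep = []
        for report in study.short_reads[method]:
            sites = collapse_strands(report).set_index(["chrom", "pos"])
            per_rep.append(sites)
        cov = sum(s["coverage"] for s in per_rep)
        meth = sum(s["n_meth_w"] + s["n_meth_c"] for s in per_rep)
        betas[method] = (meth / cov.where(cov > 0)).rename(method)
        coverages[method] = cov
    ont_calls = []
    for sample in study.ont:
        calls = sample.groupby(["chrom", "pos"])["probability"].apply(
            lambda p: concordance.ont_call_beta(
                p.to_numpy(), thresholds["ont_low"], thresholds["ont_high"]
            )
        )
        ont_calls.append(calls)
    ont_beta = pd.Series(
        {
            key: np.nanmean([c[key].beta for c in ont_calls])
            for key in ont_calls[0].index
        },
        name="ONT",
    )
    ont_cov = pd.Series(
        {
            key: sum(
                c[key].n_meth + c[key].n_unmeth + c[key].n_undetermined
                for c in ont_calls
            )
            for key in ont_calls[0].index
        }
    )
    ont_beta.index = pd.MultiIndex.from_tuples(ont_beta.index,
                                               names=["chrom", "pos"])
    ont_cov.index = ont_beta.index
    betas["ONT"] = ont_beta
    coverages["ONT"] = ont_cov

    mean_beta = pd.DataFrame(betas)
    cov_frame = pd.DataFrame(coverages)
    min_cov = cov_frame.min(axis=1)
    masked = mean_beta[min_cov >= thresholds["loci_min_cov"]]
    n_removed = int((min_cov < thresholds["loci_min_cov"]).sum())
    if masked.empty:
        logger.warning("all sites fell below the %dx coverage mask",
                       thresholds["loci_min_cov"])

    truth = study.truth_table().set_index(["chrom", "pos"])
    gc = truth.loc[masked.index, "window_gc"].to_numpy()
    tx_pos = loci.to_transcription_coords(
        masked.index.get_level_values("pos").to_numpy(), upstream_len
    )

    pairs = [("WGBS", "EM-seq"), ("ONT", "EM-seq"), ("ONT", "WGBS")]
    slopes = {}
    for a, b in pairs:
        av, bv = masked[a].to_numpy(), masked[b].to_numpy()
        ok = ~np.isnan(av) & ~np.isnan(bv) & ~np.isnan(gc)
        fit = concordance.residual_vs_gc(av, bv, gc)
        slopes[f"{a}_vs_{b}"] = fit.slope
        table = pd.DataFrame(
            {"tx_pos": tx_pos[ok], "gc": fit.gc, "residual": fit.residuals}
        )
        _write_table(table, outdir / f"residual_{a}_vs_{b}.tsv", header)

    summary = {
        "seed": seed,
        "n_sites": int(len(mean_beta)),
        "n_masked_out": n_removed,
        "n_retained": int(len(masked)),
        "mean_coverage": {m: float(cov_frame[m].mean()) for m in cov_frame},
        "residual_slopes": slopes,
    }
    _manifest(outdir, config, {"summary": summary})
    logger.info("loci study complete: %s", summary)
    return summary
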