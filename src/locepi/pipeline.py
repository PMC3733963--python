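"""End-to-end orchestration: simulate -> QC -> GWAS -> scan -> local pairs.

``run_all`` wires the stages in order, writes every stage output as TSV (or
PLINK text) under one output directory, and records a manifest (config
snapshot, per-stage seeds, output checksums, timings) so a run can be
reproduced bit-for-bit from its manifest.  ``downsample_experiment``
re-runs the pairwise scan on random subsets of samples and/or SNPs to
measure how retained-pair and local-pair counts scale with panel density.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import association, epistasis_scan, io, local_interactions, qc_preprocess
from ._anova import all_pairs_scan
from .synthetic_data import (
    GenotypeDataset,
    PhenoModelSpec,
    fig2_block,
    simulate_genotypes,
    simulate_phenotype,
    unlinked_blocks,
)

__all__ = ["RunManifest", "substream", "run_all", "downsample_experiment", "default_config"]


def substream(seed: int, name: str) -> int:
    """Deterministic per-stage seed derived from one global seed."""
    return int(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]).generate_state(1)[0]
        % 2**31
    )


@dataclass
class RunManifest:
    config: dict
    seeds: dict[str, int] = field(default_factory=dict)
    checksums: dict[str, str] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "seeds": self.seeds,
                    "checksums": self.checksums,
                    "timings": self.timings,
                },
                fh,
                indent=2,
                default=str,
            )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def default_config(seed: int = 1) -> dict:
    """A small but complete study configuration."""
    return {
        "seed": seed,
        "simulate": {
            "n_samples": 1000,
            "n_null_snps": 120,
            "null_maf": 0.3,
            "fig2": {"enabled": True, "chromosome": 11, "start_pos": 116_500_000,
                     "snp_spacing": 45_000, "effect": 2.0},
            "noise_sd": 1.0,
            "missing_rate": 0.0,
        },
        "phenotype": {"n_pcs": 5},
        "scan": {"retain": 1e-5},
        "local": {"max_dist": 1_000_000, "p_cut": 1e-5},
    }


def _build_blocks(sim_cfg: dict) -> list:
    n_null = int(sim_cfg.get("n_null_snps", 100))
    per_chrom = max(n_null // 4, 1)
    blocks = []
    placed = 0
    for chrom in (1, 2, 3, 4):
        take = min(per_chrom, n_null - placed) if chrom < 4 else n_null - placed
        if take > 0:
            blocks.extend(
                unlinked_blocks(take, maf=sim_cfg.get("null_maf", 0.3), chromosome=chrom)
            )
            placed += take
    fig2 = sim_cfg.get("fig2", {})
    if fig2.get("enabled", False):
        blocks.append(
            fig2_block(
                chromosome=fig2.get("chromosome", 11),
                start_pos=fig2.get("start_pos", 116_500_000),
                snp_spacing=fig2.get("snp_spacing", 45_000),
            )
        )
    return blocks


def run_all(config: dict, out_dir: str) -> RunManifest:
    """Run the full study described by ``config``; write outputs + manifest."""
    if not config or "seed" not in config or "simulate" not in config:
        raise ValueError("config must at least provide 'seed' and 'simulate' sections")
    os.makedirs(out_dir, exist_ok=True)
    manifest = RunManifest(config=config)
    seed = int(config["seed"])
    sim_cfg = config["simulate"]

    t0 = time.perf_counter()
    blocks = _build_blocks(sim_cfg)
    geno = simulate_genotypes(
        blocks,
        n_samples=int(sim_cfg.get("n_samples", 1000)),
        seed=substream(seed, "genotypes"),
        missing_rate=float(sim_cfg.get("missing_rate", 0.0)),
    )
    fig2_cfg = sim_cfg.get("fig2", {})
    spec = PhenoModelSpec(
        causal_haplotype_effect=float(fig2_cfg.get("effect", 0.0)) if fig2_cfg.get("enabled") else 0.0,
        noise_sd=float(sim_cfg.get("noise_sd", 1.0)),
    )
    pheno, _truth = simulate_phenotype(geno, spec, seed=substream(seed, "phenotype"))
    manifest.seeds = {
        "genotypes": substream(seed, "genotypes"),
        "phenotype": substream(seed, "phenotype"),
    }
    paths = io.write_plink_text(geno, pheno, out_dir, basename="simulated")
    manifest.timings["simulate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    clean, report = qc_preprocess.qc_filter(geno)
    report_path = os.path.join(out_dir, "qc_report.tsv")
    report.to_frame().to_csv(report_path, sep="\t", index=False)
    paths["qc_report"] = report_path
    manifest.timings["qc"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    prepared, h2, h2_se = qc_preprocess.prepare_phenotype(
        pheno, clean, n_pcs=int(config.get("phenotype", {}).get("n_pcs", 10))
    )
    pheno_path = os.path.join(out_dir, "phenotype_prepared.tsv")
    io.write_pheno_tsv(prepared, pheno_path)
    paths["phenotype"] = pheno_path
    residuals = prepared["residual"].to_numpy()
    manifest.timings["phenotype"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    gwas = association.single_snp_scan(residuals, clean)
    gwas["lambda"] = association.inflation_factor(gwas)
    gwas_path = os.path.join(out_dir, "gwas.tsv")
    gwas.to_csv(gwas_path, sep="\t", index=False, float_format="%.8g")
    paths["gwas"] = gwas_path
    marg = association.marginal_set(gwas)
    manifest.timings["gwas"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    retain = float(config.get("scan", {}).get("retain", 1e-5))
    results, thresholds = epistasis_scan.pairwise_scan(residuals, clean, marg, retain=retain)
    scan_frame = epistasis_scan.results_to_frame(results, clean, thresholds)
    scan_path = os.path.join(out_dir, "episcan.tsv")
    scan_frame.to_csv(scan_path, sep="\t", index=False, float_format="%.8g")
    paths["episcan"] = scan_path
    manifest.timings["episcan"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    loc_cfg = config.get("local", {})
    local = local_interactions.extract_local(
        results,
        clean,
        max_dist=int(loc_cfg.get("max_dist", 1_000_000)),
        p_cut=float(loc_cfg.get("p_cut", 1e-5)),
    )
    local_frame = local_interactions.local_pairs_to_frame(local, clean)
    local_path = os.path.join(out_dir, "local_pairs.tsv")
    local_frame.to_csv(local_path, sep="\t", index=False, float_format="%.8g")
    paths["local"] = local_path
    manifest.timings["local"] = time.perf_counter() - t0

    summary = pd.DataFrame(
        [
            ("n_samples_post_qc", clean.n_samples),
            ("n_snps_post_qc", clean.n_snps),
            ("k_marginal", len(marg)),
            ("h2", h2),
            ("h2_se", h2_se),
            ("t_full", thresholds.t_full),
            ("t_marginal", thresholds.t_marginal),
            ("n_retained_pairs", len(results)),
            ("n_local_pairs", len(local)),
        ],
        columns=["quantity", "value"],
    )
    summary_path = os.path.join(out_dir, "summary.tsv")
    summary.to_csv(summary_path, sep="\t", index=False)
    paths["summary"] = summary_path

    manifest.checksums = {name: _sha256(p) for name, p in sorted(paths.items())}
    manifest.write(os.path.join(out_dir, "manifest.json"))
    return manifest


def _count_pairs(
    residuals: np.ndarray,
    geno: GenotypeDataset,
    count_threshold: float,
    local_p: float,
    max_dist: int,
) -> tuple[int, int]:
    scan = all_pairs_scan(residuals, geno.dosages)
    below = int((scan["p"] < count_threshold).sum())
    chrom = geno.snp_map["chrom"].to_numpy()
    pos = geno.snp_map["pos"].to_numpy()
    same = chrom[scan["ii"]] == chrom[scan["jj"]]
    dist = np.abs(pos[scan["jj"]] - pos[scan["ii"]])
    local = int(((scan["p"] < local_p) & same & (dist < max_dist)).sum())
    return below, local


def downsample_experiment(
    geno: GenotypeDataset,
    residuals: np.ndarray,
    frac_samples: float = 1.0,
    frac_snps: float = 1.0,
    seed: int = 0,
    count_threshold: float = association.GWAS_CONSENSUS_P,
    local_p: float = 1e-5,
    max_dist: int = 1_000_000,
) -> pd.DataFrame:
    """Scan the full data and a random subsample; compare pair counts.

    Reports, for each of the full data and the subsample, the number of
    pairs with P_int below ``count_threshold`` and the number of local
    pairs (same chromosome, < ``max_dist``, P_int < ``local_p``).  With
    null SNPs and no sample reduction, the count ratio is expected to
    scale as frac_snps^2 (the fraction of surviving pairs).
    """
    for frac in (frac_samples, frac_snps):
        if not 0 < frac <= 1:
            raise ValueError("fractions must be in (0, 1]")
    y = np.asarray(residuals, dtype=float)
    below_full, local_full = _count_pairs(y, geno, count_threshold, local_p, max_dist)

    rng = np.random.default_rng(seed)
    n_s = max(int(round(frac_samples * geno.n_samples)), 2)
    n_m = max(int(round(frac_snps * geno.n_snps)), 2)
    sample_idx = np.sort(rng.choice(geno.n_samples, size=n_s, replace=False))
    snp_idx = np.sort(rng.choice(geno.n_snps, size=n_m, replace=False))
    sub = geno.subset(sample_idx, snp_idx)
    below_sub, local_sub = _count_pairs(y[sample_idx], sub, count_threshold, local_p, max_dist)

    return pd.DataFrame(
        {
            "dataset": ["full", "subsample"],
            "n_samples": [geno.n_samples, sub.n_samples],
            "n_snps": [geno.n_snps, sub.n_snps],
            "pairs_below_threshold": [below_full, below_sub],
            "local_pairs": [local_full, local_sub],
        }
    )
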