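"""End-to-end discovery and validation pipelines.

Discovery: ingest (or simulate) genotypes and traits -> QC -> impute/center ->
segment -> fit the multitrait spike-and-slab model per segment -> LD windows
-> per-window (co)variance posteriors -> significant-window loci -> reports.

Every segment's chain seed derives from the global seed plus the segment's
(chromosome, core start) through a stable hash, so adding or removing
segments never perturbs another segment's draws and serial and per-segment
parallel runs agree.

Validation re-fits the model on a second cohort but evaluates (co)variances
on the FROZEN window member sets exported by a discovery run, then reports
which discovery-significant windows replicate (significant, same sign).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as pio
from .io import GenotypePanel, TraitTable, impute_center, preadjust_traits, qc_filter
from .localcov import (
    merge_significant_windows,
    summarize_window,
    window_cov_draws,
    write_results,
)
from .model import MTModelConfig, MTPosterior, fit_segment
from .segmentation import make_segments, segments_to_table
from .simulate import SimConfig, simulate_genotypes, simulate_traits
from .windows import enumerate_windows

logger = logging.getLogger("pleiocov")

__all__ = ["PipelineConfig", "run_discovery", "run_validation",
           "rerun_local_cov", "segment_seed"]


def segment_seed(global_seed: int, chromosome: int, core_start: int) -> int:
    """Stable child seed for one segment's chain, below 2**31."""
    h = hashlib.blake2b(
        f"{global_seed}:{chromosome}:{core_start}".encode(), digest_size=4
    ).digest()
    return int.from_bytes(h, "little") % (2 ** 31)


@dataclass
class PipelineConfig:
    """Either ``simulate`` or the three input paths must be given, not both."""

    simulate: SimConfig | None = None
    genotypes: str | None = None          # PLINK prefix
    phenotypes: str | None = None         # TSV: iid + two trait columns
    covariates: str | None = None         # TSV: iid + covariate columns
    trait_columns: tuple = ("trait1", "trait2")
    log_transform: bool = True
    maf_min: float = 0.01
    miss_max: float = 0.05
    core_size: int = 1000
    flank_size: int = 250
    ld_threshold: float = 0.1
    cr_level: float = 0.95
    model: MTModelConfig = field(default_factory=MTModelConfig)
    scale: float = 1e4
    outdir: str = "pleiocov_out"
    rng_seed: int = 0
    save_posteriors: bool = True

    def __post_init__(self):
        has_files = self.genotypes is not None
        if has_files == (self.simulate is not None):
            raise ValueError("exactly one of (genotypes paths, simulate) must be set")
        if isinstance(self.simulate, dict):
            self.simulate = SimConfig(**self.simulate)
        if isinstance(self.model, dict):
            self.model = MTModelConfig(**self.model)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = {
            "genotypes": self.genotypes, "phenotypes": self.phenotypes,
            "covariates": self.covariates, "trait_columns": list(self.trait_columns),
            "log_transform": self.log_transform,
            "maf_min": self.maf_min, "miss_max": self.miss_max,
            "core_size": self.core_size, "flank_size": self.flank_size,
            "ld_threshold": self.ld_threshold, "cr_level": self.cr_level,
            "scale": self.scale, "outdir": str(self.outdir),
            "rng_seed": self.rng_seed,
            "model": {
                "n_iter": self.model.n_iter, "burn_in": self.model.burn_in,
                "thin": self.model.thin, "R_df": self.model.R_df,
                "Sigma_df": self.model.Sigma_df,
                "pi_a": self.model.pi_a, "pi_b": self.model.pi_b,
            },
            "dosage_coding": "count of A1 allele, mean-imputed, centered, "
                             "not variance-standardized",
        }
        if self.simulate is not None:
            s = self.simulate
            d["simulate"] = {
                "n_individuals": s.n_individuals, "n_snps": s.n_snps,
                "block_lengths": list(s.block_lengths),
                "within_block_rho": s.within_block_rho,
                "maf_range": list(s.maf_range),
                "R_true": np.asarray(s.R_true).tolist(),
                "rng_seed": s.rng_seed,
                "causal_blocks": [
                    {"block": cb.block, "sigma_loc": cb.sigma_loc.tolist(),
                     "n_causal": cb.n_causal}
                    for cb in s.causal_blocks
                ],
            }
        return d


def _load_inputs(config: PipelineConfig):
    if config.simulate is not None:
        panel = simulate_genotypes(config.simulate)
        traits, truth = simulate_traits(panel, config.simulate)
        return panel, traits, truth
    panel = pio.read_plink(config.genotypes)
    pheno = pio.read_trait_table(config.phenotypes)
    tables = [pheno]
    cov = None
    if config.covariates is not None:
        cov = pio.read_trait_table(config.covariates)
        tables.append(cov)
    panel, *tables = pio.align_samples(panel, *tables)
    logger.info("aligned cohort: n=%d", panel.n_individuals)
    raw = tables[0][list(config.trait_columns)].to_numpy(dtype=float)
    covmat = tables[1].to_numpy(dtype=float) if cov is not None else None
    covnames = list(tables[1].columns) if cov is not None else None
    traits = preadjust_traits(
        raw, covmat, trait_names=config.trait_columns,
        log_transform=config.log_transform, covariate_names=covnames,
    )
    return panel, traits, None


def _fit_all_segments(X, Y, segments, config: PipelineConfig, posterior_dir=None):
    posteriors = []
    for i, seg in enumerate(segments):
        seed = segment_seed(config.rng_seed, seg.chromosome, seg.core[0])
        mcfg = MTModelConfig(
            n_iter=config.model.n_iter, burn_in=config.model.burn_in,
            thin=config.model.thin, R_df=config.model.R_df,
            R_scale=config.model.R_scale, Sigma_df=config.model.Sigma_df,
            Sigma_scale=config.model.Sigma_scale,
            pi_a=config.model.pi_a, pi_b=config.model.pi_b, rng_seed=seed,
        )
        t0 = time.perf_counter()
        post = fit_segment(X[:, seg.start:seg.stop], Y, mcfg, segment=seg)
        logger.info(
            "segment %d chrom=%d core=[%d,%d) m=%d: fit in %.1fs, "
            "mean pi=(%.4f, %.4f)",
            i, seg.chromosome, seg.core[0], seg.core[1], seg.stop - seg.start,
            time.perf_counter() - t0,
            post.pi_draws[:, 0].mean(), post.pi_draws[:, 1].mean(),
        )
        if posterior_dir is not None:
            post.save(posterior_dir / f"segment_{i:04d}.npz")
        posteriors.append(post)
    return posteriors


def _window_estimates(X, windows, segments, posteriors, level):
    seg_index = {id(s): i for i, s in enumerate(segments)}
    estimates = []
    for w in windows:
        si = seg_index[id(w.segment)]
        seg = segments[si]
        mem = w.member_indices
        local = mem - seg.start
        draws = window_cov_draws(X[:, mem], posteriors[si].beta_draws[:, local, :])
        estimates.append(summarize_window(w, draws, level=level))
    return estimates


def _write_members(estimates, panel, path):
    snp = panel.snp_map["snp"]
    with open(path, "w") as fh:
        fh.write("window_id\tseed_snp\tsignificant\tcov_sign\tmembers\n")
        for e in estimates:
            mem = e.window.member_indices
            ids = ",".join(snp.iat[int(j)] for j in mem)
            sign = int(np.sign(e.post_mean["Cov"]))
            fh.write(
                f"win_{mem[0]}_{mem[-1]}\t{snp.iat[int(e.window.seed_index)]}\t"
                f"{int(e.significant)}\t{sign}\t{ids}\n"
            )


def run_discovery(config: PipelineConfig) -> dict:
    """Run the full discovery pipeline; returns a result bundle dict with the
    output paths, the manifest, and the in-memory estimates."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict()}

    panel, traits, truth = _load_inputs(config)
    manifest["n_individuals"] = panel.n_individuals
    manifest["n_snps_input"] = panel.n_snps
    panel, n_kept, n_dropped = qc_filter(panel, config.maf_min, config.miss_max)
    manifest["n_snps_kept"] = n_kept
    manifest["n_snps_dropped"] = n_dropped
    logger.info("QC: kept %d SNPs, dropped %d", n_kept, n_dropped)

    X = impute_center(panel)
    Y = traits.values
    segments = make_segments(panel, config.core_size, config.flank_size)
    manifest["n_segments"] = len(segments)
    segments_to_table(segments, panel).to_csv(
        outdir / "segments.tsv", sep="\t", index=False
    )

    posterior_dir = None
    if config.save_posteriors:
        posterior_dir = outdir / "posteriors"
        posterior_dir.mkdir(exist_ok=True)
    posteriors = _fit_all_segments(X, Y, segments, config, posterior_dir)

    windows, n_raw = enumerate_windows(X, segments, config.ld_threshold)
    manifest["n_windows_raw"] = n_raw
    manifest["n_windows_dedup"] = len(windows)
    logger.info("windows: %d raw -> %d after dedup", n_raw, len(windows))

    estimates = _window_estimates(X, windows, segments, posteriors, config.cr_level)
    significant = [e for e in estimates if e.significant]
    loci = merge_significant_windows(significant, panel=panel)
    manifest["n_windows_significant"] = len(significant)
    manifest["n_loci"] = len(loci)

    paths = write_results(estimates, loci, panel, outdir, scale=config.scale)
    _write_members(estimates, panel, outdir / "windows_members.tsv")
    paths["members"] = outdir / "windows_members.tsv"
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    paths["manifest"] = outdir / "manifest.json"

    assert manifest["n_windows_significant"] <= manifest["n_windows_dedup"] <= n_raw
    return {
        "paths": paths, "manifest": manifest, "panel": panel, "traits": traits,
        "truth": truth, "segments": segments, "windows": windows,
        "estimates": estimates, "loci": loci, "posteriors": posteriors,
    }


def rerun_local_cov(config: PipelineConfig) -> dict:
    """Recompute the windows report from the posteriors persisted by a prior
    :func:`run_discovery` with the same config; bit-identical output."""
    outdir = Path(config.outdir)
    panel, traits, _ = _load_inputs(config)
    panel, _, _ = qc_filter(panel, config.maf_min, config.miss_max)
    X = impute_center(panel)
    segments = make_segments(panel, config.core_size, config.flank_size)
    posteriors = [
        MTPosterior.load(outdir / "posteriors" / f"segment_{i:04d}.npz")
        for i in range(len(segments))
    ]
    for post, seg in zip(posteriors, segments):
        post.segment = seg
    windows, _ = enumerate_windows(X, segments, config.ld_threshold)
    estimates = _window_estimates(X, windows, segments, posteriors, config.cr_level)
    significant = [e for e in estimates if e.significant]
    loci = merge_significant_windows(significant, panel=panel)
    paths = write_results(estimates, loci, panel, outdir, scale=config.scale)
    return {"paths": paths, "estimates": estimates, "loci": loci}


def run_validation(config: PipelineConfig, frozen_windows: str | Path) -> dict:
    """Validation re-run: fit the model on the validation cohort, evaluate
    (co)variances on the frozen discovery window member sets, and report which
    discovery-significant windows replicate."""
    import pandas as pd

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frozen = pd.read_csv(frozen_windows, sep="\t", dtype=str)

    panel, traits, _ = _load_inputs(config)
    panel, _, _ = qc_filter(panel, config.maf_min, config.miss_max)
    X = impute_center(panel)
    Y = traits.values
    segments = make_segments(panel, config.core_size, config.flank_size)
    posteriors = _fit_all_segments(X, Y, segments, config, None)

    snp_to_idx = {s: j for j, s in enumerate(panel.snp_map["snp"])}
    records = []
    unknown = []
    for _, row in frozen.iterrows():
        members = row["members"].split(",")
        missing = [s for s in members if s not in snp_to_idx]
        if missing:
            unknown.extend(missing)
            continue
        idx = np.array(sorted(snp_to_idx[s] for s in members))
        seg_i = next(
            (i for i, s in enumerate(segments)
             if s.start <= idx[0] and idx[-1] < s.stop),
            None,
        )
        if seg_i is None:
            raise ValueError(
                f"frozen window {row['window_id']} does not fit inside any "
                "validation segment"
            )
        seg = segments[seg_i]
        draws = window_cov_draws(
            X[:, idx], posteriors[seg_i].beta_draws[:, idx - seg.start, :]
        )
        from .windows import LDWindow

        w = LDWindow(seed_index=int(idx[0]), member_indices=idx, segment=seg)
        est = summarize_window(w, draws, level=config.cr_level)
        sign = int(np.sign(est.post_mean["Cov"]))
        disc_sig = int(row["significant"]) == 1
        disc_sign = int(row["cov_sign"])
        records.append(
            {
                "window_id": row["window_id"],
                "discovery_significant": int(disc_sig),
                "discovery_sign": disc_sign,
                "validation_significant": int(est.significant),
                "validation_sign": sign,
                "replicated": int(disc_sig and est.significant and sign == disc_sign),
                "cov_mean_scaled": est.post_mean["Cov"] * config.scale,
                "cov_cr_low_scaled": est.cr_low["Cov"] * config.scale,
                "cov_cr_high_scaled": est.cr_high["Cov"] * config.scale,
            }
        )
    if unknown:
        raise ValueError(
            f"frozen windows reference {len(set(unknown))} SNPs absent from the "
            f"validation panel, e.g. {sorted(set(unknown))[:5]}"
        )
    rep = pd.DataFrame(records)
    rep_path = outdir / "validation_windows.tsv"
    rep.to_csv(rep_path, sep="\t", index=False)
    n_disc = int(rep["discovery_significant"].sum()) if len(rep) else 0
    n_repl = int(rep["replicated"].sum()) if len(rep) else 0
    logger.info("validation: %d/%d discovery-significant windows replicated",
                n_repl, n_disc)
    return {"table": rep, "path": rep_path,
            "n_discovery_significant": n_disc, "n_replicated": n_repl}
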