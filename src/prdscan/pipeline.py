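"""End-to-end orchestration: simulate -> aggregate -> toxicity -> features
-> epistasis -> structure, driven by one validated configuration.

The pipeline is deterministic given the configured seed: per-stage seeds
are spawned from it, every output table records it, and re-running a
stage from cached upstream outputs reproduces downstream results
exactly.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import variant_table as vt
from . import toxicity as tx
from . import landscape_features as lf
from . import epistasis_structure as es
from .design import LibraryDesign, tdp43_library, read_wt_fasta

__all__ = ["RunConfig", "validate_config", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    """Validated parameters for one pipeline run.

    Defaults reproduce the packaged TDP-43 prion-like-domain layout:
    sub-library 290-331, 1.59% doping, three replicates with two output
    cultures each, 5-6 generations of selection.
    """

    outdir: str = "prdscan_run"
    seed: int = 0
    # inputs: either simulate, or read a counts TSV
    simulate: bool = True
    counts_path: str | None = None
    wt_fasta: str | None = None
    library: str = "290-331"
    region_start: int | None = None
    region_end: int | None = None
    # simulation parameters
    doping_rate: float = 0.0159
    n_molecules: int = 150_000
    depth: float = 2_000_000
    generations: tuple[float, ...] = (5.0, 5.5, 6.0)
    per_base_misread_rate: float = 1e-4
    replicate_noise_sd: float = 0.01
    hotspot_true: tuple[int, int] | None = (312, 342)
    planted_elements: list = field(default_factory=list)  # [{element, start, end, strength}]
    # analysis parameters
    min_mean_input: float = 10.0
    fdr: float = 0.05
    loess_span: float = 0.3
    property_matrix: str | None = None
    k_neighbors: int = 1000
    range_limit_fraction: float = 0.1
    n_randomizations: int = 1000
    pdb_path: str | None = None
    pdb_chain: str = "A"
    larks_range: tuple[int, int] | None = None

    def design(self) -> LibraryDesign:
        if self.wt_fasta:
            if self.region_start is None or self.region_end is None:
                raise ValueError("wt_fasta requires region_start/region_end")
            d = read_wt_fasta(self.wt_fasta, self.region_start, self.region_end)
        else:
            d = tdp43_library(self.library)
        return d.with_(
            doping_rate=self.doping_rate,
            generations=tuple(self.generations),
            n_replicates=len(self.generations),
            per_base_misread_rate=self.per_base_misread_rate,
        )


def load_config(path) -> RunConfig:
    """Read a YAML config file into a :class:`RunConfig`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("generations", "hotspot_true", "larks_range"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def validate_config(config: RunConfig) -> list[str]:
    """Collect all validation errors (empty list means the config is ok)."""
    errors: list[str] = []
    if not 0.0 <= config.doping_rate < 1.0:
        errors.append(f"doping_rate must be in [0, 1): {config.doping_rate}")
    if not 0.0 <= config.per_base_misread_rate < 1.0:
        errors.append(
            f"per_base_misread_rate must be in [0, 1): {config.per_base_misread_rate}"
        )
    if not 0.0 < config.fdr < 1.0:
        errors.append(f"fdr must be in (0, 1): {config.fdr}")
    if not 0.0 < config.loess_span <= 1.0:
        errors.append(f"loess_span must be in (0, 1]: {config.loess_span}")
    if config.n_molecules <= 0:
        errors.append("n_molecules must be positive")
    if config.depth <= 0:
        errors.append("depth must be positive")
    if any(g <= 0 for g in config.generations):
        errors.append("generations must be positive")
    if config.n_randomizations < 100:
        errors.append("n_randomizations must be at least 100")
    if config.k_neighbors < 10:
        errors.append("k_neighbors must be at least 10")
    if not 0.0 <= config.range_limit_fraction < 0.5:
        errors.append("range_limit_fraction must be in [0, 0.5)")
    if config.region_start is not None and config.region_end is not None:
        if not config.region_start < config.region_end:
            errors.append("region_end must exceed region_start")
    elif not config.wt_fasta and config.library not in ("290-331", "332-373"):
        errors.append(f"unknown library {config.library!r}")
    for key in ("counts_path", "wt_fasta", "property_matrix", "pdb_path"):
        path = getattr(config, key)
        if path is not None and not Path(path).exists():
            errors.append(f"{key}: file not found: {path}")
    if not config.simulate and not config.counts_path:
        errors.append("either simulate: true or a counts_path is required")
    for el in config.planted_elements:
        if el.get("element") not in ("helix", "strand"):
            errors.append(f"planted element must be helix or strand: {el}")
    return errors


def _write(df: pd.DataFrame, path: Path, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed: {seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write per-stage outputs plus a report.

    Returns a summary dict (also written as ``report.json``); the human-
    readable report lands in ``report.md``. Raises on the first failing
    stage, naming it.
    """
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = config.design()
    summary: dict = {"seed": config.seed, "stages": {}}
    t_start = time.time()

    stage = "simulate"
    try:
        if config.simulate:
            from . import synthetic_data as sd

            landscape = sd.make_landscape(
                design, seed=config.seed, hotspot=config.hotspot_true
            )
            for el in config.planted_elements:
                landscape = sd.plant_epistatic_structure(
                    landscape,
                    el["element"],
                    (el["start"], el["end"]),
                    el.get("strength", -0.4),
                )
            counts = sd.simulate_experiment(
                design,
                landscape,
                n_molecules=config.n_molecules,
                depth=config.depth,
                seed=config.seed,
                replicate_noise_sd=config.replicate_noise_sd,
            )
            vt.write_counts_tsv(counts, outdir / "counts.tsv", design)
        else:
            counts = vt.read_counts_tsv(config.counts_path)
        summary["stages"][stage] = {"n_nt_variants": int(len(counts))}

        stage = "aggregate"
        counts = vt.correct_misread_inflow(counts, design)
        records = vt.translate_and_aggregate(counts, design)
        records, filter_log = vt.filter_variants(
            records, min_mean_input=config.min_mean_input
        )
        with open(outdir / "filter_log.json", "w") as fh:
            json.dump(filter_log, fh, indent=2)
        summary["stages"][stage] = filter_log

        stage = "toxicity"
        est, tox_log = tx.estimate_toxicity(records, design)
        merged = tx.merge_and_normalize([est])
        merged["class_vs_wt"] = tx.classify_vs_wt(merged, fdr=config.fdr)
        out_cols = [
            c
            for c in merged.columns
            if c == "aa_seq"
            or c.startswith(("tox_rep", "err_rep"))
            or c
            in (
                "n_aa_mut", "is_wt", "is_silent", "is_stop",
                "toxicity", "sigma", "bayes_corrected", "mean_input",
                "class_vs_wt",
            )
        ]
        _write(merged[out_cols], outdir / "toxicity.tsv", config.seed)
        counts_by_class = merged["class_vs_wt"].value_counts().to_dict()
        summary["stages"][stage] = {
            "eps_r": tox_log["error_model"].eps_r,
            "n_variants": int(len(merged)),
            "classification": {k: int(v) for k, v in counts_by_class.items()},
        }

        stage = "features"
        singles = merged[
            (merged["n_aa_mut"] == 1) & ~merged["is_stop"]
        ].reset_index(drop=True)
        profile = lf.per_position_profile(singles, span=config.loess_span)
        hotspot = lf.detect_hotspot(profile)
        _write(profile.table, outdir / "position_profile.tsv", config.seed)
        pcs = lf.build_property_pcs(lf.load_property_matrix(config.property_matrix))
        fits = {}
        if hotspot is not None:
            sub = merged[
                (merged["n_aa_mut"] >= 1)
                & ~merged["is_stop"]
                & merged["toxicity"].notna()
            ].reset_index(drop=True)
            feat = np.array(
                [
                    lf.variant_feature_value(m, pcs.feature("PC1"))
                    for m in sub["mutations"]
                ]
            )
            for mode in ("all", "inside", "outside", "interaction"):
                try:
                    fit = lf.fit_toxicity_model(sub, feat, mode, hotspot=hotspot)
                    fits[mode] = {"r_squared": fit["r_squared"], "n": fit["n"]}
                except ValueError:
                    fits[mode] = None
        summary["stages"][stage] = {
            "hotspot": list(hotspot) if hotspot else None,
            "pc1_variance_ratio": float(pcs.explained_variance_ratio[0]),
            "r_squared_pc1": fits,
        }

        stage = "epistasis"
        # condition the expected-toxicity surface on the *final* merged
        # single-mutant toxicities (same scale as the doubles)
        single_map = {
            m[0]: t
            for m, t in zip(singles["mutations"], singles["toxicity"])
            if len(m) == 1 and np.isfinite(t)
        }
        doubles = merged[
            (merged["n_aa_mut"] == 2)
            & ~merged["is_stop"]
            & merged["bayes_corrected"]
            & merged["toxicity"].notna()
        ].reset_index(drop=True)
        doubles["t1_single"] = [
            single_map.get(m[0], np.nan) for m in doubles["mutations"]
        ]
        doubles["t2_single"] = [
            single_map.get(m[1], np.nan) for m in doubles["mutations"]
        ]
        doubles = doubles[
            doubles["t1_single"].notna() & doubles["t2_single"].notna()
        ].reset_index(drop=True)
        k = min(config.k_neighbors, max(10, 2 * len(doubles) // 3))
        matrices, flags = es.epistasis_pipeline(
            doubles,
            k_neighbors=k,
            range_limit_fraction=config.range_limit_fraction,
        )
        enr = pd.DataFrame(
            matrices.enrichment, columns=[str(p) for p in matrices.positions]
        )
        enr.insert(0, "position", matrices.positions)
        _write(enr, outdir / "enrichment_matrix.tsv", config.seed)
        cor = pd.DataFrame(
            matrices.correlation, columns=[str(p) for p in matrices.positions]
        )
        cor.insert(0, "position", matrices.positions)
        _write(cor, outdir / "correlation_matrix.tsv", config.seed)
        summary["stages"][stage] = {
            "n_doubles": int(len(doubles)),
            "flags": flags.value_counts().to_dict(),
        }

        stage = "structure"
        tracks = es.randomization_pvalues(
            matrices.correlation,
            matrices.positions,
            n_rand=config.n_randomizations,
            seed=config.seed,
        )
        track_df = pd.DataFrame({"position": matrices.positions})
        for name, tr in tracks.items():
            track_df[f"{name}_prop"] = tr.propensity
            track_df[f"{name}_p"] = tr.pvalue
        _write(track_df, outdir / "structure_tracks.tsv", config.seed)
        summary["stages"][stage] = {
            name: int(np.nansum(tr.pvalue < 0.05)) for name, tr in tracks.items()
        }
        if config.pdb_path and config.larks_range:
            cmap = es.pdb_contact_map(
                config.pdb_path, config.pdb_chain, tuple(config.larks_range)
            )
            score, pval = es.larks_propensity(
                matrices.correlation,
                matrices.positions,
                cmap,
                n_rand=config.n_randomizations,
                seed=config.seed,
            )
            summary["stages"]["larks"] = {"score": score, "p": pval}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    summary["runtime_s"] = round(time.time() - t_start, 1)
    with open(outdir / "report.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    _write_report_md(outdir, config, summary)
    return summary


def _write_report_md(outdir: Path, config: RunConfig, summary: dict) -> None:
    lines = [
        "# prdscan run report",
        "",
        f"- seed: {config.seed}",
        f"- runtime: {summary['runtime_s']} s",
        "",
    ]
    for stage, info in summary["stages"].items():
        lines.append(f"## {stage}")
        lines.append("```json")
        lines.append(json.dumps(info, indent=2, default=str))
        lines.append("```")
        lines.append("")
    (outdir / "report.md").write_text("\n".join(lines))
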