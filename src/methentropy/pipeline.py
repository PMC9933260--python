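"""End-to-end orchestration: simulate -> extract -> entropy -> drift -> report.

One config object collects every threshold of the analysis (coverage 20/40,
presence 75%, span 60 bp, JSD 0.2, difference 5 percentage points, q 0.05,
|rho| 0.5, 1000 permutations, 30-day turnover factor) with those values as
defaults.  Stages run in dependency order; each writes a TSV whose '#' header
records the exact parameters, plus a JSON sidecar with a content checksum, so
reruns under an identical config are byte-identical and verifiably so.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import drift, entropy, epialleles
from .exceptions import ConfigurationError, MethentropyError
from .io import (
    CpGCountMatrix,
    SampleSheet,
    read_bed_regions,
    read_cpg_counts,
    read_epireads,
    read_sample_sheet,
    read_turnover_table,
)
from .simulate import SimulationConfig, simulate_study

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "make_report"]


@dataclass
class PipelineConfig:
    """Paths, stage toggles and every statistical threshold of the pipeline."""

    outdir: str = "run"
    seed: int = 0

    # inputs; when simulate is enabled the sample files come from the simulator
    simulate: bool = False
    simulation: dict | None = None  # SimulationConfig fields
    design: str | None = None  # sample sheet CSV driving the simulation
    sample_sheet: str | None = None
    epireads: dict[str, str] = field(default_factory=dict)  # sample -> path
    cov_files: dict[str, str] = field(default_factory=dict)  # sample -> path
    turnover: str | None = None
    cpg_islands: str | None = None
    promoters: str | None = None

    # thresholds (defaults are the analysis' printed values)
    min_site_coverage: int = 20
    min_presence: float = 0.75
    min_locus_coverage: int = 40
    max_span_bp: int = 60
    n_cpgs: int = 4
    reference_age: float = 4.0
    old_age: float = 24.0
    jsd_threshold: float = 0.2
    diff_cutoff: float = 5.0
    q_cutoff: float = 0.05
    rho_cutoff: float = 0.5
    perm_p_cutoff: float = 0.05
    n_perm: int = 1000
    turnover_factor_days: float = 30.0
    reference_scope: str = "per_tissue"

    def __post_init__(self) -> None:
        if not 0 < self.min_presence <= 1:
            raise ConfigurationError("min_presence must lie in (0, 1]")
        if not 0 < self.jsd_threshold < 1:
            raise ConfigurationError("jsd_threshold must lie in (0, 1)")
        if self.n_perm < 1:
            raise ConfigurationError("n_perm must be >= 1")
        if self.min_site_coverage < 0 or self.min_locus_coverage < 0:
            raise ConfigurationError("coverage thresholds must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**data)

    def thresholds(self) -> dict[str, object]:
        skip = {"simulation", "epireads", "cov_files"}
        return {
            k: v
            for k, v in dataclasses.asdict(self).items()
            if k not in skip and not isinstance(v, dict)
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_stage(
    df: pd.DataFrame, path: Path, params: Mapping[str, object]
) -> None:
    with open(path, "w") as fh:
        for k in sorted(params):
            fh.write(f"# {k}={params[k]}\n")
        df.to_csv(fh, sep="\t", index=False)
    sidecar = {"params": {k: params[k] for k in sorted(params)}, "sha256": _sha256(path)}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all configured stages; returns the run directory.

    A stage failure halts the pipeline with the stage named; outputs written
    so far stay on disk next to a FAILED marker naming the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        # ---------------- simulate ----------------
        if config.simulate:
            stage = "simulate"
            if config.design is None:
                raise ConfigurationError("simulate=true requires a design sample sheet")
            sim_cfg = SimulationConfig(**{**(config.simulation or {}), "seed": config.seed})
            design = read_sample_sheet(config.design)
            manifest = simulate_study(sim_cfg, design, outdir / "simulated")
            sheet = design
            epiread_paths = {s: v["epireads"] for s, v in manifest["samples"].items()}
            cov_paths = {s: v["cov"] for s, v in manifest["samples"].items()}
        else:
            stage = "load"
            if config.sample_sheet is None:
                raise ConfigurationError("sample_sheet is required when simulate=false")
            sheet = read_sample_sheet(config.sample_sheet)
            epiread_paths = dict(config.epireads)
            cov_paths = dict(config.cov_files)
            if not cov_paths:
                raise ConfigurationError("no coverage files configured")

        # ---------------- extract epialleles ----------------
        stage = "extract"
        reads_by_sample = {s: read_epireads(p) for s, p in sorted(epiread_paths.items())}
        dists = epialleles.extract_distributions(
            reads_by_sample,
            min_coverage=config.min_locus_coverage,
            max_span_bp=config.max_span_bp,
            n_cpgs=config.n_cpgs,
        )
        epialleles.write_locus_table(
            dists,
            outdir / "epialleles.tsv",
            params={
                "min_coverage": config.min_locus_coverage,
                "max_span_bp": config.max_span_bp,
                "seed": config.seed,
            },
        )

        # ---------------- entropy ----------------
        stage = "jsd"
        refs = entropy.build_reference(
            dists, sheet, config.reference_age, scope=config.reference_scope
        )
        records = entropy.jsd_records(dists, refs, sheet, scope=config.reference_scope)
        jsd_df = pd.DataFrame(
            [
                {
                    "chromosome": r.locus.chromosome,
                    "pos1": r.locus.cpg_positions[0],
                    "pos2": r.locus.cpg_positions[1],
                    "pos3": r.locus.cpg_positions[2],
                    "pos4": r.locus.cpg_positions[3],
                    "sample_id": r.sample_id,
                    "jsd": r.jsd,
                }
                for r in records
            ]
        )
        _write_stage(
            jsd_df,
            outdir / "jsd.tsv",
            {"reference_age": config.reference_age, "scope": config.reference_scope},
        )

        stage = "fold_change"
        fcs = entropy.jsd_fold_change(records, sheet, config.old_age, config.reference_age)
        fc_df = pd.DataFrame(
            [
                {
                    "group": f.group,
                    "tissue": f.tissue,
                    "cell_type": f.cell_type,
                    "mean_jsd_old": f.mean_jsd_old,
                    "mean_jsd_young": f.mean_jsd_young,
                    "fold_change": f.fold_change,
                    "ratio": f.ratio,
                    "n_old": f.n_old,
                    "n_young": f.n_young,
                }
                for f in fcs
            ]
        )
        _write_stage(
            fc_df,
            outdir / "fold_change.tsv",
            {"old_age": config.old_age, "young_age": config.reference_age},
        )

        stage = "turnover"
        if config.turnover is not None:
            turnover = read_turnover_table(config.turnover)
            r, p, matched = entropy.correlate_turnover(
                fcs, turnover, factor_days=config.turnover_factor_days
            )
            matched["pearson_r"] = r
            matched["p"] = p
            _write_stage(
                matched,
                outdir / "turnover_corr.tsv",
                {"factor_days": config.turnover_factor_days},
            )

        # ---------------- per-CpG drift ----------------
        stage = "dm"
        matrix = read_cpg_counts(
            [cov_paths[s] for s in sorted(cov_paths)],
            dialect="bismark_cov",
            sample_ids=sorted(cov_paths),
        )
        matrix = drift.filter_sites(
            matrix, min_coverage=config.min_site_coverage, min_presence=config.min_presence
        )
        young = [s for s in matrix.samples if np.isclose(sheet.age_of(s), config.reference_age)]
        old = [s for s in matrix.samples if np.isclose(sheet.age_of(s), config.old_age)]
        if young and old:
            dm = drift.differential_methylation(
                matrix, young, old, diff_cutoff=config.diff_cutoff, q_cutoff=config.q_cutoff
            )
            _write_stage(
                dm,
                outdir / "dm.tsv",
                {
                    "group_a": ",".join(young),
                    "group_b": ",".join(old),
                    "diff_cutoff": config.diff_cutoff,
                    "q_cutoff": config.q_cutoff,
                    "correction": "benjamini-hochberg",
                },
            )

        stage = "permute"
        perm = drift.permutation_age_test(
            matrix,
            sheet,
            n_perm=config.n_perm,
            rho_cutoff=config.rho_cutoff,
            p_cutoff=config.perm_p_cutoff,
            seed=config.seed,
        )
        _write_stage(
            perm,
            outdir / "perm.tsv",
            {
                "n_perm": config.n_perm,
                "rho_cutoff": config.rho_cutoff,
                "p_cutoff": config.perm_p_cutoff,
                "seed": config.seed,
            },
        )

        stage = "compartments"
        if config.cpg_islands is not None and config.promoters is not None:
            cpgi = read_bed_regions(config.cpg_islands, "cpg_islands")
            prom = read_bed_regions(config.promoters, "promoters")
            sites = list(zip(perm["chromosome"], perm["position"]))
            labels = drift.annotate_compartments(sites, cpgi, prom)
            rows = []
            for direction in ("hyper", "hypo"):
                sig = [
                    (c, p)
                    for c, p, d in zip(perm["chromosome"], perm["position"], perm["direction"])
                    if d == direction
                ]
                for res in drift.compartment_odds_ratio(labels, sig, direction=direction):
                    rows.append(
                        {
                            "compartment": res.compartment,
                            "direction": res.direction,
                            "a": res.table[0],
                            "b": res.table[1],
                            "c": res.table[2],
                            "d": res.table[3],
                            "odds_ratio": res.odds_ratio,
                            "ci_low": res.ci95[0],
                            "ci_high": res.ci95[1],
                            "p": res.p,
                            "haldane": res.haldane,
                        }
                    )
            _write_stage(pd.DataFrame(rows), outdir / "or.tsv", {"test": "fisher_exact"})

        # ---------------- report ----------------
        stage = "report"
        manifest_path = outdir / "manifest.json"
        manifest_path.write_text(
            json.dumps(
                {
                    "cov_files": {s: str(p) for s, p in sorted(cov_paths.items())},
                    "sample_sheet": config.sample_sheet or str(outdir / "simulated" / "sample_sheet.csv"),
                    "thresholds": {k: str(v) for k, v in sorted(config.thresholds().items())},
                },
                indent=1,
                sort_keys=True,
            )
        )
        make_report(outdir)
    except MethentropyError:
        (outdir / "FAILED").write_text(f"stage: {stage}\n")
        logger.error("pipeline failed at stage %r", stage)
        raise
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\n")
        raise MethentropyError(f"stage {stage!r} failed: {exc}") from exc
    return outdir


def _read_stage_tsv(path: Path) -> pd.DataFrame | None:
    if not path.exists():
        return None
    return pd.read_csv(path, sep="\t", comment="#")


def make_report(run_dir: str | Path) -> Path:
    """Summarize a run directory into report.tsv.

    Sections: per-group JSD fold changes, the turnover correlation, the
    compartment odds ratios, counts of significant sites/loci, and the
    stem/nonstem per-site aging-change concordance.  Sections whose stage
    output is absent are marked skipped.
    """
    run_dir = Path(run_dir)
    lines: list[str] = []

    fc = _read_stage_tsv(run_dir / "fold_change.tsv")
    if fc is not None and not fc.empty:
        lines.append("section\tfold_change")
        for _, row in fc.iterrows():
            lines.append(
                f"fold_change\t{row['group']}\t{row['fold_change']:.6g}\t{row['ratio']:.6g}"
            )
    else:
        lines.append("section\tfold_change\tSKIPPED (no output)")

    tc = _read_stage_tsv(run_dir / "turnover_corr.tsv")
    if tc is not None and not tc.empty:
        lines.append(f"turnover_correlation\tpearson_r\t{tc['pearson_r'].iloc[0]:.6g}")
        lines.append(f"turnover_correlation\tp\t{tc['p'].iloc[0]:.6g}")
    else:
        lines.append("section\tturnover_correlation\tSKIPPED (no output)")

    orr = _read_stage_tsv(run_dir / "or.tsv")
    if orr is not None and not orr.empty:
        for _, row in orr.iterrows():
            lines.append(
                f"odds_ratio\t{row['compartment']}\t{row['direction']}\t"
                f"{row['odds_ratio']:.6g}\t{row['p']:.3g}"
            )
    else:
        lines.append("section\todds_ratios\tSKIPPED (no output)")

    dm = _read_stage_tsv(run_dir / "dm.tsv")
    if dm is not None:
        lines.append(f"counts\tdm_significant\t{int(dm['significant'].sum())}\t{len(dm)}")
    perm = _read_stage_tsv(run_dir / "perm.tsv")
    if perm is not None:
        n_hyper = int((perm["direction"] == "hyper").sum())
        n_hypo = int((perm["direction"] == "hypo").sum())
        lines.append(f"counts\tperm_hyper\t{n_hyper}\t{len(perm)}")
        lines.append(f"counts\tperm_hypo\t{n_hypo}\t{len(perm)}")
    jsd = _read_stage_tsv(run_dir / "jsd.tsv")
    if jsd is not None and not jsd.empty:
        lines.append(f"counts\tjsd_records\t{len(jsd)}\t{jsd['sample_id'].nunique()}")

    # stem/nonstem concordance from the manifest's coverage files
    manifest_path = run_dir / "manifest.json"
    concordance_done = False
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        cov = manifest.get("cov_files", {})
        sheet_path = manifest.get("sample_sheet")
        if cov and sheet_path and Path(sheet_path).exists():
            sheet = read_sample_sheet(sheet_path)
            matrix = read_cpg_counts(
                [cov[s] for s in sorted(cov)], sample_ids=sorted(cov)
            )
            th = manifest.get("thresholds", {})
            matrix = drift.filter_sites(
                matrix,
                min_coverage=int(th.get("min_site_coverage", 20)),
                min_presence=float(th.get("min_presence", 0.75)),
            )
            try:
                r, p, n = drift.stem_nonstem_concordance(
                    matrix,
                    sheet,
                    old_age=float(th.get("old_age", 24.0)),
                    young_age=float(th.get("reference_age", 4.0)),
                )
                lines.append(f"concordance\tstem_vs_nonstem_r\t{r:.6g}\t{p:.3g}\t{n}")
                concordance_done = True
            except MethentropyError as exc:
                logger.info("concordance section skipped: %s", exc)
    if not concordance_done:
        lines.append("section\tconcordance\tSKIPPED (insufficient samples)")

    report = run_dir / "report.tsv"
    report.write_text("\n".join(lines) + "\n")
    return report
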