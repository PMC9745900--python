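"""End-to-end orchestration of the screening-analysis pipeline.

Stages run in dependency order: simulate → normalize → fit → dss → triage →
phospho → treelasso → associate.  Every stage writes a tab-separated table
plus a JSON sidecar carrying the stage name, seed, config hash and input
hashes; a completed stage whose inputs are unchanged is skipped on re-run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .doseresponse import fit_screen
from .dss import DssConfig, score_screen
from .normalize import normalize_plate, summarize_replicates
from .phospho import ratio_table, standardize_matrix
from .simulate import simulate_study
from .stats import class_aggregate_test, cluster_cell_lines, correlation_table
from .treelasso import (
    build_drug_tree,
    clamp_heights,
    filter_coefficients_for_display,
    fit_cv,
    r_squared,
)
from .variants import build_mutation_matrix, triage

ALL_STAGES = (
    "simulate", "normalize", "fit", "dss", "triage", "phospho", "treelasso",
    "associate",
)


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    noise_sd: float = 5.0
    replicate_count: int = 3
    dss: DssConfig = field(default_factory=DssConfig)
    h_cut: float = 0.7
    mu: float = 1e-4
    lam_grid_size: int = 20
    lam_grid_span: float = 100.0
    tree_distance: str = "correlation"
    tree_linkage: str = "complete"
    force: bool = False


class PipelineError(RuntimeError):
    pass


def load_config(path, **overrides) -> RunConfig:
    """Build a RunConfig from a YAML file, with keyword overrides.

    The file holds RunConfig fields; the ``dss`` key may be a mapping of
    DssConfig fields.  Overrides passed as None are ignored.
    """
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    unknown = set(data) - {f.name for f in fields(RunConfig)}
    if unknown:
        raise PipelineError(f"unknown config keys: {sorted(unknown)}")
    if isinstance(data.get("dss"), dict):
        data["dss"] = DssConfig(**data["dss"])
    if "stages" in data:
        data["stages"] = tuple(data["stages"])
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def _stage_done(out: Path, meta: dict, force: bool) -> bool:
    side = _sidecar(out)
    if force or not (out.exists() and side.exists()):
        return False
    recorded = io.read_json(side)
    return (
        recorded.get("config_hash") == meta.get("config_hash")
        and recorded.get("input_hashes") == meta.get("input_hashes")
    )


def _write_stage(df: pd.DataFrame, out: Path, meta: dict, index=False):
    io.write_table(df, out, index=index)
    io.write_json(meta, _sidecar(out))


def _meta(stage: str, config: RunConfig, inputs: list[Path]) -> dict:
    return {
        "stage": stage,
        "seed": config.seed,
        "config_hash": io.config_hash(
            {k: str(v) for k, v in vars(config).items() if k != "force"}
        ),
        "input_hashes": {str(p): io.file_hash(p) for p in inputs},
    }


def _require(path: Path, stage: str):
    if not path.exists():
        raise PipelineError(
            f"stage {stage!r} needs missing input {path}; run its upstream "
            "stage first"
        )
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages; returns (and writes) the run manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    notes: list[str] = []
    stages = config.stages

    raw_path = out / "raw_screen.tsv"
    variants_path = out / "variants.tsv"
    phospho_path = out / "phospho_readouts.tsv"
    viability_path = out / "viability.tsv"
    profile_path = out / "profile_means.tsv"
    fits_path = out / "fits.tsv"
    dss_path = out / "dss_matrix.tsv"
    mut_path = out / "mutation_matrix.tsv"
    prot_path = out / "protein_standardized.tsv"

    if "simulate" in stages:
        meta = _meta("simulate", config, [])
        if not _stage_done(raw_path, meta, config.force):
            study = simulate_study(
                seed=config.seed, noise_sd=config.noise_sd,
                replicate_count=config.replicate_count,
            )
            _write_stage(study.raw_screen, raw_path, meta)
            _write_stage(study.variant_table, variants_path, meta)
            _write_stage(study.phospho_readouts, phospho_path, meta)
            io.write_json(study.drug_classes, out / "drug_classes.json")
        artifacts["raw_screen"] = str(raw_path)
        artifacts["variants"] = str(variants_path)
        artifacts["phospho_readouts"] = str(phospho_path)

    if "normalize" in stages:
        _require(raw_path, "normalize")
        meta = _meta("normalize", config, [raw_path])
        if not _stage_done(viability_path, meta, config.force):
            raw = io.read_table(raw_path)
            viability = normalize_plate(raw)
            _write_stage(viability, viability_path, meta)
            _write_stage(summarize_replicates(viability), profile_path, meta)
        artifacts["viability"] = str(viability_path)
        artifacts["profile_means"] = str(profile_path)

    if "fit" in stages:
        _require(profile_path, "fit")
        meta = _meta("fit", config, [profile_path])
        if not _stage_done(fits_path, meta, config.force):
            profile = io.read_table(profile_path)
            fits, fallbacks = fit_screen(profile)
            _write_stage(fits, fits_path, meta)
            io.write_json(fallbacks, out / "fallback_fits.json")
            if fallbacks:
                notes.append(f"{len(fallbacks)} profiles used the L4 fallback")
        artifacts["fits"] = str(fits_path)

    if "dss" in stages:
        _require(fits_path, "dss")
        _require(profile_path, "dss")
        meta = _meta("dss", config, [fits_path])
        if not _stage_done(dss_path, meta, config.force):
            fits = io.read_table(fits_path)
            profile = io.read_table(profile_path)
            rng_lo = float(profile["concentration_nM"].min())
            rng_hi = float(profile["concentration_nM"].max())
            matrix, records = score_screen(fits, (rng_lo, rng_hi), config.dss)
            _write_stage(matrix, dss_path, meta, index=True)
            io.write_json(
                [vars(r) for r in records], out / "dss_records.json"
            )
            n_low = sum(r.low_confidence for r in records)
            if n_low:
                notes.append(f"{n_low} low-confidence (degenerate-fit) scores")
        artifacts["dss_matrix"] = str(dss_path)

    if "triage" in stages:
        _require(variants_path, "triage")
        meta = _meta("triage", config, [variants_path])
        if not _stage_done(mut_path, meta, config.force):
            table = io.read_table(variants_path)
            survivors, log = triage(table)
            matrix, _prov = build_mutation_matrix(survivors)
            _write_stage(matrix, mut_path, meta, index=True)
            io.write_json(log, out / "variant_exclusions.json")
        artifacts["mutation_matrix"] = str(mut_path)

    if "phospho" in stages:
        _require(phospho_path, "phospho")
        meta = _meta("phospho", config, [phospho_path])
        if not _stage_done(prot_path, meta, config.force):
            readouts = io.read_table(phospho_path)
            ratios = ratio_table(readouts)
            std, stats_df = standardize_matrix(ratios)
            _write_stage(std, prot_path, meta, index=True)
            if stats_df["zero_variance"].any():
                flat = list(stats_df.index[stats_df["zero_variance"]])
                notes.append(f"zero-variance analytes zeroed: {flat}")
        artifacts["protein_standardized"] = str(prot_path)

    if "treelasso" in stages:
        _require(dss_path, "treelasso")
        dss_matrix = io.read_table(dss_path, index_col=0)
        tree = clamp_heights(
            build_drug_tree(
                dss_matrix, distance=config.tree_distance,
                linkage=config.tree_linkage,
            ),
            config.h_cut,
        )
        from .treelasso import lambda_grid

        for kind, feat_path in (("mutation", mut_path), ("protein", prot_path)):
            if not feat_path.exists():
                continue
            features = io.read_table(feat_path, index_col=0)
            shared = [c for c in dss_matrix.columns if c in features.columns]
            X = features[shared].T  # samples × features
            Y = dss_matrix[shared].T  # samples × drugs
            grid = lambda_grid(
                X, Y, n_points=config.lam_grid_size, span=config.lam_grid_span
            )
            model, cv = fit_cv(X, Y, tree=tree, lam_grid_values=grid,
                               mu=config.mu)
            coef = model.coefficients()
            coef_path = out / f"treelasso_{kind}_coefficients.tsv"
            meta = _meta("treelasso", config, [dss_path, feat_path])
            _write_stage(coef, coef_path, meta, index=True)
            io.write_table(
                pd.DataFrame({"lambda": cv.lam_grid, "mse": cv.mse}),
                out / f"treelasso_{kind}_cv.tsv",
            )
            io.write_table(
                filter_coefficients_for_display(coef),
                out / f"treelasso_{kind}_coefficients_display.tsv",
                index=True,
            )
            io.write_json(
                {
                    "kind": kind,
                    "lambda": model.lam,
                    "mu": model.mu,
                    "cv_mse": float(cv.mse[cv.selected_index]),
                    "r_squared": r_squared(model, X, Y),
                    "converged": model.converged,
                    "n_iter": model.n_iter,
                    "seed": config.seed,
                    "selection_rule": cv.rule,
                },
                out / f"treelasso_{kind}_model.json",
            )
            artifacts[f"treelasso_{kind}"] = str(coef_path)

    if "associate" in stages:
        _require(dss_path, "associate")
        dss_matrix = io.read_table(dss_path, index_col=0)
        order, z = cluster_cell_lines(dss_matrix)
        io.write_json(
            {"column_order": list(order), "linkage": z.tolist()},
            out / "cell_line_clustering.json",
        )
        if prot_path.exists():
            prot = io.read_table(prot_path, index_col=0)
            corr = correlation_table(prot, dss_matrix, adjust=True)
            io.write_table(corr, out / "protein_drug_correlations.tsv")
            artifacts["correlations"] = str(out / "protein_drug_correlations.tsv")
        if mut_path.exists() and (out / "drug_classes.json").exists():
            mut = io.read_table(mut_path, index_col=0)
            classes = io.read_json(out / "drug_classes.json")
            comparisons = []
            for gene in mut.index:
                carriers = list(mut.columns[mut.loc[gene] == 1])
                wild = list(mut.columns[mut.loc[gene] == 0])
                if len(carriers) < 2 or len(wild) < 2:
                    continue
                for cls, members in classes.items():
                    members = [m for m in members if m in dss_matrix.index]
                    if not members:
                        continue
                    try:
                        cmp_res = class_aggregate_test(
                            dss_matrix, members, carriers, wild,
                            label=f"{gene}:{cls}",
                        )
                    except ValueError:
                        continue
                    comparisons.append(vars(cmp_res))
            io.write_table(
                pd.DataFrame(comparisons), out / "group_comparisons.tsv"
            )
            artifacts["group_comparisons"] = str(out / "group_comparisons.tsv")

    manifest = {
        "seed": config.seed,
        "stages": list(stages),
        "artifacts": artifacts,
        "notes": notes,
    }
    io.write_json(manifest, out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# Input validation

SCHEMAS = {
    "raw_screen": {
        "columns": ["plate", "well", "cell_line", "drug", "concentration_nM",
                    "role", "luminescence", "replicate"],
        "checks": [
            ("non-positive sample concentration",
             lambda df: (df["role"] == "sample")
             & ~(pd.to_numeric(df["concentration_nM"], errors="coerce") > 0)),
            ("non-finite luminescence",
             lambda df: ~np.isfinite(
                 pd.to_numeric(df["luminescence"], errors="coerce"))),
            ("unknown role",
             lambda df: ~df["role"].isin(["sample", "negative", "positive"])),
        ],
    },
    "variants": {
        "columns": ["gene", "cell_line", "protein_change", "consequence",
                    "kg_max_maf", "esp_max_maf", "in_dbsnp138", "has_clinvar",
                    "in_census", "polyphen"],
        "checks": [
            ("unknown consequence class (valid: missense, stop-gain, "
             "stop-loss, frameshift, non-frameshift, splice-donor, "
             "splice-acceptor, other)",
             lambda df: ~df["consequence"].isin(
                 ["missense", "stop-gain", "stop-loss", "frameshift",
                  "non-frameshift", "splice-donor", "splice-acceptor",
                  "other"])),
            ("MAF outside [0, 0.5]",
             lambda df: (
                 pd.to_numeric(df["kg_max_maf"], errors="coerce")
                 .fillna(0.0).pipe(lambda v: (v < 0) | (v > 0.5))
             )),
        ],
    },
    "phospho": {
        "columns": ["cell_line", "analyte", "signal", "isotype_signal"],
        "checks": [
            ("negative signal",
             lambda df: pd.to_numeric(df["signal"], errors="coerce") < 0),
            ("negative isotype signal",
             lambda df: pd.to_numeric(
                 df["isotype_signal"], errors="coerce") < 0),
        ],
    },
}


def validate_inputs(path, kind: str) -> pd.DataFrame:
    """Schema check of an input table; returns a row-level issue report.

    An empty report means the table is well formed.
    """
    if kind not in SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}; valid: {list(SCHEMAS)}")
    schema = SCHEMAS[kind]
    df = io.read_table(path)
    issues = []
    missing = [c for c in schema["columns"] if c not in df.columns]
    if missing:
        issues.append({"row": -1, "issue": f"missing columns: {missing}"})
        return pd.DataFrame(issues)
    for message, predicate in schema["checks"]:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bad = predicate(df)
        for idx in df.index[bad.fillna(True) if bad.isna().any() else bad]:
            issues.append({"row": int(idx), "issue": message})
    return pd.DataFrame(issues, columns=["row", "issue"])
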