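"""Synthetic data generators for the screening pipeline.

Every input the pipeline consumes can be generated here with known ground
truth: raw plate-reader screens with dose-response structure, feature →
drug-sensitivity effect matrices with planted causal features, and annotated
variant tables that exercise every branch of the somatic-variant triage
cascade.  All generators are pure functions of their seed.

The default study shape mirrors a targeted-drug screen in myeloma cell
lines: 9 cell lines, 33 drugs, five concentrations from 1 to 10,000 nM,
three replicates, and 384-well plates with 16 negative (DMSO) and 16
positive (full-kill) control wells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .doseresponse import ll4

DEFAULT_CONCENTRATIONS_NM = (1.0, 10.0, 100.0, 1000.0, 10000.0)

#: Plausible plate-reader luminescence levels for live (negative control,
#: DMSO-only) and dead (positive control, benzethonium chloride) wells.
NEG_CONTROL_MEAN = 120_000.0
POS_CONTROL_MEAN = 2_000.0

DEFAULT_DRUGS = tuple(f"drug{i:02d}" for i in range(1, 34))
DEFAULT_CELL_LINES = tuple(f"MM{i}" for i in range(1, 10))


@dataclass(frozen=True)
class ScreenSimConfig:
    """Configuration of a simulated viability screen.

    ``true_params`` maps ``(cell_line, drug)`` to the four-parameter
    log-logistic tuple ``(b, c, d, e)`` that generates the underlying true
    viability at each dose.  ``noise_sd`` is expressed in percent-viability
    units and is converted to the luminescence scale internally.
    """

    cell_lines: Sequence[str]
    drugs: Sequence[str]
    true_params: Mapping[tuple[str, str], tuple[float, float, float, float]]
    concentrations_nM: Sequence[float] = DEFAULT_CONCENTRATIONS_NM
    replicate_count: int = 3
    noise_sd: float = 5.0
    n_negative_controls: int = 16
    n_positive_controls: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations_nM, dtype=float)
        if conc.size == 0 or np.any(conc <= 0):
            raise ValueError("concentrations must be positive")
        if np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if len(self.drugs) == 0:
            raise ValueError("drug list must be non-empty")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")


def default_true_params(
    cell_lines: Sequence[str],
    drugs: Sequence[str],
    seed: int = 0,
) -> dict[tuple[str, str], tuple[float, float, float, float]]:
    """Draw a realistic spread of true dose-response parameters.

    Half-effect concentrations are log-uniform across the tested range,
    slopes moderate, lower asymptotes mostly near zero with occasional
    partial responders, upper asymptote at full viability.
    """
    rng = np.random.default_rng(seed)
    params: dict[tuple[str, str], tuple[float, float, float, float]] = {}
    for cl in cell_lines:
        for dr in drugs:
            b = rng.uniform(0.8, 2.5)
            c = float(rng.choice([0.0, rng.uniform(0.0, 30.0)], p=[0.7, 0.3]))
            d = 100.0
            e = 10.0 ** rng.uniform(0.5, 4.5)  # ~3 nM to ~30 uM
            params[(cl, dr)] = (b, c, d, e)
    return params


def simulate_plate(config: ScreenSimConfig) -> pd.DataFrame:
    """Simulate raw plate-reader luminescence for a full screen.

    One plate is laid out per (cell line, replicate): all drugs at all
    concentrations plus the configured control wells.  Sample-well
    luminescence is the convex combination of the control means set by the
    true viability, plus additive Gaussian noise whose SD is ``noise_sd``
    percent-viability units rescaled to the luminescence axis.

    Returns a long-format table with columns
    ``plate, well, cell_line, drug, concentration_nM, role, luminescence,
    replicate``; ``role`` is ``sample``/``negative``/``positive``.
    """
    rng = np.random.default_rng(config.seed)
    lum_per_pct = (NEG_CONTROL_MEAN - POS_CONTROL_MEAN) / 100.0
    noise_lum = config.noise_sd * lum_per_pct
    conc = np.asarray(config.concentrations_nM, dtype=float)

    rows: list[dict] = []
    for cl in config.cell_lines:
        for rep in range(1, config.replicate_count + 1):
            plate = f"{cl}-rep{rep}"
            well = 0
            for dr in config.drugs:
                b, c, d, e = config.true_params[(cl, dr)]
                v_true = ll4(conc, b, c, d, e)
                mean_lum = (
                    NEG_CONTROL_MEAN * v_true / 100.0
                    + POS_CONTROL_MEAN * (1.0 - v_true / 100.0)
                )
                noise = rng.normal(0.0, 1.0, size=conc.size) * noise_lum
                for x, lum in zip(conc, mean_lum + noise):
                    well += 1
                    rows.append(
                        dict(
                            plate=plate,
                            well=f"W{well:03d}",
                            cell_line=cl,
                            drug=dr,
                            concentration_nM=float(x),
                            role="sample",
                            luminescence=float(lum),
                            replicate=rep,
                        )
                    )
            for role, mean, n_ctrl in (
                ("negative", NEG_CONTROL_MEAN, config.n_negative_controls),
                ("positive", POS_CONTROL_MEAN, config.n_positive_controls),
            ):
                noise = rng.normal(0.0, 1.0, size=n_ctrl) * noise_lum
                for k in range(n_ctrl):
                    well += 1
                    rows.append(
                        dict(
                            plate=plate,
                            well=f"W{well:03d}",
                            cell_line=cl,
                            drug=f"{role}-control",
                            concentration_nM=0.0,
                            role=role,
                            luminescence=float(mean + noise[k]),
                            replicate=rep,
                        )
                    )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PlantedEffectsConfig:
    """Planted linear feature → drug-sensitivity effects.

    ``causal_map`` maps a feature name to ``(drug subset, effect size)`` in
    score units on the 0-100 sensitivity scale.  ``feature_kind`` selects
    binary mutation-style covariates (Bernoulli ``prevalence``) or
    continuous standardized protein-style covariates.
    """

    n_cell_lines: int
    features: Sequence[str]
    drugs: Sequence[str] = DEFAULT_DRUGS
    causal_map: Mapping[str, tuple[Sequence[str], float]] = field(
        default_factory=dict
    )
    baseline_dss: float | Mapping[str, float] = 30.0
    residual_sd: float = 5.0
    feature_kind: str = "binary-mutation"
    prevalence: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        if self.feature_kind not in ("binary-mutation", "continuous-protein"):
            raise ValueError(f"unknown feature_kind {self.feature_kind!r}")
        if self.feature_kind == "binary-mutation" and not (
            0.0 < self.prevalence < 1.0
        ):
            raise ValueError("prevalence must be in (0, 1)")
        for feat, (sub, eff) in self.causal_map.items():
            if feat not in self.features:
                raise ValueError(f"causal feature {feat!r} not in feature list")
            if not np.isfinite(eff):
                raise ValueError("effect sizes must be finite")
            unknown = set(sub) - set(self.drugs)
            if unknown:
                raise ValueError(f"causal drugs not in drug list: {unknown}")


def simulate_feature_response(
    config: PlantedEffectsConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (features × samples, drugs × samples, features × drugs).

    The response matrix is ``baseline + X^T B_true + noise``, clipped to the
    0-100 score scale after adding noise.  The true coefficient matrix is
    returned so recovery tests can compare against ground truth.
    """
    rng = np.random.default_rng(config.seed)
    samples = [f"sample{i:03d}" for i in range(1, config.n_cell_lines + 1)]
    features = list(config.features)
    drugs = list(config.drugs)

    if config.feature_kind == "binary-mutation":
        x = rng.binomial(1, config.prevalence, size=(len(features), len(samples)))
        x = x.astype(float)
    else:
        x = rng.normal(0.0, 1.0, size=(len(features), len(samples)))

    b_true = pd.DataFrame(0.0, index=features, columns=drugs)
    for feat, (sub, eff) in config.causal_map.items():
        b_true.loc[feat, list(sub)] = eff

    if isinstance(config.baseline_dss, Mapping):
        base = np.array([config.baseline_dss[d] for d in drugs], dtype=float)
    else:
        base = np.full(len(drugs), float(config.baseline_dss))

    noise = rng.normal(0.0, config.residual_sd, size=(len(drugs), len(samples)))
    dss = base[:, None] + b_true.to_numpy().T @ x + noise
    dss = np.clip(dss, 0.0, 100.0)

    x_df = pd.DataFrame(x, index=features, columns=samples)
    dss_df = pd.DataFrame(dss, index=drugs, columns=samples)
    return x_df, dss_df, b_true


def curve_params_for_dss(
    target_dss: float,
    dose_range_nM: tuple[float, float] = (1.0, 10000.0),
    b: float = 1.5,
    c: float = 0.0,
    d: float = 100.0,
) -> tuple[float, float, float, float]:
    """Invert the sensitivity score: find the LL4 inflection ``e`` whose
    curve scores ``target_dss`` over the given dose range.

    The score is strictly decreasing in ``e`` for a full-kill curve, so a
    bisection on log10(e) suffices.  Targets must sit strictly inside the
    achievable (0, 100) range; in practice use targets in about [0.5, 97].
    """
    from .dss import DssConfig, compute_dss
    from .doseresponse import DoseResponseFit

    cfg = DssConfig(points_per_decade=200)

    def score(log_e: float) -> float:
        fit = DoseResponseFit(
            model="LL4", b=b, c=c, d=d, e=10.0**log_e, converged=True,
            rss=0.0, n_points=5,
        )
        return compute_dss(fit, dose_range_nM, cfg).dss

    lo, hi = -8.0, 12.0
    if not (score(hi) < target_dss < score(lo)):
        raise ValueError(f"target DSS {target_dss} outside achievable range")
    for _ in range(80):
        mid = (lo + hi) / 2.0
        if score(mid) > target_dss:
            lo = mid
        else:
            hi = mid
    return (b, c, d, 10.0 ** ((lo + hi) / 2.0))


@dataclass(frozen=True)
class StudyData:
    """A complete synthetic study with ground truth attached."""

    screen_config: ScreenSimConfig
    raw_screen: pd.DataFrame
    variant_table: pd.DataFrame
    phospho_readouts: pd.DataFrame
    mutation_matrix: pd.DataFrame  # genes × cell lines, ground truth
    protein_z: pd.DataFrame  # analytes × cell lines, standardized truth
    b_mut_true: pd.DataFrame  # genes × drugs
    b_prot_true: pd.DataFrame  # analytes × drugs
    dss_target: pd.DataFrame  # drugs × cell lines, pre-noise truth
    drug_classes: dict


#: Drug-class structure of the default synthetic library: a handful of MEK
#: and PI3K/mTOR inhibitors among kinase-targeted singletons.
DEFAULT_DRUG_CLASSES = {
    "MEKi": ["drug01", "drug02", "drug03", "drug04"],
    "PI3Ki": ["drug05", "drug06", "drug07", "drug08", "drug09", "drug10"],
}

DEFAULT_CAUSAL_GENES = {
    "NRAS": ("MEKi", 28.0),
    "KRAS": ("MEKi", 22.0),
    "PIK3CA": ("PI3Ki", 24.0),
    "MTOR": ("PI3Ki", 15.0),
}

DEFAULT_ANALYTES = tuple(
    ["p-MEK1", "p-AKT", "p-TBK1", "Bcl-2", "p-Bcl-2", "p-ERK", "p-S6"]
    + [f"analyte{i:02d}" for i in range(8, 32)]
)

DEFAULT_CAUSAL_ANALYTES = {
    "p-MEK1": ("MEKi", 10.0),
    "p-TBK1": ("MEKi", -9.0),
    "Bcl-2": ("MEKi", -8.0),
    "p-AKT": ("PI3Ki", 9.0),
}


def _variants_for_matrix(
    mutation_matrix: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Annotated variant table whose triage survivors reproduce the matrix.

    Every 1-entry gets a passing coding variant in a census gene; decoy
    variants exercising each exclusion branch are interleaved so the triage
    cascade has real work to do.
    """
    aa = "ACDEFGHIKLMNPQRSTVWY"
    coding = ["missense", "stop-gain", "frameshift", "splice-donor"]
    rows = []

    def change():
        return (
            f"p.{rng.choice(list(aa))}{int(rng.integers(1, 999))}"
            f"{rng.choice(list(aa))}"
        )

    for gene in mutation_matrix.index:
        for cl in mutation_matrix.columns:
            if mutation_matrix.loc[gene, cl] == 1:
                rows.append(
                    dict(
                        gene=gene, cell_line=cl, protein_change=change(),
                        consequence=str(rng.choice(coding)),
                        kg_max_maf=0.0, esp_max_maf=0.0, in_dbsnp138=False,
                        has_clinvar=False, in_census=True,
                        polyphen=str(
                            rng.choice(["probably_damaging",
                                        "possibly_damaging", "benign"],
                                       p=[0.5, 0.3, 0.2])
                        ),
                    )
                )
            # decoys that must be filtered out
            roll = rng.random()
            if roll < 0.15:
                rows.append(
                    dict(
                        gene=gene, cell_line=cl, protein_change=change(),
                        consequence="missense",
                        kg_max_maf=float(rng.uniform(0.02, 0.4)),
                        esp_max_maf=0.0, in_dbsnp138=True, has_clinvar=False,
                        in_census=True, polyphen="benign",
                    )
                )
            elif roll < 0.25:
                rows.append(
                    dict(
                        gene=gene, cell_line=cl, protein_change=change(),
                        consequence="other", kg_max_maf=0.0, esp_max_maf=0.0,
                        in_dbsnp138=False, has_clinvar=False, in_census=True,
                        polyphen="unknown",
                    )
                )
    return pd.DataFrame(rows)


def simulate_study(
    seed: int = 0,
    cell_lines: Sequence[str] = DEFAULT_CELL_LINES,
    drugs: Sequence[str] = DEFAULT_DRUGS,
    drug_classes: Mapping[str, Sequence[str]] = DEFAULT_DRUG_CLASSES,
    causal_genes: Mapping[str, tuple[str, float]] = DEFAULT_CAUSAL_GENES,
    analytes: Sequence[str] = DEFAULT_ANALYTES,
    causal_analytes: Mapping[str, tuple[str, float]] = DEFAULT_CAUSAL_ANALYTES,
    n_decoy_genes: int = 8,
    noise_sd: float = 5.0,
    residual_sd: float = 4.0,
    replicate_count: int = 3,
    concentrations_nM: Sequence[float] = DEFAULT_CONCENTRATIONS_NM,
) -> StudyData:
    """Generate a fully coherent synthetic study.

    Drug-sensitivity targets are built as baseline + mutation effects +
    protein effects + residual noise; each (cell line, drug) target is then
    inverted into a log-logistic curve whose plate-level simulation feeds
    the normalization/fit/scoring stages.  Variant and phospho tables are
    constructed so that triage and arcsinh standardization reproduce the
    planted covariates exactly.
    """
    rng = np.random.default_rng(seed)
    cell_lines = list(cell_lines)
    drugs = list(drugs)

    # --- mutation ground truth ------------------------------------------
    genes = list(causal_genes) + [f"DECOY{i:02d}" for i in range(n_decoy_genes)]
    mut = pd.DataFrame(
        rng.binomial(1, 0.35, size=(len(genes), len(cell_lines))),
        index=genes, columns=cell_lines,
    )
    # ensure causal genes are polymorphic across the panel
    for g in causal_genes:
        while mut.loc[g].sum() in (0, len(cell_lines)):
            mut.loc[g] = rng.binomial(1, 0.35, size=len(cell_lines))
    mut.index.name = "gene"
    mut.columns.name = "cell_line"

    b_mut = pd.DataFrame(0.0, index=genes, columns=drugs)
    for gene, (cls, eff) in causal_genes.items():
        b_mut.loc[gene, list(drug_classes[cls])] = eff

    # --- protein ground truth -------------------------------------------
    z_raw = rng.normal(size=(len(analytes), len(cell_lines)))
    z = (z_raw - z_raw.mean(axis=1, keepdims=True)) / z_raw.std(
        axis=1, ddof=1, keepdims=True
    )
    prot = pd.DataFrame(z, index=list(analytes), columns=cell_lines)
    prot.index.name = "analyte"
    prot.columns.name = "cell_line"

    b_prot = pd.DataFrame(0.0, index=list(analytes), columns=drugs)
    for an, (cls, eff) in causal_analytes.items():
        b_prot.loc[an, list(drug_classes[cls])] = eff

    # --- sensitivity targets --------------------------------------------
    baseline = pd.Series(rng.uniform(8.0, 55.0, size=len(drugs)), index=drugs)
    target = (
        baseline.to_numpy()[:, None]
        + b_mut.to_numpy().T @ mut.to_numpy()
        + b_prot.to_numpy().T @ prot.to_numpy()
        + rng.normal(0.0, residual_sd, size=(len(drugs), len(cell_lines)))
    )
    target = np.clip(target, 1.0, 96.0)
    dss_target = pd.DataFrame(target, index=drugs, columns=cell_lines)

    # --- invert targets into dose-response curves ------------------------
    dose_range = (float(min(concentrations_nM)), float(max(concentrations_nM)))
    true_params = {}
    for cl in cell_lines:
        for dr in drugs:
            b_slope = float(rng.uniform(1.0, 2.2))
            true_params[(cl, dr)] = curve_params_for_dss(
                float(dss_target.loc[dr, cl]), dose_range, b=b_slope
            )

    screen_config = ScreenSimConfig(
        cell_lines=cell_lines, drugs=drugs, true_params=true_params,
        concentrations_nM=tuple(concentrations_nM),
        replicate_count=replicate_count, noise_sd=noise_sd,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    raw_screen = simulate_plate(screen_config)

    # --- variant table reproducing the mutation matrix -------------------
    variant_table = _variants_for_matrix(mut, rng)

    # --- phospho readouts whose standardized ratios equal prot exactly ---
    cofactor = 150.0
    rows = []
    for an in analytes:
        iso = float(rng.uniform(50.0, 200.0))
        scale = float(rng.uniform(0.5, 1.5))
        # offset large enough that every back-transformed signal stays > 0
        offset = float(rng.uniform(4.5, 6.0))
        for cl in cell_lines:
            ratio = offset + scale * float(prot.loc[an, cl])
            signal = cofactor * np.sinh(ratio + np.arcsinh(iso / cofactor))
            rows.append(
                dict(cell_line=cl, analyte=an, signal=float(signal),
                     isotype_signal=iso)
            )
    phospho_readouts = pd.DataFrame(rows)

    return StudyData(
        screen_config=screen_config,
        raw_screen=raw_screen,
        variant_table=variant_table,
        phospho_readouts=phospho_readouts,
        mutation_matrix=mut,
        protein_z=prot,
        b_mut_true=b_mut,
        b_prot_true=b_prot,
        dss_target=dss_target,
        drug_classes={k: list(v) for k, v in drug_classes.items()},
    )


_CONSEQUENCES = (
    "missense",
    "stop-gain",
    "stop-loss",
    "frameshift",
    "non-frameshift",
    "splice-donor",
    "splice-acceptor",
    "other",
)

#: Twelve canonical variants spanning every branch of the triage cascade.
#: truth_pass is the expected survival through the three drop-filters
#: (germline MAF, dbSNP-without-ClinVar, coding-in-census).
_CANONICAL_VARIANTS = [
    # gene, cell_line, change, consequence, kg, esp, dbsnp, clinvar, census,
    # polyphen, truth_pass, truth_reason
    ("NRAS", "IH1", "p.G12V", "missense", 0.0, 0.0, False, False, True,
     "probably_damaging", True, "pass"),
    ("KRAS", "KJON", "p.Q61H", "missense", 0.0, 0.0, True, True, True,
     "probably_damaging", True, "pass"),  # dbSNP but ClinVar-associated
    ("PIK3CA", "CAG", "p.H1047R", "missense", 0.01, 0.0, False, False, True,
     "probably_damaging", True, "pass"),  # MAF exactly at threshold: kept
    ("TP53", "INA6", "p.K132M", "stop-gain", 0.0, 0.001, False, False, True,
     "unknown", True, "pass"),  # ESP exactly at threshold: kept
    ("MTOR", "JJN3", "p.A2300D", "frameshift", np.nan, np.nan, False, False,
     True, "possibly_damaging", True, "pass"),  # missing MAF: not excluded
    ("BRAF", "U266", "p.K601N", "splice-donor", 0.0, 0.0, False, False, True,
     "benign", True, "pass"),
    ("EGFR", "OH2", "p.Q61K", "missense", 0.02, 0.0, False, False, True,
     "probably_damaging", False, "germline_1000g"),
    ("FLT3", "INA6", "p.T526M", "missense", 0.0, 0.002, False, False, True,
     "probably_damaging", False, "germline_esp"),
    ("SYK", "IH1", "p.D410Y", "missense", 0.0, 0.0, True, False, True,
     "probably_damaging", False, "dbsnp_no_clinvar"),
    ("ROS1", "URVIN", "p.R1569W", "other", 0.0, 0.0, False, False, True,
     "unknown", False, "non_coding_class"),
    ("GENEX", "VOLIN", "p.L10F", "missense", 0.0, 0.0, False, False, False,
     "possibly_damaging", False, "not_census"),
    ("ALK", "JJN3", "p.P1213S", "splice-acceptor", 0.05, 0.0, True, False,
     True, "benign", False, "germline_1000g"),  # fails several filters
]


def simulate_variant_table(n_variants: int = 12, seed: int = 0) -> pd.DataFrame:
    """Annotated variant table with known triage ground truth.

    The first 12 rows are fixed canonical cases covering every filter
    branch (germline MAF exclusions at and beyond thresholds, dbSNP with and
    without ClinVar, non-coding classes, non-census genes, missing MAFs);
    additional rows are drawn at random with labels derived from the same
    rules.  Columns ``truth_pass``/``truth_reason`` carry the ground truth.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    rng = np.random.default_rng(seed)
    cols = [
        "gene", "cell_line", "protein_change", "consequence",
        "kg_max_maf", "esp_max_maf", "in_dbsnp138", "has_clinvar",
        "in_census", "polyphen", "truth_pass", "truth_reason",
    ]
    rows = [dict(zip(cols, r)) for r in _CANONICAL_VARIANTS[:n_variants]]
    aa = "ACDEFGHIKLMNPQRSTVWY"
    while len(rows) < n_variants:
        i = len(rows)
        kg = float(rng.choice([0.0, 0.005, 0.03], p=[0.6, 0.2, 0.2]))
        esp = float(rng.choice([0.0, 0.0005, 0.01], p=[0.6, 0.2, 0.2]))
        dbsnp = bool(rng.random() < 0.4)
        clinvar = bool(dbsnp and rng.random() < 0.3)
        census = bool(rng.random() < 0.7)
        cons = str(rng.choice(_CONSEQUENCES))
        if kg > 0.01:
            truth, reason = False, "germline_1000g"
        elif esp > 0.001:
            truth, reason = False, "germline_esp"
        elif dbsnp and not clinvar:
            truth, reason = False, "dbsnp_no_clinvar"
        elif cons == "other":
            truth, reason = False, "non_coding_class"
        elif not census:
            truth, reason = False, "not_census"
        else:
            truth, reason = True, "pass"
        rows.append(
            dict(
                gene=f"GENE{i:03d}",
                cell_line=f"MM{int(rng.integers(1, 10))}",
                protein_change=(
                    f"p.{rng.choice(list(aa))}{int(rng.integers(1, 999))}"
                    f"{rng.choice(list(aa))}"
                ),
                consequence=cons,
                kg_max_maf=kg,
                esp_max_maf=esp,
                in_dbsnp138=dbsnp,
                has_clinvar=clinvar,
                in_census=census,
                polyphen=str(
                    rng.choice(
                        ["benign", "possibly_damaging", "probably_damaging",
                         "unknown"]
                    )
                ),
                truth_pass=truth,
                truth_reason=reason,
            )
        )
    return pd.DataFrame(rows[:n_variants], columns=cols)
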