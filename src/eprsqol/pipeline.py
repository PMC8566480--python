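"""End-to-end orchestration: simulate/load -> QC -> score -> phenotypes -> models.

`run_pipeline` executes the whole analysis chain deterministically for a given
seed and returns a :class:`ReportBundle` whose tables mirror the shape of a
cohort study report: a characteristics table by depressive type, adjusted HRQoL means
by type, score-outcome association tables (crude and fully adjusted),
predicted subtype probabilities per score category, and the interaction
analyses with per-stratum slopes.  In synthetic mode the bundle also carries a
machine-readable comparison of key estimates against the generating truth.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats as st
import yaml

from . import __version__
from .genotypes import GenotypeMatrix
from .instruments import (
    Sf36Norms,
    derive_covariates_frame,
    score_bdi_frame,
)
from .inference import (
    DEFAULT_COVARIATES,
    BootstrapGLM,
    InteractionModel,
    MultinomialSubtypeModel,
    adjust_bonferroni,
)
from .qc import QcThresholds, filter_markers, filter_samples, genotype_pcs
from .score import ld_clump, compute_eprs, standardize_and_categorize
from .simulate import TruthRecord, simulate_study

HRQOL_OUTCOMES = ["pf", "rp", "bp", "gh", "vt", "sf", "re", "mh", "mcs", "pcs"]
CRUDE_COVARIATES = ["age", "sex", "pc1", "pc2", "pc3"]
METABOLIC_OUTCOMES = [
    "glucose_0", "glucose_30", "glucose_120",
    "insulin_0", "insulin_30", "insulin_120", "homa_ir",
]
# crude metabolic models adjust for stratification only; full models add lifestyle
METABOLIC_CRUDE = ["pc1", "pc2", "pc3"]
METABOLIC_FULL = METABOLIC_CRUDE + [
    "smoking", "alcohol", "ses", "comorbidity_class", "bmi", "ltpa_met_h_wk",
]

DEFAULT_SKEWED = [
    "ltpa_met_h_wk", "homa_ir", "insulin_0", "insulin_30", "insulin_120",
]
CHARACTERISTIC_CONTINUOUS = [
    "age", "bmi", "glucose_0", "glucose_30", "glucose_120",
    "insulin_0", "insulin_30", "insulin_120", "homa_ir", "ltpa_met_h_wk",
]
CHARACTERISTIC_CATEGORICAL = [
    "sex", "smoking", "alcohol", "ses", "comorbidity_class", "glucose_status",
]


@dataclass
class PipelineConfig:
    """Run configuration; ``synthetic`` mode generates its own inputs."""

    mode: str = "synthetic"  # synthetic | files
    # synthetic-mode sizes (defaults = emulated study conditions)
    n_samples: int = 1558
    n_markers: int = 4000
    n_genes: int = 498
    snps_per_gene: int = 8
    beta_interaction_mcs: float = -3.4
    # files-mode inputs
    vcf: str | None = None
    weights: str | None = None
    cohort: str | None = None
    truth: str | None = None
    # stage parameters
    window_bp: int = 250_000
    n_pcs: int = 3
    n_boot_glm: int = 10_000
    n_boot_multinomial: int = 1500
    n_boot_characteristics: int = 10_000
    skewed_variables: list[str] = field(default_factory=lambda: list(DEFAULT_SKEWED))
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


@dataclass
class ReportBundle:
    """All pipeline outputs plus run metadata."""

    characteristics: pd.DataFrame
    hrqol_by_type: pd.DataFrame
    eprs_associations: pd.DataFrame
    subtype_probabilities: pd.DataFrame
    subtype_probability_differences: pd.DataFrame
    eprs_subtype_coefficients: pd.DataFrame
    metabolic_associations: pd.DataFrame
    interaction_tests: pd.DataFrame
    stratum_slopes: pd.DataFrame
    stratum_contrasts: pd.DataFrame
    adjusted_cell_means: pd.DataFrame
    analysis_table: pd.DataFrame
    metadata: dict
    truth_comparison: dict | None = None

    _TABLES = [
        "characteristics", "hrqol_by_type", "eprs_associations",
        "subtype_probabilities", "subtype_probability_differences",
        "eprs_subtype_coefficients", "metabolic_associations",
        "interaction_tests", "stratum_slopes", "stratum_contrasts",
        "adjusted_cell_means", "analysis_table",
    ]

    def save(self, out_dir: str | Path) -> dict[str, str]:
        """Write TSV tables + JSON metadata; returns sha256 checksums."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        checksums: dict[str, str] = {}
        for name in self._TABLES:
            path = out / f"{name}.tsv"
            getattr(self, name).to_csv(path, sep="\t", index=False)
            checksums[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
        meta = {"metadata": self.metadata, "truth_comparison": self.truth_comparison}
        mpath = out / "report.json"
        mpath.write_text(json.dumps(meta, indent=1, sort_keys=True, default=str))
        checksums[mpath.name] = hashlib.sha256(mpath.read_bytes()).hexdigest()
        (out / "checksums.json").write_text(json.dumps(checksums, indent=1, sort_keys=True))
        return checksums


def _bootstrap_anova_p(
    values: np.ndarray, groups: np.ndarray, n_boot: int, rng: np.random.Generator
) -> float:
    """Bootstrap test of equal group means (resampling a mean-aligned null)."""
    levels, codes = np.unique(groups, return_inverse=True)
    mask = ~np.isnan(values)
    values, codes = values[mask], codes[mask]
    k, n = len(levels), len(values)
    if k < 2 or n < k + 2:
        return float("nan")

    def f_stat(v: np.ndarray, c: np.ndarray) -> float:
        grand = v.mean()
        ssb = ssw = 0.0
        for g in range(k):
            vg = v[c == g]
            ssb += len(vg) * (vg.mean() - grand) ** 2
            ssw += ((vg - vg.mean()) ** 2).sum()
        return (ssb / (k - 1)) / (ssw / (n - k))

    f_obs = f_stat(values, codes)
    # null sample: remove group mean differences, keep within-group spread
    group_means = np.array([values[codes == g].mean() for g in range(k)])
    # group labels are exchangeable for draws from the pooled null sample, so
    # resampled columns are assigned to groups by contiguous blocks
    null = values - group_means[codes] + values.mean()
    sizes = np.bincount(codes, minlength=k)
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    exceed = 0
    chunk = 500
    for start in range(0, n_boot, chunk):
        b = min(chunk, n_boot - start)
        draws = null[rng.integers(0, n, size=(b, n))]
        grand = draws.mean(axis=1)
        ssb = np.zeros(b)
        ssw = np.zeros(b)
        for g in range(k):
            seg = draws[:, bounds[g] : bounds[g + 1]]
            mg = seg.mean(axis=1)
            ssb += sizes[g] * (mg - grand) ** 2
            ssw += ((seg - mg[:, None]) ** 2).sum(axis=1)
        f_null = (ssb / (k - 1)) / (ssw / (n - k))
        exceed += int((f_null >= f_obs).sum())
    return (1 + exceed) / (n_boot + 1)


def characteristics_table(
    data: pd.DataFrame,
    group: str = "subtype",
    skewed: list[str] | None = None,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-subtype descriptive table with between-group p-values.

    Continuous variables show mean (SD), or median (IQR) when listed as
    skewed; p-values come from a bootstrap analysis-of-variance.  Categorical
    variables show count (%) with chi-square p-values.
    """
    rng = np.random.default_rng(seed)
    skewed = DEFAULT_SKEWED if skewed is None else skewed
    groups = [g for g in data[group].cat.categories] if isinstance(
        data[group].dtype, pd.CategoricalDtype
    ) else sorted(data[group].unique())
    rows = []
    for var in CHARACTERISTIC_CONTINUOUS:
        if var not in data.columns:
            continue
        cells = {}
        for g in groups:
            v = data.loc[data[group] == g, var].dropna()
            if var in skewed:
                q1, med, q3 = v.quantile([0.25, 0.5, 0.75])
                cells[str(g)] = f"{med:.1f} ({q1:.1f}, {q3:.1f})"
            else:
                cells[str(g)] = f"{v.mean():.1f} ({v.std(ddof=1):.1f})"
        p = _bootstrap_anova_p(
            data[var].to_numpy(dtype=float), data[group].to_numpy(), n_boot, rng
        )
        rows.append({"variable": var, **cells, "p": p})
    for var in CHARACTERISTIC_CATEGORICAL:
        if var not in data.columns:
            continue
        tab = pd.crosstab(data[var], data[group])
        chi2_p = st.chi2_contingency(tab.to_numpy())[1]
        first = True
        for lev in tab.index:
            cells = {}
            for g in groups:
                cnt = int(tab.at[lev, g]) if g in tab.columns else 0
                tot = int((data[group] == g).sum())
                cells[str(g)] = f"{cnt} ({100 * cnt / max(tot, 1):.0f}%)"
            rows.append(
                {
                    "variable": f"{var}: {lev}",
                    **cells,
                    "p": chi2_p if first else np.nan,
                }
            )
            first = False
    return pd.DataFrame(rows)


def build_analysis_table(
    genotypes: GenotypeMatrix,
    weights: pd.DataFrame,
    cohort: pd.DataFrame,
    *,
    window_bp: int = 250_000,
    n_pcs: int = 3,
    qc_thresholds: QcThresholds | None = None,
    norms: Sf36Norms | None = None,
) -> tuple[pd.DataFrame, dict]:
    """QC, score and phenotype stages merged into one analysis DataFrame.

    When no SF-36 norms are supplied they are estimated from the analysis
    sample itself (in-sample standardization of the component scores).
    """
    gm, marker_report = filter_markers(genotypes, qc_thresholds)
    gm, sample_report = filter_samples(gm, qc_thresholds)
    pcs = genotype_pcs(gm, k=n_pcs)

    clumped = ld_clump(weights[weights["snp_id"].isin(gm.markers["snp_id"])],
                       window_bp=window_bp)
    raw = compute_eprs(gm, clumped)
    eprs = standardize_and_categorize(raw)

    cohort = cohort.set_index("sample_id").loc[gm.samples]
    bdi_cols = [f"bdi_{i}" for i in range(1, 22)]
    sf_cols = [f"sf36_{i}" for i in range(1, 37)]
    bdi = score_bdi_frame(cohort[bdi_cols])
    sf_items = cohort[sf_cols]
    from .instruments.sf36 import recode_items, domain_scores, components

    domains = domain_scores(recode_items(sf_items))
    if norms is None:
        norms = Sf36Norms.from_sample(domains)
    comp = components(domains, norms)
    covs = derive_covariates_frame(cohort)

    table = pd.concat(
        [bdi, domains, comp, covs, pcs, eprs.rename(columns={"raw": "eprs_raw",
                                                             "z": "eprs_z",
                                                             "category": "eprs_cat"})],
        axis=1,
    )
    for col in cohort.columns:
        if col.startswith("truth_") or col in (
            "glucose_0", "glucose_30", "glucose_120",
            "insulin_0", "insulin_30", "insulin_120",
        ):
            table[col] = cohort[col]
    table.index.name = "sample_id"
    info = {
        "n_markers_kept": marker_report.n_kept,
        "n_markers_removed": marker_report.n_removed,
        "n_samples_kept": sample_report.n_kept,
        "n_samples_removed": sample_report.n_removed,
        "n_snps_clumped": len(clumped),
        "norms_source": "in-sample" if norms is not None else "provided",
    }
    return table.reset_index(), info


def run_pipeline(
    config: PipelineConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> ReportBundle:
    """Execute the full chain and assemble the report tables."""
    cfg = config or PipelineConfig()
    ss = np.random.SeedSequence(seed)
    seeds = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(6)]
    s_sim, s_char, s_glm, s_inter, s_multi, _s_extra = seeds

    truth: TruthRecord | None = None
    if cfg.mode == "synthetic":
        bundle = simulate_study(
            n_samples=cfg.n_samples,
            n_markers=cfg.n_markers,
            n_genes=cfg.n_genes,
            snps_per_gene=cfg.snps_per_gene,
            seed=s_sim,
            beta_interaction_mcs=cfg.beta_interaction_mcs,
        )
        genotypes, weights, cohort, truth = (
            bundle.genotypes, bundle.weights, bundle.cohort, bundle.truth,
        )
    elif cfg.mode == "files":
        if not (cfg.vcf and cfg.weights and cfg.cohort):
            raise ValueError("files mode requires vcf, weights and cohort paths")
        genotypes = GenotypeMatrix.from_vcf(cfg.vcf)
        weights = pd.read_csv(cfg.weights, sep="\t")
        cohort = pd.read_csv(cfg.cohort)
        if cfg.truth:
            truth = TruthRecord.from_json(cfg.truth)
    else:
        raise ValueError(f"unknown mode {cfg.mode!r}")

    data, stage_info = build_analysis_table(
        genotypes, weights, cohort, window_bp=cfg.window_bp, n_pcs=cfg.n_pcs
    )

    characteristics = characteristics_table(
        data, skewed=cfg.skewed_variables,
        n_boot=cfg.n_boot_characteristics, seed=s_char,
    )

    # adjusted HRQoL by depressive type
    hrqol_rows = []
    for outcome in ("pcs", "mcs"):
        glm = BootstrapGLM(
            data,
            f'{outcome} ~ C(subtype, Treatment("none")) + '
            + " + ".join(_cov_terms(data, DEFAULT_COVARIATES)),
        )
        res = glm.fit(n_boot=cfg.n_boot_glm, seed=s_glm)
        means = res.adjusted_means("subtype")
        sub_terms = [t for t in res.params.index if t.startswith("C(subtype")]
        joint = res.wald_joint(sub_terms)
        for lev, row in means.iterrows():
            hrqol_rows.append(
                {
                    "outcome": outcome,
                    "subtype": lev,
                    "adjusted_mean": row["estimate"],
                    "ci_lower": row["ci_lower"],
                    "ci_upper": row["ci_upper"],
                    "p_overall": joint["pvalue"],
                }
            )
    hrqol_by_type = pd.DataFrame(hrqol_rows)

    # score vs HRQoL outcomes, crude and fully adjusted, with Bonferroni
    assoc_rows = []
    for outcome in HRQOL_OUTCOMES:
        for label, covs in (("crude", CRUDE_COVARIATES), ("fully_adjusted", DEFAULT_COVARIATES)):
            glm = BootstrapGLM(
                data, f"{outcome} ~ eprs_z + " + " + ".join(_cov_terms(data, covs))
            )
            res = glm.fit(n_boot=cfg.n_boot_glm, seed=s_glm)
            ci = res.conf_int().loc["eprs_z"]
            assoc_rows.append(
                {
                    "outcome": outcome,
                    "model": label,
                    "B": res.params["eprs_z"],
                    "ci_lower": ci["lower"],
                    "ci_upper": ci["upper"],
                    "p": res.pvalues["eprs_z"],
                }
            )
    eprs_associations = pd.DataFrame(assoc_rows)
    adj = eprs_associations.loc[eprs_associations["model"] == "fully_adjusted", "p"]
    eprs_associations.loc[adj.index, "p_bonferroni"] = adjust_bonferroni(
        adj.to_numpy(), m=len(HRQOL_OUTCOMES)
    )

    # predicted subtype probabilities per score category
    multi = MultinomialSubtypeModel(data, subtype="subtype", modifier="eprs_cat")
    multi_res = multi.fit(n_boot=cfg.n_boot_multinomial, seed=s_multi)
    subtype_probabilities = multi_res.predicted_probabilities()
    subtype_probability_differences = multi_res.category_differences()

    # subtype on continuous score: multinomial coefficients, crude and adjusted
    coef_rows = []
    for label, covs in (("crude", CRUDE_COVARIATES), ("adjusted", DEFAULT_COVARIATES)):
        mm = MultinomialSubtypeModel(
            data, subtype="subtype", modifier="eprs_z", covariates=covs
        )
        mr = mm.fit(n_boot=max(200, cfg.n_boot_multinomial // 5), seed=s_multi)
        coef_rows += _mnlogit_coef_rows(mm, mr, "eprs_z", label)
    eprs_subtype_coefficients = pd.DataFrame(coef_rows)

    # score vs metabolic markers
    metab_rows = []
    for outcome in METABOLIC_OUTCOMES:
        if outcome not in data.columns:
            continue
        for label, covs in (("crude", METABOLIC_CRUDE), ("adjusted", METABOLIC_FULL)):
            glm = BootstrapGLM(
                data, f"{outcome} ~ eprs_z + " + " + ".join(_cov_terms(data, covs))
            )
            res = glm.fit(n_boot=cfg.n_boot_glm, seed=s_glm)
            ci = res.conf_int().loc["eprs_z"]
            metab_rows.append(
                {
                    "outcome": outcome,
                    "model": label,
                    "B": res.params["eprs_z"],
                    "ci_lower": ci["lower"],
                    "ci_upper": ci["upper"],
                    "p": res.pvalues["eprs_z"],
                }
            )
    metabolic_associations = pd.DataFrame(metab_rows)

    # interaction analyses: depressive type x score on MCS and PCS
    inter_rows, slope_frames, contrast_frames, cell_frames = [], [], [], []
    interaction_results = {}
    for outcome in ("mcs", "pcs"):
        for mod, mod_label in (("eprs_cat", "categorical"), ("eprs_z", "continuous")):
            im = InteractionModel(data, outcome=outcome, modifier=mod)
            ir = im.fit(n_boot=cfg.n_boot_glm, seed=s_inter)
            interaction_results[(outcome, mod_label)] = ir
            inter_rows.append(
                {
                    "outcome": outcome,
                    "modifier": mod_label,
                    "wald_chi2": ir.interaction_test["statistic"],
                    "df": ir.interaction_test["df"],
                    "p_interaction": ir.interaction_pvalue,
                }
            )
            if mod_label == "continuous":
                sl = ir.stratum_slopes().reset_index()
                sl.insert(0, "outcome", outcome)
                slope_frames.append(sl)
            else:
                ct = ir.stratum_contrasts()
                ct.insert(0, "outcome", outcome)
                contrast_frames.append(ct)
                cm = ir.adjusted_cell_means()
                cm.insert(0, "outcome", outcome)
                cell_frames.append(cm)
    interaction_tests = pd.DataFrame(inter_rows)
    stratum_slopes = pd.concat(slope_frames, ignore_index=True)
    stratum_contrasts = pd.concat(contrast_frames, ignore_index=True)
    adjusted_cell_means = pd.concat(cell_frames, ignore_index=True)

    truth_comparison = None
    if truth is not None:
        mel_slope = stratum_slopes.query(
            "outcome == 'mcs' and subtype == 'melancholic'"
        ).iloc[0]
        counts = data["subtype"].value_counts()
        truth_comparison = {
            "beta_interaction_mcs_truth": truth.beta_interaction_mcs,
            "melancholic_stratum_slope_mcs": float(mel_slope["estimate"]),
            "melancholic_stratum_slope_ci": [
                float(mel_slope["ci_lower"]), float(mel_slope["ci_upper"]),
            ],
            "subtype_prevalence_truth": list(truth.subtype_prevalence),
            "subtype_counts_scored": {
                str(k): int(v) for k, v in counts.items()
            },
            "subtype_agreement": float(
                (data["subtype"].astype(str) == data["truth_subtype"]).mean()
            )
            if "truth_subtype" in data.columns
            else None,
        }

    metadata = {
        "package_version": __version__,
        "seed": seed,
        "stage_seeds": {
            "simulate": s_sim, "characteristics": s_char,
            "glm": s_glm, "interaction": s_inter, "multinomial": s_multi,
        },
        "config": asdict(cfg),
        "stage_info": stage_info,
        "n_analysis": int(len(data)),
    }

    bundle_out = ReportBundle(
        characteristics=characteristics,
        hrqol_by_type=hrqol_by_type,
        eprs_associations=eprs_associations,
        subtype_probabilities=subtype_probabilities,
        subtype_probability_differences=subtype_probability_differences,
        eprs_subtype_coefficients=eprs_subtype_coefficients,
        metabolic_associations=metabolic_associations,
        interaction_tests=interaction_tests,
        stratum_slopes=stratum_slopes,
        stratum_contrasts=stratum_contrasts,
        adjusted_cell_means=adjusted_cell_means,
        analysis_table=data,
        metadata=metadata,
        truth_comparison=truth_comparison,
    )
    if out_dir is not None:
        bundle_out.save(out_dir)
        if cfg.make_plots:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            ax = interaction_results[("mcs", "continuous")].plot_stratum_slopes()
            ax.figure.savefig(Path(out_dir) / "stratum_slopes_mcs.png", dpi=120)
            plt.close(ax.figure)
    return bundle_out


def _cov_terms(data: pd.DataFrame, covariates) -> list[str]:
    from .inference import _term

    return [_term(data, c) for c in covariates if c in data.columns]


def _mnlogit_coef_rows(model, results, term: str, label: str) -> list[dict]:
    """Rows of the continuous-score coefficient per subtype logit."""
    j = model.exog_names.index(term)
    params = np.asarray(results.params)
    rows = []
    for k, lev in enumerate(model.subtype_levels[1:]):
        rows.append(
            {
                "subtype": lev,
                "model": label,
                "B": float(params[j, k]),
            }
        )
    return rows
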