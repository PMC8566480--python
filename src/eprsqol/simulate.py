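"""Synthetic study generator: genotypes, SNP weight table, phenotype cohort.

Emulates a birth-cohort study of roughly 1,558 older adults in which a brain
expression-weighted polygenic network score modifies the association between
melancholic depressive symptoms and the mental component of health-related
quality of life.  Every generated bundle carries a :class:`TruthRecord` with
the generating parameters so downstream stages can be tested against known
ground truth.

Generating model (per sample):

* allele dosages from within-block copy-with-mutation haplotypes (tunable LD,
  exact marginal allele frequencies),
* a ground-truth network score: the standardized signed weighted dosage sum
  over the LD-clumped weight table (the same functional the scorer computes),
* latent mental/physical component scores::

      MCS* = baseline + main(subtype) + beta_int * score_z * 1[melancholic]
             + covariate effects + Normal(0, noise_sd)

* SF-36 item responses discretized monotonically from domain latents that are
  affine in MCS*/PCS*, and BDI items drawn per subtype so the dominant
  subscale mean exceeds the other by a configurable margin.

Default parameter values reproduce the marginal structure of the emulated
cohort: subtype prevalences 1262/199/97 of 1558, component baselines 56.4 /
49.2 with subtype shifts matching the reported group means, age 61.5 (2.9),
56% women.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .score import compute_eprs, ld_clump
from .instruments import sf36

__all__ = [
    "TruthRecord",
    "StudyBundle",
    "generate_genotypes",
    "generate_weight_table",
    "generate_cohort",
    "simulate_study",
]

# marginal defaults matching the emulated cohort's characteristics table
DEFAULT_PREVALENCE = (1262 / 1558, 199 / 1558, 97 / 1558)
DEFAULT_MAIN_MCS = {"non_melancholic": -13.1, "melancholic": -11.8}
DEFAULT_MAIN_PCS = {"non_melancholic": -7.1, "melancholic": -3.4}
BASELINE_MCS = 56.4
BASELINE_PCS = 49.2

# centers used when applying covariate effects, so baselines stay interpretable
COVARIATE_CENTERS = {"age": 61.5, "bmi": 27.7, "ltpa_met_h_wk": 30.0, "female": 0.0}

MENTAL_DOMAINS = ["vt", "sf", "re", "mh"]
PHYSICAL_DOMAINS = ["pf", "rp", "bp", "gh"]
# domain latent = center + DOMAIN_SCALE * (component - 50) + noise.  Centers
# and scale keep the domain targets inside the 0-100 item range for the
# realized latent spread, so the latent -> scored-component mapping stays
# affine (no floor/ceiling compression); item realism is deliberately not a
# goal — the scorer's round trip is.
DOMAIN_CENTERS = {d: 50.0 for d in ["pf", "rp", "bp", "gh", "vt", "sf", "re", "mh"]}
DOMAIN_SCALE = 1.2
DOMAIN_NOISE_SD = 5.0
ITEM_NOISE_SD = 7.5

# BDI item-endorsement probabilities (per 0-3 rating drawn Binomial(3, p)):
# the dominant subscale of a depressed respondent, the other subscale, and
# the rate for screen-negative respondents.
BDI_P_DOMINANT = 0.45
BDI_P_OTHER = 0.15
BDI_P_NONE = 0.05


@dataclass
class TruthRecord:
    """Ground-truth generating parameters of a synthetic study."""

    maf_per_marker: np.ndarray
    ld_block_assignments: np.ndarray
    true_score_weights: dict[str, float]  # snp_id -> signed weight (post-clump)
    subtype_prevalence: tuple[float, float, float]  # none, non-mel, melancholic
    beta_interaction_mcs: float
    beta_main_depression: dict[str, dict[str, float]]  # subtype -> {mcs, pcs}
    covariate_effects: dict[str, float]  # covariate -> MCS shift per unit
    noise_sd: float
    seed: int
    baseline_mcs: float = BASELINE_MCS
    baseline_pcs: float = BASELINE_PCS

    def __post_init__(self) -> None:
        prev = np.asarray(self.subtype_prevalence, dtype=float)
        if prev.shape != (3,) or (prev < 0).any() or abs(prev.sum() - 1) > 1e-9:
            raise ValueError("subtype_prevalence must be 3 probabilities summing to 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        self.maf_per_marker = np.asarray(self.maf_per_marker, dtype=float)
        self.ld_block_assignments = np.asarray(self.ld_block_assignments)
        if len(self.maf_per_marker) != len(self.ld_block_assignments):
            raise ValueError("every marker needs exactly one block assignment")

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["maf_per_marker"] = self.maf_per_marker.tolist()
        d["ld_block_assignments"] = self.ld_block_assignments.tolist()
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        d = json.loads(Path(path).read_text())
        d["subtype_prevalence"] = tuple(d["subtype_prevalence"])
        return cls(**d)


def generate_genotypes(
    n_samples: int,
    n_markers: int,
    block_size: int = 10,
    maf_range: tuple[float, float] = (0.05, 0.5),
    missing_rate: float = 0.01,
    seed: int = 0,
    switch_prob: float = 0.1,
) -> tuple[GenotypeMatrix, np.ndarray, np.ndarray]:
    """Simulate hard-call dosages with block-wise linkage disequilibrium.

    Within a block all markers share one allele frequency (drawn uniformly
    from ``maf_range``); each haplotype copies the previous marker's allele
    with probability ``1 - switch_prob`` and redraws it otherwise, giving a
    correlation of ``(1 - switch_prob)`` per marker step while keeping the
    marginal frequency exact.  Blocks are independent and laid out on
    chromosomes 1-22 with 40 kb marker spacing and 1 Mb between blocks.

    Returns the genotype matrix plus the per-marker true MAF and block label
    arrays (for the :class:`TruthRecord`).
    """
    if n_samples <= 0 or n_markers <= 0 or block_size <= 0:
        raise ValueError("dimensions must be positive")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    if not (0 <= missing_rate <= 0.2):
        raise ValueError("missing_rate must be in [0, 0.2]")
    rng = np.random.default_rng(seed)

    n_blocks = int(np.ceil(n_markers / block_size))
    block_mafs = rng.uniform(lo, hi, size=n_blocks)
    blocks = np.repeat(np.arange(n_blocks), block_size)[:n_markers]
    mafs = block_mafs[blocks]

    hap = np.empty((2 * n_samples, n_markers), dtype=np.int8)
    for j in range(n_markers):
        fresh = rng.random(2 * n_samples) < mafs[j]
        if j > 0 and blocks[j] == blocks[j - 1]:
            copy = rng.random(2 * n_samples) >= switch_prob
            hap[:, j] = np.where(copy, hap[:, j - 1], fresh)
        else:
            hap[:, j] = fresh
    dosages = (hap[0::2] + hap[1::2]).astype(float)
    if missing_rate > 0:
        dosages[rng.random(dosages.shape) < missing_rate] = np.nan

    # marker map: blocks tiled over chromosomes, non-ambiguous allele pairs
    chrom = (blocks % 22) + 1
    block_rank = blocks // 22
    within = np.arange(n_markers) - blocks * block_size
    pos = 1_000_000 + block_rank * 1_000_000 + within * 40_000
    pairs = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]
    pick = rng.integers(0, len(pairs), size=n_markers)
    swap = rng.random(n_markers) < 0.5
    markers = pd.DataFrame(
        {
            "snp_id": [f"snp{i + 1}" for i in range(n_markers)],
            "chrom": chrom,
            "pos": pos,
            "ref": np.where(swap, [pairs[p][1] for p in pick], [pairs[p][0] for p in pick]),
            "alt": np.where(swap, [pairs[p][0] for p in pick], [pairs[p][1] for p in pick]),
        }
    )
    samples = [f"s{i + 1}" for i in range(n_samples)]
    return GenotypeMatrix(dosages, samples, markers), mafs, blocks


def generate_weight_table(
    genotypes: GenotypeMatrix,
    n_genes: int = 498,
    snps_per_gene: int = 8,
    beta_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """SNP weight table over the genotype panel.

    Consecutive runs of ``snps_per_gene`` markers form a gene; each SNP gets
    an expression effect size beta ~ Normal(0, beta_sd), a gene-level
    co-expression sign in {+1, -1}, and a clumping p-value ~ Uniform(0, 1).
    Effect allele is the panel's alternate allele.
    """
    if n_genes <= 0 or snps_per_gene <= 0 or beta_sd <= 0:
        raise ValueError("counts and beta_sd must be positive")
    n_snps = n_genes * snps_per_gene
    if n_snps > genotypes.n_markers:
        raise ValueError(
            f"requested {n_snps} SNPs but panel has {genotypes.n_markers} markers"
        )
    rng = np.random.default_rng(seed)
    m = genotypes.markers.iloc[:n_snps]
    genes = np.repeat([f"gene{g + 1}" for g in range(n_genes)], snps_per_gene)
    signs = np.repeat(rng.choice([-1, 1], size=n_genes), snps_per_gene)
    return pd.DataFrame(
        {
            "snp_id": m["snp_id"].to_numpy(),
            "chrom": m["chrom"].to_numpy(),
            "pos": m["pos"].to_numpy(),
            "effect_allele": m["alt"].to_numpy(),
            "other_allele": m["ref"].to_numpy(),
            "gene": genes,
            "beta": rng.normal(0.0, beta_sd, size=n_snps),
            "sign": signs,
            "clump_p": rng.uniform(1e-8, 1.0, size=n_snps),
        }
    )


def make_truth(
    genotypes: GenotypeMatrix,
    weights: pd.DataFrame,
    mafs: np.ndarray,
    blocks: np.ndarray,
    *,
    beta_interaction_mcs: float = -3.4,
    subtype_prevalence: tuple[float, float, float] = DEFAULT_PREVALENCE,
    beta_main_depression: Mapping[str, Mapping[str, float]] | None = None,
    covariate_effects: Mapping[str, float] | None = None,
    noise_sd: float = 8.0,
    seed: int = 0,
    window_bp: int = 250_000,
) -> TruthRecord:
    """Assemble a TruthRecord; the true score weights are the clumped set."""
    clumped = ld_clump(weights, window_bp=window_bp)
    w = {
        r.snp_id: float(r.beta * r.sign) for r in clumped.itertuples(index=False)
    }
    if beta_main_depression is None:
        beta_main_depression = {
            "non_melancholic": {
                "mcs": DEFAULT_MAIN_MCS["non_melancholic"],
                "pcs": DEFAULT_MAIN_PCS["non_melancholic"],
            },
            "melancholic": {
                "mcs": DEFAULT_MAIN_MCS["melancholic"],
                "pcs": DEFAULT_MAIN_PCS["melancholic"],
            },
        }
    if covariate_effects is None:
        covariate_effects = {"age": -0.1, "female": -0.5, "bmi": -0.05}
    return TruthRecord(
        maf_per_marker=mafs,
        ld_block_assignments=blocks,
        true_score_weights=w,
        subtype_prevalence=tuple(subtype_prevalence),
        beta_interaction_mcs=float(beta_interaction_mcs),
        beta_main_depression={k: dict(v) for k, v in beta_main_depression.items()},
        covariate_effects=dict(covariate_effects),
        noise_sd=float(noise_sd),
        seed=int(seed),
    )


def _draw_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Covariate marginals follow the emulated cohort's characteristics table."""
    df = pd.DataFrame(index=range(n))
    df["age"] = rng.normal(61.5, 2.9, n)
    df["sex"] = np.where(rng.random(n) < 0.562, "female", "male")
    df["smoking"] = rng.choice(["never", "former", "current"], n, p=[0.43, 0.33, 0.24])
    df["alcohol"] = rng.choice(
        ["never_or_quit", "lt_weekly", "weekly"], n, p=[0.07, 0.43, 0.50]
    )
    df["ses"] = rng.choice(
        ["high_official", "low_official", "self_employed", "manual"],
        n,
        p=[0.145, 0.43, 0.095, 0.33],
    )
    df["n_chronic"] = rng.choice([0, 1, 2, 3], n, p=[0.31, 0.31, 0.25, 0.13])
    df["bmi"] = np.clip(rng.normal(27.7, 4.6, n), 16.0, None)
    n_act = 1 + rng.binomial(2, 0.5, n)
    for i in range(1, 4):
        active = (n_act >= i).astype(float)
        df[f"ltpa_met_{i}"] = np.round(rng.uniform(3, 9, n), 1) * active
        df[f"ltpa_hours_{i}"] = np.round(rng.uniform(0.5, 1.5, n), 2) * active
        df[f"ltpa_freq_{i}"] = np.round(rng.uniform(1, 4, n), 1) * active
    # OGTT: log-normal marginals, 2-h and 30-min values tied to fasting level
    fg = np.exp(rng.normal(np.log(5.8), 0.12, n))
    df["glucose_0"] = np.round(fg, 2)
    df["glucose_30"] = np.round(fg * np.exp(rng.normal(np.log(1.6), 0.15, n)), 2)
    df["glucose_120"] = np.round(fg * np.exp(rng.normal(np.log(1.33), 0.28, n)), 2)
    ins0 = np.exp(rng.normal(np.log(8.0), 0.5, n))
    df["insulin_0"] = np.round(ins0, 1)
    df["insulin_30"] = np.round(ins0 * np.exp(rng.normal(np.log(7.0), 0.4, n)), 1)
    df["insulin_120"] = np.round(ins0 * np.exp(rng.normal(np.log(7.0), 0.5, n)), 1)
    return df


def _covariate_shift(df: pd.DataFrame, effects: Mapping[str, float]) -> np.ndarray:
    shift = np.zeros(len(df))
    for name, beta in effects.items():
        if name == "female":
            x = (df["sex"] == "female").to_numpy(dtype=float)
        else:
            x = df[name].to_numpy(dtype=float)
        shift += beta * (x - COVARIATE_CENTERS.get(name, 0.0))
    return shift


def _sf36_items(
    mcs: np.ndarray, pcs: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """Monotone discretization of domain latents into item response codes."""
    n = len(mcs)
    out = {}
    comp = {**{d: mcs for d in MENTAL_DOMAINS}, **{d: pcs for d in PHYSICAL_DOMAINS}}
    for item in range(1, sf36.N_ITEMS + 1):
        domain, rec = sf36.ITEM_TABLE[item]
        rec_arr = np.asarray(rec)
        if domain is None:
            codes = rng.integers(1, len(rec) + 1, size=n)
        else:
            lat = (
                DOMAIN_CENTERS[domain]
                + DOMAIN_SCALE * (comp[domain] - 50.0)
                + rng.normal(0, DOMAIN_NOISE_SD, n)
            )
            target = lat + rng.normal(0, ITEM_NOISE_SD, n)
            codes = np.abs(target[:, None] - rec_arr[None, :]).argmin(axis=1) + 1
        out[f"sf36_{item}"] = codes.astype(int)
    return pd.DataFrame(out)


def _bdi_items(
    subtype: np.ndarray,
    rng: np.random.Generator,
    mel_items: tuple[int, ...],
    p_dominant: float = BDI_P_DOMINANT,
    p_other: float = BDI_P_OTHER,
    p_none: float = BDI_P_NONE,
) -> pd.DataFrame:
    n = len(subtype)
    mel_set = set(mel_items)
    probs = np.full((n, 21), p_none)
    for j in range(21):
        is_mel_item = (j + 1) in mel_set
        probs[:, j] = np.where(
            subtype == "melancholic",
            p_dominant if is_mel_item else p_other,
            np.where(
                subtype == "non_melancholic",
                p_other if is_mel_item else p_dominant,
                p_none,
            ),
        )
    items = rng.binomial(3, probs)
    return pd.DataFrame({f"bdi_{j + 1}": items[:, j] for j in range(21)})


def generate_cohort(
    genotypes: GenotypeMatrix,
    weights: pd.DataFrame,
    truth: TruthRecord,
    mel_items: tuple[int, ...] = (1, 3, 4, 5, 6, 11, 12, 16, 18),
) -> pd.DataFrame:
    """Phenotype table for the given genotype panel under the truth parameters.

    Observable columns: 21 BDI items, 36 SF-36 items, covariates, LTPA
    activity slots and OGTT values.  Ground-truth per-sample columns are
    included with a ``truth_`` prefix (intended subtype, latent components,
    standardized score) for validation; analysis stages ignore them.
    """
    missing = set(weights["snp_id"]) - set(genotypes.markers["snp_id"])
    if missing:
        raise ValueError(f"weights refer to {len(missing)} markers absent from panel")
    rng = np.random.default_rng(truth.seed)
    n = genotypes.n_samples

    subtype = rng.choice(
        np.array(["none", "non_melancholic", "melancholic"]),
        size=n,
        p=np.asarray(truth.subtype_prevalence),
    )
    cov = _draw_covariates(n, rng)

    # ground-truth modifier: standardized clumped signed score
    clump_ids = set(truth.true_score_weights)
    wsub = weights[weights["snp_id"].isin(clump_ids)]
    raw = compute_eprs(genotypes, wsub)
    score_z = ((raw - raw.mean()) / raw.std(ddof=1)).to_numpy()

    is_mel = subtype == "melancholic"
    is_nonmel = subtype == "non_melancholic"
    main_mcs = (
        is_nonmel * truth.beta_main_depression["non_melancholic"]["mcs"]
        + is_mel * truth.beta_main_depression["melancholic"]["mcs"]
    )
    main_pcs = (
        is_nonmel * truth.beta_main_depression["non_melancholic"]["pcs"]
        + is_mel * truth.beta_main_depression["melancholic"]["pcs"]
    )
    shift = _covariate_shift(cov, truth.covariate_effects)
    mcs_lat = (
        truth.baseline_mcs
        + main_mcs
        + truth.beta_interaction_mcs * score_z * is_mel
        + shift
        + rng.normal(0, truth.noise_sd, n)
    )
    pcs_lat = truth.baseline_pcs + main_pcs + rng.normal(0, truth.noise_sd, n)

    sf = _sf36_items(mcs_lat, pcs_lat, rng)
    bdi = _bdi_items(subtype, rng, mel_items)

    out = pd.concat(
        [
            pd.DataFrame({"sample_id": genotypes.samples}),
            bdi,
            sf,
            cov.reset_index(drop=True),
        ],
        axis=1,
    )
    out["truth_subtype"] = subtype
    out["truth_mcs"] = mcs_lat
    out["truth_pcs"] = pcs_lat
    out["truth_score_z"] = score_z
    return out


@dataclass
class StudyBundle:
    genotypes: GenotypeMatrix
    weights: pd.DataFrame
    cohort: pd.DataFrame
    truth: TruthRecord

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.genotypes.to_vcf(out / "genotypes.vcf")
        self.genotypes.to_tsv(out / "genotypes.tsv")
        self.weights.to_csv(out / "weights.tsv", sep="\t", index=False)
        self.cohort.to_csv(out / "cohort.csv", index=False)
        self.truth.to_json(out / "truth.json")


def simulate_study(
    n_samples: int = 1558,
    n_markers: int = 4000,
    n_genes: int = 498,
    snps_per_gene: int = 8,
    seed: int = 0,
    **truth_kwargs,
) -> StudyBundle:
    """One-call generation of a full synthetic study bundle.

    Sub-seeds for the genotype, weight and cohort stages are derived from
    ``seed`` so a bundle is reproducible from the single integer.
    """
    ss = np.random.SeedSequence(seed)
    s_geno, s_w, s_cohort = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3))
    genotypes, mafs, blocks = generate_genotypes(n_samples, n_markers, seed=s_geno)
    weights = generate_weight_table(
        genotypes, n_genes=n_genes, snps_per_gene=snps_per_gene, seed=s_w
    )
    truth = make_truth(genotypes, weights, mafs, blocks, seed=s_cohort, **truth_kwargs)
    cohort = generate_cohort(genotypes, weights, truth)
    return StudyBundle(genotypes, weights, cohort, truth)
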