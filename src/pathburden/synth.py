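"""Synthetic SCLC-like cohorts with the statistical structure the pipeline
assumes, plus ground truth for parameter-recovery testing.

The generative model, per sample s:

* mutation counts: gene g gets Poisson(lambda_g * m_s) variants, with
  per-gene background rates lambda_g log-normal across genes and a
  per-sample rate multiplier m_s log-normal across samples (tumors differ
  in mutational background by far more than Poisson noise; the multiplier
  also makes pathway-burden groups differ in total burden, as real
  cohorts do);
* grouping: the causal gene set's burden is median-split (strictly above
  = mut-high) — the realized assignment is the ground-truth group;
* survival: Weibull(shape k, scale lam) baseline with the hazard
  multiplied by exp(beta) for mut-high samples; independent uniform
  censoring on [0, c_max] with c_max solved numerically so the expected
  censoring fraction hits the configured target;
* expression: Normal(0, 1) log-scale values with a +delta shift (in SD
  units) on causal-pathway genes in mut-high samples;
* drug response: lnIC50 ~ Normal(mu_d, sigma_d) per drug with a
  configured shift added for mut-low samples on the sensitive drug panel
  (mut-low less drug-sensitive, i.e. higher lnIC50).

A single master seed spawns independent substreams per table, so adding
or regenerating one table never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .burden import GroupAssignment, compute_burden, dichotomize
from .io import (
    ClinicalTable,
    DrugResponseTable,
    ExpressionMatrix,
    GeneSetCollection,
    MutationTable,
)

_VARIANT_CLASSES = np.array(
    ["Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Del",
     "Frame_Shift_Ins", "Splice_Site", "In_Frame_Del"]
)
_VARIANT_PROBS = np.array([0.70, 0.10, 0.07, 0.05, 0.05, 0.03])


@dataclass
class SynthConfig:
    """Study-condition defaults: a chemotherapy-treated SCLC-like cohort of
    96 patients, a ~1000-gene mutation universe with a 30-gene causal
    pathway whose burden median lands near 2, a protective group effect of
    HR 0.5, and ~30% censoring."""

    n_samples: int = 96
    gene_universe: int = 1000
    rate_median: float = 0.05        # median per-gene Poisson rate
    rate_sigma: float = 0.8          # log-SD of per-gene rates
    sample_rate_sigma: float = 0.5   # log-SD of the per-sample multiplier
    causal_set_name: str = "FA_METABOLISM_LIKE"
    causal_set_size: int = 30
    beta: float = float(np.log(0.5))  # log-HR for mut-high
    weibull_shape: float = 1.2
    weibull_scale: float = 20.0       # months
    censoring_target: float = 0.30
    n_expr_genes: int = 2000
    expr_delta: float = 1.0           # SD shift on causal genes in mut-high
    n_drugs: int = 20
    n_shifted_drugs: int = 5
    drug_shift: float = 0.5           # lnIC50 added for mut-low on shifted drugs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 10:
            raise ValueError("n_samples must be >= 10")
        if not 0 <= self.censoring_target <= 0.9:
            raise ValueError("censoring target must be in [0, 0.9]")
        for nm in ("rate_median", "weibull_shape", "weibull_scale"):
            if getattr(self, nm) <= 0:
                raise ValueError(f"{nm} must be > 0")
        if self.causal_set_size > self.gene_universe:
            raise ValueError("causal set larger than the gene universe")


@dataclass
class GroundTruth:
    groups: GroupAssignment
    beta: float
    expr_delta: float
    causal_set: frozenset
    causal_set_name: str
    c_max: float
    shifted_drugs: list


@dataclass
class SynthCohort:
    mutations: MutationTable
    clinical: ClinicalTable
    expression: ExpressionMatrix
    drugs: DrugResponseTable
    gene_sets: GeneSetCollection     # contains the causal set
    truth: GroundTruth
    config: SynthConfig

    @property
    def roster(self) -> list[str]:
        return list(self.clinical.samples)


def _gene_names(n: int) -> list[str]:
    return [f"G{k:04d}" for k in range(n)]


def _censoring_cmax(times_surv: np.ndarray, target: float) -> float:
    """c_max for uniform censoring on [0, c_max] hitting the target
    expected censoring fraction, given the drawn event times.

    P(censored) = P(U*c_max < T) = mean_i min(T_i / c_max, 1) for
    U ~ Uniform(0,1); monotone decreasing in c_max, solved by bisection.
    """
    if target <= 0:
        return np.inf

    def frac(c):
        return float(np.mean(np.minimum(times_surv / c, 1.0))) - target

    lo = float(times_surv.min()) * 1e-3 + 1e-9
    hi = float(times_surv.max()) * 2
    while frac(hi) > 0:
        hi *= 2
    return float(optimize.brentq(frac, lo, hi, xtol=1e-8))


def generate_cohort(config: SynthConfig) -> SynthCohort:
    """Draw one synthetic cohort; bit-identical for equal configs."""
    cfg = config
    streams = np.random.SeedSequence(cfg.seed).spawn(6)
    rng_mut, rng_surv, rng_cens, rng_expr, rng_drug, rng_cov = (
        np.random.default_rng(s) for s in streams
    )
    roster = [f"S{k:03d}" for k in range(cfg.n_samples)]
    genes = _gene_names(cfg.gene_universe)
    causal_genes = frozenset(genes[: cfg.causal_set_size])

    # --- mutations -------------------------------------------------------
    lam_g = cfg.rate_median * np.exp(rng_mut.normal(0, cfg.rate_sigma, cfg.gene_universe))
    m_s = np.exp(rng_mut.normal(0, cfg.sample_rate_sigma, cfg.n_samples))
    counts = rng_mut.poisson(np.outer(m_s, lam_g))  # samples x genes
    si, gi = np.nonzero(counts)
    reps = counts[si, gi]
    sample_col = np.repeat(np.array(roster)[si], reps)
    gene_col = np.repeat(np.array(genes)[gi], reps)
    vclass = rng_mut.choice(_VARIANT_CLASSES, size=len(sample_col), p=_VARIANT_PROBS)
    records = pd.DataFrame(
        {
            "sample_id": sample_col,
            "gene": gene_col,
            "variant_class": vclass,
            "protein_change": pd.NA,
        }
    )
    mutations = MutationTable(records)
    gene_sets = GeneSetCollection({cfg.causal_set_name: causal_genes},
                                  source="synthetic")

    # --- grouping (ground truth = realized median split) -----------------
    burden = compute_burden(mutations, gene_sets, roster)
    groups = dichotomize(burden.column(cfg.causal_set_name), cfg.causal_set_name)
    z = groups.indicator().to_numpy(float)

    # --- survival ---------------------------------------------------------
    # S(t) = exp(-(t/scale)^shape * exp(beta*z)): inverse-CDF sampling
    u = rng_surv.uniform(size=cfg.n_samples)
    t_event = cfg.weibull_scale * (-np.log(u) / np.exp(cfg.beta * z)) ** (
        1.0 / cfg.weibull_shape
    )
    if cfg.censoring_target > 0:
        c_max = _censoring_cmax(t_event, cfg.censoring_target)
        t_cens = rng_cens.uniform(0, c_max, cfg.n_samples)
    else:
        c_max = np.inf
        t_cens = np.full(cfg.n_samples, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-6)

    age = np.clip(rng_cov.normal(60, 8, cfg.n_samples), 30, 85).round(1)
    sex = rng_cov.choice(["male", "female"], size=cfg.n_samples, p=[0.85, 0.15])
    stage = rng_cov.choice(["early", "advanced"], size=cfg.n_samples, p=[0.3, 0.7])
    prior = rng_cov.choice([0, 1], size=cfg.n_samples, p=[0.86, 0.14])
    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "time": time,
                "event": event,
                "age": age,
                "sex": sex,
                "stage": stage,
                "prior_chemo": prior,
            },
            index=pd.Index(roster, name="sample_id"),
        ),
        covariate_kinds={
            "age": "continuous",
            "sex": "binary",
            "stage": "categorical",
            "prior_chemo": "binary",
        },
        levels={"stage": ["early", "advanced"]},
        endpoint="OS",
    )

    # --- expression -------------------------------------------------------
    n_expr = cfg.n_expr_genes
    expr_genes = (genes + _gene_names(n_expr)[cfg.gene_universe:])[:n_expr] \
        if n_expr > cfg.gene_universe else genes[:n_expr]
    X = rng_expr.normal(0, 1, (n_expr, cfg.n_samples))
    causal_rows = [i for i, g in enumerate(expr_genes) if g in causal_genes]
    X[np.ix_(causal_rows, np.nonzero(z == 1)[0])] += cfg.expr_delta
    expression = ExpressionMatrix(
        pd.DataFrame(X, index=expr_genes, columns=roster)
    )

    # --- drug response ----------------------------------------------------
    drug_names = [f"DRUG{k:02d}" for k in range(cfg.n_drugs)]
    shifted = drug_names[: cfg.n_shifted_drugs]
    mu_d = rng_drug.normal(3.0, 1.0, cfg.n_drugs)
    rows = []
    for k, d in enumerate(drug_names):
        vals = rng_drug.normal(mu_d[k], 1.0, cfg.n_samples)
        if d in shifted:
            vals = vals + cfg.drug_shift * (1 - z)  # mut-low less sensitive
        rows.append(pd.DataFrame({"cell_line": roster, "drug": d, "ln_ic50": vals}))
    drugs = DrugResponseTable(pd.concat(rows, ignore_index=True))

    truth = GroundTruth(groups, cfg.beta, cfg.expr_delta, causal_genes,
                        cfg.causal_set_name, float(c_max), shifted)
    return SynthCohort(mutations, clinical, expression, drugs, gene_sets, truth, cfg)


def generate_null_geneset_universe(
    n_sets: int,
    size_range: tuple[int, int] = (10, 100),
    universe=None,
    seed: int | None = None,
    planted: tuple[str, frozenset] | None = None,
) -> GeneSetCollection:
    """Random gene subsets standing in for a pathway database, optionally
    with one planted (causal) set."""
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    universe = list(universe) if universe is not None else _gene_names(1000)
    rng = np.random.default_rng(seed)
    lo, hi = size_range
    sets: dict[str, frozenset] = {}
    if planted is not None:
        sets[planted[0]] = frozenset(planted[1])
    for k in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(universe), size=size, replace=False)
        sets[f"NULL_SET_{k:04d}"] = frozenset(universe[i] for i in members)
    return GeneSetCollection(sets, source="synthetic-null")
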