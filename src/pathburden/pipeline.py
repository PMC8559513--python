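"""End-to-end orchestration: discovery (burden -> screen -> concordance),
verification on a held-out cohort, mechanism stages (TMB, per-gene
comparisons, DGE, GSEA, per-sample scoring, pathway survival), and drug
stages (lnIC50 group tests, connectivity scoring), driven by one YAML
config with stage toggles.

Verification cohorts reuse the grouping RULE, not the discovery
threshold: the chosen gene set is median-split within the verification
cohort itself, so each cohort uses its own median burden.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .assoc import compare_top_genes, wilcoxon_ranksum
from .burden import compute_burden, compute_tmb, dichotomize
from .cmap import ReferenceRankMatrix, TagSignature, connectivity_score
from .enrichment import (
    dge_moderated_t,
    diff_pathway_expression,
    gsea_preranked,
    pathway_score_survival,
    ssgsea_score,
)
from .io import (
    read_clinical,
    read_drug_response,
    read_expression,
    read_gmt,
    read_mutation_table,
)
from .screen import concordance_filter, screen_cohort
from .survival import cox_fit, km_fit_groups

logger = logging.getLogger(__name__)


@dataclass
class CohortSpec:
    name: str
    mutations: str
    clinical: str
    endpoint: str = "OS"
    clinical_schema: dict = field(default_factory=dict)
    role: str = "discovery"  # or "verification"


@dataclass
class RunConfig:
    cohorts: list[CohortSpec]
    gmt: str
    out_dir: str
    alpha: float = 0.05
    counting_mode: str = "variants"
    seed: int = 0
    chosen_set: str | None = None     # gene set carried into verification/mechanism
    expression: str | None = None     # path, genes x samples
    expression_cohort: str | None = None
    drug_response: str | None = None
    cmap_refs: str | None = None      # rank matrix TSV
    cmap_meta: str | None = None
    n_gsea_perm: int = 1000
    stages: dict = field(
        default_factory=lambda: {
            "screen": True, "verify": True, "mechanism": True, "drugs": True,
        }
    )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cohorts = [CohortSpec(**c) for c in raw.pop("cohorts")]
        stages = {**cls.__dataclass_fields__["stages"].default_factory(),
                  **raw.pop("stages", {})}
        return cls(cohorts=cohorts, stages=stages, **raw)

    def validate(self) -> None:
        disc = [c for c in self.cohorts if c.role == "discovery"]
        if any(self.stages.values()) and not disc:
            raise ValueError("at least one discovery cohort is required")


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory.

    Every stage writes TSV outputs; ``run_log.json`` records the package
    version, seed, alpha, counting mode, input checksums and the stages
    executed.  A stage failure aborts the run (partial outputs retained).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "alpha": config.alpha,
        "counting_mode": config.counting_mode,
        "stages": config.stages,
        "defaults": {
            "split": "median-strict (mut_high iff burden > cohort median)",
            "ties": "efron",
            "multiplicity": "none (cross-cohort replication)",
            "gsea_weight": 1.0,
            "ssgsea_alpha": 0.25,
        },
        "inputs": {},
    }
    stage = "config"
    try:
        gene_sets = read_gmt(config.gmt) if any(config.stages.values()) else None
        if gene_sets is not None:
            manifest["inputs"][config.gmt] = _checksum(config.gmt)
        cohort_data = {}
        for c in config.cohorts:
            mut = read_mutation_table(c.mutations)
            clin = read_clinical(c.clinical, c.clinical_schema)
            clin.endpoint = c.endpoint
            cohort_data[c.name] = (c, mut, clin)
            manifest["inputs"][c.mutations] = _checksum(c.mutations)
            manifest["inputs"][c.clinical] = _checksum(c.clinical)

        chosen = config.chosen_set
        if config.stages.get("screen"):
            stage = "screen"
            reports, skipped = {}, {}
            for name, (c, mut, clin) in cohort_data.items():
                if c.role != "discovery":
                    continue
                burden = compute_burden(mut, gene_sets, clin.samples,
                                        mode=config.counting_mode)
                rows, skip = screen_cohort(burden, clin, cohort_id=name,
                                           endpoint=c.endpoint, alpha=config.alpha)
                rows.to_csv(out / f"screen_{name}.tsv", sep="\t", index=False)
                reports[name] = rows
                skipped[name] = skip
            if len(reports) >= 2:
                report = concordance_filter(reports, alpha=config.alpha,
                                            skipped=skipped)
                report.concordant.to_csv(out / "concordant_sets.tsv",
                                         sep="\t", index=False)
                report.discordant.to_csv(out / "discordant_sets.tsv",
                                         sep="\t", index=False)
                if chosen is None and len(report.concordant):
                    chosen = report.concordant["set_name"].iloc[0]
            manifest["chosen_set"] = chosen

        if config.stages.get("verify") and chosen is not None:
            stage = "verify"
            ver_rows = []
            for name, (c, mut, clin) in cohort_data.items():
                if c.role != "verification":
                    continue
                burden = compute_burden(mut, gene_sets, clin.samples,
                                        mode=config.counting_mode)
                grp = dichotomize(burden.column(chosen), chosen)
                clin2 = clin.with_covariate("group", grp.labels, kind="binary")
                res = cox_fit(clin2, ["group"])[0]
                curves = km_fit_groups(clin.data["time"], clin.data["event"],
                                       grp.labels)
                for lbl, cv in curves.items():
                    pd.DataFrame({"time": cv.times, "survival": cv.survival}) \
                        .to_csv(out / f"km_{name}_{lbl}.tsv", sep="\t", index=False)
                lo, hi = res.ci95
                ver_rows.append({"cohort": name, "set_name": chosen,
                                 "threshold": grp.threshold, "HR": res.hr,
                                 "ci_low": lo, "ci_high": hi, "p": res.p})
            if ver_rows:
                pd.DataFrame(ver_rows).to_csv(out / "verification.tsv",
                                              sep="\t", index=False)

        if config.stages.get("mechanism") and chosen is not None:
            stage = "mechanism"
            mech_cohort = config.expression_cohort or next(
                n for n, (c, *_r) in cohort_data.items() if c.role == "discovery"
            )
            c, mut, clin = cohort_data[mech_cohort]
            burden = compute_burden(mut, gene_sets, clin.samples,
                                    mode=config.counting_mode)
            grp = dichotomize(burden.column(chosen), chosen)
            tmb = compute_tmb(mut, clin.samples)
            hi = grp.labels == "mut_high"
            tmb_test = wilcoxon_ranksum(tmb.counts[hi], tmb.counts[~hi])
            top = compare_top_genes(mut, grp, top_k=20,
                                    extra_genes=gene_sets[chosen])
            top.to_csv(out / "top_genes.tsv", sep="\t", index=False)
            mech = {"tmb_p": tmb_test.p, "tmb_method": tmb_test.method}
            if config.expression:
                expr = read_expression(config.expression)
                manifest["inputs"][config.expression] = _checksum(config.expression)
                shared = [s for s in expr.samples if s in set(clin.samples)]
                from .io import ExpressionMatrix
                expr_sub = ExpressionMatrix(expr.values[shared])
                dge = dge_moderated_t(expr_sub, grp)
                dge.table.to_csv(out / "dge.tsv", sep="\t")
                ranking = dge.table["logFC"].dropna()
                gsea = gsea_preranked(ranking, gene_sets,
                                      n_perm=config.n_gsea_perm, seed=config.seed)
                gsea.table.to_csv(out / "gsea.tsv", sep="\t", index=False)
                scores = ssgsea_score(expr_sub, gene_sets)
                scores.scores.to_csv(out / "ssgsea_scores.tsv", sep="\t")
                diff = diff_pathway_expression(scores, grp)
                diff.to_csv(out / "pathway_diff.tsv", sep="\t")
                if chosen in scores.scores.index:
                    _curves, cox = pathway_score_survival(scores, clin, chosen)
                    lo, hi_ci = cox.ci95
                    mech["pathway_score_HR"] = cox.hr
                    mech["pathway_score_p"] = cox.p
            with open(out / "mechanism.json", "w") as fh:
                json.dump(mech, fh, indent=2)

        if config.stages.get("drugs") and chosen is not None:
            stage = "drugs"
            if config.drug_response:
                drugs = read_drug_response(config.drug_response)
                manifest["inputs"][config.drug_response] = _checksum(config.drug_response)
                first = next(n for n, (c, *_r) in cohort_data.items()
                             if c.role == "discovery")
                c, mut, clin = cohort_data[first]
                lines = sorted(set(drugs.rows["cell_line"]))
                burden = compute_burden(mut, gene_sets, lines,
                                        mode=config.counting_mode)
                grp = dichotomize(burden.column(chosen), chosen)
                rows = []
                for d in drugs.drugs:
                    v = drugs.ln_ic50(d)
                    lab = grp.labels.reindex(v.index)
                    res = wilcoxon_ranksum(v[lab == "mut_high"], v[lab == "mut_low"])
                    rows.append({"drug": d, "p": res.p,
                                 "rank_biserial": res.effect})
                pd.DataFrame(rows).to_csv(out / "lnic50_tests.tsv",
                                          sep="\t", index=False)
            if config.cmap_refs and config.cmap_meta and config.expression:
                ranks = pd.read_csv(config.cmap_refs, sep="\t", index_col=0)
                meta = pd.read_csv(config.cmap_meta, sep="\t", index_col=0)
                refs = ReferenceRankMatrix(ranks, meta)
                dge_path = out / "dge.tsv"
                if dge_path.exists():
                    dge_tab = pd.read_csv(dge_path, sep="\t", index_col=0)
                    up = dge_tab[(dge_tab["p"] < 0.05) & (dge_tab["logFC"] > 1)].index
                    down = dge_tab[(dge_tab["p"] < 0.05) & (dge_tab["logFC"] < -1)].index
                    if len(up) and len(down):
                        sig = TagSignature(tuple(up), tuple(down))
                        conn = connectivity_score(sig, refs, seed=config.seed)
                        conn.per_compound.to_csv(out / "connectivity.tsv", sep="\t")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        with open(out / "run_log.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return out
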