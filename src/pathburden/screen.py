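"""The discovery engine: median-split + univariate Cox over every gene set,
then cross-cohort concordance filtering.

Each gene set is screened independently: dichotomize the cohort at the
median burden (strictly above = mut-high), fit a univariate Cox model on
the group indicator, and record the hazard ratio with Wald inference.
Replication, not multiplicity correction, is the default error control:
a set survives only if it is significant with the same direction of
effect in every cohort (Benjamini-Hochberg q-values are available as an
option).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .burden import BurdenMatrix, dichotomize
from .io import ClinicalTable
from .survival import CoxResult, newton_cox

#: minimum per-group size for a usable median split
MIN_GROUP = 3

SCREEN_COLUMNS = [
    "set_name", "cohort_id", "endpoint", "threshold", "n_high", "n_low",
    "beta", "se", "HR", "ci_low", "ci_high", "p", "direction",
]


@dataclass
class ScreenReport:
    """Cross-cohort concordance summary.

    ``concordant`` holds sets significant (p < alpha) in every cohort with
    the same direction; ``discordant`` holds sets significant everywhere
    but with conflicting directions (the gray dots of a two-cohort HR
    scatter).  ``classification`` maps each concordant set to 'protective'
    (HR < 1 everywhere) or 'risk' (HR > 1 everywhere).
    """

    per_cohort: dict[str, pd.DataFrame]
    concordant: pd.DataFrame
    discordant: pd.DataFrame
    classification: dict[str, str]
    alpha: float
    skipped: dict[str, list] = field(default_factory=dict)


def screen_cohort(
    burden: BurdenMatrix,
    clinical: ClinicalTable,
    cohort_id: str = "cohort",
    endpoint: str | None = None,
    alpha: float = 0.05,
    ties: str = "efron",
) -> tuple[pd.DataFrame, list]:
    """Screen every gene set in ``burden`` against survival in ``clinical``.

    Returns (rows, skipped): one row per non-degenerate set regardless of
    p; ``skipped`` lists (set_name, reason) for degenerate groupings.
    len(rows) + len(skipped) always equals the number of gene sets.
    """
    shared = [s for s in burden.samples if s in set(clinical.samples)]
    if len(shared) < 10:
        raise ValueError(
            f"burden and clinical tables share only {len(shared)} samples (need >= 10)"
        )
    sub = clinical.subset(shared)
    times = sub.data["time"].to_numpy(float)
    events = sub.data["event"].to_numpy(int)
    if events.sum() < 1:
        raise ValueError("cohort has no events")
    endpoint = endpoint or clinical.endpoint
    counts = burden.counts.loc[shared]
    rows, skipped = [], []
    for set_name in counts.columns:
        col = counts[set_name]
        grp = _quiet_dichotomize(col, set_name)
        if grp.degenerate:
            skipped.append((set_name, "degenerate grouping"))
            continue
        if min(grp.n_high, grp.n_low) < MIN_GROUP:
            skipped.append((set_name, f"group smaller than {MIN_GROUP}"))
            continue
        x = grp.indicator().to_numpy(float)
        if events[x == 1].sum() + events[x == 0].sum() < 1:
            skipped.append((set_name, "no events"))
            continue
        beta, se, _, diag = newton_cox(times, events, x[:, None], ties=ties)
        res = CoxResult("group", float(beta[0]), float(se[0]), diag["n"],
                        diag["n_events"], ties, diag["converged"], diag["flag"])
        lo, hi = res.ci95
        rows.append(
            {
                "set_name": set_name,
                "cohort_id": cohort_id,
                "endpoint": endpoint,
                "threshold": grp.threshold,
                "n_high": grp.n_high,
                "n_low": grp.n_low,
                "beta": res.beta,
                "se": res.se,
                "HR": res.hr,
                "ci_low": lo,
                "ci_high": hi,
                "p": res.p,
                "direction": 1 if res.beta > 0 else -1,
            }
        )
    df = pd.DataFrame(rows, columns=SCREEN_COLUMNS)
    return df, skipped


def _quiet_dichotomize(col, set_name):
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return dichotomize(col, set_name)


def concordance_filter(reports: dict[str, pd.DataFrame], alpha: float = 0.05,
                       skipped: dict[str, list] | None = None) -> ScreenReport:
    """Intersect per-cohort screens: keep sets significant everywhere with
    one direction of effect.

    The result is invariant to cohort ordering.  Sets significant in every
    cohort but with conflicting directions are reported separately.
    """
    if len(reports) < 2:
        raise ValueError("concordance requires >= 2 cohort screens")
    names = sorted(reports)
    shared = set(reports[names[0]]["set_name"])
    for c in names[1:]:
        shared &= set(reports[c]["set_name"])
    if not shared:
        raise ValueError("no shared gene-set universe across cohorts")
    sig = {}
    for c in names:
        df = reports[c]
        df = df[df["set_name"].isin(shared) & (df["p"] < alpha)]
        sig[c] = df.set_index("set_name")
    everywhere = set(sig[names[0]].index)
    for c in names[1:]:
        everywhere &= set(sig[c].index)
    conc_rows, disc_rows, classification = [], [], {}
    for s in sorted(everywhere):
        dirs = {int(sig[c].loc[s, "direction"]) for c in names}
        row = {"set_name": s}
        for c in names:
            row[f"HR_{c}"] = float(sig[c].loc[s, "HR"])
            row[f"p_{c}"] = float(sig[c].loc[s, "p"])
        if len(dirs) == 1:
            conc_rows.append(row)
            classification[s] = "risk" if dirs == {1} else "protective"
        else:
            disc_rows.append(row)
    cols = ["set_name"] + [f"HR_{c}" for c in names] + [f"p_{c}" for c in names]
    return ScreenReport(
        per_cohort={c: reports[c] for c in names},
        concordant=pd.DataFrame(conc_rows, columns=cols),
        discordant=pd.DataFrame(disc_rows, columns=cols),
        classification=classification,
        alpha=alpha,
        skipped=skipped or {},
    )


def multiplicity_adjust(rows: pd.DataFrame, method: str = "none") -> pd.DataFrame:
    """Append Benjamini-Hochberg q-values when method='bh'; no-op otherwise.

    The default mirrors a raw p < alpha screen that relies on cross-cohort
    replication instead of multiplicity correction — a deliberate and
    statistically liberal choice; use method='bh' for FDR control within
    one cohort.
    """
    if len(rows) == 0:
        raise ValueError("no screen rows to adjust")
    if method == "none":
        return rows
    if method != "bh":
        raise ValueError(f"unknown adjustment {method!r}")
    out = rows.copy()
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out
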