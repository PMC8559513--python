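"""Per-sample gene-set mutation burden, TMB, and the median-split grouping.

The biomarker at the heart of the pipeline is the number of nonsilent
somatic variants a sample carries inside a gene set (a pathway).  Samples
strictly above the cohort median burden form the mut-high group; the
median itself and everything below it is mut-low.  With burdens that are
small integers (the motivating cohorts had pathway medians of 1 and 2)
this strict split is deliberately asymmetric: |mut_high| <= floor(n/2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import DEFAULT_NONSILENT, GeneSetCollection, MutationTable

MUT_HIGH = "mut_high"
MUT_LOW = "mut_low"


@dataclass
class BurdenMatrix:
    """samples x gene_sets matrix of non-negative integer mutation counts."""

    counts: pd.DataFrame  # index = samples, columns = gene sets
    counting_mode: str = "variants"
    class_filter: frozenset = DEFAULT_NONSILENT

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def set_names(self) -> list[str]:
        return list(self.counts.columns)

    def column(self, set_name: str) -> pd.Series:
        return self.counts[set_name]


@dataclass
class TmbVector:
    """Per-sample nonsilent variant count; optionally per megabase."""

    counts: pd.Series
    exome_size_mb: float | None = None

    @property
    def per_mb(self) -> pd.Series | None:
        if self.exome_size_mb is None:
            return None
        return self.counts / self.exome_size_mb


@dataclass
class GroupAssignment:
    """Median-strict mut-high / mut-low labels for one gene set."""

    labels: pd.Series  # values MUT_HIGH / MUT_LOW
    threshold: float
    set_name: str
    degenerate: bool = False

    @property
    def n_high(self) -> int:
        return int((self.labels == MUT_HIGH).sum())

    @property
    def n_low(self) -> int:
        return int((self.labels == MUT_LOW).sum())

    def indicator(self) -> pd.Series:
        """1 for mut_high, 0 for mut_low."""
        return (self.labels == MUT_HIGH).astype(int)


def _filtered_records(mutations: MutationTable, class_filter) -> pd.DataFrame:
    rec = mutations.records
    if class_filter is None:
        return rec
    return rec[rec["variant_class"].isin(class_filter)]


def compute_burden(
    mutations: MutationTable,
    sets: GeneSetCollection,
    roster,
    mode: str = "variants",
    class_filter=DEFAULT_NONSILENT,
) -> BurdenMatrix:
    """Count, per sample and gene set, the filtered mutations inside the set.

    mode='variants' counts variant records (a gene hit twice counts twice);
    mode='genes' counts distinct mutated genes.  ``roster`` enumerates the
    cohort so zero-mutation samples get explicit zero rows.
    """
    roster = list(roster)
    if not roster:
        raise ValueError("empty sample roster")
    if mode not in ("variants", "genes"):
        raise ValueError(f"unknown counting mode {mode!r}")
    rec = _filtered_records(mutations, class_filter)
    rec = rec[rec["sample_id"].isin(roster)]
    if mode == "genes":
        rec = rec.drop_duplicates(["sample_id", "gene"])
    # sample x gene count matrix, then project onto set membership
    pivot = (
        rec.groupby(["sample_id", "gene"]).size().unstack(fill_value=0)
        if len(rec)
        else pd.DataFrame(index=pd.Index([], name="sample_id"))
    )
    pivot = pivot.reindex(index=roster, fill_value=0).astype(int)
    universe = list(pivot.columns)
    cols = {}
    for name, members in sets.sets.items():
        hit = [g for g in universe if g in members]
        if not hit:
            warnings.warn(f"gene set {name!r} has zero overlap with the mutation universe")
            cols[name] = np.zeros(len(roster), dtype=int)
        else:
            cols[name] = pivot[hit].sum(axis=1).to_numpy()
    counts = pd.DataFrame(cols, index=pd.Index(roster, name="sample_id"))
    return BurdenMatrix(counts, counting_mode=mode, class_filter=frozenset(class_filter or []))


def compute_tmb(
    mutations: MutationTable,
    roster,
    class_filter=DEFAULT_NONSILENT,
    exome_size_mb: float | None = None,
) -> TmbVector:
    """Per-sample count of nonsilent variants (raw count; per-Mb optional).

    Downstream group comparisons use the raw count; a log scale is a
    display choice only.
    """
    roster = list(roster)
    if not roster:
        raise ValueError("empty sample roster")
    rec = _filtered_records(mutations, class_filter)
    counts = rec.groupby("sample_id").size().reindex(roster, fill_value=0).astype(int)
    counts.index.name = "sample_id"
    return TmbVector(counts, exome_size_mb=exome_size_mb)


def dichotomize(burden_column: pd.Series, set_name: str = "") -> GroupAssignment:
    """Median-strict split: mut_high iff burden > cohort median.

    All-identical values yield an all-mut_low degenerate assignment with a
    warning; survival operations must refuse such single-group input.
    """
    values = burden_column.to_numpy(float)
    if len(values) < 2:
        raise ValueError("need at least 2 samples to dichotomize")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite burden values")
    threshold = float(np.median(values))
    labels = pd.Series(
        np.where(values > threshold, MUT_HIGH, MUT_LOW), index=burden_column.index
    )
    degenerate = labels.nunique() < 2
    if degenerate:
        warnings.warn(
            f"degenerate grouping for {set_name or 'burden column'}: "
            "all samples fall in one group"
        )
    return GroupAssignment(labels, threshold, set_name, degenerate)
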