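"""Readers, writers and validated in-memory tables for the pipeline's inputs.

Five external formats are consumed: MAF-style somatic mutation tables, GMT
gene-set collections, clinical survival tables, log-scale expression
matrices (genes x samples) and drug-response tables (lnIC50 per cell line
and drug).  Every reader normalises gene symbols the same way (uppercase,
whitespace-trimmed) so that downstream joins are exact.

Symbol normalisation is deliberately minimal: no alias/HGNC-history
mapping is attempted, which means symbols retired between annotation
releases will simply fail to overlap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Variant classes counted as nonsilent by default (MAF vocabulary).
DEFAULT_NONSILENT = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Translation_Start_Site",
    }
)

#: Recognised silent/non-coding MAF classes (kept in tables, excluded from
#: nonsilent counts).
KNOWN_SILENT = frozenset(
    {"Silent", "Intron", "3'UTR", "5'UTR", "3'Flank", "5'Flank", "IGR",
     "RNA", "Targeted_Region"}
)

#: Full default variant-class vocabulary for validation/flagging.
DEFAULT_VOCABULARY = DEFAULT_NONSILENT | KNOWN_SILENT

#: Default MAF column mapping.
DEFAULT_MAF_DIALECT = {
    "sample": "Tumor_Sample_Barcode",
    "gene": "Hugo_Symbol",
    "variant_class": "Variant_Classification",
    "protein_change": "HGVSp_Short",
}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def normalize_symbol(symbol: str) -> str:
    """Uppercase and trim a gene symbol."""
    return str(symbol).strip().upper()


def _sep_for(path: str) -> str:
    p = str(path)
    if p.endswith(".gz"):
        p = p[:-3]
    return "," if p.endswith(".csv") else "\t"


# ---------------------------------------------------------------------------
# Mutation tables


@dataclass
class MutationTable:
    """Long-form somatic variant records keyed by sample and gene.

    ``records`` has columns ``sample_id``, ``gene``, ``variant_class``,
    ``protein_change``.  Duplicate identical records are permitted (a gene
    can carry several variants in one sample).  A gene-level binary call
    table is representable as one record per mutated gene.
    """

    records: pd.DataFrame
    known_classes: frozenset = DEFAULT_VOCABULARY
    n_dropped: int = 0

    def __post_init__(self) -> None:
        req = ["sample_id", "gene", "variant_class", "protein_change"]
        missing = [c for c in req if c not in self.records.columns]
        if missing:
            raise FormatError(f"MutationTable missing columns {missing}")
        self.records = self.records[req].reset_index(drop=True)
        self.records["gene"] = self.records["gene"].map(normalize_symbol)

    @property
    def samples(self) -> list[str]:
        return sorted(self.records["sample_id"].unique())

    @property
    def genes(self) -> list[str]:
        return sorted(self.records["gene"].unique())

    def unknown_classes(self) -> set[str]:
        """Variant classes outside the configured vocabulary (kept, flagged)."""
        return set(self.records["variant_class"]) - set(self.known_classes)

    def __len__(self) -> int:
        return len(self.records)


def read_mutation_table(
    path,
    dialect: dict | None = None,
    known_classes: frozenset = DEFAULT_VOCABULARY,
) -> MutationTable:
    """Read a MAF-style TSV/CSV of somatic variants.

    ``dialect`` maps the logical fields (``sample``, ``gene``,
    ``variant_class``, ``protein_change``) to the file's column names;
    unspecified fields fall back to the MAF defaults.  Rows with a blank
    sample or gene are dropped with a warning count.
    """
    d = dict(DEFAULT_MAF_DIALECT)
    if dialect:
        d.update(dialect)
    df = pd.read_csv(path, sep=_sep_for(path), comment="#", dtype=str)
    if df.empty:
        raise FormatError(f"{path}: empty mutation table")
    for key in ("sample", "gene", "variant_class"):
        if d[key] not in df.columns:
            raise FormatError(f"{path}: missing required column {d[key]!r}")
    out = pd.DataFrame(
        {
            "sample_id": df[d["sample"]].astype(str).str.strip(),
            "gene": df[d["gene"]].astype(str),
            "variant_class": df[d["variant_class"]].astype(str).str.strip(),
            "protein_change": (
                df[d["protein_change"]] if d["protein_change"] in df.columns else pd.NA
            ),
        }
    )
    bad = (
        out["sample_id"].isin(["", "nan"])
        | out["gene"].astype(str).str.strip().isin(["", "nan"])
        | out["sample_id"].isna()
        | out["gene"].isna()
    )
    n_dropped = int(bad.sum())
    if n_dropped:
        warnings.warn(f"{path}: dropped {n_dropped} rows with blank sample/gene")
    out = out[~bad].reset_index(drop=True)
    logger.info("read %d mutation records (%d dropped) from %s", len(out), n_dropped, path)
    mt = MutationTable(out, known_classes=known_classes, n_dropped=n_dropped)
    unk = mt.unknown_classes()
    if unk:
        warnings.warn(f"{path}: {len(unk)} variant classes outside vocabulary: {sorted(unk)[:5]}")
    return mt


def write_mutation_table(table: MutationTable, path) -> None:
    table.records.to_csv(path, sep=_sep_for(path), index=False,
                         header=["Tumor_Sample_Barcode", "Hugo_Symbol",
                                 "Variant_Classification", "HGVSp_Short"])


# ---------------------------------------------------------------------------
# Gene sets


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. MSigDB H/C2/C5) with normalised member symbols."""

    sets: dict[str, frozenset]
    source: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")
            self.sets[name] = frozenset(normalize_symbol(g) for g in members)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>genes...``.

    The description field is discarded; duplicate member symbols within a
    set are deduplicated; a duplicated set name is fatal.
    """
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    sets: dict[str, frozenset] = {}
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has <3 fields")
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            sets[name] = frozenset(g for g in fields[2:] if g.strip())
    return GeneSetCollection(sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# Clinical tables


@dataclass
class ClinicalTable:
    """Per-sample survival endpoint plus typed covariates.

    ``data`` is indexed by unique sample_id with columns ``time`` (months,
    strictly positive) and ``event`` (0/1), plus one column per covariate.
    ``covariate_kinds`` maps covariate name to 'continuous', 'binary' or
    'categorical'; categorical covariates carry an explicit level order in
    ``levels`` (reference level first).
    """

    data: pd.DataFrame
    covariate_kinds: dict[str, str] = field(default_factory=dict)
    levels: dict[str, list] = field(default_factory=dict)
    endpoint: str = "OS"

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise FormatError(f"duplicate sample ids: {dups[:5]}")
        t = self.data["time"].to_numpy(float)
        if not np.all(np.isfinite(t)) or np.any(t <= 0):
            bad = self.data.index[~(np.isfinite(t) & (t > 0))].tolist()
            raise FormatError(f"non-positive/non-finite survival times for {bad[:5]}")
        ev = set(self.data["event"].unique())
        if not ev <= {0, 1}:
            raise FormatError(f"event indicator must be 0/1, saw {sorted(ev)[:5]}")
        for name, kind in self.covariate_kinds.items():
            if kind == "categorical" and name not in self.levels:
                observed = list(pd.unique(self.data[name].dropna()))
                self.levels[name] = observed

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_events(self) -> int:
        return int(self.data["event"].sum())

    def subset(self, samples) -> "ClinicalTable":
        return ClinicalTable(
            self.data.loc[list(samples)].copy(),
            dict(self.covariate_kinds),
            {k: list(v) for k, v in self.levels.items()},
            self.endpoint,
        )

    def with_covariate(self, name: str, values: pd.Series, kind: str = "binary",
                       levels: list | None = None) -> "ClinicalTable":
        """Return a copy with an extra covariate column (e.g. a group label)."""
        data = self.data.copy()
        data[name] = values.reindex(data.index)
        kinds = dict(self.covariate_kinds)
        kinds[name] = kind
        lv = {k: list(v) for k, v in self.levels.items()}
        if kind == "categorical":
            lv[name] = levels or list(pd.unique(data[name].dropna()))
        return ClinicalTable(data, kinds, lv, self.endpoint)

    def collapse_levels(self, name: str, mapping: dict, levels: list) -> "ClinicalTable":
        """Merge categorical levels (e.g. stage III+IV -> 'advanced')."""
        data = self.data.copy()
        data[name] = data[name].map(lambda v: mapping.get(v, v))
        lv = {k: list(v) for k, v in self.levels.items()}
        lv[name] = levels
        return ClinicalTable(data, dict(self.covariate_kinds), lv, self.endpoint)


def read_clinical(path, schema: dict | None = None) -> ClinicalTable:
    """Read a clinical TSV/CSV.

    ``schema`` keys: ``sample`` / ``time`` / ``event`` column names,
    ``time_factor`` multiplying the stored time into months (e.g. 1/30.44
    for days), ``covariates`` mapping column name -> kind, ``levels``
    mapping categorical covariate -> ordered levels (reference first),
    ``endpoint`` ('OS' or 'PFS').
    """
    schema = dict(schema or {})
    sample_col = schema.get("sample", "sample_id")
    time_col = schema.get("time", "time")
    event_col = schema.get("event", "event")
    factor = float(schema.get("time_factor", 1.0))
    covs: dict[str, str] = dict(schema.get("covariates", {}))
    df = pd.read_csv(path, sep=_sep_for(path))
    for col in (sample_col, time_col, event_col, *covs):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    data = df.set_index(df[sample_col].astype(str))[[time_col, event_col, *covs]]
    data = data.rename(columns={time_col: "time", event_col: "event"})
    data.index.name = "sample_id"
    data["time"] = data["time"].astype(float) * factor
    bad = data.index[~(data["time"] > 0)].tolist()
    if bad:
        raise FormatError(f"{path}: non-positive survival time for samples {bad[:10]}")
    if not set(data["event"].unique()) <= {0, 1}:
        raise FormatError(f"{path}: event column is not binary 0/1")
    data["event"] = data["event"].astype(int)
    return ClinicalTable(data, covs, dict(schema.get("levels", {})),
                         schema.get("endpoint", "OS"))


def write_clinical(table: ClinicalTable, path) -> None:
    table.data.to_csv(path, sep=_sep_for(path), index=True)


# ---------------------------------------------------------------------------
# Expression matrices


@dataclass
class ExpressionMatrix:
    """Log-scale expression, genes x samples, unique normalised gene labels."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values.to_numpy(float))):
            raise FormatError("expression matrix contains non-finite values")
        self.values.index = [normalize_symbol(g) for g in self.values.index]
        if self.values.index.has_duplicates:
            raise FormatError("duplicate gene labels after collapsing")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def collapse_duplicate_genes(df: pd.DataFrame) -> pd.DataFrame:
    """Keep, per duplicated gene label, the row with highest variance.

    Ties break to the first occurrence, which makes the collapse
    deterministic under row shuffling only up to variance ties; exact
    duplicates collapse to one row either way.
    """
    df = df.copy()
    df.index = [normalize_symbol(g) for g in df.index]
    if not df.index.has_duplicates:
        return df
    var = df.var(axis=1, ddof=1).fillna(0.0).to_numpy()
    order = np.arange(len(df))
    pick = (
        pd.DataFrame({"gene": df.index, "var": var, "order": order})
        .sort_values(["gene", "var", "order"], ascending=[True, False, True],
                     kind="stable")
        .drop_duplicates("gene")["order"]
        .sort_values()
    )
    warnings.warn(f"collapsed {len(df) - len(pick)} duplicate gene rows by max variance")
    return df.iloc[pick.to_numpy()]


def read_expression(path) -> ExpressionMatrix:
    """Read a dense genes x samples TSV/CSV (first column = gene labels)."""
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.empty:
        raise FormatError(f"{path}: empty expression matrix")
    return ExpressionMatrix(collapse_duplicate_genes(df))


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep=_sep_for(path))


# ---------------------------------------------------------------------------
# Drug response


@dataclass
class DrugResponseTable:
    """lnIC50 per (cell line, drug) pair with optional target/MoA annotations."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        req = ["cell_line", "drug", "ln_ic50"]
        missing = [c for c in req if c not in self.rows.columns]
        if missing:
            raise FormatError(f"DrugResponseTable missing columns {missing}")
        if self.rows.duplicated(["cell_line", "drug"]).any():
            raise FormatError("duplicate (cell_line, drug) pairs")
        if not np.all(np.isfinite(self.rows["ln_ic50"].to_numpy(float))):
            raise FormatError("non-finite ln_ic50 values")

    @property
    def drugs(self) -> list[str]:
        return sorted(self.rows["drug"].unique())

    def ln_ic50(self, drug: str) -> pd.Series:
        sub = self.rows[self.rows["drug"] == drug]
        return pd.Series(sub["ln_ic50"].to_numpy(float), index=sub["cell_line"].to_numpy())


def read_drug_response(path, columns: dict | None = None) -> DrugResponseTable:
    cols = {"cell_line": "cell_line", "drug": "drug", "ln_ic50": "ln_ic50"}
    cols.update(columns or {})
    df = pd.read_csv(path, sep=_sep_for(path))
    for c in cols.values():
        if c not in df.columns:
            raise FormatError(f"{path}: missing column {c!r}")
    out = df.rename(columns={v: k for k, v in cols.items()})
    return DrugResponseTable(out)


def write_drug_response(table: DrugResponseTable, path) -> None:
    table.rows.to_csv(path, sep=_sep_for(path), index=False)
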