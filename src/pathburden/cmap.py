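"""Connectivity-map style two-tag KS drug scoring against a reference rank
matrix, with a permutation null and mechanism-of-action aggregation.

The statistic is the classic build-02 connectivity score: for a query
signature (up-tags, down-tags) and a reference instance whose features
are ranked 1 (most up-regulated) to n, each tag list gets a signed KS
statistic; the raw connectivity s = ks_up - ks_down when the two have
opposite signs, else 0; scores are then scaled so the most extreme
instance of each sign sits at +1 / -1.  A positive score means the
instance's transcriptional response resembles the query (up-tags up,
down-tags down).

The feature space here is gene symbols, not array probes: mapping query
genes onto a platform's probe space is an external concern, so queries
and references must share a symbol universe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class TagSignature:
    """Disjoint, non-empty up- and down-regulated tag lists."""

    up_tags: tuple
    down_tags: tuple

    def __post_init__(self) -> None:
        self.up_tags = tuple(dict.fromkeys(self.up_tags))
        self.down_tags = tuple(dict.fromkeys(self.down_tags))
        if not self.up_tags or not self.down_tags:
            raise ValueError("both tag lists must be non-empty")
        overlap = set(self.up_tags) & set(self.down_tags)
        if overlap:
            raise ValueError(f"tags appear in both lists: {sorted(overlap)[:5]}")

    def swapped(self) -> "TagSignature":
        return TagSignature(self.down_tags, self.up_tags)


@dataclass
class ReferenceRankMatrix:
    """features x instances matrix of ranks (1 = most up-regulated) plus
    per-instance metadata (compound, dose, cell line, MoA...)."""

    ranks: pd.DataFrame
    meta: pd.DataFrame  # indexed by instance id; must carry 'compound'

    def __post_init__(self) -> None:
        R = self.ranks.to_numpy()
        n = R.shape[0]
        expected = np.arange(1, n + 1)
        for j, col in enumerate(self.ranks.columns):
            if not np.array_equal(np.sort(R[:, j]), expected):
                raise ValueError(f"column {col!r} is not a permutation of 1..{n}")
        if "compound" not in self.meta.columns:
            raise ValueError("instance metadata must carry a 'compound' column")
        missing = [c for c in self.ranks.columns if c not in self.meta.index]
        if missing:
            raise ValueError(f"instances missing metadata: {missing[:5]}")

    @property
    def n_features(self) -> int:
        return self.ranks.shape[0]

    @property
    def instances(self) -> list[str]:
        return list(self.ranks.columns)


def ks_tag_score(tag_positions, n: int) -> float:
    """Signed KS statistic for t tag positions among n ranked features.

    a = max_i (i/t - V(i)/n), b = max_i (V(i)/n - (i-1)/t) over the sorted
    positions V; the score is a when a >= b (tags concentrated near the
    top) and -b otherwise.  Ties a == b resolve to +a.
    """
    v = np.sort(np.asarray(tag_positions, dtype=float))
    t = len(v)
    if t == 0 or t >= n:
        raise ValueError(f"need 1 <= t < n tags, got t={t}, n={n}")
    if len(np.unique(v)) != t:
        raise ValueError("tag positions must be distinct")
    i = np.arange(1, t + 1)
    a = float(np.max(i / t - v / n))
    b = float(np.max(v / n - (i - 1) / t))
    return a if a >= b else -b


@dataclass
class ConnectivityResult:
    per_instance: pd.DataFrame    # ks_up, ks_down, s, score, p per instance
    per_compound: pd.DataFrame    # extreme (or mean) score per compound
    n_perm: int
    seed: int | None
    dropped_tags: dict = field(default_factory=dict)


def _raw_connectivity(ks_up: float, ks_down: float) -> float:
    if np.sign(ks_up) == np.sign(ks_down):
        return 0.0
    return ks_up - ks_down


def _scale(s: np.ndarray) -> np.ndarray:
    scaled = np.zeros_like(s)
    pos = s > 0
    neg = s < 0
    if pos.any():
        scaled[pos] = s[pos] / s[pos].max()
    if neg.any():
        scaled[neg] = s[neg] / abs(s[neg].min())
    return scaled


def connectivity_score(
    sig: TagSignature,
    refs: ReferenceRankMatrix,
    n_perm: int = 1000,
    seed: int | None = None,
    compound_summary: str = "extreme",
) -> ConnectivityResult:
    """Score every reference instance against the query signature.

    Permutation p per instance comes from ``n_perm`` random tag sets of
    the same sizes drawn from the feature universe:
    p = (1 + #{|s_perm| >= |s|}) / (1 + n_perm).
    """
    universe = set(refs.ranks.index)
    up = [g for g in sig.up_tags if g in universe]
    down = [g for g in sig.down_tags if g in universe]
    dropped = {
        "up": [g for g in sig.up_tags if g not in universe],
        "down": [g for g in sig.down_tags if g not in universe],
    }
    if dropped["up"] or dropped["down"]:
        warnings.warn(
            f"dropped {len(dropped['up'])} up / {len(dropped['down'])} down tags "
            "absent from the reference universe"
        )
    if not up or not down:
        raise ValueError("no query tags map into the reference feature universe")
    n = refs.n_features
    R = refs.ranks
    up_idx = R.index.get_indexer(up)
    down_idx = R.index.get_indexer(down)
    Rv = R.to_numpy(float)
    ks_up = np.array([ks_tag_score(Rv[up_idx, j], n) for j in range(Rv.shape[1])])
    ks_down = np.array([ks_tag_score(Rv[down_idx, j], n) for j in range(Rv.shape[1])])
    s = np.array([_raw_connectivity(u, d) for u, d in zip(ks_up, ks_down)])
    score = _scale(s)
    # permutation null: size-matched random tag positions (ranks are a
    # permutation of 1..n, so random features == random distinct positions)
    rng = np.random.default_rng(seed)
    t_up, t_down = len(up), len(down)
    exceed = np.zeros(len(s))
    for _ in range(n_perm):
        pu = rng.choice(n, size=t_up, replace=False) + 1
        pdn = rng.choice(n, size=t_down, replace=False) + 1
        su = ks_tag_score(pu, n)
        sd = ks_tag_score(pdn, n)
        sp = _raw_connectivity(su, sd)
        exceed += np.abs(sp) >= np.abs(s)
    pvals = (1 + exceed) / (1 + n_perm)
    per_instance = pd.DataFrame(
        {
            "ks_up": ks_up,
            "ks_down": ks_down,
            "s": s,
            "score": score,
            "p": pvals,
            "compound": refs.meta.loc[refs.instances, "compound"].to_numpy(),
        },
        index=pd.Index(refs.instances, name="instance"),
    )
    per_compound = _summarize_compounds(per_instance, compound_summary)
    return ConnectivityResult(per_instance, per_compound, n_perm, seed, dropped)


def _summarize_compounds(per_instance: pd.DataFrame, how: str) -> pd.DataFrame:
    rows = []
    for compound, grp in per_instance.groupby("compound"):
        if how == "extreme":
            k = grp["score"].abs().idxmax()
            rows.append({"compound": compound, "score": grp.loc[k, "score"],
                         "p": grp.loc[k, "p"], "n_instances": len(grp)})
        elif how == "mean":
            rows.append({"compound": compound, "score": grp["score"].mean(),
                         "p": grp["p"].min(), "n_instances": len(grp)})
        else:
            raise ValueError(f"unknown compound summary {how!r}")
    return pd.DataFrame(rows).set_index("compound")


def moa_aggregate(
    result: ConnectivityResult,
    moa_table: pd.DataFrame,
    score_cut: float = 0.8,
    p_cut: float = 0.05,
) -> pd.DataFrame:
    """Count, per mechanism of action, the compounds passing the score and
    p cuts in each direction.

    ``moa_table`` maps compound -> moa (column 'moa'); compounds without
    an annotation are bucketed as 'unannotated'.
    """
    pc = result.per_compound
    moa = moa_table.set_index("compound")["moa"] if "compound" in moa_table.columns \
        else moa_table["moa"]
    annotated = pc.join(moa, how="left")
    annotated["moa"] = annotated["moa"].fillna("unannotated")
    pos = annotated[(annotated["score"] > score_cut) & (annotated["p"] < p_cut)]
    neg = annotated[(annotated["score"] < -score_cut) & (annotated["p"] < p_cut)]
    moas = sorted(set(pos["moa"]) | set(neg["moa"]))
    rows = [
        {
            "moa": m,
            "n_positive": int((pos["moa"] == m).sum()),
            "n_negative": int((neg["moa"] == m).sum()),
            "positive_compounds": sorted(pos.index[pos["moa"] == m]),
            "negative_compounds": sorted(neg.index[neg["moa"] == m]),
        }
        for m in moas
    ]
    return pd.DataFrame(rows, columns=["moa", "n_positive", "n_negative",
                                       "positive_compounds", "negative_compounds"])
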