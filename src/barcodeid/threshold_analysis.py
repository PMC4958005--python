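"""PIdent distributions, 5%-error heuristic thresholds, accuracy at
threshold, representation curves and distribution comparison.

The heuristic threshold is the integer PIdent separating reliable from
unreliable identifications at a rank, under an error budget (default
5%).  Two published phrasings of the rule differ and both are
implemented:

* ``error_share_below`` (default): the smallest integer T such that at
  least (1 - budget) of all *incorrect* hits have PIdent < T.
* ``error_rate_above``: the smallest integer T such that among hits
  with PIdent >= T fewer than budget are incorrect.

The boundary convention is always "hits with pident >= T count as
above threshold".  PIdent values are floor-binned onto the integer
grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .library_io import ReferenceLibrary
from .rank_scoring import best_hits, evaluable, match_column


def histogram(evaluable_hits: pd.DataFrame, rank: str, scope: str = "all_hits"):
    """Floor-binned PIdent counts for correct and incorrect hits.

    scope 'all_hits' uses every ranked hit, 'best_hits' only rank-1
    rows.  Returns (correct, incorrect) integer-indexed Series that
    together partition the hits in scope.
    """
    if scope not in ("all_hits", "best_hits"):
        raise ValueError(f"scope must be 'all_hits' or 'best_hits', got {scope!r}")
    if evaluable_hits.empty:
        raise ValueError("no hits to histogram")
    df = best_hits(evaluable_hits) if scope == "best_hits" else evaluable_hits
    col = match_column(rank)
    bins = np.floor(df["pident"].to_numpy()).astype(int)
    lo = min(75, bins.min())
    idx = pd.RangeIndex(lo, 101, name="pident_bin")
    correct = (
        pd.Series(bins[df[col].to_numpy()]).value_counts().reindex(idx, fill_value=0)
    )
    incorrect = (
        pd.Series(bins[~df[col].to_numpy()]).value_counts().reindex(idx, fill_value=0)
    )
    return correct.rename("correct"), incorrect.rename("incorrect")


@dataclass
class ThresholdReport:
    rank: str
    definition: str
    error_budget: float
    threshold: Optional[int]
    degenerate: bool
    n_correct: int
    n_incorrect: int
    best_hit_accuracy_at_threshold: Optional[float]
    n_best_hits_at_threshold: int
    table: pd.DataFrame = field(repr=False)
    boundary: str = "pident >= T counts as above threshold"


def _per_t_table(pidents: np.ndarray, correct: np.ndarray) -> pd.DataFrame:
    """Cumulative correctness accounting on the integer PIdent grid."""
    lo = int(min(75, math.floor(pidents.min()))) if len(pidents) else 75
    rows = []
    n_inc_total = int((~correct).sum())
    for t in range(lo, 102):
        above = pidents >= t
        n_c = int((correct & above).sum())
        n_i = int((~correct & above).sum())
        share_below = ((~correct & ~above).sum() / n_inc_total) if n_inc_total else float("nan")
        rate_above = n_i / (n_c + n_i) if (n_c + n_i) else float("nan")
        rows.append((t, n_c, n_i, share_below, rate_above))
    return pd.DataFrame(
        rows,
        columns=["T", "n_correct_ge_T", "n_incorrect_ge_T", "error_share_below", "error_rate_above"],
    )


def heuristic_threshold(
    evaluable_hits: pd.DataFrame,
    rank: str,
    error_budget: float = 0.05,
    definition: str = "error_share_below",
) -> ThresholdReport:
    """Integer PIdent threshold at which <= error_budget of
    identifications at `rank` are wrong, under the chosen definition.

    With no incorrect hits the threshold is degenerate and reported as
    the floor of the smallest observed PIdent.
    """
    if definition not in ("error_share_below", "error_rate_above"):
        raise ValueError(f"unknown definition {definition!r}")
    if not 0 < error_budget < 1:
        raise ValueError("error_budget must be in (0, 1)")
    col = match_column(rank)
    pid = evaluable_hits["pident"].to_numpy()
    cor = evaluable_hits[col].to_numpy()
    n_inc = int((~cor).sum())
    table = _per_t_table(pid, cor)
    degenerate = n_inc == 0
    threshold: Optional[int] = None
    if degenerate:
        threshold = int(math.floor(pid.min())) if len(pid) else None
    elif definition == "error_share_below":
        ok = table[table["error_share_below"] >= 1 - error_budget]
        if not ok.empty:
            threshold = int(ok["T"].iloc[0])
    else:
        sub = table[(table["n_correct_ge_T"] + table["n_incorrect_ge_T"]) > 0]
        ok = sub[sub["error_rate_above"] < error_budget]
        if not ok.empty:
            threshold = int(ok["T"].iloc[0])
    acc: Optional[float] = None
    n_best = 0
    if threshold is not None:
        acc, n_best = best_hit_accuracy(evaluable_hits, rank, threshold)
    return ThresholdReport(
        rank=rank,
        definition=definition,
        error_budget=error_budget,
        threshold=threshold,
        degenerate=degenerate,
        n_correct=int(cor.sum()),
        n_incorrect=n_inc,
        best_hit_accuracy_at_threshold=acc,
        n_best_hits_at_threshold=n_best,
        table=table,
    )


def best_hit_accuracy(
    evaluable_hits: pd.DataFrame, rank: str, threshold: float
) -> Tuple[Optional[float], int]:
    """Fraction of rank-1 hits with pident >= threshold that are correct.

    Returns (fraction or None when no best hit qualifies, n qualifying).
    """
    if not 0 <= threshold <= 101:
        raise ValueError("threshold out of range")
    col = match_column(rank)
    best = best_hits(evaluable_hits)
    sel = best[best["pident"] >= threshold]
    if sel.empty:
        return None, 0
    return float(sel[col].mean()), len(sel)


def compare_distributions(
    correct_pidents, incorrect_pidents, method: str = "rank_sum"
) -> Tuple[float, float]:
    """Two-sided test of correct-vs-incorrect PIdent distributions."""
    x = np.asarray(correct_pidents, dtype=float)
    y = np.asarray(incorrect_pidents, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least two values")
    if method == "rank_sum":
        res = stats.ranksums(x, y)
    elif method == "ks":
        res = stats.ks_2samp(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


def representation_curves(
    scored: pd.DataFrame,
    lib: ReferenceLibrary,
    thresholds: Dict[str, int],
) -> Dict[str, pd.DataFrame]:
    """Identification quality versus taxonomic representation.

    Genus rank: queries grouped by how many species their genus has in
    the library; family rank: by how many genera their family has.
    Per group size the curve reports the number of queries, the
    proportion of their ranked hits with pident >= the rank threshold,
    and the proportion of correct best hits.  Forced failures are
    excluded before grouping.
    """
    genus_size = {g: len(ids) for g, ids in lib.by_genus.items()}
    fam_genera: Dict[str, set] = {}
    for r in lib:
        fam_genera.setdefault(r.family, set()).add(r.genus)
    fam_size = {f: len(g) for f, g in fam_genera.items()}
    genus_of = {r.record_id: r.genus for r in lib}
    family_of = {r.record_id: r.family for r in lib}
    out: Dict[str, pd.DataFrame] = {}
    for rank in ("genus", "family"):
        ev = evaluable(scored, rank)
        if ev.empty:
            out[rank] = pd.DataFrame(
                columns=["group_size", "n_queries", "prop_hits_above_threshold", "prop_best_correct"]
            )
            continue
        if rank == "genus":
            size = ev["query_id"].map(lambda q: genus_size[genus_of[q]])
        else:
            size = ev["query_id"].map(lambda q: fam_size[family_of[q]])
        ev = ev.assign(group_size=size.to_numpy())
        t = thresholds[rank]
        col = match_column(rank)
        rows = []
        for gs, grp in ev.groupby("group_size"):
            best = grp[grp["rank"] == 1]
            rows.append(
                (
                    int(gs),
                    grp["query_id"].nunique(),
                    float((grp["pident"] >= t).mean()),
                    float(best[col].mean()) if len(best) else float("nan"),
                )
            )
        out[rank] = pd.DataFrame(
            rows, columns=["group_size", "n_queries", "prop_hits_above_threshold", "prop_best_correct"]
        )
    return out


def error_anatomy(
    scored: pd.DataFrame,
    lib: ReferenceLibrary,
    rank: str = "family",
    include_forced: bool = False,
) -> pd.DataFrame:
    """Incorrect identifications sorted by PIdent descending, with
    lineages, for manual audit of suspect records (high-PIdent wrong
    hits are the signature of mislabels)."""
    col = match_column(rank)
    df = scored if include_forced else evaluable(scored, rank)
    bad = df[~df[col]].copy()
    genus_of = {r.record_id: r.genus for r in lib}
    family_of = {r.record_id: r.family for r in lib}
    bad["query_genus"] = bad["query_id"].map(genus_of)
    bad["query_family"] = bad["query_id"].map(family_of)
    bad["target_genus"] = bad["target_id"].map(genus_of)
    bad["target_family"] = bad["target_id"].map(family_of)
    bad = bad.sort_values(
        ["pident", "bit_score", "query_id", "target_id"],
        ascending=[False, False, True, True],
    ).reset_index(drop=True)
    return bad
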