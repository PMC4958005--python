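"""Genus/family correctness scoring of hits, with singleton accounting.

A hit is correct at a rank when query and target carry the same name at
that rank; a correct genus implies a correct family because genera nest
in families.  Records that are the only member of their genus (or
family) in the library cannot match correctly at that rank — these
"forced failures" are kept as targets but excluded as queries from
rank-level accuracy assessments.
"""

from __future__ import annotations

from typing import Tuple

import pandas as pd

from .library_io import ReferenceLibrary

SCORED_COLUMNS = [
    "genus_match",
    "family_match",
    "query_genus_singleton",
    "query_family_singleton",
]


def score_hits(hits: pd.DataFrame, lib: ReferenceLibrary) -> pd.DataFrame:
    """Annotate a hit table with match and singleton flags.

    Raises KeyError if any query/target id is not in the library.
    """
    genus = {r.record_id: r.genus for r in lib}
    family = {r.record_id: r.family for r in lib}
    unknown = (set(hits["query_id"]) | set(hits["target_id"])) - set(genus)
    if unknown:
        raise KeyError(f"hit ids not in library: {sorted(unknown)[:5]}")
    gsing = lib.genus_singletons()
    fsing = lib.family_singletons()
    scored = hits.copy()
    qg = hits["query_id"].map(genus)
    tg = hits["target_id"].map(genus)
    qf = hits["query_id"].map(family)
    tf = hits["target_id"].map(family)
    scored["genus_match"] = (qg == tg).to_numpy()
    scored["family_match"] = (qf == tf).to_numpy()
    scored["query_genus_singleton"] = hits["query_id"].isin(gsing).to_numpy()
    scored["query_family_singleton"] = hits["query_id"].isin(fsing).to_numpy()
    return scored


def evaluable(scored: pd.DataFrame, rank: str) -> pd.DataFrame:
    """Drop forced failures: hits whose query cannot match at `rank`.

    At genus rank a genus- or family-singleton query is excluded; at
    family rank only family singletons are (a genus singleton can still
    match its family through a confamilial genus).
    """
    if rank == "genus":
        mask = ~(scored["query_genus_singleton"] | scored["query_family_singleton"])
    elif rank == "family":
        mask = ~scored["query_family_singleton"]
    else:
        raise ValueError(f"rank must be 'genus' or 'family', got {rank!r}")
    return scored[mask].reset_index(drop=True)


def match_column(rank: str) -> str:
    if rank not in ("genus", "family"):
        raise ValueError(f"rank must be 'genus' or 'family', got {rank!r}")
    return f"{rank}_match"


def best_hits(scored: pd.DataFrame) -> pd.DataFrame:
    """The rank-1 hit of every query that has any hits."""
    return scored[scored["rank"] == 1].reset_index(drop=True)


def congener_best_match_rate(
    scored: pd.DataFrame, lib: ReferenceLibrary, semantics: str = "all"
) -> Tuple[int, int, float]:
    """How many multi-species genera best-match within themselves.

    Considers genera with >= 2 species.  Under 'all' semantics a genus
    succeeds when every one of its queries' best hits is a congener;
    under 'any', when at least one is.  Returns
    (n_genera_ge2, n_success, rate).
    """
    if semantics not in ("all", "any"):
        raise ValueError("semantics must be 'all' or 'any'")
    genus_of = {r.record_id: r.genus for r in lib}
    multi = {g for g, ids in lib.by_genus.items() if len(ids) >= 2}
    best = best_hits(scored)
    ok_by_genus: dict = {}
    for row in best.itertuples(index=False):
        g = genus_of[row.query_id]
        if g not in multi:
            continue
        ok_by_genus.setdefault(g, []).append(bool(row.genus_match))
    n_success = 0
    for g in multi:
        flags = ok_by_genus.get(g, [])
        if not flags:
            continue  # no hits at all -> failure
        if (all(flags) if semantics == "all" else any(flags)):
            n_success += 1
    n_multi = len(multi)
    rate = n_success / n_multi if n_multi else float("nan")
    return n_multi, n_success, rate
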