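"""End-to-end analysis of one reference library.

Chains search -> scoring -> threshold analysis and returns everything
a report needs in a single object.  Thin orchestration only; each step
is a public function of its own module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import pandas as pd

from .library_io import CompositionSummary, ReferenceLibrary, composition
from .rank_scoring import congener_best_match_rate, evaluable, score_hits
from .search import all_vs_all
from .threshold_analysis import (
    ThresholdReport,
    compare_distributions,
    error_anatomy,
    heuristic_threshold,
    representation_curves,
)


@dataclass
class AnalysisResult:
    composition: CompositionSummary
    hits: pd.DataFrame
    scored: pd.DataFrame
    thresholds: Dict[str, Dict[str, ThresholdReport]]  # rank -> definition -> report
    congener: tuple  # (n_genera_ge2, n_success, rate) under 'all' semantics
    congener_any: tuple
    curves: Dict[str, pd.DataFrame]
    anatomy: pd.DataFrame

    def threshold(self, rank: str, definition: str = "error_share_below") -> Optional[int]:
        return self.thresholds[rank][definition].threshold


def analyze_library(
    lib: ReferenceLibrary,
    k: int = 10,
    evalue_max: float = 1e-10,
    error_budget: float = 0.05,
    word_size: int = 11,
) -> AnalysisResult:
    """Run the full matching experiment on a curated library."""
    hits = all_vs_all(lib, k=k, evalue_max=evalue_max, word_size=word_size)
    scored = score_hits(hits, lib)
    thresholds: Dict[str, Dict[str, ThresholdReport]] = {}
    for rank in ("genus", "family"):
        ev = evaluable(scored, rank)
        thresholds[rank] = {
            d: heuristic_threshold(ev, rank, error_budget=error_budget, definition=d)
            for d in ("error_share_below", "error_rate_above")
        }
    t_for_curves = {
        rank: (thresholds[rank]["error_share_below"].threshold or 0)
        for rank in ("genus", "family")
    }
    return AnalysisResult(
        composition=composition(lib),
        hits=hits,
        scored=scored,
        thresholds=thresholds,
        congener=congener_best_match_rate(scored, lib, semantics="all"),
        congener_any=congener_best_match_rate(scored, lib, semantics="any"),
        curves=representation_curves(scored, lib, t_for_curves),
        anatomy=error_anatomy(scored, lib, rank="family"),
    )


def significance(result: AnalysisResult, rank: str, method: str = "rank_sum"):
    """Correct-vs-incorrect PIdent distribution test on the evaluable set."""
    ev = evaluable(result.scored, rank)
    col = f"{rank}_match"
    return compare_distributions(
        ev.loc[ev[col], "pident"], ev.loc[~ev[col], "pident"], method=method
    )
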