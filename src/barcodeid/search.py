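"""All-vs-all leave-self-out similarity search over a reference library.

Every record is queried against the full library; the hit of the query
to itself is removed by record id (identical sequences under different
ids remain legitimate targets), hits are filtered to E <= evalue_max
and truncated to the top k by bit score.  The E-value search space is
query length x total library length, so results depend on the whole
library, as in a database search.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from ._kernels import banded_affine_local
from .align import (
    DEFAULT_SCHEME,
    AlignmentResult,
    ScoringScheme,
    encode,
    evalue_of,
    extend_seeds,
)
from .library_io import ReferenceLibrary

HIT_COLUMNS = [
    "query_id",
    "target_id",
    "rank",
    "pident",
    "aligned_columns",
    "identities",
    "bit_score",
    "evalue",
    "query_coverage",
]


@dataclass
class SeedIndex:
    """Inverted word index: word bytes -> list of (record_id, offset)."""

    word_size: int
    postings: Dict[bytes, List[Tuple[str, int]]]
    encoded: Dict[str, np.ndarray]

    def n_postings(self) -> int:
        return sum(len(v) for v in self.postings.values())


def build_index(lib: ReferenceLibrary, word_size: int = 11) -> SeedIndex:
    """Index every ACGT-only word of every sequence, once per occurrence."""
    postings: Dict[bytes, List[Tuple[str, int]]] = {}
    encoded: Dict[str, np.ndarray] = {}
    for rec in lib:
        ea = encode(rec.sequence)
        encoded[rec.record_id] = ea
        for off in range(len(ea) - word_size + 1):
            w = ea[off : off + word_size]
            if w.max() >= 4:
                continue
            postings.setdefault(w.tobytes(), []).append((rec.record_id, off))
    return SeedIndex(word_size=word_size, postings=postings, encoded=encoded)


def _candidate_seeds(query_ea: np.ndarray, index: SeedIndex, exclude_id: str):
    """Group the query's word matches by target: target_id -> seed lists."""
    w = index.word_size
    seeds: Dict[str, Tuple[List[int], List[int]]] = {}
    for qoff in range(len(query_ea) - w + 1):
        word = query_ea[qoff : qoff + w]
        if word.max() >= 4:
            continue
        for target_id, toff in index.postings.get(word.tobytes(), ()):
            if target_id == exclude_id:
                continue
            qs, ts = seeds.setdefault(target_id, ([], []))
            qs.append(qoff)
            ts.append(toff)
    return seeds


def top_hits(
    query,
    lib: ReferenceLibrary,
    index: SeedIndex,
    k: int = 10,
    evalue_max: float = 1e-10,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    x_drop: int = 20,
    band_pad: int = 16,
) -> List[AlignmentResult]:
    """Ranked hit list for one query against the library minus itself.

    Sort key: bit score descending, then E-value ascending, then
    target_id ascending (a total, reproducible order).  Zero hits is a
    valid outcome.
    """
    total_n = lib.total_length()
    query_ea = index.encoded.get(query.record_id)
    if query_ea is None:
        query_ea = encode(query.sequence)
    seeds = _candidate_seeds(query_ea, index, exclude_id=query.record_id)
    results: List[AlignmentResult] = []
    for target_id, (qs, ts) in seeds.items():
        raw = extend_seeds(
            query_ea,
            index.encoded[target_id],
            np.asarray(qs, dtype=np.int64),
            np.asarray(ts, dtype=np.int64),
            scheme,
            index.word_size,
            x_drop,
            band_pad,
        )
        score, q0, q1, t0, t1, ident, cols = raw
        if score <= 0:
            continue
        bit, ev = evalue_of(score, len(query_ea), total_n, scheme)
        if ev > evalue_max:
            continue
        res = AlignmentResult(
            query_id=query.record_id,
            target_id=target_id,
            score=score,
            identities=ident,
            aligned_columns=cols,
            query_span=(q0, q1),
            target_span=(t0, t1),
            query_length=len(query_ea),
        )
        res.bit_score, res.evalue = bit, ev
        results.append(res)
    results.sort(key=lambda r: (-r.bit_score, r.evalue, r.target_id))
    return results[:k]


def _rows_from_results(results: List[AlignmentResult]):
    for rank, r in enumerate(results, start=1):
        yield (
            r.query_id,
            r.target_id,
            rank,
            r.pident,
            r.aligned_columns,
            r.identities,
            r.bit_score,
            r.evalue,
            r.query_coverage,
        )


def all_vs_all(
    lib: ReferenceLibrary,
    k: int = 10,
    evalue_max: float = 1e-10,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    word_size: int = 11,
    x_drop: int = 20,
    band_pad: int = 16,
) -> pd.DataFrame:
    """Query every record against the full set; return the hit table.

    One row per (query, rank) with HIT_COLUMNS; deterministic given the
    library and parameters.
    """
    if len(lib) < 2:
        raise ValueError("all-vs-all needs at least two records")
    index = build_index(lib, word_size=word_size)
    rows = []
    for rec in lib:
        hits = top_hits(
            rec, lib, index, k=k, evalue_max=evalue_max, scheme=scheme,
            x_drop=x_drop, band_pad=band_pad,
        )
        rows.extend(_rows_from_results(hits))
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def write_hits(hits: pd.DataFrame, path) -> None:
    hits.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_hits(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def all_vs_all_oracle(
    lib: ReferenceLibrary,
    k: int = 10,
    evalue_max: float = 1e-10,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> pd.DataFrame:
    """Exhaustive Smith-Waterman variant of all_vs_all (no seeding).

    Quadratic in sequence length per pair; intended for small libraries
    as an independent check of the seeded search path.
    """
    total_n = lib.total_length()
    encoded = {r.record_id: encode(r.sequence) for r in lib}
    rows = []
    for query in lib:
        qa = encoded[query.record_id]
        results = []
        for target in lib:
            if target.record_id == query.record_id:
                continue
            ta = encoded[target.record_id]
            raw = banded_affine_local(
                qa, ta, scheme.match_reward, scheme.mismatch_penalty,
                scheme.gap_open, scheme.gap_extend, -len(ta), len(qa),
            )
            score, q0, q1, t0, t1, ident, cols = raw
            if score <= 0:
                continue
            bit, ev = evalue_of(score, len(qa), total_n, scheme)
            if ev > evalue_max:
                continue
            res = AlignmentResult(
                query_id=query.record_id,
                target_id=target.record_id,
                score=score,
                identities=ident,
                aligned_columns=cols,
                query_span=(q0, q1),
                target_span=(t0, t1),
                query_length=len(qa),
            )
            res.bit_score, res.evalue = bit, ev
            results.append(res)
        results.sort(key=lambda r: (-r.bit_score, r.evalue, r.target_id))
        rows.extend(_rows_from_results(results[:k]))
    return pd.DataFrame(rows, columns=HIT_COLUMNS)
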