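"""Barcode reference library I/O, curation and composition summaries.

A reference library couples a FASTA file of CO1 barcodes with a
4-column tab-separated taxonomy table (record_id, species, genus,
family).  Lineage is never parsed from FASTA headers; the header token
before the first whitespace is the record id and the taxonomy table is
authoritative for names.  Curation enforces the inclusion rules used to
assemble supra-specific test libraries: a minimum sequence length,
identification to species, and a single sequence per species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import pandas as pd
from Bio import SeqIO


@dataclass
class BarcodeRecord:
    """One barcode sequence with its (possibly absent) lineage."""

    record_id: str
    sequence: str
    species: Optional[str] = None
    genus: Optional[str] = None
    family: Optional[str] = None
    source: str = "synthetic"  # original | downloaded | synthetic

    def __post_init__(self) -> None:
        if not self.record_id:
            raise ValueError("record_id must be non-empty")
        if not self.sequence:
            raise ValueError(f"{self.record_id}: sequence must be non-empty")
        self.sequence = self.sequence.upper()
        if self.species is not None and (self.genus is None or self.family is None):
            raise ValueError(
                f"{self.record_id}: species-level identification requires genus and family"
            )

    @property
    def species_key(self) -> Optional[Tuple[str, str]]:
        """(genus, species) pair — the uniqueness key for 'one sequence
        per species' (epithets may repeat across genera)."""
        if self.species is None:
            return None
        return (self.genus, self.species)


class TaxonomyError(ValueError):
    """Inconsistent or malformed taxonomy input."""


class ReferenceLibrary:
    """A curated set of records: one per species, genera nested in
    exactly one family each."""

    def __init__(self, records: Iterable[BarcodeRecord]):
        self.records: List[BarcodeRecord] = list(records)
        self.by_id: Dict[str, BarcodeRecord] = {}
        self.by_species: Dict[Tuple[str, str], str] = {}
        self.by_genus: Dict[str, List[str]] = {}
        self.by_family: Dict[str, List[str]] = {}
        genus_family: Dict[str, str] = {}
        for r in self.records:
            if r.record_id in self.by_id:
                raise TaxonomyError(f"duplicate record_id {r.record_id!r}")
            if r.genus is None or r.family is None:
                raise TaxonomyError(f"{r.record_id}: curated library requires genus and family")
            if r.species is not None and r.species_key in self.by_species:
                raise TaxonomyError(
                    f"more than one record for species {' '.join(r.species_key)}"
                )
            prev = genus_family.get(r.genus)
            if prev is not None and prev != r.family:
                raise TaxonomyError(
                    f"genus {r.genus!r} appears under families {prev!r} and {r.family!r}"
                )
            genus_family[r.genus] = r.family
            self.by_id[r.record_id] = r
            if r.species is not None:
                self.by_species[r.species_key] = r.record_id
            self.by_genus.setdefault(r.genus, []).append(r.record_id)
            self.by_family.setdefault(r.family, []).append(r.record_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def genus_singletons(self) -> set:
        return {ids[0] for ids in self.by_genus.values() if len(ids) == 1}

    def family_singletons(self) -> set:
        return {ids[0] for ids in self.by_family.values() if len(ids) == 1}

    def total_length(self) -> int:
        return sum(len(r.sequence) for r in self.records)


@dataclass
class CompositionSummary:
    n_species: int
    n_genera: int
    n_families: int
    genus_sizes: Dict[str, int]
    family_sizes_species: Dict[str, int]
    family_sizes_genera: Dict[str, int]
    n_singleton_genera_records: int
    n_singleton_family_records: int
    n_genera_ge2: int
    max_species_per_genus: int
    max_species_per_family: int


@dataclass
class CurationReport:
    n_input: int
    n_dropped_short: int
    n_dropped_no_species: int
    n_dropped_duplicates: int
    n_output: int
    dropped_ids: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = (
            self.n_output
            + self.n_dropped_short
            + self.n_dropped_no_species
            + self.n_dropped_duplicates
        )
        assert self.n_input == total, "curation counts do not reconcile"


def read_fasta(path) -> List[BarcodeRecord]:
    """Read FASTA into bare records (id + sequence, no lineage)."""
    records: List[BarcodeRecord] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise TaxonomyError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append(BarcodeRecord(record_id=rec.id, sequence=str(rec.seq)))
    return records


def write_fasta(records: Iterable[BarcodeRecord], path) -> None:
    """Write one-line-per-sequence FASTA (round-trips byte-identically
    through read_fasta + write_fasta)."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.record_id}\n{r.sequence}\n")


def read_taxonomy(path) -> Dict[str, Tuple[Optional[str], str, str]]:
    """Read the 4-column TSV taxonomy table.

    Returns record_id -> (species or None, genus, family).  An empty
    species cell means the record was not identified to species.
    Raises TaxonomyError on repeated ids or a genus listed under two
    families.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    expected = ["record_id", "species", "genus", "family"]
    if list(df.columns) != expected:
        raise TaxonomyError(f"taxonomy header must be {expected}, got {list(df.columns)}")
    if df["record_id"].duplicated().any():
        dup = df.loc[df["record_id"].duplicated(), "record_id"].iloc[0]
        raise TaxonomyError(f"record_id {dup!r} repeated in taxonomy table")
    gf = df[df["genus"] != ""].groupby("genus")["family"].nunique()
    bad = gf[gf > 1]
    if len(bad):
        g = bad.index[0]
        fams = sorted(df.loc[df["genus"] == g, "family"].unique())
        raise TaxonomyError(f"genus {g!r} appears under families {fams}")
    out = {}
    for row in df.itertuples(index=False):
        out[row.record_id] = (row.species or None, row.genus, row.family)
    return out


def write_taxonomy(records: Iterable[BarcodeRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("record_id\tspecies\tgenus\tfamily\n")
        for r in records:
            fh.write(f"{r.record_id}\t{r.species or ''}\t{r.genus or ''}\t{r.family or ''}\n")


def curate_library(
    records: Iterable[BarcodeRecord],
    lineages: Dict[str, Tuple[Optional[str], str, str]],
    min_length: int = 600,
    require_species: bool = True,
    pick_rule: str = "longest",
) -> Tuple[ReferenceLibrary, CurationReport]:
    """Apply the inclusion rules and collapse to one record per species.

    Records shorter than min_length are dropped first, then records not
    identified to species (when require_species), then duplicate-species
    records are collapsed: 'longest' keeps the longest sequence, ties
    broken by lexicographically smallest record_id.  Idempotent.
    """
    if pick_rule != "longest":
        raise ValueError(f"unknown pick_rule {pick_rule!r}")
    annotated: List[BarcodeRecord] = []
    for r in records:
        if r.record_id not in lineages:
            raise TaxonomyError(f"{r.record_id}: no taxonomy entry")
        sp, genus, family = lineages[r.record_id]
        annotated.append(
            BarcodeRecord(
                record_id=r.record_id,
                sequence=r.sequence,
                species=sp,
                genus=genus or None,
                family=family or None,
                source=r.source,
            )
        )
    n_input = len(annotated)
    dropped: List[str] = []
    long_enough = []
    n_short = 0
    for r in annotated:
        if len(r.sequence) < min_length:
            n_short += 1
            dropped.append(r.record_id)
        else:
            long_enough.append(r)
    with_species = []
    n_no_species = 0
    for r in long_enough:
        if require_species and r.species is None:
            n_no_species += 1
            dropped.append(r.record_id)
        else:
            with_species.append(r)
    best: Dict[Tuple[str, str], BarcodeRecord] = {}
    no_key: List[BarcodeRecord] = []
    n_dup = 0
    for r in with_species:
        key = r.species_key
        if key is None:  # allowed when require_species is off
            no_key.append(r)
            continue
        cur = best.get(key)
        if cur is None:
            best[key] = r
        else:
            n_dup += 1
            # keep the longer sequence; ties -> smaller record_id
            if (len(r.sequence), cur.record_id) > (len(cur.sequence), r.record_id):
                dropped.append(cur.record_id)
                best[key] = r
            else:
                dropped.append(r.record_id)
    kept = sorted(list(best.values()) + no_key, key=lambda r: r.record_id)
    lib = ReferenceLibrary(kept)
    report = CurationReport(
        n_input=n_input,
        n_dropped_short=n_short,
        n_dropped_no_species=n_no_species,
        n_dropped_duplicates=n_dup,
        n_output=len(kept),
        dropped_ids=dropped,
    )
    return lib, report


def composition(lib: ReferenceLibrary) -> CompositionSummary:
    """Count species/genera/families, group sizes and singleton records."""
    genus_sizes = {g: len(ids) for g, ids in lib.by_genus.items()}
    fam_sp = {f: len(ids) for f, ids in lib.by_family.items()}
    fam_gen: Dict[str, set] = {}
    for r in lib:
        fam_gen.setdefault(r.family, set()).add(r.genus)
    fam_gen_sizes = {f: len(gs) for f, gs in fam_gen.items()}
    return CompositionSummary(
        n_species=len(lib),
        n_genera=len(genus_sizes),
        n_families=len(fam_sp),
        genus_sizes=genus_sizes,
        family_sizes_species=fam_sp,
        family_sizes_genera=fam_gen_sizes,
        n_singleton_genera_records=sum(1 for n in genus_sizes.values() if n == 1),
        n_singleton_family_records=sum(1 for n in fam_sp.values() if n == 1),
        n_genera_ge2=sum(1 for n in genus_sizes.values() if n >= 2),
        max_species_per_genus=max(genus_sizes.values()) if genus_sizes else 0,
        max_species_per_family=max(fam_sp.values()) if fam_sp else 0,
    )


def composition_frame(summary: CompositionSummary) -> pd.DataFrame:
    """Scalar composition counts as a tidy two-column frame (for TSV)."""
    rows = [
        ("n_species", summary.n_species),
        ("n_genera", summary.n_genera),
        ("n_families", summary.n_families),
        ("n_singleton_genera_records", summary.n_singleton_genera_records),
        ("n_singleton_family_records", summary.n_singleton_family_records),
        ("n_genera_ge2", summary.n_genera_ge2),
        ("max_species_per_genus", summary.max_species_per_genus),
        ("max_species_per_family", summary.max_species_per_family),
    ]
    return pd.DataFrame(rows, columns=["statistic", "value"])


def load_library(fasta_path, taxonomy_path, **curate_kwargs):
    """Convenience: read FASTA + taxonomy and curate in one call."""
    return curate_library(read_fasta(fasta_path), read_taxonomy(taxonomy_path), **curate_kwargs)
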