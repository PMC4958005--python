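"""Synthetic barcode libraries with known taxonomic ground truth.

The generator emulates the composition of a curated spider CO1 test
library — few families, heavy-tailed genus and family sizes, many
genus- and some family-level singletons — and controls pairwise
sequence identity by rank through a hierarchical Jukes-Cantor process:
a single random root gives rise to family ancestors, genus ancestors
and finally species sequences, each branch substituting sites
uniformly among the three alternative bases.

Divergence parameters are *pairwise* expected substitutions per site
for taxa whose most recent common ancestor sits at the given rank, so
with defaults (0.18, 0.08, 0.03) two congeners are ~97% identical, two
confamilial non-congeners ~92%, and members of different families
~82-84% — reproducing a 75-100% PIdent regime structured by rank.
Because Jukes-Cantor distances compose additively along a path, the
per-branch rates are half the increments between rank levels.

Optional corruptions emulate database reality: a small fraction of
records trimmed to shorter fragments, and label errors that move a
record into a wrong family while the manifest keeps the truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .library_io import BarcodeRecord, ReferenceLibrary, write_fasta, write_taxonomy

# distribution spec: an int (constant), an explicit list of counts, or
# ("zipf", exponent, cap) for a truncated power law with support 1..cap
DistSpec = Union[int, Sequence[int], Tuple[str, float, int]]

_BASES = np.array([ord(c) for c in "ACGT"], dtype=np.uint8)


@dataclass(frozen=True)
class Divergence:
    """Expected pairwise substitutions/site by rank of the MRCA."""

    between_family: float = 0.18
    between_genus_within_family: float = 0.08
    within_genus: float = 0.03

    def __post_init__(self) -> None:
        if not (self.between_family > self.between_genus_within_family > self.within_genus > 0):
            raise ValueError("divergence must decrease strictly with rank depth")
        if self.between_family >= 1:
            raise ValueError("divergence rates must be in (0, 1)")

    def branch_rates(self) -> Tuple[float, float, float]:
        """(root->family, family->genus, genus->species) substitutions/site."""
        b_s = self.within_genus / 2
        b_g = (self.between_genus_within_family - self.within_genus) / 2
        b_f = (self.between_family - self.between_genus_within_family) / 2
        return b_f, b_g, b_s


@dataclass(frozen=True)
class SyntheticConfig:
    """Shape + divergence + corruption parameters for one library.

    Taxonomy shape: when ``n_species_target`` is set (the default),
    genera are drawn one at a time from ``species_per_genus`` until the
    species total reaches the target, and each genus lands in a family
    with probability proportional to ``rank ** -family_weight_exponent``
    (after one guaranteed genus per family) — giving heavy-tailed family
    sizes and a stable library size.  With ``n_species_target=None`` the
    per-family genus counts are drawn from ``genera_per_family`` instead.

    ``rate_sd`` is the sigma of a mean-one lognormal multiplier applied
    to every branch's substitution rate, so lineages differ in how far
    they have diverged — the source of the broad, overlapping PIdent
    ranges seen in real libraries.
    """

    n_families: int = 10
    n_species_target: Optional[int] = 150
    genera_per_family: DistSpec = ("zipf", 1.3, 34)
    species_per_genus: DistSpec = ("zipf", 2.0, 12)
    family_weight_exponent: float = 1.0
    seq_length: int = 649
    divergence: Divergence = field(default_factory=Divergence)
    rate_sd: float = 0.4
    indel_rate: float = 0.002
    mislabel_rate: float = 0.0
    short_fragment_rate: float = 18 / 816
    short_fragment_range: Tuple[int, int] = (570, 648)
    seed: int = 0


def _jc_change_prob(d: float) -> float:
    """Probability a site differs after d expected substitutions/site."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def expected_pident(d: float) -> float:
    """Jukes-Cantor expected percent identity at pairwise distance d."""
    return 100.0 * (1.0 - _jc_change_prob(d))


def _draw_counts(spec: DistSpec, n: int, rng: np.random.Generator) -> List[int]:
    if isinstance(spec, int):
        return [spec] * n
    if isinstance(spec, tuple) and len(spec) == 3 and spec[0] == "zipf":
        _, a, cap = spec
        k = np.arange(1, cap + 1)
        w = k ** (-a)
        w /= w.sum()
        return [int(v) for v in rng.choice(k, size=n, p=w)]
    counts = [int(v) for v in spec]
    if len(counts) != n:
        raise ValueError(f"explicit counts {counts} do not cover {n} groups")
    return counts


def sample_taxonomy(cfg: SyntheticConfig) -> List[List[int]]:
    """Draw the taxonomy skeleton: per family, species counts per genus.

    Singleton genera and families arise naturally from the heavy-tailed
    size distributions.  Deterministic given cfg.seed.
    """
    rng = np.random.default_rng([cfg.seed, 101])
    skeleton: List[List[int]]
    if cfg.n_species_target is not None and not _is_explicit(cfg.genera_per_family):
        skeleton = [[] for _ in range(cfg.n_families)]
        w = np.arange(1, cfg.n_families + 1, dtype=float) ** (-cfg.family_weight_exponent)
        w /= w.sum()
        total = 0
        i = 0
        while total < cfg.n_species_target or any(not f for f in skeleton):
            n_sp = _draw_counts(cfg.species_per_genus, 1, rng)[0]
            if i < cfg.n_families:
                fam = i  # one guaranteed genus per family
            else:
                fam = int(rng.choice(cfg.n_families, p=w))
            skeleton[fam].append(n_sp)
            total += n_sp
            i += 1
    else:
        n_genera = _draw_counts(cfg.genera_per_family, cfg.n_families, rng)
        total_genera = sum(n_genera)
        flat = _draw_counts(cfg.species_per_genus, total_genera, rng)
        skeleton = []
        pos = 0
        for ng in n_genera:
            skeleton.append(flat[pos : pos + ng])
            pos += ng
    if sum(sum(f) for f in skeleton) < 2:
        raise ValueError("taxonomy skeleton yields fewer than 2 species")
    return skeleton


def _is_explicit(spec: DistSpec) -> bool:
    return not isinstance(spec, int) and not (
        isinstance(spec, tuple) and len(spec) == 3 and spec[0] == "zipf"
    )


def _mutate(seq: np.ndarray, d: float, indel_rate: float, rng: np.random.Generator):
    """One branch: Jukes-Cantor substitutions, then single-base indels.

    Returns (child sequence, substitution count)."""
    child = seq.copy()
    q = _jc_change_prob(d)
    mask = rng.random(len(child)) < q
    n_subs = int(mask.sum())
    if n_subs:
        # uniform among the three alternative bases
        shift = rng.integers(1, 4, size=n_subs).astype(np.uint8)
        child[mask] = (child[mask] + shift) % 4
    if indel_rate > 0:
        n_events = rng.binomial(len(child), indel_rate)
        for _ in range(n_events):
            pos = int(rng.integers(0, len(child)))
            if rng.random() < 0.5 and len(child) > 1:
                child = np.delete(child, pos)
            else:
                child = np.insert(child, pos, rng.integers(0, 4))
    return child, n_subs


@dataclass
class SyntheticManifest:
    """Ground truth for a generated library."""

    table: pd.DataFrame
    identity_brackets: Dict[str, float]
    config: SyntheticConfig


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def evolve_sequences(
    skeleton: List[List[int]], cfg: SyntheticConfig
) -> Tuple[ReferenceLibrary, SyntheticManifest]:
    """Evolve one sequence per species down the family/genus hierarchy."""
    rng = np.random.default_rng([cfg.seed, 202])
    b_f, b_g, b_s = cfg.divergence.branch_rates()

    def branch_d(b: float) -> float:
        # mean-preserving lognormal rate multiplier per branch
        if cfg.rate_sd <= 0:
            return b
        return b * rng.lognormal(-cfg.rate_sd**2 / 2, cfg.rate_sd)

    root = rng.integers(0, 4, size=cfg.seq_length).astype(np.uint8)
    records: List[BarcodeRecord] = []
    rows = []
    rid = 0
    for fi, genera in enumerate(skeleton):
        fam = f"Fam{fi + 1:02d}"
        fam_anc, _ = _mutate(root, branch_d(b_f), cfg.indel_rate, rng)
        for gi, n_species in enumerate(genera):
            gen = f"{fam}-Gen{gi + 1:02d}"
            gen_anc, _ = _mutate(fam_anc, branch_d(b_g), cfg.indel_rate, rng)
            for si in range(n_species):
                seq, n_subs = _mutate(gen_anc, branch_d(b_s), cfg.indel_rate, rng)
                if cfg.short_fragment_rate > 0 and rng.random() < cfg.short_fragment_rate:
                    lo, hi = cfg.short_fragment_range
                    seq = seq[: int(rng.integers(lo, hi + 1))]
                rid += 1
                record_id = f"SYN{rid:04d}"
                species = f"{gen} sp{si + 1:02d}"
                records.append(
                    BarcodeRecord(
                        record_id=record_id,
                        sequence=_decode(seq),
                        species=species,
                        genus=gen,
                        family=fam,
                        source="synthetic",
                    )
                )
                rows.append(
                    {
                        "record_id": record_id,
                        "species": species,
                        "genus": gen,
                        "family": fam,
                        "true_species": species,
                        "true_genus": gen,
                        "true_family": fam,
                        "mislabel": False,
                        "n_subs_species_branch": n_subs,
                        "seq_length": len(seq),
                    }
                )
    lib = ReferenceLibrary(records)
    table = pd.DataFrame(rows)
    gsing = lib.genus_singletons()
    fsing = lib.family_singletons()
    table["is_genus_singleton"] = table["record_id"].isin(gsing)
    table["is_family_singleton"] = table["record_id"].isin(fsing)
    d = cfg.divergence
    brackets = {
        "within_genus": expected_pident(d.within_genus),
        "between_genus_within_family": expected_pident(d.between_genus_within_family),
        "between_family": expected_pident(d.between_family),
    }
    return lib, SyntheticManifest(table=table, identity_brackets=brackets, config=cfg)


def inject_mislabels(
    lib: ReferenceLibrary, manifest: SyntheticManifest, cfg: SyntheticConfig
) -> Tuple[ReferenceLibrary, SyntheticManifest]:
    """Give a fraction of records the family (and an existing genus) of
    another family; the manifest keeps the true lineage."""
    if cfg.mislabel_rate <= 0:
        return lib, manifest
    families = sorted(lib.by_family)
    if len(families) < 2:
        raise ValueError("mislabel injection requires >= 2 families")
    rng = np.random.default_rng([cfg.seed, 303])
    n_flip = int(round(cfg.mislabel_rate * len(lib)))
    flip_ids = set(
        rng.choice([r.record_id for r in lib], size=n_flip, replace=False)
    )
    genus_by_family = {}
    for r in lib:
        genus_by_family.setdefault(r.family, set()).add(r.genus)
    new_records = []
    table = manifest.table.set_index("record_id", drop=False)
    for r in lib:
        if r.record_id not in flip_ids:
            new_records.append(r)
            continue
        others = [f for f in families if f != r.family]
        fam = others[int(rng.integers(0, len(others)))]
        genera = sorted(genus_by_family[fam])
        gen = genera[int(rng.integers(0, len(genera)))]
        epithet = r.species.split(" ", 1)[1]
        new_records.append(
            replace_record(r, species=f"{gen} {epithet}-{r.record_id}", genus=gen, family=fam)
        )
        table.loc[r.record_id, ["species", "genus", "family", "mislabel"]] = [
            f"{gen} {epithet}-{r.record_id}",
            gen,
            fam,
            True,
        ]
    new_lib = ReferenceLibrary(new_records)
    new_table = table.reset_index(drop=True)
    gsing = new_lib.genus_singletons()
    fsing = new_lib.family_singletons()
    new_table["is_genus_singleton"] = new_table["record_id"].isin(gsing)
    new_table["is_family_singleton"] = new_table["record_id"].isin(fsing)
    return new_lib, SyntheticManifest(
        table=new_table, identity_brackets=manifest.identity_brackets, config=cfg
    )


def replace_record(r: BarcodeRecord, **kwargs) -> BarcodeRecord:
    fields = dict(
        record_id=r.record_id,
        sequence=r.sequence,
        species=r.species,
        genus=r.genus,
        family=r.family,
        source=r.source,
    )
    fields.update(kwargs)
    return BarcodeRecord(**fields)


def generate(cfg: SyntheticConfig) -> Tuple[ReferenceLibrary, SyntheticManifest]:
    """Skeleton -> sequences -> label errors, in one deterministic call."""
    skeleton = sample_taxonomy(cfg)
    lib, manifest = evolve_sequences(skeleton, cfg)
    return inject_mislabels(lib, manifest, cfg)


def write_library(lib: ReferenceLibrary, manifest: SyntheticManifest, outdir) -> None:
    """Emit FASTA + taxonomy TSV + manifest TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(lib, outdir / "library.fasta")
    write_taxonomy(lib, outdir / "taxonomy.tsv")
    manifest.table.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
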