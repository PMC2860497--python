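"""Reading, validating and filtering gene-set annotations.

Functional modules (GO terms, KEGG pathways, any named gene set) enter the
analysis either as GMT files — one set per line: identifier, description,
then member genes, all tab-separated — or as two-column gene/term pair
files, the common export format of annotation databases.  Sets are turned
into 0/1 membership indicators over the gene universe, which in a
competitive gene-set analysis is the set of genes carrying a ranking
statistic: each model compares a module against its complement in that
universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .exceptions import DegenerateSetError, ParseError

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "MembershipVector",
    "read_gmt",
    "write_gmt",
    "read_annotation_pairs",
    "filter_by_size",
    "membership_vector",
]


@dataclass
class GeneSetCollection:
    """Named gene sets (functional modules) with optional descriptions.

    ``sets`` maps a set identifier to a tuple of unique gene identifiers,
    preserving first-seen order.  ``descriptions`` maps set identifiers to
    free text (may be missing for sets read from pair files).
    """

    sets: dict[str, tuple[str, ...]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for set_id, genes in self.sets.items():
            if set_id == "":
                raise ValueError("empty set identifier")
            if len(set(genes)) != len(genes):
                raise ValueError(f"duplicate genes within set {set_id!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.sets

    def __iter__(self):
        return iter(self.sets)

    def description(self, set_id: str) -> str:
        return self.descriptions.get(set_id, "")


@dataclass
class MembershipVector:
    """Binary membership indicator of one set over an ordered gene universe."""

    universe: tuple[str, ...]
    indicator: np.ndarray  # int8, values in {0, 1}

    def __post_init__(self) -> None:
        self.indicator = np.asarray(self.indicator, dtype=np.int8)
        if self.indicator.shape != (len(self.universe),):
            raise ValueError("indicator length does not match universe size")

    @property
    def n_members(self) -> int:
        return int(self.indicator.sum())


def _dedup(genes: list[str]) -> tuple[str, ...]:
    return tuple(dict.fromkeys(genes))


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: ``set_id<TAB>description<TAB>gene...`` per line.

    Duplicate genes within a line are collapsed (with a logged warning);
    a duplicate set identifier or a line with fewer than three fields is an
    error.  Blank lines are ignored.
    """
    sets: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            set_id, desc, *genes = fields
            genes = [g for g in genes if g]
            if set_id in sets:
                raise ParseError(f"{path}: line {lineno}: duplicate set id {set_id!r}")
            unique = _dedup(genes)
            if len(unique) < len(genes):
                logger.warning(
                    "set %s: %d duplicate gene(s) collapsed",
                    set_id,
                    len(genes) - len(unique),
                )
            sets[set_id] = unique
            descriptions[set_id] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(coll: GeneSetCollection, path) -> None:
    """Write a collection in GMT format (inverse of :func:`read_gmt`)."""
    with open(path, "w", encoding="utf-8") as fh:
        for set_id, genes in coll.sets.items():
            desc = coll.description(set_id)
            fh.write("\t".join([set_id, desc, *genes]) + "\n")


def read_annotation_pairs(path, header: bool = False) -> GeneSetCollection:
    """Read a two-column ``gene<TAB>term`` file and invert it to term -> genes.

    Duplicate (gene, term) pairs are collapsed.  Lines without exactly two
    fields are a parse error.  An empty file yields an empty collection.
    """
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected 2 tab-separated fields, "
                    f"got {len(fields)}"
                )
            gene, term = fields
            sets.setdefault(term, [])
            if gene not in sets[term]:
                sets[term].append(gene)
    return GeneSetCollection(sets={t: tuple(g) for t, g in sets.items()})


def filter_by_size(
    coll: GeneSetCollection,
    universe,
    min_size: int = 10,
    max_size: int = 500,
) -> GeneSetCollection:
    """Keep sets whose *effective* size lies in ``[min_size, max_size]``.

    The effective size is the number of set genes present in ``universe``:
    very large modules are too generic to be informative and very small ones
    cannot support a stable logistic fit, so both are dropped before
    modelling.  Sizes are computed after intersecting with the universe
    because the fitted model only ever sees universe genes.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if max_size < min_size:
        raise ValueError("max_size must be >= min_size")
    uni = set(universe)
    kept: dict[str, tuple[str, ...]] = {}
    n_small = n_large = 0
    for set_id, genes in coll.sets.items():
        eff = sum(g in uni for g in genes)
        if eff < min_size:
            n_small += 1
        elif eff > max_size:
            n_large += 1
        else:
            kept[set_id] = genes
    if n_small or n_large:
        logger.info(
            "size filter [%d, %d]: removed %d too-small and %d too-large set(s), "
            "kept %d",
            min_size,
            max_size,
            n_small,
            n_large,
            len(kept),
        )
    return GeneSetCollection(
        sets=kept,
        descriptions={s: coll.descriptions[s] for s in kept if s in coll.descriptions},
    )


def membership_vector(
    coll: GeneSetCollection, set_id: str, universe
) -> MembershipVector:
    """Indicator of ``set_id`` over ``universe`` (1 = gene annotated to the set).

    Genes annotated to the set but absent from the universe are ignored with
    a logged count.  An indicator that is all zeros or all ones cannot be
    modelled and raises :class:`DegenerateSetError`.
    """
    if set_id not in coll.sets:
        raise KeyError(f"unknown set id {set_id!r}")
    universe = tuple(universe)
    members = set(coll.sets[set_id])
    indicator = np.fromiter(
        (1 if g in members else 0 for g in universe), dtype=np.int8, count=len(universe)
    )
    n_dropped = len(members) - int(indicator.sum())
    if n_dropped:
        logger.info("set %s: %d annotated gene(s) not in universe", set_id, n_dropped)
    n1 = int(indicator.sum())
    if n1 == 0 or n1 == len(universe):
        raise DegenerateSetError(
            f"set {set_id!r}: membership indicator is constant "
            f"({n1}/{len(universe)} members); cannot fit"
        )
    return MembershipVector(universe=universe, indicator=indicator)
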