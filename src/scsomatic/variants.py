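"""Variant keys, call sets, germline subtraction and burden extrapolation.

Single-cell somatic mutation analysis starts from per-cell variant call
sets plus one bulk call set per individual.  Bulk calls are germline and
are subtracted exactly, by normalized ``(chrom, pos, ref, alt)`` key, to
leave the somatic fraction.  Observed per-cell counts are extrapolated to
genome-wide burdens by dividing by the cell's callable-genome fraction.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

_DNA = frozenset("ACGT")

BURDEN_COLUMNS = [
    "cell_id",
    "individual_id",
    "group",
    "snv_count",
    "indel_count",
    "snv_burden",
    "indel_burden",
]


class VariantClass(str, Enum):
    SNV = "SNV"
    INS = "INS"
    DEL = "DEL"


class MnvError(ValueError):
    """Multi-nucleotide substitutions are rejected, not decomposed."""


class IndividualMismatchError(ValueError):
    """Cell and bulk call sets belong to different individuals."""


@dataclass(frozen=True, order=True)
class VariantKey:
    """A biallelic variant identified by chromosome, 1-based position, ref and alt."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if not _DNA.issuperset(self.ref) or not _DNA.issuperset(self.alt):
            raise ValueError(f"non-DNA allele in {self.chrom}:{self.pos} {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")

    def as_string(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @classmethod
    def from_string(cls, s: str) -> "VariantKey":
        chrom, pos, ref, alt = s.split(":")
        return cls(chrom, int(pos), ref, alt)


def normalize_key(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Left-normalize an allele pair: trim the shared suffix, then the shared
    prefix (advancing ``pos``), always leaving at least one base on each side.

    Prevents representation-dependent mismatches when subtracting germline
    INDELs (e.g. ``CTT>CT`` and ``CT>C`` at adjacent anchors are the same event).
    """
    ref = ref.upper()
    alt = alt.upper()
    # suffix first, then prefix: the canonical left-alignment order
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return VariantKey(chrom, pos, ref, alt)


def classify_variant(key: VariantKey) -> VariantClass:
    """SNV iff both alleles are single bases; otherwise INS/DEL by length.

    Raises :class:`MnvError` for equal-length multi-base substitutions, which
    fall outside the SNV/small-INDEL scope of the analysis.
    """
    lr, la = len(key.ref), len(key.alt)
    if lr == la == 1:
        return VariantClass.SNV
    if lr == la:
        raise MnvError(f"MNV not supported: {key.as_string()}")
    return VariantClass.INS if la > lr else VariantClass.DEL


@dataclass(frozen=True)
class CallInfo:
    """Optional per-call annotation carried alongside a key."""

    context: str | None = None  # 3-mer 5'REF3' for SNVs
    flank5: str | None = None  # 5' flanking sequence (INDELs)
    flank3: str | None = None  # 3' flanking sequence (INDELs)
    score: float | None = None  # deleteriousness annotation (e.g. CADD)


@dataclass
class CellCallset:
    """One cell's variant calls with sample metadata.

    ``calls`` maps each :class:`VariantKey` to its :class:`CallInfo`; the dict
    doubles as the de-duplicated key set.
    """

    cell_id: str
    individual_id: str
    group: str
    calls: dict[VariantKey, CallInfo] = field(default_factory=dict)
    callable_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.callable_fraction <= 1.0:
            raise ValueError(
                f"callable_fraction must lie in (0, 1], got {self.callable_fraction}"
            )

    @property
    def keys(self) -> set[VariantKey]:
        return set(self.calls)

    def partition(self) -> tuple[dict[VariantKey, CallInfo], dict[VariantKey, CallInfo]]:
        """Split calls into (SNVs, INDELs)."""
        snv: dict[VariantKey, CallInfo] = {}
        indel: dict[VariantKey, CallInfo] = {}
        for key, info in self.calls.items():
            if classify_variant(key) is VariantClass.SNV:
                snv[key] = info
            else:
                indel[key] = info
        return snv, indel


@dataclass
class GermlineCallset:
    """Bulk-derived germline call set for one individual."""

    individual_id: str
    calls: set[VariantKey] = field(default_factory=set)


def subtract_germline(
    cell: CellCallset, bulk: GermlineCallset | set[VariantKey] | frozenset[VariantKey]
) -> CellCallset:
    """Remove bulk germline calls from a cell's call set by exact key.

    Keys matching only on (chrom, pos) but differing in alleles are retained.
    Idempotent; the result never intersects the bulk set.
    """
    if isinstance(bulk, GermlineCallset):
        if bulk.individual_id != cell.individual_id:
            raise IndividualMismatchError(
                f"cell {cell.cell_id} is from {cell.individual_id!r}, "
                f"bulk from {bulk.individual_id!r}"
            )
        bulk_keys: set[VariantKey] = bulk.calls
    else:
        bulk_keys = set(bulk)
    somatic = {k: v for k, v in cell.calls.items() if k not in bulk_keys}
    n_removed = len(cell.calls) - len(somatic)
    logger.debug("cell %s: removed %d germline calls, %d somatic remain",
                 cell.cell_id, n_removed, len(somatic))
    return replace(cell, calls=somatic)


def extrapolate_burden(count: int, callable_fraction: float) -> float:
    """Extrapolate an observed count to the whole genome: count / callable_fraction."""
    if count < 0:
        raise ValueError("count must be non-negative")
    if not 0.0 < callable_fraction <= 1.0:
        raise ValueError(f"callable_fraction must lie in (0, 1], got {callable_fraction}")
    return count / callable_fraction


def filter_deleterious(
    calls: Mapping[VariantKey, CallInfo],
    gene_assignment: Mapping[VariantKey, str],
    gene_list: set[str] | frozenset[str],
    threshold: float = 15.0,
) -> dict[VariantKey, CallInfo]:
    """Keep calls with annotation score >= threshold in a gene from ``gene_list``.

    Scores arrive as input annotation (CADD-style, higher = more deleterious);
    the conventional cut-off of 15 is inclusive.  Calls without a score are
    excluded and their number is logged, never silently dropped.
    """
    if not gene_list:
        raise ValueError("gene_list is empty; likely a misconfiguration")
    unscored = sum(1 for info in calls.values() if info.score is None)
    if unscored:
        logger.warning("filter_deleterious: %d calls lack a score and were excluded", unscored)
    return {
        key: info
        for key, info in calls.items()
        if info.score is not None
        and info.score >= threshold
        and gene_assignment.get(key) in gene_list
    }


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    m = re.fullmatch(r"(?:chr)?(\d+)", chrom)
    return (int(m.group(1)), "") if m else (10**9, chrom)


def sorted_keys(keys: Iterable[VariantKey]) -> list[VariantKey]:
    """Sort variant keys by (chromosome — natural order, position, ref, alt)."""
    return sorted(keys, key=lambda k: (_chrom_sort_key(k.chrom), k.pos, k.ref, k.alt))


def burden_record(cell: CellCallset) -> dict:
    """Per-cell SNV/INDEL counts and genome-extrapolated burdens."""
    snv, indel = cell.partition()
    return {
        "cell_id": cell.cell_id,
        "individual_id": cell.individual_id,
        "group": cell.group,
        "snv_count": len(snv),
        "indel_count": len(indel),
        "snv_burden": extrapolate_burden(len(snv), cell.callable_fraction),
        "indel_burden": extrapolate_burden(len(indel), cell.callable_fraction),
    }


def burden_table(cells: Iterable[CellCallset]) -> pd.DataFrame:
    """Assemble the per-cell burden table (one row per cell, fixed column order)."""
    rows = [burden_record(c) for c in cells]
    return pd.DataFrame(rows, columns=BURDEN_COLUMNS)


def write_burden_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
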