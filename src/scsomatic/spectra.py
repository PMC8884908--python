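"""Mutation spectrum classification: SBS-96 contexts and ID-83 INDEL categories.

SNVs are classified by the COSMIC 96-channel convention: six
pyrimidine-centred substitution types (C>A, C>G, C>T, T>A, T>C, T>G)
crossed with the 5' and 3' flanking bases, flanks ordered A, C, G, T.
Purine-centred calls are reverse-complemented first, so the
classification is strand-symmetric.

INDELs follow the COSMIC ID-83 scheme: 1-bp insertions/deletions of C or
T by homopolymer run length, longer events by repeat-unit count, and
non-repetitive deletions by microhomology length.  The repeat run is
counted on the 3' flank of the left-normalized event.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .variants import CellCallset, VariantClass, VariantKey, classify_variant

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

SUBSTITUTION_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _build_sbs96_labels() -> list[str]:
    labels = []
    for sub in SUBSTITUTION_TYPES:
        ref = sub[0]
        for five in _BASES:
            for three in _BASES:
                labels.append(f"{five}[{sub}]{three}")
    return labels


SBS96_LABELS: list[str] = _build_sbs96_labels()
SBS96_INDEX: dict[str, int] = {lab: i for i, lab in enumerate(SBS96_LABELS)}


def _build_id83_labels() -> list[str]:
    labels = []
    for base in ("C", "T"):
        labels += [f"1:Del:{base}:{n}" for n in range(6)]
    for base in ("C", "T"):
        labels += [f"1:Ins:{base}:{n}" for n in range(6)]
    for size in ("2", "3", "4", "5"):
        labels += [f"{size}:Del:R:{n}" for n in range(6)]
    for size in ("2", "3", "4", "5"):
        labels += [f"{size}:Ins:R:{n}" for n in range(6)]
    for size, max_mh in (("2", 1), ("3", 2), ("4", 3), ("5", 5)):
        labels += [f"{size}:Del:M:{m}" for m in range(1, max_mh + 1)]
    return labels


ID83_LABELS: list[str] = _build_id83_labels()
ID83_INDEX: dict[str, int] = {lab: i for i, lab in enumerate(ID83_LABELS)}

assert len(SBS96_LABELS) == 96 and len(ID83_LABELS) == 83


def classify_snv_96(context: str, alt: str) -> str:
    """Classify an SNV given its 3-mer context (centred on the ref base) and alt.

    Returns the category label, e.g. ``"A[C>A]A"``.  If the central base is a
    purine, context and alt are reverse-complemented first.
    """
    context = context.upper()
    alt = alt.upper()
    if len(context) != 3 or len(alt) != 1:
        raise ValueError(f"need a 3-mer context and single alt base, got {context!r}, {alt!r}")
    if set(context) - set(_BASES) or alt not in _BASES:
        raise ValueError(f"non-DNA characters in {context!r}>{alt!r}")
    ref = context[1]
    if alt == ref:
        raise ValueError(f"alt equals ref base in context {context!r}")
    if ref in "AG":  # purine-centred: collapse to the pyrimidine strand
        context = _revcomp(context)
        alt = alt.translate(_COMPLEMENT)
        ref = context[1]
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def snv96_index(context: str, alt: str) -> int:
    return SBS96_INDEX[classify_snv_96(context, alt)]


def _run_length(seq: str, base: str) -> int:
    n = 0
    for c in seq:
        if c != base:
            break
        n += 1
    return n


def _repeat_copies(flank3: str, unit: str) -> int:
    n = 0
    while flank3.startswith(unit * (n + 1)):
        n += 1
    return n


def _microhomology(del_seq: str, flank5: str, flank3: str) -> int:
    """Longest partial-duplication overlap between the deleted sequence and
    its immediate flanks (prefix of the deletion vs 3' flank, suffix vs 5' flank)."""
    best = 0
    for m in range(1, len(del_seq)):
        if flank3.startswith(del_seq[:m]):
            best = max(best, m)
        if flank5.endswith(del_seq[-m:]):
            best = max(best, m)
    return best


def classify_indel_83(key: VariantKey, flank5: str, flank3: str) -> str:
    """Classify a left-normalized INDEL into its ID-83 category label.

    The event must be in anchor-base form (``ref`` is a prefix of ``alt`` for
    insertions and vice versa).  The homopolymer/repeat run is counted on the
    3' flank; 1-bp events involving A or G are complemented to the T/C strand
    (an A-run is a T-run on the opposite strand).
    """
    vclass = classify_variant(key)
    if vclass is VariantClass.SNV:
        raise ValueError(f"classify_indel_83 expects an INDEL, got SNV {key.as_string()}")
    flank5 = flank5.upper()
    flank3 = flank3.upper()
    if vclass is VariantClass.INS:
        if not key.alt.startswith(key.ref):
            raise ValueError(f"insertion not in anchor form: {key.as_string()}")
        seq = key.alt[len(key.ref):]
    else:
        if not key.ref.startswith(key.alt):
            raise ValueError(f"deletion not in anchor form: {key.as_string()}")
        seq = key.ref[len(key.alt):]
    length = len(seq)

    if length == 1:
        base = seq
        run = _run_length(flank3, base)  # existing copies 3' of the event
        if vclass is VariantClass.DEL:
            run += 1  # the deleted base itself is part of the run
            cat = min(run, 6) - 1  # suffix 0..5 <-> run length 1..6+
        else:
            cat = min(run, 5)  # suffix 0..5 <-> existing run 0..5+
        label_base = base if base in "CT" else base.translate(_COMPLEMENT)
        op = "Del" if vclass is VariantClass.DEL else "Ins"
        return f"1:{op}:{label_base}:{cat}"

    size = str(min(length, 5))
    copies = _repeat_copies(flank3, seq)
    if vclass is VariantClass.INS:
        return f"{size}:Ins:R:{min(copies, 5)}"
    if copies > 0:
        units = copies + 1  # total units including the deleted one
        return f"{size}:Del:R:{min(units, 6) - 1}"
    mh = _microhomology(seq, flank5, flank3)
    if mh > 0:
        cap = {2: 1, 3: 2, 4: 3}.get(length, 5)
        return f"{size}:Del:M:{min(mh, cap)}"
    return f"{size}:Del:R:0"


def build_spectrum(
    callsets: Iterable[CellCallset],
    grouping: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Count classified mutations per group into SBS-96 + ID-83 columns.

    ``grouping`` maps cell_id to a row label; by default each cell's ``group``
    attribute is used.  Returns ``(matrix, skipped)`` where ``matrix`` has one
    row per group over the 96 SNV then 83 INDEL categories, and ``skipped``
    counts unclassifiable calls (missing context/flanks) per group.
    """
    callsets = list(callsets)
    if grouping is None:
        grouping = {c.cell_id: c.group for c in callsets}
    rows = sorted({grouping[c.cell_id] for c in callsets}) if callsets else []
    columns = SBS96_LABELS + ID83_LABELS
    mat = pd.DataFrame(0, index=rows, columns=columns, dtype=int)
    skipped = pd.Series(0, index=rows, dtype=int)
    for cell in callsets:
        if cell.cell_id not in grouping:
            raise KeyError(f"cell {cell.cell_id} has no group assignment")
        g = grouping[cell.cell_id]
        for key, info in cell.calls.items():
            try:
                vclass = classify_variant(key)
            except ValueError:
                skipped[g] += 1
                continue
            if vclass is VariantClass.SNV:
                if info.context is None:
                    skipped[g] += 1
                    continue
                label = classify_snv_96(info.context, key.alt)
            else:
                if info.flank5 is None or info.flank3 is None:
                    skipped[g] += 1
                    continue
                label = classify_indel_83(key, info.flank5, info.flank3)
            mat.loc[g, label] += 1
    total_skipped = int(skipped.sum())
    if total_skipped:
        logger.info("build_spectrum: %d calls lacked context and were tallied as skipped",
                    total_skipped)
    return mat, skipped


def snv_spectrum(matrix: pd.DataFrame) -> pd.DataFrame:
    """The SBS-96 block of a combined spectrum matrix."""
    return matrix[SBS96_LABELS]


def indel_spectrum(matrix: pd.DataFrame) -> pd.DataFrame:
    """The ID-83 block of a combined spectrum matrix."""
    return matrix[ID83_LABELS]


def collapse_to_6(spectrum96: pd.DataFrame, relative: bool = False) -> pd.DataFrame:
    """Sum the 16 context columns of each substitution type.

    With ``relative=True`` rows are divided by their sums (zero rows stay zero).
    """
    if list(spectrum96.columns) != SBS96_LABELS:
        raise ValueError("expected a 96-column SBS spectrum in canonical order")
    out = pd.DataFrame(index=spectrum96.index, columns=list(SUBSTITUTION_TYPES), dtype=float)
    for i, sub in enumerate(SUBSTITUTION_TYPES):
        out[sub] = spectrum96.iloc[:, 16 * i : 16 * (i + 1)].sum(axis=1)
    if relative:
        sums = out.sum(axis=1)
        out = out.div(sums.replace(0, np.nan), axis=0).fillna(0.0)
    return out


def write_spectrum(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="group")


def read_spectrum(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="group")
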