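"""VCF 4.2 reading and writing for cell and bulk call sets (via pysam).

Records carry the trinucleotide context of SNVs in INFO/CTX and, for
INDELs, flanking sequence in INFO/F5 and INFO/F3 (there is no reference
genome to look flanks up in).  Multi-allelic records are split into
biallelic keys on read; alleles are left-normalized; MNV alleles are
counted and skipped.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

from .variants import CallInfo, MnvError, VariantKey, normalize_key, sorted_keys

logger = logging.getLogger(__name__)

#: contig layout of the virtual genome: 24 contigs x 125 Mb = 3 Gb total.
#: htslib stores POS as int32, so a single 3 Gb contig is not representable.
DEFAULT_CONTIGS: dict[str, int] = {f"chr{i}": 125_000_000 for i in range(1, 25)}


def _build_header(contigs: Mapping[str, int], sample: str | None = None) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.info.add("CTX", 1, "String", "Trinucleotide context 5'REF3' of an SNV")
    header.info.add("F5", 1, "String", "5' flanking sequence of an INDEL")
    header.info.add("F3", 1, "String", "3' flanking sequence of an INDEL")
    if sample is not None:
        header.formats.add("GT", 1, "String", "Genotype")
        header.add_sample(sample)
    return header


def write_vcf(
    path: str | Path,
    calls: Mapping[VariantKey, CallInfo],
    sample: str,
    contigs: Mapping[str, int] = DEFAULT_CONTIGS,
) -> None:
    """Write a call set as an uncompressed VCF sorted by (chrom, pos)."""
    header = _build_header(contigs, sample=sample)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for key in sorted_keys(calls):
            info = calls[key]
            rec = vcf.new_record(
                contig=key.chrom,
                start=key.pos - 1,
                alleles=(key.ref, key.alt),
            )
            if info.context is not None:
                rec.info["CTX"] = info.context
            if info.flank5 is not None:
                rec.info["F5"] = info.flank5
            if info.flank3 is not None:
                rec.info["F3"] = info.flank3
            rec.samples[sample]["GT"] = (0, 1)
            vcf.write(rec)


def read_vcf(path: str | Path) -> dict[VariantKey, CallInfo]:
    """Read a VCF into a normalized call dict.

    Multi-allelic records contribute one key per ALT; symbolic/equal-length
    multi-base alleles are skipped with a logged count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"VCF not found: {path}")
    calls: dict[VariantKey, CallInfo] = {}
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        declared = set(vcf.header.info)
        for rec in vcf:
            ctx = rec.info.get("CTX") if "CTX" in declared else None
            f5 = rec.info.get("F5") if "F5" in declared else None
            f3 = rec.info.get("F3") if "F3" in declared else None
            for alt in rec.alts or ():
                if set(alt) - set("ACGT"):
                    n_skipped += 1  # symbolic or non-DNA allele
                    continue
                try:
                    key = normalize_key(rec.contig, rec.pos, rec.ref, alt)
                except ValueError:
                    n_skipped += 1
                    continue
                if len(key.ref) == len(key.alt) and len(key.ref) > 1:
                    n_skipped += 1  # MNV: out of analysis scope
                    continue
                calls[key] = CallInfo(context=ctx, flank5=f5, flank3=f3)
    if n_skipped:
        logger.info("read_vcf(%s): skipped %d non-SNV/INDEL alleles", path.name, n_skipped)
    return calls


def read_key_set(path: str | Path) -> set[VariantKey]:
    return set(read_vcf(path))


def classify_or_none(key: VariantKey):
    from .variants import classify_variant

    try:
        return classify_variant(key)
    except MnvError:
        return None
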