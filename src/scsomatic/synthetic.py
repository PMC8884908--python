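"""Synthetic single-cell mutation cohorts with known ground truth.

Generates cohorts with the statistical structure the downstream analysis
assumes: two groups (mutation carriers vs controls) of individuals, each
with a handful of single cells; germline variants shared by all cells of
an individual and present in the matched bulk call set; somatic SNVs and
INDELs drawn from mixtures of trinucleotide-context signatures with
negative-binomially dispersed per-cell totals; clonal mutations
inherited along a per-individual clone tree; binomial thinning by each
cell's callable-genome fraction; and private artifact calls.

Mutations are context-annotated records on a virtual genome (positions
drawn uniformly without replacement), not placed on a real reference:
the spectrum stage needs only the 3-mer context of SNVs and the flanking
sequence of INDELs, both carried on the record.  Default parameters
mirror the published study design: 8 carrier vs 7 control individuals,
2-8 cells each, per-individual median burdens near 1900 vs 1500 SNVs,
NB dispersion theta = 10, and carrier-shifted signature mixtures.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import vcfio
from .signatures import fixture_id_catalog, fixture_sbs_catalog
from .variants import CallInfo, CellCallset, VariantKey
from .spectra import ID83_LABELS, SBS96_LABELS

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: defaults mirror the study design: carrier vs control HMEC cohorts
DEFAULT_MIXTURES = {
    "carrier": {"TS1": 0.297, "TS2": 0.571, "TS3": 0.132},
    "control": {"TS1": 0.069, "TS2": 0.728, "TS3": 0.203},
}
DEFAULT_INDEL_MIXTURES = {
    "carrier": {"TID1": 0.7, "TID2": 0.2, "TID3": 0.1},
    "control": {"TID1": 0.7, "TID2": 0.2, "TID3": 0.1},
}


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Parameters of a synthetic cohort; defaults emulate the study design."""

    n_individuals_per_group: dict[str, int] = field(
        default_factory=lambda: {"carrier": 8, "control": 7})
    cells_per_individual: tuple[int, int] = (2, 8)
    germline_variants_per_individual: int = 200
    mean_burden_per_group: dict[str, float] = field(
        default_factory=lambda: {"carrier": 1902.0, "control": 1506.0})
    nb_dispersion: float = 10.0
    signature_mixture_per_group: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(m) for g, m in DEFAULT_MIXTURES.items()})
    indel_signature_mixture_per_group: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(m) for g, m in DEFAULT_INDEL_MIXTURES.items()})
    indel_fraction: float = 0.08
    clone_tree_depth: int = 3
    clonal_fraction: float = 0.05
    callable_fraction_range: tuple[float, float] = (0.5, 0.9)
    artifact_rate: float = 10.0
    genome_length: int = 3_000_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        groups = sorted(self.n_individuals_per_group)
        if groups != sorted(self.mean_burden_per_group):
            raise ConfigurationError("group labels differ between n_individuals and mean_burden")
        for g, n in self.n_individuals_per_group.items():
            if n < 1:
                raise ConfigurationError(f"group {g!r} needs at least one individual")
        for g, mu in self.mean_burden_per_group.items():
            if mu < 0:
                raise ConfigurationError(f"negative mean burden for group {g!r}")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion (theta) must be positive")
        for g, mix in self.signature_mixture_per_group.items():
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ConfigurationError(f"signature mixture for {g!r} does not sum to 1")
            if any(w < 0 for w in mix.values()):
                raise ConfigurationError(f"negative mixture weight for {g!r}")
        for g, mix in self.indel_signature_mixture_per_group.items():
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ConfigurationError(f"INDEL mixture for {g!r} does not sum to 1")
        if not 0.0 <= self.indel_fraction <= 1.0:
            raise ConfigurationError("indel_fraction must lie in [0, 1]")
        if not 0.0 <= self.clonal_fraction <= 1.0:
            raise ConfigurationError("clonal_fraction must lie in [0, 1]")
        lo, hi = self.callable_fraction_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ConfigurationError("callable_fraction_range must be within (0, 1]")
        if self.artifact_rate < 0:
            raise ConfigurationError("artifact_rate must be non-negative")
        cmin, cmax = self.cells_per_individual
        if not 1 <= cmin <= cmax:
            raise ConfigurationError("invalid cells_per_individual range")

    @property
    def groups(self) -> list[str]:
        return sorted(self.n_individuals_per_group)


@dataclass
class TrueCloneNode:
    cells: list[str]
    mutations: list[VariantKey] = field(default_factory=list)
    children: list["TrueCloneNode"] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "cells": sorted(self.cells),
            "n_mutations": len(self.mutations),
            "mutations": [k.as_string() for k in self.mutations],
            "children": [c.to_dict() for c in self.children],
        }

    def nonempty_supports(self) -> set[frozenset]:
        """Cell-support sets of every edge carrying >= 1 mutation and >= 2 cells."""
        out: set[frozenset] = set()
        if self.mutations and len(self.cells) >= 2:
            out.add(frozenset(self.cells))
        for c in self.children:
            out |= c.nonempty_supports()
        return out


@dataclass
class SyntheticIndividual:
    individual_id: str
    group: str
    germline: dict[VariantKey, CallInfo]
    cells: list[CellCallset]  # observed calls: germline + somatic (thinned) + artifacts
    clone_tree: TrueCloneNode
    true_counts: dict[str, dict[str, int]]  # cell_id -> {snv, indel, artifacts}
    true_exposures: dict[str, dict[str, int]]  # cell_id -> signature -> SNV count


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    individuals: list[SyntheticIndividual]

    @property
    def cells(self) -> list[CellCallset]:
        return [c for ind in self.individuals for c in ind.cells]

    def truth_burden_table(self) -> pd.DataFrame:
        rows = []
        for ind in self.individuals:
            for cell in ind.cells:
                t = ind.true_counts[cell.cell_id]
                rows.append({
                    "cell_id": cell.cell_id, "individual_id": ind.individual_id,
                    "group": ind.group, "snv_count": t["snv"], "indel_count": t["indel"],
                })
        return pd.DataFrame(rows)


def _draw_positions(rng: np.random.Generator, n: int, genome_length: int,
                    taken: set[int]) -> list[int]:
    out: list[int] = []
    while len(out) < n:
        batch = rng.integers(0, genome_length, size=max(16, 2 * (n - len(out))))
        for p in batch:
            p = int(p)
            if p not in taken:
                taken.add(p)
                out.append(p)
                if len(out) == n:
                    break
    return out


def _locate(pos_linear: int, contigs: dict[str, int]) -> tuple[str, int]:
    for name, length in contigs.items():
        usable = length - 100  # keep room for flanks/alleles at the contig end
        if pos_linear < usable:
            return name, pos_linear + 1
        pos_linear -= usable
    raise ValueError("position beyond virtual genome")


def _random_seq(rng: np.random.Generator, n: int, exclude_first: str = "") -> str:
    bases = [b for b in _BASES if b not in exclude_first]
    first = bases[rng.integers(len(bases))] if n else ""
    rest = "".join(_BASES[i] for i in rng.integers(0, 4, size=max(n - 1, 0)))
    return first + rest


def _snv_record(rng: np.random.Generator, chrom: str, pos: int,
                label: str) -> tuple[VariantKey, CallInfo]:
    """Materialize an SBS-96 category as a VCF-style record; half the records
    are emitted on the purine strand to exercise the strand-collapse rule."""
    five, sub, three = label[0], label[2:5], label[6]
    ref, alt = sub[0], sub[2]
    ctx = five + ref + three
    if rng.random() < 0.5:
        ctx = ctx.translate(_COMPLEMENT)[::-1]
        ref = ref.translate(_COMPLEMENT)
        alt = alt.translate(_COMPLEMENT)
    return VariantKey(chrom, pos, ref, alt), CallInfo(context=ctx)


def _indel_record(rng: np.random.Generator, chrom: str, pos: int,
                  label: str) -> tuple[VariantKey, CallInfo]:
    """Materialize an ID-83 category as a left-normalized anchor-form record
    with flanking sequence consistent with the category."""
    size_s, op, kind, n_s = label.split(":")
    n = int(n_s)
    flank_len = 12

    if size_s == "1":
        base = kind
        if rng.random() < 0.5:  # emit on the purine strand
            base = base.translate(_COMPLEMENT)
        anchor = _random_seq(rng, 1, exclude_first=base)
        if op == "Del":
            run_total = n + 1 if n < 5 else 6 + int(rng.integers(0, 2))
            existing_after = run_total - 1  # the deleted base leads the run
            ref, alt = anchor + base, anchor
        else:
            run_total = n if n < 5 else 5 + int(rng.integers(0, 2))
            existing_after = run_total
            ref, alt = anchor, anchor + base
        f3 = base * existing_after + _random_seq(rng, flank_len - existing_after,
                                                 exclude_first=base)
        f5 = _random_seq(rng, flank_len, exclude_first=base)[::-1]
        if f5[-1] == base:  # keep the event left-aligned
            f5 = f5[:-1] + anchor
        return VariantKey(chrom, pos, ref, alt), CallInfo(flank5=f5, flank3=f3)

    length = int(size_s) if size_s != "5" else 5
    if kind == "M" and n >= length:
        length = n + 1  # microhomology must be shorter than the deleted tract
    unit = _random_seq(rng, length)
    anchor = _random_seq(rng, 1, exclude_first=unit[0] + unit[-1])
    if kind == "R":
        if op == "Del":
            units_total = n + 1 if n < 5 else 6
            copies_after = units_total - 1
            ref, alt = anchor + unit, anchor
        else:
            copies_after = n if n < 5 else 5
            ref, alt = anchor, anchor + unit
        f3 = unit * copies_after + _random_seq(rng, flank_len, exclude_first=unit[0])
        f5 = _random_seq(rng, flank_len, exclude_first=unit[-1])[::-1]
        return VariantKey(chrom, pos, ref, alt), CallInfo(flank5=f5, flank3=f3)

    # microhomology deletion: 3' flank shares an m-base prefix with the deleted
    # sequence but no full repeat copy
    caps = {"2": 1, "3": 2, "4": 3, "5": 5}
    m = min(n, caps[size_s], length - 1)
    ref, alt = anchor + unit, anchor
    tail = _random_seq(rng, flank_len - m, exclude_first=unit[m] if m < length else "")
    f3 = unit[:m] + tail
    f5 = _random_seq(rng, flank_len, exclude_first=unit[-1])[::-1]
    return VariantKey(chrom, pos, ref, alt), CallInfo(flank5=f5, flank3=f3)


def _sample_categories(rng: np.random.Generator, n: int, catalog: pd.DataFrame,
                       mixture: dict[str, float]) -> tuple[list[str], list[str]]:
    """Draw n category labels from a signature mixture; returns (labels, signatures)."""
    if n == 0:
        return [], []
    sigs = list(mixture)
    weights = np.array([mixture[s] for s in sigs], dtype=float)
    weights = weights / weights.sum()
    per_sig = rng.multinomial(n, weights)
    labels: list[str] = []
    sig_out: list[str] = []
    index = list(catalog.index)
    for sig, count in zip(sigs, per_sig):
        if count == 0:
            continue
        p = catalog[sig].to_numpy(dtype=float)
        idx = rng.choice(len(p), size=count, p=p / p.sum())
        labels += [index[i] for i in idx]
        sig_out += [sig] * count
    perm = rng.permutation(n)
    return [labels[i] for i in perm], [sig_out[i] for i in perm]


def _build_true_tree(cell_ids: list[str], depth: int,
                     rng: np.random.Generator) -> TrueCloneNode:
    """Balanced recursive bisection of the cell list to the requested depth."""
    node = TrueCloneNode(cells=list(cell_ids))
    if depth <= 0 or len(cell_ids) < 2:
        return node
    half = len(cell_ids) // 2
    left, right = cell_ids[:half], cell_ids[half:]
    for part in (left, right):
        if part:
            node.children.append(_build_true_tree(part, depth - 1, rng))
    return node


def _tree_edges(node: TrueCloneNode) -> list[TrueCloneNode]:
    out = [node]
    for c in node.children:
        out += _tree_edges(c)
    return out


def simulate_cohort(
    config: SimulationConfig,
    sbs_catalog: pd.DataFrame | None = None,
    id_catalog: pd.DataFrame | None = None,
) -> SyntheticCohort:
    """Simulate a full two-group cohort; deterministic given ``config.seed``.

    Per cell, the true somatic count is NB(mean_burden, theta); a fraction
    of it is inherited from ancestral clones shared with other cells of the
    same individual; each true mutation is observed with probability equal
    to the cell's callable fraction; artifact calls are added on top and
    never enter the truth records.
    """
    sbs_catalog = fixture_sbs_catalog() if sbs_catalog is None else sbs_catalog
    id_catalog = fixture_id_catalog() if id_catalog is None else id_catalog
    for g in config.groups:
        for s in config.signature_mixture_per_group[g]:
            if s not in sbs_catalog.columns:
                raise ConfigurationError(f"signature {s!r} not in the SBS catalog")
        for s in config.indel_signature_mixture_per_group[g]:
            if s not in id_catalog.columns:
                raise ConfigurationError(f"signature {s!r} not in the ID catalog")

    root_ss = np.random.SeedSequence(config.seed)
    contigs = dict(vcfio.DEFAULT_CONTIGS)
    # positions are drawn in the usable span (contig ends reserved for flanks)
    usable_length = min(config.genome_length,
                        sum(length - 100 for length in contigs.values()))
    total_ind = sum(config.n_individuals_per_group.values())
    ind_seeds = root_ss.spawn(total_ind)
    individuals: list[SyntheticIndividual] = []
    ind_counter = 0
    theta = config.nb_dispersion
    for group in config.groups:
        mu = config.mean_burden_per_group[group]
        mixture = config.signature_mixture_per_group[group]
        id_mixture = config.indel_signature_mixture_per_group[group]
        for _ in range(config.n_individuals_per_group[group]):
            rng = np.random.default_rng(ind_seeds[ind_counter])
            ind_counter += 1
            ind_id = f"M{ind_counter:02d}"
            n_cells = int(rng.integers(config.cells_per_individual[0],
                                       config.cells_per_individual[1] + 1))
            cell_ids = [f"{ind_id}-{i + 1}" for i in range(n_cells)]
            taken: set[int] = set()

            # germline: SNVs with uniform context, present in bulk and all cells
            germline: dict[VariantKey, CallInfo] = {}
            g_pos = _draw_positions(rng, config.germline_variants_per_individual,
                                    usable_length, taken)
            g_labels = [SBS96_LABELS[i] for i in rng.integers(0, 96,
                        size=config.germline_variants_per_individual)]
            for p, lab in zip(g_pos, g_labels):
                chrom, pos = _locate(p, contigs)
                key, info = _snv_record(rng, chrom, pos, lab)
                germline[key] = info

            # clone tree with clonal mutations on its edges
            tree = _build_true_tree(cell_ids, config.clone_tree_depth, rng)
            edges = [e for e in _tree_edges(tree) if len(e.cells) >= 2]
            depth = max(config.clone_tree_depth, 1)
            clonal_mu = config.clonal_fraction * mu / depth
            cell_records: dict[str, dict[VariantKey, CallInfo]] = {c: {} for c in cell_ids}
            cell_truth_class: dict[str, dict[str, int]] = {
                c: {"snv": 0, "indel": 0, "artifacts": 0} for c in cell_ids}
            cell_expo: dict[str, dict[str, int]] = {c: {} for c in cell_ids}

            def make_mutation(lab_is_indel: bool, label: str) -> tuple[VariantKey, CallInfo]:
                p = _draw_positions(rng, 1, usable_length, taken)[0]
                chrom, pos = _locate(p, contigs)
                if lab_is_indel:
                    return _indel_record(rng, chrom, pos, label)
                return _snv_record(rng, chrom, pos, label)

            for edge in edges:
                n_mut = int(rng.poisson(clonal_mu)) if clonal_mu > 0 else 0
                n_indel = int(rng.binomial(n_mut, config.indel_fraction)) if n_mut else 0
                n_snv = n_mut - n_indel
                labels, sigs = _sample_categories(rng, n_snv, sbs_catalog, mixture)
                id_labels, _ = _sample_categories(rng, n_indel, id_catalog, id_mixture)
                for lab, sig in zip(labels, sigs):
                    key, info = make_mutation(False, lab)
                    edge.mutations.append(key)
                    for c in edge.cells:
                        cell_records[c][key] = info
                        cell_truth_class[c]["snv"] += 1
                        cell_expo[c][sig] = cell_expo[c].get(sig, 0) + 1
                for lab in id_labels:
                    key, info = make_mutation(True, lab)
                    edge.mutations.append(key)
                    for c in edge.cells:
                        cell_records[c][key] = info
                        cell_truth_class[c]["indel"] += 1

            # private mutations top the inherited count up to the NB total
            for cid in cell_ids:
                target = int(rng.negative_binomial(theta, theta / (theta + mu))) if mu > 0 else 0
                inherited = cell_truth_class[cid]["snv"] + cell_truth_class[cid]["indel"]
                n_private = max(target - inherited, 0)
                n_indel = int(rng.binomial(n_private, config.indel_fraction)) if n_private else 0
                n_snv = n_private - n_indel
                labels, sigs = _sample_categories(rng, n_snv, sbs_catalog, mixture)
                id_labels, _ = _sample_categories(rng, n_indel, id_catalog, id_mixture)
                for lab, sig in zip(labels, sigs):
                    key, info = make_mutation(False, lab)
                    cell_records[cid][key] = info
                    cell_truth_class[cid]["snv"] += 1
                    cell_expo[cid][sig] = cell_expo[cid].get(sig, 0) + 1
                for lab in id_labels:
                    key, info = make_mutation(True, lab)
                    cell_records[cid][key] = info
                    cell_truth_class[cid]["indel"] += 1

            # observation: binomial thinning by callable fraction + artifacts
            cells: list[CellCallset] = []
            lo, hi = config.callable_fraction_range
            for cid in cell_ids:
                cf = float(rng.uniform(lo, hi))
                observed: dict[VariantKey, CallInfo] = {}
                kept = {"snv": 0, "indel": 0}
                for key, info in cell_records[cid].items():
                    if cf >= 1.0 or rng.random() < cf:
                        observed[key] = info
                        kept["snv" if len(key.ref) == len(key.alt) else "indel"] += 1
                n_art = int(rng.poisson(config.artifact_rate)) if config.artifact_rate > 0 else 0
                for _ in range(n_art):
                    lab = SBS96_LABELS[int(rng.integers(0, 96))]
                    key, info = make_mutation(False, lab)
                    observed[key] = info
                cell_truth_class[cid]["artifacts"] = n_art
                calls = dict(germline)
                calls.update(observed)
                cells.append(CellCallset(cell_id=cid, individual_id=ind_id, group=group,
                                         calls=calls, callable_fraction=cf))
            individuals.append(SyntheticIndividual(
                individual_id=ind_id, group=group, germline=germline, cells=cells,
                clone_tree=tree, true_counts=cell_truth_class, true_exposures=cell_expo,
            ))
    logger.info("simulated %d individuals, %d cells", len(individuals),
                sum(len(i.cells) for i in individuals))
    return SyntheticCohort(config=config, individuals=individuals)


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict[str, Path]:
    """Write a cohort as VCFs + metadata TSV + truth JSON; round-trip exact.

    Layout: ``bulk_<individual>.vcf``, ``<cell_id>.vcf``, ``metadata.tsv``
    (columns cell_id, individual_id, group, callable_fraction), ``truth.json``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta_rows = []
    truth: dict = {"seed": cohort.config.seed, "individuals": {}}
    for ind in cohort.individuals:
        bulk_path = directory / f"bulk_{ind.individual_id}.vcf"
        vcfio.write_vcf(bulk_path, ind.germline, sample=ind.individual_id)
        for cell in ind.cells:
            vcfio.write_vcf(directory / f"{cell.cell_id}.vcf", cell.calls,
                            sample=cell.cell_id)
            meta_rows.append({
                "cell_id": cell.cell_id, "individual_id": ind.individual_id,
                "group": ind.group, "callable_fraction": round(cell.callable_fraction, 6),
            })
        truth["individuals"][ind.individual_id] = {
            "group": ind.group,
            "germline": [k.as_string() for k in sorted(ind.germline)],
            "true_counts": ind.true_counts,
            "true_exposures": ind.true_exposures,
            "clone_tree": ind.clone_tree.to_dict(),
        }
    meta = pd.DataFrame(meta_rows, columns=["cell_id", "individual_id", "group",
                                            "callable_fraction"])
    meta_path = directory / "metadata.tsv"
    meta.to_csv(meta_path, sep="\t", index=False)
    truth_path = directory / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return {"metadata": meta_path, "truth": truth_path, "directory": directory}
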