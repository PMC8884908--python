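"""End-to-end orchestration: burdens -> spectra -> signatures -> clonality.

The pipeline consumes either a directory of VCFs plus a metadata TSV
(one VCF per cell, one bulk VCF per individual) or a synthetic cohort
generated in-process, and writes a fixed output layout: the per-cell
burden table, group-comparison results, spectrum matrices, de novo
signatures with catalog matches, bootstrap contribution intervals, the
contribution chi-squared test, per-individual sharing reports and clone
trees, and a run manifest.  All randomness flows from one seed, so a
(config, seed) pair reproduces a run exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, burden, clonality, signatures, spectra, synthetic, variants, vcfio

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of a full run; exactly one input mode."""

    mode: str = "synthetic"  # "synthetic" | "vcf-dir"
    input_dir: str | None = None  # vcf-dir mode: VCFs + metadata.tsv
    catalog_path: str | None = None  # optional COSMIC-layout TSV; default fixture
    k: int | None = None  # NMF rank; None -> select from k_range
    k_range: tuple[int, int] = (1, 5)
    n_boot: int = 1000
    exclude_outliers: bool = True
    seed: int = 0
    out_dir: str = "scsomatic_out"
    simulation: synthetic.SimulationConfig | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "vcf-dir"):
            raise ValueError(f"unknown input mode {self.mode!r}")
        if self.mode == "vcf-dir" and not self.input_dir:
            raise ValueError("vcf-dir mode needs input_dir")


def read_cohort_dir(directory: str | Path):
    """Load cells and bulk germline sets from a written cohort directory."""
    directory = Path(directory)
    meta_path = directory / "metadata.tsv"
    if not meta_path.exists():
        raise FileNotFoundError(f"metadata file not found: {meta_path}")
    meta = pd.read_csv(meta_path, sep="\t")
    cells: list[variants.CellCallset] = []
    bulks: dict[str, variants.GermlineCallset] = {}
    for row in meta.itertuples():
        calls = vcfio.read_vcf(directory / f"{row.cell_id}.vcf")
        cells.append(variants.CellCallset(
            cell_id=str(row.cell_id), individual_id=str(row.individual_id),
            group=str(row.group), calls=calls,
            callable_fraction=float(row.callable_fraction),
        ))
        ind = str(row.individual_id)
        if ind not in bulks:
            bulk_path = directory / f"bulk_{ind}.vcf"
            bulks[ind] = variants.GermlineCallset(ind, set(vcfio.read_vcf(bulk_path)))
    return cells, bulks, meta


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns a bundle of in-memory results.

    Stages run in the order burdens -> spectra -> signatures -> clonality;
    a failing stage raises after earlier outputs are already on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = int(config.seed)

    if config.mode == "synthetic":
        sim = config.simulation or synthetic.SimulationConfig(seed=rng_seed)
        cohort = synthetic.simulate_cohort(sim)
        cells = cohort.cells
        bulks = {i.individual_id: variants.GermlineCallset(i.individual_id,
                                                           set(i.germline))
                 for i in cohort.individuals}
        synthetic.write_cohort(cohort, out / "cohort")
    else:
        cells, bulks, _ = read_cohort_dir(config.input_dir)
        cohort = None

    logger.info("stage germline-subtraction: %d cells", len(cells))
    somatic = [variants.subtract_germline(c, bulks[c.individual_id]) for c in cells]

    logger.info("stage burdens")
    table = variants.burden_table(somatic)
    variants.write_burden_table(table, out / "burden_table.tsv")
    results, excluded = burden.compare_burdens(table,
                                               exclude_outliers=config.exclude_outliers)
    burden.write_results(results, out / "comparisons.tsv")

    logger.info("stage spectra")
    # outlier cells form their own spectrum group, as when an aberrant cell is
    # profiled separately from its cohort
    grouping = {c.cell_id: ("outlier" if c.cell_id in excluded else c.group)
                for c in somatic}
    spec, skipped = spectra.build_spectrum(somatic, grouping)
    spectra.write_spectrum(spec, out / "spectrum_full.tsv")
    snv_spec = spectra.snv_spectrum(spec)
    id_spec = spectra.indel_spectrum(spec)
    spectra.write_spectrum(spectra.collapse_to_6(snv_spec, relative=True),
                           out / "spectrum_6type.tsv")

    logger.info("stage signatures")
    if config.catalog_path:
        catalog = signatures.read_catalog(config.catalog_path)
    else:
        catalog = signatures.fixture_sbs_catalog()
    nonzero = snv_spec[snv_spec.sum(axis=1) > 0]
    # extraction works on per-individual spectra (outliers separated): group
    # pooling would cap the feasible rank at the number of groups
    ind_grouping = {c.cell_id: ("outlier" if c.cell_id in excluded else c.individual_id)
                    for c in somatic}
    ind_spec, _ = spectra.build_spectrum(somatic, ind_grouping)
    ind_snv = spectra.snv_spectrum(ind_spec)
    ind_snv = ind_snv[ind_snv.sum(axis=1) > 0]
    bundle: dict = {"burden_table": table, "comparisons": results,
                    "excluded_outliers": excluded, "spectrum": spec,
                    "skipped_calls": skipped, "cohort": cohort}
    if len(nonzero) >= 2 and len(ind_snv) >= 2:
        if config.k is not None:
            k = int(config.k)
            diag = None
        else:
            kmax = min(config.k_range[1], len(ind_snv))
            k, diag = signatures.select_rank(ind_snv, range(config.k_range[0], kmax + 1),
                                             seed=rng_seed)
        sigset = signatures.nmf_extract(ind_snv, k, n_restarts=50, seed=rng_seed,
                                        labels=[f"M{i + 1}" for i in range(k)])
        sigset.profiles.to_csv(out / "signatures_snv.tsv", sep="\t", index_label="category")
        matches, sim_matrix = signatures.match_to_catalog(sigset, catalog)
        pd.DataFrame([dataclasses.asdict(m) for m in matches]).to_csv(
            out / "catalog_matches.tsv", sep="\t", index=False)
        contribs = signatures.bootstrap_contributions(nonzero, sigset,
                                                      n_boot=config.n_boot, seed=rng_seed)
        ctab = signatures.contributions_table(contribs)
        ctab.to_csv(out / "contributions.tsv", sep="\t", index=False,
                    float_format="%.6g")
        attributed = _attributed_counts(nonzero, sigset)
        if len(attributed) >= 2:
            chi2 = signatures.compare_contribution_profiles(attributed)
            with open(out / "contribution_test.json", "w") as fh:
                json.dump(chi2, fh, indent=1)
            bundle["contribution_test"] = chi2
        bundle.update({"signatures": sigset, "catalog_matches": matches,
                       "contributions": ctab, "rank_diagnostics": diag})
    else:
        logger.warning("fewer than 2 non-empty groups: skipping signature extraction")

    logger.info("stage clonality")
    sharing_rows = []
    by_ind: dict[str, list] = {}
    for c in somatic:
        by_ind.setdefault(c.individual_id, []).append(c)
    trees: dict[str, clonality.CloneTree] = {}
    for ind, ind_cells in sorted(by_ind.items()):
        if len(ind_cells) < 2:
            continue
        report = clonality.sharing_analysis(ind_cells)
        clonality.write_sharing_matrix(report, out / f"sharing_{ind}.tsv")
        sharing_rows.append({"individual_id": ind, "n_cells": len(ind_cells),
                             "n_distinct": report.n_distinct, "n_shared": report.n_shared,
                             "percent_shared": report.percent_shared})
        tree = clonality.build_clone_tree(ind_cells)
        clonality.write_newick(tree, out / f"clone_tree_{ind}.nwk")
        trees[ind] = tree
    sharing_summary = pd.DataFrame(
        sharing_rows, columns=["individual_id", "n_cells", "n_distinct", "n_shared",
                               "percent_shared"])
    sharing_summary.to_csv(out / "sharing_summary.tsv", sep="\t", index=False,
                           float_format="%.6g")
    bundle["sharing_summary"] = sharing_summary
    bundle["clone_trees"] = trees

    manifest = {
        "version": __version__,
        "seed": rng_seed,
        "mode": config.mode,
        "exclude_outliers": config.exclude_outliers,
        "n_boot": config.n_boot,
        "k": config.k,
        "k_range": list(config.k_range),
        "catalog": config.catalog_path or "fixture",
        "n_cells": len(cells),
        "numpy": np.__version__,
    }
    if config.mode == "synthetic":
        sim_dict = dataclasses.asdict(config.simulation
                                      or synthetic.SimulationConfig(seed=rng_seed))
        manifest["simulation"] = sim_dict
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    bundle["manifest"] = manifest
    return bundle


def _attributed_counts(spectrum: pd.DataFrame,
                       sigset: signatures.SignatureSet) -> pd.DataFrame:
    """Groups x signatures table of mutation counts attributed to each signature."""
    rows = {}
    for group in spectrum.index:
        rel = signatures.refit_exposures(spectrum.loc[group].to_numpy(),
                                         sigset.profiles)
        total = spectrum.loc[group].sum()
        rows[group] = np.round(rel.to_numpy() * total).astype(int)
    return pd.DataFrame.from_dict(rows, orient="index", columns=sigset.labels)
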