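"""Validation experiments: parameter recovery, error calibration, coverage.

Each function runs a self-contained simulation experiment under the
cohort conditions the package models (two groups of individuals with
negative-binomially dispersed per-cell burdens, signature-mixture
spectra) and returns summary numbers.  They back the statistical
guarantees quoted in the documentation and are reused by the
reproduction script.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pandas as pd

from . import burden, pipeline, signatures, synthetic
from .spectra import SBS96_LABELS


def fold_change_worked_examples() -> dict[str, float]:
    """Fold changes between published per-cell mean burdens.

    4196 vs 1825 SNVs and 397 vs 231 INDELs per cell in the engineered
    cell-line comparison; 1902 vs 1506 SNVs for the per-individual medians
    in the primary-cell comparison.
    """
    return {
        "imec_snv": round(burden.fold_change(4196, 1825), 1),
        "imec_indel": round(burden.fold_change(397, 231), 1),
        "hmec_median_snv": round(burden.fold_change(1902, 1506), 1),
    }


def nmf_recovery_experiment(seed: int = 0, n_samples: int = 8,
                            n_restarts: int = 8) -> dict[str, float]:
    """Recover three known signatures from an exact rank-3 spectrum.

    Signatures occupy disjoint category blocks and the exposure matrix
    contains one pure sample per signature, making the factorization
    identifiable; recovery is scored by the worst matched cosine over all
    assignments, and the rank selector is run over 1..5.
    """
    rng = np.random.default_rng(seed)
    W0 = np.zeros((96, 3))
    for j in range(3):
        W0[32 * j: 32 * (j + 1), j] = rng.dirichlet(np.full(32, 1.0))
    H0 = np.zeros((3, n_samples))
    for j in range(3):
        H0[j, j] = 3000.0
    H0[:, 3:] = rng.uniform(0.3, 2.0, size=(3, n_samples - 3)) * 1500.0
    V = pd.DataFrame((W0 @ H0).T, columns=SBS96_LABELS)
    sig = signatures.nmf_extract(V, 3, n_restarts=n_restarts, seed=seed)
    W = sig.profiles.to_numpy()
    min_cos = max(
        min(signatures.cosine_similarity(W0[:, i], W[:, p[i]]) for i in range(3))
        for p in permutations(range(3))
    )
    k, _ = signatures.select_rank(V, range(1, 6), n_restarts=n_restarts, seed=seed + 1)
    return {"min_cosine": float(min_cos), "selected_rank": int(k)}


def _nb_counts(rng, mu, theta, n):
    return rng.negative_binomial(theta, theta / (theta + mu), size=n)


def _simulate_design(rng, fold: float, base: float = 1500.0, theta: float = 10.0,
                     sigma_u: float = 0.3, n_ind=(8, 7), cells=(2, 8)) -> pd.DataFrame:
    """Counts for the study design: 8 vs 7 individuals, 2-8 cells each."""
    rows = []
    for g, n, mu in (("carrier", n_ind[0], base * fold), ("control", n_ind[1], base)):
        for i in range(n):
            m = mu * np.exp(rng.normal(0.0, sigma_u))
            n_cells = int(rng.integers(cells[0], cells[1] + 1))
            for v in _nb_counts(rng, m, theta, n_cells):
                rows.append({"y": int(v), "group": g, "ind": f"{g}{i}"})
    return pd.DataFrame(rows)


def nb_recovery_experiment(seed: int = 0, n_reps: int = 100,
                           folds=(2.3, 1.3)) -> dict[str, float]:
    """Wald-interval coverage of the true log fold change at the study size.

    Each replicate simulates a cohort at one of the true folds, fits the
    NB GLM on rounded per-individual medians and the NB GLMM on per-cell
    counts, and checks whether the 95% Wald interval covers the truth.
    Returns coverage percentages over ``n_reps`` replicates per model
    (replicates alternate between the folds).
    """
    ss = np.random.SeedSequence(seed)
    covered = {"NBGLM": 0, "NBGLMM": 0}
    done = {"NBGLM": 0, "NBGLMM": 0}
    for rep, child in enumerate(ss.spawn(n_reps)):
        rng = np.random.default_rng(child)
        fold = folds[rep % len(folds)]
        log_true = np.log(fold)
        df = _simulate_design(rng, fold)
        med = df.groupby(["ind", "group"], as_index=False)["y"].median()
        try:
            glm = burden.fit_nbglm(np.round(med.y).astype(int), med.group)
            done["NBGLM"] += 1
            lo, hi = glm.log_fc_ci()
            covered["NBGLM"] += lo <= log_true <= hi
        except (ValueError, RuntimeError):
            pass
        try:
            mm = burden.fit_nbglmm(df.y, df.group, df.ind)
            done["NBGLMM"] += 1
            lo, hi = mm.log_fc_ci()
            covered["NBGLMM"] += lo <= log_true <= hi
        except (ValueError, RuntimeError):
            pass
    return {
        "nbglm_coverage_pct": 100.0 * covered["NBGLM"] / max(done["NBGLM"], 1),
        "nbglmm_coverage_pct": 100.0 * covered["NBGLMM"] / max(done["NBGLMM"], 1),
        "n_reps": n_reps,
    }


def type1_error_experiment(seed: int = 0, n_reps: int = 1000, n_per_group: int = 30,
                           mu: float = 1500.0, theta: float = 10.0) -> dict[str, float]:
    """Rejection rate of the NB GLM Wald test under the null at alpha = 0.05."""
    ss = np.random.SeedSequence(seed)
    rejections = 0
    done = 0
    group = ["a"] * n_per_group + ["b"] * n_per_group
    for child in ss.spawn(n_reps):
        rng = np.random.default_rng(child)
        y = _nb_counts(rng, mu, theta, 2 * n_per_group)
        try:
            res = burden.fit_nbglm(y, group)
        except (ValueError, RuntimeError):
            continue
        done += 1
        rejections += res.p_value < 0.05
    return {"type1_error": rejections / max(done, 1), "n_reps": done}


def bootstrap_coverage_experiment(seed: int = 0, n_runs: int = 100,
                                  n_mutations: int = 10_000,
                                  n_boot: int = 2000) -> dict[str, float]:
    """Coverage of bootstrap 95% CIs for a 50/50 two-signature mixture.

    Each run draws a multinomial spectrum from an equal mixture of two
    well-separated reference signatures, refits exposures under the
    percentile bootstrap, and checks that each signature's CI covers 0.5.
    The 2.5/97.5 percentile endpoints are themselves Monte-Carlo estimates;
    about 2000 replicates are needed before their noise stops eroding
    coverage, hence the default.
    """
    catalog = signatures.fixture_sbs_catalog()[["TS1", "TS3"]]
    mix = 0.5 * catalog["TS1"].to_numpy() + 0.5 * catalog["TS3"].to_numpy()
    mix = mix / mix.sum()
    ss = np.random.SeedSequence(seed)
    covered = {"TS1": 0, "TS3": 0}
    for child in ss.spawn(n_runs):
        data_seed, boot_seed = child.spawn(2)
        rng = np.random.default_rng(data_seed)
        counts = rng.multinomial(n_mutations, mix)
        spec = pd.DataFrame([counts], index=["g"], columns=catalog.index)
        est = signatures.bootstrap_contributions(spec, catalog, n_boot=n_boot,
                                                 seed=int(boot_seed.generate_state(1)[0] % 2**31))
        for e in est:
            if e.ci_low <= 0.5 <= e.ci_high:
                covered[e.signature] += 1
    return {
        "coverage_pct": 100.0 * min(covered.values()) / n_runs,
        "per_signature": {k: 100.0 * v / n_runs for k, v in covered.items()},
        "n_runs": n_runs,
    }


def end_to_end_identity_experiment(seed: int = 0, out_dir: str | None = None) -> dict:
    """Full pipeline on a noiseless cohort: burden identity + tree topology.

    With callable fraction 1 and no artifacts, the recovered burden table
    must equal the simulation truth cell-by-cell and every reconstructed
    clone tree must match the true topology (restricted to clones that
    acquired at least one mutation).
    """
    import tempfile

    sim = synthetic.SimulationConfig(
        n_individuals_per_group={"carrier": 3, "control": 3},
        cells_per_individual=(3, 4),
        germline_variants_per_individual=80,
        mean_burden_per_group={"carrier": 330.0, "control": 250.0},
        clone_tree_depth=2,
        clonal_fraction=0.3,
        callable_fraction_range=(1.0, 1.0),
        artifact_rate=0.0,
        seed=seed,
    )
    cohort = synthetic.simulate_cohort(sim)
    with tempfile.TemporaryDirectory() as tmp:
        cfg = pipeline.PipelineConfig(mode="synthetic", out_dir=out_dir or tmp,
                                      n_boot=150, k=3, seed=seed, simulation=sim)
        bundle = pipeline.run_pipeline(cfg)
    table = bundle["burden_table"].set_index("cell_id")
    truth = cohort.truth_burden_table().set_index("cell_id")
    n_cells = len(truth)
    burden_match = int((table.snv_count == truth.snv_count).sum()
                       + (table.indel_count == truth.indel_count).sum())
    trees_match = 0
    for ind in cohort.individuals:
        tree = bundle["clone_trees"][ind.individual_id]
        all_cells = frozenset(c.cell_id for c in ind.cells)
        got = {n.cells for n in tree.edges()
               if len(n.cells) >= 2 and n.mutations and n.cells != all_cells}
        want = {s for s in ind.clone_tree.nonempty_supports() if s != all_cells}
        trees_match += got == want and not tree.conflicts
    return {
        "burden_identity_pct": 100.0 * burden_match / (2 * n_cells),
        "tree_topology_match_pct": 100.0 * trees_match / len(cohort.individuals),
        "n_cells": n_cells,
    }
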