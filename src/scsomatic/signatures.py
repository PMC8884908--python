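"""De novo mutational signature extraction and exposure estimation.

The extraction is nonnegative matrix factorization of the spectrum matrix
V (categories x samples) into signature profiles W (categories x k,
columns summing to 1) and exposures H (k x samples), minimizing the
generalized Kullback-Leibler divergence

    D(V || WH) = sum_ij [ V_ij log(V_ij / (WH)_ij) - V_ij + (WH)_ij ]

by multiplicative updates — the standard objective for count-based
mutational-signature analysis.  Multiple random restarts guard against
local minima; the best run by final objective is kept.

Exposures against a fixed reference catalog are refit by non-negative
least squares, and 95% confidence intervals for relative contributions
come from a multinomial bootstrap of each group's spectrum at fixed
total mutation count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

logger = logging.getLogger(__name__)

_EPS = 1e-12  # pseudocount inside logarithms/denominators only, never added to data


@dataclass
class SignatureSet:
    """Signature profiles with matching exposures.

    ``profiles``: categories x k, each column a probability distribution.
    ``exposures``: k x samples, in mutation-count units so that
    ``profiles @ exposures`` reconstructs the spectrum.
    """

    profiles: pd.DataFrame
    exposures: pd.DataFrame
    objective: float = np.nan

    def __post_init__(self) -> None:
        if (self.profiles.values < 0).any() or (self.exposures.values < 0).any():
            raise ValueError("profiles and exposures must be non-negative")
        colsums = self.profiles.sum(axis=0).values
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValueError("profile columns must sum to 1")

    @property
    def labels(self) -> list[str]:
        return list(self.profiles.columns)

    @property
    def k(self) -> int:
        return self.profiles.shape[1]


@dataclass
class ContributionEstimate:
    group: str
    signature: str
    mean: float
    ci_low: float
    ci_high: float


@dataclass
class CatalogMatch:
    de_novo: str
    catalog: str
    cosine: float


def cosine_similarity(a, b) -> float:
    """Cosine of the angle between two non-negative, non-zero vectors."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    mask = V > 0
    div = np.sum(V[mask] * np.log(V[mask] / (WH[mask] + _EPS))) - V.sum() + WH.sum()
    return float(div)


def _nmf_single(V: np.ndarray, k: int, rng: np.random.Generator,
                max_iter: int, tol: float) -> tuple[np.ndarray, np.ndarray, float]:
    n, m = V.shape
    scale = np.sqrt(V.mean() / k)
    W = rng.uniform(0.1, 1.0, size=(n, k)) * scale
    H = rng.uniform(0.1, 1.0, size=(k, m)) * scale
    prev = np.inf
    for it in range(max_iter):
        WH = W @ H + _EPS
        H *= W.T @ (V / WH) / (W.sum(axis=0)[:, None] + _EPS)
        WH = W @ H + _EPS
        W *= (V / WH) @ H.T / (H.sum(axis=1)[None, :] + _EPS)
        if it % 10 == 9 or it == max_iter - 1:
            obj = _kl_divergence(V, W @ H)
            if prev - obj < tol * max(abs(prev), 1.0) and np.isfinite(prev):
                break
            prev = obj
    obj = _kl_divergence(V, W @ H)
    return W, H, obj


def nmf_extract(
    spectrum: pd.DataFrame,
    k: int,
    n_restarts: int = 100,
    seed: int | None = 0,
    max_iter: int = 10_000,
    tol: float = 1e-8,
    labels: list[str] | None = None,
) -> SignatureSet:
    """Extract ``k`` de novo signatures from a samples-x-categories spectrum.

    The best of ``n_restarts`` randomly initialized multiplicative-update runs
    (by final KL objective) is kept; W columns are renormalized to sum to 1
    with the compensating scale folded into H, leaving WH unchanged.
    """
    V = spectrum.to_numpy(dtype=float).T  # categories x samples
    if (V < 0).any():
        raise ValueError("spectrum contains negative counts")
    if V.sum() == 0:
        raise ValueError("all-zero spectrum")
    if not 1 <= k <= min(V.shape):
        raise ValueError(f"k={k} outside the feasible range 1..{min(V.shape)}")
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for _ in range(max(1, n_restarts)):
        W, H, obj = _nmf_single(V, k, rng, max_iter, tol)
        if best is None or obj < best[2]:
            best = (W, H, obj)
    W, H, obj = best
    col = W.sum(axis=0)
    col[col == 0] = 1.0
    W = W / col
    H = H * col[:, None]
    # stable presentation: order signatures by total exposure, largest first
    order = np.argsort(-H.sum(axis=1), kind="stable")
    W, H = W[:, order], H[order]
    if labels is None:
        labels = [f"S{i + 1}" for i in range(k)]
    profiles = pd.DataFrame(W, index=spectrum.columns, columns=labels)
    exposures = pd.DataFrame(H, index=labels, columns=spectrum.index)
    return SignatureSet(profiles=profiles, exposures=exposures, objective=obj)


def _match_columns(A: np.ndarray, B: np.ndarray) -> list[int]:
    """Greedy maximal-cosine assignment of columns of B to columns of A.

    Ties broken by lower index; adequate and deterministic for small k.
    """
    k = A.shape[1]
    sim = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            sim[i, j] = cosine_similarity(A[:, i], B[:, j])
    assignment = [-1] * k
    used: set[int] = set()
    for _ in range(k):
        best, bi, bj = -np.inf, -1, -1
        for i in range(k):
            if assignment[i] >= 0:
                continue
            for j in range(k):
                if j in used:
                    continue
                if sim[i, j] > best:
                    best, bi, bj = sim[i, j], i, j
        assignment[bi] = bj
        used.add(bj)
    return assignment


def select_rank(
    spectrum: pd.DataFrame,
    k_range=range(1, 6),
    n_restarts: int = 20,
    seed: int | None = 0,
    stability_threshold: float = 0.95,
    improvement_threshold: float = 1e-2,
    max_iter: int = 2000,
) -> tuple[int, pd.DataFrame]:
    """Choose the factorization rank by restart stability and error improvement.

    For each candidate k all restarts are matched signature-by-signature to
    the best run; stability(k) is the mean matched cosine.  The chosen rank is
    the largest k with stability >= ``stability_threshold`` whose KL objective
    improves on k-1 by at least ``improvement_threshold`` (relative); k=1 is
    always admissible.  Returns (k, diagnostics table).
    """
    ks = list(k_range)
    if not ks:
        raise ValueError("empty k_range")
    V = spectrum.to_numpy(dtype=float).T
    if V.shape[1] < 2:
        raise ValueError("rank selection needs at least two samples")
    rng = np.random.default_rng(seed)
    rows = []
    prev_obj = None
    for k in ks:
        runs = [_nmf_single(V, k, rng, max_iter, 1e-8) for _ in range(n_restarts)]
        objs = [r[2] for r in runs]
        best_idx = int(np.argmin(objs))
        Wb = runs[best_idx][0]
        sims = []
        for i, (W, _, _) in enumerate(runs):
            if i == best_idx:
                continue
            assignment = _match_columns(Wb, W)
            sims += [cosine_similarity(Wb[:, c], W[:, assignment[c]]) for c in range(k)]
        stability = float(np.mean(sims)) if sims else 1.0
        obj = objs[best_idx]
        scale = max(prev_obj if prev_obj is not None else 0.0, 1e-9 * V.sum())
        improvement = np.nan if prev_obj is None else (prev_obj - obj) / scale
        rows.append({"k": k, "objective": obj, "stability": stability,
                     "rel_improvement": improvement})
        prev_obj = obj
    diag = pd.DataFrame(rows)
    chosen = ks[0]
    for row in rows:
        ok_stab = row["stability"] >= stability_threshold
        ok_impr = np.isnan(row["rel_improvement"]) or row["rel_improvement"] >= improvement_threshold
        if ok_stab and ok_impr:
            chosen = row["k"]
        if not ok_impr:
            break  # objective has flattened: larger k only splits noise
    return int(chosen), diag


def match_to_catalog(
    signatures: SignatureSet, catalog: pd.DataFrame
) -> tuple[list[CatalogMatch], pd.DataFrame]:
    """Best catalog entry per de novo signature by cosine similarity."""
    if signatures.profiles.shape[0] != catalog.shape[0]:
        raise ValueError(
            f"category dimension mismatch: {signatures.profiles.shape[0]} vs {catalog.shape[0]}"
        )
    sim = pd.DataFrame(
        np.zeros((signatures.k, catalog.shape[1])),
        index=signatures.labels,
        columns=catalog.columns,
    )
    for lab in signatures.labels:
        for cat in catalog.columns:
            sim.loc[lab, cat] = cosine_similarity(
                signatures.profiles[lab].values, catalog[cat].values
            )
    matches = [
        CatalogMatch(lab, sim.loc[lab].idxmax(), float(sim.loc[lab].max()))
        for lab in signatures.labels
    ]
    return matches, sim


def refit_exposures(counts, catalog: pd.DataFrame) -> pd.Series:
    """Non-negative least-squares exposure of one spectrum against a catalog.

    Solves min ||v - C e||_2 with e >= 0 and returns relative contributions
    e / sum(e) (all-zero if the spectrum is orthogonal to every signature).
    """
    if catalog.shape[1] == 0:
        raise ValueError("empty catalog")
    v = np.asarray(counts, dtype=float).ravel()
    if v.shape[0] != catalog.shape[0]:
        raise ValueError("spectrum/catalog dimension mismatch")
    e, _ = nnls(catalog.to_numpy(dtype=float), v)
    total = e.sum()
    rel = e / total if total > 0 else e
    return pd.Series(rel, index=catalog.columns)


def bootstrap_contributions(
    spectrum: pd.DataFrame,
    catalog: pd.DataFrame | SignatureSet,
    n_boot: int = 1000,
    seed: int | None = 0,
) -> list[ContributionEstimate]:
    """Mean and percentile 95% CI of relative contributions per group.

    Each group's spectrum is resampled as a multinomial over categories at its
    observed total, and exposures are refit per replicate by NNLS.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100 for stable percentile intervals")
    if isinstance(catalog, SignatureSet):
        catalog = catalog.profiles
    rng = np.random.default_rng(seed)
    C = catalog.to_numpy(dtype=float)
    out: list[ContributionEstimate] = []
    for group in spectrum.index:
        v = spectrum.loc[group].to_numpy(dtype=float)
        total = int(round(v.sum()))
        if total == 0:
            raise ValueError(f"group {group!r} has zero mutations")
        p = v / v.sum()
        reps = np.empty((n_boot, catalog.shape[1]))
        for b in range(n_boot):
            vb = rng.multinomial(total, p).astype(float)
            e, _ = nnls(C, vb)
            s = e.sum()
            reps[b] = e / s if s > 0 else e
        mean = reps.mean(axis=0)
        # renormalize so per-group means sum to 1 (guards all-zero replicates)
        if mean.sum() > 0:
            mean = mean / mean.sum()
        lo = np.percentile(reps, 2.5, axis=0)
        hi = np.percentile(reps, 97.5, axis=0)
        for j, sig in enumerate(catalog.columns):
            out.append(ContributionEstimate(
                group=str(group), signature=str(sig),
                mean=float(mean[j]),
                ci_low=float(min(lo[j], mean[j])),
                ci_high=float(max(hi[j], mean[j])),
            ))
    return out


def contributions_table(estimates: list[ContributionEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"group": e.group, "signature": e.signature, "mean": e.mean,
          "ci_low": e.ci_low, "ci_high": e.ci_high} for e in estimates],
        columns=["group", "signature", "mean", "ci_low", "ci_high"],
    )


def compare_contribution_profiles(attributed_counts: pd.DataFrame) -> dict:
    """Pearson chi-squared test that groups share one signature-contribution profile.

    ``attributed_counts``: groups x signatures table of integer mutation counts
    attributed to each signature.  Returns chi2, p, df, and a low-expected-count
    warning flag (any expected cell < 1).
    """
    table = attributed_counts.to_numpy(dtype=float)
    if table.shape[0] < 2:
        raise ValueError("need at least two groups")
    chi2, p, df, expected = stats.chi2_contingency(table, correction=False)
    if np.allclose(table, table[0], atol=1e-12) and np.ptp(table, axis=0).max() == 0:
        chi2, p = 0.0, 1.0
    warning = bool((expected < 1).any())
    if warning:
        logger.warning("chi-squared: some expected cells < 1; test may be unreliable")
    return {"chi2": float(chi2), "p_value": float(p), "df": int(df),
            "low_expected_warning": warning}


def read_catalog(path: str | Path) -> pd.DataFrame:
    """Read a reference catalog TSV: first column category labels, one column
    per signature (COSMIC reference-signature layout)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ValueError("catalog contains negative entries")
    return df / df.sum(axis=0)


def fixture_sbs_catalog() -> pd.DataFrame:
    """The small bundled SBS-like catalog (5 toy signatures over 96 contexts)."""
    with resources.files("scsomatic").joinpath("data/fixture_sbs.tsv").open() as fh:
        return read_catalog(fh)


def fixture_id_catalog() -> pd.DataFrame:
    """The small bundled ID-like catalog (3 toy signatures over 83 categories)."""
    with resources.files("scsomatic").joinpath("data/fixture_id.tsv").open() as fh:
        return read_catalog(fh)
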