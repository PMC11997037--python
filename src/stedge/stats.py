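"""Enrichment statistics: odds ratios, permutation tests, trend tests.

Spatial enrichment claims ("this spot set sits closer to the tumor edge
than chance", "density rises toward the boundary") are tested with
seeded permutation/resampling nulls constructed from the same section:

* edge enrichment — the observed mean distance-to-edge of a spot set is
  compared with uniformly resampled spot sets of the same size;
* density trend — Spearman correlation between shell midpoint distance
  and density, with a complete-spatial-randomness null that re-places
  the observed number of cells uniformly over the region mask
  (multinomial over shell areas);
* proximity — mean nearest-neighbor distance from set A to set B versus
  resampled A-sized sets.

All tests use the (1 + more-extreme)/(1 + n_perm) estimator, so p is in
(0, 1] and the tests are valid under the null by construction.  One-sided
directions are explicit arguments, never inferred from the data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
from scipy.spatial import cKDTree
from statsmodels.stats.multitest import multipletests

from .geometry import DensityProfile, EdgeDistanceField
from .types import SpotGrid

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: a=in-cluster&tumor, b=in-cluster&normal, c/d the rest."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError("contingency cells must be nonnegative integers")
        if sum(cells) <= 0:
            raise ValueError("all-zero contingency table")


@dataclass(frozen=True)
class ORResult:
    or_point: float
    log_or: float
    se_log_or: float
    ci95_lo: float
    ci95_hi: float
    correction_applied: bool
    fisher_p: float

    def __post_init__(self) -> None:
        if not (self.ci95_lo <= self.or_point <= self.ci95_hi):
            raise ValueError("odds-ratio CI does not bracket the point estimate")


@dataclass(frozen=True)
class PermutationTestResult:
    observed_stat: float
    n_perm: int
    null_mean: float
    null_sd: float
    p_value: float
    direction: str
    seed: int

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise ValueError("p_value must be in (0, 1]")

    def to_dict(self) -> dict:
        return {
            "observed_stat": self.observed_stat,
            "n_perm": self.n_perm,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "p_value": self.p_value,
            "direction": self.direction,
            "seed": self.seed,
        }


def _perm_p(observed: float, null: np.ndarray, direction: str) -> float:
    if direction == "less":
        extreme = int(np.sum(null <= observed))
    elif direction == "greater":
        extreme = int(np.sum(null >= observed))
    else:
        raise ValueError("direction must be 'less' or 'greater'")
    return (1 + extreme) / (1 + len(null))


def odds_ratio(t: ContingencyTable, haldane: bool = True) -> ORResult:
    """OR = ad/bc with optional Haldane–Anscombe 0.5 correction.

    The correction (default on) adds 0.5 to every cell when any cell is
    zero, and is flagged in the result.  The Woolf 95% CI is computed on
    the (corrected) cells; a Fisher exact p accompanies the estimate.
    """
    a, b, c, d = (float(t.a), float(t.b), float(t.c), float(t.d))
    fisher_p = float(st.fisher_exact([[t.a, t.b], [t.c, t.d]])[1])
    corrected = False
    if min(a, b, c, d) == 0:
        if not haldane:
            raise ValueError(
                "zero cell makes the odds ratio degenerate; "
                "enable the Haldane-Anscombe correction"
            )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    or_point = (a * d) / (b * c)
    log_or = np.log(or_point)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ORResult(
        or_point=float(or_point),
        log_or=float(log_or),
        se_log_or=float(se),
        ci95_lo=float(np.exp(log_or - 1.96 * se)),
        ci95_hi=float(np.exp(log_or + 1.96 * se)),
        correction_applied=corrected,
        fisher_p=fisher_p,
    )


def population_or_table(labels: pd.DataFrame, haldane: bool = True) -> pd.DataFrame:
    """Per-cluster odds of occurring in tumor vs normal, one-vs-rest.

    ``labels`` needs columns ``cluster`` and ``condition`` (values
    'tumor'/'normal').  Returns one row per cluster with OR, Woolf CI,
    Fisher p and BH-adjusted q.
    """
    for col in ("cluster", "condition"):
        if col not in labels.columns:
            raise ValueError(f"labels missing column {col!r}")
    conditions = set(labels["condition"])
    if not conditions <= {"tumor", "normal"}:
        raise ValueError(f"unknown condition labels: {sorted(conditions - {'tumor', 'normal'})}")
    if len(conditions) < 2:
        raise ValueError("both tumor and normal conditions are required")
    clusters = sorted(set(labels["cluster"]))
    if len(clusters) < 2:
        raise ValueError("at least two clusters are required")
    is_tumor = (labels["condition"] == "tumor").to_numpy()
    rows = []
    for cl in clusters:
        in_cl = (labels["cluster"] == cl).to_numpy()
        t = ContingencyTable(
            a=int(np.sum(in_cl & is_tumor)),
            b=int(np.sum(in_cl & ~is_tumor)),
            c=int(np.sum(~in_cl & is_tumor)),
            d=int(np.sum(~in_cl & ~is_tumor)),
        )
        r = odds_ratio(t, haldane=haldane)
        rows.append(
            {
                "cluster": cl,
                "a": t.a,
                "b": t.b,
                "c": t.c,
                "d": t.d,
                "or": r.or_point,
                "ci95_lo": r.ci95_lo,
                "ci95_hi": r.ci95_hi,
                "correction_applied": r.correction_applied,
                "fisher_p": r.fisher_p,
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["fisher_p"].to_numpy())
    return out


def edge_enrichment_test(
    S: Sequence[str],
    field: EdgeDistanceField,
    n_perm: int = 1000,
    seed: int = 0,
    direction: str = "less",
) -> PermutationTestResult:
    """Is the spot set closer to the tumor edge than a random set?

    Observed statistic: mean distance-to-edge of S.  Null: means of
    uniformly resampled subsets of size |S| (without replacement) from
    the field's subjects.  ``direction='less'`` tests edge proximity.
    """
    dist = field.as_series()
    S = list(dict.fromkeys(S))
    missing = [s for s in S if s not in dist.index]
    if missing:
        raise ValueError(f"spot {missing[0]!r} not in the distance field")
    if len(S) < 2:
        raise ValueError("S must contain at least 2 spots")
    values = dist.to_numpy(dtype=float)
    m, N = len(S), len(values)
    observed = float(dist.loc[S].mean())
    if m == N:
        warnings.warn("S covers the whole field; test is degenerate (p = 1)")
        return PermutationTestResult(
            observed_stat=observed,
            n_perm=n_perm,
            null_mean=observed,
            null_sd=0.0,
            p_value=1.0,
            direction=direction,
            seed=seed,
        )
    rng = np.random.default_rng(seed)
    keys = rng.random((n_perm, N))
    take = np.argpartition(keys, m - 1, axis=1)[:, :m]
    null = values[take].mean(axis=1)
    return PermutationTestResult(
        observed_stat=observed,
        n_perm=n_perm,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)),
        p_value=_perm_p(observed, null, direction),
        direction=direction,
        seed=seed,
    )


def _spearman_vs_midpoints(midpoints: np.ndarray, dens: np.ndarray) -> np.ndarray:
    """Row-wise Spearman correlation of density rows against midpoints."""
    rd = st.rankdata(dens, axis=-1)
    rm = st.rankdata(midpoints)
    rd_c = rd - rd.mean(axis=-1, keepdims=True)
    rm_c = rm - rm.mean()
    denom = np.sqrt((rd_c**2).sum(axis=-1) * (rm_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rd_c @ rm_c) / denom
    return rho


def density_trend_test(
    profile: DensityProfile,
    cls: str,
    n_perm: int = 1000,
    seed: int = 0,
    direction: str = "less",
):
    """Does shell density fall with distance from the edge?

    Statistic: Spearman rho between shell midpoint distance and density.
    Null: the observed number of cells is re-placed uniformly over the
    mask — per-shell counts resampled as multinomial with probabilities
    proportional to shell areas — and rho recomputed.  With
    ``direction='less'`` the one-sided p is for rho below the null
    (density rising toward the edge).  Returns (rho, result).
    """
    if profile.n_bins < 4:
        raise ValueError("insufficient shells: need >= 4 bins")
    area = np.asarray(profile.area_mm2, dtype=float)
    if np.any(area <= 0):
        raise ValueError("profile has empty shells (zero area)")
    n_cells = profile.total(cls)
    if n_cells == 0:
        raise ValueError(f"no cells of class {cls!r} in the profile")
    mid = profile.midpoints_um
    dens = profile.density(cls)
    rho = float(_spearman_vs_midpoints(mid, dens[None, :])[0])
    rng = np.random.default_rng(seed)
    p_bins = area / area.sum()
    null_counts = rng.multinomial(n_cells, p_bins, size=n_perm)
    null_rho = _spearman_vs_midpoints(mid, null_counts / area)
    result = PermutationTestResult(
        observed_stat=rho,
        n_perm=n_perm,
        null_mean=float(np.nanmean(null_rho)),
        null_sd=float(np.nanstd(null_rho, ddof=1)),
        p_value=_perm_p(rho, null_rho, direction),
        direction=direction,
        seed=seed,
    )
    return rho, result


def proximity_test(
    A: Sequence[str],
    B: Sequence[str],
    grid: SpotGrid,
    scope: Optional[Sequence[str]] = None,
    n_perm: int = 1000,
    seed: int = 0,
    direction: str = "less",
) -> PermutationTestResult:
    """Is spot set A closer to spot set B than a random set would be?

    Observed statistic: mean over a in A of the minimum Euclidean
    distance to B.  Null: A-sized sets resampled (without replacement)
    from ``scope`` (default: all grid spots).
    """
    B = list(dict.fromkeys(B))
    if not B:
        raise ValueError("B is empty")
    A = list(dict.fromkeys(A))
    if not A:
        raise ValueError("A is empty")
    idx = grid.barcode_index()
    for s in A + B + (list(scope) if scope is not None else []):
        if s not in idx:
            raise ValueError(f"spot {s!r} not on the grid")
    coords = grid.coords
    tree = cKDTree(coords[[idx[b] for b in B]])
    scope_bcs = list(dict.fromkeys(scope)) if scope is not None else list(grid.barcodes)
    scope_pos = np.array([idx[s] for s in scope_bcs])
    d_scope, _ = tree.query(coords[scope_pos], k=1)
    a_pos = np.array([idx[s] for s in A])
    d_a, _ = tree.query(coords[a_pos], k=1)
    observed = float(d_a.mean())
    m, N = len(A), len(scope_bcs)
    if m > N:
        raise ValueError("|A| exceeds the resampling scope")
    rng = np.random.default_rng(seed)
    keys = rng.random((n_perm, N))
    take = np.argpartition(keys, m - 1, axis=1)[:, :m]
    null = d_scope[take].mean(axis=1)
    return PermutationTestResult(
        observed_stat=observed,
        n_perm=n_perm,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)),
        p_value=_perm_p(observed, null, direction),
        direction=direction,
        seed=seed,
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (monotone, q >= p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
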