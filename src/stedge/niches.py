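"""Marker-niche calling, niche overlap/composition, and gene-set scoring.

A "niche" here is the operational definition used throughout the
analysis: the top quantile (default 10%) of spots ranked by a marker's
expression, within a ranking scope (all spots of the section, or tumor
spots only).  Two spot-level gene-set scores are provided:

* ``auc_score`` — a rank-recovery AUC: genes are ranked per spot by
  expression and the score is the normalized area under the signature's
  recovery curve across the top fraction of ranks (in [0, 1], invariant
  under any strictly monotone transform of the spot's profile);
* ``module_score`` — a background-corrected mean-expression score:
  mean signature expression minus the mean of expression-matched control
  genes, on log1p counts-per-10k.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    TUMOR_ZONES,
    CompartmentMap,
    CountMatrix,
    SignatureLibrary,
)

logger = logging.getLogger(__name__)

SCOPES = ("all_spots", "tumor_only")


@dataclass(frozen=True)
class NicheCall:
    """Top-quantile spot set for one marker (or signature) on one section."""

    section_id: str
    marker: str
    q: float
    scope: str
    member_barcodes: np.ndarray

    def __post_init__(self) -> None:
        if not 0 < self.q < 1:
            raise ValueError("q must be in (0, 1)")
        if self.scope not in SCOPES:
            raise ValueError(f"scope must be one of {SCOPES}")

    @property
    def members(self) -> set:
        return set(self.member_barcodes.tolist())

    def __len__(self) -> int:
        return len(self.member_barcodes)


@dataclass(frozen=True)
class OverlapSummary:
    """Exact inclusion–exclusion region counts and pairwise Jaccard."""

    markers: tuple
    exact_region_counts: Mapping[tuple, int]
    jaccard: pd.DataFrame

    def union_size(self) -> int:
        return int(sum(self.exact_region_counts.values()))


def _top_quantile(
    values: np.ndarray, barcodes: np.ndarray, q: float
) -> np.ndarray:
    """Top ceil(q*N) barcodes by value desc, ties broken by barcode asc."""
    n_sel = math.ceil(q * len(values))
    order = np.lexsort((np.asarray(barcodes, dtype=object), -np.asarray(values, dtype=float)))
    return np.asarray(barcodes, dtype=object)[order[:n_sel]]


def call_marker_niches(
    counts: CountMatrix,
    marker: str,
    comp: Optional[CompartmentMap] = None,
    q: float = 0.10,
    scope: str = "all_spots",
    section_id: str = "section",
) -> NicheCall:
    """Rank spots by a marker's expression and keep the top quantile.

    Exactly ceil(q * N_scope) spots are returned; ties are resolved by
    ascending barcode, so the call is deterministic and invariant under
    any strictly monotone transform of the expression vector.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if scope not in SCOPES:
        raise ValueError(f"scope must be one of {SCOPES}")
    expr = counts.gene_vector(marker)  # KeyError if absent
    barcodes = np.asarray(counts.barcodes, dtype=object)
    if scope == "tumor_only":
        if comp is None:
            raise ValueError("tumor_only scope requires a CompartmentMap")
        tumor = set(comp.barcodes_for("tumor").tolist())
        keep = np.array([b in tumor for b in barcodes])
        expr, barcodes = expr[keep], barcodes[keep]
        if barcodes.size == 0:
            raise ValueError("tumor_only scope is empty")
    members = _top_quantile(expr, barcodes, q)
    return NicheCall(
        section_id=section_id, marker=marker, q=q, scope=scope, member_barcodes=members
    )


def overlap_summary(calls: Sequence[NicheCall]) -> OverlapSummary:
    """Venn-style exact region counts plus the pairwise Jaccard matrix."""
    if not calls:
        raise ValueError("no niche calls")
    sections = {c.section_id for c in calls}
    if len(sections) > 1:
        raise ValueError(f"niche calls from mixed sections: {sorted(sections)}")
    markers = tuple(c.marker for c in calls)
    if len(set(markers)) != len(markers):
        raise ValueError("duplicate markers in overlap")
    sets = {c.marker: c.members for c in calls}
    union = set().union(*sets.values())
    exact: Dict[tuple, int] = {}
    for spot in union:
        key = tuple(m for m in markers if spot in sets[m])
        exact[key] = exact.get(key, 0) + 1
    jac = pd.DataFrame(np.eye(len(markers)), index=markers, columns=markers)
    for a, b in itertools.combinations(markers, 2):
        inter = len(sets[a] & sets[b])
        uni = len(sets[a] | sets[b])
        jac.loc[a, b] = jac.loc[b, a] = inter / uni if uni else 0.0
    return OverlapSummary(markers=markers, exact_region_counts=exact, jaccard=jac)


def niche_composition(call: NicheCall, comp: CompartmentMap) -> pd.Series:
    """Fraction of niche members per tumor zone T1..T5 plus non_tumor.

    Fractions sum to 1 over the niche.
    """
    zone = comp.zone_of()
    compartment = comp.compartment_of()
    buckets = {z: 0 for z in TUMOR_ZONES}
    buckets["non_tumor"] = 0
    for b in call.member_barcodes:
        if compartment.get(b) == "tumor" and zone.get(b) in TUMOR_ZONES:
            buckets[zone[b]] += 1
        else:
            buckets["non_tumor"] += 1
    n = len(call)
    return pd.Series({k: v / n for k, v in buckets.items()}, name=call.marker)


def _present_signature(counts: CountMatrix, signature: Sequence[str], name: str) -> list:
    gene_set = set(counts.gene_ids.tolist())
    present = [g for g in dict.fromkeys(signature) if g in gene_set]
    absent = [g for g in dict.fromkeys(signature) if g not in gene_set]
    if absent:
        warnings.warn(
            f"signature {name!r}: {len(absent)} gene(s) absent from the matrix: {absent}",
            stacklevel=3,
        )
    if not present:
        raise ValueError(f"signature {name!r} has no genes in the count matrix")
    return present


def auc_score(
    counts: CountMatrix,
    signature: Sequence[str],
    top_frac: float = 0.05,
    name: str = "signature",
) -> pd.Series:
    """Rank-recovery AUC of a gene set, per spot, in [0, 1].

    Genes are ranked per spot by expression descending (ties by gene id
    ascending).  The recovery curve counts signature hits over the top
    floor(top_frac * G) ranks; the score is its area normalized by the
    maximal area (all signature genes at the very top).
    """
    if not 0 < top_frac <= 1:
        raise ValueError("top_frac must be in (0, 1]")
    present = _present_signature(counts, signature, name)
    G = counts.n_genes
    window = int(np.floor(top_frac * G))
    if window < 1:
        raise ValueError("top_frac window is empty for this matrix size")
    # pre-sort genes by id so a stable sort breaks expression ties by gene id
    id_order = np.argsort(counts.gene_ids.astype(str), kind="stable")
    X = counts.to_dense().astype(float)[id_order, :]
    order = np.argsort(-X, axis=0, kind="stable")  # rank -> gene row
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(G)[:, None], axis=0)
    gene_pos = {g: i for i, g in enumerate(counts.gene_ids[id_order])}
    sig_rows = np.array([gene_pos[g] for g in present])
    sig_ranks = ranks[sig_rows, :]  # (k, n_spots), 0-based
    contrib = np.clip(window - sig_ranks, 0, None)
    area = contrib.sum(axis=0).astype(float)
    k = len(present)
    max_area = float(sum(window - i for i in range(min(k, window))))
    scores = area / max_area
    return pd.Series(scores, index=counts.barcodes, name=name)


def module_score(
    counts: CountMatrix,
    signature: Sequence[str],
    n_bins: int = 25,
    n_ctrl: int = 50,
    seed: int = 0,
    name: str = "signature",
    normalize: bool = True,
) -> pd.Series:
    """Background-corrected mean expression of a gene set, per spot.

    Genes are binned into ``n_bins`` by mean expression across spots; for
    each signature gene, ``n_ctrl`` control genes are drawn (seeded,
    without replacement; with replacement plus a warning if the bin is
    smaller) from the same bin.  The score is mean signature expression
    minus mean control expression on log1p counts-per-10k.
    """
    present = _present_signature(counts, signature, name)
    X = counts.to_dense().astype(float)
    if normalize:
        lib = X.sum(axis=0)
        lib[lib == 0] = 1.0
        X = np.log1p(X / lib * 1e4)
    else:
        warnings.warn("module_score on raw (unnormalized) counts", stacklevel=2)
    gene_means = X.mean(axis=1)
    order = np.argsort(gene_means, kind="stable")
    n_bins_eff = min(n_bins, counts.n_genes)
    bin_of = np.empty(counts.n_genes, dtype=int)
    bin_of[order] = (np.arange(counts.n_genes) * n_bins_eff) // counts.n_genes
    gene_idx = counts.gene_index()
    rng = np.random.default_rng(seed)
    ctrl_rows: list = []
    for g in present:
        gi = gene_idx[g]
        pool = np.flatnonzero(bin_of == bin_of[gi])
        if len(pool) >= n_ctrl:
            ctrl_rows.append(rng.choice(pool, size=n_ctrl, replace=False))
        else:
            warnings.warn(
                f"bin of gene {g!r} has {len(pool)} < {n_ctrl} genes; "
                "sampling controls with replacement",
                stacklevel=2,
            )
            ctrl_rows.append(rng.choice(pool, size=n_ctrl, replace=True))
    sig_rows = np.array([gene_idx[g] for g in present])
    ctrl = np.concatenate(ctrl_rows)
    scores = X[sig_rows, :].mean(axis=0) - X[ctrl, :].mean(axis=0)
    return pd.Series(scores, index=counts.barcodes, name=name)


def population_signature_map(
    counts: CountMatrix,
    comp: Optional[CompartmentMap],
    library: SignatureLibrary,
    q: float = 0.10,
    top_frac: float = 0.05,
    scope: str = "all_spots",
    section_id: str = "section",
) -> Dict[str, NicheCall]:
    """High-spot sets per population signature.

    Each signature is AUC-scored per spot, then thresholded at the top
    quantile with the same deterministic tie policy as marker niches.
    """
    out: Dict[str, NicheCall] = {}
    barcodes = np.asarray(counts.barcodes, dtype=object)
    for pop in library.names():
        scores = auc_score(counts, library[pop], top_frac=top_frac, name=pop)
        values = scores.to_numpy()
        bcs = barcodes
        if scope == "tumor_only":
            if comp is None:
                raise ValueError("tumor_only scope requires a CompartmentMap")
            tumor = set(comp.barcodes_for("tumor").tolist())
            keep = np.array([b in tumor for b in bcs])
            values, bcs = values[keep], bcs[keep]
        members = _top_quantile(values, bcs, q)
        out[pop] = NicheCall(
            section_id=section_id, marker=pop, q=q, scope=scope, member_barcodes=members
        )
    return out


def score_table(scores: Mapping[str, pd.Series], method: str) -> pd.DataFrame:
    """Long-format (barcode, signature, score, method) table."""
    rows = []
    for name, s in scores.items():
        df = s.rename("score").rename_axis("barcode").reset_index()
        df["signature"] = name
        df["method"] = method
        rows.append(df[["barcode", "signature", "score", "method"]])
    return pd.concat(rows, ignore_index=True)
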