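"""Weighted Kolmogorov-Smirnov-style gene-set enrichment with a permutation
null.

The enrichment score (ES) walks the ranked list: set members ("hits") push
the running sum up in proportion to |metric|^weight (normalized to 1 over
hits) and non-members push it down by 1/(N - Nh); ES is the signed extremum
of the walk, so ES is always in [-1, 1]. Significance uses a gene-set
permutation null (random same-size sets from the ranked universe) rather
than phenotype permutation, which is degenerate with 2-3 replicates per
group. NES divides ES by the mean |null ES| of matching sign, nominal p is
the add-one-smoothed fraction of same-sign null ES at least as extreme, and
FDR q pools normalized null and observed scores per sign.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Set, Tuple

import numpy as np
import pandas as pd

from .expression import Contrast, ExpressionTable, compute_fold_changes, contrast_name
from .models import GeneSetCollection, ValidationError


@dataclass
class RankedList:
    """Gene ids ordered by a descending ranking metric."""

    gene_ids: list
    metric: np.ndarray

    def __post_init__(self) -> None:
        self.metric = np.asarray(self.metric, dtype=float)
        if len(self.gene_ids) != len(self.metric):
            raise ValidationError("gene_ids and metric lengths differ")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids in ranked list")
        if not np.all(np.isfinite(self.metric)):
            raise ValidationError("non-finite ranking metric")
        if np.any(np.diff(self.metric) > 0):
            raise ValidationError("metric must be non-increasing")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def positions_of(self, gene_set: Iterable[str]) -> np.ndarray:
        index = {g: i for i, g in enumerate(self.gene_ids)}
        return np.sort(np.array([index[g] for g in gene_set if g in index], dtype=int))


def rank_genes(
    table: ExpressionTable, contrast: Contrast, metric: str = "log2fc"
) -> RankedList:
    """Rank genes for one contrast, descending; ties break by gene_id.

    Metrics: ``log2fc`` (log2 of the post-offset fold change) or
    ``signed_log10p`` (sign of the fold change times -log10 of the
    precomputed p-value).
    """
    if len(table.rpkm) == 0:
        raise ValidationError("empty expression table")
    fc = compute_fold_changes(table, contrast)
    log2fc = np.log2(fc.where(fc > 0))
    if metric == "log2fc":
        values = log2fc
    elif metric == "signed_log10p":
        name = contrast_name(contrast)
        if name not in table.pvalues:
            raise ValidationError(f"no precomputed p-values for {name!r}")
        p = table.pvalues[name].reindex(fc.index).clip(lower=1e-300)
        values = np.sign(log2fc) * (-np.log10(p))
    else:
        raise ValidationError(f"unknown ranking metric {metric!r}")
    values = values.dropna()
    order = sorted(values.index, key=lambda g: (-values[g], g))
    return RankedList(gene_ids=list(order), metric=values[order].to_numpy())


def _hit_weights(metric: np.ndarray, weight_p: float) -> np.ndarray:
    w = np.abs(metric) ** weight_p if weight_p != 0 else np.ones_like(metric)
    return w


def _es_batch(
    positions: np.ndarray, weights: np.ndarray, n_total: int
) -> Tuple[np.ndarray, np.ndarray]:
    """ES for each row of sorted hit positions.

    ``positions``: (n_rows, k) sorted ascending; ``weights``: |metric|^p for
    every position in the ranked list. Returns (es, extremum_position).
    """
    n_rows, k = positions.shape
    w = weights[positions].astype(float)
    cumw = np.cumsum(w, axis=1)
    denom = cumw[:, -1:].copy()
    flat = denom[:, 0] <= 0
    if flat.any():  # all-zero metric over hits: fall back to equal weights
        cumw[flat] = np.arange(1, k + 1)[None, :]
        denom[flat] = float(k)
    miss = 1.0 / (n_total - k) if n_total > k else 0.0
    ranks = np.arange(k)[None, :]
    # running sum just after the i-th hit, and just before it
    after = cumw / denom - (positions - ranks) * miss
    hit_step = (cumw - np.concatenate(
        [np.zeros((n_rows, 1)), cumw[:, :-1]], axis=1
    )) / denom
    before = after - hit_step
    pos_dev = np.maximum(after.max(axis=1), 0.0)
    neg_dev = np.minimum(before.min(axis=1), 0.0)
    es = np.where(pos_dev >= -neg_dev, pos_dev, neg_dev)
    arg = np.where(
        pos_dev >= -neg_dev, after.argmax(axis=1), before.argmin(axis=1)
    )
    return es, arg


def enrichment_score(
    ranked: RankedList, gene_set: Iterable[str], weight_p: float = 1.0
) -> Tuple[float, np.ndarray, Set[str]]:
    """ES, full running sum, and leading-edge genes for one gene set.

    The leading edge is the hits at or before the positive extremum (or at
    and after the negative extremum for a negative ES).
    """
    positions = ranked.positions_of(gene_set)
    if len(positions) == 0:
        raise ValidationError("gene set does not intersect the ranked list")
    n = len(ranked)
    k = len(positions)
    weights = _hit_weights(ranked.metric, weight_p)
    hit_w = weights[positions].astype(float)
    if hit_w.sum() <= 0:
        hit_w = np.ones(k)
    increments = np.full(n, -(1.0 / (n - k)) if n > k else 0.0)
    increments[positions] = hit_w / hit_w.sum()
    running = np.cumsum(increments)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    pos_dev = max(running[i_max], 0.0)
    neg_dev = min(running[i_min], 0.0)
    es = pos_dev if pos_dev >= -neg_dev else neg_dev
    if es >= 0:
        leading = {ranked.gene_ids[i] for i in positions if i <= i_max}
    else:
        leading = {ranked.gene_ids[i] for i in positions if i >= i_min}
    return float(es), running, leading


def _null_es(
    ranked: RankedList,
    set_size: int,
    n_perm: int,
    rng: np.random.Generator,
    weight_p: float,
) -> np.ndarray:
    n = len(ranked)
    weights = _hit_weights(ranked.metric, weight_p)
    # sample n_perm same-size sets without replacement
    positions = np.argsort(
        rng.random((n_perm, n)), axis=1, kind="stable"
    )[:, :set_size]
    positions.sort(axis=1)
    es, _ = _es_batch(positions, weights, n)
    return es


@dataclass
class EnrichmentResult:
    name: str
    size: int
    es: float
    nes: float
    p_value: float
    fdr_q: float
    leading_edge_n: int


def gsea(
    ranked: RankedList,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
) -> pd.DataFrame:
    """Run enrichment for every gene set against a shared permutation budget.

    Returns a DataFrame indexed by set name with columns size, es, nes,
    p_value, fdr_q, leading_edge_n. Sets that do not intersect the ranked
    universe are dropped (reported via the ``n_skipped`` attribute in
    ``DataFrame.attrs``). Reproducible for a fixed seed.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    n = len(ranked)
    universe = set(ranked.gene_ids)
    rows = []
    null_nes_pool = []
    skipped = 0
    for name in collection.names():
        members = collection[name] & universe
        if len(collection[name]) > n:
            raise ValidationError(f"gene set {name!r} larger than the universe")
        if not members:
            skipped += 1
            continue
        es, _, leading = enrichment_score(ranked, members, weight_p)
        null = _null_es(ranked, len(members), n_perm, rng, weight_p)
        same_sign = null[null >= 0] if es >= 0 else null[null < 0]
        if len(same_sign):
            b = int(np.sum(np.abs(same_sign) >= abs(es)))
            p = (b + 1) / (len(same_sign) + 1)
            norm = np.abs(same_sign).mean()
        else:
            p = 1.0 / (n_perm + 1)
            norm = np.abs(null).mean() if len(null) else 1.0
        norm = norm if norm > 0 else 1.0
        nes = es / norm
        # normalize the whole null the same way for the FDR pool
        pos_mean = np.abs(null[null >= 0]).mean() if (null >= 0).any() else norm
        neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else norm
        null_nes = np.where(
            null >= 0,
            null / (pos_mean if pos_mean > 0 else 1.0),
            null / (neg_mean if neg_mean > 0 else 1.0),
        )
        null_nes_pool.append(null_nes)
        rows.append(
            EnrichmentResult(
                name=name,
                size=len(members),
                es=es,
                nes=nes,
                p_value=p,
                fdr_q=np.nan,
                leading_edge_n=len(leading),
            )
        )
    if not rows:
        raise ValidationError("no gene set intersects the ranked list")
    pooled = np.concatenate(null_nes_pool)
    obs = np.array([r.nes for r in rows])
    for r in rows:
        r.fdr_q = _fdr_q(r.nes, obs, pooled)
    frame = pd.DataFrame(
        {
            "size": [r.size for r in rows],
            "es": [r.es for r in rows],
            "nes": [r.nes for r in rows],
            "p_value": [r.p_value for r in rows],
            "fdr_q": [r.fdr_q for r in rows],
            "leading_edge_n": [r.leading_edge_n for r in rows],
        },
        index=pd.Index([r.name for r in rows], name="gene_set"),
    )
    frame.attrs["n_skipped"] = skipped
    return frame


def _fdr_q(nes: float, observed: np.ndarray, null_pool: np.ndarray) -> float:
    """FDR by pooling same-sign normalized null and observed scores."""
    if nes >= 0:
        null_same = null_pool[null_pool >= 0]
        obs_same = observed[observed >= 0]
        null_tail = np.sum(null_same >= nes)
        obs_tail = np.sum(obs_same >= nes)
    else:
        null_same = null_pool[null_pool < 0]
        obs_same = observed[observed < 0]
        null_tail = np.sum(null_same <= nes)
        obs_tail = np.sum(obs_same <= nes)
    if len(null_same) == 0 or obs_tail == 0:
        return 1.0
    null_frac = null_tail / len(null_same)
    obs_frac = obs_tail / len(obs_same)
    return float(min(1.0, null_frac / obs_frac))
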