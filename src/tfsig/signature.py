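"""Integrate peak assignments with DEG results into target-gene signatures.

Two tiers mirror the two rule sets used to define cytokine/TF signatures:

* full — gene is TF-bound (>=1 assigned peak) AND changes more than
  ``fc_threshold``-fold (default 2, either direction) with p < 0.05 AND has
  mean RPKM above ``min_mean_rpkm`` in at least one condition;
* compact — as full, but binding must include a high-amplitude peak (top
  quartile of all peaks by default) and the fold change must exceed 3.

With default thresholds the compact signature is a subset of the full one by
construction. The abundance filter is applied to both tiers; it can be
disabled with ``min_mean_rpkm=0``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Set, Tuple

import numpy as np

from .expression import DEGResult, ExpressionTable
from .models import Signature, SignatureEvidence, ValidationError
from .peaks import AmplitudeFlags, PeakGeneAssignment


def _best_peak(
    assignment: PeakGeneAssignment,
    gene_id: str,
    restrict_to: Optional[Set[str]] = None,
) -> Tuple[str, float, str]:
    """Highest-amplitude assigned peak for a gene (ties -> smallest peak_id)."""
    peak_ids = assignment.gene_to_peaks[gene_id]
    if restrict_to is not None:
        peak_ids = peak_ids & restrict_to
    best_id = max(
        sorted(peak_ids), key=lambda pid: assignment.peaks[pid].amplitude
    )
    relation = next(
        pair.relation
        for pair in assignment.pairs
        if pair.peak_id == best_id and pair.gene_id == gene_id
    )
    return best_id, assignment.peaks[best_id].amplitude, relation


def _derive(
    tier: str,
    assignment: PeakGeneAssignment,
    degs: DEGResult,
    table: ExpressionTable,
    fc_threshold: float,
    p_threshold: float,
    min_mean_rpkm: float,
    high_peaks: Optional[Set[str]],
) -> Signature:
    bound = assignment.bound_gene_ids
    universe = set(degs.table.index)
    if bound and universe and not (bound & universe):
        raise ValidationError(
            "assignment and DEG gene universes are disjoint "
            "(likely an ID-space mismatch)"
        )
    means = table.condition_means(raw=table.offset is not None)
    abundant = set(means.index[(means > min_mean_rpkm).any(axis=1)])
    log_thr = np.log2(fc_threshold)
    members: Dict[str, SignatureEvidence] = {}
    for gene_id in sorted(bound & universe & abundant):
        if high_peaks is not None and not (
            assignment.gene_to_peaks[gene_id] & high_peaks
        ):
            continue
        row = degs.table.loc[gene_id]
        fc, p = row["fold_change"], row["p_value"]
        if not np.isfinite(fc) or not np.isfinite(p):
            continue
        if not (abs(np.log2(fc)) > log_thr and p < p_threshold):
            continue
        best_id, best_amp, relation = _best_peak(assignment, gene_id, high_peaks)
        members[gene_id] = SignatureEvidence(
            fold_change=float(fc),
            p_value=float(p),
            direction=str(row["direction"]),
            best_peak_id=best_id,
            best_amplitude=float(best_amp),
            relation=relation,
        )
    return Signature(tier=tier, members=members)


def derive_full_signature(
    assignment: PeakGeneAssignment,
    degs: DEGResult,
    table: ExpressionTable,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    min_mean_rpkm: float = 2.0,
) -> Signature:
    """Full signature: bound genes with more-than-``fc_threshold``-fold
    response (p < ``p_threshold``) and mean RPKM > ``min_mean_rpkm`` in at
    least one condition.

    ``assignment`` must come from the treated-condition peak set and
    ``degs`` from the treated-vs-reference contrast. The abundance filter
    uses raw (pre-offset) RPKM means when an offset has been applied.
    """
    return _derive(
        "full", assignment, degs, table,
        fc_threshold, p_threshold, min_mean_rpkm, high_peaks=None,
    )


def derive_compact_signature(
    assignment: PeakGeneAssignment,
    degs: DEGResult,
    table: ExpressionTable,
    amplitude_flags: AmplitudeFlags,
    fc_threshold: float = 3.0,
    p_threshold: float = 0.05,
    min_mean_rpkm: float = 2.0,
) -> Signature:
    """Compact signature: as the full tier, but at least one assigned peak
    must be high-amplitude (``amplitude_flags`` from the same peak set used
    for the assignment) and the fold-change bar is higher (default 3)."""
    missing = set(amplitude_flags.flags) ^ {p.peak_id for p in assignment.peaks}
    if missing:
        raise ValidationError(
            "amplitude flags do not cover the assignment's peak set"
        )
    return _derive(
        "compact", assignment, degs, table,
        fc_threshold, p_threshold, min_mean_rpkm,
        high_peaks=amplitude_flags.high_peak_ids(),
    )


@dataclass
class FractionReport:
    """Bound-vs-responsive summary (the donut-plot statistics)."""

    n_bound: int
    n_responsive: int
    n_bound_and_responsive: int
    n_up: int
    n_down: int

    def __post_init__(self) -> None:
        assert self.n_bound_and_responsive <= min(self.n_bound, self.n_responsive)
        assert self.n_up + self.n_down == self.n_responsive

    @property
    def frac_bound_that_respond(self) -> float:
        return self.n_bound_and_responsive / self.n_bound if self.n_bound else 0.0

    @property
    def frac_responsive_that_are_bound(self) -> float:
        return (
            self.n_bound_and_responsive / self.n_responsive
            if self.n_responsive
            else 0.0
        )

    def to_dict(self) -> dict:
        return {
            "n_bound": self.n_bound,
            "n_responsive": self.n_responsive,
            "n_bound_and_responsive": self.n_bound_and_responsive,
            "n_up": self.n_up,
            "n_down": self.n_down,
            "frac_bound_that_respond": self.frac_bound_that_respond,
            "frac_responsive_that_are_bound": self.frac_responsive_that_are_bound,
        }


def bound_responsive_fractions(
    assignment: PeakGeneAssignment, degs: DEGResult
) -> FractionReport:
    """Share of bound genes that respond and share of responsive genes that
    are bound, with the up/down split of the responsive set."""
    bound = assignment.bound_gene_ids
    responsive = degs.deg_ids
    return FractionReport(
        n_bound=len(bound),
        n_responsive=len(responsive),
        n_bound_and_responsive=len(bound & responsive),
        n_up=len(degs.up_ids()),
        n_down=len(degs.down_ids()),
    )


def signature_collapse_stats(
    gene_set: Iterable[str],
    degs: DEGResult,
    mode: str = "significance",
) -> Dict[str, int]:
    """Classify a gene set's members as reduced / enhanced / unchanged under a
    knockout-vs-control contrast.

    ``mode='significance'`` requires the DEG-level call (fold change beyond
    the threshold and p below the threshold) before counting a gene as
    reduced (FC < 1) or enhanced (FC > 1); ``mode='raw'`` classifies on the
    fold change alone. Members absent from the expression universe are
    counted separately as ``n_absent``.
    """
    gene_set = set(gene_set)
    if not gene_set:
        raise ValidationError("empty gene set")
    if mode not in ("significance", "raw"):
        raise ValidationError(f"unknown mode {mode!r}")
    n_reduced = n_enhanced = n_unchanged = n_absent = 0
    for gene_id in sorted(gene_set):
        if gene_id not in degs.table.index:
            n_absent += 1
            continue
        row = degs.table.loc[gene_id]
        fc = row["fold_change"]
        changed = bool(row["is_deg"]) if mode == "significance" else (
            np.isfinite(fc) and fc != 1.0
        )
        if changed and fc < 1.0:
            n_reduced += 1
        elif changed and fc > 1.0:
            n_enhanced += 1
        else:
            n_unchanged += 1
    return {
        "n_reduced": n_reduced,
        "n_enhanced": n_enhanced,
        "n_unchanged": n_unchanged,
        "n_absent": n_absent,
    }
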