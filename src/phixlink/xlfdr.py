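"""Hierarchical target-decoy FDR filtering of crosslink identifications.

Candidate matches are prefiltered on fragment evidence, collapsed to unique
residue pairs, thresholded to a residue-pair FDR, aggregated to
protein-protein interaction (PPI) edges, and thresholded again to a PPI
FDR.  The FDR estimator is the reversed-decoy form
``max(0, TD - DD) / TT``: false matches against a target+decoy database of
equal sizes distribute their decoy classes as TT:TD:DD = 1:2:1, so
``TD - DD`` estimates the number of false matches hiding among the TT
class.  "Boosting for PPIs" grid-searches the residue-pair cutoff to
maximize accepted target PPIs subject to both FDR constraints.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .datamodel import (CandidateMatch, CrosslinkRecord, DecoyClass)

logger = logging.getLogger(__name__)


@dataclass
class FDRReport:
    """Decoy accounting at one score threshold."""

    level: str                       # "residue_pair" | "ppi"
    threshold_score: float
    counts: tuple[int, int, int]     # (TT, TD, DD) at score >= threshold
    fdr_est: float | None            # None when TT == 0 (undefined)

    @property
    def n_accepted_targets(self) -> int:
        return self.counts[0]


@dataclass
class PPIEdge:
    """An aggregated protein-pair edge backed by residue-pair crosslinks."""

    protein_a: str
    protein_b: str
    residue_pairs: list[CrosslinkRecord]
    aggregate_score: float
    decoy_class: DecoyClass
    datasets: frozenset[str] = frozenset()

    @property
    def pair(self) -> tuple[str, str]:
        return (self.protein_a, self.protein_b)

    @property
    def score(self) -> float:
        """Alias so edges and residue pairs share the FDR machinery."""
        return self.aggregate_score


@dataclass
class HierarchicalResult:
    """Outcome of the two-level filter.

    ``residue_pairs`` and ``ppi_edges`` are the final target-only outputs:
    intra-protein pairs pass at the residue-pair threshold alone, while
    inter-protein pairs must additionally belong to an accepted PPI edge.
    Decoy-containing items are removed from the final sets but counted in
    the reports.
    """

    residue_pairs: list[CrosslinkRecord]
    ppi_edges: list[PPIEdge]
    rp_report: FDRReport
    ppi_report: FDRReport


def prefilter_candidates(matches: Iterable[CandidateMatch]) -> list[CandidateMatch]:
    """Fragment-evidence prefilter: > 2 non-cleaved SDA fragments and
    >= 5 matched fragments on each peptide."""
    return [m for m in matches
            if m.n_noncleaved_sda_fragments > 2
            and min(m.n_matches_peptide_a, m.n_matches_peptide_b) >= 5]


def aggregate_to_residue_pairs(matches: Iterable[CrosslinkRecord]
                               ) -> list[CrosslinkRecord]:
    """Collapse matches to unique residue pairs, keeping the best score.

    The surviving record inherits the decoy class and provenance of its
    best-scoring member.
    """
    best: dict[tuple, CrosslinkRecord] = {}
    for m in matches:
        rec = m.as_crosslink() if isinstance(m, CandidateMatch) else m
        key = rec.pair_key
        if key not in best or rec.score > best[key].score:
            best[key] = rec
    return sorted(best.values(), key=lambda r: (-r.score, r.pair_key))


def estimate_fdr(items: Sequence, threshold: float, level: str = "residue_pair"
                 ) -> FDRReport:
    """Count TT/TD/DD at ``score >= threshold``; FDR = max(0, TD - DD)/TT."""
    tt = td = dd = 0
    for it in items:
        if it.score >= threshold:
            if it.decoy_class is DecoyClass.TT:
                tt += 1
            elif it.decoy_class is DecoyClass.TD:
                td += 1
            else:
                dd += 1
    fdr = max(0, td - dd) / tt if tt > 0 else None
    return FDRReport(level, threshold, (tt, td, dd), fdr)


def _fdr_curve(items: Sequence):
    """FDR estimate at every unique score threshold, descending.

    Returns ``(thresholds, TT, TD, DD, fdr)`` numpy arrays where entry i
    gives the counts and estimate at ``score >= thresholds[i]``.
    """
    scores = np.array([it.score for it in items], dtype=float)
    badness = np.array([it.decoy_class.badness for it in items])
    order = np.argsort(-scores, kind="stable")
    s, c = scores[order], badness[order]
    tt = np.cumsum(c == 0)
    td = np.cumsum(c == 1)
    dd = np.cumsum(c == 2)
    last = np.r_[s[1:] != s[:-1], True]      # last index of each tie group
    thr, TT, TD, DD = s[last], tt[last], td[last], dd[last]
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(TT > 0, np.maximum(0, TD - DD) / np.maximum(TT, 1),
                       np.nan)
    return thr, TT, TD, DD, fdr


def _passing_indices(items: Sequence, target_fdr: float
                     ) -> tuple[tuple, np.ndarray] | None:
    """Indices of the FDR curve reachable under the stopping rule.

    Scanning from the best score downward, acceptance grows while the
    running estimate stays within the target; the scan stops at the first
    violation outside the burn-in region (TT < 1/target, where a single
    decoy necessarily overshoots and the estimator has no resolution).
    Stopping at the first sustained violation, rather than taking the
    globally lowest passing threshold, avoids selecting thresholds where
    the estimate only dipped below the target by chance — the naive rule
    is measurably anti-conservative.
    """
    if not items:
        return None
    curve = _fdr_curve(items)
    thr, TT, TD, DD, fdr = curve
    passing = np.isfinite(fdr) & (fdr <= target_fdr)
    burn_in = TT < np.ceil(1.0 / target_fdr)
    bad = np.where(np.isfinite(fdr) & (fdr > target_fdr) & ~burn_in)[0]
    stop = int(bad.min()) if bad.size else len(thr)
    valid = np.where((np.arange(len(thr)) < stop) & passing)[0]
    if valid.size == 0:
        # a decoy excess right at the top can abort the scan before any
        # threshold passes; fall back to the plain lowest-passing rule so a
        # couple of unlucky high-scoring decoys cannot empty the result
        valid = np.where(passing)[0]
    if valid.size == 0:
        return None
    return curve, valid


def _report_at(curve, i: int, level: str) -> FDRReport:
    thr, TT, TD, DD, fdr = curve
    return FDRReport(level, float(thr[i]),
                     (int(TT[i]), int(TD[i]), int(DD[i])), float(fdr[i]))


def _lowest_passing_threshold(items: Sequence, target_fdr: float, level: str
                              ) -> FDRReport | None:
    """Most permissive threshold reachable under the stopping rule."""
    res = _passing_indices(items, target_fdr)
    if res is None:
        return None
    curve, valid = res
    return _report_at(curve, int(valid.max()), level)


def build_ppi_edges(residue_pairs: Iterable[CrosslinkRecord]) -> list[PPIEdge]:
    """Aggregate inter-protein residue pairs into protein-pair edges.

    Self-links (both endpoints on one protein) are excluded.  The edge score
    is the sum of member scores; the edge decoy class is the worst class
    among members.
    """
    groups: dict[tuple[str, str], list[CrosslinkRecord]] = {}
    for rp in residue_pairs:
        if not rp.is_inter_protein:
            continue
        groups.setdefault(rp.protein_pair, []).append(rp)
    edges = []
    for (pa, pb), members in sorted(groups.items()):
        members = sorted(members, key=lambda r: (-r.score, r.pair_key))
        worst = max((m.decoy_class for m in members), key=lambda c: c.badness)
        edges.append(PPIEdge(
            protein_a=pa, protein_b=pb, residue_pairs=members,
            aggregate_score=sum(m.score for m in members),
            decoy_class=worst,
            datasets=frozenset(d for m in members
                               for d in m.dataset_id.split(";") if d)))
    return edges


def _empty_report(level: str) -> FDRReport:
    return FDRReport(level, math.inf, (0, 0, 0), None)


def _apply_thresholds(residue_pairs: Sequence[CrosslinkRecord],
                      rp_threshold: float, ppi_fdr: float
                      ) -> tuple[list[CrosslinkRecord], list[PPIEdge],
                                 FDRReport | None]:
    surv = [rp for rp in residue_pairs if rp.score >= rp_threshold]
    edges = build_ppi_edges(surv)
    ppi_rep = _lowest_passing_threshold(edges, ppi_fdr, "ppi")
    return surv, edges, ppi_rep


def hierarchical_filter(matches: Iterable[CandidateMatch | CrosslinkRecord],
                        rp_fdr: float = 0.02, ppi_fdr: float = 0.05,
                        boost: bool = False, prefiltered: bool = True
                        ) -> HierarchicalResult:
    """Two-level target-decoy filter at residue-pair then PPI FDR.

    Without boosting, the residue-pair threshold is the lowest score cutoff
    whose estimated FDR is <= ``rp_fdr``; survivors are aggregated to PPI
    edges and thresholded to ``ppi_fdr``.  With ``boost``, the residue-pair
    cutoff is grid-searched over the observed scores to maximize the number
    of accepted target PPIs while keeping both estimates within their
    limits.
    """
    pool = list(matches) if prefiltered else prefilter_candidates(list(matches))
    residue_pairs = aggregate_to_residue_pairs(pool)
    if not residue_pairs:
        return HierarchicalResult([], [], _empty_report("residue_pair"),
                                  _empty_report("ppi"))

    base = _lowest_passing_threshold(residue_pairs, rp_fdr, "residue_pair")
    candidates: list[FDRReport] = []
    if base is not None:
        candidates.append(base)
    if boost:
        floor = base.threshold_score if base is not None else -math.inf
        res = _passing_indices(residue_pairs, rp_fdr)
        if res is not None:
            curve, valid = res
            for i in valid:
                if curve[0][i] > floor:
                    candidates.append(_report_at(curve, int(i), "residue_pair"))

    best: tuple[int, HierarchicalResult] | None = None
    for rp_rep in candidates:
        surv, edges, ppi_rep = _apply_thresholds(
            residue_pairs, rp_rep.threshold_score, ppi_fdr)
        if ppi_rep is None:
            continue
        accepted_edges = [e for e in edges
                          if e.aggregate_score >= ppi_rep.threshold_score]
        n_targets = sum(e.decoy_class is DecoyClass.TT for e in accepted_edges)
        final_edges = [e for e in accepted_edges
                       if e.decoy_class is DecoyClass.TT]
        kept_pairs = {id(rp) for e in final_edges for rp in e.residue_pairs}
        final_rps = [rp for rp in surv
                     if rp.decoy_class is DecoyClass.TT
                     and (not rp.is_inter_protein or id(rp) in kept_pairs)]
        result = HierarchicalResult(final_rps, final_edges, rp_rep, ppi_rep)
        if best is None or n_targets > best[0]:
            best = (n_targets, result)

    if best is None:
        logger.warning("no threshold satisfies the FDR constraints; "
                       "returning an empty accepted set")
        rp_rep = base or _empty_report("residue_pair")
        return HierarchicalResult([], [], rp_rep, _empty_report("ppi"))
    return best[1]


def merge_datasets(sets: Sequence[Sequence[CrosslinkRecord]]
                   ) -> tuple[list[CrosslinkRecord], FDRReport]:
    """Union residue-pair sets across datasets with redundancy collapse.

    Identical canonical residue pairs are merged keeping the best score;
    dataset provenance is unioned (``;``-joined in ``dataset_id``).  The
    combined PPI-level FDR is re-estimated from the pooled TT/TD/DD edge
    counts of the merged set, not averaged across datasets.
    """
    merged: dict[tuple, CrosslinkRecord] = {}
    for records in sets:
        for rec in records:
            key = rec.pair_key
            prev = merged.get(key)
            if prev is None:
                merged[key] = rec
            else:
                datasets = set(prev.dataset_id.split(";")) | \
                    set(rec.dataset_id.split(";"))
                datasets.discard("")
                keep = rec if rec.score > prev.score else prev
                merged[key] = replace(keep,
                                      dataset_id=";".join(sorted(datasets)))
    out = sorted(merged.values(), key=lambda r: r.pair_key)
    edges = build_ppi_edges(out)
    report = estimate_fdr(edges, -math.inf, "ppi")
    return out, report


def enrichment_filter_ppis(edges: Iterable[PPIEdge], enriched: set[str],
                           core: set[str]) -> list[PPIEdge]:
    """Keep edges whose non-core partners were all AP-MS-enriched.

    Core-core edges are always kept.  An edge with at least one non-core
    partner survives only if every non-core partner is in the enriched set.
    """
    if not enriched:
        warnings.warn("empty enriched set: only core-core edges survive")
    kept = []
    for e in edges:
        non_core = [p for p in (e.protein_a, e.protein_b) if p not in core]
        if all(p in enriched for p in non_core):
            kept.append(e)
    return kept
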