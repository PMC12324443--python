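"""Mapping crosslink distance restraints onto structures and ensembles.

Crosslink endpoints are 1-based positions in the canonical full-length
sequence; deposited structures use arbitrary author numbering and may carry
several copies of the same protein.  Each accession is reconciled with each
candidate chain by global pairwise alignment, a crosslink is measured as
the minimum Cα–Cα Euclidean distance over all chain-copy combinations, and
a restraint is satisfied when that minimum does not exceed the crosslinker
cutoff (27 Å for SDA, inclusive).  Over an ensemble, a crosslink counts as
satisfied when it is satisfied on at least one member — the natural reading
for a snapshot of interconverting conformers.
"""

from __future__ import annotations

import logging
from collections import namedtuple
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from Bio import Align

from .config import PipelineConfig
from .datamodel import Chain, CrosslinkRecord, ProteinRecord, StructureModel

logger = logging.getLogger(__name__)

CopyDistance = namedtuple(
    "CopyDistance", ["chain_a", "resnum_a", "chain_b", "resnum_b", "distance"])

SATISFIED = "satisfied"
VIOLATED = "violated"
UNMAPPED = "unmapped"


@dataclass
class ChainMap:
    """Alignment-derived map from canonical sequence positions to one chain."""

    accession: str
    chain_id: str
    offset_map: dict[int, int]    # 1-based sequence position -> author resnum
    identity: float


@dataclass
class DistanceMeasurement:
    """Per-structure distances of one crosslink over all chain-copy pairs."""

    crosslink: CrosslinkRecord
    structure_id: str
    per_copy: list[CopyDistance]
    min_distance: float            # inf when unmapped
    status: str                    # satisfied | violated | unmapped


@dataclass
class EnsembleReport:
    """Ensemble-level satisfaction summary.

    ``summary`` is the fraction of crosslinks satisfied on at least one
    structure, among crosslinks mappable on at least one structure; it is
    None when nothing maps.
    """

    measurements: dict[tuple, dict[str, DistanceMeasurement]]
    satisfied_any: dict[tuple, bool]
    best_structure: dict[tuple, str | None]
    per_structure_satisfied: dict[str, int]
    summary: float | None


@dataclass
class ViolationCluster:
    """A co-located group of violated crosslinks between one protein pair."""

    protein_pair: tuple[str, str]
    members: list[DistanceMeasurement]
    span_a: tuple[int, int]
    span_b: tuple[int, int]

    @property
    def size(self) -> int:
        return len(self.members)


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -0.5
    # free end gaps: chains are usually fragments of the canonical sequence
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # Biopython < 1.86 naming
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def build_chain_maps(proteins: Iterable[ProteinRecord],
                     structure: StructureModel,
                     min_identity: float = 0.95) -> list[ChainMap]:
    """Align canonical sequences to structure chains.

    Every chain assigned to an accession (via ``chain_to_protein``) is
    globally aligned against that accession's canonical sequence; the map
    records, for each aligned column, canonical position -> author residue
    number.  Maps whose identity over aligned (non-gap) columns falls below
    ``min_identity`` are discarded with a warning.
    """
    seqs = {p.accession: p.sequence for p in proteins}
    aligner = _aligner()
    maps: list[ChainMap] = []
    for chain in structure.chains:
        acc = structure.chain_to_protein.get(chain.chain_id)
        if acc is None:
            continue
        seq = seqs.get(acc)
        if seq is None:
            logger.warning("no sequence for %s; chain %s skipped",
                           acc, chain.chain_id)
            continue
        aln = aligner.align(seq, chain.sequence)[0]
        offset_map: dict[int, int] = {}
        identical = 0
        for (t0, t1), (q0, q1) in zip(*aln.aligned):
            for k in range(t1 - t0):
                pos = t0 + k            # 0-based canonical position
                qi = q0 + k             # 0-based chain residue index
                if seq[pos] == chain.sequence[qi]:
                    identical += 1
                offset_map[pos + 1] = int(chain.resnums[qi])
        # identity over the full chain length: with free end gaps a short
        # perfect overlap must not masquerade as a high-identity match
        identity = identical / len(chain.sequence) if chain.sequence else 0.0
        if identity < min_identity:
            logger.warning("chain %s vs %s: identity %.3f < %.2f; map discarded",
                           chain.chain_id, acc, identity, min_identity)
            continue
        maps.append(ChainMap(acc, chain.chain_id, offset_map, identity))
    return maps


def assign_chains(proteins: Iterable[ProteinRecord],
                  structure: StructureModel,
                  min_identity: float = 0.95) -> StructureModel:
    """Fill in ``chain_to_protein`` by best-identity sequence alignment.

    Chains already assigned are kept; each unassigned chain is aligned
    against every candidate sequence and mapped to the best hit when its
    identity reaches ``min_identity``, otherwise left unassigned.
    """
    proteins = list(proteins)
    aligner = _aligner()
    for chain in structure.chains:
        if chain.chain_id in structure.chain_to_protein:
            continue
        best: tuple[float, str] | None = None
        for p in proteins:
            aln = aligner.align(p.sequence, chain.sequence)[0]
            identical = 0
            for (t0, t1), (q0, q1) in zip(*aln.aligned):
                for k in range(t1 - t0):
                    identical += p.sequence[t0 + k] == chain.sequence[q0 + k]
            identity = identical / len(chain.sequence) if chain.sequence else 0.0
            if best is None or identity > best[0]:
                best = (identity, p.accession)
        if best is not None and best[0] >= min_identity:
            structure.chain_to_protein[chain.chain_id] = best[1]
        else:
            logger.warning("chain %s: no sequence reaches identity %.2f",
                           chain.chain_id, min_identity)
    return structure


def _maps_by_accession(maps: Iterable[ChainMap]) -> dict[str, list[ChainMap]]:
    out: dict[str, list[ChainMap]] = {}
    for m in maps:
        out.setdefault(m.accession, []).append(m)
    return out


def measure_crosslink(crosslink: CrosslinkRecord, structure: StructureModel,
                      maps: Sequence[ChainMap] | Mapping[str, list[ChainMap]]
                      ) -> DistanceMeasurement:
    """Minimum Cα–Cα distance over all chain-copy combinations.

    Self-links on a protein with several copies are evaluated over both
    intra-copy and inter-copy placements.  The measurement is ``unmapped``
    when no combination resolves both residues.
    """
    by_acc = maps if isinstance(maps, Mapping) else _maps_by_accession(maps)
    chains = {c.chain_id: c for c in structure.chains}
    per_copy: list[CopyDistance] = []
    maps_a = by_acc.get(crosslink.protein_a, [])
    maps_b = by_acc.get(crosslink.protein_b, [])
    for ma in maps_a:
        ra = ma.offset_map.get(crosslink.residue_a)
        if ra is None:
            continue
        ca = chains[ma.chain_id].coord_of(ra)
        if ca is None:
            continue
        for mb in maps_b:
            rb = mb.offset_map.get(crosslink.residue_b)
            if rb is None:
                continue
            cb = chains[mb.chain_id].coord_of(rb)
            if cb is None:
                continue
            if ma.chain_id == mb.chain_id and ra == rb:
                continue  # degenerate: the same atom
            # ordered copy assignments of a self-link are distinct placements
            per_copy.append(CopyDistance(
                ma.chain_id, ra, mb.chain_id, rb,
                float(np.linalg.norm(ca - cb))))
    if not per_copy:
        return DistanceMeasurement(crosslink, structure.model_id, [],
                                   float("inf"), UNMAPPED)
    dmin = min(c.distance for c in per_copy)
    return DistanceMeasurement(crosslink, structure.model_id, per_copy,
                               dmin, VIOLATED)  # status set by classify


def classify(measurement: DistanceMeasurement, threshold: float = 27.0
             ) -> str:
    """Binary satisfaction: satisfied iff min distance <= threshold."""
    if measurement.status == UNMAPPED:
        return UNMAPPED
    status = SATISFIED if measurement.min_distance <= threshold else VIOLATED
    measurement.status = status
    return status


def classify_band(measurement: DistanceMeasurement,
                  bands: tuple[float, float] = (21.5, 28.5)) -> int | None:
    """Three-way distance band: 0 below the lower edge, 1 inside the band
    (lower-inclusive), 2 above the upper edge.  None when unmapped."""
    if measurement.status == UNMAPPED:
        return None
    lo, hi = bands
    d = measurement.min_distance
    return 0 if d < lo else (1 if d < hi else 2)


def measure_and_classify(crosslinks: Iterable[CrosslinkRecord],
                         structure: StructureModel,
                         maps: Sequence[ChainMap],
                         threshold: float = 27.0) -> list[DistanceMeasurement]:
    by_acc = _maps_by_accession(maps)
    out = []
    for xl in crosslinks:
        m = measure_crosslink(xl, structure, by_acc)
        classify(m, threshold)
        out.append(m)
    return out


def ensemble_satisfaction(crosslinks: Sequence[CrosslinkRecord],
                          structures: Sequence[StructureModel],
                          proteins: Iterable[ProteinRecord],
                          config: PipelineConfig | None = None
                          ) -> EnsembleReport:
    """Evaluate crosslinks against every ensemble member.

    A crosslink is ensemble-satisfied when its minimum distance on at least
    one structure does not exceed the cutoff.  ``summary`` is the fraction
    of ensemble-satisfied crosslinks among those mappable somewhere.
    """
    cfg = config or PipelineConfig()
    if not structures:
        raise ValueError("at least one structure is required")
    proteins = list(proteins)
    threshold = cfg.sda_max_ca_distance
    measurements: dict[tuple, dict[str, DistanceMeasurement]] = {}
    per_structure_satisfied = {s.model_id: 0 for s in structures}
    for struct in structures:
        maps = build_chain_maps(proteins, struct, cfg.min_chain_identity)
        for m in measure_and_classify(crosslinks, struct, maps, threshold):
            measurements.setdefault(m.crosslink.pair_key, {})[struct.model_id] = m
            if m.status == SATISFIED:
                per_structure_satisfied[struct.model_id] += 1
    satisfied_any: dict[tuple, bool] = {}
    best_structure: dict[tuple, str | None] = {}
    n_mappable = n_satisfied = 0
    for key, per_struct in measurements.items():
        mapped = [m for m in per_struct.values() if m.status != UNMAPPED]
        sat = any(m.status == SATISFIED for m in mapped)
        satisfied_any[key] = sat
        best_structure[key] = (min(mapped, key=lambda m: m.min_distance)
                               .structure_id if mapped else None)
        if mapped:
            n_mappable += 1
            n_satisfied += int(sat)
    summary = n_satisfied / n_mappable if n_mappable else None
    if summary is None:
        logger.warning("no crosslink mappable on any ensemble member")
    return EnsembleReport(measurements, satisfied_any, best_structure,
                          per_structure_satisfied, summary)


def detect_violation_clusters(measurements: Sequence[DistanceMeasurement],
                              window: int = 10, min_size: int = 3
                              ) -> list[ViolationCluster]:
    """Find co-located violated crosslinks suggesting alternative conformers.

    Violated crosslinks sharing the same unordered protein pair are linked
    when both endpoint positions differ by at most ``window`` residues on
    their respective proteins; connected components of size >= ``min_size``
    are returned largest first.
    """
    violated = [m for m in measurements if m.status == VIOLATED]
    g = nx.Graph()
    g.add_nodes_from(range(len(violated)))
    for i in range(len(violated)):
        xi = violated[i].crosslink
        for j in range(i + 1, len(violated)):
            xj = violated[j].crosslink
            if xi.protein_pair != xj.protein_pair:
                continue
            if abs(xi.residue_a - xj.residue_a) <= window and \
               abs(xi.residue_b - xj.residue_b) <= window:
                g.add_edge(i, j)
    clusters = []
    for comp in nx.connected_components(g):
        if len(comp) < min_size:
            continue
        members = [violated[i] for i in sorted(comp)]
        ra = [m.crosslink.residue_a for m in members]
        rb = [m.crosslink.residue_b for m in members]
        clusters.append(ViolationCluster(
            protein_pair=members[0].crosslink.protein_pair,
            members=members,
            span_a=(min(ra), max(ra)), span_b=(min(rb), max(rb))))
    clusters.sort(key=lambda c: (-c.size, c.protein_pair))
    return clusters
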