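"""Confidence scoring and crosslink validation of predicted complexes.

Predicted multimer models carry an interface score (ipTM) and a global
score (pTM); the combined model confidence is ``0.8 * ipTM + 0.2 * pTM``.
A prediction is high-confidence when its confidence averaged over all
supplied models is strictly above the cutoff (0.65 by default).  Crosslink
validation maps observed restraints onto a model's coordinates and reports
satisfied / mappable counts; restraints with an unresolved endpoint are
excluded from the denominator and reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .config import PipelineConfig
from .datamodel import CrosslinkRecord, ModelScoreSet, ProteinRecord, StructureModel
from .restraints import (SATISFIED, UNMAPPED, build_chain_maps,
                         measure_and_classify)


@dataclass
class ModelConfidence:
    """Aggregated confidence and crosslink support for one predicted pair."""

    pair_id: tuple[str, ...]
    per_model_confidence: list[float]
    mean_confidence: float
    mean_iptm: float
    high_confidence: bool
    xl_satisfied: int = 0
    xl_mappable: int = 0

    @property
    def xl_fraction(self) -> float | None:
        if self.xl_mappable == 0:
            return None
        return self.xl_satisfied / self.xl_mappable


def model_confidence(iptm: float, ptm: float,
                     weights: tuple[float, float] = (0.8, 0.2)) -> float:
    """Combined model confidence: weighted sum of ipTM and pTM."""
    if not (0.0 <= iptm <= 1.0 and 0.0 <= ptm <= 1.0):
        raise ValueError(f"scores must lie in [0, 1]; got ipTM={iptm}, pTM={ptm}")
    return weights[0] * iptm + weights[1] * ptm


def score_prediction(scores: ModelScoreSet, cutoff: float = 0.65,
                     weights: tuple[float, float] = (0.8, 0.2)
                     ) -> ModelConfidence:
    """Per-model and mean confidence; high-confidence iff mean > cutoff."""
    per_model = [model_confidence(i, p, weights) for i, p in scores.per_model]
    mean_conf = sum(per_model) / len(per_model)
    mean_iptm = sum(i for i, _ in scores.per_model) / len(scores.per_model)
    return ModelConfidence(
        pair_id=scores.pair_id,
        per_model_confidence=per_model,
        mean_confidence=mean_conf,
        mean_iptm=mean_iptm,
        high_confidence=mean_conf > cutoff,
    )


def validate_prediction_with_xls(model: StructureModel,
                                 crosslinks: Sequence[CrosslinkRecord],
                                 proteins: Iterable[ProteinRecord],
                                 config: PipelineConfig | None = None
                                 ) -> tuple[int, int, float | None]:
    """Count crosslinks satisfied on a single predicted model.

    Returns ``(satisfied, mappable, fraction)``; crosslinks with an
    endpoint missing from the model (e.g. in a trimmed disordered region)
    are unmappable and excluded from the denominator.  ``fraction`` is None
    when nothing maps.
    """
    cfg = config or PipelineConfig()
    maps = build_chain_maps(list(proteins), model, cfg.min_chain_identity)
    measurements = measure_and_classify(crosslinks, model, maps,
                                        cfg.sda_max_ca_distance)
    mappable = [m for m in measurements if m.status != UNMAPPED]
    satisfied = sum(m.status == SATISFIED for m in mappable)
    n = len(mappable)
    return satisfied, n, (satisfied / n if n else None)


def score_and_validate(scores: ModelScoreSet,
                       crosslinks: Sequence[CrosslinkRecord],
                       proteins: Iterable[ProteinRecord],
                       config: PipelineConfig | None = None) -> ModelConfidence:
    """Confidence-score a prediction and tally crosslink support.

    Crosslink satisfaction is evaluated on the best-confidence model that
    carries coordinates.
    """
    cfg = config or PipelineConfig()
    conf = score_prediction(scores, cfg.confidence_cutoff, cfg.confidence_weights)
    if scores.coordinates:
        proteins = list(proteins)
        candidates = [(c, m) for c, m in
                      zip(conf.per_model_confidence, scores.coordinates)
                      if m is not None]
        if candidates:
            _, best_model = max(candidates, key=lambda t: t[0])
            sat, mappable, _ = validate_prediction_with_xls(
                best_model, crosslinks, proteins, cfg)
            conf.xl_satisfied, conf.xl_mappable = sat, mappable
    return conf


def rank_interfaces(confidences: Sequence[ModelConfidence]
                    ) -> list[ModelConfidence]:
    """Sort by (high_confidence, mean confidence, crosslink fraction) desc,
    breaking full ties lexicographically by pair id."""
    def key(c: ModelConfidence):
        frac = c.xl_fraction if c.xl_fraction is not None else -1.0
        return (not c.high_confidence, -c.mean_confidence, -frac, c.pair_id)
    return sorted(confidences, key=key)
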