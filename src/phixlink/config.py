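"""Pipeline configuration.

All scalar thresholds used across the toolkit live in a single
:class:`PipelineConfig` value so that a run is fully described by one YAML
file plus a seed.  Defaults follow the SDA photo-crosslinking workflow:
a 27 Å Cα–Cα satisfaction cutoff, 2 % residue-pair / 5 % PPI target-decoy
FDR, QProMS-style mixed imputation (down-shift 1.8 SD, width 0.3 SD),
|log2FC| >= 2 with BH-adjusted p < 0.05 for enrichment calls, and the
0.8·ipTM + 0.2·pTM model-confidence score with a strict 0.65 cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import yaml

# SDA chemistry: the NHS-ester end acylates primary amines and hydroxyls
# (K, S, T, Y and the protein N-terminus); the UV-activated diazirine end
# inserts broadly but with measurable preference for these residues and
# the chain termini.
NHS_RESIDUES = frozenset("KSTY")
DIAZIRINE_RESIDUES = frozenset("ACDEGHIKLPSTVY")


class ConfigError(ValueError):
    """Raised when a configuration value is outside its stated domain."""


@dataclass
class PipelineConfig:
    """Scalar parameters shared by all pipeline stages.

    Attributes
    ----------
    sda_max_ca_distance:
        Maximum Cα–Cα distance (Å) for a crosslink to count as satisfied.
    band_edges:
        Distance band edges (Å) for three-way coloring of mapped links.
    residue_pair_fdr, ppi_fdr:
        Target-decoy FDR thresholds at the residue-pair and PPI level.
    completeness_min:
        Minimum fraction of replicates with an observed intensity, in at
        least one group, for a protein to be retained.
    imputation_downshift, imputation_width:
        Down-shifted-Gaussian imputation parameters, in multiples of the
        per-sample SD of observed values.
    lfc_min, alpha:
        Enrichment call thresholds (log2 fold change; BH-adjusted p).
    confidence_weights, confidence_cutoff:
        ipTM/pTM weights and the strict mean-confidence cutoff.
    decoy_prefix:
        Accession prefix marking reversed-sequence decoys.
    core_subunits:
        Canonical complex subunits exempted from AP-MS-based PPI filtering.
    """

    sda_max_ca_distance: float = 27.0
    band_edges: tuple[float, float] = (21.5, 28.5)
    residue_pair_fdr: float = 0.02
    ppi_fdr: float = 0.05
    completeness_min: float = 0.8
    imputation_downshift: float = 1.8
    imputation_width: float = 0.3
    lfc_min: float = 2.0
    alpha: float = 0.05
    confidence_weights: tuple[float, float] = (0.8, 0.2)
    confidence_cutoff: float = 0.65
    nhs_residues: frozenset[str] = NHS_RESIDUES
    diazirine_residues: frozenset[str] = DIAZIRINE_RESIDUES
    decoy_prefix: str = "REV_"
    core_subunits: tuple[str, ...] = ()
    min_chain_identity: float = 0.95
    cluster_window: int = 10
    cluster_min_size: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.band_edges = tuple(self.band_edges)  # type: ignore[assignment]
        self.confidence_weights = tuple(self.confidence_weights)  # type: ignore[assignment]
        self.nhs_residues = frozenset(self.nhs_residues)
        self.diazirine_residues = frozenset(self.diazirine_residues)
        self.core_subunits = tuple(self.core_subunits)
        for name in ("residue_pair_fdr", "ppi_fdr", "completeness_min", "alpha",
                     "confidence_cutoff"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]; got {v!r}")
        if self.sda_max_ca_distance <= 0:
            raise ConfigError("sda_max_ca_distance must be positive")
        if not self.band_edges[0] < self.band_edges[1]:
            raise ConfigError("band_edges must be strictly increasing")
        if self.imputation_downshift < 0 or self.imputation_width < 0:
            raise ConfigError("imputation parameters must be non-negative")
        if not self.decoy_prefix:
            raise ConfigError("decoy_prefix must be non-empty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(
                "unknown configuration keys: " + ", ".join(sorted(unknown)))
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["nhs_residues"] = sorted(self.nhs_residues)
        data["diazirine_residues"] = sorted(self.diazirine_residues)
        data["band_edges"] = list(self.band_edges)
        data["confidence_weights"] = list(self.confidence_weights)
        data["core_subunits"] = list(self.core_subunits)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def is_nhs_eligible(residue: str, position: int, config: PipelineConfig,
                    length: int | None = None) -> bool:
    """True if the residue can carry the amine-reactive (NHS-ester) end."""
    return residue in config.nhs_residues or position == 1


def is_diazirine_eligible(residue: str, position: int, config: PipelineConfig,
                          length: int | None = None) -> bool:
    """True if the residue can carry the photo-activated (diazirine) end."""
    if residue in config.diazirine_residues or position == 1:
        return True
    return length is not None and position == length
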