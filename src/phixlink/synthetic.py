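"""Seeded generators of desk-scale inputs with known ground truth.

Every stage of the pipeline can be exercised against data whose truth is
known by construction: toy multi-chain complexes built from self-avoiding
Cα walks, crosslinks sampled under the SDA chemistry and a distance cutoff
with planted false positives and decoys, candidate score sets for FDR
calibration, and log-normal quantification matrices with planted fold
changes and MAR/MNAR missingness.  All generators are bit-reproducible for
a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .config import PipelineConfig, is_diazirine_eligible, is_nhs_eligible
from .datamodel import (CandidateMatch, Chain, CrosslinkRecord, DecoyClass,
                        ProteinRecord, QuantMatrix, StructureModel)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: score model: identifications produce a right-skewed null (false matches,
#: decoys) and a shifted, roughly Gaussian signal (true matches)
SIGNAL_MEAN, SIGNAL_SD = 8.0, 1.5
NULL_LOC, NULL_SCALE = 3.0, 1.0

CA_STEP = 3.8           # consecutive Cα spacing, Å
MIN_SEPARATION = 3.4    # self-avoidance radius for non-consecutive residues
INTERFACE_MAX = 10.0    # chains are placed with min inter-chain distance <= this


class GeneratorError(RuntimeError):
    """Requested synthetic data cannot be produced from the given geometry."""


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated dataset."""

    true_links: set = field(default_factory=set)
    false_links: set = field(default_factory=set)
    true_ppis: set = field(default_factory=set)
    planted_enriched: set = field(default_factory=set)
    generating_threshold: float | None = None
    seed: int = 0


def _unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _self_avoiding_walk(n: int, rng: np.random.Generator,
                        max_tries: int = 500) -> np.ndarray:
    pts = np.zeros((n, 3))
    k = 1
    while k < n:
        placed = False
        for _ in range(max_tries):
            cand = pts[k - 1] + CA_STEP * _unit(rng)
            if k < 2 or np.min(np.linalg.norm(pts[:k - 1] - cand, axis=1)) \
                    >= MIN_SEPARATION:
                pts[k] = cand
                placed = True
                break
        if not placed:      # rare dead end: back up and try again
            k = max(1, k - 5)
            continue
        k += 1
    return pts


def _place_chain(existing: np.ndarray, coords: np.ndarray,
                 direction: np.ndarray) -> np.ndarray:
    """Translate ``coords`` along ``direction`` until it touches ``existing``
    (minimum inter-chain distance in (MIN_SEPARATION, INTERFACE_MAX])."""
    coords = coords - coords.mean(axis=0)
    anchor = existing.mean(axis=0)
    span = (np.linalg.norm(existing - anchor, axis=1).max()
            + np.linalg.norm(coords, axis=1).max())
    d = span + INTERFACE_MAX + 5.0
    step = 0.25
    while d > 0:
        trial = coords + anchor + d * direction
        dmin = cdist(existing, trial).min()
        if dmin <= INTERFACE_MAX:
            if dmin <= MIN_SEPARATION:
                raise GeneratorError("chain placement produced a clash")
            return trial
        d -= step
    raise GeneratorError("could not place chain at an interface")


def generate_toy_complex(n_chains: int, n_res_per_chain: int, seed: int,
                         ) -> tuple[StructureModel, list[ProteinRecord]]:
    """Build a seed-reproducible multi-chain Cα complex plus its sequences.

    Each chain is a 3D self-avoiding random walk with exact 3.8 Å steps;
    chains after the first are translated toward the growing complex until
    they share an interface (minimum inter-chain Cα distance <= 10 Å).
    Chain ``i`` is assigned to protein ``SYNP{i+1:02d}`` with author
    numbering 1..n, so sequence positions and residue numbers coincide.
    """
    if n_chains < 1 or n_res_per_chain < 5:
        raise GeneratorError("need n_chains >= 1 and n_res_per_chain >= 5")
    rng = np.random.default_rng(seed)
    chains: list[Chain] = []
    proteins: list[ProteinRecord] = []
    chain_to_protein: dict[str, str] = {}
    placed: np.ndarray | None = None
    for i in range(n_chains):
        coords = _self_avoiding_walk(n_res_per_chain, rng)
        if placed is not None:
            coords = _place_chain(placed, coords, _unit(rng))
        placed = coords if placed is None else np.vstack([placed, coords])
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=n_res_per_chain))
        cid = chr(ord("A") + i)
        acc = f"SYNP{i + 1:02d}"
        chains.append(Chain(cid, np.arange(1, n_res_per_chain + 1), seq, coords))
        proteins.append(ProteinRecord(acc, seq))
        chain_to_protein[cid] = acc
    model = StructureModel(f"toy_{seed}", chains, chain_to_protein)
    return model, proteins


def displace_chain(structure: StructureModel, chain_id: str, seed: int,
                   model_id: str | None = None) -> StructureModel:
    """An alternative conformer: one chain rotated and re-docked on the
    opposite face of the rest of the complex.

    All chain identities, sequences and residue numbering are preserved, so
    the result is a second state of the same assembly.
    """
    rng = np.random.default_rng(seed)
    others = [c for c in structure.chains if c.chain_id != chain_id]
    if not others:
        raise GeneratorError("cannot displace the only chain")
    moving = structure.chain(chain_id)
    rest = np.vstack([c.coords for c in others])
    old_dir = moving.coords.mean(axis=0) - rest.mean(axis=0)
    old_dir /= np.linalg.norm(old_dir)
    rot = Rotation.random(rng=rng).as_matrix()
    turned = (moving.coords - moving.coords.mean(axis=0)) @ rot.T
    new_coords = _place_chain(rest, turned, -old_dir)
    chains = [Chain(c.chain_id, c.resnums.copy(), c.sequence, c.coords.copy())
              if c.chain_id != chain_id else
              Chain(c.chain_id, c.resnums.copy(), c.sequence, new_coords)
              for c in structure.chains]
    return StructureModel(model_id or structure.model_id + "_alt", chains,
                          dict(structure.chain_to_protein))


# ---------------------------------------------------------------------------
# crosslink simulation

def _residue_table(structure: StructureModel, proteins: list[ProteinRecord],
                   config: PipelineConfig):
    """Flat arrays of (accession, position, coordinate, eligibilities)."""
    lengths = {p.accession: len(p) for p in proteins}
    acc, pos, nhs, dia, coords = [], [], [], [], []
    for chain in structure.chains:
        a = structure.chain_to_protein[chain.chain_id]
        n = lengths[a]
        for num, letter, xyz in zip(chain.resnums, chain.sequence, chain.coords):
            acc.append(a)
            pos.append(int(num))
            nhs.append(is_nhs_eligible(letter, int(num), config, n))
            dia.append(is_diazirine_eligible(letter, int(num), config, n))
            coords.append(xyz)
    return (np.array(acc), np.array(pos), np.array(nhs), np.array(dia),
            np.array(coords))


def _eligible_pairs(structure: StructureModel, proteins: list[ProteinRecord],
                    config: PipelineConfig, inter_protein_only: bool):
    """All chemistry-eligible residue pairs with their minimum Cα distance.

    Distances are minimized over chain copies so that truth labels match
    what the restraint mapper will measure.
    """
    acc, pos, nhs, dia, coords = _residue_table(structure, proteins, config)
    n = len(acc)
    dist = cdist(coords, coords)
    pairs: dict[tuple, float] = {}
    iu, ju = np.triu_indices(n, k=1)
    ok = (nhs[iu] & dia[ju]) | (nhs[ju] & dia[iu])
    if inter_protein_only:
        ok &= acc[iu] != acc[ju]
    else:
        ok &= ~((acc[iu] == acc[ju]) & (pos[iu] == pos[ju]))
    for i, j in zip(iu[ok], ju[ok]):
        key = CrosslinkRecord(acc[i], int(pos[i]), acc[j], int(pos[j])).pair_key
        d = dist[i, j]
        if key not in pairs or d < pairs[key]:
            pairs[key] = d
    return pairs


def _sample_keys(rng: np.random.Generator, pool: list, k: int, what: str) -> list:
    if len(pool) < k:
        raise GeneratorError(
            f"only {len(pool)} eligible {what} pairs available, {k} requested")
    idx = rng.choice(len(pool), size=k, replace=False)
    return [pool[i] for i in sorted(idx)]


def simulate_crosslinks(structure: StructureModel,
                        proteins: list[ProteinRecord],
                        n_true: int, n_false: int,
                        config: PipelineConfig | None = None,
                        threshold: float | None = None, seed: int = 0,
                        inter_protein_only: bool = False,
                        n_decoys: int = 0, dataset_id: str = "sim",
                        ) -> tuple[list[CrosslinkRecord], SyntheticTruth]:
    """Sample true and false crosslinks on a structure under SDA chemistry.

    True links are drawn uniformly from chemistry-eligible residue pairs
    with Cα–Cα distance <= ``threshold``; false links from eligible pairs
    strictly beyond ``threshold + 5`` Å (a guard band that keeps truth
    labels unambiguous).  Scores follow the documented signal/null model.
    ``n_decoys`` additional decoy records (TD:DD at 2:1) are produced by
    relabeling random eligible pairs to decoy accessions with null scores.
    """
    cfg = config or PipelineConfig()
    thr = cfg.sda_max_ca_distance if threshold is None else threshold
    rng = np.random.default_rng(seed)
    pairs = _eligible_pairs(structure, proteins, cfg, inter_protein_only)
    pool_true = sorted(k for k, d in pairs.items() if d <= thr)
    pool_false = sorted(k for k, d in pairs.items() if d > thr + 5.0)
    true_keys = _sample_keys(rng, pool_true, n_true, "within-threshold")
    false_keys = _sample_keys(rng, pool_false, n_false, "beyond-threshold")
    records = []
    for key in true_keys:
        records.append(CrosslinkRecord(
            *key, score=float(rng.normal(SIGNAL_MEAN, SIGNAL_SD)),
            decoy_class=DecoyClass.TT, dataset_id=dataset_id))
    for key in false_keys:
        records.append(CrosslinkRecord(
            *key, score=float(rng.gumbel(NULL_LOC, NULL_SCALE)),
            decoy_class=DecoyClass.TT, dataset_id=dataset_id))
    all_keys = sorted(pairs)
    for _ in range(n_decoys):
        pa, ra, pb, rb = all_keys[rng.integers(len(all_keys))]
        if rng.random() < 2.0 / 3.0:
            pa, dc = cfg.decoy_prefix + pa, DecoyClass.TD
        else:
            pa, pb, dc = cfg.decoy_prefix + pa, cfg.decoy_prefix + pb, DecoyClass.DD
        records.append(CrosslinkRecord(
            pa, ra, pb, rb, score=float(rng.gumbel(NULL_LOC, NULL_SCALE)),
            decoy_class=dc, dataset_id=dataset_id))
    truth = SyntheticTruth(true_links=set(true_keys),
                           false_links=set(false_keys),
                           generating_threshold=thr, seed=seed)
    return records, truth


def simulate_two_state_crosslinks(conformer_a: StructureModel,
                                  conformer_b: StructureModel,
                                  proteins: list[ProteinRecord],
                                  n_state_a: int, n_b_only: int,
                                  config: PipelineConfig | None = None,
                                  threshold: float | None = None,
                                  seed: int = 0,
                                  ) -> tuple[list[CrosslinkRecord], SyntheticTruth]:
    """Crosslinks from a two-conformer ensemble.

    ``n_state_a`` links are satisfiable on conformer A; ``n_b_only`` links
    are satisfiable on conformer B but violated (strictly beyond the
    cutoff) on A — the signature of a second conformational state.
    """
    cfg = config or PipelineConfig()
    thr = cfg.sda_max_ca_distance if threshold is None else threshold
    rng = np.random.default_rng(seed)
    pairs_a = _eligible_pairs(conformer_a, proteins, cfg, inter_protein_only=True)
    pairs_b = _eligible_pairs(conformer_b, proteins, cfg, inter_protein_only=True)
    pool_a = sorted(k for k, d in pairs_a.items() if d <= thr)
    pool_b_only = sorted(k for k, d in pairs_b.items()
                         if d <= thr and pairs_a.get(k, np.inf) > thr)
    keys_a = _sample_keys(rng, pool_a, n_state_a, "state-A")
    keys_b = _sample_keys(rng, pool_b_only, n_b_only, "state-B-exclusive")
    records = [CrosslinkRecord(*k, score=float(rng.normal(SIGNAL_MEAN, SIGNAL_SD)),
                               dataset_id="two_state")
               for k in keys_a + keys_b]
    truth = SyntheticTruth(true_links=set(keys_a) | set(keys_b),
                           generating_threshold=thr, seed=seed)
    return records, truth


# ---------------------------------------------------------------------------
# quantification matrices

def simulate_quant_matrix(n_proteins: int = 2000, n_enriched: int = 100,
                          n_per_group: int = 3, effect_log2: float = 3.0,
                          sd: float = 0.5, missing_mar_rate: float = 0.05,
                          missing_mnar_rate: float = 0.05, seed: int = 0,
                          groups: tuple[str, str] = ("ctrl", "test"),
                          ) -> tuple[QuantMatrix, SyntheticTruth]:
    """Log2 intensity matrix with planted enrichment and mixed missingness.

    Baseline per-protein means are Normal(25, 2); replicate noise is
    Normal(0, sd); planted proteins gain ``effect_log2`` in the test group.
    MAR cells are masked uniformly at random at ``missing_mar_rate``; MNAR
    masking removes the lowest-intensity cells up to ``missing_mnar_rate``
    of the matrix, emulating the detection limit of label-free MS.
    """
    if not (0 <= missing_mar_rate < 1 and 0 <= missing_mnar_rate < 1):
        raise ValueError("missingness rates must lie in [0, 1)")
    if missing_mar_rate + missing_mnar_rate >= 1:
        raise ValueError("missingness rates must sum to < 1")
    if n_per_group < 2:
        raise ValueError("need >= 2 samples per group")
    if n_enriched > n_proteins:
        raise ValueError("n_enriched exceeds n_proteins")
    rng = np.random.default_rng(seed)
    ctrl, test = groups
    accessions = [f"P{i + 1:05d}" for i in range(n_proteins)]
    samples = [f"{ctrl}_{r + 1}" for r in range(n_per_group)] + \
              [f"{test}_{r + 1}" for r in range(n_per_group)]
    group_of = {s: (ctrl if s.startswith(ctrl) else test) for s in samples}
    mu = rng.normal(25.0, 2.0, size=n_proteins)
    vals = mu[:, None] + rng.normal(0.0, sd, size=(n_proteins, 2 * n_per_group))
    planted = rng.choice(n_proteins, size=n_enriched, replace=False)
    vals[planted, n_per_group:] += effect_log2
    if missing_mar_rate > 0:
        mar_mask = rng.random(vals.shape) < missing_mar_rate
        vals[mar_mask] = np.nan
    if missing_mnar_rate > 0:
        flat = vals.ravel()
        obs = np.isfinite(flat)
        # mask the lowest cells so that ~missing_mnar_rate of ALL cells go
        # missing-not-at-random (quantile taken over the full matrix)
        cutoff = np.nanquantile(flat, missing_mnar_rate)
        flat[obs & (flat <= cutoff)] = np.nan
    matrix = QuantMatrix(
        pd.DataFrame(vals, index=accessions, columns=samples),
        group_of, scale="log2")
    truth = SyntheticTruth(
        planted_enriched={accessions[i] for i in planted}, seed=seed)
    return matrix, truth


# ---------------------------------------------------------------------------
# candidate score sets for FDR calibration

def simulate_candidate_scores(n_true_targets: int, n_false_targets: int,
                              n_decoys: int, seed: int = 0,
                              td_dd_ratio: float = 2.0,
                              n_complex_proteins: int = 20,
                              n_background_proteins: int = 200,
                              rp_per_ppi: int = 8,
                              decoy_prefix: str = "REV_",
                              ) -> tuple[list[CandidateMatch], SyntheticTruth]:
    """Candidate matches emulating a target+reversed-decoy crosslink search.

    True targets score from the signal distribution and concentrate on a
    small set of true protein pairs (about ``rp_per_ppi`` residue pairs
    each); false targets and decoys score from the shared null and land on
    random background protein pairs.  Decoys split TD:DD at
    ``td_dd_ratio`` : 1 — with n_false_targets false TT matches and
    ``n_decoys = 3 * n_false_targets`` this reproduces the 1:2:1 TT:TD:DD
    expectation of a reversed-decoy database, under which
    E[TD - DD] equals the number of false target matches.
    """
    rng = np.random.default_rng(seed)
    complex_pool = [f"CPL{i + 1:02d}" for i in range(n_complex_proteins)]
    background = [f"BKG{i + 1:03d}" for i in range(n_background_proteins)]
    n_ppis = max(1, n_true_targets // rp_per_ppi)
    true_ppis = set()
    while len(true_ppis) < n_ppis:
        a, b = rng.choice(n_complex_proteins, size=2, replace=False)
        true_ppis.add(tuple(sorted((complex_pool[a], complex_pool[b]))))
    true_ppis = sorted(true_ppis)

    used_keys: set[tuple] = set()

    def fresh_record(pa: str, pb: str, score: float,
                     dc: DecoyClass) -> CandidateMatch:
        while True:
            ra, rb = int(rng.integers(1, 400)), int(rng.integers(1, 400))
            m = CandidateMatch(
                pa, ra, pb, rb, score=score, decoy_class=dc, dataset_id="cal",
                n_noncleaved_sda_fragments=int(rng.integers(3, 7)),
                n_matches_peptide_a=int(rng.integers(5, 13)),
                n_matches_peptide_b=int(rng.integers(5, 13)))
            if m.pair_key not in used_keys:
                used_keys.add(m.pair_key)
                return m

    def random_background_pair() -> tuple[str, str]:
        a, b = rng.choice(n_background_proteins, size=2, replace=False)
        return background[a], background[b]

    matches: list[CandidateMatch] = []
    truth = SyntheticTruth(seed=seed, true_ppis=set(true_ppis))
    for _ in range(n_true_targets):
        pa, pb = true_ppis[rng.integers(len(true_ppis))]
        m = fresh_record(pa, pb, float(rng.normal(SIGNAL_MEAN, SIGNAL_SD)),
                         DecoyClass.TT)
        matches.append(m)
        truth.true_links.add(m.pair_key)
    for _ in range(n_false_targets):
        pa, pb = random_background_pair()
        m = fresh_record(pa, pb, float(rng.gumbel(NULL_LOC, NULL_SCALE)),
                         DecoyClass.TT)
        matches.append(m)
        truth.false_links.add(m.pair_key)
    p_td = td_dd_ratio / (td_dd_ratio + 1.0)
    for _ in range(n_decoys):
        pa, pb = random_background_pair()
        if rng.random() < p_td:
            pa, dc = decoy_prefix + pa, DecoyClass.TD
        else:
            pa, pb, dc = decoy_prefix + pa, decoy_prefix + pb, DecoyClass.DD
        matches.append(fresh_record(pa, pb,
                                    float(rng.gumbel(NULL_LOC, NULL_SCALE)), dc))
    return matches, truth
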