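"""Readers and writers for the external formats the pipeline touches.

Tabular crosslink/candidate tables follow an xiFDR-style residue-pair
dialect whose column names are remappable (``dialect`` argument, YAML-able);
structures are parsed with gemmi (PDB and mmCIF); sequences with Biopython.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .config import PipelineConfig
from .datamodel import (CandidateMatch, Chain, CrosslinkRecord, DecoyClass,
                        ModelScoreSet, ProteinRecord, QuantMatrix,
                        StructureModel, decoy_class_for)

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file does not conform to its documented format."""


class RowError(FormatError):
    """A single table row failed to parse; carries the 0-based row index."""

    def __init__(self, row: int, message: str):
        super().__init__(f"row {row}: {message}")
        self.row = row


#: default xiFDR-style column dialect for residue-pair tables
DEFAULT_DIALECT: dict[str, str] = {
    "protein_a": "protein_a",
    "residue_a": "residue_a",
    "protein_b": "protein_b",
    "residue_b": "residue_b",
    "score": "score",
    "dataset_id": "dataset_id",
}

CANDIDATE_DIALECT: dict[str, str] = {
    **DEFAULT_DIALECT,
    "n_noncleaved_sda_fragments": "n_noncleaved_sda_fragments",
    "n_matches_peptide_a": "n_matches_peptide_a",
    "n_matches_peptide_b": "n_matches_peptide_b",
}


def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def _row_int(value: str, row: int, column: str) -> int:
    try:
        return int(value)
    except (TypeError, ValueError):
        raise RowError(row, f"column {column!r}: expected integer, got {value!r}")


def _row_float(value: str, row: int, column: str) -> float:
    if value == "":
        return 0.0
    try:
        return float(value)
    except (TypeError, ValueError):
        raise RowError(row, f"column {column!r}: expected number, got {value!r}")


def _require_columns(df: pd.DataFrame, dialect: Mapping[str, str],
                     required: Sequence[str], path: str | Path) -> None:
    for field in required:
        col = dialect[field]
        if col not in df.columns:
            raise FormatError(
                f"{path}: missing required column {col!r} (field {field!r})")


def read_crosslink_table(path: str | Path, config: PipelineConfig,
                         dialect: Mapping[str, str] | None = None
                         ) -> list[CrosslinkRecord]:
    """Read a residue-pair table into canonical :class:`CrosslinkRecord`\\ s.

    The decoy class is derived from per-protein decoy accession prefixes
    (``config.decoy_prefix``): target/target -> TT, one decoy -> TD, both -> DD.
    """
    d = {**DEFAULT_DIALECT, **(dialect or {})}
    df = _read_table(path)
    _require_columns(df, d, ("protein_a", "residue_a", "protein_b",
                             "residue_b", "score"), path)
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        pa, pb = str(row[d["protein_a"]]), str(row[d["protein_b"]])
        records.append(CrosslinkRecord(
            protein_a=pa,
            residue_a=_row_int(row[d["residue_a"]], i, d["residue_a"]),
            protein_b=pb,
            residue_b=_row_int(row[d["residue_b"]], i, d["residue_b"]),
            score=_row_float(row[d["score"]], i, d["score"]),
            decoy_class=decoy_class_for(pa, pb, config.decoy_prefix),
            dataset_id=str(row.get(d["dataset_id"], "")),
        ))
    return records


def read_candidate_table(path: str | Path, config: PipelineConfig,
                         dialect: Mapping[str, str] | None = None
                         ) -> list[CandidateMatch]:
    """Read a candidate-match table including fragment-evidence counts."""
    d = {**CANDIDATE_DIALECT, **(dialect or {})}
    df = _read_table(path)
    _require_columns(df, d, ("protein_a", "residue_a", "protein_b", "residue_b",
                             "score", "n_noncleaved_sda_fragments",
                             "n_matches_peptide_a", "n_matches_peptide_b"), path)
    matches = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        pa, pb = str(row[d["protein_a"]]), str(row[d["protein_b"]])
        matches.append(CandidateMatch(
            protein_a=pa,
            residue_a=_row_int(row[d["residue_a"]], i, d["residue_a"]),
            protein_b=pb,
            residue_b=_row_int(row[d["residue_b"]], i, d["residue_b"]),
            score=_row_float(row[d["score"]], i, d["score"]),
            decoy_class=decoy_class_for(pa, pb, config.decoy_prefix),
            dataset_id=str(row.get(d["dataset_id"], "")),
            n_noncleaved_sda_fragments=_row_int(
                row[d["n_noncleaved_sda_fragments"]], i,
                d["n_noncleaved_sda_fragments"]),
            n_matches_peptide_a=_row_int(
                row[d["n_matches_peptide_a"]], i, d["n_matches_peptide_a"]),
            n_matches_peptide_b=_row_int(
                row[d["n_matches_peptide_b"]], i, d["n_matches_peptide_b"]),
        ))
    return matches


def write_crosslink_table(records: Iterable[CrosslinkRecord],
                          path: str | Path) -> None:
    rows = [{
        "protein_a": r.protein_a, "residue_a": r.residue_a,
        "protein_b": r.protein_b, "residue_b": r.residue_b,
        "score": r.score, "decoy_class": r.decoy_class.value,
        "dataset_id": r.dataset_id,
    } for r in records]
    sep = "," if str(path).endswith(".csv") else "\t"
    pd.DataFrame(rows, columns=["protein_a", "residue_a", "protein_b",
                                "residue_b", "score", "decoy_class",
                                "dataset_id"]).to_csv(path, sep=sep, index=False)


def write_candidate_table(matches: Iterable[CandidateMatch],
                          path: str | Path) -> None:
    rows = [{
        "protein_a": m.protein_a, "residue_a": m.residue_a,
        "protein_b": m.protein_b, "residue_b": m.residue_b,
        "score": m.score, "dataset_id": m.dataset_id,
        "n_noncleaved_sda_fragments": m.n_noncleaved_sda_fragments,
        "n_matches_peptide_a": m.n_matches_peptide_a,
        "n_matches_peptide_b": m.n_matches_peptide_b,
    } for m in matches]
    sep = "," if str(path).endswith(".csv") else "\t"
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# structures

_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR", "X": "UNK",
}


def _one_letter(resname: str) -> str:
    info = gemmi.find_tabulated_residue(resname)
    if info is not None and info.is_amino_acid():
        code = info.one_letter_code.upper()
        return code if code.isalpha() else "X"
    return "X"


def read_structure(path: str | Path, fmt: str | None = None,
                   chain_to_protein: Mapping[str, str] | None = None,
                   model_id: str | None = None) -> StructureModel:
    """Read Cα coordinates of the first model of a PDB or mmCIF file.

    Only residues possessing a Cα atom (carbon, name ``CA``) are retained;
    alternate locations are resolved to the highest-occupancy, then
    first-listed, conformer.  Chains without any Cα are dropped with a
    warning.
    """
    fmt_map = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif,
               None: gemmi.CoorFormat.Detect}
    if fmt not in fmt_map:
        raise ValueError(f"unknown structure format {fmt!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt_map[fmt])
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: cannot parse structure: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"{path}: file contains no model")
    model = st[0]
    chains: list[Chain] = []
    for ch in model:
        resnums: list[int] = []
        seq: list[str] = []
        coords: list[tuple[float, float, float]] = []
        for res in ch:
            cas = [a for a in res if a.name == "CA" and a.element.name == "C"]
            if not cas:
                continue
            ca = max(cas, key=lambda a: a.occ)
            num = res.seqid.num
            if resnums and num <= resnums[-1]:
                continue  # duplicate seqid (altloc residue / insertion code)
            resnums.append(num)
            seq.append(_one_letter(res.name))
            coords.append((ca.pos.x, ca.pos.y, ca.pos.z))
        if not resnums:
            logger.warning("%s: chain %s has no Cα atoms; dropped", path, ch.name)
            continue
        chains.append(Chain(ch.name, np.array(resnums), "".join(seq),
                            np.array(coords)))
    if not chains:
        raise FormatError(f"{path}: no Cα atoms")
    return StructureModel(
        model_id=model_id or Path(path).stem,
        chains=chains,
        chain_to_protein=dict(chain_to_protein or {}))


def write_structure(model: StructureModel, path: str | Path,
                    fmt: str | None = None) -> None:
    """Write a Cα-only model as PDB or mmCIF (inferred from the extension)."""
    if fmt is None:
        fmt = "mmcif" if str(path).endswith((".cif", ".mmcif")) else "pdb"
    st = gemmi.Structure()
    st.name = model.model_id
    gm = gemmi.Model("1") if _model_takes_str() else gemmi.Model(1)
    for ch in model.chains:
        gc = gemmi.Chain(ch.chain_id)
        for num, aa, xyz in zip(ch.resnums, ch.sequence, ch.coords):
            res = gemmi.Residue()
            res.name = _THREE.get(aa, "UNK")
            res.seqid = gemmi.SeqId(int(num), " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*map(float, xyz))
            atom.occ = 1.0
            res.add_atom(atom)
            gc.add_residue(res)
        gm.add_chain(gc)
    st.add_model(gm)
    st.setup_entities()
    if fmt == "pdb":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))


def _model_takes_str() -> bool:
    try:
        gemmi.Model("1")
        return True
    except TypeError:
        return False


# ---------------------------------------------------------------------------
# sequences

def read_fasta(path: str | Path, config: PipelineConfig) -> list[ProteinRecord]:
    records = []
    core = set(config.core_subunits)
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id
        records.append(ProteinRecord(
            accession=acc, sequence=str(rec.seq),
            is_decoy=acc.startswith(config.decoy_prefix),
            core_subunit=acc in core))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    SeqIO.write([SeqRecord(Seq(r.sequence), id=r.accession, description="")
                 for r in records], str(path), "fasta")


# ---------------------------------------------------------------------------
# quantification matrices

def read_quant_matrix(path: str | Path, groups: Mapping[str, str] | str | Path,
                      scale: str = "raw") -> QuantMatrix:
    """Read a protein x sample TSV/CSV plus a sample -> group assignment.

    ``groups`` may be a mapping or the path of a two-column (sample, group)
    table.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index.name = None
    if isinstance(groups, (str, Path)):
        gsep = "," if str(groups).endswith(".csv") else "\t"
        gdf = pd.read_csv(groups, sep=gsep, dtype=str)
        if gdf.shape[1] < 2:
            raise FormatError(f"{groups}: expected columns (sample, group)")
        groups = dict(zip(gdf.iloc[:, 0], gdf.iloc[:, 1]))
    return QuantMatrix(df, dict(groups), scale)


def write_quant_matrix(matrix: QuantMatrix, path: str | Path,
                       groups_path: str | Path | None = None) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    matrix.intensities.to_csv(path, sep=sep, index_label="accession")
    if groups_path is not None:
        pd.DataFrame({"sample": matrix.samples,
                      "group": [matrix.groups[s] for s in matrix.samples]}
                     ).to_csv(groups_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pseudobonds and edge lists

def write_pseudobonds(measurements: Iterable, path: str | Path,
                      config: PipelineConfig,
                      color_scheme: str = "binary") -> int:
    """Write mapped crosslinks as a ChimeraX pseudobond file.

    ``measurements`` are :class:`~phixlink.restraints.DistanceMeasurement`
    objects for a single structure.  Binary scheme: satisfied (min distance
    <= the configured cutoff) -> blue, violated -> red.  Banded scheme uses
    ``config.band_edges``: blue below the lower edge, yellow inside the band
    (lower-inclusive), red above.  Unmapped crosslinks are skipped; the
    number written is returned.
    """
    if color_scheme not in ("binary", "banded"):
        raise ValueError(f"unknown color scheme {color_scheme!r}")
    lo, hi = config.band_edges
    lines = []
    skipped = 0
    for m in measurements:
        if not m.per_copy:
            skipped += 1
            continue
        best = min(m.per_copy, key=lambda c: c.distance)
        d = m.min_distance
        if color_scheme == "binary":
            color = "blue" if d <= config.sda_max_ca_distance else "red"
        else:
            color = "blue" if d < lo else ("yellow" if d < hi else "red")
        lines.append(f"/{best.chain_a}:{best.resnum_a}@CA "
                     f"/{best.chain_b}:{best.resnum_b}@CA {color}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
    if skipped:
        logger.info("write_pseudobonds: skipped %d unmapped crosslinks", skipped)
    return len(lines)


def write_ppi_edges(edges: Iterable, path: str | Path) -> None:
    """Write PPI edges as TSV (protein_a, protein_b, n_residue_pairs, ...)."""
    rows = [{
        "protein_a": e.protein_a, "protein_b": e.protein_b,
        "n_residue_pairs": len(e.residue_pairs),
        "aggregate_score": e.aggregate_score,
        "decoy_class": e.decoy_class.value,
        "datasets": ";".join(sorted(e.datasets)),
    } for e in edges]
    pd.DataFrame(rows, columns=["protein_a", "protein_b", "n_residue_pairs",
                                "aggregate_score", "decoy_class", "datasets"]
                 ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# predicted-model score files

def read_model_scores(path: str | Path, load_coordinates: bool = False,
                      base_dir: str | Path | None = None) -> list[ModelScoreSet]:
    """Read a JSON list of per-pair ipTM/pTM score sets.

    Schema: ``[{"pair": [acc, ...], "models": [{"iptm": f, "ptm": f,
    "coords_path": optional str}, ...]}, ...]``.  With ``load_coordinates``,
    each model's structure is read and its chains are assigned to the pair's
    accessions in order (or per an explicit ``chain_map`` entry).
    """
    base = Path(base_dir) if base_dir is not None else Path(path).parent
    with open(path) as fh:
        data = json.load(fh)
    out = []
    for entry in data:
        pair = tuple(entry["pair"])
        per_model = [(float(m["iptm"]), float(m["ptm"])) for m in entry["models"]]
        coords = None
        if load_coordinates:
            coords = []
            for m in entry["models"]:
                cp = m.get("coords_path")
                if cp is None:
                    coords.append(None)
                    continue
                struct = read_structure(base / cp)
                cmap = entry.get("chain_map") or dict(
                    zip((c.chain_id for c in struct.chains), pair))
                struct.chain_to_protein = dict(cmap)
                coords.append(struct)
        out.append(ModelScoreSet(pair, per_model, coords))
    return out
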