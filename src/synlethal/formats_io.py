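"""Readers and writers for every external file format the pipeline touches.

Formats: PDB structures (one model per protein, AlphaFold-DB style), FASTA
sequences, STRING-style TSV edge lists, SynLethDB-style CSV pair tables,
2-column gene↔protein TSV maps, and embedding tables as TSV.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning
from Bio.PDB.Polypeptide import protein_letters_3to1

from .containers import (
    NON_SL,
    SL,
    EmbeddingTable,
    GeneProteinMap,
    PairTable,
    ProteinStructure,
    WeightedGraph,
    canonical_pair,
)

log = logging.getLogger(__name__)

__all__ = [
    "read_structure",
    "read_fasta",
    "read_edge_list",
    "read_pair_table",
    "read_gene_map",
    "read_embeddings",
    "write_embeddings",
]


class FormatError(ValueError):
    """A file violated its expected format."""


def _residue_letter(resname: str) -> str:
    return protein_letters_3to1.get(resname.upper(), "X")


def read_structure(path: str | Path, protein_id: str) -> ProteinStructure:
    """Extract the Cα trace of one protein from a PDB file.

    Uses the first model and, among its chains, the one with the most CA
    atoms (ties broken by alphabetical chain ID) — AlphaFold files are
    single-chain, so this is a safe generalization. Residues lacking a CA
    atom are dropped with a warning and the sequence shortened consistently.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            model = next(parser.get_structure(protein_id, str(path)).get_models())
    except (PDBConstructionException, ValueError, StopIteration) as exc:
        raise FormatError(f"{path}: malformed PDB record ({exc})") from exc

    best_chain, best_count = None, -1
    for chain in sorted(model.get_chains(), key=lambda c: c.id):
        count = sum(1 for res in chain if "CA" in res)
        if count > best_count:
            best_chain, best_count = chain, count
    if best_chain is None or best_count == 0:
        raise FormatError(f"{path}: zero CA atoms")

    letters: list[str] = []
    coords: list[np.ndarray] = []
    n_dropped = 0
    for res in best_chain:
        if res.id[0] != " ":  # skip HETATM / water residues
            continue
        if "CA" not in res:
            n_dropped += 1
            continue
        letters.append(_residue_letter(res.get_resname()))
        coords.append(res["CA"].get_coord().astype(float))
    if n_dropped:
        log.warning("%s: dropped %d residue(s) lacking a CA atom", path, n_dropped)
    if not coords:
        raise FormatError(f"{path}: zero CA atoms")
    return ProteinStructure(protein_id, "".join(letters), np.asarray(coords))


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ID → sequence mapping (uppercased)."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"{path}: duplicate FASTA record {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    return records


def read_edge_list(path: str | Path, min_score: float = 0.0) -> WeightedGraph:
    """Read a 3-column (protein_a, protein_b, score) edge list into a graph.

    Rows with score < min_score are excluded (ties kept); duplicate rows in
    either orientation are collapsed keeping the maximum score; self-loops
    are dropped.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
    if df.shape[1] < 3:
        raise FormatError(f"{path}: expected >= 3 columns, got {df.shape[1]}")
    df = df.iloc[:, :3]
    df.columns = ["a", "b", "score"]
    # tolerate an optional header row
    first = df.iloc[0]["score"]
    try:
        float(first)
    except ValueError:
        df = df.iloc[1:]
    try:
        scores = df["score"].astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric score ({exc})") from exc

    best: dict[tuple[str, str], float] = {}
    for a, b, s in zip(df["a"], df["b"], scores):
        if a == b:
            continue
        key = (a, b) if a < b else (b, a)
        if key not in best or s > best[key]:
            best[key] = s
    g = WeightedGraph()
    for (a, b), s in best.items():
        if s >= min_score:
            g.add_edge(a, b, s)
    return g


def read_pair_table(path: str | Path) -> PairTable:
    """Read a gene-pair CSV with columns gene_a, gene_b, label ∈ {SL, nonSL}.

    Pairs are canonicalized and deduplicated; conflicting labels for one
    canonical pair raise an error.
    """
    df = pd.read_csv(path, dtype=str)
    required = {"gene_a", "gene_b", "label"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    bad = set(df["label"]) - {SL, NON_SL}
    if bad:
        raise FormatError(f"{path}: labels outside {{SL, nonSL}}: {sorted(bad)}")
    try:
        return PairTable(list(zip(df["gene_a"], df["gene_b"], df["label"])))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def read_gene_map(path: str | Path) -> list[tuple[str, str]]:
    """Read a 2-column (gene_id, protein_id) TSV as raw entries.

    Many-to-many resolution (keeping the mapping whose protein has the
    longest sequence) is a dataset-building decision and lives there.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected 2 columns, got {df.shape[1]}")
    return list(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_embeddings(table: EmbeddingTable, path: str | Path) -> None:
    """Write an embedding table as TSV with header ``id dim_0 … dim_{d-1}``.

    Values use repr-round-trip precision so read_embeddings recovers them
    numerically exactly.
    """
    path = Path(path)
    with path.open("w") as fh:
        header = ["id"] + [f"dim_{j}" for j in range(table.dim)]
        fh.write("\t".join(header) + "\n")
        for i, entity in enumerate(table.ids):
            row = "\t".join(np.format_float_scientific(v, unique=True)
                            for v in table.vectors[i])
            fh.write(f"{entity}\t{row}\n" if table.dim else f"{entity}\n")


def read_embeddings(path: str | Path) -> EmbeddingTable:
    """Read a TSV embedding table written by :func:`write_embeddings`."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "id":
            raise FormatError(f"{path}: missing 'id' header")
        dim = len(header) - 1
        ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != dim + 1 and not (dim == 0 and len(parts) == 1):
                raise FormatError(
                    f"{path}:{lineno}: expected {dim + 1} fields, got {len(parts)}"
                )
            ids.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    vectors = np.asarray(rows, dtype=float) if ids else np.empty((0, dim))
    if vectors.size == 0:
        vectors = vectors.reshape(len(ids), dim)
    return EmbeddingTable(ids, vectors)
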