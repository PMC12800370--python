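"""End-to-end orchestration: featurize → fuse → sample/split → train →
evaluate, with content-hash stage caching and input validation.

Each stage records a hash of its inputs (file contents + the stage's
configuration); a rerun with unchanged inputs reuses the cached outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import formats_io
from .config import RunConfig, derive_seed
from .containers import EmbeddingTable
from .dataset_builder import (
    PairDataset,
    build_balanced_dataset,
    fuse_features,
    resolve_gene_map,
    split_cv,
)
from .graph_embedding import SkipGramConfig, WalkConfig, node2vec_embed
from .sequence_embedding import kmer_hash_embedder, sequence_embedding
from .sl_mlp import MLPConfig, run_cv
from .structure_features import featurize_structures

log = logging.getLogger(__name__)

__all__ = ["run_pipeline", "validate_inputs", "save_dataset", "load_dataset"]


def _hash_parts(*parts: str | bytes) -> str:
    h = hashlib.sha256()
    for part in parts:
        h.update(part.encode() if isinstance(part, str) else part)
        h.update(b"\x00")
    return h.hexdigest()


def _hash_file(path: str | Path) -> str:
    return _hash_parts(Path(path).read_bytes())


def _hash_dir(path: str | Path) -> str:
    files = sorted(Path(path).glob("*"))
    return _hash_parts(*(f.name.encode() + f.read_bytes() for f in files))


def save_dataset(dataset: PairDataset, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.pairs.to_csv(out / "pairs.csv", index=False)
    if dataset.assignments is not None:
        dataset.assignments.to_csv(out / "assignments.csv", index=False)
    np.save(out / "features.npy", dataset.X)
    (out / "dataset_report.json").write_text(
        json.dumps({"block_dims": dataset.block_dims, **dataset.report},
                   indent=2, sort_keys=True)
    )


def load_dataset(out_dir: str | Path) -> PairDataset:
    out = Path(out_dir)
    pairs = pd.read_csv(out / "pairs.csv", dtype={"gene_a": str, "gene_b": str})
    meta = json.loads((out / "dataset_report.json").read_text())
    assignments = None
    if (out / "assignments.csv").exists():
        assignments = pd.read_csv(out / "assignments.csv")
    return PairDataset(
        pairs,
        np.load(out / "features.npy"),
        meta.pop("block_dims"),
        assignments=assignments,
        report=meta,
    )


def validate_inputs(
    pdb_dir: str | Path,
    fasta: str | Path,
    ppi: str | Path,
    sl_pairs: str | Path,
    gene_map: str | Path,
) -> dict:
    """Cross-file referential-integrity report.

    Fatal findings: SL genes absent from the gene map, mapped proteins
    without a FASTA record or a PDB file. Proteins absent from the PPI
    network are reported as warnings (they simply lack that feature block).
    """
    sequences = formats_io.read_fasta(fasta)
    entries = formats_io.read_gene_map(gene_map)
    gmap = resolve_gene_map(entries, sequences)
    table = formats_io.read_pair_table(sl_pairs)
    graph = formats_io.read_edge_list(ppi)
    pdb_ids = {p.stem for p in Path(pdb_dir).glob("*.pdb")}

    sl_genes = {g for a, b, _ in table.pairs for g in (a, b)}
    fatal, warnings_ = [], []
    for g in sorted(sl_genes - set(gmap.entries)):
        fatal.append(f"gene {g} has no protein mapping")
    for g, p in sorted(gmap.entries.items()):
        if p not in sequences:
            fatal.append(f"protein {p} (gene {g}) missing from FASTA")
        if p not in pdb_ids:
            fatal.append(f"protein {p} (gene {g}) missing structure file")
        if p not in graph:
            warnings_.append(f"protein {p} (gene {g}) absent from PPI network")
    return {
        "n_genes_mapped": len(gmap),
        "n_sl_genes": len(sl_genes),
        "n_structures": len(pdb_ids),
        "fatal": fatal,
        "warnings": warnings_,
    }


class _StageRunner:
    def __init__(self, out_dir: Path) -> None:
        self.out_dir = out_dir
        self.cache_file = out_dir / "stage_hashes.json"
        self.hashes = (
            json.loads(self.cache_file.read_text())
            if self.cache_file.exists()
            else {}
        )
        self.status: dict[str, str] = {}

    def run(self, name: str, input_hash: str, outputs: list[Path], fn) -> None:
        if (
            self.hashes.get(name) == input_hash
            and all(o.exists() for o in outputs)
        ):
            self.status[name] = "cached"
            log.info("stage %s: cache hit", name)
            return
        t0 = time.time()
        fn()
        self.hashes[name] = input_hash
        self.cache_file.write_text(json.dumps(self.hashes, indent=2))
        self.status[name] = "run"
        log.info("stage %s: ran in %.1f s", name, time.time() - t0)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run every stage in order, returning the metrics summary.

    Writes per-stage outputs, the resolved configuration, the metrics JSON
    and a provenance manifest into ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")
    paths = config.paths
    feat = config.features
    n2v = feat.node2vec
    runner = _StageRunner(out)

    report = validate_inputs(
        paths.pdb_dir, paths.fasta, paths.ppi, paths.sl_pairs, paths.gene_map
    )
    if report["fatal"]:
        raise ValueError(
            "input validation failed: " + "; ".join(report["fatal"][:5])
        )

    cfg_blob = json.dumps(config.model_dump(), sort_keys=True)

    struct_out = out / "struct_embeddings.tsv"
    def _featurize_structures() -> None:
        seed = derive_seed(config.seed, "structures")
        structures = [
            formats_io.read_structure(p, p.stem)
            for p in sorted(Path(paths.pdb_dir).glob("*.pdb"))
        ]
        table = featurize_structures(
            structures,
            cmap_thresh=feat.cmap_thresh,
            walk_cfg=WalkConfig(
                p=n2v.p, q=n2v.q, walks_per_node=n2v.walks_per_node,
                walk_length=n2v.walk_length, seed=seed,
            ),
            sg_cfg=SkipGramConfig(
                dim=feat.struct_dim, window=n2v.window, epochs=n2v.epochs,
                negative=n2v.negative, seed=seed,
            ),
        )
        formats_io.write_embeddings(table, struct_out)

    runner.run(
        "featurize_structures",
        _hash_parts(_hash_dir(paths.pdb_dir), cfg_blob),
        [struct_out],
        _featurize_structures,
    )

    ppi_out = out / "ppi_embeddings.tsv"
    def _featurize_ppi() -> None:
        seed = derive_seed(config.seed, "ppi")
        graph = formats_io.read_edge_list(paths.ppi, min_score=feat.min_ppi_score)
        table = node2vec_embed(
            graph,
            WalkConfig(
                p=n2v.p, q=n2v.q, walks_per_node=n2v.walks_per_node,
                walk_length=n2v.walk_length, seed=seed,
            ),
            SkipGramConfig(
                dim=feat.ppi_dim, window=n2v.window, epochs=n2v.epochs,
                negative=n2v.negative, seed=seed,
            ),
        )
        formats_io.write_embeddings(table, ppi_out)

    runner.run(
        "featurize_ppi",
        _hash_parts(_hash_file(paths.ppi), cfg_blob),
        [ppi_out],
        _featurize_ppi,
    )

    seq_out = out / "seq_embeddings.tsv"
    def _featurize_seq() -> None:
        seed = derive_seed(config.seed, "sequences")
        embedder = kmer_hash_embedder(
            k=feat.kmer_k, d_model=feat.seq_dim,
            layers=feat.embedder_layers, seed=seed,
        )
        sequences = formats_io.read_fasta(paths.fasta)
        table = EmbeddingTable.from_dict(
            {pid: sequence_embedding(s, embedder) for pid, s in sequences.items()}
        )
        formats_io.write_embeddings(table, seq_out)

    runner.run(
        "featurize_seq",
        _hash_parts(_hash_file(paths.fasta), cfg_blob),
        [seq_out],
        _featurize_seq,
    )

    ds_dir = out / "dataset"
    def _build_dataset() -> None:
        seed = derive_seed(config.seed, "dataset")
        sequences = formats_io.read_fasta(paths.fasta)
        gmap = resolve_gene_map(formats_io.read_gene_map(paths.gene_map), sequences)
        features = fuse_features(
            formats_io.read_embeddings(seq_out),
            formats_io.read_embeddings(ppi_out),
            formats_io.read_embeddings(struct_out),
            gmap,
        )
        pairs = formats_io.read_pair_table(paths.sl_pairs)
        ds = build_balanced_dataset(
            pairs.positives, pairs.negatives, features,
            ratio=config.parse_ratio(), seed=seed,
        )
        ds = split_cv(ds, folds=config.dataset.folds, seed=seed)
        save_dataset(ds, ds_dir)

    runner.run(
        "build_dataset",
        _hash_parts(
            _hash_file(paths.sl_pairs), _hash_file(paths.gene_map),
            _hash_file(paths.fasta),
            *(str(_hash_file(p)) for p in (struct_out, ppi_out, seq_out)),
            cfg_blob,
        ),
        [ds_dir / "pairs.csv", ds_dir / "features.npy"],
        _build_dataset,
    )

    metrics_out = out / "metrics.json"
    def _train_eval() -> None:
        seed = derive_seed(config.seed, "train")
        ds = load_dataset(ds_dir)
        mlp = config.mlp
        cfg = MLPConfig(
            hidden_sizes=tuple(mlp.hidden_sizes),
            dropout_rate=mlp.dropout_rate,
            learning_rate=mlp.learning_rate,
            l2_lambda=mlp.l2_lambda,
            max_epochs=mlp.max_epochs,
            patience=mlp.patience,
            batch_size=mlp.batch_size,
            seed=seed,
        )
        rep = run_cv(ds, cfg)
        metrics_out.write_text(rep.to_json())

    runner.run(
        "train_evaluate",
        _hash_parts(
            *(str(_hash_file(ds_dir / f)) for f in
              ("pairs.csv", "features.npy", "assignments.csv")),
            cfg_blob,
        ) if (ds_dir / "assignments.csv").exists() else _hash_parts(cfg_blob, "fresh"),
        [metrics_out],
        _train_eval,
    )

    manifest = {
        "stages": runner.status,
        "validation": report,
        "metrics": json.loads(metrics_out.read_text())["summary"],
    }
    (out / "provenance.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
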