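"""Shared fixtures: toy-scale featurization settings and generated bundles.

Featurization of a 40-protein bundle takes a few seconds, so bundles and
their feature tables are session-scoped and shared across test modules.
"""

from __future__ import annotations

import pytest

from synlethal import formats_io
from synlethal.containers import EmbeddingTable
from synlethal.dataset_builder import fuse_features, resolve_gene_map
from synlethal.graph_embedding import SkipGramConfig, WalkConfig, node2vec_embed
from synlethal.sequence_embedding import kmer_hash_embedder, sequence_embedding
from synlethal.sl_mlp import MLPConfig
from synlethal.structure_features import featurize_structures
from synlethal.synthetic_fixtures import FixtureConfig, generate_fixture

# toy-scale settings used for every fixture-driven experiment in the suite;
# study-scale defaults (dim 1024/128, walks 10x80) stay in the library
TOY_WALKS = dict(walks_per_node=4, walk_length=15)
TOY_SG = dict(window=3, epochs=2, negative=2)
TOY_DIMS = dict(seq=64, ppi=32, struct=32)


def toy_mlp_config(seed: int) -> MLPConfig:
    return MLPConfig(seed=seed, batch_size=32)


def featurize_bundle(bundle, seed: int):
    """Run all three feature branches on a bundle at toy scale."""
    walk_cfg = WalkConfig(seed=seed, **TOY_WALKS)
    structures = [
        formats_io.read_structure(p, p.stem)
        for p in sorted(bundle.pdb_dir.glob("*.pdb"))
    ]
    struct_table = featurize_structures(
        structures,
        cmap_thresh=10.0,
        walk_cfg=walk_cfg,
        sg_cfg=SkipGramConfig(dim=TOY_DIMS["struct"], seed=seed, **TOY_SG),
    )
    graph = formats_io.read_edge_list(bundle.ppi_path)
    ppi_table = node2vec_embed(
        graph,
        walk_cfg,
        SkipGramConfig(dim=TOY_DIMS["ppi"], seed=seed, **TOY_SG),
    )
    embedder = kmer_hash_embedder(k=3, d_model=TOY_DIMS["seq"], layers=2, seed=seed)
    sequences = formats_io.read_fasta(bundle.fasta_path)
    seq_table = EmbeddingTable.from_dict(
        {pid: sequence_embedding(s, embedder) for pid, s in sequences.items()}
    )
    gene_map = resolve_gene_map(
        formats_io.read_gene_map(bundle.gene_map_path), sequences
    )
    fused = fuse_features(seq_table, ppi_table, struct_table, gene_map)
    pairs = formats_io.read_pair_table(bundle.sl_path)
    return {
        "fused": fused,
        "pairs": pairs,
        "seq": seq_table,
        "ppi": ppi_table,
        "struct": struct_table,
        "gene_map": gene_map,
    }


@pytest.fixture(scope="session")
def planted_bundle(tmp_path_factory):
    """Default 40-gene bundle with signal in every feature block."""
    cfg = FixtureConfig(seed=1)
    return cfg, generate_fixture(cfg, tmp_path_factory.mktemp("planted"))


@pytest.fixture(scope="session")
def planted_features(planted_bundle):
    _, bundle = planted_bundle
    return featurize_bundle(bundle, seed=11)
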