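"""Synthetic input bundles with a planted, tunable synthetic-lethality signal.

The generator emits all five pipeline inputs at toy scale — PDB structures,
FASTA sequences, a STRING-style PPI edge list, an SL pair CSV and a
gene↔protein map — internally consistent and fully determined by a seed.

Planted-signal design: genes carry latent functional modules. SL pairs are
drawn within modules, known non-SL pairs across modules, and the selected
feature block(s) make module membership recoverable:

* ``struct`` — module members share a fold template (small Cα jitter plus a
  random rigid motion, which the contact map ignores);
* ``seq`` — module members share a template sequence with point mutations;
* ``ppi`` — module members are densely interconnected, giving SL partners
  many common neighbors;
* ``none`` / strength 0 — every feature is background noise and SL labels
  are random pairs, so no classifier should beat chance.

All proteins in one bundle share a single chain length drawn from
``seq_length_range``, so that protein length never confounds the planted
signal's location.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from Bio.Data.IUPACData import protein_letters_1to3

from .containers import canonical_pair

__all__ = ["FixtureConfig", "FixtureBundle", "generate_fixture"]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
CA_STEP = 3.8  # Å between consecutive Cα atoms


@dataclass(frozen=True)
class FixtureConfig:
    n_genes: int = 40
    seq_length_range: tuple[int, int] = (20, 80)
    ppi_edge_prob: float = 0.1
    n_sl_pairs: int = 140
    n_known_nonsl: int = 20
    signal_block: str = "all"  # seq | ppi | struct | all | none
    signal_strength: float = 3.0
    module_size: int = 8
    seed: int = 7

    def __post_init__(self) -> None:
        if self.signal_block not in {"seq", "ppi", "struct", "all", "none"}:
            raise ValueError(f"unknown signal_block {self.signal_block!r}")
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be >= 0")
        if self.n_sl_pairs > self.n_genes * (self.n_genes - 1) // 2:
            raise ValueError("n_sl_pairs exceeds the number of gene pairs")

    def has_signal(self, block: str) -> bool:
        return (
            self.signal_strength > 0
            and self.signal_block in (block, "all")
        )


@dataclass
class FixtureBundle:
    pdb_dir: Path
    fasta_path: Path
    ppi_path: Path
    sl_path: Path
    gene_map_path: Path
    manifest_path: Path
    manifest: dict


def _random_chain(length: int, rng: np.random.Generator) -> np.ndarray:
    """Self-avoiding-ish 3D Cα trace with exact 3.8 Å consecutive spacing.

    A persistent random walk: each step direction is the previous direction
    plus an isotropic perturbation, renormalized — extended enough to avoid
    most clashes at toy scale.
    """
    coords = np.zeros((length, 3))
    direction = rng.standard_normal(3)
    direction /= np.linalg.norm(direction)
    for i in range(1, length):
        direction = direction + 0.6 * rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        coords[i] = coords[i - 1] + CA_STEP * direction
    return coords


def _renormalize_steps(coords: np.ndarray) -> np.ndarray:
    """Rescale each consecutive step back to exactly 3.8 Å.

    Applied after template jitter so the backbone-spacing contract survives
    the perturbation; directions (and hence the contact pattern) keep the
    jitter.
    """
    out = np.empty_like(coords)
    out[0] = coords[0]
    for i in range(1, len(coords)):
        step = coords[i] - coords[i - 1]
        out[i] = out[i - 1] + CA_STEP * step / np.linalg.norm(step)
    return out


def _rigid_motion(coords: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random rotation + translation (a contact-map no-op)."""
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return coords @ q.T + rng.uniform(-50, 50, 3)


def _mutate(sequence: str, prob: float, rng: np.random.Generator) -> str:
    out = list(sequence)
    for i in range(len(out)):
        if rng.random() < prob:
            out[i] = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
    return "".join(out)


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(AMINO_ACIDS[k] for k in rng.integers(0, len(AMINO_ACIDS), length))


def _write_pdb(path: Path, sequence: str, coords: np.ndarray,
               rng: np.random.Generator) -> None:
    """Minimal conformant single-chain PDB with one CA atom per residue."""
    lines = []
    for i, (letter, (x, y, z)) in enumerate(zip(sequence, coords), start=1):
        res3 = protein_letters_1to3.get(letter, "Unk").upper()
        bfac = rng.uniform(70.0, 95.0)  # mimics a pLDDT column
        lines.append(
            f"ATOM  {i:5d}  CA  {res3:>3s} A{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{bfac:6.2f}"
            f"          {'C':>2s}"
        )
    lines.append("TER")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def _balanced_cross_pairs(
    genes: list[str],
    modules: dict[str, int],
    n_pairs: int,
    forbidden: set[tuple[str, str]],
    rng: np.random.Generator,
) -> list[tuple[str, str]]:
    """Cross-module non-SL pairs with near-uniform per-gene counts.

    Built from successive random cross-module perfect matchings, so every
    gene appears equally often (±1). Benchmarks that supply as many known
    negatives as positives thereby eliminate gene-frequency artifacts — a
    classifier cannot score pairs by how often their genes appear among
    negatives — isolating the feature-driven signal under test.
    """
    out: list[tuple[str, str]] = []
    used: set[tuple[str, str]] = set(forbidden)
    for _ in range(200):
        if len(out) >= n_pairs:
            break
        order = [genes[k] for k in rng.permutation(len(genes))]
        pool = list(order)
        while len(pool) > 1 and len(out) < n_pairs:
            a = pool.pop(0)
            match = next(
                (
                    b
                    for b in pool
                    if modules[a] != modules[b]
                    and canonical_pair(a, b) not in used
                ),
                None,
            )
            if match is None:
                continue
            pool.remove(match)
            pair = canonical_pair(a, match)
            used.add(pair)
            out.append(pair)
    if len(out) < n_pairs:
        raise ValueError(
            f"could not construct {n_pairs} balanced cross-module pairs"
        )
    return sorted(out)


def _plan(cfg: FixtureConfig) -> dict:
    """Deterministic latent plan: modules, sequences, structures, pairs.

    Every file writer consumes this one plan, so the five files are
    referentially consistent by construction.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [f"g{i:03d}" for i in range(cfg.n_genes)]
    proteins = [f"p{i:03d}" for i in range(cfg.n_genes)]
    modules = {g: i // cfg.module_size for i, g in enumerate(genes)}
    n_modules = max(modules.values()) + 1
    length = int(rng.integers(cfg.seq_length_range[0], cfg.seq_length_range[1] + 1))

    # --- sequences -------------------------------------------------------
    if cfg.has_signal("seq"):
        mut_prob = min(0.6, 0.15 / cfg.signal_strength)
        templates = [_random_sequence(length, rng) for _ in range(n_modules)]
        sequences = {
            p: _mutate(templates[modules[g]], mut_prob, rng)
            for g, p in zip(genes, proteins)
        }
    else:
        sequences = {p: _random_sequence(length, rng) for p in proteins}

    # --- structures ------------------------------------------------------
    if cfg.has_signal("struct"):
        jitter_sd = 0.15 / (1.0 + cfg.signal_strength)
        fold_templates = [_random_chain(length, rng) for _ in range(n_modules)]
        coords = {}
        for g, p in zip(genes, proteins):
            base = fold_templates[modules[g]] + jitter_sd * rng.standard_normal(
                (length, 3)
            )
            coords[p] = _rigid_motion(_renormalize_steps(base), rng)
    else:
        coords = {p: _rigid_motion(_random_chain(length, rng), rng)
                  for p in proteins}

    # --- PPI edges -------------------------------------------------------
    edges: dict[tuple[str, str], int] = {}
    for i in range(cfg.n_genes):
        for j in range(i + 1, cfg.n_genes):
            if rng.random() < cfg.ppi_edge_prob:
                key = canonical_pair(proteins[i], proteins[j])
                edges[key] = int(rng.integers(150, 1000))
    if cfg.has_signal("ppi"):
        p_intra = 1.0 - math.exp(-cfg.signal_strength)
        for i in range(cfg.n_genes):
            for j in range(i + 1, cfg.n_genes):
                gi, gj = genes[i], genes[j]
                if modules[gi] == modules[gj] and rng.random() < p_intra:
                    key = canonical_pair(proteins[i], proteins[j])
                    edges[key] = int(rng.integers(900, 1000))

    # --- SL labels -------------------------------------------------------
    all_pairs = [
        canonical_pair(genes[i], genes[j])
        for i in range(cfg.n_genes)
        for j in range(i + 1, cfg.n_genes)
    ]
    within = [p for p in all_pairs if modules[p[0]] == modules[p[1]]]
    across = [p for p in all_pairs if modules[p[0]] != modules[p[1]]]
    signal_on = cfg.signal_strength > 0 and cfg.signal_block != "none"
    sl_pool = within if signal_on else all_pairs
    if cfg.n_sl_pairs > len(sl_pool):
        raise ValueError(
            f"n_sl_pairs={cfg.n_sl_pairs} exceeds the {len(sl_pool)} "
            f"candidate pairs of this design"
        )
    sl_idx = rng.choice(len(sl_pool), size=cfg.n_sl_pairs, replace=False)
    sl_pairs = [sl_pool[k] for k in sorted(sl_idx)]
    if signal_on:
        nonsl_pairs = _balanced_cross_pairs(
            genes, modules, cfg.n_known_nonsl, set(sl_pairs), rng
        )
    else:
        nonsl_pool = [p for p in all_pairs if p not in set(sl_pairs)]
        ns_idx = rng.choice(len(nonsl_pool), size=cfg.n_known_nonsl, replace=False)
        nonsl_pairs = [nonsl_pool[k] for k in sorted(ns_idx)]

    return {
        "genes": genes,
        "proteins": proteins,
        "modules": modules,
        "length": length,
        "sequences": sequences,
        "coords": coords,
        "edges": edges,
        "sl_pairs": sl_pairs,
        "nonsl_pairs": nonsl_pairs,
        "pdb_rng_seed": int(rng.integers(0, 2**31 - 1)),
    }


def generate_fixture(cfg: FixtureConfig, out_dir: str | Path) -> FixtureBundle:
    """Write a complete input bundle to ``out_dir`` and return its paths.

    Byte-identical across runs with the same config.
    """
    out = Path(out_dir)
    pdb_dir = out / "structures"
    pdb_dir.mkdir(parents=True, exist_ok=True)
    plan = _plan(cfg)
    genes, proteins = plan["genes"], plan["proteins"]

    pdb_rng = np.random.default_rng(plan["pdb_rng_seed"])
    for p in proteins:
        _write_pdb(pdb_dir / f"{p}.pdb", plan["sequences"][p],
                   plan["coords"][p], pdb_rng)

    fasta_path = out / "sequences.fasta"
    with fasta_path.open("w") as fh:
        for p in proteins:
            fh.write(f">{p}\n{plan['sequences'][p]}\n")

    ppi_path = out / "ppi.tsv"
    with ppi_path.open("w") as fh:
        fh.write("protein_a\tprotein_b\tscore\n")
        for (a, b), s in sorted(plan["edges"].items()):
            fh.write(f"{a}\t{b}\t{s}\n")

    sl_path = out / "sl_pairs.csv"
    with sl_path.open("w") as fh:
        fh.write("gene_a,gene_b,label\n")
        for a, b in plan["sl_pairs"]:
            fh.write(f"{a},{b},SL\n")
        for a, b in plan["nonsl_pairs"]:
            fh.write(f"{a},{b},nonSL\n")

    gene_map_path = out / "gene_map.tsv"
    with gene_map_path.open("w") as fh:
        for g, p in zip(genes, proteins):
            fh.write(f"{g}\t{p}\n")

    manifest = {
        "config": asdict(cfg),
        "n_genes": len(genes),
        "protein_length": plan["length"],
        "modules": plan["modules"],
        "n_ppi_edges": len(plan["edges"]),
        "n_sl_pairs": len(plan["sl_pairs"]),
        "n_known_nonsl": len(plan["nonsl_pairs"]),
        "sl_pairs": [list(p) for p in plan["sl_pairs"]],
        "nonsl_pairs": [list(p) for p in plan["nonsl_pairs"]],
        # paths are stored relative to the bundle root so regeneration into
        # any directory is byte-identical
        "files": {
            "pdb_dir": pdb_dir.name,
            "fasta": fasta_path.name,
            "ppi": ppi_path.name,
            "sl": sl_path.name,
            "gene_map": gene_map_path.name,
        },
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return FixtureBundle(
        pdb_dir=pdb_dir,
        fasta_path=fasta_path,
        ppi_path=ppi_path,
        sl_path=sl_path,
        gene_map_path=gene_map_path,
        manifest_path=manifest_path,
        manifest=manifest,
    )
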