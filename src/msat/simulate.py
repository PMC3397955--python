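"""Synthetic data: 454-like reads with planted repeat tracks, Yule trees, traits.

Reads are i.i.d. background bases at a configurable GC level with perfect
repeat tracks of known motif and unit count overwritten at non-overlapping
uniform positions; a truth table records every planted interval.  Trees are
pure-birth topologies rescaled to a chosen root age; leaf traits evolve under
Brownian motion (variance accruing with branch length) or white noise.
All generators are seeded and deterministic.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import numpy as np

from msat.motifs import canonical_name

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class GenerationError(RuntimeError):
    """Raised when planted tracks cannot be placed within bounded retries."""


@dataclass(frozen=True)
class ReadSimConfig:
    n_reads: int
    read_length_mean: float = 350.0
    read_length_sd: float = 100.0
    min_read_length: int = 50
    gc_background: float = 0.5
    planted_tracks: tuple[tuple[str, int, int], ...] = ()  # (motif, n_units, count)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if not 0.0 < self.gc_background < 1.0:
            raise ValueError("gc_background must be in (0, 1)")
        for motif, n_units, count in self.planted_tracks:
            if n_units <= 0 or count <= 0:
                raise ValueError("planted n_units and count must be positive")
            canonical_name(motif)  # validates alphabet and length


@dataclass(frozen=True)
class PlantedTrack:
    """Truth-table row for one planted repeat interval (0-based, half-open)."""

    read_id: str
    start: int
    end: int
    motif: str
    n_units: int


def _read_id(i: int) -> str:
    return f"read{i:06d}"


def generate_reads(
    cfg: ReadSimConfig, max_retries: int = 1000
) -> tuple[list[tuple[str, str]], list[PlantedTrack]]:
    """Simulated read set plus the truth table of planted tracks."""
    rng = np.random.default_rng(cfg.seed)
    lengths = rng.normal(cfg.read_length_mean, cfg.read_length_sd, cfg.n_reads)
    lengths = np.maximum(np.rint(lengths), cfg.min_read_length).astype(int)
    gc = cfg.gc_background
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    reads = [_BASES[rng.choice(4, size=int(n), p=probs)].copy() for n in lengths]

    occupied: dict[int, list[tuple[int, int]]] = {}
    truth: list[PlantedTrack] = []
    for motif, n_units, count in cfg.planted_tracks:
        unit = canonical_name(motif)
        track_arr = np.frombuffer((unit * n_units).encode("ascii"), dtype=np.uint8)
        tlen = track_arr.size
        eligible = np.flatnonzero(lengths >= tlen)
        if eligible.size == 0:
            raise GenerationError(f"no read long enough for {unit} x {n_units}")
        for _ in range(count):
            for attempt in range(max_retries + 1):
                ridx = int(rng.choice(eligible))
                start = int(rng.integers(0, int(lengths[ridx]) - tlen + 1))
                end = start + tlen
                if not any(s < end and start < e for s, e in occupied.get(ridx, [])):
                    break
            else:
                raise GenerationError(
                    f"could not place {count} tracks of {unit} x {n_units} "
                    f"within {max_retries} retries"
                )
            reads[ridx][start:end] = track_arr
            occupied.setdefault(ridx, []).append((start, end))
            truth.append(PlantedTrack(_read_id(ridx), start, end, unit, n_units))

    out = [(_read_id(i), r.tobytes().decode("ascii")) for i, r in enumerate(reads)]
    truth.sort(key=lambda t: (t.read_id, t.start))
    return out, truth


def write_truth_table(truth: Iterable[PlantedTrack], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tstart\tend\tmotif\tn_units\n")
        for t in truth:
            fh.write(f"{t.read_id}\t{t.start}\t{t.end}\t{t.motif}\t{t.n_units}\n")


def write_manifest(config, path) -> None:
    """Record the seed and full config of a simulation run beside its outputs."""
    payload = asdict(config)
    payload["config_class"] = type(config).__name__
    Path(path).write_text(json.dumps(payload, indent=2, default=list) + "\n")


@dataclass(frozen=True)
class TraitSimConfig:
    n_leaves: int
    root_age_mya: float
    model: str = "brownian"  # or "white_noise"
    sigma2: float = 1.0
    root_value: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_leaves < 3:
            raise ValueError("n_leaves must be >= 3")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if self.model not in ("brownian", "white_noise"):
            raise ValueError(f"unknown trait model {self.model!r}")
        if self.root_age_mya <= 0:
            raise ValueError("root_age_mya must be positive")


def simulate_yule_tree(cfg: TraitSimConfig) -> dendropy.Tree:
    """Pure-birth topology with node depths rescaled so the root age is exact.

    Leaves are labeled ``s001 .. sNNN`` and sit at age 0; the root (first
    split) sits at ``cfg.root_age_mya``.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    n = cfg.n_leaves
    taxa = dendropy.TaxonNamespace([f"s{i + 1:03d}" for i in range(n)])
    tree = dendropy.Tree(taxon_namespace=taxa)

    birth_time: dict[dendropy.Node, float] = {}
    t = 0.0
    root = tree.seed_node
    active: list[dendropy.Node] = []
    for _ in range(2):
        child = root.new_child()
        birth_time[child] = 0.0
        active.append(child)
    split_time: dict[dendropy.Node, float] = {root: 0.0}
    while len(active) < n:
        k = len(active)
        t += float(rng.exponential(1.0 / k))
        node = active.pop(int(rng.integers(k)))
        split_time[node] = t
        for _ in range(2):
            child = node.new_child()
            birth_time[child] = t
            active.append(child)
    t_end = t + float(rng.exponential(1.0 / n))

    scale = cfg.root_age_mya / t_end
    for i, leaf in enumerate(active):
        leaf.taxon = taxa[i]
    for node in tree.preorder_node_iter():
        if node is root:
            node.edge.length = 0.0
        elif node in split_time:
            node.edge.length = (split_time[node] - birth_time[node]) * scale
        else:
            node.edge.length = (t_end - birth_time[node]) * scale
    return tree


def simulate_trait(tree: dendropy.Tree, cfg: TraitSimConfig) -> dict[str, float]:
    """Leaf trait values under Brownian motion along branches or white noise.

    The trait stream is decoupled from the tree stream so one config can seed
    both without reusing draws.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    leaves = list(tree.leaf_node_iter())
    labels = [
        leaf.taxon.label if leaf.taxon is not None else leaf.label for leaf in leaves
    ]
    if cfg.model == "white_noise":
        draws = rng.normal(cfg.root_value, np.sqrt(cfg.sigma2), len(leaves))
        return dict(zip(labels, draws.tolist()))
    value: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            value[node] = cfg.root_value
        else:
            edge = node.edge.length or 0.0
            value[node] = value[node.parent_node] + float(
                rng.normal(0.0, np.sqrt(cfg.sigma2 * edge))
            )
    return {
        (leaf.taxon.label if leaf.taxon is not None else leaf.label): value[leaf]
        for leaf in leaves
    }


def write_trait_csv(values: Mapping[str, float], path) -> None:
    with open(path, "w") as fh:
        fh.write("species_id,value\n")
        for species in sorted(values):
            fh.write(f"{species},{values[species]!r}\n")
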