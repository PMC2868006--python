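"""Synthetic proteomes and interaction networks with plantable triad signal.

The generator produces desk-scale stand-ins for a curated interactome so
that the whole pipeline is testable without external databases.  Residue
*compositions* are drawn i.i.d. from a configurable 7-group frequency
profile (defaulting to the groups' natural abundances), so empirical
group frequencies always converge to the profile.  Learnable signal is
planted at the triad-arrangement level: each protein carries a latent
stickiness u ~ Uniform(0, 1) and its residues are partially rearranged --
composition preserved -- to assemble occurrences of a configured motif
triad set, in proportion to u.  Because the significance encoding
measures exactly arrangement enrichment beyond composition, this is the
feature family the predictor can see.

The interaction network mixes motif-driven wiring with uniform noise at
the edge level: round(theta * n_interactions) edges are drawn with weight
(u_a * u_b)**gamma -- u re-estimated from the sequences as the rank
percentile of a motif-enrichment z-score -- and the remainder uniformly.
theta = 0 gives a uniformly random network (no learnable signal);
theta = 1 a fully motif-determined one.  Real
interactomes' domain structure, homology and degree distributions are
deliberately not modelled.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .datasets import PairKey, pair_key
from .encoding import AMINO_ACID_GROUPS, N_TRIADS, count_triads, map_to_groups
from .io import derive_seed, write_fasta, write_pairs

#: Natural occurrence of the 7 amino-acid groups (percent), normalised.
_RAW_PROFILE = np.array([22.0, 24.2, 17.3, 11.4, 11.4, 12.2, 1.4])
DEFAULT_GROUP_PROFILE: np.ndarray = _RAW_PROFILE / _RAW_PROFILE.sum()


@dataclass
class SyntheticConfig:
    """Study conditions for synthetic data generation.

    Defaults are the desk-scale benchmark profile: 300 proteins of length
    50-300 with 400 interactions and fully motif-determined wiring
    (signal_strength = 1).
    """

    n_proteins: int = 300
    length_range: tuple[int, int] = (50, 300)
    group_profile: np.ndarray | None = None
    n_interactions: int = 400
    signal_strength: float = 1.0   # theta in [0, 1]
    motif_set: list[tuple[int, int, int]] | None = None
    n_motifs: int = 16             # used when motif_set is None
    plant_max_fraction: float = 0.3  # max fraction of residues in planted motifs
    pair_sharpness: float = 6.0    # gamma exponent on the pair compatibility
    seed: int = 0

    def __post_init__(self):
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        lo, hi = self.length_range
        if lo < 1 or lo > hi:
            raise ValueError(f"degenerate length range {self.length_range}")
        if self.group_profile is not None:
            p = np.asarray(self.group_profile, dtype=float)
            if p.shape != (7,) or (p < 0).any() or not np.isclose(p.sum(), 1.0):
                raise ValueError("group_profile must be 7 probabilities "
                                 "summing to 1")
            self.group_profile = p
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError("signal_strength must lie in [0, 1]")
        max_pairs = self.n_proteins * (self.n_proteins + 1) // 2
        if self.n_interactions > max_pairs:
            raise ValueError(
                f"{self.n_interactions} interactions exceed the {max_pairs} "
                f"unordered pairs over {self.n_proteins} proteins"
            )
        if not 0.0 <= self.plant_max_fraction <= 1.0:
            raise ValueError("plant_max_fraction must lie in [0, 1]")

    @property
    def profile(self) -> np.ndarray:
        return (DEFAULT_GROUP_PROFILE if self.group_profile is None
                else self.group_profile)

    def resolved_motifs(self) -> list[tuple[int, int, int]]:
        """The motif triads, deriving a seeded default set when unset."""
        if self.motif_set is not None:
            motifs = [tuple(m) for m in self.motif_set]
            if any(len(m) != 3 or not all(1 <= g <= 7 for g in m)
                   for m in motifs):
                raise ValueError("motifs must be triples of groups 1..7")
            return motifs
        rng = np.random.default_rng(derive_seed(self.seed, "motifs"))
        codes = rng.choice(N_TRIADS, size=self.n_motifs, replace=False)
        return [(int(c) // 49 + 1, (int(c) // 7) % 7 + 1, int(c) % 7 + 1)
                for c in sorted(codes)]

    def as_dict(self) -> dict:
        return {
            "n_proteins": self.n_proteins,
            "length_range": list(self.length_range),
            "group_profile": [round(float(x), 6) for x in self.profile],
            "n_interactions": self.n_interactions,
            "signal_strength": self.signal_strength,
            "motif_set": [list(m) for m in self.resolved_motifs()],
            "plant_max_fraction": self.plant_max_fraction,
            "pair_sharpness": self.pair_sharpness,
            "seed": self.seed,
        }


def _stickiness(cfg: SyntheticConfig) -> np.ndarray:
    rng = np.random.default_rng(derive_seed(cfg.seed, "stickiness"))
    return rng.random(cfg.n_proteins)


def _plant_motifs(
    residues: list[str],
    groups: np.ndarray,
    n_plants: int,
    motifs: Sequence[tuple[int, int, int]],
    rng: np.random.Generator,
) -> str:
    """Rearrange a residue multiset to assemble motif triads (composition kept).

    Residues are pooled by group; up to ``n_plants`` motif blocks are
    withdrawn from the pools (skipping motifs whose groups are exhausted)
    and re-inserted at random positions among the shuffled remainder.
    """
    pools: dict[int, list[str]] = {g: [] for g in range(1, 8)}
    for res, g in zip(residues, groups):
        pools[int(g)].append(res)
    for g in pools:
        rng.shuffle(pools[g])
    blocks: list[str] = []
    motif_order = list(motifs)
    for _ in range(n_plants):
        rng.shuffle(motif_order)
        for motif in motif_order:
            need: dict[int, int] = {}
            for g in motif:
                need[g] = need.get(g, 0) + 1
            if all(len(pools[g]) >= k for g, k in need.items()):
                blocks.append("".join(pools[g].pop() for g in motif))
                break
        else:
            break  # no motif can be assembled from the remaining pools
    rest = [r for pool in pools.values() for r in pool]
    rng.shuffle(rest)
    for block in blocks:
        pos = int(rng.integers(0, len(rest) + 1))
        rest[pos:pos] = list(block)
    return "".join(rest)


def generate_proteome(cfg: SyntheticConfig) -> list[tuple[str, str]]:
    """Generate (id, sequence) records; reproducible from cfg.seed.

    Residue counts follow the group-frequency profile i.i.d. (uniform
    residue choice within each group); motif planting only rearranges
    residues, so the group composition of every sequence -- and hence the
    empirical group frequencies -- is unaffected by it.
    """
    rng = np.random.default_rng(derive_seed(cfg.seed, "proteome"))
    u = _stickiness(cfg)
    motifs = cfg.resolved_motifs()
    lo, hi = cfg.length_range
    profile = cfg.profile
    group_residues = {g: list(AMINO_ACID_GROUPS[g]) for g in range(1, 8)}
    records: list[tuple[str, str]] = []
    width = max(4, len(str(cfg.n_proteins)))
    for i in range(cfg.n_proteins):
        L = int(rng.integers(lo, hi + 1))
        groups = rng.choice(np.arange(1, 8), size=L, p=profile)
        residues = [
            group_residues[int(g)][int(rng.integers(0, len(group_residues[int(g)])))]
            for g in groups
        ]
        n_plants = int(u[i] * cfg.plant_max_fraction * L / 3)
        seq = _plant_motifs(residues, groups, n_plants, motifs, rng)
        records.append((f"P{i:0{width}d}", seq))
    return records


def motif_enrichment(
    proteome: Sequence[tuple[str, str]],
    motifs: Sequence[tuple[int, int, int]],
) -> np.ndarray:
    """Per-protein z-score of total motif-triad count vs composition null.

    The expected count of triad (a, b, c) in a random arrangement is
    approximately (L - 2) p_a p_b p_c with p the sequence's own group
    fractions; the z-score standardises the summed observed excess.
    """
    z = np.empty(len(proteome))
    for k, (_, seq) in enumerate(proteome):
        gs = map_to_groups(seq)
        o = count_triads(gs)
        L = len(gs)
        comp = np.array(gs.composition, dtype=float)
        p = comp / comp.sum()
        observed = expected = 0.0
        for a, b, c in motifs:
            observed += o[(a - 1) * 49 + (b - 1) * 7 + (c - 1)]
            expected += max(0, L - 2) * p[a - 1] * p[b - 1] * p[c - 1]
        z[k] = (observed - expected) / np.sqrt(expected + 1e-9)
    return z


def generate_network(
    cfg: SyntheticConfig,
    proteome: Sequence[tuple[str, str]],
) -> set[PairKey]:
    """Sample an interaction network wired by shared motif enrichment.

    round(theta * n_interactions) motif-driven edges are drawn without
    replacement with weight (u_a * u_b)**gamma, where u is the rank
    percentile of each protein's motif-enrichment z-score; the remaining
    edges are drawn uniformly from the leftover pairs (self-pairs
    included throughout).
    """
    n = len(proteome)
    max_pairs = n * (n + 1) // 2
    if cfg.n_interactions > max_pairs:
        raise ValueError(
            f"{cfg.n_interactions} interactions infeasible over {n} proteins "
            f"({max_pairs} pairs)"
        )
    z = motif_enrichment(proteome, cfg.resolved_motifs())
    ranks = np.argsort(np.argsort(z, kind="stable"), kind="stable")
    u = ranks / max(1, n - 1)
    ii, jj = np.triu_indices(n)
    w = (u[ii] * u[jj]) ** cfg.pair_sharpness
    rng = np.random.default_rng(derive_seed(cfg.seed, "network"))
    n_motif = round(cfg.signal_strength * cfg.n_interactions)
    chosen: list[int] = []
    if n_motif > 0:
        p = w / w.sum()
        chosen.extend(rng.choice(len(ii), size=n_motif, replace=False, p=p))
    if cfg.n_interactions - n_motif > 0:
        remaining = np.setdiff1d(np.arange(len(ii)), np.array(chosen, int))
        chosen.extend(rng.choice(remaining,
                                 size=cfg.n_interactions - n_motif,
                                 replace=False))
    ids = [pid for pid, _ in proteome]
    return {pair_key(ids[ii[k]], ids[jj[k]]) for k in chosen}


def simulate(cfg: SyntheticConfig, out_dir: str | Path | None = None
             ) -> tuple[list[tuple[str, str]], set[PairKey]]:
    """Generate a proteome and network; optionally write FASTA/TSV/manifest."""
    proteome = generate_proteome(cfg)
    network = generate_network(cfg, proteome)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(proteome, out_dir / "proteome.fasta")
        write_pairs(
            [(a, b, "in_vivo") for a, b in sorted(network)],
            out_dir / "interactions.tsv",
            header=("protein_a", "protein_b", "detection"),
        )
        manifest = {"config": cfg.as_dict(),
                    "n_proteins": len(proteome),
                    "n_interactions": len(network)}
        (out_dir / "simulate_manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
    return proteome, network
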