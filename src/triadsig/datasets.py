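"""Construction of imbalanced PPI datasets with disjointness guarantees.

Positive instances are curated interactions filtered to binary (two
participant) records, in-vivo detections only, and proteins free of
non-standard residues such as selenocysteine.  Negative instances are
drawn uniformly from the complement of the known-interaction set over the
positive proteins: a pool of n proteins with m excluded pairs offers
n(n+1)/2 - m candidate negatives (unordered pairs, self-pairs included).

Ratio-controlled datasets reuse one positive train/test split per
repetition and draw distinct negative sets for every ratio, never
re-selecting a negative pair within the repetition (optionally across
repetitions when the pair space allows).
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import derive_seed, write_pairs

logger = logging.getLogger(__name__)

PairKey = tuple[str, str]

DETECTION_KINDS = ("in_vivo", "in_vitro", "other")


def pair_key(a: str, b: str) -> PairKey:
    """Canonical unordered pair (id_a <= id_b); self-pairs allowed."""
    if not a or not b:
        raise ValueError("protein ids must be non-empty strings")
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class InteractionRecord:
    """One curated interaction: participant ids plus detection context."""

    protein_ids: tuple[str, ...]
    detection: str = "in_vivo"
    source_line: str = ""

    def __post_init__(self):
        if len(self.protein_ids) < 2:
            raise ValueError("an interaction needs at least two participants")
        if any(not p for p in self.protein_ids):
            raise ValueError("protein ids must be non-empty strings")
        if self.detection not in DETECTION_KINDS:
            raise ValueError(f"unknown detection kind {self.detection!r}")


@dataclass
class FilterStats:
    n_records: int = 0
    removed_multi_protein: int = 0
    removed_nonstandard_residue: int = 0
    removed_not_in_vivo: int = 0
    removed_missing_sequence: int = 0
    n_pairs: int = 0
    n_proteins: int = 0

    def as_dict(self) -> dict:
        return dict(vars(self))


def _has_nonstandard(seq: str) -> bool:
    from .encoding import STANDARD_AMINO_ACIDS

    return any(ch not in STANDARD_AMINO_ACIDS for ch in seq)


def filter_interactions(
    records: Iterable[InteractionRecord],
    sequences: Mapping[str, str],
    *,
    on_missing: str = "error",
) -> tuple[set[PairKey], set[str], FilterStats]:
    """Apply the positive-set filters and return canonical pairs + proteins.

    Removes records with more than two participants, records whose protein
    sequences contain non-standard residues (selenocysteine U in
    particular), and records not detected in vivo.  Duplicate pairs are
    collapsed to one canonical pair.  Proteins missing from ``sequences``
    raise (``on_missing='error'``) or drop the record (``'drop'``).
    """
    if on_missing not in ("error", "drop"):
        raise ValueError("on_missing must be 'error' or 'drop'")
    stats = FilterStats()
    pairs: set[PairKey] = set()
    for rec in records:
        stats.n_records += 1
        if len(rec.protein_ids) > 2:
            stats.removed_multi_protein += 1
            continue
        a, b = rec.protein_ids
        missing = [p for p in (a, b) if p not in sequences]
        if missing:
            if on_missing == "error":
                raise KeyError(
                    f"protein {missing[0]!r} has no sequence in the FASTA index"
                )
            stats.removed_missing_sequence += 1
            continue
        if _has_nonstandard(sequences[a]) or _has_nonstandard(sequences[b]):
            stats.removed_nonstandard_residue += 1
            continue
        if rec.detection != "in_vivo":
            stats.removed_not_in_vivo += 1
            continue
        pairs.add(pair_key(a, b))
    if not pairs:
        raise ValueError("no positive pairs survive the filters")
    proteins = {p for pr in pairs for p in pr}
    stats.n_pairs = len(pairs)
    stats.n_proteins = len(proteins)
    logger.info(
        "filtered %d records -> %d pairs over %d proteins "
        "(removed: %d multi-protein, %d non-standard residue, %d not in vivo, "
        "%d missing sequence)",
        stats.n_records, stats.n_pairs, stats.n_proteins,
        stats.removed_multi_protein, stats.removed_nonstandard_residue,
        stats.removed_not_in_vivo, stats.removed_missing_sequence,
    )
    return pairs, proteins, stats


def expand_exclusions(records: Iterable[InteractionRecord]) -> set[PairKey]:
    """All pairwise combinations from every record, regardless of detection.

    This is the exclusion set for negative sampling: a negative must not
    appear in *any* known interaction, including in-vitro detections and
    pairs derived from multi-protein records.
    """
    out: set[PairKey] = set()
    for rec in records:
        for a, b in itertools.combinations(sorted(set(rec.protein_ids)), 2):
            out.add(pair_key(a, b))
        if len(set(rec.protein_ids)) == 1:
            out.add(pair_key(rec.protein_ids[0], rec.protein_ids[0]))
    return out


def negative_space_size(n_proteins: int, n_excluded_interactions: int) -> int:
    """n(n+1)/2 - m candidate negatives over n proteins with m exclusions."""
    if n_proteins < 1:
        raise ValueError("need at least one protein")
    total = n_proteins * (n_proteins + 1) // 2
    if n_excluded_interactions > total:
        raise ValueError(
            f"{n_excluded_interactions} exclusions exceed the "
            f"{total} unordered pairs over {n_proteins} proteins"
        )
    size = total - n_excluded_interactions
    if size < 0:
        raise ValueError("negative space size is negative")
    return size


# Below this pair-space size the complement is enumerated explicitly;
# above it, rejection sampling with a used-pair registry is cheaper.
_ENUMERATION_LIMIT = 1_000_000


def sample_negatives(
    proteins: Iterable[str],
    excluded: set[PairKey],
    count: int,
    seed: int,
    already_used: set[PairKey] = frozenset(),
) -> set[PairKey]:
    """Uniform sample (without replacement) of non-interacting pairs.

    Candidates are the unordered pairs (self-pairs included) over
    ``proteins`` minus ``excluded`` minus ``already_used``.  Deterministic
    given ``seed``; raises with the exact available count when ``count``
    exceeds the remaining space.
    """
    ids = sorted(set(proteins))
    n = len(ids)
    id_set = set(ids)
    total = n * (n + 1) // 2

    def _in_space(p: PairKey) -> bool:
        return p[0] in id_set and p[1] in id_set

    blocked = {p for p in excluded if _in_space(p)}
    blocked |= {p for p in already_used if _in_space(p)}
    available = total - len(blocked)
    if count < 0:
        raise ValueError("count must be non-negative")
    if count > available:
        raise ValueError(
            f"requested {count} negatives but only {available} remain "
            f"({total} pairs, {len(blocked)} excluded or already used)"
        )
    rng = np.random.default_rng(seed)
    if total <= _ENUMERATION_LIMIT:
        candidates = [
            (ids[i], ids[j])
            for i in range(n)
            for j in range(i, n)
            if (ids[i], ids[j]) not in blocked
        ]
        chosen = rng.choice(len(candidates), size=count, replace=False)
        return {candidates[k] for k in chosen}
    # Rejection sampling against the registry for huge implicit complements.
    selected: set[PairKey] = set()
    while len(selected) < count:
        batch = max(1024, 2 * (count - len(selected)))
        draws = rng.integers(0, n, size=(batch, 2))
        for i, j in draws:
            p = pair_key(ids[i], ids[j])
            if p in blocked or p in selected:
                continue
            selected.add(p)
            if len(selected) == count:
                break
    return selected


@dataclass(frozen=True)
class RatioDataset:
    """Train/test split at a 1:ratio positive-to-negative balance."""

    ratio: int
    repetition: int
    train_pos: tuple[PairKey, ...]
    train_neg: tuple[PairKey, ...]
    test_pos: tuple[PairKey, ...]
    test_neg: tuple[PairKey, ...]
    seed: int

    def __post_init__(self):
        if len(self.train_neg) != self.ratio * len(self.train_pos):
            raise ValueError("train negatives must number ratio * positives")
        if len(self.test_neg) != self.ratio * len(self.test_pos):
            raise ValueError("test negatives must number ratio * positives")


def build_ratio_datasets(
    positives: set[PairKey],
    proteins: Iterable[str],
    excluded: set[PairKey],
    *,
    ratios: Sequence[int],
    split: tuple[int, int],
    repetitions: int = 1,
    seed: int = 0,
    disjoint_across_repetitions: bool = False,
) -> list[RatioDataset]:
    """Generate ratio-controlled datasets with disjointness guarantees.

    Within one repetition the positive train/test split is shared by all
    ratios, each ratio draws its own negatives, and no negative pair is
    selected twice (train vs test or across ratios).  Repetitions use
    fresh sub-seeds; ``disjoint_across_repetitions`` extends the no-reuse
    registry across repetitions when the pair space is large enough.
    """
    ids = sorted(set(proteins))
    ratios = sorted(set(int(r) for r in ratios))
    if any(r < 1 for r in ratios):
        raise ValueError("ratios must be >= 1")
    n_train_pos, n_test_pos = split
    if n_train_pos + n_test_pos != len(positives):
        raise ValueError(
            f"split {split} must sum to the number of positives "
            f"({len(positives)})"
        )
    if n_train_pos < 1 or n_test_pos < 1:
        raise ValueError("both split sizes must be positive")
    all_excluded = set(excluded) | set(positives)
    blocked_n = len({p for p in all_excluded
                     if p[0] in set(ids) and p[1] in set(ids)})
    available = negative_space_size(len(ids), blocked_n)
    per_rep = sum(r for r in ratios) * (n_train_pos + n_test_pos)
    needed = per_rep * repetitions if disjoint_across_repetitions else per_rep
    if needed > available:
        raise ValueError(
            f"insufficient negative space: need {needed} disjoint negatives "
            f"but only {available} are available"
        )

    pos_sorted = sorted(positives)
    datasets: list[RatioDataset] = []
    used_global: set[PairKey] = set()
    for rep in range(repetitions):
        rep_rng = np.random.default_rng(derive_seed(seed, "split", rep))
        order = rep_rng.permutation(len(pos_sorted))
        train_pos = tuple(sorted(pos_sorted[k] for k in order[:n_train_pos]))
        test_pos = tuple(sorted(pos_sorted[k] for k in order[n_train_pos:]))
        used = used_global if disjoint_across_repetitions else set()
        for r in ratios:
            train_neg = sample_negatives(
                ids, all_excluded, r * n_train_pos,
                derive_seed(seed, "neg", rep, r, "train"), already_used=used,
            )
            used |= train_neg
            test_neg = sample_negatives(
                ids, all_excluded, r * n_test_pos,
                derive_seed(seed, "neg", rep, r, "test"), already_used=used,
            )
            used |= test_neg
            datasets.append(
                RatioDataset(
                    ratio=r,
                    repetition=rep,
                    train_pos=train_pos,
                    train_neg=tuple(sorted(train_neg)),
                    test_pos=test_pos,
                    test_neg=tuple(sorted(test_neg)),
                    seed=seed,
                )
            )
    return datasets


def write_ratio_dataset(ds: RatioDataset, out_dir: str | Path) -> list[Path]:
    """One TSV per set (pair ids + label), named by repetition and ratio."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for part in ("train", "test"):
        path = out_dir / f"rep{ds.repetition}_ratio{ds.ratio}_{part}.tsv"
        pos = getattr(ds, f"{part}_pos")
        neg = getattr(ds, f"{part}_neg")
        rows = [(a, b, 1) for a, b in pos] + [(a, b, 0) for a, b in neg]
        write_pairs(rows, path, header=("protein_a", "protein_b", "label"))
        written.append(path)
    return written


def write_build_manifest(
    datasets: Sequence[RatioDataset],
    out_dir: str | Path,
    *,
    seed: int,
    filter_stats: FilterStats | None = None,
) -> Path:
    out_dir = Path(out_dir)
    manifest = {
        "seed": seed,
        "ratios": sorted({ds.ratio for ds in datasets}),
        "repetitions": len({ds.repetition for ds in datasets}),
        "counts": [
            {
                "repetition": ds.repetition,
                "ratio": ds.ratio,
                "train_pos": len(ds.train_pos),
                "train_neg": len(ds.train_neg),
                "test_pos": len(ds.test_pos),
                "test_neg": len(ds.test_neg),
            }
            for ds in datasets
        ],
    }
    if filter_stats is not None:
        manifest["filter_stats"] = filter_stats.as_dict()
    path = out_dir / "datasets_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
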