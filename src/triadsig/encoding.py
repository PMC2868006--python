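"""Triad-based feature encodings of protein primary sequences.

A protein sequence is reduced to a 7-letter alphabet of physicochemical
amino-acid groups (clustered by dipole strength and side-chain volume).
Every window of three consecutive residues -- a *conjoint triad* -- is one
of 7**3 = 343 types. Three per-protein encodings are provided:

``occurrence``
    Raw counts of each triad along the grouped sequence (overlapping
    windows), the vector **O** with entries ``o_i``.
``frequency``
    Counts normalised by the number of windows, ``o_i / (L - 2)``.
    This is the classical conjoint-triad feature used as a comparison
    baseline.
``significance``
    For each triad, the probability that a composition-preserving random
    shuffle of the sequence contains *strictly fewer* occurrences than
    observed, estimated over ``n_permutations`` shuffles.  This is one
    minus the permutation p-value: it measures how surprising the observed
    triad count is given the amino-acid composition, decoupling the
    feature from the background residue distribution.

A protein *pair* is encoded by concatenating the two per-protein vectors
in canonical (lexicographic-by-identifier) order, giving a 686-dimensional
feature vector that is invariant to the order the two proteins are given.
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Physicochemical amino-acid groups (dipole strength / side-chain volume).
AMINO_ACID_GROUPS: dict[int, str] = {
    1: "AGV",
    2: "ILFP",
    3: "YMTS",
    4: "HNQW",
    5: "RK",
    6: "DE",
    7: "C",
}

STANDARD_AMINO_ACIDS: frozenset[str] = frozenset("ACDEFGHIKLMNPQRSTVWY")

AA_TO_GROUP: dict[str, int] = {
    aa: g for g, members in AMINO_ACID_GROUPS.items() for aa in members
}

N_GROUPS = 7
N_TRIADS = N_GROUPS**3  # 343
PAIR_DIM = 2 * N_TRIADS  # 686
UNGROUPED_PAIR_DIM = 2 * 20**3  # 16000, without the 7-group reduction

#: Column labels "g1g2g3" in triad-index order.
TRIAD_LABELS: list[str] = [
    f"{a}{b}{c}"
    for a in range(1, 8)
    for b in range(1, 8)
    for c in range(1, 8)
]

# Fast residue -> group lookup over byte values; -1 marks invalid residues.
_GROUP_LUT = np.full(256, -1, dtype=np.int8)
for _aa, _g in AA_TO_GROUP.items():
    _GROUP_LUT[ord(_aa)] = _g


class InvalidResidueError(ValueError):
    """A sequence contains a character outside the 20 standard residues."""

    def __init__(self, residue: str, position: int, source_id: str = ""):
        self.residue = residue
        self.position = position  # 1-based
        self.source_id = source_id
        where = f" in '{source_id}'" if source_id else ""
        super().__init__(
            f"invalid residue {residue!r} at position {position}{where}; "
            "only the 20 standard one-letter amino-acid codes are accepted"
        )


@dataclass(frozen=True)
class GroupSequence:
    """A protein sequence mapped onto the 7 amino-acid groups."""

    symbols: np.ndarray  # int8 values in 1..7
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def composition(self) -> tuple[int, ...]:
        """Counts of each group 1..7, the permutation-invariant of the sequence."""
        return tuple(np.bincount(self.symbols, minlength=N_GROUPS + 1)[1:])


@dataclass(frozen=True)
class SignificanceVector:
    """Per-protein 343-dim permutation-significance feature Pr(X_i < o_i)."""

    s: np.ndarray  # float64, values in [0, 1]
    n_permutations: int
    seed: int
    source_id: str = ""


@dataclass(frozen=True)
class PairFeature:
    """686-dim concatenated feature vector for an unordered protein pair."""

    vector: np.ndarray
    protein_a: str
    protein_b: str


def map_to_groups(sequence: str, source_id: str = "") -> GroupSequence:
    """Substitute each residue by its group index (1..7).

    Raises :class:`InvalidResidueError` for any character outside the 20
    standard codes, including U (selenocysteine), B, Z and X.
    """
    if not sequence:
        raise ValueError("empty sequence")
    raw = np.frombuffer(sequence.encode("ascii", errors="replace"), dtype=np.uint8)
    symbols = _GROUP_LUT[raw]
    bad = np.flatnonzero(symbols < 0)
    if bad.size:
        pos = int(bad[0])
        raise InvalidResidueError(sequence[pos], pos + 1, source_id)
    return GroupSequence(symbols=symbols, source_id=source_id)


def _triad_codes(symbols: np.ndarray) -> np.ndarray:
    """0-based triad index of every window; empty for length < 3."""
    if symbols.shape[-1] < 3:
        return np.empty(symbols.shape[:-1] + (0,), dtype=np.int32)
    s = symbols.astype(np.int32) - 1
    return (
        s[..., :-2] * (N_GROUPS * N_GROUPS) + s[..., 1:-1] * N_GROUPS + s[..., 2:]
    )


def count_triads(gs: GroupSequence | np.ndarray) -> np.ndarray:
    """Occurrence vector **O**: counts of every triad, overlapping windows.

    A sequence of length L yields max(0, L - 2) windows; shorter sequences
    give the all-zero vector.
    """
    symbols = gs.symbols if isinstance(gs, GroupSequence) else np.asarray(gs)
    return np.bincount(_triad_codes(symbols), minlength=N_TRIADS).astype(np.int64)


def encode_frequency(gs: GroupSequence) -> np.ndarray:
    """Relative triad frequencies o_i / (L - 2); the comparison encoding."""
    o = count_triads(gs)
    windows = o.sum()
    if windows == 0:
        return np.zeros(N_TRIADS)
    return o / windows


def triad_index(a: int, b: int, c: int) -> int:
    """0-based vector index of triad (a, b, c), groups in 1..7."""
    for g in (a, b, c):
        if not 1 <= g <= N_GROUPS:
            raise ValueError(f"group index {g} outside 1..{N_GROUPS}")
    return (a - 1) * 49 + (b - 1) * 7 + (c - 1)


class SignificanceEncoder:
    """Monte-Carlo estimator of triad significance vectors.

    The null distribution of triad counts depends only on the group
    composition of a sequence, so null count matrices are cached keyed by
    composition and the RNG substream for each protein is derived
    deterministically from (seed, composition).  Encoding order therefore
    never changes results, and two proteins with identical composition
    share one null exactly.
    """

    def __init__(self, n_permutations: int = 10_000, seed: int = 0,
                 cache_size: int = 4):
        if n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        self.n_permutations = int(n_permutations)
        self.seed = int(seed)
        self._cache: OrderedDict[tuple[int, ...], np.ndarray] = OrderedDict()
        self._cache_size = cache_size

    def _null_counts(self, gs: GroupSequence) -> np.ndarray:
        """(n_permutations, 343) triad counts over composition-preserving shuffles."""
        key = gs.composition
        cached = self._cache.get(key)
        if cached is not None:
            self._cache.move_to_end(key)
            return cached
        rng = np.random.default_rng([self.seed, *(int(k) for k in key)])
        n, L = self.n_permutations, len(gs)
        counts = np.zeros((n, N_TRIADS), dtype=np.int32)
        # Shuffle a canonical arrangement of the composition (not the observed
        # order): a uniform shuffle of any fixed arrangement is uniform over
        # arrangements, and this makes the composition-keyed cache exact.
        canonical = np.repeat(np.arange(1, N_GROUPS + 1, dtype=np.int8), key)
        if L >= 3:
            # Chunk rows so the permutation matrix stays small.
            chunk = max(1, min(n, 2_000_000 // L))
            offsets = np.arange(chunk, dtype=np.int64)[:, None] * N_TRIADS
            for start in range(0, n, chunk):
                stop = min(start + chunk, n)
                block = np.tile(canonical, (stop - start, 1))
                block = rng.permuted(block, axis=1)
                codes = _triad_codes(block).astype(np.int64)
                codes += offsets[: stop - start]
                flat = np.bincount(codes.ravel(), minlength=(stop - start) * N_TRIADS)
                counts[start:stop] = flat.reshape(stop - start, N_TRIADS)
        if self._cache_size > 0:
            self._cache[key] = counts
            while len(self._cache) > self._cache_size:
                self._cache.popitem(last=False)
        return counts

    def encode(self, gs: GroupSequence) -> SignificanceVector:
        o = count_triads(gs)
        null = self._null_counts(gs)
        s = (null < o).mean(axis=0)
        return SignificanceVector(
            s=s,
            n_permutations=self.n_permutations,
            seed=self.seed,
            source_id=gs.source_id,
        )


def significance_vector(
    sequence: str,
    n_permutations: int = 10_000,
    seed: int = 0,
    source_id: str = "",
) -> SignificanceVector:
    """Estimate s_i = Pr(X_i < o_i) under composition-preserving shuffles.

    ``X_i`` is the count of triad i in a uniformly random permutation of
    the sequence; the inequality is strict, so any triad with o_i = 0 has
    s_i = 0 and ties count against significance.  Deterministic given
    (sequence, n_permutations, seed).
    """
    gs = map_to_groups(sequence, source_id=source_id)
    return SignificanceEncoder(n_permutations, seed).encode(gs)


def encode_pair(
    protein_a: tuple[str, np.ndarray],
    protein_b: tuple[str, np.ndarray],
) -> PairFeature:
    """Concatenate two per-protein 343-vectors into one 686-dim pair vector.

    The two proteins are first put in lexicographic order by identifier,
    so ``encode_pair(a, b) == encode_pair(b, a)``.
    """
    (id_a, vec_a), (id_b, vec_b) = protein_a, protein_b
    vec_a = np.asarray(vec_a, dtype=float)
    vec_b = np.asarray(vec_b, dtype=float)
    for name, v in ((id_a, vec_a), (id_b, vec_b)):
        if v.shape != (N_TRIADS,):
            raise ValueError(
                f"per-protein vector for {name!r} has shape {v.shape}, "
                f"expected ({N_TRIADS},)"
            )
    if id_b < id_a:
        id_a, id_b = id_b, id_a
        vec_a, vec_b = vec_b, vec_a
    return PairFeature(
        vector=np.concatenate([vec_a, vec_b]), protein_a=id_a, protein_b=id_b
    )


def encode_proteins(
    records: Iterable[tuple[str, str]],
    feature: str = "significance",
    n_permutations: int = 10_000,
    seed: int = 0,
    on_invalid: str = "error",
) -> pd.DataFrame:
    """Encode many proteins into a (protein x 343) feature table.

    ``feature`` is one of ``significance``, ``frequency`` or ``occurrence``.
    ``on_invalid='drop'`` silently skips sequences with non-standard
    residues (logged); ``'error'`` re-raises.
    """
    if feature not in ("significance", "frequency", "occurrence"):
        raise ValueError(f"unknown feature kind {feature!r}")
    if on_invalid not in ("error", "drop"):
        raise ValueError(f"on_invalid must be 'error' or 'drop', got {on_invalid!r}")
    encoder = SignificanceEncoder(n_permutations, seed)
    ids: list[str] = []
    rows: list[np.ndarray] = []
    dropped = 0
    for pid, seq in records:
        try:
            gs = map_to_groups(seq, source_id=pid)
        except InvalidResidueError:
            if on_invalid == "error":
                raise
            dropped += 1
            continue
        if feature == "significance":
            rows.append(encoder.encode(gs).s)
        elif feature == "frequency":
            rows.append(encode_frequency(gs))
        else:
            rows.append(count_triads(gs).astype(float))
        ids.append(pid)
    if dropped:
        logger.info("dropped %d sequence(s) with non-standard residues", dropped)
    return pd.DataFrame(np.array(rows).reshape(len(ids), N_TRIADS),
                        index=pd.Index(ids, name="protein"),
                        columns=TRIAD_LABELS)


def pair_matrix(
    pairs: Sequence[tuple[str, str]],
    features: pd.DataFrame,
) -> np.ndarray:
    """Stack canonical 686-dim pair vectors for a list of protein-id pairs."""
    lut = {pid: np.asarray(row, dtype=float)
           for pid, row in zip(features.index, features.to_numpy())}
    out = np.empty((len(pairs), PAIR_DIM))
    for k, (a, b) in enumerate(pairs):
        if b < a:
            a, b = b, a
        out[k, :N_TRIADS] = lut[a]
        out[k, N_TRIADS:] = lut[b]
    return out
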