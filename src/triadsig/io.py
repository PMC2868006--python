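"""Shared plumbing: FASTA/TSV readers and writers, manifests, seed derivation.

Every source of randomness in the pipeline flows from one top-level seed;
subcommand/substream seeds are derived deterministically with
:func:`derive_seed` and recorded in run manifests.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)


def derive_seed(seed: int, *tokens) -> int:
    """Stable sub-seed (< 2**31) from a master seed and a token path."""
    payload = repr((int(seed),) + tuple(str(t) for t in tokens)).encode()
    digest = hashlib.sha256(payload).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


class FastaError(ValueError):
    """Malformed, empty or duplicate-id FASTA input."""


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a multi-record FASTA file into ordered (id, SEQUENCE) tuples.

    Identifiers are the header token up to the first whitespace; wrapped
    lines are joined and sequences upper-cased.  Empty files and duplicate
    identifiers raise :class:`FastaError`.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaError(f"duplicate FASTA identifier {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq).upper()))
    if not records:
        raise FastaError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path,
                width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for pid, seq in records:
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_pairs(
    path: str | Path,
    known_ids: set[str] | None = None,
    on_unknown: str = "error",
) -> list[tuple[tuple[str, str], list[str]]]:
    """Read a pair TSV into canonical ((id_a, id_b), annotations) entries.

    The first two columns are protein ids (canonicalised so id_a <= id_b,
    self-pairs allowed); remaining columns are kept as annotations.  Blank
    lines are skipped and counted.  When ``known_ids`` is supplied, rows
    referencing unknown proteins either raise or are dropped per
    ``on_unknown`` ('error' | 'drop').
    """
    if on_unknown not in ("error", "drop"):
        raise ValueError("on_unknown must be 'error' or 'drop'")
    path = Path(path)
    out: list[tuple[tuple[str, str], list[str]]] = []
    blanks = dropped = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                blanks += 1
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ValueError(f"{path}:{lineno}: expected at least two "
                                 "tab-separated protein ids")
            a, b = fields[0], fields[1]
            if known_ids is not None and (a not in known_ids or b not in known_ids):
                if on_unknown == "error":
                    missing = a if a not in known_ids else b
                    raise ValueError(f"{path}:{lineno}: unknown protein id "
                                     f"{missing!r}")
                dropped += 1
                continue
            if b < a:
                a, b = b, a
            out.append(((a, b), fields[2:]))
    if blanks:
        logger.info("skipped %d blank line(s) in %s", blanks, path)
    if dropped:
        logger.info("dropped %d pair(s) with unknown protein ids in %s",
                    dropped, path)
    return out


def write_pairs(
    pairs: Iterable[Sequence],
    path: str | Path,
    header: Sequence[str] | None = None,
) -> None:
    """Write rows of (id_a, id_b, ...) as TSV."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        if header:
            writer.writerow(header)
        for row in pairs:
            writer.writerow(row)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with Path(path).open("rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    *,
    command: str,
    config: dict,
    seeds: dict,
    inputs: dict[str, str | Path] | None = None,
    outputs: Sequence[str | Path] = (),
    record_time: bool = False,
) -> dict:
    """Write a JSON run manifest tracing artifacts to their inputs and seeds.

    Input files are recorded with SHA-256 checksums.  Wall-clock time is
    recorded only on request so that reruns with identical inputs produce
    byte-identical manifests.
    """
    from . import __version__

    manifest: dict = {
        "tool": "triadsig",
        "version": __version__,
        "command": command,
        "config": config,
        "seeds": seeds,
        "inputs": {
            name: {"path": str(p), "sha256": sha256_file(p)}
            for name, p in (inputs or {}).items()
        },
        "outputs": [str(p) for p in outputs],
    }
    if record_time:
        manifest["created"] = datetime.now(timezone.utc).isoformat()
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
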