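"""Combinatorial barcode codebook and split-probe record layout.

Each olfactory receptor (OR) transcript is encoded by a constant-weight
binary barcode: a unique set of ``on_bits`` readout bits out of ``n_bits``
imaging rounds (4 of 15 by default).  A soma or molecule is decoded by
matching the set of bits in which it fluoresces against this codebook.

Probe-level metadata follows the split-probe layout: each adjacent probe
pair carries one bit via a 5'/3' split readout pair flanking a 30-32 nt
target region, and each bit is tiled 4-10 times along the transcript.
Nucleotide sequences themselves are out of scope; records store layout
metadata only.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Codebook",
    "ProbeRecord",
    "CodebookCapacityError",
    "ProbeLayoutError",
    "build_codebook",
    "assemble_probe_records",
    "validate_codebook",
    "write_codebook_csv",
    "read_codebook_csv",
    "probe_records_to_frame",
]


class CodebookCapacityError(ValueError):
    """More receptors requested than distinct constant-weight codes exist."""


class ProbeLayoutError(ValueError):
    """A probe record violates the split-probe layout constraints."""


@dataclass(frozen=True)
class Codebook:
    """Mapping from receptor id to its ordered on-bit tuple."""

    n_bits: int = 15
    on_bits: int = 4
    entries: dict[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # malformed codes are rejected here; duplicate codes are representable
        # so that validate_codebook can report them (build_codebook never
        # produces duplicates)
        for rid, code in self.entries.items():
            code = tuple(sorted(int(b) for b in code))
            if len(code) != self.on_bits or len(set(code)) != self.on_bits:
                raise ValueError(
                    f"{rid}: code {code} does not have {self.on_bits} distinct bits"
                )
            if not all(0 <= b < self.n_bits for b in code):
                raise ValueError(f"{rid}: bit index out of range in {code}")
        object.__setattr__(self, "entries", {r: tuple(sorted(c)) for r, c in self.entries.items()})

    @property
    def receptors(self) -> list[str]:
        return list(self.entries)

    def code_of(self, receptor_id: str) -> tuple[int, ...]:
        return self.entries[receptor_id]

    def lookup(self, bits) -> str | None:
        """Exact reverse lookup: bit set -> receptor id, or None."""
        key = tuple(sorted(int(b) for b in bits))
        return self._reverse().get(key)

    def _reverse(self) -> dict[tuple[int, ...], str]:
        # rebuilt lazily; the dataclass is frozen so entries never mutate
        rev = getattr(self, "_rev", None)
        if rev is None:
            rev = {code: rid for rid, code in self.entries.items()}
            object.__setattr__(self, "_rev", rev)
        return rev

    @property
    def capacity(self) -> int:
        return math.comb(self.n_bits, self.on_bits)


@dataclass(frozen=True)
class ProbeRecord:
    """Layout metadata for one adjacent split-probe pair on a transcript.

    ``target_interval`` is half-open, 0-based on the transcript; its length
    must be 30-32 nt.  ``layout_lengths`` records the nt lengths of the
    forward primer, RT primer, 5' split readout, 3' split readout and
    reverse primer segments.
    """

    receptor_id: str
    target_interval: tuple[int, int]
    bit_index: int
    repeat_index: int
    layout_lengths: tuple[int, int, int, int, int] = (20, 20, 15, 15, 20)

    def __post_init__(self) -> None:
        start, end = self.target_interval
        if not 30 <= end - start <= 32:
            raise ProbeLayoutError(
                f"target interval [{start}, {end}) has length {end - start}, not in [30, 32]"
            )
        if not 1 <= self.repeat_index <= 10:
            raise ProbeLayoutError(f"repeat index {self.repeat_index} outside [1, 10]")
        fwd, rt, split5, split3, rev = self.layout_lengths
        if not (fwd in (19, 20) and rt == 20 and split5 == 15 and split3 == 15 and rev in (19, 20)):
            raise ProbeLayoutError(f"layout lengths {self.layout_lengths} violate the split-probe design")


def build_codebook(
    receptor_ids: list[str],
    n_bits: int = 15,
    on_bits: int = 4,
    seed: int = 0,
    n_blank: int = 0,
) -> Codebook:
    """Assign a unique constant-weight code to every receptor.

    Codes are the lexicographic enumeration of ``on_bits``-subsets of
    ``range(n_bits)``, shuffled by ``seed``, then assigned to receptors in
    input order.  ``n_blank`` extra codes may be reserved (receptor ids
    ``blank_0`` ...) for error-rate estimation; none are reserved by default.

    Raises
    ------
    CodebookCapacityError
        If more codes are requested than C(n_bits, on_bits).
    """
    receptor_ids = list(receptor_ids)
    if len(set(receptor_ids)) != len(receptor_ids):
        raise ValueError("receptor ids must be unique")
    blanks = [f"blank_{i}" for i in range(n_blank)]
    capacity = math.comb(n_bits, on_bits)
    needed = len(receptor_ids) + len(blanks)
    if needed > capacity:
        raise CodebookCapacityError(
            f"{needed} codes requested but only C({n_bits},{on_bits}) = {capacity} exist"
        )
    codes = list(itertools.combinations(range(n_bits), on_bits))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(codes))
    entries = {
        rid: codes[order[i]] for i, rid in enumerate(receptor_ids + blanks)
    }
    return Codebook(n_bits=n_bits, on_bits=on_bits, entries=entries)


def assemble_probe_records(
    codebook: Codebook,
    target_intervals: dict[str, list[tuple[int, int]]],
    repeats_per_bit: int = 4,
) -> list[ProbeRecord]:
    """Lay out one ProbeRecord per (receptor, bit, repeat).

    ``target_intervals`` maps receptor id to a list of non-overlapping
    half-open transcript intervals, consumed in order; it must supply at
    least ``on_bits * repeats_per_bit`` intervals per receptor.
    """
    if not 4 <= repeats_per_bit <= 10:
        raise ProbeLayoutError(f"repeats_per_bit {repeats_per_bit} outside [4, 10]")
    records: list[ProbeRecord] = []
    for rid, code in codebook.entries.items():
        intervals = list(target_intervals[rid])
        need = len(code) * repeats_per_bit
        if len(intervals) < need:
            raise ProbeLayoutError(f"{rid}: {len(intervals)} intervals supplied, {need} needed")
        ordered = sorted(intervals)
        for a, b in zip(ordered, ordered[1:]):
            if a[1] > b[0]:
                raise ProbeLayoutError(f"{rid}: overlapping intervals {a} and {b}")
        it = iter(intervals)
        for bit in code:
            for rep in range(1, repeats_per_bit + 1):
                records.append(
                    ProbeRecord(
                        receptor_id=rid,
                        target_interval=tuple(next(it)),
                        bit_index=int(bit),
                        repeat_index=rep,
                    )
                )
    return records


def validate_codebook(codebook: Codebook) -> dict:
    """Report duplicate codes and the minimum pairwise Hamming distance."""
    rids = codebook.receptors
    mat = np.zeros((len(rids), codebook.n_bits), dtype=bool)
    for i, rid in enumerate(rids):
        mat[i, list(codebook.entries[rid])] = True
    duplicates: list[tuple[str, str]] = []
    min_dist = None
    if len(rids) >= 2:
        # pairwise Hamming via boolean dot products
        on = mat.astype(np.int32)
        shared = on @ on.T
        dist = 2 * (codebook.on_bits - shared)
        iu = np.triu_indices(len(rids), k=1)
        min_dist = int(dist[iu].min())
        for i, j in zip(*np.where(dist == 0)):
            if i < j:
                duplicates.append((rids[i], rids[j]))
    return {
        "n_codes": len(rids),
        "duplicates": duplicates,
        "min_hamming_distance": min_dist,
        "valid": not duplicates,
    }


def write_codebook_csv(codebook: Codebook, path) -> None:
    rows = [
        {"receptor_id": rid, **{f"bit_{k}": b for k, b in enumerate(code)}}
        for rid, code in codebook.entries.items()
    ]
    frame = pd.DataFrame(rows)
    frame.attrs["n_bits"] = codebook.n_bits
    frame.to_csv(path, index=False)


def read_codebook_csv(path, n_bits: int = 15) -> Codebook:
    frame = pd.read_csv(path)
    bit_cols = sorted(c for c in frame.columns if c.startswith("bit_"))
    entries = {
        str(row["receptor_id"]): tuple(int(row[c]) for c in bit_cols)
        for _, row in frame.iterrows()
    }
    return Codebook(n_bits=n_bits, on_bits=len(bit_cols), entries=entries)


def probe_records_to_frame(records: list[ProbeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "receptor_id": [r.receptor_id for r in records],
            "target_start": [r.target_interval[0] for r in records],
            "target_end": [r.target_interval[1] for r in records],
            "bit_index": [r.bit_index for r in records],
            "repeat_index": [r.repeat_index for r in records],
        }
    )
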