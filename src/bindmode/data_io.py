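"""Reading, filtering and writing of count tables, reads and model states.

The only experimental observable in a selection campaign is a table of
sequencing read counts per variant per dataset.  This module owns that table
(:class:`CountTable`), the extraction of the variable CDR region from raw
nucleotide reads (with the two filters applied to the data: exact flank match
and stop-codon removal), and serialization of fitted model states.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable

from .space import SequenceSpace, SpaceError

STATE_FORMAT = "bindmode-model-state"
STATE_VERSION = 1


class CountTableError(ValueError):
    """Raised on malformed count-table input."""


class ModelStateIOError(ValueError):
    """Raised on malformed, truncated or incompatible model-state files."""


@dataclass
class CountTable:
    """Integer read counts per sequence for one sequencing dataset.

    ``counts`` maps sequence strings to non-negative integer read counts.  If a
    :class:`SequenceSpace` is attached, every key is validated against it and
    the table can be densified into the space's enumeration order; sequences
    absent from the mapping have count 0 (they are not "missing" — the model
    distinguishes absent from unobserved only through inferred abundances).
    """

    dataset_id: str
    counts: dict[str, int]
    space: SequenceSpace | None = None

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for seq, c in self.counts.items():
            if isinstance(c, float) and not float(c).is_integer():
                raise CountTableError(
                    f"{self.dataset_id}: non-integer count {c!r} for {seq!r}"
                )
            c = int(c)
            if c < 0:
                raise CountTableError(
                    f"{self.dataset_id}: negative count {c} for {seq!r}"
                )
            if self.space is not None and not self.space.contains(seq):
                raise CountTableError(
                    f"{self.dataset_id}: sequence {seq!r} not in the attached "
                    f"space (length {self.space.length})"
                )
            clean[seq] = clean.get(seq, 0) + c
        self.counts = clean

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    def count(self, sequence: str) -> int:
        return self.counts.get(sequence, 0)

    def dense(self, space: SequenceSpace | None = None) -> np.ndarray:
        """Count vector in the enumeration order of ``space``."""
        space = space or self.space
        if space is None:
            raise CountTableError("dense() needs a SequenceSpace")
        v = np.zeros(space.size, dtype=np.int64)
        for seq, c in self.counts.items():
            v[space.index(seq)] = c
        return v

    @classmethod
    def from_dense(
        cls, dataset_id: str, vector: np.ndarray, space: SequenceSpace
    ) -> "CountTable":
        vector = np.asarray(vector)
        nz = np.nonzero(vector)[0]
        return cls(
            dataset_id,
            {space.sequence(int(i)): int(vector[i]) for i in nz},
            space=space,
        )


def read_count_table(
    path, dataset_id: str | None = None, space: SequenceSpace | None = None
) -> CountTable:
    """Read a two-column (sequence, count) delimited text file.

    Tab, comma or whitespace delimited; a header line is detected by a
    non-integer second field.  Duplicate sequence rows are summed.
    """
    path = Path(path)
    counts: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.replace(",", "\t").split()
            if len(parts) != 2:
                raise CountTableError(
                    f"{path}:{lineno}: expected 2 columns, got {len(parts)}"
                )
            seq, raw = parts
            try:
                c = int(raw)
            except ValueError:
                if lineno == 1:  # header
                    continue
                raise CountTableError(
                    f"{path}:{lineno}: non-integer count {raw!r}"
                ) from None
            if c < 0:
                raise CountTableError(f"{path}:{lineno}: negative count {c}")
            counts[seq] = counts.get(seq, 0) + c
    try:
        return CountTable(dataset_id or path.stem, counts, space=space)
    except CountTableError as e:
        raise CountTableError(f"{path}: {e}") from None


def write_count_table(table: CountTable, path) -> None:
    """Write the canonical tab-separated (sequence, count) format."""
    with open(path, "w") as fh:
        fh.write("sequence\tcount\n")
        for seq in sorted(table.counts):
            fh.write(f"{seq}\t{table.counts[seq]}\n")


# ---------------------------------------------------------------------------
# Raw-read extraction
# ---------------------------------------------------------------------------

def _standard_codon_map() -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[1]
    m = dict(table.forward_table)
    for codon in table.stop_codons:
        m[codon] = "*"
    return m


@dataclass(frozen=True)
class ReadExtractionSpec:
    """How to locate and translate the variable CDR region in raw reads.

    The variable region sits between two constant flanks; reads whose flanks
    deviate from the designed framework by even one base are filtered out, as
    are variable regions containing stop codons.
    """

    upstream_flank: str
    downstream_flank: str
    variable_length_nt: int = 12
    genetic_code: dict[str, str] = field(default_factory=_standard_codon_map)

    def __post_init__(self) -> None:
        for name, flank in (
            ("upstream_flank", self.upstream_flank),
            ("downstream_flank", self.downstream_flank),
        ):
            if not flank or set(flank) - set("ACGT"):
                raise ValueError(f"{name} must be non-empty and ACGT-only")
        if self.variable_length_nt % 3 != 0 or self.variable_length_nt <= 0:
            raise ValueError("variable_length_nt must be a positive multiple of 3")


@dataclass
class ExtractionReport:
    """Per-category read tally; categories partition the input reads."""

    accepted: int = 0
    flank_mismatch: int = 0
    stop_codon: int = 0
    ambiguous_base: int = 0
    too_short: int = 0

    @property
    def total(self) -> int:
        return (
            self.accepted
            + self.flank_mismatch
            + self.stop_codon
            + self.ambiguous_base
            + self.too_short
        )


def extract_and_translate(
    reads,
    spec: ReadExtractionSpec,
    dataset_id: str = "reads",
    space: SequenceSpace | None = None,
) -> tuple[CountTable, CountTable, ExtractionReport]:
    """Extract, filter and translate the variable region of raw reads.

    Returns the amino-acid-keyed table, the codon-level (nucleotide-keyed)
    table, and a rejection report.  Filters, in order: reads too short to hold
    flanks plus variable region; flanks not matching the designed framework
    exactly; ambiguous bases (N etc.) in the variable region; stop codons in
    the translated variable region.  Amino-acid counts are by construction the
    sums of their synonymous codon-level counts.
    """
    up, down, k = spec.upstream_flank, spec.downstream_flank, spec.variable_length_nt
    report = ExtractionReport()
    aa_counts: dict[str, int] = {}
    nt_counts: dict[str, int] = {}
    min_len = len(up) + k + len(down)
    for read in reads:
        read = str(read).upper()
        if len(read) < min_len:
            report.too_short += 1
            continue
        region = None
        start = read.find(up)
        while start != -1:
            v0 = start + len(up)
            candidate = read[v0 : v0 + k]
            if len(candidate) == k and read[v0 + k : v0 + k + len(down)] == down:
                region = candidate
                break
            start = read.find(up, start + 1)
        if region is None:
            report.flank_mismatch += 1
            continue
        if set(region) - set("ACGT"):
            report.ambiguous_base += 1
            continue
        codons = [region[i : i + 3] for i in range(0, k, 3)]
        aas = [spec.genetic_code[c] for c in codons]
        if "*" in aas:
            report.stop_codon += 1
            continue
        aa = "".join(aas)
        report.accepted += 1
        aa_counts[aa] = aa_counts.get(aa, 0) + 1
        nt_counts[region] = nt_counts.get(region, 0) + 1
    aa_table = CountTable(dataset_id, aa_counts, space=space)
    nt_table = CountTable(f"{dataset_id}.codon", nt_counts)
    return aa_table, nt_table, report


def read_fastq(path) -> list[str]:
    """Sequences of a FASTQ file (qualities ignored)."""
    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")]


# ---------------------------------------------------------------------------
# Model-state serialization
# ---------------------------------------------------------------------------

def save_model_state(state, path) -> None:
    """Write a fitted model state as a single versioned JSON text file.

    Refuses to serialize non-finite parameters: a NaN/inf in a saved state is
    always a training failure and should surface at save time, not at reload.
    """
    payload = state.to_dict()
    _assert_finite(payload, where="model state")
    payload = {"format": STATE_FORMAT, "version": STATE_VERSION, **payload}
    with open(path, "w") as fh:
        json.dump(payload, fh)
        fh.write("\n")


def load_model_state(path):
    from .inference import ModelState  # deferred: data_io must not cycle

    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as e:
        raise ModelStateIOError(f"{path}: truncated or invalid state file ({e})")
    if payload.get("format") != STATE_FORMAT:
        raise ModelStateIOError(f"{path}: not a {STATE_FORMAT} file")
    if payload.get("version") != STATE_VERSION:
        raise ModelStateIOError(
            f"{path}: unsupported state version {payload.get('version')!r}"
        )
    return ModelState.from_dict(payload)


def _assert_finite(obj, where: str) -> None:
    if isinstance(obj, dict):
        for v in obj.values():
            _assert_finite(v, where)
    elif isinstance(obj, (list, tuple)):
        for v in obj:
            _assert_finite(v, where)
    elif isinstance(obj, float) and not math.isfinite(obj):
        raise ModelStateIOError(f"non-finite value in {where}; refusing to save")
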