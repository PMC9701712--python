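"""Reading, validating and writing DNA sequences for 81-bp promoter windows.

Two input dialects are accepted: FASTA (multi-line bodies allowed, parsed via
Biopython) and a plain-text "single line" dialect with one sequence per line.
Sequences are uppercased, RNA ``U`` is mapped to ``T``, and anything outside
the four-letter DNA alphabet is rejected — the downstream feature formulas are
defined only on {A, C, G, T}, so ambiguity codes are an error, not something
to impute.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

from Bio import SeqIO as _BioSeqIO

#: Length convention of the classifier: every training window is 81 bp,
#: spanning positions -60..+20 around the transcription start site.
WINDOW_LEN = 81

_VALID = frozenset("ACGT")
_NORMALIZE = str.maketrans("acgtuU", "ACGTTT")


@dataclass
class NucleotideSequence:
    """A validated DNA sequence with an identifier.

    ``origin_length`` records the length before any padding or truncation so
    that outputs can report what was actually submitted.
    """

    id: str
    seq: str
    origin_length: int = field(default=0)

    def __post_init__(self) -> None:
        if self.origin_length == 0:
            self.origin_length = len(self.seq)

    def __len__(self) -> int:
        return len(self.seq)


class SequenceError(ValueError):
    """Raised for malformed or invalid sequence input."""


def _validate(raw: str, rec_id: str) -> str:
    seq = raw.translate(_NORMALIZE)
    for i, ch in enumerate(seq):
        if ch not in _VALID:
            raise SequenceError(
                f"invalid residue {raw[i]!r} in record {rec_id} at position {i + 1}"
            )
    return seq


def _as_text(path_or_text: str | os.PathLike) -> str:
    """Return file contents if the argument names an existing file, else the
    argument itself as text."""
    p = os.fspath(path_or_text)
    if "\n" not in p and os.path.exists(p):
        with open(p) as fh:
            return fh.read()
    return p


def read_sequences(
    path_or_text: str | os.PathLike, dialect: str = "auto"
) -> list[NucleotideSequence]:
    """Read DNA sequences from a path or a literal text block.

    Parameters
    ----------
    path_or_text:
        A file path, or the raw text itself.
    dialect:
        ``"fasta"``, ``"single_line"`` (one sequence per line, blank lines
        skipped, ids auto-generated as ``seq_<k>`` in file order), or
        ``"auto"`` which resolves to FASTA iff the first non-blank character
        is ``>``.

    Input order is preserved; lowercase is uppercased and ``U`` becomes ``T``.
    """
    text = _as_text(path_or_text)
    stripped = text.strip()
    if not stripped:
        raise SequenceError("no sequences in input")

    if dialect == "auto":
        dialect = "fasta" if stripped[0] == ">" else "single_line"

    records: list[NucleotideSequence] = []
    if dialect == "fasta":
        for rec in _BioSeqIO.parse(io.StringIO(text.lstrip()), "fasta"):
            records.append(NucleotideSequence(rec.id, _validate(str(rec.seq), rec.id)))
    elif dialect == "single_line":
        k = 0
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            k += 1
            rid = f"seq_{k}"
            records.append(NucleotideSequence(rid, _validate(line, rid)))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if not records:
        raise SequenceError("no sequences in input")
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise SequenceError(f"duplicate sequence id {r.id!r} in input batch")
        seen.add(r.id)
    return records


def write_fasta(records: list[NucleotideSequence], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n{r.seq}\n")


def normalize_length(
    s: NucleotideSequence, target: int = WINDOW_LEN
) -> NucleotideSequence:
    """Pad (with 3'-appended ``A``) or truncate (keep the first ``target``
    bases) a sequence to exactly ``target`` nucleotides.

    The classifier only accepts fixed 81-bp windows; submissions shorter than
    the window are extended with dummy ``A`` characters and longer ones keep
    only their first 81 nucleotides. Appending at the 3' end keeps the
    upstream -35/-10 region — where most of the promoter signal lives —
    intact. Idempotent when the input is already at the target length.
    """
    if target < 1:
        raise ValueError("target length must be >= 1")
    seq = s.seq
    if len(seq) < target:
        seq = seq + "A" * (target - len(seq))
    elif len(seq) > target:
        seq = seq[:target]
    return NucleotideSequence(s.id, seq, origin_length=s.origin_length)


def write_predictions(records, path: str | os.PathLike) -> None:
    """Write prediction records to CSV (header + one row per record).

    Scores are printed with 3 decimals. ``start``/``end`` columns (1-based,
    inclusive) appear when any record carries coordinates; a ``mutation``
    column appears when any record carries a mutation descriptor.
    """
    records = list(records)
    if not records:
        raise ValueError("no prediction records to write")
    has_coords = any(getattr(r, "start", None) is not None for r in records)
    has_mut = any(getattr(r, "mutation", None) is not None for r in records)
    header = ["id", "score", "label", "threshold"]
    if has_coords:
        header += ["start", "end"]
    if has_mut:
        header.append("mutation")
    with open(path, "w") as fh:
        fh.write(",".join(header) + "\n")
        for r in records:
            row = [r.id, f"{r.score:.3f}", r.label, f"{r.threshold:g}"]
            if has_coords:
                row += [
                    "" if getattr(r, "start", None) is None else str(r.start),
                    "" if getattr(r, "end", None) is None else str(r.end),
                ]
            if has_mut:
                row.append(getattr(r, "mutation", None) or "")
            fh.write(",".join(row) + "\n")
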