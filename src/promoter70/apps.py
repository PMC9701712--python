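"""The three user-facing application modes of a trained promoter model.

``predict`` classifies submitted sequences (padding/truncating to the 81-bp
window), ``scan`` slides the window over a longer sequence at stride 1 to
locate promoter regions in a genome, and ``design_mutants`` performs in-silico
saturation mutagenesis — every single-position substitution of an 81-mer —
to find minimum edits that flip the predicted class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoders import BASES, encode_all
from .pipeline import TrainedModel
from .seqio import WINDOW_LEN, NucleotideSequence, normalize_length

POSITIVE_LABEL = "sigma70 promoter"
NEGATIVE_LABEL = "non-promoter"


@dataclass
class PredictionRecord:
    """One scored sequence/window/mutant.

    ``start``/``end`` are 1-based inclusive window coordinates (scan mode);
    ``mutation`` is a descriptor like ``pos17A->G`` (design mode).
    """

    id: str
    score: float
    label: str
    threshold: float
    start: int | None = None
    end: int | None = None
    mutation: str | None = None


def _label(score: float, threshold: float) -> str:
    return POSITIVE_LABEL if score >= threshold else NEGATIVE_LABEL


def _check_threshold(threshold: float) -> None:
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")


def predict(
    seqs: list[NucleotideSequence],
    model: TrainedModel,
    threshold: float | None = None,
) -> list[PredictionRecord]:
    """Score sequences and label each as promoter / non-promoter.

    Sequences are first normalized to the 81-bp window (3' ``A`` padding for
    short inputs, first-81 truncation for long ones), then encoded with the
    model's configuration and PSTNP table, scaled, subset to the selected
    features and scored. Input order is preserved.
    """
    t = model.default_threshold if threshold is None else threshold
    _check_threshold(t)
    windows = [normalize_length(s, WINDOW_LEN) for s in seqs]
    scores = model.score_sequences(windows)
    return [
        PredictionRecord(s.id, float(sc), _label(float(sc), t), t)
        for s, sc in zip(seqs, scores)
    ]


def scan(
    s: NucleotideSequence,
    model: TrainedModel,
    threshold: float | None = None,
    revcomp: bool = False,
) -> list[PredictionRecord]:
    """Score every overlapping 81-bp window of a longer sequence.

    Windows start at positions 1, 2, ..., L-80 (1-based, stride 1) and are
    never padded. With ``revcomp=True`` the reverse complement is scanned as
    well, its records carrying ids suffixed ``|rc`` with coordinates on the
    forward strand.
    """
    t = model.default_threshold if threshold is None else threshold
    _check_threshold(t)
    L = len(s.seq)
    if L < WINDOW_LEN:
        raise ValueError(f"sequence {s.id} shorter than window ({L} < {WINDOW_LEN})")

    def strand_records(seq: str, rc: bool) -> list[PredictionRecord]:
        windows = [
            NucleotideSequence(f"{s.id}|{i + 1}", seq[i : i + WINDOW_LEN])
            for i in range(L - WINDOW_LEN + 1)
        ]
        scores = model.score_sequences(windows)
        recs = []
        for i, sc in enumerate(scores):
            if rc:
                start, end = L - WINDOW_LEN - i + 1, L - i
                rid = f"{s.id}|rc|{start}"
            else:
                start, end = i + 1, i + WINDOW_LEN
                rid = f"{s.id}|{start}"
            recs.append(
                PredictionRecord(rid, float(sc), _label(float(sc), t), t, start, end)
            )
        return recs

    records = strand_records(s.seq, rc=False)
    if revcomp:
        comp = str.maketrans("ACGT", "TGCA")
        records += strand_records(s.seq.translate(comp)[::-1], rc=True)
    return records


def design_mutants(
    s: NucleotideSequence,
    model: TrainedModel,
    threshold: float | None = None,
) -> list[PredictionRecord]:
    """Saturation mutagenesis: the original 81-mer plus all 243 single-position
    substitutions, scored and labeled.

    Enumeration is position-major with alternative bases in alphabetical
    order, so the output order is deterministic. Record 0 is always the
    original.
    """
    t = model.default_threshold if threshold is None else threshold
    _check_threshold(t)
    if len(s.seq) != WINDOW_LEN:
        raise ValueError(
            f"design requires a {WINDOW_LEN}-bp sequence; {s.id} has {len(s.seq)}"
        )
    variants = [NucleotideSequence(s.id, s.seq)]
    descriptors: list[str | None] = [None]
    for i in range(WINDOW_LEN):
        ref = s.seq[i]
        for alt in BASES:
            if alt == ref:
                continue
            mutated = s.seq[:i] + alt + s.seq[i + 1 :]
            desc = f"pos{i + 1}{ref}->{alt}"
            variants.append(NucleotideSequence(f"{s.id}|{desc}", mutated))
            descriptors.append(desc)
    scores = model.score_sequences(variants)
    return [
        PredictionRecord(v.id, float(sc), _label(float(sc), t), t, mutation=d)
        for v, sc, d in zip(variants, scores, descriptors)
    ]


def flip_set(records: list[PredictionRecord]) -> list[PredictionRecord]:
    """Mutants whose predicted label differs from the original's.

    Each element is a single-substitution conversion, i.e. a minimum edit
    (Hamming distance 1) that flips the call. The original record (the one
    without a mutation descriptor) is never included.
    """
    original = next((r for r in records if r.mutation is None), None)
    if original is None:
        raise ValueError("records must include the unmutated original")
    return [r for r in records if r.mutation is not None and r.label != original.label]


def to_bed(records: list[PredictionRecord], chrom: str | None = None) -> str:
    """Render scan records as BED lines (0-based half-open) with the score in
    column 5; promoter calls only."""
    lines = []
    for r in records:
        if r.start is None or r.label != POSITIVE_LABEL:
            continue
        name = chrom or r.id.split("|")[0]
        lines.append(f"{name}\t{r.start - 1}\t{r.end}\t{r.id}\t{r.score:.3f}")
    return "\n".join(lines) + ("\n" if lines else "")
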