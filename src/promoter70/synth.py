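"""Synthetic labeled promoter / non-promoter datasets.

Positives emulate 81-bp windows spanning -60..+20 around a transcription
start site: a TATAAT (-10, Pribnow) box and a TTGACA (-35) box separated by a
variable spacer are planted on an A/T-rich background, with a small per-base
chance of a box letter being randomized (real promoters deviate from the
consensus). Negatives are i.i.d. coding-like background with a lower A+T
fraction and no planted boxes. The generator gives every pipeline stage a
dataset with the structural signal the method assumes, without any download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqio import WINDOW_LEN, NucleotideSequence, write_fasta

BASES = "ACGT"


@dataclass
class SynthConfig:
    """Study conditions for the generator.

    ``tss_index`` is the 1-based window position representing +1, so the
    window spans -60..+20. The -10 box is anchored at window indices
    ``box10_end - 5 .. box10_end`` (default 49-54, i.e. offsets -12..-7) and
    the -35 box sits immediately upstream across the sampled spacer.
    """

    n_pos: int = 300
    n_neg: int = 300
    seed: int = 0
    window: int = WINDOW_LEN
    tss_index: int = 61
    box35: str = "TTGACA"
    box10: str = "TATAAT"
    box10_end: int = 54
    spacer_range: tuple[int, int] = (15, 19)
    box_mut_rate: float = 0.1
    bg_at_fraction_pos: float = 0.6
    bg_at_fraction_neg: float = 0.48

    def __post_init__(self) -> None:
        if not 0.0 <= self.box_mut_rate <= 1.0:
            raise ValueError("box_mut_rate must be in [0, 1]")
        for p in (self.bg_at_fraction_pos, self.bg_at_fraction_neg):
            if not 0.0 <= p <= 1.0:
                raise ValueError("background A+T fractions must be in [0, 1]")
        # boxes plus the maximal spacer must fit upstream of the TSS
        min_start = self.box10_end - len(self.box10) + 1 - max(self.spacer_range) - len(
            self.box35
        )
        if min_start < 1:
            raise ValueError("boxes + maximal spacer do not fit in the window")
        if self.box10_end > self.tss_index:
            raise ValueError("-10 box must lie upstream of the TSS")

    def box_positions(self, spacer: int) -> tuple[int, int]:
        """1-based start indices (box35_start, box10_start) for a spacer."""
        box10_start = self.box10_end - len(self.box10) + 1
        box35_start = box10_start - spacer - len(self.box35)
        return box35_start, box10_start


def _background_probs(at_fraction: float) -> np.ndarray:
    # A and T split the A+T mass equally; likewise C and G
    at = at_fraction / 2.0
    gc = (1.0 - at_fraction) / 2.0
    return np.array([at, gc, gc, at])  # order A, C, G, T


def _draw_background(n: int, at_fraction: float, rng: np.random.Generator) -> list[str]:
    codes = rng.choice(4, size=n, p=_background_probs(at_fraction))
    return [BASES[c] for c in codes]


def make_positive(cfg: SynthConfig, rng: np.random.Generator) -> NucleotideSequence:
    """One synthetic promoter window: AT-rich background with the two
    consensus boxes planted across a uniformly sampled spacer; each box base
    is randomized (uniformly over A/C/G/T) with probability ``box_mut_rate``."""
    chars = _draw_background(cfg.window, cfg.bg_at_fraction_pos, rng)
    spacer = int(rng.integers(cfg.spacer_range[0], cfg.spacer_range[1] + 1))
    b35, b10 = cfg.box_positions(spacer)
    for start, box in ((b35, cfg.box35), (b10, cfg.box10)):
        for j, base in enumerate(box):
            if rng.random() < cfg.box_mut_rate:
                base = BASES[rng.integers(4)]
            chars[start - 1 + j] = base
    return NucleotideSequence("pos", "".join(chars))


def make_negative(cfg: SynthConfig, rng: np.random.Generator) -> NucleotideSequence:
    """One non-promoter window: i.i.d. coding-like background, no boxes."""
    return NucleotideSequence(
        "neg", "".join(_draw_background(cfg.window, cfg.bg_at_fraction_neg, rng))
    )


def make_dataset(
    cfg: SynthConfig, outdir=None
) -> tuple[list[NucleotideSequence], list[NucleotideSequence], pd.DataFrame]:
    """Generate the full labeled dataset, deterministically under the seed.

    Returns (positives, negatives, label table); when ``outdir`` is given,
    writes ``positives.fasta``, ``negatives.fasta`` and ``labels.csv`` there.
    """
    rng = np.random.default_rng(cfg.seed)
    pos = []
    for i in range(cfg.n_pos):
        s = make_positive(cfg, rng)
        pos.append(NucleotideSequence(f"pos_{i + 1}", s.seq))
    neg = []
    for i in range(cfg.n_neg):
        s = make_negative(cfg, rng)
        neg.append(NucleotideSequence(f"neg_{i + 1}", s.seq))
    labels = pd.DataFrame(
        {
            "id": [s.id for s in pos] + [s.id for s in neg],
            "label": [1] * cfg.n_pos + [0] * cfg.n_neg,
        }
    )
    if outdir is not None:
        import os

        os.makedirs(outdir, exist_ok=True)
        write_fasta(pos, os.path.join(outdir, "positives.fasta"))
        write_fasta(neg, os.path.join(outdir, "negatives.fasta"))
        labels.to_csv(os.path.join(outdir, "labels.csv"), index=False)
    return pos, neg, labels


def make_genome(
    cfg: SynthConfig,
    rng: np.random.Generator,
    length: int = 500,
    promoter_start: int = 200,
) -> tuple[NucleotideSequence, int]:
    """A synthetic genome fragment: negative-style background with one
    promoter window planted at a known offset (1-based start).

    Returns (sequence, promoter_start) for scan-localization experiments.
    """
    if promoter_start < 1 or promoter_start + cfg.window - 1 > length:
        raise ValueError("promoter window does not fit in the genome fragment")
    chars = _draw_background(length, cfg.bg_at_fraction_neg, rng)
    promoter = make_positive(cfg, rng)
    chars[promoter_start - 1 : promoter_start - 1 + cfg.window] = list(promoter.seq)
    return NucleotideSequence("synthetic_genome", "".join(chars)), promoter_start
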