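"""Nucleotide feature encoders for fixed-length promoter windows.

Implements the feature families used by the classifier as pure functions of
(sequence, config): mono/di/trinucleotide composition, GC/AT skew, trinucleotide
electron-ion interaction pseudopotentials (EIIP), dinucleotide auto-/cross-
correlation of physicochemical property series (DAC/DCC/DACC), Moran and
normalized Moreau-Broto autocorrelation (MAC/NMBAC), parallel-correlation
pseudo trinucleotide composition (PC-PseTNC), exact motif counts, and the one
data-dependent encoder: the position-specific trinucleotide propensity (PSTNP)
table learned from labeled training sequences.

Physicochemical property tables ship as editable TSVs under ``data/``; each
property column is standardized to mean 0 / sd 1 across its 16 (or 64) words
before use, as is conventional for pseudo-composition encodings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from itertools import product

import numpy as np

from .seqio import WINDOW_LEN, NucleotideSequence

BASES = "ACGT"
DINUCS = ["".join(p) for p in product(BASES, repeat=2)]
TRINUCS = ["".join(p) for p in product(BASES, repeat=3)]

#: Electron-ion interaction pseudopotentials per nucleotide (Ry), the standard
#: published constants.
EIIP = {"A": 0.1260, "C": 0.1340, "G": 0.0806, "T": 0.1335}

_CODE = np.full(128, -1, dtype=np.int64)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i


def _codes(seq: str) -> np.ndarray:
    """Map a validated A/C/G/T string to integer codes 0..3."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _di_codes(codes: np.ndarray) -> np.ndarray:
    return codes[:-1] * 4 + codes[1:]


def _tri_codes(codes: np.ndarray) -> np.ndarray:
    return codes[:-2] * 16 + codes[1:-1] * 4 + codes[2:]


def _standardize_columns(values: np.ndarray) -> np.ndarray:
    """Standardize each property row to mean 0 / sd 1 across its words."""
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (values - mu) / sd


def _load_property_table(filename: str, words: list[str]):
    """Read a word->properties TSV shipped with the package."""
    text = resources.files("promoter70.data").joinpath(filename).read_text()
    lines = [ln.split("\t") for ln in text.strip().splitlines()]
    names = lines[0][1:]
    table = {row[0]: [float(v) for v in row[1:]] for row in lines[1:]}
    missing = [w for w in words if w not in table]
    if missing:
        raise ValueError(f"property table {filename} missing words: {missing}")
    values = np.array([table[w] for w in words]).T  # (n_props, n_words)
    return names, values


def load_dinucleotide_properties():
    return _load_property_table("dinucleotide_properties.tsv", DINUCS)


def load_trinucleotide_properties():
    return _load_property_table("trinucleotide_properties.tsv", TRINUCS)


@dataclass
class EncoderConfig:
    """Tunable knobs of the feature encoders.

    Parameters
    ----------
    lag_max:
        Maximum spacing ``d`` for the autocorrelation families.
    pse_lambda, pse_weight:
        Number of sequence-order correlation factors and their weight ``w``
        in PC-PseTNC.
    motifs:
        Exact-match motif strings counted on the given strand; defaults to
        the two sigma70 consensus boxes.
    di_prop_names / di_props, tri_prop_names / tri_props:
        Physicochemical property tables, one row per index, standardized to
        mean 0 / sd 1 across the 16 (64) words. Default: the six helical
        parameters Twist, Tilt, Roll, Shift, Slide, Rise and the
        DNase-bendability + nucleosome-positioning triplet scales.
    """

    lag_max: int = 2
    pse_lambda: int = 2
    pse_weight: float = 0.05
    motifs: tuple[str, ...] = ("TATAAT", "TTGACA")
    eiip: dict = field(default_factory=lambda: dict(EIIP))
    di_prop_names: list[str] = None
    di_props: np.ndarray = None
    tri_prop_names: list[str] = None
    tri_props: np.ndarray = None

    def __post_init__(self) -> None:
        if self.di_props is None:
            self.di_prop_names, raw = load_dinucleotide_properties()
            self.di_props = _standardize_columns(raw)
        if self.tri_props is None:
            self.tri_prop_names, raw = load_trinucleotide_properties()
            self.tri_props = _standardize_columns(raw)
        if self.lag_max < 1 or self.lag_max > WINDOW_LEN - 2:
            raise ValueError("lag_max must be in [1, WINDOW_LEN - 2]")
        if self.pse_lambda < 0 or self.pse_lambda > WINDOW_LEN - 3:
            raise ValueError("pse_lambda must be in [0, WINDOW_LEN - 3]")
        if not 0.0 <= self.pse_weight <= 1.0:
            raise ValueError("pse_weight must be in [0, 1]")
        if self.di_props.shape[1] != 16 or self.tri_props.shape[1] != 64:
            raise ValueError("property tables must cover all 16/64 words")

    # -- flat key/value serialization of the scalar knobs ------------------
    def to_dict(self) -> dict:
        return {
            "lag_max": self.lag_max,
            "pse_lambda": self.pse_lambda,
            "pse_weight": self.pse_weight,
            "motifs": ",".join(self.motifs),
            **{f"eiip_{b}": self.eiip[b] for b in BASES},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EncoderConfig":
        kw = {}
        if "lag_max" in d:
            kw["lag_max"] = int(d["lag_max"])
        if "pse_lambda" in d:
            kw["pse_lambda"] = int(d["pse_lambda"])
        if "pse_weight" in d:
            kw["pse_weight"] = float(d["pse_weight"])
        if "motifs" in d:
            m = d["motifs"]
            kw["motifs"] = tuple(m.split(",")) if isinstance(m, str) else tuple(m)
        eiip = {b: float(d.get(f"eiip_{b}", EIIP[b])) for b in BASES}
        kw["eiip"] = eiip
        return cls(**kw)

    @property
    def theta_lookup(self) -> np.ndarray:
        """64x64 matrix of squared-difference correlation Theta(a, b) averaged
        over the trinucleotide property indices (cached)."""
        cached = getattr(self, "_theta_lookup", None)
        if cached is None:
            diff = self.tri_props[:, :, None] - self.tri_props[:, None, :]
            cached = (diff**2).mean(axis=0)
            object.__setattr__(self, "_theta_lookup", cached)
        return cached

    @property
    def eiip_tri_sums(self) -> np.ndarray:
        """Summed per-base EIIP constants for each of the 64 trinucleotides."""
        per_base = np.array([self.eiip[b] for b in BASES])
        cached = getattr(self, "_eiip_tri", None)
        if cached is None:
            t = np.arange(64)
            cached = per_base[t // 16] + per_base[(t // 4) % 4] + per_base[t % 4]
            object.__setattr__(self, "_eiip_tri", cached)
        return cached


@dataclass
class PSTNPTable:
    """Learned position x trinucleotide frequency-difference table.

    ``z[i, t]`` is the relative frequency of trinucleotide ``t`` starting at
    window position ``i+1`` among positive training sequences minus the same
    frequency among negatives. Rows therefore sum to 0 and entries lie in
    [-1, 1]. This is the single-stranded PSTNP variant.
    """

    z: np.ndarray  # (WINDOW_LEN - 2, 64)

    def __post_init__(self) -> None:
        if self.z.shape != (WINDOW_LEN - 2, 64):
            raise ValueError(f"PSTNP table must be {(WINDOW_LEN - 2, 64)}")


@dataclass
class FeatureMatrix:
    """Named, ordered per-sequence feature vectors."""

    feature_names: list[str]
    values: np.ndarray
    sequence_ids: list[str]

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.sequence_ids), len(self.feature_names)):
            raise ValueError("FeatureMatrix shape mismatch")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.values, index=self.sequence_ids, columns=self.feature_names
        )

    def subset(self, names: list[str]) -> "FeatureMatrix":
        pos = {n: j for j, n in enumerate(self.feature_names)}
        missing = [n for n in names if n not in pos]
        if missing:
            raise ValueError(f"features not in matrix: {missing[:5]}")
        idx = [pos[n] for n in names]
        return FeatureMatrix(list(names), self.values[:, idx], self.sequence_ids)


# ---------------------------------------------------------------------------
# composition-style families


def mono_composition(s: NucleotideSequence) -> np.ndarray:
    """Fraction of A, C, G, T in the sequence (sums to 1)."""
    if len(s.seq) < 1:
        raise ValueError("empty sequence")
    c = np.bincount(_codes(s.seq), minlength=4)
    return c / len(s.seq)


def kmer_counts(s: NucleotideSequence, k: int) -> np.ndarray:
    """Overlapping k-mer counts in lexicographic order over {A,C,G,T}^k."""
    if len(s.seq) < k:
        raise ValueError(f"sequence {s.id} shorter than k={k}")
    codes = _codes(s.seq)
    if k == 2:
        idx = _di_codes(codes)
    elif k == 3:
        idx = _tri_codes(codes)
    else:
        idx = np.zeros(len(codes) - k + 1, dtype=np.int64)
        for j in range(k):
            idx = idx * 4 + codes[j : len(codes) - k + 1 + j]
    return np.bincount(idx, minlength=4**k).astype(float)


def skews(s: NucleotideSequence) -> tuple[float, float]:
    """(GC skew, AT skew); a zero denominator yields 0 by convention."""
    c = np.bincount(_codes(s.seq), minlength=4)
    a, cc, g, t = (float(x) for x in c)
    gc = (g - cc) / (g + cc) if g + cc else 0.0
    at = (a - t) / (a + t) if a + t else 0.0
    return gc, at


def eiip_pse(s: NucleotideSequence, cfg: EncoderConfig) -> np.ndarray:
    """64-vector: normalized trinucleotide frequency times the summed EIIP
    constants of the triplet's bases."""
    if len(s.seq) < 3:
        raise ValueError("sequence shorter than 3")
    counts = kmer_counts(s, 3)
    freqs = counts / counts.sum()
    return freqs * cfg.eiip_tri_sums


def motif_counts(s: NucleotideSequence, cfg: EncoderConfig) -> np.ndarray:
    """Overlapping exact-match occurrence count of each configured motif."""
    out = np.zeros(len(cfg.motifs))
    for j, m in enumerate(cfg.motifs):
        start = 0
        while True:
            hit = s.seq.find(m, start)
            if hit < 0:
                break
            out[j] += 1
            start = hit + 1
    return out


# ---------------------------------------------------------------------------
# PSTNP (the only data-dependent encoder)


def pstnp_fit(
    pos: list[NucleotideSequence], neg: list[NucleotideSequence]
) -> PSTNPTable:
    """Fit the position-specific trinucleotide propensity table.

    ``z[i, t] = F+(t, i) - F-(t, i)`` where ``F±`` are per-class relative
    frequencies of trinucleotide ``t`` starting at window position ``i``
    (1-based, i = 1 .. WINDOW_LEN-2).
    """
    if not pos or not neg:
        raise ValueError("PSTNP requires both classes to be non-empty")

    def class_freqs(seqs):
        counts = np.zeros((WINDOW_LEN - 2, 64))
        for s in seqs:
            if len(s.seq) != WINDOW_LEN:
                raise ValueError(
                    f"record {s.id} has length {len(s.seq)}, expected {WINDOW_LEN}"
                )
            tri = _tri_codes(_codes(s.seq))
            counts[np.arange(WINDOW_LEN - 2), tri] += 1
        return counts / len(seqs)

    return PSTNPTable(class_freqs(pos) - class_freqs(neg))


def pstnp_encode(s: NucleotideSequence, table: PSTNPTable) -> np.ndarray:
    """Per-position lookup of the fitted z table along the sequence."""
    if len(s.seq) != WINDOW_LEN:
        raise ValueError(
            f"record {s.id} has length {len(s.seq)}, expected {WINDOW_LEN}"
        )
    tri = _tri_codes(_codes(s.seq))
    return table.z[np.arange(WINDOW_LEN - 2), tri]


# ---------------------------------------------------------------------------
# dinucleotide property autocorrelation families
#
# P_u(i) is the standardized property-u value of the dinucleotide starting at
# position i (i = 1 .. L-1); P̄_u its mean along the sequence.


def _property_series(s: NucleotideSequence, cfg: EncoderConfig) -> np.ndarray:
    return cfg.di_props[:, _di_codes(_codes(s.seq))]  # (n_props, L-1)


def dac(s: NucleotideSequence, cfg: EncoderConfig) -> np.ndarray:
    """Dinucleotide autocorrelation at lags d = 1 .. lag_max, per property."""
    if len(s.seq) < cfg.lag_max + 2:
        raise ValueError("sequence too short for lag_max")
    P = _property_series(s, cfg)
    Pc = P - P.mean(axis=1, keepdims=True)
    out = []
    for u in range(P.shape[0]):
        for d in range(1, cfg.lag_max + 1):
            n = Pc.shape[1] - d
            out.append(float(Pc[u, :n] @ Pc[u, d:]) / n)
    return np.array(out)


def dcc(s: NucleotideSequence, cfg: EncoderConfig) -> np.ndarray:
    """Dinucleotide cross-correlation over ordered property pairs u1 != u2."""
    if len(s.seq) < cfg.lag_max + 2:
        raise ValueError("sequence too short for lag_max")
    P = _property_series(s, cfg)
    Pc = P - P.mean(axis=1, keepdims=True)
    out = []
    for u1 in range(P.shape[0]):
        for u2 in range(P.shape[0]):
            if u1 == u2:
                continue
            for d in range(1, cfg.lag_max + 1):
                n = Pc.shape[1] - d
                out.append(float(Pc[u1, :n] @ Pc[u2, d:]) / n)
    return np.array(out)


def dacc(s: NucleotideSequence, cfg: EncoderConfig) -> np.ndarray:
    """DAC followed by DCC (N^2 * lag_max values)."""
    return np.concatenate([dac(s, cfg), dcc(s, cfg)])


def mac(s: NucleotideSequence, cfg: EncoderConfig) -> np.ndarray:
    """Moran autocorrelation: centered lag product normalized by the
    property-series variance; zero variance yields 0."""
    P = _property_series(s, cfg)
    Pc = P - P.mean(axis=1, keepdims=True)
    var = (Pc**2).mean(axis=1)
    out = []
    for u in range(P.shape[0]):
        for d in range(1, cfg.lag_max + 1):
            n = Pc.shape[1] - d
            num = float(Pc[u, :n] @ Pc[u, d:]) / n
            # variance below this cutoff means a constant property series up
            # to rounding (standardized values are order 1) -> 0 by convention
            out.append(num / var[u] if var[u] > 1e-10 else 0.0)
    return np.array(out)


def nmbac(s: NucleotideSequence, cfg: EncoderConfig) -> np.ndarray:
    """Normalized Moreau-Broto autocorrelation: mean lagged product of the
    standardized property series, without centering."""
    P = _property_series(s, cfg)
    out = []
    for u in range(P.shape[0]):
        for d in range(1, cfg.lag_max + 1):
            n = P.shape[1] - d
            out.append(float(P[u, :n] @ P[u, d:]) / n)
    return np.array(out)


# ---------------------------------------------------------------------------
# pseudo trinucleotide composition


def pc_pse_tnc(s: NucleotideSequence, cfg: EncoderConfig) -> np.ndarray:
    """Parallel-correlation pseudo trinucleotide composition (64 + lambda
    values, summing to 1).

    The first 64 entries are the normalized overlapping trinucleotide
    frequencies damped by the sequence-order factor; the last ``lambda``
    entries are the weighted correlation factors theta_j.
    """
    lam, w = cfg.pse_lambda, cfg.pse_weight
    if len(s.seq) < lam + 3:
        raise ValueError("sequence shorter than pse_lambda + 3")
    counts = kmer_counts(s, 3)
    f = counts / counts.sum()
    tri = _tri_codes(_codes(s.seq))
    theta = np.empty(lam)
    look = cfg.theta_lookup
    for j in range(1, lam + 1):
        theta[j - 1] = look[tri[:-j], tri[j:]].mean() if j < len(tri) else 0.0
    denom = 1.0 + w * theta.sum()
    return np.concatenate([f / denom, w * theta / denom])


# ---------------------------------------------------------------------------
# full encoding


def feature_names(cfg: EncoderConfig, with_pstnp: bool = True) -> list[str]:
    """The fixed, documented column order of :func:`encode_all`."""
    names: list[str] = []
    names += [f"DNC|{w}" for w in DINUCS]
    names += [f"TNC|{w}" for w in TRINUCS]
    names += ["SKEW|GC", "SKEW|AT"]
    names += [f"EIIP|{w}" for w in TRINUCS]
    if with_pstnp:
        names += [f"PSTNP|pos={i}" for i in range(1, WINDOW_LEN - 1)]
    dac_names = [
        f"{u}|d={d}" for u in cfg.di_prop_names for d in range(1, cfg.lag_max + 1)
    ]
    dcc_names = [
        f"{u1}|{u2}|d={d}"
        for u1 in cfg.di_prop_names
        for u2 in cfg.di_prop_names
        if u1 != u2
        for d in range(1, cfg.lag_max + 1)
    ]
    names += [f"DAC|{n}" for n in dac_names]
    names += [f"DCC|{n}" for n in dcc_names]
    names += [f"DACC|{n}" for n in dac_names] + [f"DACC|{n}" for n in dcc_names]
    names += [f"MAC|{n}" for n in dac_names]
    names += [f"NMBAC|{n}" for n in dac_names]
    names += [f"PCPseTNC|{w}" for w in TRINUCS]
    names += [f"PCPseTNC|theta={j}" for j in range(1, cfg.pse_lambda + 1)]
    names += [f"MOTIF|{m}" for m in cfg.motifs]
    return names


def encode_one(
    s: NucleotideSequence, cfg: EncoderConfig, table: PSTNPTable | None
) -> np.ndarray:
    parts = [
        kmer_counts(s, 2),
        kmer_counts(s, 3),
        np.array(skews(s)),
        eiip_pse(s, cfg),
    ]
    if table is not None:
        parts.append(pstnp_encode(s, table))
    parts += [
        dac(s, cfg),
        dcc(s, cfg),
        dacc(s, cfg),
        mac(s, cfg),
        nmbac(s, cfg),
        pc_pse_tnc(s, cfg),
        motif_counts(s, cfg),
    ]
    return np.concatenate(parts)


def encode_all(
    seqs: list[NucleotideSequence],
    cfg: EncoderConfig,
    table: PSTNPTable | None = None,
) -> FeatureMatrix:
    """Encode sequences into the full named feature matrix.

    Families appear in a fixed order (DNC, TNC, SKEW, EIIP, PSTNP, DAC, DCC,
    DACC, MAC, NMBAC, PCPseTNC, MOTIF); the PSTNP block is present only when
    a fitted table is supplied. Deterministic: identical inputs and config
    yield identical matrices.
    """
    for s in seqs:
        if len(s.seq) != WINDOW_LEN:
            raise ValueError(
                f"record {s.id} has length {len(s.seq)}, expected {WINDOW_LEN}"
            )
    names = feature_names(cfg, with_pstnp=table is not None)
    values = np.empty((len(seqs), len(names)))
    for i, s in enumerate(seqs):
        values[i] = encode_one(s, cfg, table)
    return FeatureMatrix(names, values, [s.id for s in seqs])
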