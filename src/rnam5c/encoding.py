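"""Sequence-to-feature encoders: binary, k-mer, and PseDNC.

A window of L nucleotides is mapped to a numeric vector of 4·L + 106
features under the defaults:

* binary — 4 indicator features per position (A/C/G/U one-hot, N all-zero),
  4·L features;
* k-mer — occurrence frequencies of all k-mers for k ∈ {1, 2, 3},
  4 + 16 + 64 = 84 features;
* PseDNC — pseudo dinucleotide composition: the 16 normalized adjacent
  dinucleotide frequencies plus λ pseudo components built from the mean
  squared physicochemical distance between dinucleotides j positions
  apart (j = 1..λ), weighted by w and jointly normalized to sum to 1;
  16 + λ = 22 features with λ = 6.

Encoders are pure functions: the same window and configuration always
produce the identical named vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product
from typing import Mapping, Sequence

import numpy as np

from .errors import AlphabetError, ValidationError

BASES = "ACGU"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: The 16 dinucleotides in lexicographic order (AA, AC, ..., UU).
DINUCLEOTIDES = tuple(a + b for a in BASES for b in BASES)
_DINUC_INDEX = {d: i for i, d in enumerate(DINUCLEOTIDES)}

# Default physicochemical table: six structural properties of RNA
# dinucleotide steps (shift, slide, rise in Å; tilt, roll, twist in deg),
# literature consensus values.  They are standardized to mean 0 / sd 1
# across the 16 dinucleotides before use, so only relative differences
# matter.  Overridable via EncodingConfig.property_table or a TSV file.
DEFAULT_PROPERTY_NAMES = ("shift", "slide", "rise", "tilt", "roll", "twist")
DEFAULT_PROPERTY_TABLE: dict[str, tuple[float, ...]] = {
    "AA": (-0.08, -1.27, 3.18, -0.8, 7.0, 31.0),
    "AC": (0.23, -1.43, 3.24, 0.8, 4.8, 32.0),
    "AG": (-0.04, -1.50, 3.30, 0.5, 8.5, 30.0),
    "AU": (-0.06, -1.36, 3.24, 1.1, 7.1, 33.0),
    "CA": (0.11, -1.46, 3.09, 1.0, 9.9, 31.0),
    "CC": (-0.01, -1.78, 3.32, 0.3, 8.7, 32.0),
    "CG": (0.30, -1.89, 3.30, -0.1, 12.1, 27.0),
    "CU": (-0.04, -1.50, 3.30, 0.5, 8.5, 30.0),
    "GA": (0.07, -1.70, 3.38, 1.3, 9.4, 32.0),
    "GC": (0.07, -1.39, 3.22, 0.0, 6.1, 35.0),
    "GG": (-0.01, -1.78, 3.32, 0.3, 12.1, 32.0),
    "GU": (0.23, -1.43, 3.24, 0.8, 4.8, 32.0),
    "UA": (-0.02, -1.45, 3.26, -0.2, 10.7, 32.0),
    "UC": (0.07, -1.70, 3.38, 1.3, 9.4, 32.0),
    "UG": (0.11, -1.46, 3.09, 1.0, 9.9, 31.0),
    "UU": (-0.08, -1.27, 3.18, -0.8, 7.0, 31.0),
}


def standardize_property_table(table: Mapping[str, Sequence[float]]) -> np.ndarray:
    """Return a (16, n_properties) matrix standardized to mean 0, sd 1 per
    property across the 16 dinucleotides."""
    if set(table) != set(DINUCLEOTIDES):
        raise ValidationError("property table must have exactly the 16 dinucleotide keys")
    lengths = {len(v) for v in table.values()}
    if len(lengths) != 1:
        raise ValidationError("all property vectors must have the same length")
    mat = np.array([table[d] for d in DINUCLEOTIDES], dtype=float)
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0)
    if np.any(sd == 0):
        raise ValidationError("a physicochemical property is constant across dinucleotides")
    return (mat - mean) / sd


@dataclass
class EncodingConfig:
    """All encoder parameters.

    ``lam`` (λ) is the maximal dinucleotide separation used for the pseudo
    components; ``weight`` (w) balances them against the plain dinucleotide
    frequencies.  λ = 6 and w = 0.1 give the published 16 + λ = 22 PseDNC
    features and the 4·L + 106 total.
    """

    k_values: tuple[int, ...] = (1, 2, 3)
    lam: int = 6
    weight: float = 0.1
    property_table: Mapping[str, Sequence[float]] | None = None
    include_binary: bool = True
    include_kmer: bool = True
    include_psednc: bool = True

    def __post_init__(self) -> None:
        if self.lam < 1:
            raise ValidationError("lambda must be >= 1")
        if not 0.0 < self.weight <= 1.0:
            raise ValidationError("weight must be in (0, 1]")
        table = self.property_table if self.property_table is not None else DEFAULT_PROPERTY_TABLE
        self._property_matrix = standardize_property_table(table)

    @property
    def property_matrix(self) -> np.ndarray:
        """Standardized (16, n_properties) physicochemical matrix."""
        return self._property_matrix

    def n_features(self, window_length: int) -> int:
        n = 0
        if self.include_binary:
            n += 4 * window_length
        if self.include_kmer:
            n += sum(4 ** k for k in self.k_values)
        if self.include_psednc:
            n += 16 + self.lam
        return n


def _check_alphabet(window: str) -> None:
    bad = set(window) - set("ACGUN")
    if bad:
        raise AlphabetError(f"invalid characters in window: {sorted(bad)}")


def binary_feature_names(window_length: int, upstream: int | None = None) -> list[str]:
    """Per-position indicator names; positions labeled relative to the
    window center (``upstream`` defaults to L // 2)."""
    if upstream is None:
        upstream = window_length // 2
    return [
        f"bin_pos{i - upstream}_{b}" for i in range(window_length) for b in BASES
    ]


def encode_binary(window: str) -> np.ndarray:
    """One-hot encoding, 4 features per position, N → all zeros."""
    _check_alphabet(window)
    arr = np.zeros((len(window), 4))
    for i, ch in enumerate(window):
        j = _BASE_INDEX.get(ch)
        if j is not None:
            arr[i, j] = 1.0
    return arr.ravel()


def kmer_feature_names(k_values: Sequence[int] = (1, 2, 3)) -> list[str]:
    return [
        "kmer_" + "".join(km)
        for k in k_values
        for km in product(BASES, repeat=k)
    ]


def encode_kmer(window: str, k_values: Sequence[int] = (1, 2, 3)) -> np.ndarray:
    """k-mer occurrence frequencies.

    For each k the counts are divided by the number of k-length substrings
    that contain no N; a block whose substrings all contain N is all-zero.
    """
    _check_alphabet(window)
    if len(window) == 0:
        raise ValidationError("cannot k-mer-encode an empty window")
    blocks = []
    for k in k_values:
        counts = np.zeros(4 ** k)
        valid = 0
        for i in range(len(window) - k + 1):
            sub = window[i : i + k]
            if "N" in sub:
                continue
            valid += 1
            idx = 0
            for ch in sub:
                idx = idx * 4 + _BASE_INDEX[ch]
            counts[idx] += 1
        blocks.append(counts / valid if valid else counts)
    return np.concatenate(blocks)


def psednc_feature_names(lam: int = 6) -> list[str]:
    return [f"psednc_{i}" for i in range(1, 16 + lam + 1)]


def encode_psednc(window: str, cfg: EncodingConfig | None = None) -> np.ndarray:
    """Pseudo dinucleotide composition (type-I pseudo components).

    d_u = f_u / (Σf + w Σθ) for the 16 adjacent-dinucleotide frequencies
    f_u, and d_{16+j} = w θ_j / (Σf + w Σθ) for j = 1..λ, where θ_j is the
    mean over the sequence of the squared physicochemical distance between
    dinucleotides j positions apart (distance = mean squared difference of
    the standardized property values).  All features are non-negative and
    sum to 1.  Dinucleotides containing N are skipped in both the f and θ
    sums; if nothing remains all features are 0.  A θ_j with no available
    pair at separation j (window shorter than j + 2) is 0, so the vector
    keeps its 16 + λ length at every window size down to L = 2.
    """
    if cfg is None:
        cfg = EncodingConfig()
    _check_alphabet(window)
    L = len(window)
    lam, w = cfg.lam, cfg.weight
    if L < 2:
        raise ValidationError(f"window of length {L} has no dinucleotide")
    props = cfg.property_matrix
    n_props = props.shape[1]

    # dinucleotide index at each start position, -1 where it contains N
    din = np.full(L - 1, -1, dtype=int)
    for i in range(L - 1):
        a, b = window[i], window[i + 1]
        if a != "N" and b != "N":
            din[i] = _DINUC_INDEX[a + b]

    valid = din >= 0
    f = np.zeros(16)
    if valid.any():
        np.add.at(f, din[valid], 1.0)
        f /= valid.sum()

    theta = np.zeros(lam)
    for j in range(1, lam + 1):
        if j > L - 2:  # no pair at this separation
            continue
        a = din[: L - 1 - j]
        b = din[j:]
        ok = (a >= 0) & (b >= 0)
        if ok.any():
            diff = props[a[ok]] - props[b[ok]]
            theta[j - 1] = np.mean(np.sum(diff * diff, axis=1) / n_props)

    denom = f.sum() + w * theta.sum()
    if denom == 0:
        return np.zeros(16 + lam)
    return np.concatenate([f, w * theta]) / denom


@lru_cache(maxsize=32)
def _names_cached(L: int, k_values: tuple, lam: int, flags: tuple, upstream) -> tuple:
    names: list[str] = []
    inc_bin, inc_kmer, inc_pse = flags
    if inc_bin:
        names += binary_feature_names(L, upstream)
    if inc_kmer:
        names += kmer_feature_names(k_values)
    if inc_pse:
        names += psednc_feature_names(lam)
    return tuple(names)


def feature_names(
    window_length: int, cfg: EncodingConfig | None = None, upstream: int | None = None
) -> list[str]:
    """Ordered feature names: binary block (5′→3′, A,C,G,U within each
    position), then k-mer (k ascending, lexicographic), then PseDNC."""
    if cfg is None:
        cfg = EncodingConfig()
    return list(
        _names_cached(
            window_length,
            tuple(cfg.k_values),
            cfg.lam,
            (cfg.include_binary, cfg.include_kmer, cfg.include_psednc),
            upstream,
        )
    )


def encode_window(window: str, cfg: EncodingConfig | None = None) -> np.ndarray:
    """Concatenated binary + k-mer + PseDNC vector for one window."""
    if cfg is None:
        cfg = EncodingConfig()
    parts = []
    if cfg.include_binary:
        parts.append(encode_binary(window))
    if cfg.include_kmer:
        parts.append(encode_kmer(window, cfg.k_values))
    if cfg.include_psednc:
        parts.append(encode_psednc(window, cfg))
    if not parts:
        raise ValidationError("no encoding scheme enabled")
    return np.concatenate(parts)


def encode_windows(windows: Sequence[str], cfg: EncodingConfig | None = None) -> np.ndarray:
    """Feature matrix, one row per window (all windows must share a length)."""
    if cfg is None:
        cfg = EncodingConfig()
    if not windows:
        raise ValidationError("no windows to encode")
    lengths = {len(wdw) for wdw in windows}
    if len(lengths) != 1:
        raise ValidationError("windows must all have the same length")
    return np.array([encode_window(wdw, cfg) for wdw in windows])


def load_property_table(path) -> dict[str, tuple[float, ...]]:
    """Read a property TSV: 16 dinucleotide rows × named property columns
    (first column `dinucleotide`, T accepted for U)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    key = df.columns[0]
    table = {}
    for row in df.itertuples(index=False):
        dinuc = str(getattr(row, key)).upper().replace("T", "U")
        table[dinuc] = tuple(float(v) for v in row[1:])
    if set(table) != set(DINUCLEOTIDES):
        raise ValidationError("property table must cover exactly the 16 dinucleotides")
    return table


def write_feature_matrix(
    X: np.ndarray, names: Sequence[str], labels: Sequence[str], path
) -> None:
    """TSV export: header of feature names, one sample per row, label last."""
    import pandas as pd

    df = pd.DataFrame(X, columns=list(names))
    df["label"] = list(labels)
    df.to_csv(path, sep="\t", index=False)
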