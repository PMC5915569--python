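"""Synthetic transcripts, planted m5C sites, and bisulfite count tables.

The generator makes every other module testable without any download:

* transcripts are i.i.d. draws from a background base composition;
* positives are planted at cytosines whose flanks are redrawn from a
  positional weight model interpolating, with effect strength ε ∈ [0, 1],
  between the background and a G-enriched profile (real m5C flanks are
  G-biased near the site); ε = 0 leaves flanks at pure background;
* optionally each positive is forced into a programmed CG/CHG/CHH
  sequence-context mix;
* bisulfite read counts are simulated per cytosine: coverage from a
  negative binomial, C-count binomial with the planted methylation level
  at positives and the non-conversion error rate elsewhere.

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CapacityError, ValidationError

BASES = "ACGU"


@dataclass
class SimConfig:
    """Study conditions of a simulation.

    ``background_composition`` are the A/C/G/U fractions; the signal
    profile puts ``signal_g_weight`` on G at the offsets in
    ``g_enriched_offsets`` (relative to the site) when ``epsilon`` = 1,
    interpolating linearly toward background as ε → 0.  Coverage is
    negative binomial with the given mean and dispersion (size), floored
    at ``coverage_min``.
    """

    n_transcripts: int = 50
    length_range: tuple[int, int] = (500, 2000)
    background_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    n_positives: int = 100
    epsilon: float = 1.0
    signal_halfwidth: int = 5
    g_enriched_offsets: tuple[int, ...] = (-3, -2, -1, 1, 2, 3)
    signal_g_weight: float = 0.9
    context_mix: tuple[float, float, float] | None = None  # CG, CHG, CHH
    methylation_level: float = 0.3
    conversion_error: float = 0.005
    coverage_mean: float = 100.0
    coverage_dispersion: float = 5.0
    coverage_min: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        comp = np.asarray(self.background_composition, dtype=float)
        if comp.shape != (4,) or np.any(comp < 0) or abs(comp.sum() - 1.0) > 1e-9:
            raise ValidationError("background_composition must be 4 fractions summing to 1")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValidationError("epsilon must be in [0, 1]")
        if self.context_mix is not None:
            mix = np.asarray(self.context_mix, dtype=float)
            if mix.shape != (3,) or np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-9:
                raise ValidationError("context_mix must be 3 fractions summing to 1")
        if not 0.0 <= self.methylation_level <= 1.0:
            raise ValidationError("methylation_level must be in [0, 1]")
        if not 0.0 <= self.conversion_error < 1.0:
            raise ValidationError("conversion_error must be in [0, 1)")


def signal_weights(cfg: SimConfig, offset: int) -> np.ndarray:
    """Base probabilities at a flank offset under the ε-interpolated
    positional weight model."""
    bg = np.asarray(cfg.background_composition, dtype=float)
    if offset not in cfg.g_enriched_offsets:
        return bg
    target = np.empty(4)
    g_idx = BASES.index("G")
    rest = (1.0 - cfg.signal_g_weight) / 3.0
    target[:] = rest
    target[g_idx] = cfg.signal_g_weight
    return (1.0 - cfg.epsilon) * bg + cfg.epsilon * target


def simulate_dataset(
    cfg: SimConfig,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Generate transcripts and plant positives; return (transcripts,
    truth table).

    The truth table has one row per planted site: transcript_id, 0-based
    position, planted methylation level, and (when a context mix is
    configured) the programmed context.  Raises :class:`CapacityError`
    when the requested number of positives exceeds the cytosines that can
    host one (full flank inside the transcript, no overlap with an
    already-planted site).
    """
    rng = np.random.default_rng(cfg.seed)
    comp = np.asarray(cfg.background_composition, dtype=float)
    lo, hi = cfg.length_range

    seqs: dict[str, list[str]] = {}
    for i in range(cfg.n_transcripts):
        length = int(rng.integers(lo, hi + 1))
        seqs[f"synthetic_tx{i + 1}"] = list(
            "".join(rng.choice(list(BASES), size=length, p=comp))
        )

    h = cfg.signal_halfwidth
    candidates = [
        (tid, p)
        for tid, s in seqs.items()
        for p in range(h, len(s) - h)
        if s[p] == "C"
    ]
    rng.shuffle(candidates)

    planted: list[tuple[str, int]] = []
    occupied: dict[str, list[int]] = {}
    min_gap = 2 * h + 1
    for tid, p in candidates:
        if len(planted) == cfg.n_positives:
            break
        if any(abs(p - q) < min_gap for q in occupied.get(tid, [])):
            continue
        planted.append((tid, p))
        occupied.setdefault(tid, []).append(p)
    if len(planted) < cfg.n_positives:
        raise CapacityError(
            f"only {len(planted)} plantable cytosines for {cfg.n_positives} requested positives"
        )
    planted.sort()

    contexts = []
    if cfg.context_mix is not None:
        contexts = list(
            rng.choice(["CG", "CHG", "CHH"], size=len(planted), p=cfg.context_mix)
        )

    truth_rows = []
    for idx, (tid, p) in enumerate(planted):
        s = seqs[tid]
        forced: dict[int, str] = {}
        if cfg.context_mix is not None:
            ctx = contexts[idx]
            h_bases = ["A", "C", "U"]
            if ctx == "CG":
                forced[1] = "G"
            elif ctx == "CHG":
                forced[1] = str(rng.choice(h_bases))
                forced[2] = "G"
            else:  # CHH
                forced[1] = str(rng.choice(h_bases))
                forced[2] = str(rng.choice(h_bases))
        for off in range(-h, h + 1):
            if off == 0:
                continue
            if off in forced:
                s[p + off] = forced[off]
            else:
                s[p + off] = str(rng.choice(list(BASES), p=signal_weights(cfg, off)))
        row = {
            "transcript_id": tid,
            "position": p,
            "level": cfg.methylation_level,
        }
        if cfg.context_mix is not None:
            row["context"] = contexts[idx]
        truth_rows.append(row)

    transcripts = {tid: "".join(s) for tid, s in seqs.items()}
    return transcripts, pd.DataFrame(truth_rows)


def simulate_bisulfite_counts(
    truth: pd.DataFrame,
    transcripts: Mapping[str, str],
    cfg: SimConfig,
) -> pd.DataFrame:
    """Per-cytosine read counts: columns transcript_id, position (0-based),
    c_count, t_count, is_positive.

    Coverage ~ NegBinom(mean=coverage_mean, size=coverage_dispersion),
    floored at coverage_min; C-count ~ Binomial(coverage, m) with m the
    planted level at positives and the non-conversion error elsewhere.
    Zero-coverage rows are emitted with zero counts.
    """
    positives = {
        (row.transcript_id, int(row.position)) for row in truth.itertuples(index=False)
    }
    for tid, p in positives:
        if tid not in transcripts or transcripts[tid][p] != "C":
            raise ValidationError(f"truth site {tid}:{p} is not a C in the transcripts")

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]).generate_state(1)[0])
    size = cfg.coverage_dispersion
    p_nb = size / (size + cfg.coverage_mean)
    rows = []
    for tid, seq in transcripts.items():
        for i, b in enumerate(seq):
            if b != "C":
                continue
            cov = max(int(rng.negative_binomial(size, p_nb)), cfg.coverage_min)
            m = cfg.methylation_level if (tid, i) in positives else cfg.conversion_error
            c = int(rng.binomial(cov, m)) if cov > 0 else 0
            rows.append(
                {
                    "transcript_id": tid,
                    "position": i,
                    "c_count": c,
                    "t_count": cov - c,
                    "is_positive": (tid, i) in positives,
                }
            )
    return pd.DataFrame(rows)


def write_simulation(
    transcripts: Mapping[str, str],
    truth: pd.DataFrame,
    counts: pd.DataFrame | None,
    cfg: SimConfig,
    fasta_path,
    truth_path,
    counts_path=None,
) -> None:
    """Write FASTA + truth TSV (+ count TSV), seed-stamped, 1-based
    positions in the TSVs."""
    with open(fasta_path, "w") as fh:
        for tid, seq in transcripts.items():
            fh.write(f">{tid} seed={cfg.seed}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    t = truth.copy()
    t["position"] = t["position"] + 1
    with open(truth_path, "w") as fh:
        fh.write(f"# seed={cfg.seed}\n")
        t.to_csv(fh, sep="\t", index=False)
    if counts is not None and counts_path is not None:
        c = counts.copy()
        c["position"] = c["position"] + 1
        with open(counts_path, "w") as fh:
            fh.write(f"# seed={cfg.seed}\n")
            c.to_csv(fh, sep="\t", index=False)


def labeled_windows_from_simulation(
    transcripts: Mapping[str, str],
    truth: pd.DataFrame,
    neg_per_pos: int = 10,
    upstream: int = 5,
    downstream: int = 5,
    seed: int = 0,
) -> tuple[list[str], np.ndarray]:
    """Convenience for experiments: windows at every planted site (label 1)
    plus ``neg_per_pos`` random other cytosines per positive (label 0)."""
    from .datasets import extract_window

    rng = np.random.default_rng(seed)
    pos_set = {
        (row.transcript_id, int(row.position)) for row in truth.itertuples(index=False)
    }
    windows, labels = [], []
    for tid, p in sorted(pos_set):
        windows.append(extract_window(transcripts[tid], p, upstream, downstream))
        labels.append(1)
    others = [
        (tid, i)
        for tid, seq in transcripts.items()
        for i, b in enumerate(seq)
        if b == "C" and (tid, i) not in pos_set
    ]
    n_neg = min(len(others), neg_per_pos * len(pos_set))
    if n_neg == 0:
        raise ValidationError("no negative cytosines available")
    idx = rng.choice(len(others), size=n_neg, replace=False)
    for j in sorted(idx):
        tid, i = others[int(j)]
        windows.append(extract_window(transcripts[tid], i, upstream, downstream))
        labels.append(0)
    return windows, np.asarray(labels)
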