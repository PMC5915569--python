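"""Build labeled training samples from bisulfite-derived cytosine counts.

Bisulfite treatment converts unmethylated cytosines to uracil (sequenced as
T) while methylated cytosines stay C, so the per-site C/T read counts
estimate the methylation level.  This module turns a per-cytosine count
table plus transcript sequences into positive samples (methylated sites)
and GC-matched negative samples (nearby unmethylated cytosines), each
represented as a fixed-width RNA window centered on the cytosine.

Coordinates are 0-based internally; all emitted TSV files use 1-based
positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import CoverageError, ValidationError, WindowError

logger = logging.getLogger(__name__)

#: Pseudo-count added to the C numerator of the methylation-level statistic.
DEFAULT_PSEUDO = 1.0 / 8.0

_RNA_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


@dataclass
class CytosineCall:
    """One cytosine with its bisulfite read counts and derived statistics.

    ``position`` is a 0-based index into the transcript sequence and must
    address a 'C'.  ``level`` is the pseudo-counted methylation proportion
    (C + Ψ)/(T + C); ``p_value``/``fdr`` quantify evidence against the
    non-conversion-error null.
    """

    transcript_id: str
    position: int
    c_count: int
    t_count: int
    level: float | None = None
    p_value: float | None = None
    fdr: float | None = None


@dataclass
class LabeledSample:
    """A fixed-width RNA window centered on a cytosine, with a binary label."""

    window: str
    label: str  # "pos" or "neg"
    transcript_id: str
    position: int

    def __post_init__(self) -> None:
        if self.label not in ("pos", "neg"):
            raise ValidationError(f"label must be 'pos' or 'neg', got {self.label!r}")


@dataclass
class SamplingConfig:
    """Parameters of positive calling and GC-matched negative sampling.

    Defaults follow the published design: negatives are drawn 10 per
    positive from the 200-nt region around it with window GC content
    within 5%, and positives require methylation level >= 1% at FDR <= 0.3.
    """

    neg_per_pos: int = 10
    region_halfwidth: int = 100
    gc_tolerance: float = 0.05
    level_min: float = 0.01
    fdr_max: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.neg_per_pos < 1:
            raise ValidationError("neg_per_pos must be >= 1")
        if not 0.0 <= self.gc_tolerance <= 1.0:
            raise ValidationError("gc_tolerance must be in [0, 1]")


def normalize_rna(seq: str) -> str:
    """Uppercase and convert DNA 'T' to RNA 'U'."""
    return seq.upper().replace("T", "U")


def compute_methylation_level(
    c_count: int, t_count: int, pseudo: float = DEFAULT_PSEUDO
) -> float:
    """Methylation proportion (C + Ψ)/(T + C) with pseudo-count Ψ.

    The pseudo-count keeps fully unmethylated, well-covered sites at a
    small positive level instead of exactly zero.
    """
    if c_count < 0 or t_count < 0:
        raise ValidationError("read counts must be non-negative")
    total = c_count + t_count
    if total == 0:
        raise CoverageError("zero total coverage: methylation level undefined")
    return (c_count + pseudo) / total


def binomial_pvalues(
    calls: Sequence[CytosineCall], conversion_error: float = 0.005
) -> list[float]:
    """One-sided binomial p-values for the observed C counts.

    The null hypothesis at an unmethylated site is that every C read
    reflects bisulfite non-conversion error; the p-value is
    P(X >= c_count) with X ~ Binomial(c+t, conversion_error).  Sites with
    zero coverage get p = 1.
    """
    if not 0.0 < conversion_error < 1.0:
        raise ValidationError("conversion_error must be in (0, 1)")
    pvals = []
    for call in calls:
        n = call.c_count + call.t_count
        if n == 0:
            pvals.append(1.0)
        else:
            pvals.append(float(stats.binom.sf(call.c_count - 1, n, conversion_error)))
    return pvals


def annotate_statistics(
    calls: Sequence[CytosineCall],
    conversion_error: float = 0.005,
    pseudo: float = DEFAULT_PSEUDO,
) -> list[CytosineCall]:
    """Fill level, p_value and Benjamini-Hochberg FDR in place; skip
    zero-coverage sites (their level stays None and they can never be
    called positive)."""
    covered = [c for c in calls if c.c_count + c.t_count > 0]
    for call in covered:
        call.level = compute_methylation_level(call.c_count, call.t_count, pseudo)
    if covered:
        pvals = binomial_pvalues(covered, conversion_error)
        fdrs = multipletests(pvals, method="fdr_bh")[1]
        for call, p, q in zip(covered, pvals, fdrs):
            call.p_value = p
            call.fdr = float(q)
    return list(calls)


def call_positives(
    calls: Iterable[CytosineCall], cfg: SamplingConfig
) -> list[CytosineCall]:
    """Retain calls with level >= level_min and FDR <= fdr_max (both
    boundaries inclusive).  Order-preserving and idempotent."""
    out = []
    for call in calls:
        if call.level is None:
            continue
        if call.fdr is None:
            raise ValidationError(
                f"call {call.transcript_id}:{call.position} has no fdr; "
                "run annotate_statistics or supply an fdr column"
            )
        if call.level >= cfg.level_min and call.fdr <= cfg.fdr_max:
            out.append(call)
    return out


def extract_window(
    transcript_seq: str, position: int, upstream: int, downstream: int
) -> str:
    """Window of upstream+1+downstream bases around ``position``.

    Positions falling outside the transcript are filled with 'N'; DNA
    input is normalized to the RNA alphabet.
    """
    if upstream < 0 or downstream < 0:
        raise ValidationError("upstream/downstream must be non-negative")
    seq = normalize_rna(transcript_seq)
    if not 0 <= position < len(seq):
        raise WindowError(
            f"position {position} outside sequence of length {len(seq)}"
        )
    lo, hi = position - upstream, position + downstream + 1
    left_pad = max(0, -lo)
    right_pad = max(0, hi - len(seq))
    return "N" * left_pad + seq[max(0, lo) : min(hi, len(seq))] + "N" * right_pad


def gc_content(window: str) -> float:
    """G+C fraction over the non-N positions of a window (NaN if all N)."""
    n_known = sum(1 for b in window if b != "N")
    if n_known == 0:
        return float("nan")
    return sum(1 for b in window if b in "GC") / n_known


def sample_gc_matched_negatives(
    positive: CytosineCall,
    transcript_seq: str,
    known_positives: set[int],
    cfg: SamplingConfig,
    upstream: int = 21,
    downstream: int = 21,
    rng: np.random.Generator | None = None,
) -> list[LabeledSample]:
    """Draw up to ``cfg.neg_per_pos`` negative windows near a positive.

    Candidates are cytosines within ±region_halfwidth of the positive that
    are not themselves called positive and whose window GC content differs
    from the positive's by at most gc_tolerance.  Selection among eligible
    candidates is uniform at random under the configured seed.
    """
    seq = normalize_rna(transcript_seq)
    pos = positive.position
    if not 0 <= pos < len(seq) or seq[pos] != "C":
        raise WindowError(
            f"positive site {positive.transcript_id}:{pos} is not a C in its transcript"
        )
    pos_window = extract_window(seq, pos, upstream, downstream)
    pos_gc = gc_content(pos_window)

    lo = max(0, pos - cfg.region_halfwidth)
    hi = min(len(seq), pos + cfg.region_halfwidth + 1)
    eligible = []
    for i in range(lo, hi):
        if i == pos or seq[i] != "C" or i in known_positives:
            continue
        win = extract_window(seq, i, upstream, downstream)
        if abs(gc_content(win) - pos_gc) <= cfg.gc_tolerance:
            eligible.append((i, win))

    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if len(eligible) > cfg.neg_per_pos:
        idx = rng.choice(len(eligible), size=cfg.neg_per_pos, replace=False)
        chosen = [eligible[int(i)] for i in sorted(idx)]
    else:
        chosen = eligible
        if len(chosen) < cfg.neg_per_pos:
            logger.warning(
                "only %d of %d GC-matched negatives found for %s:%d",
                len(chosen), cfg.neg_per_pos, positive.transcript_id, pos,
            )
    return [
        LabeledSample(win, "neg", positive.transcript_id, i) for i, win in chosen
    ]


def build_dataset(
    calls: Sequence[CytosineCall],
    transcripts: Mapping[str, str],
    cfg: SamplingConfig,
    upstream: int = 21,
    downstream: int = 21,
) -> list[LabeledSample]:
    """Full dataset build: call positives, extract their windows, and
    attach GC-matched negatives.  Deterministic under ``cfg.seed``."""
    positives = call_positives(calls, cfg)
    by_transcript: dict[str, set[int]] = {}
    for p in positives:
        by_transcript.setdefault(p.transcript_id, set()).add(p.position)

    rng = np.random.default_rng(cfg.seed)
    samples: list[LabeledSample] = []
    for p in positives:
        if p.transcript_id not in transcripts:
            raise ValidationError(f"transcript {p.transcript_id} missing from FASTA")
        seq = normalize_rna(transcripts[p.transcript_id])
        if not 0 <= p.position < len(seq) or seq[p.position] != "C":
            raise WindowError(
                f"positive {p.transcript_id}:{p.position} does not address a C"
            )
        samples.append(
            LabeledSample(
                extract_window(seq, p.position, upstream, downstream),
                "pos",
                p.transcript_id,
                p.position,
            )
        )
        samples.extend(
            sample_gc_matched_negatives(
                p, seq, by_transcript[p.transcript_id], cfg,
                upstream=upstream, downstream=downstream, rng=rng,
            )
        )
    return samples


# ---------------------------------------------------------------------------
# I/O — count tables, FASTA, dataset files
# ---------------------------------------------------------------------------

def read_count_table(path) -> list[CytosineCall]:
    """Read a TSV of `transcript_id position c_count t_count [p_value] [fdr]`
    with 1-based positions (converted to 0-based internally)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"transcript_id", "position", "c_count", "t_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"count table missing columns: {sorted(missing)}")
    calls = []
    for row in df.itertuples(index=False):
        calls.append(
            CytosineCall(
                transcript_id=str(row.transcript_id),
                position=int(row.position) - 1,
                c_count=int(row.c_count),
                t_count=int(row.t_count),
                p_value=float(row.p_value) if hasattr(row, "p_value") else None,
                fdr=float(row.fdr) if hasattr(row, "fdr") else None,
            )
        )
    return calls


def read_fasta(path) -> dict[str, str]:
    """Read a multi-record FASTA; IDs are truncated at the first whitespace."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_dataset_fasta(samples: Sequence[LabeledSample], path) -> None:
    """Write samples as FASTA with `|label=pos|` / `|label=neg|` header tokens
    (positions 1-based in headers)."""
    with open(path, "w") as fh:
        for s in samples:
            fh.write(f">{s.transcript_id}:{s.position + 1}|label={s.label}|\n")
            fh.write(s.window + "\n")


def read_dataset_fasta(path) -> list[LabeledSample]:
    """Read a dataset FASTA produced by :func:`write_dataset_fasta` (or any
    FASTA whose headers carry a `|label=pos|`/`|label=neg|` token)."""
    from Bio import SeqIO

    samples = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description
        if "|label=pos|" in header:
            label = "pos"
        elif "|label=neg|" in header:
            label = "neg"
        else:
            raise ValidationError(f"no |label=...| token in header {header!r}")
        tid, _, pos1 = rec.id.partition(":")
        position = int(pos1.split("|")[0]) - 1 if pos1 else -1
        samples.append(LabeledSample(normalize_rna(str(rec.seq)), label, tid, position))
    return samples


def write_dataset_tsv(samples: Sequence[LabeledSample], path) -> None:
    """Sidecar TSV: transcript_id, 1-based position, label, window GC."""
    with open(path, "w") as fh:
        fh.write("transcript_id\tposition\tlabel\tgc\n")
        for s in samples:
            fh.write(
                f"{s.transcript_id}\t{s.position + 1}\t{s.label}\t"
                f"{gc_content(s.window):.6f}\n"
            )
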