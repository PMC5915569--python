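"""Transcriptome-wide scanning and downstream site analyses.

Every cytosine of every transcript is windowed with the trained model's
geometry, encoded, scored by the ensemble, and emitted with the
confidence modes it passes, its CG/CHG/CHH sequence context, its mRNA
region (5'UTR / CDS / 3'UTR) and its distance to the translational start
site.  Aggregate views: per-RNA-class tallies, candidate-vs-background
context proportions, and a length-normalized metagene profile.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import extract_window, normalize_rna
from .encoding import encode_windows, feature_names
from .errors import SchemaError, ValidationError
from .model import MODES, EnsembleModel, modes_passed, score_samples

logger = logging.getLogger(__name__)

RNA_CLASSES = (
    "mRNA", "lncRNA", "miRNA", "pri-miRNA", "rRNA", "snoRNA", "snRNA", "tRNA", "other",
)

_GFF_TYPE_TO_CLASS = {
    "mrna": "mRNA",
    "lnc_rna": "lncRNA",
    "lncrna": "lncRNA",
    "mirna": "miRNA",
    "mirna_primary_transcript": "pri-miRNA",
    "pri_mirna": "pri-miRNA",
    "rrna": "rRNA",
    "snorna": "snoRNA",
    "snrna": "snRNA",
    "trna": "tRNA",
}

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class TranscriptModel:
    """A transcript sequence with its RNA class and optional CDS interval
    (0-based half-open, in transcript coordinates)."""

    transcript_id: str
    sequence: str
    rna_class: str = "other"
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        self.sequence = normalize_rna(self.sequence)
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValidationError("cds_start and cds_end must be set together")
        if self.cds_start is not None:
            if not 0 <= self.cds_start < self.cds_end <= len(self.sequence):
                raise ValidationError(
                    f"invalid CDS interval [{self.cds_start}, {self.cds_end}) "
                    f"for {self.transcript_id} of length {len(self.sequence)}"
                )
            if self.sequence[self.cds_start : self.cds_start + 3] != "AUG":
                logger.warning(
                    "CDS of %s does not begin with AUG", self.transcript_id
                )


@dataclass
class SiteAnnotation:
    transcript_id: str
    position: int  # 0-based
    score: float
    modes_passed: list[str] = field(default_factory=list)
    context: str = "NA"  # CG / CHG / CHH / NA
    region: str = "NA"  # 5UTR / CDS / 3UTR / noncoding / NA
    dist_to_start: int | None = None


def classify_context(sequence: str, position: int, min_downstream: int = 2) -> str:
    """CG/CHG/CHH context of a cytosine from its two downstream bases
    (H = A, C or U).

    With ``min_downstream=1`` a CG call is made from a single downstream
    base and only a lone terminal C is NA; with the default 2, any C with
    fewer than two downstream bases is NA unless the first one is G.
    """
    seq = normalize_rna(sequence)
    if not 0 <= position < len(seq) or seq[position] != "C":
        raise ValidationError(f"position {position} is not a C")
    nxt = seq[position + 1] if position + 1 < len(seq) else None
    nxt2 = seq[position + 2] if position + 2 < len(seq) else None
    if nxt == "G":
        return "CG"
    if nxt is None or nxt == "N":
        return "NA"
    if nxt2 == "G":
        return "CHG"
    if nxt2 is None:
        return "NA" if min_downstream >= 2 else "CHH"
    if nxt2 == "N":
        return "NA"
    return "CHH"


def region_of(position: int, tm: TranscriptModel) -> str:
    """5UTR / CDS / 3UTR by the half-open CDS interval; noncoding classes
    map to 'noncoding'; an mRNA without CDS annotation gives NA."""
    if tm.rna_class != "mRNA":
        return "noncoding"
    if tm.cds_start is None:
        logger.warning("mRNA %s has no CDS annotation", tm.transcript_id)
        return "NA"
    if position < tm.cds_start:
        return "5UTR"
    if position < tm.cds_end:
        return "CDS"
    return "3UTR"


def distance_to_start(position: int, tm: TranscriptModel) -> int | None:
    """Signed distance to the translational start, with the A of the AUG
    start codon as nucleotide 1 (so the C of AUGC is 4; upstream sites
    are negative)."""
    if tm.cds_start is None:
        return None
    return position - tm.cds_start + 1


def scan_transcripts(
    model: EnsembleModel,
    transcripts: Iterable[TranscriptModel],
    batch_size: int = 4096,
) -> Iterator[SiteAnnotation]:
    """Score every cytosine of every transcript (streaming per transcript).

    Windows use the model's geometry with N padding at borders; features
    are the model's selected subset of the full encoding for that
    geometry.  Exactly one annotation is emitted per cytosine.
    """
    full_names = feature_names(
        model.window_length, model.encoding_config, upstream=model.upstream
    )
    try:
        cols = [full_names.index(nm) for nm in model.selected_features]
    except ValueError as exc:
        raise SchemaError(
            "model feature names are not a subset of the encoding for its geometry"
        ) from exc

    for tm in transcripts:
        seq = tm.sequence
        if not seq:
            logger.warning("skipping empty transcript %s", tm.transcript_id)
            continue
        positions = [i for i, b in enumerate(seq) if b == "C"]
        for start in range(0, len(positions), batch_size):
            chunk = positions[start : start + batch_size]
            windows = [
                extract_window(seq, p, model.upstream, model.downstream)
                for p in chunk
            ]
            X = encode_windows(windows, model.encoding_config)[:, cols]
            scores = score_samples(model, X)
            for p, s in zip(chunk, scores):
                yield SiteAnnotation(
                    transcript_id=tm.transcript_id,
                    position=p,
                    score=float(s),
                    modes_passed=modes_passed(float(s), model.thresholds),
                    context=classify_context(seq, p),
                    region=region_of(p, tm),
                    dist_to_start=distance_to_start(p, tm),
                )


def context_proportions(
    annotations: Sequence[SiteAnnotation],
    transcripts: Sequence[TranscriptModel],
    candidate_mode: str | None = None,
) -> tuple[dict[str, float], dict[str, float]]:
    """CG/CHG/CHH fractions among candidate sites vs all transcript
    cytosines (the background).  Both triples sum to 1 over classifiable
    sites.  ``candidate_mode`` restricts candidates to sites passing that
    confidence mode (default: all annotations given)."""
    cand = [
        a for a in annotations
        if a.context != "NA"
        and (candidate_mode is None or candidate_mode in a.modes_passed)
    ]
    if not cand:
        raise ValidationError("no classifiable candidate sites")
    cand_counts = {c: 0 for c in ("CG", "CHG", "CHH")}
    for a in cand:
        cand_counts[a.context] += 1

    bg_counts = {c: 0 for c in ("CG", "CHG", "CHH")}
    for tm in transcripts:
        seq = tm.sequence
        for i, b in enumerate(seq):
            if b == "C":
                ctx = classify_context(seq, i)
                if ctx != "NA":
                    bg_counts[ctx] += 1
    if sum(bg_counts.values()) == 0:
        raise ValidationError("no classifiable background cytosines")

    n_c, n_b = sum(cand_counts.values()), sum(bg_counts.values())
    return (
        {c: v / n_c for c, v in cand_counts.items()},
        {c: v / n_b for c, v in bg_counts.items()},
    )


def metagene_profile(
    annotations: Sequence[SiteAnnotation],
    transcripts: Sequence[TranscriptModel],
    bins_per_region: int = 30,
) -> pd.DataFrame:
    """Length-normalized site density along 5'UTR / CDS / 3'UTR.

    Each site in a coding transcript maps to a fractional position within
    its region; counts are aggregated into ``bins_per_region`` equal-width
    bins per region, next to the background density of all cytosines.
    Zero-length regions are skipped with a warning.
    """
    if bins_per_region < 1:
        raise ValidationError("bins_per_region must be >= 1")
    by_id = {tm.transcript_id: tm for tm in transcripts}
    regions = ("5UTR", "CDS", "3UTR")
    site_counts = {r: np.zeros(bins_per_region) for r in regions}
    bg_counts = {r: np.zeros(bins_per_region) for r in regions}

    def region_bounds(tm: TranscriptModel, region: str) -> tuple[int, int]:
        return {
            "5UTR": (0, tm.cds_start),
            "CDS": (tm.cds_start, tm.cds_end),
            "3UTR": (tm.cds_end, len(tm.sequence)),
        }[region]

    def bin_of(pos: int, lo: int, hi: int) -> int | None:
        if hi <= lo:
            return None
        frac = (pos - lo) / (hi - lo)
        return min(int(frac * bins_per_region), bins_per_region - 1)

    for a in annotations:
        tm = by_id.get(a.transcript_id)
        if tm is None or tm.cds_start is None:
            continue
        region = region_of(a.position, tm)
        if region not in regions:
            continue
        lo, hi = region_bounds(tm, region)
        b = bin_of(a.position, lo, hi)
        if b is None:
            logger.warning(
                "zero-length %s in %s; site %d skipped", region, tm.transcript_id, a.position
            )
            continue
        site_counts[region][b] += 1

    for tm in transcripts:
        if tm.cds_start is None:
            continue
        for i, base in enumerate(tm.sequence):
            if base != "C":
                continue
            region = region_of(i, tm)
            if region not in regions:
                continue
            lo, hi = region_bounds(tm, region)
            b = bin_of(i, lo, hi)
            if b is not None:
                bg_counts[region][b] += 1

    total_sites = sum(c.sum() for c in site_counts.values())
    total_bg = sum(c.sum() for c in bg_counts.values())
    rows = []
    for r in regions:
        for b in range(bins_per_region):
            rows.append(
                {
                    "region": r,
                    "bin": b,
                    "count": int(site_counts[r][b]),
                    "density": site_counts[r][b] / total_sites if total_sites else 0.0,
                    "background_count": int(bg_counts[r][b]),
                    "background_density": bg_counts[r][b] / total_bg if total_bg else 0.0,
                }
            )
    return pd.DataFrame(rows)


def class_tallies(
    annotations: Sequence[SiteAnnotation],
    transcripts: Sequence[TranscriptModel],
    candidate_mode: str | None = "VHmode",
) -> pd.DataFrame:
    """Per-RNA-class summary: transcripts, cytosines, methylated cytosines
    (sites passing the candidate mode) and transcripts containing one."""
    cand = [
        a for a in annotations
        if candidate_mode is None or candidate_mode in a.modes_passed
    ]
    per_class: dict[str, dict] = {}
    for tm in transcripts:
        d = per_class.setdefault(
            tm.rna_class,
            {"n_transcripts": 0, "n_cytosines": 0, "n_methylated": 0, "trans_with_site": set()},
        )
        d["n_transcripts"] += 1
        d["n_cytosines"] += tm.sequence.count("C")
    by_id = {tm.transcript_id: tm for tm in transcripts}
    for a in cand:
        tm = by_id.get(a.transcript_id)
        if tm is None:
            continue
        d = per_class[tm.rna_class]
        d["n_methylated"] += 1
        d["trans_with_site"].add(a.transcript_id)
    rows = []
    for cls, d in sorted(per_class.items()):
        rows.append(
            {
                "rna_class": cls,
                "n_transcripts": d["n_transcripts"],
                "n_cytosines": d["n_cytosines"],
                "n_methylated": d["n_methylated"],
                "prop_methylated": (
                    d["n_methylated"] / d["n_cytosines"] if d["n_cytosines"] else 0.0
                ),
                "n_transcripts_with_m5c": len(d["trans_with_site"]),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# GFF3 / BED ingestion
# ---------------------------------------------------------------------------

def _gff_attributes(attr: str) -> dict[str, str]:
    out = {}
    for item in attr.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3_transcripts(
    gff3_path, genome: Mapping[str, str]
) -> list[TranscriptModel]:
    """Reconstruct spliced transcripts from a GFF3 and genome sequences.

    Transcripts are exon concatenations (minus-strand genes reverse-
    complemented); CDS intervals are mapped into transcript coordinates.
    GFF3 is 1-based inclusive; internal coordinates are 0-based half-open.
    Feature types outside the recognized RNA classes map to 'other'.
    """
    tx_meta: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}

    with open(gff3_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                continue
            seqid, _, ftype, start, end, _, strand, _, attrs = parts[:9]
            attrs = _gff_attributes(attrs)
            lo, hi = int(start) - 1, int(end)  # to 0-based half-open
            ftype_l = ftype.lower()
            if ftype_l in _GFF_TYPE_TO_CLASS or ftype_l in ("transcript",):
                tid = attrs.get("ID")
                if tid:
                    cls = _GFF_TYPE_TO_CLASS.get(
                        ftype_l,
                        _GFF_TYPE_TO_CLASS.get(
                            attrs.get("biotype", "").lower(), "other"
                        ),
                    )
                    tx_meta[tid] = {"seqid": seqid, "strand": strand, "class": cls}
            elif ftype_l == "exon":
                parent = attrs.get("Parent")
                if parent:
                    for tid in parent.split(","):
                        exons.setdefault(tid, []).append((lo, hi))
            elif ftype_l == "cds":
                parent = attrs.get("Parent")
                if parent:
                    for tid in parent.split(","):
                        cds.setdefault(tid, []).append((lo, hi))

    transcripts = []
    for tid, meta in tx_meta.items():
        seqid, strand = meta["seqid"], meta["strand"]
        if seqid not in genome:
            logger.warning("sequence %s for transcript %s not in FASTA", seqid, tid)
            continue
        chrom = genome[seqid].upper().replace("U", "T")
        ex = sorted(exons.get(tid, []))
        if not ex:
            logger.warning("transcript %s has no exons; skipped", tid)
            continue
        spliced = "".join(chrom[lo:hi] for lo, hi in ex)
        # genomic -> transcript coordinate offsets (plus strand order)
        offsets = []
        acc = 0
        for lo, hi in ex:
            offsets.append((lo, hi, acc))
            acc += hi - lo
        tx_len = acc

        def to_tx(gpos: int) -> int | None:
            for lo, hi, off in offsets:
                if lo <= gpos < hi:
                    return off + (gpos - lo)
            return None

        cds_start = cds_end = None
        if tid in cds:
            c_lo = min(lo for lo, _ in cds[tid])
            c_hi = max(hi for _, hi in cds[tid])
            t_lo, t_hi = to_tx(c_lo), to_tx(c_hi - 1)
            if t_lo is not None and t_hi is not None:
                cds_start, cds_end = t_lo, t_hi + 1

        if strand == "-":
            spliced = spliced.translate(_DNA_COMPLEMENT)[::-1]
            if cds_start is not None:
                cds_start, cds_end = tx_len - cds_end, tx_len - cds_start

        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                sequence=spliced,
                rna_class=meta["class"],
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    return transcripts


def read_bed(path) -> dict[str, list[tuple[int, int]]]:
    """BED intervals (0-based half-open) grouped by sequence id and sorted."""
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            intervals.setdefault(parts[0], []).append((int(parts[1]), int(parts[2])))
    for v in intervals.values():
        v.sort()
    return intervals


def sites_in_intervals(
    annotations: Sequence[SiteAnnotation],
    intervals: Mapping[str, Sequence[tuple[int, int]]],
) -> tuple[int, int]:
    """Count (sites falling inside an interval, intervals covered by at
    least one site) — the overlap statistic used to validate predictions
    against immunoprecipitation peak regions."""
    n_sites_in = 0
    covered: set[tuple[str, int, int]] = set()
    for a in annotations:
        ivs = intervals.get(a.transcript_id, [])
        starts = [lo for lo, _ in ivs]
        j = bisect_right(starts, a.position) - 1
        hit = False
        while j >= 0 and ivs[j][1] > a.position:
            if ivs[j][0] <= a.position:
                covered.add((a.transcript_id, *ivs[j]))
                hit = True
            j -= 1
        if hit:
            n_sites_in += 1
    return n_sites_in, len(covered)


def write_annotations_tsv(annotations: Iterable[SiteAnnotation], path) -> None:
    """Main scan output: 1-based positions, one column per confidence mode."""
    with open(path, "w") as fh:
        fh.write(
            "transcript_id\tposition\tscore\tVH\tH\tN\tL\tcontext\tregion\tdist_to_start\n"
        )
        for a in annotations:
            flags = "\t".join(
                "1" if m in a.modes_passed else "0" for m in MODES
            )
            dist = "" if a.dist_to_start is None else str(a.dist_to_start)
            fh.write(
                f"{a.transcript_id}\t{a.position + 1}\t{a.score:.6f}\t{flags}\t"
                f"{a.context}\t{a.region}\t{dist}\n"
            )
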