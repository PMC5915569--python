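"""Scanning, sequence context, mRNA regions, metagene, GFF3/BED ingestion."""

import numpy as np
import pytest

import rnam5c as r
from rnam5c.annotate import read_bed
from rnam5c.errors import ValidationError


class TestClassifyContext:
    @pytest.mark.parametrize(
        "seq, pos, expected",
        [
            ("ACGA", 1, "CG"),
            ("CAG", 0, "CHG"),
            ("CAU", 0, "CHH"),
            ("CCG", 0, "CHG"),
            ("ACG", 1, "CG"),
            ("AC", 1, "NA"),     # no downstream base
            ("AAC", 2, "NA"),    # C at the end
            ("CA", 0, "NA"),     # one downstream base, not G
        ],
    )
    def test_definition(self, seq, pos, expected):
        assert r.classify_context(seq, pos) == expected

    def test_single_downstream_cg_callable(self):
        assert r.classify_context("ACG", 1) == "CG"
        assert r.classify_context("CA", 0, min_downstream=1) == "CHH"

    def test_not_a_c_raises(self):
        with pytest.raises(ValidationError):
            r.classify_context("ACGU", 0)

    def test_contexts_partition_classifiable_cytosines(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGU"), size=500))
        contexts = [
            r.classify_context(seq, i) for i, b in enumerate(seq) if b == "C"
        ]
        classifiable = [c for c in contexts if c != "NA"]
        assert set(classifiable) <= {"CG", "CHG", "CHH"}
        assert len(classifiable) >= len(contexts) - 2  # only border Cs are NA


class TestRegions:
    tm = None

    def setup_method(self):
        seq = "A" * 10 + "AUG" + "C" * 84 + "AUG" + "A" * 10  # CDS [10, 100)
        self.tm = r.TranscriptModel("tx", seq, rna_class="mRNA", cds_start=10, cds_end=100)

    def test_half_open_boundaries(self):
        assert r.region_of(5, self.tm) == "5UTR"
        assert r.region_of(10, self.tm) == "CDS"
        assert r.region_of(99, self.tm) == "CDS"
        assert r.region_of(100, self.tm) == "3UTR"

    def test_noncoding_class(self):
        tm = r.TranscriptModel("t", "ACGU" * 10, rna_class="tRNA")
        assert r.region_of(3, tm) == "noncoding"

    def test_mrna_without_cds_is_na(self):
        tm = r.TranscriptModel("t", "ACGU" * 10, rna_class="mRNA")
        assert r.region_of(3, tm) == "NA"


class TestDistanceToStart:
    def test_convention_anchor_and_augc(self):
        seq = "AAAAAUGCAAA"  # AUG at 5..8, C at 8
        tm = r.TranscriptModel("t", seq, rna_class="mRNA", cds_start=5, cds_end=11)
        assert r.distance_to_start(5, tm) == 1   # the A of AUG
        assert r.distance_to_start(8, tm) == 4   # the C of AUGC
        assert r.distance_to_start(2, tm) == -2  # 3 nt before the A

    def test_missing_cds_gives_none(self):
        tm = r.TranscriptModel("t", "ACGU", rna_class="lncRNA")
        assert r.distance_to_start(1, tm) is None


class TestScanTranscripts:
    def test_one_annotation_per_cytosine(self, trained_model, sim_small):
        _, transcripts, _ = sim_small
        tms = [r.TranscriptModel(tid, seq) for tid, seq in list(transcripts.items())[:4]]
        anns = list(r.scan_transcripts(trained_model, tms))
        n_c = sum(tm.sequence.count("C") for tm in tms)
        assert len(anns) == n_c
        assert {(a.transcript_id, a.position) for a in anns} == {
            (tm.transcript_id, i)
            for tm in tms
            for i, b in enumerate(tm.sequence)
            if b == "C"
        }

    def test_zero_cytosines_zero_annotations(self, trained_model):
        tms = [r.TranscriptModel("t", "AGUAGU" * 10)]
        assert list(r.scan_transcripts(trained_model, tms)) == []

    def test_ccc_transcript_padded_windows(self, trained_model):
        tms = [r.TranscriptModel("t", "CCC")]
        anns = list(r.scan_transcripts(trained_model, tms))
        assert len(anns) == 3
        assert all(0.0 <= a.score <= 1.0 for a in anns)

    def test_planted_site_scores_highest(self, trained_model, sim_small):
        _, transcripts, truth = sim_small
        row = truth.iloc[0]
        tid = row.transcript_id
        tms = [r.TranscriptModel(tid, transcripts[tid])]
        anns = list(r.scan_transcripts(trained_model, tms))
        best = max(anns, key=lambda a: a.score)
        planted = set(
            truth[truth.transcript_id == tid].position.astype(int).tolist()
        )
        assert best.position in planted


class TestContextProportions:
    def test_all_cg(self):
        tm = r.TranscriptModel("t", "ACGACGACG")
        anns = [
            r.SiteAnnotation("t", i, 0.9, context="CG")
            for i, b in enumerate(tm.sequence)
            if b == "C"
        ]
        cand, bg = r.context_proportions(anns, [tm])
        assert cand == {"CG": 1.0, "CHG": 0.0, "CHH": 0.0}
        assert sum(bg.values()) == pytest.approx(1.0)

    def test_background_covers_all_cytosines(self):
        # candidates only CG but background counts every classifiable C
        tm = r.TranscriptModel("t", "ACGACAACAUCGA")
        anns = [r.SiteAnnotation("t", 1, 0.9, context="CG")]
        cand, bg = r.context_proportions(anns, [tm])
        assert cand["CG"] == 1.0
        assert bg["CHH"] > 0.0

    def test_zero_classifiable_raises(self):
        tm = r.TranscriptModel("t", "AAAA")
        with pytest.raises(ValidationError):
            r.context_proportions([], [tm])


class TestMetagene:
    def _mrna(self, tid="t"):
        seq = "U" * 30 + "AUG" + "C" * 57 + "A" * 30
        return r.TranscriptModel(tid, seq, rna_class="mRNA", cds_start=30, cds_end=90)

    def test_cds_midpoint_peak(self):
        tm = self._mrna()
        anns = [r.SiteAnnotation("t", 60, 0.9)]
        prof = r.metagene_profile(anns, [tm], bins_per_region=10)
        cds = prof[prof.region == "CDS"]
        assert cds["count"].sum() == 1
        assert cds.loc[cds["count"].idxmax(), "bin"] == 5

    def test_background_tracks_cytosine_availability(self):
        tm = self._mrna()
        prof = r.metagene_profile([], [tm], bins_per_region=5)
        # all cytosines are in the CDS of this construct
        assert prof[prof.region == "CDS"]["background_count"].sum() == 57
        assert prof[prof.region == "5UTR"]["background_count"].sum() == 0

    def test_cds_enrichment_recovered(self):
        rng = np.random.default_rng(8)
        tms = [self._mrna(f"t{i}") for i in range(5)]
        anns = []
        for tm in tms:
            # plant 8 CDS sites, 1 in the 3'UTR region boundary-free zone
            cds_positions = rng.choice(np.arange(33, 90), size=8, replace=False)
            anns += [r.SiteAnnotation(tm.transcript_id, int(p), 0.9) for p in cds_positions]
        prof = r.metagene_profile(anns, tms, bins_per_region=5)
        dens = prof.groupby("region")["density"].sum()
        assert dens["CDS"] > dens["5UTR"] and dens["CDS"] > dens["3UTR"]


GFF3 = """\
##gff-version 3
chr1\ttest\tgene\t1\t200\t.\t+\t.\tID=g1
chr1\ttest\tmRNA\t1\t200\t.\t+\t.\tID=m1;Parent=g1
chr1\ttest\texon\t1\t60\t.\t+\t.\tParent=m1
chr1\ttest\texon\t101\t200\t.\t+\t.\tParent=m1
chr1\ttest\tCDS\t31\t60\t.\t+\t.\tParent=m1
chr1\ttest\tCDS\t101\t130\t.\t+\t.\tParent=m1
chr1\ttest\ttRNA\t301\t380\t.\t-\t.\tID=trna1
chr1\ttest\texon\t301\t380\t.\t-\t.\tParent=trna1
"""


class TestGff3:
    @pytest.fixture()
    def genome(self):
        rng = np.random.default_rng(17)
        chrom = list(rng.choice(list("ACGT"), size=400))
        chrom[30:33] = list("ATG")  # start codon at CDS start
        return {"chr1": "".join(chrom)}

    def test_spliced_transcript_and_cds_mapping(self, tmp_path, genome):
        path = tmp_path / "a.gff3"
        path.write_text(GFF3)
        tms = {t.transcript_id: t for t in r.read_gff3_transcripts(path, genome)}
        m1 = tms["m1"]
        assert m1.rna_class == "mRNA"
        assert len(m1.sequence) == 160  # 60 + 100 spliced
        assert m1.cds_start == 30 and m1.cds_end == 90
        assert m1.sequence[30:33] == "AUG"

    def test_minus_strand_reverse_complemented(self, tmp_path, genome):
        path = tmp_path / "a.gff3"
        path.write_text(GFF3)
        tms = {t.transcript_id: t for t in r.read_gff3_transcripts(path, genome)}
        trna = tms["trna1"]
        assert trna.rna_class == "tRNA"
        genomic = genome["chr1"][300:380]
        rc = genomic[::-1].translate(str.maketrans("ACGT", "TGCA"))
        assert trna.sequence == rc.replace("T", "U")


class TestBedOverlap:
    def test_sites_and_peaks_counted(self, tmp_path):
        bed = tmp_path / "p.bed"
        bed.write_text("t1\t10\t20\nt1\t50\t60\nt2\t0\t5\n")
        intervals = read_bed(bed)
        anns = [
            r.SiteAnnotation("t1", 15, 0.9),
            r.SiteAnnotation("t1", 19, 0.9),
            r.SiteAnnotation("t1", 20, 0.9),  # half-open: outside
            r.SiteAnnotation("t3", 1, 0.9),
        ]
        n_in, n_cov = r.sites_in_intervals(anns, intervals)
        assert n_in == 2
        assert n_cov == 1
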