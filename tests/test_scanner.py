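"""PWM parsing, exact-p-value thresholds, and sequence scanning."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from atacmd.scanner import (
    DEFAULT_GRANULARITY,
    PWM,
    PwmParseError,
    parse_pwm,
    reverse_complement,
    scan_genome,
    scan_sequence,
    score_distribution,
    threshold_from_pvalue,
)
from conftest import random_sequence

MEME_TWO_MOTIFS = """MEME version 4

ALPHABET= ACGT

strands: + -

Background letter frequencies
A 0.25 C 0.25 G 0.25 T 0.25

MOTIF M1 FIRST
letter-probability matrix: alength= 4 w= 8 nsites= 20 E= 0
{rows8}
MOTIF M2
letter-probability matrix: alength= 4 w= 12 nsites= 20 E= 0
{rows12}
"""


def _meme_text():
    row = " 0.400000 0.300000 0.200000 0.100000\n"
    return MEME_TWO_MOTIFS.format(rows8=row * 8, rows12=row * 12)


class TestParsing:
    def test_meme_multi_motif_widths(self, tmp_path):
        path = tmp_path / "motifs.meme"
        path.write_text(_meme_text())
        pwms = parse_pwm(path)
        assert [p.motif_id for p in pwms] == ["M1", "M2"]
        assert [p.width for p in pwms] == [8, 12]
        assert np.allclose(pwms[0].matrix[0], [0.4, 0.3, 0.2, 0.1])

    def test_meme_bad_row_names_motif_and_line(self, tmp_path):
        text = _meme_text().replace(" 0.400000 0.300000 0.200000 0.100000", " 0.4 oops", 1)
        path = tmp_path / "bad.meme"
        path.write_text(text)
        with pytest.raises(PwmParseError, match="M1"):
            parse_pwm(path)

    def test_pcm_add_one_normalization(self, tmp_path):
        path = tmp_path / "TF1.pcm"
        path.write_text(">TF1\n8 0 0 0\n0 8 0 0\n")
        (pwm,) = parse_pwm(path, format="HOCOMOCO-PCM", pseudocount=1.0)
        assert pwm.motif_id == "TF1"
        assert np.allclose(pwm.matrix[0], [9 / 12, 1 / 12, 1 / 12, 1 / 12])

    def test_pcm_negative_counts_rejected(self, tmp_path):
        path = tmp_path / "neg.pcm"
        path.write_text("1 2 -3 4\n")
        with pytest.raises(PwmParseError, match="negative"):
            parse_pwm(path, format="HOCOMOCO-PCM")

    def test_pcm_id_falls_back_to_filename(self, tmp_path):
        path = tmp_path / "NAMELESS.txt"
        path.write_text("1 1 1 1\n2 2 2 2\n")
        (pwm,) = parse_pwm(path, format="HOCOMOCO-PCM")
        assert pwm.motif_id == "NAMELESS" and pwm.width == 2

    def test_uniform_probability_column_passes_through(self):
        pwm = PWM.from_probabilities("u", np.full((3, 4), 0.25))
        assert np.allclose(pwm.matrix, 0.25, atol=1e-9)

    def test_zero_probability_cells_are_smoothed_positive(self):
        pwm = PWM.from_probabilities("z", np.array([[1.0, 0.0, 0.0, 0.0]]))
        assert np.all(pwm.matrix > 0)
        assert np.isfinite(pwm.log_odds()).all()


class TestLogOdds:
    @pytest.mark.parametrize("p, expected", [(0.25, 0.0), (0.5, 1.0), (0.125, -1.0)])
    def test_bits_against_uniform_background(self, p, expected):
        rest = (1.0 - p) / 3
        pwm = PWM.from_probabilities("t", np.array([[p, rest, rest, rest]]))
        assert pwm.log_odds()[0, 0] == pytest.approx(expected, abs=1e-12)


def _enumerated_survival(pwm, granularity=DEFAULT_GRANULARITY):
    """Exhaustive background W-mer score distribution (integer-discretized)."""
    ilom = np.rint(pwm.log_odds() * granularity).astype(np.int64)
    scores = {}
    for word in itertools.product(range(4), repeat=pwm.width):
        s = int(sum(ilom[i, b] for i, b in enumerate(word)))
        prob = float(np.prod([pwm.background[b] for b in word]))
        scores[s] = scores.get(s, 0.0) + prob
    return scores


class TestThreshold:
    def test_width1_sharp_pwm_quartile_threshold(self):
        # only base A (1 of 4 equally likely) reaches its own log-odds score
        pwm = PWM.from_probabilities("t", np.array([[0.97, 0.01, 0.01, 0.01]]))
        t = threshold_from_pvalue(pwm, 0.25)
        assert t == pytest.approx(pwm.log_odds()[0, 0], abs=1 / DEFAULT_GRANULARITY)

    def test_pvalue_one_admits_everything(self):
        pwm = PWM.from_probabilities("t", np.array([[0.97, 0.01, 0.01, 0.01]]))
        t = threshold_from_pvalue(pwm, 1.0)
        assert t == pytest.approx(pwm.log_odds().min(), abs=1 / DEFAULT_GRANULARITY)

    def test_uniform_matrix_scores_zero_everywhere(self):
        pwm = PWM.from_probabilities("u", np.full((3, 4), 0.25))
        assert threshold_from_pvalue(pwm, 1.0) == 0.0
        # all 64 trimers pass: P(score >= 0) = 1
        low, dist = score_distribution(pwm)
        assert low == 0 and dist.tolist() == [1.0]

    @pytest.mark.parametrize("pvalue", [0.0, -0.1, 1.5])
    def test_pvalue_domain_checked(self, pvalue):
        pwm = PWM.from_probabilities("u", np.full((3, 4), 0.25))
        with pytest.raises(ValueError):
            threshold_from_pvalue(pwm, pvalue)

    @pytest.mark.parametrize("width", [1, 2, 3, 4, 5, 6])
    def test_dp_survival_equals_enumeration(self, width, rng):
        probs = rng.dirichlet(np.full(4, 0.7), size=width)
        pwm = PWM.from_probabilities(f"w{width}", probs)
        low, dist = score_distribution(pwm)
        enum = _enumerated_survival(pwm)
        for s, prob in enum.items():
            assert dist[s - low] == pytest.approx(prob, abs=1e-12)
        assert dist.sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("width", [2, 4, 6])
    def test_threshold_matches_enumeration(self, width, rng):
        probs = rng.dirichlet(np.full(4, 0.7), size=width)
        pwm = PWM.from_probabilities(f"w{width}", probs)
        enum = _enumerated_survival(pwm)
        ordered = sorted(enum)
        for pvalue in (1.0, 0.5, 0.1, 1e-2, 1e-3):
            tail = 0.0
            expected = None
            for s in reversed(ordered):
                tail += enum[s]
                if tail <= pvalue * (1 + 1e-12):
                    expected = s
            got = threshold_from_pvalue(pwm, pvalue) * DEFAULT_GRANULARITY
            if expected is None:
                assert got > max(ordered)
            else:
                assert round(got) == expected

    def test_lower_pvalue_never_lowers_threshold(self, sharp_pwm):
        thresholds = [
            threshold_from_pvalue(sharp_pwm, p) for p in (1.0, 0.1, 1e-2, 1e-4, 1e-6)
        ]
        assert thresholds == sorted(thresholds)


class TestScanSequence:
    def test_sequence_shorter_than_motif(self, sharp_pwm):
        assert scan_sequence("ACGTACG", "chr1", sharp_pwm, threshold=0.0) == []

    def test_planted_consensus_found_uniquely(self, sharp_pwm, rng):
        seq = random_sequence(rng, 400)
        seq = seq[:100] + sharp_pwm.consensus() + seq[108:]
        threshold = threshold_from_pvalue(sharp_pwm, 1e-4)
        hits = scan_sequence(seq, "chr1", sharp_pwm, threshold, strands="forward")
        # brute-force check: the planted window is the only one above threshold
        ilom = np.rint(sharp_pwm.log_odds() * DEFAULT_GRANULARITY).astype(int)
        code = np.array(["ACGT".index(c) for c in seq])
        brute = [
            i
            for i in range(len(seq) - 7)
            if sum(ilom[j, code[i + j]] for j in range(8))
            >= round(threshold * DEFAULT_GRANULARITY)
        ]
        assert [h.interval.start for h in hits] == brute == [100]
        assert hits[0].interval.end == 108 and hits[0].motif_id == "SHARP"

    def test_palindromic_match_reported_on_both_strands(self, palindromic_pwm):
        seq = "GGGGACGTGGGG"
        threshold = threshold_from_pvalue(palindromic_pwm, 1e-2)
        hits = scan_sequence(seq, "chr1", palindromic_pwm, threshold)
        starts = [(h.interval.start, h.strand) for h in hits]
        assert starts == [(4, "+"), (4, "-")]

    def test_windows_containing_n_are_skipped(self, sharp_pwm):
        consensus = sharp_pwm.consensus()
        seq = consensus[:4] + "N" + consensus[5:]
        assert scan_sequence(seq, "chr1", sharp_pwm, threshold=-100.0) == []

    def test_case_insensitive(self, sharp_pwm):
        threshold = threshold_from_pvalue(sharp_pwm, 1e-4)
        hits = scan_sequence(
            sharp_pwm.consensus().lower(), "chr1", sharp_pwm, threshold,
            strands="forward",
        )
        assert [h.interval.start for h in hits] == [0]

    @given(st.integers(0, 2**32 - 1))
    def test_strand_symmetry(self, sharp_pwm, seed):
        rng = np.random.default_rng(seed)
        seq = random_sequence(rng, 200)
        threshold = threshold_from_pvalue(sharp_pwm, 1e-2)
        fwd = scan_sequence(seq, "chr1", sharp_pwm, threshold)
        rev = scan_sequence(reverse_complement(seq), "chr1", sharp_pwm, threshold)
        # mirror coordinates and flip strand labels of the reverse scan
        mirrored = sorted(
            (len(seq) - h.interval.end, {"+": "-", "-": "+"}[h.strand], h.score)
            for h in rev
        )
        original = sorted((h.interval.start, h.strand, h.score) for h in fwd)
        assert mirrored == original

    def test_lower_pvalue_is_monotone_in_site_count(self, sharp_pwm, rng):
        seq = random_sequence(rng, 3000)
        counts = []
        for pvalue in (0.5, 0.1, 1e-2, 1e-4, 1e-6):
            t = threshold_from_pvalue(sharp_pwm, pvalue)
            counts.append(len(scan_sequence(seq, "chr1", sharp_pwm, t)))
        assert counts == sorted(counts, reverse=True)


class TestScanGenome:
    @pytest.fixture
    def toy_genome(self, tmp_path, sharp_pwm, rng):
        from atacmd.simulate import plant_consensus, write_fasta

        genome = {
            "chr1": random_sequence(rng, 2000),
            "chr2": random_sequence(rng, 1500),
        }
        genome = plant_consensus(
            genome, sharp_pwm, [("chr1", 300), ("chr1", 900), ("chr2", 700)]
        )
        fasta = tmp_path / "toy.fa"
        write_fasta(genome, fasta)
        return fasta

    def test_planted_sites_written_as_bed(self, toy_genome, tmp_path, sharp_pwm):
        out = tmp_path / "sites"
        written = scan_genome(toy_genome, [sharp_pwm], 1e-4, out)
        lines = written["SHARP"].read_text().splitlines()
        found = {(l.split("\t")[0], int(l.split("\t")[1])) for l in lines}
        assert {("chr1", 300), ("chr1", 900), ("chr2", 700)} <= found
        assert len(lines) >= 3
        for line in lines:
            fields = line.split("\t")
            assert len(fields) == 6 and fields[3] == "SHARP" and fields[5] in "+-"

    def test_motif_without_matches_writes_empty_file(
        self, toy_genome, tmp_path, sharp_pwm
    ):
        # a sharp width-16 motif: at p=2e-5 essentially only near-consensus
        # windows qualify, and none occur in 3.5 kb of random sequence; its
        # consensus AACCGGTTAACCGGTT shares no frame with the planted SHARP
        matrix = np.full((16, 4), 0.01)
        matrix[np.arange(16), [0, 0, 1, 1, 2, 2, 3, 3] * 2] = 0.97
        other = PWM.from_probabilities("OTHER", matrix / matrix.sum(1, keepdims=True))
        out = tmp_path / "sites2"
        written = scan_genome(toy_genome, [sharp_pwm, other], 2e-5, out)
        assert written["OTHER"].read_text() == ""
        assert written["SHARP"].read_text() != ""

    def test_rescan_is_byte_identical(self, toy_genome, tmp_path, sharp_pwm):
        out1 = tmp_path / "s1"
        out2 = tmp_path / "s2"
        scan_genome(toy_genome, [sharp_pwm], 1e-4, out1)
        scan_genome(toy_genome, [sharp_pwm], 1e-4, out2)
        assert (out1 / "SHARP.bed").read_bytes() == (out2 / "SHARP.bed").read_bytes()
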