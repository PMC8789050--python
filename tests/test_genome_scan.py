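import re

import numpy as np
import pandas as pd
import pytest

from guidegp.genome_scan import (
    CAS9_MASK,
    CAS12A_MASK,
    PAMMask,
    TargetSite,
    categorize_offtargets,
    enumerate_offtargets,
    guide_with_site_pam,
    scan_targets,
    score_and_rank,
)
from guidegp.sequence_io import reverse_complement

# ---------------------------------------------------------------- oracles

_IUPAC_RE = {"A": "A", "C": "C", "G": "G", "T": "T", "R": "[AG]", "N": "[ACGT]"}


def scan_oracle(seq, mask):
    """Regex brute force over both strands with overlapping matches."""
    pattern = re.compile("(?=(" + "".join(_IUPAC_RE[c] for c in mask.pattern) + "))")
    hits = []
    for m in pattern.finditer(seq):
        hits.append((m.start(1), "+", m.group(1)))
    rc = reverse_complement(seq)
    for m in pattern.finditer(rc):
        hits.append((len(seq) - m.start(1) - len(mask), "-", m.group(1)))
    return sorted(hits)


def offtarget_oracle(guide, seq, mask, max_mm):
    """Window-by-window Hamming count over both strands."""
    proto = mask.protospacer_positions
    pam = mask.pam_positions
    K = len(mask)
    hits = []
    for text, strand in ((seq, "+"), (reverse_complement(seq), "-")):
        for j in range(len(text) - K + 1):
            window = text[j : j + K]
            if any(window[p] not in _IUPAC_RE[mask.pattern[p]].strip("[]")
                   for p in pam):
                continue
            if any(window[p] not in "ACGT" for p in range(K)):
                continue
            mm = sum(window[p] != guide[r] for r, p in enumerate(proto))
            if mm <= max_mm:
                start = j if strand == "+" else len(seq) - j - K
                hits.append((start, strand, window, mm))
    return sorted(hits)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


# ---------------------------------------------------------------- masks


class TestPAMMask:
    def test_cas9_mask_structure(self):
        assert CAS9_MASK.pattern == "NNNNNNNNNNNNNNNNNNNNNRG"
        assert len(CAS9_MASK) == 23
        assert CAS9_MASK.protospacer_positions == tuple(range(21))

    def test_cas12a_mask_structure(self):
        assert CAS12A_MASK.pattern == "TTTNNNNNNNNNNNNNNNNNNNNN"
        assert CAS12A_MASK.pam_positions == (0, 1, 2)

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError, match="invalid mask"):
            PAMMask("NNXRG")


class TestScanTargets:
    def test_polyg_cas9_three_forward_sites(self):
        sites = scan_targets("G" * 25, CAS9_MASK)
        assert [(s.start, s.strand) for s in sites] == [(0, "+"), (1, "+"), (2, "+")]

    def test_polyt_cas9_no_sites(self):
        assert scan_targets("T" * 25, CAS9_MASK) == []

    def test_cas12a_five_prime_pam(self):
        sites = scan_targets("TTTA" + "A" * 21, CAS12A_MASK)
        fwd = [(s.start, s.strand) for s in sites if s.strand == "+"]
        assert fwd == [(0, "+")]

    def test_mask_longer_than_sequence_gives_empty(self):
        assert scan_targets("ACGT", CAS9_MASK) == []

    def test_minus_strand_coordinates_and_sequence(self):
        # CCN... reverse complement carries the NGG
        seq = "CC" + "A" * 21
        sites = scan_targets(seq, CAS9_MASK)
        assert len(sites) == 1
        site = sites[0]
        assert site.strand == "-" and site.start == 0
        assert site.seq == reverse_complement(seq)

    @pytest.mark.parametrize("mask", [CAS9_MASK, CAS12A_MASK])
    def test_matches_regex_oracle_on_random_sequences(self, mask):
        rng = np.random.default_rng(123)
        for _ in range(50):
            seq = random_seq(rng, int(rng.integers(200, 2001)))
            got = sorted((s.start, s.strand, s.seq) for s in scan_targets(seq, mask))
            assert got == scan_oracle(seq, mask)


class TestEnumerateOfftargets:
    def test_exact_site_has_zero_mismatches(self):
        guide = "G" * 21
        seq = "A" * 10 + "G" * 21 + "AGG" + "A" * 10
        hits = enumerate_offtargets(guide, seq, CAS9_MASK, max_mm=0)
        assert any(mm == 0 and t.strand == "+" for t, mm in hits)

    def test_max_mm_zero_only_exact(self):
        rng = np.random.default_rng(5)
        guide = random_seq(rng, 21)
        seq = random_seq(rng, 500)
        hits = enumerate_offtargets(guide, seq, CAS9_MASK, max_mm=0)
        for site, mm in hits:
            assert mm == 0
            proto = "".join(site.seq[p] for p in CAS9_MASK.protospacer_positions)
            assert proto == guide

    def test_guide_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="protospacer"):
            enumerate_offtargets("ACGT", "A" * 100, CAS9_MASK)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(77)
        for trial in range(5):
            guide = random_seq(rng, 21)
            seq = random_seq(rng, 2000)
            hits = enumerate_offtargets(guide, seq, CAS9_MASK, max_mm=6)
            got = sorted((t.start, t.strand, t.seq, mm) for t, mm in hits)
            assert got == offtarget_oracle(guide, seq, CAS9_MASK, 6)

    def test_pam_positions_never_counted_as_mismatches(self):
        guide = "A" * 21
        seq = "A" * 21 + "GG" + "C" * 5  # AGG PAM window at start 0? mask needs RG
        hits = enumerate_offtargets(guide, seq, CAS9_MASK, max_mm=0)
        starts = [t.start for t, mm in hits if t.strand == "+"]
        assert 0 in starts  # the A|GG tail satisfies R=A? no: R matches A or G
        # position 21 is 'R' and holds 'G'; position 22 is 'G' - matches, 0 mm


class TestGuideWithSitePam:
    def test_guide_embedded_pam_copied(self):
        site = "C" * 21 + "GG"
        full = guide_with_site_pam("A" * 21, site, CAS9_MASK)
        assert full == "A" * 21 + "GG"

    def test_wrong_guide_length_rejected(self):
        with pytest.raises(ValueError, match="protospacer"):
            guide_with_site_pam("A" * 5, "C" * 23, CAS9_MASK)


class _StubModel:
    """Minimal stand-in exposing the scoring interface (synthetic)."""

    def __init__(self, means, stds, input_length=23, is_pair=False):
        self.means = np.asarray(means, dtype=float)
        self.stds = np.asarray(stds, dtype=float)
        self.input_length = input_length
        self.is_pair = is_pair

    def predict(self, X, n_samples=None, seed=0):
        from guidegp.model import PosteriorPrediction

        n = len(X)
        return PosteriorPrediction(self.means[:n], self.stds[:n],
                                   np.zeros((n, 2)))


class TestScoreAndRank:
    def make_sites(self, n=4):
        return [TargetSite(i * 10, "+", "G" * 21 + "GG", "g") for i in range(n)]

    def test_table_schema_and_descending_order(self):
        model = _StubModel([0.2, 0.9, 0.5, 0.7], [0.1, 0.2, 0.1, 0.1])
        table = score_and_rank(model, self.make_sites())
        assert list(table.columns) == ["Start", "Sequence", "Strand", "Mean", "Variance"]
        assert list(table["Mean"]) == sorted(table["Mean"], reverse=True)
        assert len(table) == 4  # permutation of input, no loss

    def test_ties_break_by_variance_then_start(self):
        model = _StubModel([0.5, 0.5, 0.5, 0.9], [0.2, 0.1, 0.1, 0.3])
        table = score_and_rank(model, self.make_sites())
        assert list(table["Start"]) == [30, 10, 20, 0]

    def test_top_k_larger_than_site_count_returns_all(self):
        model = _StubModel([0.1, 0.2, 0.3, 0.4], [0.1] * 4)
        assert len(score_and_rank(model, self.make_sites(), top_k=100)) == 4

    def test_wrong_length_sites_skipped(self):
        model = _StubModel([0.5], [0.1], input_length=23)
        sites = [TargetSite(0, "+", "G" * 23, "g"), TargetSite(5, "+", "G" * 10, "g")]
        assert len(score_and_rank(model, sites)) == 1

    def test_no_usable_sites_raises(self):
        model = _StubModel([0.5], [0.1], input_length=23)
        with pytest.raises(ValueError, match="length"):
            score_and_rank(model, [TargetSite(0, "+", "GGG", "g")])

    def test_one_based_offset(self):
        model = _StubModel([0.5], [0.1])
        table = score_and_rank(model, self.make_sites(1), one_based=True)
        assert table.loc[0, "Start"] == 1


class TestCategorize:
    def test_one_record_per_category(self):
        rec = pd.DataFrame(
            {"guide": ["g"] * 4,
             "mean": [0.1, 0.2, 0.1, 0.2],
             "variance": [0.01, 0.01, 0.02, 0.02]}
        )
        out, props = categorize_offtargets(rec)
        assert sorted(out["category"]) == sorted(
            ["lowE_lowV", "highE_lowV", "lowE_highV", "highE_highV"]
        )
        np.testing.assert_allclose(props.loc["g"], 0.25)

    def test_boundary_equality_is_high(self):
        rec = pd.DataFrame({"guide": ["g"], "mean": [0.15], "variance": [0.015]})
        out, _ = categorize_offtargets(rec)
        assert out.loc[0, "category"] == "highE_highV"

    def test_single_low_low(self):
        rec = pd.DataFrame({"guide": ["g"], "mean": [0.10], "variance": [0.010]})
        out, _ = categorize_offtargets(rec)
        assert out.loc[0, "category"] == "lowE_lowV"

    def test_negative_variance_rejected(self):
        rec = pd.DataFrame({"guide": ["g"], "mean": [0.1], "variance": [-0.1]})
        with pytest.raises(ValueError, match="negative"):
            categorize_offtargets(rec)

    def test_proportions_sum_to_one_exactly(self, rng):
        rec = pd.DataFrame(
            {"guide": rng.choice(["a", "b", "c"], 100),
             "mean": rng.random(100),
             "variance": rng.random(100) * 0.05}
        )
        _, props = categorize_offtargets(rec)
        np.testing.assert_array_equal(props.sum(axis=1), 1.0)


class TestCLI:
    @pytest.fixture
    def runner(self):
        from click.testing import CliRunner

        return CliRunner()

    def test_scan_command(self, runner, tmp_path):
        from guidegp.cli import main

        fasta = tmp_path / "x.fa"
        fasta.write_text(">g\n" + "G" * 25 + "\n")
        result = runner.invoke(main, ["scan", str(fasta)])
        assert result.exit_code == 0
        assert result.output.count("\n") == 4  # header + 3 sites

    def test_offtargets_command(self, runner, tmp_path):
        from guidegp.cli import main

        fasta = tmp_path / "x.fa"
        fasta.write_text(">g\n" + "A" * 10 + "G" * 21 + "AGG" + "\n")
        result = runner.invoke(main, ["offtargets", "G" * 21, str(fasta),
                                      "--max-mm", "2"])
        assert result.exit_code == 0
        assert "Mismatches" in result.output

    def test_rank_command_with_checkpoint(self, runner, tmp_path, small_model):
        from guidegp.cli import main

        ckpt = tmp_path / "model.npz"
        small_model.save(ckpt)
        fasta = tmp_path / "x.fa"
        fasta.write_text(">g\n" + "G" * 30 + "\n")
        mask = "N" * 10 + "RG"  # 12 = the fixture model's input length
        result = runner.invoke(
            main,
            ["rank", str(fasta), "--model", str(ckpt), "--mask", "custom",
             "--custom-mask", mask, "--top-k", "5"],
        )
        assert result.exit_code == 0, result.output
        lines = [l for l in result.output.strip().splitlines() if l]
        assert lines[0].split("\t") == ["Gene", "Start", "Sequence", "Strand",
                                        "Mean", "Variance"]
        assert len(lines) == 6
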