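"""Pair classification, codon alignment, and NG86 Ka/Ks."""

import numpy as np
import pytest

from erf_survey import duplication_selection as ds, oracles, synthetic_data as sd
from erf_survey.io_formats import CdsRecord, GeneModel


def _model(gid, chrom, start, end):
    return GeneModel(gid, chrom, start, end, "+", [(start, end)])


class TestClassifyPair:
    def test_adjacent_same_chromosome_tandem(self):
        models = {
            "a": _model("a", "chr1", 1000, 2000),
            "b": _model("b", "chr1", 22000, 23000),
        }
        pair = ds.classify_pair(ds.GenePair("a", "b"), models)
        assert pair.relationship == "tandem"

    def test_different_chromosomes_segmental(self):
        models = {"a": _model("a", "chr1", 1, 100), "b": _model("b", "chr2", 1, 100)}
        assert ds.classify_pair(ds.GenePair("a", "b"), models).relationship == "segmental"

    def test_distant_with_many_intervening_segmental(self):
        models = {
            "a": _model("a", "chr1", 1000, 2000),
            "b": _model("b", "chr1", 2_001_000, 2_002_000),
        }
        for k in range(30):
            gid = f"x{k}"
            s = 10_000 + 60_000 * k
            models[gid] = _model(gid, "chr1", s, s + 1000)
        assert ds.classify_pair(ds.GenePair("a", "b"), models).relationship == "segmental"

    def test_missing_coordinates_unknown(self):
        with pytest.warns(UserWarning, match="missing coordinates"):
            pair = ds.classify_pair(ds.GenePair("a", "b"), {})
        assert pair.relationship == "unknown"

    def test_pair_canonicalized(self):
        pair = ds.GenePair("zzz", "aaa")
        assert (pair.gene_a, pair.gene_b) == ("aaa", "zzz")
        with pytest.raises(ValueError):
            ds.GenePair("a", "a")


class TestCodonAlign:
    def test_identical_cds_all_paired(self):
        cds = "ATGAAATTTGGG"
        pairs = ds.codon_align(cds, cds, ("MKFG", "MKFG"))
        assert len(pairs) == 4
        assert all(a == b for a, b in pairs)

    def test_gap_column_dropped(self):
        a, b = "ATGAAATTT", "ATGTTT"
        pairs = ds.codon_align(a, b, ("MKF", "M-F"))
        assert pairs == [("ATG", "ATG"), ("TTT", "TTT")]

    def test_terminal_stop_trimmed(self):
        pairs = ds.codon_align("ATGTTTTAA", "ATGTTTTGA", ("MF", "MF"))
        assert len(pairs) == 2

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop codon at codon 2"):
            ds.codon_align("ATGTAATTT", "ATGTAATTT", ("MXF", "MXF"))

    def test_translation_mismatch_named(self):
        with pytest.raises(ValueError, match="residue 2"):
            ds.codon_align("ATGAAATTT", "ATGAAATTT", ("MRF", "MRF"))


class TestNg86:
    def test_identical_cds_zero_rates(self):
        r = ds.ng86([("ATG", "ATG"), ("AAA", "AAA")])
        assert r.ka == 0.0 and r.ks == 0.0 and r.ratio is None

    def test_synonymous_only_change(self):
        # Phe TTT->TTC embedded in invariant context so JC does not saturate
        pairs = [("TTT", "TTC")] + [("GGG", "GGG")] * 10
        r = ds.ng86(pairs)
        assert r.ka == 0.0 and r.ks > 0.0
        ka_o, ks_o = oracles.ng86_oracle(pairs)
        assert r.ks == pytest.approx(ks_o, abs=1e-12)

    def test_nonsynonymous_only_change(self):
        pairs = [("GCT", "GTT")] + [("GGG", "GGG")] * 10
        r = ds.ng86(pairs)
        assert r.ks == 0.0 and r.ka > 0.0
        ka_o, _ = oracles.ng86_oracle(pairs)
        assert r.ka == pytest.approx(ka_o, abs=1e-12)

    def test_symmetry_exact(self):
        rng = np.random.default_rng(3)
        codons = [ds.SENSE_CODONS[i] for i in rng.integers(0, 61, size=40)]
        others = [ds.SENSE_CODONS[i] for i in rng.integers(0, 61, size=40)]
        fwd = ds.ng86(list(zip(codons, others)))
        rev = ds.ng86(list(zip(others, codons)))
        assert fwd.ka == rev.ka and fwd.ks == rev.ks

    def test_site_counts_sum_to_three_per_codon(self):
        rng = np.random.default_rng(4)
        pairs = [
            (ds.SENSE_CODONS[i], ds.SENSE_CODONS[j])
            for i, j in zip(rng.integers(0, 61, 25), rng.integers(0, 61, 25))
        ]
        r = ds.ng86(pairs)
        assert r.sites_syn + r.sites_nonsyn == pytest.approx(3 * len(pairs))

    def test_stop_codon_in_pair_rejected(self):
        with pytest.raises(ValueError):
            ds.ng86([("TAA", "ATG")])

    def test_simulated_purifying_pair(self):
        """A pair evolved with 10x non-synonymous suppression is flagged
        purifying."""
        a, b, _ = sd.generate_cds_pair(3000, ks_target=0.3, ka_target=0.03, seed=8)
        pairs = [
            (a.sequence[i : i + 3], b.sequence[i : i + 3])
            for i in range(0, len(a.sequence), 3)
        ]
        r = ds.ng86(pairs)
        assert r.ratio is not None and r.ratio < 1 and r.purifying

    def test_estimates_match_generating_targets(self):
        a, b, truth = sd.generate_cds_pair(10_000, ks_target=0.3, ka_target=0.1, seed=3)
        pairs = [
            (a.sequence[i : i + 3], b.sequence[i : i + 3])
            for i in range(0, len(a.sequence), 3)
        ]
        r = ds.ng86(pairs)
        # 2 standard errors of the JC-corrected proportions at this size
        se_ks = 2 * np.sqrt(0.26 * 0.74 / r.sites_syn) / (1 - 4 * 0.26 / 3)
        se_ka = 2 * np.sqrt(0.095 * 0.905 / r.sites_nonsyn) / (1 - 4 * 0.095 / 3)
        assert abs(r.ks - truth.ks_target) < se_ks
        assert abs(r.ka - truth.ka_target) < se_ka
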