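"""Domain detection, subfamily decision tree, EAR scan, physicochemistry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from erf_survey import domain_architecture as da
from erf_survey import oracles
from erf_survey import synthetic_data as sd
from erf_survey.io_formats import ProteinRecord
from tests.conftest import AP2_DREB_SEGMENT, AP2_ERF_SEGMENT

AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_protein(rng, length=300):
    return "".join(AA[i] for i in rng.integers(0, 20, size=length))


class TestDetector:
    def test_planted_motif_recovered(self, erf_protein):
        hits = da.detect_ap2_internal(erf_protein)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end) == (101, 121)
        assert hits[0].score == 1.0

    def test_two_embeds_two_nonoverlapping_hits(self):
        seq = "M" * 50 + AP2_ERF_SEGMENT + "M" * 100 + AP2_DREB_SEGMENT + "M" * 50
        hits = da.detect_ap2_internal(ProteinRecord("p", seq))
        assert len(hits) == 2
        assert hits[0].end < hits[1].start

    def test_false_positive_rate_below_one_percent(self):
        """Monte-Carlo: random 300-aa proteins essentially never reach the
        default score threshold."""
        rng = np.random.default_rng(2024)
        fp = sum(
            bool(da.detect_ap2_internal(ProteinRecord(f"r{i}", _random_protein(rng))))
            for i in range(2000)
        )
        assert fp / 2000 < 0.01

    def test_short_protein_no_crash(self):
        assert da.detect_ap2_internal(ProteinRecord("s", "MKV")) == []


class TestDecisionTree:
    def _hit(self, pid, kind, start, end):
        return da.DomainHit(pid, kind, start, end, 0.9, "table")

    @pytest.mark.parametrize(
        "kinds,expected",
        [
            (["AP2", "AP2"], "AP2"),
            (["AP2", "B3"], "RAV"),
            (["B3"], "RAV"),
            ([], "other"),
        ],
    )
    def test_architecture_rules(self, kinds, expected):
        seq = "M" * 200
        hits = [
            self._hit("p", k, 10 + 60 * i, 50 + 60 * i) for i, k in enumerate(kinds)
        ]
        call = da.classify_architecture(hits, ProteinRecord("p", seq))
        assert call.family == expected

    def test_single_ap2_with_signature_is_erf(self, erf_protein):
        hits = [self._hit("erf1", "AP2", 101, 121)]
        call = da.classify_architecture(hits, erf_protein)
        assert call.family == "ERF" and call.aaeird_present

    def test_single_ap2_without_signature_is_dreb(self):
        p = ProteinRecord("d", "M" * 100 + AP2_DREB_SEGMENT + "M" * 100)
        call = da.classify_architecture([self._hit("d", "AP2", 101, 121)], p)
        assert call.family == "DREB" and not call.aaeird_present

    def test_signature_slack_window(self):
        """AAEIRD just outside the envelope still counts within the slack."""
        p = ProteinRecord("p", "M" * 94 + "AAEIRD" + "M" * 100)
        call = da.classify_architecture([self._hit("p", "AP2", 98, 118)], p, signature_slack=3)
        assert call.family == "ERF"
        call2 = da.classify_architecture([self._hit("p", "AP2", 98, 118)], p, signature_slack=0)
        assert call2.family == "DREB"

    def test_hit_order_invariance(self, erf_protein):
        hits = [self._hit("erf1", "B3", 10, 50), self._hit("erf1", "AP2", 101, 121)]
        a = da.classify_architecture(hits, erf_protein)
        b = da.classify_architecture(hits[::-1], erf_protein)
        assert a == b

    def test_hit_beyond_protein_rejected(self):
        p = ProteinRecord("p", "M" * 50)
        with pytest.raises(ValueError, match="exceeds"):
            da.classify_architecture([self._hit("p", "AP2", 10, 80)], p)


class TestEarScan:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("MKLDLNLAPG", [(3, "LDLNLAP")]),
            ("FDLNFQP", [(1, "FDLNFQP")]),
            ("LDLNAQP", []),
            ("LDLNLAPDLNLPP", [(1, "LDLNLAP")]),
        ],
    )
    def test_pattern(self, seq, expected):
        hits = da.scan_ear(ProteinRecord("p", seq))
        assert [(h.start, h.matched_text) for h in hits] == expected

    def test_overlapping_matches_all_reported(self):
        # two overlapping heptamers sharing the L at position 5/1
        seq = "LDLNLDLNLLP" + "LDLNFAP"
        hits = da.scan_ear(ProteinRecord("p", seq))
        assert len(hits) >= 2


class TestPhysicoChem:
    def test_gravy_single_isoleucine(self):
        assert da.compute_physicochem(ProteinRecord("p", "I")).gravy == pytest.approx(4.5)

    def test_pi_matches_grid_oracle_on_random_peptides(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            seq = _random_protein(rng, int(rng.integers(10, 120)))
            fast = da.compute_physicochem(ProteinRecord("p", seq)).isoelectric_point
            slow = oracles.grid_search_pi(seq, step=0.001)
            assert fast == pytest.approx(slow, abs=0.01)

    def test_poly_gly_pi_is_terminal_driven(self):
        fast = da.compute_physicochem(ProteinRecord("p", "GGGGG")).isoelectric_point
        assert fast == pytest.approx(oracles.grid_search_pi("GGGGG"), abs=0.01)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.text(alphabet=AA, min_size=1, max_size=40))
    def test_appending_lysine_never_decreases_pi(self, seq):
        before = da.compute_physicochem(ProteinRecord("p", seq)).isoelectric_point
        after = da.compute_physicochem(ProteinRecord("p", seq + "K")).isoelectric_point
        assert after >= before - 1e-6

    def test_x_residues_flagged_approximate(self):
        phys = da.compute_physicochem(ProteinRecord("p", "MKVXLL"))
        assert phys.approximate and phys.length_aa == 6

    def test_empty_effective_sequence_errors(self):
        with pytest.raises(ValueError):
            da.compute_physicochem(ProteinRecord("p", "XXX"))


class TestIdentifyFunnel:
    def test_planted_family_recovery_table_path(self, small_proteome):
        records, rows, truth = small_proteome
        calls = da.identify_erf_set(records, rows)
        got = {c.protein_id: c.family for c in calls}
        for r in records:
            assert got.get(r.id, "other") == truth.family[r.id]

    def test_internal_path_recovers_non_rav(self, small_proteome):
        records, _rows, truth = small_proteome
        calls = da.identify_erf_set(records)
        got = {c.protein_id: c.family for c in calls}
        wrong = [
            r.id
            for r in records
            if truth.family[r.id] != "RAV" and got.get(r.id, "other") != truth.family[r.id]
        ]
        assert not wrong

    def test_cross_path_consistency(self, small_proteome):
        """Table and internal paths agree wherever their hits agree (all
        non-RAV proteins in this construction)."""
        records, rows, truth = small_proteome
        table_calls = {c.protein_id: c.family for c in da.identify_erf_set(records, rows)}
        internal_calls = {c.protein_id: c.family for c in da.identify_erf_set(records)}
        for r in records:
            if truth.family[r.id] == "RAV":
                continue
            assert table_calls.get(r.id, "other") == internal_calls.get(r.id, "other")

    def test_empty_proteome(self):
        assert da.identify_erf_set([]) == []

    def test_unknown_table_id_rejected(self, small_proteome):
        records, rows, _ = small_proteome
        from erf_survey.io_formats import DomainTableRow

        bad = list(rows) + [DomainTableRow("NOPE", "AP2", 1e-9, 1, 21)]
        with pytest.raises(ValueError, match="NOPE"):
            da.identify_erf_set(records, bad)

    def test_labels_partition_input(self, small_proteome):
        records, rows, _ = small_proteome
        calls = da.identify_erf_set(records, rows)
        ids = [c.protein_id for c in calls]
        assert len(ids) == len(set(ids))
        assert all(c.family in {"AP2", "RAV", "ERF", "DREB", "other"} for c in calls)
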