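import math

import numpy as np
import pytest

from coevonet import metrics as M
from coevonet.labels import COIL, HELIX, SHEET, SS_MASKED


def naive_top_lk_precision(p, y, lo, hi, k):
    """O(L^2) reference: explicit candidate list, stable sort, count hits."""
    L = p.shape[0]
    cands = []
    for i in range(L):
        for j in range(i + 1, L):
            s = j - i
            if lo <= s <= hi and np.isfinite(y[i, j]):
                cands.append((-p[i, j], s, i, j))
    if not cands:
        return None
    cands.sort()
    take = cands[: math.ceil(L / k)]
    hits = sum(y[i, j] == 1.0 for _, _, i, j in take)
    return hits / len(take)


def random_instance(rng, L=20):
    p = rng.random((L, L))
    p = (p + p.T) / 2
    y = (rng.random((L, L)) < 0.15).astype(float)
    y = np.maximum(y, y.T)
    mask = rng.random((L, L)) < 0.05
    mask = mask | mask.T
    y[mask] = np.nan
    np.fill_diagonal(y, 0.0)
    return p, y


class TestTopLkPrecision:
    def test_all_selected_true(self):
        L = 12
        y = np.ones((L, L))
        p = np.random.default_rng(0).random((L, L))
        p = (p + p.T) / 2
        assert M.top_lk_precision(p, y, "short", 2) == 1.0

    def test_hand_enumerated_short_range_case(self):
        """L=12, k=2 -> ceil(12/2)=6 short-range pairs selected, 4 true."""
        L = 12
        y = np.zeros((L, L))
        p = np.zeros((L, L))
        # six highest-probability short-range pairs, four of them contacts
        chosen = [(0, 6), (1, 7), (2, 8), (3, 9), (0, 11), (4, 10)]
        for rank, (i, j) in enumerate(chosen):
            p[i, j] = p[j, i] = 0.9 - 0.01 * rank
        for i, j in chosen[:4]:
            y[i, j] = y[j, i] = 1.0
        # a seventh, lower-probability true pair must not be selected
        p[5, 11] = p[11, 5] = 0.5
        y[5, 11] = y[11, 5] = 1.0
        assert M.top_lk_precision(p, y, "short", 2) == pytest.approx(4 / 6)

    def test_perfect_anti_predictor(self):
        rng = np.random.default_rng(1)
        _, y = random_instance(rng)
        y = np.nan_to_num(y)
        p = 1.0 - y
        assert M.top_lk_precision(p, y, "all", 5) == 0.0

    def test_empty_bin_reports_absent(self):
        y = np.zeros((8, 8))  # L=8: no pair reaches separation 24
        p = np.random.default_rng(2).random((8, 8))
        assert M.top_lk_precision(p, y, "long", 1) is None

    def test_truncation_flagged(self):
        L = 30
        y = np.full((L, L), np.nan)
        y[0, 24] = y[24, 0] = 1.0  # a single unmasked long-range pair
        rep = M.top_lk_report(np.ones((L, L)) * 0.5, y, "long", 1)
        assert rep["truncated"] and rep["n_selected"] == 1
        assert rep["precision"] == 1.0

    @pytest.mark.parametrize("bin_name,k", [("short", 10), ("medium", 5), ("long", 2), ("all", 1)])
    def test_matches_naive_reference(self, bin_name, k):
        rng = np.random.default_rng(hash((bin_name, k)) % 2**31)
        rb = M.RANGE_BINS[bin_name]
        for _ in range(20):
            p, y = random_instance(rng, L=int(rng.integers(8, 40)))
            got = M.top_lk_precision(p, y, bin_name, k)
            want = naive_top_lk_precision(p, y, rb.lo, rb.hi, k)
            assert (got is None and want is None) or got == pytest.approx(want)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(3)
        p, y = random_instance(rng)
        a = M.top_lk_precision(p, y, "all", 5)
        b = M.top_lk_precision(np.sqrt(p) * 3 + 1, y, "all", 5)
        assert a == b

    def test_range_bins_disjoint_and_exclude_trivial(self):
        assert M.SHORT.lo == 6 and M.SHORT.hi == 11
        assert M.MEDIUM.lo == 12 and M.MEDIUM.hi == 23
        assert M.LONG.lo == 24
        for s in range(0, 6):
            assert not any(b.contains(np.array([s])) for b in (M.SHORT, M.MEDIUM, M.LONG))


class TestSSMetrics:
    def test_perfect_prediction(self):
        t = np.array([HELIX, SHEET, COIL, HELIX])
        rep = M.ss_metrics(t, t)
        assert rep["accuracy"] == 1.0
        for cls in "HEC":
            assert rep["per_class"][cls]["recall"] == 1.0
            assert rep["per_class"][cls]["precision"] == 1.0

    def test_confusion_arithmetic(self):
        # truth H H E C predicted H E E C
        t = np.array([HELIX, HELIX, SHEET, COIL])
        q = np.array([HELIX, SHEET, SHEET, COIL])
        rep = M.ss_metrics(t, q)
        assert rep["accuracy"] == 0.75
        assert rep["per_class"]["H"]["recall"] == 0.5
        assert rep["per_class"]["E"]["precision"] == 0.5

    def test_absent_class_reports_none(self):
        t = np.array([HELIX, HELIX])
        q = np.array([HELIX, HELIX])
        rep = M.ss_metrics(t, q)
        assert rep["per_class"]["E"]["recall"] is None

    def test_masked_residues_excluded(self):
        t = np.array([HELIX, SS_MASKED])
        q = np.array([HELIX, COIL])
        assert M.ss_metrics(t, q)["accuracy"] == 1.0

    def test_probability_input_argmaxed(self):
        t = np.array([HELIX, COIL])
        probs = np.array([[0.7, 0.2, 0.1], [0.1, 0.2, 0.7]])
        assert M.ss_metrics(t, probs)["accuracy"] == 1.0


class TestAsaAccuracy:
    def test_perfect(self):
        asa = np.array([10.0, 60.0, 100.0])
        assert M.asa_three_state_accuracy(asa, asa, ["A", "A", "A"]) == 1.0

    def test_all_shifted_to_exposed(self):
        true = np.array([5.0, 6.0])  # buried on alanine (max 129)
        pred = np.array([120.0, 125.0])  # > 40%
        assert M.asa_three_state_accuracy(true, pred, ["A", "A"]) == 0.0

    def test_mixed_hand_case(self):
        # alanine rel thresholds: B < 12.9, M <= 51.6, E above
        true = np.array([5.0, 20.0, 100.0, 60.0, np.nan])
        pred = np.array([10.0, 60.0, 110.0, 5.0, 50.0])
        # states: true B M E E -, pred B E E B - -> 2/4 correct
        assert M.asa_three_state_accuracy(true, pred, ["A"] * 5) == 0.5


class TestContactTypes:
    def test_hs_is_unordered(self):
        L = 16
        ss = np.full(L, COIL)
        ss[0], ss[8] = HELIX, SHEET
        ss[1], ss[9] = SHEET, HELIX
        y = np.zeros((L, L))
        p = np.zeros((L, L))
        for i, j in [(0, 8), (1, 9)]:
            y[i, j] = y[j, i] = 1.0
            p[i, j] = p[j, i] = 0.9
        rep = M.contact_type_metrics(p, y, ss)
        assert rep["HS"]["recall"] == 1.0 and rep["HS"]["precision"] == 1.0

    def test_coil_pairs_untyped(self):
        L = 16
        ss = np.full(L, COIL)
        y = np.zeros((L, L))
        y[0, 8] = y[8, 0] = 1.0
        p = y.copy()
        rep = M.contact_type_metrics(p, y, ss)
        for t in M.CONTACT_TYPES:
            assert rep[t]["recall"] is None and rep[t]["precision"] is None

    def test_enumerated_mistakes_per_type(self):
        L = 20
        ss = np.full(L, COIL)
        helix, sheet = [0, 1, 12, 13], [6, 7, 18, 19]
        for i in helix:
            ss[i] = HELIX
        for i in sheet:
            ss[i] = SHEET
        y = np.zeros((L, L))
        p = np.zeros((L, L))
        # one hit and one miss per type
        cases = [
            ((0, 12), (1, 13)),  # HH: predicted hit, unpredicted true
            ((0, 6), (1, 7)),    # HS
            ((6, 18), (7, 19)),  # SS
        ]
        for hit, miss in cases:
            y[hit] = y[hit[::-1]] = 1.0
            y[miss] = y[miss[::-1]] = 1.0
            p[hit] = p[hit[::-1]] = 0.95
        rep = M.contact_type_metrics(p, y, ss, selection=[h for h, _ in cases])
        for t in M.CONTACT_TYPES:
            assert rep[t]["recall"] == pytest.approx(0.5)
            assert rep[t]["precision"] == 1.0


class TestTopContactExport:
    def test_selection_rules(self):
        rng = np.random.default_rng(4)
        L = 10
        p = rng.random((L, L))
        p = (p + p.T) / 2
        pairs = M.select_top_contacts(p)
        assert len(pairs) <= 2 * L
        probs = [pr for _, _, pr in pairs]
        assert probs == sorted(probs, reverse=True)
        assert all(j - i >= 6 for i, j, _ in pairs)

    def test_rr_format_line(self):
        text = M.write_casp_rr([(0, 7, 0.9)], "ACDEFGHK")
        assert "1 8 0 8 0.9" in text.splitlines()

    def test_rr_roundtrip(self):
        seq = "ACDEFGHIKLMNPQRSTVWY" * 3
        pairs = [(0, 7, 0.9), (2, 59, 0.25), (10, 30, 0.5)]
        seq_back, pairs_back = M.read_casp_rr(M.write_casp_rr(pairs, seq))
        assert seq_back == seq
        assert pairs_back == pairs

    def test_i_less_than_j_enforced(self):
        text = M.write_casp_rr([(7, 0, 0.5)], "ACDEFGHK")
        _, pairs = M.read_casp_rr(text)
        assert pairs == [(0, 7, 0.5)]
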