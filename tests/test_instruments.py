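"""BDI scoring/subtyping, SF-36 scoring, and derived covariates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from eprsqol.instruments import (
    BdiItemMap,
    Sf36Norms,
    comorbidity_class,
    derive_covariates,
    glucose_status,
    homa_ir,
    ltpa_met_hours,
    score_bdi,
    score_sf36,
)
from eprsqol.instruments.bdi import DEFAULT_ITEM_MAP
from eprsqol.instruments.sf36 import (
    DOMAINS,
    DOMAIN_ITEMS,
    ITEM_TABLE,
    best_response,
    components,
    domain_scores,
    recode_items,
    score_sf36_frame,
    worst_response,
)


class TestBdi:
    def test_all_zero_items(self):
        res = score_bdi([0] * 21)
        assert res.total == 0 and not res.depressed and res.subtype == "none"

    def test_maximum_score_ties_to_melancholic(self):
        res = score_bdi([3] * 21)
        assert res.total == 63 and res.depressed
        assert res.mel_mean == res.nonmel_mean == 3.0
        assert res.subtype == "melancholic"

    def test_total_nine_is_below_threshold(self):
        items = [1] * 9 + [0] * 12
        res = score_bdi(items)
        assert res.total == 9 and not res.depressed and res.subtype == "none"

    def test_total_ten_is_depressed(self):
        items = [1] * 10 + [0] * 11
        assert score_bdi(items).depressed

    def test_subscale_means_decide_subtype_and_swap_flips_it(self):
        items = np.zeros(21, dtype=int)
        mel_idx = np.array(DEFAULT_ITEM_MAP.melancholic) - 1
        nonmel_idx = np.array(DEFAULT_ITEM_MAP.non_melancholic) - 1
        items[mel_idx] = 1  # mel mean 1.0
        items[nonmel_idx[:3]] = 1  # nonmel mean 0.25
        res = score_bdi(items.tolist())
        assert res.total == 12 and res.subtype == "melancholic"
        assert res.mel_mean == pytest.approx(1.0)
        assert res.nonmel_mean == pytest.approx(0.25)
        # swap subscale loadings -> non-melancholic (needs total >= 10 still)
        swapped = np.zeros(21, dtype=int)
        swapped[nonmel_idx] = 1
        swapped[mel_idx[:3]] = 1
        res2 = score_bdi(swapped.tolist())
        assert res2.subtype == "non_melancholic"

    def test_input_validation(self):
        with pytest.raises(ValueError):
            score_bdi([0] * 20)
        with pytest.raises(ValueError):
            score_bdi([0] * 20 + [4])
        with pytest.raises(ValueError):
            BdiItemMap(melancholic=(1, 1, 2))

    @given(hst.lists(hst.integers(0, 3), min_size=21, max_size=21),
           hst.randoms(use_true_random=False))
    @settings(max_examples=60, deadline=None)
    def test_total_permutation_invariant(self, items, rnd):
        perm = list(range(21))
        rnd.shuffle(perm)
        assert score_bdi(items).total == score_bdi([items[i] for i in perm]).total

    @given(hst.lists(hst.integers(0, 3), min_size=21, max_size=21),
           hst.integers(0, 8))
    @settings(max_examples=80, deadline=None)
    def test_raising_melancholic_item_never_flips_to_nonmelancholic(self, items, k):
        res = score_bdi(items)
        if res.subtype != "melancholic":
            return
        pos = DEFAULT_ITEM_MAP.melancholic[k] - 1
        bumped = list(items)
        bumped[pos] = min(3, bumped[pos] + 1)
        assert score_bdi(bumped).subtype == "melancholic"


def _norming_domains(n=600, seed=21):
    """Synthetic norming sample of domain scores with two latent components."""
    rng = np.random.default_rng(seed)
    m = rng.normal(0, 10, n)
    p = rng.normal(0, 10, n)
    cols = {}
    for d in DOMAINS:
        latent = p if d in ("pf", "rp", "bp", "gh") else m
        cols[d] = np.clip(60 + 1.5 * latent + rng.normal(0, 8, n), 0, 100)
    return pd.DataFrame(cols)


class TestSf36:
    def test_best_responses_score_100_everywhere(self):
        items = [best_response(i) for i in range(1, 37)]
        norms = Sf36Norms.us_1990()
        res = score_sf36(items, norms)
        assert res.domains.tolist() == pytest.approx([100.0] * 8)

    def test_worst_responses_score_0_everywhere(self):
        items = [worst_response(i) for i in range(1, 37)]
        res = score_sf36(items, Sf36Norms.us_1990())
        assert res.domains.tolist() == pytest.approx([0.0] * 8)

    def test_norming_sample_components_have_mean_50_sd_10(self):
        dom = _norming_domains()
        norms = Sf36Norms.from_sample(dom)
        comp = components(dom, norms)
        for c in ("pcs", "mcs"):
            assert comp[c].mean() == pytest.approx(50.0, abs=1e-6)
            assert comp[c].std(ddof=1) == pytest.approx(10.0, abs=1e-6)

    def test_component_labels_follow_domain_structure(self):
        dom = _norming_domains()
        norms = Sf36Norms.from_sample(dom)
        # physical domains must dominate the PCS coefficients
        phys = norms.coef_pcs[["pf", "rp", "bp", "gh"]].abs().sum()
        ment = norms.coef_pcs[["vt", "sf", "re", "mh"]].abs().sum()
        assert phys > ment
        # higher mental-domain scores raise MCS
        assert norms.coef_mcs[["vt", "sf", "re", "mh"]].sum() > 0

    def test_half_scale_rule(self):
        items = [float(best_response(i)) for i in range(1, 37)]
        frame = pd.DataFrame([items], columns=[f"sf36_{i}" for i in range(1, 37)])
        # physical functioning has 10 items (items 3-12): blank 5 -> still scored
        f1 = frame.copy()
        f1.iloc[0, 2:7] = np.nan
        d1 = domain_scores(recode_items(f1))
        assert d1.loc[0, "pf"] == pytest.approx(100.0)
        # blank 6 of 10 -> unscorable, flagged missing
        f2 = frame.copy()
        f2.iloc[0, 2:8] = np.nan
        d2 = domain_scores(recode_items(f2))
        assert np.isnan(d2.loc[0, "pf"])
        # dependent component is missing, not fabricated
        comp = components(d2, Sf36Norms.us_1990())
        assert np.isnan(comp.loc[0, "pcs"])

    def test_item_increment_moves_domain_by_step_over_k(self):
        # one recode step on one item of a k-item domain moves the domain mean
        # by step/k
        for d in DOMAINS:
            items = {i: best_response(i) for i in range(1, 37)}
            first = DOMAIN_ITEMS[d][0]
            rec = np.asarray(ITEM_TABLE[first][1])
            order = np.argsort(rec)
            second_best = int(order[-2]) + 1
            items2 = dict(items)
            items2[first] = second_best
            f = pd.DataFrame(
                [list(items.values()), list(items2.values())],
                columns=[f"sf36_{i}" for i in range(1, 37)],
            )
            dom = domain_scores(recode_items(f))
            k = len(DOMAIN_ITEMS[d])
            step = 100.0 - float(rec[order[-2]])
            assert dom.loc[0, d] - dom.loc[1, d] == pytest.approx(step / k)

    def test_out_of_range_code_rejected(self):
        items = [best_response(i) for i in range(1, 37)]
        items[0] = 9
        with pytest.raises(ValueError):
            score_sf36(items, Sf36Norms.us_1990())

    def test_frame_and_single_row_scoring_agree(self):
        rng = np.random.default_rng(22)
        items = [int(rng.integers(1, len(ITEM_TABLE[i][1]) + 1)) for i in range(1, 37)]
        norms = Sf36Norms.us_1990()
        single = score_sf36(items, norms)
        frame = score_sf36_frame(
            pd.DataFrame([items], columns=[f"sf36_{i}" for i in range(1, 37)]), norms
        )
        assert single.mcs == pytest.approx(frame.loc[0, "mcs"])
        assert single.pcs == pytest.approx(frame.loc[0, "pcs"])


class TestCovariates:
    def test_homa_formula(self):
        assert homa_ir(22.5, 1.0) == pytest.approx(1.0)
        assert homa_ir(5.0, 9.0) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            homa_ir(-1.0, 5.0)

    def test_ltpa_met_hours(self):
        assert ltpa_met_hours([(7, 1, 3)]) == pytest.approx(21.0)
        assert ltpa_met_hours([(7, 1, 3), (3, 0.5, 2)]) == pytest.approx(24.0)

    def test_comorbidity_class_caps_at_two_plus(self):
        assert comorbidity_class(0) == "0"
        assert comorbidity_class(1) == "1"
        assert comorbidity_class(3) == "2+"

    @pytest.mark.parametrize(
        "fg,g2,flag,expected",
        [
            (7.2, 6.0, False, "diabetes"),
            (5.5, 8.5, False, "prediabetes"),
            (5.5, 11.5, False, "diabetes"),
            (6.5, 6.0, False, "prediabetes"),
            (5.5, 6.0, False, "normoglycaemia"),
            (5.5, 6.0, True, "diabetes"),
            (6.1, 7.8, False, "prediabetes"),
            (7.0, 0.0, False, "diabetes"),
        ],
    )
    def test_who_2006_decision_table(self, fg, g2, flag, expected):
        assert glucose_status(fg, g2, flag) == expected

    def test_derive_covariates_record(self):
        raw = {
            "age": 61.0, "sex": "female", "smoking": "never",
            "alcohol": "weekly", "ses": "manual", "n_chronic": 2, "bmi": 27.0,
            "glucose_0": 5.0, "glucose_120": 6.0, "insulin_0": 9.0,
            "ltpa_met_1": 7.0, "ltpa_hours_1": 1.0, "ltpa_freq_1": 3.0,
        }
        rec = derive_covariates(raw)
        assert rec.homa_ir == pytest.approx(2.0)
        assert rec.ltpa_met_h_wk == pytest.approx(21.0)
        assert rec.comorbidity_class == "2+"
        assert rec.glucose_status == "normoglycaemia"
        with pytest.raises(ValueError):
            derive_covariates({**raw, "bmi": 0.0})
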