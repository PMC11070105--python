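"""Agreement statistics against hand computations, sklearn, and oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score, f1_score, recall_score

from cardiosleep.metrics import (
    bland_altman,
    efficiency_sweep,
    epoch_metrics,
    estimate_ahi,
    estimate_rei,
    estimate_tst,
    mae,
    nbl_classes,
    severity_class,
    severity_confusion,
    spearman,
)


class TestEpochMetrics:
    def test_perfect_agreement(self):
        y = np.array([0, 1, 1, 0, 1, 1])
        m = epoch_metrics(y, y)
        assert m["kappa"] == pytest.approx(1.0)
        assert m["f1_sleep"] == pytest.approx(1.0)
        assert m["f1_wake"] == pytest.approx(1.0)

    def test_chance_agreement_kappa_zero(self):
        # confusion [[25,25],[25,25]]
        ref = np.repeat([0, 0, 1, 1], 25)
        pred = np.tile([0, 1], 50)
        m = epoch_metrics(pred, ref)
        assert m["kappa"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_kappa(self):
        # confusion [[40,10],[5,45]]: po=0.85, pe=0.5, kappa=0.70
        ref = np.concatenate([np.zeros(50, int), np.ones(50, int)])
        pred = np.concatenate(
            [np.zeros(40, int), np.ones(10, int), np.zeros(5, int), np.ones(45, int)]
        )
        m = epoch_metrics(pred, ref)
        assert m["kappa"] == pytest.approx(0.70)

    def test_single_class_reference_reported_missing(self):
        m = epoch_metrics(np.array([1, 1, 0]), np.array([1, 1, 1]))
        assert np.isnan(m["kappa"])
        assert "single class" in m["kappa_missing_reason"]

    def test_agrees_with_sklearn_on_random_confusions(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(20, 200))
            ref = (rng.random(n) < rng.uniform(0.2, 0.8)).astype(int)
            pred = (rng.random(n) < rng.uniform(0.2, 0.8)).astype(int)
            if len(np.unique(ref)) < 2 or len(np.unique(pred)) < 2:
                continue
            m = epoch_metrics(pred, ref)
            assert m["kappa"] == pytest.approx(cohen_kappa_score(ref, pred))
            assert m["f1_sleep"] == pytest.approx(
                f1_score(ref, pred, pos_label=1)
            )
            assert m["f1_wake"] == pytest.approx(
                f1_score(ref, pred, pos_label=0)
            )
            assert m["sensitivity_sleep"] == pytest.approx(
                recall_score(ref, pred, pos_label=1)
            )
            assert m["specificity_sleep"] == pytest.approx(
                recall_score(ref, pred, pos_label=0)
            )


class TestEstimators:
    def test_tst_from_epochs(self):
        assert estimate_tst(np.ones(840, int)) == pytest.approx(7.0)

    def test_ahi_and_rei(self):
        assert estimate_ahi(35, 7.0) == pytest.approx(5.0)
        assert estimate_rei(35, 8.0) == pytest.approx(4.375)

    def test_ahi_dominates_rei(self):
        for n in (0, 5, 50):
            assert estimate_ahi(n, 6.0) >= estimate_rei(n, 8.0)

    def test_zero_tst_flags_undefined(self):
        assert np.isnan(estimate_ahi(3, 0.0))
        assert estimate_ahi(0, 0.0) == 0.0


class TestSeverity:
    @pytest.mark.parametrize(
        "ahi,cls",
        [(0.0, "normal"), (4.9, "normal"), (5.0, "mild"), (14.99, "mild"),
         (15.0, "moderate"), (29.9, "moderate"), (30.0, "severe"),
         (108.4, "severe")],
    )
    def test_boundaries(self, ahi, cls):
        assert severity_class(ahi) == cls

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            severity_class(-1.0)

    def test_nbl_far_from_boundary_singleton(self):
        assert nbl_classes(10.0) == {"mild"}
        assert nbl_classes(50.0) == {"severe"}

    def test_nbl_inside_zone_doubles(self):
        # zone at 15 has half-width 1.5
        assert nbl_classes(15.0 + 0.75) == {"mild", "moderate"}
        assert nbl_classes(15.0 - 1.5) == {"mild", "moderate"}
        assert nbl_classes(4.6) == {"normal", "mild"}

    def test_confusion_identity(self):
        ref = [2.0, 10.0, 20.0, 50.0]
        out = severity_confusion(ref, ref)
        assert out["accuracy"] == 1.0
        assert out["kappa"] == pytest.approx(1.0)
        nbl = severity_confusion(ref, ref, nbl=True)
        assert np.array_equal(nbl["confusion"], out["confusion"])

    def test_nbl_rescues_near_boundary_miss(self):
        ref = [2.0, 14.2, 20.0, 50.0]  # 14.2 is within the 15 +/- 1.5 zone
        est = [2.0, 16.0, 20.0, 50.0]  # misclassified as moderate
        plain = severity_confusion(ref, est)
        nbl = severity_confusion(ref, est, nbl=True)
        assert plain["accuracy"] == pytest.approx(0.75)
        assert nbl["accuracy"] == pytest.approx(1.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_nbl_accuracy_never_below_plain(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        ref = rng.uniform(0, 60, n).tolist()
        est = rng.uniform(0, 60, n).tolist()
        plain = severity_confusion(ref, est)
        nbl = severity_confusion(ref, est, nbl=True)
        assert nbl["accuracy"] >= plain["accuracy"]


class TestAgreement:
    def test_identity(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        ba = bland_altman(x, x)
        assert ba == {"bias": 0.0, "loa_low": 0.0, "loa_high": 0.0}
        assert spearman(x, x) == pytest.approx(1.0)
        assert mae(x, x) == 0.0

    def test_constant_offset(self):
        x = np.array([1.0, 2.0, 3.0])
        ba = bland_altman(x, x + 1)
        assert ba["bias"] == pytest.approx(1.0)
        assert ba["loa_low"] == pytest.approx(1.0)
        assert ba["loa_high"] == pytest.approx(1.0)
        assert mae(x, x + 1) == pytest.approx(1.0)

    def test_against_definition_oracles(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(10, 5, 20)
        est = ref + rng.normal(0, 2, 20)
        ba = bland_altman(ref, est)
        d = est - ref
        sd = np.sqrt(((d - d.mean()) ** 2).sum() / (d.size - 1))
        assert ba["bias"] == pytest.approx(d.mean(), abs=1e-10)
        assert ba["loa_low"] == pytest.approx(d.mean() - 1.96 * sd, abs=1e-10)
        assert ba["loa_high"] == pytest.approx(d.mean() + 1.96 * sd, abs=1e-10)

        # Spearman oracle: Pearson on average ranks
        def ranks(v):
            order = np.argsort(v)
            r = np.empty(v.size)
            r[order] = np.arange(1, v.size + 1)
            for val in np.unique(v):
                m = v == val
                r[m] = r[m].mean()
            return r

        ra, rb = ranks(ref), ranks(est)
        expect = (
            ((ra - ra.mean()) * (rb - rb.mean())).sum()
            / np.sqrt(((ra - ra.mean()) ** 2).sum() * ((rb - rb.mean()) ** 2).sum())
        )
        assert spearman(ref, est) == pytest.approx(expect, abs=1e-10)
        assert mae(ref, est) == pytest.approx(np.abs(d).mean(), abs=1e-12)

    def test_degenerate_spearman_missing(self):
        assert np.isnan(spearman(np.ones(5), np.arange(5.0)))


class TestEfficiencySweep:
    def _frame(self):
        rng = np.random.default_rng(0)
        n = 30
        se = rng.uniform(0.4, 1.0, n)
        ahi_ref = rng.uniform(0, 50, n)
        return pd.DataFrame(
            {
                "sleep_efficiency_ref": se,
                "ahi_ref": ahi_ref,
                "ahi_est": ahi_ref + rng.normal(0, 3, n),
                "rei_est": ahi_ref * se + rng.normal(0, 3, n),
            }
        )

    def test_full_cutoff_uses_everyone(self):
        df = self._frame()
        sweep = efficiency_sweep(df, cutoffs=[1.0])
        assert sweep.loc[0, "n"] == len(df)

    def test_monotone_inclusion(self):
        df = self._frame()
        sweep = efficiency_sweep(df, cutoffs=[0.5, 0.7, 0.9, 1.0])
        assert sweep["n"].is_monotonic_increasing

    def test_small_subsets_missing(self):
        df = self._frame()
        sweep = efficiency_sweep(df, cutoffs=[0.01])
        assert sweep.loc[0, "n"] < 3
        assert np.isnan(sweep.loc[0, "r_ahi"])

    def test_rei_denominator_penalty_at_low_efficiency(self):
        # REI divides by TIB, so for low-efficiency subjects it
        # underestimates the sleep-based index by construction
        df = self._frame()
        sweep = efficiency_sweep(df, cutoffs=[0.6, 1.0])
        assert sweep.loc[0, "mae_rei"] > sweep.loc[0, "mae_ahi"]

    def test_empty_report_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            efficiency_sweep(pd.DataFrame())
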