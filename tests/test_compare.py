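"""Paired monthly comparison: common-random-numbers structure,
conservation, scaling laws and report shapes."""

from dataclasses import replace

import numpy as np
import pytest

from orsim import (
    DurationModel,
    neostigmine_arm,
    run_month,
    run_paired,
    scenario_sweep,
    sensitivity_suite,
    sugammadex_arm,
    table3_frame,
    table5_frame,
)
from orsim.compare import deep_block_exploratory, deep_block_model
from orsim.variates import DistributionSpec


def test_crn_null_identical_arms_give_exact_zero_differences(base_policy, neostigmine):
    """With the comparator equal to the reference, every replication-wise
    difference is exactly zero (not merely small)."""
    row = run_paired(
        base_policy, neostigmine, neostigmine_arm(), 0.25, 5, 77, keep_replications=True
    )
    assert row.minutes_saved_per_day == 0.0
    for name in (
        "procedures_gained", "cancellations_avoided", "overtime_avoided",
        "rnmb_avoided", "hypoxemia_avoided", "airway_avoided",
    ):
        assert getattr(row, name) == 0.0
    np.testing.assert_array_equal(
        row.replications["reference_cancelled_time"],
        row.replications["comparator_cancelled_time"],
    )


def test_crn_monotonicity_per_replication(base_policy, neostigmine, sugammadex):
    """Earlier starts can only rescue time-cancellations, and coupled
    thresholds can only avoid RNMB cases — in every single replication."""
    row = run_paired(
        base_policy, neostigmine, sugammadex, 1.0, 30, 5, keep_replications=True
    )
    r = row.replications
    assert (r["comparator_cancelled_time"] <= r["reference_cancelled_time"]).all()
    assert (r["comparator_performed"] >= r["reference_performed"]).all()
    row0 = run_paired(
        base_policy, neostigmine, sugammadex, 0.0, 30, 5, keep_replications=True
    )
    assert (row0.replications["rnmb_avoided"] >= 0).all()
    assert (row0.replications["hypoxemia_avoided"] >= 0).all()
    assert (row0.replications["airway_avoided"] >= 0).all()


@pytest.mark.parametrize("p_emergency", [0.0, 0.15])
def test_monthly_conservation_of_scheduled_slots(base_policy, neostigmine, sugammadex, p_emergency):
    policy = replace(base_policy, p_emergency=p_emergency)
    row = run_paired(policy, neostigmine, sugammadex, 0.5, 10, 9, keep_replications=True)
    total = policy.working_days * policy.procedures_per_day
    for arm in ("reference", "comparator"):
        r = row.replications
        scheduled_performed = r[f"{arm}_performed"] - r[f"{arm}_emergency"]
        np.testing.assert_allclose(
            scheduled_performed
            + r[f"{arm}_cancelled_time"]
            + r[f"{arm}_cancelled_other"],
            total,
        )


def test_run_month_matches_reference_arm_of_paired_run(base_policy, neostigmine, sugammadex):
    row = run_paired(base_policy, neostigmine, sugammadex, 0.5, 1, 123)
    solo = run_month(base_policy, neostigmine, 0.5, 123, 0)
    for name in ("procedures_performed", "cancelled_time", "overtime_hours", "rnmb_cases"):
        assert getattr(solo, name) == getattr(row.reference, name)


def test_paired_run_is_deterministic(base_policy, neostigmine, sugammadex):
    a = run_paired(base_policy, neostigmine, sugammadex, 1.0, 4, 42)
    b = run_paired(base_policy, neostigmine, sugammadex, 1.0, 4, 42)
    assert a == b


def test_full_verification_eliminates_rnmb_in_both_arms(base_policy, neostigmine, sugammadex):
    row = run_paired(base_policy, neostigmine, sugammadex, 1.0, 10, 3)
    for arm in (row.reference, row.comparator):
        assert arm.rnmb_cases == 0.0
        assert arm.hypoxemia_cases == 0.0
        assert arm.airway_cases == 0.0


def test_minutes_saved_equals_delta_times_performed(base_policy, neostigmine, sugammadex):
    """At 100% verification every performed comparator procedure yields
    the full 14-minute saving (the 1-minute floor essentially never
    binds at these durations)."""
    row = run_paired(base_policy, neostigmine, sugammadex, 1.0, 20, 6)
    expected = 14.0 * row.comparator.procedures_performed / base_policy.working_days
    assert row.minutes_saved_per_day == pytest.approx(expected, rel=1e-9)


def test_cases_avoided_scale_with_unverified_fraction(base_policy, neostigmine, sugammadex):
    rows = scenario_sweep(
        base_policy, neostigmine, sugammadex, (0.0, 0.5, 1.0), n_replications=100, master_seed=21
    )
    full, half, none = rows[0].rnmb_avoided, rows[1].rnmb_avoided, rows[2].rnmb_avoided
    assert none == 0.0
    assert half == pytest.approx(full / 2, rel=0.12)


def test_minutes_saved_monotone_in_verified_fraction(base_policy, neostigmine, sugammadex):
    rows = scenario_sweep(
        base_policy, neostigmine, sugammadex, (0.0, 0.25, 1.0), n_replications=20, master_seed=13
    )
    saved = [r.minutes_saved_per_day for r in rows]
    assert saved == sorted(saved)
    assert saved[0] == 0.0


def test_replication_means_stabilize(base_policy, neostigmine, sugammadex):
    """Doubling the replication count leaves headline means (whose 2%
    band exceeds their Monte Carlo error) essentially unchanged."""
    a = run_paired(base_policy, neostigmine, sugammadex, 1.0, 200, 31)
    b = run_paired(base_policy, neostigmine, sugammadex, 1.0, 400, 31)
    for get in (
        lambda r: r.reference.procedures_performed,
        lambda r: r.reference.pct_days_complete,
        lambda r: r.reference.overtime_hours,
        lambda r: r.minutes_saved_per_day,
    ):
        assert get(a) == pytest.approx(get(b), rel=0.02)


def test_table3_frame_layout(base_policy, neostigmine, sugammadex):
    rows = scenario_sweep(
        base_policy, neostigmine, sugammadex, n_replications=2, master_seed=1
    )
    frame = table3_frame(rows)
    assert frame.shape == (10, 8)
    assert list(frame.columns)[:2] == ["neostigmine", "0% verified"]
    assert frame.loc["Cases of residual blockade avoided", "100% verified"] == 0


def test_never_cancel_variant_has_zero_time_cancellations(base_policy, neostigmine, sugammadex):
    frame = sensitivity_suite(base_policy, neostigmine, sugammadex, 3, 17)
    never = frame.loc["never_cancel"]
    assert (never["cancelled_time"] == 0.0).all()
    move_up = frame.loc["move_up_on_cancel", "pct_days_complete"]
    primary = frame.loc["primary", "pct_days_complete"]
    assert (move_up.values > primary.values).all()


def test_deep_block_grid_shares_reference_and_schedule():
    rows = deep_block_exploratory((15.0, 30.0), n_replications=5, master_seed=8)
    assert rows[0].reference == rows[1].reference
    # savings applied per performed procedure, all patients unverified
    for s, row in zip((15.0, 30.0), rows):
        expected = s * row.comparator.procedures_performed / 21
        assert row.minutes_saved_per_day == pytest.approx(expected, rel=1e-9)
    frame = table5_frame(rows, (15.0, 30.0))
    assert list(frame.columns) == ["neostigmine", "15 min saved", "30 min saved"]


def test_deep_block_model_preserves_variability_ratio():
    model = deep_block_model(DurationModel(), 145.0)
    assert model.procedure.mean() == pytest.approx(145.0)
    assert model.procedure.sd() == pytest.approx(145.0 * 29.2 / 72.9)
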