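"""Shared fixtures: simulator scenario runs are expensive, so each is
computed once per session and shared between module and acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from berrytrack.evaluation import tracking_score
from berrytrack.synthetic import (cohort_series, ground_truth_series,
                                  scenario_library, simulate)
from berrytrack.tracking import track


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def random_ellipse(rng, centre_range=200.0, w_range=(4.0, 60.0),
                   ratio_range=(1.0, 3.0)):
    from berrytrack.geometry import Ellipse

    x, y = rng.uniform(-centre_range, centre_range, 2)
    w = rng.uniform(*w_range)
    h = w * rng.uniform(*ratio_range)
    return Ellipse(x, y, w, h, rng.uniform(0.0, 180.0))


@pytest.fixture(scope="session")
def scenario_runs():
    """Tracking results for the named scenarios (computed once)."""
    lib = scenario_library()
    out = {}
    for name in ["static", "nominal_jitter", "rigid_rotation_event",
                 "nonaffine_break"]:
        gt = simulate(lib[name])
        series, ids = ground_truth_series(gt)
        table, tree, matrix = track(series)
        out[name] = {
            "gt": gt, "series": series, "ids": ids, "table": table,
            "tree": tree, "matrix": matrix,
            "score": tracking_score(table.labels, ids),
        }
    # chronological baseline (no registration, no tree) where it is compared
    for name in ["nominal_jitter", "rigid_rotation_event"]:
        r = out[name]
        table1, _, _ = track(r["series"], use_registration=False, use_tree=False)
        r["baseline_score"] = tracking_score(table1.labels, r["ids"])
    return out


@pytest.fixture(scope="session")
def cohort_run():
    """Asynchronous logistic cohort with its kinetics series."""
    gt = simulate(scenario_library()["asynchronous_cohort"])
    return {"gt": gt, "series": cohort_series(gt),
            "truth": {b.berry_id: b for b in gt.berries}}


@pytest.fixture(scope="session")
def mini_render_run():
    """Small rendered scenario for the image pipeline."""
    gt = simulate(scenario_library()["mini_render"])
    return gt
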