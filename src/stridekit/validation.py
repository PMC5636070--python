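"""End-to-end recovery benchmarks against simulator ground truth.

These helpers run the full measurement chain — segmentation, event
detection, ZUPT reconstruction, parameter assembly — on synthetic data
and compare every measured stride with the generator's exact labels.
They back both the package's validation tests and the reproduction
script, so the numbers reported in either come from one code path.
"""

from __future__ import annotations

import math

import numpy as np

from .parameters import PARAMETER_FIELDS
from .pipeline import analyze_recording, analyze_walk
from .segmentation import default_template, default_threshold
from .synth import (
    DEFAULT_NOISE_SD,
    CohortSpec,
    StrideDistribution,
    control_reference_distribution,
    default_stride_distribution,
    pd_reference_distribution,
    synthesize_cohort,
    synthesize_recording,
)

__all__ = ["stride_error_batch", "cohort_grand_means"]


def stride_error_batch(
    n_strides: int = 200,
    seed: int = 42,
    distribution: StrideDistribution | None = None,
    noise_sd: tuple[float, float] = DEFAULT_NOISE_SD,
    strides_per_recording: int = 5,
) -> dict:
    """Measure per-stride timing and length errors over a seeded batch.

    Short recordings of ``strides_per_recording`` strides drawn from
    ``distribution`` (default: the healthy-walker stride distribution)
    are synthesized with sensor noise, pushed through the full pipeline
    with default template and threshold, and each measured stride is
    matched to its ground-truth gait cycle.  Returns arrays of signed
    errors plus the batch bookkeeping.
    """
    if distribution is None:
        distribution = default_stride_distribution()
    rng = np.random.default_rng(seed)
    template = default_template()
    threshold = default_threshold()

    pairs_per_rec = strides_per_recording - 1
    n_recordings = math.ceil(n_strides / pairs_per_rec) + 2

    time_err, length_err, stance_err, clearance_err = [], [], [], []
    n_missed = 0
    for _ in range(n_recordings):
        if len(time_err) >= n_strides:
            break
        specs = distribution.sample(rng, strides_per_recording)
        rec, truth = synthesize_recording(specs, noise_sd=noise_sd, seed=rng)
        result = analyze_recording(rec, template=template, threshold=threshold)
        pair_truth = truth.measured_pair_truth()
        bounds = truth.boundaries
        for i, k in enumerate(pair_truth["index"]):
            if len(time_err) >= n_strides:
                break
            rows = [r for r in result.rows if abs(r.start - bounds[k]) <= 4]
            if not rows:
                n_missed += 1
                continue
            p = rows[0].params
            time_err.append(p.stride_time - pair_truth["stride_time"][i])
            length_err.append(p.stride_length - pair_truth["stride_length"][i])
            stance_err.append(p.stance_time_pct - pair_truth["stance_pct"][i])
            clearance_err.append(p.clearance / 100.0 - pair_truth["clearance"][i])

    return {
        "time_err_s": np.asarray(time_err),
        "length_err_m": np.asarray(length_err),
        "stance_err_pct": np.asarray(stance_err),
        "clearance_err_m": np.asarray(clearance_err),
        "n_measured": len(time_err),
        "n_missed": n_missed,
    }


def cohort_grand_means(
    group: str = "PD",
    n_subjects: int = 50,
    seed: int = 1,
    include_initiation: bool = True,
) -> dict:
    """Full-pipeline grand means over a synthetic cohort.

    Synthesizes ``n_subjects`` subjects (both feet, 4×10 m walks) from
    the named group's reference distribution, analyzes every recording,
    pools strides per subject, and averages across subjects.  Returns the
    grand means, their standard errors over subjects, and the per-subject
    values.
    """
    between = (
        pd_reference_distribution()
        if group == "PD"
        else control_reference_distribution()
    )
    spec = CohortSpec(group=group, n_subjects=n_subjects, between=between, seed=seed)
    data = synthesize_cohort(spec)
    template = default_template()
    threshold = default_threshold()

    per_subject: dict[str, list[float]] = {name: [] for name in PARAMETER_FIELDS}
    n_failed = 0
    for sid, sides in data.walks.items():
        recordings = {side: rec for side, (rec, _) in sides.items()}
        try:
            summary, _ = analyze_walk(
                recordings,
                template=template,
                threshold=threshold,
                include_initiation=include_initiation,
            )
        except Exception:
            n_failed += 1
            continue
        for name in PARAMETER_FIELDS:
            per_subject[name].append(summary.means[name])

    out = {"n_subjects": n_subjects - n_failed, "n_failed": n_failed, "group": group}
    for name, values in per_subject.items():
        arr = np.asarray(values)
        out[name] = float(arr.mean())
        out[f"{name}_sem"] = float(arr.std(ddof=1) / np.sqrt(len(arr)))
        out[f"{name}_values"] = arr
    return out
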