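"""Preprocessing: localization filtering, log transform, quantile normalization.

Canonical order for a cohort's matrix:

    filter_localization (phosphosites only, prob >= 0.7, inclusive)
    -> filter_complete (complete-case within each cohort)
    -> optional per-channel scaling (label-lot correction)
    -> log2_transform
    -> quantile_normalize (per cohort / plex, never across plexes)

Missing-data policy is complete-case: TMT within-plex data are near-complete
and imputation would introduce an extra modelling choice; a feature with any
missing channel in the cohort under analysis is dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import FormatError
from .io_formats import IntensityMatrix, SampleDesign

log = logging.getLogger(__name__)


@dataclass
class PreprocessReport:
    """Feature counts and per-sample medians across preprocessing stages."""

    n_input_features: int = 0
    n_after_localization: int = 0
    n_after_completeness: int = 0
    per_sample_median_before: dict[str, float] = field(default_factory=dict)
    per_sample_median_after: dict[str, float] = field(default_factory=dict)


def filter_localization(matrix: IntensityMatrix, min_prob: float = 0.7) -> IntensityMatrix:
    """Retain phosphosites with localization probability >= ``min_prob``.

    The threshold is inclusive ("minimum of 0.7" = lowest allowed value).
    Protein-level matrices pass through unchanged.
    """
    if matrix.level != "phosphosite":
        return matrix
    probs = []
    for feat in matrix.features:
        if feat.localization_prob is None:
            raise FormatError(f"phosphosite {feat.feature_id!r} lacks localization_prob")
        probs.append(feat.localization_prob)
    keep = np.asarray(probs) >= min_prob
    if not keep.any():
        log.warning("all %d phosphosites fall below localization %g", matrix.n_features, min_prob)
    return matrix.subset_features(keep)


def apply_channel_scaling(
    matrix: IntensityMatrix, factors: Mapping[str, float] | None
) -> IntensityMatrix:
    """Optional per-channel multiplicative correction on raw intensities.

    Represents vendor label-lot value correction; default (``None``) is a
    no-op.  Factors are keyed by sample id; unlisted samples keep factor 1.0.
    """
    if not factors:
        return matrix
    if matrix.scale != "raw":
        raise FormatError("channel scaling applies to raw intensities only")
    scale = np.array([float(factors.get(s, 1.0)) for s in matrix.samples])
    if np.any(scale <= 0):
        raise FormatError("channel scaling factors must be positive")
    return matrix.with_values(matrix.values * scale[None, :])


def log2_transform(matrix: IntensityMatrix) -> IntensityMatrix:
    if matrix.scale != "raw":
        raise FormatError(f"log2_transform expects raw scale, got {matrix.scale!r}")
    values = matrix.values
    bad = np.argwhere(~np.isnan(values) & (values <= 0))
    if bad.size:
        i, j = bad[0]
        raise FormatError(
            f"non-positive intensity for feature {matrix.feature_ids[i]!r}, "
            f"sample {matrix.samples[j]!r}"
        )
    with np.errstate(invalid="ignore"):
        out = np.log2(values)
    return matrix.with_values(out, scale="log2")


def quantile_normalize(matrix: IntensityMatrix) -> IntensityMatrix:
    """Map every column onto the common distribution of row-wise sorted means.

    After normalization each column's sorted values equal the reference
    vector (mean of column-sorted values); tied values receive the mean of
    the reference values across their tied rank span, which makes the
    operation deterministic and idempotent.
    """
    if matrix.scale not in ("log2", "log2_quantile_normalized"):
        raise FormatError("quantile_normalize expects a log2-scale matrix")
    if matrix.n_samples < 2:
        raise FormatError("quantile normalization needs at least 2 samples")
    if matrix.missing_mask.any():
        raise FormatError("quantile_normalize requires a complete matrix; filter first")
    vals = matrix.values
    sorted_vals = np.sort(vals, axis=0)
    ref = sorted_vals.mean(axis=1)
    ref_cum = np.concatenate([[0.0], np.cumsum(ref)])
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        order = np.argsort(col, kind="stable")
        sc = col[order]
        starts = np.flatnonzero(np.r_[True, sc[1:] != sc[:-1]])
        ends = np.r_[starts[1:], len(sc)]
        group_means = (ref_cum[ends] - ref_cum[starts]) / (ends - starts)
        expanded = np.repeat(group_means, ends - starts)
        out[order, j] = expanded
    return matrix.with_values(out, scale="log2_quantile_normalized")


def filter_complete(
    matrix: IntensityMatrix, design: Sequence[SampleDesign]
) -> tuple[IntensityMatrix, PreprocessReport]:
    """Drop features with any missing value within each cohort's sample group."""
    report = PreprocessReport(
        n_input_features=matrix.n_features,
        n_after_localization=matrix.n_features,
    )
    report.per_sample_median_before = _sample_medians(matrix)
    by_cohort: dict[str, list[int]] = {}
    design_map = {d.sample_id: d for d in design}
    for j, s in enumerate(matrix.samples):
        if s in design_map:
            by_cohort.setdefault(design_map[s].cohort, []).append(j)
    if not by_cohort:
        by_cohort = {"all": list(range(matrix.n_samples))}
    keep = np.ones(matrix.n_features, dtype=bool)
    mask = matrix.missing_mask
    for cols in by_cohort.values():
        keep &= ~mask[:, cols].any(axis=1)
    filtered = matrix.subset_features(keep)
    report.n_after_completeness = filtered.n_features
    report.per_sample_median_after = _sample_medians(filtered)
    return filtered, report


def _sample_medians(matrix: IntensityMatrix) -> dict[str, float]:
    out = {}
    for j, s in enumerate(matrix.samples):
        col = matrix.values[:, j]
        present = col[~np.isnan(col)]
        out[s] = float(np.median(present)) if present.size else float("nan")
    return out


def preprocess_matrix(
    matrix: IntensityMatrix,
    design: Sequence[SampleDesign],
    min_loc_prob: float = 0.7,
    channel_factors: Mapping[str, float] | None = None,
) -> tuple[IntensityMatrix, PreprocessReport]:
    """Run the canonical preprocessing chain on one cohort's raw matrix."""
    n_input = matrix.n_features
    matrix = filter_localization(matrix, min_loc_prob)
    n_loc = matrix.n_features
    matrix, report = filter_complete(matrix, design)
    report.n_input_features = n_input
    report.n_after_localization = n_loc
    matrix = apply_channel_scaling(matrix, channel_factors)
    matrix = log2_transform(matrix)
    matrix = quantile_normalize(matrix)
    report.per_sample_median_after = _sample_medians(matrix)
    return matrix, report
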