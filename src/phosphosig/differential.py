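"""Paired and two-group moderated-t differential analysis.

The paired BE vs adjacent contrast is fit as a one-sample problem on
within-patient log2 differences (equivalent to a patient-blocked two-group
fit for a balanced pair design).  Per-feature variances are shrunk toward a
prior by empirical Bayes: the sample variances ``s_f^2`` with ``d`` residual
degrees of freedom each are moment-matched on the log scale to a scaled F
distribution ``s0^2 * F(d, d0)``, giving prior degrees of freedom ``d0`` and
prior variance ``s0^2``.  The moderated statistic uses the posterior variance

    s_tilde^2 = (d0 * s0^2 + d * s^2) / (d0 + d)

and is referred to a t distribution on ``d0 + d`` degrees of freedom
(standard normal in the ``d0 = +inf`` limit).  Two-sided p-values throughout;
multiple testing by Benjamini-Hochberg.

Features with zero sample variance (possible with few pairs and ties) are
excluded from hyperparameter estimation and, when the posterior variance
depends on the sample variance (finite ``d0``), flagged with an undefined
statistic and p = 1 rather than reporting a spuriously confident t.  In the
complete-shrinkage limit (``d0 = +inf``) the statistic does not involve the
sample variance at all and is computed normally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .errors import DesignError, FormatError
from .io_formats import IntensityMatrix, SampleDesign, paired_patients


@dataclass
class PairedDiffMatrix:
    """Within-patient log2(BE) - log2(ADJ) differences, features x pairs."""

    features: list[str]
    pairs: list[str]  # patient ids
    deltas: np.ndarray

    def __post_init__(self) -> None:
        self.deltas = np.asarray(self.deltas, dtype=float)
        if self.deltas.shape != (len(self.features), len(self.pairs)):
            raise FormatError("deltas shape does not match features x pairs")
        if not np.all(np.isfinite(self.deltas)):
            raise FormatError("paired differences must be finite (complete matrix required)")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass
class EBHyperparams:
    """Prior degrees of freedom and prior variance of the shrinkage target.

    ``s0_sq`` may be a scalar or a per-feature array (the latter is used by
    the classical-t reduction oracle, where each feature is shrunk onto its
    own variance).
    """

    d0: float
    s0_sq: float | np.ndarray

    def __post_init__(self) -> None:
        if not (self.d0 > 0):  # also rejects NaN
            raise FormatError("d0 must be positive (may be +inf)")
        if np.any(np.asarray(self.s0_sq) <= 0):
            raise FormatError("s0_sq must be positive")


@dataclass
class DifferentialResult:
    feature_id: str
    log2fc: float
    s2: float
    t_mod: float
    df_total: float
    p_value: float
    q_value: float
    zero_variance: bool = False


def pair_differences(
    matrix: IntensityMatrix, design: Sequence[SampleDesign]
) -> PairedDiffMatrix:
    """Compute within-patient BE - ADJ differences for every feature."""
    pairs = [p for p in paired_patients(design) if p[1] in matrix.samples or p[2] in matrix.samples]
    if not pairs:
        raise DesignError("no BE/ADJ pairs found among the matrix samples")
    col = {s: j for j, s in enumerate(matrix.samples)}
    for patient, be, adj in pairs:
        if be not in col or adj not in col:
            raise DesignError(f"patient {patient!r}: BE or ADJ sample absent from matrix")
    deltas = np.column_stack(
        [matrix.values[:, col[be]] - matrix.values[:, col[adj]] for _, be, adj in pairs]
    )
    return PairedDiffMatrix(matrix.feature_ids, [p[0] for p in pairs], deltas)


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise FormatError("trigamma_inverse needs y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_eb_hyperparams(s2: np.ndarray, d: int) -> EBHyperparams:
    """Moment-match log sample variances to a scaled F distribution.

    Under the hierarchical model ``s^2 ~ s0^2 * F(d, d0)``, the excess
    spread of ``log s^2`` over ``trigamma(d/2)`` identifies ``d0``; zero or
    negative excess yields ``d0 = +inf`` (complete shrinkage to ``s0^2``).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2)]
    if np.any(s2 <= 0):
        raise FormatError("estimate_eb_hyperparams requires strictly positive variances")
    if s2.size < 2:
        raise FormatError("need at least 2 features with positive variance")
    if d < 1:
        raise FormatError("residual degrees of freedom must be >= 1")
    z = np.log(s2)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1))
    excess = evar - float(special.polygamma(1, d / 2.0))
    if excess > 0:
        d0 = 2.0 * trigamma_inverse(excess)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = float("inf")
        s0_sq = float(np.exp(emean))
    return EBHyperparams(d0=d0, s0_sq=s0_sq)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise FormatError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _moderate(
    feature_ids: Sequence[str],
    means: np.ndarray,
    s2: np.ndarray,
    se2_factor: float,
    d: int,
    hyper: EBHyperparams,
) -> list[DifferentialResult]:
    """Shared moderated-t core for paired and two-group designs.

    ``se2_factor`` converts the posterior variance into the squared standard
    error of the mean difference (``1/n`` paired, ``1/na + 1/nb`` unpaired).
    """
    d0, s0 = hyper.d0, np.asarray(hyper.s0_sq, dtype=float)
    if np.isinf(d0):
        # complete shrinkage: the statistic no longer involves the sample
        # variance, so zero-variance features are perfectly well-defined
        zero_var = np.zeros(s2.shape, dtype=bool)
        s2_post = np.broadcast_to(s0, s2.shape).copy()
        df_total = float("inf")
    else:
        zero_var = s2 <= 0
        s2_post = (d0 * s0 + d * s2) / (d0 + d)
        df_total = d0 + d
    with np.errstate(invalid="ignore", divide="ignore"):
        t = means / np.sqrt(s2_post * se2_factor)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    t = np.where(zero_var, np.nan, t)
    p = np.where(zero_var, 1.0, p)
    q = bh_adjust(p)
    return [
        DifferentialResult(
            feature_id=fid,
            log2fc=float(means[i]),
            s2=float(s2[i]),
            t_mod=float(t[i]),
            df_total=df_total,
            p_value=float(p[i]),
            q_value=float(q[i]),
            zero_variance=bool(zero_var[i]),
        )
        for i, fid in enumerate(feature_ids)
    ]


def moderated_t(diffs: PairedDiffMatrix, hyper: EBHyperparams) -> list[DifferentialResult]:
    """One-sample moderated t on paired differences."""
    n = diffs.n_pairs
    if n < 2:
        raise DesignError("moderated t needs at least 2 pairs")
    means = diffs.deltas.mean(axis=1)
    s2 = diffs.deltas.var(axis=1, ddof=1)
    return _moderate(diffs.features, means, s2, 1.0 / n, n - 1, hyper)


def paired_moderated_t(diffs: PairedDiffMatrix) -> tuple[list[DifferentialResult], EBHyperparams]:
    """Estimate shrinkage hyperparameters and run the paired moderated t."""
    s2 = diffs.deltas.var(axis=1, ddof=1)
    hyper = estimate_eb_hyperparams(s2[s2 > 0], diffs.n_pairs - 1)
    return moderated_t(diffs, hyper), hyper


def two_group_contrast(
    matrix: IntensityMatrix,
    design: Sequence[SampleDesign],
    class_a: str,
    class_b: str,
    collapse_patients: bool = True,
) -> list[DifferentialResult]:
    """Unpaired moderated t between two tissue classes (log2fc = mean_a - mean_b).

    With ``collapse_patients`` (default), replicate biopsies of one patient
    are averaged first, so the unit of replication is the patient; treating
    within-patient replicates as independent samples would understate the
    group-mean variance (pseudoreplication).
    """
    if matrix.missing_mask.any():
        raise FormatError("two_group_contrast requires a complete matrix")
    design_map = {d.sample_id: d for d in design}
    cols: dict[str, dict[str, list[int]]] = {class_a: {}, class_b: {}}
    for j, s in enumerate(matrix.samples):
        d = design_map.get(s)
        if d is not None and d.tissue_class in (class_a, class_b):
            unit = d.patient_id if collapse_patients else d.sample_id
            cols[d.tissue_class].setdefault(unit, []).append(j)
    na, nb = len(cols[class_a]), len(cols[class_b])
    if na < 2 or nb < 2:
        raise DesignError(
            f"two_group_contrast needs >= 2 replication units per class "
            f"(got {class_a}={na}, {class_b}={nb})"
        )
    a = np.column_stack(
        [matrix.values[:, idx].mean(axis=1) for _, idx in sorted(cols[class_a].items())]
    )
    b = np.column_stack(
        [matrix.values[:, idx].mean(axis=1) for _, idx in sorted(cols[class_b].items())]
    )
    means = a.mean(axis=1) - b.mean(axis=1)
    d = na + nb - 2
    s2 = ((na - 1) * a.var(axis=1, ddof=1) + (nb - 1) * b.var(axis=1, ddof=1)) / d
    hyper = estimate_eb_hyperparams(s2[s2 > 0], d)
    return _moderate(matrix.feature_ids, means, s2, 1.0 / na + 1.0 / nb, d, hyper)


def results_to_frame(results: Sequence[DifferentialResult]):
    """Tabulate results for TSV export (deterministic column order)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "log2fc": [r.log2fc for r in results],
            "s2": [r.s2 for r in results],
            "t_mod": [r.t_mod for r in results],
            "df_total": [r.df_total for r in results],
            "p_value": [r.p_value for r in results],
            "q_value": [r.q_value for r in results],
            "zero_variance": [r.zero_variance for r in results],
        }
    )
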