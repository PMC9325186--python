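"""Disease-signature selection, randomization-based empirical FDR and
clustering-based classification of independent cohorts.

The signature is the top 1% of features by moderated-t p-value that also
show at least +/-0.75 log2-fold change (a deliberately strict bound given
TMT ratio compression).  Its reliability is quantified by an empirical FDR:
the full selection procedure is rerun on label-randomized data (independent
sign flips of each patient's paired-difference column -- the exact null for
a paired design) and the mean null selection count is compared with the
observed count.

Classification of an independent cohort is unsupervised: samples are
hierarchically clustered (average linkage, correlation distance) on the
standardized expression of the signature features, and the cut at k clusters
is scored against known tissue labels by purity and adjusted Rand index.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from .differential import (
    DifferentialResult,
    PairedDiffMatrix,
    estimate_eb_hyperparams,
    moderated_t,
    pair_differences,
    paired_moderated_t,
)
from .errors import DesignError, FormatError
from .io_formats import IntensityMatrix, SampleDesign

log = logging.getLogger(__name__)


@dataclass
class SignatureSet:
    """Ordered signature features with their BE direction and provenance."""

    features: list[tuple[str, str]]  # (feature_id, "up_in_BE"|"down_in_BE")
    selection_params: dict = field(default_factory=lambda: {"top_frac": 0.01, "min_abs_lfc": 0.75})
    empirical_fdr: float | None = None
    n_randomizations: int = 100

    def __len__(self) -> int:
        return len(self.features)

    @property
    def feature_ids(self) -> list[str]:
        return [f for f, _ in self.features]

    @property
    def n_up(self) -> int:
        return sum(1 for _, d in self.features if d == "up_in_BE")

    @property
    def n_down(self) -> int:
        return sum(1 for _, d in self.features if d == "down_in_BE")


@dataclass
class ClusteringResult:
    linkage_tree: np.ndarray
    cluster_assignments: dict[str, int]
    k: int
    purity: float
    adjusted_rand: float


def _selection_order(results: Sequence[DifferentialResult]) -> list[int]:
    """Rank by ascending p, ties by descending |t|, then feature_id."""

    def key(i: int):
        r = results[i]
        abst = abs(r.t_mod) if np.isfinite(r.t_mod) else -1.0
        return (r.p_value, -abst, r.feature_id)

    return sorted(range(len(results)), key=key)


def select_signature(
    results: Sequence[DifferentialResult],
    top_frac: float = 0.01,
    min_abs_lfc: float = 0.75,
) -> SignatureSet:
    """Top ``ceil(top_frac * m)`` features by p-value, intersected with the
    fold-change bound; direction follows the sign of log2fc."""
    if not results:
        raise FormatError("select_signature needs a non-empty result list")
    m = len(results)
    n_top = math.ceil(top_frac * m)
    order = _selection_order(results)
    chosen = []
    for i in order[:n_top]:
        r = results[i]
        if abs(r.log2fc) >= min_abs_lfc:
            chosen.append((r.feature_id, "up_in_BE" if r.log2fc > 0 else "down_in_BE"))
    if not chosen:
        log.warning("signature selection is empty (no candidate met |log2FC| >= %g)", min_abs_lfc)
    return SignatureSet(
        features=chosen,
        selection_params={"top_frac": top_frac, "min_abs_lfc": min_abs_lfc},
    )


def empirical_fdr(
    matrix: IntensityMatrix,
    design: Sequence[SampleDesign],
    top_frac: float = 0.01,
    min_abs_lfc: float = 0.75,
    n_rand: int = 100,
    seed: int = 0,
) -> float:
    """Randomization-based empirical FDR of the signature selection.

    Each randomization independently flips the sign of every patient's
    paired-difference column with probability 1/2 and reruns the full
    moderated-t + selection procedure with identical parameters; the
    estimate is mean(null count) / max(1, observed count).  Returns NaN
    (with a warning) when the observed selection is empty.

    With very few pairs the flip group is small (2^n patterns including the
    identity and the global flip, both of which reproduce a two-sided
    selection), which floors the achievable estimate; see docs/methods.md.
    """
    diffs = pair_differences(matrix, design)
    observed_results, _ = paired_moderated_t(diffs)
    observed = len(select_signature(observed_results, top_frac, min_abs_lfc))
    if observed == 0:
        log.warning("observed selection empty; empirical FDR undefined")
        return float("nan")
    rng = np.random.default_rng(seed)
    d = diffs.n_pairs - 1
    null_counts = np.empty(n_rand)
    for r in range(n_rand):
        signs = rng.choice([-1.0, 1.0], size=diffs.n_pairs)
        flipped = diffs.deltas * signs[None, :]
        s2 = flipped.var(axis=1, ddof=1)
        hyper = estimate_eb_hyperparams(s2[s2 > 0], d)
        null_res = moderated_t(
            PairedDiffMatrix(diffs.features, diffs.pairs, flipped), hyper
        )
        null_counts[r] = len(select_signature(null_res, top_frac, min_abs_lfc))
    return float(null_counts.mean() / max(1, observed))


def project_signature(matrix: IntensityMatrix, signature: SignatureSet) -> IntensityMatrix:
    """Row-subset a matrix to the signature and standardize each feature.

    Matching is by feature id first, then (for cross-omics projection, e.g.
    onto transcriptomes) by upper-cased gene symbol.  Constant rows cannot be
    standardized and are dropped with a warning; unmatched signature members
    are reported, not silently ignored.
    """
    wanted = signature.feature_ids
    by_id = {f.feature_id: i for i, f in enumerate(matrix.features)}
    by_gene: dict[str, int] = {}
    for i, f in enumerate(matrix.features):
        by_gene.setdefault(f.gene_symbol.upper(), i)
    rows, matched = [], set()
    for fid in wanted:
        i = by_id.get(fid)
        if i is None:
            i = by_gene.get(fid.split("_")[0].upper())
        if i is not None and i not in rows:
            rows.append(i)
            matched.add(fid)
    unmatched = [f for f in wanted if f not in matched]
    if unmatched:
        log.warning("%d signature members not found in matrix: %s",
                    len(unmatched), ", ".join(unmatched[:10]))
    if not rows:
        raise FormatError("signature/matrix overlap is 0 features")
    sub = matrix.subset_features(np.array(rows))
    vals = sub.values
    mu = np.nanmean(vals, axis=1, keepdims=True)
    sd = np.nanstd(vals, axis=1, ddof=1, keepdims=True)
    keep = (sd > 0).ravel()
    if not keep.all():
        log.warning("dropping %d constant signature rows", int((~keep).sum()))
    sub = sub.subset_features(keep)
    z = (sub.values - mu[keep]) / sd[keep]
    return sub.with_values(z)


def hierarchical_cluster(
    matrix: IntensityMatrix,
    k: int,
    labels: Mapping[str, str] | None = None,
) -> ClusteringResult:
    """Average-linkage clustering of samples with 1 - Pearson distance.

    Samples are ordered lexicographically before linkage so the tree is
    invariant to input column order.  Purity and adjusted Rand index are
    computed against ``labels`` when provided (NaN otherwise).
    """
    if k > matrix.n_samples:
        raise DesignError(f"k={k} exceeds {matrix.n_samples} samples")
    if matrix.n_features < 1:
        raise FormatError("clustering needs at least one feature")
    order = sorted(range(matrix.n_samples), key=lambda j: matrix.samples[j])
    samples = [matrix.samples[j] for j in order]
    vals = matrix.values[:, order]
    if np.isnan(vals).any():
        raise FormatError("clustering requires a complete matrix")
    sd = vals.std(axis=0)
    if np.any(sd == 0):
        bad = samples[int(np.argmax(sd == 0))]
        raise FormatError(f"sample {bad!r} is constant across features; correlation undefined")
    corr = np.corrcoef(vals.T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    tree = linkage(squareform(dist, checks=False), method="average")
    assign = fcluster(tree, t=k, criterion="maxclust")
    assignments = {s: int(c) for s, c in zip(samples, assign)}
    purity = float("nan")
    ari = float("nan")
    if labels is not None:
        true = [labels[s] for s in samples]
        purity = _purity(assign, true)
        ari = float(adjusted_rand_score(true, assign))
    return ClusteringResult(tree, assignments, k, purity, ari)


def _purity(assign: np.ndarray, true_labels: Sequence[str]) -> float:
    total = len(true_labels)
    correct = 0
    for c in np.unique(assign):
        members = [true_labels[i] for i in np.flatnonzero(assign == c)]
        correct += max(members.count(lbl) for lbl in set(members))
    return correct / total
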