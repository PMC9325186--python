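"""Preranked gene-set enrichment with a gene-permutation null.

The enrichment score is the weighted Kolmogorov-Smirnov-style statistic:
walking down the ranked list, set members increment the running sum by
``|stat|^w / sum_hits |stat|^w`` and non-members decrement it by
``1/(N - |S|)``; the ES is the signed maximum deviation from zero.  A
positive score indicates concentration of the set at the top of the ranking
(enriched in BE for a BE-vs-adjacent ranking), negative at the bottom.

The null distribution draws random same-size member sets from the ranked
universe (gene permutation; sample permutation is not meaningful with only a
handful of pairs).  p-values are one-sided within the sign of the observed
ES, NES normalizes by the mean |null ES| of the same sign, and FDR is
Benjamini-Hochberg across sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .differential import DifferentialResult, bh_adjust
from .errors import FormatError
from .io_formats import GeneSetCollection

log = logging.getLogger(__name__)


@dataclass
class RankedList:
    """(id, stat) pairs in strictly deterministic descending-stat order."""

    ids: list[str]
    stats: np.ndarray

    def __post_init__(self) -> None:
        self.stats = np.asarray(self.stats, dtype=float)
        if len(self.ids) != self.stats.size:
            raise FormatError("ids and stats length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise FormatError("duplicate ids in ranked list")

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class EnrichmentResult:
    set_name: str
    size: int
    es: float
    nes: float
    p_value: float
    fdr: float
    leading_edge: list[str]


def make_ranked_list(
    results: Sequence[DifferentialResult],
    level: str = "protein",
    gene_map: dict[str, str] | None = None,
) -> RankedList:
    """Rank features by moderated t (descending; ties broken by id).

    Phosphosite results are collapsed to gene level by keeping, per gene,
    the site with the largest |t|.  Gene symbols come from ``gene_map``
    (feature id -> gene) when given, else from the canonical ``GENE_S123``
    site-id convention.  Zero-variance features (undefined t) are excluded.
    """
    usable = [r for r in results if not r.zero_variance and np.isfinite(r.t_mod)]
    if not usable:
        raise FormatError("no usable statistics to rank")
    if level == "phosphosite":
        best: dict[str, DifferentialResult] = {}
        for r in usable:
            gene = (gene_map or {}).get(r.feature_id) or r.feature_id.rsplit("_", 1)[0]
            gene = gene.upper()
            if gene not in best or abs(r.t_mod) > abs(best[gene].t_mod):
                best[gene] = r
        entries = [(g, r.t_mod) for g, r in best.items()]
    else:
        entries = [(r.feature_id.upper(), r.t_mod) for r in usable]
    entries.sort(key=lambda e: (-e[1], e[0]))
    return RankedList([e[0] for e in entries], np.array([e[1] for e in entries]))


def enrichment_score(
    ranked: RankedList, members: Iterable[str], weight_exp: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment score and the full running sum."""
    member_set = {m.upper() for m in members}
    hits = np.array([gid.upper() in member_set for gid in ranked.ids])
    n_hit = int(hits.sum())
    N = len(ranked)
    if n_hit == 0 or n_hit == N:
        raise FormatError(f"set overlaps ranked list in {n_hit}/{N} genes; ES undefined")
    w = np.abs(ranked.stats) ** weight_exp
    hit_w = np.where(hits, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        # all member stats are exactly zero; fall back to equal hit weights
        hit_w = hits.astype(float)
        denom = hit_w.sum()
    steps = hit_w / denom - (~hits) / (N - n_hit)
    running = np.cumsum(steps)
    i_max, i_min = int(np.argmax(running)), int(np.argmin(running))
    es = running[i_max] if running[i_max] >= -running[i_min] else running[i_min]
    return float(es), running


def _null_es(
    stats: np.ndarray, size: int, n_perm: int, rng: np.random.Generator, weight_exp: float
) -> np.ndarray:
    """Vectorized ES for random same-size member draws.

    Works from sorted hit positions only: with hits at 0-based ranks
    p_1 < ... < p_s, cumulative normalized hit weights W_j and miss step
    m = 1/(N-s), the running sum immediately after hit j is
    W_j - (p_j - (j-1)) * m and immediately before it is the same minus the
    hit increment; the ES extremes occur at those points.
    """
    N = stats.size
    w_all = np.abs(stats) ** weight_exp
    # sample `size` distinct indices per permutation: draw, sort, redraw rows
    # that contain duplicates (few, since size << N)
    pos = np.sort(rng.integers(0, N, size=(n_perm, size)), axis=1)
    bad = (np.diff(pos, axis=1) == 0).any(axis=1)
    while bad.any():
        pos[bad] = np.sort(rng.integers(0, N, size=(int(bad.sum()), size)), axis=1)
        bad = (np.diff(pos, axis=1) == 0).any(axis=1)
    w = w_all[pos]
    denom = w.sum(axis=1, keepdims=True)
    safe = denom > 0
    cw = np.where(safe, np.cumsum(w, axis=1) / np.where(safe, denom, 1.0),
                  np.cumsum(np.ones_like(w), axis=1) / size)
    miss = 1.0 / (N - size)
    j = np.arange(size)[None, :]
    after = cw - (pos - j) * miss
    before = after - np.where(safe, w / np.where(safe, denom, 1.0), 1.0 / size)
    max_dev = after.max(axis=1)
    min_dev = before.min(axis=1)
    return np.where(max_dev >= -min_dev, max_dev, min_dev)


def gsea_preranked(
    ranked: RankedList,
    sets: GeneSetCollection,
    n_perm: int = 10000,
    min_size: int = 5,
    max_size: int = 500,
    seed: int = 0,
    weight_exp: float = 1.0,
) -> list[EnrichmentResult]:
    """Permutation GSEA over all eligible sets of a collection."""
    if n_perm < 100:
        log.warning("n_perm=%d is very small; p-values will be coarse", n_perm)
    rng = np.random.default_rng(seed)
    id_pos = {gid.upper(): i for i, gid in enumerate(ranked.ids)}
    eligible: list[tuple[str, list[int]]] = []
    for name in sorted(sets.sets):
        positions = sorted(id_pos[m] for m in sets.sets[name].members if m in id_pos)
        if min_size <= len(positions) <= max_size and len(positions) < len(ranked):
            eligible.append((name, positions))
    if not eligible:
        raise FormatError("no gene set within size bounds overlaps the ranked list")

    null_cache: dict[int, np.ndarray] = {}
    partial: list[tuple[str, int, float, float, float, list[str]]] = []
    for name, positions in eligible:
        size = len(positions)
        member_ids = {ranked.ids[i] for i in positions}
        es, running = enrichment_score(ranked, member_ids, weight_exp)
        if size not in null_cache:
            null_cache[size] = _null_es(ranked.stats, size, n_perm, rng, weight_exp)
        nulls = null_cache[size]
        same_sign = nulls >= 0 if es >= 0 else nulls < 0
        n_same = int(same_sign.sum())
        p = (1.0 + float((np.abs(nulls[same_sign]) >= abs(es)).sum())) / (1.0 + n_same)
        mean_null = float(np.abs(nulls[same_sign]).mean()) if n_same else float("nan")
        nes = es / mean_null if n_same and mean_null > 0 else float("nan")
        extremum = int(np.argmax(running)) if es >= 0 else int(np.argmin(running))
        if es >= 0:
            ledge = [ranked.ids[i] for i in positions if i <= extremum]
        else:
            ledge = [ranked.ids[i] for i in positions if i >= extremum]
        partial.append((name, size, es, nes, p, ledge))
    fdrs = bh_adjust(np.array([t[4] for t in partial]))
    results = [
        EnrichmentResult(name, size, es, nes, p, float(fdr), ledge)
        for (name, size, es, nes, p, ledge), fdr in zip(partial, fdrs)
    ]
    return results
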