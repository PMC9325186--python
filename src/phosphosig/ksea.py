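"""Kinase-substrate enrichment: z-scores of substrate-set statistics against
the background of all quantified phosphosites.

For kinase k with m quantified substrate sites, the enrichment score is

    z_k = (mean(substrate stats) - mean(all site stats)) * sqrt(m) / sd(all)

with a two-sided p-value from the standard normal.  Positive z means the
kinase's substrates are collectively shifted toward BE (inferred activity
elevated in the lesion), negative toward adjacent normal.  The site statistic
is the moderated t of the site by default (consistent with the GSEA
ranking).  An independent permutation p-value drawing random same-size site
sets is available as a cross-check of the normal approximation.

Substrate matching is exact on canonical site ids (``GENE_S123``); map edges
that do not match any quantified site are counted and reported.  No
kinase-level multiple-testing correction is applied to the headline p < alpha
call, but BH q-values are reported alongside for transparency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .differential import bh_adjust
from .errors import FormatError
from .io_formats import KinaseSubstrateMap

log = logging.getLogger(__name__)


@dataclass
class KinaseEnrichment:
    kinase: str
    m: int
    mean_stat: float
    z: float
    p_value: float
    bh_q: float
    direction: str  # "BE" | "adjacent"
    n_unmatched_edges: int = 0


def kinase_zscores(
    site_stats: Mapping[str, float],
    ksmap: KinaseSubstrateMap,
    min_substrates: int = 3,
) -> list[KinaseEnrichment]:
    """Score every kinase with >= ``min_substrates`` quantified substrates."""
    ids = sorted(site_stats)
    stats = np.array([site_stats[i] for i in ids], dtype=float)
    if stats.size < 2:
        raise FormatError("need at least 2 site statistics")
    mu = float(stats.mean())
    sd = float(stats.std(ddof=1))
    if sd == 0:
        raise FormatError("background site statistics have zero spread")
    by_kinase = ksmap.substrates_by_kinase()
    records = []
    for kinase in sorted(by_kinase):
        subs = by_kinase[kinase]
        matched = [site_stats[s] for s in subs if s in site_stats]
        m = len(matched)
        if m < min_substrates:
            continue
        mean_sub = float(np.mean(matched))
        z = (mean_sub - mu) * np.sqrt(m) / sd
        p = float(np.clip(2.0 * sps.norm.sf(abs(z)), np.finfo(float).tiny, 1.0))
        records.append(
            KinaseEnrichment(
                kinase=kinase,
                m=m,
                mean_stat=mean_sub,
                z=float(z),
                p_value=p,
                bh_q=float("nan"),
                direction="BE" if z > 0 else "adjacent",
                n_unmatched_edges=len(subs) - m,
            )
        )
    if not records:
        log.warning("no kinase has >= %d quantified substrates", min_substrates)
        return []
    qs = bh_adjust(np.array([r.p_value for r in records]))
    for r, q in zip(records, qs):
        r.bh_q = float(q)
    return records


def kinase_permutation_p(
    site_stats: Mapping[str, float],
    ksmap: KinaseSubstrateMap,
    kinase: str,
    n_perm: int = 10000,
    seed: int = 0,
) -> float:
    """Permutation verification: random same-size site sets from the background."""
    if n_perm < 100:
        log.warning("n_perm=%d is very small for a permutation p-value", n_perm)
    ids = sorted(site_stats)
    stats = np.array([site_stats[i] for i in ids], dtype=float)
    subs = ksmap.substrates_by_kinase().get(kinase.upper(), set())
    matched = [site_stats[s] for s in subs if s in site_stats]
    if not matched:
        raise FormatError(f"kinase {kinase!r} has no quantified substrates")
    m = len(matched)
    mu = stats.mean()
    obs = abs(np.mean(matched) - mu)
    rng = np.random.default_rng(seed)
    draws = np.empty(n_perm)
    for r in range(n_perm):
        draws[r] = stats[rng.choice(stats.size, size=m, replace=False)].mean()
    return float((1.0 + np.sum(np.abs(draws - mu) >= obs)) / (1.0 + n_perm))


def significant_kinases(
    results: Sequence[KinaseEnrichment], alpha: float = 0.05
) -> list[KinaseEnrichment]:
    """Kinases with p < alpha, strongest |z| first."""
    hits = [r for r in results if r.p_value < alpha]
    return sorted(hits, key=lambda r: (-abs(r.z), r.kinase))


def kinase_substrate_edges(
    results: Sequence[KinaseEnrichment],
    ksmap: KinaseSubstrateMap,
    site_log2fc: Mapping[str, float],
):
    """Edge-list export for network graphing.

    One row per (kinase, substrate gene): of the substrate's quantified
    sites, the one with the largest |log2FC| represents the gene.
    """
    import pandas as pd

    wanted = {r.kinase for r in results}
    best: dict[tuple[str, str], tuple[str, float]] = {}
    for kinase, gene, site in sorted(ksmap.edges):
        if kinase not in wanted:
            continue
        sid = f"{gene}_{site}"
        if sid not in site_log2fc:
            continue
        lfc = site_log2fc[sid]
        key = (kinase, gene)
        if key not in best or abs(lfc) > abs(best[key][1]):
            best[key] = (site, lfc)
    rows = [
        {"kinase": k, "substrate": g, "site": site, "site_log2fc": lfc}
        for (k, g), (site, lfc) in sorted(best.items())
    ]
    return pd.DataFrame(rows, columns=["kinase", "substrate", "site", "site_log2fc"])
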