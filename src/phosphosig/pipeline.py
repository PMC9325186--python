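"""End-to-end orchestration: simulate -> preprocess -> differential ->
signature -> classify -> GSEA -> KSEA -> ADJ-vs-NONBE contrast.

Every stage writes its outputs as deterministic TSV/JSON under the run
directory; ``manifest.json`` records package version, parameters, per-stage
seeds and input digests (never wall-clock times, so two runs with the same
seed are byte-identical).  A master seed deterministically derives one child
seed per stage, so stages are reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .differential import (
    pair_differences,
    paired_moderated_t,
    results_to_frame,
    two_group_contrast,
)
from .errors import ConfigError, PhosphosigError
from .gsea import gsea_preranked, make_ranked_list
from .io_formats import (
    IntensityMatrix,
    read_design,
    read_gmt,
    read_intensity_table,
    read_kinase_substrate,
    write_design,
    write_gmt,
    write_intensity_table,
    write_kinase_substrate,
)
from .ksea import kinase_substrate_edges, kinase_zscores, significant_kinases
from .preprocessing import preprocess_matrix
from .signature import (
    SignatureSet,
    empirical_fdr,
    hierarchical_cluster,
    project_signature,
    select_signature,
)
from .synthetic import SimConfig, simulate_dataset, simulate_transcriptome

log = logging.getLogger(__name__)

STAGES = [
    "simulate",
    "preprocess",
    "diff",
    "signature",
    "classify",
    "gsea",
    "ksea",
    "contrast",
]


class StageError(RuntimeError):
    """A pipeline stage failed; completed outputs are preserved."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All pipeline parameters; defaults follow the analysis they emulate."""

    sim: SimConfig = field(default_factory=SimConfig)
    simulate: bool = True
    proteome_path: str | None = None
    phospho_path: str | None = None
    design_path: str | None = None
    gmt_path: str | None = None
    ksmap_path: str | None = None
    min_loc_prob: float = 0.7
    top_frac: float = 0.01
    min_abs_lfc: float = 0.75
    n_rand: int = 100
    n_perm: int = 10000
    alpha: float = 0.05
    fdr_pathway: float = 0.05
    min_set_size: int = 5
    max_set_size: int = 500
    min_substrates: int = 3
    k_validation: int = 3
    transcriptome_n_be: int = 7
    transcriptome_n_normal: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.top_frac <= 1:
            raise ConfigError("top_frac must lie in (0, 1]")
        if self.min_abs_lfc < 0:
            raise ConfigError("min_abs_lfc must be non-negative")
        if not 0 <= self.min_loc_prob <= 1:
            raise ConfigError("min_loc_prob must lie in [0, 1]")
        if self.n_rand < 1 or self.n_perm < 1:
            raise ConfigError("n_rand and n_perm must be positive")
        if not 0 < self.alpha < 1 or not 0 < self.fdr_pathway < 1:
            raise ConfigError("alpha and fdr_pathway must lie in (0, 1)")
        if not self.simulate:
            missing = [
                n for n in ("proteome_path", "phospho_path", "design_path",
                            "gmt_path", "ksmap_path")
                if getattr(self, n) is None
            ]
            if missing:
                raise ConfigError(f"simulate=false requires paths: {', '.join(missing)}")

    # -- YAML round trip -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["effect_size_range"] = list(d["sim"]["effect_size_range"])
        d["sim"]["geneset_size_range"] = list(d["sim"]["geneset_size_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        if isinstance(sim, dict):
            sim = dict(sim)
            for key in ("effect_size_range", "geneset_size_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            sim = SimConfig(**sim)
        return cls(sim=sim, **d)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Derive one sub-2^31 seed per stage from the master seed."""
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(STAGES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(STAGES, children)
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, allow_nan=True) + "\n")


def _signature_frame(sig: SignatureSet) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": sig.feature_ids,
            "direction": [d for _, d in sig.features],
        }
    )


def run_all(config: PipelineConfig, outdir) -> dict:
    """Execute every stage; return (and write) the run manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    manifest: dict = {
        "package": "phosphosig",
        "version": __version__,
        "parameters": config.to_dict(),
        "stage_seeds": seeds,
        "stages": [],
        "input_digests": {},
    }
    state: dict = {}
    for stage in STAGES:
        t0 = time.monotonic()
        try:
            outputs = _STAGE_FUNCS[stage](config, out, seeds[stage], state)
        except Exception as exc:  # noqa: BLE001 - abort with the stage name
            raise StageError(stage, exc) from exc
        log.info("stage %-10s done in %.1fs -> %s", stage, time.monotonic() - t0,
                 ", ".join(outputs))
        manifest["stages"].append({"name": stage, "outputs": sorted(outputs)})
    for name in sorted(state.get("input_files", [])):
        manifest["input_digests"][name] = _sha256(out / name)
    _write_json(manifest, out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: PipelineConfig, out: Path, seed: int, state: dict) -> list[str]:
    if config.simulate:
        sim_cfg = replace(config.sim, seed=seed)
        proteome, phospho, design, genesets, ksmap, truth = simulate_dataset(sim_cfg)
        expr, tx_labels = simulate_transcriptome(
            truth,
            n_be=config.transcriptome_n_be,
            n_normal=config.transcriptome_n_normal,
            correlation=sim_cfg.transcript_effect_correlation,
            seed=seed + 1,
        )
        write_intensity_table(proteome, out / "proteome_raw.tsv")
        write_intensity_table(phospho, out / "phospho_raw.tsv")
        write_design(design, out / "design.tsv")
        write_gmt(genesets, out / "genesets.gmt")
        write_kinase_substrate(ksmap, out / "ksmap.tsv")
        write_intensity_table(expr, out / "transcriptome.tsv")
        _write_tsv(
            pd.DataFrame(
                {"sample_id": list(tx_labels), "label": [tx_labels[s] for s in tx_labels]}
            ),
            out / "transcriptome_labels.tsv",
        )
        all_ids = proteome.feature_ids + phospho.feature_ids
        _write_tsv(
            pd.DataFrame(
                {
                    "feature": all_ids,
                    "true_effect": [truth.differential_features.get(f, 0.0) for f in all_ids],
                    "is_differential": [f in truth.differential_features for f in all_ids],
                }
            ),
            out / "truth.tsv",
        )
        rows = [
            {"name": name, "kind": "gene_set", "direction": d}
            for name, d in sorted(truth.planted_sets.items())
        ] + [
            {"name": name, "kind": "kinase", "direction": d}
            for name, d in sorted(truth.active_kinases.items())
        ]
        _write_tsv(pd.DataFrame(rows, columns=["name", "kind", "direction"]),
                   out / "truth_sets.tsv")
        state.update(
            proteome=proteome, phospho=phospho, design=design, genesets=genesets,
            ksmap=ksmap, truth=truth, transcriptome=expr, tx_labels=tx_labels,
        )
        state["input_files"] = [
            "proteome_raw.tsv", "phospho_raw.tsv", "design.tsv", "genesets.gmt",
            "ksmap.tsv", "transcriptome.tsv",
        ]
        return state["input_files"] + ["truth.tsv", "truth_sets.tsv", "transcriptome_labels.tsv"]
    # user-supplied inputs
    for name in ("proteome_path", "phospho_path", "design_path", "gmt_path", "ksmap_path"):
        p = Path(getattr(config, name))
        if not p.exists():
            raise PhosphosigError(f"input file not found: {p}")
    state.update(
        proteome=read_intensity_table(config.proteome_path, "protein"),
        phospho=read_intensity_table(config.phospho_path, "phosphosite"),
        design=read_design(config.design_path),
        genesets=read_gmt(config.gmt_path),
        ksmap=read_kinase_substrate(config.ksmap_path),
        truth=None, transcriptome=None, tx_labels=None,
    )
    state["input_files"] = []
    return []


def _stage_preprocess(config: PipelineConfig, out: Path, seed: int, state: dict) -> list[str]:
    design = state["design"]
    outputs = []
    for level, key in (("proteome", "proteome"), ("phospho", "phospho")):
        raw: IntensityMatrix = state[key]
        for cohort in ("discovery", "validation"):
            sample_ids = [d.sample_id for d in design
                          if d.cohort == cohort and d.sample_id in raw.samples]
            if not sample_ids:
                continue
            sub = raw.subset_samples(sample_ids)
            norm, report = preprocess_matrix(sub, design, min_loc_prob=config.min_loc_prob)
            state[f"{key}_{cohort}"] = norm
            name = f"{level}_{cohort}_normalized.tsv"
            write_intensity_table(norm, out / name)
            outputs.append(name)
            state.setdefault("preprocess_reports", {})[f"{level}_{cohort}"] = report
    rows = [
        {
            "matrix": name,
            "n_input": rep.n_input_features,
            "n_after_localization": rep.n_after_localization,
            "n_after_completeness": rep.n_after_completeness,
        }
        for name, rep in sorted(state["preprocess_reports"].items())
    ]
    _write_tsv(pd.DataFrame(rows), out / "preprocess_report.tsv")
    return outputs + ["preprocess_report.tsv"]


def _stage_diff(config: PipelineConfig, out: Path, seed: int, state: dict) -> list[str]:
    design = state["design"]
    outputs = []
    for key, level in (("proteome", "protein"), ("phospho", "phosphosite")):
        for cohort in ("discovery", "validation"):
            matrix = state.get(f"{key}_{cohort}")
            if matrix is None:
                continue
            diffs = pair_differences(matrix, design)
            results, hyper = paired_moderated_t(diffs)
            state[f"diff_{key}_{cohort}"] = results
            name = f"diff_{key}_{cohort}.tsv"
            _write_tsv(results_to_frame(results), out / name)
            outputs.append(name)
    return outputs


def _stage_signature(config: PipelineConfig, out: Path, seed: int, state: dict) -> list[str]:
    design = state["design"]
    outputs = []
    for key in ("proteome", "phospho"):
        results = state[f"diff_{key}_discovery"]
        sig = select_signature(results, config.top_frac, config.min_abs_lfc)
        sig.n_randomizations = config.n_rand
        sig.empirical_fdr = empirical_fdr(
            state[f"{key}_discovery"],
            design,
            top_frac=config.top_frac,
            min_abs_lfc=config.min_abs_lfc,
            n_rand=config.n_rand,
            seed=seed,
        )
        state[f"signature_{key}"] = sig
        name = f"signature_{key}.tsv"
        _write_tsv(_signature_frame(sig), out / name)
        outputs.append(name)
    _write_json(
        {
            key: {
                "n_features": len(state[f"signature_{key}"]),
                "n_up": state[f"signature_{key}"].n_up,
                "n_down": state[f"signature_{key}"].n_down,
                "empirical_fdr": state[f"signature_{key}"].empirical_fdr,
                "n_randomizations": config.n_rand,
            }
            for key in ("proteome", "phospho")
        },
        out / "signature_summary.json",
    )
    return outputs + ["signature_summary.json"]


def _stage_classify(config: PipelineConfig, out: Path, seed: int, state: dict) -> list[str]:
    design = state["design"]
    sig = state["signature_proteome"]
    summary = {}
    outputs = []
    val = state.get("proteome_validation")
    if val is not None and len(sig) > 0:
        projected = project_signature(val, sig)
        labels = {d.sample_id: d.tissue_class for d in design}
        clust = hierarchical_cluster(projected, k=config.k_validation, labels=labels)
        state["classify_validation"] = clust
        _write_tsv(
            pd.DataFrame(
                {
                    "sample_id": sorted(clust.cluster_assignments),
                    "cluster": [clust.cluster_assignments[s]
                                for s in sorted(clust.cluster_assignments)],
                    "label": [labels[s] for s in sorted(clust.cluster_assignments)],
                }
            ),
            out / "clusters_validation.tsv",
        )
        outputs.append("clusters_validation.tsv")
        summary["validation"] = {
            "k": clust.k, "purity": clust.purity, "adjusted_rand": clust.adjusted_rand,
            "n_signature_features_used": projected.n_features,
        }
    tx = state.get("transcriptome")
    if tx is not None and len(sig) > 0:
        projected = project_signature(tx, sig)
        clust = hierarchical_cluster(projected, k=2, labels=state["tx_labels"])
        state["classify_transcriptome"] = clust
        _write_tsv(
            pd.DataFrame(
                {
                    "sample_id": sorted(clust.cluster_assignments),
                    "cluster": [clust.cluster_assignments[s]
                                for s in sorted(clust.cluster_assignments)],
                    "label": [state["tx_labels"][s]
                              for s in sorted(clust.cluster_assignments)],
                }
            ),
            out / "clusters_transcriptome.tsv",
        )
        outputs.append("clusters_transcriptome.tsv")
        summary["transcriptome"] = {
            "k": 2, "purity": clust.purity, "adjusted_rand": clust.adjusted_rand,
            "n_signature_features_used": projected.n_features,
        }
    _write_json(summary, out / "classify_summary.json")
    return outputs + ["classify_summary.json"]


def _stage_gsea(config: PipelineConfig, out: Path, seed: int, state: dict) -> list[str]:
    genesets = state["genesets"]
    outputs = []
    for i, (key, level) in enumerate((("proteome", "protein"), ("phospho", "phosphosite"))):
        results = state[f"diff_{key}_discovery"]
        gene_map = {f.feature_id: f.gene_symbol for f in state[f"{key}_discovery"].features}
        ranked = make_ranked_list(results, level=level, gene_map=gene_map)
        enr = gsea_preranked(
            ranked, genesets,
            n_perm=config.n_perm, min_size=config.min_set_size,
            max_size=config.max_set_size, seed=seed + i,
        )
        state[f"gsea_{key}"] = enr
        name = f"gsea_{key}.tsv"
        _write_tsv(
            pd.DataFrame(
                {
                    "set_name": [e.set_name for e in enr],
                    "size": [e.size for e in enr],
                    "es": [e.es for e in enr],
                    "nes": [e.nes for e in enr],
                    "p_value": [e.p_value for e in enr],
                    "fdr": [e.fdr for e in enr],
                    "leading_edge": [",".join(e.leading_edge) for e in enr],
                }
            ),
            out / name,
        )
        outputs.append(name)
    return outputs


def _stage_ksea(config: PipelineConfig, out: Path, seed: int, state: dict) -> list[str]:
    results = state["diff_phospho_discovery"]
    matrix = state["phospho_discovery"]
    canonical = {f.feature_id: f.canonical_id for f in matrix.features}
    site_stats = {
        canonical[r.feature_id]: r.t_mod
        for r in results
        if not r.zero_variance and np.isfinite(r.t_mod)
    }
    site_lfc = {canonical[r.feature_id]: r.log2fc for r in results}
    enr = kinase_zscores(site_stats, state["ksmap"], min_substrates=config.min_substrates)
    state["ksea"] = enr
    sig = significant_kinases(enr, alpha=config.alpha)
    state["ksea_significant"] = sig
    _write_tsv(
        pd.DataFrame(
            {
                "kinase": [r.kinase for r in enr],
                "m": [r.m for r in enr],
                "mean_stat": [r.mean_stat for r in enr],
                "z": [r.z for r in enr],
                "p_value": [r.p_value for r in enr],
                "bh_q": [r.bh_q for r in enr],
                "direction": [r.direction for r in enr],
            }
        ),
        out / "kinases.tsv",
    )
    edges = kinase_substrate_edges(sig, state["ksmap"], site_lfc)
    _write_tsv(edges, out / "kinase_network_edges.tsv")
    return ["kinases.tsv", "kinase_network_edges.tsv"]


def _stage_contrast(config: PipelineConfig, out: Path, seed: int, state: dict) -> list[str]:
    """ADJ vs NONBE unpaired contrast on the merged normalized proteome."""
    design = state["design"]
    mats = [state[k] for k in ("proteome_discovery", "proteome_validation") if k in state]
    if not mats:
        raise PhosphosigError("no normalized proteome matrices available")
    common = set(mats[0].feature_ids)
    for m in mats[1:]:
        common &= set(m.feature_ids)
    common_sorted = sorted(common)
    pieces = []
    for m in mats:
        idx = {f: i for i, f in enumerate(m.feature_ids)}
        pieces.append(m.subset_features(np.array([idx[f] for f in common_sorted])))
    merged = IntensityMatrix(
        pieces[0].features,
        [s for m in pieces for s in m.samples],
        np.concatenate([m.values for m in pieces], axis=1),
        scale=pieces[0].scale,
    )
    results = two_group_contrast(merged, design, "ADJ", "NONBE")
    state["contrast_adj_nonbe"] = results
    _write_tsv(results_to_frame(results), out / "contrast_adj_vs_nonbe.tsv")
    return ["contrast_adj_vs_nonbe.tsv"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "diff": _stage_diff,
    "signature": _stage_signature,
    "classify": _stage_classify,
    "gsea": _stage_gsea,
    "ksea": _stage_ksea,
    "contrast": _stage_contrast,
}


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def make_report(outdir) -> Path:
    """Summarize a completed run into report.md plus volcano-plot TSVs."""
    out = Path(outdir)
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        raise PhosphosigError("run incomplete: manifest.json missing")
    manifest = json.loads(manifest_path.read_text())
    done = {s["name"] for s in manifest["stages"]}
    missing = [s for s in STAGES if s not in done]
    if missing:
        raise PhosphosigError(f"run incomplete: missing stages {', '.join(missing)}")

    lines = ["# Pipeline run report", ""]
    pre = pd.read_csv(out / "preprocess_report.tsv", sep="\t")
    lines.append("## Feature counts through preprocessing")
    lines.append("")
    for _, row in pre.iterrows():
        lines.append(
            f"- {row['matrix']}: {row['n_input']} input, "
            f"{row['n_after_localization']} after localization filter, "
            f"{row['n_after_completeness']} complete"
        )
    sig = json.loads((out / "signature_summary.json").read_text())
    lines += ["", "## Signature"]
    for key in sorted(sig):
        s = sig[key]
        efdr = s["empirical_fdr"]
        efdr_s = "undefined" if efdr is None or (isinstance(efdr, float) and np.isnan(efdr)) \
            else f"{efdr:.3f}"
        lines.append(
            f"- {key}: {s['n_features']} features "
            f"({s['n_up']} up in BE, {s['n_down']} down); "
            f"empirical FDR {efdr_s} ({s['n_randomizations']} randomizations)"
        )
    cls = json.loads((out / "classify_summary.json").read_text())
    lines += ["", "## Classification of independent cohorts"]
    for key in sorted(cls):
        c = cls[key]
        lines.append(
            f"- {key}: k={c['k']}, purity {c['purity']:.3f}, "
            f"adjusted Rand {c['adjusted_rand']:.3f} "
            f"({c['n_signature_features_used']} signature features used)"
        )
    lines += ["", "## Pathway enrichment (FDR < %g)" % manifest["parameters"]["fdr_pathway"]]
    for key in ("proteome", "phospho"):
        df = pd.read_csv(out / f"gsea_{key}.tsv", sep="\t")
        n_sig = int((df["fdr"] < manifest["parameters"]["fdr_pathway"]).sum())
        lines.append(f"- {key}: {n_sig} of {len(df)} sets enriched")
    kin = pd.read_csv(out / "kinases.tsv", sep="\t")
    n_kin = int((kin["p_value"] < manifest["parameters"]["alpha"]).sum())
    lines += ["", "## Kinase enrichment",
              f"- {n_kin} of {len(kin)} scored kinases significant "
              f"(p < {manifest['parameters']['alpha']:g})"]

    for key in ("proteome", "phospho"):
        df = pd.read_csv(out / f"diff_{key}_discovery.tsv", sep="\t")
        volcano = pd.DataFrame(
            {
                "feature_id": df["feature_id"],
                "log2fc": df["log2fc"],
                "neg_log10_p": -np.log10(df["p_value"]),
            }
        )
        _write_tsv(volcano, out / f"volcano_{key}.tsv")
    report = out / "report.md"
    report.write_text("\n".join(lines) + "\n")
    return report
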