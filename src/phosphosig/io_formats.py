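"""Readers, writers and typed in-memory containers for the pipeline's external formats.

All downstream modules operate on the objects defined here:

* :class:`IntensityMatrix` -- features x samples abundance grid with a missing
  mask (NaN cells), at raw, log2 or quantile-normalized scale.
* :class:`SampleDesign` -- one record per TMT channel/sample, carrying the
  patient pairing that defines the BE vs adjacent-normal contrast.
* :class:`GeneSetCollection` -- named gene sets read from GMT.
* :class:`KinaseSubstrateMap` -- curated kinase -> (substrate gene, site) edges.

Conventions: intensity tables are MaxQuant-style TSV with one row per feature;
zero and blank intensity cells are treated as missing (zero reporter intensity
is non-detection, not a measurement).  Site positions are 1-based.  Phosphosite
features are joined to the kinase-substrate map through the canonical id
``GENE_<residue><position>`` (e.g. ``CRNN_S383``); gene symbols are matched
case-insensitively after trimming.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DesignError, FormatError

TISSUE_CLASSES = ("BE", "ADJ", "NONBE")
COHORTS = ("discovery", "validation")
SITE_RE = re.compile(r"^([STY])([1-9][0-9]*)$")

_DESIGN_COLUMNS = ["sample_id", "patient_id", "tissue_class", "cohort", "tmt_channel"]
_PHOS_META = ["feature_id", "gene_symbol", "site_residue", "site_position", "localization_prob"]
_PROT_META = ["feature_id", "gene_symbol"]

# %.17g round-trips IEEE doubles exactly through decimal text.
_FLOAT_FMT = "%.17g"


def canonical_site_id(gene_symbol: str, residue: str, position: int) -> str:
    """Canonical phosphosite id used to join quantification and kinase maps."""
    return f"{gene_symbol.strip().upper()}_{residue}{int(position)}"


@dataclass(frozen=True)
class FeatureRecord:
    """One quantified feature: a protein group or a localized phosphosite."""

    feature_id: str
    gene_symbol: str
    level: str  # "protein" | "phosphosite"
    site_residue: str | None = None
    site_position: int | None = None
    localization_prob: float | None = None

    def __post_init__(self) -> None:
        if self.level not in ("protein", "phosphosite"):
            raise FormatError(f"unknown feature level {self.level!r}")
        site_fields = (self.site_residue, self.site_position, self.localization_prob)
        if self.level == "phosphosite":
            if any(v is None for v in site_fields):
                raise FormatError(
                    f"phosphosite feature {self.feature_id!r} must carry "
                    "site_residue, site_position and localization_prob"
                )
            if self.site_residue not in ("S", "T", "Y"):
                raise FormatError(
                    f"feature {self.feature_id!r}: site residue must be S, T or Y, "
                    f"got {self.site_residue!r}"
                )
            if int(self.site_position) < 1:
                raise FormatError(f"feature {self.feature_id!r}: site position must be >= 1")
            if not 0.0 <= float(self.localization_prob) <= 1.0:
                raise FormatError(
                    f"feature {self.feature_id!r}: localization_prob outside [0, 1]"
                )
        else:
            if any(v is not None for v in site_fields):
                raise FormatError(
                    f"protein feature {self.feature_id!r} must not carry site fields"
                )

    @property
    def canonical_id(self) -> str:
        if self.level == "phosphosite":
            return canonical_site_id(self.gene_symbol, self.site_residue, self.site_position)
        return self.feature_id


class IntensityMatrix:
    """Features x samples abundance grid; NaN marks missing cells.

    ``scale`` tracks the transformation state: ``raw`` (positive intensities),
    ``log2``, or ``log2_quantile_normalized``.
    """

    SCALES = ("raw", "log2", "log2_quantile_normalized")

    def __init__(
        self,
        features: Sequence[FeatureRecord],
        samples: Sequence[str],
        values: np.ndarray,
        scale: str = "raw",
    ) -> None:
        if scale not in self.SCALES:
            raise FormatError(f"unknown scale {scale!r}")
        values = np.asarray(values, dtype=float)
        if values.shape != (len(features), len(samples)):
            raise FormatError(
                f"values shape {values.shape} does not match "
                f"{len(features)} features x {len(samples)} samples"
            )
        ids = [f.feature_id for f in features]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate feature ids: {', '.join(dupes)}")
        if len(set(samples)) != len(samples):
            raise FormatError("duplicate sample ids")
        if scale == "raw":
            present = values[~np.isnan(values)]
            if present.size and not np.all(present > 0):
                raise FormatError("raw-scale matrix contains non-positive present values")
        self.features = list(features)
        self.samples = list(samples)
        self.values = values
        self.scale = scale

    # -- basic introspection -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return [f.feature_id for f in self.features]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def level(self) -> str | None:
        levels = {f.level for f in self.features}
        if len(levels) > 1:
            raise FormatError("matrix mixes protein and phosphosite features")
        return levels.pop() if levels else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.samples)

    # -- subsetting ----------------------------------------------------------
    def subset_features(self, keep: np.ndarray | Sequence[int]) -> "IntensityMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        feats = [self.features[i] for i in keep]
        return IntensityMatrix(feats, self.samples, self.values[keep, :], self.scale)

    def subset_samples(self, sample_ids: Sequence[str]) -> "IntensityMatrix":
        index = {s: j for j, s in enumerate(self.samples)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise FormatError(f"samples not in matrix: {', '.join(missing)}")
        cols = [index[s] for s in sample_ids]
        return IntensityMatrix(self.features, list(sample_ids), self.values[:, cols], self.scale)

    def with_values(self, values: np.ndarray, scale: str | None = None) -> "IntensityMatrix":
        return IntensityMatrix(self.features, self.samples, values, scale or self.scale)


@dataclass(frozen=True)
class SampleDesign:
    """One sample/channel of a TMT plex."""

    sample_id: str
    patient_id: str
    tissue_class: str
    cohort: str
    tmt_channel: str

    def __post_init__(self) -> None:
        if self.tissue_class not in TISSUE_CLASSES:
            raise DesignError(
                f"sample {self.sample_id!r}: tissue_class must be one of "
                f"{TISSUE_CLASSES}, got {self.tissue_class!r}"
            )
        if self.cohort not in COHORTS:
            raise DesignError(
                f"sample {self.sample_id!r}: cohort must be one of {COHORTS}, "
                f"got {self.cohort!r}"
            )


def validate_design(design: Sequence[SampleDesign]) -> None:
    """Enforce uniqueness and the within-patient BE/ADJ pairing invariant."""
    ids = [d.sample_id for d in design]
    if len(set(ids)) != len(ids):
        raise DesignError("duplicate sample_id in design")
    chans = [(d.cohort, d.tmt_channel) for d in design]
    if len(set(chans)) != len(chans):
        raise DesignError("duplicate (cohort, tmt_channel) in design")
    by_patient: dict[tuple[str, str], dict[str, int]] = {}
    for d in design:
        counts = by_patient.setdefault((d.cohort, d.patient_id), {c: 0 for c in TISSUE_CLASSES})
        counts[d.tissue_class] += 1
    for (cohort, patient), counts in sorted(by_patient.items()):
        if counts["BE"] > 0:
            if counts["BE"] != 1 or counts["ADJ"] != 1:
                raise DesignError(
                    f"patient {patient!r} (cohort {cohort}) must contribute exactly one "
                    f"BE and one ADJ sample; got BE={counts['BE']}, ADJ={counts['ADJ']}"
                )
            if counts["NONBE"] > 0:
                raise DesignError(
                    f"patient {patient!r} (cohort {cohort}) mixes BE and NONBE samples"
                )
        elif counts["ADJ"] > 0:
            raise DesignError(
                f"patient {patient!r} (cohort {cohort}) has an ADJ sample without a BE partner"
            )


def paired_patients(
    design: Sequence[SampleDesign], cohort: str | None = None
) -> list[tuple[str, str, str]]:
    """Return sorted (patient_id, be_sample_id, adj_sample_id) triples."""
    rows = [d for d in design if cohort is None or d.cohort == cohort]
    be = {(d.cohort, d.patient_id): d.sample_id for d in rows if d.tissue_class == "BE"}
    adj = {(d.cohort, d.patient_id): d.sample_id for d in rows if d.tissue_class == "ADJ"}
    pairs = []
    for key in sorted(be):
        if key not in adj:
            raise DesignError(f"patient {key[1]!r} has BE sample but no ADJ partner")
        pairs.append((key[1], be[key], adj[key]))
    return pairs


@dataclass
class GeneSet:
    description: str
    members: set[str]


@dataclass
class GeneSetCollection:
    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def add(self, name: str, description: str, members: Iterable[str]) -> None:
        if name in self.sets:
            raise FormatError(f"duplicate gene set name {name!r}")
        members = {m.strip().upper() for m in members if m.strip()}
        if not members:
            raise FormatError(f"gene set {name!r} is empty")
        self.sets[name] = GeneSet(description, members)


@dataclass
class KinaseSubstrateMap:
    """Set of (kinase, substrate_gene, site) edges; genes upper-cased."""

    edges: set[tuple[str, str, str]] = field(default_factory=set)

    def add(self, kinase: str, substrate_gene: str, site: str) -> None:
        site = site.strip().upper()
        if not SITE_RE.match(site):
            raise FormatError(
                f"malformed site {site!r} for kinase {kinase!r} "
                "(expected residue S/T/Y followed by a positive integer)"
            )
        self.edges.add((kinase.strip().upper(), substrate_gene.strip().upper(), site))

    def substrates_by_kinase(self) -> dict[str, set[str]]:
        """Map kinase -> set of canonical substrate site ids (GENE_S123)."""
        out: dict[str, set[str]] = {}
        for kinase, gene, site in self.edges:
            out.setdefault(kinase, set()).add(f"{gene}_{site}")
        return out


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc


def read_intensity_table(path, level: str, scale: str = "raw") -> IntensityMatrix:
    """Read a MaxQuant-style feature x channel intensity TSV.

    Zero and blank cells become missing.  For ``level='phosphosite'`` the
    site residue/position/localization columns are required.  Pass
    ``scale='log2'`` (or ``'log2_quantile_normalized'``) to re-read matrices
    this package wrote after transformation; zero cells are then taken at
    face value, not as missing.
    """
    df = _read_tsv(path)
    meta_cols = _PHOS_META if level == "phosphosite" else _PROT_META
    for col in meta_cols:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    sample_cols = [c for c in df.columns if c not in meta_cols]
    if not sample_cols:
        raise FormatError(f"{path}: no intensity columns found")

    ids = df["feature_id"].str.strip()
    dup = ids[ids.duplicated()].unique()
    if dup.size:
        raise FormatError(f"{path}: duplicate feature_id: {', '.join(sorted(dup))}")

    features = []
    for _, row in df.iterrows():
        if level == "phosphosite":
            try:
                pos = int(row["site_position"])
                prob = float(row["localization_prob"])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: feature {row['feature_id']!r}: bad site metadata"
                ) from exc
            features.append(
                FeatureRecord(
                    feature_id=row["feature_id"].strip(),
                    gene_symbol=row["gene_symbol"].strip().upper(),
                    level="phosphosite",
                    site_residue=row["site_residue"].strip(),
                    site_position=pos,
                    localization_prob=prob,
                )
            )
        else:
            features.append(
                FeatureRecord(
                    feature_id=row["feature_id"].strip(),
                    gene_symbol=row["gene_symbol"].strip().upper(),
                    level="protein",
                )
            )

    values = np.full((len(df), len(sample_cols)), np.nan)
    for j, col in enumerate(sample_cols):
        # float() is correctly rounded, so written values re-read exactly
        for i, cell in enumerate(df[col].str.strip()):
            if cell == "":
                continue
            try:
                v = float(cell)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric intensity {cell!r} in column {col!r}, "
                    f"line {i + 2}"  # header is line 1
                ) from None
            if np.isnan(v):
                continue
            values[i, j] = v
        if scale == "raw":
            col_vals = values[:, j]
            col_vals[col_vals == 0.0] = np.nan  # zero intensity = non-detection
    return IntensityMatrix(features, sample_cols, values, scale=scale)


def read_design(path) -> list[SampleDesign]:
    df = _read_tsv(path)
    for col in _DESIGN_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    design = [
        SampleDesign(
            sample_id=row["sample_id"].strip(),
            patient_id=row["patient_id"].strip(),
            tissue_class=row["tissue_class"].strip(),
            cohort=row["cohort"].strip(),
            tmt_channel=row["tmt_channel"].strip(),
        )
        for _, row in df.iterrows()
    ]
    validate_design(design)
    return design


def read_gmt(path) -> GeneSetCollection:
    collection = GeneSetCollection()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >= 3 tab-separated fields")
            name, desc, *members = parts
            collection.add(name.strip(), desc.strip(), members)
    return collection


def read_kinase_substrate(path) -> KinaseSubstrateMap:
    df = _read_tsv(path)
    for col in ("kinase", "substrate_gene", "site"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    ksmap = KinaseSubstrateMap()
    for _, row in df.iterrows():
        ksmap.add(row["kinase"], row["substrate_gene"], row["site"])
    return ksmap


# ---------------------------------------------------------------------------
# writers (deterministic column and row order)
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return "" if np.isnan(x) else _FLOAT_FMT % x


def write_intensity_table(matrix: IntensityMatrix, path) -> None:
    meta_cols = _PHOS_META if matrix.level == "phosphosite" else _PROT_META
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(meta_cols + matrix.samples) + "\n")
        for i, feat in enumerate(matrix.features):
            if matrix.level == "phosphosite":
                meta = [
                    feat.feature_id,
                    feat.gene_symbol,
                    feat.site_residue,
                    str(feat.site_position),
                    _FLOAT_FMT % feat.localization_prob,
                ]
            else:
                meta = [feat.feature_id, feat.gene_symbol]
            fh.write("\t".join(meta + [_fmt(v) for v in matrix.values[i]]) + "\n")


def write_design(design: Sequence[SampleDesign], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_DESIGN_COLUMNS) + "\n")
        for d in design:
            fh.write(
                "\t".join([d.sample_id, d.patient_id, d.tissue_class, d.cohort, d.tmt_channel])
                + "\n"
            )


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(collection.sets):
            gs = collection.sets[name]
            fh.write("\t".join([name, gs.description] + sorted(gs.members)) + "\n")


def write_kinase_substrate(ksmap: KinaseSubstrateMap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("kinase\tsubstrate_gene\tsite\n")
        for kinase, gene, site in sorted(ksmap.edges):
            fh.write(f"{kinase}\t{gene}\t{site}\n")
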