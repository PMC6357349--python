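"""Per-variant feature matrix assembly, zero-imputation and z-scoring.

The matrix is pandas-backed: rows are variants (ids ``contig:pos:ref:alt``),
columns are named features.  Missing values (no score-table key, undefined
geometry on single-exon transcripts, ...) are tracked in a boolean mask, set
to zero on the raw scale, and only then z-score normalised — normalisation
parameters are fitted on training rows and frozen for any later data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import features as ft
from . import external_scores as xs
from . import genomic_io as gio

logger = logging.getLogger(__name__)

#: the optimised feature set (native geometry/motif/codon features plus the
#: score-table and track columns they are usually paired with)
DEFAULT_FEATURES = [
    "dsp",
    "tfbs",
    "mde",
    "dve",
    "ese_dens",
    "mes",
    "sr_lost",
    "dpsiz",
    "ver_phylop",
    "te",
]

#: native features computed from sequence/annotation (everything else is
#: resolved against score tables / BED tracks by column name)
NATIVE_FEATURES = {
    "dsp",
    "mde",
    "dve",
    "ese_dens",
    "mes",
    "mes_alt",
    "sr_lost",
    "sr_gained",
    "te",
    "te_delta",
    "delta_rscu",
    "cpg",
    "rel_pos",
}

LABEL_CODES = {"deleterious": 1, "benign": 0}


@dataclass
class ExtractorConfig:
    """Resources needed by the feature extractors.

    Score tables and BED tracks are keyed by the feature-column name they
    populate; any configured feature name not in :data:`NATIVE_FEATURES`
    must appear in one of these mappings.
    """

    features: list[str] = field(default_factory=lambda: list(DEFAULT_FEATURES))
    ese_motifs: ft.MotifSet | None = None
    sr_motifs: ft.MotifSet | None = None
    splice_model: ft.SpliceModel | None = None
    usage: ft.CodonUsageTable | None = None
    trna: ft.TrnaTable | None = None
    position_tables: dict[str, xs.ScoreTable] = field(default_factory=dict)
    allele_tables: dict[str, xs.ScoreTable] = field(default_factory=dict)
    tracks: dict[str, xs.IntervalTrack] = field(default_factory=dict)


@dataclass
class FeatureMatrix:
    """Variants x features with a missing mask, optional labels, and, once
    fitted, per-feature normalisation parameters."""

    values: pd.DataFrame  # float; NaN where missing (before imputation)
    missing_mask: pd.DataFrame  # bool, same shape
    labels: pd.Series | None = None  # 1 = deleterious, 0 = benign
    norm_params: pd.DataFrame | None = None  # index=feature, cols mean/sd
    rejected: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.values.shape != self.missing_mask.shape:
            raise ValueError("values and missing_mask shapes differ")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate feature names")

    @property
    def variant_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(
            self.values.copy(),
            self.missing_mask.copy(),
            None if self.labels is None else self.labels.copy(),
            None if self.norm_params is None else self.norm_params.copy(),
            list(self.rejected),
        )

    def to_tsv(self, path: str) -> None:
        out = self.values.copy()
        out.insert(0, "variant_id", out.index)
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path: str, labels_path: str | None = None) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
        df = df.set_index("variant_id")
        df = df.astype(float)
        labels = None
        if labels_path is not None:
            lab = pd.read_csv(labels_path, sep="\t", dtype={"variant_id": str})
            lab = lab.set_index("variant_id")["label"]
            labels = lab.map(lambda v: LABEL_CODES.get(v, v)).astype(int)
            labels = labels.reindex(df.index)
        return cls(df, df.isna(), labels=labels)


def _compute_native(
    name: str,
    ctx: gio.CodingContext,
    tx: gio.Transcript,
    genome: gio.GenomeSequence,
    config: ExtractorConfig,
    cache: dict,
) -> float | None:
    if name == "dsp":
        return ft.dsp(ctx, tx)
    if name == "mde":
        return ft.mde(ctx, tx)
    if name == "dve":
        return ft.dve(ctx, tx)
    if name == "cpg":
        return float(ft.cpg_context(ctx, genome))
    if name == "rel_pos":
        return ft.relative_mrna_position(ctx, tx)
    if name == "ese_dens":
        if config.ese_motifs is None:
            return None
        return ft.ese_density(ft.exon_sequence(ctx, tx, genome), config.ese_motifs)
    if name in ("mes", "mes_alt"):
        if config.splice_model is None:
            return None
        return ft.max_splice_site_score(
            ctx, tx, genome, config.splice_model, use_alt=(name == "mes_alt")
        )
    if name in ("sr_lost", "sr_gained"):
        if config.sr_motifs is None:
            return None
        if "sr" not in cache:
            ref_w, alt_w = ft.variant_motif_windows(ctx, tx, genome)
            cache["sr"] = ft.motif_gain_loss(ref_w, alt_w, config.sr_motifs)
        gained, lost = cache["sr"]
        return float(lost if name == "sr_lost" else gained)
    if name in ("te", "te_delta"):
        if config.trna is None:
            return None
        if "tai" not in cache:
            cache["tai"] = ft.tai_weights(config.trna)
        return ft.te_feature(ctx, cache["tai"], delta=(name == "te_delta"))
    if name == "delta_rscu":
        if config.usage is None:
            return None
        if "rscu" not in cache:
            cache["rscu"] = ft.rscu_table(config.usage)
        return ft.delta_rscu(ctx, cache["rscu"])
    raise KeyError(name)


def assemble(
    variants: list[gio.Variant],
    gene_models: list[gio.Transcript],
    genome: gio.GenomeSequence,
    config: ExtractorConfig | None = None,
) -> FeatureMatrix:
    """One feature row per synonymous variant, columns in configured order.

    Variants that are non-coding or non-synonymous in their canonical
    transcript are excluded and listed in ``rejected`` as (id, reason).
    """
    if not variants:
        raise ValueError("no variants to assemble")
    config = config or ExtractorConfig()
    for name in config.features:
        if name not in NATIVE_FEATURES and not (
            name in config.position_tables
            or name in config.allele_tables
            or name in config.tracks
        ):
            raise KeyError(
                f"feature {name!r} is neither native nor backed by a "
                "score table or track"
            )

    shared_cache: dict = {}
    rows, mask_rows, ids, label_vals = [], [], [], []
    rejected: list[tuple[str, str]] = []
    for variant in variants:
        try:
            tx = gio.choose_canonical_transcript(variant, gene_models)
            ctx = gio.project_variant(variant, tx, genome)
        except ValueError as exc:
            rejected.append((variant.id, str(exc)))
            continue
        if not gio.is_synonymous(ctx):
            rejected.append((variant.id, "not synonymous"))
            continue
        cache = dict(shared_cache)
        row, mask = [], []
        for name in config.features:
            if name in NATIVE_FEATURES:
                value = _compute_native(name, ctx, tx, genome, config, cache)
            elif name in config.position_tables:
                value = xs.lookup_position_score(
                    config.position_tables[name], variant.contig, variant.pos
                )
            elif name in config.allele_tables:
                value = xs.lookup_allele_score(
                    config.allele_tables[name],
                    variant.contig,
                    variant.pos,
                    variant.ref,
                    variant.alt,
                )
            else:
                value = float(
                    xs.in_track(config.tracks[name], variant.contig, variant.pos)
                )
            row.append(math.nan if value is None else float(value))
            mask.append(value is None)
        # tAI weights and RSCU are variant-independent; keep them shared
        for key in ("tai", "rscu"):
            if key in cache:
                shared_cache[key] = cache[key]
        rows.append(row)
        mask_rows.append(mask)
        ids.append(variant.id)
        label_vals.append(LABEL_CODES.get(variant.label))
    if rejected:
        logger.info("assemble: excluded %d variants", len(rejected))
    if not rows:
        raise ValueError("all variants were rejected during assembly")
    values = pd.DataFrame(rows, index=ids, columns=config.features, dtype=float)
    mask = pd.DataFrame(mask_rows, index=ids, columns=config.features, dtype=bool)
    labels = None
    if all(v is not None for v in label_vals):
        labels = pd.Series(label_vals, index=ids, dtype=int, name="label")
    return FeatureMatrix(values, mask, labels=labels, rejected=rejected)


def impute_missing(matrix: FeatureMatrix) -> FeatureMatrix:
    """Set every missing cell to zero on the raw scale; the mask is retained."""
    out = matrix.copy()
    out.values = out.values.fillna(0.0)
    return out


def zscore_fit(matrix: FeatureMatrix) -> pd.DataFrame:
    """Per-feature mean and sample (n-1) standard deviation over rows."""
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 rows to fit normalisation")
    params = pd.DataFrame(
        {"mean": matrix.values.mean(axis=0), "sd": matrix.values.std(axis=0, ddof=1)}
    )
    return params


def zscore_apply(matrix: FeatureMatrix, norm_params: pd.DataFrame) -> FeatureMatrix:
    """(x - mean) / sd per feature; constant (sd == 0) columns become zero."""
    missing = set(matrix.feature_names) - set(norm_params.index)
    if missing:
        raise KeyError(f"no normalisation parameters for features {sorted(missing)}")
    out = matrix.copy()
    mu = norm_params["mean"].reindex(out.feature_names)
    sd = norm_params["sd"].reindex(out.feature_names)
    safe_sd = sd.replace(0.0, np.nan)
    normed = (out.values - mu) / safe_sd
    out.values = normed.fillna(0.0) if (sd == 0).any() else normed
    out.norm_params = norm_params.copy()
    return out


def normalize(matrix: FeatureMatrix) -> FeatureMatrix:
    """Impute to zero, fit z-score parameters, and apply them (training path)."""
    imputed = impute_missing(matrix)
    return zscore_apply(imputed, zscore_fit(imputed))
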