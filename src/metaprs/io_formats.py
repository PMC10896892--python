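"""Readers and writers for every external representation the pipeline touches.

All downstream modules operate on three in-memory domain types defined here:
:class:`GenotypePanel` (sample x variant dosages plus variant metadata),
:class:`SummaryStats` (one trait's GWAS effect table) and
:class:`SurvivalFrame` (per-sample follow-up, event flag and covariates).

Supported on-disk formats
-------------------------
* VCF v4.x with ``GT`` and/or ``DS`` FORMAT fields (``DS`` wins when both are
  present); dosages count copies of the ALT allele, which becomes the panel's
  effect allele.  Allele re-orientation never happens at parse time — that is
  the job of :func:`metaprs.prs_engine.harmonize_alleles`.
* PLINK ``.raw`` additive dosage export (``FID IID PAT MAT SEX PHENOTYPE``
  followed by ``<id>_<allele>`` columns).  This dialect carries no coordinates,
  so chromosome is set to ``"0"``, position to the column ordinal and the
  unknown other allele to ``"N"``.
* dosage-tsv: header ``sample_id`` + variant ids, one row per sample, empty
  cells for missing dosages.  Variant metadata travels in a sidecar file
  ``<path>.variants.tsv`` written and required by this module.
* Summary-statistics TSV with a configurable column-name mapping
  (default ``SNP, CHR, POS, A1, A2, BETA, SE, P``; ``A1`` is the effect allele).
* Phenotype TSV (``sample_id``, ``time`` in years, ``event`` 0/1, covariates;
  ``PC1..PCk`` columns are recognised as genotype principal components).
* Model TSV: ``#key<TAB>value`` header block plus a variant-weight table;
  round-trips :class:`~metaprs.prs_engine.PrsModel` and
  :class:`~metaprs.metaprs_pipeline.MetaPrsModel` to full float precision.

Coordinates are 1-based inclusive throughout (VCF convention).  Missing
dosages are ``NaN``, never a numeric sentinel.  Readers canonically sort
samples by id and variants by (chromosome, position, alleles, id) so output
is independent of input row order.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def _float_fmt(v) -> str:
    """Shortest representation that round-trips the float exactly."""
    return repr(float(v))


VALID_ALLELES = frozenset("ACGT")
#: panel other-allele may be unknown ("N") when read from PLINK .raw exports
PANEL_ALLELES = frozenset("ACGTN")

#: default column-name mapping for summary-statistics TSVs
DEFAULT_SUMSTATS_COLUMNS: Mapping[str, str] = {
    "variant_id": "SNP",
    "chromosome": "CHR",
    "position": "POS",
    "effect_allele": "A1",
    "other_allele": "A2",
    "beta": "BETA",
    "se": "SE",
    "p_value": "P",
}

VARIANT_COLUMNS = [
    "variant_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "imputation_r2",
]


class FormatError(ValueError):
    """Malformed or unrecognised file content."""


class ValidationError(ValueError):
    """Structurally parseable input that violates a domain invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


def _canonical_variant_order(variants: pd.DataFrame) -> np.ndarray:
    key = variants[
        ["chromosome", "position", "effect_allele", "other_allele", "variant_id"]
    ]
    return np.lexsort(
        [
            key["variant_id"].to_numpy(),
            key["other_allele"].to_numpy(),
            key["effect_allele"].to_numpy(),
            key["position"].to_numpy(),
            key["chromosome"].to_numpy(),
        ]
    )


@dataclass
class GenotypePanel:
    """Sample x variant dosage matrix plus per-variant metadata.

    ``dosage[i, j]`` is the expected count (in ``[0, 2]``) of the effect
    allele of variant ``j`` carried by sample ``i``; ``NaN`` marks missing.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.variants = self.variants.reset_index(drop=True)
        self.dosage = np.asarray(self.dosage, dtype=float)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids in panel")
        missing_cols = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing_cols:
            raise ValidationError(f"variant table lacks columns: {missing_cols}")
        if self.dosage.shape != (len(self.sample_ids), len(self.variants)):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} does not match "
                f"({len(self.sample_ids)}, {len(self.variants)})"
            )
        keys = list(
            zip(
                self.variants["chromosome"].astype(str),
                self.variants["position"].astype(int),
                self.variants["effect_allele"],
                self.variants["other_allele"],
            )
        )
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate (chromosome, position, alleles) key")
        for col in ("effect_allele", "other_allele"):
            bad = ~self.variants[col].isin(
                PANEL_ALLELES if col == "other_allele" else VALID_ALLELES
            )
            if bad.any():
                raise ValidationError(
                    f"non-ACGT {col}: {self.variants.loc[bad, col].unique()[:5]}"
                )
        with np.errstate(invalid="ignore"):
            out = (self.dosage < 0) | (self.dosage > 2)
        if np.any(out):
            i, j = np.argwhere(out)[0]
            raise ValidationError(
                f"dosage {self.dosage[i, j]} outside [0, 2] "
                f"(sample {self.sample_ids[i]}, variant "
                f"{self.variants['variant_id'].iloc[j]})"
            )

    # -- convenience --------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_keys(self) -> pd.Index:
        """(chromosome, position, effect, other) tuples as an index."""
        return pd.Index(
            zip(
                self.variants["chromosome"].astype(str),
                self.variants["position"].astype(int),
                self.variants["effect_allele"],
                self.variants["other_allele"],
            )
        )

    def subset(
        self,
        sample_mask: np.ndarray | None = None,
        variant_mask: np.ndarray | None = None,
    ) -> "GenotypePanel":
        samples = self.sample_ids
        dosage = self.dosage
        variants = self.variants
        if sample_mask is not None:
            samples = [s for s, k in zip(samples, sample_mask) if k]
            dosage = dosage[np.asarray(sample_mask, bool), :]
        if variant_mask is not None:
            variant_mask = np.asarray(variant_mask, bool)
            variants = variants.loc[variant_mask].reset_index(drop=True)
            dosage = dosage[:, variant_mask]
        return GenotypePanel(samples, variants, dosage.copy())

    def sort_canonical(self) -> "GenotypePanel":
        s_order = np.argsort(np.asarray(self.sample_ids, dtype=object))
        v_order = _canonical_variant_order(self.variants)
        return GenotypePanel(
            [self.sample_ids[i] for i in s_order],
            self.variants.iloc[v_order].reset_index(drop=True),
            self.dosage[np.ix_(s_order, v_order)],
        )


@dataclass
class SummaryStats:
    """One trait's GWAS marginal-effect table.

    ``beta`` is the additive effect per copy of ``effect_allele``; ``p_value``
    lies in (0, 1] and ``se`` is strictly positive.  ``n_dropped`` records
    rows rejected at parse time (p <= 0 or missing beta).
    """

    trait_name: str
    table: pd.DataFrame
    n_dropped: int = 0

    REQUIRED = [
        "variant_id",
        "chromosome",
        "position",
        "effect_allele",
        "other_allele",
        "beta",
        "se",
        "p_value",
    ]

    def __post_init__(self) -> None:
        self.table = self.table.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"summary stats lack columns: {missing}")
        t = self.table
        if ((t["p_value"] <= 0) | (t["p_value"] > 1)).any():
            raise ValidationError("p_value outside (0, 1]")
        if (t["se"] <= 0).any():
            raise ValidationError("non-positive standard error")
        for col in ("effect_allele", "other_allele"):
            bad = ~t[col].isin(VALID_ALLELES)
            if bad.any():
                raise ValidationError(
                    f"non-ACGT {col} in summary stats: "
                    f"{t.loc[bad, col].unique()[:5]}"
                )
        keys = list(
            zip(t["chromosome"].astype(str), t["position"].astype(int),
                t["effect_allele"], t["other_allele"])
        )
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate variant key in summary stats")

    @property
    def n_variants(self) -> int:
        return len(self.table)

    def sort_canonical(self) -> "SummaryStats":
        order = _canonical_variant_order(self.table)
        return SummaryStats(self.trait_name, self.table.iloc[order],
                            self.n_dropped)


@dataclass
class SurvivalFrame:
    """Per-sample right-censored follow-up with covariates.

    ``data`` is indexed by sample id and holds ``time`` (years, > 0),
    ``event`` (0/1, 1 = all-cause death), named covariate columns and
    genotype principal components (``pc_names``).
    """

    data: pd.DataFrame
    covariate_names: list[str] = field(default_factory=list)
    pc_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for col in ("time", "event"):
            if col not in self.data.columns:
                raise ValidationError(f"survival frame lacks '{col}' column")
        if self.data.index.duplicated().any():
            raise ValidationError("duplicate sample ids in survival frame")
        bad_t = self.data["time"] <= 0
        if bad_t.any():
            raise ValidationError(
                f"non-positive time for sample(s) "
                f"{list(self.data.index[bad_t][:5])}"
            )
        if not self.data["event"].isin([0, 1]).all():
            raise ValidationError("event indicator not in {0, 1}")
        for col in self.covariate_names + self.pc_names:
            if col not in self.data.columns:
                raise ValidationError(f"declared column '{col}' absent")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(int)

    def with_columns(self, extra: Mapping[str, np.ndarray]) -> "SurvivalFrame":
        """Copy of the frame with additional (non-covariate) columns."""
        data = self.data.copy()
        for name, values in extra.items():
            data[name] = np.asarray(values)
        return SurvivalFrame(data, list(self.covariate_names), list(self.pc_names))

    def align_to(self, sample_ids: Sequence[str]) -> "SurvivalFrame":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise ValidationError(f"samples absent from frame: {missing[:5]}")
        return SurvivalFrame(
            self.data.loc[list(sample_ids)], list(self.covariate_names),
            list(self.pc_names)
        )


# ---------------------------------------------------------------------------
# genotype readers / writer
# ---------------------------------------------------------------------------


def read_genotypes(path: str | os.PathLike, format: str = "vcf") -> GenotypePanel:
    """Read genotype dosages from ``path``.

    ``format`` is one of ``vcf``, ``plink-text`` (``.raw``) or ``dosage-tsv``.
    Hard GT calls become dosages 0/1/2 counting the ALT (effect) allele; DS is
    preferred over GT when both FORMAT fields are present.  Missing genotypes
    stay missing (NaN) — imputation of residual missingness happens in QC.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format == "vcf":
        panel = _read_vcf(path)
    elif format == "plink-text":
        panel = _read_plink_raw(path)
    elif format == "dosage-tsv":
        panel = _read_dosage_tsv(path)
    else:
        raise ValueError(f"unknown genotype format: {format!r}")
    return panel.sort_canonical()


def _read_vcf(path: str) -> GenotypePanel:
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    rows = []
    columns = []
    for rec in vcf:
        if rec.ALT is None or len(rec.ALT) == 0:
            raise FormatError(f"VCF record without ALT at {rec.CHROM}:{rec.POS}")
        alt = rec.ALT[0]
        ref = rec.REF
        if len(alt) != 1 or len(ref) != 1:
            # indels / multi-nucleotide records are not scoreable variants
            logger.warning("skipping non-SNV record at %s:%s", rec.CHROM, rec.POS)
            continue
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            col = np.asarray(ds, float).reshape(-1)
            col = np.where(col < -0.5, np.nan, col)  # cyvcf2 missing sentinel
        else:
            gts = rec.gt_types  # 0=hom ref, 1=het, 2=unknown, 3=hom alt
            col = np.asarray(gts, float)
            col[col == 2] = np.nan
            col[col == 3] = 2.0
        r2 = rec.INFO.get("R2", rec.INFO.get("DR2", None))
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        rows.append(
            (vid, str(rec.CHROM), int(rec.POS), alt.upper(), ref.upper(),
             float(r2) if r2 is not None else np.nan)
        )
        columns.append(col)
    if not columns:
        raise FormatError(f"no usable SNV records in {path}")
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    dosage = np.column_stack(columns)
    if np.nanmax(dosage, initial=0.0) > 2 or np.nanmin(dosage, initial=0.0) < 0:
        raise ValidationError("VCF dosage outside [0, 2]")
    return GenotypePanel(samples, variants, dosage)


def _read_plink_raw(path: str) -> GenotypePanel:
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    meta_cols = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    missing = [c for c in meta_cols[:2] if c not in df.columns]
    if missing:
        raise FormatError(f".raw file lacks columns {missing}")
    variant_cols = [c for c in df.columns if c not in meta_cols]
    rows = []
    for ordinal, col in enumerate(variant_cols, start=1):
        vid, _, allele = col.rpartition("_")
        if not vid or allele.upper() not in VALID_ALLELES:
            raise FormatError(f"cannot parse counted allele from column {col!r}")
        rows.append((vid, "0", ordinal, allele.upper(), "N", np.nan))
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    dosage = df[variant_cols].apply(pd.to_numeric, errors="coerce").to_numpy(float)
    return GenotypePanel(list(df["IID"]), variants, dosage)


def _read_dosage_tsv(path: str) -> GenotypePanel:
    sidecar = path + ".variants.tsv"
    if not os.path.exists(sidecar):
        raise FormatError(f"dosage-tsv requires variant sidecar {sidecar}")
    variants = pd.read_csv(
        sidecar, sep="\t", float_precision="round_trip",
        dtype={"variant_id": str, "chromosome": str, "position": int,
               "effect_allele": str, "other_allele": str},
    )
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str},
                     float_precision="round_trip")
    if df.columns[0] != "sample_id":
        raise FormatError("dosage-tsv must start with a 'sample_id' column")
    file_ids = list(df.columns[1:])
    if file_ids != list(variants["variant_id"]):
        raise FormatError("dosage-tsv columns do not match variant sidecar")
    dosage = df[file_ids].to_numpy(float)
    return GenotypePanel(list(df["sample_id"]), variants, dosage)


def write_genotypes(panel: GenotypePanel, path: str | os.PathLike) -> None:
    """Write ``panel`` as dosage-tsv plus the ``.variants.tsv`` sidecar."""
    path = os.fspath(path)
    df = pd.DataFrame(panel.dosage, columns=list(panel.variants["variant_id"]))
    df.insert(0, "sample_id", panel.sample_ids)
    df.to_csv(path, sep="\t", index=False, float_format=_float_fmt)
    panel.variants.to_csv(
        path + ".variants.tsv", sep="\t", index=False, float_format=_float_fmt
    )


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------


def read_summary_stats(
    path: str | os.PathLike,
    trait_name: str,
    column_map: Mapping[str, str] | None = None,
) -> SummaryStats:
    """Read one trait's GWAS summary-statistics TSV.

    ``column_map`` maps internal names to file header names (default
    ``SNP/CHR/POS/A1/A2/BETA/SE/P``).  Rows with ``p_value <= 0`` or missing
    beta are dropped with a logged count; a missing mandatory column or a
    non-ACGT allele raises.
    """
    colmap = dict(DEFAULT_SUMSTATS_COLUMNS)
    if column_map:
        colmap.update(column_map)
    df = pd.read_csv(os.fspath(path), sep="\t", dtype={colmap["chromosome"]: str},
                     float_precision="round_trip")
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise FormatError(f"summary-stats file lacks column(s) {missing}")
    df = df.rename(columns={v: k for k, v in colmap.items()})[
        SummaryStats.REQUIRED
    ]
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()
    df["beta"] = pd.to_numeric(df["beta"], errors="coerce")
    df["p_value"] = pd.to_numeric(df["p_value"], errors="coerce")
    bad = df["beta"].isna() | df["p_value"].isna() | (df["p_value"] <= 0)
    n_dropped = int(bad.sum())
    if n_dropped:
        logger.info(
            "read_summary_stats(%s): dropped %d row(s) with p<=0 or missing beta",
            trait_name, n_dropped,
        )
    df = df.loc[~bad]
    return SummaryStats(trait_name, df, n_dropped=n_dropped).sort_canonical()


def write_summary_stats(stats: SummaryStats, path: str | os.PathLike) -> None:
    out = stats.table.rename(
        columns={k: v for k, v in DEFAULT_SUMSTATS_COLUMNS.items()}
    )
    out.to_csv(os.fspath(path), sep="\t", index=False, float_format=_float_fmt)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def read_phenotypes(
    path: str | os.PathLike,
    categorical_maps: Mapping[str, Mapping[str, int]] | None = None,
) -> SurvivalFrame:
    """Read the phenotype/covariate TSV into a :class:`SurvivalFrame`.

    Columns besides ``sample_id``, ``time`` and ``event`` become covariates;
    names matching ``PC<k>`` are classified as genotype principal components.
    ``categorical_maps`` declares string→0/1 encodings per column.
    """
    df = pd.read_csv(os.fspath(path), sep="\t", dtype={"sample_id": str},
                     float_precision="round_trip")
    for col in ("sample_id", "time", "event"):
        if col not in df.columns:
            raise FormatError(f"phenotype file lacks '{col}' column")
    df = df.set_index("sample_id").sort_index()
    if categorical_maps:
        for col, mapping in categorical_maps.items():
            df[col] = df[col].map(lambda v: mapping[str(v)])
    pc_names = sorted(
        (c for c in df.columns if c.startswith("PC") and c[2:].isdigit()),
        key=lambda c: int(c[2:]),
    )
    covariates = [c for c in df.columns if c not in {"time", "event", *pc_names}]
    df[covariates + pc_names] = df[covariates + pc_names].apply(pd.to_numeric)
    return SurvivalFrame(df, covariates, pc_names)


def write_phenotypes(frame: SurvivalFrame, path: str | os.PathLike) -> None:
    out = frame.data.reset_index(names="sample_id")
    out.to_csv(os.fspath(path), sep="\t", index=False, float_format=_float_fmt)


# ---------------------------------------------------------------------------
# model serialization
# ---------------------------------------------------------------------------

_MODEL_VERSION = "1"


def write_model(model, path: str | os.PathLike) -> None:
    """Serialize a PrsModel or MetaPrsModel as a self-describing TSV."""
    from .metaprs_pipeline import MetaPrsModel
    from .prs_engine import PrsModel

    lines: list[str] = [f"#format_version\t{_MODEL_VERSION}"]
    if isinstance(model, PrsModel):
        lines.append("#model_type\tPrsModel")
        lines.append(f"#trait\t{model.trait_name}")
        lines.append(f"#p_threshold\t{model.p_threshold!r}")
        weights = model.weights
    elif isinstance(model, MetaPrsModel):
        lines.append("#model_type\tMetaPrsModel")
        lines.append(f"#alpha\t{model.alpha!r}")
        lines.append(f"#lambda\t{model.lambda_!r}")
        lines.append(f"#cv_seed\t{model.cv_seed!r}")
        lines.append(f"#horizon\t{model.horizon!r}")
        lines.append(f"#score_mean\t{model.score_mean!r}")
        lines.append(f"#score_sd\t{model.score_sd!r}")
        for _, row in model.components.iterrows():
            lines.append(
                "#component\t"
                f"{row['trait']}\t{row['mix_weight']!r}\t"
                f"{row['score_mean']!r}\t{row['score_sd']!r}"
            )
        weights = model.weights
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")

    buf = io.StringIO()
    table = weights.copy()
    weight_col = "beta" if "beta" in table.columns else "weight"
    table[weight_col] = [repr(float(w)) for w in table[weight_col]]
    table.to_csv(buf, sep="\t", index=False)
    with open(os.fspath(path), "w") as fh:
        fh.write("\n".join(lines) + "\n" + buf.getvalue())


def read_model(path: str | os.PathLike):
    """Inverse of :func:`write_model`; returns the same model type."""
    from .metaprs_pipeline import MetaPrsModel
    from .prs_engine import PrsModel

    header: dict[str, str] = {}
    components: list[tuple[str, float, float, float]] = []
    body_lines: list[str] = []
    with open(os.fspath(path)) as fh:
        for line in fh:
            if line.startswith("#"):
                parts = line[1:].rstrip("\n").split("\t")
                if parts[0] == "component":
                    components.append(
                        (parts[1], float(parts[2]), float(parts[3]),
                         float(parts[4]))
                    )
                else:
                    header[parts[0]] = parts[1] if len(parts) > 1 else ""
            else:
                body_lines.append(line)
    if header.get("format_version") != _MODEL_VERSION:
        raise FormatError(
            f"unsupported model file version {header.get('format_version')!r}"
        )
    if body_lines:
        table = pd.read_csv(
            io.StringIO("".join(body_lines)), sep="\t",
            dtype={"chromosome": str, "variant_id": str},
            float_precision="round_trip",
        )
    else:
        table = pd.DataFrame()
    mtype = header.get("model_type")
    if mtype == "PrsModel":
        if table.empty:
            table = pd.DataFrame(
                columns=["variant_id", "chromosome", "position",
                         "effect_allele", "beta"]
            )
        return PrsModel(
            trait_name=header["trait"],
            p_threshold=float(header["p_threshold"]),
            weights=table,
        )
    if mtype == "MetaPrsModel":
        if table.empty:
            table = pd.DataFrame(
                columns=["variant_id", "chromosome", "position",
                         "effect_allele", "weight"]
            )
        comp = pd.DataFrame(
            components, columns=["trait", "mix_weight", "score_mean", "score_sd"]
        )
        return MetaPrsModel(
            components=comp,
            weights=table,
            alpha=float(header["alpha"]),
            lambda_=float(header["lambda"]),
            cv_seed=int(header["cv_seed"]),
            horizon=float(header["horizon"]),
            score_mean=float(header["score_mean"]),
            score_sd=float(header["score_sd"]),
        )
    raise FormatError(f"unknown model_type {mtype!r} in {path}")
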