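"""Shared data model, delimited-file I/O, configuration and pipeline driver.

The on-disk layout is fixed by convention (the upstream data providers do not
prescribe one): feature matrices are cell line x feature with cell-line
identifiers in the first column and feature identifiers in the header row;
response tables are drug x cell line.  Missing values are encoded by an empty
cell or a configurable token (default ``"NA"``).
"""

from __future__ import annotations

import dataclasses
import io
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("autoborutarf")

Kind = Literal["expression", "cna", "snv"]
KINDS: tuple[Kind, ...] = ("expression", "cna", "snv")

#: label values used throughout the pipeline; "sensitive" is the positive class
SENSITIVE = "sensitive"
NON_SENSITIVE = "non_sensitive"


class FormatError(ValueError):
    """Malformed input file (duplicate ids, out-of-domain values, ...)."""


class DegenerateDataError(ValueError):
    """Data reduced to something the pipeline cannot work with."""


class LookupError_(KeyError):
    """Requested drug or cell line is not present."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class FeatureMatrix:
    """A cell-line x feature table of one kind.

    ``values`` is a float DataFrame indexed by cell-line id with feature ids
    as columns; missing entries are NaN.  For ``kind="snv"`` every non-missing
    entry must be 0 or 1 (mutation indicator).
    """

    values: pd.DataFrame
    kind: Kind

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise FormatError(f"unknown feature kind {self.kind!r}")
        if self.values.index.has_duplicates:
            raise FormatError("duplicate cell-line identifiers")
        if self.values.columns.has_duplicates:
            raise FormatError("duplicate feature identifiers")
        self.values = self.values.astype(float)
        if self.kind == "snv":
            arr = self.values.to_numpy()
            ok = np.isnan(arr) | (arr == 0.0) | (arr == 1.0)
            if not ok.all():
                bad = arr[~ok][0]
                raise FormatError(f"snv value {bad!r} outside {{0, 1, missing}}")

    @property
    def cell_line_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def subset(self, cells=None, features=None) -> "FeatureMatrix":
        df = self.values
        if cells is not None:
            df = df.loc[list(cells)]
        if features is not None:
            df = df[list(features)]
        return FeatureMatrix(df.copy(), self.kind)

    def equals(self, other: "FeatureMatrix") -> bool:
        return self.kind == other.kind and self.values.equals(other.values)


@dataclass
class ResponseTable:
    """Drug x cell-line IC50 table; missing entries are NaN."""

    ic50: pd.DataFrame

    def __post_init__(self) -> None:
        if self.ic50.index.has_duplicates:
            raise FormatError("duplicate drug identifiers")
        if self.ic50.columns.has_duplicates:
            raise FormatError("duplicate cell-line identifiers")
        self.ic50 = self.ic50.astype(float)
        arr = self.ic50.to_numpy()
        if np.isinf(arr).any():
            raise FormatError("non-finite IC50 value")

    @property
    def drug_ids(self) -> list[str]:
        return list(self.ic50.index)

    @property
    def cell_line_ids(self) -> list[str]:
        return list(self.ic50.columns)

    def drug_vector(self, drug: str) -> pd.Series:
        if drug not in self.ic50.index:
            raise LookupError_(f"drug {drug!r} not in response table")
        return self.ic50.loc[drug]

    def subset_cells(self, cells) -> "ResponseTable":
        return ResponseTable(self.ic50[list(cells)].copy())

    def equals(self, other: "ResponseTable") -> bool:
        return self.ic50.equals(other.ic50)


@dataclass
class PipelineConfig:
    """All tunable settings of the pipeline, with the published defaults."""

    # preprocessing
    K_impute: int = 10
    missing_feature_threshold: float = 0.5
    missing_cell_threshold: float = 0.5
    impute_weight_mode: str = "inverse_distance"  # or "as_printed"
    joint_cell_filter: bool = True  # response missingness counts with features

    # autoencoder screen
    screen_keep_fraction: float = 0.5
    corr_threshold: float = 0.95
    ae_hidden_size: int | None = None  # None -> min(128, ceil(G/4))
    ae_epochs: int = 500
    ae_learning_rate: float = 1e-2

    # Boruta
    boruta_max_iter: int = 200
    boruta_alpha: float = 0.01
    boruta_n_trees: int = 500
    keep_tentative: bool = False

    # random forest / EasyEnsemble
    rf_n_trees: int = 1000
    bootstrap_fraction: float = 0.632
    bootstrap_replace: bool = False
    ir_bypass_threshold: float = 2.0

    # evaluation
    cv_folds: int = 10
    select_per_fold: bool = True

    master_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("missing_feature_threshold", "missing_cell_threshold",
                     "screen_keep_fraction", "corr_threshold",
                     "bootstrap_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in ("K_impute", "ae_epochs", "boruta_max_iter",
                     "boruta_n_trees", "rf_n_trees", "cv_folds"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from the master seed.

    The stage name is hashed (CRC-32, stable across platforms and runs) into
    the spawn key so each stage has an independent, reproducible stream.
    """
    key = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(key,)))


def stage_seed(master_seed: int, stage: str) -> int:
    """A plain integer seed (< 2**31) for APIs that take one."""
    return int(stage_rng(master_seed, stage).integers(2**31))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_NA_TOKENS = ("", "NA")


def _read_table(path, delimiter: str | None, na_token: str) -> pd.DataFrame:
    sep = delimiter
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    na_values = sorted({na_token, *_NA_TOKENS})
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=na_values,
                     keep_default_na=False, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_feature_matrix(path, kind: Kind, delimiter: str | None = None,
                        na_token: str = "NA") -> FeatureMatrix:
    """Read a cell-line x feature CSV/TSV into a validated FeatureMatrix."""
    df = _read_table(path, delimiter, na_token)
    if df.dtypes.apply(lambda d: d == object).any():
        bad = df.dtypes[df.dtypes == object].index[0]
        raise FormatError(f"non-numeric value in feature column {bad!r}")
    return FeatureMatrix(df, kind)


def write_feature_matrix(matrix: FeatureMatrix, path,
                         delimiter: str | None = None,
                         na_token: str = "NA") -> None:
    sep = delimiter or ("\t" if str(path).endswith((".tsv", ".tab")) else ",")
    # %.17g is lossless for float64 round-trips
    matrix.values.to_csv(path, sep=sep, na_rep=na_token, float_format="%.17g")


def read_response_table(path, delimiter: str | None = None,
                        na_token: str = "NA") -> ResponseTable:
    """Read a drug x cell-line IC50 CSV/TSV into a validated ResponseTable."""
    df = _read_table(path, delimiter, na_token)
    if df.dtypes.apply(lambda d: d == object).any():
        bad = df.dtypes[df.dtypes == object].index[0]
        raise FormatError(f"non-numeric IC50 value in column {bad!r}")
    return ResponseTable(df)


def write_response_table(table: ResponseTable, path,
                         delimiter: str | None = None,
                         na_token: str = "NA") -> None:
    sep = delimiter or ("\t" if str(path).endswith((".tsv", ".tab")) else ",")
    table.ic50.to_csv(path, sep=sep, na_rep=na_token, float_format="%.17g")


def write_feature_list(feature_ids, path) -> None:
    Path(path).write_text("".join(f"{f}\n" for f in feature_ids))


def read_feature_list(path) -> list[str]:
    return [ln for ln in Path(path).read_text().splitlines() if ln]


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig, features: dict, response: ResponseTable,
                 drug: str, out_dir=None):
    """Run preprocess -> label -> screen -> Boruta -> CV-evaluate for one drug.

    ``features`` maps kind -> FeatureMatrix (all three kinds).  Returns the
    cross-validation MetricsReport together with the Boruta selection made on
    the full dataset (the per-fold selections live in the report).  When
    ``out_dir`` is given, writes ``selected_features.txt``, ``metrics.csv``
    and ``labels.csv`` there; outputs are byte-identical for identical
    configuration (including the master seed).
    """
    from . import preprocess as pp
    from . import labeling
    from . import autoencoder_screen as screen
    from . import boruta_select
    from . import evaluation

    if drug not in response.drug_ids:
        raise LookupError_(f"drug {drug!r} not in response table")

    logger.info("pipeline start: drug=%s seed=%d", drug, config.master_seed)

    feats, resp, report = pp.filter_missing(
        features, response,
        feature_threshold=config.missing_feature_threshold,
        cell_threshold=config.missing_cell_threshold,
        joint_cell_filter=config.joint_cell_filter,
    )
    feats, resp = pp.impute_all(
        feats, resp, K=config.K_impute, weight_mode=config.impute_weight_mode)

    labels = labeling.assign_labels(resp.drug_vector(drug))
    cells = labels.cell_line_ids

    rng_screen = stage_rng(config.master_seed, "screen")
    screened = []
    for kind in ("expression", "cna"):
        fm = feats[kind].subset(cells=cells)
        if fm.values.shape[1] == 0:
            continue
        reduced, _ = screen.screen_kind(
            fm, keep_fraction=config.screen_keep_fraction,
            corr_threshold=config.corr_threshold,
            hidden_size=config.ae_hidden_size, epochs=config.ae_epochs,
            learning_rate=config.ae_learning_rate,
            seed=int(rng_screen.integers(2**31)))
        screened.append(reduced.values)
    if "snv" in feats and feats["snv"].values.shape[1] > 0:
        screened.append(feats["snv"].subset(cells=cells).values)
    X = pd.concat(screened, axis=1)

    report_cv = evaluation.cross_validate(
        X, labels, config, seed=stage_seed(config.master_seed, "cv"))

    boruta = boruta_select.boruta_run(
        X, labels.y, rng=stage_rng(config.master_seed, "boruta-final"),
        max_iter=config.boruta_max_iter, alpha=config.boruta_alpha,
        n_trees=config.boruta_n_trees,
        bootstrap_fraction=config.bootstrap_fraction,
        bootstrap_replace=config.bootstrap_replace)

    selected = list(boruta.confirmed)
    if config.keep_tentative:
        selected += list(boruta.tentative)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_feature_list(selected, out / "selected_features.txt")
        report_cv.to_frame().to_csv(out / "metrics.csv", float_format="%.10g")
        lab = pd.DataFrame({"cell_line": labels.cell_line_ids,
                            "label": labels.labels})
        with open(out / "labels.csv", "w") as fh:
            fh.write(f"# threshold={labels.threshold!r}\n")
            lab.to_csv(fh, index=False)
    logger.info("pipeline done: drug=%s confirmed=%d mean AUC=%.3f",
                drug, len(boruta.confirmed), report_cv.mean_metrics["AUC"])
    return report_cv, boruta
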