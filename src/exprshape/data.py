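"""Core containers and delimited-text IO for expression cohorts.

An :class:`ExpressionMatrix` is a genes x samples grid of finite reals with a
declared scale (raw intensities/counts vs log2).  A :class:`SurvivalTable`
carries right-censored time-to-event data per sample, optionally with a
pathologist tumor-purity percentage.  :class:`AnalysisConfig` collects the
pipeline's tunable thresholds in one validated place.

Files are plain TSV/CSV: expression with gene ids in the first column and a
header row of sample ids; clinical with columns ``sample_id  time_days  event
[purity]``.  Missing expression values are a hard error — imputation is out of
scope; clinical rows with missing survival time are dropped and counted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Scale",
    "ExpressionMatrix",
    "SurvivalTable",
    "AnalysisConfig",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_clinical",
    "write_clinical",
    "align_cohort",
]


class Scale(str, Enum):
    """Scale of the stored expression values."""

    RAW = "raw"
    LOG2 = "log2"


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Genes x samples expression grid with identifiers and a known scale."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: Scale = Scale.RAW

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        self.scale = Scale(self.scale)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.values)):
            g, s = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite expression value for gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(
            list(self.gene_ids), list(sample_ids), self.values[:, idx], self.scale
        )

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.gene_ids.index(g) for g in gene_ids]
        return ExpressionMatrix(
            list(gene_ids), list(self.sample_ids), self.values[idx], self.scale
        )


@dataclass
class SurvivalTable:
    """Right-censored survival data per sample (time in days, event 1=death)."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    purity: np.ndarray | None = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        n = len(self.sample_ids)
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValueError("time/event length does not match sample count")
        _check_unique(self.sample_ids, "sample")
        if np.any(self.time < 0) or np.any(~np.isfinite(self.time)):
            bad = self.sample_ids[int(np.argmax((self.time < 0) | ~np.isfinite(self.time)))]
            raise ValueError(f"negative or non-finite survival time for sample {bad!r}")
        ev = np.asarray(self.event, dtype=float)
        if not np.all(np.isin(ev, (0.0, 1.0))):
            bad = self.sample_ids[int(np.argmax(~np.isin(ev, (0.0, 1.0))))]
            raise ValueError(f"event indicator outside {{0,1}} for sample {bad!r}")
        self.event = ev.astype(int)
        if self.purity is not None:
            self.purity = np.asarray(self.purity, dtype=float)
            if self.purity.shape != (n,):
                raise ValueError("purity length does not match sample count")
            ok = np.isnan(self.purity) | ((self.purity >= 0) & (self.purity <= 100))
            if not np.all(ok):
                bad = self.sample_ids[int(np.argmax(~ok))]
                raise ValueError(f"tumor purity outside [0, 100] for sample {bad!r}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, sample_ids: Sequence[str]) -> "SurvivalTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return SurvivalTable(
            list(sample_ids),
            self.time[idx],
            self.event[idx],
            None if self.purity is None else self.purity[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        d = {"sample_id": self.sample_ids, "time_days": self.time, "event": self.event}
        if self.purity is not None:
            d["purity"] = self.purity
        return pd.DataFrame(d)


@dataclass
class AnalysisConfig:
    """Thresholds and sizes for the shape-classification pipeline.

    alpha_fit
        Significance level for each per-family goodness-of-fit test (Shapiro
        on raw/logged data, bootstrap KS for Cauchy/Gamma/Pareto).
    alpha_survival
        Log-rank significance level for calling a gene prognostic.
    bi_threshold
        Bimodality Index above which a gene is called bimodal outright.
    tail_fraction
        Tail mass used for extreme/non-extreme patient splits (0.10 = deciles).
    n_bootstrap
        Parametric-bootstrap replicates for the Lilliefors-style KS p-value.
    n_trees / n_repeats / n_selected_genes
        Survival-forest size, train/test repeats, and top-k gene selection for
        the classifier comparison.
    cauchy_scale
        "half-iqr" sets the Cauchy scale to IQR/2 (the quartiles of a Cauchy
        sit at x0 +/- gamma); "iqr" uses the IQR itself.
    """

    alpha_fit: float = 0.01
    alpha_survival: float = 0.05
    bi_threshold: float = 1.1
    tail_fraction: float = 0.10
    n_bootstrap: int = 200
    n_trees: int = 1000
    n_repeats: int = 100
    n_selected_genes: int = 100
    rng_seed: int = 0
    cauchy_scale: str = "half-iqr"
    log2_offset: float = 1.0
    use_kmeans_modes: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.alpha_fit < 1 and 0 < self.alpha_survival < 1):
            raise ValueError("alpha_fit and alpha_survival must lie in (0, 1)")
        if not (0 < self.tail_fraction < 0.5):
            raise ValueError("tail_fraction must lie in (0, 0.5)")
        if self.bi_threshold <= 0:
            raise ValueError("bi_threshold must be positive")
        for name in ("n_bootstrap", "n_trees", "n_repeats", "n_selected_genes"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.cauchy_scale not in ("half-iqr", "iqr"):
            raise ValueError("cauchy_scale must be 'half-iqr' or 'iqr'")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load from JSON or flat ``key=value`` text."""
        text = Path(path).read_text()
        stripped = text.lstrip()
        if stripped.startswith("{"):
            raw = json.loads(text)
        else:
            raw = {}
            for line in text.splitlines():
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, val = line.partition("=")
                raw[key.strip()] = val.strip()
        kwargs: dict = {}
        for f_ in cls.__dataclass_fields__.values():
            if f_.name in raw:
                v = raw[f_.name]
                if f_.type in ("float", float):
                    v = float(v)
                elif f_.type in ("int", int):
                    v = int(v)
                elif f_.type in ("bool", bool) and isinstance(v, str):
                    v = v.lower() in ("1", "true", "yes")
                kwargs[f_.name] = v
        return cls(**kwargs)

    def with_(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)


def _sniff_sep(path: Path) -> str:
    first = path.open().readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_expression_matrix(path: str | Path, scale: Scale | str = Scale.RAW) -> ExpressionMatrix:
    """Read a genes x samples delimited matrix (first column gene ids).

    Delimiter is auto-detected between tab and comma.  Duplicate ids, missing
    cells and non-numeric cells are hard errors naming the offender.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]
    _check_unique(gene_ids, "gene")
    _check_unique(sample_ids, "sample")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().to_numpy()
    if bad.any():
        raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
        g, s = np.argwhere(bad)[0]
        cell = raw.iloc[g, s]
        if pd.isna(cell) or str(cell).upper() in ("NA", "NAN", ""):
            raise ValueError(
                f"missing expression value for gene {gene_ids[g]!r}, sample "
                f"{sample_ids[s]!r} (imputation is not supported)"
            )
        raise ValueError(
            f"non-numeric cell {cell!r} for gene {gene_ids[g]!r}, sample {sample_ids[s]!r}"
        )
    return ExpressionMatrix(gene_ids, sample_ids, numeric.to_numpy(dtype=float), Scale(scale))


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    """Write tab-separated, full float precision (round-trips bit-exactly)."""
    with Path(path).open("w") as fh:
        fh.write("gene_id\t" + "\t".join(m.sample_ids) + "\n")
        for g, row in zip(m.gene_ids, m.values):
            fh.write(g + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_clinical(path: str | Path) -> SurvivalTable:
    """Read a clinical table (``sample_id  time_days  event  [purity]``).

    Rows with missing survival time are dropped; the count is logged and
    recorded on the returned table as ``n_dropped``.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower(): c for c in df.columns}
    try:
        sid = cols.get("sample_id") or cols["sample"]
        time_col = cols.get("time_days") or cols["time"]
        event_col = cols["event"]
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"clinical table missing required column: {exc}") from exc
    time = pd.to_numeric(df[time_col], errors="coerce")
    keep = time.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("read_clinical: %d row(s) with missing survival time dropped", n_dropped)
    df = df[keep]
    purity = None
    pur_col = cols.get("purity")
    if pur_col is not None:
        purity = pd.to_numeric(df[pur_col], errors="coerce").to_numpy()
    table = SurvivalTable(
        [str(s) for s in df[sid]],
        time[keep].to_numpy(dtype=float),
        pd.to_numeric(df[event_col]).to_numpy(),
        purity,
    )
    table.n_dropped = n_dropped
    return table


def write_clinical(surv: SurvivalTable, path: str | Path) -> None:
    surv.to_frame().to_csv(path, sep="\t", index=False)


def align_cohort(
    expr: ExpressionMatrix, clin: SurvivalTable
) -> tuple[ExpressionMatrix, SurvivalTable]:
    """Restrict both objects to their common samples, in expression order.

    Idempotent; errors on an empty intersection.
    """
    clin_set = set(clin.sample_ids)
    common = [s for s in expr.sample_ids if s in clin_set]
    if not common:
        raise ValueError("expression and clinical tables share no sample ids")
    logger.info("align_cohort: %d common samples", len(common))
    if common == expr.sample_ids and common == clin.sample_ids:
        return expr, clin
    return expr.subset_samples(common), clin.subset(common)
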