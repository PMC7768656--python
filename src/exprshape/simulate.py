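"""Seeded synthetic cohorts with known distribution families and planted
survival structure.

Each gene is drawn i.i.d. from a declared family; survival times are
exponential with a per-sample hazard that multiplies a baseline by the
hazard ratio of every prognostic gene for which the sample falls in the risk
group (upper/lower tail for unimodal genes, upper mode for bimodal ones).
Censoring is independent exponential, calibrated per sample so the expected
censored fraction matches the requested rate exactly
(P(censor) = c/(c+h) for competing exponentials, so c = h * r/(1-r)).

The ``benchmark_panel`` presets freeze the study conditions used throughout
the test-suite: a 600-gene/6-family classification panel at n = 300, and a
500-gene survival cohort with 20 bimodal mode-linked plus 10 Gamma
tail-linked prognostic genes at hazard ratio 3 and 30% censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, Scale, SurvivalTable
from .distributions import Family

__all__ = ["GeneSpec", "CohortSpec", "CohortTruth", "simulate_cohort", "benchmark_panel"]

#: per-family parameter meaning: see exprshape.distributions.FitParams;
#: BIMODAL uses (pi, mu1, mu2, sigma) with pi the upper-component weight.
_PARAM_LEN = {Family.BIMODAL: 4}


@dataclass(frozen=True)
class GeneSpec:
    gene_id: str
    family: Family
    params: tuple[float, ...]
    prognostic: str = "none"  # none | tail | mode
    hazard_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.prognostic not in ("none", "tail", "mode"):
            raise ValueError("prognostic must be none/tail/mode")
        if self.prognostic == "mode" and self.family is not Family.BIMODAL:
            raise ValueError("mode-linked genes must be bimodal")
        if self.prognostic == "tail" and self.family is Family.BIMODAL:
            raise ValueError("tail-linked genes must be unimodal")
        if (self.hazard_ratio == 1.0) != (self.prognostic == "none"):
            raise ValueError("hazard_ratio != 1 exactly for prognostic genes")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")
        need = _PARAM_LEN.get(self.family, 2)
        if len(self.params) != need:
            raise ValueError(
                f"{self.family.value} takes {need} parameters, got {len(self.params)}"
            )


@dataclass(frozen=True)
class CohortSpec:
    n_samples: int
    gene_specs: tuple[GeneSpec, ...]
    baseline_hazard: float = np.log(2) / 500.0  # median survival ~500 days
    censor_rate: float = 0.0
    tail_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 20:
            raise ValueError("need at least 20 samples")
        ids = [g.gene_id for g in self.gene_specs]
        if len(set(ids)) != len(ids):
            raise ValueError("gene ids must be unique")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be positive")
        if not (0 <= self.censor_rate < 1):
            raise ValueError("censor_rate must lie in [0, 1)")


@dataclass
class CohortTruth:
    """Ground truth written beside the data: per-gene spec and per-sample risk membership."""

    genes: pd.DataFrame  # gene_id, family, prognostic, hazard_ratio
    risk_membership: pd.DataFrame  # prognostic genes x samples, boolean


def _sample_gene(spec: GeneSpec, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray | None]:
    """Draw n values; returns (values, upper-component mask for bimodal)."""
    p = spec.params
    fam = spec.family
    if fam is Family.NORMAL:
        return p[0] + p[1] * rng.standard_normal(n), None
    if fam is Family.LOGNORMAL:
        return np.exp(p[0] + p[1] * rng.standard_normal(n)), None
    if fam is Family.CAUCHY:
        return p[0] + p[1] * rng.standard_cauchy(n), None
    if fam is Family.GAMMA:
        return rng.gamma(p[0], 1.0 / p[1], size=n), None
    if fam is Family.PARETO:
        return p[0] * (1.0 - rng.random(n)) ** (-1.0 / p[1]), None
    if fam is Family.BIMODAL:
        pi, mu1, mu2, sigma = p
        upper = rng.random(n) < pi
        mu = np.where(upper, mu2, mu1)
        return mu + sigma * rng.standard_normal(n), upper
    raise ValueError(f"cannot simulate family {fam}")


def _risk_mask(
    spec: GeneSpec, values: np.ndarray, upper: np.ndarray | None, tail_fraction: float
) -> np.ndarray:
    if spec.prognostic == "mode":
        return upper
    # tail-linked: risk group sits beyond the long-tail quantile
    from scipy.stats import skew

    if spec.family in (Family.LOGNORMAL, Family.GAMMA, Family.PARETO) or skew(values) > 0:
        return values > np.quantile(values, 1.0 - tail_fraction)
    return values < np.quantile(values, tail_fraction)


def simulate_cohort(spec: CohortSpec) -> tuple[ExpressionMatrix, SurvivalTable, CohortTruth]:
    """Generate (expression, survival, truth); bit-identical for equal seeds."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    sample_ids = [f"S{i:04d}" for i in range(n)]
    values = np.empty((len(spec.gene_specs), n))
    hazard = np.full(n, spec.baseline_hazard)
    truth_rows = []
    memberships: dict[str, np.ndarray] = {}
    for i, g in enumerate(spec.gene_specs):
        values[i], upper = _sample_gene(g, n, rng)
        truth_rows.append(
            {
                "gene_id": g.gene_id,
                "family": g.family.value,
                "prognostic": g.prognostic,
                "hazard_ratio": g.hazard_ratio,
            }
        )
        if g.prognostic != "none":
            mask = _risk_mask(g, values[i], upper, spec.tail_fraction)
            memberships[g.gene_id] = mask
            hazard = np.where(mask, hazard * g.hazard_ratio, hazard)
    time = rng.exponential(1.0 / hazard)
    event = np.ones(n, dtype=int)
    if spec.censor_rate > 0:
        c_rate = hazard * spec.censor_rate / (1.0 - spec.censor_rate)
        censor_time = rng.exponential(1.0 / c_rate)
        event = (time <= censor_time).astype(int)
        time = np.minimum(time, censor_time)
    expr = ExpressionMatrix(
        [g.gene_id for g in spec.gene_specs], sample_ids, values, Scale.LOG2
    )
    surv = SurvivalTable(sample_ids, time, event)
    truth = CohortTruth(
        genes=pd.DataFrame(truth_rows),
        risk_membership=pd.DataFrame(memberships, index=sample_ids).T
        if memberships
        else pd.DataFrame(index=pd.Index([], name="gene_id"), columns=sample_ids),
    )
    return expr, surv, truth


def _cycle(values, i):
    return float(values[i % len(values)])


def _classify_panel() -> list[GeneSpec]:
    """600 genes, 100 per family, parameters cycled over fixed grids."""
    specs: list[GeneSpec] = []
    for i in range(100):
        specs.append(
            GeneSpec(
                f"NORM{i:03d}", Family.NORMAL,
                (_cycle((5, 6, 7, 8, 9, 10), i), _cycle((0.5, 1.0, 1.5, 2.0), i)),
            )
        )
        specs.append(
            GeneSpec(
                f"CAUC{i:03d}", Family.CAUCHY,
                (_cycle((5, 6, 7, 8, 9, 10), i), _cycle((0.3, 0.5, 0.8, 1.0), i)),
            )
        )
        specs.append(
            GeneSpec(
                f"LNOR{i:03d}", Family.LOGNORMAL,
                (_cycle((1.0, 1.5, 2.0, 2.5), i), _cycle((0.3, 0.4, 0.5), i)),
            )
        )
        specs.append(
            GeneSpec(
                f"GAMM{i:03d}", Family.GAMMA,
                (_cycle((1, 2, 3, 4, 5), i), _cycle((0.5, 1.0, 2.0), i)),
            )
        )
        specs.append(
            GeneSpec(
                f"PARE{i:03d}", Family.PARETO,
                (_cycle((1.0, 1.5, 2.0, 3.0), i), _cycle((2.0, 3.0, 4.0), i)),
            )
        )
        sigma = _cycle((0.5, 0.75, 1.0), i)
        delta = _cycle((3.0, 3.5, 4.0, 4.5, 5.0), i) * sigma
        mu1 = _cycle((3.0, 4.0, 5.0, 6.0), i)
        pi = _cycle((0.35, 0.45, 0.5, 0.55, 0.65), i)
        specs.append(
            GeneSpec(f"BIMO{i:03d}", Family.BIMODAL, (pi, mu1, mu1 + delta, sigma))
        )
    return specs


def _survival_panel() -> list[GeneSpec]:
    """500 genes: 20 bimodal mode-linked + 10 Gamma tail-linked at HR 3, rest null."""
    specs: list[GeneSpec] = []
    for i in range(20):
        sigma = _cycle((0.5, 0.75, 1.0), i)
        delta = _cycle((3.0, 4.0, 5.0), i) * sigma
        mu1 = _cycle((3.0, 4.0, 5.0), i)
        specs.append(
            GeneSpec(
                f"PBIM{i:03d}", Family.BIMODAL,
                (_cycle((0.4, 0.5, 0.6), i), mu1, mu1 + delta, sigma),
                prognostic="mode", hazard_ratio=3.0,
            )
        )
    for i in range(10):
        specs.append(
            GeneSpec(
                f"PGAM{i:03d}", Family.GAMMA,
                (_cycle((1.5, 2.0, 3.0), i), _cycle((0.5, 1.0), i)),
                prognostic="tail", hazard_ratio=3.0,
            )
        )
    for i in range(290):
        specs.append(
            GeneSpec(
                f"NNOR{i:03d}", Family.NORMAL,
                (_cycle((5, 7, 9), i), _cycle((0.5, 1.0, 1.5), i)),
            )
        )
    for i in range(60):
        specs.append(
            GeneSpec(
                f"NGAM{i:03d}", Family.GAMMA,
                (_cycle((1, 2, 4), i), _cycle((0.5, 1.0), i)),
            )
        )
    for i in range(60):
        specs.append(
            GeneSpec(
                f"NLNO{i:03d}", Family.LOGNORMAL,
                (_cycle((1.0, 1.5), i), _cycle((0.4, 0.7), i)),
            )
        )
    for i in range(40):
        sigma = _cycle((0.5, 1.0), i)
        mu1 = _cycle((4.0, 5.0), i)
        specs.append(
            GeneSpec(
                f"NBIM{i:03d}", Family.BIMODAL,
                (0.5, mu1, mu1 + 4.0 * sigma, sigma),
            )
        )
    for i in range(20):
        specs.append(
            GeneSpec(
                f"NCAU{i:03d}", Family.CAUCHY,
                (_cycle((6, 8), i), _cycle((0.5, 1.0), i)),
            )
        )
    return specs


def benchmark_panel(preset: str, seed: int = 0) -> CohortSpec:
    """Frozen cohort designs used across the test-suite.

    ``classify``: 600 genes, 100 per family (bimodal separations 3-5 sigma,
    Gamma shapes 1-5, Pareto indices 2-4), n = 300, no survival linkage.
    ``survival``: 500 genes with 30 planted prognostic genes at HR 3 and 30%
    censoring, n = 300.  ``compare``: the survival design sized for repeated
    2/3-1/3 train/test splitting.
    """
    preset = preset.lower()
    if preset == "classify":
        return CohortSpec(300, tuple(_classify_panel()), seed=seed)
    if preset == "survival":
        return CohortSpec(300, tuple(_survival_panel()), censor_rate=0.3, seed=seed)
    if preset == "compare":
        return CohortSpec(300, tuple(_survival_panel()), censor_rate=0.3, seed=seed)
    raise ValueError(f"unknown preset {preset!r} (classify/survival/compare)")
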