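"""Plot-aggregate carbon density from mean canopy height.

The drone arm of the analysis: aboveground carbon density (ACD, in
Mg C ha^-1) is predicted from a single stand metric, the plot's mean
top-of-canopy height (TCH, m), through published plot-aggregate
allometric equations. Four are plain power laws ``ACD = a * TCH**b``:

====  ======  ======  =============================================
id       a       b    calibration
====  ======  ======  =============================================
I      6.85   0.952   pantropical forest plots
II     7.37   0.87    lowland rainforest, Sabah (with sub-models)
III    1.03   1.535   lowland rainforest, Sabah (field BA and WD)
IV     0.47   1.87    peat swamp pole forest, Kalimantan
====  ======  ======  =============================================

Equation V is a three-factor Sabah-wide model
``ACD = 0.567 * TCH**0.554 * BA**1.081 * WD**0.186`` whose basal area
and wood density inputs are themselves predicted from TCH by sub-models
``BA = 1.112 * TCH`` and ``WD = 0.385 * TCH**0.097``, so TCH remains
the only input.

Measurement uncertainty in TCH is propagated by Monte Carlo: TCH draws
from ``Normal(mean_tch, sigma)`` under a small-error (sigma = 1.5 m)
and a conservative large-error (sigma = 4 m) scenario are pushed
through each equation, and the resulting ACD samples are pooled across
equations so the pooled spread carries both measurement and
between-model variance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PlotAggregateEquation:
    """One ACD = f(TCH) model: a power law, optionally with BA/WD sub-models.

    For the three-factor form, ``ba_coef`` and ``(wd_coef, wd_exp)``
    define the linear BA and power-law WD sub-models and ``ba_exp`` /
    ``wd_power`` their exponents inside the main equation; plain power
    laws leave them at None.
    """

    id: str
    a: float
    b: float
    ba_coef: float | None = None
    ba_exp: float | None = None
    wd_coef: float | None = None
    wd_exp: float | None = None
    wd_power: float | None = None

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("coefficients a, b must be positive")

    @property
    def effective_exponent(self) -> float:
        """Total TCH exponent after composing any sub-models."""
        if self.ba_coef is None:
            return self.b
        return self.b + self.ba_exp + self.wd_exp * self.wd_power


#: The five published plot-aggregate equations, keyed by roman numeral.
EQUATIONS: dict[str, PlotAggregateEquation] = {
    "I": PlotAggregateEquation("I", 6.85, 0.952),
    "II": PlotAggregateEquation("II", 7.37, 0.87),
    "III": PlotAggregateEquation("III", 1.03, 1.535),
    "IV": PlotAggregateEquation("IV", 0.47, 1.87),
    "V": PlotAggregateEquation(
        "V", 0.567, 0.554, ba_coef=1.112, ba_exp=1.081, wd_coef=0.385, wd_exp=0.097, wd_power=0.186
    ),
}

ALL_EQUATIONS = ("I", "II", "III", "IV", "V")
REGIONAL_EQUATIONS = ("III", "IV", "V")  # the regionally calibrated subset


def evaluate_equation(eq: PlotAggregateEquation | str, tch) -> np.ndarray | float:
    """Evaluate an equation at TCH >= 0 (scalar or array), in Mg C ha^-1.

    The three-factor form composes its BA and WD sub-models internally.
    Negative TCH is a caller error: apply a negative-draw rule first.
    """
    if isinstance(eq, str):
        eq = EQUATIONS[eq]
    t = np.asarray(tch, dtype=float)
    if np.any(t < 0):
        raise ValueError("TCH must be >= 0; apply a negative_rule to draws first")
    with np.errstate(divide="ignore"):
        if eq.ba_coef is None:
            acd = eq.a * t**eq.b
        else:
            ba = eq.ba_coef * t
            wd = eq.wd_coef * t**eq.wd_exp
            acd = eq.a * t**eq.b * ba**eq.ba_exp * wd**eq.wd_power
    acd = np.where(t == 0, 0.0, acd)  # 0^b = 0 for b > 0, incl. sub-models
    return float(acd) if np.isscalar(tch) else acd


@dataclass(frozen=True)
class ErrorScenario:
    """A canopy-height measurement-error model for the Monte Carlo.

    ``sigma`` is the SD (m) of the Gaussian error on mean TCH;
    ``negative_rule`` decides what happens to negative draws (the
    published workflow does not say): ``truncate_zero`` sets them to 0,
    ``resample`` redraws until non-negative, ``none`` leaves them (the
    equations will then reject them).
    """

    label: str
    sigma: float
    n_draws: int = 1000
    seed: int | None = None
    negative_rule: str = "truncate_zero"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if self.negative_rule not in ("truncate_zero", "resample", "none"):
            raise ValueError(f"unknown negative_rule {self.negative_rule!r}")

    def with_seed(self, seed: int | None) -> "ErrorScenario":
        return replace(self, seed=seed)


SMALL_ERROR = ErrorScenario("small", 1.5)
LARGE_ERROR = ErrorScenario("large", 4.0)


def draw_tch_samples(mean_tch: float, scenario: ErrorScenario) -> np.ndarray:
    """Draw ``n_draws`` mean-TCH values from Normal(mean_tch, sigma)."""
    if mean_tch < 0:
        raise ValueError("mean_tch must be >= 0")
    rng = np.random.default_rng(scenario.seed)
    draws = rng.normal(mean_tch, scenario.sigma, scenario.n_draws)
    if scenario.negative_rule == "truncate_zero":
        draws = np.maximum(draws, 0.0)
    elif scenario.negative_rule == "resample":
        bad = draws < 0
        while bad.any():
            draws[bad] = rng.normal(mean_tch, scenario.sigma, int(bad.sum()))
            bad = draws < 0
    return draws


@dataclass
class AcdSampleSet:
    """Monte Carlo ACD draws tagged by equation, error scenario and region.

    Backed by a tidy DataFrame with columns
    ``region, scenario, equation, draw, acd_mg_c_ha``.
    """

    samples: pd.DataFrame

    COLUMNS = ("region", "scenario", "equation", "draw", "acd_mg_c_ha")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.samples.columns)
        if missing:
            raise ValueError(f"sample table missing columns: {sorted(missing)}")
        if (self.samples["acd_mg_c_ha"] < 0).any():
            raise ValueError("ACD samples must be non-negative")

    def __len__(self) -> int:
        return len(self.samples)

    def select(
        self,
        equations: tuple[str, ...] | None = None,
        scenario: str | None = None,
        region: str | None = None,
    ) -> pd.DataFrame:
        df = self.samples
        if equations is not None:
            df = df[df["equation"].isin(equations)]
        if scenario is not None:
            df = df[df["scenario"] == scenario]
        if region is not None:
            df = df[df["region"] == region]
        return df

    @classmethod
    def concat(cls, sets: list["AcdSampleSet"]) -> "AcdSampleSet":
        return cls(pd.concat([s.samples for s in sets], ignore_index=True))

    def to_csv(self, path) -> None:
        self.samples.to_csv(path, index=False)


def propagate_acd(
    tch_samples: np.ndarray,
    equations: tuple[str, ...] = ALL_EQUATIONS,
    scenario_label: str = "small",
    region: str = "plot",
) -> AcdSampleSet:
    """Push a single TCH draw vector through a set of equations.

    The same draws are reused across equations (paired comparison), so
    the output has one ACD per (equation, draw).
    """
    if len(equations) == 0:
        raise ValueError("need at least one equation")
    tch_samples = np.asarray(tch_samples, dtype=float)
    frames = []
    for eid in equations:
        acd = evaluate_equation(EQUATIONS[eid], tch_samples)
        frames.append(
            pd.DataFrame(
                {
                    "region": region,
                    "scenario": scenario_label,
                    "equation": eid,
                    "draw": np.arange(len(tch_samples)),
                    "acd_mg_c_ha": acd,
                }
            )
        )
    return AcdSampleSet(pd.concat(frames, ignore_index=True))


@dataclass
class SummaryStats:
    """Pooled summary of an ACD sample selection."""

    mean: float
    sd: float
    median: float
    q025: float
    q975: float
    n: int


def summarize_acd(
    sample_set: AcdSampleSet,
    equations: tuple[str, ...] | None = None,
    scenario: str | None = None,
    region: str | None = None,
) -> SummaryStats:
    """Pooled statistics over all samples matching the selection.

    Pooling across equations mixes between-equation spread with Monte
    Carlo spread, which is exactly what a model-agnostic uncertainty
    statement needs.
    """
    df = sample_set.select(equations, scenario, region)
    if len(df) == 0:
        raise ValueError("selection matches no samples")
    vals = df["acd_mg_c_ha"].to_numpy()
    return SummaryStats(
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        median=float(np.median(vals)),
        q025=float(np.percentile(vals, 2.5)),
        q975=float(np.percentile(vals, 97.5)),
        n=int(vals.size),
    )
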