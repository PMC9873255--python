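"""Cylinder-model decomposition of the tenotomy mass deficit.

Modeling fibers as cylinders, the tenotomy-to-sham muscle mass ratio is

    dm = dFN * (dCSA_1*AF_1 + dCSA_2a*AF_2a + dCSA_2x*AF_2x + dCSA_2b*AF_2b) * dFL * rho

with dFN the fiber-number ratio, dCSA_i the per-type fiber CSA ratios
weighted by the fiber-type area fractions AF_i (assumed unchanged by
tenotomy), dFL the fiber-length ratio, and rho the muscle density.  When
every delta is a dimensionless tenotomy-to-sham ratio, rho cancels; it
is retained on the type for absolute-mass use.

The predicted deficit is 1 - dm.  Because the model is multiplicative,
the unique exact additive split of the deficit over its three factors is
the log decomposition share_k = ln(f_k) / ln(dm); a one-at-a-time
variant (with its unallocated interaction remainder) is provided for
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, InputError

__all__ = [
    "MorphologyDelta",
    "DecompositionResult",
    "ValidationRegression",
    "predicted_mass_ratio",
    "contribution_shares",
    "validate_predictions",
    "decompose_cohort",
    "validate_cohort",
]

FIBER_TYPES = ("1", "2a", "2x", "2b")
FACTORS = ("fiber_number", "fiber_csa", "fiber_length")

#: standard mammalian muscle density, g/cm^3
MUSCLE_DENSITY = 1.056


@dataclass
class MorphologyDelta:
    """Per-animal (or per-group) morphological change ratios.

    All deltas are dimensionless tenotomy-to-sham ratios (tenotomized
    value over the sex-matched sham mean).  A fiber type missing a CSA
    ratio is treated as unchanged (ratio 1) and recorded in
    ``missing_types``.
    """

    fn_ratio: float
    csa_ratio: dict[str, float]
    area_fraction: dict[str, float]
    fl_ratio: float
    density: float = MUSCLE_DENSITY
    missing_types: tuple[str, ...] = field(init=False, default=())

    def __post_init__(self):
        if not self.fn_ratio > 0 or not self.fl_ratio > 0 or not self.density > 0:
            raise InputError("ratios and density must be positive")
        if any(not r > 0 for r in self.csa_ratio.values()):
            raise InputError("CSA ratios must be positive")
        af = self.area_fraction
        if any(v < 0 for v in af.values()):
            raise InputError("area fractions must be nonnegative")
        if abs(sum(af.values()) - 1.0) > 1e-6:
            raise InputError(f"area fractions sum to {sum(af.values())}, expected 1")
        self.missing_types = tuple(t for t in af if t not in self.csa_ratio)

    @property
    def csa_factor(self) -> float:
        """Aggregated CSA factor sum_i AF_i * dCSA_i."""
        return sum(
            self.area_fraction[t] * self.csa_ratio.get(t, 1.0)
            for t in self.area_fraction
        )


@dataclass
class DecompositionResult:
    """Predicted mass ratio/deficit and per-factor contribution shares."""

    mass_ratio: float
    predicted_deficit: float
    shares: dict[str, float]
    method: str
    interaction_remainder: float | None = None
    degenerate: bool = False  # ratio == 1: shares undefined
    missing_types: tuple[str, ...] = ()


@dataclass
class ValidationRegression:
    """OLS of measured deficit on predicted deficit."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def predicted_mass_ratio(delta: MorphologyDelta) -> float:
    """Tenotomy-to-sham mass ratio predicted by the cylinder model."""
    return delta.fn_ratio * delta.csa_factor * delta.fl_ratio


def contribution_shares(delta: MorphologyDelta, method: str = "log") -> DecompositionResult:
    """Split the predicted deficit over fiber number, CSA, and length.

    ``log`` (default): share_k = ln(f_k)/ln(ratio) — exact, sums to 1.
    ``one-at-a-time``: share_k = (1 - f_k)/(1 - ratio), reported with the
    unallocated interaction remainder.
    """
    if method not in ("log", "one-at-a-time"):
        raise ValueError(f"unknown method {method!r}")
    factors = {
        "fiber_number": delta.fn_ratio,
        "fiber_csa": delta.csa_factor,
        "fiber_length": delta.fl_ratio,
    }
    ratio = predicted_mass_ratio(delta)
    deficit = 1.0 - ratio
    if ratio == 1.0:
        return DecompositionResult(
            mass_ratio=ratio,
            predicted_deficit=0.0,
            shares={k: float("nan") for k in factors},
            method=method,
            degenerate=True,
            missing_types=delta.missing_types,
        )
    if method == "log":
        log_ratio = np.log(ratio)
        shares = {k: float(np.log(f) / log_ratio) for k, f in factors.items()}
        remainder = None
    else:
        shares = {k: float((1.0 - f) / deficit) for k, f in factors.items()}
        remainder = 1.0 - sum(shares.values())
    return DecompositionResult(
        mass_ratio=float(ratio),
        predicted_deficit=float(deficit),
        shares=shares,
        method=method,
        interaction_remainder=remainder,
        missing_types=delta.missing_types,
    )


def validate_predictions(predicted, measured) -> ValidationRegression:
    """Ordinary least squares of measured deficit on predicted deficit."""
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(measured, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("predicted and measured must be 1-D arrays of equal length")
    if x.size < 3:
        raise InputError("regression needs at least 3 paired observations")
    if np.ptp(x) == 0:
        raise DegenerateInputError("zero variance in the predictor")
    res = stats.linregress(x, y)
    return ValidationRegression(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
        p_value=float(res.pvalue),
        n=int(x.size),
    )


# -- cohort-table drivers ---------------------------------------------------

_GROUP_COLS = ["sex", "genotype", "timepoint"]


def _sham_means(df: pd.DataFrame) -> pd.DataFrame:
    sham = df[df["treatment"] == "SHM"]
    if sham.empty:
        raise InputError("cohort contains no sham animals")
    return sham.groupby(_GROUP_COLS).mean(numeric_only=True)


def decompose_cohort(
    df: pd.DataFrame,
    area_fractions: dict[str, float],
    method: str = "log",
    aggregate: str = "animal",
) -> pd.DataFrame:
    """Decompose every tenotomized animal (or group) against matched sham means.

    Deltas are tenotomized values over the sham mean of the same sex,
    genotype, and timepoint.  ``aggregate='animal'`` decomposes per
    animal; ``aggregate='group'`` decomposes the group-mean deltas.
    Returns a table with the deltas, predicted ratio/deficit, measured
    ratio/deficit (from muscle mass), and contribution shares.
    """
    if aggregate not in ("animal", "group"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    sham_means = _sham_means(df)
    ten = df[df["treatment"] == "TEN"]
    if ten.empty:
        raise InputError("cohort contains no tenotomized animals")
    if aggregate == "group":
        ten = ten.groupby(_GROUP_COLS, as_index=False).mean(numeric_only=True)
        ten = ten.assign(animal_id=[f"group-{i}" for i in range(len(ten))])

    rows = []
    for _, rec in ten.iterrows():
        key = tuple(rec[c] for c in _GROUP_COLS)
        try:
            sham = sham_means.loc[key]
        except KeyError:
            raise InputError(f"no sham group for cell {key}") from None
        delta = MorphologyDelta(
            fn_ratio=rec["fiber_number"] / sham["fiber_number"],
            csa_ratio={
                t: rec[f"csa_{t}_um2"] / sham[f"csa_{t}_um2"]
                for t in area_fractions
                if f"csa_{t}_um2" in rec.index
            },
            area_fraction=dict(area_fractions),
            fl_ratio=rec["fiber_length_cm"] / sham["fiber_length_cm"],
        )
        result = contribution_shares(delta, method=method)
        measured_ratio = rec["ss_mass_mg"] / sham["ss_mass_mg"]
        row = {
            "animal_id": rec["animal_id"],
            **{c: rec[c] for c in _GROUP_COLS},
            "fn_ratio": delta.fn_ratio,
            "csa_factor": delta.csa_factor,
            "fl_ratio": delta.fl_ratio,
            "predicted_ratio": result.mass_ratio,
            "predicted_deficit": result.predicted_deficit,
            "measured_ratio": measured_ratio,
            "measured_deficit": 1.0 - measured_ratio,
            "share_fiber_number": result.shares["fiber_number"],
            "share_fiber_csa": result.shares["fiber_csa"],
            "share_fiber_length": result.shares["fiber_length"],
            "method": method,
        }
        rows.append(row)
    return pd.DataFrame(rows)


def validate_cohort(
    df: pd.DataFrame, area_fractions: dict[str, float]
) -> ValidationRegression:
    """Predicted-vs-measured deficit regression over all tenotomized animals."""
    table = decompose_cohort(df, area_fractions, method="log", aggregate="animal")
    return validate_predictions(
        table["predicted_deficit"].to_numpy(), table["measured_deficit"].to_numpy()
    )
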