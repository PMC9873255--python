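"""Synthetic cohort generation.

Animals are laid out on a fully crossed sex x genotype x treatment x
timepoint design.  Sham animals realize sex-specific baselines; each
tenotomized animal realizes baseline x group effect factor x
multiplicative lognormal noise for every morphological quantity, and its
muscle mass is then *constructed* through the cylinder relation

    m = FN * (sum_i AF_i * CSA_i) * FL * rho

so the geometric decomposition downstream is exactly recoverable.
Tabular noise is lognormal (masses and lengths are positive and
CV-parameterized); records carry the realized per-animal true factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError

__all__ = [
    "FIBER_TYPES",
    "CohortDesign",
    "GroupEffect",
    "SexBaseline",
    "EffectModel",
    "generate_cohort",
]

FIBER_TYPES = ("1", "2a", "2x", "2b")
SEXES = ("M", "F")
GENOTYPES = ("WT", "MKD", "MCA")
TREATMENTS = ("SHM", "TEN")
TIMEPOINTS = ("W1", "W2", "W8")

#: conversion: um^2 -> cm^2
_UM2_TO_CM2 = 1e-8


@dataclass(frozen=True)
class CohortDesign:
    """Factor levels and group size of a fully crossed cohort."""

    sexes: tuple[str, ...] = SEXES
    genotypes: tuple[str, ...] = ("WT",)
    treatments: tuple[str, ...] = TREATMENTS
    timepoints: tuple[str, ...] = TIMEPOINTS
    n_per_group: int = 7
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 1:
            raise ConfigurationError("n_per_group must be >= 1")
        for name, levels, valid in (
            ("sexes", self.sexes, SEXES),
            ("genotypes", self.genotypes, GENOTYPES),
            ("treatments", self.treatments, TREATMENTS),
            ("timepoints", self.timepoints, TIMEPOINTS),
        ):
            if not levels:
                raise ConfigurationError(f"empty factor level set: {name}")
            unknown = set(levels) - set(valid)
            if unknown:
                raise ConfigurationError(f"unknown {name} levels: {sorted(unknown)}")


@dataclass
class GroupEffect:
    """Multiplicative tenotomy-to-sham effect factors for one (sex, timepoint)."""

    csa_ratio: dict[str, float]
    fn_ratio: float = 1.0
    fl_ratio: float = 1.0
    tension_ratio: float = 1.0

    def __post_init__(self):
        ratios = [self.fn_ratio, self.fl_ratio, *self.csa_ratio.values()]
        if any(not 0 < r <= 1.5 for r in ratios):
            raise ConfigurationError("effect ratios must lie in (0, 1.5]")

    @classmethod
    def unit(cls) -> "GroupEffect":
        return cls(csa_ratio={t: 1.0 for t in FIBER_TYPES})

    def csa_factor(self, area_fractions: dict[str, float]) -> float:
        """The aggregated CSA factor sum_i AF_i * dCSA_i."""
        return sum(area_fractions[t] * self.csa_ratio.get(t, 1.0) for t in area_fractions)


@dataclass
class SexBaseline:
    """Sham morphology baseline for one sex."""

    body_mass_g: float
    fiber_number: float
    csa_um2: dict[str, float]
    muscle_length_cm: float
    ta_mass_mg: float
    is_to_ss_ratio: float = 1.2
    specific_tension_n_cm2: float = 22.0


@dataclass
class EffectModel:
    """Baselines, area fractions, per-group effects and the noise level."""

    baselines: dict[str, SexBaseline]
    area_fractions: dict[str, float]
    effects: dict[tuple[str, str], GroupEffect]
    noise_cv: float = 0.05
    density_g_cm3: float = 1.056
    fl_to_ml_ratio: float = 0.6

    def __post_init__(self):
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be >= 0")
        af = self.area_fractions
        if any(v < 0 for v in af.values()) or abs(sum(af.values()) - 1.0) > 1e-8:
            raise ConfigurationError("area fractions must be >= 0 and sum to 1")

    @classmethod
    def default(cls, noise_cv: float | None = None) -> "EffectModel":
        """Load the packaged (literature-inspired) default effect configuration."""
        text = resources.files("myomorph.data").joinpath("default_effects.yaml").read_text()
        return cls.from_dict(yaml.safe_load(text), noise_cv=noise_cv)

    @classmethod
    def from_dict(cls, cfg: dict, noise_cv: float | None = None) -> "EffectModel":
        baselines = {
            sex: SexBaseline(
                body_mass_g=b["body_mass_g"],
                fiber_number=b["fiber_number"],
                csa_um2={str(k): float(v) for k, v in b["csa_um2"].items()},
                muscle_length_cm=b["muscle_length_cm"],
                ta_mass_mg=b["ta_mass_mg"],
                is_to_ss_ratio=b.get("is_to_ss_ratio", 1.2),
                specific_tension_n_cm2=b.get("specific_tension_n_cm2", 22.0),
            )
            for sex, b in cfg["baselines"].items()
        }
        effects = {
            (sex, tp): GroupEffect(
                csa_ratio={str(k): float(v) for k, v in e["csa_ratio"].items()},
                fn_ratio=e["fn_ratio"],
                fl_ratio=e["fl_ratio"],
                tension_ratio=e.get("tension_ratio", 1.0),
            )
            for sex, per_tp in cfg["effects"].items()
            for tp, e in per_tp.items()
        }
        return cls(
            baselines=baselines,
            area_fractions={str(k): float(v) for k, v in cfg["area_fractions"].items()},
            effects=effects,
            noise_cv=cfg["noise_cv"] if noise_cv is None else noise_cv,
            density_g_cm3=cfg.get("density_g_cm3", 1.056),
            fl_to_ml_ratio=cfg.get("fl_to_ml_ratio", 0.6),
        )


def _lognormal(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean multiplicative lognormal noise with coefficient of variation cv."""
    if cv <= 0:
        return 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return float(rng.lognormal(-sigma * sigma / 2.0, sigma))


def generate_cohort(design: CohortDesign, effects: EffectModel) -> pd.DataFrame:
    """Generate one animal record per design slot.

    Returns a DataFrame with one row per animal.  Columns (units):
    identifiers and factors; ``body_mass_g``; ``ss_mass_mg``,
    ``is_mass_mg``, ``ta_mass_mg``; ``muscle_length_cm`` (optimal muscle
    length), ``fiber_length_cm``; ``fiber_number``; ``csa_<type>_um2``;
    ``p0_n`` (peak tetanic force, N); and the realized per-animal true
    factors ``true_fn_ratio``, ``true_csa_<type>_ratio``,
    ``true_fl_ratio``, ``true_mass_ratio`` for recovery tests.
    """
    missing = [s for s in design.sexes if s not in effects.baselines]
    if missing:
        raise ConfigurationError(f"no baseline for sexes: {missing}")
    rng = np.random.default_rng(design.seed)
    af = effects.area_fractions
    rho = effects.density_g_cm3
    rows = []
    for sex in design.sexes:
        base = effects.baselines[sex]
        base_mean_csa = sum(af[t] * base.csa_um2[t] for t in af)
        for genotype in design.genotypes:
            for treatment in design.treatments:
                for timepoint in design.timepoints:
                    if treatment == "TEN":
                        try:
                            fac = effects.effects[(sex, timepoint)]
                        except KeyError:
                            raise ConfigurationError(
                                f"no effect factors for ({sex}, {timepoint})"
                            ) from None
                    else:
                        fac = GroupEffect.unit()
                    for k in range(design.n_per_group):
                        cv = effects.noise_cv
                        fn = base.fiber_number * fac.fn_ratio * _lognormal(rng, cv)
                        csa = {
                            t: base.csa_um2[t] * fac.csa_ratio.get(t, 1.0) * _lognormal(rng, cv)
                            for t in af
                        }
                        lm = base.muscle_length_cm * fac.fl_ratio * _lognormal(rng, cv)
                        fl = lm * effects.fl_to_ml_ratio
                        # AF_i are sham *area* fractions, so the aggregated fiber CSA
                        # is the sham mean scaled by sum_i AF_i * dCSA_i; this keeps
                        # the cylinder mass consistent with the decomposition identity
                        csa_factor = sum(af[t] * csa[t] / base.csa_um2[t] for t in af)
                        mean_csa = base_mean_csa * csa_factor
                        ss_mass_g = (
                            fn * mean_csa * _UM2_TO_CM2 * fl * rho * _lognormal(rng, cv)
                        )
                        is_mass_g = (
                            ss_mass_g * base.is_to_ss_ratio * _lognormal(rng, cv)
                        )
                        pcsa_cm2 = ss_mass_g / (rho * fl)
                        p0 = (
                            base.specific_tension_n_cm2
                            * fac.tension_ratio
                            * pcsa_cm2
                            * _lognormal(rng, cv)
                        )
                        row = {
                            "animal_id": f"{sex}-{genotype}-{treatment}-{timepoint}-{k + 1:02d}",
                            "sex": sex,
                            "genotype": genotype,
                            "treatment": treatment,
                            "timepoint": timepoint,
                            "body_mass_g": base.body_mass_g * _lognormal(rng, cv),
                            "ss_mass_mg": ss_mass_g * 1e3,
                            "is_mass_mg": is_mass_g * 1e3,
                            "ta_mass_mg": base.ta_mass_mg * _lognormal(rng, cv),
                            "muscle_length_cm": lm,
                            "fiber_length_cm": fl,
                            "fiber_number": fn,
                            "p0_n": p0,
                            "true_fn_ratio": fn / base.fiber_number,
                            "true_fl_ratio": lm / base.muscle_length_cm,
                        }
                        for t in af:
                            row[f"csa_{t}_um2"] = csa[t]
                            row[f"true_csa_{t}_ratio"] = csa[t] / base.csa_um2[t]
                        row["true_mass_ratio"] = (
                            row["true_fn_ratio"] * csa_factor * row["true_fl_ratio"]
                        )
                        rows.append(row)
    return pd.DataFrame(rows)
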