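"""Seeded simulator for admixed-colony phenotype datasets.

The generator produces datasets with the statistical structure the
analysis pipeline assumes, so every stage can be exercised and calibrated
without the real colony data.

Genetic model
-------------
Each measurement is controlled by L autosomal loci (2L alleles).  Every
allele derives from the Indian or the Chinese lineage; an individual with
Chinese-ancestry fraction A carries Chinese alleles either

* deterministically: round(2LA) Chinese alleles spread as evenly as
  possible across loci (pedigree ancestry taken at face value), or
* stochastically (``realized_ancestry``): each allele is Chinese
  independently with probability A, so realized ancestry varies around
  the pedigree value as it does after real recombination.

Allelic effects are equal on average and additive: each allele's effect
is drawn from a normal distribution with lineage mean ``a_I`` or ``a_C``
and spread ``allele_effect_sd`` (within-lineage allelic heterogeneity).
The additive parental trait means are therefore mu_I = 2L a_I and
mu_C = 2L a_C, and the expected hybrid value is the ancestry-weighted
parental mean — exactly the additive expectation the analysis tests.

Dominance enters as a constant d per *heterospecific* locus (one allele
from each lineage): the trait gains d times the number of such loci.
With realized ancestry a locus is heterospecific with probability
2A(1-A), giving the closed-form expected shift 2A(1-A) L d — positive d
produces heterosis, negative d dysgenesis, both maximal at A = 1/2 and
vanishing in full-breds.  With deterministic ancestry the even spread
makes the heterospecific count min(C, 2L-C) for C Chinese alleles.

On top of the genetic value come a lineage-specific sexual dimorphism
offset (male minus female, interpolated linearly in A between the two
lineages; females are the baseline) and Gaussian environmental noise.
Outputs are strictly positive: the environmental draw is resampled (with
a log message) for the rare value at or below zero.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from os import PathLike
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import reference
from .errors import DomainError
from .phenodata import RAW_MEASUREMENTS, group_of

logger = logging.getLogger(__name__)

_MEAS = RAW_MEASUREMENTS


def _per_measurement(value, name: str) -> dict[str, float]:
    """Broadcast a scalar, or validate a mapping covering all measurements."""
    if isinstance(value, Mapping):
        missing = set(_MEAS) - set(value)
        if missing:
            raise ValueError(f"{name} missing measurement(s): {sorted(missing)}")
        return {m: float(value[m]) for m in _MEAS}
    return {m: float(value) for m in _MEAS}


@dataclass
class SimConfig:
    """Parameters of the synthetic colony generator.

    Defaults reproduce the modelled colony: the 134-animal composition by
    ancestry bin and sex, parental lineage means, and dispersion at the
    levels published for the real colony (see
    :func:`default_config`).
    """

    #: {ancestry fraction: (n_female, n_male)}
    bin_counts: dict[float, tuple[int, int]]
    #: loci per measurement (the additive model is explicit in 2L alleles)
    loci: int
    #: per-measurement mean allelic effect of an Indian-derived allele
    allele_effect_indian: dict[str, float]
    #: per-measurement mean allelic effect of a Chinese-derived allele
    allele_effect_chinese: dict[str, float]
    #: within-lineage sd of single-allele effects
    allele_effect_sd: dict[str, float]
    #: per-heterospecific-locus dominance deviation (0 additive,
    #: >0 heterosis, <0 dysgenesis)
    dominance: dict[str, float] = field(default_factory=lambda: {m: 0.0 for m in _MEAS})
    #: environmental (residual) sd per measurement
    env_sd: dict[str, float] = field(default_factory=lambda: {m: 0.0 for m in _MEAS})
    #: male-minus-female offset per measurement, Indian lineage
    dimorphism_indian: dict[str, float] = field(default_factory=lambda: {m: 0.0 for m in _MEAS})
    #: male-minus-female offset per measurement, Chinese lineage
    dimorphism_chinese: dict[str, float] = field(default_factory=lambda: {m: 0.0 for m in _MEAS})
    #: sample per-allele ancestry instead of taking pedigree A exactly
    realized_ancestry: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.loci < 1:
            raise ValueError("loci must be >= 1")
        for a, (nf, nm) in self.bin_counts.items():
            if not 0.0 <= a <= 1.0:
                raise DomainError(f"ancestry bin {a} outside [0, 1]")
            if nf < 0 or nm < 0:
                raise ValueError("bin counts must be >= 0")
        for name in ("allele_effect_indian", "allele_effect_chinese",
                     "allele_effect_sd", "dominance", "env_sd",
                     "dimorphism_indian", "dimorphism_chinese"):
            setattr(self, name, _per_measurement(getattr(self, name), name))
        if any(v < 0 for v in self.env_sd.values()):
            raise ValueError("env_sd must be >= 0")
        if any(v < 0 for v in self.allele_effect_sd.values()):
            raise ValueError("allele_effect_sd must be >= 0")

    @property
    def n_animals(self) -> int:
        return sum(nf + nm for nf, nm in self.bin_counts.values())

    def to_dict(self) -> dict:
        return {
            "bin_counts": {str(a): list(c) for a, c in self.bin_counts.items()},
            "loci": self.loci,
            "allele_effect_indian": self.allele_effect_indian,
            "allele_effect_chinese": self.allele_effect_chinese,
            "allele_effect_sd": self.allele_effect_sd,
            "dominance": self.dominance,
            "env_sd": self.env_sd,
            "dimorphism_indian": self.dimorphism_indian,
            "dimorphism_chinese": self.dimorphism_chinese,
            "realized_ancestry": self.realized_ancestry,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        d["bin_counts"] = {float(a): tuple(c) for a, c in d["bin_counts"].items()}
        return cls(**d)


@dataclass(frozen=True)
class SimTruth:
    """Ground truth implied by a :class:`SimConfig`, for recovery tests."""

    #: additive (female-baseline) parental means mu = 2L * allele effect
    parental_mean_indian: dict[str, float]
    parental_mean_chinese: dict[str, float]
    config: SimConfig

    def additive_mean(self, ancestry, measurement: str):
        """(1-A) mu_I + A mu_C, the female additive expectation."""
        a = np.asarray(ancestry, dtype=float)
        out = (1 - a) * self.parental_mean_indian[measurement] + a * self.parental_mean_chinese[measurement]
        return float(out) if out.ndim == 0 else out

    def dimorphism(self, ancestry, measurement: str):
        """Male-minus-female offset interpolated linearly in ancestry."""
        a = np.asarray(ancestry, dtype=float)
        out = (1 - a) * self.config.dimorphism_indian[measurement] + a * self.config.dimorphism_chinese[measurement]
        return float(out) if out.ndim == 0 else out

    def expected_value(self, ancestry, measurement: str, sex="F"):
        """Expected trait value at (ancestry, sex) under d = 0."""
        male = np.asarray(sex) == "M"
        return self.additive_mean(ancestry, measurement) + male * self.dimorphism(ancestry, measurement)

    def heterotic_shift(self, ancestry, measurement: str):
        """Expected dominance shift 2A(1-A) L d (realized-ancestry form)."""
        a = np.asarray(ancestry, dtype=float)
        out = 2 * a * (1 - a) * self.config.loci * self.config.dominance[measurement]
        return float(out) if out.ndim == 0 else out

    def to_dict(self) -> dict:
        return {
            "parental_mean_indian": self.parental_mean_indian,
            "parental_mean_chinese": self.parental_mean_chinese,
            "config": self.config.to_dict(),
        }

    def to_json(self, path: str | PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


# Lineage-specific sexual dimorphism defaults (male minus female), chosen at
# rhesus-plausible magnitudes with the Indian lineage slightly more dimorphic;
# calibration choices of this package, documented in docs/methods.md.
_DEFAULT_DIMORPHISM_INDIAN = {
    "weight": 3.2, "crown_rump": 30.0, "humerus": 9.0,
    "radius": 9.0, "femur": 11.0, "tibia": 10.0,
}
_DEFAULT_DIMORPHISM_CHINESE = {
    "weight": 2.4, "crown_rump": 24.0, "humerus": 8.0,
    "radius": 8.0, "femur": 9.0, "tibia": 8.0,
}


def default_config(seed: int = 0, loci: int = 100, realized_ancestry: bool = False) -> SimConfig:
    """Default colony configuration.

    Composition and parental means come straight from the published colony
    reference tables.  Allelic effects are the parental means divided by
    2L.  Total phenotypic sd per measurement targets (mean published V*
    across the three groups) x mid-parent mean, split half genetic
    (allelic-effect spread) and half environmental.
    """
    a_ind, a_chi, eff_sd, env = {}, {}, {}, {}
    for m in _MEAS:
        mu_i, mu_c = reference.parental_means(m)
        a_ind[m] = mu_i / (2 * loci)
        a_chi[m] = mu_c / (2 * loci)
        target_cv = np.mean(reference.GROUP_VSTAR[m]) / 100.0
        target_sd = target_cv * 0.5 * (mu_i + mu_c)
        eff_sd[m] = target_sd * np.sqrt(0.5 / (2 * loci))
        env[m] = target_sd * np.sqrt(0.5)
    return SimConfig(
        bin_counts=dict(reference.COLONY_BIN_COUNTS),
        loci=loci,
        allele_effect_indian=a_ind,
        allele_effect_chinese=a_chi,
        allele_effect_sd=eff_sd,
        dominance={m: 0.0 for m in _MEAS},
        env_sd=env,
        dimorphism_indian=dict(_DEFAULT_DIMORPHISM_INDIAN),
        dimorphism_chinese=dict(_DEFAULT_DIMORPHISM_CHINESE),
        realized_ancestry=realized_ancestry,
        seed=seed,
    )


def sim_truth(config: SimConfig) -> SimTruth:
    L = config.loci
    return SimTruth(
        parental_mean_indian={m: 2 * L * config.allele_effect_indian[m] for m in _MEAS},
        parental_mean_chinese={m: 2 * L * config.allele_effect_chinese[m] for m in _MEAS},
        config=config,
    )


def simulate_genotypes(A: float, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-locus allele ancestries for one individual.

    Returns an (L, 2) int8 array, 0 = Indian allele, 1 = Chinese allele.
    Deterministic mode places round(2LA) Chinese alleles as evenly as
    possible across loci (no locus carries two until every locus carries
    one); realized mode draws each allele independently with probability A.
    """
    if not 0.0 <= A <= 1.0:
        raise DomainError(f"ancestry {A} outside [0, 1]")
    L = config.loci
    if config.realized_ancestry:
        return (rng.random((L, 2)) < A).astype(np.int8)
    c = int(round(2 * L * A))
    g = np.zeros((L, 2), dtype=np.int8)
    q, r = divmod(c, L)
    if q >= 1:
        g[:, 0] = 1
    if q == 2:
        g[:, 1] = 1
    if r:
        g[:r, 1 if q >= 1 else 0] = 1
    return g


def _dimorphism_at(config: SimConfig, A, measurement: str):
    return (1 - np.asarray(A, float)) * config.dimorphism_indian[measurement] + np.asarray(
        A, float
    ) * config.dimorphism_chinese[measurement]


def simulate_trait(
    genotypes: np.ndarray,
    config: SimConfig,
    sex: str,
    measurement: str,
    rng: np.random.Generator,
) -> float:
    """One trait value from explicit per-allele effect draws.

    value = sum of 2L allelic effects (lineage mean a_I or a_C, sd
    allele_effect_sd) + d x (number of heterospecific loci) + sexual
    dimorphism term (males only; interpolated in realized ancestry)
    + N(0, env_sd), resampling the environmental draw if the result is
    not strictly positive.
    """
    g = np.asarray(genotypes)
    a_i = config.allele_effect_indian[measurement]
    a_c = config.allele_effect_chinese[measurement]
    means = np.where(g == 1, a_c, a_i)
    effects = rng.normal(means, config.allele_effect_sd[measurement])
    het = int((g.sum(axis=1) == 1).sum())
    a_real = g.mean()
    base = effects.sum() + config.dominance[measurement] * het
    if sex == "M":
        base += _dimorphism_at(config, a_real, measurement)
    env = config.env_sd[measurement]
    for attempt in range(1000):
        value = base + rng.normal(0.0, env)
        if value > 0:
            if attempt:
                logger.warning(
                    "resampled environmental noise %d time(s) for %s to keep value positive",
                    attempt, measurement,
                )
            return float(value)
    raise RuntimeError(f"could not draw a positive {measurement} value (base={base})")


def _allele_count_matrices(A: np.ndarray, config: SimConfig, rng: np.random.Generator):
    """Vectorized ancestry draws: per-animal Chinese-allele and het-locus counts.

    Allele effects are exchangeable within an individual, so the effect sum
    depends on genotypes only through the Chinese-allele count C and the
    heterospecific-locus count H.  Matches :func:`simulate_genotypes`:
    deterministic mode gives C = round(2LA), H = min(C, 2L - C); realized
    mode draws per-locus Binomial(2, A).
    """
    L = config.loci
    n = A.size
    if config.realized_ancestry:
        x = rng.binomial(2, A[:, None], size=(n, L))
        c = x.sum(axis=1)
        het = (x == 1).sum(axis=1)
    else:
        c = np.rint(2 * L * A).astype(int)
        het = np.minimum(c, 2 * L - c)
    return c, het


def simulate_colony(config: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate a full colony dataset; deterministic given ``config.seed``.

    Returns a phenotype frame (``id, sex, ancestry, group`` plus the six
    raw measurements) and the :class:`SimTruth` used to generate it.
    Internally vectorized but drawing explicit per-allele effects, so the
    per-record :func:`simulate_trait` path has the same distribution.
    """
    rng = np.random.default_rng(config.seed)
    A_list, sex_list = [], []
    for a in sorted(config.bin_counts):
        nf, nm = config.bin_counts[a]
        A_list += [a] * (nf + nm)
        sex_list += ["F"] * nf + ["M"] * nm
    A = np.array(A_list, dtype=float)
    sex = np.array(sex_list)
    n = A.size
    L = config.loci

    df = pd.DataFrame(
        {
            "id": [f"sim-{i:04d}" for i in range(n)],
            "sex": sex,
            "ancestry": A,
            "group": group_of(A) if n else np.array([], dtype=object),
        }
    )
    male = sex == "M"
    for m in _MEAS:
        c, het = _allele_count_matrices(A, config, rng)
        a_i, a_c = config.allele_effect_indian[m], config.allele_effect_chinese[m]
        # per-allele effect draws: first c[i] alleles Chinese-derived
        means = np.where(np.arange(2 * L)[None, :] < c[:, None], a_c, a_i)
        effects = rng.normal(means, config.allele_effect_sd[m])
        a_real = c / (2 * L)
        value = effects.sum(axis=1) + config.dominance[m] * het
        value = value + np.where(male, _dimorphism_at(config, a_real, m), 0.0)
        env = rng.normal(0.0, config.env_sd[m], size=n)
        out = value + env
        resampled = 0
        for _ in range(1000):
            bad = out <= 0
            if not bad.any():
                break
            resampled += int(bad.sum())
            out[bad] = value[bad] + rng.normal(0.0, config.env_sd[m], size=int(bad.sum()))
        else:
            raise RuntimeError(
                f"could not draw positive {m} values; the configured effects "
                "push the trait at or below zero"
            )
        if resampled:
            logger.warning(
                "resampled %d non-positive %s draw(s) to keep values positive",
                resampled, m,
            )
        df[m] = out
    return df, sim_truth(config)


def power_analysis(
    config: SimConfig,
    effect_grid: Sequence[float],
    alpha: float = 0.05,
    reps: int = 200,
    seed: int | None = None,
) -> pd.DataFrame:
    """Rejection rates of the mid-parental battery block over planted effects.

    Each grid entry ``lam`` plants dominance d = lam * env_sd / L per
    measurement, i.e. ``lam`` is the total per-locus-dominance shift L*d
    expressed in units of that measurement's environmental sd (dominance
    has trait units, so a shared scalar must be scaled per measurement).
    ``lam = 0`` is the null row and measures empirical type-I error.

    For each replicate a colony is simulated and the battery's
    mid-parental block is evaluated against the *true* additive
    expectations (sex-specific, from :class:`SimTruth`) on unadjusted
    values, with the one-tailed direction matching the planted sign
    (``smaller`` at lam = 0).  Using the truth as reference isolates the
    test's calibration from parental-mean estimation error and from the
    variance distortion introduced by add-offset sex adjustment (see
    docs/methods.md); both would otherwise dominate the null rate.

    Returns a long DataFrame: ``effect_L_d_env_sd, measurement,
    rejection_rate, fraction_above, n_reps`` with extra rows
    ``measurement="any"`` (family-wise: at least one measurement flagged)
    and ``"all"`` (every measurement flagged).
    """
    from .test_battery import run_size_battery  # local import to avoid cycle

    ss = np.random.SeedSequence(config.seed if seed is None else seed)
    rows = []
    for lam in effect_grid:
        cfg = replace(
            config,
            dominance={m: lam * config.env_sd[m] / config.loci for m in _MEAS},
        )
        direction = "larger" if lam > 0 else "smaller"
        child_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(reps)]
        rej = {m: 0 for m in _MEAS}
        n_any = n_all = 0
        above = {m: 0 for m in _MEAS}
        total = {m: 0 for m in _MEAS}
        for s in child_seeds:
            colony, truth = simulate_colony(replace(cfg, seed=s))
            hyb = colony[colony["group"] == "hybrid"]
            exp_rows = []
            for m in _MEAS:
                e = truth.expected_value(hyb["ancestry"].to_numpy(), m, hyb["sex"].to_numpy())
                exp_rows.append(pd.DataFrame({"id": hyb["id"], "measurement": m, "expected": e}))
                dev = hyb[m].to_numpy() - e
                above[m] += int((dev > 0).sum())
                total[m] += dev.size
            expected = pd.concat(exp_rows, ignore_index=True)
            ref = {
                m: (truth.parental_mean_indian[m], truth.parental_mean_chinese[m])
                for m in _MEAS
            }
            bat = run_size_battery(
                colony, alpha=alpha, reference_means=ref, expected=expected,
                direction=direction, blocks=("mid_parental",),
            )
            sig = bat.set_index("measurement")["significant"]
            hits = [bool(sig[m]) for m in _MEAS]
            for m, h in zip(_MEAS, hits):
                rej[m] += h
            n_any += any(hits)
            n_all += all(hits)
        for m in _MEAS:
            rows.append(
                {
                    "effect_L_d_env_sd": lam, "measurement": m,
                    "rejection_rate": rej[m] / reps,
                    "fraction_above": above[m] / total[m] if total[m] else np.nan,
                    "n_reps": reps,
                }
            )
        rows.append({"effect_L_d_env_sd": lam, "measurement": "any",
                     "rejection_rate": n_any / reps, "fraction_above": np.nan, "n_reps": reps})
        rows.append({"effect_L_d_env_sd": lam, "measurement": "all",
                     "rejection_rate": n_all / reps, "fraction_above": np.nan, "n_reps": reps})
    return pd.DataFrame(rows)
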