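"""Synthetic multi-breed cohort generator.

Emulates the statistical structure of a mixed *Bos indicus* / *Bos taurus*
beef cohort with consumer-panel eating-quality phenotypes so the whole
pipeline is testable offline:

* two breeds plus F1 crosses, with per-breed allele frequencies drawn from
  the Balding-Nichols model around a common ancestral frequency (the standard
  FST-parameterised choice), so PC1 of the GRM acts as an ancestry proxy;
* SNP effects from the four-component BayesR mixture
  (0, 1e-4, 1e-3, 1e-2) * sigma_g2;
* heterosis proportional to each animal's proportion of heterozygous loci;
* contemporary groups blocked by breed and confounded with days aged (days
  aged is drawn once per group, plus small within-group jitter) and carcass
  weight drawn from the cohort's observed distribution (mean 261 kg, SD 74,
  truncated to 50.6-576 kg);
* 10-consumer sensory panels per animal per trait, clipped to the middle six
  scores, with the MQ4 composite.

All randomness flows from one integer seed; the orchestrator derives fixed
per-stage substreams (seed, seed+1, seed+2) for genotypes, QTL effects and
phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeMatrix, PhenotypeTable
from .sensory import PANEL_SIZE, panel_traits
from .structure import heterozygosity

# Variance of the clipped mean (middle 6 of 10 order statistics) of i.i.d.
# standard normal consumer noise, by large Monte Carlo; used to back the
# panel-noise contribution out of the residual variance so the realized
# heritability of the clipped phenotype hits its target.
CLIPPED_MEAN_VAR_FACTOR = 0.1133

DEFAULT_PI = (0.95, 0.03, 0.015, 0.005)

# carcass weight distribution observed in the cohort
CW_MEAN, CW_SD, CW_LO, CW_HI = 261.0, 74.0, 50.6, 576.0


class ParameterError(ValueError):
    pass


@dataclass
class SimulationTruth:
    """Generative ground truth recorded for test oracles."""

    effects: np.ndarray            # (m,) per-allele trait units; 0 in component 1
    components: np.ndarray         # (m,) mixture index 1..4
    ancestral_freq: np.ndarray     # (m,)
    breed_freqs: np.ndarray        # (2, m)
    admixture: np.ndarray          # (n,) proportion of breed-A ancestry
    group_labels: np.ndarray       # (n,) "A", "B" or "F1"
    sigma_g2: float = np.nan       # mixture scale used to draw effects
    cg_effects: np.ndarray | None = None
    days_aged_slope: float = 0.0
    carcass_weight_slope: float = 0.0
    heterosis_slope: float = 0.0
    breed_shift: float = 0.0
    mu: float = 0.0
    sigma_e2: float = np.nan       # animal-level residual variance used
    var_zg: float = np.nan         # realized var of Zg over animals
    h2_target: float = np.nan
    h2_realized: float = np.nan    # var(Zg) / within-cg var of clipped scores
    genetic_values: np.ndarray | None = None  # (n,) Zg

    def to_json_dict(self) -> dict:
        out = {}
        for k, v in self.__dict__.items():
            out[k] = v.tolist() if isinstance(v, np.ndarray) else v
        return out


@dataclass
class PhenotypeDesign:
    """Fixed-effect and panel structure of the simulated cohort.

    Defaults emulate the study conditions: ~26 animals per contemporary
    group, aging improves eating quality by about half a point per day,
    carcass weight has a small positive slope, heterosis is worth a few
    points across the observed heterozygosity range, and the breed-mean
    shift is most of a phenotypic SD so breed structure matters.
    """

    n_cg: int | None = None          # default: ceil(n / 26), at least 2
    cg_sd: float = 5.0               # SD of contemporary-group effects (points)
    cg_breed_mixing: float = 0.1     # prob. an animal joins an off-breed cg
    days_aged_slope: float = 0.2     # points per day aged: modest, so the
                                     # estimated term carries little signal
                                     # relative to its estimation error under
                                     # cg confounding (the regime the cohort
                                     # analysis reports)
    days_aged_jitter_sd: float = 0.5 # within-cg days-aged spread (days);
                                     # small: aging time is a cohort property
    carcass_weight_slope: float = 0.02  # points per kg
    heterosis_slope: float = 8.0     # points per unit heterozygosity
    breed_shift: float = 21.0        # points per unit breed-A ancestry
                                     # (1.5 within-cg phenotypic SD: breed
                                     # matters, as in the mixed indicus/
                                     # taurus cohort)
    mu: float = 42.0                 # baseline (breed-B) mean; with the
                                     # breed and heterosis contributions the
                                     # realized cohort mean sits near 57 on
                                     # the 0-100 scale, keeping the 100-point
                                     # ceiling rarely binding
    consumer_sd: float = 10.0        # per-consumer panel noise SD (points)
    phenotypic_sd: float = 14.0      # target within-cg SD of clipped scores


def simulate_breed_genotypes(
    n_per_group: tuple[int, int, int],
    m: int,
    fst: float,
    seed: int = 0,
) -> tuple[GenotypeMatrix, SimulationTruth]:
    """Two Balding-Nichols breeds plus F1 crosses.

    Ancestral frequencies are uniform on [0.05, 0.95]; each breed's frequency
    is Beta-distributed around the ancestral value with differentiation
    parameter ``fst``. Purebreds draw binomial(2, breed frequency) genotypes;
    each F1 animal draws one allele from each breed.
    """
    if m < 2:
        raise ParameterError("need m >= 2 SNPs")
    if not 0.0 < fst <= 0.5:
        raise ParameterError("fst must lie in (0, 0.5]")
    n_a, n_b, n_f1 = n_per_group
    if min(n_a, n_b, n_f1) < 0:
        raise ParameterError("group counts must be non-negative")
    n = n_a + n_b + n_f1
    if n == 0:
        raise ParameterError("need at least one animal")

    rng = np.random.default_rng(seed)
    p0 = rng.uniform(0.05, 0.95, size=m)
    shape = (1.0 - fst) / fst
    freqs = np.empty((2, m))
    for b in range(2):
        freqs[b] = rng.beta(p0 * shape, (1.0 - p0) * shape)
    np.clip(freqs, 0.0, 1.0, out=freqs)

    codes = np.empty((n, m), dtype=np.int8)
    codes[:n_a] = rng.binomial(2, freqs[0], size=(n_a, m))
    codes[n_a:n_a + n_b] = rng.binomial(2, freqs[1], size=(n_b, m))
    # one allele from each parental breed
    codes[n_a + n_b:] = (
        rng.binomial(1, freqs[0], size=(n_f1, m))
        + rng.binomial(1, freqs[1], size=(n_f1, m))
    ).astype(np.int8)

    admixture = np.concatenate(
        [np.ones(n_a), np.zeros(n_b), np.full(n_f1, 0.5)]
    )
    groups = np.array(["A"] * n_a + ["B"] * n_b + ["F1"] * n_f1)

    snp_meta = pd.DataFrame(
        {
            "chrom": "1",
            "snp_id": [f"snp{j}" for j in range(m)],
            "cm": 0.0,
            "pos": np.arange(1, m + 1) * 1000,
            "a1": "A",
            "a2": "B",
        }
    )
    geno = GenotypeMatrix(
        codes=codes,
        snp_meta=snp_meta,
        animal_ids=[f"an{i}" for i in range(n)],
    )
    truth = SimulationTruth(
        effects=np.zeros(m),
        components=np.ones(m, dtype=int),
        ancestral_freq=p0,
        breed_freqs=freqs,
        admixture=admixture,
        group_labels=groups,
    )
    return geno, truth


def simulate_qtl_effects(
    m: int,
    pi: tuple = DEFAULT_PI,
    sigma_g2: float = 1.0,
    seed: int = 0,
    gamma: tuple = (0.0, 1e-4, 1e-3, 1e-2),
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP effects from the four-component BayesR mixture.

    Returns ``(effects, components)`` with components 1-based; component-1
    effects are exactly zero.
    """
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (4,) or np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-8:
        raise ParameterError("pi must be 4 non-negative entries summing to 1")
    if sigma_g2 <= 0:
        raise ParameterError("sigma_g2 must be positive")
    rng = np.random.default_rng(seed)
    components = rng.choice(4, size=m, p=pi) + 1
    sds = np.sqrt(np.asarray(gamma) * sigma_g2)[components - 1]
    effects = rng.standard_normal(m) * sds
    effects[components == 1] = 0.0
    return effects, components


def _assign_contemporary_groups(groups, n_cg, mixing, rng):
    """Breed-blocked cg assignment: each cg has a home breed group and draws
    mostly from it, emulating cohort/breed confounding."""
    labels = np.unique(groups)
    home = np.array([labels[c % len(labels)] for c in range(n_cg)])
    cg = np.empty(len(groups), dtype=np.int64)
    for i, grp in enumerate(groups):
        if rng.random() < mixing:
            cg[i] = rng.integers(n_cg)
        else:
            candidates = np.where(home == grp)[0]
            if len(candidates) == 0:
                candidates = np.arange(n_cg)
            cg[i] = rng.choice(candidates)
    return cg


def simulate_phenotypes(
    geno: GenotypeMatrix,
    truth: SimulationTruth,
    design: PhenotypeDesign,
    h2_target: float = 0.3,
    n_consumers: int = PANEL_SIZE,
    seed: int = 0,
) -> tuple[dict, PhenotypeTable, SimulationTruth]:
    """Consumer panels and the clipped phenotype table for simulated animals.

    The latent animal value is ``mu + cg + days_aged + carcass_weight +
    heterosis + breed shift + Zg + e`` with the residual variance set so the
    clipped trait score realizes the target heritability (the clipped panel
    mean contributes ``CLIPPED_MEAN_VAR_FACTOR * consumer_sd^2`` of
    environmental variance on top of the animal-level residual). Returns the
    raw panels (trait -> (n, 10) array), the phenotype table, and the truth
    updated with the realized quantities.
    """
    if not 0.0 < h2_target < 1.0:
        raise ParameterError("h2_target must lie in (0, 1)")
    if n_consumers != PANEL_SIZE:
        raise ParameterError(f"panels have exactly {PANEL_SIZE} consumers")
    rng = np.random.default_rng(seed)
    n = geno.n_animals

    # rescale the QTL effects so the genetic variance takes exactly an
    # h2_target share of the within-cg phenotypic variance budget; the
    # generative sigma_g2 only sets the *relative* spread of the mixture
    sigma_p2 = design.phenotypic_sd**2
    zg = geno.codes.astype(float) @ truth.effects
    var_zg_raw = float(np.var(zg))
    if var_zg_raw > 0:
        scale = np.sqrt(h2_target * sigma_p2 / var_zg_raw)
        truth.effects = truth.effects * scale
        zg = zg * scale
    var_zg = float(np.var(zg))

    n_cg = design.n_cg if design.n_cg is not None else max(2, int(np.ceil(n / 26)))
    if n < n_cg:
        raise ParameterError("fewer animals than contemporary groups")
    cg = _assign_contemporary_groups(truth.group_labels, n_cg, design.cg_breed_mixing, rng)
    cg_effects = rng.standard_normal(n_cg) * design.cg_sd

    # days aged: one integer draw per cg (confounded with cg), small jitter
    cg_days = rng.integers(3, 36, size=n_cg)
    days = cg_days[cg] + np.rint(
        rng.standard_normal(n) * design.days_aged_jitter_sd
    ).astype(int)
    days = np.clip(days, 3, 35)

    a, b = (CW_LO - CW_MEAN) / CW_SD, (CW_HI - CW_MEAN) / CW_SD
    cw = stats.truncnorm.rvs(a, b, loc=CW_MEAN, scale=CW_SD, size=n, random_state=rng)

    het = heterozygosity(geno.codes)

    fixed_part = (
        design.mu
        + cg_effects[cg]
        + design.days_aged_slope * (days - days.mean())
        + design.carcass_weight_slope * (cw - cw.mean())
        + design.heterosis_slope * het
        + design.breed_shift * truth.admixture
    )

    panel_noise_var = CLIPPED_MEAN_VAR_FACTOR * design.consumer_sd**2
    sigma_e2_total = (1.0 - h2_target) * sigma_p2
    if panel_noise_var > sigma_e2_total:
        raise ParameterError(
            "consumer panel noise alone exceeds the environmental variance "
            "budget; lower consumer_sd or h2_target"
        )
    sigma_e2_animal = sigma_e2_total - panel_noise_var
    e = rng.standard_normal(n) * np.sqrt(sigma_e2_animal)

    latent = fixed_part + zg + e
    panels = {}
    for trait in ("tender", "juicy", "flavor", "overall"):
        noise = rng.standard_normal((n, PANEL_SIZE)) * design.consumer_sd
        panels[trait] = np.clip(latent[:, None] + noise, 0.0, 100.0)

    traits = panel_traits(panels)
    df = pd.DataFrame(
        {
            "animal_id": geno.animal_ids,
            **{t: traits[t] for t in ("tender", "juicy", "flavor", "overall", "mq4")},
            "cg": [f"cg{c}" for c in cg],
            "days_aged": days,
            "carcass_weight": cw,
        }
    )
    table = PhenotypeTable(data=df)

    y = traits["tender"]
    cg_ser = pd.Series(y).groupby(cg)
    within = float((cg_ser.transform("var").mean()))
    truth.cg_effects = cg_effects
    truth.days_aged_slope = design.days_aged_slope
    truth.carcass_weight_slope = design.carcass_weight_slope
    truth.heterosis_slope = design.heterosis_slope
    truth.breed_shift = design.breed_shift
    truth.mu = design.mu
    truth.sigma_e2 = sigma_e2_animal
    truth.var_zg = var_zg
    truth.h2_target = h2_target
    truth.h2_realized = var_zg / within if within > 0 else np.nan
    truth.genetic_values = zg
    return panels, table, truth


@dataclass
class SimulatedCohort:
    geno: GenotypeMatrix
    phenotypes: PhenotypeTable
    panels: dict
    truth: SimulationTruth


def simulate_cohort(
    n_per_group: tuple[int, int, int] = (400, 400, 200),
    m: int = 2_000,
    fst: float = 0.1,
    pi: tuple = DEFAULT_PI,
    sigma_g2: float = 1.0,
    h2_target: float = 0.3,
    design: PhenotypeDesign | None = None,
    seed: int = 0,
) -> SimulatedCohort:
    """Full cohort: genotypes, QTL effects, covariates and panels.

    ``sigma_g2`` sets the relative spread of the effect mixture; effects are
    then used as drawn and the residual variance is chosen to realize
    ``h2_target``, so the absolute scale of ``sigma_g2`` is immaterial.
    """
    design = design or PhenotypeDesign()
    geno, truth = simulate_breed_genotypes(n_per_group, m, fst, seed=seed)
    effects, components = simulate_qtl_effects(
        m, pi=pi, sigma_g2=sigma_g2, seed=seed + 1
    )
    truth.effects = effects
    truth.components = components
    truth.sigma_g2 = sigma_g2
    panels, table, truth = simulate_phenotypes(
        geno, truth, design, h2_target=h2_target, seed=seed + 2
    )
    return SimulatedCohort(geno=geno, phenotypes=table, panels=panels, truth=truth)
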