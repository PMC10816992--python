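"""Seeded generator of synthetic screening cohorts.

Emulates the statistical structure the threshold analysis relies on, so
the whole pipeline is testable end to end:

* a bimodal plasma 42/40 ratio -- two truncated Gaussians, the
  amyloid-positive component shifted low;
* group-dependent latent amyloid prevalence (AD patients mostly positive,
  volunteers following an age-dependent population prevalence anchored at
  15.8% at age 60 and 32.6% at age 80);
* APOE e4 enrichment among amyloid-positive participants;
* MMSE driven by dementia status;
* CSF A-beta-42 / Centiloid observations consistent with the latent
  status (flippable via ``label_noise``), available only for a labelled
  subset, with randomised blood-to-amyloid measurement delays so the
  two-year eligibility window actually filters.

Every draw flows from one ``numpy`` Generator seeded from the config, so
a config uniquely determines the cohort.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, asdict
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import integrate, stats

from .cohort import ApoE, Cohort, Group, Participant, Sex
from .mixture import MixtureFit, gaussian_intersection

__all__ = [
    "GeneratorConfig",
    "paper_like_config",
    "generate_cohort",
    "generate_cohort_with_truth",
    "prevalence_at_age",
    "expected_positive_fraction",
    "analytic_intersection",
]

_AGE_LO, _AGE_HI = 50.0, 95.0
_BASE_DATE = _dt.date(2021, 6, 15)

_CARRIER_GENOTYPES = (ApoE.E3E4, ApoE.E4E4, ApoE.E2E4)
_CARRIER_P = (0.80, 0.15, 0.05)
_NONCARRIER_GENOTYPES = (ApoE.E3E3, ApoE.E2E3, ApoE.E2E2)
_NONCARRIER_P = (0.80, 0.18, 0.02)


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-generator settings.

    The ratio components are calibrated so that, at the default group mix,
    the weighted intersection of the two true Gaussians sits near 0.047 --
    the neighbourhood where published plasma 42/40 cutoffs fall. They are
    a stand-in with the right shape, not estimates from any study.

    ``p_amyloid_by_group`` maps a clinical group to its latent
    amyloid-positive probability; ``None`` defers to the age-dependent
    population prevalence (used for volunteers).
    """

    n_volunteers: int = 277
    n_ad: int = 70
    n_nonad: int = 18
    # ratio mixture (dimensionless)
    mu_pos: float = 0.0391
    sigma_pos: float = 0.0040
    mu_neg: float = 0.0584
    sigma_neg: float = 0.0050
    # latent amyloid status
    p_amyloid_by_group: Dict[str, Optional[float]] = field(
        default_factory=lambda: {"volunteer": None, "ad": 0.87, "non_ad": 0.10}
    )
    prevalence_by_age: Tuple[Tuple[float, float], Tuple[float, float]] = ((60.0, 0.158), (80.0, 0.326))
    # APOE e4 carriage by latent status
    p_e4_given_pos: float = 0.70
    p_e4_given_neg: float = 0.30
    # dementia and MMSE
    p_dementia_by_group: Dict[str, float] = field(
        default_factory=lambda: {"volunteer": 0.0, "ad": 23 / 70, "non_ad": 2 / 18}
    )
    mmse_params: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {"non_demented": (28.3, 1.3), "demented": (20.0, 3.0)}
    )
    # demographics
    age_by_group: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {"volunteer": (66.5, 7.78), "ad": (71.1, 8.05), "non_ad": (65.6, 9.55)}
    )
    p_female_by_group: Dict[str, float] = field(
        default_factory=lambda: {"volunteer": 179 / 277, "ad": 38 / 70, "non_ad": 11 / 18}
    )
    # labelling (confirmatory CSF/PET exam)
    labeled_fraction_by_group: Dict[str, float] = field(
        default_factory=lambda: {"volunteer": 73 / 277, "ad": 1.0, "non_ad": 1.0}
    )
    p_csf: float = 0.5
    p_pib_given_pet: float = 0.05
    label_noise: float = 0.0
    # blood-to-amyloid measurement delay (days)
    delay_days_distribution: Dict[str, float] = field(
        default_factory=lambda: {
            "p_within": 0.9,
            "max_within": 730,
            "max_beyond": 1460,
            "p_before_given_beyond": 0.7,
        }
    )
    # plasma A-beta-40 concentration (pg/mL)
    ab40_mean: float = 220.0
    ab40_sd: float = 35.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_volunteers, self.n_ad, self.n_nonad) < 0:
            raise ValueError("group counts must be non-negative")
        if not (self.sigma_pos > 0 and self.sigma_neg > 0 and self.ab40_sd > 0):
            raise ValueError("scale parameters must be positive")
        if not self.mu_pos < self.mu_neg:
            raise ValueError("the amyloid-positive component must sit at lower ratios (mu_pos < mu_neg)")
        probs = [
            self.p_e4_given_pos,
            self.p_e4_given_neg,
            self.p_csf,
            self.p_pib_given_pet,
            self.label_noise,
            *[v for v in self.p_amyloid_by_group.values() if v is not None],
            *self.p_dementia_by_group.values(),
            *self.p_female_by_group.values(),
            *self.labeled_fraction_by_group.values(),
            *[p for _, p in self.prevalence_by_age],
            self.delay_days_distribution["p_within"],
            self.delay_days_distribution["p_before_given_beyond"],
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        d = self.delay_days_distribution
        if not 0 < d["max_within"] < d["max_beyond"]:
            raise ValueError("delay bounds must satisfy 0 < max_within < max_beyond")

    def to_dict(self) -> dict:
        return asdict(self)


def paper_like_config(seed: int = 0) -> GeneratorConfig:
    """The calibrated default configuration: 277 volunteers, 70 AD and 18
    non-AD patients, with all patients and roughly 73 volunteers sent for
    a confirmatory CSF/PET exam, targeting an eligible labelled subset of
    about 151 (of whom about 126 are without dementia)."""
    return GeneratorConfig(seed=seed)


def prevalence_at_age(age, anchors=((60.0, 0.158), (80.0, 0.326))):
    """Amyloid prevalence among clinically normal adults at a given age.

    Linear in age through the two anchor points, extrapolated and clamped
    to [0.01, 0.99].
    """
    (a0, p0), (a1, p1) = anchors
    p = p0 + (p1 - p0) * (np.asarray(age, dtype=float) - a0) / (a1 - a0)
    return np.clip(p, 0.01, 0.99)


def _age_dist(mean: float, sd: float) -> stats.rv_continuous:
    a, b = (_AGE_LO - mean) / sd, (_AGE_HI - mean) / sd
    return stats.truncnorm(a, b, loc=mean, scale=sd)


def _group_positive_probability(cfg: GeneratorConfig, group: Group) -> float:
    """Expected latent amyloid probability of one group (ages integrated out)."""
    p = cfg.p_amyloid_by_group[group.value]
    if p is not None:
        return p
    dist = _age_dist(*cfg.age_by_group[group.value])
    val, _ = integrate.quad(
        lambda a: prevalence_at_age(a, cfg.prevalence_by_age) * dist.pdf(a), _AGE_LO, _AGE_HI
    )
    return float(val)


def expected_positive_fraction(cfg: GeneratorConfig) -> float:
    """Expected fraction of latent amyloid-positive participants overall."""
    counts = {Group.VOLUNTEER: cfg.n_volunteers, Group.AD: cfg.n_ad, Group.NON_AD: cfg.n_nonad}
    total = sum(counts.values())
    return sum(n * _group_positive_probability(cfg, g) for g, n in counts.items()) / total


def analytic_intersection(cfg: GeneratorConfig, weighted: bool = True) -> float:
    """Crossing point of the generator's true component curves.

    The weighted variant multiplies each component by its expected overall
    mass (the population the unsupervised mixture fit sees); this is the
    value the fitted-mixture intersection estimates.
    """
    w = expected_positive_fraction(cfg) if weighted else 0.5
    fit = MixtureFit(
        weights=(w, 1.0 - w),
        means=(cfg.mu_pos, cfg.mu_neg),
        sds=(cfg.sigma_pos, cfg.sigma_neg),
        loglik=0.0,
        n_iter=0,
        converged=True,
    )
    return gaussian_intersection(fit, weighted=True).value


def _truncated_positive_normal(rng: np.random.Generator, mu: float, sigma: float, size: int):
    """Normal draws truncated to > 0 by rejection (negligible at defaults)."""
    out = rng.normal(mu, sigma, size=size)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mu, sigma, size=int(bad.sum()))
        bad = out <= 0
    return out


def _draw_delay(rng: np.random.Generator, d: Dict[str, float]) -> int:
    """Signed blood-to-amyloid delay in days (negative: exam before blood)."""
    if rng.random() < d["p_within"]:
        return int(rng.integers(-d["max_within"], d["max_within"] + 1))
    magnitude = int(rng.integers(d["max_within"] + 1, d["max_beyond"] + 1))
    sign = -1 if rng.random() < d["p_before_given_beyond"] else 1
    return sign * magnitude

def generate_cohort_with_truth(cfg: GeneratorConfig):
    """Generate a cohort plus the latent amyloid truth of every participant.

    Returns ``(cohort, truth)`` where ``truth`` maps participant id to
    ``True`` (latent amyloid-positive) or ``False``. The truth of labelled
    participants is recoverable from their CSF/Centiloid values (exactly,
    when ``label_noise`` is 0); for unlabelled participants it is
    otherwise unobservable.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    participants: list[Participant] = []
    truth: dict[str, bool] = {}
    specs = [
        (Group.VOLUNTEER, "V", cfg.n_volunteers),
        (Group.AD, "A", cfg.n_ad),
        (Group.NON_AD, "N", cfg.n_nonad),
    ]
    for group, prefix, n in specs:
        gkey = group.value
        mean, sd = cfg.age_by_group[gkey]
        a, b = (_AGE_LO - mean) / sd, (_AGE_HI - mean) / sd
        ages = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
        p_fixed = cfg.p_amyloid_by_group[gkey]
        p_pos = np.full(n, p_fixed) if p_fixed is not None else prevalence_at_age(ages, cfg.prevalence_by_age)
        for i in range(n):
            pid = f"{prefix}{i + 1:04d}"
            pos = bool(rng.random() < p_pos[i])
            truth[pid] = pos
            mu, sigma = (cfg.mu_pos, cfg.sigma_pos) if pos else (cfg.mu_neg, cfg.sigma_neg)
            ratio = float(_truncated_positive_normal(rng, mu, sigma, 1)[0])
            ab40 = float(_truncated_positive_normal(rng, cfg.ab40_mean, cfg.ab40_sd, 1)[0])
            demented = bool(rng.random() < cfg.p_dementia_by_group[gkey])
            mkey = "demented" if demented else "non_demented"
            mmse_mu, mmse_sd = cfg.mmse_params[mkey]
            lo, hi = (0, 23) if demented else (24, 30)
            mmse = int(np.clip(round(rng.normal(mmse_mu, mmse_sd)), lo, hi))
            carrier_p = cfg.p_e4_given_pos if pos else cfg.p_e4_given_neg
            if rng.random() < carrier_p:
                apoe = _CARRIER_GENOTYPES[rng.choice(3, p=_CARRIER_P)]
            else:
                apoe = _NONCARRIER_GENOTYPES[rng.choice(3, p=_NONCARRIER_P)]
            sex = Sex.FEMALE if rng.random() < cfg.p_female_by_group[gkey] else Sex.MALE
            blood_date = _BASE_DATE + _dt.timedelta(days=int(rng.integers(-180, 181)))

            csf = centiloid = tracer = None
            amyloid_date = None
            if rng.random() < cfg.labeled_fraction_by_group[gkey]:
                observed_pos = pos if rng.random() >= cfg.label_noise else not pos
                if rng.random() < cfg.p_csf:
                    csf = float(rng.uniform(180.0, 437.0)) if observed_pos else float(rng.uniform(438.5, 1100.0))
                else:
                    centiloid = float(rng.uniform(27.0, 120.0)) if observed_pos else float(rng.uniform(-8.0, 26.0))
                    tracer = "pib" if rng.random() < cfg.p_pib_given_pet else "flutemetamol"
                amyloid_date = blood_date + _dt.timedelta(days=_draw_delay(rng, cfg.delay_days_distribution))
            participants.append(
                Participant(
                    id=pid,
                    group=group,
                    age=float(ages[i]),
                    sex=sex,
                    mmse=mmse,
                    apoe=apoe,
                    ab42_plasma=ratio * ab40,
                    ab40_plasma=ab40,
                    ratio=None,  # recomputed from the concentrations
                    csf_ab42=csf,
                    centiloid=centiloid,
                    pet_tracer=tracer,
                    blood_date=blood_date,
                    amyloid_date=amyloid_date,
                )
            )
    return Cohort(participants), truth


def generate_cohort(cfg: GeneratorConfig) -> Cohort:
    """Generate a reproducible synthetic cohort (see module docstring)."""
    cohort, _ = generate_cohort_with_truth(cfg)
    return cohort
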