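"""Synthetic glioma cohorts under the dilution model.

The generator embodies the mechanism by which paucicellular specimens produce
false-negative MGMT results: a bulk methylation signal is the purity-weighted
mixture of the tumor-cell signal and a low non-neoplastic background,

    observed = f * signal_tumor + (1 - f) * signal_background + noise,

with tumor fraction f = min(2 * VAF, 1) for a heterozygous clonal driver.
Truly methylated tumors at low VAF thus fall below the pyrosequencing
positivity cutoff, while unmethylated tumors stay negative at any purity.

Defaults emulate the structure of a real single-institution glioma cohort:
subtype mix ~68/21/11% (IDH-wildtype GBM / IDH-mutant astrocytoma /
oligodendroglioma), methylation prevalence 35/70/96% by subtype, and mean
driver VAF 0.34-0.39 via subtype-specific Beta draws scaled to [0, 0.5].
All generator constants are synthetic design choices; they are not estimates
of any real cohort's signal parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import Assay, Call, CohortTable, DriverGene, GliomaSample, Subtype
from .curves import CumulativeCurve, Statistic

__all__ = [
    "SimConfig",
    "expected_observed_score",
    "simulate_cohort",
    "make_hinge_curve",
    "make_step_cohort",
    "analytic_positivity_noise_free",
]


def _default_mix() -> dict[Subtype, float]:
    return {
        Subtype.GBM_IDHWT: 0.68,
        Subtype.ASTRO_IDHMUT: 0.21,
        Subtype.OLIGO_IDHMUT_CODEL: 0.11,
    }


def _default_prevalence() -> dict[Subtype, float]:
    return {
        Subtype.GBM_IDHWT: 0.35,
        Subtype.ASTRO_IDHMUT: 0.70,
        Subtype.OLIGO_IDHMUT_CODEL: 0.96,
    }


def _default_vaf_beta() -> dict[Subtype, tuple[float, float]]:
    # 0.5 * Beta(a, b) means: GBM 0.34, astro 0.38, oligo 0.39
    return {
        Subtype.GBM_IDHWT: (3.4, 1.6),
        Subtype.ASTRO_IDHMUT: (3.8, 1.2),
        Subtype.OLIGO_IDHMUT_CODEL: (3.9, 1.1),
    }


@dataclass
class SimConfig:
    """Full parameterization of the dilution-model cohort generator.

    Signal parameters are percent methylation: ``mu_meth`` is the mean
    per-CpG signal of a truly methylated tumor's cells, ``mu_unmeth`` of an
    unmethylated tumor's cells, ``mu_background`` of non-neoplastic cells.
    ``sigma_signal`` spreads per-site tumor signals and the shared per-sample
    background draw; ``sigma_noise`` is per-site measurement noise.
    ``micro_bias_slope`` adds +slope*(1-f) percentage points to the
    microscopic cellularity estimate, reproducing microscopy's tendency to
    overestimate cellularity in paucicellular specimens.
    """

    n: int = 500
    subtype_mix: dict = field(default_factory=_default_mix)
    prevalence_by_subtype: dict = field(default_factory=_default_prevalence)
    vaf_beta_params: dict = field(default_factory=_default_vaf_beta)
    mu_meth: float = 30.0
    mu_unmeth: float = 3.0
    mu_background: float = 2.0
    sigma_signal: float = 8.0
    sigma_noise: float = 2.0
    micro_bias_slope: float = 30.0
    micro_sigma: float = 8.0
    pyro_cutoff: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be positive, got {self.n}")
        mix = np.array([self.subtype_mix[st] for st in Subtype])
        if np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError("subtype_mix must be nonnegative and sum to 1")
        for st in Subtype:
            p = self.prevalence_by_subtype[st]
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence for {st.value} outside [0, 1]")
            a, b = self.vaf_beta_params[st]
            if a <= 0 or b <= 0:
                raise ValueError(f"Beta parameters for {st.value} must be positive")
        for name in ("sigma_signal", "sigma_noise", "micro_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not self.mu_background < self.pyro_cutoff < self.mu_meth:
            raise ValueError(
                "must have mu_background < pyro_cutoff < mu_meth "
                f"({self.mu_background}, {self.pyro_cutoff}, {self.mu_meth})"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["subtype_mix"] = {st.value: v for st, v in self.subtype_mix.items()}
        d["prevalence_by_subtype"] = {
            st.value: v for st, v in self.prevalence_by_subtype.items()
        }
        d["vaf_beta_params"] = {
            st.value: list(v) for st, v in self.vaf_beta_params.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key, conv in (
            ("subtype_mix", float),
            ("prevalence_by_subtype", float),
            ("vaf_beta_params", tuple),
        ):
            if key in d:
                d[key] = {Subtype[k.upper()]: conv(v) for k, v in d[key].items()}
        return cls(**d)


def expected_observed_score(
    f: float, s_tumor: float, s_background: float
) -> float:
    """Noise-free bulk signal: f * s_tumor + (1 - f) * s_background."""
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"tumor fraction {f} outside [0, 1]")
    for name, v in (("s_tumor", s_tumor), ("s_background", s_background)):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} {v} outside [0, 100]")
    return f * s_tumor + (1.0 - f) * s_background


def simulate_cohort(config: SimConfig) -> tuple[CohortTable, pd.DataFrame]:
    """Draw a synthetic pyrosequencing cohort plus its latent truth table.

    Deterministic given ``config.seed``. Per sample: subtype ~ mix, true
    methylation ~ Bernoulli(subtype prevalence), VAF ~ 0.5*Beta(subtype
    params), f = min(2*VAF, 1). Four per-CpG tumor signals are drawn around
    ``mu_meth`` or ``mu_unmeth``; one shared background draw per sample makes
    the sites correlate through purity. Each observed site is the dilution
    mixture plus measurement noise, clamped to [0, 100]; the pyrosequencing
    score is the mean of the four observed sites, called at ``pyro_cutoff``.

    Returns ``(cohort, truth)`` where ``truth`` holds the latent
    ``true_methylated``, ``tumor_fraction`` and mean latent tumor signal —
    never mixed into the cohort table.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n
    subtype_list = list(Subtype)
    mix = np.array([config.subtype_mix[st] for st in subtype_list], dtype=float)
    mix = mix / mix.sum()
    subtype_idx = rng.choice(len(subtype_list), size=n, p=mix)

    alpha = np.array([config.vaf_beta_params[subtype_list[i]][0] for i in subtype_idx])
    beta = np.array([config.vaf_beta_params[subtype_list[i]][1] for i in subtype_idx])
    vaf = 0.5 * rng.beta(alpha, beta)
    prev = np.array(
        [config.prevalence_by_subtype[subtype_list[i]] for i in subtype_idx]
    )
    truly_meth = rng.random(n) < prev
    f = np.minimum(2.0 * vaf, 1.0)

    mu_sites = np.where(truly_meth, config.mu_meth, config.mu_unmeth)
    sites = rng.normal(mu_sites[:, None], config.sigma_signal, size=(n, 4))
    sites = np.clip(sites, 0.0, 100.0)
    background = np.clip(
        rng.normal(config.mu_background, config.sigma_signal, size=n), 0.0, 100.0
    )
    observed = (
        f[:, None] * sites
        + (1.0 - f)[:, None] * background[:, None]
        + rng.normal(0.0, config.sigma_noise, size=(n, 4))
    )
    observed = np.clip(observed, 0.0, 100.0)
    score = observed.mean(axis=1)

    micro = np.clip(
        100.0 * f
        + config.micro_bias_slope * (1.0 - f)
        + rng.normal(0.0, config.micro_sigma, size=n),
        0.0,
        100.0,
    )
    # annotations: IDH1 vs IDH2 for IDH-mutant tumors, sex, age
    idh2 = rng.random(n) < 0.15
    sex = np.where(rng.random(n) < 0.6, "M", "F")
    age_mu = np.array([64.0, 40.0, 45.0])[subtype_idx]
    age = np.clip(np.rint(rng.normal(age_mu, 12.0)), 18, 95).astype(int)

    width = len(str(n))
    samples = []
    for i in range(n):
        st = subtype_list[subtype_idx[i]]
        if st is Subtype.GBM_IDHWT:
            gene = DriverGene.TERTP
        else:
            gene = DriverGene.IDH2 if idh2[i] else DriverGene.IDH1
        site_vals = tuple(round(float(v), 6) for v in observed[i])
        s_score = sum(site_vals) / 4.0
        samples.append(
            GliomaSample(
                sample_id=f"SIM-{i + 1:0{width}d}",
                subtype=st,
                driver_gene=gene,
                driver_vaf=float(vaf[i]),
                assay=Assay.PYRO,
                mgmt_score=s_score,
                mgmt_call=Call.POSITIVE
                if s_score >= config.pyro_cutoff
                else Call.NEGATIVE,
                site_percents=site_vals,
                micro_cellularity=float(micro[i]),
                sex=str(sex[i]),
                age=int(age[i]),
            )
        )
    truth = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "subtype": [s.subtype.value for s in samples],
            "true_methylated": truly_meth,
            "tumor_fraction": f,
            "true_site_signal": sites.mean(axis=1),
        }
    )
    cohort = CohortTable(samples, provenance=f"simulate:seed={config.seed}:n={n}")
    return cohort, truth


def analytic_positivity_noise_free(config: SimConfig) -> float:
    """Expected positivity rate in the noise-free limit of the generator.

    With all sigmas zero, a truly methylated sample is positive iff
    f * mu_meth + (1 - f) * mu_background >= pyro_cutoff, i.e. iff its Beta
    draw exceeds a closed-form threshold; unmethylated samples are positive
    iff the same holds with mu_unmeth (never, under the default geometry).
    Integrates the indicator over the subtype mix and VAF distributions.
    """
    from scipy.stats import beta as beta_dist

    config.validate()
    total = 0.0
    for st in Subtype:
        w = config.subtype_mix[st]
        prev = config.prevalence_by_subtype[st]
        a, b = config.vaf_beta_params[st]
        for mu_tumor, p_state in (
            (config.mu_meth, prev),
            (config.mu_unmeth, 1.0 - prev),
        ):
            if mu_tumor == config.mu_background:
                p_pos = 1.0 if config.mu_background >= config.pyro_cutoff else 0.0
            else:
                f_star = (config.pyro_cutoff - config.mu_background) / (
                    mu_tumor - config.mu_background
                )
                if mu_tumor > config.mu_background:
                    # positive iff f >= f_star; f = Beta draw (since f = 2 * 0.5 * Beta)
                    p_pos = float(beta_dist.sf(f_star, a, b)) if f_star <= 1 else 0.0
                    if f_star < 0:
                        p_pos = 1.0
                else:
                    p_pos = float(beta_dist.cdf(f_star, a, b)) if f_star >= 0 else 0.0
            total += w * p_state * p_pos
    return total


def make_hinge_curve(
    knee: float,
    low_slope: float,
    plateau: float,
    grid_step: float = 0.02,
    noise_sd: float = 0.0,
    seed: int = 0,
    x_max: float = 0.5,
) -> CumulativeCurve:
    """Piecewise-linear hinge on a VAF grid, optionally with Gaussian noise.

    y = plateau + low_slope * (x - knee) for x <= knee, y = plateau beyond;
    noise_sd = 0 gives the exact hinge. Values are clipped to [0, 1] so the
    curve remains a valid positivity curve. Same seed, same curve.
    """
    if not 0.0 < knee < x_max:
        raise ValueError(f"knee {knee} outside (0, {x_max})")
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    x = np.arange(grid_step, x_max + grid_step / 2, grid_step)
    y = np.where(x <= knee, plateau + low_slope * (x - knee), plateau)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=x.size)
    y = np.clip(y, 0.0, 1.0)
    return CumulativeCurve(
        vaf_ranked=x,
        cumulative_value=y,
        statistic=Statistic.MEAN_POSITIVITY,
        n_at_point=np.arange(1, x.size + 1),
    )


def make_step_cohort(
    n: int = 500,
    step_vaf: float = 0.20,
    p_low: float = 0.10,
    p_high: float = 0.60,
    seed: int = 0,
) -> CohortTable:
    """Cohort with a sharp positivity step at ``step_vaf``.

    VAFs are uniform on (0.01, 0.5); each sample is POSITIVE with probability
    ``p_high`` at or above the step and ``p_low`` below it. Used to exercise
    cutpoint-scan recovery of a known dilution threshold.
    """
    if not (0.0 <= p_low <= 1.0 and 0.0 <= p_high <= 1.0):
        raise ValueError("positivity probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    vaf = rng.uniform(0.01, 0.5, size=n)
    p = np.where(vaf >= step_vaf, p_high, p_low)
    pos = rng.random(n) < p
    width = len(str(n))
    samples = [
        GliomaSample(
            sample_id=f"STEP-{i + 1:0{width}d}",
            subtype=Subtype.GBM_IDHWT,
            driver_gene=DriverGene.TERTP,
            driver_vaf=float(vaf[i]),
            assay=Assay.PYRO,
            mgmt_score=30.0 if pos[i] else 3.0,
            mgmt_call=Call.POSITIVE if pos[i] else Call.NEGATIVE,
        )
        for i in range(n)
    ]
    return CohortTable(samples, provenance=f"step:seed={seed}:n={n}")
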