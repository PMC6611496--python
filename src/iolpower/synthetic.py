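"""Synthetic surgical cohorts with the statistical structure the pipeline assumes.

The generator emulates a cataract-surgery population: biometry marginals
(age, mean keratometry, anterior chamber depth, axial length) are truncated
normals matching the study population's summary statistics; the
pre-operative refraction is a right-skewed (skew-normal) variable,
negatively correlated with axial length through a Gaussian copula (long
eyes are myopic).  A configurable share of patients contributes both eyes,
with strongly correlated fellow-eye biometry.

Surgical outcomes are produced by the forward vergence model: the clinic
implants the SRK/T emmetropic power computed with the *surgeon's*
A-constant (rounded to the commercial 0.5 D step), while the eye's true
effective lens position is the SRK/T prediction at the *true* A-constant
plus a Gaussian per-eye deviation.  The gap between the two constants
induces the systematic myopic bias of the clinical baseline; lens-step
rounding, ELP deviation, measurement noise and 0.125 D refraction
quantization make up the error budget.  Latent ground truth (true ELP, the
power that would have zeroed the refraction, the noise-free outcome) is
emitted separately and never shown to the models.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import COHORT_COLUMNS
from .optics import (
    OpticsConstants,
    clinical_iol_choice,
    iol_for_emmetropia,
    rx_theor_post,
    srkt_elp,
)

__all__ = [
    "MarginalSpec",
    "SyntheticConfig",
    "sample_biometry",
    "simulate_surgery",
    "simulate_outcome",
    "generate_cohort",
]


@dataclass(frozen=True)
class MarginalSpec:
    """Truncated-normal (or skew-normal if ``skew`` != 0) marginal parameters."""

    mean: float
    std: float
    min: float
    max: float
    skew: float = 0.0

    def _frozen(self):
        if self.skew == 0.0:
            a = (self.min - self.mean) / self.std
            b = (self.max - self.mean) / self.std
            return stats.truncnorm(a, b, loc=self.mean, scale=self.std)
        # skew-normal with loc/scale solved from the target mean/std
        delta = self.skew / np.sqrt(1.0 + self.skew**2)
        scale = self.std / np.sqrt(1.0 - 2.0 * delta**2 / np.pi)
        loc = self.mean - scale * delta * np.sqrt(2.0 / np.pi)
        return stats.skewnorm(self.skew, loc=loc, scale=scale)

    def ppf_from_uniform(self, u: np.ndarray) -> np.ndarray:
        """Quantile transform of uniforms, truncated to [min, max]."""
        if self.std == 0.0:
            return np.full_like(np.asarray(u, dtype=float), self.mean)
        dist = self._frozen()
        lo, hi = dist.cdf(self.min), dist.cdf(self.max)
        if not hi > lo:
            raise ValueError("infeasible truncation for marginal")
        return dist.ppf(lo + np.asarray(u, dtype=float) * (hi - lo))


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition parameters of the synthetic cohort.

    Marginal defaults reproduce the study population's selection-set
    characteristics.  ``a_constant_surgeon`` exceeds ``a_constant_true`` by
    a fixed offset calibrated once so the clinical baseline's mean signed
    error lands near -0.46 D; ``sigma_elp_mm`` and ``sigma_meas_d`` set the
    unpredictable part of the outcome (see docs/methods.md for the variance
    budget).
    """

    n_eyes: int = 2194
    seed: int = 0
    age: MarginalSpec = MarginalSpec(56.89, 7.25, 36.0, 78.0)
    k: MarginalSpec = MarginalSpec(43.27, 1.40, 39.39, 47.51)
    acd: MarginalSpec = MarginalSpec(3.10, 0.32, 2.21, 4.10)
    al: MarginalSpec = MarginalSpec(23.03, 0.92, 19.94, 26.26)
    rx_pre: MarginalSpec = MarginalSpec(1.85, 1.52, -3.88, 6.63, skew=3.0)
    rho_al_rxpre: float = -0.40
    rho_fellow: float = 0.85
    fellow_eye_fraction: float = 0.30
    sigma_elp_mm: float = 0.25
    sigma_meas_d: float = 0.15
    rx_quantum_d: float = 0.125
    a_constant_true: float = 119.1
    a_constant_surgeon: float = 119.54
    contamination_fraction: float = 0.0
    optics: OpticsConstants = OpticsConstants()

    def true_consts(self) -> OpticsConstants:
        return replace(self.optics, a_constant=self.a_constant_true)

    def surgeon_consts(self) -> OpticsConstants:
        return replace(self.optics, a_constant=self.a_constant_surgeon)


_BIOM_VARS = ("age_years", "k_d", "acd_mm", "al_mm", "rx_pre_d")


def sample_biometry(
    config: SyntheticConfig,
    n: Optional[int] = None,
    seed: Optional[int | np.random.Generator] = None,
) -> pd.DataFrame:
    """Draw per-eye biometry with patient/eye structure.

    A Gaussian copula imposes the axial-length/pre-operative-refraction
    correlation and, for patients contributing both eyes, a strong
    within-patient correlation of every biometric variable (age is shared
    exactly).  Marginals are preserved by construction.
    """
    n = config.n_eyes if n is None else n
    if seed is None:
        rng = np.random.default_rng(config.seed)
    elif isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(seed)

    # patient layout: two-eye patients until the fellow fraction is met
    patient_ids: list = []
    eyes: list = []
    pid = 0
    i = 0
    while i < n:
        both = (rng.random() < config.fellow_eye_fraction) and (i + 1 < n)
        if both:
            patient_ids += [pid, pid]
            eyes += ["right", "left"]
            i += 2
        else:
            patient_ids += [pid]
            eyes += [rng.choice(["right", "left"])]
            i += 1
        pid += 1
    patient_ids_arr = np.asarray(patient_ids)
    n_pat = pid

    # latent standard normals: patient-level and eye-level, blended for
    # fellow-eye correlation; age is a pure patient-level trait
    rho_f = config.rho_fellow
    z = {}
    for var in ("k_d", "acd_mm", "al_mm", "rx_raw"):
        z_pat = rng.standard_normal(n_pat)[patient_ids_arr]
        z_eye = rng.standard_normal(n)
        z[var] = np.sqrt(rho_f) * z_pat + np.sqrt(1.0 - rho_f) * z_eye
    z_age = rng.standard_normal(n_pat)[patient_ids_arr]

    # cross-variable copula: Rx_pre latent correlated with AL latent
    rho = config.rho_al_rxpre
    z_rx = rho * z["al_mm"] + np.sqrt(1.0 - rho**2) * z["rx_raw"]

    u = {k: stats.norm.cdf(v) for k, v in
         (("age_years", z_age), ("k_d", z["k_d"]), ("acd_mm", z["acd_mm"]),
          ("al_mm", z["al_mm"]), ("rx_pre_d", z_rx))}
    spec_by_var = {
        "age_years": config.age, "k_d": config.k, "acd_mm": config.acd,
        "al_mm": config.al, "rx_pre_d": config.rx_pre,
    }
    data = {var: spec_by_var[var].ppf_from_uniform(u[var]) for var in _BIOM_VARS}
    data["age_years"] = np.round(data["age_years"])

    df = pd.DataFrame(data)
    df.insert(0, "eye", eyes)
    df.insert(0, "patient_id", [f"P{p:05d}" for p in patient_ids_arr])
    df.insert(0, "eye_id", [f"E{j:05d}" for j in range(n)])
    return df


def simulate_surgery(
    biometry: pd.DataFrame, config: SyntheticConfig
) -> np.ndarray:
    """Implanted IOL power per eye: the clinic's SRK/T emmetropic choice.

    Uses the surgeon's (possibly non-optimized) A-constant, rounded to the
    commercial step and clamped to the available range.
    """
    consts = config.surgeon_consts()
    return np.array(
        [
            clinical_iol_choice(k, al, consts)
            for k, al in zip(biometry["k_d"], biometry["al_mm"])
        ]
    )


def simulate_outcome(
    biometry: pd.DataFrame,
    iol_implanted: np.ndarray,
    config: SyntheticConfig,
    seed: Optional[int | np.random.Generator] = None,
) -> Tuple[np.ndarray, pd.DataFrame]:
    """Post-operative refraction via the forward vergence model + ground truth.

    true ELP = SRK/T prediction at the true A-constant plus N(0, sigma_elp);
    the clean outcome is the vergence-model refraction of the implanted lens
    at the true ELP; the observed outcome adds measurement noise and is
    quantized to the refraction step.  Returns ``(rx_post, ground_truth)``
    where the ground-truth frame holds true_elp_mm, iol_required_d and
    rx_post_clean_d per eye.
    """
    if seed is None:
        rng = np.random.default_rng(config.seed + 1)
    elif isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(seed)
    consts = config.true_consts()
    n = len(biometry)
    iol_implanted = np.asarray(iol_implanted, dtype=float)

    true_elp = np.empty(n)
    iol_req = np.empty(n)
    rx_clean = np.empty(n)
    for i, (k, al, impl) in enumerate(
        zip(biometry["k_d"], biometry["al_mm"], iol_implanted)
    ):
        pred_elp = srkt_elp(float(k), float(al), consts).elp_mm
        for _ in range(100):  # bounded resampling on degenerate geometry
            elp = pred_elp + rng.normal(0.0, config.sigma_elp_mm)
            if 0.5 < elp < float(al) - 5.0:
                break
        else:
            raise RuntimeError("could not draw a feasible true ELP")
        true_elp[i] = elp
        iol_req[i] = iol_for_emmetropia(float(k), float(al), elp, consts)
        rx_clean[i] = rx_theor_post(float(k), float(al), elp, float(impl), consts)

    noisy = rx_clean + rng.normal(0.0, config.sigma_meas_d, size=n)
    q = config.rx_quantum_d
    rx_post = np.round(noisy / q) * q if q > 0 else noisy
    truth = pd.DataFrame(
        {
            "eye_id": biometry["eye_id"].to_numpy(),
            "true_elp_mm": true_elp,
            "iol_required_d": iol_req,
            "rx_post_clean_d": rx_clean,
        }
    )
    return rx_post, truth


def _ancillary_fields(n: int, rng: np.random.Generator) -> Dict[str, np.ndarray]:
    """Filter-passing defaults for acuities, astigmatism, delay and texts."""
    cdva_post = np.round(np.abs(rng.normal(0.05, 0.05, n)), 2).clip(0.0, 0.3)
    udva_post = np.round(cdva_post + np.abs(rng.normal(0.05, 0.05, n)), 2)
    cdva_pre = np.round(np.abs(rng.normal(0.3, 0.15, n)), 2)
    udva_pre = np.round(cdva_pre + np.abs(rng.normal(0.2, 0.15, n)), 2)
    astig = np.round(np.abs(rng.normal(0.8, 0.5, n)), 2).clip(0.0, 3.0)
    days = rng.integers(25, 90, n).astype(float)
    empty = np.array([""] * n, dtype=object)
    return {
        "udva_pre": udva_pre, "cdva_pre": cdva_pre,
        "udva_post": udva_post, "cdva_post": cdva_post,
        "astig_pre_d": astig, "days_postop": days,
        "surgery_text": empty.copy(), "finding_text": empty.copy(),
        "diagnosis_text": empty.copy(),
    }


def _contaminate(df: pd.DataFrame, fraction: float, rng: np.random.Generator) -> None:
    """Inject filter-violating values into a random subset of cases (in place)."""
    if fraction <= 0:
        return
    n = len(df)
    n_bad = int(round(fraction * n))
    idx = rng.choice(df.index.to_numpy(), size=n_bad, replace=False)
    modes = rng.integers(0, 5, n_bad)
    for j, mode in zip(idx, modes):
        if mode == 0:
            df.loc[j, "diagnosis_text"] = "st. p. LASIK OU"
        elif mode == 1:
            df.loc[j, "finding_text"] = "cornea guttata centralis"
        elif mode == 2:
            df.loc[j, "astig_pre_d"] = 3.5
        elif mode == 3:
            df.loc[j, "cdva_post"] = 0.4
        else:
            df.loc[j, "days_postop"] = 10.0


def generate_cohort(
    config: SyntheticConfig = SyntheticConfig(),
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Full synthetic cohort ready for the pipeline, plus latent ground truth.

    Composes biometry sampling, the clinic's lens choice, the forward
    outcome model and filter-passing ancillary fields; optionally
    contaminates a configured share of cases with filter-violating entries
    (keywords, astigmatism, acuity, follow-up delay).  Deterministic for a
    fixed ``config.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x10C)))
    biometry = sample_biometry(config, seed=rng)
    iol = simulate_surgery(biometry, config)
    rx_post, truth = simulate_outcome(biometry, iol, config, seed=rng)
    cohort = biometry.copy()
    cohort["iol_implanted_d"] = iol
    cohort["rx_post_d"] = rx_post
    for k, v in _ancillary_fields(len(cohort), rng).items():
        cohort[k] = v
    _contaminate(cohort, config.contamination_fraction, rng)
    return cohort[COHORT_COLUMNS], truth
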