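"""Synthetic mark-recapture growth data with known ground truth.

Emulates the structure of a multi-year salmonid tagging study: several
populations (each mapped to a species) sampled once a year in September,
fish first catchable at age 1, sparse individual trajectories produced by
annual survival and capture probabilities, individual random effects on
all three growth-curve parameters, and Gaussian measurement error on
length. Optionally, fish are only recorded from the first capture at
which they exceed a tagging length threshold (small fish cannot carry a
tag). The generator can also draw the asymptote and rate effects from a
correlated bivariate normal, which the fitted model — whose priors stay
independent — should recover as an emergent individual-level correlation
between asymptotic size and growth rate.

Capture and survival rates of the real study are not published; the
defaults here are plausible placeholders for stream salmonids and are
documented as such in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curves import GompertzParams, VbgfParams, gompertz_length, vbgf_length
from .design import GrowthDataset

__all__ = ["SimulationConfig", "generate", "summarize_truth"]

# population label -> species label, mirroring a 3-species / 4-population design
DEFAULT_POPULATIONS = {
    "LIdri_MT": "MT",
    "UIdri_MT": "MT",
    "LIdri_RT": "RT",
    "UVol_BT": "BT",
}

# natural-scale (asymptote mm, rate 1/yr, location yr) per population
DEFAULT_TRUE_VBGF = {
    "LIdri_MT": (330.0, 0.35, -0.30),
    "UIdri_MT": (318.0, 0.38, -0.30),
    "LIdri_RT": (331.0, 0.33, -0.40),
    "UVol_BT": (222.0, 0.60, -0.20),
}

DEFAULT_TRUE_GOMPERTZ = {
    "LIdri_MT": (326.0, 0.55, 0.90),
    "UIdri_MT": (318.0, 0.58, 0.90),
    "LIdri_RT": (331.0, 0.52, 1.00),
    "UVol_BT": (222.0, 0.85, 0.60),
}


@dataclass
class SimulationConfig:
    """Study-design and generative parameters.

    populations : mapping population label -> species label.
    fish_per_population : tagged fish simulated per population.
    cohorts : candidate birth years.
    age_first_capture / max_age : September captures happen at integer
        ages in [age_first_capture, max_age].
    capture_prob : annual probability a live fish is captured.
    survival : annual survival probability after the first capture age.
    tag_threshold_mm : fish are recorded only from their first capture
        with length > threshold (None disables thresholding).
    true_params : population -> (asymptote, rate, location) on the
        natural scale; defaults themed on stream salmonids.
    sigma_* : random-effect sds on the link scales (asymptote and rate:
        log scale; location: identity) and observation-error sd in mm.
    rho_asym_rate : correlation between the asymptote and rate effects
        (generator-only; the fitted model keeps independent priors).
    """

    populations: dict = field(default_factory=lambda: dict(DEFAULT_POPULATIONS))
    fish_per_population: int = 150
    cohorts: tuple = (2004, 2005, 2006, 2007, 2008, 2009, 2010, 2011)
    age_first_capture: int = 1
    max_age: int = 8
    capture_prob: float = 0.7
    survival: float = 0.6
    tag_threshold_mm: float | None = 115.0
    function: str = "vbgf"
    true_params: dict | None = None
    sigma_asym: float = 0.15
    sigma_rate: float = 0.15
    sigma_loc: float = 0.3
    sigma_eps: float = 5.0
    rho_asym_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.capture_prob <= 1.0 and 0.0 <= self.survival <= 1.0):
            raise ValueError("capture_prob and survival must be in [0, 1]")
        for s in (self.sigma_asym, self.sigma_rate, self.sigma_loc, self.sigma_eps):
            if s < 0:
                raise ValueError("sigmas must be >= 0")
        if not (-1.0 < self.rho_asym_rate < 1.0):
            raise ValueError("|rho_asym_rate| must be < 1")
        if self.function not in ("vbgf", "gompertz"):
            raise ValueError(f"unknown growth function {self.function!r}")
        if self.true_params is None:
            base = DEFAULT_TRUE_VBGF if self.function == "vbgf" else DEFAULT_TRUE_GOMPERTZ
            self.true_params = {p: base.get(p, next(iter(base.values())))
                                for p in self.populations}


def _curve(function: str, ages: np.ndarray, asym: float, rate: float, loc: float):
    if function == "vbgf":
        return vbgf_length(ages, VbgfParams(L_inf=asym, k=rate, t0=loc))
    return gompertz_length(ages, GompertzParams(A=asym, k_G=rate, T_i=loc))


def generate(config: SimulationConfig) -> tuple[GrowthDataset, pd.DataFrame]:
    """Simulate a dataset plus its ground-truth table.

    Returns (dataset, truth); truth has one row per recorded fish with
    the drawn standardized effects and the natural-scale individual
    parameters. Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    rows, truth_rows = [], []
    cov = np.array(
        [[1.0, config.rho_asym_rate], [config.rho_asym_rate, 1.0]]
    )
    chol = np.linalg.cholesky(cov)
    ages_all = np.arange(config.age_first_capture, config.max_age + 1)

    for pop, species in config.populations.items():
        mu_asym, mu_rate, mu_loc = config.true_params[pop]
        for i in range(config.fish_per_population):
            fish_id = f"{pop}_{i:04d}"
            cohort = int(rng.choice(config.cohorts))
            v_u = chol @ rng.standard_normal(2)  # (asymptote, rate) effects
            v, u = float(v_u[0]), float(v_u[1])
            z = float(rng.standard_normal())
            asym = mu_asym * np.exp(config.sigma_asym * v)
            rate = mu_rate * np.exp(config.sigma_rate * u)
            loc = mu_loc + config.sigma_loc * z

            # survival then capture, year by year; alive at first capture age
            alive = np.empty(ages_all.size, dtype=bool)
            alive[0] = True
            for a in range(1, ages_all.size):
                alive[a] = alive[a - 1] and (rng.random() < config.survival)
            captured = alive & (rng.random(ages_all.size) < config.capture_prob)
            if not captured.any():
                continue
            ages = ages_all[captured]
            true_len = _curve(config.function, ages.astype(float), asym, rate, loc)
            lengths = true_len + rng.normal(0.0, config.sigma_eps, size=ages.size)

            if config.tag_threshold_mm is not None:
                # fish enters the record at its first capture above threshold
                big = lengths > config.tag_threshold_mm
                if not big.any():
                    continue
                first = int(np.argmax(big))
                ages, lengths = ages[first:], lengths[first:]
            keep = lengths > 0
            ages, lengths = ages[keep], lengths[keep]
            if ages.size == 0:
                continue
            for a, ln in zip(ages, lengths):
                rows.append(
                    {
                        "fish_id": fish_id,
                        "species": species,
                        "population": pop,
                        "cohort": cohort,
                        "age": float(a),
                        "length": float(ln),
                        "season": f"Sep-{cohort + int(a)}",
                    }
                )
            truth_rows.append(
                {
                    "fish_id": fish_id,
                    "species": species,
                    "population": pop,
                    "cohort": cohort,
                    "effect_asymptote": v,
                    "effect_rate": u,
                    "effect_location": z,
                    "asymptote": asym,
                    "rate": rate,
                    "location": loc,
                }
            )
    if not rows:
        raise ValueError("configuration produced zero observations")
    data = GrowthDataset(pd.DataFrame(rows))
    truth = pd.DataFrame(truth_rows).set_index("fish_id")
    return data, truth


def summarize_truth(dataset: GrowthDataset, truth: pd.DataFrame):
    """Per-population summaries of the generated truth.

    Returns (param_summary, size_at_age): mean/sd of the natural-scale
    individual parameters per population, and mean/sd of recorded length
    per population and age.
    """
    param_summary = (
        truth.groupby("population")[["asymptote", "rate", "location"]]
        .agg(["mean", "std", "count"])
    )
    size_at_age = (
        dataset.frame.groupby(["population", "age"])["length"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    return param_summary, size_at_age
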