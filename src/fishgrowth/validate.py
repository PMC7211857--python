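"""Held-out prediction protocol, accuracy measures and model ranking.

The protocol mirrors a single-observation forecasting task on
mark-recapture data: (i) find fish captured at least ``min_captures``
times; (ii) randomly sample a fraction of them as test fish; (iii) keep
only each test fish's earliest observation in the training data; (iv)
refit the model; (v) predict the deleted observations from the test
fish's empirical-Bayes effects (estimated from that single retained
capture); (vi) score the predictions with R^2 against the 1:1
predicted-observed line and the maximum absolute error. The split is
redrawn ``n_replicates`` times (five by default) and the accuracy
measures are averaged; candidate models are ranked by mean R^2, with a
model eligible for ranking only if its full-data fit and every replicate
fit converged. The same replicate splits are reused across candidate
models so the comparison is paired.

Also here: individual-level correlation analyses — the asymptote-rate
Pearson correlation within populations (a positive value means size
ranks tend to be maintained through life) and cross-growth-function
agreement of asymptotes and of size-at-age predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import GrowthDataset, ModelSpec
from .model import FitOptions, GrowthModel, GrowthResults

__all__ = [
    "Accuracy",
    "ValidationReport",
    "select_test_fish",
    "mask_test_observations",
    "r2_identity_line",
    "run_validation",
    "rank_correlation_analysis",
    "cross_function_comparison",
    "predict_length",
]


def predict_length(fit: GrowthResults, fish_id, age, fallback_labels=None) -> pd.DataFrame:
    """Predicted length-at-age (with delta-method SE) for fitted fish.

    Thin functional wrapper over :meth:`GrowthResults.predict`.
    """
    return fit.predict(fish_id, age, fallback_labels=fallback_labels)


def select_test_fish(
    data: GrowthDataset, min_captures: int = 4, fraction: float = 1.0 / 3.0,
    seed: int | np.random.Generator = 0,
) -> list:
    """Deterministically sample test fish among the frequently captured.

    Eligible fish have at least ``min_captures`` records (the default 4
    reads "sampled more than three times" strictly); ``floor(fraction x
    n_eligible)`` of them are drawn without replacement.
    """
    if min_captures < 2:
        raise ValueError("min_captures must be >= 2 (need held-out records)")
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    counts = data.capture_counts()
    eligible = [f for f in data.fish_ids if counts[f] >= min_captures]
    n_test = int(np.floor(fraction * len(eligible)))
    if not eligible or n_test == 0:
        import warnings

        warnings.warn("no eligible test fish under the given settings")
        return []
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    picked = rng.choice(len(eligible), size=n_test, replace=False)
    return [eligible[i] for i in sorted(picked)]


def mask_test_observations(
    data: GrowthDataset, test_ids: Sequence
) -> tuple[GrowthDataset, pd.DataFrame]:
    """Keep only each test fish's earliest observation; return the rest.

    Returns (masked_dataset, held_out_frame). Non-test fish are
    untouched; masked and held-out rows partition the original records.
    """
    test_set = set(test_ids)
    unknown = test_set - set(data.fish_ids)
    if unknown:
        raise ValueError(f"test ids not in dataset: {sorted(map(str, unknown))}")
    fr = data.frame
    is_test = fr["fish_id"].isin(test_set).to_numpy()
    # rows are sorted by fish then age, so the first row of a fish is its earliest
    first_of_fish = ~fr.duplicated(subset="fish_id").to_numpy()
    keep = ~is_test | first_of_fish
    held_out = fr.loc[~keep].copy()
    masked = data.subset_rows(keep)
    return masked, held_out


class Accuracy(NamedTuple):
    """R^2 against the 1:1 line and the largest absolute error (mm)."""

    r2: float
    max_error: float


def r2_identity_line(predicted, observed) -> Accuracy:
    """R^2 of predictions with respect to the 1:1 predicted-observed line.

    ``1 - sum((obs - pred)^2) / sum((obs - mean(obs))^2)``; can be
    negative for predictions worse than the observed mean. Undefined
    (NaN) when the observations have zero variance.
    """
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise ValueError("predicted and observed must be equal-length 1-D arrays")
    if obs.size < 2:
        raise ValueError("need at least two observations")
    max_err = float(np.max(np.abs(obs - pred)))
    denom = float(np.sum((obs - obs.mean()) ** 2))
    if denom == 0.0:
        return Accuracy(float("nan"), max_err)
    return Accuracy(1.0 - float(np.sum((obs - pred) ** 2)) / denom, max_err)


@dataclass
class ValidationReport:
    """Per-model, per-replicate accuracy plus full-data AIC and ranking."""

    records: pd.DataFrame  # one row per (model, replicate)
    full_fits: dict = field(default_factory=dict)  # label -> GrowthResults

    def table(self) -> pd.DataFrame:
        """Ranking table: mean/sd of R^2 over replicates, AIC, eligibility.

        Sorted by mean R^2 (descending); models with any non-converged
        fit are flagged ineligible and sorted to the bottom.
        """
        rows = []
        for label, grp in self.records.groupby("model", sort=False):
            fit = self.full_fits.get(label)
            full_ok = bool(fit is not None and fit.converged)
            reps_ok = bool(grp["converged"].all())
            eligible = full_ok and reps_ok
            r2 = grp.loc[grp["converged"], "r2"]
            rows.append(
                {
                    "model": label,
                    "function": grp["function"].iloc[0],
                    "r2_mean": float(r2.mean()) if len(r2) else float("nan"),
                    "r2_sd": float(r2.std(ddof=1)) if len(r2) > 1 else float("nan"),
                    "max_error_mean": float(grp.loc[grp["converged"], "max_error"].mean())
                    if len(r2)
                    else float("nan"),
                    "aic": fit.aic if full_ok else float("nan"),
                    "n_replicates": int(len(grp)),
                    "n_converged": int(grp["converged"].sum()),
                    "rank_eligible": eligible,
                }
            )
        df = pd.DataFrame(rows)
        return df.sort_values(
            ["rank_eligible", "r2_mean"], ascending=[False, False]
        ).reset_index(drop=True)


def run_validation(
    data: GrowthDataset,
    specs: Sequence[ModelSpec],
    n_replicates: int = 5,
    min_captures: int = 4,
    fraction: float = 1.0 / 3.0,
    seed: int = 0,
    fit_options: FitOptions | None = None,
) -> ValidationReport:
    """Full-data fit + masked refits and held-out accuracy per model.

    The test-fish draws are derived from ``seed`` once and shared across
    all candidate specs; per-replicate fit failures are recorded in the
    report, never raised.
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    ss = np.random.SeedSequence(seed)
    rep_rngs = [np.random.default_rng(s) for s in ss.spawn(n_replicates)]
    splits = []
    for rng in rep_rngs:
        test_ids = select_test_fish(data, min_captures, fraction, seed=rng)
        splits.append(mask_test_observations(data, test_ids) + (test_ids,))

    rows = []
    full_fits: dict = {}
    for spec in specs:
        label = spec.label
        try:
            full_fits[label] = GrowthModel(data, spec).fit(options=fit_options)
        except Exception:
            full_fits[label] = None
        for rep, (masked, held_out, test_ids) in enumerate(splits):
            rec = {
                "model": label,
                "function": spec.function,
                "replicate": rep,
                "n_test_fish": len(test_ids),
                "n_predictions": len(held_out),
                "converged": False,
                "r2": float("nan"),
                "max_error": float("nan"),
            }
            try:
                fit = GrowthModel(masked, spec).fit(options=fit_options)
                if fit.converged and len(held_out) >= 2:
                    pred = fit.predict(
                        held_out["fish_id"].to_numpy(), held_out["age"].to_numpy()
                    )
                    acc = r2_identity_line(
                        pred["predicted_length"].to_numpy(), held_out["length"].to_numpy()
                    )
                    rec.update(converged=True, r2=acc.r2, max_error=acc.max_error)
            except Exception:
                pass
            rows.append(rec)
    return ValidationReport(records=pd.DataFrame(rows), full_fits=full_fits)


def rank_correlation_analysis(fit: GrowthResults, min_fish: int = 3) -> pd.DataFrame:
    """Within-population Pearson correlation of individual asymptote vs rate.

    A positive correlation indicates that size ranks tend to be
    maintained through the life of individuals. Populations with fewer
    than ``min_fish`` fish or zero variance get NaN (reported, not
    raised). The p-value is the usual two-sided t-transform.
    """
    ip = fit.individual_parameters()
    rows = []
    for pop, grp in ip.groupby("population", sort=False):
        n = len(grp)
        r = p = float("nan")
        if n >= min_fish:
            a, k = grp["asymptote"].to_numpy(), grp["rate"].to_numpy()
            if np.std(a) > 0 and np.std(k) > 0:
                res = stats.pearsonr(a, k)
                r, p = float(res.statistic), float(res.pvalue)
        rows.append({"population": pop, "n_fish": n, "r": r, "p_value": p})
    return pd.DataFrame(rows)


def cross_function_comparison(
    fit_a: GrowthResults, fit_b: GrowthResults
) -> dict:
    """Agreement between two fitted growth functions on the same data.

    Returns the Pearson correlation of the per-fish asymptote estimates,
    the Pearson correlation of the per-observation size-at-age
    predictions at every observed (fish, age), and the paired scatter
    data frames behind both. Asymptote estimates can disagree wildly
    while predictions agree almost perfectly: asymptotes extrapolate,
    predictions interpolate.
    """
    da, db = fit_a.model.data, fit_b.model.data
    if da.fish_ids != db.fish_ids:
        raise ValueError("fits must share the same fish")
    ia = fit_a.individual_parameters()["asymptote"]
    ib = fit_b.individual_parameters()["asymptote"]
    asym = pd.DataFrame({"asymptote_a": ia, "asymptote_b": ib})
    r_asym = float(stats.pearsonr(asym["asymptote_a"], asym["asymptote_b"]).statistic)

    fr = da.frame
    pa = fit_a.predict(fr["fish_id"].to_numpy(), fr["age"].to_numpy())
    pb = fit_b.predict(fr["fish_id"].to_numpy(), fr["age"].to_numpy())
    preds = pd.DataFrame(
        {
            "fish_id": fr["fish_id"],
            "age": fr["age"],
            "pred_a": pa["predicted_length"].to_numpy(),
            "pred_b": pb["predicted_length"].to_numpy(),
        }
    )
    r_pred = float(stats.pearsonr(preds["pred_a"], preds["pred_b"]).statistic)
    return {
        "r_asymptote": r_asym,
        "r_predictions": r_pred,
        "asymptotes": asym,
        "predictions": preds,
    }
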