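"""Data model and design-matrix machinery.

A :class:`GrowthDataset` holds long-format mark-recapture records (one row
per capture of a tagged fish). A :class:`ModelSpec` names a growth function
and assigns, to each of its three parameters (asymptote, rate, location),
a set of fixed-effect predictor terms plus an on/off switch for the
per-individual random effect.

Each growth parameter gets its own per-individual design matrix (group
covariates are constant within a fish). Coding is treatment coding with
the reference level being the first level in order of first appearance in
the dataset, so the coding is deterministic and locale-independent. The
asymptote and rate use a log link (they must stay positive); the location
parameter (t0 of the vBGF or T_i of the Gompertz) uses the identity link.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GrowthDataset",
    "ModelSpec",
    "ParameterSet",
    "ParameterLayout",
    "DesignMatrices",
    "build_design_matrices",
    "design_rows_for_labels",
    "linear_predictors",
]

PARAM_NAMES = ("asymptote", "rate", "location")

_REQUIRED = ("fish_id", "species", "population", "age", "length")
_CATEGORICAL = ("species", "population", "cohort")


def _levels_in_order(values) -> list:
    """Unique values in order of first appearance."""
    seen: dict = {}
    for v in values:
        if v not in seen:
            seen[v] = None
    return list(seen)


class GrowthDataset:
    """Long-format individual capture records with categorical registries.

    Parameters
    ----------
    frame : DataFrame with columns fish_id, species, population, age,
        length; optional cohort, season and numeric covariate columns.
    levels : optional mapping column -> ordered level list, used to pin
        categorical codings when a dataset is derived from another one
        (e.g. the masked training set of a validation split).
    """

    def __init__(self, frame: pd.DataFrame, levels: dict | None = None):
        missing = [c for c in _REQUIRED if c not in frame.columns]
        if missing:
            raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")
        df = frame.copy()
        df["age"] = pd.to_numeric(df["age"], errors="raise").astype(float)
        df["length"] = pd.to_numeric(df["length"], errors="raise").astype(float)
        if len(df) == 0:
            raise ValueError("dataset is empty")
        bad = df.index[~np.isfinite(df["age"]) | (df["age"] < 0)]
        if len(bad):
            raise ValueError(f"age must be finite and >= 0 (row {bad[0]})")
        bad = df.index[~np.isfinite(df["length"]) | (df["length"] <= 0)]
        if len(bad):
            raise ValueError(f"length must be finite and > 0 (row {bad[0]})")

        dup = df.duplicated(subset=["fish_id", "age"])
        if dup.any():
            row = df.index[dup][0]
            raise ValueError(f"duplicate (fish_id, age) record at row {row}")
        for col in ("species", "population", "cohort"):
            if col in df.columns:
                n = df.groupby("fish_id", sort=False)[col].nunique(dropna=False)
                conflicted = n[n > 1]
                if len(conflicted):
                    raise ValueError(
                        f"fish {conflicted.index[0]!r} has inconsistent {col!r} labels"
                    )

        # stable order: fish in order of first appearance, ages increasing
        fish_order = {f: i for i, f in enumerate(_levels_in_order(df["fish_id"]))}
        df = df.assign(_forder=df["fish_id"].map(fish_order))
        df = df.sort_values(["_forder", "age"], kind="stable").drop(columns="_forder")
        df = df.reset_index(drop=True)

        self.frame = df
        self.fish_ids: list = _levels_in_order(df["fish_id"])
        self._fish_index = {f: i for i, f in enumerate(self.fish_ids)}
        self.levels: dict = {}
        for col in _CATEGORICAL:
            if col in df.columns:
                found = _levels_in_order(df[col].dropna())
                if levels and col in levels:
                    pinned = list(levels[col])
                    extra = [v for v in found if v not in pinned]
                    if extra:
                        raise ValueError(f"unknown {col} level(s): {extra}")
                    self.levels[col] = pinned
                else:
                    self.levels[col] = found
        # one row per fish, in fish order, carrying the individual-constant columns
        keep = [c for c in df.columns if c not in ("fish_id", "age", "length", "season")]
        self.fish_table = df.groupby("fish_id", sort=False)[keep].first().loc[self.fish_ids]

    # -- basic accessors -------------------------------------------------
    @property
    def n_fish(self) -> int:
        return len(self.fish_ids)

    @property
    def n_obs(self) -> int:
        return len(self.frame)

    def fish_index(self) -> np.ndarray:
        """Integer fish index (0..n_fish-1) for every observation row."""
        return self.frame["fish_id"].map(self._fish_index).to_numpy()

    def capture_counts(self) -> pd.Series:
        return self.frame.groupby("fish_id", sort=False)["age"].size().loc[self.fish_ids]

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, levels: dict | None = None) -> "GrowthDataset":
        return cls(frame, levels=levels)

    def subset_rows(self, mask: np.ndarray) -> "GrowthDataset":
        """New dataset from a boolean row mask, keeping this one's codings."""
        return GrowthDataset(self.frame.loc[np.asarray(mask)], levels=self.levels)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GrowthDataset(n_fish={self.n_fish}, n_obs={self.n_obs})"


@dataclass(frozen=True)
class ModelSpec:
    """Growth function + per-parameter predictor assignment.

    Each of ``asymptote``, ``rate`` and ``location`` is a predictor term
    (or tuple of terms): ``"constant"`` for intercept only, a categorical
    column name (``"species"``, ``"population"``, ``"cohort"``), a declared
    continuous covariate name, or a two-way interaction ``"a:b"``. The
    intercept is always included. ``random_effects`` switches the
    individual effect per parameter, in (asymptote, rate, location) order.
    """

    function: str = "vbgf"
    asymptote: str | tuple = "constant"
    rate: str | tuple = "constant"
    location: str | tuple = "constant"
    random_effects: tuple = (True, True, True)
    covariates: tuple = ()

    def __post_init__(self):
        if self.function not in ("vbgf", "gompertz"):
            raise ValueError(f"unknown growth function {self.function!r}")
        if len(self.random_effects) != 3:
            raise ValueError("random_effects must have exactly three entries")
        for key in ("asymptote", "rate", "location"):
            t = getattr(self, key)
            object.__setattr__(self, key, (t,) if isinstance(t, str) else tuple(t))
        object.__setattr__(self, "random_effects", tuple(bool(b) for b in self.random_effects))
        object.__setattr__(self, "covariates", tuple(self.covariates))

    def terms(self, param: str) -> tuple:
        t = getattr(self, param)
        if isinstance(t, str):
            t = (t,)
        return tuple(t)

    @property
    def label(self) -> str:
        sym = {
            "vbgf": ("Linf", "k", "t0"),
            "gompertz": ("A", "kG", "Ti"),
        }[self.function]

        def tname(param):
            ts = [t for t in self.terms(param) if t != "constant"]
            return "+".join(t.capitalize() for t in ts) if ts else "Constant"

        return (
            f"{self.function}: {sym[0]}({tname('asymptote')}), "
            f"{sym[1]}({tname('rate')}), {sym[2]}({tname('location')})"
        )

    def to_dict(self) -> dict:
        return {
            "function": self.function,
            "asymptote": list(self.terms("asymptote")),
            "rate": list(self.terms("rate")),
            "location": list(self.terms("location")),
            "random_effects": list(self.random_effects),
            "covariates": list(self.covariates),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        kwargs = dict(d)
        for key in ("asymptote", "rate", "location"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        if "random_effects" in kwargs:
            kwargs["random_effects"] = tuple(kwargs["random_effects"])
        if "covariates" in kwargs:
            kwargs["covariates"] = tuple(kwargs["covariates"])
        return cls(**kwargs)

    def with_function(self, function: str) -> "ModelSpec":
        return replace(self, function=function)


def _dummies(data, col: str) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded indicators for the non-reference levels of col."""
    if col not in data.levels:
        raise ValueError(f"categorical column {col!r} not present in dataset")
    levels = data.levels[col]
    if col not in data.fish_table.columns:
        raise ValueError(f"no value supplied for categorical column {col!r}")
    values = data.fish_table[col].to_numpy()
    unknown = {v for v in values if not pd.isna(v)} - set(levels)
    if unknown:
        raise ValueError(f"unknown {col} level(s): {sorted(map(str, unknown))}")
    cols, names = [], []
    for lev in levels[1:]:
        cols.append((values == lev).astype(float))
        names.append(f"{col}[{lev}]")
    if not cols:
        return np.empty((data.n_fish, 0)), []
    return np.column_stack(cols), names


def _term_columns(data, spec: ModelSpec, term: str):
    if term == "constant":
        return np.empty((data.n_fish, 0)), []
    if ":" in term:
        a, b = term.split(":", 1)
        Xa, na = _term_columns(data, spec, a)
        Xb, nb = _term_columns(data, spec, b)
        cols, names = [], []
        for i, ni in enumerate(na):
            for j, nj in enumerate(nb):
                cols.append(Xa[:, i] * Xb[:, j])
                names.append(f"{ni}:{nj}")
        if not cols:
            return np.empty((data.n_fish, 0)), []
        return np.column_stack(cols), names
    if term in _CATEGORICAL:
        return _dummies(data, term)
    if term in spec.covariates:
        if term not in data.fish_table.columns:
            raise ValueError(f"covariate column {term!r} not present in dataset")
        x = pd.to_numeric(data.fish_table[term], errors="raise").to_numpy(dtype=float)
        return x[:, None], [term]
    raise ValueError(
        f"unknown predictor term {term!r}: not a categorical column, a declared "
        f"covariate, or 'constant'"
    )


@dataclass
class DesignMatrices:
    """Per-parameter design matrices, one row per fish."""

    X: dict  # param name -> (n_fish, p) array
    names: dict  # param name -> coefficient name list

    def ncols(self, param: str) -> int:
        return self.X[param].shape[1]


def build_design_matrices(data: GrowthDataset, spec: ModelSpec) -> DesignMatrices:
    """Build the three treatment-coded design matrices (intercept first)."""
    X, names = {}, {}
    for param in PARAM_NAMES:
        blocks = [np.ones((data.n_fish, 1))]
        cnames = ["intercept"]
        for term in spec.terms(param):
            Xt, nt = _term_columns(data, spec, term)
            blocks.append(Xt)
            cnames.extend(nt)
        X[param] = np.column_stack(blocks)
        names[param] = [f"{param}.{n}" for n in cnames]
    return DesignMatrices(X=X, names=names)


class _DesignContext:
    """Minimal stand-in for a GrowthDataset when building ad-hoc rows."""

    def __init__(self, levels: dict, fish_table: pd.DataFrame):
        self.levels = levels
        self.fish_table = fish_table
        self.n_fish = len(fish_table)


def design_rows_for_labels(data: GrowthDataset, spec: ModelSpec, labels: dict) -> dict:
    """Design rows for a hypothetical individual with the given labels.

    Returns a mapping parameter -> (p,) row, using the dataset's level
    registries; used for group-mean-curve predictions of fish that were
    not part of the fitted dataset.
    """
    shim = _DesignContext(data.levels, pd.DataFrame([labels]))
    rows = {}
    for param in PARAM_NAMES:
        blocks = [np.ones((1, 1))]
        for term in spec.terms(param):
            Xt, _ = _term_columns(shim, spec, term)
            blocks.append(Xt)
        rows[param] = np.column_stack(blocks)[0]
    return rows


@dataclass
class ParameterSet:
    """One full estimation state: fixed effects + log standard deviations.

    ``log_sigma`` entries are None for switched-off random effects (the
    corresponding sd is exactly 0 and is not part of the estimation
    vector); ``log_sigma_eps`` is the log observation-error sd (mm).
    """

    beta: dict  # param name -> coefficient array
    log_sigma: dict  # param name -> float | None
    log_sigma_eps: float

    def sigma(self, param: str) -> float:
        ls = self.log_sigma[param]
        return 0.0 if ls is None else float(np.exp(ls))

    @property
    def sigma_eps(self) -> float:
        return float(np.exp(self.log_sigma_eps))


@dataclass
class ParameterLayout:
    """Deterministic packing of a ParameterSet into one flat vector.

    Order: asymptote coefficients, rate coefficients, location
    coefficients, then the active random-effect log-sds in (asymptote,
    rate, location) order, then the log observation-error sd.
    """

    design: DesignMatrices
    active: tuple  # (bool, bool, bool) in PARAM_NAMES order
    names: list = field(init=False)

    def __post_init__(self):
        names = []
        for p in PARAM_NAMES:
            names.extend(self.design.names[p])
        for p, on in zip(PARAM_NAMES, self.active):
            if on:
                names.append(f"log_sigma.{p}")
        names.append("log_sigma.eps")
        self.names = names

    @property
    def size(self) -> int:
        return len(self.names)

    def pack(self, theta: ParameterSet) -> np.ndarray:
        parts = [np.asarray(theta.beta[p], dtype=float) for p in PARAM_NAMES]
        for p, c in zip(PARAM_NAMES, parts):
            if c.shape != (self.design.ncols(p),):
                raise ValueError(
                    f"{p} coefficient block has length {c.shape}, "
                    f"expected ({self.design.ncols(p)},)"
                )
        sds = []
        for p, on in zip(PARAM_NAMES, self.active):
            if on:
                if theta.log_sigma[p] is None:
                    raise ValueError(f"active random effect {p!r} has no log_sigma")
                sds.append(float(theta.log_sigma[p]))
        sds.append(float(theta.log_sigma_eps))
        return np.concatenate(parts + [np.asarray(sds)])

    def unpack(self, x: np.ndarray) -> ParameterSet:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.size,):
            raise ValueError(f"expected vector of length {self.size}, got {x.shape}")
        beta, pos = {}, 0
        for p in PARAM_NAMES:
            n = self.design.ncols(p)
            beta[p] = x[pos : pos + n].copy()
            pos += n
        log_sigma = {}
        for p, on in zip(PARAM_NAMES, self.active):
            if on:
                log_sigma[p] = float(x[pos])
                pos += 1
            else:
                log_sigma[p] = None
        return ParameterSet(beta=beta, log_sigma=log_sigma, log_sigma_eps=float(x[pos]))


def linear_predictors(
    theta: ParameterSet,
    effects: np.ndarray,
    design: DesignMatrices,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Natural-scale per-fish growth parameters.

    ``effects`` is (n_fish, 3) of standardized individual effects in
    (asymptote, rate, location) order; a switched-off effect contributes
    nothing regardless of the stored value because its sd is exactly 0.

    Returns (asymptote, rate, location): the first two through the exp of
    their linear predictor (log link), the location on the identity scale.
    """
    effects = np.asarray(effects, dtype=float)
    n_fish = design.X["asymptote"].shape[0]
    if effects.shape != (n_fish, 3):
        raise ValueError(f"effects must have shape ({n_fish}, 3), got {effects.shape}")
    eta = {}
    for j, p in enumerate(PARAM_NAMES):
        Xb = design.X[p] @ np.asarray(theta.beta[p], dtype=float)
        if Xb.shape != (n_fish,):
            raise ValueError(f"coefficient block for {p!r} has the wrong length")
        eta[p] = Xb + theta.sigma(p) * effects[:, j]
    return np.exp(eta["asymptote"]), np.exp(eta["rate"]), eta["location"]
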